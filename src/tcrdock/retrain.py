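"""Scoring-weight retraining by multi-start downhill simplex on hit/non-hit AUC.

The training signal is the mean area under the ROC curve for separating hit
from non-hit models among the top-30 ranked models of each decoy case (AUC in
its Mann–Whitney form: the probability that a random hit scores better, i.e.
lower, than a random non-hit, ties counted 0.5). Weights are selected by
running a Nelder–Mead downhill simplex from many random non-negative starting
points and keeping the best restart; the reference protocol uses 12,000
restarts. Cross-validation folds never place two cases sharing a TCR on
opposite sides of the split.

The module exposes both the functional operations (:func:`auc_for_case`,
:func:`objective`, :func:`optimize_weights`, :func:`build_cv_folds`) and a
model/results pair (:class:`WeightTraining` → :class:`WeightTrainingResults`)
for interactive use.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import rankdata

from .scoring import TERM_NAMES, WeightVector

__all__ = [
    "DecoyCase",
    "TrainConfig",
    "auc_from_scores",
    "auc_for_case",
    "objective",
    "optimize_weights",
    "build_cv_folds",
    "WeightTraining",
    "WeightTrainingResults",
    "read_decoy_tsv",
    "write_decoy_tsv",
    "load_decoy_cases",
]

N_TERMS = len(TERM_NAMES)


@dataclass
class DecoyCase:
    """One docking case's decoy set: per-model energy terms and hit labels."""

    case_id: str
    tcr_id: str
    terms: np.ndarray                  # (n_models, 8)
    labels: np.ndarray                 # bool, True = hit
    model_ids: list[str] = field(default_factory=list)
    baseline_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.terms = np.asarray(self.terms, float)
        self.labels = np.asarray(self.labels, bool)
        if self.terms.ndim != 2 or self.terms.shape[1] != N_TERMS:
            raise ValueError(f"terms must be (n_models, {N_TERMS})")
        if len(self.labels) != len(self.terms):
            raise ValueError("label/term count mismatch")
        if not self.model_ids:
            self.model_ids = [f"model_{i}" for i in range(len(self.terms))]
        if self.baseline_scores is not None:
            self.baseline_scores = np.asarray(self.baseline_scores, float)
        if len(self.terms) < 30:
            warnings.warn(f"case {self.case_id}: only {len(self.terms)} models; "
                          "fewer than the preferred 30")

    @property
    def n_models(self) -> int:
        return len(self.terms)


@dataclass
class TrainConfig:
    """Optimizer settings; the defaults are the reference protocol."""

    n_random_starts: int = 12000
    seed: int = 0
    top_k: int = 30
    k_folds: int = 3
    selection_mode: str = "self"   # "self": top-k by the candidate weights'
    #                                own ranking; "baseline": by a fixed prior
    start_range: tuple[float, float] = (0.0, 2.0)
    simplex_step: float = 0.5      # initial simplex edge; large, because the
    #                                AUC surface is piecewise constant
    xatol: float = 1e-3
    fatol: float = 1e-6
    maxfev: int = 1000

    def __post_init__(self) -> None:
        if self.n_random_starts < 1:
            raise ValueError("need at least one random start")
        if self.top_k < 2:
            raise ValueError("top_k must be at least 2")
        if self.selection_mode not in ("self", "baseline"):
            raise ValueError("selection_mode must be 'self' or 'baseline'")


# ---------------------------------------------------------------------------
# AUC and the training objective
# ---------------------------------------------------------------------------

def auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(random hit scores lower than random non-hit),
    ties counted 0.5. Requires both classes present."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)           # average ranks handle ties as 0.5
    u_gt = ranks[labels].sum() - n1 * (n1 + 1) / 2.0   # hit-worse-than-nonhit pairs
    return 1.0 - u_gt / (n1 * n0)


def auc_for_case(case: DecoyCase, weights, top_k: int = 30,
                 selection_mode: str = "self") -> float | None:
    """Hit/non-hit AUC among the case's top-k ranked models.

    Ranking for the top-k selection uses the candidate weights' own scores
    (``self`` mode) or the fixed baseline ranking (``baseline`` mode). When
    the selected models are single-class the AUC is undefined and ``None`` is
    returned; callers exclude such cases from the mean.
    """
    w = weights.as_array() if isinstance(weights, WeightVector) else np.asarray(weights, float)
    scores = case.terms @ w
    if selection_mode == "baseline":
        if case.baseline_scores is None:
            raise ValueError(f"case {case.case_id} has no baseline scores")
        ranking = case.baseline_scores
    else:
        ranking = scores
    k = min(top_k, case.n_models)
    idx = np.argpartition(ranking, k - 1)[:k]
    sub_labels = case.labels[idx]
    if sub_labels.all() or not sub_labels.any():
        return None
    return auc_from_scores(scores[idx], sub_labels)


def objective(cases, weights, top_k: int = 30, selection_mode: str = "self",
              warn_undefined: bool = True) -> float:
    """Unweighted mean AUC over the cases with a defined AUC."""
    values, undefined = [], []
    for case in cases:
        auc = auc_for_case(case, weights, top_k, selection_mode)
        if auc is None:
            undefined.append(case.case_id)
        else:
            values.append(auc)
    if undefined and warn_undefined:
        warnings.warn(f"single-class top-{top_k} for case(s) {undefined}; "
                      "excluded from the mean AUC")
    if not values:
        raise ValueError("no case has a defined AUC under these weights")
    return float(np.mean(values))


def _neg_objective(cases, top_k, selection_mode):
    terms = [np.ascontiguousarray(c.terms) for c in cases]
    labels = [c.labels for c in cases]
    baselines = [c.baseline_scores for c in cases]

    def f(w):
        w = np.maximum(w, 0.0)   # non-negative weights: clamp at the boundary
        total, n = 0.0, 0
        for t, lab, base in zip(terms, labels, baselines):
            s = t @ w
            ranking = base if selection_mode == "baseline" else s
            k = min(top_k, len(s))
            idx = np.argpartition(ranking, k - 1)[:k]
            sl = lab[idx]
            n1 = int(sl.sum())
            if n1 == 0 or n1 == k:
                continue
            ranks = rankdata(s[idx])
            total += 1.0 - (ranks[sl].sum() - n1 * (n1 + 1) / 2.0) / (n1 * (k - n1))
            n += 1
        return -(total / n) if n else 1.0
    return f


def optimize_weights(cases, config: TrainConfig | None = None,
                     ) -> tuple[WeightVector, float, pd.DataFrame]:
    """Multi-start downhill simplex maximizing the mean top-k AUC.

    Deterministic given the seed. Returns the best (non-negative) weight
    vector over all restarts, its objective value, and a per-start trace of
    the converged objectives.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    neg = _neg_objective(cases, cfg.top_k, cfg.selection_mode)
    lo, hi = cfg.start_range
    best_x, best_f = None, np.inf
    trace = []
    for i in range(cfg.n_random_starts):
        x0 = rng.uniform(lo, hi, N_TERMS)
        sim = np.vstack([x0, x0 + np.eye(N_TERMS) * cfg.simplex_step])
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"initial_simplex": sim, "xatol": cfg.xatol,
                                "fatol": cfg.fatol, "maxfev": cfg.maxfev})
        trace.append((i, -res.fun))
        if res.fun < best_f:
            best_f, best_x = res.fun, np.maximum(res.x, 0.0)
    trace = pd.DataFrame(trace, columns=["start", "objective"])
    return WeightVector.from_array(best_x), -best_f, trace


def build_cv_folds(cases, k: int, seed: int = 0) -> list[tuple[list, list]]:
    """k train/test partitions where cases sharing a TCR stay together.

    Returns ``[(train_cases, test_cases), ...]``; each fold's test set is one
    part of the partition. TCR-identity groups are shuffled by the seed and
    assigned greedily to the currently-smallest fold, so fold sizes differ by
    at most one group.
    """
    groups: dict[str, list] = {}
    for c in cases:
        groups.setdefault(c.tcr_id, []).append(c)
    if k > len(groups):
        raise ValueError(f"cannot build {k} folds from {len(groups)} distinct TCR(s)")
    rng = np.random.default_rng(seed)
    names = sorted(groups)
    rng.shuffle(names)
    names.sort(key=lambda n: -len(groups[n]))
    folds: list[list] = [[] for _ in range(k)]
    for name in names:
        folds[min(range(k), key=lambda i: (len(folds[i]), i))].extend(groups[name])
    out = []
    for i in range(k):
        test = folds[i]
        train = [c for j in range(k) if j != i for c in folds[j]]
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class WeightTraining:
    """Weight-retraining model over a collection of decoy cases.

    Parameters
    ----------
    cases : list of DecoyCase
    config : TrainConfig, optional
    """

    def __init__(self, cases, config: TrainConfig | None = None):
        self.cases = list(cases)
        if not self.cases:
            raise ValueError("no decoy cases")
        self.config = config or TrainConfig()

    @classmethod
    def from_directory(cls, path, config: TrainConfig | None = None) -> "WeightTraining":
        return cls(load_decoy_cases(path), config)

    def evaluate(self, weights) -> float:
        """Mean top-k AUC of an arbitrary weight vector on these cases."""
        return objective(self.cases, weights, self.config.top_k,
                         self.config.selection_mode, warn_undefined=False)

    def fit(self, n_starts: int | None = None) -> "WeightTrainingResults":
        cfg = self.config
        if n_starts is not None:
            cfg = TrainConfig(**{**cfg.__dict__, "n_random_starts": n_starts})
        weights, value, trace = optimize_weights(self.cases, cfg)
        return WeightTrainingResults(self, weights, value, trace, cfg)

    def cross_validate(self, n_starts: int | None = None) -> pd.DataFrame:
        """Same-TCR-constrained k-fold CV; one row per fold with the train
        and held-out mean AUC of the weights fitted on that fold's train set."""
        cfg = self.config
        if n_starts is not None:
            cfg = TrainConfig(**{**cfg.__dict__, "n_random_starts": n_starts})
        rows = []
        for f, (train, test) in enumerate(build_cv_folds(self.cases, cfg.k_folds,
                                                         cfg.seed)):
            w, train_auc, _ = optimize_weights(train, cfg)
            test_auc = objective(test, w, cfg.top_k, cfg.selection_mode,
                                 warn_undefined=False)
            rows.append({"fold": f, "n_train": len(train), "n_test": len(test),
                         "train_auc": train_auc, "test_auc": test_auc,
                         **{f"w_{n}": v for n, v in zip(TERM_NAMES, w.as_array())}})
        return pd.DataFrame(rows)


class WeightTrainingResults:
    """Fitted weights with their objective value and restart trace."""

    def __init__(self, model: WeightTraining, params: WeightVector,
                 objective_value: float, trace: pd.DataFrame, config: TrainConfig):
        self.model = model
        self.params = params
        self.objective_value = objective_value
        self.trace = trace
        self.config = config

    def per_case_auc(self) -> pd.DataFrame:
        rows = []
        for c in self.model.cases:
            auc = auc_for_case(c, self.params, self.config.top_k,
                               self.config.selection_mode)
            rows.append({"case_id": c.case_id, "tcr_id": c.tcr_id,
                         "n_models": c.n_models, "auc": auc})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Scoring-weight retraining (multi-start downhill simplex)",
            "=" * 58,
            f"cases: {len(self.model.cases)}   restarts: {self.config.n_random_starts}"
            f"   top-k: {self.config.top_k} ({self.config.selection_mode} ranking)",
            f"mean top-{self.config.top_k} AUC: {self.objective_value:.4f}",
            "-" * 58,
            f"{'term':<14}{'weight':>10}{'ZRT ref':>10}{'ZR2 ref':>10}",
        ]
        zrt, zr2 = WeightVector.zrt().as_array(), WeightVector.zr2().as_array()
        for name, w, a, b in zip(TERM_NAMES, self.params.as_array(), zrt, zr2):
            lines.append(f"{name:<14}{w:>10.3f}{a:>10.3f}{b:>10.3f}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"weights": dict(zip(TERM_NAMES, self.params.as_array())),
                       "objective": self.objective_value,
                       "n_random_starts": self.config.n_random_starts,
                       "top_k": self.config.top_k,
                       "selection_mode": self.config.selection_mode},
                      fh, indent=1)


# ---------------------------------------------------------------------------
# Decoy-case I/O (TSV per case + a JSON manifest of TCR identities)
# ---------------------------------------------------------------------------

def write_decoy_tsv(case: DecoyCase, path) -> None:
    df = pd.DataFrame(case.terms, columns=list(TERM_NAMES))
    df.insert(0, "model", case.model_ids)
    df["label"] = case.labels.astype(int)
    if case.baseline_scores is not None:
        df["baseline_score"] = case.baseline_scores
    df.to_csv(path, sep="\t", index=False)


def read_decoy_tsv(path, case_id: str | None = None, tcr_id: str = "") -> DecoyCase:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("model", "label", *TERM_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    base = df["baseline_score"].to_numpy() if "baseline_score" in df.columns else None
    return DecoyCase(case_id or Path(path).stem, tcr_id,
                     df[list(TERM_NAMES)].to_numpy(),
                     df["label"].to_numpy().astype(bool),
                     df["model"].astype(str).tolist(), base)


def load_decoy_cases(directory) -> list[DecoyCase]:
    """Read every ``*.tsv`` decoy case in a directory; ``tcr_ids.json`` maps
    case ids to TCR identities for the CV constraint."""
    directory = Path(directory)
    tcr_map = {}
    manifest = directory / "tcr_ids.json"
    if manifest.exists():
        tcr_map = json.loads(manifest.read_text())
    cases = []
    for f in sorted(directory.glob("*.tsv")):
        cid = f.stem
        cases.append(read_decoy_tsv(f, cid, tcr_map.get(cid, cid)))
    if not cases:
        raise ValueError(f"no decoy case TSVs in {directory}")
    return cases
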