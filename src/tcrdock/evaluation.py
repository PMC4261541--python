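"""CAPRI-criteria assessment of docking models against a bound reference.

Models are classified high / medium / acceptable / incorrect from the
fraction of native contacts (fnat), the ligand RMSD (TCR backbone after
superposing the receptor) and the interface RMSD. Antigen atoms count when
determining native contacts and interface residues, but only protein backbone
atoms ever enter an RMSD. Models of medium or high accuracy are "hits".
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structio import AnnotatedComplex, TCR_ROLES, residue_correspondence
from .geometry import backbone_rmsd

__all__ = [
    "CapriThresholds",
    "CapriMetrics",
    "CaseReport",
    "CapriEvaluator",
    "native_contacts",
    "fnat",
    "interface_selection",
    "capri_metrics",
    "case_report",
    "pool_reports",
]

_RECEPTOR_ROLES = ("mhc_platform", "mhc_other", "antigen")
ACCURACY_ORDER = {"incorrect": 0, "acceptable": 1, "medium": 2, "high": 3}


@dataclass(frozen=True)
class CapriThresholds:
    """Classification thresholds; the community-standard values by default."""

    contact_cutoff: float = 5.0    # Å, heavy-atom native-contact distance
    interface_cutoff: float = 10.0  # Å, heavy-atom interface-residue distance
    high: tuple[float, float, float] = (0.5, 1.0, 1.0)        # fnat, lrmsd, irmsd
    medium: tuple[float, float, float] = (0.3, 5.0, 2.0)
    acceptable: tuple[float, float, float] = (0.1, 10.0, 4.0)

    def classify(self, fnat_: float, lrmsd: float, irmsd: float) -> str:
        for name, (f, l, i) in (("high", self.high), ("medium", self.medium),
                                ("acceptable", self.acceptable)):
            if fnat_ >= f and (lrmsd <= l or irmsd <= i):
                return name
        return "incorrect"


@dataclass
class CapriMetrics:
    fnat: float
    lrmsd: float
    irmsd: float
    accuracy_class: str

    @property
    def is_hit(self) -> bool:
        return self.accuracy_class in ("medium", "high")


# ---------------------------------------------------------------------------
# Contacts and interface residues (computed on the bound reference)
# ---------------------------------------------------------------------------

def _partner_heavy(complex_: AnnotatedComplex, roles, keys=None):
    out = []
    for r in complex_.residues:
        if r.role in roles and (keys is None or r.key in keys):
            for a in r.heavy_atoms():
                out.append((r.key, a.coord))
    return out


def _residue_pairs_within(complex_: AnnotatedComplex, cutoff: float,
                          tcr_keys=None, rec_keys=None) -> set:
    tcr = _partner_heavy(complex_, TCR_ROLES, tcr_keys)
    rec = _partner_heavy(complex_, _RECEPTOR_ROLES, rec_keys)
    if not tcr or not rec:
        return set()
    d = cdist(np.array([c for _, c in tcr]), np.array([c for _, c in rec]))
    ii, jj = np.nonzero(d < cutoff)
    return {(tcr[i][0], rec[j][0]) for i, j in zip(ii, jj)}


def native_contacts(bound: AnnotatedComplex, cutoff: float = 5.0) -> set:
    """Residue pairs (TCR side, receptor side) with any inter-partner
    heavy-atom distance under the cutoff; antigen residues count as
    receptor-side contacts per the evaluation convention."""
    pairs = _residue_pairs_within(bound, cutoff)
    if not pairs:
        warnings.warn("no native contacts found in the bound reference")
    return pairs


def fnat(model: AnnotatedComplex, native_pairs: set,
         correspondence: dict | None = None, cutoff: float = 5.0) -> float:
    """Fraction of native residue contacts reproduced by the model."""
    if not native_pairs:
        raise ValueError("empty native contact set")
    mapping = correspondence if correspondence is not None else {}
    inv = {v: k for k, v in mapping.items()} if mapping else None

    def to_model(key):
        return inv.get(key, key) if inv else key

    wanted_t = {to_model(t) for t, _ in native_pairs}
    wanted_r = {to_model(r) for _, r in native_pairs}
    model_pairs = _residue_pairs_within(model, cutoff, wanted_t, wanted_r)
    preserved = sum((to_model(t), to_model(r)) in model_pairs
                    for t, r in native_pairs)
    return preserved / len(native_pairs)


def interface_selection(bound: AnnotatedComplex, cutoff: float = 10.0) -> set:
    """Bound-reference interface residues: any protein residue of either
    partner with a heavy atom within the cutoff of the other partner (antigen
    atoms included when measuring, antigen residues excluded from the set)."""
    pairs = _residue_pairs_within(bound, cutoff)
    keys = {t for t, _ in pairs} | {r for _, r in pairs}
    return {k for k in keys if bound[k].is_amino_acid}


# ---------------------------------------------------------------------------
# Per-model metrics
# ---------------------------------------------------------------------------

class CapriEvaluator:
    """Caches the bound-derived native contacts, interface set and residue
    correspondence, then assesses models one by one.

    ``evaluated_chains`` restricts the assessment to a chain subset of the
    model (e.g. TCR α chain + MR1 only, when the bound and unbound β chains
    differ in sequence).
    """

    def __init__(self, bound: AnnotatedComplex,
                 evaluated_chains: list[str] | None = None,
                 thresholds: CapriThresholds | None = None):
        self.bound = bound
        self.evaluated_chains = list(evaluated_chains) if evaluated_chains else None
        self.th = thresholds or CapriThresholds()
        self._interface = interface_selection(bound, self.th.interface_cutoff)
        self._native = native_contacts(bound, self.th.contact_cutoff)
        self._corr_cache: dict[int, dict] = {}

    def _mapping(self, model: AnnotatedComplex) -> dict:
        key = id(model)
        if key not in self._corr_cache:
            m = residue_correspondence(model, self.bound)
            if self.evaluated_chains is not None:
                m = {k: v for k, v in m.items() if k[0] in self.evaluated_chains}
            if len(self._corr_cache) > 64:
                self._corr_cache.clear()
            self._corr_cache[key] = m
        return self._corr_cache[key]

    def assess(self, model: AnnotatedComplex,
               correspondence: dict | None = None) -> CapriMetrics:
        mapping = correspondence if correspondence is not None else self._mapping(model)
        inv = {v: k for k, v in mapping.items()}
        native = {(t, r) for t, r in self._native if t in inv and r in inv}
        if not native:
            raise ValueError("no native contacts within the evaluated chains")
        f = fnat(model, native, mapping, self.th.contact_cutoff)

        rec_keys = [inv[r.key] for r in self.bound.residues
                    if r.role in ("mhc_platform", "mhc_other")
                    and r.is_amino_acid and r.key in inv]
        tcr_keys = [inv[r.key] for r in self.bound.residues
                    if r.role in TCR_ROLES and r.is_amino_acid and r.key in inv]
        lrmsd = backbone_rmsd(model, self.bound, tcr_keys, rec_keys, mapping)

        iface_keys = [inv[k] for k in self._interface if k in inv]
        if not iface_keys:
            raise ValueError("empty interface residue set within the evaluated chains")
        irmsd = backbone_rmsd(model, self.bound, iface_keys, None, mapping)
        return CapriMetrics(f, lrmsd, irmsd, self.th.classify(f, lrmsd, irmsd))


def capri_metrics(model: AnnotatedComplex, bound: AnnotatedComplex,
                  evaluated_chains: list[str] | None = None,
                  thresholds: CapriThresholds | None = None) -> CapriMetrics:
    """One-shot CAPRI assessment of a single model against a bound reference."""
    return CapriEvaluator(bound, evaluated_chains, thresholds).assess(model)


# ---------------------------------------------------------------------------
# Case reports and multi-start pooling
# ---------------------------------------------------------------------------

@dataclass
class CaseReport:
    """Ranking summary of one scored, assessed model set."""

    model_ids: list[str]                 # sorted ascending by score
    scores: list[float]
    metrics: list[CapriMetrics]
    start_sites: list[str] = field(default_factory=list)
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if not (len(self.model_ids) == len(self.scores) == len(self.metrics)):
            raise ValueError("model/score/metric counts differ")
        if not self.start_sites:
            self.start_sites = [""] * len(self.model_ids)

    @property
    def n_models(self) -> int:
        return len(self.model_ids)

    @property
    def n_hits(self) -> int:
        return sum(m.is_hit for m in self.metrics)

    @property
    def rank_of_first_hit(self) -> int | None:
        for i, m in enumerate(self.metrics, 1):
            if m.is_hit:
                return i
        return None

    @property
    def rank_of_first_acceptable(self) -> int | None:
        for i, m in enumerate(self.metrics, 1):
            if ACCURACY_ORDER[m.accuracy_class] >= 1:
                return i
        return None

    @property
    def t20_rmsd(self) -> float:
        """Lowest interface RMSD among the top min(20, n) ranked models."""
        top = self.metrics[: min(20, self.n_models)]
        return min(m.irmsd for m in top)

    def funnel(self) -> list[tuple[str, float, float, str, str]]:
        """(model, score, irmsd, class, start site) rows for funnel plots."""
        return [(i, s, m.irmsd, m.accuracy_class, st) for i, s, m, st in
                zip(self.model_ids, self.scores, self.metrics, self.start_sites)]

    def summary_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "n_hits": self.n_hits,
            "rank_of_first_hit": self.rank_of_first_hit,
            "rank_of_first_acceptable": self.rank_of_first_acceptable,
            "t20_rmsd": round(self.t20_rmsd, 3),
        }

    def format_rank(self, rank: int | None) -> str:
        return "--" if rank is None else str(rank)

    def to_json(self, path) -> None:
        d = self.summary_dict()
        d["funnel"] = [{"model": i, "score": s, "irmsd": r, "class": c, "start": st}
                       for i, s, r, c, st in self.funnel()]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _sorted_report(ids, scores, metrics, sites, reference_id) -> CaseReport:
    # Equal scores tie-break by model id: stable and documented, since the
    # first-hit rank depends on it.
    order = sorted(range(len(ids)), key=lambda i: (scores[i], str(ids[i])))
    return CaseReport([ids[i] for i in order], [scores[i] for i in order],
                      [metrics[i] for i in order], [sites[i] for i in order],
                      reference_id)


def case_report(model_ids, scores, metrics, start_site: str = "",
                reference_id: str | None = None) -> CaseReport:
    """Rank one model set ascending by score and summarize it."""
    ids, scores, metrics = list(model_ids), list(scores), list(metrics)
    if not (len(ids) == len(scores) == len(metrics)):
        raise ValueError("model/score/metric counts differ")
    return _sorted_report(ids, scores, metrics, [start_site] * len(ids), reference_id)


def pool_reports(reports: list[CaseReport]) -> CaseReport:
    """Union of several start-site model sets, ranked jointly by score.

    Every model keeps its own metrics and start-site provenance; all reports
    must have been assessed against the same bound reference.
    """
    if not reports:
        raise ValueError("nothing to pool")
    refs = {r.reference_id for r in reports}
    if len(refs) > 1:
        raise ValueError(f"mixed bound references: {sorted(map(str, refs))}")
    ids, scores, metrics, sites = [], [], [], []
    for rep in reports:
        ids += rep.model_ids
        scores += rep.scores
        metrics += rep.metrics
        sites += rep.start_sites
    return _sorted_report(ids, scores, metrics, sites, reports[0].reference_id)


def plot_funnel(report: CaseReport, path=None, ax=None):
    """Score-versus-interface-RMSD scatter (the binding-funnel view)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sites = sorted({st for st in report.start_sites})
    for st in sites:
        xs = [m.irmsd for m, s in zip(report.metrics, report.start_sites) if s == st]
        ys = [sc for sc, s in zip(report.scores, report.start_sites) if s == st]
        ax.scatter(xs, ys, s=12, alpha=0.7, label=st or None)
    ax.set_xlabel("interface RMSD (Å)")
    ax.set_ylabel("score")
    if any(sites):
        ax.legend(title="start site", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
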