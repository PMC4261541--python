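import itertools

import numpy as np
import pytest

from tcrdock.fixtures import PlantedDecoySpec, make_planted_decoys
from tcrdock.retrain import (DecoyCase, TrainConfig, WeightTraining,
                             auc_for_case, auc_from_scores, build_cv_folds,
                             load_decoy_cases, objective, optimize_weights,
                             read_decoy_tsv, write_decoy_tsv)
from tcrdock.scoring import TERM_NAMES, WeightVector


def _case(terms, labels, cid="c0", tid="t0", baseline=None):
    return DecoyCase(cid, tid, np.asarray(terms, float),
                     np.asarray(labels, bool), baseline_scores=baseline)


def _single_term_cases(n_cases=5, n_models=120, seed=3):
    """Decoy cases where term 0 alone separates hits perfectly, with margin."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        t = rng.normal(0, 1, (n_models, 8))
        hits = np.zeros(n_models, bool)
        hits[:8] = True
        t[hits, 0] -= 8.0          # hits far below every non-hit in term 0
        cases.append(_case(t, hits, f"c{i}", f"t{i}"))
    return cases


# ---------------------------------------------------------------- AUC

def test_auc_perfect_separation():
    assert auc_from_scores([-5, -4, -3, -2], [1, 1, 0, 0]) == 1.0


def test_auc_three_of_four_concordant():
    # hits at -4 and -2, non-hits at -3 and -1: 3 of 4 hit/non pairs concordant
    assert auc_from_scores([-4, -3, -2, -1], [1, 0, 1, 0]) == 0.75


def test_auc_ties_count_half():
    assert auc_from_scores([1.0, 1.0], [1, 0]) == 0.5


def test_auc_single_class_undefined():
    with pytest.raises(ValueError, match="one class"):
        auc_from_scores([1, 2, 3], [1, 1, 1])


def test_auc_matches_pair_count_oracle_on_enumerated_vectors():
    """Exhaustive check against direct concordant-pair counting for every
    two-class label vector of length 6 over a fixed score set."""
    rng = np.random.default_rng(9)
    scores = rng.normal(size=6)
    scores[3] = scores[0]           # plant a tie across classes
    for labels in itertools.product([0, 1], repeat=6):
        labels = np.array(labels, bool)
        if labels.all() or not labels.any():
            continue
        conc = sum((scores[i] < scores[j]) + 0.5 * (scores[i] == scores[j])
                   for i in range(6) for j in range(6)
                   if labels[i] and not labels[j])
        expected = conc / (labels.sum() * (~labels).sum())
        assert auc_from_scores(scores, labels) == pytest.approx(expected)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(13)
    for _ in range(10):
        s = rng.normal(size=40)
        lab = rng.random(40) < 0.3
        if lab.all() or not lab.any():
            continue
        # lower score = better = "hit", hence the sign flip for sklearn
        assert auc_from_scores(s, lab) == pytest.approx(
            roc_auc_score(lab, -s))


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(15)
    s = rng.normal(size=30)
    lab = rng.random(30) < 0.4
    base = auc_from_scores(s, lab)
    assert auc_from_scores(3 * s + 7, lab) == pytest.approx(base)
    assert auc_from_scores(np.exp(s), lab) == pytest.approx(base)


# ---------------------------------------------------------------- case AUC / objective

def test_auc_for_case_self_ranking_top_k():
    terms = np.zeros((6, 8))
    terms[:, 0] = [-5, -4, -3, -2, -1, 0]
    case = _case(terms, [1, 1, 0, 0, 0, 0])
    w = np.zeros(8)
    w[0] = 1.0
    assert auc_for_case(case, w, top_k=4) == 1.0
    # top-2 by this ranking is all-hit → undefined
    assert auc_for_case(case, w, top_k=2) is None


def test_auc_for_case_baseline_mode():
    terms = np.zeros((4, 8))
    terms[:, 0] = [-4, -3, -2, -1]
    case = _case(terms, [1, 0, 1, 0], baseline=np.array([0.0, 1.0, 2.0, 3.0]))
    assert auc_for_case(case, np.eye(8)[0], top_k=4,
                        selection_mode="baseline") == 0.75


def test_objective_mean_and_errors():
    t = np.zeros((4, 8))
    t[:, 0] = [-4, -3, -2, -1]
    perfect = _case(t, [1, 1, 0, 0], "a", "ta")
    half = _case(t, [1, 0, 1, 0], "b", "tb")     # AUC 0.75
    w = np.eye(8)[0]
    assert objective([perfect], w, top_k=4) == 1.0
    assert objective([perfect, half], w, top_k=4) == pytest.approx(0.875)
    single = _case(t, [1, 1, 1, 1], "c", "tc")
    with pytest.raises(ValueError, match="no case"):
        objective([single], w, top_k=4, warn_undefined=False)


def test_objective_invariant_under_weight_scaling():
    cases = make_planted_decoys(PlantedDecoySpec(seed=2, n_cases=4,
                                                 models_per_case=100))
    w = WeightVector.zrt()
    w2 = WeightVector.from_array(2 * w.as_array())
    assert objective(cases, w) == pytest.approx(objective(cases, w2))


# ---------------------------------------------------------------- optimizer

def test_optimizer_reaches_perfect_objective_on_separable_decoys():
    cases = _single_term_cases()
    cfg = TrainConfig(n_random_starts=30, seed=5, top_k=30)
    w, value, trace = optimize_weights(cases, cfg)
    assert value == pytest.approx(1.0)
    assert value >= trace["objective"].max() - 1e-12
    assert (w.as_array() >= 0).all()


def test_optimizer_deterministic_given_seed():
    cases = _single_term_cases(n_cases=3, n_models=60)
    cfg = TrainConfig(n_random_starts=1, seed=42)
    w1, v1, _ = optimize_weights(cases, cfg)
    w2, v2, _ = optimize_weights(cases, cfg)
    np.testing.assert_array_equal(w1.as_array(), w2.as_array())
    assert v1 == v2


def test_optimizer_dominates_zr2_preset_on_training_cases():
    cases = _single_term_cases()
    w, value, _ = optimize_weights(cases, TrainConfig(n_random_starts=30, seed=5))
    assert value >= objective(cases, WeightVector.zr2(), warn_undefined=False)


# ---------------------------------------------------------------- CV folds

def test_cv_three_tcrs_three_folds():
    cases = [_case(np.zeros((30, 8)), [1] * 15 + [0] * 15, f"c{i}", f"t{i // 2}")
             for i in range(6)]
    folds = build_cv_folds(cases, 3)
    for train, test in folds:
        assert len(test) == 2
        assert len({c.tcr_id for c in test}) == 1


def test_cv_unique_tcrs_balanced():
    cases = [_case(np.zeros((30, 8)), [1] * 15 + [0] * 15, f"c{i}", f"t{i}")
             for i in range(7)]
    folds = build_cv_folds(cases, 3, seed=1)
    sizes = sorted(len(test) for _, test in folds)
    assert sum(sizes) == 7
    assert sizes[-1] - sizes[0] <= 1


def test_cv_too_many_folds_rejected():
    cases = [_case(np.zeros((30, 8)), [1] * 15 + [0] * 15, f"c{i}", f"t{i // 2}")
             for i in range(6)]
    with pytest.raises(ValueError, match="distinct TCR"):
        build_cv_folds(cases, 4)


def test_cv_never_leaks_shared_tcrs():
    """Randomized case sets: folds partition the cases and no TCR id ever
    appears in both train and test of the same fold."""
    rng = np.random.default_rng(19)
    for trial in range(10):
        n = int(rng.integers(6, 15))
        cases = [_case(np.zeros((30, 8)), [1] * 15 + [0] * 15, f"c{i}",
                       f"t{rng.integers(0, max(3, n // 2))}") for i in range(n)]
        k = min(3, len({c.tcr_id for c in cases}))
        folds = build_cv_folds(cases, k, seed=trial)
        all_test = [c.case_id for _, test in folds for c in test]
        assert sorted(all_test) == sorted(c.case_id for c in cases)
        for train, test in folds:
            assert not ({c.tcr_id for c in train} & {c.tcr_id for c in test})


# ---------------------------------------------------------------- model surface & IO

def test_weight_training_fit_and_summary():
    cases = _single_term_cases(n_cases=3, n_models=60)
    model = WeightTraining(cases, TrainConfig(n_random_starts=10, seed=8))
    res = model.fit()
    text = res.summary()
    assert "mean top-30 AUC" in text
    for name in TERM_NAMES:
        assert name in text
    assert res.per_case_auc().shape[0] == 3


def test_weight_training_cross_validate():
    cases = _single_term_cases(n_cases=6)
    model = WeightTraining(cases, TrainConfig(n_random_starts=5, seed=8, k_folds=3))
    cv = model.cross_validate()
    assert len(cv) == 3
    assert (cv["test_auc"] > 0.5).all()    # separable structure generalizes


def test_decoy_tsv_round_trip(tmp_path):
    case = make_planted_decoys(PlantedDecoySpec(seed=7, n_cases=1,
                                                models_per_case=50))[0]
    path = tmp_path / "case00.tsv"
    write_decoy_tsv(case, path)
    back = read_decoy_tsv(path, "case00", case.tcr_id)
    np.testing.assert_allclose(back.terms, case.terms)
    np.testing.assert_array_equal(back.labels, case.labels)
    np.testing.assert_allclose(back.baseline_scores, case.baseline_scores)

    (tmp_path / "tcr_ids.json").write_text('{"case00": "tcrX"}')
    cases = load_decoy_cases(tmp_path)
    assert cases[0].tcr_id == "tcrX"
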