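import numpy as np
import pytest

from tcrdock.evaluation import (ACCURACY_ORDER, CapriEvaluator, CapriMetrics,
                                CapriThresholds, capri_metrics, case_report,
                                fnat, interface_selection, native_contacts,
                                pool_reports)
from tcrdock.structio import AnnotatedComplex, Atom, Residue
from conftest import random_rigid


def _res(chain, sid, name, role, atoms):
    return Residue(chain, str(sid), name,
                   [Atom(n, el, xyz, is_backbone=n in ("N", "CA", "C", "O"))
                    for n, el, xyz in atoms], role)


def _minimal_pair(gap):
    """One TCR residue and one receptor residue, CB atoms `gap` Å apart."""
    a = _res("A", 1, "ALA", "tcr_alpha",
             [("CA", "C", (0, 0, 1.5)), ("CB", "C", (0, 0, 0))])
    b = _res("M", 1, "ALA", "mhc_platform",
             [("CA", "C", (0, 0, -gap - 1.5)), ("CB", "C", (0, 0, -gap))])
    return AnnotatedComplex([a, b])


# ---------------------------------------------------------------- native contacts

def test_native_contacts_empty_when_far(toy_case):
    with pytest.warns(UserWarning, match="no native contacts"):
        assert native_contacts(_minimal_pair(100.0)) == set()


def test_native_contacts_single_cb_pair():
    cx = _minimal_pair(4.9)
    assert native_contacts(cx) == {(("A", "1"), ("M", "1"))}
    with pytest.warns(UserWarning):
        assert native_contacts(_minimal_pair(5.1)) == set()


def test_antigen_only_contact_still_recorded():
    tcr = _res("A", 1, "ALA", "tcr_alpha",
               [("CA", "C", (0, 0, 0)), ("CB", "C", (0, 0, -1.5))])
    lig = Residue("M", "9", "LIG", [Atom("C1", "C", (0, 0, -5.5))], "antigen")
    far = _res("M", 1, "ALA", "mhc_platform",
               [("CA", "C", (0, 0, -20)), ("CB", "C", (0, 0, -21))])
    cx = AnnotatedComplex([tcr, lig, far])
    assert (("A", "1"), ("M", "9")) in native_contacts(cx)


def test_fnat_extremes(toy_case):
    native = native_contacts(toy_case.bound)
    assert fnat(toy_case.bound, native) == 1.0
    far = toy_case.bound.copy()
    for r in far.residues:
        if r.role in ("tcr_alpha", "tcr_beta"):
            for a in r.atoms:
                a.coord = a.coord + np.array([0.0, 0.0, 80.0])
    assert fnat(far, native) == 0.0
    with pytest.raises(ValueError, match="empty native"):
        fnat(toy_case.bound, set())


def test_fnat_partial_preservation():
    """4 native CB–CB contacts, model keeps exactly 2 → fnat 0.5."""
    def build(gaps):
        residues = []
        for i, g in enumerate(gaps):
            residues.append(_res("A", i + 1, "ALA", "tcr_alpha",
                                 [("CA", "C", (6.0 * i, 0, 1.5)),
                                  ("CB", "C", (6.0 * i, 0, 0))]))
            residues.append(_res("M", i + 1, "ALA", "mhc_platform",
                                 [("CA", "C", (6.0 * i, 0, -g - 1.5)),
                                  ("CB", "C", (6.0 * i, 0, -g))]))
        return AnnotatedComplex(residues)

    bound = build([4.0, 4.0, 4.0, 4.0])
    native = native_contacts(bound)
    assert len(native) == 4
    model = build([4.0, 4.0, 8.0, 8.0])
    assert fnat(model, native) == 0.5


# ---------------------------------------------------------------- CAPRI classes

def _oracle_class(f, l, i):
    """Independent restatement of the CAPRI threshold table."""
    if f >= 0.5 and (l <= 1.0 or i <= 1.0):
        return "high"
    if f >= 0.3 and (l <= 5.0 or i <= 2.0):
        return "medium"
    if f >= 0.1 and (l <= 10.0 or i <= 4.0):
        return "acceptable"
    return "incorrect"


def test_capri_threshold_grid_matches_oracle():
    th = CapriThresholds()
    grid_f = [0.0, 0.05, 0.1, 0.2, 0.3, 0.45, 0.5, 0.8, 1.0]
    grid_l = [0.5, 1.0, 2.0, 4.5, 5.0, 7.0, 10.0, 15.0]
    grid_i = [0.5, 1.0, 1.9, 2.0, 3.0, 4.0, 6.0]
    for f in grid_f:
        for l in grid_l:
            for i in grid_i:
                assert th.classify(f, l, i) == _oracle_class(f, l, i)


def test_capri_class_nesting_property():
    """Any triple good enough for a class also satisfies every lower class."""
    rng = np.random.default_rng(31)
    th = CapriThresholds()
    for _ in range(500):
        f, l, i = rng.uniform(0, 1), rng.uniform(0, 15), rng.uniform(0, 8)
        c = th.classify(f, l, i)
        if c == "high":
            assert _oracle_class(max(f, 0.5), l, i) == "high"
        if ACCURACY_ORDER[c] >= 1:
            assert _oracle_class(f, l, i) != "incorrect"


def test_specified_toy_triples():
    th = CapriThresholds()
    assert th.classify(0.35, 4.5, 1.9) == "medium"
    assert th.classify(0.05, 0.1, 0.1) == "incorrect"  # fnat gate is absolute
    assert CapriMetrics(0.35, 4.5, 1.9, "medium").is_hit
    assert not CapriMetrics(0.15, 8.0, 3.0, "acceptable").is_hit


def test_bound_as_model_is_high(toy_case):
    m = capri_metrics(toy_case.bound, toy_case.bound)
    assert m.fnat == 1.0
    assert m.lrmsd == pytest.approx(0.0, abs=1e-6)
    assert m.irmsd == pytest.approx(0.0, abs=1e-6)
    assert m.accuracy_class == "high" and m.is_hit


def test_capri_metrics_rigid_motion_invariant(toy_case):
    ev = CapriEvaluator(toy_case.bound)
    perturbed = toy_case.bound.copy()
    for r in perturbed.residues:
        if r.role in ("tcr_alpha", "tcr_beta"):
            for a in r.atoms:
                a.coord = a.coord + np.array([1.5, 0.5, 2.0])
    base = ev.assess(perturbed)
    tf = random_rigid(41)
    moved = perturbed.transformed(tf.rotation, tf.translation)
    after = ev.assess(moved)
    assert after.fnat == pytest.approx(base.fnat)
    assert after.lrmsd == pytest.approx(base.lrmsd, abs=1e-6)
    assert after.irmsd == pytest.approx(base.irmsd, abs=1e-6)


def test_interface_selection_protein_only(toy_case):
    sel = interface_selection(toy_case.bound)
    assert sel
    assert all(toy_case.bound[k].is_amino_acid for k in sel)


def test_evaluated_chain_subset(toy_case):
    """α-chain-only evaluation drops β-chain contacts but still assesses."""
    m_all = capri_metrics(toy_case.bound, toy_case.bound)
    m_alpha = capri_metrics(toy_case.bound, toy_case.bound,
                            evaluated_chains=["A", "M"])
    assert m_alpha.accuracy_class == "high"
    assert m_all.fnat == m_alpha.fnat == 1.0


# ---------------------------------------------------------------- reports

def _metrics(cls):
    base = {"incorrect": (0.0, 20.0, 10.0), "acceptable": (0.15, 8.0, 3.5),
            "medium": (0.4, 4.0, 1.8), "high": (0.8, 0.5, 0.5)}
    f, l, i = base[cls]
    return CapriMetrics(f, l, i, cls)


def test_case_report_ranks_and_counts():
    classes = ["incorrect", "medium", "incorrect", "high", "acceptable"]
    scores = [-10.0, -9.0, -8.0, -7.0, -6.0]
    rep = case_report([f"m{i}" for i in range(5)], scores,
                      [_metrics(c) for c in classes])
    assert rep.n_hits == 2
    assert rep.rank_of_first_hit == 2
    assert rep.rank_of_first_acceptable == 2


def test_case_report_no_hits_formats_dashes():
    rep = case_report(["a", "b"], [-1.0, 0.0],
                      [_metrics("incorrect"), _metrics("incorrect")])
    assert rep.n_hits == 0
    assert rep.rank_of_first_hit is None
    assert rep.format_rank(rep.rank_of_first_hit) == "--"


def test_case_report_single_hit_model():
    m = _metrics("medium")
    rep = case_report(["only"], [-3.0], [m])
    assert rep.rank_of_first_hit == 1
    assert rep.t20_rmsd == m.irmsd


def test_case_report_t20_window():
    mets = [_metrics("incorrect") for _ in range(30)]
    mets[25] = CapriMetrics(0.4, 4.0, 0.01, "medium")  # outside the top 20
    rep = case_report([f"m{i:02d}" for i in range(30)],
                      list(np.linspace(-30, -1, 30)), mets)
    assert rep.t20_rmsd > 0.01


def test_case_report_invariant_under_monotone_score_transform():
    rng = np.random.default_rng(17)
    scores = list(rng.normal(size=12))
    classes = rng.choice(["incorrect", "acceptable", "medium", "high"], 12)
    mets = [_metrics(c) for c in classes]
    ids = [f"m{i}" for i in range(12)]
    rep1 = case_report(ids, scores, mets)
    rep2 = case_report(ids, [np.exp(0.3 * s) for s in scores], mets)
    assert rep1.model_ids == rep2.model_ids
    assert rep1.summary_dict() == rep2.summary_dict()


def test_class_count_hierarchy_property():
    rng = np.random.default_rng(23)
    classes = rng.choice(["incorrect", "acceptable", "medium", "high"], 50)
    rep = case_report([f"m{i}" for i in range(50)], list(rng.normal(size=50)),
                      [_metrics(c) for c in classes])
    n_acc = sum(ACCURACY_ORDER[m.accuracy_class] >= 1 for m in rep.metrics)
    n_high = sum(m.accuracy_class == "high" for m in rep.metrics)
    assert n_acc >= rep.n_hits >= n_high


def test_pooling_doubles_and_merges():
    classes = ["incorrect", "medium"]
    rep = case_report(["a", "b"], [-5.0, -4.0], [_metrics(c) for c in classes],
                      start_site="start1", reference_id="ref")
    doubled = pool_reports([rep, rep])
    assert doubled.n_models == 4
    assert doubled.n_hits == 2 * rep.n_hits

    set_a = case_report(["a0"], [-10.0], [_metrics("incorrect")],
                        start_site="start1", reference_id="ref")
    set_b = case_report(["b0"], [-9.0], [_metrics("medium")],
                        start_site="start2", reference_id="ref")
    pooled = pool_reports([set_a, set_b])
    assert pooled.rank_of_first_hit == 2
    assert pooled.start_sites == ["start1", "start2"]
    # metrics travel unchanged
    assert pooled.metrics[1] is set_b.metrics[0]


def test_pooling_mixed_references_rejected():
    a = case_report(["a"], [0.0], [_metrics("high")], reference_id="r1")
    b = case_report(["b"], [0.0], [_metrics("high")], reference_id="r2")
    with pytest.raises(ValueError, match="mixed"):
        pool_reports([a, b])
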