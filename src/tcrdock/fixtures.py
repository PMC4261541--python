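"""Deterministic synthetic structures and decoy sets.

Two generators make every other module testable without downloading any
crystal structure:

* :func:`make_toy_complex` builds an idealized antigen-presenting platform
  (two antiparallel α-helices flanking a small charged antigen cluster), a
  TCR-like module of two rigid pseudo-domains related by an exact two-fold,
  and a bound complex realizing a planted start pose, plus unbound copies
  perturbed by Gaussian coordinate noise.
* :func:`make_planted_decoys` draws per-model energy-term vectors and labels
  hits by thresholding the score under a known "true" weight vector, with
  optional label noise — the ground truth for weight-recovery tests.

The toys are geometric, not chemical: backbone geometry is idealized, side
chains stop at Cβ, and energetics on them are physically meaningless beyond
the invariances the tests exercise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structio import (AnnotatedComplex, Atom, CaseManifest, Residue,
                       assign_contact_types, assign_partial_charges,
                       write_mol2_charges, write_pdb)
from .geometry import StartPoseSpec, place_start
from .retrain import DecoyCase
from .scoring import WeightVector

__all__ = ["ToyComplexSpec", "ToyCase", "make_toy_complex",
           "PlantedDecoySpec", "make_planted_decoys"]

_AA = ("ALA", "ARG", "ASN", "ASP", "GLN", "GLU", "HIS", "ILE", "LEU", "LYS",
       "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL")


@dataclass
class ToyComplexSpec:
    seed: int = 0
    n_helix_res: int = 20          # residues per platform helix
    domain_res: int = 12           # residues per TCR pseudo-domain
    n_cdr_res: int = 3             # loop residues marked per domain
    antigen_atoms: int = 6
    antigen_charges: tuple = (0.4, -0.4, 0.2, -0.2, 0.0, 0.0)
    planted_pose: StartPoseSpec = field(
        default_factory=lambda: StartPoseSpec(10.0, 0.0, 45.0, 0.0))
    noise_sigma: float = 0.0       # Å, on the unbound copies

    def __post_init__(self) -> None:
        if self.n_helix_res < 10 or self.domain_res < 6:
            raise ValueError("toy complex too small to define frames")
        if len(self.antigen_charges) < self.antigen_atoms:
            raise ValueError("need one charge per antigen atom")


@dataclass
class ToyCase:
    bound: AnnotatedComplex
    tcr: AnnotatedComplex
    receptor: AnnotatedComplex
    manifest: CaseManifest
    antigen_charges: dict[str, float]

    def write(self, directory) -> CaseManifest:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_pdb(self.bound, d / "bound.pdb")
        write_pdb(self.tcr, d / "tcr.pdb")
        write_pdb(self.receptor, d / "receptor.pdb")
        lig = [r for r in self.receptor.residues if r.role == "antigen"][0]
        write_mol2_charges([(a.name, a.element, a.coord, a.partial_charge)
                            for a in lig.atoms], d / "antigen.mol2", "LIG")
        m = self.manifest
        m.tcr_file, m.receptor_file, m.bound_file = "tcr.pdb", "receptor.pdb", "bound.pdb"
        m.to_json(d / "case.json")
        return m


# ---------------------------------------------------------------------------
# Idealized secondary-structure pieces
# ---------------------------------------------------------------------------

_RISE, _RADIUS, _TWIST = 1.5, 2.3, np.radians(100.0)


def _helix_backbone(n: int) -> dict[str, np.ndarray]:
    """Idealized α-helix backbone along +x (N-term at x=0): CA trace from
    canonical rise/radius/twist, N/C interpolated on the trace, O and CB
    displaced radially."""
    i = np.arange(n)
    ca = np.stack([_RISE * i, _RADIUS * np.cos(_TWIST * i),
                   _RADIUS * np.sin(_TWIST * i)], axis=1)
    out_dir = ca.copy()
    out_dir[:, 0] = 0.0
    out_dir /= np.linalg.norm(out_dir, axis=1, keepdims=True)
    step = np.diff(ca, axis=0, prepend=ca[:1] - (ca[1] - ca[0]))
    nxt = np.diff(ca, axis=0, append=ca[-1:] + (ca[-1] - ca[-2]))
    return {"N": ca - 0.45 * step, "CA": ca, "C": ca + 0.45 * nxt,
            "O": ca + 0.45 * nxt + 1.0 * out_dir, "CB": ca + 1.53 * out_dir,
            "TIP": ca + 3.0 * out_dir}


# Charged side chains get a single tip atom so the toys exercise the
# electrostatic terms; everything else stops at Cβ.
_TIP_ATOMS = {"LYS": ("NZ", "N"), "ASP": ("OD1", "O"),
              "GLU": ("OE1", "O"), "ARG": ("NH1", "N")}


def _seq(rng: np.random.Generator, n: int) -> list[str]:
    return [str(x) for x in rng.choice(_AA, n)]


def _residues_from_backbone(chain: str, start: int, names, bb,
                            transform=None, role: str = "other") -> list[Residue]:
    n = len(names)
    res = []
    for i in range(n):
        atoms = []
        atom_plan = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
        if names[i] != "GLY":
            atom_plan.append(("CB", "C"))
        if names[i] in _TIP_ATOMS:
            atom_plan.append(_TIP_ATOMS[names[i]])
        for atom_name, element in atom_plan:
            key = atom_name if atom_name in bb else "TIP"
            xyz = bb[key][i]
            if transform is not None:
                xyz = transform(xyz)
            atoms.append(Atom(atom_name, element, xyz,
                              is_backbone=atom_name in ("N", "CA", "C", "O")))
        res.append(Residue(chain, str(start + i), names[i], atoms, role))
    return res


def make_toy_complex(spec: ToyComplexSpec | None = None) -> ToyCase:
    """Build (bound complex, unbound TCR, unbound receptor, manifest).

    The platform is two antiparallel helices along x at y = ±5.5 Å (chain M;
    the first helix, in N→C order along +x, plays α1), with the antigen
    cluster seated in the groove just above the helix plane. The TCR is two
    rigid pseudo-domains related by an exact 180° rotation about z, CDR
    residues marked at the platform-facing end. The bound complex realizes
    the planted pose exactly via :func:`tcrdock.geometry.place_start`; the
    unbound copies are the same molecules perturbed by ``noise_sigma``.
    """
    spec = spec or ToyComplexSpec()
    rng = np.random.default_rng(spec.seed)
    nh = spec.n_helix_res

    # --- receptor: platform helices + antigen -----------------------------
    bb = _helix_backbone(nh)
    half_len = _RISE * (nh - 1) / 2.0
    seq1, seq2 = _seq(rng, nh), _seq(rng, nh)
    seq1[nh // 2], seq2[nh // 2] = "GLU", "ARG"   # guaranteed charged rim atoms
    helix1 = _residues_from_backbone(
        "M", 1, seq1, bb,
        lambda p: p + np.array([-half_len, 5.5, 0.0]), "mhc_platform")
    helix2 = _residues_from_backbone(  # 180° z-rotation: antiparallel, N-term at +x
        "M", nh + 1, seq2, bb,
        lambda p: np.array([half_len - p[0], -p[1] - 5.5, p[2]]), "mhc_platform")
    lig_atoms = []
    for j in range(spec.antigen_atoms):
        ang = 2 * np.pi * j / spec.antigen_atoms
        xyz = np.array([1.4 * np.cos(ang), 1.4 * np.sin(ang), 2.6 + 0.2 * (j % 2)])
        el = ("C", "O", "N")[j % 3]
        lig_atoms.append(Atom(f"{el}{j + 1}", el, xyz,
                              partial_charge=float(spec.antigen_charges[j])))
    ligand = Residue("M", str(2 * nh + 1), "LIG", lig_atoms, "antigen")
    receptor = AnnotatedComplex(helix1 + helix2 + [ligand],
                                provenance={"generator": "toy", "seed": spec.seed})

    # --- TCR: two pseudo-domains, exact two-fold about z -------------------
    nd = spec.domain_res
    dbb = _helix_backbone(nd)
    dom_half = _RISE * (nd - 1) / 2.0
    # domain helix runs along z (N-term at the bottom = CDR end), offset in x
    names_a = _seq(rng, nd)  # Vβ reuses the Vα sequence: an exact pseudo-two-fold
    names_a[0], names_a[1] = "LYS", "ASP"  # charged CDR-end residues

    def to_alpha(p):
        return np.array([p[1] - 4.25, p[2], p[0] - dom_half])

    def to_beta(p):  # 180° rotation of the α domain about z
        q = to_alpha(p)
        return np.array([-q[0], -q[1], q[2]])

    va = _residues_from_backbone("A", 1, names_a, dbb, to_alpha, "tcr_alpha")
    vb = _residues_from_backbone("B", 1, names_a, dbb, to_beta, "tcr_beta")
    ncdr = spec.n_cdr_res
    cdr_sel = {"CDR3A": {r.key for r in va[:ncdr]},
               "CDR3B": {r.key for r in vb[:ncdr]}}
    tcr_local = AnnotatedComplex([r.copy() for r in va + vb],
                                 provenance={"generator": "toy", "seed": spec.seed},
                                 cdr_sel=cdr_sel)

    # --- bound complex: plant the pose -------------------------------------
    placed, _ = place_start(tcr_local, receptor, spec.planted_pose)
    bound = AnnotatedComplex([r.copy() for r in placed.residues]
                             + [r.copy() for r in receptor.residues],
                             provenance={"generator": "toy", "seed": spec.seed,
                                         "planted_pose": vars(spec.planted_pose)},
                             cdr_sel=cdr_sel)

    # --- unbound copies with coordinate noise ------------------------------
    def jitter(cx: AnnotatedComplex) -> AnnotatedComplex:
        out = cx.copy()
        if spec.noise_sigma > 0:
            for r in out.residues:
                for a in r.atoms:
                    a.coord = a.coord + rng.normal(0.0, spec.noise_sigma, 3)
        return out

    tcr_unbound = jitter(tcr_local)
    receptor_unbound = jitter(receptor)

    manifest = CaseManifest(
        case_id=f"toy{spec.seed}",
        chain_roles={"A": "tcr_alpha", "B": "tcr_beta", "M": "mhc_platform"},
        antigen_residues=[("M", str(2 * nh + 1))],
        evaluated_chains=["A", "B", "M"],
        alpha1_residues=[r.key for r in helix1],
        cdr_overrides={k: sorted(v) for k, v in cdr_sel.items()},
    )
    charges = {a.name: a.partial_charge for a in lig_atoms}
    for cx in (bound, tcr_unbound, receptor_unbound):
        assign_contact_types(cx)
        assign_partial_charges(cx, charges)
    return ToyCase(bound, tcr_unbound, receptor_unbound, manifest, charges)


# ---------------------------------------------------------------------------
# Planted decoy sets
# ---------------------------------------------------------------------------

@dataclass
class PlantedDecoySpec:
    seed: int = 0
    n_cases: int = 20              # mirrors the 20-case training collection
    models_per_case: int = 1000    # one docking run's model count
    n_hits_per_case: int = 10      # hits are the n lowest true-weighted scores
    true_weights: WeightVector | None = None   # defaults to the ZRT preset
    label_noise: float = 0.0       # probability of flipping each label
    term_sigma: float = 1.0        # spread of the drawn term values
    baseline_sigma: float = 1.0    # noise on the fixed baseline ranking
    hit_margin: float = 0.0        # true-score gap opened between hits and non-hits
    max_retries: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.n_hits_per_case < self.models_per_case:
            raise ValueError("need 0 < n_hits_per_case < models_per_case")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise is a probability")


def make_planted_decoys(spec: PlantedDecoySpec | None = None) -> list[DecoyCase]:
    """Draw decoy cases whose hit labels come from a known weight vector.

    Per model, the 8 term values are independent draws; the ``n_hits_per_case``
    models with the lowest true-weighted score are labelled hits, then each
    label is flipped with probability ``label_noise``. Cases that end up
    single-class are redrawn (bounded retries). Two consecutive cases share a
    TCR identity, giving the cross-validation constraint something to bite on.
    """
    spec = spec or PlantedDecoySpec()
    rng = np.random.default_rng(spec.seed)
    w = (spec.true_weights or WeightVector.zrt()).as_array()
    cases = []
    for i in range(spec.n_cases):
        for attempt in range(spec.max_retries):
            terms = rng.normal(0.0, spec.term_sigma, (spec.models_per_case, len(w)))
            true_score = terms @ w
            order = np.argsort(true_score, kind="stable")
            labels = np.zeros(spec.models_per_case, bool)
            labels[order[: spec.n_hits_per_case]] = True
            if spec.hit_margin > 0:
                # Push hit models down-score along the true-weight direction,
                # opening a clean margin (recoverability "by construction").
                terms[labels] -= spec.hit_margin * w / float(w @ w)
                true_score = terms @ w
            if spec.label_noise > 0:
                flip = rng.random(spec.models_per_case) < spec.label_noise
                labels ^= flip
            if labels.any() and not labels.all():
                break
        else:
            raise RuntimeError(f"case {i}: could not draw a two-class label set")
        baseline = true_score + rng.normal(0.0, spec.baseline_sigma,
                                           spec.models_per_case)
        cases.append(DecoyCase(case_id=f"case{i:02d}", tcr_id=f"tcr{i // 2:02d}",
                               terms=terms, labels=labels,
                               baseline_scores=baseline))
    return cases
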