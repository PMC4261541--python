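"""ZRANK-style interface scoring: 8 energy terms and weighted presets.

The score of a docking model is a weighted sum of eight inter-partner terms —
attractive/repulsive Lennard-Jones, short/long-range attractive/repulsive
Coulomb electrostatics, and two atomic-contact-energy pair potentials (ACE and
its interface recalibration IFACE). Two weight presets are shipped: ``ZR2``
(the general protein–protein rescoring weights) and ``ZRT`` (re-trained
against TCR–pMHC decoy sets; see :mod:`tcrdock.retrain`). More negative
scores rank better.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structio import (AnnotatedComplex, Atom, TCR_ROLES, load_lj_params,
                       load_pair_potential)

__all__ = [
    "TERM_NAMES",
    "EnergyBreakdown",
    "WeightVector",
    "ScoringConfig",
    "partner_atoms",
    "vdw_terms",
    "elec_terms",
    "contact_potential",
    "score",
]

TERM_NAMES = ("vdw_attr", "vdw_rep", "elec_sr_attr", "elec_sr_rep",
              "elec_lr_attr", "elec_lr_rep", "ace", "iface")

_RECEPTOR_ROLES = ("mhc_platform", "mhc_other", "antigen")


@dataclass
class EnergyBreakdown:
    """The eight interface energy terms (dimensionless score units)."""

    vdw_attr: float = 0.0
    vdw_rep: float = 0.0
    elec_sr_attr: float = 0.0
    elec_sr_rep: float = 0.0
    elec_lr_attr: float = 0.0
    elec_lr_rep: float = 0.0
    ace: float = 0.0
    iface: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TERM_NAMES], float)

    @classmethod
    def from_array(cls, arr) -> "EnergyBreakdown":
        arr = np.asarray(arr, float)
        if arr.shape != (len(TERM_NAMES),):
            raise ValueError(f"expected {len(TERM_NAMES)} terms")
        return cls(**dict(zip(TERM_NAMES, map(float, arr))))

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown.from_array(self.as_array() + other.as_array())


@dataclass
class WeightVector:
    """One weight per energy term; ``score = Σ wᵢ·termᵢ`` (lower is better)."""

    vdw_attr: float
    vdw_rep: float
    elec_sr_attr: float
    elec_sr_rep: float
    elec_lr_attr: float
    elec_lr_rep: float
    ace: float
    iface: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TERM_NAMES], float)

    @classmethod
    def from_array(cls, arr) -> "WeightVector":
        arr = np.asarray(arr, float)
        return cls(**dict(zip(TERM_NAMES, map(float, arr))))

    @classmethod
    def zrt(cls) -> "WeightVector":
        """TCR-retrained weights (note the low vdW-attractive weight)."""
        return cls(0.027, 1.33, 0.35, 0.29, 0.30, 0.21, 0.64, 0.27)

    @classmethod
    def zr2(cls) -> "WeightVector":
        """General protein–protein rescoring weights."""
        return cls(1.0, 0.23, 0.57, 0.56, 1.09, 0.29, 0.7, 0.38)

    @classmethod
    def preset(cls, name: str) -> "WeightVector":
        try:
            return {"zrt": cls.zrt, "zr2": cls.zr2}[name.lower()]()
        except KeyError:
            raise ValueError(f"unknown weight preset {name!r}; use 'zrt' or 'zr2'")

    def combine(self, breakdown: EnergyBreakdown) -> float:
        return float(self.as_array() @ breakdown.as_array())


@dataclass
class ScoringConfig:
    """Functional-form constants of the score (all tunable)."""

    sr_cutoff: float = 5.0        # Å, short-range electrostatics shell
    lr_cutoff: float = 12.0       # Å, long-range electrostatics cutoff
    contact_cutoff: float = 6.0   # Å, ACE/IFACE contact shell
    vdw_cutoff: float = 8.0       # Å, Lennard-Jones cutoff
    pair_clamp: float = 100.0     # per-pair |energy| cap (guards clash blow-ups
    #                               without touching ordinary contact energies)
    coulomb_k: float = 332.0637   # kcal·Å/(mol·e²)

    def __post_init__(self) -> None:
        if not (0 < self.sr_cutoff < self.lr_cutoff):
            raise ValueError("need 0 < sr_cutoff < lr_cutoff")
        if self.contact_cutoff <= 0 or self.vdw_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


# ---------------------------------------------------------------------------
# Atom gathering
# ---------------------------------------------------------------------------

def partner_atoms(complex_: AnnotatedComplex,
                  ) -> tuple[list[Atom], list[Atom]]:
    """Split a model's atoms into the TCR partner and the receptor partner
    (MHC-like molecule plus antigen). Residues with role ``other`` belong to
    neither and never contribute to any term."""
    tcr = [a for r in complex_.residues if r.role in TCR_ROLES for a in r.atoms]
    rec = [a for r in complex_.residues if r.role in _RECEPTOR_ROLES for a in r.atoms]
    return tcr, rec


def _coords(atoms: list[Atom]) -> np.ndarray:
    return np.array([a.coord for a in atoms], float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Terms
# ---------------------------------------------------------------------------

def vdw_terms(partner_a: list[Atom], partner_b: list[Atom],
              config: ScoringConfig | None = None) -> tuple[float, float]:
    """Lennard-Jones 6-12 over inter-partner heavy-atom pairs within the vdW
    cutoff; negative pair energies accumulate into ``vdw_attr``, positive into
    ``vdw_rep``, each pair clamped to ±``pair_clamp``."""
    cfg = config or ScoringConfig()
    params = load_lj_params()
    default = params["*"]
    ha = [a for a in partner_a if not a.is_hydrogen]
    hb = [a for a in partner_b if not a.is_hydrogen]
    if not ha or not hb:
        return 0.0, 0.0
    ra, ea = zip(*(params.get(a.element, default) for a in ha))
    rb, eb = zip(*(params.get(b.element, default) for b in hb))
    rmin = np.add.outer(np.array(ra), np.array(rb))
    eps = np.sqrt(np.outer(ea, eb))
    d = cdist(_coords(ha), _coords(hb))
    mask = (d < cfg.vdw_cutoff) & (d > 1e-6)
    if not mask.any():
        return 0.0, 0.0
    x = (rmin[mask] / d[mask]) ** 6
    e = np.clip(eps[mask] * (x * x - 2.0 * x), -cfg.pair_clamp, cfg.pair_clamp)
    return float(e[e < 0].sum()), float(e[e > 0].sum())


def elec_terms(partner_a: list[Atom], partner_b: list[Atom],
               config: ScoringConfig | None = None,
               ) -> tuple[float, float, float, float]:
    """Coulomb ``k·qᵢqⱼ/r`` per inter-partner pair, split by sign and by the
    short/long range shells. Hydrogens participate (they carry charge)."""
    cfg = config or ScoringConfig()
    qa = np.array([a.partial_charge for a in partner_a], float)
    qb = np.array([b.partial_charge for b in partner_b], float)
    if not len(qa) or not len(qb) or (not qa.any()) or (not qb.any()):
        return 0.0, 0.0, 0.0, 0.0
    d = cdist(_coords(partner_a), _coords(partner_b))
    qq = np.outer(qa, qb)
    out = []
    for lo, hi in ((0.0, cfg.sr_cutoff), (cfg.sr_cutoff, cfg.lr_cutoff)):
        mask = (d >= lo) & (d < hi) & (d > 1e-6) & (qq != 0.0)
        e = np.clip(cfg.coulomb_k * qq[mask] / d[mask],
                    -cfg.pair_clamp, cfg.pair_clamp)
        out.extend([float(e[e < 0].sum()), float(e[e > 0].sum())])
    return tuple(out)  # (sr_attr, sr_rep, lr_attr, lr_rep)


def contact_potential(partner_a: list[Atom], partner_b: list[Atom],
                      pair_table: dict[tuple[str, str], float],
                      config: ScoringConfig | None = None) -> float:
    """Sum of pair-table energies over typed inter-partner heavy-atom pairs
    within the contact shell; untyped atoms are skipped (and counted)."""
    cfg = config or ScoringConfig()
    ha = [a for a in partner_a if not a.is_hydrogen]
    hb = [a for a in partner_b if not a.is_hydrogen]
    n_untyped = sum(a.contact_type == "untyped" for a in ha + hb)
    ha = [a for a in ha if a.contact_type != "untyped"]
    hb = [a for a in hb if a.contact_type != "untyped"]
    if n_untyped:
        warnings.warn(f"{n_untyped} untyped heavy atom(s) skipped in contact potential")
    if not ha or not hb:
        return 0.0
    d = cdist(_coords(ha), _coords(hb))
    total = 0.0
    for i, j in zip(*np.nonzero(d < cfg.contact_cutoff)):
        e = pair_table.get((ha[i].contact_type, hb[j].contact_type))
        if e is not None:
            total += e
    return float(total)


def score(model: AnnotatedComplex, weights: WeightVector | None = None,
          config: ScoringConfig | None = None,
          ) -> tuple[float, EnergyBreakdown]:
    """Score a docking model: the weighted sum of the 8 interface terms.

    Requires contact types (and, for non-zero electrostatics, partial
    charges) to have been assigned; lower scores rank better.
    """
    cfg = config or ScoringConfig()
    w = weights or WeightVector.zrt()
    tcr, rec = partner_atoms(model)
    if not tcr or not rec:
        raise ValueError("model must contain both a TCR partner and a receptor partner")
    va, vr = vdw_terms(tcr, rec, cfg)
    sr_a, sr_r, lr_a, lr_r = elec_terms(tcr, rec, cfg)
    ace = contact_potential(tcr, rec, load_pair_potential("ace"), cfg)
    iface = contact_potential(tcr, rec, load_pair_potential("iface"), cfg)
    br = EnergyBreakdown(va, vr, sr_a, sr_r, lr_a, lr_r, ace, iface)
    return w.combine(br), br
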