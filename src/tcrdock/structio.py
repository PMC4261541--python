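"""Structure I/O and annotation.

Reads PDB coordinate files into an :class:`AnnotatedComplex` whose residues are
tagged with interface roles (TCR variable domains, MHC-like platform, antigen),
reads antigen partial charges from Mol2, and assigns the 18 ACE/IFACE-style
heavy-atom contact classes used by the scoring terms.

Residues are addressed throughout by author numbering plus insertion code,
kept verbatim; selections are sets of ``(chain_id, seq_id)`` keys, never index
ranges, so bound/unbound correspondence survives renumbering differences.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "AnnotatedComplex",
    "CaseManifest",
    "read_pdb",
    "write_pdb",
    "read_mol2_charges",
    "write_mol2_charges",
    "assign_contact_types",
    "assign_partial_charges",
    "residue_correspondence",
    "load_contact_class_table",
    "load_pair_potential",
    "CONTACT_CLASSES",
]

ROLES = ("tcr_alpha", "tcr_beta", "mhc_platform", "mhc_other", "antigen", "other")
TCR_ROLES = ("tcr_alpha", "tcr_beta")

#: The 18 heavy-atom contact classes of the shipped typing table.
CONTACT_CLASSES = ("N", "CA", "C", "O", "GC", "CB", "KNZ", "KCD", "DOD", "RNH",
                   "NND", "RNE", "SOG", "HNE", "YCZ", "FCZ", "LCD", "CSG")

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

# Covalent radii (Å) for bond inference in the antigen-typing congruence rule.
_COVALENT_RADIUS = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
                    "P": 1.07, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39}
_BOND_SLACK = 0.45

# Element-level fallback classes for atoms the congruence rule cannot place.
_ELEMENT_DEFAULT = {"C": "LCD", "N": "N", "O": "O", "S": "CSG"}


@dataclass
class Atom:
    """A single atom: label, element, coordinates and scoring annotations."""

    name: str
    element: str
    coord: np.ndarray
    partial_charge: float = 0.0
    contact_type: str = "untyped"
    is_backbone: bool = False
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        self.element = self.element.upper()

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def copy(self) -> "Atom":
        return replace(self, coord=self.coord.copy())


@dataclass
class Residue:
    """A residue (or het-group) with its atoms and interface role."""

    chain_id: str
    seq_id: str            # author number + insertion code, e.g. "100" or "100A"
    name: str
    atoms: list[Atom] = field(default_factory=list)
    role: str = "other"

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.seq_id)

    @property
    def is_amino_acid(self) -> bool:
        return self.name in AA3TO1

    @property
    def one_letter(self) -> str:
        return AA3TO1.get(self.name, "X")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.chain_id}/{self.seq_id} {self.name}: no atom {name}")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def backbone_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_backbone]

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq_id, self.name,
                       [a.copy() for a in self.atoms], self.role)


@dataclass
class CaseManifest:
    """Per-case configuration naming files, chain roles and antigen residues."""

    case_id: str
    chain_roles: dict[str, str]
    tcr_file: str | None = None
    receptor_file: str | None = None
    bound_file: str | None = None
    antigen_residues: list[tuple[str, str]] = field(default_factory=list)
    evaluated_chains: list[str] = field(default_factory=list)
    alpha1_residues: list[tuple[str, str]] = field(default_factory=list)
    cdr_overrides: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role in self.chain_roles.values():
            if role not in ROLES:
                raise ValueError(f"unknown chain role {role!r}; expected one of {ROLES}")
        self.antigen_residues = [tuple(t) for t in self.antigen_residues]
        self.alpha1_residues = [tuple(t) for t in self.alpha1_residues]
        self.cdr_overrides = {k: [tuple(t) for t in v] for k, v in self.cdr_overrides.items()}
        if not self.evaluated_chains:
            self.evaluated_chains = sorted(self.chain_roles)

    @classmethod
    def from_json(cls, path: str | Path) -> "CaseManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        d = {
            "case_id": self.case_id,
            "chain_roles": self.chain_roles,
            "tcr_file": self.tcr_file,
            "receptor_file": self.receptor_file,
            "bound_file": self.bound_file,
            "antigen_residues": [list(t) for t in self.antigen_residues],
            "evaluated_chains": self.evaluated_chains,
            "alpha1_residues": [list(t) for t in self.alpha1_residues],
            "cdr_overrides": {k: [list(t) for t in v] for k, v in self.cdr_overrides.items()},
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


class AnnotatedComplex:
    """An ordered list of role-tagged residues plus named selections.

    Selections (``tcr_variable_sel``, ``platform_sel`` …) are reconstructed
    from residue roles, so the role partition is the single source of truth.
    """

    def __init__(self, residues: Sequence[Residue], provenance: dict | None = None,
                 cdr_sel: Mapping[str, Iterable[tuple[str, str]]] | None = None):
        self.residues: list[Residue] = list(residues)
        self.provenance = dict(provenance or {})
        self.cdr_sel: dict[str, set[tuple[str, str]]] = {
            k: set(map(tuple, v)) for k, v in (cdr_sel or {}).items()}
        self._index = {r.key: r for r in self.residues}
        if len(self._index) != len(self.residues):
            raise ValueError("duplicate (chain, seq_id) residue keys")
        tv, plat = self.tcr_variable_sel, self.platform_sel
        if tv & plat:
            raise ValueError("tcr_variable_sel and platform_sel overlap")
        for loop, sel in self.cdr_sel.items():
            if not sel <= tv:
                raise ValueError(f"CDR selection {loop} not inside the TCR variable domains")

    # -- indexing -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, key: tuple[str, str]) -> Residue:
        return self._index[tuple(key)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self._index

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    # -- role selections ----------------------------------------------------
    def select(self, *roles: str) -> set[tuple[str, str]]:
        return {r.key for r in self.residues if r.role in roles}

    @property
    def tcr_variable_sel(self) -> set[tuple[str, str]]:
        return self.select(*TCR_ROLES)

    @property
    def platform_sel(self) -> set[tuple[str, str]]:
        return self.select("mhc_platform")

    @property
    def antigen_sel(self) -> set[tuple[str, str]]:
        return self.select("antigen")

    def residues_in(self, selection: Iterable[tuple[str, str]]) -> list[Residue]:
        sel = set(map(tuple, selection))
        return [r for r in self.residues if r.key in sel]

    # -- coordinates --------------------------------------------------------
    def coords(self, selection: Iterable[tuple[str, str]] | None = None, *,
               atoms: str = "all") -> np.ndarray:
        """Coordinate array over a selection; ``atoms`` is all|heavy|backbone|ca."""
        res = self.residues if selection is None else self.residues_in(selection)
        out = []
        for r in res:
            if atoms == "all":
                pool = r.atoms
            elif atoms == "heavy":
                pool = r.heavy_atoms()
            elif atoms == "backbone":
                pool = r.backbone_atoms()
            elif atoms == "ca":
                pool = [a for a in r.atoms if a.name == "CA"]
            else:
                raise ValueError(f"unknown atom filter {atoms!r}")
            out.extend(a.coord for a in pool)
        return np.array(out, dtype=float).reshape(-1, 3)

    def copy(self) -> "AnnotatedComplex":
        return AnnotatedComplex([r.copy() for r in self.residues],
                                dict(self.provenance),
                                {k: set(v) for k, v in self.cdr_sel.items()})

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnnotatedComplex":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for r in out.residues:
            for a in r.atoms:
                a.coord = R @ a.coord + t
        return out

    def subset(self, selection: Iterable[tuple[str, str]]) -> "AnnotatedComplex":
        keep = set(map(tuple, selection))
        cdr = {k: v & keep for k, v in self.cdr_sel.items()}
        return AnnotatedComplex([r.copy() for r in self.residues if r.key in keep],
                                dict(self.provenance), cdr)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in res:
        if at.name not in best:
            order.append(at.name)
            best[at.name] = at
        elif at.occ > best[at.name].occ:
            best[at.name] = at
    return [best[n] for n in order]


def read_pdb(path: str | Path, manifest: CaseManifest,
             require_chains: Iterable[str] | None = None) -> AnnotatedComplex:
    """Parse a PDB file and annotate it using the case manifest.

    Alternate locations are resolved to the highest-occupancy copy, waters are
    dropped, and hydrogens are kept if present (never built). Chains listed in
    ``require_chains`` (by default every chain in the manifest) must exist in
    the file; unmapped chains are kept with role ``other``.
    """
    st = gemmi.read_structure(str(path))
    st.remove_waters()
    model = st[0]
    antigen_keys = set(manifest.antigen_residues)
    residues: list[Residue] = []
    chains_seen: set[str] = set()
    for chain in model:
        chains_seen.add(chain.name)
        role = manifest.chain_roles.get(chain.name)
        if role is None:
            warnings.warn(f"chain {chain.name} not in manifest; role set to 'other'")
            role = "other"
        for gres in chain:
            seq_id = f"{gres.seqid.num}{gres.seqid.icode}".strip()
            rname = gres.name.strip()
            atoms = []
            for gat in _resolve_altlocs(gres):
                el = gat.element.name.upper() if gat.element else "C"
                atoms.append(Atom(
                    name=gat.name, element=el, coord=np.array(gat.pos.tolist()),
                    occupancy=gat.occ,
                    is_backbone=(rname in AA3TO1 and gat.name in BACKBONE_ATOMS
                                 and el != "H"),
                ))
            if not atoms:
                continue
            res_role = role
            if (chain.name, seq_id) in antigen_keys or (
                    rname not in AA3TO1 and role in ("mhc_platform", "mhc_other", "other")):
                res_role = "antigen"
            residues.append(Residue(chain.name, seq_id, rname, atoms, res_role))
    required = set(manifest.chain_roles) if require_chains is None \
        else set(require_chains)
    missing = required - chains_seen
    if missing:
        raise ValueError(f"manifest chain(s) {sorted(missing)} absent from {path}")
    prov = {"source_file": str(path), "manifest_id": manifest.case_id}
    return AnnotatedComplex(residues, provenance=prov)


def write_pdb(complex_: AnnotatedComplex, path: str | Path) -> None:
    """Write the complex as a PDB file (ATOM/HETATM with TER records)."""
    st = gemmi.Structure()
    st.name = complex_.provenance.get("manifest_id", "complex")
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for r in complex_.residues:
        ch = chain_map.get(r.chain_id)
        if ch is None:
            ch = gemmi.Chain(r.chain_id)
            chain_map[r.chain_id] = ch
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chain_map[r.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = r.name
        num = r.seq_id
        icode = " "
        if num and num[-1].isalpha():
            num, icode = num[:-1], num[-1]
        gres.seqid = gemmi.SeqId(int(num), icode)
        gres.het_flag = "A" if r.is_amino_acid else "H"
        for a in r.atoms:
            gat = gemmi.Atom()
            gat.name = a.name
            gat.element = gemmi.Element(a.element.capitalize())
            gat.pos = gemmi.Position(*a.coord)
            gat.occ = a.occupancy
            gres.add_atom(gat)
        ch.add_residue(gres)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Mol2 charges
# ---------------------------------------------------------------------------

def read_mol2_charges(path: str | Path) -> dict[str, float]:
    """Read ``atom label -> partial charge`` from a Mol2 ATOM block.

    Charges are the ninth column of each ATOM record; a Mol2 written without
    charges is rejected. The net molecular charge is stored on the returned
    mapping under the attribute-free key convention of a plain dict, and also
    logged via :func:`warnings.warn` when it deviates from an integer by >0.01.
    """
    lines = Path(path).read_text().splitlines()
    charges: dict[str, float] = {}
    in_atoms = False
    saw_block = False
    for line in lines:
        s = line.strip()
        if s.startswith("@<TRIPOS>"):
            in_atoms = s == "@<TRIPOS>ATOM"
            saw_block = saw_block or in_atoms
            continue
        if not in_atoms or not s:
            continue
        parts = s.split()
        if len(parts) < 9:
            raise ValueError(f"{path}: Mol2 ATOM record lacks a charge column: {s!r}")
        charges[parts[1]] = float(parts[8])
    if not saw_block:
        raise ValueError(f"{path}: no @<TRIPOS>ATOM block")
    net = sum(charges.values())
    if abs(net - round(net)) > 0.01:
        warnings.warn(f"{path}: non-integral net charge {net:.3f}")
    return charges


def write_mol2_charges(names_elements_coords_charges, path: str | Path,
                       mol_name: str = "LIG") -> None:
    """Write a minimal Mol2 file (ATOM block only) carrying partial charges."""
    rows = list(names_elements_coords_charges)
    with open(path, "w") as fh:
        fh.write("@<TRIPOS>MOLECULE\n")
        fh.write(f"{mol_name}\n{len(rows)} 0 0 0 0\nSMALL\nUSER_CHARGES\n")
        fh.write("@<TRIPOS>ATOM\n")
        for i, (name, el, xyz, q) in enumerate(rows, 1):
            x, y, z = xyz
            fh.write(f"{i:7d} {name:<8s}{x:10.4f}{y:10.4f}{z:10.4f} "
                     f"{el:<6s}1  {mol_name:<8s}{q:9.4f}\n")


# ---------------------------------------------------------------------------
# Contact typing and charges
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=None)
def _read_data_tsv(fname: str) -> list[list[str]]:
    text = resources.files("tcrdock.data").joinpath(fname).read_text()
    rows = [tuple(ln.split("\t")) for ln in text.splitlines()
            if ln and not ln.startswith("#")]
    return rows[1:]  # drop header


def load_contact_class_table() -> dict[tuple[str, str], str]:
    """The shipped ``(residue, atom) -> contact class`` typing table."""
    return {(res, atom): cls for res, atom, cls in _read_data_tsv("contact_classes.tsv")}


def load_pair_potential(which: str = "ace") -> dict[tuple[str, str], float]:
    """Symmetric 18x18 pair-energy table; ``which`` is ``ace`` or ``iface``."""
    fname = {"ace": "ace_pair_potential.synthetic.tsv",
             "iface": "iface_pair_potential.synthetic.tsv"}[which]
    table: dict[tuple[str, str], float] = {}
    for ci, cj, e in _read_data_tsv(fname):
        table[(ci, cj)] = table[(cj, ci)] = float(e)
    return table


def load_lj_params() -> dict[str, tuple[float, float]]:
    return {el: (float(r), float(e)) for el, r, e in _read_data_tsv("lj_params.tsv")}


def load_residue_charges() -> dict[tuple[str, str], float]:
    return {(res, atom): float(q)
            for res, atom, q in _read_data_tsv("residue_charges.synthetic.tsv")}


def _infer_bonds(atoms: list[Atom]) -> list[set[int]]:
    n = len(atoms)
    coords = np.array([a.coord for a in atoms])
    radii = np.array([_COVALENT_RADIUS.get(a.element, 0.8) for a in atoms])
    nb: list[set[int]] = [set() for _ in range(n)]
    if n < 2:
        return nb
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    cut = radii[:, None] + radii[None, :] + _BOND_SLACK
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < cut[i, j]:
                nb[i].add(j)
                nb[j].add(i)
    return nb


def _congruence_class(atom: Atom, heavy_neighbors: list[tuple[str, float, list[str]]]) -> str:
    """Type a non-amino-acid heavy atom by matching its element and bonded
    heavy-neighbor environment (one and two bonds out) to the nearest
    amino-acid atom class.

    ``heavy_neighbors`` rows are ``(element, bond length, that neighbor's own
    heavy-neighbor elements)``.
    """
    el = atom.element
    n_o = sum(1 for e, _, _ in heavy_neighbors if e == "O")
    n_n = sum(1 for e, _, _ in heavy_neighbors if e == "N")
    if el == "C":
        if n_o >= 2:
            return "C"        # carboxylate/ester carbon (Asp/Glu CG/CD congener)
        if n_o == 1 and n_n >= 1:
            return "C"        # amide carbon
        if n_n >= 1:
            return "KCD"      # carbon alpha to an amine (Lys CE congener)
        if n_o == 1:
            return "CB"       # alcohol-bearing carbon (Ser CB congener)
        return "LCD" if heavy_neighbors else _ELEMENT_DEFAULT["C"]
    if el == "N":
        if any(e == "C" and "O" in nn for e, _, nn in heavy_neighbors):
            return "NND"      # amide nitrogen (Asn ND2 congener)
        if len(heavy_neighbors) >= 2:
            return "HNE"      # ring / secondary nitrogen (His congener)
        if len(heavy_neighbors) == 1:
            return "KNZ"      # terminal amine (Lys NZ congener)
        return _ELEMENT_DEFAULT["N"]
    if el == "O":
        if any(e == "P" for e, _, _ in heavy_neighbors):
            return "DOD"      # phosphate oxygen: carboxylate-oxygen congener
        if any(e == "C" and nn.count("O") >= 2 for e, _, nn in heavy_neighbors):
            return "DOD"      # carboxylate oxygen
        if len(heavy_neighbors) == 1 and heavy_neighbors[0][1] < 1.30:
            return "O"        # short C=O bond: carbonyl oxygen
        if heavy_neighbors:
            return "SOG"      # single-bonded: hydroxyl/ether oxygen
        return _ELEMENT_DEFAULT["O"]
    if el == "S":
        return "CSG"
    return _ELEMENT_DEFAULT.get(el, "untyped")


def assign_contact_types(complex_: AnnotatedComplex,
                         type_table: Mapping[tuple[str, str], str] | None = None,
                         ) -> AnnotatedComplex:
    """Assign a contact class to every heavy atom, in place, and return the complex.

    Amino-acid atoms come straight from the typing table. Antigen (het) atoms
    are typed by congruence: the element plus bonded heavy-neighbor environment
    is matched to the closest amino-acid atom class, falling back to an
    element-default class; atoms of exotic elements stay ``untyped`` with a
    warning and are excluded from the contact-potential sums.
    """
    table = dict(type_table) if type_table is not None else load_contact_class_table()
    n_untyped = 0
    for res in complex_.residues:
        heavy = res.heavy_atoms()
        if res.is_amino_acid:
            for a in heavy:
                cls = table.get((res.name, a.name))
                if cls is None:
                    cls = _ELEMENT_DEFAULT.get(a.element, "untyped")
                a.contact_type = cls
                n_untyped += cls == "untyped"
        else:
            nb = _infer_bonds(res.atoms)
            idx = {id(a): i for i, a in enumerate(res.atoms)}
            for a in heavy:
                i = idx[id(a)]
                info = []
                for j in sorted(nb[i]):
                    other = res.atoms[j]
                    if other.is_hydrogen:
                        continue
                    second = [res.atoms[k].element for k in sorted(nb[j])
                              if k != i and not res.atoms[k].is_hydrogen]
                    info.append((other.element,
                                 float(np.linalg.norm(a.coord - other.coord)),
                                 second))
                a.contact_type = _congruence_class(a, info)
                n_untyped += a.contact_type == "untyped"
        for a in res.atoms:
            if a.is_hydrogen:
                a.contact_type = "untyped"  # hydrogens carry charge, never a type
    if n_untyped:
        warnings.warn(f"{n_untyped} heavy atom(s) left untyped; "
                      "they are excluded from ACE/IFACE sums")
    complex_.provenance["contact_typing"] = "assigned"
    return complex_


def assign_partial_charges(complex_: AnnotatedComplex,
                           antigen_charges: Mapping[str, float] | None = None,
                           ) -> AnnotatedComplex:
    """Assign partial charges in place: protein atoms from the shipped
    formal-charge template, antigen atoms from a Mol2-derived mapping."""
    table = load_residue_charges()
    for res in complex_.residues:
        if res.is_amino_acid:
            for a in res.atoms:
                q = table.get((res.name, a.name))
                if q is None:
                    q = table.get(("*", a.name), 0.0)
                a.partial_charge = q
        elif res.role == "antigen" and antigen_charges:
            for a in res.atoms:
                a.partial_charge = antigen_charges.get(a.name, 0.0)
    complex_.provenance["charges"] = "assigned"
    return complex_


# ---------------------------------------------------------------------------
# Bound/unbound residue correspondence
# ---------------------------------------------------------------------------

def _chain_sequence(residues: list[Residue]) -> str:
    return "".join(r.one_letter for r in residues if r.is_amino_acid)


def residue_correspondence(a: AnnotatedComplex, b: AnnotatedComplex,
                           roles: Iterable[str] | None = None,
                           ) -> dict[tuple[str, str], tuple[str, str]]:
    """Map residue keys of ``a`` to keys of ``b`` by per-role sequence alignment.

    Bound and unbound entries routinely differ in numbering conventions, so the
    pairing is established from a global alignment of each role's chain
    sequence, never from residue numbers. Het (antigen) residues are paired by
    residue name and order within the role.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5

    roles = tuple(roles) if roles is not None else ROLES
    mapping: dict[tuple[str, str], tuple[str, str]] = {}
    for role in roles:
        ra = [r for r in a.residues if r.role == role]
        rb = [r for r in b.residues if r.role == role]
        if not ra or not rb:
            continue
        aa = [r for r in ra if r.is_amino_acid]
        bb = [r for r in rb if r.is_amino_acid]
        if aa and bb:
            aln = aligner.align(_chain_sequence(aa), _chain_sequence(bb))[0]
            for block_a, block_b in zip(aln.aligned[0], aln.aligned[1]):
                for i, j in zip(range(*block_a), range(*block_b)):
                    mapping[aa[i].key] = bb[j].key
        het_a = [r for r in ra if not r.is_amino_acid]
        het_b = [r for r in rb if not r.is_amino_acid]
        by_name: dict[str, list[Residue]] = {}
        for r in het_b:
            by_name.setdefault(r.name, []).append(r)
        for r in het_a:
            pool = by_name.get(r.name)
            if pool:
                mapping[r.key] = pool.pop(0).key
    return mapping
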