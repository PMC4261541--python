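"""Rigid-body geometry: superposition, RMSD, groove frame and start poses.

The docking start positions are parameterized over an orthonormal frame built
from the MHC-like platform helices: the groove axis (first principal axis of
the helix Cα cloud, oriented N→C along the α1 helix), the helix-plane normal
(pointing from the platform toward the TCR side), and their cross product.
A start pose is then four numbers — height above the helix centroid along the
normal, shift along the groove axis, crossing angle in the helix plane, and a
tilt toward the groove-axis C-terminus — which is exactly the parameterization
behind the shipped ``start1``–``start4`` presets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import AnnotatedComplex, residue_correspondence

__all__ = [
    "RigidTransform",
    "GrooveFrame",
    "StartPoseSpec",
    "START_SITES",
    "superpose",
    "rmsd",
    "groove_frame",
    "tcr_axis",
    "place_start",
    "measure_start_pose",
    "backbone_rmsd",
]


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``first`` then ``self``."""
        return RigidTransform(self.rotation @ first.rotation,
                              self.rotation @ first.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(mobile_coords: np.ndarray, ref_coords: np.ndarray,
              ) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) superposition of paired coordinate sets.

    Returns the proper rigid transform minimizing the RMSD of
    ``R @ mobile + t`` onto ``ref``, and that minimum RMSD.
    """
    P = np.asarray(mobile_coords, float).reshape(-1, 3)
    Q = np.asarray(ref_coords, float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError("superpose needs equal-length paired coordinate sets")
    if len(P) < 3:
        raise ValueError("superpose needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    tf = RigidTransform(R, t)
    return tf, rmsd(tf.apply(P), Q)


# ---------------------------------------------------------------------------
# Groove frame and TCR pseudo-symmetry axis
# ---------------------------------------------------------------------------

@dataclass
class GrooveFrame:
    """Right-handed orthonormal frame anchored on the platform helices."""

    origin: np.ndarray       # centroid of α1/α2 helix Cα atoms
    groove_axis: np.ndarray  # toward the α1-helix C-terminus
    normal: np.ndarray       # perpendicular to the helix plane, toward the TCR
    third_axis: np.ndarray   # normal × groove_axis

    def __post_init__(self) -> None:
        for name in ("origin", "groove_axis", "normal", "third_axis"):
            setattr(self, name, np.asarray(getattr(self, name), float).reshape(3))
        M = np.stack([self.groove_axis, self.third_axis, self.normal])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-6):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(M) < 0:
            raise ValueError("frame must be right-handed")

    def transformed(self, tf: RigidTransform) -> "GrooveFrame":
        R = tf.rotation
        return GrooveFrame(tf.apply(self.origin[None])[0], R @ self.groove_axis,
                           R @ self.normal, R @ self.third_axis)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length direction vector")
    return v / n


def groove_frame(complex_: AnnotatedComplex,
                 alpha1: list[tuple[str, str]] | None = None) -> GrooveFrame:
    """Build the groove frame from the platform-helix Cα atoms.

    ``alpha1`` optionally names the α1-helix residues in N→C order (e.g. from
    the case manifest); by default the first half of the platform residues in
    file order stands in for α1. The groove axis is the first principal axis
    of the helix Cα coordinates oriented along the α1 N→C direction; the
    normal is the smallest principal axis (perpendicular to the helix plane),
    oriented toward the antigen — i.e. the TCR-accessible face of the groove.
    """
    platform = [r for r in complex_.residues if r.role == "mhc_platform"]
    ca = complex_.coords(complex_.platform_sel, atoms="ca")
    if len(ca) < 20:
        raise ValueError(f"platform has only {len(ca)} Cα atoms; need >= 20 "
                         "spanning both helices")
    origin = ca.mean(axis=0)
    X = ca - origin
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    axis, normal = Vt[0], Vt[2]

    if alpha1:
        a1 = complex_.residues_in(alpha1)
    else:
        a1 = platform[: len(platform) // 2]
    if len(a1) < 2:
        raise ValueError("cannot orient the groove axis: α1 helix under-defined")
    n_to_c = a1[-1].atom("CA").coord - a1[0].atom("CA").coord
    if np.dot(axis, n_to_c) < 0:
        axis = -axis

    ag = complex_.antigen_sel
    other = complex_.select("mhc_other")
    if ag:
        ref = complex_.coords(ag, atoms="all").mean(axis=0) - origin
        if np.dot(normal, ref) < 0:
            normal = -normal
    elif other:
        ref = origin - complex_.coords(other, atoms="all").mean(axis=0)
        if np.dot(normal, ref) < 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal

    normal = _unit(normal - np.dot(normal, axis) * axis)  # enforce exact orthogonality
    return GrooveFrame(origin, _unit(axis), normal, np.cross(normal, axis))


def _framework_ca(complex_: AnnotatedComplex, role: str) -> np.ndarray:
    cdr = set().union(*complex_.cdr_sel.values()) if complex_.cdr_sel else set()
    keys = [r.key for r in complex_.residues
            if r.role == role and r.is_amino_acid and r.key not in cdr]
    return complex_.coords(keys, atoms="ca")


def tcr_axis(complex_: AnnotatedComplex,
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The pseudo-two-fold axis relating Vα and Vβ, plus the domain centroids.

    The axis is the rotation axis of the transform superposing the Vα
    framework Cα trace onto the Vβ framework (γδ TCRs are handled upstream by
    assigning δ the α role and γ the β role). Its sign is fixed toward the
    CDR loops — the face that engages the antigen-presenting platform — when
    CDR selections are annotated, and is otherwise made deterministic by
    pointing away from the backbone centroid of the whole variable module.
    """
    va, vb = _framework_ca(complex_, "tcr_alpha"), _framework_ca(complex_, "tcr_beta")
    if len(va) < 3 or len(vb) < 3:
        raise ValueError("both TCR variable domains are required for the pseudo-symmetry axis")
    n = min(len(va), len(vb))
    tf, _ = superpose(va[:n], vb[:n])
    rotvec = Rotation.from_matrix(tf.rotation).as_rotvec()
    if np.linalg.norm(rotvec) < 1e-6:
        raise ValueError("Vα and Vβ are related by a pure translation; axis undefined")
    axis = _unit(rotvec)
    ca_all = complex_.coords(complex_.tcr_variable_sel, atoms="ca")
    centroid = ca_all.mean(axis=0)
    if complex_.cdr_sel and any(complex_.cdr_sel.values()):
        cdr_keys = set().union(*complex_.cdr_sel.values())
        cdr_centroid = complex_.coords(cdr_keys, atoms="ca").mean(axis=0)
        if np.dot(axis, cdr_centroid - centroid) < 0:
            axis = -axis
    else:
        bb = complex_.coords(complex_.tcr_variable_sel, atoms="backbone").mean(axis=0)
        if np.dot(axis, centroid - bb) < 0:
            axis = -axis
    return axis, va.mean(axis=0), vb.mean(axis=0)


# ---------------------------------------------------------------------------
# Start poses
# ---------------------------------------------------------------------------

@dataclass
class StartPoseSpec:
    """Four-parameter rigid placement of a TCR over the groove frame."""

    height: float = 25.0          # Å along the normal
    shift: float = 0.0            # Å along the groove axis (toward α1 C-term)
    crossing_angle: float = 45.0  # degrees, in the helix plane
    tilt: float = 0.0             # degrees, toward the groove-axis C-term

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be positive")


#: Shipped docking start sites (height Å, shift Å, crossing °, tilt °).
START_SITES = {
    "start1": StartPoseSpec(25.0, 0.0, 45.0, 0.0),
    "start2": StartPoseSpec(25.0, 20.0, 0.0, 25.0),
    "start3": StartPoseSpec(25.0, 10.0, 22.5, 12.5),
    "start4": StartPoseSpec(25.0, 25.0, -15.0, 40.0),
}


def _tcr_triad(complex_: AnnotatedComplex) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal TCR body frame [axis, in-plane interdomain dir, cross]."""
    axis, ca_cent, cb_cent = tcr_axis(complex_)
    inter = cb_cent - ca_cent
    w = _unit(inter - np.dot(inter, axis) * axis)
    return np.stack([axis, w, np.cross(axis, w)], axis=1), \
        complex_.coords(complex_.tcr_variable_sel, atoms="ca").mean(axis=0)


def place_start(tcr: AnnotatedComplex, receptor: AnnotatedComplex,
                spec: StartPoseSpec,
                frame: GrooveFrame | None = None,
                ) -> tuple[AnnotatedComplex, RigidTransform]:
    """Place the TCR over the groove per a start-pose spec.

    The TCR pseudo-symmetry axis is set anti-parallel to the groove normal,
    the Vα→Vβ inter-domain direction (projected on the helix plane) is set at
    the requested crossing angle from the groove axis (counter-clockwise
    positive viewed down the normal), the variable-domain centroid is placed
    at ``origin + height·normal + shift·groove_axis``, and the tilt is applied
    last as a rotation about the third axis through the TCR centroid.
    """
    fr = frame if frame is not None else groove_frame(receptor)
    B, centroid = _tcr_triad(tcr)

    u_t = -fr.normal
    chi = np.radians(spec.crossing_angle)
    w_t = Rotation.from_rotvec(chi * fr.normal).apply(fr.groove_axis)
    T = np.stack([u_t, w_t, np.cross(u_t, w_t)], axis=1)
    R = T @ B.T
    target = fr.origin + spec.height * fr.normal + spec.shift * fr.groove_axis
    base = RigidTransform(R, target - R @ centroid)

    tilt = Rotation.from_rotvec(np.radians(spec.tilt) * fr.third_axis).as_matrix()
    tilt_tf = RigidTransform(tilt, target - tilt @ target)
    tf = tilt_tf.compose(base)
    return tcr.transformed(tf.rotation, tf.translation), tf


def measure_start_pose(placed_tcr: AnnotatedComplex, receptor: AnnotatedComplex,
                       frame: GrooveFrame | None = None) -> StartPoseSpec:
    """Inverse of :func:`place_start`: read (height, shift, crossing, tilt)
    off an already-placed TCR."""
    fr = frame if frame is not None else groove_frame(receptor)
    B, centroid = _tcr_triad(placed_tcr)
    u = B[:, 0]
    d = centroid - fr.origin
    height = float(np.dot(d, fr.normal))
    shift = float(np.dot(d, fr.groove_axis))
    # Tilt rotated -normal within the (groove_axis, normal) plane:
    # u = -cosθ·normal - sinθ·groove_axis.
    theta = np.arctan2(-np.dot(u, fr.groove_axis), -np.dot(u, fr.normal))
    untilt = Rotation.from_rotvec(-theta * fr.third_axis).as_matrix()
    w = untilt @ B[:, 1]
    w = w - np.dot(w, fr.normal) * fr.normal
    chi = np.arctan2(np.dot(w, fr.third_axis), np.dot(w, fr.groove_axis))
    return StartPoseSpec(height, shift, float(np.degrees(chi)), float(np.degrees(theta)))


# ---------------------------------------------------------------------------
# Backbone RMSD over selections
# ---------------------------------------------------------------------------

def _paired_backbone(a: AnnotatedComplex, b: AnnotatedComplex,
                     selection, mapping) -> tuple[np.ndarray, np.ndarray]:
    pa, pb = [], []
    for key in selection:
        key = tuple(key)
        bkey = mapping.get(key)
        if bkey is None or key not in a or bkey not in b:
            continue
        ra, rb = a[key], b[bkey]
        if not (ra.is_amino_acid and rb.is_amino_acid):
            continue  # only protein backbone atoms enter any RMSD
        atoms_b = {at.name: at for at in rb.backbone_atoms()}
        for at in ra.backbone_atoms():
            mate = atoms_b.get(at.name)
            if mate is not None:
                pa.append(at.coord)
                pb.append(mate.coord)
    return np.array(pa, float).reshape(-1, 3), np.array(pb, float).reshape(-1, 3)


def backbone_rmsd(complex_a: AnnotatedComplex, complex_b: AnnotatedComplex,
                  selection, fit_selection=None,
                  correspondence: dict | None = None) -> float:
    """Backbone RMSD over ``selection`` after superposing on ``fit_selection``
    (on the selection itself when no fit selection is given).

    Residue pairing comes from ``correspondence`` (keys of ``complex_a`` →
    keys of ``complex_b``); by default it is established by per-role sequence
    alignment. Antigen/het residues never contribute atoms.
    """
    mapping = correspondence if correspondence is not None else \
        residue_correspondence(complex_a, complex_b)
    sel_a, sel_b = _paired_backbone(complex_a, complex_b, selection, mapping)
    if len(sel_a) == 0:
        raise ValueError("empty residue pairing over the RMSD selection")
    if fit_selection is None:
        tf, value = superpose(sel_a, sel_b)
        return value
    fit_a, fit_b = _paired_backbone(complex_a, complex_b, fit_selection, mapping)
    if len(fit_a) == 0:
        raise ValueError("empty residue pairing over the fit selection")
    tf, _ = superpose(fit_a, fit_b)
    return rmsd(tf.apply(sel_a), sel_b)
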