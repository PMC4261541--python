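"""Pairwise comparison and clustering of docking models.

Distances between models are backbone RMSDs over a shared loop selection
(e.g. the germline CDR1α/CDR2α loops of two clonally related TCRs) measured
after superposing the receptor platforms — so the distance captures where the
loops sit over the groove, not internal loop geometry. The distance matrix
feeds single-linkage flat clustering and a neighbor-joining unrooted tree.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structio import AnnotatedComplex
from .geometry import rmsd, superpose

__all__ = ["ModelDistanceMatrix", "model_distance", "distance_matrix", "cluster_tree"]


def _backbone_coords(model: AnnotatedComplex, keys) -> np.ndarray:
    out = []
    for key in keys:
        res = model[key]
        for a in sorted(res.backbone_atoms(), key=lambda a: a.name):
            out.append((a.name, a.coord))
    return np.array([c for _, c in out], float).reshape(-1, 3)


def _check_loops(a: AnnotatedComplex, b: AnnotatedComplex, loop_keys) -> None:
    bad = []
    for key in loop_keys:
        if key not in a or key not in b:
            bad.append(f"{key} missing")
        elif a[key].name != b[key].name:
            bad.append(f"{key}: {a[key].name} vs {b[key].name}")
    if bad:
        raise ValueError("loop selection not shared between models: " + "; ".join(bad))


def model_distance(model_a: AnnotatedComplex, model_b: AnnotatedComplex,
                   receptor_sel=None, loop_sel=None) -> float:
    """Loop backbone RMSD between two models over a superposed receptor.

    ``model_b``'s receptor (platform backbone by default) is superposed onto
    ``model_a``'s; the RMSD over ``loop_sel`` backbone atoms is then taken
    with no further fitting. Loop residues must be identical in sequence
    between the two models (mismatches are reported by position).
    """
    rec_keys = sorted(receptor_sel) if receptor_sel is not None else \
        sorted(model_a.platform_sel)
    if loop_sel is None:
        raise ValueError("a loop selection is required")
    loop_keys = sorted(loop_sel)
    _check_loops(model_a, model_b, loop_keys)
    _check_loops(model_a, model_b, rec_keys)
    tf, _ = superpose(_backbone_coords(model_b, rec_keys),
                      _backbone_coords(model_a, rec_keys))
    la = _backbone_coords(model_a, loop_keys)
    lb = tf.apply(_backbone_coords(model_b, loop_keys))
    if la.shape != lb.shape:
        raise ValueError("loop atom counts differ between models")
    return rmsd(la, lb)


@dataclass
class ModelDistanceMatrix:
    """Symmetric RMSD matrix over the models of one or two sets."""

    ids: list[str]
    set_labels: list[str]
    matrix: np.ndarray
    loop_sel: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("matrix must be symmetric")
        if (self.matrix < -1e-12).any():
            raise ValueError("negative distances")

    def min_pair(self) -> tuple[str, str, float]:
        """Smallest distance (between the two sets when two are present,
        otherwise off-diagonal) and its model pair."""
        two_sets = len(set(self.set_labels)) == 2
        best = (None, None, np.inf)
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if two_sets and self.set_labels[i] == self.set_labels[j]:
                    continue
                if self.matrix[i, j] < best[2]:
                    best = (self.ids[i], self.ids[j], float(self.matrix[i, j]))
        return best

    def to_tsv(self, path) -> None:
        import pandas as pd
        labels = [f"{s}:{i}" if s else i for s, i in zip(self.set_labels, self.ids)]
        pd.DataFrame(self.matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def distance_matrix(set_a: dict[str, AnnotatedComplex],
                    set_b: dict[str, AnnotatedComplex] | None = None,
                    receptor_sel=None, loop_sel=None) -> ModelDistanceMatrix:
    """All-pairs loop-RMSD matrix over one model set, or the joint matrix
    over two sets (the cross-set block is the Additional-file-style heat map;
    the minimum cross-set entry is available from :meth:`min_pair`)."""
    if not set_a or (set_b is not None and not set_b):
        raise ValueError("each model set needs at least one model")
    items = [("A", k, v) for k, v in set_a.items()]
    if set_b is not None:
        items += [("B", k, v) for k, v in set_b.items()]
    n = len(items)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = model_distance(items[i][2], items[j][2],
                                               receptor_sel, loop_sel)
    return ModelDistanceMatrix([k for _, k, _ in items],
                               [s if set_b is not None else "" for s, _, _ in items],
                               m, sorted(loop_sel) if loop_sel else [])


def cluster_tree(matrix: ModelDistanceMatrix | np.ndarray,
                 ids: list[str] | None = None, cut: float = 4.0,
                 ) -> tuple[str | None, dict[str, int]]:
    """Neighbor-joining unrooted tree (newick) plus single-linkage flat
    clusters at an RMSD cut height (default 4 Å).

    With fewer than 3 leaves no tree is built and only the clusters are
    returned.
    """
    if isinstance(matrix, ModelDistanceMatrix):
        m = matrix.matrix
        labels = [f"{s}:{i}" if s else i for s, i in
                  zip(matrix.set_labels, matrix.ids)]
    else:
        m = np.asarray(matrix, float)
        labels = list(ids) if ids is not None else [str(i) for i in range(len(m))]
    n = len(labels)
    if n == 1:
        return None, {labels[0]: 1}
    condensed = squareform(m, checks=False)
    assignments = fcluster(linkage(condensed, method="single"), t=cut,
                           criterion="distance")
    clusters = dict(zip(labels, map(int, assignments)))
    if n < 3:
        return None, clusters
    from io import StringIO
    from skbio import DistanceMatrix
    from skbio.tree import nj
    tree = nj(DistanceMatrix(m, ids=labels))
    buf = StringIO()
    tree.write(buf)
    return buf.getvalue().strip(), clusters
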