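"""Principal components of shape and phylomorphospace projection.

Covariance (not correlation) PCA of the centered, flattened Procrustes
coordinates — the standard ordination for shape data.  Extreme shapes along
an axis are reconstructed as mean + score * eigenvector.  The
phylomorphospace projects the phylogeny into score space via maximum
likelihood ancestral states under Brownian motion, which on a dated tree is
equivalent to weighted squared-change parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .datatypes import AlignedShapes
from .phylo_comparative import Phylogeny


@dataclass
class PCAResult:
    scores: np.ndarray           # specimen x k
    eigenvectors: np.ndarray     # (3 * points) x k, orthonormal columns
    eigenvalues: np.ndarray      # non-increasing
    mean: np.ndarray             # flattened mean shape
    specimen_ids: List[str]
    point_ids: List[str]

    @property
    def variance_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    def n_components_for(self, fraction: float) -> int:
        """Smallest number of axes explaining at least `fraction` of variance."""
        cum = np.cumsum(self.variance_fraction)
        return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def pca(aligned: AlignedShapes,
        point_subset: Sequence[str] | None = None) -> PCAResult:
    """Covariance PCA of shape via SVD of the centered coordinate matrix.

    Retains k = min(n - 1, 3p) axes.  Eigenvector sign is fixed by making
    each column's largest-magnitude loading positive so plots reproduce.
    """
    sub = aligned if point_subset is None else aligned.subset_points(point_subset)
    if sub.n_specimens < 3:
        raise ValueError("need at least 3 specimens")
    X = sub.flat()
    n, p3 = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, p3)
    s, Vt, U = s[:k], Vt[:k], U[:, :k]
    eigenvalues = s ** 2 / (n - 1)
    # sign convention: largest-|loading| entry of each eigenvector positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U * s
    return PCAResult(scores=scores, eigenvectors=Vt.T, eigenvalues=eigenvalues,
                     mean=mean, specimen_ids=list(sub.specimen_ids),
                     point_ids=list(sub.point_ids))


def reconstruct_shape(result: PCAResult, axis: int = 0,
                      score: float = 0.0) -> np.ndarray:
    """Coordinates (points x 3) of the shape at a given score on one axis."""
    if axis >= result.eigenvectors.shape[1]:
        raise ValueError("axis beyond retained components")
    flat = result.mean + score * result.eigenvectors[:, axis]
    return flat.reshape(-1, 3)


def extreme_shapes(result: PCAResult, axis: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Shapes at the +/- observed score extremes of an axis."""
    m = float(np.max(np.abs(result.scores[:, axis])))
    return (reconstruct_shape(result, axis, +m),
            reconstruct_shape(result, axis, -m))


@dataclass
class Phylomorphospace:
    tip_scores: Dict[str, np.ndarray]
    node_scores: Dict[str, np.ndarray]
    edges: List[Tuple[str, str]]


def ancestral_scores(phylogeny: Phylogeny, tip_scores: np.ndarray,
                     tip_names: Sequence[str]) -> Phylomorphospace:
    """ML ancestral states of ordination scores under Brownian motion.

    Solves the weighted squared-change parsimony problem: internal values
    minimising sum over edges of (difference along edge)^2 / edge length.
    The minimiser satisfies a sparse linear system (each internal node is
    the edge-length-weighted average of its neighbours).
    """
    Y = np.atleast_2d(np.asarray(tip_scores, dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    phylogeny.check_names(tip_names)
    row = {name: i for i, name in enumerate(tip_names)}
    tree = phylogeny.tree

    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    node_id = {id(nd): i for i, nd in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros((m, Y.shape[1]))
    edges: List[Tuple[str, str]] = []
    labels: Dict[int, str] = {}
    for i, nd in enumerate(internal):
        labels[id(nd)] = nd.taxon.label if nd.taxon else f"node{i}"

    def name_of(nd) -> str:
        return nd.taxon.label if (nd.is_leaf() and nd.taxon) else labels[id(nd)]

    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        if parent is None:
            continue
        w = 1.0 / max(nd.edge.length or 0.0, 1e-12)
        pi = node_id[id(parent)]
        if nd.is_leaf():
            A[pi, pi] += w
            b[pi] += w * Y[row[nd.taxon.label]]
        else:
            ci = node_id[id(nd)]
            A[pi, pi] += w
            A[ci, ci] += w
            A[pi, ci] -= w
            A[ci, pi] -= w
        edges.append((name_of(parent), name_of(nd)))

    vals = np.linalg.solve(A, b)
    node_scores = {labels[id(nd)]: vals[node_id[id(nd)]] for nd in internal}
    tips = {name: Y[row[name]] for name in tip_names}
    return Phylomorphospace(tip_scores=tips, node_scores=node_scores, edges=edges)
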