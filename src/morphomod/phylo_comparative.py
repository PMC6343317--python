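"""Phylogenetic comparative methods for high-dimensional shape data.

Implements the Brownian-motion machinery used throughout the pipeline:

* :class:`Phylogeny` — a rooted, dated tree with its BM covariance matrix
  ``C`` (entry ``C[i, j]`` is the shared root-to-MRCA path length of tips
  ``i`` and ``j``).
* Felsenstein phylogenetic independent contrasts (:func:`pic`).
* Multivariate phylogenetic signal K_mult (:func:`k_mult`), the
  multivariate generalisation of Blomberg's K: the ratio of observed to
  Brownian-expected phylogenetic structure, 1 under exact BM.
* Phylogenetic generalised least squares for high-dimensional responses
  (:func:`pgls_fit`) and phylogenetic ANOVA (:func:`phylo_anova`), with
  significance by permutation of phenotypes across tips.
* Benjamini-Hochberg false-discovery-rate adjustment (:func:`bh_adjust`).

All permutation p-values use the (b + 1) / (m + 1) convention, where b is
the number of permuted statistics at least as extreme as the observed one
and m the number of permutations.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from statsmodels.stats.multitest import multipletests


class Phylogeny:
    """Rooted, dated phylogeny with cached BM covariance structure.

    Wraps a :class:`dendropy.Tree`. Tip order (and hence row/column order
    of ``C``) is the order of ``tip_labels``.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        leaves = list(tree.leaf_node_iter())
        labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
        if any(l is None for l in labels):
            raise ValueError("all tips must be labelled")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip names: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has edges without branch lengths")
        self.tip_labels: List[str] = sorted(labels)
        self._C: Optional[np.ndarray] = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate tip names in tree: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick())

    def as_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + "\n"

    # -- structure ---------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def root_to_tip_distances(self) -> Dict[str, float]:
        out = {}
        for lf in self.tree.leaf_node_iter():
            d = 0.0
            node = lf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[lf.taxon.label] = d
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = list(self.root_to_tip_distances().values())
        return (max(d) - min(d)) <= tol * max(max(d), 1.0)

    def depth(self) -> float:
        return max(self.root_to_tip_distances().values())

    def covariance(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        """BM covariance C: shared root-to-MRCA path length per tip pair."""
        if self._C is None:
            labels = self.tip_labels
            index = {l: i for i, l in enumerate(labels)}
            n = len(labels)
            C = np.zeros((n, n))
            # accumulate: each edge of length b adds b to C[i, j] for every
            # tip pair (i, j) below it
            for node in self.tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                below = [index[lf.taxon.label] for lf in node.leaf_iter()]
                b = node.edge.length or 0.0
                C[np.ix_(below, below)] += b
            self._C = C
        if order is None:
            return self._C.copy()
        idx = [self.tip_labels.index(l) for l in order]
        return self._C[np.ix_(idx, idx)]

    def check_names(self, names: Sequence[str]) -> None:
        tips = set(self.tip_labels)
        extra = sorted(set(names) - tips)
        missing = sorted(tips - set(names))
        if extra or missing:
            raise ValueError(
                f"specimen/tip mismatch: not on tree {extra[:5]}, "
                f"no data for tips {missing[:5]}"
            )

    def prune_to(self, names: Sequence[str]) -> "Phylogeny":
        tree = self.tree.clone(depth=1)
        keep = set(names)
        taxa = [t for t in tree.taxon_namespace if t.label in keep]
        tree.retain_taxa(taxa)
        return Phylogeny(tree)


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition.

    Eigendecomposition (rather than Cholesky) keeps the transform invariant
    to tip ordering.
    """
    w, V = np.linalg.eigh(C)
    if w.min() <= 0:
        raise np.linalg.LinAlgError(
            f"phylogenetic covariance not positive definite (min eig {w.min():.3g})"
        )
    return (V * (1.0 / np.sqrt(w))) @ V.T


def _sqrt_pd(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0, None)
    return (V * np.sqrt(w)) @ V.T


def gls_mean(C_inv: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """GLS (phylogenetic) mean a = (1'C^-1 1)^-1 1'C^-1 Y."""
    ones = np.ones(C_inv.shape[0])
    w = C_inv @ ones
    return (w @ Y) / (ones @ w)


# ---------------------------------------------------------------------------
# Phylogenetic independent contrasts
# ---------------------------------------------------------------------------

def pic(phylogeny: Phylogeny, tip_matrix: np.ndarray,
        tip_names: Sequence[str]) -> np.ndarray:
    """Felsenstein standardized independent contrasts, column-wise.

    At each internal node the contrast is (x_left - x_right)/sqrt(b_l + b_r)
    and the ancestral branch is lengthened by b_l*b_r/(b_l + b_r).
    Polytomies are resolved arbitrarily into zero-length branches with a
    warning. Returns an (n-1) x p matrix (row order: postorder).
    """
    Y = np.atleast_2d(np.asarray(tip_matrix, dtype=float))
    if Y.shape[0] != len(tip_names):
        raise ValueError("tip_matrix rows must match tip_names")
    phylogeny.check_names(tip_names)
    row = {name: i for i, name in enumerate(tip_names)}

    tree = phylogeny.tree.clone(depth=1)
    poly = [nd for nd in tree.preorder_node_iter() if len(nd.child_nodes()) > 2]
    if poly:
        warnings.warn("polytomies resolved to zero-length branches for contrasts")
        tree.resolve_polytomies()

    values: Dict[int, np.ndarray] = {}
    lengths: Dict[int, float] = {}
    contrasts: List[np.ndarray] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            values[id(node)] = Y[row[node.taxon.label]]
            lengths[id(node)] = node.edge.length or 0.0
            continue
        children = node.child_nodes()
        if len(children) == 1:  # knuckle: pass through
            c = children[0]
            values[id(node)] = values[id(c)]
            lengths[id(node)] = (node.edge.length or 0.0) + lengths[id(c)]
            continue
        left, right = children
        bl, br = lengths[id(left)], lengths[id(right)]
        xl, xr = values[id(left)], values[id(right)]
        denom = bl + br
        if denom <= 0:
            denom = 1e-12
        contrasts.append((xl - xr) / np.sqrt(denom))
        values[id(node)] = (br * xl + bl * xr) / denom if denom > 0 else 0.5 * (xl + xr)
        lengths[id(node)] = (node.edge.length or 0.0) + bl * br / denom
    return np.array(contrasts)


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    k_mult: float
    p_value: float
    n_perm: int
    permuted: np.ndarray = field(repr=False, default=None)


def k_mult(phylogeny: Phylogeny, Y: np.ndarray, tip_names: Sequence[str],
           n_perm: int = 999, seed: int = 0) -> SignalResult:
    """Multivariate phylogenetic signal K_mult.

    K = [sum ||Y_i - a||^2 / sum ||U_i||^2] / [(tr C - n/(1'C^-1 1))/(n-1)],
    with a the GLS phylogenetic mean and U = C^(-1/2)(Y - 1a').  Equals 1
    exactly when C is proportional to the identity (star tree) and in
    expectation under BM on the analysis tree.  p-value by permuting rows
    of Y across tips (large K = strong signal).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 tips")
    C = phylogeny.covariance(order=tip_names)
    C_inv = np.linalg.inv(C)
    P = _inv_sqrt(C)
    ones = np.ones(n)
    denom_scale = (np.trace(C) - n / (ones @ C_inv @ ones)) / (n - 1)

    def stat(Ymat: np.ndarray) -> float:
        a = gls_mean(C_inv, Ymat)
        R = Ymat - a
        num = float(np.sum(R ** 2))
        U = P @ R
        den = float(np.sum(U ** 2))
        return (num / den) / denom_scale

    obs = stat(Y)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        permuted[b] = stat(Y[rng.permutation(n)])
    p = (np.sum(permuted >= obs) + 1) / (n_perm + 1)
    return SignalResult(k_mult=obs, p_value=float(p), n_perm=n_perm, permuted=permuted)


# ---------------------------------------------------------------------------
# PGLS / phylogenetic ANOVA
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    r_squared: float
    f_statistic: float
    p_value: float
    coefficients: np.ndarray
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    n_perm: int = 0


def _fit_transformed(Yt: np.ndarray, Xt: np.ndarray,
                     X0t: np.ndarray) -> Tuple[float, float, np.ndarray, np.ndarray]:
    """R^2 and F of the full design Xt against the intercept-only design X0t,
    summed over all response columns (transformed scale)."""
    beta, *_ = np.linalg.lstsq(Xt, Yt, rcond=None)
    fitted = Xt @ beta
    sse_full = float(np.sum((Yt - fitted) ** 2))
    beta0, *_ = np.linalg.lstsq(X0t, Yt, rcond=None)
    sse_red = float(np.sum((Yt - X0t @ beta0) ** 2))
    n, k_full = Xt.shape
    k_red = X0t.shape[1]
    ss_model = sse_red - sse_full
    r2 = ss_model / sse_red if sse_red > 0 else 1.0
    df1 = k_full - k_red
    df2 = n - k_full
    f = (ss_model / df1) / (sse_full / df2) if sse_full > 0 and df2 > 0 else np.inf
    return r2, f, beta, fitted


def pgls_fit(phylogeny: Phylogeny, Y: np.ndarray, X: np.ndarray,
             tip_names: Sequence[str], n_perm: int = 1000,
             seed: int = 0) -> RegressionResult:
    """Phylogenetic GLS regression of a (possibly high-dimensional) Y on X.

    Both sides are premultiplied by C^(-1/2); R^2 is the model sum of
    squares over the total sum of squares on the transformed scale, summed
    over all columns.  Significance by permuting rows of Y across tips and
    refitting (F statistic compared).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = Y.shape[0]
    C = phylogeny.covariance(order=tip_names)
    P = _inv_sqrt(C)
    ones = np.ones((n, 1))
    Xd = np.hstack([ones, X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("rank-deficient design matrix")
    Xt, X0t = P @ Xd, P @ ones

    def fit(Ymat):
        return _fit_transformed(P @ Ymat, Xt, X0t)

    r2, f, beta, fitted_t = fit(Y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        _, f_perm, _, _ = fit(Y[rng.permutation(n)])
        count += f_perm >= f
    p = (count + 1) / (n_perm + 1)
    Pinv = _sqrt_pd(C)
    fitted = Pinv @ fitted_t
    return RegressionResult(r_squared=r2, f_statistic=f, p_value=float(p),
                            coefficients=beta, fitted=fitted,
                            residuals=Y - fitted, n_perm=n_perm)


def dummy_code(groups: Sequence) -> np.ndarray:
    """Treatment-coded design columns (first level as reference)."""
    levels = sorted(set(groups), key=str)
    cols = [[1.0 if g == lv else 0.0 for g in groups] for lv in levels[1:]]
    return np.array(cols).T if cols else np.empty((len(list(groups)), 0))


def phylo_anova(phylogeny: Phylogeny, Y: np.ndarray, groups: Sequence,
                tip_names: Sequence[str], n_perm: int = 1000,
                seed: int = 0) -> RegressionResult:
    """Phylogenetic ANOVA: PGLS with a dummy-coded categorical factor.

    Tips with a missing (None/NaN) group value are dropped from the
    analysis, and the tree pruned to match.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    groups = list(groups)
    keep = [i for i, g in enumerate(groups)
            if g is not None and not (isinstance(g, float) and np.isnan(g))]
    if len(keep) < len(groups):
        tip_names = [tip_names[i] for i in keep]
        Y = Y[keep]
        groups = [groups[i] for i in keep]
        phylogeny = phylogeny.prune_to(tip_names)
    levels = sorted(set(groups), key=str)
    if len(levels) < 2:
        raise ValueError("need at least two group levels")
    counts = {lv: groups.count(lv) for lv in levels}
    singletons = [lv for lv, c in counts.items() if c < 2]
    if singletons:
        warnings.warn(f"group levels with a single member: {singletons}")
    X = dummy_code(groups)
    return pgls_fit(phylogeny, Y, X, tip_names, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float],
              alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject
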