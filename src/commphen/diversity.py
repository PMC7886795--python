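"""Alpha/beta diversity of phylotype communities.

Shannon entropy on relative abundances, midpoint rooting of phylogenies,
branch-weighted (weighted UniFrac) distances between communities on a
rooted tree, and classical principal coordinates analysis (metric MDS) of
the resulting distance matrix. Trees are :class:`skbio.TreeNode` objects
(Newick I/O comes with them); distance matrices are
:class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from sklearn.base import BaseEstimator

__all__ = [
    "shannon",
    "shannon_table",
    "midpoint_root",
    "weighted_unifrac",
    "unifrac_matrix",
    "PCoA",
    "pcoa",
]

_SUM_TOL = 1e-6


def shannon(p, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i of a composition.

    Parameters
    ----------
    p : array-like
        Non-negative abundances summing to 1 (renormalized if within 1e-6).
    base : float, optional
        Logarithm base; natural log (nats) by default.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if np.any(p < 0):
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"abundances sum to {total}, not 1")
    p = p / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannon_table(table: pd.DataFrame, base: float | None = None) -> pd.Series:
    """Per-sample Shannon diversity of a normalized table."""
    return pd.Series(
        {s: shannon(table[s].to_numpy(), base=base) for s in table.columns},
        name="shannon",
    )


# ---------------------------------------------------------------------------
# midpoint rooting


def _tip_distances(tree: TreeNode) -> pd.DataFrame:
    """All-pairs leaf path-length matrix (plain Dijkstra-free postorder)."""
    tips = sorted(t.name for t in tree.tips())
    dm = tree.tip_tip_distances(endpoints=tips)
    return pd.DataFrame(dm.data, index=tips, columns=tips)


def _path(tree: TreeNode, u: str, v: str):
    """Nodes on the tip-u -> tip-v path with cumulative distance from u."""
    nu, nv = tree.find(u), tree.find(v)
    anc_u = [nu] + list(nu.ancestors())
    anc_v = [nv] + list(nv.ancestors())
    set_u = set(map(id, anc_u))
    lca = next(n for n in anc_v if id(n) in set_u)
    path = []
    d = 0.0
    for n in anc_u:  # u up to and including the lca
        path.append((n, d))
        if n is lca:
            break
        d += n.length or 0.0
    d_u_lca = path[-1][1]
    vside = []  # nodes from v (excl. lca) with distance from v
    d = 0.0
    for n in anc_v:
        if n is lca:
            break
        vside.append((n, d))
        d += n.length or 0.0
    d_v_lca = d
    for n, dist_from_v in reversed(vside):  # lca down to v
        path.append((n, d_u_lca + d_v_lca - dist_from_v))
    return path


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    The returned tree preserves every pairwise leaf distance. If the
    midpoint falls exactly on an existing node, that node becomes the root
    (no zero-length edge is added); when several leaf pairs tie for the
    diameter, the lexicographically first pair of leaf names is used.
    """
    tree = tree.copy()
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("midpoint rooting requires >= 2 leaves")
    dmat = _tip_distances(tree)
    names = list(dmat.index)
    arr = dmat.to_numpy()
    diameter = arr.max()
    if diameter <= 0:
        raise ValueError("tree has zero diameter")
    # lexicographic tie-break: names are sorted, scan in order
    u = v = None
    for i, a in enumerate(names):
        for b, d in zip(names[i + 1 :], arr[i, i + 1 :]):
            if d == diameter:
                u, v = a, b
                break
        if u is not None:
            break
    half = diameter / 2.0
    path = _path(tree, u, v)
    eps = 1e-12 * max(1.0, diameter)
    for k, (node, dist) in enumerate(path):
        if abs(dist - half) <= eps:
            return _root_at_node(tree, node)
        if dist > half:
            prev_node, prev_dist = path[k - 1]
            return _root_on_edge(tree, prev_node, node, half - prev_dist)
    raise AssertionError("midpoint not found on diameter path")


def _root_at_node(tree: TreeNode, node: TreeNode) -> TreeNode:
    if node.is_root():
        return tree
    rooted = tree.root_at(node)
    return rooted


def _root_on_edge(
    tree: TreeNode, a: TreeNode, b: TreeNode, offset_from_a: float
) -> TreeNode:
    """Insert a node on the edge a--b at ``offset_from_a`` and root there."""
    # orient child -> parent
    if b.parent is a:
        child, dist_from_child = b, (b.length or 0.0) - offset_from_a
    elif a.parent is b:
        child, dist_from_child = a, offset_from_a
    else:  # pragma: no cover - path nodes are always adjacent
        raise AssertionError("non-adjacent edge endpoints")
    parent = child.parent
    new = TreeNode(length=(child.length or 0.0) - dist_from_child)
    parent.append(new)
    parent.remove(child)
    child.length = dist_from_child
    new.append(child)
    return tree.root_at(new)


# ---------------------------------------------------------------------------
# weighted UniFrac


def _leaf_weights(tree_tips: list[str], comm) -> dict[str, float]:
    if isinstance(comm, pd.Series):
        comm = comm.to_dict()
    extra = set(comm) - set(tree_tips)
    if extra:
        raise ValueError(f"abundance keys not on tree: {sorted(extra)[:5]}")
    total = float(sum(comm.values()))
    if total <= 0:
        raise ValueError("empty community")
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"community sums to {total}, not 1")
    return {k: v / total for k, v in comm.items()}


def weighted_unifrac(tree: TreeNode, a, b, normalized: bool = True) -> float:
    """Weighted UniFrac distance between two communities on a rooted tree.

    For every branch i with length l_i, let A_i and B_i be the fractions
    of community a and b descending through that branch. The raw distance
    is sum_i l_i |A_i - B_i|; the normalized variant divides by
    sum_i l_i (A_i + B_i) and lies in [0, 1].
    """
    tips = [t.name for t in tree.tips()]
    wa = _leaf_weights(tips, a)
    wb = _leaf_weights(tips, b)
    raw = 0.0
    denom = 0.0
    # postorder accumulation of the descending mass per node
    masses: dict[int, tuple[float, float]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            m = (wa.get(node.name, 0.0), wb.get(node.name, 0.0))
        else:
            ca = cb = 0.0
            for ch in node.children:
                xa, xb = masses[id(ch)]
                ca += xa
                cb += xb
            m = (ca, cb)
        masses[id(node)] = m
        if node.parent is not None and node.length:
            raw += node.length * abs(m[0] - m[1])
            denom += node.length * (m[0] + m[1])
    if not normalized:
        return raw
    return raw / denom if denom > 0 else 0.0


def unifrac_matrix(
    tree: TreeNode, table: pd.DataFrame, normalized: bool = True
) -> DistanceMatrix:
    """Pairwise weighted UniFrac over the samples of a normalized table."""
    samples = list(table.columns)
    n = len(samples)
    comms = [table[s] for s in samples]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = weighted_unifrac(tree, comms[i], comms[j], normalized=normalized)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=samples)


# ---------------------------------------------------------------------------
# PCoA


class PCoA(BaseEstimator):
    """Classical principal coordinates analysis (Gower's metric MDS).

    The squared distance matrix is double-centred (B = -1/2 J D^2 J) and
    eigendecomposed; axes are ordered by decreasing eigenvalue and axes
    with non-positive eigenvalues are dropped (their magnitudes are kept in
    ``negative_eigvals_``). ``correction="lingoes"`` instead adds the
    Lingoes constant to off-diagonal squared distances so all eigenvalues
    become non-negative.

    Attributes
    ----------
    coordinates_ : pandas.DataFrame
        Samples x retained axes ("PC1", "PC2", ...).
    eigvals_ : numpy.ndarray
        Retained (positive) eigenvalues, descending.
    proportion_explained_ : numpy.ndarray
        eigvals_ / sum(eigvals_); sums to at most 1.
    negative_eigvals_ : numpy.ndarray
        Magnitudes of any negative eigenvalues of the uncorrected solution.
    """

    def __init__(self, correction: str | None = None):
        self.correction = correction

    def fit(self, dm, y=None):
        ids, d = _as_distance_array(dm)
        n = d.shape[0]
        if n < 2:
            raise ValueError("PCoA needs at least two samples")
        d2 = d**2
        eigvals, eigvecs = self._decompose(d2)
        if self.correction == "lingoes" and eigvals.min() < -1e-12:
            c = -eigvals.min()
            d2c = d2 + 2.0 * c * (1 - np.eye(n))
            eigvals, eigvecs = self._decompose(d2c)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        tol = 1e-10 * max(1.0, abs(eigvals[0])) if len(eigvals) else 0.0
        pos = eigvals > tol
        self.negative_eigvals_ = np.abs(eigvals[eigvals < -tol])
        lam = eigvals[pos]
        coords = eigvecs[:, pos] * np.sqrt(lam)
        axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
        self.eigvals_ = lam
        self.proportion_explained_ = (
            lam / lam.sum() if lam.size else np.array([])
        )
        self.coordinates_ = pd.DataFrame(coords, index=ids, columns=axes)
        return self

    @staticmethod
    def _decompose(d2: np.ndarray):
        n = d2.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        b = (b + b.T) / 2.0
        return np.linalg.eigh(b)

    def fit_transform(self, dm, y=None) -> pd.DataFrame:
        return self.fit(dm).coordinates_


def _as_distance_array(dm):
    if isinstance(dm, DistanceMatrix):
        return list(dm.ids), dm.data.astype(float)
    if isinstance(dm, pd.DataFrame):
        ids, arr = list(dm.index), dm.to_numpy(dtype=float)
    else:
        arr = np.asarray(dm, dtype=float)
        ids = list(range(arr.shape[0]))
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(arr)) > 1e-12) or np.any(arr < 0):
        raise ValueError("invalid distance matrix (diagonal/negative entries)")
    return ids, arr


def pcoa(dm, correction: str | None = None) -> PCoA:
    """Fit :class:`PCoA` on a distance matrix and return the fitted model."""
    return PCoA(correction=correction).fit(dm)
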