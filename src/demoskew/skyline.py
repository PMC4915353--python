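"""Ultrametric trees, coalescent intervals, and (generalized) skyline plots.

The pipeline is: pairwise distances -> UPGMA ultrametric tree (node height =
half the merged-cluster distance) -> ordered coalescent intervals (k
lineages during the k-th interval from the present) -> skyline estimates of
Ne*u per interval, with time measured in expected substitutions per site
(0 = present at the tips, increasing into the past).

The classic skyline estimates Ne*u on every interval as t_k * C(k,2). The
generalized skyline pools consecutive intervals whose composite duration is
below a smoothing parameter epsilon and uses the maximum-likelihood
estimate (1/c) * sum_i C(k_i,2) t_i over the c pooled coalescent events;
epsilon is chosen by AIC. A constant-size Kingman coalescent simulator is
included as an independent oracle for parameter-recovery checks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .sampling import DistanceMatrix

__all__ = [
    "CoalescentIntervals",
    "SkylineEstimate",
    "upgma_tree",
    "tree_depth",
    "is_ultrametric",
    "coalescent_intervals",
    "classic_skyline",
    "generalized_skyline",
    "aic_select_epsilon",
    "default_epsilon_grid",
    "skyline_amplitude",
    "simulate_kingman_tree",
    "write_newick",
    "read_newick",
]

_ULTRAMETRIC_TOL = 1e-9


@dataclass
class CoalescentIntervals:
    """Ordered coalescent intervals from the tips (k = n) to the root (k = 2)."""

    k: np.ndarray  # lineage counts, n..2
    durations: np.ndarray

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.k.shape != self.durations.shape:
            raise ValueError("k and durations must align")
        n = self.k[0]
        if not np.array_equal(self.k, np.arange(n, 1, -1)):
            raise ValueError("lineage counts must decrease n..2")
        if (self.durations < 0).any():
            raise ValueError("durations must be non-negative")

    @property
    def n(self) -> int:
        return int(self.k[0])

    @property
    def depth(self) -> float:
        return float(self.durations.sum())


@dataclass
class SkylineEstimate:
    """Stepwise Ne*u estimate through time.

    ``boundaries`` has K+1 increasing values starting at 0 (the present);
    segment j spans boundaries[j]..boundaries[j+1] with estimate values[j].
    """

    boundaries: np.ndarray
    values: np.ndarray
    epsilon: float
    #: per segment, the (k, duration) sub-intervals pooled into it
    segments: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.boundaries.ndim != 1 or self.boundaries.size != self.values.size + 1:
            raise ValueError("need K+1 boundaries for K segments")
        if self.boundaries[0] != 0 or (np.diff(self.boundaries) < 0).any():
            raise ValueError("boundaries must increase from 0")

    @property
    def K(self) -> int:
        return int(self.values.size)

    @property
    def has_zero(self) -> bool:
        """True when some segment estimate is zero (degenerate intervals)."""
        return bool((self.values == 0).any())


# --------------------------------------------------------------------- #
# trees


def upgma_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) ultrametric tree from a distance matrix.

    Node height is half the distance between the merged clusters, so branch
    lengths are on the same scale as the input distances (substitutions per
    site for sequence distances).
    """
    m = dm.size
    if m < 2:
        raise ValueError("need at least two taxa")
    if (dm.d < 0).any():
        raise ValueError("negative distances")
    Z = linkage(squareform(dm.d, checks=False), method="average")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[tuple[dendropy.Node, float]] = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append((node, 0.0))
    for ca, cb, dist, _size in Z:
        height = dist / 2.0
        parent = dendropy.Node()
        for child_idx in (int(ca), int(cb)):
            child, child_h = nodes[child_idx]
            child.edge.length = height - child_h
            parent.add_child(child)
        nodes.append((parent, height))
    root = nodes[-1][0]
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def tree_depth(tree: dendropy.Tree) -> float:
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, tol: float = _ULTRAMETRIC_TOL) -> bool:
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    depth = max(depths)
    scale = max(depth, 1.0)
    return max(depths) - min(depths) <= tol * scale


def coalescent_intervals(tree: dendropy.Tree,
                         tol: float = _ULTRAMETRIC_TOL) -> CoalescentIntervals:
    """Coalescent intervals of an ultrametric binary tree.

    Sorted internal-node heights (measured from the tips) delimit the
    intervals; k lineages exist during the k-th interval from the present.
    """
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    if n < 2:
        raise ValueError("need at least two tips")
    if not is_ultrametric(tree, tol):
        raise ValueError("tree is not ultrametric")
    depth = max(leaf.distance_from_root() for leaf in leaves)
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    for nd in internals:
        if len(nd.child_nodes()) != 2:
            raise ValueError("tree must be strictly bifurcating")
    if len(internals) != n - 1:
        raise ValueError("a binary tree on n tips has n - 1 internal nodes")
    heights = np.sort([depth - nd.distance_from_root() for nd in internals])
    heights = np.clip(heights, 0.0, None)
    durations = np.diff(np.concatenate([[0.0], heights]))
    return CoalescentIntervals(k=np.arange(n, 1, -1), durations=durations)


# --------------------------------------------------------------------- #
# skyline estimators


def _choose2(k):
    return k * (k - 1) / 2.0


def classic_skyline(intervals: CoalescentIntervals) -> SkylineEstimate:
    """Per-interval estimate M_k = t_k * C(k,2) (the epsilon -> 0 case)."""
    vals = intervals.durations * _choose2(intervals.k)
    boundaries = np.concatenate([[0.0], np.cumsum(intervals.durations)])
    segments = [
        [(int(k), float(t))] for k, t in zip(intervals.k, intervals.durations)
    ]
    return SkylineEstimate(boundaries=boundaries, values=vals, epsilon=0.0,
                           segments=segments)


def _pool(intervals: CoalescentIntervals, epsilon: float) -> list[list[tuple[int, float]]]:
    groups: list[list[tuple[int, float]]] = []
    current: list[tuple[int, float]] = []
    total = 0.0
    for k, t in zip(intervals.k, intervals.durations):
        current.append((int(k), float(t)))
        total += t
        if total >= epsilon:
            groups.append(current)
            current, total = [], 0.0
    if current:
        # trailing composite shorter than epsilon: merge into the previous
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    return groups


def generalized_skyline(intervals: CoalescentIntervals,
                        epsilon: float) -> SkylineEstimate:
    """Skyline with intervals pooled while a composite is shorter than epsilon.

    A composite spanning c coalescent events with sub-intervals (k_i, t_i)
    receives the maximum-likelihood estimate (1/c) sum_i C(k_i,2) t_i,
    constant over the composite. epsilon = 0 recovers the classic skyline.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return classic_skyline(intervals)
    groups = _pool(intervals, epsilon)
    values, boundaries = [], [0.0]
    for grp in groups:
        ks = np.array([k for k, _ in grp], dtype=float)
        ts = np.array([t for _, t in grp], dtype=float)
        values.append((_choose2(ks) * ts).sum() / len(grp))
        boundaries.append(boundaries[-1] + ts.sum())
    return SkylineEstimate(boundaries=np.array(boundaries),
                           values=np.array(values), epsilon=float(epsilon),
                           segments=groups)


def _log_likelihood(est: SkylineEstimate) -> float:
    """Piecewise-constant coalescent log-likelihood of a skyline estimate."""
    lnL = 0.0
    for value, grp in zip(est.values, est.segments):
        if value <= 0:
            return -np.inf
        for k, t in grp:
            c2 = _choose2(k)
            lnL += np.log(c2 / value) - c2 * t / value
    return float(lnL)


def default_epsilon_grid(intervals: CoalescentIntervals,
                         n_points: int = 20) -> np.ndarray:
    """0 plus n_points log-spaced values from depth/1e3 to the tree depth."""
    depth = intervals.depth
    if depth <= 0:
        return np.array([0.0])
    return np.concatenate(
        [[0.0], np.geomspace(depth / 1e3, depth, n_points)]
    )


def aic_select_epsilon(intervals: CoalescentIntervals,
                       epsilon_grid=None) -> tuple[float, SkylineEstimate]:
    """Pick the pooling parameter epsilon minimizing AIC = 2K - 2 lnL.

    K is the number of skyline segments. Ties resolve to the smaller
    epsilon. Raises if every candidate skyline is degenerate (zero
    estimates give -inf likelihood).
    """
    if epsilon_grid is None:
        epsilon_grid = default_epsilon_grid(intervals)
    epsilon_grid = np.sort(np.asarray(epsilon_grid, dtype=float))
    if epsilon_grid.size == 0:
        raise ValueError("epsilon grid must be nonempty")
    best = None
    for eps in epsilon_grid:
        est = generalized_skyline(intervals, float(eps))
        aic = 2.0 * est.K - 2.0 * _log_likelihood(est)
        if np.isfinite(aic) and (best is None or aic < best[0] - 1e-12):
            best = (aic, float(eps), est)
    if best is None:
        raise ValueError("all candidate skylines are degenerate (zero estimates)")
    return best[1], best[2]


def skyline_amplitude(est: SkylineEstimate) -> float:
    """Ratio between the maximal and minimal Ne*u values of a skyline."""
    lo = est.values.min()
    if lo <= 0:
        raise ValueError("amplitude undefined: minimal estimate is zero")
    return float(est.values.max() / lo)


# --------------------------------------------------------------------- #
# Kingman oracle and Newick I/O


def simulate_kingman_tree(n: int, scaled_size: float,
                          rng: np.random.Generator) -> dendropy.Tree:
    """Constant-size coalescent tree: interval with k lineages is
    Exponential with rate C(k,2)/scaled_size; joins are uniform."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if scaled_size <= 0:
        raise ValueError("scaled_size must be > 0")
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    active: list[tuple[dendropy.Node, float]] = []
    for i in range(n):
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(f"t{i}")
        active.append((node, 0.0))
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(scaled_size / _choose2(k))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = active[i], active[j]
        parent = dendropy.Node()
        na.edge.length = t - ha
        nb.edge.length = t - hb
        parent.add_child(na)
        parent.add_child(nb)
        del active[j], active[i]
        active.append((parent, t))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = active[0][0]
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick with full-precision branch lengths."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    Path(path).write_text(text)


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a path (or a literal Newick string)."""
    try:
        is_file = Path(str(source)).is_file()
    except OSError:  # e.g. a long literal Newick string
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    tree = dendropy.Tree.get(
        file=io.StringIO(text), schema="newick",
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return tree
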