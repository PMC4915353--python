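"""Sampling-bias schemes over a k-medoids clustering of the population.

The full final population (all N individuals) is clustered on a pairwise
sequence-distance matrix by PAM (partitioning around medoids), and 100
individuals are drawn per scheme:

* uniform — one individual per cluster, with the population in 100 clusters;
* clustered — all 100 from a single cluster, population in 10 clusters;
* mixed — 91 from one focal cluster and 1 from each of the other 9.

Distances default to p-distances (fraction of mismatching sites), with an
optional JC69 correction d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .population import SampleAlignment

__all__ = [
    "DistanceMatrix",
    "Clustering",
    "distance_matrix",
    "jc69_correct",
    "KMedoids",
    "pam_cluster",
    "sample_uniform",
    "sample_clustered",
    "sample_mixed",
    "write_phylip",
    "read_phylip",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        m = len(self.labels)
        if self.d.shape != (m, m):
            raise ValueError("distance matrix shape must match labels")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def size(self) -> int:
        return len(self.labels)


def jc69_correct(p: np.ndarray) -> np.ndarray:
    """JC69 distance -(3/4) ln(1 - 4p/3) applied elementwise."""
    p = np.asarray(p, dtype=float)
    if (p >= 0.75).any():
        raise ValueError("p-distance >= 3/4 cannot be JC69-corrected")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def distance_matrix(source, method: str = "p") -> DistanceMatrix:
    """Pairwise distances between aligned sequences.

    ``source`` is a :class:`SampleAlignment` or an (m, L) code matrix.
    ``method`` is ``"p"`` (fraction of mismatching sites) or ``"jc69"``.
    Computation is restricted to polymorphic columns, which leaves the
    distances unchanged and keeps large populations tractable.
    """
    if isinstance(source, SampleAlignment):
        seqs = source.sequences
        labels = list(source.labels)
    else:
        seqs = np.asarray(source, dtype=np.uint8)
        labels = [f"ind_{i}" for i in range(seqs.shape[0])]
    m, L = seqs.shape
    if m < 2:
        raise ValueError("need at least two sequences")
    poly = np.flatnonzero((seqs != seqs[0]).any(axis=0))
    if poly.size == 0:
        d = np.zeros((m, m))
    else:
        sub = seqs[:, poly]
        matches = np.zeros((m, m), dtype=np.float32)
        for a in range(4):
            ind = (sub == a).astype(np.float32)
            matches += ind @ ind.T
        mism = poly.size - matches
        d = mism / float(L)
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        d = np.clip(d.astype(float), 0.0, None)
    if method == "jc69":
        d = jc69_correct(d)
    elif method != "p":
        raise ValueError(f"unknown distance method {method!r}")
    return DistanceMatrix(labels=labels, d=d)


# --------------------------------------------------------------------- #
# PAM (k-medoids)


class KMedoids:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Standard BUILD initialization followed by best-improvement SWAP until no
    single medoid exchange lowers the total within-cluster distance to
    medoids. Deterministic: ties are broken toward the lowest index.

    Attributes (after :meth:`fit`)
    ------------------------------
    medoid_indices_ : ndarray (k,)
    labels_ : ndarray (m,) cluster index of every point
    inertia_ : float, total distance of points to their medoid
    """

    def __init__(self, n_clusters: int, max_iter: int = 300,
                 random_state=None):
        self.n_clusters = int(n_clusters)
        self.max_iter = int(max_iter)
        self.random_state = random_state  # kept for API symmetry; unused

    def get_params(self, deep=True):
        return {
            "n_clusters": self.n_clusters,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, D: np.ndarray) -> "KMedoids":
        D = np.asarray(D, dtype=float)
        m = D.shape[0]
        k = self.n_clusters
        if D.shape != (m, m):
            raise ValueError("D must be square")
        if not 2 <= k <= m:
            raise ValueError(f"n_clusters must be in [2, {m}]")

        # BUILD: first medoid minimizes total distance; then greedily add the
        # point whose addition reduces the cost most.
        medoids = [int(np.argmin(D.sum(axis=0)))]
        d_near = D[medoids[0]].copy()
        while len(medoids) < k:
            reduction = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
            reduction[medoids] = -np.inf
            h = int(np.argmax(reduction))
            medoids.append(h)
            d_near = np.minimum(d_near, D[h])

        medoids = np.array(sorted(medoids))
        cost_history = []
        for _ in range(self.max_iter):
            Dm = D[medoids]  # (k, m)
            order = np.argsort(Dm, axis=0, kind="stable")
            labels = order[0]
            d_near = Dm[labels, np.arange(m)]
            d_sec = Dm[order[1], np.arange(m)]
            cost_history.append(float(d_near.sum()))
            is_medoid = np.zeros(m, dtype=bool)
            is_medoid[medoids] = True
            candidates = np.flatnonzero(~is_medoid)
            best = (0.0, None, None)
            for h in candidates:
                d_h = D[h]
                gain = np.minimum(d_h - d_near, 0.0)
                total_gain = gain.sum()
                # per removed medoid: points of that cluster lose their
                # medoid and move to min(second-nearest, h)
                move = np.minimum(d_sec, d_h) - d_near
                per_m = (
                    total_gain
                    - np.bincount(labels, weights=gain, minlength=k)
                    + np.bincount(labels, weights=move, minlength=k)
                )
                j = int(np.argmin(per_m))
                if per_m[j] < best[0] - 1e-12:
                    best = (float(per_m[j]), j, int(h))
            if best[1] is None:
                break
            medoids[best[1]] = best[2]
            medoids = np.array(sorted(medoids))

        Dm = D[medoids]
        labels = np.argmin(Dm, axis=0)
        # a medoid always belongs to its own cluster
        labels[medoids] = np.arange(len(medoids))
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = float(Dm[labels, np.arange(m)].sum())
        cost_history.append(self.inertia_)
        #: total cost at the start of each swap iteration (non-increasing)
        self.cost_history_ = cost_history
        self.n_iter_ = max(len(cost_history) - 1, 0)
        return self

    def fit_predict(self, D: np.ndarray) -> np.ndarray:
        return self.fit(D).labels_


@dataclass
class Clustering:
    """A PAM partition: medoids, assignment, and total cost."""

    k: int
    medoids: np.ndarray
    assignment: np.ndarray
    cost: float

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)


def pam_cluster(dm: DistanceMatrix, k: int,
                rng: np.random.Generator | None = None) -> Clustering:
    """Cluster a distance matrix into k groups around medoids (PAM)."""
    km = KMedoids(n_clusters=k, random_state=rng).fit(dm.d)
    return Clustering(
        k=k,
        medoids=km.medoid_indices_,
        assignment=km.labels_,
        cost=km.inertia_,
    )


# --------------------------------------------------------------------- #
# sampling schemes


def _subset(pop_aln: SampleAlignment, indices: np.ndarray) -> SampleAlignment:
    return pop_aln.subset(np.sort(np.asarray(indices, dtype=int)))


def sample_uniform(pop_aln: SampleAlignment, clustering: Clustering,
                   rng: np.random.Generator) -> SampleAlignment:
    """One uniformly drawn individual per cluster (k clusters -> k samples)."""
    chosen = []
    for c in range(clustering.k):
        members = clustering.members(c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        chosen.append(rng.choice(members))
    return _subset(pop_aln, np.array(chosen))


def sample_clustered(pop_aln: SampleAlignment, clustering: Clustering,
                     rng: np.random.Generator, size: int = 100,
                     ) -> SampleAlignment:
    """All ``size`` individuals from one cluster with >= ``size`` members.

    The focal cluster is drawn uniformly among eligible clusters; raises if
    no cluster is large enough (caller may re-cluster or re-simulate).
    """
    sizes = clustering.sizes()
    eligible = np.flatnonzero(sizes >= size)
    if eligible.size == 0:
        raise ValueError(
            f"no cluster has >= {size} members (sizes: {sizes.tolist()})"
        )
    focal = int(rng.choice(eligible))
    members = clustering.members(focal)
    chosen = rng.choice(members, size=size, replace=False)
    return _subset(pop_aln, chosen)


def sample_mixed(pop_aln: SampleAlignment, clustering: Clustering,
                 rng: np.random.Generator, focal_size: int = 91,
                 ) -> SampleAlignment:
    """``focal_size`` individuals from one cluster plus 1 from each other.

    With the population in 10 clusters this yields the 91 + 9x1 mixed
    sampling-bias composition.
    """
    sizes = clustering.sizes()
    eligible = np.flatnonzero(sizes >= focal_size)
    if eligible.size == 0:
        raise ValueError(
            f"no cluster has >= {focal_size} members (sizes: {sizes.tolist()})"
        )
    focal = int(rng.choice(eligible))
    chosen = list(rng.choice(clustering.members(focal), size=focal_size,
                             replace=False))
    for c in range(clustering.k):
        if c == focal:
            continue
        members = clustering.members(c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        chosen.append(rng.choice(members))
    return _subset(pop_aln, np.array(chosen))


# --------------------------------------------------------------------- #
# PHYLIP square matrix I/O


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{dm.size}\n")
        for label, row in zip(dm.labels, dm.d):
            fh.write(label + "  " + "  ".join(f"{v:.10f}" for v in row) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        m = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(m):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(labels=labels, d=np.array(rows))
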