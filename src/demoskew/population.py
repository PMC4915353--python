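"""Population and sample containers.

Haplotypes are stored as integer codes 0..3 over the alphabet ACGT. The
population uses a copy-on-write row store: after Wright-Fisher resampling,
offspring share their parent's haplotype row; an individual only receives a
private copy when a mutation or conversion event touches it. This keeps the
per-generation memory traffic proportional to the number of events rather
than to ``N * L``.

The per-site "ancestral" sequence is the fixed background of the population:
derived alleles that reach fixation are periodically absorbed into it (see
:meth:`PopulationState.absorb_fixed`), so that at sampling time the ancestral
allele of each segregating site is the allele its mutation(s) arose from.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "ANCESTRAL_LABEL",
    "encode_sequence",
    "decode_sequence",
    "SampleAlignment",
    "PopulationState",
]

ALPHABET = "ACGT"
#: Reserved FASTA record id for the ancestral sequence.
ANCESTRAL_LABEL = "ANCESTRAL"

_CODE = {c: i for i, c in enumerate(ALPHABET)}
_NUC = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
_DECODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _DECODE_TABLE[ord(_c)] = _i
    _DECODE_TABLE[ord(_c.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _DECODE_TABLE[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _NUC[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


class SampleAlignment:
    """An alignment of ``n`` sampled sequences plus the ancestral sequence.

    Parameters
    ----------
    sequences : ndarray of shape (n, L), uint8
        Sampled haplotypes as 0..3 codes.
    ancestral : ndarray of shape (L,), uint8
        Ancestral (true polarizing) sequence.
    labels : sequence of str, optional
        Sample identifiers; generated as ``ind_<i>`` when omitted.
    """

    def __init__(self, sequences, ancestral, labels=None):
        seqs = np.ascontiguousarray(sequences, dtype=np.uint8)
        anc = np.ascontiguousarray(ancestral, dtype=np.uint8)
        if seqs.ndim != 2:
            raise ValueError("sequences must be a 2-D (n, L) array")
        if seqs.shape[0] == 0:
            raise ValueError("alignment must contain at least one sequence")
        if anc.shape != (seqs.shape[1],):
            raise ValueError("ancestral length must match the alignment")
        if seqs.max(initial=0) > 3 or anc.max(initial=0) > 3:
            raise ValueError("sequence codes must be in 0..3 (ACGT)")
        if labels is None:
            labels = [f"ind_{i}" for i in range(seqs.shape[0])]
        labels = [str(x) for x in labels]
        if len(labels) != seqs.shape[0]:
            raise ValueError("one label per sequence required")
        if ANCESTRAL_LABEL in labels:
            raise ValueError(f"label {ANCESTRAL_LABEL!r} is reserved")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        self.sequences = seqs
        self.ancestral = anc
        self.labels = labels

    @property
    def n(self) -> int:
        return self.sequences.shape[0]

    @property
    def L(self) -> int:
        return self.sequences.shape[1]

    @classmethod
    def from_strings(cls, seqs, ancestral, labels=None) -> "SampleAlignment":
        lengths = {len(s) for s in seqs} | {len(ancestral)}
        if len(lengths) != 1:
            raise ValueError("all sequences must have equal length")
        mat = np.stack([encode_sequence(s) for s in seqs])
        return cls(mat, encode_sequence(ancestral), labels)

    def subset(self, indices, labels=None) -> "SampleAlignment":
        indices = np.asarray(indices, dtype=int)
        if labels is None:
            labels = [self.labels[i] for i in indices]
        return SampleAlignment(self.sequences[indices], self.ancestral, labels)

    def write_fasta(self, path: str | Path) -> None:
        """Write the alignment, ancestral record first, as plain FASTA."""
        records = [
            SeqRecord(Seq(decode_sequence(self.ancestral)), id=ANCESTRAL_LABEL,
                      description="")
        ]
        records.extend(
            SeqRecord(Seq(decode_sequence(row)), id=label, description="")
            for row, label in zip(self.sequences, self.labels)
        )
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "SampleAlignment":
        ancestral = None
        seqs, labels = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id == ANCESTRAL_LABEL:
                ancestral = encode_sequence(str(rec.seq))
            else:
                seqs.append(encode_sequence(str(rec.seq)))
                labels.append(rec.id)
        if ancestral is None:
            raise ValueError(
                f"FASTA {path} lacks the reserved {ANCESTRAL_LABEL!r} ancestral record"
            )
        if not seqs:
            raise ValueError(f"FASTA {path} contains no sample sequences")
        return cls(np.stack(seqs), ancestral, labels)


class PopulationState:
    """Haplotypes of ``N`` individuals over a finite-sites locus.

    Attributes
    ----------
    ancestral : ndarray (L,) uint8
        Current fixed background; the ancestral allele of segregating sites.
    selection_coeffs : dict[(site, allele), float]
        Selection coefficient of every non-neutral derived allele currently
        tracked; absent keys are neutral (s = 0).
    fitness : ndarray (N,) float
        Multiplicative fitness, product of ``(1 + s)`` over carried derived
        alleles; maintained incrementally and re-derived exactly at every
        :meth:`absorb_fixed`.
    """

    def __init__(self, N: int, L: int, ancestral: np.ndarray, capacity: int | None = None):
        if capacity is None:
            capacity = 2 * N + 64
        self.N = int(N)
        self.L = int(L)
        self.generation = 0
        self.ancestral = np.ascontiguousarray(ancestral, dtype=np.uint8)
        if self.ancestral.shape != (self.L,):
            raise ValueError("ancestral must have length L")
        self.selection_coeffs: dict[tuple[int, int], float] = {}
        self.fitness = np.ones(N, dtype=np.float64)
        self._storage = np.empty((capacity, L), dtype=np.uint8)
        self._refcnt = np.zeros(capacity, dtype=np.int64)
        self._free = list(range(capacity - 1, 0, -1))
        self._ids = np.zeros(N, dtype=np.int64)
        self._storage[0] = self.ancestral
        self._refcnt[0] = N

    # ------------------------------------------------------------------ #
    # construction

    @classmethod
    def monomorphic(cls, N: int, L: int, rng: np.random.Generator | None = None,
                    ancestral: np.ndarray | None = None) -> "PopulationState":
        """Start a population in which everyone carries the ancestral sequence.

        The ancestral sequence is drawn uniformly over ACGT (all nucleotides
        at similar frequencies) unless given explicitly.
        """
        if ancestral is None:
            if rng is None:
                rng = np.random.default_rng()
            ancestral = rng.integers(0, 4, size=L, dtype=np.uint8)
        return cls(N, L, ancestral)

    # ------------------------------------------------------------------ #
    # row store plumbing

    def _alloc(self) -> int:
        if not self._free:
            self._grow()
        return self._free.pop()

    def _grow(self) -> None:
        old = self._storage.shape[0]
        new = old * 2
        storage = np.empty((new, self.L), dtype=np.uint8)
        storage[:old] = self._storage
        self._storage = storage
        refcnt = np.zeros(new, dtype=np.int64)
        refcnt[:old] = self._refcnt
        self._refcnt = refcnt
        self._free.extend(range(new - 1, old - 1, -1))

    def row_for_write(self, i: int) -> np.ndarray:
        """Return individual ``i``'s haplotype row, private to ``i`` (COW)."""
        rid = self._ids[i]
        if self._refcnt[rid] > 1:
            new = self._alloc()
            self._storage[new] = self._storage[rid]
            self._refcnt[rid] -= 1
            self._refcnt[new] = 1
            self._ids[i] = new
            rid = new
        return self._storage[rid]

    def row_view(self, i: int) -> np.ndarray:
        """Read-only view of individual ``i``'s haplotype."""
        return self._storage[self._ids[i]]

    def reassign_parents(self, parents: np.ndarray) -> None:
        """Replace the population by offspring copied from ``parents``."""
        new_ids = self._ids[parents]
        np.add.at(self._refcnt, new_ids, 1)
        np.subtract.at(self._refcnt, self._ids, 1)
        for rid in np.unique(self._ids):
            if self._refcnt[rid] == 0:
                self._free.append(int(rid))
        self._ids = new_ids.copy()
        self.fitness = self.fitness[parents]

    # ------------------------------------------------------------------ #
    # inspection

    @property
    def haplotypes(self) -> np.ndarray:
        """Dense (N, L) haplotype matrix (materialized copy)."""
        return self._storage[self._ids].copy()

    def _live(self) -> np.ndarray:
        return np.flatnonzero(self._refcnt > 0)

    def allele_counts(self) -> np.ndarray:
        """(L, 4) matrix of population allele counts at every site."""
        live = self._live()
        sub = self._storage[live]
        w = self._refcnt[live].astype(np.float64)
        counts = np.empty((self.L, 4), dtype=np.int64)
        for a in range(4):
            counts[:, a] = np.rint(w @ (sub == a)).astype(np.int64)
        return counts

    def derived_allele_set(self) -> set[tuple[int, int]]:
        """Set of (site, allele) pairs present and different from ancestral."""
        counts = self.allele_counts()
        sites, alleles = np.nonzero(counts > 0)
        return {
            (int(s), int(a))
            for s, a in zip(sites, alleles)
            if self.ancestral[s] != a
        }

    # ------------------------------------------------------------------ #
    # fitness bookkeeping

    def recompute_fitness(self) -> np.ndarray:
        """Fitness of every individual recomputed from scratch.

        Uses the current ``selection_coeffs`` table and the haplotypes; does
        not modify the tracked ``fitness`` array.
        """
        if not self.selection_coeffs:
            return np.ones(self.N, dtype=np.float64)
        keys = list(self.selection_coeffs)
        sites = np.array([k[0] for k in keys], dtype=np.int64)
        alleles = np.array([k[1] for k in keys], dtype=np.uint8)
        logf = np.log1p(np.array([self.selection_coeffs[k] for k in keys]))
        live = self._live()
        carried = self._storage[np.ix_(live, sites)] == alleles  # (R, K)
        row_logfit = carried @ logf
        pos = np.searchsorted(live, self._ids)
        return np.exp(row_logfit[pos])

    def absorb_fixed(self) -> int:
        """Fold fixed derived alleles into the ancestral background.

        Sites where a single non-ancestral allele is carried by all ``N``
        individuals become the new ancestral state there. Selection
        coefficients of absorbed or lost alleles are dropped and fitness is
        re-derived exactly. Returns the number of absorbed sites.
        """
        live = self._live()
        sub = self._storage[live]
        col_min = sub.min(axis=0)
        fixed = (col_min == sub.max(axis=0)) & (col_min != self.ancestral)
        n_fixed = int(fixed.sum())
        if n_fixed:
            self.ancestral = self.ancestral.copy()
            self.ancestral[fixed] = col_min[fixed]
        if self.selection_coeffs:
            counts = self.allele_counts()
            for key in list(self.selection_coeffs):
                site, allele = key
                if allele == self.ancestral[site] or counts[site, allele] == 0:
                    del self.selection_coeffs[key]
        self.fitness = self.recompute_fitness()
        return n_fixed

    # ------------------------------------------------------------------ #
    # sampling

    def sample(self, n: int, rng: np.random.Generator) -> SampleAlignment:
        """Draw ``n`` individuals uniformly without replacement."""
        if n > self.N:
            raise ValueError(f"cannot sample {n} individuals from N={self.N}")
        chosen = np.sort(rng.choice(self.N, size=n, replace=False))
        seqs = self._storage[self._ids[chosen]].copy()
        labels = [f"ind_{i}" for i in chosen]
        return SampleAlignment(seqs, self.ancestral.copy(), labels)

    def population_alignment(self) -> SampleAlignment:
        """The whole population as an alignment (for sampling-bias studies)."""
        return SampleAlignment(
            self.haplotypes, self.ancestral.copy(),
            [f"ind_{i}" for i in range(self.N)],
        )
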