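"""Site-frequency-spectrum statistics and misorientation correction.

The unfolded SFS counts, for each frequency class i in 1..n-1, the number of
biallelic segregating sites whose derived allele is carried by exactly i of
the n sampled sequences; polarization uses the known ancestral sequence.
Under finite-sites JC69 mutation a few sites carry more than two alleles or
have lost their ancestral allele from the sample; those are excluded from
the spectrum and counted in the returned object's bookkeeping fields.

The transformed spectrum i*xi_i, normalized by its sum, has a flat
expectation 1/(n-1) under the standard neutral model (E[xi_i] = theta/i),
which makes deviations easy to read.

When polarization comes from an outgroup instead of a known ancestor, a
fraction of sites is misoriented. With q the probability that the outgroup
nucleotide equals the ancestral nucleotide, the observed spectrum mixes
frequency classes k and n-k:

    xi_k_obs = q * xi_k + (1 - q) * xi_{n-k}

q can be estimated from x, the proportion of segregating sites whose
outgroup nucleotide differs from both SNP alleles. Under JC69,
P(outgroup differs from both | segregating) = 2(1-q)/3, giving the default
estimator q = 1 - 3x/2 (mode ``jc_consistent``); the alternative estimator
q = x/2 is kept as mode ``half_x``. The mixing system is inverted
exactly (mode ``exact_inverse``) or with the shortcut formula
(xi_k_obs - xi_{n-k}_obs (1-q)) / (2q - 1) (mode ``unweighted``, which
omits the q weight on the observed class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .population import SampleAlignment

__all__ = [
    "SiteFrequencySpectrum",
    "TransformedSFS",
    "site_allele_counts",
    "unfolded_sfs",
    "transform_normalize",
    "segregating_site_count",
    "segregating_fraction",
    "tajimas_d",
    "watterson_expected_S",
    "harmonic_number",
    "simulate_outgroup",
    "outgroup_mismatch_fraction",
    "estimate_q",
    "correct_sfs",
    "mix_sfs",
]


@dataclass
class SiteFrequencySpectrum:
    """Unfolded SFS: counts xi_1..xi_{n-1} of derived-allele classes."""

    n: int
    xi: np.ndarray
    folded: bool = False
    #: sites with >2 alleles in the sample, excluded from the spectrum
    excluded_multiallelic: int = 0
    #: biallelic sites whose ancestral allele is absent from the sample
    excluded_unpolarized: int = 0

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        if self.xi.shape != (self.n - 1,):
            raise ValueError("xi must have length n - 1")
        if (self.xi < 0).any():
            raise ValueError("xi counts must be non-negative")

    @property
    def S(self) -> float:
        """Number of segregating sites in the spectrum."""
        return float(self.xi.sum())


@dataclass
class TransformedSFS:
    """The normalized transform i*xi_i / sum_j j*xi_j (sums to one)."""

    n: int
    values: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n - 1,):
            raise ValueError("values must have length n - 1")


def site_allele_counts(sequences: np.ndarray) -> np.ndarray:
    """(L, 4) allele counts per site of an (n, L) code matrix."""
    seqs = np.asarray(sequences)
    counts = np.empty((seqs.shape[1], 4), dtype=np.int64)
    for a in range(4):
        counts[:, a] = (seqs == a).sum(axis=0)
    return counts


def _biallelic_mask(counts: np.ndarray) -> np.ndarray:
    return (counts > 0).sum(axis=1) == 2


def unfolded_sfs(sample: SampleAlignment) -> SiteFrequencySpectrum:
    """Unfolded SFS of a sample with known ancestral sequence.

    Only biallelic sites at which the ancestral allele is present in the
    sample enter the spectrum; multiallelic and unpolarizable sites are
    excluded and counted.
    """
    n = sample.n
    counts = site_allele_counts(sample.sequences)
    biallelic = _biallelic_mask(counts)
    anc_count = counts[np.arange(sample.L), sample.ancestral]
    polarizable = biallelic & (anc_count > 0)
    derived = n - anc_count[polarizable]
    xi = np.bincount(derived, minlength=n)[1:n]
    n_multi = int(((counts > 0).sum(axis=1) > 2).sum())
    n_unpol = int((biallelic & (anc_count == 0)).sum())
    return SiteFrequencySpectrum(
        n=n, xi=xi, excluded_multiallelic=n_multi, excluded_unpolarized=n_unpol
    )


def transform_normalize(sfs: SiteFrequencySpectrum) -> TransformedSFS:
    """i*xi_i normalized by its sum; flat (1/(n-1)) under neutrality."""
    i = np.arange(1, sfs.n)
    weighted = i * sfs.xi
    total = weighted.sum()
    if total <= 0:
        raise ValueError("transformed SFS undefined for an empty spectrum (S = 0)")
    return TransformedSFS(n=sfs.n, values=weighted / total)


def segregating_site_count(sample: SampleAlignment) -> int:
    """Number of biallelic segregating sites (polarization not required)."""
    return int(_biallelic_mask(site_allele_counts(sample.sequences)).sum())


def segregating_fraction(sample: SampleAlignment) -> float:
    """Fraction of segregating (biallelic) sites, S / L."""
    return segregating_site_count(sample) / sample.L


def harmonic_number(m: int) -> float:
    """a_m = sum_{i=1}^{m} 1/i."""
    return float(np.sum(1.0 / np.arange(1, m + 1))) if m >= 1 else 0.0


def watterson_expected_S(theta: float, L: int, n: int) -> float:
    """Expected segregating sites under neutrality: theta * L * a_{n-1}."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return theta * L * harmonic_number(n - 1)


def tajimas_d(sample: SampleAlignment) -> float:
    """Tajima's D of a sample alignment.

    Computed from biallelic sites: pi is the mean number of pairwise
    differences, S the number of segregating sites, with the standard
    normalizing constants. Returns NaN (undefined) when S = 0; such
    replicates are excluded from averages downstream.
    """
    n = sample.n
    if n < 2:
        raise ValueError("Tajima's D needs at least two sequences")
    counts = site_allele_counts(sample.sequences)
    biallelic = _biallelic_mask(counts)
    S = int(biallelic.sum())
    if S == 0:
        warnings.warn("Tajima's D undefined for S = 0", stacklevel=2)
        return float("nan")
    # pi from per-site allele counts: sum_a c_a (n - c_a) / 2 mismatching pairs
    c = counts[biallelic].astype(float)
    mismatch_pairs = (c * (n - c)).sum(axis=1) / 2.0
    pi = mismatch_pairs.sum() / (n * (n - 1) / 2.0)

    a1 = harmonic_number(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi - S / a1) / np.sqrt(var))


# --------------------------------------------------------------------- #
# outgroup misorientation


def simulate_outgroup(sample: SampleAlignment, q_true: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Simulate an outgroup sequence for the misorientation model.

    Per site, the outgroup equals the ancestral nucleotide with probability
    ``q_true`` and is otherwise uniform among the other three (JC69).
    """
    if not 0.5 < q_true <= 1:
        raise ValueError("q_true must be in (0.5, 1]")
    out = sample.ancestral.copy()
    miss = rng.random(sample.L) >= q_true
    k = int(miss.sum())
    if k:
        out[miss] = (out[miss] + rng.integers(1, 4, k).astype(np.uint8)) % 4
    return out


def outgroup_mismatch_fraction(sample: SampleAlignment,
                               outgroup: np.ndarray) -> float:
    """x: proportion of segregating sites whose outgroup nucleotide differs
    from both SNP alleles."""
    counts = site_allele_counts(sample.sequences)
    biallelic = _biallelic_mask(counts)
    sites = np.flatnonzero(biallelic)
    if sites.size == 0:
        raise ValueError("no segregating sites")
    out = np.asarray(outgroup)[sites]
    present = counts[sites] > 0
    out_present = present[np.arange(sites.size), out]
    return float(1.0 - out_present.mean())


def estimate_q(x: float, mode: str = "jc_consistent") -> float:
    """Estimate q, the probability the outgroup matches the ancestor.

    ``jc_consistent`` (default) inverts P(U|S) = 2(1-q)/3, giving
    q = 1 - 3x/2. ``half_x`` returns x/2.
    """
    if not 0 <= x <= 1:
        raise ValueError("x must be in [0, 1]")
    if mode == "jc_consistent":
        q = 1.0 - 1.5 * x
        if q < 0:
            warnings.warn(
                f"x={x} > 2/3 gives a negative q estimate", stacklevel=2
            )
        return q
    if mode == "half_x":
        return x / 2.0
    raise ValueError(f"unknown mode {mode!r}")


def correct_sfs(sfs_obs: SiteFrequencySpectrum, q: float,
                mode: str = "exact_inverse") -> SiteFrequencySpectrum:
    """Undo misorientation mixing of the observed spectrum.

    The forward model is xi_k_obs = q xi_k + (1-q) xi_{n-k}. Mode
    ``exact_inverse`` (default) solves the 2x2 system,
    xi_k = (q xi_k_obs - (1-q) xi_{n-k}_obs) / (2q - 1); mode
    ``unweighted`` uses xi_k = (xi_k_obs - xi_{n-k}_obs (1-q)) / (2q - 1).
    Negative corrected counts are clamped to zero with a warning.
    """
    if q <= 0.5:
        raise ValueError("correction requires q > 0.5 (mixing not invertible)")
    obs = sfs_obs.xi.astype(float)
    rev = obs[::-1]  # xi_{n-k}
    if mode == "exact_inverse":
        xi = (q * obs - (1.0 - q) * rev) / (2.0 * q - 1.0)
    elif mode == "unweighted":
        xi = (obs - rev * (1.0 - q)) / (2.0 * q - 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if (xi < 0).any():
        if xi.min() < -1e-9 * max(1.0, float(np.abs(xi).max())):
            warnings.warn("negative corrected SFS counts clamped to 0",
                          stacklevel=2)
        xi = np.clip(xi, 0.0, None)
    return SiteFrequencySpectrum(
        n=sfs_obs.n, xi=xi,
        excluded_multiallelic=sfs_obs.excluded_multiallelic,
        excluded_unpolarized=sfs_obs.excluded_unpolarized,
    )


def mix_sfs(sfs: SiteFrequencySpectrum, q: float) -> SiteFrequencySpectrum:
    """Forward misorientation mixing (test/oracle helper)."""
    xi = sfs.xi.astype(float)
    mixed = q * xi + (1.0 - q) * xi[::-1]
    return SiteFrequencySpectrum(n=sfs.n, xi=mixed)
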