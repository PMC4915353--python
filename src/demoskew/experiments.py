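"""Scenario orchestration: replicate batches, statistics, summary tables.

:func:`run_scenario` runs ``replicates`` independent simulations of one
:class:`~demoskew.config.ScenarioConfig` under a sampling scheme (random,
uniform, clustered, mixed), computes the per-replicate statistics
(segregating sites, Tajima's D, unfolded and transformed SFS, AIC-selected
generalized skyline and its amplitude), and optionally writes FASTA, Newick,
TSV and JSON-provenance outputs under ``outdir/<scenario>/<replicate>/``.

Replicate ``r`` always uses the RNG stream
``numpy.random.SeedSequence(seed, spawn_key=(r,))`` so any single replicate
is reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .population import SampleAlignment
from .sampling import (
    distance_matrix,
    pam_cluster,
    sample_clustered,
    sample_mixed,
    sample_uniform,
)
from .sfs import (
    SiteFrequencySpectrum,
    segregating_site_count,
    tajimas_d,
    transform_normalize,
    unfolded_sfs,
)
from .simulate import run_simulation
from .skyline import (
    SkylineEstimate,
    aic_select_epsilon,
    coalescent_intervals,
    skyline_amplitude,
    upgma_tree,
    write_newick,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMES",
    "ReplicateRecord",
    "ScenarioResult",
    "replicate_rng",
    "run_scenario",
    "summarize",
    "skyline_to_frame",
    "sfs_to_frame",
]

SCHEMES = ("random", "uniform", "clustered", "mixed")


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic RNG stream of one replicate of an experiment."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


@dataclass
class ReplicateRecord:
    """Per-replicate statistics of one scenario run."""

    index: int
    S: int
    S_frac: float
    tajima_d: float
    sfs: SiteFrequencySpectrum
    tsfs: np.ndarray | None
    skyline: SkylineEstimate | None
    amplitude: float
    epsilon: float

    def row(self) -> dict:
        return {
            "replicate": self.index,
            "S": self.S,
            "S_frac": self.S_frac,
            "tajima_d": self.tajima_d,
            "amplitude": self.amplitude,
            "epsilon": self.epsilon,
        }


@dataclass
class ScenarioResult:
    """All replicates of one (scenario, sampling scheme) experiment."""

    name: str
    scheme: str
    config: ScenarioConfig
    records: list[ReplicateRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.row() for r in self.records])

    def provenance(self) -> dict:
        from . import __version__

        return {
            "scenario": self.name,
            "scheme": self.scheme,
            "config": self.config.to_dict(),
            "replicates": len(self.records),
            "seed": self.config.seed,
            "seed_derivation": "SeedSequence(seed, spawn_key=(replicate,))",
            "package": "demoskew",
            "version": __version__,
        }


def sfs_to_frame(sfs: SiteFrequencySpectrum) -> pd.DataFrame:
    i = np.arange(1, sfs.n)
    weighted = i * sfs.xi
    total = weighted.sum()
    norm = weighted / total if total > 0 else np.full(sfs.n - 1, np.nan)
    return pd.DataFrame({"i": i, "xi": sfs.xi, "transformed": norm})


def skyline_to_frame(est: SkylineEstimate) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_start": est.boundaries[:-1],
            "t_end": est.boundaries[1:],
            "Ne_u": est.values,
            "segment_index": np.arange(est.K),
            "epsilon": est.epsilon,
        }
    )


def _biased_sample(pop_aln: SampleAlignment, scheme: str, n_sample: int,
                   rng: np.random.Generator) -> SampleAlignment:
    k = n_sample if scheme == "uniform" else 10
    dm = distance_matrix(pop_aln, method="p")
    clustering = pam_cluster(dm, k, rng)
    if scheme == "uniform":
        return sample_uniform(pop_aln, clustering, rng)
    if scheme == "clustered":
        return sample_clustered(pop_aln, clustering, rng, size=n_sample)
    if scheme == "mixed":
        return sample_mixed(pop_aln, clustering, rng,
                            focal_size=n_sample - (k - 1))
    raise ValueError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")


def analyze_sample(sample: SampleAlignment, index: int = 0,
                   compute_skyline: bool = True) -> ReplicateRecord:
    """Compute the full statistics record for one sample alignment."""
    S = segregating_site_count(sample)
    sfs = unfolded_sfs(sample)
    tsfs = transform_normalize(sfs).values if sfs.S > 0 else None
    d = tajimas_d(sample) if S > 0 else float("nan")
    est, amplitude, epsilon = None, float("nan"), float("nan")
    if compute_skyline and S > 0:
        dm = distance_matrix(sample, method="jc69")
        intervals = coalescent_intervals(upgma_tree(dm))
        try:
            epsilon, est = aic_select_epsilon(intervals)
            amplitude = skyline_amplitude(est)
        except ValueError as exc:  # degenerate genealogy
            logger.warning("replicate %d: skyline degenerate (%s)", index, exc)
    return ReplicateRecord(
        index=index, S=S, S_frac=S / sample.L, tajima_d=d, sfs=sfs,
        tsfs=tsfs, skyline=est, amplitude=amplitude, epsilon=epsilon,
    )


def run_scenario(config: ScenarioConfig, scheme: str = "random",
                 replicates: int | None = None, name: str | None = None,
                 outdir: str | Path | None = None,
                 compute_skyline: bool = True) -> ScenarioResult:
    """Run a replicate batch of one scenario and collect its statistics."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")
    replicates = config.replicate_count if replicates is None else replicates
    name = name or "scenario"
    result = ScenarioResult(name=name, scheme=scheme, config=config)
    for r in range(replicates):
        rng = replicate_rng(config.seed, r)
        try:
            pop, sample = run_simulation(config, rng)
            if scheme != "random":
                sample = _biased_sample(pop.population_alignment(), scheme,
                                        config.n_sample, rng)
            rec = analyze_sample(sample, index=r,
                                 compute_skyline=compute_skyline)
        except Exception as exc:
            raise RuntimeError(f"replicate {r} of {name!r} failed: {exc}") from exc
        logger.info("%s[%s] replicate %d: S=%d D=%.3f", name, scheme, r,
                    rec.S, rec.tajima_d)
        result.records.append(rec)
        if outdir is not None:
            rep_dir = Path(outdir) / name / str(r)
            rep_dir.mkdir(parents=True, exist_ok=True)
            sample.write_fasta(rep_dir / "sample.fasta")
            sfs_to_frame(rec.sfs).to_csv(rep_dir / "sfs.tsv", sep="\t", index=False)
            if rec.skyline is not None:
                skyline_to_frame(rec.skyline).to_csv(
                    rep_dir / "skyline.tsv", sep="\t", index=False
                )
                write_newick(upgma_tree(distance_matrix(sample, "jc69")),
                             rep_dir / "tree.nwk")
    if outdir is not None:
        scen_dir = Path(outdir) / name
        scen_dir.mkdir(parents=True, exist_ok=True)
        result.to_frame().to_csv(scen_dir / "replicates.tsv", sep="\t", index=False)
        (scen_dir / "provenance.json").write_text(
            json.dumps(result.provenance(), indent=2)
        )
    return result


_STATISTICS = ("S", "S_frac", "tajima_d", "amplitude")


def summarize(results: list[ScenarioResult]) -> pd.DataFrame:
    """Long-format comparison table: scenario x statistic x summary values.

    The SD/SE of single-replicate scenarios are undefined (NaN).
    """
    if not results:
        raise ValueError("need at least one ScenarioResult")
    rows = []
    for res in results:
        frame = res.to_frame()
        for stat in _STATISTICS:
            x = frame[stat].dropna().to_numpy(dtype=float)
            n = x.size
            sd = float(np.std(x, ddof=1)) if n > 1 else float("nan")
            rows.append(
                {
                    "scenario": res.name,
                    "scheme": res.scheme,
                    "statistic": stat,
                    "n": n,
                    "mean": float(np.mean(x)) if n else float("nan"),
                    "sd": sd,
                    "se": sd / np.sqrt(n) if n > 1 else float("nan"),
                    "median": float(np.median(x)) if n else float("nan"),
                    "q1": float(np.percentile(x, 25)) if n else float("nan"),
                    "q3": float(np.percentile(x, 75)) if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)
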