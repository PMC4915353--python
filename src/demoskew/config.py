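"""Scenario configuration for the simulation study.

A :class:`ScenarioConfig` gathers every knob of one experiment: the
Wright-Fisher population (size ``N``, locus length ``L``, population-scaled
mutation rate ``theta``), the three-point-mass selection model (class
probabilities for deleterious / neutral / adaptive mutations and their
selection coefficients), bacterial gene conversion (initiation rate relative
to mutation, mean tract length), the sample drawn at the end, and the
replication/seeding scheme.

Named presets encode the *E. coli* parameterization used throughout:
mutation-class probabilities are derived from the genomic deleterious
(2e-4) and adaptive (1e-5) mutation rates over the total genomic mutation
rate (8.9e-11 per site per generation x 5e6 sites).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ScenarioConfig",
    "ECOLI_CLASS_PROBS",
    "PRESETS",
    "get_preset",
    "load_config",
    "save_config",
]

# E. coli per-mutation fitness-class probabilities: genomic deleterious and
# adaptive rates divided by the total genomic mutation rate u * genome size.
_GENOMIC_DELETERIOUS_RATE = 2e-4
_GENOMIC_ADAPTIVE_RATE = 1e-5
_GENOMIC_MUTATION_RATE = 8.9e-11 * 5e6  # = 4.45e-4 per genome per generation

_P_DEL = _GENOMIC_DELETERIOUS_RATE / _GENOMIC_MUTATION_RATE  # ~0.449
_P_ADV = _GENOMIC_ADAPTIVE_RATE / _GENOMIC_MUTATION_RATE  # ~0.0225

#: (deleterious, neutral, adaptive) probabilities for a new mutation.
ECOLI_CLASS_PROBS: tuple[float, float, float] = (_P_DEL, 1.0 - _P_DEL - _P_ADV, _P_ADV)


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulation scenario.

    Parameters
    ----------
    N : int
        Haploid population size (constant through time).
    L : int
        Locus length in nucleotides.
    theta : float
        Per-site population-scaled mutation rate, ``theta = 2 N u_site``.
    n_sample : int
        Number of individuals drawn (uniformly, without replacement) from
        the final population.
    class_probs : tuple of float
        Probabilities ``(deleterious, neutral, adaptive)`` that a new
        mutation falls in each fitness class.
    s_del, s_adv : float
        Per-generation selection coefficients of deleterious (negative) and
        adaptive (positive) mutations. Individual fitness is multiplicative,
        ``(1 + s)`` per carried derived allele.
    conv_init_ratio : float
        Gene-conversion initiation rate over the mutation rate (rho/mu,
        per site). 0 disables conversion.
    tract_mean : float
        Mean conversion tract length in nucleotides (geometric distribution).
    burnin_gens : int or None
        Generations to evolve from the monomorphic start; ``None`` means
        ``10 * N``.
    seed : int
        Master seed; replicate ``r`` uses the deterministic child stream
        ``numpy.random.SeedSequence(seed, spawn_key=(r,))``.
    replicate_count : int
        Default number of replicates for scenario batches.
    """

    N: int = 1000
    L: int = 20000
    theta: float = 0.02
    n_sample: int = 100
    class_probs: tuple[float, float, float] = (0.0, 1.0, 0.0)
    s_del: float = 0.0
    s_adv: float = 0.0
    conv_init_ratio: float = 0.0
    tract_mean: float = 542.0
    burnin_gens: int | None = None
    seed: int = 0
    replicate_count: int = 10

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        probs = tuple(float(p) for p in self.class_probs)
        object.__setattr__(self, "class_probs", probs)
        if len(probs) != 3 or any(p < 0 or p > 1 for p in probs):
            raise ValueError("class_probs must be three probabilities in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if not 0 <= self.u_site < 1:
            raise ValueError("per-site mutation rate theta/(2N) must be in [0, 1)")
        if self.tract_mean < 1:
            raise ValueError("tract_mean must be >= 1 nt")
        if self.conv_init_ratio < 0:
            raise ValueError("conv_init_ratio must be >= 0")
        if self.s_del > 0 or self.s_adv < 0:
            raise ValueError("expected s_del <= 0 and s_adv >= 0")
        if self.s_del <= -1:
            raise ValueError("s_del must exceed -1 (fitness must stay positive)")
        if self.n_sample < 1 or self.n_sample > self.N:
            raise ValueError("n_sample must be in [1, N]")

    @property
    def u_site(self) -> float:
        """Per-site per-generation mutation rate u = theta / (2N)."""
        return self.theta / (2.0 * self.N)

    @property
    def burnin(self) -> int:
        """Effective burn-in length (``burnin_gens`` or ``10 * N``)."""
        return 10 * self.N if self.burnin_gens is None else self.burnin_gens

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_probs"] = list(d["class_probs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "class_probs" in d:
            d["class_probs"] = tuple(d["class_probs"])
        return cls(**d)


def _weak_s(N: int) -> float:
    # weak selection is specified as N*s = 5
    return 5.0 / N


#: Scenario presets; Table-of-parameters values for E. coli populations.
PRESETS: dict[str, ScenarioConfig] = {
    "neutral": ScenarioConfig(),
    "recomb_1x": ScenarioConfig(conv_init_ratio=1.0),
    "recomb_10x": ScenarioConfig(conv_init_ratio=10.0),
    "weak_selection": ScenarioConfig(
        class_probs=ECOLI_CLASS_PROBS, s_del=-_weak_s(1000), s_adv=_weak_s(1000)
    ),
    # Strong selection: the literal population-scaled coefficient exceeds 1,
    # so |s| is capped at 0.5; any |2Ns| >> 1 is deep in the strong regime.
    "ecoli_strong": ScenarioConfig(
        class_probs=ECOLI_CLASS_PROBS, s_del=-0.5, s_adv=0.5
    ),
    "weak_selection_recomb": ScenarioConfig(
        class_probs=ECOLI_CLASS_PROBS,
        s_del=-_weak_s(1000),
        s_adv=_weak_s(1000),
        conv_init_ratio=1.0,
    ),
}


def get_preset(name: str) -> ScenarioConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}"
        ) from None


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a scenario configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ScenarioConfig.from_dict(data)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
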