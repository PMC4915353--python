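"""Forward Wright-Fisher simulation with selection and gene conversion.

One generation is: multinomial reproduction weighted by multiplicative
fitness (:func:`select_reproduce`), finite-sites JC69 mutation
(:func:`mutate_generation`) where each new derived allele is assigned one of
three fitness classes (deleterious / neutral / adaptive, a point-mass
selection model), and optionally bacterial gene conversion
(:func:`gene_conversion_step`) in which a donor tract overwrites the
homologous recipient tract without crossover.

:func:`run_simulation` evolves a monomorphic population for the configured
burn-in and returns the final population together with a uniform sample that
carries the true ancestral states, ready for unfolded-SFS and genealogy
analyses.
"""

from __future__ import annotations

import numpy as np

from .config import ScenarioConfig
from .population import PopulationState, SampleAlignment

__all__ = [
    "assign_mutation_class",
    "mutate_generation",
    "select_reproduce",
    "gene_conversion_step",
    "draw_tract_lengths",
    "run_simulation",
]

#: Default interval (generations) between absorptions of fixed alleles.
ABSORB_EVERY = 500


def assign_mutation_class(class_probs, s_del, s_adv, rng) -> tuple[str, float]:
    """Draw the fitness class of a new mutation.

    Returns ``(label, s)`` where label is one of ``"deleterious"``,
    ``"neutral"``, ``"adaptive"`` with the configured probabilities and
    ``s`` the matching selection coefficient (0 for neutral).
    """
    p_del, p_neut, p_adv = class_probs
    u = rng.random()
    if u < p_del:
        return "deleterious", s_del
    if u < p_del + p_neut:
        return "neutral", 0.0
    return "adaptive", s_adv


def _coeff(pop: PopulationState, site: int, allele: int) -> float:
    """Selection coefficient of an allele at a site (ancestral => 0)."""
    if allele == pop.ancestral[site]:
        return 0.0
    return pop.selection_coeffs.get((site, allele), 0.0)


def mutate_generation(pop: PopulationState, u_site: float, class_probs,
                      s_del: float, s_adv: float,
                      rng: np.random.Generator) -> PopulationState:
    """Apply one generation of JC69 mutation.

    The number of events is Binomial(N*L, u_site); each event picks a
    uniform (individual, site) and replaces the current nucleotide by one of
    the other three uniformly. A derived allele seen for the first time is
    assigned a fitness class by ``class_probs``; colliding events on the same
    (individual, site) are applied sequentially.
    """
    if not 0 <= u_site < 1:
        raise ValueError("u_site must be in [0, 1)")
    n_events = rng.binomial(pop.N * pop.L, u_site) if u_site > 0 else 0
    if n_events == 0:
        return pop
    ind = rng.integers(0, pop.N, n_events)
    site = rng.integers(0, pop.L, n_events)
    shift = rng.integers(1, 4, n_events).astype(np.uint8)
    selected = class_probs[0] + class_probs[2] > 0
    class_u = rng.random(n_events) if selected else None

    order = np.argsort(ind, kind="stable")
    ind, site, shift = ind[order], site[order], shift[order]
    if class_u is not None:
        class_u = class_u[order]
    p_del, p_neut, _ = class_probs

    anc = pop.ancestral
    sel = pop.selection_coeffs
    fitness = pop.fitness
    start = 0
    while start < n_events:
        i = ind[start]
        end = start
        while end < n_events and ind[end] == i:
            end += 1
        row = pop.row_for_write(i)
        for e in range(start, end):
            j = site[e]
            old = row[j]
            new = (old + shift[e]) % 4
            row[j] = new
            if selected:
                s_old = 0.0 if old == anc[j] else sel.get((j, old), 0.0)
                if new == anc[j]:
                    s_new = 0.0
                else:
                    key = (j, new)
                    if key in sel:
                        s_new = sel[key]
                    else:
                        u = class_u[e]
                        if u < p_del:
                            s_new = s_del
                        elif u < p_del + p_neut:
                            s_new = 0.0
                        else:
                            s_new = s_adv
                        # the class is a property of the (site, allele) pair:
                        # record neutral draws too, so an independent second
                        # origin of the same allele keeps the same coefficient
                        sel[key] = s_new
                if s_new != s_old:
                    fitness[i] *= (1.0 + s_new) / (1.0 + s_old)
        start = end
    return pop


def select_reproduce(pop: PopulationState,
                     rng: np.random.Generator) -> PopulationState:
    """Wright-Fisher resampling: N offspring drawn multinomially.

    Offspring counts are multinomial with probabilities proportional to
    parental fitness (uniform when all fitnesses are equal); the population
    size stays constant.
    """
    w = pop.fitness
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ArithmeticError("non-positive or non-finite fitness encountered")
    cdf = np.cumsum(w)
    total = cdf[-1]
    if total <= 0:
        raise ArithmeticError("total fitness is zero")
    parents = np.searchsorted(cdf, rng.random(pop.N) * total, side="right")
    pop.reassign_parents(parents)
    pop.generation += 1
    return pop


def draw_tract_lengths(tract_mean: float, rng: np.random.Generator,
                       size=None) -> np.ndarray:
    """Geometric tract lengths (support 1, 2, ...) with the given mean."""
    if tract_mean < 1:
        raise ValueError("tract_mean must be >= 1")
    return rng.geometric(1.0 / tract_mean, size=size)


def gene_conversion_step(pop: PopulationState, conv_init_ratio: float,
                         u_site: float, tract_mean: float,
                         rng: np.random.Generator) -> PopulationState:
    """Apply one generation of gene conversion (no crossovers).

    Initiation events are Binomial(N*L, conv_init_ratio * u_site). Each event
    picks a recipient (individual, site) uniformly and a donor uniformly
    among the other N-1 individuals; a geometric tract with the configured
    mean, starting at the initiation site and clipped at the locus end, is
    copied from donor to recipient. No new alleles are created.
    """
    if conv_init_ratio < 0:
        raise ValueError("conv_init_ratio must be >= 0")
    p_init = conv_init_ratio * u_site
    if p_init <= 0:
        return pop
    if p_init >= 1:
        raise ValueError("per-site initiation probability must be < 1")
    n_events = rng.binomial(pop.N * pop.L, p_init)
    if n_events == 0:
        return pop
    recip = rng.integers(0, pop.N, n_events)
    start = rng.integers(0, pop.L, n_events)
    donor = rng.integers(0, pop.N - 1, n_events)
    donor += donor >= recip
    tracts = draw_tract_lengths(tract_mean, rng, n_events)

    sel = pop.selection_coeffs
    anc = pop.ancestral
    fitness = pop.fitness
    for e in range(n_events):
        i, d = int(recip[e]), int(donor[e])
        a = int(start[e])
        b = min(pop.L, a + int(tracts[e]))
        if pop._ids[i] == pop._ids[d]:
            continue  # identical shared haplotype: copying is a no-op
        drow = pop.row_view(d)
        rrow = pop.row_view(i)
        seg_d = drow[a:b]
        seg_r = rrow[a:b]
        diff = np.flatnonzero(seg_d != seg_r)
        if diff.size == 0:
            continue
        donor_alleles = seg_d[diff].copy()
        row = pop.row_for_write(i)
        if sel:
            ratio = 1.0
            for off, new in zip(diff, donor_alleles):
                j = a + int(off)
                old = row[j]
                s_old = 0.0 if old == anc[j] else sel.get((j, old), 0.0)
                s_new = 0.0 if new == anc[j] else sel.get((j, int(new)), 0.0)
                ratio *= (1.0 + s_new) / (1.0 + s_old)
            fitness[i] *= ratio
        row[a + diff] = donor_alleles
    return pop


def run_simulation(config: ScenarioConfig,
                   rng: np.random.Generator | None = None,
                   absorb_every: int = ABSORB_EVERY,
                   ) -> tuple[PopulationState, SampleAlignment]:
    """Evolve a population under ``config`` and draw the final sample.

    The population starts monomorphic for a uniformly drawn ancestral
    sequence, evolves ``config.burnin`` generations (reproduction, mutation,
    then conversion each generation), and ``config.n_sample`` individuals are
    drawn uniformly without replacement. Fixed derived alleles are absorbed
    into the ancestral background every ``absorb_every`` generations and once
    at the end, so the returned sample carries true ancestral states.
    """
    if config.n_sample > config.N:
        raise ValueError("n_sample exceeds the population size N")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = PopulationState.monomorphic(config.N, config.L, rng)
    u = config.u_site
    conv = config.conv_init_ratio
    for g in range(config.burnin):
        select_reproduce(pop, rng)
        mutate_generation(pop, u, config.class_probs, config.s_del,
                          config.s_adv, rng)
        if conv > 0:
            gene_conversion_step(pop, conv, u, config.tract_mean, rng)
        if absorb_every and (g + 1) % absorb_every == 0:
            pop.absorb_fixed()
    pop.absorb_fixed()
    sample = pop.sample(config.n_sample, rng)
    return pop, sample
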