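"""Finite-population individual-based counterpart of the deterministic engine.

A Wright–Fisher-style stochastic simulation with N diploid individuals per
sex, following the same generational rules as the deterministic recursion:
parents are sampled with probability proportional to their sex-specific
marginal fitness, and each transmits one gamete drawn from the same
recombination kernel. Its expectation is exactly the deterministic model,
which makes it an independent check on the frequency recursion (and a way to
gauge how much genetic drift would matter at a given population size); it is
not used by the strategy runners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitness import marginal_fitness
from .simulator import _diploid_fitness
from .strategies import Scenario, _deployment_exposure


@dataclass
class StochasticPopulation:
    """Haplotype-pair arrays per sex; entries index {S1S2, S1R2, R1S2, R1R2}."""

    female: np.ndarray  # shape (N, 2), integer haplotype codes
    male: np.ndarray

    @property
    def size(self) -> int:
        return self.female.shape[0]

    def allele_frequencies(self) -> tuple[float, float]:
        """Sex-averaged R frequency at each locus."""
        both = np.concatenate([self.female, self.male])
        p1 = float(np.mean(both >= 2))  # haplotypes R1S2, R1R2 carry R at locus 1
        p2 = float(np.mean(both % 2))  # haplotypes S1R2, R1R2 carry R at locus 2
        return p1, p2


def init_stochastic(
    p1: float, p2: float, n_per_sex: int, rng: np.random.Generator
) -> StochasticPopulation:
    """Sample haplotypes independently at linkage equilibrium."""
    probs = np.array([(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2])

    def draw() -> np.ndarray:
        return rng.choice(4, size=(n_per_sex, 2), p=probs)

    return StochasticPopulation(female=draw(), male=draw())


def _gametes(parents: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent: parental haplotypes w.p. (1-c)/2, recombinant c/2."""
    a, b = parents[:, 0], parents[:, 1]
    rec1 = (a & 0b10) | (b & 0b01)
    rec2 = (b & 0b10) | (a & 0b01)
    u = rng.random(a.shape[0])
    half = (1 - c) / 2
    return np.select(
        [u < half, u < 2 * half, u < 2 * half + c / 2], [a, b, rec1], default=rec2
    )


def step_stochastic(
    pop: StochasticPopulation,
    scenario: Scenario,
    deployed: frozenset[int],
    rng: np.random.Generator,
) -> StochasticPopulation:
    """One generation: fitness-weighted parent sampling, then meiosis."""
    c = scenario.recombination_rate
    n = pop.size
    children = {}
    parent_pools = {}
    for sex, parents in (("female", pop.female), ("male", pop.male)):
        table = marginal_fitness(
            scenario.insecticide1,
            scenario.insecticide2,
            deployed,
            _deployment_exposure(scenario, deployed, sex),
        )
        W4 = _diploid_fitness(table)
        w = W4[parents[:, 0], parents[:, 1]]
        total = w.sum()
        if total <= 0:
            raise RuntimeError(f"all {sex} individuals have zero fitness")
        parent_pools[sex] = (parents, w / total)
    for sex in ("female", "male"):
        mothers = rng.choice(n, size=n, p=parent_pools["female"][1])
        fathers = rng.choice(n, size=n, p=parent_pools["male"][1])
        egg = _gametes(parent_pools["female"][0][mothers], c, rng)
        sperm = _gametes(parent_pools["male"][0][fathers], c, rng)
        children[sex] = np.column_stack([egg, sperm])
    return StochasticPopulation(female=children["female"], male=children["male"])


def run_stochastic(
    scenario: Scenario,
    deployed: frozenset[int],
    n_generations: int,
    n_per_sex: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Allele-frequency trajectory under a fixed deployment.

    Returns an array of shape (n_generations + 1, 2) with the sex-averaged
    R frequency at each locus per census generation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = init_stochastic(
        scenario.insecticide1.start_frequency,
        scenario.insecticide2.start_frequency,
        n_per_sex,
        rng,
    )
    out = [pop.allele_frequencies()]
    for _ in range(n_generations):
        pop = step_stochastic(pop, scenario, deployed, rng)
        out.append(pop.allele_frequencies())
    return np.array(out)
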