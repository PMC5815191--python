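"""Genotype fitness construction for one and two resistance loci.

Fitness is relative to an unexposed SS insect, whose fitness is 1 by
definition. For an exposed insect, effectiveness sets the SS fitness,
resistance restoration returns a fraction of the lost fitness to RR, and
dominance of resistance interpolates SR between the two homozygotes:

    w_SS = 1 - effectiveness
    w_RR = (1 - effectiveness) + effectiveness * restoration
    w_SR = w_SS + dominance * (w_RR - w_SS)

For an unexposed insect the cost of resistance and its dominance play the
mirrored role:

    w_SS = 1
    w_RR = 1 - cost
    w_SR = 1 - dominance_cost * cost

With two loci the fitness of a two-locus genotype is the product of its two
single-locus fitnesses, each evaluated as exposed if the corresponding
insecticide is part of the exposure class (multiplicative interaction: an
insect contacting a mixture must survive both products independently).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import InsecticideParams

#: Single-locus genotypes ordered by number of resistance alleles.
GENOTYPES = ("SS", "SR", "RR")

#: The full exposure class for a two-insecticide mixture.
BOTH: frozenset[int] = frozenset({1, 2})
NEITHER: frozenset[int] = frozenset()


class FitnessTriple(NamedTuple):
    """Relative fitness of the SS, SR and RR genotypes at one locus."""

    w_ss: float
    w_sr: float
    w_rr: float

    def as_array(self) -> np.ndarray:
        """Fitness indexed by the number of resistance alleles (0, 1, 2)."""
        return np.array(self, dtype=float)


def single_locus_fitness(params: InsecticideParams, exposed: bool) -> FitnessTriple:
    """Fitness of SS/SR/RR at one locus in the exposed or unexposed state."""
    if exposed:
        w_ss = 1.0 - params.effectiveness
        w_rr = w_ss + params.effectiveness * params.resistance_restoration
        w_sr = w_ss + params.dominance_resistance * (w_rr - w_ss)
    else:
        w_ss = 1.0
        w_rr = 1.0 - params.cost
        w_sr = 1.0 - params.dominance_cost * params.cost
    return FitnessTriple(w_ss, w_sr, w_rr)


def two_locus_fitness(
    params1: InsecticideParams,
    params2: InsecticideParams,
    exposure_class: frozenset[int] | set[int],
) -> np.ndarray:
    """Fitness table for the nine two-locus genotypes under one exposure class.

    Parameters
    ----------
    exposure_class
        Subset of ``{1, 2}`` naming the insecticides the class contacts.

    Returns
    -------
    3x3 array, ``table[i, j]`` = fitness of the genotype with ``i`` resistance
    alleles at locus 1 and ``j`` at locus 2 (outer product of the two
    single-locus triples).
    """
    exposure_class = frozenset(exposure_class)
    if not exposure_class <= BOTH:
        raise ValueError(f"exposure class {set(exposure_class)} is not a subset of {{1, 2}}")
    t1 = single_locus_fitness(params1, exposed=1 in exposure_class).as_array()
    t2 = single_locus_fitness(params2, exposed=2 in exposure_class).as_array()
    return np.outer(t1, t2)


def marginal_fitness(
    params1: InsecticideParams,
    params2: InsecticideParams,
    deployed: frozenset[int] | set[int],
    exposure: float,
) -> np.ndarray:
    """Exposure-weighted fitness of the nine genotypes under a deployment.

    A fraction ``exposure`` of the population contacts every deployed
    insecticide simultaneously; the remainder contacts none. The marginal
    fitness of a genotype is the corresponding mixture of the exposed-class
    and unexposed-class tables:

        w = exposure * w(deployed class) + (1 - exposure) * w(neither)

    ``deployed`` is a subset of ``{1, 2}``: empty for no deployment,
    ``{i}`` for sole use of insecticide ``i``, ``{1, 2}`` for a mixture.
    """
    if not 0.0 <= exposure <= 1.0:
        raise ValueError(f"exposure={exposure!r} is outside [0, 1]")
    unexposed = two_locus_fitness(params1, params2, NEITHER)
    if not deployed:
        return unexposed
    exposed = two_locus_fitness(params1, params2, deployed)
    return exposure * exposed + (1.0 - exposure) * unexposed
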