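"""Deterministic two-locus, sex-structured haplotype-frequency engine.

The population is infinite and censused as gamete (haplotype) frequencies,
one 4-vector per sex over {S1S2, S1R2, R1S2, R1R2}. Each non-overlapping
generation proceeds as:

1. random union of gametes — offspring diploid frequencies are the outer
   product of the female and male gamete pools (identical genotype
   distribution in both sexes at birth, 1:1 sex ratio);
2. sex-specific selection — diploid frequencies are multiplied by that
   sex's marginal fitness and renormalised by the sex's mean fitness;
3. gamete production — each surviving diploid transmits its two parental
   haplotypes with probability (1 - c)/2 each and the two recombinant
   haplotypes with probability c/2 each, c being the recombination rate
   (for non-double-heterozygotes the recombinants coincide with the
   parentals, so this rule is uniform over genotypes).

There is no mutation, migration or drift: selection and recombination are
the only forces, so with all fitnesses equal the recursion is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

#: Haplotype order used throughout; index = 2 * (R at locus 1) + (R at locus 2).
HAPLOTYPES = ("S1S2", "S1R2", "R1S2", "R1R2")

#: Numeric tolerance for frequency-vector normalisation checks.
FREQ_TOL = 1e-12

_R1 = np.array([0, 0, 1, 1])  # resistance allele at locus 1 per haplotype
_R2 = np.array([0, 1, 0, 1])


class ExtinctionError(RuntimeError):
    """Mean fitness of a sex reached zero: no survivors under the scenario."""


def _check_freqs(name: str, freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (4,):
        raise ValueError(f"{name} must have 4 entries, got shape {freqs.shape}")
    if np.any(freqs < 0):
        raise ValueError(f"{name} has negative entries: {freqs}")
    if abs(freqs.sum() - 1.0) > FREQ_TOL:
        raise ValueError(f"{name} sums to {freqs.sum()!r}, expected 1")
    return freqs


@dataclass(frozen=True)
class PopulationState:
    """Haplotype frequencies per sex at one generation."""

    hap_female: np.ndarray
    hap_male: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hap_female", _check_freqs("hap_female", self.hap_female))
        object.__setattr__(self, "hap_male", _check_freqs("hap_male", self.hap_male))
        if self.generation < 0:
            raise ValueError("generation index must be non-negative")


class AlleleFrequencies(NamedTuple):
    """R-allele frequencies per locus: per sex and the unweighted sex mean."""

    p1_female: float
    p1_male: float
    p1_mean: float
    p2_female: float
    p2_male: float
    p2_mean: float


class LinkageDisequilibrium(NamedTuple):
    """Coefficient D and normalised D' for each sex."""

    d_female: float
    dprime_female: float
    d_male: float
    dprime_male: float


def init_population(p1: float, p2: float) -> PopulationState:
    """Population at linkage equilibrium with R frequencies ``p1`` and ``p2``.

    Both sexes start identical; f(R1R2) = p1*p2 and so on, so D = 0 by
    construction.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name}={p!r} must lie strictly inside (0, 1)")
    hap = np.array([(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2])
    return PopulationState(hap, hap.copy(), generation=0)


def allele_frequencies(state: PopulationState) -> AlleleFrequencies:
    p1f = float(state.hap_female @ _R1)
    p1m = float(state.hap_male @ _R1)
    p2f = float(state.hap_female @ _R2)
    p2m = float(state.hap_male @ _R2)
    return AlleleFrequencies(p1f, p1m, (p1f + p1m) / 2, p2f, p2m, (p2f + p2m) / 2)


def _ld_one_sex(hap: np.ndarray) -> tuple[float, float]:
    p1 = float(hap @ _R1)
    p2 = float(hap @ _R2)
    d = float(hap[3] - p1 * p2)
    if d > 0:
        d_max = min(p1 * (1 - p2), (1 - p1) * p2)
    elif d < 0:
        d_max = min(p1 * p2, (1 - p1) * (1 - p2))
    else:
        return 0.0, 0.0
    return d, (d / d_max if d_max > 0 else 0.0)


def linkage_disequilibrium(state: PopulationState) -> LinkageDisequilibrium:
    """D = f(R1R2) - p1*p2 and D' = D / D_max, per sex.

    D_max is the smaller of the two marginal bounds on the side of D's sign;
    a monomorphic locus gives D = D' = 0.
    """
    df, dpf = _ld_one_sex(state.hap_female)
    dm, dpm = _ld_one_sex(state.hap_male)
    return LinkageDisequilibrium(df, dpf, dm, dpm)


@lru_cache(maxsize=None)
def transmission_tensor(recombination_rate: float) -> np.ndarray:
    """T[a, b, g]: probability a diploid with haplotypes (a, b) transmits g.

    Parental haplotypes are emitted with weight (1 - c)/2 each, recombinants
    (locus-1 allele of one parent haplotype with the locus-2 allele of the
    other) with weight c/2 each.
    """
    c = recombination_rate
    if not 0.0 <= c <= 0.5:
        raise ValueError(f"recombination rate {c!r} is outside [0, 0.5]")
    T = np.zeros((4, 4, 4))
    for a in range(4):
        for b in range(4):
            rec1 = (a & 0b10) | (b & 0b01)
            rec2 = (b & 0b10) | (a & 0b01)
            T[a, b, a] += (1 - c) / 2
            T[a, b, b] += (1 - c) / 2
            T[a, b, rec1] += c / 2
            T[a, b, rec2] += c / 2
    T.setflags(write=False)
    return T


def _diploid_fitness(table: np.ndarray) -> np.ndarray:
    """Expand a 3x3 genotype fitness table to the 4x4 haplotype-pair matrix."""
    table = np.asarray(table, dtype=float)
    if table.shape != (3, 3):
        raise ValueError(f"fitness table must be 3x3, got {table.shape}")
    return table[np.add.outer(_R1, _R1), np.add.outer(_R2, _R2)]


def step_generation(
    state: PopulationState,
    fitness_female: np.ndarray,
    fitness_male: np.ndarray,
    recombination_rate: float = 0.5,
) -> PopulationState:
    """Advance one generation of mating, sex-specific selection and meiosis.

    ``fitness_female`` / ``fitness_male`` are 3x3 marginal genotype fitness
    tables (rows: R copies at locus 1; columns: at locus 2), typically from
    :func:`resistsim.fitness.marginal_fitness`.
    """
    Wf = _diploid_fitness(fitness_female)
    Wm = _diploid_fitness(fitness_male)
    if np.any(Wf < 0) or np.any(Wm < 0):
        raise ValueError("fitness tables must be non-negative")
    T = transmission_tensor(recombination_rate)

    zygotes = np.outer(state.hap_female, state.hap_male)
    new_haps = []
    for sex, W in (("female", Wf), ("male", Wm)):
        selected = zygotes * W
        mean_w = selected.sum()
        if mean_w <= 0.0:
            raise ExtinctionError(f"mean {sex} fitness is zero: population extinct")
        selected /= mean_w
        gametes = np.einsum("ab,abg->g", selected, T)
        new_haps.append(gametes / gametes.sum())
    return PopulationState(new_haps[0], new_haps[1], state.generation + 1)


@dataclass(frozen=True)
class TrajectoryRecord:
    """One generation's census: allele frequencies, LD and deployment label."""

    generation: int
    deployment: str
    freqs: AlleleFrequencies
    d: float
    dprime: float


@dataclass
class Trajectory:
    """Per-generation records of a simulation run."""

    records: list[TrajectoryRecord] = field(default_factory=list)

    def append(self, state: PopulationState, deployment: str) -> None:
        freqs = allele_frequencies(state)
        ld = linkage_disequilibrium(state)
        self.records.append(
            TrajectoryRecord(
                generation=state.generation,
                deployment=deployment,
                freqs=freqs,
                d=(ld.d_female + ld.d_male) / 2,
                dprime=(ld.dprime_female + ld.dprime_male) / 2,
            )
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrajectoryRecord]:
        return iter(self.records)

    def frequency(self, locus: int, generation: int) -> float:
        """Sex-averaged R frequency at ``locus`` (1 or 2) and ``generation``."""
        rec = self.records[generation]
        if rec.generation != generation:
            raise IndexError(f"no record for generation {generation}")
        return rec.freqs.p1_mean if locus == 1 else rec.freqs.p2_mean

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per generation."""
        rows = [
            {
                "generation": r.generation,
                "deployment": r.deployment,
                "freq_locus1_female": r.freqs.p1_female,
                "freq_locus1_male": r.freqs.p1_male,
                "freq_locus1_mean": r.freqs.p1_mean,
                "freq_locus2_female": r.freqs.p2_female,
                "freq_locus2_male": r.freqs.p2_male,
                "freq_locus2_mean": r.freqs.p2_mean,
                "D": r.d,
                "Dprime": r.dprime,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)
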