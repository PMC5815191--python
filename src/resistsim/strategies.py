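"""Deployment strategies and time-to-resistance metrics.

Three ways of using two insecticides are compared:

* **single** — one insecticide deployed alone; the other locus experiences
  only unexposed (cost) selection.
* **sequence** — insecticide 1 deployed until its resistance allele first
  reaches the threshold, then replaced by insecticide 2; total time is the
  generation at which the second locus crosses.
* **mixture** — both insecticides co-deployed every generation; total time
  is the first generation at which both loci have crossed.

Time-to-resistance is the smallest census generation at which the
sex-averaged resistance frequency is at or above the threshold (0.5 by
default); crossings are read at integer generations with no interpolation,
and a run that hits the generation cap reports a not-reached sentinel
(``None``) rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .fitness import marginal_fitness
from .params import InsecticideParams, ParameterError
from .simulator import PopulationState, Trajectory, init_population, step_generation

#: Label used in serialized output for a threshold never reached under the cap.
NOT_REACHED = "NOT_REACHED"


@dataclass(frozen=True)
class Scenario:
    """Two insecticides plus the global simulation settings."""

    insecticide1: InsecticideParams
    insecticide2: InsecticideParams
    recombination_rate: float = 0.5
    resistance_threshold: float = 0.5
    max_generations: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.recombination_rate <= 0.5:
            raise ParameterError(
                f"recombination_rate={self.recombination_rate!r} is outside [0, 0.5]"
            )
        if not 0.0 < self.resistance_threshold < 1.0:
            raise ParameterError(
                f"resistance_threshold={self.resistance_threshold!r} is outside (0, 1)"
            )
        if int(self.max_generations) != self.max_generations or self.max_generations < 1:
            raise ParameterError(
                f"max_generations={self.max_generations!r} must be a positive integer"
            )

    def params(self, which: int) -> InsecticideParams:
        if which == 1:
            return self.insecticide1
        if which == 2:
            return self.insecticide2
        raise ValueError(f"insecticide index must be 1 or 2, got {which!r}")


@dataclass(frozen=True)
class StrategyResult:
    """Outcome of one strategy run."""

    strategy_label: str
    time_locus1: int | None
    time_locus2: int | None
    total_time: int | None
    trajectory: Trajectory

    def summary(self) -> dict[str, object]:
        def fmt(t: int | None) -> object:
            return NOT_REACHED if t is None else t

        return {
            "strategy": self.strategy_label,
            "time_locus1": fmt(self.time_locus1),
            "time_locus2": fmt(self.time_locus2),
            "total_time": fmt(self.total_time),
        }


def time_to_resistance(
    trajectory: Trajectory, locus: int, threshold: float
) -> int | None:
    """First generation at which the locus's mean R frequency is >= threshold."""
    for rec in trajectory:
        freq = rec.freqs.p1_mean if locus == 1 else rec.freqs.p2_mean
        if freq >= threshold:
            return rec.generation
    return None


def _deployment_exposure(scenario: Scenario, deployed: frozenset[int], sex: str) -> float:
    """Exposure of one sex to the currently deployed product(s).

    A mixture is a single co-formulated deployment, so both insecticides must
    declare the same contact probability per sex.
    """
    if not deployed:
        return 0.0
    exposures = {scenario.params(i).exposure(sex) for i in sorted(deployed)}
    if len(exposures) > 1:
        raise ParameterError(
            "mixture deployment requires equal exposures for both insecticides "
            f"({sex}: {sorted(exposures)})"
        )
    return exposures.pop()


def _fitness_pair(scenario: Scenario, deployed: frozenset[int]):
    return tuple(
        marginal_fitness(
            scenario.insecticide1,
            scenario.insecticide2,
            deployed,
            _deployment_exposure(scenario, deployed, sex),
        )
        for sex in ("female", "male")
    )


def _label(deployed: frozenset[int]) -> str:
    if not deployed:
        return "none"
    if deployed == frozenset({1, 2}):
        return "mixture"
    return f"insecticide{next(iter(deployed))}"


def _run(scenario: Scenario, policy) -> Trajectory:
    """Iterate generations, asking ``policy(trajectory)`` for each deployment.

    ``policy`` returns the insecticide set to deploy for the coming
    generation, or ``None`` to stop early.
    """
    state = init_population(
        scenario.insecticide1.start_frequency, scenario.insecticide2.start_frequency
    )
    traj = Trajectory()
    traj.append(state, deployment="none")
    cache: dict[frozenset[int], tuple] = {}
    for _ in range(scenario.max_generations):
        deployed = policy(traj)
        if deployed is None:
            break
        if deployed not in cache:
            cache[deployed] = _fitness_pair(scenario, deployed)
        wf, wm = cache[deployed]
        state = step_generation(state, wf, wm, scenario.recombination_rate)
        traj.append(state, deployment=_label(deployed))
    return traj


def run_single(scenario: Scenario, which_insecticide: int) -> StrategyResult:
    """Deploy one insecticide alone until its threshold or the cap."""
    target = frozenset({which_insecticide})
    thr = scenario.resistance_threshold

    def policy(traj: Trajectory):
        freq = traj.records[-1].freqs
        current = freq.p1_mean if which_insecticide == 1 else freq.p2_mean
        return None if current >= thr else target

    traj = _run(scenario, policy)
    t1 = time_to_resistance(traj, 1, thr)
    t2 = time_to_resistance(traj, 2, thr)
    total = t1 if which_insecticide == 1 else t2
    return StrategyResult(f"single{which_insecticide}", t1, t2, total, traj)


def run_sequence(scenario: Scenario) -> StrategyResult:
    """Insecticide 1 until its locus crosses, then insecticide 2.

    The crossing generation counts toward phase 1; the switch takes effect
    the following generation. Total time is the generation at which the
    second locus crosses (``None`` if either phase hits the cap).
    """
    thr = scenario.resistance_threshold
    switched = False  # once locus 1 crosses, insecticide 1 is retired for good

    def policy(traj: Trajectory):
        nonlocal switched
        freq = traj.records[-1].freqs
        if not switched:
            if freq.p1_mean < thr:
                return frozenset({1})
            switched = True
        if freq.p2_mean < thr:
            return frozenset({2})
        return None

    traj = _run(scenario, policy)
    t1 = time_to_resistance(traj, 1, thr)
    t2 = time_to_resistance(traj, 2, thr)
    total = t2 if (t1 is not None and t2 is not None) else None
    return StrategyResult("sequence", t1, t2, total, traj)


def run_mixture(scenario: Scenario) -> StrategyResult:
    """Both insecticides co-deployed until both loci have crossed."""
    thr = scenario.resistance_threshold
    both = frozenset({1, 2})

    def policy(traj: Trajectory):
        freq = traj.records[-1].freqs
        if freq.p1_mean >= thr and freq.p2_mean >= thr:
            return None
        return both

    traj = _run(scenario, policy)
    t1 = time_to_resistance(traj, 1, thr)
    t2 = time_to_resistance(traj, 2, thr)
    total = max(t1, t2) if (t1 is not None and t2 is not None) else None
    return StrategyResult("mixture", t1, t2, total, traj)


def round_ratio(ratio: float) -> float:
    """Round to one decimal, half away from zero (figure-annotation style)."""
    return float(Decimal(repr(ratio)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StrategyComparison:
    """Sequence vs mixture on one scenario, with the mixture/sequence ratio."""

    sequence: StrategyResult
    mixture: StrategyResult
    ratio: float | None = field(init=False)
    ratio_rounded: float | None = field(init=False)

    def __post_init__(self) -> None:
        seq_t, mix_t = self.sequence.total_time, self.mixture.total_time
        if seq_t is None or mix_t is None or seq_t == 0:
            ratio = rounded = None
        else:
            ratio = mix_t / seq_t
            rounded = round_ratio(ratio)
        object.__setattr__(self, "ratio", ratio)
        object.__setattr__(self, "ratio_rounded", rounded)

    def summary(self) -> dict[str, object]:
        return {
            "sequence_total": self.sequence.summary()["total_time"],
            "mixture_total": self.mixture.summary()["total_time"],
            "ratio": self.ratio if self.ratio is not None else NOT_REACHED,
            "ratio_rounded": (
                self.ratio_rounded if self.ratio_rounded is not None else NOT_REACHED
            ),
        }


def compare_strategies(scenario: Scenario) -> StrategyComparison:
    """Run sequence and mixture and report the mixture/sequence time ratio."""
    return StrategyComparison(run_sequence(scenario), run_mixture(scenario))
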