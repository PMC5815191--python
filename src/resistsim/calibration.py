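"""Derive model inputs from genotype-specific bioassay survival.

Field bioassays (e.g. experimental-hut trials) report numbers alive and dead
per genotype, in an insecticide-exposed arm and ideally an unexposed control
arm. Survival proportions stand in for fitness. After rescaling so that the
unexposed SS genotype has fitness 1, the model inputs follow directly from
the fitness construction:

    effectiveness          = 1 - w_SS            (exposed)
    resistance_restoration = (w_RR - w_SS) / effectiveness   (exposed)
    dominance_resistance   = (w_SR - w_SS) / (w_RR - w_SS)   (exposed)
    cost                   = 1 - w_RR            (unexposed)
    dominance_cost         = (w_SS - w_SR) / (w_SS - w_RR)   (unexposed)

Exposure and the starting resistance frequency are properties of the setting,
not of the assay, and are supplied by the caller.

Estimates outside [0, 1] are clamped with a warning rather than rejected:
assay noise routinely produces, e.g., an unexposed heterozygote surviving
worse than the resistant homozygote (apparent underdominance, biologically
implausible for unexposed genotypes), in which case the dominance is set to
1 so SR and RR share the same fitness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .params import InsecticideParams

GENOTYPE_ORDER = ("SS", "SR", "RR")


class CalibrationWarning(UserWarning):
    """A derived parameter was clamped into its legal range."""


class CalibrationError(ValueError):
    """The survival data cannot support the requested derivation."""


class SurvivalTriple(NamedTuple):
    """Survival proportion of each genotype in one assay arm."""

    ss: float
    sr: float
    rr: float


@dataclass(frozen=True)
class GenotypeSurvivalData:
    """Genotype-specific survival, exposed arm required, control arm optional."""

    exposed: SurvivalTriple
    unexposed: SurvivalTriple | None = None

    def __post_init__(self) -> None:
        for arm_name, arm in (("exposed", self.exposed), ("unexposed", self.unexposed)):
            if arm is None:
                continue
            for geno, value in zip(GENOTYPE_ORDER, arm):
                if not 0.0 <= value <= 1.0:
                    raise CalibrationError(
                        f"{arm_name} {geno} survival {value!r} is outside [0, 1]"
                    )


def survival_from_counts(alive: int, dead: int) -> float:
    """Survival proportion alive / (alive + dead)."""
    if alive < 0 or dead < 0:
        raise CalibrationError("counts must be non-negative")
    total = alive + dead
    if total == 0:
        raise CalibrationError("alive + dead must be positive")
    return alive / total


def rescale_survivals(data: GenotypeSurvivalData) -> GenotypeSurvivalData:
    """Express all survivals relative to the unexposed SS genotype.

    Every survival is divided by the unexposed SS survival so the reference
    genotype has fitness 1; quotients above 1 are capped at 1 with a warning.
    """
    if data.unexposed is None:
        raise CalibrationError(
            "no unexposed arm: rescaling needs the unexposed SS survival "
            "(assume a no-cost calibration instead)"
        )
    ref = data.unexposed.ss
    if ref <= 0.0:
        raise CalibrationError(
            "unexposed SS survival is zero: cannot rescale "
            "(assume a no-cost calibration instead)"
        )

    def scale(arm: SurvivalTriple) -> SurvivalTriple:
        out = []
        for geno, value in zip(GENOTYPE_ORDER, arm):
            scaled = value / ref
            if scaled > 1.0:
                warnings.warn(
                    f"rescaled {geno} survival {scaled:.3f} capped at 1",
                    CalibrationWarning,
                    stacklevel=3,
                )
                scaled = 1.0
            out.append(scaled)
        return SurvivalTriple(*out)

    return GenotypeSurvivalData(exposed=scale(data.exposed), unexposed=scale(data.unexposed))


def _clamped_dominance(num: float, den: float, label: str) -> float:
    if den == 0.0:
        warnings.warn(
            f"{label}: homozygote fitnesses are equal, dominance is undefined; using 0",
            CalibrationWarning,
            stacklevel=3,
        )
        return 0.0
    dom = num / den
    if not 0.0 <= dom <= 1.0:
        warnings.warn(
            f"{label} {dom:.3f} lies outside [0, 1] (underdominance is "
            "biologically implausible); set to 1 so SR matches RR",
            CalibrationWarning,
            stacklevel=3,
        )
        return 1.0
    return dom


def derive_insecticide_params(
    data: GenotypeSurvivalData,
    *,
    exposure_female: float = 0.5,
    exposure_male: float = 0.5,
    start_frequency: float = 0.01,
    rescale: bool = True,
) -> InsecticideParams:
    """Turn genotype survivals into a full set of model inputs.

    With no unexposed arm the cost of resistance and its dominance are taken
    as 0 and the exposed survivals are used as-is (unexposed SS assumed to
    survive fully). Exposure and starting frequency cannot be derived from a
    bioassay and must be supplied by the caller.
    """
    if data.unexposed is not None and rescale:
        data = rescale_survivals(data)

    ss_e, sr_e, rr_e = data.exposed
    effectiveness = 1.0 - ss_e
    if rr_e < ss_e:
        warnings.warn(
            f"exposed RR survival {rr_e:.3f} below SS {ss_e:.3f}: no resistance "
            "signal, restoration set to 0",
            CalibrationWarning,
            stacklevel=2,
        )
        restoration = 0.0
        dominance_res = 0.0
    else:
        if effectiveness == 0.0:
            warnings.warn(
                "exposed SS survival is 1 (zero effectiveness); restoration "
                "is undefined and set to 0",
                CalibrationWarning,
                stacklevel=2,
            )
            restoration = 0.0
        else:
            restoration = (rr_e - ss_e) / effectiveness
            if restoration > 1.0:
                warnings.warn(
                    f"restoration {restoration:.3f} above 1 capped at 1",
                    CalibrationWarning,
                    stacklevel=2,
                )
                restoration = 1.0
        dominance_res = _clamped_dominance(sr_e - ss_e, rr_e - ss_e, "dominance of resistance")

    if data.unexposed is None:
        cost = 0.0
        dominance_cost = 0.0
    else:
        ss_u, sr_u, rr_u = data.unexposed
        cost = max(0.0, 1.0 - rr_u)
        if cost == 0.0:
            dominance_cost = 0.0
        else:
            dominance_cost = _clamped_dominance(ss_u - sr_u, ss_u - rr_u, "dominance of cost")

    return InsecticideParams(
        effectiveness=effectiveness,
        exposure_female=exposure_female,
        exposure_male=exposure_male,
        resistance_restoration=restoration,
        dominance_resistance=dominance_res,
        start_frequency=start_frequency,
        cost=cost,
        dominance_cost=dominance_cost,
    )


def read_bioassay_csv(path: str | Path) -> GenotypeSurvivalData:
    """Load genotype survival data from CSV.

    Expected columns: ``genotype`` (SS|SR|RR), ``arm`` (exposed|unexposed)
    and either integer ``alive``/``dead`` counts or a ``survival`` proportion.
    The unexposed arm may be absent.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"genotype", "arm"}
    if not required <= set(df.columns):
        raise CalibrationError(f"CSV must have columns {sorted(required)}; got {list(df.columns)}")
    has_counts = {"alive", "dead"} <= set(df.columns)
    if not has_counts and "survival" not in df.columns:
        raise CalibrationError("CSV needs either alive/dead counts or a survival column")

    arms: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        geno = str(row["genotype"]).strip().upper()
        arm = str(row["arm"]).strip().lower()
        if geno not in GENOTYPE_ORDER:
            raise CalibrationError(f"unknown genotype {geno!r}")
        if arm not in ("exposed", "unexposed"):
            raise CalibrationError(f"unknown arm {arm!r}")
        if has_counts and not pd.isna(row.get("alive")):
            surv = survival_from_counts(int(row["alive"]), int(row["dead"]))
        else:
            surv = float(row["survival"])
        arms.setdefault(arm, {})[geno] = surv

    if "exposed" not in arms or set(arms["exposed"]) != set(GENOTYPE_ORDER):
        raise CalibrationError("exposed arm must cover all of SS, SR, RR")
    exposed = SurvivalTriple(**{k.lower(): v for k, v in arms["exposed"].items()})
    unexposed = None
    if "unexposed" in arms:
        if set(arms["unexposed"]) != set(GENOTYPE_ORDER):
            raise CalibrationError("unexposed arm, when present, must cover SS, SR, RR")
        unexposed = SurvivalTriple(**{k.lower(): v for k, v in arms["unexposed"].items()})
    return GenotypeSurvivalData(exposed=exposed, unexposed=unexposed)


def format_report(params: InsecticideParams, notes: list[str] | None = None) -> str:
    """Human-readable two-decimal summary of derived parameters."""
    lines = ["Derived model inputs (displayed to 2 decimals):"]
    for name in (
        "effectiveness",
        "resistance_restoration",
        "dominance_resistance",
        "cost",
        "dominance_cost",
    ):
        lines.append(f"  {name:24s} {getattr(params, name):.2f}")
    lines.append(f"  {'exposure_female':24s} {params.exposure_female:.2f} (user-supplied)")
    lines.append(f"  {'exposure_male':24s} {params.exposure_male:.2f} (user-supplied)")
    lines.append(f"  {'start_frequency':24s} {params.start_frequency:.3g} (user-supplied)")
    for note in notes or []:
        lines.append(f"  warning: {note}")
    return "\n".join(lines)
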