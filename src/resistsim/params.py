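"""Per-insecticide model inputs and their validation.

Seven quantities describe how one insecticide interacts with the resistance
allele at its locus:

* ``effectiveness`` — proportion of fully susceptible (SS) insects killed on
  exposure.
* ``exposure_female`` / ``exposure_male`` — proportion of each sex that
  contacts the deployed insecticide(s) in a generation.
* ``resistance_restoration`` — fraction of the insecticide-induced fitness
  loss that the RR genotype regains when exposed.
* ``dominance_resistance`` — position of the SR fitness between SS and RR
  when exposed (0 = recessive, 1 = dominant).
* ``start_frequency`` — initial frequency of the resistance allele.
* ``cost`` — fitness reduction of RR in the absence of the insecticide.
* ``dominance_cost`` — position of the SR fitness between SS and RR when
  unexposed.

All are proportions on [0, 1]; the start frequency must be strictly inside
(0, 1) so that both alleles are segregating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


class ParameterError(ValueError):
    """An insecticide or scenario parameter is outside its legal range."""


def _check_proportion(name: str, value: float, *, open_interval: bool = False) -> None:
    lo_ok = value > 0.0 if open_interval else value >= 0.0
    hi_ok = value < 1.0 if open_interval else value <= 1.0
    if not (lo_ok and hi_ok):
        interval = "(0, 1)" if open_interval else "[0, 1]"
        raise ParameterError(f"{name}={value!r} is outside the interval {interval}")


@dataclass(frozen=True)
class InsecticideParams:
    """The seven model inputs for one insecticide and its resistance locus."""

    effectiveness: float = 0.5
    exposure_female: float = 0.5
    exposure_male: float = 0.5
    resistance_restoration: float = 0.5
    dominance_resistance: float = 0.5
    start_frequency: float = 0.01
    cost: float = 0.0
    dominance_cost: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ParameterError(f"{f.name}={value!r} is not a number")
            _check_proportion(
                f.name, float(value), open_interval=(f.name == "start_frequency")
            )

    def exposure(self, sex: str) -> float:
        """Sex-specific exposure, ``sex`` being ``"female"`` or ``"male"``."""
        if sex == "female":
            return self.exposure_female
        if sex == "male":
            return self.exposure_male
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")

    def with_(self, **changes: float) -> "InsecticideParams":
        """Return a copy with the given fields replaced (validated again)."""
        return replace(self, **changes)
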