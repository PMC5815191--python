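"""Trajectory serialisation.

Trajectories are written as plain CSV with one row per census generation and
a stable header::

    generation, deployment, freq_locus1_female, freq_locus1_male,
    freq_locus1_mean, freq_locus2_female, freq_locus2_male,
    freq_locus2_mean, D, Dprime

Frequencies are written at full double precision so a read/write round trip
is lossless to 1e-12.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulator import Trajectory

TRAJECTORY_COLUMNS = [
    "generation",
    "deployment",
    "freq_locus1_female",
    "freq_locus1_male",
    "freq_locus1_mean",
    "freq_locus2_female",
    "freq_locus2_male",
    "freq_locus2_mean",
    "D",
    "Dprime",
]


def write_trajectory(trajectory: Trajectory, destination: str | Path) -> Path:
    """Write one row per generation; returns the path written."""
    destination = Path(destination)
    frame = trajectory.to_frame()
    frame = frame[TRAJECTORY_COLUMNS]
    frame.to_csv(destination, index=False, float_format="%.17g")
    return destination


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back, validating the schema."""
    frame = pd.read_csv(path)
    if list(frame.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(
            f"{path} is not a trajectory file: columns {list(frame.columns)}"
        )
    if not frame["generation"].is_monotonic_increasing:
        raise ValueError(f"{path}: generation indices are not increasing")
    return frame
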