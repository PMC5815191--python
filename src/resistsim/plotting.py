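"""Optional matplotlib views of trajectories and strategy comparisons.

Plot styling follows the figure convention of the literature this model
belongs to: solid lines for mixture deployment, dashed for sequence, one
colour per insecticide. Plotting never feeds back into any computed result.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .simulator import Trajectory
from .strategies import StrategyComparison, StrategyResult

_COLORS = {1: "tab:red", 2: "tab:blue"}


def _series(trajectory: Trajectory, locus: int) -> tuple[list[int], list[float]]:
    gens = [r.generation for r in trajectory]
    freqs = [r.freqs.p1_mean if locus == 1 else r.freqs.p2_mean for r in trajectory]
    return gens, freqs


def plot_result(result: StrategyResult, destination: str | Path, threshold: float = 0.5) -> Path:
    """Resistance-frequency curves for one strategy run."""
    fig, ax = plt.subplots(figsize=(6, 4))
    style = "-" if result.strategy_label == "mixture" else "--"
    for locus in (1, 2):
        gens, freqs = _series(result.trajectory, locus)
        ax.plot(gens, freqs, style, color=_COLORS[locus], label=f"insecticide {locus}")
    _finish(ax, threshold, f"strategy: {result.strategy_label}")
    return _save(fig, destination)


def plot_comparison(
    comparison: StrategyComparison, destination: str | Path, threshold: float = 0.5
) -> Path:
    """Mixture (solid) vs sequence (dashed) resistance curves."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for locus in (1, 2):
        gens, freqs = _series(comparison.mixture.trajectory, locus)
        ax.plot(gens, freqs, "-", color=_COLORS[locus], label=f"insecticide {locus} (mixture)")
        gens, freqs = _series(comparison.sequence.trajectory, locus)
        ax.plot(gens, freqs, "--", color=_COLORS[locus], label=f"insecticide {locus} (sequence)")
    ratio = comparison.ratio_rounded
    title = "mixture vs sequence" + (f" (mix/seq = {ratio})" if ratio is not None else "")
    _finish(ax, threshold, title)
    return _save(fig, destination)


def _finish(ax: plt.Axes, threshold: float, title: str) -> None:
    ax.axhline(threshold, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("generation")
    ax.set_ylabel("resistance allele frequency")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)


def _save(fig: plt.Figure, destination: str | Path) -> Path:
    destination = Path(destination)
    fig.tight_layout()
    fig.savefig(destination, dpi=150)
    plt.close(fig)
    return destination
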