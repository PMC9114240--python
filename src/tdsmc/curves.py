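"""TDS dominance-rate curves on standardized time.

Because panelists finish tasting at different times, raw clocks are not
comparable across the panel.  Each sequence is therefore mapped onto a
standardized time axis t in [0, 1]: at time t, panelist i's dominant
attribute is the one observed at second ``min(L_i, floor(t * L_i) + 1)``
of their own record (1-based, right-continuous).  The dominance rate of
attribute j at t is the fraction of panelists dominated by j there, so the
J rates sum to one at every grid point.

The chance level is 1/J (dominance by pure guessing among J attributes)
and the significance limit is the one-sided normal approximation to the
binomial, ``P0 + z_{1-alpha} * sqrt(P0 (1 - P0) / n)``, the conventional
threshold drawn on TDS curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import AttributeScheme, TDSDataError, TDSSequence

__all__ = [
    "CurveSet",
    "dominance_curves",
    "significance_limit",
    "chance_level",
    "significant_bands",
    "plot_curves",
]


def chance_level(n_attributes: int) -> float:
    """Baseline dominance rate 1/J under uniform guessing."""
    if n_attributes < 1:
        raise ValueError("need at least one attribute")
    return 1.0 / n_attributes


def significance_limit(n: int, n_attributes: int, alpha: float = 0.05) -> float:
    """One-sided upper confidence limit on the chance dominance rate.

    ``P0 + z_{1-alpha} sqrt(P0 (1 - P0) / n)`` with ``P0 = 1/J``; rates above
    this line are unlikely (at level alpha) under attribute-blind clicking.
    """
    if n < 1:
        raise ValueError("panel size must be >= 1")
    if n_attributes < 2:
        raise ValueError("need at least two attributes")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p0 = chance_level(n_attributes)
    z = stats.norm.ppf(1.0 - alpha)
    return float(p0 + z * np.sqrt(p0 * (1.0 - p0) / n))


@dataclass
class CurveSet:
    """Dominance rates on a standardized-time grid.

    ``rates`` is J x T; column sums are 1 at every grid point.
    """

    grid: np.ndarray
    rates: np.ndarray
    chance_level: float
    significance_limit: float
    n_panelists: int
    labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.rates.T, columns=list(self.labels))
        frame.insert(0, "time", self.grid)
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def dominance_curves(
    sequences: Sequence[TDSSequence],
    scheme: AttributeScheme,
    grid_size: int = 101,
    alpha: float = 0.05,
    smooth_window: int | None = None,
) -> CurveSet:
    """Compute the panel's dominance-rate curves on standardized time.

    ``smooth_window`` applies a centered moving average of that many grid
    points to each attribute's curve (edges use the available window);
    rates still sum to one per grid point.  Default is no smoothing.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if not sequences:
        raise TDSDataError("no sequences given")
    grid = np.linspace(0.0, 1.0, grid_size)
    J = scheme.n_attributes
    counts = np.zeros((J, grid_size), dtype=float)
    for seq in sequences:
        states = seq.states()
        L = seq.length
        # 1-based second floor(t*L)+1, clamped to L  ->  0-based index
        idx = np.minimum(L - 1, np.floor(grid * L).astype(int))
        for t, j in enumerate(states[idx]):
            counts[j, t] += 1.0
    rates = counts / len(sequences)
    if smooth_window is not None and smooth_window > 1:
        rates = (
            pd.DataFrame(rates.T)
            .rolling(smooth_window, center=True, min_periods=1)
            .mean()
            .to_numpy()
            .T
        )
    return CurveSet(
        grid=grid,
        rates=rates,
        chance_level=chance_level(J),
        significance_limit=significance_limit(len(sequences), J, alpha) if J >= 2 else 1.0,
        n_panelists=len(sequences),
        labels=scheme.labels,
    )


def significant_bands(curves: CurveSet) -> dict[str, list[tuple[float, float]]]:
    """Maximal standardized-time intervals where each rate strictly exceeds the limit."""
    bands: dict[str, list[tuple[float, float]]] = {}
    for j, label in enumerate(curves.labels):
        above = curves.rates[j] > curves.significance_limit
        intervals: list[tuple[float, float]] = []
        start = None
        for t, flag in enumerate(above):
            if flag and start is None:
                start = t
            elif not flag and start is not None:
                intervals.append((float(curves.grid[start]), float(curves.grid[t - 1])))
                start = None
        if start is not None:
            intervals.append((float(curves.grid[start]), float(curves.grid[-1])))
        bands[label] = intervals
    return bands


def plot_curves(curves: CurveSet, path: str | Path) -> None:
    """Render the curves with chance and significance lines to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for j, label in enumerate(curves.labels):
        ax.plot(curves.grid, curves.rates[j], label=label, lw=1.2)
    ax.axhline(curves.chance_level, color="grey", lw=0.8, ls="-", label="chance")
    ax.axhline(
        curves.significance_limit, color="black", lw=0.8, ls=":", label="significance (5%)"
    )
    bands = significant_bands(curves)
    y = 1.02
    for label, intervals in bands.items():
        for lo, hi in intervals:
            ax.plot([lo, hi], [y, y], lw=3, solid_capstyle="butt")
        if intervals:
            y += 0.03
    ax.set_xlabel("standardized time")
    ax.set_ylabel("dominance rate")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, max(1.0, y) + 0.02)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
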