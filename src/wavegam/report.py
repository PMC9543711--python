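"""Results-layer computations on a fitted wave model.

Spatio-temporal prediction fields (the data behind animation frames),
conditional-contribution curves, the cumulative wave-front speed rule
(southernmost location with predicted growth above a threshold, tracked
between two times) and speed-unit conversions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import FittedWaveModel
from .waves import build_design

__all__ = [
    "PredictionField",
    "predict_field",
    "front_speed",
    "convert_speed",
    "contribution_table",
    "plot_field",
]

DAYS_PER_YEAR = 365.25


@dataclass
class PredictionField:
    """Predicted growth rates on a regular spatial grid at one time."""

    x: np.ndarray  # grid x coordinates (metres, mean-centred), shape (nx,)
    y: np.ndarray  # grid y coordinates, shape (ny,)
    time: float  # days since study start
    r: np.ndarray  # predictions, shape (ny, nx); NaN where masked
    label: str

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"X": xx.ravel(), "Y": yy.ravel(),
                             "t": self.time, "r": self.r.ravel()})


def predict_field(model: FittedWaveModel, time: float,
                  extent: tuple[float, float, float, float],
                  resolution: float = 2000.0,
                  data_extent: tuple[float, float, float, float] | None = None,
                  margin: float = 0.1) -> PredictionField:
    """Evaluate the fitted growth surface on a regular grid at one time.

    ``extent`` is ``(xmin, xmax, ymin, ymax)`` in mean-centred metres;
    the default cell size is 2 km.  If ``data_extent`` is given, cells
    outside it (plus a fractional ``margin``) are masked NaN with a warning
    — the smooths are not trusted under extrapolation.
    """
    xmin, xmax, ymin, ymax = extent
    gx = np.arange(xmin, xmax + resolution / 2, resolution)
    gy = np.arange(ymin, ymax + resolution / 2, resolution)
    xx, yy = np.meshgrid(gx, gy)
    T = np.full(xx.size, float(time))
    Z, specs = build_design(model.label, model.params, T, xx.ravel(), yy.ravel(),
                            river_y=model.river_y)
    masks = [s.rows for s in specs]
    pred = model.gam.predict(Z, smooth_rows=masks).reshape(xx.shape)
    if data_extent is not None:
        dxmin, dxmax, dymin, dymax = data_extent
        mx = margin * (dxmax - dxmin)
        my = margin * (dymax - dymin)
        outside = ((xx < dxmin - mx) | (xx > dxmax + mx)
                   | (yy < dymin - my) | (yy > dymax + my))
        if outside.any():
            warnings.warn(
                f"masking {int(outside.sum())} grid cells beyond the data "
                "extent margin", stacklevel=2)
            pred = np.where(outside, np.nan, pred)
    return PredictionField(gx, gy, float(time), pred, model.label)


def front_speed(field0: PredictionField, field1: PredictionField,
                threshold: float = 0.5) -> dict:
    """Cumulative wave-front speed from two prediction snapshots.

    The front is the *southernmost* grid cell whose predicted growth rate
    exceeds ``threshold`` (ties broken by smallest x); its displacement
    between the two times divided by the elapsed time gives the speed.
    Returns a dict with km/day and km/year plus the two front locations.
    """
    if field1.time == field0.time:
        raise ValueError("the two fields must be at different times")

    def southernmost(f: PredictionField):
        above = np.argwhere(np.nan_to_num(f.r, nan=-np.inf) > threshold)
        if above.size == 0:
            raise ValueError(
                f"no cell exceeds threshold {threshold} at t={f.time} "
                f"(max prediction {np.nanmax(f.r):.3f})")
        ys = f.y[above[:, 0]]
        ymin = ys.min()
        at_ymin = above[ys == ymin]
        xs = f.x[at_ymin[:, 1]]
        return float(xs.min()), float(ymin)

    p0, p1 = southernmost(field0), southernmost(field1)
    dist_km = np.hypot(p1[0] - p0[0], p1[1] - p0[1]) / 1000.0
    dt = abs(field1.time - field0.time)
    return {
        "km_per_day": dist_km / dt,
        "km_per_year": dist_km / dt * DAYS_PER_YEAR,
        "front0": p0,
        "front1": p1,
        "threshold": threshold,
    }


def convert_speed(zeta: float, round_to_int: bool = False) -> float:
    """Convert a wave speed from metres/day to km/year (365.25-day year)."""
    if zeta <= 0:
        raise ValueError("zeta must be > 0")
    out = zeta * DAYS_PER_YEAR / 1000.0
    return float(round(out)) if round_to_int else float(out)


def contribution_table(model: FittedWaveModel, smooth_index: int,
                       grid: np.ndarray) -> pd.DataFrame:
    """Conditional-contribution curve of one smooth as a tidy table.

    Columns ``grid, estimate, lower, upper``: the smooth's contribution
    including the intercept, with the pointwise 95% band — the data behind
    a conditional-prediction figure.
    """
    est, lo, hi = model.gam.contribution(smooth_index, grid)
    return pd.DataFrame({"grid": np.asarray(grid, float).ravel(),
                         "estimate": est, "lower": lo, "upper": hi})


def plot_field(field: PredictionField, path=None, ax=None):
    """Render one prediction field as an image (an animation frame)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4.5))
    else:
        fig = ax.figure
    im = ax.pcolormesh(field.x / 1000.0, field.y / 1000.0, field.r,
                       shading="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="growth rate r (per quarter)")
    ax.set_xlabel("X (km)")
    ax.set_ylabel("Y (km)")
    ax.set_title(f"{field.label}: predicted growth at day {field.time:.0f}")
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return ax
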