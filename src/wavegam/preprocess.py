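"""Aggregate raw transect surveys into centroid-level quarterly growth rates.

Surveys are clustered by a greedy radius cover (each still-unassigned survey
in input order becomes a new centroid reference; everything unassigned
within 5 km joins it), aggregated per centroid x quarter by arithmetic
means, and converted to log-difference growth rates between consecutive
quarters with weights ``w = n_t * n_{t+1} / (n_t + n_{t+1})`` that reflect
observation variance proportional to 1/n under varying monitoring effort.
A constant offset (default 3.03, the smallest non-zero index) is added
before taking logs to tolerate zero indices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import INDEX_OFFSET, QUARTER_DAYS

__all__ = [
    "assign_centroids",
    "aggregate",
    "compute_growth",
    "surveys_to_growth",
]


def assign_centroids(surveys: pd.DataFrame, radius: float = 5000.0,
                     order: np.ndarray | None = None) -> np.ndarray:
    """Greedy radius cover: map each survey to a centroid id.

    Surveys are scanned in input-row order (or the explicit ``order``
    permutation); each unassigned survey becomes the reference point of the
    next centroid and captures every unassigned survey within ``radius``
    metres (boundary inclusive, Euclidean).  Returns an integer centroid id
    per row.  Reference points of distinct centroids are therefore always
    more than ``radius`` apart.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    n = len(surveys)
    if n == 0:
        raise ValueError("no surveys")
    x = surveys["x"].to_numpy(float)
    y = surveys["y"].to_numpy(float)
    if order is None:
        order = np.arange(n)
    else:
        order = np.asarray(order, int)
    assigned = np.full(n, -1, int)
    cid = 0
    for i in order:
        if assigned[i] >= 0:
            continue
        free = assigned < 0
        d2 = (x - x[i]) ** 2 + (y - y[i]) ** 2
        members = free & (d2 <= radius * radius)
        assigned[members] = cid
        cid += 1
    return assigned


def aggregate(surveys: pd.DataFrame, assignment: np.ndarray,
              quarter_length: float = QUARTER_DAYS,
              mean_center: bool = True) -> pd.DataFrame:
    """One row per (centroid, quarter): means of day, coordinates and index.

    Columns: ``centroid, quarter, T, x, y, N, n``.  ``T`` is the mean day
    since study start, ``N`` the mean index, ``n`` the member-survey count.
    Coordinates are mean-centred over the aggregated dataset (the centring
    constants are attached as ``DataFrame.attrs['x_center'/'y_center']`` so
    estimated epicentres can be mapped back to original coordinates).
    Quarters with no surveys simply produce no row — no interpolation.
    """
    df = surveys.copy()
    df["centroid"] = np.asarray(assignment, int)
    df["quarter"] = (df["day"].to_numpy(float) // quarter_length).astype(int)
    cells = (
        df.groupby(["centroid", "quarter"], sort=True)
        .agg(T=("day", "mean"), x=("x", "mean"), y=("y", "mean"),
             N=("index", "mean"), n=("index", "size"))
        .reset_index()
    )
    x_center = y_center = 0.0
    if mean_center:
        x_center = float(cells["x"].mean())
        y_center = float(cells["y"].mean())
        cells["x"] = cells["x"] - x_center
        cells["y"] = cells["y"] - y_center
    cells.attrs["x_center"] = x_center
    cells.attrs["y_center"] = y_center
    return cells


def compute_growth(cells: pd.DataFrame, offset: float = INDEX_OFFSET,
                   time_anchor: str = "start") -> pd.DataFrame:
    """Log-difference growth rates between consecutive quarters per centroid.

    For every centroid with cells in quarters ``t`` and ``t+1``:
    ``r = ln(N_{t+1} + offset) - ln(N_t + offset)`` with weight
    ``w = n_t * n_{t+1} / (n_t + n_{t+1})``.  The observation's coordinates
    are the mean of the two cells' (already mean-centred) coordinates; its
    time ``T`` is the first quarter's mean day (``time_anchor="start"``,
    the convention that indexes r_t by its starting quarter) or the midpoint
    of the two (``"mid"``).  Non-consecutive quarters yield no observation.

    Returns columns ``centroid, quarter, r, T, X, Y, w, n_t, n_prev``.
    """
    if offset <= 0:
        raise ValueError("offset must be > 0")
    if time_anchor not in ("start", "mid"):
        raise ValueError("time_anchor must be 'start' or 'mid'")
    c = cells.sort_values(["centroid", "quarter"]).reset_index(drop=True)
    nxt = c.shift(-1)
    ok = (nxt["centroid"] == c["centroid"]) & (nxt["quarter"] == c["quarter"] + 1)
    a = c[ok.fillna(False)]
    b = nxt[ok.fillna(False)]
    r = np.log(b["N"].to_numpy(float) + offset) - np.log(a["N"].to_numpy(float) + offset)
    n_t = a["n"].to_numpy(float)
    n_next = b["n"].to_numpy(float)
    w = n_t * n_next / (n_t + n_next)
    T = a["T"].to_numpy(float) if time_anchor == "start" else \
        0.5 * (a["T"].to_numpy(float) + b["T"].to_numpy(float))
    out = pd.DataFrame({
        "centroid": a["centroid"].to_numpy(int),
        "quarter": a["quarter"].to_numpy(int),
        "r": r,
        "T": T,
        "X": 0.5 * (a["x"].to_numpy(float) + b["x"].to_numpy(float)),
        "Y": 0.5 * (a["y"].to_numpy(float) + b["y"].to_numpy(float)),
        "w": w,
        "n_t": n_t.astype(int),
        "n_prev": n_next.astype(int),
    })
    out.attrs.update(cells.attrs)
    return out


def surveys_to_growth(surveys: pd.DataFrame, radius: float = 5000.0,
                      quarter_length: float = QUARTER_DAYS,
                      offset: float = INDEX_OFFSET,
                      time_anchor: str = "start") -> pd.DataFrame:
    """Full pipeline: surveys -> centroids -> cells -> growth observations."""
    assignment = assign_centroids(surveys, radius=radius)
    cells = aggregate(surveys, assignment, quarter_length=quarter_length)
    return compute_growth(cells, offset=offset, time_anchor=time_anchor)
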