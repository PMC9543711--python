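"""Synthetic survey generator over a known travelling-wave growth field.

Emulates the statistical structure the downstream analysis assumes: a
vole-like multi-annual cycle whose quarterly log-growth rate is a smooth
periodic function of space-modified time, observed through transect surveys
that report an activity index on a 0-100 scale (per cent of 33 transect
sections showing signs of presence).  Supports a uniform random survey
design and an adaptive one in which a core area is monitored intensively
while the periphery is mainly surveyed when local growth is exceptionally
high.

The generator works in *growth-rate space*: the noise-free field
``r(x, y, t) = alpha1 + sum_w amplitude * shape(2 pi rho_w / period)`` is a
sum of wave contributions (``rho_w`` the wave's space-modified time), and
abundance indices are obtained by exponentiating the field's running
integral so that quarterly log-differences of ``index + offset`` recover
the field.  Defaults describe a 3-year cycle with growth-rate amplitude
1.5 per quarter — strong, vole-realistic cyclicity in which indices range
over more than two orders of magnitude and are clipped at the 0 and 100
boundaries at cycle extremes, as real proportion-of-sections indices are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .waves import planar_distance, radial_distance, space_modified_time

__all__ = [
    "Wave",
    "WaveFieldSpec",
    "SamplingDesign",
    "evaluate_growth_field",
    "integrated_growth",
    "simulate_index_series",
    "noise_free_index",
    "generate_surveys",
    "write_surveys",
    "read_surveys",
]

#: days per quarter used by the whole package (calendar quarters only at I/O)
QUARTER_DAYS = 91.0

#: offset added to indices before taking logs: the smallest non-zero value of
#: a proportion-of-33-sections index on the 0-100 scale, 100/33
INDEX_OFFSET = 3.03


def _sinusoid(phase: np.ndarray) -> np.ndarray:
    return np.sin(phase)


@dataclass
class Wave:
    """One travelling-wave component of the growth field.

    form
        "planar" (direction ``theta``), "radial-expanding" or
        "radial-contracting" (epicentre ``gamma, psi``).
    zeta
        wave speed, metres/day (> 0).
    amplitude
        growth-rate amplitude of this wave's contribution (per quarter).
    shape
        periodic function of phase (radians); defaults to a sinusoid.  The
        fitted smooth is free-form, so the generator accepts any callable.
    """

    form: Literal["planar", "radial-expanding", "radial-contracting"]
    zeta: float
    theta: float | None = None
    gamma: float | None = None
    psi: float | None = None
    amplitude: float = 1.5
    shape: Callable[[np.ndarray], np.ndarray] = _sinusoid
    phase0: float = 0.0  # phase offset (radians) at rho = 0

    def __post_init__(self):
        if self.zeta <= 0:
            raise ValueError("zeta must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.form == "planar":
            if self.theta is None:
                raise ValueError("planar wave needs theta")
        elif self.form in ("radial-expanding", "radial-contracting"):
            if self.gamma is None or self.psi is None:
                raise ValueError("radial wave needs gamma and psi")
        else:
            raise ValueError(f"unknown wave form {self.form!r}")

    def rho(self, x, y, day):
        if self.form == "planar":
            D = planar_distance(x, y, self.theta)
        else:
            D = radial_distance(
                x, y, self.gamma, self.psi,
                expanding=(self.form == "radial-expanding"),
            )
        return space_modified_time(day, D, self.zeta)


@dataclass
class WaveFieldSpec:
    """A noise-free growth field plus its residual-error scale.

    ``alpha1`` is the intercept (mean quarterly growth rate), ``period`` the
    cycle length in days, ``sigma`` the residual SD of per-survey indices
    (index units, 0-100 scale), ``extent`` the study rectangle in metres
    ``(xmin, xmax, ymin, ymax)`` and ``duration`` the study length in days.
    """

    waves: list[Wave] = dc_field(default_factory=list)
    alpha1: float = 0.0
    period: float = 3.0 * 365.0  # 3-year vole cycle
    sigma: float = 0.3  # residual sd of growth rates via index noise
    extent: tuple[float, float, float, float] = (0.0, 200_000.0, 0.0, 150_000.0)
    duration: float = 6 * 365.0  # a six-year study: two full 3-year cycles
    baseline_index: float = 7.0  # index at the geometric mid-level of the cycle

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        xmin, xmax, ymin, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent rectangle is degenerate")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class SamplingDesign:
    """Where and when surveys happen.

    mode "uniform": locations uniform over the extent each quarter.
    mode "adaptive": with probability ``core_fraction`` a survey falls in
    the ``core_region``; peripheral candidate locations are kept only with
    probability ``peripheral_keep`` unless the local noise-free growth rate
    exceeds ``peripheral_trigger``.
    """

    mode: Literal["uniform", "adaptive"] = "uniform"
    n_surveys_per_quarter: int = 400
    core_region: tuple[float, float, float, float] | None = None
    core_fraction: float = 0.75
    peripheral_trigger: float = 0.75
    peripheral_keep: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_surveys_per_quarter < 1:
            raise ValueError("n_surveys_per_quarter must be >= 1")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")
        if self.mode == "adaptive" and self.core_region is None:
            raise ValueError("adaptive design needs a core_region")


def evaluate_growth_field(spec: WaveFieldSpec, x, y, day):
    """Noise-free quarterly growth rate at (x, y, day).

    ``alpha1 + sum_w amplitude_w * shape_w(2 pi rho_w / period + phase0_w)``;
    deterministic, no residual error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    day = np.asarray(day, float)
    out = np.broadcast_arrays(x, y, day)[0] * 0.0 + spec.alpha1
    for w in spec.waves:
        phase = 2.0 * np.pi * w.rho(x, y, day) / spec.period + w.phase0
        out = out + w.amplitude * w.shape(phase)
    return out


def integrated_growth(spec: WaveFieldSpec, x, y, day0: float, day1: float,
                      n_nodes: int = 16):
    """Integral of the growth field over [day0, day1], in quarter units.

    Gauss-Legendre quadrature; exact to machine precision for smooth shapes
    at the default node count.  Dividing by QUARTER_DAYS expresses the
    integral on the same per-quarter scale as the field itself.
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    mid, half = 0.5 * (day0 + day1), 0.5 * (day1 - day0)
    total = 0.0
    for t, wt in zip(mid + half * nodes, weights):
        total = total + wt * evaluate_growth_field(spec, x, y, t)
    return total * half / QUARTER_DAYS


def _index_from_log(logN):
    """Map log(index + offset) back to the clipped 0-100 index scale."""
    idx = np.exp(logN) - INDEX_OFFSET
    clipped_low = idx < 0.0
    clipped_high = idx > 100.0
    return np.clip(idx, 0.0, 100.0), clipped_low | clipped_high


def simulate_index_series(spec: WaveFieldSpec, x: float, y: float,
                          days: Sequence[float], baseline: float | None = None):
    """Noise-free abundance-index series at one location.

    Starting from ``baseline`` at ``days[0]``, each step multiplies
    ``index + offset`` by ``exp`` of the field's integrated growth over the
    interval (scaled to the quarterly step), then clips to the 0-100 index
    scale.  Clipping is reported with a warning because it makes observed
    log-differences saturate at cycle extremes.
    """
    days = np.asarray(days, float)
    if days.ndim != 1 or days.size < 1 or np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if baseline is None:
        baseline = spec.baseline_index
    out = np.empty(days.size)
    out[0] = np.clip(baseline, 0.0, 100.0)
    any_clip = False
    logN = np.log(out[0] + INDEX_OFFSET)
    for k in range(days.size - 1):
        g = float(integrated_growth(spec, x, y, days[k], days[k + 1]))
        logN = np.log(out[k] + INDEX_OFFSET) + g
        out[k + 1], clipped = _index_from_log(logN)
        any_clip = any_clip or bool(np.any(clipped))
    if any_clip:
        warnings.warn("index series clipped at the 0-100 boundary", stacklevel=2)
    return out


def _shape_antiderivative(wave: Wave, period: float, rho) -> np.ndarray:
    """``amplitude * int_0^rho shape(2 pi u / period + phase0) du``.

    Composite Gauss-Legendre over period/24 chunks plus a per-point
    remainder: exact to machine precision for smooth periodic shapes, for
    arbitrary (including negative) ``rho``.
    """
    rho = np.asarray(rho, float)
    h = period / 24.0
    nodes, wts = np.polynomial.legendre.leggauss(8)
    lo = min(0.0, float(rho.min()))
    hi = max(0.0, float(rho.max()))
    k_lo = int(np.floor(lo / h))
    k_hi = int(np.ceil(hi / h)) + 1
    edges = np.arange(k_lo, k_hi + 1) * h
    mids = 0.5 * (edges[:-1] + edges[1:])
    vals = wave.shape(2.0 * np.pi * (mids[:, None] + 0.5 * h * nodes[None, :])
                      / period + wave.phase0)
    chunk = (vals @ wts) * (0.5 * h)
    F_edges = np.concatenate([[0.0], np.cumsum(chunk)])
    F_edges = F_edges - F_edges[-k_lo]  # anchor F(0) = 0
    m = np.floor(rho / h).astype(int)
    a = m * h
    halfr = 0.5 * (rho - a)
    pts = a[..., None] + halfr[..., None] * (nodes + 1.0)
    rem = (wave.shape(2.0 * np.pi * pts / period + wave.phase0) @ wts) * halfr
    return wave.amplitude * (F_edges[m - k_lo] + rem)


def noise_free_index(spec: WaveFieldSpec, x, y, day):
    """Noise-free index at arbitrary points, phase-consistent with the wave.

    Log-abundance is the exact running integral of the growth field along
    the wave: ``log(index + offset) = log(baseline + offset) +
    (alpha1 * day + sum_w F_w(rho_w)) / QUARTER_DAYS`` where ``F_w`` is the
    antiderivative of the wave's shape (anchored at ``F_w(0) = 0``), then
    clipped to the 0-100 scale.  At day 0 different locations therefore sit
    at different cycle phases, as an established travelling wave demands,
    and quarterly log-differences of ``index + offset`` recover the field's
    integrated growth exactly wherever no clipping occurs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    day = np.asarray(day, float)
    shape = np.broadcast(x, y, day).shape
    G = np.broadcast_to(spec.alpha1 * day, shape).astype(float).copy()
    for w in spec.waves:
        rho = np.broadcast_to(w.rho(x, y, day), shape)
        G += _shape_antiderivative(w, spec.period, rho)
    logN = np.log(spec.baseline_index + INDEX_OFFSET) + G / QUARTER_DAYS
    idx, _ = _index_from_log(logN)
    return idx


def generate_surveys(spec: WaveFieldSpec, design: SamplingDesign,
                     sigma_obs: float | None = None,
                     quarter_days: float = QUARTER_DAYS) -> pd.DataFrame:
    """Draw a transect-survey table from the field under a sampling design.

    Returns a DataFrame with columns ``id, day, x, y, index, n_sections``.
    Reproducible under the design's seed.  Per-survey observation noise is
    Normal with SD ``sigma_obs`` (defaults to ``spec.sigma`` scaled to index
    units via the local index level) added to the noise-free index, then
    clipped to [0, 100].
    """
    n_quarters = int(np.floor(spec.duration / quarter_days))
    if n_quarters < 2:
        raise ValueError("duration must cover at least two quarters")
    rng = np.random.default_rng(design.seed)
    xmin, xmax, ymin, ymax = spec.extent
    rows = []
    sid = 0
    for q in range(n_quarters):
        # days jittered inside the quarter, never on a boundary
        lo, hi = q * quarter_days + 1.0, (q + 1) * quarter_days - 1.0
        n_target = design.n_surveys_per_quarter
        pts = []
        if design.mode == "uniform":
            xs = rng.uniform(xmin, xmax, n_target)
            ys = rng.uniform(ymin, ymax, n_target)
            ds = rng.uniform(lo, hi, n_target)
            pts = list(zip(xs, ys, ds))
        else:
            cxmin, cxmax, cymin, cymax = design.core_region
            while len(pts) < n_target:
                d = rng.uniform(lo, hi)
                if rng.uniform() < design.core_fraction:
                    x = rng.uniform(cxmin, cxmax)
                    y = rng.uniform(cymin, cymax)
                    pts.append((x, y, d))
                else:
                    x = rng.uniform(xmin, xmax)
                    y = rng.uniform(ymin, ymax)
                    g = float(evaluate_growth_field(spec, x, y, d))
                    if g > design.peripheral_trigger or rng.uniform() < design.peripheral_keep:
                        pts.append((x, y, d))
        for (x, y, d) in pts:
            rows.append((sid, d, x, y))
            sid += 1
    df = pd.DataFrame(rows, columns=["id", "day", "x", "y"])
    clean = noise_free_index(spec, df["x"].to_numpy(), df["y"].to_numpy(),
                             df["day"].to_numpy())
    if sigma_obs is None:
        # spec.sigma is the residual SD of growth rates; per-survey index
        # noise of SD sigma * (index + offset) yields approximately that
        # residual SD on the log scale, and averaging independent transect
        # errors makes the centroid-mean variance proportional to 1/n
        sigma_obs_vec = spec.sigma * (clean + INDEX_OFFSET)
    else:
        sigma_obs_vec = np.full(len(df), float(sigma_obs))
    noisy = clean + rng.normal(0.0, 1.0, len(df)) * sigma_obs_vec
    df["index"] = np.clip(noisy, 0.0, 100.0)
    df["n_sections"] = 33
    return df


def write_surveys(df: pd.DataFrame, path, spec: WaveFieldSpec | None = None,
                  design: SamplingDesign | None = None) -> None:
    """Write the survey table as CSV plus an adjacent YAML metadata file."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta: dict = {"n_surveys": int(len(df))}
    if design is not None:
        meta["seed"] = design.seed
        meta["mode"] = design.mode
        meta["n_surveys_per_quarter"] = design.n_surveys_per_quarter
    if spec is not None:
        meta["alpha1"] = spec.alpha1
        meta["period_days"] = spec.period
        meta["sigma"] = spec.sigma
        meta["extent"] = list(spec.extent)
        meta["duration_days"] = spec.duration
        meta["waves"] = [
            {k: v for k, v in dict(
                form=w.form, zeta=w.zeta, theta=w.theta, gamma=w.gamma,
                psi=w.psi, amplitude=w.amplitude, phase0=w.phase0,
            ).items() if v is not None}
            for w in spec.waves
        ]
    with open(path.with_suffix(".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_surveys(path) -> pd.DataFrame:
    """Read a survey CSV (columns id, day, x, y, index[, n_sections])."""
    df = pd.read_csv(path)
    required = {"id", "day", "x", "y", "index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survey table missing columns {sorted(missing)}")
    if "n_sections" not in df.columns:
        df["n_sections"] = 33
    return df
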