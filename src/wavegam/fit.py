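"""Outer wave-parameter estimation and model selection.

Wave parameters (direction or epicentre, speed) enter the growth-rate GAM
only through the space-modified-time covariates, so they are estimated by
minimising the inner GAM's AIC over the wave parameters: a coarse
deterministic direct search supplies starting values, a simulated-annealing
(SANN) optimizer refines them, and competing model structures are ranked by
``adjustedAIC = AIC + 2 K`` where ``K`` counts the wave parameters
estimated outside the smoother.  Profile confidence intervals re-optimize
the remaining parameters along a grid of one fixed parameter and cut the
profile at the chi-square(1) drop.

The SANN schedule: geometric cooling ``T_k = T0 * cooling**k`` with the
initial temperature calibrated so roughly 60% of early proposals are
accepted; Gaussian proposals per parameter (epicentre coordinates 5 km,
angles 0.2 rad, speeds 10% multiplicative on the log scale) whose scale
shrinks with the relative temperature, so late iterations refine locally.
Speeds are optimized on the log scale.  The best-ever parameters are
returned, not the final state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .smoother import PenalizedSplineGAM
from .waves import (
    DEFAULT_RIVER_Y,
    MODEL_CATALOGUE,
    MODEL_LABELS,
    WaveParameterSet,
    build_design,
)

__all__ = [
    "FittedWaveModel",
    "ProfileCI",
    "WaveModelRegressor",
    "direct_search_init",
    "sann_optimize",
    "fit_catalogue",
    "profile_ci",
    "epicentre_separation",
    "inner_objective",
]

# Gaussian proposal scales per parameter kind
PROPOSAL_SCALES = {"theta": 0.2, "gamma": 5000.0, "psi": 5000.0, "zeta": 0.1}
#: direct-search speed grid, metres/day
ZETA_GRID = tuple(np.geomspace(10.0, 50_000.0, 8))


@dataclass
class FittedWaveModel:
    """One fitted catalogue entry: wave parameters + inner smoother fit."""

    label: str
    params: WaveParameterSet | None
    gam: PenalizedSplineGAM
    objective: float  # inner criterion (GAM AIC) at the best parameters
    aic: float
    K: int
    seed: int | None = None
    trace: pd.DataFrame | None = None
    init: WaveParameterSet | None = None
    river_y: float = DEFAULT_RIVER_Y

    @property
    def adjusted_aic(self) -> float:
        return self.aic + 2.0 * self.K


@dataclass
class ProfileCI:
    """Likelihood-profile confidence interval for one wave parameter."""

    parameter: str
    grid: np.ndarray
    objective: np.ndarray
    lower95: float
    upper95: float
    level: float = 0.95
    cutoff: float = 3.84
    one_sided: bool = False


def _as_arrays(obs: pd.DataFrame):
    return (obs["T"].to_numpy(float), obs["X"].to_numpy(float),
            obs["Y"].to_numpy(float), obs["r"].to_numpy(float),
            obs["w"].to_numpy(float))


def inner_objective(label: str, params: WaveParameterSet | None, obs: pd.DataFrame,
                    river_y: float = DEFAULT_RIVER_Y,
                    criterion: str = "gcv") -> tuple[float, PenalizedSplineGAM | None]:
    """Inner GAM AIC for one parameter set; inf if the design is degenerate."""
    T, X, Y, r, w = _as_arrays(obs)
    try:
        Z, specs = build_design(label, params, T, X, Y, river_y=river_y)
        gam = PenalizedSplineGAM(specs, criterion=criterion).fit(Z, r, sample_weight=w)
    except ValueError:
        return np.inf, None
    return gam.aic_, gam


def _neutral_wave(form: str, obs: pd.DataFrame) -> dict:
    zeta = float(np.sqrt(ZETA_GRID[0] * ZETA_GRID[-1]))
    if form == "planar":
        return {"theta": 0.0, "zeta": zeta}
    return {"gamma": float(obs["X"].mean()), "psi": float(obs["Y"].mean()),
            "zeta": zeta}


def _wave_grid(form: str, obs: pd.DataFrame, n_lattice: int, n_theta: int):
    """Candidate single-wave parameter dicts on the deterministic grid."""
    out = []
    if form == "planar":
        for theta in np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False):
            for zeta in ZETA_GRID:
                out.append({"theta": float(theta), "zeta": float(zeta)})
    else:
        x, y = obs["X"].to_numpy(float), obs["Y"].to_numpy(float)
        dx, dy = x.max() - x.min(), y.max() - y.min()
        gx = np.linspace(x.min() - 0.2 * dx, x.max() + 0.2 * dx, n_lattice)
        gy = np.linspace(y.min() - 0.2 * dy, y.max() + 0.2 * dy, n_lattice)
        for gamma in gx:
            for psi in gy:
                for zeta in ZETA_GRID:
                    out.append({"gamma": float(gamma), "psi": float(psi),
                                "zeta": float(zeta)})
    return out


def direct_search_init(label: str, obs: pd.DataFrame,
                       river_y: float = DEFAULT_RIVER_Y,
                       n_lattice: int = 6, n_theta: int = 16,
                       criterion: str = "gcv") -> WaveParameterSet:
    """Deterministic coarse-grid starting values for the SANN optimizer.

    Single-wave models scan a full cross of candidate directions/epicentres
    (lattice over the data bounding box +/- 20%) and log-spaced speeds.
    Two-wave models search sequentially: wave 1 over its grid with wave 2
    held at a neutral central value, then wave 2 over its grid with wave 1
    fixed at its best cell.  No randomness is involved.
    """
    structure = MODEL_CATALOGUE[label]
    if structure.kind == "null":
        return WaveParameterSet(label, [])
    if "quarter" in obs.columns and obs["quarter"].nunique() < 3:
        raise ValueError("observations must span at least 3 quarters")

    if structure.kind == "single":
        best, best_obj = None, np.inf
        for cand in _wave_grid(structure.forms[0], obs, n_lattice, n_theta):
            params = WaveParameterSet(label, [cand])
            obj, _ = inner_objective(label, params, obs, river_y, criterion)
            if obj < best_obj:
                best, best_obj = params, obj
        if best is None:
            raise ValueError("direct search found no admissible parameters")
        return best

    # two waves: sequential conditional grid search
    waves = [_neutral_wave(f, obs) for f in structure.forms]
    for k in (0, 1):
        best_cand, best_obj = dict(waves[k]), np.inf
        for cand in _wave_grid(structure.forms[k], obs, n_lattice, n_theta):
            trial = [dict(w) for w in waves]
            trial[k] = cand
            params = WaveParameterSet(label, trial)
            obj, _ = inner_objective(label, params, obs, river_y, criterion)
            if obj < best_obj:
                best_cand, best_obj = cand, obj
        waves[k] = best_cand
    return WaveParameterSet(label, waves)


def _proposal_sd(params: WaveParameterSet) -> np.ndarray:
    sds = []
    for form, w in zip(params.structure.forms, params.waves):
        names = ("theta", "zeta") if form == "planar" else ("gamma", "psi", "zeta")
        sds.extend(PROPOSAL_SCALES[n] for n in names)
    return np.asarray(sds)


def sann_optimize(label: str, obs: pd.DataFrame, init: WaveParameterSet,
                  iterations: int = 15_000, seed=0,
                  river_y: float = DEFAULT_RIVER_Y, cooling: float | None = None,
                  accept_target: float = 0.6, scale_floor: float = 0.02,
                  temp_ratio: float = 1e-3,
                  criterion: str = "gcv", keep_trace: bool = True,
                  fixed: Sequence[int] = ()) -> FittedWaveModel:
    """Simulated annealing over the wave parameters, inner GAM AIC objective.

    Geometric cooling is normalised to the iteration budget: by default the
    temperature falls from the calibrated T0 to ``temp_ratio * T0`` over the
    run (``cooling = temp_ratio ** (1 / iterations)``, about 0.9995 at the
    15,000-iteration default), so short runs still end cold enough to
    refine.  Proposal scales shrink as ``sqrt(T / T0)`` with a floor.

    ``fixed`` lists flat-vector indices (speeds on the log scale) held at
    their initial values — used by profiling.  With a fixed seed the whole
    run, including the returned best-ever parameters, is reproducible; runs
    sharing a seed and an explicit cooling rate share their proposal stream
    prefix, so more iterations can only improve the best-ever objective.
    """
    structure = MODEL_CATALOGUE[label]
    if structure.kind == "null":
        obj, gam = inner_objective(label, None, obs, river_y, criterion)
        return FittedWaveModel(label, WaveParameterSet(label, []), gam, obj,
                               aic=obj, K=0, seed=None)
    if init.label != label:
        raise ValueError("init parameters are for a different model")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    vec = init.to_vector()
    sds = _proposal_sd(init)
    free = np.ones(vec.size, bool)
    free[list(fixed)] = False

    def objective(v):
        return inner_objective(label, WaveParameterSet.from_vector(label, v),
                               obs, river_y, criterion)[0]

    cur_obj = objective(vec)
    if not np.isfinite(cur_obj):
        raise ValueError("initial parameters give a degenerate design")
    best_vec, best_obj = vec.copy(), cur_obj

    # calibrate T0 so that ~accept_target of early uphill proposals accept
    probe_deltas = []
    for _ in range(20):
        step = rng.normal(0.0, sds) * free
        d = objective(vec + step) - cur_obj
        if np.isfinite(d) and d > 0:
            probe_deltas.append(d)
    t0 = (float(np.median(probe_deltas)) / np.log(1.0 / accept_target)
          if probe_deltas else 1.0)
    t0 = max(t0, 1e-8)

    if cooling is None:
        cooling = float(temp_ratio) ** (1.0 / max(iterations, 1))

    rows = []
    n_degenerate = 0
    temp = t0
    for k in range(iterations):
        factor = max(np.sqrt(temp / t0), scale_floor)
        step = rng.normal(0.0, sds * factor) * free
        cand = vec + step
        cand_obj = objective(cand)
        if not np.isfinite(cand_obj):
            n_degenerate += 1
            accept = False
        else:
            d = cand_obj - cur_obj
            accept = d <= 0 or rng.uniform() < np.exp(-d / temp)
        if accept:
            vec, cur_obj = cand, cand_obj
            if cur_obj < best_obj:
                best_vec, best_obj = vec.copy(), cur_obj
        if keep_trace:
            rows.append((k, cand_obj, cur_obj, best_obj, accept))
        temp *= cooling
    if n_degenerate == iterations:
        raise RuntimeError(
            "optimization failure: every SANN proposal produced a degenerate "
            "design (check data extent and wave-speed scales)")

    best = WaveParameterSet.from_vector(label, best_vec)
    obj, gam = inner_objective(label, best, obs, river_y, criterion)
    trace = (pd.DataFrame(rows, columns=["iteration", "proposal_objective",
                                         "current_objective", "best_objective",
                                         "accepted"])
             if keep_trace else None)
    seed_out = None if isinstance(seed, np.random.Generator) else int(seed)
    return FittedWaveModel(label, best, gam, obj, aic=obj, K=structure.K,
                           seed=seed_out, trace=trace, init=init,
                           river_y=river_y)


def fit_wave_model(label: str, obs: pd.DataFrame, iterations: int = 15_000,
                   seed=0, river_y: float = DEFAULT_RIVER_Y,
                   n_lattice: int = 6, n_theta: int = 16,
                   criterion: str = "gcv", keep_trace: bool = False,
                   **sann_kwargs) -> FittedWaveModel:
    """Direct-search initialisation followed by SANN for one label."""
    structure = MODEL_CATALOGUE[label]
    if structure.kind == "null":
        obj, gam = inner_objective(label, None, obs, river_y, criterion)
        return FittedWaveModel(label, WaveParameterSet(label, []), gam, obj,
                               aic=obj, K=0)
    init = direct_search_init(label, obs, river_y, n_lattice, n_theta, criterion)
    return sann_optimize(label, obs, init, iterations=iterations, seed=seed,
                         river_y=river_y, criterion=criterion,
                         keep_trace=keep_trace, **sann_kwargs)


def fit_catalogue(obs: pd.DataFrame, labels: Sequence[str] = MODEL_LABELS,
                  iterations: int = 15_000, seed: int = 0,
                  river_y: float = DEFAULT_RIVER_Y, n_lattice: int = 6,
                  n_theta: int = 16, criterion: str = "gcv"):
    """Fit every requested catalogue entry and rank by adjusted AIC.

    Returns ``(comparison, fits)``: a DataFrame with one row per label
    (K, AIC, adjustedAIC, delta, selected, error) sorted by adjusted AIC,
    and a dict of the successful :class:`FittedWaveModel` objects.  A
    failing model becomes a row with an error message, never an abort.
    Ties in adjusted AIC are broken by fewer wave parameters, then by label.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(labels))
    fits: dict[str, FittedWaveModel] = {}
    rows = []
    for label, child in zip(labels, children):
        try:
            fm = fit_wave_model(label, obs, iterations=iterations,
                                seed=np.random.default_rng(child),
                                river_y=river_y, n_lattice=n_lattice,
                                n_theta=n_theta, criterion=criterion)
            fits[label] = fm
            rows.append({"label": label, "K": fm.K, "AIC": fm.aic,
                         "adjustedAIC": fm.adjusted_aic, "error": ""})
        except Exception as exc:  # noqa: BLE001 - per-model failures are rows
            rows.append({"label": label, "K": MODEL_CATALOGUE[label].K,
                         "AIC": np.nan, "adjustedAIC": np.nan,
                         "error": f"{type(exc).__name__}: {exc}"})
    comp = pd.DataFrame(rows)
    ok = comp["adjustedAIC"].notna()
    comp["delta"] = comp["adjustedAIC"] - comp.loc[ok, "adjustedAIC"].min()
    comp = comp.sort_values(["adjustedAIC", "K", "label"],
                            na_position="last").reset_index(drop=True)
    comp["selected"] = False
    if ok.any():
        comp.loc[0, "selected"] = True
    return comp, fits


def profile_ci(model: FittedWaveModel, obs: pd.DataFrame, parameter: str,
               grid: Sequence[float], level: float = 0.95,
               iterations: int = 2000, seed: int = 0,
               river_y: float | None = None,
               criterion: str = "gcv") -> ProfileCI:
    """Profile confidence interval for one wave parameter.

    For each grid value the parameter is fixed and all remaining wave
    parameters are re-optimized by a short SANN restart from the joint
    optimum; the profile of the inner criterion is cut ``chi2_1(level)``
    units above its minimum (3.84 at 95%), with linear interpolation for
    the crossing points.  The grid must bracket the point estimate.  A
    profile monotone over the whole grid yields a one-sided interval and
    sets ``one_sided``.
    """
    if model.params is None or not model.params.waves:
        raise ValueError("model has no wave parameters to profile")
    names = model.params.parameter_names()
    if parameter not in names:
        raise ValueError(f"parameter {parameter!r} not in {names}")
    idx = names.index(parameter)
    joint_vec = model.params.to_vector()
    is_zeta = parameter.startswith("zeta")
    point = np.exp(joint_vec[idx]) if is_zeta else joint_vec[idx]

    grid = np.sort(np.asarray(grid, float))
    if not (grid.min() <= point <= grid.max()):
        raise ValueError(
            f"profile grid [{grid.min()}, {grid.max()}] does not contain the "
            f"point estimate {point}")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(grid.size)
    prof = np.empty(grid.size)
    for j, (g, child) in enumerate(zip(grid, children)):
        vec = joint_vec.copy()
        vec[idx] = np.log(g) if is_zeta else g
        init = WaveParameterSet.from_vector(model.label, vec)
        if len(vec) == 1:
            obj, _ = inner_objective(model.label, init, obs,
                                     model.river_y, criterion)
            prof[j] = obj
        else:
            fm = sann_optimize(model.label, obs, init, iterations=iterations,
                               seed=np.random.default_rng(child),
                               river_y=model.river_y, criterion=criterion,
                               keep_trace=False, fixed=[idx])
            prof[j] = fm.objective

    cutoff = float(stats.chi2.ppf(level, df=1))
    ref = min(float(np.min(prof)), model.objective)
    bound = ref + cutoff

    def cross(lo_side: bool) -> float | None:
        inside = prof <= bound
        if not inside.any():
            return None
        first, last = np.argmax(inside), len(inside) - 1 - np.argmax(inside[::-1])
        if lo_side:
            if first == 0:
                return None  # bound not crossed inside the grid
            x0, x1 = grid[first - 1], grid[first]
            y0, y1 = prof[first - 1], prof[first]
        else:
            if last == len(grid) - 1:
                return None
            x0, x1 = grid[last], grid[last + 1]
            y0, y1 = prof[last], prof[last + 1]
        if y1 == y0:
            return float(x1 if lo_side else x0)
        t = (bound - y0) / (y1 - y0)
        return float(x0 + t * (x1 - x0))

    lo, hi = cross(True), cross(False)
    one_sided = lo is None or hi is None
    if one_sided:
        import warnings
        warnings.warn(
            f"profile for {parameter} does not cross the cutoff on "
            f"{'both sides' if lo is None and hi is None else 'one side'}; "
            "reporting a one-sided interval", stacklevel=2)
    return ProfileCI(parameter, grid, prof,
                     lower95=float(grid[0]) if lo is None else lo,
                     upper95=float(grid[-1]) if hi is None else hi,
                     level=level, cutoff=cutoff, one_sided=one_sided)


def epicentre_separation(model) -> float:
    """Distance (km) between the two epicentres of a dual-radial model."""
    params = model.params if isinstance(model, FittedWaveModel) else model
    if params is None or len(params.waves) != 2 or any(
            "gamma" not in w for w in params.waves):
        raise ValueError("epicentre separation needs a model with two radial waves")
    w1, w2 = params.waves
    return float(np.hypot(w1["gamma"] - w2["gamma"], w1["psi"] - w2["psi"]) / 1000.0)


class WaveModelRegressor(BaseEstimator, RegressorMixin):
    """sklearn-style estimator for one travelling-wave model structure.

    ``fit(X, y, sample_weight)`` takes ``X`` with columns ``(T, X, Y)``
    (days since start, mean-centred easting/northing in metres), ``y`` the
    log-difference growth rates and ``sample_weight`` the pairing weights.
    Wave parameters are estimated by direct search + SANN; the inner
    smoother is a weighted penalized-spline GAM.

    Attributes after fit: ``params_`` (WaveParameterSet), ``gam_``,
    ``aic_``, ``adjusted_aic_``, ``K_``, ``objective_``, ``trace_``.
    """

    def __init__(self, label: str = "RE", iterations: int = 15_000,
                 seed: int = 0, river_y: float = DEFAULT_RIVER_Y,
                 n_lattice: int = 6, n_theta: int = 16,
                 criterion: str = "gcv", keep_trace: bool = False):
        self.label = label
        self.iterations = iterations
        self.seed = seed
        self.river_y = river_y
        self.n_lattice = n_lattice
        self.n_theta = n_theta
        self.criterion = criterion
        self.keep_trace = keep_trace

    def _obs_frame(self, X, y=None, sample_weight=None):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must have columns (T, X, Y)")
        obs = pd.DataFrame({"T": X[:, 0], "X": X[:, 1], "Y": X[:, 2]})
        if y is not None:
            obs["r"] = np.asarray(y, float)
            obs["w"] = (np.ones(len(obs)) if sample_weight is None
                        else np.asarray(sample_weight, float))
        return obs

    def fit(self, X, y, sample_weight=None):
        if self.label not in MODEL_CATALOGUE:
            raise ValueError(f"unknown model label {self.label!r}")
        obs = self._obs_frame(X, y, sample_weight)
        fm = fit_wave_model(self.label, obs, iterations=self.iterations,
                            seed=self.seed, river_y=self.river_y,
                            n_lattice=self.n_lattice, n_theta=self.n_theta,
                            criterion=self.criterion,
                            keep_trace=self.keep_trace)
        self.fitted_model_ = fm
        self.params_ = fm.params
        self.gam_ = fm.gam
        self.objective_ = fm.objective
        self.aic_ = fm.aic
        self.adjusted_aic_ = fm.adjusted_aic
        self.K_ = fm.K
        self.trace_ = fm.trace
        self.intercept_ = fm.gam.intercept_
        return self

    def predict(self, X):
        obs = self._obs_frame(X)
        from .waves import build_design as _bd
        Z, specs = _bd(self.label, self.params_, obs["T"], obs["X"], obs["Y"],
                       river_y=self.river_y)
        masks = [s.rows for s in specs]
        return self.gam_.predict(Z, smooth_rows=masks)
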