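"""Weighted penalized-spline regression: the inner GAM of every wave model.

The growth-rate equation of every catalogue entry is an additive Gaussian
model ``r = alpha1 + sum_k f_k(z_k) + eps`` fitted by weighted penalized
least squares.  Each smooth ``f_k`` is a low-rank radial-basis spline of the
thin-plate family: basis columns are a linear term plus cubic radial bumps
``|u - kappa_j|^3`` at knots placed at covariate quantiles, the wiggliness
penalty is a ridge on the radial coefficients (so the penalty null space
contains exactly the linear functions), and the smoothing parameter is
chosen by GCV.  Knot positions follow a van der Corput ordering of quantile
levels, which makes bases of increasing size nested — convenient for
likelihood-monotonicity checks and stable across basis sizes.

AIC convention (used consistently across the whole model catalogue):
``AIC = -2 * logLik + 2 * (edf + 1)`` where ``logLik`` is the weighted
Gaussian log-likelihood at the ML variance estimate ``RSS_w / n``, ``edf``
is the trace of the hat matrix (intercept included) and the ``+1`` counts
the variance.  Only differences of AIC between models matter for selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["SmoothSpec", "PenalizedSplineGAM", "conditional_contribution"]


@dataclass
class SmoothSpec:
    """Layout of one smooth term.

    cols
        indices of the covariate column(s) in the design input: one index
        for a univariate smooth, two for a tensor-product surface.
    rows
        optional boolean mask; the smooth applies only to these rows (used
        by the river-split models, where each observation belongs to
        exactly one of two smooths).
    max_basis
        basis dimension: total columns for a univariate smooth (default 12),
        per-margin dimension for a tensor product (default 10 when built by
        the wave layer).
    """

    cols: tuple[int, ...]
    rows: np.ndarray | None = None
    max_basis: int = 12

    def __post_init__(self):
        self.cols = tuple(int(c) for c in self.cols)
        if len(self.cols) not in (1, 2):
            raise ValueError("a smooth takes 1 or 2 covariates")
        if self.max_basis < 3:
            raise ValueError("max_basis must be >= 3")


def _van_der_corput(n: int) -> np.ndarray:
    """First n terms of the base-2 van der Corput sequence (in (0, 1))."""
    out = np.empty(n)
    for i in range(n):
        v, denom, k = 0.0, 1.0, i + 1
        while k:
            denom *= 2.0
            k, rem = divmod(k, 2)
            v += rem / denom
        out[i] = v
    return out


def _quantile_knots(u: np.ndarray, n_knots: int) -> np.ndarray:
    """Knots at quantiles of ``u`` taken in van der Corput order.

    The returned sequence is a prefix of an infinite one, so bases of
    increasing size are nested.  Duplicate quantiles are skipped.
    """
    levels = _van_der_corput(max(4 * n_knots, 16))
    qs = np.quantile(u, levels)
    knots: list[float] = []
    for q in qs:
        if all(abs(q - k) > 1e-9 for k in knots):
            knots.append(float(q))
        if len(knots) == n_knots:
            break
    if len(knots) < n_knots:
        raise ValueError(
            f"covariate has too few distinct values for {n_knots} knots"
        )
    return np.asarray(knots)


class _SmoothBasis:
    """Frozen basis for one smooth: scaling, knots, centring, penalty mask."""

    def __init__(self, spec: SmoothSpec, Z: np.ndarray, w: np.ndarray,
                 offset_col: bool = False):
        # offset_col: prepend an unpenalized 0/1 group-level column so that a
        # row-masked smooth can carry its own mean level (the subsets of a
        # river-split model need not share the global intercept)
        self.offset_col = offset_col
        self.spec = spec
        rows = np.ones(Z.shape[0], bool) if spec.rows is None else np.asarray(spec.rows, bool)
        self.lo = Z[rows][:, spec.cols].min(axis=0)
        self.hi = Z[rows][:, spec.cols].max(axis=0)
        span = self.hi - self.lo
        if np.any(span <= 0):
            raise ValueError("degenerate smooth: covariate is constant on its rows")
        self.span = span

        if len(spec.cols) == 1:
            u = self._scale(Z[rows][:, spec.cols])[:, 0]
            if np.unique(u).size < 3:
                raise ValueError("degenerate basis: fewer than 3 unique covariate values")
            n_knots = min(spec.max_basis - 1, np.unique(u).size - 1)
            self.knots = _quantile_knots(u, n_knots)
            self.penalized = np.r_[False, np.ones(n_knots, bool)]
        else:
            self.knots = []
            for j in range(2):
                u = self._scale(Z[rows][:, spec.cols])[:, j]
                if np.unique(u).size < 3:
                    raise ValueError("degenerate basis: fewer than 3 unique covariate values")
                n_knots = min(spec.max_basis - 2, np.unique(u).size - 1)
                self.knots.append(_quantile_knots(u, n_knots))
            # marginal columns: [1, u, radial...]; tensor drops the 1*1 cell
            p1 = 2 + len(self.knots[0])
            p2 = 2 + len(self.knots[1])
            pen1 = np.r_[False, False, np.ones(len(self.knots[0]), bool)]
            pen2 = np.r_[False, False, np.ones(len(self.knots[1]), bool)]
            mask = (pen1[:, None] | pen2[None, :]).ravel()
            self.penalized = np.delete(mask, 0)  # drop constant x constant
            self._tensor_shape = (p1, p2)

        raw = self._raw_columns(Z, rows)
        wr = w[rows]
        wsum = wr.sum()
        self.center = (wr[:, None] * raw).sum(axis=0) / wsum
        centred = raw - self.center
        rms = np.sqrt((wr[:, None] * centred**2).sum(axis=0) / wsum)
        rms[rms <= 0] = 1.0
        self.col_scale = rms
        self.rows_fit = rows
        # cache the training design block (full length, zero off-rows)
        self.fit_block = np.zeros((Z.shape[0], self.center.size))
        self.fit_block[rows] = centred / rms
        if offset_col:
            self.penalized = np.r_[False, self.penalized]
            self.fit_block = np.column_stack([rows.astype(float), self.fit_block])

    def _scale(self, zc: np.ndarray) -> np.ndarray:
        return (zc - self.lo) / self.span

    def _raw_columns(self, Z: np.ndarray, rows: np.ndarray) -> np.ndarray:
        zc = self._scale(Z[rows][:, self.spec.cols])
        if len(self.spec.cols) == 1:
            u = zc[:, 0]
            rad = np.abs(u[:, None] - self.knots[None, :]) ** 3
            return np.column_stack([u, rad])
        u, v = zc[:, 0], zc[:, 1]
        m1 = np.column_stack([np.ones_like(u), u] + [np.abs(u - k) ** 3 for k in self.knots[0]])
        m2 = np.column_stack([np.ones_like(v), v] + [np.abs(v - k) ** 3 for k in self.knots[1]])
        tensor = (m1[:, :, None] * m2[:, None, :]).reshape(len(u), -1)
        return tensor[:, 1:]  # drop constant x constant

    def design(self, Z: np.ndarray, rows: np.ndarray | None = None) -> np.ndarray:
        """Centred, scaled design block; zero outside the smooth's rows."""
        n = Z.shape[0]
        if rows is None:
            rows = np.ones(n, bool)
        out = np.zeros((n, self.center.size))
        out[rows] = (self._raw_columns(Z, rows) - self.center) / self.col_scale
        if self.offset_col:
            out = np.column_stack([rows.astype(float), out])
        return out

    @property
    def n_cols(self) -> int:
        return self.center.size + int(self.offset_col)


class PenalizedSplineGAM(BaseEstimator, RegressorMixin):
    """Weighted additive Gaussian model with penalized radial-spline smooths.

    Parameters
    ----------
    smooth_specs : sequence of SmoothSpec
        Layout of the smooth terms over the covariate columns of ``X``.
        An empty list fits the intercept-only model.
    criterion : {"gcv", "fixed"}
        Smoothing-parameter selection: generalized cross-validation
        (default) or fixed values given by ``lam``.
    lam : float or sequence of float, optional
        Smoothing parameter(s) when ``criterion="fixed"``; one per smooth.

    Observation weights enter as inverse relative variances
    (``Var[eps_i] = sigma^2 / w_i``), matching survey counts per centroid.

    Attributes (after ``fit``)
    --------------------------
    intercept_ : float — the global mean level ``alpha1``
    coef_ : ndarray — spline coefficients (all smooths concatenated)
    lam_ : ndarray — selected smoothing parameter per smooth
    edf_ : float — trace of the hat matrix, intercept included
    log_likelihood_ : float — weighted Gaussian logLik at the ML variance
    aic_ : float — ``-2 logLik + 2 (edf + 1)``
    scale_ : float — residual variance estimate ``RSS_w / (n - edf)``
    """

    _LAM_GRID = np.logspace(-4.0, 7.0, 12)

    def __init__(self, smooth_specs: Sequence[SmoothSpec] = (), criterion: str = "gcv",
                 lam=None):
        self.smooth_specs = smooth_specs
        self.criterion = criterion
        self.lam = lam

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, float)
        n = y.shape[0]
        if X.shape[0] != n:
            raise ValueError("X and y lengths differ")
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        if w.shape[0] != n:
            raise ValueError("sample_weight length differs from y")
        if np.any(w <= 0):
            raise ValueError("weights must be > 0")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y)) and np.all(np.isfinite(w))):
            raise ValueError("non-finite values in inputs")
        w_raw = w
        w = w / w.mean()  # normalised weights: fits invariant to uniform rescaling

        specs = list(self.smooth_specs)
        masked = [i for i, s in enumerate(specs) if s.rows is not None]
        bases = [_SmoothBasis(s, X, w, offset_col=(i in masked[1:]))
                 for i, s in enumerate(specs)]

        sw = np.sqrt(w)
        blocks = [sw[:, None]]  # weighted intercept column
        pen_masks = [np.zeros(1, bool)]
        for b in bases:
            blocks.append(sw[:, None] * b.fit_block)
            pen_masks.append(b.penalized)
        Xw = np.hstack(blocks)
        yw = sw * y

        slices, start = [], 0
        for blk in blocks:
            slices.append(slice(start, start + blk.shape[1]))
            start += blk.shape[1]
        p = start

        A = Xw.T @ Xw
        bvec = Xw.T @ yw
        yy = float(yw @ yw)

        pen_diag_per_smooth = []
        for k, mask in enumerate(pen_masks[1:], start=1):
            dd = np.zeros(p)
            dd[slices[k]] = mask.astype(float)
            pen_diag_per_smooth.append(dd)

        eye = np.eye(p)
        jitter_base = 1e-10 * max(np.trace(A), 1.0) / p

        def solve(lams):
            M = A.copy()
            for lam, d in zip(lams, pen_diag_per_smooth):
                M[np.diag_indices(p)] += lam * d
            rhs = np.concatenate([bvec[:, None], A], axis=1)
            jitter = 0.0
            for _ in range(5):
                try:
                    sol = np.linalg.solve(M + jitter * eye, rhs)
                    break
                except np.linalg.LinAlgError:
                    jitter = max(jitter * 100.0, jitter_base)
            else:  # pragma: no cover - pathological
                raise ValueError("normal equations singular")
            beta = sol[:, 0]
            edf = float(np.trace(sol[:, 1:]))
            rss = max(yy - 2.0 * beta @ bvec + beta @ (A @ beta), 1e-300)
            return beta, edf, rss, M + jitter * eye

        n_smooth = len(bases)
        if n_smooth == 0:
            lams = np.empty(0)
        elif self.criterion == "fixed":
            lam = self.lam if self.lam is not None else 1.0
            lams = np.broadcast_to(np.atleast_1d(np.asarray(lam, float)), (n_smooth,)).copy()
        elif self.criterion == "gcv":
            lams = self._select_gcv(solve, n, n_smooth)
        else:
            raise ValueError(f"unknown criterion {self.criterion!r}")

        beta, edf, rss, M = solve(lams)

        self.n_obs_ = n
        self.bases_ = bases
        self.slices_ = slices
        self.lam_ = np.asarray(lams, float)
        self.beta_ = beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.edf_ = edf
        self.rss_ = float(rss)
        sigma2_ml = rss / n
        self.log_likelihood_ = float(
            -0.5 * n * (np.log(2.0 * np.pi * sigma2_ml) + 1.0) + 0.5 * np.sum(np.log(w))
        )
        self.aic_ = float(-2.0 * self.log_likelihood_ + 2.0 * (edf + 1.0))
        self.scale_ = float(rss / max(n - edf, 1.0))
        # Bayesian posterior covariance of the coefficients
        self.coef_cov_ = self.scale_ * np.linalg.inv(M)
        self.fitted_values_ = (Xw @ beta) / sw
        self.residuals_ = y - self.fitted_values_
        self.weights_ = w_raw
        self.smooth_values_ = [
            (Xw[:, sl] @ beta[sl]) / sw for sl in slices[1:]
        ]  # each smooth's centred contribution on the training rows
        return self

    def _select_gcv(self, solve, n, n_smooth):
        def gcv(lams):
            _, edf, rss, _ = solve(lams)
            denom = max(n - edf, 1e-8)
            return n * rss / denom**2

        lams = np.ones(n_smooth)
        grid = self._LAM_GRID
        n_pass = 1 if n_smooth == 1 else 2
        for _ in range(n_pass):
            for k in range(n_smooth):
                scores = []
                for g in grid:
                    trial = lams.copy()
                    trial[k] = g
                    scores.append(gcv(trial))
                lams[k] = grid[int(np.argmin(scores))]
        # local refinement around the grid optimum
        for k in range(n_smooth):
            local = lams[k] * np.array([0.1, 0.3, 1.0, 3.0, 10.0])
            scores = []
            for g in local:
                trial = lams.copy()
                trial[k] = g
                scores.append(gcv(trial))
            lams[k] = local[int(np.argmin(scores))]
        return lams

    # ------------------------------------------------------------- predict
    def _design_all(self, X, rows_list):
        n = X.shape[0]
        cols = [np.ones((n, 1))]
        for b, rows in zip(self.bases_, rows_list):
            cols.append(b.design(X, rows))
        return np.hstack(cols)

    def predict(self, X, smooth_rows: Sequence[np.ndarray | None] | None = None):
        """Predict the additive model at new covariate rows.

        ``smooth_rows`` gives, per smooth, the boolean mask of rows the
        smooth applies to (needed for river-split layouts); by default every
        smooth applies to every row, except that a smooth fitted with a row
        mask requires an explicit mask when ``X`` is not the training matrix.
        """
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        if smooth_rows is None:
            rows_list = []
            for b in self.bases_:
                if b.spec.rows is None:
                    rows_list.append(np.ones(n, bool))
                elif len(b.rows_fit) == n:
                    rows_list.append(b.rows_fit)
                else:
                    raise ValueError(
                        "smooth has a row mask; pass smooth_rows for new data")
        else:
            rows_list = [np.ones(n, bool) if r is None else np.asarray(r, bool)
                         for r in smooth_rows]
        return self._design_all(X, rows_list) @ self.beta_

    def contribution(self, smooth_index: int, grid):
        """Conditional contribution ``alpha1 + f_k(grid)`` with 95% band.

        Returns ``(estimate, lower, upper)`` arrays over ``grid`` (values of
        the smooth's covariate; for tensor smooths an (m, 2) array).  The
        band is the Bayesian pointwise 95% interval including intercept
        uncertainty.
        """
        b = self.bases_[smooth_index]
        grid = np.asarray(grid, float)
        if grid.ndim == 1 and len(b.spec.cols) == 1:
            Z = np.zeros((grid.size, max(b.spec.cols) + 1))
            Z[:, b.spec.cols[0]] = grid
        else:
            Z = np.zeros((grid.shape[0], max(b.spec.cols) + 1))
            Z[:, list(b.spec.cols)] = grid
        block = b.design(Z, np.ones(Z.shape[0], bool))
        sl = self.slices_[smooth_index + 1]
        C = np.zeros((Z.shape[0], self.beta_.size))
        C[:, 0] = 1.0
        C[:, sl] = block
        est = C @ self.beta_
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, self.coef_cov_, C), 0.0))
        return est, est - 1.96 * se, est + 1.96 * se

    def partial_residuals(self, smooth_index: int):
        """Response minus all other components: residuals + alpha1 + f_k."""
        return self.residuals_ + self.intercept_ + self.smooth_values_[smooth_index]

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = False
        return tags


def conditional_contribution(fit: PenalizedSplineGAM, smooth_index: int, grid):
    """Functional wrapper over :meth:`PenalizedSplineGAM.contribution`."""
    return fit.contribution(smooth_index, grid)
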