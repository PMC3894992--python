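"""Spatially coupled Bayesian regression of visual-field series (ANSWERS).

Given a series of Q visual-field tests at times t_1..t_Q, each measuring M
locations, every location j follows its own linear trend

    mu_ij = intercept_j + slope_j * t_i

and an observed sensitivity y_ij is drawn from the fitted retest density
p(y | mu_ij): the measurement error is the level-dependent Weibull-mixture
scatter, not additive Gaussian noise.  Measurements are conditionally
independent given the trends, so the series log-likelihood is the sum of
per-measurement log-densities.

Slopes and intercepts carry multivariate-normal priors whose covariances
(a*Psi, b*Psi) encode nerve-fibre spatial correlation; the log posterior is
maximised by quasi-Newton ascent (MAP) and the posterior is approximated as
Gaussian at the mode via Laplace's method (inverse negative Hessian).  Each
location's marginal slope distribution is summarised as the probability of
no deterioration, Pnd_j = P(slope_j >= 0), and the per-eye indices

    S_d = -sum_j log Pnd_j        (deterioration)
    S_i = -sum_j log (1 - Pnd_j)  (improvement)

aggregate them across the field.  Running the same machinery with the
off-diagonal prior correlation zeroed gives the no-spatial variant
(ANSWER).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .grid import SpatialPrior, VisualFieldGrid
from .retest import DLS_MAX, DLS_MIN, RetestModel

__all__ = [
    "VFSeries",
    "RegressionWeights",
    "PosteriorEstimate",
    "log_likelihood",
    "log_posterior",
    "map_estimate",
    "laplace_covariance",
    "pnd",
    "s_index",
    "analyze",
]

PND_FLOOR = 1e-300
_CLAMP_SHARPNESS = 10.0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VFSeries:
    """One eye's visual-field time series: Q tests by M locations.

    times are years from the first retained test, strictly increasing;
    values are DLS in dB, complete (no missing locations).
    """

    times: np.ndarray
    values: np.ndarray
    grid: VisualFieldGrid | None = None
    eye_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != t.shape[0]:
            raise ValueError("values must be Q x M matching times")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("test times must be strictly increasing")
        if v.size and (np.any(v < 0) or np.any(v > 50)):
            raise ValueError("DLS values must lie in [0, 50] dB")
        if self.grid is not None and v.shape[1] != self.grid.n_locations:
            raise ValueError("value columns must match grid size")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n_tests(self) -> int:
        return int(self.times.shape[0])

    @property
    def n_locations(self) -> int:
        return int(self.values.shape[1])

    @property
    def span_years(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n_tests else 0.0

    def prefix(self, q: int) -> "VFSeries":
        """The sub-series of the first q tests."""
        return VFSeries(self.times[:q], self.values[:q], self.grid, self.eye_id)


@dataclass(frozen=True)
class RegressionWeights:
    """Per-location linear trends: predicted level = intercept + slope * t."""

    slopes: np.ndarray  # dB/year
    intercepts: np.ndarray  # dB

    def __post_init__(self) -> None:
        s = np.asarray(self.slopes, dtype=float)
        b = np.asarray(self.intercepts, dtype=float)
        if s.shape != b.shape or s.ndim != 1:
            raise ValueError("slopes and intercepts must be matching vectors")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(b))):
            raise ValueError("regression weights must be finite")
        object.__setattr__(self, "slopes", s)
        object.__setattr__(self, "intercepts", b)

    @property
    def n_locations(self) -> int:
        return int(self.slopes.shape[0])

    def predicted(self, times: np.ndarray) -> np.ndarray:
        """Q x M matrix of predicted levels (unclamped)."""
        t = np.asarray(times, dtype=float)[:, None]
        return self.intercepts[None, :] + self.slopes[None, :] * t

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.slopes, self.intercepts])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "RegressionWeights":
        m = x.shape[0] // 2
        return cls(slopes=x[:m].copy(), intercepts=x[m:].copy())


@dataclass(frozen=True)
class PosteriorEstimate:
    """MAP fit with Laplace uncertainty and the change indices."""

    mode: RegressionWeights
    covariance: np.ndarray  # 2M x 2M over (slopes, intercepts)
    pnd: np.ndarray  # per-location P(no deterioration)
    s_d: float
    s_i: float
    log_posterior_at_mode: float
    converged: bool = True
    eye_id: str = ""
    variant: str = "ANSWERS"

    @property
    def slope_sds(self) -> np.ndarray:
        m = self.mode.n_locations
        return np.sqrt(np.diag(self.covariance)[:m])

    def to_dict(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "mode": self.variant,
            "slopes": self.mode.slopes.tolist(),
            "intercepts": self.mode.intercepts.tolist(),
            "slope_sds": self.slope_sds.tolist(),
            "pnd": self.pnd.tolist(),
            "s_d": self.s_d,
            "s_i": self.s_i,
            "converged": self.converged,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Smooth range clamp
# ---------------------------------------------------------------------------

def smooth_clamp(x, lo: float = DLS_MIN, hi: float = DLS_MAX, sharpness: float = _CLAMP_SHARPNESS):
    """Differentiable squeeze of x into (lo, hi); returns (value, d/dx).

    Softplus at both ends: near-identity inside the range, flattening
    smoothly at the boundaries so the regression objective keeps a
    continuous gradient when predicted levels leave the modelled range.
    """
    k = sharpness
    x = np.asarray(x, dtype=float)
    u = lo + np.logaddexp(0.0, k * (x - lo)) / k
    du = expit(k * (x - lo))
    v = hi - np.logaddexp(0.0, k * (hi - u)) / k
    dv = expit(k * (hi - u))
    return v, du * dv


# ---------------------------------------------------------------------------
# Likelihood and posterior
# ---------------------------------------------------------------------------

def _likelihood_value_grad(series: VFSeries, w: RegressionWeights, retest: RetestModel):
    """Series log-likelihood and its gradient w.r.t. (slopes, intercepts)."""
    if series.n_tests == 0:
        m = w.n_locations
        return 0.0, np.zeros(2 * m)
    mu_raw = w.predicted(series.times)
    if not np.all(np.isfinite(mu_raw)):
        raise FloatingPointError("non-finite predicted levels")
    mu, dmu = smooth_clamp(mu_raw)
    logp, dlogp = retest.logpdf_grad(series.values, mu)
    g = dlogp * dmu  # Q x M, d loglik / d mu_raw
    grad_slope = g.T @ series.times
    grad_intercept = g.sum(axis=0)
    return float(np.sum(logp)), np.concatenate([grad_slope, grad_intercept])


def log_likelihood(series: VFSeries, w: RegressionWeights, retest: RetestModel) -> float:
    """Sum over tests and locations of log p(y_ij | mu_ij)."""
    value, _ = _likelihood_value_grad(series, w, retest)
    return value


class _PriorOps:
    """Cached Cholesky solves for the slope/intercept prior precision."""

    def __init__(self, prior: SpatialPrior):
        self.prior = prior
        self._cho = cho_factor(prior.psi)

    def value_grad(self, w: RegressionWeights):
        p = self.prior
        ds = w.slopes - p.mu_slope
        db = w.intercepts - p.mu_intercept
        sol_s = cho_solve(self._cho, ds) / p.a
        sol_b = cho_solve(self._cho, db) / p.b
        value = -0.5 * float(ds @ sol_s) - 0.5 * float(db @ sol_b)
        return value, np.concatenate([-sol_s, -sol_b])

    def precision(self) -> np.ndarray:
        """Block-diagonal prior precision over (slopes, intercepts)."""
        p = self.prior
        m = p.n_locations
        inv_psi = cho_solve(self._cho, np.eye(m))
        out = np.zeros((2 * m, 2 * m))
        out[:m, :m] = inv_psi / p.a
        out[m:, m:] = inv_psi / p.b
        return out


def log_posterior(
    series: VFSeries,
    w: RegressionWeights,
    retest: RetestModel,
    prior: SpatialPrior,
) -> float:
    """Log posterior density of the trends, up to an additive constant."""
    if prior.n_locations != w.n_locations:
        raise ValueError("prior dimension must match the number of locations")
    lik, _ = _likelihood_value_grad(series, w, retest)
    pv, _ = _PriorOps(prior).value_grad(w)
    return lik + pv


def _posterior_value_grad(series, w, retest, prior_ops):
    lik, glik = _likelihood_value_grad(series, w, retest)
    pv, gp = prior_ops.value_grad(w)
    return lik + pv, glik + gp


def log_posterior_grad(series, w, retest, prior: SpatialPrior) -> np.ndarray:
    """Gradient of the log posterior w.r.t. the packed (slopes, intercepts)."""
    _, g = _posterior_value_grad(series, w, retest, _PriorOps(prior))
    return g


# ---------------------------------------------------------------------------
# MAP and Laplace
# ---------------------------------------------------------------------------

_SLOPE_GRID = np.arange(-5.0, 5.01, 0.5)
_INTERCEPT_GRID = np.arange(0.0, 40.01, 1.0)


def _scan_likelihood(series: VFSeries, retest: RetestModel) -> np.ndarray:
    """Per-location log-likelihood over the coarse (slope, intercept) grid.

    Returns an (S, B, M) tensor; computed once per series and reused by the
    initialisation and the conditional basin rescan.
    """
    t = series.times
    mu = (
        _INTERCEPT_GRID[None, :, None]
        + _SLOPE_GRID[:, None, None] * t[None, None, :]
    )
    mu_c, _ = smooth_clamp(mu)
    logp, _ = retest._eval(
        series.values[None, None, :, :],
        np.broadcast_to(mu_c[:, :, :, None], mu.shape + (series.n_locations,)),
        grad=False,
    )
    return logp.sum(axis=2)


def _initial_weights(
    lik_grid: np.ndarray, prior: SpatialPrior
) -> RegressionWeights:
    """Per-location coarse grid search for the starting point.

    The retest density is multimodal in the predicted level (a
    lapse-reversion mode sits near healthy sensitivity at every damaged
    level), so the joint posterior has distinct basins per location and a
    least-squares start can strand the ascent in the wrong one.  The scan
    of each location's (slope, intercept) plane - with the diagonal part
    of the prior added - lands every location in its best basin; the
    quasi-Newton stage then refines jointly.
    """
    m = lik_grid.shape[-1]
    score = (
        lik_grid
        - (_SLOPE_GRID[:, None, None] - prior.mu_slope) ** 2 / (2 * prior.a)
        - (_INTERCEPT_GRID[None, :, None] - prior.mu_intercept) ** 2 / (2 * prior.b)
    )
    best = np.argmax(score.reshape(-1, m), axis=0)
    si, bi = np.unravel_index(best, score.shape[:2])
    return RegressionWeights(slopes=_SLOPE_GRID[si], intercepts=_INTERCEPT_GRID[bi])


def _conditional_rescan(
    lik_grid: np.ndarray,
    w: RegressionWeights,
    ops: _PriorOps,
    series: VFSeries,
    retest: RetestModel,
) -> RegressionWeights | None:
    """Coordinate-wise basin check at the current iterate.

    For each location j, scores the coarse (slope, intercept) grid under
    the likelihood plus the location's conditional Gaussian prior given
    all other locations' current values.  Locations whose current value is
    beaten by a grid point jump there; returns the adjusted weights, or
    None when no location moved.  Catches joint modes that the independent
    per-location initialisation misses once spatial coupling matters.
    """
    p = ops.prior
    m = w.n_locations
    prec = ops.precision()
    lam_s, lam_b = prec[:m, :m], prec[m:, m:]
    ds = w.slopes - p.mu_slope
    db = w.intercepts - p.mu_intercept
    dj_s = np.diag(lam_s)
    dj_b = np.diag(lam_b)
    cond_mean_s = p.mu_slope - (lam_s @ ds - dj_s * ds) / dj_s
    cond_mean_b = p.mu_intercept - (lam_b @ db - dj_b * db) / dj_b

    score = (
        lik_grid
        - dj_s[None, None, :] * (_SLOPE_GRID[:, None, None] - cond_mean_s) ** 2 / 2
        - dj_b[None, None, :] * (_INTERCEPT_GRID[None, :, None] - cond_mean_b) ** 2 / 2
    )
    best = np.argmax(score.reshape(-1, m), axis=0)
    si, bi = np.unravel_index(best, score.shape[:2])
    best_val = score.reshape(-1, m)[best, np.arange(m)]

    # current iterate's score under the same conditional objective
    mu_c, _ = smooth_clamp(w.predicted(series.times))
    logp, _ = retest._eval(series.values, mu_c, grad=False)
    cur = (
        logp.sum(axis=0)
        - dj_s * (w.slopes - cond_mean_s) ** 2 / 2
        - dj_b * (w.intercepts - cond_mean_b) ** 2 / 2
    )
    move = best_val > cur + 1e-6
    if not move.any():
        return None
    slopes = np.where(move, _SLOPE_GRID[si], w.slopes)
    intercepts = np.where(move, _INTERCEPT_GRID[bi], w.intercepts)
    return RegressionWeights(slopes=slopes, intercepts=intercepts)


def _likelihood_hessian(
    series: VFSeries,
    x: np.ndarray,
    retest: RetestModel,
    fd_step: float = 1e-4,
) -> np.ndarray:
    """Hessian of the series log-likelihood at the packed weights x.

    Central finite differences of the analytic likelihood gradient.
    Measurements couple slope_j and intercept_j only within the same
    location, so perturbing all slopes (then all intercepts) at once
    recovers every per-location 2x2 block with four gradient evaluations.
    """
    m = x.shape[0] // 2

    def lik_grad(xv: np.ndarray) -> np.ndarray:
        _, g = _likelihood_value_grad(series, RegressionWeights.from_vector(xv), retest)
        return g

    h = fd_step
    hess_lik = np.zeros((2 * m, 2 * m))
    idx = np.arange(m)
    for block, sl in (("slope", slice(0, m)), ("intercept", slice(m, 2 * m))):
        e = np.zeros(2 * m)
        e[sl] = h
        col = (lik_grad(x + e) - lik_grad(x - e)) / (2 * h)
        target = idx if block == "slope" else m + idx
        hess_lik[idx, target] += col[:m]
        hess_lik[m + idx, target] += col[m:]
    return 0.5 * (hess_lik + hess_lik.T)


def _neg_hessian(
    series: VFSeries,
    x: np.ndarray,
    retest: RetestModel,
    ops: _PriorOps,
    fd_step: float = 1e-4,
) -> np.ndarray:
    """Negative Hessian of the log posterior: prior precision minus the
    (finite-difference) likelihood Hessian."""
    return ops.precision() - _likelihood_hessian(series, x, retest, fd_step)


def map_estimate(
    series: VFSeries,
    retest: RetestModel,
    prior: SpatialPrior,
    gtol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[RegressionWeights, dict]:
    """Maximise the log posterior over the 2M trend parameters.

    Quasi-Newton (L-BFGS) with the analytic gradient, started from a
    per-location basin scan.  Stationary points with a negative-curvature
    direction (saddles between basins of the multimodal likelihood) are
    escaped by stepping along the offending eigenvector and re-running the
    ascent.  Returns the mode and a diagnostics dict.
    """
    if series.n_tests < 3:
        raise ValueError("need at least 3 tests for trend estimation")
    ops = _PriorOps(prior)
    lik_grid = _scan_likelihood(series, retest)
    w0 = _initial_weights(lik_grid, prior)

    def neg(x: np.ndarray):
        v, g = _posterior_value_grad(series, RegressionWeights.from_vector(x), retest, ops)
        return -v, -g

    # ftol 1e-9 halves the iteration count relative to machine-precision
    # targets while leaving S_d unchanged to ~0.1%
    opts = {"maxiter": max_iter, "gtol": gtol, "ftol": 1e-9, "maxcor": 30}
    x0 = w0.as_vector()
    res = minimize(neg, x0, jac=True, method="L-BFGS-B", options=opts)
    x = res.x
    if not np.all(np.isfinite(x)):
        # restart from the prior mean before giving up
        m = prior.n_locations
        x0 = np.concatenate(
            [np.full(m, prior.mu_slope), np.full(m, prior.mu_intercept)]
        )
        res = minimize(neg, x0, jac=True, method="L-BFGS-B", options=opts)
        x = res.x
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("MAP optimisation produced non-finite weights")
    # polish: L-BFGS-B occasionally stops at its iteration cap or a weak
    # line search before the gradient target; restarts are cheap
    for _ in range(3):
        if np.max(np.abs(res.jac)) < 1e-3:
            break
        prev = res.fun
        res = minimize(neg, res.x, jac=True, method="L-BFGS-B", options=opts)
        if res.fun >= prev - 1e-12:
            break
    # conditional basin rescan: spatial coupling can shift a location's
    # best basin away from its independent choice; jump and re-ascend
    for _ in range(2):
        w_adj = _conditional_rescan(
            lik_grid, RegressionWeights.from_vector(res.x), ops, series, retest
        )
        if w_adj is None:
            break
        res_new = minimize(neg, w_adj.as_vector(), jac=True, method="L-BFGS-B", options=opts)
        if res_new.fun < res.fun:
            res = res_new
        else:
            break
    # saddle escape: at a genuine mode the negative Hessian is PSD
    for _ in range(3):
        neg_hess = _neg_hessian(series, res.x, retest, ops)
        eigval, eigvec = np.linalg.eigh(neg_hess)
        if eigval[0] >= -1e-6 * max(1.0, eigval[-1]):
            break
        direction = eigvec[:, 0]
        stepped = None
        for step in (0.5, 0.1, 2.0):
            for sign in (1.0, -1.0):
                cand = res.x + sign * step * direction
                if neg(cand)[0] < res.fun:
                    stepped = cand
                    break
            if stepped is not None:
                break
        if stepped is None:
            break
        res = minimize(neg, stepped, jac=True, method="L-BFGS-B", options=opts)
    x = res.x
    gnorm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or gnorm < 1e-4)
    if not converged:
        warnings.warn(
            f"MAP optimisation did not converge (grad max-norm {gnorm:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    diag = {
        "converged": converged,
        "n_iter": int(res.nit),
        "grad_max_norm": gnorm,
        "log_posterior": -float(res.fun),
    }
    return RegressionWeights.from_vector(x), diag


def laplace_covariance(
    series: VFSeries,
    w_mode: RegressionWeights,
    retest: RetestModel,
    prior: SpatialPrior,
    fd_step: float = 1e-4,
    eig_floor: float = 1e-10,
) -> np.ndarray:
    """Laplace posterior covariance: inverse negative Hessian at the mode.

    The prior contributes its exact (constant) precision; the likelihood
    Hessian comes from finite differences of the analytic likelihood
    gradient (see :func:`_likelihood_hessian`).  At a mode the likelihood
    curvature should be concave per location, but the interpolated density
    is only C1 at integer predicted levels and modes frequently sit on
    those knots, where the one-sided finite difference can read a spurious
    convex direction.  Each per-location 2x2 likelihood block is therefore
    projected onto the concave cone (positive eigenvalues zeroed, with a
    warning) before the prior precision is added, which bounds every
    marginal variance by its prior value and keeps the result positive
    definite.  Remaining indefiniteness raises.
    """
    ops = _PriorOps(prior)
    m = w_mode.n_locations
    hess_lik = _likelihood_hessian(series, w_mode.as_vector(), retest, fd_step)
    # gather per-location 2x2 blocks: (slope_j, intercept_j)
    blocks = np.empty((m, 2, 2))
    jj = np.arange(m)
    blocks[:, 0, 0] = hess_lik[jj, jj]
    blocks[:, 0, 1] = blocks[:, 1, 0] = hess_lik[jj, m + jj]
    blocks[:, 1, 1] = hess_lik[m + jj, m + jj]
    bval, bvec = np.linalg.eigh(blocks)
    n_clipped = int((bval > 0).sum())
    if n_clipped:
        warnings.warn(
            f"{n_clipped} convex likelihood-curvature direction(s) at the "
            "mode projected out (density kink)",
            RuntimeWarning,
            stacklevel=2,
        )
        bval = np.minimum(bval, 0.0)
    proj = bvec @ (bval[..., None] * np.swapaxes(bvec, 1, 2))
    hess_proj = np.zeros_like(hess_lik)
    hess_proj[jj, jj] = proj[:, 0, 0]
    hess_proj[jj, m + jj] = hess_proj[m + jj, jj] = proj[:, 0, 1]
    hess_proj[m + jj, m + jj] = proj[:, 1, 1]
    neg_hess = ops.precision() - hess_proj
    eigval, eigvec = np.linalg.eigh(neg_hess)
    if eigval.min() < -1e-6 * max(1.0, eigval.max()):
        bad = eigval[eigval < 0]
        raise np.linalg.LinAlgError(
            f"indefinite Hessian at the mode: negative eigenvalues {bad}"
        )
    if eigval.min() < eig_floor:
        warnings.warn(
            "near-singular posterior curvature; eigenvalues clipped",
            RuntimeWarning,
            stacklevel=2,
        )
        eigval = np.maximum(eigval, eig_floor)
    cov = (eigvec / eigval) @ eigvec.T
    return 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# Change indices
# ---------------------------------------------------------------------------

def pnd(slope_mean, slope_sd):
    """Probability of no deterioration: P(slope >= 0) = Phi(mean / sd)."""
    slope_sd = np.asarray(slope_sd, dtype=float)
    if np.any(slope_sd <= 0):
        raise ValueError("slope_sd must be positive")
    p = norm.cdf(np.asarray(slope_mean, dtype=float) / slope_sd)
    out = np.clip(p, PND_FLOOR, 1.0)
    return float(out) if out.ndim == 0 else out


def s_index(pnd_values) -> float:
    """Global change index: negative log-product of per-location Pnd."""
    p = np.atleast_1d(np.asarray(pnd_values, dtype=float))
    if np.any(p > 1.0) or np.any(p < 0.0):
        raise ValueError("Pnd values must lie in [0, 1]")
    if np.any(p == 0.0):
        warnings.warn(
            "Pnd of exactly 0 floored for the log", RuntimeWarning, stacklevel=2
        )
        p = np.maximum(p, PND_FLOOR)
    return float(-np.sum(np.log(p)))


def analyze(
    series: VFSeries,
    retest: RetestModel,
    prior: SpatialPrior,
    variant: str = "ANSWERS",
) -> PosteriorEstimate:
    """Full pipeline: MAP fit, Laplace covariance, Pnd and S indices.

    variant "ANSWERS" uses the spatial prior as given; "ANSWER" zeroes the
    off-diagonal prior correlation (no spatial coupling).
    """
    variant = variant.upper()
    if variant not in ("ANSWERS", "ANSWER"):
        raise ValueError("variant must be 'ANSWERS' or 'ANSWER'")
    use_prior = prior if variant == "ANSWERS" else prior.diagonalized()
    w, diag = map_estimate(series, retest, use_prior)
    cov = laplace_covariance(series, w, retest, use_prior)
    m = w.n_locations
    slope_sd = np.sqrt(np.maximum(np.diag(cov)[:m], 1e-300))
    p = pnd(w.slopes, slope_sd)
    return PosteriorEstimate(
        mode=w,
        covariance=cov,
        pnd=p,
        s_d=s_index(p),
        s_i=s_index(np.clip(1.0 - p, PND_FLOOR, 1.0)),
        log_posterior_at_mode=diag["log_posterior"],
        converged=diag["converged"],
        eye_id=series.eye_id,
        variant=variant,
    )
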