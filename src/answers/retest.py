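"""Non-stationary retest variability modelled as Weibull mixtures.

Repeat visual-field tests taken over a window too short for true change
measure pure test-retest scatter.  That scatter is non-stationary: narrow
and symmetric where sensitivity is healthy (~32 dB), wide, skewed, bimodal
and censored at 0 dB where it is damaged.  No single parametric family
captures all of those shapes, so at each integer true level (0..35 dB) the
retest distribution is modelled as a mixture of Weibull densities

    f(y; alpha, beta) = (alpha/beta) (y/beta)^(alpha-1) exp(-(y/beta)^alpha)

fitted by expectation-maximisation, with the number of components chosen by
cross-validated held-out likelihood (stop when adding a component no longer
improves it at p < 1%).  Because log-Weibull densities are undefined at
0 dB, observed values are first passed through a C1 floor transform that is
the identity above 1 dB and exp(y - 1) below.

The fitted per-level mixtures are knitted into a density p(y | mu) that is
smooth in the continuous predicted level mu by shape-preserving (PCHIP)
interpolation of the component parameters across levels (weights in
log/softmax space, shape and scale in log space), so the regression stage
can differentiate through it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import ttest_rel

__all__ = [
    "WeibullComponent",
    "WeibullMixture",
    "RetestModel",
    "RetestPairs",
    "weibull_pdf",
    "weibull_logpdf",
    "transform_dls",
    "em_fit",
    "select_k",
    "fit_retest_model",
]

DLS_MIN, DLS_MAX = 0.0, 35.0  # modelled sensitivity range, dB
# shape capped at 50 (coefficient of variation ~2.5%): DLS is recorded in
# whole dB, and unbounded shapes let EM collapse a component onto a single
# tied integer value, degenerating the density
_ALPHA_BOUNDS = (0.05, 50.0)
_WEIGHT_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Weibull density and the low-end transform
# ---------------------------------------------------------------------------

def weibull_logpdf(y, alpha: float, beta: float):
    """Log density of Weibull(shape=alpha, scale=beta) at y > 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("Weibull density undefined for negative values")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = y / beta
        out = (
            math.log(alpha)
            - math.log(beta)
            + (alpha - 1.0) * np.log(z)
            - z**alpha
        )
    if np.ndim(out) == 0:
        return float(out)
    return out


def weibull_pdf(y, alpha: float, beta: float):
    """Weibull density; 0 at y = 0 when alpha > 1."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("Weibull density undefined for negative values")
    logp = weibull_logpdf(np.where(y > 0, y, 1.0), alpha, beta)
    p = np.exp(logp)
    # at the origin the density is 0 for alpha>1, alpha/beta for alpha==1
    at0 = 0.0 if alpha > 1 else (alpha / beta if alpha == 1 else np.inf)
    p = np.where(y > 0, p, at0)
    if np.ndim(y) == 0:
        return float(p)
    return p


def transform_dls(y):
    """Floor transform keeping sensitivities strictly positive.

    Identity for y >= 1 dB; exp(y - 1) below, matching value and first
    derivative at the 1 dB knot.  Keeps log-Weibull densities defined at
    the 0 dB measurement floor while leaving the measurable range intact.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("DLS values must be >= 0 dB")
    out = np.where(y >= 1.0, y, np.exp(y - 1.0))
    if np.ndim(y) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Mixture containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeibullComponent:
    alpha: float  # shape, dimensionless
    beta: float  # scale, dB

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("Weibull shape and scale must be positive")


@dataclass(frozen=True)
class WeibullMixture:
    """Finite mixture of Weibull components."""

    weights: tuple[float, ...]
    components: tuple[WeibullComponent, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.components) or not self.components:
            raise ValueError("weights and components must match, K >= 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")

    @property
    def k(self) -> int:
        return len(self.components)

    def logpdf(self, y):
        y = np.atleast_1d(np.asarray(y, dtype=float))
        terms = np.stack(
            [
                math.log(max(w, 1e-300)) + weibull_logpdf(y, c.alpha, c.beta)
                for w, c in zip(self.weights, self.components)
            ]
        )
        out = logsumexp(terms, axis=0)
        return out if out.size > 1 else float(out[0])

    def pdf(self, y):
        return np.exp(self.logpdf(y))


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _weighted_weibull_mle(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted Weibull MLE: 1-D root-find for the shape, closed-form scale."""
    wsum = w.sum()
    scale = float(y.max())  # work on y/scale: the score is scale-invariant
    ys = y / scale
    logys = np.log(ys)
    mean_logy = float(w @ logys) / wsum

    def score(alpha: float) -> float:
        ya = ys**alpha
        s = float(w @ ya)
        if s <= 0:
            return -1.0 / alpha - mean_logy
        return float(w @ (ya * logys)) / s - 1.0 / alpha - mean_logy

    lo, hi = _ALPHA_BOUNDS
    slo, shi = score(lo), score(hi)
    if slo > 0 and shi > 0:
        alpha = lo
    elif slo < 0 and shi < 0:
        alpha = hi  # near-degenerate data: cap the shape
    else:
        alpha = brentq(score, lo, hi, xtol=1e-10)
    beta = scale * (float(w @ (ys**alpha)) / wsum) ** (1.0 / alpha)
    return float(alpha), float(beta)


def _mixture_loglik(y: np.ndarray, weights, alphas, betas) -> tuple[float, np.ndarray]:
    """Total log-likelihood and per-point component log-terms."""
    terms = np.stack(
        [
            math.log(max(wk, 1e-300)) + weibull_logpdf(y, a, b)
            for wk, a, b in zip(weights, alphas, betas)
        ]
    )
    lse = logsumexp(terms, axis=0)
    return float(lse.sum()), terms - lse


def _init_params(y: np.ndarray, k: int, rng: np.random.Generator, restart: int):
    """K-quantile split with per-block Weibull MLE; later restarts jittered."""
    n = len(y)
    order = np.argsort(y)
    blocks = np.array_split(order, k)
    assign = np.empty(n, dtype=int)
    for ki, idx in enumerate(blocks):
        assign[idx] = ki
    if restart > 0:  # perturb a fraction of the assignments
        flip = rng.random(n) < 0.25
        assign[flip] = rng.integers(0, k, size=int(flip.sum()))
    weights, alphas, betas = [], [], []
    for ki in range(k):
        mask = assign == ki
        if mask.sum() < 2:
            mask = np.ones(n, dtype=bool)
        a, b = _weighted_weibull_mle(y[mask], np.ones(int(mask.sum())))
        weights.append(max(mask.mean(), 1e-3))
        alphas.append(a)
        betas.append(b)
    w = np.array(weights)
    return w / w.sum(), np.array(alphas), np.array(betas)


def em_fit(
    data,
    k: int,
    seed: int | np.random.Generator | None = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    return_history: bool = False,
):
    """Fit a K-component Weibull mixture by EM.

    ``data`` must be strictly positive (already floor-transformed).  The
    E-step computes component responsibilities; the M-step updates the
    mixing proportions in closed form and each component's shape by a 1-D
    root-find (scale closed-form given shape).  Iterates until the
    log-likelihood gain falls below ``tol``.  Runs ``n_restarts``
    initialisations and keeps the best likelihood.

    Returns (mixture, final log-likelihood).
    """
    y = np.asarray(data, dtype=float)
    if np.any(y <= 0):
        raise ValueError("em_fit expects strictly positive (transformed) data")
    if len(y) < 10 * k:
        raise ValueError(f"need at least {10 * k} points to fit K={k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best: tuple[float, tuple, list] | None = None
    for restart in range(n_restarts if k > 1 else 1):
        w, alphas, betas = _init_params(y, k, rng, restart)
        ll, log_resp = _mixture_loglik(y, w, alphas, betas)
        history = [ll]
        for _ in range(max_iter):
            resp = np.exp(log_resp)  # K x N responsibilities
            # prune degenerate components
            w_new = resp.mean(axis=1)
            keep = w_new >= _WEIGHT_FLOOR
            if not keep.all():
                warnings.warn(
                    f"pruned {int((~keep).sum())} degenerate mixture component(s)",
                    RuntimeWarning,
                    stacklevel=2,
                )
                resp = resp[keep]
                resp = resp / resp.sum(axis=0, keepdims=True)
                w_new = resp.mean(axis=1)
                alphas, betas = alphas[keep], betas[keep]
            for ki in range(len(w_new)):
                alphas[ki], betas[ki] = _weighted_weibull_mle(y, resp[ki])
            w = w_new / w_new.sum()
            ll_new, log_resp = _mixture_loglik(y, w, alphas, betas)
            if not np.isfinite(ll_new):
                raise FloatingPointError("non-finite mixture log-likelihood")
            history.append(ll_new)
            if ll_new - ll < tol:
                ll = ll_new
                break
            ll = ll_new
        if best is None or ll > best[0]:
            best = (ll, (w.copy(), alphas.copy(), betas.copy()), history)

    ll, (w, alphas, betas), history = best
    order = np.argsort(betas)  # canonical order: ascending scale
    mixture = WeibullMixture(
        weights=tuple(float(x) for x in w[order]),
        components=tuple(
            WeibullComponent(float(a), float(b))
            for a, b in zip(alphas[order], betas[order])
        ),
    )
    if return_history:
        return mixture, float(ll), history
    return mixture, float(ll)


def select_k(
    data,
    k_max: int = 4,
    n_folds: int = 5,
    seed: int | None = 0,
    p_threshold: float = 0.01,
) -> int:
    """Choose the mixture size by cross-validated held-out likelihood.

    K grows from 1; K+1 is accepted only while it improves the held-out
    log-likelihood across folds at p < ``p_threshold`` (one-sided paired
    t-test over folds).
    """
    y = np.asarray(data, dtype=float)
    if len(y) < 50:
        raise ValueError("need at least 50 points for component selection")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, n_folds)

    def heldout(k: int) -> np.ndarray:
        scores = []
        for f in range(n_folds):
            test = folds[f]
            train = np.concatenate([folds[g] for g in range(n_folds) if g != f])
            try:
                mix, _ = em_fit(y[train], k, seed=rng)
            except (ValueError, FloatingPointError) as exc:
                warnings.warn(
                    f"EM failed in fold {f} for K={k}: {exc}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                scores.append(np.nan)
                continue
            scores.append(float(np.sum(mix.logpdf(y[test]))))
        scores = np.array(scores)
        if np.all(np.isnan(scores)):
            raise RuntimeError(f"EM failed in every fold for K={k}")
        return scores

    k = 1
    cur = heldout(1)
    while k < k_max:
        nxt = heldout(k + 1)
        ok = ~(np.isnan(cur) | np.isnan(nxt))
        if ok.sum() < 2:
            break
        res = ttest_rel(nxt[ok], cur[ok], alternative="greater")
        if res.pvalue < p_threshold:
            k += 1
            cur = nxt
        else:
            break
    return k


# ---------------------------------------------------------------------------
# Retest pairs and the level-indexed model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetestPairs:
    """Pooled (baseline, retest) sensitivity pairs.

    ``frame`` columns: eye_id, test_a_index, test_b_index, location_index,
    baseline_dls, retest_dls.  For E eyes with T repeats each, the number
    of unordered test pairs is E * C(T, 2).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"baseline_dls", "retest_dls"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"retest pairs need columns {sorted(required)}")
        vals = self.frame[["baseline_dls", "retest_dls"]].to_numpy()
        if vals.size and (np.any(vals < 0) or np.any(vals > 50)):
            raise ValueError("sensitivities must lie in [0, 50] dB")

    def __len__(self) -> int:
        return len(self.frame)

    def n_test_pairs(self) -> int:
        """Distinct (eye, test_a, test_b) combinations in the pool."""
        cols = ["eye_id", "test_a_index", "test_b_index"]
        if not set(cols).issubset(self.frame.columns):
            return len(self.frame)
        return len(self.frame[cols].drop_duplicates())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RetestPairs":
        return cls(pd.read_csv(path))


@dataclass
class RetestModel:
    """Smooth retest density p(y_obs | mu) over predicted levels mu in [0, 35].

    Holds one fitted Weibull mixture per integer level plus shape-preserving
    piecewise-cubic interpolants of the component parameters across levels, giving a log-density that is
    continuous and differentiable in mu (required by the gradient-based
    regression stage).
    """

    level_mixtures: dict[int, WeibullMixture]
    _splines: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        levels = sorted(self.level_mixtures)
        if levels != list(range(int(DLS_MIN), int(DLS_MAX) + 1)):
            raise ValueError("need a fitted mixture at every integer level 0..35")
        ks = {m.k for m in self.level_mixtures.values()}
        if len(ks) != 1:
            raise ValueError("all levels must share the same component count")
        self.k = ks.pop()
        self._build_splines()

    def _build_splines(self) -> None:
        levels = np.arange(DLS_MIN, DLS_MAX + 1)
        logw = np.empty((len(levels), self.k))
        loga = np.empty_like(logw)
        logb = np.empty_like(logw)
        for i, v in enumerate(levels):
            mix = self.level_mixtures[int(v)]
            w = np.maximum(np.array(mix.weights), _WEIGHT_FLOOR)
            logw[i] = np.log(w / w.sum())
            loga[i] = np.log([c.alpha for c in mix.components])
            logb[i] = np.log([c.beta for c in mix.components])
        # monotone (PCHIP) interpolation: cubic-spline overshoot between
        # integer levels puts spurious wiggles - hence false local optima -
        # into the regression objective; PCHIP is shape-preserving and C1
        self._splines = {
            "logw": PchipInterpolator(levels, logw, axis=0),
            "loga": PchipInterpolator(levels, loga, axis=0),
            "logb": PchipInterpolator(levels, logb, axis=0),
        }

    # -- evaluation --------------------------------------------------------

    def _params_at(self, mu: np.ndarray, deriv: bool):
        sp = self._splines
        s = sp["logw"](mu)  # (..., K) unnormalised log-weights
        la, lb = sp["loga"](mu), sp["logb"](mu)
        alpha, beta = np.exp(la), np.exp(lb)
        logw = s - logsumexp(s, axis=-1, keepdims=True)
        if not deriv:
            return logw, alpha, beta, None, None, None
        ds = sp["logw"](mu, 1)
        dalpha = alpha * sp["loga"](mu, 1)
        dbeta = beta * sp["logb"](mu, 1)
        return logw, alpha, beta, ds, dalpha, dbeta

    def logpdf(self, y, mu):
        """log p(y | mu); y in dB (untransformed), mu clipped to [0, 35]."""
        logp, _ = self._eval(y, mu, grad=False)
        return logp

    def logpdf_grad(self, y, mu):
        """(log p(y|mu), d log p / d mu), vectorised over matching shapes."""
        return self._eval(y, mu, grad=True)

    def _eval(self, y, mu, grad: bool):
        y = np.asarray(y, dtype=float)
        mu = np.clip(np.asarray(mu, dtype=float), DLS_MIN, DLS_MAX)
        scalar = y.ndim == 0
        ty = np.atleast_1d(transform_dls(y))[..., None]  # (..., 1)
        mu = np.atleast_1d(mu)
        logw, alpha, beta, ds, dalpha, dbeta = self._params_at(mu, grad)
        z = ty / beta
        logz = np.log(z)
        za = np.exp(np.minimum(alpha * logz, 500.0))  # overflow-safe z**alpha
        logf = np.log(alpha) - np.log(beta) + (alpha - 1.0) * logz - za
        terms = logw + logf
        logp = logsumexp(terms, axis=-1)
        if not grad:
            return (float(logp[0]) if scalar else logp), None
        resp = np.exp(terms - logp[..., None])
        dlogw = ds - np.sum(np.exp(logw) * ds, axis=-1, keepdims=True)
        dlogf_da = 1.0 / alpha + logz * (1.0 - za)
        dlogf_db = (alpha / beta) * (za - 1.0)
        dterm = dlogw + dlogf_da * dalpha + dlogf_db * dbeta
        dlogp = np.sum(resp * dterm, axis=-1)
        if scalar:
            return float(logp[0]), float(dlogp[0])
        return logp, dlogp

    def quantiles(self, mu: float, qs, grid_max: float = 50.0, n: int = 4000):
        """Numeric quantiles of the retest density at predicted level mu."""
        ys = np.linspace(1e-6, grid_max, n)
        pdf = np.exp(self.logpdf(ys, np.full_like(ys, mu)))
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        return np.interp(np.asarray(qs, dtype=float), cdf, ys)

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            str(v): {
                "weights": list(m.weights),
                "alphas": [c.alpha for c in m.components],
                "betas": [c.beta for c in m.components],
            }
            for v, m in self.level_mixtures.items()
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RetestModel":
        import os

        if isinstance(source, dict):
            payload = source
        elif isinstance(source, os.PathLike) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        mixtures = {
            int(v): WeibullMixture(
                weights=tuple(d["weights"]),
                components=tuple(
                    WeibullComponent(a, b) for a, b in zip(d["alphas"], d["betas"])
                ),
            )
            for v, d in payload.items()
        }
        return cls(level_mixtures=mixtures)


def fit_retest_model(
    pairs: RetestPairs,
    k_components: int | None = None,
    min_level_points: int = 50,
    symmetric_pairs: bool = True,
    probe_levels: tuple[int, ...] = (5, 20, 30),
    seed: int | None = 0,
    k_max: int = 4,
    n_folds: int = 5,
) -> RetestModel:
    """Fit the full per-level retest model from pooled retest pairs.

    For each integer level v the retest values whose baseline rounds to v
    are collected (pooling +-1 neighbouring levels when fewer than
    ``min_level_points`` are available) and a Weibull mixture is fitted to
    their floor-transformed values.  With ``symmetric_pairs`` each
    unordered pair contributes both orderings, doubling the effective data
    without asserting an ordering.  The component count is selected by
    cross-validated likelihood on the ``probe_levels`` (the maximum of the
    per-probe selections, applied at every level so the parameter splines
    are well defined); pass ``k_components`` to fix it instead.
    """
    base = pairs.frame["baseline_dls"].to_numpy(dtype=float)
    ret = pairs.frame["retest_dls"].to_numpy(dtype=float)
    if symmetric_pairs:
        base, ret = np.concatenate([base, ret]), np.concatenate([ret, base])

    levels = np.arange(int(DLS_MIN), int(DLS_MAX) + 1)
    rounded = np.rint(base).astype(int)

    def level_data(v: int) -> np.ndarray:
        sel = rounded == v
        width = 0
        while sel.sum() < min_level_points:
            width += 1
            sel = np.abs(rounded - v) <= width
            if width > len(levels):
                break
        vals = ret[sel]
        if len(vals) == 0:
            raise ValueError(f"no retest data available for level {v} dB")
        return transform_dls(vals)

    if k_components is None:
        ks = [
            select_k(level_data(v), k_max=k_max, n_folds=n_folds, seed=seed)
            for v in probe_levels
        ]
        k_components = max(ks)

    mixtures: dict[int, WeibullMixture] = {}
    rng = np.random.default_rng(seed)
    for v in levels:
        mix, _ = em_fit(level_data(int(v)), k_components, seed=rng)
        while mix.k < k_components:
            # a pruned component would break the cross-level splines; pad
            # with a vanishing copy of the widest component
            mix = WeibullMixture(
                weights=tuple(
                    list(np.array(mix.weights) * (1 - _WEIGHT_FLOOR))
                    + [_WEIGHT_FLOOR]
                ),
                components=tuple(list(mix.components) + [mix.components[-1]]),
            )
        mixtures[int(v)] = mix
    return RetestModel(level_mixtures=mixtures)
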