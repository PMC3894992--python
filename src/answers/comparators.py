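"""Reference change-detection methods: MD regression and point-wise OLS.

Two conventional detectors serve as comparators for the Bayesian model:

* ordinary least-squares regression of a mean-deviation (MD) style global
  summary — the per-test average departure from a normative per-location
  profile — flagged on a negative slope with p below a threshold;
* point-wise linear regression (PLR) — an independent OLS per location,
  a location deteriorating when its slope is negative with p < 1%, and the
  eye flagged when at least n contiguous locations deteriorate.

"Contiguous" is taken as 4-neighbour grid adjacency with no edges across
the horizontal midline, consistent with the nerve-fibre anatomy; both
choices are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .core import VFSeries
from .grid import VisualFieldGrid

__all__ = ["MDResult", "PLRResult", "ols_fit", "md_regression", "plr"]


def ols_fit(times, values) -> tuple[float, float, float]:
    """OLS line fit: (slope, intercept, two-sided slope p-value).

    p from the t distribution with Q-2 degrees of freedom.  A perfectly
    constant response has an undefined slope SE; its p is set to 1.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or len(t) < 3:
        raise ValueError("need matching 1-D arrays with at least 3 points")
    if np.ptp(t) == 0:
        raise ValueError("degenerate design: all times equal")
    res = linregress(t, y)
    p = float(res.pvalue)
    if not np.isfinite(p):  # zero residual variance
        p = 0.0 if res.slope != 0 and np.allclose(y, res.intercept + res.slope * t) else 1.0
    if np.ptp(y) == 0:
        p = 1.0
    return float(res.slope), float(res.intercept), p


@dataclass(frozen=True)
class MDResult:
    """Mean-deviation summary regression."""

    md_series: np.ndarray  # per-test mean deviation, dB
    slope: float  # dB/year
    p_value: float

    def deteriorating(self, p_threshold: float = 0.05) -> bool:
        return self.slope < 0 and self.p_value < p_threshold


def md_regression(
    series: VFSeries,
    normative: np.ndarray,
    p_threshold: float = 0.05,
) -> MDResult:
    """Regress the mean deviation from a normative profile over time.

    md_i = mean_j (y_ij - normative_j); this is an unweighted mean
    deviation against a supplied normative vector (clinical MD additionally
    age-corrects and eccentricity-weights against a proprietary database).
    """
    normative = np.asarray(normative, dtype=float)
    if normative.shape != (series.n_locations,):
        raise ValueError("normative profile must supply one value per location")
    md = (series.values - normative[None, :]).mean(axis=1)
    slope, _, p = ols_fit(series.times, md)
    return MDResult(md_series=md, slope=slope, p_value=p)


@dataclass(frozen=True)
class PLRResult:
    """Point-wise linear regression with contiguity criteria."""

    slopes: np.ndarray  # per-location dB/year
    p_values: np.ndarray
    deteriorating: np.ndarray  # per-location flag: slope<0 and p<0.01
    clusters: tuple[frozenset, ...]  # maximal connected deteriorating sets

    def decision(self, contiguity_n: int) -> bool:
        """Flag the eye when some cluster has at least n locations."""
        if contiguity_n < 1:
            raise ValueError("contiguity criterion must be >= 1")
        return any(len(c) >= contiguity_n for c in self.clusters)


def _plr_adjacency(
    grid: VisualFieldGrid,
    respect_hemifields: bool = True,
    eight_neighbour: bool = False,
) -> np.ndarray:
    adj = grid.adjacency.copy()
    if eight_neighbour:
        xy = grid.coordinates()
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        adj |= np.isclose(d2, 2 * 6.0**2)
        np.fill_diagonal(adj, False)
    if respect_hemifields:
        hemi = grid.hemifields
        same = hemi[:, None] == hemi[None, :]
        adj &= same
    return adj


def _connected_components(nodes: np.ndarray, adj: np.ndarray) -> tuple[frozenset, ...]:
    nodes = set(int(i) for i in nodes)
    seen: set[int] = set()
    comps = []
    for start in sorted(nodes):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            stack.extend(j for j in np.flatnonzero(adj[i]) if j in nodes and j not in comp)
        seen |= comp
        comps.append(frozenset(comp))
    return tuple(comps)


def plr(
    series: VFSeries,
    p_threshold: float = 0.01,
    respect_hemifields: bool = True,
    eight_neighbour: bool = False,
) -> PLRResult:
    """Point-wise linear regression over the whole field.

    Each location gets its own OLS fit; deteriorating means a negative
    slope with p below ``p_threshold`` (1% by default).  Deteriorating
    locations are grouped into maximal connected clusters under the grid
    adjacency (within-hemifield 4-neighbour by default).
    """
    if series.grid is None:
        raise ValueError("PLR needs the series' grid for contiguity")
    m = series.n_locations
    slopes = np.empty(m)
    pvals = np.empty(m)
    for j in range(m):
        slopes[j], _, pvals[j] = ols_fit(series.times, series.values[:, j])
    det = (slopes < 0) & (pvals < p_threshold)
    adj = _plr_adjacency(series.grid, respect_hemifields, eight_neighbour)
    clusters = _connected_components(np.flatnonzero(det), adj)
    return PLRResult(slopes=slopes, p_values=pvals, deteriorating=det, clusters=clusters)
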