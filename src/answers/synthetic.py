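"""Synthetic visual-field data with realistic measurement structure.

Generates every input the rest of the package consumes, emulating the
statistical features of real perimetry:

* per-location healthy sensitivities around 30 dB with an eccentricity
  fall-off, depressed in damaged eyes;
* retest scatter drawn from a two-component Weibull mixture per true
  level: an on-target component whose spread widens as sensitivity falls,
  plus a low-value "lapse" component whose weight grows with damage — so
  the scatter is skewed, bimodal at mid-range levels, and censored at the
  0 dB floor (values are rounded to integer dB and clipped, producing a
  spike of exact zeros in damaged regions);
* stable series (constant true field plus scatter) and progressing series
  (linear decline in a spatially contiguous same-hemifield cluster).

Defaults mirror the study conditions: 30 eyes tested 12 times for the
retest set (1,980 unordered test pairs), one test per year for cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import VFSeries
from .grid import VisualFieldGrid, build_grid
from .retest import RetestPairs

__all__ = ["GeneratorConfig", "SeriesTruth", "gen_retest_pairs", "gen_cohort",
           "healthy_profile", "draw_observed"]


def healthy_profile(grid: VisualFieldGrid, peak: float = 33.0, falloff: float = 0.12) -> np.ndarray:
    """Per-location healthy mean DLS: ~33 dB centrally, less peripherally."""
    xy = grid.coordinates()
    r = np.hypot(xy[:, 0], xy[:, 1])
    return peak - falloff * r


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator (all rates per year, levels in dB)."""

    n_eyes: int = 30
    n_repeats: int = 12
    # healthy field profile
    peak_dls: float = 33.0
    eccentricity_falloff: float = 0.12  # dB per degree of eccentricity
    # noise model (see draw_observed)
    lapse_weight_floor: float = 0.02
    lapse_weight_span: float = 0.10
    lapse_scale: float = 2.0
    ontarget_shape_min: float = 1.1
    ontarget_shape_span: float = 30.0
    # damage used to cover low levels in retest data
    damage_prob: float = 0.7
    damage_depth_range: tuple[float, float] = (5.0, 40.0)
    # progressing-cohort model
    n_tests: int = 7
    interval_years: float = 1.0
    frac_progressing: float = 0.3
    cluster_size: int = 6
    progression_slope: float = -1.0  # dB/year at cluster locations
    onset_years: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_size < 1 or self.n_eyes < 1:
            raise ValueError("cluster size and eye count must be positive")
        if not 0.0 <= self.frac_progressing <= 1.0:
            raise ValueError("frac_progressing must lie in [0, 1]")


def _noise_params(level: np.ndarray, cfg: GeneratorConfig):
    """Mixture parameters of the observation model at true level(s)."""
    level = np.clip(np.asarray(level, dtype=float), 0.0, 35.0)
    frac = level / 35.0
    w_lapse = cfg.lapse_weight_floor + cfg.lapse_weight_span * (1.0 - frac) ** 2
    shape_on = cfg.ontarget_shape_min + cfg.ontarget_shape_span * frac**2
    # scale so the on-target component's median sits at the true level
    # (median matching stays stable as the shape approaches 1 at the floor)
    scale_on = np.maximum(level, 0.4) / np.log(2.0) ** (1.0 / shape_on)
    # attention lapses read near the floor regardless of the true level
    shape_lapse = np.full_like(level, 1.2)
    scale_lapse = np.full_like(level, cfg.lapse_scale)
    return w_lapse, shape_on, scale_on, shape_lapse, scale_lapse


def draw_observed(level, rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """Observed integer DLS at true level(s): Weibull-mixture scatter,
    rounded to whole dB and censored into [0, 40]."""
    level = np.asarray(level, dtype=float)
    w_lapse, a_on, b_on, a_lp, b_lp = _noise_params(level, cfg)
    lapse = rng.random(level.shape) < w_lapse
    draws = np.where(
        lapse,
        b_lp * rng.weibull(a_lp, size=level.shape),
        b_on * rng.weibull(a_on, size=level.shape),
    )
    return np.clip(np.rint(draws), 0.0, 40.0)


def _eye_true_field(grid: VisualFieldGrid, rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """A fixed true field: healthy profile, possibly with depressed patches."""
    base = healthy_profile(grid, cfg.peak_dls, cfg.eccentricity_falloff)
    base = base + rng.normal(0.0, 1.0, size=base.shape)  # eye-to-eye spread
    if rng.random() < cfg.damage_prob:
        k = rng.integers(3, 13)
        seed_loc = int(rng.integers(grid.n_locations))
        locs = _grow_cluster(grid, seed_loc, int(k), rng)
        lo, hi = cfg.damage_depth_range
        base[list(locs)] -= rng.uniform(lo, hi, size=len(locs))
    return np.clip(base, 0.0, 35.0)


def _grow_cluster(
    grid: VisualFieldGrid, seed_loc: int, size: int, rng: np.random.Generator
) -> set[int]:
    """Random connected within-hemifield cluster grown from a seed location."""
    hemi = grid.hemifields
    adj = grid.adjacency & (hemi[:, None] == hemi[None, :])
    cluster = {seed_loc}
    frontier = set(np.flatnonzero(adj[seed_loc]))
    while len(cluster) < size:
        frontier -= cluster
        if not frontier:
            raise ValueError(
                f"cannot grow a connected cluster of {size} from location {seed_loc}"
            )
        nxt = int(rng.choice(sorted(frontier)))
        cluster.add(nxt)
        frontier |= set(np.flatnonzero(adj[nxt]))
    return cluster


def gen_retest_pairs(cfg: GeneratorConfig | None = None, grid: VisualFieldGrid | None = None) -> RetestPairs:
    """Simulated test-retest study: each eye measured n_repeats times.

    Every eye and location keeps a fixed true level; repeats differ only by
    measurement scatter.  All unordered pairs of repeats are emitted, so 30
    eyes x 12 repeats give 30 * C(12,2) = 1,980 test pairs.
    """
    cfg = cfg or GeneratorConfig()
    grid = grid or build_grid()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    m = grid.n_locations
    for eye in range(cfg.n_eyes):
        truth = _eye_true_field(grid, rng, cfg)
        obs = np.stack(
            [draw_observed(truth, rng, cfg) for _ in range(cfg.n_repeats)]
        )  # n_repeats x M
        for ta in range(cfg.n_repeats):
            for tb in range(ta + 1, cfg.n_repeats):
                rows.append(
                    pd.DataFrame(
                        {
                            "eye_id": f"eye{eye:03d}",
                            "test_a_index": ta,
                            "test_b_index": tb,
                            "location_index": np.arange(m),
                            "baseline_dls": obs[ta],
                            "retest_dls": obs[tb],
                        }
                    )
                )
    return RetestPairs(frame=pd.concat(rows, ignore_index=True))


def gen_repeat_matrices(
    cfg: GeneratorConfig | None = None, grid: VisualFieldGrid | None = None
) -> dict[str, np.ndarray]:
    """Per-eye repeat matrices (n_repeats x M), for pseudo-series building."""
    cfg = cfg or GeneratorConfig()
    grid = grid or build_grid()
    rng = np.random.default_rng(cfg.seed)
    out = {}
    for eye in range(cfg.n_eyes):
        truth = _eye_true_field(grid, rng, cfg)
        out[f"eye{eye:03d}"] = np.stack(
            [draw_observed(truth, rng, cfg) for _ in range(cfg.n_repeats)]
        )
    return out


@dataclass(frozen=True)
class SeriesTruth:
    """Ground truth attached to one generated series."""

    progressing: bool
    true_slopes: np.ndarray  # dB/year per location
    cluster: frozenset = field(default_factory=frozenset)


def gen_cohort(
    cfg: GeneratorConfig | None = None,
    grid: VisualFieldGrid | None = None,
    noise: bool = True,
) -> list[tuple[VFSeries, SeriesTruth]]:
    """Cohort of stable and progressing series with ground-truth labels.

    Stable eyes keep a constant true field; progressing eyes decline
    linearly (from ``onset_years``) at a connected same-hemifield cluster
    of locations.  Scatter is the same observation model as the retest
    generator; ``noise=False`` emits the rounded true levels directly.
    """
    cfg = cfg or GeneratorConfig()
    grid = grid or build_grid()
    rng = np.random.default_rng(cfg.seed)
    n_prog = int(round(cfg.frac_progressing * cfg.n_eyes))
    times = np.arange(cfg.n_tests, dtype=float) * cfg.interval_years
    cohort = []
    for eye in range(cfg.n_eyes):
        progressing = eye < n_prog
        base = _eye_true_field(grid, rng, cfg)
        slopes = np.zeros(grid.n_locations)
        cluster: set[int] = set()
        if progressing:
            seed_loc = int(rng.integers(grid.n_locations))
            cluster = _grow_cluster(grid, seed_loc, cfg.cluster_size, rng)
            slopes[list(cluster)] = cfg.progression_slope
        elapsed = np.maximum(times - cfg.onset_years, 0.0)
        levels = np.clip(base[None, :] + slopes[None, :] * elapsed[:, None], 0.0, 35.0)
        if noise:
            values = draw_observed(levels, rng, cfg)
        else:
            values = np.clip(np.rint(levels), 0.0, 40.0)
        series = VFSeries(times, values, grid, eye_id=f"sim{eye:03d}")
        cohort.append((series, SeriesTruth(progressing, slopes, frozenset(cluster))))
    return cohort
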