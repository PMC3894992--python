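"""False-positive-calibrated evaluation of change detectors.

Detectors can only be compared fairly at matched false-positive rates
(FPR).  The null distribution of any score comes from pseudo-series:
random reorderings (and truncations) of short-interval repeat tests, in
which no true change can exist.  From those null scores an empirical
threshold is chosen per series length and target FPR; detectors are then
compared on cohorts via

* time to detect — run the detector on growing prefixes (minimum length
  3) and record the elapsed time to the first flagged prefix, or the full
  span if never flagged;
* hit rate — the proportion of series flagged; at matched FPR a surrogate
  for sensitivity, since hit rate = p * sensitivity + (1 - p) * FPR for an
  unknown progressing fraction p;
* normalised partial AUC — the area under the hit-rate-vs-FPR curve over
  FPR in [0, 0.15], divided by 0.15 so a perfect detector scores 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.stats import binomtest

from .core import VFSeries
from .grid import VisualFieldGrid

__all__ = [
    "PseudoSeriesSet",
    "ThresholdTable",
    "make_pseudo_series",
    "fpr_estimate",
    "threshold_at_fpr",
    "time_to_detect",
    "hit_rate",
    "partial_auc",
    "benchmark_methods",
]

FPR_GRID_MAX = 0.15  # rates above this are not clinically useful


@dataclass(frozen=True)
class PseudoSeriesSet:
    """Lazy collection of reordered-and-truncated null series.

    Stores the per-eye repeat matrices and the sampled permutations;
    individual series are materialised on iteration, so the full
    combinatorial set (eyes x reorderings x lengths) never needs to sit in
    memory at once.
    """

    repeats: dict[str, np.ndarray]  # eye_id -> (n_repeats x M) matrix
    permutations: dict[str, np.ndarray]  # eye_id -> (n_reorder x n_repeats)
    lengths: tuple[int, ...]
    interval_years: float = 1.0
    grid: VisualFieldGrid | None = None

    def __len__(self) -> int:
        n_reorder = next(iter(self.permutations.values())).shape[0]
        return len(self.repeats) * n_reorder * len(self.lengths)

    def __iter__(self) -> Iterator[tuple[VFSeries, tuple]]:
        """Yields (series, provenance) with provenance (eye_id, reorder, L)."""
        for eye_id, mat in self.repeats.items():
            perms = self.permutations[eye_id]
            for r, perm in enumerate(perms):
                for length in self.lengths:
                    values = mat[perm[:length]]
                    times = np.arange(length, dtype=float) * self.interval_years
                    yield (
                        VFSeries(times, values, self.grid, eye_id=eye_id),
                        (eye_id, r, length),
                    )

    def of_length(self, length: int) -> Iterator[VFSeries]:
        if length not in self.lengths:
            raise ValueError(f"length {length} not in {self.lengths}")
        for series, (_, _, L) in self:
            if L == length:
                yield series


def make_pseudo_series(
    repeats: dict[str, np.ndarray],
    n_reorder: int = 300,
    lengths: Sequence[int] = tuple(range(3, 13)),
    interval_years: float = 1.0,
    seed: int | None = 0,
    grid: VisualFieldGrid | None = None,
    identity_first: bool = False,
) -> PseudoSeriesSet:
    """Build the reordered pseudo-series set from per-eye repeat matrices.

    Each eye's repeats are permuted ``n_reorder`` times (uniformly at
    random, seeded); for every permutation and requested length L the first
    L entries form one pseudo-series with tests ``interval_years`` apart.
    ``identity_first`` forces the first permutation to be the original
    ordering.
    """
    lengths = tuple(int(x) for x in lengths)
    max_len = max(lengths)
    for eye_id, mat in repeats.items():
        if mat.shape[0] < max_len:
            raise ValueError(
                f"eye {eye_id!r} has {mat.shape[0]} repeats; need >= {max_len}"
            )
    rng = np.random.default_rng(seed)
    permutations = {}
    for eye_id, mat in repeats.items():
        n = mat.shape[0]
        perms = np.stack([rng.permutation(n) for _ in range(n_reorder)])
        if identity_first:
            perms[0] = np.arange(n)
        permutations[eye_id] = perms
    return PseudoSeriesSet(
        repeats=dict(repeats),
        permutations=permutations,
        lengths=lengths,
        interval_years=interval_years,
        grid=grid,
    )


def fpr_estimate(decisions) -> tuple[float, tuple[float, float]]:
    """Proportion of null series flagged, with an exact binomial 95% CI."""
    d = np.asarray(list(decisions), dtype=bool)
    if d.size == 0:
        raise ValueError("no decisions supplied")
    k, n = int(d.sum()), int(d.size)
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95)
    return k / n, (float(ci.low), float(ci.high))


def threshold_at_fpr(scores, target_fpr: float) -> float:
    """Empirical score threshold achieving a target FPR on null scores.

    The (1 - target_fpr) empirical quantile of the null scores; a series
    is flagged when its score strictly exceeds the threshold (ties are
    conservative).
    """
    s = np.sort(np.asarray(list(scores), dtype=float))
    n = s.size
    if not 0.0 < target_fpr < 1.0:
        raise ValueError("target_fpr must lie in (0, 1)")
    if n < 100:
        raise ValueError(f"need at least 100 null scores, got {n}")
    if target_fpr < 1.0 / n:
        return float(s[-1])
    k = int(math.floor(target_fpr * n))  # flag the top-k strictly above
    return float(s[n - k - 1])


@dataclass
class ThresholdTable:
    """(method, series length, target FPR) -> decision threshold."""

    table: dict[tuple[str, int, float], float] = field(default_factory=dict)

    def set(self, method: str, length: int, target_fpr: float, threshold: float) -> None:
        self.table[(method, int(length), float(target_fpr))] = float(threshold)

    def get(self, method: str, length: int, target_fpr: float) -> float:
        return self.table[(method, int(length), float(target_fpr))]

    def calibrate(self, method: str, length: int, scores, target_fprs) -> None:
        for f in target_fprs:
            self.set(method, length, f, threshold_at_fpr(scores, f))


def time_to_detect(
    series: VFSeries,
    detector: Callable[[VFSeries], bool],
    min_length: int = 3,
) -> float:
    """Years from the first test to the earliest flagged prefix.

    The detector is run on prefixes of length 3, 4, ..., Q; if no prefix
    is ever flagged the full span of the series is returned.  A detector
    failure on a prefix counts as not flagged.
    """
    if series.n_tests < min_length:
        raise ValueError(f"need at least {min_length} tests")
    for q in range(min_length, series.n_tests + 1):
        prefix = series.prefix(q)
        try:
            flagged = bool(detector(prefix))
        except Exception:  # noqa: BLE001 - detector failure => not flagged
            flagged = False
        if flagged:
            return float(prefix.times[-1] - prefix.times[0])
    return series.span_years


def hit_rate(decisions) -> float:
    """Proportion of series flagged as deteriorating."""
    d = np.asarray(list(decisions), dtype=bool)
    if d.size == 0:
        raise ValueError("no decisions supplied")
    return float(d.mean())


def partial_auc(fprs, hit_rates, fpr_max: float = FPR_GRID_MAX) -> float:
    """Normalised area under the hit-rate curve for FPR in [0, fpr_max].

    Trapezoidal area divided by fpr_max, so an always-right detector
    (hit rate 1 everywhere) scores exactly 1.
    """
    f = np.asarray(fprs, dtype=float)
    h = np.asarray(hit_rates, dtype=float)
    order = np.argsort(f)
    f, h = f[order], h[order]
    if f[0] > 1e-12 or f[-1] < fpr_max - 1e-12:
        raise ValueError(f"FPR grid must cover [0, {fpr_max}]")
    keep = f <= fpr_max + 1e-12
    return float(np.trapezoid(h[keep], f[keep]) / fpr_max)


def benchmark_methods(
    retest,
    grid,
    prior,
    seed: int = 0,
    length: int = 7,
    n_null_eyes: int = 30,
    n_null_repeats: int = 8,
    n_reorder: int = 5,
    cohort_eyes: int = 80,
    frac_progressing: float = 0.3,
    progression_slope: float = -1.0,
    target_fpr: float = 0.05,
    fpr_grid: np.ndarray | None = None,
    ttd_eyes: int = 40,
) -> dict:
    """Calibrated four-way comparison on synthetic data.

    Builds reordered pseudo-series from a synthetic test-retest study and
    calibrates each method's decision threshold to the target
    false-positive rate on those null series - for the S_d detectors and
    MD regression at every prefix length from 3 to ``length``, as the
    time-to-detect protocol requires - then measures hit rate (and the
    normalised partial AUC over the FPR grid) on a labelled cohort, plus
    mean time-to-detect for the spatial Bayesian detector and MD
    regression.

    Returns a nested dict of thresholds, hit rates, sensitivities,
    empirical FPRs, partial AUCs and mean times-to-detect.
    """
    from .comparators import md_regression, plr
    from .core import analyze
    from .synthetic import GeneratorConfig, gen_cohort, gen_repeat_matrices, healthy_profile

    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, FPR_GRID_MAX, 16)
    fpr_grid = np.asarray(fpr_grid, dtype=float)
    normative = healthy_profile(grid)

    lengths = tuple(range(3, length + 1))
    null_cfg = GeneratorConfig(
        seed=seed + 1, n_eyes=n_null_eyes, n_repeats=max(n_null_repeats, length)
    )
    reps = gen_repeat_matrices(null_cfg, grid)
    pseudo = make_pseudo_series(
        reps, n_reorder=n_reorder, lengths=lengths, seed=seed + 2, grid=grid
    )
    null_sd_by_len: dict[int, list] = {L: [] for L in lengths}
    null_md_by_len: dict[int, list] = {L: [] for L in lengths}
    null_scores = {"answers": [], "answer": []}
    null_plr2 = []
    for s, (_, _, L) in pseudo:
        null_sd_by_len[L].append(analyze(s, retest, prior, "ANSWERS").s_d)
        m = md_regression(s, normative)
        null_md_by_len[L].append(m.p_value if m.slope < 0 else 1.0)
        if L == length:
            null_scores["answer"].append(analyze(s, retest, prior, "ANSWER").s_d)
            null_plr2.append(plr(s).decision(2))
    null_scores["answers"] = null_sd_by_len[length]
    null_md_p = np.array(null_md_by_len[length])
    sd_thr_by_len = {
        L: threshold_at_fpr(null_sd_by_len[L], target_fpr) for L in lengths
    }
    md_thr_by_len = {
        L: float(np.quantile(np.array(null_md_by_len[L]), target_fpr))
        for L in lengths
    }

    cohort_cfg = GeneratorConfig(
        seed=seed + 3,
        n_eyes=cohort_eyes,
        n_tests=length,
        frac_progressing=frac_progressing,
        progression_slope=progression_slope,
    )
    cohort = gen_cohort(cohort_cfg, grid)
    labels = np.array([t.progressing for _, t in cohort])
    scores = {"answers": [], "answer": []}
    md_p = []
    plr2 = []
    for s, _ in cohort:
        scores["answers"].append(analyze(s, retest, prior, "ANSWERS").s_d)
        scores["answer"].append(analyze(s, retest, prior, "ANSWER").s_d)
        m = md_regression(s, normative)
        md_p.append(m.p_value if m.slope < 0 else 1.0)
        plr2.append(plr(s).decision(2))
    md_p = np.array(md_p)
    plr2 = np.array(plr2)

    report: dict = {
        "length": length,
        "target_fpr": target_fpr,
        "n_null": len(null_scores["answers"]),
        "n_cohort": cohort_eyes,
        "labels": labels.tolist(),
        "scores": {k: [float(x) for x in v] for k, v in scores.items()},
        "methods": {},
    }

    def summarise(decisions: np.ndarray) -> dict:
        return {
            "hit_rate": float(decisions.mean()),
            "sensitivity": float(decisions[labels].mean()),
            "empirical_fpr": float(decisions[~labels].mean()),
        }

    thresholds = {}
    for name in ("answers", "answer"):
        null = np.array(null_scores[name])
        coh = np.array(scores[name])
        thr = threshold_at_fpr(null, target_fpr)
        thresholds[name] = thr
        entry = {"threshold": float(thr), **summarise(coh > thr)}
        curve = [float(np.mean(coh > threshold_at_fpr(null, f))) if f > 0
                 else float(np.mean(coh > null.max())) for f in fpr_grid]
        entry["partial_auc"] = partial_auc(fpr_grid, curve)
        report["methods"][name] = entry

    md_thr = float(np.quantile(null_md_p, target_fpr))
    entry = {"p_threshold": md_thr, **summarise(md_p < md_thr)}
    curve = [float(np.mean(md_p < np.quantile(null_md_p, f))) if f > 0 else 0.0
             for f in fpr_grid]
    entry["partial_auc"] = partial_auc(fpr_grid, curve)
    report["methods"]["md"] = entry

    report["methods"]["plr2"] = {
        "null_fpr": float(np.mean(null_plr2)),
        **summarise(plr2),
    }

    # time to detect at per-length matched thresholds, on a cohort subset
    subset = cohort[: min(ttd_eyes, len(cohort))]

    def sd_detector(p) -> bool:
        return analyze(p, retest, prior, "ANSWERS").s_d > sd_thr_by_len[p.n_tests]

    def md_detector(p) -> bool:
        r = md_regression(p, normative)
        return r.slope < 0 and r.p_value < md_thr_by_len[p.n_tests]

    ttd = {"answers": [], "md": []}
    for s, _ in subset:
        ttd["answers"].append(time_to_detect(s, sd_detector))
        ttd["md"].append(time_to_detect(s, md_detector))
    report["time_to_detect_years"] = {k: float(np.mean(v)) for k, v in ttd.items()}
    report["sd_threshold_by_length"] = {
        int(L): float(t) for L, t in sd_thr_by_len.items()
    }
    return report
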