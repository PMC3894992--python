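"""Series file formats and the data-curation rules.

Two tabular layouts are accepted for visual-field series:

* wide — one row per test: ``eye_id``, either ``test_date`` (ISO-8601) or
  ``test_date_years`` (decimal years), then ``loc_0`` .. ``loc_51``;
* long — one row per measurement: ``eye_id``, ``time``, ``location_index``,
  ``dls``.

The writer emits the long layout.  Curation applies, in order: the
same-day rule (keep the last test of any day), discarding the first test
(to blunt learning effects), then minimum test-count and follow-up-span
filters.  Missing per-location values are rejected: the model assumes
complete fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import VFSeries
from .grid import VisualFieldGrid

__all__ = ["CurationPolicy", "CurationRejection", "curate",
           "read_series_csv", "write_series_csv"]

_DAYS_PER_YEAR = 365.2425


@dataclass(frozen=True)
class CurationPolicy:
    """Series-inclusion rules."""

    drop_first_test: bool = True
    same_day_rule: bool = True  # keep the last test of a day
    min_tests: int = 3
    min_span_years: float = 0.0

    def __post_init__(self) -> None:
        if self.min_tests < 3:
            raise ValueError("min_tests must be >= 3")


@dataclass(frozen=True)
class CurationRejection:
    eye_id: str
    reason: str


def curate(
    times_years: np.ndarray,
    values: np.ndarray,
    policy: CurationPolicy = CurationPolicy(),
    grid: VisualFieldGrid | None = None,
    eye_id: str = "",
) -> VFSeries | CurationRejection:
    """Apply the curation rules to one raw series.

    ``times_years`` need not start at zero and may contain same-day
    duplicates (equal values); returns either a curated :class:`VFSeries`
    with times rebased to the first retained test, or a rejection record.
    """
    t = np.asarray(times_years, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        return CurationRejection(eye_id, "empty")
    if v.ndim != 2 or v.shape[0] != t.size:
        return CurationRejection(eye_id, "shape_mismatch")
    if not np.all(np.isfinite(v)):
        return CurationRejection(eye_id, "missing_values")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if policy.same_day_rule:
        days = np.floor(t * _DAYS_PER_YEAR).astype(int)
        keep = np.r_[days[:-1] != days[1:], True]  # last test of each day
        t, v = t[keep], v[keep]
    if policy.drop_first_test:
        t, v = t[1:], v[1:]
    if t.size < policy.min_tests:
        return CurationRejection(eye_id, "min_tests")
    if t[-1] - t[0] < policy.min_span_years:
        return CurationRejection(eye_id, "min_span_years")
    return VFSeries(t - t[0], v, grid, eye_id=eye_id)


def _times_from_frame(df: pd.DataFrame) -> np.ndarray:
    if "test_date_years" in df.columns:
        return df["test_date_years"].to_numpy(dtype=float)
    if "test_date" in df.columns:
        dates = pd.to_datetime(df["test_date"], format="ISO8601")
        delta = dates - dates.min()
        return (delta.dt.total_seconds() / (86400.0 * _DAYS_PER_YEAR)).to_numpy()
    raise ValueError("need a test_date or test_date_years column")


def read_series_csv(
    path,
    grid: VisualFieldGrid | None = None,
    policy: CurationPolicy | None = None,
) -> list[VFSeries | CurationRejection]:
    """Read all series from a wide- or long-format CSV, optionally curated."""
    df = pd.read_csv(path)
    if "eye_id" not in df.columns:
        raise ValueError("series file needs an eye_id column")
    long_format = {"time", "location_index", "dls"}.issubset(df.columns)
    out: list[VFSeries | CurationRejection] = []
    for eye_id, sub in df.groupby("eye_id", sort=False):
        if long_format:
            pivot = sub.pivot_table(
                index="time", columns="location_index", values="dls", sort=True
            )
            times = pivot.index.to_numpy(dtype=float)
            values = pivot.to_numpy(dtype=float)
        else:
            loc_cols = sorted(
                (c for c in sub.columns if c.startswith("loc_")),
                key=lambda c: int(c.split("_")[1]),
            )
            if not loc_cols:
                raise ValueError("wide format needs loc_* columns")
            times = _times_from_frame(sub)
            values = sub[loc_cols].to_numpy(dtype=float)
        if policy is None:
            order = np.argsort(times)
            out.append(
                VFSeries(times[order] - times.min(), values[order], grid, eye_id=str(eye_id))
            )
        else:
            out.append(curate(times, values, policy, grid, eye_id=str(eye_id)))
    return out


def write_series_csv(path, series_list: list[VFSeries]) -> None:
    """Write series in the long layout (one row per measurement)."""
    frames = []
    for s in series_list:
        q, m = s.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "eye_id": np.repeat(s.eye_id, q * m),
                    "time": np.repeat(s.times, m),
                    "location_index": np.tile(np.arange(m), q),
                    "dls": s.values.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
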