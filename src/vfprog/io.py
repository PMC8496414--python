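"""Visual-field series containers and tabular I/O.

A visual-field (VF) test records a sensitivity threshold, in integer dB on the
0-50 dB instrument scale, at each of the 54 locations of the 24-2 pattern.  The
instrument floor makes the scale left-censored: any true threshold below 0 dB is
recorded as 0 dB, so a recorded 0 is treated as a censored observation, not as a
measurement of zero sensitivity.

Series are stored in a long CSV format, one row per eye/visit/location::

    eye_id,time_years,location_id,sensitivity_db

Times are decimal years from the series baseline.  All data are stored in the
canonical right-eye orientation (nasal-positive x); the reader can mirror
left-eye charts into this frame (row-wise positional flip of the lattice).

Test-retest sets reuse the same format with ``time_years`` holding the repeat
index; the times carry no meaning for variability modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid24_2, load_grid

__all__ = [
    "VFTest",
    "VFSeries",
    "TestRetestSet",
    "VFDataError",
    "read_series",
    "write_series",
    "read_testretest",
    "write_testretest",
    "mirror_test_values",
]

N_LOCATIONS = 54
DB_MIN, DB_MAX = 0, 50


class VFDataError(ValueError):
    """Malformed or inconsistent visual-field data."""


@dataclass(frozen=True)
class VFTest:
    """One VF examination: a time stamp and 54 pointwise sensitivities.

    ``censored`` flags locations recorded at the 0 dB instrument floor.
    Blind-spot locations are carried along but excluded from every model fit.
    """

    time_years: float
    sensitivities: np.ndarray  # (54,) integer dB

    def __post_init__(self):
        s = np.asarray(self.sensitivities)
        if s.shape != (N_LOCATIONS,):
            raise VFDataError(f"expected {N_LOCATIONS} sensitivities, got {s.shape}")
        if not np.issubdtype(s.dtype, np.integer):
            if not np.allclose(s, np.round(s)):
                raise VFDataError("sensitivities must be integer dB")
            s = np.round(s).astype(int)
        if s.min() < DB_MIN or s.max() > DB_MAX:
            raise VFDataError(
                f"sensitivity out of range [{DB_MIN}, {DB_MAX}]: "
                f"min={s.min()}, max={s.max()}"
            )
        if self.time_years < 0:
            raise VFDataError(f"negative time {self.time_years}")
        object.__setattr__(self, "sensitivities", s.astype(int))

    @property
    def censored(self) -> np.ndarray:
        """Per-location flag: True iff the recorded value sits at 0 dB."""
        return self.sensitivities == 0

    def __eq__(self, other):
        return (
            isinstance(other, VFTest)
            and self.time_years == other.time_years
            and np.array_equal(self.sensitivities, other.sensitivities)
        )


@dataclass(frozen=True)
class VFSeries:
    """Ordered longitudinal sequence of VF tests for one eye."""

    eye_id: str
    tests: tuple  # tuple[VFTest, ...] with strictly increasing times

    def __post_init__(self):
        object.__setattr__(self, "tests", tuple(self.tests))
        times = [t.time_years for t in self.tests]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise VFDataError(f"eye {self.eye_id}: visit times not strictly increasing")

    @property
    def n_tests(self) -> int:
        return len(self.tests)

    @property
    def times(self) -> np.ndarray:
        return np.array([t.time_years for t in self.tests], dtype=float)

    @property
    def values(self) -> np.ndarray:
        """(n_tests, 54) integer sensitivity matrix."""
        return np.stack([t.sensitivities for t in self.tests])

    def truncate(self, n: int) -> "VFSeries":
        """First ``n`` tests as a new series."""
        if n < 1 or n > self.n_tests:
            raise VFDataError(f"cannot truncate series of {self.n_tests} tests to {n}")
        return VFSeries(self.eye_id, self.tests[:n])

    def __eq__(self, other):
        return (
            isinstance(other, VFSeries)
            and self.eye_id == other.eye_id
            and self.tests == other.tests
        )


@dataclass(frozen=True)
class TestRetestSet:
    """Short-interval repeats of the same eye; times are repeat indices."""

    eye_id: str
    tests: tuple

    MIN_REPEATS = 3

    def __post_init__(self):
        object.__setattr__(self, "tests", tuple(self.tests))
        if len(self.tests) < self.MIN_REPEATS:
            raise VFDataError(
                f"eye {self.eye_id}: test-retest requires >= {self.MIN_REPEATS} "
                f"repeats, got {len(self.tests)}"
            )

    @property
    def n_repeats(self) -> int:
        return len(self.tests)

    @property
    def values(self) -> np.ndarray:
        return np.stack([t.sensitivities for t in self.tests])


def mirror_test_values(values: np.ndarray, grid: Grid24_2 | None = None) -> np.ndarray:
    """Mirror a (..., 54) sensitivity array between left- and right-eye charts.

    The flip reverses the reading order within each lattice row, which maps a
    left-eye chart onto the canonical right-eye frame (and is its own inverse).
    """
    grid = grid or load_grid()
    perm = np.empty(N_LOCATIONS, dtype=int)
    for y in np.unique(grid.y_deg):
        idx = np.where(grid.y_deg == y)[0]
        perm[idx] = idx[::-1]
    return np.asarray(values)[..., perm]


_HEADER = ["eye_id", "time_years", "location_id", "sensitivity_db"]


def _frame_to_series(df: pd.DataFrame, cls, mirror_eyes=()):
    out = []
    grid = load_grid()
    for eye_id, g in df.groupby("eye_id", sort=True):
        tests = []
        for time, gt in g.groupby("time_years", sort=True):
            locs = gt["location_id"].to_numpy()
            if sorted(locs.tolist()) != list(range(1, N_LOCATIONS + 1)):
                raise VFDataError(
                    f"eye {eye_id}, time {time}: expected exactly one row per "
                    f"location 1..{N_LOCATIONS}"
                )
            vals = np.empty(N_LOCATIONS)
            vals[locs - 1] = gt["sensitivity_db"].to_numpy()
            if str(eye_id) in mirror_eyes:
                vals = mirror_test_values(vals, grid)
            try:
                tests.append(VFTest(float(time), vals))
            except VFDataError as e:
                raise VFDataError(f"eye {eye_id}, time {time}: {e}") from e
        if cls is VFSeries:
            # equal times collapse into one group above only if identical rows;
            # duplicated visit times show up as >54 rows and fail there.
            out.append(VFSeries(str(eye_id), tests))
        else:
            out.append(TestRetestSet(str(eye_id), tests))
    return out


def _read_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != _HEADER:
        raise VFDataError(f"expected header {_HEADER}, got {list(df.columns)}")
    if df[["time_years", "location_id", "sensitivity_db"]].isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise VFDataError(f"malformed row {bad + 2} (missing value)")
    return df


def read_series(path, mirror_eyes=()) -> list:
    """Read a long-format CSV into a list of :class:`VFSeries`.

    Parameters
    ----------
    mirror_eyes : collection of eye ids recorded as left-eye charts; their
        values are laterally flipped into the right-eye frame.

    Series are returned sorted by eye id, tests by time.
    """
    return _frame_to_series(_read_frame(path), VFSeries, set(map(str, mirror_eyes)))


def read_testretest(path, mirror_eyes=()) -> list:
    """Read a long-format CSV into a list of :class:`TestRetestSet`."""
    return _frame_to_series(
        _read_frame(path), TestRetestSet, set(map(str, mirror_eyes))
    )


def _to_frame(series_list) -> pd.DataFrame:
    rows = {k: [] for k in _HEADER}
    loc_ids = np.arange(1, N_LOCATIONS + 1)
    for s in series_list:
        for t in s.tests:
            rows["eye_id"].extend([s.eye_id] * N_LOCATIONS)
            rows["time_years"].extend([t.time_years] * N_LOCATIONS)
            rows["location_id"].extend(loc_ids.tolist())
            rows["sensitivity_db"].extend(t.sensitivities.tolist())
    return pd.DataFrame(rows)


def write_series(series_list, path) -> None:
    """Write series (or test-retest sets) to the long CSV format.

    Round-trips: ``read_series(write_series(x)) == x``.
    """
    _to_frame(series_list).to_csv(path, index=False)


write_testretest = write_series
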