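"""Hip-accelerometer processing: from minute-level counts to time-use compositions.

The processing chain mirrors a standard large-cohort actigraphy protocol:

1. wake-window filtering (drop registrations during estimated time in bed),
2. non-wear detection (>=60 min of zero counts, allowing short low-count
   interruptions),
3. intensity classification from counts-per-minute (cpm) cut-offs,
4. per-participant summarisation into fractions of wear time spent in
   sedentary (SED), low- (LIPA), moderate- (MPA) and vigorous-intensity
   (VPA) activity, with valid-day accounting,
5. additive log-ratio (alr) transformation of the four-part composition
   with LIPA as the reference component.

All operations accept tidy :class:`pandas.DataFrame` inputs with columns
``participant_id``, ``timestamp`` (minute-resolution) and ``cpm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time as dtime

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCompositionError,
    DomainError,
    InsufficientDataError,
    ResolutionError,
)

__all__ = [
    "WakeWindows",
    "INTENSITY_CUTOFFS",
    "detect_nonwear",
    "nonwear_mask",
    "apply_wake_window",
    "derive_wake_window",
    "classify_intensity",
    "summarize_participants",
    "alr_transform",
    "standardize_alr",
    "select_reference",
]

#: cpm bands for SED / LIPA / MPA / VPA (validated hip-worn cut-offs).
INTENSITY_CUTOFFS = {"SED": (0, 199), "LIPA": (200, 2689), "MPA": (2690, 6166), "VPA": (6167, None)}

PARTS = ("SED", "LIPA", "MPA", "VPA")

#: Maximum low-count interruption length (minutes) inside a non-wear bout.
NONWEAR_MAX_INTERRUPTION = 2
#: Upper cpm bound (inclusive) for a qualifying interruption minute.
NONWEAR_INTERRUPTION_CPM = 199
#: Minimum non-wear bout length in minutes.
NONWEAR_MIN_LENGTH = 60


@dataclass(frozen=True)
class WakeWindows:
    """Wake-time filtering windows (inclusive) for weekdays and weekends."""

    weekday_start: dtime
    weekday_end: dtime
    weekend_start: dtime
    weekend_end: dtime

    def __post_init__(self) -> None:
        if not (self.weekday_start < self.weekday_end and self.weekend_start < self.weekend_end):
            raise ValueError("window start must precede window end within the day")

    @classmethod
    def default(cls) -> "WakeWindows":
        """Cohort defaults: 05:52-23:46 on weekdays, 07:15-23:59 on weekends."""
        return cls(dtime(5, 52), dtime(23, 46), dtime(7, 15), dtime(23, 59))


def _check_minute_grid(timestamps: pd.Series) -> None:
    ts = pd.to_datetime(timestamps)
    if len(ts) > 1:
        deltas = ts.diff().dropna().dt.total_seconds().to_numpy()
        # gaps of whole days are tolerated; sub-minute or off-grid spacing is not
        if np.any(deltas <= 0) or np.any(deltas % 60 != 0):
            raise ResolutionError("count series must be on a strictly increasing 60-s grid")


def detect_nonwear(cpm: np.ndarray | pd.Series) -> list[tuple[int, int]]:
    """Find non-wear bouts in a contiguous minute-level cpm vector.

    A non-wear bout is a maximal run of at least ``NONWEAR_MIN_LENGTH``
    minutes of zero counts, in which interruptions of at most
    ``NONWEAR_MAX_INTERRUPTION`` consecutive minutes with cpm in
    [0, ``NONWEAR_INTERRUPTION_CPM``] are tolerated and counted as part of
    the bout.  Any minute with cpm >= 200, or a low-count run longer than
    2 minutes, terminates the candidate bout.  Bouts begin and end on a
    zero-count minute.

    Returns a list of half-open ``(start, stop)`` index intervals.
    """
    x = np.asarray(cpm)
    if np.any(x < 0):
        raise DomainError("cpm must be non-negative")
    n = len(x)
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if x[i] != 0:
            i += 1
            continue
        start = i
        last_zero = i
        low_run = 0
        j = i + 1
        while j < n:
            if x[j] == 0:
                last_zero = j
                low_run = 0
            elif x[j] <= NONWEAR_INTERRUPTION_CPM:
                low_run += 1
                if low_run > NONWEAR_MAX_INTERRUPTION:
                    break
            else:
                break
            j += 1
        if last_zero - start + 1 >= NONWEAR_MIN_LENGTH:
            intervals.append((start, last_zero + 1))
        i = max(j, last_zero + 1)
    return intervals


def nonwear_mask(cpm: np.ndarray | pd.Series) -> np.ndarray:
    """Boolean mask marking minutes that fall inside a non-wear bout."""
    mask = np.zeros(len(cpm), dtype=bool)
    for start, stop in detect_nonwear(cpm):
        mask[start:stop] = True
    return mask


def apply_wake_window(counts: pd.DataFrame, windows: WakeWindows | None = None) -> pd.DataFrame:
    """Flag minutes inside the applicable wake window (``in_window`` column).

    Weekday vs weekend is decided by the calendar date of each minute
    (weekend = Saturday/Sunday); window bounds are inclusive.
    """
    if windows is None:
        windows = WakeWindows.default()
    out = counts.copy()
    ts = pd.to_datetime(out["timestamp"])
    tod = ts.dt.hour * 60 + ts.dt.minute
    weekend = ts.dt.dayofweek >= 5

    def _mins(t: dtime) -> int:
        return t.hour * 60 + t.minute

    wd = (tod >= _mins(windows.weekday_start)) & (tod <= _mins(windows.weekday_end))
    we = (tod >= _mins(windows.weekend_start)) & (tod <= _mins(windows.weekend_end))
    out["in_window"] = np.where(weekend, we, wd)
    return out


def derive_wake_window(in_bed: pd.DataFrame) -> WakeWindows:
    """Derive wake windows from per-participant-day in-bed intervals.

    The window start is the first quartile of in-bed *end* times (wake-up)
    and the window end the third quartile of in-bed *start* times (bed
    time), computed separately for weekdays and weekends.  Quartiles use
    linear interpolation (numpy default, R type 7) and are rounded to the
    nearest minute.

    Parameters
    ----------
    in_bed : DataFrame with datetime columns ``start`` and ``end``.
    """
    if in_bed.empty:
        raise InsufficientDataError("no in-bed intervals supplied")
    starts = pd.to_datetime(in_bed["start"])
    ends = pd.to_datetime(in_bed["end"])

    def _q(tods: np.ndarray, q: float, label: str) -> dtime:
        if len(tods) == 0:
            raise InsufficientDataError(f"empty stratum: {label}")
        m = int(round(float(np.quantile(tods, q))))
        return dtime(m // 60, m % 60)

    end_tod = (ends.dt.hour * 60 + ends.dt.minute).to_numpy()
    start_tod = (starts.dt.hour * 60 + starts.dt.minute).to_numpy()
    end_weekend = (ends.dt.dayofweek >= 5).to_numpy()
    start_weekend = (starts.dt.dayofweek >= 5).to_numpy()

    return WakeWindows(
        weekday_start=_q(end_tod[~end_weekend], 0.25, "weekday in-bed ends"),
        weekday_end=_q(start_tod[~start_weekend], 0.75, "weekday in-bed starts"),
        weekend_start=_q(end_tod[end_weekend], 0.25, "weekend in-bed ends"),
        weekend_end=_q(start_tod[start_weekend], 0.75, "weekend in-bed starts"),
    )


def classify_intensity(cpm: np.ndarray | pd.Series) -> np.ndarray:
    """Map cpm values onto intensity classes SED/LIPA/MPA/VPA."""
    x = np.asarray(cpm)
    if np.any(x < 0):
        raise DomainError("cpm must be non-negative")
    return np.select(
        [x < 200, x <= 2689, x <= 6166],
        ["SED", "LIPA", "MPA"],
        default="VPA",
    )


def _flag_series(counts: pd.DataFrame, windows: WakeWindows | None) -> pd.DataFrame:
    """Attach in_window, wear and intensity flags, per participant."""
    df = apply_wake_window(counts, windows)
    df = df.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(drop=True)
    wear = np.empty(len(df), dtype=bool)
    for _, idx in df.groupby("participant_id", sort=False).indices.items():
        sub = df.loc[idx]
        _check_minute_grid(sub["timestamp"])
        wear[idx] = ~nonwear_mask(sub["cpm"].to_numpy())
    df["wear"] = wear
    intensity = classify_intensity(df["cpm"].to_numpy())
    df["intensity"] = np.where(df["wear"] & df["in_window"], intensity, "none")
    return df


def summarize_participants(
    counts: pd.DataFrame,
    windows: WakeWindows | None = None,
    min_valid_days: int = 4,
    min_wear_minutes: int = 600,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant time-use composition with valid-day accounting.

    A valid day has strictly more than ``min_wear_minutes`` (default 600,
    i.e. >10 h) of wear time inside the wake window; participants with
    fewer than ``min_valid_days`` valid days are excluded.  Percentages of
    time in each intensity are taken over total wear minutes across valid
    days.  Non-wear is detected on the raw series; wear accounting happens
    after the wake-window filter.

    Returns
    -------
    (compositions, exclusions)
        ``compositions`` has one row per retained participant with minutes
        and percentages per intensity, ``valid_days``, ``wear_minutes`` and
        ``pct_weekend_wear``.  ``exclusions`` lists dropped participants
        with a ``reason`` code.
    """
    df = _flag_series(counts, windows)
    ts = pd.to_datetime(df["timestamp"])
    df["_date"] = ts.dt.date
    df["_weekend"] = ts.dt.dayofweek >= 5
    df["_active"] = df["wear"] & df["in_window"]

    rows, excluded = [], []
    for pid, sub in df.groupby("participant_id", sort=True):
        day_wear = sub.groupby("_date")["_active"].sum()
        valid_days = day_wear.index[day_wear > min_wear_minutes]
        n_valid = len(valid_days)
        if n_valid < min_valid_days:
            excluded.append({"participant_id": pid, "reason": "insufficient_valid_days",
                             "valid_days": n_valid})
            continue
        mins = sub[sub["_active"] & sub["_date"].isin(valid_days)]
        total = len(mins)
        counts_by = mins["intensity"].value_counts()
        row = {"participant_id": pid, "valid_days": n_valid, "wear_minutes": total}
        for part in PARTS:
            m = int(counts_by.get(part, 0))
            row[f"min_{part}"] = m
            row[f"pct_{part}"] = 100.0 * m / total
        row["pct_weekend_wear"] = 100.0 * float(mins["_weekend"].sum()) / total
        rows.append(row)

    comp = pd.DataFrame(rows)
    excl = pd.DataFrame(excluded, columns=["participant_id", "reason", "valid_days"])
    return comp, excl


def alr_transform(
    compositions: pd.DataFrame,
    reference: str = "LIPA",
    vpa_shift: float = 0.1,
    shift_all_rows: bool = True,
) -> pd.DataFrame:
    """Additive log-ratio coordinates of the four-part time-use composition.

    ``vpa_shift`` (default 0.1 percentage points) is added to VPA before
    the transform to remove zeros; with ``shift_all_rows`` (default) it is
    a uniform shift applied to every row, otherwise only to zero rows.
    After transformation, rows whose *original* part value was zero are
    assigned, per coordinate, the minimum transformed value among rows
    whose original value was non-zero.

    Expects columns ``pct_SED``, ``pct_LIPA``, ``pct_MPA``, ``pct_VPA``;
    returns a frame with ``alr_<part>`` for each non-reference part.
    """
    parts = {p: compositions[f"pct_{p}"].to_numpy(dtype=float) for p in PARTS}
    for p, v in parts.items():
        if np.any(v < 0):
            raise DomainError(f"negative {p} percentage")
    ref = parts[reference]
    if np.any(ref <= 0):
        raise DegenerateCompositionError(f"reference component {reference} is zero for some rows")

    out = pd.DataFrame(index=compositions.index)
    if "participant_id" in compositions:
        out["participant_id"] = compositions["participant_id"]
    for p in PARTS:
        if p == reference:
            continue
        orig = parts[p]
        val = orig.copy()
        if p == "VPA" and vpa_shift:
            val = val + vpa_shift if shift_all_rows else np.where(val == 0, vpa_shift, val)
        with np.errstate(divide="ignore"):
            coord = np.log(val / ref)
        zero = orig == 0
        if zero.any():
            if (~zero).any():
                coord[zero] = coord[~zero].min()
            elif not (p == "VPA" and vpa_shift):
                raise DegenerateCompositionError(f"component {p} is zero in every row")
        if not np.all(np.isfinite(coord)):
            raise DegenerateCompositionError(f"non-finite alr coordinate for {p}")
        out[f"alr_{p}"] = coord
    return out


def standardize_alr(alr: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """z-score the alr coordinates (columns named ``alr_*`` -> ``z_alr_*``)."""
    out = alr.copy()
    for col in [c for c in alr.columns if c.startswith("alr_")]:
        v = alr[col].to_numpy(dtype=float)
        out["z_" + col] = (v - v.mean()) / v.std(ddof=ddof)
    return out


def select_reference(compositions: pd.DataFrame, vpa_shift: float = 0.1) -> tuple[str, pd.DataFrame]:
    """Pick the alr reference giving the least-correlated coordinates.

    For each candidate reference the pairwise Pearson correlations among
    the three resulting alr coordinates are computed; the candidate with
    the smallest mean absolute off-diagonal correlation wins.  Returns the
    winner and a diagnostics table (one row per candidate).
    """
    if len(compositions) < 3:
        raise InsufficientDataError("need at least 3 rows to compare references")
    diag = []
    for ref in PARTS:
        try:
            coords = alr_transform(compositions, reference=ref, vpa_shift=vpa_shift)
        except DegenerateCompositionError:
            diag.append({"reference": ref, "mean_abs_corr": np.inf})
            continue
        mat = coords[[c for c in coords.columns if c.startswith("alr_")]].to_numpy()
        r = np.corrcoef(mat, rowvar=False)
        off = r[np.triu_indices_from(r, k=1)]
        diag.append({"reference": ref, "mean_abs_corr": float(np.mean(np.abs(off))),
                     **{f"r_{i}{j}": float(r[i, j]) for i in range(3) for j in range(i + 1, 3)}})
    table = pd.DataFrame(diag)
    best = table.loc[table["mean_abs_corr"].idxmin(), "reference"]
    return str(best), table
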