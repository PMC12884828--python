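"""From raw EMA tables to the analysis-ready lagged dataset.

Covers composite scoring (0-100 sliders averaged, reverse-coding, /10
rescale), time-in-bed from 12-h clock strings with a deterministic
recoding ladder, adjacent-beep lag construction with within-day/overnight
dummy coding and interval filters, and the centering/decomposition used
by the moderation models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(KeyError):
    """A required column is missing from the input table."""


class DataError(ValueError):
    """The input table violates a structural assumption (e.g. duplicates)."""


# ----------------------------------------------------------------------
# composites
# ----------------------------------------------------------------------
@dataclass
class CompositeSpec:
    """How to score one composite from its 0-100 slider items."""

    name: str
    items: list[str]
    reverse_coded: list[str] = field(default_factory=list)
    input_range: tuple[float, float] = (0.0, 100.0)
    rescale_divisor: float = 10.0

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("items must be non-empty")
        extra = set(self.reverse_coded) - set(self.items)
        if extra:
            raise ValueError(f"reverse_coded items not in items: {sorted(extra)}")


def compute_composite(rows: pd.DataFrame, spec: CompositeSpec) -> pd.Series:
    """Average answered items (reverse-coding first) and rescale to 0-10.

    Missing items are skipped; a row with no answered items gets NaN.
    """
    missing = [c for c in spec.items if c not in rows.columns]
    if missing:
        raise SchemaError(f"missing item columns for {spec.name}: {missing}")
    lo, hi = spec.input_range
    vals = rows[spec.items].astype(float).copy()
    for col in spec.reverse_coded:
        vals[col] = (hi + lo) - vals[col]
    out = vals.mean(axis=1, skipna=True) / spec.rescale_divisor
    out.name = spec.name
    return out


# ----------------------------------------------------------------------
# time in bed
# ----------------------------------------------------------------------
_CLOCK_RE = re.compile(r"^\s*(\d{1,2}):(\d{2})\s*(AM|PM)\s*$", re.IGNORECASE)


def _parse_clock(value: str) -> float:
    """12-h clock string -> hours since midnight."""
    m = _CLOCK_RE.match(str(value))
    if not m:
        raise ValueError(f"unparseable clock time: {value!r}")
    h, mnt, suffix = int(m.group(1)), int(m.group(2)), m.group(3).upper()
    if not (1 <= h <= 12) or mnt > 59:
        raise ValueError(f"unparseable clock time: {value!r}")
    h = h % 12
    if suffix == "PM":
        h += 12
    return h + mnt / 60.0


def _duration(bed: float, rise: float) -> float:
    d = rise - bed
    return d + 24.0 if d <= 0 else d


def compute_time_in_bed(
    bed_time: str,
    rise_time: str,
    plausibility: tuple[float, float] = (2.0, 16.0),
) -> float:
    """Hours from bed time to rise time with AM/PM-slip recoding.

    The raw duration (adding 24 h when rise precedes bed on the clock) is
    accepted if it falls inside the plausibility window. Durations above
    the window are treated as the classic AM/PM entry slip and recoded by
    toggling AM/PM on the bed time first, then on the rise time, keeping
    the first plausible result. Durations below the window indicate an
    unrecoverable entry error and are marked missing (NaN), as are
    unparseable strings.
    """
    try:
        bed = _parse_clock(bed_time)
        rise = _parse_clock(rise_time)
    except ValueError:
        return float("nan")
    lo, hi = plausibility
    d = _duration(bed, rise)
    if lo <= d <= hi:
        return d
    if d < lo:
        return float("nan")
    for cand in (_duration((bed + 12.0) % 24.0, rise), _duration(bed, (rise + 12.0) % 24.0)):
        if lo <= cand <= hi:
            return cand
    return float("nan")


def add_time_in_bed(
    mornings: pd.DataFrame, plausibility: tuple[float, float] = (2.0, 16.0)
) -> pd.DataFrame:
    """Attach a ``time_in_bed`` column computed from clock strings."""
    out = mornings.copy()
    out["time_in_bed"] = [
        compute_time_in_bed(b, r, plausibility)
        for b, r in zip(out["bed_time"], out["rise_time"])
    ]
    return out


# ----------------------------------------------------------------------
# lag construction
# ----------------------------------------------------------------------
DEFAULT_GAP_BOUNDS = {"withinday": (1.0, 4.0), "overnight": (10.0, 17.0)}


def construct_lags(
    beeps: pd.DataFrame,
    gap_bounds: dict[str, tuple[float, float]] | None = None,
    outcomes: tuple[str, ...] = ("na", "pa"),
    drop_non_prompted: bool = True,
    beeps_per_day: int | None = None,
) -> pd.DataFrame:
    """Augment answered beeps with adjacent-beep lags and interval dummies.

    Only directly adjacent *scheduled* beeps form an interval: the lag of
    a beep is the previous scheduled beep's composite when that beep was
    answered, and missing otherwise (a skipped beep breaks the chain).
    ``withinday`` is 1 on same-day scheduled adjacencies with a gap inside
    within-day bounds; ``overnight`` is 1 on the first beep of a day when
    the previous day's last scheduled beep was answered and the gap falls
    inside overnight bounds. Out-of-bounds gaps (e.g. a 4.5 h same-day
    gap) leave the lag missing; such rows are retained but flagged
    ineligible for the likelihood.

    ``beeps_per_day`` identifies the last scheduled beep of a day;
    inferred as the largest beep index present when not given.
    """
    bounds = gap_bounds or DEFAULT_GAP_BOUNDS
    wd_lo, wd_hi = bounds["withinday"]
    on_lo, on_hi = bounds["overnight"]

    df = beeps.copy()
    if drop_non_prompted and "prompted" in df.columns:
        df = df[df["prompted"].astype(bool)]
    df = df.sort_values(["person_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(subset=["person_id", "timestamp"]).any():
        raise DataError("duplicate (person_id, timestamp) rows")
    last_beep = beeps_per_day if beeps_per_day is not None else int(df["beep"].max())

    same_person = df["person_id"].eq(df["person_id"].shift())
    gap = df["timestamp"] - df["timestamp"].shift()
    gap = gap.where(same_person)
    prev = df.groupby("person_id", sort=False)[["wave", "day", "beep"]].shift()
    same_day = same_person & (df["wave"] == prev["wave"]) & (df["day"] == prev["day"])
    adj_within = same_day & (df["beep"] == prev["beep"] + 1)
    adj_overnight = (
        same_person
        & (df["wave"] == prev["wave"])
        & (df["day"] == prev["day"] + 1)
        & (df["beep"] == 1)
        & (prev["beep"] == last_beep)
    )

    withinday = (adj_within & gap.between(wd_lo, wd_hi)).astype(int)
    overnight = (adj_overnight & gap.between(on_lo, on_hi)).astype(int)
    eligible = (withinday + overnight) == 1

    df["adjacent"] = (adj_within | adj_overnight).fillna(False).astype(bool)
    df["gap"] = gap
    df["withinday"] = withinday
    df["overnight"] = overnight
    df["eligible"] = eligible
    for col in outcomes:
        lagged = df.groupby("person_id", sort=False)[col].shift()
        df[f"{col}_lag"] = lagged.where(eligible)
    # NaN composites at the previous beep also make the row ineligible
    df["eligible"] = df["eligible"] & df[[f"{c}_lag" for c in outcomes]].notna().all(axis=1)
    return df


def exclusion_report(lagged: pd.DataFrame) -> dict[str, int]:
    """Counts of rows by lag-eligibility reason (for a JSON audit file).

    ``no_previous_beep`` covers rows without a scheduled-adjacent answered
    predecessor (burst starts, skipped beeps, cross-wave transitions);
    ``gap_out_of_bounds`` counts adjacent pairs whose interval falls
    outside the within-day/overnight windows.
    """
    n = len(lagged)
    adjacent = lagged["adjacent"].astype(bool)
    no_prev = int((~adjacent).sum())
    oob = int((adjacent & ~lagged["eligible"]).sum())
    return {
        "rows": n,
        "eligible": int(lagged["eligible"].sum()),
        "no_previous_beep": no_prev,
        "gap_out_of_bounds": oob,
    }


# ----------------------------------------------------------------------
# centering / decomposition
# ----------------------------------------------------------------------
def center_and_decompose(
    lagged: pd.DataFrame,
    mode: str = "uncentered",
    outcomes: tuple[str, ...] = ("na", "pa"),
    time_varying: tuple[str, ...] = (),
    traits: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Apply the lag-centering mode and within/between decompositions.

    ``mode='uncentered'`` keeps the raw lag (used for estimating the
    inertia contrasts, where centering would bias the autoregressive
    slope); ``mode='person_mean'`` adds ``<outcome>_lag_centered``
    columns (used by the moderation models). Each time-varying covariate
    gains ``<name>_within`` (person-mean-centered) and ``<name>_between``
    (person mean minus grand mean); traits are grand-mean centered into
    ``<name>_centered``.
    """
    if mode not in ("uncentered", "person_mean"):
        raise ValueError(f"unknown centering mode {mode!r}")
    df = lagged.copy()
    grp = df.groupby("person_id", sort=False)
    if mode == "person_mean":
        for col in outcomes:
            lag = f"{col}_lag"
            pmean = grp[lag].transform("mean")
            df[f"{lag}_centered"] = df[lag] - pmean
    for name in time_varying:
        if name not in df.columns:
            raise SchemaError(f"missing covariate column {name!r}")
        pmean = grp[name].transform("mean")
        df[f"{name}_within"] = df[name] - pmean
        df[f"{name}_between"] = pmean - pmean.mean()
    for name in traits:
        if name not in df.columns:
            raise SchemaError(f"missing trait column {name!r}")
        df[f"{name}_centered"] = df[name] - df[name].mean()
    return df
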