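"""Geologic-timescale bookkeeping.

Stage boundary tables, stage-by-stage recalibration of age-indexed series
between chart editions, and the named-event timeline used by the
junction-disjunction model of the Siberian Land Bridge (SLB).

Age convention (package-wide): ages are in Ma before present, larger is
older.  Intervals are written ``(older, younger)`` and treated as half-open
``[older, younger)`` so adjacent intervals never double-count a boundary
instant; an instant on a boundary belongs to the older interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MODEL_SPAN = (350.0, 250.0)
"""Older/younger bounds (Ma) of the Late Palaeozoic model span."""


class TimescaleError(ValueError):
    """Raised for invalid timescales, unknown stages or out-of-range ages."""


class ValidationError(ValueError):
    """Raised when an event timeline fails validation."""


# ---------------------------------------------------------------------------
# GeoTimescale


@dataclass(frozen=True)
class Stage:
    name: str
    base_age: float  # Ma, older bound
    top_age: float   # Ma, younger bound

    def __post_init__(self) -> None:
        if not self.base_age > self.top_age:
            raise TimescaleError(
                f"stage {self.name!r}: base_age ({self.base_age}) must be "
                f"older than top_age ({self.top_age})"
            )


@dataclass(frozen=True)
class GeoTimescale:
    """An ordered, contiguous sequence of chronostratigraphic stages.

    Stages are ordered oldest first; stage *i*'s top age must equal stage
    *i+1*'s base age (contiguity), and ages strictly decrease toward the
    present.
    """

    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise TimescaleError("timescale needs at least one stage")
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise TimescaleError("duplicate stage names")
        for a, b in zip(self.stages, self.stages[1:]):
            if not math.isclose(a.top_age, b.base_age, abs_tol=1e-9):
                raise TimescaleError(
                    f"stages {a.name!r} and {b.name!r} are not contiguous "
                    f"({a.top_age} != {b.base_age})"
                )

    @property
    def span(self) -> tuple[float, float]:
        return (self.stages[0].base_age, self.stages[-1].top_age)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.stages)

    def boundaries(self) -> np.ndarray:
        """All stage boundary ages, oldest first (len = n_stages + 1)."""
        out = [self.stages[0].base_age]
        out.extend(s.top_age for s in self.stages)
        return np.asarray(out, dtype=float)

    def stage_of(self, age: float) -> Stage:
        base, top = self.span
        if not (base >= age >= top):
            raise TimescaleError(f"age {age} Ma outside timescale span {self.span}")
        for s in self.stages:
            if s.base_age >= age > s.top_age:
                return s
        return self.stages[-1]  # age == youngest top

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeoTimescale":
        required = {"stage", "base_age_ma", "top_age_ma"}
        missing = required - set(df.columns)
        if missing:
            raise TimescaleError(f"missing columns: {sorted(missing)}")
        stages = tuple(
            Stage(str(r.stage), float(r.base_age_ma), float(r.top_age_ma))
            for r in df.itertuples()
        )
        return cls(stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.name for s in self.stages],
                "base_age_ma": [s.base_age for s in self.stages],
                "top_age_ma": [s.top_age for s in self.stages],
            }
        )


def load_timescale(source: str | Path) -> GeoTimescale:
    """Read a timescale from a CSV with columns stage,base_age_ma,top_age_ma."""
    return GeoTimescale.from_frame(pd.read_csv(source))


# ---------------------------------------------------------------------------
# Recalibration


def recalibrate_ages(
    ages: Sequence[float] | np.ndarray,
    old_ts: GeoTimescale,
    new_ts: GeoTimescale,
) -> np.ndarray:
    """Remap sample ages from one chart edition onto another, stage by stage.

    Each age is mapped piecewise-linearly within its containing stage: the
    old stage base maps onto the new base and the old top onto the new top.
    Because stages are contiguous this is a single piecewise-linear map over
    the shared boundary ladder; it is the identity when the charts agree,
    strictly order-preserving, and exactly invertible by swapping the charts.
    """
    if old_ts.names != new_ts.names:
        raise TimescaleError(
            "timescales must share the same ordered stage names; got "
            f"{old_ts.names} vs {new_ts.names}"
        )
    ages = np.asarray(ages, dtype=float)
    base, top = old_ts.span
    if ages.size and (ages.max() > base or ages.min() < top):
        bad = ages[(ages > base) | (ages < top)]
        raise TimescaleError(
            f"sample ages {bad.tolist()} outside old timescale span {old_ts.span}"
        )
    # np.interp needs increasing x; boundary ladders are strictly decreasing.
    old_nodes = old_ts.boundaries()[::-1]
    new_nodes = new_ts.boundaries()[::-1]
    return np.interp(ages, old_nodes, new_nodes)


def recalibrate_series(
    series: pd.DataFrame,
    old_ts: GeoTimescale,
    new_ts: GeoTimescale,
    age_column: str = "age_ma",
) -> pd.DataFrame:
    """Recalibrate the age column of a table; all other columns untouched."""
    if age_column not in series.columns:
        raise TimescaleError(f"series lacks age column {age_column!r}")
    out = series.copy()
    out[age_column] = recalibrate_ages(out[age_column].to_numpy(), old_ts, new_ts)
    return out


# ---------------------------------------------------------------------------
# EventTimeline


EVENT_KINDS = frozenset(
    {
        "lowstand",
        "transgression",
        "failed_transgression",
        "glacial_onset",
        "glacial_end",
        "zone_boundary",
    }
)


@dataclass(frozen=True)
class Event:
    """A named, dated event: either a point age or an (older, younger) window.

    ``age`` on an interval event returns its onset (older bound), matching
    how sequence boundaries are quoted by their nominal ages.
    """

    name: str
    kind: str
    point_age: float | None = None
    older: float | None = None
    younger: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"event {self.name!r}: unknown kind {self.kind!r}")
        has_point = self.point_age is not None
        has_interval = self.older is not None or self.younger is not None
        if has_point == has_interval:
            raise ValidationError(
                f"event {self.name!r}: give a point age or an interval, not both"
            )
        if has_interval:
            if self.older is None or self.younger is None:
                raise ValidationError(f"event {self.name!r}: incomplete interval")
            if not self.older > self.younger:
                raise ValidationError(
                    f"event {self.name!r}: interval must have older > younger"
                )

    @property
    def is_interval(self) -> bool:
        return self.older is not None

    @property
    def age(self) -> float:
        """Nominal age: the point age, or the onset of an interval event."""
        return float(self.point_age if self.point_age is not None else self.older)

    @property
    def window(self) -> tuple[float, float]:
        """The event's time window; a point event is a degenerate window."""
        if self.is_interval:
            return (float(self.older), float(self.younger))
        return (float(self.point_age), float(self.point_age))


@dataclass(frozen=True)
class EventTimeline:
    events: tuple[Event, ...]
    span: tuple[float, float] = MODEL_SPAN

    def __post_init__(self) -> None:
        names = [e.name for e in self.events]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate event names: {dupes}")
        older, younger = self.span
        for e in self.events:
            lo, hi = e.window
            if lo > older or hi < younger:
                raise ValidationError(
                    f"event {e.name!r} ({e.window}) outside model span {self.span}"
                )

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __getitem__(self, name: str) -> Event:
        for e in self.events:
            if e.name == name:
                return e
        raise KeyError(name)

    def of_kind(self, *kinds: str) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.kind in kinds)

    def glacial_periods(self) -> dict[str, tuple[float, float]]:
        """Pair ``<name> onset`` / ``<name> end`` rows into (onset, end) spans."""
        onsets = {e.name.rsplit(" ", 1)[0]: e.age for e in self.of_kind("glacial_onset")}
        ends = {e.name.rsplit(" ", 1)[0]: e.age for e in self.of_kind("glacial_end")}
        periods: dict[str, tuple[float, float]] = {}
        for name, onset in onsets.items():
            if name not in ends:
                raise ValidationError(f"glacial period {name!r} has no end event")
            end = ends[name]
            if onset < end:
                raise ValidationError(
                    f"glacial period {name!r}: onset {onset} younger than end {end}"
                )
            periods[name] = (onset, end)
        return periods

    @classmethod
    def from_frame(cls, df: pd.DataFrame, span: tuple[float, float] = MODEL_SPAN) -> "EventTimeline":
        required = {"name", "age_ma", "older_ma", "younger_ma", "kind", "notes"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        events = []
        for r in df.itertuples():
            point = None if pd.isna(r.age_ma) else float(r.age_ma)
            older = None if pd.isna(r.older_ma) else float(r.older_ma)
            younger = None if pd.isna(r.younger_ma) else float(r.younger_ma)
            notes = "" if pd.isna(r.notes) else str(r.notes)
            events.append(
                Event(str(r.name), str(r.kind), point, older, younger, notes)
            )
        return cls(tuple(events), span)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "name": e.name,
                    "age_ma": e.point_age,
                    "older_ma": e.older,
                    "younger_ma": e.younger,
                    "kind": e.kind,
                    "notes": e.notes,
                }
            )
        return pd.DataFrame(rows, columns=["name", "age_ma", "older_ma", "younger_ma", "kind", "notes"])


def load_event_timeline(
    source: str | Path, span: tuple[float, float] = MODEL_SPAN
) -> EventTimeline:
    """Read and validate an event timeline from CSV.

    Columns: ``name,age_ma,older_ma,younger_ma,kind,notes`` — each row gives
    either a point ``age_ma`` or an (``older_ma``, ``younger_ma``) interval.
    """
    return EventTimeline.from_frame(pd.read_csv(source), span=span)
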