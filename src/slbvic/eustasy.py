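"""Eustatic sea-level curve handling.

The model's driving signal is a reference sea-level curve.  Maximal
sub-threshold intervals of the curve are exposure windows of the Siberian
Land Bridge (SLB): terrestrial *junction* phases of Pangaea.  Everything
else is *disjunction* (the land bridge flooded, east and west Pangaea
isolated).  After a configurable mode-switch age (the Kungurian/Roadian
boundary by default) the curve no longer tracks the seaway because of
orogeny, and phases are taken from a named event timeline instead: the
default state is terrestrial (junction) and transgression events create
disjunction intervals.

Conventions: ages in Ma, strictly decreasing along a curve (oldest first);
intervals half-open ``[older, younger)``.  A level exactly equal to the
threshold counts as exposed (ties resolve toward junction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .timescale import EventTimeline, ValidationError

KUNGURIAN_ROADIAN_SWITCH = 273.0
"""Default active->passive mode-switch age (Ma): Kungurian/Roadian boundary."""


class CurveError(ValueError):
    """Raised for empty or non-monotone sea-level curves."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class SeaLevelCurve:
    """An age-ordered eustatic level series (ages strictly decreasing)."""

    ages: np.ndarray
    levels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "levels", levels)
        if ages.size == 0:
            raise CurveError("empty sea-level curve")
        if ages.shape != levels.shape:
            raise CurveError("ages and levels differ in length")
        if not np.all(np.diff(ages) < 0):
            raise CurveError("curve ages must be strictly decreasing (oldest first)")
        if not np.all(np.isfinite(levels)):
            raise CurveError("curve levels must be finite")

    @property
    def span(self) -> tuple[float, float]:
        return (float(self.ages[0]), float(self.ages[-1]))

    def level_at(self, age: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated level; ages may be scalar or array."""
        return np.interp(-np.asarray(age, dtype=float), -self.ages, self.levels)

    def restrict(self, older: float, younger: float) -> "SeaLevelCurve":
        mask = (self.ages <= older) & (self.ages >= younger)
        return SeaLevelCurve(self.ages[mask], self.levels[mask], self.label)


@dataclass(frozen=True)
class ThresholdSpec:
    """Exposure threshold: level at-or-below which the SLB is emergent.

    ``min_duration`` discards sub-threshold blips shorter than the given
    length (My); ``merge_gap`` fuses exposure windows separated by flooded
    gaps shorter than the given length (My).
    """

    level: float
    min_duration: float = 0.2
    merge_gap: float = 0.1

    def __post_init__(self) -> None:
        if self.min_duration < 0 or self.merge_gap < 0:
            raise ValueError("min_duration and merge_gap must be >= 0")


@dataclass(frozen=True)
class PhaseInterval:
    """One junction (land bridge emergent) or disjunction (flooded) phase."""

    kind: str  # "junction" | "disjunction"
    older: float
    younger: float
    label: str = ""
    mode: str = "active"  # "active" (curve-driven) | "passive" (event-driven)
    glacials: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("junction", "disjunction"):
            raise ValueError(f"bad phase kind {self.kind!r}")
        if self.mode not in ("active", "passive"):
            raise ValueError(f"bad mode {self.mode!r}")
        if not self.older > self.younger:
            raise ValueError(
                f"phase interval needs older > younger, got ({self.older}, {self.younger})"
            )

    @property
    def onset(self) -> float:
        return self.older

    @property
    def duration(self) -> float:
        return self.older - self.younger

    def contains(self, age: float) -> bool:
        """Half-open membership: the onset instant belongs to this interval."""
        return self.older >= age > self.younger

    def overlaps(self, older: float, younger: float) -> bool:
        return self.older > younger and older > self.younger


@dataclass(frozen=True)
class PhaseTimeline:
    """Alternating junction/disjunction intervals tiling a time span."""

    intervals: tuple[PhaseInterval, ...]
    span: tuple[float, float]

    def __post_init__(self) -> None:
        older, younger = self.span
        if not older > younger:
            raise ValueError("timeline span needs older > younger")
        if self.intervals:
            if self.intervals[0].older != older or self.intervals[-1].younger != younger:
                raise ValueError("intervals do not tile the span")
            for a, b in zip(self.intervals, self.intervals[1:]):
                if abs(a.younger - b.older) > 1e-9:
                    raise ValueError(
                        f"gap/overlap between intervals at {a.younger} vs {b.older}"
                    )
                if a.kind == b.kind:
                    raise ValueError("junction/disjunction kinds must alternate")

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def of_kind(self, kind: str) -> tuple[PhaseInterval, ...]:
        return tuple(iv for iv in self.intervals if iv.kind == kind)

    @property
    def junctions(self) -> tuple[PhaseInterval, ...]:
        return self.of_kind("junction")

    @property
    def disjunctions(self) -> tuple[PhaseInterval, ...]:
        return self.of_kind("disjunction")

    def at(self, age: float) -> PhaseInterval:
        """The interval containing an instant (onset belongs to its interval)."""
        older, younger = self.span
        if not older >= age >= younger:
            raise ValueError(f"age {age} outside timeline span {self.span}")
        for iv in self.intervals:
            if iv.contains(age):
                return iv
        return self.intervals[-1]  # age == youngest bound

    def index_of(self, interval: PhaseInterval) -> int:
        return self.intervals.index(interval)


# ---------------------------------------------------------------------------
# Exposure-window detection


def _threshold_crossings(curve: SeaLevelCurve, level: float) -> list[tuple[float, float]]:
    """Maximal sub-threshold windows [older, younger] with interpolated edges."""
    ages, levels = curve.ages, curve.levels
    below = levels <= level
    windows: list[tuple[float, float]] = []
    start: float | None = None
    for i in range(len(ages)):
        if below[i] and start is None:
            if i == 0:
                start = float(ages[0])
            else:
                # interpolate crossing between samples i-1 (above) and i
                a0, a1 = ages[i - 1], ages[i]
                l0, l1 = levels[i - 1], levels[i]
                frac = (l0 - level) / (l0 - l1)
                start = float(a0 + frac * (a1 - a0))
        elif not below[i] and start is not None:
            a0, a1 = ages[i - 1], ages[i]
            l0, l1 = levels[i - 1], levels[i]
            frac = (l0 - level) / (l0 - l1)
            end = float(a0 + frac * (a1 - a0))
            windows.append((start, end))
            start = None
    if start is not None:
        windows.append((start, float(ages[-1])))
    return windows


def detect_exposure_windows(
    curve: SeaLevelCurve,
    thr: ThresholdSpec,
    labels: EventTimeline | None = None,
) -> PhaseTimeline:
    """Detect SLB exposure (junction) windows by threshold crossing.

    Every maximal interval where the interpolated level is at-or-below the
    threshold, lasting at least ``thr.min_duration``, becomes a junction;
    windows separated by flooded gaps shorter than ``thr.merge_gap`` are
    merged first.  The remainder of the curve span is disjunction, so the
    returned timeline tiles the span exactly.

    If ``labels`` is given, each junction is labelled with the name of the
    event whose window midpoint is nearest to the detected window midpoint.
    """
    windows = _threshold_crossings(curve, thr.level)
    # merge windows separated by small flooded gaps
    merged: list[tuple[float, float]] = []
    for w in windows:
        if merged and merged[-1][1] - w[0] < thr.merge_gap:
            merged[-1] = (merged[-1][0], w[1])
        else:
            merged.append(list(w))  # type: ignore[arg-type]
    merged = [(o, y) for o, y in merged if o - y >= thr.min_duration]

    older, younger = curve.span
    intervals: list[PhaseInterval] = []
    cursor = older
    for o, y in merged:
        if cursor - o > 1e-12:
            intervals.append(PhaseInterval("disjunction", cursor, o))
        label = _nearest_event_label(labels, o, y) if labels is not None else ""
        intervals.append(PhaseInterval("junction", o, y, label=label))
        cursor = y
    if cursor - younger > 1e-12:
        intervals.append(PhaseInterval("disjunction", cursor, younger))
    if not intervals:  # degenerate: whole span one state
        kind = "junction" if float(curve.levels[0]) <= thr.level else "disjunction"
        intervals = [PhaseInterval(kind, older, younger)]
    return PhaseTimeline(tuple(intervals), (older, younger))


def _nearest_event_label(
    events: EventTimeline, older: float, younger: float
) -> str:
    mid = 0.5 * (older + younger)
    best, best_d = "", np.inf
    for e in events.of_kind("lowstand"):
        lo, hi = e.window
        d = abs(0.5 * (lo + hi) - mid)
        if d < best_d:
            best, best_d = e.name, d
    return best


# ---------------------------------------------------------------------------
# Event-driven timeline synthesis (active era + passive era)


def build_timeline(
    events: EventTimeline,
    span: tuple[float, float] | None = None,
    switch_age: float = KUNGURIAN_ROADIAN_SWITCH,
    curve: SeaLevelCurve | None = None,
    thr: ThresholdSpec | None = None,
) -> PhaseTimeline:
    """Synthesise the full junction-disjunction timeline.

    Active era (older than ``switch_age``): junction windows come from the
    curve (threshold detection) when ``curve``/``thr`` are given, otherwise
    from interval lowstand events; the default state is disjunction (the
    seaway is open unless a lowstand closes it).  Point lowstand events are
    sub-threshold markers and create no window.

    Passive era (younger than ``switch_age``): the land bridge region is
    predominantly terrestrial, so the default state is junction and each
    interval transgression event creates a disjunction.  Events of kind
    ``failed_transgression`` create nothing.
    """
    if span is None:
        span = events.span
    older, younger = span

    if curve is not None:
        if thr is None:
            raise ValueError("a ThresholdSpec is required with a curve")
        detected = detect_exposure_windows(curve.restrict(older, max(switch_age, younger)), thr, labels=events)
        junctions = [
            (iv.older, iv.younger, iv.label) for iv in detected.junctions
        ]
    else:
        junctions = [
            (e.older, e.younger, e.name)
            for e in events.of_kind("lowstand")
            if e.is_interval
        ]
    junctions = [(o, y, lab) for o, y, lab in junctions if o > switch_age]
    disjunctions = [
        (e.older, e.younger, e.name)
        for e in events.of_kind("transgression")
        if e.is_interval and e.older <= switch_age
    ]

    explicit = sorted(
        [("junction", o, y, lab, "active") for o, y, lab in junctions]
        + [("disjunction", o, y, lab, "passive") for o, y, lab in disjunctions],
        key=lambda t: -t[1],
    )
    for (k1, o1, y1, *_), (k2, o2, y2, *_) in zip(explicit, explicit[1:]):
        if y1 < o2:
            raise ValidationError(
                f"overlapping phase-defining events at {y1}..{o2} Ma"
            )

    intervals: list[PhaseInterval] = []

    def fill(gap_older: float, gap_younger: float) -> None:
        """Fill a gap with default-state intervals, split at the mode switch."""
        if gap_older - gap_younger <= 1e-12:
            return
        pieces = []
        if gap_older > switch_age > gap_younger:
            pieces = [(gap_older, switch_age), (switch_age, gap_younger)]
        else:
            pieces = [(gap_older, gap_younger)]
        for o, y in pieces:
            active = o > switch_age
            kind = "disjunction" if active else "junction"
            mode = "active" if active else "passive"
            _append(PhaseInterval(kind, o, y, mode=mode))

    def _append(iv: PhaseInterval) -> None:
        if intervals and intervals[-1].kind == iv.kind:
            prev = intervals.pop()
            iv = PhaseInterval(
                prev.kind,
                prev.older,
                iv.younger,
                label=prev.label or iv.label,
                mode=prev.mode,
            )
        intervals.append(iv)

    cursor = older
    for kind, o, y, lab, mode in explicit:
        fill(cursor, o)
        _append(PhaseInterval(kind, o, y, label=lab, mode=mode))
        cursor = y
    fill(cursor, younger)
    return PhaseTimeline(tuple(intervals), span)


# ---------------------------------------------------------------------------
# Transgression/regression cycle labelling


@dataclass(frozen=True)
class TRLeg:
    older: float
    younger: float
    leg: str  # "transgression" | "regression" | "flat"


def label_tr_cycles(
    curve: SeaLevelCurve, min_prominence: float = 0.0
) -> list[TRLeg]:
    """Split the curve span into transgression/regression legs.

    Legs are the runs between consecutive local extrema; a level rising
    toward the present is a transgression, falling is a regression.  With
    ``min_prominence`` > 0, extrema are prominence-filtered (noise wiggles
    ignored).  A constant curve yields a single leg flagged ``flat``.
    """
    if len(curve.ages) < 3:
        raise CurveError("need at least 3 samples to label T/R cycles")
    levels = curve.levels
    if np.ptp(levels) == 0:
        return [TRLeg(*curve.span, "flat")]
    kwargs = {"prominence": min_prominence} if min_prominence > 0 else {}
    maxima, _ = find_peaks(levels, **kwargs)
    minima, _ = find_peaks(-levels, **kwargs)
    cuts = sorted(set(maxima) | set(minima))
    idx = [0] + cuts + [len(levels) - 1]
    legs: list[TRLeg] = []
    for i0, i1 in zip(idx, idx[1:]):
        if i1 <= i0:
            continue
        rising = levels[i1] > levels[i0]
        legs.append(
            TRLeg(
                float(curve.ages[i0]),
                float(curve.ages[i1]),
                "transgression" if rising else "regression",
            )
        )
    return legs


# ---------------------------------------------------------------------------
# Glacial overlay


def overlay_glacials(
    timeline: PhaseTimeline, glacials: EventTimeline
) -> PhaseTimeline:
    """Annotate each phase interval with the overlapping glacial periods.

    Glacial periods are taken from paired ``glacial_onset``/``glacial_end``
    events (e.g. "P4 onset" at 259.5 Ma and "P4 end" at 254.5 Ma).  Interval
    boundaries are unchanged; only the annotation set is filled in.
    """
    periods = glacials.glacial_periods()
    annotated = []
    for iv in timeline.intervals:
        tags = tuple(
            sorted(
                name
                for name, (onset, end) in periods.items()
                if iv.overlaps(onset, end)
            )
        )
        annotated.append(replace(iv, glacials=tags))
    return PhaseTimeline(tuple(annotated), timeline.span)
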