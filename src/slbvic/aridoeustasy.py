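"""Arido-eustasy interpretation of chemostratigraphic and facies data.

Under the arido-eustasy (aquifer-eustasy) model, wet global climates store
fresh water in continental aquifers and *lower* sea level, while dry
climates *raise* it.  Its observable signatures are:

* extreme (> 1.5 permil) and abrupt negative excursions of marine
  carbonate and terrestrial organic carbon isotopes -> wet-mode onsets;
* positive culminations of marine carbonate d13C, the Optimum of
  Terrestrial Productivity (OTP), during maximal terrestrial carbon uptake;
* lithofacies rules: gypsum -> lowstand, shale -> highstand, dolomite ->
  regressive systems tract, coal -> wet lowstand, red beds -> dry highstand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .eustasy import SeaLevelCurve

ISOTOPE_SOURCES = ("carb", "org_wood", "org_marine_mixed")

#: lithology -> sea-level/climate regime rule table
LITHOLOGY_RULES = {
    "gypsum": "lowstand",
    "shale": "highstand",
    "dolomite": "regressive-tract",
    "coal": "wet-lowstand",
    "redbed": "dry-highstand",
    "sandstone": "context",
    "limestone": "context",
}


class SeriesError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class IsotopeSeries:
    """An age-ordered d13C series (permil), tagged with its carbon source."""

    ages: np.ndarray
    deltas: np.ndarray
    source: str = "carb"
    label: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        deltas = np.asarray(self.deltas, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "deltas", deltas)
        if self.source not in ISOTOPE_SOURCES:
            raise SeriesError(f"unknown isotope source {self.source!r}")
        if ages.size and not np.all(np.diff(ages) < 0):
            raise SeriesError("isotope ages must be strictly decreasing")
        if not np.all(np.isfinite(deltas)):
            raise SeriesError("isotope deltas must be finite")

    def __len__(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class ExcursionCall:
    older: float
    younger: float
    magnitude: float  # permil, peak |departure| from baseline
    abruptness: float  # permil / My
    direction: str  # "negative" | "positive"

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise SeriesError("excursion magnitude must be > 0")
        if self.direction not in ("negative", "positive"):
            raise SeriesError(f"bad direction {self.direction!r}")

    @property
    def span(self) -> tuple[float, float]:
        return (self.older, self.younger)


@dataclass(frozen=True)
class FaciesUnit:
    name: str
    lithology: str
    position: int  # stratigraphic order, increasing upward (younger)


@dataclass(frozen=True)
class LithofaciesSequence:
    units: tuple[FaciesUnit, ...]

    def __post_init__(self) -> None:
        pos = [u.position for u in self.units]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise SeriesError("facies positions must strictly increase")

    def __iter__(self):
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)


# ---------------------------------------------------------------------------
# Excursion detection


def running_baseline(series: IsotopeSeries, window: float = 2.0) -> np.ndarray:
    """Running-median baseline over a window of the given width in My.

    A median resists single-sample spikes and, for excursions shorter than
    half the window, is nearly unaffected by the excursion itself.
    """
    if len(series) < 2:
        return series.deltas.copy()
    step = float(np.median(np.abs(np.diff(series.ages))))
    half = max(1, int(round(0.5 * window / step)))
    return median_filter(series.deltas, size=2 * half + 1, mode="nearest")


def detect_excursions(
    series: IsotopeSeries,
    min_magnitude: float = 1.5,
    min_abruptness: float = 1.0,
    baseline_window: float = 2.0,
) -> list[ExcursionCall]:
    """Call extreme, abrupt isotopic excursions against a running baseline.

    A call is a maximal run of samples whose departure from the running
    median baseline is at least ``min_magnitude`` permil (one sign per
    call), provided the departure built up at a rate of at least
    ``min_abruptness`` permil/My from the last near-baseline sample.
    Negative calls mark wet-mode onsets under the arido-eustasy model.
    """
    if len(series) < 5:
        raise SeriesError("need at least 5 samples to call excursions")
    departure = series.deltas - running_baseline(series, baseline_window)
    calls: list[ExcursionCall] = []
    for direction, sign in (("negative", -1.0), ("positive", 1.0)):
        dep = sign * departure  # excursion samples have dep >= min_magnitude
        over = dep >= min_magnitude
        i = 0
        while i < len(over):
            if not over[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(over) and over[j + 1]:
                j += 1
            magnitude = float(dep[i:j + 1].max())
            # rate of departure build-up: from the last sample at-or-below
            # half magnitude before the run, up to the run's peak
            k = i
            while k > 0 and dep[k - 1] > 0.5 * min_magnitude:
                k -= 1
            peak = i + int(np.argmax(dep[i:j + 1]))
            dt = float(series.ages[k] - series.ages[peak])
            abruptness = magnitude / dt if dt > 0 else np.inf
            if abruptness >= min_abruptness:
                calls.append(
                    ExcursionCall(
                        float(series.ages[k]),
                        float(series.ages[j]),
                        magnitude,
                        float(abruptness),
                        direction,
                    )
                )
            i = j + 1
    calls.sort(key=lambda c: -c.older)
    return calls


def detect_otp(series: IsotopeSeries, prominence: float = 0.5) -> list[dict]:
    """Find Optimum-of-Terrestrial-Productivity culminations.

    OTPs are positive local culminations of the *marine carbonate* d13C
    record exceeding the given prominence (permil); each peak is returned
    with its age, delta and prominence, tagged ``OTP``.
    """
    if series.source != "carb":
        raise SeriesError(
            f"OTP detection is defined on carbonate d13C, got {series.source!r}"
        )
    idx, props = find_peaks(series.deltas, prominence=prominence)
    return [
        {
            "tag": "OTP",
            "age_ma": float(series.ages[i]),
            "delta_permil": float(series.deltas[i]),
            "prominence": float(p),
        }
        for i, p in zip(idx, props["prominences"])
    ]


# ---------------------------------------------------------------------------
# Lithofacies rules


def lithology_to_regime(seq: LithofaciesSequence) -> list[tuple[FaciesUnit, str]]:
    """Map each facies unit to its sea-level/climate regime label.

    Total, deterministic lookup in the rule table; an unknown lithology is
    an error naming the offending unit.
    """
    out = []
    for unit in seq:
        if unit.lithology not in LITHOLOGY_RULES:
            raise SeriesError(
                f"unit {unit.name!r}: unknown lithology {unit.lithology!r}"
            )
        out.append((unit, LITHOLOGY_RULES[unit.lithology]))
    return out


def align_regimes_to_curve(
    labels: Sequence[tuple[FaciesUnit, str]],
    curve: SeaLevelCurve,
    min_prominence: float = 0.0,
) -> list[dict]:
    """Match labelled facies units to successive curve troughs and crests.

    Lowstand-type labels (lowstand, wet-lowstand) are matched in
    stratigraphic order to successive troughs of the curve, highstand-type
    labels to successive crests; matching is order-preserving and greedy
    (first available extremum).  Other labels, and units left without an
    extremum, are reported unmatched.  ``min_prominence`` filters extrema so
    background wiggles are not offered as candidates.
    """
    kwargs = {"prominence": min_prominence} if min_prominence > 0 else {}
    trough_idx, _ = find_peaks(-curve.levels, **kwargs)
    crest_idx, _ = find_peaks(curve.levels, **kwargs)
    troughs = [float(curve.ages[i]) for i in trough_idx]
    crests = [float(curve.ages[i]) for i in crest_idx]
    t_cursor = c_cursor = 0
    matches = []
    for unit, regime in labels:
        if regime in ("lowstand", "wet-lowstand"):
            if t_cursor < len(troughs):
                matches.append(
                    {"unit": unit.name, "regime": regime,
                     "matched_age_ma": troughs[t_cursor], "extremum": "trough"}
                )
                t_cursor += 1
            else:
                matches.append(
                    {"unit": unit.name, "regime": regime,
                     "matched_age_ma": None, "extremum": "trough"}
                )
        elif regime in ("highstand", "dry-highstand"):
            if c_cursor < len(crests):
                matches.append(
                    {"unit": unit.name, "regime": regime,
                     "matched_age_ma": crests[c_cursor], "extremum": "crest"}
                )
                c_cursor += 1
            else:
                matches.append(
                    {"unit": unit.name, "regime": regime,
                     "matched_age_ma": None, "extremum": "crest"}
                )
        else:
            matches.append(
                {"unit": unit.name, "regime": regime,
                 "matched_age_ma": None, "extremum": None}
            )
    return matches


# ---------------------------------------------------------------------------
# Tables


def isotopes_from_frame(df: pd.DataFrame, label: str = "") -> IsotopeSeries:
    for col in ("age_ma", "delta_permil", "source"):
        if col not in df.columns:
            raise SeriesError(f"isotope table missing column {col!r}")
    sources = df["source"].unique()
    if len(sources) != 1:
        raise SeriesError(f"one source per series expected, got {list(sources)}")
    return IsotopeSeries(
        df["age_ma"].to_numpy(float), df["delta_permil"].to_numpy(float),
        str(sources[0]), label,
    )


def isotopes_to_frame(series: IsotopeSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {"age_ma": series.ages, "delta_permil": series.deltas,
         "source": series.source}
    )


def lithology_from_frame(df: pd.DataFrame) -> LithofaciesSequence:
    for col in ("position", "name", "lithology"):
        if col not in df.columns:
            raise SeriesError(f"lithology table missing column {col!r}")
    units = tuple(
        FaciesUnit(str(r.name), str(r.lithology), int(r.position))
        for r in df.sort_values("position").itertuples(index=False)
    )
    return LithofaciesSequence(units)
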