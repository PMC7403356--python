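"""Packaged fixtures for the Siberian Land Bridge model.

Events and intervals whose ages are not printed anywhere are
figure-digitised (each such row carries a provenance note); the early
synapsid tree is a synthetic figure-digitised stand-in whose time-slice
branch counts honour the two counts stated verbatim in the literature
(eight synapsid branches at the Garnett/Kas 2 window; eight tapinocephalid
branches in the lower *Tapinocephalus* Assemblage Zone).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from . import data as _data
from .aridoeustasy import LithofaciesSequence, lithology_from_frame
from .cladofit import TaxonOccurrence, occurrences_from_frame
from .eustasy import (
    KUNGURIAN_ROADIAN_SWITCH,
    PhaseTimeline,
    SeaLevelCurve,
    ThresholdSpec,
    build_timeline,
)
from .synthdata import SynthSpec, gen_curve
from .timescale import EventTimeline, GeoTimescale, load_event_timeline, load_timescale
from .vicariance import CladoStratTree, MarineUnit

#: Exposure threshold matched to the reference curve (figure-digitised: the
#: printed window ages are reproduced with this value; no numeric threshold
#: is printed anywhere).
SLB_THRESHOLD = ThresholdSpec(level=0.0, min_duration=0.2, merge_gap=0.1)

#: Root of the area cladogram: the ephemeral Laurussia-Gondwana connection.
ROOT_AGE = 350.0

#: Onset of the Bash 3 window: Amniote Chrone numbering starts here.
AMNIOTE_ORIGIN = 321.0


def _path(name: str) -> Path:
    return Path(resources.files(_data) / name)


def event_timeline() -> EventTimeline:
    """The named-event timeline (lowstands, transgressions, glacials, zones)."""
    return load_event_timeline(_path("events.csv"))


def timescale_2018() -> GeoTimescale:
    """Carboniferous-Permian stages of the August 2018 chart update."""
    return load_timescale(_path("timescale_ics2018.csv"))


def timescale_2012() -> GeoTimescale:
    """The older chart edition (differs within the Permian)."""
    return load_timescale(_path("timescale_gts2012.csv"))


def phase_timeline(switch_age: float = KUNGURIAN_ROADIAN_SWITCH) -> PhaseTimeline:
    """The junction-disjunction timeline built from the packaged events."""
    return build_timeline(event_timeline(), switch_age=switch_age)


def fixture_spec(seed: int = 0) -> SynthSpec:
    """Generator conditions for the packaged reference-style curve.

    Troughs are planted at the packaged lowstand events; the digitisation
    noise (0.5 level units) keeps planted exposures 30 noise SDs below the
    threshold and marker troughs clearly separable from the 1.4-1.6 My
    background cycles.
    """
    return SynthSpec(
        seed=seed,
        planted_events=event_timeline(),
        noise_sd=0.5,
        threshold=SLB_THRESHOLD.level,
    )


def reference_curve(seed: int = 0) -> SeaLevelCurve:
    """The packaged reference-style sea-level curve (seeded digitisation)."""
    curve, _ = gen_curve(fixture_spec(seed))
    return curve


def synapsid_tree() -> CladoStratTree:
    """The packaged early-synapsid clado-stratigraphic tree (synthetic,
    figure-digitised stand-in; see module docstring)."""
    return CladoStratTree.from_files(
        _path("synapsid_tree.nwk"),
        _path("synapsid_tree_nodes.csv"),
        label="early synapsids (figure-digitised)",
    )


def tapinocephalid_occurrences() -> list[TaxonOccurrence]:
    """The 11 tapinocephalid genera described from the Tapinocephalus AZ."""
    return occurrences_from_frame(
        pd.read_csv(_path("tapinocephalid_occurrences.tsv"), sep="\t")
    )


def garnett_occurrences() -> list[TaxonOccurrence]:
    """The 7 synapsid genera recovered from the Garnett locality."""
    return occurrences_from_frame(
        pd.read_csv(_path("garnett_occurrences.tsv"), sep="\t")
    )


def joggins_occurrences() -> list[TaxonOccurrence]:
    """Hylonomus and Protoclepsydrops from the Joggins locality."""
    return occurrences_from_frame(
        pd.read_csv(_path("joggins_occurrences.tsv"), sep="\t")
    )


def marine_units() -> list[MarineUnit]:
    """North American marine units; the Newwellian is the excepted zone."""
    df = pd.read_csv(_path("marine_units.csv"))
    units = []
    for r in df.itertuples(index=False):
        units.append(
            MarineUnit(
                str(r.name), int(r.order),
                None if pd.isna(r.older_ma) else float(r.older_ma),
                None if pd.isna(r.younger_ma) else float(r.younger_ma),
                bool(r.excepted),
            )
        )
    return units


def flowerpot_lithology() -> LithofaciesSequence:
    """The Flowerpot Shale / Blaine evaporitic cycle sequence."""
    return lithology_from_frame(pd.read_csv(_path("flowerpot_lithology.csv")))
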