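"""Readers/writers and the top-level pipeline.

All ages are serialised with 2-decimal Ma precision; computation is done at
full precision.  Reports are JSON and carry the seed and a hash of the
configuration that produced them, so a rerun with the same configuration is
reproducible and verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures
from .cladofit import (
    FitReport,
    assign_taxa,
    congruence_test,
    detect_conflicts,
    emit_chrones,
    occurrences_from_frame,
    occurrences_to_frame,
)
from .eustasy import (
    KUNGURIAN_ROADIAN_SWITCH,
    PhaseTimeline,
    SeaLevelCurve,
    ThresholdSpec,
    build_timeline,
    detect_exposure_windows,
)
from .timescale import load_event_timeline
from .vicariance import CladoStratTree, build_area_cladogram


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Curve / timeline round-trip formats


def read_curve(path: str | Path, label: str = "") -> SeaLevelCurve:
    df = pd.read_csv(path)
    for col in ("age_ma", "level"):
        if col not in df.columns:
            raise ConfigError(f"curve file {path}: missing column {col!r}")
    return SeaLevelCurve(
        df["age_ma"].to_numpy(float), df["level"].to_numpy(float), label or str(path)
    )


def write_curve(curve: SeaLevelCurve, path: str | Path) -> None:
    pd.DataFrame({"age_ma": curve.ages, "level": curve.levels}).to_csv(
        path, index=False, float_format="%.6g"
    )


def timeline_to_frame(timeline: PhaseTimeline) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kind": iv.kind,
                "older_ma": round(iv.older, 2),
                "younger_ma": round(iv.younger, 2),
                "label": iv.label,
                "mode": iv.mode,
                "glacials": ";".join(iv.glacials),
            }
            for iv in timeline.intervals
        ]
    )


def write_timeline(timeline: PhaseTimeline, path: str | Path) -> None:
    timeline_to_frame(timeline).to_csv(path, index=False)


def read_timeline(path: str | Path) -> PhaseTimeline:
    from .eustasy import PhaseInterval

    df = pd.read_csv(path)
    intervals = tuple(
        PhaseInterval(
            str(r.kind), float(r.older_ma), float(r.younger_ma),
            "" if pd.isna(r.label) else str(r.label),
            str(r.mode),
            tuple() if pd.isna(r.glacials) or not str(r.glacials)
            else tuple(str(r.glacials).split(";")),
        )
        for r in df.itertuples(index=False)
    )
    return PhaseTimeline(intervals, (intervals[0].older, intervals[-1].younger))


def read_occurrences(path: str | Path):
    return occurrences_from_frame(pd.read_csv(path, sep="\t"))


def write_occurrences(occurrences, path: str | Path) -> None:
    occurrences_to_frame(occurrences).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RunConfig and pipeline


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With no explicit inputs the packaged fixtures are used: the seeded
    reference-style curve, the packaged event timeline and the packaged
    early-synapsid tree.
    """

    curve: str | None = None  # CSV path; None -> packaged seeded curve
    events: str | None = None  # CSV path; None -> packaged event timeline
    tree_newick: str | None = None
    tree_nodes: str | None = None
    occurrences: str | None = None  # TSV path; None -> packaged Joggins+AZ data
    threshold: float = fixtures.SLB_THRESHOLD.level
    min_duration: float = fixtures.SLB_THRESHOLD.min_duration
    merge_gap: float = fixtures.SLB_THRESHOLD.merge_gap
    switch_age: float = KUNGURIAN_ROADIAN_SWITCH
    root_age: float = fixtures.ROOT_AGE
    congruence_tolerance: float = 1.0
    n_perm: int = 999
    seed: int = 0
    outdir: str = "slbvic-out"

    def validate(self) -> None:
        for name in ("curve", "events", "tree_newick", "tree_nodes", "occurrences"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input file for {name!r} not found: {path}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute curve -> windows -> cladogram -> fit -> report.

    Returns the report dict and writes ``report.json``, the phase timeline
    and the curve into ``config.outdir``.  Deterministic for a fixed config.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    events = (
        load_event_timeline(config.events) if config.events else fixtures.event_timeline()
    )
    curve = (
        read_curve(config.curve) if config.curve else fixtures.reference_curve(config.seed)
    )
    thr = ThresholdSpec(config.threshold, config.min_duration, config.merge_gap)
    windows = detect_exposure_windows(curve, thr, labels=events)
    timeline = build_timeline(events, switch_age=config.switch_age)
    cladogram = build_area_cladogram(timeline, root_age=config.root_age)

    if config.tree_newick:
        tree = CladoStratTree.from_files(config.tree_newick, config.tree_nodes)
    else:
        tree = fixtures.synapsid_tree()
    if config.occurrences:
        occurrences = read_occurrences(config.occurrences)
    else:
        occurrences = (
            fixtures.joggins_occurrences()
            + fixtures.garnett_occurrences()
            + fixtures.tapinocephalid_occurrences()
        )

    assignments = assign_taxa(occurrences, timeline)
    conflicts = detect_conflicts(assignments, tree, timeline)
    score, p_value = congruence_test(
        tree, timeline, n_perm=config.n_perm, seed=config.seed,
        tolerance=config.congruence_tolerance,
    )
    chrones = emit_chrones(timeline, origin=fixtures.AMNIOTE_ORIGIN)
    report = FitReport(assignments, conflicts, score, p_value, chrones)

    junctions = [
        {"older_ma": round(iv.older, 2), "younger_ma": round(iv.younger, 2),
         "label": iv.label}
        for iv in windows.junctions
    ]
    payload = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "detected_junction_windows": junctions,
        "first_junction_window_ma": junctions[0]["older_ma"] if junctions else None,
        "root_age_ma": cladogram.root.age,
        "n_intervals": len(timeline),
        "fit": report.to_dict(),
    }
    write_curve(curve, outdir / "curve.csv")
    write_timeline(timeline, outdir / "timeline.csv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload
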