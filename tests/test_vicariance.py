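"""Area cladogram construction, branch capacity, divergence dating, biozones."""

import numpy as np
import pytest

from conftest import random_alternating_timeline
from slbvic import fixtures as fx
from slbvic.cladofit import TaxonOccurrence
from slbvic.eustasy import PhaseInterval, PhaseTimeline
from slbvic.synthdata import SynthSpec, gen_occurrences, gen_tree
from slbvic.vicariance import (
    BranchTable,
    CapacityQuery,
    CladeError,
    CladoStratTree,
    MarineUnit,
    TreeBranch,
    branch_capacity,
    build_area_cladogram,
    calibrate_marine_units,
    capacity_overlapping,
    doubling_bound,
    infer_divergence_date,
)


class TestBuildAreaCladogram:
    def test_zero_junctions_gives_single_split_for_whole_span(self):
        tl = PhaseTimeline(
            (PhaseInterval("disjunction", 100.0, 0.0),), (100.0, 0.0)
        )
        clad = build_area_cladogram(tl, root_age=100.0)
        assert clad.root.age == 100.0
        east_west = clad.split_segments()
        assert len(east_west) == 2
        assert {b.territory for b in east_west} == {"East", "West"}
        assert all((b.older, b.younger) == (100.0, 0.0) for b in east_west)

    def test_fixture_root_at_350_and_first_merge_at_321(self, timeline):
        clad = build_area_cladogram(timeline, root_age=fx.ROOT_AGE)
        assert clad.root.age == 350.0
        merges = [n for n in clad.nodes if n.kind == "merge"]
        assert merges[0].age == 321.0
        assert merges[0].label == "Bash 3"

    @pytest.mark.parametrize("seed", range(5))
    def test_split_segment_count_equals_disjunction_count(self, seed):
        rng = np.random.default_rng(seed)
        tl = random_alternating_timeline(rng)
        clad = build_area_cladogram(tl, root_age=tl.span[0])
        assert len(clad.split_segments()) == 2 * len(tl.disjunctions)

    @pytest.mark.parametrize("seed", range(3))
    def test_branch_count_is_one_in_junctions_two_in_disjunctions(self, seed):
        rng = np.random.default_rng(50 + seed)
        tl = random_alternating_timeline(rng)
        clad = build_area_cladogram(tl, root_age=tl.span[0])
        for iv in tl:
            mid = 0.5 * (iv.older + iv.younger)
            expected = 2 if iv.kind == "disjunction" else 1
            assert clad.branch_count(mid) == expected


class TestBranchCapacity:
    def test_single_branch_tree_counts_one_anywhere(self):
        table = BranchTable([TreeBranch(0, None, "only", "West", 50.0, 10.0)],
                            clades={"C": {0}})
        for t in (49.0, 30.0, 10.5):
            assert branch_capacity(table, CapacityQuery("C", t)) == 1

    def test_eight_synapsid_branches_at_the_garnett_window(self, tree, timeline):
        # Kas 2 is a junction window: geodispersal pools the territories
        q = CapacityQuery("Synapsida", 304.0, "West")
        assert branch_capacity(tree, q, timeline=timeline) == 8

    def test_eight_tapinocephalid_branches_in_the_tapinocephalus_az(self, tree, timeline):
        q = CapacityQuery("Tapinocephalidae", 264.0, "West")
        assert branch_capacity(tree, q, timeline=timeline) == 8

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_time_slice_oracle_on_random_histories(self, seed, timeline):
        table, _ = gen_tree(timeline, SynthSpec(seed=seed, p_split=0.6))
        rng = np.random.default_rng(1000 + seed)
        times = rng.uniform(251.0, 349.0, size=100)
        for t in times:
            want = sum(b.older >= t > b.younger for b in table.branches)
            got = branch_capacity(table, CapacityQuery("Synthetica", float(t)))
            assert got == want

    def test_widening_territory_never_decreases_capacity(self, tree):
        for t in (310.0, 295.0, 270.0, 264.0):
            east = branch_capacity(tree, CapacityQuery("Synapsida", t, "East"))
            west = branch_capacity(tree, CapacityQuery("Synapsida", t, "West"))
            both = branch_capacity(tree, CapacityQuery("Synapsida", t, "both"))
            assert both >= max(east, west)

    def test_unknown_clade_raises(self, tree):
        with pytest.raises(CladeError):
            branch_capacity(tree, CapacityQuery("Dinosauria", 300.0))

    def test_doubling_bound_dominates_fixture_counts(self, tree, timeline):
        # 9 disjunction onsets separate 321 from 304; the 2^d closed form is
        # a loose upper bound on the explicit time-slice count
        d = sum(1 for iv in timeline.disjunctions if 321 >= iv.older > 304)
        assert doubling_bound(d) >= branch_capacity(
            tree, CapacityQuery("Synapsida", 304.0), timeline=timeline
        )


class TestCladoStratTree:
    def test_round_trips_through_newick_and_sidecar(self, tree, tmp_path):
        tree.to_files(tmp_path / "t.nwk", tmp_path / "t.csv")
        back = CladoStratTree.from_files(tmp_path / "t.nwk", tmp_path / "t.csv")
        want = sorted((b.name, b.territory, b.older, b.younger) for b in tree.branches)
        got = sorted((b.name, b.territory, b.older, b.younger) for b in back.branches)
        assert got == want
        assert set(back.clades) == set(tree.clades)


def _occ(taxon, fad, lad, territory="West"):
    return TaxonOccurrence(taxon, "genus", "Synapsida", "loc", territory, fad, lad)


class TestInferDivergenceDate:
    def test_joggins_co_occurrence_dates_the_reptile_mammal_split(self, timeline):
        jog = fx.joggins_occurrences()
        hylo = [o for o in jog if o.taxon == "Hylonomus"]
        proto = [o for o in jog if o.taxon == "Protoclepsydrops"]
        d = infer_divergence_date(hylo, proto, timeline)
        assert d.age == 321.0
        assert d.window_label == "Bash 3"
        assert not d.no_prior_disjunction

    def test_no_prior_disjunction_returns_root_with_flag(self):
        tl = PhaseTimeline(
            (
                PhaseInterval("junction", 100.0, 90.0),
                PhaseInterval("disjunction", 90.0, 0.0),
            ),
            (100.0, 0.0),
        )
        d = infer_divergence_date([_occ("a", 95.0, 93.0)], [_occ("b", 94.0, 92.0)], tl)
        assert d.age == 100.0
        assert d.no_prior_disjunction

    @pytest.mark.parametrize("seed", range(25))
    def test_recovers_planted_split_windows(self, seed, timeline):
        spec = SynthSpec(seed=seed)
        table, truth = gen_tree(timeline, spec)
        occ, _, _ = gen_occurrences(timeline, spec, tree=table)
        records = {}
        for o in occ:
            records.setdefault(o.taxon, []).append(o)
        siblings = {}
        for t in truth:
            if t.parent is not None:
                siblings.setdefault(t.parent, []).append(t)
        for kids in siblings.values():
            if len(kids) != 2 or any(k.name not in records for k in kids):
                continue
            d = infer_divergence_date(records[kids[0].name], records[kids[1].name], timeline)
            closing = next(
                iv for iv in timeline.intervals[kids[0].split_interval + 1:]
                if iv.kind == "junction"
            )
            assert d.age == pytest.approx(closing.onset)

    def test_occurrence_outside_span_rejected(self, timeline):
        with pytest.raises(ValueError):
            infer_divergence_date(
                [_occ("a", 360.0, 355.0)], [_occ("b", 320.0, 319.0)], timeline
            )


class TestCalibrateMarineUnits:
    def test_one_unit_spans_the_single_highstand(self):
        tl = PhaseTimeline(
            (
                PhaseInterval("junction", 10.0, 8.0),
                PhaseInterval("disjunction", 8.0, 3.0),
                PhaseInterval("junction", 3.0, 0.0),
            ),
            (10.0, 0.0),
        )
        dated, rem = calibrate_marine_units([MarineUnit("U", 1)], tl)
        assert not rem
        assert (dated[0].older, dated[0].younger) == (8.0, 3.0)

    def test_leonardian_begins_at_the_highstand_after_art2(self, timeline):
        dated, rem = calibrate_marine_units(
            fx.marine_units(), timeline, start_age=293.5
        )
        assert not rem
        by_name = {d.name: d for d in dated}
        art2 = next(iv for iv in timeline.junctions if iv.label == "Art 2")
        assert by_name["Leonardian"].older == art2.younger == 285.5
        assert by_name["Newwellian"].excepted and not by_name["Newwellian"].assigned

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_order_preserving_greedy_oracle(self, seed):
        rng = np.random.default_rng(2000 + seed)
        tl = random_alternating_timeline(rng, n_intervals=int(rng.integers(4, 9)))
        highstands = tl.disjunctions
        k = int(rng.integers(1, len(highstands) + 2))
        units = [MarineUnit(f"U{i}", i) for i in range(k)]
        dated, rem = calibrate_marine_units(units, tl)
        assert len(dated) + len(rem) == k
        for i, d in enumerate(dated):  # greedy oracle: unit i -> highstand i
            assert (d.older, d.younger) == (highstands[i].older, highstands[i].younger)
        olders = [d.older for d in dated]
        assert olders == sorted(olders, reverse=True)  # no inversions

    def test_leftover_units_reported_not_dropped(self):
        tl = PhaseTimeline(
            (
                PhaseInterval("disjunction", 10.0, 5.0),
                PhaseInterval("junction", 5.0, 0.0),
            ),
            (10.0, 0.0),
        )
        units = [MarineUnit("U1", 1), MarineUnit("U2", 2)]
        dated, rem = calibrate_marine_units(units, tl)
        assert [u.name for u in rem] == ["U2"]
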