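"""Occurrence fitting: assignment, conflicts, congruence, dating, chrones."""

import numpy as np
import pytest

from conftest import random_alternating_timeline
from slbvic import fixtures as fx
from slbvic.cladofit import (
    FitError,
    TaxonOccurrence,
    assign_taxa,
    congruence_test,
    date_assemblage,
    detect_conflicts,
    emit_chrones,
)
from slbvic.eustasy import PhaseInterval, PhaseTimeline
from slbvic.synthdata import SynthSpec, gen_occurrences, gen_tree
from slbvic.vicariance import BranchTable, TreeBranch


def occ(taxon, fad, lad, territory="West", rank="genus", clade="Synthetica"):
    return TaxonOccurrence(taxon, rank, clade, "loc", territory, fad, lad)


class TestAssignTaxa:
    def test_empty_occurrence_list(self, timeline, tree):
        assert assign_taxa([], timeline) == []
        assert detect_conflicts([], tree, timeline) == []

    def test_joggins_pair_attributed_to_either_territory(self, timeline):
        out = assign_taxa(fx.joggins_occurrences(), timeline)
        for a in out:
            # the records sit inside the Bash 3 junction window: geodispersal
            assert a.branches == frozenset({"East", "West"})
            assert not a.straddles

    def test_disjunction_record_is_territory_endemic(self, timeline):
        a, = assign_taxa([occ("x", 300.0, 299.0, territory="East")], timeline)
        assert a.branches == frozenset({"East"})

    def test_straddling_record_gets_union_and_flag(self, timeline):
        a, = assign_taxa([occ("x", 322.0, 320.0, territory="West")], timeline)
        assert a.straddles
        assert a.branches == frozenset({"East", "West"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_interval_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tl = random_alternating_timeline(rng)
        older, younger = tl.span
        records = []
        for i in range(30):
            fad = rng.uniform(younger + 0.5, older)
            lad = max(younger, fad - rng.uniform(0.0, 3.0))
            records.append(occ(f"t{i}", fad, lad,
                               territory="East" if rng.uniform() < 0.5 else "West"))
        for a in assign_taxa(records, tl):
            want = set()
            hit = []
            for idx, iv in enumerate(tl.intervals):
                if a.occurrence.overlaps(iv.older, iv.younger):
                    hit.append(idx)
                    if iv.kind == "junction":
                        want |= {"East", "West"}
                    else:
                        want.add(a.occurrence.territory)
            assert a.branches == frozenset(want)
            assert list(a.intervals) == hit


class TestDetectConflicts:
    @pytest.mark.parametrize("seed", range(10))
    def test_model_generated_records_are_conflict_free(self, seed, timeline):
        occs, _, table = gen_occurrences(timeline, SynthSpec(seed=seed))
        conflicts = detect_conflicts(assign_taxa(occs, timeline), table, timeline)
        assert [c for c in conflicts if c.kind == "capacity_violation"] == []

    def test_eleven_tapinocephalid_genera_exceed_capacity_once(self, tree, timeline):
        assignments = assign_taxa(fx.tapinocephalid_occurrences(), timeline)
        conflicts = detect_conflicts(assignments, tree, timeline)
        violations = [c for c in conflicts if c.kind == "capacity_violation"]
        assert len(violations) == 1
        v = violations[0]
        assert (v.observed, v.allowed) == (11, 8)
        assert v.clade == "Tapinocephalidae"

    def test_garnett_fauna_is_within_capacity(self, tree, timeline):
        assignments = assign_taxa(fx.garnett_occurrences(), timeline)
        conflicts = detect_conflicts(assignments, tree, timeline)
        assert [c for c in conflicts if c.kind == "capacity_violation"] == []

    def test_adding_an_occurrence_never_removes_a_violation(self, tree, timeline):
        base = fx.tapinocephalid_occurrences()
        before = {
            (c.kind, c.time, c.clade)
            for c in detect_conflicts(assign_taxa(base, timeline), tree, timeline)
        }
        extra = base + [
            TaxonOccurrence("Extranius", "genus", "Tapinocephalidae",
                            "Tapinocephalus AZ", "West", 264.9, 260.3)
        ]
        after = {
            (c.kind, c.time, c.clade)
            for c in detect_conflicts(assign_taxa(extra, timeline), tree, timeline)
        }
        assert before <= after

    def test_species_excess_in_one_branch_flags_chronospecies(self, tree, timeline):
        records = [
            occ("Moschops capensis", 264.5, 263.5, rank="species",
                clade="Tapinocephalidae"),
            occ("Moschops koupensis", 264.0, 263.2, rank="species",
                clade="Tapinocephalidae"),
        ]
        conflicts = detect_conflicts(assign_taxa(records, timeline), tree, timeline)
        kinds = {c.kind for c in conflicts}
        assert kinds == {"span_violation"}  # anagenesis, not a capacity breach


class TestCongruenceTest:
    def test_model_generated_tree_scores_one(self, timeline):
        table, _ = gen_tree(timeline, SynthSpec(seed=4, p_split=0.7))
        assert len(table.node_ages()) > 0
        score, p = congruence_test(table, timeline, n_perm=99, seed=0)
        assert score == 1.0
        assert 0.0 < p <= 1.0

    def test_fixed_seed_is_deterministic(self, tree, timeline):
        a = congruence_test(tree, timeline, n_perm=199, seed=7)
        b = congruence_test(tree, timeline, n_perm=199, seed=7)
        assert a == b

    def test_p_value_matches_closed_form_enumeration(self):
        # 3 dated nodes, 2 disjunction onsets: under the uniform null each
        # node independently lands within tolerance with probability
        # q = |union of onset windows| / span, so P(score >= obs) is an
        # exact binomial tail the permutation p-value must approach.
        tl = PhaseTimeline(
            (
                PhaseInterval("junction", 100.0, 90.0),
                PhaseInterval("disjunction", 90.0, 60.0),
                PhaseInterval("junction", 60.0, 40.0),
                PhaseInterval("disjunction", 40.0, 10.0),
                PhaseInterval("junction", 10.0, 0.0),
            ),
            (100.0, 0.0),
        )
        tol = 1.0
        table = BranchTable(
            [TreeBranch(0, None, "x", "West", 100.0, 0.0)],
            internal_node_ages=[90.3, 39.5, 70.0],  # two hits, one miss
        )
        score, p = congruence_test(table, tl, n_perm=4999, seed=11, tolerance=tol)
        assert score == pytest.approx(2 / 3)
        q = (2 * 2 * tol) / 100.0  # two windows of width 2*tol in a 100 My span
        from scipy.stats import binom

        exact = binom.sf(1, 3, q)  # P(X >= 2)
        assert p == pytest.approx(exact, abs=0.03)

    def test_tree_without_dated_nodes_rejected(self, timeline):
        empty = BranchTable([TreeBranch(0, None, "x", "West", 300.0, 290.0)],
                            internal_node_ages=[])
        with pytest.raises(FitError):
            congruence_test(empty, timeline, n_perm=9, seed=0)


class TestDateAssemblage:
    def test_garnett_dated_by_the_kas2_window(self, events):
        window, flagged = date_assemblage("Garnett", [("lowstand", "Kas 2")], events)
        assert window == (304.5, 303.5)
        assert not flagged

    def test_single_point_event_returns_its_window(self, events):
        window, flagged = date_assemblage("x", [("lowstand", "Kun3")], events)
        assert window == (277.6, 277.6)
        assert not flagged

    def test_unknown_event_rejected(self, events):
        with pytest.raises(FitError):
            date_assemblage("x", [("lowstand", "Nonesuch 9")], events)

    def test_disjoint_citations_fall_back_with_flag(self, events):
        window, flagged = date_assemblage(
            "x", [("lowstand", "Bash 3"), ("transgression", "Zechstein")], events
        )
        assert flagged
        assert window == (258.0, 256.5)  # the last-cited event's window

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_interval_intersection_oracle(self, seed, events):
        rng = np.random.default_rng(3000 + seed)
        interval_events = [e for e in events if e.is_interval]
        chosen = rng.choice(len(interval_events), size=2, replace=False)
        cites = [(interval_events[i].kind, interval_events[i].name) for i in chosen]
        windows = [interval_events[i].window for i in chosen]
        older = min(w[0] for w in windows)
        younger = max(w[1] for w in windows)
        got, flagged = date_assemblage("x", cites, events)
        if older >= younger:
            assert not flagged and got == (older, younger)
        else:
            assert flagged and got == windows[-1]


class TestEmitChrones:
    def test_empty_timeline_yields_no_chrones(self):
        tl = PhaseTimeline((), (10.0, 0.0))
        assert emit_chrones(tl) == []

    def test_alternating_labels_count_within_kind(self):
        tl = PhaseTimeline(
            (
                PhaseInterval("disjunction", 40.0, 30.0),
                PhaseInterval("junction", 30.0, 20.0),
                PhaseInterval("disjunction", 20.0, 10.0),
                PhaseInterval("junction", 10.0, 0.0),
            ),
            (40.0, 0.0),
        )
        assert [c.label for c in emit_chrones(tl)] == ["Ame1", "Amg1", "Ame2", "Amg2"]

    def test_tapinocephalus_zone_interval_is_amniote_chrone_10(self, timeline):
        chrones = emit_chrones(timeline, origin=fx.AMNIOTE_ORIGIN)
        host = timeline.at(264.0)  # inside the Tapinocephalus AZ
        match = [c for c in chrones if c.older == host.older]
        assert match and match[0].display == "Amniote Chrone 10"
        assert match[0].kind == "Ame"
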