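"""Transfer-event detection, heteroplasmy calling, group-variant logic."""

import dendropy
import numpy as np
import pytest

from mthijack.ht_detection import (HTEvent, call_heteroplasmy,
                                   classify_group_variants,
                                   count_somatic_recurrence, detect_ht_events,
                                   discover_haplotype_specific_variants,
                                   estimate_haplotype_fractions,
                                   infer_event_location,
                                   infer_replaced_haplotype)
from mthijack.phylo_core import fitch_parsimony
from mthijack.reference import a1d1a_specific_variants
from mthijack.variant_store import Variant, VariantTable


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


class TestDetection:
    def test_single_haplotype_single_clade_is_one_event(self):
        tree = _tree("((A,B),(C,D));")
        events = detect_ht_events(tree, dict.fromkeys("ABCD", "A1e"))
        assert len(events) == 1
        assert events[0].members == ("A", "B", "C", "D")

    def test_interrupted_haplotype_splits_by_parsimony(self):
        """Two same-haplotype tumours separated by a different-haplotype
        tumour: the parsimony oracle (1 change) gives 2 events in total."""
        tree = _tree("((A,B),C);")
        labels = {"A": "h1", "B": "h2", "C": "h1"}
        events = detect_ht_events(tree, labels)
        _, changes = fitch_parsimony(tree, labels)
        assert changes == 1
        assert len(events) == changes + 1 == 2
        by_donor = {e.donor_haplotype: set(e.members) for e in events}
        assert by_donor == {"h1": {"A", "C"}, "h2": {"B"}}

    def test_default_cohort_structure_recovered(self, default_cohort,
                                                truth_labels):
        """The study-condition cohort yields 19 events, 11 with donor A1d1a."""
        events = detect_ht_events(default_cohort.nuclear_tree, truth_labels)
        assert len(events) == 19
        assert sum(1 for e in events if e.donor_haplotype == "A1d1a") == 11
        # partition property: members tile the cohort exactly
        all_members = [m for e in events for m in e.members]
        assert len(all_members) == len(set(all_members)) == 539

    def test_tumour_missing_from_tree_rejected(self):
        tree = _tree("((A,B),C);")
        with pytest.raises(ValueError, match="absent"):
            detect_ht_events(tree, {"A": "h", "B": "h", "C": "h", "Z": "h"})


class TestReplacedHaplotype:
    def test_nested_clade_reports_background(self):
        tree = _tree("(((X1,X2),(E1,E2)),(X3,X4));")
        labels = {"X1": "A1e", "X2": "A1e", "X3": "A1e", "X4": "A1e",
                  "E1": "A1d1a", "E2": "A1d1a"}
        events = detect_ht_events(tree, labels)
        event = next(e for e in events if e.donor_haplotype == "A1d1a")
        assert infer_replaced_haplotype(event, tree, labels) == "A1e"

    def test_whole_tree_event_is_unknown(self):
        tree = _tree("((A,B),C);")
        labels = dict.fromkeys("ABC", "A1e")
        event = detect_ht_events(tree, labels)[0]
        assert infer_replaced_haplotype(event, tree, labels) == "Unknown"

    def test_ambiguous_background_is_unknown(self):
        # the transfer clade sits between two equally parsimonious donors
        tree = _tree("((X1,(E1,E2)),Y1);")
        labels = {"X1": "A1e", "Y1": "A1a1", "E1": "B1", "E2": "B1"}
        events = detect_ht_events(tree, labels)
        event = next(e for e in events if e.donor_haplotype == "B1")
        assert infer_replaced_haplotype(event, tree, labels) == "Unknown"

    def test_default_cohort_replaced_all_match_truth(self, default_cohort,
                                                     truth_labels):
        tree = default_cohort.nuclear_tree
        truth = default_cohort.truth
        by_members = {
            tuple(sorted(g)): eid
            for eid, g in truth.tumours.groupby("event_id")["tumour"]}
        replaced = dict(zip(truth.events["event_id"],
                            truth.events["replaced"]))
        for event in detect_ht_events(tree, truth_labels):
            eid = by_members[event.members]
            assert infer_replaced_haplotype(event, tree, truth_labels) \
                == replaced[eid]


class TestHeteroplasmy:
    @pytest.mark.parametrize("fractions, host, expected", [
        ({"B1": 0.55, "A1e": 0.45}, "A1a1", True),    # balanced mixture
        ({"A1a1": 0.15, "A1e": 0.85}, "B1", True),    # minor incoming 15%
        ({"A1e": 0.95, "A1a1": 0.05}, "B1", False),   # below 10% threshold
        ({"A1e": 0.60, "B1": 0.40}, "B1", False),     # host-explained
        ({"A1e": 0.90, "A1a1": 0.10}, "B1", False),   # threshold is strict
    ])
    def test_rule_table(self, fractions, host, expected):
        call = call_heteroplasmy(fractions, host)
        assert call.is_heteroplasmic is expected

    def test_empty_fraction_map_rejected(self):
        with pytest.raises(ValueError):
            call_heteroplasmy({}, "A1e")

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            call_heteroplasmy({"A1e": 0.5, "B1": 0.4}, "A1a1")

    def test_mixture_fractions_recovered(self, default_cohort, profiles):
        """Heteroplasmic tumours decompose into fractions within 0.05."""
        truth = default_cohort.truth.tumours
        het = truth[truth["het_fraction"] < 1.0]
        assert len(het) >= 2
        for row in het.itertuples(index=False):
            vafs = default_cohort.variants.vafs_of(row.tumour)
            fractions = estimate_haplotype_fractions(vafs, profiles)
            assert abs(fractions[row.donor] - row.het_fraction) < 0.05
            assert abs(sum(fractions.values()) - 1.0) < 1e-9


class TestGroupVariants:
    def _event(self, members):
        return HTEvent(event_id="HT1", donor_haplotype="A1e",
                       members=tuple(members))

    def _table(self, calls):
        return VariantTable.from_calls(
            [(s, v, 1.0) for s, v in calls])

    def test_strict_subset_is_somatic(self):
        v = Variant(100, "A", "G")
        table = self._table([("T1", v), ("T2", v),
                             ("T3", Variant(200, "C", "T"))])
        somatic, fixed = classify_group_variants(
            self._event(["T1", "T2", "T3"]), table, donor_profile=set())
        assert v in somatic["T1"] and v in somatic["T2"]
        assert v not in fixed

    def test_variant_in_all_members_is_fixed_unknown(self):
        v = Variant(100, "A", "G")
        table = self._table([("T1", v), ("T2", v), ("T3", v)])
        somatic, fixed = classify_group_variants(
            self._event(["T1", "T2", "T3"]), table, donor_profile=set())
        assert fixed == frozenset({v})
        assert all(v not in s for s in somatic.values())

    def test_singleton_event_private_variants_all_fixed(self):
        v1, v2 = Variant(100, "A", "G"), Variant(200, "C", "T")
        table = self._table([("T1", v1), ("T1", v2)])
        somatic, fixed = classify_group_variants(
            self._event(["T1"]), table, donor_profile=set())
        assert fixed == frozenset({v1, v2})
        assert somatic["T1"] == set()


class TestEventLocation:
    def test_unanimous_location(self):
        event = HTEvent("HT1", "A1e", ("T1", "T2"))
        locs = {"T1": "Nicaragua", "T2": "Nicaragua"}
        assert infer_event_location(event, locs) == "Nicaragua"

    def test_parsimonious_clade_location(self):
        tree = _tree("(((T1,T2),T3),(X1,X2));")
        event = HTEvent("HT1", "A1e", ("T1", "T2", "T3"))
        locs = {"T1": "Belize", "T2": "Belize", "T3": "Chile",
                "X1": "Belize", "X2": "Belize"}
        # parsimony oracle: states at the clade root cost Belize 1 / Chile 2
        # (two within-clade Belize tips and a Belize background)
        assert infer_event_location(event, locs, tree) == "Belize"

    def test_tied_locations_are_ambiguous(self):
        tree = _tree("((T1,T2),(X1,X2));")
        event = HTEvent("HT1", "A1e", ("T1", "T2"))
        # both locations cost 2 changes at the clade root: a tie
        locs = {"T1": "Belize", "T2": "Chile", "X1": "Belize", "X2": "Chile"}
        assert infer_event_location(event, locs, tree) == "ambiguous"

    def test_missing_location_rejected(self):
        event = HTEvent("HT1", "A1e", ("T1", "T2"))
        with pytest.raises(ValueError):
            infer_event_location(event, {"T1": "Belize"})


class TestHaplotypeSpecificVariants:
    def test_nine_variants_unique_to_target(self, profiles):
        found = discover_haplotype_specific_variants(
            "A1d1a", profiles, allow_shared_with={"A1d1"})
        assert found == a1d1a_specific_variants()
        assert len(found) == 9
        kinds = sorted(v.kind for v in found)
        assert kinds.count("substitution") == 8
        assert kinds.count("insertion") == 1

    def test_widely_shared_variant_excluded(self, profiles):
        shared = Variant(16672, "C", "T")  # carried by several haplotypes
        assert shared in profiles["A1d1a"]
        found = discover_haplotype_specific_variants(
            "A1d1a", profiles, allow_shared_with={"A1d1"})
        assert shared not in found

    def test_allow_shared_with_widens_the_set(self, profiles):
        strict = discover_haplotype_specific_variants("A1d1a", profiles)
        relaxed = discover_haplotype_specific_variants(
            "A1d1a", profiles, allow_shared_with={"A1d1"})
        assert strict < relaxed
        assert len(relaxed - strict) == 3  # the variants shared with A1d1

    def test_unknown_haplotype_rejected(self, profiles):
        with pytest.raises(ValueError):
            discover_haplotype_specific_variants("Z9", profiles)


class TestSomaticRecurrence:
    def test_two_independent_backgrounds_count_twice(self):
        ins = Variant(16660, "A", "ACC")
        table = VariantTable.from_calls([
            ("T_HT1", ins, 1.0), ("T_HT2", ins, 1.0), ("T_A1d1a", ins, 1.0)])
        haps = {"T_HT1": "A1e", "T_HT2": "A1a1", "T_A1d1a": "A1d1a"}
        count = count_somatic_recurrence(ins, table, haps,
                                         exclude_haplotypes={"A1d1a"})
        assert count == 2

    def test_only_excluded_carriers_count_zero(self):
        ins = Variant(16660, "A", "ACC")
        table = VariantTable.from_calls([("T1", ins, 1.0), ("T2", ins, 1.0)])
        haps = {"T1": "A1d1a", "T2": "A1d1a"}
        assert count_somatic_recurrence(ins, table, haps,
                                        exclude_haplotypes={"A1d1a"}) == 0

    def test_carriers_within_one_event_collapse(self):
        v = Variant(5000, "G", "A")
        table = VariantTable.from_calls([("T1", v, 1.0), ("T2", v, 1.0)])
        haps = {"T1": "A1e", "T2": "A1e"}
        event = HTEvent("HT1", "A1e", ("T1", "T2"))
        assert count_somatic_recurrence(v, table, haps, set(), [event]) == 1


class TestPartitionInvariant:
    def test_every_tumour_in_exactly_one_event(self):
        rng = np.random.default_rng(2)
        from mthijack.synthetic_cohort import (SimulationConfig,
                                               simulate_ctvt_cohort)
        for seed in rng.integers(2 ** 31, size=3):
            cohort = simulate_ctvt_cohort(SimulationConfig(
                n_tumours=80, n_ht_events=8, seed=int(seed)))
            labels = dict(zip(cohort.truth.tumours["tumour"],
                              cohort.truth.tumours["donor"]))
            events = detect_ht_events(cohort.nuclear_tree, labels)
            members = [m for e in events for m in e.members]
            assert sorted(members) == sorted(labels)
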