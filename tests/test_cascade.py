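"""SAG/DAG/SynAG selection logic, temporal grouping, Venn decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senosyn.cascade import (
    assign_temporal_groups,
    pattern_label,
    select_dags,
    select_sags,
    select_synags,
    venn_counts,
)

from conftest import make_deg_table


def tables_old_young(calls_by_dpt):
    return {
        dpt: make_deg_table(f"old/young@{dpt}", calls)
        for dpt, calls in calls_by_dpt.items()
    }


class TestSelectSags:
    def test_union_over_timepoints(self):
        tables = tables_old_young(
            {
                3: {"gA": ("UP", 1.0), "gB": ("NS", 0.1)},
                8: {"gA": ("NS", 0.1), "gB": ("NS", 0.2)},
                15: {"gA": ("NS", 0.0), "gB": ("NS", 0.0)},
            }
        )
        sags = select_sags(tables)
        assert set(sags) == {"gA"}
        assert sags["gA"].triple() == ("U", "N", "N")

    def test_all_ns_gene_excluded(self):
        tables = tables_old_young({3: {"g": ("NS", 2.0)}})
        assert select_sags(tables) == {}

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            select_sags({})


def drug_tables(calls_by_drug_dpt):
    return {
        (drug, dpt): make_deg_table(f"{drug}/DMSO@{dpt}", calls)
        for (drug, dpt), calls in calls_by_drug_dpt.items()
    }


def full_drug_tables(overrides):
    base = {(drug, dpt): {} for drug in ("KU", "Y", "KUY") for dpt in (3, 8, 15)}
    base.update(overrides)
    return drug_tables(base)


class TestSelectDags:
    def sags_up_at_8(self):
        tables = tables_old_young({8: {"gA": ("UP", 2.0)}})
        return select_sags(tables)

    def test_opposite_direction_restores(self):
        sags = self.sags_up_at_8()
        tables = full_drug_tables({("KU", 8): {"gA": ("DOWN", -1.5)}})
        dags = select_dags(sags, tables)
        assert dags["KU"] == {"gA"}
        assert dags["Y"] == set()

    def test_same_direction_excluded(self):
        sags = self.sags_up_at_8()
        tables = full_drug_tables({("KU", 8): {"gA": ("UP", 1.5)}})
        assert select_dags(sags, tables)["KU"] == set()

    def test_restoration_requires_matching_timepoint_significance(self):
        # senescence change only at 8 DPT; drug effect only at 3 DPT -> no DAG
        sags = self.sags_up_at_8()
        tables = full_drug_tables({("KU", 3): {"gA": ("DOWN", -1.5)}})
        assert select_dags(sags, tables)["KU"] == set()

    def test_strict_mode_requires_return_to_young_level(self):
        sags = self.sags_up_at_8()  # senescence lfc +2.0 at 8 DPT
        # partial restoration: -0.8 leaves residual 1.2 > 0.58 -> rejected
        partial = full_drug_tables({("KU", 8): {"gA": ("DOWN", -0.8)}})
        assert select_dags(sags, partial, mode="strict")["KU"] == set()
        # near-complete restoration: -1.7 leaves residual 0.3 -> accepted
        full = full_drug_tables({("KU", 8): {"gA": ("DOWN", -1.7)}})
        assert select_dags(sags, full, mode="strict")["KU"] == {"gA"}

    def test_missing_table_errors(self):
        sags = self.sags_up_at_8()
        tables = full_drug_tables({})
        del tables[("Y", 15)]
        with pytest.raises(ValueError, match="Y"):
            select_dags(sags, tables)


def combo_tables(vs_ku, vs_y):
    mk = lambda tag, by_dpt: {
        dpt: make_deg_table(f"KU+Y/{tag}@{dpt}", by_dpt.get(dpt, {}))
        for dpt in (3, 8, 15)
    }
    return mk("KU", vs_ku), mk("Y", vs_y)


class TestSelectSynags:
    def test_conjunction_same_direction(self):
        ku, y = combo_tables(
            {15: {"gA": ("UP", 1.0)}}, {15: {"gA": ("UP", 0.9)}}
        )
        synags = select_synags({"gA"}, ku, y)
        assert synags[15] == {"gA": "U"}
        assert synags[3] == {} and synags[8] == {}

    def test_significant_vs_one_drug_only_excluded(self):
        ku, y = combo_tables({15: {"gA": ("UP", 1.0)}}, {})
        assert select_synags({"gA"}, ku, y)[15] == {}

    def test_conflicting_directions_excluded_in_both_modes(self):
        ku, y = combo_tables(
            {15: {"gA": ("UP", 1.0)}}, {15: {"gA": ("DOWN", -1.0)}}
        )
        assert select_synags({"gA"}, ku, y)[15] == {}
        assert select_synags({"gA"}, ku, y, mode="or")[15] == {}

    def test_or_mode_accepts_single_drug_significance(self):
        ku, y = combo_tables({15: {"gA": ("UP", 1.0)}}, {})
        assert select_synags({"gA"}, ku, y, mode="or")[15] == {"gA": "U"}

    def test_non_dag_gene_never_selected(self):
        ku, y = combo_tables(
            {15: {"gB": ("UP", 1.0)}}, {15: {"gB": ("UP", 1.0)}}
        )
        assert select_synags({"gA"}, ku, y)[15] == {}


class TestTemporalGroups:
    @pytest.mark.parametrize(
        "triple,label",
        [
            (("U", "U", "U"), "EML-UP"),
            (("N", "U", "U"), "ML-UP"),
            (("N", "U", "N"), "M-UP"),
            (("N", "N", "U"), "L-UP"),
            (("D", "N", "N"), "E-DOWN"),
            (("N", "D", "N"), "M-DOWN"),
            (("N", "N", "D"), "L-DOWN"),
            (("U", "N", "D"), "U-N-D"),  # mixed pattern keeps its triple name
        ],
    )
    def test_pattern_labels(self, triple, label):
        assert pattern_label(triple) == label

    def test_all_ns_pattern_rejected(self):
        with pytest.raises(ValueError):
            pattern_label(("N", "N", "N"))

    def test_groups_partition_synag_union(self):
        synags = {
            3: {"a": "U", "b": "D"},
            8: {"a": "U"},
            15: {"a": "U", "c": "U"},
        }
        groups, major = assign_temporal_groups(synags)
        members = [g for genes in groups.values() for g in genes]
        assert sorted(members) == ["a", "b", "c"]  # partition, no duplicates
        assert groups["EML-UP"] == ["a"]
        assert groups["E-DOWN"] == ["b"]
        assert groups["L-UP"] == ["c"]
        assert major == {}

    def test_major_group_threshold_is_strict(self):
        ten = {f"g{i}": "U" for i in range(10)}
        eleven = {f"h{i}": "D" for i in range(11)}
        synags = {3: {}, 8: ten, 15: eleven}
        _, major = assign_temporal_groups(synags)
        assert "L-DOWN" in major  # 11 > 10
        assert "M-UP" not in major  # exactly 10 is not major


class TestVennCounts:
    def test_disjoint_singletons(self):
        synags = {3: {"a": "U"}, 8: {"b": "U"}, 15: {"c": "D"}}
        counts = venn_counts(synags)
        assert counts["dpt3_only"] == counts["dpt8_only"] == counts["dpt15_only"] == 1
        assert sum(counts.values()) == 3

    def test_identical_sets(self):
        same = {f"g{i}": "U" for i in range(5)}
        counts = venn_counts({3: same, 8: same, 15: same})
        assert counts["dpt3_dpt8_dpt15"] == 5
        assert sum(counts.values()) == 5

    @given(
        s3=st.sets(st.integers(0, 15)),
        s8=st.sets(st.integers(0, 15)),
        s15=st.sets(st.integers(0, 15)),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_membership_enumeration(self, s3, s8, s15):
        synags = {
            3: {f"g{i}": "U" for i in s3},
            8: {f"g{i}": "U" for i in s8},
            15: {f"g{i}": "U" for i in s15},
        }
        counts = venn_counts(synags)
        # oracle: classify every gene of the union by its membership triple
        brute = {}
        for i in s3 | s8 | s15:
            key = (i in s3, i in s8, i in s15)
            brute[key] = brute.get(key, 0) + 1
        mapping = {
            (True, False, False): "dpt3_only",
            (False, True, False): "dpt8_only",
            (False, False, True): "dpt15_only",
            (True, True, False): "dpt3_dpt8",
            (True, False, True): "dpt3_dpt15",
            (False, True, True): "dpt8_dpt15",
            (True, True, True): "dpt3_dpt8_dpt15",
        }
        for key, region in mapping.items():
            assert counts[region] == brute.get(key, 0)
        assert sum(counts.values()) == len(s3 | s8 | s15)
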