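"""Association tables and the regular/specialist classification."""

import warnings

import pandas as pd
import pytest

from porelist.records import DecayStage
from porelist.substrate import (
    RegularRule,
    build_association_table,
    classify_regular,
    classify_specialist,
    classify_table,
    cluster_hosts,
    host_range_summary,
    host_similarity_input,
)


class TestAssociationTable:
    def test_small_host_table(self, make_record):
        records = [make_record("sp1", host_taxon="Picea abies")] * 3 + \
                  [make_record("sp1", host_taxon="Betula spp.")]
        t = build_association_table(records, "host_taxon")
        assert t.counts.loc["sp1", "Picea abies"] == 3
        assert t.counts.loc["sp1", "Betula spp."] == 1

    def test_missing_axis_excluded_but_counted_in_totals(self, make_record):
        records = [make_record("sp1"), make_record("sp1", host_taxon=None)]
        t = build_association_table(records, "host_taxon")
        assert t.species_totals["sp1"] == 2
        assert t.counts.loc["sp1"].sum() == 1
        assert t.missing_axis["sp1"] == 1

    def test_axis_absent_everywhere_errors(self, make_record):
        records = [make_record("sp1", host_taxon=None)]
        with pytest.raises(ValueError):
            build_association_table(records, "host_taxon")

    def test_unknown_axis_errors(self, make_record):
        with pytest.raises(ValueError, match="unknown axis"):
            build_association_table([make_record()], "colour")

    def test_decay_axis_uses_recoded_classes(self, make_record):
        records = [make_record("sp1", decay_raw=DecayStage.I),
                   make_record("sp1", decay_raw=DecayStage.V)]
        t = build_association_table(records, "decay_class")
        assert set(t.counts.columns) == {"early", "late"}

    def test_cross_axis(self, make_record):
        t = build_association_table([make_record()],
                                    ("host_taxon", "decay_class"))
        assert list(t.counts.columns) == ["Picea abies|medium"]

    def test_against_crosstab_oracle(self, default_sim):
        _, _, records = default_sim
        t = build_association_table(records, "host_taxon")
        df = pd.DataFrame([(r.species_id, r.host_taxon) for r in records
                           if r.host_taxon],
                          columns=["species", "host"])
        oracle = pd.crosstab(df["species"], df["host"])
        assert t.counts.loc[oracle.index, oracle.columns].equals(oracle)

    def test_category_species_counts_match_recount(self, default_sim):
        _, _, records = default_sim
        t = build_association_table(records, "host_taxon")
        per_cat_species = (t.counts > 0).sum(axis=0)
        for host in t.counts.columns:
            seen = {r.species_id for r in records if r.host_taxon == host}
            assert per_cat_species[host] == len(seen)


class TestClassifyRegular:
    @pytest.mark.parametrize("n_cat,total,cat_total,regular,rule", [
        (10, 100, 5000, True, RegularRule.a_share5_total40),
        (2, 30, 5000, True, RegularRule.b_gt1_total_lt40),
        (3, 200, 40, True, RegularRule.c_cat_share5),
        (1, 30, 5000, False, RegularRule.none),
        (1, 100, 5000, False, RegularRule.none),
        (2, 40, 5000, True, RegularRule.a_share5_total40),  # 5% boundary
    ])
    def test_rules(self, n_cat, total, cat_total, regular, rule):
        got_regular, got_rule = classify_regular(n_cat, total, cat_total)
        assert got_regular is regular and got_rule is rule

    def test_zero_category_total_skips_rule_c(self):
        regular, rule = classify_regular(0, 100, 0)
        assert not regular and rule is RegularRule.none

    def test_ratio_rules_are_scale_invariant_above_forty_records(self):
        # for species already in the >= 40-record regime, only ratios
        # matter, so multiplying all counts by 10 never changes the call
        for n_cat in range(0, 30):
            for total in range(max(n_cat, 40), 80, 3):
                before = classify_regular(n_cat, total, 1000)
                after = classify_regular(10 * n_cat, 10 * total, 10000)
                assert before == after

    def test_scaling_can_change_rule_b_outcomes(self):
        # rule b depends on absolute counts: one record of three is not
        # regular, but ten of thirty is
        assert classify_regular(1, 3, 1000)[0] is False
        regular, rule = classify_regular(10, 30, 10000)
        assert regular and rule is RegularRule.b_gt1_total_lt40


class TestClassifySpecialist:
    @pytest.mark.parametrize("n_cat,total,expected", [
        (5, 5, True),     # all records, total within 3-9
        (36, 40, True),   # exactly 90%
        (35, 40, False),  # 87.5% and total outside 3-9
        (2, 2, False),    # needs more than two records
        (8, 9, False),    # 88.9%, and not all records of a 3-9 species
        (3, 3, True),
    ])
    def test_rules(self, n_cat, total, expected):
        regular, _ = classify_regular(n_cat, total, 10_000)
        assert classify_specialist(n_cat, total, regular) is expected

    def test_not_specialist_without_regular(self):
        assert classify_specialist(5, 5, regular=False) is False


class TestHostRange:
    def test_classes_and_threshold(self, make_record):
        records = []
        records += [make_record("one_host", host_taxon="Picea abies")] * 15
        records += [make_record("at_cutoff", host_taxon="Picea abies")] * 10
        for i, host in enumerate(["Picea abies", "Pinus sylvestris",
                                  "Betula spp.", "Populus tremula",
                                  "Alnus incana", "Salix spp.",
                                  "Quercus robur", "Ulmus spp."]):
            records += [make_record("many_hosts", host_taxon=host)] * 2
        t = build_association_table(records, "host_taxon")
        hr = host_range_summary(t, min_records=10).set_index("species_id")
        assert hr.loc["one_host", "host_range_class"] == "1-2"
        assert hr.loc["many_hosts", "host_range_class"] == ">=8"
        # exactly 10 records: excluded (strictly more than min_records)
        assert "at_cutoff" not in hr.index


class TestHostSimilarityInput:
    def _table(self, cells, make_record):
        records = []
        for species, host, n in cells:
            records += [make_record(species, host_taxon=host)] * n
        return build_association_table(records, "host_taxon")

    def test_five_percent_of_species_records(self, make_record):
        t = self._table([("sp1", "Picea abies", 6), ("sp1", "Betula spp.", 94)],
                        make_record)
        pa = host_similarity_input(t)
        assert pa.loc["sp1", "Picea abies"] == 1

    def test_five_percent_of_host_records(self, make_record):
        # 1 of 100 species records, but 10% of the host's 10 records
        t = self._table([("sp1", "Picea abies", 1), ("sp1", "Betula spp.", 99),
                         ("sp2", "Picea abies", 9),
                         ("sp2", "Betula spp.", 500)], make_record)
        pa = host_similarity_input(t)
        assert pa.loc["sp1", "Picea abies"] == 1

    def test_irregular_pair_excluded(self, make_record):
        t = self._table([("sp1", "Picea abies", 1), ("sp1", "Betula spp.", 99),
                         ("sp2", "Picea abies", 99),
                         ("sp2", "Betula spp.", 1)], make_record)
        pa = host_similarity_input(t)
        assert pa.loc["sp1", "Picea abies"] == 0


class TestClusterHosts:
    def test_identical_host_assemblages_merge_at_zero(self):
        pa = pd.DataFrame({"h1": [1, 1, 0], "h2": [1, 1, 0], "h3": [0, 0, 1]},
                          index=["s1", "s2", "s3"])
        d = cluster_hosts(pa)
        assert d.merges[0][2] == pytest.approx(0.0)
        first = {d.leaf_labels[d.merges[0][0]], d.leaf_labels[d.merges[0][1]]}
        assert first == {"h1", "h2"}

    def test_empty_host_column_dropped_with_warning(self):
        pa = pd.DataFrame({"h1": [1, 0], "h2": [1, 1], "h3": [0, 1],
                           "empty": [0, 0]}, index=["s1", "s2"])
        with pytest.warns(UserWarning, match="empty"):
            d = cluster_hosts(pa)
        assert "empty" not in d.leaf_labels

    def test_too_few_hosts_errors(self):
        pa = pd.DataFrame({"h1": [1], "h2": [1]}, index=["s1"])
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cluster_hosts(pa)


class TestClassifyTable:
    def test_specialists_are_regular_in_simulated_data(self, default_sim):
        _, _, records = default_sim
        t = build_association_table(records, "host_taxon")
        for r in classify_table(t):
            if r.specialist:
                assert r.regular
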