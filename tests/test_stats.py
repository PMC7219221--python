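"""Cohort statistics: exact tests, burdens, ratios, rankings, caller voting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from pcpgx import (
    ContingencyTable2x2,
    ValidationError,
    VariantCallSet,
    ensemble_variant_vote,
    fisher_exact_two_sided,
    fold_ratio_table,
    metabolite_rank,
    mutation_burden,
    rank_metabolites,
)
from pcpgx import datasets


class TestFisherExact:
    def test_embryo_arrest_table_reproduces_published_p(self):
        p = fisher_exact_two_sided(ContingencyTable2x2(9, 22, 1, 30))
        assert round(p, 4) == 0.0125

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_diagonal_two_by_two_enumerates_to_one_third(self):
        # margins (2,2)/(2,2): three tables with probabilities 1/6, 4/6, 1/6
        p = fisher_exact_two_sided(ContingencyTable2x2(2, 0, 0, 2))
        assert p == pytest.approx(1 / 3)

    def test_degenerate_margins_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_matches_scipy_oracle_exhaustively_for_small_totals(self):
        for n in range(1, 17):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = ContingencyTable2x2(a, b, c, d)
                        r1 = a + b
                        c1 = a + c
                        if r1 in (0, n) or c1 in (0, n):
                            continue
                        expected = scipy_fisher([[a, b], [c, d]]).pvalue
                        assert fisher_exact_two_sided(t) == pytest.approx(expected)

    def test_matches_scipy_oracle_on_random_tables_up_to_total_100(self):
        rng = np.random.default_rng(77)
        for _ in range(300):
            n = int(rng.integers(4, 101))
            cuts = np.sort(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            if (a + b) in (0, n) or (a + c) in (0, n):
                continue
            expected = scipy_fisher([[a, b], [c, d]]).pvalue
            assert fisher_exact_two_sided(
                ContingencyTable2x2(int(a), int(b), int(c), int(d))
            ) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_invariant_under_row_and_column_swaps(self, cells):
        a, b, c, d = cells
        if (a + b + c + d) == 0:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1 = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            p2 = fisher_exact_two_sided(ContingencyTable2x2(d, c, b, a))
        assert p1 == pytest.approx(p2)

    def test_negative_or_fractional_cells_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestMutationBurden:
    @pytest.mark.parametrize(
        "count,expected",
        [(30, 0.8004269), (36, 0.96)],
    )
    def test_published_burdens(self, count, expected):
        got = mutation_burden(count, 37.48)
        assert round(got, 7 if expected < 0.9 else 2) == expected

    def test_zero_mutations_zero_burden(self):
        assert mutation_burden(0, 37.48) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            mutation_burden(-1, 37.48)


class TestFoldRatios:
    def test_epas1_published_ratio(self):
        out = fold_ratio_table({"Epas1": 1074.63}, {"Epas1": 80.01}, ["Epas1"])
        assert out.iloc[0]["ratio"] == 13.43

    def test_equal_values_ratio_one(self):
        out = fold_ratio_table({"g": 7.7}, {"g": 7.7}, ["g"])
        assert out.iloc[0]["ratio"] == 1.00

    def test_zero_case_value_gives_zero_ratio(self):
        out = fold_ratio_table({"Egln3": 0.0}, {"Egln3": 1.44}, ["Egln3"])
        assert out.iloc[0]["ratio"] == 0.0

    def test_zero_reference_flagged_undefined_not_infinite(self):
        out = fold_ratio_table({"g": 3.0}, {"g": 0.0}, ["g"])
        assert bool(out.iloc[0]["undefined"])
        assert np.isnan(out.iloc[0]["ratio"])

    def test_missing_gene_listed_in_error(self):
        with pytest.raises(ValidationError, match="gX"):
            fold_ratio_table({"g": 1.0}, {"g": 1.0}, ["g", "gX"])

    def test_marker_table_recomputes_printed_ratios_except_flagged_cells(self):
        m = datasets.HIF2A_MARKER_RPKM
        for col, printed_col, tag in [
            ("RS0", "printed_rs0_ram", "rs0_ram"),
            ("RS12", "printed_rs12_ram", "rs12_ram"),
        ]:
            out = fold_ratio_table(
                dict(zip(m["gene"], m[col])), dict(zip(m["gene"], m["RAM"])),
                list(m["gene"]))
            for rec, printed in zip(out.itertuples(index=False), m[printed_col]):
                key = (rec.gene, tag)
                if key in datasets.MARKER_RATIO_DISCREPANCIES:
                    assert rec.ratio == pytest.approx(
                        datasets.MARKER_RATIO_DISCREPANCIES[key])
                    assert rec.ratio != printed
                else:
                    assert rec.ratio == pytest.approx(printed)


class TestMetaboliteRanking:
    def test_succinate_third_most_abundant_in_rs0(self):
        ranking = rank_metabolites(datasets.METABOLITES_RS0)
        assert metabolite_rank(ranking, "Succinate") == 3

    def test_tied_abundances_share_smaller_rank_alphabetically(self):
        # RS0 has Ascorbate and Glutamate tied at 2.57
        ranking = rank_metabolites(datasets.METABOLITES_RS0)
        tied = ranking[ranking["abundance"] == 2.57]
        assert tied["rank"].tolist() == [5, 5]
        assert tied["metabolite"].tolist() == ["Ascorbate", "Glutamate"]

    def test_single_entry_is_rank_one(self):
        ranking = rank_metabolites([("Lactate", 3.2)])
        assert metabolite_rank(ranking, "Lactate") == 1

    def test_random_profile_matches_brute_force_sort(self):
        rng = np.random.default_rng(55)
        names = [f"m{i}" for i in range(12)]
        profile = [(n, float(rng.uniform(0, 20))) for n in names]
        ranking = rank_metabolites(profile)
        expected = [n for n, _ in sorted(profile, key=lambda r: (-r[1], r[0]))]
        assert ranking["metabolite"].tolist() == expected

    def test_unknown_metabolite_query_rejected(self):
        ranking = rank_metabolites([("Lactate", 1.0)])
        with pytest.raises(ValidationError, match="Krebsium"):
            metabolite_rank(ranking, "Krebsium")


class TestEnsembleVote:
    def _sets(self, *groups):
        return [VariantCallSet.from_keys(f"c{i}", g) for i, g in enumerate(groups)]

    def test_three_identical_sets_returned(self):
        keys = {("1", 10, "A", "T"), ("2", 20, "C", "G")}
        assert ensemble_variant_vote(self._sets(keys, keys, keys), 2) == keys

    def test_pairwise_disjoint_sets_give_empty(self):
        sets = self._sets({("1", 1, "A", "T")}, {("2", 2, "C", "G")}, {("3", 3, "G", "A")})
        assert ensemble_variant_vote(sets, 2) == frozenset()

    def test_overlap_counting_matches_brute_force(self):
        sets = self._sets({"A", "B"}, {"B", "C"}, {"C", "D"})
        assert ensemble_variant_vote(sets, 2) == {"B", "C"}

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.integers(0, 15)), min_size=3, max_size=5))
    def test_raising_min_callers_never_adds_variants(self, groups):
        sets = self._sets(*groups)
        for k in range(1, len(sets)):
            assert ensemble_variant_vote(sets, k + 1) <= ensemble_variant_vote(sets, k)

    def test_min_callers_above_set_count_rejected(self):
        with pytest.raises(ValidationError):
            ensemble_variant_vote(self._sets({"A"}), 2)

    def test_variant_line_parsing(self):
        cs = VariantCallSet.from_lines("varscan", ["chr1:100:A:T", "", "chr2:5:G:C"])
        assert ("chr1", 100, "A", "T") in cs.variants
        with pytest.raises(ValidationError, match="malformed"):
            VariantCallSet.from_lines("x", ["chr1:100:A"])
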