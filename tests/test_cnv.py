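"""Arm-level CNV calling, cohort frequencies, synteny and concordance."""

import numpy as np
import pandas as pd
import pytest

from pcpgx import (
    GenomeArms,
    SegmentProfile,
    ValidationError,
    arm_fraction_altered,
    call_arm_events,
    cohort_arm_loss_frequency,
    concordance_table,
    default_toy_arms,
    simulate_segment_cohort,
    syntenic_proportion,
)


def _arms(rows):
    return GenomeArms(pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"]))


def _profile(sample, segs):
    return SegmentProfile(
        sample=sample,
        segments=pd.DataFrame(segs, columns=["chrom", "start", "end", "copy_number"]))


ONE_ARM = _arms([("1", "p", 0, 100)])


class TestArmFraction:
    def test_full_arm_loss_segment_gives_fraction_one(self):
        p = _profile("S1", [("1", 0, 100, 1.0)])
        out = arm_fraction_altered(p, ONE_ARM)
        assert out.iloc[0]["fraction_loss"] == 1.0
        assert out.iloc[0]["fraction_gain"] == 0.0

    def test_no_segments_gives_zero_fractions(self):
        out = arm_fraction_altered(_profile("S1", []), ONE_ARM)
        assert (out[["fraction_loss", "fraction_gain"]] == 0.0).all().all()

    def test_partial_coverage_matches_per_base_count(self):
        p = _profile("S1", [("1", 0, 30, 1.0), ("1", 50, 80, 0.0)])
        out = arm_fraction_altered(p, ONE_ARM)
        assert out.iloc[0]["fraction_loss"] == pytest.approx(0.6)

    def test_random_toy_genomes_match_per_base_oracle(self):
        rng = np.random.default_rng(31)
        arms = _arms([("1", "p", 0, 400), ("1", "q", 400, 1000), ("2", "q", 0, 700)])
        for trial in range(10):
            segs = []
            for chrom, lo, hi in [("1", 0, 1000), ("2", 0, 700)]:
                pos = lo
                while pos < hi:
                    length = int(rng.integers(20, 300))
                    end = min(pos + length, hi)
                    if rng.random() < 0.7:
                        segs.append((chrom, pos, end, float(rng.choice([0, 1, 2, 3, 4]))))
                    pos = end
            p = _profile("S", segs)
            out = arm_fraction_altered(p, arms, 2.0, 2.0)
            # per-base oracle
            for rec in out.itertuples(index=False):
                arm = arms.table[(arms.table["chrom"] == rec.chrom)
                                 & (arms.table["arm"] == rec.arm)].iloc[0]
                base_state = np.zeros(arm["end"] - arm["start"])
                for chrom, s, e, cn in segs:
                    if chrom != rec.chrom:
                        continue
                    s2, e2 = max(s, arm["start"]), min(e, arm["end"])
                    if s2 < e2:
                        if cn < 2:
                            base_state[s2 - arm["start"]: e2 - arm["start"]] = -1
                        elif cn > 2:
                            base_state[s2 - arm["start"]: e2 - arm["start"]] = 1
                assert rec.fraction_loss == pytest.approx((base_state == -1).mean())
                assert rec.fraction_gain == pytest.approx((base_state == 1).mean())


class TestCallArmEvents:
    def test_exactly_half_is_neutral(self):
        t = pd.DataFrame([{"sample": "S", "chrom": "1", "arm": "p",
                           "fraction_loss": 0.5, "fraction_gain": 0.0}])
        assert call_arm_events(t, 0.5).iloc[0]["call"] == "neutral"

    def test_just_above_half_is_loss(self):
        t = pd.DataFrame([{"sample": "S", "chrom": "1", "arm": "p",
                           "fraction_loss": 0.51, "fraction_gain": 0.0}])
        assert call_arm_events(t, 0.5).iloc[0]["call"] == "loss"

    def test_random_tables_match_brute_force_rule(self):
        rng = np.random.default_rng(4)
        loss = rng.uniform(0, 1, 50)
        gain = np.minimum(rng.uniform(0, 1, 50), 1 - loss)
        t = pd.DataFrame({"sample": "S", "chrom": "1", "arm": "p",
                          "fraction_loss": loss, "fraction_gain": gain})
        thr = 0.3
        out = call_arm_events(t, thr)
        for rec in out.itertuples(index=False):
            if rec.fraction_loss > thr and rec.fraction_gain > thr:
                expected = "loss" if rec.fraction_loss >= rec.fraction_gain else "gain"
            elif rec.fraction_loss > thr:
                expected = "loss"
            elif rec.fraction_gain > thr:
                expected = "gain"
            else:
                expected = "neutral"
            assert rec.call == expected


class TestCohortFrequency:
    def test_single_sample_loss_gives_frequency_one(self):
        fr = arm_fraction_altered(_profile("S1", [("1", 0, 100, 1.0)]), ONE_ARM)
        freq = cohort_arm_loss_frequency([call_arm_events(fr, 0.5)])
        assert freq.iloc[0]["loss_frequency"] == 1.0

    def test_seeded_cohort_frequency_equals_truth_realization(self):
        arms = default_toy_arms(n_chroms=2)
        profiles, truth = simulate_segment_cohort({"1p": 0.4}, 10, arms, seed=5)
        events = [call_arm_events(arm_fraction_altered(p, arms), 0.5) for p in profiles]
        freq = cohort_arm_loss_frequency(events)
        truth_freq = (
            truth[(truth["chrom"] == "1") & (truth["arm"] == "p")]["call"] == "loss"
        ).mean()
        got = freq[(freq["chrom"] == "1") & (freq["arm"] == "p")].iloc[0]
        assert got["loss_frequency"] == truth_freq

    def test_frequencies_invariant_to_sample_order(self):
        arms = default_toy_arms(n_chroms=1)
        profiles, _ = simulate_segment_cohort({"1p": 0.6, "1q": 0.3}, 8, arms, seed=2)
        events = [call_arm_events(arm_fraction_altered(p, arms), 0.5) for p in profiles]
        a = cohort_arm_loss_frequency(events)
        b = cohort_arm_loss_frequency(list(reversed(events)))
        pd.testing.assert_frame_equal(a, b)
        assert a["loss_frequency"].between(0, 1).all()


def _hom(pairs):
    return pd.DataFrame(pairs, columns=["rat_gene", "human_gene"])


class TestSynteny:
    def test_no_shared_orthologs_absent_from_table(self):
        syn = syntenic_proportion(
            _hom([("r1", "h1")]),
            pd.DataFrame([{"gene": "r1", "chrom": "1", "arm": "p"}]),
            pd.DataFrame([{"gene": "h1", "chrom": "A"}, {"gene": "h2", "chrom": "B"}]),
        )
        assert not ((syn["rat_arm"] == "p") & (syn["human_chrom"] == "B")).any()

    def test_full_chromosome_syntenic_gives_proportion_one(self):
        pairs = [(f"r{i}", f"h{i}") for i in range(10)]
        rat = pd.DataFrame([{"gene": r, "chrom": "5", "arm": "q"} for r, _ in pairs])
        hum = pd.DataFrame([{"gene": h, "chrom": "A"} for _, h in pairs])
        syn = syntenic_proportion(_hom(pairs), rat, hum)
        assert syn.iloc[0]["proportion"] == 1.0

    def test_partial_synteny_matches_brute_force_count(self):
        pairs = [(f"r{i}", f"h{i}") for i in range(3)]
        rat = pd.DataFrame([{"gene": f"r{i}", "chrom": "5", "arm": "q"} for i in range(3)])
        hum = pd.DataFrame([{"gene": f"h{i}", "chrom": "A"} for i in range(10)])
        syn = syntenic_proportion(_hom(pairs), rat, hum)
        row = syn[(syn["rat_arm"] == "q") & (syn["human_chrom"] == "A")].iloc[0]
        assert row["syntenic_gene_count"] == 3
        assert row["proportion"] == pytest.approx(0.3)

    def test_counts_never_exceed_human_totals(self):
        rng = np.random.default_rng(9)
        pairs = [(f"r{i}", f"h{i}") for i in range(40)]
        rat = pd.DataFrame(
            [{"gene": r, "chrom": str(rng.integers(1, 4)),
              "arm": rng.choice(["p", "q"])} for r, _ in pairs])
        hum = pd.DataFrame(
            [{"gene": h, "chrom": rng.choice(["A", "B"])} for _, h in pairs])
        syn = syntenic_proportion(_hom(pairs), rat, hum)
        totals = hum.groupby("chrom")["gene"].nunique()
        per_chrom = syn.groupby("human_chrom")["syntenic_gene_count"].sum()
        for chrom, count in per_chrom.items():
            assert count <= totals[chrom]
        assert syn["proportion"].between(0, 1).all()


class TestConcordance:
    def _synteny(self, rows):
        return pd.DataFrame(
            rows, columns=["rat_chrom", "rat_arm", "human_chrom",
                           "syntenic_gene_count", "human_chrom_gene_total", "proportion"])

    def test_single_row_join_gives_nan_with_warning(self):
        syn = self._synteny([("1", "p", "A", 5, 10, 0.5)])
        freq = pd.DataFrame([{"chrom": "A", "arm": "p", "loss_frequency": 0.4}])
        with pytest.warns(UserWarning, match="undefined"):
            table, rho = concordance_table(syn, freq, {"1p"})
        assert len(table) == 1
        assert np.isnan(rho)

    def test_monotone_construction_gives_perfect_rank_correlation(self):
        rng = np.random.default_rng(14)
        props = rng.uniform(0.05, 0.95, 6)
        syn = self._synteny(
            [("1", "p", f"C{i}", 1, 10, p) for i, p in enumerate(props)])
        freq = pd.DataFrame(
            [{"chrom": f"C{i}", "arm": "", "loss_frequency": p * 0.8}
             for i, p in enumerate(props)])
        table, rho = concordance_table(syn, freq, {"1p"})
        assert rho == pytest.approx(1.0)

    def test_join_row_count_contract(self):
        syn = self._synteny(
            [("1", "p", "A", 1, 10, 0.1), ("2", "q", "A", 1, 10, 0.2),
             ("3", "p", "B", 1, 10, 0.3)])
        freq = pd.DataFrame(
            [{"chrom": "A", "arm": "p", "loss_frequency": 0.1},
             {"chrom": "A", "arm": "q", "loss_frequency": 0.2},
             {"chrom": "B", "arm": "p", "loss_frequency": 0.3}])
        table, _ = concordance_table(syn, freq, {"1p", "2q", "3p"})
        # 2 synteny rows match chromosome A (2 arms each) + 1 matches B (1 arm)
        assert len(table) == 5

    def test_empty_join_rejected(self):
        syn = self._synteny([("1", "p", "A", 1, 10, 0.1)])
        freq = pd.DataFrame([{"chrom": "A", "arm": "p", "loss_frequency": 0.1}])
        with pytest.raises(ValidationError, match="empty"):
            concordance_table(syn, freq, {"9q"})
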