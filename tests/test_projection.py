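"""Cross-species projection: cluster matching, insertion modes, species artifact."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pcpgx import (
    CrossSpeciesProjection,
    SyntheticCohortSpec,
    ValidationError,
    match_clusters,
    simulate_expression_cohort,
    simulate_foreign_samples,
)
from conftest import SMALL


class TestMatchClusters:
    def test_identical_labelings_identity_mapping(self):
        labels = pd.Series([1, 1, 2, 2, 3], index=list("abcde"))
        mapping = match_clusters(labels, labels, list("abcde"))
        assert mapping == {1: 1, 2: 2, 3: 3}

    def test_label_permutation_recovered(self):
        a = pd.Series([1, 1, 2, 2, 3, 3], index=list("abcdef"))
        b = pd.Series([3, 3, 1, 1, 2, 2], index=list("abcdef"))
        assert match_clusters(a, b, list("abcdef")) == {3: 1, 1: 2, 2: 3}

    def test_matches_exhaustive_permutation_search(self):
        rng = np.random.default_rng(17)
        ids = [f"s{i}" for i in range(30)]
        for _ in range(20):
            n_cl = int(rng.integers(2, 6))
            a = pd.Series(rng.integers(1, n_cl + 1, size=30), index=ids)
            b = pd.Series(rng.integers(1, n_cl + 1, size=30), index=ids)
            mapping = match_clusters(a, b, ids)
            got = sum((mapping[b[s]] == a[s]) for s in ids)
            best = 0
            b_vals = sorted(b.unique())
            a_vals = sorted(a.unique())
            for perm in itertools.permutations(a_vals, min(len(b_vals), len(a_vals))):
                trial = dict(zip(b_vals, perm))
                best = max(best, sum(trial.get(b[s]) == a[s] for s in ids))
            assert got == best

    def test_extra_clusters_map_to_novel(self):
        a = pd.Series([1, 1, 1, 1], index=list("abcd"))
        b = pd.Series([1, 1, 2, 2], index=list("abcd"))
        mapping = match_clusters(a, b, list("abcd"))
        assert sorted(mapping.values(), key=str) == [1, "novel"]

    def test_empty_shared_set_rejected(self):
        labels = pd.Series([1], index=["a"])
        with pytest.raises(ValidationError, match="empty"):
            match_clusters(labels, labels, [])


@pytest.fixture(scope="module")
def cohort():
    return simulate_expression_cohort(SyntheticCohortSpec(seed=1, **SMALL))


def _target_reference_cluster(model, cohort, truth):
    baseline = model.fit_reference()
    mapping = match_clusters(baseline.labels, cohort.labels, list(cohort.labels.index))
    return mapping[truth["target_cluster"]]


class TestSingleProjection:
    def test_duplicate_of_reference_sample_joins_its_cluster(self, cohort):
        ref = cohort.matrix
        dup = ref.subset_samples([ref.sample_ids[0]])
        dup = dup.rename_genes({})  # no-op; keep raw state
        dup._data.columns = ["copycat"]
        model = CrossSpeciesProjection(ref, dup, k=4, n_resamples=40, seed=2)
        res = model.fit("single")
        baseline = model.fit_reference()
        expected = baseline.labels[ref.sample_ids[0]]
        row = res.table.iloc[0]
        assert row["assigned_reference_cluster"] == expected
        assert row[f"mean_consensus_{expected}"] > 0.95

    def test_zero_offset_foreign_assigned_to_target_cluster(self, cohort):
        spec = SyntheticCohortSpec(seed=1, species_offset_scale=0.0, n_foreign=2, **SMALL)
        foreign, truth = simulate_foreign_samples(spec, cohort)
        model = CrossSpeciesProjection(cohort.matrix, foreign, k=4, n_resamples=40, seed=4)
        res = model.fit("single")
        target = _target_reference_cluster(model, cohort, truth)
        assert (res.table["assigned_reference_cluster"] == target).all()

    def test_moderate_offset_still_assigned_to_target_cluster(self, cohort):
        spec = SyntheticCohortSpec(seed=2, species_offset_scale=1.0, n_foreign=2, **SMALL)
        foreign, truth = simulate_foreign_samples(spec, cohort)
        model = CrossSpeciesProjection(cohort.matrix, foreign, k=4, n_resamples=40, seed=4)
        res = model.fit("single")
        target = _target_reference_cluster(model, cohort, truth)
        assert (res.table["assigned_reference_cluster"] == target).all()
        assert res.reference_agreement >= 0.9

    def test_gene_panel_mismatch_lists_missing(self, cohort):
        foreign = cohort.matrix.subset_samples([cohort.matrix.sample_ids[0]])
        foreign = foreign.subset_genes(foreign.gene_ids[:100])
        foreign._data.columns = ["f1"]
        with pytest.raises(ValidationError, match="panel mismatch"):
            CrossSpeciesProjection(cohort.matrix, foreign, k=4)


class TestJointProjection:
    def test_large_offset_foreign_capture_their_own_cluster(self, cohort):
        spec = SyntheticCohortSpec(seed=1, species_offset_scale=3.0, **SMALL)
        foreign, _ = simulate_foreign_samples(spec, cohort)
        model = CrossSpeciesProjection(cohort.matrix, foreign, k=4, n_resamples=40, seed=6)
        res = model.fit("joint")
        assert res.table["joint_cluster"].nunique() == 1
        ff = res.joint_summary["foreign_foreign_consensus"]
        fr = res.joint_summary["foreign_reference_consensus"]
        assert all(ff > v for v in fr.values())

    def test_foreign_identical_to_reference_samples_keep_their_clusters(self, cohort):
        ref = cohort.matrix
        picked = ref.sample_ids[:3]
        foreign = ref.subset_samples(picked)
        foreign._data.columns = [f"f{i}" for i in range(3)]
        model = CrossSpeciesProjection(ref, foreign, k=4, n_resamples=40, seed=7)
        res = model.fit("joint")
        baseline = model.fit_reference()
        for orig, row in zip(picked, res.table.itertuples(index=False)):
            assert row.assigned_reference_cluster == baseline.labels[orig]

    def test_foreign_consensus_nonincreasing_in_offset_scale(self):
        # the species artifact strengthens with the offset: mean
        # foreign-foreign consensus (over seeds) is non-increasing as the
        # offset shrinks, and strictly smaller at zero offset than at 3x
        scales = [3.0, 1.5, 0.0]
        means = {s: [] for s in scales}
        conditions = dict(SMALL, separation=6.0)
        for seed in range(1, 6):
            c = simulate_expression_cohort(SyntheticCohortSpec(seed=seed, **conditions))
            for s in scales:
                spec = SyntheticCohortSpec(seed=seed, species_offset_scale=s, **conditions)
                f, _ = simulate_foreign_samples(spec, c)
                res = CrossSpeciesProjection(
                    c.matrix, f, k=4, n_resamples=30, seed=seed).fit("joint")
                means[s].append(res.joint_summary["foreign_foreign_consensus"])
        avg = {s: np.mean(v) for s, v in means.items()}
        assert avg[3.0] >= avg[1.5] >= avg[0.0]
        assert avg[3.0] > avg[0.0]

    def test_joint_mode_requires_two_foreign_samples(self, cohort):
        foreign = cohort.matrix.subset_samples([cohort.matrix.sample_ids[0]])
        foreign._data.columns = ["f1"]
        model = CrossSpeciesProjection(cohort.matrix, foreign, k=4, n_resamples=5, seed=1)
        with pytest.raises(ValidationError, match="joint"):
            model.fit("joint")


class TestReferenceClustering:
    def test_reference_labels_recover_truth(self, cohort):
        model = CrossSpeciesProjection(
            cohort.matrix,
            _dummy_foreign(cohort),
            k=4, n_resamples=60, seed=3)
        baseline = model.fit_reference()
        assert adjusted_rand_score(cohort.labels, baseline.labels) == 1.0

    def test_rerun_with_same_seed_identical(self, cohort):
        args = dict(k=4, n_resamples=30, seed=12)
        f = _dummy_foreign(cohort)
        a = CrossSpeciesProjection(cohort.matrix, f, **args).fit_reference()
        b = CrossSpeciesProjection(cohort.matrix, f, **args).fit_reference()
        assert a.labels.equals(b.labels)
        assert a.consensus.equals(b.consensus)


def _dummy_foreign(cohort):
    spec = SyntheticCohortSpec(seed=3, n_foreign=1, **SMALL)
    foreign, _ = simulate_foreign_samples(spec, cohort)
    return foreign
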