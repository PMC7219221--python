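"""Cross-species projection of foreign samples onto reference tumor subtypes.

Dropping a handful of foreign-species (rat) samples into a large human
reference cohort and clustering everything jointly fails in a characteristic
way: a shared species effect makes the foreign samples more similar to each
other than to any human subtype, so they capture their own cluster. The
scheme implemented here works around that batch-like artifact:

1. cluster the reference cohort alone (the baseline subtype solution);
2. re-cluster the reference plus *one* foreign sample at a time, so a single
   inserted sample cannot form a species cluster and must join a subtype;
3. name the joint clusters in baseline terms by optimal one-to-one matching
   over the reference samples, and read off the foreign sample's subtype.

The joint ("all foreign samples at once") mode is also provided, precisely
because contrasting it with the one-at-a-time mode demonstrates the species
artifact.

Model/results layout::

    model = CrossSpeciesProjection(reference_raw, foreign_raw, k=4, seed=7)
    res = model.fit(mode="single")   # ProjectionResults; res.table
    res_joint = model.fit(mode="joint")

Both input matrices are raw-scale, on the same (human-id) gene panel; each
consensus run re-normalizes the combined matrix so the inserted sample
participates in the same upper-quartile/log2/median-centering transform as
the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .consensus import ConsensusClustering, ConsensusResults
from .errors import ValidationError
from .matrix import ExpressionMatrix
from .prep import normalize_expression

NOVEL = "novel"


def match_clusters(
    labels_a: pd.Series, labels_b: pd.Series, shared_samples: list[str]
) -> dict:
    """Optimal one-to-one mapping of b's clusters onto a's clusters.

    Maximizes total agreement over *shared_samples* (Hungarian assignment on
    the contingency table). Clusters of b left unmatched (when b has more
    clusters than a) map to ``"novel"``.
    """
    if not shared_samples:
        raise ValidationError("shared sample set is empty")
    missing = [s for s in shared_samples if s not in labels_a.index or s not in labels_b.index]
    if missing:
        raise ValidationError(f"samples missing from a labeling: {missing[:5]}")
    a = labels_a.loc[shared_samples]
    b = labels_b.loc[shared_samples]
    a_vals = sorted(a.unique())
    b_vals = sorted(b.unique())
    table = np.zeros((len(b_vals), len(a_vals)))
    for i, bv in enumerate(b_vals):
        for j, av in enumerate(a_vals):
            table[i, j] = ((b == bv) & (a == av)).sum()
    rows, cols = linear_sum_assignment(-table)
    mapping = {bv: NOVEL for bv in b_vals}
    for i, j in zip(rows, cols):
        mapping[b_vals[i]] = a_vals[j]
    return mapping


@dataclass
class ProjectionResults:
    """Per-foreign-sample subtype assignments from a projection fit.

    ``table`` has one row per foreign sample: the joint-run cluster, the
    assigned reference cluster, and the mean consensus between the foreign
    sample and each baseline cluster's members (diagnostic columns
    ``mean_consensus_<cluster>``). Joint mode adds ``foreign_foreign_consensus``
    (mean pairwise consensus among foreign samples) and
    ``foreign_reference_consensus`` (mean to each reference cluster) in
    ``joint_summary``.
    """

    mode: str
    table: pd.DataFrame
    reference_labels: pd.Series
    reference_agreement: float
    joint_results: dict = field(default_factory=dict)
    joint_summary: dict = field(default_factory=dict)

    def assigned_cluster(self, foreign_sample: str):
        return self.table.set_index("foreign_sample").loc[foreign_sample, "assigned_reference_cluster"]

    def summary(self) -> str:
        lines = [
            f"Cross-species projection ({self.mode} mode)",
            f"  reference samples: {len(self.reference_labels)}",
            f"  foreign samples:   {len(self.table)}",
            f"  reference-label agreement vs baseline: {self.reference_agreement:.3f}",
        ]
        for rec in self.table.itertuples(index=False):
            lines.append(
                f"  {rec.foreign_sample} -> cluster {rec.assigned_reference_cluster}"
            )
        if self.joint_summary:
            ff = self.joint_summary["foreign_foreign_consensus"]
            lines.append(f"  foreign-foreign consensus: {ff:.3f}")
            for c, v in self.joint_summary["foreign_reference_consensus"].items():
                lines.append(f"  foreign-reference consensus (cluster {c}): {v:.3f}")
        return "\n".join(lines)


class CrossSpeciesProjection:
    """Project foreign samples onto a reference cohort's subtype solution.

    Parameters
    ----------
    reference, foreign
        Raw-scale expression matrices on a shared gene panel (foreign
        already translated to the reference's gene ids). A gene-panel
        mismatch raises with the missing genes listed.
    k
        Number of reference subtypes; fixed for all projection runs (the
        baseline solution's k is carried over, never re-selected with
        foreign samples included).
    """

    def __init__(
        self,
        reference: ExpressionMatrix,
        foreign: ExpressionMatrix,
        k: int = 4,
        n_resamples: int = 100,
        subsample_frac: float = 0.8,
        distance_metric: str = "pearson",
        linkage_method: str = "average",
        uq_target: float = 1000.0,
        seed: int = 0,
    ):
        if reference.state != "raw" or foreign.state != "raw":
            raise ValidationError("projection expects raw-scale matrices")
        missing = [g for g in reference.gene_ids if g not in set(foreign.gene_ids)]
        if missing:
            raise ValidationError(
                f"gene panel mismatch; {len(missing)} reference genes missing from "
                f"the foreign matrix, e.g. {missing[:5]}"
            )
        overlap = set(reference.sample_ids) & set(foreign.sample_ids)
        if overlap:
            raise ValidationError(f"sample ids present on both sides: {sorted(overlap)[:5]}")
        self.reference = reference
        self.foreign = foreign.subset_genes(reference.gene_ids)
        self.k = int(k)
        self.n_resamples = int(n_resamples)
        self.subsample_frac = float(subsample_frac)
        self.distance_metric = distance_metric
        self.linkage_method = linkage_method
        self.uq_target = float(uq_target)
        self.seed = int(seed)
        # deterministic per-run seeds: one for the baseline, one per insertion
        n_runs = 2 + foreign.n_samples
        self._run_seeds = [
            int(s) for s in
            np.random.SeedSequence(self.seed).generate_state(n_runs) % (2**31)
        ]
        self._baseline: ConsensusResults | None = None

    # ------------------------------------------------------------------
    def _consensus(self, matrix_raw: ExpressionMatrix, seed: int) -> ConsensusResults:
        normalized = normalize_expression(matrix_raw, uq_target=self.uq_target)
        model = ConsensusClustering(
            normalized,
            n_resamples=self.n_resamples,
            subsample_frac=self.subsample_frac,
            distance_metric=self.distance_metric,
            linkage_method=self.linkage_method,
            seed=seed,
        )
        return model.fit(self.k)

    def fit_reference(self) -> ConsensusResults:
        """Baseline consensus solution on the reference cohort alone."""
        if self._baseline is None:
            self._baseline = self._consensus(self.reference, self._run_seeds[0])
        return self._baseline

    # ------------------------------------------------------------------
    def _project_run(
        self, joint: ConsensusResults, foreign_ids: list[str]
    ) -> tuple[pd.DataFrame, float, dict]:
        baseline = self.fit_reference()
        ref_ids = self.reference.sample_ids
        mapping = match_clusters(baseline.labels, joint.labels, ref_ids)
        agreement = float(
            np.mean([mapping[joint.labels[s]] == baseline.labels[s] for s in ref_ids])
        )
        clusters = sorted(baseline.labels.unique())
        members = {c: baseline.cluster_members(c) for c in clusters}
        rows = []
        for f in foreign_ids:
            mean_cons = {c: joint.mean_consensus(f, members[c]) for c in clusters}
            joint_cluster = joint.labels[f]
            # a joint cluster absent from the reference samples is novel
            assigned = mapping.get(joint_cluster, NOVEL)
            if assigned == NOVEL:
                # the foreign sample's joint cluster holds no reference
                # samples; fall back to the closest baseline cluster
                assigned = max(mean_cons, key=lambda c: mean_cons[c])
            row = {
                "foreign_sample": f,
                "joint_cluster": joint_cluster,
                "assigned_reference_cluster": assigned,
            }
            row.update({f"mean_consensus_{c}": mean_cons[c] for c in clusters})
            rows.append(row)
        return pd.DataFrame(rows), agreement, members

    def fit(self, mode: str = "single") -> ProjectionResults:
        """Project foreign samples; ``mode`` is ``"single"`` or ``"joint"``."""
        baseline = self.fit_reference()
        foreign_ids = self.foreign.sample_ids
        if mode == "single":
            tables, agreements, joint_results = [], [], {}
            for i, f in enumerate(foreign_ids):
                combined = self.reference.hstack(self.foreign.subset_samples([f]))
                joint = self._consensus(combined, self._run_seeds[2 + i])
                tab, agree, _ = self._project_run(joint, [f])
                tables.append(tab)
                agreements.append(agree)
                joint_results[f] = joint
            return ProjectionResults(
                mode="single",
                table=pd.concat(tables, ignore_index=True),
                reference_labels=baseline.labels,
                reference_agreement=float(np.mean(agreements)),
                joint_results=joint_results,
            )
        if mode == "joint":
            if len(foreign_ids) < 2:
                raise ValidationError("joint mode needs >= 2 foreign samples")
            combined = self.reference.hstack(self.foreign)
            joint = self._consensus(combined, self._run_seeds[1])
            tab, agree, members = self._project_run(joint, foreign_ids)
            ff = float(
                np.mean(
                    [joint.consensus.loc[a, b]
                     for i, a in enumerate(foreign_ids)
                     for b in foreign_ids[i + 1:]]
                )
            )
            fr = {
                c: float(
                    np.mean([joint.mean_consensus(f, mem) for f in foreign_ids])
                )
                for c, mem in members.items()
            }
            return ProjectionResults(
                mode="joint",
                table=tab,
                reference_labels=baseline.labels,
                reference_agreement=agree,
                joint_results={"joint": joint},
                joint_summary={
                    "foreign_foreign_consensus": ff,
                    "foreign_reference_consensus": fr,
                },
            )
        raise ValidationError(f"mode must be 'single' or 'joint', got {mode!r}")


# ----------------------------------------------------------------------
# functional surface
# ----------------------------------------------------------------------
def cluster_reference(
    ref: ExpressionMatrix, k: int, seed: int = 0, **kwargs
) -> ConsensusResults:
    """Normalize and consensus-cluster the reference cohort alone."""
    uq_target = kwargs.pop("uq_target", 1000.0)
    normalized = normalize_expression(ref, uq_target=uq_target) if ref.state == "raw" else ref
    return ConsensusClustering(normalized, seed=seed, **kwargs).fit(k)


def project_single_sample(
    ref: ExpressionMatrix, foreign_sample: ExpressionMatrix, k: int, seed: int = 0, **kwargs
) -> ProjectionResults:
    """One-at-a-time insertion of a single foreign sample (see module docs)."""
    if foreign_sample.n_samples != 1:
        raise ValidationError("project_single_sample expects exactly one foreign sample")
    return CrossSpeciesProjection(ref, foreign_sample, k=k, seed=seed, **kwargs).fit("single")


def project_joint(
    ref: ExpressionMatrix, foreign_set: ExpressionMatrix, k: int, seed: int = 0, **kwargs
) -> ProjectionResults:
    """Joint insertion of all foreign samples at once (species-artifact mode)."""
    return CrossSpeciesProjection(ref, foreign_set, k=k, seed=seed, **kwargs).fit("joint")
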