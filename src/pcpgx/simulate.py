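"""Synthetic inputs with known ground truth.

Generators for every input the pipeline consumes, emulating the study
conditions at desk scale:

* a human-like reference cohort of 173 samples in four expression subtypes
  (sizes 60/50/40/23 — the kinase, pseudohypoxia, WNT-altered and cortical
  admixture groups of the human PCPG taxonomy), log-normal raw expression
  with subtype-marker genes carrying the separation signal;
* foreign-species samples drawn from one subtype's centroid plus a single
  shared species-offset vector (the batch-like species effect the
  one-at-a-time projection design works around);
* a biomart-style homology table in which a prescribed fraction of genes
  (default 1699/3000) end up with high-confidence one-to-one orthologs,
  plus toy rat/human gene coordinates and a cytoBand file for synteny;
* SEG copy-number cohorts with prescribed per-arm loss probabilities.

All generation is a pure function of (spec, seed); each generated artifact
round-trips through the corresponding reader, and truth tables are returned
so downstream stages can be scored without re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv import GenomeArms, SegmentProfile
from .errors import ValidationError
from .matrix import ExpressionMatrix
from .orthologs import HomologyTable

#: Subtype names of the human PCPG expression taxonomy, in cluster order.
SUBTYPE_NAMES = ("pseudohypoxia", "kinase", "wnt-altered", "cortical-admixture")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-condition parameters for the synthetic cohort.

    ``separation`` is the minimum pairwise Euclidean distance between
    subtype centroids in units of ``noise_sd``, carried by
    ``markers_per_cluster`` exclusive marker genes per subtype; all other
    genes vary with ``background_sd`` (markers are the high-variance
    genes, which is what makes MAD-based gene selection meaningful).
    Subtypes are hierarchically related: consecutive pairs form families
    sharing a parent expression program of the same size and strength, so
    family mates correlate positively — as real tumor subtypes do — and
    sit exactly ``separation`` apart while cross-family pairs sit
    ``separation * sqrt(2)`` apart. ``mappable_fraction`` controls how
    many genes receive a high-confidence one-to-one ortholog (default
    1699/3000, the study's cross-species mapping rate).
    """

    n_genes: int = 3000
    cluster_sizes: tuple[int, ...] = (60, 50, 40, 23)
    separation: float = 10.0
    noise_sd: float = 1.0
    markers_per_cluster: int = 20
    background_sd: float = 0.1
    n_foreign: int = 3
    foreign_target_cluster: int = 1
    species_offset_scale: float = 3.0
    family_strength: float = 0.7
    mappable_fraction: float = 1699 / 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.cluster_sizes):
            raise ValidationError("cluster sizes must be >= 1")
        if self.separation < 0 or self.noise_sd < 0:
            raise ValidationError("separation and noise_sd must be >= 0")
        if not (0.0 <= self.mappable_fraction <= 1.0):
            raise ValidationError("mappable_fraction must lie in [0, 1]")
        if len(self.cluster_sizes) * self.markers_per_cluster > self.n_genes:
            raise ValidationError("not enough genes for the requested marker blocks")
        if not (1 <= self.foreign_target_cluster <= len(self.cluster_sizes)):
            raise ValidationError("foreign_target_cluster out of range")

    @property
    def n_samples(self) -> int:
        return sum(self.cluster_sizes)

    @property
    def k(self) -> int:
        return len(self.cluster_sizes)


@dataclass
class SyntheticCohort:
    """A generated reference cohort plus the truth needed to score it."""

    spec: SyntheticCohortSpec
    matrix: ExpressionMatrix          # raw scale
    labels: pd.Series                 # true subtype per sample (1..k)
    centroids: pd.DataFrame           # cluster x gene, log2 scale
    gene_sds: pd.Series               # per-gene noise SD (log2 scale)
    marker_genes: dict[int, list[str]] = field(default_factory=dict)
    family_genes: dict[int, list[str]] = field(default_factory=dict)


def _rng_for(spec: SyntheticCohortSpec, stream: int) -> np.random.Generator:
    # one seed lineage per generator stream so cohort/foreign/homology/SEG
    # draws are independent but jointly reproducible
    return np.random.default_rng(np.random.SeedSequence((spec.seed, stream)))


def _to_raw(log2_values: np.ndarray) -> np.ndarray:
    return np.maximum(np.exp2(log2_values) - 1.0, 0.0)


def simulate_expression_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate the subtype-structured reference cohort (raw scale).

    Centroids live on the log2 scale: a shared per-gene baseline
    (Uniform(3, 8)) plus an elevation of
    ``e = separation * noise_sd / sqrt(2 m)`` on each subtype's exclusive
    block of ``m`` marker genes, plus the same elevation on a family block
    shared by consecutive subtype pairs (1,2), (3,4), ... (a trailing
    unpaired subtype gets no family block). Family mates are then exactly
    ``separation * noise_sd`` apart (the shared block cancels in the
    difference) and cross-family pairs farther, mirroring the hierarchy of
    real tumor subtypes. Raw values are ``2**(centroid + noise) - 1``,
    truncated at 0, so the matrix is non-negative and round-trips through
    normalization.
    """
    rng = _rng_for(spec, 1)
    G, k, m = spec.n_genes, spec.k, spec.markers_per_cluster
    genes = [f"HG{i:05d}" for i in range(1, G + 1)]
    samples = [f"H{i:03d}" for i in range(1, spec.n_samples + 1)]
    labels = np.repeat(np.arange(1, k + 1), spec.cluster_sizes)

    baseline = rng.uniform(3.0, 8.0, size=G)
    n_families = k // 2
    n_marker = k * m + n_families * m
    if n_marker > G:
        raise ValidationError("not enough genes for marker and family blocks")
    marker_idx = rng.choice(G, size=n_marker, replace=False) if m else np.array([], dtype=int)
    elevation = spec.separation * spec.noise_sd / np.sqrt(2 * m) if m else 0.0
    centroids = np.tile(baseline, (k, 1))
    marker_genes: dict[int, list[str]] = {}
    family_genes: dict[int, list[str]] = {}
    for c in range(k):
        block = marker_idx[c * m:(c + 1) * m]
        centroids[c, block] += elevation
        marker_genes[c + 1] = [genes[i] for i in block]
    fam_elev = elevation * spec.family_strength
    for fam in range(n_families):
        block = marker_idx[k * m + fam * m: k * m + (fam + 1) * m]
        centroids[2 * fam, block] += fam_elev
        centroids[2 * fam + 1, block] += fam_elev
        family_genes[fam + 1] = [genes[i] for i in block]

    sds = np.full(G, spec.background_sd * spec.noise_sd)
    if m:
        sds[marker_idx] = spec.noise_sd
    noise = rng.normal(0.0, 1.0, size=(spec.n_samples, G)) * sds
    log2_values = centroids[labels - 1] + noise
    df = pd.DataFrame(_to_raw(log2_values).T, index=genes, columns=samples)
    return SyntheticCohort(
        spec=spec,
        matrix=ExpressionMatrix(df, state="raw"),
        labels=pd.Series(labels, index=samples, name="true_cluster"),
        centroids=pd.DataFrame(centroids, index=range(1, k + 1), columns=genes),
        gene_sds=pd.Series(sds, index=genes),
        marker_genes=marker_genes,
        family_genes=family_genes,
    )


def simulate_foreign_samples(
    spec: SyntheticCohortSpec, cohort: SyntheticCohort
) -> tuple[ExpressionMatrix, dict]:
    """Generate foreign-species samples from one subtype's centroid.

    All foreign samples share a single offset vector of norm
    ``species_offset_scale * separation * noise_sd`` (a batch-like species
    effect), plus independent per-sample noise. The offset points in a
    random direction over the background (non-marker) genes — a
    species-specific expression program orthogonal to every human subtype
    program. At large offsets the foreign samples therefore decorrelate
    from every human subtype while staying tightly correlated with each
    other (the regime in which joint clustering lets them capture their
    own cluster); at small offsets they are ordinary target-subtype
    members. Returns the raw matrix and a truth record with the target
    cluster and offset norm.
    """
    target = spec.foreign_target_cluster
    if target not in cohort.marker_genes and target > spec.k:
        raise ValidationError(f"unknown target cluster {target}")
    rng = _rng_for(spec, 2)
    G = spec.n_genes
    genes = cohort.matrix.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    is_marker = np.zeros(G, dtype=bool)
    for block in list(cohort.marker_genes.values()) + list(cohort.family_genes.values()):
        for g in block:
            is_marker[gene_pos[g]] = True
    direction = rng.normal(size=G)
    direction[is_marker] = 0.0
    norm = np.linalg.norm(direction)
    if norm > 0:
        direction /= norm
    offset_norm = spec.species_offset_scale * spec.separation * spec.noise_sd
    offset = direction * offset_norm

    centroid = cohort.centroids.loc[target].to_numpy()
    sds = cohort.gene_sds.to_numpy()
    noise = rng.normal(0.0, 1.0, size=(spec.n_foreign, G)) * sds
    log2_values = centroid + offset + noise
    samples = [f"R{i:02d}" for i in range(1, spec.n_foreign + 1)]
    df = pd.DataFrame(_to_raw(log2_values).T, index=cohort.matrix.gene_ids, columns=samples)
    truth = {
        "target_cluster": target,
        "offset_norm": offset_norm,
        "offset": pd.Series(offset, index=cohort.matrix.gene_ids),
        "samples": samples,
    }
    return ExpressionMatrix(df, state="raw"), truth


# ----------------------------------------------------------------------
# homology / toy genomes
# ----------------------------------------------------------------------
@dataclass
class SyntheticHomology:
    table: HomologyTable
    rat_gene_coords: pd.DataFrame     # gene, chrom, arm, start, end (rat ids)
    human_gene_chrom: pd.DataFrame    # gene, chrom (human ids)
    rat_arms: GenomeArms
    mappable_rat_genes: list[str]     # exactly the survivors of restriction


def default_toy_arms(n_chroms: int = 5, arm_length: int = 1_000_000) -> GenomeArms:
    """A small rat-like genome: n chromosomes, each with p and q arms."""
    rows = []
    for c in range(1, n_chroms + 1):
        rows.append({"chrom": str(c), "arm": "p", "start": 0, "end": arm_length})
        rows.append({"chrom": str(c), "arm": "q", "start": arm_length, "end": 2 * arm_length})
    return GenomeArms(pd.DataFrame(rows))


def simulate_homology(
    spec: SyntheticCohortSpec,
    rat_genes: list[str],
    human_genes: list[str],
    arms: GenomeArms | None = None,
    n_human_chroms: int = 4,
) -> SyntheticHomology:
    """Biomart-style homology records with a prescribed mappable fraction.

    Exactly ``round(mappable_fraction * n_genes)`` rat genes receive a
    unique high-confidence one2one human partner (so exactly that many
    records survive :func:`~pcpgx.orthologs.restrict_high_confidence_one_to_one`);
    the remainder are split among one2many, many2many and low-confidence
    decoys that cannot survive restriction. Genes are placed uniformly on
    toy rat arms and human chromosomes for synteny analyses.
    """
    if len(rat_genes) != len(human_genes):
        raise ValidationError("rat and human gene lists must have equal length")
    rng = _rng_for(spec, 3)
    n = len(rat_genes)
    n_mappable = int(round(spec.mappable_fraction * n))
    order = rng.permutation(n)
    mappable = sorted(order[:n_mappable])
    rest = sorted(order[n_mappable:])

    rat_ids = [f"rat_{g}" for g in rat_genes]
    rows = [
        {"rat_gene": rat_ids[i], "human_gene": human_genes[i],
         "homology_type": "one2one", "confidence": "high"}
        for i in mappable
    ]
    # decoys: cycle through record shapes that never survive restriction
    for j, i in enumerate(rest):
        kind = j % 3
        partner = human_genes[i]
        if kind == 0:      # low-confidence one2one
            rows.append({"rat_gene": rat_ids[i], "human_gene": partner,
                         "homology_type": "one2one", "confidence": "low"})
        elif kind == 1:    # one rat gene -> two human genes
            alt = human_genes[rest[(j + 1) % len(rest)]]
            rows.append({"rat_gene": rat_ids[i], "human_gene": partner,
                         "homology_type": "one2many", "confidence": "high"})
            if alt != partner:
                rows.append({"rat_gene": rat_ids[i], "human_gene": alt,
                             "homology_type": "one2many", "confidence": "high"})
        else:              # many2many
            rows.append({"rat_gene": rat_ids[i], "human_gene": partner,
                         "homology_type": "many2many", "confidence": "high"})
    table = HomologyTable(pd.DataFrame(rows).drop_duplicates(["rat_gene", "human_gene"]))

    if arms is None:
        arms = default_toy_arms()
    arm_recs = arms.table
    assign = rng.integers(0, len(arm_recs), size=n)
    coord_rows = []
    for i, g in enumerate(rat_ids):
        rec = arm_recs.iloc[assign[i]]
        pos = int(rng.integers(rec["start"], rec["end"] - 1))
        coord_rows.append({"gene": g, "chrom": rec["chrom"], "arm": rec["arm"],
                           "start": pos, "end": pos + 1000})
    rat_coords = pd.DataFrame(coord_rows)
    human_chroms = [f"h{c}" for c in range(1, n_human_chroms + 1)]
    human_assign = rng.integers(0, n_human_chroms, size=n)
    human_coords = pd.DataFrame(
        {"gene": human_genes, "chrom": [human_chroms[i] for i in human_assign]}
    )
    return SyntheticHomology(
        table=table,
        rat_gene_coords=rat_coords,
        human_gene_chrom=human_coords,
        rat_arms=arms,
        mappable_rat_genes=[rat_ids[i] for i in mappable],
    )


# ----------------------------------------------------------------------
# SEG cohorts
# ----------------------------------------------------------------------
def simulate_segment_cohort(
    arm_loss_probs: dict[str, float],
    n_samples: int,
    arms: GenomeArms,
    seed: int = 0,
) -> tuple[list[SegmentProfile], pd.DataFrame]:
    """SEG cohort with prescribed per-arm loss probabilities.

    Keys of *arm_loss_probs* are arm names like ``"1p"``. When an arm draws
    a loss, a copy-number-1 segment covers a strictly-greater-than-half
    fraction of the arm (uniform in (0.5, 1]); the arm's remainder — and
    every arm not drawn — is covered at copy number 2. The truth table
    records every intended call.
    """
    for a, p in arm_loss_probs.items():
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"loss probability for arm {a} outside [0,1]")
    rng = np.random.default_rng(seed)
    profiles, truth_rows = [], []
    for s in range(1, n_samples + 1):
        sample = f"S{s:03d}"
        seg_rows = []
        for rec in arms.table.itertuples(index=False):
            arm_name = f"{rec.chrom}{rec.arm}"
            p = arm_loss_probs.get(arm_name, 0.0)
            length = rec.end - rec.start
            is_loss = rng.random() < p
            if is_loss:
                frac = rng.uniform(0.5, 1.0)
                loss_len = int(np.floor(frac * length))
                if 2 * loss_len <= length:   # enforce strict > 1/2 on integer bp
                    loss_len = length // 2 + 1
                seg_rows.append({"chrom": rec.chrom, "start": rec.start,
                                 "end": rec.start + loss_len, "copy_number": 1.0})
                if rec.start + loss_len < rec.end:
                    seg_rows.append({"chrom": rec.chrom, "start": rec.start + loss_len,
                                     "end": rec.end, "copy_number": 2.0})
            else:
                seg_rows.append({"chrom": rec.chrom, "start": rec.start,
                                 "end": rec.end, "copy_number": 2.0})
            truth_rows.append({"sample": sample, "chrom": rec.chrom, "arm": rec.arm,
                               "call": "loss" if is_loss else "neutral"})
        profiles.append(SegmentProfile(sample=sample, segments=pd.DataFrame(seg_rows)))
    return profiles, pd.DataFrame(truth_rows)
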