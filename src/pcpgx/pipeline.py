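"""End-to-end pipeline stages and the run manifest.

Each stage function reads/writes the text formats defined in
:mod:`pcpgx.io`, records its timing and record counts, and contributes to a
JSON run manifest that echoes the configuration and seed so a run can be
reproduced byte-for-byte. The CLI in :mod:`pcpgx.cli` is a thin wrapper
over these functions.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import io
from .cnv import (
    GenomeArms,
    arm_fraction_altered,
    call_arm_events,
    cohort_arm_loss_frequency,
    concordance_table,
    syntenic_proportion,
)
from .config import PipelineConfig
from .consensus import ConsensusClustering
from .errors import PcpgxError, ValidationError
from .matrix import ExpressionMatrix
from .orthologs import (
    load_homology_table,
    restrict_high_confidence_one_to_one,
    translate_to_human_ids,
    write_homology_table,
)
from .prep import drop_all_zero_genes, normalize_expression, select_top_mad_genes
from .projection import CrossSpeciesProjection
from .simulate import (
    SyntheticCohortSpec,
    default_toy_arms,
    simulate_expression_cohort,
    simulate_foreign_samples,
    simulate_homology,
    simulate_segment_cohort,
)
from . import stats as cohort_stats
from . import datasets

logger = logging.getLogger("pcpgx")

#: Default per-arm loss probabilities for the simulated human SEG cohort.
DEFAULT_ARM_LOSS_PROBS = {"h1p": 0.7, "h2q": 0.5, "h3p": 0.3, "h4q": 0.2}

#: Rat arms treated as lost in the simulated model for the concordance join.
DEFAULT_RAT_LOSS_ARMS = ("1p", "2q", "3p")


class RunManifest:
    """Collects stage timings/counts and writes the JSON manifest."""

    def __init__(self, out_dir: Path, config: PipelineConfig, seed: int):
        self.out_dir = Path(out_dir)
        self.config = config
        self.seed = seed
        self.stages: list[dict] = []
        self.complete = False

    def record(self, stage: str, elapsed: float, counts: dict) -> None:
        logger.info("stage %s finished in %.2fs: %s", stage, elapsed, counts)
        self.stages.append({"stage": stage, "seconds": round(elapsed, 3), "counts": counts})

    def write(self) -> Path:
        self.out_dir.mkdir(parents=True, exist_ok=True)
        path = self.out_dir / "manifest.json"
        payload = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "stages": self.stages,
            "complete": self.complete,
            "gene_centering": "before MAD selection",
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def _require(inputs: dict, key: str) -> Path:
    if key not in inputs or inputs[key] is None:
        raise ValidationError(f"missing required input {key!r}")
    p = Path(inputs[key])
    if not p.exists():
        raise ValidationError(f"input file for {key!r} not found: {p}")
    return p


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------
def stage_simulate(config: PipelineConfig, out_dir: Path, seed: int | None = None,
                   spec: SyntheticCohortSpec | None = None) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = SyntheticCohortSpec(seed=seed if seed is not None else config.rng_seed)
    cohort = simulate_expression_cohort(spec)
    foreign, truth = simulate_foreign_samples(spec, cohort)
    io.write_expression_tsv(cohort.matrix, out_dir / "reference_expression.tsv")
    # foreign matrix re-indexed by rat gene ids so the ortholog-translation
    # stage is exercised end to end
    foreign_rat = foreign.rename_genes({g: f"rat_{g}" for g in foreign.gene_ids})
    io.write_expression_tsv(foreign_rat, out_dir / "foreign_expression.tsv")
    cohort.labels.rename_axis("sample").to_frame().to_csv(
        out_dir / "truth_labels.tsv", sep="\t")
    hom = simulate_homology(spec, cohort.matrix.gene_ids, cohort.matrix.gene_ids)
    write_homology_table(hom.table, out_dir / "homology.tsv")
    hom.rat_gene_coords.to_csv(out_dir / "rat_gene_coords.tsv", sep="\t", index=False)
    hom.human_gene_chrom.to_csv(out_dir / "human_gene_chrom.tsv", sep="\t", index=False)
    io.write_cytoband(hom.rat_arms, out_dir / "rat_cytoband.txt")
    human_arms = GenomeArms(
        pd.DataFrame(
            [{"chrom": f"h{c}", "arm": a, "start": 0 if a == "p" else 1_000_000,
              "end": 1_000_000 if a == "p" else 2_000_000}
             for c in range(1, 5) for a in ("p", "q")]
        )
    )
    io.write_cytoband(human_arms, out_dir / "human_cytoband.txt")
    profiles, seg_truth = simulate_segment_cohort(
        DEFAULT_ARM_LOSS_PROBS, n_samples=20, arms=human_arms, seed=spec.seed)
    io.write_seg(profiles, out_dir / "human_cohort.seg")
    seg_truth.to_csv(out_dir / "truth_arm_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"foreign_sample": truth["samples"],
         "target_cluster": truth["target_cluster"],
         "offset_norm": truth["offset_norm"]}
    ).to_csv(out_dir / "truth_foreign.tsv", sep="\t", index=False)
    return {
        "reference_samples": cohort.matrix.n_samples,
        "foreign_samples": foreign.n_samples,
        "genes": cohort.matrix.n_genes,
        "homology_records": len(hom.table),
        "seg_samples": len(profiles),
    }


def stage_prep(config: PipelineConfig, inputs: dict, out_dir: Path) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = io.read_expression_tsv(_require(inputs, "expression"))
    filtered = drop_all_zero_genes(raw)
    normalized = normalize_expression(filtered, uq_target=config.uq_target)
    panel = select_top_mad_genes(normalized, config.mad_top_n)
    io.write_expression_tsv(normalized, out_dir / "normalized_expression.tsv")
    (out_dir / "selected_genes.txt").write_text("\n".join(panel) + "\n")
    return {"genes_in": raw.n_genes, "genes_kept": filtered.n_genes,
            "panel_size": len(panel)}


def stage_cluster(config: PipelineConfig, inputs: dict, out_dir: Path,
                  k: int | None = None) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = io.read_expression_tsv(_require(inputs, "expression"))
    normalized = normalize_expression(drop_all_zero_genes(raw), uq_target=config.uq_target)
    panel = select_top_mad_genes(normalized, config.mad_top_n)
    model = ConsensusClustering(
        normalized.subset_genes(panel),
        n_resamples=config.n_resamples,
        subsample_frac=config.subsample_frac,
        distance_metric=config.distance_metric,
        linkage_method=config.linkage_method,
        seed=config.rng_seed,
    )
    if k is not None:
        res = model.fit(k)
        chosen = k
        res.consensus.to_csv(out_dir / f"consensus_k{k}.tsv", sep="\t")
        results = {k: res}
        delta = None
    else:
        scan = model.fit_range(config.k_range)
        chosen = scan.k_selected
        results = scan.results
        delta = scan.delta_area
        delta.to_csv(out_dir / "delta_area.tsv", sep="\t", index=False)
        scan.results[chosen].consensus.to_csv(
            out_dir / f"consensus_k{chosen}.tsv", sep="\t")
    labels = results[chosen].labels
    labels.rename_axis("sample").to_frame().to_csv(out_dir / "labels.tsv", sep="\t")
    return {"samples": len(labels), "k": chosen,
            "cdf_area": round(results[chosen].cdf_area, 6)}


def stage_project(config: PipelineConfig, inputs: dict, out_dir: Path,
                  k: int = 4, mode: str = "single") -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_raw = io.read_expression_tsv(_require(inputs, "reference"))
    foreign_raw = io.read_expression_tsv(_require(inputs, "foreign"))
    homology = load_homology_table(_require(inputs, "homology"))
    restricted = restrict_high_confidence_one_to_one(homology)

    ref_filtered = ref_raw
    normalized_ref = normalize_expression(ref_filtered, uq_target=config.uq_target)
    panel = select_top_mad_genes(normalized_ref, config.mad_top_n)
    foreign_filtered = drop_all_zero_genes(foreign_raw)
    foreign_human, report = translate_to_human_ids(foreign_filtered, restricted, panel)
    shared_panel = [g for g in panel if g in set(foreign_human.gene_ids)]
    model = CrossSpeciesProjection(
        ref_filtered.subset_genes(shared_panel),
        foreign_human.subset_genes(shared_panel),
        k=k,
        n_resamples=config.n_resamples,
        subsample_frac=config.subsample_frac,
        distance_metric=config.distance_metric,
        linkage_method=config.linkage_method,
        uq_target=config.uq_target,
        seed=config.rng_seed,
    )
    res = model.fit(mode=mode)
    res.table.to_csv(out_dir / f"projection_{mode}.tsv", sep="\t", index=False)
    payload = res.table.to_dict(orient="records")
    (out_dir / f"projection_{mode}.json").write_text(
        json.dumps({"mode": mode, "assignments": payload}, indent=2, default=str) + "\n")
    report.to_frame().to_csv(out_dir / "mapping_report.tsv", sep="\t", index=False)
    return {"panel_size": len(shared_panel), "foreign_samples": len(res.table),
            "mapped_genes": report.n_mapped,
            "reference_agreement": round(res.reference_agreement, 4)}


def stage_cnv(config: PipelineConfig, inputs: dict, out_dir: Path,
              rat_loss_arms: tuple[str, ...] = DEFAULT_RAT_LOSS_ARMS) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    human_arms = io.read_cytoband(_require(inputs, "human_cytoband"))
    profiles = io.read_seg(_require(inputs, "seg"))
    events = []
    for p in profiles:
        fr = arm_fraction_altered(p, human_arms, config.loss_cn_cutoff, config.gain_cn_cutoff)
        events.append(call_arm_events(fr, config.arm_loss_threshold))
    event_table = pd.concat(events, ignore_index=True)
    event_table.to_csv(out_dir / "arm_events.tsv", sep="\t", index=False)
    freq = cohort_arm_loss_frequency(events)
    freq.to_csv(out_dir / "arm_loss_frequency.tsv", sep="\t", index=False)
    counts = {"seg_samples": len(profiles), "arms": len(human_arms)}
    if inputs.get("homology"):
        homology = load_homology_table(_require(inputs, "homology"))
        restricted = restrict_high_confidence_one_to_one(homology)
        rat_coords = pd.read_csv(_require(inputs, "rat_gene_coords"), sep="\t",
                                 dtype={"chrom": str})
        human_chrom = pd.read_csv(_require(inputs, "human_gene_chrom"), sep="\t",
                                  dtype={"chrom": str})
        synteny = syntenic_proportion(restricted.records, rat_coords, human_chrom)
        synteny.to_csv(out_dir / "synteny.tsv", sep="\t", index=False)
        table, rho = concordance_table(synteny, freq, set(rat_loss_arms))
        table.to_csv(out_dir / "concordance.tsv", sep="\t", index=False)
        counts.update({"synteny_rows": len(synteny), "concordance_rows": len(table),
                       "spearman_rho": None if pd.isna(rho) else round(rho, 4)})
    return counts


def stage_stats(config: PipelineConfig, out_dir: Path) -> dict:
    """Statistics over the built-in printed study tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fisher_p = cohort_stats.fisher_exact_two_sided(datasets.EMBRYO_ARREST_TABLE)
    burdens = {
        name: cohort_stats.mutation_burden(n, config.coding_genome_mb)
        for name, n in datasets.MUTATION_COUNTS.items()
    }
    markers = datasets.HIF2A_MARKER_RPKM
    ratios = cohort_stats.fold_ratio_table(
        dict(zip(markers["gene"], markers["RS0"])),
        dict(zip(markers["gene"], markers["RAM"])),
        list(markers["gene"]),
    )
    ranking = cohort_stats.rank_metabolites(datasets.METABOLITES_RS0)
    payload = {
        "embryo_arrest_fisher_p": fisher_p,
        "mutation_burden_per_mb": {k: round(v, 7) for k, v in burdens.items()},
        "rs0_ram_fold_ratios": dict(zip(ratios["gene"], ratios["ratio"])),
        "succinate_rank_rs0": cohort_stats.metabolite_rank(ranking, "Succinate"),
    }
    (out_dir / "printed_table_stats.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    ratios.to_csv(out_dir / "fold_ratios.tsv", sep="\t", index=False)
    ranking.to_csv(out_dir / "metabolite_ranking.tsv", sep="\t", index=False)
    return {"fisher_p": payload["embryo_arrest_fisher_p"],
            "succinate_rank": payload["succinate_rank_rs0"]}


_STAGE_FUNCS = {
    "simulate": lambda cfg, inp, out, **kw: stage_simulate(cfg, out, **kw),
    "prep": lambda cfg, inp, out, **kw: stage_prep(cfg, inp, out),
    "cluster": lambda cfg, inp, out, **kw: stage_cluster(cfg, inp, out, **kw),
    "project": lambda cfg, inp, out, **kw: stage_project(cfg, inp, out, **kw),
    "cnv": lambda cfg, inp, out, **kw: stage_cnv(cfg, inp, out, **kw),
    "stats": lambda cfg, inp, out, **kw: stage_stats(cfg, out),
}


def run_pipeline(config: PipelineConfig, inputs: dict, stages: list[str],
                 out_dir: str | Path, **stage_kwargs) -> RunManifest:
    """Run the requested stages in order, writing a JSON manifest.

    Any stage error aborts the run with the stage name attached; the
    manifest is still written, flagged incomplete.
    """
    manifest = RunManifest(Path(out_dir), config, config.rng_seed)
    try:
        for stage in stages:
            if stage not in _STAGE_FUNCS:
                raise ValidationError(f"unknown stage {stage!r}")
            t0 = time.perf_counter()
            counts = _STAGE_FUNCS[stage](config, inputs, Path(out_dir),
                                         **stage_kwargs.get(stage, {}))
            manifest.record(stage, time.perf_counter() - t0, counts)
    except PcpgxError as exc:
        manifest.write()
        raise PcpgxError(f"stage {stage!r} failed: {exc}") from exc
    manifest.complete = True
    manifest.write()
    return manifest
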