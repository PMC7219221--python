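"""Arm-level somatic copy-number events and rat-human synteny.

The tumor genome of the SDH-deficient rat model is typified not by point
mutations but by recurrent chromosome-arm losses. This module calls those
events from segmented copy-number profiles with an explicit rule — an arm is
"lost" when segments below the copy-number cutoff cover strictly more than
half of the arm — computes cohort-level per-arm loss frequencies, quantifies
rat-human synteny as the proportion of high-confidence one-to-one orthologs a
rat arm shares with each human chromosome, and joins the two into a
concordance table with a Spearman rank correlation.

Coordinates are 0-based half-open throughout; chromosome names are stored
without the ``chr`` prefix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ValidationError

ARM_COLUMNS = ["chrom", "arm", "start", "end"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "copy_number"]


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix so 'chr5' and '5' compare equal."""
    s = str(name).strip()
    return s[3:] if s.lower().startswith("chr") else s


# ----------------------------------------------------------------------
# Types
# ----------------------------------------------------------------------
class GenomeArms:
    """Chromosome-arm coordinate table (one row per chrom+arm)."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ARM_COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"arms table missing columns: {missing}")
        t = table[ARM_COLUMNS].copy()
        t["chrom"] = t["chrom"].map(normalize_chrom)
        if (t["start"] >= t["end"]).any():
            bad = t[t["start"] >= t["end"]]
            raise ValidationError(f"zero/negative-length arms:\n{bad}")
        if t.duplicated(["chrom", "arm"]).any():
            dups = t[t.duplicated(["chrom", "arm"], keep=False)]
            raise ValidationError(f"duplicate (chrom, arm) records:\n{dups}")
        bad_arm = ~t["arm"].isin(["p", "q"])
        if bad_arm.any():
            raise ValidationError(f"arm must be 'p' or 'q':\n{t[bad_arm]}")
        for chrom, grp in t.groupby("chrom"):
            arms = dict(zip(grp["arm"], zip(grp["start"], grp["end"])))
            if "p" in arms and "q" in arms and arms["p"][1] > arms["q"][0]:
                raise ValidationError(
                    f"chromosome {chrom}: p arm end {arms['p'][1]} exceeds "
                    f"q arm start {arms['q'][0]}"
                )
        self.table = t.sort_values(["chrom", "arm"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def arm_names(self) -> list[str]:
        return [f"{c}{a}" for c, a in zip(self.table["chrom"], self.table["arm"])]

    def __repr__(self) -> str:
        return f"<GenomeArms {len(self)} arms on {self.table['chrom'].nunique()} chromosomes>"


@dataclass
class SegmentProfile:
    """Per-sample segmented total copy-number profile.

    ``segments`` columns: chrom, start, end, copy_number; non-overlapping
    within a chromosome, sorted by (chrom, start).
    """

    sample: str
    segments: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SEGMENT_COLUMNS))

    def __post_init__(self) -> None:
        t = self.segments[SEGMENT_COLUMNS].copy() if len(self.segments) else \
            pd.DataFrame(columns=SEGMENT_COLUMNS)
        if len(t):
            t["chrom"] = t["chrom"].map(normalize_chrom)
            if (t["end"] <= t["start"]).any():
                bad = t[t["end"] <= t["start"]]
                raise ValidationError(f"sample {self.sample}: segment end <= start:\n{bad}")
            if (t["copy_number"] < 0).any():
                raise ValidationError(f"sample {self.sample}: negative copy number")
            t = t.sort_values(["chrom", "start"]).reset_index(drop=True)
            for chrom, grp in t.groupby("chrom"):
                ends = grp["end"].to_numpy()
                starts = grp["start"].to_numpy()
                if (starts[1:] < ends[:-1]).any():
                    raise ValidationError(
                        f"sample {self.sample}: overlapping segments on chromosome {chrom}"
                    )
        self.segments = t


# ----------------------------------------------------------------------
# Arm-level event calling
# ----------------------------------------------------------------------
def arm_fraction_altered(
    profile: SegmentProfile,
    arms: GenomeArms,
    loss_cn_cutoff: float = 2.0,
    gain_cn_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Fraction of each arm covered by loss (< cutoff) and gain (> cutoff) segments.

    Uncovered arm territory counts as neutral: the denominator is always the
    full arm length, matching the ">50% of a chromosome arm" phrasing.
    """
    rows = []
    segs = profile.segments
    for rec in arms.table.itertuples(index=False):
        arm_len = rec.end - rec.start
        if arm_len <= 0:  # unreachable through GenomeArms, kept as a guard
            raise ValidationError(f"arm {rec.chrom}{rec.arm} has zero length")
        on_chrom = segs[segs["chrom"] == rec.chrom]
        loss_bp = gain_bp = 0
        for seg in on_chrom.itertuples(index=False):
            overlap = min(seg.end, rec.end) - max(seg.start, rec.start)
            if overlap <= 0:
                continue
            if seg.copy_number < loss_cn_cutoff:
                loss_bp += overlap
            elif seg.copy_number > gain_cn_cutoff:
                gain_bp += overlap
        rows.append(
            {
                "sample": profile.sample,
                "chrom": rec.chrom,
                "arm": rec.arm,
                "fraction_loss": loss_bp / arm_len,
                "fraction_gain": gain_bp / arm_len,
            }
        )
    return pd.DataFrame(rows)


def call_arm_events(fractions: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Apply the strict >threshold rule to per-arm altered fractions.

    A fraction of exactly *threshold* is neutral. If both loss and gain
    exceed the threshold (impossible at 0.5, possible below) the larger
    fraction wins.
    """
    t = fractions.copy()
    bad = t[(t["fraction_loss"] < 0) | (t["fraction_loss"] > 1)
            | (t["fraction_gain"] < 0) | (t["fraction_gain"] > 1)]
    if len(bad):
        raise ValidationError(f"fractions outside [0,1]:\n{bad}")

    def _call(row) -> str:
        loss = row["fraction_loss"] > threshold
        gain = row["fraction_gain"] > threshold
        if loss and gain:
            return "loss" if row["fraction_loss"] >= row["fraction_gain"] else "gain"
        if loss:
            return "loss"
        if gain:
            return "gain"
        return "neutral"

    t["call"] = t.apply(_call, axis=1)
    return t


def cohort_arm_loss_frequency(event_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-arm loss/gain frequency across a cohort of ArmEventTables."""
    if not event_tables:
        raise ValidationError("cohort is empty")
    allt = pd.concat(event_tables, ignore_index=True)
    out = (
        allt.groupby(["chrom", "arm"], sort=True)
        .agg(
            n_samples=("sample", "nunique"),
            n_loss=("call", lambda c: int((c == "loss").sum())),
            n_gain=("call", lambda c: int((c == "gain").sum())),
        )
        .reset_index()
    )
    out["loss_frequency"] = out["n_loss"] / out["n_samples"]
    out["gain_frequency"] = out["n_gain"] / out["n_samples"]
    return out


# ----------------------------------------------------------------------
# Synteny
# ----------------------------------------------------------------------
def syntenic_proportion(
    homology: pd.DataFrame,
    rat_gene_arm: pd.DataFrame,
    human_gene_chrom: pd.DataFrame,
    human_totals: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Proportion of each human chromosome's genes syntenic with each rat arm.

    Parameters
    ----------
    homology
        Restricted (one-to-one, high-confidence) homology records with
        columns ``rat_gene``/``human_gene``.
    rat_gene_arm
        Columns ``gene``, ``chrom``, ``arm`` for rat genes.
    human_gene_chrom
        Columns ``gene``, ``chrom`` for human genes.
    human_totals
        Total gene count per human chromosome; defaults to counting
        *human_gene_chrom*.

    Ortholog pairs whose rat or human member has no coordinate record are
    dropped; the count is reported in the ``attrs['n_dropped']`` of the
    result.
    """
    rat = rat_gene_arm.copy()
    rat["chrom"] = rat["chrom"].map(normalize_chrom)
    hum = human_gene_chrom.copy()
    hum["chrom"] = hum["chrom"].map(normalize_chrom)
    if human_totals is None:
        human_totals = hum.groupby("chrom")["gene"].nunique().to_dict()
    else:
        human_totals = {normalize_chrom(k): v for k, v in human_totals.items()}

    merged = homology.merge(
        rat.rename(columns={"gene": "rat_gene", "chrom": "rat_chrom", "arm": "rat_arm"}),
        on="rat_gene", how="left",
    ).merge(
        hum.rename(columns={"gene": "human_gene", "chrom": "human_chrom"}),
        on="human_gene", how="left",
    )
    covered = merged.dropna(subset=["rat_chrom", "rat_arm", "human_chrom"])
    n_dropped = len(merged) - len(covered)

    counts = (
        covered.groupby(["rat_chrom", "rat_arm", "human_chrom"])
        .size()
        .rename("syntenic_gene_count")
        .reset_index()
    )
    rows = []
    for rec in counts.itertuples(index=False):
        total = human_totals.get(rec.human_chrom, 0)
        if total <= 0:
            raise ValidationError(
                f"human chromosome {rec.human_chrom} has total gene count 0"
            )
        rows.append(
            {
                "rat_chrom": rec.rat_chrom,
                "rat_arm": rec.rat_arm,
                "human_chrom": rec.human_chrom,
                "syntenic_gene_count": int(rec.syntenic_gene_count),
                "human_chrom_gene_total": int(total),
                "proportion": rec.syntenic_gene_count / total,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["rat_chrom", "rat_arm", "human_chrom", "syntenic_gene_count",
                 "human_chrom_gene_total", "proportion"],
    )
    out.attrs["n_dropped"] = n_dropped
    return out


def concordance_table(
    synteny: pd.DataFrame,
    loss_frequency: pd.DataFrame,
    rat_loss_arms: set[str] | list[str],
) -> tuple[pd.DataFrame, float]:
    """Join syntenic proportions (restricted to rat arms lost in the model)
    to human cohort arm-loss frequencies; report the Spearman correlation.

    The human side of *loss_frequency* may be arm-level (``chrom`` + ``arm``
    columns) — each synteny row then joins to every arm of its human
    chromosome — or chromosome-level (``arm`` absent/empty).
    Returns ``(table, rho)``; ``rho`` is NaN (with a warning) when fewer
    than two joined rows exist.
    """
    arm_set = {normalize_chrom(a[:-1]) + a[-1] if a and a[-1] in "pq" else normalize_chrom(a)
               for a in rat_loss_arms}
    syn = synteny.copy()
    syn["rat_arm_name"] = syn["rat_chrom"].astype(str) + syn["rat_arm"].astype(str)
    syn = syn[syn["rat_arm_name"].isin(arm_set)]

    freq = loss_frequency.copy()
    freq["chrom"] = freq["chrom"].map(normalize_chrom)
    rows = []
    for rec in syn.itertuples(index=False):
        match = freq[freq["chrom"] == rec.human_chrom]
        for f in match.itertuples(index=False):
            human_arm = getattr(f, "arm", "") or ""
            rows.append(
                {
                    "rat_arm": rec.rat_arm_name,
                    "human_chrom": rec.human_chrom,
                    "human_arm": f"{rec.human_chrom}{human_arm}",
                    "proportion": rec.proportion,
                    "loss_frequency": f.loss_frequency,
                }
            )
    table = pd.DataFrame(
        rows, columns=["rat_arm", "human_chrom", "human_arm", "proportion", "loss_frequency"]
    )
    if table.empty:
        raise ValidationError("concordance join is empty")
    if len(table) < 2:
        warnings.warn("single-row concordance join; Spearman correlation undefined")
        return table, float("nan")
    rho = spearmanr(table["proportion"], table["loss_frequency"]).statistic
    return table, float(rho)
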