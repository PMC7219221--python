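"""Readers and writers for the pipeline's text formats.

Formats handled here: gene x sample expression TSV, UCSC cytoBand files and
SEG segmented copy-number tables. Homology tables live in
:mod:`pcpgx.orthologs`. Conventions:

* internal coordinates are 0-based half-open everywhere;
* SEG input coordinates are declared 1-based inclusive (UCSC browser
  convention for SEG text) and converted on read, re-converted on write;
* ``chr`` prefixes are stripped internally and re-added on write.

Every reader validates its type's invariants and raises instead of coercing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import GenomeArms, SegmentProfile, normalize_chrom
from .errors import ParseError, ValidationError
from .matrix import ExpressionMatrix


# ----------------------------------------------------------------------
# Expression TSV
# ----------------------------------------------------------------------
def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV (header = sample ids, first column = gene ids).

    Returns a matrix in ``raw`` state with file order preserved.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample ids in header: {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read expression TSV {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        mask = numeric.isna()
        gi, si = np.argwhere(mask.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}: {df.iloc[gi, si]!r}"
        )
    return ExpressionMatrix(numeric, state="raw")


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ----------------------------------------------------------------------
# UCSC cytoBand
# ----------------------------------------------------------------------
def read_cytoband(path: str | Path) -> GenomeArms:
    """Aggregate a 5-column UCSC cytoBand file into chromosome arms.

    The arm is the leading letter (p/q) of the band name; per arm, start is
    the minimum band start and end the maximum band end. Band names lacking
    a p/q prefix, and overlapping bands within an arm, are rejected.
    """
    bands = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str, "stain": str},
    )
    if bands.empty:
        raise ValidationError(f"{path}: cytoBand file has no bands")
    bands["chrom"] = bands["chrom"].map(normalize_chrom)
    arm_letter = bands["band"].astype(str).str[:1]
    bad = ~arm_letter.isin(["p", "q"])
    if bad.any():
        offending = bands[bad].index.tolist()
        raise ValidationError(
            f"{path}: band name lacks p/q prefix at rows {offending}"
        )
    bands["arm"] = arm_letter
    # overlap check within each (chrom, arm)
    for (chrom, arm), grp in bands.groupby(["chrom", "arm"]):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValidationError(
                f"{path}: overlapping bands within arm {chrom}{arm}"
            )
    arms = (
        bands.groupby(["chrom", "arm"], sort=True)
        .agg(start=("start", "min"), end=("end", "max"))
        .reset_index()
    )
    return GenomeArms(arms)


def write_cytoband(arms: GenomeArms, path: str | Path, bands_per_arm: int = 2) -> None:
    """Write arms back out as a synthetic cytoBand file (equal-width bands)."""
    rows = []
    for rec in arms.table.itertuples(index=False):
        edges = np.linspace(rec.start, rec.end, bands_per_arm + 1).astype(int)
        for i in range(bands_per_arm):
            rows.append(
                (f"chr{rec.chrom}", edges[i], edges[i + 1], f"{rec.arm}1{i + 1}", "gneg")
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
# SEG
# ----------------------------------------------------------------------
def read_seg(path: str | Path) -> list[SegmentProfile]:
    """Read a SEG-format TSV into one :class:`SegmentProfile` per sample.

    Expected columns (with header): sample, chrom, start, end, optional
    marker count, segment value (total copy number). Input coordinates are
    1-based inclusive and converted to 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] not in (5, 6):
        raise ParseError(
            f"{path}: SEG file must have 5 or 6 columns, found {df.shape[1]}"
        )
    cols = ["sample", "chrom", "start", "end"] + (
        ["num_mark", "copy_number"] if df.shape[1] == 6 else ["copy_number"]
    )
    df.columns = cols
    if df.empty:
        return []
    for col in ("start", "end", "copy_number"):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = int(converted.index[converted.isna()][0])
            raise ParseError(f"{path}: non-numeric {col!r} at data row {row}")
        df[col] = converted
    if (df["end"] < df["start"]).any():
        bad = df[df["end"] < df["start"]].index.tolist()
        raise ValidationError(f"{path}: end < start at data rows {bad}")
    # 1-based inclusive -> 0-based half-open
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        segs = grp[["chrom", "start", "end", "copy_number"]].reset_index(drop=True)
        profiles.append(SegmentProfile(sample=str(sample), segments=segs))
    return profiles


def write_seg(profiles: list[SegmentProfile], path: str | Path) -> None:
    """Write profiles as SEG text (coordinates back to 1-based inclusive)."""
    rows = []
    for p in profiles:
        for seg in p.segments.itertuples(index=False):
            rows.append(
                (p.sample, f"chr{seg.chrom}", seg.start + 1, seg.end, ".",
                 seg.copy_number)
            )
    out = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "num_mark", "seg_value"]
    )
    out.to_csv(path, sep="\t", index=False)
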