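"""Rat-human homology tables and expression-matrix translation.

A biomart-style homology table pairs rat and human gene ids with a homology
type (one2one / one2many / many2many) and an orthology-confidence flag.
Cross-species clustering uses only high-confidence one-to-one pairs, with an
extra uniqueness sweep so no rat or human gene survives in more than one
record; a rat expression matrix is then translated to human ids by exact
row lookup (values are never aggregated or invented).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParseError, ValidationError
from .matrix import ExpressionMatrix

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many")
REQUIRED_COLUMNS = ("rat_gene_id", "human_gene_id", "homology_type", "confidence")

_TYPE_ALIASES = {
    "one2one": "one2one",
    "ortholog_one2one": "one2one",
    "one2many": "one2many",
    "ortholog_one2many": "one2many",
    "many2many": "many2many",
    "ortholog_many2many": "many2many",
}
_CONF_ALIASES = {"1": "high", "0": "low", "high": "high", "low": "low"}


class HomologyTable:
    """Validated rat-human gene homology records."""

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in ("rat_gene", "human_gene", "homology_type", "confidence")
                   if c not in records.columns]
        if missing:
            raise ValidationError(f"homology table missing columns: {missing}")
        t = records[["rat_gene", "human_gene", "homology_type", "confidence"]].copy()
        for col in ("rat_gene", "human_gene"):
            t[col] = t[col].astype(str)
            if (t[col].str.len() == 0).any() or t[col].isin(["nan"]).any():
                raise ValidationError(f"empty identifier in column {col!r}")
        bad_type = ~t["homology_type"].isin(HOMOLOGY_TYPES)
        if bad_type.any():
            raise ValidationError(
                f"unknown homology_type values: {t.loc[bad_type, 'homology_type'].unique().tolist()}"
            )
        bad_conf = ~t["confidence"].isin(["high", "low"])
        if bad_conf.any():
            raise ValidationError(
                f"confidence must be high/low, got: {t.loc[bad_conf, 'confidence'].unique().tolist()}"
            )
        if t.duplicated(["rat_gene", "human_gene"]).any():
            dups = t[t.duplicated(["rat_gene", "human_gene"], keep=False)]
            raise ValidationError(f"duplicate (rat_gene, human_gene) pairs:\n{dups.head()}")
        self.records = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:
        return f"<HomologyTable {len(self)} records>"


def load_homology_table(path: str | Path) -> HomologyTable:
    """Parse a homology TSV with columns rat_gene_id, human_gene_id,
    homology_type, confidence (0/1 or low/high)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    out = pd.DataFrame(
        {
            "rat_gene": df["rat_gene_id"],
            "human_gene": df["human_gene_id"],
            "homology_type": df["homology_type"].str.strip().str.lower().map(_TYPE_ALIASES),
            "confidence": df["confidence"].str.strip().str.lower().map(_CONF_ALIASES),
        }
    )
    if out["homology_type"].isna().any():
        bad = df.loc[out["homology_type"].isna(), "homology_type"].unique().tolist()
        raise ParseError(f"{path}: unrecognized homology_type values {bad}")
    if out["confidence"].isna().any():
        bad = df.loc[out["confidence"].isna(), "confidence"].unique().tolist()
        raise ParseError(f"{path}: unrecognized confidence values {bad}")
    return HomologyTable(out)


def write_homology_table(table: HomologyTable, path: str | Path) -> None:
    out = table.records.rename(
        columns={"rat_gene": "rat_gene_id", "human_gene": "human_gene_id"}
    )
    out.to_csv(path, sep="\t", index=False)


def restrict_high_confidence_one_to_one(table: HomologyTable) -> HomologyTable:
    """Keep high-confidence one2one records whose genes are globally unique.

    After filtering to ``one2one`` + ``high``, any rat or human gene still
    appearing in more than one surviving record is dropped entirely (one
    sweep suffices: dropping records only lowers multiplicities, so the
    operation is idempotent).
    """
    t = table.records
    kept = t[(t["homology_type"] == "one2one") & (t["confidence"] == "high")]
    rat_counts = kept["rat_gene"].value_counts()
    hum_counts = kept["human_gene"].value_counts()
    unique = kept[
        kept["rat_gene"].map(rat_counts).eq(1) & kept["human_gene"].map(hum_counts).eq(1)
    ]
    return HomologyTable(unique.reset_index(drop=True))


@dataclass
class MappingReport:
    """Gene counts by fate during rat-to-human id translation."""

    n_rat_genes: int
    n_mapped: int
    n_unmapped: int
    n_outside_target: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["input", "mapped", "no_one2one_ortholog", "outside_target_panel"],
                "count": [self.n_rat_genes, self.n_mapped, self.n_unmapped,
                          self.n_outside_target],
            }
        )


def translate_to_human_ids(
    rat_expr: ExpressionMatrix,
    table: HomologyTable,
    target_genes: list[str] | None = None,
) -> tuple[ExpressionMatrix, MappingReport]:
    """Re-index a rat expression matrix by human ortholog ids.

    *table* must already be restricted to unique one-to-one pairs. Each
    output row is the rat ortholog's row, unchanged; unmapped rat genes are
    dropped. With *target_genes* the output is further restricted to that
    panel (order follows the rat matrix).
    """
    t = table.records
    if t["rat_gene"].duplicated().any() or t["human_gene"].duplicated().any():
        raise ValidationError(
            "homology table is not one-to-one; call restrict_high_confidence_one_to_one first"
        )
    rat_to_human = dict(zip(t["rat_gene"], t["human_gene"]))
    mapped = [(g, rat_to_human[g]) for g in rat_expr.gene_ids if g in rat_to_human]
    n_unmapped = rat_expr.n_genes - len(mapped)
    n_outside = 0
    if target_genes is not None:
        target = set(target_genes)
        before = len(mapped)
        mapped = [(r, h) for r, h in mapped if h in target]
        n_outside = before - len(mapped)
    if not mapped:
        raise ValidationError("no mappable genes between the matrix and the target panel")
    rat_ids = [r for r, _ in mapped]
    out = rat_expr.data.loc[rat_ids].copy()
    out.index = [h for _, h in mapped]
    report = MappingReport(
        n_rat_genes=rat_expr.n_genes,
        n_mapped=len(mapped),
        n_unmapped=n_unmapped,
        n_outside_target=n_outside,
    )
    return ExpressionMatrix(out, state=rat_expr.state), report
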