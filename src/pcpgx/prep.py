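"""Expression normalization and variable-gene selection.

The normalization mirrors the TCGA PCPG convention reused for the rat data:
per-sample upper-quartile scaling (RSEM-style), log2(x+1), then per-gene
median centering across samples. Gene selection ranks genes by scaled median
absolute deviation and keeps the top N (default 3000) for clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import ExpressionMatrix

MAD_SCALE = 1.4826  # conventional consistency constant; ranking-neutral


def normalize_expression(raw: ExpressionMatrix, uq_target: float = 1000.0) -> ExpressionMatrix:
    """Upper-quartile scale, log2(x+1) transform and median-center.

    Per sample, values are scaled so the upper quartile of its *positive*
    values equals *uq_target*; then ``log2(x+1)`` is applied elementwise;
    then each gene's median across samples is subtracted. The result is
    invariant to pre-multiplying any sample by a positive constant.
    """
    if raw.state != "raw":
        raise ValidationError(f"expected a raw matrix, got state {raw.state!r}")
    if uq_target <= 0:
        raise ValidationError("uq_target must be positive")
    values = raw.values.copy()
    for j, sample in enumerate(raw.sample_ids):
        col = values[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            raise ValidationError(
                f"sample {sample!r} has no positive values; upper quartile undefined"
            )
        uq = np.percentile(positive, 75)
        values[:, j] = col * (uq_target / uq)
    logged = np.log2(values + 1.0)
    centered = logged - np.median(logged, axis=1, keepdims=True)
    df = pd.DataFrame(centered, index=raw.gene_ids, columns=raw.sample_ids)
    return ExpressionMatrix(df, state="normalized")


def drop_all_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with zero quantification in every sample (raw state)."""
    if m.state != "raw":
        raise ValidationError("drop_all_zero_genes applies to raw matrices")
    keep = (m.values != 0).any(axis=1)
    return ExpressionMatrix(m.data.loc[keep], state="raw")


def gene_mad(m: ExpressionMatrix) -> pd.Series:
    """Scaled median absolute deviation per gene across samples."""
    v = m.values
    med = np.median(v, axis=1, keepdims=True)
    return pd.Series(
        np.median(np.abs(v - med), axis=1) * MAD_SCALE, index=m.gene_ids, name="mad"
    )


def select_top_mad_genes(m: ExpressionMatrix, n: int) -> list[str]:
    """Ids of the *n* most-variable genes by scaled MAD.

    Descending MAD; ties broken by gene id ascending; returns
    ``min(n, n_genes)`` ids. Requires >= 2 samples (MAD of one sample is
    identically zero and would make the ranking meaningless).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if m.n_samples < 2:
        raise ValidationError("MAD ranking needs at least 2 samples")
    mad = gene_mad(m)
    order = sorted(mad.index, key=lambda g: (-mad[g], g))
    return order[: min(n, len(order))]
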