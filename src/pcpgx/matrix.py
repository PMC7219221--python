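"""Gene-by-sample expression matrix container.

A thin, validated wrapper around a pandas DataFrame (rows = genes,
columns = samples) carrying a processing-state flag:

``raw``
    Non-negative quantification values (RSEM/RPKM scale).
``normalized``
    Upper-quartile scaled, log2(x+1) transformed and per-gene
    median-centered — so every gene's median across samples is 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

_STATES = ("raw", "normalized")
_MEDIAN_TOL = 1e-9


class ExpressionMatrix:
    """Validated gene x sample numeric matrix with a processing state."""

    def __init__(self, data: pd.DataFrame, state: str = "raw"):
        if state not in _STATES:
            raise ValidationError(f"state must be one of {_STATES}, got {state!r}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = data.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        if state == "raw" and values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"raw matrix has negative value at gene {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        if state == "normalized" and values.shape[1] >= 1 and values.size:
            med = np.median(values, axis=1)
            if np.abs(med).max() > _MEDIAN_TOL:
                worst = int(np.abs(med).argmax())
                raise ValidationError(
                    "normalized matrix must be per-gene median-centered; gene "
                    f"{data.index[worst]!r} has median {med[worst]:.3g}"
                )
        self._data = data.astype(float)
        self.state = state

    # ------------------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self._data.shape[0]

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    # ------------------------------------------------------------------
    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Row-subset (order taken from *gene_ids*); state is preserved.

        Note median-centering survives row subsetting, so a normalized
        matrix stays valid.
        """
        missing = [g for g in gene_ids if g not in self._data.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self._data.loc[list(gene_ids)], state=self.state)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:10]}")
        # column subsetting can break per-gene medians, so re-validation
        # happens naturally in the constructor for normalized matrices
        sub = self._data[list(sample_ids)]
        if self.state == "normalized":
            return ExpressionMatrix(sub.sub(sub.median(axis=1), axis=0), state="normalized")
        return ExpressionMatrix(sub, state=self.state)

    def rename_genes(self, mapping: dict) -> "ExpressionMatrix":
        return ExpressionMatrix(self._data.rename(index=mapping), state=self.state)

    def hstack(self, other: "ExpressionMatrix") -> "ExpressionMatrix":
        """Concatenate samples of two raw matrices sharing one gene panel."""
        if self.state != "raw" or other.state != "raw":
            raise ValidationError("hstack is defined for raw matrices only")
        if list(self._data.index) != list(other._data.index):
            raise ValidationError("gene panels differ; align genes before hstack")
        return ExpressionMatrix(pd.concat([self._data, other._data], axis=1), state="raw")

    def __repr__(self) -> str:
        return (
            f"<ExpressionMatrix {self.n_genes} genes x {self.n_samples} samples, "
            f"state={self.state!r}>"
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.state == other.state
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, atol=0, rtol=0)
        )
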