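"""Consensus clustering by repeated subsampling, from first principles.

For each of ``n_resamples`` iterations a fraction of samples is drawn
without replacement and partitioned into ``k`` groups by agglomerative
clustering (1 - Pearson correlation distance, average linkage, by default).
The consensus matrix records, for each sample pair, the fraction of draws in
which both were sampled *and* co-clustered; a clean subtype structure shows
up as near-0/1 blocks. Final labels come from cutting an agglomerative tree
built on ``1 - consensus``. Model selection across candidate ``k`` uses the
area under the empirical CDF of off-diagonal consensus values: the chosen
``k`` is the largest one whose relative area gain over ``k - 1`` still
exceeds a threshold.

The model/results split follows the statsmodels idiom::

    model = ConsensusClustering(normalized_matrix, seed=7)
    res = model.fit(k=4)            # ConsensusResults
    scan = model.fit_range((2, 6))  # KSelectionResults, scan.k_selected

Functional wrappers :func:`run_consensus`, :func:`assign_clusters` and
:func:`select_k` expose the same steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .matrix import ExpressionMatrix

DELTA_AREA_THRESHOLD = 0.05


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------
def sample_distance_matrix(
    values: np.ndarray, sample_ids: list[str], metric: str
) -> np.ndarray:
    """Pairwise sample distances from a genes x samples value block.

    ``pearson``: 1 - Pearson correlation between sample columns (a
    zero-variance sample makes the correlation undefined and is reported by
    name). ``euclidean``: plain Euclidean distance between columns.
    """
    if metric == "pearson":
        sd = values.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = [sample_ids[i] for i in dead[:5]]
            raise ValidationError(
                f"zero-variance sample(s) under correlation distance: {names}"
            )
        d = 1.0 - np.corrcoef(values, rowvar=False)
    elif metric == "euclidean":
        sq = (values[:, :, None] - values[:, None, :]) ** 2
        d = np.sqrt(sq.sum(axis=0))
    else:
        raise ValidationError(f"unknown distance metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _cut_tree(dist: np.ndarray, k: int, method: str) -> np.ndarray:
    """Agglomerate a square distance matrix and cut at k clusters (1..k)."""
    n = dist.shape[0]
    if k == 1:
        return np.ones(n, dtype=int)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    return fcluster(Z, t=k, criterion="maxclust")


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------
@dataclass
class ConsensusResults:
    """Fitted consensus-clustering solution for one value of ``k``.

    Attributes
    ----------
    k : int
    consensus : pandas.DataFrame
        Symmetric sample x sample co-clustering proportions, unit diagonal.
    co_sampled : pandas.DataFrame
        How often each pair was drawn together.
    labels : pandas.Series
        Final per-sample assignment in ``1..k``.
    cdf_area : float
        Area under the empirical CDF of off-diagonal consensus entries
        (computed exactly as ``1 - mean(off-diagonal values)``).
    params : dict
        Resampling settings and seed used.
    """

    k: int
    consensus: pd.DataFrame
    co_sampled: pd.DataFrame
    labels: pd.Series
    cdf_area: float
    params: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.consensus.index)

    def cluster_members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def mean_consensus(self, sample: str, members: list[str]) -> float:
        """Mean consensus between one sample and a set of other samples."""
        others = [m for m in members if m != sample]
        if not others:
            return float("nan")
        return float(self.consensus.loc[sample, others].mean())

    def ordered_consensus(self) -> pd.DataFrame:
        """Consensus matrix with samples grouped by cluster (heatmap-ready)."""
        order = sorted(self.sample_ids, key=lambda s: (self.labels[s], s))
        return self.consensus.loc[order, order]

    def summary(self) -> str:
        lines = [
            f"Consensus clustering, k={self.k}",
            f"  samples:          {len(self.sample_ids)}",
            f"  resamples:        {self.params.get('n_resamples')}",
            f"  subsample_frac:   {self.params.get('subsample_frac')}",
            f"  distance/linkage: {self.params.get('distance_metric')}/"
            f"{self.params.get('linkage_method')}",
            f"  seed:             {self.params.get('seed')}",
            f"  CDF area:         {self.cdf_area:.4f}",
            "  cluster sizes:    "
            + ", ".join(
                f"{c}:{(self.labels == c).sum()}" for c in range(1, self.k + 1)
            ),
        ]
        return "\n".join(lines)


@dataclass
class KSelectionResults:
    """Per-k consensus scan with the CDF Δ-area model-selection table."""

    results: dict[int, ConsensusResults]
    delta_area: pd.DataFrame  # columns: k, cdf_area, relative_increase
    k_selected: int

    def summary(self) -> str:
        lines = ["Consensus k scan (CDF delta-area criterion)"]
        for rec in self.delta_area.itertuples(index=False):
            marker = "  <- selected" if rec.k == self.k_selected else ""
            lines.append(
                f"  k={rec.k}: area={rec.cdf_area:.4f} "
                f"rel_increase={rec.relative_increase:.4f}{marker}"
            )
        return "\n".join(lines)


# ----------------------------------------------------------------------
# model
# ----------------------------------------------------------------------
class ConsensusClustering:
    """Consensus clustering model over a normalized expression matrix.

    Parameters
    ----------
    data
        Normalized gene x sample :class:`~pcpgx.matrix.ExpressionMatrix`.
    n_resamples, subsample_frac
        Resampling settings; each iteration draws
        ``ceil(subsample_frac * n)`` samples without replacement.
    distance_metric, linkage_method
        Inner agglomerative clustering settings.
    seed
        Seed of the single NumPy generator consumed in iteration order;
        fixing it makes the fit bit-reproducible.
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        n_resamples: int = 1000,
        subsample_frac: float = 0.8,
        distance_metric: str = "pearson",
        linkage_method: str = "average",
        seed: int = 0,
    ):
        if data.state != "normalized":
            raise ValidationError("consensus clustering expects a normalized matrix")
        if not (0 < subsample_frac <= 1):
            raise ValidationError("subsample_frac must lie in (0, 1]")
        self.data = data
        self.n_resamples = int(n_resamples)
        self.subsample_frac = float(subsample_frac)
        self.distance_metric = distance_metric
        self.linkage_method = linkage_method
        self.seed = int(seed)

    # ------------------------------------------------------------------
    def fit(self, k: int) -> ConsensusResults:
        """Run the resampling loop for one candidate cluster number."""
        n = self.data.n_samples
        samples = self.data.sample_ids
        if k < 2:
            raise ValidationError("k must be >= 2 (use assign_clusters for k=1)")
        if k > n:
            raise ValidationError(f"k={k} exceeds the number of samples ({n})")
        n_sub = int(np.ceil(self.subsample_frac * n))
        if n_sub < k:
            raise ValidationError(
                f"subsample of {n_sub} samples cannot hold k={k} clusters"
            )
        values = self.data.values
        rng = np.random.default_rng(self.seed)
        co_clustered = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(self.n_resamples):
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            sub_ids = [samples[i] for i in idx]
            dist = sample_distance_matrix(values[:, idx], sub_ids, self.distance_metric)
            labels = _cut_tree(dist, k, self.linkage_method)
            co_sampled[np.ix_(idx, idx)] += 1
            for c in range(1, k + 1):
                members = idx[labels == c]
                co_clustered[np.ix_(members, members)] += 1
        never = (co_sampled == 0) & ~np.eye(n, dtype=bool)
        if never.any():
            warnings.warn(
                f"{int(never.sum() // 2)} sample pair(s) were never co-sampled; "
                "their consensus is reported as 0"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sampled > 0, co_clustered / np.maximum(co_sampled, 1), 0.0)
        consensus = (consensus + consensus.T) / 2.0
        np.fill_diagonal(consensus, 1.0)

        labels = _cut_tree(1.0 - consensus, k, "average")
        off = consensus[~np.eye(n, dtype=bool)]
        # area under the empirical CDF on [0,1] equals 1 - mean(values)
        cdf_area = float(1.0 - off.mean()) if off.size else 1.0
        cons_df = pd.DataFrame(consensus, index=samples, columns=samples)
        cos_df = pd.DataFrame(co_sampled, index=samples, columns=samples)
        return ConsensusResults(
            k=k,
            consensus=cons_df,
            co_sampled=cos_df,
            labels=pd.Series(labels, index=samples, name="cluster"),
            cdf_area=cdf_area,
            params={
                "n_resamples": self.n_resamples,
                "subsample_frac": self.subsample_frac,
                "distance_metric": self.distance_metric,
                "linkage_method": self.linkage_method,
                "seed": self.seed,
            },
        )

    def fit_range(
        self, k_range: tuple[int, int], threshold: float = DELTA_AREA_THRESHOLD
    ) -> KSelectionResults:
        """Fit every k in the inclusive range and select one by Δ-area."""
        lo, hi = k_range
        results = {k: self.fit(k) for k in range(lo, hi + 1)}
        k_sel, table = select_k(list(results.values()), threshold=threshold)
        return KSelectionResults(results=results, delta_area=table, k_selected=k_sel)


# ----------------------------------------------------------------------
# functional surface
# ----------------------------------------------------------------------
def run_consensus(
    m: ExpressionMatrix,
    k: int,
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    distance_metric: str = "pearson",
    linkage_method: str = "average",
    seed: int = 0,
) -> ConsensusResults:
    """One consensus run (see :class:`ConsensusClustering`)."""
    return ConsensusClustering(
        m,
        n_resamples=n_resamples,
        subsample_frac=subsample_frac,
        distance_metric=distance_metric,
        linkage_method=linkage_method,
        seed=seed,
    ).fit(k)


def assign_clusters(result: ConsensusResults, k: int) -> pd.Series:
    """Cut the consensus-matrix tree at *k* (average linkage on 1-consensus).

    Deterministic for a fixed matrix; ``k=1`` is explicitly supported.
    """
    n = len(result.sample_ids)
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of samples ({n})")
    if k < 1:
        raise ValidationError("k must be >= 1")
    labels = _cut_tree(1.0 - result.consensus.to_numpy(), k, "average")
    return pd.Series(labels, index=result.sample_ids, name="cluster")


def select_k(
    results: list[ConsensusResults], threshold: float = DELTA_AREA_THRESHOLD
) -> tuple[int, pd.DataFrame]:
    """Choose k from consecutive consensus runs by relative CDF-area gain.

    The first k's "relative increase" is its own area; later ks use
    ``(area_k - area_{k-1}) / area_{k-1}``. The chosen k is the largest one
    whose relative increase exceeds *threshold*, falling back to the k with
    the largest increase.
    """
    if len(results) < 2:
        raise ValidationError("select_k needs results for at least two k values")
    ks = [r.k for r in results]
    if ks != sorted(ks) or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValidationError("results must cover consecutive increasing k values")
    areas = [r.cdf_area for r in results]
    rel = [areas[0]]
    for prev, cur in zip(areas, areas[1:]):
        rel.append((cur - prev) / prev if prev > 0 else float("inf"))
    table = pd.DataFrame({"k": ks, "cdf_area": areas, "relative_increase": rel})
    passing = [k for k, r in zip(ks, rel) if r > threshold]
    chosen = max(passing) if passing else ks[int(np.argmax(rel))]
    return chosen, table
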