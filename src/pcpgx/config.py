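"""Pipeline run configuration.

All analysis constants live here: the 3000-gene MAD panel size, the candidate
cluster-number range, consensus resampling settings, the strict >50%-of-arm
copy-number event rule, the diploid loss/gain cutoffs, the upper-quartile
normalization target and the coding-genome size used for mutation burden.
Every value can be overridden from a flat YAML mapping; unknown keys are
rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

_DISTANCE_METRICS = ("pearson", "euclidean")
_LINKAGE_METHODS = ("average", "complete", "ward")


@dataclass(frozen=True)
class PipelineConfig:
    """Constants and tunables for a full pipeline run.

    Parameters
    ----------
    mad_top_n
        Number of most-variable genes (by scaled MAD) kept for clustering.
    k_range
        Inclusive ``(lo, hi)`` range of candidate cluster numbers.
    n_resamples
        Subsampling iterations per consensus run.
    subsample_frac
        Fraction of samples drawn (without replacement) per iteration.
    distance_metric, linkage_method
        Inner agglomerative clustering settings.
    arm_loss_threshold
        Fraction of a chromosome arm that must be *strictly* exceeded by
        altered bases before an arm-level event is called.
    loss_cn_cutoff, gain_cn_cutoff
        Total copy number below/above which a segment counts as loss/gain
        (diploid baseline of 2).
    uq_target
        Upper-quartile scaling target for per-sample normalization.
    coding_genome_mb
        Coding-region size in megabases for mutation-burden (rat rn6: 37.48).
    rng_seed
        Seed for every stochastic stage.
    """

    mad_top_n: int = 3000
    k_range: tuple[int, int] = (2, 10)
    n_resamples: int = 1000
    subsample_frac: float = 0.8
    distance_metric: str = "pearson"
    linkage_method: str = "average"
    arm_loss_threshold: float = 0.5
    loss_cn_cutoff: float = 2.0
    gain_cn_cutoff: float = 2.0
    uq_target: float = 1000.0
    coding_genome_mb: float = 37.48
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mad_top_n < 1:
            raise ValidationError("mad_top_n must be >= 1")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValidationError("k_range must satisfy 2 <= lo <= hi")
        if not (0.0 < self.subsample_frac <= 1.0):
            raise ValidationError("subsample_frac must lie in (0, 1]")
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be >= 1")
        if self.distance_metric not in _DISTANCE_METRICS:
            raise ValidationError(
                f"distance_metric must be one of {_DISTANCE_METRICS}, "
                f"got {self.distance_metric!r}"
            )
        if self.linkage_method not in _LINKAGE_METHODS:
            raise ValidationError(
                f"linkage_method must be one of {_LINKAGE_METHODS}, "
                f"got {self.linkage_method!r}"
            )
        if not (0.0 <= self.arm_loss_threshold <= 1.0):
            raise ValidationError("arm_loss_threshold must lie in [0, 1]")
        if self.uq_target <= 0:
            raise ValidationError("uq_target must be positive")
        if self.coding_genome_mb <= 0:
            raise ValidationError("coding_genome_mb must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a flat YAML key-value file.

        Unknown keys raise :class:`ValidationError`; ``k_range`` may be given
        as a two-element list.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} is not a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {', '.join(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
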