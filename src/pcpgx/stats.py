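"""Exactly-reproducible cohort statistics.

Small statistics computed from printed study tables: the two-sided Fisher
exact test (explicit hypergeometric enumeration), somatic mutation burden
per coding megabase, marker fold-ratio tables, metabolite abundance ranking
and the 2-of-3 ensemble variant-caller voting rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError

# relative tolerance when comparing table probabilities, as in R's fisher.test
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError("contingency cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValidationError("contingency table must have at least one positive cell")


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    With margins fixed, every admissible table's probability is computed and
    those no more likely than the observed table (up to a 1e-7 relative
    tolerance) are summed — the standard "sum of <=-likely tables"
    convention. Degenerate margins (an empty row or column) give p = 1 with
    a warning.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate margins; association is undefined and p = 1")
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + _REL_TOL)].sum()))
    # summing the full support accumulates ulp-level error; snap to 1
    return 1.0 if 1.0 - p < 1e-9 else p


def mutation_burden(n_mutations: int, coding_mb: float) -> float:
    """Somatic mutations per megabase of coding genome."""
    if n_mutations < 0:
        raise ValidationError("mutation count must be non-negative")
    if coding_mb <= 0:
        raise ValidationError("coding_mb must be positive")
    return n_mutations / coding_mb


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def fold_ratio_table(
    case: dict[str, float], ref: dict[str, float], genes: list[str]
) -> pd.DataFrame:
    """Per-gene case/reference expression ratios, rounded to 2 decimals.

    A reference value of 0 makes the ratio undefined (flagged, never
    infinity); a case value of 0 gives ratio 0. Raw unrounded ratios are
    kept in ``ratio_raw``.
    """
    missing = [g for g in genes if g not in case or g not in ref]
    if missing:
        raise ValidationError(f"genes absent from case or reference values: {missing}")
    rows = []
    for g in genes:
        cv, rv = case[g], ref[g]
        if cv < 0 or rv < 0:
            raise ValidationError(f"negative expression value for gene {g!r}")
        if rv == 0:
            raw, rounded, undefined = float("nan"), float("nan"), True
        else:
            raw = cv / rv
            rounded, undefined = _round2(raw), False
        rows.append(
            {"gene": g, "case": cv, "ref": rv, "ratio": rounded,
             "ratio_raw": raw, "undefined": undefined}
        )
    return pd.DataFrame(rows)


def rank_metabolites(profile: list[tuple[str, float]]) -> pd.DataFrame:
    """Rank metabolites by abundance, descending.

    Ties share the smaller rank and are listed alphabetically within the
    tie. Returns columns rank, metabolite, abundance.
    """
    if not profile:
        raise ValidationError("metabolite profile is empty")
    names = [n for n, _ in profile]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate metabolite names")
    if any(v < 0 for _, v in profile):
        raise ValidationError("abundances must be non-negative")
    ordered = sorted(profile, key=lambda r: (-r[1], r[0]))
    ranks, prev_val, prev_rank = [], None, 0
    for i, (_, val) in enumerate(ordered, start=1):
        rank = prev_rank if val == prev_val else i
        ranks.append(rank)
        prev_val, prev_rank = val, rank
    return pd.DataFrame(
        {"rank": ranks, "metabolite": [n for n, _ in ordered],
         "abundance": [v for _, v in ordered]}
    )


def metabolite_rank(ranking: pd.DataFrame, name: str) -> int:
    """Rank of one metabolite in a :func:`rank_metabolites` table."""
    hit = ranking[ranking["metabolite"] == name]
    if hit.empty:
        raise ValidationError(f"unknown metabolite {name!r}")
    return int(hit["rank"].iloc[0])


@dataclass(frozen=True)
class VariantCallSet:
    """One caller's variant keys (chrom, pos, ref, alt)."""

    caller: str
    variants: frozenset

    @classmethod
    def from_keys(cls, caller: str, keys) -> "VariantCallSet":
        return cls(caller=caller, variants=frozenset(keys))

    @classmethod
    def from_lines(cls, caller: str, lines) -> "VariantCallSet":
        """Parse one-variant-per-line 'chrom:pos:ref:alt' text."""
        keys = []
        for line in lines:
            line = line.strip()
            if not line:
                continue
            parts = line.split(":")
            if len(parts) != 4:
                raise ValidationError(f"malformed variant key {line!r}")
            keys.append((parts[0], int(parts[1]), parts[2], parts[3]))
        return cls.from_keys(caller, keys)


def ensemble_variant_vote(callsets: list[VariantCallSet], min_callers: int = 2) -> frozenset:
    """Variants detected by at least *min_callers* of the given call sets."""
    if min_callers < 1:
        raise ValidationError("min_callers must be >= 1")
    if min_callers > len(callsets):
        raise ValidationError(
            f"min_callers={min_callers} exceeds the number of call sets ({len(callsets)})"
        )
    counts: dict = {}
    for cs in callsets:
        for v in cs.variants:
            counts[v] = counts.get(v, 0) + 1
    return frozenset(v for v, n in counts.items() if n >= min_callers)
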