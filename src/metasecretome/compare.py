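"""Frequency tables, fold enrichment and proportion tests between datasets.

Used to contrast the selected (metasecretome) dataset against an unselected
metagenome: per-label frequencies, fold ratios, a two-proportion z-test with
an exact fallback for sparse tables, and a Pfam -> COG functional-category
rollup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .model import ModelParams, round_half_up

#: COG functional category letters (one-letter codes A..Z minus unused)
COG_CATEGORIES = list("JAKLBDYVTMNZWUOCGEFHIPQRS")
UNKNOWN_CATEGORY = "S"  # function unknown: catch-all for unmapped Pfams


def frequency(count: int, total: int, decimals: int = 1) -> float:
    """Percentage ``100*count/total`` rounded half-up to ``decimals``."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("need 0 <= count <= total")
    return round_half_up(100.0 * count / total, decimals)


def fold_enrichment(count_a: int, total_a: int,
                    count_b: int, total_b: int) -> float:
    """Frequency ratio (a over b); ``inf`` when b's count is zero."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if count_b == 0:
        return math.inf
    return (count_a / total_a) / (count_b / total_b)


@dataclass(frozen=True)
class ProportionTest:
    p_value: float
    significant: bool
    method: str  # "z" | "exact"
    statistic: float | None = None


def compare_proportions(count_a: int, total_a: int, count_b: int,
                        total_b: int, alpha: float = 0.001) -> ProportionTest:
    """Two-sided comparison of two binomial proportions.

    Uses the pooled-variance two-proportion z-test; falls back to Fisher's
    exact (conditional) test whenever any expected cell count under the
    pooled proportion is below 5.  The significance flag is ``p <= alpha``.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must lie within their totals")
    pooled = (count_a + count_b) / (total_a + total_b)
    expected = [total_a * pooled, total_a * (1 - pooled),
                total_b * pooled, total_b * (1 - pooled)]
    if min(expected) < 5:
        table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        return ProportionTest(p_value=min(p, 1.0), significant=p <= alpha,
                              method="exact")
    p1, p2 = count_a / total_a, count_b / total_b
    se = math.sqrt(pooled * (1 - pooled) * (1 / total_a + 1 / total_b))
    if se == 0:
        return ProportionTest(p_value=1.0, significant=False, method="z",
                              statistic=0.0)
    z = (p1 - p2) / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return ProportionTest(p_value=min(p, 1.0), significant=p <= alpha,
                          method="z", statistic=z)


def frequency_table(counts_a: Mapping[str, int], counts_b: Mapping[str, int],
                    alpha: float = 0.001, decimals: int = 1) -> pd.DataFrame:
    """Label-by-label comparison of two count tables.

    Totals are the sums of each table; output columns: counts, percentages,
    fold (a over b), p-value and significance flag per label.
    """
    total_a = sum(counts_a.values())
    total_b = sum(counts_b.values())
    if total_a <= 0 or total_b <= 0:
        raise ValueError("both datasets must contain counts")
    labels = sorted(set(counts_a) | set(counts_b))
    rows = []
    for label in labels:
        a, b = counts_a.get(label, 0), counts_b.get(label, 0)
        test = compare_proportions(a, total_a, b, total_b, alpha=alpha)
        rows.append({
            "label": label, "count_a": a, "count_b": b,
            "pct_a": frequency(a, total_a, decimals),
            "pct_b": frequency(b, total_b, decimals),
            "fold": fold_enrichment(a, total_a, b, total_b),
            "p_value": test.p_value, "significant": test.significant,
            "method": test.method,
        })
    return pd.DataFrame(rows)


def cog_rollup(pfam_counts: Mapping[str, int],
               pfam_to_cog: Mapping[str, str],
               decimals: int = 1) -> pd.DataFrame:
    """Roll Pfam counts up to COG functional-category relative abundances.

    Each Pfam maps to one single-letter category; unmapped Pfams fall into
    category S (function unknown).  Returns category, count and percentage
    of total mapped counts; an empty input yields an empty table.
    """
    if not pfam_counts:
        return pd.DataFrame(columns=["category", "count", "pct"])
    cat_counts: dict[str, int] = {}
    for pfam, n in pfam_counts.items():
        cat = str(pfam_to_cog.get(pfam, UNKNOWN_CATEGORY)).upper()[:1] \
            or UNKNOWN_CATEGORY
        cat_counts[cat] = cat_counts.get(cat, 0) + int(n)
    total = sum(cat_counts.values())
    rows = [{"category": c, "count": cat_counts[c],
             "pct": frequency(cat_counts[c], total, decimals)}
            for c in sorted(cat_counts)]
    return pd.DataFrame(rows)
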