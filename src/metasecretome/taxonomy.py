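"""Best-hit taxonomic binning of inserts and cellulosome-module ORFs.

Two threshold regimes from the study design are provided as distinct
operations: insert-level assignment (E-value < 1e-5 and query coverage
> 30%) and module-level assignment (bit score >= 40 for cohesin/SLH ORFs,
>= 35 for dockerin ORFs, rolled up at family rank).  Rank rollups pool
groups under 0.1% abundance into "Other" and best hits below 30% identity
into "Unassigned".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import ModelParams

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class TabHit:
    """One tabular (outfmt-6 style) alignment hit."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    evalue: float
    bitscore: float
    query_cov: float  # fraction of the query covered by the alignment
    taxid: int | None = None
    lineage: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")
        if not 0.0 <= self.query_cov <= 1.0 + 1e-9:
            raise ValueError("query_cov must be a fraction in [0, 1]")


@dataclass(frozen=True)
class TaxonAssignment:
    query_id: str
    lineage: tuple[str, ...]  # superkingdom .. genus ("" when unknown)
    status: str  # "assigned" | "unassigned"
    basis: TabHit | None = None

    def rank_name(self, rank: str) -> str:
        if self.status != "assigned":
            return ""
        return self.lineage[RANKS.index(rank)]


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-delimited superkingdom..genus string, padding
    missing trailing ranks with empty strings."""
    parts = [p.strip() for p in str(lineage).split(";")]
    parts = (parts + [""] * len(RANKS))[:len(RANKS)]
    return tuple(parts)


def _lookup_lineage(hit: TabHit,
                    lineages: Mapping[int, str] | None) -> tuple[str, ...] | None:
    if hit.lineage is not None:
        return parse_lineage(hit.lineage)
    if lineages is not None and hit.taxid is not None and hit.taxid in lineages:
        return parse_lineage(lineages[hit.taxid])
    return None


def _best_hit(hits: Sequence[TabHit]) -> TabHit:
    """Highest bit score; ties by lowest E-value, then first in input."""
    best = hits[0]
    for h in hits[1:]:
        if (h.bitscore, -h.evalue) > (best.bitscore, -best.evalue):
            best = h
    return best


def assign_insert_taxon(hits_for_query: Sequence[TabHit],
                        lineages: Mapping[int, str] | None = None,
                        params: ModelParams | None = None,
                        query_id: str | None = None) -> TaxonAssignment:
    """Pilot-style insert assignment: best hit among those with
    E-value < evalue_strict and query coverage > qcov_min.

    A failed lineage lookup demotes the query to unassigned rather than
    raising.
    """
    params = params or ModelParams()
    hits = list(hits_for_query)
    qid = query_id or (hits[0].query_id if hits else "?")
    passing = [h for h in hits
               if h.evalue < params.evalue_strict
               and h.query_cov > params.qcov_min]
    if not passing:
        return TaxonAssignment(qid, ("",) * len(RANKS), "unassigned")
    best = _best_hit(passing)
    lineage = _lookup_lineage(best, lineages)
    if lineage is None:
        return TaxonAssignment(qid, ("",) * len(RANKS), "unassigned",
                               basis=best)
    return TaxonAssignment(qid, lineage, "assigned", basis=best)


def assign_module_taxon(hits_for_orf: Sequence[TabHit], module_kind: str,
                        lineages: Mapping[int, str] | None = None,
                        params: ModelParams | None = None,
                        query_id: str | None = None) -> TaxonAssignment:
    """Family-level assignment of a cellulosome-module ORF.

    The best hit must reach the module-specific bit-score threshold
    (cohesin/SLH 40, dockerin 35).
    """
    params = params or ModelParams()
    kind = module_kind.lower()
    if kind not in ("cohesin", "slh", "dockerin"):
        raise ValueError(f"module_kind must be cohesin/slh/dockerin, "
                         f"got {module_kind!r}")
    threshold = params.bits_dockerin if kind == "dockerin" \
        else params.bits_cohesin_slh
    hits = list(hits_for_orf)
    qid = query_id or (hits[0].query_id if hits else "?")
    if not hits:
        return TaxonAssignment(qid, ("",) * len(RANKS), "unassigned")
    best = _best_hit(hits)
    if best.bitscore < threshold:
        return TaxonAssignment(qid, ("",) * len(RANKS), "unassigned",
                               basis=best)
    lineage = _lookup_lineage(best, lineages)
    if lineage is None:
        return TaxonAssignment(qid, ("",) * len(RANKS), "unassigned",
                               basis=best)
    return TaxonAssignment(qid, lineage, "assigned", basis=best)


def assign_taxa(hits: Iterable[TabHit],
                lineages: Mapping[int, str] | None = None,
                params: ModelParams | None = None) -> list[TaxonAssignment]:
    """Group hits by query (insert-level rule) and assign each query."""
    by_query: dict[str, list[TabHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return [assign_insert_taxon(by_query[q], lineages, params, query_id=q)
            for q in by_query]


def rank_rollup(assignments: Sequence[TaxonAssignment], rank: str,
                other_threshold_pct: float = 0.1,
                identity_min_pct: float = 30.0) -> pd.DataFrame:
    """Abundance table at a rank with "Other" and "Unassigned" pooling.

    Percentages are over all queries; taxa under ``other_threshold_pct`` are
    pooled into Other; unassigned queries and best hits below the identity
    cutoff go to Unassigned.  The percentages (Other and Unassigned
    included) sum to 100.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    if not assignments:
        return pd.DataFrame(columns=["taxon", "count", "pct"])
    counts: Counter[str] = Counter()
    for a in assignments:
        if a.status != "assigned" or not a.rank_name(rank):
            counts["Unassigned"] += 1
        elif a.basis is not None and a.basis.pct_identity < identity_min_pct:
            counts["Unassigned"] += 1
        else:
            counts[a.rank_name(rank)] += 1
    total = sum(counts.values())
    pooled: Counter[str] = Counter()
    for taxon, n in counts.items():
        pct = 100.0 * n / total
        if taxon not in ("Unassigned",) and pct < other_threshold_pct:
            pooled["Other"] += n
        else:
            pooled[taxon] += n
    rows = [{"taxon": t, "count": n, "pct": 100.0 * n / total}
            for t, n in sorted(pooled.items(),
                               key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows)
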