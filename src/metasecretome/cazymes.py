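"""dbCAN-style domain-hit filtering, dedup, cellulosome calls, class rollup.

Hits from an HMM scan against CAZyme family models are filtered with the
two-branch rule (alignment length > 80 aa requires E < 1e-5, shorter
alignments E < 1e-3), deduplicated at 100% sequence identity (containment
clustering, the semantics of CD-HIT at a 1.0 threshold), classified into
cellulosome module kinds, and rolled up into a per-class frequency table
with raw and clustered counts.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import ModelParams, round_half_up


@dataclass(frozen=True)
class DomainHit:
    """One HMM match of a CAZy/dbCAN family model on a protein."""

    orf_id: str
    family: str
    aln_len: int
    evalue: float
    bitscore: float
    env_from: int  # 1-based inclusive aa coords
    env_to: int

    def __post_init__(self) -> None:
        if self.env_from > self.env_to:
            raise ValueError("env_from must be <= env_to")
        if self.aln_len <= 0:
            raise ValueError("aln_len must be positive")


_CLASS_RE = re.compile(r"^(GH|GT|CE|PL|CBM|AA)\d+", re.IGNORECASE)
_CELLULOSOME = {"dockerin": "dockerin", "cohesin": "cohesin", "slh": "SLH"}


def family_class(family: str) -> str:
    """CAZy class of a family name (GH/GT/CE/PL/CBM/AA) or the cellulosome
    module kind (dockerin/cohesin/SLH).  Raises on unknown tags."""
    fam = family.strip()
    m = _CLASS_RE.match(fam)
    if m:
        return m.group(1).upper()
    key = fam.lower().rstrip("s")
    # tolerate dbCAN-style decorations like "dockerin.hmm" or "SLH_2"
    key = re.split(r"[._]", key)[0]
    if key in _CELLULOSOME:
        return _CELLULOSOME[key]
    raise ValueError(f"unrecognised CAZyme family tag: {family!r}")


def is_cellulosome_family(family: str) -> bool:
    try:
        return family_class(family) in ("dockerin", "cohesin", "SLH")
    except ValueError:
        return False


def filter_hits(hits: Iterable[DomainHit],
                params: ModelParams | None = None) -> list[DomainHit]:
    """Keep hits passing the two-branch length/E-value rule, in stable order.

    A hit is kept iff (aln_len > 80 and E < 1e-5) or (aln_len <= 80 and
    E < 1e-3): long alignments get no relaxed branch.
    """
    params = params or ModelParams()
    kept = []
    for h in hits:
        if h.aln_len > params.aln_len_cutoff:
            ok = h.evalue < params.evalue_strict
        else:
            ok = h.evalue < params.evalue_relaxed
        if ok:
            kept.append(h)
    return kept


@dataclass(frozen=True)
class Clusters:
    """100%-identity clustering result: member -> representative mapping."""

    representative_of: Mapping[str, str]

    @property
    def representatives(self) -> set[str]:
        return set(self.representative_of.values())

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = defaultdict(list)
        for member, rep in self.representative_of.items():
            out[rep].append(member)
        return {rep: sorted(ms) for rep, ms in out.items()}

    def __len__(self) -> int:
        return len(self.representatives)


def dedup_sequences(proteins: Mapping[str, str] | Sequence[tuple[str, str]],
                    ) -> Clusters:
    """Cluster sequences at 100% identity with containment.

    Two sequences share a cluster when they are identical or one is an exact
    substring of the other.  Greedy longest-first assignment (ties broken
    lexicographically by sequence then id) makes the result independent of
    input order; the representative is the longest member.
    """
    items = list(proteins.items()) if isinstance(proteins, Mapping) \
        else list(proteins)
    order = sorted(items, key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
    reps: list[tuple[str, str]] = []  # (rep_id, rep_seq)
    assignment: dict[str, str] = {}
    for seq_id, seq in order:
        for rep_id, rep_seq in reps:
            if seq in rep_seq:
                assignment[seq_id] = rep_id
                break
        else:
            reps.append((seq_id, seq))
            assignment[seq_id] = seq_id
    return Clusters(representative_of=assignment)


@dataclass(frozen=True)
class CellulosomeCall:
    """Cellulosome-module classification of one ORF."""

    orf_id: str
    kind: str  # single_dockerin_repeat | complete_dockerin |
    #            repeat_plus_other_module | cohesin | slh
    supporting: tuple[DomainHit, ...]


def classify_cellulosome(hits: Iterable[DomainHit]) -> list[CellulosomeCall]:
    """Classify each ORF's (already filtered) hits into module kinds.

    Two or more dockerin-repeat hits on an ORF form a presumed complete
    dockerin domain (no maximum gap between the repeats is imposed); a single
    repeat co-occurring with any non-dockerin CAZyme module is a
    ``repeat_plus_other_module``; a lone repeat is a
    ``single_dockerin_repeat``.  Cohesin and SLH hits yield their own calls.
    """
    by_orf: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by_orf[h.orf_id].append(h)
    calls: list[CellulosomeCall] = []
    for orf_id in sorted(by_orf):
        orf_hits = by_orf[orf_id]
        dockerins = [h for h in orf_hits if family_class(h.family) == "dockerin"]
        cohesins = [h for h in orf_hits if family_class(h.family) == "cohesin"]
        slh = [h for h in orf_hits if family_class(h.family) == "SLH"]
        others = [h for h in orf_hits
                  if family_class(h.family) not in ("dockerin", "cohesin", "SLH")]
        if len(dockerins) >= 2:
            calls.append(CellulosomeCall(orf_id, "complete_dockerin",
                                         tuple(dockerins)))
        elif len(dockerins) == 1 and others:
            calls.append(CellulosomeCall(orf_id, "repeat_plus_other_module",
                                         tuple(dockerins + others)))
        elif len(dockerins) == 1:
            calls.append(CellulosomeCall(orf_id, "single_dockerin_repeat",
                                         tuple(dockerins)))
        if cohesins:
            calls.append(CellulosomeCall(orf_id, "cohesin", tuple(cohesins)))
        if slh:
            calls.append(CellulosomeCall(orf_id, "slh", tuple(slh)))
    return calls


CLASS_ORDER = ["CBM", "CE", "GH", "GT", "PL", "AA", "cellulosome"]
MODULE_ORDER = ["SLH", "cohesin", "dockerin"]


@dataclass(frozen=True)
class CazyClassTable:
    """Per-class counts and distributions, raw and deduplicated.

    ``table`` has one row per CAZy class (cellulosome modules pooled into a
    single exclusive ``cellulosome`` row) plus one sub-row per cellulosome
    module kind; class percentages are rounded to one decimal and module
    percentages to two, each column summing to 100% over the class rows.
    """

    table: pd.DataFrame
    total_raw: int
    total_clustered: int


def rollup_classes(hits: Iterable[DomainHit],
                   clusters: Clusters | None = None) -> CazyClassTable:
    """Build the class frequency table from filtered hits.

    Raw counts include every hit; clustered counts include only hits on
    cluster-representative sequences (100% identity dedup).  Dockerin,
    cohesin and SLH families are exclusive: they are counted once, under
    ``cellulosome``, and never under GH/CBM/etc.
    """
    hits = list(hits)
    reps = clusters.representatives if clusters is not None else None

    def tally(selected: list[DomainHit]) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for h in selected:
            cls = family_class(h.family)
            if cls in ("dockerin", "cohesin", "SLH"):
                counts["cellulosome"] += 1
                counts[cls] += 1
            else:
                counts[cls] += 1
        return counts

    raw = tally(hits)
    clustered = tally([h for h in hits if reps is None or h.orf_id in reps])
    total_raw = sum(raw.get(c, 0) for c in CLASS_ORDER)
    total_clustered = sum(clustered.get(c, 0) for c in CLASS_ORDER)

    rows = []
    for name in CLASS_ORDER + MODULE_ORDER:
        is_module = name in MODULE_ORDER
        decimals = 2 if is_module else 1
        cr, cc = raw.get(name, 0), clustered.get(name, 0)
        rows.append({
            "class": name,
            "kind": "module" if is_module else "class",
            "count_raw": cr,
            "count_clustered": cc,
            "pct_raw": round_half_up(100.0 * cr / total_raw, decimals)
            if total_raw else 0.0,
            "pct_clustered": round_half_up(100.0 * cc / total_clustered,
                                           decimals) if total_clustered else 0.0,
        })
    return CazyClassTable(table=pd.DataFrame(rows), total_raw=total_raw,
                          total_clustered=total_clustered)
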