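"""Readers/writers for the pipeline's file formats, vector trimming, config.

Formats: FASTA (wrapped at 60 columns), GFF3 for ORF ground truth, HMMER3
domtblout and the 10-column dbCAN-parser TSV for domain hits, BLAST tabular
(outfmt 6, optional staxids column), TSV reports, YAML/JSON configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cazymes import DomainHit
from .frames import DEFAULT_CASSETTE, VectorCassette
from .model import ModelParams
from .synth import LibraryClone, OrfAnnotation, SyntheticCommunity
from .signals import SignalCategory


class DuplicateIdError(ValueError):
    """FASTA input contains repeated record ids."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping.

    Raises :class:`DuplicateIdError` listing repeated ids; an empty file
    yields an empty mapping.  CRLF and LF inputs parse identically.
    """
    records: dict[str, str] = {}
    dupes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            dupes.append(rec.id)
        records[rec.id] = str(rec.seq).upper()
    if dupes:
        raise DuplicateIdError(f"duplicate FASTA ids: {sorted(set(dupes))}")
    return records


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path, wrap: int = 60) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


def write_clone_fasta(clones: Sequence[LibraryClone], path: str | Path) -> None:
    """Clone FASTA with structured headers: clone_id|orientation|src."""
    write_fasta(((c.header, c.insert) for c in clones), path)


# ---------------------------------------------------------------------------
# GFF3

def write_community_gff3(community: SyntheticCommunity,
                         path: str | Path) -> None:
    """ORF ground truth as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, seq in community.replicons:
            fh.write(f"##sequence-region {rid} 1 {len(seq)}\n")
        for o in community.orfs:
            attrs = (f"ID={o.orf_id};signal_category={o.signal_category.value}")
            fh.write("\t".join([
                o.replicon_id, "metasecretome", "CDS", str(o.start + 1),
                str(o.end), ".", o.strand, "0", attrs]) + "\n")


def read_gff3_orfs(path: str | Path) -> list[dict[str, object]]:
    """Minimal GFF3 reader for the fields this package writes."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if kv)
            rows.append({
                "replicon_id": parts[0], "type": parts[2],
                "start": int(parts[3]) - 1, "end": int(parts[4]),
                "strand": parts[6], "orf_id": attrs.get("ID"),
                "signal_category": SignalCategory(
                    attrs.get("signal_category", "NONE")),
            })
    return rows


# ---------------------------------------------------------------------------
# domain-hit tables

class ParseError(ValueError):
    pass


def _as_hit_rows(hits) -> list[dict]:
    if isinstance(hits, pd.DataFrame):
        return hits.to_dict("records")
    return [{"orf_id": h.orf_id, "family": h.family, "aln_len": h.aln_len,
             "evalue": h.evalue, "bitscore": h.bitscore,
             "env_from": h.env_from, "env_to": h.env_to} for h in hits]


def write_domtblout(hits, path: str | Path) -> None:
    """Write hits as HMMER3 per-domain tabular output (hmmscan convention:
    target = family model, query = protein)."""
    rows = _as_hit_rows(hits)
    with open(path, "w") as fh:
        fh.write("#" + " " * 30 + "--- full sequence --- "
                 "-------------- this domain -------------\n")
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  "
                 "acc description of target\n")
        for r in rows:
            fh.write(" ".join(str(x) for x in [
                r["family"], "-", r["aln_len"], r["orf_id"], "-",
                r["env_to"] + 20, f'{r["evalue"]:.2g}', f'{r["bitscore"]:.1f}',
                "0.0", 1, 1, f'{r["evalue"]:.2g}', f'{r["evalue"]:.2g}',
                f'{r["bitscore"]:.1f}', "0.0", 1, r["aln_len"], r["env_from"],
                r["env_to"], r["env_from"], r["env_to"], "0.90", "-",
            ]) + "\n")


def write_dbcan_tsv(hits, path: str | Path) -> None:
    """Write hits in the 10-column dbCAN hmmscan-parser TSV dialect."""
    rows = _as_hit_rows(hits)
    with open(path, "w") as fh:
        for r in rows:
            cov = r["aln_len"] / max(1, r["aln_len"] + 10)
            fh.write("\t".join(str(x) for x in [
                r["family"], r["aln_len"], r["orf_id"], r["env_to"] + 20,
                f'{r["evalue"]:.2g}', 1, r["aln_len"], r["env_from"],
                r["env_to"], f"{cov:.3f}"]) + "\n")


def parse_domain_hits(path: str | Path,
                      dialect: str = "domtblout") -> list[DomainHit]:
    """Parse a domain-hit table into :class:`DomainHit` records.

    ``dialect`` is ``domtblout`` (whitespace-delimited HMMER3 per-domain
    table, 23 columns incl. the description tail) or ``dbcan_tsv`` (the
    10-column dbCAN-parser dialect, which carries no bit score - it is
    recorded as 0).  Input order is preserved; malformed rows raise
    :class:`ParseError` naming the line.
    """
    if dialect not in ("domtblout", "dbcan_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            try:
                if dialect == "domtblout":
                    f = line.split(None, 22)
                    env_from, env_to = int(f[19]), int(f[20])
                    hits.append(DomainHit(
                        orf_id=f[3], family=f[0],
                        aln_len=env_to - env_from + 1,
                        evalue=float(f[12]), bitscore=float(f[13]),
                        env_from=env_from, env_to=env_to))
                else:
                    f = line.rstrip("\n").split("\t")
                    if len(f) != 10:
                        raise ValueError(f"expected 10 columns, got {len(f)}")
                    env_from, env_to = int(f[7]), int(f[8])
                    hits.append(DomainHit(
                        orf_id=f[2], family=f[0],
                        aln_len=env_to - env_from + 1,
                        evalue=float(f[4]), bitscore=0.0,
                        env_from=env_from, env_to=env_to))
            except (IndexError, ValueError) as exc:
                raise ParseError(
                    f"{path}: malformed {dialect} row at line {lineno}: "
                    f"{exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# BLAST tabular

BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                  "bitscore"]


def write_blast_tab(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_blast_tab(path: str | Path, *,
                   query_lengths: Mapping[str, int] | None = None,
                   extra: str = "staxids") -> list["TabHit"]:
    """Read 12/13-column BLAST tabular output into :class:`TabHit` records.

    A 13th column is interpreted per ``extra`` as ``staxids`` (default) or
    ``qcovs`` (percent query coverage).  When neither qcovs nor
    ``query_lengths`` is available, coverage defaults to 1.0 (the coverage
    filter is then a no-op; supply query lengths for real analyses) -
    outfmt 6 carries no coverage column by default, so it is reconstructed
    as (qend - qstart + 1) / query_length.
    """
    from .taxonomy import TabHit
    hits: list[TabHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}: expected >= 12 columns at line "
                                 f"{lineno}")
            qseqid = f[0]
            qstart, qend = int(f[6]), int(f[7])
            taxid = None
            cov = None
            if len(f) > 12:
                if extra == "staxids":
                    taxid = int(f[12].split(";")[0])
                elif extra == "qcovs":
                    cov = float(f[12]) / 100.0
                else:
                    raise ValueError(f"unknown extra column kind {extra!r}")
            if cov is None:
                if query_lengths and qseqid in query_lengths:
                    cov = (abs(qend - qstart) + 1) / query_lengths[qseqid]
                else:
                    cov = 1.0
            hits.append(TabHit(
                query_id=qseqid, subject_id=f[1], pct_identity=float(f[2]),
                aln_len=int(f[3]), evalue=float(f[10]), bitscore=float(f[11]),
                query_cov=min(cov, 1.0), taxid=taxid))
    return hits


def read_lineage_tsv(path: str | Path) -> dict[int, str]:
    """Read a taxid -> lineage table (taxid TAB superkingdom;...;genus or
    taxid TAB rank columns)."""
    out: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out[int(f[0])] = ";".join(f[1:]) if len(f) > 2 else f[1]
    return out


# ---------------------------------------------------------------------------
# vector trimming

@dataclass
class TrimReport:
    trimmed: dict[str, str]
    discarded: list[str]
    n_trimmed: int
    n_untrimmed: int


def _find_approx(seq: str, pattern: str, per15: int = 1) -> int:
    """Leftmost start of ``pattern`` in ``seq`` allowing <= len//15*per15
    mismatches (Hamming); -1 when absent."""
    budget = max(0, (len(pattern) // 15) * per15)
    n, m = len(seq), len(pattern)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(seq[i:i + m], pattern):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        else:
            return i
    return -1


def trim_vector(reads: Mapping[str, str],
                cassette: VectorCassette = DEFAULT_CASSETTE,
                min_match: int = 15) -> TrimReport:
    """Strip cassette flank sequence from read ends (SeqClean-style).

    Exact and near-exact (one mismatch per 15 nt) matches of the flanks are
    removed: everything up to the end of an upstream-flank match and from
    the start of a downstream-flank match.  Reads reduced to nothing are
    emitted to the discard list.
    """
    up, down = cassette.upstream_flank, cassette.downstream_flank
    trimmed: dict[str, str] = {}
    discarded: list[str] = []
    n_trimmed = 0
    for rid, read in reads.items():
        read = read.upper()
        lo, hi = 0, len(read)
        hit = False
        pos = _find_approx(read, up)
        if pos >= 0:
            lo, hit = pos + len(up), True
        else:  # read may begin inside the flank
            for L in range(len(up) - 1, min_match - 1, -1):
                if _find_approx(read[:L], up[-L:]) == 0:
                    lo, hit = L, True
                    break
        pos = _find_approx(read[lo:], down)
        if pos >= 0:
            hi, hit = lo + pos, True
        else:  # read may end inside the flank
            for L in range(len(down) - 1, min_match - 1, -1):
                if len(read) - L >= lo and \
                        _find_approx(read[len(read) - L:], down[:L]) == 0:
                    hi, hit = len(read) - L, True
                    break
        insert = read[lo:hi]
        if not insert:
            discarded.append(rid)
        else:
            trimmed[rid] = insert
            if hit:
                n_trimmed += 1
    return TrimReport(trimmed=trimmed, discarded=discarded,
                      n_trimmed=n_trimmed,
                      n_untrimmed=len(trimmed) - n_trimmed)


# ---------------------------------------------------------------------------
# TSV + config

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class PipelineConfig:
    """Resolved run configuration for the CLI pipeline."""

    params: ModelParams = field(default_factory=ModelParams)
    cassette: VectorCassette = DEFAULT_CASSETTE
    seed: int = 0
    outdir: str = "."
    n_replicons: int = 2
    n_orfs: int = 500
    n_clones: int = 10000
    len_min: int = 700
    len_max: int = 5000

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") \
            else yaml.safe_load(text)
        data = data or {}
        kwargs: dict = {}
        if "params" in data:
            kwargs["params"] = ModelParams.from_mapping(data["params"])
        if "cassette" in data:
            kwargs["cassette"] = VectorCassette(**data["cassette"])
        for key in ("seed", "outdir", "n_replicons", "n_orfs", "n_clones",
                    "len_min", "len_max"):
            if key in data:
                kwargs[key] = data[key]
        cfg = cls(**kwargs)
        if cfg.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        return cfg

    def to_file(self, path: str | Path) -> None:
        data = {
            "params": self.params.to_dict(),
            "cassette": {
                "upstream_flank": self.cassette.upstream_flank,
                "downstream_flank": self.cassette.downstream_flank,
                "frame_offset": self.cassette.frame_offset,
            },
            "seed": self.seed, "outdir": self.outdir,
            "n_replicons": self.n_replicons, "n_orfs": self.n_orfs,
            "n_clones": self.n_clones, "len_min": self.len_min,
            "len_max": self.len_max,
        }
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(data, fh, indent=2)
            else:
                yaml.safe_dump(data, fh, sort_keys=False)
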