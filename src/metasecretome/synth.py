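"""Synthetic communities, clone libraries and mock annotation tables.

Everything downstream of the wet lab is exercised on data generated here,
with known ground truth.  The generator emulates:

* a community of circular replicons densely packed with ORFs, a configurable
  fraction (~20%) of which carry a membrane-targeting signal recognised by
  the built-in detectors *by construction*;
* random shearing into 0.7-5 kb inserts blunt-cloned in random orientation
  into the display cassette (vector ATG - MCS - pIII C-domain);
* mock HMM domain-hit and BLAST-hit tables with planted composition.

Geometry is arranged so the analytic selection lottery holds exactly.  Each
ORF is preceded by a 12-nt spacer (``TTAGTTAGTTAA``) that contains stop
codons in all six reading frames and ends with an in-frame TAA immediately
before the ATG, so any in-frame fusion run starts exactly at the ORF's own
start codon.  Secretome proteins are 200 aa and background proteins 165 aa:
with the 12-nt spacer this makes the fraction of junction positions that
yield a >= 24-codon in-frame secretome fusion exactly ``secretome_fraction/3``
(177 of 531 nt of per-ORF genome at a 20% ORF fraction), so the expected
selected fraction is ``secretome_fraction * p_orientation * 1/3``.

Codon choice is adversarial against spurious fusions.  Hydrophobic runs use
a Val-Val-Leu repeat on GTG/TTG codons whose five alternative readings
(shifted forward and all reverse frames) are deterministically polar, and
protein tails are assembled from a library of screened 8-codon cassettes
(:data:`TAIL_CASSETTES`) that remain polar and motif-free in every reading
frame, including across cassette junctions.  An out-of-frame or
reverse-strand fusion through any ORF region therefore never mimics a
membrane-targeting signal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .frames import revcomp
from .signals import SignalCategory

# ---------------------------------------------------------------------------
# deterministic encoding machinery

#: one fixed codon per amino acid; Leu/Ser/Arg choices make the reverse
#: strand stop-rich (revcomp(TTA)=TAA, revcomp(TCA)=TGA, revcomp(CTA)=TAG)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTG", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCA", "T": "ACT", "V": "GTG",
    "W": "TGG", "Y": "TAT",
}

#: spacer placed before every ORF: stops in all six frames within 12 nt and
#: an in-frame TAA immediately preceding the ATG
SPACER = "TTAGTTAGTTAA"

#: Vetted 8-codon building blocks for protein tails and inter-helix loops.
#: Each cassette encodes a hydrophilic octapeptide whose DNA was screened so
#: that every shifted-forward and reverse-strand reading (including all
#: pairwise cassette junctions and junctions with the VVL helix DNA) stays
#: below the transmembrane hydropathy threshold and contains no lipobox or
#: prepilin motif.  Tails assembled from these cassettes therefore cannot
#: give rise to spurious membrane-targeting calls in any reading frame.
TAIL_CASSETTES: tuple[tuple[str, str], ...] = (
    ("DEGSRRPG", "GATGAAGGGTCGAGGCGTCCGGGG"),
    ("SHETGPGR", "TCTCACGAAACGGGTCCCGGACGG"),
    ("TSRTDHPS", "ACTTCACGAACCGACCATCCGTCG"),
    ("GPEGSPGE", "GGGCCGGAAGGTTCTCCCGGAGAG"),
    ("NGSTPDRG", "AATGGGTCGACGCCCGACCGAGGG"),
    ("EKGPPPSP", "GAGAAGGGTCCTCCGCCTTCCCCC"),
    ("PGQGSPGP", "CCCGGTCAGGGATCCCCGGGTCCA"),
    ("GREPSPTP", "GGCCGCGAACCTTCGCCAACTCCG"),
    ("RTPEPPGR", "CGAACTCCGGAACCTCCGGGCCGC"),
    ("SGPRPQGP", "TCCGGTCCGCGCCCCCAAGGTCCG"),
)

#: default secretome/background protein lengths (aa, incl. the initial Met);
#: chosen with the 12-nt spacer so the capture-zone arithmetic is exact
SEC_PROTEIN_LEN = 200
BG_PROTEIN_LEN = 165

#: default allocation of signal categories among secretome ORFs, proportional
#: to the pilot-library tally (35 I : 8 TMH-anchor : 6 TMH-int/multi : 3 II :
#: 1 IV : 0 Tat)
DEFAULT_CATEGORY_WEIGHTS = {
    SignalCategory.TYPE_I: 35,
    SignalCategory.TMH_ANCHOR: 8,
    SignalCategory.TMH_INTERNAL_MULTI: 6,
    SignalCategory.TYPE_II: 3,
    SignalCategory.TYPE_IV: 1,
    SignalCategory.TAT: 0,
}

#: small panel of rumen lineages used to label replicons and mock BLAST hits
RUMEN_LINEAGES = {
    1001: "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prevotellaceae;Prevotella",
    1002: "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Clostridium",
    1003: "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Butyrivibrio",
    1004: "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Ruminococcus",
    1005: "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides",
    1006: "Bacteria;Fibrobacteres;Fibrobacteria;Fibrobacterales;Fibrobacteraceae;Fibrobacter",
}


def op_rng(seed: int, op_name: str) -> np.random.Generator:
    """One RNG stream per operation: seeded from (global seed, op name)."""
    return np.random.default_rng([int(seed) % 2**31,
                                  zlib.crc32(op_name.encode())])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed) % 2**31)


def encode_protein(aa_seq: str) -> str:
    """Deterministic DNA encoding with the fixed codon table."""
    return "".join(CODON[a] for a in aa_seq)


def _tail(n: int, rng: np.random.Generator) -> tuple[str, str]:
    """Random hydrophilic tail of ``n`` residues built from vetted cassettes.

    Returns (aa, dna); the final cassette is truncated to reach exactly
    ``n`` residues.
    """
    aa: list[str] = []
    dna: list[str] = []
    total = 0
    while total < n:
        c_aa, c_dna = TAIL_CASSETTES[rng.integers(len(TAIL_CASSETTES))]
        take = min(len(c_aa), n - total)
        aa.append(c_aa[:take])
        dna.append(c_dna[:3 * take])
        total += take
    return "".join(aa), "".join(dna)


# ---------------------------------------------------------------------------
# signal-peptide synthesis

def _vvl(n: int) -> str:
    """Hydrophobic run as a Val-Val-Leu repeat.

    Encoded with the GTG/TTG codons of the fixed table, every shifted or
    reverse-strand reading of this DNA is deterministically non-hydrophobic
    (G/V/W/C or Q/H/T/N/P mixtures below the 1.6 hydropathy threshold), so
    out-of-frame fusions through a helix can never mimic one.
    """
    return ("VVL" * (n // 3 + 1))[:n]


def _signal(category: SignalCategory, rng: np.random.Generator) -> tuple[str, str]:
    """Signal peptide and its DNA for one category (see
    :func:`synthesize_signal_peptide` for the sequence rules)."""
    pick = lambda pool, k: "".join(pool[i] for i in rng.integers(len(pool), size=k))

    if category is SignalCategory.TYPE_I:
        # M + positive n-region + hydrophobic h-region + A-X-A cleavage site
        n_region = "K" + pick("NSQ", 2)
        h_region = _vvl(int(rng.integers(8, 11)))
        pep = ("M" + n_region + h_region + "S")[:14]
        pep = pep + "A" + pick("QSN", 1) + "A"  # motif ends at position 15..30
        return pep, encode_protein(pep)
    if category is SignalCategory.TYPE_II:
        pep = "M" + "K" + _vvl(int(rng.integers(6, 10))) + "LAGC"
        return pep, encode_protein(pep)  # lipobox, Cys at position 12..15
    if category is SignalCategory.TYPE_IV:
        leader = "N" + pick("NKQE", int(rng.integers(1, 3)))
        pep = "M" + leader + "GF" + _vvl(10)
        return pep, encode_protein(pep)
    if category is SignalCategory.TMH_ANCHOR:
        pep = "M" + pick("STNQ", int(rng.integers(1, 3))) + _vvl(21)
        return pep, encode_protein(pep)
    if category is SignalCategory.TMH_INTERNAL_MULTI:
        # two helices; the first starts early so truncated fusions still
        # carry a detectable helix.  The 24-residue loop (three vetted
        # cassettes) is wide enough that hydropathy windows straddling it
        # never bridge the helices, and is safe in all reading frames.
        prefix = "M" + pick("STNQ", 2)
        helix = _vvl(21)
        loop_parts = [TAIL_CASSETTES[rng.integers(len(TAIL_CASSETTES))]
                      for _ in range(3)]
        loop_aa = "".join(a for a, _ in loop_parts)
        loop_dna = "".join(d for _, d in loop_parts)
        aa = prefix + helix + loop_aa + helix
        dna = (encode_protein(prefix + helix) + loop_dna
               + encode_protein(helix))
        return aa, dna
    if category is SignalCategory.TAT:
        pep = "M" + "SRR" + pick("QNS", 1) + "FLK" + _vvl(8)
        return pep, encode_protein(pep)
    raise ValueError(f"unknown signal category: {category!r}")


def synthesize_signal_peptide(category: SignalCategory | str, seed) -> str:
    """Emit an N-terminal peptide guaranteed to satisfy the corresponding
    built-in detector (and no higher-precedence one).

    The peptides start with Met, and their detection motifs fit within the
    first 24 residues, so any in-frame fusion of at least 24 codons anchored
    at the ORF start exposes a recognisable signal.
    """
    return _signal(SignalCategory(category), _as_rng(seed))[0]


# ---------------------------------------------------------------------------
# community generation

@dataclass(frozen=True)
class OrfAnnotation:
    """Ground-truth annotation of one synthetic ORF (0-based half-open
    nucleotide coordinates on the replicon; includes the stop codon)."""

    orf_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    signal_category: SignalCategory
    protein: str
    embedded_domains: tuple[str, ...] = ()

    @property
    def protein_len(self) -> int:
        return (self.end - self.start) // 3 - 1


@dataclass
class SyntheticCommunity:
    """A set of circular replicons with fully annotated ORFs."""

    replicons: list[tuple[str, str]]
    orfs: list[OrfAnnotation]
    taxon_labels: dict[str, str]

    @property
    def proteins(self) -> dict[str, str]:
        return {o.orf_id: o.protein for o in self.orfs}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.replicons)

    def secretome_orfs(self) -> list[OrfAnnotation]:
        return [o for o in self.orfs
                if o.signal_category is not SignalCategory.NONE]


class CommunitySizingError(ValueError):
    """Requested geometry cannot be realised."""


def _allocate_counts(weights: Mapping[SignalCategory, float],
                     total: int) -> dict[SignalCategory, int]:
    """Largest-remainder allocation; deterministic tie-break by enum order."""
    cats = [c for c in DEFAULT_CATEGORY_WEIGHTS if c in weights]
    cats += [c for c in weights if c not in cats]
    wsum = float(sum(weights[c] for c in cats))
    if wsum <= 0:
        raise ValueError("category weights must sum to a positive value")
    raw = {c: total * weights[c] / wsum for c in cats}
    counts = {c: int(raw[c]) for c in cats}
    short = total - sum(counts.values())
    by_frac = sorted(cats, key=lambda c: (-(raw[c] - counts[c]), c.value))
    for c in by_frac[:short]:
        counts[c] += 1
    return counts


def generate_community(n_replicons: int = 2, n_orfs: int = 500,
                       secretome_fraction: float = 0.20, seed: int = 0, *,
                       category_weights: Mapping[SignalCategory, float] | None = None,
                       sec_protein_len: int = SEC_PROTEIN_LEN,
                       bg_protein_len: int = BG_PROTEIN_LEN,
                       replicon_length_budget: int | None = None,
                       ) -> SyntheticCommunity:
    """Build a community with an exact count of signal-carrying ORFs.

    Exactly ``round(secretome_fraction * n_orfs)`` ORFs carry a non-NONE
    category (exact-count allocation, not Bernoulli, so small communities
    have deterministic composition).  All ORFs are on the plus strand of
    circular replicons; output is bit-identical for a fixed seed.
    """
    if n_orfs <= 0:
        raise ValueError("n_orfs must be positive")
    if not 0.0 <= secretome_fraction <= 1.0:
        raise ValueError("secretome_fraction must be in [0, 1]")
    if n_replicons <= 0 or n_replicons > n_orfs:
        raise CommunitySizingError(
            f"cannot place {n_orfs} ORFs on {n_replicons} replicons")
    if min(sec_protein_len, bg_protein_len) < 30:
        raise CommunitySizingError("protein lengths below 30 aa are not supported")

    rng = op_rng(seed, "generate_community")
    n_sec = round(secretome_fraction * n_orfs)
    counts = _allocate_counts(category_weights or DEFAULT_CATEGORY_WEIGHTS,
                              n_sec)
    labels: list[SignalCategory] = []
    for cat, k in counts.items():
        labels.extend([cat] * k)
    labels.extend([SignalCategory.NONE] * (n_orfs - n_sec))
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    replicon_parts: list[list[str]] = [[] for _ in range(n_replicons)]
    replicon_ids = [f"replicon_{r:02d}" for r in range(n_replicons)]
    offsets = [0] * n_replicons
    orfs: list[OrfAnnotation] = []
    for i, category in enumerate(labels):
        r = i % n_replicons
        if category is SignalCategory.NONE:
            pep, pep_dna = "M", CODON["M"]
            total_len = bg_protein_len
        else:
            pep, pep_dna = _signal(category, rng)
            total_len = sec_protein_len
        tail_aa, tail_dna = _tail(total_len - len(pep), rng)
        protein = pep + tail_aa
        orf_dna = pep_dna + tail_dna + "TAA"
        start = offsets[r] + len(SPACER)
        end = start + len(orf_dna)
        orfs.append(OrfAnnotation(
            orf_id=f"{replicon_ids[r]}|orf{i:05d}",
            replicon_id=replicon_ids[r], start=start, end=end, strand="+",
            signal_category=category, protein=protein))
        replicon_parts[r].append(SPACER + orf_dna)
        offsets[r] = end

    replicons = [(rid, "".join(parts))
                 for rid, parts in zip(replicon_ids, replicon_parts)]
    if replicon_length_budget is not None:
        too_big = [rid for rid, seq in replicons
                   if len(seq) > replicon_length_budget]
        if too_big:
            raise CommunitySizingError(
                f"replicons exceed length budget: {too_big}")
    taxids = sorted(RUMEN_LINEAGES)
    taxon_labels = {rid: RUMEN_LINEAGES[taxids[r % len(taxids)]]
                    for r, rid in enumerate(replicon_ids)}
    return SyntheticCommunity(replicons=replicons, orfs=orfs,
                              taxon_labels=taxon_labels)


# ---------------------------------------------------------------------------
# shearing and cloning

@dataclass(frozen=True)
class LibraryClone:
    """One blunt-cloned shotgun insert with ground-truth labels.

    ``insert`` is the as-cloned sequence (already reverse-complemented for
    reverse-orientation clones); ``src_start``/``src_end`` give the source
    interval on the (circular) replicon, with ``src_end`` possibly exceeding
    the replicon length to denote wrap-around.
    """

    clone_id: str
    insert: str
    orientation: str  # "forward" | "reverse"
    replicon_id: str
    src_start: int
    src_end: int
    truth_secretome: bool
    truth_in_frame: bool
    src_orf_id: str | None = None

    @property
    def header(self) -> str:
        return (f"{self.clone_id}|{self.orientation}"
                f"|{self.replicon_id}:{self.src_start}-{self.src_end}")


def _junction_truth(orf_lookup: dict[str, list[OrfAnnotation]],
                    replicon_id: str, junction: int,
                    min_fusion_len: int) -> tuple[bool, bool, str | None]:
    """Ground truth for a forward-read 3' junction at genome position j.

    True in-frame capture requires the junction to sit on a codon boundary of
    an ORF, at least ``min_fusion_len`` codons downstream of its ATG and not
    past its last sense codon.
    """
    import bisect
    orf_list = orf_lookup[replicon_id]
    starts = [o.start for o in orf_list]
    idx = bisect.bisect_right(starts, junction) - 1
    if idx < 0:
        return False, False, None
    orf = orf_list[idx]
    offset = junction - orf.start
    if (offset % 3 == 0 and 3 * min_fusion_len <= offset
            and offset <= (orf.end - orf.start) - 3):
        secretome = orf.signal_category is not SignalCategory.NONE
        return True, secretome, orf.orf_id
    return False, False, None


def shear_and_clone(community: SyntheticCommunity, n_clones: int,
                    len_min: int = 700, len_max: int = 5000, seed: int = 0, *,
                    p_orientation: float = 0.5,
                    median_len: float = 1500.0, sigma: float = 0.6,
                    min_fusion_len: int = 24) -> list[LibraryClone]:
    """Shear the community into inserts and clone them in random orientation.

    Insert start positions are uniform on the circular replicons (chosen with
    probability proportional to replicon length); lengths follow a log-normal
    distribution truncated to [len_min, len_max] (degenerate when the bounds
    coincide).  Orientation is Bernoulli(``p_orientation``) forward.  Truth
    flags come from junction-frame arithmetic against the ORF annotations.
    """
    if len_min < 60:
        raise ValueError("len_min must be >= 60")
    if len_max < len_min:
        raise ValueError("len_max must be >= len_min")
    shortest = min(len(seq) for _, seq in community.replicons)
    if shortest < len_max:
        raise CommunitySizingError(
            f"shortest replicon ({shortest} nt) is shorter than len_max "
            f"({len_max} nt)")
    rng = op_rng(seed, "shear_and_clone")
    seqs = dict(community.replicons)
    rep_ids = [rid for rid, _ in community.replicons]
    lengths = np.array([len(seqs[r]) for r in rep_ids], dtype=float)
    rep_probs = lengths / lengths.sum()
    orf_lookup: dict[str, list[OrfAnnotation]] = {r: [] for r in rep_ids}
    for o in community.orfs:
        orf_lookup[o.replicon_id].append(o)
    for lst in orf_lookup.values():
        lst.sort(key=lambda o: o.start)

    mu = float(np.log(median_len))
    clones: list[LibraryClone] = []
    for i in range(n_clones):
        rid = rep_ids[rng.choice(len(rep_ids), p=rep_probs)]
        g = len(seqs[rid])
        if len_min == len_max:
            ln = len_min
        else:
            ln = 0
            for _ in range(1000):
                draw = rng.lognormal(mean=mu, sigma=sigma)
                if len_min <= draw <= len_max:
                    ln = int(draw)
                    break
            else:  # pragma: no cover - distribution misconfiguration
                ln = int(rng.integers(len_min, len_max + 1))
        start = int(rng.integers(g))
        end = start + ln
        fragment = (seqs[rid][start:] + seqs[rid][:end - g]) if end > g \
            else seqs[rid][start:end]
        forward = bool(rng.random() < p_orientation)
        if forward:
            insert = fragment
            junction = end % g
        else:
            insert = revcomp(fragment)
            junction = start
        in_frame, secretome, src_orf = (False, False, None)
        if forward:  # all synthetic ORFs are on the plus strand
            in_frame, secretome, src_orf = _junction_truth(
                orf_lookup, rid, junction, min_fusion_len)
        clones.append(LibraryClone(
            clone_id=f"clone{i:06d}", insert=insert,
            orientation="forward" if forward else "reverse",
            replicon_id=rid, src_start=start, src_end=end,
            truth_secretome=secretome, truth_in_frame=in_frame,
            src_orf_id=src_orf))
    return clones


# ---------------------------------------------------------------------------
# mock annotation tables

@dataclass(frozen=True)
class HitPlan:
    """Plan for planting domain hits of one family."""

    n_orfs: int
    hits_per_orf: int = 1
    evalue: float = 1e-20
    aln_len: int = 120
    bitscore: float = 150.0


def emit_mock_domain_hits(protein_ids: Sequence[str],
                          composition: Mapping[str, HitPlan | int],
                          seed: int = 0) -> pd.DataFrame:
    """Plant HMM domain hits with controlled E-values/alignment lengths.

    ``composition`` maps a CAZy/dbCAN family name (e.g. ``GH5``, ``dockerin``)
    to a :class:`HitPlan` (a bare int means that many single-hit ORFs).  Each
    family's ORFs are drawn without replacement from ``protein_ids``; an ORF
    receives ``hits_per_orf`` tandem hits (two dockerin-repeat hits model a
    complete dockerin domain).  Returns a tidy hit table; writers for the
    HMMER domtblout and dbCAN TSV dialects live in :mod:`metasecretome.io`.
    """
    from .cazymes import family_class  # validates family names
    rng = op_rng(seed, "emit_mock_domain_hits")
    plans: dict[str, HitPlan] = {}
    for family, plan in composition.items():
        family_class(family)  # raises on unknown family tag
        plans[family] = plan if isinstance(plan, HitPlan) else HitPlan(int(plan))
    needed = sum(p.n_orfs for p in plans.values())
    if needed > len(protein_ids):
        raise ValueError(
            f"composition requests {needed} ORFs but only "
            f"{len(protein_ids)} proteins are available")
    order = [protein_ids[i] for i in rng.permutation(len(protein_ids))]
    rows = []
    cursor = 0
    for family in sorted(plans):
        plan = plans[family]
        for orf_id in order[cursor:cursor + plan.n_orfs]:
            for h in range(plan.hits_per_orf):
                env_from = 1 + h * (plan.aln_len + 10)
                rows.append({
                    "orf_id": orf_id, "family": family,
                    "aln_len": plan.aln_len, "evalue": plan.evalue,
                    "bitscore": plan.bitscore, "env_from": env_from,
                    "env_to": env_from + plan.aln_len - 1,
                })
        cursor += plan.n_orfs
    columns = ["orf_id", "family", "aln_len", "evalue", "bitscore",
               "env_from", "env_to"]
    return pd.DataFrame(rows, columns=columns)


def emit_mock_blast_hits(query_ids: Sequence[str],
                         lineage_table: Mapping[int, str] | None = None,
                         seed: int = 0, *,
                         identity: float = 75.0, coverage: float = 0.75,
                         bitscore: float = 200.0, query_length: int = 300,
                         n_decoys: int = 2,
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Plant best BLAST hits with controlled identity/coverage/bit score.

    Each query receives one planted best hit to a random taxid from
    ``lineage_table`` (default: the built-in rumen panel) plus ``n_decoys``
    weaker hits to other taxids.  Returns the tabular (outfmt-6 + staxids)
    hit table and the planted query -> taxid truth mapping.
    """
    lineage_table = lineage_table or RUMEN_LINEAGES
    if not lineage_table:
        raise ValueError("lineage_table must be non-empty")
    rng = op_rng(seed, "emit_mock_blast_hits")
    taxids = sorted(lineage_table)
    rows = []
    truth: dict[str, int] = {}
    qend = max(1, int(round(coverage * query_length)))
    for q in query_ids:
        best = taxids[rng.integers(len(taxids))]
        truth[q] = best
        rows.append({
            "qseqid": q, "sseqid": f"ref|{best}|best", "pident": identity,
            "length": qend, "mismatch": int((100 - identity) / 100 * qend),
            "gapopen": 0, "qstart": 1, "qend": qend, "sstart": 1,
            "send": qend, "evalue": 1e-30, "bitscore": bitscore,
            "staxids": best,
        })
        for d in range(n_decoys):
            other = taxids[rng.integers(len(taxids))]
            rows.append({
                "qseqid": q, "sseqid": f"ref|{other}|decoy{d}",
                "pident": max(20.0, identity - 20.0), "length": qend,
                "mismatch": int(0.4 * qend), "gapopen": 1, "qstart": 1,
                "qend": qend, "sstart": 1, "send": qend,
                "evalue": 1e-10, "bitscore": bitscore - 50.0 - 10.0 * d,
                "staxids": other,
            })
    columns = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore",
               "staxids"]
    return pd.DataFrame(rows, columns=columns), truth
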