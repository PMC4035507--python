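"""Insert-pIII junction location and in-frame fusion extraction.

The display cassette reads: vector ATG ... multiple cloning site | insert |
pIII C-domain.  Whether an insert-encoded polypeptide is displayed depends on
the reading frame anchored at the *3' junction*: translation must run through
the insert suffix into the pIII C-domain without hitting a stop codon.  The
operations here locate the junctions in raw reads and extract the maximal
stop-free codon run (the "fusion ORF") in the pIII-congruent frame.

Coordinates are 0-based half-open internally; report files use 1-based
inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_ACGT = frozenset("ACGT")


class JunctionNotFoundError(ValueError):
    """Neither cassette flank anchor was found in the read."""


class AmbiguousJunctionError(ValueError):
    """Flank anchors matched in both orientations of the read."""


class AlphabetError(ValueError):
    """Sequence contains symbols outside the unambiguous DNA alphabet."""


def _check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - _ACGT
    if bad:
        raise AlphabetError(
            f"{what} contains non-ACGT symbols: {sorted(bad)} "
            "(IUPAC ambiguity codes are rejected)")
    return seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class VectorCassette:
    """The fixed vector context flanking a cloned insert.

    ``upstream_flank`` ends at the insert 5' junction (and contains the
    cassette ATG); ``downstream_flank`` begins at the insert 3' junction with
    the first base at codon phase ``frame_offset`` (0 means the junction
    coincides with a codon boundary of the pIII reading frame).
    """

    upstream_flank: str
    downstream_flank: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.upstream_flank or not self.downstream_flank:
            raise ValueError("cassette flanks must be non-empty")
        object.__setattr__(self, "upstream_flank",
                           _check_dna(self.upstream_flank, "upstream_flank"))
        object.__setattr__(self, "downstream_flank",
                           _check_dna(self.downstream_flank, "downstream_flank"))
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")


#: Synthetic secretome-selection cassette used throughout the simulator: a
#: ribosome-binding site + ATG upstream of a blunt cloning site, and a
#: Gly/Ser-linker leading into the pIII C-domain downstream.  The downstream
#: flank starts on a codon boundary of the pIII frame (frame_offset = 0).
DEFAULT_CASSETTE = VectorCassette(
    upstream_flank="GGCGCTAGCAAGGAGATATACATATGGCTAGCTCTGGTCCC",
    downstream_flank="GGGTCTGGTGGCGGCTCTGGTGGCGGCTCTGAGGGTGGCGGCTCTGAG",
    frame_offset=0,
)


@dataclass(frozen=True)
class Junction:
    """Insert interval located within a read.

    ``start``/``end`` are 0-based half-open coordinates within the oriented
    read (the reverse complement of the input when ``reverse`` is True).
    """

    start: int
    end: int
    reverse: bool

    def extract(self, read: str) -> str:
        oriented = revcomp(read) if self.reverse else read.upper()
        return oriented[self.start:self.end]


@dataclass(frozen=True)
class FusionOrf:
    """The insert-encoded open region in the pIII frame.

    ``nt_end`` coincides with the last full insert codon of the pIII frame;
    ``aa_seq`` is the bacterial-code translation of [nt_start, nt_end) and
    contains no stop symbol.
    """

    insert_id: str | None
    frame: int
    nt_start: int
    nt_end: int
    aa_seq: str
    length_aa: int
    in_frame_with_piii: bool = True


def locate_junction(read: str, cassette: VectorCassette,
                    min_anchor: int = 15) -> Junction:
    """Find the insert interval in a read by exact flank-anchor search.

    Handles reads covering both joints or only one (a primer read from the
    pIII side sees only the 3' joint).  Ties between equal matches go to the
    leftmost occurrence.  Raises :class:`JunctionNotFoundError` when no anchor
    matches and :class:`AmbiguousJunctionError` when anchors match in both
    orientations.
    """
    read = read.upper()
    if len(read) < min_anchor:
        raise ValueError("read shorter than min_anchor")
    up_anchor = cassette.upstream_flank[-min_anchor:]
    down_anchor = cassette.downstream_flank[:min_anchor]

    def scan(seq: str) -> tuple[int, int] | None:
        up = seq.find(up_anchor)
        down = seq.find(down_anchor)
        if up < 0 and down < 0:
            return None
        start = up + len(up_anchor) if up >= 0 else 0
        end = down if down >= 0 else len(seq)
        if end < start:
            return None
        return start, end

    fwd = scan(read)
    rev = scan(revcomp(read))
    if fwd is not None and rev is not None:
        raise AmbiguousJunctionError(
            "cassette anchors match in both read orientations")
    if fwd is not None:
        return Junction(fwd[0], fwd[1], reverse=False)
    if rev is not None:
        return Junction(rev[0], rev[1], reverse=True)
    raise JunctionNotFoundError("no cassette flank anchor found in read")


def open_run_bounds(insert: str, frame_offset: int = 0) -> tuple[int, int]:
    """Bounds of the maximal stop-free codon run ending at the 3' junction.

    Returns 0-based half-open nucleotide coordinates (start, end) within the
    insert.  ``end`` is the end of the last insert codon congruent with the
    downstream (pIII) phase; ``start`` is bounded by the first in-frame stop
    scanning upstream, or by the first full codon of the insert.
    """
    insert = _check_dna(insert, "insert")
    n = len(insert)
    end = n - frame_offset
    frame = end % 3
    start = end
    pos = end - 3
    while pos >= frame:
        if insert[pos:pos + 3] in STOP_CODONS:
            break
        start = pos
        pos -= 3
    return start, end


def extract_fusion_orf(insert: str, cassette: VectorCassette = DEFAULT_CASSETTE,
                       *, min_fusion_len: int = 24,
                       require_start: bool = False,
                       insert_id: str | None = None) -> FusionOrf | None:
    """Extract the insert-encoded region fused in-frame with pIII.

    The pIII-congruent frame is 3'-anchored: codon boundaries are those that
    continue into the downstream flank at its ``frame_offset`` phase.  The
    fusion region is the maximal stop-free codon run in that frame ending at
    the 3' junction.  Returns ``None`` (background) when the run is shorter
    than ``min_fusion_len`` codons.

    With ``require_start=True`` the run must additionally begin at a
    bacterial initiation codon (ATG/GTG/TTG); the run is re-anchored at the
    first such codon.  By default no start codon is required because
    translation can initiate at the cassette ATG.
    """
    if len(insert) < 3:
        raise ValueError("insert must be at least one codon long")
    insert = _check_dna(insert, "insert")
    start, end = open_run_bounds(insert, cassette.frame_offset)
    if require_start:
        pos = start
        while pos < end and insert[pos:pos + 3] not in ("ATG", "GTG", "TTG"):
            pos += 3
        start = pos
    length_aa = (end - start) // 3
    if length_aa < min_fusion_len:
        return None
    aa_seq = str(Seq(insert[start:end]).translate(table=11))
    return FusionOrf(insert_id=insert_id, frame=end % 3, nt_start=start,
                     nt_end=end, aa_seq=aa_seq, length_aa=length_aa,
                     in_frame_with_piii=True)


@dataclass(frozen=True)
class OrfSpan:
    """A maximal stop-free codon run (stop-to-stop convention).

    Coordinates refer to the analysed strand's sequence: for strand '-',
    ``start``/``end`` index into the reverse complement of the input.
    """

    strand: str
    frame: int
    start: int
    end: int
    length_aa: int


def enumerate_orfs(sequence: str, min_len_aa: int = 1) -> list[OrfSpan]:
    """All maximal stop-free codon runs in all six frames.

    Serves as the independent brute-force oracle for the 3'-anchored fusion
    extraction: a fusion, when present, is a suffix of one of these runs.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    sequence = _check_dna(sequence)
    spans: list[OrfSpan] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        n = len(seq)
        for frame in range(3):
            run_start = frame
            pos = frame
            while pos + 3 <= n:
                if seq[pos:pos + 3] in STOP_CODONS:
                    if (pos - run_start) // 3 >= min_len_aa:
                        spans.append(OrfSpan(strand, frame, run_start, pos,
                                             (pos - run_start) // 3))
                    run_start = pos + 3
                pos += 3
            if (pos - run_start) // 3 >= min_len_aa:
                spans.append(OrfSpan(strand, frame, run_start, pos,
                                     (pos - run_start) // 3))
    return spans
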