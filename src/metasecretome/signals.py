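"""Heuristic membrane-targeting signal detectors and the category decision.

Each fusion ORF is assigned exactly one membrane-targeting category:

* ``TYPE_I``   classical cleavable signal sequence (positive n-region,
  hydrophobic h-region, A-X-A cleavage site),
* ``TYPE_II``  lipoprotein signal (lipobox ending in the lipidated Cys),
* ``TYPE_IV``  pilin-like signal (Gly at -1 of the prepilin cleavage site
  followed by a hydrophobic run),
* ``TAT``      twin-arginine signal,
* ``TMH_ANCHOR``          a single N-terminal transmembrane helix,
* ``TMH_INTERNAL_MULTI``  multiple helices or a single internal helix,
* ``NONCLASSICAL``        no signal but a non-classical secretion score above
  threshold (supplied by an external predictor),
* ``BACKGROUND``          none of the above, or shorter than 24 residues.

The detectors are deliberately simple deterministic sequence rules - they are
decision logic stand-ins for the published predictor tools (SignalP, LipoP,
TMHMM, PilFind, PRED-TAT, SecretomeP), whose tabular outputs can be supplied
as overrides for real data.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .frames import FusionOrf
from .model import ModelParams


class SignalCategory(str, Enum):
    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"
    TYPE_IV = "TYPE_IV"
    TMH_ANCHOR = "TMH_ANCHOR"
    TMH_INTERNAL_MULTI = "TMH_INTERNAL_MULTI"
    TAT = "TAT"
    NONCLASSICAL = "NONCLASSICAL"
    BACKGROUND = "BACKGROUND"
    #: ground-truth label for cytoplasmic ORFs; classified as BACKGROUND
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def _kd(aa_seq: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in aa_seq])


@dataclass(frozen=True)
class DetectorVerdict:
    fires: bool
    position: int | None = None  # 1-based cleavage/anchor position


def detect_spI(aa_seq: str) -> DetectorVerdict:
    """Type I (classical) signal sequence rule.

    Fires iff (i) at least one K/R in residues 1-5, (ii) a hydrophobic run of
    >= 7 residues within residues 6-20 whose Kyte-Doolittle mean exceeds 1.6,
    and (iii) an A-X-A motif ending at a position in [15, 30].  The reported
    position is the earliest qualifying A-X-A end (the putative cleavage
    site).
    """
    if len(aa_seq) < 24:
        return DetectorVerdict(False)
    if not any(a in "KR" for a in aa_seq[:5]):
        return DetectorVerdict(False)
    window = _kd(aa_seq[5:20])
    has_core = any(window[i:i + 7].mean() > 1.6
                   for i in range(len(window) - 6))
    if not has_core:
        return DetectorVerdict(False)
    for c in range(15, 31):  # 1-based motif end
        if c <= len(aa_seq) and aa_seq[c - 3] == "A" and aa_seq[c - 1] == "A":
            return DetectorVerdict(True, c)
    return DetectorVerdict(False)


LIPOBOX = re.compile(r"[LVIFG][ASTVG][GAS]C")


def detect_lipobox(aa_seq: str) -> DetectorVerdict:
    """Type II (lipoprotein) signal rule: lipobox with Cys at position 12-35
    plus at least one K/R in residues 1-7."""
    if not any(a in "KR" for a in aa_seq[:7]):
        return DetectorVerdict(False)
    for m in LIPOBOX.finditer(aa_seq):
        cys_pos = m.start() + 4  # 1-based position of the Cys
        if 12 <= cys_pos <= 35:
            return DetectorVerdict(True, cys_pos)
    return DetectorVerdict(False)


def detect_pilin(aa_seq: str) -> DetectorVerdict:
    """Type IV (prepilin-like) rule: Gly at the -1 cleavage position within
    the first 12 residues, immediately followed by Phe and a hydrophobic run
    (>= 7 of the next 10 residues with positive hydropathy)."""
    for i in range(max(0, min(12, len(aa_seq) - 11))):
        if aa_seq[i] == "G" and aa_seq[i + 1] == "F":
            run = aa_seq[i + 2:i + 12]
            if len(run) == 10 and sum(KYTE_DOOLITTLE.get(a, 0.0) > 0
                                      for a in run) >= 7:
                return DetectorVerdict(True, i + 1)
    return DetectorVerdict(False)


TAT_MOTIF = re.compile(r"[ST]RR.FLK")


def detect_tat(aa_seq: str) -> DetectorVerdict:
    """Twin-arginine (Tat) rule: S/T-R-R-x-F-L-K motif in the first 35
    residues."""
    m = TAT_MOTIF.search(aa_seq[:35])
    if m:
        return DetectorVerdict(True, m.start() + 2)  # first R, 1-based
    return DetectorVerdict(False)


def detect_tmh(aa_seq: str, window: int = 19,
               threshold: float = 1.6) -> list[tuple[int, int]]:
    """Transmembrane helix detection by sliding Kyte-Doolittle windows.

    Returns maximal 0-based half-open intervals covered by windows whose mean
    hydropathy exceeds ``threshold``; overlapping windows are merged.  A
    sequence shorter than ``window`` yields no intervals.
    """
    if len(aa_seq) < window:
        return []
    kd = _kd(aa_seq)
    means = np.convolve(kd, np.ones(window) / window, mode="valid")
    passing = np.nonzero(means > threshold)[0]
    intervals: list[tuple[int, int]] = []
    for s in passing:
        lo, hi = int(s), int(s) + window
        if intervals and lo <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], hi)
        else:
            intervals.append((lo, hi))
    return intervals


@dataclass(frozen=True)
class SignalCall:
    """Per-ORF classification outcome with the individual detector verdicts."""

    orf_id: str | None
    category: SignalCategory
    evidence: Mapping[str, object] = field(default_factory=dict)
    secp_score: float | None = None


class ExternalCallError(ValueError):
    """Malformed external-predictor table row."""


#: accepted external predictor tool names -> category they vote for
EXTERNAL_TOOLS = {
    "signalp": SignalCategory.TYPE_I,
    "lipop": SignalCategory.TYPE_II,
    "pred-lipo": SignalCategory.TYPE_II,
    "pilfind": SignalCategory.TYPE_IV,
    "pred-tat": SignalCategory.TAT,
    "tmhmm": SignalCategory.TMH_ANCHOR,
    "secretomep": SignalCategory.NONCLASSICAL,
}


def classify_signal(orf: FusionOrf | str,
                    external_calls: Mapping[str, object] | None = None,
                    params: ModelParams | None = None,
                    orf_id: str | None = None) -> SignalCall:
    """Assign one membrane-targeting category to a fusion ORF.

    Precedence: TYPE_IV > TYPE_II > TAT > TYPE_I > TMH_ANCHOR (exactly one
    helix starting at residue <= 40) > TMH_INTERNAL_MULTI > NONCLASSICAL
    (SecretomeP-style score >= threshold) > BACKGROUND.  Specific motifs rank
    above generic hydropathy; the ordering is a package decision since tools
    can disagree on real data.

    ``external_calls`` maps tool names (see :data:`EXTERNAL_TOOLS`) to
    ``True``/``False`` verdicts (or a float score for ``secretomep``); an
    external verdict overrides the built-in detector for the same category.
    """
    params = params or ModelParams()
    if isinstance(orf, FusionOrf):
        aa_seq = orf.aa_seq
        orf_id = orf_id or orf.insert_id
    else:
        aa_seq = orf
    aa_seq = aa_seq.upper()

    external = dict(external_calls or {})
    secp_score = None
    overrides: dict[SignalCategory, bool] = {}
    for tool, verdict in external.items():
        key = str(tool).lower()
        if key not in EXTERNAL_TOOLS:
            raise ExternalCallError(f"unknown external predictor {tool!r}")
        if key == "secretomep":
            secp_score = float(verdict)  # type: ignore[arg-type]
        else:
            overrides[EXTERNAL_TOOLS[key]] = bool(verdict)

    spi = detect_spI(aa_seq)
    lipo = detect_lipobox(aa_seq)
    pilin = detect_pilin(aa_seq)
    tat = detect_tat(aa_seq)
    tmh = detect_tmh(aa_seq)
    evidence = {"spI": spi, "lipobox": lipo, "pilin": pilin, "tat": tat,
                "tmh": tmh}

    def fires(category: SignalCategory, builtin: bool) -> bool:
        return overrides.get(category, builtin)

    if len(aa_seq) < params.min_fusion_len:
        category = SignalCategory.BACKGROUND
    elif fires(SignalCategory.TYPE_IV, pilin.fires):
        category = SignalCategory.TYPE_IV
    elif fires(SignalCategory.TYPE_II, lipo.fires):
        category = SignalCategory.TYPE_II
    elif fires(SignalCategory.TAT, tat.fires):
        category = SignalCategory.TAT
    elif fires(SignalCategory.TYPE_I, spi.fires):
        category = SignalCategory.TYPE_I
    elif fires(SignalCategory.TMH_ANCHOR,
               len(tmh) == 1 and tmh[0][0] <= 39):
        category = SignalCategory.TMH_ANCHOR
    elif fires(SignalCategory.TMH_INTERNAL_MULTI, len(tmh) >= 1):
        category = SignalCategory.TMH_INTERNAL_MULTI
    elif secp_score is not None and secp_score >= params.secp_threshold:
        category = SignalCategory.NONCLASSICAL
    else:
        category = SignalCategory.BACKGROUND
    return SignalCall(orf_id=orf_id, category=category, evidence=evidence,
                      secp_score=secp_score)


def tally_signal_categories(calls: Iterable[SignalCall],
                            sequences: Mapping[str, str] | None = None,
                            ) -> dict[str, object]:
    """Count calls per category, optionally with a distinct-sequence tally.

    ``sequences`` maps orf_id -> amino-acid sequence; when given, the distinct
    count collapses 100%-identical (containment) duplicates via
    :func:`metasecretome.cazymes.dedup_sequences`.
    """
    calls = list(calls)
    counts = Counter(c.category for c in calls)
    table = {cat: counts.get(cat, 0) for cat in SignalCategory
             if cat is not SignalCategory.NONE}
    result: dict[str, object] = {"counts": table, "n_calls": len(calls)}
    if sequences is not None:
        from .cazymes import dedup_sequences
        clusters = dedup_sequences(sequences)
        result["n_distinct"] = len(clusters.representatives)
    return result
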