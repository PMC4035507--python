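"""In silico sarcosyl selection of a clone library.

A phagemid particle survives the detergent only when its insert encodes a
membrane-targeting polypeptide fused in-frame to pIII.  The in silico rule is
the analytic counterpart: a clone is selected iff its 3'-anchored fusion ORF
is at least ``min_fusion_len`` codons long *and* the signal classifier
assigns a non-background category.  Clones failing the rule may still escape
elimination independently with probability ``background_escape``, modelling
the residual post-selection background (~5.6% of selected clones in the
pilot library at the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .frames import (DEFAULT_CASSETTE, FusionOrf, VectorCassette,
                     extract_fusion_orf, open_run_bounds)
from .model import (EnrichmentResult, ModelParams, enrichment_fold,
                    expected_selection_percent)
from .signals import SignalCall, SignalCategory, classify_signal
from .synth import LibraryClone, op_rng

#: elimination / survival reasons recorded per clone
REASONS = ("not_in_frame", "too_short", "no_signal", "selected_secretome",
           "background_escape")


@dataclass
class SelectionOutcome:
    """Result of one selection round."""

    selected: list[str]
    eliminated: list[str]
    reasons: dict[str, str]
    calls: dict[str, SignalCall]
    truth_secretome: dict[str, bool]
    truth_in_frame: dict[str, bool]

    @property
    def n_input(self) -> int:
        return len(self.selected) + len(self.eliminated)

    @property
    def selected_fraction(self) -> float:
        return len(self.selected) / self.n_input if self.n_input else 0.0

    @property
    def n_escapes(self) -> int:
        return sum(1 for c in self.selected
                   if self.reasons[c] == "background_escape")


def simulate_selection(clones: Sequence[LibraryClone],
                       cassette: VectorCassette = DEFAULT_CASSETTE,
                       params: ModelParams | None = None, seed: int = 0, *,
                       classifier: Callable[[FusionOrf], SignalCall] | None = None,
                       ) -> SelectionOutcome:
    """Apply the selection rule to every clone.

    ``classifier`` defaults to the built-in :func:`classify_signal`; a
    truth-oracle or external-predictor-backed callable can be substituted.
    Deterministic for a fixed seed (the only randomness is the per-clone
    background-escape draw).
    """
    if not clones:
        raise ValueError("clone library is empty")
    params = params or ModelParams()
    classify = classifier or (lambda fo: classify_signal(fo, params=params))
    rng = op_rng(seed, "simulate_selection")
    selected: list[str] = []
    eliminated: list[str] = []
    reasons: dict[str, str] = {}
    calls: dict[str, SignalCall] = {}
    t_sec: dict[str, bool] = {}
    t_frame: dict[str, bool] = {}
    for clone in clones:
        t_sec[clone.clone_id] = clone.truth_secretome
        t_frame[clone.clone_id] = clone.truth_in_frame
        run_start, run_end = open_run_bounds(clone.insert,
                                             cassette.frame_offset)
        run_aa = (run_end - run_start) // 3
        reason = None
        if run_aa == 0:
            reason = "not_in_frame"
        elif run_aa < params.min_fusion_len:
            reason = "too_short"
        else:
            fusion = extract_fusion_orf(clone.insert, cassette,
                                        min_fusion_len=params.min_fusion_len,
                                        insert_id=clone.clone_id)
            call = classify(fusion)
            calls[clone.clone_id] = call
            if call.category is SignalCategory.BACKGROUND:
                reason = "no_signal"
            else:
                reason = "selected_secretome"
        if reason == "selected_secretome":
            selected.append(clone.clone_id)
        elif params.background_escape > 0 and rng.random() < params.background_escape:
            reason = "background_escape"
            selected.append(clone.clone_id)
        else:
            eliminated.append(clone.clone_id)
        reasons[clone.clone_id] = reason
    return SelectionOutcome(selected=selected, eliminated=eliminated,
                            reasons=reasons, calls=calls,
                            truth_secretome=t_sec, truth_in_frame=t_frame)


@dataclass(frozen=True)
class SelectionSummary:
    enrichment: EnrichmentResult | None
    background_fraction: float
    n_selected: int
    n_input: int
    selected_fraction: float


def summarize_selection(outcome: SelectionOutcome,
                        params: ModelParams | None = None) -> SelectionSummary:
    """Enrichment statistics of one selection round.

    The observed frequency is the fraction of *selected* clones that are true
    secretome clones; the expectation is the analytic lottery percentage; the
    background fraction counts escapes among selected clones.  An empty
    selected pool yields a summary with no enrichment result rather than an
    error.
    """
    if outcome.n_input == 0:
        raise ValueError("selection outcome is empty")
    params = params or ModelParams()
    n_sel = len(outcome.selected)
    if n_sel == 0:
        return SelectionSummary(enrichment=None, background_fraction=0.0,
                                n_selected=0, n_input=outcome.n_input,
                                selected_fraction=0.0)
    n_true = sum(1 for c in outcome.selected if outcome.truth_secretome[c])
    expected_pct = expected_selection_percent(params)
    enr = enrichment_fold(n_true, n_sel, expected_pct)
    return SelectionSummary(
        enrichment=enr,
        background_fraction=outcome.n_escapes / n_sel,
        n_selected=n_sel, n_input=outcome.n_input,
        selected_fraction=outcome.selected_fraction)
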