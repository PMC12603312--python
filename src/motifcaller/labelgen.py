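"""Training-label generation from AM-search calls and pre-synthesis truth.

Because every payload slot stores a composite k-of-n mixture, the specific
motif carried by one molecule is unknown a priori; labels are therefore
built by keeping the AM-search calls that are consistent with the slot's
composite ground-truth set, on the reads whose calls agree best with the
truth (the top 30% by match fraction).  Calls outside the truth set are
dropped from the label rather than replaced, so residual AM label noise is
inherited by the trained model — the same compromise the composite design
forces on any real run.

An *oracle* mode that labels with the simulator's per-molecule truth is also
provided for controlled experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .design import InformationBlock, OligoDesign
from .search import SearchResult
from .simulate import SignalRead

__all__ = [
    "ScoredRead",
    "SlotAssignment",
    "segregate_payloads",
    "match_fraction",
    "select_training_reads",
    "make_labels",
    "oracle_labels",
]


@dataclass
class ScoredRead:
    """An AM-searched read scored against its block's composite truth."""

    read_id: str
    result: SearchResult
    match_fraction: float
    block_id: str


@dataclass
class SlotAssignment:
    """Payload tokens segregated into cycle positions by boundary tokens."""

    calls: list[str | None]  # per payload slot
    orientation: str = "forward"
    unassigned: list[str] = field(default_factory=list)
    surplus_slots: list[int] = field(default_factory=list)
    ambiguous: bool = False


def _boundary_index(token: str) -> int | None:
    if token.startswith("B") and token[1:].isdigit():
        return int(token[1:])
    return None


def segregate_payloads(
    tokens: list[str], design: OligoDesign, payload_ids: set[str] | None = None
) -> SlotAssignment:
    """Assign decoded payload tokens to cycle positions between boundary tokens.

    Tokens between boundary ``B_i`` and ``B_{i+1}`` belong to slot ``i``;
    tokens outside any boundary pair stay unassigned.  A descending boundary
    sequence marks a reverse-oriented read and is handled by reversing the
    token stream.  More than one payload token in a slot keeps the first and
    flags the slot; a skipped boundary pools the enclosed tokens as
    unassigned and flags the read ambiguous.
    """
    bounds = [b for t in tokens if (b := _boundary_index(t)) is not None]
    orientation = "forward"
    if len(bounds) >= 2 and bounds[0] > bounds[-1]:
        orientation = "reverse"
        tokens = list(reversed(tokens))
    out = SlotAssignment(calls=[None] * design.n_payload, orientation=orientation)
    current: int | None = None  # slot index currently open, None = outside
    for token in tokens:
        b = _boundary_index(token)
        if b is not None:
            if current is not None and b != current + 1:
                out.ambiguous = True
            current = b if b < design.n_slots else None
            continue
        if payload_ids is not None and token not in payload_ids:
            out.unassigned.append(token)
            continue
        if current is None or current < design.n_address:
            out.unassigned.append(token)
            continue
        p = current - design.n_address
        if out.calls[p] is None:
            out.calls[p] = token
        else:
            out.surplus_slots.append(p)
    return out


def match_fraction(result: SearchResult | SlotAssignment, truth: InformationBlock) -> float:
    """Fraction of payload slots whose call lies in that slot's composite set."""
    calls = result.calls if isinstance(result, SlotAssignment) else result.slot_calls
    if len(calls) != len(truth.payload_sets):
        raise ValueError("slot counts disagree")
    matched = sum(
        c is not None and c in s for c, s in zip(calls, truth.payload_sets)
    )
    return matched / len(calls)


def select_training_reads(scored: list[ScoredRead], fraction: float = 0.30) -> list[ScoredRead]:
    """Retain the top ``fraction`` of reads by match fraction.

    Sorted descending with a stable read_id tie-break; exactly
    ``max(1, floor(fraction * N))`` reads are kept (empty input stays empty).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if not scored:
        return []
    ranked = sorted(scored, key=lambda r: (-r.match_fraction, r.read_id))
    keep = max(1, math.floor(fraction * len(ranked)))
    return ranked[:keep]


def _label_tokens(
    slot_calls: list[str | None],
    design: OligoDesign,
    include_spacers: bool,
    reverse: bool,
) -> list[str]:
    tokens: list[str] = []
    if include_spacers:
        for b in range(design.n_boundaries):
            tokens.append(f"B{b}")
            slot = b
            if slot < design.n_slots and slot >= design.n_address:
                call = slot_calls[slot - design.n_address]
                if call is not None:
                    tokens.append(call)
    else:
        tokens = [c for c in slot_calls if c is not None]
    return list(reversed(tokens)) if reverse else tokens


def make_labels(
    selected: list[ScoredRead],
    truths: dict[str, InformationBlock],
    signal_reads: dict[str, SignalRead],
    design: OligoDesign,
    include_spacers: bool = False,
) -> list[tuple[SignalRead, list[str]]]:
    """Build the training set from selected reads (faithful mode).

    Per slot the AM call is kept iff it belongs to the slot's composite truth
    set; mismatching calls leave a gap (they are dropped, not replaced).
    Labels follow signal-time order: reverse-strand reads get reversed token
    order, with boundary tokens descending when ``include_spacers``.
    """
    out: list[tuple[SignalRead, list[str]]] = []
    for sr in selected:
        truth = truths[sr.block_id]
        read = signal_reads[sr.read_id]
        calls = [
            c if c is not None and c in s else None
            for c, s in zip(sr.result.slot_calls, truth.payload_sets)
        ]
        reverse = sr.result.strand == "reverse"
        tokens = _label_tokens(calls, design, include_spacers, reverse)
        if tokens:
            out.append((read, tokens))
    return out


def oracle_labels(
    signal_reads: list[SignalRead],
    design: OligoDesign,
    include_spacers: bool = True,
) -> list[tuple[SignalRead, list[str]]]:
    """Labels from the simulator's per-molecule truth (controlled experiments)."""
    out = []
    for read in signal_reads:
        payload = read.truth[design.n_address :]
        tokens = _label_tokens(
            list(payload), design, include_spacers, read.orientation == "reverse"
        )
        out.append((read, tokens))
    return out
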