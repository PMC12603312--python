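"""Evaluation metrics: detection, error rate, majority-vote recovery, coverage.

Detection and error are deliberately not complements: *motifs detected per
read* counts slots whose call lies in the slot's composite truth set over
all payload slots (blanks count as undetected), while *motif error rate*
counts wrong calls over called slots only.  Block-level recovery takes a
per-slot majority vote across reads and declares a block recovered when
every voted motif is in its truth set; the effective coverage is the
smallest number of reads per block at which mean recovery reaches a
threshold (95% by default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import InformationBlock

__all__ = [
    "RecoveryCurve",
    "motifs_detected_per_read",
    "motif_error_rate",
    "majority_vote",
    "recovery_curve",
    "decoding_accuracy",
    "quality_proportions",
    "error_correlation",
]

SlotCalls = list  # list[str | None], one entry per payload slot


def motifs_detected_per_read(calls: SlotCalls, truth: InformationBlock) -> float:
    """Percent of payload slots whose call is in the slot's truth set."""
    if len(calls) != len(truth.payload_sets):
        raise ValueError("slot counts disagree")
    ok = sum(c is not None and c in s for c, s in zip(calls, truth.payload_sets))
    return 100.0 * ok / len(calls)


def motif_error_rate(
    results: list[SlotCalls], truths: list[InformationBlock], per_slot_denominator: bool = False
) -> float | None:
    """Percent of called motifs not in their slot's truth set.

    The denominator is the number of *called* slots (``per_slot_denominator``
    switches to all payload slots).  With zero calls the rate is undefined
    and ``None`` is returned, not 0.
    """
    called = wrong = total_slots = 0
    for calls, truth in zip(results, truths):
        for c, s in zip(calls, truth.payload_sets):
            total_slots += 1
            if c is not None:
                called += 1
                wrong += c not in s
    denom = total_slots if per_slot_denominator else called
    if denom == 0 or (not per_slot_denominator and called == 0):
        return None
    return 100.0 * wrong / denom


def majority_vote(block_results: list[SlotCalls]) -> tuple[SlotCalls, list[bool]]:
    """Per-slot modal called motif across reads (blanks excluded).

    Ties resolve to the lexicographically smallest motif id and are flagged.
    Slots with no calls at all yield None.
    """
    if not block_results:
        raise ValueError("majority_vote requires at least one read")
    n_slots = len(block_results[0])
    consensus: SlotCalls = [None] * n_slots
    tie = [False] * n_slots
    for s in range(n_slots):
        votes = Counter(r[s] for r in block_results if r[s] is not None)
        if not votes:
            continue
        top = max(votes.values())
        winners = sorted(m for m, v in votes.items() if v == top)
        consensus[s] = winners[0]
        tie[s] = len(winners) > 1
    return consensus, tie


def _block_recovered(consensus: SlotCalls, truth: InformationBlock) -> bool:
    return all(c is not None and c in s for c, s in zip(consensus, truth.payload_sets))


@dataclass
class RecoveryCurve:
    """Mean block recovery as a function of reads used per block."""

    reads_used: list[int]
    recovery: list[float]  # fraction of blocks fully recovered, in [0, 1]
    threshold: float
    coverage_at_threshold: int | None
    excluded_blocks: dict[int, int] = field(default_factory=dict)  # r -> count


def recovery_curve(
    reads_by_block: dict[str, list[SlotCalls]],
    truths: dict[str, InformationBlock],
    threshold: float = 0.95,
    n_perm: int = 20,
    seed: int = 0,
    r_max: int | None = None,
) -> RecoveryCurve:
    """Majority-vote recovery vs reads per block, averaged over ``n_perm``
    seeded shufflings of read order.

    At each r the first r reads of every permutation are voted; blocks with
    fewer than r reads are excluded at that point (and counted).  The
    effective coverage is the first r whose mean recovery reaches the
    threshold.
    """
    rng = np.random.default_rng(seed)
    max_reads = max((len(v) for v in reads_by_block.values()), default=0)
    r_max = min(r_max, max_reads) if r_max else max_reads
    perms = {
        bid: [rng.permutation(len(rs)) for _ in range(n_perm)]
        for bid, rs in sorted(reads_by_block.items())
    }
    curve = RecoveryCurve([], [], threshold, None)
    for r in range(1, r_max + 1):
        scores, excluded = [], 0
        for bid, rs in sorted(reads_by_block.items()):
            if len(rs) < r:
                excluded += 1
                continue
            hit = 0
            for perm in perms[bid]:
                consensus, _ = majority_vote([rs[i] for i in perm[:r]])
                hit += _block_recovered(consensus, truths[bid])
            scores.append(hit / n_perm)
        if not scores:
            break
        rec = float(np.mean(scores))
        curve.reads_used.append(r)
        curve.recovery.append(rec)
        if excluded:
            curve.excluded_blocks[r] = excluded
        if curve.coverage_at_threshold is None and rec >= threshold:
            curve.coverage_at_threshold = r
    return curve


def decoding_accuracy(
    reads_by_block: dict[str, list[SlotCalls]],
    truths: dict[str, InformationBlock],
) -> float:
    """Percent of blocks whose full-consensus vote matches the truth.

    Uses every available read per block; blocks without reads count as
    unrecovered.
    """
    if not truths:
        raise ValueError("no blocks")
    ok = 0
    for bid, truth in truths.items():
        rs = reads_by_block.get(bid, [])
        if not rs:
            continue
        consensus, _ = majority_vote(rs)
        ok += _block_recovered(consensus, truth)
    return 100.0 * ok / len(truths)


def quality_proportions(
    reads: list[tuple[float, float, float | None]],
    thresholds: tuple[float, ...] = (0, 10, 15, 20),
) -> list[dict]:
    """Rows (one per quality threshold): % of reads >= Qt, mean detection,
    mean error over those reads.

    ``reads`` holds (read average quality, detection %, error % or None).
    The Q0 row always covers 100% of reads.
    """
    if not reads:
        raise ValueError("no reads")
    rows = []
    for qt in thresholds:
        sub = [r for r in reads if r[0] >= qt]
        errors = [e for _, _, e in sub if e is not None]
        rows.append(
            {
                "threshold": f"Q{qt:g}",
                "pct_of_reads": 100.0 * len(sub) / len(reads),
                "motifs_detected_pct": float(np.mean([d for _, d, _ in sub])) if sub else None,
                "motif_error_pct": float(np.mean(errors)) if errors else None,
            }
        )
    return rows


def error_correlation(
    per_read_errors_a: list[float], per_read_errors_b: list[float]
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between paired per-read error rates."""
    a = np.asarray(per_read_errors_a, dtype=float)
    b = np.asarray(per_read_errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of >= 3 paired reads")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant error vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
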