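"""From posterior matrices to filtered motif calls.

Greedy decoding takes the argmax token per frame and collapses the path
(merge repeats, drop blanks).  Prefix beam search instead keeps the W most
probable *collapsed* prefixes, maintaining separate blank-terminated and
token-terminated probabilities so repeats and blanks are summed correctly;
for small instances it recovers the exact argmax of P(y|s).

Each emitted token carries a confidence P_C (mean of the per-frame max
probability over the token's frame run for greedy; CTC occupancy-weighted
probability for beam) mapped to a Phred-style quality

    Q = -10 * log10(1 - P_C)

Filtering drops tokens with P_C below a confidence floor (0.85 by default)
and fails reads whose average quality is below a read threshold (11 by
default; the search baselines use 10 on basecall qualities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctc import ctc_label_occupancy
from .model import PosteriorMatrix

__all__ = [
    "CallResult",
    "BeamConfig",
    "collapse",
    "greedy_decode",
    "beam_decode",
    "quality",
    "filter_call",
]

Q_CAP = 60.0  # Q for P_C == 1 exactly (avoids log10(0))


@dataclass(frozen=True)
class BeamConfig:
    W: int = 8

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ValueError("beam width must be >= 1")


@dataclass
class CallResult:
    """Decoded token sequence with per-token confidence and quality."""

    read_id: str
    tokens: list[str]
    confidences: list[float]
    strand: str = "unknown"
    passed: bool | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.confidences):
            raise ValueError("one confidence per token required")

    @property
    def qualities(self) -> list[float]:
        return [quality(c) for c in self.confidences]

    @property
    def read_quality(self) -> float:
        """Mean token quality; empty calls score 0 (and fail filtering)."""
        q = self.qualities
        return float(np.mean(q)) if q else 0.0


def collapse(path: list[str] | list[int], blank: object = "phi") -> list:
    """CTC collapse: merge maximal repeat runs, then drop blanks.

    >>> collapse(["A", "phi", "A", "A", "phi", "G", "G"])
    ['A', 'A', 'G']
    """
    out, prev = [], object()
    for token in path:
        if token != prev:
            out.append(token)
        prev = token
    return [t for t in out if t != blank]


def greedy_decode(post: PosteriorMatrix, read_id: str = "", strand: str = "unknown") -> CallResult:
    """Argmax per frame, collapse, with run-averaged confidences.

    Ties break toward the lower class index.  A token's P_C is the mean of
    the per-frame max probabilities over its maximal frame run.
    """
    lp = post.log_probs
    blank = post.alphabet.blank
    if lp.shape[0] == 0:
        return CallResult(read_id, [], [], strand)
    ids = lp.argmax(axis=1)
    pmax = np.exp(lp[np.arange(len(ids)), ids])
    tokens: list[str] = []
    confs: list[float] = []
    t = 0
    while t < len(ids):
        run_start, cls = t, ids[t]
        while t < len(ids) and ids[t] == cls:
            t += 1
        if cls != blank:
            tokens.append(post.alphabet.tokens[cls])
            confs.append(float(pmax[run_start:t].mean()))
    return CallResult(read_id, tokens, confs, strand)


def _beam_search(lp: np.ndarray, blank: int, W: int) -> tuple[tuple[int, ...], float]:
    """Prefix beam search over collapsed sequences; returns (best y, log P(y|s))."""
    NEG = -np.inf

    def lse(a: float, b: float) -> float:
        if a == NEG:
            return b
        if b == NEG:
            return a
        hi, lo = (a, b) if a > b else (b, a)
        return hi + np.log1p(np.exp(lo - hi))

    # prefix -> (log p ending in blank, log p ending in last token)
    beams: dict[tuple[int, ...], tuple[float, float]] = {(): (0.0, NEG)}
    for t in range(lp.shape[0]):
        nxt: dict[tuple[int, ...], tuple[float, float]] = {}

        def add(prefix: tuple[int, ...], pb: float, pnb: float) -> None:
            opb, opnb = nxt.get(prefix, (NEG, NEG))
            nxt[prefix] = (lse(opb, pb), lse(opnb, pnb))

        for prefix, (pb, pnb) in beams.items():
            total = lse(pb, pnb)
            add(prefix, total + lp[t, blank], NEG)  # emit blank
            for c in range(lp.shape[1]):
                if c == blank:
                    continue
                p = lp[t, c]
                if prefix and prefix[-1] == c:
                    # same token: either extend the run (no new symbol) or
                    # start a new symbol after an intervening blank
                    add(prefix, NEG, pnb + p)
                    add(prefix + (c,), NEG, pb + p)
                else:
                    add(prefix + (c,), NEG, total + p)
        ranked = sorted(nxt.items(), key=lambda kv: -lse(*kv[1]))
        beams = dict(ranked[:W])
    best, (pb, pnb) = max(beams.items(), key=lambda kv: lse(*kv[1]))
    return best, lse(pb, pnb)


def beam_decode(
    post: PosteriorMatrix, cfg: BeamConfig = BeamConfig(), read_id: str = "", strand: str = "unknown"
) -> CallResult:
    """Prefix beam search decode.

    Confidences come from a forced alignment of the winning sequence: each
    token's P_C is its CTC occupancy-weighted mean frame probability.
    """
    lp = post.log_probs
    if lp.shape[0] == 0:
        return CallResult(read_id, [], [], strand)
    ids, _ = _beam_search(lp, post.alphabet.blank, cfg.W)
    confs = _forced_alignment_confidences(post, list(ids))
    return CallResult(read_id, post.alphabet.decode(list(ids)), confs, strand)


def _forced_alignment_confidences(post: PosteriorMatrix, ids: list[int]) -> list[float]:
    if not ids:
        return []
    loss, q = ctc_label_occupancy(post.log_probs, np.array(ids), post.alphabet.blank)
    if not np.isfinite(loss):
        return [0.0] * len(ids)
    p = np.exp(post.log_probs)
    confs = []
    for c in ids:
        w = q[:, c]
        confs.append(float(np.clip((w * p[:, c]).sum() / max(w.sum(), 1e-12), 0.0, 1.0)))
    return confs


def quality(p_c: float) -> float:
    """Phred-style token quality Q = -10 log10(1 - P_C), capped at 60.

    >>> quality(0.9)
    10.0
    """
    if not 0.0 <= p_c <= 1.0:
        raise ValueError("confidence must lie in [0, 1]")
    if p_c == 1.0:
        return Q_CAP
    return min(-10.0 * np.log10(1.0 - p_c), Q_CAP)


def filter_call(
    call: CallResult, read_q_min: float = 11.0, token_conf_min: float = 0.85
) -> tuple[CallResult, bool]:
    """Token- and read-level quality filtering.

    Tokens with P_C below ``token_conf_min`` are treated as blanks and
    dropped; the read fails when its average quality (over all decoded
    tokens, before dropping) is below ``read_q_min``.  Empty calls fail.
    """
    passed = bool(call.tokens) and call.read_quality >= read_q_min
    keep = [i for i, c in enumerate(call.confidences) if c >= token_conf_min]
    filtered = CallResult(
        read_id=call.read_id,
        tokens=[call.tokens[i] for i in keep],
        confidences=[call.confidences[i] for i in keep],
        strand=call.strand,
        passed=passed,
    )
    return filtered, passed
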