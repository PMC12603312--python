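"""Connectionist temporal classification: loss, gradient, and posteriors.

The network emits one probability distribution over tokens-plus-blank per
downsampled frame.  A frame-level path pi collapses to a label sequence by
merging repeats then deleting blanks; the CTC objective is the negative log
of the summed probability of every path collapsing to the target:

    P(y | s) = sum_{pi in B(y)} prod_t P(pi_t | s),    L = -log P(y | s)

computed with the standard forward-backward recursion over the
blank-extended label in log space.  The gradient with respect to the
pre-softmax logits is ``softmax - occupancy``, where occupancy is the
posterior expected count of each class per frame.
"""

from __future__ import annotations

import numpy as np

__all__ = ["log_softmax", "ctc_loss_grad", "ctc_loss_from_logprobs", "ctc_label_occupancy"]

NEG_INF = -np.inf


def log_softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise log-softmax along the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def _extend(labels: np.ndarray, blank: int) -> np.ndarray:
    """Blank-extended label: [phi, y1, phi, y2, ..., phi]."""
    ext = np.full(2 * len(labels) + 1, blank, dtype=np.int64)
    ext[1::2] = labels
    return ext


def _alpha_beta(
    logp: np.ndarray, ext: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward/backward lattices (emissions included at both ends) and log P(y|s)."""
    T, _ = logp.shape
    S = len(ext)
    # skip transition s-2 -> s allowed when ext[s] is a label differing from ext[s-2]
    can_skip = np.zeros(S, dtype=bool)
    can_skip[2:] = (ext[2:] != ext[:-2]) & (ext[2:] != ext[0])
    skip_idx = np.nonzero(can_skip)[0]
    em = np.ascontiguousarray(logp[:, ext], dtype=np.float64)  # (T, S)

    alpha = np.full((T, S), NEG_INF)
    alpha[0, 0] = em[0, 0]
    if S > 1:
        alpha[0, 1] = em[0, 1]
    acc = np.empty(S)
    for t in range(1, T):
        prev = alpha[t - 1]
        acc[0] = prev[0]
        np.logaddexp(prev[1:], prev[:-1], out=acc[1:])
        if skip_idx.size:
            acc[skip_idx] = np.logaddexp(acc[skip_idx], prev[skip_idx - 2])
        np.add(em[t], acc, out=alpha[t])

    beta = np.full((T, S), NEG_INF)
    beta[T - 1, S - 1] = em[T - 1, S - 1]
    if S > 1:
        beta[T - 1, S - 2] = em[T - 1, S - 2]
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1]
        acc[S - 1] = nxt[S - 1]
        np.logaddexp(nxt[:-1], nxt[1:], out=acc[:-1])
        if skip_idx.size:
            acc[skip_idx - 2] = np.logaddexp(acc[skip_idx - 2], nxt[skip_idx])
        np.add(em[t], acc, out=beta[t])

    log_p = (
        np.logaddexp(alpha[T - 1, S - 1], alpha[T - 1, S - 2]) if S > 1 else alpha[T - 1, S - 1]
    )
    return alpha, beta, float(log_p)


def ctc_loss_from_logprobs(logp: np.ndarray, labels: np.ndarray | list[int], blank: int) -> float:
    """-log P(y|s) from a (T, C) log-probability matrix; inf if infeasible."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    T = logp.shape[0]
    min_frames = len(labels) + np.count_nonzero(labels[1:] == labels[:-1])
    if T < min_frames or (len(labels) == 0 and T < 1):
        return float("inf")
    ext = _extend(labels, blank)
    _, _, log_p = _alpha_beta(logp, ext)
    return -log_p


def ctc_label_occupancy(
    logp: np.ndarray, labels: np.ndarray | list[int], blank: int
) -> tuple[float, np.ndarray]:
    """Loss and per-frame posterior class occupancy q (same shape as logp).

    q[t, c] is the posterior probability that a path collapsing to the label
    emits class c at frame t; rows sum to 1 when the label is feasible.
    """
    labels = np.asarray(labels, dtype=np.int64)
    ext = _extend(labels, blank)
    alpha, beta, log_p = _alpha_beta(logp, ext)
    if not np.isfinite(log_p):
        return float("inf"), np.zeros_like(logp)
    # gamma includes the emission twice (once in alpha, once in beta)
    gamma = alpha + beta - logp[:, ext] - log_p
    q = np.zeros_like(logp)
    np.add.at(q, (slice(None), ext), np.exp(gamma))
    return -log_p, q


def ctc_loss_grad(
    logits: np.ndarray, labels: np.ndarray | list[int], blank: int
) -> tuple[float, np.ndarray]:
    """CTC loss and gradient with respect to the pre-softmax logits.

    Returns (loss, dL/dlogits).  Infeasible labels (longer than the frame
    budget permits) yield inf loss and a zero gradient so the caller can
    flag and skip them.
    """
    labels = np.asarray(labels, dtype=np.int64)
    logp = log_softmax(logits)
    T = logits.shape[0]
    min_frames = len(labels) + np.count_nonzero(labels[1:] == labels[:-1])
    if T < min_frames:
        return float("inf"), np.zeros_like(logits)
    loss, q = ctc_label_occupancy(logp, labels, blank)
    if not np.isfinite(loss):
        return float("inf"), np.zeros_like(logits)
    return loss, np.exp(logp) - q
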