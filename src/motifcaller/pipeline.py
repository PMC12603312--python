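"""End-to-end orchestration shared by the CLI, the tests and the acceptance run.

Wires the stages together: simulate a run, search its basecalled reads
(ZE/AM with the baselines' read quality floor), build labels, train the
caller, decode signal reads, and score every method with the same metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decode import filter_call, greedy_decode
from .design import InformationBlock, OligoDesign, encode_blocks, random_library
from .evaluate import (
    decoding_accuracy,
    motif_error_rate,
    motifs_detected_per_read,
    recovery_curve,
)
from .labelgen import ScoredRead, match_fraction, segregate_payloads
from .model import CallerConfig, MotifCallerModel, TokenAlphabet, train
from .search import AMParams, SearchResult, am_search, build_spacer_index, make_aligner, ze_search
from .simulate import SimulatedRun

__all__ = [
    "MethodReadCall",
    "MethodSummary",
    "StudyScale",
    "search_run",
    "score_against_truth",
    "decode_run",
    "summarize",
    "train_caller",
    "run_study",
]

SEARCH_READ_Q_MIN = 10.0  # basecall quality floor of the search baselines
CALLER_READ_Q_MIN = 11.0
CALLER_TOKEN_CONF_MIN = 0.85


@dataclass
class MethodReadCall:
    """One read's per-slot calls under one method, ready for scoring."""

    read_id: str
    block_id: str
    slot_calls: list[str | None]
    read_quality: float
    passed_filter: bool
    strand: str = "forward"


@dataclass
class MethodSummary:
    method: str
    n_reads_total: int
    n_reads_retained: int
    motifs_detected_pct: float
    motif_error_pct: float | None
    coverage_at_threshold: int | None
    decoding_accuracy_pct: float
    per_read_detection: list[float] = field(repr=False, default_factory=list)
    per_read_error: list[float | None] = field(repr=False, default_factory=list)


def search_run(
    run: SimulatedRun,
    method: str,
    params: AMParams = AMParams(),
    read_q_min: float = SEARCH_READ_Q_MIN,
) -> list[MethodReadCall]:
    """ZE or AM search over a run's basecalled reads.

    Reads under the basecall quality floor are excluded (retained flag
    False) but still listed, so retention statistics stay computable.
    """
    if method not in ("ZE", "AM"):
        raise ValueError(f"unknown search method {method!r}")
    junctions = {b: run.library.junction(b) for b in range(run.design.n_boundaries)}
    index = build_spacer_index(junctions, params.seed_k)
    aligner = make_aligner(params)
    out = []
    for read in run.basecalled_reads:
        ok = read.mean_q >= read_q_min
        if not ok:
            result = SearchResult(read.read_id, method, "forward",
                                  [None] * run.design.n_payload, [None] * run.design.n_payload)
        elif method == "ZE":
            result = ze_search(read, run.library, run.design)
        else:
            result = am_search(read, run.library, run.design, params, index=index, aligner=aligner)
        out.append(
            MethodReadCall(
                read_id=read.read_id,
                block_id=read.block_id,
                slot_calls=result.slot_calls,
                read_quality=read.mean_q,
                passed_filter=ok,
                strand=result.strand,
            )
        )
    return out


def score_against_truth(
    calls: list[MethodReadCall], truths: dict[str, InformationBlock]
) -> list[ScoredRead]:
    """Wrap retained AM calls as ScoredReads for label selection."""
    out = []
    for c in calls:
        if not c.passed_filter:
            continue
        result = SearchResult(c.read_id, "AM", c.strand, c.slot_calls, [None] * len(c.slot_calls))
        out.append(
            ScoredRead(
                read_id=c.read_id,
                result=result,
                match_fraction=match_fraction(result, truths[c.block_id]),
                block_id=c.block_id,
            )
        )
    return out


def decode_run(
    model: MotifCallerModel,
    run: SimulatedRun,
    read_q_min: float = CALLER_READ_Q_MIN,
    token_conf_min: float = CALLER_TOKEN_CONF_MIN,
    batch_size: int = 64,
) -> list[MethodReadCall]:
    """Greedy-decode every signal read, filter, and segregate into slots."""
    from .ctc import log_softmax
    from .model import PosteriorMatrix

    payload_ids = set(run.library.motifs)
    model.net.eval()
    out = []
    reads = run.signal_reads
    for start in range(0, len(reads), batch_size):
        chunk = reads[start : start + batch_size]
        logits, fl = model.forward_batch([r.samples for r in chunk])
        for i, read in enumerate(chunk):
            post = PosteriorMatrix(log_softmax(logits[i, : fl[i]]), model.alphabet)
            call = greedy_decode(post, read_id=read.read_id)
            filtered, passed = filter_call(call, read_q_min, token_conf_min)
            assignment = segregate_payloads(filtered.tokens, run.design, payload_ids)
            out.append(
                MethodReadCall(
                    read_id=read.read_id,
                    block_id=read.block_id,
                    slot_calls=assignment.calls if passed else [None] * run.design.n_payload,
                    read_quality=call.read_quality,
                    passed_filter=passed,
                )
            )
    return out


def summarize(
    method: str,
    calls: list[MethodReadCall],
    truths: dict[str, InformationBlock],
    recovery_threshold: float = 0.95,
    n_perm: int = 20,
    seed: int = 0,
) -> MethodSummary:
    """Detection/error/coverage/decoding metrics over the retained reads."""
    retained = [c for c in calls if c.passed_filter]
    per_det, per_err = [], []
    reads_by_block: dict[str, list] = {}
    for c in retained:
        truth = truths[c.block_id]
        per_det.append(motifs_detected_per_read(c.slot_calls, truth))
        per_err.append(motif_error_rate([c.slot_calls], [truth]))
        reads_by_block.setdefault(c.block_id, []).append(c.slot_calls)
    curve = recovery_curve(
        reads_by_block, truths, threshold=recovery_threshold, n_perm=n_perm, seed=seed
    )
    return MethodSummary(
        method=method,
        n_reads_total=len(calls),
        n_reads_retained=len(retained),
        motifs_detected_pct=float(np.mean(per_det)) if per_det else 0.0,
        motif_error_pct=motif_error_rate(
            [c.slot_calls for c in retained], [truths[c.block_id] for c in retained]
        )
        if retained
        else None,
        coverage_at_threshold=curve.coverage_at_threshold,
        decoding_accuracy_pct=decoding_accuracy(reads_by_block, truths),
        per_read_detection=per_det,
        per_read_error=per_err,
    )


@dataclass
class StudyScale:
    """Problem sizes of the scaled-down end-to-end study.

    In oracle label mode every training read is labelled
    (``train_blocks * train_coverage`` reads); in faithful mode only the
    top ``label_fraction`` of AM-searched reads survives selection.
    """

    train_blocks: int = 60
    train_coverage: int = 90
    eval_blocks: int = 30
    eval_coverage: int = 20
    label_fraction: float = 0.30
    epochs: int = 12
    batch_size: int = 32
    lr: float = 2e-3
    lr_decay: float = 0.9
    hidden: int = 128
    rnn_layers: int = 2
    conv_filters: tuple = (16, 32, 64, 96)
    fc_size: int = 256


def run_study(
    seed: int = 1,
    scale: StudyScale | None = None,
    log=print,
    label_mode: str = "oracle",
) -> dict:
    """The full scaled-down experiment: simulate, label, train, score.

    One motif library and pore model (the 'chemistry') underlie a training
    run and a disjoint evaluation run.  ``label_mode`` selects the training
    labels: ``"oracle"`` (default here) uses the simulator's per-molecule
    truth with spacer boundary tokens — the controlled mode that isolates
    the caller's learning capability; ``"faithful"`` follows the
    composite-truth procedure (AM search on the training run, reads ranked
    by match fraction, top fraction retained, per-slot calls kept only when
    inside the slot's truth set), which inherits AM label noise and at this
    scale caps token confidence near the 0.85 filter.  Returns summaries
    and per-read calls for caller, AM and ZE on the shared evaluation reads.
    """
    from .labelgen import make_labels, oracle_labels, select_training_reads
    from .simulate import build_pore_model, simulate_run

    scale = scale or StudyScale()
    design = OligoDesign()
    library = random_library(
        n=design.composite_n, l=design.motif_len, min_hamming=10, seed=seed, design=design
    )
    pore = build_pore_model(K=6, seed=seed + 1)
    train_blocks = encode_blocks(scale.train_blocks, design, library, seed=seed + 2)
    eval_blocks = encode_blocks(scale.eval_blocks, design, library, seed=seed + 3)
    train_run = simulate_run(
        train_blocks, library, design, scale.train_coverage, pore=pore, seed=seed + 4
    )
    eval_run = simulate_run(
        eval_blocks, library, design, scale.eval_coverage, pore=pore, seed=seed + 5
    )
    truths_train = {b.block_id: b for b in train_blocks}
    truths_eval = {b.block_id: b for b in eval_blocks}

    if label_mode == "oracle":
        labels = oracle_labels(train_run.signal_reads, design, include_spacers=True)
    elif label_mode == "faithful":
        log("searching training run (AM) for labels...")
        am_train = search_run(train_run, "AM")
        scored = score_against_truth(am_train, truths_train)
        selected = select_training_reads(scored, scale.label_fraction)
        labels = make_labels(
            selected, truths_train, {r.read_id: r for r in train_run.signal_reads}, design,
            include_spacers=True,
        )
    else:
        raise ValueError(f"unknown label_mode {label_mode!r}")
    log(f"training caller on {len(labels)} labelled reads ({label_mode} labels)...")
    cfg = CallerConfig(
        conv_filters=tuple(scale.conv_filters), rnn_layers=scale.rnn_layers,
        hidden=scale.hidden, fc_size=scale.fc_size,
        n_classes=TokenAlphabet.for_design(design, sorted(library.motifs)).n_classes,
        lr=scale.lr, lr_decay=scale.lr_decay, epochs=scale.epochs,
        batch_size=scale.batch_size, seed=seed,
    )
    model, history = train_caller(labels, design, sorted(library.motifs), cfg=cfg)

    log("scoring methods on the evaluation run...")
    ze_calls = search_run(eval_run, "ZE")
    am_calls = search_run(eval_run, "AM")
    caller_calls = decode_run(model, eval_run)
    out = {
        "design": design,
        "library": library,
        "model": model,
        "loss_history": history,
        "truths": truths_eval,
        "eval_run": eval_run,
        "ze_calls": ze_calls,
        "am_calls": am_calls,
        "caller_calls": caller_calls,
        "n_labels": len(labels),
        "n_train_reads": len(train_run.signal_reads),
    }
    for name, calls in (("ze", ze_calls), ("am", am_calls), ("caller", caller_calls)):
        out[f"{name}_summary"] = summarize(name.upper(), calls, truths_eval, seed=seed)
    return out


def train_caller(
    labels: list,
    design: OligoDesign,
    motif_ids: list[str],
    cfg: CallerConfig | None = None,
    reduced: bool = True,
    **cfg_kw,
) -> tuple[MotifCallerModel, list[float]]:
    """Train a caller on (SignalRead, token list) pairs with a design-derived alphabet."""
    alphabet = TokenAlphabet.for_design(design, motif_ids)
    if cfg is None:
        maker = CallerConfig.reduced if reduced else CallerConfig
        cfg = maker(n_classes=alphabet.n_classes, **cfg_kw)
    return train(labels, cfg, alphabet)
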