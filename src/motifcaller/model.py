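"""The Motif Caller network: conv encoder, bidirectional GRU stack, CTC training.

The network maps a raw current trace s = [s_1 .. s_T] directly to a motif
token sequence y = [y_1 .. y_k] with no event segmentation.  A convolutional
encoder downsamples time by exactly 64x (two stride-2 convolutions and two
stride-4 max-pools, interleaved with stride-1 convolutions), a stack of
bidirectional GRUs models temporal context at the frame rate, and a fully
connected head emits per-frame log-probabilities over the token alphabet
plus the CTC blank.  Training minimizes the CTC loss so the alignment
between frames and motifs is learned implicitly.

Defaults follow the full-scale architecture (filters growing 32->128, three
BiGRU layers of hidden size 256, fully connected 512); ``CallerConfig.reduced``
is a smaller preset for desk-scale experiments.
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass

import numpy as np

from .ctc import ctc_loss_grad, ctc_loss_from_logprobs, log_softmax
from .design import OligoDesign
from .nn import Adam, BatchNorm1d, BiGRU, Conv1d, Linear, MaxPool1d, Sequential
from .simulate import SignalRead

__all__ = [
    "TokenAlphabet",
    "CallerConfig",
    "PosteriorMatrix",
    "MotifCallerModel",
    "normalize_signal",
    "ctc_loss",
    "forward",
    "train",
    "finetune",
]

DOWNSAMPLE = 64


@dataclass(frozen=True)
class TokenAlphabet:
    """Ordered token set: motif/spacer tokens followed by the blank.

    The blank always sits at the last index.  Boundary (spacer junction)
    tokens are named ``B<i>``; payload motif ids keep their library names.
    """

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("tokens must be unique")

    @property
    def n_classes(self) -> int:
        return len(self.tokens) + 1

    @property
    def blank(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        return self.tokens.index(token)

    def encode(self, tokens: list[str]) -> np.ndarray:
        try:
            return np.array([self.tokens.index(t) for t in tokens], dtype=np.int64)
        except ValueError as exc:
            raise KeyError(f"token outside alphabet: {exc}") from None

    def decode(self, ids: list[int] | np.ndarray) -> list[str]:
        return [self.tokens[i] for i in ids]

    @classmethod
    def for_design(cls, design: OligoDesign, motif_ids: list[str]) -> "TokenAlphabet":
        """Payload motif tokens plus one boundary token per spacer junction."""
        boundary = [f"B{b}" for b in range(design.n_boundaries)]
        return cls(tokens=tuple(sorted(motif_ids)) + tuple(boundary))


@dataclass
class CallerConfig:
    """Architecture and optimization settings.

    conv_filters grow across the four conv layers; strides realize the
    2*4*2*4 = 64x temporal downsampling.  ``n_classes`` includes the blank.
    """

    conv_filters: tuple[int, int, int, int] = (32, 48, 64, 128)
    kernel: int = 5
    rnn_layers: int = 3
    hidden: int = 256
    fc_size: int = 512
    n_classes: int = 20
    lr: float = 1e-3
    lr_decay: float = 1.0  # multiplicative per-epoch decay
    epochs: int = 10
    batch_size: int = 32
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2 (at least one token plus blank)")

    @classmethod
    def reduced(cls, n_classes: int, **kw) -> "CallerConfig":
        """Desk-scale preset: filters 16->64, two BiGRU layers of hidden 64."""
        defaults = dict(
            conv_filters=(16, 32, 48, 64), rnn_layers=2, hidden=64, fc_size=128,
            n_classes=n_classes,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class PosteriorMatrix:
    """Per-frame log-probabilities over the token alphabet plus blank."""

    log_probs: np.ndarray  # (T_frames, n_classes)
    alphabet: TokenAlphabet

    def __post_init__(self) -> None:
        rows = np.exp(self.log_probs).sum(axis=1)
        if self.log_probs.size and not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("posterior rows must sum to 1")

    @property
    def T_frames(self) -> int:
        return self.log_probs.shape[0]


def normalize_signal(samples: np.ndarray) -> np.ndarray:
    """Median-centre and MAD-scale one read; constant input maps to zeros."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 1:
        raise ValueError("empty signal")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    return (x - med) / mad


def _build_network(cfg: CallerConfig, rng: np.random.Generator) -> Sequential:
    f1, f2, f3, f4 = cfg.conv_filters
    k = cfg.kernel
    # batch-normalized conv blocks, as in production basecaller encoders
    layers = [
        Conv1d(1, f1, k, stride=2, relu=False, rng=rng),
        BatchNorm1d(f1),
        MaxPool1d(4),
        Conv1d(f1, f2, k, stride=1, relu=False, rng=rng),
        BatchNorm1d(f2),
        Conv1d(f2, f3, k, stride=2, relu=False, rng=rng),
        BatchNorm1d(f3),
        MaxPool1d(4),
        Conv1d(f3, f4, k, stride=1, relu=False, rng=rng),
        BatchNorm1d(f4),
    ]
    c = f4
    for _ in range(cfg.rnn_layers):
        layers.append(BiGRU(c, cfg.hidden, rng=rng))
        c = 2 * cfg.hidden
    layers.append(Linear(c, cfg.fc_size, relu=True, rng=rng))
    layers.append(Linear(cfg.fc_size, cfg.n_classes, rng=rng))
    return Sequential(layers)


class MotifCallerModel:
    """Trained (or trainable) caller: network weights plus the token alphabet."""

    def __init__(self, cfg: CallerConfig, alphabet: TokenAlphabet) -> None:
        if alphabet.n_classes != cfg.n_classes:
            raise ValueError("alphabet size does not match cfg.n_classes")
        self.cfg = cfg
        self.alphabet = alphabet
        self.net = _build_network(cfg, np.random.default_rng(cfg.seed))

    # -- inference ---------------------------------------------------------
    def forward_batch(
        self, signals: list[np.ndarray]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Normalized, padded batch forward pass -> (logits (B,F,C), frame lengths)."""
        lengths = np.array([len(s) for s in signals], dtype=np.int64)
        if lengths.min(initial=DOWNSAMPLE) < DOWNSAMPLE:
            raise ValueError(f"reads must have at least {DOWNSAMPLE} samples")
        T = int(-(-lengths.max() // DOWNSAMPLE) * DOWNSAMPLE)
        x = np.zeros((len(signals), T, 1))
        for i, s in enumerate(signals):
            x[i, : len(s), 0] = normalize_signal(s)
        logits, frame_lengths = self.net.forward(x, lengths)
        return logits, frame_lengths

    def posteriors(self, read: SignalRead | np.ndarray) -> PosteriorMatrix:
        samples = read.samples if isinstance(read, SignalRead) else np.asarray(read)
        if len(samples) < DOWNSAMPLE:
            raise ValueError(
                f"read too short: {len(samples)} samples < minimum {DOWNSAMPLE}"
            )
        self.net.eval()
        logits, fl = self.forward_batch([samples])
        return PosteriorMatrix(log_softmax(logits[0, : fl[0]]), self.alphabet)

    # -- persistence -------------------------------------------------------
    SCHEMA_VERSION = 1

    def save(self, path: str) -> None:
        meta = {
            "schema_version": self.SCHEMA_VERSION,
            "config": asdict(self.cfg),
            "tokens": list(self.alphabet.tokens),
        }
        state = self.net.state_dict()
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path: str) -> "MotifCallerModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            if meta.get("schema_version") != cls.SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported checkpoint schema {meta.get('schema_version')!r}"
                )
            cfgd = meta["config"]
            cfgd["conv_filters"] = tuple(cfgd["conv_filters"])
            model = cls(CallerConfig(**cfgd), TokenAlphabet(tuple(meta["tokens"])))
            model.net.load_state_dict({k: archive[k] for k in archive.files if k != "__meta__"})
        return model


def forward(model: MotifCallerModel, signal: np.ndarray | SignalRead) -> PosteriorMatrix:
    """Posterior matrix for one read: shape (floor(T/64), n_classes)."""
    return model.posteriors(signal)


def ctc_loss(posteriors: PosteriorMatrix, label_tokens: list[str]) -> float:
    """-log P(y|s) for a label token sequence under a posterior matrix."""
    ids = posteriors.alphabet.encode(label_tokens)
    return ctc_loss_from_logprobs(posteriors.log_probs, ids, posteriors.alphabet.blank)


TrainingSet = list[tuple[SignalRead, list[str]]]


def _epoch(
    model: MotifCallerModel,
    data: TrainingSet,
    opt: Adam | None,
    rng: np.random.Generator | None,
) -> float:
    """One pass over the data; trains when ``opt`` is given, else evaluates."""
    order = np.arange(len(data))
    if rng is not None:
        rng.shuffle(order)
    bs = model.cfg.batch_size
    total, count = 0.0, 0
    for start in range(0, len(order), bs):
        batch = [data[i] for i in order[start : start + bs]]
        signals = [r.samples for r, _ in batch]
        labels = [model.alphabet.encode(toks) for _, toks in batch]
        logits, fl = model.forward_batch(signals)
        dlogits = np.zeros_like(logits)
        for i, lab in enumerate(labels):
            loss, g = ctc_loss_grad(logits[i, : fl[i]], lab, model.alphabet.blank)
            if not np.isfinite(loss):
                continue  # infeasible label for this frame budget; skipped
            total += loss
            count += 1
            dlogits[i, : fl[i]] = g / len(batch)
        if opt is not None:
            model.net.zero_grad()
            model.net.backward(dlogits)
            opt.step()
    if count == 0:
        raise RuntimeError("no feasible training samples in epoch")
    mean = total / count
    if not np.isfinite(mean):
        raise FloatingPointError("training diverged (non-finite loss)")
    return mean


def train(
    X: TrainingSet,
    cfg: CallerConfig,
    alphabet: TokenAlphabet,
    model: MotifCallerModel | None = None,
    log: list[str] | None = None,
) -> tuple[MotifCallerModel, list[float]]:
    """Train a caller with Adam + CTC; returns the model and per-epoch mean loss.

    Deterministic given ``cfg.seed`` (weight init and shuffling share one
    seeded generator).  Raises on divergence (non-finite loss).
    """
    if not X:
        raise ValueError("empty training set")
    model = model or MotifCallerModel(cfg, alphabet)
    opt = Adam(model.net, lr=cfg.lr, clip_norm=cfg.clip_norm)
    rng = np.random.default_rng(cfg.seed + 1)
    history: list[float] = []
    model.net.train()
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * cfg.lr_decay**epoch
        mean_loss = _epoch(model, X, opt, rng)
        history.append(mean_loss)
        if log is not None:
            log.append(f"epoch={epoch + 1} loss={mean_loss:.4f}")
    model.net.eval()
    return model, history


def finetune(
    model: MotifCallerModel,
    X_new: TrainingSet,
    epochs: int = 15,
    lr: float | None = None,
) -> tuple[MotifCallerModel, list[float]]:
    """Warm-start training on new data with the alphabet held fixed."""
    if epochs == 0:
        return model, []
    for _, toks in X_new:
        for t in toks:
            if t not in model.alphabet.tokens:
                raise ValueError(f"token {t!r} not in the model's alphabet")
    cfg = CallerConfig(**{**asdict(model.cfg), "epochs": epochs, "lr": lr or model.cfg.lr})
    cfg.conv_filters = tuple(cfg.conv_filters)
    return train(X_new, cfg, model.alphabet, model=model)
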