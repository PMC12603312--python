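"""Synthetic nanopore squiggle and basecall simulation.

Stands in for the sequencer plus a production basecaller so the whole
pipeline can be exercised with known ground truth.  A k-mer pore model
assigns each 6-mer a standardized mean current level; a molecule's squiggle
is the concatenation, k-mer by k-mer, of dwell-many noisy samples of that
level.  Reverse-oriented reads are generated from the reverse complement
(a genuinely different k-mer level sequence, as in real pores, not a
time-reversed copy of the forward signal).

Basecalled reads come from an independent substitution/insertion/deletion
error channel with a Phred quality model that scores errors low, so
quality filtering behaves qualitatively like real basecaller output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .design import DNA, InformationBlock, MotifLibrary, OligoDesign, block_to_oligo, revcomp

__all__ = [
    "PoreModel",
    "SimConfig",
    "SignalRead",
    "BasecalledRead",
    "SimulatedRun",
    "build_pore_model",
    "simulate_squiggle",
    "simulate_basecalls",
    "simulate_run",
]


@dataclass
class PoreModel:
    """Mean current level (standardized) and spread per k-mer."""

    K: int
    level: dict[str, float]
    level_sd: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.level) != 4**self.K:
            raise ValueError(f"pore model must cover all 4^{self.K} k-mers")

    def level_array(self) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
        """Vectorized view: (levels, sds, kmer -> row index)."""
        kmers = sorted(self.level)
        idx = {k: i for i, k in enumerate(kmers)}
        lv = np.array([self.level[k] for k in kmers])
        sd = np.array([self.level_sd[k] for k in kmers])
        return lv, sd, idx


@dataclass(frozen=True)
class SimConfig:
    """Squiggle generation parameters.

    dwell_mean
        expected samples per k-mer step (default 8).
    dwell_dispersion
        in [0, 1]: 0 gives a constant dwell of round(dwell_mean); 1 gives a
        pure geometric dwell (support >= 1, CV ~ 1); intermediate values
        shift the geometric component onto a deterministic base so the mean
        stays ``dwell_mean`` while the spread shrinks.  The default 0.7
        (CV ~ 0.7) matches the dwell variability of real pores at this
        sampling rate, which rarely produce sub-2-sample events.
    noise_sd
        Gaussian amplitude noise added on top of the per-k-mer spread.
    event_drop_prob
        probability a k-mer step contributes zero samples (skipped event).
    reverse_fraction
        share of reads simulated from the reverse complement.
    """

    dwell_mean: float = 8.0
    dwell_dispersion: float = 0.7
    noise_sd: float = 0.25
    event_drop_prob: float = 0.01
    reverse_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")
        for p in (self.event_drop_prob, self.reverse_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SignalRead:
    """One raw-signal read with per-molecule truth labels."""

    read_id: str
    samples: np.ndarray
    orientation: str  # "forward" | "reverse"
    block_id: str
    truth: list[str]  # per-slot motif ids, address first, slot order

    @property
    def T(self) -> int:
        return len(self.samples)


@dataclass
class BasecalledRead:
    """One basecalled read (sequencing orientation) with Phred qualities."""

    read_id: str
    seq: str
    quals: np.ndarray  # ints, Phred
    orientation: str
    block_id: str

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError("quality string length must match sequence length")

    @property
    def mean_q(self) -> float:
        return float(np.mean(self.quals)) if len(self.seq) else 0.0


@dataclass
class SimulatedRun:
    """Paired signal + basecalled reads sharing per-molecule truth."""

    signal_reads: list[SignalRead]
    basecalled_reads: list[BasecalledRead]
    blocks: list[InformationBlock]
    library: MotifLibrary
    design: OligoDesign


def build_pore_model(K: int = 6, seed: int = 7, level_sd: float = 0.05) -> PoreModel:
    """Random standardized k-mer level table (zero mean, unit variance)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    kmers = ["".join(p) for p in itertools.product(DNA, repeat=K)]
    levels = rng.normal(size=len(kmers))
    levels = (levels - levels.mean()) / levels.std()
    sds = np.full(len(kmers), level_sd)
    return PoreModel(K=K, level=dict(zip(kmers, levels)), level_sd=dict(zip(kmers, sds)), seed=seed)


def _dwells(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.dwell_dispersion == 0:
        d = np.full(n, int(round(cfg.dwell_mean)))
    else:
        # geometric-like: deterministic base + geometric tail, mean preserved
        base = int(round((1.0 - cfg.dwell_dispersion) * (cfg.dwell_mean - 1)))
        geo_mean = cfg.dwell_mean - base
        d = base + rng.geometric(1.0 / geo_mean, size=n)
    if cfg.event_drop_prob > 0:
        d[rng.random(n) < cfg.event_drop_prob] = 0
    return d


def simulate_squiggle(
    seq: str,
    pore: PoreModel,
    cfg: SimConfig,
    rng: np.random.Generator,
    read_id: str = "read0",
    block_id: str = "",
    truth: list[str] | None = None,
    orientation: str = "forward",
) -> SignalRead:
    """Simulate the raw current trace of one molecule.

    ``seq`` is the forward-strand oligo; reverse-oriented reads transit the
    pore as the reverse complement, so their k-mer level sequence is taken
    from ``revcomp(seq)``.
    """
    if set(seq) - set(DNA):
        raise ValueError("sequence contains non-ACGT characters")
    if len(seq) < pore.K:
        raise ValueError(f"sequence shorter than pore k-mer length {pore.K}")
    oriented = revcomp(seq) if orientation == "reverse" else seq
    lv, sd, idx = pore.level_array()
    n_kmers = len(oriented) - pore.K + 1
    kidx = np.fromiter(
        (idx[oriented[i : i + pore.K]] for i in range(n_kmers)), dtype=np.int64, count=n_kmers
    )
    dwell = _dwells(n_kmers, cfg, rng)
    means = np.repeat(lv[kidx], dwell)
    sds = np.repeat(np.hypot(sd[kidx], cfg.noise_sd), dwell)
    samples = means if sds.max(initial=0.0) == 0 else means + rng.normal(0.0, 1.0, means.size) * sds
    return SignalRead(
        read_id=read_id,
        samples=samples.astype(np.float32),
        orientation=orientation,
        block_id=block_id,
        truth=list(truth or []),
    )


@dataclass(frozen=True)
class QualModel:
    """Phred quality generator: correct bases score high, errors low."""

    correct_mean: float = 20.0
    error_mean: float = 6.0
    sd: float = 3.0
    q_min: int = 2
    q_max: int = 40

    def draw(self, is_error: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        mean = np.where(is_error, self.error_mean, self.correct_mean)
        q = np.rint(mean + rng.normal(0.0, self.sd, size=len(is_error)))
        return np.clip(q, self.q_min, self.q_max).astype(np.int64)


def simulate_basecalls(
    seq: str,
    sub_rate: float = 0.02,
    ins_rate: float = 0.02,
    del_rate: float = 0.06,
    qual_model: QualModel | None = None,
    rng: np.random.Generator | None = None,
    read_id: str = "read0",
    block_id: str = "",
    orientation: str = "forward",
) -> BasecalledRead:
    """Push a sequence through an iid substitution/insertion/deletion channel.

    Each template base is deleted with ``del_rate``, else substituted with
    ``sub_rate``; after each surviving position a random base is inserted
    with ``ins_rate``.  Inserted and substituted bases draw low Phred
    qualities; correct bases draw high ones.
    """
    for r in (sub_rate, ins_rate, del_rate):
        if not 0.0 <= r < 1.0:
            raise ValueError("error rates must lie in [0, 1)")
    if sub_rate + del_rate >= 1.0:
        raise ValueError("sub_rate + del_rate must be < 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    qual_model = qual_model or QualModel()
    out: list[str] = []
    err: list[bool] = []
    other = {b: DNA.replace(b, "") for b in DNA}
    for base in seq:
        u = rng.random()
        if u < del_rate:
            pass
        elif u < del_rate + sub_rate:
            out.append(other[base][int(rng.integers(0, 3))])
            err.append(True)
        else:
            out.append(base)
            err.append(False)
        if rng.random() < ins_rate:
            out.append(DNA[int(rng.integers(0, 4))])
            err.append(True)
    quals = qual_model.draw(np.array(err, dtype=bool), rng) if out else np.array([], dtype=np.int64)
    return BasecalledRead(
        read_id=read_id, seq="".join(out), quals=quals, orientation=orientation, block_id=block_id
    )


@dataclass(frozen=True)
class ErrorRates:
    sub: float = 0.02
    ins: float = 0.02
    dele: float = 0.06


def simulate_run(
    blocks: list[InformationBlock],
    library: MotifLibrary,
    design: OligoDesign,
    coverage: int,
    cfg: SimConfig | None = None,
    error_rates: ErrorRates | None = None,
    pore: PoreModel | None = None,
    seed: int = 0,
) -> SimulatedRun:
    """Simulate a sequencing run: ``coverage`` molecules per block.

    Every molecule is rendered independently via :func:`block_to_oligo`
    (re-sampling the composite mixture), then emitted once as a raw-signal
    read and once as a paired basecalled read sharing the same truth labels
    and orientation.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    cfg = cfg or SimConfig()
    error_rates = error_rates or ErrorRates()
    pore = pore or build_pore_model(seed=seed + 1)
    rng = np.random.default_rng(seed)
    signal_reads: list[SignalRead] = []
    base_reads: list[BasecalledRead] = []
    for block in blocks:
        for i in range(coverage):
            read_id = f"{block.block_id}_r{i:04d}"
            oligo, chosen = block_to_oligo(block, library, design, rng)
            orientation = "reverse" if rng.random() < cfg.reverse_fraction else "forward"
            signal_reads.append(
                simulate_squiggle(
                    oligo, pore, cfg, rng,
                    read_id=read_id, block_id=block.block_id,
                    truth=chosen, orientation=orientation,
                )
            )
            template = revcomp(oligo) if orientation == "reverse" else oligo
            base_reads.append(
                simulate_basecalls(
                    template,
                    sub_rate=error_rates.sub, ins_rate=error_rates.ins, del_rate=error_rates.dele,
                    rng=rng, read_id=read_id, block_id=block.block_id, orientation=orientation,
                )
            )
    return SimulatedRun(
        signal_reads=signal_reads,
        basecalled_reads=base_reads,
        blocks=blocks,
        library=library,
        design=design,
    )
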