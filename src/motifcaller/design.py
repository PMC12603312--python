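"""Motif library, spacer set and combinatorial oligo design.

The storage architecture assembles each DNA molecule from pre-synthesized
25-nt motifs drawn from a small library.  A molecule (one *information
block* rendered once) carries one address motif followed by eight payload
slots; every slot boundary is bridged by two concatenated position-specific
20-nt spacers, so the rendered oligo is 625 nt with the defaults
(9 x 25 motif nt + 10 boundaries x 40 spacer nt).

Information is combinatorial: a payload slot stores a *composite symbol*,
a subset of k motifs chosen from a library of n (4 of 8 by default,
log2 C(8,4) ~ 6.1 bits per slot).  Each physical molecule carries only one
member of each slot's subset, so per-molecule slot content is a sample
from the block's composite ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DNA = "ACGT"

__all__ = [
    "MotifLibrary",
    "OligoDesign",
    "InformationBlock",
    "logical_density",
    "random_library",
    "encode_blocks",
    "block_to_oligo",
    "hamming",
    "revcomp",
]

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def logical_density(n: int, k: int) -> float:
    """Bits of information stored per composite slot: log2 C(n, k).

    A slot holding a k-of-n subset distinguishes C(n, k) symbols, so its
    logical density is the base-2 log of the binomial coefficient.

    >>> round(logical_density(8, 4), 1)
    6.1
    """
    if n < 1 or k < 0 or k > n:
        raise ValueError(f"invalid composite parameters n={n}, k={k}")
    return math.log2(math.comb(n, k))


@dataclass(frozen=True)
class OligoDesign:
    """Slot layout of one oligo.

    ``n_address`` address slots then ``n_payload`` payload slots; every
    boundary between/around slots carries two concatenated position-specific
    spacers of ``spacer_len`` nt each (the two ligation half-spacers of the
    adjacent motifs).
    """

    n_address: int = 1
    n_payload: int = 8
    composite_n: int = 8
    composite_k: int = 4
    motif_len: int = 25
    spacer_len: int = 20

    def __post_init__(self) -> None:
        if self.composite_k > self.composite_n:
            raise ValueError("composite_k must be <= composite_n")
        if self.n_payload < 1:
            raise ValueError("n_payload must be >= 1")

    @property
    def n_slots(self) -> int:
        return self.n_address + self.n_payload

    @property
    def n_boundaries(self) -> int:
        return self.n_slots + 1

    @property
    def n_spacers(self) -> int:
        # two position-specific spacers per boundary
        return 2 * self.n_boundaries

    @property
    def junction_len(self) -> int:
        return 2 * self.spacer_len

    @property
    def oligo_len(self) -> int:
        """Exact rendered length: motifs plus all spacer instances."""
        return self.n_slots * self.motif_len + self.n_spacers * self.spacer_len

    def boundary_start(self, b: int) -> int:
        """0-based start coordinate of junction *b* in a clean oligo."""
        return b * (self.junction_len + self.motif_len)

    def slot_start(self, s: int) -> int:
        """0-based start coordinate of slot *s* (0 = address) in a clean oligo."""
        return self.boundary_start(s) + self.junction_len


@dataclass
class MotifLibrary:
    """The motif set M plus spacers and address motifs.

    ``motifs`` maps payload motif ids to 25-nt sequences, ``spacers`` maps
    spacer cycle positions (two per boundary) to 20-nt sequences and
    ``address_motifs`` maps address ids to 25-nt sequences.
    """

    motifs: dict[str, str]
    spacers: dict[int, str]
    address_motifs: dict[str, str] = field(default_factory=dict)
    min_hamming: int = 0

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.motifs.values()}
        if len(lens) > 1:
            raise ValueError("all payload motifs must have equal length")
        for seq in list(self.motifs.values()) + list(self.spacers.values()) + list(
            self.address_motifs.values()
        ):
            if set(seq) - set(DNA):
                raise ValueError(f"non-ACGT characters in library sequence {seq!r}")
        if self.min_hamming > 0:
            ids = sorted(self.motifs)
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    if hamming(self.motifs[a], self.motifs[b]) < self.min_hamming:
                        raise ValueError(
                            f"motifs {a} and {b} closer than min_hamming={self.min_hamming}"
                        )

    @property
    def motif_len(self) -> int:
        return len(next(iter(self.motifs.values())))

    def junction(self, b: int) -> str:
        """Concatenated spacer pair bridging boundary *b*."""
        return self.spacers[2 * b] + self.spacers[2 * b + 1]

    def junctions(self, design: OligoDesign) -> list[str]:
        return [self.junction(b) for b in range(design.n_boundaries)]


@dataclass
class InformationBlock:
    """Pre-synthesis ground truth of one addressable block.

    ``payload_sets`` holds, per payload slot, the composite k-of-n subset of
    motif ids actually mixed into that slot.
    """

    block_id: str
    address_id: str
    payload_sets: list[frozenset[str]]

    def validate(self, library: MotifLibrary, design: OligoDesign) -> None:
        if len(self.payload_sets) != design.n_payload:
            raise ValueError("payload set count does not match design")
        for s in self.payload_sets:
            if len(s) != design.composite_k:
                raise ValueError("payload set size does not match composite_k")
            unknown = s - set(library.motifs)
            if unknown:
                raise KeyError(f"unknown motif ids {sorted(unknown)}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=length))


def _sample_separated(
    rng: np.random.Generator,
    n: int,
    length: int,
    min_hamming: int,
    max_tries: int = 10_000,
) -> list[str]:
    """Rejection-sample ``n`` sequences with pairwise Hamming >= min_hamming."""
    out: list[str] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} sequences of length {length} with "
                f"pairwise Hamming >= {min_hamming} in {max_tries} draws"
            )
        cand = _random_seq(rng, length)
        if all(hamming(cand, prev) >= min_hamming for prev in out):
            out.append(cand)
    return out


def random_library(
    n: int = 8,
    l: int = 25,
    min_hamming: int = 10,
    seed: int = 0,
    design: OligoDesign | None = None,
    n_address_motifs: int = 4,
) -> MotifLibrary:
    """Generate a random motif library satisfying a minimum pairwise distance.

    Payload and address motifs (length ``l``) share one distance pool;
    spacers (length ``design.spacer_len``) satisfy the same constraint among
    themselves, scaled to their length.  Deterministic given ``seed``.
    """
    if min_hamming > l:
        raise ValueError("min_hamming cannot exceed motif length")
    design = design or OligoDesign(motif_len=l)
    rng = np.random.default_rng(seed)
    motif_pool = _sample_separated(rng, n + n_address_motifs, l, min_hamming)
    # spacers obey the same separation, rescaled to their length and capped
    # at half of it so the constraint stays satisfiable by rejection sampling
    spacer_min = min(min_hamming * design.spacer_len // max(l, 1), design.spacer_len // 2)
    spacer_pool = _sample_separated(rng, design.n_spacers, design.spacer_len, spacer_min)
    return MotifLibrary(
        motifs={f"M{i}": s for i, s in enumerate(motif_pool[:n])},
        address_motifs={f"A{i}": s for i, s in enumerate(motif_pool[n:])},
        spacers=dict(enumerate(spacer_pool)),
        min_hamming=min_hamming,
    )


def encode_blocks(
    n_blocks: int,
    design: OligoDesign,
    library: MotifLibrary,
    seed: int = 0,
) -> list[InformationBlock]:
    """Draw ``n_blocks`` random information blocks (uniform composite symbols)."""
    if len(library.motifs) != design.composite_n:
        raise ValueError("library size does not match design.composite_n")
    rng = np.random.default_rng(seed)
    motif_ids = sorted(library.motifs)
    address_ids = sorted(library.address_motifs) or [""]
    blocks = []
    for i in range(n_blocks):
        sets = [
            frozenset(rng.choice(motif_ids, size=design.composite_k, replace=False))
            for _ in range(design.n_payload)
        ]
        blocks.append(
            InformationBlock(
                block_id=f"b{i:05d}",
                address_id=str(rng.choice(address_ids)),
                payload_sets=sets,
            )
        )
    return blocks


def block_to_oligo(
    block: InformationBlock,
    library: MotifLibrary,
    design: OligoDesign,
    rng: np.random.Generator,
) -> tuple[str, list[str]]:
    """Render one molecule of a block.

    For each payload slot one motif is drawn uniformly from the slot's
    composite set (each molecule carries a single member of the mixture).
    Returns the full oligo sequence and the per-slot chosen motif ids
    (address id first when the design has an address slot) — the
    per-molecule truth labels.
    """
    block.validate(library, design)
    chosen: list[str] = []
    slot_seqs: list[str] = []
    for a in range(design.n_address):
        if block.address_id not in library.address_motifs:
            raise KeyError(f"unknown address id {block.address_id!r}")
        chosen.append(block.address_id)
        slot_seqs.append(library.address_motifs[block.address_id])
    for payload_set in block.payload_sets:
        members = sorted(payload_set)
        pick = members[int(rng.integers(0, len(members)))]
        chosen.append(pick)
        slot_seqs.append(library.motifs[pick])
    parts = []
    for s, seq in enumerate(slot_seqs):
        parts.append(library.junction(s))
        parts.append(seq)
    parts.append(library.junction(design.n_slots))
    oligo = "".join(parts)
    assert len(oligo) == design.oligo_len
    return oligo, chosen
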