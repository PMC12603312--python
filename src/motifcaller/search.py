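"""Motif search on basecalled reads: the Zero-Error and Approximate-Matching baselines.

Zero-Error (ZE) search calls a payload slot only when the entire 25-nt motif
occurs verbatim in the basecalled read, so any basecall error inside a motif
suppresses the call.  Approximate-Matching (AM) search tolerates indels: it
seeds candidate spacer-junction positions with a k-mer index, chains them
according to the expected motif/spacer layout, locally aligns the segments
between chained junctions against the motif library, and resolves
overlapping chains by mapping score.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from statistics import median

from Bio import Align

from .design import MotifLibrary, OligoDesign, hamming, revcomp
from .simulate import BasecalledRead

__all__ = [
    "AMParams",
    "SpacerHit",
    "Chain",
    "SearchResult",
    "ze_search",
    "build_spacer_index",
    "find_spacer_candidates",
    "chain_spacers",
    "map_segments",
    "resolve_overlaps",
    "am_search",
]


@dataclass(frozen=True)
class AMParams:
    """Tuning knobs of the AM pipeline (all coordinates 0-based, half-open)."""

    seed_k: int = 8           # k-mer seed length into the junction index
    min_seeds: int = 2        # weak-candidate filter (non-overlapping seeds)
    merge_radius: int = 5     # merge nearby implied junction starts
    refine_window: int = 8    # +- window of the Hamming position refinement
    indel_tolerance: int = 6  # allowed deviation from design spacing per link
    min_chain_len: int = 2    # minimum junctions per chain
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_map_score_frac: float = 0.6  # fraction of the perfect-segment score
    segment_slack: int = 6    # extra bases around extrapolated end segments


@dataclass(frozen=True)
class SpacerHit:
    """One located spacer junction: read start position and boundary index."""

    read_position: int
    cycle_position: int
    score: float
    strand: str = "forward"


@dataclass
class Chain:
    """Consecutive junction hits following the designed layout."""

    hits: list[SpacerHit]
    segments: list[tuple[int, int, int]]  # (slot_index, start, end) half-open
    total_score: float = 0.0
    mapping_score: float = 0.0

    @property
    def interval(self) -> tuple[int, int]:
        starts = [h.read_position for h in self.hits] + [s for _, s, _ in self.segments]
        ends = [e for _, _, e in self.segments] + [h.read_position for h in self.hits]
        return min(starts), max(ends)


@dataclass
class SearchResult:
    """Per-payload-slot motif calls for one read."""

    read_id: str
    method: str  # "ZE" | "AM"
    strand: str  # "forward" | "reverse"
    slot_calls: list[str | None]
    slot_scores: list[float | None]
    address_call: str | None = None

    @property
    def n_called(self) -> int:
        return sum(c is not None for c in self.slot_calls)


def _empty_result(read_id: str, method: str, design: OligoDesign) -> SearchResult:
    return SearchResult(
        read_id=read_id,
        method=method,
        strand="forward",
        slot_calls=[None] * design.n_payload,
        slot_scores=[None] * design.n_payload,
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _slot_spacing(design: OligoDesign) -> int:
    return design.junction_len + design.motif_len


def _ze_one_strand(
    seq: str, library: MotifLibrary, design: OligoDesign, tol: int = 12
) -> tuple[dict[int, str], str | None]:
    """Exact-match slot calls on one oriented read sequence."""
    spacing = _slot_spacing(design)
    junction_occ: list[tuple[int, int]] = []  # (boundary, read position)
    for b in range(design.n_boundaries):
        for p in _find_all(seq, library.junction(b)):
            junction_occ.append((b, p))

    def assign_slot(p: int) -> int | None:
        """Slot index for a motif occurrence starting at read position p."""
        if junction_occ:
            b, jp = min(junction_occ, key=lambda bj: abs(p - bj[1]))
            k = round((p - jp - design.junction_len) / spacing)
            resid = abs(p - jp - design.junction_len - k * spacing)
            slot = b + k
        else:
            slot = round((p - design.junction_len) / spacing)
            resid = abs(p - design.junction_len - slot * spacing)
        if resid > tol or not 0 <= slot < design.n_slots:
            return None
        return slot

    calls: dict[int, str] = {}
    address: str | None = None
    pools = [(library.motifs, False)]
    if design.n_address:
        pools.append((library.address_motifs, True))
    for pool, is_address in pools:
        for motif_id, motif_seq in pool.items():
            for p in _find_all(seq, motif_seq):
                slot = assign_slot(p)
                if slot is None:
                    continue
                if is_address:
                    if slot < design.n_address:
                        address = motif_id
                elif slot >= design.n_address:
                    calls.setdefault(slot - design.n_address, motif_id)
    return calls, address


def ze_search(read: BasecalledRead, library: MotifLibrary, design: OligoDesign) -> SearchResult:
    """Zero-Error search: a slot is called only on a verbatim full-motif match.

    Both orientations are tried; the orientation calling more slots wins,
    ties break toward forward.  Slot assignment uses exact junction matches
    as coordinate anchors, falling back to the expected layout coordinates.
    """
    result = _empty_result(read.read_id, "ZE", design)
    if not read.seq:
        return result
    best: tuple[int, int] | None = None  # (n_called, strand_pref)
    for strand, seq in (("forward", read.seq), ("reverse", revcomp(read.seq))):
        calls, address = _ze_one_strand(seq, library, design)
        key = (len(calls) + (address is not None), strand == "forward")
        if best is None or key > best:
            best = key
            result.strand = strand
            result.address_call = address
            result.slot_calls = [calls.get(i) for i in range(design.n_payload)]
            result.slot_scores = [1.0 if calls.get(i) else None for i in range(design.n_payload)]
    return result


def build_spacer_index(
    spacers: dict[int, str], k: int = 8
) -> dict[str, list[tuple[int, int]]]:
    """Index every k-mer of every spacer junction as (cycle_position, offset)."""
    if any(k > len(s) for s in spacers.values()):
        raise ValueError("seed length k exceeds a spacer length")
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for cycle, seq in spacers.items():
        for off in range(len(seq) - k + 1):
            index[seq[off : off + k]].append((cycle, off))
    return dict(index)


def find_spacer_candidates(
    seq: str,
    index: dict[str, list[tuple[int, int]]],
    spacers: dict[int, str],
    params: AMParams = AMParams(),
    strand: str = "forward",
) -> list[SpacerHit]:
    """Seed, filter, merge and refine candidate junction positions.

    Seeds are grouped by the junction start they imply (hit position minus
    offset); groups supported by fewer than ``min_seeds`` non-overlapping
    seeds are dropped (overlapping seeds are one chance match, not
    independent evidence), groups within ``merge_radius`` are merged, and
    each survivor's position is refined by a +-``refine_window`` Hamming
    scan against the full junction sequence.
    """
    k = params.seed_k
    implied: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        for cycle, off in index.get(seq[i : i + k], ()):
            implied[cycle].append((i - off, i))
    hits: list[SpacerHit] = []
    for cycle, seeds in implied.items():
        spacer = spacers[cycle]
        L = len(spacer)
        seeds.sort()
        clusters: list[list[tuple[int, int]]] = []
        for s in seeds:
            if clusters and s[0] - clusters[-1][-1][0] <= params.merge_radius:
                clusters[-1].append(s)
            else:
                clusters.append([s])
        for cl in clusters:
            support, last = 0, -(10**9)
            for _, read_pos in sorted(cl, key=lambda t: t[1]):
                if read_pos >= last + k:
                    support += 1
                    last = read_pos
            if support < params.min_seeds:
                continue
            pos = int(median(s for s, _ in cl))
            best = None  # (hamming, |d|, d)
            for d in range(-params.refine_window, params.refine_window + 1):
                p = pos + d
                if p < 0 or p + L > len(seq):
                    continue
                h = hamming(seq[p : p + L], spacer)
                cand = (h, abs(d), d)
                if best is None or cand < best:
                    best = cand
            if best is None:
                continue
            h, _, d = best
            hits.append(
                SpacerHit(
                    read_position=pos + d,
                    cycle_position=cycle,
                    score=1.0 - h / L,
                    strand=strand,
                )
            )
    hits.sort(key=lambda h: (h.read_position, h.cycle_position))
    return hits


def chain_spacers(
    hits: list[SpacerHit],
    design: OligoDesign,
    params: AMParams = AMParams(),
) -> list[Chain]:
    """Longest-chain DP over junction hits following the designed spacing.

    Links require the boundary index to increase by exactly 1 and the
    positional gap to match junction+motif spacing within
    ``indel_tolerance``.  All maximal chains of at least ``min_chain_len``
    hits are returned, each with its implied payload segments, including one
    extrapolated segment beyond each chain end.
    """
    n = len(hits)
    if n == 0:
        return []
    spacing = _slot_spacing(design)
    order = sorted(range(n), key=lambda i: hits[i].read_position)
    length = [1] * n
    score = [hits[i].score for i in range(n)]
    parent = [-1] * n
    for oi, i in enumerate(order):
        for j in order[:oi]:
            if hits[i].cycle_position != hits[j].cycle_position + 1:
                continue
            gap = hits[i].read_position - hits[j].read_position
            if abs(gap - spacing) > params.indel_tolerance:
                continue
            if (length[j] + 1, score[j] + hits[i].score) > (length[i], score[i]):
                length[i] = length[j] + 1
                score[i] = score[j] + hits[i].score
                parent[i] = j
    used = [False] * n
    chains: list[Chain] = []
    for i in sorted(range(n), key=lambda i: -length[i]):
        if used[i] or length[i] < params.min_chain_len:
            continue
        path = []
        j = i
        while j != -1:
            path.append(j)
            j = parent[j]
        if any(used[j] for j in path):
            continue
        for j in path:
            used[j] = True
        path.reverse()
        chain_hits = [hits[j] for j in path]
        chains.append(_make_chain(chain_hits, design, params))
    chains.sort(key=lambda c: c.interval)
    return chains


def _make_chain(chain_hits: list[SpacerHit], design: OligoDesign, params: AMParams) -> Chain:
    jl = design.junction_len
    segments: list[tuple[int, int, int]] = []
    first, last = chain_hits[0], chain_hits[-1]
    if first.cycle_position > 0:  # extrapolate one slot before the chain
        start = max(0, first.read_position - design.motif_len - params.segment_slack)
        segments.append((first.cycle_position - 1, start, first.read_position))
    for a, b in zip(chain_hits, chain_hits[1:]):
        segments.append((a.cycle_position, a.read_position + jl, b.read_position))
    if last.cycle_position < design.n_slots:  # extrapolate one slot after
        start = last.read_position + jl
        segments.append((last.cycle_position, start, start + design.motif_len + params.segment_slack))
    return Chain(hits=chain_hits, segments=segments, total_score=sum(h.score for h in chain_hits))


def make_aligner(params: AMParams = AMParams()) -> Align.PairwiseAligner:
    """Affine-gap local aligner with the pipeline's scoring scheme."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def map_segments(
    seq: str,
    chain: Chain,
    library: MotifLibrary,
    design: OligoDesign,
    params: AMParams = AMParams(),
    aligner: Align.PairwiseAligner | None = None,
) -> SearchResult:
    """Locally align each inter-junction segment against the motif library.

    The best-scoring motif is called for a slot when its local alignment
    score reaches ``min_map_score_frac`` of the perfect-match score;
    degenerate (empty) segments stay blank.  The chain's ``mapping_score``
    accumulates the called slots' scores.
    """
    aligner = aligner or make_aligner(params)
    result = _empty_result("", "AM", design)
    min_score = params.min_map_score_frac * params.match * design.motif_len
    total = 0.0
    for slot, a, b in chain.segments:
        a, b = max(0, a), min(len(seq), b)
        if b <= a:
            continue
        seg = seq[a:b]
        pool = library.motifs if slot >= design.n_address else library.address_motifs
        best_id, best_score = None, -1.0
        for motif_id in sorted(pool):
            s = aligner.score(seg, pool[motif_id])
            if s > best_score:
                best_id, best_score = motif_id, s
        if best_id is None or best_score < min_score:
            continue
        total += best_score
        if slot < design.n_address:
            result.address_call = best_id
        else:
            p = slot - design.n_address
            if result.slot_scores[p] is None or best_score > result.slot_scores[p]:
                result.slot_calls[p] = best_id
                result.slot_scores[p] = best_score
    chain.mapping_score = total
    return result


def resolve_overlaps(
    chains_with_results: list[tuple[Chain, SearchResult]],
    design: OligoDesign,
) -> tuple[SearchResult, list[Chain]]:
    """Keep the highest-mapping-score chain in every overlap group.

    Chains whose read intervals overlap are grouped transitively; the argmax
    chain of each group survives, so every read base belongs to at most one
    chain.  Surviving (disjoint) chains' calls are merged into one result.
    """
    merged = _empty_result("", "AM", design)
    if not chains_with_results:
        return merged, []
    entries = sorted(chains_with_results, key=lambda cr: cr[0].interval)
    groups: list[list[tuple[Chain, SearchResult]]] = []
    group_end = -1
    for chain, res in entries:
        a, b = chain.interval
        if groups and a < group_end:
            groups[-1].append((chain, res))
            group_end = max(group_end, b)
        else:
            groups.append([(chain, res)])
            group_end = b
    survivors: list[Chain] = []
    for group in groups:
        chain, res = max(group, key=lambda cr: cr[0].mapping_score)
        survivors.append(chain)
        for p in range(design.n_payload):
            if res.slot_calls[p] is not None and (
                merged.slot_scores[p] is None or res.slot_scores[p] > merged.slot_scores[p]
            ):
                merged.slot_calls[p] = res.slot_calls[p]
                merged.slot_scores[p] = res.slot_scores[p]
        if res.address_call is not None:
            merged.address_call = res.address_call
    return merged, survivors


def am_search(
    read: BasecalledRead,
    library: MotifLibrary,
    design: OligoDesign,
    params: AMParams = AMParams(),
    index: dict[str, list[tuple[int, int]]] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> SearchResult:
    """Approximate-Matching search: seed -> chain -> map -> resolve.

    Both orientations are evaluated end to end; the orientation with the
    higher total mapping score wins, ties break toward forward.
    """
    junctions = {b: library.junction(b) for b in range(design.n_boundaries)}
    if index is None:
        index = build_spacer_index(junctions, params.seed_k)
    aligner = aligner or make_aligner(params)
    best: SearchResult | None = None
    best_key: tuple[float, bool] | None = None
    for strand, seq in (("forward", read.seq), ("reverse", revcomp(read.seq))):
        hits = find_spacer_candidates(seq, index, junctions, params, strand=strand)
        chains = chain_spacers(hits, design, params)
        mapped = [(c, map_segments(seq, c, library, design, params, aligner)) for c in chains]
        merged, survivors = resolve_overlaps(mapped, design)
        total = sum(c.mapping_score for c in survivors)
        key = (total, strand == "forward")
        if best_key is None or key > best_key:
            best_key = key
            merged.read_id = read.read_id
            merged.strand = strand
            best = merged
    assert best is not None
    return best
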