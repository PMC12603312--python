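"""ZE and AM search: exactness, seeding/chaining/mapping, overlap resolution."""

import numpy as np
import pytest

from motifcaller.design import block_to_oligo, revcomp
from motifcaller.search import (
    AMParams,
    SpacerHit,
    am_search,
    build_spacer_index,
    chain_spacers,
    find_spacer_candidates,
    make_aligner,
    map_segments,
    resolve_overlaps,
    ze_search,
)
from motifcaller.simulate import BasecalledRead, simulate_basecalls


def _clean_read(block, library, design, seed=0, read_id="r0"):
    seq, chosen = block_to_oligo(block, library, design, np.random.default_rng(seed))
    quals = np.full(len(seq), 30, dtype=np.int64)
    return (
        BasecalledRead(read_id=read_id, seq=seq, quals=quals, orientation="forward", block_id=block.block_id),
        chosen,
    )


def brute_affine_local(a: str, b: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2) -> float:
    """Independent affine-gap Smith-Waterman (Gotoh) in plain python."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestZESearch:
    def test_error_free_read_full_recovery(self, blocks, library, design):
        read, chosen = _clean_read(blocks[0], library, design)
        result = ze_search(read, library, design)
        assert result.slot_calls == chosen[design.n_address :]
        assert result.n_called == design.n_payload

    def test_single_substitution_blanks_only_that_slot(self, blocks, library, design):
        read, chosen = _clean_read(blocks[0], library, design)
        slot = 3  # payload slot index
        pos = design.slot_start(design.n_address + slot) + 12
        base = read.seq[pos]
        other = "ACGT".replace(base, "")[0]
        mutated = read.seq[:pos] + other + read.seq[pos + 1 :]
        result = ze_search(
            BasecalledRead("r1", mutated, np.full(len(mutated), 30, dtype=np.int64), "forward", ""),
            library, design,
        )
        expected = chosen[design.n_address :]
        assert result.slot_calls[slot] is None
        for p in range(design.n_payload):
            if p != slot:
                assert result.slot_calls[p] == expected[p]

    def test_empty_read_all_blank(self, library, design):
        read = BasecalledRead("r", "", np.array([], dtype=np.int64), "forward", "")
        result = ze_search(read, library, design)
        assert result.n_called == 0

    def test_reverse_complement_read_recovered(self, blocks, library, design):
        read, chosen = _clean_read(blocks[1], library, design)
        rc = BasecalledRead("r", revcomp(read.seq), read.quals[::-1], "reverse", "")
        result = ze_search(rc, library, design)
        assert result.strand == "reverse"
        assert result.slot_calls == chosen[design.n_address :]


class TestSpacerIndex:
    def test_counts_by_enumeration(self, library):
        spacers = {i: library.spacers[i] for i in range(9)}  # 9 spacers, length 20
        index = build_spacer_index(spacers, k=8)
        postings = sum(len(v) for v in index.values())
        assert postings == 9 * (20 - 8 + 1)  # minus collisions (none expected here)

    def test_k_equals_length_single_entry_each(self, library):
        spacers = {i: library.spacers[i] for i in range(5)}
        index = build_spacer_index(spacers, k=20)
        assert sum(len(v) for v in index.values()) == 5

    def test_duplicate_kmers_share_posting_list(self):
        index = build_spacer_index({0: "AAAATTTT", 1: "AAAACCCC"}, k=4)
        assert len(index["AAAA"]) == 2

    def test_k_longer_than_spacer_rejected(self):
        with pytest.raises(ValueError):
            build_spacer_index({0: "ACGT"}, k=8)


class TestFindSpacerCandidates:
    def test_clean_read_hits_exact_positions(self, blocks, library, design):
        read, _ = _clean_read(blocks[2], library, design)
        junctions = {b: library.junction(b) for b in range(design.n_boundaries)}
        index = build_spacer_index(junctions, 8)
        hits = find_spacer_candidates(read.seq, index, junctions)
        positions = {h.cycle_position: h.read_position for h in hits}
        for b in range(design.n_boundaries):
            assert positions[b] == design.boundary_start(b)
            assert all(h.score == 1.0 for h in hits)

    def test_random_sequence_yields_no_hits(self, library, design):
        junctions = {b: library.junction(b) for b in range(design.n_boundaries)}
        index = build_spacer_index(junctions, 8)
        rng = np.random.default_rng(3)
        reads_with_hits = 0
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=625))
            reads_with_hits += bool(find_spacer_candidates(seq, index, junctions))
        # empty with probability ~1 per read; isolated chance hits cannot
        # chain anyway (min_chain_len = 2)
        assert reads_with_hits <= 2

    def test_nearby_seed_groups_merge(self):
        spacer = "ACGTACGTACGTACGTACGT"
        junctions = {0: spacer}
        index = build_spacer_index(junctions, 8)
        seq = "TTTTT" + spacer + "TTTTT"
        hits = find_spacer_candidates(seq, index, junctions, AMParams(merge_radius=5, min_seeds=2))
        # periodic spacer seeds imply starts 4 apart; they merge into one hit
        assert len(hits) == 1 and hits[0].read_position == 5


class TestChainSpacers:
    def _perfect_hits(self, design, n=None):
        spacing = design.junction_len + design.motif_len
        n = n or design.n_boundaries
        return [SpacerHit(b * spacing, b, 1.0) for b in range(n)]

    def test_perfect_hits_single_full_chain(self, design):
        chains = chain_spacers(self._perfect_hits(design), design)
        assert len(chains) == 1
        assert len(chains[0].hits) == design.n_boundaries

    def test_stretched_gap_within_tolerance(self, design):
        hits = self._perfect_hits(design)
        hits = [
            SpacerHit(h.read_position + (4 if h.cycle_position >= 5 else 0), h.cycle_position, 1.0)
            for h in hits
        ]
        chains = chain_spacers(hits, design, AMParams(indel_tolerance=6))
        assert len(chains) == 1 and len(chains[0].hits) == design.n_boundaries

    def test_gap_beyond_tolerance_splits_chain(self, design):
        hits = self._perfect_hits(design)
        hits = [
            SpacerHit(h.read_position + (30 if h.cycle_position >= 5 else 0), h.cycle_position, 1.0)
            for h in hits
        ]
        chains = chain_spacers(hits, design, AMParams(indel_tolerance=6))
        assert len(chains) == 2

    def test_chimeric_concatemer_gives_two_chains(self, design):
        spacing = design.junction_len + design.motif_len
        offset = design.oligo_len + 10
        hits = self._perfect_hits(design) + [
            SpacerHit(offset + b * spacing, b, 1.0) for b in range(design.n_boundaries)
        ]
        chains = chain_spacers(sorted(hits, key=lambda h: h.read_position), design)
        assert len(chains) == 2

    def test_segments_cover_all_slots(self, design):
        chains = chain_spacers(self._perfect_hits(design), design)
        slots = {s for s, _, _ in chains[0].segments}
        assert slots == set(range(design.n_slots))


class TestMapSegments:
    def test_clean_segments_maximal_scores(self, blocks, library, design):
        read, chosen = _clean_read(blocks[3], library, design)
        junctions = {b: library.junction(b) for b in range(design.n_boundaries)}
        index = build_spacer_index(junctions, 8)
        hits = find_spacer_candidates(read.seq, index, junctions)
        chains = chain_spacers(hits, design)
        result = map_segments(read.seq, chains[0], library, design)
        assert result.slot_calls == chosen[design.n_address :]
        assert all(s == 2 * 25 for s in result.slot_scores)

    def test_agrees_with_brute_force_alignment(self, library, rng):
        """PairwiseAligner scores equal an independent Gotoh implementation."""
        motifs = list(library.motifs.values())
        aligner = make_aligner()
        for _ in range(60):
            seg = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 40))))
            for motif in motifs[:3]:
                assert aligner.score(seg, motif) == pytest.approx(
                    brute_affine_local(seg, motif)
                )

    def test_single_deletion_still_maps_correct_motif(self, blocks, library, design, rng):
        read, chosen = _clean_read(blocks[4], library, design)
        junctions = {b: library.junction(b) for b in range(design.n_boundaries)}
        chains = chain_spacers(
            find_spacer_candidates(read.seq, build_spacer_index(junctions, 8), junctions),
            design,
        )
        # delete one base inside payload slot 2
        pos = design.slot_start(design.n_address + 2) + 10
        mutated = read.seq[:pos] + read.seq[pos + 1 :]
        chains2 = chain_spacers(
            find_spacer_candidates(mutated, build_spacer_index(junctions, 8), junctions),
            design,
        )
        result = map_segments(mutated, chains2[0], library, design)
        assert result.slot_calls[2] == chosen[design.n_address + 2]

    def test_random_segment_stays_blank(self, library, design, rng):
        from motifcaller.search import Chain

        blanks = 0
        for _ in range(30):
            seg = "".join(rng.choice(list("ACGT"), size=25))
            chain = Chain(hits=[SpacerHit(0, 1, 1.0)], segments=[(1, 0, 25)])
            result = map_segments(seg, chain, library, design)
            blanks += result.slot_calls[0] is None
        assert blanks >= 28  # random 25-mers rarely reach 60% of the perfect score


class TestResolveOverlaps:
    def _chain(self, a, b, score):
        from motifcaller.search import Chain

        c = Chain(hits=[SpacerHit(a, 0, 1.0)], segments=[(1, a, b)])
        c.mapping_score = score
        return c

    def _result(self, design, call="M0"):
        from motifcaller.search import SearchResult

        calls = [None] * design.n_payload
        scores = [None] * design.n_payload
        calls[0], scores[0] = call, 50.0
        return SearchResult("r", "AM", "forward", calls, scores)

    def test_higher_score_chain_wins(self, design):
        entries = [
            (self._chain(0, 100, 40.0), self._result(design, "M1")),
            (self._chain(50, 150, 55.0), self._result(design, "M2")),
        ]
        merged, survivors = resolve_overlaps(entries, design)
        assert len(survivors) == 1 and merged.slot_calls[0] == "M2"

    def test_disjoint_chains_both_retained(self, design):
        entries = [
            (self._chain(0, 100, 40.0), self._result(design, "M1")),
            (self._chain(200, 300, 30.0), self._result(design, "M2")),
        ]
        _, survivors = resolve_overlaps(entries, design)
        assert len(survivors) == 2

    def test_three_mutual_overlaps_keep_one(self, design):
        entries = [
            (self._chain(0, 100, 40.0), self._result(design)),
            (self._chain(10, 110, 70.0), self._result(design)),
            (self._chain(20, 120, 60.0), self._result(design)),
        ]
        _, survivors = resolve_overlaps(entries, design)
        assert len(survivors) == 1 and survivors[0].mapping_score == 70.0

    def test_survivor_intervals_disjoint(self, design, rng):
        entries = []
        for _ in range(20):
            a = int(rng.integers(0, 500))
            entries.append((self._chain(a, a + int(rng.integers(20, 120)), float(rng.random())), self._result(design)))
        _, survivors = resolve_overlaps(entries, design)
        ivs = sorted(c.interval for c in survivors)
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            assert b1 <= a2


class TestAMSearch:
    def test_clean_read_full_recovery(self, blocks, library, design):
        read, chosen = _clean_read(blocks[5], library, design)
        result = am_search(read, library, design)
        assert result.slot_calls == chosen[design.n_address :]

    def test_reverse_complement_clean_read(self, blocks, library, design):
        read, chosen = _clean_read(blocks[6], library, design)
        rc = BasecalledRead("r", revcomp(read.seq), read.quals[::-1], "reverse", "")
        result = am_search(rc, library, design)
        assert result.strand == "reverse"
        assert result.slot_calls == chosen[design.n_address :]

    def test_am_beats_ze_under_error_channel(self, blocks, library, design):
        """Paired per-read detection: AM >= ZE nearly always, strictly better in sum."""
        rng = np.random.default_rng(8)
        am_total = ze_total = 0
        pairs_ge = n = 0
        for i in range(60):
            block = blocks[i % len(blocks)]
            seq, chosen = block_to_oligo(block, library, design, rng)
            read = simulate_basecalls(seq, 0.02, 0.02, 0.06, rng=rng, read_id=f"r{i}")
            truth = chosen[design.n_address :]
            am = am_search(read, library, design)
            ze = ze_search(read, library, design)
            am_n = sum(c == t for c, t in zip(am.slot_calls, truth))
            ze_n = sum(c == t for c, t in zip(ze.slot_calls, truth))
            am_total += am_n
            ze_total += ze_n
            pairs_ge += am_n >= ze_n
            n += 1
        assert am_total > ze_total
        assert pairs_ge / n >= 0.95
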