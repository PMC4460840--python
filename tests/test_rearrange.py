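"""Gene-order algebra: adjacencies, event classification, shared blocks."""

import itertools
import random
from collections import deque

import pytest

from mitofrag import thrips
from mitofrag.genome import ValidationError, rotate_chromosome, Chromosome, MitoGenome
from mitofrag.rearrange import (GeneOrder, RearrangementEvent, adjacency_set,
                                base, classify_events, dedup_paralogs,
                                extract_order, flip, shared_blocks)


def order_of(*genes, cid="chr", circular=True, anchor=None):
    return GeneOrder(chromosomes=((cid, tuple(genes)),),
                     anchor=anchor or base(genes[0]), circular=circular)


def event_signature(events):
    return sorted((e.kind, tuple(sorted(e.genes)), tuple(sorted(e.duplicated)))
                  for e in events)


def bfs_min_events(start: GeneOrder, goal: GeneOrder, max_depth=3) -> int:
    """Exhaustive search over single-gene inversions and translocations.

    Independent oracle for the minimal event count on toy circular orders;
    states are compared as anchored signed tuples.
    """
    def canon(genes):
        names = [base(t) for t in genes]
        i = names.index(min(names))
        rot = genes[i:] + genes[:i]
        return tuple(rot)

    s0 = canon(start.chromosomes[0][1])
    target = canon(goal.chromosomes[0][1])
    if s0 == target:
        return 0
    seen = {s0}
    frontier = deque([(s0, 0)])
    while frontier:
        state, depth = frontier.popleft()
        if depth == max_depth:
            continue
        n = len(state)
        moves = []
        for i in range(n):  # single-gene inversion
            moves.append(state[:i] + (flip(state[i]),) + state[i + 1:])
        for i in range(n):  # single-gene translocation
            rest = state[:i] + state[i + 1:]
            for j in range(len(rest) + 1):
                if j != i:
                    moves.append(rest[:j] + (state[i],) + rest[j:])
        for m in moves:
            c = canon(m)
            if c == target:
                return depth + 1
            if c not in seen:
                seen.add(c)
                frontier.append((c, depth + 1))
    raise AssertionError("goal unreachable within max_depth")


class TestExtractOrder:
    def test_anchor_first_and_positive(self, ancestor):
        order = extract_order(ancestor)
        genes = order.chromosomes[0][1]
        assert genes[0] == "cox1"

    def test_rotation_invariance(self, ancestor):
        chrom = ancestor.chromosomes[0]
        rotated = MitoGenome(label="rot", chromosomes=(
            rotate_chromosome(chrom, 1000),))
        assert extract_order(rotated).chromosomes[0][1] == \
            extract_order(ancestor).chromosomes[0][1]

    def test_flipped_chromosome_normalizes(self, ancestor):
        # reverse-complementing the whole record must yield the same order
        from mitofrag.genome import SequenceRecord, GeneFeature, reverse_complement
        chrom = ancestor.chromosomes[0]
        n = len(chrom.record)
        rc_rec = SequenceRecord(id="rc", residues=reverse_complement(
            chrom.record.residues), topology="circular")
        rc_feats = tuple(GeneFeature(name=f.name, kind=f.kind,
                                     strand="N" if f.strand == "J" else "J",
                                     start=n - f.end, end=n - f.start)
                         for f in chrom.features if not f.wraps)
        flipped = MitoGenome(label="rc", chromosomes=(
            Chromosome(record=rc_rec, features=rc_feats),))
        assert extract_order(flipped).chromosomes[0][1] == \
            extract_order(ancestor).chromosomes[0][1]

    def test_absent_anchor_rejected(self, ancestor):
        with pytest.raises(ValidationError):
            extract_order(ancestor, anchor="trnZZ")

    def test_minicircle_linearized_without_anchor(self, bipartite_genome):
        order = extract_order(bipartite_genome)
        mini = min(order.chromosomes, key=lambda c: len(c[1]))
        assert set(base(t) for t in mini[1]) == \
            {"nad6", "trnC", "trnS1", "control_region"}
        assert mini[1][0] == "control_region"   # lexicographically smallest


class TestAdjacencies:
    def test_three_gene_circle(self):
        order = order_of("a", "b", "c")
        assert adjacency_set(order) == frozenset({
            frozenset({"a", "b"}), frozenset({"b", "c"}), frozenset({"a", "c"})})

    def test_strand_blind_ignores_sign_oriented_does_not(self):
        plain = order_of("a", "b", "c")
        flipped = order_of("a", "-b", "c")
        assert adjacency_set(plain) == adjacency_set(flipped)
        assert adjacency_set(plain, oriented=True) != \
            adjacency_set(flipped, oriented=True)

    def test_published_orders_differ_only_at_fission_boundaries(self):
        sa1 = dedup_paralogs(thrips.SA1_ORDER)
        diff = adjacency_set(sa1) ^ adjacency_set(thrips.EA1_ORDER)
        touched = {g for pair in diff for g in pair}
        assert touched <= {"nad6", "trnC", "nad4L", "trnV"}


class TestClassifyEvents:
    def test_identical_orders_empty(self):
        order = order_of("a", "b", "c", "d")
        assert classify_events(order, order) == []

    def test_published_contrast(self):
        events = classify_events(thrips.EA1_ORDER, thrips.SA1_ORDER)
        assert event_signature(events) == [
            ("fragmentation", ("nad6", "trnC"), ("control_region", "trnS1")),
            ("inversion", ("trnF",), ()),
            ("inversion", ("trnY",), ()),
        ]

    def test_direction_symmetry_of_event_counts(self):
        fwd = classify_events(thrips.EA1_ORDER, thrips.SA1_ORDER)
        rev = classify_events(thrips.SA1_ORDER, thrips.EA1_ORDER)
        assert sorted(e.kind for e in fwd) == sorted(e.kind for e in rev)
        assert all(a.genes == b.genes for a, b in
                   zip(sorted(fwd, key=str), sorted(rev, key=str)))

    def test_single_translocation(self):
        a = order_of("a", "b", "c", "d", "e", "f")
        b = order_of("a", "c", "d", "b", "e", "f")
        events = classify_events(a, b)
        assert event_signature(events) == [("translocation", ("b",), ())]

    def test_run_translocation_is_one_event(self):
        a = order_of("a", "b", "c", "d", "e", "f", "g")
        b = order_of("a", "d", "e", "f", "b", "c", "g")
        events = classify_events(a, b)
        assert len(events) == 1
        assert events[0].kind == "translocation"

    def test_vocabulary_mismatch_lists_orphans(self):
        a = order_of("a", "b", "c")
        b = order_of("a", "b", "d")
        with pytest.raises(ValidationError, match="c.*d|d.*c"):
            classify_events(a, b)

    @pytest.mark.parametrize("seed", range(12))
    def test_toy_orders_match_exhaustive_search(self, seed):
        """Minimal event count equals BFS over single-gene moves on <=8 genes."""
        rng = random.Random(seed)
        n = rng.randint(6, 8)
        genes = [f"g{i}" for i in range(n)]
        a = order_of(*genes)

        def nbrs_in_a(g):
            i = genes.index(g)
            return {genes[(i - 1) % n], genes[(i + 1) % n]}

        # pick mutually non-interfering events against the ancestral order:
        # no event gene adjacent (in A) to another event gene
        chosen = []
        blocked = {"g0"}
        for _ in range(rng.randint(1, 2)):
            free = [g for g in genes if g not in blocked]
            if not free:
                break
            g = rng.choice(free)
            chosen.append((rng.choice(["inversion", "translocation"]), g))
            blocked |= {g} | nbrs_in_a(g)

        state = list(genes)
        event_genes = {g for _, g in chosen}
        for kind, g in chosen:
            i = state.index(g)
            if kind == "inversion":
                state[i] = flip(state[i])
            else:
                state.pop(i)
                spots = [j for j in range(1, len(state) + 1)
                         if j != i
                         and base(state[j - 1]) not in event_genes
                         and base(state[j % len(state)]) not in event_genes]
                if not spots:
                    state.insert(i, g)
                    event_genes.discard(g)
                    continue
                state.insert(rng.choice(spots), g)
        b = order_of(*state, anchor="g0")
        events = classify_events(a, b)
        assert len(events) == bfs_min_events(a, b)


class TestSharedBlocks:
    def test_identical_orders_single_full_block(self):
        order = order_of("a", "b", "c", "d", "e")
        blocks = shared_blocks([order, order])
        assert len(blocks) == 1 and blocks[0]["size"] == 5

    def test_translocation_splits_block_at_breakpoints(self):
        a = order_of("a", "b", "c", "d", "e", "f")
        b = order_of("a", "b", "d", "c", "e", "f")   # c moved past d
        blocks = shared_blocks([a, b])
        sizes = sorted(blk["size"] for blk in blocks)
        assert max(sizes) < 6
        joined = {g for blk in blocks for g in blk["genes"]}
        assert joined == {"a", "b", "c", "d", "e", "f"}

    def test_monotone_under_additional_orders(self):
        a = order_of("a", "b", "c", "d", "e", "f")
        b = order_of("a", "b", "d", "c", "e", "f")
        c = order_of("a", "c", "b", "d", "e", "f")
        two = max(blk["size"] for blk in shared_blocks([a, b]))
        three = max(blk["size"] for blk in shared_blocks([a, b, c]))
        assert three <= two

    def test_argument_permutation_changes_only_reference_frame(self):
        a = order_of("a", "b", "c", "d", "e", "f")
        b = order_of("a", "b", "d", "c", "e", "f")
        sizes_ab = sorted(blk["size"] for blk in shared_blocks([a, b]))
        sizes_ba = sorted(blk["size"] for blk in shared_blocks([b, a]))
        assert sizes_ab == sizes_ba

    def test_published_pair_shares_all_but_fission_boundaries(self):
        blocks = shared_blocks([thrips.SA1_ORDER, thrips.EA1_ORDER])
        sizes = sorted((blk["size"] for blk in blocks), reverse=True)
        assert sizes[0] == 36   # everything except the mini-circle split
        big = max(blocks, key=lambda blk: blk["size"])
        run = big["genes"]
        i = run.index("trnY")
        assert tuple(run[i:i + 10]) == thrips.TEN_GENE_BLOCK

    def test_fewer_than_two_orders_rejected(self):
        with pytest.raises(ValidationError):
            shared_blocks([order_of("a", "b")])
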