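import itertools

import numpy as np
import pytest

from pedclique.clique_index import (CliqueDictionary, IBDGraph, affinity,
                                    build_dictionary, build_graph,
                                    max_call_rate, partition_cliques)
from pedclique.ibd import IBDSegment, IBDSegmentStore


def H(name, slot=0):
    return (name, slot)


def graph_from(edge_list):
    edges = {}
    for u, v, w in edge_list:
        a, b = sorted((u, v))
        edges[(a, b)] = w
    return IBDGraph(0, edges)


def seg(a, b, start, end, post=0.99, chrom=1):
    return IBDSegment(a, b, chrom, start, end, start * 100, end * 100, post)


class TestBuildGraph:
    def test_no_covering_segments(self):
        store = IBDSegmentStore()
        store.add(seg(H("a"), H("b"), 10, 20))
        assert build_graph(store, 50).edges == {}

    def test_single_edge_weight_is_mean_posterior(self):
        store = IBDSegmentStore()
        store.add(seg(H("a"), H("b"), 0, 30, 0.97))
        g = build_graph(store, 15)
        assert g.weight(H("a"), H("b")) == pytest.approx(0.97)

    def test_multiple_covering_segments_take_max(self):
        store = IBDSegmentStore()
        store.add(seg(H("a"), H("b"), 0, 30, 0.9))
        store.add(seg(H("a"), H("b"), 10, 40, 0.95))
        g = build_graph(store, 15)
        assert g.weight(H("a"), H("b")) == pytest.approx(0.95)


class TestAffinity:
    def test_identical_closed_neighborhoods(self):
        # triangle with unit weights: u and v see exactly the same world
        g = graph_from([(H("u"), H("v"), 1.0), (H("u"), H("x"), 1.0),
                        (H("v"), H("x"), 1.0)])
        assert affinity(g, H("u"), H("v")) == pytest.approx(1.0)

    def test_disconnected_nodes_zero(self):
        g = graph_from([(H("u"), H("x"), 1.0), (H("v"), H("y"), 1.0)])
        assert affinity(g, H("u"), H("v")) == 0.0

    def test_path_graph_hand_computed(self):
        # a-b-c-d unit weights; closed neighborhoods:
        # b: {a:1, b:1, c:1}, c: {b:1, c:1, d:1}; dot = b·c = 1*0+1*1+1*1 = 2
        # norms: sqrt(3) each → affinity = 2/3
        g = graph_from([(H("a"), H("b"), 1.0), (H("b"), H("c"), 1.0),
                        (H("c"), H("d"), 1.0)])
        assert affinity(g, H("b"), H("c")) == pytest.approx(2 / 3)


class TestPartitionCliques:
    def test_clique_union_is_fixed_point(self):
        blocks = [[H(c) for c in grp] for grp in ("abc", "de")]
        edges = [(u, v, 1.0) for grp in blocks
                 for u, v in itertools.combinations(grp, 2)]
        out = partition_cliques(graph_from(edges))
        assert sorted(map(sorted, out)) == sorted(map(sorted, blocks))

    def test_bridged_cliques_split(self):
        left = [H(c) for c in "abcd"]
        right = [H(c) for c in "efgh"]
        edges = [(u, v, 1.0) for grp in (left, right)
                 for u, v in itertools.combinations(grp, 2)]
        edges.append((H("d"), H("e"), 0.9))  # bridge: no shared neighbors
        g = graph_from(edges)
        # bridge affinity by hand: closed nbhd d = {a,b,c,d,e}, e = {d,e,f,g,h}
        # shared entries d,e with weights (1,0.9)·(0.9,1) → dot = 1.8
        # |d| = sqrt(3·1 + 1 + 0.81), |e| = same → affinity < 0.9 → removed
        dot = 1.0 * 0.9 + 0.9 * 1.0
        norm = np.sqrt(3 + 1 + 0.81)
        assert dot / norm ** 2 < 0.9
        out = partition_cliques(g)
        assert sorted(map(sorted, out)) == sorted(map(sorted, (left, right)))

    def test_planted_partition_recovery(self):
        """5 planted 10-cliques with 5% spurious inter-clique edges at
        weight 0.86 are recovered with Rand index ≥ 0.95."""
        rng = np.random.default_rng(0)
        nodes = [H(f"n{i}") for i in range(50)]
        label = {n: i // 10 for i, n in enumerate(nodes)}
        edges = [(u, v, 1.0) for u, v in itertools.combinations(nodes, 2)
                 if label[u] == label[v]]
        cross = [(u, v) for u, v in itertools.combinations(nodes, 2)
                 if label[u] != label[v]]
        pick = rng.choice(len(cross), size=int(0.05 * len(cross)), replace=False)
        edges += [(cross[i][0], cross[i][1], 0.86) for i in pick]
        blocks = partition_cliques(graph_from(edges))
        found = {}
        for bi, blk in enumerate(blocks):
            for n in blk:
                found[n] = bi
        same_true = same_found = agree = 0
        pairs = list(itertools.combinations(nodes, 2))
        for u, v in pairs:
            t = label[u] == label[v]
            f = found[u] == found[v]
            agree += t == f
        rand = agree / len(pairs)
        assert rand >= 0.95

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_thresholds_only_refine(self, seed):
        """Raising w_min or a_min never merges blocks on noisy clique-union
        graphs (the structure IBD graphs actually have)."""
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 8, size=5)
        nodes = [H(f"n{i:02d}") for i in range(int(sizes.sum()))]
        label = np.repeat(np.arange(len(sizes)), sizes)
        edges = [(nodes[i], nodes[j], float(rng.uniform(0.86, 1.0)))
                 for i, j in itertools.combinations(range(len(nodes)), 2)
                 if label[i] == label[j]]
        cross = [(i, j) for i, j in itertools.combinations(range(len(nodes)), 2)
                 if label[i] != label[j]]
        pick = rng.choice(len(cross), size=max(1, len(cross) // 20),
                          replace=False)
        edges += [(nodes[cross[i][0]], nodes[cross[i][1]],
                   float(rng.uniform(0.8, 0.95))) for i in pick]
        g = graph_from(edges)
        base = partition_cliques(g, w_min=0.8, a_min=0.8)
        block_of = {n: i for i, blk in enumerate(base) for n in blk}
        for w_min, a_min in [(0.85, 0.8), (0.8, 0.9), (0.85, 0.9), (0.9, 0.95)]:
            finer = partition_cliques(g, w_min=w_min, a_min=a_min)
            for blk in finer:
                assert len({block_of[n] for n in blk}) == 1

    def test_matches_exhaustive_minimum_edit(self):
        """On small perturbed clique unions, the partition equals the
        minimum-edit clique union found by exhaustive search."""
        rng = np.random.default_rng(2)
        for trial in range(8):
            sizes = rng.integers(2, 5, size=rng.integers(2, 4))
            nodes = [H(f"n{i}") for i in range(int(sizes.sum()))]
            if len(nodes) > 12:
                continue
            label = np.repeat(np.arange(len(sizes)), sizes)
            edges = [(nodes[i], nodes[j], 1.0)
                     for i, j in itertools.combinations(range(len(nodes)), 2)
                     if label[i] == label[j]]
            # ≤1 perturbing edge between blocks
            cross = [(i, j) for i, j in itertools.combinations(range(len(nodes)), 2)
                     if label[i] != label[j]]
            if trial % 2 == 0 and cross:
                i, j = cross[rng.integers(len(cross))]
                edges.append((nodes[i], nodes[j], 0.86))
            got = sorted(map(sorted, partition_cliques(graph_from(edges))))
            best = _min_edit_clique_union(nodes, edges)
            assert got == sorted(map(sorted, best))


def _min_edit_clique_union(nodes, edges):
    """Exhaustive minimum-edit clique union over all set partitions."""
    present = {tuple(sorted((u, v))) for u, v, _ in edges}

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best, best_cost = None, None
    for part in partitions(list(nodes)):
        cost = 0
        block_of = {n: i for i, blk in enumerate(part) for n in blk}
        for u, v in itertools.combinations(nodes, 2):
            key = tuple(sorted((u, v)))
            same = block_of[u] == block_of[v]
            if same and key not in present:
                cost += 1
            elif not same and key in present:
                cost += 1
        if best_cost is None or cost < best_cost:
            best, best_cost = part, cost
    return best


class TestDictionary:
    def test_single_segment_two_block(self):
        store = IBDSegmentStore()
        store.add(seg(H("a"), H("b"), 0, 10))
        d = build_dictionary(store, [5])
        assert sorted(d.clique_members(5, H("a"))) == [H("a"), H("b")]

    def test_unlisted_haplotype_is_singleton(self):
        store = IBDSegmentStore()
        store.add(seg(H("a"), H("b"), 0, 10))
        d = build_dictionary(store, [5])
        assert d.clique_members(5, H("z")) == [H("z")]

    def test_consistent_with_marker_by_marker_partition(self):
        rng = np.random.default_rng(3)
        store = IBDSegmentStore()
        names = "abcdefgh"
        for _ in range(30):
            i, j = rng.choice(len(names), 2, replace=False)
            a, b = H(names[i]), H(names[j])
            s = int(rng.integers(0, 40))
            e = s + int(rng.integers(10, 30))
            store.add(seg(a, b, s, e, float(rng.uniform(0.6, 1.0))))
        markers = [0, 10, 20, 30, 40]
        d = build_dictionary(store, markers)
        for m in markers:
            blocks = partition_cliques(build_graph(store, m))
            assert sorted(map(sorted, d.blocks(m))) == sorted(map(sorted, blocks))

    def test_round_trip_serialization(self, tmp_path):
        store = IBDSegmentStore()
        store.add(seg(H("a"), H("b"), 0, 10))
        store.add(seg(H("c"), H("d"), 0, 10, 0.9))
        d = build_dictionary(store, [3, 7])
        path = tmp_path / "cliques.tsv"
        d.write_tsv(path)
        back = CliqueDictionary.read_tsv(path)
        for m in (3, 7):
            assert back.blocks(m) == d.blocks(m)


class TestMaxCallRate:
    def _dict(self, blocks, marker=0):
        d = CliqueDictionary()
        d.set_partition(marker, [frozenset(b) for b in blocks])
        return d

    def test_all_cliques_covered(self):
        d = self._dict([{H("s1"), H("a")}, {H("s1", 1), H("b"), H("b", 1)},
                        {H("a", 1)}])
        assert max_call_rate(d, ["s1"], ["s1", "a", "b"], 0) == pytest.approx(5 / 6)

    def test_no_sequenced_haplotypes(self):
        d = self._dict([{H("a"), H("b")}])
        assert max_call_rate(d, [], ["a", "b"], 0) == 0.0

    def test_direct_ratio(self):
        # 10 haplotypes: one 6-block with a sequenced member, rest without
        blocks = [{H("s"), H("s", 1), H("a"), H("a", 1), H("b"), H("b", 1)},
                  {H("c"), H("c", 1), H("d"), H("d", 1)}]
        d = self._dict(blocks)
        assert max_call_rate(d, ["s"], ["s", "a", "b", "c", "d"], 0) == pytest.approx(0.6)

    def test_partition_property(self, small_pipeline):
        D = small_pipeline.D
        H_ = small_pipeline.H
        samples = H_.sample_ids
        for m in D.markers()[:10]:
            seen = set()
            for s in samples:
                for k in (0, 1):
                    members = frozenset(D.clique_members(m, (s, k)))
                    assert (s, k) in members
                    for h in members:
                        assert D.same_clique(m, (s, k), h)
                    seen |= members
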