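"""Per-marker IBD graphs, affinity pruning and the clique dictionary.

True IBD at a marker is an equivalence relation, so the ideal IBD graph is
a disjoint union of cliques — one per ancestral haplotype.  The observed
graph (edges = haplotype pairs whose called segments span the marker,
weighted by the segment's mean HMM posterior) is a perturbation of that
union.  We recover cliques by (i) computing an *affinity* for every edge —
the cosine similarity of the two closed-neighborhood weight vectors, which
is large when the endpoints share many common neighbors — then (ii)
removing edges with weight < 0.85 or affinity < 0.9, and (iii) taking
connected components of what remains as the clique blocks.  Both filters
are evaluated on the unpruned graph and applied simultaneously; the whole
procedure is linear in the number of edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .ibd import Hap, IBDSegmentStore

W_MIN_DEFAULT = 0.85
A_MIN_DEFAULT = 0.9


@dataclass
class IBDGraph:
    """Weighted undirected IBD graph at one marker.

    ``edges`` maps a canonically ordered haplotype pair to a weight in
    (0, 1] (the max mean posterior over covering segments).
    """

    marker: int
    edges: dict[tuple[Hap, Hap], float]

    def nodes(self) -> list[Hap]:
        out = {h for pair in self.edges for h in pair}
        return sorted(out)

    def weight(self, u: Hap, v: Hap) -> float:
        if u > v:
            u, v = v, u
        return self.edges.get((u, v), 0.0)

    def neighbors(self, u: Hap) -> dict[Hap, float]:
        out = {}
        for (a, b), w in self.edges.items():
            if a == u:
                out[b] = w
            elif b == u:
                out[a] = w
        return out


def build_graph(store: IBDSegmentStore, marker: int) -> IBDGraph:
    """Graph of all haplotype pairs whose segments cover ``marker``; when
    several segments of a pair cover it, the max weight is kept."""
    edges: dict[tuple[Hap, Hap], float] = {}
    for segs in store.by_chrom.values():
        for s in segs:
            if s.start <= marker < s.end:
                key = (s.hap_a, s.hap_b)
                w = s.mean_posterior
                if w > edges.get(key, 0.0):
                    edges[key] = w
    return IBDGraph(marker, edges)


def affinity(G: IBDGraph, u: Hap, v: Hap) -> float:
    """Cosine similarity of the closed-neighborhood weight vectors of u and
    v (each vector has entry w_ux for neighbors x and 1 at the node
    itself); 0 when either vector is empty."""
    if u == v:
        raise ValueError("affinity requires distinct nodes")
    nu = G.neighbors(u)
    nv = G.neighbors(v)
    nu[u] = 1.0
    nv[v] = 1.0
    dot = sum(w * nv[x] for x, w in nu.items() if x in nv)
    norm = np.sqrt(sum(w * w for w in nu.values()) * sum(w * w for w in nv.values()))
    return float(dot / norm) if norm > 0 else 0.0


def _edge_affinities(nodes: list[Hap], edges: dict[tuple[Hap, Hap], float]
                     ) -> dict[tuple[Hap, Hap], float]:
    """Affinity for every edge, computed sparsely on the full graph."""
    index = {h: i for i, h in enumerate(nodes)}
    n = len(nodes)
    nbr: list[dict[int, float]] = [dict() for _ in range(n)]
    for (a, b), w in edges.items():
        ia, ib = index[a], index[b]
        nbr[ia][ib] = w
        nbr[ib][ia] = w
    for i in range(n):
        nbr[i][i] = 1.0
    norms = np.array([np.sqrt(sum(w * w for w in d.values())) for d in nbr])
    out = {}
    for (a, b) in edges:
        ia, ib = index[a], index[b]
        da, db = nbr[ia], nbr[ib]
        if len(db) < len(da):
            da, db = db, da
        dot = sum(w * db[x] for x, w in da.items() if x in db)
        out[(a, b)] = dot / (norms[ia] * norms[ib])
    return out


def partition_cliques(G: IBDGraph, w_min: float = W_MIN_DEFAULT,
                      a_min: float = A_MIN_DEFAULT) -> list[frozenset[Hap]]:
    """Clique blocks via affinity pruning.

    Edges with weight < w_min are dropped first.  Then the edge with the
    lowest affinity below a_min is removed and the affinities of edges
    touching its endpoints are recomputed, until every surviving edge has
    affinity ≥ a_min; connected components of the remainder are the
    blocks.  The sequential order matters: removing a spurious edge first
    restores the neighborhood similarity of the genuine edges it was
    polluting, which a single simultaneous sweep would also discard.
    Nodes isolated by pruning become singleton blocks.
    """
    import heapq

    nodes = G.nodes()
    nbr: dict[Hap, dict[Hap, float]] = {h: {} for h in nodes}
    for (a, b), w in G.edges.items():
        if w >= w_min:
            nbr[a][b] = w
            nbr[b][a] = w

    norm2 = {h: 1.0 + sum(w * w for w in nbr[h].values()) for h in nodes}

    def edge_aff(u: Hap, v: Hap) -> float:
        du, dv = nbr[u], nbr[v]
        su, sv = u, v
        if len(dv) < len(du):
            du, dv = dv, du
            su, sv = sv, su
        # closed neighborhoods: a 1.0 entry at each node itself
        dot = sum(w * dv[x] for x, w in du.items() if x in dv)
        dot += du.get(sv, 0.0) * 1.0 + dv.get(su, 0.0) * 1.0
        norm = np.sqrt(norm2[u] * norm2[v])
        return dot / norm if norm > 0 else 0.0

    aff: dict[tuple[Hap, Hap], float] = {}
    heap: list[tuple[float, tuple[Hap, Hap]]] = []
    for (a, b), w in G.edges.items():
        if w >= w_min:
            aff[(a, b)] = edge_aff(a, b)
            heapq.heappush(heap, (aff[(a, b)], (a, b)))
    while heap:
        a_val, (u, v) = heapq.heappop(heap)
        if aff.get((u, v)) != a_val:
            continue  # stale entry
        if a_val >= a_min:
            break  # all remaining edges qualify
        w_uv = nbr[u][v]
        del aff[(u, v)]
        del nbr[u][v]
        del nbr[v][u]
        norm2[u] -= w_uv * w_uv
        norm2[v] -= w_uv * w_uv
        for x in (u, v):
            for y in list(nbr[x]):
                key = (x, y) if x <= y else (y, x)
                if key in aff:
                    new = edge_aff(*key)
                    if new != aff[key]:
                        aff[key] = new
                        heapq.heappush(heap, (new, key))
    parent = {h: h for h in nodes}

    def find(x: Hap) -> Hap:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in aff:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    blocks: dict[Hap, set[Hap]] = {}
    for h in nodes:
        blocks.setdefault(find(h), set()).add(h)
    return sorted((frozenset(b) for b in blocks.values()), key=lambda s: sorted(s))


class CliqueDictionary:
    """Per-marker partition of haplotypes into IBD cliques with O(1)
    same-clique queries.  Haplotypes not present in any clique at a marker
    are implicit singletons."""

    def __init__(self, w_min: float = W_MIN_DEFAULT, a_min: float = A_MIN_DEFAULT):
        self.w_min = w_min
        self.a_min = a_min
        self._clique_of: dict[int, dict[Hap, int]] = {}
        self._members: dict[int, dict[int, list[Hap]]] = {}

    def markers(self) -> list[int]:
        return sorted(self._clique_of)

    def set_partition(self, marker: int, blocks: Sequence[frozenset[Hap]]) -> None:
        cl: dict[Hap, int] = {}
        mem: dict[int, list[Hap]] = {}
        for cid, block in enumerate(blocks):
            members = sorted(block)
            mem[cid] = members
            for h in members:
                cl[h] = cid
        self._clique_of[marker] = cl
        self._members[marker] = mem

    def clique_id(self, marker: int, hap: Hap) -> int | None:
        """Clique id, or None for an implicit singleton."""
        return self._clique_of[marker].get(hap)

    def same_clique(self, marker: int, a: Hap, b: Hap) -> bool:
        if a == b:
            return True
        cl = self._clique_of[marker]
        ca, cb = cl.get(a), cl.get(b)
        return ca is not None and ca == cb

    def clique_members(self, marker: int, hap: Hap) -> list[Hap]:
        cid = self._clique_of[marker].get(hap)
        if cid is None:
            return [hap]
        return list(self._members[marker][cid])

    def blocks(self, marker: int) -> list[list[Hap]]:
        return [list(v) for _, v in sorted(self._members[marker].items())]

    # -- serialization -----------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#w_min={self.w_min}\ta_min={self.a_min}\n")
            fh.write("marker\tsample\tslot\tclique\n")
            for m in self.markers():
                for cid, members in sorted(self._members[m].items()):
                    for (s, k) in members:
                        fh.write(f"{m}\t{s}\t{k}\t{cid}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CliqueDictionary":
        d = cls()
        per_marker: dict[int, dict[int, set[Hap]]] = {}
        with open(path) as fh:
            header = next(fh)
            parts = dict(p.split("=") for p in header.lstrip("#").split("\t"))
            d.w_min = float(parts["w_min"])
            d.a_min = float(parts["a_min"])
            next(fh)
            for ln in fh:
                m, s, k, cid = ln.rstrip("\n").split("\t")
                per_marker.setdefault(int(m), {}).setdefault(int(cid), set()).add(
                    (s, int(k)))
        for m, cl in per_marker.items():
            d.set_partition(m, [frozenset(v) for _, v in sorted(cl.items())])
        return d


def build_dictionary(store: IBDSegmentStore, markers: Iterable[int],
                     w_min: float = W_MIN_DEFAULT, a_min: float = A_MIN_DEFAULT
                     ) -> CliqueDictionary:
    """Clique partition at each requested marker, streaming segments per
    chromosome through an active-interval sweep."""
    markers = sorted(set(int(m) for m in markers))
    d = CliqueDictionary(w_min, a_min)
    # sweep: per chromosome, sort segments by start; maintain marker list
    seg_by_chrom = {c: sorted(v, key=lambda s: s.start)
                    for c, v in store.by_chrom.items()}
    all_segs = [s for v in seg_by_chrom.values() for s in v]
    if not all_segs:
        for m in markers:
            d.set_partition(m, [])
        return d
    starts_sorted = sorted(all_segs, key=lambda s: s.start)
    import heapq

    active: list[tuple[int, int]] = []  # (end, idx into starts_sorted)
    si = 0
    for m in markers:
        while si < len(starts_sorted) and starts_sorted[si].start <= m:
            heapq.heappush(active, (starts_sorted[si].end, si))
            si += 1
        while active and active[0][0] <= m:
            heapq.heappop(active)
        edges: dict[tuple[Hap, Hap], float] = {}
        for _, k in active:
            s = starts_sorted[k]
            if s.start <= m < s.end:
                key = (s.hap_a, s.hap_b)
                if s.mean_posterior > edges.get(key, 0.0):
                    edges[key] = s.mean_posterior
        d.set_partition(m, partition_cliques(IBDGraph(m, edges), w_min, a_min))
    return d


def max_call_rate(D: CliqueDictionary, sequenced: Sequence[str],
                  all_samples: Sequence[str], marker: int) -> float:
    """Ratio of haplotypes in cliques containing a sequenced individual's
    haplotype to the total number of haplotypes (2 per sample)."""
    seq = set(sequenced)
    if not set(sequenced) <= set(all_samples):
        raise ValueError("sequenced ids must be a subset of all samples")
    total = 2 * len(all_samples)
    covered = 0
    for s in all_samples:
        for k in (0, 1):
            members = D.clique_members(marker, (s, k))
            if any(h[0] in seq for h in members):
                covered += 1
    return covered / total if total else 0.0
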