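"""Framework-genotype phasing.

Pipeline (applied in this order by :func:`phase_cohort`):

1. homozygote phasing — a homozygous genotype determines both alleles;
2. Mendelian trio phasing — within nuclear families, sites where
   transmission is logically forced are phased; the child's slot 0 receives
   the father-derived allele (when the father is genotyped);
3. sibling-template phasing — the most completely phased child of a family
   serves as a template: IBD segments between a sibling's provisional
   haplotypes and the template resolve the sibling's remaining het sites;
4. surrogate-parent phasing — individuals with remaining unphased het sites
   (in particular quasi-founders, who have no genotyped parents) are phased
   through IBD segments with the phased haplotypes of their non-descendant
   relatives ("surrogate parents"); overlapping-segment conflicts are
   resolved by the highest posterior.

No stage ever contradicts an input genotype, and the set of phased
(sample, site) pairs only grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, HaplotypeMatrix
from .ibd import HMMParams, batch_posteriors, extract_segments
from .pedigree import NuclearFamily, Pedigree


@dataclass
class PhaseStats:
    """Phasing outcome fractions over non-missing framework genotypes."""

    fraction_unphased: float
    fraction_concordant: float | None = None
    fraction_discordant: float | None = None


# ---------------------------------------------------------------------------
# Stage 1: homozygotes
# ---------------------------------------------------------------------------

def phase_homozygotes(H: HaplotypeMatrix, G: GenotypeMatrix) -> int:
    """Set both slots at homozygous sites; returns newly phased site count."""
    n_new = 0
    for s in range(len(G.sample_ids)):
        g = G.calls[s]
        for val in (0, 2):
            sel = (g == val) & (H.alleles[s, 0] == MISSING)
            H.alleles[s, 0, sel] = val // 2
            H.alleles[s, 1, sel] = val // 2
            n_new += int(sel.sum())
    return n_new


# ---------------------------------------------------------------------------
# Stage 2: Mendelian trio phasing
# ---------------------------------------------------------------------------

def phase_by_mendel(family: NuclearFamily, G: GenotypeMatrix,
                    H: HaplotypeMatrix) -> np.ndarray:
    """Phase forced transmissions within one nuclear family.

    For each child het site the paternal allele is forced when either
    genotyped parent is homozygous.  Slot 0 of the child holds the paternal
    allele.  Mendelian-inconsistent sites are left unphased and returned as
    a flag array (per-marker count of inconsistent children).
    """
    have = set(G.sample_ids)
    father = family.father_id if family.father_id in have else None
    mother = family.mother_id if family.mother_id in have else None
    flags = np.zeros(len(G.markers), dtype=np.int32)
    n_typed = (father is not None) + (mother is not None)
    fg = G.row(father) if father else np.full(len(G.markers), MISSING, dtype=np.int8)
    mg = G.row(mother) if mother else np.full(len(G.markers), MISSING, dtype=np.int8)
    for child in family.child_ids:
        if child not in have or n_typed + 1 < 2:
            continue
        ci = H.sample_index(child)
        cg = G.row(child)
        het = cg == 1
        unphased = H.alleles[ci, 0] == MISSING
        # impossible triples (treat missing as wildcards)
        bad = ((fg == 0) & (mg == 0) & (cg >= 1)) | \
              ((fg == 2) & (mg == 2) & (cg <= 1)) | \
              ((fg == 0) & (cg == 2)) | ((fg == 2) & (cg == 0)) | \
              ((mg == 0) & (cg == 2)) | ((mg == 2) & (cg == 0)) | \
              (((fg == 0) & (mg == 2)) | ((fg == 2) & (mg == 0))) & (cg != 1) & (cg != MISSING)
        flags += bad
        ok = het & unphased & ~bad
        # paternal allele forced by a homozygous father
        for hom, pat in ((fg == 0, 0), (fg == 2, 1)):
            sel = ok & hom
            H.alleles[ci, 0, sel] = pat
            H.alleles[ci, 1, sel] = 1 - pat
        # or by a homozygous mother (child is het: paternal = 1 - maternal)
        still = ok & (H.alleles[ci, 0] == MISSING)
        for hom, mat in ((mg == 0, 0), (mg == 2, 1)):
            sel = still & hom
            H.alleles[ci, 0, sel] = 1 - mat
            H.alleles[ci, 1, sel] = mat
    return flags


# ---------------------------------------------------------------------------
# Segment-based allele copying (stages 3 and 4 share this machinery)
# ---------------------------------------------------------------------------

def _segments_vs_candidates(target: np.ndarray, cand_haps: np.ndarray,
                            phis: np.ndarray, cm: np.ndarray, freqs: np.ndarray,
                            eps: float, threshold: float, min_markers: int
                            ) -> list[tuple[int, int, int, float]]:
    """IBD runs of ``target`` (one haplotype vector) against each row of
    ``cand_haps``; returns (candidate row, start, end, mean posterior) with
    start/end local to the chromosome slice."""
    if len(cand_haps) == 0:
        return []
    P = len(cand_haps)
    pis = np.clip(phis, HMMParams.PI_CLIP, 1 - HMMParams.PI_CLIP)
    lams = np.array([HMMParams(min(p, 0.5), None, eps).lam for p in phis])
    post = batch_posteriors(np.broadcast_to(target, (P, len(target))).copy(),
                            cand_haps, cm, freqs, pis, lams, eps)
    out = []
    for k in range(P):
        mask = post[k] >= threshold
        edges = np.diff(np.concatenate(([0], mask.view(np.uint8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_markers:
                out.append((k, int(s), int(e), float(post[k, s:e].mean())))
    return out


def _geno_freqs(G: GenotypeMatrix) -> np.ndarray:
    """Alt-allele frequency per marker estimated from the genotypes."""
    known = G.calls != MISSING
    n = 2 * known.sum(axis=0)
    alt = np.where(known, G.calls, 0).sum(axis=0)
    p = np.where(n > 0, alt / np.maximum(n, 1), 0.5)
    return np.clip(p, 0.01, 0.99)


def phase_siblings_by_template(proband: str, siblings: list[str],
                               G: GenotypeMatrix, H: HaplotypeMatrix,
                               phi: float = 0.25, eps: float = 0.005,
                               threshold: float = 0.5, min_markers: int = 10) -> int:
    """Use a phased proband as a template to phase its siblings.

    For each sibling slot, IBD sharing with each proband haplotype is
    inferred; het sibling sites inside a shared segment copy the proband
    allele onto the shared slot.  Returns newly phased het-site count.
    """
    pi_ = H.sample_index(proband)
    n_new = 0
    all_freqs = _geno_freqs(G)
    for sib in siblings:
        si = H.sample_index(sib)
        sg = G.row(sib)
        for c in H.markers.chromosomes():
            sl = H.markers.chrom_slice(c)
            cm = H.markers.cm[sl]
            freqs = all_freqs[sl]
            votes: dict[tuple[int, int], tuple[float, int]] = {}
            for sslot in (0, 1):
                target = H.alleles[si, sslot, sl]
                cands = H.alleles[pi_, :, sl]
                segs = _segments_vs_candidates(target, cands,
                                               np.full(2, phi), cm, freqs, eps,
                                               threshold, min_markers)
                for k, s, e, w in segs:
                    span = np.arange(s, e)
                    tmpl = cands[k, s:e]
                    het = (sg[sl][s:e] == 1) & (H.alleles[si, 0, sl][s:e] == MISSING) \
                          & (tmpl != MISSING)
                    for t, a in zip(span[het], tmpl[het]):
                        key = (sslot, int(t))
                        if key not in votes or w > votes[key][0]:
                            votes[key] = (w, int(a))
            for (sslot, t), (_, a) in sorted(votes.items()):
                gi = sl.start + t
                if H.alleles[si, sslot, gi] == MISSING:
                    H.alleles[si, sslot, gi] = a
                    H.alleles[si, 1 - sslot, gi] = 1 - a
                    n_new += 1
    return n_new


def phase_by_surrogate_parents(proband: str, candidates: list[tuple[str, int]],
                               G: GenotypeMatrix, H: HaplotypeMatrix,
                               ped: Pedigree, eps: float = 0.005,
                               threshold: float = 0.5, min_markers: int = 10,
                               cand_alleles: np.ndarray | None = None,
                               rephase: bool = False) -> int:
    """Phase a proband's het sites through IBD with surrogate haplotypes.

    The proband is represented by its genotype "pseudo-haplotype" (hom sites
    carry the allele, het and missing sites are unknown).  Each called
    segment against a candidate haplotype is attributed to one of the
    proband's two slots by posterior-weighted agreement with the phase
    assembled so far (a few relaxation sweeps); covered het sites then take
    the candidate allele on the attributed slot, conflicts resolved by the
    highest total posterior weight.
    """
    pi_ = H.sample_index(proband)
    pg = G.row(proband)
    n_new = 0
    if not candidates:
        return 0
    cand_rows = np.array([H.sample_index(s) * 2 + k for s, k in candidates])
    phis = np.array([ped.kinship(proband, s) for s, _ in candidates])
    # candidates may be read from a frozen snapshot so that a cohort-wide
    # pass updates everyone from the same state (no order dependence)
    src_alleles = H.alleles if cand_alleles is None else cand_alleles
    flat = src_alleles.reshape(-1, src_alleles.shape[2])
    all_freqs = _geno_freqs(G)
    for c in H.markers.chromosomes():
        sl = H.markers.chrom_slice(c)
        cm = H.markers.cm[sl]
        freqs = all_freqs[sl]
        target = np.where(pg[sl] == 0, 0, np.where(pg[sl] == 2, 1, MISSING)
                          ).astype(np.int8)
        segs = _segments_vs_candidates(target, flat[cand_rows][:, sl], phis, cm,
                                       freqs, eps, threshold, min_markers)
        if not segs:
            continue
        all_het = np.flatnonzero(pg[sl] == 1)
        unphased = H.alleles[pi_, 0, sl][all_het] == MISSING
        het = all_het if rephase else all_het[unphased]
        if het.size == 0:
            continue
        # candidate alleles at *all* proband het sites per segment: the
        # already-phased ones connect segment chunks to the anchor, the
        # unphased ones receive the votes
        seg_sites: list[tuple[np.ndarray, np.ndarray, float]] = []
        for k, s, e, w in sorted(segs, key=lambda x: -x[3]):
            cand = flat[cand_rows[k], sl]
            sites = all_het[(all_het >= s) & (all_het < e)]
            sites = sites[cand[sites] != MISSING]
            if sites.size:
                seg_sites.append((sites, cand[sites].astype(np.int8), w))
        if not seg_sites:
            continue
        # anchor: het sites already phased by earlier stages pin the
        # orientation of any block they overlap to the existing slot order
        # (no anchor when rephasing: the old assembly must not vote)
        anchor_idx = None
        phased_het = np.flatnonzero((pg[sl] == 1)
                                    & (H.alleles[pi_, 0, sl] != MISSING))
        if not rephase and phased_het.size:
            seg_sites.append((phased_het,
                              H.alleles[pi_, 0, sl][phased_het].astype(np.int8),
                              10.0))
            anchor_idx = len(seg_sites) - 1
        slot0 = _assemble_slot0(seg_sites, len(cm), anchor=anchor_idx)
        for t in het:
            a = slot0[t]
            if a != MISSING:
                gi = sl.start + int(t)
                if H.alleles[pi_, 0, gi] == MISSING:
                    n_new += 1
                H.alleles[pi_, 0, gi] = a
                H.alleles[pi_, 1, gi] = 1 - a
    return n_new


def _assemble_slot0(seg_sites: list[tuple[np.ndarray, np.ndarray, float]],
                    n_markers: int, anchor: int | None = None) -> np.ndarray:
    """Merge per-segment allele tracks into one haplotype.

    Two segments lying on the same proband slot agree at shared het sites;
    segments on opposite slots carry complementary alleles.  Relative
    orientations are therefore propagated over the segment-overlap graph
    (edges weighted by |agreements − disagreements|, strongest first) with
    a parity union-find; a weighted per-site vote then fixes the slot-0
    allele.  Components without overlap keep independent (arbitrary)
    anchors — the unavoidable residual phase ambiguity.
    """
    # Split segments into chunks of ~CHUNK het sites.  A relative's tract
    # can switch which proband haplotype it matches at a parental
    # recombination point, so whole-segment orientation is unsound; chunks
    # of one segment are tied by moderate-weight continuity edges that
    # strong local disagreement can override at such switch points.
    CHUNK = 20
    CONT_WEIGHT = 6
    chunks: list[tuple[np.ndarray, np.ndarray, float]] = []
    edges = []  # (|score|, i, j, parity) parity 0 = same slot
    anchor_chunks: set[int] = set()
    for si_, (sites, alleles, w) in enumerate(seg_sites):
        n_ch = max(1, int(round(len(sites) / CHUNK)))
        bounds = np.linspace(0, len(sites), n_ch + 1).astype(int)
        first = len(chunks)
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b1 > b0:
                chunks.append((sites[b0:b1], alleles[b0:b1], w))
        if si_ == anchor:
            anchor_chunks.update(range(first, len(chunks)))
        else:
            for i in range(first, len(chunks) - 1):
                edges.append((CONT_WEIGHT, i, i + 1, 0))
    # anchor chunks all share orientation 0 by construction
    for a, b in zip(sorted(anchor_chunks)[:-1], sorted(anchor_chunks)[1:]):
        edges.append((10 ** 6, a, b, 0))
    k = len(chunks)
    # pairwise agree-minus-disagree scores in one product of ±1 tracks
    tracks = np.zeros((k, n_markers), dtype=np.float32)
    for i, (sites, alleles, _w) in enumerate(chunks):
        tracks[i, sites] = 2.0 * alleles - 1.0
    score = tracks @ tracks.T
    iu, ju = np.nonzero(np.triu(score, 1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        sc = int(round(score[i, j]))
        edges.append((abs(sc), i, j, 0 if sc > 0 else 1))
    # Greedy seeded expansion over the signed chunk graph: starting from
    # the anchors (or the heaviest-degree chunk), repeatedly orient the
    # unoriented chunk with the strongest absolute signed connection to the
    # oriented set, by the sign of that connection.  A few local sweeps
    # then flip any chunk whose signed agreement with its neighbors is
    # negative (anchors stay fixed).
    import heapq

    nbrs: list[list[tuple[int, int, int]]] = [[] for _ in range(k)]
    for w, i, j, rel in edges:
        nbrs[i].append((j, w, rel))
        nbrs[j].append((i, w, rel))
    ori = np.full(k, -1, dtype=np.int8)
    conn = np.zeros(k)
    heap: list[tuple[float, int]] = []

    def orient_and_push(x: int) -> None:
        for j, w, rel in nbrs[x]:
            if ori[j] == -1:
                conn[j] += w * (1 if (ori[x] ^ rel) == 0 else -1)
                heapq.heappush(heap, (-abs(conn[j]), j))

    for a in sorted(anchor_chunks):
        ori[a] = 0
        orient_and_push(a)
    while True:
        while heap:
            negc, x = heapq.heappop(heap)
            if ori[x] != -1 or abs(conn[x]) != -negc:
                continue
            ori[x] = 0 if conn[x] >= 0 else 1
            orient_and_push(x)
        rest = [x for x in range(k) if ori[x] == -1]
        if not rest:
            break
        # new component: seed at its heaviest node, arbitrary orientation
        seed = max(rest, key=lambda x: (sum(w for _, w, _ in nbrs[x]), -x))
        ori[seed] = 0
        orient_and_push(seed)
    pos_rank = np.argsort(np.argsort([float(c[0].mean()) for c in chunks],
                                     kind="stable"), kind="stable")
    for _round in range(4):
        changed = False
        for i in range(k):
            if i in anchor_chunks or not nbrs[i]:
                continue
            score = sum(w * (1 if (ori[i] ^ ori[j] ^ rel) == 0 else -1)
                        for j, w, rel in nbrs[i])
            if score < 0:
                ori[i] ^= 1
                changed = True
        # block moves along the chromosome: flipping everything on one side
        # of a positional cut can escape the half-flip local minimum that
        # single-chunk moves cannot fix (anchored chromosomes are pinned
        # well enough that the cut search is skipped)
        if not anchor_chunks:
            diff = np.zeros(k + 1)
            for w, i, j, rel in edges:
                lo, hi = sorted((pos_rank[i], pos_rank[j]))
                if lo == hi:
                    continue
                sgn = w if (ori[i] ^ ori[j] ^ rel) == 0 else -w
                diff[lo + 1] += sgn
                diff[hi + 1] -= sgn
            crossing = np.cumsum(diff)[1:k]  # cut after rank c-1
            if crossing.size and crossing.min() < 0:
                cut = int(np.argmin(crossing)) + 1
                ori[pos_rank >= cut] ^= 1
                changed = True
        if not changed:
            break
    vote = np.zeros((n_markers, 2))
    for i, (sites, alleles, w) in enumerate(chunks):
        if i in anchor_chunks:
            continue  # anchored sites are already phased; votes not needed
        a0 = alleles if ori[i] == 0 else 1 - alleles
        np.add.at(vote, (sites, a0.astype(np.int64)), w)
    decided = vote.sum(axis=1) > 0
    margin = np.abs(vote[:, 0] - vote[:, 1]) > 1e-9  # drop exact ties
    return np.where(decided & margin, vote.argmax(axis=1), MISSING).astype(np.int8)


def transmission_repair(H: HaplotypeMatrix, G: GenotypeMatrix, ped: Pedigree,
                        window: int = 20, min_evidence: int = 8) -> int:
    """Heal phase flips in quasi-founders using their children's gametes.

    A child's transmitted haplotype is a contiguous copy of the proband's
    two chromosomes, switching only at the child's own meiotic
    breakpoints — which are independent between children.  A position
    where *every* child's gamete simultaneously switches which proband
    slot it matches is therefore a flip in the proband's assembled phase,
    not a recombination; the proband's slots are swapped beyond that
    point.  Requires ≥ 2 genotyped children.  Returns the number of
    block flips applied.
    """
    n_fixed = 0
    qf = ped.quasi_founders()
    for s in sorted(qf):
        if s not in H._index:
            continue
        kids = [k for k in ped.children_of(s) if k in H._index]
        if len(kids) < 2:
            continue
        si = H.sample_index(s)
        slot_of = {k: (0 if ped.father(k) == s else 1) for k in kids}
        for c in H.markers.chromosomes():
            sl = H.markers.chrom_slice(c)
            het = np.flatnonzero((G.calls[si, sl] == 1)
                                 & (H.alleles[si, 0, sl] != MISSING))
            if het.size < 2 * window:
                continue
            slot0 = H.alleles[si, 0, sl][het]
            signs = []
            for k in kids:
                ki = H.sample_index(k)
                ca = H.alleles[ki, slot_of[k], sl][het]
                signs.append(np.where(ca == MISSING, 0,
                                      np.where(ca == slot0, 1, -1)))
            signs = np.array(signs)  # (kids, het sites)
            n_win = het.size // window
            if n_win < 2:
                continue
            bounds = np.linspace(0, het.size, n_win + 1).astype(int)
            net = np.array([[signs[k, b0:b1].sum() for b0, b1
                             in zip(bounds[:-1], bounds[1:])]
                            for k in range(len(kids))])
            decisive = np.abs(net) >= min_evidence
            sgn = np.sign(net)
            # DP over window orientations (0 keep, 1 flip): boundary cost =
            # number of children whose gamete must recombine there; a tiny
            # flip penalty keeps ties on the existing phase.  Windows where
            # no child is decisive (the mixed window containing a true
            # switch point) are skipped — they inherit the preceding
            # orientation — so the chain of evidence is not broken.
            active = [w for w in range(n_win) if decisive[:, w].any()]
            if len(active) < 2:
                continue
            FLIP_PEN = 0.01
            cost = np.array([0.0, FLIP_PEN])
            back = np.zeros((len(active), 2), dtype=np.int8)
            for ai in range(1, len(active)):
                wp, w = active[ai - 1], active[ai]
                new = np.empty(2)
                for cur in (0, 1):
                    opts = []
                    for prev in (0, 1):
                        switches = 0
                        for k in range(len(kids)):
                            if decisive[k, wp] and decisive[k, w]:
                                left = sgn[k, wp] * (-1) ** prev
                                right = sgn[k, w] * (-1) ** cur
                                switches += left != right
                        opts.append(cost[prev] + switches
                                    + (FLIP_PEN if cur else 0.0))
                    best = int(np.argmin(opts))
                    back[ai, cur] = best
                    new[cur] = opts[best]
                cost = new
            a_ori = np.empty(len(active), dtype=np.int8)
            a_ori[-1] = int(np.argmin(cost))
            for ai in range(len(active) - 1, 0, -1):
                a_ori[ai - 1] = back[ai, a_ori[ai]]
            ori = np.empty(n_win, dtype=np.int8)
            cur = a_ori[0]
            nxt = dict(zip(active, a_ori))
            for w in range(n_win):
                cur = nxt.get(w, cur)
                ori[w] = cur
            if ori.any():
                for w in np.flatnonzero(ori):
                    lo = sl.start + int(het[bounds[w]])
                    hi = (sl.start + int(het[bounds[w + 1]])
                          if w + 1 < n_win else sl.stop)
                    H.alleles[si, :, lo:hi] = H.alleles[si, ::-1, lo:hi]
                n_fixed += 1
    return n_fixed


# ---------------------------------------------------------------------------
# Cohort driver
# ---------------------------------------------------------------------------

def _family_generation(ped: Pedigree, fam: NuclearFamily) -> int:
    depth = {}

    def d(i):
        if i not in depth:
            par = ped.parents(i)
            depth[i] = 0 if par is None else 1 + max(d(par[0]), d(par[1]))
        return depth[i]

    return d(fam.child_ids[0])


def phase_cohort(ped: Pedigree, G: GenotypeMatrix, *, eps: float = 0.005,
                 threshold: float = 0.5, min_markers: int = 10,
                 surrogate_min_phi: float = 1 / 64,
                 truth=None) -> tuple[HaplotypeMatrix, PhaseStats]:
    """Run the full phasing pipeline on a genotyped cohort.

    ``truth`` (a SimTruth) enables concordance accounting in the returned
    PhaseStats.  Haplotype/genotype consistency is asserted after every
    stage.
    """
    H = HaplotypeMatrix.empty(G.sample_ids, G.markers)
    phase_homozygotes(H, G)
    H.check_consistent(G)
    fams = sorted(ped.nuclear_families(),
                  key=lambda f: (_family_generation(ped, f), f.father_id))
    for fam in fams:
        phase_by_mendel(fam, G, H)
    H.check_consistent(G)
    phased = H.phased_mask()
    for fam in fams:
        kids = [c for c in fam.child_ids if c in G._index]
        if len(kids) < 2:
            continue
        # template proband = the child with the most phased *het* sites; a
        # proband phased only at homozygous sites has indistinguishable
        # slots and cannot attribute copied alleles to a sibling slot
        het_counts = {}
        for c in kids:
            ci = G.sample_index(c)
            het = G.calls[ci] == 1
            het_counts[c] = (int((phased[ci] & het).sum()), int(het.sum()))
        proband = max(kids, key=lambda c: (het_counts[c][0], c))
        n_ph, n_het = het_counts[proband]
        if n_het == 0 or n_ph < 0.5 * n_het:
            continue
        phase_siblings_by_template(proband, [c for c in kids if c != proband],
                                   G, H, phi=0.25, eps=eps, threshold=threshold,
                                   min_markers=min_markers)
    H.check_consistent(G)
    # surrogate-parent phasing: quasi-founders first, then anyone unfinished
    qf = ped.quasi_founders()
    order = [s for s in G.sample_ids if s in qf] + \
            [s for s in G.sample_ids if s not in qf]
    # three synchronous passes reading candidates from a frozen snapshot
    # (no order dependence): fill, then re-assemble the quasi-founders'
    # entirely surrogate-derived phase against fully phased candidates
    # (heals orientation flips at sparse-coverage cut points), then fill
    # any remainder
    def surrogate_candidates(s: str, snapshot: np.ndarray) -> list[tuple[str, int]]:
        # descendants are included: a child's Mendel-phased paternal
        # haplotype is a recombinant of the proband's own two haplotypes
        # and carries independent phase information
        cands = []
        for o in G.sample_ids:
            if o == s or ped.kinship(s, o) < surrogate_min_phi:
                continue
            if (snapshot[G.sample_index(o)] != MISSING).mean() < 0.5:
                continue
            cands.extend([(o, 0), (o, 1)])
        return cands

    for pass_no in range(3):
        snapshot = H.alleles.copy()  # synchronous pass: no order dependence
        rephase = pass_no == 1
        if rephase:
            # only samples whose het phase is entirely surrogate-derived
            # (no genotyped parent contributed Mendelian phase) may be
            # re-assembled; their slot orientation is free by construction
            targets = [s for s in order if s in qf
                       and not any(p in ped.genotyped
                                   for p in (ped.parents(s) or ()))]
        else:
            targets = order
        for s in targets:
            si = G.sample_index(s)
            if not rephase and not ((G.calls[si] == 1)
                                    & (H.alleles[si, 0] == MISSING)).any():
                continue
            phase_by_surrogate_parents(s, surrogate_candidates(s, snapshot),
                                       G, H, ped, eps=eps, threshold=threshold,
                                       min_markers=min_markers,
                                       cand_alleles=snapshot, rephase=rephase)
    transmission_repair(H, G, ped)
    H.check_consistent(G)
    stats = compute_phase_stats(H, G, truth)
    return H, stats


def compute_phase_stats(H: HaplotypeMatrix, G: GenotypeMatrix,
                        truth=None) -> PhaseStats:
    """Unphased / concordant / discordant fractions over non-missing
    genotypes.  Concordance picks, per sample and chromosome, the slot
    orientation that best matches the true haplotypes."""
    known = G.calls != MISSING
    phased = H.phased_mask() & known
    frac_unphased = 1.0 - phased.sum() / known.sum()
    if truth is None:
        return PhaseStats(float(frac_unphased))
    n_conc = 0
    fw_idx = getattr(truth, "_fw_index_cache", None)
    # map framework markers of H into truth's union map by (chrom, bp)
    pos = {(int(c), int(b)): i for i, (c, b)
           in enumerate(zip(truth.markers.chrom, truth.markers.bp))}
    t_idx = np.array([pos[(int(c), int(b))]
                      for c, b in zip(H.markers.chrom, H.markers.bp)])
    for s in range(len(G.sample_ids)):
        ti = truth.sample_index(G.sample_ids[s])
        for c in H.markers.chromosomes():
            sl = H.markers.chrom_slice(c)
            ph = phased[s, sl]
            if not ph.any():
                continue
            obs = H.alleles[s, :, sl][:, ph]
            tru = truth.haplotypes[ti][:, t_idx[sl][ph]]
            same = ((obs[0] == tru[0]) & (obs[1] == tru[1])).sum()
            swap = ((obs[0] == tru[1]) & (obs[1] == tru[0])).sum()
            n_conc += max(int(same), int(swap))
    frac_conc = n_conc / known.sum()
    return PhaseStats(float(frac_unphased), float(frac_conc),
                      float(1 - frac_unphased - frac_conc))
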