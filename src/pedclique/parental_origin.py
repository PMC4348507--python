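"""Parental-origin (PO) assignment of haplotype slots.

Within a nuclear family, children's haplotype regions are first assigned to
four "bins" — the four parental haplotypes — such that IBD regions among
siblings share bins and the number of bin switches (recombinations) is
minimized (dynamic programming).  The three ways of pairing four bins into
two parents are then scored per child by coverage fractions, and the
pairing maximizing the minimum child separation fixes a consistent A/B slot
ordering across children.

For a quasi-founder C (no genotyped parents, but parents recorded in the
pedigree), parental origin is decided from IBD cliques: at a marker s, a
2×2 matrix K holds the median kinship between each recorded parent of C
and the eligible members (quasi-founders that are neither C nor siblings
of C) of the cliques of C's two slots.  The separation

    m(C, s) = (d − o) / (d + o),   d = K[A][1] + K[B][2],  o = K[A][2] + K[B][1]

lies in [−1, 1]: near +1 when the diagonal dominates (slot 1 belongs to
parent A), near −1 when the off-diagonal dominates.  Markers with
|m| > 0.25 are informative; with n₊/n₋ the informative counts by sign,
M(C) = max(n₊, n₋)/(n₊ + n₋), and PO is assigned per chromosome when
M(C) > 0.75, by the majority sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clique_index import CliqueDictionary
from .genotype_io import HaplotypeMatrix
from .ibd import IBDSegmentStore
from .pedigree import NuclearFamily, Pedigree

INFORMATIVE_CUT = 0.25
ASSIGN_CUT = 0.75

# DP costs: an IBD-inconsistent (pair, marker) observation vs a bin switch
_COST_IBD_SPLIT = 1.0     # IBD pair in different bins
_COST_NONIBD_JOIN = 0.25  # non-IBD pair sharing a bin (IBD calls miss more
                          # often than they false-alarm)
_COST_SWITCH = 12.0       # per bin switch between adjacent markers; a
                          # switch needs ≥ 48 contradicting same-bin markers
                          # (or 12 split-IBD markers) of support


@dataclass
class POMeasure:
    """Per-chromosome PO evidence for one quasi-founder."""

    n_plus: int
    n_minus: int
    m_values: np.ndarray

    @property
    def M(self) -> float:
        tot = self.n_plus + self.n_minus
        return max(self.n_plus, self.n_minus) / tot if tot else 0.5


# ---------------------------------------------------------------------------
# Step a: family bins
# ---------------------------------------------------------------------------

def _pair_ibd_mask(store: IBDSegmentStore, a, b, n_markers: int) -> np.ndarray:
    mask = np.zeros(n_markers, dtype=bool)
    for seg in store.pair_segments(a, b):
        mask[seg.start:seg.end] = True
    return mask


_STATES = [(swap, pa, mb) for swap in (0, 1) for pa in (0, 1) for mb in (2, 3)]


def _state_bins(state) -> tuple[int, int]:
    swap, pa, mb = state
    return (pa, mb) if swap == 0 else (mb, pa)


def assign_family_bins(family: NuclearFamily, H: HaplotypeMatrix,
                       store: IBDSegmentStore) -> np.ndarray:
    """Assign children's haplotype regions to the four parental-haplotype
    bins (0/1 = one parent, 2/3 = the other), minimizing bin switches under
    sibling-IBD consistency.  Returns int array (n_children, 2, n_markers).

    Children are processed sequentially: the first child anchors bins
    (slot 0 → bin 0, slot 1 → bin 2); each next child is solved by dynamic
    programming over 8 (swap, paternal-bin, maternal-bin) states.
    """
    kids = [c for c in family.child_ids if c in H._index]
    if len(kids) < 2:
        raise ValueError("family bin assignment needs at least 2 genotyped children")
    M = len(H.markers)
    bins = np.zeros((len(kids), 2, M), dtype=np.int8)
    bins[0, 0, :] = 0
    bins[0, 1, :] = 2
    chrom_slices = [H.markers.chrom_slice(c) for c in H.markers.chromosomes()]
    for ci in range(1, len(kids)):
        # IBD masks vs all previously assigned haplotypes
        prev_haps = [(kids[p], s) for p in range(ci) for s in (0, 1)]
        ibd = {p_hap: {s: _pair_ibd_mask(store, (kids[ci], s), p_hap, M)
                       for s in (0, 1)} for p_hap in prev_haps}
        for sl in chrom_slices:
            n_states = len(_STATES)
            emit = np.zeros((n_states, sl.stop - sl.start))
            for si, st in enumerate(_STATES):
                b0, b1 = _state_bins(st)
                for p_idx, p_hap in enumerate(prev_haps):
                    pbin = bins[p_idx // 2, p_idx % 2, sl]
                    for s, bb in ((0, b0), (1, b1)):
                        shared = ibd[p_hap][s][sl]
                        same = pbin == bb
                        emit[si] += np.where(shared & ~same, _COST_IBD_SPLIT,
                                             np.where(~shared & same,
                                                      _COST_NONIBD_JOIN, 0.0))
            # switch cost between states = number of differing bins
            ns = len(_STATES)
            sw = np.zeros((ns, ns))
            for i, a in enumerate(_STATES):
                for j, b in enumerate(_STATES):
                    ba, bb = _state_bins(a), _state_bins(b)
                    sw[i, j] = _COST_SWITCH * ((ba[0] != bb[0]) + (ba[1] != bb[1]))
            T = sl.stop - sl.start
            cost = emit[:, 0].copy()
            back = np.zeros((T, ns), dtype=np.int8)
            for t in range(1, T):
                tot = cost[None, :].T + sw  # prev i -> cur j
                back[t] = np.argmin(tot, axis=0)
                cost = tot[back[t], np.arange(ns)] + emit[:, t]
            path = np.empty(T, dtype=np.int8)
            path[-1] = int(np.argmin(cost))
            for t in range(T - 1, 0, -1):
                path[t - 1] = back[t, path[t]]
            for t in range(T):
                b0, b1 = _state_bins(_STATES[path[t]])
                bins[ci, 0, sl.start + t] = b0
                bins[ci, 1, sl.start + t] = b1
    return bins


def family_po_orientation(bins: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """Choose the bin→parent pairing maximizing the minimum child separation.

    Returns (pairing index, per-child swap flags, per-child separations).
    Pairing p assigns bins ``_PAIRINGS[p][0]`` to parent A; a swap flag of 1
    means the child's slots must be exchanged so that slot 0 ↔ parent A.
    Child separation is max(F1, F2)/(F1 + F2) ∈ [0.5, 1], where F1 is the
    fraction of slot 0 covered by A's bins plus the fraction of slot 1
    covered by B's bins, and F2 the swapped sum.
    """
    n_children = bins.shape[0]
    best = None
    for p_idx, (a_bins, b_bins) in enumerate(_PAIRINGS):
        seps = np.empty(n_children)
        swaps = np.zeros(n_children, dtype=np.int8)
        for c in range(n_children):
            in_a0 = np.isin(bins[c, 0], a_bins).mean()
            in_b1 = np.isin(bins[c, 1], b_bins).mean()
            in_b0 = np.isin(bins[c, 0], b_bins).mean()
            in_a1 = np.isin(bins[c, 1], a_bins).mean()
            f1 = in_a0 + in_b1
            f2 = in_b0 + in_a1
            tot = f1 + f2
            seps[c] = max(f1, f2) / tot if tot > 0 else 0.5
            swaps[c] = 0 if f1 >= f2 else 1
        score = seps.min()
        if best is None or score > best[0]:
            best = (score, p_idx, swaps, seps)
    _, p_idx, swaps, seps = best
    return p_idx, swaps, seps


_PAIRINGS = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]


# ---------------------------------------------------------------------------
# Quasi-founder clique-kinship stage
# ---------------------------------------------------------------------------

def po_kinship_matrix(C: str, marker: int, D: CliqueDictionary, ped: Pedigree,
                      quasi_founders: set[str] | None = None) -> np.ndarray:
    """2×2 median-kinship matrix K[parent, slot] for quasi-founder ``C``.

    Rows: C's recorded parents (A = father, B = mother); columns: the IBD
    cliques of C's slots.  Eligible clique members are quasi-founders other
    than C and C's siblings; an empty eligible set gives entry 0.
    """
    par = ped.parents(C)
    if par is None:
        raise ValueError(f"{C} has no recorded parents")
    if quasi_founders is None:
        quasi_founders = ped.quasi_founders()
    sibs = {s for s in ped.individuals
            if s != C and ped.parents(s) == par}
    K = np.zeros((2, 2))
    for h in (0, 1):
        members = {m[0] for m in D.clique_members(marker, (C, h))}
        eligible = sorted(m for m in members
                          if m in quasi_founders and m != C and m not in sibs)
        if not eligible:
            continue
        for p in (0, 1):
            K[p, h] = float(np.median([ped.kinship(par[p], m) for m in eligible]))
    return K


def separation_m(K: np.ndarray) -> float:
    """m = (d − o)/(d + o) ∈ [−1, 1]; 0 when d + o = 0."""
    K = np.asarray(K, dtype=float)
    if (K < 0).any():
        raise ValueError("kinship entries must be non-negative")
    d = K[0, 0] + K[1, 1]
    o = K[0, 1] + K[1, 0]
    return float((d - o) / (d + o)) if d + o > 0 else 0.0


def assign_po(m_values: np.ndarray, informative_cut: float = INFORMATIVE_CUT,
              assign_cut: float = ASSIGN_CUT) -> tuple[int | None, POMeasure]:
    """Chromosome-level PO decision from per-marker m values.

    Returns (orientation, POMeasure): orientation 0 keeps the slot order
    (slot 0 ↔ parent A = father), 1 swaps it, None withholds assignment
    (M ≤ assign_cut or no informative markers).
    """
    m_values = np.asarray(m_values, dtype=float)
    informative = np.abs(m_values) > informative_cut
    n_plus = int((m_values[informative] > 0).sum())
    n_minus = int((m_values[informative] < 0).sum())
    meas = POMeasure(n_plus, n_minus, m_values)
    if n_plus + n_minus == 0 or meas.M <= assign_cut:
        return None, meas
    return (0 if n_plus >= n_minus else 1), meas


def assign_po_cohort(H: HaplotypeMatrix, D: CliqueDictionary, ped: Pedigree,
                     *, thin: int = 5, informative_cut: float = INFORMATIVE_CUT,
                     assign_cut: float = ASSIGN_CUT,
                     apply_swaps: bool = True) -> dict[tuple[str, int], POMeasure]:
    """Per-chromosome PO assignment for every quasi-founder with recorded
    parents, evaluated at every ``thin``-th dictionary marker.

    Updates ``H.po`` (and, when ``apply_swaps``, reorders slots so slot 0 is
    paternal for assigned chromosomes).  Returns the POMeasure per
    (sample, chromosome).
    """
    qf = ped.quasi_founders()
    dict_markers = np.array(D.markers())
    chroms = H.markers.chromosomes()
    out: dict[tuple[str, int], POMeasure] = {}
    for C in sorted(qf):
        if C not in H._index or ped.parents(C) is None:
            continue
        si = H.sample_index(C)
        for ci, c in enumerate(chroms):
            sl = H.markers.chrom_slice(c)
            use = dict_markers[(dict_markers >= sl.start) & (dict_markers < sl.stop)]
            use = use[::thin] if thin > 1 else use
            ms = np.array([separation_m(po_kinship_matrix(C, int(m), D, ped, qf))
                           for m in use])
            orient, meas = assign_po(ms, informative_cut, assign_cut)
            out[(C, c)] = meas
            if orient is None:
                continue
            if orient == 1 and apply_swaps:
                H.alleles[si, :, sl] = H.alleles[si, ::-1, sl]
            H.po[si, ci] = H.PO_SLOT0_PATERNAL
    # non-quasi-founders: slot 0 is paternal by the Mendelian convention
    for s in H.sample_ids:
        if s in qf:
            continue
        par = ped.parents(s)
        if par and all(p in ped.genotyped for p in par):
            H.po[H.sample_index(s), :] = H.PO_SLOT0_PATERNAL
    return out
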