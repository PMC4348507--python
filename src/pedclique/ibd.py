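"""Pairwise-haplotype IBD detection with a two-state HMM.

For a pair of haplotypes the hidden state at each marker is IBD / not-IBD.
The stationary prior of the IBD state is the pair's kinship coefficient φ
(the probability that a random allele pair is IBD; the four haplotype
pairings of two individuals average to φ).  Transitions over a genetic
distance of d cM follow the continuous-time two-state chain

    P(IBD  → IBD) = π + (1 − π) e^(−λ d)
    P(¬IBD → IBD) = π (1 − e^(−λ d))

with transition rate λ per cM.  Emissions depend only on whether the two
observed alleles match: under IBD a match has probability (1−ε)² + ε² for
per-allele genotyping error ε; under non-IBD it is p² + q² with p the
marker's alt-allele frequency.  Missing alleles emit 1 in both states.

Posteriors are computed by forward–backward with per-marker rescaling,
which is immune to underflow on arbitrarily long chromosomes.  Maximal runs
of posterior ≥ threshold become IBD segments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import MISSING, HaplotypeMatrix, MarkerMap

Hap = tuple[str, int]  # (sample id, slot 0/1)


@dataclass
class HMMParams:
    """Per-pair HMM parameters.

    λ defaults to g/100 per cM where g = max(1, round(−log2 2φ)) approximates
    the number of meioses separating the pair: the expected IBD tract length
    is inversely proportional to the meiosis count.
    """

    phi: float
    lam: float | None = None
    eps: float = 0.005

    PI_CLIP = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 0.5):
            raise ValueError("phi must be in [0, 0.5]")
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must be in (0, 0.5)")
        if self.lam is None:
            self.lam = default_lambda(self.phi)
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def pi(self) -> float:
        return float(np.clip(self.phi, self.PI_CLIP, 1 - self.PI_CLIP))


def default_lambda(phi: float) -> float:
    """λ = g/100 per cM with g = max(1, round(−log2 2φ)) meioses."""
    phi = max(phi, HMMParams.PI_CLIP)
    g = max(1, round(-np.log2(min(2 * phi, 1.0))))
    return g / 100.0


@dataclass
class IBDSegment:
    """Half-open marker interval [start, end) of IBD between two haplotypes."""

    hap_a: Hap
    hap_b: Hap
    chrom: int
    start: int              # global marker index, inclusive
    end: int                # global marker index, exclusive
    start_bp: int
    end_bp: int
    mean_posterior: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty segment interval")
        if self.hap_a > self.hap_b:
            self.hap_a, self.hap_b = self.hap_b, self.hap_a

    @property
    def n_markers(self) -> int:
        return self.end - self.start

    def key(self) -> tuple:
        return (self.hap_a, self.hap_b, self.chrom, self.start, self.end)


class IBDSegmentStore:
    """Segments indexed by chromosome and by haplotype; pair order is
    canonicalized and duplicate (pair, interval) entries are rejected."""

    def __init__(self) -> None:
        self.by_chrom: dict[int, list[IBDSegment]] = {}
        self.by_hap: dict[Hap, list[IBDSegment]] = {}
        self._keys: set[tuple] = set()
        self.n_pairs_processed = 0

    def __len__(self) -> int:
        return len(self._keys)

    def add(self, seg: IBDSegment) -> None:
        k = seg.key()
        if k in self._keys:
            return
        self._keys.add(k)
        self.by_chrom.setdefault(seg.chrom, []).append(seg)
        self.by_hap.setdefault(seg.hap_a, []).append(seg)
        self.by_hap.setdefault(seg.hap_b, []).append(seg)

    def segments(self) -> list[IBDSegment]:
        return [s for c in sorted(self.by_chrom) for s in self.by_chrom[c]]

    def pair_segments(self, a: Hap, b: Hap) -> list[IBDSegment]:
        if a > b:
            a, b = b, a
        return [s for s in self.by_hap.get(a, ()) if s.hap_a == a and s.hap_b == b]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("hapA_sample\thapA_slot\thapB_sample\thapB_slot\tchrom\t"
                     "start_marker\tend_marker\tstart_bp\tend_bp\tmean_posterior\n")
            for s in self.segments():
                fh.write(f"{s.hap_a[0]}\t{s.hap_a[1]}\t{s.hap_b[0]}\t{s.hap_b[1]}\t"
                         f"{s.chrom}\t{s.start}\t{s.end}\t{s.start_bp}\t{s.end_bp}\t"
                         f"{s.mean_posterior:.6f}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "IBDSegmentStore":
        store = cls()
        with open(path) as fh:
            next(fh)
            for ln in fh:
                f = ln.rstrip("\n").split("\t")
                store.add(IBDSegment((f[0], int(f[1])), (f[2], int(f[3])), int(f[4]),
                                     int(f[5]), int(f[6]), int(f[7]), int(f[8]),
                                     float(f[9])))
        return store


# ---------------------------------------------------------------------------
# Forward-backward engine
# ---------------------------------------------------------------------------

def _emissions(hapsA: np.ndarray, hapsB: np.ndarray, freqs: np.ndarray,
               eps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Emission likelihoods (P, M) for the IBD and non-IBD states."""
    match = hapsA == hapsB
    missing = (hapsA == MISSING) | (hapsB == MISSING)
    eps = np.asarray(eps, dtype=np.float64).reshape(-1, 1)
    p = freqs[None, :]
    q = 1.0 - p
    e_ibd = np.where(match, (1 - eps) ** 2 + eps ** 2, 2 * eps * (1 - eps))
    e_non = np.where(match, p * p + q * q, 2 * p * q)
    e_ibd = np.where(missing, 1.0, e_ibd)
    e_non = np.where(missing, 1.0, e_non)
    return e_ibd, e_non


def batch_posteriors(hapsA: np.ndarray, hapsB: np.ndarray, cm: np.ndarray,
                     freqs: np.ndarray, pi: np.ndarray, lam: np.ndarray,
                     eps: np.ndarray | float) -> np.ndarray:
    """Posterior P(IBD) per marker for a batch of haplotype pairs.

    hapsA/hapsB: (P, M) int8 alleles; cm/freqs: (M,); pi/lam: (P,).
    Returns (P, M) float64 posteriors.  Uses rescaled forward–backward.
    """
    P, M = hapsA.shape
    if hapsB.shape != (P, M) or cm.shape != (M,):
        raise ValueError("shape mismatch between haplotypes and map")
    if np.any(np.diff(cm) <= 0):
        raise ValueError("cM positions must be strictly increasing")
    pi = np.asarray(pi, dtype=np.float64)
    lam = np.asarray(lam, dtype=np.float64)
    eps_arr = np.broadcast_to(np.asarray(eps, dtype=np.float64), (P,))
    e_ibd, e_non = _emissions(hapsA, hapsB, np.asarray(freqs, dtype=np.float64),
                              eps_arr)
    d = np.diff(cm)
    # stay[t-1, :] per pair computed on the fly: exp(-lam * d[t-1])
    alpha_i = np.empty((M, P))
    alpha_n = np.empty((M, P))
    a_i = pi * e_ibd[:, 0]
    a_n = (1 - pi) * e_non[:, 0]
    norm = a_i + a_n
    a_i /= norm
    a_n /= norm
    alpha_i[0] = a_i
    alpha_n[0] = a_n
    exp_d = np.exp(-np.outer(d, lam))  # (M-1, P)
    for t in range(1, M):
        e = exp_d[t - 1]
        stay_i = pi + (1 - pi) * e       # IBD -> IBD
        go_i = pi * (1 - e)              # non -> IBD
        n_i = (a_i * stay_i + a_n * go_i) * e_ibd[:, t]
        n_n = (a_i * (1 - stay_i) + a_n * (1 - go_i)) * e_non[:, t]
        norm = n_i + n_n
        a_i = n_i / norm
        a_n = n_n / norm
        alpha_i[t] = a_i
        alpha_n[t] = a_n
    b_i = np.ones(P)
    b_n = np.ones(P)
    post = np.empty((M, P))
    post[M - 1] = alpha_i[M - 1] * b_i / (alpha_i[M - 1] * b_i + alpha_n[M - 1] * b_n)
    for t in range(M - 2, -1, -1):
        e = exp_d[t]
        stay_i = pi + (1 - pi) * e
        go_i = pi * (1 - e)
        bi_e = b_i * e_ibd[:, t + 1]
        bn_e = b_n * e_non[:, t + 1]
        n_bi = stay_i * bi_e + (1 - stay_i) * bn_e
        n_bn = go_i * bi_e + (1 - go_i) * bn_e
        norm = n_bi + n_bn
        b_i = n_bi / norm
        b_n = n_bn / norm
        num = alpha_i[t] * b_i
        post[t] = num / (num + alpha_n[t] * b_n)
    return post.T.copy()


def hmm_posterior(hapA: np.ndarray, hapB: np.ndarray, markers: MarkerMap,
                  params: HMMParams, freqs: np.ndarray | None = None) -> np.ndarray:
    """Per-marker IBD posterior for one haplotype pair on one chromosome."""
    hapA = np.asarray(hapA, dtype=np.int8)
    hapB = np.asarray(hapB, dtype=np.int8)
    if hapA.shape != hapB.shape:
        raise ValueError("haplotype length mismatch")
    if len(np.unique(markers.chrom)) != 1:
        raise ValueError("hmm_posterior expects a single chromosome")
    if freqs is None:
        freqs = np.full(len(markers), 0.5)
    return batch_posteriors(hapA[None, :], hapB[None, :], markers.cm, freqs,
                            np.array([HMMParams(params.phi, params.lam, params.eps).pi]),
                            np.array([params.lam]), params.eps)[0]


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------

def extract_segments(posterior: np.ndarray, markers: MarkerMap,
                     threshold: float = 0.5, min_markers: int = 10,
                     *, hap_a: Hap = ("a", 0), hap_b: Hap = ("b", 0),
                     offset: int = 0) -> list[IBDSegment]:
    """Maximal runs of posterior ≥ threshold, discarding runs shorter than
    ``min_markers``.  ``offset`` is the global index of the first marker of
    the chromosome slice the posterior covers."""
    posterior = np.asarray(posterior, dtype=np.float64)
    if posterior.min() < 0 or posterior.max() > 1:
        raise ValueError("posterior outside [0,1]")
    mask = posterior >= threshold
    edges = np.diff(np.concatenate(([0], mask.view(np.uint8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    out = []
    chrom = int(markers.chrom[offset])
    for s, e in zip(starts, ends):
        if e - s < min_markers:
            continue
        out.append(IBDSegment(hap_a, hap_b, chrom, offset + int(s), offset + int(e),
                              int(markers.bp[offset + s]),
                              int(markers.bp[offset + e - 1]),
                              float(posterior[s:e].mean())))
    return out


# ---------------------------------------------------------------------------
# All-pairs scan
# ---------------------------------------------------------------------------

def haplotype_pairs(sample_ids: Sequence[str], include_within: bool = True
                    ) -> Iterable[tuple[Hap, Hap]]:
    """All unordered pairs of the 2n haplotypes (optionally excluding the n
    within-individual pairs)."""
    haps = [(s, k) for s in sample_ids for k in (0, 1)]
    for a, b in itertools.combinations(haps, 2):
        if not include_within and a[0] == b[0]:
            continue
        yield a, b


def pairwise_ibd(H: HaplotypeMatrix, ped, *, eps: float = 0.005,
                 threshold: float = 0.5, min_markers: int = 10,
                 include_within: bool = True, min_phi: float = 0.0,
                 lam_overrides: dict[tuple[str, str], float] | None = None,
                 batch_size: int = 20000) -> IBDSegmentStore:
    """IBD segments between every pair of haplotypes in ``H``.

    φ per pair comes from the pedigree; the within-individual (HBD) pair of
    an individual uses the kinship of its parents (its inbreeding
    coefficient).  ``min_phi`` optionally skips pairs with smaller kinship
    (0 processes every pair).
    """
    store = IBDSegmentStore()
    samples = H.sample_ids
    freqs = _hap_freqs(H)
    pairs: list[tuple[Hap, Hap]] = []
    pis: list[float] = []
    lams: list[float] = []
    phi_cache: dict[tuple[str, str], float] = {}

    def pair_phi(i: str, j: str) -> float:
        key = (i, j) if i <= j else (j, i)
        if key not in phi_cache:
            if i == j:
                par = ped.parents(i)
                phi_cache[key] = 0.0 if par is None else ped.kinship(*par)
            else:
                phi_cache[key] = ped.kinship(i, j)
        return phi_cache[key]

    for a, b in haplotype_pairs(samples, include_within):
        phi = pair_phi(a[0], b[0])
        store.n_pairs_processed += 1
        if phi < min_phi:
            continue
        lam = None
        if lam_overrides:
            lam = lam_overrides.get((a[0], b[0])) or lam_overrides.get((b[0], a[0]))
        p = HMMParams(min(phi, 0.5), lam, eps)
        pairs.append((a, b))
        pis.append(p.pi)
        lams.append(p.lam)

    idx = {s: i for i, s in enumerate(samples)}
    flat = H.alleles.reshape(-1, H.alleles.shape[2])  # (2n, M)
    rowA = np.array([idx[a[0]] * 2 + a[1] for a, _ in pairs], dtype=np.int64)
    rowB = np.array([idx[b[0]] * 2 + b[1] for _, b in pairs], dtype=np.int64)
    pis_arr = np.array(pis)
    lams_arr = np.array(lams)
    for c in H.markers.chromosomes():
        sl = H.markers.chrom_slice(c)
        cm = H.markers.cm[sl]
        fr = freqs[sl]
        for lo in range(0, len(pairs), batch_size):
            hi = min(lo + batch_size, len(pairs))
            post = batch_posteriors(flat[rowA[lo:hi], sl], flat[rowB[lo:hi], sl],
                                    cm, fr, pis_arr[lo:hi], lams_arr[lo:hi], eps)
            for k in range(hi - lo):
                a, b = pairs[lo + k]
                for seg in extract_segments(post[k], H.markers, threshold,
                                            min_markers, hap_a=a, hap_b=b,
                                            offset=sl.start):
                    store.add(seg)
    return store


def _hap_freqs(H: HaplotypeMatrix) -> np.ndarray:
    """Alt-allele frequency per marker from the phased alleles."""
    known = H.alleles != MISSING
    n = known.sum(axis=(0, 1))
    alt = np.where(known, H.alleles, 0).sum(axis=(0, 1))
    p = np.where(n > 0, alt / np.maximum(n, 1), 0.5)
    return np.clip(p, 0.01, 0.99)


# ---------------------------------------------------------------------------
# Interval algebra and pair-level summaries
# ---------------------------------------------------------------------------

def union_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]
                        ) -> list[tuple[int, int]]:
    a = union_intervals(a)
    b = union_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def genome_ibd_fraction(store: IBDSegmentStore, pair: tuple[str, str],
                        markers: MarkerMap) -> float:
    """Fraction of the genetic map covered by IBD segments over any of the
    four cross-individual haplotype pairings of the sample pair."""
    i, j = pair
    total = 0.0
    covered = 0.0
    for c in markers.chromosomes():
        sl = markers.chrom_slice(c)
        cm = markers.cm[sl]
        total += cm[-1] - cm[0]
        ivals = []
        for sa in (0, 1):
            for sb in (0, 1):
                for seg in store.pair_segments((i, sa), (j, sb)):
                    if seg.chrom == c:
                        ivals.append((seg.start - sl.start, seg.end - sl.start))
        for s, e in union_intervals(ivals):
            covered += cm[e - 1] - cm[s]
    return covered / total if total > 0 else 0.0


def ibd2_segments(store: IBDSegmentStore, pair: tuple[str, str]
                  ) -> dict[int, list[tuple[int, int]]]:
    """Per-chromosome marker intervals where both disjoint haplotype
    pairings are simultaneously IBD (IBD state = 2)."""
    i, j = pair
    chroms = set()
    segs = {}
    for sa in (0, 1):
        for sb in (0, 1):
            lst = store.pair_segments((i, sa), (j, sb))
            segs[(sa, sb)] = lst
            chroms.update(s.chrom for s in lst)
    out: dict[int, list[tuple[int, int]]] = {}
    for c in sorted(chroms):
        def iv(key):
            return [(s.start, s.end) for s in segs[key] if s.chrom == c]
        p1 = intersect_intervals(iv((0, 0)), iv((1, 1)))
        p2 = intersect_intervals(iv((0, 1)), iv((1, 0)))
        merged = union_intervals(p1 + p2)
        if merged:
            out[c] = merged
    return out
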