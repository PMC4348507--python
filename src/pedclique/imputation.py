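"""Queue-based clique imputation of sequence variants.

Each variant is imputed independently.  Homozygous genotypes of sequenced
samples are phased trivially and both haplotypes enter a FIFO queue (seeded
in ascending sample id, guaranteeing determinism).  Popping a haplotype,
the alleles of all already-assigned sequenced haplotypes in its IBD clique
are tallied; if a two-thirds majority exists, the winning allele is
propagated to every unassigned haplotype in the clique, otherwise the
clique is marked conflicted and all of its calls are withdrawn.  A
heterozygous sequenced sample whose first haplotype is resolved has its
second haplotype phased by complement and enqueued.  Sequenced genotypes
are never overwritten.

Cliques are defined at framework markers only; a sequence variant uses the
clique partition at its nearest framework marker by bp (ties to the left).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .clique_index import CliqueDictionary
from .genotype_io import MISSING, GenotypeMatrix, HaplotypeMatrix, MarkerMap

MAJORITY_FRACTION = 2.0 / 3.0

SOURCE_NONE = 0
SOURCE_PEDIGREE = 1
SOURCE_LD = 2
SOURCE_OBSERVED = 3


@dataclass
class VariantRecord:
    """A sequence variant with genotypes over the sequenced samples."""

    chrom: int
    bp: int
    ref: str
    alt: str
    rs_known: bool
    genotypes: np.ndarray  # alt counts over sequenced samples, -1 missing
    id: str = ""

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def variant_type(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def call_rate(self) -> float:
        return float((self.genotypes != MISSING).mean())

    @property
    def n_alt(self) -> int:
        return int(self.genotypes[self.genotypes != MISSING].sum())

    @property
    def singleton(self) -> bool:
        return self.n_alt == 1

    @property
    def maf(self) -> float:
        known = self.genotypes != MISSING
        if known.sum() == 0:
            return 0.0
        p = self.genotypes[known].sum() / (2 * known.sum())
        return float(min(p, 1 - p))


@dataclass
class ImputedPanel:
    """Imputation result: per-variant haplotype alleles for all samples."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    alleles: np.ndarray       # int8 (n_variants, n_samples, 2), -1 missing
    source: np.ndarray        # int8 (n_variants, n_samples) SOURCE_* codes
    phasing_rate: float = 0.0  # sequenced het genotypes phased
    sequenced_ids: list[str] = field(default_factory=list)
    genotype_override: np.ndarray | None = None  # unphased genotype-level calls

    def genotype_calls(self) -> np.ndarray:
        """(n_variants, n_samples) genotypes; called iff both alleles are
        (or an unphased genotype-level call, e.g. from LD merging, exists)."""
        both = (self.alleles != MISSING).all(axis=2)
        out = np.where(both, self.alleles.sum(axis=2, dtype=np.int16), MISSING
                       ).astype(np.int8)
        if self.genotype_override is not None:
            ov = self.genotype_override
            out = np.where((out == MISSING) & (ov != MISSING), ov, out)
        return out

    def allele_call_rate(self, samples: Sequence[str] | None = None) -> float:
        sel = self._sel(samples)
        return float((self.alleles[:, sel] != MISSING).mean())

    def genotype_call_rate(self, samples: Sequence[str] | None = None) -> float:
        sel = self._sel(samples)
        return float((self.genotype_calls()[:, sel] != MISSING).mean())

    def _sel(self, samples: Sequence[str] | None) -> np.ndarray:
        if samples is None:
            return np.arange(len(self.sample_ids))
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([index[s] for s in samples])


def majority_allele(votes: Iterable[int],
                    fraction: float = MAJORITY_FRACTION) -> int | None:
    """The allele holding at least ``fraction`` of the votes, else None."""
    votes = list(votes)
    if not votes:
        return None
    for allele in (0, 1):
        if votes.count(allele) >= fraction * len(votes) - 1e-12:
            return allele
    return None


def nearest_framework_marker(markers: MarkerMap, chrom: int, bp: int) -> int:
    """Global index of the framework marker nearest ``bp`` (ties → left)."""
    sl = markers.chrom_slice(chrom)
    pos = markers.bp[sl]
    i = int(np.searchsorted(pos, bp))
    if i == 0:
        return sl.start
    if i >= len(pos):
        return sl.stop - 1
    left, right = bp - pos[i - 1], pos[i] - bp
    return sl.start + (i - 1 if left <= right else i)


def impute_variant(v: VariantRecord, D: CliqueDictionary, anchor: int,
                   sample_ids: Sequence[str], sequenced_ids: Sequence[str],
                   majority_fraction: float = MAJORITY_FRACTION
                   ) -> tuple[dict[tuple[str, int], int], int, int]:
    """Queue propagation of one variant through the cliques at ``anchor``.

    Returns (allele per haplotype, n sequenced het genotypes, n of them
    phased).  Conflicted cliques have their propagated calls withdrawn, but
    complements already propagated out of them are kept.
    """
    assigned: dict[tuple[str, int], int] = {}
    clique_calls: dict[tuple[str, int], list[tuple[str, int]]] = {}
    seq_index = {s: i for i, s in enumerate(sequenced_ids)}
    sequenced = set(sequenced_ids)
    queue: deque[tuple[str, int]] = deque()
    het_pending: dict[str, int] = {}
    n_het = 0
    for s in sorted(sequenced_ids):
        g = int(v.genotypes[seq_index[s]])
        if g == MISSING:
            continue
        if g in (0, 2):
            for k in (0, 1):
                assigned[(s, k)] = g // 2
                queue.append((s, k))
        else:
            n_het += 1
            het_pending[s] = 1
    dead_cliques: set[int] = set()
    withdrawn: set[tuple[str, int]] = set()
    while queue:
        hap = queue.popleft()
        cid = D.clique_id(anchor, hap)
        members = D.clique_members(anchor, hap)
        if cid is not None and cid in dead_cliques:
            continue
        votes = [assigned[m] for m in members
                 if m[0] in sequenced and m in assigned and m not in withdrawn]
        win = majority_allele(votes, majority_fraction)
        if win is None:
            if cid is not None:
                dead_cliques.add(cid)
            # withdraw propagated calls in this clique (keep sequenced-sample
            # alleles derived from their own genotypes)
            for m in members:
                if m in assigned and m[0] not in sequenced:
                    withdrawn.add(m)
            continue
        for m in members:
            if m in assigned:
                continue
            assigned[m] = win
            if m[0] in sequenced:
                s = m[0]
                g = int(v.genotypes[seq_index[s]])
                if g == 1 and het_pending.get(s):
                    other = (s, 1 - m[1])
                    if other not in assigned:
                        assigned[other] = 1 - win
                        queue.append(other)
                    het_pending[s] = 0
    for m in withdrawn:
        assigned.pop(m, None)
    n_phased = n_het - sum(het_pending.values())
    return assigned, n_het, n_phased


def impute_all(variants: Sequence[VariantRecord], D: CliqueDictionary,
               H: HaplotypeMatrix, sequenced_ids: Sequence[str],
               majority_fraction: float = MAJORITY_FRACTION,
               anchors: Sequence[int] | None = None) -> ImputedPanel:
    """Impute every variant independently (order-invariant).

    ``anchors`` optionally gives the dictionary marker per variant;
    otherwise the nearest framework marker of ``H.markers`` is used.
    """
    samples = H.sample_ids
    n_s = len(samples)
    alleles = np.full((len(variants), n_s, 2), MISSING, dtype=np.int8)
    source = np.full((len(variants), n_s), SOURCE_NONE, dtype=np.int8)
    index = {s: i for i, s in enumerate(samples)}
    seq_set = set(sequenced_ids)
    tot_het = tot_phased = 0
    for vi, v in enumerate(variants):
        anchor = (anchors[vi] if anchors is not None
                  else nearest_framework_marker(H.markers, v.chrom, v.bp))
        assigned, n_het, n_phased = impute_variant(v, D, anchor, samples,
                                                   sequenced_ids,
                                                   majority_fraction)
        tot_het += n_het
        tot_phased += n_phased
        for (s, k), a in assigned.items():
            if s in index:
                alleles[vi, index[s], k] = a
        for s in samples:
            si = index[s]
            if s in seq_set:
                source[vi, si] = SOURCE_OBSERVED
            elif (alleles[vi, si] != MISSING).all():
                source[vi, si] = SOURCE_PEDIGREE
    panel = ImputedPanel(list(samples), list(variants), alleles, source,
                         phasing_rate=(tot_phased / tot_het if tot_het else 1.0),
                         sequenced_ids=list(sequenced_ids))
    return panel


# ---------------------------------------------------------------------------
# Cross validation on framework markers
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    n_markers: int
    n_called: int
    n_concordant: int
    het_called: int
    het_concordant: int
    by_maf: "list[tuple[float, float, int, int]]"  # (maf_lo, maf_hi, called, concordant)

    @property
    def concordance(self) -> float:
        return self.n_concordant / self.n_called if self.n_called else float("nan")

    @property
    def het_concordance(self) -> float:
        return self.het_concordant / self.het_called if self.het_called else float("nan")


def cross_validate(G: GenotypeMatrix, D: CliqueDictionary,
                   sequenced_ids: Sequence[str], thin: int = 5,
                   majority_fraction: float = MAJORITY_FRACTION,
                   maf_bins: Sequence[float] = (0.0, 0.05, 0.1, 0.2, 0.5),
                   markers: Sequence[int] | None = None) -> ConcordanceReport:
    """Mask the framework genotypes of non-sequenced samples at every
    ``thin``-th framework marker, impute them through the cliques, and
    report overall and heterozygote concordance (het = called het by either
    source) by MAF bin."""
    if markers is None:
        avail = np.array(D.markers())
        markers = avail[::thin]
    masked = [s for s in G.sample_ids if s not in set(sequenced_ids)]
    midx = np.array([G.sample_index(s) for s in masked])
    seq_idx = np.array([G.sample_index(s) for s in sequenced_ids])
    maf = G.maf()
    n_called = n_conc = het_called = het_conc = 0
    bins = [[lo, hi, 0, 0] for lo, hi in zip(maf_bins[:-1], maf_bins[1:])]
    for m in markers:
        m = int(m)
        v = VariantRecord(int(G.markers.chrom[m]), int(G.markers.bp[m]),
                          str(G.markers.ref[m]), str(G.markers.alt[m]), True,
                          G.calls[seq_idx, m])
        assigned, _, _ = impute_variant(v, D, m, G.sample_ids, list(sequenced_ids),
                                        majority_fraction)
        for s, si in zip(masked, midx):
            a0 = assigned.get((s, 0), MISSING)
            a1 = assigned.get((s, 1), MISSING)
            truth_g = G.calls[si, m]
            if a0 == MISSING or a1 == MISSING or truth_g == MISSING:
                continue
            imp = a0 + a1
            n_called += 1
            ok = imp == truth_g
            n_conc += ok
            if imp == 1 or truth_g == 1:
                het_called += 1
                het_conc += ok
            for b in bins:
                if b[0] <= maf[m] < b[1] or (maf[m] == 0.5 and b[1] == 0.5):
                    b[2] += 1
                    b[3] += ok
    return ConcordanceReport(len(list(markers)), n_called, n_conc, het_called,
                             het_conc, [tuple(b) for b in bins])


# ---------------------------------------------------------------------------
# LD-call merging
# ---------------------------------------------------------------------------

def hard_call(probs: np.ndarray, min_prob: float = 0.99) -> np.ndarray:
    """Convert genotype probability triples to hard calls (missing unless
    the max probability exceeds ``min_prob``)."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError("probability array must be (n, 3)")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    best = probs.argmax(axis=1)
    return np.where(probs.max(axis=1) > min_prob, best, MISSING).astype(np.int8)


def merge_ld_calls(panel: ImputedPanel, ld_probs: dict[int, np.ndarray],
                   *, min_prob: float = 0.99, min_het_concordance: float = 0.99,
                   min_maf: float = 0.01) -> ImputedPanel:
    """Fill missing pedigree genotypes with LD-based calls.

    ``ld_probs[vi]`` holds (n_samples, 3) genotype probabilities for variant
    index ``vi``.  LD hard calls are made where max prob > ``min_prob``; a
    variant's LD calls are kept only if the pedigree/LD heterozygote
    concordance (over genotypes called by both, het by at least one) is
    ≥ ``min_het_concordance`` and its MAF ≥ ``min_maf``.  Pedigree calls are
    never overwritten.
    """
    geno = panel.genotype_calls()
    alleles = panel.alleles.copy()
    source = panel.source.copy()
    override = np.full(geno.shape, MISSING, dtype=np.int8)
    if panel.genotype_override is not None:
        override = panel.genotype_override.copy()
    for vi, probs in sorted(ld_probs.items()):
        v = panel.variants[vi]
        if v.maf < min_maf:
            continue
        ld = hard_call(probs, min_prob)
        ped_called = geno[vi] != MISSING
        both = ped_called & (ld != MISSING)
        het_any = both & ((geno[vi] == 1) | (ld == 1))
        if het_any.sum() > 0:
            conc = (geno[vi][het_any] == ld[het_any]).mean()
            if conc < min_het_concordance:
                continue
        fill = (~ped_called) & (ld != MISSING)
        for si in np.flatnonzero(fill):
            g = int(ld[si])
            if g in (0, 2):
                alleles[vi, si] = (g // 2, g // 2)
            else:
                override[vi, si] = 1  # unphased het: genotype-level call only
            source[vi, si] = SOURCE_LD
    return ImputedPanel(panel.sample_ids, panel.variants, alleles, source,
                        panel.phasing_rate, panel.sequenced_ids, override)


# ---------------------------------------------------------------------------
# Haploid PO export
# ---------------------------------------------------------------------------

def export_haploid_po_panels(H: HaplotypeMatrix, prefix: str | Path
                             ) -> tuple[Path, Path]:
    """Write "paternal haploid" and "maternal haploid" pseudo-sample GEN
    files: each haplotype becomes a homozygous diploid pseudo-sample;
    unphased sites are exported missing.  Chromosome-level PO flags select
    which slot is paternal; unassigned chromosomes fall back to slot order.
    """
    prefix = Path(prefix)
    paths = (prefix.with_suffix(".paternal.gen"), prefix.with_suffix(".maternal.gen"))
    mk = H.markers
    chroms = mk.chromosomes()
    for which, path in enumerate(paths):
        with open(path, "w") as fh:
            for m in range(len(mk)):
                ci = chroms.index(int(mk.chrom[m]))
                cells = []
                for s in range(len(H.sample_ids)):
                    po = H.po[s, ci]
                    slot = which if po != H.PO_SLOT0_MATERNAL else 1 - which
                    a = H.alleles[s, slot, m]
                    b = H.alleles[s, 1 - slot, m]
                    if a == MISSING or b == MISSING:  # unphased → missing
                        cells.append("0 0 0")
                    else:
                        cells.append("1 0 0" if a == 0 else "0 0 1")
                fh.write(f"{mk.chrom[m]} {mk.ids[m]} {mk.bp[m]} {mk.ref[m]} "
                         f"{mk.alt[m]} " + " ".join(cells) + "\n")
    return paths
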