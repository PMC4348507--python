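"""Genotype and haplotype containers, file IO, and framework-SNV QC.

Genotypes are stored as alt-allele counts in {0, 1, 2} with -1 for missing.
Haplotype alleles are in {0, 1} with -1 for unphased/unknown.  Marker
coordinates are 1-based base pairs as in VCF; all marker intervals elsewhere
in the package are half-open ``[start, end)`` over marker indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

log = logging.getLogger(__name__)

MISSING = -1


@dataclass
class MarkerMap:
    """Ordered biallelic markers: chromosome, bp, cM and alleles.

    Within a chromosome both bp and cM must be strictly increasing.  When no
    genetic map is available, cM positions are imputed at 1 cM/Mb.
    """

    chrom: np.ndarray          # int, 1..22
    bp: np.ndarray             # int, 1-based
    cm: np.ndarray             # float
    ref: np.ndarray            # str alleles
    alt: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        if self.cm is None:
            log.info("no genetic map provided; imputing cM as bp * 1e-6 (1 cM/Mb)")
            self.cm = self.bp * 1e-6
        self.cm = np.asarray(self.cm, dtype=np.float64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.ids is None:
            self.ids = np.array(
                [f"{c}:{p}" for c, p in zip(self.chrom, self.bp)], dtype=object
            )
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            if np.any(np.diff(self.bp[sel]) <= 0):
                raise ValueError(f"bp positions not strictly increasing on chrom {c}")
            if np.any(np.diff(self.cm[sel]) <= 0):
                raise ValueError(f"cM positions not strictly increasing on chrom {c}")

    def __len__(self) -> int:
        return len(self.bp)

    @property
    def n_markers(self) -> int:
        return len(self.bp)

    def chromosomes(self) -> list[int]:
        return [int(c) for c in np.unique(self.chrom)]

    def chrom_slice(self, c: int) -> slice:
        idx = np.flatnonzero(self.chrom == c)
        if idx.size == 0:
            raise KeyError(f"chromosome {c} not in map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, index: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.chrom[index], self.bp[index], self.cm[index],
            self.ref[index], self.alt[index], self.ids[index],
        )


@dataclass
class GenotypeMatrix:
    """samples × markers alt-allele counts with -1 missing."""

    sample_ids: list[str]
    markers: MarkerMap
    calls: np.ndarray  # int8 (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError("genotype matrix dimensions inconsistent with ids/map")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype values outside {missing,0,1,2}")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def row(self, sample: str) -> np.ndarray:
        return self.calls[self._index[sample]]

    def sample_index(self, sample: str) -> int:
        return self._index[sample]

    def marker_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker over all genotyped samples."""
        present = self.calls != MISSING
        n = 2 * present.sum(axis=0)
        alt = np.where(present, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return np.fmin(p, 1 - p)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sample_ids), self.markers.subset(index),
                              self.calls[:, index])


@dataclass
class HaplotypeMatrix:
    """Two haplotype rows per sample; slot 0 / slot 1 are the two parental
    haplotypes ("A"/"B"), whose paternal/maternal identity is resolved later
    by parental-origin assignment (per sample and chromosome).
    """

    sample_ids: list[str]
    markers: MarkerMap
    alleles: np.ndarray             # int8 (n_samples, 2, n_markers)
    po: np.ndarray | None = None    # int8 (n_samples, n_chroms): -1/0/1

    PO_UNASSIGNED = -1
    PO_SLOT0_PATERNAL = 0
    PO_SLOT0_MATERNAL = 1

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        n = len(self.sample_ids)
        if self.alleles.shape != (n, 2, len(self.markers)):
            raise ValueError("haplotype matrix dimensions inconsistent")
        if self.po is None:
            self.po = np.full((n, len(self.markers.chromosomes())), self.PO_UNASSIGNED,
                              dtype=np.int8)
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def sample_index(self, sample: str) -> int:
        return self._index[sample]

    def hap(self, sample: str, slot: int) -> np.ndarray:
        return self.alleles[self._index[sample], slot]

    def phased_mask(self) -> np.ndarray:
        """(n_samples, n_markers) — both slots non-missing."""
        return (self.alleles != MISSING).all(axis=1)

    def check_consistent(self, G: GenotypeMatrix) -> None:
        """Assert phased haplotype sums reconcile with input genotypes."""
        both = self.phased_mask()
        geno_ok = G.calls != MISSING
        chk = both & geno_ok
        sums = self.alleles[:, 0, :] + self.alleles[:, 1, :]
        if not np.array_equal(sums[chk], G.calls[chk]):
            raise AssertionError("haplotype sums contradict genotypes")

    @classmethod
    def empty(cls, sample_ids: Sequence[str], markers: MarkerMap) -> "HaplotypeMatrix":
        return cls(list(sample_ids), markers,
                   np.full((len(sample_ids), 2, len(markers)), MISSING, dtype=np.int8))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (``.vcf``) or PED/MAP (``.ped`` + ``.map``) genotype file.

    Markers come out sorted by (chrom, bp); multiallelic sites are excluded
    with a logged count.
    """
    path = Path(path)
    if path.suffix == ".ped":
        return _read_ped(path)
    return _read_vcf(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, bp, ref, alt, ids, rows = [], [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        chrom.append(int(var.CHROM.removeprefix("chr")))
        bp.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = var.genotype.array()[:, :2]
        calls = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        rows.append(calls.astype(np.int8))
    if n_multi:
        log.warning("excluded %d multiallelic site(s)", n_multi)
    if not rows:
        raise ValueError(f"no biallelic sites in {path}")
    calls = np.stack(rows, axis=1)
    order = np.lexsort((np.array(bp), np.array(chrom)))
    key = np.stack([np.array(chrom)[order], np.array(bp)[order]])
    if len(order) > 1 and np.any((np.diff(key[0]) == 0) & (np.diff(key[1]) == 0)):
        raise ValueError("duplicate (chrom, bp) positions")
    markers = MarkerMap(np.array(chrom)[order], np.array(bp)[order], None,
                        np.array(ref, dtype=object)[order],
                        np.array(alt, dtype=object)[order],
                        np.array(ids, dtype=object)[order])
    return GenotypeMatrix(samples, markers, calls[:, order])


def _read_ped(path: Path) -> GenotypeMatrix:
    map_path = path.with_suffix(".map")
    mp = [ln.split() for ln in map_path.read_text().splitlines() if ln.strip()]
    chrom = np.array([int(r[0]) for r in mp])
    ids = np.array([r[1] for r in mp], dtype=object)
    cm = np.array([float(r[2]) for r in mp])
    bp = np.array([int(r[3]) for r in mp])
    samples, rows = [], []
    allele_codes: list[dict] = [dict() for _ in mp]
    raw: list[list[tuple[str, str]]] = []
    for ln in path.read_text().splitlines():
        if not ln.strip():
            continue
        f = ln.split()
        samples.append(f[1])
        pairs = list(zip(f[6::2], f[7::2]))
        if len(pairs) != len(mp):
            raise ValueError("PED row length inconsistent with MAP")
        raw.append(pairs)
    # determine ref/alt per marker from observed alleles (sorted for determinism)
    ref, alt = [], []
    for m in range(len(mp)):
        seen = sorted({a for row in raw for a in row[m] if a != "0"})
        if len(seen) > 2:
            raise ValueError(f"more than two alleles at marker {ids[m]}")
        seen = (seen + ["A", "B"])[:2]
        ref.append(seen[0])
        alt.append(seen[1])
        allele_codes[m] = {seen[0]: 0, seen[1]: 1}
    for pairs in raw:
        row = np.empty(len(mp), dtype=np.int8)
        for m, (a, b) in enumerate(pairs):
            row[m] = MISSING if "0" in (a, b) else allele_codes[m][a] + allele_codes[m][b]
        rows.append(row)
    order = np.lexsort((bp, chrom))
    markers = MarkerMap(chrom[order], bp[order], cm[order] if cm.any() else None,
                        np.array(ref, dtype=object)[order],
                        np.array(alt, dtype=object)[order], ids[order])
    return GenotypeMatrix(samples, markers, np.stack(rows)[:, order])


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path: str | Path, markers: MarkerMap, sample_ids: Sequence[str],
              calls: np.ndarray | None = None,
              haplotypes: np.ndarray | None = None,
              extra_format: dict[str, np.ndarray] | None = None) -> None:
    """Write genotypes (unphased, ``/``) or haplotypes (phased sites with
    ``|``, unphased with ``/``) to an uncompressed VCF."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if extra_format:
            for tag in extra_format:
                fh.write(f'##FORMAT=<ID={tag},Number=1,Type=String,Description="{tag}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        fmt = "GT" + ("".join(":" + t for t in extra_format) if extra_format else "")
        for m in range(len(markers)):
            cells = []
            for s in range(len(sample_ids)):
                if haplotypes is not None:
                    a, b = haplotypes[s, 0, m], haplotypes[s, 1, m]
                    if a == MISSING or b == MISSING:
                        g = calls[s, m] if calls is not None else MISSING
                        cell = "./." if g == MISSING else ("0/1" if g == 1 else f"{g // 2}/{g // 2}")
                    else:
                        cell = f"{a}|{b}"
                else:
                    g = calls[s, m]
                    cell = "./." if g == MISSING else {0: "0/0", 1: "0/1", 2: "1/1"}[g]
                if extra_format:
                    cell += "".join(":" + str(v[s, m]) for v in extra_format.values())
                cells.append(cell)
            fh.write(f"{markers.chrom[m]}\t{markers.bp[m]}\t{markers.ids[m]}\t"
                     f"{markers.ref[m]}\t{markers.alt[m]}\t.\tPASS\t.\t{fmt}\t"
                     + "\t".join(cells) + "\n")


def write_reference_panel(H: HaplotypeMatrix, subset: Sequence[str],
                          prefix: str | Path) -> tuple[Path, Path]:
    """Export a HAPS/SAMPLE reference panel for the given (fully phased)
    samples: one marker per row, two 0/1 haplotype columns per sample."""
    idx = [H.sample_index(s) for s in subset]
    hp = H.alleles[idx]  # (k, 2, M)
    unphased = np.flatnonzero((hp == MISSING).any(axis=(0, 1)))
    if unphased.size:
        m = int(unphased[0])
        raise ValueError(
            f"unphased site {H.markers.ids[m]} (marker index {m}) in reference subset")
    prefix = Path(prefix)
    haps_path = prefix.with_suffix(".haps")
    sample_path = prefix.with_suffix(".sample")
    mk = H.markers
    with open(haps_path, "w") as fh:
        for m in range(len(mk)):
            cols = " ".join(f"{hp[k, 0, m]} {hp[k, 1, m]}" for k in range(len(idx)))
            fh.write(f"{mk.chrom[m]} {mk.ids[m]} {mk.bp[m]} {mk.ref[m]} {mk.alt[m]} {cols}\n")
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in subset:
            fh.write(f"{s} {s} 0\n")
    return haps_path, sample_path


def read_reference_panel(haps_path: str | Path) -> tuple[MarkerMap, np.ndarray]:
    """Inverse of :func:`write_reference_panel`; returns (map, (k,2,M) alleles)."""
    chrom, bp, ref, alt, ids, rows = [], [], [], [], [], []
    for ln in Path(haps_path).read_text().splitlines():
        f = ln.split()
        chrom.append(int(f[0]))
        ids.append(f[1])
        bp.append(int(f[2]))
        ref.append(f[3])
        alt.append(f[4])
        rows.append([int(x) for x in f[5:]])
    arr = np.array(rows, dtype=np.int8).T  # (2k, M)
    haps = arr.reshape(-1, 2, arr.shape[1])
    markers = MarkerMap(np.array(chrom), np.array(bp), None,
                        np.array(ref, dtype=object), np.array(alt, dtype=object),
                        np.array(ids, dtype=object))
    return markers, haps


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy–Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all-zero genotype counts")
    n_a = 2 * n_aa + n_ab            # minor-or-either allele count; symmetric
    n_rare = min(n_a, 2 * n - n_a)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(n_het) ∝ n! / (n_hom1! n_het! n_hom2!) * 2^n_het, multinomial
    # conditional on allele counts (Levene's exact distribution)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (hets * np.log(2) - gammaln(hom_r + 1) - gammaln(hets + 1)
            - gammaln(hom_c + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.flatnonzero(hets == n_ab)[0]]
    return float(p[p <= obs * (1 + 1e-12)].sum())


# 3x3x3 truth table: is (father, mother, child) Mendelian-possible?
def _mendel_possible() -> np.ndarray:
    ok = np.zeros((3, 3, 3), dtype=bool)
    for f in range(3):
        for m in range(3):
            fa = {0: (0,), 1: (0, 1), 2: (1,)}[f]
            mo = {0: (0,), 1: (0, 1), 2: (1,)}[m]
            for a in fa:
                for b in mo:
                    ok[f, m, a + b] = True
    return ok


_MENDEL_OK = _mendel_possible()


def mendelian_error_count(G: GenotypeMatrix, trios: Sequence[tuple[str, str, str]]
                          ) -> np.ndarray:
    """Per-marker count of trios whose (father, mother, child) genotype
    triple is impossible under Mendelian transmission.

    ``trios`` is a list of (father, mother, child) sample ids; missing
    genotypes are marginalized (a triple with a missing member only counts
    as an error if *no* completion of the missing genotypes is consistent).
    """
    # possible[f, m, c] with missing handled by OR over completions
    errors = np.zeros(len(G.markers), dtype=np.int64)
    for fa, mo, ch in trios:
        f, m, c = G.row(fa), G.row(mo), G.row(ch)
        fs = [np.arange(3)] * 1
        possible = np.zeros(len(G.markers), dtype=bool)
        for fg in range(3):
            fmask = (f == fg) | (f == MISSING)
            if not fmask.any():
                continue
            for mg in range(3):
                mmask = fmask & ((m == mg) | (m == MISSING))
                if not mmask.any():
                    continue
                for cg in range(3):
                    if _MENDEL_OK[fg, mg, cg]:
                        possible |= mmask & ((c == cg) | (c == MISSING))
        errors += ~possible
    return errors


def trios_from_pedigree(ped, samples: Iterable[str]) -> list[tuple[str, str, str]]:
    """All (father, mother, child) trios fully contained in ``samples``."""
    have = set(samples)
    out = []
    for fam in ped.nuclear_families():
        if fam.father_id in have and fam.mother_id in have:
            for ch in fam.child_ids:
                if ch in have:
                    out.append((fam.father_id, fam.mother_id, ch))
    return out


@dataclass
class QCReport:
    """Per-marker QC outcome; ``reason`` is '' for retained markers."""
    marker_ids: np.ndarray
    mendel_errors: np.ndarray
    hwe_p: np.ndarray
    call_rate: np.ndarray
    maf: np.ndarray
    reason: list[str]
    flagged_samples: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "marker": self.marker_ids, "mendel_errors": self.mendel_errors,
            "hwe_p": self.hwe_p, "call_rate": self.call_rate, "maf": self.maf,
            "filter": self.reason,
        })


def framework_qc(G: GenotypeMatrix, ped, *, max_mendel: int = 5,
                 hwe_threshold: float = 1e-3, min_call_rate: float = 0.95,
                 min_maf: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    """Framework-marker QC: drop markers with ≥ ``max_mendel`` Mendelian
    errors, HWE p < ``hwe_threshold`` or call rate < ``min_call_rate``; then
    restrict to MAF ≥ ``min_maf``.  Samples with call rate ≤ ``min_call_rate``
    are flagged (not removed)."""
    trios = trios_from_pedigree(ped, G.sample_ids)
    mendel = mendelian_error_count(G, trios)
    call_rate = G.marker_call_rate()
    maf = G.maf()
    hwe = np.ones(len(G.markers))
    for m in range(len(G.markers)):
        col = G.calls[:, m]
        counts = [(col == g).sum() for g in (0, 1, 2)]
        if sum(counts) > 0:
            hwe[m] = hwe_exact_p(*counts)
    reason = []
    for m in range(len(G.markers)):
        why = []
        if mendel[m] >= max_mendel:
            why.append("mendel")
        if hwe[m] < hwe_threshold:
            why.append("hwe")
        if call_rate[m] < min_call_rate:
            why.append("call_rate")
        if not why and not (maf[m] >= min_maf):
            why.append("maf")
        reason.append("+".join(why))
    keep = np.array([r == "" for r in reason])
    flagged = [s for s, cr in zip(G.sample_ids, G.sample_call_rate())
               if cr <= min_call_rate]
    report = QCReport(G.markers.ids.copy(), mendel, hwe, call_rate, maf, reason, flagged)
    return G.subset_markers(np.flatnonzero(keep)), report
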