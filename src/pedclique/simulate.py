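"""Gene-dropping simulator: pedigrees, genotypes, sequence panels, truth.

The generator emulates a multi-generation founder-population study: a deep
pedigree whose most recent generations are genotyped at dense framework
SNVs, with a small subset of individuals "sequenced" at additional
sequence-only variants.  Founder haplotypes are drawn in linkage
equilibrium from per-marker allele frequencies; each meiosis recombines
with a Poisson number of breakpoints (mean = map length in Morgans, no
interference) placed uniformly on the cM map.  Every transmitted allele
carries a founder-haplotype label, so true IBD (label equality) is known
everywhere — it is an equivalence relation at each marker by construction.

The top generations of the pedigree are recorded but *not* genotyped,
mirroring study designs where the genotyped cohort sits inside a deeper
known pedigree: the top genotyped generation ("quasi-founders") are then
relatives of each other through ungenotyped ancestors, which is what gives
surrogate-parent phasing and clique-kinship parental-origin assignment
their signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, HaplotypeMatrix, MarkerMap
from .pedigree import Pedigree


@dataclass
class SimConfig:
    generations: int = 3                 # genotyped generations
    ungenotyped_generations: int = 2     # ancestral depth above them
    n_families: int = 24                 # couples formed per generation
    mean_children: float = 2.8           # Poisson, truncated to [1, max_children]
    max_children: int = 6
    n_framework_markers: int = 2000
    n_sequence_variants: int = 500
    n_chromosomes: int = 2
    chrom_length_cm: float = 100.0
    chrom_length_bp: int = 100_000_000
    framework_af: tuple[float, float] = (0.1, 0.9)   # uniform alt-freq range
    sequence_af: tuple[float, float] = (0.02, 0.5)
    genotyping_error: float = 0.001
    missing_rate: float = 0.002
    n_sequenced: int = 20
    sequenced_kinship_cap: float = 0.1   # pairwise kinship bound for the panel
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("generations", "ungenotyped_generations", "n_families",
                     "n_framework_markers", "n_sequence_variants", "n_chromosomes",
                     "n_sequenced"):
            if getattr(self, name) < (0 if name == "ungenotyped_generations" else 1):
                raise ValueError(f"{name} must be positive")
        for name in ("genotyping_error", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth from gene dropping.

    ``labels``/``haplotypes`` cover *all* pedigree members over the union of
    framework and sequence-only markers; slot 0 of every non-founder is the
    father-derived haplotype (true parental origin).
    """

    sample_ids: list[str]
    markers: MarkerMap                    # union map
    framework_mask: np.ndarray            # bool per marker
    labels: np.ndarray                    # int32 (n, 2, M) founder-haplotype label
    haplotypes: np.ndarray                # int8 (n, 2, M)
    breakpoints: dict[tuple[str, int], list[float]] = field(default_factory=dict)

    def sample_index(self, s: str) -> int:
        return self.sample_ids.index(s)

    def ibd_fraction(self, i: str, j: str) -> float:
        """Realized genome-wide IBD fraction: expected probability that a
        random allele from i and one from j share a founder label."""
        a = self.labels[self.sample_index(i)]
        b = self.labels[self.sample_index(j)]
        share = (a[:, None, :] == b[None, :, :]).mean(axis=(0, 1))
        return float(share.mean())

    def true_ibd_intervals(self, hap_a: tuple[str, int], hap_b: tuple[str, int]
                           ) -> dict[int, list[tuple[int, int]]]:
        """Per-chromosome half-open marker intervals where the two haplotypes
        carry the same founder label."""
        la = self.labels[self.sample_index(hap_a[0]), hap_a[1]]
        lb = self.labels[self.sample_index(hap_b[0]), hap_b[1]]
        eq = la == lb
        out: dict[int, list[tuple[int, int]]] = {}
        for c in self.markers.chromosomes():
            sl = self.markers.chrom_slice(c)
            m = eq[sl].astype(np.uint8)
            edges = np.diff(np.concatenate(([0], m, [0])))
            starts = np.flatnonzero(edges == 1) + sl.start
            ends = np.flatnonzero(edges == -1) + sl.start
            ivals = [(int(s), int(e)) for s, e in zip(starts, ends)]
            if ivals:
                out[c] = ivals
        return out


@dataclass
class StudyData:
    """Observed data handed to the pipeline, plus the generating truth."""

    pedigree: Pedigree
    framework: GenotypeMatrix             # genotyped samples × framework markers
    sequenced_ids: list[str]
    seq_variants: MarkerMap               # sequence-only markers
    seq_calls: np.ndarray                 # (n_sequenced, n_seq_variants)
    truth: SimTruth
    framework_index: np.ndarray           # union-map indices of framework markers
    seq_index: np.ndarray                 # union-map indices of sequence-only markers


# ---------------------------------------------------------------------------


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None
                      ) -> Pedigree:
    """Layered multi-generation pedigree; the last ``cfg.generations`` layers
    are genotyped.  Couples are formed within a layer avoiding siblings."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    total_layers = cfg.ungenotyped_generations + cfg.generations
    individuals: dict[str, tuple[str | None, str | None, int]] = {}
    layers: list[list[str]] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:04d}"

    founders = []
    for _ in range(2 * cfg.n_families):
        iid = new_id()
        individuals[iid] = (None, None, 0)
        founders.append(iid)
    sexes = {iid: (1 if k < cfg.n_families else 2)
             for k, iid in enumerate(founders)}
    couples = list(zip(founders[:cfg.n_families], founders[cfg.n_families:]))
    layers.append(founders)
    family_of: dict[str, int] = {}
    for layer in range(1, total_layers):
        children: list[str] = []
        for fam_idx, (fa, mo) in enumerate(couples):
            k = 0
            while not (1 <= k <= cfg.max_children):
                k = rng.poisson(cfg.mean_children)
            for _ in range(k):
                iid = new_id()
                sexes[iid] = int(rng.integers(1, 3))
                individuals[iid] = (fa, mo, sexes[iid])
                family_of[iid] = fam_idx + layer * 10000
                children.append(iid)
        layers.append(children)
        if layer == total_layers - 1:
            break
        males = [c for c in children if sexes[c] == 1]
        females = [c for c in children if sexes[c] == 2]
        rng.shuffle(males)
        rng.shuffle(females)
        couples = []
        used: set[str] = set()
        for m in males:
            if len(couples) >= cfg.n_families:
                break
            for f in females:
                if f in used or family_of[f] == family_of[m]:
                    continue
                couples.append((m, f))
                used.add(f)
                break
    for iid, (fa, mo, _) in list(individuals.items()):
        individuals[iid] = (fa, mo, sexes[iid])
    genotyped = {iid for layer in layers[cfg.ungenotyped_generations:] for iid in layer}
    return Pedigree(individuals, genotyped=genotyped)


def _make_union_map(cfg: SimConfig, rng: np.random.Generator
                    ) -> tuple[MarkerMap, np.ndarray, np.ndarray]:
    """Union marker map with framework markers evenly spread and
    sequence-only variants uniformly interleaved; returns (map, framework
    mask, alt-allele frequencies)."""
    per_chrom_fw = np.full(cfg.n_chromosomes, cfg.n_framework_markers // cfg.n_chromosomes)
    per_chrom_fw[: cfg.n_framework_markers % cfg.n_chromosomes] += 1
    per_chrom_sq = np.full(cfg.n_chromosomes, cfg.n_sequence_variants // cfg.n_chromosomes)
    per_chrom_sq[: cfg.n_sequence_variants % cfg.n_chromosomes] += 1
    chrom, bp, cm, is_fw, freq = [], [], [], [], []
    bp_per_cm = cfg.chrom_length_bp / cfg.chrom_length_cm
    for c in range(1, cfg.n_chromosomes + 1):
        nf, ns = int(per_chrom_fw[c - 1]), int(per_chrom_sq[c - 1])
        fw_cm = (np.arange(nf) + 0.5) * cfg.chrom_length_cm / nf
        sq_cm = rng.uniform(0, cfg.chrom_length_cm, size=ns)
        pos = np.concatenate([fw_cm, sq_cm])
        fw_flag = np.concatenate([np.ones(nf, bool), np.zeros(ns, bool)])
        f = np.concatenate([rng.uniform(*cfg.framework_af, size=nf),
                            rng.uniform(*cfg.sequence_af, size=ns)])
        order = np.argsort(pos, kind="stable")
        pos, fw_flag, f = pos[order], fw_flag[order], f[order]
        # enforce distinct bp / strictly increasing cm
        pos += np.arange(len(pos)) * 1e-9
        bps = np.unique(np.round(pos * bp_per_cm).astype(np.int64))
        while len(bps) < len(pos):  # resolve rounding collisions
            pos += np.arange(len(pos)) * 1e-6
            bps = np.unique(np.round(pos * bp_per_cm).astype(np.int64))
        chrom.extend([c] * len(pos))
        cm.extend(pos)
        bp.extend(bps)
        is_fw.extend(fw_flag)
        freq.extend(f)
    n = len(chrom)
    ref = np.array(["A"] * n, dtype=object)
    alt = np.array(["G"] * n, dtype=object)
    markers = MarkerMap(np.array(chrom), np.array(bp), np.array(cm), ref, alt)
    return markers, np.array(is_fw), np.array(freq)


def gene_drop(ped: Pedigree, cfg: SimConfig,
              rng: np.random.Generator | None = None,
              markers: MarkerMap | None = None,
              framework_mask: np.ndarray | None = None,
              freqs: np.ndarray | None = None) -> tuple[HaplotypeMatrix, SimTruth]:
    """Drop founder alleles through the pedigree with recombination.

    Returns the true haplotypes of every pedigree member (as a
    HaplotypeMatrix) and the SimTruth with founder-haplotype labels.
    """
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    if markers is None:
        markers, framework_mask, freqs = _make_union_map(cfg, rng)
    ids = ped.ids  # founders-first topological order
    n, M = len(ids), len(markers)
    haps = np.zeros((n, 2, M), dtype=np.int8)
    labels = np.zeros((n, 2, M), dtype=np.int32)
    idx = {s: i for i, s in enumerate(ids)}
    breakpoints: dict[tuple[str, int], list[float]] = {}
    next_label = 1
    chrom_slices = [markers.chrom_slice(c) for c in markers.chromosomes()]
    for iid in ids:
        i = idx[iid]
        par = ped.parents(iid)
        if par is None:
            for k in (0, 1):
                haps[i, k] = rng.random(M) < freqs
                labels[i, k] = next_label
                next_label += 1
        else:
            for k, parent in enumerate(par):  # slot 0 = father-derived
                p = idx[parent]
                bks: list[float] = []
                for sl in chrom_slices:
                    cm = markers.cm[sl]
                    length = float(cm[-1] - cm[0]) if len(cm) > 1 else 0.0
                    nb = rng.poisson(length / 100.0)
                    b = np.sort(rng.uniform(cm[0], cm[-1], size=nb))
                    start = int(rng.integers(0, 2))
                    slot = (start + np.searchsorted(b, cm, side="right")) % 2
                    ar = np.arange(sl.start, sl.stop)
                    haps[i, k, sl] = haps[p, slot, ar]
                    labels[i, k, sl] = labels[p, slot, ar]
                    bks.extend(float(x) for x in b)
                breakpoints[(iid, k)] = bks
    truth = SimTruth(list(ids), markers, framework_mask, labels, haps, breakpoints)
    H = HaplotypeMatrix(list(ids), markers, haps.copy())
    return H, truth


# ---------------------------------------------------------------------------


def _apply_genotype_error(calls: np.ndarray, error: float, missing: float,
                          rng: np.random.Generator) -> np.ndarray:
    """With probability ``error`` replace a genotype by one of the other two
    values (uniformly); with probability ``missing`` set it missing."""
    out = calls.copy()
    if error > 0:
        hit = rng.random(out.shape) < error
        shift = rng.integers(1, 3, size=out.shape)
        out = np.where(hit, (out + shift) % 3, out).astype(np.int8)
    if missing > 0:
        out[rng.random(out.shape) < missing] = MISSING
    return out


def select_sequenced(ped: Pedigree, n: int, kinship_cap: float = 0.1,
                     candidates: Sequence[str] | None = None) -> list[str]:
    """Greedy sequencing-panel selection: repeatedly add the individual with
    the highest mean kinship to the not-yet-selected genotyped individuals,
    subject to pairwise kinship < ``kinship_cap`` with those already
    selected.  Returns fewer than ``n`` (with a warning) when infeasible."""
    import warnings

    pool = sorted(candidates if candidates is not None else ped.genotyped)
    selected: list[str] = []
    while len(selected) < n:
        best, best_score = None, -1.0
        rest = [s for s in pool if s not in selected]
        for cand in rest:
            if any(ped.kinship(cand, s) >= kinship_cap for s in selected):
                continue
            others = [s for s in rest if s != cand]
            score = float(np.mean([ped.kinship(cand, o) for o in others])) if others else 0.0
            if score > best_score:
                best, best_score = cand, score
        if best is None:
            warnings.warn(f"sequencing panel infeasible at kinship cap {kinship_cap}: "
                          f"selected {len(selected)} of {n}")
            break
        selected.append(best)
    return selected


def make_study(ped: Pedigree, truth: SimTruth, cfg: SimConfig,
               rng: np.random.Generator | None = None) -> StudyData:
    """Observed study data: framework genotypes for the genotyped samples
    (with genotyping error and missingness) and a sequenced panel over the
    sequence-only variants for the greedily selected subset."""
    rng = np.random.default_rng(cfg.seed + 2 if rng is None else rng)
    genotyped = [s for s in truth.sample_ids if s in ped.genotyped]
    gidx = [truth.sample_index(s) for s in genotyped]
    true_geno = truth.haplotypes.sum(axis=1, dtype=np.int8)  # (n_all, M)
    # framework panels are ascertained common markers: drop framework
    # markers whose realized cohort MAF fell below 5% through drift
    p = true_geno[gidx].mean(axis=0) / 2.0
    ascertained = truth.framework_mask & (np.minimum(p, 1 - p) >= 0.05)
    fw = np.flatnonzero(ascertained)
    sq = np.flatnonzero(~truth.framework_mask)
    fw_calls = _apply_genotype_error(true_geno[np.ix_(gidx, fw)],
                                     cfg.genotyping_error, cfg.missing_rate, rng)
    framework = GenotypeMatrix(genotyped, truth.markers.subset(fw), fw_calls)
    sequenced = select_sequenced(ped, cfg.n_sequenced, cfg.sequenced_kinship_cap,
                                 candidates=genotyped)
    sidx = [truth.sample_index(s) for s in sequenced]
    seq_calls = _apply_genotype_error(true_geno[np.ix_(sidx, sq)],
                                      cfg.genotyping_error, cfg.missing_rate, rng)
    return StudyData(ped, framework, sequenced, truth.markers.subset(sq), seq_calls,
                     truth, fw, sq)


def simulate_study(cfg: SimConfig) -> StudyData:
    """Convenience wrapper: pedigree → gene drop → observed study data."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    _, truth = gene_drop(ped, cfg, rng)
    return make_study(ped, truth, cfg, rng)
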