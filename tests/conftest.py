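"""Shared fixtures: simulated studies at two scales.

``small_study`` is a compact gene-dropped cohort for module-level tests;
``headline_study`` runs the full pipeline (phase → IBD → cliques → impute)
at the default study scale once per session for the accuracy benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from pedclique import clique_index, ibd, imputation, phasing
from pedclique.genotype_io import MISSING
from pedclique.simulate import (SimConfig, StudyData, gene_drop, make_study,
                                simulate_pedigree)


@dataclass
class PipelineResult:
    study: StudyData
    H: "phasing.HaplotypeMatrix"
    stats: "phasing.PhaseStats"
    store: ibd.IBDSegmentStore
    D: clique_index.CliqueDictionary
    panel: imputation.ImputedPanel
    anchors: list[int]

    @property
    def truth(self):
        return self.study.truth

    @property
    def ped(self):
        return self.study.pedigree


def run_pipeline(cfg: SimConfig, extra_markers=(), po_thin: int | None = None
                 ) -> PipelineResult:
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    _, truth = gene_drop(ped, cfg, rng)
    study = make_study(ped, truth, cfg, rng)
    H, stats = phasing.phase_cohort(ped, study.framework, truth=truth)
    store = ibd.pairwise_ibd(H, ped)
    sq = study.seq_variants
    anchors = [imputation.nearest_framework_marker(H.markers, int(c), int(b))
               for c, b in zip(sq.chrom, sq.bp)]
    want = set(anchors) | set(extra_markers)
    if po_thin:
        want.update(range(0, len(H.markers), po_thin))
    D = clique_index.build_dictionary(store, sorted(want))
    variants = [imputation.VariantRecord(int(sq.chrom[i]), int(sq.bp[i]),
                                         str(sq.ref[i]), str(sq.alt[i]), True,
                                         study.seq_calls[:, i])
                for i in range(len(sq))]
    panel = imputation.impute_all(variants, D, H, study.sequenced_ids,
                                  anchors=anchors)
    return PipelineResult(study, H, stats, store, D, panel, anchors)


SMALL_CFG = SimConfig(n_families=8, generations=2, ungenotyped_generations=2,
                      n_framework_markers=800, n_sequence_variants=120,
                      n_chromosomes=1, n_sequenced=10, seed=11)


@pytest.fixture(scope="session")
def small_study() -> StudyData:
    cfg = SMALL_CFG
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    _, truth = gene_drop(ped, cfg, rng)
    return make_study(ped, truth, cfg, rng)


@pytest.fixture(scope="session")
def small_pipeline() -> PipelineResult:
    return run_pipeline(SMALL_CFG)


@pytest.fixture(scope="session")
def headline_pipeline() -> PipelineResult:
    """The default-scale study with the full pipeline applied."""
    cfg = SimConfig(seed=1)
    return run_pipeline(cfg, po_thin=25)


def genotype_concordance(panel: imputation.ImputedPanel, study: StudyData
                         ) -> tuple[float, float]:
    """(concordance on called genotypes, genotype call rate) for the
    non-sequenced samples against simulation truth."""
    geno = panel.genotype_calls()
    nonseq = [s for s in panel.sample_ids if s not in set(study.sequenced_ids)]
    nz = np.array([panel.sample_ids.index(s) for s in nonseq])
    tidx = np.array([study.truth.sample_index(s) for s in nonseq])
    tg = study.truth.haplotypes.sum(axis=1)[:, study.seq_index][tidx].T
    called = geno[:, nz] != MISSING
    conc = float((geno[:, nz][called] == tg[called]).mean())
    return conc, float(called.mean())


@pytest.fixture(scope="session")
def sibling_ibd2_truth():
    """A sibling-rich gene drop with truth-derived IBD2 intervals: IBD2 is
    essentially a full-sibling phenomenon, so sib pairs supply the ≥10⁴
    covering (pair, variant) instances the estimator checks need."""
    from pedclique.ibd import intersect_intervals, union_intervals
    from pedclique.simulate import SimConfig, gene_drop, simulate_pedigree

    cfg = SimConfig(n_families=24, generations=2, ungenotyped_generations=0,
                    n_framework_markers=1000, n_sequence_variants=10,
                    n_chromosomes=1, n_sequenced=4, mean_children=4.0, seed=9)
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    _, truth = gene_drop(ped, cfg, rng)
    sib_pairs = []
    for fam in ped.nuclear_families():
        kids = list(fam.child_ids)
        for i, a in enumerate(kids):
            sib_pairs.extend((a, b) for b in kids[i + 1:])
    ibd2 = {}
    for a, b in sib_pairs:
        p1 = intersect_intervals(
            truth.true_ibd_intervals((a, 0), (b, 0)).get(1, []),
            truth.true_ibd_intervals((a, 1), (b, 1)).get(1, []))
        p2 = intersect_intervals(
            truth.true_ibd_intervals((a, 0), (b, 1)).get(1, []),
            truth.true_ibd_intervals((a, 1), (b, 0)).get(1, []))
        iv = union_intervals(p1 + p2)
        if iv:
            ibd2[(a, b)] = {1: iv}
    ids = sorted({s for p in ibd2 for s in p})
    return truth, ibd2, ids
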