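import itertools

import numpy as np
import pytest

from pedclique.genotype_io import MISSING, HaplotypeMatrix, MarkerMap
from pedclique.ibd import (HMMParams, IBDSegment, IBDSegmentStore,
                           batch_posteriors, default_lambda, extract_segments,
                           genome_ibd_fraction, haplotype_pairs, hmm_posterior,
                           ibd2_segments, pairwise_ibd, union_intervals,
                           intersect_intervals)
from pedclique.pedigree import Pedigree


def make_map(cm, chrom=1):
    cm = np.asarray(cm, dtype=float)
    n = len(cm)
    return MarkerMap(np.full(n, chrom), (cm * 1e6).astype(np.int64) + 1, cm,
                     np.array(["A"] * n, dtype=object),
                     np.array(["G"] * n, dtype=object))


def brute_force_posterior(hapA, hapB, cm, freqs, pi, lam, eps):
    """Oracle: sum over all 2^M hidden state paths explicitly."""
    M = len(hapA)
    d = np.diff(cm)

    def emit(state, t):
        if hapA[t] == MISSING or hapB[t] == MISSING:
            return 1.0
        match = hapA[t] == hapB[t]
        if state == 1:
            return (1 - eps) ** 2 + eps ** 2 if match else 2 * eps * (1 - eps)
        p, q = freqs[t], 1 - freqs[t]
        return p * p + q * q if match else 2 * p * q

    def trans(a, b, t):
        e = np.exp(-lam * d[t - 1])
        p_to_ibd = pi + (1 - pi) * e if a == 1 else pi * (1 - e)
        return p_to_ibd if b == 1 else 1 - p_to_ibd

    total = np.zeros(M)
    norm = 0.0
    for path in itertools.product([0, 1], repeat=M):
        p = (pi if path[0] == 1 else 1 - pi) * emit(path[0], 0)
        for t in range(1, M):
            p *= trans(path[t - 1], path[t], t) * emit(path[t], t)
        norm += p
        for t in range(M):
            if path[t] == 1:
                total[t] += p
    return total / norm


class TestHmmPosterior:
    def test_single_marker_is_bayes_update(self):
        mk = make_map([0.0])
        params = HMMParams(phi=0.1, eps=0.01)
        hapA = np.array([1], dtype=np.int8)
        hapB = np.array([1], dtype=np.int8)
        freqs = np.array([0.3])
        post = hmm_posterior(hapA, hapB, mk, params, freqs)
        pi = params.pi
        e_ibd = (1 - 0.01) ** 2 + 0.01 ** 2
        e_non = 0.3 ** 2 + 0.7 ** 2
        expected = pi * e_ibd / (pi * e_ibd + (1 - pi) * e_non)
        assert post[0] == pytest.approx(expected, abs=1e-12)

    def test_huge_lambda_decouples_markers(self):
        mk = make_map([0.0, 1.0, 2.0, 3.0])
        params = HMMParams(phi=0.05, lam=1e6, eps=0.01)
        hapA = np.array([1, 0, 1, 0], dtype=np.int8)
        hapB = np.array([1, 1, 1, 0], dtype=np.int8)
        freqs = np.array([0.5, 0.2, 0.8, 0.4])
        post = hmm_posterior(hapA, hapB, mk, params, freqs)
        pi = params.pi
        for t in range(4):
            match = hapA[t] == hapB[t]
            e_ibd = (1 - 0.01) ** 2 + 0.01 ** 2 if match else 2 * 0.01 * 0.99
            p = freqs[t]
            e_non = p * p + (1 - p) ** 2 if match else 2 * p * (1 - p)
            expected = pi * e_ibd / (pi * e_ibd + (1 - pi) * e_non)
            assert post[t] == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_path_sum(self, seed):
        rng = np.random.default_rng(seed)
        M = 3 + seed * 2  # 3, 5, 7 markers
        cm = np.sort(rng.uniform(0, 10, M))
        mk = make_map(cm)
        freqs = rng.uniform(0.1, 0.9, M)
        hapA = rng.integers(0, 2, M).astype(np.int8)
        hapB = rng.integers(0, 2, M).astype(np.int8)
        hapB[0] = MISSING  # exercise missing emission too
        params = HMMParams(phi=0.15, lam=0.05, eps=0.02)
        post = hmm_posterior(hapA, hapB, mk, params, freqs)
        oracle = brute_force_posterior(hapA, hapB, cm, freqs, params.pi,
                                       params.lam, params.eps)
        np.testing.assert_allclose(post, oracle, atol=1e-10)

    def test_identical_long_haplotypes_high_interior_posterior(self):
        rng = np.random.default_rng(0)
        M = 500
        mk = make_map(np.arange(M) * 0.1)
        hap = rng.integers(0, 2, M).astype(np.int8)
        params = HMMParams(phi=1 / 32, eps=0.001)
        post = hmm_posterior(hap, hap.copy(), mk, params,
                             np.full(M, 0.5))
        assert post[50:-50].min() >= 0.99

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(4)
        M = 60
        mk = make_map(np.arange(M) * 0.5)
        a = rng.integers(0, 2, M).astype(np.int8)
        b = rng.integers(0, 2, M).astype(np.int8)
        params = HMMParams(phi=0.1, eps=0.01)
        f = rng.uniform(0.2, 0.8, M)
        np.testing.assert_allclose(hmm_posterior(a, b, mk, params, f),
                                   hmm_posterior(b, a, mk, params, f),
                                   atol=1e-14)

    def test_no_underflow_on_long_chromosome(self):
        M = 100_000
        mk = make_map(np.arange(M) * 0.001)
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, M).astype(np.int8)
        b = rng.integers(0, 2, M).astype(np.int8)
        params = HMMParams(phi=0.05, eps=0.01)
        post = hmm_posterior(a, b, mk, params, np.full(M, 0.5))
        assert np.isfinite(post).all()
        assert post.min() >= 0 and post.max() <= 1


class TestDefaultLambda:
    def test_meiosis_rule(self):
        assert default_lambda(0.25) == pytest.approx(0.01)   # 1 meiosis
        assert default_lambda(1 / 64) == pytest.approx(0.05)  # 5 meioses


class TestExtractSegments:
    def test_all_low_gives_empty(self):
        mk = make_map(np.arange(50) * 0.1)
        assert extract_segments(np.full(50, 0.1), mk) == []

    def test_all_high_gives_full_span(self):
        mk = make_map(np.arange(100) * 0.1)
        segs = extract_segments(np.full(100, 0.99), mk)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 100)

    def test_interior_run_has_half_open_bounds(self):
        mk = make_map(np.arange(60) * 0.1)
        post = np.full(60, 0.1)
        post[17:37] = 0.95
        segs = extract_segments(post, mk)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (17, 37)
        assert segs[0].mean_posterior == pytest.approx(0.95)

    def test_short_runs_discarded(self):
        mk = make_map(np.arange(30) * 0.1)
        post = np.full(30, 0.1)
        post[5:12] = 0.9  # 7 markers < default 10
        assert extract_segments(post, mk) == []


class TestPairEnumeration:
    def test_two_samples_give_six_pairs(self):
        assert len(list(haplotype_pairs(["a", "b"]))) == 6

    def test_excluding_within_pairs(self):
        assert len(list(haplotype_pairs(["a", "b"], include_within=False))) == 4

    def test_study_scale_pair_count(self):
        # 2n haplotypes for n = 1,415 samples → 2830·2829/2 pairs
        n = 1415
        count = sum(1 for _ in itertools.combinations(range(2 * n), 2))
        assert count == 4_003_035


def _seg(a, b, chrom, start, end, post=0.99):
    return IBDSegment(a, b, chrom, start, end, start * 1000, end * 1000, post)


class TestIntervalOps:
    def test_union_merges_overlaps(self):
        assert union_intervals([(0, 10), (5, 20), (30, 40)]) == [(0, 20), (30, 40)]

    def test_intersection(self):
        assert intersect_intervals([(0, 10), (20, 30)], [(5, 25)]) == [(5, 10), (20, 25)]


class TestGenomeIbdFraction:
    def test_no_segments_zero(self):
        mk = make_map(np.arange(100) * 1.0)
        assert genome_ibd_fraction(IBDSegmentStore(), ("a", "b"), mk) == 0.0

    def test_full_span_is_one(self):
        mk = make_map(np.arange(100) * 1.0)
        store = IBDSegmentStore()
        store.add(_seg(("a", 0), ("b", 0), 1, 0, 100))
        assert genome_ibd_fraction(store, ("a", "b"), mk) == pytest.approx(1.0)

    def test_overlapping_segments_counted_once(self):
        mk = make_map(np.arange(100) * 1.0)
        store = IBDSegmentStore()
        store.add(_seg(("a", 0), ("b", 0), 1, 0, 60))
        store.add(_seg(("a", 1), ("b", 0), 1, 40, 80))
        # union covers markers 0..79 → cM 0..79 of 99
        assert genome_ibd_fraction(store, ("a", "b"), mk) == pytest.approx(79 / 99)


class TestIbd2Segments:
    def test_both_pairings_required(self):
        store = IBDSegmentStore()
        store.add(_seg(("a", 0), ("b", 0), 1, 0, 50))
        assert ibd2_segments(store, ("a", "b")) == {}  # IBD1 only

    def test_intersection_of_disjoint_pairings(self):
        store = IBDSegmentStore()
        store.add(_seg(("a", 0), ("b", 0), 1, 0, 50))
        store.add(_seg(("a", 1), ("b", 1), 1, 20, 80))
        assert ibd2_segments(store, ("a", "b")) == {1: [(20, 50)]}

    def test_unrelated_founders_empty(self, small_pipeline):
        ped = small_pipeline.ped
        founders = [s for s in sorted(ped.genotyped)
                    if all(p not in ped.genotyped for p in (ped.parents(s) or ()))]
        a = founders[0]
        b = next(f for f in founders if ped.kinship(a, f) == 0)
        assert ibd2_segments(small_pipeline.store, (a, b)) == {}


def _slot_flips(res):
    """Per (sample, chromosome): 1 if the inferred slot order is swapped
    relative to the true haplotypes (slot orientation of quasi-founders is
    arbitrary, so truth comparisons must align it first)."""
    truth, H, G = res.truth, res.H, res.study.framework
    pos = {(int(c), int(b)): i
           for i, (c, b) in enumerate(zip(truth.markers.chrom, truth.markers.bp))}
    t_idx = np.array([pos[(int(c), int(b))]
                      for c, b in zip(H.markers.chrom, H.markers.bp)])
    flips = {}
    for s in H.sample_ids:
        si = H.sample_index(s)
        ti = truth.sample_index(s)
        for c in H.markers.chromosomes():
            sl = H.markers.chrom_slice(c)
            ph = (H.alleles[si, :, sl] != MISSING).all(axis=0)
            obs = H.alleles[si, :, sl][:, ph]
            tru = truth.haplotypes[ti][:, t_idx[sl][ph]]
            same = ((obs[0] == tru[0]) & (obs[1] == tru[1])).sum()
            swap = ((obs[0] == tru[1]) & (obs[1] == tru[0])).sum()
            flips[(s, c)] = int(swap > same)
    return flips


class TestPairwiseIbd:
    def test_true_tracts_recovered(self, headline_pipeline):
        """≥90% of true IBD tracts ≥2 cM between relatives are overlapped by
        a called segment (after aligning slot orientation to truth)."""
        res = headline_pipeline
        truth, ped, H = res.truth, res.ped, res.H
        mk = H.markers
        pos = {(int(c), int(b)): i
               for i, (c, b) in enumerate(zip(truth.markers.chrom, truth.markers.bp))}
        fw_of_union = {pos[(int(c), int(b))]: i
                       for i, (c, b) in enumerate(zip(mk.chrom, mk.bp))}
        flips = _slot_flips(res)
        ids = sorted(ped.genotyped)
        rng = np.random.default_rng(0)
        hit = tot = 0
        for _ in range(400):
            i, j = rng.choice(len(ids), 2, replace=False)
            a, b = ids[i], ids[j]
            if ped.kinship(a, b) < 1 / 32:
                continue
            sa, sb = int(rng.integers(2)), int(rng.integers(2))
            for chrom, ivals in truth.true_ibd_intervals((a, sa), (b, sb)).items():
                ca = (a, sa ^ flips[(a, chrom)])
                cb = (b, sb ^ flips[(b, chrom)])
                called = res.store.pair_segments(ca, cb)
                for s, e in ivals:
                    cm_span = truth.markers.cm[e - 1] - truth.markers.cm[s]
                    if cm_span < 2.0:
                        continue
                    fw_sites = [fw_of_union[t] for t in range(s, e)
                                if t in fw_of_union]
                    if len(fw_sites) < 10:
                        continue
                    tot += 1
                    if any(seg.start < fw_sites[-1] and seg.end > fw_sites[0]
                           for seg in called):
                        hit += 1
        assert tot >= 50
        assert hit / tot >= 0.9

    def test_sibling_ibd2_recovered(self, small_pipeline):
        """IBD2 called over ≥90% of a true double-shared span for some full
        sibs."""
        res = small_pipeline
        ped, truth = res.ped, res.truth
        sib_pairs = []
        for fam in ped.nuclear_families():
            kids = [k for k in fam.child_ids if k in ped.genotyped]
            sib_pairs.extend(itertools.combinations(kids, 2))
        checked = covered_frac = 0
        mk = res.H.markers
        pos = {(int(c), int(b)): i
               for i, (c, b) in enumerate(zip(truth.markers.chrom, truth.markers.bp))}
        fw_of_union = {pos[(int(c), int(b))]: i
                       for i, (c, b) in enumerate(zip(mk.chrom, mk.bp))}
        for a, b in sib_pairs[:40]:
            # true IBD2: both disjoint pairings share founder labels
            p1 = [intersect_intervals(
                      truth.true_ibd_intervals((a, 0), (b, 0)).get(1, []),
                      truth.true_ibd_intervals((a, 1), (b, 1)).get(1, []))]
            p2 = [intersect_intervals(
                      truth.true_ibd_intervals((a, 0), (b, 1)).get(1, []),
                      truth.true_ibd_intervals((a, 1), (b, 0)).get(1, []))]
            true_iv = union_intervals([iv for lst in p1 + p2 for iv in lst])
            true_fw = [t for s, e in true_iv for t in range(s, e) if t in fw_of_union]
            if len(true_fw) < 100:
                continue
            called = ibd2_segments(res.store, (a, b)).get(1, [])
            called_set = {t for s, e in called for t in range(s, e)}
            frac = np.mean([fw_of_union[t] in called_set for t in true_fw])
            checked += 1
            covered_frac += frac
        assert checked >= 3
        assert covered_frac / checked >= 0.9


class TestStoreSerialization:
    def test_tsv_round_trip(self, tmp_path):
        store = IBDSegmentStore()
        store.add(_seg(("a", 0), ("b", 1), 1, 5, 25, 0.87))
        store.add(_seg(("c", 1), ("a", 0), 2, 0, 40, 0.93))
        path = tmp_path / "segs.tsv"
        store.write_tsv(path)
        back = IBDSegmentStore.read_tsv(path)
        assert {s.key() for s in back.segments()} == {s.key() for s in store.segments()}
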