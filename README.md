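# pedclique

Pedigree-based phasing and IBD-clique imputation for founder populations.

In a founder population, a few whole-genome-sequenced individuals can
stand in for everyone else: most chromosomal segments of the unsequenced
cohort are identical by descent (IBD) with a segment carried by somebody
who *was* sequenced. `pedclique` turns that observation into a pipeline.
Given a pedigree, dense "framework" SNV genotypes for the whole cohort and
sequence variants for a small subset, it

1. quality-filters the framework markers (Mendelian errors, exact
   Hardy–Weinberg test, call rate, MAF);
2. phases the framework genotypes by Mendelian transmission, sibling
   templates, and long-range "surrogate parent" IBD;
3. detects IBD segments between every pair of the 2n haplotypes with a
   two-state hidden Markov model — prior π = φ (the pair's kinship
   coefficient), transition P(IBD→IBD) = π + (1−π)e^(−λd) over d cM, and
   match/mismatch emissions with per-allele error ε;
4. indexes segments into a per-marker **IBD clique dictionary**: at each
   marker the IBD graph (edge weight = segment posterior) is pruned by
   edge weight < 0.85 or neighborhood affinity < 0.9 and its connected
   components become cliques, giving O(1) "are these haplotypes IBD
   here?" queries;
5. assigns parental origin to haplotype slots: within families by
   recombination-minimizing bin assignment, and for quasi-founders
   (individuals without genotyped parents) through the median kinship
   between each recorded parent and each slot's clique members — the
   separation m = (d−o)/(d+o) ∈ [−1, 1], with a chromosome assigned when
   M = max(n₊, n₋)/(n₊+n₋) > 0.75 over informative markers (|m| > 0.25);
6. imputes every sequence variant independently through the cliques with
   a queue: homozygous sequenced genotypes seed haplotype alleles, a
   clique is filled when a two-thirds allele majority exists among its
   sequenced members, and newly resolved heterozygotes enqueue their
   complementary haplotype;
7. estimates sequence genotyping error via a generalized Mendelian check:
   genotype mismatches inside IBD2 segments (regions where two
   individuals share both haplotypes), classified by singleton status,
   novelty and variant type with per-class call-rate cutoffs;
8. optionally merges LD-based genotype probabilities (hard calls at
   probability > 0.99, kept per variant only at het concordance ≥ 0.99
   and MAF ≥ 1%) into the gaps the pedigree leaves, and exports
   paternal/maternal haploid panels and HAPS/SAMPLE reference panels.

A gene-dropping simulator (`pedclique.simulate`) generates multi-generation
founder pedigrees with recombination and full founder-allele labels, so
every stage can be validated against known truth.

## Worked example

```python
import numpy as np
from pedclique import SimConfig
from pedclique.simulate import simulate_pedigree, gene_drop, make_study
from pedclique import phasing, ibd, clique_index, imputation
from pedclique.genotype_io import MISSING

cfg = SimConfig(seed=1)          # ~200 genotyped, 20 sequenced, 2,000 markers
rng = np.random.default_rng(cfg.seed)
ped = simulate_pedigree(cfg, rng)
_, truth = gene_drop(ped, cfg, rng)
study = make_study(ped, truth, cfg, rng)

H, stats = phasing.phase_cohort(ped, study.framework)
print(f"unphased fraction: {stats.fraction_unphased:.4f}")

store = ibd.pairwise_ibd(H, ped)
print(f"pairs: {store.n_pairs_processed}, segments: {len(store)}")

sq = study.seq_variants
anchors = [imputation.nearest_framework_marker(H.markers, int(c), int(b))
           for c, b in zip(sq.chrom, sq.bp)]
D = clique_index.build_dictionary(store, sorted(set(anchors)))
variants = [imputation.VariantRecord(int(sq.chrom[i]), int(sq.bp[i]),
                                     str(sq.ref[i]), str(sq.alt[i]), True,
                                     study.seq_calls[:, i])
            for i in range(len(sq))]
panel = imputation.impute_all(variants, D, H, study.sequenced_ids,
                              anchors=anchors)
nonseq = [s for s in panel.sample_ids if s not in set(study.sequenced_ids)]
print(f"genotype call rate: {panel.genotype_call_rate(nonseq):.3f}")
```

Output:

```
unphased fraction: 0.0024
pairs: 74305, segments: 19844
genotype call rate: 0.405
```

That is: 0.24% of framework genotypes remain unphased, the IBD stage
enumerates all 74,305 haplotype pairs of the 193 genotyped individuals and
calls ~20k segments, and 40% of the unsequenced samples' sequence-variant
genotypes are imputed (both haplotype alleles resolved).  Comparing the
called genotypes with the simulator's truth gives 99.2% concordance —
calls propagated through IBD cliques are essentially Mendelian-exact; the
call rate, not the accuracy, is what shrinks with panel size.

The same pipeline is available as a CLI over a working directory:

```
pedclique init-config cfg.yaml
pedclique run workdir --config cfg.yaml
```

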