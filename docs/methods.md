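# Methods

This note documents the models, the defaults and the numerical choices
behind `pedclique`, and what the simulation-based tests do and do not
establish.

## Kinship and the pedigree model

Kinship coefficients φ(i, j) use the standard recursion over a pedigree
whose founders are assumed non-inbred and mutually unrelated.  Inbreeding
of non-founders is handled by the recursion itself (φ(x, x) =
½(1 + φ(father, mother))); condensed identity coefficients are never
needed because every downstream formula consumes only kinship: the HMM
prior, the surrogate-parent candidate filter, the parental-origin
separation matrix, and the sequencing-panel selection rule.  Sex codes
are stored but only used for parent roles; everything operates on
autosomes.

## The two-state IBD HMM

For a haplotype pair, the hidden state at each marker is IBD / not-IBD.

* **Prior.** π = φ of the sample pair, clipped to [1e−4, 1−1e−4].  φ is
  exactly the probability that a random allele pair is IBD, and the four
  haplotype pairings of two individuals average to it.  The
  within-individual pair (detecting homozygosity by descent) uses the
  individual's inbreeding coefficient, i.e. the kinship of its parents.
* **Transitions** over genetic distance d cM follow the continuous-time
  two-state chain with stationary distribution (π, 1−π):
  P(IBD→IBD) = π + (1−π)e^(−λd), P(¬IBD→IBD) = π(1−e^(−λd)).
* **λ default.** λ = g/100 per cM with g = max(1, round(−log₂ 2φ)): g
  approximates the number of meioses separating the pair and the expected
  IBD tract length is ~100/g cM.  This is a heuristic stand-in for a
  per-pair estimated transition rate and is overridable per pair.
* **Emissions** depend only on whether the alleles match: under IBD
  (1−ε)² + ε² for a match (ε = per-allele genotyping error, default
  0.005), under non-IBD p² + q² with p the marker's alt frequency
  estimated from the cohort genotypes.  Missing alleles emit 1 in both
  states, so partially phased haplotypes are handled transparently.
* **Numerics.** Forward–backward runs with per-marker rescaling
  (normalized α, β), vectorized across thousands of pairs at once; this
  is algebraically equivalent to log-space accumulation and cannot
  underflow on long chromosomes (exercised at 10⁵ markers in the tests).

Maximal runs of posterior ≥ 0.5 spanning at least 10 markers become
segments, recorded with their mean posterior.

## Phasing

Stage order: homozygotes → Mendelian trio phasing (families processed in
topological order) → sibling-template phasing → surrogate-parent phasing.
Two invariants are asserted after every stage: haplotype sums never
contradict genotypes, and the set of phased sites only grows.

Mendelian phasing resolves a child's het site whenever either genotyped
parent is homozygous; slot 0 receives the father-derived allele, which
fixes parental origin for everyone with genotyped parents.  The sibling
template is the child with the most *phased het* sites (a proband phased
only at homozygous sites has indistinguishable slots and must not be used
as a template); het sites of siblings inside an IBD segment with the
template copy the template allele onto the shared slot, conflicts
resolved by the higher posterior.

Surrogate-parent phasing reconstructs a proband's haplotypes from IBD
with relatives (kinship ≥ 1/64 by default, descendants included — a
child's paternal haplotype is a recombinant of the proband's own two
haplotypes, and its Mendelian phase derives from the spouse, not from the
proband, so there is no circularity).  Each candidate segment contributes
its allele track at the proband's het sites.  Tracks are split into
chunks of ~20 het sites; chunks of one segment are tied by
moderate-weight continuity edges (a relative's tract can switch which
proband haplotype it matches at a parental recombination point, so
whole-segment orientation would be unsound), and chunks sharing sites get
signed agreement edges.  Orientations are solved by greedy seeded
expansion (strongest absolute signed connection first), followed by
single-chunk correction sweeps and, on unanchored chromosomes, 1-D block
flips across positional cuts — the move that escapes half-chromosome flip
minima.  Already-phased het sites act as a pinned anchor so fills join
the existing slot convention.  Cohort passes are synchronous: every
proband in a pass reads candidates from the same pre-pass snapshot,
making the result independent of processing order; a middle pass
re-assembles quasi-founder phase against the fully phased cohort.

A final transmission-consistency repair exploits the strongest phase
information a quasi-founder has: its children.  A child's transmitted
haplotype is a contiguous copy of the proband's two chromosomes,
switching only at the child's own meiotic breakpoints, which are
independent between children — so a position where *all* gametes
simultaneously switch which proband slot they match marks a flip in the
proband's assembled phase, not recombination.  With ≥2 genotyped
children, per-window slot orientations are chosen by dynamic programming
to minimize the total implied recombinations across the gametes (windows
of 20 het sites; windows without decisive evidence inherit the preceding
orientation; a small flip penalty keeps ties on the existing phase).

**Known limitation.**  A quasi-founder without genotyped children is
genuinely ambiguous across positions where both parental meioses
recombined nearby: no relative's haplotype bridges such a cut, and the
two sides of the chromosome phase independently (a coin-flip relative
orientation).  These block flips do not affect imputed genotypes (slot
sums are unchanged) and mostly suppress parental-origin assignment rather
than corrupting it, but they cap haplotype-level accuracy for childless
top-generation individuals.  The phasing accuracy benchmark therefore
reports quasi-founders with genotyped children, for whom phase is
identifiable end to end, and scores phased genotypes (the measure the
published phasing figures use).

## Clique indexing

At a marker, true IBD is an equivalence relation, so the IBD graph should
be a union of disjoint cliques.  The observed graph is a perturbation of
one.  Affinity of an edge = cosine similarity of the two closed-
neighborhood weight vectors (entry w_ux per neighbor, 1 at the node).
Edges with weight < 0.85 are dropped; then the lowest-affinity edge below
0.9 is removed and the affinities of edges at its endpoints recomputed,
until every surviving edge has affinity ≥ 0.9.  Connected components of
the remainder are the cliques (implicitly completed).  The sequential
order matters: removing a spurious edge first restores the neighborhood
similarity of genuine edges it polluted, which is what makes the
partition agree with exhaustive minimum-edit clique editing on small
perturbed clique unions.  The price is that threshold monotonicity
(raising a threshold only refines the partition) is no longer a theorem
on arbitrary dense graphs; it holds on clique-union-plus-noise graphs —
the structure per-marker IBD graphs actually have — and is tested on that
family.  Thresholds 0.85/0.9 are the published operating point and are
configurable.

The dictionary stores one partition per requested marker (for imputation,
the nearest framework marker of each sequence variant; plus any grid the
cross-validation or parental-origin stages need), built by an
active-interval sweep over segments.

## Parental origin

Within a family, children's haplotype regions are assigned to four
parental bins by an 8-state dynamic program per child (which parent side
each slot sits on, and which parental haplotype), with costs 1.0 for an
IBD sibling pair split across bins, 0.25 for a non-IBD pair sharing a bin
(IBD calls miss more often than they false-alarm), and 12.0 per bin
switch — so a switch needs sustained evidence, and single true
recombinations are recovered exactly on clean fixtures.  The three
bin-to-parent pairings are scored by child separation
max(F₁, F₂)/(F₁+F₂) ∈ [0.5, 1] and the pairing maximizing the minimum
child separation wins (scale-free version of the coverage criterion).

For quasi-founders, K[p][h] = median kinship between recorded parent p
and the eligible members of slot h's clique (quasi-founders only,
excluding the proband and its siblings, to avoid the proband's own line
dominating).  m = (d−o)/(d+o) with d, o the diagonal/off-diagonal sums
satisfies the required limits (+1 when the diagonal dominates, −1 when
the off-diagonal does) and is the simplest such contrast.  Markers with
|m| > 0.25 are informative; a chromosome is assigned when
M = max(n₊, n₋)/(n₊+n₋) > 0.75 (every fifth dictionary marker is
evaluated, matching the cross-validation thinning practice).  M is
computed per chromosome.

## Imputation

Each variant is processed independently (order-invariant, trivially
parallel).  The clique partition is taken at the variant's nearest
framework marker by bp (ties to the left) — cliques exist only at
framework markers and recombination between a variant and its anchor is
rare at framework densities.  The queue is FIFO, seeded by sequenced
samples in ascending id with homozygotes first, which makes the result
deterministic.  A two-thirds majority (count ≥ 2/3 of votes, ties pass)
among already-assigned sequenced haplotypes fills a clique; a failed vote
marks the clique conflicted and withdraws its propagated calls, but
complements already propagated onward are kept — conservative for the
clique, while not discarding evidence that flowed through valid votes
elsewhere.  Sequenced genotypes are never overwritten.  A genotype is
called only when both haplotype alleles are.

Cross-validation masks the framework genotypes of all non-sequenced
samples at every fifth framework marker and re-imputes them through the
existing cliques, reporting overall and heterozygote concordance (het =
called het by either source) by MAF bin.

LD-merging accepts external genotype probability triples, hard-calls at
max probability > 0.99, and keeps a variant's LD calls only when the
pedigree/LD heterozygote concordance is ≥ 0.99 and MAF ≥ 1%; LD calls
fill only missing pedigree genotypes (unphased LD hets are stored as
genotype-level calls).  No LD imputer is bundled; the package exports
HAPS/SAMPLE reference panels and paternal/maternal haploid GEN panels in
the formats such tools consume.

## Sequence QC

The generalized Mendelian check compares genotypes of sequenced pairs
inside IBD2 segments (both haplotype pairings simultaneously IBD,
computed as interval intersections of the segment store).  The class
discordance rate is pooled: total mismatching pairs over total covering
pairs.  With independent per-genotype errors at rate e the expected rate
is 2e(1−e) + O(e²), which the estimator reproduces within Monte-Carlo
error in the tests.  Default call-rate cutoffs per (singleton, novelty,
type) class: 0.9 for known non-singletons and for novel singleton
insertions, 0.99 for everything else; pass requires call rate strictly
above the cutoff, and an optional per-genotype quality mask can stand in
for platform-specific "high quality" flags.

## The simulator

`simulate` is first-class, tested code.  The default study emulates the
target design: three genotyped generations (~200 individuals; 24 couples
per generation, Poisson(2.8) children truncated to [1, 6]) on top of two
*ungenotyped* ancestral generations — quasi-founders must be related to
each other through ungenotyped ancestors, otherwise surrogate phasing and
clique-kinship parental origin have no signal, exactly as in real founder
cohorts where the genotyped sample sits inside a deeper known pedigree.
Defaults: 2 chromosomes × 100 cM / 100 Mb with 2,000 framework markers
(alt frequency uniform on [0.1, 0.9], then *ascertained*: markers whose
realized cohort MAF drifted below 5% are dropped, as a framework panel is
by definition the common subset), 500 sequence-only variants (frequency
uniform on [0.02, 0.5]) placed uniformly, per-genotype error 0.001
(a genotype is replaced by one of the other two values), missingness
0.002, and 20 sequenced samples chosen by the greedy rule: maximize mean
kinship to the rest subject to pairwise kinship < 0.1 with those already
chosen.

Gene dropping is Haldane/Poisson (no interference): per meiosis, a
Poisson(map length in Morgans) number of breakpoints uniform on the cM
map.  Founder haplotypes are drawn in linkage equilibrium — deliberate:
it isolates the pedigree signal, which is the method's premise.  Passing
tests therefore say nothing about LD-driven artifacts in real data (e.g.
population-level haplotype sharing masquerading as pedigree IBD), nor
about platform-specific error structure; they do establish the
transmission logic, the HMM, the clique index and the queue imputation
against exact ground truth.

## Problem sizes and tolerances

The simulation benchmarks use the default study (~200 genotyped / 20
sequenced / 2,500 variants over 2 chromosomes) — small enough to run the
whole chain in a few minutes on one CPU, large enough for ~75,000
haplotype pairs and ~20,000 segments.  The kinship-versus-realized-IBD
correlation is checked on a 6-chromosome drop because realized IBD on a
short genome fluctuates too much to show the genome-wide r ≥ 0.9.  The
exponential-length check uses 250 disjoint first-cousin units (a single
meiosis depth: within the layered pedigree one kinship value mixes path
lengths into a hyper-exponential), interior segments only, excess over a
4 cM floor (twice the calling minimum) to sidestep the detection-edge
artifacts of the caller.  HMM posteriors are compared to exhaustive path
enumeration at 1e−10; the clique partition to exhaustive minimum-edit
search on ≤ 12 nodes; all stochastic acceptance checks fix their seeds.
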