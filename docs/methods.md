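# Methods

This note documents the statistical model behind the package, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical choices that matter for reproducibility.

## The hybridogenesis model

A hybridogenetic hybrid is diploid with one haploid subgenome from each
parental species (labelled L and R throughout). Before meiosis one
subgenome is eliminated from the germline; the other is transmitted
clonally, unrecombined. Hybridity is restored each generation by mating
with the sexual host species. Two observable consequences drive every
statistic in the package:

* all hybrids descending from one founding event share an identical
  haploid allele vector in the transmitted genome (one **hemiclone**),
  up to stepwise mutation and scoring artifacts;
* the other subgenome is a fresh recombinant gamete from the sympatric
  sexual pool, so it is unique per individual with high probability at
  polymorphic loci.

Two system types are handled by one engine with the genome roles
switched: populations where hybrids transmit L and live with sexual RR
("R-E male" systems — all hybrids male), and populations where hybrids
transmit R and live with sexual LL ("L-E" systems).

## Clonality statistics

**MLG definition.** A multilocus genotype (MLG) is the canonical vector
of per-locus states (allele pairs sorted ascending, missing sentinel 0).
Indexing is exact: records differing at a locus where either is missing
are distinct exact MLGs.

**Missing-data-aware merging.** Two MLGs are *compatible* when they
conflict at no co-scored locus and share at least `min_shared_loci`
(default 5) co-scored loci. A connected component of the compatibility
graph merges into one clone only if it is a clique — pairwise
compatibility then guarantees a unique conflict-free consensus. Non-clique
components are split into maximal cliques assigned greedily (largest
total membership first, ties by lexicographic consensus); the split is
recorded on the reports. Transitive merging is deliberately rejected:
A~B and B~C must never fuse A with C when A and C conflict. The
`min_shared_loci` floor prevents vacuous merges of mostly-missing
records.

**Round-robin frequencies.** Clonal repetition biases naive allele
frequencies toward the clone's own alleles. At each locus the frequency
sample is therefore one representative (smallest id, a choice that cannot
affect the result when sub-MLG members agree at the focal locus) of each
distinct sub-MLG defined over the *other* loci. F_IS per locus is
`1 − H_OBS/H_EXP` with `H_EXP = 1 − Σp²` from these round-robin
frequencies and `H_OBS` the heterozygote fraction among the same
representatives; monomorphic loci give F_IS = 0 by convention, values are
clamped to [−1, 1].

**P_GEN.** The probability that a single sexual event yields a given MLG
is the product over scored loci of the inbreeding-adjusted genotype
probability: `p² + p(1−p)F` (homozygote), `2 p_a p_b (1−F)`
(heterozygote), with each factor clamped to [0, 1]. Half-scored loci
`(a, –)` contribute the single-copy factor `p_a`; missing loci are
skipped. P_GEN requires pseudo-counted frequency tables (every observed
allele gets `ε = 0.5/(2N)` before normalization) so no factor is exactly
zero by sampling accident.

**P_SEX.** With `n_obs` copies of an MLG among `N` analysed genomes,
`P_SEX = P[X ≥ n_obs]` for `X ~ Binomial(N, P_GEN)`, computed with the
scipy binomial survival function (accurate in double precision far below
1e−50). The tail starts at `n_obs`; the `n_obs − 1` convention is a
switch, default off. `N` is ambiguous in practice — per population or
whole dataset — so both values are computed and reported; the verdict
uses the minimum.

**Verdict.** `clonal` requires both signals: at least `min_copies`
(default 3) identical copies *and* `P_SEX ≤ α` (default 0.05). A repeated
MLG with only one signal is `putative`; everything else `sexual`. The
copy-count floor encodes the field rule that two identical genotypes can
plausibly be coincidence but three or more indicate clonal inheritance.

**Why self-doubling works.** Clonal subgenomes are haploid; the diploid
machinery accepts them after doubling each allele into a homozygote. The
identity that justifies this: doubled haploids have `H_OBS = 0`, hence
round-robin `F_IS = 1`, and with `F = 1` the homozygote factor collapses
to `p² + p(1−p) = p` — so P_GEN is exactly the haploid product of allele
frequencies. This identity is asserted analytically in the test suite.

**Frequency reference.** The clonality stage runs on the *combined*
diploidized set — self-doubled hybrid subgenomes plus sympatric sexual
diploids, restricted to loci amplifying in both genomes. Round-robin
frequencies then reflect the sexual gene pool: a clone's alleles are rare
among the representatives, so its P_GEN is small. Running the clone's
subgenomes alone would yield allele frequencies near 1 and no power.

## Quality screening

**HWE test.** Monte-Carlo exact test: allele copies at a locus are
permuted among individuals (default 10,000 reps; seeded), the statistic
is the multinomial probability of the genotype configuration under
Hardy–Weinberg proportions (multinomial coefficient included — it varies
across configurations), and
`p = (1 + #{reps with prob ≤ observed}) / (n_reps + 1)`. Ties are
compared with a 1e−9 log-tolerance. Monomorphic loci return p = 1.
Exhaustive enumeration over perfect matchings of the allele copies serves
as the oracle for small samples in the tests.

**Null alleles.** The estimator fits, by EM to 1e−6, the
maximum-likelihood three-class model over visible heterozygotes
(`2pᵢpⱼ`), visible homozygotes (`pᵢ² + 2pᵢr`) and blanks (`r²`), with
`Σpᵢ = 1 − r`; blanks count as data (null homozygotes). When the data
carry no signal (no blanks and no heterozygote deficit) the estimate is 0
outright; all-blank data give r = 1; a single visible allele reduces the
ML fit to the moment estimator `√(blank fraction)`, which the tests
verify.

**Flagging and correction.** A locus carries nulls when `r̂ ≥ 0.05` *and*
the HWE p-value is < 0.05 in the heterozygote-deficit direction (the
two-signal rule avoids flagging mere dropout or mere inbreeding).
Correction recodes blanks as null homozygotes `(∅,∅)` and each visible
homozygote `(a,a)` as `(a,∅)` with the posterior probability
`2r̂/(p̂_a + 2r̂)` that it truly carries a null copy (seeded). After
correction the null segregates as an ordinary allele, so the locus
re-screens clean — verified by simulation. Corrected (locus, population)
pairs are marked on the dataset; re-applying a correction is a no-op,
which makes the operation idempotent by construction rather than by
re-estimation.

## Partitioning and assignment

Partitioning routes species-specific alleles to their genome; a
shared/nonspecific partner allele goes to the remaining genome only if it
occurs in that species' sympatric sexual pool (default: same population,
falling back to — or switchable to — the system-wide pool). Anything else
is left unresolved in *both* subgenomes and surfaced in the report;
nothing is imputed. Single-allele cells are stored as `(a, missing)` —
never auto-doubled, because a lone peak may be a homozygote, a null
heterozygote, or a single-genome locus; doubling is an explicit operation
with two modes (`self-double` for clonality statistics, `missing-partner`
for matching and summaries).

Taxon calls take a majority vote of per-locus compositions (LL/RR/RL)
over informative loci; loci amplifying in a single parental genome do not
vote, since they cannot separate a hybrid from the pure species they
amplify in. Default support threshold 0.75; discordant loci are listed,
never reinterpreted. The hybrid index is a supervised two-source
likelihood maximized on [0, 1] (bounded Brent, tolerance 1e−6, boundary
polish at 0 and 1); the per-copy likelihood is linear in q, so the
log-likelihood is concave and the optimum unique unless every copy has
`f_L = f_R`, which is reported as a flat-likelihood flag. This supervised
estimator reproduces the qualitative three-cluster pattern (sexuals near
0 and 1, hybrids near 0.5); it is not an MCMC admixture model and its q
values are not comparable to one beyond that pattern.

## Relatedness

Nei's DA between groups uses plain sample allele frequencies; loci
unscored in any group are dropped and recorded. UPGMA is size-weighted
average linkage with ultrametric heights; exact distance ties are broken
by the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf). Bootstrap support resamples loci with
replacement and counts, per internal node of the original tree, the
fraction of replicate trees containing the same leaf set (default 7000
replicates in the pipeline). Newick output carries support as internal
node labels. The PCA operates on per-allele count columns (diploid 0/1/2,
half-scored cells 0/2 to match self-doubling), mean-imputes missing
cells, drops zero-variance columns, standardizes, and reports axes
strictly by eigenvalue rank.

## The simulator

`SimConfig` defaults describe a 17-locus diagnostic panel (3 L-only, 3
R-only, 11 both-genome loci; 6–17 alleles per locus per genome on a
2-bp grid in disjoint size bands 100–198 / 200–298) over five R-E male
populations whose composition (8+1+8+6+9 → 17/1/8/6/9 sexual RR and
12/2/4/4/5 hybrid males) mirrors the field system that motivated the
package; one founding clone; sexual pools at Hardy–Weinberg equilibrium
(`fis_sexual = 0`, configurable via
`P(hom) = p² + Fp(1−p)`); 3% sporadic dropout; no mutation. The clone
haplotype is sampled once from the species allele frequencies at
generation 0 — the simulator models the observable consequence of a
founding event, not its history. Mutation, when enabled, is stepwise
(±1 motif step per event, Binomial(generations, rate) events per locus
lineage). Null alleles are injected per allele copy at the configured
frequency: both copies null → blank, one null → apparent homozygote.
All randomness flows from a single root seed through per-population
`SeedSequence` substreams; the ground-truth log records clone
haplotypes, memberships and every injected event, and the same seed
reproduces the dataset bit for bit.

What the simulator does **not** emulate: ecological dynamics (mate
choice, fitness, migration between ponds), triploids, allele-size
homoplasy across species bands (bands are disjoint by construction,
making partitioning easier than in data where species share allele
sizes), genotyping stutter, and population divergence between sexual
pools of one species (all populations share species-level frequencies).
Passing tests therefore demonstrate correctness of the inference chain
under the model's assumptions, not robustness to every field artifact.

## Problem sizes and determinism

The test suite and the acceptance script scale simulations to desk-size
problems chosen to keep Monte-Carlo error well inside the asserted
tolerances: 100 seeds for end-to-end recovery (60 individuals, 10 loci
each), 200 replicates of n = 500 for null-allele recovery, 1000 random
4-leaf matrices against the exhaustive UPGMA oracle, and 200 simulations
for p-value uniformity (KS at α = 0.01). Every stochastic component
takes an explicit seed; pipeline manifests are byte-identical across
runs with the same config.

## Known limitations

* Exact-or-missing MLG compatibility only: there is no scoring-error
  slider allowing k mismatching loci, so a clone member with a mutated or
  mis-scored allele forms its own (compatible-conflicting) MLG.
* Clique merging can split a true clone when two members' missing-data
  patterns leave fewer than `min_shared_loci` co-scored loci between
  them, even though both are compatible with the consensus; this is the
  conservative reading of pairwise compatibility and occurs in ~2% of
  simulated systems at 5% dropout.
* The null-allele correction is stochastic (posterior recoding); analyses
  downstream of a correction should fix the seed for reproducibility.
* P_SEX assumes the N analysed genomes are exchangeable draws from the
  frequency reference; with strong substructure among sexual pools the
  binomial tail is only an approximation.
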