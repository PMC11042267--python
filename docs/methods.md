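# Methods

This note documents the models implemented in `transpoly`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Site classification

Sites are biallelic SNPs; multiallelic records are skipped on input (the
analyses are defined for two alleles). Within each species the alt-allele
frequency is computed over non-missing calls only. With folded frequencies
`maf = min(f, 1−f)` and threshold `maf_min` (default 0.01, exposed):

- `fixed_diff` — the species are fixed for opposite alleles (strict 0 vs 1
  after missing-data exclusion; a 0.995 frequency is not "fixed", such sites
  fall into the private/monomorphic classes by the threshold logic);
- `shared_poly` — `maf > maf_min` in both species;
- `private_A` / `private_B` — `maf > maf_min` in exactly one species;
- `monomorphic` — everything else. A site with zero calls in one species is
  labelled monomorphic with an `unassessable` flag rather than dropped:
  silent dropping would bias shared counts downward.

The labels are a deterministic, exhaustive and exclusive function of the two
frequencies, symmetric under species exchange (with the private labels
swapped) — both properties are asserted by tests.

Post-hoc filters mirror standard practice for this kind of data: samples
with genome-wide missingness > 10% are removed first, then sites with mean
depth ≤ 8 or ≥ 35 and sites with call missingness > 10%. One pass is
applied; the order (samples before sites) matters and is fixed.

Multi-locus genotypes (clonal lineages) are grouped by single-linkage on the
pairwise genotype mismatch fraction over mutually non-missing sites, default
threshold 0 (identity). With missing data single linkage is not a true
equivalence; the grouping is deterministic and the threshold exposed. The
representative of an MLG is its highest-mean-depth member, ties broken by
sample id for determinism.

## Diversity, divergence and the ILS expectation

π uses the unbiased per-site estimator `2p̂q̂·n/(n−1)`; d_xy is
`p̂_A(1−p̂_B) + p̂_B(1−p̂_A)`; both are averaged over a common site set, with
an optional rescaling by the surveyed length when the matrix holds only
segregating sites.

The expected number of neutrally retained (ILS) shared polymorphisms is

    E[shared] = L · π_A · π_B · exp(−(2·d_xy − π_A − π_B) / max(π_A, π_B)).

The exponent is a split-time proxy: in expectation `2·d_xy − π_A − π_B =
4μT` and `max(π_A, π_B) = 4μN` for the larger population, so the exponent
estimates T/N, the split time in within-species coalescent units, and
`exp(−T/N)` is the probability that a sampled allele pair in each species
predates the split. Both the exponent and the per-site probability are
returned separately so alternative orientations can be audited.

**Validity domain.** The product π_A·π_B treats "polymorphic in A" and
"polymorphic in B" as independent events. They are not: under retention a
*single* ancestral mutation makes both species polymorphic at once. For one
diploid sample per species the exact neutral rate is
`exp(−T/N)·μ·(4N/3)` per site (the 4N/3 is the expected length of genealogy
branches subtending exactly one allele from each species, conditional on
retention — verified in the tests against both a brute-force Kingman
simulation and msprime), so the formula underestimates the true rate by a
factor of roughly `1/(3θ)` with `θ = 4Nμ` per site. The approximation is
therefore only quantitatively accurate when the per-site polymorphism
probability is of order 0.1–1. The acceptance checks run the comparison in
that regime (θ_site = 0.3, one diploid sample per species, so that the
per-site polymorphism probability equals π exactly); there the simulated
neutral counts fall within a factor-2 band of the expectation across split
times of 2–6 coalescent units. At realistic genomic θ (10⁻³–10⁻²) the
formula understates neutral sharing by one to two orders of magnitude — a
caveat worth keeping in mind when the same formula is applied to real data.

The joint SFS is folded on the globally minor allele (orientation by total
projected count, the convention of standard joint-SFS software) and
projected by hypergeometric expectation: a site with k of n alleles
contributes mass `C(k,i)·C(n−k,n_proj−i)/C(n,n_proj)` to cell i, computed
with exact integer binomials (the projection agrees exactly with exhaustive
subsample enumeration for all n ≤ 6 — asserted). Expectation projection is
the default for determinism; a seeded single-draw mode exists for simulation
studies. The monomorphic corners are masked. Shared-polymorphism mass counts
cells with projected count ≥ 2 on both axes under the default
`min_count = 1` ("frequency above 1/20 in both species" with a
20-projection). Standardized residuals are `(E − M)/√M` cell-wise, with
0/0 → 0 and E>0/M=0 flagged infinite. Spectra serialize to a dadi-style
plain-text layout.

Coalescent-unit conversions follow `N_A = N_anc·η_A`, `N_B = N_anc·η_B`,
`t_split = 2·N_anc·τ` generations, `m = M/(2·N_anc)` per generation, with an
exact inverse. No generation time is assumed; conversion to years is out of
scope.

## Balancing-selection statistics

**α_b** is `1 − (Poly_NS·SP_SYN)/(Poly_SYN·SP_NS)`, i.e. `1 − 1/OR` for the
odds ratio of NS/SYN composition between shared and non-shared (private)
polymorphisms; the two categories are disjoint by construction from the
classification. The orientation (positive when the shared class is
NS-enriched) is a config flag with this default. CIs come from a gene-level
bootstrap — the gene, not the SNP, is the resampling unit, because linked
SNPs within a gene are not independent and SNP-level resampling understates
the variance. Replicates with a zero denominator are dropped; fewer than 10
genes flags the CI unreliable.

**β⁽¹⁾** is the folded-spectrum balancing statistic `θ̂_β − θ̂_W` over a
window around a core SNP. θ̂_β weights each window SNP by a similarity
kernel between its folded frequency and the core's,
`w = (1 − |f − f_c|/0.5)^p` (sharpness p default 2), normalized by the
neutral folded-class expectation `g(k,n) = (1/k + 1/(n−k))/(1+δ_{k,n−k})` so
that θ̂_β is unbiased for θ under neutrality; θ̂_W is S/a_n on the same
window. The core SNP is excluded from its own window; an empty window gives
0 by convention. Window half-width defaults to 500 bp (mirroring the
allele-tree window; the upstream analysis states no window size, so this is
a package default, not a claim). Under neutral windows E[β⁽¹⁾] = 0 exactly
by the normalization — asserted by Monte Carlo. The scan uses the species'
nominal haploid sample size for the kernel normalization; with missing data
folded frequencies still use non-missing calls (a mild approximation,
adequate at the low missingness the filters enforce).

## The cophenetic concordance test

For each focal shared SNP (default: non-synonymous, within-species
MAF > 0.25 in both species — the figure-level criterion; the alternative 0.1
threshold is exposed), phased haplotypes over the SNPs within ±500 bp are
extracted for up to 30 samples per species (highest depth first, seeded
tie-break). Distances are per-site-normalized mismatches over mutually
non-missing positions; invariant positions never change mismatch counts, so
SNP-only vectors suffice. Trees are neighbor joining (deterministic, no
external tools; negative branch lengths clamped at zero); externally
computed Newick trees can be supplied instead, tip names `sampleid_hapindex`.

`CPD_within` pools within-species tip pairs across both species before
taking the median (per-species medians are reported for audit);
`CPD_between` is the median over cross-species pairs;
`diff = within − between > 0` calls the tree discordant. The geometry of the
call: with balanced haplotype classes near frequency ½, within-species
cross-class pairs slightly outnumber same-class pairs, so the within median
lands on the deep cross-class distance while the between median averages the
shallow same-class and deep cross-class distances — positive diff. The call
is invariant to tip relabeling within species and to rerooting (path
lengths do not change), and NJ on additive matrices reproduces them to
1e-10 — all asserted.

## Segregation and F_IS with a read-depth-aware null

The default genotype caller is transparent and exactly enumerable: call
heterozygote iff both alleles are observed at least once, homozygote for the
observed allele otherwise, no-call at depth 0. Its depth bias — a true
heterozygote at depth d is miscalled homozygous with probability
`2·(1/2)^d` — is the phenomenon the read-depth-aware null exists to control;
a maximum-binomial-likelihood caller is available as an alternative.
Sequencing error ε defaults to 0 (exposed); for a heterozygote a symmetric
error between the two alleles has no effect.

Expected F1 segregation under an AB×AB cross is `(0.25 + 0.5·(1/2)^d,
0.5·(1 − 2·(1/2)^d), …)` averaged over the per-offspring depths, available
in closed form for the default caller and by Monte Carlo for any caller;
frequencies are over calls (no-calls excluded), with the closed form using
the ratio of expectations (identical when every depth is positive).

F_IS is `1 − H_obs/H_exp` with `H_exp = 2p̂(1−p̂)` from the sample allele
frequency; gene-level F_IS is the unweighted mean over the gene's SNPs. The
null distribution simulates replicate cohorts — 1:2:1 F1s, or
Hardy–Weinberg at a given allele frequency in cohort mode for genes not
known to be F1s — at the gene's empirical per-SNP, per-offspring depths,
calls genotypes, and records the gene-average F_IS of the calls. SNPs are
simulated independently within a replicate; for a gene whose SNPs form one
tightly linked block (the motif that makes trans-specific haplotypes
detectable) the null therefore understates the observed F_IS variance, and
the observed value's quantile is conservative only in the direction of the
selection test (a strongly negative observed F_IS remains strong evidence).
The synthetic cross generator models exactly that linked block: each
offspring inherits one haplotype per parent, viability weights
`(1 : 1+s : 1)` are applied as survival resampling, so with s = 1 the
expected heterozygote fraction is 2/3.

## The synthetic-data generator

`simulate_split` is a bespoke per-window structured coalescent in continuous
time: within-population pair coalescence at rate `k(k−1)/(4N)` per
generation, symmetric per-lineage migration at rate m, a clean merge into
the ancestral population at `t_split`, and Poisson mutations at
`μ·window_bp` per branch generation, one biallelic site per mutation
(infinite sites; in heavily scaled-down runs the per-bp mutation density can
exceed 1 and physical positions may repeat — each record is still its own
site). Windows are unlinked; sites within a window share one genealogy with
no recombination — the two extremes bracket real linkage. Accuracy is
pinned by closed forms: θ recovery in the single-population limit, the
absence of shared polymorphism at very deep splits, and agreement of the
shared-polymorphism rate with msprime under an identical model.

Scenario injection realizes the two adaptive hypotheses in a window:

- `trans_specific`: haplotypes are partitioned exactly (not binomially) into
  two allelic classes at `class_frequency` (default 0.5 — the frequency
  balancing selection maintains, and the regime in which the median-based
  CPD contrast has its sign guaranteed by the pair-counting argument above)
  and `n_class_mutations` (default 13, the size of the opsin's linked block)
  shared class-defining mutations are added in perfect linkage. Background
  variants fixed between species inside the window are removed first: a
  haplotype pair maintained through the split cannot carry post-split
  species-fixed differences on both backgrounds, and retaining them would
  make the window's distance structure internally inconsistent with the
  scenario being injected.
- `convergent`: one identical-state mutation is added independently within
  each species at `convergent_frequency`; the species-structured background
  is untouched, so the allele tree stays concordant.
- `neutral`: passthrough.

The scenario base demography (N = 500, μ = 10⁻⁶, 1 kb windows, split 3000
generations ≈ 6 coalescent units, 8 diploid samples per species) gives each
window an expected ~6 species-divergence variants and ~2 within-species
polymorphisms: enough background signal that convergent windows are reliably
concordant, small enough that a 13-SNP trans-specific block dominates the
medians. Desk-scale sizes throughout preserve θ and split times in
coalescent units relative to the study system (where the two species have
N_e of roughly 7×10⁵ and 3×10⁵ and μ = 5.69×10⁻⁹, the package default
mutation rate).

The generator does not emulate: recombination within windows, linkage
between windows, selection other than the two scenario devices, sequencing
error beyond a symmetric base-error rate, mapping or phasing artefacts, or
annotation structure (SYN/NS labels are assigned, not derived from codons).
Passing tests therefore demonstrate the statistical machinery under the
stated models, not robustness to alignment, phasing or annotation error in
real data.

## Numerical conventions

- Coordinates: 1-based inclusive at the VCF boundary, 0-based half-open
  internally; conversion confined to I/O.
- Missing data: −1 in genotype/haplotype/AD arrays; frequencies and
  distances always over non-missing (pairwise-complete) entries; pairs with
  zero overlap are flagged missing, excluded from medians, and an error in
  tree construction (impute or drop first).
- All stochastic operations take explicit seeds and are bit-reproducible;
  pipeline stages derive sub-seeds by hashing the run seed with the stage
  name, so no stage perturbs another's stream.
- Ties: MLG representative by lexicographic sample id; window sample
  selection by seeded shuffle after depth ranking; the likelihood caller
  resolves ties toward the heterozygote.
- The pipeline's JSON summary is written with sorted keys; identical
  config + seed reproduces it byte for byte.

## Problem sizes

Test-suite and acceptance-script runs use desk-scale sizes chosen so the
whole suite completes in minutes on one core: 10⁵ random sites for
classification algebra; 15 000 × 20 bp windows per ILS replicate (20
replicates per split time, 10 replicate sets for migration); 200 loci per
tree-test scenario (100 in the acceptance script); 400-offspring crosses
with 300–500 null replicates; 100 bootstrap tables of ~10⁴ SNPs for α_b
calibration.
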