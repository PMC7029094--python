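# Methods

This note records the models, estimators and numerical choices behind
`radkin`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the underlying procedures are
conventionally under-specified.

## Breeding-matrix simulator

A breeding matrix is an N_females × N_males array of expected
offspring counts. Construction, per simulated spawning event:

1. The males:females sex ratio is drawn uniform on [1, 2] and
   N_parents is split by round-half-even with a floor of one per sex
   (the split rule is a package choice; any deterministic rounding
   preserves the study design).
2. Each female draws a mate number from Poisson(λ = 3), clamped to
   [1, N_males]. The clamp at 1 guarantees every female appears in the
   matrix; the cap is forced by sampling mates without replacement and
   only binds at very small parent numbers. Mates are chosen uniformly
   without replacement and their order is shuffled before weights are
   assigned (nothing in the design says which mate receives the
   largest share).
3. Fecundity is uniform on [25,000, 100,000] eggs and is split among
   the m mates as fractions (m − i + 1)/(1 + 2 + … + m) — a descending
   triangular schedule, e.g. 60 eggs over 3 mates → (30, 20, 10).
4. Males left unmated repeat steps 2–3 with the sexes mirrored (their
   own fecundity draw included), so no parent is added or removed and
   the realized sex ratio is exactly the step-1 split.

Expected counts are kept as reals; integerization happens only when
offspring are sampled (multinomially, with cell probabilities
proportional to expected counts), which preserves the triangular
ratios exactly and avoids rounding bias. Offspring ids embed their
parents' ids, giving a `TruePedigree` for scoring.

**Mate-number accounting.** The simulator's calibration targets are a
mean of ~3 mates per female and ~2 per male. Counting occupied cells
of the *final* matrix would inflate the female mean to ~3.4–3.7,
because the remating pass adds cells to female rows; both targets are
properties of the *primary*, female-initiated phase (the female's own
truncated-Poisson draw, and the male occupancy it induces, whose mean
is ≈ λ/ratio ≈ 3·ln 2 ≈ 2.08 when averaged over the ratio range).
`BreedingMatrix.mates_per_*` therefore report the primary phase;
`realized_mates_per_*` count all cells. Measured grand means across
the three design sizes are ≈ 2.98 and ≈ 2.04.

## Pairwise dyad likelihood

For individuals x and y at locus ℓ with ALT frequency p, the joint
genotype probability under a relationship R with Cotterman
coefficients (k₀, k₁, k₂) is

  P(g_x, g_y | R) = k₀·J₀ + k₁·J₁ + k₂·J₂,

where J_m is the joint dosage table given m alleles shared identical
by descent, obtained by enumerating transmitted alleles under HWE
(J₀ is the product of HWE margins; J₂ the HWE margin on the
diagonal). Genotyping error rate ε enters as a genotype-level mixture:
with probability ε an observed genotype is an independent HWE draw,
which collapses to

  P_obs = (1 − ε)²·J_R + (1 − (1 − ε)²)·J₀

because an error-replaced genotype is distributed exactly like an
unrelated one. Log-likelihoods sum over jointly non-missing loci.
Classification is maximum likelihood over {FS, HS, U} with equal
priors; exact ties resolve toward the less-related label (U over HS
over FS), a conservative bias against false kin. Pairs sharing fewer
than `min_shared_loci` (default 100, the smallest panel evaluated in
the power design) are left uncalled. Allele frequencies are clipped to
[1e-6, 1 − 1e-6] to keep logs finite at monomorphic loci.

This pairwise composite likelihood is a deliberate methodological
substitute for joint full-likelihood sibship partitioning (COLONY-style
software): the acceptance surface of the power study — per-dyad
accuracy and false-negative rate — is itself pairwise, and the
composite classifier reproduces the qualitative power behavior
(accuracy increasing in locus count, decreasing in parent count, half
sibs hardest). It is not a re-implementation of any partition sampler,
and per-dataset results will differ from one.

**Family clustering.** Full-sib families are connected components of
FS edges. Pairwise calls need not be transitive; repair is iterative
and deterministic: while any component's mean internal FS margin
(llFS − max(llHS, llU) over all internal pairs) is negative, the
component's weakest FS edge is removed and components recomputed.
Half-sib links join family pairs in which more than half of the
cross-family dyads are called HS.

## Pedigree summaries

- **N_s (contributing adults):** two latent parent slots per full-sib
  family; each HS link merges one slot between the two families
  (union–find, links processed in sorted order, slots not yet shared
  preferred, and a merge is skipped if the families already share a
  parent). 33 singleton families with no links imply 66 adults.
- **Reproductive success:** each offspring credits one offspring to
  each of its family's slots, so the mean is identically
  2·n_offspring/N_s; the variance is the sample variance of per-slot
  totals.
- **Group coancestry:** Θ = (0.125·n_FS + 0.0625·n_HS)/C(n, 2) over
  unordered dyads, zero for sib-free cohorts. Dyad counts are treated
  as opaque inputs (counts exceeding C(n,2) warn rather than fail,
  since published tables sometimes report ordered counts).
- **N_b, sibship method:** with Q_m (Q_f) the probability that a
  random dyad shares a mother (father), effective parent numbers are
  1/Q and N_b = 4/(Q_m + Q_f) (Wright's composition; exact under
  non-selfing, no-inbreeding assumptions). When parents are unsexed
  family slots the total sharing rate is split evenly. The CI is a
  percentile bootstrap over offspring (500 resamples, computed on the
  1/N_b scale so censored draws stay finite); resampled copies of the
  same offspring are excluded from sharing counts, since such
  self-pairs trivially share both parents and would bias Q upward.
- **N_b, LD method:** Burrows composite r̂² per locus pair — the
  squared dosage correlation with the S/(S−1) correction on the
  composite disequilibrium — averaged (weighted by per-pair S) over
  pairs passing MAF ≥ P_crit (default 0.05) and, by default, located
  on different scaffolds. The sample-size expectation
  E[r̂²] = 1/S + 3.19/S² is subtracted (valid for S ≥ 30; smaller
  samples are rejected rather than approximated) and
  N̂_b = (1/3 + √(1/9 − 2.76·r̂²′))/(2·r̂²′) under random mating;
  non-positive r̂²′ or a negative discriminant censor the estimate to
  infinity. The CI is a delete-one jackknife over individuals with a
  normal approximation on the 1/N̂_b scale, standard practice for LD
  estimators.

## Spatial randomization test

The statistic is the proportion of related dyads whose members share a
sampling location (the proportion of *all* dyads that are related is
fixed by design and cannot vary under randomization, so it cannot
carry a test). Null draws place the observed number of related labels
uniformly without replacement over all C(N_gt, 2) dyads (vectorized by
random-key partial sort). The default p-value is the strictly-greater
tail, matching the usual verbal definition; because the null is
heavily tied on small cohorts, the strict version is anti-conservative
and `inclusive=True` (≥) gives the variant whose type-I error is
controlled — the calibration tests use it. An alternative null that
permutes location labels over individuals (different variance) is
available via `method="permute-locations"` without any claim of
equivalence. Individuals without location labels are dropped with a
warning. Cohort comparisons use two-sided Fisher exact tests on
within/between × cohort 2×2 tables.

## Population-genomic summaries

- **Diversity:** per population × locus, H_e = 2p̂q̂·2n/(2n−1)
  (unbiased), F_IS = 1 − H_o/H_e (Nei convention; negative values
  retained; undefined where H_e = 0).
- **Differentiation:** Nei–Chesser sample-size-corrected H_S and H_T
  with harmonic-mean sample sizes; G_ST = (H_T − H_S)/H_T per locus,
  pairwise and globally. The multilocus value defaults to the ratio of
  averages Σ(H_T − H_S)/ΣH_T (more stable at small H_T); the
  average-of-ratios alternative is a flag. The uncorrected (plug-in)
  per-locus variant feeds the outlier scan.
- **Outlier scan:** the neutral model takes x·df/F̄ ~ χ²(df) for locus
  statistic x. (F̄, df) are fitted by maximum likelihood of the doubly
  truncated density on the sample trimmed 5% from each tail
  (truncation bounds at the empirical quantiles; optimization by
  Nelder–Mead on log parameters, initialized from the trimmed
  moments). Right-tail p-values are computed for all loci and
  thresholded by Benjamini–Hochberg at FDR 0.10. On synthetic χ² data
  the fitted df recovers the truth within ±15%; on pure-neutral data
  flags are ≈ 0 and realized FDP stays near nominal in spiked
  simulations.
- **DAPC ordination:** per-locus mean imputation of missing dosages
  (deterministic), full-SVD PCA to a user-chosen number of components
  (the retention criterion is deliberately left to the user), then
  LDA. Discriminant directions are back-projected through the PCA
  rotation to per-locus loadings and reported as percentile ranks of
  absolute loadings, min–max normalized so each axis spans exactly
  [0, 100].
- **HDplot statistics:** H is the heterozygote fraction among called
  genotypes; D = (n_A − n_B)/√(n_A + n_B) over ref/alt reads summed
  across heterozygotes. Flags at H > 0.60 or |D| > 7. Allele balance
  is the mean heterozygote ref-read fraction, with a [0.3, 0.7]
  well-behaved band.

## Genotype I/O and filtering

VCF 4.2 in/out with GT, GQ, DP, AD (reading via cyvcf2; multiallelic
records skipped with a logged count; the writer uses placeholder A/C
alleles since panels carry dosages, and round trips are lossless).
The filter cascade order is pinned — (1) GQ < 10 genotypes masked,
(2) individuals > 75% missing removed (50% recommended before
population-genetic summaries), (3) sites with mean depth < 10×
removed, (4) sites > 30% missing removed — because the stages
interact and order changes survivor counts; the report makes each
stage's removals additive. Independent-locus selection is greedy per
scaffold left-to-right with 2 Mb spacing and a > 80% genotyping-rate
screen; earliest-first greedy is optimal for maximizing the number of
kept loci under a separation constraint, and a brute-force check on
small instances confirms it.

## Age assignment

Body lengths are fitted with a K = 4 Gaussian mixture by EM:
quantile-based initialization (equal-count blocks of the sorted
sample, hence order-invariant and deterministic), tolerance 1e-8 on
the log-likelihood, at most 500 iterations, variance floor 1e-4 mm².
Non-convergence raises with the trace attached; a variance pinned at
the floor flags the fit as degenerate instead. Components map to age
classes 0/1/2/3+ in ascending order of mean — biologically forced for
length-at-age. Default simulation means (35, 70, 105, 135 mm) are a
loose calibration to larval lamprey length-frequency modes.

## Synthetic data: what it does and does not emulate

Defaults: allele frequencies from a beta(0.7, 0.7) truncated to
[0.05, 0.95] (a U-shaped spectrum typical of RAD SNP ascertainment,
mean MAF ≈ 0.2); read depth negative binomial (mean 30, dispersion 5),
matching a ≥ 10× mean-depth filtering regime without claiming any real
depth distribution; heterozygote allele depths Binomial(DP, 0.5);
genotype-level error as an independent HWE redraw; population
structure by Balding–Nichols beta frequencies calibrated so the
multilocus G_ST estimate at target F = 0.01 lands in [0.005, 0.02].
Dosages count the ALT allele; coordinates are 1-based; panels place
loci ≥ 2 Mb apart so they behave as independent.

Not emulated: linked loci and realistic recombination maps, locus
dropout correlated with genotype (allelic dropout), phred-calibrated
error as a function of depth, null alleles, and age-dependent
sampling. Tests passing on these generators therefore demonstrate
estimator correctness under the stated models, not robustness to
those real-data pathologies.

## Problem sizes used in tests

The test suite and acceptance script run at desk scale as the
package's own choice of problem sizes: the power-design ordering
checks use 3 replicates per design cell (the full 3 × 3 × 100 design
is enumerated and countable, and any replication can be requested via
the API or CLI); N_b recovery uses 20 replicates of 50-breeder
cohorts; the randomization-test calibration uses 500 null datasets at
199 permutations each; outlier-scan checks use 5,000-locus panels.

## Known limitations

- The pairwise classifier ignores information in triads and larger
  sibships that joint partition methods exploit; its half-sib accuracy
  at very large parent numbers is correspondingly lower.
- HS-link detection by majority vote can under-merge families when
  cross-family dyads are noisy, biasing N_s upward slightly.
- The LD N_b estimator implements only the large-sample (S ≥ 30) bias
  correction and the random-mating model.
- Cohort "relatedness" (as distinct from coancestry) is not
  implemented; no standard coefficient set reproduces the published
  example values from dyad counts, so the quantity is left out rather
  than guessed.
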