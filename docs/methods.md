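# Methods

This note documents the models behind `hybridzone`, the default parameters
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter for reproducing results.

## The six-class genotype-frequency model

The classifier implements the standard two-species hybrid-category model
(the model behind the NewHybrids program). An individual's class determines
the expected proportions (φ_AA, φ_AB, φ_BB) of loci whose two gene copies
descend from species pairs AA, AB and BB; the six classes are pure A
(1,0,0), pure B (0,0,1), F1 (0,1,0), F2 (¼,½,¼), backcross to A (½,½,0) and
backcross to B (0,½,½). Given per-species allele frequencies, the genotype
likelihood at a locus is the φ-weighted mixture of the three
"one copy from p, one from q" genotype probabilities
M(i,j; p,q) = p_i q_j + p_j q_i (i ≠ j) or p_i q_i (i = j). Assumptions:
loci unlinked and in Hardy–Weinberg proportions within the source species,
no genotyping error or null-allele model, classes restricted to two
generations of admixture (no F3 or double backcross).

Three estimators share this likelihood:

- **Exact posterior** (`exact_posterior`): product over loci × class prior,
  normalized; requires known (plug-in) frequencies. Used as the analytic
  oracle for the sampler and for fast screening. Plug-in frequencies are
  Jeffreys-smoothed — (count + ½) / (copies + ½·K) over the K alleles in
  the support — so alleles unseen in a finite reference sample do not
  produce hard zeros.
- **Gibbs sampler** (`gibbs_classify`): alternates sampling (a) each
  individual's class from its exact class-conditional probabilities given
  current frequencies, (b) the latent species-of-origin of each gene copy
  given the class, and (c) per-species per-locus frequencies from
  Dirichlet(½ + reference copies + latent copies). Reference parental
  individuals are hard-assigned to their purebred class (supervised mode,
  the default, reflecting the use of allopatric reference populations); an
  unsupervised flag treats them as latent too. Reported posteriors are
  across-chain means of post-burn-in class-indicator frequencies; per-chain
  means are available for convergence inspection. The contract is a fixed
  sweep budget — defaults 20 000 sweeps, 2 000 burn-in, 5 chains, which is
  desk-scale and converges quickly for panels of ≤ 10 loci (the sampler
  matches the analytic posterior within 0.01 when references are large).
- **Admixture EM** (`admixture_q`): a deliberately simple supervised
  two-cluster admixture proportion — per individual, maximize
  ∏_copies [q·f_A + (1−q)·f_B] by EM with plug-in frequencies. It is a
  continuous-q companion to the discrete six-class model, not a
  reimplementation of Structure (no K selection, no admixture
  hyper-priors, no correlated frequencies).

**Thresholding.** `assign` uses strict `>` at T_q, with purebred checks
first, then combined-hybrid membership q_hybrid = ΣP(hybrid classes); above
T_q ≥ 0.5 at most one category can exceed the threshold, so the order is
cosmetic. T_q = 0.5 is accepted (the published power tables include it)
even though thresholds are usually quoted in (0.9, 1].

**Class prior.** Uniform over the six classes. The source protocol states
Jeffreys priors for the model's frequency parameters and reports no
informative class prior.

## Power and accuracy evaluation

Power for a category = correctly identified / true count; accuracy =
correctly identified / assigned count (undefined, reported as NaN/"—", when
nothing is assigned). The combined HYBRID row pools the four admixed
classes and uses q_hybrid as its membership regardless of which subclass
dominates, matching the "sum the assignment probabilities of the four
hybrid categories" convention. Unassigned individuals stay in power
denominators and enter no accuracy ratio. Power per class is provably
non-decreasing as T_q decreases (membership exceedance is monotone), and
the test suite asserts this across the six published thresholds
{0.95, 0.9, 0.8, 0.7, 0.6, 0.5}.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline needs, not
the biology of any real locus:

- **Microsatellite panel** (`simulate_panel`): by default 7 loci — 5
  "private" loci, each with one A-private and one B-private allele at
  within-species frequency 0.7 plus one shared allele at 0.3, and 2 shared
  "variable" loci with frequencies 0.8/0.2 mirrored between species. The
  0.7 choice makes private alleles diagnostic-when-present but absent from
  ~9% of purebred genotypes per locus, the regime in which F1 detection is
  imperfect — the situation the published power tables describe. Alleles
  are positive integers (fragment-size surrogates); no mutation model, no
  genealogy, no null alleles, no missing data in simulated individuals.
- **mtDNA** (`simulate_mtdna`): three regions of 365/319/690 bp carrying
  7/4/21 planted fixed inter-species differences. Within-species background
  polymorphism (off by default) is placed only at non-diagnostic sites so
  planted truth stays unambiguous; at high rates and small sample sizes
  spurious fixed differences can still arise by chance, which is realistic
  but means exact round-trip recovery is only guaranteed at rate 0.
- **Validation sets** (`hybridsim`): purebred pools are pooled-allele
  resamples of the parental genotypes (matching the published simulation
  recipe); crosses draw gametes per-individual (pick a parent, then one of
  its alleles), with a pooled-allele scheme available behind a flag since
  the original tool's internal scheme is not documented. Under
  Hardy–Weinberg the two schemes agree in distribution.
- **Phenotypes**: subcaudal scale state is fixed "absent" for pure A and
  "present" for pure B; hybrids draw present/reduced/absent at
  0.50/0.45/0.05. Continuous variables (head width:length 0.30/0.38/0.355,
  snout ratio 0.55/0.70/0.655, transverse scale count 4.0/6.0/5.4 for
  A/B/hybrid, normal within group) place hybrids intermediate but
  overlapping the B distribution — the overlap that limits field
  identification. The values are stylized, chosen once to give clear but
  not trivial group separation at n ≈ 30/group; `PhenotypeEffects.null()`
  gives the zero-effect configuration for calibration checks.
- **Environment**: salinity uniform on 25–40 ppt for pure A and 0–5 ppt
  for everyone else — disjoint supports encoding "only the saltwater
  species occupies saline habitat" — plus four standard-normal climate
  covariates with no group effect, included to exercise FDR behaviour.
- **Eggs**: per-egg masses drawn from zero-truncated normals matching the
  published group summaries (A: n=280, 85.6±9.7 g; B: n=170, 69.0±29.4 g;
  hybrid nests: n=308, 105.1±20.3 g).

Passing tests on these data show the *pipeline* is correct under its own
model; they say nothing about mutation processes, linkage, genotyping
error, spatial sampling structure, or the realism of any phenotype value.

## Field statistics

All implemented from first principles (each is cross-checked in the test
suite against an independent route — exhaustive enumeration at small n, and
scipy/statsmodels/scikit-bio):

- **Kruskal–Wallis**: tie-corrected H, p from χ² with G−1 df. The χ²
  approximation is rough below n ≈ 8; the tests compare it with exhaustive
  permutation there.
- **BH-FDR** (`fdr_adjust`): step-up adjusted p-values
  min_{j≥i}(p_(j)·m/j) capped at 1, returned in input order. Monotone and
  elementwise ≥ raw p.
- **Pairwise rank-sum tests**: exact two-sided p by full enumeration of
  label assignments when both groups have ≤ 10 observations (mandatory for
  singleton groups), otherwise normal approximation with tie and
  continuity corrections; BH across the pair set.
- **PERMANOVA**: standard distance-based decomposition
  (SS_T = Σ_{i<j} d²_ij/n, within-group analogues per group), pseudo-F with
  (G−1, N−G) df, r² = SS_A/SS_T, significance by random label permutation
  with the add-one convention p = (hits+1)/(m+1) to avoid zero p-values.
  The matrix is caller-supplied; `distance_matrix` provides the default
  Euclidean-on-standardized-columns construction.
- **Summary-statistics ANOVA** (`anova_from_summary`): reconstructs the
  one-way table exactly from per-group (n, mean, sd) — SS_B = Σ n_g(m_g −
  m̄)², SS_W = Σ (n_g−1)s_g² — and equals raw-data ANOVA to floating
  precision whenever the summaries derive from raw data (sd with ddof=1).
  The categorical subcaudal state enters rank tests through the fixed
  ordinal coding present=2, reduced=1, absent=0.

## Numerical and design choices

- All randomness flows from integer seeds (or `numpy` SeedSequences)
  through `numpy.random.default_rng`; identical seeds give byte-identical
  outputs. Multi-stage operations split their seed with
  `SeedSequence.spawn`.
- Alignment columns containing a gap or ambiguity character in any sequence
  are excluded from fixed-site calls (conservative barcoding); ties in
  haplotype classification return "undetermined" rather than an arbitrary
  call. Positions are 0-based internally, 1-based in reports.
- The "variable locus" screen uses a default between-species frequency
  difference threshold δ_min = 0.3; no standard value exists, so it is an
  explicit argument.
- Likelihoods are floored at 1e-300 inside the sampler only to guard the
  log; sampled Dirichlet frequencies are almost surely positive.
- Sampler class indicators are accumulated after burn-in only; chains are
  vectorized together, so `n_chains` replicates differ only through the
  shared generator stream and the run is deterministic given the config.

## Known limitations

- The Gibbs sampler's posteriors depend on how much information pins the
  species frequencies of rare/unseen alleles: with small reference samples
  (tens of individuals) the Jeffreys floor on "wrong-species" private
  alleles leaves borderline backcross genotypes with appreciable purebred
  posterior, so combined-hybrid detection power at strict thresholds is a
  few points lower than the analytic posterior at known frequencies would
  suggest. This is a property of the model under frequency uncertainty,
  not of the sampler: with large references the two routes agree to < 0.02.
  Misattributed private-allele copies from individuals currently sampled
  into a purebred class feed back into the frequency update, which slightly
  reinforces the effect — a behaviour shared by the joint model this
  package implements.
- No linkage, mutation, genotyping-error or null-allele modelling; no
  spatial/geographic simulation; niche modelling (MAXENT-style) and climate
  raster handling are out of scope.
- PERMANOVA assumes exchangeability under the null; no strata/blocking.
- The summary-statistics ANOVA trusts the supplied summaries; internally
  inconsistent published tables can only be checked cell by cell.
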