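# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the limitations of the `pgebv` pipeline. The
pipeline's object of study is phenomics-assisted genomic prediction in a
biparental maize doubled-haploid (DH) population evaluated in testcross
under heat and combined heat-and-drought stress: grain yield is predicted
within and across environments from bin markers (M), canopy hyperspectral
reflectance (H), or both (HM), with four learners (PLSR, random forest,
ridge regression, BayesB) under two cross-validation schemes.

## 1. Synthetic study design

No real field or genotyping data are distributed with the package; every
analysis runs on a generator that emulates the structure of such a
study. The
default configuration (`SimConfig`) is:

| parameter | default | meaning |
| --- | --- | --- |
| `n_lines` | 97 | DH lines from one biparental F1 |
| `n_chrom`, `total_map_cM` | 10, 1150.16 | genome size (cM) |
| `n_snps` | 5,000 | markers before QC (desk-scale working size) |
| `n_envs`, `n_reps` | 4, 2 | 2 years x WW/DS, alpha-lattice with 2 replicates |
| `block_size` | 10 | incomplete-block size (97 = 9 blocks of 10 + 1 of 7) |
| `n_qtl` | 5 | few-QTL additive architecture |
| `sigma_g2`, `gxe_ratio` | 1.0, 0.5 | genetic and GxE variance, (Mg/ha)^2 |
| `sigma_rep2`, `sigma_block2`, `sigma_e2` | 0.1, 0.1, 2.0 | design and plot error variances |
| `missing_rate`, `het_error_rate` | 0.08, 0.025 | GBS noise (matches un-imputed GBS data after filtering) |
| `n_bands`, `n_flights` | 62, 5 | reflectance bands 392-850 nm, flights 55-83 d after planting |
| `env_means` | 5.7, 3.6, 5.9, 1.9 | Mg/ha for 14WW, 14DS, 16WW, 16DS |

**DH meiosis.** Each line is one gamete of the F1, doubled: per
chromosome the starting parental phase is a fair coin, crossover counts
are Poisson(length/100) with uniform positions (Haldane model, no
interference). Calls are strictly homozygous (+/-1 coding) before noise.
The model is closed-form testable: the recombinant fraction between
markers d cM apart converges to (1 - e^(-d/50))/2.

**GBS noise.** Each call independently becomes missing with rate 0.08,
otherwise flips to heterozygous with rate 0.025. These defaults are typical
of filtered, un-imputed maize GBS data (~8% missing and ~2.5%
heterozygous calls in DH lines, where heterozygosity is necessarily an
artifact).

**Genetic values.** `n_qtl` positions are drawn without replacement;
Gaussian effects are rescaled so that the in-sample variance of the
genetic values equals `sigma_g2` *exactly*. This makes the genetic
variance a hard invariant rather than a random target, at the cost of a
small correlation between effect size and the realized QTL genotype
frequencies (negligible at 97 lines). The few-QTL default reflects a sparse
architecture for yield under severe abiotic stress; it is the regime
where BayesB's point-mass prior should beat ridge regression.

**Trials.** Plot value = grand mean + genotype + environment + GxE +
rep(env) + block(rep) + error, all Gaussian. GxE deviations are iid per
line x environment and exactly centered within environment. Environments
are labeled year x treatment; their means default to yield levels
realistic for tropical maize testcrosses under these regimes (5.7 and
5.9 Mg/ha well-watered; 3.6 and 1.9 Mg/ha under drought). Genotypes are freshly randomized within
each replicate and cut into consecutive blocks of 10, a typical block
size for alpha-lattices of ~100 entries. Plot-level heritability implied by the
defaults is 1.0/3.7 ~ 0.27; the entry-mean repeatability implied by Eq.
(2) below is 1/(1 + 0.5/4 + 2/8) ~ 0.73.

**Reflectance.** A latent physiological score per line x environment,
s = 0.7 z_g + 0.5 z_gxe + N(0, 0.5^2), drives every band:
reflectance(plot, band, flight) = baseline(lambda) + w(band, flight, env) s
+ measurement noise. The baseline is a vegetation-like spectrum (dark
visible range, green bump, red edge at ~715 nm, NIR plateau). Loadings
grow linearly with flight (later flights more informative) and are tilted
by environment: bands above 700 nm carry 1.6x weight under drought
stress, the early year reads relatively more through the visible range
and the late year through the NIR (x1.12-1.15), and stressed trials have
double the measurement noise. These factors were calibrated once to repeatability levels typical of
aerial hyperspectral trials under such conditions (WW ~0.5, DS ~0.35,
with the informative spectral range shifting between seasons); with them
the generator yields band repeatabilities of ~0.25 (DS) to ~0.45 (WW)
rising with flight number from ~0.2 to ~0.5.

**Band grid.** A 62-band grid over 392-850 nm implies ~7.5 nm
band spacing; the generator uses 62 evenly spaced band centers and
treats the instrument's finer spectral resolution as a sensor property,
not the band spacing.

**Seeds.** All stages draw from seeds derived deterministically (via
`numpy.random.SeedSequence` spawn keys) from the single master seed, so
one integer reproduces the entire study bit-for-bit.

## 2. Bin map

The five QC steps operate on the noisy matrix in a fixed order: (1) drop
SNPs with MAF <= 0.05 (hets count half per allele) or missing rate >=
0.20 — thresholds are strict inequalities exactly as stated ("greater
than 0.05", "less than 20%"); (2) drop lines with heterozygosity > 5% or
missing > 20%; (3) drop SNPs whose maximum similarity to any neighbour in
a centered window of 8 SNPs (4 each side, truncated at chromosome ends)
is below 0.95, in one pass (removals do not cascade); (4) merge
consecutive SNPs into bins by a greedy left-to-right scan: a SNP joins
the bin if its similarity to the bin's running consensus is >= 0.95,
else opens a new bin; (5) treat bins as markers, re-estimating adjacent
distances from recombinant fractions with the Haldane map function
d = -50 ln(1 - 2r).

*Similarity* between two call vectors is orientation-free —
max(p_match, 1 - p_match) over lines where both calls are homozygous —
because allele labeling is arbitrary and heterozygous calls are GBS
artifacts in a DH population. Pairs with fewer than 10 comparable lines
are treated as non-informative (they never support retention or merging).
The bin consensus call per line is the majority non-missing call with
ties mapped to missing (the consensus never invents a call); a candidate
SNP anti-correlated with the consensus is flipped before voting.

On noise-free data with threshold 1.0 the bins equal the exact partition
into runs of identical segregation patterns (verified against a
pattern-hash oracle). At the defaults, the bin count is
recombination-limited: 97 lines x 11.5 Morgans give ~1,100 crossovers,
and merging at 95% similarity (<= 4 discordant lines) collapses them to
~120-130 bins regardless of marker density. Real GBS bin maps of comparable populations come out several times
larger because real data carry additional heterogeneity (segregation
distortion, local error bursts) that the generator does not model; no result in this package depends on the absolute bin count.

## 3. Mixed models, BLUEs and repeatability

The trial model is

    Y_mhlk = u + a_h + E_ml + a_h E_ml + r(E_ml) + r(E_ml)delta_k + eps_mhlk

with genotype a_h, environment E, their interaction, replicate within
environment and block within replicate. Two fits are used, mirroring
standard multi-environment practice:

* **per environment, genotype fixed** (cell-means parameterization; rep
  and block random) — the fixed-effect solutions are the BLUEs used as
  responses and features downstream;
* **all random, across environments** — REML variance components for
  entry-mean repeatability

      h^2 = sigma_G^2 / (sigma_G^2 + sigma_GxE^2 / l + sigma_e^2 / (r l)),

  with l = 4 environments and r = 2 replicates. A within-environment
  variant h^2 = sigma_G^2 / (sigma_G^2 + sigma_e^2 / r) is also exposed;
  published per-environment repeatabilities are typically of this form.

REML is computed on Henderson's mixed-model equations: monotone EM
updates for a short warm-up (with a method-of-moments start for the
combined model), then average-information (AI) steps with step-halving,
each accepted only if the restricted likelihood does not decrease, with
EM as fallback. Components are floored at 1e-10 var(y) during iteration;
a component pinned near zero while still shrinking is frozen at the
boundary and reported as 0 (truncation recorded). Convergence is a
maximum component change below 1e-8 relative to var(y), max 500
iterations. The restricted likelihood is evaluated through the MME
identity -2 l_R = (n-p-q) log s_e^2 + sum_i q_i log s_i^2 + log|C| +
y'Py, verified in the tests against the dense-V formula and against
lme4's REML fits (agreement to ~1e-3 relative on the default study).

The BLUE table holds 388 genotype x environment rows by 311 columns
(grain yield + 62 bands x 5 flights); per-environment fits warm-start
from the previous trait's components, which cuts the full table to ~15 s.
Missing plots are handled by the likelihood (no imputation); a genotype
absent from an environment gets a missing BLUE, propagated and counted.

## 4. Learners

All four learners are implemented in this package; scikit-learn and R
serve only as independent cross-checks in the tests. All standardize
feature columns internally (fit on the training partition only), so
marker and reflectance blocks are commensurate in HM; zero-variance
columns are excluded from scaling and receive zero coefficients.

* **Ridge (RR).** beta = (X'X + lambda I)^{-1} X'y on standardized X,
  unpenalized intercept, solved in the primal or dual form (whichever is
  smaller; both verified equal to 1e-8). `lambda="reml"` (default)
  profiles the equivalent random-effects model sigma_e^2/sigma_b^2 on the
  eigendecomposition of XX', i.e. the marker-BLUP shrinkage level.
* **PLSR.** NIPALS with deflation on standardized X, univariate y;
  `ncomp="cv"` (default) picks 1-15 components by inner 5-fold CV
  (smallest MSE, ties to fewer). At full rank PLSR reproduces OLS.
* **Random forest (RF).** Bagged unpruned CART regression trees;
  variance-reduction splits over mtry = floor(p/3) features drawn fresh
  per node; terminal nodes at <= 5 samples; out-of-bag predictions
  retained. Defaults (ntree = 500) follow the conventions of the R
  `randomForest` package.
* **BayesB.** y = mu + X beta + e with beta_j = delta_j b_j,
  P(delta_j = 0) = pi = 0.9, b_j | s_j^2 ~ N(0, s_j^2), s_j^2 ~
  scaled-inv-chi2(nu = 5, s^2) — the standard augmentation of a point
  mass at zero plus a t-slab. Gibbs sampling integrates b_j out of the
  inclusion step (marginal Bayes-factor form); marker variances are
  redrawn from the prior when excluded; the slab scale solves
  E[genetic variance] = 0.5 var(y) given pi and p. Defaults: 6,000
  iterations, 1,000 burn-in. Chains are bit-identical given a seed.
  pi was set below the 0.95 often used with dense marker panels because
  the bins number only a few hundred.

The Gibbs sampler and the CART kernels are JIT-compiled with numba;
first use in a fresh environment costs a one-time compilation of ~20 s.

## 5. Prediction schemes

Datasets are keyed (genotype, environment) with y = grain-yield BLUE.
M features are coded bin calls (-1/+1, mean-imputed per bin across
lines — a genotype attribute, so imputed once globally), identical for a
genotype across its environments; H features are the 310 band x flight
BLUEs of that genotype-environment; HM concatenates both blocks.

* **Within-environment two-fold CV**: per environment, genotypes split at
  random into halves (48/49); both directions are scored and averaged;
  repeated `reps` times. A pooled-split variant (one split over all 388
  records) is exposed via `pooled=True`.
* **Across-environment leave-one-environment-out (LOEO)**: each
  environment's 97 records are predicted from the 291 records of the
  other three. By default the held-out environment contributes its own
  (pre-harvest) reflectance features at test time; `use_target_h=False`
  substitutes the genotype's training-environment average H instead.

r_GP is the Pearson correlation of predicted vs observed BLUEs, per
environment, averaged over environments (and replicates/directions).
Undefined correlations (constant predictions) contribute 0 and are
flagged rather than dropped, since dropping them would inflate averages.
Bootstrap standard errors resample (predicted, observed) pairs with
replacement (default 1,000 resamples at desk scale; 10,000 is the conventional
choice at these sample sizes); degenerate resamples are skipped and counted, and
more than 50% degenerate is an error.

The experiment grid is the full factorial {2 schemes} x {PLSR, RF, RR,
BayesB} x {M, H, HM} = 24 cells. Replication defaults are desk-scale
(10); the preset `reps="paper"` restores the full study-scale per-learner
counts (PLSR 1000, RF 2000, RR 3000, BayesB 1000). Failed cells are recorded
with their error and the grid continues.

## 6. Problem sizes and runtime

Default sizes are chosen so the full pipeline runs on one core in
minutes: 5,000 simulated SNPs (QC behavior is identical at higher marker
counts since bins are recombination-limited), 310 reflectance features,
10 CV replications for the grid (~3.5 min end to end). The test suite
uses further-reduced sizes (500-800 SNPs, 16-32 band features, 2-4
replications) for its Monte-Carlo checks; ordering checks aggregate over
20 master seeds with a one-sided sign test at alpha = 0.05 (>= 15/20).
`scripts/acceptance.py --seed N --out f.json` re-runs the default-scale
pipeline from scratch and writes the headline quantities.

## 7. What the generator does and does not show

Passing tests demonstrate that the pipeline's algorithms are correct
(against closed forms, brute-force oracles, lme4 and scikit-learn) and
that the expected qualitative phenomena emerge under the generator's
assumptions: BayesB beats ridge under a few-QTL architecture (20/20
seeds), and adding hyperspectral to marker features improves accuracy
(20/20 seeds), with accuracies (r_GP ~ 0.4-0.7) in a realistic range.

They do not certify behavior on real data. Known gaps: (i) GxE is iid
additive — real stress trials show structured, partly antagonistic GxE, with some
environments nearly unpredictable from the others. A direct consequence, measured over 20 seeds: under the
default generator, across-environment LOEO *matches or exceeds*
within-environment accuracy, because LOEO trains on three environment
replicates of the same 97 lines while a within-environment half-split
trains on 48 records, and iid GxE plus transferable spectra are not
punishing enough to reverse that data advantage. The within-beats-across pattern reported in real stress-trial studies
therefore reflects environment heterogeneity beyond this generator's
structure, and the corresponding ordering check in the acceptance suite
fails by design of the generator, not by a defect of the CV code. (ii) Reflectance is linear in a single latent
score; real spectra are high-rank with band-specific chemistry. (iii)
No segregation distortion, no epistasis, no spatial field trend, no
pixel-level mixing. (iv) Bin counts are recombination-limited (~126),
not data-heterogeneity-limited as in real GBS bin maps (hundreds of
bins from tens of thousands of SNPs).

## 8. File formats

CSV, UTF-8, comma-separated; missing = empty cell (never "."). Genotype
calls export as {0, 1, 2} dosage with parent A = 0; positions are cM
floats; physical positions in the minimal VCF writer encode cM x 10^4
(1-based, GT-only, unphased, biallelic). Floats are written with a fixed
general format so reruns are byte-identical; run metadata (seed, version,
row counts) lives in a JSON sidecar manifest, and timestamps appear only
in logs.
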