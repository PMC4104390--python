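# Methods

## The estimation problem

`snpherit` estimates the proportion of liability variance of a rare binary
trait that is captured jointly by common SNPs, from an ascertained
case-control sample. The trait is modeled through a latent standard-normal
liability; an individual is a case when liability exceeds
t = Φ⁻¹(1−K) for population prevalence K. Because cases of a rare trait are
massively over-represented in any feasible study (case proportion P ≫ K),
the analysis proceeds in three stages: (1) a genetic relationship matrix
(GRM) summarizing realized relatedness among nominally unrelated
individuals, (2) a linear mixed model fitted by REML directly on the
observed 0/1 disease status, (3) a post-hoc conversion of the
observed-scale estimate to the liability scale with an ascertainment
correction.

## GRM

Entries follow the standard GREML definition with sample-estimated allele
frequencies and per-pair denominators N_jk over SNPs non-missing in both
individuals; nothing is imputed. The diagonal uses the
`1 + [x² − (1+2p)x + 2p²]/(2p(1−p))` form (expectation 1 under
Hardy–Weinberg at the estimated frequency) rather than the plain
standardized self-covariance, for interoperability with GCTA-format GRM
files, which the package reads and writes bit-exactly (float32 lower
triangle). Frequencies are estimated from the pooled case+control sample.
Under strong ascertainment this biases the centering of causal SNPs — it is
retained deliberately because it reproduces the procedure as actually run
on case-control data.

Defaults: minimum MAF 0.01 ("common" variants; configurable), no
relatedness-cutoff pruning (an option exists). Chromosome partitioning
(all / focal chromosome / complement) restricts the SNP set before
averaging, so the un-normalized numerators are exactly additive across the
partition when there is no missingness.

The imperfect-LD adjustment shrinks the GRM toward its expectation:
β = 1 − (c + 1/N) / Var(A_jk) over off-diagonal entries, applied as
A*_jk = βA_jk off-diagonal and A*_jj = 1 + β(A_jj − 1), with c = 0 by
default. The adjustment is undefined when the off-diagonal variance does
not exceed the sampling floor c + 1/N — which is the typical situation in a
perfectly homogeneous unrelated sample, where Var(A_jk) ≈ 1/N; it is
meaningful in structured samples. It is intentionally not idempotent
(re-applying shrinks again), and an error is raised rather than a silent
no-op when undefined.

Population structure is handled by projecting out top eigenvectors of the
GRM as fixed-effect covariates (deterministic sign convention: the
largest-magnitude loading is positive). Two PCs is the conventional choice
for mildly structured European case-control panels; zero is appropriate for
a homogeneous cohort.

## REML

The restricted log-likelihood
−½[log|V| + log|XᵀV⁻¹X| + yᵀPy] with V = Σ_r σ²_r A_r + σ²_e I is exposed
publicly so independent oracles (grid searches) can maximize it. Fitting
uses one EM warm-up step followed by average-information updates. Numerical
policy:

* **Constraint** (default on): components are clamped at a floor of
  10⁻⁶ × Var(y); consequently observed-scale h² lies in [0, 1]. A clamped
  component with an outward-pointing gradient is flagged as a boundary
  estimate and its standard error marked unreliable. With the constraint
  off, genetic components may go negative (used to verify that the pile-up
  of null estimates at zero is produced by the clamp, not the optimizer).
* **Step halving**: any proposed update that would decrease the restricted
  likelihood, or make V indefinite, is halved toward the current point (at
  most 30 times); a plain EM step is the fallback; if no admissible ascent
  direction remains the current (boundary) point is declared the optimum.
* **Convergence**: |Δ log L| < 10⁻⁸, at most 100 iterations;
  non-convergence returns the fit flagged `converged=False` with a warning.
* **Single-GRM fast path**: with one component the GRM is eigendecomposed
  once and all per-iteration quantities are computed in the eigenbasis in
  O(n·p²); this is exact algebra, not an approximation, and is
  cross-checked against the dense multi-component path and against grid
  maximization of the public likelihood in the tests.
* Standard errors come from the inverse AI matrix at the optimum;
  heritability ratios and their SEs use the delta method. Starting values
  split Var(y) evenly across components.

Binary status enters as 0/1 — a linear model on disease status, not a
liability-link GLMM; the liability interpretation is recovered by the scale
transformation below. Chromosome-partitioned results are reported from
separate single-component fits by default (an explicit joint two-component
fit is available through the library), so the partitioned estimates need
not sum to the genome-wide one.

## Liability transformation

h²_liab = h²_obs · [K(1−K)/z²] · [K(1−K)/(P(1−P))], with z = φ(t). P is
always computed from the analyzed phenotype vector (an override exists for
reproducing published rows). SEs transform by the same factor (delta method
on a linear map). At K = P the factor reduces to K(1−K)/z², and at
K = P = 0.5 it is exactly π/2. Both the ascertainment-corrected (default)
and the unascertained variants are implemented; the transformation is post
hoc, so one observed-scale fit serves any number of assumed prevalences.

## Synthetic cohorts

The generator produces the structure the estimator assumes: allele
frequencies uniform on a MAF range (default 0.05–0.5), independent
biallelic SNPs laid out over chromosomes, causal SNPs placed per chromosome
with normal effects on the standardized-dosage scale normalized so each
chromosome's genetic-liability variance equals its prescribed share of h²
exactly, residual liability N(0, 1−h²), and case status by thresholding at
t(K). Ascertainment is by rejection sampling — individuals are simulated
until the case quota fills — so case genotype distributions are exact under
the threshold model. Only causal dosages are generated during rejection
(the liability depends on nothing else); non-causal dosages are drawn
afterwards for retained individuals, which is distributionally identical
and makes prevalences down to ~10⁻³ tractable; a cap (default 10⁷ simulated
individuals) guards lower prevalences, and the genuinely rare settings
(K = 5×10⁻⁴) are exercised through the negative-control design, which needs
no ascertainment. An optional two-subpopulation Balding–Nichols mode
(parameter Fst) creates structure-confounded cohorts for testing PC
adjustment. Five named RNG streams (frequencies, genotypes, effects,
residuals, missingness) hang off one integer seed, so toggling missingness
leaves genotypes untouched.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent given subpopulation), realistic human allele-frequency spectra,
genotyping-batch artifacts, imputation error. Passing tests therefore
validate the estimator under its own model assumptions — they quantify
correctness of the machinery, not robustness to LD misspecification on real
arrays (the LD shrinkage adjustment is exercised only qualitatively).

## Experiment drivers and reporting conventions

* `run_partitioned`: all/chr6/complement single-component fits at one or
  more prevalences; model SE per fit.
* `run_subsample`: repeated draws (without replacement within a draw,
  independent across draws, overlap allowed) of n cases and ratio·n
  controls from one large pool; reports mean and SD *across replicates* —
  a different "(·)" convention from the model SE, kept deliberately.
  Default 20 replicates and a 1:3 case:control ratio, the design used to
  probe stability at 75 and 200 cases.
* `run_negative_control`: an all-SNP fit on a cohort whose labels are
  independent of genotype (two relabeled control groups); near-zero
  constrained estimates indicate no spurious heritability from the
  pipeline.

Problem sizes used by the shipped validation runs: 5,000 SNPs over 20
chromosomes; 288/864 for the negative control; 200/600 ascertained at
K = 0.008 for parameter recovery; a 400-case pool for the subsampling
comparison. These sizes make each replicate's GRM and REML fit take on the
order of a second on one CPU while leaving sampling noise small enough for
the qualitative patterns to be stable.

## Known limitations

* Observed-scale GREML with the cumulative-normal ascertainment correction
  is known to attenuate toward zero under strong case-control ascertainment
  (severe K ≪ P): at K ≈ 0.008 with P = 0.25 and true liability h² = 0.5
  the pipeline's replicate mean sits around 0.44–0.46 rather than 0.50.
  This is a property of the estimator family implemented here, shared with
  the standard tooling it mirrors, not a numerical defect; methods that
  address it (e.g. phenotype-correlation regression) are out of scope.
* Estimates at the h²_obs boundary carry unreliable SEs (flagged).
* Autosomal, additive effects only; no dominance, interaction, or
  X-chromosome models; PLINK v1 and GCTA binary formats only.
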