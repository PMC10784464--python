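# Methods

`metgp` implements a two-stage genomic-prediction workflow for single-cross
hybrids evaluated in multi-environment trials (MET), together with a
synthetic-data generator that reproduces the workflow's assumed data
structure so every stage can be tested without field data.

## Stage 1: per-trial adjusted means

Each trial (location x year x water regime) is analysed independently by
ordinary least squares,

    y = mu + replicate + set + hybrid + e,      e ~ N(0, sigma2_e I),

all effects fixed. Hybrids are nested in sets, so the set/hybrid
decomposition is aliased; the reported adjusted mean (eBLUE) is the
estimable function mu + set(h) + hybrid(h) with replicate effects averaged
out. In a balanced complete design this equals the raw hybrid mean. The
fit uses minimum-norm least squares on the full dummy design; every
reported mean is checked for estimability against the design's row space
(a rank-deficiency beyond the set/hybrid nesting raises an error naming
the hybrid). Residual variance is RSS / (n - rank). A consequence worth
noting: adding a constant c to one of f replicates moves every eBLUE by
c/f — hybrid contrasts, which are what the joint model consumes, are
invariant.

Outliers are removed from the eBLUEs in a single pass, per environment and
trait, using Tukey fences: values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]
with quartiles by the linear-interpolation convention. The interval is
closed, so an all-equal group (IQR = 0) loses nothing. Applying the rule
at the eBLUE stage (rather than to raw plots) and in a single pass makes
the filter deterministic; re-running it on its own output can remove more
points only if fences are recomputed, which we do not do. Commercial-check
entries may sit in the plot table (they improve the stage-1 fit) but are
excluded from all downstream prediction.

## Stage 2: joint GBLUP with compound-symmetric G x E

The q environments of one regime are modelled jointly. With cells ordered
environment-major, hybrid-minor:

    ybar = X b + u_a + u_d + e
    u_a ~ MVN(0, [I_q s2_ua + rho_a s2_ua (J_q - I_q)] kron A)
    u_d ~ MVN(0, [I_q s2_ud + rho_d s2_ud (J_q - I_q)] kron D)
    e   ~ MVN(0, I s2_e)

A is the additive genomic relationship matrix from centered dosages
(W = M - 2p, A = WW' / 2*sum p(1-p)) and D the dominance matrix from the
dominance coding (-2q^2, 2pq, -2p^2 for dosages 2, 1, 0, divided by
sum (2pq)^2). Allele frequencies are estimated from the hybrid panel
itself, which gives A exact zero row sums — a property the tests exploit.
Dropping u_d yields the additive-only model (GBLUP-A); restricting to a
single environment (q = 1, no correlations) yields the within-environment
variant. Genetic parameters are the variance ratios h2 = s2_ua / (s2_ua +
s2_ud + s2_e), d2 likewise for dominance, H2 = h2 + d2. Model comparison
uses the likelihood-ratio statistic 2(logL_full - logL_reduced) against a
chi-square with 1 degree of freedom at the 5% level. The statistic is
referred to the plain chi-square despite the known boundary-mixture issue
for variance components — the workflow this package mirrors does the
same, and we keep fidelity over asymptotic nicety.

### REML

Variance components maximise the restricted log-likelihood
-(1/2)[log|V| + log|X'V^-1 X| + y'Py] over transformed parameters: log
variance ratios gamma = s2/s2_e and correlations mapped onto their open
interval (-1/(q-1), 1) by a scaled logit. The residual variance is
profiled out analytically, which removes one dimension and much of the
objective's ill-conditioning. Optimisation is bounded L-BFGS-B with
numerical gradients, at most 200 iterations, and up to 3 deterministically
jittered restarts on non-convergence; estimates landing on a transform
bound are flagged as boundary solutions rather than silently clipped.

Likelihood evaluations never factorise the full observed-cell covariance.
Any pair of compound-symmetry matrices is diagonalised by one orthogonal
basis (the equal-weights vector plus any completion), so on a complete
p x q grid V block-diagonalises into one "mean" block and q - 1 identical
"contrast" blocks of size p. Masked cells (cross-validation holdouts) are
handled by partitioned-inverse identities — solves against V restricted
to observed cells cost one factorisation per distinct block plus one of
size n_masked. A dense reference implementation is kept and the test
suite asserts agreement of the two paths to numerical precision. Missing
cells are handled by row/column deletion (no data augmentation). A ridge
of 1e-6 is added to kernel diagonals before any factorisation; realized
kernels are otherwise frequently semidefinite.

Predictions are conditional means under the fitted model: environment
effects by generalized least squares, then for any target cell
Cov(u_target, y_obs) V_obs^-1 (y_obs - X bhat), with the covariance
assembled from the same compound-symmetry kron kernel blocks. Small
instances are verified against an explicit joint-Gaussian conditional-mean
oracle to 1e-8.

## Tree ensembles

Bagging, random forest and squared-error gradient boosting operate on a
fixed feature layout: marker dosages first, then one-hot location and
year indicators (one-hot rather than ordinal: portable across tree
implementations and split-equivalent for binary factors). Defaults follow
the study setup: 500 trees for bagging and random forest; 250 trees,
shrinkage 0.1 and depth 3 for boosting; random forest samples
floor(p/3) (at least 1) candidate predictors per split with p counted
over all columns including the environment indicators; bagging uses all
p, and with m_try = p the two methods coincide by construction.
Bagging/RF trees are fully grown with minimum leaf size 5 (the common
default of the reference tools); boosting is depth-limited instead.
Boosting accumulates trees around the training-mean baseline — a zero
baseline would merely shift predictions by a constant. The base tree
learner is scikit-learn's `DecisionTreeRegressor`; the bootstrap,
averaging and shrinkage loops are this package's code and are asserted by
property tests (one-tree identity, monotone training error, the
RF-to-bagging collapse, seed reproducibility). No row subsampling is used
in boosting.

## Cross-validation design

Hybrids are split into k = 5 folds after shuffling within cross-type
strata (line group x tester group), dealt round-robin so fold sizes
within a stratum differ by at most one; 265 hybrids give five folds of
53. Three scenarios mask cells of the validation fold: CV1 removes all q
environments (a never-phenotyped hybrid), CV2-50% a uniformly random
q/2, CV2-25% a uniformly random q/4. Folds and masks are drawn once per
repeat and shared by every method, so method comparisons are paired; 5
repeats re-randomise both folds and masks. Skill is the per-environment
Pearson correlation between held-out eBLUEs and predictions. The default
summary scores each fold separately and reports the mean with SE =
SD(scores)/sqrt(repeats).

Two measurement options exist for small or scaled-down panels and are
used by the benchmark experiments:

* `pool_folds` scores each repeat once over the pooled held-out
  predictions of all folds (every validation hybrid predicted exactly
  once per repeat). Per-fold scoring on a small panel computes
  correlations from very few cells per environment, which is noisy and
  small-sample biased against the sparser scenarios.
* `nested_masks` draws the CV2-25 masked environment inside the CV2-50
  pair (and CV1 masks everything); each scenario's marginal masking law
  is unchanged, but scenario contrasts become paired, isolating the
  information effect from mask sampling noise.

## Synthetic data generator

The generator emulates the study design: 85 dent + 86 flint + 17 group-C
inbred lines crossed to two testers (drawn from the flint and dent pools)
for 265 hybrids; four environments per water regime (two locations x two
years); sets of hybrids fixed across trials; 2-3 replicates. Marker base
frequencies are uniform on the configured MAF range; heterotic-group
divergence perturbs them on the logit scale with scale
`group_divergence` (default 0.3, a moderate differentiation; the trait
model shares marker effects across groups, matching the assumption of
equal allele substitution effects between pools). Parents are fully
homozygous; hybrids are parental means. Markers are unlinked — linkage
disequilibrium is irrelevant to every inferential contract tested here.

Genetic effects are the exact generative counterpart of the joint model:
per marker, the q-vector of additive effects is MVN with
compound-symmetric correlation rho_a, scaled by sigma2_a over the
VanRaden denominator of the realized panel, so Cov(u_a) = CS(sigma2_a,
rho_a) kron A_realized holds exactly (and likewise for dominance with the
dominance coding). The components are therefore defined relative to the
realized kernel; the within-environment variance of u_a equals sigma2_a
only up to mean diag(A), which for a testcross panel deviates from 1.
This is deliberate: it makes REML recovery a well-posed check. Plot
values add environment intercepts (defaults: the observed water-stress
grain-yield trial means 3.49, 2.86, 3.34, 4.93 t/ha), optional replicate
and set effects (defaults 0 — their real-trial magnitudes are not
reported anywhere, so they are exercised by tests rather than asserted),
genetic values and N(0, sigma2_e) plot noise. Default genetic parameters
are the grain-yield water-stress joint estimates (0.60, 0.30, 0.81,
rho_a 0.35, rho_d 0.83).

What the generator does not emulate: linkage and recombination, selection
history, pedigree structure beyond line x tester, group-specific marker
effects, spatial field trend, and heteroscedastic residuals. Passing
tests therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to their violation in real
trials.

## Benchmark experiments and problem sizes

`metgp.experiments` (driven by `scripts/acceptance.py` and the
acceptance tests) runs:

* ratio arithmetic on the published variance-component table (60 cells;
  two printed values are known truncation anomalies and the check allows
  them);
* dominance shares and the phenotyping-budget worked example (the
  budget function reports lines x per-line cost for genotyping);
* REML recovery on 20 fresh panels of 300 hybrids x 4 environments,
  truth (0.6, 0.3, 0.8, 0.35, 0.8);
* oracle-equivalence error norms on small instances;
* exact CV masking combinatorics at 265 hybrids;
* the qualitative orderings (CV2-25 >= CV2-50 >= CV1 for GBLUP-AD;
  GBLUP-AD >= GBLUP-A) on 20 panels at the full 265-hybrid scale with
  2 repeats, pooled scoring and nested masks — the paired design chosen
  because the CV2-25 vs CV2-50 contrast is a small effect that unpaired
  masking noise would otherwise dominate;
* the ensemble combination-rule contracts at the study hyperparameters.

## Known limitations

* The LRT p-value ignores the boundary problem for variance components
  (deliberate, see above).
* Compound symmetry imposes one common correlation per effect type;
  unstructured or factor-analytic G x E covariances are out of scope.
* Imputation is per-marker modal fill (ties to the lower dosage) — a
  placeholder adequate for QC-filtered panels with <= 20% missingness,
  not an imputation method in its own right.
* Within-environment fits on a single environment cannot separate
  additive from residual variance when the kernel is near-identity;
  realized genomic kernels keep the model identified.
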