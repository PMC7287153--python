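# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Models and procedures

**Tree preparation.** Trees are rooted, with branch lengths in relative
time. Polytomies are resolved into random bifurcation sequences whose new
internal branches get a fixed small length ε (default 1e-4), randomized by
seed. Ultrametricization defaults to `extend` (terminal branches lengthened
until all root-to-tip depths equal the maximum), which preserves all
internal structure; `scale_paths` (node heights rescaled so each
root-to-tip path stretches roughly proportionally) is provided as a
sensitivity alternative. Pruning preserves root-to-tip depths: history
removed on one side of the root survives as a root edge length, which all
downstream covariance computations treat as shared by every tip. Trees with
a single tip are rejected everywhere — no comparative method applies.

**Mk habitat model.** The habitat character takes values in an ordered
state list (CS, HF, WA). ER has one exchange rate q; SYM has K(K−1)/2
symmetric rates. Both generators are symmetric matrices, so transition
matrices come from the spectral decomposition (ER additionally uses the
closed form P_ii = 1/K + (1−1/K)e^{−Kqt}). The likelihood is Felsenstein
pruning with per-node rescaling; the root prior is uniform 1/K
(configurable), matching the flat prior customary for re-rooting
reconstructions. Rates are optimized on the log scale in [1e-8, 1e3] from
10 seeded log-uniform multi-starts (L-BFGS-B). The LRT degrees of freedom
come from parameter counts — 2 for ER vs SYM at K = 3. (Published accounts
of this comparison sometimes print a different subscript on the χ²; the
parameter-count df is what the nesting implies and is what the package
reports.) Marginal ancestral states re-root the tree at each internal node
with rates held at the global ML estimates (empirical Bayes); ties in the
most-probable-state assignment break by state order with a warning.

**Contrasts and rates.** Traits are ln-transformed then z-scored per column
(sample SD, ddof = 1) across the full taxon set once, before any clade
extraction, so clade rates share one scale. Contrasts follow the standard
algorithm (postorder; contrast (xᵢ−xⱼ)/√(bᵢ+bⱼ); weighted node value;
parent branch extended by bᵢbⱼ/(bᵢ+bⱼ)). The rate estimator β = Σc²/(n−1)
equals the GLS quadratic form (x−â1)ᵀC⁻¹(x−â1)/(n−1), which the tests
verify. Rate comparisons use two-tailed variance-ratio F tests with df
(n_a−1, n_b−1); the among-trait comparison on the full tree ignores
cross-trait dependence (a known limitation of the classical procedure).
Compact letters come from maximal cliques of the non-significance graph at
uncorrected α = 0.05. At the default clade sizes (10/12/12) the joint power
to letter an 8×-rate clade separately from both others is ≈ 0.8; expecting
near-certain detection at this n would be unrealistic.

**λ and PGLS.** The λ transform multiplies off-diagonal entries of C.
Likelihoods are full ML (β and σ² profiled analytically; λ by bounded
scalar search on [0, 1] with both endpoints checked), so AICs are
comparable across models with different fixed effects. AIC counts: each
regression coefficient, σ², and λ when estimated (so intercept-only fixed-λ
models have k = 2, the ML-λ signal model k = 3). The overall F test is
computed on the λ̂-whitened problem against the intercept-only fit, df
(p, n−p−1). Two calibration facts, established by simulation and pinned in
tests: with λ fixed at its true value the F test is exact (measured
rejection 0.050 at nominal 0.05); with plug-in ML λ and a phylogenetically
clumped factor the test is anticonservative by roughly a factor of two at
n = 34, because the factor absorbs clade structure and λ̂ is biased down.
`pgls_fixed_lambda` exists for exactly this sensitivity check. Relatedly,
at n = 34 the AIC comparison "ML-λ model beats λ = 0" succeeds in roughly
three quarters of replicates for a BM trait, not near-always: the λ
parameter costs 2 AIC units against a modest likelihood gain.

**Phylogenetic PCA.** Covariance-mode (traits are pre-standardized
upstream; λ is not re-estimated inside the PCA). Scores are centered,
unwhitened projections; GLS-whitened scores have covariance
diag(eigenvalues), which the tests check. Component signs follow a
deterministic convention — the largest-|loading| entry of each component is
positive — so runs are comparable; analyses that need a biological
orientation (e.g. "slow strategy scores low") re-orient by the sign of a
named loading (the package uses LMA). One selection effect worth knowing:
the leading axis maximizes C⁻¹-weighted variance, so PC1 preferentially
captures directions that look *least* Brownian, and its apparent λ is
biased low relative to a randomly chosen BM trait.

**Covariance ratio.** Computed on the contrast covariance taken about zero
(contrasts have zero expectation under BM; centering is available behind a
flag since the classical implementations do not document their choice).
Significance is one-tailed on the low side with the +1/+1 rule, so p > 0
always. With 7 traits in modules of 5 and 2 there are only C(7,2) = 21
distinct trait-to-module assignments; a naive permutation that can redraw
the observed assignment places ≈ 1/21 of the null mass in exact ties at the
observed value and floors the attainable p near 0.05 regardless of the
permutation count. The null therefore samples uniformly from the 20
assignments that differ from the observed one. Measured calibration under
a fully integrated truth: type-I 0.078 at α = 0.05 (within a reasonable
band for a 21-assignment group); power 1.0 at n = 34 under a strongly
modular truth. With fewer than 10 distinct assignments the test switches to
exact enumeration with a warning.

## The synthetic-data generator

The generator emulates the study design: 34 taxa in three clades
(10/12/12) on an ultrametric depth-1 tree; an ER habitat history with a CS
root and 5–9 changes (resampled with bounded retries, all three states
required at the tips); seven log-scale traits under multivariate BM with a
two-block covariance (slow block LMA/LT/LD/RSR, fast block PH/LA/AR;
within-block correlation 0.6, between 0, unit rates); λ = 0 for AR and 1
otherwise; an additive +2 (default) shift on the slow-block traits of CS
taxa; climate covariates with habitat-linked means (wMAT 4/10/13 °C,
wMAP 450/900/250 mm for CS/HF/WA) plus BM noise. These values are round
defaults, not estimates.

Tree shape: each clade subtree is a Yule realization whose terminal
branches are stretched by a fixed half of the crown depth before rescaling
(`tip_stretch = 0.5`), keeping the subtree ultrametric. This mirrors
consensus trees made ultrametric by terminal extension and avoids a
pathology of raw Yule realizations, whose near-zero terminal branches give
a no-signal (λ = 0) trait enormous apparent evolutionary variance under
C⁻¹ weighting — an 34-taxon raw Yule tree inflates it ~30-fold, letting AR
alone dominate the phylogenetic PCA, whereas empirical rate tables in this
kind of study show the no-signal trait within a factor ~2 of the others.
The clade backbone is fixed ((I,(II,III)), stems at 0.4/0.2 of depth);
λ-damped traits are drawn from the exact matrix-normal construction
X = L_C Z₁ L_Rᵀ·diag(√λ) + D^{1/2} Z₂ L_Rᵀ·diag(√(1−λ)), which reproduces
the per-trait λ transform exactly; clade-specific rate matrices (used by
the modularity scenario) switch to branchwise increment simulation and
require λ = 1.

The clade-modularity scenario (`modularity_scenario_config`) gives Clade I
a fully integrated covariance (all correlations 0.6) and Clades II/III a
leaf/life-form-modular one (within 0.9, between 0), plus a strong (3 SD)
CS shift; under these conditions the modular clades receive lower CR
p-values than the integrated clade and the CS-vs-rest PGLS contrast on PC1
is negative and significant in ≈ 75% of fixtures jointly.

What passing tests show — and don't. The generator is Gaussian,
homoscedastic in time, and additive in habitat effects; real trait data add
measurement error, intraspecific variation, non-BM processes (selection
regimes, bounded traits), and tree uncertainty, none of which are modeled.
Calibrations established here (F-test sizes, λ recovery, CR power) are
statements about this generative family at these sample sizes, not about
any particular empirical dataset.

## Numerical choices and degenerate inputs

- Natural log throughout; the base cancels in z-scoring anyway.
- Newick serialization keeps 12 significant digits; round-trips are tested
  to topology and branch-length identity.
- Cholesky factorizations everywhere a covariance is inverted; singular
  matrices raise named errors rather than being regularized silently.
- Zero-length sibling branch pairs make contrasts undefined and raise;
  polytomies instruct the caller to resolve them first.
- All randomness flows through seeded `numpy` generators (plus a seeded
  `random.Random` for polytomy resolution order); pipeline tables are
  written with fixed float formatting, so identical seeds give
  byte-identical outputs.
- Problem sizes in the test suite (e.g. 200–1000 replicates for
  calibrations, 30 trees for enumeration oracles, 4–6 tips for exhaustive
  sums) were chosen to estimate each property to comfortably better than
  the asserted tolerance.

## Known limitations

- No OU or early-burst alternatives; λ is the only signal model.
- No measurement-error-aware estimation; species values are taken as known.
- ARD Mk fitting is not exposed; polymorphic tips must be resolved
  upstream.
- The compact-letter display uses uncorrected pairwise tests, as in the
  classical rate-comparison procedure; a multiplicity-corrected variant
  would need only a different α.
- `scale_paths` ultrametricization can fail (negative implied branch) on
  pathological inputs; it raises rather than clamping.
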