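# Methods

## The feedforward-loop model

The GAT1–DAL80–MEP2 incoherent type-1 feedforward loop is modelled as a
linear ODE system with constant input: GAT1 is held fixed (dGAT1/dt = 0),
DAL80 is produced at rate A·X·GAT1 and MEP2 at rate A·GAT1 − R·DAL80, and
both decay at a common first-order rate c.  The model's assumptions are
deliberately minimal: promoter activities are linear in regulator level (no
Hill saturation, no cooperativity), repression is subtractive, and all
species share one degradation constant.  These choices keep the steady
state closed-form,

    DAL80* = A·X·GAT1/c,    MEP2* = A·GAT1·(1 − R·X/c)/c,

and make the central claim transparent: MEP2* relative to an ancestral
(A₀, X₀) depends on A and the composite R·X/c only, so the qualitative
phase diagram is invariant to the particular values of R and c.

Parameters and defaults: A ∈ [0, 2] and X ∈ [0, 1] are swept on a 101×101
grid by default; R = 2, c = 1 and GAT1 = 1 are the reference
parameterization used throughout, with the ancestral state at (A, X) =
(1, 0.4) — chosen so that direct MEP2 activation (A) exceeds DAL80
activation (A·X), the regime in which affinity-reducing mutations can be
adaptive; all are configurable.  A and R carry arbitrary rate units, X is
dimensionless, c is 1/time.

Two consequences of linearity are treated as features, not bugs:

- **Negative MEP2\*** arises for X > c/R.  Values are reported as computed
  and sweeps carry a `has_negative` flag; clamping would silently distort
  the relative-expression surface.
- **X semantics**: X multiplies the *DAL80* production rate (DAL80
  activation = A·X); all sweep and ratio semantics follow the equations.

Numerics: integration uses `scipy.integrate.solve_ivp` (LSODA,
rtol = atol = 1e−9) to a default horizon of 100/c — far beyond the slowest
relaxation time 1/c — and the final state is declared a numeric steady
state when the maximum absolute time derivative is ≤ 1e−8.  These
tolerances are implementation choices.  A sweep whose reference state has
MEP2* = 0 exactly returns the absolute surface with a degenerate-reference
flag instead of dividing.

## EMSA dose–response fitting

Fraction bound is bound/(bound + unbound) band intensity.  The titration
is fit to `Fr = Frmax·x/(x + Kx)` by unweighted nonlinear least squares
(`scipy.optimize.curve_fit`); the zero-dose point stays in the fit since
the model passes through the origin.  Starting values are deterministic —
Frmax₀ = max observed fraction, Kx₀ = the positive dose whose fraction is
nearest Frmax₀/2 — so fits are reproducible without random restarts.
Standard errors come from the residual-variance-scaled covariance at the
optimum; per-parameter significance is a two-sided t-test (n − 2 df), the
standard per-coefficient report for dose–response fits, evaluated against
a 0.02 threshold by the `significant()` helper.  Fractions outside [0, 1]
(gel noise) are flagged on both input and result, never dropped: least
squares is defined regardless and dropping would bias Frmax.

Recovery behaviour at the six-dose design (0, 1, 5, 10, 15, 20 μg) with
Frmax = 0.8, Kx = 5, noise sd 0.02: the asymptotic standard error of Kx is
0.77 μg, so the median |relative error| of Kx is ≈ 10.4% — Kx is
intrinsically about three times harder to pin down than Frmax (≈ 3.3%)
because only the two lowest doses constrain the curve's rise.  Nominal 95%
Wald intervals cover the truth ≈ 95% of the time for both parameters.

## PWM from top-scoring k-mers

The top `n` k-mers by score (default 10; ties broken lexicographically for
determinism) are aligned ungapped at offset zero against the top-scoring
k-mer, each optionally flipped to its reverse complement when that
orientation matches the anchor at more positions, and per-position base
frequencies tallied.  Gapped or offset alignment and prior collapsing of
reverse complements are intentionally out of scope; the anchor-identity
orientation rule is this package's choice where no standard exists.

## Per-codon dN/dS

Potential sites per sense codon: each of the nine single-nucleotide
neighbours is classified synonymous/nonsynonymous under the standard
nuclear code; S = synonymous count / 3 and N = 3 − S, with stop-producing
changes counted as nonsynonymous so S + N = 3 holds exactly.  Observed
substitutions between two codons differing at k positions average the
synonymous/nonsynonymous step counts over the k! single-step pathway
orderings, skipping pathways through stop codons and re-weighting the rest
equally (a fallback counts stop-crossing steps as nonsynonymous in the
k = 3 corner where every ordering could be blocked).  Per amino-acid
position, counts are **pooled** over all unordered sequence pairs —
dN = ΣNd/ΣN, dS = ΣSd/ΣS — rather than averaging per-pair proportions; the
two conventions differ when potential-site counts vary between pairs, and
pooling is the stabler choice at low divergence.  No multiple-hit
(Jukes–Cantor) correction is applied: dN and dS are raw proportions and can
exceed 1 (a single observed synonymous difference at a codon with S = 1/3
gives dS = 3).  Positions with zero potential sites of a class are NaN,
not zero; pairs containing gaps, ambiguity codes or stop codons are
skipped per position with counts reported.

One subtlety: pathway averaging assigns fractional nonsynonymous counts
even between synonymous variants of six-fold codon families (AGA vs CGC,
both one synonymous step from CGA, average Nd = 1 across the two
orderings), so a region with zero nonsynonymous *mutations* still shows a
small positive dN.  Purifying selection is therefore read as strong
suppression relative to the background, not as exact zero.

## Fitness, permutation test, reporter normalization

**Fitness.** The selection coefficient s is the OLS slope of
ln(query/reference) against elapsed generations; the 95% CI uses the slope
standard error and a t-quantile (n − 2 df).  Following the reporting
convention for sparse assays, the CI is suppressed when fewer than five
time points were sampled, although the numbers remain on the estimate for
diagnostics.  Counts and frequencies give identical estimates (the ratio
is all that enters); zero counts raise an error naming the offending time
point.

**Permutation correlation.** The focal-set correlation (Spearman by
default, matching the headline use; Pearson available — the discrepancy
between the two conventions in the source analyses is surfaced, not
resolved) is compared against `n_perm` (default 10,000) random gene sets
of the focal size drawn without replacement from all genes, focal genes
included (exclusion is an option).  p = (1 + #{null ≥ observed}) /
(n_perm + 1): add-one smoothing never returns 0, and the test is one-sided
toward positive association by default since that is the hypothesis;
"less" and "two-sided" are options.  The null is computed by a vectorized
rank-then-Pearson path independent of the scipy call that produces the
observed statistic.

**Reporter normalization.** log10(GFP/FSC-A) per event; non-positive GFP
events are dropped with a reported count, non-positive FSC-A is an error.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed) built on
`numpy.random.default_rng`; defaults are the study conditions the
estimators were designed around.

- `gen_emsa_data`: the six-dose titration with iid Gaussian noise
  (sd 0.02 default) on the model curve.  Real gels have
  heteroscedastic, correlated lane noise and saturation; none is modelled.
- `gen_codon_alignment`: 42 descendants of a random 510-codon sense
  ancestor (the scale of the GAT1 ORF), each codon independently mutated
  at most once per lineage — synonymous with probability 0.05,
  nonsynonymous 0.05 outside / 0.0 inside the constrained window (codons
  309–348, 0-based, the DNA-binding-domain span).  Single-hit-per-codon
  keeps the ground truth analytically transparent; real isolates share
  phylogenetic structure and mutation-spectrum biases that are not
  modelled, so passing tests demonstrate estimator correctness, not
  robustness to phylogeny.
- `gen_gene_table`: 6000 genes with a 41-gene focal set; focal (affinity,
  lfc) pairs are bivariate normal with correlation `true_corr` (default
  0.31), background genes use the identical marginals with zero
  correlation, making focal and background exchangeable under the null —
  the property the calibration tests rely on.  Real affinity scores and
  fold changes are not normal; normality is a simulation convenience.
- `gen_competition`: query frequency r/(1 + r) with
  r = init_ratio·e^{s·t} (defaults 1:9 mix, s = 0.1, six time points over
  15 generations), binomially sampled at depth 10,000 per time point;
  `depth=None` returns exact frequencies so the regression inverts the
  generator exactly.  Shared-environment effects and frequency-dependent
  selection are out of scope.
- `gen_ffl_timecourse`: deterministic integration plus iid observation
  noise — noise never enters the dynamics.

## Problem sizes used in the self-checks

The recovery experiments use 200 replicate EMSA fits, 500 binomial
competition replicates, 500 null + 200 alternative permutation runs at
n_perm = 1000, and a 20×20 steady-state grid; together they run in about a
minute, which makes the full check cheap enough to run on every change.

## Known limitations

- The loop model is linear; saturating promoters, autoregulation of GAT1
  (observed in the motivating system) and stochastic kinetics are not
  modelled.
- dN/dS is pairwise-pooled and phylogeny-free by design; it is a scan
  statistic, not a substitute for codon-model inference.
- The Michaelis–Menten fit reports asymptotic (Wald) uncertainty; profile
  or bootstrap intervals are not implemented.
- No FCS or gel-image parsing: inputs are numeric tables produced by
  upstream instrument software.
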