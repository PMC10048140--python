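# Methods

This note documents the model, the numerical choices and the
assumptions behind `edrw`, and what the synthetic test-bed does and does
not demonstrate.

## Model and procedure

The pipeline treats a pathway not as a flat gene set but as a directed
graph whose topology redistributes evidence between genes.  Three
ingredients are combined:

**Gene scoring (PCT).**  For gene gᵢ with expression row x and 0/1
phenotype y (0 = normal, 1 = tumor):

- t(gᵢ): equal-variance two-sample t statistic,
  (x̄₁ − x̄₂)/(S_p·√(1/N₁ + 1/N₂)), with the classic pooled standard
  deviation over N₁ + N₂ − 2 degrees of freedom; p-values are
  two-tailed.
- ρ_pb(gᵢ): point-biserial correlation, computed as the Pearson
  correlation between x and y.  With the population standard deviation
  this is algebraically identical to (M₁ − M₂)/S·√(p·q) up to sign, and
  satisfies ρ² = t²/(t² + n − 2) exactly — an identity the test suite
  asserts to 1e-10 as a cross-check that both statistics are computed
  consistently.  We report the Pearson sign convention (positive =
  higher in tumor); only |ρ| and ρ² are consumed downstream.
- PCT score: Z(gᵢ) = t² + |ρ_pb| ≥ 0, monotone in both ingredients.

**Initial weights.**  W₀ = |Z − max Z|/(max Z − min Z) ∈ [0, 1].  Note
this orientation gives the *largest* PCT score weight 0; it is the
default (`w0_orientation="literal"`), with `"complement"`
((Z − min)/(max − min)) available.  Because the walk only uses W₀ as a
start distribution and pathway ranking is scale-free in H∞, planted
pathways are recovered under either orientation; the default passes the
end-to-end recovery checks and is kept as the literal form.

**Entropy weighting.**  The entropy of gene g over m samples is computed
on the cleaned, pre-z-score matrix (z-scored rows have zero mean and
negative entries, which a distribution cannot have): the row is shifted
by its minimum plus ε = 1e-12, normalised to pₖ, and scored as
E(g) = −Σ pₖ ln pₖ / ln m ∈ [0, 1].  The entropy-weight-method criterion
ew = (1 − E)/Σ(1 − E), with the sum over the genes shared by the
network and the expression matrix, favours genes whose expression
concentrates in few samples.  If every E equals 1 the weights are
degenerate and an error instructs the caller to fall back to uniform
weights.

**Transition matrix.**  Each node u distributes its outgoing probability
over out-neighbours v proportionally to ew(v).  Rows therefore stay
stochastic, probability is conserved at every walk iteration, and with
equal weights the matrix reduces exactly to the conventional
out-degree-normalised DRW transition (asserted against a naive dense
reference).  Degenerate rows: a node whose out-neighbours all have zero
weight falls back to a uniform row (logged); a dangling node keeps its
mass via a unit self-loop.  Genes present in a network but absent from
the expression matrix get weight 0 and never attract transition mass
except through these fallbacks.

**Walk.**  H_{t+1} = (1 − r)·TᵀH_t + r·H₀, with H₀ = W₀ restricted to
the network's nodes and renormalised.  Convergence: L1 change < 1e-10,
at most 1000 iterations (the spectral contraction factor is 1 − r, so
even r = 0.1 converges far below the cap).  The walk is run on the two
networks *independently* — no merged network, no cross-network coupling;
this is deliberate, as the two databases' profiles are concatenated only
at the activity stage.  Default restart r = 0.5; the pipeline config can
sweep `restart_scan: "0.1:0.9:0.1"` against all three classifiers.

**Pathway activity.**  For pathway Pⱼ, the used genes are the members
with raw t-test p < 0.05 (no multiplicity correction — the filter is a
per-pathway gene screen, not an inference) that appear in the source
network and the expression matrix.  Then

    a_k(Pⱼ) = Σᵢ H∞(gᵢ)·PCT(gᵢ)·z_k(gᵢ) / sqrt(Σᵢ ew(gᵢ)²),

with both sums over the used genes.  The denominator is the L2 norm of
the entropy weights, *not* of H∞, so activities are exactly linear in
the walk vector (scale equivariance is property-tested).  No sign term
appears by default; `sign_adjust=True` multiplies z by sign(t), which
helps coherently deregulated pathways accumulate rather than cancel and
is the setting under which the formula reduces to the conventional
DRW-style activity when entropy weights are forced equal.  Pathways
with no usable genes are dropped (logged).

**Ranking and classification.**  Per-network profiles are concatenated
with source-prefixed ids; the top 50 pathways by |t| of their activity
vector on *training samples only* are the candidate features (ties
break lexicographically).  Greedy forward selection walks the ranked
list: the first pathway always initialises the set; a candidate is kept
only if the mean AUC over stratified 10-fold CV (folds seeded, identical
across candidates so comparisons are paired) *strictly* increases —
ties reject, preventing feature bloat.  Base classifiers: Gaussian
naive Bayes, k-nearest-neighbours with k = 5 (scored by the neighbour
class-1 fraction), and L2-regularised logistic regression (the small
ridge keeps separable data finite); hyperparameters are deliberately
plain and configurable.

**Protocol.**  Per repeat: stratified 60/20/20 split (per class,
n_train = round(0.6n), n_val = round(0.2n), remainder test), the whole
scoring → entropy → walk → activity → ranking → selection chain refit on
the training samples, final AUC on the test split.  The validation
split is held out and unused by default (nothing in the protocol
consumes it; it is reserved for optional restart-probability tuning).
Ten repeats with seeds derived via `numpy.random.SeedSequence` give the
mean/sd AUC and pathway selection frequencies.  Each repeat re-splits
the cohort entirely (rather than merely re-folding the CV), the
stricter of the two plausible repetition schemes.

## Leakage

Inside the estimators, the per-gene standardisation moments are learned
from training samples only and applied to new samples, so no test
information can reach gene scoring, the walk, the ranking or the
selection; the test suite includes a leakage audit (replacing held-out
rows by noise leaves the learned features identical).  The standalone
`edrw preprocess` command, by contrast, standardises the whole file at
once — the conventional usage when preparing a matrix for inspection.
Similarly, `edrw classify` operates on a precomputed activity matrix
(ranking and selection still training-only per repeat) as a lighter
protocol; the full per-repeat refit is what `edrw run` and
`run_repeated_experiment` execute.

## Synthetic test-bed

The generator emulates the two-database setting: a gene pool (default
1000 genes) split into two per-network pools overlapping by ~30%;
per network, 50 pathways of 10–40 genes drawn uniformly from the pool;
within-pathway directed Erdős–Rényi edges at p = 0.3 and sparse
background edges at 5e-4; expression i.i.d. N(0, 1) with genes of three
planted first-network pathways shifted by +1.5 SD in tumor samples
(full direction coherence by default); optional uniform missingness;
a 60 normal + 60 tumor cohort.  These defaults are the standard study
conditions used by the end-to-end tests and `scripts/acceptance.py`;
under them the planted pathways are recovered in the top-10 ranking in
10/10 repeats and the mean test AUC is 1.0, while label permutation
collapses the mean AUC to ~0.5.

What this does *not* show: the generator has no probe-level artifacts,
no correlated background expression, no realistic degree distribution
or pathway overlap structure, and its planted effects are homogeneous.
Passing the recovery checks demonstrates the machinery is correct and
leak-free, not that the method attains any particular AUC on real
cohorts.

## Numerical choices and degenerate inputs

- One SD convention package-wide: the sample (n − 1) denominator, so
  z-scores, t statistics and correlations stay mutually consistent
  (Pearson correlations are denominator-invariant).
- Zero-variance genes are dropped at normalisation (they carry no class
  signal and make the z-score undefined); all-missing genes are dropped
  at imputation.  Both are logged.
- The scalar t-test raises on zero pooled variance with unequal means;
  the matrix-level `gene_stats` adds ε = 1e-12 to the pooled SD so a
  pathological row scores extremely rather than aborting a cohort, and
  defines t = 0, p = 1 when both class means and variances coincide.
- Entropy shift ε = 1e-12 keeps the log defined for the row minimum.
- `log2` preprocessing (optional flag) maps non-positive intensities to
  missing before imputation; the order log2 → impute → z-normalise is a
  package choice.
- Duplicate expression rows collapse by arithmetic mean
  (order-independent); gene identifiers match by exact string equality —
  ID mapping between platforms is out of scope.
- Reports and manifests contain no timestamps; reruns with the same
  config and seed are byte-identical.  All derived seeds stay below
  2³¹.

## Problem sizes

The default test-bed (1000 genes, 2 × 50 pathways, 120 samples,
10 repeats) runs the full repeated experiment in well under a minute on
one CPU; `scripts/acceptance.py` (planted plus null experiment) takes
about a minute.  These sizes were chosen so the sampling behaviour of
the statistics is in its asymptotic regime (per-gene |t| ≈ δ·√(n₁n₂/n)
for planted genes) while the whole suite stays fast enough to run
routinely.
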