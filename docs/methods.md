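# Methods

This note documents the models and procedures implemented in `cyclegrn`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## GRN comparison

A GRN is a set of directed (TF, target) pairs over opaque, case-sensitive
gene identifiers; one edge-list line is one pair, duplicates are dropped
(and counted), and self-loops are retained. The comparison statistics are:

- **Overlap coefficient** |A∩B| / min(|A|, |B|) over interaction sets.
- **Randomization null**: for each of `n_perm` (default 1000)
  permutations, every TF in each network draws a uniform random target set
  of its true out-degree, without replacement, from the pooled target
  universe of all loaded networks. This preserves per-TF degree but
  destroys TF-target association. The observed overlap is placed on the
  resulting null by a two-tailed z-test under a normal approximation; with
  only ~10³ draws a permutation p-value would be floor-limited at 10⁻³, so
  the z-based p is reported instead. A degenerate null (sd = 0) sets an
  explicit undefined flag rather than dividing by zero.
- **Per-TF degree correlation**: Pearson r over TFs present in *both*
  networks (default). The union-with-zero-filling alternative inflates |r|
  by rewarding joint absence and is available as `mode="union"`.
- **Uniqueness**: over the multiset union of several networks, the
  fraction of interactions present in exactly one dataset, plus the
  per-TF flag for whether a majority (>50%) of its pooled interactions are
  dataset-unique.

## Feed-forward loops

An FFL is the ordered triplet (p, s, t) with edges p→s, p→t and s→t,
p ≠ s, t ∉ {p, s}. Targets that are themselves TFs may serve as FFL
targets; self-loops never contribute; mutually regulating TF pairs that
share a target yield both role-ordered triplets (the feedback-loop case is
deliberately represented as two FFLs). Enumeration walks each primary TF's
regulated-TF list and intersects target sets, and is property-tested
against an exhaustive triple loop on random graphs.

The expected count in a randomly wired network of the same mean
connectivity λ = |interactions| / |nodes| is λ³, with standard deviation
√λ³ (Poisson-like), giving z = (N_obs − λ³)/√λ³. This is an
order-of-magnitude null: real regulatory networks exceed it by orders of
magnitude, and the z-score is reported for that qualitative contrast, not
as a calibrated test.

## Balanced-ensemble linear SVM

Features are binary: one column per (dataset, TF) pair for TF-target
features — 1 iff the TF targets the gene — and one column per
(dataset, primary→secondary) pair for FFL features — 1 iff the gene is
that FFL's target. Dataset tags keep identically named features from
different sources distinct when matrices are concatenated. Genes with no
feature are excluded (they are unclassifiable by construction).

Because most of the genome is non-cyclic, each model is an ensemble over
`n_balanced_sets` (default 100) training subsets containing all positives
plus round(R × n_pos) negatives drawn uniformly without replacement. R
generalizes the 1:1 balanced construction and is tuned as a hyperparameter
over R ∈ (0.25, 0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4) alongside the SVM cost
C ∈ (0.01, 0.1, 0.5, 1, 1.5, 2.0). R values requiring more negatives than
exist are skipped with a warning. The classifier is the standard
soft-margin linear SVM (hinge loss, L2 penalty), solved exactly so that
feature weights are recoverable; scores are raw decision values w·x + b
(AUC is rank-based, so calibration is irrelevant).

Scoring contract: within a training subset, genes are scored out-of-fold
under stratified `n_folds` (default 10) cross-validation; genes outside
the subset are scored by the model trained on the whole subset. Per-gene
scores are averaged across the ensemble, and a single AUC-ROC against all
featured genes evaluates each (C, R). The grid maximum defines the
representative model; ties break toward smaller C, then smaller R (the
more regular model). Reported feature weights are the mean over the
ensemble's full-subset models at the best (C, R); a single refit on all
data is a reasonable alternative but averaging is the default because it
matches how the scores themselves are produced. AUC uses the Mann-Whitney
formulation with half-credit for ties.

The class × dataset effect on AUC is assessed by a two-way fixed-effects
ANOVA with interaction (type-I sums of squares; the intended designs are
balanced, where type I/II/III coincide for the main effects reported).

## Feature importance and networks

Weights are ranked 1 (largest positive, most associated with the positive
class) to n (largest negative). Percentile subsets are conservative under
ties: the cutoff for the top Xth percentile is the smallest weight
strictly above which lie ≤ X% of *all* features, so a tie straddling the
boundary shrinks the subset (possibly to empty) rather than exceeding the
budget; the negative side is the exact mirror. The denominator is all
features of the model, not per-sign counts.

Importance networks take the general (cyclic) model's top-decile features:
TF→TF pair features become directed edges, single-TF features become
nodes, and each element is annotated with the phases in whose model it is
also top-decile (positive side only — annotation marks what a feature is
important *for*). Modules are the connected components of the undirected
projection; components are the minimal formalization of visually clustered
sub-networks. Known-regulator enrichment is a one-sided Fisher test with
the model's own feature-TF set as the universe — the least-assuming choice
when no external TF census is imposed.

## FFL expression dynamics

The FFL ODE model treats the primary TF's expression f(t) as an exogenous
driver of a linear two-gene cascade:

    dS/dt = α_S·S + β_PS·f(t)
    dT/dt = β_ST·S + α_T·T + β_PT·f(t)

with decay rates α (1/min) and production rates β. f(t) is represented by
default as a 4-parameter sinusoid (amplitude, period, phase, offset)
least-squares-fitted to the primary trace before the ODE fit — a sinusoid
matches the cyclic context and keeps the solution closed-form — with
piecewise-linear interpolation of the raw trace available
(`forcing_mode="trace"`). For constant or sinusoidal forcing the solution
is exact: the forcing is embedded in an augmented 5-state autonomous
linear system (S, T, sin, cos, 1) and propagated by matrix exponentials,
which handles degenerate rates (α = 0, α_S = α_T) without special cases;
uniform time grids reuse a single propagator. Arbitrary forcing falls back
to adaptive LSODA integration; the two paths agree to < 10⁻⁶.

Fitting is Gaussian maximum likelihood with i.i.d. residuals and a shared
sd across S and T — equivalent to joint least squares — run as
Levenberg-Marquardt from one fixed initialization
(α_S = α_T = −0.05, β = 0.05), unbounded so that the sign filter stays
meaningful. Initial conditions S0, T0 are the first observed points. A fit
is **accepted** when the optimizer converged, moved off the initialization
(> 10⁻⁶ relative on at least one parameter), and the signs are
biologically reasonable (α < 0, all β > 0). `validate_ffl_set` reports the
accepted fraction over a set of triplets and supports a control mode of
uniform random TF-TF-gene triplets; on synthetic data, true FFL triplets
are accepted far more often than random or white-noise triplets, the
qualitative contrast the filter is designed for. Whether S and T should be
fitted jointly or sequentially is an open choice; joint fitting is the
default because the likelihood is then a single coherent objective.

## Enrichment

Fisher's exact test, one-sided (greater) by default — the question asked
is over-representation, and depleted or saturated tables legitimately
return p = 1 — with Benjamini-Hochberg step-up correction across all
tested terms. Annotations are flat 2-column gene→term pairs; no
ontology-graph propagation is performed. Degenerate margins (e.g. the
query set equals the universe) carry no enrichment signal and return
p = 1 by convention at the enrichment level, while the bare `fisher_exact`
operation raises on zero margins.

## Synthetic data generator

The generator emulates the statistical regime the analyses assume, at desk
scale:

- **Degrees**: per-TF out-degrees are geometric with configurable mean
  (default 20) — the simplest one-parameter heavy-tailed choice; real
  degree distributions are unknown and the default is a pragmatic stand-in,
  not a claim about real networks. Degrees are drawn once and shared
  across datasets.
- **Cross-dataset overlap**: each TF has a shared "core" target pool used
  by every dataset plus dataset-specific uniform draws. With degree d,
  core c = x·d and pool P, the expected pairwise overlap per TF is
  c + (d−c)²/(P−c); the shared fraction x is solved globally (Brent's
  method) so the expected realized overlap coefficient equals the
  configured target (default 0.1, the regime of weakly agreeing assays).
  Randomized rounding of core sizes keeps the calibration unbiased; a
  target below the chance overlap implied by the degrees is rejected as
  unattainable. Monte-Carlo tests confirm the realized mean matches the
  target to within Monte-Carlo error.
- **Phase structure**: five phase classes sized by configuration (default
  80 of 600 genes cyclic, G1 largest — cyclic genes are a small minority,
  as in real genomes). Expression is a cosine over two periods
  (default period 125 min, 50 timepoints) peaking at the phase's offset —
  consecutive phases offset by period/5 — plus Gaussian noise (default
  sd 0.05), then min-max normalized to [0, 1]; non-cyclic genes are noise
  about a constant.
- **Planted signal**: phase-linked TFs (default 10, rotating through the
  phases) gain an edge to each in-phase gene with probability
  `tf_phase_effect` on top of background, recorded as ground truth — this
  is what makes classifier performance interpretable. Planted FFLs are
  added to every dataset with accepted-sign ODE parameters recorded.
- **Determinism**: one root seed; every stage derives a stable sub-seed
  from the stage name (multiplicative hash + CRC32, reduced mod 2³¹), so
  reruns are byte-identical and stages are independently reproducible.

What the generator does **not** emulate: promoter sequence, binding-site
locations, correlated errors between assay types, TF autoregulation
structure, expression amplitude differences, or realistic genome scale.
Because degrees are drawn once and shared across datasets (which makes the
overlap calibration exact), synthetic datasets have near-perfectly
correlated per-TF degrees — the opposite of real assays, whose per-TF
interaction counts are essentially uncorrelated; the degree-correlation
statistic on synthetic collections therefore characterizes the generator,
not real data.
Passing tests on synthetic data therefore demonstrate that the
implementation recovers structure *of the kind assumed*, under clean
conditions; they do not certify performance on real regulatory data,
whose disagreement structure is richer than the shared-core model.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced-scale versions of each
analysis, chosen to exercise the full protocol while keeping the suite
fast: ensembles of 20 balanced sets (instead of 100) over the full
6 × 9 (C, R) grid on ~700-gene universes for the classifier checks, 10³
permutations for nulls and tie-rule sweeps, 50-point time courses for ODE
fits, and exhaustive exact-test verification up to table totals of 30.
Key tolerances: closed-form vs numeric ODE agreement 10⁻⁶; superposition
10⁻⁸; ANOVA decomposition 10⁻¹⁰; SVM flip-symmetry 10⁻⁶ (solver tolerance
is set to 10⁻⁶ accordingly); "moved off initialization" 10⁻⁶ relative.

## Known limitations

- The λ³ motif expectation ignores degree heterogeneity; it is a
  deliberate, simple yardstick and overstates enrichment significance for
  heavy-tailed networks.
- The linear SVM cannot express conjunctive rules ("two in-phase TFs
  required"); near-perfect synthetic recovery relies on additive signal.
- The ODE acceptance filter tests parameter plausibility, not causal
  regulation; smooth noise can be fitted with plausible signs, so the
  filter is informative only as a contrast against controls.
- Grid-maximized AUC is optimistically biased under the null (selection
  over ~50 grid points); the permutation check bounds this bias rather
  than eliminating it.
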