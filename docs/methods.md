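# Methods

This note documents the models, conventions and numerical choices behind
`panthoot`, in the spirit of a statistical package's model documentation.

## Data model and filters

A feature table holds one row per call with factor columns
(`call_id`, `site`, `community`, `individual`, `context`), boolean phase
flags, and numeric features typed as `continuous`, `count` or `binary`.
Missing values are a first-class state (`NaN` in memory, empty cell in
CSV), never conflated with 0. For count features, 0 with the phase flag set
means "phase present but empty"; phase absence is count 0 *and* flag
`False`. Phase-requirement filters treat the flag as authoritative, because
a zero count alone is ambiguous between the two states.

When several behavioural contexts co-occur during a recording, the single
kept label is the highest-priority one under travel > feed > display >
rest; the rationale is that travel most constrains call function, and the
ordering matches field practice for these data.

The standard filter cascade is: (1) drop individuals with fewer than 8
calls (trading calls-per-individual against individuals retained); (2) for
context analyses, keep only feed/travel calls from individuals with at
least 3 calls in *each* context; (3) per feature set, drop excluded
columns, rows failing phase requirements, and rows with any missing value
among retained features (complete case). Filters only remove rows/columns,
never edit values, and are idempotent; every stage returns an additive
`FilterReport` (input = retained + dropped).

Which features make up the "structural" set is configuration, not code:
drumming-related features and categorical presence flags are excluded by
the caller's `FeatureSetSpec`, since the exact surviving feature list
depends on missingness in a given dataset.

## Causal adjustment

The packaged DAG encodes: location → {environment, community, genetics};
genetics → {individual, acoustic structure}; environment → acoustic
structure; individual → {acoustic structure, community}; context → acoustic
structure. Context is modelled as a root node with a single edge into
acoustic structure — the graph takes no stance on what drives context, and
none of the analyses require one.

d-separation uses standard chain/fork/collider semantics (a collider is
open iff it or a descendant is conditioned on). Adjustment-set search is
exhaustive enumeration over subsets of the observable nodes (minus the
exposure, outcome and the exposure's descendants), pruned so supersets of a
valid set are never reported. Graphs in this domain have ≤ 10 nodes, so
exhaustive search is exact and fast; no scalable algorithm is needed. "No
backdoor path" yields `{∅}` (adjust for nothing), distinct from the empty
result "no observable set suffices".

## PCA reduction

Acoustic features mix units (s, Hz, counts), so the default is
correlation-matrix (standardized) PCA; covariance-matrix PCA is available
via `standardize=False`. Components carry a deterministic sign (largest
|loading| positive) so permutation runs are bit-reproducible. Constant
columns are dropped with a warning when standardizing.

Component count:

* **cap heuristic** — min(size of the smallest test-factor category,
  smallest k with cumulative explained variance ≥ 0.90). The category cap
  prevents LDA overfitting; the 90 % rule avoids dragging in near-noise
  components when the cap is generous.
* **scree elbow** — Cattell's elbow has no canonical formula; it is
  operationalised here as the index maximizing perpendicular distance to
  the chord joining the first and last scree points, ties toward fewer
  components. A max-second-difference variant is available
  (`method="second_diff"`). Pipelines can run under both heuristics as a
  stability check (`AnalysisPlan.component_heuristics`).

## LDA

Fisher discriminant vectors solve Sb·v = λ·Sw·v with pooled (unbiased)
within-class scatter, scaled to unit pooled within-class score variance
(the convention of the classic R implementation this mirrors), sign-fixed
as in PCA. Classification uses the Gaussian discriminant score with the
pooled covariance and training-frequency priors (balancing upstream makes
priors equal in practice); ties break deterministically to the first class
label. A singular Sw (possible on degenerate permutation resamples)
triggers a ridge of 1e-8·trace(Sw)/d with a warning instead of aborting a
permutation loop. Standardized coefficients are raw vectors scaled by each
variable's pooled within-class SD, so "highest coefficient" comparisons are
units-invariant; raw coefficients are available behind a flag.

## pDFA

Design conventions, where the original procedure leaves room:

* **Balancing quota** — crossed: per-control-level minimum cell count;
  nested: global per-individual minimum; both overridable via
  `n_select_per_cell`.
* **Fresh split per iteration** — a new balanced subsample is drawn for
  every permutation (default), so reported accuracies average over
  selection noise; a fixed-split mode exists
  (`rebalance_each_perm=False`).
* **p-value** — uses ≥ and includes the original dataset in the
  denominator, so p ∈ [1/n_perm, 1]; "expected" accuracy is the arithmetic
  mean over the randomized (non-original) datasets.
* **Unequal unit counts** — nested designs may have unequal individuals
  per test level (6/5/7); unit reassignment preserves the observed
  per-level unit counts.
* **Nested without a control factor** — when the test factor itself is the
  repeated-measures unit (individual identity), rows are the units:
  balancing draws the smallest per-category count from each category and
  permutation shuffles row labels within each restriction level.
* **RNG** — permutation *i* uses the independent substream
  `default_rng([seed, i])`, so results are independent of execution order
  and exactly reproducible from `(data, seed)`.

Significance is declared on the cross-validated accuracy at α = 0.05.
Pairwise community follow-ups are reported without multiplicity
correction, as descriptive follow-ups to the omnibus test (noted in the
report rows).

## repDFA

Crossed mode reuses the pDFA balancing (true labels, no permutation);
nested mode resamples the same number of recordings per individual *with*
replacement. Each refit records the variable with the highest
|standardized coefficient| on DF1 and DF2. With two test levels DF2 does
not exist and its counts are reported as absent (`None`), distinguishing
"absent" from "never top". Within a single dataset the winner is sticky
across refits (the dataset-level chance advantage persists), so symmetry
properties of the counter are only meaningful across independent datasets;
the test suite checks them that way.

## Post-hoc mixed models

Count features: Poisson log-link GLMM with a random intercept per
individual. Estimation maximizes the Laplace-approximated marginal
likelihood (inner Newton for each group's conditional mode; Nelder–Mead
then BFGS over (β, log σ)); a 30-node Gauss–Hermite quadrature evaluation
of the same likelihood is provided (`method="quadrature"`) and agrees with
Laplace to ~3 decimals on realistic data — the suite asserts this. Wald
z-tests on the fixed contrast are the default (LRT-style alternatives were
deliberately left out of scope). The reference level is feed when present,
so β(travel) > 0 means "more in travel". Continuous features use
statsmodels `MixedLM` (REML) behind the same interface. Non-convergence
flags the result rather than raising, so batch loops never abort.

Benjamini–Hochberg adjustment is the step-up rule
adjusted₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j capped at 1, applied per analysis batch
(the set of features tested together).

## Synthetic generator

Gaussian features: x = μ + c_k + a_i + g_ctx + ε with
c_k ~ N(0, σ²_community), a_i ~ N(0, σ²_individual),
ε ~ N(0, σ²_residual). Poisson and Bernoulli features share the linear
predictor on the log/logit scale; for Poisson the residual variation *is*
the Poisson noise. Context is i.i.d. categorical per call (default
feed 0.55 / travel 0.45); per-individual context imbalance is achievable
via explicit per-individual call lists. Individual effects are drawn
independently within communities — kinship correlation between related
males is real in field data but off by default here. Missingness, when
requested, is completely at random; structured missingness (e.g.
unrecorded call openings) is not modelled. Consequently, passing
calibration tests show correct behaviour under exchangeable hierarchical
noise, not robustness to kinship structure or informative missingness.

The default "study-shaped" configuration is 3 communities with 6/5/7 males
and 8–45 calls each; its count features carry context shifts of +0.57
(let-down), +0.34 (build-up) and −0.27 (climax) on the log scale — the
magnitudes a field study of this design reports — and σ_individual = 1,
σ_residual = 1 for the continuous block, chosen so individual identity is
clearly detectable at this sample size while community effects are
controlled explicitly per experiment.

## Pipeline

Per feature set: context pDFA first (crossed, control = individual); if
significant, subsequent community tests stratify by context. Community
pDFAs run nested (control = individual) per configured community subset,
with pairwise follow-ups gated on the omnibus (`pairwise =
never|if_significant|always` — left as an explicit toggle because running
pairwise after a non-significant omnibus is sometimes wanted
descriptively). Individual identity runs nested with community as the
restriction factor. Significant omnibus tests trigger repDFA; a
significant context test additionally triggers Poisson mixed models on the
count features loading highest on the winning principal component, with BH
adjustment. Infeasible analyses (e.g. too few individuals in both
contexts) are recorded as skipped with the reason, never raised.

One master seed spawns per-analysis seeds as
`crc32(f"{seed}:{analysis_name}") & 0x7fffffff`, so adding an analysis
never changes the others, and a report replayed from its recorded seeds
reproduces every p-value exactly.

## Problem sizes in the test and acceptance runs

Calibration uses 200 null datasets × 200 permutations (4 continuous
features, 8–30 calls per male) — the binomial 95 % band around a true 5 %
rate at 200 datasets is roughly [0.02, 0.09]. Power uses 50 datasets per
community-effect level (σ_community ∈ {0, 0.5, 1.5}·σ_residual at 100
permutations). Mixed-model recovery uses 100 replicates of 20 individuals
× 20 calls. These sizes make the whole suite run in a few minutes while
keeping the Monte-Carlo bands tight enough to be informative.

## Known limitations

* Monte-Carlo permutation only; no exact enumeration for tiny designs.
* Wald inference for GLMM fixed effects; no parametric bootstrap.
* The generator does not model call-sequence structure, kinship, or
  audio-level phenomena — feature extraction from recordings is explicitly
  out of scope.
* Importance counts are descriptive; no formal inference is attached to
  them.
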