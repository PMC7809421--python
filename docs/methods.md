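# Methods

## Pipeline overview

`hemilat` analyzes hemispheric lateralization of structural brain networks
in neonatal cohorts. The stages are: (1) connectome construction from
streamline summaries, (2) per-hemisphere graph metrics with a
degree-preserving null model, (3) the asymmetry (lateralization) score,
(4) covariate-adjusted group statistics with FDR correction. A synthetic
cohort generator drives testing and calibration.

## Connectome construction

A streamline summary lists, per fiber, two atlas endpoint labels and the
fractional-anisotropy values of the voxels it traverses. Edge FA follows a
two-stage average: FA is averaged over the voxels of each fiber, then
(unweighted) over the fibers of a region pair, so long fibers carry no
extra weight. Self-loop fibers are dropped (logged). The unweighted view
declares an edge when a pair is joined by at least `min_fibers`
streamlines; the default is 1, the most permissive reading of an
"unweighted matrix", and the threshold is exposed for sensitivity
analysis. All metrics operate on the binary view; the FA-weighted matrix
is carried through the I/O layer for inspection but no claims are attached
to weighted metrics.

Hemispheric networks are the **induced subgraphs** on the left and right
label sets: interhemispheric edges and midline labels are excluded, with
counts logged. The alternative reading — whole-brain metrics restricted to
one side's nodes — is deliberately not the default; with hemispheres as
separate graphs, each hemisphere's measures depend only on its own
topology, which is what a left/right comparison should isolate.

## Graph metrics

On a binary undirected graph G with node set N (hop-count distances
L_ij):

- `Lp = 1/(N(N-1)) Σ_{i≠j} L_ij`. On disconnected graphs Lp is evaluated
  on the largest connected component and the restriction is recorded in a
  component note; this keeps Lp finite without inventing distances.
- `Eglob = 1/(N(N-1)) Σ_{i≠j} 1/L_ij` with 1/∞ = 0, needing no
  restriction.
- `Cp = 1/N Σ_i 2E_i/(k_i(k_i−1))` with E_i the edges among node i's
  neighbors. Nodes with degree < 2 contribute 0 but stay in the 1/N
  average (the literal reading of the formula).
- `Elocal = 1/N Σ_i Eglob(G[neighbors(i)])`, node itself excluded; nodes
  with < 2 neighbors contribute 0.
- Betweenness centrality: Brandes path counting, vectorized
  level-synchronously over all sources, normalized by `(N−1)(N−2)/2` so a
  star center scores exactly 1. This is the scale on which fronto-limbic
  hub values of order 10⁻³–10⁻² arise for 32-node hemispheres.
- `σ = (Cp/C_ran)/(Lp/L_ran)`. References are degree-preserving
  double-edge-swap randomizations (`swap_factor·|E|` attempted swaps,
  default 10; rejected if they would create a self-loop or multi-edge;
  connectivity not enforced, disconnected references contribute their
  largest component's path length). `n_random` defaults to 100. σ > 1
  marks the small-world regime. The reciprocal orientation
  `(Lp/L_ran)/(Cp/C_ran)` — which some reports print although their σ
  values and small-world interpretation only fit the standard form — is
  available as `orientation="printed"`; both orientations share the same
  references, so their product is exactly 1.

Degenerate inputs are signaled, not silently patched: an edgeless graph
has no Lp, and a graph whose references have zero clustering (e.g. a star,
which admits no valid swap) has no σ; both raise a distinct computation
error.

## Asymmetry score

`AS(X) = 100 (X(L) − X(R)) / (X(L) + X(R))`, bounded in [−100, 100],
scale-invariant and antisymmetric under hemisphere swap. Positive =
leftward dominance. (Descriptions that call positive AS "rightward" are
inconsistent with this formula; the package follows the formula.) For Lp,
where larger is worse, a positive AS(Lp) means a *rightward* integration
advantage; no sign flip is applied — interpretation belongs to reporting.
When X is 0 in both hemispheres (possible for betweenness of a peripheral
ROI node) the score is undefined; such records are flagged, dropped
per-outcome in the statistics with a logged count, never imputed. The
score is computed ratio-first and clamped so the ±100 bound survives
floating-point rounding.

## Statistics

Group comparisons of AS values use OLS:
`AS ~ group + sex + age_at_MRI + BPD` (BPD = bronchopulmonary dysplasia).
The effect is the group coefficient, its two-sided t-test the raw p.
Benjamini–Hochberg correction is applied within analysis families that
mirror how the comparisons are grouped in reporting: the five global
measures form one family, the four fronto-limbic betweenness values a
second, and the age-correlation and social-emotional subgroup analyses
each form their own. The subgroup analysis contrasts assessed preterm
infants with Bayley-III social-emotional composite < 85 (one SD below the
norm mean of 100) against the rest, adjusting for gestational age and age
at MRI. Student's t is the pooled-variance version; Mann–Whitney uses
exact enumeration for small untied samples and the tie-corrected normal
approximation otherwise; Fisher's exact test sums hypergeometric point
probabilities ≤ the observed table's. The two-proportion sample-size
computation uses the standard normal-approximation formula with ceiling
and dropout inflation `1/(1 − dropout)`, and reports both pre- and
post-dropout n (for proportions 0.15/0.40 at α = 0.05, power 0.8, dropout
10%: 49/group, 110 total after inflation).

## Synthetic cohorts

The generator emulates the structure of a preterm/term neonatal DTI
study: 64 preterm + 33 term subjects by default; a 64-label atlas with 32
homotopic pairs per hemisphere, four of them flagged as the fronto-limbic
circuit; covariates (gestational age, age at MRI, sex, BPD, Bayley-III
composites with follow-up attrition) drawn from group-specific truncated
normal/Bernoulli distributions parameterized by the cohort
characteristics of such studies. Each hemisphere is a rewired ring
lattice (Watts–Strogatz family): the edge density (default 0.26, i.e. 8
lattice neighbors on 32 nodes) fixes the substrate, each edge rewires with
probability 0.20, and the graph is regenerated until connected. This
substrate was chosen over Erdős–Rényi because it reaches the σ ≈ 1.2
regime that neonatal hemispheric networks occupy. Interhemispheric edges
are sparse Bernoulli (default density 0.05) and exist so the
hemisphere-splitting convention can be stress-tested; FA weights are
truncated-normal (mean 0.25, SD 0.05 — neonatal white matter), fiber
counts zero-truncated Poisson (mean 5).

Asymmetry is planted through topology, never by perturbing metric values:
a `sigma` effect δ rewires the left hemisphere with p − δ/2 and the right
with p + δ/2 (less rewiring → more lattice-like → higher σ, so δ > 0 is a
leftward small-worldness advantage); a `density` effect splits edge
density the same way; a fronto-limbic ROI effect reroutes that fraction
of a hemisphere's edges onto the ROI node, raising its betweenness.
Effects apply to the preterm group; a second effect map targets only the
Bayley-SE < 85 subgroup. All draws descend from one master seed through
`SeedSequence(master, spawn_key=(stream, subject))`, so any subject is
reproducible independently of generation order.

What the generator does **not** emulate: spatial geometry and distance-
dependent connection probabilities, registration or parcellation error,
tractography false positives/negatives (the FA < 0.1 and 45° curvature
stopping rules exist upstream of this package and appear only as the
conceptual source of the streamline summaries), hub architecture beyond
the lattice family, or correlations between covariates and topology
unless planted. Passing calibration on these cohorts therefore
demonstrates that the *pipeline* is statistically sound — type-I control
and power behave as designed when its modeling assumptions hold — not
that real neonatal data meet those assumptions.

## Calibration experiments

Two experiments characterize the full pipeline at the study's sample size
(64 + 33 subjects, 32 nodes per hemisphere, 100 replicate cohorts):

- **Null calibration** — no planted effects; per correction family, the
  fraction of replicates with any FDR-significant outcome must stay below
  α + 2·√(α(1−α)/100) ≈ 0.094 (BH controls the probability of any
  rejection at α under a complete null).
- **Effect recovery** — a leftward σ effect of 1.5 within-group standard
  deviations of AS(σ) must be detected (FDR-significant) in ≥ 80/100
  replicates. The δ realizing "1.5 SD" is found by a pilot: 60 null
  subjects estimate the within-group SD of AS(σ), 60 subjects at a probe
  δ = 0.12 estimate the approximately linear slope dAS/dδ, and the target
  δ is solved from the two (clipped to keep rewiring probabilities in
  [0, 1]).

Within these experiments σ uses 6 random references and swap factor 4
(instead of the public defaults 100 and 10) so that 19,400 subject-
hemisphere σ evaluations complete in minutes on one CPU. The extra Monte-
Carlo noise from the smaller null enters the within-group SD — the very
unit in which the planted effect is expressed — so the power condition
remains self-consistent.

## Numerical and design notes

- All-pairs BFS, the Brandes accumulation, and the triangle counts are
  vectorized; metrics on ≤ 5-node graphs agree with brute-force
  Floyd–Warshall/path-enumeration oracles to machine precision (this is an
  acceptance check).
- A Watts–Strogatz graph at rewire probability 1 is only approximately a
  configuration-model graph: at sparse densities (k = 4 on 32 nodes) its
  clustering exceeds that of its own degree-preserving rewirings by
  ~20%, so σ ≈ 1 under full rewiring holds at the default density (k = 8)
  but not arbitrarily sparse ones. Unbiased σ ≈ 1 checks therefore draw
  the test graph itself by exhaustive double-edge-swap randomization.
- The exact two-sided Fisher p for a 13/44 vs 0/21 table is 0.0155
  (reported as 0.016 at three decimals) under the point-probability
  convention shared by R, SPSS and scipy; published values for such tables
  occasionally differ in the last digit depending on software and
  rounding.
- Atlas tables are validated once and marked in `DataFrame.attrs`;
  mutating a validated table afterwards is unsupported.
- TSV everywhere, `#`-prefixed metadata (config hash, master seed,
  version) on every output; writers and readers round-trip bit-exactly
  for integer matrices and to 6 significant digits for FA.

## Known limitations

- No weighted-graph distances; FA-weighted metrics are out of scope.
- No mixed models, longitudinal structure, or imputation of missing
  Bayley scores; unassessed subjects are simply excluded from outcome
  analyses.
- The null model does not enforce connectedness of references; for very
  sparse graphs Lran is then a largest-component quantity.
- Betweenness normalization and the induced-subgraph hemispheric
  convention are declared choices; alternatives (whole-brain restriction,
  other normalizations) would shift absolute values but are not provided.
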