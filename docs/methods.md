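# Methods

## Network model

A subject's structural connectome is a symmetric N×N matrix of streamline
counts over labeled parcels (default fixture: 90 regions, AAL-90 style),
with a zero diagonal. Edges supported by fewer than `min_streamlines`
(default 3) streamlines are considered absent; the comparison is inclusive
(a count of exactly 3 survives) and thresholding zeroes entries while
retaining surviving counts unchanged, because class strengths are defined on
the raw counts. Degree is always binary — the number of nonzero entries in a
row — never weighted strength.

The group-averaged network keeps an edge iff it is present in at least a
`prevalence` fraction (default 0.60, inclusive) of the group's subjects.
Prevalence 1 reduces to the edge-wise intersection and prevalence 1/n to the
union.

## Rich-club coefficient and normalization

For integer k from the minimum non-isolated degree to the maximum degree,
nodes with degree < k (degrees taken on the full network) are removed and

    Φ(k) = E_sub / (S (S − 1) / 2)

is the edge density among the S survivors; Φ is undefined (NaN sentinel,
never an exception) when S < 2. The default survivor rule keeps nodes with
degree ≥ k; much of the classic literature removes nodes with degree ≤ k,
so a `survivor_rule="gt"` flag provides that variant (the two are related by
a shift of one in k).

Because Φ rises mechanically with k in any degree-heterogeneous network,
Φ is normalized by the mean Φ of `n_random` (default 1000) degree-preserving
random networks built by Maslov–Sneppen pairwise edge swaps: each attempt
picks two edges (a,b), (c,d) and replaces them with (a,d), (c,b) unless a
self-loop or duplicate edge would result. We attempt 10 swaps per edge per
null, which conserves the degree sequence exactly and is the field-standard
null for rich-club normalization. Per-null seeds are spawned from the master
seed by counter, so profiles are reproducible. At each k the null average is
taken over the nulls where Φ(k) is defined; Φ_norm(k) = Φ(k)/⟨Φ_random(k)⟩
is NaN where Φ is undefined, no null defines Φ, or the null mean is zero
(this avoids 0/0 at the degenerate tail).

## Hubs, edge classes, class metrics

Rich-club regions are the top `round(hub_fraction × N)` nodes by degree on
the group-averaged network (round half up: 12% of 90 nodes gives exactly
11). Ties at the cut degree are broken by ascending label order and logged —
the result is deterministic and permutation-invariant up to that tie-break.
Each existing edge is then rich (both endpoints hubs), feeder (one) or local
(none). For one subject, class connectivity strength is the sum of that
subject's edge weights within the class (each undirected edge counted
once) and class density is class strength divided by whole-network strength,
so the three densities sum to 1; a weightless network yields NaN densities.
Subjects are classified with their own group's hub set; Φ is computed on
binarized networks, hubs on the binary group-averaged network, strengths on
subject-level weights.

## Inference

Group contrasts use two-sided label-permutation tests on |mean(a) − mean(b)|
(the statistic is pluggable), with the add-one estimator
p = (1 + #{perm ≥ obs})/(n_perm + 1) so p is never zero and is exactly
calibrated at n_perm chosen so that α(n_perm + 1) is an integer. The
contrast family — 6 pairwise group comparisons × {strength, density} × 3
classes = 36 tests — is corrected together by Benjamini–Hochberg FDR;
family membership is a deliberate choice, configurable in principle by
calling the pieces separately. Nodal-degree contrasts of the common
rich-club regions reuse the same machinery with an offset seed.

Partial correlation regresses x and y on [intercept | covariates] (age, sex
as a 0/1 indicator, education) and correlates the residuals; p comes from
the t distribution with n − 2 − (#covariates) df. Constant covariate columns
are absorbed by the intercept and dropped; genuinely collinear columns raise
an error naming the column; a variable fully explained by the covariates has
partial correlation 0 by definition (guarded against dividing noise by
noise). Correlations are computed within patients (CTQ total + 5 subscales,
HAMD, HAMA) and controls (CTQ scores) separately; both raw and
FDR-adjusted p values are reported because published correlation tables of
this kind are often uncorrected.

Summary-statistics reconstructions use the exact algebraic identities:
SSB = Σ nᵢ(mᵢ − m̄)², SSW = Σ (nᵢ−1)sᵢ² for the one-way F; the pooled-variance
two-sample t; Pearson χ² without continuity correction; and Tukey HSD via
the studentized range distribution (scipy's `studentized_range`) with the
Tukey–Kramer harmonic standard error for unequal group sizes. When the
summaries are exact these equal the raw-data statistics exactly; against
printed (rounded) summaries they agree to ~1%.

## CTQ classification

A subject is maltreatment-exposed (CM) iff any subscale meets or exceeds its
cut-off: emotional abuse ≥ 13, physical abuse ≥ 10, sexual abuse ≥ 8,
emotional neglect ≥ 15, physical neglect ≥ 10; otherwise nCM. Boundaries are
inclusive. Subscales are five items scored 1–5, hence the 5–25 range check.

## Synthetic cohort generator

The generator exists so that every pipeline stage has a ground truth. Its
defaults are the study conditions the pipeline targets: four groups of
84/46/32/90 subjects, 90 nodes, hub fraction 0.12, and the published
per-group score summaries as the phenotype distributions.

**Topology.** All subjects share one planted-core template: hub–hub pairs
connect with probability `base_density + hub_density_boost` (0.08 + 0.82),
hub–nonhub pairs with `base_density + hub_feeder_boost` (0.08 + 0.08), the
rest with `base_density`. Two of these choices deserve comment. First, the
hub-block density must far exceed the configuration-model expectation for
the hub degrees, because degree-preserving nulls concentrate edges among
high-degree nodes; a mild boost produces Φ_norm ≤ 1. Second, the feeder
boost is essential for hub identifiability: a pure two-probability block
model raises hub interconnection but leaves hub *degree* within the
background fluctuation, so the top-degree rule cannot recover the planted
hubs. With the defaults, planted-hub recovery is ≥ 10 of 11 and top-quartile
Φ_norm lies in roughly [1.4, 1.9] across seeds. Per subject, template edges
are kept with probability 0.9 and spurious edges appear with probability
0.02, so a 60%-prevalence group average recovers the template essentially
exactly.

**Weights.** Streamline counts are overdispersed nonnegative integers, drawn
as `weight_floor + Poisson(gamma intensity)` (gamma–Poisson ≈ negative
binomial; mean 25, shape 3, floor 3). The floor at the edge-existence
threshold means generated matrices survive default thresholding unchanged.

**Effects.** Group effects multiply the Poisson intensity of class-specific
edges of the shared template: rich ×0.7 in MDD-CM, feeder ×0.9 in MDD-nCM,
feeder ×0.8 in HC-CM, all ×1 in HC-nCM — the observed effect directions
(rich-club loss in maltreated patients, with the complementary feeder
density rise; feeder loss in maltreated controls) at magnitudes chosen once
by pilot power runs to give ≥ 90% detection at the study's group sizes. The
CTQ–feeder coupling multiplies feeder intensities by exp(c · z), with z the
CTQ total standardized within diagnosis and c = +0.15 in patients, −0.15 in
controls, producing the opposite-sign partial correlations. These magnitudes
are free parameters of the generator, not estimates of any real effect; the
synthetic correlations (|r| ≈ 0.9) are far stronger than plausible clinical
ones, which makes sign recovery a construction check rather than a power
claim.

**Phenotypes.** CTQ subscales are truncated rounded normals at the per-group
published means/SDs, clipped to 5–25, rejection-sampled until the cut-off
rule yields the requested CM/nCM label, so group sizes are hit exactly. Age,
education, sex proportions, and HAMD/HAMA (patients only) follow the
published summaries. Everything derives from one master seed via spawned
seed sequences; the same seed reproduces the cohort byte for byte.

**What the generator does not emulate:** spatial geometry and distance-
dependent connectivity, hemispheric symmetry, realistic degree
distributions beyond the planted core, measurement artifacts of
tractography (gyral bias, false continuations), or realistic effect sizes.
Passing recovery tests therefore demonstrates that the pipeline detects what
it is pointed at — not that the published effects would replicate.

## Problem sizes in the shipped tests and acceptance script

The test suite uses reduced problem sizes chosen to exercise every code
path while keeping the suite quick: oracle equivalence on ≤ 30-node graphs,
null ensembles of 100–200 networks, 10 full-size recovery replicates at 500
permutations, a 1000-replicate type-I calibration at 199 permutations, and
one shared 44-subject, 60-node cohort for pipeline tests. The acceptance
script runs the full 252-subject, 90-node cohort with 200 nulls and 5000
permutations. Production defaults (1000 nulls, 10,000 permutations) remain
the configured defaults of `RunConfig`.

## Known limitations

- The rich-club sweep treats k as integer binary degree; weighted rich-club
  variants are out of scope.
- Tukey HSD from summaries assumes homoscedasticity, as the classic test
  does; no Games–Howell fallback.
- The permutation statistic is exchangeable-mean-difference; heavy-tailed
  metrics may warrant a studentized statistic (pluggable via `statistic=`).
- FDR family membership is fixed to the 36-contrast family in the pipeline;
  other family definitions require composing the library calls directly.
- `edge_class` maps and per-edge dictionaries are fine at N ≈ 100 but were
  not designed for voxel-scale graphs.
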