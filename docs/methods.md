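# Methods

`conngraph` implements a group-level connectome analysis for a three-group
resting-state fMRI + diffusion MRI design: schizophrenia patients with
auditory verbal hallucinations (AVH, n = 35), patients without (nAVH,
n = 41), and healthy controls (HC, n = 50).  Each subject contributes a
90-region (AAL-style) weighted functional network and a weighted structural
network; global topology metrics are normalized against degree-preserving
null ensembles and compared across groups with permutation statistics.
Because no subject-level data are deposited with the original study, the
package ships a synthetic cohort generator that emulates the data structure
with controllable, planted group effects; all tests run against it.

## Functional arm

The pipeline starts at region-averaged BOLD time series (180 volumes,
TR = 2 s) and the six rigid-body motion parameters.  Steps, in fixed order:

1. **Volume discard** — the first k = 10 volumes are dropped (signal
   equilibration); motion and nuisance-signal columns are truncated in
   lockstep.
2. **Framewise displacement** — the Power-style scalar
   FD(t) = Σ|Δd| + r·Σ|Δθ| with rotation radius r = 50 mm and FD(1) = 0.
   The study names FD but no formula; this is the dominant convention.
   Mean FD is reported over volumes 2..T.
3. **Spike detection** — volumes with FD strictly above 0.5 mm.
4. **Nuisance regression** — one joint least-squares fit per ROI against an
   intercept, 6 motion parameters, their 6 backward first differences
   (leading 0), global/white-matter/CSF signals, and one indicator column
   per spike volume (15 + n_spikes regressors).  Whether spike and
   covariate regression were simultaneous or sequential is not documented
   in the protocol this follows; a single joint regression is used.
   Residuals are computed by orthogonal projection (pivoted QR), so they
   are orthogonal to every retained regressor to machine precision;
   exactly collinear columns are pruned with a warning naming them, which
   means the retained design is always full rank and a rank-deficiency
   rejection can only arise from degenerate inputs.
5. **Band-pass** — an ideal rectangular mask on the discrete spectrum
   retaining 0.01–0.08 Hz; the 0 Hz mean is always removed.  The protocol
   states only the band edges, not a filter family; the ideal mask makes
   the passband contract exactly testable (in-band sinusoids are preserved
   bit-near-exactly, out-of-band ones removed entirely).

Edges are Pearson correlations between conditioned ROI series with
two-tailed p-values from the t transform at nominal df = n − 2 (the
filtering-induced loss of effective df is not modelled — the same nominal
convention typical analyses use).  Only positive correlations whose p
survives the threshold scheme are retained, with r as the edge weight.
Three schemes are supported: P < 0.05 Bonferroni over the 4005 unique
pairs (default), P < 0.001 uncorrected, and P < 0.01 Bonferroni.  Their
effective thresholds nest, so edge sets nest per subject.

## Structural arm

Symmetric integer fiber-number (FN) matrices are thresholded at
≥ 3 streamlines; surviving counts become edge weights.  Tractography
itself is out of scope; the generator produces FN matrices directly.

## Global metrics

All metrics are computed on max-normalized weights ŵ = w / max(w) and are
therefore invariant to the overall weight scale.  Shortest paths use edge
length 1/ŵ.

- **Cp** — Onnela geometric-mean weighted clustering,
  C_i = [k_i(k_i−1)]⁻¹ Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}, averaged over all
  90 nodes (isolates and degree-1 nodes contribute 0).  The protocol does
  not name a weighted-clustering variant; this is the default of the
  common network toolboxes and keeps Cp ∈ [0, 1].
- **Lp** — mean shortest-path distance over ordered pairs within the
  largest connected component.  The handling of disconnected graphs is a
  convention, not a documented choice of the protocol.
- **Eg** — mean of 1/d over all ordered pairs among all 90 nodes, with
  1/∞ = 0 for disconnected pairs.
- **Eloc** — mean over nodes of Eg applied to each neighbour-induced
  subgraph.  Each subgraph is re-normalized by its own maximum weight;
  this keeps Eloc ∈ [0, 1] and makes the unweighted triangle evaluate to
  exactly 1.
- Basic properties: density, mean nodal strength (raw weights), size of
  the largest component.

Implementation: distances and components come from
`scipy.sparse.csgraph`; the metric formulas themselves are implemented
here and verified in the test suite against exhaustive brute-force
enumeration (all simple paths, triple-loop triangles) on hundreds of
seeded random graphs with ≤ 7 nodes, to 10⁻¹².

## Null models and normalized indices

Matched random networks preserve node count, edge count and the degree
sequence via repeated double-edge swaps; swaps creating self-loops or
duplicate edges are rejected, and 10 attempted swaps per edge are used
(standard burn-in, configurable).  Weights travel with their edges, so the
edge-weight multiset — and hence the normalizing max weight — is preserved
exactly.  Whether the original analysis reshuffled weights in its null
networks is undocumented; the ride-along choice is this package's
convention.  Normalized indices are γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩,
σ = γ/λ, and analogously normalized Eg and Eloc, with ensembles of 1000
nulls by default (scaled down in tests).

## Group statistics

Each metric is compared across the three groups with a permutation one-way
ANOVA: the observed F statistic is referenced to F values from uniformly
permuted group labels (10000 permutations by default), with the add-one
convention p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm).  Post-hoc pairwise
comparisons permute the absolute difference of group means.  The original
protocol does not describe its permutation statistic or post-hoc method;
F permutation and mean-difference permutation are this package's
documented choices.  Pairwise tests are run per metric at α = 0.05 without
multiplicity correction (the analyses are exploratory by design).
Metric–symptom association in the AVH group uses Spearman rank correlation
(mid-ranks for ties) against the AHRS total score; it is computed on both
raw and normalized metrics.

## Synthetic cohort generator

The generator defines the study conditions; nothing downstream depends on
real data.

**Functional.**  Each subject's ROI × volume matrix is drawn from a
zero-mean multivariate normal whose correlation matrix has three levels:
`rho_within` inside each of 6 modules of 15 regions (per group), a common
`rho_between = 0.08` across modules, and a group-invariant
`rho_homotopic = 0.60` on the 45 left/right homologue pairs (ROI i with
ROI i + 45).  The homotopic level emulates the strong inter-hemispheric
homologue correlations of real resting-state data, and it is load-bearing:
because every metric divides by the maximum edge weight, a purely
two-level (within/between) structure makes the normalizing maximum itself
track rho_within, which cancels the path-length consequences of weakened
within-module coupling — measured across the whole rho grid, the planted
Lp effect is ≈ 0 without the homotopic anchor.  With the anchor pinning
the weight scale, weakening rho_within lengthens normalized within-module
edges and sparsifies modules, so Lp rises and Cp/Eg/Eloc fall, the pattern
the functional arm is meant to exhibit.  Requested structures are checked
for positive definiteness and rejected otherwise.

On top of the correlated signal, each series receives a shared contaminant
(coupling 0.2 of three fabricated smooth AR(1) global/WM/CSF signals), and
an amplitude jump of 4 at high-motion volumes.  Motion traces are smooth
low-amplitude drifts (increments clipped so spike-free FD stays below
0.5 mm) plus persistent 1.5 mm translation steps at randomly placed spike
volumes (expected fraction `spike_rate = 0.02`); spikes use translations
only to avoid coupling to the FD rotation-radius convention.

**Structural.**  Fiber counts are negative binomial (mean/dispersion
parameterization; tract counts are overdispersed relative to Poisson) with
mean 30 within modules and 1 between, dispersion 8, sampled on the upper
triangle and mirrored.  Long-range shortcuts: each between-module pair is
upgraded to a within-strength connection with the group's
`shortcut_density`; fewer shortcuts lengthen paths.

**Symptoms.**  AHRS totals for the AVH group are normal(23.9, 8.4)
truncated at zero.

**Planted effects and calibration.**  Group effects enter only through the
named per-group parameters.  Defaults: `rho_within` 0.44 (HC) vs 0.34
(both patient groups), and `shortcut_density` 0.06 (HC, nAVH) vs 0.03
(AVH).  These were calibrated by Monte-Carlo so the planted standardized
effect on the least-sensitive metric is ≈ 1 pooled within-group SD at the
study's group sizes: the functional Lp effect is ≈ +1.0 SD (with Cp, Eg,
Eloc responding more strongly, ≈ −1.5 to −4 SD, since a single
within-module dial cannot equalize the four metric sensitivities), and the
structural Lp effect for AVH vs HC is ≈ +1.2 SD with ≈ 0 for nAVH vs HC.

**What the generator does not emulate.**  No voxel-level images, scanner
artifacts, physiological noise spectra, spatially heterogeneous
connectivity, hub architecture, or tractography geometry.  The
distributions are stand-ins chosen for testability, not estimates of any
real cohort: passing tests demonstrate that the pipeline recovers planted
effects of the stated size under these idealized conditions, not that it
would detect effects in real patient data.

## Numerical choices and degenerate inputs

- Permutation p-values use the add-one convention, so p ∈ [1/(n_perm+1), 1].
- Zero within-group variance: F is degenerate; p is reported as the
  minimum attainable value if groups differ, else 1.
- Constant inputs to the Spearman correlation are reported as degenerate
  (rho = NaN) rather than raising.
- Graphs whose largest component has < 2 nodes reject Lp; empty graphs
  yield Cp = 0 with a warning; a null-ensemble mean of 0 for any metric
  rejects normalization naming the metric.
- Rigid graphs (no valid double-edge swap) are returned unchanged with a
  warning.
- Master seeds spawn per-stage/per-subject sub-seeds through
  `numpy.random.SeedSequence`, so arms are reproducible end to end and
  subject-level work could be parallelized without seed collisions.

## Problem sizes used by the test suite

The shipped tests scale simulation sizes to desk hardware: null ensembles
of 100–200 (instead of 1000), 1000–2000 permutations (instead of 10000),
50 replicate cohorts for the effect-recovery experiment, and 500 random
graphs for oracle equivalence.  `scripts/acceptance.py` runs the full
126-subject pipeline with n_null = 30 and n_perm = 2000.

## Known limitations

- The nominal df = n − 2 correlation p-values ignore the autocorrelation
  induced by band-pass filtering, so the "significance" of edges is a
  thresholding device (as in the original protocol), not a calibrated
  per-edge test.
- Lp on fragmented graphs is a largest-component convention; comparisons
  between subjects with very different component structure mix effects.
- The rewiring null model preserves topology and the weight multiset but
  not nodal strength; strength-preserving variants are out of scope.
- Demographic comparisons, covariate adjustment and multiple-testing
  correction across metrics are deliberately not implemented.
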