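# Methods

This note documents the models, parameter choices and numerical behaviour
of `seasonet`, in the order the pipeline runs.

## Quantification

**TPM.** For sample *s*, `rate_i = counts_i / L_i` with effective length
`L_i` (bp), and `TPM_i = 10⁶ · rate_i / Σ_j rate_j`. The normalization
universe is whatever rows the matrix holds; after spike-in rows are
removed, biological TPM is renormalized to 10⁶ by default (flag
`renormalize_tpm=False` to disable — whether to renormalize after spike
removal is genuinely open, and renormalizing keeps the "columns sum to
10⁶" invariant simple).

**Relative abundance fractions.** Computed over taxonomically annotated
transcripts only (identity strictly above the cut; 60 for coarse groups,
90 for species-level work), per sample or after pooling TPM within a
month. Groups strictly below 2% of a column are pooled into `rare`.
All quoted thresholds in the package are strict inequalities (>90, >60,
<2%, >100, >800): boundary values fall outside.

**Transcripts per liter.** Spike-ins of known molecular input calibrate
one pooled recovery factor per sample,

    k = Σ_s counts_s / Σ_s (molecules_added_s · length_s)   [reads / (molecule·bp)]

Pooling across spike species length-weights the estimate and is robust
for a three-species spike set; per-spike ratios are available for
diagnostics but unused. A transcript's molecule count in the library
input is `counts_i / (k · L_i)`; the chain back to nature multiplies by
`rna_yield_ng / library_input_ng` (library → whole extract), then by
`resuspension_volume_ml / extraction_input_ml` (extract → whole filter
residue), and divides by `volume_filtered_l`:

    TPL_i = counts_i / (k·L_i) · (yield/input) · (resusp/extract) / V_filtered

Every factor is an explicit metadata column, so the chain is exactly
invertible: on a synthetic dataset the expected-count matrix propagated
through this chain recovers the planted molecules-per-liter to machine
precision (the test budget allows 10⁻⁶ relative error). TPL shares the
usual caveats of spike-calibrated estimates — taxon-specific lysis and
extraction efficiencies are *not* modelled, so TPL is comparable across
samples for a taxon, not across taxa.

## Co-expression modules

Input is the KO × sample TPM matrix (transcript TPM summed per KO).
Preprocessing sets values below 1 TPM to 0, drops KOs whose total across
samples is below 10, and applies log₂(x+1). Sample outliers are flagged
(not removed) when their standardized inter-sample correlation
connectivity falls below Z = −2.5.

The network is unsigned: `a_ij = |cor_ij|^β`. β is the smallest candidate
(1..20) whose signed scale-free fit `−sign(slope)·R²` of the binned
log₁₀ p(k) vs log₁₀ k regression (10 equal-width connectivity bins)
reaches 0.85; when no candidate reaches the target — the usual case for
block-structured planted data, whose degree distribution is bimodal
rather than scale-free — the best-fitting power is used and a warning is
raised. The fit table is always returned so users can pick an elbow power
explicitly, which is the idiomatic workflow.

Topological overlap refines the adjacency
(`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`), and
1 − TOM feeds average-linkage hierarchical clustering. The tree cut is a
bounded approximation of dynamic tree cut: a static cut at
`cut_height_quantile × max merge height` (default 0.98 — the cutHeight
convention; a cut at a *quantile of the height distribution* was
evaluated and rejected, because with a large weakly-correlated background
the high quantiles coincide with the maximum and everything collapses
into one cluster), then clusters larger than 3× the minimum module size
are recursively re-split (a split is accepted only when both children
reach the minimum size) down to `deep_split` levels; `deep_split = 0` is
the plain static cut. Undersized clusters dissolve to the unassigned
label 0; unassigned KOs whose best absolute module membership reaches
0.3 are reassigned.

Eigengenes are first principal components of the module's standardized
member rows, scaled to unit variance (ddof = 1) and sign-oriented so the
mean member correlation is positive. Modules whose eigengenes correlate
above 0.6 are merged pairwise-greedily, recomputing eigengenes after each
merge; the merge history is recorded. Module–trait correlations use the
Pearson t-transform with df = n−2, BH-adjusted over the whole
module × trait grid.

## Pathway association

KOs are ranked by decreasing module membership; per pathway, a one-sided
Mann–Whitney U compares member membership values against all other
retained KOs (including unassigned ones — the ranked list is the full
retained set). The U test uses midranks for ties; p-values come from
exact enumeration of all C(n, n_x) rank assignments when n_x+n_y ≤ 12
(ties included) and otherwise from the normal approximation with tie and
continuity corrections. Exact and approximate one-sided p agree within
0.01 for every split with min(n_x, n_y) ≥ 4 at n = 12; for extremely
unbalanced splits (n_x ≤ 3) the discrete null has too few atoms for any
continuous approximation to track that closely — an intrinsic property,
not an implementation artifact. BH adjustment is the step-up
`q_(i) = min_{j≥i} p_(j)·m/j`, applied within module across pathways
(a flag widens the scope).

## Richness and tests

Functional richness counts KOs with TPM > 0 in a sample (a configurable
floor exists but defaults to 0, as no floor is part of the definition).
Active species richness counts species bins (identity > 90) retained by
a *global* support rule — more than 100 of the bin's transcripts non-zero
in at least one sample — and present (≥1 non-zero transcript) in the
sample. ANOVA, Kruskal–Wallis (tie-corrected) and Pearson tests report
p-values through the package's own tail routines: regularized incomplete
gamma (series for x < a+1, continued fraction otherwise) and regularized
incomplete beta (Lentz continued fraction with the symmetry split).
These agree with independent library evaluations to better than 10⁻¹⁰
over df ≤ 200. Abundance covariates are log₁₀(x+1)-transformed before
correlation.

## Trophic-mode protocol

Species profiles sum TPM over all transcripts carrying each PFAM (a
multi-PFAM transcript contributes fully to each; a presence/absence mode
exists). Only profiles with more than 800 non-zero PFAMs are eligible.
Profiles are restricted to the training feature union, missing features
are imputed with 0, and values are MinMax-scaled by the scaler fitted on
the training set; out-of-range values clip to [0,1] (disable with
`clip=False`). The classifier is pluggable (any fit/predict estimator);
the default is XGBoost with a fixed seed, 200 trees, depth 4. Monthly
consensus is a strict majority over a bin's eligible sample predictions;
exact ties are reported as `ambiguous`. The original externally-trained
model and its feature list are not shipped — the package trains on
labelled profiles supplied by the user or generated synthetically — so no
claim is made of reproducing the original model's reported precision.

## Synthetic communities

The generator emulates a year of monthly sampling at six stations
(12-month cycle, July–June labels) after assembly and annotation:

- **Phenology.** Each taxon has a circular-Gaussian activity curve
  `A·exp(−d²/2σ²)` over months (d = circular month distance), peaks
  spread across the year, width σ = 1.5 months, plus a 2% baseline —
  single-peaked annual blooms in the simplest two-parameter form.
- **Counts.** Expected transcript intensities (taxon activity ×
  log-normal transcript weight) are scaled to a mean depth of 2×10⁵
  reads and sampled gamma-Poisson with dispersion 0.3
  (Var = μ + 0.3μ²), the standard overdispersion model for sequencing
  counts; dispersion 0 degenerates to Poisson.
- **Spike-ins.** Three spike species with distinct lengths receive a 1%
  expected read share (the spike-to-total proportion the protocol
  targets), allocated by molecules × length; the per-sample true recovery
  factor and the implied molecules-per-liter truth are recorded, closing
  the TPL loop exactly in expectation.
- **Planted modules.** Five modules of 80 KOs (against the 70-KO
  detection minimum) each follow a latent seasonal trajectory; month-level
  latents are QR-orthogonalized across modules so cross-module
  correlations are near zero by construction, and member KOs are noisy
  affine copies carried by three dedicated transcripts each.
- **Annotation.** Taxonomic and functional annotation are *independent*
  channels (as when taxonomy and function come from different reference
  searches): each is absent with probability `frac_unannotated`
  (default 0.2); identities are drawn from a 60/25/15 mixture of
  >90 / 60–90 / <60 bands. `frac_unannotated = 1` degenerates to fully
  null annotations.
- **Trophic blocks.** The first tenth of the PFAM catalog is a
  "photosynthesis" block, the second tenth a "degradation" block; a
  species' block (by its planted label) is up-weighted by (1+effect),
  effect 5 by default, identically in the training-set generator and the
  community generator. Each transcript carries one primary PFAM (plus
  occasional extras), so per-PFAM TPM sums inherit the block contrast.

What the generator does **not** emulate: taxon-specific lysis/extraction
biases, compositional coupling between taxa beyond shared normalization,
reference-database gaps (all lineages resolve to species), read-level
error, assembly chimerism, and the real feature-selection history of the
trophic model. Passing recovery tests therefore demonstrates correctness
of the algorithms under the stated generative model, not field
performance on deposited data.

## Problem sizes and determinism

The test suite and the acceptance script use a community of 12 taxa ×
2,400 transcripts (~30k rows × 72 samples), a module-recovery problem of
1,000 KOs × 60 samples with 5 planted modules, 500 null replicates for
rank-test calibration, and 200 training profiles per trophic class —
sizes at which every stage completes in seconds while leaving the
planted-signal margins wide. All randomness flows through
`numpy.random.default_rng` seeded from a single integer; fixed seeds give
byte-identical outputs, including the serialized truth JSON.

## Known limitations

- The recursive tree cut approximates, but is not, the published dynamic
  hybrid algorithm; deepSplit maps to recursion depth.
- Module detection quality degrades at very high soft powers (adjacency
  compresses toward 0 and all TOM dissimilarities toward 1); when the
  scale-free target is unreached, inspect the returned fit table rather
  than trusting the argmax fallback blindly.
- The Mann–Whitney normal approximation is inaccurate for extremely
  unbalanced small samples (see above); the exact route covers n ≤ 12.
- TPL assumes spike recovery is representative of biological transcripts
  of similar length; length-dependent recovery bias is not modelled.
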