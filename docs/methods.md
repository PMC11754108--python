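# Methods

## The measurement model

The pipeline analyses growth-rate selections in which a domain's cellular
abundance sets the growth rate of the cell carrying it. A two-state
thermodynamic picture connects sequence to signal: a variant with folding
free energy ΔG (dimensionless, RT = 1 until rescaled) is folded with
Boltzmann probability p_f = 1/(1 + e^ΔG), and the expected growth rate is
affine in the folded fraction, γ₀ + γ₁·p_f with γ₁ > 0. All downstream
stages assume (i) fitness is monotone in abundance, (ii) abundance is
dominated by fold stability except at functional sites, and (iii) the
measurement error of a variant's fitness is approximately Gaussian.

## Family energy model

For a family aligned into L columns, the additive model is

    ΔG(variant) = b0 + Σ_c U[c, wt_aa(c)] + D[c_mut, mut_aa]

with U the per-(column, amino acid) wild-type composition energies — so a
homologue's baseline stability is determined by its sequence — and D the
mutation energies shared by all homologues (the no-specific-epistasis
assumption). Wild-type identity and mutation features are kept separate:
the same amino acid at the same column can appear in U (as someone's wild
type) and in D (as a mutation) with different energies.

Fitting minimizes Σ_i (f_i − γ₀ − γ₁·p_f(ΔG_i))²/σ_i² + λ(‖U‖² + ‖D‖²)
with L-BFGS-B and an analytic gradient (γ₁ bounded positive). Numerical
choices that matter:

* **Initialization.** Random starts frequently landed in poor basins in
  which saturated homologues drift to meaningless baselines. The default
  start instead inverts the Boltzmann map on range-clipped fitness,
  alternately solves per-homologue baselines and shared D on the linear
  scale (8 sweeps), and ridge-solves the minimum-norm U reproducing those
  baselines. Seeded jittered restarts remain as a fallback.
* **Ridge strength, λ = 0.1.** Energies with almost no curvature —
  stabilizing changes on an already folded background, or strong further
  destabilization of an unfolded one — are not identifiable from the
  assay and otherwise drift to large magnitudes chasing noise above the
  folded plateau. λ = 0.1 pins them near zero while attenuating
  well-determined energies negligibly; λ = 0 reproduces the unregularized
  model for testing.
* **Error moderation.** Standard errors estimated from k = 3 replicates
  have 2 degrees of freedom, and their reciprocal squares are wild as
  weights. `encode_family` shrinks each replicate variance toward the
  family-pooled variance with prior weight d₀ = 6 (empirical-Bayes style,
  as count-based error models in this field do) before use in the fit.
* **Gauge.** Adding a constant to a column of U and subtracting it from
  b0 changes nothing; after fitting, each fully observed column of U is
  centred over the residues present there and the shift absorbed into b0,
  making the reported parameterization unique.
* **Convergence** by relative loss change below 1e-9 (configurable); the
  tighter tolerances used in exact-interpolation tests are noted there.

Cross-validation assigns variants to ten folds uniformly at random under
the given seed (no stratification). The explainable fraction is
R²(observed, predicted) / R²(replicate 1, replicate 2); on synthetic data
where the fitted model is the true model this ratio exceeds 1 (predictions
are less noisy than single replicates) and is flagged, not clipped.
Leave-one-homologue-out predicts the held-out baseline purely from its
composition through U; wild-type residues never observed in training
contribute the column-centred mean (0) with a coverage warning. Genetic
distances are the mean per-column Hamming mismatch count and the mean
BLOSUM62 dissimilarity Σ_c (s(a,a) + s(b,b))/2 − s(a,b) over mutually
non-gap columns (a standard positive form; no canonical definition
exists).

Scaled energies: the 2.5th percentile of the fitness-oriented
(sign-flipped) energy distribution defines magnitude 1, the wild type is
0, and the output convention is positive = destabilizing so thresholds
like "scaled ΔΔG > 0.3" select strong destabilization; the orientation is
recorded in the metadata and the opposite sign is a flip away.
Destabilization calls for predicted homologues use approximate parameter
standard errors from the diagonal Gauss-Newton curvature of the D block
(one-tailed test for ΔΔG > 0, BH-FDR over the prediction set).

A linear-output variant of the model (no Boltzmann transformation) is
kept behind `transform="linear"` solely for the invariance check that its
energies track the primary model; it is not a supported analysis path.

## QC and normalization

Four per-domain metrics — wild-type position (f_wt − p95)/(p95 − p5),
replicate Pearson r (missense only, averaged over replicate pairs),
fitness-vs-rSASA correlation, and fitness-vs-mutant-hydrophobicity
correlation (Kyte–Doolittle by default; any 20-value scale accepted; the
choice only affects this QC metric) — are standardized and combined by
PCA. PC1 is oriented to track replicate correlation; ranking is by PC1
descending with ties broken by domain id. Retention requires rank ≤
max_rank (default: all domains in synthetic runs), replicate r strictly
greater than 0.485, coverage above 50% (≥ 10 reads in ≥ 1 replicate), and
absence from an explicit manual exclusion list. Foldedness screening
excludes domains with under 10% buried residues (rSASA < 25%) or mean
pLDDT below 50.

Normalization is exactly affine per domain: wild type ↦ 0 and the 2.5th
percentile (linear-interpolation quantile rule) of missense + wild-type
growth rates ↦ −1; errors scale by the same factor. Stop-codon variants
ride through the map but never enter percentiles or model fits.

## Destabilization and clinical statistics

z = f_norm/σ_norm, one-tailed p = Φ(z) (only fitness below wild type can
be significant), BH-FDR in one batch over the declared analysis set
(global, matching dataset-wide claims; configurable). Destabilizing:
q < 0.1 and f_norm < 0; strong additionally f_norm < −0.3. Fisher
enrichments report the sample (cross-product) odds ratio, with the
Haldane–Anscombe 0.5 correction only when a cell is zero, and the exact
two-tailed p from the raw table. MCC uses the closed-form 2×2 expression;
its error is the standard deviation over 10 resamples drawing
f* ~ Normal(f_norm, σ_norm) and re-running the caller. The default
prediction rule for clinical evaluation is strong destabilization
(configurable to any destabilization). Population variants count as
benign above an allele-frequency floor of 1e-5. Conflicting clinical
labels between sources drop to VUS with a warning.

## Functional sites

Domains qualify when (1) fewer than 30% of variants are strictly fitter
than the wild type — our reading of "wild type above the 30th percentile"
— and (2) the 5th–95th percentile range of the evolutionary score exceeds
10. The sigmoid f̂ = −1 + 1/(1 + e^−(s − xmid)/scal) is fitted by
weighted nonlinear least squares with weights
w_i = (max f − min f − (f_i + 1))², which prioritizes low-stability
variants; initialization xmid = median(s), scal = (p95 − p5)/10, with 5
seeded jittered restarts before declaring non-convergence. Residual sign:
positive = observed stability above the curve, i.e. evolutionary fitness
lower than stability explains — the signature of function beyond
stability. Mutations are functional at q < 0.1 (two-tailed z on
residual/σ_norm, BH within domain — the residual null is domain-specific)
and residual > 0.3; residues are sites when the 1/σ²-weighted mean
residual exceeds 0.3 with at least 3 measured substitutions. Variance
explained by stability uses the disattenuation R_xy = r_xy/√r_xx (both
Pearson and Spearman computed; the Pearson version reported), clipped at
1 with a warning when the correction overshoots.

## Epistasis

Residuals to the family model are tested two-tailed (z = residual/σ,
BH per family); epistatic requires q < 0.1 and |residual| > 0.05 h⁻¹ in
raw growth-rate units (when fitting on normalized fitness, residuals are
converted back through the per-domain affine map before gating — units
are declared, never guessed). Columns are core (rSASA < 25% in ≥ 75% of
non-gap homologues), surface (> 25% in ≥ 75%) or changing. Per-column
enrichment uses the same Fisher machinery with BH over columns
(within-family); epistatic sites need log₂OR > 1.5 and q < 0.05. A
family-level core-vs-surface odds ratio summarizes the burial bias.

## The synthetic generator

`simulate_family` runs the model forwards under one seed: per-column
energies U ~ N(0, 0.25²) and mutation energies D ~ N(2.5 RT… — see
below), wild types drawn per column from a softmax over −U at temperature
0.1 (≈ 30–45% pairwise identity, comparable to a diverged domain family),
folding energies mapped through p_f to growth rates γ₀ = 0.05 h⁻¹ (the
unfolded floor), γ₁ = 0.35 h⁻¹, replicate noise such that the fitness
mean has sd 0.05 h⁻¹, per-variant errors as floored replicate standard
errors, Poisson(100) read counts, one synonymous variant per domain and
one stop per position (fully unfolded).

Energy scales are chosen to be realistic and identifiable at once: wild
types are marginally stable (mean −2.5 RT ≈ 1.5 kcal/mol, typical of
small domains) and conditioned into a ±1 RT band around the family
median — emulating an assay that only retains well-behaved wild types,
and keeping every domain within the dynamic range that the eligibility
rules require; core mutations are strongly destabilizing
(D ~ N(5, 2) RT ≈ 3 kcal/mol, as buried hydrophobic→polar substitutions
are) and surface mutations mild (N(1, 0.8) RT). Functional columns
(10% of columns, drawn from the surface — binding sites are rarely
structurally critical) subtract 12 score units from the evolutionary
score, whose base value tracks the folded fraction over a 20-unit range
with 0.5 noise. Clinical labels are sampled with pathogenicity
probability increasing in combined deleteriousness (destabilization plus
functional-site effect), benign and population labels from near-neutral
variants with log-uniform allele frequencies in [1e-6, 1e-2]; label
densities are far higher than in real annotation databases, deliberately,
to give the evaluators statistical power.

Planted epistasis shifts a uniformly chosen 5% of missense variants
before fitness generation. By default the energy shift is sized per
variant so the expected growth rate moves by 5 measurement-noise sd
(capped near the transition midpoint where the dynamic range cannot
deliver it); a fixed-magnitude energy shift is available instead, in
which case its direction is chosen toward the observable side of the
dynamic range — a symmetric ± sign would render roughly half the planted
deviations invisible (a stabilizing shift on a folded background does not
move the growth rate), which says something about assays, not about
callers. A hotspot mode concentrates part of the planted set at one
column for site-enrichment validation, and `core_bias` tilts sampling
toward buried columns.

What the generator does **not** emulate: read-count noise propagating
into fitness (counts are decorative), codon-level effects, indels or
alignment uncertainty, domains violating two-state folding,
position-dependent error structure, and any correlation between the
evolutionary score's errors and the assay's. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to real-data pathologies such as misalignment or
non-two-state behaviour.

## Problem sizes and determinism

The default family — 12 homologues × 40 columns, every missense variant
(9,132 fitted observations, ~19 observations per shared energy) — fits in
1–2 s on one CPU; tenfold CV in ~15 s. Null calibrations use 10,000
variants. All randomness flows from explicit seeds; pipeline stages
derive sub-seeds from a stable hash of (master seed, stage name) so
adding a stage never perturbs another.

## Known limitations

* Baselines of homologues far outside the assay's dynamic range are only
  weakly identified (their exact ΔG does not change any fitness); the
  ridge keeps them finite rather than meaningful.
* Standard errors for predicted-homologue calls come from the diagonal
  curvature only and ignore parameter covariances; they are adequate for
  ranking and FDR gating, not for formal confidence intervals.
* The epistasis caller inherits the additive model's blind spots: a
  deviation shared by most homologues at a column is absorbed into the
  shared energy and surfaces only as site-level enrichment, not as
  per-variant calls (visible in the hotspot validation).
* Eligibility condition (1) has two textual readings; the implemented
  one (wild type within the top 30% of the domain's fitness distribution)
  is flagged as an interpretation and configurable.
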