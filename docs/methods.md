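# Methods

## Phase-interaction connectivity

ROI time series are band-pass filtered to 0.04–0.07 Hz with a Butterworth
filter of order 2 applied forward–backward (`sosfiltfilt`), i.e. zero phase:
any phase distortion from the filter would contaminate the quantity of
interest, the instantaneous phase φᵢ(t) of each region obtained from the
analytic (Hilbert) signal. The phase-interaction matrix is the time average
⟨P⟩ᵢⱼ = (1/T) Σₜ cos(φᵢ(t) − φⱼ(t)), computed over however many samples the
subject has (no resampling across subjects; the average absorbs differing T).
Two regions score 1 when locked in phase, 0 in quadrature, −1 in anti-phase.

Hilbert phases are unreliable near the record boundaries, so an optional
`trim` parameter (default 0) excludes the first and last k samples from the
average; reference computations here use trim = 64 on 2048-sample records.
The filter family and order are package defaults, configurable via
`BandpassSpec`; band edges must satisfy high < Nyquist = 1/(2·tr). Pearson
correlation matrices are accepted wherever phase-interaction matrices are.

## Harmonization models

All three harmonizers act on a subjects × edge-features table (strict upper
triangle of each connectome, row-major; the unit diagonal carries no site
information and is excluded).

**ComBat.** Per feature v: y = αᵥ + Xβᵥ + γₜᵥ + δₜᵥ·ε, ε ~ N(0, σᵥ²).
Estimation follows the standard parametric empirical-Bayes recipe: least
squares with site effects constrained to a sample-size-weighted zero sum;
pooled residual variance σ̂ᵥ²; standardization; per-site moments γ̂, δ̂²;
hyperparameters by moment matching across features (normal prior on γ,
inverse-gamma on δ²); iterated conditional posterior means until the largest
parameter change is below 1e−4 (cap 100 iterations). The harmonized value is
σ(z − γ*)/δ* plus the restored intercept and covariate effects. γ* is stored
on the standardized scale; γ*·σ is the data-scale site offset. Protected
covariates default to whichever of age/sex/diagnosis the phenotype table
carries; categoricals are one-hot encoded against the first sorted level,
and the encoding is frozen in the model so held-out cohorts are transformed
identically (unseen sites or levels are errors, not silent extrapolation).

`eb=False` disables shrinkage (plain location/scale adjustment). Two
degenerate regimes fall back to it automatically: a single feature (the
across-feature prior moments do not exist) and zero across-feature spread.
With shrinkage off, the pooled per-feature mean is preserved exactly under
an intercept-only design; with shrinkage on, it moves by O(1e−4) because the
shrunken site effects no longer sum exactly to zero — this is inherent to
empirical Bayes, not an implementation artifact.

The multiplicative effect is identified only relative to the pooled residual
scale (standardization divides by σ̂ᵥ). Recovery checks therefore compare
δ* and the generating δ after normalizing each by its weighted root mean
square; the ratio between sites is the identified quantity.

**CovBat.** After ComBat, the covariate-free residuals are decomposed by
thin SVD (subjects ≪ features is the expected regime). K is the smallest
number of components reaching the requested cumulative variance fraction
(default 0.95). For k ≤ K each site's score mean and standard deviation are
mapped to the pooled values (mean 0, variance λₖ); scores beyond K pass
through. The site scale ρ̂ₜₖ is stored as site-SD / pooled-SD, so the
correction (ξ − μ̂)/ρ̂ lands directly on the pooled scale. The α̂, β̂ from the
ComBat step are reused when restoring covariate effects. No empirical Bayes
is applied to the scores.

What CovBat can and cannot fix: per-component score scaling equalizes the
*variance profile* of each site along the pooled principal axes. Site
covariance differences that live in the score *correlations* — e.g. a
rotation of one site's residual structure relative to the pooled axes — are
off-diagonal in that basis and are not touched. The covariance-alignment
simulation in the test suite therefore uses the regime the method targets:
two sites sharing residual principal axes (latent variances [8, 3, 1] vs
[3, 1, 0.3] on shared loadings, ambient noise SD 0.3, 300 subjects per site,
45 features). There CovBat removes most of the inter-site covariance
Frobenius distance and consistently beats ComBat alone; the distinct pooled
spectrum also matters, since degenerate pooled eigenvalues leave the
principal axes undetermined and the per-axis correction ill-posed.

**Traveling subject.** The companion dataset — the same healthy reference
subjects scanned once at every site — is fitted per feature with
y = const + m(site) + p(participant) + e by ridge regression (penalty λ on
everything but the intercept, default 0.1) under sum-to-zero constraints on
m and p, implemented by deviation (sum) coding. Because the travelers form a
single healthy group and the main cohort is not modeled jointly, the
sampling-bias and disorder terms vanish and are stored as zeros. Measurement
bias is estimated from the companion only; harmonization subtracts the
site's m̂ᵥ from every scan (deliberately non-idempotent — applying twice
subtracts twice). On the balanced 9-traveler × 12-site design with scan
noise SD 0.05, the estimation error of m̂ is ≈ noise/√9 ≈ 0.017 per entry.

## Workflow scale

The harmonizers are scale-agnostic, but the end-to-end workflow
(`harmonize_cohort`, the CLI) applies them on the Fisher-z (arctanh) scale
and maps back through tanh. Correlation-like weights are
variance-stabilized there, additive site effects are closer to truly
additive, and the output is guaranteed to land back in (−1, 1) where the
binarization threshold lives. Raw-scale harmonization is available via
`on_fisher_z=False`.

## Network information measures

Connectomes are binarized with a strict rule: edge present iff weight >
threshold (default 0.5; an exact tie is *not* an edge). Node i's random-walk
distribution is p_{i→j} = aᵢⱼ/kᵢ over the other N−1 nodes in ascending node
order. Nodal entropy is S[P(i)]/ln(N−1); since the distribution is uniform
over kᵢ neighbors this equals ln kᵢ/ln(N−1), and the brute-force loop
implementation used as a test oracle evaluates the −Σ p ln p sum directly.
Nodal Fisher information is ½ Σ over the N−2 consecutive pairs of
(√p_next − √p)²; the index order is the ascending node order (the measure is
order-dependent; this convention is fixed package-wide). The prefactor ½ is
kept as is even though a single boundary jump then scores ½ rather than 1;
the bound F ≤ 1 still holds, with equality at two unit jumps (an interior
spike) and for isolated nodes.

Isolated nodes leave p undefined; they are assigned H(i) = 0 and F(i) = 1 —
the maximally ordered convention, consistent with the plane's corners — and
logged. Network H and F are plain means over all N nodes, so (H, F) always
lies in the unit square: complete graphs at (1, 0), empty graphs at (0, 1).

## Site-effect quantification

For each harmonization variant the Kruskal–Wallis rank test (tie-corrected;
H and F values tie exactly for identical graphs) is applied twice: to the
subjects' H values (measure "SE") and to their F values ("FI"), grouped by
site, null hypothesis of equal population medians. p-values are reported as
p′ = −log₁₀(p); the base is fixed by the correspondence 1.301 ↔ 0.05.
Completely tied data carry no evidence and return (H = 0, p = 1). No
multiplicity correction is applied by default (a Bonferroni helper exists).
Every group needs ≥ 2 observations and ≥ 2 groups must be present.

## Synthetic cohorts

The generator builds each edge feature on the Fisher-z scale as
base + covariate effects + γₜᵥ + pⱼᵥ + δₜ·ε, then maps through tanh:

- base ~ N(0.55, 0.35²): the bulk of tanh(base) spans ≈ 0.1–0.85, straddling
  the whole 0.2–0.8 threshold range so binarization is informative at every
  threshold in the robustness sweep.
- Site additive effects γₜᵥ (SD 0.2 by default, zero-sum across sites) split
  their variance budget evenly between a site-wide systematic offset and
  edge-specific terms. The systematic half models the calibration/SNR
  component of scanner differences and is what makes the site's mean edge
  density — and hence H and F — shift coherently; purely edge-independent
  effects average out as 1/√V and leave site detectability erratic. With
  the default settings a 4-site × 30-subject cohort shows unharmonized
  p′ of order 10–40, the same regime the real multi-site datasets exhibit.
- Per-site noise scales δₜ are log-uniform in (0.7, 1.4); scan noise SD 0.15;
  per-subject biological deviations SD 0.2 (constant across a traveler's
  scans, which is what identifies m in the companion regression).
- Covariate effects: diagnosis shift 0.15 on a contiguous 10% block of edges
  (so covariate protection is measurable), age slope 0.002/year, sex shift
  0.05.
- The traveling companion shares the cohort's γ (as measurement bias m) and
  noise model; travelers are fresh healthy subjects scanned once per site.

Everything is deterministic under the config seed. The generator emulates
the statistical structure the harmonizers assume — it does not emulate
hemodynamics, spatially correlated noise, site-specific demographics, or
motion artifacts, so passing tests demonstrate correctness of the methods
under their own model, not performance on real scanners.

Null-behavior checks (ComBat as identity when no site effects exist; CovBat
collapsing to ComBat when site covariances agree) are run at quiet noise
settings (noise and subject-factor SD 0.05): empirical-Bayes shrinkage and
PC-score rescaling perturb values in proportion to the residual SD, and the
0.02 elementwise band on those checks is meaningful only when sampling-driven
adjustments sit below it.

## Problem sizes and numerical choices

Reference and test computations use desk-scale problems chosen to make each
effect unambiguous: 2048-sample sinusoids for the connectivity anchors,
N = 10 for the complete-graph entropy, 100 subjects/site for ComBat
recovery, the 9 × 12 traveling design, 300 subjects/site × 45 features for
covariance alignment, 50 seeded replicates of 4 × 30 cohorts (16 ROIs) for
the end-to-end pattern, and 2000 null simulations for Kruskal–Wallis
calibration. EB convergence 1e−4 (cap 100 iterations); SVD rank cut at
machine-precision scale; arctanh inputs clipped to ±(1 − 1e−12); harmonized
values are never clipped to [−1, 1] (binarization tolerates excursions).

## Known limitations

- The Fisher-information ordering convention follows input ROI order;
  reordering ROIs changes F slightly. ROI order is preserved as given.
- The traveling-subject model here covers the healthy-travelers design only;
  joint modeling of the main cohort (sampling-bias and disorder terms) is
  not implemented.
- CovBat corrects score means and variances, not score correlations (see
  above); nonparametric ComBat priors, ComBat-GAM and longitudinal variants
  are out of scope.
- Binarized, threshold-dependent graphs only; weighted-graph generalizations
  of H and F are not provided.
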