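# Methods

This note records the models, parameter choices and numerical conventions
behind `spreadfoci`, and what the synthetic-data tests do and do not
establish.

## 1. Synthetic spread nuclei

The original STED micrographs behind the published per-strain focus
statistics are not publicly deposited, so the package ships a generator
whose *population structure* copies the published per-strain moments and
whose ground truth makes every downstream stage testable.

**Geometry.** A nucleus is an ellipse; the default is a circle of radius
1800 nm, a configuration default chosen so wild-type focus densities look
like typical spread-nucleus images, not a biological claim. Semi-axes are
validated to [500, 5000] nm.

**Counts.** Per-nucleus focus counts are Poisson with the published
per-strain mean (e.g. wild-type: 70.0 RPA, 26.9 Dmc1). The published
count SDs (e.g. ±22.2 for wild-type RPA) are overdispersed relative to
Poisson; the generator does not reproduce that between-nucleus
heterogeneity. Consequently a green moment test certifies the *mean*
structure only.

**Lengths.** Only mean ± SD are published for focus lengths, so the family
is a modelling choice: a moment-matched lognormal (positive, right-skewed,
as focus-length populations are); gamma and fixed are available.
Moment matching is exact in mean and SD
(`σ² = ln(1+(sd/mean)²), μ = ln mean − σ²/2`).

**Pairing.** A fraction of Dmc1 foci ("DSB-coupled") is anchored to an RPA
partner at a center distance drawn from a zero-truncated normal (default
90 ± 40 nm, roughly the side-by-side contact distance of a ~97 nm Dmc1 and
a ~77 nm RPA focus); the rest are uniform ("DSB-independent"). Partner RPA
foci are drawn without replacement while possible. Default paired
fractions use the only printed colocalization percentages (wild-type
0.355, *dmc1-E157D* 0.701, *dmc1-E157D mei5* 0.691); strains without a
printed value default to 0.5, which is explicitly arbitrary.

**Paired lengths and the mixture constraint.** Where a strain has printed
RPA-colocalized Dmc1 length moments (wild-type 118.9 ± 40.0 nm,
*dmc1-E157D* 149.5 ± 66.8, *dmc1-E157D mei5* 168.0 ± 66.4), paired foci
draw from that law. Sampling paired and unpaired foci from the *same*
overall law would then inflate the pooled mean above the printed overall
moments (wild-type: 0.355·118.9 + 0.645·97.1 ≈ 104.8 vs 97.1 nm). The
generator therefore solves the unpaired component's (mean, sd) so that the
paired/unpaired mixture reproduces the printed overall moments exactly
(wild-type unpaired ≈ 85.1 ± 32.4 nm; *dmc1-E157D* ≈ 98.0 ± 18.1;
*dmc1-E157D mei5* ≈ 100.4 ± 35.3; all feasible). Infeasible user
combinations raise.

**RNG.** One root seed; each nucleus gets an independent stream derived
from `(seed, crc32(nucleus_id))`, so per-nucleus output does not depend on
how many nuclei are simulated. Offsets that push a paired focus outside
the nucleus are redrawn up to 100 times, then an error names the focus.

**Rendering.** Each focus is a uniform-density line segment of its length
and orientation convolved with an isotropic Gaussian PSF, evaluated in
closed form at pixel centers (perpendicular Gaussian × difference of
normal CDFs along the axis). Defaults: 20 nm pixels, σ = 15 nm
(FWHM ≈ 35 nm, i.e. below the ~50 nm depletion-microscope resolution
limit), background 100 counts, amplitude 50 counts/nm, 16-bit output.
Optional Poisson photon noise (gain) and additive Gaussian read noise;
with both off the image is deterministic and above-background integrated
intensity is proportional to total segment length. The simulator emits
post-deconvolution-like images: no 3-D structure, no chromatin axes, no
antibody stoichiometry, no spatially varying background.

## 2. Focus detection

The measurement chain mirrors the common ImageJ workflow: strict
`intensity > threshold` binarization (Otsu by default), 8-connected
component labeling, unweighted pixel centroid, and the full major axis of
the ellipse with the same normalized second central moments as the pixel
set (4·√λ₁). `min_area_px = 2` suppresses single-pixel noise. All three
conventions are config-visible; the original study does not state its
threshold method or size filter, so these defaults are explicit choices,
not claims of equivalence.

Detected lengths systematically exceed ground-truth segment lengths by a
PSF- and threshold-dependent inflation; the pipeline deliberately applies
no deconvolution or correction, so length comparisons are valid *within*
a fixed imaging configuration (rank recovery is what the tests assert:
Spearman ρ > 0.99 over 60–300 nm). Touching foci merge (no watershed); at
*dmc1-E157D* densities rendered-and-redetected counts run below ground
truth for that reason.

## 3. Colocalization

A Dmc1 focus is scored against its single nearest RPA focus
(center-to-center Euclidean distance in the spread plane); colocalized iff
`d < L_dmc1 + RPA value`, strict. The full Dmc1 length is used (the rule
as stated); a half-length variant is available behind
`ColocConfig(half_length=True)`. The RPA value is computed per strain over
all pooled RPA focus lengths: `mean/2 + sample SD`. Multiple Dmc1 foci may
share one RPA focus.

**Fortuitous colocalization.** Primary null: re-draw all Dmc1 centers
uniformly within the nucleus region (counts and lengths preserved, RPA
configuration fixed), 1000 randomizations by default, seeded; the
fortuitous fraction is the mean observed fraction over randomizations.
Conditional on the RPA configuration this is an exactly unbiased estimate
of the chance colocalization rate. A secondary analytic null
(`dense_region`) approximates the densest-region style of chance
estimation as `1 − exp(−λπr̄²)` with λ the RPA density of the densest
nucleus quadrant; it is a documented over-estimate and is reported with
its method label. The originally cited densest-region procedure is not
fully specified in the source and is not claimed to be reproduced.

**Informativeness.** A nucleus is informative iff observed − fortuitous
> 5 percentage points (absolute, strict; an epsilon of 1e−9 guards the
strict comparison against float noise). Note the statistical floor: the
observed fraction of a nucleus with n Dmc1 foci has binomial noise
√(p(1−p)/n) — ≈5 pp at p ≈ 0.4, n = 100 — so at high focus densities the
5-pp filter admits an appreciable chance-only false-positive rate
(~10–16% in our calibration runs). This mirrors the behaviour of the
published filter; the package reports both fractions per nucleus so users
can see the margin.

## 4. Statistics

- SDs are sample SDs (n−1) throughout; SD is reported missing for n = 1.
- Wilcoxon rank-sum: midranks for ties; exact conditional enumeration of
  all C(n, n₁) rank assignments when min(n₁, n₂) ≤ 8 and the enumeration
  is ≤ 4·10⁵ combinations, else a normal approximation with tie
  correction and 0.5 continuity correction. Identical samples give p = 1.
- Two-proportion z: pooled variance; z² equals the uncorrected 2×2
  chi-square. Each spore is treated as an independent Bernoulli trial,
  ignoring within-tetrad correlation — the convention of the test being
  reproduced. No multiple-testing correction is applied (none was in the
  source analysis).
- Viability reconstruction: total spores = 4 × tetrads; the viable count
  is the unique integer whose percentage rounds (half-up, exact integer
  arithmetic) to the printed one-decimal value. Three table rows admit no
  such integer — the two heterozygote rows (91.2%, 58.8%) and the
  *dmc1-E157D sae3* row (57.0%, where 89/156 already rounds to 57.1) —
  indicating not every dissected tetrad yielded four spores; these raise
  an inconsistent-row error by design. `strict=False` falls back to the
  nearest count for exploratory comparisons.
- nm→nt conversion: `nt = (L − offset)/rise`, rise = 0.34 × 1.5 =
  0.51 nm/nt (B-DNA rise times the 1.5-fold filament stretch). The offset
  (67.9 nm) is fixed by requiring 118.9 nm ↔ 100 nt and reproduces the
  149.5 nm ↔ 160 nt pair exactly and 168.0 nm ↔ ~190 nt within ~4%
  (196 nt); it is interpretable as PSF plus antibody-decoration inflation
  of the measured contour. Both parameters are exposed; lengths below the
  offset return 0 nt with a warning.

## 5. Known limitations

- Count dispersion across nuclei is Poisson, narrower than the published
  between-nucleus SDs.
- Rendered-image detection merges touching foci at high densities; count
  recovery is exact only for well-separated foci.
- The generator's paired fraction equals the published *experimental*
  colocalization percentage where one exists, but measured colocalization
  of a simulated strain also includes chance colocalization of unpaired
  foci, so it will overshoot that input at high densities.
- The per-nucleus 5-pp informativeness margin does not control the
  chance-only flag rate below 5% at realistic densities (see §3).
- Nucleus geometry is taken from the simulator or sidecar metadata; no
  nucleus segmentation from images is attempted.
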