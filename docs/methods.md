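# Methods

This note documents the models, conventions and parameter choices
behind each analysis stage, what the synthetic generators emulate (and
what they do not), and the numerical decisions that were genuinely
open.

## Coordinate and calibration conventions

All masks are 2-D integer label images (0 = background) with one
isotropic calibration, `pixel_size` in μm/px; physical distances are
between *pixel centres*, so sub-pixel edge geometry is never inferred.
`x` is the column index, `y` the row index; angles are measured from
the +x axis, counterclockwise positive with y pointing up (row index
negated). Object areas are rasterized areas, pixel count ×
`pixel_size`² — this is what any mask-based morphometry actually
measures, and the synthetic generators record the same quantity as
ground truth rather than analytic ellipse areas.

## Nuclei morphometry

* **Area gate.** Nuclei are retained when 40 μm² ≤ A ≤ 200 μm². The
  bounds are read as a closed interval; objects exactly at a bound are
  kept. The gate removes debris and under-/over-segmented objects.
* **Clustering.** Two nuclei are linked when the minimal Euclidean
  distance between their 8-connectivity boundary pixel centres is
  strictly below 3 μm; clusters are connected components of that graph
  (single linkage). This transitive reading is the only one that can
  produce the large aggregates (10–20 nuclei) seen on unpatterned
  substrates: a chain of nuclei each < 3 μm from the next forms one
  cluster even if its ends are far apart. A cluster of size 1 is an
  *isolated* nucleus. The implementation queries one KD-tree over all
  boundary pixels and is verified in the tests against brute-force
  all-pairs distances with BFS components.
* **Shape.** Eccentricity and orientation come from the eigendecomposition
  of the central second-moment matrix of the pixel set,
  e = √(1 − λ₋/λ₊), θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂) mapped to
  [−90°, 90°). Single-pixel objects are degenerate and reported as
  (0, 0) with a flag. Eccentricity agrees with
  `skimage.measure.regionprops` (cross-checked in tests); the
  orientation convention is kept in-package so generator and
  measurement share one definition.
* **Fusion index and marker fractions.** A nucleus is "within" a
  myotube when its centroid pixel carries a myotube label. Centroid
  membership is robust to partial edge overlap; any-overlap membership
  would count grazing contacts. Marker fractions are positives over
  retained nuclei.
* **Per-field summary.** Median cluster size is computed over all
  clusters *including singletons* by default (a flag restricts to
  multi-nucleus aggregates); median eccentricity is computed over
  isolated nuclei only, and is undefined (signalled) when no nucleus
  is isolated. One field contributes one summary value to downstream
  statistics.

## Ca²⁺ transients

The stimulation protocol (defaults: 1 s bursts at 10 Hz, every 10 s,
180 s total, 2 ms pulses as metadata) is treated as known, and the
analysis is stimulus-locked: burst onsets are taken from the protocol,
never detected from the trace. The time axis puts t = 0 at the first
burst onset; the pre-stimulus baseline lives at negative times.

* **Normalization.** F₀ is the mean raw fluorescence over the 5 s
  preceding the first onset (≥ 3 samples required; the window must not
  overlap stimulation). Normalization is idempotent.
* **Per-burst amplitude.** For burst k, amplitude = max(F/F₀) − 1 over
  [tₖ, tₖ + burst + 2 s], clipped at 0. The 2 s extension accommodates
  the decay-delayed maximum at ~3.3 Hz sampling. "Amplitude 0.5" thus
  means F/F₀ reaching 1.5; a cell is a **responder** when the *first*
  amplitude strictly exceeds 0.5 (an exact tie is a non-responder).
* **Decay time.** Time from the first-transient peak to the first
  crossing of 1 + A/e, linearly interpolated between samples; censored
  (NaN + flag) if no crossing occurs before the second burst. A
  monoexponential fit of τ is available as an alternative; both can be
  reported. For a true exponential the 1/e crossing equals τ, so the
  two definitions coincide on clean data.
* **Remaining Ca²⁺.** 100 × (last amplitude)/(first amplitude);
  undefined when the first amplitude is 0.

## AChR clusters and sarcomere spacing

AChR clusters come from a label mask; the retention rule is *strictly*
area > 5 μm². Per-field count, mean area, and per-myotube counts by
centroid membership are reported; a global-Otsu + connected-components
utility is provided for raw α-BTX images, as a convenience pre-step
only — it is not a validated segmentation procedure.

Sarcomere (z-line) spacing is estimated from a uniformly sampled line
profile as the lag of the highest positive-lag local maximum of the
autocorrelation of the mean-subtracted profile, refined by parabolic
interpolation; lags below 1 μm are excluded so the zero-lag lobe of a
single peak is never selected. Mean subtraction leaves a ramp
∝ (N − lag) under the correlation peaks whose slope biases the
parabolic vertex by a few hundredths of a μm at short periods; the DC
component above baseline (5th percentile) is added back before
refinement, which keeps the estimate offset- and scale-invariant and
holds the bias below 2% across periods of 1.5–4 μm at 0.1 μm sampling.
Estimates are rejected (signalled) when the correlation peak falls
below 0.2 × the zero-lag value (flat or aperiodic profiles) or when
fewer than 3 intensity peaks are detectable; the mean inter-peak
distance is returned as an independent cross-check.

## qPCR (geNorm)

Relative quantities Q = E^(Ct_cal − Ct) with amplification efficiency
E = 2 (the classic ΔΔCt assumption; per-gene efficiencies are rarely
reported) and calibrator = the gene's minimum Ct across samples
(mean-Ct calibrator available by option; fold changes are invariant to
the choice). The per-sample normalization factor is the geometric mean
of the housekeeping quantities — at least two housekeeping genes are
required, matching standard geNorm practice. Normalized quantities
Q/NF are averaged per condition and divided by the reference-condition
mean, so the reference fold is exactly 1. Missing Ct values drop the
gene–sample pair; nothing is imputed, and a missing housekeeping value
invalidates that sample's NF rather than silently skewing it. The full
geNorm stability ranking (M values) is provided as a diagnostic only:
the housekeeping set is fixed by assay design, not chosen post hoc.
A global per-sample Ct offset (pipetting/loading) cancels exactly in
Q/NF; this invariance is exercised in the tests.

## Statistics

Substrate comparisons of nuclei metrics use the Wilcoxon rank-sum test
on per-field medians: midranks for ties, tie-corrected variance,
normal approximation *without* continuity correction,
p = 2·(1 − Φ(|z|)). This mapping reproduces published worked examples
of the form z = 4.023 → p ≈ 5.75 × 10⁻⁵ and |z| = 7.384 → p ≈
1.54 × 10⁻¹³ (note that a z printed to 3 decimals pins p only to about
±0.2–0.4% relative). All other comparisons use the classical
equal-variance two-sample Student t test (Welch by flag), with
mean ± SEM as the descriptive summary. Stars: \*p<0.05, \*\*p<0.01,
\*\*\*p<0.001, \*\*\*\*p<0.00001, strict inequalities, so p = 0.05
earns no star. Degenerate inputs (all values identical) yield p = 1
with a flag instead of a division by zero.

The exhaustive-permutation rank-sum p (used as an oracle in the tests)
counts all C(N, n₁) group assignments whose rank-sum deviation from
the null mean is at least the observed one. Without continuity
correction the normal approximation tracks this exact p closely in the
strong-effect regime the assay operates in (published |z| ≈ 4–7.4),
but near z ≈ 0 the discreteness of the rank-sum distribution makes the
exact p larger than the approximation by up to ~0.08 even at 8 + 8
samples; agreement bounds are therefore stated, and tested, for
well-separated groups.

## Synthetic data: what it emulates, and what it does not

* **Nuclei fields** are non-overlapping filled ellipses rasterized on
  the pixel grid, placed in spatial clusters. Cluster sizes follow a
  user-supplied distribution; within a cluster, consecutive members
  are placed with border-to-border gaps below the 3 μm threshold
  (target 1 μm) while different clusters are kept ≥ 8 μm apart, so
  the planted partition is exactly recoverable and serves as ground
  truth. Eccentricities are drawn around a mean (default 0.70 ± 0.10,
  clipped to [0, 0.95]); orientations follow an axial von Mises
  distribution (concentration 0 = uniform, as on an unpatterned
  substrate; large = aligned with x, as on a striated one). Defaults —
  512² px at 0.32 μm/px (a 20× widefield regime), 60 nuclei, areas
  60–150 μm² — give uncrowded fields typical of day-4 myotube
  cultures. Placement is rejection sampling with a retry cap; an
  overfull field raises a placement error rather than degrading.
* **Traces** have an instantaneous rise at each burst onset (at 3.3 Hz
  sampling a ~100 ms physiological rise is unresolvable),
  monoexponential decay (default τ = 2 s, so the response fully
  recovers between bursts and inter-burst carry-over stays below 1%),
  log-linear amplitude run-down across bursts, and additive Gaussian
  noise. The sampling grid is aligned so burst onsets fall exactly on
  samples, making the noiseless first amplitude exactly recoverable.
* **AChR fields** are non-overlapping disks with prescribed target
  areas; the truth records the rasterized area of each blob.
* **Striation profiles** are Gaussian peak trains (default FWHM
  0.8 μm, 10 periods, 0.1 μm sampling) with exact peak spacing.
* **Ct tables** encode true fold changes as Ct shifts
  (−log_E fold) around per-gene baselines (18 housekeeping / 24
  target cycles), with optional per-sample global offsets and Gaussian
  Ct noise; noiseless tables invert exactly under the geNorm pipeline.

Not emulated: optics (PSF, shot noise, bleaching), 3-D structure,
segmentation errors (masks are perfect by construction), cell motion,
Ca²⁺ dye kinetics and saturation, or qPCR efficiency heterogeneity.
Passing tests therefore validate the *quantification* given correct
segmentation masks and calibrated recordings — not the upstream
segmentation or acquisition steps.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data at desk scale: 20–50 nuclei fields of 10–30 nuclei (384–512 px),
50–100 traces per sweep, cohorts of 40 cells, 3 replicates per qPCR
condition and 8 fields per substrate in the end-to-end comparison —
sizes at which the brute-force oracles (all-pairs boundary distances,
exhaustive rank-sum enumeration at 5–8 per group) remain exact and
fast.

## Known limitations

* Border-to-border distances are between boundary pixel centres, so
  the effective clustering threshold is quantized at the pixel size.
* The responder threshold tie (amplitude exactly 0.5) is assigned to
  non-responders by convention.
* The decay-time default (1/e crossing) and the monoexponential τ
  agree only when the decay is truly monoexponential.
* The centroid membership rule (fusion index, AChR-per-myotube) can
  misassign strongly concave objects whose centroid falls outside
  their own mask; such shapes do not occur in the generators.
* `genorm_stability` implements the pairwise-variation M measure but
  not stepwise gene exclusion; it is diagnostic only.
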