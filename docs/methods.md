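# Methods

`smadgrad` quantifies nuclear pSmad2 immunofluorescence gradients in
laterally imaged early zebrafish embryos. The measurement problem: Nodal
signaling activity is read out as per-nucleus nuclear pSmad2 intensity, and
its spatial profile must be expressed against a biologically meaningful 1D
coordinate — the distance of each nucleus from the blastoderm margin *along
the curved tissue*, not the straight line. The package implements the full
chain (segmentation → tissue contour → margin distances → gradient metrics)
plus a synthetic-stack generator with exact ground truth so that every stage
is validated by parameter recovery, without any external image data.

## The synthetic embryo

The specimen is idealized as a spherical-cap shell of nuclei: a sphere of
radius `R` (default 300 µm) carries nuclei in a shell of thickness 40 µm
below its surface, over polar angles 0 (animal pole) to `φ_max` (the margin
rim; `π/2` corresponds to a blastoderm covering half the sphere, i.e. 50%
epiboly). Nucleus centers (default n = 800, radius r = 4 µm) are sampled
uniformly over the shell volume with rejection sampling enforcing a 2r
center separation. Each nucleus's true margin distance is the great-circle
arc `d_true = R·(φ_max − φ)`, and its true pSmad2 intensity is

    I(d) = b + A·exp(−d/λ)

with defaults A = 100 a.u., λ = 80 µm, b = 10 a.u. The exponential form is
the package's metric convention for "amplitude" and "range"; it is a
simulator choice, not a biological claim (in particular, whether the real
profile plateaus at the margin is not modeled).

Mounting is lateral: the animal–vegetal axis lies in the imaging plane and
the rendered raster is a slab of z-planes (default ±30 µm, 2 µm spacing →
31 slices) centered on the mid-sagittal plane, which is the configuration
in which the entire gradient is sampled within single slices. Depth for
attenuation is measured from the first rendered plane; the constant
attenuation accumulated above the slab is a multiplicative factor absorbed
into the amplitude and irrelevant to recovery. The ground-truth table
records **all** placed nuclei with an `in_stack` flag; only in-slab nuclei
are rasterized.

Rendering, per nucleus: a 3D Gaussian blob (σ_xy = √((r/2)² + psf_xy²) ≈
2.06 µm, σ_z ≈ 2.5 µm) **truncated at the spherical nuclear envelope** of
radius r. Truncation keeps each cross-section's support exactly
π(r² − dz²), so "which (nucleus, slice) pairs should a perfect segmentation
report" is well defined — the out-of-focus haze that real confocal stacks
show is carried instead by the explicit bleed term below. Channel 0
(nuclear stain) renders every nucleus at a common brightness C = 100 a.u.;
channel 1 at its I(d).

Artifacts, in fixed order (signal degradations before detection noise):

1. **Attenuation** — each slice is scaled by `exp(−depth/τ)`, τ = 150 µm
   (light scattering; ~33% loss across the default slab).
2. **Bleed-through** — `slice_i += β·(slice_{i−1} + slice_{i+1})`,
   β = 0.15 (out-of-plane signal; nearest neighbors only, mirroring the
   one-neighbor background model the segmentation inverts).
3. **Poisson noise** at `photon_scale` = 2 photons per intensity unit
   (≈7% shot noise at the margin amplitude), then **Gaussian read noise**,
   s.d. 2 a.u.

All outputs are pure functions of (parameters, seed). What the generator
does **not** emulate: realistic nuclear texture and shape variation,
touching/overlapping nuclei, EVL vs deep-cell differences, cell movement,
a structured (autofluorescent) background, or a physical PSF model
(Richards–Wolf, refractive-index mismatch). Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
artifact model, not segmentation robustness on arbitrary real data — on
real stacks the manual-corrections hook and the exposed thresholds matter.

## Segmentation (2D, per slice)

1. **Out-of-plane background**: for slice i the background is
   `G_σ(slice_{i−1}) + G_σ(slice_{i+1})` (Gaussian blur, σ = 5 px); it is
   subtracted and clamped at zero. Edge slices use their single neighbor;
   single-slice stacks pass through. Blurring a constant stack returns the
   constant exactly, so a uniform stack subtracts to exactly zero — a
   useful analytic test case.
2. **Adaptive threshold**: foreground where
   `pixel > local_mean(31 px window, reflective borders) + offset`. The
   offset defaults to `3.0 × σ_noise`, floored at 1.0 a.u., where σ_noise
   is estimated per slice from the 75th percentile of the subtracted image
   divided by 0.6745: after clamping, more than half the background pixels
   are exactly zero (a plain MAD collapses), while for zero-mean noise
   clamped at zero the upper quartile equals the half-normal 0.6745·σ. A
   multiplier of ~0.5, sometimes suggested for adaptive offsets, admits a
   fifth of the background at this noise level and floods the size filter
   with percolation clusters (measured precision 0.41); 3σ reduces the
   per-slice false-pixel count to O(100) scattered pixels that cannot form
   filter-passing clusters.
3. **Size filter**: 8-connected components outside [25, 200] px are
   discarded; surviving labels are renumbered 1..K in raster order of each
   component's first pixel (exactly reproducible by flood fill).
4. **Measurement**: per label, unweighted pixel centroid (µm) and the mean
   of its pixels in each **raw** channel. Subtraction only shapes the
   segmentation image; measured intensities are raw by default
   (configurable).

Segmentation is deliberately 2D: a nucleus crossing several planes yields
several records, and the evaluation defines per-slice truth as the nuclei
whose rasterized cross-section passes the size filter. The interactive
"manual checking" step of a human workflow is replaced by a
machine-readable corrections mapping (per-slice keep/drop of labels).

## Contour and margin distances

1. **Slice selection**: the quantified records come from the ten z-slices
   around the center slice k. The argmax-of-counts rule (ties to the lower
   index) is implemented, but for a spherical shell the per-slab nucleus
   count is *constant* in z (Archimedes' hat-box theorem), so counting
   cannot locate the mid-plane better than noise; simulated runs therefore
   pin k to the known mid-plane slice, and k is config-pinnable for real
   data.
2. **Projection**: centroids of all slices are projected to one plane
   (z discarded). Using all slices (≈90 distinct nuclei at default
   density) rather than only the central ten (≈36) matters: margin
   anchoring degrades visibly below ~50 points.
3. **Hull and margins**: the convex hull of the cloud is the embryo
   outline (also rasterized as the embryo mask). Margin corners are the
   two highest-curvature hull vertices subject to a perimeter separation
   of ≥ 20%. Two curvature estimators are provided: the per-vertex
   exterior turning angle divided by the mean adjacent edge length
   (`curvature_window_um = 0`), and a perimeter-windowed net turning
   (default window 40 µm in the pipeline) that cancels the alternating
   short-edge jitter of sparse hulls while preserving a true corner's
   full turn. Additionally, when the hull has a single dominant edge —
   the straight margin-to-margin closure that any crescent-shaped tissue
   cloud produces across the nucleus-free yolk side (gated at ≥ 20% of
   perimeter and ≥ 1.5× the runner-up edge) — its endpoints are taken as
   the margin corners directly: they are by construction the outermost
   sampled nuclei at each rim, which pure curvature ranking can miss by a
   vertex or two on sparse corners. Ties: maximal Euclidean separation,
   then lexicographic (x, y); left/right by x.
4. **Valley trace**: the contour is the minimal-cost 8-connected path
   between the margin corners with per-step cost
   `step_length × (D_max − mean(D_u, D_v) + ε)`, `ε = 1e−6·D_max`, where
   D is the Euclidean distance transform of a binary mask — i.e. the path
   hugs the ridge of D (the valley of its negation). The pipeline traces
   on the **tissue band** (the centroid raster dilated by a disk whose
   radius is auto-laddered 30–100 µm until the margins connect), not on
   the filled hull: the hull of a crescent section is a half-disk whose
   interior medial path cuts through the yolk and, measured on the
   default geometry, misestimates margin distances with a median error of
   ~2× the benchmark tolerance near the pole. The band's ridge is the
   mid-shell arc. Dijkstra (scipy csgraph) guarantees the exact optimum;
   the path cost is verified against an independent Bellman-Ford oracle
   on the identical cost graph.
5. **Smoothing**: the rough path is resampled to 1 px arc spacing and
   x(s), y(s) are Savitzky–Golay filtered (window min(51, len/5) rounded
   odd, polyorder 3 — exact on polynomials up to cubic, so straight
   segments are preserved to machine precision); endpoints are re-pinned.
6. **Distances**: each record is orthogonally projected onto the polyline
   (ties toward smaller arc position); the margin distance is
   `min(s*, L − s*)` ∈ [0, L/2], pooling left and right margins.

Margin distances are measured along the mid-shell contour while the
simulator's `d_true` is the arc at the outer sphere radius; this imposes a
~7% systematic scale compression (280/300), well inside the benchmark
tolerances, plus a zero-point offset at each margin equal to the rim
sampling gap (expected ~10 µm at default density).

## Gradient metrics

Fits use per-nucleus records, not binned means; the binned profile
(default 20 µm bins from zero, per-bin mean/s.d./count, empty bins
reported) is a presentation layer. The model `I(d) = b + A·exp(−d/λ)` is
fitted by bounded least squares (A, b ≥ 0; λ ∈ (0, 10·max d]; trust-region
reflective, tolerances 1e−12) with data-driven initialization (b₀ = min
bin mean; A₀ = range of bin means; λ₀ = half-decay distance / ln 2).
Constant data converge to A ≈ 0 with the `amplitude-null` flag (λ is then
unidentifiable and must not be interpreted); non-convergence withholds
parameters. Preconditions: ≥ 10 records spanning ≥ 3 distance bins.

Intensity normalization options: `none` (default; raw pSmad2 means),
`embryo_median` (divide by the embryo's median nuclear-channel mean), and
`nuclear_ratio` — replace each record's pSmad2 mean by
`scale × mean_psmad2 / mean_nuclear`. Because both channels are measured
over the same label pixels and share the blob profile, depth attenuation
and bleed geometry, the per-record ratio cancels those factors; with
`scale` set to the nuclear-channel brightness (known in simulation) it is
a calibrated absolute estimate, and it is the estimator used for recovery
benchmarks. Without it, fitted amplitudes are compressed several-fold by
blob-pixel averaging and depth attenuation — a scale factor that cancels
in between-condition ratios but not against absolute truth.

Conditions are compared per embryo (the embryo, not the nucleus, is the
unit of replication): point estimates are ratios of across-embryo median
A and median λ, with percentile bootstrap CIs (default 1000 resamples,
95%) resampling embryos with replacement within each condition,
deterministic given the seed.

Two caveats on absolute amplitude recovery. First, the contour's zero
point sits at the outermost sampled nucleus, not the true rim, so
end-to-end fitted amplitudes carry a bias factor `exp(−d₀/λ)` with d₀ the
rim sampling gap — typically 10–25 µm (5–25% of A) at default density.
The recovery benchmark therefore fits calibrated measured intensities
against true distances (validating rendering → segmentation → measurement
→ fitting), while contour fidelity is benchmarked separately on the
distances themselves and the *directional* two-condition comparison runs
fully end-to-end, where the bias largely cancels between conditions.
Second, all absolute statements assume the nuclear-channel brightness is
actually uniform across nuclei.

## Reproducibility and I/O

Every run writes one output directory (never silently overwritten):
per-embryo stacks (multi-page TIFF, interleaved ZC pages, calibration as
JSON in the ImageDescription tag), ground truth and records and contour
and profile CSVs, the per-embryo fit table, the comparison CSV, a
Fig-style profile plot, the fully resolved configuration (YAML), and a
manifest (version, timestamp, input checksums, per-stage counts,
warnings) written atomically. Configuration is schema-validated
(unknown keys rejected); explicit calibration overrides file metadata
with a recorded warning. All randomness derives from the configured seed
through `numpy.random.SeedSequence` spawning; two runs with identical
configuration produce byte-identical CSVs. Exit codes of the CLI:
0 success, 1 usage/config, 2 data, 3 internal.

## Benchmark problem sizes

The test suite and the acceptance script use the default embryo
(R = 300 µm, 800 nuclei, 31-slice slab, ≈90 rendered nuclei, ≈215
cross-section records) for five seeds per property, a compact embryo
(R = 100 µm, 250 nuclei) for unit tests and the ≤256² oracle masks, and
5 + 5 embryos for the two-condition comparison. On one CPU a full default
embryo takes ≈3 s through segmentation and ≈6 s through the contour and
fit; the complete acceptance script runs in under two minutes.

## Known limitations

- No watershed splitting: touching nuclei would merge (the generator's
  2r separation plus envelope truncation makes overlap impossible in
  simulation; real data are not so kind).
- No 3D linking of cross-sections; multiplicity is handled statistically.
- The tissue-band contour requires the margin corners to be connected
  through the cloud; a cloud with a genuine gap wider than the dilation
  ladder fails loudly rather than guessing.
- Only the laterally mounted geometry is quantified; animal-pole-mounted
  (sphere-stage) stacks would need a radial coordinate scheme that is out
  of scope.
- λ is reported per embryo without small-sample bias correction; with
  ~150 records per embryo the fit noise (±3%) dominates any such bias.
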