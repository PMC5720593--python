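# smadgrad

Quantification of nuclear pSmad2 signaling gradients in laterally imaged
early zebrafish embryos — nuclear segmentation, curved-contour margin
distances, and gradient amplitude/range metrics — together with a
synthetic confocal-stack generator that makes every stage verifiable by
parameter recovery.

## The problem

Nodal signaling activity in the early embryo is read out as the nuclear
intensity of phosphorylated Smad2 (pSmad2) immunostaining. The signal
forms a gradient emanating from the blastoderm margin, so the meaningful
spatial coordinate for each nucleus is its distance from the margin
measured *along the curved tissue*, not the straight line. Given a
two-channel confocal stack (channel 0: nuclear stain such as Sytox;
channel 1: pSmad2), the pipeline:

1. **Segments nuclei per z-slice**: out-of-plane background (the
   Gaussian-blurred sum of the two adjacent slices) is subtracted, nuclei
   are found by adaptive (local-mean + offset) thresholding, spurious
   objects are removed by size, and each nucleus cross-section's mean raw
   intensity is measured in both channels.
2. **Builds the embryo contour**: all segmented centroids are projected
   to one plane; the convex hull's two maximum-curvature vertices are the
   left and right margins; a minimal-cost path along the ridge of the
   distance transform of the nucleated tissue band traces the contour,
   which is smoothed with a Savitzky–Golay filter.
3. **Assigns margin distances**: each nucleus is projected onto the
   contour; its distance is the arc length to the closer margin.
4. **Quantifies the gradient**: per-nucleus intensity versus distance is
   summarized by a bounded least-squares fit of

       I(d) = b + A·exp(−d/λ)

   where A is the gradient **amplitude** (peak above baseline at the
   margin, a.u.), λ the **range** (decay length, µm) and b the baseline.
   Conditions (e.g. wild-type vs feedback-inhibitor mutants) are compared
   by ratios of across-embryo median A and λ with bootstrap confidence
   intervals (embryo = unit of replication).

Because raw image data for this kind of experiment are rarely published,
the package ships a first-class simulator (`smadgrad.synthetic`): a
spherical-cap shell of nuclei with a known exponential gradient, rendered
with depth attenuation, inter-slice bleed-through, and Poisson + read
noise, plus an exact ground-truth table. See `docs/methods.md` for the
model and all conventions.

## Worked example

`examples/` contains one narrative script per capability. Generating a
default synthetic embryo, segmenting it and fitting its gradient
(`examples/02_segment_nuclei.py`, `examples/04_fit_gradient.py`) prints:

```
records (nucleus cross-sections): 214 across 31 slices
detection vs truth (Hungarian match, 2 µm radius): F1=0.998  precision=1.000  recall=0.995

contour length L = 878 µm (true mid-shell arc is ~880 µm)
matched nuclei: 62; median |assigned - true| = 31.7 µm (3.6% of L); Spearman rho = 0.998

fit:   A = 78.4 a.u.   lambda = 73.2 µm   b = 10.3 a.u.
truth: A = 100.0 a.u.   lambda = 80.0 µm   b = 10.0 a.u.
```

F1 near 1 means essentially every sufficiently large nucleus
cross-section is found exactly once; the contour length and distance
fidelity show the 1D margin coordinate tracks the true geodesic; the
fitted decay length recovers the simulated range (the amplitude reads
slightly low because the measured contour starts at the outermost sampled
nucleus, a few tens of µm inside the true rim — see `docs/methods.md`).
The two-condition comparison (`examples/05_compare_conditions.py`) on
five wild-type-like (A=100, λ=80) vs five mutant-like (A=180, λ=130)
embryos prints:

```
amplitude ratio (mutant/wildtype):    1.86 [95% CI 1.52-2.92]
decay-length ratio (mutant/wildtype): 1.71 [95% CI 1.25-1.87]
```

— the mutant-like condition has a higher-amplitude, longer-ranged
gradient, with confidence intervals excluding 1.

## Command line

A thin CLI wraps the library for batch use:

```bash
smadgrad run --config run.yaml --out results/run1    # full pipeline
smadgrad simulate --out stacks/ --seed 5             # stacks + truth only
smadgrad segment stack.tif --out records.csv
smadgrad contour records.csv --out annotated.csv --contour-out contour.csv
smadgrad quantify annotated.csv --out profile.csv
smadgrad compare fits.csv --cond1 wildtype --cond2 mutant
```

Configuration is a schema-validated YAML/JSON file (unknown keys
rejected); every run writes its fully resolved configuration and a
manifest sufficient to reproduce it bit-identically.

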