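# Methods

## Measurement model

A lamella fragment is treated as a noisy raster observation of an underlying
smooth planar curve. The waviness ratio `r_ec` compares two length
functionals of the same polygonal reconstruction of that curve:

- **geodesic-like length** `L_g`: the sum of Euclidean distances between
  consecutive polyline vertices — an estimate of the curvilinear (true arc)
  length;
- **Euclidean-like length** `L_e`: the sum of chords between points marked
  every `step = 100` px of geodesic length along the polyline — an estimate
  of the end-to-end span that is robust to very long fragments bending
  back on themselves. For `L_g < step` the single first-to-last chord is
  used; for `step ≤ L_g < 2·step`, two chords through the vertex nearest
  half the geodesic length (ties to the earlier vertex). In the walking
  regime the final vertex is always a mark, so no trailing stretch of curve
  is silently dropped.

`r_ec = L_e / L_g ∈ (0, 1]` up to float error; 1 means straight. The
shortfall `1 − r_ec` is the fragment's relative reserve length.

The polyline itself comes from the skeleton of the fragment: every *s*-th
pixel of the skeleton's longest path is selected (the last pixel is always
retained) and `s − 1` equally spaced vertices are interpolated back into
each gap, so the polyline has exactly as many vertices as the path had
pixels. Subsampling at `s = 3` (the default) removes the pixel-staircase
bias that would otherwise inflate `L_g` by several percent; oversampling
restores the vertex budget so the 100-px marking grid is equally dense for
every `s`.

## Extraction parameters

| parameter | default | meaning |
|---|---|---|
| `otsu_factor` | 2.0 | threshold = factor × Otsu threshold of the slice |
| `min_area` | 100 px | keep rule 1: area ≥ min_area (inclusive) |
| `max_bbox_occupancy` | 0.15 | keep rule 2: area / bbox area < 0.15 (strict) |
| `max_solidity` | 0.36 | keep rule 3: area / convex-hull area < 0.36 (strict) |
| `connectivity` | 8 | component adjacency; thin oblique curves fragment under 4 |
| `s` | 3 | sampling factor of the polyline scheme |
| `step` | 100 px | geodesic mark spacing of the Euclidean-like length |

Inequality senses follow the rule wording (area "above or equal", the two
ratios "below"/"less than"). The Otsu threshold is computed on a 256-bin
histogram of the slice after min–max rescaling to [0, 255]; this fixes a
binning convention for float input. A rejected region is attributed to the
*first* rule it violates, in the order area → occupancy → solidity; the
per-rule rejection counts in the run manifest use this attribution.

Note a structural consequence of the filters: a perfectly straight stroke
has solidity ≈ 1 and axis-aligned bounding-box occupancy ≈ 1, so the keep
rules — designed for wavy curves — reject it. Identity checks on straight
strokes (`r_ec = 1`) therefore run the measurement chain with
`apply_filters=False`; the filters are a fragment *selection* step, not
part of the length measurement.

## Skeleton and longest path

Thinning uses a standard topology-preserving 2D skeletonization. Holes are
filled before thinning: a lamella cross-section is a solid stroke, so any
hole in the thresholded mask is a noise artifact and would otherwise become
a spurious skeleton loop. The longest simple path of the skeleton's
8-adjacency pixel graph is found

- by exhaustive DFS for graphs of ≤ 24 pixels,
- exactly by best-leaf-pair search for trees,
- after removal of redundant diagonal shortcut edges (a diagonal edge whose
  endpoints also share an orthogonal neighbor — corner triangles of
  8-connectivity) for larger graphs, which in practice turns skeletons into
  trees, and
- by branch-graph enumeration with partial corridor extensions, or a
  double-sweep heuristic, for the rare remaining cyclic cases.

Ties are broken toward the lexicographically smallest start pixel, so
repeated runs return identical paths. A pure cycle (no endpoints) is opened
at its lexicographically smallest pixel. Fragments whose skeleton collapses
to a single pixel are skipped with a logged reason.

## Synthetic generator

Curves are parameterized along a chord axis (sinusoids `y = A sin(2πt/λ +
φ)`, circular arcs by chord and sagitta, straight segments) then rotated
and translated; arc length comes from closed form or adaptive quadrature,
and the *step-rule* truth `true_rec_step` applies the same 100-px chord
rule to a dense (~4 points/px) analytic sampling, so recovery tests compare
like with like. The plain chord/arc ratio is stored alongside as
`true_rec_chord`.

Rendering stamps a disc of the stroke thickness (default 3 px) along a
dense sampling of the curve, guaranteeing an 8-connected solid stroke, then
adds distractors and i.i.d. Gaussian noise (default sd 10 on an 8-bit
scale). Foreground/background default to 220/30: with the sparse
foreground of a lamella slice, 2× the Otsu threshold then sits comfortably
between background and stroke level across noise realizations, keeping the
thresholding rule well-posed. Each distractor kind is built to trip exactly
one filter under the first-violation attribution: specks (area < 100 px),
dense crosshatch patches (occupancy ≈ 0.44), and tilted eccentric solid
ellipses (solidity > 0.9 with occupancy ≈ 0.12, so the solidity rule — not
the occupancy rule — fires).

Two-cohort datasets mimic the study design: 10 "control" vs 11 "diabetic"
stacks, cohort effect injected through the amplitude distribution only
(wavelength held common). Cohort mean amplitudes are solved by root
bracketing so the *true* step-rule ratios sit at 0.823 (control) and 0.889
(diabetic) — a 0.066 gap; per-curve amplitudes get sd 1.5 px, orientations
and phases are uniform, and placement is greedy non-overlapping with
per-stack/per-slice seeds spawned deterministically from the cohort seed.
The default study canvas is 512² with 300 px baselines; a reduced variant
(224², 130 px baselines, 2 slices × 3 curves per stack) is used for
Monte-Carlo calibration studies, with the same pinned target ratios.

What the generator does **not** emulate: phase-contrast edge artifacts and
reconstruction ringing, intensity gradients across the wall, touching or
branching lamellae, non-sinusoidal waviness spectra, and 3D continuity of
lamellae across slices. Passing tests therefore validate the measurement
chain and its statistics on well-posed curvilinear input, not robustness to
every artifact of real tomograms.

## Statistics

The statistical unit is the per-stack mean `r_ec` (one value per stack;
fragments within a stack are strongly correlated, and fragment-level
testing with n ~ 10⁵ would declare any difference significant). Groups are
compared with the two-sided Mann–Whitney–Wilcoxon rank-sum test using the
tie-corrected normal approximation with continuity correction (equivalent
to R's `wilcox.test(correct = TRUE)`); for small tie-free samples the exact
permutation p-value is reported alongside. Shapiro–Wilk p-values per group
are diagnostic output only and never gate the main test. No
multiple-testing correction is applied across the regional scopes (all /
arch / thoracic / abdominal); the report says so.

Calibration of the full pipeline (generate → render → extract → measure →
test), at the reduced rendering size for runtime: the type-I error over 200
null datasets is ~0.045 against the exact value 0.043 of the
continuity-corrected rule at n = 10/11, and power at the 0.066 gap exceeds
0.99. The cohort verdict is unchanged for s ∈ {1, 2, 3}.

## Numerical notes and known limitations

- Skeleton end-trimming (~2–4 px per end) shifts the 100-px chord marks
  relative to the wave phase. When the wavelength nearly divides the step
  (e.g. λ ≈ 110 vs step 100) this resonance moves `r_ec` by up to ~0.02;
  away from resonance the orientation spread of repeated measurements is
  ≤ 0.005. Recovery tolerances of ±0.03 absorb this.
- Measured per-stack means sit ~0.01 below the analytic targets (staircase
  and trimming bias); the bias is common to both cohorts and cancels in the
  gap.
- `subsample_oversample` falls back to `s = 1` for paths shorter than
  `s + 1` pixels; zero-length polylines and single-pixel skeletons are
  skipped, with logged reasons, rather than producing NaNs.
- The exact longest path is guaranteed for trees and small graphs; for
  large cyclic skeletons the branch-graph search with corridor extensions
  is exact in all configurations we generate but falls back to a
  double-sweep heuristic beyond 20 branch nodes.
- Lengths are reported in pixels; `pixel_size` (µm/px, default 0.65) is
  carried in stack metadata and the run manifest for unit conversion but
  never enters `r_ec`, which is dimensionless.
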