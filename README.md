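# wavimetry

Quantification of elastic-lamella waviness in grayscale tomographic image
stacks of the arterial wall, with a fully ground-truthed synthetic data
generator and a nonparametric two-cohort comparison.

## The problem

Elastic lamellae — the concentric elastin sheets of the aortic media —
appear in high-resolution micro-CT cross-sections as bright, thin, wavy
curves. Their waviness is functional: the excess curvilinear length of a
wavy lamella over its end-to-end span (its *reserve length*) is the slack
the vessel wall can recruit when it stretches. Pathologies such as type-2
diabetes are associated with visibly *smoother* lamellae, i.e. a loss of
reserve length.

`wavimetry` measures this with the arc–chord ratio

```
r_ec = Euclidean-like length / geodesic-like length
```

of each lamella fragment: `r_ec = 1` for a perfectly straight fragment,
`r_ec < 1` for a wavy one. Per slice, the pipeline

1. thresholds at a configurable multiple (default 2×) of the Otsu threshold,
2. labels connected bright regions and keeps those that look like lamella
   fragments (area ≥ 100 px, bounding-box occupancy < 15 %, solidity < 36 %),
3. thins each kept fragment to a skeleton and keeps only the longest simple
   path of its pixel-adjacency graph,
4. subsamples the path at every *s*-th pixel (default *s* = 3) and
   re-oversamples it to the original vertex count — the *geodesic-like
   length* is the vertex-to-vertex sum, the *Euclidean-like length* is the
   chord sum between points spaced 100 px of geodesic length apart (with
   one- and two-chord fallbacks for short fragments), and
5. aggregates `r_ec` per stack and compares two cohorts of per-stack means
   with the two-sided Mann–Whitney–Wilcoxon rank-sum test with continuity
   correction (Shapiro–Wilk normality p-values reported as a diagnostic).

Because real synchrotron volumes are huge and not publicly archived, the
package ships a first-class synthetic generator: parametric curves
(sinusoids, arcs, straight strokes) with closed-form or quadrature ground
truth, rendered into noisy slices alongside distractor objects that are each
designed to trip exactly one of the three filters.

## Worked example

Measure one wavy stroke against its analytic truth:

```python
import wavimetry as wm

spec = wm.CurveSpec("sinusoid", baseline_length=300, amplitude=15, wavelength=100)
image, truth, _ = wm.render_single_curve(spec, wm.RenderSpec(noise_sd=0))
records, _ = wm.measure_slice(image, wm.ExtractionParams(), apply_filters=False)
rec = records[0]
print(f"geodesic-like length: {rec.geodesic_like:.1f} px")
print(f"euclidean-like length: {rec.euclid_like:.1f} px")
print(f"r_ec measured: {rec.r_ec:.3f}  (analytic step-rule truth: {truth.true_rec_step:.3f})")
```

prints

```
geodesic-like length: 359.7 px
euclidean-like length: 301.8 px
r_ec measured: 0.839  (analytic step-rule truth: 0.842)
```

— the rendered 300 px stroke carries ~60 px of reserve length, and the
measured ratio recovers the analytic value to 0.003.

The full pipeline runs from the shell. `wavimetry all` simulates a
two-cohort study (10 wavy-control vs 11 smooth-diabetic stacks whose true
mean ratios are pinned at 0.823 and 0.889), measures every stack and
compares the groups:

```sh
wavimetry all --out-dir run --seed 1
```

reports, for the `all` scope (a JSON report is also written to
`run/report.json`):

```
n_a 10   mean_a 0.807   sd_a 0.007      # control: wavier, lower r_ec
n_b 11   mean_b 0.881   sd_b 0.008      # diabetic: smoother, higher r_ec
U 0.0    p_value 1.2e-4                 # rank-sum, two-sided
```

The control cohort loses ~0.07 of ratio to waviness and the rank-sum test
detects the difference decisively. Subcommands `simulate`, `measure` and
`compare` run the stages separately on multi-page TIFF stacks and CSV
tables; see `wavimetry --help`.

## Layout

- `src/wavimetry/synthetic.py` — curve specs, analytic truth, rendering, cohorts
- `src/wavimetry/extraction.py` — thresholding, labeling, the three filters
- `src/wavimetry/geometry.py` — skeleton, longest path, sampling, `r_ec`
- `src/wavimetry/stats.py` — per-stack aggregation, rank-sum, Shapiro–Wilk
- `src/wavimetry/pipeline.py` — TIFF/CSV/JSON batch orchestration
- `src/wavimetry/cli.py` — `wavimetry simulate | measure | compare | all`
- `docs/methods.md` — model, parameter and design notes
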