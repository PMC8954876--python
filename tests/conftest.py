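"""Shared fixtures and scene builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import wavimetry as wm


@pytest.fixture
def extraction_params():
    return wm.ExtractionParams()


def measure_one_curve(spec: wm.CurveSpec, noise_sd: float = 0.0,
                      s: int = 3, apply_filters: bool = False):
    """Render one curve on a tight canvas and push it through threshold,
    labeling, skeleton, longest path, sampling and the length measurements.

    Returns ``(record, truth)``; fails the calling test if the curve did not
    survive as exactly one region.
    """
    render = wm.RenderSpec(noise_sd=noise_sd)
    image, truth, _ = wm.render_single_curve(spec, render)
    records, _ = wm.measure_slice(image, wm.ExtractionParams(),
                                  s=s, apply_filters=apply_filters)
    assert len(records) == 1, f"expected 1 measured fragment, got {len(records)}"
    return records[0], truth


def fidelity_scene(seed: int):
    """Five lamella strokes in horizontal strips plus one distractor of each
    kind, positioned so no two objects can touch.

    Returns ``(image, distractor_specs)``.
    """
    rng = np.random.default_rng(seed)
    curves = []
    for k in range(5):
        amp = float(rng.uniform(12, 18))
        curves.append(wm.CurveSpec(
            "sinusoid", 280, amplitude=amp,
            wavelength=float(rng.uniform(100, 130)),
            phase=float(rng.uniform(0, 2 * np.pi)),
            orientation=float(rng.uniform(-0.05, 0.05)),
            origin=(float(rng.uniform(20, 130)), 30 + 100 * k + amp)))
    distractors = (wm.DistractorSpec("speck", 6.0, (480.0, 60.0)),
                   wm.DistractorSpec("solid_blob", 80.0, (455.0, 250.0)),
                   wm.DistractorSpec("dense_texture", 48.0, (475.0, 450.0)))
    render = wm.RenderSpec(image_shape=(512, 512), distractors=distractors,
                           seed=seed)
    image, _ = wm.render_slice(curves, render)
    return image, distractors


def measure_dataset(stacks, params=None, s: int = 3):
    """Measure every slice of every stack; returns per-stack summaries."""
    params = params or wm.ExtractionParams()
    summaries = []
    for st in stacks:
        records = []
        for zi, img in enumerate(st.slices):
            recs, _ = wm.measure_slice(img, params, s=s, slice_index=zi,
                                       stack_id=st.stack_id)
            records.extend(recs)
        summaries.append(wm.summarize_stack(
            records, group_label=st.group_label, region_label=st.region_label))
    return summaries
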