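"""Batch orchestration: simulate → extract → measure → compare.

Reads multi-page grayscale (or pre-binarized) TIFF stacks, runs per-slice
fragment extraction and waviness measurement, and writes a measurements CSV
plus a JSON run manifest that fully serializes the parameters needed to
reproduce the run.  The compare step consumes the measurements CSV and a
stack metadata CSV and emits one cohort comparison per requested regional
scope as JSON.

Conventions: (row, col) pixel coordinates, 0-based, pixel centers at integer
coordinates; lengths in pixels (``pixel_size`` recorded in the manifest for
micrometre conversion downstream); CSV is comma-separated UTF-8 with a
header row and '.' decimals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .extraction import ExtractionParams, ImageStack
from .geometry import DEFAULT_S, DEFAULT_STEP, WavinessRecord, measure_fragment
from .stats import REGION_SCOPES, compare_cohorts, summarize_stacks

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["stack_id", "slice", "region", "area",
                       "geodesic_like", "euclid_like", "r_ec", "s"]


@dataclass
class RunConfig:
    """Everything a measurement run needs; serialized into the manifest."""

    inputs: list[str] = field(default_factory=list)   # TIFF stack paths
    params: ExtractionParams = field(default_factory=ExtractionParams)
    s: int = DEFAULT_S
    step: float = DEFAULT_STEP
    slice_range: tuple[int, int, int] | None = None   # (start, stop, stride)
    binary_input: bool = False
    apply_filters: bool = True
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"


def read_stack(path: str | Path, pixel_size: float = 0.65) -> ImageStack:
    """Load a multi-page TIFF as an :class:`ImageStack`."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as err:
        raise ValueError(f"cannot read TIFF stack {path}: {err}") from err
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2D grayscale pages, "
                         f"got shape {data.shape}")
    return ImageStack(slices=list(data), pixel_size=pixel_size,
                      stack_id=path.stem)


def measure_slice(image: np.ndarray, params: ExtractionParams,
                  s: int = DEFAULT_S, step: float = DEFAULT_STEP,
                  slice_index: int = 0, stack_id: str = "stack",
                  binary_input: bool = False, apply_filters: bool = True,
                  ) -> tuple[list[WavinessRecord], dict[str, int]]:
    """Extract and measure one slice; returns records and rejection counts."""
    from .extraction import filter_fragments, label_fragments, threshold_slice

    binary = (np.asarray(image) > 0 if binary_input
              else threshold_slice(image, params))
    all_regions = label_fragments(binary, params, slice_index=slice_index)
    result = filter_fragments(all_regions, params)
    regions = result.kept if apply_filters else all_regions
    records = []
    for region in regions:
        rec = measure_fragment(region, s=s, step=step, stack_id=stack_id)
        if rec is not None:
            records.append(rec)
    return records, result.rejection_counts


def measure_stack(stack: ImageStack, config: RunConfig,
                  ) -> tuple[pd.DataFrame, list[dict]]:
    """Measure every selected slice of one stack."""
    n = len(stack.slices)
    if config.slice_range is None:
        indices = range(n)
    else:
        start, stop, stride = config.slice_range
        if not (0 <= start <= n and stop <= n):
            raise ValueError(
                f"slice_range {config.slice_range} outside stack of {n} slices")
        indices = range(start, stop, stride)
    rows, slice_log = [], []
    for zi in indices:
        records, rejected = measure_slice(
            stack.slices[zi], config.params, s=config.s, step=config.step,
            slice_index=zi, stack_id=stack.stack_id,
            binary_input=config.binary_input,
            apply_filters=config.apply_filters)
        slice_log.append({"stack_id": stack.stack_id, "slice": zi,
                          "kept": len(records), "rejected": rejected})
        for r in records:
            rows.append({"stack_id": r.stack_id, "slice": r.slice_index,
                         "region": r.region_id, "area": r.area,
                         "geodesic_like": r.geodesic_like,
                         "euclid_like": r.euclid_like,
                         "r_ec": r.r_ec, "s": r.s})
        if (zi + 1) % 100 == 0:
            log.info("%s: processed %d slices", stack.stack_id, zi + 1)
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS), slice_log


def run_measure(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Measure all configured stacks; write measurements.csv and manifest.json.

    Returns the measurements table and the manifest.  Completes with a
    warning (not an error) when no fragment survives filtering anywhere.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames, slice_logs = [], []
    for path in config.inputs:
        stack = read_stack(path)
        df, slog = measure_stack(stack, config)
        frames.append(df)
        slice_logs.extend(slog)
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=MEASUREMENT_COLUMNS))
    if table.empty:
        log.warning("no fragments kept in any input stack")
    manifest = {
        "software_version": __version__,
        "seed": config.seed,
        "inputs": [str(p) for p in config.inputs],
        "params": dataclasses.asdict(config.params),
        "s": config.s,
        "step": config.step,
        "slice_range": config.slice_range,
        "binary_input": config.binary_input,
        "apply_filters": config.apply_filters,
        "n_fragments": int(len(table)),
        "per_slice": slice_logs,
    }
    table.to_csv(out / "measurements.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return table, manifest


def run_compare(measurements: str | Path | pd.DataFrame,
                metadata: str | Path | pd.DataFrame,
                scopes: list[str] | None = None,
                out_path: str | Path | None = None) -> dict:
    """Per-stack aggregation plus one cohort comparison per scope."""
    if not isinstance(measurements, pd.DataFrame):
        measurements = pd.read_csv(measurements)
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata)
    if measurements.empty:
        raise ValueError("measurements table is empty")
    missing = {"stack_id", "r_ec"} - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements CSV missing columns: {sorted(missing)}")
    summaries = summarize_stacks(measurements, metadata)
    scopes = list(scopes) if scopes else ["all"]
    report: dict = {"note": "no multiple-testing correction across scopes",
                    "scopes": {}}
    for scope in scopes:
        if scope not in REGION_SCOPES:
            raise ValueError(f"unknown scope {scope!r}")
        if scope != "all" and all(s.region_label is None for s in summaries):
            raise ValueError(
                f"scope {scope!r} requested but metadata has no region_label")
        report["scopes"][scope] = compare_cohorts(summaries, scope=scope).to_dict()
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
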