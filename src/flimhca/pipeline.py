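"""End-to-end plate processing: directory of FOV stacks -> result tables."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .fitting import FOVResult, process_fov
from .plate_io import (
    AcquisitionTemplate,
    PlateLayout,
    ReferenceDecay,
    read_fov_stack,
)
from .stats import build_report

log = logging.getLogger(__name__)

__all__ = ["process_directory", "run_plate"]


def process_directory(
    input_dir: str | Path,
    ref: ReferenceDecay,
    template: AcquisitionTemplate | None = None,
    pattern: str = "*.tif",
    **fov_kwargs,
) -> list[FOVResult]:
    """Process every gated stack in a directory into FOV results."""
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob(pattern)) + sorted(input_dir.glob(pattern + "f"))
    if not paths:
        raise FileNotFoundError(f"no TIFF stacks matching {pattern} in {input_dir}")
    results = []
    for path in paths:
        stack = read_fov_stack(path, template=template)
        if not stack.fov_id:
            stack.fov_id = path.stem
        results.append(process_fov(stack, ref, **fov_kwargs))
    log.info("processed %d FOVs from %s", len(results), input_dir)
    return results


def run_plate(
    input_dir: str | Path,
    ref: ReferenceDecay,
    layout: PlateLayout,
    out_dir: str | Path,
    template: AcquisitionTemplate | None = None,
    **fov_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Process a plate directory and emit the per-strain report."""
    results = process_directory(input_dir, ref, template=template, **fov_kwargs)
    return build_report(results, layout, out_dir=out_dir)
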