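"""End-to-end detection pipeline and batch driver."""

from __future__ import annotations

import glob
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import RunConfig
from .extract import Detection, extract_detections
from .match import build_correlation_map
from .model import TemplateBank, build_bank
from .preselect import draw_line_image, select_candidates, sobel_gradient

__all__ = ["detect_particles", "run_batch"]

log = logging.getLogger("ricmfringe")


def detect_particles(
    image: np.ndarray,
    run: RunConfig,
    bank: TemplateBank | None = None,
    *,
    debug: dict | None = None,
) -> list[Detection]:
    """Run preselection, matching and extraction on one image.

    A pre-built template bank may be passed to amortize its construction
    over a batch.  If ``debug`` is a dict, the line image and correlation
    map are stored into it under those keys.
    """
    if bank is None:
        bank = build_bank(run.grid, run.optical)
    field = sobel_gradient(image)
    line = draw_line_image(field, run.optical.r_max, run.magnitude_floor)
    candidates = select_candidates(line, run.c)
    cmap = build_correlation_map(image, candidates, bank, run.constraints, run.m)
    detections = extract_detections(
        cmap,
        image,
        bank,
        run.extraction,
        run.optical,
        m=run.m,
        e_modulus=run.e_modulus,
        poisson=run.poisson,
    )
    if debug is not None:
        debug["line_image"] = line.accumulator
        debug["correlation_map"] = cmap.best_corr
        debug["best_template"] = cmap.best_template
        debug["n_candidates"] = len(candidates)
    return detections


def run_batch(run: RunConfig) -> pd.DataFrame:
    """Process every image matching the input glob; one results CSV.

    The template bank is built once; each image goes through
    preselect -> match -> extract.  Per-image failures are logged and
    skipped.  The pipeline itself is deterministic; re-running a batch
    reproduces the results byte for byte.
    """
    if not run.input:
        raise ValueError("run config has no input glob")
    files = sorted(glob.glob(run.input))
    if not files:
        raise FileNotFoundError(f"no images match input glob {run.input!r}")
    outdir = Path(run.output or ".")
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    bank = build_bank(run.grid, run.optical)
    log.info("template bank: %d templates (%.2fs)", len(bank), time.time() - t0)

    records = []
    failures = 0
    for path in files:
        try:
            data = rio.load_image(path)
        except Exception:
            log.exception("failed to load %s; skipping", path)
            failures += 1
            continue
        frames = data[None] if data.ndim == 2 else data
        for fi, frame in enumerate(frames):
            t1 = time.time()
            debug: dict = {}
            try:
                dets = detect_particles(frame, run, bank, debug=debug)
            except Exception:
                log.exception("failed to process %s frame %d; skipping", path, fi)
                failures += 1
                continue
            stem = Path(path).stem + (f"_f{fi}" if data.ndim == 3 else "")
            if run.save_line_image:
                rio.save_float_tiff(outdir / f"{stem}_line.tif", debug["line_image"])
            if run.save_correlation_map:
                rio.save_float_tiff(outdir / f"{stem}_corr.tif", debug["correlation_map"])
            if run.overlay:
                rio.save_overlay(outdir / f"{stem}_overlay.png", frame, dets)
            log.info(
                "%s frame %d: %d candidates, %d detections (%.2fs)",
                path,
                fi,
                debug["n_candidates"],
                len(dets),
                time.time() - t1,
            )
            records.extend((Path(path).name, fi, det) for det in dets)

    table = rio.detections_to_frame(records)
    rio.results_to_csv(outdir / "results.csv", table)
    if failures:
        raise RuntimeError(f"{failures} image(s)/frame(s) failed; see log")
    return table
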