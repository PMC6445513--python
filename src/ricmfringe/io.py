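"""Image loading and result/debug writing."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = ["load_image", "save_float_tiff", "save_overlay", "results_to_csv"]

_COLUMNS = [
    "image",
    "frame",
    "x_px",
    "y_px",
    "correlation",
    "slope_score",
    "d_um",
    "p_um",
    "dec",
    "particle_diameter_um",
    "contact_radius_um",
    "adhesion_energy_J_m2",
    "rank",
]

_HEADER_NOTE = (
    "# ricmfringe results. Coordinates are 0-based integer pixels, x = column, y = row.\n"
    "# d_um is the relative height for phase index i = 0; absolute height is ambiguous\n"
    "# modulo lambda/(2n)*(1-sin^2(alpha/2)) (irrelevant for adhering probes, d <= 0).\n"
)


def load_image(path) -> np.ndarray:
    """Load a grayscale TIFF (or PNG) scaled to [0, 1] by bit-depth maximum.

    Returns shape (H, W) for single images and (frames, H, W) for
    multi-page TIFF stacks.  RGB input raises with a conversion hint.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read image: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if data.ndim == 3 and data.shape[-1] in (3, 4):
        raise ValueError(
            f"{path} is RGB(A); convert to monochrome before processing"
        )
    if data.ndim not in (2, 3):
        raise ValueError(f"{path}: unsupported image shape {data.shape}")
    if data.dtype == np.uint8:
        return data.astype(float) / 255.0
    if data.dtype == np.uint16:
        return data.astype(float) / 65535.0
    return data.astype(float)


def save_float_tiff(path, array: np.ndarray) -> None:
    """Write a float32 TIFF debug artifact (line image, correlation map)."""
    tifffile.imwrite(Path(path), np.asarray(array, dtype=np.float32))


def save_overlay(path, image: np.ndarray, detections) -> None:
    """PNG overlay: grayscale image with detections marked by crosses."""
    rgb = np.stack([np.clip(image, 0, 1)] * 3, axis=-1)
    h, w = image.shape
    for det in detections:
        x, y, arm = det.x, det.y, 6
        rows = np.clip(np.arange(y - arm, y + arm + 1), 0, h - 1)
        cols = np.clip(np.arange(x - arm, x + arm + 1), 0, w - 1)
        rgb[rows, x] = [1.0, 0.2, 0.2]
        rgb[y, cols] = [1.0, 0.2, 0.2]
    iio.imwrite(Path(path), (rgb * 255).astype(np.uint8))


def detections_to_frame(records) -> pd.DataFrame:
    """Flatten (image, frame, Detection) records into the results table."""
    rows = []
    for image_name, frame, det in records:
        rows.append(
            {
                "image": image_name,
                "frame": frame,
                "x_px": det.x,
                "y_px": det.y,
                "correlation": det.correlation,
                "slope_score": det.slope_score,
                "d_um": det.params.d,
                "p_um": det.params.p,
                "dec": det.params.dec,
                "particle_diameter_um": det.particle_diameter_um,
                "contact_radius_um": det.contact_radius_um,
                "adhesion_energy_J_m2": det.adhesion_energy_J_m2,
                "rank": det.rank,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def results_to_csv(path, frame: pd.DataFrame) -> None:
    with open(Path(path), "w") as fh:
        fh.write(_HEADER_NOTE)
        frame.to_csv(fh, index=False)
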