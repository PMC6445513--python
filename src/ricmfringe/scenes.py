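"""Synthetic RICM scene generation with known ground truth.

Renders images of spherical probes directly from the interference forward
model, with configurable background level, fringe contrast, additive
Gaussian sensor noise, and a radially symmetric multiplicative vignette.
Every rendered particle carries its generating parameters, so the full
detection pipeline can be validated closed-loop without experimental data.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .model import OpticalConfig, ParameterGrid, decay_factor, template_intensity

__all__ = [
    "ParticleGroundTruth",
    "SceneSpec",
    "RenderedScene",
    "render_scene",
    "sample_scene_spec",
    "write_fixture_set",
    "read_fixture_manifest",
]


@dataclass(frozen=True)
class ParticleGroundTruth:
    """One particle's true center (px, real-valued) and model parameters."""

    cx: float
    cy: float
    d: float
    p: float
    dec: float = 0.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene.

    Intensities are fractions of the dynamic range: pixel values are
    ``background + contrast * model`` (model in [-1, 1]), multiplied by the
    vignette, plus N(0, noise_sigma) noise, clipped to [0, 1].
    """

    width: int
    height: int
    particles: tuple[ParticleGroundTruth, ...]
    background: float = 0.5
    contrast: float = 0.25
    noise_sigma: float = 0.02
    vignette_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "particles", tuple(self.particles))
        if not (0 <= self.background - self.contrast and self.background + self.contrast <= 1):
            raise ValueError("background +- contrast must stay within [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.vignette_strength < 0:
            raise ValueError("vignette_strength must be >= 0")


@dataclass(frozen=True)
class RenderedScene:
    image: np.ndarray  # float64 in [0, 1], shape (height, width)
    spec: SceneSpec


def render_scene(spec: SceneSpec, config: OpticalConfig) -> RenderedScene:
    """Render a scene from the forward model; deterministic given the seed.

    Each particle contributes the model intensity (with its decay) inside a
    disc of ``r_max`` pixels around its center; contributions add where
    discs overlap (a warning is issued for centers closer than ``r_max``).
    """
    h_px, w_px = spec.height, spec.width
    r_max = config.r_max
    signal = np.zeros((h_px, w_px))

    centers = [(pt.cx, pt.cy) for pt in spec.particles]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dist = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if dist < r_max:
                warnings.warn(
                    f"particles {i} and {j} are {dist:.1f} px apart (< r_max={r_max}); "
                    "their fringe patterns overlap additively",
                    stacklevel=2,
                )

    for pt in spec.particles:
        c0 = max(0, int(np.floor(pt.cx - r_max)))
        c1 = min(w_px, int(np.ceil(pt.cx + r_max)) + 1)
        r0 = max(0, int(np.floor(pt.cy - r_max)))
        r1 = min(h_px, int(np.ceil(pt.cy + r_max)) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dist_px = np.hypot(xx - pt.cx, yy - pt.cy)
        mask = dist_px <= r_max
        r_um = dist_px[mask] * config.u
        vals = template_intensity(r_um, pt.d, pt.p, config)
        vals = vals * decay_factor(dist_px[mask], pt.dec, r_max)
        patch = signal[r0:r1, c0:c1]
        patch[mask] += vals

    image = spec.background + spec.contrast * signal
    if spec.vignette_strength > 0:
        yy, xx = np.mgrid[0:h_px, 0:w_px]
        rho = np.hypot(xx - (w_px - 1) / 2.0, yy - (h_px - 1) / 2.0)
        rho_max = rho.max()
        image = image * (1.0 - spec.vignette_strength * (rho / rho_max) ** 2)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    return RenderedScene(image=np.clip(image, 0.0, 1.0), spec=spec)


def sample_scene_spec(
    seed: int,
    n_particles: int,
    grid: ParameterGrid,
    *,
    width: int = 512,
    height: int = 512,
    margin: int = 100,
    background: float = 0.5,
    contrast: float = 0.25,
    noise_sigma: float = 0.02,
    vignette_strength: float = 0.0,
    adhering_only: bool = False,
    subpixel: bool = True,
) -> SceneSpec:
    """Draw a reproducible random scene from the search-space grid.

    Particle parameters are drawn uniformly from the grid *values* (so
    exact recovery is possible); centers are uniform within the image with
    a ``margin``-pixel border.  With ``adhering_only`` the height ``d`` is
    drawn from the strictly negative grid values only.
    """
    if width - 1 - 2 * margin <= 0 or height - 1 - 2 * margin <= 0:
        raise ValueError(
            f"image {width}x{height} too small for margin {margin} px"
        )
    rng = np.random.default_rng(seed)
    d_pool = [d for d in grid.d_values if d < 0] if adhering_only else list(grid.d_values)
    if not d_pool:
        raise ValueError("no admissible d values in the grid")
    particles = []
    for _ in range(n_particles):
        cx = rng.uniform(margin, width - 1 - margin)
        cy = rng.uniform(margin, height - 1 - margin)
        if not subpixel:
            cx, cy = round(cx), round(cy)
        particles.append(
            ParticleGroundTruth(
                cx=float(cx),
                cy=float(cy),
                d=float(rng.choice(d_pool)),
                p=float(rng.choice(grid.p_values)),
                dec=float(rng.choice(grid.dec_values)),
            )
        )
    return SceneSpec(
        width=width,
        height=height,
        particles=tuple(particles),
        background=background,
        contrast=contrast,
        noise_sigma=noise_sigma,
        vignette_strength=vignette_strength,
        seed=int(rng.integers(2**31)),
    )


def write_fixture_set(
    directory,
    specs: list[SceneSpec],
    config: OpticalConfig,
    *,
    bit_depth: int = 16,
) -> dict:
    """Render each spec to a TIFF plus a CSV/JSON ground-truth manifest.

    Returns the manifest dictionary; ``read_fixture_manifest`` round-trips
    it losslessly back to the scene specs.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vmax = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16

    rows = []
    entries = []
    for i, spec in enumerate(specs):
        name = f"scene_{i:03d}.tif"
        scene = render_scene(spec, config)
        quantized = np.round(scene.image * vmax).astype(dtype)
        try:
            tifffile.imwrite(directory / name, quantized)
        except OSError as exc:  # pragma: no cover - I/O failure path
            raise OSError(f"failed writing fixture {directory / name}: {exc}") from exc
        for pt in spec.particles:
            rows.append(
                {"file": name, "cx": pt.cx, "cy": pt.cy, "d": pt.d, "p": pt.p, "dec": pt.dec}
            )
        entry = dataclasses.asdict(spec)
        entry["particles"] = [dataclasses.asdict(pt) for pt in spec.particles]
        entry["file"] = name
        entries.append(entry)

    manifest = {"bit_depth": bit_depth, "scenes": entries}
    pd.DataFrame(rows, columns=["file", "cx", "cy", "d", "p", "dec"]).to_csv(
        directory / "manifest.csv", index=False
    )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_fixture_manifest(directory) -> list[tuple[str, SceneSpec]]:
    """Parse manifest.json back into (filename, SceneSpec) pairs."""
    with open(Path(directory) / "manifest.json") as fh:
        manifest = json.load(fh)
    out = []
    for entry in manifest["scenes"]:
        particles = tuple(ParticleGroundTruth(**pt) for pt in entry["particles"])
        spec = SceneSpec(
            width=entry["width"],
            height=entry["height"],
            particles=particles,
            background=entry["background"],
            contrast=entry["contrast"],
            noise_sigma=entry["noise_sigma"],
            vignette_strength=entry["vignette_strength"],
            seed=entry["seed"],
        )
        out.append((entry["file"], spec))
    return out
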