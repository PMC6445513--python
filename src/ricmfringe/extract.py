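"""Detection extraction, size refinement, and derived measurements.

Detections are pulled iteratively from the correlation map: take the
global maximum, suppress a disc of radius ``r_max`` around it, repeat
until the map drops below the correlation threshold ``t1`` or the
iteration cap is reached.  Each accepted position then gets a second,
extrema-focused matching pass: the bank template whose slopes run in
synchronism with the measured profile (rising/falling together) wins.
Extrema positions encode the particle size directly, so this refinement
estimates the radius markedly better than the amplitude-blind Pearson
pass.  The refined template's (d, p) yield the contact radius, particle
diameter, relative height, and - given elastic constants - the JKR
adhesion energy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .match import CorrelationMap, RadialSampleSet, pearson, radial_sample
from .model import (
    OpticalConfig,
    TemplateBank,
    TemplateParams,
    adhesion_energy,
    contact_radius,
)

__all__ = [
    "Detection",
    "ExtractionConfig",
    "slope_sync_score",
    "refine_template",
    "derive_measurements",
    "extract_detections",
]


@dataclass(frozen=True)
class Detection:
    """One detected fringe pattern and its physical measurements.

    ``relative_height_um`` is the best template's ``d`` with the implicit
    phase index i = 0; the true height is ambiguous modulo the
    interference period (see ``model.relative_height``), which is
    immaterial for adhering probes.
    """

    x: int
    y: int
    params: TemplateParams
    correlation: float
    slope_score: float
    contact_radius_um: float | None = None
    particle_diameter_um: float | None = None
    relative_height_um: float | None = None
    adhesion_energy_J_m2: float | None = None
    rank: int = 0


@dataclass(frozen=True)
class ExtractionConfig:
    """Stopping rule of the iterative extraction.

    ``t1``: minimum correlation for a detection; ``r_max``: suppression
    radius in px; ``max_iterations``: hard cap on extractions.
    """

    t1: float = 0.9
    r_max: int = 100
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if not (-1 <= self.t1 <= 1):
            raise ValueError("t1 must lie in [-1, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def slope_sync_score(
    profile: np.ndarray, template: np.ndarray, flat_tol: float = 0.0
) -> float:
    """Fraction of radial positions where profile and template run in synchronism.

    Counts positions whose successive differences have the same sign
    (both rising, both falling, or both flat) and divides by ``r_max``.
    Only ``r_max - 1`` differences exist, so the maximum score is
    ``(r_max - 1) / r_max``, not 1.  Flat stretches (the contact zone of
    undecayed templates) synchronize only with flat stretches, which
    makes the contact-zone width informative.

    ``flat_tol`` is an absolute slope magnitude below which a *measured*
    profile difference is classified as flat; measured profiles are never
    exactly flat under sensor noise, so an exact-zero rule would deny the
    true template any credit inside its contact zone.  The default 0
    keeps the exact rule (appropriate for template-vs-template use).
    """
    profile = np.asarray(profile, dtype=float)
    template = np.asarray(template, dtype=float)
    if profile.shape != template.shape or profile.ndim != 1:
        raise ValueError(f"length mismatch: {profile.shape} vs {template.shape}")
    r_max = profile.size
    pdiff = np.diff(profile)
    psign = np.sign(pdiff)
    if flat_tol > 0:
        psign[np.abs(pdiff) <= flat_tol] = 0
    agree = psign == np.sign(np.diff(template))
    return float(agree.sum()) / r_max


def refine_template(
    sampleset: RadialSampleSet, bank: TemplateBank, flat_frac: float = 0.05
) -> tuple[TemplateParams, float]:
    """Second, extrema-focused matching pass at an accepted position.

    Returns the bank parameters maximizing the slope-synchronism score
    against ``p_mean`` (amplitude is ignored entirely), plus the winning
    score.  Ties break to the higher Pearson correlation, then to the
    lowest bank index.

    Measured slopes whose magnitude is below ``flat_frac`` times the
    profile's steepest slope are classified as flat, so that the noisy
    but physically flat contact core can synchronize with the flat core
    of the true template instead of handing random credit to oscillating
    templates.
    """
    profile = sampleset.mean_profile
    pdiff = np.diff(profile)
    psign = np.sign(pdiff).astype(np.int8)
    if flat_frac > 0 and pdiff.size:
        psign[np.abs(pdiff) <= flat_frac * np.max(np.abs(pdiff))] = 0
    counts = (bank.diff_signs == psign[None, :]).sum(axis=1)
    r_max = profile.size
    best_count = counts.max()
    tied = np.nonzero(counts == best_count)[0]
    if len(tied) > 1:
        corrs = np.array([pearson(profile, bank.values[i]) for i in tied])
        tied = tied[corrs == corrs.max()]
    best = int(tied[0])
    return bank.lookup(best), float(best_count) / r_max


def derive_measurements(
    detection: Detection,
    optical: OpticalConfig,
    e_modulus: float | None = None,
    poisson: float | None = None,
) -> Detection:
    """Fill the physical measurements derived from the refined template.

    Adhesion energy is attached only when both elastic constants are
    supplied; otherwise the field stays absent (None), not zero.
    """
    params = detection.params
    r_c = contact_radius(params.d, params.p)
    w_adh = None
    if e_modulus is not None and poisson is not None:
        w_adh = adhesion_energy(r_c, params.p, e_modulus, poisson)
    return replace(
        detection,
        contact_radius_um=r_c,
        particle_diameter_um=2.0 * params.p,
        relative_height_um=params.d,
        adhesion_energy_J_m2=w_adh,
    )


def extract_detections(
    cmap: CorrelationMap,
    image: np.ndarray,
    bank: TemplateBank,
    config: ExtractionConfig,
    optical: OpticalConfig,
    *,
    m: int = 90,
    e_modulus: float | None = None,
    poisson: float | None = None,
) -> list[Detection]:
    """Iteratively extract detections from the correlation map.

    Returns detections in descending first-pass correlation order with
    pairwise center distances > ``r_max`` px; stops when the remaining map
    maximum drops below ``t1`` or after ``max_iterations`` extractions.
    An empty list is a valid result.
    """
    working = cmap.best_corr.copy()
    h, w = working.shape
    r_max = config.r_max
    yy, xx = np.mgrid[0:h, 0:w]
    detections: list[Detection] = []
    for _ in range(config.max_iterations):
        if not np.isfinite(working).any():
            break
        flat = np.nanargmax(working)
        y, x = np.unravel_index(flat, working.shape)
        corr = float(working[y, x])
        if corr < config.t1:
            break
        sampleset = radial_sample(image, int(x), int(y), m, r_max)
        if sampleset.coverage >= 0.5:
            params, score = refine_template(sampleset, bank)
        else:  # defensive: matcher should never have accepted such a position
            params, score = bank.lookup(int(cmap.best_template[y, x])), 0.0
        det = Detection(
            x=int(x),
            y=int(y),
            params=params,
            correlation=corr,
            slope_score=score,
            rank=len(detections) + 1,
        )
        detections.append(derive_measurements(det, optical, e_modulus, poisson))
        working[(xx - x) ** 2 + (yy - y) ** 2 <= r_max * r_max] = np.nan
    return detections
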