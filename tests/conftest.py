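import numpy as np
import pytest

from ricmfringe import (
    OpticalConfig,
    ParameterGrid,
    ParticleGroundTruth,
    SceneSpec,
    build_bank,
    render_scene,
)


@pytest.fixture(scope="session")
def cfg_table() -> OpticalConfig:
    """The standard optical configuration (r_max = 100 px)."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def cfg_small() -> OpticalConfig:
    """Reduced template radius for fast unit tests."""
    return OpticalConfig(r_max=40)


@pytest.fixture(scope="session")
def grid_small() -> ParameterGrid:
    """Coarse search grid (75 templates) for fast unit tests."""
    return ParameterGrid.from_ranges([-0.4, 0.1, 0.0], [10, 5, 30], [0, 5, 10])


@pytest.fixture(scope="session")
def bank_small(grid_small, cfg_small):
    return build_bank(grid_small, cfg_small)


def make_single_particle_scene(
    cfg: OpticalConfig,
    *,
    cx: float,
    cy: float,
    d: float,
    p: float,
    dec: float = 0.0,
    size: int = 192,
    noise_sigma: float = 0.0,
    vignette: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, ParticleGroundTruth]:
    pt = ParticleGroundTruth(cx=cx, cy=cy, d=d, p=p, dec=dec)
    spec = SceneSpec(
        width=size,
        height=size,
        particles=(pt,),
        noise_sigma=noise_sigma,
        vignette_strength=vignette,
        seed=seed,
    )
    return render_scene(spec, cfg).image, pt


@pytest.fixture(scope="session")
def clean_scene_small(cfg_small):
    """Noise-free single particle on the small config, integer center."""
    return make_single_particle_scene(cfg_small, cx=96, cy=96, d=-0.2, p=10, dec=2.0)
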