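import numpy as np
import pytest

from petscatter import (
    KernelParams,
    ScannerGeometry,
    ScatterModelConfig,
    forward_project,
    simulate_scatter,
    uniform_cylinder,
)


@pytest.fixture(scope="session")
def small_geom():
    """Coarse but adequately sampled scanner for fast tests."""
    return ScannerGeometry(
        n_views=16,
        n_radial=96,
        radial_bin_cm=0.2,
        n_slices=12,
        slice_thickness_cm=0.26,
        fov_radius_cm=9.6,
    )


@pytest.fixture(scope="session")
def cyl_phantom(small_geom):
    """10 cm cylinder, shorter than the axial FOV (axial scatter tails)."""
    return uniform_cylinder(small_geom, diameter_cm=10.0, activity_kbq_ml=10.0, length_cm=2.0)


@pytest.fixture(scope="session")
def cyl_trues(small_geom, cyl_phantom):
    act, mu, _ = cyl_phantom
    return forward_project(act, small_geom, mu)


TRUE_PARAMS = KernelParams(0.35, 3.0)


@pytest.fixture(scope="session")
def sc_world(small_geom, cyl_phantom, cyl_trues):
    """Self-consistent scatter world: prompts = trues/(1 - S) per view.

    Returns (trues, scatter, prompts, mu, params); DEC with these params in
    circular mode recovers the trues exactly.
    """
    _, mu, _ = cyl_phantom
    cfg = ScatterModelConfig(mode="dec_self_consistent", kernel_params=TRUE_PARAMS)
    scatter = simulate_scatter(cyl_trues, mu, cfg)
    prompts = cyl_trues.with_counts(cyl_trues.counts + scatter.counts, label="SEW")
    return cyl_trues, scatter, prompts, mu, TRUE_PARAMS


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
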