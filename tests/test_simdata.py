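"""Synthetic data: phantoms, projector, scatter generator, prompts."""

import numpy as np
import pytest

from petscatter import (
    ScannerGeometry,
    ScatterModelConfig,
    WindowConfig,
    brain_phantom,
    build_phantom,
    compose_prompts,
    forward_project,
    simulate_scatter,
    uniform_cylinder,
)
from petscatter.containers import ActivityVolume, MuMap
from petscatter.simdata import LABELS


class TestPhantoms:
    def test_cylinder_values(self, small_geom):
        act, mu, labels = uniform_cylinder(small_geom, 8.0, 10.0)
        inside = labels == LABELS["water"]
        assert np.all(act.values[inside] == 10.0)
        assert np.all(act.values[~inside] == 0.0)
        assert np.all(mu.values[inside] == pytest.approx(0.096))
        assert np.all(mu.values[~inside] == 0.0)

    def test_zero_activity_phantom(self, small_geom):
        act, _, _ = uniform_cylinder(small_geom, 8.0, 0.0)
        assert act.values.sum() == 0.0

    def test_brain_gm_wm_ratio_exact(self, small_geom):
        act, _, labels = brain_phantom(small_geom, gm_activity_kbq_ml=40, gm_wm_ratio=4)
        gm = act.values[labels == LABELS["gm"]].mean()
        wm = act.values[labels == LABELS["wm"]].mean()
        assert gm / wm == pytest.approx(4.0, abs=1e-12)

    def test_shape_larger_than_fov_rejected(self, small_geom):
        with pytest.raises(ValueError, match="FOV"):
            uniform_cylinder(small_geom, diameter_cm=30.0)

    def test_negative_activity_rejected(self, small_geom):
        with pytest.raises(ValueError):
            uniform_cylinder(small_geom, 8.0, activity_kbq_ml=-1.0)

    def test_build_phantom_dispatch(self, small_geom):
        act, mu, labels = build_phantom(
            {"shape": "uniform_cylinder", "diameter_cm": 8.0, "activity_kbq_ml": 5.0},
            small_geom,
        )
        assert act.values.max() == 5.0
        with pytest.raises(ValueError, match="shape"):
            build_phantom({"diameter_cm": 8.0}, small_geom)
        with pytest.raises(ValueError, match="unsupported"):
            build_phantom({"shape": "donut"}, small_geom)


class TestForwardProject:
    def test_point_source_hits_central_bin(self, small_geom):
        values = np.zeros(small_geom.image_shape)
        c = small_geom.n_radial // 2
        values[c, c, 5] = 1.0
        sino = forward_project(ActivityVolume(values, small_geom.voxel_size_cm), small_geom)
        for v in range(small_geom.n_views):
            assert sino.counts[v, :, 5].argmax() == c

    def test_disc_profile_closed_form(self):
        """Projection of a uniform disc is 2 a sqrt(R^2 - s^2).

        Checked at bin centres over the inner 80% of the disc (the rim
        bins are dominated by voxelisation of the disc boundary, not by
        projector error) with adequately fine radial sampling.
        """
        geom = ScannerGeometry(
            n_views=8, n_radial=160, radial_bin_cm=0.1, n_slices=2,
            slice_thickness_cm=0.26, fov_radius_cm=8.0,
        )
        R, a = 6.0, 10.0
        act, _, _ = uniform_cylinder(geom, 2 * R, a)
        sino = forward_project(act, geom)
        offsets = geom.radial_offsets_cm
        expected = np.where(
            np.abs(offsets) < R, 2 * a * np.sqrt(np.clip(R**2 - offsets**2, 0, None)), 0.0
        )
        inner = np.abs(offsets) <= 0.8 * R
        for view in (0, geom.n_views // 2):
            prof = sino.counts[view, :, 0]
            rel = np.abs(prof[inner] - expected[inner]) / expected[inner]
            assert rel.max() < 0.02

    def test_lead_slab_attenuation(self):
        """0.7 cm of lead (mu = 1.75/cm) attenuates ~70% of 511 keV photons.

        A slab 0.7 cm thick is crossed perpendicularly by the rays of one
        view; for that view the line integral is 1.225 everywhere and the
        transmitted fraction exp(-1.225) ~ 0.294.
        """
        from petscatter.project import mu_line_integrals

        geom = ScannerGeometry(
            n_views=8, n_radial=64, radial_bin_cm=0.1, n_slices=2,
            slice_thickness_cm=0.26, fov_radius_cm=3.2,
        )
        mu = np.zeros(geom.image_shape)
        c = geom.n_radial // 2
        mu[:, c - 3 : c + 4, :] = 1.75  # 7 voxels x 0.1 cm = 0.7 cm thick
        x = (np.arange(geom.n_radial) - c) * geom.radial_bin_cm
        outside = np.hypot(x[:, None], x[None, :]) > geom.fov_radius_cm
        mu[outside, :] = 0.0  # radon only sees the inscribed circle
        integrals = mu_line_integrals(MuMap(mu, geom.voxel_size_cm), geom)
        # perpendicular crossing is the shortest path through a slab
        central = integrals[:, c - 8 : c + 8, 0]
        per_view = central.mean(axis=1)
        transmitted = np.exp(-per_view.min())
        assert transmitted == pytest.approx(np.exp(-1.75 * 0.7), rel=0.02)
        assert 1.0 - transmitted == pytest.approx(0.70, abs=0.02)

    def test_projector_linearity(self, small_geom, cyl_phantom):
        act, mu, _ = cyl_phantom
        s1 = forward_project(act, small_geom, mu)
        s2 = forward_project(act.scaled(2.5), small_geom, mu)
        assert np.allclose(s2.counts, 2.5 * s1.counts, atol=1e-9)

    def test_total_counts_constant_across_views(self, small_geom, cyl_trues):
        totals = cyl_trues.counts.sum(axis=(1, 2))
        assert totals.std() / totals.mean() < 0.01

    def test_grid_mismatch_rejected(self, small_geom):
        bad = ActivityVolume(np.zeros((10, 10, 3)), (0.2, 0.2, 0.26))
        with pytest.raises(ValueError, match="grid"):
            forward_project(bad, small_geom)


class TestScatterGenerator:
    def test_zero_scatter_fraction(self, small_geom, cyl_phantom, cyl_trues):
        _, mu, _ = cyl_phantom
        cfg = ScatterModelConfig(scatter_fraction_sew=0.0, scatter_fraction_uew=0.0)
        sc = simulate_scatter(cyl_trues, mu, cfg)
        assert sc.counts.sum() == 0.0

    @pytest.mark.parametrize("sf", [0.2, 0.4])
    def test_scatter_fraction_enforced(self, small_geom, cyl_phantom, cyl_trues, sf):
        _, mu, _ = cyl_phantom
        cfg = ScatterModelConfig(scatter_fraction_sew=sf, scatter_fraction_uew=0.1)
        sc = simulate_scatter(cyl_trues, mu, cfg)
        ratio = sc.total / (sc.total + cyl_trues.total)
        assert ratio == pytest.approx(sf, abs=1e-6)

    def test_scatter_has_tails_outside_support(self, small_geom, cyl_phantom, cyl_trues):
        """Blur spreads counts beyond the object's projected support —
        exactly the signal tail-matching calibration exploits."""
        _, mu, _ = cyl_phantom
        cfg = ScatterModelConfig(scatter_fraction_sew=0.3)
        sc = simulate_scatter(cyl_trues, mu, cfg)
        tail = cyl_trues.counts == 0
        assert tail.any()
        assert sc.counts[tail].sum() > 0

    def test_invalid_scatter_fraction_rejected(self):
        with pytest.raises(ValueError):
            ScatterModelConfig(scatter_fraction_sew=1.0)
        with pytest.raises(ValueError):
            ScatterModelConfig(scatter_fraction_sew=0.2, scatter_fraction_uew=0.3)

    def test_self_consistent_needs_params(self):
        with pytest.raises(ValueError, match="kernel_params"):
            ScatterModelConfig(mode="dec_self_consistent")

    def test_oof_ramp_adds_low_slice_background(self, small_geom, cyl_phantom, cyl_trues):
        _, mu, _ = cyl_phantom
        base = ScatterModelConfig(scatter_fraction_sew=0.3)
        with_oof = ScatterModelConfig(scatter_fraction_sew=0.3, oof_background_amplitude=5.0)
        s0 = simulate_scatter(cyl_trues, mu, base)
        s1 = simulate_scatter(cyl_trues, mu, with_oof)
        extra = s1.counts - s0.counts
        assert extra[:, :, 0].mean() > extra[:, :, -1].mean()
        assert extra.min() >= 0


class TestComposePrompts:
    def test_identity_composition(self, small_geom, cyl_phantom, cyl_trues):
        _, mu, _ = cyl_phantom
        cfg = ScatterModelConfig(scatter_fraction_sew=0.3, scatter_fraction_uew=0.1)
        sc = simulate_scatter(cyl_trues, mu, cfg)
        win = WindowConfig(sew_true_efficiency=1.0, uew_true_efficiency=1.0)
        sew, _ = compose_prompts(cyl_trues, sc, win, cfg)
        assert np.allclose(sew.counts, cyl_trues.counts + sc.counts)

    def test_count_conservation(self, small_geom, cyl_phantom, cyl_trues):
        _, mu, _ = cyl_phantom
        cfg = ScatterModelConfig(scatter_fraction_sew=0.3, scatter_fraction_uew=0.1)
        sc = simulate_scatter(cyl_trues, mu, cfg)
        win = WindowConfig(0.9, 0.3)
        sew, _ = compose_prompts(cyl_trues, sc, win, cfg)
        assert sew.total == pytest.approx(0.9 * cyl_trues.total + sc.total, rel=1e-12)

    def test_seed_reproducibility(self, small_geom, cyl_phantom, cyl_trues):
        _, mu, _ = cyl_phantom
        cfg = ScatterModelConfig()
        sc = simulate_scatter(cyl_trues, mu, cfg)
        win = WindowConfig()
        a1, b1 = compose_prompts(cyl_trues, sc, win, cfg, seed=42)
        a2, b2 = compose_prompts(cyl_trues, sc, win, cfg, seed=42)
        assert np.array_equal(a1.counts, a2.counts)
        assert np.array_equal(b1.counts, b2.counts)

    def test_uew_scatter_fraction_smaller(self, small_geom, cyl_phantom, cyl_trues):
        _, mu, _ = cyl_phantom
        cfg = ScatterModelConfig(scatter_fraction_sew=0.35, scatter_fraction_uew=0.10)
        sc = simulate_scatter(cyl_trues, mu, cfg)
        win = WindowConfig(0.9, 0.3)
        sew, uew = compose_prompts(cyl_trues, sc, win, cfg)
        sf_sew = (sew.total - 0.9 * cyl_trues.total) / sew.total
        sf_uew = (uew.total - 0.3 * cyl_trues.total) / uew.total
        assert sf_uew < sf_sew
        assert sf_uew == pytest.approx(0.10, abs=1e-9)

    def test_poisson_mean_matches_noiseless(self, small_geom, cyl_phantom):
        """Across 100 seeds the per-bin mean stays within 5 sigma of the
        noiseless expectation (tiny sinogram keeps this cheap)."""
        geom = ScannerGeometry(
            n_views=4, n_radial=24, radial_bin_cm=0.4, n_slices=3,
            slice_thickness_cm=1.0, fov_radius_cm=4.8,
        )
        act, mu, _ = uniform_cylinder(geom, 6.0, 50.0)
        trues = forward_project(act, geom, mu)
        cfg = ScatterModelConfig(scatter_fraction_sew=0.3)
        sc = simulate_scatter(trues, mu, cfg)
        win = WindowConfig()
        noiseless, _ = compose_prompts(trues, sc, win, cfg)
        acc = np.zeros_like(noiseless.counts)
        n = 100
        for seed in range(n):
            s, _ = compose_prompts(trues, sc, win, cfg, seed=seed)
            acc += s.counts
        mean = acc / n
        sigma = np.sqrt(np.clip(noiseless.counts, 1e-12, None) / n)
        z = np.abs(mean - noiseless.counts) / sigma
        assert z.max() < 5.0


def test_mu_map_validation(small_geom):
    bad = np.full(small_geom.image_shape, 3.0)
    with pytest.raises(ValueError, match="unphysical"):
        MuMap(bad, small_geom.voxel_size_cm)
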