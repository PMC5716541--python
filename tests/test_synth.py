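"""Synthetic world: scene sampling, rasterization, noise pipeline, SNR."""

import numpy as np
import pytest
from shapely.geometry import Point

from eitpost.dataset import BoundaryPerturbation, build_dataset
from eitpost.noise import (
    NoiseModel,
    estimate_snr,
    snr_profile_adjacent,
    synthesize_channel_waves,
    synthesize_noisy_frame,
)
from eitpost.scenes import (
    CONDUCTIVITY_REGIMES,
    PhantomScene,
    TargetSpec,
    rasterize_scene,
    sample_scene,
    scene_polygons,
)

BACKGROUND = 0.9


class TestSceneSampling:
    def test_seeded_determinism(self):
        s1 = sample_scene(np.random.default_rng(42), shape_set=("ellipse",))
        s2 = sample_scene(np.random.default_rng(42), shape_set=("ellipse",))
        assert s1 == s2

    def test_area_fraction_bounds_and_containment(self):
        """Across many draws: area fractions in [0.05, 0.40], targets inside."""
        rng = np.random.default_rng(0)
        domain = Point(0, 0).buffer(0.5, quad_segs=64)
        fracs = []
        for _ in range(300):
            scene = sample_scene(rng)
            for t in scene.targets:
                fracs.append(t.area_fraction)
                assert domain.contains(t.polygon())
        assert min(fracs) >= 0.05
        assert max(fracs) <= 0.40

    def test_two_targets_never_overlap(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            scene = sample_scene(rng, n_targets=2)
            p1, p2 = scene_polygons(scene)
            assert p1.intersection(p2).area == 0.0

    def test_shapes_uniform(self):
        rng = np.random.default_rng(2)
        counts = {s: 0 for s in ("ellipse", "triangle", "rectangle")}
        n = 2000
        for _ in range(n):
            scene = sample_scene(rng, n_targets=1)
            counts[scene.targets[0].shape] += 1
        p = 1 / 3
        se = np.sqrt(p * (1 - p) * n)
        for c in counts.values():
            assert abs(c - n * p) < 3 * se

    def test_infeasible_ranges_error(self):
        rng = np.random.default_rng(3)
        with pytest.raises(RuntimeError, match="rejected"):
            sample_scene(rng, area_range=(0.95, 0.99), max_rejections=50)

    def test_polygon_area_matches_fraction(self):
        for shape in ("ellipse", "triangle", "rectangle"):
            t = TargetSpec(shape, (0.0, 0.0), 0.2, 0.7, 0.01, aspect=1.5)
            domain_area = np.pi * 0.25
            assert abs(t.polygon().area - 0.2 * domain_area) < 1e-6 * domain_area

    def test_lung_regime_conductivity_range(self):
        rng = np.random.default_rng(4)
        lo, hi = CONDUCTIVITY_REGIMES["lungs"][1]
        for _ in range(50):
            s = sample_scene(rng, regime="lungs", n_targets=1)
            assert lo <= s.targets[0].conductivity <= hi


class TestRasterize:
    def test_empty_scene_equivalent(self, ref_mesh):
        scene = PhantomScene([TargetSpec("ellipse", (0, 0), 0.05, 0, BACKGROUND)])
        sigma = rasterize_scene(scene, ref_mesh)
        assert np.all(sigma == BACKGROUND)

    def test_rasterized_area_close_to_analytic(self, ref_mesh):
        scene = PhantomScene([TargetSpec("ellipse", (0.0, 0.0), 0.1, 0.0, 0.01)])
        sigma = rasterize_scene(scene, ref_mesh)
        areas = ref_mesh.element_areas()
        frac = areas[sigma != BACKGROUND].sum() / areas.sum()
        assert 0.08 <= frac <= 0.12

    def test_zero_conductivity_rejected(self, ref_mesh):
        scene = PhantomScene([TargetSpec("ellipse", (0, 0), 0.1, 0, 0.0)])
        with pytest.raises(ValueError, match="insulator"):
            rasterize_scene(scene, ref_mesh)


class TestNoise:
    def test_noise_free_roundtrip_within_filter_ripple(self, ref_solution):
        nm = NoiseModel(channel_snr_db=np.full(256, np.inf))
        out = synthesize_noisy_frame(ref_solution.frame, nm, np.random.default_rng(0))
        v = ref_solution.frame.voltages
        assert np.abs(out.voltages - v).max() <= 0.01 * np.abs(v).max()

    def test_seeded_determinism(self, ref_solution):
        nm = NoiseModel(channel_snr_db=np.full(256, 40.0))
        a = synthesize_noisy_frame(ref_solution.frame, nm, np.random.default_rng(7))
        b = synthesize_noisy_frame(ref_solution.frame, nm, np.random.default_rng(7))
        c = synthesize_noisy_frame(ref_solution.frame, nm, np.random.default_rng(8))
        assert np.array_equal(a.voltages, b.voltages)
        assert not np.array_equal(a.voltages, c.voltages)

    def test_snr_estimator_unit_cases(self):
        wave = np.sin(np.linspace(0, 20 * np.pi, 400))
        assert estimate_snr(2 * wave, wave) == pytest.approx(0.0)  # residual = signal
        assert estimate_snr(wave, wave) == np.inf

    def test_snr_estimator_recovers_injected_power_ratio(self):
        """WGN at power ratio 100 reads ~20 dB over 1e4 samples."""
        rng = np.random.default_rng(9)
        n = 10_000
        t = np.arange(n)
        sig = np.sin(0.3 * t)
        sigma = np.sqrt(np.mean(sig**2) / 100.0)
        est = estimate_snr(sig + rng.normal(0, sigma, n), sig)
        assert abs(est - 20.0) < 0.5

    def test_snr_roundtrip_50db_over_500_frames(self, ref_solution):
        """Injected 50 dB re-estimated within 1 dB, averaging 500 frames."""
        nm = NoiseModel(channel_snr_db=np.full(256, 50.0))
        rng = np.random.default_rng(10)
        ch = 40  # one representative channel
        ests = []
        for _ in range(500):
            clean, noisy = synthesize_channel_waves(ref_solution.frame, nm, rng)
            ests.append(estimate_snr(noisy[ch], clean[ch]))
        assert abs(np.mean(ests) - 50.0) < 1.0

    def test_profile_anchors(self, protocol16):
        prof = snr_profile_adjacent(protocol16)
        assert prof.shape == (256,)
        pairs = protocol16.channel_pairs()
        dist = np.minimum((pairs[:, 1] - pairs[:, 0]) % 16, (pairs[:, 0] - pairs[:, 1]) % 16)
        assert np.all(prof[dist == 0] == 55.0)
        assert np.all(prof[dist == 8] == 8.0)


@pytest.fixture(scope="module")
def tiny_dataset(ref_mesh, gn_model, protocol16):
    return build_dataset(
        4, ref_mesh, gn_model, protocol16, np.random.default_rng(0),
        distortion=BoundaryPerturbation(), noise=NoiseModel(
            channel_snr_db=snr_profile_adjacent(protocol16)),
        n_targets=1,
    )


class TestDataset:

    def test_shapes_and_alignment(self, tiny_dataset, ref_mesh):
        ds = tiny_dataset
        assert ds.dv_clean.shape == (4, 256)
        assert ds.inputs_for("postprocess", noisy=True).shape == (4, ref_mesh.n_nodes)
        assert ds.inputs_for("direct", noisy=True).shape == (4, 256)
        assert ds.outputs.shape == (4, ref_mesh.n_nodes)
        assert len(ds.scenes) == 4

    def test_pure_function_of_seed(self, ref_mesh, gn_model, protocol16):
        kw = dict(distortion=BoundaryPerturbation(), noise=None, n_targets=1)
        a = build_dataset(2, ref_mesh, gn_model, protocol16, np.random.default_rng(3), **kw)
        b = build_dataset(2, ref_mesh, gn_model, protocol16, np.random.default_rng(3), **kw)
        assert np.array_equal(a.dv_clean, b.dv_clean)
        assert np.array_equal(a.truth_nodes, b.truth_nodes)

    def test_zero_distortion_no_noise_is_plain_gn(self, ref_mesh, gn_model, protocol16):
        """Without distortion and noise, inputs are GN images of the
        undistorted scenes exactly."""
        ds = build_dataset(
            2, ref_mesh, gn_model, protocol16, np.random.default_rng(4),
            distortion=None, noise=None, n_targets=1,
        )
        from eitpost.inverse import gn_reconstruct

        for i in range(2):
            assert np.allclose(ds.gn_clean[i], gn_reconstruct(gn_model, ds.dv_clean[i]))

    def test_distortion_leaves_inverse_mesh_alone(self, tiny_dataset, ref_mesh):
        assert tiny_dataset.mesh_hash == ref_mesh.content_hash()
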