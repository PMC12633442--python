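"""Phantom layout, U-arc and spurious bundle generation, and population draws."""
import numpy as np
import pytest

from safconn.atlas import ConnectionKey, build_atlas, build_connection_keys
from safconn.concordance import plausibility_heuristic
from safconn.phantom import (
    ConnectionProfile,
    PhantomConfig,
    PhantomError,
    generate_population,
    generate_spurious_bundle,
    generate_u_bundle,
    make_layout,
    roi_label_volume,
    simulate_observations,
)
from safconn.streamlines import read_tck, streamline_length, write_tck

KEY = ConnectionKey("8", "9")


class TestLayout:
    def test_default_layout_has_14_rois_inside_grid(self):
        layout = make_layout(0)
        assert len(layout.roi_centers) == 14
        lo = np.asarray(layout.grid.origin)
        hi = lo + np.asarray(layout.grid.shape) * layout.grid.voxel_size
        for c in layout.roi_centers.values():
            c = np.asarray(c)
            assert np.all(c - layout.roi_radius_mm >= lo)
            assert np.all(c + layout.roi_radius_mm <= hi)

    def test_same_seed_same_layout(self):
        assert make_layout(3).roi_centers == make_layout(3).roi_centers

    def test_oversized_roi_radius_rejected(self):
        with pytest.raises(PhantomError):
            make_layout(0, roi_radius_mm=60.0)

    def test_roi_label_volume_covers_all_areas(self):
        labels = roi_label_volume(make_layout(0))
        assert set(np.unique(labels)) == set(range(15))  # background + 14 ROIs


class TestUBundle:
    def test_zero_jitter_collapses_to_centroid_arc(self):
        layout = make_layout(0)
        config = PhantomConfig(seed=1, n_streamlines=5, streamline_jitter_sd_mm=0.0)
        bundle = generate_u_bundle(layout, KEY, config, (0,), n_streamlines=5)
        # endpoints still sampled in the ROI spheres, but control jitter is zero:
        # midpoints of all arcs coincide to within the ROI radius scale
        apexes = np.stack([s[len(s) // 2] for s in bundle.streamlines])
        assert np.all(np.std(apexes, axis=0) < 4.0)

    def test_deterministic_and_bit_identical_tck(self, tmp_path):
        layout = make_layout(0)
        config = PhantomConfig(seed=5, n_streamlines=10)
        b1 = generate_u_bundle(layout, KEY, config, (3, 1, 0, 2))
        b2 = generate_u_bundle(layout, KEY, config, (3, 1, 0, 2))
        p1 = write_tck(b1, tmp_path / "a.tck")
        p2 = write_tck(b2, tmp_path / "b.tck")
        assert p1.read_bytes() == p2.read_bytes()

    def test_endpoints_inside_roi_spheres_and_lengths_capped(self):
        layout = make_layout(0)
        config = PhantomConfig(seed=2, n_streamlines=50)
        for key in (KEY, ConnectionKey("11", "32")):
            bundle = generate_u_bundle(layout, key, config, (0, 0, 0, 1))
            a = layout.center(key.area_a)
            b = layout.center(key.area_b)
            for s in bundle.streamlines:
                assert streamline_length(s) <= 125.0
                assert np.linalg.norm(s[0] - a) <= layout.roi_radius_mm + 1e-9
                assert np.linalg.norm(s[-1] - b) <= layout.roi_radius_mm + 1e-9

    def test_plausible_and_spurious_separate_under_heuristic(self):
        layout = make_layout(0)
        config = PhantomConfig(seed=0, n_streamlines=8)
        n_ok = 0
        for rep in range(200):
            bundle = generate_u_bundle(layout, KEY, config, (10, rep))
            n_ok += plausibility_heuristic(bundle)
        assert n_ok >= 190  # >= 95% of draws
        n_bad = 0
        for rep in range(200):
            bundle = generate_spurious_bundle(layout, KEY, config, (11, rep))
            n_bad += not plausibility_heuristic(bundle)
        assert n_bad >= 190

    def test_spurious_bundle_respects_streamline_budget(self):
        layout = make_layout(0)
        config = PhantomConfig(seed=0, n_streamlines=7)
        assert len(generate_spurious_bundle(layout, KEY, config, (1,))) == 7


class TestPopulation:
    def test_presence_probability_extremes(self):
        keys = [KEY, ConnectionKey("9", "46")]
        layout = make_layout(0)
        config = PhantomConfig(
            n_subjects=4,
            seed=0,
            n_streamlines=4,
            profiles={
                keys[0]: ConnectionProfile(presence_probability=1.0),
                keys[1]: ConnectionProfile(presence_probability=0.0),
            },
        )
        pop = generate_population(layout, config, keys=keys)
        for s in range(4):
            assert len(pop.bundle(f"sub-{s:03d}", "test", keys[0])) == 4
            assert len(pop.bundle(f"sub-{s:03d}", "test", keys[1])) == 0

    def test_presence_fraction_concentrates(self):
        key = KEY
        config = PhantomConfig(
            n_subjects=500,
            seed=12,
            profiles={key: ConnectionProfile(presence_probability=0.6)},
        )
        observations = simulate_observations(config, keys=[key])[key]
        fraction = np.mean([o.present for o in observations])
        assert abs(fraction - 0.6) <= 0.05

    def test_observation_fast_path_matches_geometric_presence(self):
        keys = build_connection_keys(build_atlas())[:6]
        layout = make_layout(0)
        config = PhantomConfig(
            n_subjects=3,
            seed=9,
            n_streamlines=3,
            default_profile=ConnectionProfile(presence_probability=0.5),
        )
        pop = generate_population(layout, config, keys=keys)
        fast = simulate_observations(config, keys=keys)
        for c, key in enumerate(keys):
            for s in range(3):
                geometric = len(pop.bundle(f"sub-{s:03d}", "test", key)) > 0
                assert fast[key][s].present == geometric

    def test_population_files_round_trip(self, tmp_path):
        layout = make_layout(0)
        config = PhantomConfig(n_subjects=2, sessions=2, seed=4, n_streamlines=3)
        pop = generate_population(layout, config, keys=[KEY], out_dir=tmp_path)
        assert (tmp_path / "truth.csv").exists()
        assert (tmp_path / "config.json").exists()
        name = f"sub-000_test_{KEY.area_a}-{KEY.area_b}".replace("/", "x")
        back = read_tck(tmp_path / "tck" / f"{name}.tck")
        expected = pop.bundle("sub-000", "test", KEY)
        assert len(back) == len(expected)

    def test_sessions_share_subject_presence(self):
        layout = make_layout(0)
        config = PhantomConfig(
            n_subjects=6, sessions=2, seed=2, n_streamlines=2,
            default_profile=ConnectionProfile(presence_probability=0.5),
        )
        pop = generate_population(layout, config, keys=[KEY])
        for s in range(6):
            test = len(pop.bundle(f"sub-{s:03d}", "test", KEY)) > 0
            retest = len(pop.bundle(f"sub-{s:03d}", "retest", KEY)) > 0
            assert test == retest
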