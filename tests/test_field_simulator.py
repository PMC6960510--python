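import numpy as np
import pandas as pd
import pytest

from furrowscan import field_simulator as fsim
from furrowscan import protocol
from furrowscan.errors import LayoutError

from conftest import make_gradient_scene


def small_scene(**kw):
    defaults = dict(seed=1, n_accessions=4, n_checks=1, check_reps=2,
                    blocks=1, n_cols=2, n_ranges=3)
    defaults.update(kw)
    return fsim.generate_field(**defaults)


class TestGenerateField:
    def test_default_design_fills_1728_plots(self):
        scene = fsim.generate_field(seed=2)
        plots = scene.layout.plots
        assert len(plots) == 1728
        # each block: every accession once, each check 10 times
        for _, block in plots.groupby("block"):
            counts = block["genotype"].value_counts()
            assert (counts.loc[counts.index.str.startswith("G")] == 1).all()
            assert (counts.loc[counts.index.str.startswith("CHK")] == 10).all()
        assert set(plots["treatment"]) == set(fsim.TREATMENTS)
        assert plots.groupby("treatment").size().nunique() == 1

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(LayoutError):
            fsim.generate_field(seed=1, n_accessions=100)  # != 288/block
        with pytest.raises(LayoutError):
            fsim.generate_field(seed=1, n_cols=70)  # not divisible by blocks

    def test_zero_genetic_variance_gives_equal_genotype_means(self):
        scene = fsim.generate_field(seed=3, sigma_g_m=0.0, sigma_e_m=0.0)
        df = scene.layout.plots.assign(
            ch=scene.plants["canopy_height_m"].to_numpy())
        per_treatment = df.groupby("treatment")["ch"].nunique()
        assert (per_treatment == 1).all()

    def test_same_seed_reproduces_scene(self):
        a, b = fsim.generate_field(seed=9), fsim.generate_field(seed=9)
        pd.testing.assert_frame_equal(a.layout.plots, b.layout.plots)
        pd.testing.assert_frame_equal(a.plants, b.plants)


class TestRaycast:
    def test_bare_soil_nadir_equals_mount_height(self, geom):
        scene = small_scene(mu_ch_m=(0.0, 0.0), sigma_g_m=0.0, sigma_e_m=0.0,
                            soil_roughness_mm=0.0)
        scene.plants["canopy_height_m"] = 0.0
        sweep = fsim.raycast_sweep(
            scene, scene.layout.column_center_easting(0),
            scene.layout.origin_northing + 1.0, 1682.0, geom,
            np.random.default_rng(0))
        assert sweep[geom.nadir_index] == 1682

    def test_bare_soil_oblique_follows_secant_law(self, geom):
        scene = small_scene(soil_roughness_mm=0.0)
        scene.plants["canopy_height_m"] = 0.0
        sweep = fsim.raycast_sweep(
            scene, scene.layout.column_center_easting(0),
            scene.layout.origin_northing + 1.0, 1682.0, geom,
            np.random.default_rng(0))
        expected = 1682.0 / np.cos(np.radians(geom.angles()))
        assert np.all(np.abs(sweep - expected) <= 1.0)

    def test_opaque_slab_returns_mount_minus_height_at_nadir(self, geom):
        scene = small_scene(soil_roughness_mm=0.0)
        # rows widened and recentered into one opaque slab over the furrow
        scene.plants["canopy_height_m"] = 0.8
        scene.plants["porosity"] = 0.0
        scene.plants["row_halfwidth_m"] = 0.37
        scene.plants["row_offset_m"] = 0.0
        sweep = fsim.raycast_sweep(
            scene, scene.layout.column_center_easting(0),
            scene.layout.origin_northing + 1.0, 1682.0, geom,
            np.random.default_rng(0))
        assert abs(int(sweep[geom.nadir_index]) - (1682 - 800)) <= 1

    def test_hit_fraction_monotone_in_cover(self, geom):
        fractions = []
        for cover in (0.2, 0.45, 0.7):
            scene = small_scene(soil_roughness_mm=0.0)
            scene.plants["canopy_height_m"] = 1.0
            scene.plants["cover_fraction"] = cover
            scene.plants["row_halfwidth_m"] = fsim._cover_to_halfwidth(
                np.full(6, cover), np.full(6, 0.25), 0.76)
            rng = np.random.default_rng(42)
            x = scene.layout.column_center_easting(0)
            ys = scene.layout.origin_northing + np.linspace(0.2, 3.4, 40)
            block = fsim.raycast_block(scene, x, ys, 2230.0, geom, rng)
            z = block * np.cos(np.radians(geom.angles()))
            plant = (2230.0 - z) > 50
            fractions.append(plant.mean())
        assert fractions[0] < fractions[1] < fractions[2]

    def test_hit_fraction_converges_to_effective_cover(self, geom):
        scene = small_scene(soil_roughness_mm=0.0)
        scene.plants["canopy_height_m"] = 1.0
        pid = 1
        expected = fsim.expected_plot_cover(scene, pid, geom, 2230.0)
        lay = scene.layout
        col, rng_i = divmod(pid, lay.n_ranges)
        x = lay.column_center_easting(col)
        y0 = lay.origin_northing + rng_i * lay.range_pitch
        ys = y0 + np.linspace(0.1, 3.5, 120)
        block = fsim.raycast_block(scene, x, ys, 2230.0, geom,
                                   np.random.default_rng(3))
        from furrowscan.trait_extraction import CalibrationState, extract_block
        calib = CalibrationState(2230.0, (2230.0, 2230.0))
        out = extract_block(block, calib, geom)
        n_beams = (out["n_plant"] + out["n_soil"]).sum()
        sd = np.sqrt(expected * (1 - expected) / n_beams)
        assert out["cc_frac"].mean() == pytest.approx(expected, abs=3 * sd + 0.01)


class TestSession:
    def test_transect_record_count_formula(self):
        assert fsim.transect_record_count(10.0, 0.096) == 105
        assert fsim.transect_record_count(0.0, 0.096) == 1
        # exact multiple keeps the endpoint sweep
        assert fsim.transect_record_count(0.96, 0.096) == 11

    def test_sweep_spacing_is_096_m(self):
        track = fsim.PlatformTrack()
        assert track.sweep_spacing_m == pytest.approx(0.096)
        assert round(track.sweep_spacing_m, 1) == 0.1

    def test_session_files_and_record_counts(self, tmp_path, geom):
        scene = small_scene()
        track = fsim.PlatformTrack()
        res = fsim.simulate_session(scene, track, seed=4, out_dir=tmp_path)
        expected = fsim.transect_record_count(
            scene.layout.field_length, track.sweep_spacing_m)
        assert res.n_records_per_sensor == expected
        for path in (res.dat00, res.dat01):
            records, skipped = protocol.read_dat(path)
            assert skipped == 0
            assert len(records) == expected

    def test_recording_paused_outside_field(self, tmp_path):
        scene = small_scene()
        res = fsim.simulate_session(scene, fsim.PlatformTrack(), seed=5,
                                    out_dir=tmp_path)
        lay = scene.layout
        for path in (res.dat00, res.dat01):
            records, _ = protocol.read_dat(path)
            n = np.array([r.northing for r in records])
            assert np.all(n >= lay.origin_northing - 1e-3)
            assert np.all(n <= lay.origin_northing + lay.field_length + 1e-3)

    def test_interlaced_sensors_share_cycle_timestamps(self, tmp_path):
        scene = small_scene()
        res = fsim.simulate_session(scene, fsim.PlatformTrack(), seed=6,
                                    out_dir=tmp_path)
        r00, _ = protocol.read_dat(res.dat00)
        r01, _ = protocol.read_dat(res.dat01)
        ms00 = protocol.parse_message(r00[10].message).timestamp_ms
        ms01 = protocol.parse_message(r01[10].message).timestamp_ms
        assert ms01 - ms00 == 110  # unit 01 trails its cycle partner

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        scene = small_scene()
        a = fsim.simulate_session(scene, fsim.PlatformTrack(), seed=8,
                                  out_dir=tmp_path / "a")
        b = fsim.simulate_session(scene, fsim.PlatformTrack(), seed=8,
                                  out_dir=tmp_path / "b")
        assert a.dat00.read_bytes() == b.dat00.read_bytes()
        assert a.dat01.read_bytes() == b.dat01.read_bytes()

    def test_truth_table_monotone_cover_in_height(self):
        scene = make_gradient_scene(n_cols=2, n_ranges=6)
        from furrowscan.sweep_geometry import SensorGeometry
        t = fsim.truth_table(scene, SensorGeometry(), 2230.0)
        assert t["true_cc_pct"].is_monotonic_increasing
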