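"""Synthetic frame generator: statistics, conservation, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from ssxkit.config import PipelineConfig, SimulationParams
from ssxkit.crystal import SymmetryInfo, UnitCell
from ssxkit.geometry import pixel_to_q
from ssxkit.physics import edge_resolution
from ssxkit.prediction import predict_still
from ssxkit.simulator import (CrystalEvent, background_lambda, random_rotation,
                              render_frame, sample_crystal_events,
                              sample_structure_factors, simulate_dataset)

CELL = UnitCell(79.5, 79.4, 38.4)
SYM = SymmetryInfo()


class TestStructureFactors:
    def test_wilson_falloff_and_flat_limit(self):
        sf = sample_structure_factors(CELL, SYM, 2.1, wilson_b=44.1, seed=1)
        d = CELL.d_spacing(sf.hkl)
        s2 = 1.0 / d ** 2
        lo = sf.amplitude[s2 < 0.05] ** 2
        hi = sf.amplitude[s2 > 0.18] ** 2
        expected_ratio = math.exp(-44.1 * (np.mean(s2[s2 > 0.18]) -
                                           np.mean(s2[s2 < 0.05])) / 2)
        assert hi.mean() / lo.mean() == pytest.approx(expected_ratio, rel=0.2)
        flat = sample_structure_factors(CELL, SYM, 2.1, wilson_b=0.0, seed=1)
        lo_f = flat.amplitude[s2 < 0.05] ** 2
        hi_f = flat.amplitude[s2 > 0.18] ** 2
        assert hi_f.mean() / lo_f.mean() == pytest.approx(1.0, abs=0.1)

    def test_absences_not_generated(self):
        sf = sample_structure_factors(CELL, SYM, 2.5, wilson_b=44.1, seed=1)
        assert not SYM.is_absent(sf.hkl).any()
        assert sf.intensity_lookup(np.array([[0, 0, 2]]))[0] == 0.0

    def test_symmetry_mates_share_amplitude(self):
        sf = sample_structure_factors(CELL, SYM, 3.0, wilson_b=20.0, seed=3)
        a = sf.intensity_lookup(np.array([[3, 5, 2]]))[0]
        for op in SYM.laue_operations():
            assert sf.intensity_lookup((op @ np.array([3, 5, 2]))[None, :])[0] == a


class TestCrystalEvents:
    def test_poisson_hit_fraction(self):
        cfg = PipelineConfig()
        events = sample_crystal_events(cfg, 4000, seed=5)
        frac = np.mean([len(e) >= 1 for e in events])
        expect = 1 - math.exp(-0.3)
        assert frac == pytest.approx(expect, abs=3 * math.sqrt(expect * (1 - expect) / 4000))

    def test_zero_rate_all_blank(self):
        cfg = PipelineConfig(simulation=SimulationParams(mean_crystals_per_frame=0.0))
        events = sample_crystal_events(cfg, 50, seed=1)
        assert all(len(e) == 0 for e in events)

    def test_orientations_uniform(self):
        # Haar measure: the mean rotation matrix vanishes
        R = random_rotation(np.random.default_rng(7), 4000)
        assert np.abs(R.mean(axis=0)).max() < 0.05
        assert np.allclose(np.einsum("nij,nkj->nik", R, R), np.eye(3), atol=1e-12)

    def test_transit_times_within_bounds(self):
        cfg = PipelineConfig()
        events = sample_crystal_events(cfg, 300, seed=2, force_singles=True)
        t = np.array([e[0].transit_time_ms for e in events])
        lo, hi = cfg.simulation.transit_time_range_ms
        assert t.min() >= lo and t.max() <= hi


class TestPrediction:
    def test_exact_bragg_full_partiality(self):
        pred = predict_still(np.eye(3), CELL, SYM, PipelineConfig().beam,
                             PipelineConfig().detector, d_min=2.0)
        assert len(pred) > 0
        assert np.all((pred.partiality >= 0) & (pred.partiality <= 1))
        near = np.abs(pred.excitation) < 0.05 * pred.sigma
        assert np.all(pred.partiality[near] > 0.99)

    def test_bandwidth_widens_acceptance(self, small_config):
        det = small_config.detector
        counts = []
        for bw in (1e-4, 1e-3, 5e-3):
            beam = PipelineConfig().beam.__class__(bandwidth=bw)
            n = [len(predict_still(random_rotation(np.random.default_rng(s)),
                                   CELL, SYM, beam, det, d_min=2.1))
                 for s in range(5)]
            counts.append(np.mean(n))
        assert counts[0] < counts[1] < counts[2]

    def test_absent_reflections_never_predicted(self):
        pred = predict_still(np.eye(3), CELL, SYM, PipelineConfig().beam,
                             PipelineConfig().detector, d_min=2.0,
                             mosaicity_deg=2.0)  # wide window, many spots
        h, k, l = pred.hkl.T
        on_l_axis = (h == 0) & (k == 0)
        assert not np.any(on_l_axis & (l % 4 != 0))

    def test_edge_reflection_lands_at_edge_radius(self, small_config):
        # a reflection at the center-edge resolution must project at the
        # center-edge distance from the beam center
        det, beam = small_config.detector, small_config.beam
        d_edge = edge_resolution(det, beam)
        pred = predict_still(random_rotation(np.random.default_rng(3)), CELL,
                             SYM, beam, det, d_min=d_edge * 0.98)
        qlen = np.linalg.norm(pred.q, axis=1)
        sel = pred.on_panel & (np.abs(1 / qlen - d_edge) / d_edge < 0.01)
        assert sel.any()
        r_px = np.hypot(pred.fast[sel] - det.beam_center_fast,
                        pred.slow[sel] - det.beam_center_slow)
        r_expect = min(det.beam_center_fast, det.beam_center_slow,
                       det.n_fast - det.beam_center_fast,
                       det.n_slow - det.beam_center_slow)
        assert np.all(np.abs(r_px - r_expect) / r_expect < 0.02)

    def test_symmetry_mates_of_orientation_equivalent(self):
        cellt = UnitCell.tetragonal(79.5, 38.4)
        cfg = PipelineConfig()
        base = predict_still(np.eye(3), cellt, SYM, cfg.beam, cfg.detector, 2.5)
        # rotating the crystal by the 2-fold about c is a lattice symmetry:
        # the predicted ASU intensity list must be identical
        r2z = np.diag([-1.0, -1.0, 1.0])
        rot = predict_still(r2z, cellt, SYM, cfg.beam, cfg.detector, 2.5)
        asu_a = {tuple(h) for h in SYM.map_to_asu(base.hkl)}
        asu_b = {tuple(h) for h in SYM.map_to_asu(rot.hkl)}
        assert asu_a == asu_b


class TestRendering:
    def test_no_events_zero_background(self, small_config):
        cfg = small_config.replace(simulation=SimulationParams(
            background_flat=0.0, ring_amplitude=0.0))
        sf = sample_structure_factors(CELL, SYM, 2.1, 44.1, seed=1)
        image, truth = render_frame([], sf, cfg, seed=0)
        assert image.sum() == 0 and len(truth) == 0

    def test_photon_conservation_noiseless(self, clean_config):
        cfg = clean_config
        sf = sample_structure_factors(CELL, SYM, cfg.simulation.d_min, 44.1, seed=1)
        events = sample_crystal_events(cfg, 1, seed=4, force_singles=True)[0]
        image, truth = render_frame(events, sf, cfg, seed=0, poisson=False)
        bg = background_lambda(cfg.detector, cfg.beam, cfg.simulation)
        spot_integral = image.sum() - bg.sum()
        # PSF tails beyond the ±4σ stamp lose <0.1%
        assert spot_integral == pytest.approx(truth["photons"].sum(), rel=2e-3)

    def test_photon_conservation_poisson(self, clean_config):
        cfg = clean_config
        sf = sample_structure_factors(CELL, SYM, cfg.simulation.d_min, 44.1, seed=1)
        events = sample_crystal_events(cfg, 1, seed=4, force_singles=True)[0]
        image, truth = render_frame(events, sf, cfg, seed=0)
        bg = background_lambda(cfg.detector, cfg.beam, cfg.simulation)
        total_expected = bg.sum() + truth["photons"].sum()
        assert abs(image.sum() - total_expected) < 5 * math.sqrt(total_expected)

    def test_transit_scaling(self, clean_config):
        cfg = clean_config
        sf = sample_structure_factors(CELL, SYM, cfg.simulation.d_min, 44.1, seed=1)
        base = sample_crystal_events(cfg, 1, seed=4, force_singles=True)[0][0]
        ev1 = CrystalEvent(orientation=base.orientation, transit_time_ms=1.5)
        ev2 = CrystalEvent(orientation=base.orientation, transit_time_ms=3.0)
        _, t1 = render_frame([ev1], sf, cfg, seed=0, poisson=False)
        _, t2 = render_frame([ev2], sf, cfg, seed=0, poisson=False)
        assert t2["photons"].sum() == pytest.approx(2 * t1["photons"].sum(), rel=1e-9)

    def test_arc_smear_geometry(self, small_config):
        cfg = small_config.replace(simulation=SimulationParams(
            background_flat=0.0, ring_amplitude=0.0, rolling_fraction=1.0))
        sf = sample_structure_factors(CELL, SYM, cfg.simulation.d_min, 44.1, seed=1)
        ev = sample_crystal_events(cfg, 1, seed=6, force_singles=True)[0][0]
        assert ev.arc_angle_deg == 5.0
        image, truth = render_frame([ev], sf, cfg, seed=0, poisson=False)
        det = cfg.detector
        # pick the brightest truth spot, look at illuminated pixels near it
        spot = truth.sort_values("photons").iloc[-1]
        r0 = math.hypot(spot.fast - det.beam_center_fast,
                        spot.slow - det.beam_center_slow)
        ys, xs = np.nonzero(image > 0.05 * image.max())
        r = np.hypot(xs - det.beam_center_fast, ys - det.beam_center_slow)
        ang = np.degrees(np.arctan2(ys - det.beam_center_slow,
                                    xs - det.beam_center_fast))
        ang0 = math.degrees(math.atan2(spot.slow - det.beam_center_slow,
                                       spot.fast - det.beam_center_fast))
        near = np.abs(r - r0) < 3.0
        dphi = (ang[near] - ang0 + 180) % 360 - 180
        local = np.abs(dphi) < 6.0
        # radius preserved within ±0.5 px over the arc, span ≈ 5°
        assert np.abs(r[near][local] - r0).max() <= 2.5  # PSF width included
        span = dphi[local].max() - dphi[local].min()
        assert 3.0 <= span <= 8.0


class TestDataset:
    def test_seed_determinism(self, small_config):
        a = simulate_dataset(small_config, 2, seed=9, force_singles=True)
        b = simulate_dataset(small_config, 2, seed=9, force_singles=True)
        assert np.array_equal(a.images, b.images)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_save_load_round_trip(self, small_config, tmp_path):
        stack = simulate_dataset(small_config, 2, seed=9, force_singles=True)
        path = tmp_path / "stack.h5"
        stack.save(path)
        back = stack.load(path)
        assert np.array_equal(back.images, stack.images)
        assert back.detector == stack.detector and back.beam == stack.beam

    def test_memory_guard(self):
        cfg = PipelineConfig()
        with pytest.raises(MemoryError):
            simulate_dataset(cfg, 500, seed=0, max_memory_bytes=1 << 20)

    def test_default_geometry_is_the_experiment(self):
        cfg = PipelineConfig()
        assert cfg.beam.photon_energy == 9800.0
        assert cfg.detector.distance == 300.0
        assert cfg.flow.inner_diameter == 100.0
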