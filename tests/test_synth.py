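"""Synthetic emulsion generator: Poisson loading, forward kinetics,
rendering fidelity and determinism."""

import numpy as np
import pytest
from scipy import stats

from dropmap import synth
from dropmap.config import (
    AcquisitionSchedule,
    AssayChemistry,
    CohortSpec,
    EmulsionConfig,
    NoiseModel,
)
from dropmap.core import GroundTruthCell


class TestEmulsionSampling:
    def test_zero_occupancy_gives_empty_droplets(self):
        cfg = EmulsionConfig(n_droplets=200, mean_occupancy=0.0)
        droplets, cells = synth.sample_emulsion(cfg, np.random.default_rng(0))
        assert all(d.n_cells == 0 for d in droplets)
        assert cells == []

    def test_one_or_two_cell_count_matches_poisson_mass(self):
        # 80,000 * (0.3 + 0.3^2/2) exp(-0.3) = 20,449 droplets expected
        cfg = EmulsionConfig(n_droplets=80_000, mean_occupancy=0.3)
        droplets, _ = synth.sample_emulsion(cfg, np.random.default_rng(123))
        counts = np.array([d.n_cells for d in droplets])
        n12 = int(np.sum((counts == 1) | (counts == 2)))
        assert n12 == pytest.approx(20_449, rel=0.02)

    def test_default_volume_from_density_and_occupancy(self):
        # 0.3 cells/droplet at 30e6 cells/mL implies 10 pL per droplet
        implied_ml = 0.3 / 30e6
        assert implied_ml * 1e-3 == pytest.approx(1.0e-11)
        assert EmulsionConfig().droplet_volume_l == pytest.approx(implied_ml * 1e-3)

    def test_occupancy_histogram_matches_poisson_chisquare(self):
        lam = 0.3
        cfg = EmulsionConfig(n_droplets=100_000, mean_occupancy=lam)
        droplets, _ = synth.sample_emulsion(cfg, np.random.default_rng(42))
        counts = np.array([d.n_cells for d in droplets])
        kmax = 4
        observed = np.array(
            [np.sum(counts == k) for k in range(kmax)] + [np.sum(counts >= kmax)]
        )
        pmf = stats.poisson.pmf(np.arange(kmax), lam)
        expected = np.append(pmf, 1.0 - pmf.sum()) * len(counts)
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.01

    def test_droplets_do_not_overlap(self):
        cfg = EmulsionConfig(n_droplets=100)
        droplets, _ = synth.sample_emulsion(cfg, np.random.default_rng(3))
        centers = np.array([(d.cy, d.cx) for d in droplets])
        from scipy.spatial.distance import pdist

        assert pdist(centers).min() >= 2 * cfg.droplet_radius_px

    def test_chamber_too_small_raises(self):
        cfg = EmulsionConfig(n_droplets=500, chamber_shape=(60, 60))
        with pytest.raises(synth.PlacementError):
            synth.sample_emulsion(cfg, np.random.default_rng(0))


class TestForwardKinetics:
    def make_cell(self, s, kd):
        return GroundTruthCell(
            0, secretion_rate=s, kd=kd, is_igg_secretor=s > 0, n_cells_in_droplet=1
        )

    def test_no_secretion_means_no_relocation(self):
        tr = synth.forward_kinetics(
            self.make_cell(0.0, 30e-9), AssayChemistry(), AcquisitionSchedule(), 1e-11
        )
        assert np.allclose(tr.r_red, 1.0)
        assert np.allclose(tr.r_green, 1.0)

    @pytest.mark.parametrize("s", [4.0, 33.0, 200.0, 800.0])
    def test_relocation_starts_at_one_and_is_nondecreasing(self, s):
        tr = synth.forward_kinetics(
            self.make_cell(s, 30e-9), AssayChemistry(), AcquisitionSchedule(), 1e-11
        )
        assert tr.r_red[0] == pytest.approx(1.0)
        assert tr.r_green[0] == pytest.approx(1.0)
        assert np.all(np.diff(tr.r_red) > 0)
        assert np.all(np.diff(tr.r_green) > 0)

    def test_green_signal_decreases_with_kd(self):
        chem, sched = AssayChemistry(), AcquisitionSchedule()
        kds = np.array([0.5, 2.3, 10.0, 30.0, 65.0, 100.0]) * 1e-9
        finals = [
            synth.forward_kinetics(self.make_cell(50.0, kd), chem, sched, 1e-11).r_green[-1]
            for kd in kds
        ]
        assert np.all(np.diff(finals) < 0)

    def test_capture_capacity_saturates_trace(self):
        chem = AssayChemistry(capture_capacity=1e4)
        tr = synth.forward_kinetics(
            self.make_cell(100.0, 30e-9), chem, AcquisitionSchedule(), 1e-11
        )
        # 1e4 molecules reached within the first interval: flat afterwards
        assert tr.r_red[-1] == pytest.approx(tr.r_red[1], rel=1e-12)


class TestRendering:
    def test_no_relocation_beadline_equals_background(self, sched, noiseless):
        cfg = EmulsionConfig(n_droplets=9, mean_occupancy=0.0)
        droplets, _ = synth.sample_emulsion(cfg, np.random.default_rng(0))
        red, green, _ = synth.render_stack(
            droplets, {}, noiseless, sched, synth.chamber_shape_for(cfg),
            np.random.default_rng(0),
        )
        from dropmap.imaging import analyze_stack

        for obs in analyze_stack(red, green, sched):
            for ch in ("red", "green"):
                assert np.allclose(
                    obs.beadline_mean[ch], obs.background_mean[ch], rtol=1e-6
                )

    def test_rendered_trace_round_trip_within_one_percent(
        self, small_secretor_stack, sched
    ):
        """Measured beadline/background ratios reproduce the input traces."""
        from scipy.spatial import cKDTree

        from dropmap.imaging import analyze_stack, compute_relocation

        s = small_secretor_stack
        obs = analyze_stack(s["red"], s["green"], sched)
        assert len(obs) == len(s["droplets"])
        tree = cKDTree([(d.cy, d.cx) for d in s["droplets"]])
        for o in obs:
            _, i = tree.query([o.cy, o.cx])
            truth = s["traces"][s["droplets"][i].droplet_id]
            meas = compute_relocation(o, sched.times_min())
            assert np.allclose(meas.r_red, truth.r_red, rtol=0.01)
            assert np.allclose(meas.r_green, truth.r_green, rtol=0.01)

    def test_stack_determinism_byte_for_byte(self, sched, noiseless):
        def run():
            rng = np.random.default_rng(99)
            cfg = EmulsionConfig(n_droplets=50, rng_seed=99)
            d, c, t = synth.sample_cohort(
                cfg, CohortSpec(), AssayChemistry(), sched, rng
            )
            red, green, _ = synth.render_stack(
                d, t, NoiseModel(), sched, synth.chamber_shape_for(cfg), rng
            )
            return red, green

        r1, g1 = run()
        r2, g2 = run()
        assert r1.tobytes() == r2.tobytes()
        assert g1.tobytes() == g2.tobytes()

    def test_overflow_clips_with_warning(self, sched, noiseless):
        chem = AssayChemistry()
        cfg, droplets, _, traces = synth.make_secretor_cohort(
            [800.0], 1e-9, chem, sched
        )
        with pytest.warns(UserWarning, match="clip"):
            red, _, _ = synth.render_stack(
                droplets, traces, noiseless, sched, synth.chamber_shape_for(cfg),
                np.random.default_rng(0), base_intensity=(60000.0, 60000.0),
            )
        assert red.max() == 65535

    def test_stacks_are_uint16(self, small_secretor_stack):
        assert small_secretor_stack["red"].dtype == np.uint16
        assert small_secretor_stack["green"].dtype == np.uint16


class TestCohortSampling:
    def test_secretors_only_in_occupied_droplets(self, chem, sched):
        rng = np.random.default_rng(5)
        cfg = EmulsionConfig(n_droplets=500)
        droplets, cells, traces = synth.sample_cohort(
            cfg, CohortSpec(), chem, sched, rng
        )
        occupied = {d.droplet_id for d in droplets if d.n_cells > 0}
        assert set(traces).issubset(occupied)
        for c in cells:
            if c.is_igg_secretor:
                assert c.secretion_rate >= 4.0
                assert c.kd > 0

    def test_dataset_write_read_round_trip(self, tmp_path, small_secretor_stack):
        s = small_secretor_stack
        truth = synth.ground_truth_table(s["info"], s["cells"])
        out = synth.write_dataset(tmp_path / "ds", s["red"], s["green"], truth)
        red2 = synth.read_stack(out / "red.tif")
        assert np.array_equal(red2, s["red"])

    def test_corrupt_tiff_raises_with_filename(self, tmp_path):
        bad = tmp_path / "broken.tif"
        bad.write_text("this is not a TIFF")
        with pytest.raises(ValueError, match="broken.tif"):
            synth.read_stack(bad)
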