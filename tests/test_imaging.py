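"""Segmentation, beadline location, relocation extraction and QC."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from dropmap import synth
from dropmap.config import EmulsionConfig, NoiseModel
from dropmap.core import (
    FLAG_BG_INVALID,
    FLAG_EDGE,
    FLAG_MOVED,
    FLAG_MULTI_CELL,
    RelocationTrace,
)
from dropmap.imaging import (
    DropletObservation,
    analyze_stack,
    compute_relocation,
    locate_beadline,
    qc_droplet,
    segment_droplets,
)


def draw_disks(shape, centers, radius, value=2000.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img


class TestSegmentation:
    def test_fifty_disks_recovered_with_subpixel_centers(self):
        rng = np.random.default_rng(0)
        cfg = EmulsionConfig(n_droplets=50)
        droplets, _ = synth.sample_emulsion(cfg, rng)
        shape = synth.chamber_shape_for(cfg)
        img = draw_disks(shape, [(d.cy, d.cx) for d in droplets], cfg.droplet_radius_px)
        regions = segment_droplets(img)
        assert len(regions) == 50  # recall and precision 1.0
        tree = cKDTree([(d.cy, d.cx) for d in droplets])
        dists, _ = tree.query([(g.cy, g.cx) for g in regions])
        assert np.all(dists <= 1.0)

    def test_blank_image_yields_empty_list_with_warning(self):
        with pytest.warns(UserWarning, match="no droplets"):
            assert segment_droplets(np.zeros((64, 64))) == []

    def test_border_disk_flagged_edge(self):
        img = draw_disks((60, 60), [(0, 30), (30, 30)], 9)
        regions = segment_droplets(img)
        edges = {g.touches_edge for g in regions}
        assert edges == {True, False}


class TestBeadline:
    def test_mask_overlaps_rendered_bar(self, small_secretor_stack, sched):
        s = small_secretor_stack
        regions = segment_droplets(
            s["red"][0].astype(float) + s["green"][0].astype(float)
        )
        tree = cKDTree([(d.cy, d.cx) for d in s["droplets"]])
        for g in regions:
            _, i = tree.query([g.cy, g.cx])
            d = s["droplets"][i]
            ext = synth.beadline_extent(d.radius_px)
            true_px = {
                (y, x)
                for y in range(d.cy - 1, d.cy + 2)
                for x in range(d.cx - ext, d.cx + ext + 1)
            }
            rr, cc, _ = locate_beadline(g)
            got = set(zip(rr.tolist(), cc.tolist()))
            iou = len(got & true_px) / len(got | true_px)
            assert iou >= 0.7

    def test_uniform_droplet_falls_back_to_center_bar(self):
        img = draw_disks((40, 40), [(20, 20)], 9)
        (g,) = segment_droplets(img)
        rr, cc, suspicious = locate_beadline(g, img)
        assert not suspicious
        # elongated, axis-centered: 3 rows through the centroid row
        assert set(rr.tolist()) == {19, 20, 21}
        aspect = (cc.max() - cc.min() + 1) / 3
        assert aspect >= 3

    def test_offcenter_speck_keeps_mask_centered_and_flags(self):
        img = draw_disks((40, 40), [(20, 20)], 9)
        img[14:16, 20:22] = 6000.0  # bright artifact above the axis
        (g,) = segment_droplets(img)
        rr, cc, suspicious = locate_beadline(g, img)
        assert set(rr.tolist()) == {19, 20, 21}  # still axis-centered
        assert suspicious


class TestRelocation:
    def make_obs(self, bead, bg):
        n = len(bead)
        return DropletObservation(
            droplet_id=0, cx=10, cy=10, radius=9,
            beadline_mean={"red": np.array(bead, float), "green": np.array(bead, float)},
            background_mean={"red": np.array(bg, float), "green": np.array(bg, float)},
        )

    def test_equal_means_give_unity(self):
        obs = self.make_obs([100] * 6, [100] * 6)
        tr = compute_relocation(obs, np.arange(6) * 7.5)
        assert np.allclose(tr.r_red, 1.0)

    def test_double_beadline_gives_two(self):
        obs = self.make_obs([200] * 6, [100] * 6)
        tr = compute_relocation(obs, np.arange(6) * 7.5)
        assert np.allclose(tr.r_red, 2.0)

    def test_nonpositive_background_discards_droplet(self):
        obs = self.make_obs([100] * 6, [100, 100, 0, 100, 100, 100])
        assert compute_relocation(obs, np.arange(6) * 7.5) is None
        assert FLAG_BG_INVALID in obs.qc_flags

    @pytest.mark.parametrize("scale", [0.25, 3.0])
    def test_relocation_is_scale_invariant(self, small_secretor_stack, sched, scale):
        """Multiplying every pixel by a constant leaves all traces unchanged."""
        s = small_secretor_stack
        obs_a = analyze_stack(s["red"], s["green"], sched)
        obs_b = analyze_stack(
            s["red"].astype(float) * scale, s["green"].astype(float) * scale, sched
        )
        assert len(obs_a) == len(obs_b)
        for a, b in zip(obs_a, obs_b):
            ta = compute_relocation(a, sched.times_min())
            tb = compute_relocation(b, sched.times_min())
            assert np.allclose(ta.r_red, tb.r_red, rtol=1e-9)
            assert np.allclose(ta.r_green, tb.r_green, rtol=1e-9)


class TestQc:
    def test_static_single_cell_droplet_has_no_flags(self):
        pos = np.tile([10.0, 10.0], (6, 1))
        assert qc_droplet(pos, n_cells=1, has_artifact=False, touches_edge=False) == set()

    def test_three_cells_flag_multi_cell(self):
        pos = np.tile([10.0, 10.0], (6, 1))
        flags = qc_droplet(pos, n_cells=3, has_artifact=False, touches_edge=False)
        assert flags == {FLAG_MULTI_CELL}

    def test_displacement_above_two_px_flags_moved(self):
        pos = np.array([[10, 10], [10, 13], [10, 10], [10, 13], [10, 10], [10, 13]], float)
        assert FLAG_MOVED in qc_droplet(pos, 1, False, False)
        pos_small = np.array([[10, 10], [10, 11.5]] * 3, float)
        assert FLAG_MOVED not in qc_droplet(pos_small, 1, False, False)

    def test_flags_are_additive(self):
        pos = np.array([[10, 10], [10, 14]] * 3, float)
        flags = qc_droplet(pos, 4, True, True)
        assert flags == {FLAG_MOVED, FLAG_MULTI_CELL, "ARTIFACT", FLAG_EDGE}

    def test_jittered_generator_droplets_all_flagged_moved(self, chem, sched):
        cfg, droplets, _, traces = synth.make_secretor_cohort(
            [20.0] * 16, 65e-9, chem, sched
        )
        red, green, _ = synth.render_stack(
            droplets, traces,
            NoiseModel(read_noise_sd=2.0, movement_fraction=1.0), sched,
            synth.chamber_shape_for(cfg), np.random.default_rng(8),
        )
        obs = analyze_stack(red, green, sched)
        assert all(FLAG_MOVED in o.qc_flags for o in obs)

    def test_cell_counts_recovered_on_clean_render(self, sched, noiseless):
        cfg = EmulsionConfig(n_droplets=60, mean_occupancy=0.8)
        rng = np.random.default_rng(17)
        droplets, _ = synth.sample_emulsion(cfg, rng)
        red, green, _ = synth.render_stack(
            droplets, {}, noiseless, sched, synth.chamber_shape_for(cfg), rng
        )
        obs = analyze_stack(red, green, sched)
        tree = cKDTree([(d.cy, d.cx) for d in droplets])
        for o in obs:
            _, i = tree.query([o.cy, o.cx])
            assert o.n_cells_detected == droplets[i].n_cells
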