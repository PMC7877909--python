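"""Generator contracts: atlas partition, connectivity truth, planted counts,
closed-form trajectory and calcium truths, and seeded determinism."""

import numpy as np
import pytest

from mbonmap import synthetic as syn
from mbonmap.behavior import kinematic_features

from conftest import flood_fill


class TestAtlas:
    def test_requested_region_count_and_disjointness(self, atlas34):
        present = set(np.unique(atlas34.labels)) - {0}
        assert len(present) == 34
        # a label grid assigns one region per voxel, so masks are disjoint
        # by construction; verify each region is nonempty instead
        assert all((atlas34.labels == r).any() for r in present)

    def test_standard_abbreviations_at_34_regions(self, atlas34):
        abbr = list(atlas34.region_table["abbreviation"])
        assert len(abbr) == 34
        assert abbr[0] == "AL" and abbr[-1] == "WED"
        assert len(set(abbr)) == 34

    def test_single_region_degenerate_case(self):
        atlas = syn.generate_atlas((32, 32, 32), n_regions=1, seed=0)
        assert set(np.unique(atlas.labels)) == {0, 1}

    def test_seeded_determinism(self):
        a = syn.generate_atlas((24, 24, 24), n_regions=8, seed=3)
        b = syn.generate_atlas((24, 24, 24), n_regions=8, seed=3)
        assert (a.labels == b.labels).all()

    def test_capacity_and_domain_errors(self):
        with pytest.raises(ValueError, match="too small"):
            syn.generate_atlas((4, 4, 4), n_regions=34, seed=0)
        with pytest.raises(ValueError, match="n_regions"):
            syn.generate_atlas((16, 16, 16), n_regions=0, seed=0)


class TestFsbLayers:
    def test_layers_partition_the_mask(self, rng):
        mask = np.zeros((20, 12, 12), dtype=bool)
        mask[3:17, 2:10, 2:10] = rng.random((14, 8, 8)) > 0.3
        layers = syn.generate_fsb_layers(mask, n_layers=9, axis=0)
        assert ((layers > 0) == mask).all()
        assert set(np.unique(layers[mask])) <= set(range(1, 10))

    def test_forced_one_slab_per_layer(self):
        mask = np.zeros((9, 4, 4), dtype=bool)
        mask[:, 1:3, 1:3] = True
        layers = syn.generate_fsb_layers(mask, n_layers=9, axis=0)
        for z in range(9):
            got = set(np.unique(layers[z][mask[z]]))
            assert got == {z + 1}

    def test_single_layer_is_identity(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:5, 1:4, 0:3] = True
        layers = syn.generate_fsb_layers(mask, n_layers=1, axis=2)
        assert ((layers == 1) == mask).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            syn.generate_fsb_layers(np.zeros((4, 4, 4), dtype=bool), 9, 0)


class TestTracingBrain:
    def test_no_clutter_means_all_signal_connected(self, atlas34):
        plan = syn.TracingPlan(target_regions=[(8, 1.0)], terminal_region=19,
                               n_clutter_components=0, noise_sigma=0.0, seed=4)
        _, post, truth = syn.generate_tracing_brain(atlas34, plan)
        assert truth.clutter_mask.sum() == 0
        supra = post.data > 50.0
        assert (supra == truth.connected_mask).all()

    def test_flood_fill_oracle_confirms_connectivity_truth(self, atlas34):
        plan = syn.TracingPlan(target_regions=[(8, 0.5), (16, 0.5)],
                               terminal_region=19, n_clutter_components=5,
                               noise_sigma=0.0, seed=5)
        pre, post, truth = syn.generate_tracing_brain(atlas34, plan)
        supra = post.data > 50.0
        seeds = pre.data > 50.0
        # signal reachable from the terminal field must be exactly the
        # connected truth; the rest exactly the clutter truth
        reach = flood_fill(supra | seeds, seeds, connectivity=26) & supra
        assert (reach == truth.connected_mask).all()
        assert ((supra & ~reach) == truth.clutter_mask).all()
        assert not (truth.connected_mask & truth.clutter_mask).any()

    def test_voxel_allocation_tracks_weights(self, atlas34):
        fractions = []
        for seed in range(20):
            plan = syn.TracingPlan(target_regions=[(8, 0.7), (16, 0.3)],
                                   terminal_region=19, seed=seed)
            _, _, truth = syn.generate_tracing_brain(atlas34, plan)
            fractions.append(truth.per_region_planted_fraction[8])
        assert abs(np.mean(fractions) - 0.7) <= 0.05

    def test_unknown_region_rejected(self, atlas34):
        plan = syn.TracingPlan(target_regions=[(99, 1.0)], terminal_region=19)
        with pytest.raises(ValueError, match="target region 99"):
            syn.generate_tracing_brain(atlas34, plan)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            syn.TracingPlan(target_regions=[(1, 0.5), (2, 0.2)],
                            terminal_region=3)


class TestCellChannels:
    def test_disjoint_by_construction_when_no_coloc(self):
        th, tango, truth = syn.generate_cell_channels(
            (32, 48, 48), n_th=6, n_tango=5, n_coloc=0,
            soma_radius=3, min_separation=10, seed=0)
        a = truth.planted_cell_centroids["TH"]
        b = truth.planted_cell_centroids["tango"]
        d = np.linalg.norm(a[:, None] - b[None, :], axis=2)
        assert d.min() > 2 * 3

    def test_planted_coloc_pairs_by_distance_oracle(self):
        _, _, truth = syn.generate_cell_channels(
            (40, 72, 72), n_th=12, n_tango=10, n_coloc=7,
            soma_radius=3, min_separation=10, seed=1)
        a = truth.planted_cell_centroids["TH"]
        b = truth.planted_cell_centroids["tango"]
        d = np.linalg.norm(a[:, None] - b[None, :], axis=2)
        assert (d <= 3).sum() == 7            # each pair unique at this spacing
        assert (d.min(axis=1) <= 1.0).sum() == 7

    def test_seeded_determinism(self):
        r1 = syn.generate_cell_channels((24, 32, 32), 4, 4, 2, seed=9)
        r2 = syn.generate_cell_channels((24, 32, 32), 4, 4, 2, seed=9)
        assert (r1[0].data == r2[0].data).all()
        np.testing.assert_array_equal(r1[2].planted_cell_centroids["tango"],
                                      r2[2].planted_cell_centroids["tango"])

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="could not pack"):
            syn.generate_cell_channels((12, 12, 12), 40, 40, 0,
                                       soma_radius=2, min_separation=8, seed=0)


class TestTrajectories:
    def test_stationary_truth_is_zero(self):
        trajs, truths = syn.generate_trajectories(
            2, syn.Stationary(), fps=33, duration=5, seed=0)
        t = truths["fly000"]
        assert (t.pathlength, t.mean_speed, t.mean_angular_speed) == (0, 0, 0)
        assert np.ptp(trajs[0].positions, axis=0).max() == 0

    def test_straight_line_pathlength_is_speed_times_duration(self):
        trajs, truths = syn.generate_trajectories(
            1, syn.Straight(5.0), fps=33, duration=10, arena_diameter=300,
            seed=0)
        feats = kinematic_features(trajs[0], smoothing_window=1)
        assert truths["fly000"].pathlength == pytest.approx(50.0)
        assert feats.pathlength == pytest.approx(50.0)
        assert feats.mean_velocity == pytest.approx(5.0)

    def test_circular_motion_angular_speed_closed_form(self):
        trajs, truths = syn.generate_trajectories(
            1, syn.Circle(radius=10.0, period=20.0), fps=33, duration=20,
            seed=0)
        feats = kinematic_features(trajs[0], smoothing_window=1)
        assert truths["fly000"].mean_angular_speed == pytest.approx(18.0)
        assert feats.mean_angular_velocity == pytest.approx(18.0, rel=0.02)
        assert feats.pathlength == pytest.approx(
            truths["fly000"].pathlength, rel=1e-9)

    def test_walkers_stay_inside_the_arena(self):
        trajs, _ = syn.generate_trajectories(
            5, syn.CorrelatedWalk(mu_speed=20.0), fps=33, duration=20,
            arena_diameter=37.0, seed=2)
        for t in trajs:
            assert np.linalg.norm(t.positions, axis=1).max() <= 18.5 + 1e-9


class TestCalciumGenerator:
    def test_null_amplitude_gives_flat_trace(self):
        traces, _ = syn.generate_calcium_traces(
            1, amplitude_ratio=0.0, noise_sigma=0.0, baseline=100.0, seed=0)
        open_frames = ~traces[0].shutter_closed
        assert np.allclose(traces[0].F[open_frames], 100.0)

    def test_peak_dff_equals_amplitude_ratio(self):
        traces, truth = syn.generate_calcium_traces(
            1, amplitude_ratio=0.5, noise_sigma=0.0, seed=0)
        f = traces[0]
        f0 = truth.calcium_truth.baseline
        peak = np.nanmax((f.F[~f.shutter_closed] - f0) / f0)
        assert peak == pytest.approx(0.5, abs=1e-9)

    def test_replicate_mean_baseline_scatter_scales_as_sqrt_n(self):
        n = 32
        traces, _ = syn.generate_calcium_traces(
            n, amplitude_ratio=0.4, noise_sigma=5.0, baseline=100.0,
            duration=30.0, onset=10.0, seed=7)
        pre = np.stack([t.F[: t.onset_index] for t in traces])
        across = pre.mean(axis=0)        # mean over replicates, per frame
        observed = across.std(ddof=1)
        assert observed == pytest.approx(5.0 / np.sqrt(n), rel=0.3)
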