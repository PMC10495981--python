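"""Generator properties: walk statistics, rendering, plate and Ct tables."""

import math

import numpy as np
import pytest

from ielquant.synthetic import (
    SimulationConfig,
    simulate_confined_walk,
    simulate_ct_table,
    simulate_plate,
    simulate_timelapse,
)


class TestConfinedWalk:
    def test_zero_speed_stays_at_anchor(self):
        pos = simulate_confined_walk(50, 30.0, 0.0, 10.0, (5.0, -3.0), seed=0)
        assert pos.shape == (50, 2)
        assert np.all(pos == [5.0, -3.0])

    def test_unbounded_mean_step_length_matches_speed(self):
        # speed 0.1 um/s at dt=30 s -> mean step 3 um
        pos = simulate_confined_walk(10000, 30.0, 0.1, math.inf, (0.0, 0.0), seed=1)
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert steps.mean() == pytest.approx(3.0, rel=0.05)

    def test_confinement_bounds_excursions(self):
        pos = simulate_confined_walk(10000, 30.0, 0.1, 10.0, (0.0, 0.0), seed=2)
        r = np.linalg.norm(pos, axis=1)
        assert np.quantile(r, 0.99) <= 4 * 10.0

    def test_deterministic_under_seed(self):
        a = simulate_confined_walk(100, 30.0, 0.1, 10.0, (0.0, 0.0), seed=7)
        b = simulate_confined_walk(100, 30.0, 0.1, 10.0, (0.0, 0.0), seed=7)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_steps=0), dict(dt=0.0), dict(dt=-1.0), dict(speed=-0.1),
         dict(confinement_radius=0.0)],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        args = dict(n_steps=10, dt=30.0, speed=0.1, confinement_radius=10.0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            simulate_confined_walk(**args, anchor=(0, 0), seed=0)

    def test_confined_gyration_smaller_than_free(self):
        """Confined walkers stay more compact than free ones at equal
        speed, consistently across seeds."""
        wins = 0
        n_seeds = 20
        for s in range(n_seeds):
            conf = simulate_confined_walk(200, 30.0, 0.1, 10.0, (0, 0), seed=1000 + s)
            free = simulate_confined_walk(200, 30.0, 0.1, math.inf, (0, 0), seed=1000 + s)
            rg = lambda p: np.sqrt(((p - p.mean(axis=0)) ** 2).sum(axis=1).mean())
            wins += rg(conf) < rg(free)
        assert wins >= 0.95 * n_seeds


class TestTimelapse:
    def test_reproducible_bit_identical(self):
        cfg = SimulationConfig(n_frames=5, n_tcells=3, n_nuclei=30, seed=11)
        s1, t1 = simulate_timelapse(cfg)
        s2, t2 = simulate_timelapse(cfg)
        assert np.array_equal(s1, s2)
        assert np.array_equal(t1.true_positions, t2.true_positions)
        assert np.array_equal(t1.dead_labels, t2.dead_labels)

    def test_dead_count_is_exact_round(self):
        cfg = SimulationConfig(n_frames=2, n_nuclei=200, dead_fraction=0.25, seed=3)
        _, truth = simulate_timelapse(cfg)
        assert truth.dead_labels.sum() == 50
        assert truth.true_dead_fraction == pytest.approx(0.25)

    def test_empty_tcell_channel_is_background_noise_only(self):
        cfg = SimulationConfig(n_frames=3, n_tcells=0, seed=5)
        stack, _ = simulate_timelapse(cfg)
        ch = stack[2]
        assert abs(ch.mean() - cfg.background_level) < 1.0
        assert ch.max() < cfg.background_level + 7 * cfg.noise_sigma

    def test_no_dead_cells_gives_blobless_pi_channel(self):
        cfg = SimulationConfig(n_frames=3, dead_fraction=0.0, seed=5)
        stack, truth = simulate_timelapse(cfg)
        assert truth.dead_labels.sum() == 0
        assert stack[1].max() < cfg.background_level + 7 * cfg.noise_sigma

    def test_dead_nuclei_are_subset_of_all_nuclei(self):
        cfg = SimulationConfig(n_frames=2, dead_fraction=0.3, seed=9)
        _, truth = simulate_timelapse(cfg)
        dead = truth.nuclei_positions_um[truth.dead_labels]
        # every PI blob center coincides with a Hoechst blob center
        for p in dead:
            d = np.linalg.norm(truth.nuclei_positions_um - p, axis=1)
            assert d.min() == 0.0

    def test_confined_positions_stay_in_annulus(self):
        cfg = SimulationConfig(n_frames=91, confinement_radius_um=10.0, seed=13)
        _, truth = simulate_timelapse(cfg)
        center = np.array(cfg.organoid_center_um)
        r = np.linalg.norm(truth.true_positions - center, axis=2)
        assert np.all(r >= cfg.lumen_radius_um - 1e-9)
        assert np.all(r <= cfg.outer_radius_um + 1e-9)

    def test_organoid_larger_than_fov_warns(self):
        cfg = SimulationConfig(image_width_px=100, image_height_px=100,
                               organoid_center_um=(50, 50), outer_radius_um=80.0,
                               lumen_radius_um=30.0, n_frames=1, seed=1)
        with pytest.warns(UserWarning, match="field of view"):
            simulate_timelapse(cfg)

    @pytest.mark.parametrize(
        "field,value",
        [("dead_fraction", 1.5), ("lumen_radius_um", 90.0), ("pixel_size_um", 0.0),
         ("n_frames", 0), ("mean_speed_um_s", -1.0), ("noise_sigma", -1.0)],
    )
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            SimulationConfig(**{field: value})


class TestPlate:
    CONDITIONS = [
        ("organoid_only", "B6", 0.05, 6),
        ("syngeneic", "B6", 0.10, 6),
        ("allogeneic", "BALB/c", 0.25, 6),
    ]

    def test_zero_death_gives_background_pi(self):
        df, _ = simulate_plate([("c", "B6", 0.0, 8)], pi_background=20.0, seed=0)
        assert np.allclose(df["pi_intensity"], 20.0)

    def test_hoechst_and_pi_scale_jointly_with_seeding(self):
        lo, _ = simulate_plate([("c", "B6", 0.2, 40)], per_well_cells=2000,
                               pi_background=0.0, hoechst_background=0.0, seed=4)
        hi, _ = simulate_plate([("c", "B6", 0.2, 40)], per_well_cells=4000,
                               pi_background=0.0, hoechst_background=0.0, seed=4)
        assert hi["hoechst_intensity"].mean() / lo["hoechst_intensity"].mean() == pytest.approx(2.0, rel=0.1)
        assert hi["pi_intensity"].mean() / lo["pi_intensity"].mean() == pytest.approx(2.0, rel=0.1)

    def test_mean_raw_ratio_ordering_follows_dead_fraction(self):
        df, _ = simulate_plate(self.CONDITIONS, seed=8)
        ratios = (df["pi_intensity"] / df["hoechst_intensity"]).groupby(df["condition"]).mean()
        assert ratios["allogeneic"] > ratios["syngeneic"] > ratios["organoid_only"]

    def test_invalid_dead_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_plate([("c", "B6", 1.2, 4)])


class TestCtTable:
    def test_fold_one_no_noise_gives_identical_delta_ct(self):
        df = simulate_ct_table(["G"], {"G": 1.0}, ct_noise_sigma=0.0, seed=0)
        dct = df.groupby(["condition", "sample_id", "gene"])["ct"].mean().unstack("gene")
        delta = dct["G"] - dct["Hprt"]
        assert delta.groupby("condition").mean().std() == pytest.approx(0.0, abs=1e-9)

    def test_fold_two_lowers_target_ct_by_one_cycle(self):
        df = simulate_ct_table(["G"], {"G": 2.0}, ct_noise_sigma=0.0,
                               sample_loading_sd=0.0, seed=0)
        means = df[df.gene == "G"].groupby("condition")["ct"].mean()
        assert means["syngeneic"] - means["allogeneic"] == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            simulate_ct_table(["G"], {"G": 0.0})
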