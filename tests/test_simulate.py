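"""Ground-truth simulator: determinism, referencing, planted structure."""

import numpy as np

import pytest

import topoplast as tp
from topoplast.dataset import CONDITIONS
from topoplast.simulate import GaussianBumps, SimulationError

from conftest import fast_config


def flat_schedule(k=3):
    return {c: tuple(1.0 / k for _ in range(k)) for c in CONDITIONS}


class TestDeterminismAndStructure:
    def test_same_seed_bit_identical(self):
        cfg = fast_config(seed=11)
        a, _ = tp.generate_erp_dataset(cfg)
        b, _ = tp.generate_erp_dataset(cfg)
        assert np.array_equal(a.data, b.data)
        assert tp.generate_trial_counts(cfg).equals(
            tp.generate_trial_counts(cfg))

    def test_average_referenced(self):
        ds, _ = tp.generate_erp_dataset(fast_config(seed=1))
        assert np.abs(ds.data.mean(axis=-2)).max() < 1e-12

    def test_noise_free_gfp_equals_envelope(self):
        cfg = fast_config(seed=2, noise_sd=0.0)
        ds, _ = tp.generate_erp_dataset(cfg)
        env = cfg.gfp_envelope(ds.times)
        g = tp.gfp_series(ds)
        np.testing.assert_allclose(
            g, np.broadcast_to(env, g.shape), atol=1e-9)

    def test_noise_free_single_template_correlates_one(self):
        cfg = fast_config(
            seed=3, noise_sd=0.0, n_templates=1,
            occupancy_schedule={c: (1.0,) for c in CONDITIONS},
            occupancy_jitter_kappa=0.0,
        )
        ds, truth = tp.generate_erp_dataset(cfg)
        mask = ds.time_mask(cfg.analysis_window)
        maps = ds.data[..., mask]
        r = np.einsum("c,abdect->abdet", truth.template_bank[0],
                      maps) / (cfg.n_channels * cfg.gfp_envelope(
                          ds.times[mask]))
        np.testing.assert_allclose(r, 1.0, atol=1e-9)

    def test_noise_free_backfit_recovers_schedule_exactly(self):
        schedule = dict(flat_schedule(2))
        schedule[("puff", "more_affected", "pre")] = (0.6, 0.4)
        schedule[("puff", "more_affected", "post")] = (0.3, 0.7)
        cfg = fast_config(seed=4, noise_sd=0.0, n_templates=2,
                          occupancy_schedule=schedule,
                          occupancy_jitter_kappa=0.0)
        ds, truth = tp.generate_erp_dataset(cfg)
        fits = tp.backfit(ds, truth.template_bank, cfg.analysis_window)
        wide = fits.wide()
        pre = wide.loc[(slice(None), "more_affected", "pre"), "map1"]
        post = wide.loc[(slice(None), "more_affected", "post"), "map1"]
        np.testing.assert_allclose(pre, 0.6, atol=1 / 37)  # block rounding
        np.testing.assert_allclose(post, 0.3, atol=1 / 37)

    def test_ground_truth_durations_consistent_with_labels(self):
        _, truth = tp.generate_erp_dataset(fast_config(seed=5))
        counts = np.stack([
            (truth.labels == m).mean(axis=-1) for m in range(3)
        ], axis=-1)
        np.testing.assert_allclose(counts, truth.durations, atol=1e-12)


class TestValidation:
    def test_occupancy_not_summing_rejected(self):
        bad = flat_schedule()
        bad[("puff", "more_affected", "pre")] = (0.5, 0.2, 0.2)
        with pytest.raises(SimulationError, match="sum to 1"):
            fast_config(occupancy_schedule=bad)

    def test_too_few_channels_rejected(self):
        with pytest.raises(SimulationError, match="n_channels"):
            tp.default_config(n_channels=1)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(SimulationError, match="analysis window"):
            tp.default_config(analysis_window=(250.0, 800.0))

    def test_behavior_requires_truth(self):
        with pytest.raises(SimulationError, match="ground truth"):
            tp.generate_behavioral_table(fast_config(), None)


class TestBehavioralLinks:
    def test_null_link_centred_near_zero(self):
        rhos = []
        for seed in range(50):
            cfg = fast_config(seed=seed, behavior_links={},
                              occupancy_schedule=flat_schedule(),
                              occupancy_jitter_kappa=30.0)
            _, truth = tp.generate_erp_dataset(cfg)
            table = tp.generate_behavioral_table(cfg, truth)
            r = tp.pooled_hand_correlation(
                truth.durations_frame(), table, "map1", "grip")
            rhos.append(r.rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_perfect_negative_link_exact(self):
        cfg = fast_config(seed=6, behavior_links={"grip": -1.0},
                          occupancy_schedule=flat_schedule(),
                          occupancy_jitter_kappa=30.0)
        _, truth = tp.generate_erp_dataset(cfg)
        table = tp.generate_behavioral_table(cfg, truth)
        r = tp.pooled_hand_correlation(truth.durations_frame(), table,
                                       "map1", "grip")
        assert r.rho == pytest.approx(-1.0)

    def test_trial_counts_distribution(self):
        cfg = fast_config(seed=7, n_subjects=40)
        counts = tp.generate_trial_counts(cfg)
        assert (counts.n_trials >= cfg.trial_count_offset).all()
        assert counts.n_trials.mean() == pytest.approx(
            cfg.trial_count_mean, abs=1.5)

    def test_low_count_subject_excluded_dataset_wide(self):
        ds, _ = tp.generate_erp_dataset(fast_config(seed=8))
        counts = tp.generate_trial_counts(fast_config(seed=8))
        counts.loc[counts.index[0], "n_trials"] = 11
        victim = counts.loc[counts.index[0], "subject"]
        out = tp.filter_min_trials(ds, counts)
        assert victim not in out.subjects


class TestOccupancyRecovery:
    def test_moderate_noise_mean_occupancy_within_5pp(self):
        """Monte-Carlo: back-fitting with the true templates recovers the
        scheduled occupancy to within 5 percentage points on average, at
        noise half the envelope peak."""
        errors = []
        for seed in range(8):
            cfg = fast_config(seed=seed)
            cfg = cfg.replace(noise_sd=0.5 * GaussianBumps().peak)
            ds, truth = tp.generate_erp_dataset(cfg)
            fits = tp.backfit(ds, truth.template_bank, cfg.analysis_window)
            wide = fits.wide()
            for (stim, side, sess) in CONDITIONS:
                if stim != "puff":
                    continue
                sched = np.array(cfg.occupancy_schedule[(stim, side, sess)])
                got = wide.xs((side, sess), level=("side", "session")).mean()
                errors.append(np.abs(
                    got[[f"map{m+1}" for m in range(3)]].to_numpy() - sched))
        assert np.mean(errors) < 0.05
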