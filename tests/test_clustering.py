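"""AAHC segmentation, Krzanowski-Lai selection, back-fitting, duration ANOVA."""

import numpy as np
import pandas as pd
import pytest

import topoplast as tp
from topoplast.clustering import ClusteringError, SegmentationResult
from topoplast.dataset import SESSIONS, SIDES

from conftest import fast_config
from _oracles import within_anova_oracle


def two_template_maps(n=40, n_ch=8):
    """Noise-free sample maps alternating between two orthogonal templates."""
    t1 = np.zeros(n_ch); t1[:4] = [1, -1, 1, -1]
    t2 = np.zeros(n_ch); t2[4:] = [1, 1, -1, -1]
    t1 = tp.normalize_by_gfp(t1); t2 = tp.normalize_by_gfp(t2)
    maps = np.stack([t1 if (i // 10) % 2 == 0 else t2 for i in range(n)])
    return maps, t1, t2


class TestAahc:
    def test_noise_free_two_templates_exact(self):
        maps, t1, t2 = two_template_maps()
        seg = tp.cluster_topographies(
            {("more_affected", "pre"): maps.T}, np.arange(40.0), (1, 5))
        best = [max(abs(tp.spatial_correlation(c, t)) for t in (t1, t2))
                for c in seg.templates[2]]
        assert min(best) == pytest.approx(1.0)
        assert seg.gev[2] == pytest.approx(1.0)

    def test_single_template_k1_explains_all(self):
        maps, t1, _ = two_template_maps()
        maps = np.tile(t1, (30, 1))
        seg = tp.cluster_topographies(
            {("more_affected", "pre"): maps.T}, np.arange(30.0), (1, 4))
        assert seg.gev[1] == pytest.approx(1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            assert tp.select_k_krzanowski_lai(seg) == 1

    def test_polarity_flip_of_input_flips_templates_only(self):
        maps, _, _ = two_template_maps()
        a = tp.cluster_topographies(
            {("more_affected", "pre"): maps.T}, np.arange(40.0), (1, 4))
        b = tp.cluster_topographies(
            {("more_affected", "pre"): -maps.T}, np.arange(40.0), (1, 4))
        np.testing.assert_allclose(b.templates[2], -a.templates[2],
                                   atol=1e-12)
        np.testing.assert_array_equal(b.labels[2], a.labels[2])

    def test_degenerate_input_rejected(self):
        with pytest.raises(ClusteringError, match="constant"):
            tp.cluster_topographies(
                {("more_affected", "pre"): np.ones((8, 10))},
                np.arange(10.0), (1, 3))

    def test_gev_nondecreasing_in_k(self, study_bundle):
        ds = study_bundle["relabeled"]
        mask = ds.time_mask((250.0, 550.0))
        group = {(sd, ss): ds.group_mean("puff", sd, ss)[:, mask]
                 for sd in SIDES for ss in SESSIONS}
        seg = tp.cluster_topographies(group, ds.times[mask], (1, 8))
        gev = [seg.gev[k] for k in sorted(seg.gev)]
        assert all(b >= a - 1e-6 for a, b in zip(gev, gev[1:]))


class TestKrzanowskiLai:
    def test_geometric_curve_tie_breaks_to_smallest(self):
        """A strictly geometric dispersion curve has no elbow: every
        interior ratio is equal, and the documented tie rule returns the
        smallest candidate."""
        ks = range(1, 7)
        res = SegmentationResult(
            templates={k: np.zeros((k, 8)) for k in ks},
            labels={}, gev={},
            dispersion={k: 100.0 * 0.5 ** k for k in ks},
            sample_info=pd.DataFrame(), k_range=(1, 6),
        )
        # infinite dimensionality -> k**(2/m) scaling is exactly 1, so all
        # interior ratios are exactly 2 and the tie goes to the smallest k
        assert tp.select_k_krzanowski_lai(res, dimensionality=np.inf) == 2
        vals = [v for k, v in sorted(res.kl.items()) if 1 < k < 6]
        assert np.allclose(vals, 2.0)

    def test_narrow_range_rejected(self):
        res = SegmentationResult(
            templates={2: np.zeros((2, 8))}, labels={}, gev={},
            dispersion={2: 1.0, 3: 0.5}, sample_info=pd.DataFrame(),
            k_range=(2, 3))
        with pytest.raises(ClusteringError, match="narrow"):
            tp.select_k_krzanowski_lai(res)

    def test_recovers_three_planted_templates(self):
        """KL picks k = 3 and the recovered maps match the planted bank
        (a deeper 50-seed version runs in the acceptance suite)."""
        hits = 0
        for seed in range(5):
            cfg = tp.default_config(seed=seed, randomize_affected_side=False)
            ds, truth = tp.generate_erp_dataset(cfg)
            mask = ds.time_mask(cfg.analysis_window)
            group = {(sd, ss): ds.group_mean("puff", sd, ss)[:, mask]
                     for sd in SIDES for ss in SESSIONS}
            seg = tp.cluster_topographies(group, ds.times[mask], (1, 8))
            k = tp.select_k_krzanowski_lai(seg)
            if k != 3:
                continue
            r = np.abs(seg.templates[3] @ truth.template_bank.T
                       / cfg.n_channels)
            hits += bool(np.all(r.max(axis=1) >= 0.95))
        assert hits >= 4


class TestBackfit:
    def test_pure_template_gets_full_duration(self):
        cfg = fast_config(seed=1, noise_sd=0.0, n_templates=1,
                          occupancy_schedule={
                              c: (1.0,) for c in tp.CONDITIONS},
                          occupancy_jitter_kappa=0.0)
        ds, truth = tp.generate_erp_dataset(cfg)
        extra = tp.normalize_by_gfp(
            np.random.default_rng(0).standard_normal(cfg.n_channels))
        fits = tp.backfit(ds, np.stack([truth.template_bank[0], extra]),
                          cfg.analysis_window)
        wide = fits.wide(include_unlabeled=True)
        assert np.allclose(wide["map1"], 1.0)
        assert np.allclose(wide["map2"], 0.0)
        assert np.allclose(wide["unlabeled"], 0.0)

    def test_durations_sum_to_one(self, study_bundle):
        fits = tp.backfit(study_bundle["relabeled"],
                          study_bundle["truth"].template_bank, (250.0, 550.0))
        sums = fits.frame.groupby(["subject", "side", "session"])[
            "fraction"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_template_permutation_permutes_durations(self, study_bundle):
        bank = study_bundle["truth"].template_bank
        a = tp.backfit(study_bundle["relabeled"], bank, (250.0, 550.0))
        b = tp.backfit(study_bundle["relabeled"], bank[::-1], (250.0, 550.0))
        wa, wb = a.wide(), b.wide()
        np.testing.assert_allclose(wa["map1"], wb["map3"], atol=1e-12)
        np.testing.assert_allclose(wa["map3"], wb["map1"], atol=1e-12)

    def test_empty_template_list_rejected(self, study_bundle):
        with pytest.raises(ClusteringError, match="empty"):
            tp.backfit(study_bundle["relabeled"], np.zeros((0, 32)),
                       (250.0, 550.0))


class TestDurationAnova:
    @staticmethod
    def _fit_from_array(y):
        """Wrap a (subjects, maps, side, session) array as FitDurations."""
        n_sub, k, _, _ = y.shape
        rows = []
        for i in range(n_sub):
            for m in range(k):
                for b, side in enumerate(SIDES):
                    for c, sess in enumerate(SESSIONS):
                        rows.append({
                            "subject": f"s{i}", "side": side,
                            "session": sess, "map": f"map{m+1}",
                            "fraction": y[i, m, b, c]})
        from topoplast.clustering import FitDurations
        return FitDurations(pd.DataFrame(rows), np.zeros((n_sub, 2, 2, 1)),
                            [f"map{m+1}" for m in range(k)],
                            (250.0, 550.0), "puff")

    def test_identical_cells_give_zero_f(self):
        y = np.tile(np.array([0.5, 0.3, 0.2])[None, :, None, None],
                    (4, 1, 2, 2))
        res = tp.duration_anova(self._fit_from_array(y))
        assert np.allclose(res.per_map["F"], 0.0)
        assert np.allclose(res.contrasts["t"], 0.0)

    def test_three_way_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0.1, 0.9, size=(3, 3, 2, 2))
        res = tp.duration_anova(self._fit_from_array(y))
        oracle = within_anova_oracle(y)  # axes: 1=Map, 2=Side, 3=Session
        table = res.three_way.set_index("effect")["F"]
        assert table["Map"] == pytest.approx(oracle[(1,)][0], abs=1e-8)
        assert table["Session"] == pytest.approx(oracle[(3,)][0], abs=1e-8)
        assert table["Side"] == pytest.approx(oracle[(2,)][0], abs=1e-8)
        assert table["Map:Session"] == pytest.approx(oracle[(1, 3)][0],
                                                     abs=1e-8)
        assert table["Map:Session:Side"] == pytest.approx(
            oracle[(1, 2, 3)][0], abs=1e-8)

    def test_per_map_2x2_matches_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(0.1, 0.9, size=(3, 1, 2, 2))
        res = tp.duration_anova(self._fit_from_array(y))
        oracle = within_anova_oracle(y[:, 0])  # (S, side, session)
        got = res.per_map.set_index("effect")["F"]
        assert got["side"] == pytest.approx(oracle[(1,)][0], abs=1e-8)
        assert got["session"] == pytest.approx(oracle[(2,)][0], abs=1e-8)
        assert got["interaction"] == pytest.approx(oracle[(1, 2)][0],
                                                   abs=1e-8)

    def test_crossover_detected_per_map(self, study_bundle):
        """The planted crossover yields a Session x Side interaction for
        the dominant map with the planted sign pattern of contrasts."""
        fits = tp.backfit(study_bundle["relabeled"],
                          study_bundle["truth"].template_bank, (250.0, 550.0))
        res = tp.duration_anova(fits)
        inter = res.per_map.query("map == 'map1' and effect == 'interaction'")
        assert inter["p"].iloc[0] < 0.05
        c = res.contrasts.set_index(["map", "contrast"])["t"]
        assert c[("map1", "pre: more vs less")] > 0
        assert c[("map1", "more_affected: post vs pre")] < 0
        assert c[("map1", "less_affected: post vs pre")] > 0
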