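"""Behavioral statistics: paired hand tests, change tests, pooled Spearman."""

import numpy as np
import pandas as pd
import pytest

import topoplast as tp
from topoplast.behavior import BehaviorError, spearman

from conftest import fast_config


def make_table(scores):
    """scores: dict (subject, side, session) -> value, single test 'grip'."""
    rows = [{"subject": s, "side": h, "session": ses, "test": "grip",
             "score": v, "unit": "psi"}
            for (s, h, ses), v in scores.items()]
    return pd.DataFrame(rows)


class TestPairedHandTests:
    def test_identical_hands_give_t0_p_half(self):
        scores = {}
        for i in range(4):
            for h in ("more_affected", "less_affected"):
                scores[(f"s{i}", h, "pre")] = 10.0 + i
        res = tp.paired_hand_tests(make_table(scores), "pre")
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(0.5)

    def test_constant_difference_flagged_degenerate(self):
        scores = {}
        for i in range(4):
            scores[(f"s{i}", "less_affected", "pre")] = 12.0 + i
            scores[(f"s{i}", "more_affected", "pre")] = 10.0 + i
        res = tp.paired_hand_tests(make_table(scores), "pre")
        assert res["degenerate"].iloc[0]
        assert np.isinf(res["t"].iloc[0])
        assert res["p"].iloc[0] == 0.0  # direction: less affected better

    def test_too_few_pairs_rejected(self):
        scores = {("s0", "less_affected", "pre"): 1.0,
                  ("s0", "more_affected", "pre"): 2.0,
                  ("s1", "less_affected", "pre"): 1.5,
                  ("s1", "more_affected", "pre"): 2.5}
        with pytest.raises(BehaviorError, match="pairs"):
            tp.paired_hand_tests(make_table(scores), "pre")

    def test_planted_asymmetry_detected_selectively(self):
        """With a hand deficit planted only in stereognosis, grip and
        pinch (and no duration links), those tests are detected at high
        rate while the unshifted tests stay at their nominal error rate."""
        shifted = {"stereognosis": 2.5, "grip": 2.5, "pinch": 2.5}
        n_seeds = 25
        sig_counts: dict[str, int] = {}
        for seed in range(n_seeds):
            cfg = fast_config(seed=seed, behavior_links={},
                              hand_shift=shifted)
            _, truth = tp.generate_erp_dataset(cfg)
            table = tp.generate_behavioral_table(cfg, truth)
            res = tp.paired_hand_tests(table, "pre").set_index("test")
            for test, row in res.iterrows():
                sig_counts[test] = sig_counts.get(test, 0) + (row["p"] < 0.05)
        for test in shifted:
            assert sig_counts[test] >= 0.8 * n_seeds, test
        for test in set(sig_counts) - set(shifted):
            assert sig_counts[test] <= 0.25 * n_seeds, test


class TestPrePostChange:
    def test_identical_sessions_give_zero_t(self):
        scores = {}
        for i in range(4):
            for h in ("more_affected", "less_affected"):
                for ses in ("pre", "post"):
                    scores[(f"s{i}", h, ses)] = 10.0 + i + (h == "less_affected")
        res = tp.pre_post_change_tests(make_table(scores))
        assert np.allclose(res["t"], 0.0)

    def test_planted_grip_gain_one_hand_only(self):
        hits_target, hits_other = 0, 0
        for seed in range(15):
            cfg = fast_config(
                seed=seed, behavior_links={},
                prepost_shift={("grip", "more_affected"): 2.0})
            _, truth = tp.generate_erp_dataset(cfg)
            table = tp.generate_behavioral_table(cfg, truth)
            res = tp.pre_post_change_tests(table).set_index(["test", "side"])
            hits_target += res.loc[("grip", "more_affected"), "p"] < 0.05
            others = res.drop(("grip", "more_affected"))
            hits_other += int((others["p"] < 0.05).sum())
        assert hits_target >= 12
        # 7 remaining cells x 15 seeds at alpha .05 -> ~5 expected nulls
        assert hits_other <= 15


class TestSpearman:
    def test_perfect_monotone_decreasing(self):
        x = np.arange(10.0)
        rho, p, _ = spearman(x, np.exp(-x))
        assert rho == pytest.approx(-1.0)

    def test_exact_small_n_p_value(self):
        """For n = 4 and a perfect ranking, 2 of the 24 permutations reach
        |rho| = 1, so the exact two-sided p is 1/12."""
        rho, p, method = spearman(np.arange(4.0), np.arange(4.0) ** 3)
        assert method == "exact permutation"
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        r1, _, _ = spearman(x, y)
        r2, _, _ = spearman(np.exp(x), 3.0 * y**3 + y)
        assert r1 == pytest.approx(r2)

    def test_zero_variance_flagged(self):
        rho, p, method = spearman(np.ones(8), np.arange(8.0))
        assert method == "degenerate"
        assert np.isnan(rho)


class TestPooledHandCorrelation:
    @staticmethod
    def _durations(values):
        rows = [{"subject": s, "side": h, "session": ses, "map": "map1",
                 "fraction": v} for (s, h, ses), v in values.items()]
        return pd.DataFrame(rows)

    def test_perfect_link_minus_one(self):
        dur, scores = {}, {}
        v = 0.1
        for i in range(6):
            for h in ("more_affected", "less_affected"):
                dur[(f"s{i}", h, "pre")] = v
                scores[(f"s{i}", h, "pre")] = 50.0 - v
                v += 0.05
        res = tp.pooled_hand_correlation(self._durations(dur),
                                         make_table(scores), "map1", "grip")
        assert res.rho == pytest.approx(-1.0)
        assert res.n == 12

    def test_change_correlation(self):
        dur, scores = {}, {}
        rng = np.random.default_rng(1)
        for i in range(8):
            for h in ("more_affected", "less_affected"):
                pre_d, post_d = rng.uniform(0, 1, 2)
                dur[(f"s{i}", h, "pre")] = pre_d
                dur[(f"s{i}", h, "post")] = post_d
                scores[(f"s{i}", h, "pre")] = 10.0
                scores[(f"s{i}", h, "post")] = 10.0 - 5 * (post_d - pre_d)
        res = tp.pooled_hand_correlation(
            self._durations(dur), make_table(scores), "map1", "grip",
            session=None, change=True)
        assert res.rho == pytest.approx(-1.0)

    def test_independence_diagnostic_reports_not_gates(self):
        cfg = fast_config(seed=9)
        _, truth = tp.generate_erp_dataset(cfg)
        table = tp.generate_behavioral_table(cfg, truth)
        diag = tp.behavior.between_hand_independence(
            truth.durations_frame(), table, "map1", "grip")
        assert set(diag["variable"]) == {"map1 duration", "grip"}
        assert diag["rho_between_hands"].between(-1, 1).all()
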