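"""DVH machinery, plan metrics and the signed-rank comparison protocol."""
import itertools

import numpy as np
import pytest
from scipy import stats

import wbrtplan as w
from wbrtplan.dose import DoseGrid
from wbrtplan.evaluate import (ENDPOINTS, PlanMetrics, compare_cohorts, dvh,
                               plan_metrics, wilcoxon_signed_rank_one_sided)


def _grid(dose_array, vox=2.5):
    return DoseGrid(np.asarray(dose_array, float), np.zeros(3), vox)


def _mini_phantom(dose_value=5000.0, shape=(6, 6, 6)):
    dose = np.full(shape, float(dose_value))
    masks = {
        "body": np.ones(shape, bool),
        "breast_target": np.zeros(shape, bool),
        "ipsilateral_lung": np.zeros(shape, bool),
        "heart": np.zeros(shape, bool),
    }
    masks["breast_target"][1:5, 1:5, 1:5] = True
    masks["ipsilateral_lung"][0, :, :] = True
    masks["heart"][5, :, :] = True
    p = w.Phantom(density=np.ones(shape, np.float32), masks=masks,
                  origin=np.zeros(3), voxel_size=2.5)
    return _grid(dose), p


def brute_force_wilcoxon(a, b, alternative):
    """Independent oracle: enumerate all 2^n sign assignments."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = ranks[np.array(signs, bool)].sum()
        if alternative == "greater":
            count += w_plus >= w_obs - 1e-12
        else:
            count += w_plus <= w_obs + 1e-12
    return count / 2 ** n


class TestDvh:
    def test_uniform_dose_step_function(self):
        curve = dvh(_grid(np.full((4, 4, 4), 4000.0)),
                    np.ones((4, 4, 4), bool), bin_width=100.0)
        vol = curve["volume_pct"].to_numpy()
        dose = curve["dose_cgy"].to_numpy()
        assert vol[0] == 100.0
        assert np.all(vol[dose <= 4000.0] == 100.0)
        assert np.all(vol[dose > 4000.0] == 0.0)

    def test_two_voxel_median(self):
        dose = np.array([[[4000.0, 6000.0]]])
        curve = dvh(_grid(dose), np.ones((1, 1, 2), bool), bin_width=100.0)
        at_5000 = curve.loc[curve["dose_cgy"] == 5000.0, "volume_pct"]
        assert float(at_5000.iloc[0]) == 50.0

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        curve = dvh(_grid(rng.uniform(0, 6000, (5, 5, 5))),
                    np.ones((5, 5, 5), bool))
        assert np.all(np.diff(curve["volume_pct"].to_numpy()) <= 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dvh(_grid(np.zeros((2, 2, 2))), np.zeros((2, 2, 2), bool))


class TestPlanMetrics:
    def test_uniform_prescription_dose(self):
        grid, p = _mini_phantom(5000.0)
        m = plan_metrics(grid, p, 5000.0)
        assert m.target_v100_pct == 100.0
        assert m.target_v105_pct == 0.0
        assert m.plan_max_pct == 100.0
        assert m.heart_mean_pct == 100.0

    def test_half_target_hot(self):
        grid, p = _mini_phantom(5000.0)
        t = p.masks["breast_target"]
        idx = np.argwhere(t)
        hot = idx[: len(idx) // 2]
        grid.dose[hot[:, 0], hot[:, 1], hot[:, 2]] = 1.06 * 5000.0
        m = plan_metrics(grid, p, 5000.0)
        assert m.target_v105_pct == 50.0
        target_cc = t.sum() * (2.5 / 10.0) ** 3
        assert m.v105_cc == pytest.approx(target_cc / 2.0)

    def test_nesting_invariant_on_cohort_plans(self, tuned_heldout):
        for rec in tuned_heldout:
            for m in (rec["metrics_before"], rec["metrics_after"]):
                assert m.target_v90_pct >= m.target_v95_pct \
                    >= m.target_v100_pct >= m.target_v105_pct

    def test_v105cc_consistent_with_target_v105(self, tuned_heldout):
        for rec in tuned_heldout:
            p = rec["case"].phantom
            t = p.masks["breast_target"]
            m = rec["metrics_after"]
            in_target_cc = float(
                (rec["dose_after"].dose[t] >= 1.05 * 5000.0).sum()) \
                * p.voxel_volume_cc
            expect = m.target_v105_pct / 100.0 * t.sum() * p.voxel_volume_cc
            assert in_target_cc <= expect + p.voxel_volume_cc
            assert m.v105_cc >= in_target_cc - 1e-9

    def test_missing_mask_rejected(self):
        grid, p = _mini_phantom()
        del p.masks["heart"]
        with pytest.raises(ValueError, match="heart"):
            plan_metrics(grid, p, 5000.0)

    def test_dvh_monotone_on_cohort_plans(self, tuned_heldout):
        rec = tuned_heldout[0]
        p = rec["case"].phantom
        curve = dvh(rec["dose_after"], p.masks["breast_target"])
        assert np.all(np.diff(curve["volume_pct"].to_numpy()) <= 0)
        assert curve["volume_pct"].iloc[0] == 100.0


class TestWilcoxon:
    def test_all_positive_n5(self):
        _, p = wilcoxon_signed_rank_one_sided(
            np.arange(1.0, 6.0), np.zeros(5), "greater")
        assert p == pytest.approx(1.0 / 32.0, abs=1e-15)

    def test_identical_pairs_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            _, p = wilcoxon_signed_rank_one_sided(np.ones(4), np.ones(4))
        assert p == 1.0

    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_matches_brute_force_enumeration(self, alternative):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(2, 11))
            a = np.round(rng.normal(size=n), 1)  # rounding induces ties/zeros
            b = np.round(rng.normal(size=n), 1)
            if np.all(a == b):
                continue
            _, p = wilcoxon_signed_rank_one_sided(a, b, alternative)
            assert p == pytest.approx(
                brute_force_wilcoxon(a, b, alternative), abs=1e-12)

    def test_matches_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.normal(size=9)
            b = rng.normal(size=9)
            _, p = wilcoxon_signed_rank_one_sided(a, b, "greater")
            ref = stats.wilcoxon(a, b, alternative="greater",
                                 method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_large_n_normal_approximation_reasonable(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.5, 1.0, 40)
        b = rng.normal(0.0, 1.0, 40)
        _, p = wilcoxon_signed_rank_one_sided(a, b, "greater")
        ref = stats.wilcoxon(a, b, alternative="greater",
                             method="approx", correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_one_sided(np.ones(3), np.ones(4))


def _random_metrics(rng, n):
    out = []
    for _ in range(n):
        v90 = rng.uniform(93, 97)
        v95 = v90 - rng.uniform(1, 3)
        v100 = v95 - rng.uniform(5, 15)
        v105 = rng.uniform(2, 10)
        out.append(PlanMetrics(
            target_v90_pct=v90, target_v95_pct=v95, target_v100_pct=v100,
            target_v105_pct=min(v105, v100), v105_cc=rng.uniform(20, 150),
            lung_v10gy_pct=rng.uniform(10, 30),
            lung_v20gy_pct=rng.uniform(5, 25),
            lung_v95_pct=rng.uniform(0, 5),
            heart_mean_pct=rng.uniform(1, 3),
            plan_max_pct=rng.uniform(106, 112)))
    return out


class TestCompareCohorts:
    def test_identical_cohorts_nothing_significant(self):
        rng = np.random.default_rng(1)
        ms = _random_metrics(rng, 10)
        report = compare_cohorts(ms, ms)
        assert report.significant() == []
        assert len(report.table) == 8

    def test_bonferroni_threshold(self):
        rng = np.random.default_rng(2)
        ms = _random_metrics(rng, 6)
        report = compare_cohorts(ms, ms, alpha=0.05, m=8)
        assert report.adjusted_threshold == pytest.approx(0.05 / 8)
        assert round(report.adjusted_threshold, 3) == 0.006

    def test_shifted_endpoint_flagged_alone(self):
        rng = np.random.default_rng(3)
        auto = _random_metrics(rng, 20)
        clinical = _random_metrics(rng, 20)
        # shift one harm-direction endpoint by ~10 SD in the auto cohort
        for m in auto:
            m.heart_mean_pct += 10.0
        report = compare_cohorts(auto, clinical)
        assert report.significant() == ["heart_mean_pct"]

    def test_unpaired_cohorts_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            compare_cohorts(_random_metrics(rng, 3), _random_metrics(rng, 4))
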