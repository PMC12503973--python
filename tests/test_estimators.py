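"""Causal estimators and diagnostics against hand-computed oracles."""

import numpy as np
import pytest
from scipy import stats

from protmr.estimators import (NotApplicable, cochran_q, egger, ivw,
                               mode_estimate, mr_presso, wald_ratio,
                               weighted_median)
from protmr.simulate import simulate_mr_protein
from tests.conftest import pair


class TestWaldRatio:
    def test_delta_rule_hand_value(self):
        e = wald_ratio(pair(be=0.1, se_e=0.02, bo=0.05, se_o=0.01))
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.1)

    def test_null_outcome(self):
        e = wald_ratio(pair(bo=0.0))
        assert e.beta == 0.0 and e.pval == pytest.approx(1.0)

    def test_sign_symmetry(self):
        a = wald_ratio(pair(be=0.1, bo=0.05))
        b = wald_ratio(pair(be=-0.1, bo=0.05))
        assert b.beta == pytest.approx(-a.beta) and b.se == pytest.approx(a.se)

    def test_zero_exposure_raises(self):
        with pytest.raises(ValueError):
            wald_ratio(pair(be=0.0))


class TestIVW:
    def test_weighted_mean_hand_value(self, ratio_pairs):
        e = ivw(ratio_pairs)
        assert e.beta == pytest.approx(0.6, abs=1e-12)
        assert e.se == pytest.approx((100 + 25) ** -0.5, abs=1e-12)

    def test_multiplicative_random_scales_by_q(self, ratio_pairs):
        e = ivw(ratio_pairs, "multiplicative_random")
        # Q = 5, J-1 = 1 -> scale sqrt(5)
        assert e.se == pytest.approx(np.sqrt(5) * (125) ** -0.5, abs=1e-12)

    def test_mre_scale_floored_at_one(self):
        pairs = [pair(f"v{i}", be=1.0, bo=0.5, se_o=0.1) for i in range(3)]
        fe = ivw(pairs, "fixed")
        mre = ivw(pairs, "multiplicative_random")
        assert mre.beta == pytest.approx(0.5) and mre.se == pytest.approx(fe.se)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            ivw([pair()])

    def test_two_pair_ivw_with_equal_snps_degenerates_to_wald(self):
        """IVW with duplicated identical instruments equals the Wald ratio."""
        p = pair("v1", be=0.2, se_e=0.01, bo=0.08, se_o=0.02)
        e = ivw([p, pair("v2", be=0.2, se_e=0.01, bo=0.08, se_o=0.02)])
        w = wald_ratio(p)
        assert e.beta == pytest.approx(w.beta)
        assert e.se == pytest.approx(w.se / np.sqrt(2))

    def test_joint_negation_of_exposure_invariant(self, ratio_pairs):
        flipped = [pair(p.variant_id, -p.beta_exp, p.se_exp, -p.beta_out,
                        p.se_out) for p in ratio_pairs]
        assert ivw(flipped).beta == pytest.approx(ivw(ratio_pairs).beta)


class TestCochranQ:
    def test_hand_value_against_chi_square_oracle(self, ratio_pairs):
        q, df, p = cochran_q(ratio_pairs)
        assert q == pytest.approx(5.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(5.0, 1), abs=1e-12)
        assert p == pytest.approx(0.02535, abs=1e-4)

    def test_identical_ratios_give_zero(self):
        pairs = [pair(f"v{i}", be=1.0, bo=0.4, se_o=0.1) for i in range(4)]
        q, df, p = cochran_q(pairs)
        assert q == pytest.approx(0.0, abs=1e-20) and p == pytest.approx(1.0)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(3)
        pairs = [pair(f"v{i}", be=1.0, bo=float(rng.normal(0.3, 0.2)),
                      se_o=float(rng.uniform(0.05, 0.3))) for i in range(6)]
        ratios = np.array([p.beta_out / p.beta_exp for p in pairs])
        w = np.array([(p.beta_exp / p.se_out) ** 2 for p in pairs])
        mu = np.sum(w * ratios) / np.sum(w)
        q_oracle = float(np.sum(w * (ratios - mu) ** 2))
        q, *_ = cochran_q(pairs)
        assert q == pytest.approx(q_oracle, rel=1e-12)


class TestEgger:
    def test_recovers_noiseless_intercept_and_slope(self):
        be = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
        pairs = [pair(f"v{i}", be=float(b), bo=float(0.05 + 0.3 * b), se_o=0.01)
                 for i, b in enumerate(be)]
        est, b0, se0, p0 = egger(pairs)
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert b0 == pytest.approx(0.05, abs=1e-10)

    def test_orientation_invariance_of_slope(self):
        rng = np.random.default_rng(0)
        pairs = [pair(f"v{i}", be=float(rng.uniform(0.05, 0.3)),
                      bo=float(rng.normal(0, 0.05)), se_o=0.02)
                 for i in range(6)]
        flipped = [pair(p.variant_id, -p.beta_exp, p.se_exp, -p.beta_out,
                        p.se_out) for p in pairs]
        assert egger(flipped)[0].beta == pytest.approx(egger(pairs)[0].beta)

    def test_two_instruments_not_applicable(self):
        with pytest.raises(NotApplicable):
            egger([pair("a"), pair("b")])

    def test_intercept_rejection_monotone_in_pleiotropy_mean(self):
        """Directional pleiotropy drives the intercept test: rejection
        rate grows strictly with the planted pleiotropy mean."""
        rates = []
        for mean in (0.0, 0.03, 0.06):
            rej = 0
            for s in range(120):
                pairs, _ = simulate_mr_protein(20, gamma=0.1,
                                               pleiotropy_mean=mean,
                                               pleiotropy_sd=0.01, seed=s)
                _, _, _, p0 = egger(pairs)
                rej += p0 < 0.05
            rates.append(rej / 120)
        assert rates[0] < rates[1] < rates[2]
        assert rates[1] > 0.05

    def test_constant_exposure_is_degenerate(self):
        pairs = [pair(f"v{i}", be=0.1, bo=float(b), se_o=0.01)
                 for i, b in enumerate([0.01, 0.02, 0.03])]
        with pytest.raises(ValueError):
            egger(pairs)


class TestWeightedMedian:
    def test_equal_weights_middle_element(self):
        pairs = [pair(f"v{i}", be=1.0, bo=b, se_o=0.1)
                 for i, b in enumerate([0.4, 0.5, 0.9])]
        e = weighted_median(pairs, n_boot=100, seed=1)
        assert e.beta == pytest.approx(0.5, abs=1e-9)

    def test_dominant_weight_pulls_estimate(self):
        # one instrument with ~97% of weight at ratio 1.0
        pairs = [pair("big", be=1.0, bo=1.0, se_o=0.05)]
        pairs += [pair(f"s{i}", be=1.0, bo=0.1, se_o=0.5) for i in range(3)]
        e = weighted_median(pairs, n_boot=100, seed=1)
        assert e.beta == pytest.approx(1.0, abs=0.05)
        # brute-force cumulative-weight walk oracle
        ratios = np.array([0.1, 0.1, 0.1, 1.0])
        w = np.array([4.0, 4.0, 4.0, 400.0])
        wn = w / w.sum()
        s = np.cumsum(wn) - wn / 2
        k = int(np.searchsorted(s, 0.5))
        oracle = ratios[k - 1] + (0.5 - s[k - 1]) / (s[k] - s[k - 1]) * (
            ratios[k] - ratios[k - 1])
        assert e.beta == pytest.approx(oracle, abs=1e-9)

    def test_seeded_bootstrap_is_deterministic(self):
        pairs = [pair(f"v{i}", be=1.0, bo=b, se_o=0.1)
                 for i, b in enumerate([0.4, 0.5, 0.9])]
        a = weighted_median(pairs, n_boot=200, seed=42)
        b = weighted_median(pairs, n_boot=200, seed=42)
        assert a.se == b.se

    def test_equal_weights_equals_plain_median_odd_j(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0.3, 0.2, size=7)
        pairs = [pair(f"v{i}", be=1.0, bo=float(v), se_o=0.1)
                 for i, v in enumerate(vals)]
        e = weighted_median(pairs, n_boot=50, seed=0)
        assert e.beta == pytest.approx(float(np.median(vals)), abs=1e-9)


class TestModeEstimators:
    def test_simple_mode_finds_cluster(self):
        pairs = [pair(f"v{i}", be=1.0, bo=b, se_o=0.1)
                 for i, b in enumerate([0.5, 0.5, 0.5, 2.0])]
        e = mode_estimate(pairs, "simple", n_boot=50, seed=0)
        assert e.beta == pytest.approx(0.5, abs=0.1)

    def test_all_equal_ratios_return_constant(self):
        pairs = [pair(f"v{i}", be=1.0, bo=0.7, se_o=0.1) for i in range(4)]
        e = mode_estimate(pairs, "simple", n_boot=50, seed=0)
        assert e.beta == pytest.approx(0.7, abs=1e-9)

    def test_weighted_mode_tracks_dominant_weight_cluster(self):
        pairs = [pair(f"b{i}", be=1.0, bo=1.2, se_o=0.05) for i in range(3)]
        pairs += [pair(f"s{i}", be=1.0, bo=0.2, se_o=0.5) for i in range(3)]
        e = mode_estimate(pairs, "weighted", n_boot=50, seed=0)
        assert e.beta == pytest.approx(1.2, abs=0.1)


class TestMRPresso:
    def test_planted_outlier_flagged_and_corrected(self):
        pairs, truth = simulate_mr_protein(11, gamma=0.3, outlier_fraction=0.09,
                                           outlier_scale=10, seed=12)
        assert len(truth.outlier_ids) == 1
        gp, outliers, corrected = mr_presso(pairs, n_sim=1000, seed=12)
        assert set(truth.outlier_ids) <= set(outliers)
        raw = ivw(pairs)
        assert abs(corrected.beta - 0.3) < abs(raw.beta - 0.3)

    def test_concordant_instruments_null_global_p(self):
        """Without planted outliers the global p is uniform-like and
        outlier calls are rare."""
        ps, n_outl = [], 0
        for s in range(20):
            pairs, _ = simulate_mr_protein(10, gamma=0.3, seed=s)
            gp, outliers, _ = mr_presso(pairs, n_sim=300, seed=s)
            ps.append(gp)
            n_outl += len(outliers)
        assert np.median(ps) > 0.2
        assert n_outl <= 2

    def test_seeded_determinism(self):
        pairs, _ = simulate_mr_protein(8, gamma=0.2, seed=9)
        a = mr_presso(pairs, n_sim=300, seed=5)
        b = mr_presso(pairs, n_sim=300, seed=5)
        assert a[0] == b[0] and a[1] == b[1]

    def test_too_few_instruments_not_applicable(self):
        with pytest.raises(NotApplicable):
            mr_presso([pair("a"), pair("b"), pair("c")])
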