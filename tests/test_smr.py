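"""SMR effect test and HEIDI linkage-vs-pleiotropy discrimination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protmr.simulate import make_ld, simulate_locus, standard_truth
from protmr.smr import (classify_smr, correlated_chisq_tail, heidi_select,
                        heidi_test, smr_heidi, smr_test, top_variant)
from protmr.sumstats import HarmonizedPair
from tests.conftest import pair


class TestSMRTest:
    def test_hand_value_with_chi_square_oracle(self):
        b, se, p = smr_test(6.0, 4.0, 0.3, 0.12)
        t = 16 * 36 / (16 + 36)
        assert t == pytest.approx(11.0769, abs=1e-4)
        assert p == pytest.approx(stats.chi2.sf(t, 1), abs=1e-12)
        assert p == pytest.approx(8.7e-4, rel=0.01)
        assert b == pytest.approx(0.4)

    def test_null_gwas_z(self):
        b, se, p = smr_test(6.0, 0.0, 0.3, 0.0)
        assert p == 1.0

    def test_equal_z_gives_half_z_squared(self):
        for z in (2.0, 5.0, -3.0):
            _, _, p = smr_test(z, z, 0.2, 0.2)
            assert p == pytest.approx(stats.chi2.sf(z ** 2 / 2, 1))

    def test_zero_qtl_effect_rejected(self):
        with pytest.raises(ValueError):
            smr_test(6.0, 4.0, 0.0, 0.1)

    def test_harmonic_bound_on_statistic(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            zq, zg = rng.normal(0, 5, 2)
            if zq == 0:
                continue
            _, _, p = smr_test(zq, zg, 1.0, zg / max(abs(zq), 1e-9))
            t = stats.chi2.isf(p, 1) if p < 1 else 0.0
            assert t <= min(zq ** 2, zg ** 2) + 1e-6


def _locus_pairs(m=30, rho=0.8, seed=0, arch="H4_shared", **kw):
    truth = standard_truth(arch, m=m, seed=seed, **kw)
    st = simulate_locus(truth, m=m, rho=rho, seed=seed)
    return [HarmonizedPair(e.variant_id, "A", e.beta, e.se, e.eaf,
                           o.beta, o.se, o.eaf, "aligned")
            for e, o in zip(st.exposure.itertuples(), st.outcome.itertuples())], st.ld


class TestHeidiSelect:
    def test_truncates_to_highest_r2(self):
        pairs, ld = _locus_pairs(m=40, rho=0.95, seed=1, gamma=0.5,
                                 exposure_effect=0.4)
        sel = heidi_select(pairs, ld, max_snps=5)
        assert len(sel) <= 5
        top = top_variant(pairs)
        if len(sel) >= 2:
            r2s = [float(ld.loc[top.variant_id, v]) ** 2 for v in sel]
            assert r2s == sorted(r2s, reverse=True)

    def test_excludes_top_variant_and_r2_window(self):
        pairs, ld = _locus_pairs(m=30, rho=0.8, seed=2, gamma=0.5,
                                 exposure_effect=0.4)
        top = top_variant(pairs)
        sel = heidi_select(pairs, ld)
        assert top.variant_id not in sel
        for v in sel:
            r2 = float(ld.loc[top.variant_id, v]) ** 2
            assert 0.05 <= r2 <= 0.9

    def test_all_neighbors_too_correlated_yields_empty(self):
        # three tightly linked strong variants: all r2 > 0.9 with the top
        ld = make_ld(3, 0.99)
        pairs = [pair(v, be=0.5, se_e=0.01, bo=0.2, se_o=0.05)
                 for v in ld.index]
        assert heidi_select(pairs, ld, r2_max=0.9) == []


class TestHeidiTest:
    def test_zero_deviation_gives_p_one(self):
        ld = make_ld(4, 0.5)
        ids = list(ld.index)
        # identical SMR ratio at every variant: b_out = 0.4 * b_exp
        pairs = [pair(v, be=0.3, se_e=0.01, bo=0.12, se_o=0.01) for v in ids]
        p = heidi_test(pairs[1:], pairs[0], ld)
        assert p == pytest.approx(1.0)

    def test_relabeling_selected_variants_invariant(self):
        pairs, ld = _locus_pairs(m=25, rho=0.8, seed=3, gamma=0.5,
                                 exposure_effect=0.4)
        top = top_variant(pairs)
        sel_ids = heidi_select(pairs, ld)
        by_id = {p.variant_id: p for p in pairs}
        sel = [by_id[v] for v in sel_ids]
        if len(sel) >= 3:
            p_a = heidi_test(sel, top, ld)
            p_b = heidi_test(sel[::-1], top, ld)
            assert p_a == pytest.approx(p_b, rel=1e-9)

    def test_shared_variant_truth_gives_uniform_like_p(self):
        ps = []
        for s in range(60):
            pairs, ld = _locus_pairs(m=30, rho=0.8, seed=s, gamma=0.5,
                                     exposure_effect=0.25)
            res = smr_heidi(pairs, ld)
            if res.p_heidi is not None:
                ps.append(res.p_heidi)
        assert len(ps) >= 30
        assert np.median(ps) > 0.2

    def test_linkage_truth_rejected_often(self):
        rejections, n = 0, 0
        for s in range(40):
            pairs, ld = _locus_pairs(m=30, rho=0.8, seed=s, arch="H3_linkage",
                                     exposure_effect=0.25, outcome_effect=0.25,
                                     linkage_separation=2)
            res = smr_heidi(pairs, ld)
            if res.p_heidi is not None:
                n += 1
                rejections += res.p_heidi < 0.05
        assert n >= 20
        assert rejections / n > 0.5


class TestCorrelatedChisqTail:
    def test_identity_correlation_matches_chi_square(self):
        corr = np.eye(5)
        for s in (2.0, 5.0, 11.0):
            assert correlated_chisq_tail(s, corr) == pytest.approx(
                stats.chi2.sf(s, 5), rel=1e-5)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(123)
        a = rng.normal(size=(6, 6))
        cov = a @ a.T
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(6))
        draws = (chol @ rng.standard_normal((6, 50_000)))
        stats_mc = np.sum(draws ** 2, axis=0)
        for q in (0.1, 0.3, 0.5, 0.7, 0.9):
            s = float(np.quantile(stats_mc, q))
            p_mc = float(np.mean(stats_mc > s))
            p_mm = correlated_chisq_tail(s, corr)
            assert abs(p_mm - p_mc) < 0.01


class TestClassifySMR:
    @pytest.mark.parametrize("p_smr, m, p_heidi, expect", [
        (3.09e-4, 22, 0.222, True),    # significant SMR, HEIDI clean
        (8.79e-7, 22, 1.74e-3, False),  # HEIDI indicates linkage
        (0.05 / 22, 22, 0.5, False),    # boundary is strict
        (1e-6, 22, None, False),        # undefined HEIDI fails
    ])
    def test_dispositions(self, p_smr, m, p_heidi, expect):
        assert classify_smr(p_smr, m, p_heidi) is expect
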