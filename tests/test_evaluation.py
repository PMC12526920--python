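"""Error, agreement and group-comparison statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cecgkit as ck


class TestRRErrors:
    @pytest.mark.parametrize("ref,tex,err,erp", [
        (1.0, 1.0, 0.0, 0.0),
        (1.0, 0.95, 0.05, 5.0),
        (0.8, 0.9, -0.1, 12.5),   # checks the absolute-value convention of ERP
    ])
    def test_hand_arithmetic(self, ref, tex, err, erp):
        pair = ck.rr_errors(ref, tex)
        assert pair.err == pytest.approx(err)
        assert pair.erp == pytest.approx(erp)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            ck.rr_errors(0.0, 1.0)
        with pytest.raises(ValueError):
            ck.rr_errors(1.0, -0.5)


class TestCoverageRates:
    def test_all_zero_erps(self):
        cov = ck.coverage_rates([0.0] * 35)
        assert cov.rates == (100.0, 0.0, 0.0, 0.0, 0.0)

    def test_boundary_membership(self):
        cov = ck.coverage_rates([4.0, 5.0, 6.0])  # 5 belongs to [0, 5]
        assert cov.rates[0] == pytest.approx(200 / 3)
        assert cov.rates[1] == pytest.approx(100 / 3)
        assert cov.rates[2:] == (0.0, 0.0, 0.0)

    def test_open_upper_bin(self):
        assert ck.coverage_rates([25.0]).rates[-1] == 100.0

    def test_negative_erp_rejected(self):
        with pytest.raises(ValueError):
            ck.coverage_rates([-1.0])

    @given(st.lists(st.floats(0, 60, allow_nan=False), min_size=1, max_size=50))
    def test_rates_sum_to_100_and_bins_partition(self, erps):
        cov = ck.coverage_rates(erps)
        assert sum(cov.rates) == pytest.approx(100.0, abs=1e-9)
        assert all(r >= 0 for r in cov.rates)


class TestBlandAltman:
    def test_hand_computed_symmetric_case(self):
        res = ck.bland_altman([-1.0, 0.0, 1.0])
        assert res.bias == pytest.approx(0.0)
        assert res.sd == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)

    def test_zero_variance(self):
        res = ck.bland_altman([0.3, 0.3, 0.3])
        assert res.bias == res.loa_low == res.loa_high == pytest.approx(0.3)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            ck.bland_altman([0.1])

    def test_sign_convention_reference_minus_textile(self):
        ref = np.array([1.0, 1.1, 0.9])
        tex = np.array([1.05, 1.0, 0.95])
        errs = [ck.rr_errors(r, t).err for r, t in zip(ref, tex)]
        res = ck.bland_altman(errs)
        assert res.bias == pytest.approx(-float(np.mean(tex - ref)))


class TestLinfitCorr:
    def test_identity_line(self):
        x = np.linspace(0.5, 1.2, 20)
        slope, intercept, r = ck.linfit_corr(x, x)
        assert (slope, intercept, r) == pytest.approx((1.0, 0.0, 1.0))

    def test_exact_affine_line(self):
        x = np.linspace(0, 10, 30)
        slope, intercept, r = ck.linfit_corr(x, 2 * x + 1)
        assert (slope, intercept, r) == pytest.approx((2.0, 1.0, 1.0))

    def test_independent_samples_have_small_r(self):
        rng = np.random.default_rng(100)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        _, _, r = ck.linfit_corr(x, y)
        assert abs(r) < 0.2

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            ck.linfit_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def exhaustive_sign_test_p(n_pos: int, n: int) -> float:
    """Oracle: enumerate all 2^n equally likely sign patterns."""
    patterns = list(itertools.product([1, -1], repeat=n))
    le = sum(1 for p in patterns if sum(1 for s in p if s > 0) <= n_pos)
    ge = sum(1 for p in patterns if sum(1 for s in p if s > 0) >= n_pos)
    return min(1.0, 2.0 * min(le, ge) / 2 ** n)


class TestSignTest:
    def test_five_positive_differences(self):
        res = ck.sign_test([1] * 5, [0] * 5)
        assert res.p == pytest.approx(0.0625)
        assert (res.n_pos, res.n_neg, res.n_zero) == (5, 0, 0)

    def test_balanced_pair(self):
        assert ck.sign_test([1, 0], [0, 1]).p == pytest.approx(1.0)

    def test_zeros_excluded_from_trials(self):
        a = [1] * 7 + [5] * 3
        b = [0] * 7 + [5] * 3
        res = ck.sign_test(a, b)
        assert res.n_zero == 3
        assert res.p == pytest.approx(2 * 0.5 ** 7)

    def test_all_zero_differences_flagged(self):
        res = ck.sign_test([2, 2], [2, 2])
        assert res.p == 1.0 and res.all_zero

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8, 12])
    def test_agrees_with_exhaustive_enumeration(self, n):
        for k in range(n + 1):
            a = [1.0] * k + [-1.0] * (n - k)
            res = ck.sign_test(a, [0.0] * n)
            assert res.p == pytest.approx(exhaustive_sign_test_p(k, n), abs=1e-12)


def _group_df(values, subject="s1"):
    return pd.DataFrame({"subject": subject, "section": range(len(values)),
                         "sqi": values})


class TestRunComparison:
    def test_identical_groups_null_case(self):
        vals = list(np.linspace(0.5, 2.0, 35))
        table = ck.run_comparison({"A": _group_df(vals), "B": _group_df(vals)})
        assert table.p_values.loc["A", "B"] == 1.0
        assert (table.summary.loc["A"] == table.summary.loc["B"]).all()

    def test_uniform_shift_forces_all_signs(self):
        vals = np.linspace(0.5, 2.0, 20)
        table = ck.run_comparison({
            "A": _group_df(vals), "B": _group_df(vals + 0.1)})
        assert table.p_values.loc["A", "B"] == pytest.approx(2 * 0.5 ** 20)

    def test_summary_matches_independent_computation(self):
        rng = np.random.default_rng(9)
        va, vb = rng.uniform(0.2, 3.0, 35), rng.uniform(0.2, 3.0, 35)
        table = ck.run_comparison({"A": _group_df(va), "B": _group_df(vb)})
        row = table.summary.loc["A"]
        assert row["median"] == pytest.approx(float(np.median(va)))
        assert row["mean"] == pytest.approx(float(np.mean(va)))
        assert row["std"] == pytest.approx(float(np.std(va, ddof=1)))
        assert row["range"] == pytest.approx(float(np.ptp(va)))
        assert row["N"] == 35

    def test_unpairable_sections_rejected(self):
        a = _group_df([1.0, 2.0, 3.0])
        b = _group_df([1.0, 2.0, 3.0], subject="s2")
        with pytest.raises(ValueError):
            ck.run_comparison({"A": a, "B": b})


class TestEndToEndRecovery:
    def test_mean_erp_decreases_with_noise_and_vanishes_clean(self):
        spec = ck.RRSeriesSpec(mean_hr=None, hr_sd=0, duration=5 * 15 + 2)
        cfg = ck.RunConfig(n_sections=5)
        noises = [ck.NoiseSpec.none(),
                  ck.NoiseSpec(broadband_sd=0.3),
                  ck.NoiseSpec(broadband_sd=1.2)]
        means = []
        for noise in noises:
            pairs = ck.gen_paired_dataset(3, spec, noise=noise, seed=17)
            df = ck.paired_section_errors(pairs, cfg)
            means.append(df["erp"].mean())
        assert means[0] <= 1.0
        assert means[0] <= means[1] <= means[2]
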