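"""Closed-form scale-factor fits against independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vibscale.errors import DegenerateInputError, EmptyDatasetError
from vibscale.fitting import (
    ScaleFactorFit,
    evaluate_armsd,
    evaluate_rrmsd,
    fit_absolute,
    fit_relative,
    format_fit,
    lsq_scale,
)

from conftest import (
    armsd_direct,
    make_table,
    numeric_s_abs,
    numeric_s_rel,
    random_table,
    rrmsd_direct,
)

# frozen from the golden-section/direct-sum oracle on (1000,980),(2000,1880),(3000,2850)
THREE_PAIR_S_ABS = 0.9492857142857143
THREE_PAIR_ARMSD = 20.759392595940312
THREE_PAIR_SIGMA_ABS = 5.548181046538596e-3
THREE_PAIR_S_REL = 0.9560712121838727
THREE_PAIR_RRMSD = 0.017600629905612696


class TestLsqScale:
    def test_exact_proportionality(self):
        res = lsq_scale([1.0, 2.0], [2.0, 4.0])
        assert res.s_min == pytest.approx(2.0)
        assert res.sigma0 == 0.0 and res.sigma_s == 0.0

    def test_single_point_fits_exactly(self):
        res = lsq_scale([1.0], [3.0])
        assert res.s_min == pytest.approx(3.0)
        assert res.sigma0 == 0.0

    def test_three_point_example_against_oracle_values(self):
        res = lsq_scale([1000.0, 2000.0, 3000.0], [980.0, 1880.0, 2850.0])
        assert res.s_min == pytest.approx(THREE_PAIR_S_ABS, abs=1e-12)
        assert res.sigma0 == pytest.approx(THREE_PAIR_ARMSD, rel=1e-10)
        assert res.sigma_s == pytest.approx(THREE_PAIR_SIGMA_ABS, rel=1e-10)

    @pytest.mark.parametrize(
        "x, y",
        [([1.0, 2.0], [1.0]), ([], []), ([0.0, 0.0], [1.0, 2.0])],
    )
    def test_degenerate_inputs_rejected(self, x, y):
        with pytest.raises(DegenerateInputError):
            lsq_scale(x, y)

    def test_uncertainty_identity_sigma_s_sq_times_sxx(self):
        """sigma_s^2 * S_xx == sigma0^2: the ML variance identity."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = random_table(rng)
            res = lsq_scale(t.nu_calc, t.nu_exp)
            assert res.sigma_s**2 * res.s_xx == pytest.approx(
                res.sigma0**2, rel=1e-12, abs=1e-300
            )

    def test_sigma_s_matches_curvature_of_objective(self):
        """sigma_s agrees with (d2Phi/ds2)^(-1/2)*sigma0 from second
        differences of the summed squared-residual objective."""
        rng = np.random.default_rng(11)
        t = random_table(rng, n=500)
        res = lsq_scale(t.nu_calc, t.nu_exp)
        x, y = t.nu_calc, t.nu_exp

        def phi(s):
            return 0.5 * math.fsum((s * x - y) ** 2) / res.sigma0**2

        h = 1e-5
        curvature = (phi(res.s_min + h) - 2 * phi(res.s_min)
                     + phi(res.s_min - h)) / h**2
        assert res.sigma_s == pytest.approx(curvature**-0.5, rel=1e-4)


class TestFitObjectives:
    def test_absolute_exact_table(self, exact_table):
        fit = fit_absolute(exact_table)
        assert fit.s == pytest.approx(0.95, abs=1e-14)
        assert fit.armsd == pytest.approx(0.0, abs=1e-9)

    def test_relative_exact_table(self, exact_table):
        fit = fit_relative(exact_table)
        assert fit.s == pytest.approx(0.95, abs=1e-14)
        assert fit.rrmsd == pytest.approx(0.0, abs=1e-12)

    def test_absolute_three_pair(self, three_pair_table):
        fit = fit_absolute(three_pair_table)
        assert fit.objective == "absolute"
        assert fit.s == pytest.approx(THREE_PAIR_S_ABS, abs=1e-12)
        assert fit.armsd == pytest.approx(THREE_PAIR_ARMSD, rel=1e-10)
        assert fit.sigma == pytest.approx(THREE_PAIR_SIGMA_ABS, rel=1e-10)
        # cross-evaluated metric matches a direct evaluation
        assert fit.rrmsd == pytest.approx(
            evaluate_rrmsd(fit.s, three_pair_table), rel=1e-12
        )

    def test_relative_three_pair(self, three_pair_table):
        fit = fit_relative(three_pair_table)
        assert fit.objective == "relative"
        assert fit.s == pytest.approx(THREE_PAIR_S_REL, abs=1e-12)
        assert fit.rrmsd == pytest.approx(THREE_PAIR_RRMSD, rel=1e-10)
        assert fit.armsd == pytest.approx(
            evaluate_armsd(fit.s, three_pair_table), rel=1e-12
        )

    def test_relative_rejects_zero_experimental_frequency(self):
        table = make_table([1000.0], [1000.0])
        object.__setattr__(table.pairs[0], "nu_exp", 0.0)
        with pytest.raises(DegenerateInputError):
            fit_relative(table)

    def test_single_pair_sigma_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            fit = fit_absolute(make_table([1000.0], [950.0]))
        assert fit.s == pytest.approx(0.95)
        assert fit.sigma == 0.0
        assert any("single pair" in r.message for r in caplog.records)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_closed_form_agrees_with_numeric_minimiser(self, seed):
        """Closed-form s equals scalar minimisation of the objective."""
        rng = np.random.default_rng(seed)
        t = random_table(rng)
        x, y = t.nu_calc, t.nu_exp
        assert fit_absolute(t).s == pytest.approx(
            numeric_s_abs(x, y), abs=1e-10
        )
        assert fit_relative(t).s == pytest.approx(
            numeric_s_rel(x, y), abs=1e-10
        )

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_covariance_under_rescaling_of_computed_axis(self, seed, c):
        """nu_calc -> c*nu_calc maps s -> s/c and sigma -> sigma/c and
        leaves the minimised aRMSD unchanged."""
        rng = np.random.default_rng(seed)
        t = random_table(rng)
        t2 = make_table(c * t.nu_calc, t.nu_exp)
        for fit_fn in (fit_absolute, fit_relative):
            f1, f2 = fit_fn(t), fit_fn(t2)
            assert f2.s == pytest.approx(f1.s / c, rel=1e-12)
            assert f2.sigma == pytest.approx(f1.sigma / c, rel=1e-9)
            minimised = f1.armsd if fit_fn is fit_absolute else f1.rrmsd
            minimised2 = f2.armsd if fit_fn is fit_absolute else f2.rrmsd
            assert minimised2 == pytest.approx(minimised, rel=1e-9, abs=1e-12)

    def test_each_objective_minimises_its_own_metric(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            t = random_table(rng)
            fa, fr = fit_absolute(t), fit_relative(t)
            tol = 1e-12
            assert evaluate_armsd(fa.s, t) <= evaluate_armsd(fr.s, t) + tol
            assert evaluate_rrmsd(fr.s, t) <= evaluate_rrmsd(fa.s, t) + tol


class TestEvaluators:
    def test_zero_at_identity_on_identical_lists(self):
        t = make_table([500.0, 1200.0], [500.0, 1200.0])
        assert evaluate_armsd(1.0, t) == 0.0
        assert evaluate_rrmsd(1.0, t) == 0.0

    def test_three_pair_armsd_at_optimum(self, three_pair_table):
        assert evaluate_armsd(THREE_PAIR_S_ABS, three_pair_table) == pytest.approx(
            THREE_PAIR_ARMSD, rel=1e-9
        )

    def test_single_equal_pair_rrmsd_closed_form(self):
        t = make_table([1234.0], [1234.0])
        for s in (0.8, 1.0, 1.3):
            assert evaluate_rrmsd(s, t) == pytest.approx(abs(s - 1.0))

    def test_agree_with_direct_sums(self, three_pair_table):
        x, y = three_pair_table.nu_calc, three_pair_table.nu_exp
        for s in (0.9, 0.95, 1.05):
            assert evaluate_armsd(s, three_pair_table) == pytest.approx(
                armsd_direct(s, x, y), rel=1e-14
            )
            assert evaluate_rrmsd(s, three_pair_table) == pytest.approx(
                rrmsd_direct(s, x, y), rel=1e-14
            )

    def test_empty_table_rejected(self):
        from vibscale.dataset import PairTable

        with pytest.raises(EmptyDatasetError):
            evaluate_armsd(1.0, PairTable(method="m", pairs=[]))


class TestFormatFit:
    @pytest.mark.parametrize(
        "s, sigma, expected",
        [
            (0.96883, 0.00031, "0.9688(3)"),
            (0.84004, 0.00058, "0.8400(6)"),
            (1.01841, 0.0019, "1.018(2)"),
            (0.98200, 0.00095, "0.982(1)"),  # sigma rounds up a decade
        ],
    )
    def test_printed_style(self, s, sigma, expected):
        fit = ScaleFactorFit("absolute", s, sigma, 35.0, 0.02, 100, "x")
        assert format_fit(fit) == expected

    def test_zero_sigma_notes_exact_fit(self, caplog):
        fit = ScaleFactorFit("absolute", 1.0, 0.0, 0.0, 0.0, 2, "x")
        with caplog.at_level("INFO"):
            assert format_fit(fit) == "1.0000(0)"
        assert any("exact fit" in r.message for r in caplog.records)
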