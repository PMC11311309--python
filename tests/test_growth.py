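"""Primary growth models: forward evaluation and inversion."""

import numpy as np
import pytest

from freshshelf import (
    GrowthParams,
    LimitAlreadyExceededError,
    LimitNeverReachedError,
    MODEL_KINDS,
    ParameterDomainError,
    evaluate_baranyi,
    evaluate_gompertz,
    evaluate_growth,
    evaluate_huang,
    evaluate_logistic,
    invert_growth,
)
from conftest import TABLE_GOMPERTZ, random_growth_params


class TestEvaluation:
    # frozen values computed independently by direct scalar evaluation of
    # the model equations (see each model's docstring)
    @pytest.mark.parametrize(
        "fn, t, params, expected",
        [
            (evaluate_gompertz, 0.0, (4.691, 6.912, 0.431, 0.087), 4.819995202643537),
            (evaluate_logistic, 5.0, (2.530, 7.267, 0.702, 0.993), 6.532747083857771),
            (evaluate_baranyi, 5.0, (4.832, 6.558, 0.544, 1.715), 6.026184716796816),
            (evaluate_huang, 5.0, (2.530, 7.149, 0.703, 0.994), 5.199336522242736),
        ],
    )
    def test_frozen_oracle_values(self, fn, t, params, expected):
        assert fn(t, GrowthParams(*params)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_asymptote_is_nmax(self, kind, gompertz_ck):
        assert evaluate_growth(kind, 1e6, gompertz_ck) == pytest.approx(
            gompertz_ck.nmax, abs=1e-9
        )

    def test_gompertz_inflection_identity(self):
        # with Nmax - N0 = mu*e the inner exponent is exactly 1 at t = lag
        mu = 0.5
        p = GrowthParams(3.0, 3.0 + mu * np.e, mu, 2.0)
        expected = p.n0 + (p.nmax - p.n0) * np.exp(-np.e)
        assert evaluate_gompertz(p.lag, p) == pytest.approx(expected, rel=1e-12)

    def test_logistic_equals_n0_at_lag(self):
        p = GrowthParams(2.0, 8.0, 0.7, 1.5)
        assert evaluate_logistic(p.lag, p) == pytest.approx(p.n0, rel=1e-12)

    @pytest.mark.parametrize("kind", ["baranyi", "huang"])
    def test_exact_anchor_at_t0(self, kind):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = random_growth_params(rng)
            assert evaluate_growth(kind, 0.0, p) == p.n0

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_monotone_and_bounded(self, kind):
        grid = np.arange(0.0, 50.0 + 1e-9, 0.1)
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = random_growth_params(rng)
            n = np.asarray(evaluate_growth(kind, grid, p))
            assert np.all(np.diff(n) >= -1e-12)
            assert np.all(n < p.nmax + 1e-12)
            floor = p.n0 if kind in ("baranyi", "huang") else min(
                float(evaluate_growth(kind, 0.0, p)), p.n0
            )
            assert np.all(n >= floor - 1e-9)

    @pytest.mark.parametrize("kind", ["baranyi", "huang"])
    def test_stable_at_long_times_and_large_h0(self, kind):
        # contract: finite output up to 1000 d even with overflow-prone params
        p = GrowthParams(3.0, 9.0, 8.0, 100.0)
        vals = np.asarray(evaluate_growth(kind, np.array([0.0, 500.0, 1000.0]), p))
        assert np.all(np.isfinite(vals))

    def test_negative_time_rejected(self, gompertz_ck):
        for kind in MODEL_KINDS:
            with pytest.raises(ValueError):
                evaluate_growth(kind, -0.5, gompertz_ck)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterDomainError):
            GrowthParams(5.0, 4.0, 0.5, 0.1)  # nmax <= n0
        with pytest.raises(ParameterDomainError):
            GrowthParams(2.0, 6.0, -0.1, 0.1)  # mu <= 0
        with pytest.raises(ParameterDomainError):
            GrowthParams(2.0, 6.0, 0.5, -1.0)  # negative lag
        with pytest.raises(ParameterDomainError):
            evaluate_logistic(1.0, GrowthParams(0.0, 6.0, 0.5, 0.0))  # n0 = 0


class TestInversion:
    def test_gompertz_closed_form_frozen(self, gompertz_ck):
        # independent oracle: closed-form algebra cross-checked by bisection
        assert invert_growth("gompertz", gompertz_ck, 5.0) == pytest.approx(
            0.695081159203325, abs=1e-9
        )

    def test_baranyi_bisection_frozen(self):
        p = GrowthParams(4.832, 6.558, 0.544, 1.715)
        assert invert_growth("baranyi", p, 5.5) == pytest.approx(
            2.8449158274697637, abs=1e-9
        )

    def test_logistic_limit_n0_gives_lag(self):
        p = GrowthParams(2.0, 8.0, 0.7, 1.5)
        assert invert_growth("logistic", p, p.n0) == pytest.approx(p.lag, abs=1e-9)

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_round_trip(self, kind):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            p = random_growth_params(rng)
            n_start = float(evaluate_growth(kind, 0.0, p))
            limit = n_start + rng.uniform(0.05, 0.95) * (p.nmax - n_start)
            t = invert_growth(kind, p, limit)
            assert float(evaluate_growth(kind, t, p)) == pytest.approx(limit, abs=1e-9)

    @pytest.mark.parametrize("kind", ["gompertz", "logistic"])
    def test_closed_form_agrees_with_bisection(self, kind):
        from scipy.optimize import brentq

        rng = np.random.default_rng(99)
        for _ in range(100):
            p = random_growth_params(rng)
            n_start = float(evaluate_growth(kind, 0.0, p))
            limit = n_start + rng.uniform(0.05, 0.95) * (p.nmax - n_start)
            t_cf = invert_growth(kind, p, limit)
            t_bis = brentq(
                lambda t: float(evaluate_growth(kind, t, p)) - limit,
                0.0,
                max(2 * t_cf, 10.0),
                xtol=1e-12,
            )
            assert t_cf == pytest.approx(t_bis, abs=1e-9)

    def test_limit_signals(self, gompertz_ck):
        with pytest.raises(LimitAlreadyExceededError):
            invert_growth("gompertz", gompertz_ck, 4.5)  # below N(0) = 4.82
        with pytest.raises(LimitNeverReachedError):
            invert_growth("gompertz", gompertz_ck, 7.5)  # above Nmax

    def test_treatment_inversions_consistent(self):
        # inversions of the fitted arms, consistent with the model algebra
        # (deliberately not the published shelf-life column, which is not
        # reproducible from its own parameters)
        expected = {"CK": 0.695081159203325, "NaClO": 1.9069165436358844,
                    "PDT": 4.260407744589981}
        for trt, p in TABLE_GOMPERTZ.items():
            assert invert_growth("gompertz", p, 5.0) == pytest.approx(
                expected[trt], abs=1e-9
            )
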