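"""Closed-form behaviour of the growth sigmoids and their derived quantities.

Frozen expected values were computed with a 40-digit mpmath evaluation of
the same closed forms (root finding included) as an independent oracle.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leaffit import models
from leaffit.errors import ConfigurationError, ParameterDomainError
from leaffit.models import CellProfileParams, GrowthParams, SigmoidFamily


def valid_growth_params():
    return st.builds(
        lambda lm, t0, d_m, d_e: GrowthParams(
            Lm=lm, t0=t0, tm=t0 + d_m, te=t0 + d_m + d_e
        ),
        lm=st.floats(10, 2000),
        t0=st.floats(0, 50),
        d_m=st.floats(5, 300),
        d_e=st.floats(5, 300),
    )


def valid_profile_params():
    return st.builds(
        lambda lb, amp, pm, d_e: CellProfileParams(
            Lb=lb, Lm=lb + amp, Pm=pm, Pe=pm + d_e
        ),
        lb=st.floats(1, 30),
        amp=st.floats(5, 300),
        pm=st.floats(0.5, 40),
        d_e=st.floats(1, 60),
    )


class TestLengthAt:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (231.0, 535.0),  # L(te) = Lm by construction
            (0.0, 0.0),  # zero at growth start
            (167.0, 331.77148051953),  # oracle value at tm
            (300.0, 535.0),  # plateau beyond te
            (-5.0, 0.0),  # pre-growth
        ],
    )
    def test_control_curve(self, control_params, t, expected):
        assert models.length_at(control_params, t) == pytest.approx(expected, rel=1e-9)

    def test_vectorized(self, control_params):
        t = np.array([0.0, 167.0, 231.0, 250.0])
        out = models.length_at(control_params, t)
        assert out.shape == t.shape
        assert out[-1] == pytest.approx(535.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterDomainError):
            GrowthParams(Lm=-1, t0=0, tm=100, te=200)
        with pytest.raises(ParameterDomainError):
            GrowthParams(Lm=100, t0=0, tm=200, te=200)  # tm >= te

    @settings(derandomize=True, max_examples=50)
    @given(params=valid_growth_params())
    def test_nondecreasing_on_domain(self, params):
        grid = np.linspace(params.t0, params.te, 400)
        vals = models.length_at(params, grid)
        assert np.all(np.diff(vals) >= -1e-9 * params.Lm)


class TestRateAt:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.0, 0.0), (231.0, 0.0), (167.0, 4.578620263532)],
    )
    def test_control_rate(self, control_params, t, expected):
        assert models.rate_at(control_params, t) == pytest.approx(expected, abs=1e-9)

    def test_matches_finite_difference(self, control_params):
        h = 1e-4
        for t in (50.0, 120.0, 167.0, 210.0):
            fd = (
                models.length_at(control_params, t + h)
                - models.length_at(control_params, t - h)
            ) / (2 * h)
            assert models.rate_at(control_params, t) == pytest.approx(fd, rel=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(params=valid_growth_params())
    def test_nonnegative_and_zero_at_ends(self, params):
        grid = np.linspace(params.t0 - 10, params.te + 10, 300)
        rates = models.rate_at(params, grid)
        assert np.all(rates >= 0)
        assert models.rate_at(params, params.t0) == 0.0
        assert models.rate_at(params, params.te) == 0.0


class TestMaxRate:
    def test_control_value(self, control_params):
        tm, lermax = models.max_rate(control_params)
        assert tm == 167.0
        assert lermax == pytest.approx(4.578620263532, rel=1e-9)
        # the paper-style rounded report
        assert round(lermax, 1) == 4.6

    def test_linear_in_final_length(self, control_params):
        doubled = GrowthParams(2 * control_params.Lm, 0, 167, 231)
        assert models.max_rate(doubled)[1] == pytest.approx(
            2 * models.max_rate(control_params)[1]
        )

    def test_equals_rate_at_tm(self, control_params):
        tm, lermax = models.max_rate(control_params)
        assert lermax == pytest.approx(models.rate_at(control_params, tm), rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(params=valid_growth_params())
    def test_closed_form_is_grid_maximum(self, params):
        grid = np.arange(params.t0, params.te, 0.01)
        grid_max = models.rate_at(params, grid).max()
        _, lermax = models.max_rate(params)
        assert lermax >= grid_max - 1e-9
        # within one grid step of the dense maximum
        assert lermax == pytest.approx(grid_max, rel=1e-4)


class TestInversion:
    @pytest.mark.parametrize(
        "L, expected",
        [
            (535.0, 231.0),  # inverse at the plateau onset
            (100.0, 107.8162846288),  # t100 oracle; paper prints 108 ± 4 °Cd
            (267.5, 152.8127900687),  # t50% oracle; paper prints 153 ± 5 °Cd
        ],
    )
    def test_time_at_length(self, control_params, L, expected):
        assert models.time_at_length(control_params, L) == pytest.approx(
            expected, abs=1e-6
        )

    @pytest.mark.parametrize(
        "f, expected",
        [
            (1.0, 231.0),
            (0.9, 202.7272641947),  # paper prints 203 ± 5 °Cd
            (0.2, 110.2565105886),  # paper prints 111 ± 4 °Cd
        ],
    )
    def test_time_at_fraction(self, control_params, f, expected):
        assert models.time_at_fraction(control_params, f) == pytest.approx(
            expected, abs=1e-6
        )

    @pytest.mark.parametrize("L", [0.0, -5.0, 600.0])
    def test_out_of_range_length(self, control_params, L):
        with pytest.raises(ParameterDomainError):
            models.time_at_length(control_params, L)

    @pytest.mark.parametrize("f", [0.0, -0.1, 1.5])
    def test_out_of_range_fraction(self, control_params, f):
        with pytest.raises(ParameterDomainError):
            models.time_at_fraction(control_params, f)

    @settings(derandomize=True, max_examples=50)
    @given(
        params=valid_growth_params(),
        u=st.floats(0.01, 1.0),
    )
    def test_round_trip(self, params, u):
        t = params.t0 + u * (params.te - params.t0)
        L = models.length_at(params, t)
        if L <= 0:
            return
        assert models.time_at_length(params, L) == pytest.approx(t, abs=1e-6)

    @settings(derandomize=True, max_examples=30)
    @given(params=valid_growth_params())
    def test_fraction_ordering(self, params):
        ts = [models.time_at_fraction(params, f) for f in (0.2, 0.5, 0.9, 1.0)]
        assert ts == sorted(ts)
        assert ts[-1] == params.te


class TestRateWindow:
    def test_degenerate_full_fraction(self, control_params):
        assert models.rate_window(control_params, 1.0) == (167.0, 167.0, 0.0)

    def test_control_widths(self, control_params):
        # oracle values; the steadier (95 %) window is the narrower one
        _, _, w90 = models.rate_window(control_params, 0.90)
        _, _, w95 = models.rate_window(control_params, 0.95)
        assert w90 == pytest.approx(49.3186468486, abs=1e-6)
        assert w95 == pytest.approx(34.6393838805, abs=1e-6)

    @settings(derandomize=True, max_examples=30)
    @given(params=valid_growth_params())
    def test_nesting_and_monotone_width(self, params):
        lo90, hi90, w90 = models.rate_window(params, 0.90)
        lo95, hi95, w95 = models.rate_window(params, 0.95)
        assert lo90 < lo95 < params.tm < hi95 < hi90
        assert w95 < w90

    def test_bad_fraction(self, control_params):
        with pytest.raises(ParameterDomainError):
            models.rate_window(control_params, 0.0)


class TestCellLength:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.0, 10.9),  # basal value is Lb
            (43.4, 118.5),  # mature value is Lm
            (21.3, 64.0877381097),  # oracle value at Pm
            (60.0, 118.5),  # plateau beyond Pe
        ],
    )
    def test_control_profile(self, control_profile, p, expected):
        assert models.cell_length_at(control_profile, p) == pytest.approx(
            expected, rel=1e-9
        )

    def test_negative_position_rejected(self, control_profile):
        with pytest.raises(ParameterDomainError):
            models.cell_length_at(control_profile, -1.0)

    def test_invalid_params(self):
        with pytest.raises(ParameterDomainError):
            CellProfileParams(Lb=50, Lm=40, Pm=10, Pe=20)  # Lb >= Lm

    @settings(derandomize=True, max_examples=50)
    @given(params=valid_profile_params())
    def test_nondecreasing_with_fixed_ends(self, params):
        grid = np.linspace(0, params.Pe, 300)
        vals = models.cell_length_at(params, grid)
        assert np.all(np.diff(vals) >= -1e-9 * params.Lm)
        assert vals[0] == pytest.approx(params.Lb)
        assert vals[-1] == pytest.approx(params.Lm)


class TestAltSigmoids:
    def test_logistic_midpoint(self):
        fam = SigmoidFamily("logistic", 0.0, 1.0, 0.0, 1.0)
        assert models.alt_sigmoid_at(fam, 0.0) == pytest.approx(0.5)

    def test_gompertz_upper_asymptote(self):
        fam = SigmoidFamily("gompertz", 0.0, 1.0, 0.0, 1.0)
        assert models.alt_sigmoid_at(fam, 50.0) == pytest.approx(1.0)

    def test_weibull_oracle_value(self):
        fam = SigmoidFamily("weibull", 2.0, 10.0, 5.0, 2.0)
        # 2 + 8 (1 - e^-1)
        assert models.alt_sigmoid_at(fam, 5.0) == pytest.approx(
            2 + 8 * (1 - np.exp(-1))
        )

    def test_unknown_family(self):
        with pytest.raises(ConfigurationError):
            SigmoidFamily("richards", 0.0, 1.0, 0.0, 1.0)

    @pytest.mark.parametrize("family", ["logistic", "gompertz", "weibull", "beta"])
    def test_monotone_nondecreasing(self, family):
        fam = SigmoidFamily(family, 2.0, 50.0, 10.0, 2.0 if family != "beta" else 20.0)
        grid = np.linspace(0, 40, 200)
        vals = models.alt_sigmoid_at(fam, grid)
        assert np.all(np.diff(vals) >= -1e-9)
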