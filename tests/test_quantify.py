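"""Charcoal correction, two-component deconvolution, and contents."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duospec.quantify import (
    AbsorptivityMatrix,
    CorrectionCoefficients,
    NonPositiveAbsorbanceError,
    PUBLISHED_EPSILON,
    SingularSystemError,
    contents,
    correction_coefficient,
    quantify_sample,
    solve_two_component,
)
from duospec.spectra import Spectrum


def forward(c_hmf, c_la, path_length=1.0, eps=PUBLISHED_EPSILON):
    """Forward Beer's law at the two analytical wavelengths."""
    a266 = path_length * (eps["HMF"][266.0] * c_hmf + eps["LA"][266.0] * c_la)
    a284 = path_length * (eps["HMF"][284.0] * c_hmf + eps["LA"][284.0] * c_la)
    return a266, a284


def grid_search_oracle(a266, a284, bounds=((0.0, 0.1), (0.0, 65.0)),
                       passes=6, points=81):
    """Brute-force least-squares oracle: minimize ||A − E·C|| over a grid,
    refined around the best point each pass."""
    e = AbsorptivityMatrix().as_array()
    target = np.array([a266, a284])
    (lo_h, hi_h), (lo_l, hi_l) = bounds
    best = None
    for _ in range(passes):
        gh = np.linspace(lo_h, hi_h, points)
        gl = np.linspace(lo_l, hi_l, points)
        hh, ll = np.meshgrid(gh, gl, indexing="ij")
        resid = (
            (e[0, 0] * hh + e[0, 1] * ll - target[0]) ** 2
            + (e[1, 0] * hh + e[1, 1] * ll - target[1]) ** 2
        )
        i, j = np.unravel_index(np.argmin(resid), resid.shape)
        best = (gh[i], gl[j])
        span_h = (hi_h - lo_h) / (points - 1) * 2
        span_l = (hi_l - lo_l) / (points - 1) * 2
        lo_h, hi_h = best[0] - span_h, best[0] + span_h
        lo_l, hi_l = best[1] - span_l, best[1] + span_l
    return best


class TestCorrectionCoefficient:
    @staticmethod
    def flat(value):
        return Spectrum([250.0, 300.0], [value, value])

    def test_published_la_ratio(self):
        # A ratio 0.81 / 0.50 reproduces the published K_LA = 1.62
        k = correction_coefficient(self.flat(0.81), self.flat(0.50), 266.0)
        assert k == pytest.approx(1.62)

    def test_identical_spectra_give_unity(self):
        s = self.flat(0.7)
        assert correction_coefficient(s, s, 284.0) == pytest.approx(1.0)

    def test_zero_after_absorbance_rejected(self):
        with pytest.raises(NonPositiveAbsorbanceError):
            correction_coefficient(self.flat(0.8), self.flat(0.0), 284.0)

    def test_ratio_below_one_warns(self):
        with pytest.warns(UserWarning, match="K = "):
            k = correction_coefficient(self.flat(0.5), self.flat(0.8), 284.0)
        assert k == pytest.approx(0.625)

    def test_coefficients_container_rejects_k_below_one(self):
        with pytest.raises(ValueError):
            CorrectionCoefficients(K={"HMF": 0.9, "LA": 1.62})


class TestSolveTwoComponent:
    def test_inverts_forward_construction(self):
        a266, a284 = forward(0.05, 30.0)
        assert a266 == pytest.approx(1.309)
        assert a284 == pytest.approx(1.555)
        c_hmf, c_la = solve_two_component(a266, a284)
        assert c_hmf == pytest.approx(0.05, rel=1e-12)
        assert c_la == pytest.approx(30.0, rel=1e-12)

    def test_cramers_rule_by_hand(self):
        # 2x2 Cramer check with the published epsilon matrix
        a266, a284 = 1.0, 1.5
        e = AbsorptivityMatrix().as_array()
        det = e[0, 0] * e[1, 1] - e[0, 1] * e[1, 0]
        c_hmf_hand = (a266 * e[1, 1] - e[0, 1] * a284) / det
        c_la_hand = (e[0, 0] * a284 - a266 * e[1, 0]) / det
        c_hmf, c_la = solve_two_component(a266, a284)
        assert c_hmf == pytest.approx(c_hmf_hand, rel=1e-12)
        assert c_la == pytest.approx(c_la_hand, rel=1e-12)

    def test_zero_absorbance_gives_zero(self):
        assert solve_two_component(0.0, 0.0) == (0.0, 0.0)

    def test_pure_hmf(self):
        a266, a284 = forward(0.08, 0.0)
        c_hmf, c_la = solve_two_component(a266, a284)
        assert c_hmf == pytest.approx(0.08, rel=1e-12)
        assert c_la == pytest.approx(0.0, abs=1e-12)

    def test_path_length_scales_absorbance(self):
        a266, a284 = forward(0.05, 30.0, path_length=2.0)
        c = solve_two_component(a266, a284, path_length=2.0)
        assert c == pytest.approx((0.05, 30.0), rel=1e-12)

    def test_singular_matrix_rejected(self):
        with pytest.raises(SingularSystemError):
            AbsorptivityMatrix(
                entries={"HMF": {266.0: 1.0, 284.0: 2.0}, "LA": {266.0: 2.0, 284.0: 4.0}}
            )

    @given(
        c_hmf=st.floats(0.0, 0.1),
        c_la=st.floats(0.0, 65.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_round_trip_property(self, c_hmf, c_la):
        """Forward Beer's law then solve recovers concentrations to 1e-9."""
        got = np.array(solve_two_component(*forward(c_hmf, c_la)))
        want = np.array([c_hmf, c_la])
        # vector-relative error, the standard accuracy measure for a linear
        # solve; tiny absolute floor covers the all-zero input
        assert np.linalg.norm(got - want) <= 1e-9 * np.linalg.norm(want) + 1e-14

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            c_hmf, c_la = rng.uniform(0.01, 0.09), rng.uniform(5.0, 60.0)
            a266, a284 = forward(c_hmf, c_la)
            solved = solve_two_component(a266, a284)
            oracle = grid_search_oracle(a266, a284)
            assert solved[0] == pytest.approx(oracle[0], abs=1e-6)
            assert solved[1] == pytest.approx(oracle[1], abs=1e-4)


class TestContents:
    @pytest.mark.parametrize(
        "c,m,k,r,expected",
        [
            (1.0, 1.0, 1.0, 1.0, 1.0),
            (1.0, 116.12, 1.62, 2.0, 376.2288),  # LA with published K, R=2
            (0.0, 126.11, 69.3, 10.0, 0.0),
        ],
    )
    def test_product_formula(self, c, m, k, r, expected):
        assert contents(c, m, k, r) == pytest.approx(expected)

    @given(c=st.floats(0, 1), m=st.floats(0, 200), k=st.floats(1, 100),
           r=st.floats(1, 10), scale=st.floats(0.1, 10))
    @settings(deadline=None, max_examples=50)
    def test_linear_in_each_argument(self, c, m, k, r, scale):
        base = contents(c, m, k, r)
        assert contents(c, m, k, r * scale) == pytest.approx(base * scale, rel=1e-12)
        assert contents(c * scale, m, k, r) == pytest.approx(base * scale, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            contents(-1.0, 1.0, 1.0, 1.0)


class TestQuantifySample:
    @staticmethod
    def spectrum_from(c_hmf, c_la, dilution=1.0):
        grid = np.array([260.0, 266.0, 275.0, 284.0, 290.0])
        eps = PUBLISHED_EPSILON
        a266 = eps["HMF"][266.0] * c_hmf + eps["LA"][266.0] * c_la
        a284 = eps["HMF"][284.0] * c_hmf + eps["LA"][284.0] * c_la
        # linear ramp between the two anchor wavelengths; only 266/284 are read
        absorbances = np.interp(grid, [260.0, 266.0, 284.0, 290.0],
                                [a266, a266, a284, a284])
        return Spectrum(grid, absorbances, dilution_factor=dilution)

    def test_unit_correction_round_trip(self):
        """With K = 1, R = 1: W equals C × M for both analytes."""
        c_hmf, c_la = 0.06, 42.0
        result = quantify_sample(
            self.spectrum_from(c_hmf, c_la),
            correction={"HMF": 1.0, "LA": 1.0},
        )
        assert result.concentrations["HMF"] == pytest.approx(c_hmf, rel=1e-9)
        assert result.concentrations["LA"] == pytest.approx(c_la, rel=1e-9)
        assert result.contents_mg_L["HMF"] == pytest.approx(c_hmf * 126.11, rel=1e-9)
        assert result.contents_mg_L["LA"] == pytest.approx(c_la * 116.12, rel=1e-9)
        assert result.flags == set()

    def test_correction_and_dilution_applied(self):
        result = quantify_sample(self.spectrum_from(0.05, 30.0, dilution=2.0))
        assert result.contents_mg_L["HMF"] == pytest.approx(
            0.05 * 126.11 * 69.3 * 2.0, rel=1e-9
        )
        assert result.contents_mg_L["LA"] == pytest.approx(
            30.0 * 116.12 * 1.62 * 2.0, rel=1e-9
        )

    def test_all_zero_spectrum_flags_below_loq(self):
        s = Spectrum([260.0, 270.0, 284.0, 290.0], [0.0, 0.0, 0.0, 0.0])
        result = quantify_sample(s, loqs={"HMF": 0.017, "LA": 4.68})
        assert result.contents_mg_L == {"HMF": 0.0, "LA": 0.0}
        assert "below_loq:HMF" in result.flags
        assert "below_loq:LA" in result.flags

    def test_negative_concentration_clamped_and_flagged(self):
        # A284 too low relative to A266 forces a negative HMF solution
        s = Spectrum([260.0, 266.0, 284.0, 290.0], [0.9, 0.9, 0.4, 0.4])
        result = quantify_sample(s, correction={"HMF": 1.0, "LA": 1.0})
        assert result.concentrations["HMF"] == 0.0
        assert "negative_clamped:HMF" in result.flags
        assert result.contents_mg_L["HMF"] == 0.0
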