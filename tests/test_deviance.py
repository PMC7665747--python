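"""Standardized deviance, FHR distance, and c-deviant feature distributions."""

import math

import numpy as np
import pytest

from endevs.deviance import (
    NormativePrediction,
    c_deviant_distribution,
    deviant_patterns,
    fhr_deviance,
    fhr_distance,
    per_subject_effective,
    select_deviant,
    standardized_deviance,
)
from endevs.errors import (
    DegenerateDevianceError,
    ThresholdError,
    ValidationError,
    ZeroVarianceError,
)


def make_pred(mu, sigma2, eta2):
    return NormativePrediction(np.atleast_2d(mu), np.atleast_2d(sigma2), np.atleast_1d(eta2))


class TestStandardizedDeviance:
    def test_centered_observation_gives_zero(self):
        pred = make_pred(np.ones((3, 2)), np.ones((3, 2)), [0.5, 0.5])
        assert np.all(standardized_deviance(np.ones((3, 2)), pred) == 0)

    def test_unit_deviation(self):
        mu = np.zeros((2, 2))
        sigma2 = np.full((2, 2), 0.75)
        eta2 = np.array([0.25, 0.25])
        y = mu + 1.0  # sqrt(0.75 + 0.25) = 1
        pred = make_pred(mu, sigma2, eta2)
        assert standardized_deviance(y, pred) == pytest.approx(np.ones((2, 2)))

    def test_hand_arithmetic(self):
        pred = make_pred([[2.0]], [[0.16]], [0.09])
        assert standardized_deviance([[3.0]], pred)[0, 0] == pytest.approx(2.0)

    def test_shift_invariance(self, rng):
        mu = rng.standard_normal((4, 3))
        y = rng.standard_normal((4, 3))
        pred = make_pred(mu, np.ones((4, 3)), np.ones(3))
        shifted = make_pred(mu + 7.0, np.ones((4, 3)), np.ones(3))
        np.testing.assert_allclose(
            standardized_deviance(y, pred), standardized_deviance(y + 7.0, shifted)
        )

    def test_zero_variance_names_feature(self):
        pred = make_pred(np.zeros((2, 3)), np.zeros((2, 3)), [1.0, 0.0, 1.0])
        with pytest.raises(ZeroVarianceError, match=r"\[1\]"):
            standardized_deviance(np.zeros((2, 3)), pred)


class TestFHR:
    @pytest.mark.parametrize(
        "p, y, expected",
        [
            (0.3, 0.3, 0.0),
            (0.0, 1.0, math.pi),
            (0.5, 1.0, math.pi / 2),
        ],
    )
    def test_known_values(self, p, y, expected):
        assert fhr_distance(p, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_arcsin_form(self, rng):
        p, y = rng.random(50), rng.random(50)
        d = fhr_distance(p, y)
        np.testing.assert_allclose(d, fhr_distance(y, p))
        alt = 2.0 * np.abs(np.arcsin(np.sqrt(p)) - np.arcsin(np.sqrt(y)))
        np.testing.assert_allclose(d, alt, atol=1e-9)

    def test_triangle_inequality(self, rng):
        a, b, c = rng.random((3, 300))
        assert np.all(fhr_distance(a, c) <= fhr_distance(a, b) + fhr_distance(b, c) + 1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            fhr_distance(-0.1, 0.5)
        with pytest.raises(ValidationError):
            fhr_distance(0.5, 1.2)

    def test_deviance_matrix(self):
        z = fhr_deviance([[0.0, 0.5, 0.3]], [[1.0, 1.0, 0.3]])
        assert z[0, 0] == pytest.approx(math.pi**2)
        assert z[0, 1] == pytest.approx((math.pi / 2) ** 2)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert np.all((z >= 0) & (z <= math.pi**2 + 1e-12))


class TestSelection:
    def test_modes_on_signed_row(self):
        z = np.array([[-3.0, 0.0, 2.0]])
        np.testing.assert_allclose(select_deviant(z, "absolute-top"), [[3, 0, 2]])
        # signed-bottom ranks on -Z: the most negative feature ranks first
        ranked = select_deviant(z, "signed-bottom")
        np.testing.assert_allclose(ranked, [[3, 0, -2]])
        assert ranked[0].argmax() == 0
        assert select_deviant(z, "signed-top")[0].argmax() == 2

    def test_unknown_mode(self):
        with pytest.raises(ValidationError):
            select_deviant(np.zeros((1, 2)), "median")


class TestCDeviantDistribution:
    def test_c_one_preserves_proportionality(self):
        pat = c_deviant_distribution([3.0, 2.0, 1.0], 1.0)
        np.testing.assert_allclose(pat.psi, [0.5, 1 / 3, 1 / 6])
        assert list(pat.support) == [0, 1, 2]

    def test_survival_thresholding(self):
        pat = c_deviant_distribution([3.0, 2.0, 1.0], 0.4)
        np.testing.assert_allclose(pat.psi, [0.6, 0.4, 0.0])

    def test_tied_maximum_both_survive(self):
        pat = c_deviant_distribution([5.0, 5.0, 1.0], 0.1)
        np.testing.assert_allclose(pat.psi, [0.5, 0.5, 0.0])

    def test_retention_monotone_in_c(self, rng):
        z = np.abs(rng.standard_normal(40))
        sizes = [c_deviant_distribution(z, c).support.size for c in (0.05, 0.2, 0.5, 1.0)]
        assert sizes == sorted(sizes)
        # as c -> 0+ exactly the maximal tie-set survives
        tiny = c_deviant_distribution(z, 1e-12)
        assert list(tiny.support) == [int(np.argmax(z))]

    def test_errors(self):
        with pytest.raises(ThresholdError):
            c_deviant_distribution([1.0, 2.0], 0.0)
        with pytest.raises(ThresholdError):
            c_deviant_distribution([1.0, 2.0], 1.5)
        with pytest.raises(DegenerateDevianceError):
            c_deviant_distribution([0.0, 0.0], 0.5)


class TestPerSubjectEffective:
    def test_bounded_by_support_with_equality_iff_uniform(self, rng):
        z = np.abs(rng.standard_normal(20)) + 0.01
        pat = c_deviant_distribution(z, 0.5)
        eff = per_subject_effective(pat, 1.0)
        assert eff <= pat.support.size + 1e-9
        uniform = c_deviant_distribution(np.ones(7), 1.0)
        assert per_subject_effective(uniform, 2.0) == pytest.approx(7.0)

    def test_hand_value(self):
        pat = c_deviant_distribution([3.0, 2.0, 1.0], 0.4)  # psi = (0.6, 0.4, 0)
        assert per_subject_effective(pat, 2.0) == pytest.approx(1.0 / 0.52)


def test_deviant_patterns_drops_degenerate_rows(caplog):
    Z = np.array([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
    psi, kept = deviant_patterns(Z, "absolute-top", 1.0)
    assert list(kept) == [0, 2]
    assert psi.shape == (2, 2)
    with pytest.raises(DegenerateDevianceError):
        deviant_patterns(Z, "absolute-top", 1.0, on_degenerate="raise")


def test_signed_bottom_weights_are_magnitudes():
    # most negative entries selected, but psi weights use |Z|
    Z = np.array([[-4.0, -1.0, 3.0]])
    psi, _ = deviant_patterns(Z, "signed-bottom", 0.5)
    np.testing.assert_allclose(psi, [[0.8, 0.2, 0.0]])
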