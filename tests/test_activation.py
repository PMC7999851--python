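"""Density estimation, the intersection/legacy cutoffs, percent activation."""

import numpy as np
import pytest
from scipy.stats import norm

from hitfca import (
    ActivationCutoff,
    CutoffError,
    DataError,
    DensityCurve,
    density_on_log_fl1,
    intersection_cutoff,
    legacy_cutoff,
    paired_densities,
    percent_activation,
)

from conftest import full_gate, make_log_table


def gaussian_curve(mu, sigma, grid, n=10_000):
    return DensityCurve(grid=grid, density=norm.pdf(grid, mu, sigma), bandwidth=sigma, n=n)


def two_gaussian_crossing(m1, s1, m2, s2):
    """Closed form: root of the density-equality quadratic between the means."""
    if np.isclose(s1, s2):
        return 0.5 * (m1 + m2)
    a = 1 / (2 * s1**2) - 1 / (2 * s2**2)
    b = -m1 / s1**2 + m2 / s2**2
    c = m1**2 / (2 * s1**2) - m2**2 / (2 * s2**2) + np.log(s1 / s2)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots > m1) & (roots < m2)]
    assert inside.size == 1
    return float(inside[0])


class TestDensity:
    def test_mode_location_standard_normal(self):
        # a standard normal is flat at its peak, so the KDE argmax has
        # sampling sd ~0.1 at n=10,000; 0.3 is a 3-sigma bound on recovery
        rng = np.random.default_rng(0)
        t = make_log_table(fl1=rng.normal(0.0, 1.0, 10_000))
        curve = density_on_log_fl1(t, full_gate(t))
        assert abs(curve.mode) <= 0.3

    def test_mode_location_sharp_component(self):
        # at the assay's realistic FL1 spread the mode is recovered tightly
        rng = np.random.default_rng(0)
        t = make_log_table(fl1=rng.normal(1.0, 0.3, 10_000))
        curve = density_on_log_fl1(t, full_gate(t))
        assert curve.mode == pytest.approx(1.0, abs=0.1)

    def test_integral_is_one(self):
        rng = np.random.default_rng(1)
        t = make_log_table(fl1=rng.normal(2.0, 0.4, 5_000))
        curve = density_on_log_fl1(t, full_gate(t))
        assert np.trapezoid(curve.density, curve.grid) == pytest.approx(1.0, abs=0.01)

    def test_too_few_events_rejected(self):
        t = make_log_table(fl1=np.random.default_rng(2).normal(0, 1, 50))
        with pytest.raises(DataError):
            density_on_log_fl1(t, full_gate(t))


class TestIntersectionCutoff:
    def test_equal_variance_crossing_at_midpoint(self):
        grid = np.linspace(-1, 5, 2000)
        neg = gaussian_curve(1.0, 0.3, grid)
        pos = gaussian_curve(3.0, 0.3, grid)
        cut = intersection_cutoff(neg, pos)
        assert cut.value == pytest.approx(2.0, abs=0.05)
        assert cut.method == "intersection"

    def test_unequal_variance_matches_quadratic_root(self):
        grid = np.linspace(-2, 7, 4000)
        neg = gaussian_curve(1.0, 0.2, grid)
        pos = gaussian_curve(3.0, 0.6, grid)
        cut = intersection_cutoff(neg, pos)
        assert cut.value == pytest.approx(two_gaussian_crossing(1.0, 0.2, 3.0, 0.6), abs=0.05)

    def test_identical_curves_rejected(self):
        grid = np.linspace(-2, 4, 1000)
        neg = gaussian_curve(1.0, 0.3, grid)
        pos = gaussian_curve(1.0, 0.3, grid)
        with pytest.raises(CutoffError):
            intersection_cutoff(neg, pos)

    def test_sampled_tubes_give_crossing_between_modes(self):
        rng = np.random.default_rng(3)
        neg_t = make_log_table(fl1=rng.normal(1.0, 0.3, 10_000), role="NEG")
        pos_t = make_log_table(fl1=rng.normal(3.0, 0.3, 10_000), role="POS")
        neg, pos = paired_densities(neg_t, full_gate(neg_t), pos_t, full_gate(pos_t))
        cut = intersection_cutoff(neg, pos)
        assert 1.0 < cut.value < 3.0
        assert cut.value == pytest.approx(2.0, abs=0.07)


class TestLegacyCutoff:
    def test_zero_variance_is_the_mean(self):
        t = make_log_table(fl1=np.full(200, 1.5), role="NEG")
        cut = legacy_cutoff(t, full_gate(t))
        assert cut.value == pytest.approx(1.5, abs=1e-6)
        assert cut.method == "legacy_mean2sd"

    def test_normal_sample_mean_plus_two_sd(self):
        rng = np.random.default_rng(4)
        t = make_log_table(fl1=rng.normal(1.0, 0.3, 10_000), role="NEG")
        cut = legacy_cutoff(t, full_gate(t))
        assert cut.value == pytest.approx(1.6, abs=0.02)

    def test_agrees_with_intersection_for_pure_resting_neg(self):
        # when NEG is a single resting Gaussian (its normality assumption
        # holds), the legacy rule classifies POS within 3 points of the
        # intersection rule
        rng = np.random.default_rng(8)
        n = 10_000
        neg_t = make_log_table(fl1=rng.normal(1.0, 0.3, n), role="NEG")
        act = rng.random(n) < 0.93
        pos_fl1 = np.where(act, rng.normal(3.0, 0.3, n), rng.normal(1.0, 0.3, n))
        pos_t = make_log_table(fl1=pos_fl1, role="POS")
        neg, pos = paired_densities(neg_t, full_gate(neg_t), pos_t, full_gate(pos_t))
        cut_i = intersection_cutoff(neg, pos)
        cut_l = legacy_cutoff(neg_t, full_gate(neg_t))
        pct_i = percent_activation(pos_t, full_gate(pos_t), cut_i).percent_activated
        pct_l = percent_activation(pos_t, full_gate(pos_t), cut_l).percent_activated
        assert abs(pct_i - pct_l) <= 3.0

    def test_gaussian_tail_beyond_legacy_cutoff(self):
        rng = np.random.default_rng(5)
        t = make_log_table(fl1=rng.normal(1.0, 0.3, 50_000), role="NEG")
        cut = legacy_cutoff(t, full_gate(t))
        pct = percent_activation(t, full_gate(t), cut).percent_activated
        assert pct == pytest.approx(2.3, abs=0.5)


class TestPercentActivation:
    def test_saturation_and_baseline(self):
        t = make_log_table(fl1=np.full(100, 3.0))
        assert percent_activation(t, full_gate(t), ActivationCutoff(2.0, "intersection")).percent_activated == 100.0
        assert percent_activation(t, full_gate(t), ActivationCutoff(4.0, "intersection")).percent_activated == 0.0

    def test_boundary_events_are_inactive(self):
        t = make_log_table(fl1=np.array([2.0, 2.0, 3.0, 1.0]))
        pct = percent_activation(t, full_gate(t), ActivationCutoff(2.0, "intersection"))
        assert pct.percent_activated == 25.0

    def test_mixture_recovery(self):
        rng = np.random.default_rng(6)
        n = 10_000
        act = rng.random(n) < 0.55
        fl1 = np.where(act, rng.normal(3.0, 0.3, n), rng.normal(1.0, 0.3, n))
        t = make_log_table(fl1=fl1)
        pct = percent_activation(t, full_gate(t), ActivationCutoff(2.0, "intersection"))
        assert pct.percent_activated == pytest.approx(55.0, abs=2.0)

    def test_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(7)
        t = make_log_table(fl1=rng.normal(2.0, 0.5, 5_000))
        cuts = np.linspace(0.0, 4.0, 21)
        pcts = [percent_activation(t, full_gate(t), ActivationCutoff(c, "intersection")).percent_activated
                for c in cuts]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))
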