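"""Rate laws, temporal strategies and the eps-mediated trade-off."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mepweb import (ScheduleSpec, balanced_coupling, kinetic_drive_fk,
                    monod_rate, omega_schedule, photo_rate, prey_weighting)


def test_circadian_window_allocation():
    s = ScheduleSpec("circadian", 0.2389, 0.7799, 1.0)
    assert omega_schedule(0.5, s) == 1.0          # midday: all to fixation
    assert omega_schedule(0.1, s) == 0.0          # night: all to biosynthesis
    assert omega_schedule(123.5, s) == 1.0        # diel periodicity


def test_circadian_wraparound_window():
    s = ScheduleSpec("circadian", 0.8, 0.2, 0.7)
    assert omega_schedule(0.9, s) == 0.7
    assert omega_schedule(0.1, s) == 0.7
    assert omega_schedule(0.5, s) == 0.0


def test_full_window_equals_passive():
    c = ScheduleSpec("circadian", 0.0, 1.0, 0.8036)
    p = ScheduleSpec("passive", amplitude=0.8036)
    for t in np.linspace(0, 2, 37):
        assert omega_schedule(t, c) == omega_schedule(t, p)


def test_kinetic_drive_half_saturation():
    eps = 0.1628
    half = 5000.0 * eps ** 4
    assert half == pytest.approx(3.51, abs=0.01)
    assert kinetic_drive_fk([half], eps, 5000.0) == pytest.approx(0.5)
    assert kinetic_drive_fk([], eps, 5000.0) == 1.0     # empty product
    assert kinetic_drive_fk([1.0, 1.0], 0.0, 5000.0) == 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.01, 0.999), st.floats(0, 1e4), st.floats(0, 1e4))
def test_kinetic_drive_bounded_monotone(eps, c1, c2):
    fk = kinetic_drive_fk([c1, c2], eps, 5000.0)
    assert 0.0 <= fk <= 1.0
    assert kinetic_drive_fk([c1 + 1.0, c2], eps, 5000.0) >= fk


def test_adaptive_monod_reference_value():
    assert monod_rate(350.0, 0.1628, 0.4349, 1.0, 1.0, 1.0) == pytest.approx(
        4.034, abs=1e-3)
    assert monod_rate(350.0, 0.0, 0.5, 10.0, 1.0, 1.0) == 0.0
    assert monod_rate(350.0, 0.3, 0.5, 2.0, 1.0, 1.0) == 2 * monod_rate(
        350.0, 0.3, 0.5, 1.0, 1.0, 1.0)


def test_oligotroph_copiotroph_crossover():
    """On a fixed substrate, the low-eps (high affinity) ecotype outgrows
    the high-eps (fast) one below a crossover concentration and loses above
    it; brute-force grid agrees with the closed form."""
    e1, e2, kappa = 0.2, 0.6, 5000.0
    def rate(eps, c):
        return monod_rate(350.0, eps, 1.0, 1.0,
                          kinetic_drive_fk([c], eps, kappa), 1.0)
    # closed form: nu e1^2 c/(c+k e1^4) = nu e2^2 c/(c+k e2^4)  =>
    # c* = kappa e1^2 e2^2
    c_star = kappa * (e1 * e2) ** 2
    assert c_star > 0
    grid = np.geomspace(1e-3, 5e4, 4000)
    diff = np.array([rate(e1, c) - rate(e2, c) for c in grid])
    sign_change = grid[np.where(np.diff(np.sign(diff)))[0]]
    assert len(sign_change) == 1
    assert sign_change[0] == pytest.approx(c_star, rel=0.02)
    assert rate(e1, c_star / 10) > rate(e2, c_star / 10)
    assert rate(e1, c_star * 10) < rate(e2, c_star * 10)


def test_photo_rate_limits():
    assert photo_rate(0.0, 2.0, 1.0, 1.0) == 0.0        # night
    assert photo_rate(100.0, 2.0, 1.0, 1.0) == 50.0
    assert photo_rate(100.0, 2.0, 0.5, 0.0187) == pytest.approx(0.4675)
    with pytest.raises(ValueError):
        photo_rate(100.0, 0.0, 1.0, 1.0)


def test_prey_weighting_normalization():
    w = prey_weighting([0.5], [3.0])
    assert w[0] == 1.0
    assert prey_weighting([0.5, 0.5], [0.0, 0.0]).sum() == 0.0
    np.testing.assert_allclose(prey_weighting([0.4, 0.4], [3.0, 1.0]),
                               [0.75, 0.25])
    with pytest.raises(ValueError):
        prey_weighting([], [])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=6),
       st.lists(st.floats(0, 100), min_size=1, max_size=6))
def test_prey_weighting_sums_to_one_or_zero(om, conc):
    n = min(len(om), len(conc))
    w = prey_weighting(om[:n], conc[:n])
    assert w.sum() == pytest.approx(1.0) or w.sum() == 0.0
    assert np.all(w >= 0)


def test_balanced_coupling_night_shutdown():
    r1, r2 = balanced_coupling(0.0, 5.0, 0.25, 1.1)
    assert r1 == 0.0 and r2 == 0.0


def test_balanced_coupling_holds_storage_ratio():
    """In a closed system (no transport bias) the coupled rates satisfy
    eps r1 - r2 = rho* eps r2, i.e. d([CP]/[SP])/dt = 0."""
    eps, rho = 0.2536, 1.1
    for r1k, r2k in [(10.0, 5.0), (2.0, 50.0), (7.0, 7.0)]:
        r1, r2 = balanced_coupling(r1k, r2k, eps, rho)
        assert r1 <= r1k + 1e-12 and r2 <= r2k + 1e-12
        assert eps * r1 - r2 == pytest.approx(rho * eps * r2, abs=1e-10)


def test_balanced_coupling_rejects_bad_ratio():
    with pytest.raises(ValueError):
        balanced_coupling(1.0, 1.0, 0.5, 0.0)


def test_sinusoid_schedule_is_periodic_and_bounded():
    s = ScheduleSpec("sinusoid", amplitude=0.6, freq=1.0, phase=0.25)
    ts = np.linspace(0, 3, 301)
    vals = np.array([omega_schedule(t, s) for t in ts])
    assert vals.min() >= 0.0 and vals.max() <= 0.6 + 1e-12
    # diel periodicity at freq = 1/d
    assert omega_schedule(0.4, s) == pytest.approx(omega_schedule(2.4, s))
    # phase shifts the peak: maximum sits a quarter period after the phase
    assert omega_schedule(0.5, s) == pytest.approx(0.6)
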