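"""Closed-form layer: frequency functions, growth estimators, effect
inversion and population scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hitchdriver as hd
from hitchdriver.growth import GrowthParams


def consistent_params(r, k, f_d, n_tot):
    """Growth parameters whose biopsy time is implied by (r, k, f_d, N):
    e^{r t2} equals the subclone's neutral-equivalent size and e^{rT}
    equals the regular-population bookkeeping total."""
    fdn = f_d * n_tot
    root = fdn ** (1.0 / k)
    T = math.log(n_tot - fdn + root) / r
    t2 = math.log(root) / r
    return GrowthParams(r=r, k=k, t1=T - t2, t2=t2, n_tot=n_tot, f_d=f_d)


@pytest.mark.parametrize(
    "t_n, r, expected",
    [(0.0, 0.5, 1.0), (2.0, 0.0, 1.0), (1.0, math.log(2), 0.5)],
)
def test_neutral_frequency(t_n, r, expected):
    assert hd.neutral_frequency(t_n, r) == pytest.approx(expected, abs=1e-12)


def test_k1_collapses_to_neutral():
    """A neutral 'driver' leaves the hitchhiker curve exactly exponential."""
    p = GrowthParams(r=0.3, k=1.0, t1=40, t2=20, n_tot=1e6, f_d=0.2)
    t = np.linspace(0.0, 40.0, 101)
    np.testing.assert_allclose(
        hd.hitchhiker_frequency(t, p), hd.neutral_frequency(t, 0.3), rtol=1e-9
    )


def test_hitchhiker_limit_is_driver_frequency():
    """As the hitchhiker's birth time approaches the driver's, its
    frequency approaches the driver's frequency from above."""
    p = consistent_params(r=0.1, k=2.0, f_d=0.3, n_tot=1e6)
    assert hd.hitchhiker_frequency(p.t1, p) == pytest.approx(p.f_d, rel=1e-9)
    assert hd.hitchhiker_frequency(p.t1 * 0.9, p) > p.f_d


def test_hitchhiker_two_population_oracle():
    """Frequency equals the explicit regular + fitness - overlap ledger."""
    r, k, f_d, n_tot, t_m = 0.2, 2.0, 0.25, 1e6, 10.0
    p = consistent_params(r, k, f_d, n_tot)
    # independent bookkeeping: regular descendants of the hitchhiker's
    # origin cell, the driver subclone, minus the subclone's hypothetical
    # neutral growth (not double counted)
    n_regular = math.exp(r * (p.T - t_m))
    n_fitness = math.exp(k * r * p.t2)
    n_overlap = math.exp(r * p.t2)
    expected = (n_regular + n_fitness - n_overlap) / n_tot
    assert hd.hitchhiker_frequency(t_m, p) == pytest.approx(expected, rel=1e-10)


def test_hitchhiker_monotone_and_bounded():
    p = consistent_params(r=0.05, k=3.0, f_d=0.2, n_tot=1e8)
    t = np.linspace(0.0, p.t1, 200)
    f = hd.hitchhiker_frequency(t, p)
    assert np.all(np.diff(f) < 0)
    assert np.all(f >= p.f_d - 1e-12)
    assert f[0] <= 1.0 + 1e-12


def test_rejects_degenerate_subclone():
    with pytest.raises(ValueError):
        hd.hitchhiker_frequency(1.0, GrowthParams(r=0.1, k=2, t1=10, t2=5, n_tot=1e6, f_d=0.0))


@given(
    r=st.floats(0.05, 2.0),
    A=st.floats(0.1, 1.0),
    B=st.floats(0.0, 0.3),
    t0=st.floats(0.0, 5.0),
)
@settings(max_examples=60, deadline=None)
def test_growth_estimators_exact_and_affine_invariant(r, A, B, t0):
    """Both growth estimators are exact on any noiseless A e^{-rt} + B
    series, hence invariant to affine scaling of the frequencies."""
    f = lambda t: A * math.exp(-r * t) + B
    est1 = hd.growth_from_triplet(f(t0), f(t0 + 1), f(t0 + 2))
    assert est1 == pytest.approx(r, abs=1e-10)
    for n in (1, 2, 5):
        est2 = hd.growth_closed_form(f(t0), f(t0 + n), f(t0 + 2 * n), n)
        assert est2 == pytest.approx(r, abs=1e-10)


def test_closed_form_worked_root():
    """Lambda ~ 0.7311 at r = 0.5, n = 2: the non-trivial quadratic root
    e^{-1} is taken (the other root is the trivial zero-growth x^n = 1)."""
    f = lambda t: math.exp(-0.5 * t)
    lam = (f(0) - f(2)) / (f(0) - f(4))
    assert lam == pytest.approx(0.7311, abs=1e-4)
    assert hd.growth_closed_form(f(0), f(2), f(4), 2) == pytest.approx(0.5, abs=1e-12)


def test_closed_form_matches_triplet_at_unit_spacing():
    f = lambda t: 0.8 * math.exp(-0.3 * t) + 0.05
    a, b, c = f(1), f(2), f(3)
    assert hd.growth_closed_form(a, b, c, 1) == pytest.approx(
        hd.growth_from_triplet(a, b, c), abs=1e-12
    )


def test_negative_growth_and_undefined_flags():
    f = lambda t: 0.2 * math.exp(0.4 * t)  # growing series -> negative r
    assert hd.growth_from_triplet(f(0), f(1), f(2)) == pytest.approx(-0.4, abs=1e-10)
    # non-monotone triplet is flagged, not raised
    assert math.isnan(hd.growth_from_triplet(0.5, 0.6, 0.4))
    assert math.isnan(hd.growth_closed_form(0.5, 0.5, 0.5, 1))


@given(
    k=st.floats(1.01, 10.0),
    f_d=st.floats(0.05, 0.5),
    log_n=st.floats(4.0, 10.0),
)
@settings(max_examples=80, deadline=None)
def test_effect_roundtrip(k, f_d, log_n):
    """Plateau -> effect inversion is the identity on the forward map."""
    n_tot = 10.0**log_n
    alpha = hd.asymptote_from_effect(k, f_d, n_tot)
    assert hd.effect_from_asymptote(alpha, f_d, n_tot) == pytest.approx(k, rel=1e-6)


def test_effect_worked_example():
    alpha = hd.asymptote_from_effect(2.0, 0.3, 1e6)
    assert alpha == pytest.approx(0.29945, abs=1e-5)
    assert hd.effect_from_asymptote(alpha, 0.3, 1e6) == pytest.approx(2.0, abs=1e-9)


def test_effect_neutral_plateau():
    """alpha = 0 with f_d N = e gives exactly k = 1."""
    n_tot = 1e6
    f_d = math.e / n_tot
    assert hd.effect_from_asymptote(0.0, f_d, n_tot) == pytest.approx(1.0, rel=1e-12)


def test_effect_invalid_fits_flagged():
    assert math.isnan(hd.effect_from_asymptote(0.4, 0.3, 1e6))  # alpha >= f_d
    assert math.isnan(hd.effect_from_asymptote(0.3 - 1e-7, 0.3, 1e6))  # gap <= 1 cell


@pytest.mark.parametrize(
    "k, expected", [(4.0, 1.03), (1.1, 1.001), (1.0, 1.0)]
)
def test_scale_effect_examples(k, expected):
    assert hd.scale_effect(k, 1e4, 1e6) == pytest.approx(expected, abs=1e-12)


@given(k=st.floats(0.0, 10.0), n_sim=st.floats(1e2, 1e6), n_real=st.floats(1e2, 1e10))
@settings(max_examples=50, deadline=None)
def test_scale_effect_conserves_selection_mass(k, n_sim, n_real):
    k_star = hd.scale_effect(k, n_sim, n_real)
    assert n_real * (k_star - 1.0) == pytest.approx(n_sim * (k - 1.0), rel=1e-6, abs=1e-6)


def test_generation_interval():
    assert hd.generation_interval(2.0) == 1.0
    assert hd.generation_interval(10.0) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        hd.generation_interval(0.0)
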