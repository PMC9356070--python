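"""Rate-function unit and property tests.

The central property is thermodynamic consistency: for every reversible
strain-dependent transition pair, ln(forward/backward) must equal the
free-energy drop read from the free-energy profile at the same strain.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from crossbridge import (clamp_rate, equilibrium_chain, force_AM, G_AM,
                         rate_adp_step, rate_attach, rate_attach_rev,
                         rate_detach, rate_pi_exchange, rate_pir_step,
                         rate_powerstroke, reference_parameters,
                         weak_binding_K)
from crossbridge.scheme import build_scheme, free_energy_profile

P = reference_parameters("E_twostep")
PA = reference_parameters("A_beforePS")

x_strain = st.floats(min_value=-22.0, max_value=14.0)


# ---------------------------------------------------------------------------
# clamping
# ---------------------------------------------------------------------------

def test_clamp_band():
    assert clamp_rate(0.0, P) == pytest.approx(1e-6)
    assert clamp_rate(5e4, P, "isometric") == 5e4
    assert clamp_rate(1e7, P, "isometric") == 1e5
    assert clamp_rate(np.inf, P, "shortening") == P.r_max_shortening
    with pytest.raises(ValueError):
        clamp_rate(-1.0, P)
    with pytest.raises(ValueError):
        P.r_max("sideways")


@given(x=x_strain)
@settings(derandomize=True, max_examples=60)
def test_all_rates_nonnegative_and_within_band(x):
    for r in (rate_attach(x, P), rate_attach_rev(x, P),
              rate_adp_step(x, P), rate_detach(x, P, 5e-3),
              *rate_powerstroke(x, P), *rate_pir_step(x, P)):
        assert r >= 0.0
        if r > 0:
            assert P.r_min - 1e-12 <= r <= P.r_max("isometric") + 1e-9


# ---------------------------------------------------------------------------
# attachment
# ---------------------------------------------------------------------------

def test_weak_binding_window():
    assert weak_binding_K(0.0, P) == pytest.approx(np.exp(P.dG_w))
    assert weak_binding_K(P.window_lo - 0.1, P) == 0.0
    assert weak_binding_K(P.window_hi + 0.1, P) == 0.0


def test_attach_zero_outside_window():
    assert rate_attach(P.window_hi + 1.0, P) == 0.0
    assert rate_attach(P.window_lo - 1.0, P) == 0.0
    assert rate_attach_rev(P.window_hi + 1.0, P) == 0.0


def test_attach_at_zero_strain():
    # quadratic term vanishes at x1
    want = min(PA.k_on_prime * np.exp(PA.dG_AMDP_AMDL),
               PA.r_max("isometric"))
    assert rate_attach(PA.x1, PA, "A_beforePS") == pytest.approx(want)
    assert rate_attach_rev(PA.x1, PA, "A_beforePS") == pytest.approx(
        max(PA.k_on_prime, PA.r_min))


def test_attach_matches_printed_formula():
    # high-precision re-evaluation at x = x1 + 2 nm
    x = P.x1 + 2.0
    expo = P.dG_on - (P.k_s / 2) * 4.0 / (2 * P.kBT)
    assert rate_attach(x, P, clamp=False) == pytest.approx(
        P.k_on_prime * np.exp(expo), rel=1e-12)


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="A_beforePS"):
        rate_attach(0.0, P, variant="Z_unknown")


# ---------------------------------------------------------------------------
# Pi exchange
# ---------------------------------------------------------------------------

def test_pi_exchange_pseudo_first_order():
    p = P.replace(k_p_plus=100.0)
    assert rate_pi_exchange(p, p.K_C) == (100.0, 100.0)
    assert rate_pi_exchange(p, 0.0)[1] == 0.0
    p40 = P.replace(k_p_plus=40.0)
    assert rate_pi_exchange(p40, 2 * p40.K_C)[1] == pytest.approx(80.0)
    with pytest.raises(ValueError):
        rate_pi_exchange(P, 1.0, site_K=0.0)


# ---------------------------------------------------------------------------
# power-stroke
# ---------------------------------------------------------------------------

def test_powerstroke_reverse_constant():
    for x in (-10.0, 0.0, 7.7):
        assert rate_powerstroke(x, P)[1] == 2000.0


def test_powerstroke_symmetric_midpoint():
    x = 0.5 * (P.x1 + P.x2)
    k_plus, _ = rate_powerstroke(x, P, clamp=False)
    assert k_plus == pytest.approx(2000.0 * np.exp(P.dG_AMDL_AMDH),
                                   rel=1e-12)


def test_powerstroke_matches_printed_formula():
    p = P.replace(dG_AMDL_AMDH=3.0)
    x = p.x2
    expo = 3.0 + p.k_s * (x - p.x1) ** 2 / (2 * p.kBT)
    assert rate_powerstroke(x, p, clamp=False)[0] == pytest.approx(
        2000.0 * np.exp(expo), rel=1e-12)


# ---------------------------------------------------------------------------
# rigor force law and ADP/detachment steps
# ---------------------------------------------------------------------------

def test_G_AM_anchored_at_x3():
    assert G_AM(P.x3, P) == 0.0
    assert force_AM(P.x3, P) == 0.0


def test_G_AM_single_segment_closed_form():
    p = P.replace(FAM_slopes=(2.0, 2.0))
    L = 3.0
    assert G_AM(p.x3 - L, p) == pytest.approx(2.0 * L ** 2 / (2 * p.kBT))


def test_G_AM_matches_quadrature():
    p = P.replace(FAM_breakpoints=(-2.0, 0.0, 1.5),
                  FAM_slopes=(0.5, 1.2, 2.8, 4.0))
    for x in (-8.0, -1.0, 0.3, 2.0, 6.0):
        # integrate segment-wise so the quadrature never straddles a kink
        knots = np.sort(np.concatenate([[0.0, x - p.x3],
                                        np.asarray(p.FAM_breakpoints)]))
        lo, hi = min(0.0, x - p.x3), max(0.0, x - p.x3)
        knots = knots[(knots >= lo) & (knots <= hi)]
        val = sum(quad(lambda xi: force_AM(p.x3 + xi, p), a, b)[0]
                  for a, b in zip(knots[:-1], knots[1:]))
        if x - p.x3 < 0:
            val = -val
        assert G_AM(x, p) == pytest.approx(val / p.kBT, rel=1e-10,
                                           abs=1e-12)


def test_adp_step_prefactor_and_cap():
    # pick x where the exponent vanishes by solving numerically
    from scipy.optimize import brentq
    f = lambda x: (P.dG_AMDH_AM + P.k_s * (x - P.x2) ** 2 / (2 * P.kBT)
                   - G_AM(x, P))
    x0 = brentq(f, P.x2, 20.0)
    assert rate_adp_step(x0, P) == pytest.approx(P.k_5_at_x1, rel=1e-9)
    # deep negative strain drives the rate into the cap
    assert rate_adp_step(-20.0, P) == P.r_max("isometric")


def test_detach_limits():
    x = P.x3  # F_AM = 0 there
    k2 = P.k_2_zero
    # saturating MgATP
    assert rate_detach(x, P, 1e3) == pytest.approx(
        k2 * P.k_6 / (k2 + P.k_6), rel=1e-3)
    # linear regime
    T = 1e-9
    assert rate_detach(x, P, T, clamp=False) == pytest.approx(
        P.K_1 * k2 * T, rel=1e-3)
    with pytest.raises(ValueError):
        rate_detach(0.0, P, -1e-3)


# ---------------------------------------------------------------------------
# detailed balance against the free-energy profile
# ---------------------------------------------------------------------------

@given(x=st.floats(min_value=-2.7, max_value=14.0))
@settings(derandomize=True, max_examples=60)
def test_detailed_balance_attach_variant_A(x):
    prof = free_energy_profile(build_scheme("A_beforePS", PA), PA, 0.5)
    f = rate_attach(x, PA, "A_beforePS", clamp=False)
    b = rate_attach_rev(x, PA, "A_beforePS", clamp=False)
    drop = prof.evaluate("AMDP", x) - prof.evaluate("AMDP_T", x)
    assert np.log(f / b) == pytest.approx(drop, abs=1e-10)


@given(x=x_strain)
@settings(derandomize=True, max_examples=60)
def test_detailed_balance_powerstroke(x):
    prof = free_energy_profile(build_scheme("E_twostep", P), P, 0.5)
    f, b = rate_powerstroke(x, P, clamp=False)
    drop = prof.evaluate("AMD_L", x) - prof.evaluate("AMD_H", x)
    assert np.log(f / b) == pytest.approx(drop, abs=1e-10)


@given(x=x_strain)
@settings(derandomize=True, max_examples=60)
def test_detailed_balance_pir_step(x):
    prof = free_energy_profile(build_scheme("E_twostep", P), P, 0.5)
    f, b = rate_pir_step(x, P, clamp=False)
    drop = prof.evaluate("AMDP_PP", x) - prof.evaluate("AMDPp_L", x)
    assert np.log(f / b) == pytest.approx(drop, abs=1e-10)


def test_pir_step_symmetry():
    # dG_PiR = 0 and x equidistant from x1 and x_w: full symmetry
    p = P.replace(dG_PiR=0.0)
    x = 0.5 * (p.x1 + p.x_w)
    f, b = rate_pir_step(x, p, clamp=False)
    assert f == pytest.approx(p.k_Pr_prime, rel=1e-12)
    assert b == pytest.approx(p.k_Pr_prime, rel=1e-12)


# ---------------------------------------------------------------------------
# free-energy profile structure
# ---------------------------------------------------------------------------

def test_profile_minima_and_flat_states():
    sch = build_scheme("E_twostep", P)
    prof = free_energy_profile(sch, P, 0.5)
    xg = np.linspace(-22, 14, 361)
    g_L = prof.sample(xg)["AMD_L"]
    g_H = prof.sample(xg)["AMD_H"]
    assert xg[np.argmin(g_L)] == pytest.approx(P.x1, abs=0.11)
    assert xg[np.argmin(g_H)] == pytest.approx(P.x2, abs=0.11)
    # detached states are strain-independent
    g_mdp = prof.sample(xg)["MDP"]
    assert np.ptp(g_mdp) == 0.0


def test_profile_weak_state_flat_variant_A():
    sch = build_scheme("A_beforePS", PA)
    prof = free_energy_profile(sch, PA, 0.5)
    xg = np.linspace(-2, 10, 50)
    assert np.ptp(prof.sample(xg)["AMDP"]) == 0.0


def test_profile_pi_mass_action_shift():
    sch = build_scheme("E_twostep", P)
    gap = lambda pi: (free_energy_profile(sch, P, pi).level("AMD_L")
                      - free_energy_profile(sch, P, pi).level("AMDPp_L"))
    assert gap(5.0) - gap(0.5) == pytest.approx(np.log(10.0), rel=1e-12)


# ---------------------------------------------------------------------------
# equilibrium chain
# ---------------------------------------------------------------------------

def test_equilibrium_chain_product(rng):
    assert equilibrium_chain(1, 1, 1).K_Tot == 1.0
    assert equilibrium_chain(2, 0.5, 3).K_Tot == pytest.approx(3.0)
    for _ in range(20):
        a, b, c = np.exp(rng.uniform(-3, 3, 3))
        chain = equilibrium_chain(a, b, c)
        assert np.log(chain.K_Tot) == pytest.approx(
            np.log(a) + np.log(b) + np.log(c), rel=1e-12)
    with pytest.raises(ValueError):
        equilibrium_chain(0.0, 1.0, 1.0)
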