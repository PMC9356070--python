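"""Strain-dependent rate functions of the cross-bridge cycle.

Every transition rate of the five scheme variants is built from a small set
of functions of the cross-bridge strain ``x`` (nm).  The conventions:

* attachment into the first stereospecifically bound state carries a Gaussian
  strain penalty centred on the pre-stroke minimum ``x1`` and is restricted
  to the attachment window (``window_lo``, ``window_hi``), outside of which
  both the weak-binding equilibrium constant K_w and the attachment rate are
  exactly zero;
* the power-stroke follows the Huxley-Simmons form: a constant reverse rate
  ``k_LH_minus`` and a forward rate fixed by detailed balance between the
  Hookean free-energy parabolas at ``x1`` and ``x2``;
* the shift of Pi from the active site to the secondary site is a symmetric
  Boltzmann split (half the free-energy drop in each direction) between
  parabolas at ``x_w`` and ``x1``;
* Pi exchange between a binding site and solution is strain independent,
  with pseudo-first-order rebinding ``k_p_plus * [Pi] / K``;
* ADP release and ATP-induced detachment feel the piecewise-linear rigor
  force law ``F_AM``.

After formula evaluation every rate is clamped into ``[r_min, r_max]``,
where ``r_max`` depends on the context (isometric vs shortening), before any
solver sees it; pass ``clamp=False`` to obtain the bare formula value (used
by the detailed-balance diagnostics).
"""

from __future__ import annotations

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "clamp_rate", "weak_binding_K", "rate_attach", "rate_attach_rev",
    "rate_pi_exchange", "rate_powerstroke", "force_AM", "stiffness_AM",
    "G_AM", "rate_adp_step", "rate_detach", "rate_pir_step",
    "equilibrium_chain", "EquilibriumChain",
]

_ATTACH_VARIANTS_AB = frozenset({"A_beforePS", "B_afterPS"})
_ATTACH_VARIANTS_CDE = frozenset({"C_beforePS_PiR", "D_afterPS", "E_twostep"})


def clamp_rate(r, params: ModelParameters, context: str = "isometric"):
    """Clamp a nonnegative rate into the numerically safe band.

    ``context`` selects the upper cap: 1e5/s for isometric work, the
    configurable shortening cap (default 1e6/s) otherwise.  Negative rates
    are rejected; +inf maps to the cap.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    out = np.clip(r, params.r_min, params.r_max(context))
    return out if out.ndim else float(out)


def _in_window(x, params: ModelParameters):
    x = np.asarray(x, dtype=float)
    return (x > params.window_lo) & (x < params.window_hi)


def weak_binding_K(x, params: ModelParameters):
    """K_w = exp(dG_w) inside the attachment window, exactly 0 outside."""
    return np.where(_in_window(x, params), np.exp(params.dG_w), 0.0)


def _attach_exponent(x, params: ModelParameters):
    # (k_s/2)(x-x1)^2 / (2 kBT): the half-stiffness Gaussian penalty shared
    # by the printed attachment laws of all variants
    x = np.asarray(x, dtype=float)
    return (params.k_s / 2.0) * (x - params.x1) ** 2 / (2.0 * params.kBT)


def rate_attach(x, params: ModelParameters, variant: str = "E_twostep",
                context: str = "isometric", clamp: bool = True):
    """Attachment into the first strongly bound state (AMDP_T or AMDP_PP).

    Variants A/B use the weak-to-strong free-energy drop dG_AMDP_AMDL;
    variants C/D/E (with the lumped detached state) use dG_on.  Zero outside
    the attachment window.
    """
    dG = _attach_dG(params, variant)
    raw = params.k_on_prime * np.exp(dG - _attach_exponent(x, params))
    if clamp:
        raw = clamp_rate(raw, params, context)
    out = np.where(_in_window(x, params), raw, 0.0)
    return out if out.ndim else float(out)


def _attach_dG(params: ModelParameters, variant: str) -> float:
    if variant in _ATTACH_VARIANTS_AB:
        return params.dG_AMDP_AMDL
    if variant in _ATTACH_VARIANTS_CDE:
        return params.dG_on
    raise ValueError(
        f"unknown variant {variant!r}; valid: "
        f"{sorted(_ATTACH_VARIANTS_AB | _ATTACH_VARIANTS_CDE)}")


def rate_attach_rev(x, params: ModelParameters, variant: str = "E_twostep",
                    context: str = "isometric", clamp: bool = True):
    """Reverse of :func:`rate_attach`; strictly positive inside the window."""
    _attach_dG(params, variant)  # validate variant
    raw = params.k_on_prime * np.exp(_attach_exponent(x, params))
    if clamp:
        raw = clamp_rate(raw, params, context)
    out = np.where(_in_window(x, params), raw, 0.0)
    return out if out.ndim else float(out)


def rate_pi_exchange(params: ModelParameters, conc_Pi: float,
                     site_K: float | None = None) -> tuple[float, float]:
    """Strain-independent Pi exchange with one binding site.

    Returns ``(k_plus, k_minus)`` where ``k_plus`` is the first-order off
    rate and ``k_minus = k_plus * [Pi] / K`` the pseudo-first-order
    rebinding rate at phosphate concentration ``conc_Pi`` (mM).
    """
    if site_K is None:
        site_K = params.K_C
    if site_K <= 0:
        raise ValueError("site dissociation constant must be positive")
    if conc_Pi < 0:
        raise ValueError("conc_Pi must be nonnegative")
    return params.k_p_plus, params.k_p_plus * conc_Pi / site_K


def rate_powerstroke(x, params: ModelParameters, context: str = "isometric",
                     clamp: bool = True):
    """Huxley-Simmons power-stroke rates ``(k_LH_plus, k_LH_minus)``.

    The reverse rate is the constant ``k_LH_minus``; the forward rate
    follows from detailed balance between the parabolas at x1 and x2.
    """
    x = np.asarray(x, dtype=float)
    c = params.k_s / (2.0 * params.kBT)
    expo = (params.dG_AMDL_AMDH
            + c * (x - params.x1) ** 2 - c * (x - params.x2) ** 2)
    k_plus = params.k_LH_minus * np.exp(expo)
    k_minus = np.full_like(np.asarray(k_plus, dtype=float),
                           params.k_LH_minus)
    if clamp:
        k_plus = clamp_rate(k_plus, params, context)
        k_minus = clamp_rate(k_minus, params, context)
    if np.ndim(k_plus) == 0:
        return float(k_plus), float(k_minus)
    return k_plus, k_minus


# ---------------------------------------------------------------------------
# piecewise-linear rigor force law and its energy
# ---------------------------------------------------------------------------

def _fam_knots(params: ModelParameters):
    """Knot values of F_AM and its energy integral at the breakpoints.

    F_AM is anchored at F_AM(0) = 0; the energy E(xi) = int_0^xi F dxi' is
    the stored elastic energy (nonnegative, minimum 0 at xi = 0).
    """
    b = np.asarray(params.FAM_breakpoints, dtype=float)
    s = np.asarray(params.FAM_slopes, dtype=float)
    # segment containing xi=0
    i0 = int(np.searchsorted(b, 0.0))
    nb = len(b)
    F = np.zeros(nb)
    E = np.zeros(nb)
    # march upward from 0
    prev_xi, prev_F, prev_E = 0.0, 0.0, 0.0
    for i in range(i0, nb):
        d = b[i] - prev_xi
        F[i] = prev_F + s[i] * d
        E[i] = prev_E + prev_F * d + 0.5 * s[i] * d * d
        prev_xi, prev_F, prev_E = b[i], F[i], E[i]
    # march downward from 0
    prev_xi, prev_F, prev_E = 0.0, 0.0, 0.0
    for i in range(i0 - 1, -1, -1):
        d = b[i] - prev_xi  # negative
        F[i] = prev_F + s[i + 1] * d
        E[i] = prev_E + prev_F * d + 0.5 * s[i + 1] * d * d
        prev_xi, prev_F, prev_E = b[i], F[i], E[i]
    return b, s, F, E


def force_AM(x, params: ModelParameters):
    """Rigor-state force F_AM(x - x3), pN: continuous piecewise linear."""
    xi = np.asarray(x, dtype=float) - params.x3
    b, s, F, E = _fam_knots(params)
    idx = np.searchsorted(b, xi)  # segment index; slope s[idx]
    ref_xi = np.where(idx == 0, b[0], b[np.maximum(idx - 1, 0)])
    ref_F = np.where(idx == 0, F[0], F[np.maximum(idx - 1, 0)])
    # for idx==0 the reference knot is b[0] itself
    out = ref_F + s[idx] * (xi - ref_xi)
    return out if out.ndim else float(out)


def stiffness_AM(x, params: ModelParameters):
    """Local slope of F_AM at strain x, pN/nm."""
    xi = np.asarray(x, dtype=float) - params.x3
    b = np.asarray(params.FAM_breakpoints, dtype=float)
    s = np.asarray(params.FAM_slopes, dtype=float)
    out = s[np.searchsorted(b, xi)]
    return out if out.ndim else float(out)


def G_AM(x, params: ModelParameters):
    """Elastic energy of the rigor force law, kBT units; minimum 0 at x3."""
    xi = np.asarray(x, dtype=float) - params.x3
    b, s, F, E = _fam_knots(params)
    idx = np.searchsorted(b, xi)
    ref_xi = np.where(idx == 0, b[0], b[np.maximum(idx - 1, 0)])
    ref_F = np.where(idx == 0, F[0], F[np.maximum(idx - 1, 0)])
    ref_E = np.where(idx == 0, E[0], E[np.maximum(idx - 1, 0)])
    d = xi - ref_xi
    out = (ref_E + ref_F * d + 0.5 * s[idx] * d * d) / params.kBT
    return out if out.ndim else float(out)


def rate_adp_step(x, params: ModelParameters, context: str = "isometric",
                  clamp: bool = True):
    """Irreversible ADP-release step AMD_H -> AM/AMD (rate k_5(x))."""
    x = np.asarray(x, dtype=float)
    c = params.k_s / (2.0 * params.kBT)
    expo = (params.dG_AMDH_AM + c * (x - params.x2) ** 2 - G_AM(x, params))
    raw = params.k_5_at_x1 * np.exp(expo)
    if clamp:
        raw = clamp_rate(raw, params, context)
    return raw if np.ndim(raw) else float(raw)


def rate_detach(x, params: ModelParameters, conc_MgATP: float,
                context: str = "isometric", clamp: bool = True):
    """ATP-induced detachment AM/AMD -> MT (rate k_off(x)).

    Saturates at k_2(x) k_6 / (k_2(x) + k_6) for large [MgATP] and is linear
    (K_1 k_2(x) [MgATP]) at low [MgATP]; k_2(x) grows exponentially with the
    magnitude of the rigor force times x_crit.
    """
    if conc_MgATP < 0:
        raise ValueError("conc_MgATP must be nonnegative")
    k2 = params.k_2_zero * np.exp(
        np.abs(force_AM(x, params)) * params.x_crit / params.kBT)
    T = conc_MgATP
    denom = 1.0 / params.K_1 + (k2 / params.k_6) * T + T
    raw = k2 * T / denom
    if clamp:
        raw = clamp_rate(raw, params, context)
    return raw if np.ndim(raw) else float(raw)


def rate_pir_step(x, params: ModelParameters, context: str = "isometric",
                  clamp: bool = True):
    """Shift of Pi from the active site to the secondary site and back.

    Symmetric Boltzmann split between the AMDP_PP parabola (offset x_w) and
    the AMDP_PiR parabola (offset x1): half the free-energy drop enters each
    direction with opposite sign, so the forward/backward ratio equals the
    exponential of the full drop.  Returns ``(k_Pr_plus, k_Pr_minus)``.
    """
    x = np.asarray(x, dtype=float)
    h = (params.k_s / 2.0) / (2.0 * params.kBT)
    strain = h * (x - params.x_w) ** 2 - h * (x - params.x1) ** 2
    k_plus = params.k_Pr_prime * np.exp(params.dG_PiR / 2.0 + strain)
    k_minus = params.k_Pr_prime * np.exp(-params.dG_PiR / 2.0 - strain)
    if clamp:
        k_plus = clamp_rate(k_plus, params, context)
        k_minus = clamp_rate(k_minus, params, context)
    if np.ndim(k_plus) == 0:
        return float(k_plus), float(k_minus)
    return k_plus, k_minus


class EquilibriumChain:
    """Coupled equilibria of the multistep Pi-release path.

    K_Tot = K_Pr * K_C' * K_C'' — active-site-to-secondary-site step times
    the two downstream site equilibria.
    """

    def __init__(self, K_Pr: float, K_C_prime: float, K_C_second: float):
        for name, val in (("K_Pr", K_Pr), ("K_C_prime", K_C_prime),
                          ("K_C_second", K_C_second)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        self.K_Pr = K_Pr
        self.K_C_prime = K_C_prime
        self.K_C_second = K_C_second

    @property
    def K_Tot(self) -> float:
        return self.K_Pr * self.K_C_prime * self.K_C_second

    def __repr__(self) -> str:  # pragma: no cover
        return (f"EquilibriumChain(K_Pr={self.K_Pr}, "
                f"K_C_prime={self.K_C_prime}, "
                f"K_C_second={self.K_C_second}, K_Tot={self.K_Tot})")


def equilibrium_chain(K_Pr: float, K_C_prime: float,
                      K_C_second: float) -> EquilibriumChain:
    """Build the equilibrium chain; K_Tot is the exact product."""
    return EquilibriumChain(K_Pr, K_C_prime, K_C_second)
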