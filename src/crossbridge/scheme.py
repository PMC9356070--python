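"""Kinetic schemes: states and strain-dependent transitions per model variant.

Five variants of the cross-bridge cycle are supported:

* ``A_beforePS``   – Pi leaves the active site before the power-stroke, via
  the transient strongly bound AMDP_T state;
* ``B_afterPS``    – Pi leaves after the power-stroke (AMDP_L/AMDP_H replace
  AMD_L/AMD_H before Pi loss);
* ``C_beforePS_PiR`` – before-stroke release through the pre-power-stroke
  AMDP_PP and Pi-release AMDP_PiR states (detached and weakly bound states
  lumped into MDP);
* ``D_afterPS``    – as C but with Pi leaving after the stroke;
* ``E_twostep``    – the two-step-release scheme: Pi pauses on a secondary
  site outside the active site, giving a primed (AMDP'_L/AMDP'_H/AM-AMDP')
  row of states mechanically identical to the unprimed row.

Each transition references a rate-function id resolved by
:func:`build_rate_table`, so a scheme plus parameters plus conditions fully
determines the generator matrix Q(x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rates as _r
from .parameters import Conditions, ModelParameters

VALID_VARIANTS = ("A_beforePS", "B_afterPS", "C_beforePS_PiR",
                  "D_afterPS", "E_twostep")


@dataclass(frozen=True)
class State:
    name: str
    attached: bool              # stereospecifically bound to actin
    stiffness: bool             # bears cross-bridge stiffness
    offset: float | None = None  # zero-force strain, nm (None for detached)
    rigor: bool = False         # uses the piecewise F_AM force law
    weak: bool = False          # weakly/non-stereospecifically bound


@dataclass(frozen=True)
class Transition:
    frm: str
    to: str
    rate_id: str


@dataclass(frozen=True)
class KineticScheme:
    variant: str
    states: tuple[State, ...]
    transitions: tuple[Transition, ...]
    force_state_names: tuple[str, ...]   # states in the occupancy-force readout
    powerstroke_entry: str               # initial state of the stroke protocol

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    def state(self, name: str) -> State:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    @property
    def n_states(self) -> int:
        return len(self.states)


def _require_variant(variant: str) -> None:
    if variant not in VALID_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; valid: {list(VALID_VARIANTS)}")


def build_scheme(variant: str, params: ModelParameters) -> KineticScheme:
    """Construct the full state/transition graph for one model variant."""
    _require_variant(variant)
    p = params
    S, T = [], []

    def st(*args, **kw):
        S.append(State(*args, **kw))

    def tr(frm, to, rid):
        T.append(Transition(frm, to, rid))

    if variant == "A_beforePS":
        st("MT", False, False)
        st("MDP", False, False)
        st("AMDP", False, False, weak=True)   # weakly bound, zero stiffness
        st("AMDP_T", True, True, p.x1)
        st("AMD_L", True, True, p.x1)
        st("AMD_H", True, True, p.x2)
        st("AM_AMD", True, True, p.x3, rigor=True)
        tr("MT", "MDP", "hydrolysis_fwd")
        tr("MDP", "MT", "hydrolysis_rev")
        tr("MDP", "AMDP", "weak_attach")
        tr("AMDP", "MDP", "weak_detach")
        tr("AMDP", "AMDP_T", "attach")
        tr("AMDP_T", "AMDP", "attach_rev")
        tr("AMDP_T", "AMD_L", "pi_plus")
        tr("AMD_L", "AMDP_T", "pi_minus")
        tr("AMD_L", "AMD_H", "ps_fwd")
        tr("AMD_H", "AMD_L", "ps_rev")
        tr("AMD_H", "AM_AMD", "adp_step")
        tr("AM_AMD", "MT", "detach")
        force_states = ("AMD_H",)
        entry = "AMDP_T"

    elif variant == "B_afterPS":
        st("MT", False, False)
        st("MDP", False, False)
        st("AMDP", False, False, weak=True)
        st("AMDP_L", True, True, p.x1)
        st("AMDP_H", True, True, p.x2)
        st("AMD_H", True, True, p.x2)
        st("AM_AMD", True, True, p.x3, rigor=True)
        tr("MT", "MDP", "hydrolysis_fwd")
        tr("MDP", "MT", "hydrolysis_rev")
        tr("MDP", "AMDP", "weak_attach")
        tr("AMDP", "MDP", "weak_detach")
        tr("AMDP", "AMDP_L", "attach")
        tr("AMDP_L", "AMDP", "attach_rev")
        tr("AMDP_L", "AMDP_H", "ps_fwd")
        tr("AMDP_H", "AMDP_L", "ps_rev")
        tr("AMDP_H", "AMD_H", "pi_plus")
        tr("AMD_H", "AMDP_H", "pi_minus")
        tr("AMD_H", "AM_AMD", "adp_step")
        tr("AM_AMD", "MT", "detach")
        force_states = ("AMDP_H", "AMD_H")
        entry = "AMDP_L"

    elif variant == "C_beforePS_PiR":
        st("MT", False, False)
        st("MDP", False, False)
        st("AMDP_PP", True, True, p.x_w)
        st("AMDP_PiR", True, True, p.x1)
        st("AMD_L", True, True, p.x1)
        st("AMD_H", True, True, p.x2)
        st("AM_AMD", True, True, p.x3, rigor=True)
        tr("MT", "MDP", "hydrolysis_fwd")
        tr("MDP", "MT", "hydrolysis_rev")
        tr("MDP", "AMDP_PP", "attach")
        tr("AMDP_PP", "MDP", "attach_rev")
        tr("AMDP_PP", "AMDP_PiR", "pir_fwd")
        tr("AMDP_PiR", "AMDP_PP", "pir_rev")
        tr("AMDP_PiR", "AMD_L", "pi_plus")
        tr("AMD_L", "AMDP_PiR", "pi_minus")
        tr("AMD_L", "AMD_H", "ps_fwd")
        tr("AMD_H", "AMD_L", "ps_rev")
        tr("AMD_H", "AM_AMD", "adp_step")
        tr("AM_AMD", "MT", "detach")
        force_states = ("AMD_H",)
        entry = "AMDP_PP"

    elif variant == "D_afterPS":
        st("MT", False, False)
        st("MDP", False, False)
        st("AMDP_PP", True, True, p.x_w)
        st("AMDP_L", True, True, p.x1)
        st("AMDP_H", True, True, p.x2)
        st("AMD_H", True, True, p.x2)
        st("AM_AMD", True, True, p.x3, rigor=True)
        tr("MT", "MDP", "hydrolysis_fwd")
        tr("MDP", "MT", "hydrolysis_rev")
        tr("MDP", "AMDP_PP", "attach")
        tr("AMDP_PP", "MDP", "attach_rev")
        tr("AMDP_PP", "AMDP_L", "pir_fwd")
        tr("AMDP_L", "AMDP_PP", "pir_rev")
        tr("AMDP_L", "AMDP_H", "ps_fwd")
        tr("AMDP_H", "AMDP_L", "ps_rev")
        tr("AMDP_H", "AMD_H", "pi_plus")
        tr("AMD_H", "AMDP_H", "pi_minus")
        tr("AMD_H", "AM_AMD", "adp_step")
        tr("AM_AMD", "MT", "detach")
        force_states = ("AMDP_H", "AMD_H")
        entry = "AMDP_PP"

    else:  # E_twostep
        st("MT", False, False)
        st("MTPp", False, False)
        st("MDP", False, False)
        st("AMDP_PP", True, True, p.x_w)
        st("AMDPp_L", True, True, p.x1)   # Pi on the secondary site
        st("AMDPp_H", True, True, p.x2)
        st("AM_AMDPp", True, True, p.x3, rigor=True)
        st("AMD_L", True, True, p.x1)     # Pi released to solution
        st("AMD_H", True, True, p.x2)
        st("AM_AMD", True, True, p.x3, rigor=True)
        tr("MT", "MDP", "hydrolysis_fwd")
        tr("MDP", "MT", "hydrolysis_rev")
        tr("MDP", "AMDP_PP", "attach")
        tr("AMDP_PP", "MDP", "attach_rev")
        # AMDP_PiR and AMDP'_L are lumped: the Pr step lands in AMDPp_L
        tr("AMDP_PP", "AMDPp_L", "pir_fwd")
        tr("AMDPp_L", "AMDP_PP", "pir_rev")
        # the power-stroke uses the same rate-function ids in both rows:
        # Pi on the secondary site has no allosteric effect
        tr("AMDPp_L", "AMDPp_H", "ps_fwd")
        tr("AMDPp_H", "AMDPp_L", "ps_rev")
        tr("AMD_L", "AMD_H", "ps_fwd")
        tr("AMD_H", "AMD_L", "ps_rev")
        # Pi exchange between the rows (same k_p+ from every primed state)
        tr("AMDPp_L", "AMD_L", "pi_plus")
        tr("AMD_L", "AMDPp_L", "pi_minus")
        tr("AMDPp_H", "AMD_H", "pi_plus")
        tr("AMD_H", "AMDPp_H", "pi_minus")
        tr("AM_AMDPp", "AM_AMD", "pi_plus")
        tr("AM_AMD", "AM_AMDPp", "pi_minus")
        # ADP release and detachment, identical in both rows
        tr("AMDPp_H", "AM_AMDPp", "adp_step")
        tr("AMD_H", "AM_AMD", "adp_step")
        tr("AM_AMDPp", "MTPp", "detach")
        tr("AM_AMD", "MT", "detach")
        # rapid irreversible Pi loss from MTP'
        tr("MTPp", "MT", "pi_loss_fast")
        force_states = ("AMDPp_H", "AMD_H")
        entry = "AMDP_PP"

    return KineticScheme(variant, tuple(S), tuple(T), force_states, entry)


def build_rate_table(scheme: KineticScheme, params: ModelParameters,
                     cond: Conditions, context: str = "isometric",
                     clamp: bool = True) -> dict:
    """Map every rate-function id used by *scheme* to a callable of x."""
    p, variant = params, scheme.variant
    k_p_plus, k_p_minus = _r.rate_pi_exchange(p, cond.conc_Pi)

    def const(value):
        return lambda x: np.broadcast_to(float(value), np.shape(x)).copy() \
            if np.ndim(x) else float(value)

    table = {
        "hydrolysis_fwd": const(p.k_h_plus),
        "hydrolysis_rev": const(p.k_h_minus),
        "attach": lambda x: _r.rate_attach(x, p, variant, context, clamp),
        "attach_rev": lambda x: _r.rate_attach_rev(x, p, variant, context,
                                                   clamp),
        "pi_plus": const(k_p_plus),
        "pi_minus": const(k_p_minus),
        "ps_fwd": lambda x: _r.rate_powerstroke(x, p, context, clamp)[0],
        "ps_rev": lambda x: _r.rate_powerstroke(x, p, context, clamp)[1],
        "adp_step": lambda x: _r.rate_adp_step(x, p, context, clamp),
        "detach": lambda x: _r.rate_detach(x, p, cond.conc_MgATP, context,
                                           clamp),
        "pir_fwd": lambda x: _r.rate_pir_step(x, p, context, clamp)[0],
        "pir_rev": lambda x: _r.rate_pir_step(x, p, context, clamp)[1],
        "weak_attach": lambda x: p.k_w_base * _r.weak_binding_K(x, p),
        "weak_detach": const(p.k_w_base),
        "pi_loss_fast": const(p.r_max(context)),
    }
    used = {t.rate_id for t in scheme.transitions}
    missing = used - set(table)
    if missing:  # pragma: no cover - construction guard
        raise KeyError(f"unimplemented rate ids: {sorted(missing)}")
    return {rid: table[rid] for rid in used}


def generator_matrix(scheme: KineticScheme, rate_table: dict, x: float):
    """Column-stochastic generator Q(x): da/dt = Q a."""
    n = scheme.n_states
    Q = np.zeros((n, n))
    for t in scheme.transitions:
        k = float(rate_table[t.rate_id](x))
        i, j = scheme.index(t.frm), scheme.index(t.to)
        Q[i, i] -= k
        Q[j, i] += k
    return Q


# ---------------------------------------------------------------------------
# free-energy profile
# ---------------------------------------------------------------------------

class FreeEnergyProfile:
    """Free energy G_j(x) (kBT units) for every state of a scheme.

    Strongly bound Hookean states are parabolas of stiffness k_s at their
    zero-force offsets; the rigor-like AM/AMD states follow the piecewise
    elastic energy of F_AM; detached and weakly bound states are flat.
    Levels are chained from the MDP reference (G = 0) through the
    free-energy drops of the parameter set; the gap between the primed and
    unprimed rows carries the mass-action term ln([Pi]/K_C).
    """

    def __init__(self, scheme: KineticScheme, params: ModelParameters,
                 conc_Pi: float):
        self.scheme = scheme
        self.params = params
        self.conc_Pi = conc_Pi
        self.levels = _state_levels(scheme, params, conc_Pi)

    def level(self, name: str) -> float:
        return self.levels[name]

    def evaluate(self, name: str, x):
        s = self.scheme.state(name)
        base = self.levels[name]
        if not s.stiffness:
            return base + np.zeros_like(np.asarray(x, dtype=float)) \
                if np.ndim(x) else base
        if s.rigor:
            return base + _r.G_AM(x, self.params)
        c = self.params.k_s / (2.0 * self.params.kBT)
        out = base + c * (np.asarray(x, dtype=float) - s.offset) ** 2
        return out if np.ndim(out) else float(out)

    def sample(self, x_grid):
        """Return {state: G(x)} arrays on the given strain grid."""
        x_grid = np.asarray(x_grid, dtype=float)
        return {s.name: np.broadcast_to(
            self.evaluate(s.name, x_grid), x_grid.shape).copy()
            for s in self.scheme.states}


def _state_levels(scheme: KineticScheme, p: ModelParameters,
                  conc_Pi: float) -> dict[str, float]:
    """Free-energy minima (kBT) chained from MDP = 0."""
    # Pi release to solution drops the free energy by ln(K_C/[Pi])
    with np.errstate(divide="ignore"):
        dG_sol = float(np.log(p.K_C / conc_Pi)) if conc_Pi > 0 else np.inf
    lv: dict[str, float] = {"MDP": 0.0, "MT": np.log(p.k_h_plus
                                                     / p.k_h_minus)}
    v = scheme.variant
    if v in ("A_beforePS", "B_afterPS"):
        lv["AMDP"] = -p.dG_w
        if v == "A_beforePS":
            lv["AMDP_T"] = lv["AMDP"] - p.dG_AMDP_AMDL
            lv["AMD_L"] = lv["AMDP_T"] - dG_sol
            lv["AMD_H"] = lv["AMD_L"] - p.dG_AMDL_AMDH
        else:
            lv["AMDP_L"] = lv["AMDP"] - p.dG_AMDP_AMDL
            lv["AMDP_H"] = lv["AMDP_L"] - p.dG_AMDL_AMDH
            lv["AMD_H"] = lv["AMDP_H"] - dG_sol
        lv["AM_AMD"] = lv["AMD_H"] - p.dG_AMDH_AM
    else:
        lv["AMDP_PP"] = -p.dG_on
        if v == "C_beforePS_PiR":
            lv["AMDP_PiR"] = lv["AMDP_PP"] - p.dG_PiR
            lv["AMD_L"] = lv["AMDP_PiR"] - dG_sol
            lv["AMD_H"] = lv["AMD_L"] - p.dG_AMDL_AMDH
            lv["AM_AMD"] = lv["AMD_H"] - p.dG_AMDH_AM
        elif v == "D_afterPS":
            lv["AMDP_L"] = lv["AMDP_PP"] - p.dG_PiR
            lv["AMDP_H"] = lv["AMDP_L"] - p.dG_AMDL_AMDH
            lv["AMD_H"] = lv["AMDP_H"] - dG_sol
            lv["AM_AMD"] = lv["AMD_H"] - p.dG_AMDH_AM
        else:  # E_twostep
            lv["AMDPp_L"] = lv["AMDP_PP"] - p.dG_PiR
            lv["AMDPp_H"] = lv["AMDPp_L"] - p.dG_AMDL_AMDH
            lv["AM_AMDPp"] = lv["AMDPp_H"] - p.dG_AMDH_AM
            lv["AMD_L"] = lv["AMDPp_L"] - dG_sol
            lv["AMD_H"] = lv["AMD_L"] - p.dG_AMDL_AMDH
            lv["AM_AMD"] = lv["AMD_H"] - p.dG_AMDH_AM
            lv["MTPp"] = lv["MT"] + 5.0  # rapid irreversible loss; nominal
    return {s.name: lv[s.name] for s in scheme.states}


def free_energy_profile(scheme: KineticScheme, params: ModelParameters,
                        conc_Pi: float) -> FreeEnergyProfile:
    """Free-energy landscape of the scheme at the given [Pi] (mM)."""
    return FreeEnergyProfile(scheme, params, conc_Pi)
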