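"""Physical parameters and experimental conditions for the cross-bridge model.

All quantities carry fixed units: lengths in nm, forces in pN, energies in
units of kBT, rates in 1/s, [Pi] in mM, [MgATP] in M, velocities in nm/s.
Free-energy differences are stored as (G_initial - G_final)/kBT so that a
positive value favours the forward transition.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set for the mechanokinetic cross-bridge model.

    The defaults form a documented reference set: cross-bridge stiffness
    2.8 pN/nm, thermal energy 4 pN nm, reverse power-stroke rate 2000/s,
    attachment window (-2.8, 18.2) nm and averaging window (-22, 14) nm.
    Remaining prefactors and free-energy drops are chosen so that the
    two-step-release scheme produces a concave force-velocity relation,
    isometric force in the single-pN-per-head range and an ATPase of a few
    per second per head.  Every value can be overridden from file, see
    :func:`load_parameters`.
    """

    # elasticity / thermal
    k_s: float = 2.8          # cross-bridge stiffness, pN/nm
    kBT: float = 4.0          # thermal energy, pN nm

    # free-energy differences, kBT units (initial - final, forward-positive)
    dG_w: float = 1.0             # MDP -> AMDP weak binding
    dG_AMDP_AMDL: float = 12.4    # AMDP -> AMDP_T attachment (variants A/B)
    dG_AMDL_AMDH: float = 22.0    # power-stroke drop
    dG_AMDH_AM: float = 5.0       # ADP-release step drop
    dG_on: float = -3.0           # MDP -> AMDP_PP attachment (variants C/D/E)
    dG_PiR: float = -1.4          # AMDP_PP -> AMDP_PiR step

    # zero-force strain offsets, nm
    x1: float = 7.7               # pre-power-stroke minimum
    x2: float = 0.7               # post-power-stroke minimum
    x3: float = -0.3              # AM/AMD (rigor-like) minimum
    x_w: float = 8.7              # AMDP_PP minimum (variants C/D/E)
    x_crit: float = 2.0           # strain sensitivity of ATP-induced detachment, nm

    # rate constants, 1/s
    k_on_prime: float = 2.0e4     # attachment prefactor
    k_Pr_prime: float = 6.0e4     # active-site -> secondary-site prefactor
    k_LH_minus: float = 2000.0    # reverse power-stroke rate
    k_5_at_x1: float = 5.0        # ADP-step prefactor
    k_2_zero: float = 1000.0      # ATP-induced detachment at zero force
    k_6: float = 1.0e4            # ADP dissociation
    k_p_plus: float = 80.0        # Pi off-rate from the secondary site
    k_h_plus: float = 100.0       # MT -> MDP hydrolysis
    k_h_minus: float = 10.0       # reverse hydrolysis
    k_w_base: float = 1.0e4       # weak-binding detachment rate (A/B)
    k_det: float = 5.0            # end-of-stroke detachment, simplified scheme

    # equilibrium constants
    K_1: float = 2.0e3            # ATP binding, 1/M
    K_C: float = 3.0              # Pi dissociation of the secondary site, mM
    K_C_prime: float = 10.0       # inner->outer transfer equilibrium (2-site)
    K_C_second: float = 0.3       # outer-site Pi dissociation, mM

    # geometry, nm
    window_lo: float = -2.8       # attachment window
    window_hi: float = 18.2
    x_int_lo: float = -22.0       # strain-averaging bounds
    x_int_hi: float = 14.0
    d_site: float = 36.0          # actin site spacing

    # rate caps, 1/s
    r_max_isometric: float = 1.0e5
    r_max_shortening: float = 1.0e6
    r_min: float = 1.0e-6

    # piecewise-linear AM/AMD force law F_AM(xi); breakpoints in xi = x - x3
    FAM_breakpoints: tuple[float, ...] = (0.0,)
    FAM_slopes: tuple[float, ...] = (1.0, 2.8)   # pN/nm per segment

    def __post_init__(self) -> None:
        if self.k_s <= 0 or self.kBT <= 0:
            raise ValueError("k_s and kBT must be positive")
        if not (self.x1 > self.x2 >= self.x3):
            raise ValueError("strain offsets must satisfy x1 > x2 >= x3")
        if not (self.window_lo < self.x1 < self.window_hi):
            raise ValueError("x1 must lie inside the attachment window")
        if self.r_min >= self.r_max_isometric:
            raise ValueError("r_min must lie below r_max")
        if abs((self.x_int_hi - self.x_int_lo) - self.d_site) > 1e-9:
            raise ValueError("d_site must equal x_int_hi - x_int_lo")
        if len(self.FAM_slopes) != len(self.FAM_breakpoints) + 1:
            raise ValueError("need one more F_AM slope than breakpoints")
        if any(b2 <= b1 for b1, b2 in
               zip(self.FAM_breakpoints, self.FAM_breakpoints[1:])):
            raise ValueError("F_AM breakpoints must be strictly increasing")
        for name in ("k_on_prime", "k_Pr_prime", "k_LH_minus", "k_5_at_x1",
                     "k_2_zero", "k_6", "k_p_plus", "k_h_plus", "k_h_minus",
                     "k_w_base", "k_det", "K_1", "K_C", "K_C_prime",
                     "K_C_second"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def r_max(self, context: str) -> float:
        if context == "isometric":
            return self.r_max_isometric
        if context == "shortening":
            return self.r_max_shortening
        raise ValueError(f"unknown clamp context {context!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["FAM_breakpoints"] = list(self.FAM_breakpoints)
        d["FAM_slopes"] = list(self.FAM_slopes)
        return d


@dataclass(frozen=True)
class Conditions:
    """Solution conditions for a simulation."""

    conc_Pi: float = 0.5       # mM
    conc_MgATP: float = 5.0e-3  # M
    v: float = 0.0             # sliding velocity, nm/s
    label: str = ""

    def __post_init__(self) -> None:
        if self.conc_Pi < 0 or self.conc_MgATP < 0:
            raise ValueError("concentrations must be nonnegative")

    def replace(self, **changes) -> "Conditions":
        return dataclasses.replace(self, **changes)


#: Per-variant overrides of the reference set, mirroring the use of separate
#: parameter tables per scheme.  The contrasting fast-release schemes (A, C)
#: assume Pi leaves the relevant state rapidly (>1000/s); the after-stroke
#: schemes B/D and the two-step scheme E use the slow experimental off-rate
#: range (40-120/s).  In A/B the K_C is the (weak, ~40 mM) active-site Pi
#: dissociation constant and the reverse-attachment prefactor is small
#: (strong stereospecific binding); in C/D/E K_C belongs to the secondary
#: site.  A/B use the high shortening rate cap because their steep
#: reverse-attachment exponential is the velocity-limiting escape route.
_VARIANT_OVERRIDES: dict[str, dict] = {
    "A_beforePS": {"k_p_plus": 3000.0, "K_C": 40.0, "k_on_prime": 0.003,
                   "r_max_shortening": 1e8},
    "B_afterPS": {"k_p_plus": 80.0, "K_C": 40.0, "k_on_prime": 0.003,
                  "r_max_shortening": 1e8},
    "C_beforePS_PiR": {"k_p_plus": 3000.0, "K_C": 10.0},
    "D_afterPS": {"k_p_plus": 80.0, "K_C": 10.0},
    "E_twostep": {"k_p_plus": 80.0},
}


def reference_parameters(variant: str | None = None) -> ModelParameters:
    """The documented reference parameter set, optionally variant-adjusted."""
    if variant is None:
        return ModelParameters()
    if variant not in _VARIANT_OVERRIDES:
        raise ValueError(
            f"unknown variant {variant!r}; valid: {sorted(_VARIANT_OVERRIDES)}")
    return ModelParameters(**_VARIANT_OVERRIDES[variant])


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}


def _from_mapping(data: dict) -> ModelParameters:
    flat: dict = {}
    for key, value in data.items():
        # one table per parameter group is allowed; flatten it
        if isinstance(value, dict):
            for k, v in value.items():
                flat[k] = v
        else:
            flat[key] = value
    unknown = set(flat) - _PARAM_FIELDS
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    for key in ("FAM_breakpoints", "FAM_slopes"):
        if key in flat:
            flat[key] = tuple(flat[key])
    return ModelParameters(**flat)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a parameter file (TOML or JSON); unknown keys are errors."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return _from_mapping(data)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Serialise a parameter set as JSON (readable back by load_parameters)."""
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))
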