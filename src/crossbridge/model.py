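"""Ensemble steady-state behaviour of the cross-bridge model.

The central object is :class:`CrossBridgeModel`, which couples a parameter
set to one of the five kinetic-scheme variants.  Steady shortening at
velocity ``v`` is solved as a boundary-value sweep in the strain variable:
with each myosin head passing actin sites at speed ``v``, the state
probabilities obey ``da_j/dx = (inflow - outflow)/v`` and are integrated
from the top of the averaging window (x = 14 nm) downward, starting from
the detached-state equilibrium.  Ensemble observables (mean force per head,
stiffness, attached fraction, ATPase) are strain averages over the 36 nm
actin site spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import rates as _r
from .parameters import Conditions, ModelParameters, reference_parameters
from .scheme import (KineticScheme, build_rate_table, build_scheme,
                     free_energy_profile)

__all__ = ["CrossBridgeModel", "StateDistribution", "EnsembleObservables",
           "sensitivity_analysis"]


@dataclass(frozen=True)
class EnsembleObservables:
    """Strain-averaged ensemble outputs, per myosin head."""

    mean_force: float      # pN
    stiffness: float       # pN/nm
    frac_attached: float   # dimensionless
    atpase: float          # 1/s

    def summary(self) -> str:
        return ("Ensemble observables (per head)\n"
                f"  mean force     {self.mean_force: .5g} pN\n"
                f"  stiffness      {self.stiffness: .5g} pN/nm\n"
                f"  attached frac  {self.frac_attached: .5g}\n"
                f"  ATPase         {self.atpase: .5g} 1/s")


class StateDistribution:
    """State probabilities a_j(x) on a strain grid at steady shortening."""

    def __init__(self, scheme: KineticScheme, params: ModelParameters,
                 conditions: Conditions, x_grid: np.ndarray,
                 a: np.ndarray):
        self.scheme = scheme
        self.params = params
        self.conditions = conditions
        self.x_grid = x_grid          # ascending, nm
        self.a = a                    # (n_states, n_grid)

    @property
    def v(self) -> float:
        return self.conditions.v

    def probability(self, name: str) -> np.ndarray:
        return self.a[self.scheme.index(name)]

    def total(self) -> np.ndarray:
        """Sum of state probabilities at each grid point (should be 1)."""
        return self.a.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x_nm": self.x_grid})
        for name in self.scheme.state_names:
            df[name] = self.probability(name)
        return df

    # -- observables -------------------------------------------------------

    def observables(self) -> EnsembleObservables:
        """Mean force, stiffness, attached fraction and ATPase (per head).

        The sampled state probabilities are treated as piecewise linear in
        x; each strain integral uses a per-segment Simpson rule, which is
        exact for the product of the linear interpolant with a linear
        weight (the Hookean force term).
        """
        p = self.params
        x = self.x_grid
        span = x[-1] - x[0]
        if abs(span - p.d_site) > 1e-6:
            raise ValueError(
                f"grid spans {span} nm; must cover the full {p.d_site} nm "
                "actin site spacing")

        def integral(a, wfun):
            xm = 0.5 * (x[:-1] + x[1:])
            w, wm = wfun(x), wfun(xm)
            am = 0.5 * (a[:-1] + a[1:])
            h = np.diff(x)
            return float(np.sum(h / 6.0 * (a[:-1] * w[:-1] + 4 * am * wm
                                           + a[1:] * w[1:])))

        force = stiff = attached = 0.0
        for s in self.scheme.states:
            a_j = self.probability(s.name)
            if s.attached:
                attached += integral(a_j, lambda xx: np.ones_like(xx))
            if not s.stiffness:
                continue
            if s.rigor:
                force += integral(a_j, lambda xx: _r.force_AM(xx, p))
                stiff += integral(a_j, lambda xx: _r.stiffness_AM(xx, p))
            else:
                xj = s.offset
                force += integral(a_j, lambda xx: p.k_s * (xx - xj))
                stiff += integral(a_j, lambda xx: np.full_like(xx, p.k_s))
        a3 = np.zeros_like(x)
        for name in ("AMD_H", "AMDPp_H"):
            if name in self.scheme.state_names:
                a3 += self.probability(name)
        atpase = integral(a3, lambda xx: _r.rate_detach(
            xx, p, self.conditions.conc_MgATP, context="shortening"))
        d = p.d_site
        return EnsembleObservables(
            mean_force=force / d, stiffness=stiff / d,
            frac_attached=attached / d, atpase=atpase / d)


class CrossBridgeModel:
    """A cross-bridge cycle variant coupled to a parameter set.

    Parameters
    ----------
    variant : str
        One of the five scheme variants (default the two-step-release
        scheme ``"E_twostep"``).
    params : ModelParameters, optional
        Defaults to the variant-adjusted reference set.
    """

    def __init__(self, variant: str = "E_twostep",
                 params: ModelParameters | None = None):
        self.params = params if params is not None \
            else reference_parameters(variant)
        self.variant = variant
        self.scheme = build_scheme(variant, self.params)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_config(cls, path, variant: str = "E_twostep"):
        from .parameters import load_parameters
        return cls(variant, load_parameters(path))

    def free_energy_profile(self, conc_Pi: float):
        return free_energy_profile(self.scheme, self.params, conc_Pi)

    # -- steady state ------------------------------------------------------

    def solve_steady_state(self, conditions: Conditions,
                           rtol: float = 1e-8, atol: float = 1e-12,
                           n_grid: int = 721,
                           context: str = "shortening") -> StateDistribution:
        """Solve the strain-resolved steady state at sliding velocity v > 0.

        Integration starts at x = x_int_hi with all attached states empty
        and the detached states at their chemical equilibrium, and proceeds
        in the negative-x direction with an adaptive implicit stepper.
        Isometric behaviour (v = 0) is handled by the simplified
        compartment scheme in :mod:`crossbridge.transients`.
        """
        v = conditions.v
        if v <= 0:
            raise ValueError(
                "solve_steady_state requires v > 0; use the isometric "
                "compartment model for v = 0")
        p = self.params
        sch = self.scheme
        table = build_rate_table(sch, p, conditions, context=context)
        trans = [(sch.index(t.frm), sch.index(t.to), table[t.rate_id])
                 for t in sch.transitions]
        n = sch.n_states

        def rhs(s, a):
            x = p.x_int_hi - s
            da = np.zeros(n)
            for i, j, fn in trans:
                flux = fn(x) * a[i]
                da[i] -= flux
                da[j] += flux
            return da / v

        y0 = np.zeros(n)
        z = p.k_h_plus + p.k_h_minus
        y0[sch.index("MT")] = p.k_h_minus / z
        y0[sch.index("MDP")] = p.k_h_plus / z
        s_grid = np.linspace(0.0, p.x_int_hi - p.x_int_lo, n_grid)
        sol = solve_ivp(rhs, (s_grid[0], s_grid[-1]), y0, method="LSODA",
                        t_eval=s_grid, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"steady-state integration failed near x = "
                f"{p.x_int_hi - sol.t[-1]:.3f} nm: {sol.message}")
        x_grid = p.x_int_hi - sol.t
        order = np.argsort(x_grid)
        return StateDistribution(sch, p, conditions,
                                 x_grid[order], sol.y[:, order])

    def ensemble_observables(self, conditions: Conditions,
                             **kw) -> EnsembleObservables:
        return self.solve_steady_state(conditions, **kw).observables()

    def force_velocity_curve(self, conditions: Conditions,
                             v_grid, **kw) -> pd.DataFrame:
        """One steady-state solve per velocity; CSV-ready table."""
        v_grid = np.asarray(v_grid, dtype=float)
        if np.any(v_grid <= 0) or np.any(np.diff(v_grid) <= 0):
            raise ValueError("v_grid must be positive and strictly sorted")
        rows = []
        for v in v_grid:
            obs = self.ensemble_observables(conditions.replace(v=v), **kw)
            rows.append({"v_nm_per_s": v,
                         "force_pN": obs.mean_force,
                         "stiffness_pN_per_nm": obs.stiffness,
                         "frac_attached": obs.frac_attached,
                         "atpase_per_s": obs.atpase})
        return pd.DataFrame(rows)

    def find_vmax(self, conditions: Conditions,
                  bracket: tuple[float, float] = (10.0, 30000.0),
                  tol_force: float = 1e-4, **kw) -> float:
        """Unloaded shortening velocity: bisection on <F>(v) = 0."""
        lo, hi = bracket
        f_lo = self.ensemble_observables(conditions.replace(v=lo),
                                         **kw).mean_force
        f_hi = self.ensemble_observables(conditions.replace(v=hi),
                                         **kw).mean_force
        if f_lo * f_hi > 0:
            raise ValueError(
                f"no sign change of mean force on bracket {bracket}: "
                f"F({lo}) = {f_lo:.4g} pN, F({hi}) = {f_hi:.4g} pN")
        while True:
            mid = 0.5 * (lo + hi)
            f_mid = self.ensemble_observables(conditions.replace(v=mid),
                                              **kw).mean_force
            if abs(f_mid) < tol_force or (hi - lo) / mid < 1e-6:
                return mid
            if f_lo * f_mid <= 0:
                hi, f_hi = mid, f_mid
            else:
                lo, f_lo = mid, f_mid

    # -- condition scans ---------------------------------------------------

    def condition_scan(self, conditions: Conditions, axis: str, grid,
                       mode: str, **kw) -> pd.DataFrame:
        """Scan [Pi] or [MgATP] for isometric force or Vmax.

        Isometric force is computed from the simplified fixed-strain
        compartment scheme (the strain-resolved equations are singular at
        v = 0); Vmax comes from :meth:`find_vmax`.
        """
        if axis not in ("Pi", "MgATP"):
            raise ValueError("axis must be 'Pi' or 'MgATP'")
        grid = np.asarray(grid, dtype=float)
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be positive and strictly sorted")
        rows = []
        for val in grid:
            cond = (conditions.replace(conc_Pi=val) if axis == "Pi"
                    else conditions.replace(conc_MgATP=val))
            row = {f"conc_{axis}": val}
            if mode == "isometric_force":
                from .transients import IsometricModel
                iso = IsometricModel(self.params, n_secondary_sites=1,
                                     conc_Pi=cond.conc_Pi)
                ss = iso.analytic_steady_state()
                row["force_pN"] = ss.force_pN
                row["force_occupancy"] = ss.force
            elif mode == "vmax":
                row["vmax_nm_per_s"] = self.find_vmax(cond, **kw)
            else:
                raise ValueError("mode must be 'isometric_force' or 'vmax'")
            rows.append(row)
        return pd.DataFrame(rows)


def sensitivity_analysis(params: ModelParameters, outputs: dict,
                         parameter_ids, rel: float = 0.10) -> pd.DataFrame:
    """Sensitivities S_ij = dy_j / dp_i for ±10% parameter perturbations.

    ``outputs`` maps an output id to a callable evaluating that output for
    a given :class:`ModelParameters`.  Perturbations that violate the
    parameter invariants are flagged per cell rather than raising.
    """
    base = {name: fn(params) for name, fn in outputs.items()}
    rows = []
    for pid in parameter_ids:
        p0 = getattr(params, pid)
        for sign, tag in ((+1, "+10%"), (-1, "-10%")):
            dp = sign * rel * p0
            try:
                pert = params.replace(**{pid: p0 + dp})
            except ValueError as err:
                for name in outputs:
                    rows.append({"parameter": pid, "output": name,
                                 "direction": tag, "S": np.nan,
                                 "delta_p": dp, "note": str(err)})
                continue
            for name, fn in outputs.items():
                try:
                    val = fn(pert)
                    S = (val - base[name]) / dp if dp != 0 else np.nan
                    note = ""
                except Exception as err:  # solver failure in one cell
                    S, note = np.nan, str(err)
                rows.append({"parameter": pid, "output": name,
                             "direction": tag, "S": S, "delta_p": dp,
                             "note": note})
    return pd.DataFrame(rows)
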