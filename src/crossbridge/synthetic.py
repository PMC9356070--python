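"""Seeded generators for every input the analysis stages consume.

The generators emulate the statistical structure of the single-molecule
and AFM datasets: exponential-mixture dwell durations whose amplitudes
(not rates) shrink with [Pi] through a two-site Hill occupancy model,
Poisson hotspot counts, Gaussian-mixture lever-arm angles, and
exponential-with-lag transient traces.  Presets ``fig2`` and ``fig6``
bundle the published headline values (basal ATPase 0.05/s, fast phases
0.35 and 3.5/s, dissociation constants 0.3 and 16 mM, the per-condition
angle mixtures); they are emulation presets, not experimental data.

All generation is integer-seeded through ``numpy.random.default_rng`` and
fully reproducible: the same spec and arguments give identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dwell import DwellDataset
from .leverarm import AngleDataset
from .transients import TransientTrace

__all__ = ["GeneratorSpec", "fig2_spec", "fig6_spec",
           "generate_dwell_durations", "generate_dwell_events",
           "generate_hotspot_counts", "generate_angle_samples",
           "generate_exp_lag_trace"]

#: lever-arm angle mixtures per condition: (mean deg, SD deg, weight)
FIG6_ANGLE_MIXTURES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "ADP": ((51.0, 13.42, 1.0),),
    "ADP-metavanadate": ((68.6, 13.8, 0.5), (99.2, 6.7, 0.5)),
    "ADP-PAB": ((53.6, 8.3, 0.5), (87.7, 16.6, 0.5)),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic single-molecule experiment."""

    seed: int = 0
    n_spots: int = 60
    events_per_spot: float = 14.0      # Poisson mean per window at [Pi]=0
    window: float = 900.0              # observation window, s
    dwell_rates: tuple[float, ...] = (0.05, 0.35, 3.5)    # 1/s
    dwell_fractions: tuple[float, ...] = (0.45, 0.35, 0.20)
    # two-site Hill occupancy mapping [Pi] (mM) to amplitude scaling
    Kd1: float = 0.3
    Kd2: float = 16.0
    f1: float = 0.5
    f2: float = 0.5
    hill_n1: float = 1.0
    hill_n2: float = 1.0
    n_control_hotspots: int = 51       # expected count at [Pi] = 0
    angle_mixtures: dict = field(
        default_factory=lambda: dict(FIG6_ANGLE_MIXTURES))
    trace_noise_sd: float = 0.0

    def __post_init__(self):
        if abs(sum(self.dwell_fractions) - 1.0) > 1e-9:
            raise ValueError("dwell fractions must sum to 1")
        if any(r <= 0 for r in self.dwell_rates):
            raise ValueError("dwell rates must be positive")
        if len(self.dwell_rates) != len(self.dwell_fractions):
            raise ValueError("rates and fractions must align")

    def replace(self, **changes) -> "GeneratorSpec":
        return replace(self, **changes)

    def occupancy(self, conc_Pi) -> np.ndarray | float:
        """Fraction of binding not blocked by Pi: 1 - f1 H1 - f2 H2."""
        c = np.asarray(conc_Pi, dtype=float)
        h1 = c ** self.hill_n1 / (self.Kd1 ** self.hill_n1
                                  + c ** self.hill_n1)
        h2 = c ** self.hill_n2 / (self.Kd2 ** self.hill_n2
                                  + c ** self.hill_n2)
        out = 1.0 - self.f1 * h1 - self.f2 * h2
        return out if out.ndim else float(out)


def fig2_spec(seed: int = 0) -> GeneratorSpec:
    """Preset emulating the [Pi]-competition dwell-time experiment."""
    return GeneratorSpec(seed=seed)


def fig6_spec(seed: int = 0) -> GeneratorSpec:
    """Preset emulating the lever-arm-angle experiment."""
    return GeneratorSpec(seed=seed)


def _rng(spec: GeneratorSpec, *salt) -> np.random.Generator:
    return np.random.default_rng(
        [int(spec.seed)] + [int(round(float(s) * 1000)) for s in salt])


def _draw_dwells(rng: np.random.Generator, spec: GeneratorSpec,
                 n: int) -> np.ndarray:
    phases = rng.choice(len(spec.dwell_rates), size=n,
                        p=np.asarray(spec.dwell_fractions))
    scales = 1.0 / np.asarray(spec.dwell_rates)
    return rng.exponential(scales[phases])


def generate_dwell_durations(spec: GeneratorSpec, n: int,
                             salt: float = 0.0) -> np.ndarray:
    """Exactly n dwell durations from the exponential mixture."""
    if n <= 0:
        raise ValueError("n must be positive")
    return _draw_dwells(_rng(spec, 1, salt), spec, n)


def generate_dwell_events(spec: GeneratorSpec,
                          conc_Pi: float = 0.0) -> DwellDataset:
    """Per-spot event table at one [Pi].

    Event counts are Poisson with mean ``events_per_spot`` scaled by the
    two-site occupancy at [Pi] (the amplitudes of all phases shrink with
    [Pi]; the rates do not change).  Dwells longer than the observation
    window are not visible and are dropped.
    """
    rng = _rng(spec, 2, conc_Pi)
    occ = spec.occupancy(conc_Pi)
    rows = []
    for spot in range(spec.n_spots):
        n = rng.poisson(spec.events_per_spot * occ)
        if n == 0:
            continue
        dwells = _draw_dwells(rng, spec, n)
        dwells = dwells[dwells < spec.window]
        starts = rng.uniform(0.0, spec.window - dwells)
        for t0, d in zip(starts, dwells):
            rows.append((spot, t0, d))
    ev = pd.DataFrame(rows, columns=["spot_id", "t_start_s", "dwell_s"])
    return DwellDataset(ev, conc_Pi=conc_Pi, window=spec.window,
                        label=f"synthetic_{conc_Pi:g}mM")


def generate_hotspot_counts(spec: GeneratorSpec, pi_grid,
                            noise: bool = True) -> pd.DataFrame:
    """Hotspot counts vs [Pi]: expected N(0)·occupancy, Poisson noise."""
    grid = np.asarray(pi_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("Pi grid must be nonnegative")
    rng = _rng(spec, 3)
    expected = spec.n_control_hotspots * spec.occupancy(grid)
    counts = rng.poisson(expected).astype(float) if noise else expected
    return pd.DataFrame({"conc_Pi_mM": grid, "count": counts,
                         "expected": expected,
                         "sd": np.sqrt(np.maximum(counts, 0.0))})


def generate_angle_samples(spec: GeneratorSpec, condition: str,
                           n: int) -> AngleDataset:
    """Per-frame lever-arm angles from the condition's Gaussian mixture."""
    if n <= 0:
        raise ValueError("n must be positive")
    if condition not in spec.angle_mixtures:
        raise KeyError(f"no angle mixture for condition {condition!r}; "
                       f"have {sorted(spec.angle_mixtures)}")
    comps = spec.angle_mixtures[condition]
    weights = np.array([c[2] for c in comps], dtype=float)
    weights = weights / weights.sum()
    salt = zlib.crc32(condition.encode()) % 100000
    rng = _rng(spec, 4, salt)
    which = rng.choice(len(comps), size=n, p=weights)
    mus = np.array([c[0] for c in comps])
    sds = np.array([c[1] for c in comps])
    angles = np.clip(rng.normal(mus[which], sds[which]), 0.0, 180.0)
    ev = pd.DataFrame({"frame": np.arange(n),
                       "molecule_id": rng.integers(0, max(n // 20, 1), n),
                       "angle_deg": angles})
    return AngleDataset(ev, condition=condition)


def generate_exp_lag_trace(k: float, lag: float, amplitude: float,
                           noise_sd: float = 0.0, seed: int = 0,
                           baseline: float = 0.0, t_max: float | None = None,
                           n_points: int = 400) -> TransientTrace:
    """Noisy exponential-with-lag trace for fitter validation."""
    if k <= 0:
        raise ValueError("k must be positive")
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    if t_max is None:
        t_max = lag + 6.0 / k
    t = np.linspace(0.0, t_max, n_points)
    clean = baseline + amplitude * np.where(
        t > lag, 1.0 - np.exp(-k * np.clip(t - lag, 0.0, None)), 0.0)
    if noise_sd > 0:
        clean = clean + np.random.default_rng(seed).normal(0, noise_sd,
                                                           t.shape)
    return TransientTrace(t, clean, kind="synthetic_exp_lag",
                          meta={"k": k, "lag": lag, "amplitude": amplitude,
                                "baseline": baseline, "noise_sd": noise_sd,
                                "seed": seed})
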