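"""Single-molecule dwell-time analysis.

The pipeline mirrors the TIRF competition assay workflow: event tables of
fluorescent-nucleotide dwells per surface spot are reduced to "hotspots"
(spots with at least ten events per observation window), pooled dwell
durations are turned into cumulative (survival) distributions, and those
are fitted with 1-, 2- or 3-exponential mixtures.  Model order is chosen
by the corrected Akaike information criterion with a fall-back to the
simpler model whenever a fit is ambiguous.  Hotspot counts versus [Pi] are
fitted with a sum of two Hill inhibition terms, with Poisson (√N) counting
errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["DwellDataset", "filter_hotspots", "cumulative_distribution",
           "MultiExponentialModel", "MultiExpFit", "fit_multiexponential",
           "select_model_aicc", "normalize_phases", "HillSumModel",
           "HillSumFit", "fit_hill_sum", "poisson_count_error"]

EVENT_COLUMNS = ["spot_id", "t_start_s", "dwell_s"]


@dataclass
class DwellDataset:
    """Event table of single-molecule dwell times for one condition."""

    events: pd.DataFrame          # columns spot_id, t_start_s, dwell_s
    conc_Pi: float = 0.0          # added [Pi], mM
    window: float = 900.0         # observation window, s
    label: str = ""

    def __post_init__(self):
        missing = set(EVENT_COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"event table lacks columns {sorted(missing)}")
        ev = self.events
        if len(ev) and (ev.dwell_s <= 0).any():
            raise ValueError("dwell durations must be positive")
        if len(ev) and (ev.t_start_s + ev.dwell_s > self.window + 1e-9).any():
            raise ValueError("events must end within the observation window")

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "DwellDataset":
        df = pd.read_csv(path)
        meta = {}
        if "added_pi_mM" in df.columns:
            meta["conc_Pi"] = float(df["added_pi_mM"].iloc[0])
        return cls(df[EVENT_COLUMNS].copy(), **{**meta, **kw})

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def durations(self) -> np.ndarray:
        return self.events.dwell_s.to_numpy()

    def spot_counts(self) -> pd.Series:
        return self.events.groupby("spot_id").size()


def filter_hotspots(dataset: DwellDataset,
                    min_events: int = 10) -> tuple[DwellDataset, pd.Series]:
    """Keep spots with at least ``min_events`` dwells in the window.

    Returns the hotspot-only dataset and the per-spot event counts of the
    input (for reporting).
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    counts = dataset.spot_counts()
    if counts.empty:
        warnings.warn("empty dwell dataset; no hotspots")
        return dataset, counts
    keep = counts[counts >= min_events].index
    ev = dataset.events[dataset.events.spot_id.isin(keep)].reset_index(
        drop=True)
    sub = DwellDataset(ev, conc_Pi=dataset.conc_Pi, window=dataset.window,
                       label=dataset.label)
    return sub, counts


def cumulative_distribution(durations, direction: str = "survival"):
    """Cumulative dwell-time curve.

    ``survival`` (default): C(t) = #{dwell >= t} evaluated at 0 and the
    sorted unique durations, so C(0) = N — the form a sum of decaying
    exponentials fits directly.  ``ascending`` gives the usual empirical
    CDF counts #{dwell <= t}.
    """
    d = np.sort(np.asarray(durations, dtype=float))
    if d.size == 0:
        raise ValueError("no dwell durations")
    uniq = np.unique(d)
    t = np.concatenate(([0.0], uniq)) if uniq[0] > 0 else uniq
    if direction == "survival":
        c = d.size - np.searchsorted(d, t, side="left")
    elif direction == "ascending":
        c = np.searchsorted(d, t, side="right")
    else:
        raise ValueError("direction must be 'survival' or 'ascending'")
    return t, c.astype(float)


# ---------------------------------------------------------------------------
# exponential-mixture fitting with AICc selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiExpFit:
    """A 1/2/3-exponential fit of a cumulative dwell-time curve."""

    n_phases: int
    rates: tuple[float, ...]        # 1/s, ascending
    amplitudes: tuple[float, ...]   # event-count units, matching order
    rate_ci: tuple[float, ...]      # 95% CI half-widths
    amplitude_ci: tuple[float, ...]
    ssr: float
    aicc: float
    nobs: int
    ambiguous: bool

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return sum(A * np.exp(-k * t)
                   for A, k in zip(self.amplitudes, self.rates))

    @property
    def total_amplitude(self) -> float:
        return float(sum(self.amplitudes))

    def summary(self) -> str:
        lines = [f"{self.n_phases}-exponential fit of the cumulative "
                 f"dwell-time distribution (n = {self.nobs} support points)"]
        for i, (k, A, kci, aci) in enumerate(zip(
                self.rates, self.amplitudes, self.rate_ci,
                self.amplitude_ci), 1):
            lines.append(f"  phase {i}: rate {k:.4g} ± {kci:.2g} 1/s, "
                         f"amplitude {A:.4g} ± {aci:.2g}")
        lines.append(f"  SSR {self.ssr:.5g}   AICc {self.aicc:.4f}"
                     + ("   [ambiguous]" if self.ambiguous else ""))
        return "\n".join(lines)


def _aicc(ssr: float, n: int, n_params: int) -> float:
    # Gaussian-residual AICc of a curve fit; K counts the variance too
    k = n_params + 1
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(ssr, 1e-300) / n) + 2 * k \
        + 2 * k * (k + 1) / (n - k - 1)


def _aicc_loglik(ll: float, n: int, n_params: int) -> float:
    if n - n_params - 1 <= 0:
        return np.inf
    return -2.0 * ll + 2 * n_params \
        + 2 * n_params * (n_params + 1) / (n - n_params - 1)


class MultiExponentialModel:
    """Exponential-mixture model of a cumulative dwell-time distribution.

    Construct from raw durations (the survival curve is built internally)
    or from a precomputed ``(t, counts)`` pair, then ``fit(n_phases)`` or
    ``fit_best()`` for AICc-based order selection.
    """

    def __init__(self, durations=None, cumdist=None):
        self.durations = None
        if cumdist is not None:
            self.t, self.c = (np.asarray(cumdist[0], dtype=float),
                              np.asarray(cumdist[1], dtype=float))
        elif durations is not None:
            self.durations = np.asarray(durations, dtype=float)
            self.t, self.c = cumulative_distribution(durations)
        else:
            raise ValueError("provide durations or cumdist")

    def fit(self, n_phases: int, n_starts: int = 8, seed: int = 0,
            weighting: str = "poisson") -> MultiExpFit:
        if n_phases not in (1, 2, 3):
            raise ValueError("n_phases must be 1, 2 or 3")
        t, c = self.t, self.c
        n = len(t)
        if n < 5 * n_phases:
            raise ValueError(
                f"need at least {5 * n_phases} support points for a "
                f"{n_phases}-exponential fit, have {n}")
        # counting noise on the survival curve scales as sqrt(C)
        if weighting == "poisson":
            w = 1.0 / np.sqrt(np.maximum(c, 1.0))
        elif weighting == "none":
            w = np.ones_like(c)
        else:
            raise ValueError("weighting must be 'poisson' or 'none'")
        total = c.max()
        t_pos = t[t > 0]
        lo, hi = 0.1 / t_pos.max(), 5.0 / t_pos.min()

        def resid(theta):
            A = theta[:n_phases]
            k = np.exp(theta[n_phases:])
            return w * ((A[:, None] * np.exp(-np.outer(k, t))).sum(0) - c)

        rng = np.random.default_rng(seed)
        best = None
        for s in range(n_starts):
            if s == 0:
                k0 = np.logspace(np.log10(max(lo, 1e-6)),
                                 np.log10(hi), n_phases + 2)[1:-1]
            else:
                k0 = np.exp(rng.uniform(np.log(max(lo, 1e-6)),
                                        np.log(hi), n_phases))
            theta0 = np.concatenate([np.full(n_phases, total / n_phases),
                                     np.log(np.sort(k0))])
            res = least_squares(
                resid, theta0,
                bounds=(np.concatenate([np.zeros(n_phases),
                                        np.full(n_phases, -50.0)]),
                        np.concatenate([np.full(n_phases, np.inf),
                                        np.full(n_phases, 50.0)])))
            if best is None or res.cost < best.cost:
                best = res

        A = best.x[:n_phases]
        k = np.exp(best.x[n_phases:])
        order = np.argsort(k)
        A, k = A[order], k[order]
        ssr = float(2 * best.cost)

        # covariance approximation for 95% CIs; note d(rate)/d(log-rate)
        ambiguous = False
        J = best.jac
        try:
            JtJ = J.T @ J
            if np.linalg.cond(JtJ) > 1e10:
                raise np.linalg.LinAlgError
            dof = max(n - 2 * n_phases, 1)
            cov = np.linalg.inv(JtJ) * ssr / dof
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            a_ci = 1.96 * se[:n_phases][order]
            k_ci = 1.96 * se[n_phases:][order] * k   # delta method
        except np.linalg.LinAlgError:
            ambiguous = True
            a_ci = np.full(n_phases, np.nan)
            k_ci = np.full(n_phases, np.nan)
        if not ambiguous and np.any(k_ci > k):
            ambiguous = True        # CI wider than the estimate itself

        # Model-selection AICc.  The cumulative-curve residuals are strongly
        # serially correlated (each step shares almost all events with its
        # neighbours), so a Gaussian AICc over the support points
        # systematically rewards spurious extra phases.  When the raw
        # durations are available the AICc is therefore computed from the
        # exponential-mixture log-likelihood of the durations at the fitted
        # parameters; otherwise the curve-fit AICc is the fallback.
        if self.durations is not None and A.sum() > 0:
            w = np.clip(A / A.sum(), 1e-12, None)
            dens = (w[None, :] * k[None, :]
                    * np.exp(-np.outer(self.durations, k))).sum(1)
            ll = float(np.log(np.clip(dens, 1e-300, None)).sum())
            aicc = _aicc_loglik(ll, len(self.durations), 2 * n_phases - 1)
        else:
            aicc = _aicc(ssr, n, 2 * n_phases)

        return MultiExpFit(
            n_phases=n_phases, rates=tuple(k), amplitudes=tuple(A),
            rate_ci=tuple(k_ci), amplitude_ci=tuple(a_ci), ssr=ssr,
            aicc=aicc, nobs=n, ambiguous=ambiguous)

    def fit_mle(self, n_phases: int, censor_at: float | None = None,
                n_starts: int = 6, seed: int = 0) -> MultiExpFit:
        """Maximum-likelihood exponential-mixture fit of the durations.

        Cross-check for the least-squares curve fit; with ``censor_at`` the
        likelihood accounts for dwells truncated by the observation window
        (right-censoring at the window end).
        """
        if self.durations is None:
            raise ValueError("MLE fitting needs the raw durations")
        if n_phases not in (1, 2, 3):
            raise ValueError("n_phases must be 1, 2 or 3")
        from scipy.optimize import minimize
        d = self.durations
        N = d.size

        def nll(theta):
            k = np.exp(theta[:n_phases])
            logits = np.concatenate([theta[n_phases:], [0.0]])
            w = np.exp(logits - logits.max())
            w = w / w.sum()
            dens = (w[None] * k[None] * np.exp(-np.outer(d, k))).sum(1)
            out = -np.sum(np.log(np.clip(dens, 1e-300, None)))
            if censor_at is not None:
                # renormalise by the probability of observing a dwell
                surv = (w * np.exp(-k * censor_at)).sum()
                out += N * np.log(max(1.0 - surv, 1e-300))
            return out

        rng = np.random.default_rng(seed)
        lo, hi = np.log(0.1 / d.max()), np.log(5.0 / max(d.min(), 1e-9))
        best = None
        for s in range(n_starts):
            k0 = (np.linspace(lo, hi, n_phases + 2)[1:-1] if s == 0
                  else np.sort(rng.uniform(lo, hi, n_phases)))
            theta0 = np.concatenate([k0, np.zeros(n_phases - 1)])
            res = minimize(nll, theta0, method="Nelder-Mead",
                           options={"maxiter": 5000})
            if best is None or res.fun < best.fun:
                best = res
        k = np.exp(best.x[:n_phases])
        logits = np.concatenate([best.x[n_phases:], [0.0]])
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        order = np.argsort(k)
        k, w = k[order], w[order]
        aicc = _aicc_loglik(-best.fun, N, 2 * n_phases - 1)
        nan = tuple([np.nan] * n_phases)
        return MultiExpFit(n_phases, tuple(k), tuple(w * N), nan, nan,
                           ssr=np.nan, aicc=aicc, nobs=N, ambiguous=False)

    def fit_all(self, orders=(1, 2, 3), **kw) -> list[MultiExpFit]:
        fits = []
        for m in orders:
            try:
                fits.append(self.fit(m, **kw))
            except ValueError:
                pass
        return fits

    def fit_best(self, **kw) -> MultiExpFit:
        return select_model_aicc(self.fit_all(**kw))


def fit_multiexponential(cumdist, n_phases: int, **kw) -> MultiExpFit:
    """Functional wrapper: fit one mixture order to a cumulative curve."""
    return MultiExponentialModel(cumdist=cumdist).fit(n_phases, **kw)


def select_model_aicc(fits: list[MultiExpFit]) -> MultiExpFit:
    """Choose the mixture order: lowest AICc wins; ambiguous fits are
    demoted; exact ties break toward fewer phases."""
    if not fits:
        raise ValueError("no candidate fits")
    clean = [f for f in fits if not f.ambiguous]
    if not clean:
        warnings.warn("all candidate fits ambiguous; returning the "
                      "simplest model")
        return min(fits, key=lambda f: f.n_phases)
    return min(clean, key=lambda f: (f.aicc, f.n_phases))


def normalize_phases(fit: MultiExpFit, control_N: float) -> tuple[float, ...]:
    """Phase amplitudes as fractions of the control event count."""
    if control_N <= 0:
        raise ValueError("control_N must be positive")
    return tuple(A / control_N for A in fit.amplitudes)


# ---------------------------------------------------------------------------
# two-site Hill competition fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillSumFit:
    """Sum-of-two-Hill-terms inhibition fit of hotspot counts vs [Pi]."""

    Kd1: float            # mM, smaller
    Kd2: float            # mM, larger
    f1: float
    f2: float
    n1: float
    n2: float
    ssr: float

    def predict(self, conc_Pi):
        c = np.asarray(conc_Pi, dtype=float)
        h1 = c ** self.n1 / (self.Kd1 ** self.n1 + c ** self.n1)
        h2 = c ** self.n2 / (self.Kd2 ** self.n2 + c ** self.n2)
        return 1.0 - self.f1 * h1 - self.f2 * h2

    def summary(self) -> str:
        return ("Two-site Hill inhibition fit\n"
                f"  Kd1 {self.Kd1:.4g} mM (fraction {self.f1:.3f}, "
                f"n = {self.n1:g})\n"
                f"  Kd2 {self.Kd2:.4g} mM (fraction {self.f2:.3f}, "
                f"n = {self.n2:g})\n"
                f"  SSR {self.ssr:.5g}")


class HillSumModel:
    """Normalized hotspot count N([Pi])/N(0) as two competing sites.

    ``exclude`` marks outlier points (boolean mask or index list) left out
    of the fit, mirroring the outlier-flag convention of the assay.
    """

    def __init__(self, conc_Pi, counts_normalized, n1: float = 1.0,
                 n2: float = 1.0, exclude=None, weights=None):
        self.pi = np.asarray(conc_Pi, dtype=float)
        self.y = np.asarray(counts_normalized, dtype=float)
        self.weights = None if weights is None \
            else np.asarray(weights, dtype=float)
        if self.pi.shape != self.y.shape:
            raise ValueError("conc_Pi and counts must align")
        mask = np.ones_like(self.pi, dtype=bool)
        if exclude is not None:
            exclude = np.asarray(exclude)
            if exclude.dtype == bool:
                mask = ~exclude
            else:
                mask[exclude] = False
        self.mask = mask
        if mask.sum() < 6:
            raise ValueError("need at least 6 concentration points")
        self.n1, self.n2 = n1, n2

    def fit(self, n_starts: int = 12, seed: int = 0) -> HillSumFit:
        pi, y = self.pi[self.mask], self.y[self.mask]
        w = np.ones_like(y) if self.weights is None \
            else self.weights[self.mask]
        n1, n2 = self.n1, self.n2

        def resid(theta):
            lK1, lK2, f1, f2 = theta
            K1, K2 = np.exp(lK1), np.exp(lK2)
            h1 = pi ** n1 / (K1 ** n1 + pi ** n1)
            h2 = pi ** n2 / (K2 ** n2 + pi ** n2)
            pred = 1.0 - f1 * h1 - f2 * h2
            penalty = max(f1 + f2 - 1.0, 0.0) * 10.0
            return np.concatenate([w * (pred - y), [penalty]])

        pos = pi[pi > 0]
        lo = np.log(max(pos.min() / 10, 1e-4))
        hi = np.log(pos.max() * 10)
        rng = np.random.default_rng(seed)
        best = None
        for s in range(n_starts):
            if s == 0:
                l1, l2 = lo + 0.25 * (hi - lo), lo + 0.75 * (hi - lo)
            else:
                l1, l2 = np.sort(rng.uniform(lo, hi, 2))
            res = least_squares(
                resid, [l1, l2, 0.5, 0.5],
                bounds=([lo - 5, lo - 5, 0.0, 0.0], [hi + 5, hi + 5,
                                                     1.0, 1.0]))
            if best is None or res.cost < best.cost:
                best = res
        if best.cost > 1e6:  # pragma: no cover
            raise RuntimeError("Hill-sum fit failed to converge from the "
                               "start grid")
        lK1, lK2, f1, f2 = best.x
        K1, K2 = float(np.exp(lK1)), float(np.exp(lK2))
        if K1 > K2:
            K1, K2, f1, f2 = K2, K1, f2, f1
        resid_vec = resid(best.x)[:-1]
        return HillSumFit(K1, K2, float(f1), float(f2), n1, n2,
                          float(np.sum(resid_vec ** 2)))


def fit_hill_sum(conc_Pi, counts_normalized, **kw) -> HillSumFit:
    """Fit the sum-of-two-Hill inhibition model to normalized counts."""
    init_kw = {k: kw.pop(k) for k in ("n1", "n2", "exclude") if k in kw}
    return HillSumModel(conc_Pi, counts_normalized, **init_kw).fit(**kw)


def poisson_count_error(N: float) -> float:
    """Counting-process SD of an observed count: √N."""
    if N < 0:
        raise ValueError("count must be nonnegative")
    return float(np.sqrt(N))
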