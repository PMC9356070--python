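"""Dwell-time pipeline tests: hotspot filtering, cumulative distributions,
exponential-mixture fitting with AICc selection, Hill competition fits."""

import numpy as np
import pandas as pd
import pytest

from crossbridge import (DwellDataset, HillSumModel, MultiExponentialModel,
                         cumulative_distribution, filter_hotspots,
                         fit_hill_sum, normalize_phases,
                         poisson_count_error, select_model_aicc)
from crossbridge import synthetic as syn


def _dataset(counts_per_spot, window=900.0):
    rows = []
    for spot, n in enumerate(counts_per_spot):
        for k in range(n):
            rows.append((spot, 10.0 * k, 1.0))
    return DwellDataset(pd.DataFrame(
        rows, columns=["spot_id", "t_start_s", "dwell_s"]), window=window)


# ---------------------------------------------------------------------------
# hotspot filter
# ---------------------------------------------------------------------------

def test_hotspot_threshold():
    ds = _dataset([12, 9, 10])
    hot, counts = filter_hotspots(ds, min_events=10)
    assert set(hot.events.spot_id) == {0, 2}
    assert counts.to_dict() == {0: 12, 1: 9, 2: 10}
    all_kept, _ = filter_hotspots(ds, min_events=1)
    assert all_kept.n_events == ds.n_events
    with pytest.raises(ValueError):
        filter_hotspots(ds, min_events=0)


def test_hotspot_empty_warns():
    empty = DwellDataset(pd.DataFrame(
        columns=["spot_id", "t_start_s", "dwell_s"]))
    with pytest.warns(UserWarning):
        hot, counts = filter_hotspots(empty)
    assert hot.n_events == 0 and counts.empty


def test_hotspot_retention_matches_poisson_tail():
    from scipy.stats import poisson
    spec = syn.fig2_spec(5)
    ds = syn.generate_dwell_events(spec, conc_Pi=0.0)
    hot, counts = filter_hotspots(ds, min_events=10)
    # spots with zero events never appear in the table; condition on >= 1
    lam = spec.events_per_spot
    p_hot = poisson.sf(9, lam) / poisson.sf(0, lam)
    frac = counts.ge(10).mean()
    sd = np.sqrt(p_hot * (1 - p_hot) / len(counts))
    assert abs(frac - p_hot) < 4 * sd + 0.02


# ---------------------------------------------------------------------------
# cumulative distribution
# ---------------------------------------------------------------------------

def test_survival_counting():
    t, c = cumulative_distribution([1.0, 2.0, 2.0, 5.0])
    assert list(t) == [0.0, 1.0, 2.0, 5.0]
    assert list(c) == [4.0, 4.0, 3.0, 1.0]


def test_single_dwell_step():
    t, c = cumulative_distribution([3.0])
    assert list(t) == [0.0, 3.0] and list(c) == [1.0, 1.0]


def test_survival_nonincreasing_and_starts_at_N(rng):
    d = rng.exponential(2.0, 300)
    t, c = cumulative_distribution(d)
    assert c[0] == 300
    assert np.all(np.diff(c) <= 0)


def test_ascending_direction_option(rng):
    d = rng.exponential(1.0, 50)
    t, c = cumulative_distribution(d, direction="ascending")
    assert c[-1] == 50
    assert np.all(np.diff(c) >= 0)


def test_exponential_slope_regression(rng):
    d = rng.exponential(1.0 / 0.3, 5000)
    t, c = cumulative_distribution(d)
    keep = c > 50
    slope = np.polyfit(t[keep], np.log(c[keep]), 1)[0]
    assert -slope == pytest.approx(0.3, rel=0.05)


# ---------------------------------------------------------------------------
# exponential-mixture fits
# ---------------------------------------------------------------------------

def test_single_exponential_recovery():
    spec = syn.fig2_spec().replace(dwell_rates=(0.05,),
                                   dwell_fractions=(1.0,))
    d = syn.generate_dwell_durations(spec, 745)
    fit = MultiExponentialModel(d).fit(1)
    assert fit.rates[0] == pytest.approx(0.05, rel=0.10)
    assert fit.total_amplitude == pytest.approx(745, rel=0.05)


def test_triple_exponential_recovery_median():
    spec = syn.fig2_spec()
    errs = {0: [], 1: [], 2: []}
    for seed in range(20):
        d = syn.generate_dwell_durations(spec.replace(seed=seed), 745)
        fit = MultiExponentialModel(d).fit(3)
        for i, true in enumerate(spec.dwell_rates):
            errs[i].append(abs(fit.rates[i] - true) / true)
    for i in range(3):
        assert np.median(errs[i]) < 0.25


def test_ssr_decreases_with_order():
    d = syn.generate_dwell_durations(syn.fig2_spec(3), 500)
    m = MultiExponentialModel(d)
    ssr = [m.fit(n).ssr for n in (1, 2, 3)]
    assert ssr[0] >= ssr[1] >= ssr[2]


def test_fit_requires_support_points():
    with pytest.raises(ValueError, match="support points"):
        MultiExponentialModel([1.0, 2.0, 3.0]).fit(1)
    with pytest.raises(ValueError):
        MultiExponentialModel([1.0] * 30).fit(4)


def test_mle_cross_check_agrees_with_curve_fit():
    spec = syn.fig2_spec().replace(dwell_rates=(0.2,),
                                   dwell_fractions=(1.0,))
    d = syn.generate_dwell_durations(spec, 600)
    m = MultiExponentialModel(d)
    ls = m.fit(1)
    mle = m.fit_mle(1)
    assert mle.rates[0] == pytest.approx(ls.rates[0], rel=0.05)


# ---------------------------------------------------------------------------
# AICc selection
# ---------------------------------------------------------------------------

def test_selection_consistency_on_single_exponential():
    spec = syn.fig2_spec().replace(dwell_rates=(0.05,),
                                   dwell_fractions=(1.0,))
    hits = 0
    for seed in range(10):
        d = syn.generate_dwell_durations(spec.replace(seed=seed), 745)
        hits += MultiExponentialModel(d).fit_best().n_phases == 1
    assert hits >= 9


def test_selection_power_on_triple_exponential():
    spec = syn.fig2_spec()   # rates separated 7x and 10x
    hits = 0
    for seed in range(6):
        d = syn.generate_dwell_durations(spec.replace(seed=seed), 745)
        hits += MultiExponentialModel(d).fit_best().n_phases == 3
    assert hits >= 4


def test_tie_breaks_toward_fewer_phases():
    from crossbridge.dwell import MultiExpFit
    mk = lambda n, amb=False: MultiExpFit(
        n, tuple([1.0] * n), tuple([1.0] * n), tuple([0.1] * n),
        tuple([0.1] * n), 1.0, 100.0, 50, amb)
    assert select_model_aicc([mk(3), mk(2)]).n_phases == 2
    # ambiguity demotes a candidate regardless of its AICc
    good2 = mk(2)
    amb1 = mk(1, amb=True)
    assert select_model_aicc([amb1, good2]).n_phases == 2
    with pytest.warns(UserWarning):
        assert select_model_aicc([mk(3, True), mk(1, True)]).n_phases == 1
    with pytest.raises(ValueError):
        select_model_aicc([])


# ---------------------------------------------------------------------------
# phase normalization
# ---------------------------------------------------------------------------

def test_normalize_phases_division():
    from crossbridge.dwell import MultiExpFit
    fit = MultiExpFit(3, (0.05, 0.35, 3.5), (300.0, 200.0, 245.0),
                      (0,) * 3, (0,) * 3, 1.0, 0.0, 100, False)
    fr = normalize_phases(fit, 745)
    assert fr == pytest.approx((0.4027, 0.2685, 0.3289), abs=1e-4)
    assert sum(normalize_phases(fit, fit.total_amplitude)) == pytest.approx(
        1.0)
    with pytest.raises(ValueError):
        normalize_phases(fit, 0)


def test_pipeline_fractions_decrease_with_pi():
    """Amplitude scaling of the generator propagates through the fits."""
    spec = syn.fig2_spec(11)
    control = syn.generate_dwell_events(spec, 0.0)
    control_N = control.n_events
    totals = []
    for pi in (0.0, 1.0, 10.0):
        ds = syn.generate_dwell_events(spec, pi)
        hot, _ = filter_hotspots(ds, min_events=5)
        fit = MultiExponentialModel(hot.durations).fit(3)
        totals.append(sum(normalize_phases(fit, control_N)))
    assert totals[0] > totals[1] > totals[2]


# ---------------------------------------------------------------------------
# Hill-sum competition fit
# ---------------------------------------------------------------------------

def test_hill_noiseless_round_trip():
    pi = np.array([0.05, 0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 43])
    y = syn.fig2_spec().occupancy(pi)
    fit = fit_hill_sum(pi, y)
    assert fit.Kd1 == pytest.approx(0.3, rel=0.05)
    assert fit.Kd2 == pytest.approx(16.0, rel=0.05)
    assert fit.f1 + fit.f2 <= 1.0 + 1e-6


def test_hill_boundary_predictions():
    fit = fit_hill_sum(np.logspace(-1.5, 1.7, 10),
                       syn.fig2_spec().occupancy(np.logspace(-1.5, 1.7,
                                                             10)))
    assert fit.predict(0.0) == pytest.approx(1.0)
    assert fit.predict(1e6) == pytest.approx(1.0 - fit.f1 - fit.f2,
                                             abs=1e-3)


def test_hill_outlier_exclusion():
    pi = np.array([0.05, 0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 43])
    y = syn.fig2_spec().occupancy(pi).copy()
    y[3] = 1.5   # gross outlier
    fit = fit_hill_sum(pi, y, exclude=[3])
    assert fit.Kd1 == pytest.approx(0.3, rel=0.05)


def test_hill_needs_enough_points():
    with pytest.raises(ValueError):
        HillSumModel(np.array([1.0, 2, 3]), np.array([1.0, 0.5, 0.2]))


def test_poisson_count_error():
    assert poisson_count_error(51) == pytest.approx(7.14, abs=0.01)
    assert poisson_count_error(0) == 0.0
    assert poisson_count_error(100) == 10.0
    with pytest.raises(ValueError):
        poisson_count_error(-1)


# ---------------------------------------------------------------------------
# dataset validation
# ---------------------------------------------------------------------------

def test_dataset_schema_validation():
    with pytest.raises(ValueError, match="dwell_s"):
        DwellDataset(pd.DataFrame({"spot_id": [1], "t_start_s": [0.0]}))
    with pytest.raises(ValueError, match="positive"):
        DwellDataset(pd.DataFrame({"spot_id": [1], "t_start_s": [0.0],
                                   "dwell_s": [-1.0]}))
    with pytest.raises(ValueError, match="window"):
        DwellDataset(pd.DataFrame({"spot_id": [1], "t_start_s": [899.0],
                                   "dwell_s": [5.0]}), window=900.0)


def test_dataset_csv_round_trip(tmp_path):
    ds = syn.generate_dwell_events(syn.fig2_spec(1), 0.5)
    path = tmp_path / "events.csv"
    ev = ds.events.copy()
    ev["added_pi_mM"] = 0.5
    ev.to_csv(path, index=False)
    back = DwellDataset.from_csv(path)
    assert back.n_events == ds.n_events
    assert back.conc_Pi == 0.5
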