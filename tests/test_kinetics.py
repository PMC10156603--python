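"""Rate estimators, censoring behaviour and the binding isotherm."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smdecode.idealize import DwellRecord
from smdecode.kinetics import (
    BindingIsotherm,
    ExponentialCdf,
    FitError,
    TitrationModel,
    association_rate,
    catalytic_efficiency,
    classical_fraction,
    detect_binding_events,
    fit_titration,
    passage_rate,
    state_lifetime,
    zero_state_dwells,
)


def _dwell(duration, state=2, left=False, right=False, tid="t0", start=0):
    return DwellRecord(tid, state, start, int(duration / 0.01), duration, left, right)


# -- event detection -------------------------------------------------------


def test_event_detection_flags_first_and_last():
    series = np.array([0, 0, 0.3, 0.3, 0, 0.5, 0])
    events = detect_binding_events(series, threshold=0.1)
    assert len(events) == 2
    assert events[0].is_first and events[1].is_last
    assert (events[0].start_frame, events[0].end_frame) == (2, 4)
    assert detect_binding_events(np.zeros(50), 0.1) == []


def test_zero_dwells_come_from_interior_gaps_only():
    series = np.zeros(100)
    for start in (10, 30, 50, 70, 90):
        series[start:start + 5] = 0.5
    events = detect_binding_events(series, 0.1)
    dwells = zero_state_dwells(events, frame_interval=0.01)
    # 5 events -> 3 interior events -> 2 gaps of 15 frames
    assert dwells.size == 2
    assert np.allclose(dwells, 0.15)


# -- exponential CDF fits --------------------------------------------------


def test_exact_exponential_dwells_recover_closed_form_rate():
    """Deterministic quantile sample of Exp(mean 0.5 s) at 0.02 uM gives
    k_on = 1/(0.5 x 0.02) = 100 uM^-1 s^-1."""
    q = (np.arange(1, 201) - 0.5) / 200
    dwells = -0.5 * np.log(1 - q)
    est = association_rate(dwells, concentration=0.02, n_boot=100)
    assert est.value == pytest.approx(100.0, rel=0.02)
    assert est.ci[0] <= est.value <= est.ci[1]


def test_association_requires_minimum_events():
    with pytest.raises(FitError, match=">= 30"):
        association_rate(np.ones(5), 0.02)


def test_single_exponential_limit_of_delay_fit():
    rng = np.random.default_rng(1)
    t0, k = 0.2, 2.0
    times = t0 + rng.exponential(1 / k, 400)
    fit = ExponentialCdf(times=times).fit("double-exp-with-delay")
    assert fit.mean == pytest.approx(t0 + 1 / k, rel=0.06)


def test_catalytic_efficiency_on_synthetic_arrivals():
    """Without censoring the recovered mean arrival equals the sample mean
    and the efficiency is its reciprocal scaled by concentration."""
    rng = np.random.default_rng(2)
    times = rng.exponential(1.0, 500)
    est = catalytic_efficiency(times, concentration=0.01, n_boot=100)
    assert est.params["mean_arrival_s"] == pytest.approx(times.mean(), rel=0.02)
    assert est.value == pytest.approx(1.0 / (times.mean() * 0.01), rel=0.02)


def test_passage_rate_scripted_interval():
    times = np.full(60, 0.5)
    est = passage_rate(times, n_boot=60)
    assert est.params["mean_passage_s"] == pytest.approx(0.5, rel=1e-3)
    assert est.value == pytest.approx(2.0, rel=1e-3)


def test_passage_rate_increases_with_ga_to_ac_rate(cognate25):
    """3-point sweep: faster proofreading shortens passage times."""
    import warnings

    from smdecode.idealize import HmmSpec
    from smdecode.pipeline import process_dataset
    from smdecode.simulate import SimulationConfig, simulate_dataset

    values = []
    for k in (0.8, 1.7, 5.0):
        model = cognate25.with_rates({("GA", "AC"): k})
        cfg = SimulationConfig(n_frames=2000, seed=33)
        ds = simulate_dataset(model, cfg, 120)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            proc = process_dataset(ds, hmm_spec=HmmSpec.from_model(model), select=False)
        pt = proc.passage_times(3)
        est = passage_rate(pt, n_boot=50)
        values.append(est.value)
    assert values[0] < values[1] < values[2]


# -- lifetimes and censoring ----------------------------------------------


def test_lifetime_of_constant_dwells():
    dwells = [_dwell(1.0), _dwell(1.0), _dwell(1.0)]
    est = state_lifetime(dwells, 2, n_boot=50)
    assert est.value == pytest.approx(1.0)


def test_censored_mle_unbiased_where_naive_exclusion_is_low():
    """Right-censor every dwell above 0.8 s: the censoring-aware MLE
    recovers the true 1 s mean; excluding censored dwells is biased low."""
    rng = np.random.default_rng(3)
    true = rng.exponential(1.0, 3000)
    cut = 0.8
    dwells = [
        _dwell(min(d, cut), right=d > cut, tid=f"t{i}")
        for i, d in enumerate(true)
    ]
    cens = state_lifetime(dwells, 2, censored_mle=True, n_boot=100)
    naive = state_lifetime(dwells, 2, censored_mle=False, n_boot=100)
    se = 1.0 / np.sqrt(np.sum(true <= cut))
    assert abs(cens.value - 1.0) < 3 * se
    assert naive.value < 1.0 - 3 * se


def test_lifetime_errors_without_usable_dwells():
    with pytest.raises(FitError, match="no dwells"):
        state_lifetime([], 2)
    only_censored = [_dwell(0.5, right=True), _dwell(0.2, left=True)]
    with pytest.raises(FitError, match="censored_mle"):
        state_lifetime(only_censored, 2)


def test_cdf_fit_agrees_with_mle_on_exponential_sample():
    rng = np.random.default_rng(4)
    sample = rng.exponential(0.7, 1000)
    fit = ExponentialCdf(times=sample).fit("single-exp")
    mle = sample.mean()
    se = mle / np.sqrt(sample.size)
    assert abs(1 / fit.params["k1"] - mle) < 2 * se


# -- Gaussian fractions and the isotherm ----------------------------------


def test_classical_fraction_pure_and_balanced():
    rng = np.random.default_rng(5)
    pure = np.clip(rng.normal(0.7, 0.05, 3000), 0, 1)
    frac, se = classical_fraction(pure)
    assert frac == pytest.approx(1.0, abs=0.02)
    half = np.concatenate([
        rng.normal(0.7, 0.05, 2000), rng.normal(0.3, 0.05, 2000)
    ])
    frac, se = classical_fraction(np.clip(half, 0, 1))
    assert frac == pytest.approx(0.5, abs=0.03)


def test_classical_fraction_mode_collapse_raises():
    rng = np.random.default_rng(6)
    uni = np.clip(rng.normal(0.5, 0.05, 2000), 0, 1)
    with pytest.raises(FitError):
        classical_fraction(uni)


def test_isotherm_limits_and_exact_inversion():
    truth = TitrationModel(kd=0.8, a_c5a=0.9, a_capo=0.25)
    assert truth.fraction_classical(0.0) == pytest.approx(0.25)
    assert truth.fraction_classical(1e9) == pytest.approx(0.9, abs=1e-6)
    L = np.array([0.0, 0.2, 0.5, 1.0, 2.0, 5.0, 20.0])
    f = truth.fraction_classical(L)
    res = fit_titration(L, f, n_boot=100)
    assert res.model.kd == pytest.approx(0.8, abs=1e-4)
    assert res.model.a_c5a == pytest.approx(0.9, abs=1e-4)
    assert res.model.a_capo == pytest.approx(0.25, abs=1e-4)
    assert res.model.fraction_classical(0.0) == pytest.approx(res.model.a_capo)


def test_flat_titration_not_identifiable():
    L = np.array([0.0, 0.5, 1.0, 5.0])
    with pytest.raises(FitError, match="flat"):
        BindingIsotherm(L, np.full(4, 0.5))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    kd=st.floats(0.05, 50.0),
    a1=st.floats(0.3, 1.0),
    a0=st.floats(0.01, 0.29),
)
def test_isotherm_is_monotone_with_correct_limits(kd, a1, a0):
    model = TitrationModel(kd=kd, a_c5a=a1, a_capo=a0)
    L = np.logspace(-3, 4, 200)
    f = model.fraction_classical(L)
    assert np.all(np.diff(f) > -1e-12)
    assert model.fraction_classical(0.0) == pytest.approx(a0, rel=1e-9)
    assert f[-1] <= a1 + 1e-9


def test_efficiency_not_above_association_on_cognate_sim(cognate25):
    """Post-binding losses make catalytic efficiency <= association rate."""
    import warnings

    from smdecode.idealize import HmmSpec
    from smdecode.kinetic_model import load_preset
    from smdecode.pipeline import process_dataset
    from smdecode.simulate import SimulationConfig, simulate_dataset

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = SimulationConfig(n_frames=3000, seed=44)
        ds = simulate_dataset(cognate25, cfg, 250)
        proc = process_dataset(ds, hmm_spec=HmmSpec.from_model(cognate25))
        arr, cens = proc.arrival_times(3)
        eff = catalytic_efficiency(arr, cognate25.concentration,
                                   censored_times=cens, n_boot=60)
        gt = load_preset("cognate-25C-GTPyS")
        dsg = simulate_dataset(gt, SimulationConfig(n_frames=5000, seed=45), 250)
        procg = process_dataset(dsg, hmm_spec=HmmSpec.from_model(gt))
        zd, tids = procg.zero_dwell_table()
        assoc = association_rate(zd, gt.concentration, trace_ids=tids, n_boot=60)
    assert eff.value < assoc.value


def test_association_invariant_under_concentration_change(gtpys):
    """Doubling the concentration halves the zero dwell but leaves the
    recovered bimolecular constant unchanged within CI."""
    import warnings

    from smdecode.idealize import HmmSpec
    from smdecode.pipeline import process_dataset
    from smdecode.simulate import SimulationConfig, simulate_dataset

    values = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for conc in (0.0125, 0.025):
            ds = simulate_dataset(
                gtpys, SimulationConfig(n_frames=5000, seed=46), 250,
                concentration=conc,
            )
            proc = process_dataset(ds, hmm_spec=HmmSpec.from_model(gtpys))
            zd, tids = proc.zero_dwell_table()
            values[conc] = (association_rate(zd, conc, trace_ids=tids, n_boot=120), zd.mean())
    est1, mean1 = values[0.0125]
    est2, mean2 = values[0.025]
    assert mean2 < 0.75 * mean1
    lo = max(est1.ci[0], est2.ci[0])
    hi = min(est1.ci[1], est2.ci[1])
    assert lo < hi  # overlapping CIs: bimolecular constant unchanged
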