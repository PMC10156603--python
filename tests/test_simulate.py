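"""Simulator: path sampling, trace rendering, determinism, titration."""

import numpy as np
import pytest

from smdecode.kinetic_model import DecodingModel, StateSpec
from smdecode.simulate import (
    GroundTruth,
    SimulationConfig,
    render_trace,
    sample_path,
    simulate_dataset,
    simulate_titration,
)
from smdecode.io import load_dataset, save_dataset
from smdecode.kinetics import TitrationModel
from smdecode.trace_processing import compute_fret, correct_trace


def _truth_for(path, model, config, means=None):
    return GroundTruth(
        trace_id="t0",
        events=[(model.state_names[s], t0, t1) for s, t0, t1 in path],
        donor_bleach_time=np.inf,
        acceptor_bleach_time=np.inf,
        blinks=[],
        state_means=model.fret_means if means is None else means,
        state_names=model.state_names,
    )


def test_single_edge_dwell_mean(rng):
    model = DecodingModel(
        states=[StateSpec("Unbound", 0.0), StateSpec("CR", 0.23)],
        rates={("Unbound", "CR"): 1.0},
    )
    dwells = []
    for _ in range(4000):
        path = sample_path(model, 100.0, rng)
        dwells.append(path[0][2] - path[0][1])
    dwells = np.array(dwells)
    se = dwells.std(ddof=1) / np.sqrt(dwells.size)
    assert abs(dwells.mean() - 1.0) < 3 * se


def test_zero_concentration_never_leaves_unbound(cognate25, rng):
    path = sample_path(cognate25, 10.0, rng, concentration=0.0)
    assert len(path) == 1 and path[0][0] == cognate25.index("Unbound")


def test_productive_fraction_matches_absorption_oracle(cognate25, rng):
    """The fraction of CR entries that reach AC before dissociating matches
    the hitting-probability oracle."""
    from smdecode.kinetic_model import absorption_probability, build_generator

    Q = build_generator(cognate25)
    cr, ac, u = (cognate25.index(s) for s in ("CR", "GA", "AC"))
    cr = cognate25.index("CR")
    p_oracle = absorption_probability(Q, cr, cognate25.index("AC"), cognate25.index("Unbound"))
    hits = trials = 0
    for _ in range(600):
        path = sample_path(cognate25, 120.0, rng, start_state="CR")
        trials += 1
        for s, _, _ in path:
            if s == cognate25.index("AC"):
                hits += 1
                break
            if s == cognate25.index("Unbound"):
                break
    p_hat = hits / trials
    se = np.sqrt(p_oracle * (1 - p_oracle) / trials)
    assert abs(p_hat - p_oracle) < 3 * se


def test_render_pure_ac_trace_is_exact(cognate25, clean_config):
    """Zero noise, path fully accommodated: corrected FRET is 0.74 exactly."""
    dur = clean_config.duration
    path = [(cognate25.index("AC"), 0.0, dur)]
    truth = _truth_for(path, cognate25, clean_config)
    tr = render_trace(path, truth, cognate25, clean_config, np.random.default_rng(0))
    fret = compute_fret(correct_trace(tr, 0.0, 1.0), floor=1.0)
    assert np.allclose(fret, 0.74, atol=1e-12)


def test_correction_inverts_rendering_exactly(cognate25, clean_config):
    """With crosstalk and gamma applied, correct_trace recovers the ideal
    intensities algebraically at zero noise."""
    from dataclasses import replace

    cfg = replace(clean_config, crosstalk_alpha=0.075, gamma=1.2)
    dur = cfg.duration
    path = [(cognate25.index("GA"), 0.0, dur)]
    truth = _truth_for(path, cognate25, cfg)
    tr = render_trace(path, truth, cognate25, cfg, np.random.default_rng(0))
    corrected = correct_trace(tr, 0.075, 1.2)
    assert np.allclose(corrected.acceptor, 0.49 * cfg.total_intensity, atol=1e-9)
    assert np.allclose(corrected.donor, 0.51 * cfg.total_intensity, atol=1e-9)


def test_subframe_dwell_gives_occupancy_weighted_frame(cognate25, clean_config):
    """A 5-ms AC event inside a 10-ms frame of Unbound yields frame FRET
    0.5 x 0.74 (occupancy-weighted average, not midpoint sampling)."""
    dur = clean_config.duration
    u, ac = cognate25.index("Unbound"), cognate25.index("AC")
    path = [(u, 0.0, 0.020), (ac, 0.020, 0.025), (u, 0.025, dur)]
    truth = _truth_for(path, cognate25, clean_config)
    tr = render_trace(path, truth, cognate25, clean_config, np.random.default_rng(0))
    fret = compute_fret(correct_trace(tr, 0.0, 1.0), floor=1.0)
    assert fret[2] == pytest.approx(0.5 * 0.74, abs=1e-12)
    assert fret[1] == pytest.approx(0.0, abs=1e-12)


def test_datasets_are_bit_reproducible(cognate25):
    cfg = SimulationConfig(n_frames=300, seed=123)
    a = simulate_dataset(cognate25, cfg, 5)
    b = simulate_dataset(cognate25, cfg, 5)
    for ta, tb in zip(a.traces, b.traces):
        assert np.array_equal(ta.donor, tb.donor)
        assert np.array_equal(ta.acceptor, tb.acceptor)


def test_empty_dataset_has_valid_metadata(cognate25):
    ds = simulate_dataset(cognate25, SimulationConfig(n_frames=100, seed=1), 0)
    assert ds.n_traces == 0
    assert ds.metadata()["n_traces"] == 0
    assert ds.to_frame().empty


def test_dataset_roundtrip_through_tsv(cognate25, tmp_path):
    cfg = SimulationConfig(n_frames=200, seed=5)
    ds = simulate_dataset(cognate25, cfg, 3)
    save_dataset(ds, tmp_path)
    back = load_dataset(tmp_path)
    assert back.n_traces == 3
    for ta, tb in zip(ds.traces, back.traces):
        assert np.allclose(ta.donor, tb.donor, rtol=1e-4, atol=1e-2)


def test_bleach_and_blink_times_are_exponential(cognate25):
    """KS test of photobleach times against the configured exponential."""
    from scipy.stats import kstest

    cfg = SimulationConfig(n_frames=100, seed=9, donor_bleach_rate=0.05)
    ds = simulate_dataset(cognate25, cfg, 400)
    times = np.array([t.donor_bleach_time for t in ds.truths])
    stat = kstest(times, "expon", args=(0, 1 / 0.05))
    assert stat.pvalue > 0.01


def test_per_state_frame_fret_statistics(cognate25):
    """With channel noise off, frames fully inside a dwell carry the
    per-trace state mean exactly; across many traces the per-state mean
    matches the StateSpec mean and the static spread follows the
    configured heterogeneity scale."""
    from smdecode.simulate import _frame_occupancy

    cfg = SimulationConfig(
        n_frames=600, seed=3, noise_sd=0.0, crosstalk_alpha=0.0, gamma=1.0,
        donor_bleach_rate=0.0, acceptor_bleach_rate=0.0, blink_on_rate=0.0,
    )
    ds = simulate_dataset(cognate25, cfg, 150)
    vals = {s: [] for s in range(4)}
    for tr, truth in zip(ds.traces, ds.truths):
        fret = compute_fret(correct_trace(tr, 0.0, 1.0), floor=1.0)
        occ = _frame_occupancy(truth._index_events(), cfg.n_frames, cfg.frame_interval, n_states=4)
        for s in range(4):
            full = occ[:, s] >= 0.999999
            vals[s].extend(fret[full])
    for s, spec in enumerate(cognate25.states):
        v = np.asarray(vals[s])
        if v.size < 200:
            continue
        se = v.std(ddof=1) / np.sqrt(v.size / 50)  # frames correlate within traces
        assert abs(v.mean() - spec.fret_mean) < max(3 * se, 0.01)
        expected_sd = spec.fret_sd * cfg.static_heterogeneity_scale
        if expected_sd > 0:
            assert v.std(ddof=1) < 1.2 * expected_sd + 0.01


def test_titration_fraction_tracks_isotherm(rng):
    truth = TitrationModel(kd=0.5, a_c5a=0.85, a_capo=0.30)
    data = simulate_titration(truth, [0.0, 0.5, 50.0], 120, rng, n_frames=200)
    for L, frame in data.items():
        fc = truth.fraction_classical(L)
        classical = (frame["fret"] > 0.5).mean()
        assert classical == pytest.approx(fc, abs=0.04)
    with pytest.raises(ValueError):
        simulate_titration(truth, [], 10, rng)
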