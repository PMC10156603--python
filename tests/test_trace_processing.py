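"""Correction, FRET, bleach/blink detection and the five selection criteria."""

import numpy as np
import pytest

from smdecode.simulate import SimulationConfig, simulate_dataset
from smdecode.trace_processing import (
    FluorescenceTrace,
    SelectionCriteria,
    TraceStateError,
    compute_fret,
    correct_trace,
    count_blinks,
    detect_bleach,
    detection_floor,
    evaluate_trace,
    select_traces,
)


def _trace(donor, acceptor, dt=0.01, corrected=False, tid="t"):
    return FluorescenceTrace(tid, dt, np.asarray(donor, float), np.asarray(acceptor, float), corrected)


def _clean_trace(n=400, bleach_at=300, noise=5.0, fret=0.74, total=1000.0, seed=0, tid="t"):
    """Synthetic corrected trace: constant FRET, terminal donor bleach."""
    rng = np.random.default_rng(seed)
    donor = np.full(n, (1 - fret) * total)
    acceptor = np.full(n, fret * total)
    donor[bleach_at:] = 0.0
    acceptor[bleach_at:] = 0.0
    donor += rng.normal(0, noise, n)
    acceptor += rng.normal(0, noise, n)
    return _trace(donor, acceptor, corrected=True, tid=tid)


# -- correction ------------------------------------------------------------


def test_crosstalk_subtraction():
    tr = _trace([100.0], [110.0])
    out = correct_trace(tr, alpha=0.1, gamma=1.0)
    assert out.acceptor[0] == pytest.approx(100.0)
    assert out.donor[0] == pytest.approx(100.0)


def test_identity_correction_and_idempotence_guard():
    tr = _trace([50.0, 60.0], [10.0, 20.0])
    out = correct_trace(tr, alpha=0.0, gamma=1.0)
    assert np.allclose(out.donor, tr.donor) and np.allclose(out.acceptor, tr.acceptor)
    with pytest.raises(TraceStateError):
        correct_trace(out, 0.0, 1.0)


def test_fret_ratio_and_floor_rule():
    tr = _trace([260.0, 1.0], [740.0, 1.0], corrected=True)
    fret = compute_fret(tr, floor=100.0)
    assert fret[0] == pytest.approx(0.74)
    assert fret[1] == 0.0  # below detection floor -> zero by convention


def test_fret_requires_corrected_trace():
    with pytest.raises(TraceStateError):
        compute_fret(_trace([1.0], [1.0]))


# -- bleach / blink detection ---------------------------------------------


def test_noise_free_step_detected_exactly():
    donor = np.concatenate([np.full(400, 1000.0), np.zeros(200)])
    tr = _trace(donor, np.zeros(600), corrected=True)
    events = detect_bleach(tr)
    assert [(e.frame, e.channel) for e in events] == [(400, "donor")]


def test_flat_trace_has_no_events():
    tr = _trace(np.full(100, 800.0), np.full(100, 200.0), corrected=True)
    assert detect_bleach(tr) == []


def test_acceptor_bleach_detected_as_acceptor_channel():
    n = 300
    donor = np.concatenate([np.full(150, 260.0), np.full(150, 1000.0)])
    acceptor = np.concatenate([np.full(150, 740.0), np.full(150, 0.0)])
    tr = _trace(donor, acceptor, corrected=True)
    events = detect_bleach(tr)
    assert any(e.channel == "acceptor" and abs(e.frame - 150) <= 1 for e in events)


def test_bleach_frame_accuracy_on_simulated_traces(cognate25):
    """Detected donor-bleach frame within +/-2 frames of truth for >=99%."""
    cfg = SimulationConfig(n_frames=2000, seed=77, donor_bleach_rate=0.1,
                           blink_on_rate=0.0)
    ds = simulate_dataset(cognate25, cfg, 150)
    ok = total = 0
    for tr, truth in zip(ds.traces, ds.truths):
        if not np.isfinite(truth.donor_bleach_time) or truth.donor_bleach_time >= cfg.duration - 0.1:
            continue
        if truth.donor_bleach_time < 0.3:
            continue  # too few pre-bleach frames to detect anything
        corrected = correct_trace(tr, cfg.crosstalk_alpha, cfg.gamma)
        cat = [e.frame for e in detect_bleach(corrected) if e.channel == "donor"]
        total += 1
        true_frame = truth.donor_bleach_time / cfg.frame_interval
        if cat and abs(cat[0] - true_frame) <= 2:
            ok += 1
    assert total > 50
    assert ok / total >= 0.99


def test_scripted_blinks_are_counted():
    donor = np.full(300, 1000.0)
    donor[100:103] = 0.0
    donor[200:202] = 0.0
    donor[280:] = 0.0  # catastrophic bleach
    tr = _trace(donor, np.zeros(300), corrected=True)
    events = detect_bleach(tr)
    floor = detection_floor(tr, events)
    assert count_blinks(tr, events, floor) == 2
    clean = _clean_trace()
    assert count_blinks(clean) == 0


# -- selection -------------------------------------------------------------


def test_clean_trace_passes_all_criteria():
    r = evaluate_trace(_clean_trace())
    assert r["accepted"], r["reason"]


def test_each_criterion_rejects_its_targeted_violation():
    # 1. two bleach steps (aggregate): 1000 -> 500 -> 0
    donor = np.concatenate([np.full(150, 1000.0), np.full(100, 500.0), np.zeros(150)])
    two_step = _trace(donor + np.random.default_rng(1).normal(0, 4, 400),
                      np.zeros(400), corrected=True)
    assert evaluate_trace(two_step)["reason"] == "multiple bleach events"

    # 2. low signal/background SNR: tiny total intensity over noisy background
    rng = np.random.default_rng(2)
    n = 400
    donor = np.full(n, 120.0); donor[300:] = 0.0
    tr = _trace(donor + rng.normal(0, 20, n), rng.normal(0, 20, n), corrected=True)
    assert evaluate_trace(tr)["reason"] == "low signal/background-noise"

    # 3. low signal/signal SNR: two resolvable FRET modes whose separation
    # over within-state width is ~5, below the 6:1 floor
    rng = np.random.default_rng(3)
    n = 600
    state = (np.arange(n) // 30) % 2
    fret = np.where(state, 0.65, 0.35) + rng.normal(0, 0.058, n)
    fret = np.clip(fret, 0.01, 0.99)
    total = 1000.0
    donor = (1 - fret) * total; acceptor = fret * total
    donor[550:] = 0.0; acceptor[550:] = 0.0
    donor += rng.normal(0, 3, n); acceptor += rng.normal(0, 3, n)
    tr = _trace(donor, acceptor, corrected=True)
    assert evaluate_trace(tr)["reason"] == "low signal/signal-noise"

    # 4. too many donor blinks
    donor = np.full(500, 1000.0)
    for start in (50, 120, 200, 280, 350):
        donor[start:start + 3] = 0.0
    donor[450:] = 0.0
    tr = _trace(donor + np.random.default_rng(4).normal(0, 4, 500),
                np.zeros(500), corrected=True)
    assert evaluate_trace(tr)["reason"] == "too many donor blinks"

    # 5. correlated donor/acceptor (shared slow drift, no anticorrelation)
    rng = np.random.default_rng(5)
    n = 400
    drift = np.cumsum(rng.normal(0, 8, n))
    donor = 500.0 + drift; acceptor = 500.0 + drift
    donor[350:] = 0.0; acceptor[350:] = 0.0
    donor += rng.normal(0, 2, n); acceptor += rng.normal(0, 2, n)
    tr = _trace(donor, acceptor, corrected=True)
    assert evaluate_trace(tr)["reason"] == "donor-acceptor correlation too high"


def test_anticorrelated_dynamics_pass_correlation_criterion():
    """Genuine FRET dynamics anticorrelate the channels (corr ~ -1 < 0.5)."""
    rng = np.random.default_rng(6)
    n = 600
    fret = np.where((np.arange(n) // 40) % 2, 0.74, 0.23)
    donor = (1 - fret) * 1000.0; acceptor = fret * 1000.0
    donor[550:] = 0.0; acceptor[550:] = 0.0
    donor += rng.normal(0, 5, n); acceptor += rng.normal(0, 5, n)
    r = evaluate_trace(_trace(donor, acceptor, corrected=True))
    assert r["da_corr"] < -0.5
    assert r["accepted"], r["reason"]


def test_selection_is_order_independent():
    traces = [_clean_trace(seed=i, tid=f"t{i}") for i in range(12)]
    acc_fwd, rep_fwd = select_traces(traces)
    acc_rev, rep_rev = select_traces(traces[::-1])
    assert {t.trace_id for t in acc_fwd} == {t.trace_id for t in acc_rev}


def test_acceptance_fraction_decreases_with_noise(cognate25):
    fractions = []
    for noise in (25.0, 65.0, 300.0):
        cfg = SimulationConfig(n_frames=1500, seed=31, noise_sd=noise,
                               donor_bleach_rate=0.05)
        ds = simulate_dataset(cognate25, cfg, 60)
        corrected = [correct_trace(t, cfg.crosstalk_alpha, cfg.gamma) for t in ds.traces]
        _, report = select_traces(corrected)
        fractions.append(report["accepted"].mean())
    assert fractions[0] > fractions[1] >= fractions[2]
    assert fractions[0] > fractions[2]


def test_criteria_defaults_match_published_thresholds():
    c = SelectionCriteria()
    assert (c.max_bleach_events, c.min_snr_background, c.min_snr_signal,
            c.max_donor_blinks, c.max_da_correlation) == (1, 8.0, 6.0, 3, 0.5)
    with pytest.raises(ValueError):
        SelectionCriteria(min_snr_background=0.0)
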