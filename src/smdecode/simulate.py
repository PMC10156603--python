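"""Synthetic smFRET trace generator for the decoding kinetic scheme.

State paths are sampled by the Gillespie algorithm from the continuous-time
Markov model and rendered into donor/acceptor fluorescence traces with the
statistical structure the analysis chain assumes:

* camera **frame integration**: the ideal FRET of a frame is the
  occupancy-time-weighted mean of the state FRET means inside the frame,
  so sub-frame dwells (e.g. ~10 ms codon-recognition events at 10-ms
  frames) produce intermediate frame values rather than being sampled at
  the frame midpoint;
* **static heterogeneity**: each state's FRET SD is realized as a
  per-trace, per-state offset of the emission mean (conformational and
  calibration heterogeneity between molecules), resampled so that state
  means stay ordered with a minimum separation -- per-frame width within a
  trace comes from channel noise;
* **spectral crosstalk** (donor leakage into the acceptor channel) and
  **gamma** (acceptor/donor detection-efficiency ratio), the exact inverse
  of :func:`smdecode.trace_processing.correct_trace`;
* additive Gaussian **channel noise** with constant SD;
* single-step **photobleaching** of each fluorophore (exponential times)
  and transient **donor blinking** (both channels fall to background, then
  recover).

Datasets are reproducible: a master seed is split into per-trace child
seeds with ``numpy.random.SeedSequence.spawn``, so the same
(model, config, seed) gives bit-identical data and any single trace can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from smdecode.kinetic_model import DecodingModel, build_generator
from smdecode.trace_processing import FluorescenceTrace

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TraceDataset",
    "sample_path",
    "render_trace",
    "simulate_dataset",
    "simulate_titration",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition and photophysics parameters for trace rendering.

    Defaults emulate a prism-TIRF measurement at 10-ms integration with a
    total (corrected-space) intensity of 1000 a.u., channel noise of 25
    a.u. per frame (frame FRET SD ~ 0.02), 7.5% crosstalk, gamma 1.15,
    donor bleaching at 0.025 s^-1 and rare, short donor blinks.
    """

    frame_interval: float = 0.010
    n_frames: int = 5000
    total_intensity: float = 1000.0
    noise_sd: float = 25.0
    crosstalk_alpha: float = 0.075
    gamma: float = 1.15
    donor_bleach_rate: float = 0.025
    acceptor_bleach_rate: float = 0.005
    blink_on_rate: float = 0.01
    blink_off_rate: float = 20.0
    seed: int = 0
    static_heterogeneity: bool = True
    static_heterogeneity_scale: float = 0.4
    min_state_separation: float = 0.10

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("donor_bleach_rate", "acceptor_bleach_rate", "blink_on_rate", "blink_off_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass
class GroundTruth:
    """Per-trace generative truth used to validate the analysis chain."""

    trace_id: str
    events: list[tuple[str, float, float]]  # (state, t_enter_s, t_exit_s)
    donor_bleach_time: float
    acceptor_bleach_time: float
    blinks: list[tuple[float, float]]
    state_means: np.ndarray  # per-trace emission means after heterogeneity
    state_names: list[str] = field(default_factory=list)

    def frame_states(self, n_frames: int, frame_interval: float) -> np.ndarray:
        """Majority-occupancy state index per frame (for accuracy scoring)."""
        occ = _frame_occupancy(
            self._index_events(), n_frames, frame_interval, n_states=len(self.state_names)
        )
        return np.argmax(occ, axis=1)

    def _index_events(self) -> list[tuple[int, float, float]]:
        idx = {n: i for i, n in enumerate(self.state_names)}
        return [(idx[s], t0, t1) for s, t0, t1 in self.events]


def sample_path(
    model: DecodingModel,
    duration: float,
    rng: np.random.Generator,
    start_state: str = "Unbound",
    concentration: float | None = None,
) -> list[tuple[int, float, float]]:
    """Sample a continuous-time state path by the Gillespie algorithm.

    Returns a contiguous event list ``(state_index, t_enter, t_exit)``
    covering ``[0, duration]``.  Dwells are exponential with rate
    ``-Q[i, i]``; the successor is drawn proportional to the off-diagonal
    rates.  An absorbing start state yields a single event.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    Q = build_generator(model, concentration)
    n = Q.shape[0]
    exit_rates = -np.diag(Q)
    # successor distributions per state (guard absorbing states)
    jump = np.zeros_like(Q)
    for i in range(n):
        if exit_rates[i] > 0:
            jump[i] = Q[i] / exit_rates[i]
            jump[i, i] = 0.0
    events: list[tuple[int, float, float]] = []
    state = model.index(start_state)
    t = 0.0
    while t < duration:
        rate = exit_rates[state]
        dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_exit = min(t + dt, duration)
        events.append((state, t, t_exit))
        if t + dt >= duration:
            break
        state = int(rng.choice(n, p=jump[state]))
        t = t_exit
    return events


def _frame_occupancy(
    events: list[tuple[int, float, float]],
    n_frames: int,
    frame_interval: float,
    n_states: int | None = None,
) -> np.ndarray:
    """Fractional occupancy of each state within each frame, shape (F, S)."""
    if n_states is None:
        n_states = max(s for s, _, _ in events) + 1
    occ = np.zeros((n_frames, n_states))
    for s, t0, t1 in events:
        _accumulate(occ[:, s], t0, t1, frame_interval, n_frames)
    return occ


def _accumulate(
    target: np.ndarray, t0: float, t1: float, dt: float, n_frames: int
) -> None:
    """Add the fractional overlap of [t0, t1) with each frame into target."""
    t0 = max(t0, 0.0)
    t1 = min(t1, n_frames * dt)
    if t1 <= t0:
        return
    f0 = int(t0 / dt)
    f1 = min(int(np.ceil(t1 / dt)), n_frames)
    idx = np.arange(f0, f1)
    lo = np.maximum(t0, idx * dt)
    hi = np.minimum(t1, (idx + 1) * dt)
    target[idx] += (hi - lo) / dt


def _sample_state_means(
    model: DecodingModel, rng: np.random.Generator, config: SimulationConfig
) -> np.ndarray:
    """Per-trace emission means: base means plus static heterogeneity.

    The static (per-molecule) component of each state's FRET SD is
    ``static_heterogeneity_scale`` times the StateSpec SD -- the remainder
    of the printed population-histogram width arises dynamically from
    frame noise and sub-frame averaging.  Offsets keeping the non-zero
    state means ordered with at least ``min_state_separation`` between
    neighbours (and clear of the zero state) are accepted as drawn; a
    violating draw is replaced by its mirror image (sign-flipped offsets),
    which restores the margins whenever the base separations exceed the
    margin and keeps the sampler exactly mean-unbiased.  The rare draws
    whose mirror also violates (a sign-symmetric event) are rejected and
    redrawn.
    """
    base = model.fret_means.copy()
    if not config.static_heterogeneity:
        return base
    sds = model.fret_sds * config.static_heterogeneity_scale
    nonzero = np.flatnonzero(base > 0)
    if nonzero.size == 0:
        return base
    order = nonzero[np.argsort(base[nonzero])]

    def valid(means: np.ndarray) -> bool:
        seps = np.diff(np.concatenate([[0.0], means[order]]))
        return bool(np.all(seps >= config.min_state_separation)) and bool(
            np.all((means[nonzero] > 0.02) & (means[nonzero] < 0.98))
        )

    for _ in range(200):
        offsets = rng.normal(0.0, sds[nonzero])
        for signed in (offsets, -offsets):
            means = base.copy()
            means[nonzero] = base[nonzero] + signed
            if valid(means):
                return means
    return base


def _blink_intervals(
    duration: float, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Donor dark intervals from a two-state (on/off) telegraph process."""
    if config.blink_on_rate <= 0:
        return []
    intervals = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / config.blink_on_rate)
        if t >= duration:
            break
        off = rng.exponential(1.0 / config.blink_off_rate) if config.blink_off_rate > 0 else duration
        intervals.append((t, min(t + off, duration)))
        t += off
        if t >= duration:
            break
    return intervals


def render_trace(
    path: list[tuple[int, float, float]],
    truth: GroundTruth,
    model: DecodingModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> FluorescenceTrace:
    """Render a state path into a raw donor/acceptor fluorescence trace.

    Within each frame, donor and acceptor signals are integrated over the
    sub-frame segments defined by the state path, the bleach times and the
    blink intervals: while both dyes are active the corrected-space split
    is E and 1 - E of the total intensity (E from the per-trace state
    mean); after acceptor bleaching all emission returns to the donor;
    while the donor is dark (blink) or bleached both channels are at
    background.  Gamma and crosstalk are then applied (the exact inverse of
    the correction step) and Gaussian channel noise is added.
    """
    n_frames, dt = config.n_frames, config.frame_interval
    duration = n_frames * dt
    if path[-1][2] < duration - 1e-9:
        raise ValueError("path duration is shorter than the trace duration")
    T, alpha, gamma = config.total_intensity, config.crosstalk_alpha, config.gamma
    means = truth.state_means

    donor = np.zeros(n_frames)
    acceptor = np.zeros(n_frames)

    # breakpoints of the photophysics timeline
    cuts = {0.0, duration, min(truth.donor_bleach_time, duration), min(truth.acceptor_bleach_time, duration)}
    for b0, b1 in truth.blinks:
        cuts.add(min(b0, duration))
        cuts.add(min(b1, duration))
    cut_arr = np.array(sorted(cuts))

    def donor_active(t: float) -> bool:
        if t >= truth.donor_bleach_time:
            return False
        return not any(b0 <= t < b1 for b0, b1 in truth.blinks)

    for s, t0, t1 in path:
        t1 = min(t1, duration)
        if t1 <= t0:
            continue
        # split the event at photophysics breakpoints
        inner = cut_arr[(cut_arr > t0) & (cut_arr < t1)]
        bounds = np.concatenate([[t0], inner, [t1]])
        for a0, a1 in zip(bounds[:-1], bounds[1:]):
            mid = 0.5 * (a0 + a1)
            if not donor_active(mid):
                continue
            if mid < truth.acceptor_bleach_time:
                E = means[s]
                d_rate = (1.0 - E) * T / gamma
                a_rate = E * T + alpha * d_rate
            else:
                d_rate = T / gamma
                a_rate = alpha * d_rate
            _weighted_accumulate(donor, acceptor, a0, a1, dt, n_frames, d_rate, a_rate)

    if config.noise_sd > 0:
        donor += rng.normal(0.0, config.noise_sd, n_frames)
        acceptor += rng.normal(0.0, config.noise_sd, n_frames)

    return FluorescenceTrace(
        trace_id=truth.trace_id,
        frame_interval=dt,
        donor=donor,
        acceptor=acceptor,
        corrected=False,
        meta={"alpha": alpha, "gamma": gamma, "total_intensity": T},
    )


def _weighted_accumulate(
    donor: np.ndarray,
    acceptor: np.ndarray,
    t0: float,
    t1: float,
    dt: float,
    n_frames: int,
    d_rate: float,
    a_rate: float,
) -> None:
    t0 = max(t0, 0.0)
    t1 = min(t1, n_frames * dt)
    if t1 <= t0:
        return
    f0 = int(t0 / dt)
    f1 = min(int(np.ceil(t1 / dt)), n_frames)
    idx = np.arange(f0, f1)
    lo = np.maximum(t0, idx * dt)
    hi = np.minimum(t1, (idx + 1) * dt)
    w = (hi - lo) / dt
    donor[idx] += w * d_rate
    acceptor[idx] += w * a_rate


@dataclass
class TraceDataset:
    """A set of simulated traces with ground truth and full metadata."""

    traces: list[FluorescenceTrace]
    truths: list[GroundTruth]
    config: SimulationConfig
    model_name: str = ""
    concentration: float = 0.0

    @property
    def n_traces(self) -> int:
        return len(self.traces)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: trace_id, frame, time_s, donor, acceptor."""
        parts = []
        for t in self.traces:
            parts.append(
                pd.DataFrame(
                    {
                        "trace_id": t.trace_id,
                        "frame": np.arange(t.n_frames),
                        "time_s": t.times,
                        "donor": t.donor,
                        "acceptor": t.acceptor,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=["trace_id", "frame", "time_s", "donor", "acceptor"])
        return pd.concat(parts, ignore_index=True)

    def metadata(self) -> dict:
        return {
            "config": asdict(self.config),
            "model_name": self.model_name,
            "concentration_uM": self.concentration,
            "n_traces": self.n_traces,
        }


def simulate_dataset(
    model: DecodingModel,
    config: SimulationConfig,
    n_traces: int,
    concentration: float | None = None,
    start_state: str = "Unbound",
) -> TraceDataset:
    """Simulate a dataset of independently seeded traces.

    The master seed in ``config.seed`` is split into one child seed per
    trace via ``SeedSequence.spawn``, so datasets are bit-reproducible and
    any trace can be regenerated individually.
    """
    if n_traces < 0:
        raise ValueError("n_traces must be >= 0")
    conc = model.concentration if concentration is None else concentration
    children = np.random.SeedSequence(config.seed).spawn(max(n_traces, 1))
    traces: list[FluorescenceTrace] = []
    truths: list[GroundTruth] = []
    for i in range(n_traces):
        rng = np.random.Generator(np.random.PCG64(children[i]))
        trace_id = f"trace{i:05d}"
        path = sample_path(model, config.duration, rng, start_state, conc)
        means = _sample_state_means(model, rng, config)
        donor_bleach = (
            rng.exponential(1.0 / config.donor_bleach_rate)
            if config.donor_bleach_rate > 0
            else np.inf
        )
        acceptor_bleach = (
            rng.exponential(1.0 / config.acceptor_bleach_rate)
            if config.acceptor_bleach_rate > 0
            else np.inf
        )
        blinks = _blink_intervals(config.duration, config, rng)
        truth = GroundTruth(
            trace_id=trace_id,
            events=[(model.state_names[s], t0, t1) for s, t0, t1 in path],
            donor_bleach_time=donor_bleach,
            acceptor_bleach_time=acceptor_bleach,
            blinks=blinks,
            state_means=means,
            state_names=model.state_names,
        )
        traces.append(render_trace(path, truth, model, config, rng))
        truths.append(truth)
    return TraceDataset(
        traces=traces,
        truths=truths,
        config=config,
        model_name=model.name,
        concentration=conc,
    )


def simulate_titration(
    truth,
    concentrations: list[float],
    n_traces_per_conc: int,
    rng: np.random.Generator,
    classical_mean: float = 0.70,
    hybrid_mean: float = 0.30,
    fret_sd: float = 0.06,
    relax_rate: float = 2.0,
    frame_interval: float = 0.100,
    n_frames: int = 300,
) -> dict[float, pd.DataFrame]:
    """Simulate equilibrium two-state FRET datasets for an eIF5A titration.

    ``truth`` is a :class:`smdecode.kinetics.TitrationModel`; at each ligand
    concentration L the classical-state time fraction equals the isotherm
    value f_c(L).  Each trace is a two-state telegraph process
    (classical high-FRET / hybrid low-FRET) whose stationary classical
    occupancy is f_c, rendered directly at FRET level with Gaussian width
    ``fret_sd`` per frame.  Returns ``{L: DataFrame(trace_id, frame, fret)}``.
    """
    if len(concentrations) == 0:
        raise ValueError("concentrations list must not be empty")
    out: dict[float, pd.DataFrame] = {}
    for L in concentrations:
        fc = truth.fraction_classical(L)
        k_hc = relax_rate * fc          # hybrid -> classical
        k_ch = relax_rate * (1.0 - fc)  # classical -> hybrid
        states = _telegraph_frames(
            k_hc, k_ch, fc, n_traces_per_conc, n_frames, frame_interval, rng
        )
        means = np.where(states == 1, classical_mean, hybrid_mean)
        fret = np.clip(means + rng.normal(0.0, fret_sd, means.shape), 0.0, 1.0)
        out[L] = pd.DataFrame(
            {
                "trace_id": np.repeat(np.arange(n_traces_per_conc), n_frames),
                "frame": np.tile(np.arange(n_frames), n_traces_per_conc),
                "fret": fret.ravel(),
            }
        )
    return out


def _telegraph_frames(
    k_hc: float,
    k_ch: float,
    p_classical: float,
    n_traces: int,
    n_frames: int,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Frame-sampled two-state telegraph paths (1 = classical, 0 = hybrid).

    Uses the exact frame-to-frame transition probabilities of the two-state
    CTMC; all traces evolve in one vectorized sweep over frames.
    """
    ktot = k_hc + k_ch
    if ktot <= 0:
        return np.broadcast_to(
            (rng.random(n_traces) < p_classical).astype(int)[:, None],
            (n_traces, n_frames),
        ).copy()
    decay = np.exp(-ktot * dt)
    p_cc = p_classical + (1 - p_classical) * decay  # stay classical
    p_hh = (1 - p_classical) + p_classical * decay  # stay hybrid
    states = np.empty((n_traces, n_frames), dtype=np.int8)
    states[:, 0] = rng.random(n_traces) < p_classical
    u = rng.random((n_traces, n_frames))
    for f in range(1, n_frames):
        prev = states[:, f - 1]
        stay = np.where(prev == 1, p_cc, p_hh)
        states[:, f] = np.where(u[:, f] < stay, prev, 1 - prev)
    return states
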