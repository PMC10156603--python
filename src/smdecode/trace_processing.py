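"""Trace correction, FRET computation, photobleach/blink detection, selection.

Implements the standard single-molecule TIRF post-processing chain: raw
donor/acceptor intensity traces are corrected for spectral crosstalk and
gamma (detection-efficiency imbalance), converted to ratiometric FRET, and
screened by five selection criteria before idealization:

1. exactly one catastrophic photobleaching event,
2. signal/background-noise ratio >= 8,
3. signal/signal-noise ratio >= 6,
4. fewer than four donor blinking events,
5. donor--acceptor Pearson correlation < 0.5.

"Catastrophic" means a terminal drop of total intensity to background with
no recovery; transient excursions to background that recover are counted
as donor blinks.  Two strategies are provided for the signal/signal-noise
criterion (neither is defined by upstream imaging software publicly): the
default ``fret_separation`` strategy (mean separation of adjacent FRET
states over the pooled within-state frame FRET SD) and an ``intensity``
strategy (mean pre-bleach total intensity over its own SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "BleachEvent",
    "SelectionCriteria",
    "correct_trace",
    "compute_fret",
    "detect_bleach",
    "count_blinks",
    "detection_floor",
    "select_traces",
]


class TraceStateError(ValueError):
    """Raised when an operation is applied to a trace in the wrong state."""


@dataclass
class FluorescenceTrace:
    """Per-frame donor/acceptor intensities with acquisition metadata.

    ``corrected`` flags whether gamma/crosstalk correction has been applied;
    :func:`correct_trace` refuses to correct twice.
    """

    trace_id: str
    frame_interval: float
    donor: np.ndarray
    acceptor: np.ndarray
    corrected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise TraceStateError("donor and acceptor must be 1-D arrays of equal length")
        if self.frame_interval <= 0:
            raise TraceStateError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    @property
    def times(self) -> np.ndarray:
        """Frame-centre times in seconds."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval


@dataclass(frozen=True)
class BleachEvent:
    """A detected photobleaching step."""

    frame: int
    channel: str  # "donor" (catastrophic, total -> background) or "acceptor"


def correct_trace(trace: FluorescenceTrace, alpha: float, gamma: float) -> FluorescenceTrace:
    """Apply crosstalk and gamma correction to a raw trace.

    ``acceptor' = acceptor - alpha * donor`` removes donor emission leaking
    into the acceptor channel; ``donor' = gamma * donor`` equalizes the
    detection efficiencies so that FRET = A'/(A' + D').  Correcting an
    already-corrected trace raises :class:`TraceStateError`.
    """
    if trace.corrected:
        raise TraceStateError(f"trace {trace.trace_id!r} is already corrected")
    if gamma <= 0:
        raise TraceStateError("gamma must be > 0")
    acceptor = trace.acceptor - alpha * trace.donor
    donor = gamma * trace.donor
    meta = dict(trace.meta, correction={"alpha": alpha, "gamma": gamma})
    return replace(trace, donor=donor, acceptor=acceptor, corrected=True, meta=meta)


def _background_stats(trace: FluorescenceTrace, bleach: list[BleachEvent]) -> tuple[float, float]:
    """Mean and SD of total intensity in the post-catastrophic-bleach region.

    Falls back to a robust estimate from frame-to-frame differences when the
    trace never bleaches (no background window available).
    """
    total = trace.total
    cat = [b for b in bleach if b.channel == "donor"]
    if cat:
        tail = total[cat[0].frame:]
        if tail.size >= 5:
            return float(tail.mean()), float(tail.std(ddof=1))
    # robust fallback: sigma of the differenced series / sqrt(2), zero mean
    diffs = np.diff(total)
    sd = float(np.median(np.abs(diffs)) / (0.6744897501960817 * np.sqrt(2))) if diffs.size else 0.0
    return 0.0, sd


def detection_floor(trace: FluorescenceTrace, bleach: list[BleachEvent] | None = None) -> float:
    """Intensity floor below which a frame is treated as background.

    Defined as background mean + 4 x background SD of the total intensity,
    with the background estimated from post-bleach frames.  Shared by the
    FRET floor rule and by blink/event detection.
    """
    if bleach is None:
        bleach = detect_bleach(trace)
    mean, sd = _background_stats(trace, bleach)
    return mean + 4.0 * sd


def compute_fret(trace: FluorescenceTrace, floor: float | None = None) -> np.ndarray:
    """Ratiometric FRET efficiency series ``E = A / (A + D)`` in [0, 1].

    Frames whose total intensity falls below the detection floor (donor
    bleached or blinking) are assigned E = 0.
    """
    if not trace.corrected:
        raise TraceStateError("compute_fret requires a corrected trace")
    if floor is None:
        floor = detection_floor(trace)
    total = trace.total
    with np.errstate(divide="ignore", invalid="ignore"):
        fret = np.where(total > max(floor, 1e-12), trace.acceptor / total, 0.0)
    return np.clip(fret, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Change-point detection of photobleaching
# ---------------------------------------------------------------------------


def _best_step(x: np.ndarray) -> tuple[int, float]:
    """Best single change-point of a piecewise-constant fit to ``x``.

    Returns ``(index, gain)`` where the step is between ``index - 1`` and
    ``index`` and ``gain`` is the reduction in the sum of squared residuals
    relative to a constant fit.  O(n) via cumulative sums.
    """
    n = x.size
    if n < 2:
        return 0, 0.0
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(1, n)
    mean_l = csum[:-1] / k
    mean_r = (total - csum[:-1]) / (n - k)
    # SSE reduction of a two-segment fit vs one-segment fit
    gain = k * (n - k) / n * (mean_l - mean_r) ** 2
    i = int(np.argmax(gain))
    return i + 1, float(gain[i])


def detect_bleach(
    trace: FluorescenceTrace,
    min_drop_sigma: float = 4.0,
    max_events: int = 4,
) -> list[BleachEvent]:
    """Detect photobleaching steps by binary-segmentation change points.

    Catastrophic (donor) bleaching is a terminal step of the *total*
    intensity down to background with no recovery; acceptor bleaching is a
    step down of the acceptor channel while the total stays at signal level
    (FRET-sensitized emission returns to the donor).  Events are returned
    ordered by frame.  Requires >= 20 frames.
    """
    if trace.n_frames < 20:
        raise TraceStateError("detect_bleach requires at least 20 frames")
    total = trace.total
    noise = float(np.median(np.abs(np.diff(total))) / (0.6744897501960817 * np.sqrt(2)))
    noise = max(noise, 1e-9)

    events: list[BleachEvent] = []

    # --- binary segmentation of the total intensity into plateaus ---
    # min_size 2 keeps a bleach landing mid-frame (one partial frame) from
    # yielding duplicate steps while still isolating >= 2-frame blinks
    min_size = 2

    def _recurse(lo: int, hi: int, depth: int, out: list[int]) -> None:
        if depth == 0 or hi - lo < 2 * min_size:
            return
        idx, _ = _best_step(total[lo:hi])
        if idx < min_size or idx > (hi - lo) - min_size:
            return
        left = total[lo: lo + idx]
        right = total[lo + idx: hi]
        if abs(left.mean() - right.mean()) < min_drop_sigma * noise:
            return
        cp = lo + idx
        _recurse(lo, cp, depth - 1, out)
        out.append(cp)
        _recurse(cp, hi, depth - 1, out)

    cps: list[int] = []
    _recurse(0, total.size, max_events + 1, cps)
    cps = sorted(cps)

    # Interpret plateau structure: a catastrophic bleach step is a downward
    # step after which the signal never recovers; a dip that recovers is a
    # blink and is counted elsewhere.
    bounds = [0, *cps, total.size]
    levels = [total[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    cat_frames: list[int] = []
    for j in range(1, len(levels)):
        drop = levels[j - 1] - levels[j]
        if drop < min_drop_sigma * noise or drop < 0.4 * abs(levels[j - 1]):
            continue  # not a significant, fluorophore-scale step down
        recovery_level = levels[j] + 0.5 * drop
        if all(lv < recovery_level for lv in levels[j:]):
            cat_frames.append(bounds[j])
    events.extend(BleachEvent(f, "donor") for f in cat_frames[:max_events])

    # --- acceptor bleach within the pre-catastrophic region ---
    end = cat_frames[0] if cat_frames else total.size
    if end >= 8:
        acc = trace.acceptor[:end]
        idx, gain = _best_step(acc)
        if 0 < idx < acc.size:
            pre_a = acc[:idx].mean()
            post_a = acc[idx:].mean()
            total_post = total[idx:end].mean()
            noise_a = float(
                np.median(np.abs(np.diff(acc))) / (0.6744897501960817 * np.sqrt(2))
            ) if acc.size > 1 else noise
            noise_a = max(noise_a, 1e-9)
            if (
                pre_a - post_a > min_drop_sigma * noise_a
                and total_post > 0.5 * total[:end].mean()
                and post_a < 0.5 * pre_a
            ):
                events.append(BleachEvent(idx, "acceptor"))

    return sorted(events, key=lambda e: e.frame)


def analysis_end(trace: FluorescenceTrace, bleach: list[BleachEvent] | None = None) -> int:
    """Last frame (exclusive) usable for FRET analysis: the first bleach."""
    if bleach is None:
        bleach = detect_bleach(trace)
    if not bleach:
        return trace.n_frames
    return min(e.frame for e in bleach)


def count_blinks(
    trace: FluorescenceTrace,
    bleach: list[BleachEvent] | None = None,
    floor: float | None = None,
) -> int:
    """Count donor blinking events before the catastrophic bleach.

    A blink is a run (>= 1 frame) of total intensity at background that
    recovers to signal level before the catastrophic bleach.
    """
    if bleach is None:
        bleach = detect_bleach(trace)
    if floor is None:
        floor = detection_floor(trace, bleach)
    cat = [b.frame for b in bleach if b.channel == "donor"]
    end = cat[0] if cat else trace.n_frames
    total = trace.total[:end]
    below = total <= floor
    if below.size == 0:
        return 0
    # runs of below-floor frames that recover (i.e. do not touch the end)
    padded = np.concatenate([[False], below, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    n = 0
    for s, e in zip(starts, ends):
        if e < below.size:  # recovers before the bleach boundary
            n += 1
    return n


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionCriteria:
    """The five trace-selection thresholds.

    Defaults follow the standard criteria: a single catastrophic
    photobleaching event, signal/background-noise >= 8, signal/signal-noise
    >= 6, fewer than four donor blinks, and donor--acceptor correlation
    < 0.5.
    """

    max_bleach_events: int = 1
    min_snr_background: float = 8.0
    min_snr_signal: float = 6.0
    max_donor_blinks: int = 3
    max_da_correlation: float = 0.5
    snr_signal_strategy: str = "fret_separation"  # or "intensity"

    def __post_init__(self) -> None:
        if self.min_snr_background <= 0 or self.min_snr_signal <= 0:
            raise ValueError("SNR thresholds must be positive")
        if self.snr_signal_strategy not in ("fret_separation", "intensity"):
            raise ValueError(f"unknown snr_signal_strategy {self.snr_signal_strategy!r}")


def _snr_background(trace: FluorescenceTrace, cat_frame: int) -> float:
    pre = trace.total[:cat_frame]
    post = trace.total[cat_frame:]
    if pre.size == 0 or post.size < 2:
        return np.inf
    sd = post.std(ddof=1)
    return float(pre.mean() / sd) if sd > 0 else np.inf


def _snr_signal_intensity(trace: FluorescenceTrace, cat_frame: int) -> float:
    pre = trace.total[:cat_frame]
    if pre.size < 2:
        return np.inf
    sd = pre.std(ddof=1)
    return float(pre.mean() / sd) if sd > 0 else np.inf


def _snr_signal_fret(fret: np.ndarray, floor_mask: np.ndarray) -> float:
    """Mean adjacent FRET-state separation over pooled within-state width.

    The above-floor FRET values are histogrammed, modes are located as
    smoothed local maxima, each value is assigned to its nearest mode, and
    the within-mode width is a robust (MAD-based) SD so that the minority
    of transition-smeared frames between states does not inflate it.  This
    is a screening statistic, not an idealization.
    """
    vals = fret[floor_mask]
    # the statistic concerns FRET signal states: drop the zero-FRET mode
    # (unbound frames, donor-only emission) before locating modes
    vals = vals[vals > 0.15]
    if vals.size < 20:
        return np.inf
    edges = np.linspace(0.0, 1.0, 51)
    hist, _ = np.histogram(vals, bins=edges)
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(hist, kernel / kernel.sum(), mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = [
        i
        for i in range(1, smooth.size - 1)
        if smooth[i] >= smooth[i - 1]
        and smooth[i] > smooth[i + 1]
        and smooth[i] >= 0.05 * smooth.max()
    ]
    if len(peaks) < 2:
        return np.inf  # effectively single-state: criterion not informative
    modes = centers[np.array(peaks)]
    sep = float(np.mean(np.diff(np.sort(modes))))
    assign = np.argmin(np.abs(vals[:, None] - modes[None, :]), axis=1)
    widths, ns = [], []
    for m in range(modes.size):
        grp = vals[assign == m]
        if grp.size >= 5:
            widths.append(1.4826 * np.median(np.abs(grp - np.median(grp))))
            ns.append(grp.size)
    if not widths:
        return np.inf
    pooled = float(np.sqrt(np.average(np.square(widths), weights=ns)))
    return sep / pooled if pooled > 0 else np.inf


def evaluate_trace(
    trace: FluorescenceTrace, criteria: SelectionCriteria | None = None
) -> dict:
    """Evaluate the five selection criteria on a corrected trace.

    Returns a dict with the per-criterion statistics, ``accepted`` and the
    first failed criterion under ``reason`` (empty string if accepted).
    """
    if criteria is None:
        criteria = SelectionCriteria()
    if not trace.corrected:
        raise TraceStateError("selection operates on corrected traces")
    bleach = detect_bleach(trace)
    cat = [b.frame for b in bleach if b.channel == "donor"]
    n_cat = len(cat)
    cat_frame = cat[0] if cat else trace.n_frames
    floor = detection_floor(trace, bleach)
    fret = compute_fret(trace, floor=floor)
    pre = slice(0, cat_frame)
    above = trace.total[pre] > floor

    snr_bg = _snr_background(trace, cat_frame)
    if criteria.snr_signal_strategy == "intensity":
        snr_sig = _snr_signal_intensity(trace, cat_frame)
    else:
        snr_sig = _snr_signal_fret(fret[pre], above)
    n_blinks = count_blinks(trace, bleach, floor)
    d, a = trace.donor[pre], trace.acceptor[pre]
    if d.size > 2 and d.std() > 0 and a.std() > 0:
        corr = float(np.corrcoef(d, a)[0, 1])
    else:
        corr = 0.0

    reason = ""
    if n_cat != 1:
        reason = "multiple bleach events" if n_cat > 1 else "no catastrophic bleach"
    elif snr_bg < criteria.min_snr_background:
        reason = "low signal/background-noise"
    elif snr_sig < criteria.min_snr_signal:
        reason = "low signal/signal-noise"
    elif n_blinks > criteria.max_donor_blinks:
        reason = "too many donor blinks"
    elif corr >= criteria.max_da_correlation:
        reason = "donor-acceptor correlation too high"

    return {
        "trace_id": trace.trace_id,
        "accepted": reason == "",
        "reason": reason,
        "n_bleach_events": n_cat,
        "bleach_frame": cat_frame if n_cat else -1,
        "snr_bg": snr_bg,
        "snr_signal": snr_sig,
        "n_blinks": n_blinks,
        "da_corr": corr,
    }


def select_traces(
    traces: list[FluorescenceTrace], criteria: SelectionCriteria | None = None
) -> tuple[list[FluorescenceTrace], pd.DataFrame]:
    """Apply the five selection criteria to a dataset of corrected traces.

    Returns the accepted traces and a per-trace report (one row per input
    trace, with the first failed criterion as the rejection reason).
    Selection is deterministic and independent of dataset order.
    """
    rows = [evaluate_trace(t, criteria) for t in traces]
    report = pd.DataFrame(rows)
    accepted_ids = set(report.loc[report["accepted"], "trace_id"])
    accepted = [t for t in traces if t.trace_id in accepted_ids]
    return accepted, report
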