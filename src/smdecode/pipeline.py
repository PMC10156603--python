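"""End-to-end processing: correct -> select -> idealize -> dwells/events.

Glue between the modules: applies gamma/crosstalk correction, runs the
five-criterion selection, truncates every accepted trace at its first
photobleaching event, idealizes the FRET series by segmental k-means and
extracts dwell records and binding events.  The result object carries
everything the rate estimators in :mod:`smdecode.kinetics` consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from smdecode import trace_processing as tp
from smdecode.idealize import DwellRecord, HmmSpec, Idealization, extract_dwells, idealize_traces
from smdecode.kinetics import BindingEvent, detect_binding_events
from smdecode.simulate import TraceDataset

__all__ = ["ProcessedDataset", "process_dataset"]


@dataclass
class ProcessedDataset:
    """Corrected, selected and idealized traces plus derived quantities."""

    trace_ids: list[str]
    frame_interval: float
    fret: list[np.ndarray]             # pre-bleach FRET series per trace
    ideals: list[Idealization]
    dwells: list[DwellRecord]
    events: list[list[BindingEvent]]   # threshold-crossing binding events
    fret_threshold: float              # background noise threshold on FRET
    report: pd.DataFrame               # selection report (all input traces)
    dark: list[np.ndarray] = field(default_factory=list)  # donor-dark frames
    n_input: int = 0
    concentration: float = 0.0

    @property
    def n_traces(self) -> int:
        return len(self.trace_ids)

    def population_means(self, min_frames: int = 5) -> np.ndarray:
        """Occupancy-weighted population mean FRET per state.

        Averages the per-trace refined emission means over traces, weighting
        each trace by its frame occupancy of the state (traces whose
        idealization never visits a state do not contribute to it).
        """
        k = self.ideals[0].means.size
        num = np.zeros(k)
        den = np.zeros(k)
        for ideal in self.ideals:
            w = np.where(ideal.occupancy >= min_frames, ideal.occupancy, 0.0)
            num += w * ideal.means
            den += w
        with np.errstate(invalid="ignore"):
            return num / den

    def state_fret_statistics(self, min_dwell_frames: int = 3) -> pd.DataFrame:
        """Robust per-state FRET means from dwell-interior frames.

        Frame integration contaminates the first and last frame of every
        dwell with the neighbouring states, so only interior frames of
        dwells of at least ``min_dwell_frames`` frames are used.  Each
        trace contributes one mean per state it visits; the population
        value is the across-trace median (robust to the occasional trace
        whose state labelling is distorted by molecule-specific offsets),
        with a MAD-based standard error.
        """
        k = self.ideals[0].means.size
        per_trace: list[list[float]] = [[] for _ in range(k)]
        for ideal, fret in zip(self.ideals, self.fret):
            sums = np.zeros(k)
            ns = np.zeros(k)
            for d in extract_dwells(ideal):
                if d.n_frames >= min_dwell_frames:
                    seg = fret[d.start_frame + 1: d.start_frame + d.n_frames - 1]
                    sums[d.state] += seg.sum()
                    ns[d.state] += seg.size
            for s in range(k):
                if ns[s] >= max(min_dwell_frames - 2, 1):
                    per_trace[s].append(sums[s] / ns[s])
        rows = []
        for s in range(k):
            v = np.array(per_trace[s])
            if v.size == 0:
                rows.append({"state": s, "fret_mean": np.nan, "se": np.nan, "n_traces": 0})
                continue
            med = float(np.median(v))
            mad_sd = 1.4826 * float(np.median(np.abs(v - med)))
            rows.append(
                {
                    "state": s,
                    "fret_mean": med,
                    "se": 1.2533 * mad_sd / np.sqrt(v.size),
                    "n_traces": int(v.size),
                }
            )
        return pd.DataFrame(rows)

    def zero_dwell_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled zero-state dwells between retained events + trace ids.

        A gap containing donor-dark frames (total intensity at background:
        a blink, not genuine unbound residence) is discarded -- the
        zero-FRET reading there does not report on ternary-complex binding.
        """
        from smdecode.kinetics import zero_state_dwells

        dwell_list, tid_list = [], []
        for m, (tid, ev) in enumerate(zip(self.trace_ids, self.events)):
            kept = [e for e in ev if not (e.is_first or e.is_last)]
            gaps = []
            dark = self.dark[m] if self.dark else None
            for a, b in zip(kept[:-1], kept[1:]):
                if b.start_frame <= a.end_frame:
                    continue
                if dark is not None and dark[a.end_frame: b.start_frame].any():
                    continue
                gaps.append((b.start_frame - a.end_frame) * self.frame_interval)
            z = np.asarray(gaps)
            dwell_list.append(z)
            tid_list.append(np.full(z.size, tid, dtype=object))
        dwells = np.concatenate(dwell_list) if dwell_list else np.array([])
        tids = np.concatenate(tid_list) if tid_list else np.array([])
        return dwells, tids

    def arrival_times(self, ac_state: int) -> tuple[np.ndarray, np.ndarray]:
        """(arrivals, censored): waiting time from trace start to the first
        visit of ``ac_state``; traces that never arrive contribute their
        observation end as a censoring time."""
        arr, cens = [], []
        for ideal in self.ideals:
            hits = np.flatnonzero(ideal.path == ac_state)
            if hits.size:
                arr.append(hits[0] * self.frame_interval)
            else:
                cens.append(ideal.n_frames * self.frame_interval)
        return np.array(arr), np.array(cens)

    def passage_times(self, ac_state: int) -> np.ndarray:
        """Time from the start of the binding event directly preceding the
        first accommodation to the accommodation event itself."""
        out = []
        for ideal, ev in zip(self.ideals, self.events):
            hits = np.flatnonzero(ideal.path == ac_state)
            if hits.size == 0:
                continue
            t_ac = hits[0]
            containing = [e for e in ev if e.start_frame <= t_ac]
            if not containing:
                continue
            start = containing[-1].start_frame
            if t_ac >= start:
                out.append((t_ac - start) * self.frame_interval)
        return np.array(out)


def _zero_fret_sigma(trace: tp.FluorescenceTrace, path: np.ndarray, floor: float) -> float:
    """Frame FRET SD in the zero-FRET state, from the unclipped A/(A+D) ratio."""
    total = trace.total[: path.size]
    mask = (path == 0) & (total > floor)
    if mask.sum() < 10:
        return np.nan
    ratio = trace.acceptor[: path.size][mask] / total[mask]
    return float(ratio.std(ddof=1))


def process_dataset(
    dataset: TraceDataset,
    criteria: tp.SelectionCriteria | None = None,
    hmm_spec: HmmSpec | None = None,
    alpha: float | None = None,
    gamma: float | None = None,
    select: bool = True,
    threshold_sigmas: float = 4.0,
) -> ProcessedDataset:
    """Run the full processing chain on a simulated (or loaded) dataset.

    The FRET background-noise threshold shared by event detection is
    ``threshold_sigmas`` times the zero-state frame FRET SD (median over
    traces), mirroring the intensity detection-floor rule.
    """
    cfg = dataset.config
    a = cfg.crosstalk_alpha if alpha is None else alpha
    g = cfg.gamma if gamma is None else gamma
    corrected = [tp.correct_trace(t, a, g) for t in dataset.traces]

    if select:
        accepted, report = tp.select_traces(corrected, criteria)
    else:
        accepted = corrected
        report = pd.DataFrame(
            {"trace_id": [t.trace_id for t in corrected], "accepted": True, "reason": ""}
        )

    fret_list: list[np.ndarray] = []
    floors: list[float] = []
    dark_list: list[np.ndarray] = []
    kept: list[tp.FluorescenceTrace] = []
    for tr in accepted:
        bleach = tp.detect_bleach(tr)
        end = tp.analysis_end(tr, bleach)
        if end < 10:
            continue
        floor = tp.detection_floor(tr, bleach)
        fret_list.append(tp.compute_fret(tr, floor=floor)[:end])
        floors.append(floor)
        dark_list.append(tr.total[:end] < floor)
        kept.append(tr)

    if hmm_spec is None:
        raise ValueError("an HmmSpec is required (use HmmSpec.from_model(model))")
    ids = [t.trace_id for t in kept]
    ideals = idealize_traces(fret_list, hmm_spec, cfg.frame_interval, ids)

    sigmas = [
        _zero_fret_sigma(tr, ideal.path, fl)
        for tr, ideal, fl in zip(kept, ideals, floors)
    ]
    sigma0 = float(np.nanmedian(sigmas)) if np.isfinite(np.nanmedian(sigmas)) else 0.02
    fret_threshold = threshold_sigmas * sigma0

    dwells: list[DwellRecord] = []
    for ideal in ideals:
        dwells.extend(extract_dwells(ideal))
    # events must clear 1.5x the threshold at their peak: suppresses
    # single-frame noise crossings that would split zero-state dwells
    events = [
        detect_binding_events(f, fret_threshold, min_peak=1.5 * fret_threshold)
        for f in fret_list
    ]

    return ProcessedDataset(
        trace_ids=ids,
        frame_interval=cfg.frame_interval,
        fret=fret_list,
        ideals=ideals,
        dwells=dwells,
        events=events,
        fret_threshold=fret_threshold,
        report=report,
        dark=dark_list,
        n_input=dataset.n_traces,
        concentration=dataset.concentration,
    )
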