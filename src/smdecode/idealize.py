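"""Segmental k-means (SKM) HMM idealization of FRET traces.

The idealizer alternates Viterbi decoding under Gaussian emissions with
re-estimation of the emission means/SDs and transition frequencies from
the decoded segmentation, until the decoded path likelihood stops
improving.  It is deterministic: ties in the Viterbi maximization are
broken toward the lower state index, and no random initialization is used
(states start at the spec's FRET means).

Emission parameters are refined *per trace* (molecule-to-molecule static
heterogeneity shifts the apparent state means), while the state inventory
is fixed by the spec -- a four-state decode (zero-FRET unbound state plus
CR/GA/AC) for the tRNA--tRNA perspective, three states for the uL11
perspective.  Dwells are extracted by run-length encoding with censoring
flags: the first and last events of every trace touch the trace start or
the photobleach/trace end and are flagged accordingly.

Rate optimization is intentionally *not* done inside the HMM; dwell-based
censoring-aware estimators live in :mod:`smdecode.kinetics`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from smdecode.kinetic_model import DecodingModel

__all__ = [
    "HmmSpec",
    "Idealization",
    "DwellRecord",
    "skm_idealize",
    "idealize_traces",
    "extract_dwells",
    "transition_density",
    "postsynchronize",
    "population_histogram",
]

_SD_FLOOR = 0.01  # FRET; prevents emission collapse onto single frames


@dataclass(frozen=True)
class HmmSpec:
    """Initial emission parameters and convergence settings for SKM.

    ``states`` lists (initial mean, initial SD) pairs, ordered by mean and
    including the zero-FRET unbound state.  Convergence is declared when
    the relative improvement of the decoded-path log-likelihood falls
    below ``tol`` (default 1e-4, at most ``max_iterations`` = 100 sweeps).

    ``mean_prior_strength`` regularizes the per-trace mean re-estimation
    toward the initial means with the weight of that many pseudo-frames;
    it anchors sparsely occupied states (a handful of codon-recognition
    frames must not drag that state onto transition-smeared values) while
    leaving well-occupied states free to follow the trace.
    """

    states: tuple[tuple[float, float], ...]
    max_iterations: int = 100
    tol: float = 1e-4
    mean_prior_strength: float = 10.0

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("an HMM spec needs at least 2 states")
        means = [m for m, _ in self.states]
        if len(set(means)) != len(means):
            raise ValueError(f"initial state means must be distinct, got {means}")

    @classmethod
    def from_model(cls, model: DecodingModel, **kwargs) -> "HmmSpec":
        return cls(
            states=tuple(
                (s.fret_mean, max(s.fret_sd, 0.03)) for s in model.states
            ),
            **kwargs,
        )

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass
class Idealization:
    """A decoded state path with refined per-trace emission parameters."""

    trace_id: str
    frame_interval: float
    path: np.ndarray          # state index per frame
    means: np.ndarray         # refined emission means, per state
    sds: np.ndarray           # refined emission SDs, per state
    log_likelihood: float
    n_iterations: int = 0
    occupancy: np.ndarray = field(default=None)  # frames per state

    @property
    def n_frames(self) -> int:
        return self.path.size

    def fitted_fret(self) -> np.ndarray:
        """The idealized FRET series (refined mean of the assigned state)."""
        return self.means[self.path]


@dataclass(frozen=True)
class DwellRecord:
    """One residence event in a hidden state.

    ``left_censored`` marks events touching the trace start; the trace end
    (or the photobleach cut, which truncates the analyzed series) marks
    ``right_censored``.  Durations are integer frame counts times the
    frame interval.
    """

    trace_id: str
    state: int
    start_frame: int
    n_frames: int
    duration: float
    left_censored: bool
    right_censored: bool


# ---------------------------------------------------------------------------
# Batched SKM engine
# ---------------------------------------------------------------------------


def _initial_transitions(k: int, p_stay: float = 0.95) -> np.ndarray:
    A = np.full((k, k), (1.0 - p_stay) / (k - 1))
    np.fill_diagonal(A, p_stay)
    return A


def _viterbi_batch(
    x: np.ndarray,
    lengths: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    logA: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Viterbi decode of a padded batch of traces.

    Parameters are per trace: ``means``/``sds`` have shape (n, k), ``logA``
    (n, k, k).  ``x`` is (n, max_len) with NaN padding.  Ties break toward
    the lower state index (argmax returns the first maximum).  Returns the
    decoded paths (n, max_len; valid up to each trace's length) and the
    decoded-path log-likelihood per trace.
    """
    n, max_len = x.shape
    k = means.shape[1]
    ptr = np.zeros((n, max_len, k), dtype=np.int8)
    # uniform initial state distribution
    delta = _emission_loglik(x[:, 0], means, sds) - np.log(k)
    final_delta = np.zeros((n, k))
    done = lengths == 1
    if done.any():
        final_delta[done] = delta[done]
    for f in range(1, max_len):
        cand = delta[:, :, None] + logA  # (n, from, to)
        best_from = cand.argmax(axis=1)  # (n, to), first max = lower index
        delta = np.take_along_axis(cand, best_from[:, None, :], axis=1)[:, 0, :]
        delta = delta + _emission_loglik(x[:, f], means, sds)
        ptr[:, f, :] = best_from
        at_end = lengths - 1 == f
        if at_end.any():
            final_delta[at_end] = delta[at_end]
    paths = np.zeros((n, max_len), dtype=np.int8)
    state = final_delta.argmax(axis=1)
    loglik = final_delta.max(axis=1)
    idx = np.arange(n)
    # backtrack from each trace's own last frame
    last = lengths - 1
    paths[idx, last] = state
    for f in range(max_len - 1, 0, -1):
        # only traces whose length exceeds f step backwards through frame f
        step = last >= f
        prev_state = ptr[idx[step], f, paths[idx[step], f]]
        paths[idx[step], f - 1] = prev_state
    return paths, loglik


def _emission_loglik(xf: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Gaussian log-density of one frame column against per-trace params."""
    z = (xf[:, None] - means) / sds
    ll = -0.5 * z * z - np.log(sds)
    return np.where(np.isnan(xf)[:, None], 0.0, ll)


def idealize_traces(
    fret_series: list[np.ndarray],
    spec: HmmSpec,
    frame_interval: float,
    trace_ids: list[str] | None = None,
) -> list[Idealization]:
    """SKM-idealize a batch of FRET series (shared spec, per-trace refinement).

    All traces are decoded together in padded arrays for speed; results are
    identical to decoding each trace alone.
    """
    n = len(fret_series)
    if n == 0:
        return []
    if trace_ids is None:
        trace_ids = [f"trace{i:05d}" for i in range(n)]
    k = spec.n_states
    lengths = np.array([len(s) for s in fret_series])
    if (lengths < 1).any():
        raise ValueError("empty FRET series cannot be idealized")
    max_len = int(lengths.max())
    x = np.full((n, max_len), np.nan)
    for i, s in enumerate(fret_series):
        x[i, : lengths[i]] = s

    means = np.tile([m for m, _ in spec.states], (n, 1)).astype(float)
    sds = np.tile([max(sd, _SD_FLOOR) for _, sd in spec.states], (n, 1)).astype(float)
    logA = np.log(np.tile(_initial_transitions(k), (n, 1, 1)))

    valid = ~np.isnan(x)
    trace_of_frame = np.broadcast_to(np.arange(n)[:, None], x.shape)

    prev_ll = np.full(n, -np.inf)
    paths = None
    n_iter = 0
    for n_iter in range(1, spec.max_iterations + 1):
        paths, ll = _viterbi_batch(x, lengths, means, sds, logA)

        # --- re-estimate per-trace emissions from the segmentation ---
        flat_idx = trace_of_frame[valid] * k + paths[valid]
        counts = np.bincount(flat_idx, minlength=n * k).reshape(n, k)
        sums = np.bincount(flat_idx, weights=x[valid], minlength=n * k).reshape(n, k)
        kappa = spec.mean_prior_strength
        m0 = np.array([m for m, _ in spec.states])
        new_means = (sums + kappa * m0) / (counts + kappa)
        sq = np.bincount(
            flat_idx, weights=x[valid] ** 2, minlength=n * k
        ).reshape(n, k)
        with np.errstate(invalid="ignore"):
            var = sq / counts - (sums / np.maximum(counts, 1)) ** 2
        means = np.clip(new_means, 0.0, 1.0)
        sds = np.where(
            counts > 1, np.sqrt(np.clip(var, _SD_FLOOR**2, None)), sds
        )

        # --- re-estimate per-trace transition frequencies ---
        pair_valid = valid[:, 1:] & valid[:, :-1]
        ti = trace_of_frame[:, 1:][pair_valid]
        a = paths[:, :-1][pair_valid].astype(int)
        b = paths[:, 1:][pair_valid].astype(int)
        tc = np.bincount(
            (ti * k + a) * k + b, minlength=n * k * k
        ).reshape(n, k, k).astype(float)
        tc += 0.1  # pseudocount keeps rarely used transitions decodable
        logA = np.log(tc / tc.sum(axis=2, keepdims=True))

        rel = np.abs(ll - prev_ll) / np.maximum(np.abs(ll), 1.0)
        prev_ll = ll
        if np.all(rel < spec.tol):
            break

    out = []
    flat_idx = trace_of_frame[valid] * k + paths[valid]
    counts = np.bincount(flat_idx, minlength=n * k).reshape(n, k)
    n_single = int(((counts > 0).sum(axis=1) <= 1).sum())
    if n_single and k > 1:
        warnings.warn(
            f"{n_single}/{n} traces converged to a single occupied state",
            stacklevel=2,
        )
    for i in range(n):
        occ = counts[i]
        out.append(
            Idealization(
                trace_id=trace_ids[i],
                frame_interval=frame_interval,
                path=paths[i, : lengths[i]].astype(int).copy(),
                means=means[i].copy(),
                sds=sds[i].copy(),
                log_likelihood=float(prev_ll[i]),
                n_iterations=n_iter,
                occupancy=occ.copy(),
            )
        )
    return out


def skm_idealize(
    fret_series: np.ndarray,
    spec: HmmSpec,
    frame_interval: float = 0.010,
    trace_id: str = "trace",
) -> Idealization:
    """SKM-idealize a single FRET series (see :func:`idealize_traces`)."""
    return idealize_traces([np.asarray(fret_series, dtype=float)], spec, frame_interval, [trace_id])[0]


# ---------------------------------------------------------------------------
# Dwells, transition density, post-synchronization, histograms
# ---------------------------------------------------------------------------


def extract_dwells(ideal: Idealization, frame_interval: float | None = None) -> list[DwellRecord]:
    """Run-length encode an idealized path into dwell records.

    The first and last events of the trace are censored by construction
    (they abut the trace start and the photobleach/trace end).  One-frame
    dwells are retained.
    """
    dt = ideal.frame_interval if frame_interval is None else frame_interval
    path = ideal.path
    if path.size == 0:
        return []
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [path.size]])
    records = []
    for j, (s, e) in enumerate(zip(starts, ends)):
        records.append(
            DwellRecord(
                trace_id=ideal.trace_id,
                state=int(path[s]),
                start_frame=int(s),
                n_frames=int(e - s),
                duration=float((e - s) * dt),
                left_censored=j == 0,
                right_censored=j == len(starts) - 1,
            )
        )
    return records


def dwells_to_frame(dwells: list[DwellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trace_id": [d.trace_id for d in dwells],
            "state": [d.state for d in dwells],
            "start_frame": [d.start_frame for d in dwells],
            "duration_s": [d.duration for d in dwells],
            "left_censored": [d.left_censored for d in dwells],
            "right_censored": [d.right_censored for d in dwells],
        }
    )


def transition_density(
    idealizations: list[Idealization],
    bins: int = 40,
    fret_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Transition density plot: 2-D histogram of FRET before vs after.

    Each state-change event contributes one count at (refined mean of the
    departing state, refined mean of the arriving state).  Self transitions
    are excluded by construction.  Returns (histogram, bin edges,
    transitions per trace).
    """
    if len(idealizations) == 0:
        raise ValueError("transition_density needs at least one idealized trace")
    before, after = [], []
    for ideal in idealizations:
        p = ideal.path
        change = np.flatnonzero(np.diff(p))
        before.append(ideal.means[p[change]])
        after.append(ideal.means[p[change + 1]])
    edges = np.linspace(*fret_range, bins + 1)
    if before and sum(len(b) for b in before):
        b = np.concatenate(before)
        a = np.concatenate(after)
        hist, _, _ = np.histogram2d(b, a, bins=[edges, edges])
        per_trace = b.size / len(idealizations)
    else:
        hist = np.zeros((bins, bins))
        per_trace = 0.0
    return hist, edges, per_trace


def n_transitions(idealizations: list[Idealization]) -> int:
    return int(sum(np.count_nonzero(np.diff(i.path)) for i in idealizations))


def postsynchronize(
    fret_series: list[np.ndarray],
    idealizations: list[Idealization],
    sync_state: int | None,
    window: tuple[int, int] = (-5, 45),
    first_nonzero: bool = False,
    zero_state: int = 0,
) -> tuple[np.ndarray, int]:
    """Align traces at the first arrival in ``sync_state`` and truncate.

    The output matrix has one row per synchronizable trace and
    ``window[1] - window[0] + 1`` columns (default 5 frames before to 45
    frames after the event); frames outside the recorded trace are NaN.
    With ``first_nonzero=True`` the alignment point is the first frame
    assigned to any non-zero-FRET state.  Returns (matrix, n_excluded).
    """
    lo, hi = window
    width = hi - lo + 1
    rows = []
    excluded = 0
    for fret, ideal in zip(fret_series, idealizations):
        p = ideal.path
        if first_nonzero:
            hits = np.flatnonzero(p != zero_state)
        else:
            hits = np.flatnonzero(p == sync_state)
        if hits.size == 0:
            excluded += 1
            continue
        t0 = int(hits[0])
        row = np.full(width, np.nan)
        src_lo = max(t0 + lo, 0)
        src_hi = min(t0 + hi + 1, len(fret))
        row[src_lo - (t0 + lo): src_hi - (t0 + lo)] = fret[src_lo:src_hi]
        rows.append(row)
    matrix = np.vstack(rows) if rows else np.empty((0, width))
    return matrix, excluded


def population_histogram(
    fret_series: list[np.ndarray],
    frame_interval: float,
    time_range: tuple[float, float] | None = None,
    fret_bins: int = 40,
    fret_range: tuple[float, float] = (-0.1, 1.1),
) -> dict:
    """Time-resolved population histogram of FRET values.

    Counts frames per (time bin = frame, FRET bin); also reports how many
    traces contribute at each frame and a column-normalized view.
    """
    max_len = max((len(s) for s in fret_series), default=0)
    if time_range is not None:
        max_len = min(max_len, int(np.ceil(time_range[1] / frame_interval)))
    edges = np.linspace(*fret_range, fret_bins + 1)
    counts = np.zeros((max_len, fret_bins))
    per_frame = np.zeros(max_len, dtype=int)
    for s in fret_series:
        m = min(len(s), max_len)
        if m == 0:
            continue
        per_frame[:m] += 1
        frames = np.arange(m)
        bins_idx = np.clip(np.digitize(s[:m], edges) - 1, 0, fret_bins - 1)
        np.add.at(counts, (frames, bins_idx), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = counts / counts.sum(axis=1, keepdims=True)
    return {
        "counts": counts,
        "normalized": np.nan_to_num(normalized),
        "fret_edges": edges,
        "times": (np.arange(max_len) + 0.5) * frame_interval,
        "traces_per_frame": per_frame,
    }
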