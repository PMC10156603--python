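"""Dwell-time and arrival-time rate estimators and the eIF5A isotherm.

Every kinetic quantity reported by the pipeline is estimated here:

* **association rate** -- single-exponential fit to the cumulative
  distribution of zero-FRET dwell times between binding events, divided by
  the ternary-complex concentration (uM^-1 s^-1);
* **catalytic efficiency** -- two-exponential-with-delay fit to the
  cumulative distribution of waiting times from trace start to the first
  accommodated-state visit; efficiency = 1 / (mean arrival x concentration);
* **passage rate** -- two-exponential fit to the time from the last
  binding event preceding accommodation to the accommodation event itself;
* **state lifetimes** -- exponential maximum likelihood on dwell records,
  either excluding censored dwells or using the censoring-aware MLE
  (total observed time / number of observed terminations);
* **transition rates** -- the continuous-time Markov MLE
  (number of i->j transitions) / (total time in i) from idealized paths;
* the **two-conformation binding isotherm** for eIF5A titrations,
  f_c(L) = A_C5A (K_D + L) / (L + K_D A_C5A / A_Capo), fitted by weighted
  least squares with bootstrap confidence intervals.

Cumulative-distribution fits are least squares on the empirical CDF
evaluated at the event times (never on binned histograms).  The "mean" of
a multi-exponential fit is the amplitude-weighted mean of its components
plus the delay.  All confidence intervals are percentile bootstrap
(default 1000 resamples over traces, fixed seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from smdecode.idealize import DwellRecord, Idealization

__all__ = [
    "RateEstimate",
    "TitrationModel",
    "BindingIsotherm",
    "ExponentialCdf",
    "detect_binding_events",
    "zero_state_dwells",
    "association_rate",
    "catalytic_efficiency",
    "passage_rate",
    "state_lifetime",
    "transition_rate",
    "classical_fraction",
    "fit_titration",
]

MIN_EVENTS = 30


class FitError(RuntimeError):
    """Raised when an estimator cannot produce a meaningful fit."""


@dataclass
class RateEstimate:
    """A fitted kinetic quantity with uncertainty.

    ``value`` is the point estimate in ``units`` (s^-1, uM^-1 s^-1 or s);
    ``ci`` the percentile-bootstrap confidence interval, ``params`` the
    underlying fit parameters (amplitudes sum to 1 for multi-exponential
    models).
    """

    label: str
    value: float
    units: str
    fit_model: str
    params: dict = field(default_factory=dict)
    ci: tuple[float, float] | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if self.ci is not None and not (self.ci[0] <= self.value <= self.ci[1]):
            warnings.warn(
                f"{self.label}: point estimate {self.value:.4g} outside CI {self.ci}",
                stacklevel=2,
            )

    def summary(self) -> str:
        lines = [
            f"{self.label}: {self.value:.4g} {self.units} "
            f"(n = {self.n}, model = {self.fit_model})"
        ]
        if self.ci is not None:
            lines.append(f"  95% CI [{self.ci[0]:.4g}, {self.ci[1]:.4g}]")
        for k, v in self.params.items():
            lines.append(f"  {k} = {v:.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Event detection on FRET series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingEvent:
    start_frame: int
    end_frame: int  # exclusive
    is_first: bool
    is_last: bool


def detect_binding_events(
    fret: np.ndarray, threshold: float, min_peak: float | None = None
) -> list[BindingEvent]:
    """Maximal intervals of the FRET series above the noise threshold.

    The first and last events of a trace are flagged: they are excluded
    from dwell bookkeeping to minimize the influence of mixing time and
    photobleaching kinetics.  ``min_peak`` additionally requires an event
    to reach that FRET value at least once: with a 4-sigma threshold a
    long trace still produces occasional single-frame noise crossings that
    would spuriously split zero-state dwells, while genuine events carry
    at least partial codon-recognition amplitude.
    """
    fret = np.asarray(fret)
    above = fret > threshold
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    intervals = [
        (int(s), int(e)) for s, e in zip(starts, ends)
        if min_peak is None or fret[s:e].max() >= min_peak
    ]
    n = len(intervals)
    return [
        BindingEvent(s, e, i == 0, i == n - 1)
        for i, (s, e) in enumerate(intervals)
    ]


def zero_state_dwells(
    events: list[BindingEvent], frame_interval: float
) -> np.ndarray:
    """Zero-FRET dwell times between retained binding events (seconds).

    First and last events are eliminated, so the dwells are the gaps
    between consecutive events of the interior event sequence; both ends
    of each retained gap are genuine detected transitions.
    """
    kept = [e for e in events if not (e.is_first or e.is_last)]
    if len(kept) < 2:
        return np.array([])
    gaps = [
        (b.start_frame - a.end_frame) * frame_interval
        for a, b in zip(kept[:-1], kept[1:])
    ]
    return np.array([g for g in gaps if g > 0])


# ---------------------------------------------------------------------------
# Exponential CDF fitting (statsmodels-style model object)
# ---------------------------------------------------------------------------


def _cdf_single(t, k):
    return 1.0 - np.exp(-k * t)


def _cdf_single_delay(t, k, t0):
    return np.where(t > t0, 1.0 - np.exp(-k * (t - t0)), 0.0)


def _cdf_double(t, a, k1, k2):
    return 1.0 - (a * np.exp(-k1 * t) + (1 - a) * np.exp(-k2 * t))


def _cdf_double_delay(t, a, k1, k2, t0):
    tt = np.clip(t - t0, 0.0, None)
    return 1.0 - (a * np.exp(-k1 * tt) + (1 - a) * np.exp(-k2 * tt))


@dataclass
class CdfFitResults:
    """Results of an exponential CDF fit."""

    model: str
    params: dict
    n: int

    @property
    def mean(self) -> float:
        """Amplitude-weighted mean of the components plus any delay."""
        p = self.params
        if self.model == "single-exp":
            return 1.0 / p["k1"]
        if self.model == "single-exp-with-delay":
            return p["t0"] + 1.0 / p["k1"]
        if self.model == "double-exp":
            return p["a"] / p["k1"] + (1 - p["a"]) / p["k2"]
        return p["t0"] + p["a"] / p["k1"] + (1 - p["a"]) / p["k2"]

    @property
    def combined_rate(self) -> float:
        return 1.0 / self.mean

    def summary(self) -> str:
        pars = ", ".join(f"{k} = {v:.4g}" for k, v in self.params.items())
        return f"{self.model} fit (n = {self.n}): mean = {self.mean:.4g} s; {pars}"


class ExponentialCdf:
    """Least-squares exponential models for an empirical CDF.

    Fits are evaluated at the observed event times (empirical CDF with the
    standard (i - 0.5)/n plotting positions), avoiding histogram bin-width
    sensitivity.  Supply ``survival`` pairs (t, S(t)) instead of raw times
    to fit a censoring-corrected (Kaplan--Meier) estimate.
    """

    def __init__(
        self,
        times: np.ndarray | None = None,
        cdf: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        if (times is None) == (cdf is None):
            raise ValueError("provide exactly one of times= or cdf=")
        if times is not None:
            t = np.sort(np.asarray(times, dtype=float))
            if t.size == 0:
                raise FitError("no event times to fit")
            F = (np.arange(1, t.size + 1) - 0.5) / t.size
            self.t, self.F, self.n = t, F, t.size
        else:
            t, F = cdf
            self.t = np.asarray(t, dtype=float)
            self.F = np.asarray(F, dtype=float)
            self.n = self.t.size

    def fit(self, model: str = "single-exp") -> CdfFitResults:
        t, F = self.t, self.F
        scale = max(float(np.sum(t * np.gradient(F)) if t.size > 3 else t.mean()), 1e-6)
        k0 = 1.0 / scale
        try:
            if model == "single-exp":
                popt, _ = curve_fit(_cdf_single, t, F, p0=[k0], bounds=(1e-9, np.inf), maxfev=10000)
                params = {"k1": popt[0]}
            elif model == "single-exp-with-delay":
                popt, _ = curve_fit(
                    _cdf_single_delay, t, F, p0=[k0, 0.0],
                    bounds=([1e-9, 0.0], [np.inf, max(t.max() * 0.5, 1e-6)]), maxfev=10000,
                )
                params = {"k1": popt[0], "t0": popt[1]}
            elif model == "double-exp":
                popt, _ = curve_fit(
                    _cdf_double, t, F, p0=[0.7, k0 * 2, k0 * 0.5],
                    bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]), maxfev=20000,
                )
                params = {"a": popt[0], "k1": popt[1], "k2": popt[2]}
            elif model == "double-exp-with-delay":
                popt, _ = curve_fit(
                    _cdf_double_delay, t, F, p0=[0.7, k0 * 2, k0 * 0.5, 0.0],
                    bounds=(
                        [0.0, 1e-9, 1e-9, 0.0],
                        [1.0, np.inf, np.inf, max(t.max() * 0.5, 1e-6)],
                    ),
                    maxfev=20000,
                )
                params = {"a": popt[0], "k1": popt[1], "k2": popt[2], "t0": popt[3]}
            else:
                raise ValueError(f"unknown model {model!r}")
        except RuntimeError as exc:
            raise FitError(f"{model} CDF fit did not converge: {exc}") from exc
        return CdfFitResults(model=model, params=params, n=self.n)

    def fit_with_fallback(self, model: str) -> CdfFitResults:
        """Fit ``model``; on non-convergence fall back to the single-exp
        variant (with delay if the requested model had one), with a warning."""
        try:
            return self.fit(model)
        except FitError:
            fallback = "single-exp-with-delay" if "delay" in model else "single-exp"
            warnings.warn(f"{model} fit failed; falling back to {fallback}", stacklevel=2)
            return self.fit(fallback)


# ---------------------------------------------------------------------------
# Bootstrap machinery (trace-level resampling)
# ---------------------------------------------------------------------------


def _bootstrap_ci(
    stat: "callable",
    group_ids: np.ndarray,
    n_boot: int = 1000,
    seed: int = 12345,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling whole groups (traces)."""
    rng = np.random.default_rng(seed)
    groups = np.unique(group_ids)
    index = {g: np.flatnonzero(group_ids == g) for g in groups}
    stats = []
    for _ in range(n_boot):
        pick = rng.choice(groups, size=groups.size, replace=True)
        idx = np.concatenate([index[g] for g in pick])
        try:
            stats.append(stat(idx))
        except (FitError, RuntimeError):
            continue
    if len(stats) < max(20, n_boot // 10):
        raise FitError("bootstrap failed in too many resamples")
    lo, hi = np.percentile(stats, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Rate estimators
# ---------------------------------------------------------------------------


def association_rate(
    zero_dwells: np.ndarray,
    concentration: float,
    trace_ids: np.ndarray | None = None,
    n_boot: int = 1000,
    boot_seed: int = 12345,
) -> RateEstimate:
    """Bimolecular association rate (uM^-1 s^-1) from zero-state dwells.

    A single exponential ``1 - exp(-k t)`` is fitted to the cumulative
    distribution of the zero-FRET dwell times; the pseudo-first-order rate
    is divided by the ternary-complex concentration.
    """
    zero_dwells = np.asarray(zero_dwells, dtype=float)
    if zero_dwells.size < MIN_EVENTS:
        raise FitError(
            f"association_rate needs >= {MIN_EVENTS} zero-state dwells, got {zero_dwells.size}"
        )
    if concentration <= 0:
        raise FitError("concentration must be > 0")

    def estimate(idx: np.ndarray) -> float:
        fit = ExponentialCdf(times=zero_dwells[idx]).fit("single-exp")
        return fit.params["k1"] / concentration

    all_idx = np.arange(zero_dwells.size)
    value = estimate(all_idx)
    gids = trace_ids if trace_ids is not None else all_idx
    ci = _bootstrap_ci(estimate, np.asarray(gids), n_boot=n_boot, seed=boot_seed)
    return RateEstimate(
        label="association rate",
        value=value,
        units="uM^-1 s^-1",
        fit_model="single-exp",
        params={"k_pseudo_first_order": value * concentration, "concentration_uM": concentration},
        ci=ci,
        n=zero_dwells.size,
    )


def catalytic_efficiency(
    arrival_times: np.ndarray,
    concentration: float,
    censored_times: np.ndarray | None = None,
    n_boot: int = 1000,
    boot_seed: int = 12345,
) -> RateEstimate:
    """Catalytic efficiency of stable accommodation (uM^-1 s^-1).

    ``arrival_times`` are waiting times from trace start to the first
    accommodated-state visit; ``censored_times`` are the observation ends
    of traces that photobleached before accommodating.  The cumulative
    arrival distribution (Kaplan--Meier when censoring is present) is
    fitted with a two-exponential function with a delay; efficiency is
    1 / (mean arrival time x concentration).
    """
    arrival_times = np.asarray(arrival_times, dtype=float)
    if arrival_times.size < MIN_EVENTS:
        raise FitError(
            f"catalytic_efficiency needs >= {MIN_EVENTS} arrivals, got {arrival_times.size}"
        )
    if concentration <= 0:
        raise FitError("concentration must be > 0")
    cens = np.asarray(censored_times, dtype=float) if censored_times is not None else np.array([])

    def km_mean(times: np.ndarray, cens_sub: np.ndarray) -> tuple[float, "ExponentialCdf"]:
        """Mean arrival from the censoring-corrected empirical CDF.

        Restricted mean (area under the Kaplan--Meier survival curve up to
        the last observed arrival) plus an exponential tail completion for
        the residual survival mass.
        """
        model = _km_cdf_model(times, cens_sub)
        t = np.concatenate([[0.0], model.t])
        S = 1.0 - np.concatenate([[0.0], model.F])
        restricted = float(np.trapezoid(S, t))
        t_last = float(t[-1])
        pi = float(S[-1])
        # The survival curve plateaus at the fraction of traces whose
        # accommodated state is never identified (labelling failures);
        # that plateau would otherwise inflate the mean.  When the plateau
        # is small and starts far beyond the arrival scale, treat it as a
        # non-detecting subpopulation and average conditional on detection.
        scale = float(np.mean(times))
        if 0.0 < pi <= 0.10 and t_last > 4.0 * scale:
            return (restricted - pi * t_last) / (1.0 - pi), model
        # otherwise complete the tail with the last-decile mean excess
        q = np.quantile(times, 0.9)
        excess = times[times > q] - q
        tail_scale = float(excess.mean()) if excess.size else scale
        return restricted + pi * tail_scale, model

    mean_arrival, km = km_mean(arrival_times, cens)
    value = 1.0 / (mean_arrival * concentration)
    # parametric description of the distribution (mixing-delay model)
    try:
        fit = km.fit_with_fallback("double-exp-with-delay")
        fit_params = {**fit.params, "fit_mean_arrival_s": fit.mean}
        fit_model = fit.model
    except FitError:
        fit_params, fit_model = {}, "km-mean"

    n_arr, n_cens = arrival_times.size, cens.size
    all_ids = np.arange(n_arr + n_cens)

    def estimate(idx: np.ndarray) -> float:
        a = idx[idx < n_arr]
        c = idx[idx >= n_arr] - n_arr
        if a.size < 5:
            raise FitError("resample without arrivals")
        m, _ = km_mean(arrival_times[a], cens[c])
        return 1.0 / (m * concentration)

    ci = _bootstrap_ci(estimate, all_ids, n_boot=n_boot, seed=boot_seed)
    return RateEstimate(
        label="catalytic efficiency",
        value=value,
        units="uM^-1 s^-1",
        fit_model="km-mean + " + fit_model,
        params={"mean_arrival_s": mean_arrival, **fit_params},
        ci=ci,
        n=n_arr,
    )


def _km_cdf_model(times: np.ndarray, censored: np.ndarray) -> ExponentialCdf:
    """Empirical (or Kaplan--Meier, if censoring) CDF of arrival times."""
    if censored.size == 0:
        return ExponentialCdf(times=times)
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    durations = np.concatenate([times, censored])
    observed = np.concatenate([np.ones_like(times), np.zeros_like(censored)])
    kmf.fit(durations, event_observed=observed)
    t = np.sort(times)
    F = 1.0 - kmf.survival_function_at_times(t).to_numpy()
    return ExponentialCdf(cdf=(t, F))


def passage_rate(
    passage_times: np.ndarray,
    n_boot: int = 1000,
    boot_seed: int = 12345,
) -> RateEstimate:
    """Combined rate of all post-binding decoding steps (s^-1).

    ``passage_times`` run from the start of the binding event directly
    preceding the first accommodation to the accommodation event.  A
    two-exponential CDF fit gives the amplitude-weighted mean passage time;
    the reported rate is its inverse.
    """
    passage_times = np.asarray(passage_times, dtype=float)
    if passage_times.size < MIN_EVENTS:
        raise FitError(
            f"passage_rate needs >= {MIN_EVENTS} passage times, got {passage_times.size}"
        )
    mean = float(passage_times.mean())
    if passage_times.std() < 0.05 * mean:
        # (near-)deterministic intervals: an exponential-mixture CDF fit is
        # ill-posed on a step function, so report the empirical mean
        se = passage_times.std(ddof=1) / np.sqrt(passage_times.size) if passage_times.size > 1 else 0.0
        return RateEstimate(
            label="passage rate",
            value=1.0 / mean,
            units="s^-1",
            fit_model="empirical-mean",
            params={"mean_passage_s": mean},
            ci=(1.0 / (mean + 1.96 * se + 1e-12), 1.0 / max(mean - 1.96 * se, 1e-12)),
            n=passage_times.size,
        )

    def estimate(idx: np.ndarray) -> float:
        fit = ExponentialCdf(times=passage_times[idx]).fit_with_fallback("double-exp")
        return fit.combined_rate

    all_idx = np.arange(passage_times.size)
    fit = ExponentialCdf(times=passage_times).fit_with_fallback("double-exp")
    ci = _bootstrap_ci(estimate, all_idx, n_boot=n_boot, seed=boot_seed)
    return RateEstimate(
        label="passage rate",
        value=fit.combined_rate,
        units="s^-1",
        fit_model=fit.model,
        params={**fit.params, "mean_passage_s": fit.mean},
        ci=ci,
        n=passage_times.size,
    )


def state_lifetime(
    dwells: list[DwellRecord],
    state: int,
    censored_mle: bool = False,
    n_boot: int = 1000,
    boot_seed: int = 12345,
) -> RateEstimate:
    """Exponential MLE lifetime (s) of a hidden state from dwell records.

    With ``censored_mle=False`` censored dwells are excluded and the
    lifetime is the mean of the uncensored dwells (which is biased low when
    long dwells are preferentially censored).  With ``censored_mle=True``
    the censoring-aware MLE is used: total observed time in the state
    divided by the number of uncensored (terminated) dwells.
    """
    sel = [d for d in dwells if d.state == state]
    if not sel:
        raise FitError(f"no dwells for state {state}")
    durations = np.array([d.duration for d in sel])
    uncensored = np.array([not (d.left_censored or d.right_censored) for d in sel])
    tids = np.array([d.trace_id for d in sel])
    if uncensored.sum() == 0:
        raise FitError(
            "no uncensored dwells; use censored_mle=True if every dwell is truncated"
        )

    def estimate(idx: np.ndarray) -> float:
        d, u = durations[idx], uncensored[idx]
        if censored_mle:
            if u.sum() == 0:
                raise FitError("resample without terminations")
            return float(d.sum() / u.sum())
        return float(d[u].mean())

    all_idx = np.arange(durations.size)
    value = estimate(all_idx)
    ci = _bootstrap_ci(estimate, tids, n_boot=n_boot, seed=boot_seed)
    return RateEstimate(
        label=f"state {state} lifetime",
        value=value,
        units="s",
        fit_model="exponential-MLE" + ("-censored" if censored_mle else ""),
        params={"n_uncensored": int(uncensored.sum())},
        ci=ci,
        n=durations.size,
    )


def transition_rate(
    idealizations: list[Idealization],
    from_state: int,
    to_state: int,
    merge_from: tuple[int, ...] | None = None,
    n_boot: int = 1000,
    boot_seed: int = 12345,
) -> RateEstimate:
    """CTMC maximum-likelihood transition rate k(i->j) (s^-1).

    The MLE for a continuously observed Markov path is the number of
    observed i->j transitions divided by the total time spent in i.  The
    idealized path is treated as the observed path; post-bleach frames
    must already be excluded.

    ``merge_from`` lists additional departure states whose steps into
    ``to_state`` are credited to ``from_state``.  This absorbs frame
    quantization: a transition landing mid-frame can leave the boundary
    frame assigned to an adjacent short-lived state (e.g. a GA->AC step
    recorded as CR->AC when the scheme has no such edge), while entries
    from the zero-FRET state -- blinking artefacts -- stay excluded.
    """
    sources = {from_state, *(merge_from or ())}
    counts = np.zeros(len(idealizations))
    times = np.zeros(len(idealizations))
    for m, ideal in enumerate(idealizations):
        p = ideal.path
        from_mask = np.isin(p[:-1], list(sources))
        counts[m] = np.count_nonzero(from_mask & (p[1:] == to_state))
        times[m] = np.count_nonzero(p == from_state) * ideal.frame_interval
    if times.sum() <= 0:
        raise FitError(f"no time observed in state {from_state}")

    def estimate(idx: np.ndarray) -> float:
        t = times[idx].sum()
        if t <= 0:
            raise FitError("resample without occupancy")
        return float(counts[idx].sum() / t)

    all_idx = np.arange(len(idealizations))
    value = estimate(all_idx)
    ci = _bootstrap_ci(estimate, all_idx, n_boot=n_boot, seed=boot_seed)
    return RateEstimate(
        label=f"k({from_state}->{to_state})",
        value=value,
        units="s^-1",
        fit_model="markov-MLE",
        params={"n_transitions": float(counts.sum()), "total_time_s": float(times.sum())},
        ci=ci,
        n=int(counts.sum()),
    )


# ---------------------------------------------------------------------------
# eIF5A titration: Gaussian fractions and the two-conformation isotherm
# ---------------------------------------------------------------------------


def _two_gauss(x, w, m1, s1, m2, s2):
    g1 = np.exp(-0.5 * ((x - m1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    g2 = np.exp(-0.5 * ((x - m2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
    return w * g1 + (1 - w) * g2


def two_gaussian_fit(
    x: np.ndarray,
    classical_guess: float = 0.7,
    hybrid_guess: float = 0.3,
    bins: int = 60,
) -> dict:
    """Two-Gaussian mixture fit to a FRET distribution.

    Returns the fitted parameters with the classical (higher-mean)
    component first: keys classical_mean/sd/weight, hybrid_mean/sd.
    """
    hist, edges = np.histogram(x, bins=bins, range=(0.0, 1.0), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(
            _two_gauss,
            centers,
            hist,
            p0=[0.5, classical_guess, 0.06, hybrid_guess, 0.06],
            bounds=([0.0, 0.0, 0.005, 0.0, 0.005], [1.0, 1.0, 0.5, 1.0, 0.5]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"mixture fit failed: {exc}") from exc
    w, m1, s1, m2, s2 = popt
    if m1 >= m2:
        return {"classical_mean": m1, "classical_sd": s1, "classical_weight": w,
                "hybrid_mean": m2, "hybrid_sd": s2}
    return {"classical_mean": m2, "classical_sd": s2, "classical_weight": 1 - w,
            "hybrid_mean": m1, "hybrid_sd": s1}


def _mixture_fraction(x: np.ndarray, classical_guess: float, hybrid_guess: float, bins: int) -> float:
    hist, edges = np.histogram(x, bins=bins, range=(0.0, 1.0), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(
            _two_gauss,
            centers,
            hist,
            p0=[0.5, classical_guess, 0.06, hybrid_guess, 0.06],
            bounds=([0.0, 0.0, 0.005, 0.0, 0.005], [1.0, 1.0, 0.5, 1.0, 0.5]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"mixture fit failed: {exc}") from exc
    w, m1, s1, m2, s2 = popt
    if abs(m1 - m2) < 2.0 * min(s1, s2):
        raise FitError("Gaussian modes collapsed; fractions are not identifiable")
    # essentially unimodal data whose single mode matches neither
    # conformation cannot be split into classical/hybrid fractions
    major_m, minor_w = (m1, 1 - w) if w >= 0.5 else (m2, w)
    if minor_w < 0.05 and min(
        abs(major_m - classical_guess), abs(major_m - hybrid_guess)
    ) > 0.1:
        raise FitError(
            "single dominant mode matches neither conformation; "
            "fractions are not identifiable"
        )
    # the classical component is the higher-FRET mode
    return float(w if m1 > m2 else 1.0 - w)


def classical_fraction(
    fret_values: np.ndarray,
    trace_ids: np.ndarray | None = None,
    classical_guess: float = 0.7,
    hybrid_guess: float = 0.3,
    bins: int = 60,
    n_boot: int = 100,
    boot_seed: int = 12345,
) -> tuple[float, float]:
    """Fraction of frames in the classical (high-FRET) state.

    Fits a two-Gaussian mixture to the equilibrium FRET distribution and
    returns (fraction, standard error) of the classical component weight.
    With ``trace_ids`` given, the SE is a bootstrap over traces -- frames
    within a trace are strongly correlated in time, so the naive
    fit-covariance SE would be far too small.  Raises :class:`FitError` if
    the two modes collapse.
    """
    x = np.asarray(fret_values, dtype=float)
    if x.size < 100:
        raise FitError("need >= 100 frames for a mixture fit")
    frac = _mixture_fraction(x, classical_guess, hybrid_guess, bins)
    if trace_ids is None:
        # crude fallback: treat ~1 frame in 10 as independent
        se = float(np.sqrt(frac * (1 - frac) / max(x.size / 10, 1)))
        return frac, se
    tid = np.asarray(trace_ids)

    def stat(idx: np.ndarray) -> float:
        return _mixture_fraction(x[idx], classical_guess, hybrid_guess, bins)

    lo, hi = _bootstrap_ci(stat, tid, n_boot=n_boot, seed=boot_seed)
    se = (hi - lo) / (2 * 1.96)
    return frac, float(se)


@dataclass
class TitrationModel:
    """Two-conformation ligand-binding isotherm for eIF5A.

    ``fraction_classical(L)`` gives the fraction of time the ribosome
    spends in classical-state-like FRET states at free ligand
    concentration L (uM):

        f_c(L) = A_C5A (K_D + L) / (L + K_D A_C5A / A_Capo)

    with the limits f_c(0) = A_Capo (ligand-free classical fraction) and
    f_c(inf) = A_C5A (ligand-bound classical fraction).
    """

    kd: float
    a_c5a: float
    a_capo: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("K_D must be > 0")
        for name in ("a_c5a", "a_capo"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def fraction_classical(self, L) -> np.ndarray | float:
        L = np.asarray(L, dtype=float)
        out = self.a_c5a * (self.kd + L) / (L + self.kd * self.a_c5a / self.a_capo)
        return float(out) if out.ndim == 0 else out


def _isotherm(L, kd, a_c5a, a_capo):
    return a_c5a * (kd + L) / (L + kd * a_c5a / a_capo)


@dataclass
class BindingIsothermResults:
    """Fitted isotherm parameters with bootstrap uncertainties."""

    model: TitrationModel
    bse: dict
    conf_int: dict
    n_concentrations: int
    residual_ss: float

    @property
    def params(self) -> dict:
        return {"kd": self.model.kd, "a_c5a": self.model.a_c5a, "a_capo": self.model.a_capo}

    def summary(self) -> str:
        lines = [f"Two-conformation binding isotherm ({self.n_concentrations} concentrations)"]
        for k, v in self.params.items():
            lo, hi = self.conf_int[k]
            lines.append(f"  {k:7s} = {v:.4g}  (se {self.bse[k]:.3g}, 95% CI [{lo:.4g}, {hi:.4g}])")
        lines.append(f"  weighted residual SS = {self.residual_ss:.4g}")
        return "\n".join(lines)


class BindingIsotherm:
    """Weighted least-squares fit of the two-conformation isotherm.

    Parameters
    ----------
    concentrations, fractions, se:
        Ligand concentrations (uM), measured classical fractions and their
        standard errors.  At least 4 concentrations are expected; a warning
        is emitted if they do not span the fitted K_D.
    """

    def __init__(
        self,
        concentrations: np.ndarray,
        fractions: np.ndarray,
        se: np.ndarray | None = None,
    ) -> None:
        self.L = np.asarray(concentrations, dtype=float)
        self.f = np.asarray(fractions, dtype=float)
        self.se = (
            np.asarray(se, dtype=float) if se is not None else np.full_like(self.f, np.nan)
        )
        if self.L.size != self.f.size:
            raise ValueError("concentrations and fractions must have equal length")
        if self.L.size < 4:
            warnings.warn("fewer than 4 concentrations: K_D is weakly constrained", stacklevel=2)
        if np.ptp(self.f) < 0.02:
            raise FitError("flat titration response; isotherm parameters not identifiable")

    def _fit_arrays(self, L, f, sigma) -> tuple[float, float, float]:
        p0 = [np.median(L[L > 0]) if (L > 0).any() else 1.0, max(f.max(), 0.5), max(f.min(), 0.05)]
        popt, _ = curve_fit(
            _isotherm, L, f, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            bounds=([1e-6, 1e-3, 1e-3], [1e4, 1.0, 1.0]), maxfev=20000,
        )
        return tuple(popt)

    def fit(self, n_boot: int = 1000, boot_seed: int = 12345) -> BindingIsothermResults:
        sigma = self.se if np.isfinite(self.se).all() and (self.se > 0).all() else None
        kd, a_c5a, a_capo = self._fit_arrays(self.L, self.f, sigma)
        if not (self.L.min() <= kd <= self.L.max()):
            warnings.warn(
                f"fitted K_D = {kd:.3g} uM lies outside the sampled range "
                f"[{self.L.min():.3g}, {self.L.max():.3g}]",
                stacklevel=2,
            )
        model = TitrationModel(kd=kd, a_c5a=a_c5a, a_capo=a_capo)
        resid = self.f - model.fraction_classical(self.L)
        if sigma is not None:
            resid = resid / sigma
        # parametric bootstrap over the per-point measurement error
        rng = np.random.default_rng(boot_seed)
        draws = {"kd": [], "a_c5a": [], "a_capo": []}
        noise_sd = self.se if sigma is not None else np.full_like(self.f, resid.std() or 1e-3)
        for _ in range(n_boot):
            fb = self.f + rng.normal(0.0, noise_sd)
            try:
                k, a1, a0 = self._fit_arrays(self.L, np.clip(fb, 1e-4, 1.0), sigma)
            except RuntimeError:
                continue
            draws["kd"].append(k)
            draws["a_c5a"].append(a1)
            draws["a_capo"].append(a0)
        if len(draws["kd"]) < n_boot // 10:
            raise FitError("bootstrap failed in too many resamples")
        bse = {k: float(np.std(v)) for k, v in draws.items()}
        ci = {k: tuple(np.percentile(v, [2.5, 97.5])) for k, v in draws.items()}
        return BindingIsothermResults(
            model=model,
            bse=bse,
            conf_int=ci,
            n_concentrations=self.L.size,
            residual_ss=float(np.sum(resid**2)),
        )


def fit_titration(
    concentrations: np.ndarray,
    fractions: np.ndarray,
    se: np.ndarray | None = None,
    n_boot: int = 1000,
    boot_seed: int = 12345,
) -> BindingIsothermResults:
    """Convenience wrapper: fit the two-conformation isotherm (see
    :class:`BindingIsotherm`)."""
    return BindingIsotherm(concentrations, fractions, se).fit(n_boot=n_boot, boot_seed=boot_seed)
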