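"""Continuous-time Markov model of ribosomal mRNA decoding.

The decoding reaction is modelled as a continuous-time Markov chain over a
small set of named conformational states.  The canonical scheme has four
states seen from the tRNA--tRNA FRET perspective::

    Unbound  --k_on[TC]-->  CR  <-->  GA  <-->  AC
      (0)                 (0.23)    (0.49)    (0.74)

Ternary-complex binding (``Unbound -> CR``) is bimolecular: its rate is
given in uM^-1 s^-1 and is multiplied by the ternary-complex concentration
(uM) to obtain a pseudo-first-order rate in s^-1.  All other rates are
first-order (s^-1).  Each state carries a FRET emission mean and standard
deviation used by the simulator and as idealization starting values.

The module also provides exact linear-algebra oracles -- state occupancy
``p0 expm(Q t)`` and mean first-passage times -- used to validate the
stochastic simulator and the downstream dwell-time estimators.

Units are fixed package-wide: time in seconds, concentration in uM,
first-order rates in s^-1, bimolecular rates in uM^-1 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.linalg import expm

__all__ = [
    "StateSpec",
    "DecodingModel",
    "build_generator",
    "state_occupancy",
    "mean_first_passage",
    "absorption_probability",
    "load_preset",
    "available_presets",
]


class ModelValidationError(ValueError):
    """Raised when a kinetic model or generator input is inconsistent."""


@dataclass(frozen=True)
class StateSpec:
    """A named kinetic state with its FRET emission parameters.

    Parameters
    ----------
    name:
        State label.  ``Unbound`` is the conventional zero-FRET state.
    fret_mean:
        Mean FRET efficiency of the state, in [0, 1].
    fret_sd:
        Standard deviation of the state's FRET efficiency (>= 0).  In the
        simulator this is interpreted as *static* (per-trace) conformational
        heterogeneity; see :mod:`smdecode.simulate`.
    """

    name: str
    fret_mean: float
    fret_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fret_mean <= 1.0:
            raise ModelValidationError(
                f"fret_mean of state {self.name!r} must be in [0, 1], got {self.fret_mean}"
            )
        if self.fret_sd < 0:
            raise ModelValidationError(
                f"fret_sd of state {self.name!r} must be >= 0, got {self.fret_sd}"
            )
        if self.name == "Unbound" and self.fret_mean != 0.0:
            raise ModelValidationError("the Unbound state must have fret_mean = 0")


@dataclass
class DecodingModel:
    """A decoding kinetic scheme: states, rates and binding edges.

    Parameters
    ----------
    states:
        Ordered list of :class:`StateSpec`; the order defines state indices.
    rates:
        Mapping ``(from_state, to_state) -> rate``.  First-order rates are
        in s^-1; rates on edges listed in ``binding_edges`` are bimolecular
        (uM^-1 s^-1).
    binding_edges:
        Edges whose rate must be multiplied by the ternary-complex
        concentration to obtain a pseudo-first-order rate.
    concentration:
        Default ternary-complex concentration in uM.
    temperature_label:
        Metadata only ("25C" or "37C"); no temperature interpolation is done.
    """

    states: list[StateSpec]
    rates: dict[tuple[str, str], float]
    binding_edges: set[tuple[str, str]] = field(default_factory=set)
    concentration: float = 0.0
    temperature_label: str = "25C"
    name: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ModelValidationError(f"duplicate state names in {names}")
        for (a, b), k in self.rates.items():
            if a == b:
                raise ModelValidationError(f"self-edge {a} -> {b} not allowed")
            if a not in names or b not in names:
                raise ModelValidationError(f"rate references unknown state: {a} -> {b}")
            if k < 0:
                raise ModelValidationError(f"negative rate on {a} -> {b}: {k}")
        for edge in self.binding_edges:
            if edge not in self.rates:
                raise ModelValidationError(f"binding edge {edge} has no rate entry")
        if self.concentration < 0:
            raise ModelValidationError("concentration must be >= 0")

    # -- helpers -------------------------------------------------------
    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError as exc:
            raise ModelValidationError(f"unknown state {name!r}") from exc

    def state(self, name: str) -> StateSpec:
        return self.states[self.index(name)]

    @property
    def fret_means(self) -> np.ndarray:
        return np.array([s.fret_mean for s in self.states])

    @property
    def fret_sds(self) -> np.ndarray:
        return np.array([s.fret_sd for s in self.states])

    def with_concentration(self, concentration: float) -> "DecodingModel":
        return replace(self, concentration=concentration)

    def with_rates(self, updates: dict[tuple[str, str], float]) -> "DecodingModel":
        """Return a copy with some rates replaced (rate 0 removes no edge)."""
        new = dict(self.rates)
        new.update(updates)
        return replace(self, rates=new)

    def generator(self, concentration: float | None = None) -> np.ndarray:
        conc = self.concentration if concentration is None else concentration
        return build_generator(self, conc)


def build_generator(model: DecodingModel, concentration: float | None = None) -> np.ndarray:
    """Build the CTMC generator matrix Q (s^-1) for a model.

    Off-diagonal ``Q[i, j]`` is the rate of ``i -> j``; rates on binding
    edges are multiplied by ``concentration`` (uM x uM^-1 s^-1 = s^-1).
    The diagonal is set so that every row sums to zero.
    """
    conc = model.concentration if concentration is None else concentration
    if conc < 0:
        raise ModelValidationError("concentration must be >= 0")
    n = model.n_states
    Q = np.zeros((n, n))
    for (a, b), k in model.rates.items():
        i, j = model.index(a), model.index(b)
        Q[i, j] = k * conc if (a, b) in model.binding_edges else k
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def state_occupancy(Q: np.ndarray, p0: np.ndarray, t: float) -> np.ndarray:
    """State occupancy ``p0 expm(Q t)`` at time ``t`` (exact oracle)."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ModelValidationError(f"Q must be square, got shape {Q.shape}")
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (Q.shape[0],):
        raise ModelValidationError("p0 length must match Q")
    if not np.isclose(p0.sum(), 1.0):
        raise ModelValidationError("p0 must sum to 1")
    if t < 0:
        raise ModelValidationError("t must be >= 0")
    p = p0 @ expm(Q * t)
    # numerical guard: expm keeps rows stochastic only to rounding error
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _reachable_from(Q: np.ndarray, source: int) -> set[int]:
    n = Q.shape[0]
    seen = {source}
    frontier = [source]
    while frontier:
        i = frontier.pop()
        for j in range(n):
            if j != i and Q[i, j] > 0 and j not in seen:
                seen.add(j)
                frontier.append(j)
    return seen


def mean_first_passage(Q: np.ndarray, source: int, target: int) -> float:
    """Mean first-passage time (s) from ``source`` to ``target``.

    Solves the linear system obtained by making ``target`` absorbing:
    ``-Q_r tau = 1`` over the non-target states, where ``Q_r`` is the
    generator restricted to those states.
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    if Q.shape != (n, n):
        raise ModelValidationError("Q must be square")
    if source == target:
        return 0.0
    if target not in _reachable_from(Q, source):
        raise ModelValidationError(
            f"target state {target} is not reachable from source {source}"
        )
    # restrict the linear system to states that can reach the target:
    # states that cannot (e.g. a disconnected absorbing state) have
    # infinite passage time and would make the system singular
    can_reach = [i for i in range(n) if i != target and target in _reachable_from(Q, i)]
    Qr = Q[np.ix_(can_reach, can_reach)]
    tau = np.linalg.solve(-Qr, np.ones(len(can_reach)))
    return float(tau[can_reach.index(source)])


def absorption_probability(
    Q: np.ndarray, source: int, target: int, competing: int
) -> float:
    """Probability of hitting ``target`` before ``competing`` from ``source``.

    Both ``target`` and ``competing`` are made absorbing and the standard
    hitting-probability linear system is solved.  Used as an oracle for the
    fraction of binding events that complete accommodation versus reject.
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    if source in (target, competing):
        return 1.0 if source == target else 0.0
    transient = [i for i in range(n) if i not in (target, competing)]
    Qr = Q[np.ix_(transient, transient)]
    b = Q[transient, target]
    h = np.linalg.solve(-Qr, b)
    return float(h[transient.index(source)])


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_PRESET_RESOURCE = "decoding_presets.yaml"


def _preset_text(path: str | Path | None = None) -> str:
    if path is not None:
        return Path(path).read_text()
    return (resources.files("smdecode") / "presets" / _PRESET_RESOURCE).read_text()


def available_presets(path: str | Path | None = None) -> list[str]:
    """Names of the kinetic presets shipped with the package."""
    return sorted(yaml.safe_load(_preset_text(path))["models"])


def load_preset(name: str, path: str | Path | None = None) -> DecodingModel:
    """Load a named kinetic preset from the versioned preset file.

    Shipped presets
    ---------------
    ``cognate-25C``
        Full cognate scheme at 25 C: k_on 70 uM^-1 s^-1, CR exit 100 s^-1
        (95.337 on to GA / 4.663 rejection), GA->CR 1.6129 s^-1,
        GA->AC 1.7 s^-1, AC->GA excursion 0.5 s^-1.
    ``cognate-37C``
        Same with GA->AC = 12.8 s^-1.
    ``cognate-25C-GTPyS``
        GTPase-blocked control: the GA->AC edge is removed, so GA dwells
        terminate only by reversal to CR; GA lifetime is 620 ms.
    ``near-cognate``
        Qualitative near-cognate scheme: high CR rejection and short GA
        lifetime (no quantitative targets attached).
    ``cognate-25C-uL11``
        Three-state variant for the uL11/GAC labelling perspective, where
        CR and GA are indistinguishable (engaged, high FRET) and the
        accommodated state has intermediate FRET.
    """
    data = yaml.safe_load(_preset_text(path))
    try:
        spec = data["models"][name]
    except KeyError as exc:
        raise ModelValidationError(
            f"unknown preset {name!r}; available: {sorted(data['models'])}"
        ) from exc
    states = [
        StateSpec(s["name"], float(s["fret_mean"]), float(s.get("fret_sd", 0.0)))
        for s in spec["states"]
    ]
    rates: dict[tuple[str, str], float] = {}
    binding: set[tuple[str, str]] = set()
    for edge in spec["rates"]:
        key = (edge["from"], edge["to"])
        rates[key] = float(edge["rate"])
        if edge.get("bimolecular", False):
            binding.add(key)
    return DecodingModel(
        states=states,
        rates=rates,
        binding_edges=binding,
        concentration=float(spec.get("concentration_uM", 0.0)),
        temperature_label=str(spec.get("temperature_label", "25C")),
        name=name,
    )
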