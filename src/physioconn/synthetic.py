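"""Seeded synthetic multichannel recordings with known directed-coupling ground truth.

The generator emulates the recorded 6-channel system (4 EEG + 1 ECG +
1 Pleth at 500 Hz): each channel is an AR(2) resonator with a chosen
center frequency and pole radius (a stylized stand-in for the dominant
rhythm of that organ's signal — mouse heart rate ~12 Hz, breathing
~4 Hz, EEG rhythms across 7-80 Hz), and directed cross-couplings are
injected as off-diagonal MVAR coefficients at chosen lags. Because the
ground truth is itself a stable MVAR process, GPDC's modeling
assumptions hold exactly and recovery of the injected topology is a
sharp test of the whole pipeline.

Three scenarios mirror the contrast the analysis is designed to detect:

* ``WT_LIKE`` — strong bidirectional brain<->heart coupling, moderate
  brain->lungs and lungs->brain feedback (a healthy-control-like
  topology);
* ``KO_LIKE`` — brain<->heart weakened, brain->lungs and heart->lungs
  strengthened, lungs->brain feedback reduced;
* ``KO_SEIZING`` — KO_LIKE with periodic "seizure" epochs during which
  the brain->lungs coupling is further elevated; epoch onsets are
  returned as event annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .mvar import MVARModel, check_stability
from .recording import MultichannelRecording

DEFAULT_LABELS = ["EEG1", "EEG2", "EEG3", "EEG4", "ECG", "PLETH"]
DEFAULT_ORGAN_MAP = {
    "EEG1": "BRAIN", "EEG2": "BRAIN", "EEG3": "BRAIN", "EEG4": "BRAIN",
    "ECG": "HEART", "PLETH": "LUNGS",
}
SCENARIOS = ("WT_LIKE", "KO_LIKE", "KO_SEIZING")

# Seizure epochs in KO_SEIZING: 80-s events (the recorded average seizure
# duration) every 300 s, confined to the first 60% of the recording so a
# seizure-free "recovery" tail remains.
SEIZURE_PERIOD_S = 300.0
SEIZURE_DURATION_S = 80.0
SEIZURE_FIRST_ONSET_S = 150.0
SEIZURE_EPOCH_FRACTION = 0.6


@dataclass(frozen=True)
class NodeDynamics:
    """AR(2) resonator: center frequency f0 (Hz) and pole radius < 1."""

    f0_hz: float
    radius: float

    def ar2_coeffs(self, fs: float) -> tuple:
        a1 = 2.0 * self.radius * np.cos(2.0 * np.pi * self.f0_hz / fs)
        return a1, -self.radius**2


@dataclass(frozen=True)
class Coupling:
    """Directed coupling: ``strength * x_from(t - lag)`` added to x_to(t)."""

    from_channel: str
    to_channel: str
    lag: int = 1
    strength: float = 0.0

    def __post_init__(self) -> None:
        if self.from_channel == self.to_channel:
            raise ValueError("coupling must connect distinct channels")
        if self.lag < 1:
            raise ValueError("coupling lag must be >= 1")


@dataclass
class CouplingSpec:
    """Ground-truth description of a simulated multichannel recording."""

    channel_labels: list = field(default_factory=lambda: list(DEFAULT_LABELS))
    organ_map: dict = field(default_factory=lambda: dict(DEFAULT_ORGAN_MAP))
    fs: float = 500.0
    node_dynamics: list = field(default_factory=list)
    couplings: list = field(default_factory=list)
    noise_sd: object = 1.0
    unit_scale: object = 1.0  # per-channel output gain; exercises scale invariance
    duration_s: float = 600.0
    seed: int | None = None

    @property
    def dim(self) -> int:
        return len(self.channel_labels)

    @property
    def order(self) -> int:
        lags = [c.lag for c in self.couplings]
        return max([2] + lags)

    def _per_channel(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.dim,))
        return np.array(arr)

    def index(self, label: str) -> int:
        return self.channel_labels.index(label)


def build_model(spec: CouplingSpec) -> MVARModel:
    """Assemble the exact MVAR model implied by a spec; reject unstable ones."""
    D, p = spec.dim, spec.order
    if len(spec.node_dynamics) != D:
        raise ValueError(f"need node dynamics for all {D} channels")
    coeffs = np.zeros((p, D, D))
    for k, nd in enumerate(spec.node_dynamics):
        if not (0 <= nd.radius < 1):
            raise ValueError(f"pole radius must be in [0, 1), got {nd.radius}")
        a1, a2 = nd.ar2_coeffs(spec.fs)
        coeffs[0, k, k] = a1
        coeffs[1, k, k] = a2
    for c in spec.couplings:
        coeffs[c.lag - 1, spec.index(c.to_channel), spec.index(c.from_channel)] += (
            c.strength
        )
    sd = spec._per_channel(spec.noise_sd)
    model = MVARModel(
        coeffs=coeffs, noise_cov=np.diag(sd**2), order=p, dim=D, fs=spec.fs
    )
    stable, radius = check_stability(model)
    if not stable:
        raise ValueError(
            f"coupling spec implies an unstable MVAR model (spectral radius {radius:.4f})"
        )
    return model


def _run_recursion(
    schedule: Sequence[tuple], D: int, p: int, noise: np.ndarray
) -> np.ndarray:
    """Drive x(t) = sum_r A_r x(t-r) + e(t) through a coefficient schedule.

    ``schedule`` is a list of (n_samples, stacked_coeffs) with
    stacked_coeffs of shape (D, p*D), columns ordered lag-major to match
    the state vector [x(t-1), ..., x(t-p)].
    """
    n_total = noise.shape[0]
    x = np.empty((n_total, D))
    state = np.zeros(p * D)
    t = 0
    for n_seg, A_stacked in schedule:
        for _ in range(n_seg):
            xt = A_stacked @ state + noise[t]
            x[t] = xt
            if p > 1:
                state[D:] = state[:-D]
            state[:D] = xt
            t += 1
    return x


def _stack(coeffs: np.ndarray) -> np.ndarray:
    return np.concatenate(list(coeffs), axis=1)  # (D, p*D), lag-major


def _topological_order(spec: CouplingSpec) -> list | None:
    """Channel order with all coupling sources first, or None if the graph has a cycle."""
    indeg = {c: 0 for c in spec.channel_labels}
    succ = {c: [] for c in spec.channel_labels}
    for c in spec.couplings:
        indeg[c.to_channel] += 1
        succ[c.from_channel].append(c.to_channel)
    ready = [c for c in spec.channel_labels if indeg[c] == 0]
    order = []
    while ready:
        node = ready.pop()
        order.append(node)
        for nxt in succ[node]:
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                ready.append(nxt)
    return order if len(order) == len(spec.channel_labels) else None


def simulate(spec: CouplingSpec, seed: int | None = None) -> MultichannelRecording:
    """Simulate a recording from a spec; bit-for-bit reproducible per seed.

    A burn-in of 10*p samples is discarded so the retained samples are
    (approximately) draws from the stationary distribution. Acyclic
    coupling graphs are simulated channel-by-channel with vectorized
    IIR filtering; cyclic graphs fall back to the sample-by-sample
    recursion.
    """
    model = build_model(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = int(round(spec.duration_s * spec.fs))
    burn = 10 * spec.order
    sd = spec._per_channel(spec.noise_sd)
    noise = rng.standard_normal((n + burn, spec.dim)) * sd
    topo = _topological_order(spec)
    if topo is not None:
        from scipy.signal import lfilter

        x = np.zeros((n + burn, spec.dim))
        for label in topo:
            k = spec.index(label)
            u = noise[:, k].copy()
            for c in spec.couplings:
                if c.to_channel == label and c.strength:
                    u[c.lag :] += c.strength * x[: -c.lag, spec.index(c.from_channel)]
            a1, a2 = spec.node_dynamics[k].ar2_coeffs(spec.fs)
            x[:, k] = lfilter([1.0], [1.0, -a1, -a2], u)
    else:
        x = _run_recursion(
            [(n + burn, _stack(model.coeffs))], spec.dim, spec.order, noise
        )
    data = x[burn:] * spec._per_channel(spec.unit_scale)
    return MultichannelRecording(data, spec.fs, spec.channel_labels, spec.organ_map)


@dataclass
class TestbedResult:
    """A simulated scenario recording with its ground truth and event annotations."""

    recording: MultichannelRecording
    spec: CouplingSpec
    events: list
    scenario: str
    ictal_couplings: list = field(default_factory=list)


def _default_dynamics() -> list:
    return [
        NodeDynamics(7.0, 0.90),   # EEG1: theta-range rhythm
        NodeDynamics(11.0, 0.90),  # EEG2: alpha-range rhythm
        NodeDynamics(40.0, 0.90),  # EEG3: low-gamma rhythm
        NodeDynamics(80.0, 0.90),  # EEG4: high-gamma rhythm
        NodeDynamics(12.0, 0.95),  # ECG: ~720 bpm mouse heart rate
        NodeDynamics(4.0, 0.95),   # PLETH: ~4 Hz mouse breathing
    ]


# Coupling strengths per scenario. The WT-like topology carries strong
# bidirectional brain<->heart flow; the KO-like topology weakens it and
# strengthens the efferent routes into the lungs. The coupling graph is
# acyclic, so the implied model inherits stability from the AR(2) poles.
_WT_COUPLINGS = [
    Coupling("EEG1", "ECG", 1, 0.40),    # Brain -> Heart
    Coupling("ECG", "EEG2", 1, 0.40),    # Heart -> Brain
    Coupling("EEG3", "PLETH", 1, 0.10),  # Brain -> Lungs (moderate)
    Coupling("PLETH", "EEG4", 2, 0.20),  # Lungs -> Brain feedback
]
_KO_COUPLINGS = [
    Coupling("EEG1", "ECG", 1, 0.10),    # Brain -> Heart (weakened)
    Coupling("ECG", "EEG2", 1, 0.10),    # Heart -> Brain (weakened)
    Coupling("EEG3", "PLETH", 1, 0.50),  # Brain -> Lungs (elevated)
    Coupling("ECG", "PLETH", 1, 0.30),   # Heart -> Lungs (new efferent route)
    Coupling("PLETH", "EEG4", 2, 0.05),  # Lungs -> Brain (reduced feedback)
]
_KO_ICTAL_BRAIN_LUNGS = 0.70  # Brain -> Lungs strength during seizure epochs

# Per-channel output gains giving physiologically flavored magnitudes
# (EEG ~100 uV, ECG ~1 mV, Pleth in fractional chamber-pressure units).
_UNIT_SCALE = [100.0, 100.0, 100.0, 100.0, 1000.0, 0.5]


def seizure_epochs(duration_s: float) -> list:
    """(onset_s, offset_s) seizure epochs for the KO_SEIZING schedule."""
    epochs = []
    onset = SEIZURE_FIRST_ONSET_S
    while onset + SEIZURE_DURATION_S <= SEIZURE_EPOCH_FRACTION * duration_s:
        epochs.append((onset, onset + SEIZURE_DURATION_S))
        onset += SEIZURE_PERIOD_S
    return epochs


def make_testbed(scenario: str, duration_s: float = 600.0,
                 seed: int = 0) -> TestbedResult:
    """Simulate a named scenario and return recording + ground truth + events."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    couplings = list(_WT_COUPLINGS if scenario == "WT_LIKE" else _KO_COUPLINGS)
    spec = CouplingSpec(
        node_dynamics=_default_dynamics(),
        couplings=couplings,
        noise_sd=1.0,
        unit_scale=list(_UNIT_SCALE),
        duration_s=duration_s,
        seed=seed,
    )
    if scenario != "KO_SEIZING":
        rec = simulate(spec)
        return TestbedResult(recording=rec, spec=spec, events=[], scenario=scenario)

    ictal = [
        replace(c, strength=_KO_ICTAL_BRAIN_LUNGS)
        if (c.from_channel, c.to_channel) == ("EEG3", "PLETH") else c
        for c in couplings
    ]
    base_model = build_model(spec)
    ictal_model = build_model(replace(spec, couplings=ictal))
    epochs = seizure_epochs(duration_s)
    fs, D, p = spec.fs, spec.dim, spec.order
    n = int(round(duration_s * fs))
    burn = 10 * p
    # Build the piecewise-constant coefficient schedule (interictal/ictal).
    t = 0.0
    base, hot = _stack(base_model.coeffs), _stack(ictal_model.coeffs)
    schedule = []
    for onset, offset in epochs:
        schedule.append((int(round((onset - t) * fs)), base))
        schedule.append((int(round((offset - onset) * fs)), hot))
        t = offset
    schedule.append((n - int(round(t * fs)), base))
    schedule[0] = (schedule[0][0] + burn, base)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n + burn, D)) * spec._per_channel(spec.noise_sd)
    x = _run_recursion(schedule, D, p, noise)
    data = x[burn:] * spec._per_channel(spec.unit_scale)
    rec = MultichannelRecording(data, fs, spec.channel_labels, spec.organ_map)
    events = [(onset, "seizure") for onset, _ in epochs]
    return TestbedResult(
        recording=rec, spec=spec, events=events, scenario=scenario,
        ictal_couplings=ictal,
    )
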