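"""Forward model of the path from gated emission to recorded MS intensity.

The chain explains why occupancy and MS intensity can decorrelate even when
emission tracks the cone perfectly: the plume gate multiplies the emission
flux by an on/off schedule; transit to the detector delays the flux
(default 1 ms) and blends temporally adjacent ion packets with a causal
exponential carryover kernel (default time constant 5 ms, spanning more
than one acquisition event); and the SIM acquisition integrates only the
first 0.8 ms dwell of every 4 ms event, discarding ions arriving in the
remaining 3.2 ms.  Together these smear and subsample the sub-millisecond
pulsation structure that occupancy measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .correlation import OccupancyTrace, bin_occupancy
from .detection import DetectionGeometry, analyze_stack, geometry_for_preset
from .synthetic import (
    AcquisitionSettings,
    EmissionTrain,
    SprayPreset,
    render_shadowgraph_stack,
)

__all__ = [
    "GateWaveform",
    "ChainParams",
    "MsTrace",
    "apply_gate",
    "transit_mixing",
    "sample_sim_events",
    "sample_continuous_events",
    "run_gated_experiment",
]

#: RE3 plume-gate levels, V: de-energized = open, energized = closed.
GATE_OPEN_LEVEL = 0.0
GATE_CLOSED_LEVEL = 1650.0


@dataclass(frozen=True)
class GateWaveform:
    """Plume-gate schedule: flux passes only inside the open intervals."""

    schedule: tuple[tuple[float, float], ...]
    open_level: float = GATE_OPEN_LEVEL
    closed_level: float = GATE_CLOSED_LEVEL

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "schedule", tuple((float(a), float(b)) for a, b in self.schedule)
        )
        prev_end = -math.inf
        for a, b in self.schedule:
            if not a < b:
                raise ValueError(f"gate interval ({a}, {b}) must have start < end")
            if a < prev_end:
                raise ValueError("gate intervals must be disjoint and increasing")
            prev_end = b

    @classmethod
    def always_open(cls, duration: float) -> "GateWaveform":
        return cls(((0.0, float(duration)),))

    @classmethod
    def always_closed(cls) -> "GateWaveform":
        return cls(())

    def transmission(self, times: np.ndarray) -> np.ndarray:
        """1 where the gate is open, 0 where it is closed."""
        times = np.asarray(times, dtype=float)
        open_ = np.zeros(times.shape, dtype=bool)
        for a, b in self.schedule:
            open_ |= (times >= a) & (times < b)
        return open_.astype(float)


@dataclass(frozen=True)
class ChainParams:
    """Timing, carryover and detector parameters of the MS signal chain.

    ``transit_delay`` is the droplet/ion travel time from the source region
    to the detector (s); ``mixing_tau`` the carryover time constant of the
    causal exponential blending kernel (s, 0 disables blending);
    ``dwell``/``event`` the SIM duty cycle (ions are detected only during
    the first ``dwell`` of each ``event``); ``gain`` converts integrated
    arrival flux to intensity counts and ``detector_noise_sd`` is additive
    Gaussian detector noise (counts, clipped at zero).
    """

    transit_delay: float = 1e-3
    mixing_tau: float = 5e-3
    dwell: float = 0.8e-3
    event: float = 4e-3
    detector_noise_sd: float = 500.0
    gain: float = 2500.0

    def __post_init__(self) -> None:
        if not 0 < self.dwell <= self.event:
            raise ValueError("dwell must satisfy 0 < dwell <= event")
        if self.mixing_tau < 0 or self.transit_delay < 0:
            raise ValueError("mixing_tau and transit_delay must be non-negative")


@dataclass
class MsTrace:
    """SIM ion-current trace: one intensity per acquisition event."""

    event_times: np.ndarray
    intensity: np.ndarray
    mz_label: float = 152.0

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.event_times) != len(self.intensity):
            raise ValueError("one intensity per event required")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.intensity)


def apply_gate(train: EmissionTrain, gate: GateWaveform) -> EmissionTrain:
    """Multiply the emission flux by the gate transmission.

    The cone state is untouched: the Taylor cone exists at the emitter
    regardless of whether the downstream plume gate passes the plume.
    """
    transmission = gate.transmission(train.times)
    return EmissionTrain(
        train.flux * transmission, train.cone_state.copy(), train.dt, train.t0
    )


def transit_mixing(train: EmissionTrain, params: ChainParams) -> np.ndarray:
    """Arrival flux at the detector: delayed and carryover-blended emission.

    The emission flux is delayed by ``transit_delay`` and convolved with a
    causal exponential kernel of time constant ``mixing_tau`` normalized to
    unit area (an order-one mixing-volume model of ion retention in the
    atmospheric interface and ion guides).  ``mixing_tau = 0`` is a pure
    delay.  Total flux is conserved up to the tail truncated at the end of
    the window.
    """
    flux = train.flux
    n = flux.size
    if n == 0:
        return flux.copy()
    shift = int(round(params.transit_delay / train.dt))
    delayed = np.zeros(n)
    if shift < n:
        delayed[shift:] = flux[: n - shift]
    if params.mixing_tau == 0.0:
        return delayed
    if train.dt > params.mixing_tau / 5:
        raise ValueError("grid step must be well below mixing_tau")
    alpha = math.exp(-train.dt / params.mixing_tau)
    # Discrete kernel k[j] = (1 - alpha) * alpha**j sums exactly to 1.
    return lfilter([1.0 - alpha], [1.0, -alpha], delayed)


def _event_starts(duration: float, event: float) -> np.ndarray:
    n_events = int(math.floor(duration / event + 1e-9))
    return event * np.arange(n_events)


def sample_sim_events(
    arrival: np.ndarray,
    dt: float,
    params: ChainParams,
    duration: float,
    seed: int,
    *,
    t0: float = 0.0,
    mz_label: float = 152.0,
) -> MsTrace:
    """Sample arrival flux into SIM event intensities.

    Each acquisition event starting at ``k * event`` integrates
    ``gain x arrival`` over its first ``dwell`` seconds only; ions arriving
    during the remaining ``event - dwell`` are lost to data transfer.
    Additive Gaussian detector noise is applied and intensities clipped at
    zero.
    """
    if duration < params.event:
        raise ValueError("duration must cover at least one event")
    starts = _event_starts(duration, params.event)
    arrival = np.asarray(arrival, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(arrival)]) * dt
    i0 = np.clip(np.rint((starts - t0) / dt), 0, arrival.size).astype(np.int64)
    i1 = np.clip(
        np.rint((starts + params.dwell - t0) / dt), 0, arrival.size
    ).astype(np.int64)
    intensity = params.gain * (csum[i1] - csum[i0])
    if params.detector_noise_sd:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDE7]))
        intensity = intensity + params.detector_noise_sd * rng.standard_normal(
            intensity.size
        )
    return MsTrace(starts, np.clip(intensity, 0.0, None), mz_label)


def sample_continuous_events(
    arrival: np.ndarray,
    dt: float,
    params: ChainParams,
    duration: float,
    *,
    t0: float = 0.0,
    align_to_transit: bool = True,
) -> MsTrace:
    """Idealized sampler: integrate the full event window, no detector noise.

    This is the duty-cycle-free, noise-free counterpart of
    :func:`sample_sim_events`, used to demonstrate that the occupancy/
    intensity correlation survives when the chain's losses are removed.
    With ``align_to_transit`` the event grid is phase-shifted by the known
    transit delay so each event window covers the arrival of exactly one
    emission window — otherwise the grid phase reintroduces a misalignment
    artifact that nearest-event matching (4 ms resolution) cannot undo.
    """
    ideal = replace(params, dwell=params.event, detector_noise_sd=0.0)
    offset = params.transit_delay if align_to_transit else 0.0
    trace = sample_sim_events(
        arrival[int(round(offset / dt)):], dt, ideal, duration - offset,
        seed=0, t0=t0,
    )
    return MsTrace(trace.event_times + offset, trace.intensity, trace.mz_label)


def run_gated_experiment(
    preset: SprayPreset,
    chain: ChainParams,
    gate: GateWaveform,
    duration: float,
    seed: int,
    *,
    frame_rate: float = 5000.0,
    bin_size: int | None = None,
    geometry: DetectionGeometry | None = None,
    pixel_noise_sd: float | None = None,
    continuous_sampling: bool = False,
) -> tuple[OccupancyTrace, MsTrace]:
    """End-to-end simulated acquisition: one run of the offline experiment.

    A single emission train drives both channels: the imaging side renders
    a shadowgraph stack at ``frame_rate``, classifies every frame with the
    reference-line detector and bins presence into occupancy percentages
    (bin size defaults to one MS event of frames, i.e. 20 frames at 5 kfps
    with the 4 ms event); the MS side passes the same train through gate,
    transit carryover and SIM event sampling.  The two outputs share the
    4 ms grid and are ready for :func:`conepulse.correlation.shift_scan`.
    """
    from .synthetic import generate_emission_train

    train = generate_emission_train(preset, duration, seed)
    settings = AcquisitionSettings(frame_rate=frame_rate, duration=duration)
    render_kwargs = {}
    if pixel_noise_sd is not None:
        render_kwargs["noise_sd"] = pixel_noise_sd
    stack = render_shadowgraph_stack(train, settings, preset, seed, **render_kwargs)
    geometry = geometry or geometry_for_preset(preset)
    cone_trace = analyze_stack(stack, geometry)
    if bin_size is None:
        bin_size = int(round(chain.event * frame_rate))
    occupancy = bin_occupancy(cone_trace, bin_size)

    gated = apply_gate(train, gate)
    arrival = transit_mixing(gated, chain)
    if continuous_sampling:
        ms = sample_continuous_events(arrival, train.dt, chain, duration)
    else:
        ms = sample_sim_events(arrival, train.dt, chain, duration, seed)
    return occupancy, ms
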