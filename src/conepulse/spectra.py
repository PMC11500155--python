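"""FFT frequency estimation for pixel-count and spray-current traces.

The meniscus (Taylor-cone) oscillation frequency is estimated from the
per-frame black-pixel-count trace of the offline 50 kfps imaging channel,
and independently from the Faraday-plate spray current sampled at 20 us;
agreement of the two peak frequencies (within one FFT bin) is the coupled
two-channel check.  Spectra are one-sided magnitude spectra of the
mean-subtracted, Hann-windowed trace; peaks are searched above 100 Hz to
exclude DC and drift, with no sub-bin interpolation (quadratic refinement
is available but off by default — bin precision matches the precision the
estimates are quoted at).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window

__all__ = [
    "Spectrum",
    "ChannelComparison",
    "UndersamplingWarning",
    "compute_spectrum",
    "peak_frequency",
    "compare_channels",
    "coupled_offline_dataset",
    "frequency_sweep",
]

DC_EXCLUSION_HZ = 100.0


class UndersamplingWarning(UserWarning):
    """The sampling rate is too low to resolve the oscillation cleanly."""


@dataclass
class Spectrum:
    """One-sided magnitude spectrum of a uniformly sampled trace."""

    frequencies: np.ndarray
    magnitude: np.ndarray
    source_rate: float
    window_label: str = "hann"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.frequencies.shape != self.magnitude.shape:
            raise ValueError("frequency and magnitude grids must match")
        if np.any(self.magnitude < 0) or not np.all(np.isfinite(self.magnitude)):
            raise ValueError("magnitudes must be finite and non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def nyquist(self) -> float:
        return 0.5 * self.source_rate


def compute_spectrum(
    values: np.ndarray,
    rate: float,
    window: str = "hann",
    *,
    times: np.ndarray | None = None,
) -> Spectrum:
    """One-sided magnitude spectrum of a mean-subtracted, windowed trace.

    ``times``, if given, is checked for grid uniformity (1% of the median
    step); non-uniform input is rejected with a hint to resample first.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 64:
        raise ValueError("at least 64 samples are required")
    if times is not None:
        steps = np.diff(np.asarray(times, dtype=float))
        med = np.median(steps)
        if med <= 0 or np.any(np.abs(steps - med) > 0.01 * med):
            raise ValueError(
                "timestamps are not on a uniform grid; resample explicitly first"
            )
    w = get_window(window, values.size, fftbins=True)
    x = (values - values.mean()) * w
    mag = np.abs(np.fft.rfft(x)) * 2.0 / w.sum()
    freqs = np.fft.rfftfreq(values.size, d=1.0 / rate)
    return Spectrum(freqs, mag, float(rate), window)


def peak_frequency(
    spectrum: Spectrum,
    band: tuple[float, float] | None = None,
    *,
    expected_hz: float | None = None,
    refine: bool = False,
) -> float:
    """Frequency of the largest magnitude inside a band, Hz.

    The default band is (100 Hz, Nyquist], excluding DC and slow drift.
    Ties break toward the lower frequency.  An :class:`UndersamplingWarning`
    is emitted when the estimate lands within one bin of Nyquist, or when
    ``expected_hz`` is given and the source rate is below 2x that frequency
    — the regime in which the online 5 kfps data cannot be Fourier-analyzed
    and is binned instead.
    """
    lo, hi = band if band is not None else (DC_EXCLUSION_HZ, spectrum.nyquist)
    if hi is None:
        hi = spectrum.nyquist
    if not 0 <= lo < hi or lo >= spectrum.nyquist:
        raise ValueError(f"invalid frequency band ({lo}, {hi})")
    hi = min(hi, spectrum.nyquist)
    mask = (spectrum.frequencies > lo) & (spectrum.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"band ({lo}, {hi}) Hz contains no FFT bins")
    idx = np.nonzero(mask)[0]
    best = idx[np.argmax(spectrum.magnitude[idx])]
    f_est = float(spectrum.frequencies[best])
    if refine and 0 < best < spectrum.frequencies.size - 1:
        a, b, c = spectrum.magnitude[best - 1 : best + 2]
        denom = a - 2 * b + c
        if denom != 0:
            f_est += 0.5 * (a - c) / denom * spectrum.bin_width
    if expected_hz is not None and spectrum.source_rate < 2 * expected_hz:
        warnings.warn(
            f"rate {spectrum.source_rate:g} Hz is below twice the expected "
            f"{expected_hz:g} Hz oscillation; the peak is aliased",
            UndersamplingWarning,
            stacklevel=2,
        )
    elif f_est >= spectrum.nyquist - spectrum.bin_width:
        warnings.warn(
            "estimated peak lies within one bin of Nyquist; increase the "
            "sampling rate",
            UndersamplingWarning,
            stacklevel=2,
        )
    return f_est


@dataclass
class ChannelComparison:
    """Peak frequencies of the image and current channels and their gap."""

    f_pixel: float
    f_current: float
    delta_f: float
    agree: bool
    pixel_bin_width: float
    current_bin_width: float


def compare_channels(
    pixel_trace: np.ndarray,
    current_trace: np.ndarray,
    pixel_rate: float,
    current_rate: float,
    *,
    band: tuple[float, float] | None = None,
    expected_hz: float | None = None,
) -> ChannelComparison:
    """Compare meniscus-oscillation and spray-current peak frequencies.

    Agreement is flagged when the absolute difference does not exceed the
    larger of the two FFT bin widths.
    """
    spec_px = compute_spectrum(np.asarray(pixel_trace, float), pixel_rate)
    spec_cur = compute_spectrum(np.asarray(current_trace, float), current_rate)
    f_px = peak_frequency(spec_px, band, expected_hz=expected_hz)
    f_cur = peak_frequency(spec_cur, band, expected_hz=expected_hz)
    delta = abs(f_px - f_cur)
    tol = max(spec_px.bin_width, spec_cur.bin_width)
    return ChannelComparison(
        f_px, f_cur, delta, delta <= tol + 1e-12,
        spec_px.bin_width, spec_cur.bin_width,
    )


def coupled_offline_dataset(
    voltage: float,
    seed: int,
    *,
    duration: float = 1.0,
    frame_rate: float = 50_000.0,
    current_step: float = 20e-6,
    current_noise_sd: float = 50.0,
):
    """Generate the offline two-channel dataset from a single spray process.

    One emission train drives both a 50 kfps shadowgraph stack (analyzed
    into a per-frame black-pixel-count trace) and a Faraday-plate current
    trace sampled every 20 us.  Returns ``(cone_trace, current_trace,
    preset)``.
    """
    from .detection import analyze_stack, geometry_for_preset
    from .synthetic import (
        AcquisitionSettings,
        generate_current_trace,
        generate_emission_train,
        make_preset,
        render_shadowgraph_stack,
    )

    preset = make_preset(voltage)
    train = generate_emission_train(preset, duration, seed)
    settings = AcquisitionSettings(frame_rate=frame_rate, duration=duration)
    stack = render_shadowgraph_stack(train, settings, preset, seed)
    cone_trace = analyze_stack(stack, geometry_for_preset(preset))
    current = generate_current_trace(
        train, current_step, current_noise_sd, seed,
        pulsation_frequency=preset.pulsation_frequency or None,
    )
    return cone_trace, current, preset


def frequency_sweep(
    voltages,
    seed: int,
    *,
    duration: float = 1.0,
    frame_rate: float = 50_000.0,
) -> pd.DataFrame:
    """Per-voltage image/current peak-frequency pairs (offline sweep).

    Returns a table with columns ``voltage_kv, f_pixel_hz, f_current_hz,
    delta_hz, agree`` — the two-channel frequency trend across emitter
    voltages.
    """
    rows = []
    for v in voltages:
        cone_trace, current, preset = coupled_offline_dataset(
            v, seed, duration=duration, frame_rate=frame_rate
        )
        cmp = compare_channels(
            cone_trace.black_count.astype(float),
            current.current,
            frame_rate,
            current.rate,
            expected_hz=preset.pulsation_frequency or None,
        )
        rows.append((v, cmp.f_pixel, cmp.f_current, cmp.delta_f, cmp.agree))
    return pd.DataFrame(
        rows, columns=["voltage_kv", "f_pixel_hz", "f_current_hz", "delta_hz", "agree"]
    )
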