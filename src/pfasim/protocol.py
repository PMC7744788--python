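"""AC burst waveform synthesis and ECG-gated burst-train scheduling.

The therapy waveform is a charge-balanced square AC burst: a short train of
bipolar oscillations (default 100 kHz internal frequency for 100 us, i.e. ten
full cycles per burst) delivered once per heartbeat, a fixed delay after the
R wave so that the shock lands inside the ventricular effective refractory
period.

Duty cycle is interpreted as the on-time fraction of the waveform: within
each half-cycle the voltage sits at +/-V for ``duty`` of the half-period and
at zero for the rest, centered so the burst stays charge balanced.  With
``duty = 1`` the waveform degenerates to a continuous bipolar square wave;
both readings of "50% duty cycle" are therefore available (see
``BurstSpec.duty``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BurstSpec",
    "GatingSchedule",
    "synthesize_burst",
    "duty_power_factor",
    "detect_r_peaks",
    "schedule_bursts",
]

#: Delay window (ms) after the R peak inside which delivery is considered safe.
GATING_DELAY_WINDOW_MS = (50.0, 75.0)

#: Lockout (s) after a detected R peak during which no new peak is accepted.
R_PEAK_REFRACTORY_S = 0.200


@dataclass(frozen=True)
class BurstSpec:
    """Parameters of one AC burst.

    Parameters
    ----------
    amplitude_volts:
        Plateau voltage of the square oscillation (V, > 0).
    duration_us:
        Burst duration in microseconds.
    internal_freq_khz:
        Internal oscillation frequency in kHz.
    duty:
        On-time fraction in (0, 1].  ``0.5`` means the voltage is applied for
        half of the burst; ``1.0`` is a continuous bipolar square wave.
    n_bursts:
        Number of bursts in the train (60 for atrial, 120 for septal
        applications).
    max_generator_volts:
        Hard amplitude ceiling of the pulse generator.
    """

    amplitude_volts: float
    duration_us: float = 100.0
    internal_freq_khz: float = 100.0
    duty: float = 0.5
    n_bursts: int = 60
    max_generator_volts: float = 1500.0

    def __post_init__(self) -> None:
        if self.amplitude_volts <= 0:
            raise ValueError("amplitude_volts must be > 0")
        if self.amplitude_volts > self.max_generator_volts:
            raise ValueError(
                f"amplitude {self.amplitude_volts} V exceeds generator maximum "
                f"{self.max_generator_volts} V"
            )
        if not (0.0 < self.duty <= 1.0):
            raise ValueError("duty must lie in (0, 1]")
        if self.n_bursts < 1:
            raise ValueError("n_bursts must be >= 1")
        n_cyc = self.duration_us * self.internal_freq_khz / 1000.0
        if n_cyc <= 0 or abs(n_cyc - round(n_cyc)) > 1e-9:
            raise ValueError(
                f"duration x frequency must give a whole number of cycles per "
                f"burst, got {n_cyc}"
            )

    @property
    def n_cycles(self) -> int:
        """Number of full bipolar oscillations per burst."""
        return int(round(self.duration_us * self.internal_freq_khz / 1000.0))

    @property
    def duration_s(self) -> float:
        return self.duration_us * 1e-6


@dataclass(frozen=True)
class GatingSchedule:
    """ECG-gated burst train: one burst per detected beat."""

    r_peak_times_s: np.ndarray
    delay_ms: float
    burst_times_s: np.ndarray
    mean_interburst_s: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if np.any(np.diff(self.burst_times_s) <= 0):
            raise ValueError("burst times must be strictly increasing")


def synthesize_burst(spec: BurstSpec, sample_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample one AC burst.

    Returns ``(t, v)``: sample times (s, cell-centered) and voltages (V).
    The waveform contains exactly ``spec.n_cycles`` bipolar cycles; within
    each half-cycle the on-phase (at +/-V) is centered and lasts ``duty`` of
    the half-period, which keeps positive and negative lobes mirror images of
    each other and the burst charge balanced.

    Raises
    ------
    ValueError
        If the sampling rate is below 20x the internal frequency (fewer than
        two samples per on-phase at duty 0.1 would alias the waveform).
    """
    f_hz = spec.internal_freq_khz * 1e3
    if sample_rate_hz < 20.0 * f_hz:
        raise ValueError(
            f"sample_rate_hz must be >= 20x internal frequency "
            f"({20.0 * f_hz:.0f} Hz), got {sample_rate_hz:.0f}"
        )
    n = int(round(spec.duration_s * sample_rate_hz))
    t = (np.arange(n) + 0.5) / sample_rate_hz
    # phase within the cycle, in [0, 1); snapped to 1e-12 so the on/off
    # boundary comparisons behave identically in both half-cycles (exact
    # charge balance)
    phase = np.round((t * f_hz) % 1.0, 12)
    # position within the half-cycle, in [0, 0.5), snapped again so both
    # half-cycles see bit-identical boundary values
    half = np.round(phase - np.where(phase < 0.5, 0.0, 0.5), 12)
    on_lo = 0.25 * (1.0 - spec.duty)
    on_hi = 0.25 * (1.0 + spec.duty)
    on = (half >= on_lo) & (half < on_hi)
    sign = np.where(phase < 0.5, 1.0, -1.0)
    v = np.where(on, sign * spec.amplitude_volts, 0.0)
    return t, v


def duty_power_factor(spec: BurstSpec) -> float:
    """Time-averaged Joule scaling of the burst.

    Mean of ``(v(t)/V)**2`` over one burst — the factor by which the on-off
    waveform scales the continuous-wave heating power.  For the centered
    square waveform this is exactly the duty.
    """
    return spec.duty


def detect_r_peaks(
    ecg: np.ndarray,
    threshold: float,
    sample_rate_hz: float,
    refractory_s: float = R_PEAK_REFRACTORY_S,
    smooth_s: float = 0.005,
    merge_s: float = 0.020,
) -> np.ndarray:
    """Detect R peaks as local maxima of over-threshold excursions.

    Mimics the gating circuit: every contiguous run of samples above
    ``threshold`` yields one detection at its maximum, and a refractory
    lockout (default 200 ms, below the shortest physiological R-R at the
    observed heart rates) suppresses double counting of a single QRS.
    The peak is localized on a lightly smoothed copy of the trace
    (``smooth_s`` moving average, default 5 ms) so sample noise does not
    jitter the detection time; thresholding uses the raw trace, and
    excursions separated by less than ``merge_s`` (default 20 ms, within
    one QRS complex) are merged so noise blips on the QRS shoulders do not
    fire early detections.

    Parameters
    ----------
    ecg:
        Uniformly sampled trace (mV, lead III convention).
    threshold:
        Detection threshold, same units as the trace; must be > 0.
    sample_rate_hz:
        Sampling rate of the trace.

    Returns
    -------
    np.ndarray
        Peak times in seconds; empty for a flat or all-subthreshold trace.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ecg = np.asarray(ecg, dtype=float)
    above = ecg > threshold
    if not above.any():
        return np.empty(0)
    win = max(int(round(smooth_s * sample_rate_hz)), 1)
    if win > 1:
        kernel = np.ones(win) / win
        loc = np.convolve(ecg, kernel, mode="same")
    else:
        loc = ecg
    # contiguous over-threshold excursions
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]
    # merge excursions separated by less than merge_s (same QRS complex)
    gap = max(int(round(merge_s * sample_rate_hz)), 1)
    merged_starts = [int(starts[0])]
    merged_stops = [int(stops[0])]
    for s, e in zip(starts[1:], stops[1:]):
        if s - merged_stops[-1] < gap:
            merged_stops[-1] = int(e)
        else:
            merged_starts.append(int(s))
            merged_stops.append(int(e))
    starts, stops = merged_starts, merged_stops
    peaks = []
    last_t = -np.inf
    for s, e in zip(starts, stops):
        i = s + int(np.argmax(loc[s:e]))
        t_i = i / sample_rate_hz
        if t_i - last_t >= refractory_s:
            peaks.append(t_i)
            last_t = t_i
    return np.asarray(peaks)


def schedule_bursts(
    r_peaks: np.ndarray, delay_ms: float, n_bursts: int
) -> GatingSchedule:
    """Build an ECG-gated burst schedule: one burst per beat, fixed delay.

    The delay must lie in the observed safe window [50, 75] ms after the
    R peak; values outside are rejected outright rather than clamped.
    """
    lo, hi = GATING_DELAY_WINDOW_MS
    if not (lo <= delay_ms <= hi):
        raise ValueError(
            f"delay_ms must lie in the safe window [{lo:g}, {hi:g}] ms, "
            f"got {delay_ms:g}"
        )
    r_peaks = np.asarray(r_peaks, dtype=float)
    if r_peaks.size < n_bursts:
        raise ValueError(
            f"need at least {n_bursts} detected beats, got {r_peaks.size}"
        )
    used = r_peaks[:n_bursts]
    bursts = used + delay_ms / 1000.0
    mean_rr = float(np.mean(np.diff(used))) if n_bursts >= 2 else float("nan")
    return GatingSchedule(
        r_peak_times_s=used,
        delay_ms=float(delay_ms),
        burst_times_s=bursts,
        mean_interburst_s=mean_rr,
    )
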