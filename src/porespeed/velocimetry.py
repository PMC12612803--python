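"""Through-transmission velocimetry by the substitution method.

The substitution method compares a signal transmitted through a sample
against a water-only reference over the same total path and converts the
arrival-time difference ``dt`` into a composite velocity through the sample
thickness ``d``:

    V = C_w / (1 + C_w * dt / d),

with ``C_w`` the speed of sound in water.  ``dt`` is negative when the
sample path is faster than water.  Three delay estimators are provided:

* group delay — lag of the peak of the normalized cross-correlation between
  the signal and reference envelopes (Hilbert magnitude);
* phase delay — unwrapped Fourier phase difference at the carrier after 4x
  zero padding, ``dt = dphi(f_c) / (2 pi f_c)``;
* steady-state phase — timing of the first post-transient peak of a
  continuous-wave record relative to the reference, expressed in radians.

All estimators deliberately use the full recorded signal rather than a
windowed ballistic portion, so reflections inside the sample contribute to
the estimates; this is a property of the measurement definition, not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
import scipy.signal

__all__ = [
    "DelayEstimate",
    "VelocityField",
    "PhaseField",
    "PhaseHistogram",
    "substitution_velocity",
    "envelope",
    "group_delay",
    "phase_delay",
    "steady_state_phase",
    "plane_statistics",
    "phase_histogram",
    "velocity_field",
]

#: Histogram bin width: one sixteenth of a period.
PHASE_BIN_WIDTH = 2 * np.pi / 16
#: Goodman phase-precision criterion: two histogram bins.
GOODMAN_SPREAD = 2 * PHASE_BIN_WIDTH


@dataclass(frozen=True)
class DelayEstimate:
    """An arrival-time difference relative to the water reference."""

    delta_t: float  # s; negative = faster than water
    method: str  # "group" | "phase"
    peak_correlation: float | None = None  # group method only

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_t):
            raise ValueError("delta_t must be finite")
        if (self.peak_correlation is not None) != (self.method == "group"):
            raise ValueError("peak_correlation present iff method='group'")


@dataclass
class VelocityField:
    """Per-pixel velocities over the measurement plane plus summaries."""

    values: np.ndarray  # m/s
    method: str
    center_frequency: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values))  # population (n) denominator


@dataclass
class PhaseField:
    """Per-pixel steady-state phase (radians, wrapped to [0, 2 pi))."""

    values: np.ndarray
    center_frequency: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values))


@dataclass
class PhaseHistogram:
    """16-bin probability histogram of wrapped phases."""

    probabilities: np.ndarray  # sums to 1
    bin_width: float
    offset: float
    goodman_pass: bool


def substitution_velocity(delta_t: float, thickness: float,
                          water_speed: float = 1500.0) -> float:
    """Composite velocity from the substitution equation.

    ``V = C_w / (1 + C_w * delta_t / d)``; raises if the implied transit
    time ``d / C_w + delta_t`` is not positive.
    """
    denom = 1.0 + water_speed * np.asarray(delta_t) / thickness
    if np.any(denom <= 0):
        raise ValueError(
            "nonphysical delay: sample transit time would be <= 0")
    return water_speed / denom


def envelope(series: np.ndarray) -> np.ndarray:
    """Signal envelope: magnitude of the analytic signal (Hilbert)."""
    return np.abs(scipy.signal.hilbert(np.asarray(series, float), axis=-1))


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location and height via three-point parabola."""
    if i == 0 or i == len(y) - 1:
        return float(i), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    peak = y1 - 0.25 * (y0 - y2) * delta
    return i + delta, float(peak)


def group_delay(signal: np.ndarray, reference: np.ndarray, dt: float,
                refine: bool = False) -> DelayEstimate:
    """Envelope cross-correlation delay.

    Normalized cross-correlation of the two Hilbert envelopes; the lag at
    the peak is the group arrival-time difference, negative when the signal
    leads the reference.  The default takes the discrete argmax: at the
    sub-nanosecond sampling used here the quantization is far below the
    estimate scale, and the envelope correlation peak is flat enough that
    parabolic refinement (``refine=True``) mostly amplifies asymmetry of
    the envelope tails.
    """
    signal = np.asarray(signal, float)
    reference = np.asarray(reference, float)
    if signal.shape != reference.shape or signal.ndim != 1:
        raise ValueError("signal and reference must be equal-length 1-D series")
    es = envelope(signal)
    er = envelope(reference)
    norm = np.sqrt(np.sum(es ** 2) * np.sum(er ** 2))
    if norm == 0:
        raise ValueError("zero-variance envelope: correlation undefined")
    xc = scipy.signal.correlate(es, er, mode="full", method="fft") / norm
    i = int(np.argmax(xc))
    if refine:
        loc, peak = _parabolic_refine(xc, i)
    else:
        loc, peak = float(i), float(xc[i])
    lag = loc - (len(er) - 1)
    return DelayEstimate(delta_t=lag * dt, method="group",
                         peak_correlation=min(peak, 1.0))


def _unwrap_from_dc(phase: np.ndarray) -> np.ndarray:
    """Cumulative-increment unwrapping starting at the bin adjacent to DC.

    Each phase increment between adjacent Fourier coefficients is mapped
    into (-pi, pi] before accumulation.  The sum is anchored at the *first
    non-DC* bin (its wrapped phase, necessarily small for broadband records
    padded to fine frequency resolution); the DC bin itself is excluded
    because any small rectified offset in a recorded trace flips its phase
    to pi and would shift the whole unwrapped curve.  The returned DC entry
    is set to zero.
    """
    inc = np.diff(phase[..., 1:], axis=-1)
    inc = -((-inc + np.pi) % (2 * np.pi) - np.pi)  # wrap into (-pi, pi]
    anchor = phase[..., 1:2]
    out = np.concatenate(
        [np.zeros_like(anchor), anchor,
         anchor + np.cumsum(inc, axis=-1)], axis=-1)
    return out


def phase_delay(signal: np.ndarray, reference: np.ndarray, dt: float,
                center_frequency: float, pad_factor: int = 4) -> DelayEstimate:
    """Fourier phase delay at the carrier frequency.

    Both series are zero-padded to ``pad_factor`` times their length; the
    per-bin phase difference ``angle(reference * conj(signal))`` is unwrapped
    from the DC bin outward, and evaluated at the discrete bin nearest the
    carrier: ``dt = dphi(f_c) / (2 pi f_c)``.  Positive ``dphi`` means the
    signal arrives later than the reference.
    """
    d = _phase_delay_field(np.asarray(signal, float)[None, :],
                           np.asarray(reference, float), dt,
                           center_frequency, pad_factor)
    return DelayEstimate(delta_t=float(d[0]), method="phase")


def _phase_delay_field(signals: np.ndarray, reference: np.ndarray, dt: float,
                       center_frequency: float, pad_factor: int = 4) -> np.ndarray:
    """Vectorized phase delay: ``signals`` is (..., n), one delay per pixel."""
    n = signals.shape[-1]
    if reference.shape != (n,):
        raise ValueError("reference must be a 1-D series of matching length")
    n_pad = pad_factor * n
    f = sfft.rfftfreq(n_pad, d=dt)
    if center_frequency <= 0 or center_frequency > f[-1]:
        raise ValueError("carrier frequency outside the resolvable band")
    S = sfft.rfft(signals, n=n_pad, axis=-1)
    R = sfft.rfft(reference, n=n_pad)
    dphi = _unwrap_from_dc(np.angle(R * np.conj(S)))
    i_c = int(np.argmin(np.abs(f - center_frequency)))
    # divide by the bin actually evaluated so a pure delay is recovered
    # exactly even when the carrier falls between bins
    return dphi[..., i_c] / (2 * np.pi * f[i_c])


def steady_state_phase(signal: np.ndarray, reference: np.ndarray, dt: float,
                       center_frequency: float, duration: float,
                       settle_fraction: float = 0.9,
                       refine: bool = True) -> float:
    """Steady-state phase from post-transient peak timing.

    Finds the first local maximum of each continuous-wave series after
    ``settle_fraction`` of the run duration (sub-sample parabolic
    refinement), converts the peak-time difference to a phase via the
    angular frequency, and wraps to ``[0, 2 pi)``.
    """
    t_peaks = []
    for series in (np.asarray(signal, float), np.asarray(reference, float)):
        i0 = int(np.ceil(settle_fraction * duration / dt))
        if i0 >= series.shape[-1] - 1:
            raise ValueError("record does not cover the post-transient window")
        seg = series[i0:]
        interior = np.nonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]))[0]
        if interior.size == 0:
            raise ValueError("no local maximum in the post-transient window")
        i = int(interior[0]) + 1
        loc = _parabolic_refine(seg, i)[0] if refine else float(i)
        t_peaks.append((i0 + loc) * dt)
    phi = 2 * np.pi * center_frequency * (t_peaks[0] - t_peaks[1])
    return float(np.mod(phi, 2 * np.pi))


def plane_statistics(field: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation over all pixels."""
    field = np.asarray(field, float)
    if field.size == 0:
        raise ValueError("empty field")
    return float(np.mean(field)), float(np.std(field))


def phase_histogram(phases: np.ndarray, offset: float = 0.0,
                    bin_width: float = PHASE_BIN_WIDTH,
                    goodman_mass: float = 0.95) -> PhaseHistogram:
    """Probability histogram of wrapped phases in 2 pi / bin_width bins.

    ``offset`` is added before wrapping (the usual trick to keep a tight
    distribution away from the wrap point).  ``goodman_pass`` is true when
    at least ``goodman_mass`` of the probability lies within two adjacent
    bins — the 2 pi / 8 Goodman precision criterion for phased-array
    focusing.
    """
    phases = np.asarray(phases, float).ravel()
    n_bins = int(round(2 * np.pi / bin_width))
    wrapped = np.mod(phases + offset, 2 * np.pi)
    counts, _ = np.histogram(wrapped, bins=n_bins, range=(0, 2 * np.pi))
    probs = counts / counts.sum()
    pair = probs + np.roll(probs, -1)  # mass of each adjacent-bin pair
    return PhaseHistogram(
        probabilities=probs,
        bin_width=bin_width,
        offset=offset,
        goodman_pass=bool(pair.max() >= goodman_mass),
    )


def velocity_field(record_pressure: np.ndarray, reference: np.ndarray,
                   dt: float, center_frequency: float, method: str,
                   thickness: float = 8e-3,
                   water_speed: float = 1500.0) -> VelocityField:
    """Per-pixel group or phase velocity over a measurement plane.

    ``record_pressure`` has shape ``transverse_dims + (n,)``; ``reference``
    is the single water-only trace (spatially uniform for a plane source).
    Returns the per-pixel substitution velocities with plane statistics.
    """
    press = np.asarray(record_pressure, float)
    flat = press.reshape(-1, press.shape[-1])
    if method == "phase":
        delays = _phase_delay_field(flat, np.asarray(reference, float), dt,
                                    center_frequency)
    elif method == "group":
        delays = np.array([
            group_delay(tr, reference, dt).delta_t for tr in flat])
    else:
        raise ValueError(f"unknown method {method!r}")
    vals = substitution_velocity(delays, thickness, water_speed)
    return VelocityField(values=np.asarray(vals).reshape(press.shape[:-1]),
                         method=method, center_frequency=center_frequency)
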