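"""Synthetic two-channel photometry recordings with known ground truth.

The generator produces a shared slow bleach plus motion bumps in both
channels, and dopamine-like transients in the 465 channel only, so that the
isosbestic regression correction is meaningfully testable. Transients are
injected multiplicatively: a transient of amplitude ``A`` (dFF %) scales the
local artifact-only signal by ``1 + A/100 * k(t)`` with a kernel ``k``
normalized to unit peak, so downstream dFF recovers ``A`` exactly in the
noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidParameterError
from ..photometry import PhotometryRecording

__all__ = [
    "PhotometryGroundTruth",
    "AmphetamineGroundTruth",
    "transient_kernel",
    "simulate_photometry",
    "simulate_amphetamine_session",
]


@dataclass
class PhotometryGroundTruth:
    """Generative parameters for one synthetic photometry session."""

    transient_times: np.ndarray = field(default_factory=lambda: np.array([]))
    transient_amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))
    kernel_rise_tau: float = 0.1
    kernel_decay_tau: float = 0.8
    bleach_tau: float = 1200.0
    bleach_amplitude: float = 20.0
    baseline: float = 100.0
    motion_events: list[tuple[float, float]] = field(default_factory=list)
    motion_tau: float = 0.5
    reference_gain: float = 1.2
    signal_offset: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.transient_times = np.atleast_1d(np.asarray(self.transient_times, float))
        self.transient_amplitudes = np.atleast_1d(
            np.asarray(self.transient_amplitudes, float)
        )
        if self.transient_times.size != self.transient_amplitudes.size:
            raise InvalidParameterError("transient times/amplitudes length mismatch")
        if self.kernel_rise_tau <= 0 or self.kernel_decay_tau <= 0:
            raise InvalidParameterError("kernel taus must be positive")
        if self.kernel_rise_tau >= self.kernel_decay_tau:
            raise InvalidParameterError("rise tau must be smaller than decay tau")
        if self.bleach_tau <= 0:
            raise InvalidParameterError("bleach tau must be positive")
        if np.any(self.transient_amplitudes < 0):
            raise InvalidParameterError("transient amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise sd must be >= 0")


def transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak, zero for t<0."""
    t = np.asarray(t, dtype=float)
    if rise_tau <= 0 or decay_tau <= 0 or rise_tau >= decay_tau:
        raise InvalidParameterError("require 0 < rise_tau < decay_tau")
    tt = np.maximum(t, 0.0)  # avoid overflow in exp for t < 0
    raw = np.where(t >= 0, np.exp(-tt / decay_tau) - np.exp(-tt / rise_tau), 0.0)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return raw / peak


def _motion_trace(t: np.ndarray, events: list[tuple[float, float]], tau: float) -> np.ndarray:
    out = np.zeros_like(t)
    for t0, amp in events:
        mask = t >= t0
        out[mask] += amp * np.exp(-(t[mask] - t0) / tau)
    return out


def simulate_photometry(
    truth: PhotometryGroundTruth, duration: float, fs: float
) -> PhotometryRecording:
    """Simulate a dual-channel recording from explicit ground truth.

    reference = bleach(t) + motion(t) + noise
    signal    = [gain * (bleach + motion) + offset] * (1 + sum of transients/100) + noise

    With zero noise and no transients the signal is an exact affine image of
    the reference, which is the identifiability condition for the regression
    correction.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    rng = np.random.default_rng(truth.seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    bleach = truth.baseline + truth.bleach_amplitude * np.exp(-t / truth.bleach_tau)
    motion = _motion_trace(t, truth.motion_events, truth.motion_tau)
    artifact = bleach + motion

    dff_frac = np.zeros(n)
    for t0, amp in zip(truth.transient_times, truth.transient_amplitudes):
        dff_frac += (amp / 100.0) * transient_kernel(
            t - t0, truth.kernel_rise_tau, truth.kernel_decay_tau
        )

    sig_base = truth.reference_gain * artifact + truth.signal_offset
    sig = sig_base * (1.0 + dff_frac)
    ref = artifact.copy()
    if truth.noise_sd > 0:
        sig = sig + rng.normal(0.0, truth.noise_sd, n)
        ref = ref + rng.normal(0.0, truth.noise_sd, n)

    return PhotometryRecording(time_s=t, sig_465=sig, ref_405=ref, fs=fs, truth=truth)


@dataclass
class AmphetamineGroundTruth:
    """Logistic-rise ground truth for an injection session."""

    injection_time_s: float
    plateau: float            # asymptotic dFF % above baseline
    rise_rate: float = 0.01   # logistic rate 1/s
    midpoint_s: float = 300.0  # seconds after injection to half-plateau
    noise_sd: float = 0.0
    seed: int = 0

    def latency_to_fraction(self, frac: float) -> float:
        """Time after injection at which the noiseless curve reaches
        ``frac * plateau`` (logistic inverse)."""
        if not 0 < frac < 1:
            raise InvalidParameterError("frac must be in (0, 1)")
        return self.midpoint_s + np.log(frac / (1 - frac)) / self.rise_rate


def simulate_amphetamine_session(
    truth: AmphetamineGroundTruth, duration: float, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (time_s, dff) for a session with a logistic post-injection rise."""
    if duration <= 0 or fs <= 0:
        raise InvalidParameterError("duration and fs must be positive")
    rng = np.random.default_rng(truth.seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rel = t - truth.injection_time_s
    dff = np.where(
        rel >= 0,
        truth.plateau / (1.0 + np.exp(-truth.rise_rate * (rel - truth.midpoint_s))),
        0.0,
    )
    if truth.noise_sd > 0:
        dff = dff + rng.normal(0.0, truth.noise_sd, n)
    return t, dff
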