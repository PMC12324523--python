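"""Synthetic stimulated FSCV sweeps with known amplitude and clearance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidParameterError
from ..fscv import FscvTrace

__all__ = ["FscvGroundTruth", "simulate_fscv_sweep"]


@dataclass(frozen=True)
class FscvGroundTruth:
    imax: float
    tau1_ms: float
    stim_time_s: float
    rise_time_s: float
    baseline: float
    noise_sd: float
    seed: int


def simulate_fscv_sweep(
    imax: float,
    tau1_ms: float,
    stim_time_s: float,
    fs: float = 200.0,
    duration_s: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rise_time_s: float = 0.2,
    baseline: float = 0.0,
    units: str = "uM",
    calibration_factor_um_per_pa: float | None = None,
) -> FscvTrace:
    """One stimulated transient: linear rise to ``imax`` then single-
    exponential decay with time constant ``tau1_ms``, plus Gaussian noise.

    The rise reaches exactly ``imax`` above baseline at
    ``stim_time_s + rise_time_s``, so the noiseless decay is exactly
    ``imax * exp(-(t - t_peak)/tau1)`` and the fitted Tau1 recovers the
    ground truth to discretization accuracy.
    """
    if imax <= 0:
        raise InvalidParameterError("imax must be positive")
    if tau1_ms <= 0:
        raise InvalidParameterError("tau1 must be positive")
    if fs <= 0 or rise_time_s <= 0:
        raise InvalidParameterError("fs and rise_time must be positive")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    tau_s = tau1_ms / 1000.0
    if duration_s is None:
        duration_s = stim_time_s + rise_time_s + 8.0 * tau_s
    if stim_time_s <= 0 or stim_time_s >= duration_s:
        raise InvalidParameterError("stim_time must fall inside the sweep")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    t_peak = stim_time_s + rise_time_s
    x = np.full(n, baseline, dtype=float)
    rising = (t >= stim_time_s) & (t < t_peak)
    x[rising] += imax * (t[rising] - stim_time_s) / rise_time_s
    decaying = t >= t_peak
    x[decaying] += imax * np.exp(-(t[decaying] - t_peak) / tau_s)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)

    truth = FscvGroundTruth(imax=imax, tau1_ms=tau1_ms, stim_time_s=stim_time_s,
                            rise_time_s=rise_time_s, baseline=baseline,
                            noise_sd=noise_sd, seed=seed)
    return FscvTrace(time_s=t, value=x, units=units, stim_time_s=stim_time_s,
                     calibration_factor_um_per_pa=calibration_factor_um_per_pa,
                     truth=truth)
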