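"""Synthetic epoch-binned rest-activity series with a 12:12 light schedule.

The recording starts at lights-on (ZT0). Activity follows a sinusoid peaking
mid-dark-phase, plus optional Gaussian noise and optional day-to-day phase
jitter, clipped to the normalized [0, 0.3] range. Sleep states are derived by
thresholding activity at its baseline.
"""

from __future__ import annotations

import numpy as np

from ..circadian import ACTIVITY_RANGE, ActivitySeries
from ..errors import InvalidParameterError

__all__ = ["simulate_activity"]


def simulate_activity(
    amplitude: float = 0.1,
    period_h: float = 24.0,
    epochs_per_day: int = 144,
    n_days: int = 5,
    noise_sd: float = 0.0,
    light_on_hour: float = 6.0,
    seed: int = 0,
    baseline: float = 0.15,
    phase_jitter_h: float = 0.0,
) -> ActivitySeries:
    """Generate ``n_days`` of epoch-binned activity with known structure.

    With ``noise_sd=0``, ``phase_jitter_h=0`` and ``period_h=24`` the series
    repeats exactly every 24 h, the perfect-zeitgeber-coupling limit. With
    ``amplitude=0`` and ``noise_sd>0`` it is pure i.i.d. Gaussian noise
    (clipped), the high-fragmentation limit.
    """
    if epochs_per_day < 24:
        raise InvalidParameterError("need at least 24 epochs per day")
    if epochs_per_day % 24 != 0:
        raise InvalidParameterError("epochs_per_day must be a multiple of 24")
    if n_days < 2:
        raise InvalidParameterError("need at least 2 days")
    if amplitude < 0 or noise_sd < 0 or phase_jitter_h < 0:
        raise InvalidParameterError("amplitude, noise_sd, jitter must be >= 0")
    if period_h <= 0:
        raise InvalidParameterError("period must be positive")

    rng = np.random.default_rng(seed)
    epoch_s = 86400.0 / epochs_per_day
    n = epochs_per_day * n_days
    start_s = np.arange(n) * epoch_s
    t_h = start_s / 3600.0

    if phase_jitter_h > 0:
        day = (np.arange(n) // epochs_per_day)
        shift = rng.normal(0.0, phase_jitter_h, n_days)[day]
    else:
        shift = 0.0
    # peak mid-dark (ZT18) for a 24-h period
    rhythm = amplitude * np.sin(2 * np.pi * (t_h - 12.0 + shift) / period_h)
    activity = baseline + rhythm
    if noise_sd > 0:
        activity = activity + rng.normal(0.0, noise_sd, n)
    activity = np.clip(activity, *ACTIVITY_RANGE)
    sleep_state = (activity < baseline).astype(int)

    # recording begins at lights-on, so ZT == recording hours
    return ActivitySeries(epoch_start_s=start_s, activity=activity,
                          sleep_state=sleep_state, epoch_s=epoch_s,
                          zt_offset_h=0.0)
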