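"""Rest-activity statistics from epoch-binned piezo data.

Implements the standard nonparametric actigraphy statistics on hourly-binned
activity — interdaily stability (IS, day-to-day constancy of the 24-h
profile, in [0, 1]) and intradaily variability (IV, hour-to-hour
fragmentation, 0 for a smooth sinusoid and approaching 2 for white noise) —
plus per-phase (light/dark) sleep and activity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "ActivitySeries",
    "CircadianMetrics",
    "PhaseSummary",
    "bin_hourly",
    "interdaily_stability",
    "intradaily_variability",
    "phase_summary",
]

ACTIVITY_RANGE = (0.0, 0.3)


@dataclass
class ActivitySeries:
    """Epoch-binned activity + sleep states under a 12:12 light schedule.

    ``zt_offset_h`` maps recording time to zeitgeber time: ZT of an epoch is
    ``(epoch_start_s/3600 + zt_offset_h) % 24`` with ZT0 = lights on. Light
    phase is ZT [0, 12), dark phase ZT [12, 24).
    """

    epoch_start_s: np.ndarray
    activity: np.ndarray
    sleep_state: np.ndarray
    epoch_s: float
    zt_offset_h: float = 0.0

    def __post_init__(self) -> None:
        self.epoch_start_s = np.asarray(self.epoch_start_s, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.sleep_state = np.asarray(self.sleep_state, dtype=int)
        n = self.epoch_start_s.size
        if self.activity.size != n or self.sleep_state.size != n:
            raise InvalidParameterError("series lengths differ")
        if self.epoch_s <= 0:
            raise InvalidParameterError("epoch duration must be positive")
        d = np.diff(self.epoch_start_s)
        if d.size and not np.allclose(d, self.epoch_s, rtol=1e-9):
            raise InvalidParameterError("epochs must be uniform and contiguous")
        lo, hi = ACTIVITY_RANGE
        if np.any(self.activity < lo - 1e-12) or np.any(self.activity > hi + 1e-12):
            raise InvalidParameterError(f"activity outside {ACTIVITY_RANGE}")

    @property
    def zt_hours(self) -> np.ndarray:
        return (self.epoch_start_s / 3600.0 + self.zt_offset_h) % 24.0

    @property
    def n_days(self) -> float:
        return self.epoch_start_s.size * self.epoch_s / 86400.0

    @property
    def is_light(self) -> np.ndarray:
        return self.zt_hours < 12.0


@dataclass(frozen=True)
class CircadianMetrics:
    IS: float
    IV: float
    bin_width_h: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.IS) and np.isfinite(self.IV)


@dataclass(frozen=True)
class PhaseSummary:
    phase: str  # "light" or "dark"
    pct_time_asleep: float
    mean_bout_length_s: float
    mean_activity: float
    activity_amplitude: float


def _require_days(s: ActivitySeries) -> None:
    if s.n_days < 2:
        raise InsufficientDataError("IS/IV require at least 2 recorded days")


def bin_hourly(s: ActivitySeries) -> np.ndarray:
    """Hourly mean activity as a 24 x n_days matrix indexed by ZT hour.

    Epochs must divide hours evenly; incomplete days are dropped wholesale.
    """
    per_hour = 3600.0 / s.epoch_s
    if abs(per_hour - round(per_hour)) > 1e-9:
        raise InvalidParameterError("epoch length must divide one hour evenly")
    per_hour = int(round(per_hour))
    zt_total = s.epoch_start_s / 3600.0 + s.zt_offset_h
    hour = np.floor(zt_total).astype(int)
    n_epochs = np.bincount(hour - hour.min())
    sums = np.bincount(hour - hour.min(), weights=s.activity)
    full = n_epochs == per_hour
    hourly = np.full(n_epochs.size, np.nan)
    hourly[full] = sums[full] / per_hour

    h0 = hour.min()
    zt_hour = (np.arange(n_epochs.size) + h0) % 24
    day = (np.arange(n_epochs.size) + h0) // 24
    out = []
    for d in np.unique(day):
        m = day == d
        if m.sum() == 24 and not np.isnan(hourly[m]).any():
            col = np.empty(24)
            col[zt_hour[m]] = hourly[m]
            out.append(col)
    if not out:
        raise InsufficientDataError("no complete days after hourly binning")
    return np.column_stack(out)


def _hourly_sequence(s: ActivitySeries) -> np.ndarray:
    """Complete-day hourly means concatenated in time order."""
    return bin_hourly(s).T.ravel()  # day-major = chronological for ZT-aligned days


def interdaily_stability(s: ActivitySeries) -> float:
    """IS = (N * sum_h (xbar_h - xbar)^2) / (p * sum_i (x_i - xbar)^2).

    Computed on hourly bins (p = 24). Returns NaN when the total variance is
    zero (undefined).
    """
    _require_days(s)
    mat = bin_hourly(s)  # 24 x n_days
    x = mat.T.ravel()
    n = x.size
    xbar = x.mean()
    denom = ((x - xbar) ** 2).sum()
    if denom == 0:
        return float("nan")
    hourly_means = mat.mean(axis=1)
    num = n * ((hourly_means - xbar) ** 2).sum()
    return float(num / (24 * denom))


def intradaily_variability(s: ActivitySeries, level: str = "hourly") -> float:
    """IV = (N * sum of squared successive differences) / ((N-1) * variance sum).

    ``level="hourly"`` (default) uses hourly bins; ``level="epoch"`` uses the
    raw epoch series. Returns NaN when the variance is zero.
    """
    _require_days(s)
    if level == "hourly":
        x = _hourly_sequence(s)
    elif level == "epoch":
        x = s.activity
    else:
        raise InvalidParameterError(f"unknown level {level!r}")
    n = x.size
    if n < 2:
        raise InsufficientDataError("need at least 2 bins for IV")
    denom = (n - 1) * ((x - x.mean()) ** 2).sum()
    if denom == 0:
        return float("nan")
    num = n * (np.diff(x) ** 2).sum()
    return float(num / denom)


def circadian_metrics(s: ActivitySeries) -> CircadianMetrics:
    return CircadianMetrics(IS=interdaily_stability(s),
                            IV=intradaily_variability(s), bin_width_h=1.0)


def _bout_lengths(sleep: np.ndarray, boundary_break: np.ndarray) -> list[int]:
    """Lengths of maximal runs of 1s, with runs split where boundary_break
    flags the first epoch of a new phase."""
    lengths: list[int] = []
    run = 0
    for i, v in enumerate(sleep):
        if v and run and boundary_break[i]:
            lengths.append(run)
            run = 0
        if v:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths


def phase_summary(
    s: ActivitySeries, bout_policy: str = "split"
) -> tuple[PhaseSummary, PhaseSummary]:
    """Sleep/activity summaries for the light and dark phases.

    Sleep bouts are maximal runs of ``sleep_state == 1``; with the default
    ``bout_policy="split"`` a run spanning a light/dark transition is cut at
    the boundary and contributes to both phases, with ``"onset"`` it is
    assigned whole to the phase in which it started.
    """
    if bout_policy not in ("split", "onset"):
        raise InvalidParameterError(f"unknown bout policy {bout_policy!r}")
    light = s.is_light
    phase_change = np.empty(light.size, dtype=bool)
    phase_change[0] = False
    phase_change[1:] = light[1:] != light[:-1]

    out = []
    for name, in_phase in (("light", light), ("dark", ~light)):
        sleep = s.sleep_state.astype(bool)
        pct = 100.0 * sleep[in_phase].mean() if in_phase.any() else float("nan")
        if bout_policy == "split":
            masked = (sleep & in_phase).astype(int)
            lengths = _bout_lengths(masked, phase_change)
        else:
            # whole runs, assigned by the phase of their first epoch
            lengths = []
            run, start = 0, 0
            for i, v in enumerate(sleep):
                if v and run == 0:
                    start = i
                if v:
                    run += 1
                elif run:
                    if in_phase[start]:
                        lengths.append(run)
                    run = 0
            if run and in_phase[start]:
                lengths.append(run)
        mean_bout = float(np.mean(lengths)) * s.epoch_s if lengths else float("nan")
        act = s.activity[in_phase]
        mean_act = float(act.mean()) if act.size else float("nan")
        active = in_phase & ~sleep
        amp = float(s.activity[active].mean()) if active.any() else float("nan")
        out.append(PhaseSummary(phase=name, pct_time_asleep=float(pct),
                                mean_bout_length_s=mean_bout,
                                mean_activity=mean_act, activity_amplitude=amp))
    return out[0], out[1]
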