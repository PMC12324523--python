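"""Synthetic operant (trough/CRF/FI) event logs and gustometer lick sessions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError
from ..operant import LickLog, OperantSession

__all__ = [
    "ScheduleSpec",
    "LatencyModel",
    "simulate_event_schedule",
    "simulate_lick_session",
]

FI_INTERVALS_S = (2.0, 4.0, 8.0, 12.0, 24.0)

#: tiny causal delay so simultaneous press/dipper events stay strictly ordered
_DIPPER_DELAY_S = 0.01


@dataclass
class ScheduleSpec:
    """Trial schedule for the synthetic operant generator."""

    schedule: str  # "trough" | "CRF" | "FI"
    n_trials: int = 30
    fixed_interval_s: float | None = None
    iti_mean_s: float = 20.0
    reward_duration_s: float = 5.0
    #: press rate (Hz) as a function of time within the FI interval
    press_rate_profile: Callable[[np.ndarray], np.ndarray] | float = 0.5

    def __post_init__(self) -> None:
        if self.schedule not in ("trough", "CRF", "FI"):
            raise InvalidParameterError(f"unknown schedule {self.schedule!r}")
        if self.n_trials < 1:
            raise InvalidParameterError("n_trials must be >= 1")
        if self.n_trials > 60:
            raise InvalidParameterError("n_trials capped at 60 reinforcements")
        if self.schedule == "FI":
            if self.fixed_interval_s is None:
                raise InvalidParameterError("FI schedule requires fixed_interval_s")
            if self.fixed_interval_s not in FI_INTERVALS_S:
                raise InvalidParameterError(
                    f"fixed interval must be one of {FI_INTERVALS_S}"
                )
        if self.iti_mean_s <= 0 or self.reward_duration_s <= 0:
            raise InvalidParameterError("iti and reward duration must be positive")

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        if callable(self.press_rate_profile):
            return np.asarray(self.press_rate_profile(t), dtype=float)
        return np.full_like(np.asarray(t, dtype=float), float(self.press_rate_profile))


@dataclass
class LatencyModel:
    """Response-latency parameters for the synthetic animal.

    With ``jitter="none"`` all latencies are deterministic, which gives exact
    oracle values in tests; ``jitter="exponential"`` draws latencies from
    exponential distributions with the stated means.
    """

    press_latency_s: float = 2.0
    retrieval_latency_s: float = 1.0
    jitter: str = "none"  # "none" | "exponential"
    p_press: float = 1.0
    p_retrieve: float = 1.0
    unanswered_timeout_s: float = 60.0

    def __post_init__(self) -> None:
        if self.jitter not in ("none", "exponential"):
            raise InvalidParameterError(f"unknown jitter mode {self.jitter!r}")
        for p in (self.p_press, self.p_retrieve):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError("probabilities must be in [0, 1]")
        if self.press_latency_s <= 0 or self.retrieval_latency_s <= 0:
            raise InvalidParameterError("latencies must be positive")

    def draw(self, mean: float, rng: np.random.Generator) -> float:
        if self.jitter == "none":
            return mean
        return float(rng.exponential(mean))


def _poisson_process(
    rate_fn, t_max: float, rng: np.random.Generator, rate_cap: float
) -> np.ndarray:
    """Inhomogeneous Poisson arrivals on [0, t_max) by thinning."""
    if rate_cap <= 0 or t_max <= 0:
        return np.array([])
    n = rng.poisson(rate_cap * t_max)
    cand = np.sort(rng.uniform(0.0, t_max, n))
    keep = rng.uniform(0.0, rate_cap, n) < rate_fn(cand)
    return cand[keep]


def simulate_event_schedule(
    spec: ScheduleSpec,
    latency_model: LatencyModel | None = None,
    seed: int = 0,
) -> OperantSession:
    """Emit a causally ordered event log for a trough, CRF or FI session.

    For FI trials, presses during the interval follow the spec's press-rate
    profile and the rewarded press is the first press after the interval
    elapses (at the model's press latency past the interval end).
    """
    lm = latency_model or LatencyModel()
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, float, int]] = []
    t = 0.0

    def iti() -> float:
        return lm.draw(spec.iti_mean_s, rng)

    for trial in range(spec.n_trials):
        if spec.schedule == "trough":
            up = t
            rows.append(("dipper_up", up, trial))
            down = up + spec.reward_duration_s
            if rng.uniform() < lm.p_retrieve:
                entry = up + lm.draw(lm.retrieval_latency_s, rng)
                rows.append(("head_entry", min(entry, down), trial))
            rows.append(("dipper_down", down, trial))
            t = down + iti()
            continue

        ext = t
        rows.append(("lever_extension", ext, trial))

        if spec.schedule == "CRF":
            if rng.uniform() < lm.p_press:
                press = ext + lm.draw(lm.press_latency_s, rng)
                rows.append(("lever_press", press, trial))
                up = press + _DIPPER_DELAY_S
            else:
                t = ext + lm.unanswered_timeout_s + iti()
                continue
        else:  # FI
            interval = float(spec.fixed_interval_s)
            in_interval = _poisson_process(
                spec.rate_at, interval, rng,
                rate_cap=float(np.max(spec.rate_at(np.linspace(0, interval, 64)))) + 1e-9,
            )
            for p in in_interval:
                rows.append(("lever_press", ext + float(p), trial))
            rewarded = ext + interval + lm.draw(lm.press_latency_s, rng)
            rows.append(("lever_press", rewarded, trial))
            up = rewarded + _DIPPER_DELAY_S

        rows.append(("dipper_up", up, trial))
        down = up + spec.reward_duration_s
        if rng.uniform() < lm.p_retrieve:
            entry = up + lm.draw(lm.retrieval_latency_s, rng)
            rows.append(("head_entry", min(entry, down), trial))
        rows.append(("dipper_down", down, trial))
        t = down + iti()

    events = pd.DataFrame(rows, columns=["event_type", "time_s", "trial_index"])
    events = events.sort_values("time_s", kind="stable").reset_index(drop=True)
    return OperantSession(
        events=events,
        schedule=spec.schedule,
        fixed_interval_s=spec.fixed_interval_s,
        n_trials_max=spec.n_trials,
        session_end_s=float(t),
        truth=spec,
    )


@dataclass
class LickGroundTruth:
    concentration_order: np.ndarray = field(default_factory=lambda: np.array([]))
    engaged: np.ndarray = field(default_factory=lambda: np.array([]))
    seed: int = 0


def simulate_lick_session(
    n_trials: int,
    concentrations: list[float],
    lick_rate_hz: float = 6.0,
    p_engage: float = 1.0,
    seed: int = 0,
    access_duration_s: float = 5.0,
    iti_s: float = 20.0,
    first_lick_latency_s: float = 0.5,
) -> LickLog:
    """Gustometer session with a balanced pseudorandom concentration order.

    Concentrations are presented in shuffled blocks, so with ``n_trials`` a
    multiple of the number of concentrations each appears equally often.
    Engaged trials (probability ``p_engage``) contain regular licks at
    ``lick_rate_hz`` starting ``first_lick_latency_s`` after trial onset.
    """
    if not concentrations:
        raise InvalidParameterError("concentrations must be non-empty")
    if not 0.0 <= p_engage <= 1.0:
        raise InvalidParameterError("p_engage must be in [0, 1]")
    if n_trials < 1 or lick_rate_hz <= 0:
        raise InvalidParameterError("n_trials and lick_rate must be positive")

    rng = np.random.default_rng(seed)
    concs = np.asarray(concentrations, dtype=float)
    n_blocks = -(-n_trials // concs.size)
    order = np.concatenate([rng.permutation(concs) for _ in range(n_blocks)])[:n_trials]
    engaged = rng.uniform(size=n_trials) < p_engage

    trial_rows, lick_rows = [], []
    t = 0.0
    for i in range(n_trials):
        trial_rows.append(dict(trial_index=i, concentration_pct=order[i], start_s=t))
        if engaged[i]:
            lick_t = t + first_lick_latency_s
            while lick_t < t + access_duration_s:
                lick_rows.append(dict(trial_index=i, time_s=lick_t))
                lick_t += 1.0 / lick_rate_hz
        t += access_duration_s + iti_s

    return LickLog(
        trials=pd.DataFrame(trial_rows),
        licks=pd.DataFrame(lick_rows, columns=["trial_index", "time_s"]),
        session_duration_s=t,
        truth=LickGroundTruth(concentration_order=order, engaged=engaged, seed=seed),
    )
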