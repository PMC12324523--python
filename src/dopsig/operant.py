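"""Behavioral metrics from normalized operant and gustometer event logs.

The event-log contract is a table with columns ``event_type`` (one of
lever_extension, lever_press, dipper_up, dipper_down, head_entry),
``time_s`` and ``trial_index``. Reward "consumption" is operationalized as
at least one head entry while the dipper is up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ScheduleMismatchError

__all__ = [
    "EVENT_TYPES",
    "OperantSession",
    "LickLog",
    "BehavioralMetrics",
    "LickMetrics",
    "ScallopCurve",
    "crf_metrics",
    "fi_metrics",
    "scallop_curve",
    "lick_metrics",
    "trough_training_metrics",
]

EVENT_TYPES = ("lever_extension", "lever_press", "dipper_up", "dipper_down",
               "head_entry")
SCHEDULES = ("trough", "CRF", "FI")


@dataclass
class OperantSession:
    """Typed event log for one trough/CRF/FI session."""

    events: pd.DataFrame
    schedule: str
    fixed_interval_s: float | None = None
    n_trials_max: int | None = None
    session_end_s: float | None = None
    truth: object | None = None

    def __post_init__(self) -> None:
        if self.schedule not in SCHEDULES:
            raise InvalidParameterError(f"unknown schedule {self.schedule!r}")
        if self.schedule == "FI" and self.fixed_interval_s is None:
            raise InvalidParameterError("FI schedule requires fixed_interval_s")
        ev = self.events
        required = {"event_type", "time_s", "trial_index"}
        if not required.issubset(ev.columns):
            raise InvalidParameterError(f"event table must have columns {required}")
        unknown = set(ev["event_type"]) - set(EVENT_TYPES)
        if unknown:
            raise InvalidParameterError(f"unknown event types {unknown}")
        if not ev["time_s"].is_monotonic_increasing:
            raise InvalidParameterError("event times must be nondecreasing")
        self._validate_causality()

    def _validate_causality(self) -> None:
        for ti, g in self.events.groupby("trial_index"):
            by_type = {k: v["time_s"].to_numpy() for k, v in g.groupby("event_type")}
            ext = by_type.get("lever_extension")
            presses = by_type.get("lever_press")
            dip = by_type.get("dipper_up")
            if ext is not None and presses is not None and presses.min() < ext[0]:
                raise InvalidParameterError(
                    f"trial {ti}: lever press before extension (lever retracted)"
                )
            if dip is not None and presses is not None and dip[0] < presses.min():
                raise InvalidParameterError(
                    f"trial {ti}: dipper raised before any press"
                )

    def trials(self):
        return self.events.groupby("trial_index", sort=True)


@dataclass
class LickLog:
    """Gustometer session: trial table plus per-lick timestamps.

    ``trials`` columns: trial_index, concentration_pct, start_s.
    ``licks`` columns: trial_index, time_s.
    """

    trials: pd.DataFrame
    licks: pd.DataFrame
    session_duration_s: float | None = None
    truth: object | None = None


@dataclass
class BehavioralMetrics:
    """Session-level operant metrics with missing-latency bookkeeping."""

    pct_lever_press: float
    pct_rewarded_trials: float
    latency_first_press_s: float
    latency_mean_press_s: float
    latency_reward_s: float
    total_presses: int
    n_presentations: int
    n_missing_press: int = 0
    n_missing_reward: int = 0
    per_trial: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class LickMetrics:
    n_trials_presented: int
    n_completed: int
    n_incomplete: int
    total_licks: int
    latency_first_lick_s: float  # NaN when no trial was completed
    licks_by_concentration: dict[float, float]  # NaN for never-completed conc


@dataclass
class ScallopCurve:
    """Within-interval press rate pooled across FI trials."""

    bin_edges_s: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    total_in_interval_presses: int
    all_zero: bool

    def normalized(self) -> np.ndarray:
        last = self.rate_hz[-1]
        if last == 0:
            return np.zeros_like(self.rate_hz)
        return self.rate_hz / last


def _mean_or_nan(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def _trial_outcomes(s: OperantSession) -> pd.DataFrame:
    """Per-trial bookkeeping shared by CRF and FI metrics."""
    rows = []
    for ti, g in s.trials():
        by = {k: v["time_s"].to_numpy() for k, v in g.groupby("event_type")}
        ext = by.get("lever_extension")
        if ext is None:
            continue  # truncated trial where the lever never extended
        ext_t = float(ext[0])
        presses = by.get("lever_press", np.array([]))
        dip_up = by.get("dipper_up", np.array([]))
        dip_down = by.get("dipper_down", np.array([]))
        heads = by.get("head_entry", np.array([]))

        pressed = presses.size > 0
        first_press = float(presses[0] - ext_t) if pressed else float("nan")
        mean_press = float((presses - ext_t).mean()) if pressed else float("nan")

        consumed = False
        reward_latency = float("nan")
        if dip_up.size:
            up = float(dip_up[0])
            down = float(dip_down[0]) if dip_down.size else float("inf")
            during = heads[(heads >= up) & (heads <= down)]
            if during.size:
                consumed = True
                reward_latency = float(during[0] - up)
        rows.append(dict(trial_index=ti, extension_s=ext_t, pressed=pressed,
                         n_presses=int(presses.size), consumed=consumed,
                         latency_first_press_s=first_press,
                         latency_mean_press_s=mean_press,
                         latency_reward_s=reward_latency))
    return pd.DataFrame(rows)


def _metrics_from_outcomes(
    s: OperantSession, per_trial: pd.DataFrame, press_latency: str
) -> BehavioralMetrics:
    n_pres = len(per_trial)
    if n_pres == 0:
        raise InvalidParameterError("session contains no lever presentations")
    pct_press = 100.0 * per_trial["pressed"].sum() / n_pres
    pct_rewarded = 100.0 * (per_trial["pressed"] & per_trial["consumed"]).sum() / n_pres

    first = per_trial["latency_first_press_s"].dropna()
    reward = per_trial["latency_reward_s"].dropna()
    if press_latency == "all_presses":
        # press-count-weighted mean over every press in the session
        pressed = per_trial[per_trial["pressed"]]
        total = (pressed["latency_mean_press_s"] * pressed["n_presses"]).sum()
        n_press_events = pressed["n_presses"].sum()
        mean_press = float(total / n_press_events) if n_press_events else float("nan")
    elif press_latency == "first_press":
        mean_press = float(first.mean()) if len(first) else float("nan")
    else:
        raise InvalidParameterError(f"unknown press_latency mode {press_latency!r}")

    return BehavioralMetrics(
        pct_lever_press=float(pct_press),
        pct_rewarded_trials=float(pct_rewarded),
        latency_first_press_s=float(first.mean()) if len(first) else float("nan"),
        latency_mean_press_s=mean_press,
        latency_reward_s=float(reward.mean()) if len(reward) else float("nan"),
        total_presses=int(per_trial["n_presses"].sum()),
        n_presentations=n_pres,
        n_missing_press=int((~per_trial["pressed"]).sum()),
        n_missing_reward=int(per_trial["latency_reward_s"].isna().sum()),
        per_trial=per_trial,
    )


def crf_metrics(s: OperantSession, press_latency: str = "all_presses") -> BehavioralMetrics:
    """Completion percentages and latencies for a continuous-reinforcement session."""
    if s.schedule != "CRF":
        raise ScheduleMismatchError(f"expected CRF session, got {s.schedule}")
    return _metrics_from_outcomes(s, _trial_outcomes(s), press_latency)


def fi_metrics(s: OperantSession, press_latency: str = "all_presses") -> BehavioralMetrics:
    """Press counts and latencies for a fixed-interval session.

    ``total_presses`` counts every press while the lever is extended,
    including unrewarded presses before the interval elapses.
    """
    if s.schedule != "FI":
        raise ScheduleMismatchError(f"expected FI session, got {s.schedule}")
    return _metrics_from_outcomes(s, _trial_outcomes(s), press_latency)


def scallop_curve(s: OperantSession, n_bins: int) -> ScallopCurve:
    """Pooled within-interval press rate across trials, in presses/s per bin."""
    if s.schedule != "FI":
        raise ScheduleMismatchError(f"expected FI session, got {s.schedule}")
    if n_bins < 1:
        raise InvalidParameterError("n_bins must be >= 1")
    interval = float(s.fixed_interval_s)
    edges = np.linspace(0.0, interval, n_bins + 1)
    counts = np.zeros(n_bins)
    n_trials = 0
    for _, g in s.trials():
        by = {k: v["time_s"].to_numpy() for k, v in g.groupby("event_type")}
        ext = by.get("lever_extension")
        if ext is None:
            continue
        n_trials += 1
        rel = by.get("lever_press", np.array([])) - ext[0]
        rel = rel[(rel >= 0) & (rel < interval)]
        counts += np.histogram(rel, bins=edges)[0]
    if n_trials == 0:
        raise InvalidParameterError("no trials with a lever extension")
    bin_dur = interval / n_bins
    rate = counts / (n_trials * bin_dur)
    return ScallopCurve(bin_edges_s=edges, rate_hz=rate, n_trials=n_trials,
                        total_in_interval_presses=int(counts.sum()),
                        all_zero=bool(counts.sum() == 0))


def lick_metrics(log: LickLog) -> LickMetrics:
    """Trial counts, lick counts and first-lick latency for a gustometer session.

    A completed trial is one with at least one lick. Per-concentration mean
    licks are computed over completed trials only; a concentration with no
    completed trial maps to NaN (absent, not zero).
    """
    trials = log.trials
    n_pres = len(trials)
    lick_counts = log.licks.groupby("trial_index").size() if len(log.licks) else pd.Series(dtype=int)
    per_trial = trials.set_index("trial_index")
    per_trial = per_trial.assign(n_licks=lick_counts).fillna({"n_licks": 0})
    per_trial["n_licks"] = per_trial["n_licks"].astype(int)
    completed = per_trial[per_trial["n_licks"] > 0]

    if len(completed) and len(log.licks):
        first_licks = log.licks.groupby("trial_index")["time_s"].min()
        latencies = first_licks - per_trial.loc[first_licks.index, "start_s"]
        latency = float(latencies.mean())
    else:
        latency = float("nan")

    by_conc: dict[float, float] = {}
    for conc in sorted(trials["concentration_pct"].unique()):
        done = completed[completed["concentration_pct"] == conc]
        by_conc[float(conc)] = float(done["n_licks"].mean()) if len(done) else float("nan")

    return LickMetrics(
        n_trials_presented=n_pres,
        n_completed=int(len(completed)),
        n_incomplete=int(n_pres - len(completed)),
        total_licks=int(per_trial["n_licks"].sum()),
        latency_first_lick_s=latency,
        licks_by_concentration=by_conc,
    )


def trough_training_metrics(s: OperantSession) -> float:
    """Percent of dipper presentations answered with a head entry while up."""
    if s.schedule != "trough":
        raise ScheduleMismatchError(f"expected trough session, got {s.schedule}")
    n_pres = 0
    n_retrieved = 0
    for _, g in s.trials():
        by = {k: v["time_s"].to_numpy() for k, v in g.groupby("event_type")}
        dip_up = by.get("dipper_up")
        if dip_up is None:
            continue
        n_pres += 1
        up = float(dip_up[0])
        down = float(by["dipper_down"][0]) if "dipper_down" in by else float("inf")
        heads = by.get("head_entry", np.array([]))
        if ((heads >= up) & (heads <= down)).any():
            n_retrieved += 1
    if n_pres == 0:
        raise InvalidParameterError("no dipper presentations in session")
    return 100.0 * n_retrieved / n_pres
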