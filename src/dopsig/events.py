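"""Peri-event analysis of z-scored dFF traces.

Trial alignment on a common relative-time grid, ITI-baseline subtraction,
AUC/peak metrics in event-specific windows, spontaneous-transient detection
by peak prominence, injection-session metrics, and a metric-vs-latency
correlation helper.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .errors import (
    ConfigurationError,
    EmptyAlignmentError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidWindowError,
)
from .photometry import DffTrace

__all__ = [
    "TrialMatrix",
    "EventMetrics",
    "TransientEvent",
    "AmphetamineMetrics",
    "CorrelationResult",
    "METRIC_WINDOWS",
    "align_to_events",
    "baseline_correct",
    "event_metrics",
    "detect_spontaneous",
    "amphetamine_metrics",
    "correlate_metric_latency",
]

#: Post-event metric windows (seconds) per alignment event type.
METRIC_WINDOWS: dict[str, tuple[float, float]] = {
    "lever_extension": (0.0, 1.5),
    "dipper_up": (0.0, 1.0),
    "dipper_presentation": (0.0, 1.0),
    "reward": (0.0, 3.0),
    "reward_delivery": (0.0, 3.0),
}

DEFAULT_BASELINE_WINDOW = (-5.0, -0.5)


@dataclass
class TrialMatrix:
    """Trials x time array of zdFF aligned to one event type."""

    aligned: np.ndarray
    rel_time_s: np.ndarray
    alignment_event: str
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
    baseline_per_trial: np.ndarray | None = None
    trial_indices: np.ndarray | None = None
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.aligned.shape[0]

    @property
    def corrected(self) -> bool:
        return self.baseline_per_trial is not None

    def mean_trace(self) -> np.ndarray:
        return self.aligned.mean(axis=0)


@dataclass
class EventMetrics:
    """AUC and peak height of the baseline-corrected trial average."""

    auc: float
    auc_per_trial: np.ndarray
    peak_height: float | None
    metric_window: tuple[float, float]
    event_type: str


@dataclass(frozen=True)
class TransientEvent:
    """One spontaneous transient detected inside an ITI span."""

    peak_time_s: float
    prominence: float
    amplitude: float
    width_s: float
    window: tuple[float, float]


@dataclass
class AmphetamineMetrics:
    """Post-injection summary: mean signal, rising slope, plateau latency."""

    mean_dff: float
    slope: float
    latency_to_plateau_s: float | None
    dose_mg_kg: float | None = None

    @property
    def plateau_defined(self) -> bool:
        return self.latency_to_plateau_s is not None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def _trace_values(trace: DffTrace) -> np.ndarray:
    return trace.zdff if trace.zdff is not None else trace.dff


def align_to_events(
    trace: DffTrace,
    events: pd.DataFrame,
    event_type: str,
    window: tuple[float, float] = (5.0, 5.0),
) -> TrialMatrix:
    """Extract one row of zdFF per event on a common relative-time grid.

    ``window`` is (pre_s, post_s), both positive. Events whose window falls
    outside the recording are dropped and counted in ``n_dropped``.
    """
    pre_s, post_s = window
    if pre_s < 0 or post_s < 0:
        raise InvalidParameterError("window extents must be non-negative")
    sel = events[events["event_type"] == event_type]
    if sel.empty:
        raise EmptyAlignmentError(f"no events of type {event_type!r}")
    x = _trace_values(trace)
    t = trace.time_s
    dt = 1.0 / trace.fs
    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    rel_time = np.arange(-n_pre, n_post + 1) * dt

    rows, kept, dropped = [], [], 0
    for _, ev in sel.iterrows():
        idx = int(round((ev["time_s"] - t[0]) / dt))
        lo, hi = idx - n_pre, idx + n_post + 1
        if lo < 0 or hi > x.size:
            dropped += 1
            continue
        rows.append(x[lo:hi])
        kept.append(ev.get("trial_index", -1))
    if not rows:
        raise EmptyAlignmentError(
            f"all {len(sel)} events of type {event_type!r} fell outside the recording"
        )
    return TrialMatrix(
        aligned=np.vstack(rows),
        rel_time_s=rel_time,
        alignment_event=event_type,
        trial_indices=np.asarray(kept),
        n_dropped=dropped,
    )


def baseline_correct(m: TrialMatrix) -> TrialMatrix:
    """Subtract each trial's mean over the ITI baseline window from its row."""
    lo, hi = m.baseline_window
    mask = (m.rel_time_s >= lo) & (m.rel_time_s <= hi)
    if not mask.any():
        raise InvalidWindowError(
            f"baseline window {m.baseline_window} outside aligned range "
            f"[{m.rel_time_s[0]:.3g}, {m.rel_time_s[-1]:.3g}]"
        )
    baseline = m.aligned[:, mask].mean(axis=1)
    return replace(m, aligned=m.aligned - baseline[:, None],
                   baseline_per_trial=baseline)


def _window_mask(rel_time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < rel_time[0] - 1e-12 or hi > rel_time[-1] + 1e-12:
        raise InvalidWindowError(f"metric window {window} outside aligned range")
    return (rel_time >= lo - 1e-12) & (rel_time <= hi + 1e-12)


def event_metrics(
    m: TrialMatrix,
    event_type: str | None = None,
    window: tuple[float, float] | None = None,
) -> EventMetrics:
    """Trapezoidal AUC and 1-SD-threshold peak height in the metric window.

    The window is resolved from the event type unless overridden. The peak
    height is the maximum of the trial-averaged corrected trace in the window
    provided it exceeds one standard deviation above the local (baseline
    window) level; otherwise it is reported absent (``None``).
    """
    if not m.corrected:
        raise InvalidParameterError("trial matrix must be baseline-corrected first")
    ev = event_type or m.alignment_event
    if window is None:
        try:
            window = METRIC_WINDOWS[ev]
        except KeyError:
            raise ConfigurationError(
                f"no metric window configured for event type {ev!r}; pass window="
            ) from None
    mask = _window_mask(m.rel_time_s, window)
    tw = m.rel_time_s[mask]
    avg = m.mean_trace()
    auc = float(np.trapezoid(avg[mask], tw))
    auc_per_trial = np.trapezoid(m.aligned[:, mask], tw, axis=1)

    bl_mask = (m.rel_time_s >= m.baseline_window[0]) & (
        m.rel_time_s <= m.baseline_window[1]
    )
    local_mean = float(avg[bl_mask].mean())
    local_sd = float(avg[bl_mask].std(ddof=0))
    peak = float(avg[mask].max())
    peak_height = peak if peak > local_mean + local_sd else None
    return EventMetrics(auc=auc, auc_per_trial=auc_per_trial,
                        peak_height=peak_height, metric_window=window,
                        event_type=ev)


def detect_spontaneous(
    trace: DffTrace,
    iti_spans: Sequence[tuple[float, float]],
    threshold_sd: float = 2.0,
    mode: str = "prominence",
    event_window: tuple[float, float] = (-2.0, 2.0),
) -> list[TransientEvent]:
    """Find spontaneous transients inside ITI spans by peak prominence.

    Local maxima are located independently within each span. In the default
    ``mode="prominence"`` a peak is retained iff its prominence exceeds
    ``threshold_sd`` times the session standard deviation of the trace; in
    ``mode="height"`` iff its height exceeds the session mean plus that many
    standard deviations. Width is full width at half prominence, in seconds.
    """
    if mode not in ("prominence", "height"):
        raise ConfigurationError(f"unknown detection mode {mode!r}")
    spans = sorted((float(a), float(b)) for a, b in iti_spans)
    for (a0, b0), (a1, _) in zip(spans, spans[1:]):
        if a1 < b0:
            raise InvalidParameterError("ITI spans must be non-overlapping")
    x = _trace_values(trace)
    t = trace.time_s
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    thr = threshold_sd * sd
    dt = 1.0 / trace.fs

    out: list[TransientEvent] = []
    for start, end in spans:
        i0 = int(np.searchsorted(t, start, side="left"))
        i1 = int(np.searchsorted(t, end, side="right"))
        seg = x[i0:i1]
        if seg.size < 3:
            continue
        peaks, _ = scipy.signal.find_peaks(seg)
        if peaks.size == 0:
            continue
        prom = scipy.signal.peak_prominences(seg, peaks)[0]
        if mode == "prominence":
            keep = prom > thr
        else:
            keep = seg[peaks] > mean + thr
        peaks, prom = peaks[keep], prom[keep]
        if peaks.size == 0:
            continue
        widths = scipy.signal.peak_widths(seg, peaks, rel_height=0.5)[0] * dt
        for p, pr, w in zip(peaks, prom, widths):
            out.append(
                TransientEvent(
                    peak_time_s=float(t[i0 + p]),
                    prominence=float(pr),
                    amplitude=float(seg[p]),
                    width_s=float(w),
                    window=event_window,
                )
            )
    out.sort(key=lambda e: e.peak_time_s)
    return out


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    # centered rolling mean, edges use partial windows
    return (
        pd.Series(x).rolling(n, center=True, min_periods=1).mean().to_numpy()
    )


def amphetamine_metrics(
    trace: DffTrace,
    injection_time_s: float,
    horizon_s: float,
    dose_mg_kg: float | None = None,
    smooth_s: float = 60.0,
    plateau_frac: float = 0.95,
    sustain_s: float = 120.0,
) -> AmphetamineMetrics:
    """Mean signal, rising slope and latency-to-plateau after an injection.

    The plateau onset is the first time the ``smooth_s``-smoothed signal
    reaches ``plateau_frac`` of its post-injection maximum and stays at or
    above that level for ``sustain_s`` (or to the end of the horizon if
    shorter). The slope is the OLS slope of the raw signal from injection to
    plateau onset (full horizon if the plateau is undefined).
    """
    x = _trace_values(trace)
    t = trace.time_s
    if injection_time_s + horizon_s > t[-1] + 1e-9:
        raise InvalidWindowError("horizon extends beyond the recording")
    post = (t > injection_time_s) & (t <= injection_time_s + horizon_s)
    if not post.any():
        raise InvalidWindowError("no samples in the post-injection span")
    tp, xp = t[post], x[post]
    mean_dff = float(xp.mean())

    n_smooth = max(1, int(round(smooth_s * trace.fs)))
    smooth = _moving_average(xp, n_smooth)
    peak = smooth.max()
    latency: float | None = None
    if peak > 0:
        level = plateau_frac * peak
        above = smooth >= level
        n_sustain = max(1, int(round(sustain_s * trace.fs)))
        for i in np.nonzero(above)[0]:
            j = min(i + n_sustain, above.size)
            if above[i:j].all():
                latency = float(tp[i] - injection_time_s)
                break

    if latency is not None:
        rise = tp <= injection_time_s + latency
        if rise.sum() < 2:
            rise = np.ones_like(tp, dtype=bool)
    else:
        rise = np.ones_like(tp, dtype=bool)
    slope = float(np.polyfit(tp[rise], xp[rise], 1)[0]) if rise.sum() >= 2 else 0.0
    return AmphetamineMetrics(mean_dff=mean_dff, slope=slope,
                              latency_to_plateau_s=latency, dose_mg_kg=dose_mg_kg)


def correlate_metric_latency(
    per_trial_metric: Sequence[float], per_trial_latency: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation between a per-trial metric and latency.

    Pairs with a missing (NaN) latency or metric are dropped; fewer than 3
    complete pairs is an error. Zero variance in either variable yields a
    NaN coefficient flagged via ``defined``.
    """
    a = np.asarray(per_trial_metric, dtype=float)
    b = np.asarray(per_trial_latency, dtype=float)
    if a.size != b.size:
        raise InvalidParameterError("metric and latency lengths differ")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, have {a.size}")
    if a.std() == 0 or b.std() == 0:
        return CorrelationResult(r=float("nan"), n=int(a.size))
    r = scipy.stats.pearsonr(a, b).statistic
    return CorrelationResult(r=float(r), n=int(a.size))
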