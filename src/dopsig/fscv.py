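"""Evoked dopamine transient quantification for FSCV sweeps.

A sweep is a calibrated (or raw-current) time course containing one
stimulated transient. Quantification measures the peak amplitude above the
pre-stimulus baseline (Imax) and fits a single exponential to the decay to
obtain the clearance time constant (Tau1, reported in milliseconds).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.optimize

from .errors import (
    AlreadyCalibratedError,
    FitFailureError,
    InsufficientSweepsError,
    InvalidParameterError,
    NoTransientError,
)

__all__ = [
    "FscvTrace",
    "FscvTransient",
    "SessionSummary",
    "calibrate",
    "quantify_transient",
    "summarize_session",
    "command_waveform",
    "scan_rate",
]

TAU_BOUNDS_S = (1e-3, 60.0)  # plausible clearance range
BASELINE_WINDOW_S = 1.0      # pre-stimulus span used for the baseline


@dataclass
class FscvTrace:
    """One sweep: uniformly sampled value vs time with a stimulation mark."""

    time_s: np.ndarray
    value: np.ndarray
    units: str  # "pA" or "uM"
    stim_time_s: float
    calibration_factor_um_per_pa: float | None = None
    truth: object | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.size != self.value.size:
            raise InvalidParameterError("time and value lengths differ")
        if self.units not in ("pA", "uM"):
            raise InvalidParameterError(f"unknown units {self.units!r}")
        if not (self.time_s[0] <= self.stim_time_s <= self.time_s[-1]):
            raise InvalidParameterError("stim_time outside trace")
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise InvalidParameterError("non-uniform sampling")

    @property
    def fs(self) -> float:
        return 1.0 / (self.time_s[1] - self.time_s[0])


@dataclass
class FscvTransient:
    """Quantified transient: amplitude, decay constant and fit diagnostics."""

    imax: float
    tau1_ms: float
    t_peak_s: float
    fit_rss: float
    fit_window_s: tuple[float, float]
    units: str
    baseline: float


@dataclass(frozen=True)
class SessionSummary:
    mean_imax: float
    mean_tau1_ms: float
    n: int
    selected: tuple[int, ...]  # 0-based indices of the sweeps used


def calibrate(trace: FscvTrace) -> FscvTrace:
    """Convert a raw-current trace to concentration via the 1 uM standard.

    Explicitly refuses a trace that is already in concentration units so a
    double application cannot silently rescale the data.
    """
    if trace.units == "uM":
        raise AlreadyCalibratedError("trace already in uM; refusing to rescale")
    factor = trace.calibration_factor_um_per_pa
    if factor is None or factor <= 0:
        raise InvalidParameterError("calibration factor must be positive")
    return replace(trace, value=trace.value * factor, units="uM")


def _decay_model(t, b, a, tau):
    return b + a * np.exp(-t / tau)


def quantify_transient(
    trace: FscvTrace, return_fraction: float = 0.05
) -> FscvTransient:
    """Measure Imax and fit Tau1 on the post-stimulus decay.

    Baseline is the mean of the second before stimulation. The peak is
    located (and the decay end detected) on a lightly smoothed copy so that
    single-sample noise extremes do not bias the measurement; the decay
    segment runs from the peak until the signal first returns within
    ``return_fraction`` of the peak excursion above baseline (or the end of
    the sweep). Tau1 comes from a bounded nonlinear least-squares fit of
    ``b + a*exp(-t/tau)`` on the raw samples, seeded by log-linear
    regression; Imax is the fitted decay evaluated at the peak, which is
    unbiased under additive noise (a raw max would inherit the noise
    maximum).
    """
    t, x = trace.time_s, trace.value
    pre = (t >= trace.stim_time_s - BASELINE_WINDOW_S) & (t < trace.stim_time_s)
    if not pre.any():
        raise InvalidParameterError("no pre-stimulus samples for the baseline")
    baseline = float(x[pre].mean())
    pre_sd = float(x[pre].std(ddof=0))

    # ~25 ms moving average; identity for clean, coarsely sampled sweeps
    w = max(1, int(round(0.025 * trace.fs)))
    xs = np.convolve(x, np.ones(w) / w, mode="same") if w > 1 else x

    post = t >= trace.stim_time_s
    ip = int(np.argmax(xs[post])) + int(np.nonzero(post)[0][0])
    # refine to the raw maximum near the smoothed peak (exact when noiseless)
    lo = max(ip - w, int(np.nonzero(post)[0][0]))
    ip = lo + int(np.argmax(x[lo:ip + w + 1]))
    peak_excursion = float(xs[ip] - baseline)
    if peak_excursion <= 3.0 * pre_sd or peak_excursion <= 0:
        raise NoTransientError(
            f"peak {peak_excursion:.4g} does not exceed baseline + 3*pre-stim SD "
            f"({3 * pre_sd:.4g})"
        )
    t_peak = float(t[ip])

    ret = np.nonzero(xs[ip:] <= baseline + return_fraction * peak_excursion)[0]
    iend = ip + int(ret[0]) + 1 if ret.size else x.size
    seg_t = t[ip:iend] - t_peak
    seg_x = x[ip:iend]
    if seg_t.size < 4:
        raise FitFailureError(f"decay segment too short ({seg_t.size} samples)")

    # log-linear seed on the baseline-subtracted positive part
    imax = peak_excursion
    pos = seg_x - baseline > 1e-12 * max(imax, 1.0)
    if pos.sum() >= 2:
        coef = np.polyfit(seg_t[pos], np.log(seg_x[pos] - baseline), 1)
        tau0 = float(np.clip(-1.0 / coef[0] if coef[0] < 0 else 1.0, *TAU_BOUNDS_S))
    else:
        tau0 = 0.5
    try:
        popt, _ = scipy.optimize.curve_fit(
            _decay_model,
            seg_t,
            seg_x,
            p0=[baseline, imax, tau0],
            bounds=([-np.inf, 0.0, TAU_BOUNDS_S[0]], [np.inf, np.inf, TAU_BOUNDS_S[1]]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitFailureError(f"decay fit did not converge: {exc}") from exc
    b, a, tau = popt
    resid = seg_x - _decay_model(seg_t, *popt)
    return FscvTransient(
        imax=float(b + a - baseline),
        tau1_ms=float(tau * 1000.0),
        t_peak_s=t_peak,
        fit_rss=float(resid @ resid),
        fit_window_s=(t_peak, float(t[iend - 1])),
        units=trace.units,
        baseline=baseline,
    )


def middle_three_indices(n: int) -> tuple[int, int, int]:
    """0-based indices of the middle three of ``n`` sweeps.

    On even counts ties resolve toward the earlier sweeps: 1-based positions
    ceil(n/2)-1 .. ceil(n/2)+1.
    """
    if n < 3:
        raise InsufficientSweepsError(f"need >= 3 sweeps, have {n}")
    mid = -(-n // 2)  # ceil(n/2), 1-based
    return (mid - 2, mid - 1, mid)


def summarize_session(
    sweeps: Sequence[FscvTransient], policy: str = "middle_three"
) -> SessionSummary:
    """Mean Imax and Tau1 over the middle three sweeps of a session."""
    if policy != "middle_three":
        raise InvalidParameterError(f"unknown policy {policy!r}")
    sel = middle_three_indices(len(sweeps))
    chosen = [sweeps[i] for i in sel]
    return SessionSummary(
        mean_imax=float(np.mean([s.imax for s in chosen])),
        mean_tau1_ms=float(np.mean([s.tau1_ms for s in chosen])),
        n=len(chosen),
        selected=sel,
    )


def command_waveform(
    v_start_mv: float = -450.0,
    v_peak_mv: float = 800.0,
    duration_ms: float = 8.5,
    n_samples: int = 1701,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the symmetric triangular command waveform.

    Rises linearly from ``v_start_mv`` to ``v_peak_mv`` and returns in the
    same total ``duration_ms``. Returns (time_s, volts).
    """
    if duration_ms <= 0:
        raise InvalidParameterError("duration must be positive")
    if v_peak_mv <= v_start_mv:
        raise InvalidParameterError("peak must exceed start")
    t = np.linspace(0.0, duration_ms / 1000.0, n_samples)
    half = duration_ms / 2000.0
    v0, vp = v_start_mv / 1000.0, v_peak_mv / 1000.0
    up = t <= half
    v = np.where(up, v0 + (vp - v0) * t / half, vp - (vp - v0) * (t - half) / half)
    return t, v


def scan_rate(t: np.ndarray, v: np.ndarray) -> float:
    """Magnitude of the voltage scan rate (V/s) of a sampled triangle wave."""
    rates = np.abs(np.diff(v) / np.diff(t))
    return float(np.median(rates))
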