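"""Two-channel fiber-photometry correction pipeline.

Converts a raw recording (465 nm signal + 405 nm isosbestic reference) into a
z-scored dFF trace: block-mean downsampling, a single ordinary-least-squares
fit of the signal channel on the reference channel over the whole session,
the ratiometric dFF formula, and full-session z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFitError,
    DegenerateTraceError,
    InvalidParameterError,
    UnusableBaselineError,
)

__all__ = [
    "PhotometryRecording",
    "ReferenceFit",
    "DffTrace",
    "downsample",
    "fit_reference",
    "compute_dff",
    "zscore",
    "process_recording",
]

#: Relative tolerance on sample spacing when checking grid uniformity.
_GRID_RTOL = 1e-6


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=["event_type", "time_s", "trial_index"])


@dataclass
class PhotometryRecording:
    """Raw two-channel photometry stream on a uniform time grid.

    Parameters
    ----------
    time_s : array of sample times (seconds, uniform, strictly increasing)
    sig_465 : dopamine-sensitive channel (a.u.)
    ref_405 : isosbestic reference channel (a.u.)
    fs : sampling rate in Hz
    events : table with columns ``event_type``, ``time_s``, ``trial_index``
    truth : optional generator ground truth (opaque to this module)
    """

    time_s: np.ndarray
    sig_465: np.ndarray
    ref_405: np.ndarray
    fs: float
    events: pd.DataFrame = field(default_factory=_empty_events)
    truth: object | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.sig_465 = np.asarray(self.sig_465, dtype=float)
        self.ref_405 = np.asarray(self.ref_405, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")
        n = self.time_s.size
        if self.sig_465.size != n or self.ref_405.size != n:
            raise InvalidParameterError("channel lengths must match time base")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise InvalidParameterError("time must be strictly increasing")
            expected = 1.0 / self.fs
            if not np.allclose(dt, expected, rtol=_GRID_RTOL, atol=expected * _GRID_RTOL):
                raise InvalidParameterError(
                    "non-uniform time grid; resampling is out of contract"
                )

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class ReferenceFit:
    """OLS fit of sig_465 on ref_405 over the full session."""

    slope: float
    intercept: float
    rss: float

    def predict(self, ref_405: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(ref_405, dtype=float) + self.intercept


@dataclass
class DffTrace:
    """Corrected dFF trace with its z-scored companion.

    ``zdff`` is ``None`` when the session standard deviation is zero (the
    degenerate flat-trace case); ``degenerate`` is then set.
    """

    time_s: np.ndarray
    dff: np.ndarray
    zdff: np.ndarray | None
    session_mean: float
    session_sd: float
    fs: float

    @property
    def degenerate(self) -> bool:
        return self.zdff is None


def downsample(rec: PhotometryRecording, factor: int) -> PhotometryRecording:
    """Block-mean downsample by an integer factor.

    Each output sample is the mean of a contiguous non-overlapping block of
    ``factor`` input samples; a trailing partial block is dropped. Event
    timestamps are left untouched.
    """
    if factor < 1 or int(factor) != factor:
        raise InvalidParameterError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return rec
    n_blocks = rec.n_samples // factor
    if n_blocks == 0:
        raise InvalidParameterError("fewer samples than one block")
    m = n_blocks * factor

    def block_mean(x: np.ndarray) -> np.ndarray:
        return x[:m].reshape(n_blocks, factor).mean(axis=1)

    return PhotometryRecording(
        time_s=block_mean(rec.time_s),
        sig_465=block_mean(rec.sig_465),
        ref_405=block_mean(rec.ref_405),
        fs=rec.fs / factor,
        events=rec.events,
        truth=rec.truth,
    )


def fit_reference(rec: PhotometryRecording) -> ReferenceFit:
    """Least-squares linear regression of the 465 channel on the 405 channel."""
    if rec.n_samples < 2:
        raise InvalidParameterError("need at least 2 samples to fit")
    x = rec.ref_405
    y = rec.sig_465
    if np.ptp(x) == 0:
        raise DegenerateFitError("reference channel is constant; OLS is degenerate")
    # Normal equations via polyfit; well conditioned after centering.
    x0 = x.mean()
    slope, intercept0 = np.polyfit(x - x0, y, 1)
    intercept = intercept0 - slope * x0
    resid = y - (slope * x + intercept)
    return ReferenceFit(slope=float(slope), intercept=float(intercept),
                        rss=float(resid @ resid))


def compute_dff(rec: PhotometryRecording, fit: ReferenceFit) -> DffTrace:
    """dFF = 100 * (sig_465 - fitted_405) / fitted_405, then z-score.

    Raises :class:`UnusableBaselineError` if the fitted reference is not
    strictly positive everywhere. A zero-variance dFF yields ``zdff=None``
    with the degenerate flag set rather than an exception.
    """
    fitted = fit.predict(rec.ref_405)
    bad = np.nonzero(fitted <= 0)[0]
    if bad.size:
        t0 = float(rec.time_s[bad[0]])
        raise UnusableBaselineError(
            f"fitted reference non-positive first at t={t0:.6g} s", t0
        )
    dff = 100.0 * (rec.sig_465 - fitted) / fitted
    mean = float(dff.mean())
    sd = float(dff.std(ddof=0))
    # treat numerically-constant dFF (floating-point residue only) as degenerate
    degenerate = sd <= 1e-12 * max(1.0, abs(mean), float(np.abs(dff).max()))
    zdff = None if degenerate else (dff - mean) / sd
    return DffTrace(time_s=rec.time_s, dff=dff, zdff=zdff,
                    session_mean=mean, session_sd=sd, fs=rec.fs)


def zscore(trace: DffTrace) -> DffTrace:
    """Recompute the z-scored dFF over the full session (population sd)."""
    if trace.dff.size < 2:
        raise InvalidParameterError("cannot z-score fewer than 2 samples")
    mean = float(trace.dff.mean())
    sd = float(trace.dff.std(ddof=0))
    if sd <= 0:
        raise DegenerateTraceError("session sd is zero; z-score undefined")
    return replace(trace, zdff=(trace.dff - mean) / sd,
                   session_mean=mean, session_sd=sd)


def process_recording(rec: PhotometryRecording, factor: int = 10) -> DffTrace:
    """Full pipeline: downsample, fit reference, dFF, z-score."""
    ds = downsample(rec, factor)
    trace = compute_dff(ds, fit_reference(ds))
    if trace.session_sd > 0:
        trace = zscore(trace)
    return trace
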