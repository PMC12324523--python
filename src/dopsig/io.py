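"""Plain-text readers and writers for the pipeline's columnar formats.

Photometry streams: CSV with columns time_s, sig_465, ref_405 (sampling rate
inferred from the grid). Event tables: CSV with event_type, time_s,
trial_index. FSCV sweeps: CSV time_s, value plus a JSON sidecar carrying the
stimulation time, units and calibration factor. Activity: CSV with
epoch_start_s, activity, sleep_state.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .circadian import ActivitySeries
from .errors import InvalidParameterError
from .fscv import FscvTrace
from .photometry import DffTrace, PhotometryRecording


def _sidecar(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_recording(rec: PhotometryRecording, path: str | Path,
                    events_path: str | Path | None = None) -> None:
    pd.DataFrame(
        {"time_s": rec.time_s, "sig_465": rec.sig_465, "ref_405": rec.ref_405}
    ).to_csv(path, index=False)
    if events_path is not None:
        rec.events.to_csv(events_path, index=False)


def read_recording(path: str | Path,
                   events_path: str | Path | None = None) -> PhotometryRecording:
    df = pd.read_csv(path)
    for col in ("time_s", "sig_465", "ref_405"):
        if col not in df.columns:
            raise InvalidParameterError(f"missing column {col!r} in {path}")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise InvalidParameterError("recording must have at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    events = read_events(events_path) if events_path is not None else None
    kwargs = {} if events is None else {"events": events}
    return PhotometryRecording(time_s=t, sig_465=df["sig_465"].to_numpy(),
                               ref_405=df["ref_405"].to_numpy(), fs=fs, **kwargs)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"event_type", "time_s", "trial_index"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"event table needs columns {required}")
    return df


def write_trace(trace: DffTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "dff_pct": trace.dff,
            "zdff": trace.zdff if trace.zdff is not None else np.nan,
        }
    ).to_csv(path, index=False)


def read_trace(path: str | Path) -> DffTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dff = df["dff_pct"].to_numpy()
    zdff = df["zdff"].to_numpy()
    if np.isnan(zdff).all():
        zdff = None
    fs = 1.0 / float(np.median(np.diff(t)))
    return DffTrace(time_s=t, dff=dff, zdff=zdff,
                    session_mean=float(dff.mean()),
                    session_sd=float(dff.std(ddof=0)), fs=fs)


def write_fscv(trace: FscvTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "value": trace.value}).to_csv(
        path, index=False
    )
    meta = {
        "units": trace.units,
        "stim_time_s": trace.stim_time_s,
        "calibration_factor_um_per_pa": trace.calibration_factor_um_per_pa,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_fscv(path: str | Path, stim_time_s: float | None = None,
              units: str | None = None,
              calibration_factor: float | None = None) -> FscvTrace:
    df = pd.read_csv(path)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    stim = stim_time_s if stim_time_s is not None else meta.get("stim_time_s")
    if stim is None:
        raise InvalidParameterError("stimulation time not given and no sidecar found")
    return FscvTrace(
        time_s=df["time_s"].to_numpy(),
        value=df["value"].to_numpy(),
        units=units or meta.get("units", "pA"),
        stim_time_s=float(stim),
        calibration_factor_um_per_pa=(
            calibration_factor
            if calibration_factor is not None
            else meta.get("calibration_factor_um_per_pa")
        ),
    )


def write_activity(s: ActivitySeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "epoch_start_s": s.epoch_start_s,
            "activity": s.activity,
            "sleep_state": s.sleep_state,
        }
    ).to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps({"epoch_s": s.epoch_s, "zt_offset_h": s.zt_offset_h})
    )


def read_activity(path: str | Path, zt_offset_h: float | None = None) -> ActivitySeries:
    df = pd.read_csv(path)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    t = df["epoch_start_s"].to_numpy(dtype=float)
    epoch_s = meta.get("epoch_s", float(np.median(np.diff(t))))
    return ActivitySeries(
        epoch_start_s=t,
        activity=df["activity"].to_numpy(),
        sleep_state=df["sleep_state"].to_numpy(),
        epoch_s=float(epoch_s),
        zt_offset_h=float(
            zt_offset_h if zt_offset_h is not None else meta.get("zt_offset_h", 0.0)
        ),
    )


def write_ground_truth(truth: object, path: str | Path) -> None:
    """Emit generator ground truth as JSON for external test harnesses."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        if callable(o):
            return repr(o)
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(truth, default=default, indent=2))
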