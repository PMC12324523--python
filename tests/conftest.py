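"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths (and scipy's
peak machinery) so that agreement tests are two-route checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dopsig.photometry import DffTrace


# ---------------------------------------------------------------------------
# brute-force peak/prominence oracle (pure python, strict local maxima)

def oracle_local_maxima(x: np.ndarray) -> list[int]:
    return [
        i
        for i in range(1, len(x) - 1)
        if x[i - 1] < x[i] and x[i] > x[i + 1]
    ]


def oracle_prominence(x: np.ndarray, p: int) -> float:
    """Walk out from peak p until a strictly higher sample (or the edge);
    prominence = height above the higher of the two interval minima."""
    left_min = x[p]
    i = p - 1
    while i >= 0 and x[i] <= x[p]:
        left_min = min(left_min, x[i])
        i -= 1
    right_min = x[p]
    i = p + 1
    while i < len(x) and x[i] <= x[p]:
        right_min = min(right_min, x[i])
        i += 1
    return x[p] - max(left_min, right_min)


def oracle_detect(x: np.ndarray, threshold: float) -> list[tuple[int, float]]:
    """All strict local maxima with prominence strictly above threshold."""
    out = []
    for p in oracle_local_maxima(x):
        pr = oracle_prominence(x, p)
        if pr > threshold:
            out.append((p, pr))
    return out


# ---------------------------------------------------------------------------
# brute-force operant recount (plain loops over the raw event rows)

def oracle_operant_recount(events: pd.DataFrame) -> dict:
    trials = sorted(events["trial_index"].unique())
    n_pres = 0
    n_pressed = 0
    n_rewarded = 0
    total_presses = 0
    first_lat, all_lat, reward_lat = [], [], []
    for ti in trials:
        rows = events[events["trial_index"] == ti]
        ext = [r.time_s for r in rows.itertuples() if r.event_type == "lever_extension"]
        if not ext:
            continue
        n_pres += 1
        presses = sorted(
            r.time_s for r in rows.itertuples() if r.event_type == "lever_press"
        )
        total_presses += len(presses)
        if presses:
            n_pressed += 1
            first_lat.append(presses[0] - ext[0])
            all_lat.extend(p - ext[0] for p in presses)
        ups = sorted(r.time_s for r in rows.itertuples() if r.event_type == "dipper_up")
        downs = sorted(
            r.time_s for r in rows.itertuples() if r.event_type == "dipper_down"
        )
        heads = sorted(
            r.time_s for r in rows.itertuples() if r.event_type == "head_entry"
        )
        if ups:
            up = ups[0]
            down = downs[0] if downs else float("inf")
            during = [h for h in heads if up <= h <= down]
            if during:
                reward_lat.append(during[0] - up)
                if presses:
                    n_rewarded += 1
    return {
        "n_presentations": n_pres,
        "pct_lever_press": 100.0 * n_pressed / n_pres,
        "pct_rewarded_trials": 100.0 * n_rewarded / n_pres,
        "total_presses": total_presses,
        "latency_first_press_s": float(np.mean(first_lat)) if first_lat else float("nan"),
        "latency_mean_press_s": float(np.mean(all_lat)) if all_lat else float("nan"),
        "latency_reward_s": float(np.mean(reward_lat)) if reward_lat else float("nan"),
    }


# ---------------------------------------------------------------------------
# brute-force IS/IV double loops on an hourly sequence

def oracle_is(hourly: np.ndarray, n_days: int) -> float:
    p = 24
    n = hourly.size
    xbar = sum(hourly) / n
    hour_means = []
    for h in range(p):
        vals = [hourly[d * p + h] for d in range(n_days)]
        hour_means.append(sum(vals) / len(vals))
    num = n * sum((m - xbar) ** 2 for m in hour_means)
    den = p * sum((v - xbar) ** 2 for v in hourly)
    return num / den


def oracle_iv(x: np.ndarray) -> float:
    n = x.size
    xbar = sum(x) / n
    num = n * sum((x[i] - x[i - 1]) ** 2 for i in range(1, n))
    den = (n - 1) * sum((v - xbar) ** 2 for v in x)
    return num / den


# ---------------------------------------------------------------------------

@pytest.fixture
def zdff_trace_factory():
    """Build a DffTrace directly from an array (as if already z-scored)."""

    def make(x: np.ndarray, fs: float = 100.0) -> DffTrace:
        x = np.asarray(x, dtype=float)
        t = np.arange(x.size) / fs
        return DffTrace(time_s=t, dff=x, zdff=x,
                        session_mean=float(x.mean()),
                        session_sd=float(x.std(ddof=0)) or 1.0, fs=fs)

    return make
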