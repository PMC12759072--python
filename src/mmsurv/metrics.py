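"""Per-generation elongation-rate fits, expression levels and windowed summaries.

The central quantity is the single-cell elongation rate mu: within one cell
cycle the length follows S_t = S_0 * exp(mu * t), so mu is the slope of an
ordinary least-squares fit of ln(length) against time.  Fits with fewer than
three frames are marked invalid.  Expression levels are total reporter
fluorescence divided by cell area, a concentration proxy that is insensitive
to cell size.

Two per-frame rate views are provided on top of the per-generation fits:

* the generation fit broadcast to its frames (the classical per-cell-cycle
  rate), and
* a windowed instantaneous rate (regression slope of ln length over a short
  sliding window, never crossing a division), which is what the fate
  classifier needs for filamenting cells whose "generations" last many hours.

Population summaries pool per-cell values over consecutive two-hour windows
after the first hours of the recording are discarded (cells are then at
steady state); with the default timeline the drug window of the re-zeroed
("retained") time axis is [2, 14) hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GenerationFit",
    "fit_elongation_rate",
    "fit_generations",
    "detect_generations",
    "expression_per_area",
    "add_rate_columns",
    "window_distributions",
    "retained_time",
]

LINEAGE_KEYS = ["condition", "replicate_id", "lineage_id"]
GENERATION_KEYS = LINEAGE_KEYS + ["generation_id"]


@dataclass(frozen=True)
class GenerationFit:
    """One exponential fit over a single cell cycle."""

    mu: float          # h^-1
    s0: float          # um, fitted length at birth_time
    birth_time: float
    end_time: float
    n_frames: int
    r2: float
    valid: bool


def fit_elongation_rate(times: Sequence[float], lengths: Sequence[float]) -> GenerationFit:
    """Least-squares exponential fit of one generation.

    ``mu`` is the slope of ln(length) on time and ``s0`` the fitted length at
    the first frame.  With fewer than 3 frames the fit is flagged invalid and
    ``mu`` is NaN, matching the minimum-frames constraint used for cell-cycle
    fits throughout the package.
    """
    t = np.asarray(times, dtype=float)
    y_raw = np.asarray(lengths, dtype=float)
    if t.ndim != 1 or t.shape != y_raw.shape or t.size == 0:
        raise ValueError("times and lengths must be equal-length 1-D sequences")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(y_raw <= 0):
        raise ValueError("lengths must be strictly positive (cannot log-transform)")
    n = t.size
    if n < 3:
        return GenerationFit(
            mu=float("nan"), s0=float(y_raw[0]), birth_time=float(t[0]),
            end_time=float(t[-1]), n_frames=n, r2=float("nan"), valid=False,
        )
    y = np.log(y_raw)
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (intercept + slope * t)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - float(resid @ resid) / sst
    return GenerationFit(
        mu=slope,
        s0=float(math.exp(intercept + slope * t[0])),
        birth_time=float(t[0]),
        end_time=float(t[-1]),
        n_frames=n,
        r2=r2,
        valid=True,
    )


def fit_generations(obs: pd.DataFrame, time_col: str = "time_h",
                    min_frames: int = 3) -> pd.DataFrame:
    """Vectorised per-generation exponential fits for a whole table.

    Returns one row per (condition, replicate, lineage, generation) with
    columns mu, s0, birth_time, end_time, n_frames, r2, valid.
    """
    if (obs["length_um"] <= 0).any():
        raise ValueError("lengths must be strictly positive")
    df = obs[GENERATION_KEYS].copy()
    x = obs[time_col].to_numpy(dtype=float)
    y = np.log(obs["length_um"].to_numpy(dtype=float))
    df["_x"] = x
    df["_y"] = y
    df["_xx"] = x * x
    df["_xy"] = x * y
    df["_yy"] = y * y
    g = df.groupby(GENERATION_KEYS, sort=False, observed=True)
    agg = g.agg(
        n=("_x", "size"),
        sx=("_x", "sum"),
        sy=("_y", "sum"),
        sxx=("_xx", "sum"),
        sxy=("_xy", "sum"),
        syy=("_yy", "sum"),
        birth_time=("_x", "min"),
        end_time=("_x", "max"),
    ).reset_index()
    n = agg["n"].to_numpy(dtype=float)
    sx, sy = agg["sx"].to_numpy(), agg["sy"].to_numpy()
    sxx, sxy, syy = agg["sxx"].to_numpy(), agg["sxy"].to_numpy(), agg["syy"].to_numpy()
    vxx = sxx - sx * sx / n
    vxy = sxy - sx * sy / n
    vyy = syy - sy * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(vxx > 0, vxy / np.where(vxx > 0, vxx, 1.0), 0.0)
        r2 = np.where(vyy > 0, slope * vxy / np.where(vyy > 0, vyy, 1.0), 1.0)
    intercept = (sy - slope * sx) / n
    valid = (agg["n"].to_numpy() >= min_frames) & (vxx > 0)
    out = agg[GENERATION_KEYS + ["birth_time", "end_time"]].copy()
    out["n_frames"] = agg["n"].to_numpy()
    out["mu"] = np.where(valid, slope, np.nan)
    out["s0"] = np.exp(intercept + slope * agg["birth_time"].to_numpy())
    out["r2"] = np.where(valid, r2, np.nan)
    out["valid"] = valid
    return out


def detect_generations(lengths: Sequence[float], drop_ratio: float = 0.6) -> np.ndarray:
    """Assign generation ids from length drops (fallback when ids are absent).

    A new generation starts at any frame whose length is below
    ``drop_ratio`` times the previous frame's length -- a division roughly
    halves the mother's length.  Monotone traces yield a single generation.
    """
    a = np.asarray(lengths, dtype=float)
    if a.size == 0:
        return np.zeros(0, dtype=np.int64)
    drops = np.zeros(a.size, dtype=np.int64)
    drops[1:] = (a[1:] < drop_ratio * a[:-1]).astype(np.int64)
    return np.cumsum(drops)


def expression_per_area(obs: pd.DataFrame) -> pd.DataFrame:
    """Add sos_expression and mkate_expression columns (totals / area, a.u.)."""
    area = obs["area_um2"].to_numpy(dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be strictly positive")
    out = obs.copy()
    out["sos_expression"] = obs["gfp_total"].to_numpy(dtype=float) / area
    out["mkate_expression"] = obs["mkate_total"].to_numpy(dtype=float) / area
    return out


def retained_time(obs: pd.DataFrame, discard_first_h: float = 4.0,
                  time_col: str = "time_h") -> pd.DataFrame:
    """Discard the first hours and re-zero time (column ``time_ret``)."""
    out = obs[obs[time_col] >= discard_first_h - 1e-9].copy()
    out["time_ret"] = out[time_col] - discard_first_h
    return out


# --------------------------------------------------------------------------- #
# sliding-window instantaneous rates
# --------------------------------------------------------------------------- #


def _window_frames(window_h: float, dt: float) -> int:
    return int(round(window_h / dt)) + 1


def _slope_kernel(k: int, dt: float) -> np.ndarray:
    idx = np.arange(k, dtype=float)
    idx -= idx.mean()
    return idx / (float(idx @ idx) * dt)


def _segment_rates(y: np.ndarray, dt: float, smooth_frames: int,
                   fwd_frames: int, min_frames: int) -> Tuple[np.ndarray, np.ndarray]:
    """Centered and forward regression slopes for one generation segment.

    The centered window shrinks to the whole segment when the segment is
    shorter than the nominal window (then the generation fit itself is the
    best rate estimate); edge positions reuse the nearest full-window value.
    Forward slopes need the full window ahead inside the segment and are NaN
    otherwise.
    """
    n = y.size
    cen = np.full(n, np.nan)
    fwd = np.full(n, np.nan)
    if n >= 2:
        k = min(smooth_frames, n)
        slopes = np.convolve(y, _slope_kernel(k, dt)[::-1], mode="valid")
        half = (k - 1) // 2
        cen[half:half + slopes.size] = slopes
        cen[:half] = slopes[0]
        cen[half + slopes.size:] = slopes[-1]
    if n >= fwd_frames and fwd_frames >= max(min_frames, 2):
        slopes = np.convolve(y, _slope_kernel(fwd_frames, dt)[::-1], mode="valid")
        fwd[:slopes.size] = slopes
    return cen, fwd


def add_rate_columns(
    frames: pd.DataFrame,
    frame_interval_h: float,
    smooth_window_h: float = 1.5,
    forward_window_h: float = 1.0,
    min_frames: int = 4,
    time_col: str = "time_ret",
) -> pd.DataFrame:
    """Attach per-frame rate estimates to an observation table.

    Adds ``rate_smooth`` (centered within-generation slope of ln length,
    window ``smooth_window_h``) and ``rate_forward`` (slope over the next
    ``forward_window_h`` within the generation).  Also broadcasts the
    per-generation fit as ``mu_gen``.
    """
    dt = frame_interval_h
    smooth_frames = _window_frames(smooth_window_h, dt)
    fwd_frames = _window_frames(forward_window_h, dt)

    out = frames.sort_values(LINEAGE_KEYS + ["frame"], kind="stable").reset_index(drop=True)
    y_all = np.log(out["length_um"].to_numpy(dtype=float))
    rate_smooth = np.full(len(out), np.nan)
    rate_forward = np.full(len(out), np.nan)

    seg_keys = out.groupby(GENERATION_KEYS, sort=False, observed=True).indices
    for _, idx in seg_keys.items():
        idx = np.sort(np.asarray(idx))
        cen, fwd = _segment_rates(y_all[idx], dt, smooth_frames, fwd_frames, min_frames)
        rate_smooth[idx] = cen
        rate_forward[idx] = fwd
    out["rate_smooth"] = rate_smooth
    out["rate_forward"] = rate_forward

    fits = fit_generations(out, time_col=time_col)
    out = out.merge(
        fits[GENERATION_KEYS + ["mu"]].rename(columns={"mu": "mu_gen"}),
        on=GENERATION_KEYS,
        how="left",
    )
    return out


# --------------------------------------------------------------------------- #
# windowed population summaries
# --------------------------------------------------------------------------- #


def window_distributions(
    frames: pd.DataFrame,
    value_col: str,
    window_h: float = 2.0,
    time_col: str = "time_ret",
    t_max: Optional[float] = None,
    mask: Optional[pd.Series] = None,
    discard_first_h: float = 0.0,
) -> pd.DataFrame:
    """Medians and counts of a per-frame quantity over consecutive windows.

    ``frames`` is expected on the retained time axis (see
    :func:`retained_time`); raw tables can instead be passed with
    ``time_col="time_h"`` and a non-zero ``discard_first_h``, which drops
    the settling period and re-zeroes time before windowing.  NaN values
    and, optionally, rows where ``mask`` is False are excluded from the
    pooled statistics but windows always cover the full observation span;
    an empty window reports count 0 and a NaN median.  A trailing window
    that the span does not fill completely is flagged ``partial``.
    """
    if frames.empty:
        raise ValueError("no trajectories to summarise")
    t = frames[time_col].to_numpy(dtype=float)
    v = frames[value_col].to_numpy(dtype=float)
    keep = ~np.isnan(v)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if discard_first_h:
        sel = t >= discard_first_h - 1e-9
        t, v, keep = t[sel] - discard_first_h, v[sel], keep[sel]
    span = float(t_max) if t_max is not None else float(t.max())
    span = max(span, float(t.max()) + 1e-9)  # final frame always falls in a window
    n_win = int(math.ceil(span / window_h))
    rows = []
    for w in range(n_win):
        t0, t1 = w * window_h, (w + 1) * window_h
        sel = keep & (t >= t0) & (t < t1)
        cnt = int(sel.sum())
        rows.append(
            {
                "t0": t0,
                "t1": t1,
                "median": float(np.median(v[sel])) if cnt else float("nan"),
                "count": cnt,
                "partial": t1 > span + 1e-9,
            }
        )
    return pd.DataFrame(rows)


def median_in_window(
    frames: pd.DataFrame,
    value_col: str,
    t0: float,
    t1: float,
    time_col: str = "time_ret",
    mask: Optional[pd.Series] = None,
) -> float:
    """Median of a per-frame quantity pooled over one time window."""
    t = frames[time_col].to_numpy(dtype=float)
    v = frames[value_col].to_numpy(dtype=float)
    sel = (t >= t0) & (t < t1) & ~np.isnan(v)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    if not sel.any():
        return float("nan")
    return float(np.median(v[sel]))
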