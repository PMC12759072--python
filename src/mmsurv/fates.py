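"""Lineage fate classification: survived, died (low/high SOS) or censored.

A mother-cell lineage is called *dead* when its instantaneous elongation
rate drops essentially to zero after drug onset and never recovers for the
remainder of the observation -- the operational definition of death for
non-recovering growth arrest in mother-machine experiments.  Concretely,
with ``mu_ref`` the drug-free median elongation rate of the population:

* the forward-looking rate (regression slope of ln length over the next
  ``arrest_window`` hours, never crossing a division) falls below
  ``arrest_fraction * mu_ref`` at some time t* after drug onset, and
* the smoothed rate never exceeds ``recovery_fraction * mu_ref`` after t*.

The death time is t*, the start of the sustained arrest.  Transient arrest
followed by sustained regrowth voids the death call.  Because slow media
make the relative thresholds smaller than the noise floor of the slope
estimates, both thresholds also have small absolute floors (in h^-1).

Lineages whose observation ends before the end of the experiment (random
channel loss, or truncation when a filament reaches the maximum channel
length) and that show no prior death are right-censored at their last
observed frame; death takes precedence over later censoring.

Dead lineages are sub-classified by their peak SOS expression between drug
onset and shortly after death: *high* if the peak exceeds a threshold set at
``sos_threshold_multiplier`` times the median SOS expression of survivors
over the final two hours of drug exposure, else *low*.  The two simulated
death modes differ by an order of magnitude in peak SOS, so the default
multiplier of 3 sits in the gap.

Quality control removes lineages that are initially filamented (mean length
in the first two retained hours above ``qc_filament_factor`` times twice the
population median birth length) or initially non-growing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from . import metrics
from .metrics import GENERATION_KEYS, LINEAGE_KEYS

__all__ = [
    "Timeline",
    "ClassifierParams",
    "LineageFate",
    "apply_qc_filters",
    "classify_fate",
    "sos_threshold",
    "classify_sos",
    "classify_population",
    "fate_fractions",
]

log = logging.getLogger(__name__)

SURVIVED = "survived"
DIED = "died"
CENSORED = "censored"


@dataclass(frozen=True)
class Timeline:
    """Experiment timing on the retained axis (hours)."""

    frame_interval: float = 5.0      # minutes
    t_drug_on: float = 2.0
    t_drug_off: float = 14.0
    t_end: float = 24.0
    discard_first_h: float = 4.0

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval / 60.0

    @classmethod
    def from_config(cls, cfg: SimulationConfig) -> "Timeline":
        return cls(
            frame_interval=cfg.frame_interval,
            t_drug_on=cfg.t_drug_on,
            t_drug_off=cfg.t_drug_off,
            t_end=cfg.t_end,
            discard_first_h=cfg.t_preamble,
        )


@dataclass(frozen=True)
class ClassifierParams:
    arrest_fraction: float = 0.05     # of the drug-free median rate
    arrest_window: float = 1.0        # h of sustained arrest
    recovery_fraction: float = 0.2    # of the drug-free median rate
    arrest_rate_floor: float = 0.05   # h^-1, absolute floor on the arrest threshold
    recovery_rate_floor: float = 0.10 # h^-1, absolute floor on the recovery threshold
    smooth_window: float = 1.5        # h, centered rate-smoothing window
    min_window_frames: int = 4
    sos_threshold_multiplier: float = 3.0
    sos_fallback_threshold: float = 1000.0  # a.u., used when survivors are too few
    min_survivors_for_threshold: int = 20
    qc_filament_factor: float = 2.0   # x (2 * median birth length)
    max_channel_length: float = 40.0

    def __post_init__(self) -> None:
        if not (0.0 < self.arrest_fraction < self.recovery_fraction < 1.0):
            raise ValueError("need 0 < arrest_fraction < recovery_fraction < 1")
        if self.arrest_rate_floor >= self.recovery_rate_floor:
            raise ValueError("arrest_rate_floor must be below recovery_rate_floor")
        if min(self.sos_threshold_multiplier, self.arrest_window, self.smooth_window) <= 0:
            raise ValueError("windows and multipliers must be positive")


@dataclass(frozen=True)
class LineageFate:
    condition: str
    replicate_id: int
    lineage_id: int
    fate: str                          # survived | died | censored
    death_time: Optional[float] = None
    censor_time: Optional[float] = None
    sos_class: str = "not_applicable"  # low | high | not_applicable
    peak_sos: float = float("nan")
    qc_excluded: bool = False
    qc_reason: str = ""

    def __post_init__(self) -> None:
        if self.fate == DIED and self.death_time is None:
            raise ValueError("died requires death_time")
        if self.fate == CENSORED and self.censor_time is None:
            raise ValueError("censored requires censor_time")
        if self.death_time is not None and self.censor_time is not None:
            raise ValueError("exactly one of death_time/censor_time may be set")


# --------------------------------------------------------------------------- #
# reference rate and QC
# --------------------------------------------------------------------------- #


def reference_mu(fits: pd.DataFrame, timeline: Timeline) -> float:
    """Population median elongation rate before drug onset (retained time)."""
    pre = fits[
        fits["valid"]
        & (fits["birth_time"] < timeline.t_drug_on)
        & (fits["mu"] > 0)
    ]
    if pre.empty:
        raise ValueError("no valid pre-drug generation fits to set the reference rate")
    return float(pre["mu"].median())


def apply_qc_filters(
    frames: pd.DataFrame,
    fits: pd.DataFrame,
    params: ClassifierParams,
    timeline: Timeline,
    mu_ref: Optional[float] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Remove initially filamented or initially non-growing lineages.

    Both rules look only at the first two retained hours (before drug
    onset).  Returns (kept frame table, exclusion log with one row per
    excluded lineage and a human-readable reason).
    """
    if mu_ref is None:
        mu_ref = reference_mu(fits, timeline)
    early = frames[frames["time_ret"] < timeline.t_drug_on]
    median_birth = float(fits.loc[fits["valid"], "s0"].median())
    len_thresh = params.qc_filament_factor * 2.0 * median_birth

    grouped = early.groupby(LINEAGE_KEYS, sort=False, observed=True)
    mean_len = grouped["length_um"].mean()
    # growth is judged only on frames inside the window: a generation born
    # before drug onset may extend far beyond it (slow media, arrested cells)
    mean_mu = grouped["rate_smooth"].mean()

    arrest_thresh = max(params.arrest_fraction * mu_ref, params.arrest_rate_floor)
    exclusions: List[dict] = []
    for key, ml in mean_len.items():
        if ml > len_thresh:
            exclusions.append(dict(zip(LINEAGE_KEYS, key), reason="initially filamented"))
            continue
        mu_i = mean_mu.get(key, float("nan"))
        if not (mu_i > arrest_thresh):  # NaN (no valid early fit) also fails
            exclusions.append(dict(zip(LINEAGE_KEYS, key), reason="non-growing at start"))
    excl = pd.DataFrame(exclusions, columns=LINEAGE_KEYS + ["reason"])
    if excl.empty:
        return frames, excl
    flag = frames[LINEAGE_KEYS].merge(
        excl[LINEAGE_KEYS].assign(_bad=True), on=LINEAGE_KEYS, how="left"
    )["_bad"].to_numpy()
    return frames[pd.isna(flag)], excl


# --------------------------------------------------------------------------- #
# per-lineage fate call
# --------------------------------------------------------------------------- #


def _first_sustained_arrest(
    t: np.ndarray,
    rate_forward: np.ndarray,
    rate_smooth: np.ndarray,
    t_drug_on: float,
    arrest_thresh: float,
    recovery_thresh: float,
    arrest_window: float,
) -> Optional[float]:
    """Earliest time of an arrest that is never followed by recovery."""
    n = t.size
    # suffix maxima of the smoothed rate, ignoring NaN
    suffix = np.full(n + 1, -np.inf)
    rs = np.where(np.isnan(rate_smooth), -np.inf, rate_smooth)
    for k in range(n - 1, -1, -1):
        suffix[k] = max(suffix[k + 1], rs[k])
    candidates = np.nonzero(
        (t >= t_drug_on - 1e-9) & (rate_forward < arrest_thresh)
    )[0]
    for i in candidates:
        # recovery must be judged after the arrest window has elapsed
        j = int(np.searchsorted(t, t[i] + arrest_window, side="left"))
        if suffix[min(j, n)] < recovery_thresh:
            return float(t[i])
    return None


def classify_fate(
    lineage: pd.DataFrame,
    params: ClassifierParams,
    timeline: Timeline,
    mu_ref: float,
) -> LineageFate:
    """Classify one lineage from its per-frame table.

    The table must carry ``time_ret``, ``length_um``, ``rate_forward`` and
    ``rate_smooth`` columns (see :func:`mmsurv.metrics.add_rate_columns`).
    """
    if lineage.empty:
        raise ValueError("empty trajectory")
    t = lineage["time_ret"].to_numpy(dtype=float)
    cond = str(lineage["condition"].iloc[0])
    rep = int(lineage["replicate_id"].iloc[0])
    lin = int(lineage["lineage_id"].iloc[0])

    arrest_thresh = max(params.arrest_fraction * mu_ref, params.arrest_rate_floor)
    recovery_thresh = max(params.recovery_fraction * mu_ref, params.recovery_rate_floor)
    death_time = _first_sustained_arrest(
        t,
        lineage["rate_forward"].to_numpy(dtype=float),
        lineage["rate_smooth"].to_numpy(dtype=float),
        timeline.t_drug_on,
        arrest_thresh,
        recovery_thresh,
        params.arrest_window,
    )
    last_t = float(t[-1])
    if death_time is not None:
        return LineageFate(cond, rep, lin, DIED, death_time=death_time)
    ends_early = last_t < timeline.t_end - timeline.frame_interval_h - 1e-9
    hit_limit = bool((lineage["length_um"].to_numpy() >= params.max_channel_length).any())
    if ends_early or hit_limit:
        return LineageFate(cond, rep, lin, CENSORED, censor_time=last_t)
    return LineageFate(cond, rep, lin, SURVIVED)


# --------------------------------------------------------------------------- #
# SOS sub-classification of dead lineages
# --------------------------------------------------------------------------- #


def sos_threshold(
    survivor_frames: pd.DataFrame,
    params: ClassifierParams,
    timeline: Timeline,
) -> Tuple[float, bool]:
    """High/low SOS threshold from the survivors' steady-state expression.

    Threshold = multiplier x median survivor SOS expression over the final
    two hours of drug exposure.  Returns (threshold, used_fallback); with
    too few surviving lineages the configured absolute fallback is used and
    a warning logged.
    """
    n_surv = survivor_frames[LINEAGE_KEYS].drop_duplicates().shape[0] if not survivor_frames.empty else 0
    if n_surv < params.min_survivors_for_threshold:
        log.warning(
            "only %d survivors (<%d): falling back to absolute SOS threshold %.1f a.u.",
            n_surv, params.min_survivors_for_threshold, params.sos_fallback_threshold,
        )
        return params.sos_fallback_threshold, True
    med = metrics.median_in_window(
        survivor_frames, "sos_expression",
        timeline.t_drug_off - 2.0, timeline.t_drug_off,
    )
    if math.isnan(med):
        log.warning("no survivor frames in the final drug window: using fallback threshold")
        return params.sos_fallback_threshold, True
    return params.sos_threshold_multiplier * med, False


def classify_sos(
    lineage: pd.DataFrame,
    death_time: float,
    threshold: float,
    timeline: Timeline,
) -> Tuple[str, float]:
    """Peak SOS expression around death and the resulting low/high call."""
    t = lineage["time_ret"].to_numpy(dtype=float)
    sos = lineage["sos_expression"].to_numpy(dtype=float)
    hi = min(death_time + 3.0, timeline.t_end)
    sel = (t >= timeline.t_drug_on) & (t <= hi)
    peak = float(np.nanmax(sos[sel])) if sel.any() else float(np.nanmax(sos))
    return ("high" if peak >= threshold else "low"), peak


# --------------------------------------------------------------------------- #
# population driver
# --------------------------------------------------------------------------- #


def classify_population(
    obs: pd.DataFrame,
    params: ClassifierParams,
    timeline: Timeline,
    qc: bool = True,
    mu_ref: Optional[float] = None,
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """End-to-end fate classification of a raw observation table.

    Discards the settling period, computes expression levels and rate
    series, applies QC, calls the fate of every lineage and sub-classifies
    dead ones by SOS level.  Returns (fate table, info) where info carries
    the QC exclusion log, the reference rate, the SOS threshold and the
    per-frame table used (``frames``).
    """
    frames = metrics.retained_time(obs, timeline.discard_first_h)
    if frames.empty:
        raise ValueError("observation table is empty after discarding the settling period")
    frames = metrics.expression_per_area(frames)
    frames = metrics.add_rate_columns(
        frames,
        timeline.frame_interval_h,
        smooth_window_h=params.smooth_window,
        forward_window_h=params.arrest_window,
        min_frames=params.min_window_frames,
    )
    fits = metrics.fit_generations(frames, time_col="time_ret")
    if mu_ref is None:
        mu_ref = reference_mu(fits, timeline)

    excl = pd.DataFrame(columns=LINEAGE_KEYS + ["reason"])
    if qc:
        frames, excl = apply_qc_filters(frames, fits, params, timeline, mu_ref)

    frames = frames.reset_index(drop=True)
    group_rows = frames.groupby(LINEAGE_KEYS, sort=False, observed=True).indices
    fates: List[LineageFate] = []
    for key, idx in group_rows.items():
        fates.append(classify_fate(frames.iloc[np.sort(idx)], params, timeline, mu_ref))

    # survivor-based SOS threshold, then sub-classify the dead
    surv_keys = [
        (f.condition, f.replicate_id, f.lineage_id) for f in fates if f.fate == SURVIVED
    ]
    surv_idx = (
        np.concatenate([group_rows[k] for k in surv_keys])
        if surv_keys
        else np.zeros(0, dtype=int)
    )
    survivor_frames = frames.iloc[surv_idx]
    threshold, used_fallback = sos_threshold(survivor_frames, params, timeline)

    final: List[LineageFate] = []
    for f in fates:
        if f.fate == DIED:
            sub = frames.iloc[np.sort(group_rows[(f.condition, f.replicate_id, f.lineage_id)])]
            cls, peak = classify_sos(sub, f.death_time, threshold, timeline)
            f = LineageFate(
                f.condition, f.replicate_id, f.lineage_id, DIED,
                death_time=f.death_time, sos_class=cls, peak_sos=peak,
            )
        final.append(f)
    for _, row in excl.iterrows():
        final.append(
            LineageFate(
                row["condition"], int(row["replicate_id"]), int(row["lineage_id"]),
                CENSORED, censor_time=0.0, qc_excluded=True, qc_reason=row["reason"],
            )
        )

    fate_df = pd.DataFrame(
        [
            {
                "condition": f.condition,
                "replicate_id": f.replicate_id,
                "lineage_id": f.lineage_id,
                "fate": f.fate,
                "death_time": np.nan if f.death_time is None else f.death_time,
                "censor_time": np.nan if f.censor_time is None else f.censor_time,
                "sos_class": f.sos_class,
                "peak_sos": f.peak_sos,
                "qc_excluded": f.qc_excluded,
                "qc_reason": f.qc_reason,
            }
            for f in final
        ]
    )
    info = {
        "mu_ref": mu_ref,
        "sos_threshold": threshold,
        "sos_threshold_fallback": used_fallback,
        "exclusions": excl,
        "frames": frames,
        "fits": fits,
    }
    return fate_df, info


def fate_fractions(fate_df: pd.DataFrame, include_censored: bool = True) -> pd.Series:
    """Population decomposition into survived / low- and high-SOS dead / censored.

    Fractions are over QC-passing lineages and sum to 1.  With
    ``include_censored=False`` the denominator is restricted to lineages
    whose fate resolved (survived or died), the same population used for
    survival fractions.
    """
    df = fate_df[~fate_df["qc_excluded"]]
    if not include_censored:
        df = df[df["fate"] != CENSORED]
    n = len(df)
    if n == 0:
        raise ValueError("no classified lineages")
    out = {
        "survived": float((df["fate"] == SURVIVED).sum()) / n,
        "died_low_sos": float(((df["fate"] == DIED) & (df["sos_class"] == "low")).sum()) / n,
        "died_high_sos": float(((df["fate"] == DIED) & (df["sos_class"] == "high")).sum()) / n,
    }
    if include_censored:
        out["censored"] = float((df["fate"] == CENSORED).sum()) / n
    return pd.Series(out)
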