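"""Kaplan-Meier survival estimation and replicate-level survival fractions.

Event records are built from classified lineage fates.  The default time
origin is drug onset, so the survival function describes post-exposure
survival; durations of lineages that never die are right-censored at the
end of the experiment, and washout / channel-length truncations are
right-censored at the last observed frame.

Survival curves use the product-limit estimator with Greenwood variance and
log(-log) ("exponential Greenwood") 95% confidence intervals, as provided
by :mod:`lifelines`.  Group comparisons use the standard two-sample
log-rank test.

The end-of-experiment survival fraction Sf of a replicate is, by default,
the Kaplan-Meier estimate evaluated at the end of the experiment: with no
censoring this equals the plain survivor fraction, and under independent
censoring (lineage washout) it remains unbiased, whereas simply dropping
censored lineages under-counts survivors because they stay at risk of
washout for the whole experiment while dying lineages leave early.  The
simpler conventions are available through ``method``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .fates import CENSORED, DIED, SURVIVED, Timeline  # noqa: F401 (Timeline in signatures)

__all__ = [
    "SurvivalCurve",
    "make_event_records",
    "kaplan_meier",
    "log_rank",
    "survival_fraction",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with pointwise 95% confidence bounds."""

    time: np.ndarray        # event/censoring times, ascending, starting at 0
    s: np.ndarray           # estimated survival probability
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray

    def at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.time, t, side="right") - 1
        return float(self.s[max(idx, 0)])


def make_event_records(
    fate_df: pd.DataFrame,
    timeline: Timeline,
    origin: str = "drug_on",
) -> pd.DataFrame:
    """Duration/event table from classified fates.

    ``origin`` is either ``"drug_on"`` (durations measured from drug onset,
    the default) or ``"start"`` (from the beginning of retained time).
    QC-excluded lineages are dropped.  Censor times before the origin clamp
    to duration 0.
    """
    t0 = {"drug_on": timeline.t_drug_on, "start": 0.0}[origin]
    df = fate_df[~fate_df["qc_excluded"]].copy()
    end = timeline.t_end - t0
    duration = np.full(len(df), end, dtype=float)
    event = np.zeros(len(df), dtype=int)
    died = (df["fate"] == DIED).to_numpy()
    cens = (df["fate"] == CENSORED).to_numpy()
    duration[died] = df.loc[df["fate"] == DIED, "death_time"].to_numpy() - t0
    duration[cens] = df.loc[df["fate"] == CENSORED, "censor_time"].to_numpy() - t0
    event[died] = 1
    duration = np.clip(duration, 0.0, None)
    out = pd.DataFrame(
        {
            "lineage_id": df["lineage_id"].to_numpy(),
            "replicate_id": df["replicate_id"].to_numpy(),
            "group": df["condition"].to_numpy(),
            "duration": duration,
            "event": event,
        }
    )
    return out


def kaplan_meier(events: pd.DataFrame) -> SurvivalCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    if len(events) == 0:
        raise ValueError("no event records")
    if (events["duration"] < 0).any():
        raise ValueError("negative durations")
    kmf = KaplanMeierFitter()
    kmf.fit(events["duration"], event_observed=events["event"])
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    times = sf.index.to_numpy(dtype=float)
    table = kmf.event_table
    return SurvivalCurve(
        time=times,
        s=sf.iloc[:, 0].to_numpy(dtype=float),
        ci_low=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_high=ci.iloc[:, 1].to_numpy(dtype=float),
        n_at_risk=table["at_risk"].to_numpy(dtype=float),
    )


def log_rank(events_a: pd.DataFrame, events_b: pd.DataFrame) -> Tuple[float, float]:
    """Two-sample log-rank chi-square statistic (1 df) and two-sided p."""
    if len(events_a) == 0 or len(events_b) == 0:
        raise ValueError("both groups must be non-empty")
    if events_a["event"].sum() == 0 and events_b["event"].sum() == 0:
        return 0.0, 1.0
    res = logrank_test(
        events_a["duration"], events_b["duration"],
        event_observed_A=events_a["event"], event_observed_B=events_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def _sf_one(group: pd.DataFrame, end: float, method: str) -> Tuple[float, int]:
    died = (group["fate"] == DIED).sum()
    surv = (group["fate"] == SURVIVED).sum()
    cens = (group["fate"] == CENSORED).sum()
    if method == "exclude":
        n = surv + died
        if n == 0:
            raise ValueError("replicate has no fate-resolved lineages")
        return surv / n, int(n)
    if method == "censored_as_survivors":
        n = surv + died + cens
        return (surv + cens) / n, int(n)
    if method == "km":
        ev = pd.DataFrame(
            {
                "duration": np.where(
                    group["fate"] == DIED,
                    group["death_time"],
                    np.where(group["fate"] == CENSORED, group["censor_time"], end),
                ),
                "event": (group["fate"] == DIED).astype(int),
            }
        )
        ev["duration"] = ev["duration"].clip(lower=0.0)
        curve = kaplan_meier(ev)
        return curve.at(end), int(len(group))
    raise ValueError(f"unknown method {method!r}")


def survival_fraction(
    fate_df: pd.DataFrame,
    timeline: Timeline,
    method: str = "km",
) -> pd.DataFrame:
    """End-of-experiment survival fraction per (condition, replicate).

    ``method``:

    * ``"km"`` (default): Kaplan-Meier estimate at ``t_end`` -- equals the
      plain fraction without censoring and corrects for it otherwise;
    * ``"exclude"``: survivors / (survivors + deaths), censored lineages
      dropped from the denominator;
    * ``"censored_as_survivors"``: censored lineages counted as survivors.

    Returns one row per replicate (columns condition, replicate_id, sf,
    n_lineages).  Use :func:`replicate_mean` for the mean +- SEM.
    """
    df = fate_df[~fate_df["qc_excluded"]]
    if df.empty:
        raise ValueError("no classified lineages")
    rows = []
    for (cond, rep), group in df.groupby(["condition", "replicate_id"], sort=True):
        if len(group) == 0:
            raise ValueError(f"empty replicate {cond}/{rep}")
        sf, n = _sf_one(group, timeline.t_end, method)
        rows.append({"condition": cond, "replicate_id": rep, "sf": sf, "n_lineages": n})
    out = pd.DataFrame(rows)
    if (out["sf"] < 0).any() or (out["sf"] > 1).any():
        raise AssertionError("survival fractions outside [0, 1]")
    return out


def replicate_mean(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of Sf across replicates, per condition."""
    rows = []
    for cond, grp in summary.groupby("condition", sort=True):
        sfs = grp["sf"].to_numpy(dtype=float)
        sem = float(np.std(sfs, ddof=1) / np.sqrt(len(sfs))) if len(sfs) > 1 else float("nan")
        rows.append(
            {
                "condition": cond,
                "sf_mean": float(sfs.mean()),
                "sf_sem": sem,
                "n_replicates": len(sfs),
            }
        )
    return pd.DataFrame(rows)
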