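"""Stochastic generator of mother-machine measurement tables.

Each simulated lineage is the mother cell at the closed end of one
microchannel, observed at a fixed frame cadence.  Cells elongate
exponentially at a lineage-specific rate, divide when they reach roughly
twice the target birth length (a sizer with multiplicative threshold noise;
the mother keeps the proximal half), and carry two fluorescent reporters: a
DNA-damage (SOS) transcriptional reporter and a constitutively expressed
one.  Reported quantities mimic a segmentation-software export: one row per
cell per frame with length, area and total fluorescence per channel.

Drug phenomenology
------------------
* Tetracycline (bacteriostatic) multiplies the elongation rate by
  ``1 - tet_reduction``, approached and released with a first-order lag.
* Ciprofloxacin (bactericidal) assigns each lineage a fate: survive, die
  with survivor-like ("low") SOS expression, or die after strong ("high")
  SOS induction.  Survivors and low-SOS deaths keep dividing until death;
  high-SOS cells stop dividing at drug onset, filament with a gradually
  decaying elongation rate, and arrest abruptly at their death time, after
  which the frozen cell volume concentrates continued reporter production
  into a large SOS spike (about ``high_sos_multiplier`` times the induced
  level) before photobleaching takes over.
* After any death both reporter concentrations decay exponentially at
  ``bleach_rate`` -- the fingerprint of arrested protein production.

Censoring paths: random washout of the lineage from its channel
(``loss_rate``) and hard truncation when the cell exceeds the channel
length (``max_channel_length``).

Randomness is organised as one stream per (seed, replicate, lineage,
condition) tuple, so enlarging an experiment never reshuffles previously
generated lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import CIP, CIP_TET, CONDITIONS, NO_DRUG, TET, SimulationConfig

__all__ = [
    "GroundTruthRecord",
    "simulate_lineage",
    "simulate_condition",
    "ground_truth_frame",
    "write_observations",
    "OBSERVATION_COLUMNS",
]

OBSERVATION_COLUMNS = [
    "condition",
    "replicate_id",
    "lineage_id",
    "generation_id",
    "frame",
    "time_h",
    "length_um",
    "area_um2",
    "gfp_total",
    "mkate_total",
]

SURVIVE = "survive"
DIE_LOW = "die_low"
DIE_HIGH = "die_high"
LOST = "lost"


@dataclass(frozen=True)
class GroundTruthRecord:
    """Simulation oracle for one lineage (never visible to the analysis)."""

    condition: str
    replicate_id: int
    lineage_id: int
    true_fate: str                      # survive | die_low | die_high | lost
    true_death_time: Optional[float]    # retained hours; None unless die_*
    true_mu: float                      # h^-1, the lineage's drug-free rate

    def __post_init__(self) -> None:
        has_death = self.true_fate in (DIE_LOW, DIE_HIGH)
        if has_death != (self.true_death_time is not None):
            raise ValueError("true_death_time present iff fate is die_low/die_high")


# --------------------------------------------------------------------------- #
# per-lineage dynamics
# --------------------------------------------------------------------------- #


def _drug_rate_multiplier(cfg: SimulationConfig, condition: str, t: np.ndarray,
                          t_on: float, t_off: float) -> np.ndarray:
    """Time course of the TET effect on the elongation rate (1 = no effect)."""
    m = np.ones_like(t)
    if condition not in (TET, CIP_TET):
        return m
    r = cfg.tet_reduction if condition == TET else cfg.tet_reduction_combo
    tau = cfg.tet_relax_time
    during = (t >= t_on) & (t < t_off)
    m[during] = 1.0 - r * (1.0 - np.exp(-(t[during] - t_on) / tau))
    after = t >= t_off
    r_off = r * (1.0 - math.exp(-(t_off - t_on) / tau))
    m[after] = 1.0 - r_off * np.exp(-(t[after] - t_off) / tau)
    return m


def _sos_concentration(cfg: SimulationConfig, condition: str, t: np.ndarray,
                       t_on: float, t_off: float) -> np.ndarray:
    """SOS reporter concentration of a metabolically active cell."""
    base, ind = cfg.sos_baseline, cfg.sos_induced
    c = np.full_like(t, base, dtype=float)
    if condition not in (CIP, CIP_TET):
        return c
    tau_r = cfg.sos_rise_time
    during = (t >= t_on) & (t < t_off)
    c[during] = ind + (base - ind) * np.exp(-(t[during] - t_on) / tau_r)
    after = t >= t_off
    c_off = ind + (base - ind) * math.exp(-(t_off - t_on) / tau_r)
    c[after] = base + (c_off - base) * np.exp(-(t[after] - t_off) / cfg.sos_recovery_time)
    return c


def _draw_fate(cfg: SimulationConfig, condition: str, probs, rng) -> Tuple[str, Optional[float]]:
    """Sample (fate, death time in retained hours)."""
    p_surv, p_low, _p_high = probs
    u = rng.random()
    if u < p_surv:
        fate = SURVIVE
    elif u < p_surv + p_low:
        fate = DIE_LOW
    else:
        fate = DIE_HIGH
    if fate == SURVIVE and condition in (NO_DRUG, TET) and cfg.late_death_prob > 0:
        if rng.random() < cfg.late_death_prob:
            return DIE_LOW, rng.uniform(cfg.t_end - 4.0, cfg.t_end)
        return SURVIVE, None
    if fate == DIE_LOW:
        return fate, rng.uniform(*cfg.death_window_low)
    if fate == DIE_HIGH:
        return fate, rng.uniform(*cfg.death_window_high)
    return SURVIVE, None


def _simulate_one(cfg: SimulationConfig, condition: str, probs, rng,
                  replicate_id: int, lineage_id: int):
    """Generate the observation arrays and truth record for one lineage."""
    dt = cfg.frame_interval_h
    n = int(round((cfg.t_preamble + cfg.t_end) / dt)) + 1
    t = np.arange(n) * dt                       # raw hours, frame 0 at t=0
    t_on = cfg.t_preamble + cfg.t_drug_on
    t_off = cfg.t_preamble + cfg.t_drug_off

    ln_sig = math.sqrt(math.log(1.0 + cfg.mu_cv**2))
    mu = cfg.mu_median * rng.lognormal(0.0, ln_sig)

    fate, death_ret = _draw_fate(cfg, condition, probs, rng)
    death_raw = None if death_ret is None else death_ret + cfg.t_preamble

    # --- elongation rate time course -------------------------------------
    rate = mu * _drug_rate_multiplier(cfg, condition, t, t_on, t_off)
    if fate == DIE_HIGH:
        # slowing filamentation: the rate decays toward a floor fraction of
        # the cell's own rate and stops abruptly at the death time
        post = t >= t_on
        decay = np.exp(-(t[post] - t_on) / cfg.filament_decay_time)
        rate[post] *= np.maximum(decay, cfg.filament_rate_floor)
    if death_raw is not None:
        rate[t >= death_raw] = 0.0

    # --- division permission ----------------------------------------------
    allowed = np.ones(n, dtype=bool)
    if death_raw is not None:
        allowed[t >= death_raw] = False
    if fate == DIE_HIGH:
        allowed[t >= t_on] = False
    if (
        fate == SURVIVE
        and condition in (CIP, CIP_TET)
        and rng.random() < cfg.filament_prob_survivor
    ):
        f0 = rng.uniform(t_on + 0.5, t_off - 3.0)
        fdur = rng.uniform(*cfg.filament_duration)
        allowed[(t >= f0) & (t < f0 + fdur)] = False

    # cumulative log-growth from frame 0
    G = np.concatenate(([0.0], np.cumsum(rate[:-1]) * dt))

    # --- sizer divisions ---------------------------------------------------
    div_sig = math.sqrt(math.log(1.0 + cfg.division_noise_cv**2))
    log_len = np.empty(n)
    gen_id = np.zeros(n, dtype=np.int64)
    # next allowed frame at or after each index (n == none)
    next_allowed = np.full(n + 1, n, dtype=np.int64)
    for k in range(n - 1, -1, -1):
        next_allowed[k] = k if allowed[k] else next_allowed[k + 1]

    lb = math.log(cfg.birth_length) + rng.normal(0.0, div_sig)
    i, g = 0, 0
    while True:
        thr = math.log(2.0 * cfg.birth_length) + rng.normal(0.0, div_sig)
        # first frame j > i whose unconstrained log-length reaches thr
        target = thr - lb + G[i]
        j = int(np.searchsorted(G, target, side="left"))
        j = max(j, i + 1)
        j = int(next_allowed[min(j, n)]) if j < n else n
        j = min(j, n)
        log_len[i:j] = lb + G[i:j] - G[i]
        gen_id[i:j] = g
        if j >= n:
            break
        lb = lb + G[j] - G[i] - math.log(2.0)
        i, g = j, g + 1

    length = np.exp(log_len)

    # --- censoring ---------------------------------------------------------
    end_idx = n
    over = length > cfg.max_channel_length
    if over.any():
        end_idx = int(np.argmax(over))
    if cfg.loss_rate > 0:
        t_loss = rng.exponential(1.0 / cfg.loss_rate)
        end_idx = min(end_idx, int(np.searchsorted(t, t_loss, side="right")))
    end_idx = max(end_idx, 1)

    observed_end = t[end_idx - 1]
    if death_raw is not None and death_raw <= observed_end:
        true_fate, true_death = fate, death_ret
    elif end_idx < n:
        true_fate, true_death = LOST, None
    else:
        true_fate, true_death = (fate, death_ret) if death_raw is not None else (SURVIVE, None)
        if true_fate == SURVIVE:
            true_death = None
    if true_fate not in (DIE_LOW, DIE_HIGH):
        true_death = None

    # --- fluorescence ------------------------------------------------------
    c_gfp = _sos_concentration(cfg, condition, t, t_on, t_off)
    c_mkate = np.full(n, cfg.mkate_baseline)
    if death_raw is not None:
        post = t >= death_raw

        def _at(time: float) -> float:
            return float(
                _sos_concentration(cfg, condition, np.array([time]), t_on, t_off)[0]
            )

        c_death = _at(death_raw)
        if fate == DIE_HIGH:
            mat = cfg.gfp_maturation_time / 60.0
            t0 = death_raw + mat                  # spike starts after maturation lag
            t1 = t0 + cfg.spike_rise_time
            peak = cfg.high_sos_multiplier * cfg.sos_induced
            lag = post & (t < t0)
            rise = (t >= t0) & (t < t1)
            decay = t >= t1
            c_gfp[lag] = c_death
            c_gfp[rise] = c_death * (peak / c_death) ** ((t[rise] - t0) / (t1 - t0))
            c_gfp[decay] = peak * np.exp(-cfg.bleach_rate * (t[decay] - t1))
        else:
            c_gfp[post] = c_death * np.exp(-cfg.bleach_rate * (t[post] - death_raw))
        c_mkate[post] = cfg.mkate_baseline * np.exp(-cfg.bleach_rate * (t[post] - death_raw))

    # --- measurement noise and export slice --------------------------------
    area = length * cfg.cell_width
    sl = slice(0, end_idx)
    m = end_idx
    if cfg.measurement_noise_cv > 0:
        nsig = math.sqrt(math.log(1.0 + cfg.measurement_noise_cv**2))
        noise = rng.lognormal(0.0, nsig, size=(4, m))
    else:
        noise = np.ones((4, m))

    obs = {
        "condition": condition,
        "replicate_id": replicate_id,
        "lineage_id": lineage_id,
        "generation_id": gen_id[sl],
        "frame": np.arange(m, dtype=np.int64),
        "time_h": t[sl],
        "length_um": length[sl] * noise[0],
        "area_um2": area[sl] * noise[1],
        "gfp_total": c_gfp[sl] * area[sl] * noise[2],
        "mkate_total": c_mkate[sl] * area[sl] * noise[3],
    }
    truth = GroundTruthRecord(
        condition=condition,
        replicate_id=replicate_id,
        lineage_id=lineage_id,
        true_fate=true_fate,
        true_death_time=true_death,
        true_mu=mu,
    )
    return obs, truth


# --------------------------------------------------------------------------- #
# public API
# --------------------------------------------------------------------------- #


def _lineage_rng(seed: int, condition: str, replicate_id: int, lineage_id: int):
    cond_idx = CONDITIONS.index(condition) if condition in CONDITIONS else 97
    return np.random.default_rng([int(seed), cond_idx, int(replicate_id), int(lineage_id)])


def simulate_lineage(
    config: SimulationConfig,
    condition: str,
    rng_state,
    replicate_id: int = 0,
    lineage_id: int = 0,
) -> Tuple[pd.DataFrame, GroundTruthRecord]:
    """Simulate one mother-cell lineage.

    ``rng_state`` is either a :class:`numpy.random.Generator` or anything
    acceptable to :func:`numpy.random.default_rng`.  The call is
    deterministic given the generator state.
    """
    probs = config.condition_probs(condition)
    rng = rng_state if isinstance(rng_state, np.random.Generator) else np.random.default_rng(rng_state)
    obs, truth = _simulate_one(config, condition, probs, rng, replicate_id, lineage_id)
    return pd.DataFrame(obs, columns=OBSERVATION_COLUMNS), truth


def _jittered_probs(probs, jitter: float, rng) -> Tuple[float, float, float]:
    """Between-replicate variation of the fate probabilities.

    The survival probability receives absolute Gaussian noise (sd =
    ``jitter``); the two death classes are rescaled proportionally so their
    ratio -- the composition of death modes -- is preserved.  This models
    day-to-day variability of the survival fraction without distorting the
    (small) high-SOS share.
    """
    p_surv, p_low, p_high = (float(p) for p in probs)
    if jitter <= 0:
        return p_surv, p_low, p_high
    p_die = p_low + p_high
    if p_die <= 0:
        return p_surv, p_low, p_high
    new_surv = float(np.clip(p_surv + rng.normal(0.0, jitter), 0.0, 1.0))
    scale = (1.0 - new_surv) / p_die
    return new_surv, p_low * scale, p_high * scale


def simulate_condition(
    config: SimulationConfig,
    condition: str,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, List[GroundTruthRecord]]:
    """Simulate all replicates of one condition.

    Returns the concatenated observation table (one row per cell per frame)
    and the per-lineage ground-truth records.  Identical ``(config, seed)``
    pairs give byte-identical output.
    """
    if config.n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    if condition not in config.fate_probs:
        raise KeyError(
            f"unknown condition {condition!r}; known: {sorted(config.fate_probs)}"
        )
    seed = config.seed if seed is None else int(seed)
    base_probs = config.condition_probs(condition)

    chunks: List[dict] = []
    truths: List[GroundTruthRecord] = []
    for rep in range(config.n_replicates):
        rep_rng = _lineage_rng(seed, condition, rep, 2**20)  # replicate-level stream
        probs = _jittered_probs(base_probs, config.replicate_jitter, rep_rng)
        for lin in range(config.n_lineages):
            rng = _lineage_rng(seed, condition, rep, lin)
            obs, truth = _simulate_one(config, condition, probs, rng, rep, lin)
            chunks.append(obs)
            truths.append(truth)

    table = pd.DataFrame(
        {
            col: (
                np.concatenate([np.asarray(c[col]) for c in chunks])
                if col not in ("condition", "replicate_id", "lineage_id")
                else np.concatenate(
                    [np.full(len(c["frame"]), c[col]) for c in chunks]
                )
            )
            for col in OBSERVATION_COLUMNS
        }
    )
    table["replicate_id"] = table["replicate_id"].astype(np.int64)
    table["lineage_id"] = table["lineage_id"].astype(np.int64)
    return table, truths


def ground_truth_frame(records: Iterable[GroundTruthRecord]) -> pd.DataFrame:
    rows = [
        {
            "condition": r.condition,
            "replicate_id": r.replicate_id,
            "lineage_id": r.lineage_id,
            "true_fate": r.true_fate,
            "true_death_time": np.nan if r.true_death_time is None else r.true_death_time,
            "true_mu": r.true_mu,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def write_observations(table: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write an observation table as UTF-8 CSV with LF newlines.

    ``meta`` key/value pairs are stored in a single leading comment line so
    any stage can verify which configuration and seed produced a file.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        table.to_csv(fh, index=False, lineterminator="\n")
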