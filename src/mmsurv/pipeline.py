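"""End-to-end driver: simulate (or read) -> fit -> classify -> survival -> interaction.

The pipeline runs one growth medium at a time across the requested
conditions and writes every intermediate artifact as CSV, stamped with the
configuration hash and master seed, so each stage can be audited or re-run
in isolation.  Stage order mirrors the analysis narrative: per-generation
elongation fits and windowed distributions; lineage fate and SOS
classification; Kaplan-Meier curves (whole population and stratified by
SOS class of death) with log-rank comparisons; replicate survival
fractions; and Bliss/suppression interaction statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import interactions, metrics, survival
from .config import CIP, CIP_TET, NO_DRUG, TET, SimulationConfig, default_parameter_sets
from .fates import ClassifierParams, Timeline, classify_population, fate_fractions
from .io import read_observations, write_table
from .simulate import simulate_condition, write_observations

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """What to run and where to put it."""

    media: Sequence[str] = ("glu-aa",)
    conditions: Sequence[str] = (NO_DRUG, TET, CIP, CIP_TET)
    out_dir: str = "mmsurv-out"
    seed: int = 0
    n_lineages: Optional[int] = None       # override the per-medium default
    n_replicates: Optional[int] = None
    observations: Optional[Dict[str, str]] = None  # medium -> CSV path (skip simulation)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    sf_method: str = "km"
    write_observation_tables: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cls_params = raw.pop("classifier", None)
        cfg = cls(**raw)
        if cls_params:
            cfg.classifier = ClassifierParams(**cls_params)
        return cfg


def _hash_config(cfg: SimulationConfig, seed: int) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True) + f"|seed={seed}"
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _curve_frame(curve: survival.SurvivalCurve, condition: str, stratum: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": condition,
            "stratum": stratum,
            "time": curve.time,
            "s": curve.s,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
            "n_at_risk": curve.n_at_risk,
        }
    )


def _stratified_sf(fates: pd.DataFrame, timeline: Timeline, sos_class: str) -> pd.DataFrame:
    """Per-replicate survival fraction counting only one death class as events.

    Deaths of the other class are treated as non-events (the lineage is not
    part of the analysed death mode), so 1 - sf is the fraction of the
    population dying with that SOS class.
    """
    df = fates[~fates["qc_excluded"]].copy()
    other = (df["fate"] == "died") & (df["sos_class"] != sos_class)
    df.loc[other, "fate"] = "survived"
    df.loc[other, "death_time"] = np.nan
    return survival.survival_fraction(df, timeline, method="exclude")


def run_pipeline(cfg: PipelineConfig) -> Dict[str, dict]:
    """Run every stage for every requested medium; returns the result bundle.

    Writes, per medium: generation fits, elongation window summaries, fate
    table, fate-fraction decomposition, survival curves (whole population
    and SOS-stratified), replicate Sf table and the interaction report.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    sets = default_parameter_sets()
    results: Dict[str, dict] = {}

    for medium in cfg.media:
        if medium not in sets:
            raise StageError("configure", KeyError(f"unknown medium {medium!r}"))
        sim_cfg = sets[medium]
        if cfg.n_lineages:
            sim_cfg = sim_cfg.replace(n_lineages=cfg.n_lineages)
        if cfg.n_replicates:
            sim_cfg = sim_cfg.replace(n_replicates=cfg.n_replicates)
        timeline = Timeline.from_config(sim_cfg)
        meta = {"config": _hash_config(sim_cfg, cfg.seed), "seed": cfg.seed, "medium": medium}
        out = out_root / medium
        out.mkdir(parents=True, exist_ok=True)

        # ------------------------------------------------------------ ingest
        tables: Dict[str, pd.DataFrame] = {}
        t0 = time.time()
        try:
            if cfg.observations and medium in cfg.observations:
                obs = read_observations(cfg.observations[medium])
                for cond, sub in obs.groupby("condition", sort=False):
                    tables[str(cond)] = sub.reset_index(drop=True)
            else:
                for cond in cfg.conditions:
                    obs, _ = simulate_condition(sim_cfg, cond, seed=cfg.seed)
                    tables[cond] = obs
                    if cfg.write_observation_tables:
                        write_observations(obs, out / f"observations_{cond}.csv", meta)
        except Exception as exc:  # noqa: BLE001 - surfaced with stage context
            raise StageError("ingest", exc) from exc
        log.info("[%s] ingest: %d condition tables, %.1fs", medium, len(tables), time.time() - t0)

        # --------------------------------------------------- fits + windows
        fits_all, windows_all = [], []
        fates_all: Dict[str, pd.DataFrame] = {}
        infos: Dict[str, dict] = {}
        try:
            for cond, obs in tables.items():
                fates, info = classify_population(obs, cfg.classifier, timeline)
                fates_all[cond] = fates
                infos[cond] = info
                fits = info["fits"].assign(condition_label=cond)
                fits_all.append(fits)
                win = metrics.window_distributions(
                    info["frames"], "mu_gen", t_max=timeline.t_end
                ).assign(condition=cond)
                windows_all.append(win)
                n_excl = len(info["exclusions"])
                if n_excl:
                    log.warning("[%s/%s] %d lineages excluded by QC", medium, cond, n_excl)
        except Exception as exc:  # noqa: BLE001
            raise StageError("classify", exc) from exc
        write_table(pd.concat(fits_all, ignore_index=True), out / "generation_fits.csv", meta)
        write_table(pd.concat(windows_all, ignore_index=True), out / "elongation_windows.csv", meta)
        write_table(pd.concat(fates_all.values(), ignore_index=True), out / "lineage_fates.csv", meta)

        # ------------------------------------------------- fate decomposition
        decomp_rows = []
        for cond, fates in fates_all.items():
            fr = fate_fractions(fates, include_censored=True)
            decomp_rows.append({"condition": cond, **fr.to_dict()})
        decomp = pd.DataFrame(decomp_rows)
        write_table(decomp, out / "fate_fractions.csv", meta)

        # ------------------------------------------------------- survival
        try:
            curves, sf_rows = [], []
            events: Dict[str, pd.DataFrame] = {}
            for cond, fates in fates_all.items():
                ev = survival.make_event_records(fates, timeline)
                events[cond] = ev
                curves.append(_curve_frame(survival.kaplan_meier(ev), cond, "all"))
                for cls in ("low", "high"):
                    keep = (fates["fate"] != "died") | (fates["sos_class"] == cls)
                    ev_s = survival.make_event_records(fates[keep], timeline)
                    if len(ev_s):
                        curves.append(
                            _curve_frame(survival.kaplan_meier(ev_s), cond, f"{cls}-sos")
                        )
                sf = survival.survival_fraction(fates, timeline, method=cfg.sf_method)
                sf_rows.append(sf)
            logrank_rows = []
            if CIP in events and CIP_TET in events:
                stat, p = survival.log_rank(events[CIP], events[CIP_TET])
                logrank_rows.append(
                    {"comparison": f"{CIP} vs {CIP_TET}", "statistic": stat, "p_value": p}
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError("survival", exc) from exc
        write_table(pd.concat(curves, ignore_index=True), out / "survival_curves.csv", meta)
        sf_table = pd.concat(sf_rows, ignore_index=True)
        write_table(sf_table, out / "replicate_sf.csv", meta)
        if logrank_rows:
            write_table(pd.DataFrame(logrank_rows), out / "logrank_tests.csv", meta)

        # ------------------------------------------------------ interaction
        interaction_rows = []
        try:
            strata = {"all": lambda f: survival.survival_fraction(f, timeline, method=cfg.sf_method),
                      "low-sos": lambda f: _stratified_sf(f, timeline, "low"),
                      "high-sos": lambda f: _stratified_sf(f, timeline, "high")}
            for name, sf_fn in strata.items():
                needed = (CIP, TET, CIP_TET)
                if not all(c in fates_all for c in needed):
                    continue
                sfs = {c: sf_fn(fates_all[c])["sf"].to_numpy() for c in needed}
                bliss = interactions.bliss_expected(sfs[CIP], sfs[TET])
                anova = interactions.bliss_anova_test(sfs[CIP], sfs[TET], sfs[CIP_TET])
                sigma = interactions.suppression_sigma(
                    float(np.mean(sfs[CIP_TET])), float(np.mean(sfs[CIP]))
                )
                _, p_tt = interactions.pairwise_ttest(sfs[CIP], sfs[CIP_TET])
                interaction_rows.append(
                    {
                        "medium": medium,
                        "stratum": name,
                        "sf_cip_mean": float(np.mean(sfs[CIP])),
                        "sf_tet_mean": float(np.mean(sfs[TET])),
                        "sf_combo_mean": float(np.mean(sfs[CIP_TET])),
                        "bliss_mean": bliss.mean,
                        "bliss_sem": bliss.sem,
                        "sigma": sigma,
                        "p_bliss_one_sided": anova.p_one_sided,
                        "p_ttest_cip_vs_combo": p_tt,
                        "combo_exceeds_bliss": float(np.mean(sfs[CIP_TET])) > bliss.mean,
                    }
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError("interaction", exc) from exc
        if interaction_rows:
            inter = pd.DataFrame(interaction_rows)
            write_table(inter, out / "interaction_report.csv", meta)
        else:
            inter = pd.DataFrame()

        results[medium] = {
            "fates": fates_all,
            "fate_fractions": decomp,
            "replicate_sf": sf_table,
            "interaction": inter,
            "logrank": pd.DataFrame(logrank_rows),
            "infos": infos,
        }
        log.info("[%s] complete", medium)
    return results
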