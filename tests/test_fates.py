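"""Fate classification: QC, death calls, SOS sub-classification."""

import numpy as np
import pandas as pd
import pytest

from mmsurv.config import CIP, NO_DRUG, default_parameter_sets
from mmsurv.fates import (
    ClassifierParams,
    Timeline,
    apply_qc_filters,
    classify_fate,
    classify_population,
    classify_sos,
    fate_fractions,
    sos_threshold,
)
from mmsurv.metrics import add_rate_columns, expression_per_area, fit_generations

TL = Timeline()  # 5-min frames, drug 2-14 h, end 24 h


def _synthetic_lineage(rate_fn, t_end=24.0, dt=1 / 12, l0=2.0, divide_at=4.0):
    """Noise-free lineage growing at rate_fn(t), dividing at a fixed length."""
    t = np.arange(0.0, t_end + 1e-9, dt)
    lengths, gens = [], []
    L, g = l0, 0
    for ti in t:
        lengths.append(L)
        gens.append(g)
        L = L * np.exp(rate_fn(ti) * dt)
        if L >= divide_at and rate_fn(ti) > 0:
            L, g = L / 2, g + 1
    frames = pd.DataFrame(
        {
            "condition": "CIP",
            "replicate_id": 0,
            "lineage_id": 0,
            "generation_id": gens,
            "frame": np.arange(t.size),
            "time_ret": t,
            "length_um": lengths,
            "area_um2": np.asarray(lengths),
            "gfp_total": np.asarray(lengths) * 100.0,
            "mkate_total": np.asarray(lengths) * 500.0,
        }
    )
    return add_rate_columns(frames, dt)


class TestClassifyFate:
    MU_REF = 1.0

    def test_constant_growth_is_survival(self):
        lin = _synthetic_lineage(lambda t: 1.0)
        fate = classify_fate(lin, ClassifierParams(), TL, self.MU_REF)
        assert fate.fate == "survived"

    def test_arrest_from_hour_five_is_death_at_five(self):
        lin = _synthetic_lineage(lambda t: 1.0 if t < 5.0 else 0.0)
        fate = classify_fate(lin, ClassifierParams(), TL, self.MU_REF)
        assert fate.fate == "died"
        assert fate.death_time == pytest.approx(5.0, abs=2 / 12)

    def test_transient_arrest_with_regrowth_is_survival(self):
        lin = _synthetic_lineage(lambda t: 0.0 if 6.0 <= t < 8.0 else 1.0)
        fate = classify_fate(lin, ClassifierParams(), TL, self.MU_REF)
        assert fate.fate == "survived"

    def test_truncated_observation_is_censored(self):
        lin = _synthetic_lineage(lambda t: 1.0, t_end=10.0)
        fate = classify_fate(lin, ClassifierParams(), TL, self.MU_REF)
        assert fate.fate == "censored"
        assert fate.censor_time == pytest.approx(10.0)

    def test_death_takes_precedence_over_later_censoring(self):
        lin = _synthetic_lineage(lambda t: 1.0 if t < 5.0 else 0.0, t_end=12.0)
        fate = classify_fate(lin, ClassifierParams(), TL, self.MU_REF)
        assert fate.fate == "died"

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_fate(pd.DataFrame(), ClassifierParams(), TL, self.MU_REF)

    def test_invariant_to_uniform_length_rescaling(self):
        lin = _synthetic_lineage(lambda t: 1.0 if t < 7.0 else 0.0)
        scaled = lin.copy()
        scaled["length_um"] *= 3.0
        scaled = add_rate_columns(
            scaled.drop(columns=["rate_smooth", "rate_forward", "mu_gen"]), 1 / 12
        )
        a = classify_fate(lin, ClassifierParams(), TL, self.MU_REF)
        b = classify_fate(scaled, ClassifierParams(), TL, self.MU_REF)
        assert (a.fate, a.death_time) == (b.fate, b.death_time)


class TestQCFilters:
    def test_healthy_population_mostly_kept(self, population):
        pop = population("glu-aa", NO_DRUG, n=300, reps=1)
        fates = pop["fates"]
        assert fates["qc_excluded"].mean() <= 0.01

    def test_rules_flag_bad_lineages(self, population):
        pop = population("glu-aa", NO_DRUG, n=30, reps=1)
        frames = pop["info"]["frames"].copy()
        lin_ids = frames["lineage_id"].unique()
        dead_id, fat_id = lin_ids[0], lin_ids[1]
        # freeze one lineage (non-growing), inflate another (filamented)
        frames.loc[frames.lineage_id == dead_id, "length_um"] = 2.0
        frames.loc[frames.lineage_id == fat_id, "length_um"] *= 10.0
        frames = add_rate_columns(
            frames.drop(columns=["rate_smooth", "rate_forward", "mu_gen"]),
            TL.frame_interval_h,
        )
        fits = fit_generations(frames, time_col="time_ret")
        kept, excl = apply_qc_filters(frames, fits, ClassifierParams(), TL)
        reasons = dict(zip(excl["lineage_id"], excl["reason"]))
        assert reasons.get(dead_id) == "non-growing at start"
        assert reasons.get(fat_id) == "initially filamented"
        assert not set(kept["lineage_id"]) & {dead_id, fat_id}


class TestSosThreshold:
    def test_threshold_arithmetic(self):
        """Survivor final-2h median 227 with multiplier 3 gives 681."""
        rng = np.random.default_rng(0)
        n = 25
        frames = pd.concat(
            [
                pd.DataFrame(
                    {
                        "condition": "CIP",
                        "replicate_id": 0,
                        "lineage_id": i,
                        "time_ret": np.arange(0, 24, 1 / 12),
                        "sos_expression": 227.0,
                    }
                )
                for i in range(n)
            ]
        )
        thr, fallback = sos_threshold(frames, ClassifierParams(), TL)
        assert not fallback
        assert thr == pytest.approx(3 * 227.0)

    def test_too_few_survivors_uses_fallback(self, caplog):
        frames = pd.DataFrame(
            {
                "condition": ["CIP"],
                "replicate_id": [0],
                "lineage_id": [0],
                "time_ret": [13.0],
                "sos_expression": [100.0],
            }
        )
        with caplog.at_level("WARNING"):
            thr, fallback = sos_threshold(frames, ClassifierParams(), TL)
        assert fallback
        assert thr == ClassifierParams().sos_fallback_threshold
        assert "falling back" in caplog.text

    def test_threshold_separates_simulated_death_classes(self, population):
        """With a 10x spike over the induced level, the survivor-based
        threshold splits dead lineages with no overlap."""
        pop = population("glu", CIP, n=300, reps=1)
        merged = pop["fates"].merge(
            pop["truth"], on=["condition", "replicate_id", "lineage_id"]
        )
        dead = merged[merged.fate == "died"]
        thr = pop["info"]["sos_threshold"]
        assert (dead.loc[dead.true_fate == "die_high", "peak_sos"] >= thr).all()
        assert (dead.loc[dead.true_fate == "die_low", "peak_sos"] < thr).all()

    def test_monotone_in_multiplier(self, population):
        """Raising the multiplier never increases the high-SOS count."""
        pop = population("glu-aa", CIP, n=200, reps=1)
        dead = pop["fates"][pop["fates"].fate == "died"]
        base = pop["info"]["sos_threshold"] / 3.0
        counts = [
            (dead.peak_sos >= m * base).sum() for m in (1.0, 2.0, 3.0, 5.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestClassifySos:
    def test_peak_below_threshold_is_low(self):
        lin = pd.DataFrame(
            {"time_ret": [2.0, 5.0, 8.0], "sos_expression": [100.0, 300.0, 50.0]}
        )
        cls, peak = classify_sos(lin, death_time=5.0, threshold=681.0, timeline=TL)
        assert cls == "low"
        assert peak == 300.0

    def test_peak_above_threshold_is_high(self):
        lin = pd.DataFrame(
            {"time_ret": [2.0, 5.0, 7.9], "sos_expression": [100.0, 300.0, 2000.0]}
        )
        cls, peak = classify_sos(lin, death_time=5.0, threshold=681.0, timeline=TL)
        assert cls == "high"
        assert peak == 2000.0


class TestPopulationAgreement:
    def test_fate_labels_match_ground_truth(self, population):
        """>=95% agreement with simulator truth; median death-time error
        within 2 frames."""
        pop = population("glu-aa", CIP, n=500, reps=1)
        m = pop["fates"].merge(
            pop["truth"], on=["condition", "replicate_id", "lineage_id"]
        )
        m = m[~m.qc_excluded]
        agree = (
            ((m.fate == "died") & m.true_fate.isin(["die_low", "die_high"]))
            | ((m.fate == "survived") & (m.true_fate == "survive"))
            | ((m.fate == "censored") & (m.true_fate == "lost"))
        )
        assert agree.mean() >= 0.95
        dead = m[(m.fate == "died") & m.true_fate.isin(["die_low", "die_high"])]
        frame_h = pop["timeline"].frame_interval_h
        err = (dead.death_time - dead.true_death_time).abs()
        assert err.median() <= 2 * frame_h

    def test_high_sos_lineages_called_high(self, population):
        pop = population("glu-aa", CIP, n=500, reps=1)
        m = pop["fates"].merge(
            pop["truth"], on=["condition", "replicate_id", "lineage_id"]
        )
        die_high = m[(m.true_fate == "die_high") & (m.fate == "died")]
        assert (die_high.sos_class == "high").mean() >= 0.95

    def test_zero_noise_confusion_matrix_is_diagonal(self, population):
        """Without measurement noise every label matches the truth."""
        pop = population(
            "glu-aa", CIP, n=150, reps=1,
            measurement_noise_cv=0.0, replicate_jitter=0.0,
        )
        m = pop["fates"].merge(
            pop["truth"], on=["condition", "replicate_id", "lineage_id"]
        )
        m = m[~m.qc_excluded]
        label_map = {"die_low": "died", "die_high": "died", "survive": "survived", "lost": "censored"}
        assert (m.fate == m.true_fate.map(label_map)).all()
        dead = m[m.fate == "died"]
        sos_map = {"die_low": "low", "die_high": "high"}
        assert (dead.sos_class == dead.true_fate.map(sos_map)).all()

    def test_fractions_sum_to_one(self, population):
        pop = population("glu-aa", CIP, n=200, reps=1)
        fr = fate_fractions(pop["fates"])
        assert fr.sum() == pytest.approx(1.0)
        fr_resolved = fate_fractions(pop["fates"], include_censored=False)
        assert fr_resolved.sum() == pytest.approx(1.0)
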