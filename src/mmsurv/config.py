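"""Simulation configurations for synthetic mother-machine experiments.

A :class:`SimulationConfig` describes one growth medium and the full set of
experimental conditions run in it (no-drug control, tetracycline, ciprofloxacin,
and the two-drug combination).  :func:`default_parameter_sets` returns configs
for the three M9-based media used throughout the package -- ``glu-aa`` (glucose
plus amino acids, fast growth), ``glu`` (glucose) and ``gly`` (glycerol, slow
growth) -- calibrated so that the simulated populations reproduce the published
summary statistics for this system: drug-free median elongation rates of
1.13, 0.54 and 0.28 h^-1; ciprofloxacin survival fractions of 36/38/43 %;
combination survival of 76/66/61 %; and steady-state SOS-reporter expression
medians of 118/95/93 a.u. without drug and 227/473/462 a.u. under
ciprofloxacin.

Times are expressed in *retained* experiment hours: hour 0 is the first frame
kept for analysis after the initial settling period is discarded, drugs are
present during hours ``t_drug_on``..``t_drug_off`` (2-14 by default) and the
experiment ends at ``t_end`` (24 h).  The simulator additionally generates
``t_preamble`` hours (default 4) of pre-steady-state frames ahead of retained
hour 0, so that raw tables resemble a segmentation export from which the first
hours still have to be discarded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import yaml

NO_DRUG = "no-drug"
TET = "TET"
CIP = "CIP"
CIP_TET = "CIP-TET"
CONDITIONS: Tuple[str, ...] = (NO_DRUG, TET, CIP, CIP_TET)

MEDIA: Tuple[str, ...] = ("glu-aa", "glu", "gly")

#: (p_survive, p_die_low_sos, p_die_high_sos)
FateProbs = Tuple[float, float, float]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic mother-machine experiment in one medium.

    Only ``medium_name``, ``mu_median``, ``sos_baseline``, ``sos_induced`` and
    ``fate_probs`` have no sensible universal default; everything else can be
    left at its default value.  All times are hours of retained experiment
    time unless noted otherwise.
    """

    medium_name: str
    mu_median: float                      # h^-1, drug-free median elongation rate
    sos_baseline: float                   # a.u., median SOS expression without drug
    sos_induced: float                    # a.u., steady SOS expression under CIP
    fate_probs: Mapping[str, FateProbs]   # condition -> (survive, die_low, die_high)

    frame_interval: float = 5.0           # minutes between frames
    t_start: float = 0.0
    t_drug_on: float = 2.0
    t_drug_off: float = 14.0
    t_end: float = 24.0
    t_preamble: float = 4.0               # raw hours generated before retained hour 0

    n_lineages: int = 500
    n_replicates: int = 2

    mu_cv: float = 0.15                   # cell-to-cell CV of the elongation rate
    tet_reduction: float = 0.16           # steady-state fractional rate reduction, TET
    tet_reduction_combo: float = 0.14     # same, under the CIP-TET combination
    tet_relax_time: float = 1.0           # h, time constant of the TET rate response

    #: uniform death-time windows (retained hours) for the two dying classes
    death_window_low: Tuple[float, float] = (3.0, 17.0)
    death_window_high: Tuple[float, float] = (3.0, 6.0)
    late_death_prob: float = 0.03         # age-related death in no-drug/TET, final 4 h

    sos_rise_time: float = 2.0            # h, first-order SOS induction time constant
    sos_recovery_time: float = 1.2        # h, SOS relaxation after drug removal
    high_sos_multiplier: float = 10.0     # fold-increase of the high-SOS peak
    spike_rise_time: float = 1.0          # h, post-arrest rise to the high-SOS peak
    gfp_maturation_time: float = 20.0     # minutes, reporter maturation delay
    bleach_rate: float = 0.5              # h^-1, post-death fluorophore decay
    mkate_baseline: float = 500.0         # a.u., constitutive reporter expression

    birth_length: float = 2.0             # um, target birth length of the sizer
    division_noise_cv: float = 0.1        # CV of the division-length threshold
    cell_width: float = 1.0               # um, used for the area proxy
    max_channel_length: float = 40.0      # um, hard tracking limit (censoring)

    filament_prob_survivor: float = 0.05  # transient filamentation of CIP survivors
    filament_duration: Tuple[float, float] = (1.0, 2.5)  # h, uniform range
    filament_decay_time: float = 1.5      # h, rate decay of high-SOS filamenting cells
    filament_rate_floor: float = 0.3      # fraction of the cell's rate kept until death

    loss_rate: float = 0.005              # h^-1, random lineage washout
    replicate_jitter: float = 0.02        # absolute between-replicate sd on fate probs
    measurement_noise_cv: float = 0.03    # multiplicative noise on length/area/totals
    seed: int = 0

    # ------------------------------------------------------------------ checks
    def __post_init__(self) -> None:
        if not (self.t_start < self.t_drug_on < self.t_drug_off < self.t_end):
            raise ValueError(
                "require t_start < t_drug_on < t_drug_off < t_end, got "
                f"{self.t_start}, {self.t_drug_on}, {self.t_drug_off}, {self.t_end}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for name, span in (
            ("pre-drug window", self.t_drug_on - self.t_start),
            ("drug window", self.t_drug_off - self.t_drug_on),
            ("recovery window", self.t_end - self.t_drug_off),
            ("preamble", self.t_preamble),
        ):
            frames = span * 60.0 / self.frame_interval
            if abs(frames - round(frames)) > 1e-9:
                raise ValueError(f"frame_interval does not divide the {name}")
        for cond, probs in self.fate_probs.items():
            if len(probs) != 3:
                raise ValueError(f"fate_probs[{cond!r}] must have 3 entries")
            if any(p < -_PROB_TOL or p > 1 + _PROB_TOL for p in probs):
                raise ValueError(f"fate_probs[{cond!r}] outside [0, 1]: {probs}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"fate_probs[{cond!r}] must sum to 1: {probs}")
        positive = {
            "mu_median": self.mu_median,
            "sos_baseline": self.sos_baseline,
            "sos_induced": self.sos_induced,
            "tet_relax_time": self.tet_relax_time,
            "sos_rise_time": self.sos_rise_time,
            "sos_recovery_time": self.sos_recovery_time,
            "bleach_rate": self.bleach_rate,
            "birth_length": self.birth_length,
            "cell_width": self.cell_width,
            "max_channel_length": self.max_channel_length,
            "filament_decay_time": self.filament_decay_time,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.loss_rate < 0 or self.replicate_jitter < 0:
            raise ValueError("rates must be non-negative")
        lo = self.death_window_low
        hi = self.death_window_high
        for name, (a, b) in (("death_window_low", lo), ("death_window_high", hi)):
            if not (self.t_drug_on <= a < b <= self.t_drug_off + 3.0):
                raise ValueError(
                    f"{name} must lie within [t_drug_on, t_drug_off + 3], got {(a, b)}"
                )

    # ------------------------------------------------------------------ helpers
    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval / 60.0

    def condition_probs(self, condition: str) -> FateProbs:
        if condition not in self.fate_probs:
            raise KeyError(
                f"unknown condition {condition!r}; known: {sorted(self.fate_probs)}"
            )
        return tuple(self.fate_probs[condition])  # type: ignore[return-value]

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    # ------------------------------------------------------------------ yaml io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fate_probs"] = {k: list(v) for k, v in self.fate_probs.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["fate_probs"] = {k: tuple(v) for k, v in d["fate_probs"].items()}
        for key in ("death_window_low", "death_window_high", "filament_duration"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _no_drug_probs() -> FateProbs:
    return (1.0, 0.0, 0.0)


def default_parameter_sets() -> Dict[str, SimulationConfig]:
    """Calibrated configurations for the three growth media.

    Fate probabilities under CIP and CIP-TET encode the published end-of-
    experiment survival fractions together with the published shares of
    high-SOS deaths; the low-SOS share is the complement.  The filamentation
    slowdown timescale of high-SOS cells scales with the medium's doubling
    time (1.5/3/6 h for glu-aa/glu/gly).  The no-drug and
    TET conditions are death-free apart from a small age-related hazard in
    the final hours.  The TET elongation-rate reductions for glu and gly are
    package defaults (the effect is growth-rate dependent and strongest in
    glu-aa, where it is 16 %, or 14 % under the combination).
    """
    sets: Dict[str, SimulationConfig] = {}
    sets["glu-aa"] = SimulationConfig(
        medium_name="glu-aa",
        frame_interval=5.0,
        mu_median=1.13,
        sos_baseline=118.0,
        sos_induced=227.0,
        tet_reduction=0.16,
        tet_reduction_combo=0.14,
        fate_probs={
            NO_DRUG: _no_drug_probs(),
            TET: _no_drug_probs(),
            CIP: (0.36, 0.52, 0.12),
            CIP_TET: (0.77, 0.15, 0.08),
        },
    )
    sets["glu"] = SimulationConfig(
        medium_name="glu",
        frame_interval=5.0,
        mu_median=0.54,
        sos_baseline=95.0,
        sos_induced=473.0,
        filament_decay_time=3.0,
        tet_reduction=0.10,
        tet_reduction_combo=0.09,
        fate_probs={
            NO_DRUG: _no_drug_probs(),
            TET: _no_drug_probs(),
            CIP: (0.38, 0.37, 0.25),
            CIP_TET: (0.66, 0.14, 0.20),
        },
    )
    sets["gly"] = SimulationConfig(
        medium_name="gly",
        frame_interval=10.0,
        mu_median=0.28,
        sos_baseline=93.0,
        sos_induced=462.0,
        filament_decay_time=6.0,
        tet_reduction=0.05,
        tet_reduction_combo=0.045,
        fate_probs={
            NO_DRUG: _no_drug_probs(),
            TET: _no_drug_probs(),
            CIP: (0.43, 0.27, 0.30),
            CIP_TET: (0.61, 0.17, 0.22),
        },
    )
    return sets
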