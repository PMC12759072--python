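"""Bliss-independence testing and suppression quantification.

Under Bliss independence two drugs act through independent survival
channels, so the expected survival fraction of the combination is the
product of the single-drug survival fractions, or equivalently
``ln Sf_expected = ln Sf_CIP + ln Sf_TET``.  The expected Sf is estimated
from the Cartesian product of replicate pairs,

    Bliss_ij = exp(ln Sf_CIP_i + ln Sf_TET_j),

and its reported standard error uses, by default, the propagation formula

    SEM = sqrt(sigma_CIP / sqrt(n_CIP) + sigma_TET / sqrt(n_TET)),

where sigma is the standard deviation of the replicate Sf values of each
single-drug arm and n the replicate count.  The formula sums standard
errors (not variances) under the root; it is kept as the default for
comparability with published tables for this system, and the conventional
variance-based propagation on the log scale is available as
``sem_method="propagated"``.

The Bliss null H0: ln(Sf_CIP) + ln(Sf_TET) - ln(Sf_CIP-TET) = 0 is tested
with a contrast in a one-way fixed-effects layout on y = ln Sf (an ANOVA
model with one group per treatment arm and pooled residual variance).  The
one-sided alternative is a negative contrast: the combination survives
*more* than independence predicts (antagonism/suppression on cell death).

Suppression is quantified as the relative gain in mean survival over the
bactericidal drug alone: Sigma = (Sf_combo - Sf_CIP) / Sf_CIP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "BlissResult",
    "AnovaContrastResult",
    "bliss_expected",
    "bliss_anova_test",
    "suppression_sigma",
    "pairwise_ttest",
]


@dataclass(frozen=True)
class BlissResult:
    values: np.ndarray      # pairwise expected Sf's, one per replicate pair
    mean: float
    sem: float


@dataclass(frozen=True)
class AnovaContrastResult:
    contrast: float         # mean lnSf_CIP + mean lnSf_TET - mean lnSf_combo
    se: float
    t_stat: float
    df: int
    p_one_sided: float      # alternative: contrast < 0


def _check_sf(name: str, sf: Sequence[float]) -> np.ndarray:
    a = np.asarray(sf, dtype=float)
    if a.size == 0:
        raise ValueError(f"{name}: need at least one replicate")
    if np.any(a <= 0):
        raise ValueError(f"{name}: survival fractions must be > 0 (log undefined)")
    if np.any(a > 1):
        raise ValueError(f"{name}: survival fractions must be <= 1")
    return a


def bliss_expected(
    sf_cip: Sequence[float],
    sf_tet: Sequence[float],
    pairing: str = "cartesian",
    sem_method: str = "printed",
) -> BlissResult:
    """Expected combination survival under Bliss independence.

    ``pairing="cartesian"`` (default) enumerates all replicate pairs of the
    two arms; ``"matched"`` pairs replicates by index (requires equal
    counts).  See the module docstring for the two ``sem_method`` options.
    """
    a = _check_sf("sf_cip", sf_cip)
    b = _check_sf("sf_tet", sf_tet)
    if pairing == "cartesian":
        values = np.exp(np.add.outer(np.log(a), np.log(b))).ravel()
    elif pairing == "matched":
        if a.size != b.size:
            raise ValueError("matched pairing requires equal replicate counts")
        values = a * b
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    mean = float(values.mean())

    if a.size < 2 or b.size < 2:
        sem = float("nan")
    elif sem_method == "printed":
        sem = float(
            np.sqrt(
                np.std(a, ddof=1) / np.sqrt(a.size)
                + np.std(b, ddof=1) / np.sqrt(b.size)
            )
        )
    elif sem_method == "propagated":
        var_log = np.var(np.log(a), ddof=1) / a.size + np.var(np.log(b), ddof=1) / b.size
        sem = float(mean * np.sqrt(var_log))
    else:
        raise ValueError(f"unknown sem_method {sem_method!r}")
    return BlissResult(values=values, mean=mean, sem=sem)


def bliss_anova_test(
    sf_cip: Sequence[float],
    sf_tet: Sequence[float],
    sf_combo: Sequence[float],
) -> AnovaContrastResult:
    """One-sided test of the Bliss null on log survival fractions.

    Fits the one-way layout y = ln Sf ~ arm by OLS and tests the contrast
    c = mean_CIP + mean_TET - mean_combo with the pooled residual variance.
    Small one-sided p means the combination survives significantly more
    than the independence prediction.
    """
    arms = [
        _check_sf("sf_cip", sf_cip),
        _check_sf("sf_tet", sf_tet),
        _check_sf("sf_combo", sf_combo),
    ]
    n_total = sum(a.size for a in arms)
    if n_total - 3 < 1:
        raise ValueError("no residual degrees of freedom: need more replicates")
    y = np.concatenate([np.log(a) for a in arms])
    X = np.zeros((n_total, 3))
    start = 0
    for j, a in enumerate(arms):
        X[start:start + a.size, j] = 1.0
        start += a.size
    fit = sm.OLS(y, X).fit()
    test = fit.t_test(np.array([1.0, 1.0, -1.0]))
    t_stat = float(np.squeeze(test.tvalue))
    df = int(fit.df_resid)
    return AnovaContrastResult(
        contrast=float(np.squeeze(test.effect)),
        se=float(np.squeeze(test.sd)),
        t_stat=t_stat,
        df=df,
        p_one_sided=float(stats.t.cdf(t_stat, df)),
    )


def suppression_sigma(sf_combo_mean: float, sf_single_mean: float) -> float:
    """Relative survival gain of the combination over the single drug.

    Sigma = (Sf_combo - Sf_single) / Sf_single; positive values mean the
    combination rescues cells that the single drug would kill, negative
    values mean the combination kills more.
    """
    if sf_single_mean <= 0:
        raise ValueError("single-drug mean survival fraction must be > 0")
    return (sf_combo_mean - sf_single_mean) / sf_single_mean


def pairwise_ttest(
    sf_a: Sequence[float],
    sf_b: Sequence[float],
    equal_var: bool = True,
) -> Tuple[float, float]:
    """Two-sample two-sided t-test on replicate survival fractions.

    Equal-variance (pooled) by default; set ``equal_var=False`` for Welch.
    Identical degenerate groups return (0, 1).
    """
    a = np.asarray(sf_a, dtype=float)
    b = np.asarray(sf_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per group")
    stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(stat) and np.allclose(a.mean(), b.mean()):
        return 0.0, 1.0
    return float(stat), float(p)
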