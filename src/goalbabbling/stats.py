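"""Repeated-measures statistics used by the analysis pipeline.

Implements the classical two-way repeated-measures ANOVA with partial
eta-squared effect sizes, the exact two-sided sign test, the Wilcoxon
signed-rank test (exact for small samples) and the Friedman rank ANOVA
with tie correction.  These are written out explicitly — sum-of-squares
decompositions and rank arithmetic — so that every number in an output
table can be traced to its defining formula; the test suite cross-checks
them against independent implementations.

The repeated-measures *unit* is deliberately generic: for the human
analyses the grouping key is the finger mapping (each mapping occurs once
per condition, giving a within-unit Condition contrast), with participant
identity available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import comb

import numpy as np
import numpy.typing as npt
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "DegenerateDesignError",
    "rm_anova_2way",
    "sign_test",
    "wilcoxon_signed_rank",
    "friedman_test",
]


class DegenerateDesignError(ValueError):
    """The design leaves no error variance (or no usable units)."""


@dataclass(frozen=True)
class AnovaEffect:
    """One row of a repeated-measures ANOVA table."""

    name: str
    ss: float
    df: int
    ms: float
    f: float
    p: float
    eta_p_sq: float
    ss_error: float
    df_error: int
    ms_error: float


@dataclass
class AnovaResult:
    effects: dict[str, AnovaEffect]
    n_units: int
    n_dropped_units: int

    @property
    def table(self) -> pd.DataFrame:
        """ANOVA table (SSq., DF, Mean Sq., F, p, partial eta-squared)."""
        rows = []
        for e in self.effects.values():
            rows.append(
                {
                    "effect": e.name,
                    "SSq": e.ss,
                    "DF": e.df,
                    "MeanSq": e.ms,
                    "F": e.f,
                    "p": e.p,
                    "eta_p_sq": e.eta_p_sq,
                    "SSq_error": e.ss_error,
                    "DF_error": e.df_error,
                }
            )
        return pd.DataFrame(rows)


def rm_anova_2way(
    table: pd.DataFrame,
    unit: str = "unit",
    time: str = "time",
    condition: str = "condition",
    value: str = "value",
) -> AnovaResult:
    """Two-way fully-within repeated-measures ANOVA.

    Expects long-format data with one observation per unit × time ×
    condition cell; units with incomplete cells are dropped (listwise
    deletion).  Each within factor is tested against its own
    factor-by-unit interaction: F_Time = MS_Time / MS_{Time×Unit}, etc.
    Partial eta-squared is SS_effect / (SS_effect + SS_error).  No
    sphericity correction is applied.
    """
    df = table[[unit, time, condition, value]].dropna()
    t_levels = sorted(df[time].unique())
    c_levels = sorted(df[condition].unique())
    a, b = len(t_levels), len(c_levels)
    if a < 2 or b < 2:
        raise DegenerateDesignError("need at least 2 levels of each factor")

    # listwise deletion of incomplete units
    counts = df.groupby(unit).size()
    cell_counts = df.groupby([unit, time, condition]).size()
    if (cell_counts > 1).any():
        raise ValueError("more than one observation per unit × time × condition cell")
    complete = counts[counts == a * b].index
    n_dropped = counts.size - complete.size
    df = df[df[unit].isin(complete)]
    n = complete.size
    if n < 2:
        raise DegenerateDesignError("fewer than 2 complete units after deletion")

    # cell means as a (n, a, b) cube
    cube = (
        df.pivot_table(index=unit, columns=[time, condition], values=value)
        .reindex(columns=pd.MultiIndex.from_product([t_levels, c_levels]))
        .to_numpy()
        .reshape(n, a, b)
    )
    grand = cube.mean()
    m_u = cube.mean(axis=(1, 2))
    m_t = cube.mean(axis=(0, 2))
    m_c = cube.mean(axis=(0, 1))
    m_ut = cube.mean(axis=2)
    m_uc = cube.mean(axis=1)
    m_tc = cube.mean(axis=0)

    ss_time = n * b * np.sum((m_t - grand) ** 2)
    ss_cond = n * a * np.sum((m_c - grand) ** 2)
    ss_tc = n * np.sum((m_tc - m_t[:, None] - m_c[None, :] + grand) ** 2)
    ss_ut = b * np.sum((m_ut - m_u[:, None] - m_t[None, :] + grand) ** 2)
    ss_uc = a * np.sum((m_uc - m_u[:, None] - m_c[None, :] + grand) ** 2)
    ss_total = np.sum((cube - grand) ** 2)
    ss_units = a * b * np.sum((m_u - grand) ** 2)
    ss_utc = ss_total - ss_units - ss_time - ss_cond - ss_tc - ss_ut - ss_uc

    effects = {}
    specs = [
        ("Time", ss_time, a - 1, ss_ut, (a - 1) * (n - 1)),
        ("Condition", ss_cond, b - 1, ss_uc, (b - 1) * (n - 1)),
        ("Time x Condition", ss_tc, (a - 1) * (b - 1), ss_utc, (a - 1) * (b - 1) * (n - 1)),
    ]
    for name, ss_eff, df_eff, ss_err, df_err in specs:
        ms_err = ss_err / df_err
        if ms_err <= 0.0:
            raise DegenerateDesignError(f"zero error variance for effect {name}")
        ms_eff = ss_eff / df_eff
        f = ms_eff / ms_err
        p = float(sps.f.sf(f, df_eff, df_err))
        effects[name] = AnovaEffect(
            name=name,
            ss=float(ss_eff),
            df=df_eff,
            ms=float(ms_eff),
            f=float(f),
            p=p,
            eta_p_sq=float(ss_eff / (ss_eff + ss_err)) if (ss_eff + ss_err) > 0 else 0.0,
            ss_error=float(ss_err),
            df_error=df_err,
            ms_error=float(ms_err),
        )
    return AnovaResult(effects=effects, n_units=n, n_dropped_units=int(n_dropped))


def sign_test(differences: npt.ArrayLike) -> float:
    """Exact two-sided sign test on paired differences.

    Zero differences are dropped; under the null, the number of positive
    signs among the n nonzero differences is Binomial(n, ½).  The p-value
    doubles the smaller exact tail and is capped at 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; sign test undefined")
    k = int(np.sum(d > 0))
    tail_ge = sum(comb(n, i) for i in range(k, n + 1)) / 2.0**n
    tail_le = sum(comb(n, i) for i in range(0, k + 1)) / 2.0**n
    return float(min(1.0, 2.0 * min(tail_ge, tail_le)))


def _signed_ranks(d: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
    """Mid-ranks of |d| (ties averaged)."""
    return sps.rankdata(np.abs(d), method="average")


def wilcoxon_signed_rank(
    differences: npt.ArrayLike,
    exact_max_n: int = 12,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test; returns ``(z, p)``.

    Zeros are dropped and ties mid-ranked.  The z statistic is the
    normal approximation of W⁺ (positive when positive differences
    dominate) with tie-corrected variance; by default no continuity
    correction is applied (``continuity_correction=True`` shrinks the
    numerator by ½ toward zero).  For n ≤ ``exact_max_n`` the p-value is
    computed by exhaustive enumeration of all 2ⁿ sign assignments of the
    observed ranks; the z statistic is reported from the normal
    approximation in either regime.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = _signed_ranks(d)
    w_plus = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    # tie-corrected variance: Var(W+) = Σ r_i² / 4 (reduces to the
    # standard n(n+1)(2n+1)/24 when all ranks are distinct)
    var = float(np.sum(ranks**2)) / 4.0
    if var == 0.0:
        return 0.0, 1.0
    num = w_plus - mu
    if continuity_correction and num != 0.0:
        num -= 0.5 * np.sign(num)
    z = num / np.sqrt(var)
    if n <= exact_max_n:
        target = abs(w_plus - mu)
        count = 0
        for signs in product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - mu) >= target - 1e-12:
                count += 1
        p = count / 2.0**n
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), float(min(1.0, p))


def friedman_test(matrix: npt.ArrayLike) -> tuple[float, float]:
    """Friedman rank ANOVA over a (units × levels) matrix; returns (χ², p).

    Values are mid-ranked within each unit; the tie-corrected statistic is

        χ² = (k−1) Σ_j (R_j − n(k+1)/2)² / (Σ_ij r_ij² − n k (k+1)²/4),

    referred to the χ² distribution with k−1 degrees of freedom.  A matrix
    with no within-unit variation yields χ² = 0, p = 1.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 units and 2 repeated levels")
    n, k = X.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, X)
    col_sums = ranks.sum(axis=0)
    numerator = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    denominator = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    if denominator <= 0.0:
        return 0.0, 1.0
    chi2 = float(numerator / denominator)
    p = float(sps.chi2.sf(chi2, k - 1))
    return chi2, p
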