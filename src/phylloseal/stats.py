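"""Rank-based inference for the repeated-measures sealing experiment.

The experimental design is fully within-subject: every leaf (subject) is
scored under each humidity condition at each evaluation time, giving a
subject x condition x time grid of relative bending angles.  Inference is
a two-way repeated-measures ANOVA on rank-transformed data — the angles
are pooled over the whole grid, replaced by average ranks, and the usual
within-subject sum-of-squares partition is applied, with each effect
tested against its own effect-by-subject interaction.  Mauchly's test and
the Greenhouse-Geisser correction guard against sphericity violations,
and Bonferroni-adjusted paired t-tests resolve the main effects.

Supporting descriptives and tests used alongside: median/IQR summaries,
Spearman rank-order correlation (exact permutation p at small n), and the
Wilcoxon-Mann-Whitney rank-sum test (exact enumeration at small n, with
the statistic in the ``wilcox.test`` convention: W = U of the first
sample).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CONDITION_LEVELS",
    "TIME_LEVELS_MIN",
    "AnovaEffect",
    "SphericityResult",
    "RmAnovaResult",
    "validate_rm_table",
    "rank_transform",
    "rm_anova_two_way",
    "pairwise_bonferroni",
    "spearman_rho",
    "mann_whitney",
    "median_iqr",
]

CONDITION_LEVELS = ("rh24", "rh49", "rh100", "droplet")
TIME_LEVELS_MIN = (1.0, 5.0, 10.0, 20.0, 40.0, 55.0)


@dataclass(frozen=True)
class SphericityResult:
    """Mauchly's test of sphericity for one within-subject effect."""

    W: float
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class AnovaEffect:
    """One effect of the within-subject ANOVA with sphericity correction."""

    name: str
    F: float
    df1: int
    df2: int
    p: float
    gg_epsilon: float
    p_gg: float
    sphericity: SphericityResult | None = None


@dataclass(frozen=True)
class RmAnovaResult:
    """Condition, time and interaction effects of the two-way RM ANOVA."""

    condition: AnovaEffect
    time: AnovaEffect
    interaction: AnovaEffect

    def effects(self):
        return (self.condition, self.time, self.interaction)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": e.name,
                "F": e.F,
                "df1": e.df1,
                "df2": e.df2,
                "p": e.p,
                "gg_epsilon": e.gg_epsilon,
                "p_gg": e.p_gg,
                "mauchly_W": e.sphericity.W if e.sphericity else np.nan,
                "mauchly_p": e.sphericity.p if e.sphericity else np.nan,
            }
            for e in self.effects()
        ]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# table handling

def validate_rm_table(
    table: pd.DataFrame,
    subject: str = "subject",
    condition: str = "condition",
    time: str = "time_min",
    value: str = "gamma_deg",
):
    """Check the long table is fully crossed and return a (n, a, b) array.

    Returns ``(cube, subjects, cond_levels, time_levels)`` where
    ``cube[s, i, j]`` is the value of subject ``s`` under condition level
    ``i`` at time level ``j``.  Missing or duplicated cells raise with the
    offending keys listed.
    """
    for col in (subject, condition, time, value):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    dup = table.duplicated(subset=[subject, condition, time])
    if dup.any():
        keys = table.loc[dup, [subject, condition, time]].to_records(index=False)
        raise ValueError(f"duplicated cells: {list(keys)[:5]}")
    subjects = sorted(table[subject].unique(), key=str)
    conds = sorted(table[condition].unique(), key=str)
    times = sorted(table[time].unique())
    wide = table.set_index([subject, condition, time])[value]
    full = pd.MultiIndex.from_product([subjects, conds, times])
    missing = full.difference(wide.index)
    if len(missing):
        raise ValueError(f"missing cells: {list(missing)[:5]}")
    cube = wide.reindex(full).to_numpy(dtype=float).reshape(
        len(subjects), len(conds), len(times)
    )
    if not np.all(np.isfinite(cube)):
        raise ValueError("non-finite values in table")
    return cube, subjects, conds, times


def rank_transform(table: pd.DataFrame, value: str = "gamma_deg") -> pd.DataFrame:
    """Replace the response by average ranks pooled over the whole table."""
    out = table.copy()
    out[value] = sps.rankdata(out[value].to_numpy(dtype=float))
    return out


# --------------------------------------------------------------------------
# two-way within-subject ANOVA

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrast matrix (rows sum to zero)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def _sphericity_and_epsilon(scores: np.ndarray):
    """Mauchly W (with chi2 approximation) and GG epsilon from contrast scores.

    ``scores`` is the (n, d) matrix of subject scores on d orthonormal
    contrasts of the effect.
    """
    n, d = scores.shape
    if d < 2:
        return SphericityResult(1.0, 0.0, 0, 1.0), 1.0
    S = np.cov(scores, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 0.0, None)
    tr = float(eig.sum())
    eps = tr**2 / (d * float((eig**2).sum())) if tr > 0 else 1.0 / d
    eps = float(min(1.0, max(eps, 1.0 / d)))
    if np.any(eig <= 0) or tr <= 0:
        # singular contrast covariance: W degenerates to 0
        W = 0.0
        logW = -np.inf
    else:
        logW = float(np.sum(np.log(eig)) - d * np.log(tr / d))
        W = float(np.exp(logW))
    # chi-square approximation with the second-order Box term, matching the
    # mauchly.test convention of R (and SPSS)
    df_chi = d * (d + 1) // 2 - 1
    f_corr = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1))
    if np.isfinite(logW) and f_corr > 0:
        chi2 = -(n - 1) * f_corr * logW
        w2 = (
            (d + 2.0) * (d - 1.0) * (d - 2.0)
            * (2.0 * d**3 + 6.0 * d**2 + 3.0 * (d + 1.0) + 2.0)
            / (288.0 * ((n - 1) * d * f_corr) ** 2)
        )
        p1 = sps.chi2.sf(chi2, df_chi)
        p2 = sps.chi2.sf(chi2, df_chi + 4)
        p = float(p1 + w2 * (p2 - p1))
    else:
        chi2 = np.inf
        p = 0.0
    return SphericityResult(W, float(chi2), int(df_chi), p), eps


def _effect(name, ss_eff, df1, ss_err, df2, eps_scores) -> AnovaEffect:
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    F = ms_eff / ms_err if ms_err > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2))
    sphericity, eps = _sphericity_and_epsilon(eps_scores)
    p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return AnovaEffect(name, float(F), int(df1), int(df2), p, eps, p_gg, sphericity)


def rm_anova_two_way(
    table: pd.DataFrame | np.ndarray,
    subject: str = "subject",
    condition: str = "condition",
    time: str = "time_min",
    value: str = "gamma_deg",
    rank: bool = False,
) -> RmAnovaResult:
    """Two-way fully within-subject ANOVA (condition x time, subject = leaf).

    Accepts the long-format table (or a ready (n, a, b) cube) and returns
    the three effects with their error terms taken from the respective
    effect-by-subject interactions:

    ==========  =====================  =======================
    effect      df1                    df2 (error)
    ==========  =====================  =======================
    condition   a - 1                  (a - 1)(n - 1)
    time        b - 1                  (b - 1)(n - 1)
    interaction (a - 1)(b - 1)         (a - 1)(b - 1)(n - 1)
    ==========  =====================  =======================

    With ``rank=True`` the response is first pooled-rank transformed.
    Mauchly's W and the Greenhouse-Geisser epsilon are computed per effect
    from the covariance of orthonormal-contrast scores; both the
    uncorrected and the epsilon-corrected p-value are reported.
    """
    if isinstance(table, np.ndarray):
        cube = np.asarray(table, dtype=float)
        if cube.ndim != 3:
            raise ValueError("cube must be (subjects, conditions, times)")
    else:
        if rank:
            table = rank_transform(table, value=value)
            rank = False
        cube, *_ = validate_rm_table(table, subject, condition, time, value)
    if rank:
        cube = sps.rankdata(cube.ravel()).reshape(cube.shape)
    n, a, b = cube.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        cube
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    scores_a = m_sa @ ca.T
    scores_b = m_sb @ cb.T
    scores_ab = cube.reshape(n, a * b) @ np.kron(ca, cb).T

    return RmAnovaResult(
        condition=_effect("condition", ss_a, a - 1, ss_as, (a - 1) * (n - 1), scores_a),
        time=_effect("time", ss_b, b - 1, ss_bs, (b - 1) * (n - 1), scores_b),
        interaction=_effect(
            "condition:time", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1), scores_ab
        ),
    )


# --------------------------------------------------------------------------
# post-hoc pairwise comparisons

def pairwise_bonferroni(
    table: pd.DataFrame,
    factor: str,
    subject: str = "subject",
    value: str = "gamma_deg",
    rank: bool = False,
) -> pd.DataFrame:
    """Bonferroni-adjusted paired t-tests between levels of one factor.

    Subject-wise values are averaged over the other factor(s) first, then
    every pair of factor levels is compared with a paired Student t-test;
    raw p-values are multiplied by the number of comparisons
    ``m = k (k - 1) / 2`` and capped at 1.  With ``rank=True`` the response
    is pooled-rank transformed first (the scale the omnibus test ran on).
    """
    if rank:
        table = rank_transform(table, value=value)
    means = table.groupby([subject, factor], sort=True)[value].mean().unstack(factor)
    if means.isna().any().any():
        raise ValueError("design not fully crossed for pairwise comparisons")
    if len(means) < 2:
        raise ValueError("need at least 2 subjects")
    levels = list(means.columns)
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    m = len(levels) * (len(levels) - 1) // 2
    rows = []
    for la, lb in itertools.combinations(levels, 2):
        diff = means[la].to_numpy() - means[lb].to_numpy()
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(means[la], means[lb])
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "t": float(t),
                "df": len(means) - 1,
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, m * p)),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# supporting rank statistics

def spearman_rho(x, y, exact_max_n: int = 9):
    """Spearman rank-order correlation with p-value.

    rho is the Pearson correlation of average-ranked data.  For
    ``n <= exact_max_n`` the p-value is the exact two-sided permutation
    probability of |rho| at least as large as observed; otherwise the
    t-distribution approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def _pearson(u, v):
        u = u - u.mean()
        v = v - v.mean()
        return float(u @ v / np.sqrt((u @ u) * (v @ v)))

    rho = _pearson(rx, ry)
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _pearson(rx, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, p


def mann_whitney(x, y, exact_max_total: int = 12):
    """Wilcoxon-Mann-Whitney rank-sum test for two independent samples.

    The statistic follows the ``wilcox.test`` convention: ``W`` is the
    U-statistic of the first sample (rank sum of ``x`` minus
    ``n1 (n1 + 1) / 2``).  The two-sided p-value is computed by exhaustive
    enumeration of all label assignments when ``n1 + n2 <= exact_max_total``
    and by the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    W = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= exact_max_total:
        count = 0
        total = 0
        idx_all = range(n1 + n2)
        for combo in itertools.combinations(idx_all, n1):
            w = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
            if abs(w - mu) >= abs(W - mu) - 1e-9:
                count += 1
            total += 1
        p = count / total
    else:
        tie_counts = np.unique(pooled, return_counts=True)[1]
        n = n1 + n2
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            return W, 1.0
        z = (abs(W - mu) - 0.5) / math.sqrt(sigma2)  # continuity correction
        p = float(2.0 * sps.norm.sf(max(z, 0.0)))
    return W, min(1.0, p)


def median_iqr(values):
    """Median, IQR, minimum, maximum and n of a sample.

    Quartiles use linear interpolation between closest ranks (the default
    of ``numpy.percentile``); the IQR is Q3 - Q1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "median": float(med),
        "iqr": float(q3 - q1),
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(v.size),
    }
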