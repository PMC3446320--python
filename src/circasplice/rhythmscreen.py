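"""The circadian screen on log2 splice scores.

Per probeset: a one-way ANOVA for an effect of circadian time, optional
empirical-Bayes moderation of the residual variances across probesets, BH
FDR adjustment, and an antiphase two-pool contrast ({t, t+12} pooling) that
removes ultradian (12-h) probesets from the candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "ModerationParams",
    "oneway_anova",
    "moderate",
    "bh_adjust",
    "antiphase_test",
    "screen_circadian",
]


class AnovaResult(NamedTuple):
    F: float
    p: float
    df_between: int
    df_within: int
    s_sq: float
    degenerate: bool = False


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior for the residual variances: d0 may be inf."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be > 0")


def oneway_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    Returns the residual (within-group) variance ``s_sq`` for downstream
    moderation. Zero within-group variance with a real between-group effect
    is flagged degenerate with p = 0.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    labels, index = np.unique(g, return_inverse=True)
    k = len(labels)
    n = len(y)
    if k < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    if n <= k:
        raise ValueError("total n must exceed the number of groups")
    counts = np.bincount(index)
    if not np.any(counts >= 2):
        raise ValueError("at least one group needs >= 2 members")
    group_means = np.bincount(index, weights=y) / counts
    grand = y.mean()
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(np.sum((y - group_means[index]) ** 2))
    df_between = k - 1
    df_within = n - k
    s_sq = ss_within / df_within
    if s_sq == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_between, df_within, 0.0, degenerate=True)
        return AnovaResult(np.inf, 0.0, df_between, df_within, 0.0, degenerate=True)
    F = (ss_between / df_between) / s_sq
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), p, df_between, df_within, s_sq)


def _trigamma_inverse(x: float, max_iter: int = 50, tol: float = 1e-10) -> float:
    """Monotone Newton solve of trigamma(y) = x (Smyth's iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif / y) < tol:
            break
    return y


def moderate(
    s_sq_list: Sequence[float], df: int
) -> tuple[ModerationParams, np.ndarray]:
    """Estimate the variance prior and shrink each variance towards it.

    Method-of-moments fit on log variances: with z = log(s^2),
    e = z - digamma(df/2) + log(df/2), the excess spread of e over the
    theoretical trigamma(df/2) determines d0 (via the inverse trigamma);
    no excess spread gives d0 = inf (fully pooled). The moderated variance
    is (d0*s0^2 + df*s^2)/(d0 + df).
    """
    s_sq = np.asarray(s_sq_list, dtype=float)
    if np.any(s_sq < 0):
        raise ValueError("variances must be non-negative")
    positive = s_sq > 0
    if positive.sum() < 10:
        raise ValueError("moderation needs >= 10 probesets with positive variance")
    if df < 1:
        raise ValueError("df must be >= 1")

    z = np.log(s_sq[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(np.sum((e - emean) ** 2) / (n - 1))
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread over sampling noise: fully pooled prior, and the
        # plain mean keeps identical variances a fixed point of the shrinkage
        d0 = np.inf
        s0_sq = float(np.mean(s_sq[positive]))
    params = ModerationParams(d0=d0, s0_sq=s0_sq)

    if np.isinf(d0):
        s_tilde = np.full_like(s_sq, s0_sq)
    else:
        s_tilde = (d0 * s0_sq + df * s_sq) / (d0 + df)
    return params, s_tilde


def bh_adjust(p_list: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, order-preserving."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _antiphase_pools(ct_labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split CT labels into the two {t, t+12} pools; error if not splittable."""
    ct = np.asarray(ct_labels, dtype=float)
    phases = np.unique(np.mod(ct, 12.0))
    if len(phases) != 2:
        raise ValueError(
            f"ct grid not splittable into two antiphase pools; phases mod 12: {phases}"
        )
    mask_a = np.isclose(np.mod(ct, 12.0), phases[0])
    if mask_a.all() or not mask_a.any():
        raise ValueError("one antiphase pool is empty")
    return mask_a, ~mask_a


def antiphase_test(
    values: Sequence[float],
    ct_labels: Sequence[float],
    s_sq: float | None = None,
    df: float | None = None,
) -> tuple[float, float]:
    """Two-sided test of pool {t, t+12} vs pool {t+6, t+18}.

    By default a classical pooled-variance two-sample t test on the pooled
    values. When a (moderated) residual variance ``s_sq`` with ``df``
    denominator degrees of freedom is supplied, the t statistic uses it
    instead -- the moderated-contrast form used by the screen.
    """
    y = np.asarray(values, dtype=float)
    mask_a, mask_b = _antiphase_pools(np.asarray(ct_labels, dtype=float))
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("one antiphase pool is empty")
    a, b = y[mask_a], y[mask_b]
    n1, n2 = len(a), len(b)
    diff = a.mean() - b.mean()
    if s_sq is None:
        if n1 + n2 <= 2:
            raise ValueError("pooled t test needs total n > 2")
        df = n1 + n2 - 2
        s_sq = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
    if s_sq == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    se = np.sqrt(s_sq * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    if np.isinf(df):
        p = float(2.0 * stats.norm.sf(abs(t)))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), p


def screen_circadian(
    scores: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    moderated: bool = True,
    anti_universe: str = "all",
) -> pd.DataFrame:
    """Run the full circadian screen on a probeset x sample score table.

    Per probeset, on log2 scores: one-way ANOVA across CT groups, BH over
    all probesets, keep q_time < alpha; antiphase contrast, BH (universe
    ``all`` probesets or only the ``kept`` set), drop q_anti < alpha.
    Returns one row per probeset with the statistics and candidate flag.
    """
    if anti_universe not in ("all", "kept"):
        raise ValueError("anti_universe must be 'all' or 'kept'")
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    missing = set(scores.columns) - set(design.index)
    if missing:
        raise ValueError(f"design does not cover samples: {sorted(missing)[:5]}")
    ct = design.loc[list(scores.columns), "circadian_time"].to_numpy(dtype=float)
    counts = pd.Series(ct).value_counts()
    if (counts < 2).any():
        raise ValueError("screen needs >= 2 replicates per circadian time")

    log_scores = np.log2(scores.to_numpy(dtype=float))
    n_ps = log_scores.shape[0]

    F = np.empty(n_ps)
    p_time = np.empty(n_ps)
    s_sq = np.empty(n_ps)
    degenerate = np.zeros(n_ps, dtype=bool)
    df_between = df_within = 0
    for i in range(n_ps):
        res = oneway_anova(log_scores[i], ct)
        F[i] = res.F
        p_time[i] = res.p
        s_sq[i] = res.s_sq
        degenerate[i] = res.degenerate
        df_between, df_within = res.df_between, res.df_within

    params = None
    anti_df: float = df_within
    s_used = s_sq.copy()
    if moderated:
        usable = ~degenerate
        params, s_tilde = moderate(s_sq[usable], df_within)
        s_used = s_sq.copy()
        s_used[usable] = s_tilde
        ratio = np.ones(n_ps)
        ratio[usable] = np.where(s_tilde > 0, s_sq[usable] / s_tilde, 1.0)
        F = F * ratio
        anti_df = df_within + params.d0
        if np.isinf(params.d0):
            # F*df1 -> chi-square(df1) as the denominator dof grows
            p_mod = stats.chi2.sf(F * df_between, df_between)
        else:
            p_mod = stats.f.sf(F, df_between, df_within + params.d0)
        p_time = np.where(degenerate, p_time, p_mod)

    stat_anti = np.empty(n_ps)
    p_anti = np.empty(n_ps)
    for i in range(n_ps):
        if moderated and not degenerate[i]:
            stat_anti[i], p_anti[i] = antiphase_test(
                log_scores[i], ct, s_sq=s_used[i], df=anti_df
            )
        else:
            stat_anti[i], p_anti[i] = antiphase_test(log_scores[i], ct)

    q_time = bh_adjust(p_time)
    kept = q_time < alpha
    if anti_universe == "all":
        q_anti = bh_adjust(p_anti)
    else:
        q_anti = np.ones(n_ps)
        if kept.any():
            q_anti[kept] = bh_adjust(p_anti[kept])
    is_candidate = kept & ~(q_anti < alpha)

    result = pd.DataFrame(
        {
            "probeset_id": scores.index,
            "F_time": F,
            "p_time": p_time,
            "q_time": q_time,
            "stat_anti": stat_anti,
            "p_anti": p_anti,
            "q_anti": q_anti,
            "degenerate": degenerate,
            "is_candidate": is_candidate,
        }
    ).set_index("probeset_id")
    result.attrs["moderation"] = params
    result.attrs["alpha"] = alpha
    return result
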