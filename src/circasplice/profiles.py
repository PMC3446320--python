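"""Temporal-profile descriptive machinery.

Signed fold changes vs a reference circadian time, acrophase/amplitude,
Pearson profile correlation, moving-average smoothing and z-scoring,
signal-to-noise ranking of two-day profiles, SOTA and hierarchical
clustering with correlation distance, and balanced two-way ANOVA with
Bonferroni planned comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "TemporalProfile",
    "PhaseMetrics",
    "ClusterAssignment",
    "FactorialResult",
    "fold_changes",
    "acrophase_amplitude",
    "profile_correlation",
    "smooth_zscore",
    "snr_rank",
    "sota_cluster",
    "hierarchical_order",
    "twoway_anova",
    "bonferroni_posthoc",
]

SIGNIFICANCE_CODES = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TemporalProfile:
    """Replicate-averaged time series for one measured quantity."""

    times: tuple[float, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    ns: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.means) == len(self.sems) == len(self.ns)):
            raise ValueError("times, means, sems, ns must have equal length")
        if list(self.times) != sorted(set(self.times)):
            raise ValueError("times must be strictly increasing")
        if any(n < 1 for n in self.ns):
            raise ValueError("n must be >= 1 at every time")
        if any(s < 0 for s in self.sems):
            raise ValueError("sem must be >= 0")

    @classmethod
    def from_replicates(
        cls, times: Sequence[float], values: Sequence[Sequence[float]]
    ) -> "TemporalProfile":
        means, sems, ns = [], [], []
        for v in values:
            v = np.asarray(v, dtype=float)
            means.append(float(v.mean()))
            ns.append(len(v))
            sems.append(float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0)
        return cls(tuple(float(t) for t in times), tuple(means), tuple(sems), tuple(ns))


@dataclass(frozen=True)
class PhaseMetrics:
    acrophase: float       # hours; time of largest positive fold vs reference
    amplitude: float       # signed fold of largest absolute value vs reference
    reference_time: float


@dataclass
class ClusterAssignment:
    labels: dict[str, int]                 # profile id -> cluster label
    centroids: dict[int, np.ndarray]       # cluster label -> centroid profile


@dataclass
class FactorialResult:
    p_main_A: float
    p_main_B: float
    p_interaction: float
    cell_means: pd.DataFrame
    cell_ns: pd.DataFrame
    mse: float
    df_resid: int
    ss: dict[str, float] = field(default_factory=dict)


def _signed_fold(ratio: float) -> float:
    return ratio if ratio >= 1.0 else -1.0 / ratio


def fold_changes(
    profile: TemporalProfile, reference_time: float | None = None
) -> dict[float, float]:
    """Signed fold change of each time's mean versus the reference time.

    Ratios >= 1 map to +ratio, ratios < 1 to -1/ratio, so the reference
    itself maps to +1 and down-regulation is encoded symmetrically.
    """
    ref = profile.times[0] if reference_time is None else reference_time
    if ref not in profile.times:
        raise ValueError(f"reference time {ref} not in profile times")
    by_time = dict(zip(profile.times, profile.means))
    if any(m <= 0 for m in by_time.values()):
        raise ValueError("fold changes need strictly positive means")
    ref_mean = by_time[ref]
    return {t: _signed_fold(m / ref_mean) for t, m in by_time.items()}


def acrophase_amplitude(folds: Mapping[float, float]) -> PhaseMetrics:
    """Acrophase = time of the maximum signed fold; amplitude = signed fold
    of maximum absolute value. Ties break to the earliest time."""
    if not folds:
        raise ValueError("empty fold table")
    times = sorted(folds)
    acro = max(times, key=lambda t: (folds[t], -t))
    amp_time = max(times, key=lambda t: (abs(folds[t]), -t))
    ref = next((t for t in times if folds[t] == 1.0), times[0])
    return PhaseMetrics(
        acrophase=float(acro), amplitude=float(folds[amp_time]), reference_time=float(ref)
    )


def profile_correlation(
    a: TemporalProfile, b: TemporalProfile
) -> tuple[float, float, float]:
    """Pearson correlation of two profiles on their shared time points.

    Returns (r, r_sq, two-sided p) using the t transform with n-2 dof.
    """
    shared = sorted(set(a.times) & set(b.times))
    if len(shared) < 3:
        raise ValueError("profile correlation needs >= 3 shared time points")
    xa = np.array([dict(zip(a.times, a.means))[t] for t in shared])
    xb = np.array([dict(zip(b.times, b.means))[t] for t in shared])
    if xa.std() == 0 or xb.std() == 0:
        raise ValueError("zero variance in a profile")
    r, p = stats.pearsonr(xa, xb)
    return float(r), float(r * r), float(p)


def moving_average(series: Sequence[float], window: int = 5) -> np.ndarray:
    """Centred moving average with edge windows truncated to available points."""
    x = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd count")
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def smooth_zscore(series: Sequence[float], window: int = 5) -> np.ndarray:
    """Five-point (by default) moving average, then z-score over the series."""
    x = np.asarray(series, dtype=float)
    if len(x) < window:
        raise ValueError(f"series length {len(x)} < window {window}")
    smoothed = moving_average(x, window)
    sd = smoothed.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance after smoothing; cannot z-score")
    return (smoothed - smoothed.mean()) / sd


def snr_rank(
    day1: Mapping[str, Sequence[float]],
    day2: Mapping[str, Sequence[float]],
    window: int = 5,
) -> pd.DataFrame:
    """Rank two-day profiles by signal-to-noise then day-to-day agreement.

    SNR = (max - min) of the two-day concatenation divided by the SD of its
    residual about a five-point moving-average smooth; reproducibility is
    the Pearson r between the two days. Profiles are ranked by descending
    SNR then descending r; the averaged-day profile is included.
    """
    if set(day1) != set(day2):
        raise ValueError("day1 and day2 must cover the same profiles")
    rows = []
    for pid in day1:
        d1 = np.asarray(day1[pid], dtype=float)
        d2 = np.asarray(day2[pid], dtype=float)
        if d1.shape != d2.shape:
            raise ValueError(f"profile {pid}: mismatched day lengths")
        concat = np.concatenate([d1, d2])
        resid_sd = float((concat - moving_average(concat, window)).std(ddof=0))
        rng_ = float(concat.max() - concat.min())
        if resid_sd > 0:
            snr = rng_ / resid_sd
        else:
            snr = np.inf if rng_ > 0 else 0.0
        if d1.std() > 0 and d2.std() > 0:
            r = float(stats.pearsonr(d1, d2)[0])
        else:
            r = 0.0
        rows.append(
            {"profile_id": pid, "snr": snr, "reproducibility": r,
             "averaged": 0.5 * (d1 + d2)}
        )
    table = pd.DataFrame(rows).sort_values(
        ["snr", "reproducibility", "profile_id"], ascending=[False, False, True]
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table.set_index("profile_id")


def _corr_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson r; constant vectors are maximally distant (r taken as 0)."""
    if x.std() == 0 or y.std() == 0:
        return 1.0
    return float(1.0 - np.corrcoef(x, y)[0, 1])


def sota_cluster(
    profiles: Mapping[str, Sequence[float]],
    max_clusters: int,
    learning_rates: tuple[float, float, float] = (0.01, 0.005, 0.001),
    epochs_per_split: int = 10,
    seed: int = 0,
) -> ClusterAssignment:
    """Self-organizing tree clustering with correlation distance.

    Grows a binary tree from a single cell: the cell with the highest
    resource (mean member-to-centroid distance) is split into two children
    initialised at the parent centroid; members are then presented in input
    order for a fixed number of epochs, adapting the winning child, the
    parent and the sibling toward each profile with the (winner, parent,
    sibling) learning rates. Growth stops at ``max_clusters`` cells.
    Deterministic for a fixed seed and presentation order.
    """
    ids = list(profiles)
    if len(ids) < max_clusters:
        raise ValueError("need at least as many profiles as clusters")
    data = {pid: np.asarray(profiles[pid], dtype=float) for pid in ids}
    lengths = {len(v) for v in data.values()}
    if len(lengths) != 1:
        raise ValueError("all profiles must share one time grid")
    rng = np.random.default_rng(seed)
    lr_w, lr_p, lr_s = learning_rates

    # each leaf: (centroid, member id list)
    root = np.mean([data[pid] for pid in ids], axis=0)
    leaves: list[tuple[np.ndarray, list[str]]] = [(root, list(ids))]

    while len(leaves) < max_clusters:
        resources = [
            np.mean([_corr_distance(data[m], c) for m in members]) if members else -1.0
            for c, members in leaves
        ]
        split_at = int(np.argmax(resources))
        parent_centroid, members = leaves.pop(split_at)
        # children start as jittered copies of the parent; the jitter only
        # breaks exact ties, adaptation does the differentiation
        jitter = rng.normal(0.0, 1e-6, size=parent_centroid.shape)
        children = [parent_centroid + jitter, parent_centroid - jitter]
        parent = parent_centroid.copy()
        for _ in range(epochs_per_split):
            for pid in members:
                x = data[pid]
                d = [_corr_distance(x, c) for c in children]
                w = int(np.argmin(d))
                s = 1 - w
                children[w] = children[w] + lr_w * (x - children[w])
                parent = parent + lr_p * (x - parent)
                children[s] = children[s] + lr_s * (x - children[s])
        assigned: list[list[str]] = [[], []]
        for pid in members:
            d = [_corr_distance(data[pid], c) for c in children]
            assigned[int(np.argmin(d))].append(pid)
        for c, mem in zip(children, assigned):
            leaves.append((c, mem))

    labels: dict[str, int] = {}
    centroids: dict[int, np.ndarray] = {}
    for label, (c, members) in enumerate(leaves, start=1):
        centroids[label] = (
            np.mean([data[m] for m in members], axis=0) if members else c.copy()
        )
        for m in members:
            labels[m] = label
    return ClusterAssignment(labels=labels, centroids=centroids)


def hierarchical_order(
    profiles: Mapping[str, Sequence[float]],
) -> tuple[list[str], np.ndarray]:
    """Average-linkage agglomerative clustering with 1 - Pearson r distance.

    Returns (leaf order for heat-map rendering, scipy linkage matrix).
    """
    ids = list(profiles)
    if len(ids) < 2:
        raise ValueError("hierarchical clustering needs >= 2 profiles")
    matrix = np.array([np.asarray(profiles[pid], dtype=float) for pid in ids])
    if np.any(matrix.std(axis=1) == 0):
        flat = [ids[i] for i in np.where(matrix.std(axis=1) == 0)[0]]
        raise ValueError(f"constant profiles have undefined correlation: {flat}")
    n = len(ids)
    condensed = np.array(
        [
            _corr_distance(matrix[i], matrix[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
    )
    linkage = hierarchy.linkage(condensed, method="average")
    order = [ids[i] for i in hierarchy.leaves_list(linkage)]
    return order, linkage


def twoway_anova(
    values: Sequence[float],
    factor_A: Sequence,
    factor_B: Sequence,
) -> FactorialResult:
    """Balanced fixed-effects two-way ANOVA with interaction.

    Partitioned sums of squares for a complete balanced design with >= 2
    replicates per cell. Degenerate zero-MSE designs report p = 1 for null
    effects and p = 0 otherwise.
    """
    y = np.asarray(values, dtype=float)
    a = pd.Categorical(factor_A)
    b = pd.Categorical(factor_B)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")
    frame = pd.DataFrame({"y": y, "A": a, "B": b})
    counts = frame.groupby(["A", "B"], observed=False).size().unstack()
    if counts.isna().any().any():
        raise ValueError("incomplete design: every A x B cell must be observed")
    if counts.to_numpy().min() < 2:
        raise ValueError("need >= 2 replicates per cell")
    if counts.to_numpy().std() != 0:
        raise ValueError("unbalanced design rejected; equal cell counts required")
    n_rep = int(counts.to_numpy()[0, 0])
    n_a, n_b = counts.shape

    grand = y.mean()
    cell_means = frame.groupby(["A", "B"], observed=False)["y"].mean().unstack()
    a_means = frame.groupby("A", observed=False)["y"].mean()
    b_means = frame.groupby("B", observed=False)["y"].mean()

    ss_total = float(np.sum((y - grand) ** 2))
    ss_a = float(n_b * n_rep * np.sum((a_means - grand) ** 2))
    ss_b = float(n_a * n_rep * np.sum((b_means - grand) ** 2))
    ss_cells = float(n_rep * np.sum((cell_means.to_numpy() - grand) ** 2))
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells

    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_err = n_a * n_b * (n_rep - 1)
    mse = ss_err / df_err

    def _p(ss_eff: float, df_eff: int) -> float:
        if mse <= 0:
            return 1.0 if ss_eff <= 1e-12 else 0.0
        F = (ss_eff / df_eff) / mse
        return float(stats.f.sf(F, df_eff, df_err))

    return FactorialResult(
        p_main_A=_p(ss_a, df_a),
        p_main_B=_p(ss_b, df_b),
        p_interaction=_p(max(ss_ab, 0.0), df_ab),
        cell_means=cell_means,
        cell_ns=counts,
        mse=float(mse),
        df_resid=df_err,
        ss={"A": ss_a, "B": ss_b, "AB": ss_ab, "error": ss_err, "total": ss_total},
    )


def significance_code(p: float) -> str:
    for cut, code in SIGNIFICANCE_CODES:
        if p <= cut:
            return code
    return "Ns"


def bonferroni_posthoc(
    values: Sequence[float],
    factor_A: Sequence,
    factor_B: Sequence,
    planned: Sequence[tuple[tuple, tuple]],
) -> pd.DataFrame:
    """Planned cell comparisons after the factorial fit.

    Each comparison is a pair of (A level, B level) cells; the t statistic
    uses the factorial MSE and its residual dof, and the Bonferroni p is
    min(1, raw p x number of planned comparisons) with the usual
    significance codes.
    """
    if not planned:
        raise ValueError("empty comparison list")
    fit = twoway_anova(values, factor_A, factor_B)
    frame = pd.DataFrame({"y": np.asarray(values, dtype=float),
                          "A": list(factor_A), "B": list(factor_B)})
    grouped = frame.groupby(["A", "B"])["y"]
    means = grouped.mean()
    ns = grouped.size()
    m = len(planned)
    rows = []
    for cell1, cell2 in planned:
        for cell in (cell1, cell2):
            if cell not in means.index:
                raise KeyError(f"planned comparison references unknown cell {cell}")
        diff = means[cell1] - means[cell2]
        se = np.sqrt(fit.mse * (1.0 / ns[cell1] + 1.0 / ns[cell2]))
        if se == 0:
            t = 0.0 if diff == 0 else np.sign(diff) * np.inf
            p_raw = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p_raw = float(2.0 * stats.t.sf(abs(t), fit.df_resid))
        p_adj = min(1.0, p_raw * m)
        rows.append(
            {
                "comparison": f"{cell1} vs {cell2}",
                "difference": float(diff),
                "t": float(t),
                "p_raw": p_raw,
                "p_bonferroni": p_adj,
                "code": significance_code(p_adj),
            }
        )
    return pd.DataFrame(rows)
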