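"""Differential accessibility over a time course and kinetic classification.

The count model is a per-feature negative binomial.  Samples are normalized by
median-of-ratios size factors; per-feature dispersions are method-of-moments
estimates shrunk 50/50 toward a log-linear mean-dispersion trend; each pair of
time points is compared with a Wald test on the log ratio of normalized group
means, with Benjamini-Hochberg correction within each comparison.  Dynamic
features are then assigned to one of five kinetic classes (immediate /
transient / gradual increase, transient / gradual decrease) by deterministic
rules on the significant comparisons, or "nondynamic" when nothing changes.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KINETIC_CLASSES",
    "make_design",
    "size_factors",
    "normalized_counts",
    "estimate_dispersions",
    "differential_test",
    "all_pairwise_calls",
    "classify_kinetics",
    "classify_all",
]

KINETIC_CLASSES = (
    "immediate_increase",
    "transient_increase",
    "gradual_increase",
    "transient_decrease",
    "gradual_decrease",
    "nondynamic",
)

_DISPERSION_FLOOR = 1e-8
# a call needs both q <= threshold and at least this |log2FC|: with all
# pairwise comparisons tested, q-control alone lets small-effect false
# positives accumulate across the union of comparisons
DEFAULT_LFC_FLOOR = 0.5


def make_design(time_points: Sequence[int], n_replicates: int) -> pd.DataFrame:
    """Sample sheet with one row per (time, replicate); sample = 't{t}_r{r}'."""
    rows = [(f"t{t}_r{r}", t, r) for t in time_points for r in range(1, n_replicates + 1)]
    return pd.DataFrame(rows, columns=["sample", "time", "replicate"]).set_index("sample")


def size_factors(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample (column).

    factor_j = median over features i of counts_ij / geometric-mean_i, taken
    over features with all-positive counts.  ``pseudocount`` may be added to
    every count when no feature is positive in every sample.
    """
    mat = counts.to_numpy(dtype=float) + pseudocount
    allpos = np.all(mat > 0, axis=1)
    if not np.any(allpos):
        raise ValueError(
            "no feature has positive counts in every sample; pass pseudocount=0.5"
        )
    sub = mat[allpos]
    log_geo = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def estimate_dispersions(counts: pd.DataFrame, design: pd.DataFrame,
                         factors: pd.Series | None = None) -> pd.Series:
    """Per-feature NB dispersion: method of moments shrunk toward the trend.

    The raw estimate pools within-time-point residual variance of normalized
    counts: alpha_hat = max(0, (s2 - mu) / mu^2).  A log-linear trend of
    alpha on mean is fitted over features with positive raw estimates and the
    final dispersion is the 50/50 arithmetic blend of the raw estimate and
    the trend value at the feature's mean.
    """
    norm = normalized_counts(counts, factors).to_numpy(dtype=float)
    groups = [np.flatnonzero(design["time"].to_numpy() == t)
              for t in design["time"].unique()]
    if min(len(g) for g in groups) < 2:
        raise ValueError("dispersion estimation needs >=2 replicates per time point")

    n_resid = 0
    ss = np.zeros(norm.shape[0])
    for g in groups:
        sub = norm[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        n_resid += len(g) - 1
    s2 = ss / n_resid
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
    raw = np.maximum(raw, 0.0)

    # log-linear trend fitted to binned arithmetic means of the raw
    # estimates: the raw MoM estimator is right-skewed at few replicates, so
    # regressing log(raw) directly would underestimate the trend (Jensen)
    ok = mu > 0
    if ok.sum() >= 20 and raw[ok].mean() > 0:
        order = np.argsort(mu[ok])
        mu_s, raw_s = mu[ok][order], raw[ok][order]
        n_bins = min(10, max(2, ok.sum() // 20))
        bins = np.array_split(np.arange(ok.sum()), n_bins)
        bx = np.array([mu_s[b].mean() for b in bins])
        by = np.maximum([raw_s[b].mean() for b in bins], _DISPERSION_FLOOR)
        if len(bx) >= 2 and np.ptp(np.log(bx)) > 0:
            slope, intercept = np.polyfit(np.log(bx), np.log(by), 1)
        else:
            slope, intercept = 0.0, float(np.log(by.mean()))
        trend = np.exp(intercept + slope * np.log(np.maximum(mu, 1e-12)))
    elif ok.sum() >= 3 and raw[ok].mean() > 0:
        trend = np.full_like(mu, max(raw[ok].mean(), _DISPERSION_FLOOR))
    else:  # degenerate matrix (e.g. noiseless input): flat near-zero trend
        trend = np.full_like(mu, _DISPERSION_FLOOR)
    alpha = 0.5 * raw + 0.5 * trend
    return pd.Series(np.maximum(alpha, _DISPERSION_FLOOR), index=counts.index,
                     name="dispersion")


def differential_test(counts: pd.DataFrame, design: pd.DataFrame,
                      time_a: int, time_b: int, q_threshold: float = 0.05,
                      factors: pd.Series | None = None,
                      dispersions: pd.Series | None = None,
                      min_abs_log2fc: float = DEFAULT_LFC_FLOOR) -> pd.DataFrame:
    """Wald test of time_b vs time_a on normalized NB means, BH-corrected.

    Returns one row per feature: log2 fold change (b over a), p-value,
    BH q-value, and direction in {'up', 'down', 'none'}; direction is
    non-none only when q <= ``q_threshold`` and |log2FC| >=
    ``min_abs_log2fc``.  Features with zero counts in both groups are
    reported with direction 'none' and p = q = 1.
    """
    for t in (time_a, time_b):
        if (design["time"] == t).sum() < 2:
            raise ValueError(f"time point {t} needs >=2 replicates")
    if factors is None:
        factors = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, design, factors)

    norm = normalized_counts(counts, factors)
    cols_a = design.index[design["time"] == time_a]
    cols_b = design.index[design["time"] == time_b]
    m_a = norm[cols_a].mean(axis=1).to_numpy()
    m_b = norm[cols_b].mean(axis=1).to_numpy()
    n_a, n_b = len(cols_a), len(cols_b)
    alpha = dispersions.to_numpy()

    both_zero = (m_a == 0) & (m_b == 0)
    # half-count offset keeps the ratio defined at zero and cancels under the null
    a_, b_ = m_a + 0.5, m_b + 0.5
    lfc = np.log2(b_ / a_)
    se_ln = np.sqrt((1.0 / a_ + alpha) / n_a + (1.0 / b_ + alpha) / n_b)
    z = np.log(b_ / a_) / se_ln
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals[both_zero] = 1.0
    lfc[both_zero] = 0.0

    _rej, qvals, *_ = multipletests(pvals, method="fdr_bh")
    called = (qvals <= q_threshold) & (np.abs(lfc) >= min_abs_log2fc)
    direction = np.where(called, np.where(lfc > 0, "up", "down"), "none")
    direction[both_zero] = "none"
    return pd.DataFrame({
        "feature": counts.index,
        "time_a": time_a,
        "time_b": time_b,
        "mean_a": m_a,
        "mean_b": m_b,
        "log2fc": lfc,
        "pvalue": pvals,
        "qvalue": qvals,
        "direction": direction,
    }).set_index("feature", drop=False)


def all_pairwise_calls(counts: pd.DataFrame, design: pd.DataFrame,
                       q_threshold: float = 0.05,
                       factors: pd.Series | None = None,
                       dispersions: pd.Series | None = None,
                       min_abs_log2fc: float = DEFAULT_LFC_FLOOR) -> pd.DataFrame:
    """Differential calls for every ordered pair of time points (a < b)."""
    if factors is None:
        factors = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, design, factors)
    times = sorted(design["time"].unique())
    frames = [
        differential_test(counts, design, a, b, q_threshold, factors,
                          dispersions, min_abs_log2fc)
        for a, b in itertools.combinations(times, 2)
    ]
    return pd.concat(frames, ignore_index=True)


def classify_kinetics(trajectory: pd.Series, calls: pd.DataFrame) -> str:
    """Assign one kinetic class from the significant pairwise comparisons.

    Rules (deterministic; ``trajectory`` is the normalized mean per time
    point, ``calls`` the feature's rows from :func:`all_pairwise_calls`):

    * no significant comparison -> nondynamic;
    * direction = sign of the first significant change (smallest ``time_b``,
      then smallest ``time_a``);
    * transient when a later significant change of opposite sign exists
      (starting no earlier than the first change's end) and the final level
      has returned within 50% of the peak excursion of baseline;
    * otherwise increases are immediate when the first significant change is
      the comparison against the second time point, else gradual; decreases
      are gradual (the class scheme has no immediate decrease).
    """
    times = sorted(trajectory.index)
    sig = calls[calls["direction"] != "none"]
    if sig.empty:
        return "nondynamic"
    first = sig.sort_values(["time_b", "time_a"]).iloc[0]
    d1 = first["direction"]
    opp = "down" if d1 == "up" else "up"
    reversal = not sig[(sig["direction"] == opp)
                       & (sig["time_a"] >= first["time_b"])].empty

    baseline = trajectory[times[0]]
    final = trajectory[times[-1]]
    extreme = trajectory.max() if d1 == "up" else trajectory.min()
    excursion = abs(extreme - baseline)
    transient = bool(reversal and excursion > 0
                     and abs(final - baseline) <= 0.5 * excursion)

    if d1 == "up":
        if transient:
            return "transient_increase"
        return "immediate_increase" if first["time_b"] == times[1] else "gradual_increase"
    return "transient_decrease" if transient else "gradual_decrease"


def classify_all(counts: pd.DataFrame, design: pd.DataFrame,
                 calls: pd.DataFrame | None = None, q_threshold: float = 0.05,
                 factors: pd.Series | None = None) -> pd.Series:
    """Kinetic class per feature (index-aligned with ``counts``)."""
    if factors is None:
        factors = size_factors(counts)
    if calls is None:
        calls = all_pairwise_calls(counts, design, q_threshold, factors)
    norm = normalized_counts(counts, factors)
    times = sorted(design["time"].unique())
    traj = pd.DataFrame(
        {t: norm[design.index[design["time"] == t]].mean(axis=1) for t in times})
    by_feature = dict(iter(calls.groupby("feature")))
    empty = calls.iloc[0:0]
    out = {
        feat: classify_kinetics(traj.loc[feat], by_feature.get(feat, empty))
        for feat in counts.index
    }
    return pd.Series(out, name="kinetic_class")
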