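"""Day/night and timepoint-pair analysis of locus occupancy scores.

Occupancy scores (log2(IP/Input) per locus and sample) are summarised
per condition and per timepoint, and two sample groups (day vs night,
or ZT02 vs ZT10) are compared with an empirical-Bayes moderated
two-sample t-test: the per-locus pooled residual variance ``s^2`` (d
degrees of freedom) is shrunk toward a common prior variance ``s0^2``
(d0 prior degrees of freedom) estimated across loci by the
method of moments on log variances, giving the posterior variance

    s_post^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and a moderated t with d + d0 degrees of freedom.  With d0 = 0 this is
the classical pooled-variance two-sample t; as d0 -> inf every locus
uses the common variance.  Results carry MVA coordinates: per-locus
difference of group means M and average of group means A.

Day samples are those at ZT in [0, 12) (lights on), night samples ZT in
[12, 24); in the canonical design the day group pools the ZT02/06/10
samples of both days and the night group ZT14/18/22.  Significance is
reported unadjusted at p < 0.05 per comparison (multiplicity handling
is left to the caller and recorded in the result metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from . import cosinor
from .errors import ConfigurationError, InsufficientDataError
from .timecourse import OccupancyTable, TimeCourse


def condition_mean(occ: TimeCourse) -> pd.DataFrame:
    """Per-locus mean score over all samples of each condition."""
    if occ.n_samples == 0:
        raise InsufficientDataError("no samples")
    cols = {}
    for cond in occ.conditions:
        keep = occ.samples.index[occ.samples["condition"] == cond]
        cols[cond] = occ.values[keep].mean(axis=1)
    return pd.DataFrame(cols)


def condition_summary(means: pd.DataFrame) -> pd.DataFrame:
    """Across-locus distribution summary of per-condition means."""
    return pd.DataFrame({"mean": means.mean(), "median": means.median()})


def timepoint_means(occ: TimeCourse, condition: str | None = None) -> pd.DataFrame:
    """Per-locus mean of replicates at each ZT (days pooled).

    Loci with missing samples are averaged over the available ones;
    NaN-only cells stay missing.
    """
    if condition is not None:
        occ = occ.subset_condition(condition)
    zts = np.unique(occ.times)
    return pd.DataFrame(
        {f"ZT{zt:g}": occ.values.loc[:, occ.times == zt].mean(axis=1) for zt in zts}
    )


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        step = (tri - x) / special.polygamma(2, y)
        y -= step
        y = max(y, 1e-8)
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Models the per-locus sample variances as ``s^2 ~ s0^2 * F(df, d0)``
    and solves for (d0, s0^2) from the mean and variance of ``log s^2``
    using digamma/trigamma moments.  Returns ``d0 = inf`` when the
    observed spread of log variances is no larger than expected from
    chi-square sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if positive.sum() < 2:
        raise InsufficientDataError("need >= 2 positive variances to fit the prior")
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * trigamma_inverse(evar)
    s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def squeeze_variances(
    s2: np.ndarray, df: int, prior_df: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Shrink per-locus variances toward the common prior.

    Returns (posterior variances, d0, s0^2).  ``prior_df`` overrides the
    estimated d0 (0 disables moderation; inf pools fully).
    """
    s2 = np.asarray(s2, dtype=float)
    if prior_df is None:
        try:
            d0, s0_sq = fit_variance_prior(s2, df)
        except InsufficientDataError:
            # (near-)deterministic data: nothing to pool, fall back to
            # unmoderated per-locus variances
            warnings.warn("variances carry no information; moderation disabled",
                          stacklevel=2)
            d0, s0_sq = 0.0, float("nan")
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ConfigurationError(f"prior_df must be >= 0, got {prior_df}")
        s0_sq = fit_variance_prior(s2, df)[1] if d0 > 0 else float("nan")
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        post = s2.copy()
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0, s0_sq


@dataclass
class GroupCompareResult:
    """Moderated two-group comparison of locus occupancy.

    ``table`` columns: mean_a, mean_b, M (= mean_b - mean_a),
    A (= (mean_a + mean_b)/2), s2 (pooled variance), s2_post, t, p_value,
    significant.  The group means behind M and A may be timepoint
    averages (day/night convention) while t always uses all samples.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    prior_df: float
    prior_var: float
    alpha: float = 0.05
    p_adjust: str = "none"
    meta: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_loci(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def moderated_group_test(
    occ: TimeCourse,
    group_a,
    group_b,
    labels: tuple[str, str] = ("a", "b"),
    prior_df: float | None = None,
    alpha: float = 0.05,
) -> GroupCompareResult:
    """Moderated t comparison of two sample groups, per locus.

    ``group_a``/``group_b`` are sample-id collections; each needs at
    least 2 samples.  M is the difference of group means (b - a), A
    their average; p-values are two-sided.
    """
    group_a, group_b = list(group_a), list(group_b)
    for name, g in zip(labels, (group_a, group_b)):
        if len(g) < 2:
            raise InsufficientDataError(
                f"group {name!r} has {len(g)} samples; need >= 2"
            )
    A_mat = occ.values[group_a].to_numpy(dtype=float)
    B_mat = occ.values[group_b].to_numpy(dtype=float)
    na, nb = A_mat.shape[1], B_mat.shape[1]
    mean_a, mean_b = A_mat.mean(axis=1), B_mat.mean(axis=1)
    df = na + nb - 2
    s2 = (A_mat.var(axis=1, ddof=1) * (na - 1) + B_mat.var(axis=1, ddof=1) * (nb - 1)) / df
    s2_post, d0, s0_sq = squeeze_variances(s2, df, prior_df=prior_df)

    M = mean_b - mean_a
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, M / se, np.where(M == 0, 0.0, np.inf * np.sign(M)))
    df_total = df + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "M": M,
            "A": (mean_a + mean_b) / 2.0,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p_value": p,
            "significant": p < alpha,
        },
        index=occ.feature_ids,
    )
    return GroupCompareResult(
        table, labels[0], labels[1], na, nb, d0, s0_sq, alpha=alpha,
        meta={"df_residual": df, "df_total": float(df_total)},
    )


def _restrict(occ: TimeCourse, condition: str | None) -> TimeCourse:
    if condition is not None:
        occ = occ.subset_condition(condition)
    if isinstance(occ, OccupancyTable):
        occ = occ.flagged()
    return occ


def day_night_compare(
    occ: TimeCourse,
    condition: str | None = None,
    prior_df: float | None = None,
    alpha: float = 0.05,
) -> GroupCompareResult:
    """Moderated night-vs-day comparison with MVA coordinates.

    Groups: day = samples at ZT in [0, 12), night = ZT in [12, 24),
    replicates of both days pooled.  The displayed MVA coordinates
    follow the day/night-average convention: per locus the day
    timepoint means are averaged, likewise the night timepoint means,
    M = night - day and A = their average; the t statistic itself uses
    all samples.
    """
    occ = _restrict(occ, condition)
    night = occ.night_mask()
    day_ids = list(occ.sample_ids[~night])
    night_ids = list(occ.sample_ids[night])
    res = moderated_group_test(
        occ, day_ids, night_ids, labels=("day", "night"),
        prior_df=prior_df, alpha=alpha,
    )
    tp = timepoint_means(occ)
    tp_zt = np.array([float(c[2:]) for c in tp.columns])
    mean_day = tp.loc[:, tp_zt < 12.0].mean(axis=1)
    mean_night = tp.loc[:, tp_zt >= 12.0].mean(axis=1)
    res.table["mean_a"] = mean_day
    res.table["mean_b"] = mean_night
    res.table["M"] = mean_night - mean_day
    res.table["A"] = (mean_day + mean_night) / 2.0
    res.meta["mva_convention"] = "timepoint averages"
    return res


def timepoint_pair_compare(
    occ: TimeCourse,
    zt_a: float = 2.0,
    zt_b: float = 10.0,
    condition: str | None = None,
    prior_df: float | None = None,
    alpha: float = 0.05,
) -> GroupCompareResult:
    """Moderated comparison of two ZT timepoints (e.g. ZT02 vs ZT10).

    Groups are all samples at each ZT (replicates x days); M = zt_b - zt_a.
    """
    occ = _restrict(occ, condition)
    times = occ.times
    ids_a = list(occ.sample_ids[times == float(zt_a)])
    ids_b = list(occ.sample_ids[times == float(zt_b)])
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise InsufficientDataError(
            f"need >= 2 samples at each of ZT{zt_a:g} ({len(ids_a)}) and "
            f"ZT{zt_b:g} ({len(ids_b)})"
        )
    return moderated_group_test(
        occ, ids_a, ids_b, labels=(f"ZT{zt_a:g}", f"ZT{zt_b:g}"),
        prior_df=prior_df, alpha=alpha,
    )


@dataclass
class CosineFitFraction:
    """Fraction of loci whose scores fit a 24-h cosine at p < threshold."""

    fraction: float
    rhythmic_loci: list
    n_loci: int
    p_threshold: float


def cosine_fit_fraction(
    occ: TimeCourse,
    p_threshold: float = 0.05,
    condition: str | None = None,
    period: float = 24.0,
) -> CosineFitFraction:
    """Fit every locus with the harmonic regression; report the rhythmic fraction."""
    occ = _restrict(occ, condition)
    if occ.n_features == 0:
        raise InsufficientDataError("empty occupancy table: fraction undefined")
    res = cosinor.fit_all(occ, period=period)
    calls = cosinor.call_rhythmic(res, p_threshold=p_threshold)
    return CosineFitFraction(
        len(calls.feature_ids) / occ.n_features,
        calls.feature_ids,
        occ.n_features,
        p_threshold,
    )
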