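"""24-h harmonic (cosinor) regression, rhythm calls and permutation FDR.

Each feature's time course is regressed on the design
``[1, cos(2*pi*t/T), sin(2*pi*t/T)]`` (T = 24 h by default) by ordinary
least squares:

    y = b0 + b1*cos(2*pi*t/T) + b2*sin(2*pi*t/T) + e

The fitted curve can be rewritten as ``b0 + A*cos(2*pi*(t - phi)/T)``
with amplitude ``A = sqrt(b1^2 + b2^2)`` (half the peak-to-trough
distance, log2 units) and acrophase ``phi = atan2(b2, b1) * T/(2*pi)``
mapped into [0, T) — the time of day at which the fitted curve peaks.
The two-argument arctangent resolves the quadrant ambiguity of the
naive ``atan(b1/b2)`` form and always returns the fitted maximum.

Rhythmicity is tested with the nested-model F statistic
``F = (SS_model/2) / (SS_resid/(n-3))`` against F(2, n-3); a feature is
called rhythmic when its p-value is strictly below the threshold
(1e-4 for expression arrays by convention here).  The false discovery
rate of a call set is estimated by permutation: the sample-to-ZT
assignment is reshuffled jointly for all features (preserving the
feature-feature correlation structure), all features are refit, and the
FDR is the mean permuted significant count divided by the observed
significant count, clipped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDesignError, InsufficientDataError
from .timecourse import TimeCourse

RESULT_COLUMNS = (
    "b0",
    "b1",
    "b2",
    "amplitude",
    "phase",
    "f_stat",
    "p_value",
    "residual_var",
    "ok",
)

#: Amplitudes below this are treated as zero and get a missing phase.
ZERO_AMPLITUDE_TOL = 1e-12


@dataclass
class RhythmCallSet:
    """Rhythmic features of one condition at a fixed p-value threshold."""

    condition: str | None
    p_threshold: float
    feature_ids: list
    n_tested: int
    fdr_estimate: float | None = None
    n_permutations: int | None = None
    permutation_seed: int | None = None

    @property
    def n_rhythmic(self) -> int:
        return len(self.feature_ids)


@dataclass
class FdrEstimate:
    """Permutation FDR of a rhythm call set."""

    fdr: float | None
    observed_count: int
    mean_permuted_count: float
    permuted_counts: np.ndarray = field(repr=False)
    n_permutations: int = 0
    seed: int | None = None
    p_threshold: float = 1e-4
    note: str = ""


def design_matrix(times: np.ndarray, period: float = 24.0) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    w = 2.0 * np.pi / period
    return np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])


def _check_design(times: np.ndarray, period: float) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 4:
        raise InsufficientDataError(
            f"cosinor fit needs >= 4 samples (3 parameters + 1 df), got {len(t)}"
        )
    X = design_matrix(t, period)
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateDesignError(
            "design matrix is rank deficient: need >= 3 distinct times mod period"
        )
    return X


def _amp_phase(b1: np.ndarray, b2: np.ndarray, period: float):
    amplitude = np.hypot(b1, b2)
    phase = (np.arctan2(b2, b1) * period / (2.0 * np.pi)) % period
    phase = np.where(phase >= period, 0.0, phase)  # fp: (-eps) % p can be p
    phase = np.where(amplitude <= ZERO_AMPLITUDE_TOL, np.nan, phase)
    return amplitude, phase


def _ols_stats(X: np.ndarray, Y: np.ndarray, period: float) -> pd.DataFrame:
    """Vectorised OLS of each row of Y on X; F against the intercept-only model."""
    n = X.shape[0]
    B, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # 3 x n_features
    fitted = X @ B
    resid = Y.T - fitted
    ss_resid = np.einsum("ij,ij->j", resid, resid)
    mean_y = Y.mean(axis=1)
    ss_model = np.einsum("ij,ij->j", fitted - mean_y[None, :], fitted - mean_y[None, :])
    # (numerically) constant features: no variation to model -> F = 0, p = 1
    scale = np.maximum(1.0, np.abs(Y).max(axis=1))
    const = ss_model + ss_resid <= n * (1e-10 * scale) ** 2
    B[1, const] = 0.0
    B[2, const] = 0.0
    df_resid = n - 3
    resid_var = ss_resid / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_model / 2.0) / resid_var
    f = np.where(const, 0.0, f)
    f = np.where(np.isfinite(f), f, np.inf)
    p = stats.f.sf(f, 2, df_resid)
    amplitude, phase = _amp_phase(B[1], B[2], period)
    return pd.DataFrame(
        {
            "b0": B[0],
            "b1": B[1],
            "b2": B[2],
            "amplitude": amplitude,
            "phase": phase,
            "f_stat": f,
            "p_value": p,
            "residual_var": resid_var,
            "ok": True,
        }
    )


def fit_cosinor(times, values, period: float = 24.0) -> pd.Series:
    """Fit one feature's samples; returns a Series with the result columns.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 samples.
    DegenerateDesignError
        Fewer than 3 distinct times mod period.
    """
    X = _check_design(times, period)
    y = np.asarray(values, dtype=float)
    if y.shape != (X.shape[0],):
        raise ConfigurationError(
            f"values length {y.shape} does not match {X.shape[0]} times"
        )
    if np.isnan(y).any():
        raise InsufficientDataError("values contain missing entries")
    row = _ols_stats(X, y[None, :], period).iloc[0]
    row.name = None
    return row


def fit_all(tc: TimeCourse, period: float = 24.0) -> pd.DataFrame:
    """Fit every feature of a time course.

    Features with missing values are flagged (``ok = False``) and carry
    NaN statistics rather than being silently dropped.  An empty matrix
    returns an empty result frame with a warning.
    """
    if tc.n_features == 0:
        warnings.warn("fit_all called on an empty matrix", stacklevel=2)
        return pd.DataFrame(columns=list(RESULT_COLUMNS))
    X = _check_design(tc.times, period)
    Y = tc.values.to_numpy(dtype=float)
    complete = ~np.isnan(Y).any(axis=1)
    out = pd.DataFrame(
        np.nan, index=tc.feature_ids, columns=list(RESULT_COLUMNS[:-1])
    )
    out["ok"] = False
    if complete.any():
        res = _ols_stats(X, Y[complete], period)
        res.index = tc.feature_ids[complete]
        out.loc[res.index, res.columns] = res
    out["ok"] = out["ok"].astype(bool)
    return out


def call_rhythmic(
    res: pd.DataFrame, p_threshold: float = 1e-4, condition: str | None = None
) -> RhythmCallSet:
    """Features with p-value strictly below the threshold."""
    if p_threshold <= 0:
        raise ConfigurationError(f"p_threshold must be positive, got {p_threshold}")
    if len(res) == 0:
        return RhythmCallSet(condition, p_threshold, [], 0)
    rhythmic = res.index[res["p_value"] < p_threshold].tolist()
    return RhythmCallSet(condition, p_threshold, rhythmic, int(res["ok"].sum()))


def estimate_fdr(
    tc: TimeCourse,
    p_threshold: float = 1e-4,
    n_perm: int = 1000,
    seed: int | None = None,
    period: float = 24.0,
) -> FdrEstimate:
    """Permutation estimate of the FDR of the rhythmic call set.

    Each permutation reshuffles the sample -> ZT assignment once for all
    features jointly (columns relabelled), refits every feature and
    counts significant calls; the estimate is the mean permuted count
    over the observed count, clipped to [0, 1].  Undefined (``None``)
    when nothing is called rhythmic on the observed labels.
    """
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
    res = fit_all(tc, period)
    observed = int((res["p_value"] < p_threshold).sum())

    rng = np.random.default_rng(seed)
    Y = tc.values.to_numpy(dtype=float)
    complete = ~np.isnan(Y).any(axis=1)
    Yc = Y[complete]
    times = tc.times
    counts = np.empty(n_perm)
    for b in range(n_perm):
        X = design_matrix(rng.permutation(times), period)
        counts[b] = int((_ols_stats(X, Yc, period)["p_value"] < p_threshold).sum())

    if observed == 0:
        return FdrEstimate(
            None, 0, float(counts.mean()), counts, n_perm, seed, p_threshold,
            note="no rhythmic calls on observed labels; FDR undefined",
        )
    fdr = float(np.clip(counts.mean() / observed, 0.0, 1.0))
    return FdrEstimate(fdr, observed, float(counts.mean()), counts, n_perm, seed, p_threshold)
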