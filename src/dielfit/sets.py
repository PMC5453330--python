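"""Rhythmic-set comparison utilities.

Amplitude filtering, Venn-style partition of rhythmic sets across
conditions, reverse-cumulative-frequency (RCF) curves of amplitudes,
hourly phase histograms, circular phase/amplitude shift summaries
between conditions, and row min-max normalisation of profile matrices.

Amplitudes are half peak-to-trough distances in log2 units, so an
amplitude A corresponds to a peak-to-trough fold change of 2**(2*A)
(e.g. the conventional cutoff A = 0.25 is a 1.4-fold change).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError

PERIOD_H = 24.0


def amplitude_to_fold_change(amplitude):
    """Peak-to-trough fold change implied by a log2 amplitude: 2**(2A)."""
    return 2.0 ** (2.0 * np.asarray(amplitude, dtype=float))


def fold_change_to_amplitude(fold_change):
    """Inverse of :func:`amplitude_to_fold_change`: A = log2(fc)/2."""
    return np.log2(np.asarray(fold_change, dtype=float)) / 2.0


def amplitude_filter(res: pd.DataFrame, min_amplitude: float = 0.25) -> pd.Index:
    """Feature ids surviving the amplitude cutoff.

    Features with amplitude strictly lower than ``min_amplitude`` are
    eliminated; equality is retained.
    """
    amp = res["amplitude"]
    return res.index[amp >= min_amplitude]


@dataclass
class SetPartition:
    """Disjoint Venn regions of 2-3 named feature-id sets.

    ``regions`` maps each non-empty membership pattern — a tuple of the
    set names a region belongs to — to its member ids; ``counts`` are
    the corresponding sizes.  Regions are pairwise disjoint and their
    sizes sum to the size of the union.
    """

    names: tuple[str, ...]
    regions: dict[tuple[str, ...], set]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


def partition_sets(sets: dict[str, set]) -> SetPartition:
    """Exact disjoint partition of 2-3 named sets into Venn regions."""
    names = tuple(sets)
    if not 2 <= len(names) <= 3:
        raise ConfigurationError(f"need 2 or 3 named sets, got {len(names)}")
    sets = {k: set(v) for k, v in sets.items()}
    regions: dict[tuple[str, ...], set] = {}
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            members = set.intersection(*(sets[c] for c in combo))
            for other in names:
                if other not in combo:
                    members -= sets[other]
            regions[combo] = members
    return SetPartition(names, regions)


@dataclass
class RcfCurve:
    """Reverse cumulative frequency of amplitudes over an evaluation grid.

    ``frequencies[i]`` is the fraction of values strictly greater than
    ``amplitudes[i]``; the curve is non-increasing and bounded in [0, 1].
    """

    amplitudes: np.ndarray
    frequencies: np.ndarray
    label: str | None = None
    n: int = 0


def rcf(values, grid=None, label: str | None = None) -> RcfCurve:
    """Reverse-cumulative-frequency curve: freq(a) = #{x > a} / n."""
    vals = np.sort(np.asarray(values, dtype=float))
    if len(vals) == 0:
        raise ConfigurationError("rcf needs at least one value")
    if grid is None:
        grid = np.linspace(0.0, vals[-1], 101)
    grid = np.asarray(grid, dtype=float)
    # #{x > a} via position of the first element strictly greater than a
    freq = (len(vals) - np.searchsorted(vals, grid, side="right")) / len(vals)
    return RcfCurve(grid, freq, label, len(vals))


def phase_histogram(phases, bin_width: float = 1.0) -> pd.Series:
    """Counts of phases in half-open ZT bins [k, k+bin_width).

    Phases must already lie in [0, 24); out-of-range values raise
    (normalise upstream with ``phase % 24``).
    """
    ph = np.asarray(phases, dtype=float)
    if len(ph) and ((ph < 0) | (ph >= PERIOD_H)).any():
        raise ConfigurationError("phases must lie in [0, 24); normalise with % 24")
    if bin_width <= 0 or PERIOD_H % bin_width:
        raise ConfigurationError(f"bin_width must evenly divide 24, got {bin_width}")
    edges = np.arange(0.0, PERIOD_H + bin_width, bin_width)
    counts, _ = np.histogram(ph, bins=edges)
    labels = [f"ZT{edges[i]:g}-{edges[i + 1]:g}" for i in range(len(counts))]
    return pd.Series(counts, index=labels, name="n_genes")


def wrap_phase_difference(delta_h):
    """Map an hour difference into the half-open interval (-12, 12]."""
    d = np.asarray(delta_h, dtype=float) % PERIOD_H
    return np.where(d > PERIOD_H / 2, d - PERIOD_H, d)


def circular_mean_hours(delta_h) -> float:
    """Circular mean of hour differences, reported in (-12, 12]."""
    ang = np.asarray(delta_h, dtype=float) * 2.0 * np.pi / PERIOD_H
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float(wrap_phase_difference(mean_ang * PERIOD_H / (2.0 * np.pi)))


@dataclass
class PhaseShiftSummary:
    """Per-feature phase/amplitude changes between two conditions.

    ``table`` has one row per comparable feature with the reference and
    alternative phases (hours), the wrapped difference alt - ref in
    (-12, 12], and both amplitudes.  ``mean_shift_h`` is the circular
    mean of the per-feature differences.  Features with an undefined
    phase (zero amplitude) in either condition are excluded and counted.
    """

    table: pd.DataFrame
    mean_shift_h: float
    n_excluded: int


def phase_shift(
    res_ref: pd.DataFrame, res_alt: pd.DataFrame, feature_ids=None
) -> PhaseShiftSummary:
    """Phase and amplitude shifts of features fitted in two conditions."""
    if feature_ids is None:
        feature_ids = res_ref.index.intersection(res_alt.index)
    feature_ids = pd.Index(feature_ids)
    ref = res_ref.loc[feature_ids]
    alt = res_alt.loc[feature_ids]
    defined = ref["phase"].notna() & alt["phase"].notna()
    n_excluded = int((~defined).sum())
    ref, alt = ref[defined], alt[defined]
    delta = wrap_phase_difference(alt["phase"].to_numpy() - ref["phase"].to_numpy())
    table = pd.DataFrame(
        {
            "phase_ref": ref["phase"],
            "phase_alt": alt["phase"],
            "phase_shift": delta,
            "amplitude_ref": ref["amplitude"],
            "amplitude_alt": alt["amplitude"],
        },
        index=ref.index,
    )
    mean_shift = circular_mean_hours(delta) if len(table) else float("nan")
    return PhaseShiftSummary(table, mean_shift, n_excluded)


def normalize_rows(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Min-max scale each row to [0, 1] across all columns.

    Intended for heatmap display of per-timepoint means concatenated
    across conditions (lowest value -> 0, highest -> 1).  Constant rows
    cannot be scaled; they map to 0.5 and are flagged.
    """
    mat = profiles.to_numpy(dtype=float)
    lo = mat.min(axis=1, keepdims=True)
    hi = mat.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0
    span[constant] = 1.0
    out = (mat - lo) / span
    out[constant] = 0.5
    return (
        pd.DataFrame(out, index=profiles.index, columns=profiles.columns),
        pd.Series(constant, index=profiles.index, name="constant"),
    )
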