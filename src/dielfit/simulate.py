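"""Synthetic diurnal time-course generator with known planted structure.

The generator emulates a liver diurnal study design: several mouse
cohorts (conditions), each sampled at six zeitgeber times (ZT02..ZT22)
over two consecutive days with a few replicates per time point.  Gene
expression is simulated on the log2 scale as a 24-h cosine

    y(t) = mesor + A * cos(2*pi*(t - phase)/24) + eps,   eps ~ N(0, sd^2)

with A = 0 for arrhythmic genes.  Occupancy tables (log2(IP/Input)
scores per locus) are simulated with additive night-feeding and
end-of-day anticipatory effects on a planted fraction of loci.  Every
generated dataset comes with a ground-truth table so downstream stages
can be verified by parameter recovery.

Day-2 samples at a given ZT are treated as replicates of day-1 samples
at the same ZT (the signal depends on ZT mod 24 only); day/night is
split at ZT12 (lights-on at ZT0, food available at night).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .timecourse import OccupancyTable, TimeCourse

DEFAULT_TIMEPOINTS_H = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)
PERIOD_H = 24.0


@dataclass(frozen=True)
class ConditionSpec:
    """Planted rhythm structure for one condition (cohort).

    The first condition in a :class:`SimulationConfig` is the reference;
    genes rhythmic in a non-reference condition that are also rhythmic
    in the reference reuse the reference gene's amplitude and phase,
    scaled by ``amplitude_damping`` and shifted by ``phase_shift_h``
    (this encodes amplitude-loss / phase-advance scenarios such as a
    clock knockout or an around-the-clock feeding regimen).  Genes
    rhythmic only in this condition draw fresh parameters from this
    condition's own ranges.

    Parameters
    ----------
    name
        Condition label (e.g. ``"control"``, ``"CF"``, ``"clock_ko"``).
    rhythmic_fraction
        Fraction of features carrying a planted cosine in this condition.
    amplitude_range
        Uniform range (log2 units) for planted amplitudes.
    phase_distribution
        Discrete distribution of peak times: list of ``(phase_h, weight)``.
    mesor_range
        Uniform range (log2 units) of baseline expression.
    amplitude_damping
        Multiplier applied to reference amplitudes (>= 0).
    phase_shift_h
        Hours added to reference phases (mod 24).
    """

    name: str
    rhythmic_fraction: float = 0.0
    amplitude_range: tuple[float, float] = (0.5, 1.0)
    phase_distribution: Sequence[tuple[float, float]] = ((0.0, 1.0),)
    mesor_range: tuple[float, float] = (6.0, 10.0)
    amplitude_damping: float = 1.0
    phase_shift_h: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rhythmic_fraction <= 1.0:
            raise ConfigurationError(
                f"rhythmic_fraction must be in [0, 1], got {self.rhythmic_fraction}"
            )
        if self.amplitude_damping < 0:
            raise ConfigurationError(
                f"amplitude_damping must be >= 0, got {self.amplitude_damping}"
            )
        for rng_name in ("amplitude_range", "mesor_range"):
            lo, hi = getattr(self, rng_name)
            if hi < lo:
                raise ConfigurationError(f"{rng_name} has max < min: ({lo}, {hi})")
        if self.amplitude_range[0] < 0:
            raise ConfigurationError("amplitude_range must be non-negative")
        weights = np.array([w for _, w in self.phase_distribution], dtype=float)
        if len(weights) == 0 or (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
            raise ConfigurationError(
                "phase_distribution weights must be non-negative and sum to 1"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Expression-simulation design: features, conditions, sampling grid."""

    n_features: int
    conditions: Sequence[ConditionSpec]
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS_H
    n_days: int = 2
    replicates_per_timepoint: int = 3  # per day; 3 -> 36 samples/condition
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 0:
            raise ConfigurationError(f"n_features must be >= 0, got {self.n_features}")
        if len(self.conditions) == 0:
            raise ConfigurationError("at least one condition is required")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate condition names: {names}")
        tp = np.asarray(self.timepoints_h, dtype=float)
        if len(tp) == 0 or (np.diff(tp) <= 0).any() or tp[0] < 0 or tp[-1] >= PERIOD_H:
            raise ConfigurationError(
                "timepoints_h must be strictly increasing within [0, 24)"
            )
        if self.n_days < 0 or self.replicates_per_timepoint < 0:
            raise ConfigurationError("n_days and replicates_per_timepoint must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def samples_per_condition(self) -> int:
        return len(self.timepoints_h) * self.n_days * self.replicates_per_timepoint


@dataclass(frozen=True)
class OccupancySimSpec:
    """Planted day/night structure for one occupancy (ChIP score) table.

    ``night_effect`` is added to night samples (ZT >= 12) of affected
    loci, emulating a feeding response; ``anticipation_effect`` is added
    at the last daytime timepoint (ZT10 in the canonical design) when
    ``clock_on`` is true, emulating clock-driven anticipation of the
    feeding period; ``condition_offset`` shifts every score, emulating a
    global de-repression (e.g. loss of a repressor).
    """

    n_loci: int
    base_mean: float = 0.0
    night_effect: float = 0.0
    anticipation_effect: float = 0.0
    clock_on: bool = True
    condition_offset: float = 0.0
    affected_fraction: float = 0.0
    noise_sd: float = 0.2
    seed: int = 0
    name: str = "occupancy"

    def __post_init__(self) -> None:
        if self.n_loci < 0:
            raise ConfigurationError(f"n_loci must be >= 0, got {self.n_loci}")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ConfigurationError(
                f"affected_fraction must be in [0, 1], got {self.affected_fraction}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _sample_sheet(config: SimulationConfig, condition: str) -> pd.DataFrame:
    rows = []
    for day in range(1, config.n_days + 1):
        for zt in config.timepoints_h:
            for rep in range(1, config.replicates_per_timepoint + 1):
                sid = f"{condition}_d{day}_zt{zt:g}_r{rep}"
                rows.append((sid, condition, float(zt), day, rep))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "zt_time", "day", "replicate"]
    ).set_index("sample_id")


def _draw_phase(rng: np.random.Generator, dist, size: int) -> np.ndarray:
    phases = np.array([p for p, _ in dist], dtype=float) % PERIOD_H
    weights = np.array([w for _, w in dist], dtype=float)
    return rng.choice(phases, size=size, p=weights / weights.sum())


def _feature_noise(seed: int, n_features: int, n_samples: int, sd: float) -> np.ndarray:
    """Per-feature deterministic noise sub-streams derived from one seed."""
    if n_features == 0 or n_samples == 0:
        return np.zeros((n_features, n_samples))
    streams = np.random.SeedSequence(seed).spawn(n_features)
    out = np.empty((n_features, n_samples))
    for i, ss in enumerate(streams):
        out[i] = np.random.default_rng(ss).normal(0.0, sd, size=n_samples) if sd > 0 else 0.0
    return out


def generate_expression(config: SimulationConfig) -> tuple[TimeCourse, pd.DataFrame]:
    """Simulate a multi-condition expression time course.

    Returns
    -------
    tc : TimeCourse
        log2 expression matrix (features x all conditions' samples) with
        sample sheet.
    truth : DataFrame
        One row per (feature, condition) with columns ``feature_id``,
        ``condition``, ``rhythmic``, ``mesor``, ``amplitude``, ``phase``.
        Arrhythmic rows carry amplitude 0 and missing phase.
    """
    n = config.n_features
    feature_ids = [f"g{i:05d}" for i in range(n)]
    param_ss, noise_ss = np.random.SeedSequence(config.seed).spawn(2)
    param_rng = np.random.default_rng(param_ss)

    ref = config.conditions[0]
    mesor = param_rng.uniform(*ref.mesor_range, size=n)
    base_amp = param_rng.uniform(*ref.amplitude_range, size=n)
    base_phase = _draw_phase(param_rng, ref.phase_distribution, n)

    sheets, blocks, truth_rows = [], [], []
    n_ref_rhythmic = round(n * ref.rhythmic_fraction)
    for ci, cond in enumerate(config.conditions):
        sheet = _sample_sheet(config, cond.name)
        zt = sheet["zt_time"].to_numpy()
        k = round(n * cond.rhythmic_fraction)
        amp = np.zeros(n)
        phase = np.full(n, np.nan)
        if cond is ref:
            amp[:k] = base_amp[:k]
            phase[:k] = base_phase[:k]
        else:
            shared = min(k, n_ref_rhythmic)
            amp[:shared] = cond.amplitude_damping * base_amp[:shared]
            phase[:shared] = (base_phase[:shared] + cond.phase_shift_h) % PERIOD_H
            if k > shared:  # rhythmic only here: fresh draws from own ranges
                extra = k - shared
                amp[shared:k] = param_rng.uniform(*cond.amplitude_range, size=extra)
                phase[shared:k] = _draw_phase(param_rng, cond.phase_distribution, extra)
        signal = mesor[:, None] + np.where(
            np.isnan(phase[:, None]),
            0.0,
            amp[:, None] * np.cos(2 * np.pi * (zt[None, :] - phase[:, None]) / PERIOD_H),
        )
        # independent noise per condition, per-feature sub-streams
        cond_seed = int(noise_ss.generate_state(len(config.conditions))[ci])
        signal = signal + _feature_noise(cond_seed, n, len(zt), config.noise_sd)
        blocks.append(pd.DataFrame(signal, index=feature_ids, columns=sheet.index))
        sheets.append(sheet)
        truth_rows.append(
            pd.DataFrame(
                {
                    "feature_id": feature_ids,
                    "condition": cond.name,
                    "rhythmic": np.arange(n) < k,
                    "mesor": mesor,
                    "amplitude": amp,
                    "phase": phase,
                }
            )
        )

    values = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=feature_ids)
    samples = pd.concat(sheets, axis=0)
    truth = pd.concat(truth_rows, ignore_index=True) if truth_rows else pd.DataFrame(
        columns=["feature_id", "condition", "rhythmic", "mesor", "amplitude", "phase"]
    )
    return TimeCourse(values, samples), truth


def last_day_timepoint(timepoints_h: Sequence[float]) -> float:
    """Last lights-on (ZT < 12) timepoint of the design — ZT10 canonically."""
    day_tp = [t for t in timepoints_h if t < 12.0]
    if not day_tp:
        raise ConfigurationError("design has no daytime (ZT < 12) timepoint")
    return float(max(day_tp))


def generate_occupancy(
    spec: OccupancySimSpec, config: SimulationConfig
) -> tuple[OccupancyTable, pd.DataFrame]:
    """Simulate one condition's locus-occupancy table.

    Scores follow ``base_mean + condition_offset`` plus, for the planted
    affected loci, ``night_effect`` at night timepoints and
    ``anticipation_effect`` at the last daytime timepoint when the clock
    is on, plus Gaussian noise.

    Returns the table and a truth table (locus_id, affected, planted
    night and anticipation effects).
    """
    locus_ids = [f"locus{i:05d}" for i in range(spec.n_loci)]
    sheet = _sample_sheet(config, spec.name)
    zt = sheet["zt_time"].to_numpy()
    night = (zt >= 12.0).astype(float)
    anticipation_tp = last_day_timepoint(config.timepoints_h)
    at_anticipation = (zt == anticipation_tp).astype(float)

    n_affected = round(spec.n_loci * spec.affected_fraction)
    affected = np.arange(spec.n_loci) < n_affected

    scores = np.full((spec.n_loci, len(zt)), spec.base_mean + spec.condition_offset)
    scores += spec.night_effect * affected[:, None] * night[None, :]
    if spec.clock_on:
        scores += spec.anticipation_effect * affected[:, None] * at_anticipation[None, :]
    scores += _feature_noise(spec.seed, spec.n_loci, len(zt), spec.noise_sd)

    table = OccupancyTable(
        pd.DataFrame(scores, index=locus_ids, columns=sheet.index), sheet
    )
    truth = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "affected": affected,
            "night_effect": np.where(affected, spec.night_effect, 0.0),
            "anticipation_effect": np.where(
                affected & spec.clock_on, spec.anticipation_effect, 0.0
            ),
        }
    )
    return table, truth
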