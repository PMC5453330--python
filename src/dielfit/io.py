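"""TSV input/output, run configuration and the end-to-end pipeline.

Interchange format: tab-separated text with a header row and '.'
decimals (gzip accepted transparently via pandas).  Matrices have the
feature id in the first column and one column per sample; sample sheets
have columns ``sample_id, condition, zt_time, day, replicate`` (plus an
optional ``occupied`` flag column for occupancy loci in the matrix
file).  ZT times may be decimal hours or labels like ``ZT02``.  Missing
values are encoded as ``NA``; features with any missing sample are
flagged and excluded from fitting, with the count logged.

Every output table starts with ``# key: value`` metadata lines
(package version, seed, thresholds) that readers skip.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cluster, cosinor, occupancy, sets
from .errors import ConfigurationError, MatrixFormatError, SampleSheetError
from .timecourse import SAMPLE_COLUMNS, OccupancyTable, TimeCourse

log = logging.getLogger("dielfit")


def parse_zt(value) -> float:
    """Parse a ZT time given as decimal hours or a label like 'ZT02'."""
    if isinstance(value, str) and value.upper().startswith("ZT"):
        value = value[2:]
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise SampleSheetError(f"cannot parse ZT time {value!r}") from exc


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in ("sample_id",) + SAMPLE_COLUMNS if c not in sheet.columns]
    if missing:
        raise SampleSheetError(f"sample sheet {path} lacks columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise SampleSheetError(f"duplicated sample ids in sheet: {dupes}")
    sheet["zt_time"] = sheet["zt_time"].map(parse_zt)
    return sheet.set_index("sample_id")


def read_matrix(path, samples_path, occupancy_table: bool = False) -> TimeCourse:
    """Read a matrix TSV plus sample sheet into a validated TimeCourse.

    The matrix's first column holds feature ids; an optional boolean
    ``occupied`` column is consumed as the locus pre-selection flag when
    ``occupancy_table`` is requested.
    """
    try:
        mat = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    except pd.errors.EmptyDataError as exc:
        raise MatrixFormatError(f"matrix file {path} is empty") from exc
    if mat.shape[1] == 0:
        raise MatrixFormatError(f"matrix file {path} has no sample columns")
    if mat.index.duplicated().any():
        dupes = mat.index[mat.index.duplicated()].tolist()
        raise MatrixFormatError(f"duplicated feature ids: {dupes}")
    occupied = None
    if "occupied" in mat.columns:
        occupied = mat.pop("occupied").astype(bool)
    for col in mat.columns:
        if not pd.api.types.is_numeric_dtype(mat[col]):
            bad = mat.index[pd.to_numeric(mat[col], errors="coerce").isna()
                            & mat[col].notna()][:5].tolist()
            raise MatrixFormatError(
                f"non-numeric values in column {col!r} (e.g. rows {bad})"
            )
    sheet = read_sample_sheet(samples_path)
    unknown = [s for s in mat.columns if s not in sheet.index]
    if unknown:
        raise SampleSheetError(f"matrix samples missing from sheet: {unknown}")
    if occupancy_table or occupied is not None:
        return OccupancyTable(mat, sheet, occupied)
    return TimeCourse(mat, sheet)


def _metadata_header(meta: dict) -> str:
    lines = [f"# dielfit_version: {__version__}"]
    lines += [f"# {k}: {v}" for k, v in meta.items()]
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, meta: dict | None = None, index: bool = True):
    """Write a TSV with '# key: value' metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_metadata_header(meta or {}))
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def write_timecourse(tc: TimeCourse, matrix_path, samples_path, meta=None):
    values = tc.values
    if isinstance(tc, OccupancyTable):
        values = values.copy()
        values["occupied"] = tc.occupied
    write_table(values.rename_axis("feature_id"), matrix_path, meta)
    write_table(tc.samples.rename_axis("sample_id"), samples_path, meta)


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (defaults match the field's
    conventional thresholds: p < 1e-4 for array rhythmicity, p < 0.05
    for occupancy comparisons, amplitude cutoff 0.25 log2 units)."""

    matrix: str
    samples: str
    out_dir: str
    mode: str = "expression"  # or "occupancy"
    period: float = 24.0
    p_threshold: float = 1e-4
    occupancy_p_threshold: float = 0.05
    min_amplitude: float = 0.25
    n_permutations: int = 1000
    k_min: int = 2
    k_max: int = 10
    metric: str = "euclidean"
    zt_pair: tuple[float, float] = (2.0, 10.0)
    reference_condition: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("expression", "occupancy"):
            raise ConfigurationError(f"mode must be expression|occupancy: {self.mode}")
        for name in ("period", "p_threshold", "occupancy_p_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.min_amplitude < 0 or self.n_permutations < 0:
            raise ConfigurationError("min_amplitude and n_permutations must be >= 0")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if "zt_pair" in data:
            data["zt_pair"] = tuple(data["zt_pair"])
        return cls(**data)

    def meta(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: d[k] for k in ("mode", "period", "p_threshold", "min_amplitude",
                                  "n_permutations", "seed")}


def _expression_pipeline(cfg: RunConfig, tc: TimeCourse, out: Path) -> dict:
    meta = cfg.meta()
    counts: dict = {}
    fits, callsets, filtered = {}, {}, {}
    for cond in tc.conditions:
        sub = tc.subset_condition(cond)
        res = cosinor.fit_all(sub, period=cfg.period)
        fits[cond] = res
        write_table(res.rename_axis("feature_id"), out / f"cosinor_{cond}.tsv", meta)
        calls = cosinor.call_rhythmic(res, cfg.p_threshold, condition=cond)
        callsets[cond] = calls
        counts[f"n_rhythmic_{cond}"] = calls.n_rhythmic
        if cfg.n_permutations > 0:
            fdr = cosinor.estimate_fdr(
                sub, cfg.p_threshold, n_perm=cfg.n_permutations, seed=cfg.seed,
                period=cfg.period,
            )
            counts[f"fdr_{cond}"] = fdr.fdr
            write_table(
                pd.DataFrame(
                    [{"condition": cond, "fdr": fdr.fdr,
                      "observed": fdr.observed_count,
                      "mean_permuted": fdr.mean_permuted_count,
                      "n_permutations": fdr.n_permutations,
                      "note": fdr.note}]
                ),
                out / f"fdr_{cond}.tsv", meta, index=False,
            )
        rhythmic_res = res.loc[calls.feature_ids]
        kept = sets.amplitude_filter(rhythmic_res, cfg.min_amplitude)
        filtered[cond] = kept
        counts[f"n_amplitude_filtered_{cond}"] = len(kept)
        hist = sets.phase_histogram(rhythmic_res.loc[kept, "phase"].dropna() % 24.0)
        write_table(hist.to_frame(), out / f"phase_histogram_{cond}.tsv", meta)
        curve = sets.rcf(rhythmic_res["amplitude"].dropna(), label=cond) \
            if calls.n_rhythmic else None
        if curve is not None:
            write_table(
                pd.DataFrame({"amplitude": curve.amplitudes,
                              "frequency": curve.frequencies}),
                out / f"rcf_{cond}.tsv", meta, index=False,
            )

    if 2 <= len(callsets) <= 3:
        part = sets.partition_sets({c: set(s.feature_ids) for c, s in callsets.items()})
        rows = [{"region": "&".join(k), "count": len(v),
                 "members": ";".join(map(str, sorted(v)))}
                for k, v in part.regions.items()]
        write_table(pd.DataFrame(rows), out / "set_partition.tsv", meta, index=False)
        counts["n_union_rhythmic"] = part.union_size

    ref = cfg.reference_condition or tc.conditions[0]
    ref_kept = filtered[ref]
    if len(ref_kept) >= 3:
        profiles, _ = cluster.profile_matrix(tc, feature_ids=ref_kept, condition=ref)
        try:
            model = cluster.select_k(
                profiles, k_range=range(cfg.k_min, cfg.k_max + 1), metric=cfg.metric
            )
        except ConfigurationError:
            model = None
        if model is not None:
            write_table(model.assignments(), out / "clusters.tsv", meta)
            write_table(
                pd.DataFrame({"k": list(model.silhouette_by_k),
                              "mean_silhouette": list(model.silhouette_by_k.values())}),
                out / "silhouette_by_k.tsv", meta, index=False,
            )
            counts["selected_k"] = model.k
            order = np.argsort(model.labels, kind="stable")
            ordered_ids = [model.feature_ids[i] for i in order]
            for cond in tc.conditions:
                prof, _ = cluster.profile_matrix(
                    tc, feature_ids=ordered_ids, condition=cond, standardize=False
                )
                normed, _ = sets.normalize_rows(prof)
                write_table(normed.rename_axis("feature_id"),
                            out / f"heatmap_{cond}.tsv", meta)
    return counts


def _occupancy_pipeline(cfg: RunConfig, occ: TimeCourse, out: Path) -> dict:
    meta = cfg.meta()
    counts: dict = {}
    means = occupancy.condition_mean(occ)
    write_table(means.rename_axis("locus_id"), out / "condition_means.tsv", meta)
    write_table(occupancy.condition_summary(means).rename_axis("condition"),
                out / "condition_summary.tsv", meta)
    for cond in occ.conditions:
        write_table(
            occupancy.timepoint_means(occ, condition=cond).rename_axis("locus_id"),
            out / f"timepoint_means_{cond}.tsv", meta,
        )
        dn = occupancy.day_night_compare(occ, condition=cond,
                                         alpha=cfg.occupancy_p_threshold)
        write_table(dn.table.rename_axis("locus_id"),
                    out / f"daynight_{cond}.tsv", meta)
        counts[f"n_daynight_significant_{cond}"] = dn.n_significant
        counts[f"mean_daynight_M_{cond}"] = float(dn.table["M"].mean())
        zp = occupancy.timepoint_pair_compare(
            occ, *cfg.zt_pair, condition=cond, alpha=cfg.occupancy_p_threshold
        )
        write_table(zp.table.rename_axis("locus_id"),
                    out / f"ztpair_{cond}.tsv", meta)
        counts[f"n_ztpair_significant_{cond}"] = zp.n_significant
        counts[f"mean_ztpair_M_{cond}"] = float(zp.table["M"].mean())
        frac = occupancy.cosine_fit_fraction(
            occ, p_threshold=cfg.occupancy_p_threshold, condition=cond,
            period=cfg.period,
        )
        counts[f"cosine_fit_fraction_{cond}"] = frac.fraction
    write_table(
        pd.Series(counts, name="value").rename_axis("quantity").to_frame(),
        out / "occupancy_counts.tsv", meta,
    )
    return counts


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full workflow for one input matrix; returns per-stage counts.

    Expression mode: per-condition cosinor fit -> rhythm calls ->
    permutation FDR -> amplitude filter -> set partition / RCF / phase
    histograms -> PAM clustering of the reference condition.  Occupancy
    mode: condition and timepoint summaries -> day/night and
    ZT-pair moderated comparisons -> cosine-fit fraction.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tc = read_matrix(cfg.matrix, cfg.samples, occupancy_table=cfg.mode == "occupancy")
    n_missing = int(tc.values.isna().any(axis=1).sum())
    if n_missing:
        log.info("%d features with missing values excluded from fitting", n_missing)
    log.info("loaded %d features x %d samples (%s mode)",
             tc.n_features, tc.n_samples, cfg.mode)
    try:
        if cfg.mode == "expression":
            counts = _expression_pipeline(cfg, tc, out)
        else:
            counts = _occupancy_pipeline(cfg, tc, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in {cfg.mode} stage: {exc}") from exc
    for k, v in counts.items():
        log.info("%s = %s", k, v)
    write_table(
        pd.Series(counts, name="value").rename_axis("quantity").to_frame(),
        out / "run_summary.tsv", cfg.meta(),
    )
    return counts
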