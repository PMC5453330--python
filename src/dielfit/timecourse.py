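"""In-memory containers for time-course matrices.

A :class:`TimeCourse` pairs a feature-by-sample numeric matrix (log2
units) with a per-sample metadata table giving the experimental
condition, zeitgeber time (ZT, hours after lights-on), day index and
replicate id.  An :class:`OccupancyTable` is the same structure for
locus occupancy scores (log2(IP/Input)) with an additional per-locus
"occupied in at least one sample" flag used to restrict analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SampleSheetError

#: Metadata columns every sample sheet must provide.
SAMPLE_COLUMNS = ("condition", "zt_time", "day", "replicate")

#: ZT hours in [0, 12) are lights-on ("day"); [12, 24) lights-off ("night").
DAY_NIGHT_BOUNDARY_H = 12.0


def is_night(zt_time) -> np.ndarray | bool:
    """True for ZT times in the dark (night) phase [12, 24)."""
    return np.asarray(zt_time, dtype=float) >= DAY_NIGHT_BOUNDARY_H


@dataclass
class TimeCourse:
    """Feature x sample matrix plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``condition``,
        ``zt_time`` (hours in [0, 24)), ``day`` and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.samples = pd.DataFrame(self.samples)
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise SampleSheetError(f"duplicated sample ids: {sorted(set(dupes))}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()]
            raise SampleSheetError(f"duplicated feature ids: {sorted(set(dupes))}")
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise SampleSheetError(f"sample sheet lacks columns: {missing_cols}")
        unknown = [s for s in self.values.columns if s not in self.samples.index]
        if unknown:
            raise SampleSheetError(f"samples missing from sample sheet: {unknown}")
        zt = self.samples["zt_time"].astype(float)
        if ((zt < 0) | (zt >= 24)).any():
            bad = self.samples.index[(zt < 0) | (zt >= 24)].tolist()
            raise SampleSheetError(f"zt_time outside [0, 24) for samples: {bad}")
        # keep metadata in matrix column order, restricted to present samples
        self.samples = self.samples.loc[self.values.columns].copy()
        self.samples["zt_time"] = self.samples["zt_time"].astype(float)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """ZT time (hours) per sample, in matrix column order."""
        return self.samples["zt_time"].to_numpy(dtype=float)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        return list(dict.fromkeys(self.samples["condition"]))

    def subset_condition(self, condition: str) -> "TimeCourse":
        """Restrict to the samples of one condition."""
        keep = self.samples.index[self.samples["condition"] == condition]
        if len(keep) == 0:
            raise SampleSheetError(f"no samples with condition {condition!r}")
        return self.__class__(self.values[keep], self.samples.loc[keep])

    def subset_features(self, feature_ids) -> "TimeCourse":
        return self.__class__(self.values.loc[list(feature_ids)], self.samples)

    def night_mask(self) -> np.ndarray:
        """Boolean mask per sample: True for night (ZT >= 12)."""
        return is_night(self.times)


@dataclass
class OccupancyTable(TimeCourse):
    """Locus x sample occupancy scores with an "occupied" pre-selection flag.

    The flag is an input (computed upstream from peak calling); analyses
    restrict themselves to flagged loci.  By default all loci are flagged.
    """

    occupied: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.occupied is None:
            self.occupied = pd.Series(True, index=self.values.index)
        else:
            occ = pd.Series(self.occupied)
            if isinstance(occ.index, pd.RangeIndex) and len(occ) == self.n_features:
                occ.index = self.values.index  # positional array-like
            self.occupied = occ.reindex(self.values.index)
            if self.occupied.isna().any():
                bad = self.occupied.index[self.occupied.isna()].tolist()
                raise SampleSheetError(f"occupied flag missing for loci: {bad}")
            self.occupied = self.occupied.astype(bool)

    def subset_condition(self, condition: str) -> "OccupancyTable":
        keep = self.samples.index[self.samples["condition"] == condition]
        if len(keep) == 0:
            raise SampleSheetError(f"no samples with condition {condition!r}")
        return OccupancyTable(self.values[keep], self.samples.loc[keep], self.occupied)

    def flagged(self) -> "OccupancyTable":
        """Restrict to loci occupied in at least one sample."""
        keep = self.occupied.index[self.occupied]
        return OccupancyTable(self.values.loc[keep], self.samples, self.occupied.loc[keep])
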