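"""Sample x feature intensity table with injection-order and group metadata.

The table is the central data structure of the preprocessing chain: rows are
injections (study samples plus pooled-QC injections), columns are identified
metabolite features. Pooled-QC rows are flagged by the group label ``"QC"``
and anchor both drift correction and the RSD stability filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

QC_GROUP = "QC"

#: leading metadata columns of the on-disk CSV layout
META_COLUMNS = ["sample_id", "group", "injection_order"]


@dataclass
class FeatureTable:
    """Intensity matrix plus per-sample metadata.

    Parameters
    ----------
    samples:
        DataFrame indexed by ``sample_id`` with columns ``group`` and
        ``injection_order``.
    values:
        DataFrame indexed by ``sample_id`` (same order as ``samples``) with
        one non-negative intensity column per feature.
    transformed:
        True once values have left the raw intensity scale (log2 or
        autoscaled); lifts the non-negativity invariant.
    """

    samples: pd.DataFrame
    values: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        if not self.samples.index.equals(self.values.index):
            raise InvalidInputError("samples and values must share the same sample_id index")
        if self.samples.index.has_duplicates:
            raise InvalidInputError("sample_ids must be unique")
        orders = self.samples["injection_order"]
        if orders.duplicated().any():
            raise InvalidInputError("injection_orders must be unique")
        if (orders <= 0).any():
            raise InvalidInputError("injection_orders must be positive")
        if not self.transformed and (self.values.to_numpy() < 0).any():
            raise InvalidInputError("negative intensities are not allowed")

    # -- accessors ---------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def qc_mask(self) -> np.ndarray:
        return (self.samples["group"] == QC_GROUP).to_numpy()

    @property
    def n_qc(self) -> int:
        return int(self.qc_mask.sum())

    def groups(self, include_qc: bool = False) -> list[str]:
        """Distinct group labels in first-appearance order."""
        labels = self.samples["group"].tolist()
        out: list[str] = []
        for g in labels:
            if g not in out and (include_qc or g != QC_GROUP):
                out.append(g)
        return out

    def group_values(self, group: str) -> pd.DataFrame:
        """Intensity sub-matrix of one group's samples."""
        mask = self.samples["group"] == group
        if not mask.any():
            raise InvalidInputError(f"group {group!r} not present in table")
        return self.values.loc[mask.to_numpy()]

    def qc_values(self) -> pd.DataFrame:
        return self.values.loc[self.qc_mask]

    # -- construction / copies --------------------------------------------

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.samples.copy(), self.values.copy(), self.transformed)

    def with_values(self, values: pd.DataFrame, transformed: bool | None = None) -> "FeatureTable":
        """Same metadata, new intensity matrix (feature subset allowed)."""
        if transformed is None:
            transformed = self.transformed
        return FeatureTable(self.samples.copy(), values, transformed)

    def drop_features(self, feature_ids) -> "FeatureTable":
        return self.with_values(self.values.drop(columns=list(feature_ids)))

    def without_qc(self) -> "FeatureTable":
        keep = ~self.qc_mask
        return FeatureTable(self.samples.loc[keep].copy(), self.values.loc[keep].copy(), self.transformed)

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV layout: sample_id, group, injection_order, features..."""
        return pd.concat([self.samples.reset_index(), self.values.reset_index(drop=True)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        missing = [c for c in META_COLUMNS if c not in frame.columns]
        if missing:
            raise InvalidInputError(f"missing metadata columns: {missing}")
        samples = frame[META_COLUMNS].set_index("sample_id")
        values = frame.drop(columns=META_COLUMNS[1:]).set_index("sample_id")
        return cls(samples, values.astype(float))

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))
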