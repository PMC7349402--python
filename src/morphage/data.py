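"""In-memory containers and plain-text I/O for morphometry tables."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import FeatureSchema

SUBJECT_COLUMNS = ("age", "group", "site", "icv")


@dataclass
class MorphometryDataset:
    """A subject x feature value matrix with per-subject metadata.

    ``subjects`` is indexed by ``subject_id`` with columns ``age`` (years),
    ``group`` (NC/ASD), ``site`` (integer site index) and ``icv``
    (intracranial volume). ``values`` shares the subject index and has one
    column per feature in ``schema``, in schema order.
    """

    subjects: pd.DataFrame = field(repr=False)
    values: pd.DataFrame = field(repr=False)
    schema: FeatureSchema = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(SUBJECT_COLUMNS) - set(self.subjects.columns)
        if missing:
            raise ValueError(f"subject table missing columns: {sorted(missing)}")
        if not self.subjects.index.equals(self.values.index):
            raise ValueError("subjects and values must share the subject index")
        if list(self.values.columns) != self.schema.feature_ids:
            raise ValueError("values columns must match schema feature ids")
        if self.values.isna().any().any():
            raise ValueError("values contain missing entries")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def ages(self) -> np.ndarray:
        return self.subjects["age"].to_numpy(float)

    @property
    def sites(self) -> np.ndarray:
        return self.subjects["site"].to_numpy(int)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(float)

    def with_values(self, values: np.ndarray | pd.DataFrame) -> "MorphometryDataset":
        """Return a copy carrying new feature values (same subjects/schema)."""
        if isinstance(values, np.ndarray):
            values = pd.DataFrame(values, index=self.values.index,
                                  columns=self.values.columns)
        return replace(self, values=values)

    def select_group(self, group: str) -> "MorphometryDataset":
        mask = self.subjects["group"] == group
        if not mask.any():
            raise ValueError(f"no subjects in group {group!r}")
        return MorphometryDataset(self.subjects.loc[mask].copy(),
                                  self.values.loc[mask].copy(), self.schema)


def write_dataset(dataset: MorphometryDataset, path: str | Path) -> None:
    """Write the wide CSV dialect: metadata columns then one per feature."""
    wide = pd.concat([dataset.subjects[list(SUBJECT_COLUMNS)], dataset.values],
                     axis=1)
    wide.index.name = "subject_id"
    wide.to_csv(path)


def read_dataset(path: str | Path, schema: FeatureSchema) -> MorphometryDataset:
    wide = pd.read_csv(path, index_col="subject_id")
    subjects = wide[list(SUBJECT_COLUMNS)].copy()
    subjects["site"] = subjects["site"].astype(int)
    values = wide[schema.feature_ids].astype(float)
    return MorphometryDataset(subjects, values, schema)
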