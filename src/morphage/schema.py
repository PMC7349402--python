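"""Feature schema for FreeSurfer-style morphometric tables.

The default layout mirrors a standard whole-brain FreeSurfer extraction:
global summary measures, Desikan-Killiany cortical parcels (8 metrics x
68 regions), Aseg sub-cortical structures (6 metrics x 40 structures) and
white-matter parcels (6 metrics x 68 regions), 1213 features in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CATEGORIES = ("global", "cortical", "sub-cortical", "WM")

#: Desikan-Killiany cortical parcellation, 34 regions per hemisphere.
DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

#: Aseg structures segmented per hemisphere (28 features as Left-/Right-).
ASEG_BILATERAL = (
    "Lateral-Ventricle", "Inf-Lat-Vent", "Cerebellum-White-Matter",
    "Cerebellum-Cortex", "Thalamus-Proper", "Caudate", "Putamen",
    "Pallidum", "Hippocampus", "Amygdala", "Accumbens-area", "VentralDC",
    "vessel", "choroid-plexus",
)

#: Midline / unpaired Aseg structures.
ASEG_MIDLINE = (
    "3rd-Ventricle", "4th-Ventricle", "5th-Ventricle", "Brain-Stem", "CSF",
    "Optic-Chiasm", "CC_Posterior", "CC_Mid_Posterior", "CC_Central",
    "CC_Mid_Anterior", "CC_Anterior", "WM-hypointensities",
)

CORTICAL_METRICS = (
    "volume", "surface-area", "gaussian-curvature", "mean-curvature",
    "curvature-index", "folding-index", "thickness-mean", "thickness-std",
)

INTENSITY_METRICS = (
    "volume", "intensity-mean", "intensity-std", "intensity-min",
    "intensity-max", "intensity-range",
)

GLOBAL_MEASURES = (
    "BrainSegVol", "BrainSegVolNotVent", "lhCortexVol", "rhCortexVol",
    "CortexVol", "lhCerebralWhiteMatterVol", "rhCerebralWhiteMatterVol",
    "CerebralWhiteMatterVol", "SubCortGrayVol", "TotalGrayVol",
    "SupraTentorialVol", "CerebellumGrayVol", "CerebellumWhiteMatterVol",
    "BrainStemVol", "CorpusCallosumVol", "WMHypointensitiesVol",
    "lhWhiteSurfArea", "rhWhiteSurfArea", "lhMeanThickness",
    "rhMeanThickness", "VentricleChoroidVol",
)


@dataclass(frozen=True)
class FeatureSchema:
    """Per-feature category / region / metric / hemisphere labels.

    ``table`` is indexed by ``feature_id`` with columns ``category``,
    ``region``, ``metric`` and ``hemisphere`` (one of left/right/none).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"category", "region", "metric", "hemisphere"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"schema table missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            raise ValueError("feature_id values must be unique")
        bad = set(self.table["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def regions(self) -> list[str]:
        """Distinct region labels, in first-appearance order."""
        return list(dict.fromkeys(self.table["region"]))

    def category_counts(self) -> pd.Series:
        return self.table["category"].value_counts().reindex(CATEGORIES, fill_value=0)

    def category_of(self, feature_id: str) -> str:
        return str(self.table.at[feature_id, "category"])

    def region_of(self, feature_id: str) -> str:
        return str(self.table.at[feature_id, "region"])

    def subset(self, feature_ids) -> "FeatureSchema":
        return FeatureSchema(self.table.loc[list(feature_ids)].copy())

    def to_json(self, path: str | Path) -> None:
        payload = {
            fid: {k: (None if pd.isna(v) else v) for k, v in row.items()}
            for fid, row in self.table.to_dict(orient="index").items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        table = pd.DataFrame.from_dict(payload, orient="index")
        table.index.name = "feature_id"
        return cls(table)

    @classmethod
    def from_records(cls, records: list[dict]) -> "FeatureSchema":
        table = pd.DataFrame.from_records(records).set_index("feature_id")
        return cls(table)


def build_generic_schema(n_features: int, n_regions: int = 10) -> FeatureSchema:
    """A compact schema of generic cortical volume features (f0, f1, ...)
    spread over ``n_regions`` regions, for reduced-scale experiments."""
    records = [
        dict(feature_id=f"f{i}", category="cortical",
             region=f"r{i % n_regions}", metric="volume", hemisphere="none")
        for i in range(n_features)
    ]
    return FeatureSchema.from_records(records)


def build_abide_schema() -> FeatureSchema:
    """Build the fixed 1213-feature layout of the multi-site study design.

    Returns a schema with 21 global, 544 cortical, 240 sub-cortical and
    408 WM features.
    """
    records: list[dict] = []
    for name in GLOBAL_MEASURES:
        records.append(
            dict(feature_id=name, category="global", region="global",
                 metric=name, hemisphere="none")
        )
    for hemi, tag in (("left", "lh"), ("right", "rh")):
        for region in DK_REGIONS:
            for metric in CORTICAL_METRICS:
                records.append(
                    dict(feature_id=f"ctx-{tag}-{region}:{metric}",
                         category="cortical", region=region, metric=metric,
                         hemisphere=hemi)
                )
    for hemi, tag in (("left", "Left"), ("right", "Right")):
        for region in ASEG_BILATERAL:
            for metric in INTENSITY_METRICS:
                records.append(
                    dict(feature_id=f"{tag}-{region}:{metric}",
                         category="sub-cortical", region=region,
                         metric=metric, hemisphere=hemi)
                )
    for region in ASEG_MIDLINE:
        for metric in INTENSITY_METRICS:
            records.append(
                dict(feature_id=f"{region}:{metric}", category="sub-cortical",
                     region=region, metric=metric, hemisphere="none")
            )
    for hemi, tag in (("left", "lh"), ("right", "rh")):
        for region in DK_REGIONS:
            for metric in INTENSITY_METRICS:
                records.append(
                    dict(feature_id=f"wm-{tag}-{region}:{metric}",
                         category="WM", region=region, metric=metric,
                         hemisphere=hemi)
                )
    return FeatureSchema.from_records(records)
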