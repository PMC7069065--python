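"""Reading, validating, and assembling region x feature morphometry tables.

Morphometric similarity networks are built from parcellated cortical
morphometry: one row per region of the Desikan-Killiany atlas (68 cortical
regions, 34 per hemisphere), one column per morphometric feature.  Three
nested feature sets are supported:

* ``msn10`` — the full multimodal set: seven T1w-derived features (CT, SA,
  GM, MC, GC, FI, CI), the T1w/T2w ratio myelin proxy, and two DWI-derived
  features (FA, MD);
* ``msn8``  — msn10 without the DWI features;
* ``msn7``  — msn8 without the T1w/T2w ratio (T1w-only acquisition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RegionAtlas",
    "FeatureSetSpec",
    "FeatureTable",
    "MSN10",
    "MSN8",
    "MSN7",
    "FEATURE_SETS",
    "dk68_atlas",
    "read_feature_table",
    "read_aparcstats_wide",
    "assemble_from_wide",
    "write_feature_table",
    "subset_features",
    "read_covariates",
]

# Desikan-Killiany cortical parcels, one hemisphere (FreeSurfer naming).
_DK_PARCELS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)


def _normalize_label(label: str) -> str:
    """Case-insensitive, '-'/'_'-insensitive canonical form of a region label."""
    return str(label).strip().lower().replace("_", "-")


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered cortical parcellation; the row order of every matrix downstream."""

    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("atlas region labels must be unique")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def index_of(self) -> dict[str, int]:
        return {_normalize_label(lab): i for i, lab in enumerate(self.region_labels)}


def dk68_atlas() -> RegionAtlas:
    """The 68-region cortical Desikan-Killiany atlas, left hemisphere first."""
    labels = tuple(f"lh-{p}" for p in _DK_PARCELS) + tuple(f"rh-{p}" for p in _DK_PARCELS)
    return RegionAtlas(region_labels=labels)


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named, ordered morphometric feature set with its MRI-modality mapping."""

    name: str
    features: tuple[str, ...]
    modality_of: Mapping[str, str] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature codes must be unique")

    @property
    def n_features(self) -> int:
        return len(self.features)


_MODALITY_OF = {
    "CT": "T1w", "SA": "T1w", "GM": "T1w", "MC": "T1w", "GC": "T1w",
    "FI": "T1w", "CI": "T1w", "T1T2": "T2w", "FA": "DWI", "MD": "DWI",
}

MSN10 = FeatureSetSpec(
    name="msn10",
    features=("CT", "SA", "GM", "MC", "GC", "FI", "CI", "T1T2", "FA", "MD"),
    modality_of=_MODALITY_OF,
)
MSN8 = FeatureSetSpec(
    name="msn8",
    features=tuple(f for f in MSN10.features if f not in ("FA", "MD")),
    modality_of=_MODALITY_OF,
)
MSN7 = FeatureSetSpec(
    name="msn7",
    features=tuple(f for f in MSN8.features if f != "T1T2"),
    modality_of=_MODALITY_OF,
)

FEATURE_SETS: dict[str, FeatureSetSpec] = {s.name: s for s in (MSN10, MSN8, MSN7)}


@dataclass
class FeatureTable:
    """A per-subject, per-session region x feature matrix in native units."""

    subject_id: str
    session: str
    values: np.ndarray  # (n_regions, n_features), float
    region_labels: tuple[str, ...]
    feature_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_labels), len(self.feature_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.region_labels)} regions x {len(self.feature_labels)} features"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at region {self.region_labels[bad[0]]!r}, "
                f"feature {self.feature_labels[bad[1]]!r}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.region_labels), columns=list(self.feature_labels)
        )


def _read_delimited(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing so written tables read back to the identical doubles
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_feature_table(
    path: str | Path,
    atlas: RegionAtlas | None = None,
    spec: FeatureSetSpec | None = None,
    subject_id: str | None = None,
    session: str = "test",
) -> FeatureTable:
    """Read a long-layout (region rows, feature columns) TSV/CSV feature table.

    Rows are reordered to atlas order regardless of file order; region-label
    matching is case-insensitive and treats '-' and '_' as equivalent.  Rows
    whose label is not in the atlas (e.g. subcortical structures) are dropped
    with a warning.  Units are left untouched.
    """
    path = Path(path)
    atlas = atlas or dk68_atlas()
    df = _read_delimited(path)
    label_col = df.columns[0]
    df = df.set_index(label_col)

    index_map = atlas.index_of()
    keep_rows: dict[int, str] = {}
    dropped: list[str] = []
    for raw_label in df.index:
        key = _normalize_label(raw_label)
        if key in index_map:
            keep_rows[index_map[key]] = raw_label
        else:
            dropped.append(str(raw_label))
    if dropped:
        logger.warning("%s: dropping %d non-atlas rows: %s", path.name, len(dropped), dropped)

    missing = [lab for i, lab in enumerate(atlas.region_labels) if i not in keep_rows]
    if missing:
        raise ValueError(f"{path.name}: missing regions: {missing}")

    if spec is not None:
        col_map = {str(c).strip().upper(): c for c in df.columns}
        absent = [f for f in spec.features if f.upper() not in col_map]
        if absent:
            raise ValueError(f"{path.name}: missing feature columns: {absent}")
        cols = [col_map[f.upper()] for f in spec.features]
        feature_labels = spec.features
    else:
        cols = list(df.columns)
        feature_labels = tuple(str(c) for c in cols)

    ordered_rows = [keep_rows[i] for i in range(atlas.n_regions)]
    sub = df.loc[ordered_rows, cols]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path.name}: non-numeric or missing cell at region "
            f"{atlas.region_labels[r]!r}, feature {feature_labels[c]!r}"
        )

    return FeatureTable(
        subject_id=subject_id or path.stem,
        session=session,
        values=numeric.to_numpy(dtype=float),
        region_labels=atlas.region_labels,
        feature_labels=tuple(feature_labels),
    )


def read_aparcstats_wide(
    path: str | Path, feature: str, atlas: RegionAtlas | None = None
) -> pd.DataFrame:
    """Read one FreeSurfer ``aparcstats2table``-style wide table (one measure).

    Layout: one row per subject, first column the subject id, remaining columns
    one region each, possibly suffixed with the measure name
    (``lh_bankssts_thickness``).  Returns a subjects x regions DataFrame in
    atlas order.
    """
    atlas = atlas or dk68_atlas()
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    index_map = atlas.index_of()

    col_for_region: dict[int, str] = {}
    for col in df.columns:
        key = _normalize_label(col)
        if key not in index_map:
            # strip a trailing "<sep>measure" suffix, e.g. lh-bankssts-thickness
            key = key.rsplit("-", 1)[0]
        if key in index_map:
            col_for_region[index_map[key]] = col
    missing = [lab for i, lab in enumerate(atlas.region_labels) if i not in col_for_region]
    if missing:
        raise ValueError(f"{Path(path).name} ({feature}): missing regions: {missing}")

    out = df[[col_for_region[i] for i in range(atlas.n_regions)]].apply(
        pd.to_numeric, errors="coerce"
    )
    if out.isna().to_numpy().any():
        raise ValueError(f"{Path(path).name} ({feature}): non-numeric cells present")
    out.columns = list(atlas.region_labels)
    out.index = out.index.astype(str)
    return out


def assemble_from_wide(
    files: Mapping[str, str | Path],
    spec: FeatureSetSpec,
    atlas: RegionAtlas | None = None,
    session: str = "test",
) -> list[FeatureTable]:
    """Assemble per-subject FeatureTables from one wide table per feature."""
    atlas = atlas or dk68_atlas()
    absent = [f for f in spec.features if f not in files]
    if absent:
        raise ValueError(f"no wide table provided for features: {absent}")
    per_feature = {f: read_aparcstats_wide(files[f], f, atlas) for f in spec.features}
    subjects = list(per_feature[spec.features[0]].index)
    for f, df in per_feature.items():
        if list(df.index) != subjects:
            raise ValueError(f"subject rows of {f} table do not match {spec.features[0]} table")
    tables = []
    for sid in subjects:
        values = np.column_stack([per_feature[f].loc[sid].to_numpy() for f in spec.features])
        tables.append(
            FeatureTable(
                subject_id=str(sid),
                session=session,
                values=values,
                region_labels=atlas.region_labels,
                feature_labels=spec.features,
            )
        )
    return tables


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write the canonical long layout: TSV, region label first, full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.to_dataframe()
    df.index.name = "region"
    df.to_csv(path, sep="\t")
    return path


def subset_features(table: FeatureTable, spec: FeatureSetSpec) -> FeatureTable:
    """Column-subset a table to a (nested) feature set, preserving spec order."""
    have = {f: i for i, f in enumerate(table.feature_labels)}
    absent = [f for f in spec.features if f not in have]
    if absent:
        raise ValueError(f"features not present in table: {absent}")
    idx = [have[f] for f in spec.features]
    return FeatureTable(
        subject_id=table.subject_id,
        session=table.session,
        values=table.values[:, idx],
        region_labels=table.region_labels,
        feature_labels=spec.features,
    )


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the cohort covariates table (subject_id, age, sex, cognition columns)."""
    df = _read_delimited(path)
    required = {"subject_id", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariates file missing columns: {sorted(missing)}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df
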