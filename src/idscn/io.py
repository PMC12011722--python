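"""Reading, writing and aligning morphometric tables, and atlas-based
regional volume extraction.

All tables are tab-separated UTF-8 text with a ``subject_id`` column.
Volumes are stored in millilitres. Sex is coded 0/1. File layouts:

``volumes.tsv``
    subject_id + one column per region label.
``covariates.tsv``
    subject_id, age, sex, education_years, tiv_ml.
``clinical.tsv``
    subject_id, group, hamd, lacune_present, cmb_present, wmh_present,
    epvs_present.

Regional volumes can also be computed from per-subject modulated
gray-matter maps (NIfTI) summed over an integer-labelled atlas image;
modulated maps preserve native tissue volume, so the sum of voxel values
times the voxel volume is the regional gray-matter volume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: float format used when writing tables; round-trips IEEE doubles exactly.
_FLOAT_FMT = "%.17g"

COVARIATE_COLUMNS = ("age", "sex", "education", "tiv")
_COVARIATE_FILE_COLUMNS = {
    "age": "age",
    "sex": "sex",
    "education": "education_years",
    "tiv": "tiv_ml",
}
CLINICAL_MARKER_COLUMNS = (
    "lacune_present",
    "cmb_present",
    "wmh_present",
    "epvs_present",
)


class TableValidationError(ValueError):
    """A table violates a structural invariant (missing value, duplicate
    identifier, non-numeric or non-positive cell)."""


def _check_unique(values: Sequence, what: str) -> None:
    seen: dict = {}
    for v in values:
        if v in seen:
            raise TableValidationError(f"duplicate {what}: {v!r}")
        seen[v] = True


@dataclass
class RegionalVolumeTable:
    """Subjects-by-regions gray-matter volumes in millilitres.

    ``data`` is indexed by subject_id with one float column per region
    label. Order of both axes is preserved everywhere.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), "subject_id")
        _check_unique(list(df.columns), "region label")
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                who = bad.index[0] if len(bad) else "?"
                raise TableValidationError(
                    f"non-numeric volume for subject {who!r}, region {col!r}"
                )
        if df.isna().any().any():
            sub = df.isna().any(axis=1)
            subject = df.index[sub][0]
            region = df.columns[df.loc[subject].isna()][0]
            raise TableValidationError(
                f"missing volume for subject {subject!r}, region {region!r}"
            )
        if (df.values <= 0).any():
            i, j = np.argwhere(df.values <= 0)[0]
            raise TableValidationError(
                f"non-positive volume for subject {df.index[i]!r}, "
                f"region {df.columns[j]!r}"
            )
        self.data = df.astype(float)

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def region_labels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_edges(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, subject_ids: Sequence) -> "RegionalVolumeTable":
        return RegionalVolumeTable(self.data.loc[list(subject_ids)])


@dataclass
class CovariateTable:
    """Per-subject nuisance covariates: age (years), sex (0/1),
    education (years), total intracranial volume (ml)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(f"covariate table lacks columns {missing}")
        _check_unique(list(df.index), "subject_id")
        df = df[list(COVARIATE_COLUMNS)]
        if df.isna().any().any():
            sub = df.isna().any(axis=1)
            subject = df.index[sub][0]
            col = df.columns[df.loc[subject].isna()][0]
            raise TableValidationError(
                f"missing covariate {col!r} for subject {subject!r}"
            )
        sex = pd.to_numeric(df["sex"], errors="coerce")
        if sex.isna().any() or not set(np.unique(sex)) <= {0.0, 1.0}:
            raise TableValidationError(
                "sex must be coded 0/1 (recode strings such as 'M'/'F' upstream)"
            )
        self.data = df.astype(float)

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    def subset(self, subject_ids: Sequence) -> "CovariateTable":
        return CovariateTable(self.data.loc[list(subject_ids)])

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class AlignedDataset:
    """Volume/covariate (and optionally clinical) tables restricted to
    their common subjects, in volume-table order."""

    volumes: RegionalVolumeTable
    covariates: CovariateTable
    clinical: pd.DataFrame | None = None
    dropped: dict = field(default_factory=dict)

    @property
    def subject_ids(self) -> list:
        return self.volumes.subject_ids


# ---------------------------------------------------------------------------
# delimited-text I/O

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                     float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise TableValidationError(
            f"{path}: expected a 'subject_id' column, found {list(df.columns)}"
        )
    return df.set_index("subject_id")


def load_volume_table(path: str | Path) -> RegionalVolumeTable:
    """Read ``volumes.tsv`` (header = region labels, one row per subject)."""
    return RegionalVolumeTable(_read_tsv(path))


def write_volume_table(table: RegionalVolumeTable, path: str | Path) -> None:
    table.data.rename_axis("subject_id").to_csv(
        path, sep="\t", float_format=_FLOAT_FMT
    )


def load_covariate_table(path: str | Path) -> CovariateTable:
    df = _read_tsv(path)
    rename = {v: k for k, v in _COVARIATE_FILE_COLUMNS.items() if v in df.columns}
    return CovariateTable(df.rename(columns=rename))


def write_covariate_table(table: CovariateTable, path: str | Path) -> None:
    out = table.data.rename(columns=_COVARIATE_FILE_COLUMNS)
    out.rename_axis("subject_id").to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def load_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read ``clinical.tsv``; returns a DataFrame indexed by subject_id with
    at least ``group`` and ``hamd`` plus the four marker presence columns."""
    df = _read_tsv(path)
    for col in ("group", "hamd"):
        if col not in df.columns:
            raise TableValidationError(f"clinical table lacks column {col!r}")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("subject_id").to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# subject alignment

def align_subjects(
    volumes: RegionalVolumeTable,
    covariates: CovariateTable,
    clinical: pd.DataFrame | None = None,
) -> AlignedDataset:
    """Inner-join all tables on subject_id, keeping the volume-table order.

    Subjects present on one side only are dropped (logged). An empty
    intersection is an error.
    """
    vol_ids = volumes.subject_ids
    cov_ids = set(covariates.subject_ids)
    keep = [s for s in vol_ids if s in cov_ids]
    if clinical is not None:
        clin_ids = set(clinical.index)
        keep = [s for s in keep if s in clin_ids]
    if not keep:
        raise TableValidationError("no subjects shared between the input tables")
    dropped = {
        "volumes": sorted(set(vol_ids) - set(keep)),
        "covariates": sorted(cov_ids - set(keep)),
    }
    if clinical is not None:
        dropped["clinical"] = sorted(set(clinical.index) - set(keep))
    for name, ids in dropped.items():
        if ids:
            logger.warning("align_subjects: dropping %d subject(s) only in %s: %s",
                           len(ids), name, ids[:5])
    return AlignedDataset(
        volumes=volumes.subset(keep),
        covariates=covariates.subset(keep),
        clinical=None if clinical is None else clinical.loc[keep],
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# atlas-based extraction from modulated gray-matter maps

@dataclass
class AtlasParcellation:
    """Integer-labelled parcellation image with a label -> region-name map.

    ``voxel_volume_ml`` defaults to the product of the voxel dimensions
    taken from the NIfTI header (1.5 mm isotropic -> 0.003375 ml).
    Label 0 is background.
    """

    label_image: np.ndarray
    label_map: Mapping[int, str]
    voxel_volume_ml: float

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if not np.issubdtype(self.label_image.dtype, np.integer):
            rounded = np.rint(self.label_image)
            if not np.allclose(self.label_image, rounded):
                raise ValueError("atlas label image must be integer-valued")
            self.label_image = rounded.astype(np.int64)
        self.label_map = {int(k): str(v) for k, v in self.label_map.items()}
        if 0 in self.label_map:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(self.label_image)) - {0}
        missing = [lab for lab in self.label_map if lab not in present]
        if missing:
            raise ValueError(
                f"atlas labels with no voxels: {sorted(missing)}"
            )
        if self.voxel_volume_ml <= 0:
            raise ValueError("voxel volume must be positive")

    @classmethod
    def from_nifti(cls, path: str | Path, label_map: Mapping[int, str] | str | Path,
                   voxel_volume_ml: float | None = None) -> "AtlasParcellation":
        import nibabel as nib

        img = nib.load(str(path))
        if isinstance(label_map, (str, Path)):
            with open(label_map) as fh:
                label_map = {int(k): v for k, v in json.load(fh).items()}
        if voxel_volume_ml is None:
            voxel_volume_ml = float(np.prod(img.header.get_zooms()[:3])) / 1000.0
        return cls(np.asanyarray(img.dataobj), label_map, voxel_volume_ml)


def extract_regional_volumes(
    gm_maps: Mapping[str, "np.ndarray | str | Path"],
    atlas: AtlasParcellation,
) -> RegionalVolumeTable:
    """Sum modulated gray-matter values over each atlas region.

    volume(subject, region) = sum of the subject's modulated GM map over
    the region's voxels, times the voxel volume in ml.

    ``gm_maps`` maps subject_id to either an in-memory 3-D array or a
    NIfTI path on the same grid as the atlas.
    """
    labels = atlas.label_image
    label_ids = sorted(atlas.label_map)
    region_names = [atlas.label_map[lab] for lab in label_ids]
    flat_labels = labels.ravel()
    nbins = int(flat_labels.max()) + 1

    rows = {}
    for subject, source in gm_maps.items():
        if isinstance(source, (str, Path)):
            import nibabel as nib

            arr = np.asanyarray(nib.load(str(source)).dataobj)
        else:
            arr = np.asarray(source)
        if arr.shape != labels.shape:
            raise ValueError(
                f"grid mismatch for subject {subject!r}: map {arr.shape} vs "
                f"atlas {labels.shape}"
            )
        sums = np.bincount(flat_labels, weights=arr.ravel().astype(float),
                           minlength=nbins)
        rows[subject] = [sums[lab] * atlas.voxel_volume_ml for lab in label_ids]

    df = pd.DataFrame.from_dict(rows, orient="index", columns=region_names)
    df.index.name = "subject_id"
    return RegionalVolumeTable(df)
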