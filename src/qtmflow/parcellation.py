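"""Arterial-territory parcellation: regional means of the velocity map.

The atlas is an integer-labeled volume co-registered to the velocity maps
(registration itself is delegated to external tools); 26 territories cover
the anterior, middle and posterior cerebral arteries, the perforator
territories, and the vertebrobasilar system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic_data import TERRITORY_NAMES, VB_TERRITORIES


def _parent_artery(name: str) -> str:
    if name.startswith("ACA"):
        return "ACA"
    if name.startswith("MCA"):
        return "MCA"
    if name.startswith("PCA"):
        return "PCA"
    if name[:-1] in ("MLS", "LLS", "ACTP"):
        return "lenticulostriate/choroidal"
    return "VB"


def default_region_table() -> pd.DataFrame:
    """Label table for the 26-territory layout (labels 1..26)."""
    return pd.DataFrame(
        {
            "label": np.arange(1, len(TERRITORY_NAMES) + 1),
            "abbreviation": TERRITORY_NAMES,
            "hemisphere": ["L" if n.endswith("L") else "R" for n in TERRITORY_NAMES],
            "parent_artery": [_parent_artery(n) for n in TERRITORY_NAMES],
        }
    )


@dataclass
class RegionAtlas:
    """Integer label volume plus its label -> territory table."""

    labels: np.ndarray
    region_table: pd.DataFrame

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.region_table["label"].tolist())
        missing = present - known
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from region_table")

    @classmethod
    def from_volume(cls, labels, region_table: Optional[pd.DataFrame] = None):
        return cls(labels, default_region_table() if region_table is None else region_table)


@dataclass
class RegionalVelocities:
    """Per-region mean velocity magnitude for one subject."""

    subject_id: str
    table: pd.DataFrame  # abbreviation, mean, n_voxels, missing

    def as_series(self) -> pd.Series:
        s = self.table.set_index("abbreviation")["mean"]
        s.name = self.subject_id
        return s


def regional_mean(
    magnitude: np.ndarray,
    atlas: RegionAtlas,
    min_voxels: int = 10,
    mask: Optional[np.ndarray] = None,
    subject_id: str = "subject",
) -> RegionalVelocities:
    """Mean velocity magnitude over masked voxels of each atlas label.

    Regions whose masked voxel count falls below ``min_voxels`` (including
    labels absent from the volume) are flagged missing (NaN mean), never
    silently zero.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.shape != atlas.labels.shape:
        raise ValueError("magnitude map and atlas are on different grids")
    if mask is None:
        mask = np.isfinite(magnitude)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(magnitude)
    if not mask.any():
        raise ValueError("mask has no overlap with the magnitude map")

    rows = []
    for _, reg in atlas.region_table.iterrows():
        sel = (atlas.labels == reg["label"]) & mask
        n = int(sel.sum())
        ok = n >= min_voxels
        rows.append(
            dict(
                abbreviation=reg["abbreviation"],
                mean=float(magnitude[sel].mean()) if ok else np.nan,
                n_voxels=n,
                missing=not ok,
            )
        )
    return RegionalVelocities(subject_id, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path):
    """Read a NIfTI volume; returns (data, voxel spacing, affine).

    Only 3D or 4D payloads are accepted.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D volume, got {data.ndim}D")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, spacing, img.affine


def write_volume(volume, path, voxel_size=(1.0, 1.0, 1.0), affine=None):
    """Write a 3D/4D array as NIfTI-1, encoding voxel spacing in the affine."""
    volume = np.asarray(volume)
    if volume.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D volume, got {volume.ndim}D")
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(volume, affine)
    img.header.set_zooms(tuple(voxel_size) + ((1.0,) if volume.ndim == 4 else ()))
    nib.save(img, str(path))
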