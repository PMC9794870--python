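"""Core in-memory containers shared across the pipeline.

Volumes are plain dataclasses around a 3-D numpy array plus voxel spacing in
millimetres; they serialize to/from NIfTI via :mod:`nibabel`.  Tabular data
(cohorts, feature tables, predictions) live in pandas DataFrames and are not
wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "ROIAtlas", "TERRITORY_NAMES", "SEGMENT_NAMES"]

#: Cerebral blood-flow territories: anterior/middle/posterior cerebral artery,
#: lateralized.
TERRITORY_NAMES = ("ACA_L", "ACA_R", "MCA_L", "MCA_R", "PCA_L", "PCA_R")

#: Major artery segments measured individually: posterior cerebral (PCA),
#: middle cerebral M1/M2, basilar (BA) and internal carotid (ICA) arteries are
#: lateralized; the short anterior cerebral A1 and distal A2 segments run
#: along the midline and carry a single label each, giving 11 segments so the
#: downstream vessel feature vector totals 24 (11 + 6 + 6 + 1).
SEGMENT_NAMES = (
    "PCA_L", "PCA_R", "MCA_M1_L", "MCA_M1_R", "MCA_M2_L", "MCA_M2_R",
    "BA", "ICA_L", "ICA_R", "ACA_A1", "ACA_A2",
)


@dataclass
class Volume3D:
    """A 3-D image volume with isotropic-or-not voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "t1-like"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) < 16:
            raise ValueError(
                f"all volume dimensions must be >= 16, got {self.data.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_nifti(self, path: str) -> None:
        affine = np.diag([*self.spacing, 1.0])
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        img.header.set_zooms(self.spacing)
        img.header["descrip"] = self.modality.encode()[:79]
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str, modality: str | None = None) -> "Volume3D":
        img = nib.load(path)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if modality is None:
            modality = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "t1-like"
        return cls(np.asarray(img.dataobj, dtype=np.float32), spacing, modality)


@dataclass
class ROIAtlas:
    """Labelled flow territories and artery segments on a phantom grid.

    Artery segments geometrically lie *inside* flow territories, so the two
    label families are stored as separate aligned integer volumes; labels are
    disjoint within each family (0 = background).
    """

    territories: np.ndarray
    segments: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    territory_labels: dict[int, str] = field(default_factory=dict)
    segment_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.territories.shape != self.segments.shape:
            raise ValueError("territory and segment grids must match")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.territories.shape

    def territory_mask(self, name: str) -> np.ndarray:
        lab = {v: k for k, v in self.territory_labels.items()}[name]
        return self.territories == lab

    def segment_mask(self, name: str) -> np.ndarray:
        lab = {v: k for k, v in self.segment_labels.items()}[name]
        return self.segments == lab
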