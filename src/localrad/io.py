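"""Image, mask, configuration and feature-matrix I/O.

Geometric conventions used throughout the package:

* arrays are row-major, 0-based, pixel-centre indexed;
* in-plane pixel spacing is isotropic (anisotropic inputs are rejected,
  because a *square* tissue unit is only well-defined on an isotropic grid);
* pixel spacing is a required input and is never inferred from headers;
* each slice is processed independently in 2D.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RoiImageStack",
    "PipelineConfig",
    "load_stack",
    "write_stack_nifti",
    "write_feature_matrix",
    "read_feature_matrix",
    "FEATURE_MATRIX_FORMAT_TAG",
]

#: version tag written as a comment on the first line of every feature CSV
FEATURE_MATRIX_FORMAT_TAG = "localrad-feature-matrix v1"

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


class FormatError(ValueError):
    """Raised when an input file does not match the expected format."""


@dataclass
class RoiImageStack:
    """One patient's stack of 2D T2w slices with binary tumour ROI masks.

    Parameters
    ----------
    patient_id:
        Identifier carried through to the feature matrix.
    slices:
        Ordered 2D real-valued intensity arrays (arbitrary T2w units).
    masks:
        Matching 2D boolean arrays; ``True`` marks tumour ROI pixels.
    pixel_spacing_mm:
        In-plane pixel spacing in millimetres (isotropic).
    slice_thickness_mm:
        Through-plane thickness in millimetres (informational; slices are
        processed independently in 2D).
    """

    patient_id: str
    slices: list[np.ndarray]
    masks: list[np.ndarray]
    pixel_spacing_mm: float
    slice_thickness_mm: float = 3.0

    def __post_init__(self) -> None:
        if len(self.slices) == 0:
            raise ValueError("a stack needs at least one slice")
        if len(self.slices) != len(self.masks):
            raise FormatError(
                f"{len(self.slices)} slices but {len(self.masks)} masks"
            )
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not self.slice_thickness_mm > 0:
            raise ValueError("slice_thickness_mm must be positive")
        slices, masks = [], []
        for i, (img, msk) in enumerate(zip(self.slices, self.masks)):
            img = np.asarray(img, dtype=np.float64)
            msk = np.asarray(msk)
            if img.ndim != 2 or msk.ndim != 2:
                raise FormatError(f"slice {i}: expected 2D arrays")
            if img.shape != msk.shape:
                raise FormatError(
                    f"slice {i}: image shape {img.shape} != mask shape {msk.shape}"
                )
            msk = msk != 0  # binarise: nonzero = ROI
            if not msk.any():
                raise ValueError(f"slice {i}: mask is empty (no ROI pixels)")
            slices.append(img)
            masks.append(msk)
        self.slices = slices
        self.masks = masks

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class PipelineConfig:
    """Tunable parameters of the extraction and selection pipeline.

    ``tissue_unit_mm`` is the side length of the square sliding window
    (0.5 cm); ``alpha`` the significance level of the univariate tests.
    T2w intensities are used raw — no normalisation is applied before
    feature extraction (documented caveat: inter-scanner comparability of
    intensity-dependent maps such as mean/median is not guaranteed).
    """

    tissue_unit_mm: float = 5.0
    window_stride_px: int = 1
    min_inmask_fraction: float = 1.0
    local_entropy_bins: int = 32
    global_entropy_bins: int = 64
    alpha: float = 0.05
    bootstrap_reps: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissue_unit_mm > 0:
            raise ValueError("tissue_unit_mm must be positive")
        if not (isinstance(self.window_stride_px, int) and self.window_stride_px >= 1):
            raise ValueError("window_stride_px must be a positive integer")
        if not 0 < self.min_inmask_fraction <= 1:
            raise ValueError("min_inmask_fraction must be in (0, 1]")
        if self.local_entropy_bins < 1 or self.global_entropy_bins < 1:
            raise ValueError("entropy bin counts must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def _read_slices(path: Path) -> list[np.ndarray]:
    """Read one file into a list of 2D arrays (a 3D NIfTI yields one per
    slice along axis 2, ascending)."""
    if _is_nifti(path):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        if len(zooms) >= 2 and abs(float(zooms[0]) - float(zooms[1])) > 1e-6:
            raise FormatError(
                f"{path.name}: anisotropic in-plane spacing {zooms[:2]} not supported"
            )
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 2:
            return [data]
        if data.ndim == 3:
            return [data[:, :, k] for k in range(data.shape[2])]
        raise FormatError(f"{path.name}: expected 2D/3D NIfTI, got {data.ndim}D")
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:  # collapse RGB(A) to a single channel if grayscale-equal
        if arr.shape[2] in (3, 4) and np.ptp(arr[:, :, :3], axis=2).max() == 0:
            arr = arr[:, :, 0]
        else:
            raise FormatError(f"{path.name}: colour images are not supported")
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected a 2D image")
    return [arr]


def load_stack(
    image_paths: Sequence[str | Path],
    mask_paths: Sequence[str | Path],
    pixel_spacing_mm: float,
    *,
    patient_id: str = "patient",
    slice_thickness_mm: float = 3.0,
) -> RoiImageStack:
    """Load a validated :class:`RoiImageStack` from files.

    Supported formats: NIfTI (a single 3D volume, sliced along axis 2, or
    per-slice 2D files) and PNG/TIFF (one 2D file per slice).  Masks are
    binarised as ``value != 0``.  Slice order follows file order, or the
    ascending slice index of a 3D volume.
    """
    image_paths = [Path(p) for p in image_paths]
    mask_paths = [Path(p) for p in mask_paths]
    for p in image_paths + mask_paths:
        if not p.exists():
            raise FileNotFoundError(p)
    if len(image_paths) != len(mask_paths):
        raise FormatError("image and mask path lists differ in length")
    slices: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for ip, mp in zip(image_paths, mask_paths):
        s = _read_slices(ip)
        m = _read_slices(mp)
        if len(s) != len(m):
            raise FormatError(f"{ip.name}: {len(s)} slices but {mp.name} has {len(m)}")
        slices.extend(s)
        masks.extend(m)
    return RoiImageStack(
        patient_id=patient_id,
        slices=slices,
        masks=masks,
        pixel_spacing_mm=float(pixel_spacing_mm),
        slice_thickness_mm=float(slice_thickness_mm),
    )


def write_stack_nifti(stack: RoiImageStack, image_path: str | Path, mask_path: str | Path) -> None:
    """Write a stack as a pair of 3D NIfTI volumes (slices along axis 2)."""
    sp = stack.pixel_spacing_mm
    affine = np.diag([sp, sp, stack.slice_thickness_mm, 1.0])
    img = np.stack(stack.slices, axis=2)
    msk = np.stack([m.astype(np.uint8) for m in stack.masks], axis=2)
    nib.save(nib.Nifti1Image(img, affine), str(image_path))
    nib.save(nib.Nifti1Image(msk, affine), str(mask_path))


def write_feature_matrix(matrix, path: str | Path) -> None:
    """Write a :class:`~localrad.global_features.FeatureMatrix` as CSV.

    The first line is a versioned comment tag; columns are ``patient_id``,
    ``group`` and the 84 canonical feature names in canonical order.
    """
    frame = matrix.frame
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {FEATURE_MATRIX_FORMAT_TAG}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_feature_matrix(path: str | Path):
    """Read a feature matrix CSV written by :func:`write_feature_matrix`."""
    from .global_features import FEATURE_NAMES, FeatureMatrix

    frame = pd.read_csv(path, comment="#")
    expected = ["patient_id", "group"] + list(FEATURE_NAMES)
    unknown = [c for c in frame.columns if c not in expected]
    if unknown:
        raise FormatError(f"unknown feature-matrix columns: {unknown}")
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise FormatError(f"missing feature-matrix columns: {missing}")
    return FeatureMatrix(frame[expected])
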