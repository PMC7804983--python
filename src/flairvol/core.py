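"""Shared image data model: volumes, label maps, lesion masks and volume accounting.

All grids are 3-D, indexed ``(i, j, k)`` with 0-based voxel indices; world
coordinates are RAS millimetres given by the affine.  Masks and label maps must
live on the grid of their source image — cross-grid operations go through the
explicit resampling in :mod:`flairvol.atlas`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "BACKGROUND",
    "CSF",
    "GM",
    "WM",
    "TISSUE_NAMES",
    "ImageVolume",
    "TissueLabelMap",
    "LesionMask",
    "VolumeReport",
    "FormatError",
    "ValidationError",
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "read_lesion_mask",
    "write_lesion_mask",
    "voxel_count_to_ml",
    "compute_tissue_volumes",
    "volume_report_frame",
]

# 4-class tissue model.  "GM" is the combined cortical + deep grey compartment.
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_NAMES = {BACKGROUND: "background", CSF: "csf", GM: "gm", WM: "wm"}

MODALITIES = ("T1", "FLAIR")
FIELD_STRENGTHS = ("1.5T", "3T")


class FormatError(ValueError):
    """Raised for inputs that are structurally not what the pipeline accepts."""


class ValidationError(ValueError):
    """Raised when a value violates a documented precondition or invariant."""


def _default_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ImageVolume:
    """A 3-D scalar intensity grid with geometry and acquisition tags.

    Parameters
    ----------
    data
        3-D array of finite intensities (arbitrary units).
    spacing
        Voxel edge lengths in mm, all positive.
    affine
        4x4 voxel-index -> RAS-mm affine.  Defaults to a diagonal affine built
        from ``spacing`` with the origin at voxel (0, 0, 0).
    modality
        ``"T1"``, ``"FLAIR"`` or ``None`` when unknown.
    field_strength
        ``"1.5T"``, ``"3T"`` or ``None`` when unspecified.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None
    modality: Optional[str] = None
    field_strength: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3-D image, got {self.data.ndim}-D")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValidationError(f"image contains {n_bad} non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if self.modality is not None and self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.field_strength is not None and self.field_strength not in FIELD_STRENGTHS:
            raise ValidationError(
                f"field_strength must be one of {FIELD_STRENGTHS}, got {self.field_strength!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same geometry and tags, new intensities."""
        return replace(self, data=np.asarray(data, dtype=np.float64))


def _check_pipeline_grid(vol: ImageVolume) -> None:
    if min(vol.shape) < 8:
        raise ValidationError(f"pipeline inputs need >= 8 voxels per axis, got {vol.shape}")


@dataclass
class TissueLabelMap:
    """Integer tissue parcellation (0 bg, 1 CSF, 2 GM, 3 WM) with optional posteriors.

    ``posteriors`` is a ``(4, *grid)`` stack ordered background, CSF, GM, WM;
    where present, per-voxel class posteriors sum to 1 and ``labels`` is their
    argmax (ties resolved to the lowest class index).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None
    posteriors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"expected a 3-D label grid, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValidationError("labels must be integer-valued")
            self.labels = rounded.astype(np.int16)
        else:
            self.labels = self.labels.astype(np.int16)
        bad = set(np.unique(self.labels)) - {BACKGROUND, CSF, GM, WM}
        if bad:
            raise ValidationError(f"labels outside {{0,1,2,3}}: {sorted(bad)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.posteriors is not None:
            self.posteriors = np.asarray(self.posteriors, dtype=np.float64)
            if self.posteriors.shape != (4,) + self.labels.shape:
                raise ValidationError(
                    f"posteriors shape {self.posteriors.shape} does not match "
                    f"(4, {self.labels.shape})"
                )
            sums = self.posteriors.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValidationError("per-voxel class posteriors must sum to 1 within 1e-6")
            if not np.array_equal(np.argmax(self.posteriors, axis=0), self.labels):
                raise ValidationError("labels must equal argmax of posteriors")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def brain_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def class_mask(self, tissue: int) -> np.ndarray:
        return self.labels == tissue


@dataclass
class LesionMask:
    """Binary lesion mask on the grid of its source image."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 3:
            raise FormatError(f"expected a 3-D mask, got {arr.ndim}-D")
        uniq = set(np.unique(arr))
        if not uniq <= {0, 1, False, True}:
            raise ValidationError(f"mask values must be binary, got {sorted(uniq)[:5]}")
        self.mask = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def volume_ml(self) -> float:
        return voxel_count_to_ml(int(self.mask.sum()), self.spacing)


@dataclass
class VolumeReport:
    """Per-class tissue volumes in millilitres; TIV = CSF + GM + WM."""

    gm_ml: float
    wm_ml: float
    csf_ml: float
    tiv_ml: float = field(default=None)  # type: ignore[assignment]
    lesion_ml: float = 0.0
    counting: str = "hard"  # "soft" (posterior sums) or "hard" (label counts)

    def __post_init__(self) -> None:
        if self.tiv_ml is None:
            self.tiv_ml = self.gm_ml + self.wm_ml + self.csf_ml
        for name in ("gm_ml", "wm_ml", "csf_ml", "tiv_ml", "lesion_ml"):
            v = float(getattr(self, name))
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
            setattr(self, name, v)
        if abs(self.tiv_ml - (self.gm_ml + self.wm_ml + self.csf_ml)) > 1e-6:
            raise ValidationError("tiv_ml must equal gm_ml + wm_ml + csf_ml within 1e-6")

    def as_dict(self) -> dict:
        return {
            "gm_ml": self.gm_ml,
            "wm_ml": self.wm_ml,
            "csf_ml": self.csf_ml,
            "tiv_ml": self.tiv_ml,
            "lesion_ml": self.lesion_ml,
            "counting": self.counting,
        }


# ---------------------------------------------------------------------------
# NIfTI I/O


def _description_string(modality, field_strength) -> str:
    parts = []
    if modality:
        parts.append(f"modality={modality}")
    if field_strength:
        parts.append(f"field={field_strength}")
    return ";".join(parts)


def _parse_description(descrip: str) -> tuple[Optional[str], Optional[str]]:
    modality = fieldstr = None
    for token in descrip.split(";"):
        key, _, value = token.partition("=")
        if key.strip() == "modality" and value in MODALITIES:
            modality = value
        elif key.strip() == "field" and value in FIELD_STRENGTHS:
            fieldstr = value
    return modality, fieldstr


def read_volume(path, expected_modality: Optional[str] = None) -> ImageVolume:
    """Read a 3-D NIfTI-1 scalar image.

    ``expected_modality`` overrides the modality recovered from the header
    description; a 4-D file or non-finite voxels are rejected.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    descrip = img.header["descrip"].tobytes().decode("utf-8", "ignore").rstrip("\x00")
    modality, fieldstr = _parse_description(descrip)
    if expected_modality is not None:
        modality = expected_modality
    return ImageVolume(
        data=np.asarray(data, dtype=np.float64),
        spacing=spacing,
        affine=np.asarray(img.affine),
        modality=modality,
        field_strength=fieldstr,
    )


def _write_nifti(data: np.ndarray, affine: np.ndarray, spacing, path, descrip: str = "") -> None:
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    if descrip:
        img.header["descrip"] = descrip.encode("utf-8")[:79]
    nib.save(img, str(path))


def write_volume(vol: ImageVolume, path) -> None:
    _write_nifti(
        vol.data.astype(np.float32),
        vol.affine,
        vol.spacing,
        path,
        _description_string(vol.modality, vol.field_strength),
    )


def write_label_map(seg: TissueLabelMap, path) -> None:
    _write_nifti(seg.labels.astype(np.int16), seg.affine, seg.spacing, path)


def read_label_map(path) -> TissueLabelMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D label map, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TissueLabelMap(labels=data, spacing=spacing, affine=np.asarray(img.affine))


def write_lesion_mask(mask: LesionMask, path) -> None:
    _write_nifti(mask.mask.astype(np.uint8), mask.affine, mask.spacing, path)


def read_lesion_mask(path) -> LesionMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionMask(mask=data, spacing=spacing, affine=np.asarray(img.affine))


# ---------------------------------------------------------------------------
# Volume accounting


def voxel_count_to_ml(count: float, spacing: Sequence[float]) -> float:
    """Convert a (possibly fractional) voxel count to millilitres.

    1 ml = 1000 mm^3, so the result is ``count * prod(spacing) / 1000``.
    """
    if count < 0:
        raise ValidationError(f"voxel count must be >= 0, got {count}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be 3 positive values, got {spacing}")
    return float(count) * float(np.prod(spacing)) / 1000.0


def compute_tissue_volumes(
    seg: TissueLabelMap, lesions: Optional[LesionMask] = None
) -> VolumeReport:
    """Per-class volumes in ml; soft (posterior sums) when posteriors exist.

    TIV is the combined CSF + GM + WM volume.  ``lesions``, when given, fills
    ``lesion_ml`` from the binary mask.
    """
    if seg.spacing is None or any(s <= 0 for s in seg.spacing):
        raise ValidationError("label map has no valid spacing")
    if seg.posteriors is not None:
        counts = {c: float(seg.posteriors[c].sum()) for c in (CSF, GM, WM)}
        counting = "soft"
    else:
        counts = {c: float((seg.labels == c).sum()) for c in (CSF, GM, WM)}
        counting = "hard"
    vols = {c: voxel_count_to_ml(counts[c], seg.spacing) for c in counts}
    lesion_ml = 0.0
    if lesions is not None:
        if lesions.shape != seg.shape:
            raise ValidationError("lesion mask grid does not match label map grid")
        lesion_ml = lesions.volume_ml
    return VolumeReport(
        gm_ml=vols[GM],
        wm_ml=vols[WM],
        csf_ml=vols[CSF],
        lesion_ml=lesion_ml,
        counting=counting,
    )


def volume_report_frame(rows: list[dict]):
    """Assemble per-subject volume rows into the canonical CSV table.

    Each row needs subject_id, method, field_strength plus a VolumeReport (or
    its fields).  Returns a pandas DataFrame with the canonical column order.
    """
    import pandas as pd

    records = []
    for row in rows:
        rec = dict(row)
        report = rec.pop("report", None)
        if report is not None:
            rec.update({k: v for k, v in report.as_dict().items() if k != "counting"})
        records.append(rec)
    cols = ["subject_id", "method", "field_strength", "gm_ml", "wm_ml", "csf_ml", "tiv_ml", "lesion_ml"]
    frame = pd.DataFrame.from_records(records)
    return frame[[c for c in cols if c in frame.columns]]


def save_sidecar(path, payload: dict) -> None:
    """Write a JSON sidecar recording how an artifact was generated."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
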