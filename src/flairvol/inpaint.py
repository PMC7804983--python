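"""Patch-based lesion inpainting: fill lesion voxels with healthy-looking WM.

Lesion voxels bias downstream tissue volumetry, so they are replaced before
atlas segmentation.  Filling proceeds from the lesion boundary inward
(onion-peel): each boundary voxel takes the centre value of the best-matching
non-lesion patch — minimum mean squared difference over the patch voxels whose
values are known — inside a local search window.  Already-filled voxels become
available as patch support for deeper layers, so large lesions fill without
holes.  Ties resolve to the smallest linear index, making the operation fully
deterministic; non-lesion voxels are never touched.

Three correction modes are supported at pipeline level: ``uncorrected`` (a
pass-through), ``manual_filled`` (fill with a supplied reference mask) and
``outlier_filled`` (fill with the mixture segmenter's own lesion mask).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import ImageVolume, LesionMask, ValidationError

__all__ = ["InpaintConfig", "InpaintError", "inpaint_lesions", "INPAINT_MODES"]

INPAINT_MODES = ("uncorrected", "manual_filled", "outlier_filled")


class InpaintError(ValueError):
    """Raised when the lesion mask cannot safely be inpainted."""


@dataclass
class InpaintConfig:
    """Patch and search geometry; mode names the source of the lesion mask."""

    patch_radius: int = 1  # 3^3 patches
    search_radius: int = 7
    mode: str = "outlier_filled"
    rim_width: int = 1  # perilesional rim treated as untrusted patch evidence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_radius < 1 or self.search_radius < 1:
            raise ValidationError("patch_radius and search_radius must be >= 1")
        if self.rim_width < 0:
            raise ValidationError("rim_width must be >= 0")
        if self.mode not in INPAINT_MODES:
            raise ValidationError(f"mode must be one of {INPAINT_MODES}, got {self.mode!r}")


def _best_match_value(
    data: np.ndarray,
    known: np.ndarray,
    candidate_ok: np.ndarray,
    voxel: tuple[int, int, int],
    patch_radius: int,
    search_radius: int,
) -> Optional[float]:
    """Centre value of the SSD-minimising candidate patch around ``voxel``.

    ``known`` marks voxels whose intensity is usable as patch support
    (originally non-lesion, or already filled); ``candidate_ok`` marks voxels
    allowed as patch centres (originally non-lesion).  Returns None when the
    window holds no candidate.
    """
    shape = data.shape
    p = patch_radius
    lo = [max(v - search_radius, p) for v in voxel]
    hi = [min(v + search_radius, s - 1 - p) for v, s in zip(voxel, shape)]
    if any(l > h for l, h in zip(lo, hi)):
        return None
    win = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    cand = candidate_ok[win]
    if not cand.any():
        return None

    offsets = [
        (di, dj, dk)
        for di in range(-p, p + 1)
        for dj in range(-p, p + 1)
        for dk in range(-p, p + 1)
    ]
    ssd = np.zeros(cand.shape)
    counts = np.zeros(cand.shape)
    vi, vj, vk = voxel
    for di, dj, dk in offsets:
        ti, tj, tk = vi + di, vj + dj, vk + dk
        if not (0 <= ti < shape[0] and 0 <= tj < shape[1] and 0 <= tk < shape[2]):
            continue
        if not known[ti, tj, tk]:
            continue
        target_val = data[ti, tj, tk]
        shifted = tuple(
            slice(l + d, h + 1 + d) for l, h, d in zip(lo, hi, (di, dj, dk))
        )
        patch_vals = data[shifted]
        patch_known = known[shifted]
        diff = (patch_vals - target_val) ** 2
        ssd += np.where(patch_known, diff, 0.0)
        counts += patch_known
    with np.errstate(invalid="ignore", divide="ignore"):
        mssd = np.where(counts > 0, ssd / np.maximum(counts, 1), np.inf)
    mssd = np.where(cand & (counts > 0), mssd, np.inf)
    if not np.isfinite(mssd).any():
        return None
    flat = int(np.argmin(mssd.reshape(-1)))  # argmin takes the first (smallest index) tie
    idx = np.unravel_index(flat, mssd.shape)
    src = tuple(l + i for l, i in zip(lo, idx))
    return float(data[src])


def inpaint_lesions(
    image: ImageVolume,
    lesions: LesionMask,
    config: Optional[InpaintConfig] = None,
    wm_mask: Optional[np.ndarray] = None,
) -> ImageVolume:
    """Replace lesion voxels by patch-matched healthy values.

    Deterministic; non-lesion voxels are bit-identical to the input.  Refuses
    masks covering more than half the WM: against ``wm_mask`` when provided,
    otherwise against a crude estimate (one third of the above-background
    volume — WM is roughly a third of the intracranial compartment).
    """
    cfg = config or InpaintConfig()
    if cfg.mode == "uncorrected":
        raise ValidationError("mode 'uncorrected' is a pipeline pass-through, not an inpaint")
    if image.shape != lesions.shape:
        raise ValidationError("image and lesion mask must share a grid")
    mask = lesions.mask
    if not mask.any():
        return image.with_data(image.data.copy())

    # coverage guard: a mask swallowing most of the WM is a bug upstream
    if wm_mask is not None:
        wm_voxels = float(wm_mask.sum())
    else:
        brain_proxy = image.data > 0.25 * np.percentile(image.data, 99)
        wm_voxels = float(brain_proxy.sum()) / 3.0
    if mask.sum() > 0.5 * max(wm_voxels, 1.0):
        raise InpaintError(
            f"lesion mask covers {int(mask.sum())} voxels, more than half the "
            f"WM (~{wm_voxels:.0f} voxels); refusing to inpaint"
        )

    data = image.data.copy()
    # the immediate perilesional rim is partial-volume contaminated: it is
    # never modified, but neither is it trusted as patch evidence, otherwise
    # its elevated intensities drag the fill bright from the boundary inward
    if cfg.rim_width > 0:
        rim = ndimage.binary_dilation(mask, iterations=cfg.rim_width) & ~mask
    else:
        rim = np.zeros_like(mask)
    known = ~mask & ~rim
    candidate_ok = known.copy()  # patch centres: originally non-lesion, non-rim
    remaining = mask.copy()
    while remaining.any():
        boundary = remaining & ndimage.binary_dilation(~remaining)
        if not boundary.any():  # disconnected pocket: peel from anywhere
            boundary = remaining
        filled_any = False
        for voxel in map(tuple, np.argwhere(boundary)):
            value = _best_match_value(
                data, known, candidate_ok, voxel, cfg.patch_radius, cfg.search_radius
            )
            if value is None:
                value = _best_match_value(
                    data, known, candidate_ok, voxel, cfg.patch_radius, 2 * cfg.search_radius
                )
            if value is None:
                warnings.warn(
                    "no candidate patch in doubled window; using nearest non-lesion voxel",
                    RuntimeWarning,
                )
                value = _nearest_known_value(data, candidate_ok, voxel)
            data[voxel] = value
            remaining[voxel] = False
            known[voxel] = True
            filled_any = True
        if not filled_any:  # pragma: no cover - safety against infinite loops
            break
    out = image.with_data(data)
    return out


def _nearest_known_value(data: np.ndarray, ok: np.ndarray, voxel) -> float:
    idx = np.argwhere(ok)
    d2 = ((idx - np.asarray(voxel)) ** 2).sum(axis=1)
    return float(data[tuple(idx[int(np.argmin(d2))])])
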