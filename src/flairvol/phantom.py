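"""Synthetic brain phantoms: paired T1/FLAIR volumes with ground-truth labels.

The generator emulates the study conditions every other module is exercised
under: isotropic ~1 mm 3-D acquisitions of a brain-like object at two
field-strength contrast presets (1.5T noisier than 3T), with a 4-class anatomy
(background / CSF / GM / WM) built from nested smoothed ellipsoids, optional
focal WM lesions that are hyperintense on FLAIR and GM-like on T1, Gaussian
tissue noise and a smooth multiplicative bias field.

Anatomy is deliberately schematic — concentric ellipsoid compartments plus an
ellipsoidal ventricle — rather than a deformed template of real anatomy; it is
sufficient to exercise mixture fitting, multi-atlas fusion, inpainting and the
statistics end-to-end with exact ground truth and no external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    BACKGROUND,
    CSF,
    GM,
    WM,
    ImageVolume,
    LesionMask,
    TissueLabelMap,
    ValidationError,
    voxel_count_to_ml,
    write_lesion_mask,
    write_label_map,
    write_volume,
)

__all__ = [
    "GenerationError",
    "PhantomSpec",
    "PhantomCase",
    "Cohort",
    "preset_spec",
    "generate_phantom",
    "generate_atlas_database",
    "generate_cohort",
]

LESION = "lesion"

# Intensity presets (arbitrary units).  Chosen once to reproduce the contrast
# relations the segmenters rely on: FLAIR CSF < WM < GM < lesion, T1
# CSF < GM < WM with lesions T1-isointense to GM; the 3T presets have lower
# noise SD (higher SNR) than 1.5T.
_MEANS = {
    "FLAIR": {"background": 2.0, "csf": 30.0, "gm": 70.0, "wm": 55.0, LESION: 95.0},
    "T1": {"background": 2.0, "csf": 30.0, "gm": 60.0, "wm": 85.0, LESION: 60.0},
}
_SDS = {
    ("FLAIR", "1.5T"): 8.0,
    ("FLAIR", "3T"): 5.0,
    ("T1", "1.5T"): 6.0,
    ("T1", "3T"): 4.0,
}
_BACKGROUND_SD = 1.5

# Compartment semi-axes as fractions of the grid shape (outer boundary of each
# nested compartment) plus a central ventricle.
_GEOMETRY = {
    "brain": (0.44, 0.41, 0.38),
    "gm": (0.39, 0.36, 0.33),
    "wm": (0.31, 0.285, 0.26),
    "ventricle": (0.09, 0.06, 0.06),
}

MIN_LESION_DIAMETER_MM = 3.0
_SPHERE_3MM_MM3 = 4.0 / 3.0 * np.pi * 1.5**3  # 14.137 mm^3


class GenerationError(RuntimeError):
    """Raised when a phantom cannot be generated under the requested spec."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    ``tissue_means``/``tissue_sds`` map modality -> tissue -> value and default
    to the field-strength presets.  ``bias_amplitude`` is the fractional
    amplitude of a smooth multiplicative bias field (0 disables it).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    field_strength: str = "3T"
    tissue_means: Optional[dict] = None
    tissue_sds: Optional[dict] = None
    lesion_count: int = 3
    lesion_diameter_range_mm: tuple[float, float] = (5.0, 10.0)
    bias_amplitude: float = 0.05
    gm_scale: float = 1.0  # multiplier on the GM outer semi-axes (cohort use)
    brain_scale: float = 1.0  # global head-size multiplier on all compartments
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 16:
            raise ValidationError(f"grid_shape must be 3 ints >= 16, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if self.field_strength not in ("1.5T", "3T"):
            raise ValidationError(f"field_strength must be 1.5T or 3T, got {self.field_strength}")
        if self.tissue_means is None:
            self.tissue_means = {m: dict(_MEANS[m]) for m in _MEANS}
        if self.tissue_sds is None:
            self.tissue_sds = {
                m: {t: _SDS[(m, self.field_strength)] for t in _MEANS[m] if t != "background"}
                | {"background": _BACKGROUND_SD}
                for m in _MEANS
            }
        if self.lesion_count < 0:
            raise ValidationError("lesion_count must be >= 0")
        lo, hi = self.lesion_diameter_range_mm
        if lo < MIN_LESION_DIAMETER_MM or hi < lo:
            raise ValidationError(
                f"lesion diameters must satisfy {MIN_LESION_DIAMETER_MM} <= min <= max, "
                f"got {self.lesion_diameter_range_mm}"
            )
        if not 0.0 <= self.bias_amplitude <= 0.3:
            raise ValidationError("bias_amplitude must be in [0, 0.3]")
        if self.tissue_means["FLAIR"][LESION] <= self.tissue_means["FLAIR"]["wm"]:
            raise ValidationError("FLAIR lesion mean must exceed FLAIR WM mean")

    def as_json_dict(self) -> dict:
        return dataclasses.asdict(self)


def preset_spec(field_strength: str = "3T", **overrides) -> PhantomSpec:
    """Spec with the default intensity preset for a field strength."""
    return PhantomSpec(field_strength=field_strength, **overrides)


@dataclass
class PhantomCase:
    """A generated subject: paired images plus exact ground truth."""

    t1: ImageVolume
    flair: ImageVolume
    truth_tissue: TissueLabelMap
    truth_lesions: LesionMask
    spec: PhantomSpec

    def write(self, out_dir, stem: str = "case") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(self.t1, out / f"{stem}_t1.nii.gz")
        write_volume(self.flair, out / f"{stem}_flair.nii.gz")
        write_label_map(self.truth_tissue, out / f"{stem}_labels.nii.gz")
        write_lesion_mask(self.truth_lesions, out / f"{stem}_lesions.nii.gz")
        sidecar = {"spec": self.spec.as_json_dict(), "seed": self.spec.seed}
        (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2, default=str))


# ---------------------------------------------------------------------------
# Geometry


def _coordinate_grid(shape) -> list[np.ndarray]:
    return np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")


def _ellipsoid_quadratic(coords, center, semiaxes) -> np.ndarray:
    f = np.zeros_like(coords[0])
    for x, c, a in zip(coords, center, semiaxes):
        f += ((x - c) / a) ** 2
    return f


def _anatomy_labels(
    shape,
    gm_scale: float = 1.0,
    brain_scale: float = 1.0,
    displacement: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Nested-compartment label map, optionally on displaced coordinates.

    ``displacement`` (3, *shape), in voxels, deforms the anatomy smoothly by
    evaluating the compartment level-sets at x + u(x).
    """
    center = [(n - 1) / 2.0 for n in shape]
    coords = _coordinate_grid(shape)
    if displacement is not None:
        coords = [x + u for x, u in zip(coords, displacement)]
    semi = {
        k: [f * n * brain_scale for f, n in zip(v, shape)] for k, v in _GEOMETRY.items()
    }
    semi["gm"] = [a * gm_scale for a in semi["gm"]]
    fields = {k: _ellipsoid_quadratic(coords, center, v) for k, v in semi.items()}

    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    labels[fields["brain"] <= 1] = CSF
    labels[fields["gm"] <= 1] = GM
    labels[fields["wm"] <= 1] = WM
    labels[fields["ventricle"] <= 1] = CSF
    return labels


def _check_compartments(labels: np.ndarray) -> None:
    for cls, name in ((CSF, "CSF"), (GM, "GM"), (WM, "WM")):
        if not (labels == cls).any():
            raise GenerationError(f"deformation collapsed the {name} compartment")
    if not (labels == BACKGROUND).any():
        raise GenerationError("deformation removed the background margin")
    # nesting sanity: WM is wrapped by the GM ribbon and CSF shell; if the
    # deformation is strong enough that WM touches background, the nested
    # compartments have inverted
    wm_rim = ndimage.binary_dilation(labels == WM) & (labels == BACKGROUND)
    if wm_rim.any():
        raise GenerationError(
            f"deformation inverts compartments: WM touches background at "
            f"{int(wm_rim.sum())} voxels"
        )


def _base_gm_voxels(shape, gm_scale: float = 1.0) -> float:
    """Analytic GM-shell volume (voxels) of the undeformed anatomy."""
    semi_gm = np.prod([f * n * gm_scale for f, n in zip(_GEOMETRY["gm"], shape)])
    semi_wm = np.prod([f * n for f, n in zip(_GEOMETRY["wm"], shape)])
    return 4.0 / 3.0 * np.pi * (semi_gm - semi_wm)


# ---------------------------------------------------------------------------
# Lesions


def _place_lesions(
    labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Ellipsoidal lesions fully inside WM, non-overlapping; 100 tries each."""
    mask = np.zeros(labels.shape, dtype=bool)
    if spec.lesion_count == 0:
        return mask
    spacing = np.asarray(spec.spacing)
    voxvol = float(np.prod(spacing))
    min_voxels = int(np.ceil(_SPHERE_3MM_MM3 / voxvol))
    wm = labels == WM
    coords = _coordinate_grid(labels.shape)
    placed = 0
    for _ in range(spec.lesion_count):
        ok = False
        for _attempt in range(100):
            d = rng.uniform(*spec.lesion_diameter_range_mm)
            semi_mm = np.maximum(d / 2.0 * rng.uniform(0.85, 1.15, size=3), 1.5)
            margin_vox = float(np.max(semi_mm / spacing)) + 1.0
            # interior distance (in voxels) of WM not already occupied
            free = wm & ~ndimage.binary_dilation(mask, iterations=1)
            dist = ndimage.distance_transform_edt(free)
            candidates = np.argwhere(dist >= margin_vox)
            if len(candidates) == 0:
                continue
            center = candidates[rng.integers(len(candidates))]
            f = np.zeros(labels.shape)
            for x, c, a, s in zip(coords, center, semi_mm, spacing):
                f += ((x - c) * s / a) ** 2
            blob = f <= 1.0
            if blob.sum() < min_voxels:
                continue
            if not wm[blob].all() or (mask & blob).any():
                continue
            mask |= blob
            placed += 1
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"could not place lesion {placed + 1} of {spec.lesion_count} in WM "
                f"(placed {placed})"
            )
    return mask


# ---------------------------------------------------------------------------
# Intensities


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape)
    coords = [2.0 * x / (n - 1) - 1.0 for x, n in zip(_coordinate_grid(shape), shape)]
    terms = [c for c in coords] + [c * c for c in coords] + [
        coords[0] * coords[1],
        coords[0] * coords[2],
        coords[1] * coords[2],
    ]
    w = rng.normal(size=len(terms))
    poly = sum(wi * t for wi, t in zip(w, terms))
    poly /= max(np.abs(poly).max(), 1e-12)
    return 1.0 + amplitude * poly


def _synthesise_modality(
    modality: str,
    labels: np.ndarray,
    lesions: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> ImageVolume:
    means = spec.tissue_means[modality]
    sds = spec.tissue_sds[modality]
    name_of = {BACKGROUND: "background", CSF: "csf", GM: "gm", WM: "wm"}
    mean_map = np.zeros(labels.shape)
    sd_map = np.zeros(labels.shape)
    for cls, name in name_of.items():
        sel = labels == cls
        mean_map[sel] = means[name]
        sd_map[sel] = sds[name]
    mean_map[lesions] = means[LESION]
    sd_map[lesions] = sds[LESION]
    # light smoothing of the noise-free image softens compartment boundaries
    clean = ndimage.gaussian_filter(mean_map, sigma=0.6)
    noisy = clean + rng.normal(size=labels.shape) * sd_map
    noisy *= _bias_field(labels.shape, spec.bias_amplitude, rng)
    return ImageVolume(
        data=np.clip(noisy, 0, None),
        spacing=spec.spacing,
        modality=modality,
        field_strength=spec.field_strength,
    )


def noise_free_means(spec: PhantomSpec, modality: str) -> dict:
    """Per-tissue noise-free mean intensities for a preset (test convenience)."""
    return dict(spec.tissue_means[modality])


# ---------------------------------------------------------------------------
# Generators


def generate_phantom(
    spec: PhantomSpec, displacement: Optional[np.ndarray] = None
) -> PhantomCase:
    """Generate one paired T1/FLAIR case with exact ground truth.

    Deterministic given ``spec.seed``.  ``displacement`` (voxels, shape
    (3, *grid)) optionally deforms the anatomy; used by the atlas-database
    generator.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _anatomy_labels(spec.grid_shape, spec.gm_scale, spec.brain_scale, displacement)
    _check_compartments(labels)
    lesions = _place_lesions(labels, spec, rng)
    flair = _synthesise_modality("FLAIR", labels, lesions, spec, rng)
    t1 = _synthesise_modality("T1", labels, lesions, spec, rng)
    truth = TissueLabelMap(labels=labels, spacing=spec.spacing)
    return PhantomCase(
        t1=t1,
        flair=flair,
        truth_tissue=truth,
        truth_lesions=LesionMask(mask=lesions, spacing=spec.spacing),
        spec=spec,
    )


def _smooth_displacement(
    shape, scale_mm: float, spacing, rng: np.random.Generator, sigma_vox: float = 8.0
) -> Optional[np.ndarray]:
    if scale_mm == 0:
        return None
    u = rng.normal(size=(3,) + tuple(shape))
    for ax in range(3):
        u[ax] = ndimage.gaussian_filter(u[ax], sigma=sigma_vox)
        u[ax] /= max(u[ax].std(), 1e-12)
        u[ax] *= scale_mm / spacing[ax]  # mm -> voxels per axis
    return u


def generate_atlas_database(
    n_subjects: int,
    base_spec: Optional[PhantomSpec] = None,
    deform_scale: float = 2.0,
    seed: Optional[int] = None,
):
    """Lesion-free atlas subjects: smoothly deformed anatomy with exact labels.

    Returns an :class:`flairvol.atlas.AtlasDatabase` whose entries carry both
    modalities and their ground-truth label maps.  Deterministic given the
    seed (defaults to ``base_spec.seed``).
    """
    from .atlas import AtlasDatabase, AtlasEntry

    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    if seed is None:
        seed = base_spec.seed
    root = np.random.SeedSequence(seed)
    entries = []
    for i, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        u = _smooth_displacement(base_spec.grid_shape, deform_scale, base_spec.spacing, rng)
        sub_seed = int(rng.integers(2**31 - 1))
        spec_i = dataclasses.replace(base_spec, lesion_count=0, seed=sub_seed)
        case = generate_phantom(spec_i, displacement=u)
        entries.append(
            AtlasEntry(
                id=f"atlas{i:03d}",
                image_t1=case.t1,
                image_flair=case.flair,
                labels=case.truth_tissue,
            )
        )
    return AtlasDatabase(entries=entries)


@dataclass
class Cohort:
    """Generated subjects plus the companion per-case table."""

    subjects: list  # list of dicts: subject_id, age_years, cases {field: PhantomCase}
    table: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sub in self.subjects:
            for fieldstr, case in sub["cases"].items():
                case.write(out / sub["subject_id"], stem=fieldstr.replace(".", "p"))
        self.table.to_csv(out / "cohort.csv", index=False)


_COHORT_DEFAULTS = {
    "age_range": (18.0, 59.0),
    "age_slope_ml_per_year": -1.5,  # GM loss per year of age
    "gm_mean_ml": 500.0,  # population mean GM volume at the mean age
    "gm_resid_sd_ml": 5.0,
    "field_strengths": ("1.5T", "3T"),
    "lesion_count_range": (0, 0),
    "grid_shape": (64, 64, 64),
    "lesion_diameter_range_mm": (5.0, 10.0),
    "bias_amplitude": 0.05,
    "brain_scale_sd": 0.03,  # per-subject head-size variation (TIV spread)
}


def generate_cohort(
    n: int, spec_ranges: Optional[dict] = None, seed: int = 0, with_images: bool = True
) -> Cohort:
    """Cohort of paired-field-strength phantoms with an injected GM-age effect.

    Ages are uniform over ``age_range``; each subject's target GM volume is
    ``gm_mean_ml + slope * (age - mean age) + N(0, gm_resid_sd_ml)`` and the GM
    compartment is scaled analytically to hit it.  The voxel size is derived
    once from ``gm_mean_ml`` so the phantom GM lands on that scale.  Setting
    ``gm_mean_ml`` to None disables volume targeting (unit spacing retained),
    for cohorts whose purpose is lesion-method comparison rather than the age
    model.  The companion table records the measured (ground-truth label)
    volumes, one row per subject and field strength.

    ``with_images=False`` skips intensity synthesis (subjects carry no
    PhantomCase, only the table) — the fast path for statistical calibration
    runs that need many cohorts but only their ground-truth volumes.
    """
    if n < 2:
        raise ValidationError("cohort size must be >= 2")
    opts = dict(_COHORT_DEFAULTS)
    if spec_ranges:
        unknown = set(spec_ranges) - set(opts)
        if unknown:
            raise ValidationError(f"unknown spec_ranges keys: {sorted(unknown)}")
        opts.update(spec_ranges)

    rng = np.random.default_rng(seed)
    shape = tuple(opts["grid_shape"])
    age_lo, age_hi = opts["age_range"]
    ages = rng.uniform(age_lo, age_hi, size=n)
    mid_age = (age_lo + age_hi) / 2.0

    brain_scales = np.clip(1.0 + opts["brain_scale_sd"] * rng.standard_normal(n), 0.9, 1.1)
    if opts["gm_mean_ml"] is not None:
        v_gm_base = _base_gm_voxels(shape)  # voxels at gm_scale 1
        s = (opts["gm_mean_ml"] * 1000.0 / v_gm_base) ** (1.0 / 3.0)
        spacing = (s, s, s)
        targets = (
            opts["gm_mean_ml"]
            + opts["age_slope_ml_per_year"] * (ages - mid_age)
            + rng.normal(0, opts["gm_resid_sd_ml"], size=n)
        )
        if np.any(targets <= 0):
            raise GenerationError("age model produced a non-positive target GM volume")
        semi_wm = np.prod([f * d for f, d in zip(_GEOMETRY["wm"], shape)])
        semi_gm = np.prod([f * d for f, d in zip(_GEOMETRY["gm"], shape)])
        target_vox = targets * 1000.0 / s**3
        b3 = brain_scales**3
        gm_scales = (
            (target_vox * 3.0 / (4.0 * np.pi) / b3 + semi_wm) / semi_gm
        ) ** (1.0 / 3.0)
    else:
        spacing = (1.0, 1.0, 1.0)
        gm_scales = np.ones(n)

    lo_l, hi_l = opts["lesion_count_range"]
    lesion_counts = rng.integers(lo_l, hi_l + 1, size=n)

    subjects = []
    rows = []
    for i in range(n):
        sid = f"sub{i:03d}"
        case_seed = int(rng.integers(2**31 - 1))
        cases = {}
        if with_images:
            for fieldstr in opts["field_strengths"]:
                spec = PhantomSpec(
                    grid_shape=shape,
                    spacing=spacing,
                    field_strength=fieldstr,
                    lesion_count=int(lesion_counts[i]),
                    lesion_diameter_range_mm=tuple(opts["lesion_diameter_range_mm"]),
                    bias_amplitude=opts["bias_amplitude"],
                    gm_scale=float(gm_scales[i]),
                    brain_scale=float(brain_scales[i]),
                    seed=case_seed,  # same anatomy/lesions per subject; noise per preset
                )
                cases[fieldstr] = generate_phantom(spec)
            labels = next(iter(cases.values())).truth_tissue.labels
            lesion_ml = next(iter(cases.values())).truth_lesions.volume_ml
        else:
            # anatomy (hence ground truth) is field-independent: rasterise once
            labels = _anatomy_labels(shape, float(gm_scales[i]), float(brain_scales[i]))
            spec_l = PhantomSpec(
                grid_shape=shape,
                spacing=spacing,
                lesion_count=int(lesion_counts[i]),
                lesion_diameter_range_mm=tuple(opts["lesion_diameter_range_mm"]),
                gm_scale=float(gm_scales[i]),
                brain_scale=float(brain_scales[i]),
                seed=case_seed,
            )
            lesion_rng = np.random.default_rng(case_seed)
            lesion_ml = voxel_count_to_ml(
                int(_place_lesions(labels, spec_l, lesion_rng).sum()), spacing
            ) if lesion_counts[i] else 0.0
        for fieldstr in opts["field_strengths"]:
            rows.append(
                {
                    "subject_id": sid,
                    "age_years": float(ages[i]),
                    "field_strength": fieldstr,
                    "true_gm_ml": voxel_count_to_ml(int((labels == GM).sum()), spacing),
                    "true_wm_ml": voxel_count_to_ml(int((labels == WM).sum()), spacing),
                    "true_csf_ml": voxel_count_to_ml(int((labels == CSF).sum()), spacing),
                    "true_lesion_ml": lesion_ml,
                }
            )
        subjects.append({"subject_id": sid, "age_years": float(ages[i]), "cases": cases})
    return Cohort(subjects=subjects, table=pd.DataFrame(rows))
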