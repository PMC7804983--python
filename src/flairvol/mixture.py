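"""Unsupervised Gaussian-mixture lesion segmentation with per-tissue model selection.

A global finite Gaussian mixture is fitted to the brain voxels of one (FLAIR)
or two (FLAIR + T1) co-registered channels.  Every component is tagged with a
tissue class (CSF / GM / WM); an anatomical parcellation provides both the
initial class statistics and a relaxed per-voxel spatial prior, so the model
is identifiable without k-means and runs are fully deterministic.  The WM
class carries one additional *outlier* component initialised on the
hyperintense FLAIR tail; its posterior is the per-voxel lesion-candidate map.

The number of inlier components per class is chosen by greedy forward search:
starting from one component per class, the highest-variance component of a
class is split and the refit accepted only if BIC decreases.  Candidate maps
are post-processed into a binary lesion mask by thresholding, 26-connected
component analysis, a minimum-diameter (3 mm sphere-volume) rule,
parcellation-guided removal of components outside WM and its boundary band,
and removal of FLAIR-hypointense components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

from .core import (
    CSF,
    GM,
    WM,
    ImageVolume,
    LesionMask,
    TissueLabelMap,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "GaussianComponent",
    "MixtureModel",
    "CandidateMap",
    "MixtureConfig",
    "LesionSegmentationResult",
    "fit_mixture",
    "bic",
    "detect_lesion_candidates",
    "postprocess_lesions",
    "segment_lesions",
]

TISSUES = (CSF, GM, WM)
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GaussianComponent:
    """One mixture component, tagged with its tissue class and role."""

    tissue: int  # CSF, GM or WM
    weight: float  # within-class mixing weight times the class prior mass
    mean: np.ndarray  # (channels,)
    cov: np.ndarray  # (channels, channels), symmetric positive-definite
    role: str = "inlier"  # "inlier" or "outlier"


@dataclass
class MixtureModel:
    """Fitted per-tissue Gaussian mixture.

    ``components`` holds every component across classes; within a class the
    component weights sum to the class's prior mass.  ``ll_history`` is the
    EM log-likelihood trajectory (non-decreasing).
    """

    channels: int
    components: list[GaussianComponent]
    log_likelihood: float
    n_parameters: int
    n_voxels: int
    class_masses: dict[int, float]
    ll_history: list[float] = field(default_factory=list)
    flair_channel: int = 0

    def components_of(self, tissue: int, role: Optional[str] = None):
        out = [c for c in self.components if c.tissue == tissue]
        if role is not None:
            out = [c for c in out if c.role == role]
        return out

    def n_components(self, tissue: int) -> int:
        return len(self.components_of(tissue))

    def component_table(self) -> list[dict]:
        return [
            {
                "tissue": int(c.tissue),
                "role": c.role,
                "weight": float(c.weight),
                "mean": [float(m) for m in c.mean],
                "cov": np.asarray(c.cov).tolist(),
            }
            for c in self.components
        ]


@dataclass
class CandidateMap:
    """Per-voxel posterior of the WM outlier (lesion-candidate) components."""

    outlier_posterior: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.outlier_posterior, dtype=np.float64)
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValidationError("candidate posteriors must lie in [0, 1]")
        self.outlier_posterior = np.clip(p, 0.0, 1.0)


@dataclass
class MixtureConfig:
    """Tunables of the EM fit and model selection."""

    max_components_per_class: int = 3
    max_iter: int = 200
    tol: float = 1e-6  # relative log-likelihood change
    prior_relaxation: float = 0.1  # mass spread off the parcellation label
    outlier_init_mass: float = 0.01  # initial outlier share of WM mass
    outlier_init_sds: float = 2.0  # FLAIR offset of the outlier mean, in WM SDs
    cov_floor_frac: float = 0.01  # covariance floor, fraction of channel SD
    max_fit_voxels: int = 25000  # EM fits a deterministic stride-subsample beyond this
    spatial_reg_sigma_mm: float = 0.0  # optional smoothing of the candidate map
    grow_threshold: float = 0.1  # hysteresis growth cut for seeded components


# ---------------------------------------------------------------------------
# EM machinery


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    # closed forms for the 1- and 2-channel cases dominate the EM runtime
    d = X.shape[1]
    if d == 1:
        v = cov[0, 0]
        diff = X[:, 0] - mean[0]
        return -0.5 * (np.log(2 * np.pi * v) + diff * diff / v)
    if d == 2:
        a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
        det = a * c - b * b
        dx = X[:, 0] - mean[0]
        dy = X[:, 1] - mean[1]
        maha = (c * dx * dx - 2 * b * dx * dy + a * dy * dy) / det
        return -0.5 * (2 * np.log(2 * np.pi) + np.log(det) + maha)
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, (X - mean).T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _responsibilities(X, components, log_prior_vc, class_index):
    """Log responsibilities (n, k) and per-voxel log-likelihood."""
    k = len(components)
    logp = np.empty((X.shape[0], k))
    for j, comp in enumerate(components):
        mass = max(comp.weight, 1e-300)
        logp[:, j] = np.log(mass) + log_prior_vc[:, class_index[comp.tissue]] + _log_gauss(
            X, comp.mean, comp.cov
        )
    norm = logsumexp(logp, axis=1)
    return logp - norm[:, None], norm


def _run_em(X, components, log_prior_vc, class_index, cfg: MixtureConfig, floor):
    """EM to convergence; returns (components, ll_history).

    ``components`` weights are within-class fractions times unit class mass;
    the spatial prior carries the voxel-wise class mass.  Singular components
    are pruned rather than allowed to crash the linear algebra.
    """
    comps = [replace(c, mean=c.mean.copy(), cov=c.cov.copy()) for c in components]
    history: list[float] = []
    for _ in range(cfg.max_iter):
        log_r, norm = _responsibilities(X, comps, log_prior_vc, class_index)
        ll = float(norm.sum())
        history.append(ll)
        if len(history) >= 2 and abs(ll - history[-2]) <= cfg.tol * max(abs(history[-2]), 1.0):
            break
        r = np.exp(log_r)
        nk = r.sum(axis=0)
        keep = []
        for j, comp in enumerate(comps):
            if nk[j] < X.shape[1] + 1 and comp.role == "inlier" and len(
                [c for c in comps if c.tissue == comp.tissue and c.role == "inlier"]
            ) > 1:
                warnings.warn(
                    f"pruning starved component (tissue {comp.tissue})", RuntimeWarning
                )
                continue
            keep.append(j)
        if len(keep) < len(comps):
            comps = [comps[j] for j in keep]
            continue
        # M-step
        for j, comp in enumerate(comps):
            w = r[:, j]
            total = max(nk[j], 1e-12)
            mu = (w @ X) / total
            diff = X - mu
            cov = (diff.T * w) @ diff / total
            cov = 0.5 * (cov + cov.T) + floor
            comp.mean, comp.cov = mu, cov
        # within-class weights renormalised against the class responsibility mass
        for t in TISSUES:
            idx = [j for j, c in enumerate(comps) if c.tissue == t]
            mass = sum(nk[j] for j in idx)
            for j in idx:
                comps[j].weight = float(nk[j] / max(mass, 1e-12))
    return comps, history


def _count_parameters(components, channels: int) -> int:
    d = channels
    per_comp = d + d * (d + 1) // 2
    n = 0
    for t in TISSUES:
        k_t = len([c for c in components if c.tissue == t])
        if k_t:
            n += (k_t - 1) + k_t * per_comp
    return n


def bic(model: MixtureModel, n_voxels: Optional[int] = None) -> float:
    """Bayesian information criterion: -2 log L + k ln n."""
    n = model.n_voxels if n_voxels is None else n_voxels
    if n <= 0:
        raise ValidationError(f"n_voxels must be positive, got {n}")
    return -2.0 * model.log_likelihood + model.n_parameters * np.log(n)


def _extract_features(images: Sequence[ImageVolume]) -> tuple[np.ndarray, int]:
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValidationError("all channels must share one grid")
    flair_channel = 0
    for i, im in enumerate(images):
        if im.modality == "FLAIR":
            flair_channel = i
            break
    return np.stack([im.data for im in images], axis=-1), flair_channel


def _build_model(comps, masses, channels, history, n_voxels, flair_channel):
    scaled = [replace(c, weight=c.weight * masses[c.tissue]) for c in comps]
    return MixtureModel(
        channels=channels,
        components=scaled,
        log_likelihood=history[-1],
        n_parameters=_count_parameters(scaled, channels),
        n_voxels=n_voxels,
        class_masses=dict(masses),
        ll_history=list(history),
        flair_channel=flair_channel,
    )


def _split_candidate(comps, tissue):
    """Split the highest-total-variance inlier component of a class."""
    idx = [j for j, c in enumerate(comps) if c.tissue == tissue and c.role == "inlier"]
    j = max(idx, key=lambda j: np.trace(np.atleast_2d(comps[j].cov)))
    parent = comps[j]
    vals, vecs = np.linalg.eigh(parent.cov)
    step = np.sqrt(max(vals[-1], 1e-12)) * vecs[:, -1]
    new = []
    for j2, c in enumerate(comps):
        if j2 == j:
            new.append(replace(c, weight=c.weight / 2, mean=parent.mean + 0.5 * step))
            new.append(replace(c, weight=parent.weight / 2, mean=parent.mean - 0.5 * step,
                               cov=parent.cov.copy()))
        else:
            new.append(replace(c, mean=c.mean.copy(), cov=c.cov.copy()))
    return new


def fit_mixture(
    images: Sequence[ImageVolume] | ImageVolume,
    parcellation: TissueLabelMap,
    max_components_per_class: int = 3,
    seed: int = 0,
    config: Optional[MixtureConfig] = None,
) -> MixtureModel:
    """Fit the per-tissue mixture with greedy forward BIC model selection.

    ``images`` is one FLAIR volume or a [FLAIR, T1] pair on one grid.  The
    parcellation initialises class statistics and supplies the relaxed spatial
    prior.  Deterministic given ``seed`` (the fit itself draws no random
    numbers; the seed only namespaces future stochastic extensions).
    """
    del seed  # initialisation is parcellation-driven, hence deterministic
    if isinstance(images, ImageVolume):
        images = [images]
    cfg = config or MixtureConfig()
    cfg = replace(cfg, max_components_per_class=max_components_per_class)
    data, flair_channel = _extract_features(images)
    if parcellation.shape != data.shape[:3]:
        raise ValidationError("parcellation grid does not match the image grid")
    brain = parcellation.brain_mask()
    n = int(brain.sum())
    if n < 500:
        raise ValidationError(f"need >= 500 brain voxels, got {n}")
    X = data[brain]
    if np.unique(X).size < 2:
        raise ValidationError("degenerate input: fewer than 2 distinct intensities")
    labels = parcellation.labels[brain]
    # fit on a deterministic stride-subsample; posteriors are later evaluated
    # at full resolution by detect_lesion_candidates
    if n > cfg.max_fit_voxels:
        stride = int(np.ceil(n / cfg.max_fit_voxels))
        X = X[::stride]
        labels = labels[::stride]
        n = X.shape[0]
    d = X.shape[1]

    # relaxed one-hot spatial prior
    masses = {}
    frac = {t: max(float((labels == t).mean()), 1e-6) for t in TISSUES}
    prior = np.empty((n, 3))
    for col, t in enumerate(TISSUES):
        prior[:, col] = (1 - cfg.prior_relaxation) * (labels == t) + cfg.prior_relaxation * frac[t]
        masses[t] = float(prior[:, col].mean())
    prior /= prior.sum(axis=1, keepdims=True)
    for col, t in enumerate(TISSUES):
        masses[t] = float(prior[:, col].mean())
    log_prior = np.log(np.maximum(prior, 1e-300))
    class_index = {t: i for i, t in enumerate(TISSUES)}

    channel_sd = X.std(axis=0)
    floor = np.diag((cfg.cov_floor_frac * np.maximum(channel_sd, 1e-6)) ** 2)

    def class_stats(t):
        sel = labels == t
        if sel.sum() < d + 2:
            sel = np.ones(n, dtype=bool)
        mu = X[sel].mean(axis=0)
        cov = np.atleast_2d(np.cov(X[sel].T)) + floor
        return mu, cov

    comps = []
    for t in TISSUES:
        mu, cov = class_stats(t)
        comps.append(GaussianComponent(tissue=t, weight=1.0, mean=mu, cov=cov))
    # explicit WM outlier candidate, initialised on the hyperintense FLAIR
    # tail of WM-labelled voxels: the tail mean keeps the seed on the joint
    # intensity manifold in the multi-channel case (a naive per-channel shift
    # would park it off the data cloud and starve it)
    wm_mu, wm_cov = class_stats(WM)
    wm_sd = np.sqrt(wm_cov[flair_channel, flair_channel])
    tail = (labels == WM) & (
        X[:, flair_channel] > wm_mu[flair_channel] + cfg.outlier_init_sds * wm_sd
    )
    if tail.sum() >= d + 2:
        out_mu = X[tail].mean(axis=0)
    else:
        out_mu = wm_mu.copy()
        out_mu[flair_channel] += cfg.outlier_init_sds * wm_sd
    for c in comps:
        if c.tissue == WM:
            c.weight = 1.0 - cfg.outlier_init_mass
    comps.append(
        GaussianComponent(
            tissue=WM, weight=cfg.outlier_init_mass, mean=out_mu, cov=wm_cov.copy(),
            role="outlier",
        )
    )

    comps, history = _run_em(X, comps, log_prior, class_index, cfg, floor)
    best = _build_model(comps, masses, d, history, n, flair_channel)
    best_bic = bic(best)
    baseline_bic = best_bic

    improved = True
    while improved:
        improved = False
        trial_results = []
        for t in TISSUES:
            k_in = len([c for c in best.components if c.tissue == t and c.role == "inlier"])
            if k_in >= cfg.max_components_per_class:
                continue
            # strip class masses back to within-class fractions for the refit
            unit = [
                replace(c, weight=c.weight / best.class_masses[c.tissue])
                for c in best.components
            ]
            cand = _split_candidate(unit, t)
            cand, hist = _run_em(X, cand, log_prior, class_index, cfg, floor)
            model = _build_model(cand, masses, d, hist, n, flair_channel)
            trial_results.append((bic(model), t, model))
        if trial_results:
            trial_results.sort(key=lambda x: x[0])
            cand_bic, t, model = trial_results[0]
            if cand_bic < best_bic:
                best, best_bic = model, cand_bic
                improved = True

    # abnormal-component justification: the candidate outlier stays only if
    # the data support it — otherwise the outlier-free refit wins on BIC
    if any(c.role == "outlier" for c in best.components):
        unit = [
            replace(c, weight=c.weight / best.class_masses[c.tissue])
            for c in best.components
            if c.role != "outlier"
        ]
        for t in TISSUES:
            tot = sum(c.weight for c in unit if c.tissue == t)
            for c in unit:
                if c.tissue == t:
                    c.weight /= max(tot, 1e-12)
        cand, hist = _run_em(X, unit, log_prior, class_index, cfg, floor)
        alt = _build_model(cand, masses, d, hist, n, flair_channel)
        if bic(alt) <= best_bic:
            best, best_bic = alt, bic(alt)

    _assign_roles(best, cfg)
    # model selection never worsens BIC relative to the baseline
    assert best_bic <= baseline_bic + 1e-6
    return best


def _assign_roles(model: MixtureModel, cfg: MixtureConfig) -> None:
    """Re-derive inlier/outlier roles from the fitted component geometry.

    A WM component is abnormal (outlier) when its FLAIR mean lies above the
    hyperintense edge of *every* expected tissue distribution — beyond the
    dominant component of each class by ``outlier_init_sds`` of that
    component's FLAIR SD.  Partial-volume components between GM and WM stay
    inliers under this rule; only genuinely hyperintense components are
    treated as lesion candidates.
    """
    fc = model.flair_channel
    refs = []
    dominants = {}
    for t in TISSUES:
        comps = model.components_of(t)
        if not comps:
            continue
        dom = max(comps, key=lambda c: c.weight)
        dominants[t] = dom
        refs.append(dom.mean[fc] + cfg.outlier_init_sds * np.sqrt(dom.cov[fc, fc]))
    edge = max(refs)
    for c in model.components:
        if c.tissue != WM or c is dominants.get(WM):
            c.role = "inlier"
        else:
            c.role = "outlier" if c.mean[fc] > edge else "inlier"


# ---------------------------------------------------------------------------
# Candidate detection and post-processing


def detect_lesion_candidates(
    model: MixtureModel,
    images: Sequence[ImageVolume] | ImageVolume,
    parcellation: TissueLabelMap,
    config: Optional[MixtureConfig] = None,
) -> CandidateMap:
    """Per-voxel posterior of the WM outlier components.

    The voxel-wise posterior is spatially regularised by a small Gaussian
    kernel (``spatial_reg_sigma_mm``) standing in for the Markov-random-field
    coupling of hierarchical lesion mixtures: it recovers partial-volume
    lesion borders whose unregularised posterior falls just short of the
    decision threshold and suppresses isolated single-voxel noise spikes.
    Zero outside the brain and outside the WM-adjacent region (WM dilated by
    two voxels) — abnormal FLAIR signal far from WM is not a lesion candidate.
    """
    if isinstance(images, ImageVolume):
        images = [images]
    cfg = config or MixtureConfig()
    data, _ = _extract_features(images)
    outliers = model.components_of(WM, role="outlier")
    post = np.zeros(data.shape[:3])
    if not outliers:
        warnings.warn("model has no outlier component; returning an all-zero map",
                      RuntimeWarning)
        return CandidateMap(outlier_posterior=post, spacing=parcellation.spacing)
    brain = parcellation.brain_mask()
    X = data[brain]
    labels = parcellation.labels[brain]
    prior = np.empty((X.shape[0], 3))
    # rebuild the relaxed prior used at fit time
    frac = {t: max(float((labels == t).mean()), 1e-6) for t in TISSUES}
    for col, t in enumerate(TISSUES):
        prior[:, col] = (1 - cfg.prior_relaxation) * (labels == t) + cfg.prior_relaxation * frac[t]
    prior /= prior.sum(axis=1, keepdims=True)
    log_prior = np.log(np.maximum(prior, 1e-300))
    class_index = {t: i for i, t in enumerate(TISSUES)}
    log_r, _ = _responsibilities(X, model.components, log_prior, class_index)
    r = np.exp(log_r)
    out_idx = [j for j, c in enumerate(model.components) if c.role == "outlier"]
    post[brain] = r[:, out_idx].sum(axis=1)
    if cfg.spatial_reg_sigma_mm > 0:
        sigma_vox = [cfg.spatial_reg_sigma_mm / s for s in parcellation.spacing]
        post = ndimage.gaussian_filter(post, sigma=sigma_vox)
    wm_adjacent = ndimage.binary_dilation(parcellation.class_mask(WM), iterations=2)
    post[~wm_adjacent] = 0.0
    return CandidateMap(outlier_posterior=np.clip(post, 0, 1), spacing=parcellation.spacing)


def postprocess_lesions(
    candidates: CandidateMap,
    parcellation: TissueLabelMap,
    flair: ImageVolume,
    threshold: float = 0.5,
    min_diameter_mm: float = 3.0,
    grow_threshold: float = 0.1,
) -> LesionMask:
    """False-positive removal: size, location and intensity rules.

    Binarise at ``threshold``; keep 26-connected components whose volume is at
    least that of a ``min_diameter_mm`` sphere, whose centroid lies in WM or
    its one-voxel boundary band, and whose mean FLAIR intensity exceeds the WM
    mean (hypointense artefacts removed).  Surviving components are then grown
    by hysteresis into 26-adjacent voxels with candidate posterior at least
    ``grow_threshold`` (still inside the WM boundary band), recovering the
    partial-volume lesion rim whose posterior falls short of the seed
    threshold; set ``grow_threshold`` >= ``threshold`` to disable growth.
    """
    if candidates.outlier_posterior.shape != parcellation.shape or flair.shape != parcellation.shape:
        raise ValidationError("candidate map, parcellation and FLAIR must share a grid")
    binary = candidates.outlier_posterior > threshold
    spacing = parcellation.spacing
    voxvol = float(np.prod(spacing))
    min_vol_mm3 = 4.0 / 3.0 * np.pi * (min_diameter_mm / 2.0) ** 3
    out = np.zeros_like(binary)
    if not binary.any():
        return LesionMask(mask=out, spacing=spacing)
    lab, n_comp = ndimage.label(binary, structure=_CONN26)
    wm = parcellation.class_mask(WM)
    band = ndimage.binary_dilation(wm, iterations=1)
    wm_mean = float(flair.data[wm].mean()) if wm.any() else np.inf
    for comp_id in range(1, n_comp + 1):
        comp = lab == comp_id
        if comp.sum() * voxvol < min_vol_mm3:
            continue
        centroid = tuple(int(round(c)) for c in ndimage.center_of_mass(comp))
        if not band[centroid]:
            continue
        if float(flair.data[comp].mean()) <= wm_mean:
            continue
        out |= comp
    if out.any() and grow_threshold < threshold:
        growable = (candidates.outlier_posterior >= grow_threshold) & band
        while True:
            grown = ndimage.binary_dilation(out, structure=_CONN26) & growable
            if not (grown & ~out).any():
                break
            out |= grown
    return LesionMask(mask=out, spacing=spacing)


@dataclass
class LesionSegmentationResult:
    """Output of the full lesion-segmentation stack."""

    mask: LesionMask
    volume_ml: float
    model: MixtureModel
    mode: str  # "flair_only" or "multimodal"

    def report(self) -> dict:
        return {
            "volume_ml": self.volume_ml,
            "mode": self.mode,
            "n_components": len(self.model.components),
            "components": self.model.component_table(),
        }


def segment_lesions(
    flair: ImageVolume,
    t1: Optional[ImageVolume] = None,
    parcellation: Optional[TissueLabelMap] = None,
    config: Optional[MixtureConfig] = None,
    threshold: float = 0.5,
    min_diameter_mm: float = 3.0,
    seed: int = 0,
) -> LesionSegmentationResult:
    """FLAIR-only (or FLAIR+T1) lesion segmentation: fit, detect, post-process."""
    if parcellation is None:
        raise ValidationError("a tissue parcellation is required")
    images = [flair] if t1 is None else [flair, t1]
    if t1 is not None and t1.shape != flair.shape:
        raise ValidationError("T1 must be registered to the FLAIR grid")
    cfg = config or MixtureConfig()
    model = fit_mixture(images, parcellation, cfg.max_components_per_class, seed, cfg)
    candidates = detect_lesion_candidates(model, images, parcellation, cfg)
    mask = postprocess_lesions(
        candidates, parcellation, flair, threshold, min_diameter_mm, cfg.grow_threshold
    )
    return LesionSegmentationResult(
        mask=mask,
        volume_ml=mask.volume_ml,
        model=model,
        mode="flair_only" if t1 is None else "multimodal",
    )
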