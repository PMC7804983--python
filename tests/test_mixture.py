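"""Gaussian-mixture lesion segmentation: EM, model selection, post-processing."""

import numpy as np
import pytest
from scipy import ndimage

import flairvol as fv
from flairvol.core import CSF, GM, WM, ImageVolume, TissueLabelMap, ValidationError
from flairvol.mixture import (
    CandidateMap,
    MixtureConfig,
    bic,
    detect_lesion_candidates,
    fit_mixture,
    postprocess_lesions,
    segment_lesions,
)


def single_gaussian_image(truth, rng, sds=5.0):
    """Image drawn from exactly one Gaussian per class; returns image + sample means."""
    means = {0: 0.0, CSF: 30.0, GM: 70.0, WM: 55.0}
    labels = truth.labels
    data = np.zeros(labels.shape)
    sample_means = {}
    for cls, mu in means.items():
        sel = labels == cls
        draws = mu + sds * rng.standard_normal(int(sel.sum()))
        data[sel] = draws
        sample_means[cls] = draws.mean()
    return ImageVolume(np.clip(data, 0, None), modality="FLAIR"), sample_means


class TestFitMixture:
    def test_em_loglik_monotone_flair_only(self, fitted_model_3t):
        h = np.asarray(fitted_model_3t.ll_history)
        assert np.all(np.diff(h) >= -1e-8 * np.abs(h[:-1]))

    def test_em_loglik_monotone_multimodal(self, case_3t):
        m = fit_mixture([case_3t.flair, case_3t.t1], case_3t.truth_tissue)
        h = np.asarray(m.ll_history)
        assert np.all(np.diff(h) >= -1e-8 * np.abs(h[:-1]))

    def test_single_gaussian_per_class_selects_one_component(self, lesion_free_case, rng):
        img, sample_means = single_gaussian_image(lesion_free_case.truth_tissue, rng)
        model = fit_mixture(img, lesion_free_case.truth_tissue)
        for cls in (CSF, GM, WM):
            comps = model.components_of(cls)
            assert len(comps) == 1
            fitted = comps[0].mean[0]
            assert abs(fitted - sample_means[cls]) / abs(sample_means[cls]) < 0.02

    def test_lesion_free_outlier_weight_negligible(self, lesion_free_case):
        model = fit_mixture(lesion_free_case.flair, lesion_free_case.truth_tissue)
        out_mass = sum(c.weight for c in model.components_of(WM, role="outlier"))
        assert out_mass / model.class_masses[WM] < 0.005

    def test_class_weights_sum_to_class_mass(self, fitted_model_3t):
        for cls in (CSF, GM, WM):
            total = sum(c.weight for c in fitted_model_3t.components_of(cls))
            assert total == pytest.approx(fitted_model_3t.class_masses[cls], abs=1e-6)

    def test_at_least_one_inlier_per_class(self, fitted_model_3t):
        for cls in (CSF, GM, WM):
            assert fitted_model_3t.components_of(cls, role="inlier")

    def test_selection_never_worse_than_baseline(self, case_3t):
        baseline = fit_mixture(
            case_3t.flair, case_3t.truth_tissue,
            config=MixtureConfig(max_components_per_class=1),
        )
        selected = fit_mixture(case_3t.flair, case_3t.truth_tissue)
        assert bic(selected) <= bic(baseline) + 1e-6

    def test_degenerate_constant_image_rejected(self, lesion_free_case):
        img = ImageVolume(np.full(lesion_free_case.flair.shape, 5.0), modality="FLAIR")
        with pytest.raises(ValidationError, match="distinct"):
            fit_mixture(img, lesion_free_case.truth_tissue)

    def test_too_few_brain_voxels_rejected(self, rng):
        labels = np.zeros((16, 16, 16), dtype=int)
        labels[8, 8, :3] = WM
        labels[8, 7, :3] = GM
        labels[8, 6, :3] = CSF
        img = ImageVolume(rng.normal(size=(16, 16, 16)) + 10)
        with pytest.raises(ValidationError, match="500"):
            fit_mixture(img, TissueLabelMap(labels))


class TestBic:
    def test_hand_arithmetic(self):
        m = type("M", (), {"log_likelihood": -100.0, "n_parameters": 4, "n_voxels": 1})()
        # -2*(-100) + 4*ln(e^2) = 200 + 8
        assert bic(m, n_voxels=np.e**2) == pytest.approx(208.0)
        assert bic(m, n_voxels=1) == pytest.approx(200.0)  # ln 1 = 0

    def test_extra_parameter_increases_bic(self, fitted_model_3t):
        import copy

        bigger = copy.copy(fitted_model_3t)
        bigger.n_parameters = fitted_model_3t.n_parameters + 1
        assert bic(bigger) > bic(fitted_model_3t)

    def test_nonpositive_n_rejected(self, fitted_model_3t):
        with pytest.raises(ValidationError):
            bic(fitted_model_3t, n_voxels=0)


class TestCandidates:
    def test_lesion_voxels_receive_high_posterior(self, case_3t, fitted_model_3t):
        cand = detect_lesion_candidates(fitted_model_3t, case_3t.flair, case_3t.truth_tissue)
        p = cand.outlier_posterior
        true = case_3t.truth_lesions.mask
        assert (p[true] > 0.5).mean() >= 0.5

    def test_zero_outside_wm_adjacent_region(self, case_3t, fitted_model_3t):
        cand = detect_lesion_candidates(fitted_model_3t, case_3t.flair, case_3t.truth_tissue)
        wm_adjacent = ndimage.binary_dilation(
            case_3t.truth_tissue.labels == WM, iterations=2
        )
        assert (cand.outlier_posterior[~wm_adjacent] == 0).all()

    def test_model_without_outlier_yields_zero_map(self, lesion_free_case):
        model = fit_mixture(lesion_free_case.flair, lesion_free_case.truth_tissue)
        assert not model.components_of(WM, role="outlier")
        with pytest.warns(RuntimeWarning, match="no outlier"):
            cand = detect_lesion_candidates(
                model, lesion_free_case.flair, lesion_free_case.truth_tissue
            )
        assert (cand.outlier_posterior == 0).all()

    def test_posterior_bounds_validated(self):
        with pytest.raises(ValidationError):
            CandidateMap(np.full((8, 8, 8), 1.5), spacing=(1, 1, 1))


class TestPostprocess:
    def test_small_component_removed(self, case_3t):
        p = np.zeros(case_3t.flair.shape)
        wm = case_3t.truth_tissue.labels == WM
        centre = tuple(int(c) for c in ndimage.center_of_mass(wm))
        p[centre[0] : centre[0] + 2, centre[1] : centre[1] + 2, centre[2] : centre[2] + 2] = 0.9
        cand = CandidateMap(p, spacing=(1, 1, 1))
        mask = postprocess_lesions(cand, case_3t.truth_tissue, case_3t.flair)
        assert not mask.mask.any()  # 8 voxels < 14.14 mm^3 sphere bound

    def test_empty_candidates_give_empty_mask(self, case_3t):
        cand = CandidateMap(np.zeros(case_3t.flair.shape), spacing=(1, 1, 1))
        mask = postprocess_lesions(cand, case_3t.truth_tissue, case_3t.flair)
        assert mask.volume_ml == 0.0

    def test_true_lesions_survive_speckles_die(self, case_3t, rng):
        p = np.where(case_3t.truth_lesions.mask, 0.95, 0.0)
        wm_idx = np.argwhere(
            (case_3t.truth_tissue.labels == WM)
            & ~ndimage.binary_dilation(case_3t.truth_lesions.mask, iterations=3)
        )
        for k in range(6):  # seeded 1-2 voxel noise speckles
            i, j, l = wm_idx[rng.integers(len(wm_idx))]
            p[i, j, l] = 0.9
            if k % 2:
                p[i, j, min(l + 1, p.shape[2] - 1)] = 0.9
        cand = CandidateMap(p, spacing=(1, 1, 1))
        mask = postprocess_lesions(cand, case_3t.truth_tissue, case_3t.flair)
        lab, n = ndimage.label(mask.mask, structure=np.ones((3, 3, 3)))
        truth_lab, n_true = ndimage.label(
            case_3t.truth_lesions.mask, structure=np.ones((3, 3, 3))
        )
        assert n == n_true

    def test_hypointense_component_removed(self, lesion_free_case):
        truth = lesion_free_case.truth_tissue
        wm = truth.labels == WM
        dist = ndimage.distance_transform_edt(wm)
        centre = tuple(np.argwhere(dist == dist.max())[0])
        p = np.zeros(lesion_free_case.flair.shape)
        sl = tuple(slice(c - 2, c + 2) for c in centre)  # 64 voxels, above size bound
        p[sl] = 0.9
        flair = lesion_free_case.flair.with_data(lesion_free_case.flair.data.copy())
        flair.data[sl] = 10.0  # hypointense artefact
        mask = postprocess_lesions(CandidateMap(p, spacing=(1, 1, 1)), truth, flair)
        assert not mask.mask.any()


class TestSegmentLesions:
    def test_flair_only_vs_multimodal_agreement(self, case_3t):
        flair_only = segment_lesions(case_3t.flair, None, case_3t.truth_tissue)
        multi = segment_lesions(case_3t.flair, case_3t.t1, case_3t.truth_tissue)
        assert flair_only.mode == "flair_only"
        assert multi.mode == "multimodal"
        assert fv.dice(flair_only.mask, multi.mask) >= 0.6

    def test_duplicated_flair_channels_match_flair_only(self, case_3t):
        flair_only = segment_lesions(case_3t.flair, None, case_3t.truth_tissue)
        dup = ImageVolume(
            case_3t.flair.data.copy(), case_3t.flair.spacing, modality="T1"
        )
        doubled = segment_lesions(case_3t.flair, dup, case_3t.truth_tissue)
        assert fv.dice(flair_only.mask, doubled.mask) >= 0.95

    def test_mask_inside_brain(self, case_3t):
        res = segment_lesions(case_3t.flair, None, case_3t.truth_tissue)
        assert not res.mask.mask[~case_3t.truth_tissue.brain_mask()].any()

    def test_deterministic(self, case_15t):
        a = segment_lesions(case_15t.flair, None, case_15t.truth_tissue)
        b = segment_lesions(case_15t.flair, None, case_15t.truth_tissue)
        np.testing.assert_array_equal(a.mask.mask, b.mask.mask)

    def test_volume_recovery_single_case(self, case_3t):
        res = segment_lesions(case_3t.flair, None, case_3t.truth_tissue)
        true = case_3t.truth_lesions.volume_ml
        assert abs(res.volume_ml - true) / true < 0.3

    def test_report_structure(self, case_3t):
        res = segment_lesions(case_3t.flair, None, case_3t.truth_tissue)
        rep = res.report()
        assert rep["mode"] == "flair_only"
        assert rep["volume_ml"] == pytest.approx(res.volume_ml)
        assert all({"tissue", "role", "weight", "mean"} <= set(c) for c in rep["components"])
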