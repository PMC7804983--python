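"""Agreement and comparison statistics for segmentation methods.

Implements the quantities used to compare lesion-segmentation and volumetry
methods: Dice similarity (DSC = 2TP / (2TP + FP + FN)), the directional
lesion-volume-difference proportion and the symmetric percentage volume
difference, through-origin (no-intercept) linear regression with uncentred R^2
and Gaussian AIC, Wilcoxon signed-rank and paired t tests, Cohen's f effect
sizes, a general linear model for the GM-volume/age association, and the
table assembly that stratifies everything by field strength.

Conventions, stated once: Dice of two empty masks is defined as 1.0
(agreement) and flagged; no multiple-testing correction is applied (raw
p-values are reported); IQRs use linear-interpolation (type-7) quantiles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import LesionMask, ValidationError

__all__ = [
    "ComparisonReport",
    "RegressionResult",
    "DegenerateTestError",
    "dice",
    "volume_difference_proportion",
    "percent_volume_difference",
    "no_intercept_regression",
    "wilcoxon_signed_rank",
    "paired_t_test",
    "cohens_f",
    "effect_size_band",
    "age_association_glm",
    "top_lesion_load_subset",
    "comparison_table",
]

AIC_SENTINEL = -1e12  # stands in for -inf when a fit is exact (RSS = 0)


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined for the given data."""


@dataclass
class ComparisonReport:
    """Pairwise agreement between two segmentation methods for one subject."""

    method_a: str
    method_b: str
    field_strength: Optional[str] = None
    dice: Optional[float] = None
    volume_a_ml: Optional[float] = None
    volume_b_ml: Optional[float] = None
    vol_diff_proportion: Optional[float] = None
    percent_vol_diff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dice is not None and not 0.0 <= self.dice <= 1.0:
            raise ValidationError(f"dice must be in [0, 1], got {self.dice}")


@dataclass
class RegressionResult:
    """Through-origin regression summary, with AICs for both model forms."""

    beta: float
    se: float
    r2: float
    aic_no_intercept: float
    aic_intercept: float
    n: int
    exact_fit: bool = False  # RSS == 0; AICs replaced by a large negative sentinel

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("standard error must be >= 0")
        if self.n < 2:
            raise ValidationError("regression needs n >= 2")


# ---------------------------------------------------------------------------
# Overlap and volume-difference measures


def dice(a: LesionMask | np.ndarray, b: LesionMask | np.ndarray) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN); symmetric.

    Two empty masks return 1.0 by declared convention (perfect agreement on
    the absence of lesions).
    """
    ma = a.mask if isinstance(a, LesionMask) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, LesionMask) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValidationError(f"mask grids differ: {ma.shape} vs {mb.shape}")
    tp = int((ma & mb).sum())
    fp = int((~ma & mb).sum())
    fn = int((ma & ~mb).sum())
    if tp + fp + fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def volume_difference_proportion(v_conventional: float, v_flair_only: float) -> float:
    """Directional proportion (FLAIR-only - conventional) / conventional."""
    if v_conventional <= 0:
        raise ValidationError("conventional volume must be > 0")
    return (v_flair_only - v_conventional) / v_conventional


def percent_volume_difference(v_conventional: float, v_flair_only: float) -> float:
    """Symmetric percentage (conventional - FLAIR-only) / mean * 100."""
    avg = (v_conventional + v_flair_only) / 2.0
    if avg <= 0:
        raise ValidationError("average volume must be > 0")
    return (v_conventional - v_flair_only) / avg * 100.0


# ---------------------------------------------------------------------------
# Regression


def no_intercept_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line through the origin: beta = Sxy / Sxx.

    SE uses an (n-1)-denominator residual variance; R^2 is uncentred
    (1 - RSS / Sum y^2, the standard convention for through-origin fits); AIC
    is the Gaussian n ln(RSS/n) + 2k with k = 1, compared against the
    intercept model's k = 2.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and equally long")
    n = x.size
    if n < 2:
        raise ValidationError("need n >= 2")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValidationError("all x are zero; slope undefined")
    beta = float(x @ y) / sxx
    rss = float(((y - beta * x) ** 2).sum())
    syy = float(y @ y)
    r2 = 1.0 - rss / syy if syy > 0 else 1.0
    se = math.sqrt((rss / (n - 1)) / sxx)

    # intercept model for the AIC comparison
    xc = x - x.mean()
    yc = y - y.mean()
    denom = float(xc @ xc)
    b1 = float(xc @ yc) / denom if denom > 0 else 0.0
    rss_int = float(((yc - b1 * xc) ** 2).sum())

    exact = rss <= 1e-300
    aic0 = AIC_SENTINEL if exact else n * math.log(rss / n) + 2 * 1
    aic1 = AIC_SENTINEL if rss_int <= 1e-300 else n * math.log(rss_int / n) + 2 * 2
    return RegressionResult(
        beta=beta, se=se, r2=r2, aic_no_intercept=aic0, aic_intercept=aic1, n=n,
        exact_fit=exact,
    )


# ---------------------------------------------------------------------------
# Paired tests


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = diffs[diffs != 0]
    if d.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))  # mid-ranks for ties
    return d, ranks


def wilcoxon_signed_rank(pairs) -> tuple[float, float]:
    """Related-samples Wilcoxon signed-rank test, two-sided.

    ``pairs`` is a sequence of differences, or of (a, b) pairs.  Zeros are
    dropped; ties get mid-ranks.  For n <= 12 the p-value is computed by
    exact enumeration of all sign patterns over the observed ranks; beyond
    that a normal approximation with tie correction and continuity correction
    is used.  Returns (W, p) with W = min(W+, W-).
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim == 2 and arr.shape[1] == 2:
        arr = arr[:, 0] - arr[:, 1]
    d, ranks = _signed_ranks(arr)
    n = d.size
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    total = ranks.sum()
    expected = total / 2.0
    if n <= 12:
        # exact: enumerate all 2^n assignments of signs to the observed ranks
        obs_dev = abs(w_pos - expected)
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            wp = float(sum(r for s, r in zip(signs, ranks) if s))
            if abs(wp - expected) >= obs_dev - 1e-12:
                count += 1
        p = count / 2.0**n
    else:
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            raise DegenerateTestError("zero variance after tie correction")
        z = (abs(w_pos - expected) - 0.5) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    return w, min(float(p), 1.0)


def paired_t_test(pairs) -> tuple[float, float]:
    """Two-sided paired t-test on differences (or (a, b) pairs)."""
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim == 2 and arr.shape[1] == 2:
        arr = arr[:, 0] - arr[:, 1]
    n = arr.size
    if n < 2:
        raise ValidationError("paired t-test needs n >= 2")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("paired differences have zero variance")
    t = float(arr.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return t, p


# ---------------------------------------------------------------------------
# Effect sizes and the age GLM


def cohens_f(r2_full: float, r2_reduced: float) -> float:
    """Cohen's f from full- vs reduced-model R^2: sqrt((R2f - R2r)/(1 - R2f))."""
    if not 0.0 <= r2_reduced <= r2_full:
        raise ValidationError("need 0 <= r2_reduced <= r2_full")
    if r2_full >= 1.0:
        raise ValidationError("r2_full must be < 1")
    return math.sqrt((r2_full - r2_reduced) / (1.0 - r2_full))


def effect_size_band(f: float) -> str:
    """Classify f against the conventional 0.10 / 0.25 / 0.40 anchors."""
    if f < 0:
        raise ValidationError("effect size must be >= 0")
    if f < 0.10:
        return "negligible"
    if f < 0.25:
        return "small-to-medium"
    if f < 0.40:
        return "medium-to-large"
    return "large"


def age_association_glm(
    volumes_ml: Sequence[float],
    age_years: Sequence[float],
    tiv_ml: Sequence[float],
    field: Sequence[str],
):
    """OLS of GM volume on age + TIV with field strength as a fixed factor.

    Returns a dict with the fitted coefficients, SEs, p-values, model R^2 and
    Cohen's f for age (full model vs the model without age).
    """
    import statsmodels.formula.api as smf

    frame = pd.DataFrame(
        {
            "gm_ml": np.asarray(volumes_ml, dtype=float),
            "age_years": np.asarray(age_years, dtype=float),
            "tiv_ml": np.asarray(tiv_ml, dtype=float),
            "field": list(field),
        }
    )
    if len(frame) < 10:
        raise ValidationError("age GLM needs n >= 10")
    if frame.isna().any().any():
        raise ValidationError("age GLM does not accept missing values")
    full = smf.ols("gm_ml ~ age_years + tiv_ml + C(field)", data=frame).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValidationError("collinear (rank-deficient) design")
    reduced = smf.ols("gm_ml ~ tiv_ml + C(field)", data=frame).fit()
    f_age = cohens_f(float(full.rsquared), float(reduced.rsquared))
    return {
        "params": dict(full.params),
        "se": dict(full.bse),
        "pvalues": dict(full.pvalues),
        "r2": float(full.rsquared),
        "r2_reduced": float(reduced.rsquared),
        "cohens_f_age": f_age,
        "effect_band": effect_size_band(f_age),
        "age_coefficient": float(full.params["age_years"]),
        "age_p": float(full.pvalues["age_years"]),
        "n": int(len(frame)),
        "results": full,
    }


# ---------------------------------------------------------------------------
# Report assembly


def top_lesion_load_subset(lesion_volumes: pd.Series, fraction: float = 0.10) -> pd.Index:
    """Subjects in the top ``fraction`` of lesion load (at least one subject)."""
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    n = len(lesion_volumes)
    k = max(int(math.ceil(n * fraction)), 1)
    return lesion_volumes.sort_values(ascending=False).index[:k]


def _iqr(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # type-7 interpolation
    return float(med), float(q1), float(q3)


def comparison_table(
    masks_by_method: Optional[dict],
    volumes_by_method: dict,
    grouping: Optional[dict] = None,
    reference_method: Optional[str] = None,
) -> dict:
    """Per-field-strength comparison tables across segmentation methods.

    ``masks_by_method``: method -> subject -> LesionMask (or None to skip the
    Dice block).  ``volumes_by_method``: method -> subject -> volume (ml).
    ``grouping``: subject -> field strength (one stratum when omitted).
    Returns a dict of DataFrames: ``volumes`` (median/IQR per method),
    ``dice`` (pairwise mean/SD), ``wilcoxon`` (pairwise p), ``volume_diff``
    and ``regression`` (both against ``reference_method``, defaulting to the
    first method), plus ``top_lesion_subset`` per stratum.
    """
    methods = list(volumes_by_method)
    if len(methods) < 2:
        raise ValidationError("need >= 2 methods to compare")
    subjects = sorted(
        set.intersection(*(set(volumes_by_method[m]) for m in methods))
    )
    if not subjects:
        raise ValidationError("no common subjects across methods")
    ref = reference_method or methods[0]
    grouping = grouping or {s: "all" for s in subjects}
    strata = sorted(set(grouping[s] for s in subjects))

    vol_rows, dice_rows, wil_rows, diff_rows, reg_rows, subset_rows = [], [], [], [], [], []
    for stratum in strata:
        subs = [s for s in subjects if grouping[s] == stratum]
        degenerate = len(subs) < 2
        for m in methods:
            vols = np.array([volumes_by_method[m][s] for s in subs], dtype=float)
            med, q1, q3 = _iqr(vols)
            vol_rows.append(
                {
                    "field_strength": stratum,
                    "method": m,
                    "n": len(subs),
                    "median_ml": med,
                    "iqr_low_ml": q1,
                    "iqr_high_ml": q3,
                    "degenerate": degenerate,
                }
            )
        for ma, mb in itertools.combinations(methods, 2):
            if masks_by_method is not None:
                dvals = [
                    dice(masks_by_method[ma][s], masks_by_method[mb][s]) for s in subs
                ]
                dice_rows.append(
                    {
                        "field_strength": stratum,
                        "method_a": ma,
                        "method_b": mb,
                        "dice_mean": float(np.mean(dvals)),
                        "dice_sd": float(np.std(dvals, ddof=1)) if len(dvals) > 1 else 0.0,
                    }
                )
            va = np.array([volumes_by_method[ma][s] for s in subs], dtype=float)
            vb = np.array([volumes_by_method[mb][s] for s in subs], dtype=float)
            try:
                w, p = wilcoxon_signed_rank(va - vb)
                flag = ""
            except DegenerateTestError:
                w, p, flag = np.nan, np.nan, "degenerate"
            wil_rows.append(
                {
                    "field_strength": stratum,
                    "method_a": ma,
                    "method_b": mb,
                    "W": w,
                    "p": p,
                    "flag": flag,
                }
            )
        for m in methods:
            if m == ref:
                continue
            vref = np.array([volumes_by_method[ref][s] for s in subs], dtype=float)
            vm = np.array([volumes_by_method[m][s] for s in subs], dtype=float)
            ok = vref > 0
            props = (vm[ok] - vref[ok]) / vref[ok]
            both = (vref + vm) > 0
            pcts = (vref[both] - vm[both]) / ((vref[both] + vm[both]) / 2.0) * 100.0
            diff_rows.append(
                {
                    "field_strength": stratum,
                    "method": m,
                    "reference": ref,
                    "median_vol_diff_proportion": float(np.median(props)) if props.size else np.nan,
                    "median_percent_vol_diff": float(np.median(pcts)) if pcts.size else np.nan,
                }
            )
            if len(subs) >= 2 and (vref != 0).any():
                reg = no_intercept_regression(vref, vm)
                reg_rows.append(
                    {
                        "field_strength": stratum,
                        "method": m,
                        "reference": ref,
                        "beta": reg.beta,
                        "se": reg.se,
                        "r2": reg.r2,
                        "aic_no_intercept": reg.aic_no_intercept,
                        "aic_intercept": reg.aic_intercept,
                        "n": reg.n,
                    }
                )
        loads = pd.Series(
            {s: volumes_by_method[ref][s] for s in subs}, dtype=float
        )
        for s in top_lesion_load_subset(loads):
            subset_rows.append(
                {"field_strength": stratum, "subject": s, "lesion_ml": float(loads[s])}
            )

    out = {
        "volumes": pd.DataFrame(vol_rows),
        "wilcoxon": pd.DataFrame(wil_rows),
        "volume_diff": pd.DataFrame(diff_rows),
        "regression": pd.DataFrame(reg_rows),
        "top_lesion_subset": pd.DataFrame(subset_rows),
    }
    if masks_by_method is not None:
        out["dice"] = pd.DataFrame(dice_rows)
    return out


def write_report(tables: dict, out_dir) -> None:
    """Write each comparison table as CSV plus a combined JSON."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    combined = {}
    for name, frame in tables.items():
        if isinstance(frame, pd.DataFrame):
            frame.to_csv(out / f"{name}.csv", index=False)
            combined[name] = frame.to_dict(orient="records")
        else:
            combined[name] = frame
    (out / "report.json").write_text(json.dumps(combined, indent=2, default=str))
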