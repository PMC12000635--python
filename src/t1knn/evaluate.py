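"""Agreement analysis between two T1 maps.

Implements the validation statistics: per-tissue mean T1 and mean absolute
voxel-wise percent difference, structural similarity (SSIM) over the brain,
Bland-Altman bias and 1.96-SD limits of agreement in percent of the pairwise
mean, and an ordinary-least-squares regression of test on reference. Tissues
are delineated by thresholding the probability maps (default 0.95, so a voxel
belongs to at most one tissue); CSF is excluded from the pooled Bland-Altman
by default, being the tissue most affected by registration and segmentation
error in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .irfit import T1Map
from .knn import FeatureBlock
from .phantom import TISSUES

__all__ = [
    "AgreementReport",
    "tissue_membership",
    "percent_diff_by_tissue",
    "ssim_map",
    "bland_altman",
    "regression_compare",
    "export_feature_scatter",
    "agreement_report",
]

logger = logging.getLogger(__name__)


def _t1_array(m) -> np.ndarray:
    return m.t1 if isinstance(m, T1Map) else np.asarray(m, dtype=float)


def _valid(m, shape) -> np.ndarray:
    if isinstance(m, T1Map):
        return m.valid_mask
    return np.ones(shape, dtype=bool)


def tissue_membership(
    prob_maps: dict[str, np.ndarray], threshold: float = 0.95
) -> dict[str, np.ndarray]:
    """Per-tissue boolean voxel sets: probability strictly above ``threshold``.

    With threshold > 0.5 the sets are disjoint. Empty tissues are omitted
    with a logged warning.
    """
    out: dict[str, np.ndarray] = {}
    for name in TISSUES:
        if name not in prob_maps:
            continue
        sel = prob_maps[name] > threshold
        if not np.any(sel):
            logger.warning("tissue %s has no voxels above probability %g; omitted", name, threshold)
            continue
        out[name] = sel
    return out


def percent_diff_by_tissue(test, ref, tissue_sets: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-tissue mean |test - ref| / ref x 100 plus mean T1s.

    Voxels with a zero reference are excluded and counted in
    ``n_excluded_zero_ref``.
    """
    t = _t1_array(test)
    r = _t1_array(ref)
    if t.shape != r.shape:
        raise ValueError(f"grid mismatch: test {t.shape} vs ref {r.shape}")
    ok = _valid(test, t.shape) & _valid(ref, r.shape)
    rows = []
    for name, sel in tissue_sets.items():
        use = sel & ok
        tv, rv = t[use], r[use]
        nonzero = rv != 0
        n_excl = int((~nonzero).sum())
        tv, rv = tv[nonzero], rv[nonzero]
        if tv.size == 0:
            logger.warning("tissue %s has no usable voxels; omitted", name)
            continue
        rows.append(
            {
                "tissue": name,
                "mean_t1_ref": rv.mean(),
                "mean_t1_test": tv.mean(),
                "mean_abs_pct_diff": float(np.mean(np.abs(tv - rv) / rv) * 100.0),
                "voxel_count": int(tv.size),
                "n_excluded_zero_ref": n_excl,
            }
        )
    return pd.DataFrame(rows)


def ssim_map(test, ref, data_range: float = 4000.0, mask: np.ndarray | None = None) -> float:
    """Mean structural similarity between two T1 maps.

    Gaussian-weighted windows (sigma 1.5), stabilizers c1 = (0.01 L)^2 and
    c2 = (0.03 L)^2 with L = ``data_range`` held fixed (default 4000 ms) so
    values are comparable across runs; averaged inside ``mask`` when given.
    """
    if data_range <= 0:
        raise ValueError(f"data_range must be positive, got {data_range}")
    t = _t1_array(test)
    r = _t1_array(ref)
    if t.shape != r.shape:
        raise ValueError(f"grid mismatch: test {t.shape} vs ref {r.shape}")
    if np.all(t == 0) and np.all(r == 0):
        raise ValueError("cannot compute SSIM of two identically zero maps")
    mssim, smap = structural_similarity(
        r,
        t,
        data_range=data_range,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        full=True,
    )
    if mask is not None:
        if mask.shape != t.shape:
            raise ValueError(f"grid mismatch: mask {mask.shape} vs maps {t.shape}")
        return float(smap[mask].mean())
    return float(mssim)


def bland_altman(test_values, ref_values, percent_mode: bool = True):
    """Bland-Altman bias and limits of agreement.

    In percent mode the paired differences are (test - ref) / pairwise mean
    x 100; bias is their mean and the limits are bias +/- 1.96 sample
    (n-1) standard deviations.
    """
    t = np.asarray(test_values, dtype=float).ravel()
    r = np.asarray(ref_values, dtype=float).ravel()
    if t.size != r.size:
        raise ValueError("paired samples must have equal length")
    if t.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    if percent_mode:
        m = 0.5 * (t + r)
        if np.any(m == 0):
            raise ValueError("pairwise mean of zero in percent mode")
        d = (t - r) / m * 100.0
    else:
        d = t - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def regression_compare(ref_values, test_values):
    """OLS of test on reference: (slope, intercept, R^2)."""
    r = np.asarray(ref_values, dtype=float).ravel()
    t = np.asarray(test_values, dtype=float).ravel()
    if r.size != t.size:
        raise ValueError("paired samples must have equal length")
    if r.size < 3:
        raise ValueError("regression needs at least 3 pairs")
    if np.ptp(r) == 0:
        raise ValueError("reference values have zero variance")
    res = stats.linregress(r, t)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def export_feature_scatter(
    features: FeatureBlock, t1, tissue_sets: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-voxel (mprage_norm, flair_norm, t1, tissue) rows for the voxels in
    the union of the tissue sets — the data-distribution view of the inputs
    against the mapped output."""
    t = _t1_array(t1)
    frames = []
    for name, sel in tissue_sets.items():
        flat = sel.ravel()[features.voxel_index]
        if not np.any(flat):
            continue
        frames.append(
            pd.DataFrame(
                {
                    "mprage_norm": features.vectors[flat, 0],
                    "flair_norm": features.vectors[flat, 1],
                    "t1": t.ravel()[features.voxel_index[flat]],
                    "tissue": name,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["mprage_norm", "flair_norm", "t1", "tissue"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class AgreementReport:
    """Full agreement analysis between a test and a reference T1 map."""

    per_tissue: pd.DataFrame
    ssim: float
    ba_bias: float
    ba_loa: tuple[float, float]
    regression_slope: float
    regression_intercept: float
    r_squared: float
    lesion_row: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {
            "ssim": self.ssim,
            "ba_bias_pct": self.ba_bias,
            "ba_loa_pct": list(self.ba_loa),
            "regression_slope": self.regression_slope,
            "regression_intercept_ms": self.regression_intercept,
            "r_squared": self.r_squared,
            "per_tissue": self.per_tissue.to_dict(orient="records"),
        }
        if self.lesion_row is not None:
            out["lesion"] = self.lesion_row.to_dict(orient="records")
        return out

    def summary(self) -> str:
        lines = [
            "T1 map agreement report",
            "=" * 34,
            self.per_tissue.to_string(
                index=False, float_format=lambda v: f"{v:.2f}"
            ),
            "",
            f"SSIM:                {self.ssim:.4f}",
            f"Bland-Altman bias:   {self.ba_bias:+.2f} %",
            f"limits of agreement: [{self.ba_loa[0]:+.2f}, {self.ba_loa[1]:+.2f}] %",
            f"regression:          test = {self.regression_slope:.3f} * ref "
            f"{self.regression_intercept:+.1f} ms (R^2 = {self.r_squared:.4f})",
        ]
        if self.lesion_row is not None and len(self.lesion_row):
            lines += ["", "lesions:", self.lesion_row.to_string(index=False,
                      float_format=lambda v: f"{v:.2f}")]
        return "\n".join(lines)


def agreement_report(
    test,
    ref,
    prob_maps: dict[str, np.ndarray],
    brain_mask: np.ndarray | None = None,
    lesion_mask: np.ndarray | None = None,
    tissue_threshold: float = 0.95,
    data_range: float = 4000.0,
    exclude_csf_from_pooled: bool = True,
) -> AgreementReport:
    """Assemble the full agreement analysis between two maps.

    The pooled Bland-Altman and regression use the union of the per-tissue
    voxel sets, excluding CSF by default. A lesion row is reported iff a
    non-empty ``lesion_mask`` is supplied.
    """
    sets = tissue_membership(prob_maps, tissue_threshold)
    table = percent_diff_by_tissue(test, ref, sets)

    pooled_names = [n for n in sets if not (exclude_csf_from_pooled and n == "csf")]
    pooled = np.zeros(_t1_array(test).shape, dtype=bool)
    for n in pooled_names:
        pooled |= sets[n]
    pooled &= _valid(test, pooled.shape) & _valid(ref, pooled.shape)
    tv = _t1_array(test)[pooled]
    rv = _t1_array(ref)[pooled]
    keep = (tv + rv) != 0
    bias, lo, hi = bland_altman(tv[keep], rv[keep], percent_mode=True)
    slope, intercept, r2 = regression_compare(rv[keep], tv[keep])
    ssim = ssim_map(test, ref, data_range=data_range, mask=brain_mask)

    lesion_df = None
    if lesion_mask is not None and np.any(lesion_mask):
        lesion_df = percent_diff_by_tissue(test, ref, {"lesion": lesion_mask})
    return AgreementReport(
        per_tissue=table,
        ssim=ssim,
        ba_bias=bias,
        ba_loa=(lo, hi),
        regression_slope=slope,
        regression_intercept=intercept,
        r_squared=r2,
        lesion_row=lesion_df,
    )
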