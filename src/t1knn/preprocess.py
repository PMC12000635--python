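"""Intensity normalization, masking and FLAIR lesion segmentation.

Both clinical contrasts are normalized per volume by the mean intensity of
high-confidence white matter (probability > 0.95), so intensities are
dimensionless with WM ~ 1 and the downstream classifier is invariant to
scanner scaling. Lesions are segmented from the normalized FLAIR by
thresholding against the WM intensity distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "NormalizedVolume",
    "wm_reference_mean",
    "normalize_by_wm",
    "segment_lesions",
    "build_training_mask",
]


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizedVolume:
    """A WM-normalized contrast volume (dimensionless, WM ~ 1)."""

    data: np.ndarray
    wm_reference: float
    source_tag: str = ""


def wm_reference_mean(
    volume: np.ndarray,
    p_wm: np.ndarray,
    threshold: float = 0.95,
    min_voxels: int = 100,
) -> float:
    """Mean intensity over high-confidence WM voxels (p_wm > threshold)."""
    if volume.shape != p_wm.shape:
        raise ValueError(f"grid mismatch: volume {volume.shape} vs p_wm {p_wm.shape}")
    sel = p_wm > threshold
    n = int(sel.sum())
    if n < min_voxels:
        raise NormalizationError(
            f"only {n} voxels exceed WM probability {threshold} (need >= {min_voxels})"
        )
    return float(np.asarray(volume, dtype=float)[sel].mean())


def normalize_by_wm(
    volume: np.ndarray, wm_mean: float, source_tag: str = ""
) -> NormalizedVolume:
    """Divide a volume by its WM reference mean."""
    if not np.isfinite(wm_mean) or wm_mean <= 0:
        raise NormalizationError(f"WM reference mean must be positive, got {wm_mean}")
    return NormalizedVolume(
        data=np.asarray(volume, dtype=float) / wm_mean,
        wm_reference=float(wm_mean),
        source_tag=source_tag,
    )


def segment_lesions(
    flair_norm: NormalizedVolume,
    brain_mask: np.ndarray,
    prob_maps: dict[str, np.ndarray],
    z_threshold: float = 3.0,
    wm_threshold: float = 0.95,
    min_component_voxels: int = 3,
    absolute_threshold: float | None = None,
) -> np.ndarray:
    """Threshold-based FLAIR lesion segmentation.

    Candidate voxels lie inside the brain with combined WM+GM probability
    above 0.5; a voxel is lesion when its normalized FLAIR exceeds
    ``mu + z_threshold * sigma`` of the high-confidence-WM FLAIR distribution.
    Connected components (26-connectivity) smaller than
    ``min_component_voxels`` are discarded. Passing ``absolute_threshold``
    (normalized units) bypasses the z-score rule — the manual-override mode
    of a semi-automated workflow.
    """
    if z_threshold <= 0:
        raise ValueError(f"z_threshold must be positive, got {z_threshold}")
    data = flair_norm.data
    wm_sel = prob_maps["wm"] > wm_threshold
    if absolute_threshold is None:
        wm_vals = data[wm_sel]
        sigma = float(wm_vals.std())
        if sigma <= 1e-10 * max(abs(float(wm_vals.mean())), 1.0):
            raise ValueError(
                "WM FLAIR distribution is degenerate (sigma = 0); "
                "use absolute_threshold for noiseless data"
            )
        cutoff = float(wm_vals.mean()) + z_threshold * sigma
    else:
        cutoff = float(absolute_threshold)
    parenchyma = (prob_maps["wm"] + prob_maps["gm"]) > 0.5
    candidate = brain_mask & parenchyma & (data > cutoff)
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return candidate
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_component_voxels)
    keep = keep[keep != 0]
    return np.isin(labels, keep)


def build_training_mask(
    brain_mask: np.ndarray,
    training_mask: np.ndarray,
    prob_maps: dict[str, np.ndarray],
) -> np.ndarray:
    """Voxels eligible as training exemplars: inside the brain, inside the
    (superior) training region, with at least one nonzero tissue probability."""
    if brain_mask.shape != training_mask.shape:
        raise ValueError(
            f"grid mismatch: brain {brain_mask.shape} vs training {training_mask.shape}"
        )
    any_prob = np.zeros(brain_mask.shape, dtype=bool)
    for p in prob_maps.values():
        any_prob |= p > 0
    out = brain_mask & training_mask & any_prob
    if not np.any(out):
        raise ValueError("training mask selects no voxels")
    return out
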