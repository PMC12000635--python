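"""Voxel-wise T1 prediction by one-nearest-neighbour classification.

Each voxel contributes a nine-element feature vector — WM-normalized MPRAGE
and FLAIR intensities plus seven tissue probabilities — mapped to a T1 value
quantized onto a discrete class grid (400–3980 ms in 10 ms steps). The
learner is lazy: training stores the exemplars verbatim; prediction assigns
each query voxel the label of its Euclidean-nearest training voxel, with
exact-distance ties resolved to the lowest T1 class. ``k > 1`` (majority
vote) is provided for completeness but 1 is the method's operating point:
larger neighbourhoods smooth away small structures.

The statsmodels-style surface is :class:`T1NearestNeighborModel` /
:class:`T1NearestNeighborResults`; the module-level functions
(:func:`quantize_t1`, :func:`assemble_features`, :func:`train`,
:func:`predict_t1`) are the underlying operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .irfit import REASON_OUTSIDE_MASK, T1Map

__all__ = [
    "FEATURE_NAMES",
    "T1ClassGrid",
    "FeatureBlock",
    "TrainingStore",
    "quantize_t1",
    "dequantize",
    "assemble_features",
    "train",
    "predict_t1",
    "linear_scan_predict",
    "T1NearestNeighborModel",
    "T1NearestNeighborResults",
]

#: Fixed feature order of the nine-element input vector.
FEATURE_NAMES = (
    "mprage_norm",
    "flair_norm",
    "p_wm",
    "p_gm",
    "p_csf",
    "p_cau",
    "p_gp",
    "p_tha",
    "p_put",
)

STORE_FORMAT_VERSION = "t1knn-store-1"


@dataclass(frozen=True)
class T1ClassGrid:
    """Discrete T1 label space: ``t1_min`` to ``t1_max`` in ``step`` ms."""

    t1_min: float = 400.0
    t1_max: float = 3980.0
    step: float = 10.0

    def __post_init__(self) -> None:
        if not (self.t1_min > 0 and self.t1_max > self.t1_min and self.step > 0):
            raise ValueError(f"invalid class grid ({self.t1_min}, {self.t1_max}, {self.step})")
        span = self.t1_max - self.t1_min
        if abs(span / self.step - round(span / self.step)) > 1e-9:
            raise ValueError(
                f"(t1_max - t1_min) = {span} must be divisible by step = {self.step}"
            )

    @property
    def n_classes(self) -> int:
        return int(round((self.t1_max - self.t1_min) / self.step)) + 1

    def values(self) -> np.ndarray:
        return self.t1_min + self.step * np.arange(self.n_classes)


def quantize_t1(t1, grid: T1ClassGrid = T1ClassGrid()):
    """Map T1 (ms) to the nearest class index; out-of-range values clamp to
    the boundary classes; exact midpoints round up."""
    t1 = np.asarray(t1, dtype=float)
    if not np.all(np.isfinite(t1)):
        raise ValueError("t1 must be finite")
    idx = np.floor((t1 - grid.t1_min) / grid.step + 0.5).astype(np.int64)
    idx = np.clip(idx, 0, grid.n_classes - 1)
    return idx if idx.ndim else int(idx)


def dequantize(labels, grid: T1ClassGrid = T1ClassGrid()):
    """Class index -> T1 value in ms."""
    return grid.t1_min + grid.step * np.asarray(labels, dtype=float)


@dataclass
class FeatureBlock:
    """Per-voxel nine-element input vectors in ``FEATURE_NAMES`` order.

    ``voxel_index`` holds flat (raveled, C-order) positions on the source
    grid of shape ``grid_shape``; ``n_dropped`` counts rows removed for
    non-finite entries.
    """

    vectors: np.ndarray
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"vectors must be N x {len(FEATURE_NAMES)}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors must be finite")
        probs = self.vectors[:, 2:]
        if np.any(probs < 0) or np.any(probs > 1 + 1e-9):
            raise ValueError("tissue probabilities must lie in [0, 1]")
        if np.any(self.vectors[:, :2] < 0):
            raise ValueError("normalized intensities must be non-negative")


def assemble_features(mprage_norm, flair_norm, prob_maps: dict, voxel_set) -> FeatureBlock:
    """Build the feature matrix for the voxels in ``voxel_set`` (a boolean
    mask or flat indices). Rows with any non-finite entry are dropped and
    counted in ``n_dropped``."""
    from .preprocess import NormalizedVolume
    from .phantom import TISSUES

    mpr = mprage_norm.data if isinstance(mprage_norm, NormalizedVolume) else np.asarray(mprage_norm)
    fla = flair_norm.data if isinstance(flair_norm, NormalizedVolume) else np.asarray(flair_norm)
    shape = mpr.shape
    if fla.shape != shape:
        raise ValueError(f"grid mismatch: mprage {shape} vs flair {fla.shape}")
    for name in TISSUES:
        if prob_maps[name].shape != shape:
            raise ValueError(f"grid mismatch: prob map {name} {prob_maps[name].shape} vs {shape}")

    voxel_set = np.asarray(voxel_set)
    if voxel_set.dtype == bool:
        if voxel_set.shape != shape:
            raise ValueError(f"grid mismatch: voxel mask {voxel_set.shape} vs {shape}")
        flat_idx = np.flatnonzero(voxel_set)
    else:
        flat_idx = voxel_set.astype(np.int64).ravel()
    if flat_idx.size == 0:
        raise ValueError("voxel_set selects no voxels")

    cols = [mpr.ravel()[flat_idx], fla.ravel()[flat_idx]]
    cols += [prob_maps[name].ravel()[flat_idx] for name in TISSUES]
    vectors = np.stack(cols, axis=1).astype(np.float64)
    finite = np.all(np.isfinite(vectors), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped == flat_idx.size:
        raise ValueError("all feature rows are non-finite")
    return FeatureBlock(
        vectors=vectors[finite],
        voxel_index=flat_idx[finite],
        grid_shape=shape,
        n_dropped=n_dropped,
    )


@dataclass
class TrainingStore:
    """The lazy learner's state: exemplars, labels and provenance."""

    features: np.ndarray
    labels: np.ndarray
    grid: T1ClassGrid = field(default_factory=T1ClassGrid)
    provenance: dict = field(default_factory=dict)
    standardize: bool = False

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"features must be M x {len(FEATURE_NAMES)}")
        if self.features.shape[0] == 0:
            raise ValueError("training store must not be empty")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must align with features")
        if np.any(self.labels < 0) or np.any(self.labels >= self.grid.n_classes):
            raise ValueError("labels outside the class grid")

    @property
    def size(self) -> int:
        return self.features.shape[0]

    def save(self, path) -> None:
        np.savez(
            path,
            format_version=np.array(STORE_FORMAT_VERSION),
            features=self.features,
            labels=self.labels,
            grid=np.array([self.grid.t1_min, self.grid.t1_max, self.grid.step]),
            standardize=np.array(self.standardize),
            provenance=np.array(json.dumps(self.provenance, sort_keys=True)),
        )

    @classmethod
    def load(cls, path) -> "TrainingStore":
        with np.load(path, allow_pickle=False) as z:
            version = str(z["format_version"])
            if version != STORE_FORMAT_VERSION:
                raise ValueError(
                    f"model store format-version mismatch: file has {version!r}, "
                    f"this build reads {STORE_FORMAT_VERSION!r}"
                )
            g = z["grid"]
            return cls(
                features=z["features"],
                labels=z["labels"],
                grid=T1ClassGrid(float(g[0]), float(g[1]), float(g[2])),
                provenance=json.loads(str(z["provenance"])),
                standardize=bool(z["standardize"]),
            )


def train(
    features: FeatureBlock,
    reference_t1,
    grid: T1ClassGrid = T1ClassGrid(),
    provenance: dict | None = None,
    standardize: bool = False,
) -> TrainingStore:
    """Store training exemplars with quantized reference-T1 labels.

    ``reference_t1`` is a :class:`~t1knn.irfit.T1Map` or a raw T1 volume in
    ms; feature rows whose reference voxel is invalid or non-positive are
    dropped and counted in the provenance.
    """
    if isinstance(reference_t1, T1Map):
        ref = reference_t1.t1
        ref_valid = reference_t1.valid_mask
    else:
        ref = np.asarray(reference_t1, dtype=float)
        ref_valid = np.isfinite(ref) & (ref > 0)
    if ref.shape != features.grid_shape:
        raise ValueError(f"grid mismatch: reference {ref.shape} vs features {features.grid_shape}")
    vals = ref.ravel()[features.voxel_index]
    ok = ref_valid.ravel()[features.voxel_index] & np.isfinite(vals) & (vals > 0)
    n_dropped = int((~ok).sum())
    if n_dropped == vals.size:
        raise ValueError("no training voxel has a valid reference T1")
    prov = dict(provenance or {})
    prov.update(
        {
            "n_training": int(ok.sum()),
            "n_dropped_invalid_reference": n_dropped,
            "standardize": bool(standardize),
            "feature_order": list(FEATURE_NAMES),
        }
    )
    return TrainingStore(
        features=features.vectors[ok],
        labels=quantize_t1(vals[ok], grid),
        grid=grid,
        provenance=prov,
        standardize=standardize,
    )


def _tie_break_labels(dist: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Resolve neighbour sets to one label per query row.

    ``dist``/``labels`` are (N, k_search) sorted by distance. For k = 1, all
    neighbours whose distance equals the minimum (to within a relative 1e-9)
    vote and the lowest class wins. For k > 1, majority vote over the first
    k neighbours, ties to the lowest class.
    """
    if k == 1:
        tol = 1e-9 * (1.0 + dist[:, :1])
        tied = dist <= dist[:, :1] + tol
        masked = np.where(tied, labels, np.iinfo(np.int64).max)
        return masked.min(axis=1)
    out = np.empty(dist.shape[0], dtype=np.int64)
    for i in range(dist.shape[0]):
        lab = labels[i, :k]
        uniq, counts = np.unique(lab, return_counts=True)
        out[i] = uniq[counts == counts.max()].min()
    return out


def predict_t1(
    store: TrainingStore,
    query: FeatureBlock,
    k: int = 1,
    block_size: int = 65536,
    tie_search: int = 8,
) -> T1Map:
    """Predict a T1 map by k-nearest-neighbour classification (default 1).

    Queries are processed in blocks of ``block_size`` rows so whole-volume
    prediction against a multi-million-row store runs in bounded memory.
    ``tie_search`` extra neighbours are retrieved so exact-distance ties can
    be resolved to the lowest class deterministically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > store.size:
        raise ValueError(f"k = {k} exceeds the store size {store.size}")
    feats = store.features
    qvecs = query.vectors
    mu = sd = None
    if store.standardize:
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        feats = (feats - mu) / sd
        qvecs = (qvecs - mu) / sd

    k_search = min(store.size, max(k, tie_search))
    nn = NearestNeighbors(n_neighbors=k_search, algorithm="auto", n_jobs=1)
    nn.fit(feats)

    pred_labels = np.empty(qvecs.shape[0], dtype=np.int64)
    for start in range(0, qvecs.shape[0], block_size):
        sl = slice(start, start + block_size)
        dist, idx = nn.kneighbors(qvecs[sl])
        pred_labels[sl] = _tie_break_labels(dist, store.labels[idx], k)

    t1_flat = dequantize(pred_labels, store.grid)
    shape = query.grid_shape
    t1_vol = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    t1_vol.ravel()[query.voxel_index] = t1_flat
    valid.ravel()[query.voxel_index] = True
    reason = np.where(valid, 0, REASON_OUTSIDE_MASK).astype(np.uint8)
    return T1Map(
        t1=t1_vol,
        fit_error=np.zeros(shape),
        valid_mask=valid,
        reason=reason,
        t1_max=store.grid.t1_max,
    )


def linear_scan_predict(store: TrainingStore, query: FeatureBlock, block_size: int = 2048) -> np.ndarray:
    """Exhaustive 1-NN by explicit distance computation (test oracle).

    Returns predicted class labels; ties at the exact minimum squared
    distance resolve to the lowest class, matching :func:`predict_t1`.
    """
    feats = store.features
    if store.standardize:
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        feats = (feats - mu) / sd
        qvecs = (query.vectors - mu) / sd
    else:
        qvecs = query.vectors
    labels = store.labels
    out = np.empty(qvecs.shape[0], dtype=np.int64)
    for start in range(0, qvecs.shape[0], block_size):
        q = qvecs[start : start + block_size]
        d2 = ((q[:, None, :] - feats[None, :, :]) ** 2).sum(axis=2)
        dmin = d2.min(axis=1, keepdims=True)
        tied = d2 <= dmin + 1e-9 * (1.0 + dmin)
        masked = np.where(tied, labels[None, :], np.iinfo(np.int64).max)
        out[start : start + block_size] = masked.min(axis=1)
    return out


class T1NearestNeighborModel:
    """Lazy 1-NN T1 mapping model.

    Parameters
    ----------
    features : FeatureBlock
        Training feature vectors (WM-normalized intensities + probabilities).
    reference_t1 : T1Map or ndarray
        Reference T1 volume (ms) supplying the labels.
    grid : T1ClassGrid
        The discrete label space.
    standardize : bool
        Z-score features before the Euclidean distance (default off: the
        normalized intensities and probabilities are already commensurate).
    """

    def __init__(self, features: FeatureBlock, reference_t1, grid: T1ClassGrid = T1ClassGrid(),
                 standardize: bool = False, provenance: dict | None = None):
        self.features = features
        self.reference_t1 = reference_t1
        self.grid = grid
        self.standardize = standardize
        self.provenance = provenance or {}

    @classmethod
    def from_volumes(cls, mprage_norm, flair_norm, prob_maps, reference_t1, training_mask,
                     grid: T1ClassGrid = T1ClassGrid(), **kwargs) -> "T1NearestNeighborModel":
        feats = assemble_features(mprage_norm, flair_norm, prob_maps, training_mask)
        return cls(feats, reference_t1, grid, **kwargs)

    def fit(self) -> "T1NearestNeighborResults":
        """Store the exemplars (training is storage for a lazy learner)."""
        store = train(
            self.features,
            self.reference_t1,
            self.grid,
            provenance=self.provenance,
            standardize=self.standardize,
        )
        return T1NearestNeighborResults(self, store)


@dataclass
class T1NearestNeighborResults:
    """Fitted (stored) 1-NN model; prediction and persistence live here."""

    model: T1NearestNeighborModel | None
    store: TrainingStore

    def predict(self, query: FeatureBlock, k: int = 1, **kwargs) -> T1Map:
        return predict_t1(self.store, query, k=k, **kwargs)

    def save(self, path) -> None:
        self.store.save(path)

    @classmethod
    def load(cls, path) -> "T1NearestNeighborResults":
        return cls(model=None, store=TrainingStore.load(path))

    def summary(self) -> str:
        s = self.store
        t1_vals = dequantize(s.labels, s.grid)
        lines = [
            "1-NN T1 classification model",
            "=" * 34,
            f"training exemplars:   {s.size}",
            f"class grid (ms):      {s.grid.t1_min:g}..{s.grid.t1_max:g} step {s.grid.step:g}"
            f" ({s.grid.n_classes} classes)",
            f"distinct labels used: {np.unique(s.labels).size}",
            f"label T1 median (ms): {np.median(t1_vals):.0f}",
            f"standardized:         {s.standardize}",
        ]
        if s.provenance:
            lines.append(f"provenance:           {json.dumps(s.provenance, sort_keys=True)}")
        return "\n".join(lines)
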