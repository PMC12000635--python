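"""Seeded synthetic brain phantom.

The phantom stands in for patient data: a concentric-ellipsoid "head" with an
outer CSF shell, a cortical GM ribbon, a WM interior hosting paired deep-GM
nuclei (caudate, globus pallidus, thalamus, putamen) and CSF ventricles, plus
spherical WM lesions with elevated T1 and hyperintense FLAIR signal.

From the ground-truth tissue structure the module renders noiseless MPRAGE,
FLAIR and IR-series contrasts by probability-weighted mixing of the per-tissue
signed signals (partial-volume model), then takes magnitudes; Rician noise and
an optional smooth multiplicative bias field are applied on top.

Everything is deterministic for a fixed ``PhantomSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .signals import FlairParams, IRSeriesParams, MprageParams, TissueProperties

__all__ = [
    "TISSUES",
    "DEFAULT_TISSUE_TABLE",
    "PhantomSpec",
    "TissuePhantom",
    "generate_phantom",
    "render_contrast",
    "render_ir_series",
    "add_rician_noise",
    "apply_bias_field",
    "simulate_study",
]

#: Canonical tissue order used everywhere (probability maps, features).
TISSUES = ("wm", "gm", "csf", "cau", "gp", "tha", "put")

#: Default 3T tissue parameters. T1/PD are literature-range values; the T2
#: column is an apparent (FSE-readout) T2 — long echo trains refocus much of
#: the static decay, so the effective T2 governing the TE=374 ms FLAIR
#: contrast is several times the spin-echo T2. CSF T1 sits above the 3980 ms
#: class-grid ceiling, so CSF labels clamp to the boundary class.
DEFAULT_TISSUE_TABLE: dict[str, TissueProperties] = {
    "wm": TissueProperties(t1=850.0, t2=300.0, pd=0.70),
    "gm": TissueProperties(t1=1330.0, t2=380.0, pd=0.85),
    "csf": TissueProperties(t1=4200.0, t2=1800.0, pd=1.00),
    "cau": TissueProperties(t1=1250.0, t2=380.0, pd=0.85),
    "gp": TissueProperties(t1=980.0, t2=300.0, pd=0.75),
    "tha": TissueProperties(t1=1150.0, t2=340.0, pd=0.80),
    "put": TissueProperties(t1=1120.0, t2=350.0, pd=0.80),
}


@dataclass(frozen=True)
class LesionSpec:
    """WM-hosted spherical lesions: count, radius range (voxels) and the
    uniform T1 draw range (ms)."""

    count: int = 5
    radius_range: tuple[float, float] = (2.0, 4.0)
    t1_range: tuple[float, float] = (1100.0, 1600.0)
    pd: float = 0.72

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("lesion count must be non-negative")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid lesion radius range {self.radius_range}")
        t_lo, t_hi = self.t1_range
        if not (400.0 <= t_lo <= t_hi <= 3980.0):
            raise ValueError(f"lesion T1 range {self.t1_range} must lie within [400, 3980] ms")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject."""

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tissue_table: dict[str, TissueProperties] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_TABLE)
    )
    lesion_spec: LesionSpec = LesionSpec()
    noise_sigma: float = 0.02
    bias_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if set(self.tissue_table) != set(TISSUES):
            raise ValueError(f"tissue_table must define exactly {TISSUES}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0.0 <= self.bias_amplitude < 1.0):
            raise ValueError("bias_amplitude must lie in [0, 1)")


@dataclass
class TissuePhantom:
    """Ground-truth volumes for one synthetic subject.

    ``label_volume`` holds integer tissue ids (0 = background, then 1..7 in
    ``TISSUES`` order); ``prob_maps`` maps tissue name -> membership volume in
    [0, 1] partitioning unity inside ``brain_mask``; ``t1/t2/pd_volume`` are the
    voxel-wise ground truth (probability-weighted mixtures, lesion-overridden);
    ``training_mask`` keeps the superior two-thirds of axial slices, emulating
    the exclusion of voxels inferior to the hippocampus.
    """

    spec: PhantomSpec
    label_volume: np.ndarray
    prob_maps: dict[str, np.ndarray]
    t1_volume: np.ndarray
    t2_volume: np.ndarray
    pd_volume: np.ndarray
    lesion_mask: np.ndarray
    brain_mask: np.ndarray
    training_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape


def _ellipsoid(coords, center, radii) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


# Deep structures in normalized [-1, 1] coordinates: (center, radii), mirrored
# left/right about x=0. Order matters: later entries overwrite earlier ones.
# Radii are generous relative to anatomy so each nucleus keeps a pure core
# (full 3-voxel neighbourhood inside the structure) on grids down to 32^3.
_STRUCTURES = (
    ("tha", (0.18, -0.30, 0.00), (0.13, 0.15, 0.12)),
    ("cau", (0.20, 0.30, 0.10), (0.11, 0.16, 0.11)),
    ("put", (0.42, 0.00, 0.02), (0.11, 0.18, 0.12)),
    ("gp", (0.24, 0.00, -0.04), (0.11, 0.13, 0.11)),
    ("csf", (0.10, 0.05, 0.15), (0.07, 0.26, 0.10)),  # lateral ventricles
)


def generate_phantom(spec: PhantomSpec) -> TissuePhantom:
    """Build the ground-truth phantom for ``spec`` (deterministic per seed)."""
    shape = tuple(int(s) for s in spec.shape)
    if min(shape) < 32:
        raise ValueError(
            f"phantom shape {shape} too small to host all seven tissues (need >= 32 per axis)"
        )
    rng = np.random.default_rng(spec.seed)

    grids = [np.linspace(-1.0, 1.0, n) for n in shape]
    coords = np.meshgrid(*grids, indexing="ij", sparse=True)

    e = (
        (coords[0] / 0.86) ** 2
        + (coords[1] / 0.90) ** 2
        + (coords[2] / 0.82) ** 2
    )
    labels = np.zeros(shape, dtype=np.int8)
    tissue_id = {name: i + 1 for i, name in enumerate(TISSUES)}
    labels[e <= 1.0] = tissue_id["csf"]  # outer subarachnoid shell
    labels[e <= 0.91**2] = tissue_id["gm"]  # cortical ribbon
    labels[e <= 0.78**2] = tissue_id["wm"]
    wm_interior = e <= 0.78**2
    for name, center, radii in _STRUCTURES:
        for sign in (+1.0, -1.0):
            c = (sign * center[0], center[1], center[2])
            blob = _ellipsoid(coords, c, radii) & wm_interior
            labels[blob] = tissue_id[name]

    brain_mask = labels > 0
    for tid in tissue_id.values():
        if not np.any(labels == tid):
            raise ValueError(f"phantom shape {shape} too small: a tissue region is empty")

    # Partial-volume shells: box-blur each indicator over a 3-voxel window,
    # then renormalize to a partition of unity inside the brain.
    prob_maps: dict[str, np.ndarray] = {}
    for name in TISSUES:
        ind = (labels == tissue_id[name]).astype(np.float64)
        prob_maps[name] = ndimage.uniform_filter(ind, size=3, mode="constant")
    total = np.zeros(shape)
    for name in TISSUES:
        prob_maps[name][~brain_mask] = 0.0
        total += prob_maps[name]
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in TISSUES:
            p = np.where(brain_mask, prob_maps[name] / total, 0.0)
            prob_maps[name] = np.clip(p, 0.0, 1.0)  # shave filter round-off

    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    pd = np.zeros(shape)
    for name in TISSUES:
        props = spec.tissue_table[name]
        t1 += prob_maps[name] * props.t1
        t2 += prob_maps[name] * props.t2
        pd += prob_maps[name] * props.pd

    lesion_mask = np.zeros(shape, dtype=bool)
    if spec.lesion_spec.count > 0:
        lesion_mask = _place_lesions(spec, prob_maps["wm"], coords, rng, t1, t2, pd)

    z_cut = shape[2] // 3  # drop the inferior third of axial slices
    training_mask = brain_mask.copy()
    training_mask[:, :, :z_cut] = False

    return TissuePhantom(
        spec=spec,
        label_volume=labels,
        prob_maps=prob_maps,
        t1_volume=t1,
        t2_volume=t2,
        pd_volume=pd,
        lesion_mask=lesion_mask,
        brain_mask=brain_mask,
        training_mask=training_mask,
    )


def _place_lesions(spec, p_wm, coords, rng, t1, t2, pd) -> np.ndarray:
    """Carve disjoint spherical lesions into pure WM, overriding the
    ground-truth property volumes in place."""
    les = spec.lesion_spec
    wm_props = spec.tissue_table["wm"]
    shape = p_wm.shape
    pure_wm = p_wm > 0.999
    # Distance (in voxels) to the nearest non-pure-WM voxel: a lesion of
    # radius r fits where the distance exceeds r + 1.
    dist = ndimage.distance_transform_edt(pure_wm)
    mask = np.zeros(shape, dtype=bool)
    centers: list[tuple[np.ndarray, float]] = []
    ii = np.indices(shape).reshape(3, -1).T
    attempts = 0
    while len(centers) < les.count:
        attempts += 1
        if attempts > 500 * les.count:
            raise ValueError(
                f"could not place {les.count} disjoint lesions in pure WM for shape {shape}"
            )
        radius = rng.uniform(*les.radius_range)
        candidates = np.flatnonzero(dist.ravel() > radius + 1.0)
        if candidates.size == 0:
            raise ValueError(f"phantom shape {shape} has no pure WM able to host a lesion")
        center = ii[rng.choice(candidates)]
        if any(
            np.linalg.norm(center - c) <= radius + r + 1.0 for c, r in centers
        ):
            continue
        centers.append((center, radius))
        lo = np.maximum(center - int(np.ceil(radius)), 0)
        hi = np.minimum(center + int(np.ceil(radius)) + 1, shape)
        sub = tuple(slice(a, b) for a, b in zip(lo, hi))
        sub_idx = np.indices([b - a for a, b in zip(lo, hi)])
        r2 = sum((sub_idx[k] + lo[k] - center[k]) ** 2 for k in range(3))
        sphere = r2 <= radius**2
        mask[sub] |= sphere

        t1_les = rng.uniform(*les.t1_range)
        # apparent T2 grows super-linearly with T1 so lesions stay
        # FLAIR-hyperintense even where the long TI suppresses their
        # recovered magnetization, and the intensity-T1 relation is smooth
        t2_les = min(wm_props.t2 * (t1_les / wm_props.t1) ** 1.8, 0.9 * t1_les)
        t1[sub][sphere] = t1_les
        t2[sub][sphere] = t2_les
        pd[sub][sphere] = les.pd
    return mask


def _tissue_signals(spec: PhantomSpec, sequence: str, *, params=None, ti=None) -> dict[str, float]:
    """Signed per-tissue signal for one contrast."""
    out = {}
    for name in TISSUES:
        props = spec.tissue_table[name]
        out[name] = _voxel_signal(props.t1, props.t2, props.pd, sequence, params=params, ti=ti)
    return out


def _voxel_signal(t1, t2, pd, sequence: str, *, params=None, ti=None):
    if sequence == "mprage":
        p = params or MprageParams()
        kernel = 1.0 - 2.0 * np.exp(-p.ti / t1) + np.exp(-p.tr_eff / t1)
        return pd * kernel * np.exp(-p.te / t2)
    if sequence == "flair":
        p = params or FlairParams()
        kernel = 1.0 - 2.0 * np.exp(-p.ti / t1) + np.exp(-p.tr / t1)
        return pd * kernel * np.exp(-p.te / t2)
    if sequence == "ir":
        if ti is None:
            raise ValueError("IR rendering requires an inversion time ti")
        p = params or IRSeriesParams()
        kernel = 1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-p.tr / t1)
        return pd * kernel * np.exp(-p.te / t2)
    raise ValueError(f"unknown sequence {sequence!r}; expected mprage, flair or ir")


def render_contrast(
    phantom: TissuePhantom, sequence: str, *, params=None, ti: float | None = None
) -> np.ndarray:
    """Render one noiseless magnitude contrast.

    Per voxel, the signed signals of the seven tissues are mixed with the
    probability weights (partial-volume model); lesion voxels are rendered
    from their own ground-truth (T1, T2, PD); the magnitude is returned.
    Background stays exactly zero.
    """
    spec = phantom.spec
    signals = _tissue_signals(spec, sequence, params=params, ti=ti)
    signed = np.zeros(phantom.shape)
    for name in TISSUES:
        signed += phantom.prob_maps[name] * signals[name]
    if np.any(phantom.lesion_mask):
        m = phantom.lesion_mask
        signed[m] = _voxel_signal(
            phantom.t1_volume[m],
            phantom.t2_volume[m],
            phantom.pd_volume[m],
            sequence,
            params=params,
            ti=ti,
        )
    return np.abs(signed)


def render_ir_series(
    phantom: TissuePhantom, params: IRSeriesParams = IRSeriesParams()
) -> list[np.ndarray]:
    """Noiseless magnitude IR series, one volume per inversion time."""
    return [
        render_contrast(phantom, "ir", params=params, ti=ti) for ti in params.inversion_times
    ]


def add_rician_noise(volume: np.ndarray, sigma: float, seed_or_rng=0) -> np.ndarray:
    """Rician-corrupt a magnitude volume: sqrt((v + n1)^2 + n2^2) with n1, n2
    iid zero-mean Gaussians of scale ``sigma``. ``sigma = 0`` returns |v|."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    v = np.asarray(volume, dtype=float)
    if sigma == 0:
        return np.abs(v)
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n1 = rng.normal(0.0, sigma, v.shape)
    n2 = rng.normal(0.0, sigma, v.shape)
    return np.sqrt((v + n1) ** 2 + n2**2)


def apply_bias_field(
    volume: np.ndarray,
    amplitude: float,
    seed_or_rng=0,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Multiply by a smooth random quadratic field with mean 1 over the mask
    (whole volume if none) and peak fractional deviation <= ``amplitude``."""
    if not (0.0 <= amplitude < 1.0):
        raise ValueError(f"bias amplitude must lie in [0, 1), got {amplitude}")
    v = np.asarray(volume, dtype=float)
    if amplitude == 0.0:
        return v.copy()
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    grids = [np.linspace(-1.0, 1.0, n) for n in v.shape]
    x, y, z = np.meshgrid(*grids, indexing="ij")
    basis = [x, y, z, x * y, x * z, y * z, x**2, y**2, z**2]
    coef = rng.normal(0.0, 1.0, len(basis))
    poly = sum(c * b for c, b in zip(coef, basis))
    mask = np.ones(v.shape, dtype=bool) if brain_mask is None else brain_mask
    poly = poly - poly[mask].mean()
    peak = np.abs(poly).max()
    field_vol = 1.0 + amplitude * poly / peak
    return v * field_vol


def simulate_study(spec: PhantomSpec, ir_params: IRSeriesParams | None = None,
                   mprage_params: MprageParams | None = None,
                   flair_params: FlairParams | None = None) -> dict:
    """Generate a full synthetic study: phantom + noisy rendered contrasts.

    Noise convention: for MPRAGE and FLAIR, the Rician sigma is
    ``noise_sigma`` times that contrast's pure-WM signal magnitude
    (per-volume WM SNR = 1/noise_sigma). The IR series uses one common
    absolute sigma anchored to the WM signal at the longest TI, since the
    per-TI WM signal crosses zero through the series.

    Returns a dict with the phantom under ``"phantom"``, noisy volumes under
    ``"mprage"``, ``"flair"`` and ``"ir_series"`` (list ordered by TI), and
    the IR parameters used under ``"ir_params"``.
    """
    ir_params = ir_params or IRSeriesParams()
    phantom = generate_phantom(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x51CA]))
    wm = spec.tissue_table["wm"]

    out: dict = {"phantom": phantom, "ir_params": ir_params}
    for name, seq, params in (
        ("mprage", "mprage", mprage_params),
        ("flair", "flair", flair_params),
    ):
        clean = render_contrast(phantom, seq, params=params)
        if spec.bias_amplitude > 0:
            clean = apply_bias_field(clean, spec.bias_amplitude, rng, phantom.brain_mask)
        wm_sig = abs(_voxel_signal(wm.t1, wm.t2, wm.pd, seq, params=params))
        out[name] = add_rician_noise(clean, spec.noise_sigma * wm_sig, rng)

    ti_max = ir_params.inversion_times[-1]
    wm_ref = abs(_voxel_signal(wm.t1, wm.t2, wm.pd, "ir", params=ir_params, ti=ti_max))
    sigma_ir = spec.noise_sigma * wm_ref
    series = []
    for ti in ir_params.inversion_times:
        clean = render_contrast(phantom, "ir", params=ir_params, ti=ti)
        series.append(add_rician_noise(clean, sigma_ir, rng))
    out["ir_series"] = series
    return out
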