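# Methods

## Signal models

All three acquisitions are modelled as an inversion preparation followed by
a readout, sharing the recovery kernel

S = PD · (1 − 2·exp(−TI/T1) + exp(−TR/T1)) · exp(−TE/T2).

* **IR FSE series** — TI ∈ {50, 100, 200, 500, 1000, 2200, 3000} ms,
  TR = 7000 ms, TE = 10 ms. TE is constant across the series, so its decay
  factor is absorbed into the fitted amplitude s0.
* **MPRAGE** — modelled as a single-point snapshot of the recovery at
  TI = 880 ms with TE = 2.2 ms. The shot repetition period of the gradient-
  echo train is not part of the model; an *effective* recovery period
  `tr_eff` (default 2300 ms, configurable) stands in for it. Full transient
  echo-train (Bloch) simulation is deliberately out of scope; the snapshot
  keeps the one property the classifier relies on — the signed signal is
  strictly decreasing in T1 over the 400–3980 ms class range for the
  default timing (verified by test, not assumed). T2* is not modelled
  separately from T2.
* **FLAIR** — TI = 1800 ms, TR = 5000 ms, TE = 374 ms. The long TI nulls
  long-T1 fluid; the long TE leaves T2-weighted parenchymal signal.

Signals are signed; magnitudes are taken at render time, where noise is
added, mirroring magnitude acquisition.

## Phantom

The phantom replaces patient data. Geometry is parametric: a brain
ellipsoid with an outer CSF shell, a cortical GM ribbon, a WM interior,
and mirrored deep structures (thalamus, caudate, putamen, globus pallidus,
CSF ventricles) sized so that every tissue keeps a pure core (a full
3-voxel neighbourhood of one class) on grids down to ~40³. Partial-volume
shells come from a 3-voxel box blur of the one-hot tissue indicators,
renormalized to a partition of unity inside the brain — this places
fractional probabilities at every boundary so the classifier is exercised
off the pure-tissue vertices.

Default tissue parameters (3T literature ranges, configurable in
`data/default_config.yaml`):

| tissue | T1 (ms) | T2app (ms) | PD |
|--------|---------|------------|------|
| WM | 850 | 300 | 0.70 |
| GM | 1330 | 380 | 0.85 |
| CSF | 4200 | 1800 | 1.00 |
| caudate | 1250 | 380 | 0.85 |
| globus pallidus | 980 | 300 | 0.75 |
| thalamus | 1150 | 340 | 0.80 |
| putamen | 1120 | 350 | 0.80 |

The T2 column is an **apparent (FSE-readout) T2**, not a spin-echo T2.
Long-echo-train FSE readouts refocus much of the decay, so the effective T2
governing contrast at the nominal TE = 374 ms of 3D FLAIR is several times
the spin-echo value; with true tissue T2 (~70–90 ms) the rendered FLAIR
would have essentially no parenchymal signal and CSF would not be the
darkest tissue. Only FLAIR is sensitive to this choice — the IR series
(TE = 10 ms) and MPRAGE (TE = 2.2 ms) are nearly TE-independent. CSF T1 is
set to 4200 ms, near the null of the default FLAIR timing and above the
3980 ms class-grid ceiling, so CSF labels clamp to the boundary class —
which is why CSF is reported but excluded from pooled agreement statistics.

**Lesions** are spheres carved into pure WM (disjoint, ≥ 1 voxel margin
from any boundary), with T1 drawn uniformly from 1100–1600 ms, PD 0.72 and
apparent T2 scaling as T2_WM·(T1/T1_WM)^1.8. The super-linear exponent
keeps lesions FLAIR-hyperintense across the whole T1 range (at the high-T1
end the inversion suppresses recovered magnetization faster than a linear
T2 gain can compensate) and makes the intensity→T1 relation smooth, hence
learnable. Lesion voxels keep p_WM = 1 in the probability maps — emulating
segmentation software that does not know about lesions — and are rendered
from their own voxel-wise (T1, T2, PD).

**Noise** is Rician: sqrt((v+n1)² + n2²) with iid Gaussian n1, n2. The
spec's `noise_sigma` is relative to the pure-WM signal of each contrast
(per-volume WM SNR = 1/σ; default 0.02, i.e. SNR 50). The IR series uses
one common absolute σ across TIs (thermal noise does not vary with TI),
anchored to the WM signal at the longest TI because the per-TI WM signal
crosses zero inside the series. An optional multiplicative bias field (a
random quadratic polynomial, mean 1 over the brain, peak deviation ≤ the
configured amplitude) can probe robustness; default amplitude 0.

The training mask keeps the superior two thirds of axial slices, emulating
the exclusion of voxels inferior to the hippocampus.

## Preprocessing

Both contrasts are divided by their own mean over high-confidence WM
(p_WM > 0.95, at least 100 voxels) — each volume by *its own* WM mean, so
FLAIR is normalized by the FLAIR WM mean. The WM reference is computed
without lesion exclusion; with default geometry lesions are < 1% of the
WM reference set and shift the FLAIR reference by < 1%. Lesion
segmentation thresholds normalized FLAIR at μ_WM + z·σ_WM (default z = 3)
inside parenchyma (p_WM + p_GM > 0.5), removes components below 3 voxels
(26-connectivity), and falls back to a user-supplied absolute threshold
when the WM distribution is degenerate (noiseless data) — the manual
override of a semi-automated workflow.

## IR fitting

Magnitude data lose the sign of the inverted magnetization. Because TIs are
ordered and the signed recovery is monotone in TI, the sign pattern is
always −…−+…+; the fitter searches all n+1 flip positions exhaustively.
Three fitting paths share the objective ‖s0·g(TI;T1) − s_signed‖²:

* `fit_ir_voxel`: scipy bounded least squares (T1 ∈ [50, 6000] ms,
  s0 ≥ 0), multi-start at T1 ∈ {400, 1000, 3000} ms to avoid local minima
  near the null crossing, cost tolerance 1e−8.
* `fit_ir_map`: vectorized profiled-cost search — s0 has a closed form for
  fixed (T1, flip), so the cost is scanned on a 160-point log grid over T1
  jointly with the flip, then refined by ~45 golden-section iterations
  inside the winning coarse bracket. The flip is ambiguous when a TI sits
  near the null crossing, so the best *two* flip candidates are refined and
  the lower final cost wins. This processes a 96³ brain in ~30 s where a
  per-voxel scipy loop would take hours; oracle-equivalence tests pin the
  two paths together to one 10 ms grid step.
* `grid_oracle_fit`: brute-force (T1 grid × flip) search, used only as a
  test oracle.

Voxels that are all-zero or non-finite are invalid ("degenerate"); fits
pinned at a T1 bound are valid but flagged ("boundary"). The 2-parameter
model (with the TR recovery term) is used throughout; TE decay is absorbed
into s0.

## Classifier

Features are assembled in a fixed order (MPRAGE, FLAIR, then the seven
probabilities); rows with non-finite entries are dropped and counted.
Labels are reference T1 quantized to the class grid (nearest value,
half-up, clamped to [400, 3980] ms). No feature standardization is applied
before the Euclidean distance by default — normalized intensities (≈0–2)
and probabilities (0–1) are already commensurate — but a z-scoring switch
exists and is recorded in the model provenance. Exact-distance ties
resolve to the lowest T1 class (deterministic and order-independent); the
accelerated neighbour search retrieves a few extra neighbours so ties are
resolved identically to the exhaustive scan. k > 1 uses majority voting
with the same tie rule. Prediction streams query rows in 65 536-voxel
blocks, so memory stays bounded against a multi-million-row store. The
store serializes to a versioned `.npz` container (features, labels, grid,
provenance) with a bit-exact round trip.

## Agreement analysis

Tissue membership is by probability threshold (default 0.95; argmax mode
exists). Percent differences are |test − ref|/ref × 100 averaged per
tissue. SSIM uses Gaussian windows (σ = 1.5), c1 = (0.01·L)²,
c2 = (0.03·L)² with L fixed at 4000 ms (input-derived ranges would make
values incomparable across runs), averaged inside the brain mask when one
is given. Bland–Altman differences are in percent of the pairwise mean
(raw-ms mode available) with limits at ±1.96 sample (n−1) SD; CSF is
excluded from the pooled analysis by default. Regression is OLS of test on
reference. A lesion row appears iff a non-empty lesion mask is supplied.

## Problem sizes and seeds

The held-out validation in `scripts/acceptance.py` uses two 96³ subjects
at WM SNR 50 — the package's default study scale, chosen so the phantom
carries ~285 k brain voxels and ~225 k training exemplars while a full run
finishes in a few minutes on one CPU. Unit and property tests run at 48³.
Every random draw descends from the configured seed (phantom geometry,
lesion draws, noise fields), so identical configurations reproduce
bit-identical volumes, maps and reports.

## What the phantom does and does not show

Passing tests demonstrate the method's internal consistency: correct
implementation of the signal physics, fitting, classification and
statistics, end-to-end scale invariance, and that prediction transfers
across subjects *drawn from the same tissue model*. The phantom's
piecewise-constant tissues with literature T1s make the classification
easier than in vivo data, where intra-tissue T1 dispersion, registration
error, segmentation error, B1 inhomogeneity and pathology-dependent
contrast all widen the feature-to-T1 mapping. Phantom agreement numbers
are therefore analogues of, not substitutes for, in vivo validation.

## Known limitations

* MPRAGE is a snapshot model; no echo-train transient, no B1+ transmit
  effects, no k-space or motion artefacts.
* Single-compartment relaxation only; no magnetization transfer or
  multi-component T1.
* The class grid ceiling (3980 ms) truncates CSF-like T1s by design.
* The phantom's geometry is parametric, not atlas-derived.
* Registration and tissue-probability segmentation are assumed done
  upstream for real data; the phantom generates its own probability maps.
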