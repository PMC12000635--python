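"""Closed-form steady-state signal models for the three acquisitions.

All three sequences are inversion-recovery preparations followed by a readout,
so each signal shares the same longitudinal recovery kernel

    S = PD * (1 - 2*exp(-TI/T1) + exp(-TR/T1)) * exp(-TE/T2)

with the sequence differing only in its (TI, TR, TE) operating point:

* IR FSE series — seven images at TI = 50..3000 ms, TR = 7 s, TE = 10 ms;
  the gold-standard T1 measurement.
* MPRAGE — treated as a single-point snapshot of the recovery at TI = 880 ms
  with an effective recovery period ``tr_eff`` standing in for the shot TR;
  full transient gradient-echo-train simulation is deliberately avoided.
* FLAIR — long-TI inversion (TI = 1800 ms, TR = 5000 ms) that nulls
  long-T1 fluid, with heavy T2 weighting at TE = 374 ms.

Signals are *signed* (real-valued): the magnitude operation belongs to the
image renderer, where noise is added, mirroring magnitude acquisition.

All functions broadcast over array-valued tissue properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueProperties",
    "IRSeriesParams",
    "MprageParams",
    "FlairParams",
    "ir_signal",
    "mprage_signal",
    "flair_signal",
]

#: Printed IR FSE inversion times (ms).
DEFAULT_IR_TIS = (50.0, 100.0, 200.0, 500.0, 1000.0, 2200.0, 3000.0)


@dataclass(frozen=True)
class TissueProperties:
    """Relaxation and density parameters of a tissue compartment.

    Parameters
    ----------
    t1 : float
        Longitudinal relaxation time in ms; must be positive.
    t2 : float
        Transverse relaxation time in ms (for the FSE readout this is an
        *apparent* T2); must be positive and not exceed t1.
    pd : float
        Proton density in arbitrary units; non-negative.
    """

    t1: float
    t2: float
    pd: float = 1.0

    def __post_init__(self) -> None:
        if not (np.all(np.asarray(self.t1) > 0) and np.all(np.isfinite(self.t1))):
            raise ValueError(f"t1 must be positive and finite, got {self.t1}")
        if not (np.all(np.asarray(self.t2) > 0) and np.all(np.isfinite(self.t2))):
            raise ValueError(f"t2 must be positive and finite, got {self.t2}")
        if np.any(np.asarray(self.t2) > np.asarray(self.t1)):
            raise ValueError(f"t2 ({self.t2}) must not exceed t1 ({self.t1})")
        if np.any(np.asarray(self.pd) < 0):
            raise ValueError(f"pd must be non-negative, got {self.pd}")


@dataclass(frozen=True)
class IRSeriesParams:
    """Inversion-recovery FSE series timing (all in ms)."""

    inversion_times: tuple[float, ...] = DEFAULT_IR_TIS
    tr: float = 7000.0
    te: float = 10.0

    def __post_init__(self) -> None:
        tis = np.asarray(self.inversion_times, dtype=float)
        if tis.size < 1 or np.any(tis <= 0):
            raise ValueError("all inversion times must be positive")
        if np.any(np.diff(tis) <= 0):
            raise ValueError("inversion times must be strictly increasing")
        if self.tr <= tis[-1]:
            raise ValueError(f"tr ({self.tr}) must exceed the longest TI ({tis[-1]})")
        object.__setattr__(self, "inversion_times", tuple(float(t) for t in tis))


@dataclass(frozen=True)
class MprageParams:
    """MPRAGE snapshot timing (ms); ``tr_eff`` is the effective recovery
    period per shot, a configurable stand-in for the unprinted shot TR."""

    ti: float = 880.0
    tr_eff: float = 2300.0
    te: float = 2.2

    def __post_init__(self) -> None:
        if self.ti <= 0:
            raise ValueError(f"ti must be positive, got {self.ti}")
        if self.tr_eff <= self.ti:
            raise ValueError(f"tr_eff ({self.tr_eff}) must exceed ti ({self.ti})")
        if self.te < 0:
            raise ValueError(f"te must be non-negative, got {self.te}")


@dataclass(frozen=True)
class FlairParams:
    """FLAIR timing (ms)."""

    ti: float = 1800.0
    tr: float = 5000.0
    te: float = 374.0

    def __post_init__(self) -> None:
        if self.ti <= 0:
            raise ValueError(f"ti must be positive, got {self.ti}")
        if self.tr <= self.ti:
            raise ValueError(f"tr ({self.tr}) must exceed ti ({self.ti})")
        if self.te < 0:
            raise ValueError(f"te must be non-negative, got {self.te}")


def _ir_kernel(t1, ti, tr):
    t1 = np.asarray(t1, dtype=float)
    return 1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr / t1)


def ir_signal(props: TissueProperties, ti: float, tr: float, te: float = 0.0):
    """Signed inversion-recovery signal at inversion time ``ti``.

    Negative at short TI (inverted magnetization not yet recovered), crossing
    zero near T1*ln2 and saturating towards +pd as TI grows.
    """
    if ti <= 0:
        raise ValueError(f"ti must be positive, got {ti}")
    if tr <= ti:
        raise ValueError(f"tr ({tr}) must exceed ti ({ti})")
    return props.pd * _ir_kernel(props.t1, ti, tr) * np.exp(-te / np.asarray(props.t2, dtype=float))


def mprage_signal(props: TissueProperties, params: MprageParams = MprageParams()):
    """Signed MPRAGE snapshot signal; monotonically decreasing in T1 over the
    physiological class range for the default timing."""
    return (
        props.pd
        * _ir_kernel(props.t1, params.ti, params.tr_eff)
        * np.exp(-params.te / np.asarray(props.t2, dtype=float))
    )


def flair_signal(props: TissueProperties, params: FlairParams = FlairParams()):
    """Signed FLAIR signal: long-T1 fluid is nulled by the inversion, and the
    long echo time leaves mostly T2-weighted parenchymal signal."""
    return (
        props.pd
        * _ir_kernel(props.t1, params.ti, params.tr)
        * np.exp(-params.te / np.asarray(props.t2, dtype=float))
    )
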