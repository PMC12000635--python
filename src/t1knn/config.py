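"""Study configuration: one human-readable YAML file, validated on load.

Unknown keys are rejected (the offending key is named in the error) so typos
cannot silently fall back to defaults. The packaged
``data/default_config.yaml`` carries the default sequence timings, class
grid, thresholds and phantom specification.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .knn import T1ClassGrid
from .phantom import LesionSpec, PhantomSpec
from .signals import FlairParams, IRSeriesParams, MprageParams, TissueProperties

__all__ = ["StudyConfig", "load_config", "default_config"]


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MprageConfig(_Forbid):
    ti: float = 880.0
    tr_eff: float = 2300.0
    te: float = 2.2


class FlairConfig(_Forbid):
    ti: float = 1800.0
    tr: float = 5000.0
    te: float = 374.0


class IRConfig(_Forbid):
    inversion_times: list[float] = [50.0, 100.0, 200.0, 500.0, 1000.0, 2200.0, 3000.0]
    tr: float = 7000.0
    te: float = 10.0


class SequenceConfig(_Forbid):
    mprage: MprageConfig = MprageConfig()
    flair: FlairConfig = FlairConfig()
    ir: IRConfig = IRConfig()


class GridConfig(_Forbid):
    t1_min: float = 400.0
    t1_max: float = 3980.0
    step: float = 10.0


class ThresholdConfig(_Forbid):
    wm_probability: float = 0.95
    tissue_probability: float = 0.95
    lesion_z: float = 3.0
    min_lesion_component: int = 3


class KnnConfig(_Forbid):
    k: int = 1
    standardize: bool = False


class EvaluateConfig(_Forbid):
    ssim_data_range: float = 4000.0
    exclude_csf_from_pooled: bool = True


class LesionConfig(_Forbid):
    count: int = 5
    radius_range: tuple[float, float] = (2.0, 4.0)
    t1_range: tuple[float, float] = (1100.0, 1600.0)
    pd: float = 0.72


class PhantomConfig(_Forbid):
    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sigma: float = 0.02
    bias_amplitude: float = 0.0
    lesions: LesionConfig = LesionConfig()
    tissue_table: dict[str, tuple[float, float, float]] = {
        "wm": (850.0, 300.0, 0.70),
        "gm": (1330.0, 380.0, 0.85),
        "csf": (4200.0, 1800.0, 1.00),
        "cau": (1250.0, 380.0, 0.85),
        "gp": (980.0, 300.0, 0.75),
        "tha": (1150.0, 340.0, 0.80),
        "put": (1120.0, 350.0, 0.80),
    }


class StudyConfig(_Forbid):
    """Validated study configuration (see ``data/default_config.yaml``)."""

    seed: int = 0
    sequence: SequenceConfig = SequenceConfig()
    grid: GridConfig = GridConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    knn: KnnConfig = KnnConfig()
    evaluate: EvaluateConfig = EvaluateConfig()
    phantom: PhantomConfig = PhantomConfig()

    # -- conversions to the domain objects -------------------------------
    def mprage_params(self) -> MprageParams:
        m = self.sequence.mprage
        return MprageParams(ti=m.ti, tr_eff=m.tr_eff, te=m.te)

    def flair_params(self) -> FlairParams:
        f = self.sequence.flair
        return FlairParams(ti=f.ti, tr=f.tr, te=f.te)

    def ir_params(self) -> IRSeriesParams:
        i = self.sequence.ir
        return IRSeriesParams(inversion_times=tuple(i.inversion_times), tr=i.tr, te=i.te)

    def class_grid(self) -> T1ClassGrid:
        g = self.grid
        return T1ClassGrid(t1_min=g.t1_min, t1_max=g.t1_max, step=g.step)

    def phantom_spec(self, seed: int | None = None) -> PhantomSpec:
        p = self.phantom
        table = {
            name: TissueProperties(t1=v[0], t2=v[1], pd=v[2])
            for name, v in p.tissue_table.items()
        }
        les = LesionSpec(
            count=p.lesions.count,
            radius_range=tuple(p.lesions.radius_range),
            t1_range=tuple(p.lesions.t1_range),
            pd=p.lesions.pd,
        )
        return PhantomSpec(
            shape=tuple(p.shape),
            voxel_size=tuple(p.voxel_size),
            tissue_table=table,
            lesion_spec=les,
            noise_sigma=p.noise_sigma,
            bias_amplitude=p.bias_amplitude,
            seed=self.seed if seed is None else int(seed),
        )

    def dump_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        )


def load_config(path) -> StudyConfig:
    """Load and validate a YAML study configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    return StudyConfig.model_validate(raw)


def default_config() -> StudyConfig:
    """The packaged default configuration."""
    text = (
        importlib.resources.files("t1knn").joinpath("data/default_config.yaml").read_text()
    )
    return StudyConfig.model_validate(yaml.safe_load(text))
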