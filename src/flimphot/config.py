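"""Run configuration: a validated schema for the full pipeline.

Unknown keys are rejected; every pump entry must state its Na+
half-activation (there is no defensible default for alpha3, so it must
be supplied explicitly when used).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .io import read_json
from .ionmodels import HillPump, SBFICalibration
from .tcspc import IRFModel
from .traces import AnalysisThresholds

__all__ = ["RunConfig", "default_config_dict", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IRFSettings(_Strict):
    center_ns: float = 0.5
    sigma_ns: float = Field(0.1, gt=0)
    mode: Literal["fixed", "fit"] = "fixed"

    def to_model(self) -> IRFModel:
        return IRFModel(center_ns=self.center_ns, sigma_ns=self.sigma_ns)


class FitSettings(_Strict):
    components: Literal[1, 2] = 2
    window_ns: float = Field(8.0, gt=0)
    objective: Literal["poisson", "lsq"] = "poisson"


class TCSPCSettings(_Strict):
    laser_period_ns: float = Field(12.5, gt=0)
    n_bins: int = Field(256, ge=16)
    irf: IRFSettings = IRFSettings()
    fit: FitSettings = FitSettings()


class UnmixingSettings(_Strict):
    ratio: float | None = Field(0.053, ge=0, lt=1)
    controls_path: str | None = None

    @model_validator(mode="after")
    def _one_source(self):
        if self.ratio is None and self.controls_path is None:
            raise ValueError("provide either a ratio or a controls_path")
        return self


class ThresholdSettings(_Strict):
    min_delta_rcamp_ns: float = Field(0.2, gt=0)
    max_half_decay_s: float = Field(35.0, gt=0)
    baseline_window_s: float = Field(60.0, gt=0)

    def to_model(self) -> AnalysisThresholds:
        return AnalysisThresholds(
            min_delta_rcamp_ns=self.min_delta_rcamp_ns,
            max_half_decay_s=self.max_half_decay_s,
            baseline_window_s=self.baseline_window_s,
        )


class CalibrationSettings(_Strict):
    kd: float = Field(gt=0)  # required: the calibration is meaningless without it
    na_rest: float = Field(ge=0)
    quench_amplitude_a: float = Field(0.74, gt=0, le=1)

    def to_model(self) -> SBFICalibration:
        return SBFICalibration(
            kd=self.kd, na_rest=self.na_rest, quench_amplitude_a=self.quench_amplitude_a
        )


class PumpSettings(_Strict):
    k_half: float = Field(gt=0)  # required for every isozyme entry
    hill_n: float = Field(3.0, gt=0)

    def to_model(self, isozyme: str) -> HillPump:
        return HillPump(isozyme=isozyme, k_half=self.k_half, hill_n=self.hill_n)


class SynthSettings(_Strict):
    preset: Literal["acsf_vs_cavblock", "puff_pair"] = "acsf_vs_cavblock"
    n_cells: int = Field(13, ge=2)
    photon_level: bool = False
    photons_per_frame: int = Field(100_000, ge=10_000)


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "results"
    tcspc: TCSPCSettings = TCSPCSettings()
    unmixing: UnmixingSettings = UnmixingSettings()
    thresholds: ThresholdSettings = ThresholdSettings()
    calibration: CalibrationSettings
    pumps: dict[str, PumpSettings] = {
        "alpha1beta1": PumpSettings(k_half=13.0, hill_n=3.0)
    }
    synth: SynthSettings = SynthSettings()

    @model_validator(mode="after")
    def _need_alpha1(self):
        if "alpha1beta1" not in self.pumps:
            raise ValueError("pumps must include an 'alpha1beta1' entry")
        return self


def default_config_dict(seed: int = 0) -> dict:
    """A complete, valid configuration as a plain dict."""
    return {
        "seed": seed,
        "output_dir": "results",
        "calibration": {"kd": 26.0, "na_rest": 13.0, "quench_amplitude_a": 0.74},
        "pumps": {"alpha1beta1": {"k_half": 13.0, "hill_n": 3.0}},
    }


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON config file before any stage runs."""
    return RunConfig.model_validate(read_json(path))
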