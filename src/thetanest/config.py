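"""Run configuration: schema-validated YAML in, model objects out.

An empty file (or missing section) yields the reference parameterization:
the published oscillator table, cell classes, synaptic increments and
tuned inter-area gains at scale 1.  Unknown keys are rejected with a
message naming the offending field.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .kuramoto import OscillatorEnsembleParams
from .network import NetworkConfig, StimulusProtocol
from .neurons import excitatory_params, inhibitory_params
from .synapses import SynapseParams, EXC_SYNAPSE, INH_SYNAPSE
from .topology import A_INTER_DEFAULT

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SeptumSection(_Strict):
    n_oscillators: int = 250
    center_frequency_hz: float = 6.0
    frequency_sd_hz: float = 0.5
    sync_ratio: float = 15.0
    reset_gain: float = 4.0
    peak_phase_rad: float = 0.0
    phase_offset_rad: float = 0.0
    theta_gain_na: float = 0.2
    rate_time_constant_ms: float = 10.0
    seed: int = 0

    def to_params(self) -> OscillatorEnsembleParams:
        return OscillatorEnsembleParams(**self.model_dump())


class CellOverrides(_Strict):
    g_CAN: float | None = None
    g_M: float | None = None
    g_Ca: float | None = None
    noise_sd_uv: float | None = None


class AreasSection(_Strict):
    counts: dict[str, tuple[int, int]] | None = None
    excitatory: CellOverrides = Field(default_factory=CellOverrides)
    inhibitory: CellOverrides = Field(default_factory=CellOverrides)

    @field_validator("counts")
    @classmethod
    def _known_areas(cls, v):
        if v is not None:
            unknown = set(v) - {"EC", "DG", "CA3", "CA1"}
            if unknown:
                raise ValueError(f"unknown areas: {sorted(unknown)}")
        return v


class SynapseSection(_Strict):
    exc_reversal_mv: float = EXC_SYNAPSE.reversal_mv
    exc_rise_ms: float = EXC_SYNAPSE.rise_ms
    exc_decay_ms: float = EXC_SYNAPSE.decay_ms
    inh_reversal_mv: float = INH_SYNAPSE.reversal_mv
    inh_rise_ms: float = INH_SYNAPSE.rise_ms
    inh_decay_ms: float = INH_SYNAPSE.decay_ms


class TopologySection(_Strict):
    a_inter: dict[str, float] | None = None   # keys like "EC->DG"
    geometry_scale_xy: float = 1.0
    z_extent_um: float | None = None

    def gains(self) -> dict:
        if self.a_inter is None:
            return dict(A_INTER_DEFAULT)
        out = {}
        for key, v in self.a_inter.items():
            src, dst = key.split("->")
            out[(src, dst)] = float(v)
        return out


class StimulationSection(_Strict):
    target_area: str = "CA1"
    amplitude_na: float = 10.0
    pulse_width_ms: float = 1.0
    mode: str = "times"
    times_ms: list[float] = Field(default_factory=list)
    phase_rad: float = 0.0
    arming_ms: float = 0.0
    train_hz: float = 6.0
    train_duration_ms: float = 2000.0
    onset_phase_rad: float | None = None
    enabled: bool = False

    def to_protocol(self) -> StimulusProtocol | None:
        if not self.enabled:
            return None
        d = self.model_dump()
        d.pop("enabled")
        d["times_ms"] = tuple(d["times_ms"])
        return StimulusProtocol(**d)


class TuningSection(_Strict):
    target_exc_rate_hz: float = 6.0
    target_osc_hz: float = 6.0
    theta_gain_grid: tuple[float, float, float] = (0.0, 0.5, 0.01)
    dg_gain_grid: tuple[float, float, float] = (0.0, 20.0, 0.1)
    ca_gain_grid: tuple[float, float, float] = (0.0, 5.0, 0.1)
    j_ceiling: float = 5.0


class AnalysisSection(_Strict):
    phase_band_hz: tuple[float, float] = (3.0, 9.0)
    amp_band_hz: tuple[float, float] = (40.0, 80.0)
    n_phase_bins: int = 72
    comodulogram_noise_fraction: float = 0.2
    rate_bin_ms: float = 5.0
    rate_overlap: float = 0.9


class RuntimeSection(_Strict):
    dt_ms: float = 0.1
    duration_ms: float = 3000.0
    burn_in_ms: float = 0.0
    seed: int = 0
    scale_factor: float = 1.0
    noise: bool = True
    reset: bool = True

    @field_validator("dt_ms")
    @classmethod
    def _dt_positive(cls, v):
        if v <= 0:
            raise ValueError("dt_ms must be > 0")
        return v

    @field_validator("duration_ms")
    @classmethod
    def _dur_positive(cls, v):
        if v <= 0:
            raise ValueError("duration_ms must be > 0")
        return v


class RunConfig(_Strict):
    """Full run configuration (all sections optional in the file)."""

    septum: SeptumSection = Field(default_factory=SeptumSection)
    areas: AreasSection = Field(default_factory=AreasSection)
    synapses: SynapseSection = Field(default_factory=SynapseSection)
    topology: TopologySection = Field(default_factory=TopologySection)
    stimulation: StimulationSection = Field(default_factory=StimulationSection)
    tuning: TuningSection = Field(default_factory=TuningSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    runtime: RuntimeSection = Field(default_factory=RuntimeSection)

    # ---- conversion ----------------------------------------------------
    def to_network_config(self) -> NetworkConfig:
        exc_over = {k: v for k, v in
                    self.areas.excitatory.model_dump().items()
                    if v is not None}
        inh_over = {k: v for k, v in
                    self.areas.inhibitory.model_dump().items()
                    if v is not None}
        inh_over.pop("g_CAN", None)
        inh_over.pop("g_M", None)
        inh_over.pop("g_Ca", None)
        syn = self.synapses
        return NetworkConfig(
            oscillator=self.septum.to_params(),
            counts=self.areas.counts,
            scale=self.runtime.scale_factor,
            a_inter=self.topology.gains(),
            exc_params=excitatory_params(**exc_over),
            inh_params=inhibitory_params(**inh_over),
            exc_synapse=SynapseParams(syn.exc_reversal_mv, syn.exc_rise_ms,
                                      syn.exc_decay_ms),
            inh_synapse=SynapseParams(syn.inh_reversal_mv, syn.inh_rise_ms,
                                      syn.inh_decay_ms),
            dt_ms=self.runtime.dt_ms,
            duration_ms=self.runtime.duration_ms,
            burn_in_ms=self.runtime.burn_in_ms,
            reset_on=self.runtime.reset,
            noise_on=self.runtime.noise,
            seed=self.runtime.seed,
            geometry_scale_xy=self.topology.geometry_scale_xy,
            z_extent_um=self.topology.z_extent_um,
        )

    def to_protocol(self) -> StimulusProtocol | None:
        return self.stimulation.to_protocol()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; empty file → all defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text()) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path):
    Path(path).write_text(config.to_yaml())
    return Path(path)
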