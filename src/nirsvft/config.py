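"""Configuration objects and task constants.

The block design is fixed: a 10 s pre-task rest, a 60 s letter verbal-fluency
task, and a 55 s post-task rest.  The frontal region of interest is an
11-channel cluster of the 52-channel prefrontal probe array (channels 25-28,
36-38 and 46-49, 1-based).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

PRE_TASK_S = 10.0
TASK_S = 60.0
POST_TASK_S = 55.0
TOTAL_S = PRE_TASK_S + TASK_S + POST_TASK_S

N_CHANNELS = 52
#: 1-based indices of the frontal cluster.
FRONTAL_CHANNELS = (25, 26, 27, 28, 36, 37, 38, 46, 47, 48, 49)
#: Minimum number of surviving cluster channels for a subject to be analyzable.
MIN_VALID_CHANNELS = 6

DIAGNOSES = ("HC", "SCZ", "MDD", "BIP")
#: Default threshold separating patients (below) from non-patients (above),
#: in integral units; taken as a given constant from the multi-site ROC study.
INTEGRAL_THRESHOLD = 73.0
#: Default threshold separating psychosis-spectrum (later) from MDD-like
#: (earlier) activation timing, seconds after task onset.
CENTROID_THRESHOLD_S = 54.0


class ConfigError(ValueError):
    """Raised when a configuration value is invalid; names the field."""


# Standardized integral offsets of each diagnosis-by-family-history cell
# relative to healthy controls, used to place the default generator
# amplitudes.  Family-history-positive schizophrenia and depression sit
# lowest; bipolar shows the reverse ordering of its FH subgroups.
_INTEGRAL_OFFSET_D = {
    "HC": 0.0,
    "SCZ+": -1.21,
    "SCZ-": -0.48,
    "MDD+": -1.21,
    "MDD-": -0.80,
    "BIP+": -0.74,
    "BIP-": -1.34,
}
_INTEGRAL_BASELINE = 85.0   # HC mean integral, arbitrary units x s
_INTEGRAL_SCALE = 30.0      # between-subject integral SD, same units

_LATENCY_MEAN_S = {
    "HC": 6.0,
    "SCZ+": 15.5,
    "SCZ-": 12.0,
    "MDD+": 12.0,
    "MDD-": 12.0,
    "BIP+": 18.0,
    "BIP-": 14.0,
}

_KERNEL_RISE_S = 15.0
_KERNEL_DECAY_TAU_S = 15.0


def _kernel_task_area_unit(latency_s: float, rise_s: float = _KERNEL_RISE_S) -> float:
    """Task-window area of the unit-amplitude response kernel (closed form)."""
    reach = TASK_S - latency_s
    if reach <= 0:
        return 0.0
    if reach >= rise_s:
        return reach - rise_s / 2.0
    return reach * reach / (2.0 * rise_s)


def _default_amplitudes() -> dict[str, float]:
    # Amplitude that puts the group's mean integral at baseline + d*scale,
    # compensating for the latency-shortened task-window kernel area.
    out = {}
    for label, d in _INTEGRAL_OFFSET_D.items():
        area = _kernel_task_area_unit(_LATENCY_MEAN_S[label])
        out[label] = (_INTEGRAL_BASELINE + d * _INTEGRAL_SCALE) / area
    return out


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort and recording generator.

    The defaults emulate the study structure: four diagnostic groups of
    45/26/22/51 subjects, family-history splits per diagnosis, 52-channel
    recordings sampled at 0.1 s with an 11-channel frontal cluster carrying
    the task response, group-dependent activation amplitude and latency, and
    a small rate of artifact-corrupted channels.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"SCZ": 45, "MDD": 26, "BIP": 22, "HC": 51})
    #: fraction of each diagnosis with a positive family history of any
    #: psychiatric disorder (17/45, 10/26, 10/22 for patients; 0 for HC).
    fh_fraction: dict[str, float] = field(
        default_factory=lambda: {"SCZ": 17 / 45, "MDD": 10 / 26,
                                 "BIP": 10 / 22, "HC": 0.0})
    #: P(FH of a *major* psychiatric disorder | any-psychiatric FH+).
    fh_major_given_any: float = 0.65
    #: P(FH of the *same* disorder | major-psychiatric FH+).
    fh_same_given_major: float = 0.5
    #: fraction of FH-negative patients whose family history is unknown.
    fh_unknown_rate: float = 0.0
    amplitude_mean: dict[str, float] = field(default_factory=_default_amplitudes)
    #: ~ integral SD 30 / mean latency-shifted kernel task area (~48)
    amplitude_sd: float = 0.62
    latency_shift_s: dict[str, float] = field(
        default_factory=lambda: dict(_LATENCY_MEAN_S))
    latency_sd_s: float = 4.0
    noise_sd: float = 0.3
    artifact_channel_rate: float = 0.02
    #: activation gain of channels outside the frontal cluster.
    nonfrontal_gain: float = 0.3
    kernel_rise_s: float = _KERNEL_RISE_S
    kernel_decay_tau_s: float = _KERNEL_DECAY_TAU_S
    sampling_interval_s: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0 or int(n) != n:
                raise ConfigError(f"group_sizes[{g!r}] must be a count >= 0, got {n}")
        for g, f in self.fh_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"fh_fraction[{g!r}] must be in [0, 1], got {f}")
        for name in ("fh_major_given_any", "fh_same_given_major",
                     "fh_unknown_rate", "artifact_channel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("amplitude_sd", "latency_sd_s", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.sampling_interval_s <= 0:
            raise ConfigError(
                f"sampling_interval_s must be > 0, got {self.sampling_interval_s}")
        if self.kernel_rise_s <= 0 or self.kernel_decay_tau_s <= 0:
            raise ConfigError("kernel_rise_s and kernel_decay_tau_s must be > 0")
        missing = [g for g in self.group_sizes if g not in DIAGNOSES]
        if missing:
            raise ConfigError(f"group_sizes has unknown diagnoses {missing}")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def group_label(self, diagnosis: str, fh_positive) -> str:
        """Amplitude/latency cell for a subject: 'HC', 'SCZ+', 'SCZ-', ..."""
        if diagnosis == "HC":
            return "HC"
        if fh_positive is None:
            # unknown family history: draw from the FH-negative cell
            return f"{diagnosis}-"
        return f"{diagnosis}{'+' if fh_positive else '-'}"


@dataclass
class WaveformConfig:
    """Feature-extraction settings (QC, baseline, integration)."""

    cluster: tuple[int, ...] = FRONTAL_CHANNELS   # 1-based channel indices
    min_valid_channels: int = MIN_VALID_CHANNELS
    #: jump threshold in robust SDs of the channel's first differences.
    jump_k: float = 10.0
    #: a flagged jump must also exceed this fraction of the channel's robust
    #: peak-to-peak range (guards smooth noise-free channels).
    jump_floor_frac: float = 0.5
    #: 'prepost' = linear fit through pre-task and late-post-task means;
    #: 'pre' = subtract the pre-task mean only.
    baseline_mode: str = "prepost"
    #: moving-average window (samples); 0 disables smoothing.
    smooth_window: int = 0

    def validate(self) -> None:
        if len(self.cluster) == 0:
            raise ConfigError("cluster must not be empty")
        if self.baseline_mode not in ("prepost", "pre"):
            raise ConfigError(
                f"baseline_mode must be 'prepost' or 'pre', got {self.baseline_mode!r}")
        if self.jump_k <= 0:
            raise ConfigError(f"jump_k must be > 0, got {self.jump_k}")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings, loadable from YAML."""

    output_dir: str = "results"
    cohort_path: str | None = None          # None => simulate
    recordings_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    waveform: WaveformConfig = field(default_factory=WaveformConfig)
    integral_threshold: float = INTEGRAL_THRESHOLD
    centroid_threshold_s: float = CENTROID_THRESHOLD_S
    covariates: tuple[str, ...] = ("age_years", "gender", "vft_performance")
    seed: int = 0

    def validate(self, check_paths: bool = False) -> None:
        self.simulation.validate()
        self.waveform.validate()
        if check_paths:
            for name in ("cohort_path", "recordings_dir"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        wf_raw = dict(raw.pop("waveform", {}))
        if "cluster" in wf_raw:
            wf_raw["cluster"] = tuple(wf_raw["cluster"])
        wf = WaveformConfig(**wf_raw)
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, waveform=wf, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["waveform"]["cluster"] = list(self.waveform.cluster)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
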