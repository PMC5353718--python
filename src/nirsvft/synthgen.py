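"""Synthetic cohort and oxy-Hb recording generator.

Emulates a four-group clinical fNIRS study of the letter verbal-fluency
task: 45 schizophrenia (SCZ), 26 major depressive disorder (MDD), 22 bipolar
disorder (BIP) and 51 healthy control (HC) subjects, each with a 52-channel
recording over a 10 s pre-task / 60 s task / 55 s post-task block.  Frontal
channels carry a subject-specific hemodynamic response kernel whose amplitude
and onset latency depend on the diagnosis-by-family-history cell; additive
Gaussian noise and occasional artifact-corrupted channels exercise the
downstream QC.  Every draw is controlled by a single integer seed, so the
same configuration always reproduces the same cohort bit for bit.

The generator exists so that the feature-extraction and statistics stages
can be tested against known ground truth: the expected frontal integral of a
noise-free subject is simply ``amplitude x kernel task-window area``, which
has a closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import (
    DIAGNOSES,
    FRONTAL_CHANNELS,
    N_CHANNELS,
    PRE_TASK_S,
    POST_TASK_S,
    TASK_S,
    TOTAL_S,
    SimulationConfig,
    _kernel_task_area_unit,
)

__all__ = [
    "Subject",
    "Recording",
    "generate_cohort",
    "generate_recording",
    "generate_study",
    "response_kernel",
    "kernel_task_area",
    "analytic_integral_sd",
    "analytic_cohens_d",
]


@dataclass
class Subject:
    """One study participant: demographics, diagnosis, family history."""

    id: str
    diagnosis: str                      # HC | SCZ | MDD | BIP
    fh_any_psychiatric: bool | None     # None = unknown
    fh_major_psychiatric: bool | None
    fh_same_disorder: bool | None
    age_years: float
    gender: str                         # male | female
    education_years: float
    premorbid_iq: float
    handedness: str                     # right | left | bilateral
    vft_performance: int                # correct words in the 60 s task
    cpz_eq_mg_day: float | None = None
    onset_age_years: float | None = None
    illness_duration_years: float | None = None
    symptom_scores: dict = field(default_factory=dict)


@dataclass
class Recording:
    """One subject's multi-channel concentration-change time series."""

    subject_id: str
    sampling_interval_s: float
    channels: np.ndarray                # [n_channels, n_samples]
    task_onset_s: float
    task_offset_s: float
    end_s: float
    deoxy: np.ndarray | None = None
    #: generator bookkeeping (true amplitude/latency, corrupted channels);
    #: not part of the on-disk signal format.
    ground_truth: dict | None = None

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval_s


# ---------------------------------------------------------------------------
# hemodynamic response kernel
# ---------------------------------------------------------------------------

def response_kernel(
    t_s,
    amplitude: float,
    latency_shift_s: float = 0.0,
    rise_s: float = 15.0,
    decay_tau_s: float = 15.0,
    task_duration_s: float = TASK_S,
):
    """Canonical task response at time ``t_s`` relative to task onset.

    Zero until ``latency_shift_s``, linear ramp to ``amplitude`` over
    ``rise_s``, plateau until the (latency-shifted) end of the task, then
    exponential decay with time constant ``decay_tau_s``.  Continuous in t;
    a latency shift is an exact time translation of the zero-latency kernel.
    """
    t = np.asarray(t_s, dtype=float)
    u = t - latency_shift_s
    rise = np.clip(u / rise_s, 0.0, 1.0)
    decay = np.where(u > task_duration_s,
                     np.exp(-(np.maximum(u - task_duration_s, 0.0)) / decay_tau_s),
                     1.0)
    out = amplitude * rise * decay
    if np.isscalar(t_s):
        return float(out)
    return out


def kernel_task_area(
    amplitude: float,
    latency_shift_s: float = 0.0,
    rise_s: float = 15.0,
) -> float:
    """Closed-form integral of the kernel over the 60 s task window."""
    return amplitude * _kernel_task_area_unit(latency_shift_s, rise_s)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# Demographic location/scale per diagnosis: mean age, SD age, male fraction,
# education, premorbid IQ, task performance, handedness probabilities
# (right/left/bilateral), CPZ-equivalent dose, onset age.
_DEMOGRAPHICS = {
    "SCZ": dict(age=(35.4, 9.1), male=16 / 45, edu=(13.2, 1.3), iq=(101.3, 11.6),
                perf=(13.0, 5.4), hand=(40, 3, 2), cpz=(465.3, 407.3),
                onset=(25.5, 6.4), scale=("panss_total", 70.0, 15.0)),
    "MDD": dict(age=(41.1, 12.7), male=17 / 26, edu=(14.3, 2.6), iq=(104.6, 9.2),
                perf=(15.7, 5.3), hand=(24, 2, 0), cpz=(51.4, 88.6),
                onset=(33.8, 13.5), scale=("hamd17", 12.0, 6.0)),
    "BIP": dict(age=(39.9, 12.5), male=13 / 22, edu=(14.7, 2.3), iq=(110.2, 6.2),
                perf=(16.9, 5.3), hand=(19, 1, 2), cpz=(76.7, 131.8),
                onset=(30.6, 9.3), scale=("ymrs", 8.0, 6.0)),
    "HC": dict(age=(35.7, 11.9), male=33 / 51, edu=(16.7, 2.5), iq=(110.0, 6.2),
               perf=(15.3, 4.7), hand=(46, 4, 1), cpz=None,
               onset=None, scale=None),
}

_HANDEDNESS = ("right", "left", "bilateral")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    # clipping rather than rejection: these fields are covariates whose exact
    # distributional shape is immaterial downstream
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def generate_cohort(config: SimulationConfig) -> list[Subject]:
    """Draw a full cohort of subjects from the configured group structure.

    Family-history-positive counts per diagnosis equal
    ``round(fh_fraction * n)`` exactly; the three FH indicators are nested
    (same disorder => major psychiatric => any psychiatric).  Unknown family
    histories (a configurable fraction of FH-negative patients) have all
    three indicators set to ``None``.  Deterministic under a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects: list[Subject] = []
    for dx in [d for d in DIAGNOSES if d in config.group_sizes]:
        n = int(config.group_sizes[dx])
        if n == 0:
            continue
        demo = _DEMOGRAPHICS[dx]

        n_pos = _round_half_up(config.fh_fraction.get(dx, 0.0) * n)
        order = rng.permutation(n)
        fh_any = np.zeros(n, dtype=object)
        fh_any[order[:n_pos]] = True
        fh_any[order[n_pos:]] = False
        # unknown histories only arise for patients; HC are screened negative
        n_unk = (0 if dx == "HC" else
                 _round_half_up(config.fh_unknown_rate * (n - n_pos)))
        if n_unk:
            fh_any[order[n_pos:n_pos + n_unk]] = None

        fh_major = np.array([
            bool(rng.random() < config.fh_major_given_any) if a is True else a
            for a in fh_any], dtype=object)
        fh_same = np.array([
            bool(rng.random() < config.fh_same_given_major) if m is True else m
            for m in fh_major], dtype=object)

        n_male = _round_half_up(demo["male"] * n)
        genders = np.array(["male"] * n_male + ["female"] * (n - n_male))
        rng.shuffle(genders)

        ages = _trunc_normal(rng, *demo["age"], 18.0, 75.0, size=n)
        edus = _trunc_normal(rng, *demo["edu"], 9.0, 21.0, size=n)
        iqs = _trunc_normal(rng, *demo["iq"], 70.0, 135.0, size=n)
        perfs = np.round(_trunc_normal(rng, *demo["perf"], 0.0, 40.0, size=n))
        hand_p = np.asarray(demo["hand"], dtype=float)
        hands = rng.choice(_HANDEDNESS, size=n, p=hand_p / hand_p.sum())

        for i in range(n):
            kw: dict = {}
            if dx != "HC":
                kw["cpz_eq_mg_day"] = float(
                    _trunc_normal(rng, *demo["cpz"], 0.0, 2500.0))
                onset = float(_trunc_normal(
                    rng, *demo["onset"], 12.0, max(ages[i] - 0.5, 12.5)))
                kw["onset_age_years"] = round(onset, 1)
                kw["illness_duration_years"] = round(float(ages[i]) - onset, 1)
                name, m, s = demo["scale"]
                kw["symptom_scores"] = {
                    name: round(float(_trunc_normal(rng, m, s, 0.0, 200.0)), 1)}
            subjects.append(Subject(
                id=f"{dx}{i + 1:03d}",
                diagnosis=dx,
                fh_any_psychiatric=fh_any[i],
                fh_major_psychiatric=fh_major[i],
                fh_same_disorder=fh_same[i],
                age_years=round(float(ages[i]), 1),
                gender=str(genders[i]),
                education_years=round(float(edus[i]), 1),
                premorbid_iq=round(float(iqs[i]), 1),
                handedness=str(hands[i]),
                vft_performance=int(perfs[i]),
                **kw,
            ))
    return subjects


# ---------------------------------------------------------------------------
# recording generation
# ---------------------------------------------------------------------------

def generate_recording(
    subject: Subject,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Recording:
    """Simulate one subject's 52-channel recording.

    Frontal-cluster channels share a per-subject response kernel (amplitude
    and latency drawn around the subject's diagnosis-by-FH cell means);
    non-frontal channels carry an attenuated copy.  Channels are corrupted
    independently with probability ``artifact_channel_rate`` by a large step
    discontinuity plus spikes, and flagged in ``ground_truth``.
    """
    dt = config.sampling_interval_s
    n_samples = int(round(TOTAL_S / dt))
    t = np.arange(n_samples) * dt

    label = config.group_label(subject.diagnosis, subject.fh_any_psychiatric)
    amplitude = float(rng.normal(config.amplitude_mean[label], config.amplitude_sd))
    latency = float(np.clip(
        rng.normal(config.latency_shift_s[label], config.latency_sd_s), 0.0, 40.0))

    kernel = response_kernel(
        t - PRE_TASK_S, amplitude, latency,
        rise_s=config.kernel_rise_s, decay_tau_s=config.kernel_decay_tau_s)

    frontal0 = np.asarray(FRONTAL_CHANNELS) - 1
    gain = np.full(N_CHANNELS, config.nonfrontal_gain)
    gain[frontal0] = 1.0
    channels = gain[:, None] * kernel[None, :]
    if config.noise_sd > 0:
        channels = channels + rng.normal(0.0, config.noise_sd,
                                         size=(N_CHANNELS, n_samples))

    corrupted = np.flatnonzero(rng.random(N_CHANNELS) < config.artifact_channel_rate)
    step_scale = 10.0 * config.noise_sd
    spike_scale = 20.0 * config.noise_sd
    for ch in corrupted:
        pos = rng.integers(n_samples // 8, 7 * n_samples // 8)
        sign = rng.choice((-1.0, 1.0))
        channels[ch, pos:] += sign * step_scale * rng.uniform(1.0, 1.5)
        for _ in range(3):
            channels[ch, rng.integers(0, n_samples)] += (
                rng.choice((-1.0, 1.0)) * spike_scale)

    return Recording(
        subject_id=subject.id,
        sampling_interval_s=dt,
        channels=channels,
        task_onset_s=PRE_TASK_S,
        task_offset_s=PRE_TASK_S + TASK_S,
        end_s=TOTAL_S,
        ground_truth={
            "amplitude": amplitude,
            "latency_s": latency,
            "group_label": label,
            "corrupted_channels": [int(c) + 1 for c in corrupted],  # 1-based
        },
    )


def generate_study(config: SimulationConfig):
    """Cohort plus one recording per subject, from a single seed."""
    cohort = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    recordings = [generate_recording(s, config, rng) for s in cohort]
    return cohort, recordings


# ---------------------------------------------------------------------------
# closed-form oracles for calibration tests
# ---------------------------------------------------------------------------

def analytic_integral_sd(
    config: SimulationConfig,
    label: str,
    n_channels: int = len(FRONTAL_CHANNELS),
) -> float:
    """SD of the extracted frontal integral under pre-task-only baseline.

    Three independent contributions: between-subject amplitude variation
    scaled by the kernel's task-window area; trapezoid-weighted sensor noise
    averaged over the cluster; and the pre-task baseline mean (estimated from
    ``n_pre`` noisy samples) propagated through the 60 s task window.
    """
    dt = config.sampling_interval_s
    n_task = int(round(TASK_S / dt)) + 1          # samples in [onset, offset]
    n_pre = int(round(PRE_TASK_S / dt))
    area = _kernel_task_area_unit(
        config.latency_shift_s[label], config.kernel_rise_s)
    var_amp = (config.amplitude_sd * area) ** 2
    var_noise = config.noise_sd ** 2 / n_channels * dt ** 2 * (n_task - 1.5)
    var_base = config.noise_sd ** 2 / (n_channels * n_pre) * TASK_S ** 2
    if config.latency_sd_s > 0:
        # d(area)/d(latency) = -1 on the plateau regime
        var_amp += (config.amplitude_mean[label] * config.latency_sd_s) ** 2
    return math.sqrt(var_amp + var_noise + var_base)


def analytic_cohens_d(config: SimulationConfig, label_a: str, label_b: str) -> float:
    """Expected standardized integral difference between two generator cells."""
    mu_a = config.amplitude_mean[label_a] * _kernel_task_area_unit(
        config.latency_shift_s[label_a], config.kernel_rise_s)
    mu_b = config.amplitude_mean[label_b] * _kernel_task_area_unit(
        config.latency_shift_s[label_b], config.kernel_rise_s)
    sd_a = analytic_integral_sd(config, label_a)
    sd_b = analytic_integral_sd(config, label_b)
    pooled = math.sqrt((sd_a ** 2 + sd_b ** 2) / 2.0)
    return (mu_a - mu_b) / pooled
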