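"""Synthetic FAIMS and eNose cohorts with planted class structure.

The generator emulates the statistical structure the downstream analysis
assumes: class-dependent analyte peak (FAIMS) or response-amplitude (eNose)
signal, an exponential decay of that signal with sample storage age, and
i.i.d. additive Gaussian measurement noise. Randomness is split into
per-sample child streams so that a sample's draws depend only on its index —
with effect_size=1 a case and a control at the same index are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from vocdx.faims import FaimsSample, N_CV_STEPS, N_DF_STEPS
from vocdx.enose import EnoseSample, N_SENSORS, N_TIMEPOINTS

DAYS_4_YEARS = 4 * 365.0

_LOCI_STREAM = 0x5F41494D  # domain separator for marker-locus draws
_SAMPLE_STREAM = 0x53414D50


@dataclass
class SyntheticConfig:
    """Cohort-generation parameters. Defaults mirror the study cohort:
    73 cases / 67 controls, ages uniform on 0-4 years."""

    n_case: int = 73
    n_control: int = 67
    seed: int = 0
    n_marker_peaks: int = 4
    effect_size: float = 2.0
    noise_sd: float = 0.05
    age_decay_rate: float = 0.0  # lambda, per day
    age_distribution: list[float] | None = None  # explicit ages; None = U[0, 4y]
    n_marker_sensors: int = 5
    # instrument-model knobs
    rip_amplitude: float = 10.0
    marker_amplitude: float = 1.0
    enose_base_amplitude: float = 5.0

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.age_decay_rate < 0:
            raise ValueError("age_decay_rate must be non-negative")
        if self.n_marker_peaks < 0 or self.n_marker_sensors > N_SENSORS:
            raise ValueError("invalid marker counts")
        if self.age_distribution is not None:
            ages = [float(a) for a in self.age_distribution]
            if any(a < 0 for a in ages):
                raise ValueError("ages must be non-negative")
            self.age_distribution = ages

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control

    def to_dict(self) -> dict:
        return asdict(self)


def marker_amplitude(config: SyntheticConfig, age_days: float, is_case: bool) -> float:
    """Planted marker amplitude: base x effect_size (cases) x exp(-lambda*age)."""
    amp = config.marker_amplitude * np.exp(-config.age_decay_rate * age_days)
    if is_case:
        amp *= config.effect_size
    return float(amp)


def _sample_meta(config: SyntheticConfig, index: int) -> tuple[str, str, float, np.random.Generator]:
    """Per-sample id, label, age and child RNG; draws depend on index only."""
    rng = np.random.default_rng([config.seed, _SAMPLE_STREAM, index])
    if config.age_distribution is not None:
        age = config.age_distribution[index % len(config.age_distribution)]
        rng.uniform()  # keep the draw sequence aligned with the sampled-age path
    else:
        age = float(rng.uniform(0.0, DAYS_4_YEARS))
    label = "case" if index < config.n_case else "control"
    return f"sample_{index:03d}", label, age, rng


def _faims_marker_loci(config: SyntheticConfig) -> list[dict]:
    """Fixed (CV, DF, polarity) marker peak loci, deterministic per config."""
    rng = np.random.default_rng([config.seed, _LOCI_STREAM])
    loci = []
    for _ in range(config.n_marker_peaks):
        loci.append(
            {
                "cv": float(rng.uniform(60, 450)),
                "df": float(rng.uniform(8, 46)),
                "polarity": int(rng.integers(0, 2)),
                "sigma_cv": float(rng.uniform(4.0, 8.0)),
                "sigma_df": float(rng.uniform(2.0, 4.0)),
            }
        )
    return loci


def _faims_background(config: SyntheticConfig) -> np.ndarray:
    """Reactive-ion peak: Gaussian ridge in CV drifting linearly with DF."""
    cv = np.arange(N_CV_STEPS, dtype=float)[:, None]
    df = np.arange(N_DF_STEPS, dtype=float)[None, :]
    blocks = []
    for pol, (c0, drift) in enumerate(((170.0, 1.6), (210.0, 1.1))):
        center = c0 + drift * df
        blocks.append(config.rip_amplitude * np.exp(-((cv - center) ** 2) / (2 * 7.0**2)))
    return np.concatenate(blocks, axis=1)


def generate_faims_cohort(config: SyntheticConfig) -> list[FaimsSample]:
    """Synthetic FAIMS cohort: n_case cases then n_control controls.

    Each 512x102 matrix holds the drifting reactive-ion ridge in both
    polarity blocks, the planted marker peaks (class- and age-modulated
    amplitude), and additive Gaussian noise.
    """
    background = _faims_background(config)
    loci = _faims_marker_loci(config)
    cv = np.arange(N_CV_STEPS, dtype=float)[:, None]
    df = np.arange(N_DF_STEPS, dtype=float)[None, :]
    peak_shapes = []
    for locus in loci:
        shape = np.exp(
            -((cv - locus["cv"]) ** 2) / (2 * locus["sigma_cv"] ** 2)
            - ((df - locus["df"]) ** 2) / (2 * locus["sigma_df"] ** 2)
        )
        block = np.zeros((N_CV_STEPS, 2 * N_DF_STEPS))
        col0 = locus["polarity"] * N_DF_STEPS
        block[:, col0 : col0 + N_DF_STEPS] = shape
        peak_shapes.append(block)

    cohort = []
    for index in range(config.n_total):
        sample_id, label, age, rng = _sample_meta(config, index)
        amp = marker_amplitude(config, age, label == "case")
        matrix = background.copy()
        for shape in peak_shapes:
            matrix += amp * shape
        if config.noise_sd > 0:
            matrix += rng.normal(0.0, config.noise_sd, matrix.shape)
        else:
            rng.normal(0.0, 1.0, matrix.shape)  # keep stream position fixed
        cohort.append(
            FaimsSample(sample_id=sample_id, matrix=matrix, label=label, age_days=age)
        )
    return cohort


# deterministic per-sensor kinetics: amplitude, time constant, baseline
_ENOSE_REL_AMP = 0.6 + 0.8 * np.arange(N_SENSORS) / (N_SENSORS - 1)
_ENOSE_TAU = 8.0 + 2.0 * np.arange(N_SENSORS)
_ENOSE_R0 = 50.0 * (1.0 + np.arange(N_SENSORS))


def generate_enose_cohort(config: SyntheticConfig) -> list[EnoseSample]:
    """Synthetic eNose cohort: first-order exposure kinetics per sensor.

    R_i(t) = R0_i - A_i (1 - exp(-t/tau_i)) with A_i scaled by effect_size for
    cases on the first n_marker_sensors sensors and by exp(-lambda*age) on all
    sensors, plus additive Gaussian noise.
    """
    t = np.arange(N_TIMEPOINTS, dtype=float)[None, :]
    kinetics = 1.0 - np.exp(-t / _ENOSE_TAU[:, None])  # 18 x 180
    base_amp = config.enose_base_amplitude * _ENOSE_REL_AMP
    marker_mask = np.arange(N_SENSORS) < config.n_marker_sensors

    cohort = []
    for index in range(config.n_total):
        sample_id, label, age, rng = _sample_meta(config, index)
        amp = base_amp * np.exp(-config.age_decay_rate * age)
        if label == "case":
            amp = np.where(marker_mask, amp * config.effect_size, amp)
        traces = _ENOSE_R0[:, None] - amp[:, None] * kinetics
        noise = rng.normal(0.0, 1.0, traces.shape)
        if config.noise_sd > 0:
            traces = traces + config.noise_sd * noise
        cohort.append(
            EnoseSample(
                sample_id=sample_id,
                traces=traces,
                baselines=_ENOSE_R0.copy(),
                label=label,
                age_days=age,
            )
        )
    return cohort
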