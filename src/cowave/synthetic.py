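"""Synthetic dual-channel (PPG + arterial pressure) waveform generator.

The simulator produces 500 Hz two-channel records with a cardiac component
near 1 Hz and a respiratory component near 0.25 Hz, arterial pressure between
physiological systolic/diastolic levels in mmHg, PPG in arbitrary units in
the 20-80 band, and reference cardiac-output readings every 2 s.

Ground-truth law
----------------
Every record obeys a known waveform -> CO relationship,

    CO [L/min] = HR [beats/min] * SV [mL] / 1000,   SV = a + b * PP,

with PP the configured arterial pulse pressure (systolic - diastolic) and
(a, b) config constants. Because downstream model inputs are min-max
normalized per segment (which erases absolute amplitude), stroke volume is
additionally encoded in the ART beat *shape*: the systolic time-to-peak and
the diastolic relaxation fraction both grow affinely with SV. The PPG beat
shape is SV-independent, so a PPG-only model can recover heart rate but not
stroke volume — the two channels carry complementary information.

Artifact injection produces segments that violate exactly one screening rule
each, for targeted testing of the quality-control stage.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
from scipy import stats

from cowave.errors import ValidationError

#: physiologic cardiac-output range used for label truncation, L/min
CO_MIN = 2.0
CO_MAX = 10.0

ARTIFACT_KINDS = (
    "spike_ppg",
    "spike_art",
    "flatline_ppg",
    "low_pulse_pressure_art",
    "out_of_range_art",
    "out_of_range_ppg",
    "out_of_range_co",
    "missing_values",
)


@dataclass(frozen=True)
class SimConfig:
    """Per-case simulation parameters.

    With the defaults, generated ART samples lie well inside [30, 200] mmHg
    and PPG samples inside [10, 100] a.u., so clean output passes every
    screening rule.
    """

    sampling_rate: float = 500.0  # Hz
    duration: float = 60.0  # s
    heart_rate: float = 75.0  # beats/min
    respiratory_rate: float = 15.0  # cycles/min (~0.25 Hz)
    systolic_mmHg: float = 120.0
    diastolic_mmHg: float = 70.0
    ppg_baseline: float = 25.0  # a.u.
    ppg_amplitude: float = 50.0  # a.u.
    noise_sd: float = 0.5  # additive white noise per channel
    co_interval: float = 2.0  # s between CO readings
    co_noise_sd: float = 0.1  # L/min measurement noise on CO readings
    sv_intercept_ml: float = -10.0  # a in SV = a + b*PP
    sv_slope_ml_per_mmHg: float = 1.6  # b in SV = a + b*PP
    resp_ppg_amplitude: float = 3.0  # a.u., additive respiratory swing
    resp_art_amplitude: float = 2.0  # mmHg, additive respiratory swing
    seed: int = 0

    def validate(self) -> None:
        for name in ("sampling_rate", "duration", "co_interval"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if not self.diastolic_mmHg < self.systolic_mmHg:
            raise ValidationError(
                f"diastolic_mmHg ({self.diastolic_mmHg}) must be below "
                f"systolic_mmHg ({self.systolic_mmHg})"
            )
        for name in ("heart_rate", "respiratory_rate", "ppg_amplitude"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.noise_sd < 0 or self.co_noise_sd < 0:
            raise ValidationError("noise_sd and co_noise_sd must be non-negative")

    @property
    def pulse_pressure(self) -> float:
        return self.systolic_mmHg - self.diastolic_mmHg

    @property
    def stroke_volume_ml(self) -> float:
        return self.sv_intercept_ml + self.sv_slope_ml_per_mmHg * self.pulse_pressure

    @property
    def true_co(self) -> float:
        """CO implied by the ground-truth law, L/min."""
        return self.heart_rate * self.stroke_volume_ml / 1000.0


@dataclass
class WaveformRecord:
    """One case: aligned PPG and ART channels plus CO readings.

    CO readings summarize consecutive ``co_interval`` windows; each reading is
    aligned to the sample at the *center* of its window, so a 60 s record at
    the default 2 s interval carries 30 readings, all with in-range indices
    and exact spacing of ``co_interval * sampling_rate`` samples.
    """

    case_id: str
    sampling_rate: float
    ppg: np.ndarray  # a.u.
    art: np.ndarray  # mmHg
    co_values: np.ndarray  # L/min
    co_sample_indices: np.ndarray  # sample index per reading
    true_co: Optional[np.ndarray] = None  # noise-free ground truth (simulation only)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.art = np.asarray(self.art, dtype=float)
        self.co_values = np.asarray(self.co_values, dtype=float)
        self.co_sample_indices = np.asarray(self.co_sample_indices, dtype=np.int64)
        if self.ppg.shape != self.art.shape:
            raise ValidationError(
                f"ppg and art must have equal length, got {self.ppg.size} and {self.art.size}"
            )
        if self.co_values.size != self.co_sample_indices.size:
            raise ValidationError("co_values and co_sample_indices must have equal length")
        if self.co_sample_indices.size:
            if np.any(np.diff(self.co_sample_indices) <= 0):
                raise ValidationError("co_sample_indices must be strictly increasing")
            if self.co_sample_indices[0] < 0 or self.co_sample_indices[-1] >= self.ppg.size:
                raise ValidationError("co_sample_indices must lie within [0, len(ppg))")

    @property
    def n_samples(self) -> int:
        return int(self.ppg.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "WaveformRecord":
        return copy.deepcopy(self)


def _ppg_beat_template(phase: np.ndarray) -> np.ndarray:
    """Two-Gaussian PPG pulse (systolic peak + dicrotic bump), range [0, 1].

    Shape is deliberately independent of stroke volume: PPG amplitude carries
    no physiological meaning, so the channel encodes timing (heart rate) only.
    """
    w = np.exp(-0.5 * ((phase - 0.28) / 0.10) ** 2) + 0.35 * np.exp(
        -0.5 * ((phase - 0.62) / 0.12) ** 2
    )
    # normalize with the template's own extrema (constants for fixed shape)
    grid = np.linspace(0.0, 1.0, 2001)
    wg = np.exp(-0.5 * ((grid - 0.28) / 0.10) ** 2) + 0.35 * np.exp(
        -0.5 * ((grid - 0.62) / 0.12) ** 2
    )
    lo, hi = wg.min(), wg.max()
    return (w - lo) / (hi - lo)


def _art_beat_template(phase: np.ndarray, stroke_volume_ml: float) -> np.ndarray:
    """Asymmetric arterial pulse: raised-cosine upstroke, exponential decay.

    Stroke volume shifts the systolic time-to-peak and the relaxation time
    constant (both as fractions of the cycle), so beat morphology encodes SV
    even after per-segment amplitude normalization. Output in [~0, 1];
    1 maps to systolic and 0 to diastolic pressure.
    """
    tp = np.clip(0.12 + 0.0012 * stroke_volume_ml, 0.13, 0.30)  # time-to-peak fraction
    tau = np.clip(0.15 + 0.0025 * stroke_volume_ml, 0.18, 0.55)  # decay fraction
    end_level = np.exp(-(1.0 - tp) / tau)  # value the decay reaches at end of cycle
    w = np.empty_like(phase)
    rising = phase < tp
    # upstroke starts where the previous beat's decay left off -> continuous
    w[rising] = end_level + (1.0 - end_level) * 0.5 * (1.0 - np.cos(np.pi * phase[rising] / tp))
    w[~rising] = np.exp(-(phase[~rising] - tp) / tau)
    return w


def generate_case(config: SimConfig) -> WaveformRecord:
    """Simulate one case under *config*; same config + seed is bit-identical.

    Returns ``duration * sampling_rate`` samples per channel and one CO
    reading per ``co_interval``, with ``true_co`` given exactly by the
    ground-truth law CO = HR * SV / 1000.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    f_card = config.heart_rate / 60.0
    f_resp = config.respiratory_rate / 60.0
    phase = np.mod(t * f_card, 1.0)

    sv = config.stroke_volume_ml
    pp = config.pulse_pressure

    art = (
        config.diastolic_mmHg
        + pp * _art_beat_template(phase, sv)
        + config.resp_art_amplitude * np.sin(2 * np.pi * f_resp * t)
        + rng.normal(0.0, config.noise_sd, n)
    )
    ppg = (
        config.ppg_baseline
        + config.ppg_amplitude * _ppg_beat_template(phase)
        + config.resp_ppg_amplitude * np.sin(2 * np.pi * f_resp * t)
        + rng.normal(0.0, config.noise_sd, n)
    )

    spacing = int(round(config.co_interval * fs))
    n_readings = int(config.duration // config.co_interval)
    # each reading sits at the center of its co_interval averaging window
    indices = (np.arange(n_readings) + 0.5) * spacing
    indices = np.round(indices).astype(np.int64)
    true_co = np.full(n_readings, config.true_co)
    co_values = np.clip(
        true_co + rng.normal(0.0, config.co_noise_sd, n_readings), CO_MIN, CO_MAX
    )

    return WaveformRecord(
        case_id=f"sim-{config.seed:06d}",
        sampling_rate=fs,
        ppg=ppg,
        art=art,
        co_values=co_values,
        co_sample_indices=indices,
        true_co=true_co,
        meta={"config": config},
    )


# population priors for multi-case datasets: CO ~ TruncNormal(5.01, 1.60) on
# [2, 10] L/min, the reference distribution the pipeline is tested against
CO_POPULATION_MEAN = 5.01
CO_POPULATION_SD = 1.60


def population_co_mean() -> float:
    """Mean of the truncated-normal CO prior (analytic, for test oracles)."""
    a = (CO_MIN - CO_POPULATION_MEAN) / CO_POPULATION_SD
    b = (CO_MAX - CO_POPULATION_MEAN) / CO_POPULATION_SD
    return float(stats.truncnorm.mean(a, b, loc=CO_POPULATION_MEAN, scale=CO_POPULATION_SD))


def _draw_case_config(base: SimConfig, co_target: float, rng: np.random.Generator, seed: int) -> SimConfig:
    """Draw case-level physiology consistent with a target CO.

    Pulse pressure is drawn around an affine function of CO (keeping heart
    rate in a plausible band), diastolic pressure independently; heart rate is
    then solved from the ground-truth law so the realized CO equals the target
    up to the physiologic clamps.
    """
    pp = float(np.clip(rng.normal(28.0 + 4.5 * co_target, 5.0), 32.0, 90.0))
    dia = float(np.clip(rng.normal(68.0, 7.0), 50.0, 95.0))
    sv = base.sv_intercept_ml + base.sv_slope_ml_per_mmHg * pp
    hr = float(np.clip(1000.0 * co_target / sv, 38.0, 135.0))
    co = hr * sv / 1000.0
    if not (CO_MIN <= co <= CO_MAX):
        hr = 1000.0 * float(np.clip(co, CO_MIN, CO_MAX)) / sv
    ppg_base = float(np.clip(rng.normal(25.0, 2.0), 20.0, 30.0))
    ppg_amp = float(np.clip(rng.normal(50.0, 4.0), 40.0, 58.0))
    return replace(
        base,
        heart_rate=hr,
        systolic_mmHg=dia + pp,
        diastolic_mmHg=dia,
        ppg_baseline=ppg_base,
        ppg_amplitude=ppg_amp,
        seed=seed,
    )


def generate_dataset(config: SimConfig, n_cases: int, seed: int) -> List[WaveformRecord]:
    """Simulate *n_cases* records with case-specific physiology.

    Case-level CO is drawn from the truncated-normal population prior
    (mean 5.01, SD 1.60, truncated to [2, 10] L/min); heart rate, pulse
    pressure and diastolic pressure follow from it as described in
    :func:`_draw_case_config`. Reproducible under *seed*.
    """
    if n_cases < 1:
        raise ValidationError(f"n_cases must be >= 1, got {n_cases}")
    config.validate()
    rng = np.random.default_rng(seed)
    a = (CO_MIN - CO_POPULATION_MEAN) / CO_POPULATION_SD
    b = (CO_MAX - CO_POPULATION_MEAN) / CO_POPULATION_SD
    co_targets = stats.truncnorm.rvs(
        a, b, loc=CO_POPULATION_MEAN, scale=CO_POPULATION_SD, size=n_cases, random_state=rng
    )
    case_seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    records = []
    for i in range(n_cases):
        cfg = _draw_case_config(config, float(co_targets[i]), rng, int(case_seeds[i]))
        rec = generate_case(cfg)
        rec.case_id = f"case-{i:04d}"
        records.append(rec)
    return records


def _covering_window(record: WaveformRecord, at: int, window: int) -> tuple[int, int, int]:
    """(reading index, window start, window stop) for the segment covering *at*."""
    centers = record.co_sample_indices
    k = int(np.argmin(np.abs(centers - at)))
    half = window // 2
    start, stop = int(centers[k] - half), int(centers[k] + half)
    if start < 0 or stop > record.n_samples:
        raise ValidationError(
            f"sample {at} is covered by reading {k} whose {window}-sample window "
            f"[{start}, {stop}) exceeds the record bounds"
        )
    return k, start, stop


def _smooth_bump(length: int, center: int, sigma: float) -> np.ndarray:
    i = np.arange(length)
    return np.exp(-0.5 * ((i - center) / sigma) ** 2)


def inject_artifact(
    record: WaveformRecord,
    kind: str,
    at: int,
    seed: int = 0,
    window: int = 2048,
) -> WaveformRecord:
    """Return a copy whose segment covering *at* violates exactly one rule.

    Each artifact kind targets one screening rule and is shaped so that no
    other rule trips on the affected segment (e.g. out-of-range excursions are
    smooth enough not to violate the slew bound, spikes stay inside the
    amplitude band). ``missing_values`` inserts NaN samples, emulating empty
    cells in an exported record.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValidationError(f"unknown artifact kind {kind!r}; expected one of {ARTIFACT_KINDS}")
    if not (0 <= at < record.n_samples):
        raise ValidationError(f"at={at} outside record bounds [0, {record.n_samples})")
    out = record.copy()
    k, start, stop = _covering_window(record, at, window)
    # keep point artifacts away from the window edges so both adjacent-sample
    # differences they create are evaluated inside this window
    at = int(np.clip(at, start + 2, stop - 3))
    win = slice(start, stop)
    sigma = max(6.0, window / 80.0)

    if kind == "spike_ppg":
        # one-sample jump > 20 a.u. either direction, staying inside [10, 100]
        out.ppg[at] += 25.0 if out.ppg[at] < 55.0 else -25.0
    elif kind == "spike_art":
        out.art[at] += 35.0 if out.art[at] < 100.0 else -35.0
    elif kind == "flatline_ppg":
        out.ppg[win] = float(np.mean(out.ppg[win]))
    elif kind == "low_pulse_pressure_art":
        seg = out.art[win]
        m = float(np.mean(seg))
        rng_now = float(np.ptp(seg))
        out.art[win] = m + (seg - m) * (20.0 / rng_now)  # compress to 20 mmHg span
    elif kind == "out_of_range_art":
        amp = 205.0 - float(out.art[at])  # bump peak reaches 205 mmHg at `at`
        out.art[win] = out.art[win] + amp * _smooth_bump(stop - start, at - start, sigma)
    elif kind == "out_of_range_ppg":
        amp = 105.0 - float(out.ppg[at])
        out.ppg[win] = out.ppg[win] + amp * _smooth_bump(stop - start, at - start, sigma)
    elif kind == "out_of_range_co":
        out.co_values[k] = 1.5  # below the 2 L/min physiologic floor
    elif kind == "missing_values":
        width = max(3, window // 256)
        out.ppg[at : at + width] = np.nan
    out.meta["artifact"] = {"kind": kind, "at": at, "reading": k}
    return out
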