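"""Synthetic 12-lead ECG cohorts with ground-truth fiducials.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed at
RR-driven beat times; every lead is the same unit waveform scaled by a
fixed per-lead gain (lead II carries the largest R amplitude, aVR is
inverted), plus an optional 0.25 Hz sinusoidal baseline wander and white
Gaussian noise.  RR intervals are log-normal around 60/HR with a stated
coefficient of variation, so intervals are strictly positive.  Wave
centers are snapped to the sample grid, which makes every true peak a
strict local extremum of the noiseless signal and gives exact ground
truth for delineation tests.

This generator is a test instrument: it makes no claim of physiological
fidelity (no AF f-waves, no realistic repolarization), only enough
structure — beat timing, P-wave morphology, wander, noise — to exercise
the coarse graining, complexity and classification stages end to end.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .signal_prep import SUPPORTED_FS, WAVES, FiducialSet

LEAD_NAMES = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

# fixed per-lead scaling of the unit beat waveform (mV multiplier);
# lead II largest, aVR inverted — chosen once, purely conventional
LEAD_GAINS = np.array(
    [0.7, 1.1, 0.5, -0.6, 0.4, 0.8, 0.5, 0.9, 1.0, 1.0, 0.9, 0.8]
)

__all__ = [
    "Wave",
    "BeatTemplate",
    "EcgRecord",
    "PatientMeta",
    "CaseEffect",
    "DEFAULT_TEMPLATE",
    "LEAD_NAMES",
    "LEAD_GAINS",
    "generate_record",
    "generate_cohort",
    "metadata_frame",
    "write_metadata_csv",
]


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: amplitude (mV), center offset from R (s), width (s)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology and rhythm parameters for one synthetic patient."""

    p: Wave = Wave(0.15, -0.20, 0.040)
    q: Wave = Wave(-0.10, -0.04, 0.015)
    r: Wave = Wave(1.00, 0.00, 0.020)
    s: Wave = Wave(-0.15, 0.04, 0.015)
    t: Wave = Wave(0.30, 0.25, 0.070)
    heart_rate: float = 60.0  # beats/min
    rr_cv: float = 0.05  # coefficient of variation of RR intervals

    def __post_init__(self):
        centers = [getattr(self, w).center for w in WAVES]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be ordered P < Q < R < S < T")
        if not 30.0 < self.heart_rate < 200.0:
            raise ValueError("heart rate must lie in (30, 200) beats/min")
        if self.rr_cv < 0:
            raise ValueError("RR coefficient of variation must be >= 0")

    @property
    def waves(self) -> dict:
        return {w: getattr(self, w) for w in WAVES}


DEFAULT_TEMPLATE = BeatTemplate()


@dataclass
class EcgRecord:
    """One 10-s multi-lead record with optional ground-truth fiducials."""

    record_id: str
    patient_id: str
    signal: np.ndarray  # (12, n) in mV
    fs: int
    rhythm: str  # "SR" or "AFIB"
    acquisition_index: int
    fiducials: dict | None = None  # lead name -> FiducialSet (synthetic only)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(LEAD_NAMES):
            raise ValueError("signal must have 12 lead rows")
        if self.fs not in SUPPORTED_FS:
            raise ValueError(f"fs must be one of {SUPPORTED_FS}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.signal[LEAD_NAMES.index(name)]


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    age: float
    sex: str  # "M" or "F"
    comorbidities: frozenset = frozenset()

    def __post_init__(self):
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")


# ---------------------------------------------------------------------------
# record synthesis


def _rr_series(rng, heart_rate: float, rr_cv: float, n: int) -> np.ndarray:
    mean = 60.0 / heart_rate
    if rr_cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(rr_cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def generate_record(
    template: BeatTemplate = DEFAULT_TEMPLATE,
    fs: int = 500,
    duration: float = 10.0,
    noise_sd: float = 0.0,
    wander_amplitude: float = 0.0,
    seed: int = 0,
    record_id: str = "rec0",
    patient_id: str = "pat0",
    rhythm: str = "SR",
    acquisition_index: int = 0,
) -> EcgRecord:
    """Synthesize one 12-lead record; identical seed gives identical output."""
    if fs not in SUPPORTED_FS:
        raise ValueError(f"fs must be one of {SUPPORTED_FS}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    mean_rr = 60.0 / template.heart_rate
    # generous beat budget, then trim to the record window
    n_beats_max = int(duration / mean_rr * 2) + 4
    rr = _rr_series(rng, template.heart_rate, template.rr_cv, n_beats_max)
    beat_times = 0.5 * mean_rr + np.concatenate([[0.0], np.cumsum(rr)])
    beat_times = beat_times[beat_times < duration]

    unit = np.zeros(n)
    wave_idx: dict[str, list] = {w: [] for w in WAVES}
    for tb in beat_times:
        for wname, wave in template.waves.items():
            idx = int(round((tb + wave.center) * fs))
            if not 0 <= idx < n:
                wave_idx[wname].append(None)
                continue
            center = idx / fs  # snap to the sample grid: exact ground truth
            unit += wave.amplitude * np.exp(-((t - center) ** 2) / (2 * wave.width**2))
            wave_idx[wname].append(idx)
    # beats whose R fell outside the window carry no fiducials at all
    keep = [i for i, r in enumerate(wave_idx["r"]) if r is not None]
    fid = FiducialSet(
        fs=fs, **{w: tuple(wave_idx[w][i] for i in keep) for w in WAVES}
    )

    signal = LEAD_GAINS[:, None] * unit[None, :]
    if wander_amplitude:
        phase = rng.uniform(0, 2 * np.pi)
        signal = signal + wander_amplitude * np.sin(2 * np.pi * 0.25 * t + phase)
    if noise_sd:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    fiducials = {name: fid for name in LEAD_NAMES}
    return EcgRecord(
        record_id=record_id,
        patient_id=patient_id,
        signal=signal,
        fs=fs,
        rhythm=rhythm,
        acquisition_index=acquisition_index,
        fiducials=fiducials,
    )


# ---------------------------------------------------------------------------
# cohort synthesis


@dataclass(frozen=True)
class CaseEffect:
    """Declarative perturbation applied to a case patient's SR template.

    The identity effect (all defaults) produces case SR records that are
    statistically exchangeable with controls.  Each field perturbs exactly
    one template property, so tests can inject one difference at a time.
    """

    rr_cv_scale: float = 1.0
    p_amplitude_scale: float = 1.0
    p_width_scale: float = 1.0
    heart_rate_shift: float = 0.0

    def apply(self, template: BeatTemplate) -> BeatTemplate:
        p = replace(
            template.p,
            amplitude=template.p.amplitude * self.p_amplitude_scale,
            width=template.p.width * self.p_width_scale,
        )
        return replace(
            template,
            p=p,
            rr_cv=template.rr_cv * self.rr_cv_scale,
            heart_rate=template.heart_rate + self.heart_rate_shift,
        )


def _patient_template(rng) -> BeatTemplate:
    hr = float(rng.uniform(55, 80))
    return replace(
        DEFAULT_TEMPLATE,
        heart_rate=hr,
        r=replace(DEFAULT_TEMPLATE.r, amplitude=float(rng.uniform(0.85, 1.15))),
        p=replace(DEFAULT_TEMPLATE.p, amplitude=float(rng.uniform(0.12, 0.18))),
        rr_cv=0.05,
    )


def _af_template(template: BeatTemplate) -> BeatTemplate:
    # irregular RR, absent organized P wave — enough to label the record
    return replace(
        template,
        p=replace(template.p, amplitude=0.0),
        rr_cv=max(0.25, 3 * template.rr_cv),
    )


def _clamp_same_decade(age: int, jitter: int) -> int:
    lo = 10 * (age // 10)
    return int(np.clip(age + jitter, lo, lo + 9))


def generate_cohort(
    n_cases: int,
    n_controls: int,
    case_effect: CaseEffect = CaseEffect(),
    seed: int = 0,
    fs: int = 500,
    duration: float = 10.0,
    noise_sd: float = 0.01,
    wander_amplitude: float = 0.05,
    n_sr_records: int = 1,
    mirror_demographics: bool = True,
):
    """Generate case and control patients with PTB-XL-like bookkeeping.

    Every case patient receives one AFIB record followed (by acquisition
    index) by ``n_sr_records`` SR records drawn from the case-effect-
    perturbed template; controls receive SR records only, with empty
    comorbidity flags.  With ``mirror_demographics`` each control reuses
    the sex and age decade of a case so age/sex matching is feasible;
    disable it to produce potentially unmatchable configurations.

    Returns ``(records, metas)``.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("n_cases and n_controls must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[EcgRecord] = []
    metas: list[PatientMeta] = []

    def _draw_age():
        return int(np.clip(round(rng.normal(68, 9)), 30, 95))

    case_demo = []
    for i in range(n_cases):
        pid = f"case{i:04d}"
        age, sex = _draw_age(), ("M" if rng.random() < 0.6 else "F")
        case_demo.append((age, sex))
        metas.append(PatientMeta(pid, age, sex))
        base = _patient_template(rng)
        records.append(
            generate_record(
                _af_template(base), fs, duration, noise_sd, wander_amplitude,
                seed=int(rng.integers(2**31)),
                record_id=f"{pid}_r0", patient_id=pid,
                rhythm="AFIB", acquisition_index=0,
            )
        )
        sr_template = case_effect.apply(base)
        for j in range(n_sr_records):
            records.append(
                generate_record(
                    sr_template, fs, duration, noise_sd, wander_amplitude,
                    seed=int(rng.integers(2**31)),
                    record_id=f"{pid}_r{j + 1}", patient_id=pid,
                    rhythm="SR", acquisition_index=j + 1,
                )
            )

    for i in range(n_controls):
        pid = f"ctrl{i:04d}"
        if mirror_demographics and i < n_cases:
            age0, sex = case_demo[i]
            age = _clamp_same_decade(age0, int(rng.integers(-3, 4)))
        else:
            age, sex = _draw_age(), ("M" if rng.random() < 0.6 else "F")
        metas.append(PatientMeta(pid, age, sex))
        base = _patient_template(rng)
        for j in range(n_sr_records):
            records.append(
                generate_record(
                    base, fs, duration, noise_sd, wander_amplitude,
                    seed=int(rng.integers(2**31)),
                    record_id=f"{pid}_r{j}", patient_id=pid,
                    rhythm="SR", acquisition_index=j,
                )
            )
    return records, metas


# ---------------------------------------------------------------------------
# metadata table


def metadata_frame(records, metas):
    """Tabulate records + patients in the metadata layout the pipeline reads."""
    import pandas as pd

    by_pid = {m.patient_id: m for m in metas}
    rows = []
    for rec in records:
        m = by_pid[rec.patient_id]
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age": m.age,
                "sex": m.sex,
                "record_id": rec.record_id,
                "acquisition_index": rec.acquisition_index,
                "rhythm_label": rec.rhythm,
                "comorbidity_codes": " ".join(sorted(m.comorbidities)),
            }
        )
    return pd.DataFrame(rows)


def write_metadata_csv(path, records, metas) -> Path:
    path = Path(path)
    frame = metadata_frame(records, metas)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(frame.columns.tolist())
        writer.writerows(frame.itertuples(index=False))
    return path
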