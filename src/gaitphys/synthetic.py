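"""Synthetic gait-cohort generator.

Generates cohorts with the nested structure of an instrumented gait
analysis study — subjects in clinical groups, left/right sides, 2-5
retained cycles per side, ~200 samples per cycle, and the full series
inventory (15 kinematic, 3 ground-reaction-force, 6 moment/power curves)
— with controllable dynamical properties so every downstream stage can be
exercised without clinical recordings.

Ground-truth generating model
-----------------------------
Each series of each cycle is built as::

    signal  = template(subject, series)          # band-limited harmonic sum
            + bump(group, series)                # optional localised shape effect
    cycle   = signal
            + gain(subject) * ar_noise(cycle)    # skewed AR(1) dynamical noise
            + cycle_noise_sd * white_noise       # measurement noise

* ``template`` is a sum of ``n_harmonics`` sinusoids over one fundamental
  period, evaluated on a time grid warped by the monotone map
  ``t -> t**(1 + asymmetry)``; a nonzero ``asymmetry`` makes rise and fall
  portions unequal and hence the waveform statistically time-irreversible.
* ``gain`` controls the amount of dynamical noise and therefore the
  entropy of the series.  Covariate effects enter log-linearly::

      log gain_i = log noise_gain + age_coef*(age_i - 10) + speed_coef*(speed_i - 1)

  so that mixed-model recovery targets are linear in age and normalised
  walking speed on the log-entropy scale.  The group ``asymmetry`` can be
  modulated the same way through ``asym_age_coef``/``asym_speed_coef``.
* The AR(1) innovations are mean-centred exponentials by default, giving
  the noise both memory and non-Gaussianity (the two classical sources of
  time irreversibility); Gaussian innovations with ``noise_alpha = 0``
  reduce it to white noise.

Two groups configured with identical parameters are statistically
exchangeable, which is the uninformed-classification baseline used
throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.signal import lfilter

from .data import Cohort, GaitCycle, SubjectRecord

__all__ = [
    "GroupParams",
    "SyntheticConfig",
    "DEFAULT_SERIES",
    "KINEMATIC_SERIES",
    "GRF_SERIES",
    "MP_SERIES",
    "gait_waveform",
    "irreversible_noise",
    "generate_cohort",
    "load_config",
]

_JOINTS = ("pelvis", "hip", "knee", "ankle", "foot")
_PLANES = ("sagittal", "coronal", "transversal")

KINEMATIC_SERIES: tuple[str, ...] = tuple(
    f"{j}_{p}" for j in _JOINTS for p in _PLANES
)
GRF_SERIES: tuple[str, ...] = (
    "grf_sagittal",
    "grf_anteroposterior",
    "grf_mediolateral",
)
MP_SERIES: tuple[str, ...] = (
    "hip_moment",
    "knee_moment",
    "ankle_moment",
    "hip_power",
    "knee_power",
    "ankle_power",
)
DEFAULT_SERIES: tuple[str, ...] = KINEMATIC_SERIES + GRF_SERIES + MP_SERIES

SERIES_FAMILIES: dict[str, tuple[str, ...]] = {
    "kinematics": KINEMATIC_SERIES,
    "grf": GRF_SERIES,
    "mp": MP_SERIES,
    "all": DEFAULT_SERIES,
}

#: reference covariate values at which injected effects vanish
AGE_CENTRE = 10.0
SPEED_CENTRE = 1.0


@dataclass(frozen=True)
class GroupParams:
    """Generator parameters of one clinical group.

    ``template_delta`` perturbs the shared harmonic amplitudes (one entry
    per harmonic); ``bump_*`` add a Gaussian-shaped waveform deviation
    localised in cycle time; ``series_noise_gain`` overrides the scalar
    ``noise_gain`` for the named series only.
    """

    name: str
    asymmetry: float = 0.1
    noise_gain: float = 0.15
    noise_alpha: float = 0.3
    noise_skew: bool = True
    template_delta: tuple[float, ...] | None = None
    bump_amp: float = 0.0
    bump_center_pct: float = 30.0
    bump_width_pct: float = 8.0
    bump_series: tuple[str, ...] | None = None
    series_noise_gain: Mapping[str, float] | None = None
    age_coef: float = 0.0
    speed_coef: float = 0.0
    asym_age_coef: float = 0.0
    asym_speed_coef: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.asymmetry < 1):
            raise ValueError(f"asymmetry must be in [0, 1), got {self.asymmetry}")
        if self.noise_gain < 0:
            raise ValueError("noise_gain must be non-negative")
        if not (0 <= self.noise_alpha < 1):
            raise ValueError("noise_alpha must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic cohort."""

    groups: tuple[GroupParams, ...]
    n_subjects_per_group: int = 10
    cycles_per_side: tuple[int, int] = (2, 5)
    samples_per_cycle: int = 200
    n_harmonics: int = 6
    subject_sd: float = 0.1
    side_sd: float = 0.05
    cycle_noise_sd: float = 0.02
    age_range: tuple[float, float] = (4.0, 16.0)
    speed_mean: float = 1.0
    speed_sd: float = 0.2
    series_names: tuple[str, ...] = DEFAULT_SERIES
    lab: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("group list must not be empty")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate group labels: {names}")
        lo, hi = self.cycles_per_side
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid cycles_per_side range {self.cycles_per_side}")
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be positive")
        if self.samples_per_cycle < 8:
            raise ValueError("samples_per_cycle must be >= 8")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be positive")
        if min(self.subject_sd, self.side_sd, self.cycle_noise_sd) < 0:
            raise ValueError("noise scales must be non-negative")


def gait_waveform(
    amplitudes: Sequence[float],
    phases: Sequence[float],
    asymmetry: float,
    length: int,
) -> np.ndarray:
    """One noise-free, time-warped harmonic gait cycle.

    Sum of sinusoids over one fundamental period evaluated on the warped
    grid ``u = t**(1 + asymmetry)`` (t in [0, 1)), then shifted/scaled to
    zero mean and unit standard deviation.  ``asymmetry = 0`` gives a
    statistically time-symmetric waveform family.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if amplitudes.shape != phases.shape or amplitudes.ndim != 1:
        raise ValueError("amplitudes and phases must be 1-d and equally long")
    if not (np.all(np.isfinite(amplitudes)) and np.all(np.isfinite(phases))):
        raise ValueError("non-finite waveform parameters")
    if not (0 <= asymmetry < 1):
        raise ValueError(f"asymmetry must be in [0, 1), got {asymmetry}")
    if length < 8:
        raise ValueError("length must be >= 8")
    t = np.arange(length) / length
    u = t ** (1.0 + asymmetry)
    k = np.arange(1, amplitudes.size + 1)
    y = np.sum(
        amplitudes[:, None] * np.sin(2 * np.pi * k[:, None] * u[None, :]
                                     + phases[:, None]),
        axis=0,
    )
    sd = y.std()
    if sd == 0:
        raise ValueError("degenerate waveform (zero variance)")
    return (y - y.mean()) / sd


def irreversible_noise(
    length: int,
    alpha: float,
    sigma: float,
    rng: np.random.Generator | int,
    skew: bool = True,
) -> np.ndarray:
    """AR(1) noise with optionally skewed innovations.

    ``x_t = alpha*x_{t-1} + e_t`` with ``e_t`` mean-centred unit-variance
    exponential (skewed, hence time-irreversible) or standard normal.
    The output is scaled to marginal standard deviation ``sigma``;
    ``alpha = 0`` with ``skew = False`` is white Gaussian noise.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if not (0 <= alpha < 1):
        raise ValueError("alpha must be in [0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    burn = 64
    if skew:
        e = rng.exponential(1.0, size=length + burn) - 1.0
    else:
        e = rng.standard_normal(length + burn)
    x = lfilter([1.0], [1.0, -alpha], e)[burn:]
    return sigma * np.sqrt(1.0 - alpha**2) * x


def _series_rng(seed: int, series_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(0, series_index))
    )


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1, subject_index))
    )


def _bump(group: GroupParams, series: str, length: int) -> float | np.ndarray:
    if group.bump_amp == 0.0:
        return 0.0
    if group.bump_series is not None and series not in group.bump_series:
        return 0.0
    t_pct = 100.0 * np.arange(length) / length
    z = (t_pct - group.bump_center_pct) / group.bump_width_pct
    return group.bump_amp * np.exp(-0.5 * z**2)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a fully reproducible synthetic cohort.

    Per subject: age and normalised walking speed are sampled; per side a
    number of cycles in ``cycles_per_side`` is drawn; per cycle every
    configured series is built from the group/subject template plus
    dynamical and measurement noise (see module docstring for the
    generating model).
    """
    L = config.samples_per_cycle
    H = config.n_harmonics

    # Shared per-series base templates (identical across groups: group
    # differences are explicit parameters, never resampled randomness).
    base_amp: dict[str, np.ndarray] = {}
    base_phase: dict[str, np.ndarray] = {}
    for si, series in enumerate(config.series_names):
        rng = _series_rng(config.seed, si)
        k = np.arange(1, H + 1)
        base_amp[series] = (0.5 + rng.uniform(0, 1, size=H)) / k
        base_phase[series] = rng.uniform(0, 2 * np.pi, size=H)

    cycles: list[GaitCycle] = []
    subjects: dict[str, SubjectRecord] = {}
    lo, hi = config.cycles_per_side
    subject_counter = 0
    for group in config.groups:
        delta = (
            np.zeros(H)
            if group.template_delta is None
            else np.asarray(group.template_delta, dtype=float)
        )
        if delta.size != H:
            raise ValueError(
                f"template_delta of group {group.name!r} must have "
                f"{H} entries, got {delta.size}"
            )
        for i in range(config.n_subjects_per_group):
            rng = _subject_rng(config.seed, subject_counter)
            subject_counter += 1
            sid = f"{group.name}_{i:03d}"
            if sid in subjects:
                raise ValueError(f"duplicate subject id {sid!r}")
            age = rng.uniform(*config.age_range)
            speed = max(0.3, rng.normal(config.speed_mean, config.speed_sd))
            sex = "F" if rng.random() < 0.5 else "M"
            subjects[sid] = SubjectRecord(
                subject_id=sid,
                group=group.name,
                age=age,
                normalised_walking_speed=speed,
                lab=config.lab,
                sex=sex,
            )
            log_gain_shift = group.age_coef * (age - AGE_CENTRE) + (
                group.speed_coef * (speed - SPEED_CENTRE)
            )
            asym = group.asymmetry * float(
                np.exp(
                    group.asym_age_coef * (age - AGE_CENTRE)
                    + group.asym_speed_coef * (speed - SPEED_CENTRE)
                )
            )
            asym = min(asym, 0.99)

            # per-subject waveform individuality, plus a smaller systematic
            # left/right difference (real gait is never perfectly symmetric)
            amp_off = rng.normal(0.0, config.subject_sd, size=(len(config.series_names), H))
            phase_off = rng.normal(0.0, config.subject_sd, size=(len(config.series_names), H))
            side_amp = {
                s: rng.normal(0.0, config.side_sd, size=(len(config.series_names), H))
                for s in ("left", "right")
            }
            templates = {}
            for side in ("left", "right"):
                for si, series in enumerate(config.series_names):
                    templates[(side, series)] = gait_waveform(
                        np.maximum(
                            base_amp[series] + delta + amp_off[si]
                            + side_amp[side][si],
                            1e-3,
                        ),
                        base_phase[series] + phase_off[si],
                        asym,
                        L,
                    ) + _bump(group, series, L)

            for side in ("left", "right"):
                n_cycles = int(rng.integers(lo, hi + 1))
                for c in range(n_cycles):
                    for series in config.series_names:
                        gain = group.noise_gain
                        if group.series_noise_gain is not None:
                            gain = group.series_noise_gain.get(series, gain)
                        gain = gain * float(np.exp(log_gain_shift))
                        samples = templates[(side, series)].copy()
                        if gain > 0:
                            samples += irreversible_noise(
                                L, group.noise_alpha, gain, rng,
                                skew=group.noise_skew,
                            )
                        if config.cycle_noise_sd > 0:
                            samples += config.cycle_noise_sd * rng.standard_normal(L)
                        cycles.append(
                            GaitCycle(
                                subject_id=sid,
                                side=side,
                                cycle_index=c,
                                series_name=series,
                                samples=samples,
                            )
                        )
    return Cohort(cycles=cycles, subjects=subjects, lab=config.lab)


def load_config(path) -> SyntheticConfig:
    """Read a :class:`SyntheticConfig` from a YAML/JSON document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    groups = tuple(
        GroupParams(
            **{
                **g,
                "template_delta": tuple(g["template_delta"])
                if g.get("template_delta") is not None
                else None,
                "bump_series": tuple(g["bump_series"])
                if g.get("bump_series") is not None
                else None,
            }
        )
        for g in doc.pop("groups")
    )
    for key in ("cycles_per_side", "age_range", "series_names"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return SyntheticConfig(groups=groups, **doc)
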