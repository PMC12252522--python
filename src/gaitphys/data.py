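"""Data model and I/O for per-cycle gait time series.

A clinical gait recording is segmented into individual gait cycles (heel
strike to the next ipsilateral heel strike) and each cycle is expressed on a
uniform percentage-of-cycle time base, nominally ~200 samples per cycle.
For every (subject, side, cycle) there is one curve per recorded series:
joint kinematics (5 joints x 3 planes), the three ground-reaction-force
components, and joint moments and powers.

The on-disk representation is a single long/tidy delimited file with one
sample per row and per-subject metadata repeated on every row::

    subject_id,group,side,cycle,series,t_index,value,age,speed[,lab][,sex]

Index 0 of a cycle is ipsilateral heel strike; the stance/swing transition
sits nominally at 60% of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GaitCycle",
    "SubjectRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "resample_cycle",
    "extract_subwindow",
]

MIN_SAMPLES = 8

REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "side",
    "cycle",
    "series",
    "t_index",
    "value",
    "age",
    "speed",
)


@dataclass(frozen=True)
class GaitCycle:
    """One time-normalised series for one (subject, side, cycle, series).

    ``samples`` lie on an implied uniform grid spanning [0, 100]% of the
    gait cycle, heel strike at index 0.
    """

    subject_id: str
    side: str
    cycle_index: int
    series_name: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < MIN_SAMPLES:
            raise ValueError(
                f"cycle {self.key()} needs >= {MIN_SAMPLES} samples, "
                f"got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"cycle {self.key()} contains non-finite samples")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def key(self) -> tuple[str, str, int, str]:
        return (self.subject_id, self.side, self.cycle_index, self.series_name)

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata: clinical group, age, normalised walking speed.

    Normalised walking speed is walking speed divided by limb length
    (units 1/s), removing stature effects.
    """

    subject_id: str
    group: str
    age: float
    normalised_walking_speed: float
    lab: str = "synthetic"
    sex: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age < 0:
            raise ValueError(f"invalid age {self.age} for {self.subject_id}")
        if not np.isfinite(self.normalised_walking_speed) or (
            self.normalised_walking_speed <= 0
        ):
            raise ValueError(
                f"normalised walking speed must be > 0 for {self.subject_id}"
            )


@dataclass
class Cohort:
    """A collection of gait cycles plus the subject metadata they belong to."""

    cycles: list[GaitCycle]
    subjects: dict[str, SubjectRecord]
    lab: str = "synthetic"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cyc in self.cycles:
            if cyc.subject_id not in self.subjects:
                raise ValueError(
                    f"cycle references unknown subject {cyc.subject_id!r}"
                )
            seen.add(cyc.subject_id)
        missing = set(self.subjects) - seen
        if missing:
            raise ValueError(f"subjects without any cycle: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def series_names(self) -> list[str]:
        return sorted({c.series_name for c in self.cycles})

    @property
    def groups(self) -> list[str]:
        return sorted({s.group for s in self.subjects.values()})

    def iter_cycles(self, series: str | None = None) -> Iterator[GaitCycle]:
        for cyc in self.cycles:
            if series is None or cyc.series_name == series:
                yield cyc

    def map_cycles(self, fn) -> "Cohort":
        """Return a new cohort with ``fn`` applied to every cycle."""
        return Cohort(
            cycles=[fn(c) for c in self.cycles],
            subjects=dict(self.subjects),
            lab=self.lab,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format representation, one sample per row."""
        frames = []
        for cyc in self.cycles:
            rec = self.subjects[cyc.subject_id]
            n = len(cyc)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": cyc.subject_id,
                        "group": rec.group,
                        "side": cyc.side,
                        "cycle": cyc.cycle_index,
                        "series": cyc.series_name,
                        "t_index": np.arange(n),
                        "value": cyc.samples,
                        "age": rec.age,
                        "speed": rec.normalised_walking_speed,
                        "lab": rec.lab,
                        "sex": rec.sex if rec.sex is not None else "",
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to the long-format delimited file."""
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Read a cohort from the long-format delimited file.

    Raises
    ------
    ValueError
        If a required column is missing, a value is non-numeric, or one
        subject carries inconsistent metadata across rows.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col in ("value", "age", "speed", "t_index", "cycle"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric entries in column {col!r}") from exc

    subjects: dict[str, SubjectRecord] = {}
    meta_cols = ["group", "age", "speed"] + (["lab"] if "lab" in df else [])
    for sid, sub in df.groupby("subject_id", sort=False):
        meta = sub[meta_cols].drop_duplicates()
        if len(meta) != 1:
            raise ValueError(
                f"inconsistent metadata for subject {sid!r}: {len(meta)} variants"
            )
        row = meta.iloc[0]
        sex = None
        if "sex" in sub.columns:
            sval = sub["sex"].iloc[0]
            if isinstance(sval, str) and sval:
                sex = sval
        subjects[str(sid)] = SubjectRecord(
            subject_id=str(sid),
            group=str(row["group"]),
            age=float(row["age"]),
            normalised_walking_speed=float(row["speed"]),
            lab=str(row["lab"]) if "lab" in meta_cols else "unknown",
            sex=sex,
        )

    cycles: list[GaitCycle] = []
    grouped = df.sort_values("t_index").groupby(
        ["subject_id", "side", "cycle", "series"], sort=False
    )
    for (sid, side, cyc_idx, series), sub in grouped:
        cycles.append(
            GaitCycle(
                subject_id=str(sid),
                side=str(side),
                cycle_index=int(cyc_idx),
                series_name=str(series),
                samples=sub["value"].to_numpy(),
            )
        )
    lab = subjects[next(iter(subjects))].lab if subjects else "unknown"
    return Cohort(cycles=cycles, subjects=subjects, lab=lab)


def resample_cycle(cycle: GaitCycle, length: int) -> GaitCycle:
    """Linearly interpolate a cycle onto ``length`` uniform points.

    Both grids span [0, 100]% inclusively, so the first and last samples
    are preserved exactly and resampling to the native length is the
    identity.
    """
    if length < MIN_SAMPLES:
        raise ValueError(
            f"target resolution {length} below minimum of {MIN_SAMPLES} samples"
        )
    n = len(cycle)
    if length == n:
        return cycle
    old_grid = np.linspace(0.0, 100.0, n)
    new_grid = np.linspace(0.0, 100.0, length)
    return replace(cycle, samples=np.interp(new_grid, old_grid, cycle.samples))


def extract_subwindow(
    cycle: GaitCycle, start_pct: float, length_pct: float
) -> GaitCycle:
    """Contiguous slice covering [start, start+length]% of the cycle.

    Index bounds are floor(start*N/100) to floor((start+length)*N/100),
    so (0, 100) returns the cycle unchanged and (60, 40) on a 200-sample
    cycle is the swing-phase slice, samples 120..200.
    """
    if not (0 <= start_pct < 100):
        raise ValueError(f"start_pct must be in [0, 100), got {start_pct}")
    if not (0 < length_pct <= 100):
        raise ValueError(f"length_pct must be in (0, 100], got {length_pct}")
    if start_pct + length_pct > 100 + 1e-9:
        raise ValueError("start_pct + length_pct must not exceed 100")
    n = len(cycle)
    i0 = int(np.floor(start_pct * n / 100.0))
    i1 = int(np.floor((start_pct + length_pct) * n / 100.0))
    if i1 - i0 < MIN_SAMPLES:
        raise ValueError(
            f"sub-window [{start_pct}, {start_pct + length_pct}]% of a "
            f"{n}-sample cycle has {i1 - i0} samples (< {MIN_SAMPLES})"
        )
    if i0 == 0 and i1 == n:
        return cycle
    return replace(cycle, samples=cycle.samples[i0:i1])
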