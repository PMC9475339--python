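"""Reading, cleaning and phase-segmentation of RR-interval recordings.

An RR (NN) interval series is the sequence of times between successive
normal heartbeats, in milliseconds.  Recordings follow a tilt-table
protocol: a supine baseline, a head-up-tilt phase and a resupine recovery
phase, separated by short tilting transitions that are excluded from
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

OK = "ok"
ARTIFACT = "artifact"

DIALECTS = ("plain_ms", "csv_timestamped")


@dataclass
class RRSeries:
    """Timestamped NN intervals for one subject.

    ``beat_times`` are beat instants in seconds from recording start
    (length ``len(rr_ms) + 1``); ``rr_ms[i]`` is the interval terminated by
    ``beat_times[i + 1]``.  ``flags`` marks per-interval quality
    (``"ok"`` / ``"artifact"``).
    """

    subject_id: str
    beat_times: np.ndarray
    rr_ms: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.rr_ms.shape, OK, dtype="<U8")
        else:
            self.flags = np.asarray(self.flags, dtype="<U8")
        if len(self.beat_times) != len(self.rr_ms) + 1:
            raise ValueError(
                f"{self.subject_id}: need len(beat_times) == len(rr_ms) + 1, "
                f"got {len(self.beat_times)} vs {len(self.rr_ms)}"
            )
        if len(self.flags) != len(self.rr_ms):
            raise ValueError("flags must align with rr_ms")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError(f"{self.subject_id}: beat_times must be strictly increasing")
        if np.any(self.rr_ms <= 0):
            raise ValueError(f"{self.subject_id}: all RR intervals must be positive")

    @property
    def n_intervals(self) -> int:
        return len(self.rr_ms)

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    @property
    def end_times(self) -> np.ndarray:
        """Terminating beat time of every interval."""
        return self.beat_times[1:]


@dataclass
class ProtocolDefinition:
    """Phase windows of a tilt protocol, in seconds from recording start.

    Windows are half-open ``[start, end)``; ``excluded_windows`` cover the
    tilting transitions whose beats are discarded from every phase.
    """

    phases: list[tuple[str, float, float]]
    excluded_windows: list[tuple[float, float]] = field(default_factory=list)
    tilt_angle_deg: float = 60.0

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for name, start, end in self.phases:
            if end <= start:
                raise ValueError(f"phase {name!r}: end must exceed start")
            if start < prev_end:
                raise ValueError("phases must be ordered and non-overlapping")
            prev_end = end

    @classmethod
    def default(cls) -> "ProtocolDefinition":
        """5-min supine, 3-min tilt, 5-min resupine; 15-s transitions excluded."""
        return cls(
            phases=[("supine", 0.0, 300.0), ("tilt", 315.0, 495.0),
                    ("resupine", 510.0, 810.0)],
            excluded_windows=[(300.0, 315.0), (495.0, 510.0)],
            tilt_angle_deg=60.0,
        )

    @property
    def total_duration_s(self) -> float:
        return self.phases[-1][2]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "tilt_angle_deg": self.tilt_angle_deg,
            "phases": [{"name": n, "start_s": s, "end_s": e} for n, s, e in self.phases],
            "excluded_windows": [{"start_s": s, "end_s": e}
                                 for s, e in self.excluded_windows],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolDefinition":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            phases=[(p["name"], float(p["start_s"]), float(p["end_s"]))
                    for p in payload["phases"]],
            excluded_windows=[(float(w["start_s"]), float(w["end_s"]))
                              for w in payload.get("excluded_windows", [])],
            tilt_angle_deg=float(payload.get("tilt_angle_deg", 60.0)),
        )


@dataclass
class SubjectRecord:
    """One row of the cohort metadata table."""

    subject_id: str
    group_label: str
    age: float | None = None
    sex: str | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    bmi_kg_m2: float | None = None
    sbp_mmHg: float | None = None
    dbp_mmHg: float | None = None

    def __post_init__(self) -> None:
        if not self.group_label:
            raise ValueError(f"{self.subject_id}: group_label must be non-empty")
        if self.age is not None and not np.isnan(self.age) and self.age <= 0:
            raise ValueError(f"{self.subject_id}: age must be positive")


@dataclass
class PhaseSegment:
    """Intervals of one subject falling inside one protocol phase."""

    phase_name: str
    rr_ms: np.ndarray
    beat_times: np.ndarray  # terminating beat time of each retained interval
    duration_s: float
    subject_id: str = ""
    min_beats: int = 60

    @property
    def n_beats(self) -> int:
        return len(self.rr_ms)

    @property
    def sufficient(self) -> bool:
        return self.n_beats >= self.min_beats


@dataclass
class CleaningReport:
    n_total: int
    n_flagged: int
    policy: str

    @property
    def fraction_flagged(self) -> float:
        return self.n_flagged / self.n_total if self.n_total else 0.0


# ---------------------------------------------------------------------------
# file I/O


def read_rr(path: str | Path, dialect: str = "plain_ms",
            subject_id: str | None = None) -> RRSeries:
    """Read one subject's RR series.

    ``plain_ms``: one interval (ms) per line; beat times reconstructed by
    cumulative summation from 0.  ``csv_timestamped``: columns
    ``beat_time_s`` (terminating beat) and ``rr_ms``.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    sid = subject_id if subject_id is not None else path.stem

    if dialect == "plain_ms":
        rr = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            tok = line.strip()
            if not tok:
                continue
            try:
                val = float(tok)
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric token {tok!r} on line {lineno}") from exc
            rr.append(val)
        rr_arr = np.asarray(rr, dtype=float)
        if np.any(rr_arr <= 0):
            bad = int(np.flatnonzero(rr_arr <= 0)[0]) + 1
            raise ValueError(f"{path}: non-positive RR interval at entry {bad}")
        beat_times = np.concatenate([[0.0], np.cumsum(rr_arr) / 1000.0])
        return RRSeries(sid, beat_times, rr_arr)

    df = pd.read_csv(path)
    for col in ("beat_time_s", "rr_ms"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if not np.issubdtype(df["rr_ms"].dtype, np.number) or df["rr_ms"].isna().any():
        raise ValueError(f"{path}: non-numeric rr_ms values")
    rr_arr = df["rr_ms"].to_numpy(float)
    end_t = df["beat_time_s"].to_numpy(float)
    if np.any(rr_arr <= 0):
        raise ValueError(f"{path}: non-positive RR interval")
    beat_times = np.concatenate([[end_t[0] - rr_arr[0] / 1000.0], end_t])
    return RRSeries(sid, beat_times, rr_arr)


def write_rr(series: RRSeries, path: str | Path, dialect: str = "plain_ms") -> None:
    path = Path(path)
    if dialect == "plain_ms":
        path.write_text("".join(f"{v:.3f}\n" for v in series.rr_ms))
    elif dialect == "csv_timestamped":
        pd.DataFrame({
            "beat_time_s": np.round(series.end_times, 3),
            "rr_ms": np.round(series.rr_ms, 3),
        }).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


METADATA_COLUMNS = ["subject_id", "group_label", "age", "sex", "height_cm",
                    "weight_kg", "bmi", "sbp", "dbp"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the subject metadata CSV; validates ids and group labels."""
    df = pd.read_csv(path)
    for col in ("subject_id", "group_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata missing column {col!r}")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{path}: duplicate subject_id {dup!r}")
    if df["group_label"].isna().any() or (df["group_label"].astype(str) == "").any():
        raise ValueError(f"{path}: empty group_label")
    return df


def subject_records(df: pd.DataFrame) -> list[SubjectRecord]:
    recs = []
    for _, row in df.iterrows():
        recs.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group_label=str(row["group_label"]),
            age=float(row["age"]) if "age" in row and pd.notna(row["age"]) else None,
            sex=str(row["sex"]) if "sex" in row and pd.notna(row["sex"]) else None,
            height_cm=float(row["height_cm"]) if "height_cm" in row and pd.notna(row.get("height_cm")) else None,
            weight_kg=float(row["weight_kg"]) if "weight_kg" in row and pd.notna(row.get("weight_kg")) else None,
            bmi_kg_m2=float(row["bmi"]) if "bmi" in row and pd.notna(row.get("bmi")) else None,
            sbp_mmHg=float(row["sbp"]) if "sbp" in row and pd.notna(row.get("sbp")) else None,
            dbp_mmHg=float(row["dbp"]) if "dbp" in row and pd.notna(row.get("dbp")) else None,
        ))
    return recs


# ---------------------------------------------------------------------------
# artifact cleaning


def clean_rr(series: RRSeries, policy: str = "flag_only", *,
             rr_min_ms: float = 300.0, rr_max_ms: float = 2000.0,
             median_window: int = 11, max_median_dev: float = 0.2,
             strict: bool = False) -> tuple[RRSeries, CleaningReport]:
    """Automated artifact screen standing in for manual beat editing.

    An interval is flagged when it lies outside ``[rr_min_ms, rr_max_ms]``
    or deviates more than ``max_median_dev`` (fractional) from the centred
    running median of ``median_window`` beats.  ``policy``:

    - ``flag_only`` — mark intervals, values untouched
    - ``delete``    — drop flagged intervals (beat times of kept intervals
      are preserved, so deleted beats leave gaps in the timeline)
    - ``interpolate`` — replace flagged values by the local running median
    """
    if policy not in ("flag_only", "delete", "interpolate"):
        raise ValueError(f"unknown cleaning policy {policy!r}")
    rr = series.rr_ms
    med = (pd.Series(rr)
           .rolling(median_window, center=True, min_periods=1)
           .median()
           .to_numpy())
    bad = (rr < rr_min_ms) | (rr > rr_max_ms) | (np.abs(rr - med) > max_median_dev * med)
    report = CleaningReport(n_total=len(rr), n_flagged=int(bad.sum()), policy=policy)

    if report.fraction_flagged > 0.2:
        msg = (f"{series.subject_id}: {report.fraction_flagged:.0%} of intervals "
               f"flagged as artifacts")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    if policy == "flag_only":
        flags = np.where(bad, ARTIFACT, series.flags)
        out = RRSeries(series.subject_id, series.beat_times.copy(), rr.copy(), flags)
    elif policy == "delete":
        keep = ~bad
        beat_times = np.concatenate([[series.beat_times[0]], series.end_times[keep]])
        out = RRSeries(series.subject_id, beat_times, rr[keep], series.flags[keep])
    else:  # interpolate
        rr_fixed = np.where(bad, med, rr)
        out = RRSeries(series.subject_id, series.beat_times.copy(), rr_fixed,
                       np.full(len(rr), OK, dtype="<U8"))
    return out, report


# ---------------------------------------------------------------------------
# phase segmentation


def segment_phases(series: RRSeries, protocol: ProtocolDefinition,
                   min_beats: int = 60) -> list[PhaseSegment]:
    """Assign intervals to protocol phases by terminating beat time.

    Membership uses half-open windows ``[start, end)``; intervals ending in
    an excluded window, or flagged as artifacts, belong to no phase.
    Segments with fewer than ``min_beats`` intervals are returned marked
    insufficient rather than dropped.
    """
    end_t = series.end_times
    usable = series.flags == OK
    for s, e in protocol.excluded_windows:
        usable &= ~((end_t >= s) & (end_t < e))

    segments = []
    for name, start, end in protocol.phases:
        mask = usable & (end_t >= start) & (end_t < end)
        segments.append(PhaseSegment(
            phase_name=name,
            rr_ms=series.rr_ms[mask],
            beat_times=end_t[mask],
            duration_s=end - start,
            subject_id=series.subject_id,
            min_beats=min_beats,
        ))
    return segments
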