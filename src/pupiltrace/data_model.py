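"""Domain types, tabular readers/writers, and structural validation.

In-memory conventions used throughout the package:

* a missing pupil diameter is ``numpy.nan`` (on disk: an empty field);
* sample indices are 0-based and all windows are half-open ``[start, end)``;
* every recording starts at 0 s and trial event times share that clock.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TASKS = ("cued_recall", "recognition")
CONDITIONS = ("weak", "strong", "foil")
RESPONSES = ("old", "new", "recalled", "not_recalled")
ALIGNMENTS = ("stimulus", "response")

#: fixation-cross duration in seconds; stimulus onset is locked 3 s after
#: fixation onset in both tasks.
FIXATION_S = 3.0
#: stimulus presentation duration in seconds.
STIMULUS_S = 5.0

#: analysis-grid geometry: stimulus-aligned epochs span [-3, +5) s,
#: response-aligned epochs span [-3, +3) s, both at 50 Hz.
STIM_EPOCH_SAMPLES = 400
RESP_EPOCH_SAMPLES = 300
EPOCH_GRID_START_S = -3.0
ANALYSIS_RATE_HZ = 50.0


class ValidationError(ValueError):
    """An input violated a structural invariant."""


def _as_float_array(x: Sequence[float]) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class SampleTrack:
    """One participant's continuous pupil recording.

    ``diameter_mm`` uses NaN for missing samples. ``valid`` is the tracker's
    own pupil-detected flag; after blink masking the two agree, but the flag
    is kept verbatim so that data-quality metrics refer to the raw recording.
    """

    participant_id: str
    task: str
    rate_hz: float
    time_s: np.ndarray
    diameter_mm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = _as_float_array(self.time_s)
        self.diameter_mm = _as_float_array(self.diameter_mm)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate_hz

    def validate(self) -> "SampleTrack":
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if not self.rate_hz > 0:
            raise ValidationError("rate_hz must be positive")
        n = len(self.time_s)
        if n == 0:
            raise ValidationError("empty track")
        if not (len(self.diameter_mm) == len(self.valid) == n):
            raise ValidationError("time_s, diameter_mm, valid must have equal length")
        dt = np.diff(self.time_s)
        if n > 1:
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValidationError(f"time_s not strictly increasing at index {i + 1}")
            nominal = 1.0 / self.rate_hz
            if np.any(np.abs(dt - nominal) > 0.1 * nominal):
                i = int(np.argmax(np.abs(dt - nominal) > 0.1 * nominal))
                raise ValidationError(
                    f"sample interval at index {i + 1} deviates >10% from 1/rate_hz"
                )
        d = self.diameter_mm[self.valid]
        if np.any(~np.isfinite(d)) or np.any(d <= 0):
            raise ValidationError("diameter_mm must be present and > 0 wherever valid")
        return self

    def copy_with(self, **kw) -> "SampleTrack":
        return dataclasses.replace(
            self,
            **{
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in {**self.__dict__, **kw}.items()
            },
        )


@dataclass
class TrialEvent:
    """One trial's design cell and behavioral outcome, with event times.

    ``rt_s`` is measured from stimulus onset to the keypress and is ``None``
    exactly when no keypress occurred (cued-recall non-retrieval trials).
    """

    trial_id: int
    participant_id: str
    task: str
    condition: str
    fixation_onset_s: float
    stimulus_onset_s: float
    rt_s: float | None
    response: str
    correct: bool

    def validate(self, tol_s: float = 1.0 / ANALYSIS_RATE_HZ) -> "TrialEvent":
        if self.task not in TASKS:
            raise ValidationError(f"trial {self.trial_id}: unknown task {self.task!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"trial {self.trial_id}: unknown condition {self.condition!r}"
            )
        if self.response not in RESPONSES:
            raise ValidationError(
                f"trial {self.trial_id}: unknown response {self.response!r}"
            )
        if self.condition == "foil" and self.task == "cued_recall":
            raise ValidationError(
                f"trial {self.trial_id}: foil condition is recognition-only"
            )
        gap = self.stimulus_onset_s - self.fixation_onset_s
        if abs(gap - FIXATION_S) > tol_s + 1e-9:
            raise ValidationError(
                f"trial {self.trial_id}: fixation-to-stimulus spacing {gap:.3f} s "
                f"!= {FIXATION_S} s"
            )
        no_press = self.response == "not_recalled"
        if no_press and self.rt_s is not None:
            raise ValidationError(f"trial {self.trial_id}: rt_s present without keypress")
        if not no_press and self.rt_s is None:
            raise ValidationError(f"trial {self.trial_id}: rt_s absent despite keypress")
        return self

    @property
    def keypress_s(self) -> float | None:
        if self.rt_s is None:
            return None
        return self.stimulus_onset_s + self.rt_s


@dataclass
class Epoch:
    """One trial segment on a fixed alignment grid, optionally baseline-corrected.

    Stimulus-aligned epochs hold 400 samples over [-3, +5) s at 50 Hz;
    response-aligned epochs hold 300 samples over [-3, +3) s with the
    keypress at index 150.
    """

    trial_id: int
    participant_id: str
    alignment: str
    grid_start_s: float
    values_mm: np.ndarray
    baseline_mm: float
    condition: str
    task: str
    correct: bool
    excluded: bool = False

    def __post_init__(self) -> None:
        self.values_mm = _as_float_array(self.values_mm)

    @property
    def n_samples(self) -> int:
        return len(self.values_mm)

    def validate(self) -> "Epoch":
        if self.alignment not in ALIGNMENTS:
            raise ValidationError(f"unknown alignment {self.alignment!r}")
        want = STIM_EPOCH_SAMPLES if self.alignment == "stimulus" else RESP_EPOCH_SAMPLES
        if self.n_samples != want:
            raise ValidationError(
                f"{self.alignment}-aligned epoch must hold {want} samples, "
                f"got {self.n_samples}"
            )
        return self


@dataclass
class ConditionAverage:
    """One participant x condition-label mean curve and its trial count."""

    participant_id: str
    condition_label: str
    alignment: str
    curve_mm: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.curve_mm = _as_float_array(self.curve_mm)


@dataclass
class Cluster:
    """A maximal run of sign-consistent pointwise-significant timepoints."""

    start: int
    end: int  # half-open
    sign: int
    mass: float
    p_perm: float = float("nan")
    significant: bool = False
    start_ms: float = float("nan")
    end_ms: float = float("nan")


@dataclass
class ClusterTestResult:
    """Pointwise Wilcoxon z/p series plus permutation family-wise inference."""

    label_a: str
    label_b: str
    alignment: str | None
    window_start_s: float
    rate_hz: float
    z_series: np.ndarray
    p_series: np.ndarray
    clusters: list[Cluster]
    null_masses: np.ndarray
    n_permutations: int
    pointwise_alpha: float
    cluster_alpha: float
    seed: int
    n_participants: int = 0

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "alignment": self.alignment,
            "window_start_s": self.window_start_s,
            "rate_hz": self.rate_hz,
            "n_participants": self.n_participants,
            "n_permutations": self.n_permutations,
            "pointwise_alpha": self.pointwise_alpha,
            "cluster_alpha": self.cluster_alpha,
            "seed": self.seed,
            "clusters": [dataclasses.asdict(c) for c in self.clusters],
            "null_mass_percentile_95": float(np.quantile(self.null_masses, 0.95))
            if len(self.null_masses)
            else None,
            "z_series": [float(z) for z in self.z_series],
            "p_series": [float(p) for p in self.p_series],
            "null_masses": [float(m) for m in self.null_masses],
        }


# ---------------------------------------------------------------------------
# Tabular I/O.  Dialect: UTF-8, header row, tab or comma auto-detected.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"  # round-trips to >= 6 significant digits


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValidationError(f"{path}: empty file")
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    return df


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _parse_bool(col: pd.Series, path: Path, name: str) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy()
    out = np.empty(len(col), dtype=bool)
    for i, v in enumerate(col):
        s = str(v).strip().lower()
        if s in _TRUE:
            out[i] = True
        elif s in _FALSE:
            out[i] = False
        else:
            raise ValidationError(
                f"{path}: line {i + 2}: cannot parse {name}={v!r} as boolean"
            )
    return out


def read_sample_table(path: str | Path, rate_hz: float, *,
                      participant_id: str = "", task: str = "recognition",
                      column_mapping: dict[str, str] | None = None) -> SampleTrack:
    """Read a continuous pupil recording from delimited text.

    Expects columns ``time``, ``diameter``, ``valid``. Rows flagged invalid
    keep their timestamp; their diameter becomes missing regardless of what
    the field holds (trackers emit 0 or garbage during blinks).
    ``column_mapping`` maps canonical names to external column names for
    foreign table dialects.
    """
    path = Path(path)
    df = _read_table(path)
    if column_mapping:
        df = df.rename(columns={v: k for k, v in column_mapping.items()})
    _require_columns(df, ("time", "diameter", "valid"), path)
    valid = _parse_bool(df["valid"], path, "valid")
    try:
        time_s = df["time"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: unparseable time column: {exc}") from exc
    diam = pd.to_numeric(df["diameter"], errors="coerce").to_numpy(dtype=float)
    bad = valid & ~np.isfinite(diam)
    if np.any(bad):
        raise ValidationError(
            f"{path}: line {int(np.argmax(bad)) + 2}: valid row with unparseable diameter"
        )
    diam = np.where(valid, diam, np.nan)
    track = SampleTrack(
        participant_id=participant_id or path.stem,
        task=task,
        rate_hz=rate_hz,
        time_s=time_s,
        diameter_mm=diam,
        valid=valid,
    )
    return track.validate()


def write_sample_table(track: SampleTrack, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        {
            "time": track.time_s,
            "diameter": track.diameter_mm,
            "valid": track.valid,
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT, na_rep="")


_EVENT_COLS = (
    "trial_id",
    "participant_id",
    "task",
    "condition",
    "fixation_onset_s",
    "stimulus_onset_s",
    "rt_s",
    "response",
    "correct",
)


def read_event_table(path: str | Path,
                     column_mapping: dict[str, str] | None = None) -> list[TrialEvent]:
    """Read a trial event table; events are returned sorted by fixation onset."""
    path = Path(path)
    df = _read_table(path)
    if column_mapping:
        df = df.rename(columns={v: k for k, v in column_mapping.items()})
    _require_columns(df, _EVENT_COLS, path)
    correct = _parse_bool(df["correct"], path, "correct")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        rt = getattr(row, "rt_s")
        rt_val = None if pd.isna(rt) or str(rt).strip() == "" else float(rt)
        ev = TrialEvent(
            trial_id=int(row.trial_id),
            participant_id=str(row.participant_id),
            task=str(row.task),
            condition=str(row.condition),
            fixation_onset_s=float(row.fixation_onset_s),
            stimulus_onset_s=float(row.stimulus_onset_s),
            rt_s=rt_val,
            response=str(row.response),
            correct=bool(correct[i]),
        )
        ev.validate()
        events.append(ev)
    events.sort(key=lambda e: e.fixation_onset_s)
    return events


def write_event_table(events: Sequence[TrialEvent], path: str | Path, sep: str = ",") -> None:
    rows = []
    for e in events:
        d = dataclasses.asdict(e)
        if d["rt_s"] is None:
            d["rt_s"] = np.nan
        rows.append(d)
    df = pd.DataFrame(rows, columns=list(_EVENT_COLS))
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT, na_rep="")


_EPOCH_META = (
    "trial_id",
    "participant_id",
    "alignment",
    "grid_start_s",
    "condition",
    "task",
    "correct",
    "excluded",
    "baseline_mm",
)


def write_epoch_matrix(epochs: Sequence[Epoch], path: str | Path, sep: str = ",") -> None:
    """Write epochs as one row each: metadata columns then value columns.

    Missing samples are written as empty fields. All epochs must share one
    alignment (and hence one grid length).
    """
    alignments = {e.alignment for e in epochs}
    if len(alignments) > 1:
        raise ValidationError(f"mixed alignments in epoch list: {sorted(alignments)}")
    if epochs:
        n = epochs[0].n_samples
        value_cols = [f"v{i:03d}" for i in range(n)]
    else:
        value_cols = []
    rows = []
    for e in epochs:
        row = {
            "trial_id": e.trial_id,
            "participant_id": e.participant_id,
            "alignment": e.alignment,
            "grid_start_s": e.grid_start_s,
            "condition": e.condition,
            "task": e.task,
            "correct": e.correct,
            "excluded": e.excluded,
            "baseline_mm": e.baseline_mm,
        }
        row.update(dict(zip(value_cols, e.values_mm)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_EPOCH_META) + value_cols)
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT, na_rep="")


def read_epoch_matrix(path: str | Path) -> list[Epoch]:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, _EPOCH_META, path)
    value_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    value_cols.sort(key=lambda c: int(c[1:]))
    epochs = []
    for i in range(len(df)):
        row = df.iloc[i]
        epochs.append(
            Epoch(
                trial_id=int(row["trial_id"]),
                participant_id=str(row["participant_id"]),
                alignment=str(row["alignment"]),
                grid_start_s=float(row["grid_start_s"]),
                values_mm=row[value_cols].to_numpy(dtype=float),
                baseline_mm=float(row["baseline_mm"]),
                condition=str(row["condition"]),
                task=str(row["task"]),
                correct=bool(_parse_bool(pd.Series([row["correct"]]), path, "correct")[0]),
                excluded=bool(_parse_bool(pd.Series([row["excluded"]]), path, "excluded")[0]),
            )
        )
    return epochs


def write_condition_averages(avgs: Sequence[ConditionAverage], path: str | Path,
                             sep: str = ",") -> None:
    if not avgs:
        pd.DataFrame(columns=["participant_id", "condition_label", "alignment",
                              "n_trials"]).to_csv(path, sep=sep, index=False)
        return
    n = len(avgs[0].curve_mm)
    value_cols = [f"v{i:03d}" for i in range(n)]
    rows = []
    for a in avgs:
        row = {
            "participant_id": a.participant_id,
            "condition_label": a.condition_label,
            "alignment": a.alignment,
            "n_trials": a.n_trials,
        }
        row.update(dict(zip(value_cols, a.curve_mm)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False,
                              float_format=_FLOAT_FMT, na_rep="")


def write_cluster_report(result: ClusterTestResult, path: str | Path) -> None:
    """JSON report of a cluster permutation test (clusters, null, parameters)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def format_cluster_summary(result: ClusterTestResult) -> str:
    """Plain-text summary in the field's reporting style (windows in ms)."""
    out = io.StringIO()
    out.write(
        f"Cluster permutation test: {result.label_a} vs {result.label_b} "
        f"({result.alignment or 'custom'}-aligned, n={result.n_participants}, "
        f"{result.n_permutations} permutations, seed={result.seed})\n"
    )
    if not result.clusters:
        out.write("  No clusters of consecutive pointwise-significant timepoints.\n")
    for c in result.clusters:
        tag = "SIGNIFICANT" if c.significant else "n.s."
        sign = "+" if c.sign > 0 else "-"
        out.write(
            f"  cluster {c.start_ms:.0f} to {c.end_ms:.0f} ms, sign {sign}, "
            f"mass {c.mass:.2f}, p_perm = {c.p_perm:.3f} [{tag}]\n"
        )
    if not result.significant_clusters:
        out.write("  => no significant clusters.\n")
    return out.getvalue()
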