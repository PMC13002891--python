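"""Event-aligned epoching, baseline correction, trial labelling, and
per-participant condition averaging.

Stimulus-aligned epochs span [-3, +5) s around stimulus onset (400 samples
at 50 Hz); response-aligned epochs span [-3, +3) s around the keypress
(300 samples, keypress at index 150). Both use the same baseline: the mean
pupil size over the final 500 ms of the fixation cross, i.e. [-0.5, 0) s
relative to *stimulus* onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    ANALYSIS_RATE_HZ,
    EPOCH_GRID_START_S,
    RESP_EPOCH_SAMPLES,
    STIM_EPOCH_SAMPLES,
    ConditionAverage,
    Epoch,
    SampleTrack,
    TrialEvent,
    ValidationError,
)


@dataclass
class SegmentConfig:
    stim_window_s: tuple[float, float] = (-3.0, 5.0)
    resp_window_s: tuple[float, float] = (-3.0, 3.0)
    baseline_window_s: tuple[float, float] = (-0.5, 0.0)
    min_trials_per_condition: int = 2
    min_baseline_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        for lo, hi in (self.stim_window_s, self.resp_window_s, self.baseline_window_s):
            if not lo < hi:
                raise ValidationError("epoch windows must be ordered (lo < hi)")


def _snap_index(t_s: float, rate_hz: float) -> int:
    """Snap an event time to the nearest sample index."""
    return int(round(t_s * rate_hz))


def _gather(track: SampleTrack, start: int, n: int) -> np.ndarray:
    """Samples [start, start+n) with NaN padding outside the recording."""
    out = np.full(n, np.nan)
    lo = max(start, 0)
    hi = min(start + n, len(track))
    if hi > lo:
        out[lo - start : hi - start] = track.diameter_mm[lo:hi]
    return out


def extract_stimulus_aligned(track: SampleTrack, event: TrialEvent,
                             cfg: SegmentConfig | None = None) -> Epoch:
    """Cut the 8 s trial segment time-locked to stimulus onset."""
    cfg = cfg or SegmentConfig()
    rate = track.rate_hz
    onset = _snap_index(event.stimulus_onset_s, rate)
    if onset < 0 or onset >= len(track):
        raise ValidationError(
            f"trial {event.trial_id}: stimulus onset at sample {onset} is outside the recording"
        )
    start = onset + int(round(cfg.stim_window_s[0] * rate))
    n = int(round((cfg.stim_window_s[1] - cfg.stim_window_s[0]) * rate))
    return Epoch(
        trial_id=event.trial_id,
        participant_id=event.participant_id,
        alignment="stimulus",
        grid_start_s=cfg.stim_window_s[0],
        values_mm=_gather(track, start, n),
        baseline_mm=np.nan,
        condition=event.condition,
        task=event.task,
        correct=event.correct,
    )


def extract_response_aligned(track: SampleTrack, event: TrialEvent,
                             cfg: SegmentConfig | None = None) -> Epoch | None:
    """Cut the +/-3 s segment time-locked to the keypress; None if no keypress."""
    cfg = cfg or SegmentConfig()
    if event.rt_s is None:
        return None
    rate = track.rate_hz
    key = _snap_index(event.keypress_s, rate)
    if key < 0 or key >= len(track):
        raise ValidationError(
            f"trial {event.trial_id}: keypress at sample {key} is outside the recording"
        )
    start = key + int(round(cfg.resp_window_s[0] * rate))
    n = int(round((cfg.resp_window_s[1] - cfg.resp_window_s[0]) * rate))
    return Epoch(
        trial_id=event.trial_id,
        participant_id=event.participant_id,
        alignment="response",
        grid_start_s=cfg.resp_window_s[0],
        values_mm=_gather(track, start, n),
        baseline_mm=np.nan,
        condition=event.condition,
        task=event.task,
        correct=event.correct,
    )


def baseline_correct(epoch: Epoch, track: SampleTrack, event: TrialEvent,
                     cfg: SegmentConfig | None = None) -> Epoch:
    """Subtract the pre-stimulus baseline mean from every epoch sample.

    For both alignments the baseline is the mean over the non-missing samples
    in [stimulus onset - 0.5 s, stimulus onset). An epoch whose baseline
    window has fewer than ``min_baseline_valid_fraction`` usable samples is
    flagged excluded rather than corrected.
    """
    cfg = cfg or SegmentConfig()
    rate = track.rate_hz
    onset = _snap_index(event.stimulus_onset_s, rate)
    b0 = onset + int(round(cfg.baseline_window_s[0] * rate))
    b1 = onset + int(round(cfg.baseline_window_s[1] * rate))
    window = _gather(track, b0, b1 - b0)
    finite = np.isfinite(window)
    if finite.mean() < cfg.min_baseline_valid_fraction:
        epoch.excluded = True
        epoch.baseline_mm = np.nan
        return epoch
    baseline = float(window[finite].mean())
    epoch.values_mm = epoch.values_mm - baseline
    epoch.baseline_mm = baseline
    return epoch


def extract_epochs(track: SampleTrack, events: Sequence[TrialEvent],
                   alignment: str = "stimulus",
                   cfg: SegmentConfig | None = None) -> list[Epoch]:
    """Epoch every trial of one participant, baseline-corrected."""
    cfg = cfg or SegmentConfig()
    epochs: list[Epoch] = []
    for ev in events:
        if alignment == "stimulus":
            ep = extract_stimulus_aligned(track, ev, cfg)
        elif alignment == "response":
            ep = extract_response_aligned(track, ev, cfg)
            if ep is None:
                continue
        else:
            raise ValidationError(f"unknown alignment {alignment!r}")
        epochs.append(baseline_correct(ep, track, ev, cfg))
    return epochs


def label_trials(events: Sequence[TrialEvent]) -> dict[int, str]:
    """Map each trial to its analysis label.

    Recognition: targets become ``hit_<cond>`` or ``miss_<cond>`` depending
    on the old/new response; foils become ``correct_rejection`` or
    ``false_alarm``. Cued recall: correctly recalled trials become
    ``recall_<cond>``; everything else is ``excluded_from_primary``.
    """
    labels: dict[int, str] = {}
    for ev in events:
        if ev.task == "recognition":
            if ev.condition == "foil":
                labels[ev.trial_id] = (
                    "correct_rejection" if ev.response == "new" else "false_alarm"
                )
            else:
                labels[ev.trial_id] = (
                    f"hit_{ev.condition}" if ev.response == "old" else f"miss_{ev.condition}"
                )
        else:  # cued recall
            if ev.response == "recalled" and ev.correct:
                labels[ev.trial_id] = f"recall_{ev.condition}"
            else:
                labels[ev.trial_id] = "excluded_from_primary"
    return labels


def condition_averages(epochs: Sequence[Epoch], labels: Mapping[int, str],
                       cfg: SegmentConfig | None = None) -> list[ConditionAverage]:
    """Pointwise mean curve per participant x label over usable epochs.

    Excluded epochs (failed baselines) and ``excluded_from_primary`` trials
    never enter an average. Grid points missing in all of a participant's
    trials stay missing in the average.
    """
    cfg = cfg or SegmentConfig()
    alignments = {e.alignment for e in epochs}
    if len(alignments) > 1:
        raise ValidationError("condition_averages requires a single alignment")
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for e in epochs:
        if e.excluded:
            continue
        label = labels.get(e.trial_id)
        if label is None or label == "excluded_from_primary":
            continue
        groups.setdefault((e.participant_id, label), []).append(e.values_mm)
    out = []
    for (pid, label), curves in sorted(groups.items()):
        stack = np.vstack(curves)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
        out.append(
            ConditionAverage(
                participant_id=pid,
                condition_label=label,
                alignment=next(iter(alignments)) if alignments else "stimulus",
                curve_mm=mean,
                n_trials=len(curves),
            )
        )
    return out


def contrast_participants(avgs: Sequence[ConditionAverage], label_a: str, label_b: str,
                          min_trials: int = 2) -> tuple[list[str], list[tuple[str, str]]]:
    """Participants eligible for a paired contrast, plus the dropped ones.

    A participant enters the contrast only if both condition curves exist and
    each pooled at least ``min_trials`` trials; dropped participants are
    returned with the reason.
    """
    by_pid: dict[str, dict[str, ConditionAverage]] = {}
    for a in avgs:
        by_pid.setdefault(a.participant_id, {})[a.condition_label] = a
    keep, dropped = [], []
    for pid in sorted(by_pid):
        have = by_pid[pid]
        reason = ""
        for lbl in (label_a, label_b):
            if lbl not in have:
                reason = f"no {lbl} trials"
                break
            if have[lbl].n_trials < min_trials:
                reason = f"only {have[lbl].n_trials} {lbl} trial(s) (< {min_trials})"
                break
        if reason:
            dropped.append((pid, reason))
        else:
            keep.append(pid)
    return keep, dropped
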