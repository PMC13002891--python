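"""Synthetic two-task paired-associate pupillometry study generator.

Emulates 500 Hz pupil recordings from a design with a 3 s fixation cross
followed by a 5 s stimulus, weak (one study presentation) and strong (two
presentations) memory-strength conditions, and -- in the recognition task --
novel foils. Each trial adds a condition-dependent evoked dilation on top of
a participant baseline, slow drift, and white measurement noise; blinks
appear as missing runs with a lognormal duration tail that straddles the
500 ms interpolation limit. Behavioral accuracy and reaction times follow
the condition-specific rates the analysis is calibrated against.

Everything is reproducible from ``(config, seed)``; ground truth (injected
amplitudes, RTs, blink intervals, baselines) is returned alongside the data
for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, sosfiltfilt

from .data_model import (
    FIXATION_S,
    STIMULUS_S,
    SampleTrack,
    TrialEvent,
    ValidationError,
)
from .segment import label_trials
from .stats import PairedCurves


def _default_amp_mm() -> dict[str, float]:
    # cued recall: weak > strong (retrieval effort falls with trace strength);
    # recognition: hits equal across strengths and above correct rejections,
    # false alarms at hit level (the old/new effect tracks subjective oldness).
    return {
        "recall_weak": 0.45,
        "recall_strong": 0.30,
        "no_recall": 0.35,
        "hit_weak": 0.40,
        "hit_strong": 0.40,
        "miss_weak": 0.30,
        "miss_strong": 0.30,
        "correct_rejection": 0.25,
        "false_alarm": 0.40,
    }


def _default_rt_lognorm() -> dict[str, tuple[float, float]]:
    # (median_s, sigma); medians anchored to the condition mean RTs the
    # analysis is calibrated against.
    return {
        "recall_weak": (2.37, 0.20),
        "recall_strong": (2.07, 0.20),
        "hit_weak": (1.74, 0.20),
        "hit_strong": (1.51, 0.20),
        "miss_weak": (1.90, 0.25),
        "miss_strong": (1.90, 0.25),
        "correct_rejection": (1.84, 0.20),
        "false_alarm": (1.90, 0.25),
    }


def _default_acc_prob() -> dict[str, dict[str, float]]:
    return {
        "cued_recall": {"weak": 0.2911, "strong": 0.5126},
        "recognition": {"weak": 0.7214, "strong": 0.8666, "foil": 0.885},
    }


@dataclass
class SynthConfig:
    """Study-level generative parameters (defaults are the study conditions)."""

    n_participants: int = 20
    task: str = "cued_recall"
    n_weak: int = 30
    n_strong: int = 15
    n_foil: int = 45  # recognition only
    rate_hz: float = 500.0
    kernel_n: float = 10.1
    kernel_tmax_s: float = 0.930
    #: duration of the sustained cognitive-load input convolved with the
    #: response kernel; 0 gives a pure transient locked at stimulus onset.
    sustain_s: float = 5.0
    amp_mm: dict[str, float] = field(default_factory=_default_amp_mm)
    rt_lognorm: dict[str, tuple[float, float]] = field(default_factory=_default_rt_lognorm)
    acc_prob: dict[str, dict[str, float]] = field(default_factory=_default_acc_prob)
    baseline_mean_mm: float = 3.5
    baseline_sd_mm: float = 0.3
    amp_scale_sd: float = 0.15  # lognormal participant-level gain spread
    noise_sd_mm: float = 0.1
    drift_sd_mm: float = 0.1
    blink_rate_hz: float = 0.6
    blink_dur_lognorm: tuple[float, float] = (0.15, 0.6)  # (median_s, sigma)
    inter_trial_s: float = 1.0
    verbal_report_s: float = 2.0
    response_locked: bool = False
    response_locked_amp_mm: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if self.task not in ("cued_recall", "recognition"):
            raise ValidationError(f"unknown task {self.task!r}")
        if min(self.n_weak, self.n_strong, self.n_foil) < 0:
            raise ValidationError("trial counts must be >= 0")
        for probs in self.acc_prob.values():
            for p in probs.values():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError("acc_prob entries must lie in [0, 1]")
        for a in self.amp_mm.values():
            if a < 0:
                raise ValidationError("amplitudes must be >= 0")


@dataclass
class SynthTruth:
    """Ground truth for recovery tests, reproducible from (config, seed)."""

    config: dict
    participants: dict[str, dict]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"config": self.config, "participants": self.participants},
                      fh, indent=2, default=float)


def pupil_response_kernel(t_s: np.ndarray | float, n: float = 10.1,
                          tmax_s: float = 0.930) -> np.ndarray | float:
    """Peak-normalized Erlang-form pupil response function.

    h(t) = (t/tmax)^n * exp(n * (1 - t/tmax)); h(0) = 0, h(tmax) = 1, and h
    decays toward 0 for large t. This is the standard impulse-response model
    for task-evoked dilation.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValidationError("kernel is defined for t >= 0 only")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(t > 0, (t / tmax_s) ** n * np.exp(n * (1.0 - t / tmax_s)), 0.0)
    return h if h.shape else float(h)


def evoked_waveform(rate_hz: float, n: float, tmax_s: float, sustain_s: float,
                    duration_s: float | None = None) -> np.ndarray:
    """Unit-peak evoked-response template starting at stimulus onset.

    The kernel is convolved with a boxcar of ``sustain_s`` seconds (the
    sustained cognitive load of the stimulus period); with ``sustain_s=0``
    the template is the pure kernel.
    """
    if duration_s is None:
        duration_s = sustain_s + 4.0 * tmax_s + 2.0
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    k = pupil_response_kernel(t, n, tmax_s)
    if sustain_s > 0:
        box = np.ones(max(1, int(round(sustain_s * rate_hz))))
        k = np.convolve(k, box)[: len(t)]
    peak = k.max()
    return k / peak if peak > 0 else k


def _trial_label(event: TrialEvent) -> str:
    return label_trials([event])[event.trial_id]


def _amp_for(cfg: SynthConfig, event: TrialEvent) -> float:
    label = _trial_label(event)
    if label == "excluded_from_primary":
        label = "no_recall"
    return cfg.amp_mm.get(label, 0.0)


def _draw_rt(cfg: SynthConfig, label: str, rng: np.random.Generator) -> float:
    if label == "excluded_from_primary":
        label = "no_recall"
    median, sigma = cfg.rt_lognorm.get(label, (2.0, 0.25))
    rt = median * np.exp(sigma * rng.standard_normal())
    return float(np.clip(rt, 0.25, STIMULUS_S - 0.05))


def generate_events(cfg: SynthConfig, rng: np.random.Generator,
                    participant_id: str) -> list[TrialEvent]:
    """One participant's pseudorandomized trial sequence with outcomes."""
    conditions = ["weak"] * cfg.n_weak + ["strong"] * cfg.n_strong
    if cfg.task == "recognition":
        conditions += ["foil"] * cfg.n_foil
    conditions = list(rng.permutation(conditions))
    events: list[TrialEvent] = []
    t = 0.0
    for trial_id, cond in enumerate(conditions):
        fix = t
        stim = fix + FIXATION_S
        acc = cfg.acc_prob[cfg.task][cond]
        correct = bool(rng.random() < acc)
        if cfg.task == "cued_recall":
            if correct:
                response = "recalled"
                rt = _draw_rt(cfg, f"recall_{cond}", rng)
            else:
                response = "not_recalled"
                rt = None
        else:
            if cond == "foil":
                response = "new" if correct else "old"
                rt_label = "correct_rejection" if correct else "false_alarm"
            else:
                response = "old" if correct else "new"
                rt_label = f"hit_{cond}" if correct else f"miss_{cond}"
            rt = _draw_rt(cfg, rt_label, rng)
        ev = TrialEvent(
            trial_id=trial_id,
            participant_id=participant_id,
            task=cfg.task,
            condition=cond,
            fixation_onset_s=fix,
            stimulus_onset_s=stim,
            rt_s=rt,
            response=response,
            correct=correct,
        )
        events.append(ev.validate())
        t = stim + STIMULUS_S + cfg.inter_trial_s
        if cfg.task == "cued_recall" and response == "recalled":
            t += cfg.verbal_report_s
    return events


def _make_drift(n: int, rate_hz: float, sd_mm: float,
                rng: np.random.Generator) -> np.ndarray:
    """Slow baseline wander: a random walk low-passed at 0.1 Hz."""
    if sd_mm <= 0 or n < 64:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    sos = butter(2, 0.1 / (rate_hz / 2.0), output="sos")
    slow = sosfiltfilt(sos, walk)
    slow = slow - slow.mean()
    s = slow.std()
    return slow * (sd_mm / s) if s > 0 else np.zeros(n)


def simulate_trial(cfg: SynthConfig, participant_state: dict,
                   event: TrialEvent, rng: np.random.Generator
                   ) -> tuple[np.ndarray, dict]:
    """Diameter segment over [fixation onset, stimulus offset) for one trial.

    ``participant_state`` carries ``baseline_mm`` and ``amp_scale`` (and
    optionally a precomputed session ``drift`` array). Returns the segment
    and its ground truth.
    """
    rate = cfg.rate_hz
    n = int(round((FIXATION_S + STIMULUS_S) * rate))
    start_idx = int(round(event.fixation_onset_s * rate))
    seg = np.full(n, float(participant_state["baseline_mm"]))
    drift = participant_state.get("drift")
    if drift is not None:
        sl = drift[start_idx : start_idx + n]
        seg[: len(sl)] += sl
    amp = _amp_for(cfg, event) * float(participant_state.get("amp_scale", 1.0))
    wave = participant_state.get("_waveform")
    if wave is None:
        wave = evoked_waveform(rate, cfg.kernel_n, cfg.kernel_tmax_s, cfg.sustain_s)
    stim_rel = int(round(FIXATION_S * rate))
    tail = n - stim_rel
    seg[stim_rel:] += amp * wave[:tail]
    if cfg.response_locked and event.rt_s is not None:
        kern = pupil_response_kernel(
            np.arange(0.0, 4.0, 1.0 / rate), cfg.kernel_n, cfg.kernel_tmax_s
        )
        key_rel = stim_rel + int(round(event.rt_s * rate))
        m = min(len(kern), n - key_rel)
        if m > 0:
            seg[key_rel : key_rel + m] += cfg.response_locked_amp_mm * kern[:m]
    if cfg.noise_sd_mm > 0:
        seg += cfg.noise_sd_mm * rng.standard_normal(n)
    truth = {"trial_id": event.trial_id, "label": _trial_label(event),
             "amp_mm": amp, "rt_s": event.rt_s}
    return seg, truth


def inject_blinks(track: SampleTrack, rate_hz: float,
                  dur_lognorm: tuple[float, float], rng: np.random.Generator
                  ) -> tuple[SampleTrack, list[tuple[float, float]]]:
    """Mark Poisson-arriving blinks as invalid missing runs.

    ``rate_hz`` is the blink arrival rate; durations are lognormal
    (median, sigma), so a tail of blinks exceeds the 500 ms interpolation
    limit and exercises the retained-gap path downstream.
    """
    if rate_hz <= 0:
        return track.copy_with(), []
    T = track.duration_s
    n_blinks = int(rng.poisson(rate_hz * T))
    onsets = np.sort(rng.uniform(0.0, T, size=n_blinks))
    median, sigma = dur_lognorm
    durs = median * np.exp(sigma * rng.standard_normal(n_blinks))
    valid = track.valid.copy()
    diam = track.diameter_mm.copy()
    intervals = []
    for onset, dur in zip(onsets, durs):
        i0 = int(round(onset * track.rate_hz))
        i1 = min(len(track), i0 + max(1, int(round(dur * track.rate_hz))))
        valid[i0:i1] = False
        diam[i0:i1] = np.nan
        intervals.append((float(onset), float(dur)))
    return track.copy_with(valid=valid, diameter_mm=diam), intervals


def generate_study(cfg: SynthConfig
                   ) -> tuple[dict[str, SampleTrack], dict[str, list[TrialEvent]], SynthTruth]:
    """Simulate the full study: one continuous track + event table per participant."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_participants)
    rate = cfg.rate_hz
    wave = evoked_waveform(rate, cfg.kernel_n, cfg.kernel_tmax_s, cfg.sustain_s)
    tracks: dict[str, SampleTrack] = {}
    events_by_pid: dict[str, list[TrialEvent]] = {}
    truth_p: dict[str, dict] = {}
    for i, child in enumerate(children):
        pid = f"p{i + 1:03d}"
        rng = np.random.default_rng(child)
        events = generate_events(cfg, rng, pid)
        session_end = events[-1].stimulus_onset_s + STIMULUS_S + cfg.inter_trial_s
        n = int(round(session_end * rate))
        baseline = float(max(1.0, rng.normal(cfg.baseline_mean_mm, cfg.baseline_sd_mm)))
        amp_scale = float(np.exp(cfg.amp_scale_sd * rng.standard_normal()))
        drift = _make_drift(n, rate, cfg.drift_sd_mm, rng)
        diam = baseline + drift
        if cfg.noise_sd_mm > 0:
            diam = diam + cfg.noise_sd_mm * rng.standard_normal(n)
        trial_truth = []
        for ev in events:
            amp = _amp_for(cfg, ev) * amp_scale
            stim_idx = int(round(ev.stimulus_onset_s * rate))
            m = min(len(wave), n - stim_idx)
            if m > 0:
                diam[stim_idx : stim_idx + m] += amp * wave[:m]
            if cfg.response_locked and ev.rt_s is not None:
                kern = pupil_response_kernel(
                    np.arange(0.0, 4.0, 1.0 / rate), cfg.kernel_n, cfg.kernel_tmax_s
                )
                key_idx = stim_idx + int(round(ev.rt_s * rate))
                mk = min(len(kern), n - key_idx)
                if mk > 0:
                    diam[key_idx : key_idx + mk] += cfg.response_locked_amp_mm * kern[:mk]
            trial_truth.append({"trial_id": ev.trial_id, "label": _trial_label(ev),
                                "amp_mm": amp, "rt_s": ev.rt_s})
        track = SampleTrack(
            participant_id=pid,
            task=cfg.task,
            rate_hz=rate,
            time_s=np.arange(n) / rate,
            diameter_mm=diam,
            valid=np.ones(n, dtype=bool),
        )
        track, blink_intervals = inject_blinks(track, cfg.blink_rate_hz,
                                               cfg.blink_dur_lognorm, rng)
        tracks[pid] = track.validate()
        events_by_pid[pid] = events
        truth_p[pid] = {"baseline_mm": baseline, "amp_scale": amp_scale,
                        "trials": trial_truth, "blinks": blink_intervals}
    truth = SynthTruth(config=dataclasses.asdict(cfg), participants=truth_p)
    return tracks, events_by_pid, truth


# ---------------------------------------------------------------------------
# Curve-level generators for calibration studies
# ---------------------------------------------------------------------------

def null_paired_curves(n_participants: int, n_points: int,
                       rng: np.random.Generator, noise_sd: float = 0.1,
                       smooth_sigma: float = 2.0) -> PairedCurves:
    """Two exchangeable condition curves per participant with no true effect.

    Curves are temporally smoothed Gaussian noise, mimicking the
    autocorrelation of trial-averaged pupil traces; under the null the
    within-participant condition assignment is exchangeable, which is what
    the sign-flip permutation scheme assumes.
    """
    a = gaussian_filter1d(rng.standard_normal((n_participants, n_points)),
                          smooth_sigma, axis=1) * noise_sd
    b = gaussian_filter1d(rng.standard_normal((n_participants, n_points)),
                          smooth_sigma, axis=1) * noise_sd
    return PairedCurves(
        participant_ids=[f"s{i}" for i in range(n_participants)],
        curves_a=a, curves_b=b, label_a="a", label_b="b",
        alignment=None, grid_start_s=0.0, rate_hz=50.0,
    )


def effect_paired_curves(n_participants: int, n_points: int,
                         rng: np.random.Generator, effect: float,
                         window: tuple[int, int], noise_sd: float = 0.1,
                         smooth_sigma: float = 2.0) -> PairedCurves:
    """Null curves plus a constant difference injected on [start, end)."""
    pc = null_paired_curves(n_participants, n_points, rng, noise_sd, smooth_sigma)
    pc.curves_a[:, window[0]:window[1]] += effect
    return pc
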