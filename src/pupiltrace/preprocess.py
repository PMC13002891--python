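"""Raw-track cleaning: blink masking, gap interpolation, Savitzky-Golay
smoothing, decimation to the analysis rate, and per-trial outlier removal.

The pipeline order is mask -> interpolate -> filter -> downsample -> trial
outlier cleaning. The Savitzky-Golay filter runs at the original rate and is
the low-pass stage; downsampling is plain decimation afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .data_model import (
    FIXATION_S,
    STIMULUS_S,
    SampleTrack,
    TrialEvent,
    ValidationError,
)


@dataclass
class PreprocessConfig:
    """Cleaning parameters.

    ``sg_frame_samples`` is defined at the *input* rate (501 samples = 1.002 s
    at 500 Hz). Gaps strictly shorter than ``max_interp_gap_s`` are linearly
    interpolated; longer gaps stay missing. After downsampling, samples that
    deviate from their trial-window mean by more than ``outlier_sd`` standard
    deviations are replaced by linear interpolation within the window.
    """

    max_interp_gap_s: float = 0.5
    sg_order: int = 2
    sg_frame_samples: int = 501
    downsample_factor: int = 10
    outlier_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.sg_frame_samples % 2 == 0 or self.sg_frame_samples <= self.sg_order:
            raise ValidationError("sg_frame_samples must be odd and > sg_order")
        if self.downsample_factor < 1:
            raise ValidationError("downsample_factor must be >= 1")
        if not self.max_interp_gap_s > 0:
            raise ValidationError("max_interp_gap_s must be > 0")


@dataclass
class QualityReport:
    participant_id: str
    missing_fraction: float
    excluded: bool = False
    exclusion_reason: str = ""


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def mask_invalid_samples(track: SampleTrack) -> tuple[SampleTrack, QualityReport]:
    """Set diameter to missing wherever the tracker flagged no pupil.

    The returned quality report carries the pre-interpolation missing
    fraction used for cohort-level data-quality screening.
    """
    diam = np.where(track.valid, track.diameter_mm, np.nan)
    frac = float(np.mean(~track.valid))
    report = QualityReport(participant_id=track.participant_id, missing_fraction=frac)
    return track.copy_with(diameter_mm=diam), report


def interpolate_short_gaps(track: SampleTrack, max_gap_s: float) -> SampleTrack:
    """Linearly fill missing runs strictly shorter than ``max_gap_s``.

    A run is filled only when flanked by valid samples on both sides; runs
    touching the track boundary, and runs of duration >= ``max_gap_s``, are
    retained as missing.
    """
    diam = track.diameter_mm.copy()
    missing = ~np.isfinite(diam)
    n = len(diam)
    for start, end in _missing_runs(missing):
        if start == 0 or end == n:
            continue  # no anchor on one side
        if (end - start) / track.rate_hz >= max_gap_s:
            continue
        y0, y1 = diam[start - 1], diam[end - 1 + 1]
        k = np.arange(1, end - start + 1, dtype=float)
        diam[start:end] = y0 + (y1 - y0) * k / (end - start + 1)
    return track.copy_with(diameter_mm=diam)


def _fit_segment_poly(seg: np.ndarray, order: int) -> np.ndarray:
    """Single least-squares polynomial fit over a short segment."""
    x = np.arange(len(seg), dtype=float)
    deg = min(order, len(seg) - 1)
    coeffs = np.polyfit(x, seg, deg)
    return np.polyval(coeffs, x)


def savitzky_golay_smooth(track: SampleTrack, order: int, frame: int) -> SampleTrack:
    """Smooth each contiguous non-missing segment by local polynomial fits.

    Segments longer than the frame get the standard moving-window fit with
    edge samples evaluated from the polynomial of the nearest full window;
    segments up to the frame length get a single whole-segment fit. The
    filter never fits across a missing run.
    """
    if order >= frame:
        raise ValidationError("sg order must be < frame length")
    if frame % 2 == 0:
        raise ValidationError("sg frame length must be odd")
    diam = track.diameter_mm.copy()
    finite = np.isfinite(diam)
    for start, end in _missing_runs(finite):
        seg = diam[start:end]
        if len(seg) > frame:
            diam[start:end] = savgol_filter(seg, frame, order, mode="interp")
        elif len(seg) >= 2:
            diam[start:end] = _fit_segment_poly(seg, order)
        # single samples pass through unchanged
    return track.copy_with(diameter_mm=diam)


def downsample_track(track: SampleTrack, factor: int) -> SampleTrack:
    """Keep every ``factor``-th sample starting at index 0 (decimation)."""
    if factor < 1:
        raise ValidationError("downsample factor must be >= 1")
    if factor == 1:
        return track.copy_with()
    return track.copy_with(
        time_s=track.time_s[::factor],
        diameter_mm=track.diameter_mm[::factor],
        valid=track.valid[::factor],
        rate_hz=track.rate_hz / factor,
    )


def trial_window_indices(event: TrialEvent, rate_hz: float) -> tuple[int, int]:
    """Half-open sample range [fixation onset, stimulus onset + 5 s)."""
    start = int(round(event.fixation_onset_s * rate_hz))
    end = int(round((event.stimulus_onset_s + STIMULUS_S) * rate_hz))
    return start, end


def clean_trial_outliers(track: SampleTrack, events: Sequence[TrialEvent],
                         sd_k: float = 3.0) -> SampleTrack:
    """Replace per-trial outlier samples by linear interpolation.

    For each trial window the mean and SD of the non-missing samples are
    computed; samples deviating by more than ``sd_k`` SDs are removed and
    re-filled by interpolating between the nearest surviving neighbors inside
    the window (held constant beyond the outermost survivors). Windows with
    zero SD, and samples outside every trial window, are untouched.
    """
    diam = track.diameter_mm.copy()
    n = len(diam)
    for ev in events:
        start, end = trial_window_indices(ev, track.rate_hz)
        if start < 0 or end > n:
            raise ValidationError(
                f"trial {ev.trial_id}: window [{start}, {end}) outside recording of {n} samples"
            )
        win = diam[start:end]
        finite = np.isfinite(win)
        if finite.sum() < 2:
            continue
        mean = win[finite].mean()
        sd = win[finite].std(ddof=0)
        if sd == 0:
            continue
        outlier = finite & (np.abs(win - mean) > sd_k * sd)
        if not outlier.any():
            continue
        survivors = finite & ~outlier
        if not survivors.any():
            win[outlier] = np.nan
        else:
            idx = np.flatnonzero(outlier)
            sidx = np.flatnonzero(survivors)
            win[idx] = np.interp(idx, sidx, win[sidx])
        diam[start:end] = win
    return track.copy_with(diameter_mm=diam)


def run_preprocessing(track: SampleTrack, events: Sequence[TrialEvent],
                      cfg: PreprocessConfig | None = None
                      ) -> tuple[SampleTrack, QualityReport]:
    """Full cleaning chain from the raw-rate track to the analysis-rate track."""
    cfg = cfg or PreprocessConfig()
    track = track.validate()
    masked, report = mask_invalid_samples(track)
    interp = interpolate_short_gaps(masked, cfg.max_interp_gap_s)
    smoothed = savitzky_golay_smooth(interp, cfg.sg_order, cfg.sg_frame_samples)
    down = downsample_track(smoothed, cfg.downsample_factor)
    cleaned = clean_trial_outliers(down, events, cfg.outlier_sd)
    return cleaned, report


def flag_missing_outliers(reports: Sequence[QualityReport],
                          sd_k: float = 3.0) -> list[QualityReport]:
    """Cohort-level data-quality screening.

    A participant whose missing fraction exceeds the cohort mean by more than
    ``sd_k`` cohort SDs is flagged for exclusion. The rule is computed across
    the whole cohort, never per file.
    """
    fracs = np.array([r.missing_fraction for r in reports], dtype=float)
    mean, sd = fracs.mean(), fracs.std(ddof=0)
    out = []
    for r in reports:
        if sd > 0 and r.missing_fraction > mean + sd_k * sd:
            out.append(replace(r, excluded=True,
                               exclusion_reason=f"missing fraction {r.missing_fraction:.3f} "
                                                f"> cohort mean + {sd_k} SD"))
        else:
            out.append(replace(r))
    return out
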