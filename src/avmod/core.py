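"""Trial-aligned spike data model and window/rate primitives.

Time axis convention: 0 s is the onset of the 500-ms static face frame that
precedes the dynamic movie; spike times are stored in seconds on this axis
and may be negative (pre-stimulus). All analysis windows are half-open
``[t_start, t_end)``: a spike exactly at ``t_end`` never counts, a spike
exactly at ``t_start`` always does.

The paradigm modelled here presents each stimulus in three modalities:
``AV`` (full audiovisual movie), ``V`` (silent movie) and ``A``
(vocalization alone, with only a fixation marker on screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import (
    InvalidStimulusError,
    NotApplicableError,
    OutOfEpochError,
    ValidationError,
)

MODALITIES = ("AV", "V", "A")
CALL_TYPES = ("coo", "agonistic-scream", "pant-threat", "bark", "bark-growl")
VISUAL_KINDS = ("natural", "avatar", "disk", "none")
AUDIO_KINDS = ("natural", "broadband-noise", "none")

#: Length of the silent gap appended to the response window after movie offset.
POST_MOVIE_PAD = 0.100
#: Default onset of the dynamic movie after the static frame (paradigm timing).
DEFAULT_MOVIE_ONSET = 0.500
#: Pre-stimulus baseline window, seconds relative to still-frame onset.
BASELINE_START, BASELINE_END = -0.300, 0.0
#: Recorded epoch extends this far beyond the response window in the simulator.
EPOCH_PAD = 0.300
EPOCH_START = -0.500


@dataclass(frozen=True)
class Window:
    """Half-open time interval ``[t_start, t_end)`` in seconds."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(
                f"window end must exceed start, got [{self.t_start}, {self.t_end})"
            )

    @property
    def length(self) -> float:
        return self.t_end - self.t_start

    def count(self, spike_times: np.ndarray) -> int:
        """Number of spikes falling in the window (half-open semantics)."""
        t = np.asarray(spike_times, dtype=float)
        return int(np.searchsorted(t, self.t_end, side="left")
                   - np.searchsorted(t, self.t_start, side="left"))


@dataclass(frozen=True)
class StimulusSpec:
    """One movie stimulus: a vocalizing-face clip with an audio track.

    ``movie_duration`` is the length of the dynamic part only, excluding the
    500-ms static first frame.
    """

    stimulus_id: str
    call_type: str
    movie_duration: float
    visual_kind: str = "natural"
    audio_kind: str = "natural"

    def __post_init__(self) -> None:
        if self.movie_duration <= 0:
            raise InvalidStimulusError(
                f"stimulus {self.stimulus_id!r}: movie_duration must be > 0, "
                f"got {self.movie_duration}"
            )
        if self.call_type not in CALL_TYPES:
            raise InvalidStimulusError(
                f"stimulus {self.stimulus_id!r}: unknown call_type {self.call_type!r}"
            )
        if self.visual_kind not in VISUAL_KINDS:
            raise InvalidStimulusError(
                f"stimulus {self.stimulus_id!r}: unknown visual_kind {self.visual_kind!r}"
            )
        if self.audio_kind not in AUDIO_KINDS:
            raise InvalidStimulusError(
                f"stimulus {self.stimulus_id!r}: unknown audio_kind {self.audio_kind!r}"
            )


@dataclass
class TrialRecord:
    """One stimulus presentation for one neuron.

    ``spike_times`` are seconds relative to still-frame onset, strictly
    ascending. The recorded epoch defaults to the simulator's convention,
    [-0.5 s, movie offset + 0.3 s], which always contains the analysis
    windows.
    """

    neuron_id: str
    session_id: str
    trial_id: int
    stimulus_id: str
    modality: str
    movie_onset: float
    movie_duration: float
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    epoch_start: float | None = None
    epoch_end: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"trial {self.trial_id}: modality must be one of {MODALITIES}, "
                f"got {self.modality!r}"
            )
        if self.movie_onset <= 0:
            raise ValidationError(
                f"trial {self.trial_id}: movie_onset must be > 0, got {self.movie_onset}"
            )
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValidationError(
                f"trial {self.trial_id}: spike_times must be strictly ascending"
            )
        if self.epoch_start is None:
            self.epoch_start = EPOCH_START
        if self.epoch_end is None:
            self.epoch_end = self.movie_onset + self.movie_duration + EPOCH_PAD


def response_window(stimulus: StimulusSpec,
                    movie_onset: float = DEFAULT_MOVIE_ONSET) -> Window:
    """Analysis window for the dynamic period of the movie.

    Runs from movie onset (end of the static frame) to 100 ms after the
    movie's conclusion; the same window is used for all three modalities.
    """
    if movie_onset <= 0:
        raise InvalidStimulusError(f"movie_onset must be > 0, got {movie_onset}")
    if stimulus.movie_duration <= 0:  # defensive; StimulusSpec already enforces
        raise InvalidStimulusError(
            f"stimulus {stimulus.stimulus_id!r}: non-positive duration"
        )
    return Window(movie_onset, movie_onset + stimulus.movie_duration + POST_MOVIE_PAD)


def baseline_window() -> Window:
    """Pre-stimulus baseline window, [-300 ms, 0) before still-frame onset."""
    return Window(BASELINE_START, BASELINE_END)


def still_frame_window(movie_onset: float = DEFAULT_MOVIE_ONSET) -> Window:
    """Window covering the static face frame, [0, movie onset)."""
    return Window(0.0, movie_onset)


def extract_rate(trial: TrialRecord, window: Window) -> float:
    """Firing rate (spikes/s) of one trial in a window: count / length."""
    if window.t_start < trial.epoch_start or window.t_end > trial.epoch_end:
        raise OutOfEpochError(
            f"trial {trial.trial_id}: window [{window.t_start}, {window.t_end}) "
            f"outside recorded epoch [{trial.epoch_start}, {trial.epoch_end}]"
        )
    return window.count(trial.spike_times) / window.length


def still_frame_response(trial: TrialRecord) -> float:
    """Baseline-subtracted rate during the static face frame, [0, movie onset).

    Only defined for trials that present a visual stimulus (AV or V); the
    auditory-only condition shows a fixation marker instead of a face.
    """
    if trial.modality == "A":
        raise NotApplicableError(
            f"trial {trial.trial_id}: still-frame response undefined for "
            "auditory-only trials"
        )
    rate = extract_rate(trial, still_frame_window(trial.movie_onset))
    base = extract_rate(trial, baseline_window())
    return rate - base


def baseline_subtracted_rates(trials: list[TrialRecord],
                              stimuli: dict[str, StimulusSpec]) -> pd.DataFrame:
    """Per-trial window rates with baseline subtraction.

    Returns a long table with one row per trial per window kind
    (``baseline``, ``response``, and ``still_frame`` for AV/V trials).
    ``rate_bs`` is the window rate minus the same trial's baseline rate;
    negative values are retained.
    """
    rows = []
    for tr in trials:
        if tr.stimulus_id not in stimuli:
            raise ValidationError(
                f"trial {tr.trial_id}: unknown stimulus_id {tr.stimulus_id!r}"
            )
        stim = stimuli[tr.stimulus_id]
        base = extract_rate(tr, baseline_window())
        resp = extract_rate(tr, response_window(stim, tr.movie_onset))
        kinds = [("baseline", base), ("response", resp)]
        if tr.modality in ("AV", "V"):
            still = extract_rate(tr, still_frame_window(tr.movie_onset))
            kinds.append(("still_frame", still))
        for kind, rate in kinds:
            rows.append((tr.neuron_id, tr.session_id, tr.trial_id, tr.stimulus_id,
                         tr.modality, kind, rate, rate - base))
    return pd.DataFrame(rows, columns=[
        "neuron_id", "session_id", "trial_id", "stimulus_id", "modality",
        "window_kind", "rate", "rate_bs",
    ])


@dataclass
class SpikeDensity:
    """Gaussian-kernel-smoothed, trial-averaged firing rate on a uniform grid."""

    time_grid: np.ndarray
    rate_estimate: np.ndarray
    kernel_sd: float

    def area(self, t_start: float, t_end: float) -> float:
        """Integral of the rate estimate over [t_start, t_end)."""
        step = self.time_grid[1] - self.time_grid[0]
        mask = (self.time_grid >= t_start) & (self.time_grid < t_end)
        return float(self.rate_estimate[mask].sum() * step)


def spike_density(trials: list[TrialRecord], kernel_sd: float = 0.020,
                  grid_step: float = 0.001,
                  t_start: float | None = None,
                  t_end: float | None = None) -> SpikeDensity:
    """Trial-averaged spike density function (for display, not statistics).

    Spikes from all trials are binned at ``grid_step`` and smoothed with a
    Gaussian kernel of standard deviation ``kernel_sd`` seconds; the result
    is in spikes/second and nonnegative everywhere.
    """
    if not trials:
        raise ValueError("spike_density requires at least one trial")
    if kernel_sd <= 0:
        raise ValueError(f"kernel_sd must be > 0, got {kernel_sd}")
    if t_start is None:
        t_start = min(tr.epoch_start for tr in trials)
    if t_end is None:
        t_end = max(tr.epoch_end for tr in trials)
    edges = np.arange(t_start, t_end + grid_step, grid_step)
    grid = edges[:-1] + grid_step / 2
    all_spikes = np.concatenate([tr.spike_times for tr in trials]) \
        if trials else np.empty(0)
    counts, _ = np.histogram(all_spikes, bins=edges)
    rate = counts / (len(trials) * grid_step)
    smoothed = gaussian_filter1d(rate, sigma=kernel_sd / grid_step, mode="nearest")
    return SpikeDensity(time_grid=grid, rate_estimate=np.maximum(smoothed, 0.0),
                        kernel_sd=kernel_sd)
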