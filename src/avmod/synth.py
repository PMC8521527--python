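"""Synthetic spike-train generator with planted multisensory ground truth.

The generator emulates the recording paradigm end to end: each stimulus is
a movie preceded by a 500-ms static face frame, presented in three
randomly interleaved modalities (audiovisual, visual-only, auditory-only)
with 20-40 repetitions each. Each simulated neuron carries a response
profile — baseline rate, a decaying onset transient to the static face,
per-stimulus visual and auditory drives, and a multiplicative interaction
gain on the visual drive in the audiovisual condition:

    lambda_AV(t) = b + g * rv + ra        (movie epoch)
    lambda_V(t)  = b + rv
    lambda_A(t)  = b + ra                 (no face on screen: no transient)

so g > 1 plants non-linear enhancement, 0 <= g < 1 suppression, and g = 1
with ra > 0 a linear (additive) neuron. Bimodal sub-variants override the
audiovisual movie drive to match one unimodal condition. After baseline
subtraction the expected modulation index of a gain-g neuron with ra = 0
is (g - 1) / (g + 1), which the recovery tests exploit.

Spikes are drawn from the inhomogeneous Poisson process via thinning;
every routine takes an explicit seed and is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    CALL_TYPES, DEFAULT_MOVIE_ONSET, EPOCH_PAD, EPOCH_START,
    StimulusSpec, TrialRecord,
)
from .errors import ConfigError

VARIANTS = ("", "enhancement", "suppression", "bimodal_visual", "bimodal_auditory")

AF_LIKE_MIXTURE = {
    "nonlinear_multisensory": 0.55,
    "linear_multisensory": 0.15,
    "auditory": 0.05,
    "visual": 0.25,
}
AM_LIKE_MIXTURE = {"visual": 0.90, "unresponsive": 0.10}


@dataclass
class ResponseProfile:
    """Ground-truth response model of one simulated neuron."""

    neuron_id: str
    true_class: str
    variant: str = ""
    baseline_rate: float = 5.0
    transient_amp: float = 0.0
    tau: float = 0.1
    visual_drive: dict[str, float] = field(default_factory=dict)
    auditory_drive: dict[str, float] = field(default_factory=dict)
    gain: float = 1.0
    latency: float = 0.0

    def validate(self) -> None:
        """Enforce consistency between the class label and the parameters."""
        rv_any = any(v > 0 for v in self.visual_drive.values())
        ra_any = any(v > 0 for v in self.auditory_drive.values())
        c = self.true_class
        if self.baseline_rate < 0 or self.transient_amp < 0 or self.gain < 0:
            raise ConfigError(f"{self.neuron_id}: negative rate parameter")
        if c == "visual" and (ra_any or self.gain != 1.0):
            raise ConfigError(f"{self.neuron_id}: visual class requires ra=0, g=1")
        if c == "auditory" and rv_any:
            raise ConfigError(f"{self.neuron_id}: auditory class requires rv=0")
        if c == "linear_multisensory" and (self.gain != 1.0 or not ra_any):
            raise ConfigError(
                f"{self.neuron_id}: linear class requires g=1 and some ra>0")
        if c == "nonlinear_multisensory":
            if self.variant == "enhancement" and not self.gain > 1.0:
                raise ConfigError(f"{self.neuron_id}: enhancement requires g>1")
            if self.variant == "suppression" and not 0.0 <= self.gain < 1.0:
                raise ConfigError(f"{self.neuron_id}: suppression requires 0<=g<1")
            if self.variant.startswith("bimodal") and not (ra_any and rv_any):
                raise ConfigError(
                    f"{self.neuron_id}: bimodal requires both drives > 0")
        if c == "unresponsive" and (rv_any or ra_any or self.transient_amp > 0):
            raise ConfigError(f"{self.neuron_id}: unresponsive must have no drives")


@dataclass
class RateFunction:
    """Piecewise intensity lambda(t) for one (profile, stimulus, modality)."""

    baseline: float
    transient_amp: float
    tau: float
    movie_onset: float
    movie_duration: float
    movie_drive: float
    drive_onset: float

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lam = np.full(t.shape, self.baseline)
        if self.transient_amp > 0:
            pre = (t >= 0) & (t < self.movie_onset)
            lam[pre] += self.transient_amp * np.exp(-t[pre] / self.tau)
        movie = (t >= self.drive_onset) & (t < self.movie_onset + self.movie_duration)
        lam[movie] += self.movie_drive
        return np.maximum(lam, 0.0)

    @property
    def lam_max(self) -> float:
        return self.baseline + self.transient_amp + max(self.movie_drive, 0.0)


def rate_function(profile: ResponseProfile, stimulus: StimulusSpec,
                  modality: str,
                  movie_onset: float = DEFAULT_MOVIE_ONSET) -> RateFunction:
    """Intensity function of one condition. See the module docstring for the
    parametric form; the auditory-only condition carries no still-frame
    transient because the subject views only a fixation marker."""
    if modality not in ("AV", "V", "A"):
        raise ValueError(f"unknown modality {modality!r}")
    rv = profile.visual_drive.get(stimulus.stimulus_id, 0.0)
    ra = profile.auditory_drive.get(stimulus.stimulus_id, 0.0)
    if modality == "V":
        drive = rv
    elif modality == "A":
        drive = ra
    elif profile.variant == "bimodal_visual":
        drive = rv
    elif profile.variant == "bimodal_auditory":
        drive = ra
    else:
        drive = profile.gain * rv + ra
    transient = profile.transient_amp if modality in ("AV", "V") else 0.0
    return RateFunction(
        baseline=profile.baseline_rate, transient_amp=transient,
        tau=profile.tau, movie_onset=movie_onset,
        movie_duration=stimulus.movie_duration, movie_drive=drive,
        drive_onset=movie_onset + profile.latency,
    )


def expected_modulation_index(profile: ResponseProfile, stimulus: StimulusSpec,
                              movie_onset: float = DEFAULT_MOVIE_ONSET) -> float:
    """Closed-form expected index of modulation for a planted profile.

    Uses the analytic mean rates over the response window (movie epoch plus
    the 100-ms pad at baseline rate); transients cancel because they end at
    movie onset.
    """
    from .classify import modulation_index
    from .core import POST_MOVIE_PAD

    D = stimulus.movie_duration
    w = D + POST_MOVIE_PAD
    frac = D / w  # drives act on the movie epoch only
    rv = profile.visual_drive.get(stimulus.stimulus_id, 0.0)
    ra = profile.auditory_drive.get(stimulus.stimulus_id, 0.0)
    if profile.variant == "bimodal_visual":
        av_drive = rv
    elif profile.variant == "bimodal_auditory":
        av_drive = ra
    else:
        av_drive = profile.gain * rv + ra
    return modulation_index(av_drive * frac, rv * frac)


def default_paradigm(n_stimuli: int, duration_range: tuple[float, float] = (1.0, 3.0),
                     seed: int = 0, visual_kind: str = "natural",
                     audio_kind: str = "natural") -> list[StimulusSpec]:
    """Stimulus table for a session: durations drawn uniformly, the five
    vocalization call types cycled in order."""
    if n_stimuli < 1:
        raise ConfigError(f"n_stimuli must be >= 1, got {n_stimuli}")
    rng = np.random.default_rng(seed)
    lo, hi = duration_range
    durations = rng.uniform(lo, hi, n_stimuli)
    return [
        StimulusSpec(
            stimulus_id=f"stim{i:02d}",
            call_type=CALL_TYPES[i % len(CALL_TYPES)],
            movie_duration=float(durations[i]),
            visual_kind=visual_kind,
            audio_kind=audio_kind,
        )
        for i in range(n_stimuli)
    ]


def simulate_trials(profile: ResponseProfile, stimuli: list[StimulusSpec],
                    n_reps: int, seed: int,
                    movie_onset: float = DEFAULT_MOVIE_ONSET,
                    session_id: str = "s01", id_offset: int = 0,
                    trial_gain_sd: float = 0.0) -> list[TrialRecord]:
    """Simulate all trials of one neuron via Poisson thinning.

    ``n_reps`` presentations of every stimulus in each of the three
    modalities are generated on the epoch [-0.5 s, movie offset + 0.3 s]
    and randomly interleaved (the assigned ``trial_id`` order is the
    presentation order). ``trial_gain_sd`` optionally applies a log-normal
    multiplicative gain per trial (mean 1) to model excess trial-to-trial
    variability beyond Poisson.
    """
    if n_reps < 1:
        raise ConfigError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)
    blocks: list[tuple[StimulusSpec, str, list[np.ndarray]]] = []
    for stim in stimuli:
        t0 = EPOCH_START
        t1 = movie_onset + stim.movie_duration + EPOCH_PAD
        span = t1 - t0
        for modality in ("AV", "V", "A"):
            lam = rate_function(profile, stim, modality, movie_onset)
            if trial_gain_sd > 0:
                gains = rng.lognormal(-0.5 * trial_gain_sd ** 2, trial_gain_sd,
                                      n_reps)
            else:
                gains = np.ones(n_reps)
            lam_max_tr = lam.lam_max * gains
            counts = rng.poisson(lam_max_tr * span)
            total = int(counts.sum())
            times = rng.uniform(t0, t1, total)
            u = rng.uniform(0.0, 1.0, total)
            trial_idx = np.repeat(np.arange(n_reps), counts)
            keep = (u * lam_max_tr[trial_idx]) < (lam(times) * gains[trial_idx])
            times, trial_idx = times[keep], trial_idx[keep]
            order = np.lexsort((times, trial_idx))
            times, trial_idx = times[order], trial_idx[order]
            bounds = np.cumsum(np.bincount(trial_idx, minlength=n_reps))[:-1]
            blocks.append((stim, modality, np.split(times, bounds)))

    # interleave: one flat list of (stimulus, modality, rep) in random order
    flat = [(stim, modality, spikes)
            for stim, modality, per_rep in blocks for spikes in per_rep]
    rng.shuffle(flat)
    trials = []
    for i, (stim, modality, spikes) in enumerate(flat):
        trials.append(TrialRecord(
            neuron_id=profile.neuron_id, session_id=session_id,
            trial_id=id_offset + i, stimulus_id=stim.stimulus_id,
            modality=modality, movie_onset=movie_onset,
            movie_duration=stim.movie_duration, spike_times=spikes,
        ))
    return trials


@dataclass
class SimConfig:
    """Study-condition parameters of a simulated population.

    Defaults mirror the recorded paradigm: 15 natural vocalization movies,
    30 repetitions per stimulus per modality (within the 20-40 range used
    in the experiments), movie durations 1-3 s after a 500-ms static
    frame. Firing-rate magnitudes (baseline 5 sp/s, visual drives 5-30,
    auditory drives 5-15) are package defaults chosen for realistic
    signal-to-noise, not values estimated from recordings.
    """

    n_neurons: int = 119
    mixture: dict[str, float] = field(
        default_factory=lambda: dict(AF_LIKE_MIXTURE))
    nonlinear_variant_split: dict[str, float] = field(default_factory=lambda: {
        "enhancement": 0.70, "suppression": 0.20,
        "bimodal_visual": 0.05, "bimodal_auditory": 0.05,
    })
    n_stimuli: int = 15
    n_reps: int = 30
    duration_range: tuple[float, float] = (1.0, 3.0)
    movie_onset: float = DEFAULT_MOVIE_ONSET
    baseline_rate: float = 5.0
    rv_range: tuple[float, float] = (5.0, 30.0)
    ra_range: tuple[float, float] = (5.0, 15.0)
    gain_enh_range: tuple[float, float] = (1.5, 2.5)
    gain_sup_range: tuple[float, float] = (0.2, 0.6)
    transient_range: tuple[float, float] = (10.0, 30.0)
    tau: float = 0.1
    trial_gain_sd: float = 0.0
    patch: str = "AF"
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 0:
            raise ConfigError("n_neurons must be >= 0")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        tot = sum(self.mixture.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ConfigError(f"class mixture must sum to 1, got {tot}")
        from .classify import NEURON_CLASSES
        for c in self.mixture:
            if c not in NEURON_CLASSES:
                raise ConfigError(f"unknown class in mixture: {c!r}")
        vtot = sum(self.nonlinear_variant_split.values())
        if not math.isclose(vtot, 1.0, abs_tol=1e-9):
            raise ConfigError("nonlinear_variant_split must sum to 1")


def draw_profile(config: SimConfig, neuron_id: str, true_class: str,
                 rng: np.random.Generator,
                 stimuli: list[StimulusSpec]) -> ResponseProfile:
    """Draw one neuron's response profile for a given class label."""
    sids = [s.stimulus_id for s in stimuli]

    def u(lo_hi):
        return float(rng.uniform(*lo_hi))

    def drives(lo_hi):
        return {sid: u(lo_hi) for sid in sids}

    prof = ResponseProfile(
        neuron_id=neuron_id, true_class=true_class,
        baseline_rate=config.baseline_rate, tau=config.tau,
    )
    if true_class == "unresponsive":
        pass
    elif true_class == "visual":
        prof.visual_drive = drives(config.rv_range)
        prof.transient_amp = u(config.transient_range)
    elif true_class == "auditory":
        prof.auditory_drive = drives(config.ra_range)
    elif true_class == "linear_multisensory":
        prof.visual_drive = drives(config.rv_range)
        prof.auditory_drive = drives(config.ra_range)
        prof.transient_amp = u(config.transient_range)
    elif true_class == "nonlinear_multisensory":
        variants = list(config.nonlinear_variant_split)
        probs = np.array([config.nonlinear_variant_split[v] for v in variants])
        variant = variants[rng.choice(len(variants), p=probs / probs.sum())]
        prof.variant = variant
        prof.visual_drive = drives(config.rv_range)
        prof.transient_amp = u(config.transient_range)
        if variant == "enhancement":
            prof.gain = u(config.gain_enh_range)
        elif variant == "suppression":
            prof.gain = u(config.gain_sup_range)
        else:  # bimodal: responds to each modality alone
            prof.auditory_drive = drives(config.ra_range)
    else:
        raise ConfigError(f"unknown class {true_class!r}")
    prof.validate()
    return prof


def simulate_population(config: SimConfig,
                        stimuli: list[StimulusSpec] | None = None):
    """Simulate a full population dataset with ground-truth labels.

    Returns an :class:`avmod.io.Dataset` whose ``truth`` table records each
    neuron's planted class, sub-variant, gain and mean drives. Pass an
    explicit ``stimuli`` list to share one stimulus table across several
    simulated populations (e.g. two recorded patches).
    """
    from .io import Dataset

    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seed_draw, seed_stim, *seed_neurons = ss.spawn(2 + config.n_neurons)
    rng = np.random.default_rng(seed_draw)
    if stimuli is None:
        stimuli = default_paradigm(
            config.n_stimuli, config.duration_range,
            seed=int(np.random.default_rng(seed_stim).integers(2 ** 31)))

    classes = sorted(config.mixture)
    probs = np.array([config.mixture[c] for c in classes])
    labels = [classes[i] for i in
              rng.choice(len(classes), size=config.n_neurons, p=probs / probs.sum())]

    all_trials: list[TrialRecord] = []
    truth_rows = []
    offset = 0
    for i, cls in enumerate(labels):
        nid = f"{config.patch}_n{i:03d}"
        prof = draw_profile(config, nid, cls, rng, stimuli)
        tr_seed = int(np.random.default_rng(seed_neurons[i]).integers(2 ** 31))
        trials = simulate_trials(
            prof, stimuli, config.n_reps, seed=tr_seed,
            movie_onset=config.movie_onset, id_offset=offset,
            trial_gain_sd=config.trial_gain_sd)
        offset += len(trials)
        all_trials.extend(trials)
        rv = list(prof.visual_drive.values())
        ra = list(prof.auditory_drive.values())
        truth_rows.append({
            "neuron_id": nid, "patch": config.patch, "true_class": cls,
            "variant": prof.variant or "none", "gain": prof.gain,
            "baseline_rate": prof.baseline_rate,
            "transient_amp": prof.transient_amp,
            "mean_rv": float(np.mean(rv)) if rv else 0.0,
            "mean_ra": float(np.mean(ra)) if ra else 0.0,
        })
    truth = pd.DataFrame(truth_rows, columns=[
        "neuron_id", "patch", "true_class", "variant", "gain", "baseline_rate",
        "transient_amp", "mean_rv", "mean_ra"])
    patches = {row["neuron_id"]: config.patch for row in truth_rows}
    return Dataset(trials=all_trials,
                   stimuli={s.stimulus_id: s for s in stimuli},
                   patches=patches, truth=truth)


def af_like_config(seed: int = 0, n_neurons: int = 119, **kw) -> SimConfig:
    """Preset emulating a strongly audiovisually modulated population."""
    return SimConfig(n_neurons=n_neurons, mixture=dict(AF_LIKE_MIXTURE),
                     patch="AF", seed=seed, **kw)


def am_like_config(seed: int = 0, n_neurons: int = 55, **kw) -> SimConfig:
    """Preset emulating a population with no auditory influence."""
    return SimConfig(n_neurons=n_neurons, mixture=dict(AM_LIKE_MIXTURE),
                     patch="AM", seed=seed, **kw)
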