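"""Dataset container, validated CSV readers/writers, and run configuration.

On-disk layout of a dataset directory (UTF-8, comma-separated, header row
mandatory, ``.`` decimal):

- ``trials.csv``  — neuron_id,session_id,trial_id,stimulus_id,modality,
  movie_onset_s,movie_duration_s  (modality is exactly AV, V or A)
- ``spikes.csv``  — trial_id,spike_time_s (long format, seconds relative
  to still-frame onset, strictly ascending within a trial)
- ``stimuli.csv`` — stimulus_id,call_type,movie_duration_s,visual_kind,
  audio_kind
- ``patches.csv`` (optional) — neuron_id,patch; enables the cross-patch
  mixed model
- ``fsi.csv`` (optional) — neuron_id,response_face,response_nonface; mean
  rates to static face / non-face images from a separate fingerprinting set
- ``truth.tsv`` (optional, simulator output) — planted ground-truth labels

All parsers reject unknown modality strings, unresolvable identifiers and
non-monotone spike times with errors naming the file and 1-based data row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MODALITIES, StimulusSpec, TrialRecord
from .errors import ConfigError, ValidationError

TRIALS_COLUMNS = ["neuron_id", "session_id", "trial_id", "stimulus_id",
                  "modality", "movie_onset_s", "movie_duration_s"]
SPIKES_COLUMNS = ["trial_id", "spike_time_s"]
STIMULI_COLUMNS = ["stimulus_id", "call_type", "movie_duration_s",
                   "visual_kind", "audio_kind"]


@dataclass
class Dataset:
    """In-memory, referentially validated dataset."""

    trials: list[TrialRecord]
    stimuli: dict[str, StimulusSpec]
    patches: dict[str, str] | None = None
    fsi: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None

    @property
    def neurons(self) -> list[str]:
        return sorted({t.neuron_id for t in self.trials})

    def by_neuron(self, neuron_id: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.neuron_id == neuron_id]

    def trials_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.neuron_id, t.session_id, t.trial_id, t.stimulus_id, t.modality,
              t.movie_onset, t.movie_duration) for t in self.trials],
            columns=TRIALS_COLUMNS)

    def spikes_frame(self) -> pd.DataFrame:
        ids = np.concatenate([np.full(t.spike_times.size, t.trial_id)
                              for t in self.trials]) if self.trials else np.empty(0, int)
        times = np.concatenate([t.spike_times for t in self.trials]) \
            if self.trials else np.empty(0)
        return pd.DataFrame({"trial_id": ids.astype(int), "spike_time_s": times})

    def stimuli_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stimulus_id, s.call_type, s.movie_duration, s.visual_kind,
              s.audio_kind) for s in self.stimuli.values()],
            columns=STIMULI_COLUMNS)


def write_dataset(ds: Dataset, outdir: str | Path) -> list[Path]:
    """Write the dataset tables; returns the list of files written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in (("trials.csv", ds.trials_frame()),
                        ("spikes.csv", ds.spikes_frame()),
                        ("stimuli.csv", ds.stimuli_frame())):
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)
    if ds.patches is not None:
        path = out / "patches.csv"
        pd.DataFrame(sorted(ds.patches.items()),
                     columns=["neuron_id", "patch"]).to_csv(path, index=False)
        written.append(path)
    if ds.fsi is not None:
        path = out / "fsi.csv"
        ds.fsi.to_csv(path, index=False)
        written.append(path)
    if ds.truth is not None:
        path = out / "truth.tsv"
        ds.truth.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def _require_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{fname}: missing columns {missing}")


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a dataset directory (see module docstring)."""
    d = Path(path)
    for fname in ("trials.csv", "spikes.csv", "stimuli.csv"):
        if not (d / fname).exists():
            raise ValidationError(f"dataset directory {d} is missing {fname}")

    stim_df = pd.read_csv(d / "stimuli.csv")
    _require_columns(stim_df, STIMULI_COLUMNS, "stimuli.csv")
    if stim_df["stimulus_id"].duplicated().any():
        dup = stim_df.loc[stim_df["stimulus_id"].duplicated(), "stimulus_id"]
        raise ValidationError(
            f"stimuli.csv: duplicate stimulus_id at row "
            f"{int(dup.index[0]) + 1}: {dup.iloc[0]!r}")
    stimuli: dict[str, StimulusSpec] = {}
    for i, row in stim_df.iterrows():
        try:
            spec = StimulusSpec(
                stimulus_id=str(row["stimulus_id"]),
                call_type=str(row["call_type"]),
                movie_duration=float(row["movie_duration_s"]),
                visual_kind=str(row["visual_kind"]),
                audio_kind=str(row["audio_kind"]))
        except Exception as e:
            raise ValidationError(f"stimuli.csv row {int(i) + 1}: {e}") from e
        stimuli[spec.stimulus_id] = spec

    tr_df = pd.read_csv(d / "trials.csv")
    _require_columns(tr_df, TRIALS_COLUMNS, "trials.csv")
    bad_mod = ~tr_df["modality"].isin(MODALITIES)
    if bad_mod.any():
        i = int(tr_df.index[bad_mod][0])
        raise ValidationError(
            f"trials.csv row {i + 1}: modality must be one of {MODALITIES}, "
            f"got {tr_df.loc[i, 'modality']!r}")
    if tr_df["trial_id"].duplicated().any():
        i = int(tr_df.index[tr_df['trial_id'].duplicated()][0])
        raise ValidationError(f"trials.csv row {i + 1}: duplicate trial_id "
                              f"{tr_df.loc[i, 'trial_id']}")
    unknown = ~tr_df["stimulus_id"].astype(str).isin(stimuli)
    if unknown.any():
        i = int(tr_df.index[unknown][0])
        raise ValidationError(
            f"trials.csv row {i + 1}: unknown stimulus_id "
            f"{tr_df.loc[i, 'stimulus_id']!r}")

    sp_df = pd.read_csv(d / "spikes.csv")
    _require_columns(sp_df, SPIKES_COLUMNS, "spikes.csv")
    known_trials = set(tr_df["trial_id"].astype(int))
    orphan = ~sp_df["trial_id"].astype(int).isin(known_trials)
    if orphan.any():
        i = int(sp_df.index[orphan][0])
        raise ValidationError(
            f"spikes.csv row {i + 1}: trial_id {sp_df.loc[i, 'trial_id']} "
            "has no matching trial")
    # strictly ascending within trial, in file order
    tid = sp_df["trial_id"].to_numpy(int)
    tt = sp_df["spike_time_s"].to_numpy(float)
    same = tid[1:] == tid[:-1]
    nonmono = same & ~(tt[1:] > tt[:-1])
    if nonmono.any():
        i = int(np.flatnonzero(nonmono)[0]) + 1
        raise ValidationError(
            f"spikes.csv row {i + 1}: spike times for trial {tid[i]} are not "
            "strictly ascending")

    spikes_by_trial: dict[int, np.ndarray] = {
        int(k): g["spike_time_s"].to_numpy(float)
        for k, g in sp_df.groupby("trial_id", sort=False)}
    trials = []
    for i, row in tr_df.iterrows():
        try:
            trials.append(TrialRecord(
                neuron_id=str(row["neuron_id"]),
                session_id=str(row["session_id"]),
                trial_id=int(row["trial_id"]),
                stimulus_id=str(row["stimulus_id"]),
                modality=str(row["modality"]),
                movie_onset=float(row["movie_onset_s"]),
                movie_duration=float(row["movie_duration_s"]),
                spike_times=spikes_by_trial.get(int(row["trial_id"]),
                                                np.empty(0)),
            ))
        except ValidationError as e:
            raise ValidationError(f"trials.csv row {int(i) + 1}: {e}") from e

    patches = None
    if (d / "patches.csv").exists():
        p_df = pd.read_csv(d / "patches.csv")
        _require_columns(p_df, ["neuron_id", "patch"], "patches.csv")
        patches = dict(zip(p_df["neuron_id"].astype(str),
                           p_df["patch"].astype(str)))
    fsi = None
    if (d / "fsi.csv").exists():
        fsi = pd.read_csv(d / "fsi.csv")
        _require_columns(fsi, ["neuron_id", "response_face", "response_nonface"],
                         "fsi.csv")
    truth = None
    if (d / "truth.tsv").exists():
        truth = pd.read_csv(d / "truth.tsv", sep="\t")
    return Dataset(trials=trials, stimuli=stimuli, patches=patches,
                   fsi=fsi, truth=truth)


@dataclass
class RunConfig:
    """Analysis configuration.

    ``alpha_combined`` is the significance level for the combined-stimuli
    classification (0.01 by convention); ``alpha_per_stimulus`` applies to
    each per-stimulus ANOVA. ``mixed_model_unit`` selects the observation
    unit of the cross-patch mixed model: per-neuron condition means
    ("neuron_modality", default) or per neuron x stimulus x condition means
    ("neuron_stimulus_modality").
    """

    alpha_combined: float = 0.01
    alpha_per_stimulus: float = 0.01
    min_trials_per_cell: int = 5
    kernel_sd: float = 0.020
    clip_negative_index: bool = True
    bonferroni: bool = False
    mixed_model_unit: str = "neuron_modality"
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_combined", "alpha_per_stimulus"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {a}")
        if self.min_trials_per_cell < 1:
            raise ConfigError("min_trials_per_cell must be >= 1")
        if self.mixed_model_unit not in ("neuron_modality",
                                         "neuron_stimulus_modality"):
            raise ConfigError(
                f"unknown mixed_model_unit {self.mixed_model_unit!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
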