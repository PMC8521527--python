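"""Analysis orchestration: rates -> ANOVAs -> screening -> classification
-> indices -> population summaries -> cross-patch mixed model.

:func:`analyze` is deterministic given the dataset and configuration; all
outputs can be serialized with :func:`write_results` together with a run
manifest listing input/output checksums and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict, field
from datetime import datetime, timezone
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    MULTISENSORY_CLASSES, PopulationSummary, classify_neuron,
    classify_per_stimulus, collapsed_index, face_selectivity_index,
    modulation_records, population_summary, screen_responsive,
)
from .core import baseline_subtracted_rates
from .errors import AvmodError, DegenerateDesignError
from .io import Dataset, RunConfig
from .stats import MixedModelResult, combined_anova, mixed_model_fit

logger = logging.getLogger(__name__)


@dataclass
class ResultsBundle:
    """All analysis outputs for one dataset."""

    classes: pd.DataFrame            # neuron-level combined classification
    per_stimulus: pd.DataFrame       # neuron x stimulus classification
    indices: pd.DataFrame            # neuron x stimulus modulation records
    collapsed: pd.DataFrame          # neuron-level collapsed index
    summaries: dict[str, PopulationSummary]   # per patch plus "all"
    mixed_model: MixedModelResult | None
    config: RunConfig
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _mixed_model_rows(rates_by_neuron: dict[str, pd.DataFrame],
                     patches: dict[str, str], unit: str) -> pd.DataFrame:
    """Condition-mean rate table feeding the mixed model.

    Each neuron contributes the mean response-window rate of each modality
    (audiovisual, visual-only, auditory-only, coded by presence flags) and
    the mean baseline-window rate as the stimulus-absent cell, averaged
    across stimuli ("neuron_modality") or per stimulus
    ("neuron_stimulus_modality").
    """
    flags = {"AV": (1, 1), "V": (0, 1), "A": (1, 0)}
    rows = []
    for nid, rates in rates_by_neuron.items():
        patch = patches.get(nid)
        if patch is None:
            continue
        resp = rates[rates["window_kind"] == "response"]
        base = rates[rates["window_kind"] == "baseline"]
        if unit == "neuron_modality":
            for mod, g in resp.groupby("modality"):
                aud, vis = flags[str(mod)]
                rows.append((nid, patch, aud, vis, float(g["rate"].mean())))
            rows.append((nid, patch, 0, 0, float(base["rate"].mean())))
        else:
            for (stim, mod), g in resp.groupby(["stimulus_id", "modality"]):
                aud, vis = flags[str(mod)]
                rows.append((nid, patch, aud, vis, float(g["rate"].mean())))
            for stim, g in base.groupby("stimulus_id"):
                rows.append((nid, patch, 0, 0, float(g["rate"].mean())))
    return pd.DataFrame(rows, columns=["neuron_id", "patch", "aud", "vis",
                                       "rate"])


def analyze(ds: Dataset, config: RunConfig | None = None,
            input_paths: list[Path] | None = None) -> ResultsBundle:
    """Run the full single-unit audiovisual analysis on a dataset."""
    config = config or RunConfig()
    config.validate()
    started = datetime.now(timezone.utc).isoformat()

    cls_rows, stim_rows, idx_rows, col_rows = [], [], [], []
    rates_by_neuron: dict[str, pd.DataFrame] = {}
    per_stim_classes: dict[str, dict[str, str]] = {}
    for nid in ds.neurons:
        trials = ds.by_neuron(nid)
        try:
            rates = baseline_subtracted_rates(trials, ds.stimuli)
            rates_by_neuron[nid] = rates
            stim_classes, n_mod, stim_anovas = classify_per_stimulus(
                rates, alpha=config.alpha_per_stimulus,
                min_trials=config.min_trials_per_cell,
                bonferroni=config.bonferroni)
            comb = combined_anova(rates)
        except AvmodError as e:
            raise AvmodError(
                f"stage per-neuron analysis failed for neuron {nid}: {e}") from e
        comb_class = classify_neuron(comb, config.alpha_combined)
        responsive = screen_responsive(stim_anovas, comb, config.alpha_combined)
        per_stim_classes[nid] = stim_classes
        cls_rows.append({
            "neuron_id": nid, "patch": (ds.patches or {}).get(nid, ""),
            "neuron_class": comb_class, "responsive": responsive,
            "n_modulated": n_mod, "F_aud": comb.F_aud, "F_vis": comb.F_vis,
            "F_int": comb.F_int, "p_aud": comb.p_aud, "p_vis": comb.p_vis,
            "p_int": comb.p_int,
        })
        for sid, res in stim_anovas.items():
            stim_rows.append({
                "neuron_id": nid, "stimulus_id": sid,
                "neuron_class": stim_classes[sid],
                "F_aud": res.F_aud, "F_vis": res.F_vis, "F_int": res.F_int,
                "p_aud": res.p_aud, "p_vis": res.p_vis, "p_int": res.p_int,
            })
        mod = modulation_records(rates, clip=config.clip_negative_index)
        mod.insert(0, "neuron_id", nid)
        idx_rows.append(mod)
        col_rows.append({"neuron_id": nid,
                         "collapsed_index": collapsed_index(mod["index"])})

    classes = pd.DataFrame(cls_rows)
    per_stimulus = pd.DataFrame(stim_rows)
    indices = (pd.concat(idx_rows, ignore_index=True) if idx_rows
               else pd.DataFrame(columns=["neuron_id", "stimulus_id", "AV",
                                          "V", "index"]))
    collapsed = pd.DataFrame(col_rows)

    fsi_map: dict[str, float] | None = None
    if ds.fsi is not None:
        fsi_map = {}
        for _, row in ds.fsi.iterrows():
            rec = face_selectivity_index(row["response_face"],
                                         row["response_nonface"],
                                         str(row["neuron_id"]))
            fsi_map[rec.neuron_id] = rec.fsi

    # population summaries over responsive neurons, per patch and overall
    summaries: dict[str, PopulationSummary] = {}
    resp_set = set(classes.loc[classes["responsive"], "neuron_id"])
    excluded = len(classes) - len(resp_set)
    if excluded:
        logger.info("screening excluded %d unresponsive neurons", excluded)
    col_map = dict(zip(collapsed["neuron_id"], collapsed["collapsed_index"]))
    nmod_map = dict(zip(classes["neuron_id"], classes["n_modulated"]))
    groups: dict[str, list[str]] = {"all": [n for n in ds.neurons
                                            if n in resp_set]}
    if ds.patches:
        for nid in ds.neurons:
            if nid in resp_set:
                groups.setdefault(ds.patches.get(nid, ""), []).append(nid)
    for label, nids in groups.items():
        if not nids:
            continue
        cls_map = dict(zip(classes["neuron_id"], classes["neuron_class"]))
        summaries[label] = population_summary(
            classes={n: cls_map[n] for n in nids},
            collapsed={n: col_map[n] for n in nids},
            fsi=fsi_map,
            n_modulated={n: nmod_map[n] for n in nids},
            per_stimulus_classes={n: per_stim_classes[n] for n in nids},
        )

    mixed = None
    patch_labels = sorted(set((ds.patches or {}).values()))
    if len(patch_labels) == 2:
        rows = _mixed_model_rows(rates_by_neuron, ds.patches,
                                 config.mixed_model_unit)
        try:
            mixed = mixed_model_fit(rows)
        except DegenerateDesignError as e:
            logger.warning("mixed model skipped: %s", e)

    manifest: dict = {
        "package": "avmod",
        "version": _pkg_version("avmod"),
        "config": asdict(config),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): _sha256(Path(p)) for p in (input_paths or [])},
        "counts": {
            "neurons": len(ds.neurons),
            "trials": len(ds.trials),
            "responsive_neurons": int(classes["responsive"].sum())
            if len(classes) else 0,
            "excluded_neurons": excluded,
            "per_stimulus_anovas": len(per_stimulus),
        },
    }
    return ResultsBundle(classes=classes, per_stimulus=per_stimulus,
                         indices=indices, collapsed=collapsed,
                         summaries=summaries, mixed_model=mixed,
                         config=config, manifest=manifest)


def write_results(bundle: ResultsBundle, outdir: str | Path) -> list[Path]:
    """Serialize a results bundle; returns the files written.

    The manifest is finalized last and lists a checksum for every other
    output file.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _tsv(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    _tsv("classes.tsv", bundle.classes)
    _tsv("per_stimulus.tsv", bundle.per_stimulus)
    _tsv("indices.tsv", bundle.indices)
    _tsv("collapsed.tsv", bundle.collapsed)
    pop = {label: s.to_dict() for label, s in bundle.summaries.items()}
    pop_path = out / "population.json"
    pop_path.write_text(json.dumps(pop, indent=2, allow_nan=True) + "\n")
    written.append(pop_path)
    if bundle.mixed_model is not None:
        _tsv("mixed_model.tsv", bundle.mixed_model.to_frame())
    manifest = dict(bundle.manifest)
    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2) + "\n")
    written.append(man_path)
    return written


def read_results(resultsdir: str | Path) -> ResultsBundle:
    """Reload a serialized results bundle (as written by write_results).

    Variance components of the mixed model are not stored in the TSV and
    are reloaded as NaN; everything the report needs is recovered.
    """
    from .stats import SpearmanResult, TTestResult

    d = Path(resultsdir)
    for fname in ("classes.tsv", "population.json"):
        if not (d / fname).exists():
            raise AvmodError(f"results directory {d} is missing {fname}")
    classes = pd.read_csv(d / "classes.tsv", sep="\t")
    per_stimulus = (pd.read_csv(d / "per_stimulus.tsv", sep="\t")
                    if (d / "per_stimulus.tsv").exists() else pd.DataFrame())
    indices = (pd.read_csv(d / "indices.tsv", sep="\t")
               if (d / "indices.tsv").exists() else pd.DataFrame())
    collapsed = (pd.read_csv(d / "collapsed.tsv", sep="\t")
                 if (d / "collapsed.tsv").exists() else pd.DataFrame())
    pop = json.loads((d / "population.json").read_text())
    summaries = {}
    for label, s in pop.items():
        t = s.get("index_t")
        sp1 = s.get("spearman_index_vs_fsi")
        sp2 = s.get("spearman_absindex_vs_fsi")
        per_stim = s.get("per_stimulus_proportions")
        summaries[label] = PopulationSummary(
            n_neurons=s["n_neurons"], class_counts=s["class_counts"],
            class_proportions=s["class_proportions"],
            multisensory_proportion=s["multisensory_proportion"],
            median_collapsed_index=(s["median_collapsed_index"]
                                    if s["median_collapsed_index"] is not None
                                    else math.nan),
            index_t_test=TTestResult(**t) if t else None,
            spearman_index_vs_fsi=SpearmanResult(**sp1) if sp1 else None,
            spearman_absindex_vs_fsi=SpearmanResult(**sp2) if sp2 else None,
            n_modulated_histogram={int(k): v for k, v
                                   in s.get("n_modulated_histogram", {}).items()},
            per_stimulus_proportions=(pd.DataFrame(per_stim)
                                      if per_stim is not None else None),
        )
    mixed = None
    if (d / "mixed_model.tsv").exists():
        mm = pd.read_csv(d / "mixed_model.tsv", sep="\t")
        mixed = MixedModelResult(
            terms=list(mm["factor"]), beta=mm["beta"].to_numpy(),
            se=mm["se"].to_numpy(), t=mm["t"].to_numpy(),
            df=int(mm["df"].iloc[0]), p=mm["p"].to_numpy(),
            var_neuron=math.nan, var_resid=math.nan, loglik=math.nan)
    manifest = {}
    if (d / "manifest.json").exists():
        manifest = json.loads((d / "manifest.json").read_text())
    config = RunConfig(**manifest.get("config", {})) if manifest else RunConfig()
    return ResultsBundle(classes=classes, per_stimulus=per_stimulus,
                         indices=indices, collapsed=collapsed,
                         summaries=summaries, mixed_model=mixed,
                         config=config, manifest=manifest)


def _fmt_table(frame: pd.DataFrame, fmt: str) -> str:
    if fmt == "md":
        return frame.to_markdown(index=False, floatfmt=".4f")
    return frame.to_csv(sep="\t", index=False, float_format="%.6g")


def report(bundle: ResultsBundle, fmt: str = "tsv") -> dict[str, str]:
    """Human-readable summary tables.

    Returns named tables: per-stimulus class-proportion rows per patch, a
    histogram of per-neuron collapsed indices, a histogram of the number
    of stimuli with auditory modulation per neuron, and the mixed-model
    coefficient table when two patches are present.
    """
    if fmt not in ("tsv", "md"):
        raise ValueError(f"unknown report format {fmt!r}")
    tables: dict[str, str] = {}

    prop_rows = []
    for label, s in bundle.summaries.items():
        row = {"population": label, "n_neurons": s.n_neurons,
               "multisensory": s.multisensory_proportion}
        row.update(s.class_proportions)
        prop_rows.append(row)
    tables["class_proportions"] = _fmt_table(pd.DataFrame(prop_rows), fmt)

    per_stim = []
    for label, s in bundle.summaries.items():
        if label == "all" or s.per_stimulus_proportions is None:
            continue
        t = s.per_stimulus_proportions.copy()
        t.insert(0, "population", label)
        per_stim.append(t)
    if not per_stim and "all" in bundle.summaries and \
            bundle.summaries["all"].per_stimulus_proportions is not None:
        t = bundle.summaries["all"].per_stimulus_proportions.copy()
        t.insert(0, "population", "all")
        per_stim.append(t)
    tables["per_stimulus_proportions"] = _fmt_table(
        pd.concat(per_stim, ignore_index=True) if per_stim
        else pd.DataFrame(), fmt)

    edges = np.arange(-1.0, 1.05, 0.1)
    hist_rows = []
    col = bundle.collapsed.set_index("neuron_id")["collapsed_index"]
    patch_of = dict(zip(bundle.classes["neuron_id"], bundle.classes["patch"]))
    for label, s in bundle.summaries.items():
        vals = np.asarray([col.get(n, math.nan) for n in col.index
                           if label == "all" or patch_of.get(n, "") == label])
        vals = vals[np.isfinite(vals)]
        counts, _ = np.histogram(vals, bins=edges)
        for lo, c in zip(edges[:-1], counts):
            hist_rows.append({"population": label, "bin_left": round(lo, 1),
                              "count": int(c)})
    tables["index_histogram"] = _fmt_table(pd.DataFrame(hist_rows), fmt)

    nm_rows = []
    for label, s in bundle.summaries.items():
        for k, c in sorted(s.n_modulated_histogram.items()):
            nm_rows.append({"population": label, "n_stimuli_modulated": k,
                            "n_neurons": c})
    tables["modulation_count_histogram"] = _fmt_table(
        pd.DataFrame(nm_rows, columns=["population", "n_stimuli_modulated",
                                       "n_neurons"]), fmt)

    if bundle.mixed_model is not None:
        tables["mixed_model"] = _fmt_table(bundle.mixed_model.to_frame(), fmt)
    return tables
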