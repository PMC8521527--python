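"""Neuron taxonomy, modulation and face-selectivity indices, and
population summaries.

Classification follows the factorial logic: a neuron is *non-linear
multisensory* if the auditory x visual interaction is significant,
*linear multisensory* if both main effects (but not the interaction) are,
*visual* or *auditory* if only the corresponding main effect is, and
*unresponsive* otherwise. The interaction takes precedence, so the five
labels are exhaustive and mutually exclusive.

The index of modulation, (AV - V) / (AV + V) on baseline-subtracted mean
rates, quantifies how the auditory component changes the visual response:
+1 is pure enhancement, -1 pure suppression, 0 no auditory effect.
The face-selectivity index (FSI) applies the same contrast formula to
mean responses to face versus non-face images; |FSI| > 1/3 is the
conventional face-selective criterion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import (
    AnovaResult, SpearmanResult, TTestResult, anova_observations,
    one_sample_t, spearman_rho, two_way_anova,
)
from .errors import DegenerateDesignError

logger = logging.getLogger(__name__)

NEURON_CLASSES = (
    "unresponsive", "visual", "auditory",
    "linear_multisensory", "nonlinear_multisensory",
)
#: Classes that show any influence of the auditory component.
MULTISENSORY_CLASSES = frozenset(
    {"auditory", "linear_multisensory", "nonlinear_multisensory"})

#: Face-selectivity criterion (strict inequality on |FSI|); the
#: conventional one-third cut, so a 2:1 face:non-face response ratio
#: (FSI exactly 1/3) is not face-selective.
FSI_THRESHOLD = 1.0 / 3.0


def classify_neuron(result: AnovaResult, alpha: float = 0.01) -> str:
    """Map a factorial ANOVA to one of the five taxonomy labels."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    sig_int = result.p_int < alpha
    sig_aud = result.p_aud < alpha
    sig_vis = result.p_vis < alpha
    if sig_int:
        return "nonlinear_multisensory"
    if sig_aud and sig_vis:
        return "linear_multisensory"
    if sig_vis:
        return "visual"
    if sig_aud:
        return "auditory"
    return "unresponsive"


def modulation_index(av: float, v: float, clip: bool = True) -> float:
    """Index of modulation (AV - V) / (AV + V) on baseline-subtracted means.

    Negative means are clipped to zero before the ratio so the index stays
    in [-1, 1]; if the clipped sum is zero the index is undefined and NaN
    is returned (never an exception). With ``clip=False`` the raw ratio is
    returned and may fall outside [-1, 1] when a mean is negative.
    """
    av_c = max(float(av), 0.0) if clip else float(av)
    v_c = max(float(v), 0.0) if clip else float(v)
    denom = av_c + v_c
    if denom <= 0.0:
        return math.nan
    return (av_c - v_c) / denom


def collapsed_index(indices) -> float:
    """Per-neuron summary: arithmetic mean of the defined per-stimulus indices."""
    arr = np.asarray(list(indices), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return math.nan
    return float(arr.mean())


@dataclass(frozen=True)
class FSIRecord:
    neuron_id: str
    response_face: float
    response_nonface: float
    fsi: float
    face_selective: bool


def face_selectivity_index(response_face: float, response_nonface: float,
                           neuron_id: str = "") -> FSIRecord:
    """FSI = (face - nonface) / (face + nonface); selective iff |FSI| > 0.333.

    Negative mean rates are clipped to zero (as for the modulation index);
    if both clipped responses are zero the FSI is undefined (NaN, not
    selective). The criterion is a strict inequality, so FSI = 1/3 exactly
    is not face-selective.
    """
    f = max(float(response_face), 0.0)
    nf = max(float(response_nonface), 0.0)
    denom = f + nf
    if denom <= 0.0:
        return FSIRecord(neuron_id, f, nf, math.nan, False)
    fsi = (f - nf) / denom
    return FSIRecord(neuron_id, f, nf, fsi, abs(fsi) > FSI_THRESHOLD)


def classify_per_stimulus(rates: pd.DataFrame, alpha: float = 0.01,
                          min_trials: int = 5, bonferroni: bool = False,
                          ) -> tuple[dict[str, str], int, dict[str, AnovaResult]]:
    """Run the factorial ANOVA separately for each stimulus of one neuron.

    Parameters
    ----------
    rates : DataFrame
        Per-trial rate table of a single neuron (output of
        :func:`avmod.core.baseline_subtracted_rates`).
    min_trials : int
        Minimum response trials required per modality per stimulus; a
        stimulus below the minimum is skipped with a logged warning.
    bonferroni : bool
        If True, divide alpha by the number of analyzed stimuli.

    Returns ``(classes, n_modulated, anovas)`` where ``n_modulated`` counts
    stimuli classed auditory, linear_multisensory or nonlinear_multisensory.
    """
    classes: dict[str, str] = {}
    anovas: dict[str, AnovaResult] = {}
    groups = dict(list(rates.groupby("stimulus_id")))
    usable = []
    for stim_id, g in groups.items():
        resp = g[g["window_kind"] == "response"]
        counts = resp.groupby("modality").size()
        if any(counts.get(m, 0) < min_trials for m in ("AV", "V", "A")):
            logger.warning(
                "stimulus %s skipped: fewer than %d trials in some condition "
                "(counts: %s)", stim_id, min_trials, dict(counts))
            continue
        usable.append(stim_id)
    eff_alpha = alpha / len(usable) if (bonferroni and usable) else alpha
    for stim_id in usable:
        y, aud, vis = anova_observations(groups[stim_id])
        res = two_way_anova(y, aud, vis)
        anovas[stim_id] = res
        classes[stim_id] = classify_neuron(res, eff_alpha)
    n_modulated = sum(1 for c in classes.values() if c in MULTISENSORY_CLASSES)
    return classes, n_modulated, anovas


def modulation_records(rates: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
    """Per-stimulus AV and V baseline-subtracted mean rates and the index.

    One row per stimulus of one neuron, columns ``stimulus_id``, ``AV``,
    ``V`` (mean response-window ``rate_bs`` per modality) and ``index``.
    """
    resp = rates[rates["window_kind"] == "response"]
    rows = []
    for stim_id, g in resp.groupby("stimulus_id"):
        means = g.groupby("modality")["rate_bs"].mean()
        av = float(means.get("AV", math.nan))
        v = float(means.get("V", math.nan))
        idx = modulation_index(av, v, clip=clip) \
            if np.isfinite(av) and np.isfinite(v) else math.nan
        rows.append((stim_id, av, v, idx))
    return pd.DataFrame(rows, columns=["stimulus_id", "AV", "V", "index"])


def screen_responsive(per_stimulus: Mapping[str, AnovaResult],
                      combined: AnovaResult | None,
                      alpha: float = 0.01) -> bool:
    """A neuron is responsive if any ANOVA term anywhere is significant.

    Mirrors the screening that excluded neurons unresponsive to every
    experimental stimulus before further analysis.
    """
    results = list(per_stimulus.values())
    if combined is not None:
        results.append(combined)
    if not results:
        raise ValueError("screen_responsive needs at least one ANOVA result")
    return any(p < alpha for r in results for p in r.p_values().values())


@dataclass
class PopulationSummary:
    """Counts, proportions and index statistics over a classified population."""

    n_neurons: int
    class_counts: dict[str, int]
    class_proportions: dict[str, float]
    multisensory_proportion: float
    median_collapsed_index: float
    index_t_test: TTestResult | None
    spearman_index_vs_fsi: SpearmanResult | None
    spearman_absindex_vs_fsi: SpearmanResult | None
    n_modulated_histogram: dict[int, int] = field(default_factory=dict)
    per_stimulus_proportions: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        def _none(x):
            return None if x is None else x

        d = {
            "n_neurons": self.n_neurons,
            "class_counts": self.class_counts,
            "class_proportions": self.class_proportions,
            "multisensory_proportion": self.multisensory_proportion,
            "median_collapsed_index": self.median_collapsed_index,
            "index_t": _none(self.index_t_test and {
                "t": self.index_t_test.t, "df": self.index_t_test.df,
                "p": self.index_t_test.p}),
            "spearman_index_vs_fsi": _none(self.spearman_index_vs_fsi and {
                "rho": self.spearman_index_vs_fsi.rho,
                "p": self.spearman_index_vs_fsi.p}),
            "spearman_absindex_vs_fsi": _none(self.spearman_absindex_vs_fsi and {
                "rho": self.spearman_absindex_vs_fsi.rho,
                "p": self.spearman_absindex_vs_fsi.p}),
            "n_modulated_histogram": {str(k): v for k, v
                                      in sorted(self.n_modulated_histogram.items())},
        }
        if self.per_stimulus_proportions is not None:
            d["per_stimulus_proportions"] = (
                self.per_stimulus_proportions.to_dict(orient="list"))
        return d


def population_summary(classes: Mapping[str, str],
                       collapsed: Mapping[str, float],
                       fsi: Mapping[str, float] | None = None,
                       n_modulated: Mapping[str, int] | None = None,
                       per_stimulus_classes: Mapping[str, Mapping[str, str]] | None = None,
                       ) -> PopulationSummary:
    """Aggregate per-neuron classifications and indices into a population table.

    ``classes`` maps neuron -> combined-ANOVA taxonomy label; ``collapsed``
    maps neuron -> mean per-stimulus modulation index (NaN allowed);
    ``fsi`` maps neuron -> face selectivity index. The Spearman correlation
    of modulation against FSI is reported for both the signed index and its
    magnitude.
    """
    if not classes:
        raise ValueError("population_summary needs at least one classified neuron")
    n = len(classes)
    counts = {c: 0 for c in NEURON_CLASSES}
    for lab in classes.values():
        counts[lab] += 1
    props = {c: counts[c] / n for c in NEURON_CLASSES}
    multi = sum(counts[c] for c in MULTISENSORY_CLASSES) / n

    idx = np.asarray([collapsed.get(nid, math.nan) for nid in classes], float)
    defined = idx[np.isfinite(idx)]
    median = float(np.median(defined)) if defined.size else math.nan
    try:
        t_res = one_sample_t(defined, 0.0) if defined.size >= 2 else None
    except DegenerateDesignError:
        t_res = None

    sp_signed = sp_abs = None
    if fsi is not None:
        pairs = [(collapsed.get(nid, math.nan), fsi.get(nid, math.nan))
                 for nid in classes]
        arr = np.asarray(pairs, float)
        ok = np.all(np.isfinite(arr), axis=1)
        if ok.sum() >= 3:
            try:
                sp_signed = spearman_rho(arr[ok, 0], arr[ok, 1])
                sp_abs = spearman_rho(np.abs(arr[ok, 0]), arr[ok, 1])
            except DegenerateDesignError:
                sp_signed = sp_abs = None

    hist: dict[int, int] = {}
    if n_modulated is not None:
        for nid in classes:
            k = int(n_modulated.get(nid, 0))
            if k >= 1:
                hist[k] = hist.get(k, 0) + 1

    per_stim = None
    if per_stimulus_classes:
        stim_ids = sorted({s for m in per_stimulus_classes.values() for s in m})
        rows = []
        for sid in stim_ids:
            labs = [m[sid] for m in per_stimulus_classes.values() if sid in m]
            tot = len(labs)
            row = {"stimulus_id": sid, "n_neurons": tot}
            for c in NEURON_CLASSES:
                row[c] = sum(1 for x in labs if x == c) / tot if tot else math.nan
            row["multisensory"] = (sum(1 for x in labs if x in MULTISENSORY_CLASSES)
                                   / tot if tot else math.nan)
            rows.append(row)
        per_stim = pd.DataFrame(rows)

    return PopulationSummary(
        n_neurons=n, class_counts=counts, class_proportions=props,
        multisensory_proportion=multi, median_collapsed_index=median,
        index_t_test=t_res, spearman_index_vs_fsi=sp_signed,
        spearman_absindex_vs_fsi=sp_abs, n_modulated_histogram=hist,
        per_stimulus_proportions=per_stim,
    )
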