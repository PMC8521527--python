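"""Neuron taxonomy, index formulas and population summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import avmod
from avmod.classify import (
    classify_neuron, classify_per_stimulus, collapsed_index,
    face_selectivity_index, modulation_index, modulation_records,
    population_summary, screen_responsive,
)
from avmod.core import baseline_subtracted_rates
from avmod.stats import AnovaResult
from avmod.synth import ResponseProfile, default_paradigm, simulate_trials


def anova(p_aud=0.5, p_vis=0.5, p_int=0.5):
    return AnovaResult(F_aud=1, F_vis=1, F_int=1, p_aud=p_aud, p_vis=p_vis,
                       p_int=p_int, df_num=1, df_den=50)


class TestClassifyNeuron:
    @pytest.mark.parametrize("p_aud,p_vis,p_int,expected", [
        # enhancement phenotype: no auditory main effect, strong interaction
        (0.3401, 1e-5, 1e-5, "nonlinear_multisensory"),
        (1e-4, 1e-4, 0.4, "linear_multisensory"),
        (0.5, 1e-4, 0.4, "visual"),
        (1e-4, 0.5, 0.4, "auditory"),
        (0.5, 0.5, 0.5, "unresponsive"),
        # interaction dominates even when both mains are significant
        (1e-4, 1e-4, 1e-4, "nonlinear_multisensory"),
    ])
    def test_taxonomy(self, p_aud, p_vis, p_int, expected):
        res = anova(p_aud, p_vis, p_int)
        assert classify_neuron(res, alpha=0.01) == expected

    def test_taxonomy_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            res = anova(*rng.uniform(0, 1, 3))
            assert classify_neuron(res) in avmod.NEURON_CLASSES

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            classify_neuron(anova(), alpha=1.5)


class TestModulationIndex:
    @pytest.mark.parametrize("av,v,expected", [
        (10.0, 10.0, 0.0),
        (10.0, 0.0, 1.0),
        (0.0, 10.0, -1.0),
        (15.0, 5.0, 0.5),
    ])
    def test_identities(self, av, v, expected):
        assert modulation_index(av, v) == pytest.approx(expected)

    def test_undefined_when_both_nonpositive(self):
        assert math.isnan(modulation_index(0.0, 0.0))
        assert math.isnan(modulation_index(-2.0, -3.0))  # clipped to 0

    def test_negative_rates_clipped(self):
        assert modulation_index(-5.0, 10.0) == -1.0
        assert modulation_index(10.0, -5.0) == 1.0

    def test_clip_disabled_returns_raw_ratio(self):
        assert modulation_index(10.0, -5.0, clip=False) == pytest.approx(3.0)

    @given(av=st.floats(min_value=0.01, max_value=100),
           v=st.floats(min_value=0.01, max_value=100),
           c=st.floats(min_value=0.1, max_value=10))
    def test_antisymmetry_and_scale_invariance(self, av, v, c):
        assert modulation_index(av, v) == pytest.approx(
            -modulation_index(v, av))
        assert modulation_index(c * av, c * v) == pytest.approx(
            modulation_index(av, v), abs=1e-9)

    def test_index_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            idx = modulation_index(*rng.uniform(-5, 30, 2))
            assert math.isnan(idx) or -1.0 <= idx <= 1.0


class TestCollapsedIndex:
    def test_mean_of_defined(self):
        assert collapsed_index([0.2, 0.4]) == pytest.approx(0.3)
        assert collapsed_index([0.7]) == pytest.approx(0.7)
        assert collapsed_index([0.2, math.nan, 0.4]) == pytest.approx(0.3)

    def test_all_undefined_gives_nan(self):
        assert math.isnan(collapsed_index([math.nan, math.nan]))
        assert math.isnan(collapsed_index([]))


class TestFSI:
    def test_equal_responses_not_selective(self):
        rec = face_selectivity_index(5.0, 5.0)
        assert rec.fsi == 0.0 and not rec.face_selective

    def test_boundary_third_is_not_selective(self):
        # strict '>' criterion: FSI of exactly 1/3 is not face-selective
        rec = face_selectivity_index(2.0, 1.0)
        assert rec.fsi == pytest.approx(1 / 3)
        assert not rec.face_selective
        assert face_selectivity_index(2.01, 1.0).face_selective

    def test_pure_face_response(self):
        rec = face_selectivity_index(1.0, 0.0)
        assert rec.fsi == 1.0 and rec.face_selective

    def test_both_zero_undefined(self):
        rec = face_selectivity_index(0.0, 0.0)
        assert math.isnan(rec.fsi) and not rec.face_selective

    @given(f=st.floats(min_value=0.01, max_value=50),
           nf=st.floats(min_value=0.01, max_value=50),
           c=st.floats(min_value=0.1, max_value=10))
    def test_scale_invariance(self, f, nf, c):
        assert face_selectivity_index(c * f, c * nf).fsi == pytest.approx(
            face_selectivity_index(f, nf).fsi, abs=1e-9)


def neuron_rates(profile, stimuli, n_reps=30, seed=0):
    trials = simulate_trials(profile, stimuli, n_reps, seed=seed)
    return baseline_subtracted_rates(trials, {s.stimulus_id: s for s in stimuli})


class TestPerStimulusClassification:
    def test_single_modulated_stimulus_counted(self):
        stimuli = default_paradigm(6, seed=1)
        prof = ResponseProfile(
            "n0", "linear_multisensory", baseline_rate=5.0, transient_amp=15.0,
            visual_drive={s.stimulus_id: 20.0 for s in stimuli},
            auditory_drive={stimuli[0].stimulus_id: 14.0})
        prof.validate()
        rates = neuron_rates(prof, stimuli, n_reps=30, seed=21)
        classes, n_mod, _ = classify_per_stimulus(rates, alpha=0.01)
        assert n_mod == 1
        assert classes[stimuli[0].stimulus_id] == "linear_multisensory"
        assert all(c == "visual" for s, c in classes.items()
                   if s != stimuli[0].stimulus_id)

    def test_purely_visual_neuron_never_modulated(self):
        stimuli = default_paradigm(4, seed=2)
        prof = ResponseProfile(
            "n0", "visual", baseline_rate=5.0, transient_amp=15.0,
            visual_drive={s.stimulus_id: 20.0 for s in stimuli})
        rates = neuron_rates(prof, stimuli, n_reps=25, seed=5)
        classes, n_mod, _ = classify_per_stimulus(rates, alpha=0.01)
        assert n_mod == 0
        assert set(classes.values()) == {"visual"}

    def test_insufficient_trials_skipped(self):
        stimuli = default_paradigm(2, seed=3)
        prof = ResponseProfile(
            "n0", "visual", baseline_rate=5.0,
            visual_drive={s.stimulus_id: 15.0 for s in stimuli})
        rates = neuron_rates(prof, stimuli, n_reps=3, seed=5)
        classes, n_mod, anovas = classify_per_stimulus(rates, min_trials=5)
        assert classes == {} and n_mod == 0 and anovas == {}


class TestScreening:
    def test_all_null_excluded(self):
        per_stim = {"s0": anova(), "s1": anova()}
        assert not screen_responsive(per_stim, anova(), alpha=0.01)

    def test_single_significant_term_included(self):
        per_stim = {"s0": anova(), "s1": anova(p_vis=1e-4)}
        assert screen_responsive(per_stim, anova(), alpha=0.01)
        assert screen_responsive({}, anova(p_int=1e-3), alpha=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            screen_responsive({}, None)


class TestPopulationSummary:
    def test_all_visual_population(self):
        classes = {f"n{i}": "visual" for i in range(5)}
        collapsed = {f"n{i}": 0.01 * i for i in range(5)}
        s = population_summary(classes, collapsed)
        assert s.multisensory_proportion == 0.0
        assert sum(s.class_proportions.values()) == pytest.approx(1.0)
        assert s.n_modulated_histogram == {}

    def test_histogram_counts_multisensory_neurons(self):
        classes = {"a": "nonlinear_multisensory", "b": "linear_multisensory",
                   "c": "visual"}
        s = population_summary(
            classes, {k: 0.1 for k in classes},
            n_modulated={"a": 3, "b": 1, "c": 0})
        assert sum(s.n_modulated_histogram.values()) == 2
        assert s.n_modulated_histogram == {1: 1, 3: 1}

    def test_spearman_computed_when_fsi_given(self):
        rng = np.random.default_rng(0)
        classes = {f"n{i}": "visual" for i in range(20)}
        collapsed = {k: float(rng.normal()) for k in classes}
        fsi = {k: float(rng.uniform(-1, 1)) for k in classes}
        s = population_summary(classes, collapsed, fsi=fsi)
        assert s.spearman_index_vs_fsi is not None
        assert -1 <= s.spearman_index_vs_fsi.rho <= 1
        assert s.spearman_absindex_vs_fsi is not None

    def test_enhancement_population_has_positive_index(self):
        # strongly enhanced neurons: median index > 0 and t-test significant
        stimuli = default_paradigm(3, seed=4)
        classes, collapsed = {}, {}
        for i in range(12):
            prof = ResponseProfile(
                f"n{i}", "nonlinear_multisensory", variant="enhancement",
                baseline_rate=5.0, gain=2.0,
                visual_drive={s.stimulus_id: 20.0 for s in stimuli})
            rates = neuron_rates(prof, stimuli, n_reps=25, seed=100 + i)
            classes[f"n{i}"] = "nonlinear_multisensory"
            collapsed[f"n{i}"] = collapsed_index(
                modulation_records(rates)["index"])
        s = population_summary(classes, collapsed)
        assert s.median_collapsed_index > 0.15
        assert s.index_t_test.p < 0.01
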