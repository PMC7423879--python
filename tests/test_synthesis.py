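"""Stimulus trajectories, trace simulation, rendering, cohort structure."""

import numpy as np
import pytest

from oculodx import synthesis
from oculodx.synthesis import (CLASS_LABELS, DEFAULT_TRACE_MODELS,
                               CohortConfig, StimulusScheme, TraceModel,
                               generate_cohort, generate_stimulus,
                               render_frame, simulate_trace)


class TestStimulus:
    def test_sweep_starts_at_left_edge_centered(self):
        stim = generate_stimulus(StimulusScheme("horizontal_sweep"))
        assert stim.shape == (250, 2)
        assert stim[0, 0] == 0.0 and stim[0, 1] == 0.5

    def test_sweep_is_periodic(self):
        scheme = StimulusScheme("horizontal_sweep", sweep_period=100)
        stim = generate_stimulus(scheme)
        assert stim[100, 0] == stim[0, 0]
        np.testing.assert_array_equal(stim[:100], stim[100:200])

    @pytest.mark.parametrize("scheme_id", ["horizontal_sweep", "zigzag"])
    def test_screen_containment(self, scheme_id):
        stim = generate_stimulus(StimulusScheme(scheme_id))
        assert np.all(stim >= 0.0) and np.all(stim <= 1.0)

    def test_zigzag_ordinate_visits_both_apexes(self):
        stim = generate_stimulus(StimulusScheme("zigzag"))
        assert stim[:, 1].min() == pytest.approx(0.25, abs=0.02)
        assert stim[:, 1].max() == pytest.approx(0.75, abs=0.02)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme_id"):
            StimulusScheme("circular_sweep")


class TestSimulateTrace:
    def test_noiseless_unit_gain_is_identity(self):
        stim = generate_stimulus(StimulusScheme("zigzag"))
        model = TraceModel("C1", tracking_gain=1.0, latency=0, noise_sd=0.0,
                           pupil_area_jitter_sd=0.0)
        trace = simulate_trace(stim, model, seed=0)
        np.testing.assert_array_equal(trace.parameter("x"), stim[:, 0])
        np.testing.assert_array_equal(trace.parameter("y"), stim[:, 1])

    def test_same_seed_bitwise_identical(self):
        stim = generate_stimulus(StimulusScheme("horizontal_sweep"))
        model = DEFAULT_TRACE_MODELS["C2"]
        t1 = simulate_trace(stim, model, seed=42)
        t2 = simulate_trace(stim, model, seed=42)
        assert t1.data.equals(t2.data)

    def test_latency_delays_the_trace(self):
        stim = generate_stimulus(StimulusScheme("horizontal_sweep"))
        model = TraceModel("C1", latency=5, noise_sd=0.0,
                           pupil_area_jitter_sd=0.0)
        trace = simulate_trace(stim, model, seed=0)
        np.testing.assert_allclose(trace.parameter("x")[5:], stim[:-5, 0])

    def test_nystagmus_increases_deviation_from_stimulus(self):
        """Monte-Carlo: vertigo-model traces deviate more than healthy ones."""
        stim = generate_stimulus(StimulusScheme("horizontal_sweep"))
        healthy = TraceModel("C1", latency=0, noise_sd=0.01)
        vertigo = TraceModel("C3", latency=0, noise_sd=0.01,
                             nystagmus_amplitude=0.05, nystagmus_freq=3.0)
        mad = {m.class_label: [] for m in (healthy, vertigo)}
        for seed in range(100):
            for m in (healthy, vertigo):
                tr = simulate_trace(stim, m, seed=seed)
                mad[m.class_label].append(
                    np.abs(tr.parameter("x") - stim[:, 0]).mean())
        assert np.mean(mad["C3"]) > np.mean(mad["C1"])

    def test_invalid_model_parameters_rejected(self):
        with pytest.raises(ValueError):
            TraceModel("C1", tracking_gain=0.0)
        with pytest.raises(ValueError):
            TraceModel("C1", noise_sd=np.nan)
        with pytest.raises(ValueError):
            TraceModel("C1", latency=-1)


class TestRenderFrame:
    def test_circle_pixel_membership_matches_lattice_count(self):
        img = render_frame((120, 100), (20, 20), 0.0, (240, 320))
        rows, cols = np.mgrid[0:240, 0:320]
        inside = (rows - 120) ** 2 + (cols - 100) ** 2 <= 400
        np.testing.assert_array_equal(img == 20, inside)

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError, match="semi-axes"):
            render_frame((120, 100), (0, 0))

    @pytest.mark.parametrize("angle", [0.0, 17.0, 45.0, 133.0])
    def test_circle_rotation_invariant(self, angle):
        base = render_frame((120, 100), (20, 20), 0.0)
        rotated = render_frame((120, 100), (20, 20), angle)
        np.testing.assert_array_equal(base, rotated)

    def test_out_of_bounds_ellipse_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            render_frame((5, 100), (20, 20))


class TestCohort:
    def test_default_cohort_is_96_subjects_in_3_groups(self, default_cohort):
        assert len(default_cohort.subjects) == 96
        for g in (1, 2, 3):
            assert len(default_cohort.group(g)) == 32

    def test_group_class_composition(self, default_cohort):
        for g in (1, 2, 3):
            labels = [s.class_label for s in default_cohort.group(g)]
            assert [labels.count(c) for c in CLASS_LABELS] == [12, 8, 12]

    def test_each_subject_has_both_schemes(self, default_cohort):
        for s in default_cohort.subjects:
            assert set(s.traces) == {"horizontal_sweep", "zigzag"}
            assert all(len(t) == 250 for t in s.traces.values())

    def test_seed_changes_values_not_structure(self, default_cohort):
        other = generate_cohort(seed=99)
        assert [s.subject_id for s in other.subjects] == \
            [s.subject_id for s in default_cohort.subjects]
        assert [s.class_label for s in other.subjects] == \
            [s.class_label for s in default_cohort.subjects]
        a = default_cohort.subjects[0].traces["zigzag"].parameter("x")
        b = other.subjects[0].traces["zigzag"].parameter("x")
        assert not np.array_equal(a, b)

    def test_invalid_class_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(class_counts=(12, 0, 12)), seed=0)

    def test_csv_roundtrip(self, default_cohort):
        traces = synthesis.cohort_to_frame(default_cohort)
        labels = synthesis.cohort_labels(default_cohort)
        back = synthesis.cohort_from_frames(traces, labels)
        assert len(back.subjects) == 96
        s0 = default_cohort.subjects[0]
        b0 = next(s for s in back.subjects if s.subject_id == s0.subject_id)
        assert b0.class_label == s0.class_label and b0.group == s0.group
        np.testing.assert_allclose(
            b0.traces["zigzag"].parameter("x"),
            s0.traces["zigzag"].parameter("x"))


def test_raw_traces_carry_class_signal():
    """Nearest-centroid on raw traces beats chance: the downstream pipeline
    has signal to find."""
    scheme = StimulusScheme("horizontal_sweep")
    stim = generate_stimulus(scheme)
    train, test = [], []
    for li, label in enumerate(CLASS_LABELS):
        model = DEFAULT_TRACE_MODELS[label]
        for seed in range(30):
            vec = simulate_trace(stim, model, seed=(li, seed)).parameter("x")
            (train if seed < 15 else test).append((vec, li))
    cents = [np.mean([v for v, l in train if l == li], axis=0)
             for li in range(3)]
    correct = sum(
        int(np.argmin([np.linalg.norm(v - c) for c in cents]) == l)
        for v, l in test)
    assert correct / len(test) > 1 / 3


def test_trace_model_seed_streams_are_scheme_independent(default_cohort):
    s = default_cohort.subjects[0]
    a = s.traces["horizontal_sweep"].parameter("x")
    b = s.traces["zigzag"].parameter("x")
    assert not np.array_equal(a, b)
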