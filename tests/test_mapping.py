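"""Feature-to-parameter mappings and parameter combinations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sts_sonify.features import FeatureFrames
from sts_sonify.mapping import (
    COMBOS,
    MappingSpec,
    ScaleSpec,
    apply_transfer,
    combo_filter,
    d_to_note,
    default_mapping_specs,
    features_to_controls,
    freeze_to_bell,
    jerk_to_multiplier,
    speed_to_pressure,
)


@pytest.fixture()
def specs_map():
    return default_mapping_specs()


class TestApplyTransfer:
    def test_lower_bound_maps_to_range_min(self, specs_map):
        assert apply_transfer(0.0, specs_map["S"]) == pytest.approx(0.0)

    def test_upper_bound_maps_to_range_max(self, specs_map):
        s = specs_map["S"]
        assert apply_transfer(s.feature_bounds[1], s) == pytest.approx(1.0)

    def test_power_law_midpoint(self):
        spec = MappingSpec("x", "y", (0.0, 1.0), "+", 0.45,
                           feature_bounds=(0.0, 1.0))
        assert apply_transfer(0.5, spec) == pytest.approx(0.5 ** 0.45,
                                                          abs=1e-4)
        assert apply_transfer(0.5, spec) == pytest.approx(0.7320, abs=1e-4)

    def test_negative_polarity_inverts(self):
        spec = MappingSpec("x", "y", (0.0, 1.0), "-", 1.0)
        assert apply_transfer(0.0, spec) == pytest.approx(1.0)
        assert apply_transfer(1.0, spec) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.lists(st.floats(-2, 3), min_size=2, max_size=20),
           order=st.sampled_from([0.45, 0.75, 1.0]),
           polarity=st.sampled_from(["+", "-"]))
    def test_monotone_in_feature_value(self, x, order, polarity):
        spec = MappingSpec("x", "y", (0.0, 1.0), polarity, order)
        xs = np.sort(np.asarray(x))
        out = apply_transfer(xs, spec)
        d = np.diff(out)
        assert np.all(d >= -1e-12) if polarity == "+" else np.all(d <= 1e-12)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            MappingSpec("x", "y", (1.0, 0.0))
        with pytest.raises(ValueError):
            MappingSpec("x", "y", (0.0, 1.0), order=-1)


class TestSpeedToPressure:
    def test_zero_speed_is_near_silence(self, specs_map):
        p = speed_to_pressure(np.zeros(300), specs_map["S"], fs=100)
        assert np.all(p <= 1e-3)

    def test_upper_bound_reaches_full_pressure(self, specs_map):
        hi = specs_map["S"].feature_bounds[1]
        p = speed_to_pressure(np.full(300, hi), specs_map["S"], fs=100)
        assert p[-1] == pytest.approx(1.0, abs=1e-6)

    def test_one_pole_step_response_time_constant(self, specs_map):
        """Step to full speed: 63% of final value after ~1/(2 pi 6 Hz)."""
        fs = 1000.0
        hi = specs_map["S"].feature_bounds[1]
        x = np.concatenate([np.zeros(1), np.full(1000, hi)])
        p = speed_to_pressure(x, specs_map["S"], fs=fs)
        tau = 1.0 / (2 * np.pi * 6.0)  # ~26.5 ms
        i_tau = int(round(tau * fs))
        assert p[i_tau] == pytest.approx(1 - np.exp(-1), abs=0.02)


class TestDToNote:
    def test_sitting_maps_to_tonic(self, specs_map):
        notes, freqs = d_to_note(np.array([1.0]), specs_map["P"])
        assert notes[0] == 0
        assert freqs[0] == pytest.approx(440.0)

    def test_standing_maps_to_octave(self, specs_map):
        notes, freqs = d_to_note(np.array([0.0]), specs_map["P"])
        assert notes[0] == 7
        assert freqs[0] == pytest.approx(880.0)

    def test_beyond_sit_clips_to_lowest_note(self, specs_map):
        notes, _ = d_to_note(np.array([1.4]), specs_map["P"])
        assert notes[0] == 0

    def test_linear_descent_emits_ascending_scale_once_each(self, specs_map):
        d = np.linspace(1.0, 0.0, 2000)
        notes, freqs = d_to_note(d, specs_map["P"])
        assert np.all(np.diff(notes) >= 0)  # ascending melody
        transitions = notes[np.concatenate([[True], np.diff(notes) > 0])]
        np.testing.assert_array_equal(transitions, np.arange(8))
        scale = ScaleSpec().frequencies
        np.testing.assert_allclose(np.unique(freqs), scale)

    def test_major_scale_frequencies(self):
        scale = ScaleSpec()
        np.testing.assert_allclose(
            scale.frequencies,
            440.0 * 2.0 ** (np.array([0, 2, 4, 5, 7, 9, 11, 12]) / 12.0))

    def test_hysteresis_prevents_note_chatter(self, specs_map):
        """d hovering exactly at a note boundary with small sway yields at
        most one note change, not per-sample flapping."""
        spec = specs_map["P"]
        # place v right at the note-3/4 boundary and add tiny sway
        v_target = 4 / 8
        d_boundary = 1.0 - v_target ** (1 / 0.75)
        t = np.arange(400)
        d = d_boundary + 0.004 * np.sin(2 * np.pi * t / 40)
        notes, _ = d_to_note(d, spec)
        assert np.sum(np.abs(np.diff(notes)) > 0) <= 1

    def test_descending_notes_allowed_on_sitback(self, specs_map):
        d = np.concatenate([np.linspace(1, .4, 300), np.linspace(.4, 1, 300)])
        notes, _ = d_to_note(d, specs_map["P"])
        assert notes.max() > notes[-1]  # melody came back down


class TestJerkToMultiplier:
    def test_below_threshold_is_unity(self, specs_map):
        j = np.full(200, 0.5 * specs_map["J"].feature_bounds[0])
        m = jerk_to_multiplier(j, specs_map["J"], fs=100)
        np.testing.assert_allclose(m, 1.0, atol=1e-9)

    def test_ceiling_saturates_at_ten(self, specs_map):
        j = np.full(400, 2 * specs_map["J"].feature_bounds[1])
        m = jerk_to_multiplier(j, specs_map["J"], fs=100)
        assert m[-1] == pytest.approx(10.0, abs=1e-3)

    def test_half_overshoot_scalar_oracle(self):
        spec = MappingSpec("jerk", "pitch_multiplier", (1.0, 10.0), "+",
                           0.45, smoothing_fc=None,
                           feature_bounds=(100.0, 300.0))
        m = jerk_to_multiplier(np.array([200.0]), spec, fs=100)
        assert m[0] == pytest.approx(1 + 9 * 0.5 ** 0.45, abs=1e-4)
        assert m[0] == pytest.approx(7.5884, abs=1e-3)


class TestFreezeToBell:
    def test_one_trigger_per_event(self):
        assert len(freeze_to_bell(np.array([4.2]))) == 1
        assert len(freeze_to_bell(np.array([1.0, 2.0, 3.0, 6.0]))) == 4

    def test_empty_event_list(self):
        assert len(freeze_to_bell(np.array([]))) == 0


def _frames(n=400, fs=100.0, rng=None):
    rng = rng or np.random.default_rng(0)
    t = np.arange(n) / fs
    return FeatureFrames(
        fs=fs, t=t,
        com_speed=np.abs(rng.normal(0.2, 0.1, n)),
        d=np.clip(np.linspace(1.1, -0.05, n), None, None),
        freeze_times=np.array([1.2, 3.0]),
        jerk=np.abs(rng.normal(15000, 20000, n)),
        jerk_crossings=np.array([2.0]),
    )


class TestComboFilter:
    def test_s_only_neutralizes_everything_else(self):
        ctrl = features_to_controls(_frames(), combo="S")
        assert np.all(ctrl.note_index == 0)
        assert np.all(ctrl.pitch_multiplier == 1.0)
        assert len(ctrl.bell_times) == 0

    def test_full_combo_is_identity(self):
        full = features_to_controls(_frames(), combo="SJPF")
        again = combo_filter(full, "SJPF")
        np.testing.assert_array_equal(full.note_index, again.note_index)
        np.testing.assert_array_equal(full.pitch_multiplier,
                                      again.pitch_multiplier)
        np.testing.assert_array_equal(full.bell_times, again.bell_times)

    def test_sp_vs_sjpf_differ_only_in_flexible_channels(self):
        f = _frames()
        sp = features_to_controls(f, combo="SP")
        full = features_to_controls(f, combo="SJPF")
        np.testing.assert_array_equal(sp.pressure, full.pressure)
        np.testing.assert_array_equal(sp.note_index, full.note_index)
        assert len(sp.bell_times) == 0 and len(full.bell_times) == 2
        assert not np.array_equal(sp.pitch_multiplier, full.pitch_multiplier)

    def test_unknown_combo_rejected(self):
        with pytest.raises(ValueError, match="combo"):
            combo_filter(features_to_controls(_frames()), "PJ")

    @pytest.mark.parametrize("combo", COMBOS)
    def test_emitted_parameters_respect_ranges(self, combo, rng):
        """Hard post-condition: pressure in [0,1], multiplier in [1,10],
        note frequency in [440, 880] Hz for every combination."""
        ctrl = features_to_controls(_frames(rng=rng), combo=combo)
        ctrl.validate()

    def test_control_stream_deterministic(self):
        a = features_to_controls(_frames())
        b = features_to_controls(_frames())
        np.testing.assert_array_equal(a.pressure, b.pressure)
        np.testing.assert_array_equal(a.note_freq, b.note_freq)
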