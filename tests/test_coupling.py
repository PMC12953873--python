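import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from choirsync import coupling as cpl
from choirsync.design import tiny_design


def tone_trace(freq, duration=400.0, fs=10.0, phase=0.0, singer="s"):
    t = np.arange(0, duration, 1 / fs)
    return cpl.RespirationTrace(
        singer=singer, samples=np.sin(2 * np.pi * freq * t + phase), sampling_rate=fs
    )


class TestClip:
    def test_clip_long_trace(self):
        tr = tone_trace(0.25, duration=400)
        out = cpl.clip_trace(tr, 360)
        assert len(out.samples) == 3600

    def test_clip_exact_is_identity(self):
        tr = tone_trace(0.25, duration=360)
        assert cpl.clip_trace(tr, 360) is tr

    def test_clip_short_trace_names_trial(self):
        tr = cpl.RespirationTrace(
            singer="tenor_1", samples=np.zeros(100), sampling_rate=10,
            block=3, condition="touch",
        )
        with pytest.raises(ValueError, match="tenor_1"):
            cpl.clip_trace(tr, 360)


class TestMorletPhases:
    def test_pure_tone_phase_ramp(self):
        """Unwrapped phase of a pure tone advances 2*pi*f per second (<1% error)."""
        spec = cpl.WaveletSpec()
        for f in (0.05, 0.25):
            tr = tone_trace(f, duration=600)
            wp = cpl.morlet_phases(tr, spec)
            k = int(np.argmin(np.abs(spec.frequencies - f)))
            ph = np.unwrap(wp.phases[wp.valid[:, k], k])
            slope = np.polyfit(np.arange(len(ph)) / tr.sampling_rate, ph, 1)[0]
            assert abs(slope - 2 * np.pi * f) / (2 * np.pi * f) < 0.01

    def test_identical_traces_zero_difference(self):
        tr = tone_trace(0.1)
        series = cpl.phase_differences(cpl.morlet_phases(tr), cpl.morlet_phases(tr))
        assert np.allclose(series.dphi[series.valid], 0.0)

    def test_quarter_period_delay_gives_half_pi(self):
        f = 0.2
        tau = 1 / f / 4
        a = tone_trace(f, duration=600)
        b = cpl.RespirationTrace(
            singer="b",
            samples=np.sin(2 * np.pi * f * (np.arange(0, 600, 0.1) - tau)),
            sampling_rate=10,
        )
        spec = cpl.WaveletSpec()
        series = cpl.phase_differences(cpl.morlet_phases(a, spec), cpl.morlet_phases(b, spec))
        k = int(np.argmin(np.abs(spec.frequencies - f)))
        d, v = series.at(k)
        assert abs(np.median(d[v]) - np.pi / 2) < 0.02

    def test_subnyquist_sampling_rejected(self):
        tr = cpl.RespirationTrace(singer="s", samples=np.zeros(100), sampling_rate=0.5)
        with pytest.raises(ValueError, match="Nyquist"):
            cpl.morlet_phases(tr)

    def test_mismatched_inputs_rejected(self):
        a = cpl.morlet_phases(tone_trace(0.1, duration=100))
        b = cpl.morlet_phases(tone_trace(0.1, duration=200))
        with pytest.raises(ValueError):
            cpl.phase_differences(a, b)

    def test_coi_masks_more_at_lower_frequencies(self):
        wp = cpl.morlet_phases(tone_trace(0.1, duration=400))
        n_valid = wp.valid.sum(axis=0)
        assert np.all(np.diff(n_valid) >= 0)  # higher frequency, shorter cone
        assert n_valid[0] < n_valid[-1]  # 0.025 Hz masks most


class TestWrap:
    def test_wrapping_convention_half_open(self):
        eps = 1e-6
        assert cpl.wrap_phase(np.pi) == pytest.approx(np.pi)
        assert cpl.wrap_phase(-np.pi) == pytest.approx(np.pi)
        assert cpl.wrap_phase(np.pi + eps) == pytest.approx(-np.pi + eps)

    @given(st.floats(-50, 50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_wrap_into_interval(self, x):
        w = cpl.wrap_phase(np.array([x]))[0]
        assert -np.pi < w <= np.pi + 1e-12
        assert np.isclose(np.exp(1j * w), np.exp(1j * x), atol=1e-9)


class TestIndices:
    def test_aci_trivial_values(self):
        assert cpl.aci(np.zeros(10)) == 1.0
        assert cpl.aci(np.tile([np.pi / 2, -np.pi / 2], 5)) == 0.0
        assert cpl.aci(np.array([np.pi / 4])) == 1.0  # closed boundary

    def test_psi_trivial_values(self):
        assert cpl.psi(np.full(7, 1.234)) == pytest.approx(1.0)
        assert cpl.psi(np.tile([0.0, np.pi], 6)) == pytest.approx(0.0, abs=1e-12)

    def test_ici_positive_window_only(self):
        assert cpl.ici(np.full(5, np.pi / 8)) == 1.0
        assert cpl.ici(np.full(5, -np.pi / 8)) == 0.0
        assert cpl.aci(np.full(5, -np.pi / 8)) == 1.0  # asymmetry vs ACI

    def test_empty_valid_set_raises(self):
        for f in (cpl.aci, cpl.psi, cpl.ici):
            with pytest.raises(ValueError):
                f(np.array([1.0]), valid=np.array([False]))

    @given(
        st.lists(st.floats(-np.pi + 1e-9, np.pi), min_size=1, max_size=50)
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_indices_bounded_and_consistent(self, vals):
        d = np.array(vals)
        a, p, i_ab = cpl.aci(d), cpl.psi(d), cpl.ici(d)
        i_ba = cpl.ici(cpl.wrap_phase(-d))
        for v in (a, p, i_ab, i_ba):
            assert 0.0 <= v <= 1.0
        # ACI symmetric under swap; ICI halves never exceed the ACI
        assert cpl.aci(cpl.wrap_phase(-d)) == pytest.approx(a)
        assert i_ab + i_ba <= a + 1e-12

    def test_brute_force_oracle_equivalence(self, rng):
        """Vectorized indices match explicit loops bit-exactly."""
        d = rng.uniform(-np.pi, np.pi, 500)
        n_aci = sum(1 for x in d if abs(x) <= np.pi / 4) / len(d)
        n_ici = sum(1 for x in d if 0 < x <= np.pi / 4) / len(d)
        re = sum(np.cos(x) for x in d) / len(d)
        im = sum(np.sin(x) for x in d) / len(d)
        assert cpl.aci(d) == n_aci
        assert cpl.ici(d) == n_ici
        assert cpl.psi(d) == pytest.approx(np.hypot(re, im), abs=1e-12)


class TestAggregation:
    def test_constant_values_propagate(self):
        d = tiny_design(n_voices=2)
        rows = [
            {"singer_a": a, "singer_b": b, "frequency_hz": f,
             "ACI": 0.5, "PSI": 0.5, "ICI": 0.5, "ICI_ba": 0.5}
            for a, b in itertools.combinations(d.singers, 2)
            for f in (0.1, 0.2)
        ]
        res = cpl.aggregate_coupling(pd.DataFrame(rows), d, "ACI")
        assert all(v == pytest.approx(0.5) for v in res.singer_means.values())
        assert all(v == pytest.approx(0.5) for v in res.voice_means.values())

    def test_three_singer_toy_hand_computed(self):
        from choirsync.design import Piece, StudyDesign

        d = StudyDesign(
            voices=("a", "b", "c"), conditions=("x",),
            pieces=(Piece("p", "u", {"a": 1, "b": 1, "c": 1}),), blocks=("u",),
            singers_per_voice=1,
        )
        vals = {("a_1", "b_1"): 0.2, ("a_1", "c_1"): 0.4, ("b_1", "c_1"): 0.6}
        rows = [
            {"singer_a": k[0], "singer_b": k[1], "frequency_hz": 0.1,
             "ACI": v, "PSI": v, "ICI": v, "ICI_ba": v}
            for k, v in vals.items()
        ]
        res = cpl.aggregate_coupling(pd.DataFrame(rows), d, "ACI")
        assert res.singer_means == pytest.approx(
            {"a_1": 0.3, "b_1": 0.4, "c_1": 0.5}
        )

    def test_missing_pair_listed(self):
        d = tiny_design(n_voices=2)
        pairs = list(itertools.combinations(d.singers, 2))[:-1]  # drop one
        rows = [
            {"singer_a": a, "singer_b": b, "frequency_hz": 0.1,
             "ACI": 0.5, "PSI": 0.5, "ICI": 0.5, "ICI_ba": 0.5}
            for a, b in pairs
        ]
        with pytest.raises(ValueError, match="missing singer pairs"):
            cpl.aggregate_coupling(pd.DataFrame(rows), d, "ACI")

    def test_band_partition_membership(self):
        spec = cpl.WaveletSpec()
        bands = [cpl.band_of_frequency(f) for f in spec.frequencies]
        assert bands[0] == "very_low"
        assert bands[-1] == "high"
        assert "low" in bands


class TestIndexCorrelations:
    def test_identical_columns_give_r_one(self):
        x = np.linspace(0.1, 0.9, 20)
        tab = pd.DataFrame({"ACI": x, "PSI": x, "ICI": x})
        out = cpl.index_correlations(tab)
        assert np.allclose(out["r"], 1.0)

    def test_independent_columns_near_zero(self, rng):
        tab = pd.DataFrame(rng.uniform(size=(2000, 3)), columns=["ACI", "PSI", "ICI"])
        out = cpl.index_correlations(tab)
        assert np.all(np.abs(out["r"]) < 0.1)

    def test_too_few_rows_rejected(self):
        tab = pd.DataFrame({"ACI": [0.1, 0.2], "PSI": [0.1, 0.2], "ICI": [0.1, 0.2]})
        with pytest.raises(ValueError):
            cpl.index_correlations(tab)
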