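"""Time-course quantitation: onset, autofluorescence, profiles, growth fits."""

import numpy as np
import pytest

from thromboprofile import profiling, synth
from thromboprofile.barcode import DIMENSIONS
from thromboprofile.profiling import (
    GrowthFit,
    OnsetNotDetected,
    TimeCourseSet,
    correct_autofluorescence,
    detect_onset,
    fit_growth,
    quantify_profile,
    residue_size,
)


def _noiseless_tcs(profile, coeff=0.0, t_half=200.0, tau_g=68.0):
    acq = synth.AcquisitionSpec(
        noise_cv=0.0, autofluorescence_coeff=coeff, baseline_noise_sd=0.0
    )
    df = synth.simulate_timecourses(profile, acq, seed=0, t_half=t_half, tau_g=tau_g)
    return TimeCourseSet.from_frame(df)


class TestAutofluorescence:
    def test_exact_leak_cancels_to_zero(self):
        platelet = np.array([0.0, 10.0, 100.0, 500.0])
        raw = 0.3 * platelet
        assert np.allclose(correct_autofluorescence(raw, platelet, 0.3), 0.0)

    def test_zero_coefficient_is_identity(self, rng):
        raw = rng.uniform(0, 100, 50)
        platelet = rng.uniform(0, 100, 50)
        assert np.array_equal(correct_autofluorescence(raw, platelet, 0.0), raw)

    def test_never_negative(self):
        out = correct_autofluorescence([1.0, 2.0], [100.0, 100.0], 0.5)
        assert np.all(out >= 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correct_autofluorescence([1.0], [1.0, 2.0], 0.1)

    def test_round_trip_recovers_injected_enrichment(self, noiseless_design):
        """Correcting a synthetic leak recovers the generator's enrichment."""
        profile = synth.generate_study(noiseless_design, seed=0).iloc[0]
        tc = _noiseless_tcs(profile, coeff=0.15)
        platelet = tc.channels["platelet"]
        corrected = correct_autofluorescence(tc.channels["fg"], platelet, 0.15)
        grown = platelet > 0
        assert np.allclose(corrected[grown] / platelet[grown], profile["fg"])


class TestOnset:
    def test_zero_noise_onset_within_one_frame(self, noiseless_design):
        profile = synth.generate_study(noiseless_design, seed=0).iloc[0]
        tc = _noiseless_tcs(profile)
        onset = detect_onset(tc.channels["platelet"], tc.times)
        assert abs(onset - 30.0) <= 5.0  # one frame

    def test_flat_trace_raises(self):
        t = np.arange(0, 100, 5.0)
        with pytest.raises(OnsetNotDetected):
            detect_onset(np.zeros_like(t), t)

    def test_shift_equivariance(self, noiseless_design):
        profile = synth.generate_study(noiseless_design, seed=0).iloc[0]
        tc = _noiseless_tcs(profile)
        y = tc.channels["platelet"]
        k = 4
        shifted = np.concatenate([np.zeros(k), y[:-k]])
        t = tc.times
        assert detect_onset(shifted, t) == pytest.approx(
            detect_onset(y, t) + k * (t[1] - t[0])
        )


class TestQuantifyProfile:
    def test_simple_ratio(self):
        t = np.arange(0, 600.0, 5.0)
        platelet = np.where(t >= 30, 100.0, 0.0)
        channels = {"platelet": platelet}
        for dim in DIMENSIONS[1:]:
            channels[dim] = 0.5 * platelet
        tc = TimeCourseSet(times=t, channels=channels)
        prof = quantify_profile(tc, onset=30.0)
        assert prof.size == pytest.approx(100.0)
        assert prof.fg == pytest.approx(0.5)

    def test_round_trip_recovers_true_profile(self, noiseless_design):
        profile = synth.generate_study(noiseless_design, seed=0).iloc[0]
        tc = _noiseless_tcs(profile, coeff=0.15)
        prof = quantify_profile(tc, autofluorescence_coeff=0.15)
        true_vals = profile[list(DIMENSIONS)].to_numpy(dtype=float)
        got = prof.as_array()
        # size is read on the rising logistic, slightly below the plateau A
        assert got[0] == pytest.approx(true_vals[0], rel=0.05)
        assert np.allclose(got[1:], true_vals[1:], rtol=1e-9)

    def test_scale_equivariance(self, noiseless_design):
        profile = synth.generate_study(noiseless_design, seed=0).iloc[0]
        tc = _noiseless_tcs(profile)
        scaled = TimeCourseSet(
            times=tc.times, channels={k: 3.0 * v for k, v in tc.channels.items()}
        )
        a = quantify_profile(tc)
        b = quantify_profile(scaled)
        assert b.size == pytest.approx(3.0 * a.size)
        assert np.allclose(b.as_array()[1:], a.as_array()[1:])

    def test_zero_size_signals_failed_formation(self):
        t = np.arange(0, 600.0, 5.0)
        # brief blip so onset is detectable, then nothing at readout
        platelet = np.where((t >= 30) & (t < 60), 5.0, 0.0)
        channels = {"platelet": platelet}
        for dim in DIMENSIONS[1:]:
            channels[dim] = np.zeros_like(t)
        tc = TimeCourseSet(times=t, channels=channels)
        with pytest.raises(profiling.FailedThrombusFormation):
            quantify_profile(tc, onset=30.0)

    def test_missing_channel_rejected(self):
        t = np.arange(0, 600.0, 5.0)
        tc = TimeCourseSet(times=t, channels={"platelet": np.ones_like(t)})
        with pytest.raises(ValueError, match="missing channels"):
            quantify_profile(tc, onset=0.0)

    def test_readout_beyond_trace_rejected(self, noiseless_design):
        profile = synth.generate_study(noiseless_design, seed=0).iloc[0]
        tc = _noiseless_tcs(profile)
        with pytest.raises(ValueError, match="beyond trace end"):
            quantify_profile(tc, read_offset=10_000.0)

    def test_no_material_bias_at_default_noise(self, default_design):
        """Measured enrichments recover the truth to first order in noise.

        A ratio of noisy channels carries a second-order Jensen bias of
        order cv²; the check allows that while excluding any material bias.
        """
        design = synth.StudyDesign(baseline_cv=(0.0,) * 7)
        profile = synth.generate_study(design, seed=0).iloc[0]
        acq = synth.AcquisitionSpec(baseline_noise_sd=0.0)
        errs = []
        for seed in range(200):
            df = synth.simulate_timecourses(profile, acq, seed=seed)
            tc = TimeCourseSet.from_frame(df)
            prof = quantify_profile(
                tc, autofluorescence_coeff=acq.autofluorescence_coeff
            )
            errs.append(prof.fg - profile["fg"])
        errs = np.asarray(errs)
        se = errs.std(ddof=1) / np.sqrt(len(errs))
        assert abs(errs.mean()) < max(2 * se, 0.01 * profile["fg"])


class TestGrowthFit:
    def test_noiseless_self_fit_recovers_parameters(self):
        t = np.arange(0, 600.0, 5.0)
        y = 1000.0 / (1.0 + np.exp(-(t - 200.0) / 50.0))
        fit = fit_growth(y, t, onset=0.0)
        assert fit.plateau == pytest.approx(1000.0, rel=1e-3)
        assert fit.t_half == pytest.approx(200.0, rel=1e-3)
        assert fit.slope_scale == pytest.approx(50.0, rel=1e-3)

    def test_plateau_time_definition(self):
        fit = GrowthFit(plateau=1.0, t_half=200.0, slope_scale=50.0, onset=0.0, rmse=0.0)
        assert fit.plateau_time == pytest.approx(200.0 + 2.944 * 50.0)

    def test_healthy_and_hypertensive_plateau_times(self, noiseless_design):
        """Generator configs are recovered: ~400 s healthy, ~500 s hypertensive."""
        profile = synth.generate_study(noiseless_design, seed=0).iloc[0]
        for (t_half, tau), expected in [
            (synth.HEALTHY_GROWTH, 400.0),
            (synth.HYPERTENSIVE_GROWTH, 500.0),
        ]:
            acq = synth.AcquisitionSpec(
                noise_cv=0.0, autofluorescence_coeff=0.0,
                baseline_noise_sd=0.0, duration=900.0,
            )
            df = synth.simulate_timecourses(
                profile, acq, seed=0, t_half=t_half, tau_g=tau
            )
            tc = TimeCourseSet.from_frame(df)
            fit = fit_growth(tc.channels["platelet"], tc.times)
            assert fit.plateau_time == pytest.approx(expected, abs=20.0)

    def test_constant_trace_rejected(self):
        t = np.arange(0, 600.0, 5.0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_growth(np.full_like(t, 100.0), t, onset=0.0)


class TestResidueSize:
    @pytest.mark.parametrize(
        "treated,control,expected", [(50.0, 50.0, 100.0), (0.0, 50.0, 0.0), (25.0, 50.0, 50.0)]
    )
    def test_percent_of_control(self, treated, control, expected):
        assert residue_size(treated, control) == pytest.approx(expected)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            residue_size(10.0, 0.0)

    def test_ic50_midpoint_via_generator(self, noiseless_design):
        """Inhibitor at its IC50 (floor 0, slope 1) leaves 50% residue."""
        from thromboprofile.barcode import Barcode

        spec = synth.InhibitorSpec(
            name="x", ic50=2.0, effect_barcode=Barcode.from_string("-000000")
        )
        profile = synth.generate_study(noiseless_design, seed=0).iloc[0]
        true_vals = profile[list(DIMENSIONS)].to_numpy(dtype=float)
        treated = synth.apply_inhibitor(true_vals, spec, 2.0)
        assert residue_size(treated[0], true_vals[0]) == pytest.approx(50.0)
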