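"""The synthetic study generator: cohort structure, time courses, kinetics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from thromboprofile import synth
from thromboprofile.barcode import DIMENSIONS
from oracles import catch_slip_peak_force


class TestGenerateStudy:
    def test_default_design_has_69_subjects(self, default_design):
        df = synth.generate_study(default_design, seed=0)
        assert len(df) == 69
        counts = df["cohort"].value_counts()
        assert counts["healthy_young"] == 33
        assert counts["healthy_older"] == 14
        assert counts["htn_young"] == 9
        assert counts["htn_older"] == 13

    def test_zero_noise_unit_multipliers_reproduce_baseline(self):
        design = synth.StudyDesign(
            baseline_cv=(0.0,) * 7,
            effect_multipliers={"hypertension": (1.0,) * 7, "aging": (1.0,) * 7},
        )
        df = synth.generate_study(design, seed=5)
        for i, dim in enumerate(DIMENSIONS):
            assert np.allclose(df[dim], design.baseline_profile[i])

    def test_fixed_seed_bit_identical(self, default_design):
        a = synth.generate_study(default_design, seed=42)
        b = synth.generate_study(default_design, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = synth.generate_study(default_design, seed=43)
        assert not a[list(DIMENSIONS)].equals(c[list(DIMENSIONS)])

    def test_cohort_effects_multiply_baseline(self, default_design):
        df = synth.generate_study(
            synth.StudyDesign(baseline_cv=(0.0,) * 7), seed=0
        )
        hy = df[df.cohort == "healthy_young"].iloc[0]
        ho = df[df.cohort == "healthy_older"].iloc[0]
        hto = df[df.cohort == "htn_older"].iloc[0]
        mult = default_design.effect_multipliers["aging"]
        for i, dim in enumerate(DIMENSIONS):
            assert ho[dim] == pytest.approx(hy[dim] * mult[i])
            assert hto[dim] == pytest.approx(hy[dim] * mult[i] ** 2)

    def test_subject_noise_is_mean_one_lognormal(self, default_design):
        """Sample mean of healthy-young size is unbiased for the baseline."""
        sizes = []
        for seed in range(200):
            df = synth.generate_study(default_design, seed=seed)
            sizes.append(df[df.cohort == "healthy_young"]["size"].mean())
        sizes = np.asarray(sizes)
        se = sizes.std(ddof=1) / np.sqrt(len(sizes))
        assert abs(sizes.mean() - 1000.0) < 3 * se

    def test_mfi_eplus_elevated_only_in_hypertension(self, default_design):
        df = synth.generate_study(default_design, seed=7)
        htn = df[df.cohort.str.startswith("htn")]
        healthy = df[~df.cohort.str.startswith("htn")]
        assert htn["mfi_eplus_aiibb3"].mean() > 1.5 * healthy["mfi_eplus_aiibb3"].mean()
        assert htn["mfi_act_aiibb3"].mean() == pytest.approx(
            healthy["mfi_act_aiibb3"].mean(), rel=0.2
        )

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ValueError, match="unknown cohort"):
            synth.StudyDesign(cohort_sizes={"martian": 5})

    def test_lognormal_marginal_distribution(self, default_design):
        """Generated sizes follow the stated log-normal family (KS at 1%)."""
        df = pd.concat(
            synth.generate_study(default_design, seed=s) for s in range(150)
        )
        x = np.log(df[df.cohort == "healthy_young"]["size"].to_numpy())
        sigma = np.sqrt(np.log1p(0.25**2))
        mu = np.log(1000.0) - 0.5 * sigma**2
        p = st.kstest(x, "norm", args=(mu, sigma)).pvalue
        assert p > 0.01


class TestTimecourses:
    def test_zero_noise_ratio_equals_enrichment(self, noiseless_design):
        profile = synth.generate_study(noiseless_design, seed=0).iloc[0]
        acq = synth.AcquisitionSpec(
            noise_cv=0.0, autofluorescence_coeff=0.0, baseline_noise_sd=0.0
        )
        tc = synth.simulate_timecourses(profile, acq, seed=0)
        wide = tc.pivot(index="time_s", columns="channel", values="intensity")
        grown = wide[wide["platelet"] > 0]
        for dim in DIMENSIONS[1:]:
            ratio = grown[dim] / grown["platelet"]
            assert np.allclose(ratio, profile[dim])

    def test_autofluorescence_inflates_391nm_channel(self, noiseless_design):
        profile = synth.generate_study(noiseless_design, seed=0).iloc[0]
        acq = synth.AcquisitionSpec(
            noise_cv=0.0, autofluorescence_coeff=0.2, baseline_noise_sd=0.0
        )
        tc = synth.simulate_timecourses(profile, acq, seed=0)
        wide = tc.pivot(index="time_s", columns="channel", values="intensity")
        grown = wide[wide["platelet"] > 0]
        ratio = grown["fg"] / grown["platelet"]
        assert np.allclose(ratio, profile["fg"] + 0.2)

    def test_fixed_seed_identical_traces(self, default_design):
        profile = synth.generate_study(default_design, seed=0).iloc[0]
        a = synth.simulate_timecourses(profile, seed=9)
        b = synth.simulate_timecourses(profile, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_duration_must_cover_readout(self):
        with pytest.raises(ValueError, match="450"):
            synth.AcquisitionSpec(duration=400.0, onset_delay=30.0)


class TestApplyInhibitor:
    @pytest.fixture
    def spec(self):
        from thromboprofile.barcode import Barcode

        return synth.InhibitorSpec(
            name="nmc4_like",
            ic50=1.0,
            hill_slope=1.0,
            floor_R=0.0,
            effect_barcode=Barcode.from_string("-0--0--"),
        )

    def test_zero_concentration_is_identity(self, spec):
        profile = np.array([1000.0, 0.5, 0.3, 0.4, 0.2, 0.3, 0.2])
        out = synth.apply_inhibitor(profile, spec, 0.0)
        assert np.allclose(out, profile)

    def test_midpoint_halves_size(self, spec):
        profile = np.array([1000.0, 0.5, 0.3, 0.4, 0.2, 0.3, 0.2])
        out = synth.apply_inhibitor(profile, spec, spec.ic50)
        assert out[0] == pytest.approx(500.0)

    def test_saturating_dose_reaches_floor(self):
        from thromboprofile.barcode import Barcode

        spec = synth.InhibitorSpec(
            name="cocktail", ic50=1.0, floor_R=5.0,
            effect_barcode=Barcode.from_string("-000000"),
        )
        profile = np.array([1000.0, 0.5, 0.3, 0.4, 0.2, 0.3, 0.2])
        out = synth.apply_inhibitor(profile, spec, 1e9)
        assert out[0] == pytest.approx(50.0, rel=1e-6)

    def test_trit_factor_applies_at_ic50(self, spec):
        profile = np.array([1000.0, 0.5, 0.3, 0.4, 0.2, 0.3, 0.2])
        out = synth.apply_inhibitor(profile, spec, spec.ic50, trit_factor=0.5)
        # '-' trits (vwf, psel, eplus, act) halved; '0' trits (fg, ps) untouched
        assert out[2] == pytest.approx(0.15)
        assert out[3] == pytest.approx(0.2)
        assert out[5] == pytest.approx(0.15)
        assert out[6] == pytest.approx(0.1)
        assert out[1] == pytest.approx(0.5)
        assert out[4] == pytest.approx(0.2)

    def test_monotone_nonincreasing_in_concentration(self, spec):
        profile = np.array([1000.0, 0.5, 0.3, 0.4, 0.2, 0.3, 0.2])
        doses = np.logspace(-3, 3, 25)
        prev = synth.apply_inhibitor(profile, spec, 0.0)
        for c in doses:
            cur = synth.apply_inhibitor(profile, spec, float(c))
            for i, trit in enumerate(spec.effect_barcode.trits):
                if trit == -1 or i == 0:
                    assert cur[i] <= prev[i] + 1e-12
            prev = cur

    def test_negative_concentration_rejected(self, spec):
        with pytest.raises(ValueError):
            synth.apply_inhibitor(np.ones(7), spec, -1.0)


class TestAdhesionAndLifetimes:
    def test_zero_probability_all_nonadhesion(self):
        scen = synth.BfpScenario(p_a=0.0)
        assert synth.simulate_adhesion(scen, seed=0).sum() == 0

    def test_bernoulli_long_run_frequency(self):
        """Monte-Carlo: 30-cycle series at p=0.2 average to 0.2."""
        scen = synth.BfpScenario(p_a=0.2, n_cycles=30)
        freqs = np.array(
            [synth.simulate_adhesion(scen, seed=s).mean() for s in range(10_000)]
        )
        se = np.sqrt(0.2 * 0.8 / (30 * 10_000))
        assert abs(freqs.mean() - 0.2) < 4 * se

    def test_eq2_forward_probability(self):
        """m_r m_l A_c K_a = 0.2231 gives P_a = 1 - e^-0.2231 ~ 0.2."""
        p_a = 1.0 - np.exp(-0.2231)
        scen = synth.BfpScenario(p_a=p_a, n_cycles=30)
        freqs = np.array(
            [synth.simulate_adhesion(scen, seed=s).mean() for s in range(4000)]
        )
        assert freqs.mean() == pytest.approx(0.2, abs=0.005)

    def test_pure_slip_limit_is_force_independent(self):
        params = synth.CatchSlipParams(k_c0=0.0, f_c=1.0, k_s0=0.5, f_s=1e9)
        scen = synth.BfpScenario(
            params=params, forces=(5.0, 25.0, 45.0), lifetimes_per_force=4000
        )
        df = synth.simulate_lifetimes(scen, seed=3)
        means = df.groupby("force_pN")["lifetime_s"].mean()
        for m in means:
            assert m == pytest.approx(2.0, rel=0.1)

    def test_catch_slip_curve_peaks_at_analytic_force(self):
        p = synth.HYPERTENSIVE_INTEGRIN_PARAMS
        f_star = catch_slip_peak_force(p.k_c0, p.f_c, p.k_s0, p.f_s)
        assert p.peak_force() == pytest.approx(f_star)
        assert p.peak_force() == pytest.approx(35.0, abs=0.5)
        assert p.peak_lifetime() == pytest.approx(10.0, rel=0.02)
        hp = synth.HEALTHY_INTEGRIN_PARAMS
        assert hp.peak_force() == pytest.approx(15.0, abs=0.5)
        assert hp.peak_lifetime() == pytest.approx(5.0, rel=0.02)

    def test_lifetimes_reproducible_under_seed(self):
        scen = synth.BfpScenario()
        a = synth.simulate_lifetimes(scen, seed=11)
        b = synth.simulate_lifetimes(scen, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_exponential_marginal(self):
        """Lifetimes at fixed force are exponential with rate k(F) (KS at 1%)."""
        p = synth.HEALTHY_INTEGRIN_PARAMS
        scen = synth.BfpScenario(params=p, forces=(15.0,), lifetimes_per_force=10_000)
        df = synth.simulate_lifetimes(scen, seed=21)
        k = p.rate(15.0)
        assert st.kstest(df["lifetime_s"], "expon", args=(0, 1 / k)).pvalue > 0.01


class TestCalcium:
    def test_zero_amplitude_trace_is_flat(self):
        params = synth.CatchSlipParams(k_c0=0.0, f_c=1.0, k_s0=1.0, f_s=1e9)
        trace, amps = synth.simulate_calcium(
            [10.0], params, seed=0, amplitude_per_second=0.0
        )
        assert np.allclose(trace["i340"] / trace["i380"], 1.0)
        assert amps == [0.0]

    def test_amplitude_proportional_to_mean_lifetime(self):
        params = synth.HYPERTENSIVE_INTEGRIN_PARAMS
        f1, f2 = 35.0, 60.0
        _, amps = synth.simulate_calcium([f1, f2], params, seed=0)
        expected = params.mean_lifetime(f1) / params.mean_lifetime(f2)
        assert amps[0] / amps[1] == pytest.approx(expected)

    def test_seed_reproducibility(self):
        params = synth.HEALTHY_INTEGRIN_PARAMS
        a, _ = synth.simulate_calcium([20.0], params, seed=4, noise_sd=0.02)
        b, _ = synth.simulate_calcium([20.0], params, seed=4, noise_sd=0.02)
        pd.testing.assert_frame_equal(a, b)
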