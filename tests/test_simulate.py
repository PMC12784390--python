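"""Synthetic detector records and the asynchronous-triggering properties."""

import numpy as np
import pytest

from ftims import (
    Amplifier,
    FrequencyStep,
    IonSpecies,
    NoiseModel,
    chirp_to_interferogram,
    fit_peaks,
    gate_correlation,
    interferogram_to_spectrum,
    plan_single_gate,
    plan_stepped,
    plan_swept,
    single_gate_record,
    steady_state_signal,
    swept_record,
    time_domain_record,
    windowed_mean,
)
from ftims.simulate import NOISE_BANDWIDTH_HZ


def step_at_phase(td_ms: float, phi: float, n_periods: int = 30,
                  k: int = 3) -> FrequencyStep:
    """A FrequencyStep whose frequency puts the gate pair at exact phase
    ``phi`` for an ion of drift time ``td_ms``: f = (k + phi) / td."""
    f = (k + phi) / (td_ms * 1e-3)
    return FrequencyStep(f=f, dwell=n_periods / f, n_pulses=n_periods)


class TestSteadyState:
    def test_single_ion_known_phases(self):
        # f = 12.5 Hz puts a 20 ms ion at phase 0.25 (signal 0.25);
        # f = 25 Hz puts it in anti-phase (signal 0).
        plan = plan_stepped(12.5, 12.5, 25.0, 1)
        ig = steady_state_signal(plan, [IonSpecies("x", td=20.0)])
        np.testing.assert_allclose(ig.signal, [0.25, 0.0], atol=1e-12)

    def test_empty_mixture_is_flat(self):
        plan = plan_stepped(10.0, 10.0, 100.0, 1)
        ig = steady_state_signal(plan, [])
        assert np.all(ig.signal == 0.0)

    def test_linearity(self):
        plan = plan_stepped(10.0, 5.0, 2000.0, 1)
        a = IonSpecies("a", td=25.0, abundance=0.7, sigma=0.1)
        b = IonSpecies("b", td=40.0, abundance=1.3, sigma=0.2)
        both = steady_state_signal(plan, [a, b]).signal
        separate = (steady_state_signal(plan, [a]).signal
                    + steady_state_signal(plan, [b]).signal)
        np.testing.assert_allclose(both, separate, rtol=1e-12)

    def test_seed_determinism_and_substreams(self):
        plan = plan_stepped(10.0, 5.0, 1000.0, 1)
        ion = [IonSpecies("x", td=30.0)]
        noise = NoiseModel(white_rms=0.5, seed=7)
        s1 = steady_state_signal(plan, ion, None, noise).signal
        s2 = steady_state_signal(plan, ion, None, noise).signal
        np.testing.assert_array_equal(s1, s2)
        s3 = steady_state_signal(plan, ion, None,
                                 NoiseModel(white_rms=0.5, seed=8)).signal
        assert not np.array_equal(s1, s3)
        # the first steps of a longer plan share the substream of a sub-plan
        longer = plan_stepped(10.0, 5.0, 2000.0, 1)
        s4 = steady_state_signal(longer, ion, None, noise).signal
        np.testing.assert_array_equal(s4[: len(s1)], s1)

    def test_noise_scales_with_dwell(self):
        ion = [IonSpecies("x", td=30.0)]
        noise = NoiseModel(white_rms=2.0, seed=3)
        for n_avg in (1, 4):
            plan = plan_stepped(2.0, 2.0, 4000.0, n_avg)
            clean = steady_state_signal(plan, ion).signal
            noisy = steady_state_signal(plan, ion, None, noise).signal
            measured = np.std(noisy - clean)
            expected = 2.0 / np.sqrt((n_avg / 2.0) * NOISE_BANDWIDTH_HZ)
            assert measured == pytest.approx(expected, rel=0.2)

    def test_refuses_non_stepped_plan(self):
        with pytest.raises(ValueError):
            steady_state_signal(plan_swept(4.0, 8000.0, 8.0), [])


class TestTimeDomainOracle:
    def test_whole_period_mean_matches_analytic_closely(self):
        """rise_time = 0, whole-period window: the sampled product of the two
        gate trains averages to the gate correlation."""
        ion = IonSpecies("x", td=20.0, sigma=0.0)
        step = step_at_phase(20.0, 0.2, n_periods=30)
        t, y = time_domain_record(step, [ion], amplifier=Amplifier(rise_time=0.0),
                                  sample_rate=1000.37 * step.f)
        analytic = gate_correlation(step.f, 20.0)
        assert windowed_mean(t, y, 0.0) == pytest.approx(analytic, rel=1e-3)

    def test_oracle_equivalence_random_pairs(self, rng):
        """50 random (ion, frequency) pairs, rise_time = 0, whole periods:
        windowed means within 1% of the analytic steady state."""
        for _ in range(50):
            td = rng.uniform(15.0, 46.0)
            phi = rng.uniform(0.05, 0.45)
            k = int(rng.integers(1, 40))
            step = step_at_phase(td, phi, n_periods=25, k=k)
            ion = IonSpecies("x", td=td, sigma=0.0)
            t, y = time_domain_record(
                step, [ion], amplifier=Amplifier(rise_time=0.0),
                sample_rate=200.71 * step.f)
            analytic = gate_correlation(step.f, td)
            assert windowed_mean(t, y, 0.0) == pytest.approx(
                analytic, rel=0.01, abs=5e-4)

    def test_oracle_equivalence_with_long_rise_time(self, rng):
        """rise_time = 100 ms, arbitrary window offsets: within 2%."""
        for _ in range(8):
            td = rng.uniform(15.0, 46.0)
            phi = rng.uniform(0.1, 0.4)
            k = int(rng.integers(5, 30))
            f = (k + phi) / (td * 1e-3)
            step = FrequencyStep(f=f, dwell=0.5, n_pulses=int(0.5 * f),
                                 trigger_offset=rng.uniform(0.0, 1.0 / f))
            ion = IonSpecies("x", td=td, sigma=0.0)
            t, y = time_domain_record(
                step, [ion], amplifier=Amplifier(rise_time=100.0),
                sample_rate=25.37 * f)
            mean = windowed_mean(t, y, step.trigger_offset)
            analytic = gate_correlation(f, td)
            assert mean == pytest.approx(analytic, rel=0.02, abs=1e-3)

    def test_trigger_offset_invariance(self):
        """With rise time >= 10 gate periods the windowed mean is flat in the
        window start: the quantitative form of 'asynchronous triggering has
        negligible effect'."""
        f = 1000.0
        step = FrequencyStep(f=f, dwell=0.5, n_pulses=500)
        ion = IonSpecies("x", td=20.05, sigma=0.0)
        t, y = time_domain_record(step, [ion],
                                  amplifier=Amplifier(rise_time=100.0),
                                  sample_rate=20000.0)
        offsets = np.linspace(0.0, 1.0 / f, 20, endpoint=False)
        means = [windowed_mean(t, y, off, 0.3) for off in offsets]
        assert np.std(means) / np.mean(means) < 0.01

    def test_zero_abundance_gives_filtered_baseline(self):
        step = FrequencyStep(f=100.0, dwell=0.2, n_pulses=20)
        ion = IonSpecies("x", td=20.0, abundance=0.0)
        noise = NoiseModel(white_rms=0.0, baseline=0.7)
        t, y = time_domain_record(step, [ion], amplifier=Amplifier(rise_time=10.0),
                                  noise=noise, sample_rate=5000.0)
        np.testing.assert_allclose(y, 0.7, rtol=1e-6)

    def test_undersampling_refused(self):
        step = FrequencyStep(f=1000.0, dwell=0.1, n_pulses=100)
        with pytest.raises(ValueError, match="undersample"):
            time_domain_record(step, [], sample_rate=5000.0)


class TestSingleGate:
    def test_peak_at_drift_time(self):
        plan = plan_single_gate(50.0, 0.2, 275)
        trace = single_gate_record(plan, [IonSpecies("x", td=30.0, sigma=0.15)],
                                   sample_rate=20000.0)
        dt_ms = trace.times[1] - trace.times[0]
        assert trace.times[np.argmax(trace.signal)] == pytest.approx(
            30.0, abs=dt_ms)

    def test_averaging_reduces_noise_by_sqrt_n(self):
        ions: list[IonSpecies] = []
        rms = []
        for n_scans in (275, 1):
            plan = plan_single_gate(50.0, 0.2, n_scans)
            trace = single_gate_record(
                plan, ions, noise=NoiseModel(white_rms=1.0, seed=11))
            rms.append(np.std(trace.signal))
        assert rms[0] / rms[1] == pytest.approx(1.0 / np.sqrt(275), rel=0.2)

    def test_empty_mixture_is_flat_baseline(self):
        plan = plan_single_gate()
        trace = single_gate_record(plan, [],
                                   noise=NoiseModel(baseline=0.3))
        np.testing.assert_allclose(trace.signal, 0.3)

    def test_requires_single_gate_plan(self):
        with pytest.raises(ValueError):
            single_gate_record(plan_stepped(10.0, 5.0, 100.0, 1), [])


class TestSwept:
    def test_chirp_record_maps_to_uniform_interferogram(self):
        plan = plan_swept(4.0, 8000.0, 8.0, 100)
        rec = swept_record(plan, [IonSpecies("x", td=20.0, sigma=0.1)],
                           sample_rate=1000.0)
        ig = chirp_to_interferogram(rec)
        assert len(ig.frequencies) == 8000
        df = np.diff(ig.frequencies)
        np.testing.assert_allclose(df, df[0], rtol=1e-9)

    def test_swept_and_stepped_agree_on_peak_centers(self):
        """A two-ion mixture reconstructs to the same drift times from a
        swept chirp and a stepped plan, within one bin of the coarser axis."""
        ions = [IonSpecies("a", td=25.0, sigma=0.15),
                IonSpecies("b", td=38.0, sigma=0.15, abundance=0.8)]
        swept = chirp_to_interferogram(
            swept_record(plan_swept(4.0, 4000.0, 4.0), ions,
                         sample_rate=1000.0))
        stepped = steady_state_signal(plan_stepped(4.0, 2.0, 4000.0, 1), ions)
        centers = {}
        bins = {}
        for label, ig in (("swept", swept), ("stepped", stepped)):
            spec = interferogram_to_spectrum(ig)
            peaks = fit_peaks(spec, 0.3)
            assert len(peaks) == 2
            centers[label] = [p.td for p in peaks]
            bins[label] = spec.bin_width
        tol = max(bins.values())
        for c_sw, c_st in zip(centers["swept"], centers["stepped"]):
            assert abs(c_sw - c_st) <= tol

    def test_empty_mixture_is_baseline(self):
        rec = swept_record(plan_swept(4.0, 1000.0, 1.0), [],
                           noise=NoiseModel(baseline=0.2))
        np.testing.assert_allclose(rec.signal, 0.2)

    def test_requires_swept_plan(self):
        with pytest.raises(ValueError):
            swept_record(plan_stepped(10.0, 5.0, 100.0, 1), [])
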