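"""Forward simulator: steady states, determinism, protocols, fixtures."""

import numpy as np
import pytest

from syncond import (
    ParameterError,
    PipelineConfig,
    reconstruct,
    run_pipeline,
)
from syncond.core import CURRENT_CLAMP, VOLTAGE_CLAMP
from syncond.preprocess import detect_burst_onsets, rectify_integrate
from syncond.simulate import (
    ConductanceTemplate,
    NeuronParams,
    Protocol,
    make_phenotype_fixture,
    phenotype_activity,
    simulate,
)

from conftest import small_protocol


def _steady_sim(i_level=0.0, gi=5.0, ge=0.0, mode=CURRENT_CLAMP,
                noise=0.0, spike_threshold=None):
    params = NeuronParams(noise_sd=noise, rng_seed=0,
                          spike_threshold=spike_threshold)
    templates_i = ((ConductanceTemplate(shape="constant", peak=gi,
                                        baseline=gi),)
                   if gi > 0 else ())
    templates_e = ((ConductanceTemplate(shape="constant", peak=ge,
                                        baseline=ge),)
                   if ge > 0 else ())
    prot = Protocol(mode=mode, levels=(i_level,), cycles_per_level=3,
                    period=3.0, sample_rate=5000.0)
    return simulate(params, templates_i, templates_e, prot)


class TestSteadyStates:
    def test_weighted_reversal_rest(self):
        # g_leak=10@-60 plus gi=5@-90 rests at -70 mV
        rec, _ = _steady_sim(i_level=0.0)
        assert rec.vm[-1] == pytest.approx(-70.0, abs=0.01)

    def test_injected_current_offset(self):
        # V = (sum gE + I) / sum g = -70 - 100/15
        rec, _ = _steady_sim(i_level=-100.0)
        assert rec.vm[-1] == pytest.approx(-70.0 - 100.0 / 15.0, abs=0.01)

    def test_voltage_clamp_holding_current_balance(self):
        # at -70 mV the leak (+100 pA) and inhibition (-100 pA) cancel
        rec, _ = _steady_sim(i_level=-70.0, mode=VOLTAGE_CLAMP)
        assert rec.i_inj[-1] == pytest.approx(0.0, abs=1e-6)

    def test_relaxes_to_leak_reversal_without_synapses(self):
        rec, _ = _steady_sim(gi=0.0, ge=0.0)
        assert rec.vm[-1] == pytest.approx(-60.0, abs=0.01)


class TestSimulatorMechanics:
    def test_seed_determinism_bit_identical(self):
        a, _ = make_phenotype_fixture("post-I", seed=42, noise_sd=0.5,
                                      protocol=small_protocol())
        b, _ = make_phenotype_fixture("post-I", seed=42, noise_sd=0.5,
                                      protocol=small_protocol())
        assert np.array_equal(a.vm, b.vm)
        assert np.array_equal(a.i_inj, b.i_inj)
        assert np.array_equal(a.ref, b.ref)

    def test_different_seeds_differ(self):
        a, _ = make_phenotype_fixture("post-I", seed=1, noise_sd=0.5,
                                      protocol=small_protocol())
        b, _ = make_phenotype_fixture("post-I", seed=2, noise_sd=0.5,
                                      protocol=small_protocol())
        assert not np.array_equal(a.vm, b.vm)

    def test_unstable_step_rejected(self):
        params = NeuronParams()  # tau_m = 10 ms
        prot = Protocol(levels=(0.0,), cycles_per_level=1,
                        sample_rate=500.0)  # dt = 2 ms > tau/10
        with pytest.raises(ParameterError, match="stability"):
            simulate(params, (), (), prot)

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ParameterError, match="phenotype"):
            make_phenotype_fixture("tonic", seed=0)

    def test_noise_sd_calibrated_at_steady_state(self):
        rec, _ = _steady_sim(noise=0.5)
        tail = rec.vm[-5000:]
        assert np.std(tail) == pytest.approx(0.5, rel=0.15)

    def test_spiking_add_on_crosses_threshold_and_resets(self):
        params = NeuronParams(spike_threshold=-45.0, noise_sd=0.0,
                              rng_seed=0)
        ge = (ConductanceTemplate(shape="constant", peak=15.0,
                                  baseline=15.0),)
        prot = Protocol(levels=(0.0,), cycles_per_level=2,
                        sample_rate=5000.0)
        rec, _ = simulate(params, (), ge, prot)
        assert rec.vm.max() == pytest.approx(params.spike_peak)
        assert np.any(rec.vm <= params.spike_reset)


class TestReferenceSignal:
    def test_burst_onsets_recovered_from_synthetic_nerve(self):
        rec, truth = make_phenotype_fixture(
            "ramp-I", seed=0, noise_sd=0.25, protocol=small_protocol())
        integ = rectify_integrate(rec.ref, 0.05, rec.sample_rate)
        cyc = detect_burst_onsets(rec.time, integ, threshold_frac=0.10)
        T = truth.protocol.period
        expected = truth.t_first_onset + T * np.arange(cyc.onsets.size)
        # onset count exact; timing within a small detection latency
        assert cyc.n_cycles == truth.protocol.n_cycles
        assert np.max(np.abs(cyc.onsets - expected)) < 0.05 * T

    def test_duty_cycle_near_inspiratory_fraction(self):
        rec, truth = make_phenotype_fixture(
            "ramp-I", seed=0, noise_sd=0.25, protocol=small_protocol())
        integ = rectify_integrate(rec.ref, 0.05, rec.sample_rate)
        cyc = detect_burst_onsets(rec.time, integ, threshold_frac=0.10)
        assert cyc.inspiratory_fraction == pytest.approx(
            truth.protocol.inspiratory_fraction, abs=0.08)


class TestPhenotypeFixtures:
    def test_fixture_passes_qc(self, config):
        rec, _ = make_phenotype_fixture("early-I", seed=0, noise_sd=0.5,
                                        protocol=small_protocol())
        res = reconstruct(rec, config)  # raises QCError if QC fails
        assert res.qc.passed

    def test_rampi_inputs_realize_described_pattern(self):
        _, truth = make_phenotype_fixture("ramp-I", seed=0,
                                          protocol=small_protocol())
        phi = (np.arange(100) + 0.5) / 100
        gi = truth.gi_at_time(truth.t_first_onset + phi * 3.0)
        ge = truth.ge_at_time(truth.t_first_onset + phi * 3.0)
        insp = phi < 0.33
        # excitation ramps during inspiration...
        assert ge[insp].max() > 5 * ge[~insp].mean() + 1e-9
        # ...inhibition occupies post-I and E2, not inspiration
        assert gi[~insp].max() > 10 * gi[insp].max()

    def test_postI_receives_inspiratory_and_late_E_inhibition(self):
        _, truth = make_phenotype_fixture("post-I", seed=0,
                                          protocol=small_protocol())
        gi = truth.gi_of_phi
        phi = (np.arange(100) + 0.5) / 100
        early_insp = gi[(phi > 0.05) & (phi < 0.2)].mean()
        late_insp = gi[(phi > 0.25) & (phi < 0.33)].mean()
        late_exp = gi[(phi > 0.85) & (phi < 0.95)].mean()
        mid = gi[(phi > 0.45) & (phi < 0.6)].mean()
        assert early_insp > late_insp          # decrementing inspiratory
        assert late_exp > 3 * mid              # incrementing late-E

    def test_activity_templates_normalized(self):
        phi = np.linspace(0, 1, 1001)
        for name in ("pre-I/I", "ramp-I", "early-I", "late-I", "post-I",
                     "aug-E"):
            act = phenotype_activity(name, phi)
            assert act.max() == pytest.approx(1.0, abs=1e-9)
            assert act.min() >= 0.0
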