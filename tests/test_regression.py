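"""Phase binning and per-bin I-V regression."""

import numpy as np
import pytest

from syncond import (
    PipelineConfig,
    bin_by_phase,
    fit_iv_bin,
    ols,
    total_conductance,
)
from syncond.core import CURRENT_CLAMP, VOLTAGE_CLAMP
from syncond.regression import PhaseRegressionTable
from syncond.validation import binned_truth


class TestBinByPhase:
    def test_edges_and_right_open_intervals(self):
        bins, centers = bin_by_phase(np.array([0.005, 0.9999]), 100)
        assert 0 in bins[0] and 1 in bins[99]
        assert centers[0] == pytest.approx(0.005)

    def test_uniform_grid_partition(self):
        phi = np.arange(10000) / 10000.0
        bins, _ = bin_by_phase(phi, 100)
        assert all(b.size == 100 for b in bins)
        assert sum(b.size for b in bins) == 10000

    def test_nan_phases_unassigned(self):
        phi = np.array([0.1, np.nan, 0.2])
        bins, _ = bin_by_phase(phi, 10)
        assert sum(b.size for b in bins) == 2


class TestOLS:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(5, 30)
            x = rng.normal(size=n)
            y = 2.0 + 3.0 * x + rng.normal(size=n)
            fit = ols(x, y)
            # brute-force normal equations via lstsq
            X = np.column_stack([x, np.ones(n)])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert fit.slope == pytest.approx(beta[0], abs=1e-10)
            assert fit.intercept == pytest.approx(beta[1], abs=1e-10)
            s2 = np.sum((y - X @ beta) ** 2) / (n - 2)
            cov = s2 * np.linalg.inv(X.T @ X)
            assert fit.se_slope == pytest.approx(np.sqrt(cov[0, 0]),
                                                 rel=1e-9)
            assert fit.se_intercept == pytest.approx(np.sqrt(cov[1, 1]),
                                                     rel=1e-9)
            assert fit.cov_ab == pytest.approx(cov[0, 1], rel=1e-9,
                                               abs=1e-12)


class TestFitIVBin:
    def test_exact_line(self):
        # 100 MOhm, V0 = -60 mV: V = -60 + 0.1 * I (mV/pA)
        i = np.repeat([0.0, -100.0, -200.0], 4)
        v = -60.0 + 0.1 * i
        R, V0, dR, dV0, n, nl, valid = fit_iv_bin(v, i, CURRENT_CLAMP,
                                                  n_min=10)
        assert valid and nl == 3
        assert R == pytest.approx(100.0, abs=1e-9)
        assert V0 == pytest.approx(-60.0, abs=1e-9)
        assert dR == pytest.approx(0.0, abs=1e-9)

    def test_monte_carlo_coverage(self):
        # noisy line: estimate within 3 SE of truth in >= 99% of replicates
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 500
        i = np.repeat([0.0, -100.0, -200.0], 50)
        for _ in range(n_rep):
            v = -60.0 + 0.1 * i + rng.normal(0.0, 1.0, size=i.size)
            R, V0, dR, dV0, *_ = fit_iv_bin(v, i, CURRENT_CLAMP)
            hits += abs(R - 100.0) <= 3.0 * dR
        assert hits / n_rep >= 0.99

    def test_single_level_invalid_not_raised(self):
        i = np.full(20, -100.0)
        v = -70.0 + 0.01 * np.arange(20)
        *_, valid = fit_iv_bin(v, i, CURRENT_CLAMP)
        assert not valid

    def test_too_few_samples_invalid(self):
        i = np.array([0.0, -100.0, -200.0])
        v = -60.0 + 0.1 * i
        *_, valid = fit_iv_bin(v, i, CURRENT_CLAMP, n_min=10)
        assert not valid

    def test_voltage_clamp_matches_current_clamp_parameters(self):
        # same underlying membrane: G = 12 nS, V0 = -65 mV
        rng = np.random.default_rng(5)
        v = np.repeat([-95.0, -80.0, -65.0], 40)
        i = 12.0 * (v - (-65.0)) + rng.normal(0.0, 2.0, size=v.size)
        R, V0, dR, dV0, n, nl, valid = fit_iv_bin(v, i, VOLTAGE_CLAMP,
                                                  level_tol=1.0)
        assert valid and nl == 3
        assert R == pytest.approx(1000.0 / 12.0, rel=0.05)
        assert V0 == pytest.approx(-65.0, abs=1.0)
        assert dR > 0 and dV0 > 0

    def test_se_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(9)
        ns = np.array([30, 100, 300, 1000, 3000])
        ses = []
        for n in ns:
            reps = []
            for _ in range(30):
                i = rng.choice([0.0, -100.0, -200.0], size=n)
                v = -60.0 + 0.1 * i + rng.normal(0.0, 1.0, size=n)
                _, _, dR, *_ = fit_iv_bin(v, i, CURRENT_CLAMP)
                reps.append(dR)
            ses.append(np.mean(reps))
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)


class TestTotalConductance:
    def _table(self, R, dR, valid=None):
        n = len(R)
        return PhaseRegressionTable(
            phase_center=(np.arange(n) + 0.5) / n,
            R=np.asarray(R, float), V0=np.full(n, -60.0),
            dR=np.asarray(dR, float), dV0=np.zeros(n),
            n_samples=np.full(n, 50), n_levels=np.full(n, 3),
            valid=np.ones(n, bool) if valid is None else np.asarray(valid))

    def test_reciprocal_and_error_propagation(self):
        tot = total_conductance(self._table([100.0], [5.0]))
        assert tot.G[0] == pytest.approx(10.0)     # 1/100 MOhm = 10 nS
        assert tot.dG[0] == pytest.approx(0.5)     # dR/R^2

    def test_invalid_bin_propagates(self):
        tot = total_conductance(self._table([100.0, np.nan], [5.0, np.nan],
                                            valid=[True, False]))
        assert np.isnan(tot.G[1]) and np.isnan(tot.dG[1])
        assert not tot.valid[1]

    def test_nonphysical_resistance_invalidated(self):
        tot = total_conductance(self._table([-50.0], [5.0]))
        assert not tot.valid[0]
        assert np.isnan(tot.G[0])


class TestQuasiStaticRecovery:
    def test_noiseless_recovery_of_G_and_V0(self, std_noiseless):
        """Slowly driven noiseless neuron: per-bin G matches
        g_leak+gi+ge within 1% and V0 the conductance-weighted reversal
        within 0.5 mV."""
        rec, truth, res = std_noiseless
        tb = binned_truth(res, truth)
        m = tb["valid"]
        rel = np.abs(res.profile.G[m] - tb["G"][m]) / tb["G"][m]
        assert np.max(rel) < 0.01
        p = truth.params
        v0_true = (p.g_leak * p.E_leak + tb["gi"][m] * p.E_i
                   + tb["ge"][m] * p.E_e) / tb["G"][m]
        assert np.max(np.abs(res.table.V0[m] - v0_true)) < 0.5
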