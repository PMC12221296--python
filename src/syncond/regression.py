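"""Phase-binned I-V regression.

Samples are grouped into phase bins of the cycle; in each bin the linear
relation between membrane potential and injected current gives the total
input resistance R(phi) (slope) and the effective resting potential
V0(phi) (intercept), with standard errors from the residual variance.

In current clamp the measured voltage is regressed on the controlled
current; in voltage clamp the measured current is regressed on the
commanded potential (slope = total conductance) and the result is
converted to (R, V0) with first-order error propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    GOHM_TO_MOHM,
    PipelineConfig,
    ValidationError,
    conductance_error,
    resistance_to_conductance,
)


@dataclass
class OLSFit:
    """Simple linear regression y = a*x + b with error estimates."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    cov_ab: float
    r2: float
    n: int


def ols(x: np.ndarray, y: np.ndarray) -> OLSFit:
    """Ordinary least squares with slope/intercept covariance.

    Closed-form normal equations; residual variance uses n - 2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError("OLS needs at least 3 samples")
    xm = x.mean()
    ym = y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx <= 0:
        raise ValidationError("regressor has zero variance")
    sxy = np.sum((x - xm) * (y - ym))
    a = sxy / sxx
    b = ym - a * xm
    resid = y - (a * x + b)
    ssr = float(np.sum(resid**2))
    syy = float(np.sum((y - ym) ** 2))
    s2 = ssr / (n - 2)
    var_a = s2 / sxx
    var_b = s2 * (1.0 / n + xm**2 / sxx)
    cov_ab = -xm * s2 / sxx
    r2 = 1.0 - ssr / syy if syy > 0 else 1.0
    return OLSFit(slope=float(a), intercept=float(b),
                  se_slope=float(np.sqrt(var_a)),
                  se_intercept=float(np.sqrt(var_b)),
                  cov_ab=float(cov_ab), r2=float(r2), n=int(n))


@dataclass
class PhaseRegressionTable:
    """Per-phase-bin I-V regression results.

    R in MOhm, V0 in mV; ``valid`` marks bins with enough samples, at
    least two distinct controlled levels and a physical (positive)
    resistance.  Invalid bins carry NaN.
    """

    phase_center: np.ndarray
    R: np.ndarray
    V0: np.ndarray
    dR: np.ndarray
    dV0: np.ndarray
    n_samples: np.ndarray
    n_levels: np.ndarray
    valid: np.ndarray

    @property
    def n_bins(self) -> int:
        return int(self.phase_center.size)


@dataclass
class TotalConductance:
    """Total conductance G(phi) = 1/R(phi) per bin, nS, with dG = dR/R^2."""

    G: np.ndarray
    dG: np.ndarray
    valid: np.ndarray


def bin_by_phase(phase: np.ndarray, n_bins: int):
    """Partition samples into right-open phase bins [i/n, (i+1)/n).

    Returns ``(bin_indices, centers)`` where ``bin_indices`` is a list of
    integer index arrays (one per bin) over the input samples; samples
    with non-finite phase are assigned to no bin.
    """
    phase = np.asarray(phase, dtype=float)
    finite = np.isfinite(phase)
    if np.any((phase[finite] < 0) | (phase[finite] >= 1)):
        raise ValidationError("phases must lie in [0, 1)")
    which = np.full(phase.shape, -1, dtype=int)
    # assign against the floating-point bin edges themselves so that a
    # phase exactly equal to i/n lands in bin i (right-open intervals)
    edges = np.arange(1, n_bins) / n_bins
    which[finite] = np.searchsorted(edges, phase[finite], side="right")
    order = np.argsort(which, kind="stable")
    sorted_bins = which[order]
    edges = np.searchsorted(sorted_bins, np.arange(n_bins + 1))
    bins = [order[edges[i]:edges[i + 1]] for i in range(n_bins)]
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return bins, centers


def count_levels(controlled: np.ndarray, tol: float) -> int:
    """Number of distinct held levels, clustered at resolution ``tol``."""
    if controlled.size == 0:
        return 0
    return int(np.unique(np.round(np.asarray(controlled) / tol)).size)


def fit_iv_bin(vm: np.ndarray, i_inj: np.ndarray, mode: str,
               n_min: int = 10, level_tol: float = 5.0):
    """Fit the linear I-V relation for one phase bin.

    Returns ``(R, V0, dR, dV0, n, n_levels, valid)``; R in MOhm.  Bins
    with too few samples, a single held level or a non-positive slope are
    marked invalid (NaN results), never raised.
    """
    vm = np.asarray(vm, dtype=float)
    i_inj = np.asarray(i_inj, dtype=float)
    n = vm.size
    controlled = i_inj if mode == CURRENT_CLAMP else vm
    n_levels = count_levels(controlled, level_tol)
    invalid = (np.nan, np.nan, np.nan, np.nan, n, n_levels, False)
    if n < max(n_min, 3) or n_levels < 2:
        return invalid
    if mode == CURRENT_CLAMP:
        fit = ols(i_inj, vm)          # slope mV/pA = GOhm
        if fit.slope <= 0:
            return invalid
        R = GOHM_TO_MOHM * fit.slope
        dR = GOHM_TO_MOHM * fit.se_slope
        V0 = fit.intercept
        dV0 = fit.se_intercept
    elif mode == VOLTAGE_CLAMP:
        fit = ols(vm, i_inj)          # slope pA/mV = nS
        g = fit.slope
        if g <= 0:
            return invalid
        R = GOHM_TO_MOHM / g
        dR = GOHM_TO_MOHM * fit.se_slope / g**2
        V0 = -fit.intercept / g
        # delta method on V0 = -b/a including cov(a, b)
        var_v0 = (fit.se_intercept**2 + V0**2 * fit.se_slope**2
                  + 2.0 * V0 * fit.cov_ab) / g**2
        dV0 = float(np.sqrt(max(var_v0, 0.0)))
    else:
        raise ValidationError(f"unknown clamp mode {mode!r}")
    return (float(R), float(V0), float(dR), float(dV0), n, n_levels, True)


def _window_levels(vm, controlled, tol, v_window):
    """Select whole levels whose median voltage is in the analysis window.

    The hyperpolarized-voltage restriction is applied per (bin, level)
    as a unit: admitting or rejecting individual samples of a level
    would let different levels sample different sub-ranges of the bin's
    phases, which biases the pooled fit wherever a level's voltage
    straddles a window edge within the bin.
    """
    lo, hi = v_window
    keep = np.zeros(vm.size, dtype=bool)
    codes = np.round(controlled / tol)
    for c in np.unique(codes):
        m = codes == c
        med = np.median(vm[m])
        if lo <= med <= hi:
            keep[m] = True
    return keep


def regress_by_phase(phase: np.ndarray, vm: np.ndarray, i_inj: np.ndarray,
                     mode: str, config: PipelineConfig
                     ) -> PhaseRegressionTable:
    """Run the per-bin I-V fits over all phase bins."""
    bins, centers = bin_by_phase(phase, config.n_bins)
    n_bins = config.n_bins
    level_tol = (config.plateau_tol if mode == CURRENT_CLAMP
                 else config.level_tol_vc)
    R = np.full(n_bins, np.nan)
    V0 = np.full(n_bins, np.nan)
    dR = np.full(n_bins, np.nan)
    dV0 = np.full(n_bins, np.nan)
    ns = np.zeros(n_bins, dtype=int)
    nl = np.zeros(n_bins, dtype=int)
    valid = np.zeros(n_bins, dtype=bool)
    for i, idx in enumerate(bins):
        v = vm[idx]
        ii = i_inj[idx]
        controlled = ii if mode == CURRENT_CLAMP else v
        keep = _window_levels(v, controlled, level_tol, config.v_window)
        (R[i], V0[i], dR[i], dV0[i], ns[i], nl[i], valid[i]) = fit_iv_bin(
            v[keep], ii[keep], mode, n_min=config.n_min,
            level_tol=level_tol)
    return PhaseRegressionTable(phase_center=centers, R=R, V0=V0, dR=dR,
                                dV0=dV0, n_samples=ns, n_levels=nl,
                                valid=valid)


def total_conductance(table: PhaseRegressionTable) -> TotalConductance:
    """G(phi) = 1/R(phi) with dG = dR/R^2; invalid bins propagate NaN.

    A valid bin with non-positive resistance is invalidated (nonphysical
    resistance) rather than producing a negative conductance.
    """
    valid = table.valid & np.isfinite(table.R) & (table.R > 0)
    G = np.full(table.n_bins, np.nan)
    dG = np.full(table.n_bins, np.nan)
    G[valid] = resistance_to_conductance(table.R[valid])
    dG[valid] = conductance_error(table.R[valid], table.dR[valid])
    return TotalConductance(G=G, dG=dG, valid=valid)
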