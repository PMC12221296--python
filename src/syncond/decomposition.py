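"""Decomposition of the total conductance into inhibitory and excitatory
components, dynamic components, leak estimate, error propagation,
significance testing and robustness scans.

Given per-bin total conductance G(phi) and effective resting potential
V0(phi), and reversal potentials (Ei, Ee):

    Gi = G (Ee - V0) / (Ee - Ei)
    Ge = G (V0 - Ei) / (Ee - Ei)

so that Gi + Ge = G identically.  The dynamic components subtract the
per-component minimum over the cycle, and the sum of the two minima
estimates the leak (plus any static synaptic) conductance.  A one-tailed
z-test checks each bin's dynamic component against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .core import ParameterError, ReversalPair, ValidationError
from .regression import PhaseRegressionTable, TotalConductance


@dataclass
class ConductanceProfile:
    """Phase-resolved synaptic conductance profile of one epoch.

    All conductances in nS.  ``dGi_dyn``/``dGe_dyn`` are the dynamic
    components (minimum over valid bins subtracted), ``err_i``/``err_e``
    their standard errors, and ``z``/``p`` the one-tailed test of the
    dynamic component against zero.  Negative Gi or Ge (V0 outside
    [Ei, Ee], typically a mis-specified reversal) are flagged, not
    clipped.
    """

    phase_center: np.ndarray
    G: np.ndarray
    dG: np.ndarray
    Gi: np.ndarray
    Ge: np.ndarray
    dGi_dyn: np.ndarray
    dGe_dyn: np.ndarray
    err_i: np.ndarray
    err_e: np.ndarray
    z_i: np.ndarray
    z_e: np.ndarray
    p_i: np.ndarray
    p_e: np.ndarray
    valid: np.ndarray
    neg_flag_i: np.ndarray
    neg_flag_e: np.ndarray
    g_leak_est: float
    e_i_used: float
    e_e_used: float
    argmin_i: int
    argmin_e: int
    alpha: float = 0.05
    config_hash: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return int(self.phase_center.size)

    def significant_i(self) -> np.ndarray:
        return self.valid & (self.p_i < self.alpha)

    def significant_e(self) -> np.ndarray:
        return self.valid & (self.p_e < self.alpha)


def decompose(G, V0, reversals: ReversalPair):
    """Split total conductance into (Gi, Ge) given reversal potentials.

    Returns ``(Gi, Ge, neg_i, neg_e)``; the flags mark bins whose
    component came out negative (V0 outside [Ei, Ee]).  The identity
    Gi + Ge = G holds to round-off on every finite bin.
    """
    G = np.asarray(G, dtype=float)
    V0 = np.asarray(V0, dtype=float)
    denom = reversals.e_e - reversals.e_i
    if denom <= 0:
        raise ParameterError("require Ee > Ei")
    Gi = G * (reversals.e_e - V0) / denom
    Ge = G * (V0 - reversals.e_i) / denom
    neg_i = np.isfinite(Gi) & (Gi < 0)
    neg_e = np.isfinite(Ge) & (Ge < 0)
    return Gi, Ge, neg_i, neg_e


def dynamic_components(Gi, Ge, valid):
    """Dynamic components and leak estimate.

    Minima are taken over valid bins only; ties in the minimizing phase
    break to the first bin index.  Returns
    ``(dGi, dGe, g_leak_est, argmin_i, argmin_e)``.
    """
    Gi = np.asarray(Gi, dtype=float)
    Ge = np.asarray(Ge, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValidationError("all phase bins are invalid")
    idx = np.flatnonzero(valid)
    argmin_i = int(idx[np.argmin(Gi[idx])])
    argmin_e = int(idx[np.argmin(Ge[idx])])
    min_i = Gi[argmin_i]
    min_e = Ge[argmin_e]
    dGi = np.where(valid, Gi - min_i, np.nan)
    dGe = np.where(valid, Ge - min_e, np.nan)
    return dGi, dGe, float(min_i + min_e), argmin_i, argmin_e


def propagate_errors(dG, argmin: int):
    """Standard error of a dynamic component.

    err(phi) = sqrt(dG(phi)^2 + dG(phi_m)^2) where phi_m is the bin at
    which the component attains its minimum; at phi_m itself the error is
    sqrt(2) * dG(phi_m).
    """
    dG = np.asarray(dG, dtype=float)
    if not np.isfinite(dG[argmin]):
        raise ValidationError("argmin bin has no error estimate")
    return np.sqrt(dG**2 + dG[argmin] ** 2)


def significance(delta_G, err, alpha: float = 0.05):
    """One-tailed z-test of the dynamic component against zero.

    z = dG/err, p = 1 - Phi(z); a bin is significant iff p < alpha
    (strict).  No multiple-testing correction (optional
    Benjamini-Hochberg via :func:`benjamini_hochberg`).
    """
    delta_G = np.asarray(delta_G, dtype=float)
    err = np.asarray(err, dtype=float)
    z = np.full(delta_G.shape, np.nan)
    p = np.full(delta_G.shape, np.nan)
    finite = np.isfinite(delta_G) & np.isfinite(err)
    zero_err = finite & (err == 0)
    ok = finite & (err > 0)
    z[ok] = delta_G[ok] / err[ok]
    p[ok] = stats.norm.sf(z[ok])
    if zero_err.any():
        warnings.warn("zero standard error with nonzero dynamic component")
        z[zero_err] = np.where(delta_G[zero_err] > 0, np.inf, 0.0)
        p[zero_err] = np.where(delta_G[zero_err] > 0, 0.0, 0.5)
    significant = np.zeros(delta_G.shape, dtype=bool)
    significant[finite] = p[finite] < alpha
    return z, p, significant


def benjamini_hochberg(p, alpha: float = 0.05):
    """BH step-up procedure over the finite p-values (optional rigor)."""
    p = np.asarray(p, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    ps = p[finite]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = ps[order] <= thresh
    if below.any():
        kmax = np.max(np.flatnonzero(below))
        rej = np.zeros(m, dtype=bool)
        rej[order[: kmax + 1]] = True
        out[finite] = rej
    return out


def build_profile(table: PhaseRegressionTable, total: TotalConductance,
                  reversals: ReversalPair, alpha: float = 0.05,
                  config_hash: str = "") -> ConductanceProfile:
    """Assemble the full conductance profile from the regression results."""
    Gi, Ge, neg_i, neg_e = decompose(total.G, table.V0, reversals)
    valid = total.valid
    dGi, dGe, g_leak, am_i, am_e = dynamic_components(Gi, Ge, valid)
    err_i = propagate_errors(total.dG, am_i)
    err_e = propagate_errors(total.dG, am_e)
    z_i, p_i, _ = significance(dGi, err_i, alpha)
    z_e, p_e, _ = significance(dGe, err_e, alpha)
    return ConductanceProfile(
        phase_center=table.phase_center, G=total.G, dG=total.dG,
        Gi=Gi, Ge=Ge, dGi_dyn=dGi, dGe_dyn=dGe,
        err_i=err_i, err_e=err_e, z_i=z_i, z_e=z_e, p_i=p_i, p_e=p_e,
        valid=valid, neg_flag_i=neg_i, neg_flag_e=neg_e,
        g_leak_est=g_leak, e_i_used=reversals.e_i, e_e_used=reversals.e_e,
        argmin_i=am_i, argmin_e=am_e, alpha=alpha, config_hash=config_hash)


def max_normalize(x, joint_with=None):
    """Normalize a profile to its maximum (joint maximum if a second
    component is supplied)."""
    x = np.asarray(x, dtype=float)
    peak = np.nanmax(x)
    if joint_with is not None:
        peak = max(peak, np.nanmax(np.asarray(joint_with, dtype=float)))
    if not (peak > 0):
        return np.zeros_like(x)
    return x / peak


def _profile_corr(a, b):
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        return np.nan
    aa, bb = a[m], b[m]
    if aa.std() == 0 or bb.std() == 0:
        return np.nan
    return float(np.corrcoef(aa, bb)[0, 1])


def sensitivity_scan(G, V0, valid, e_e_range, e_i_range, grid: int = 3,
                     alpha: float = 0.05):
    """Repeat the decomposition over a grid of reversal potentials.

    The grid spans the given ranges with ``grid`` points per axis
    (corners + midpoints for the default 3).  Returns a dict with the
    per-cell dynamic components and, for each component, the matrix of
    pairwise Pearson correlations of the max-normalized profiles.
    """
    e_e_vals = np.linspace(e_e_range[0], e_e_range[1], grid)
    e_i_vals = np.linspace(e_i_range[0], e_i_range[1], grid)
    cells = []
    for ee in e_e_vals:
        for ei in e_i_vals:
            if not (ei < ee):
                raise ParameterError(
                    f"grid cell Ee={ee}, Ei={ei} violates Ei < Ee")
            rev = ReversalPair(e_i=float(ei), e_e=float(ee))
            Gi, Ge, *_ = decompose(G, V0, rev)
            dGi, dGe, *_ = dynamic_components(Gi, Ge, valid)
            cells.append({"e_i": float(ei), "e_e": float(ee),
                          "dGi": dGi, "dGe": dGe})
    n = len(cells)
    sim = {}
    for comp in ("dGi", "dGe"):
        mat = np.eye(n)
        for a, b in combinations(range(n), 2):
            r = _profile_corr(max_normalize(cells[a][comp]),
                              max_normalize(cells[b][comp]))
            mat[a, b] = mat[b, a] = r
        sim[comp] = mat
    return {"cells": cells, "similarity": sim,
            "e_e_values": e_e_vals, "e_i_values": e_i_vals}


def compare_epochs(profile_a: ConductanceProfile,
                   profile_b: ConductanceProfile) -> dict:
    """Stability comparison of two epochs of the same neuron.

    Per-component Pearson correlation and relative RMS difference of the
    dynamic components over jointly valid bins.
    """
    if profile_a.n_bins != profile_b.n_bins:
        raise ValidationError("profiles must have equal bin counts")
    m = profile_a.valid & profile_b.valid
    if not m.any():
        raise ValidationError("no jointly valid bins")
    out = {"n_bins": int(m.sum())}
    for comp, key in (("dGi_dyn", "i"), ("dGe_dyn", "e")):
        a = getattr(profile_a, comp)[m]
        b = getattr(profile_b, comp)[m]
        out[f"r_{key}"] = _profile_corr(a, b)
        scale = 0.5 * (np.nanmax(a) + np.nanmax(b))
        rms = float(np.sqrt(np.nanmean((a - b) ** 2)))
        out[f"rms_rel_{key}"] = rms / scale if scale > 0 else np.nan
    return out
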