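"""Wedge-diagram reversal potential estimation.

The per-bin trajectory {(G(phi), I0(phi))} with I0 = -G*V0 is bounded
above by the zero-excitation line (slope -Ei, traced while the excitatory
conductance sits at its static floor Ge0) and below by the zero-inhibition
line (slope -Ee).  A nearly linear upper portion of the trajectory
therefore yields the inhibitory reversal potential from its slope; a
nearly horizontal lower portion yields the excitatory one, which is
otherwise left at a configured default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import PipelineConfig

_MIN_G_SPREAD = 1e-12


@dataclass
class BoundaryLine:
    """One fitted wedge boundary: I0 = slope * G + intercept."""

    slope: float            # -E (mV)
    intercept: float        # pA
    se_slope: float
    se_intercept: float
    r2: float
    bins: np.ndarray        # trajectory bin indices used for the fit
    contained: bool         # all other points on the correct side


@dataclass
class WedgeFit:
    """Wedge trajectory with boundary-line fits and reversal estimates."""

    G: np.ndarray
    I0: np.ndarray
    valid: np.ndarray
    upper_line: Optional[BoundaryLine]
    lower_line: Optional[BoundaryLine]
    e_i_hat: Optional[float]
    e_i_se: Optional[float]
    e_e_hat: float
    e_e_defaulted: bool
    notes: list = field(default_factory=list)


def compute_I0(G, V0):
    """I0(phi) = -G(phi) * V0(phi); nS * mV = pA."""
    return -np.asarray(G, dtype=float) * np.asarray(V0, dtype=float)


def _window_ols(cx, cy, cxx, cxy, cyy, i, j):
    """OLS over trajectory points [i, j) from prefix sums."""
    n = j - i
    sx = cx[j] - cx[i]
    sy = cy[j] - cy[i]
    sxx = cxx[j] - cxx[i]
    sxy = cxy[j] - cxy[i]
    syy = cyy[j] - cyy[i]
    vx = sxx - sx * sx / n
    if vx <= _MIN_G_SPREAD * max(1.0, sxx / n):
        return None
    vxy = sxy - sx * sy / n
    vy = syy - sy * sy / n
    a = vxy / vx
    b = (sy - a * sx) / n
    ssr = max(vy - a * vxy, 0.0)
    r2 = 1.0 - ssr / vy if vy > 0 else 1.0
    s2 = ssr / max(n - 2, 1)
    se_a = np.sqrt(s2 / vx)
    xm = sx / n
    se_b = np.sqrt(s2 * (1.0 / n + xm * xm / vx))
    rms = np.sqrt(ssr / n)
    return a, b, se_a, se_b, r2, rms


def _fit_boundary(G, I0, valid, side: str, min_bins: int, min_r2: float,
                  sigma=None, max_se=np.inf):
    """Best-scoring contiguous-phase boundary window.

    Enumerates contiguous windows of >= ``min_bins`` valid bins (wrapping
    across the cycle boundary) and fits a line to each.  Admissible
    windows must have R^2 >= ``min_r2``, a conductance spread of at
    least 10% of the trajectory's range, a slope precision of
    ``max_se`` or better both as realized and as predicted from the
    per-bin I0 errors (the predicted bound is immune to
    selected-for-luck residuals), residuals consistent with those
    errors, and every other trajectory point on the correct side of the
    line within tolerance.  The score is window length over the
    residual scale floored at the measurement error, so a short window
    aligned with noise gains nothing from its small residual, and a
    long sloppy chord through the wedge interior is penalized by its
    curvature.
    """
    idx = np.flatnonzero(valid)
    m = idx.size
    if m < min_bins:
        return None
    x = G[idx]
    y = I0[idx]
    s = (np.zeros(m) if sigma is None
         else np.asarray(sigma, dtype=float)[idx])
    # doubled sequence so boundary windows may wrap across phase 0
    x2 = np.concatenate([x, x])
    y2 = np.concatenate([y, y])
    s2 = np.concatenate([s, s])
    cx = np.concatenate([[0.0], np.cumsum(x2)])
    cy = np.concatenate([[0.0], np.cumsum(y2)])
    cxx = np.concatenate([[0.0], np.cumsum(x2 * x2)])
    cxy = np.concatenate([[0.0], np.cumsum(x2 * y2)])
    cyy = np.concatenate([[0.0], np.cumsum(y2 * y2)])
    sign = 1.0 if side == "upper" else -1.0
    # a boundary slope is only identifiable over a real conductance range
    g_range = float(x.max() - x.min())
    if g_range <= 0:
        return None
    min_spread = 0.1 * g_range
    # absolute residual floor: half a percent of the trajectory's I0
    # span, absorbing the membrane-lag curvature of noiseless data
    rms_cap_floor = 5e-3 * max(float(y.max() - y.min()), 1e-6)
    score_floor = 1e-3 * max(1.0, float(np.median(np.abs(y))))
    best = None
    best_score = -np.inf
    for i in range(m):
        for ln in range(min_bins, m + 1):
            j = i + ln
            fit = _window_ols(cx, cy, cxx, cxy, cyy, i, j)
            if fit is None:
                continue
            if x2[i:j].max() - x2[i:j].min() < min_spread:
                continue
            a, b, se_a, se_b, r2, rms = fit
            if r2 < min_r2:
                continue
            # the slope IS the reversal potential: demand real precision,
            # both realized and as predicted from the measurement errors
            if se_a > max_se:
                continue
            sig_med = float(np.median(s2[i:j]))
            vx = (cxx[j] - cxx[i]
                  - (cx[j] - cx[i]) ** 2 / ln)
            if sig_med > 0 and sig_med / np.sqrt(vx) > max_se:
                continue
            # residuals must be consistent with the per-bin I0 error:
            # SSR/sigma^2 ~ chi2(n-2), so rms well beyond sigma signals
            # curvature (the window has left the boundary line)
            if rms > 1.3 * sig_med + rms_cap_floor:
                continue
            tol = 2.0 * (rms + sig_med) + 1e-9 * max(1.0, np.abs(y).max())
            inside = np.zeros(m, dtype=bool)
            inside[np.arange(i, j) % m] = True
            excess = sign * (y[~inside] - (a * x[~inside] + b))
            if np.any(excess > tol):
                continue
            score = ln / max(rms, sig_med, score_floor)
            if score > best_score:
                best_score = score
                best = BoundaryLine(slope=a, intercept=b, se_slope=se_a,
                                    se_intercept=se_b, r2=r2,
                                    bins=idx[np.arange(i, j) % m],
                                    contained=True)
    return best


def fit_upper_boundary(G, I0, valid, config: PipelineConfig, sigma=None
                       ) -> Optional[BoundaryLine]:
    """Zero-excitation line: slope -Ei, intercept -Ge0*(Ee - Ei)."""
    return _fit_boundary(np.asarray(G, float), np.asarray(I0, float),
                         np.asarray(valid, bool), "upper",
                         config.min_boundary_bins, config.min_boundary_r2,
                         sigma=sigma, max_se=config.max_boundary_se)


def fit_lower_boundary(G, I0, valid, config: PipelineConfig, sigma=None
                       ) -> Optional[BoundaryLine]:
    """Zero-inhibition line: slope -Ee, intercept Gi0*(Ee - Ei)."""
    return _fit_boundary(np.asarray(G, float), np.asarray(I0, float),
                         np.asarray(valid, bool), "lower",
                         config.min_boundary_bins, config.min_boundary_r2,
                         sigma=sigma, max_se=config.max_boundary_se)


def fit_wedge(G, V0, valid, config: PipelineConfig,
              dG=None, dV0=None) -> WedgeFit:
    """Build the wedge diagram and estimate the reversal potentials.

    The lower boundary is accepted only when its slope corresponds to an
    excitatory reversal within the configured plausibility window;
    otherwise Ee falls back to the configured default.  If the upper fit
    yields an estimate not below the excitatory reversal (a degenerate
    single-line trajectory), it is reported but marked inconsistent.
    """
    G = np.asarray(G, dtype=float)
    V0 = np.asarray(V0, dtype=float)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(G) & np.isfinite(V0)
    I0 = compute_I0(G, V0)
    sigma = None
    if dG is not None and dV0 is not None:
        # first-order error of I0 = -G*V0 from the per-bin fit errors
        sigma = np.sqrt((np.asarray(V0) * np.asarray(dG)) ** 2
                        + (G * np.asarray(dV0)) ** 2)
        sigma = np.where(np.isfinite(sigma), sigma, 0.0)
    notes = []
    n_valid = int(valid.sum())
    if n_valid < config.min_boundary_bins:
        return WedgeFit(G=G, I0=I0, valid=valid, upper_line=None,
                        lower_line=None, e_i_hat=None, e_i_se=None,
                        e_e_hat=config.e_e_default, e_e_defaulted=True,
                        notes=["too few points"])
    upper = fit_upper_boundary(G, I0, valid, config, sigma=sigma)
    lower = fit_lower_boundary(G, I0, valid, config, sigma=sigma)

    e_e_hat = config.e_e_default
    e_e_defaulted = True
    if lower is not None:
        cand = -lower.slope
        lo, hi = config.e_e_accept
        if lo <= cand <= hi:
            e_e_hat = float(cand)
            e_e_defaulted = False
        else:
            notes.append("lower boundary slope implausible; defaulted")
    else:
        notes.append("no lower boundary; defaulted")

    e_i_hat = None
    e_i_se = None
    if upper is not None:
        e_i_hat = float(-upper.slope)
        e_i_se = float(upper.se_slope)
        if e_i_hat >= e_e_hat:
            notes.append("upper boundary inconsistent (e_i >= e_e)")
    else:
        notes.append("no upper boundary")
    return WedgeFit(G=G, I0=I0, valid=valid, upper_line=upper,
                    lower_line=lower, e_i_hat=e_i_hat, e_i_se=e_i_se,
                    e_e_hat=float(e_e_hat), e_e_defaulted=e_e_defaulted,
                    notes=notes)


def usable_e_i(fit: WedgeFit) -> Optional[float]:
    """The wedge inhibitory-reversal estimate, or None if unusable."""
    if fit.e_i_hat is None:
        return None
    if fit.e_i_hat >= fit.e_e_hat:
        return None
    return fit.e_i_hat
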