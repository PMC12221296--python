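"""Parameter-recovery scoring against simulator ground truth.

The recovered profile lives on the detected-cycle phase axis; the fair
comparison is therefore against the true conductance evaluated at the
very sample times each phase bin pooled, not against the waveform on the
simulator's internal phase convention (the burst-onset definition itself
carries a small systematic offset).
"""

from __future__ import annotations

import numpy as np

from .connectome import MotifReport
from .decomposition import significance
from .pipeline import PipelineResult
from .regression import bin_by_phase
from .simulate import EXCITATORY, INHIBITORY, GroundTruth


def binned_truth(result: PipelineResult, truth: GroundTruth) -> dict:
    """True per-bin conductances over the samples the regression pooled.

    Returns per-bin means of the true gi, ge and total G = g_leak + gi +
    ge at the analysis-sample times assigned to each bin, together with
    the true dynamic components (minimum over the same valid bins
    subtracted) and the true leak-estimate target g_leak + min gi +
    min ge.
    """
    phase = result.samples["phase"]
    t = result.samples["time"]
    bins, _ = bin_by_phase(phase, result.config.n_bins)
    n_bins = result.config.n_bins
    gi = np.full(n_bins, np.nan)
    ge = np.full(n_bins, np.nan)
    for i, idx in enumerate(bins):
        if idx.size:
            gi[i] = float(np.mean(truth.gi_at_time(t[idx])))
            ge[i] = float(np.mean(truth.ge_at_time(t[idx])))
    G = truth.params.g_leak + gi + ge
    valid = result.profile.valid & np.isfinite(gi)
    min_i = np.min(gi[valid])
    min_e = np.min(ge[valid])
    return {
        "gi": gi, "ge": ge, "G": G, "valid": valid,
        "dGi": np.where(valid, gi - min_i, np.nan),
        "dGe": np.where(valid, ge - min_e, np.nan),
        "g_leak_target": truth.params.g_leak + min_i + min_e,
    }


def recovery_errors(result: PipelineResult, truth: GroundTruth) -> dict:
    """RMSE of the recovered dynamic components and total conductance.

    RMSEs are reported both in nS and as fractions of the corresponding
    true component peak.
    """
    tb = binned_truth(result, truth)
    prof = result.profile
    m = tb["valid"] & prof.valid
    out = {"n_bins": int(m.sum())}
    for key, rec, tru in (("dGi", prof.dGi_dyn, tb["dGi"]),
                          ("dGe", prof.dGe_dyn, tb["dGe"]),
                          ("G", prof.G, tb["G"])):
        err = rec[m] - tru[m]
        rmse = float(np.sqrt(np.mean(err**2)))
        peak = float(np.max(np.abs(tru[m])))
        out[f"rmse_{key}"] = rmse
        out[f"rmse_{key}_frac"] = rmse / peak if peak > 0 else np.nan
    out["g_leak_est"] = prof.g_leak_est
    out["g_leak_target"] = tb["g_leak_target"]
    return out


def check_motif_recovery(report: MotifReport, truth: GroundTruth) -> dict:
    """Compare inferred edges with the fixture's ground-truth sources.

    Recovery holds when every ground-truth (source, sign) appears among
    the inferred edges; an edge is wrong-signed when the fixture drove
    the same source with the opposite sign.  Extra edges of an
    uncontradicted sign (e.g. near-tie templates) are tolerated.
    """
    want = {(s, sign) for sign in (INHIBITORY, EXCITATORY)
            for s in truth.sources.get(sign, {})}
    got = report.edge_set()
    opposite = {INHIBITORY: EXCITATORY, EXCITATORY: INHIBITORY}
    wrong = {(s, sign) for (s, sign) in got
             if (s, opposite[sign]) in want and (s, sign) not in want}
    return {
        "recovered": want <= got,
        "missing": sorted(want - got),
        "wrong_sign": sorted(wrong),
        "extra": sorted(got - want),
        "ok": (want <= got) and not wrong,
    }


def null_ztest_fraction(n_bins: int, dG: float, rng,
                        alpha: float = 0.05) -> float:
    """Type-I calibration of the one-tailed dynamic-component z-test.

    Simulates ``n_bins`` independent replicates of the per-bin test
    under a constant truth (dynamic component identically zero): each
    replicate draws a conductance estimate and an independent
    reference-minimum estimate with the same standard error, forms the
    dynamic component and its propagated error, and the function returns
    the fraction of replicates the z-test calls significant.
    """
    eps = rng.normal(0.0, dG, size=n_bins)
    eps_ref = rng.normal(0.0, dG, size=n_bins)
    delta = eps - eps_ref
    err = np.full(n_bins, np.sqrt(2.0) * dG)
    _, _, sig = significance(delta, err, alpha=alpha)
    return float(np.mean(sig))
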