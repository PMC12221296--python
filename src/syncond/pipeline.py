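"""End-to-end reconstruction pipeline.

Stages: spike filtration of the measured channel, downsampling to the
analysis rate, rectification/integration of the reference signal, burst
detection and cycle segmentation, quality control, phase assignment,
sample selection (hyperpolarized voltage window, post-step transients
excluded), phase-binned I-V regression, wedge reversal estimation,
conductance decomposition with significance, and motif inference.

The pipeline is deterministic: identical recording + configuration give
identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .connectome import MotifReport, PhaseWindows, classify_inputs, infer_motif
from .core import (
    CURRENT_CLAMP,
    PipelineConfig,
    QCError,
    Recording,
    ReversalPair,
)
from .decomposition import ConductanceProfile, build_profile
from .preprocess import (
    CycleSet,
    QCReport,
    compute_phase,
    detect_burst_onsets,
    downsample,
    qc_epoch,
    rectify_integrate,
    remove_spikes,
)
from .regression import PhaseRegressionTable, regress_by_phase, total_conductance
from .wedge import WedgeFit, fit_wedge, usable_e_i

logger = logging.getLogger("syncond")


@dataclass
class PipelineResult:
    """All intermediate and final products of one reconstruction run."""

    config: PipelineConfig
    cycles: CycleSet
    qc: QCReport
    table: PhaseRegressionTable
    wedge: WedgeFit
    profile: ConductanceProfile
    reversals: ReversalPair
    motifs: Optional[MotifReport] = None
    windows: Optional[PhaseWindows] = None
    # analysis-rate sample arrays (diagnostics / recovery scoring)
    samples: dict = field(default_factory=dict)


def preprocess_recording(recording: Recording, config: PipelineConfig):
    """Filter, downsample and segment a raw recording.

    Returns ``(ds, cycles)`` where ``ds`` is a dict of analysis-rate
    arrays (time, vm, i_inj, integrated reference).
    """
    fs = recording.sample_rate
    vm = recording.vm
    i_inj = recording.i_inj
    if recording.clamp_mode == CURRENT_CLAMP:
        vm = remove_spikes(vm, config.median_window, fs)
    else:
        i_inj = remove_spikes(i_inj, config.median_window, fs)
    integ = rectify_integrate(recording.ref, config.integrator_tau, fs)
    ds = {
        "time": downsample(recording.time, fs, config.target_rate),
        "vm": downsample(vm, fs, config.target_rate),
        "i_inj": downsample(i_inj, fs, config.target_rate),
        "integrated": downsample(integ, fs, config.target_rate),
    }
    cycles = detect_burst_onsets(ds["time"], ds["integrated"],
                                 threshold_frac=config.burst_threshold_frac)
    logger.info("preprocess: %d cycles, cv=%.4f, duty=%.3f",
                cycles.n_cycles, cycles.cv_period,
                cycles.inspiratory_fraction)
    return ds, cycles


def select_samples(ds: dict, cycles: CycleSet, mode: str,
                   config: PipelineConfig):
    """Phase-assign analysis samples and apply the selection masks.

    Keeps samples inside the detected cycle span and outside the
    transient window after each change of the controlled channel.  (The
    hyperpolarized-voltage restriction is applied later, per bin and
    level, inside the regression.)
    """
    phase, in_span = compute_phase(ds["time"], cycles)
    controlled = ds["i_inj"] if mode == CURRENT_CLAMP else ds["vm"]
    tol = config.plateau_tol if mode == CURRENT_CLAMP else config.level_tol_vc
    change = np.abs(np.diff(controlled)) > tol
    dt = 1.0 / config.target_rate
    k = int(np.ceil(config.transient_window / dt))
    settled = np.ones(controlled.size, dtype=bool)
    for j in np.flatnonzero(change):
        settled[j + 1: j + 1 + k] = False
    keep = in_span & settled
    phase = np.where(keep, phase, np.nan)
    return phase, keep


def reconstruct(recording: Recording, config: Optional[PipelineConfig] = None,
                force: bool = False) -> PipelineResult:
    """Run the conductance reconstruction on one epoch.

    Reversal potentials: user-supplied values in ``config.reversals``
    win; otherwise the wedge-diagram estimate of Ei is used (falling back
    to the midpoint of ``e_i_range``) and Ee comes from the lower
    boundary when identifiable, else ``e_e_default``.

    Raises :class:`~syncond.core.QCError` when the epoch fails quality
    control, unless ``force``.
    """
    config = config or PipelineConfig()
    ds, cycles = preprocess_recording(recording, config)
    ds_rec = Recording(time=ds["time"], vm=ds["vm"], i_inj=ds["i_inj"],
                       ref=ds["integrated"], sample_rate=config.target_rate,
                       clamp_mode=recording.clamp_mode,
                       metadata=dict(recording.metadata))
    qc = qc_epoch(ds_rec, cycles, config)
    if not qc.passed and not force:
        raise QCError(qc)

    phase, keep = select_samples(ds, cycles, recording.clamp_mode, config)
    table = regress_by_phase(phase, ds["vm"], ds["i_inj"],
                             recording.clamp_mode, config)
    total = total_conductance(table)
    wedge = fit_wedge(total.G, table.V0, total.valid, config,
                      dG=total.dG, dV0=table.dV0)
    logger.info("wedge: e_i_hat=%s e_e_hat=%.1f (defaulted=%s)",
                wedge.e_i_hat, wedge.e_e_hat, wedge.e_e_defaulted)

    if config.reversals is not None:
        reversals = config.reversals
    else:
        e_i = usable_e_i(wedge)
        if e_i is None:
            e_i = 0.5 * (config.e_i_range[0] + config.e_i_range[1])
        e_e = wedge.e_e_hat
        if not (e_i < e_e):
            e_e = config.e_e_default
        reversals = ReversalPair(e_i=float(e_i), e_e=float(e_e))
    profile = build_profile(table, total, reversals, alpha=config.alpha,
                            config_hash=config.hash())
    logger.info("profile: g_leak_est=%.3f nS, Ei=%.1f, Ee=%.1f",
                profile.g_leak_est, reversals.e_i, reversals.e_e)
    return PipelineResult(
        config=config, cycles=cycles, qc=qc, table=table, wedge=wedge,
        profile=profile, reversals=reversals,
        samples={"time": ds["time"], "phase": phase, "keep": keep,
                 "vm": ds["vm"], "i_inj": ds["i_inj"]})


def phase_windows_for(result: PipelineResult,
                      config: PipelineConfig) -> PhaseWindows:
    """Phase windows from configuration or the detected burst duty cycle."""
    r = config.inspiratory_fraction
    if r is None:
        r = result.cycles.inspiratory_fraction
    r = float(min(max(r, 0.05), 0.9))
    w = (1.0 - r) / 2.0
    return PhaseWindows(r=r, w=w)


def run_pipeline(recording: Recording,
                 config: Optional[PipelineConfig] = None,
                 target: Optional[str] = None,
                 force: bool = False) -> PipelineResult:
    """Full pipeline: reconstruction plus motif inference.

    ``target`` names the recorded neuron's firing phenotype for the motif
    report; when omitted, motif inference is skipped.
    """
    config = config or PipelineConfig()
    result = reconstruct(recording, config, force=force)
    if target is not None:
        windows = phase_windows_for(result, config)
        labels = classify_inputs(result.profile, windows,
                                 min_frac=config.sig_fraction,
                                 min_rel_peak=config.min_rel_peak)
        result.motifs = infer_motif(result.profile, labels, target,
                                    windows=windows,
                                    tie_margin=config.tie_margin)
        result.windows = windows
        logger.info("motifs: %d edges, %d unexplained",
                    len(result.motifs.edges),
                    len(result.motifs.unexplained))
    return result
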