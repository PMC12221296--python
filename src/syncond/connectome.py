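"""Functional-connectome motif inference.

A functional connection from a source population to the recorded neuron
is asserted when the neuron's dynamic synaptic conductance component is
statistically significant in the phase window corresponding to that
population's activity pattern.  Windows follow the three-phase cycle
organization: inspiration (I), post-inspiration (post-I) and late
expiration (E2).  The inferred edge carries only the synaptic sign; no
claim about transmitter identity or anatomical location is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ValidationError
from .decomposition import ConductanceProfile
from .simulate import (
    EXCITATORY,
    INHIBITORY,
    PHENOTYPES,
    phenotype_activity,
)

WINDOW_NAMES = ("inspiration", "post_I", "E2")


@dataclass(frozen=True)
class PhaseWindows:
    """Partition of the cycle into I, post-I and E2 windows.

    ``r`` is the inspiratory fraction, ``w`` the post-inspiratory
    fraction: inspiration [0, r), post-I [r, r+w), E2 [r+w, 1).
    """

    r: float = 0.33
    w: float = 0.33

    def __post_init__(self):
        if not (0.0 < self.r < 1.0 and 0.0 < self.w < 1.0 - self.r):
            raise ValidationError("windows must partition [0, 1)")

    def edges(self, name: str):
        if name == "inspiration":
            return (0.0, self.r)
        if name == "post_I":
            return (self.r, self.r + self.w)
        if name == "E2":
            return (self.r + self.w, 1.0)
        raise ValidationError(f"unknown window {name!r}")

    def bin_masks(self, phase_center: np.ndarray) -> dict:
        masks = {}
        for name in WINDOW_NAMES:
            lo, hi = self.edges(name)
            masks[name] = (phase_center >= lo) & (phase_center < hi)
            if not masks[name].any():
                raise ValidationError(f"window {name} spans no bin")
        return masks


@dataclass
class WindowLabel:
    """A phase window in which one synaptic sign is present."""

    window: str
    sign: str                  # inhibitory | excitatory
    frac_significant: float
    peak: float                # nS, peak dynamic component in the window
    peak_phase: float


@dataclass
class Edge:
    """One inferred functional connection onto the recorded neuron."""

    source: str
    sign: str
    windows: list
    score: float


@dataclass
class MotifReport:
    """Inferred input motif of one recorded neuron."""

    target: str
    edges: list = field(default_factory=list)
    unexplained: list = field(default_factory=list)

    def edge_set(self):
        return {(e.source, e.sign) for e in self.edges}


def classify_inputs(profile: ConductanceProfile, windows: PhaseWindows,
                    min_frac: float = 0.25,
                    min_rel_peak: float = 0.10) -> list:
    """Label each phase window with the synaptic signs present.

    A window is labeled for a sign when at least ``min_frac`` of its
    valid bins have a significant dynamic component of that sign and the
    window's peak dynamic component reaches ``min_rel_peak`` of that
    component's cycle-wide maximum.  The relative-peak floor guards
    against reading the small spillover produced by a slightly
    mis-estimated reversal potential (which leaks a scaled copy of one
    component into the other, and with long epochs is statistically
    significant at few-percent amplitude) as a synaptic input.
    """
    masks = windows.bin_masks(profile.phase_center)
    labels = []
    for name, mask in masks.items():
        m = mask & profile.valid
        if not m.any():
            continue
        for sign, sig, comp in (
                (INHIBITORY, profile.significant_i(), profile.dGi_dyn),
                (EXCITATORY, profile.significant_e(), profile.dGe_dyn)):
            frac = float(np.mean(sig[m]))
            peak_ok = (np.nanmax(comp[m])
                       >= min_rel_peak * np.nanmax(comp[profile.valid]))
            if frac >= min_frac and peak_ok:
                k = np.flatnonzero(m)[np.nanargmax(comp[m])]
                labels.append(WindowLabel(
                    window=name, sign=sign, frac_significant=frac,
                    peak=float(comp[k]),
                    peak_phase=float(profile.phase_center[k])))
    return labels


def _window_score(activity: np.ndarray, waveform: np.ndarray,
                  m: np.ndarray) -> float:
    """Pearson correlation of a template with the windowed waveform."""
    a = activity[m]
    w = waveform[m]
    ok = np.isfinite(w)
    if ok.sum() < 3:
        return -np.inf
    a, w = a[ok], w[ok]
    if a.std() == 0 or w.std() == 0:
        return -np.inf
    return float(np.corrcoef(a, w)[0, 1])


def infer_motif(profile: ConductanceProfile, labels: list, target: str,
                windows: Optional[PhaseWindows] = None,
                candidates=PHENOTYPES, tie_margin: float = 0.05,
                min_score: float = 0.0) -> MotifReport:
    """Translate window labels into population-level connections.

    For each labeled window and sign, candidate sources are the phenotype
    templates whose activity overlaps the window; the template whose
    activity best correlates with the windowed dynamic-conductance
    waveform is selected.  Near-ties (score within ``tie_margin``) report
    all tied candidates; recurrent self-edges are permitted.  Windows
    matched by no template land in ``unexplained``.
    """
    windows = windows or PhaseWindows()
    masks = windows.bin_masks(profile.phase_center)
    edges: dict = {}
    unexplained = []
    for label in labels:
        m = masks[label.window] & profile.valid
        waveform = (profile.dGi_dyn if label.sign == INHIBITORY
                    else profile.dGe_dyn)
        scores = {}
        for name in candidates:
            activity = phenotype_activity(name, profile.phase_center)
            if not np.any((activity > 1e-9) & m):
                continue        # no overlap with the window
            s = _window_score(activity, waveform, m)
            if np.isfinite(s) and s > min_score:
                scores[name] = s
        if not scores:
            unexplained.append(label.window + ":" + label.sign)
            continue
        best = max(scores.values())
        for name, s in scores.items():
            if s >= best - tie_margin:
                key = (name, label.sign)
                if key in edges:
                    edges[key].windows.append(label.window)
                    edges[key].score = max(edges[key].score, s)
                else:
                    edges[key] = Edge(source=name, sign=label.sign,
                                      windows=[label.window], score=s)
    return MotifReport(target=target, edges=list(edges.values()),
                       unexplained=unexplained)
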