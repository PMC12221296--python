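"""Conductance-based single-compartment neuron simulator.

Forward-simulates the current-balance equation

    C dVm/dt = g_leak (E_leak - Vm) + g_i(t) (E_i - Vm)
             + g_e(t) (E_e - Vm) + I_inj(t)

for a neuron driven by prescribed periodic synaptic conductance waveforms
under stepwise current-clamp or voltage-clamp protocols, together with a
burst-shaped synthetic reference nerve signal.  Ground truth is retained
for parameter-recovery testing.

The phenotype fixtures assemble the synaptic drive of each canonical
respiratory firing phenotype (pre-I/I, ramp-I, early-I, late-I, post-I,
aug-E) as a weighted sum of the canonical population activity waveforms,
so the sources used to build a fixture double as the expected functional
connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numba
import numpy as np

from .core import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    ParameterError,
    Recording,
    ValidationError,
)

INHIBITORY = "inhibitory"
EXCITATORY = "excitatory"

PHENOTYPES = ("pre-I/I", "ramp-I", "early-I", "late-I", "post-I", "aug-E")

#: Canonical population activity waveforms on the phase axis, peak 1.
#: Breakpoints (phi, activity) with linear interpolation; the cycle is
#: inspiration [0, 0.33), post-inspiration [0.33, 0.66), late expiration
#: (E2) [0.66, 1).  Activity is continuous across the cycle wrap.
PHENOTYPE_BREAKPOINTS = {
    # fires just before and throughout inspiration, decrementing
    "pre-I/I": [(0.0, 1.0), (0.25, 0.15), (0.33, 0.0), (0.92, 0.0),
                (1.0, 1.0)],
    # augmenting inspiratory ramp
    "ramp-I": [(0.0, 0.0), (0.25, 1.0), (0.33, 0.0), (1.0, 0.0)],
    # peaks shortly after inspiratory onset, decrementing
    "early-I": [(0.0, 0.0), (0.08, 1.0), (0.30, 0.05), (0.33, 0.0),
                (1.0, 0.0)],
    # confined to late inspiration
    "late-I": [(0.0, 0.0), (0.17, 0.0), (0.25, 1.0), (0.33, 0.0),
               (1.0, 0.0)],
    # decrementing post-inspiratory discharge
    "post-I": [(0.0, 0.0), (0.33, 0.0), (0.41, 1.0), (0.66, 0.0),
               (1.0, 0.0)],
    # augmenting through late expiration
    "aug-E": [(0.0, 0.0), (0.66, 0.0), (0.92, 1.0), (1.0, 0.0)],
}

#: Synaptic input composition of each phenotype fixture: weights (nS) on
#: the source populations' activity waveforms.
FIXTURE_INPUTS = {
    "pre-I/I": {INHIBITORY: {"post-I": 6.0},
                EXCITATORY: {"aug-E": 2.0, "ramp-I": 3.0}},
    "ramp-I": {INHIBITORY: {"post-I": 6.0, "aug-E": 5.0},
               EXCITATORY: {"pre-I/I": 3.0}},
    "early-I": {INHIBITORY: {"post-I": 6.0},
                EXCITATORY: {"pre-I/I": 3.0}},
    "late-I": {INHIBITORY: {"post-I": 5.0, "aug-E": 4.0, "early-I": 4.0},
               EXCITATORY: {"ramp-I": 3.0}},
    "post-I": {INHIBITORY: {"early-I": 7.0, "aug-E": 5.0},
               EXCITATORY: {"post-I": 2.0, "ramp-I": 2.0}},
    "aug-E": {INHIBITORY: {"early-I": 6.0, "post-I": 6.0},
              EXCITATORY: {"aug-E": 3.0}},
}


def phenotype_activity(name: str, phi) -> np.ndarray:
    """Canonical activity waveform of a firing phenotype at phases phi."""
    if name not in PHENOTYPE_BREAKPOINTS:
        raise ParameterError(f"unknown phenotype {name!r}; "
                             f"choose from {PHENOTYPES}")
    pts = np.asarray(PHENOTYPE_BREAKPOINTS[name], dtype=float)
    phi = np.mod(np.asarray(phi, dtype=float), 1.0)
    return np.interp(phi, pts[:, 0], pts[:, 1])


@dataclass(frozen=True)
class NeuronParams:
    """Passive membrane and synaptic reversal parameters.

    Defaults give g_leak/C = 100 pS/pF, i.e. a 10 ms membrane time
    constant, representative of the respiratory interneurons the method
    was developed on.  ``noise_sd`` is the mV-equivalent standard
    deviation of the additive white current noise at steady state.
    """

    C: float = 100.0            # pF
    g_leak: float = 10.0        # nS
    E_leak: float = -60.0       # mV
    E_i: float = -90.0          # mV
    E_e: float = -10.0          # mV
    spike_threshold: Optional[float] = None  # mV; None disables spiking
    spike_reset: float = -65.0  # mV
    spike_peak: float = 30.0    # mV, rendered spike height
    noise_sd: float = 0.0       # mV
    rng_seed: int = 0

    def __post_init__(self):
        if self.C <= 0 or self.g_leak <= 0:
            raise ValidationError("C and g_leak must be positive")
        if not (self.E_i < self.E_e):
            raise ValidationError("require E_i < E_e")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_leak in seconds."""
        return self.C / self.g_leak * 1e-3


@dataclass(frozen=True)
class ConductanceTemplate:
    """One periodic synaptic conductance waveform component.

    ``shape`` selects the profile over the phase window [phi_on, phi_off)
    (baseline outside); ``piecewise`` uses explicit breakpoints.
    ``smooth`` applies a circular Hann smoothing of the given phase width
    to the waveform — convergent synaptic drive has no kinks, and the
    quasi-static analysis assumes drive that varies slowly relative to
    the membrane time constant.
    """

    shape: str                  # ramp|incrementing|decrementing|bell|
                                # constant|piecewise
    window: tuple = (0.0, 1.0)  # [phi_on, phi_off)
    peak: float = 1.0           # nS
    baseline: float = 0.0       # nS
    breakpoints: Optional[tuple] = None  # ((phi, value), ...) for piecewise
    smooth: float = 0.0         # phase width of circular Hann smoothing

    _GRID = 4096

    def __post_init__(self):
        on, off = self.window
        if not (0.0 <= on < off <= 1.0):
            raise ValidationError(
                "window must satisfy 0 <= phi_on < phi_off <= 1 "
                "(wrap-around via two segments)")
        if not (self.peak >= self.baseline >= 0.0):
            raise ValidationError("require peak >= baseline >= 0")
        if self.smooth > 0:
            grid = (np.arange(self._GRID) + 0.5) / self._GRID
            vals = self._raw(grid)
            k = max(int(round(self.smooth * self._GRID)) | 1, 3)
            kern = np.hanning(k + 2)[1:-1]
            kern = kern / kern.sum()
            half = k // 2
            padded = np.concatenate([vals[-half:], vals, vals[:half]])
            smoothed = np.convolve(padded, kern, mode="valid")
            object.__setattr__(self, "_smoothed", smoothed)

    def __call__(self, phi) -> np.ndarray:
        phi = np.mod(np.asarray(phi, dtype=float), 1.0)
        if self.smooth > 0:
            grid = (np.arange(self._GRID) + 0.5) / self._GRID
            return np.interp(phi, grid, self._smoothed, period=1.0)
        return self._raw(phi)

    def _raw(self, phi) -> np.ndarray:
        if self.shape == "piecewise":
            pts = np.asarray(self.breakpoints, dtype=float)
            return np.interp(phi, pts[:, 0], pts[:, 1])
        on, off = self.window
        inside = (phi >= on) & (phi < off)
        u = np.zeros_like(phi)
        u[inside] = (phi[inside] - on) / (off - on)
        span = self.peak - self.baseline
        out = np.full(phi.shape, self.baseline)
        if self.shape == "constant":
            out[inside] = self.peak
        elif self.shape in ("ramp", "incrementing"):
            out[inside] = self.baseline + span * u[inside]
        elif self.shape == "decrementing":
            out[inside] = self.baseline + span * (1.0 - u[inside])
        elif self.shape == "bell":
            # raised cosine: smooth (zero-slope) at the window edges
            out[inside] = self.baseline + span * 0.5 * (
                1.0 - np.cos(2.0 * np.pi * u[inside]))
        else:
            raise ParameterError(f"unknown template shape {self.shape!r}")
        return out


def sum_waveforms(templates: Sequence, phi) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    total = np.zeros(phi.shape)
    for tmpl in templates:
        total = total + tmpl(phi)
    return total


@dataclass(frozen=True)
class Protocol:
    """Stepwise stimulation protocol.

    ``levels`` are held injected currents (pA, current clamp) or holding
    potentials (mV, voltage clamp); each level is held for
    ``cycles_per_level`` full cycles of the ``period``-second rhythm.
    """

    mode: str = CURRENT_CLAMP
    levels: tuple = (-250.0, -200.0, -150.0, -100.0, -50.0)
    cycles_per_level: int = 10
    period: float = 3.0             # s
    sample_rate: float = 12500.0    # Hz
    inspiratory_fraction: float = 0.33

    def __post_init__(self):
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.period <= 0 or self.sample_rate <= 0:
            raise ValidationError("period and sample_rate must be positive")
        if len(self.levels) < 1 or self.cycles_per_level < 1:
            raise ValidationError("need >= 1 level held >= 1 cycle")
        if not (0.0 < self.inspiratory_fraction < 1.0):
            raise ValidationError("inspiratory_fraction must be in (0, 1)")

    @property
    def n_cycles(self) -> int:
        return len(self.levels) * self.cycles_per_level


@dataclass
class GroundTruth:
    """Everything needed to score a recovery against the simulation."""

    gi_templates: tuple
    ge_templates: tuple
    params: NeuronParams
    protocol: Protocol
    t_first_onset: float        # time of the first true cycle onset, s
    gi_of_phi: np.ndarray       # true waveforms on the 100-bin grid, nS
    ge_of_phi: np.ndarray
    sources: dict = field(default_factory=dict)  # sign -> {source: weight}
    phenotype: Optional[str] = None

    def true_phase(self, t) -> np.ndarray:
        return np.mod((np.asarray(t, float) - self.t_first_onset)
                      / self.protocol.period, 1.0)

    def gi_at_time(self, t) -> np.ndarray:
        return sum_waveforms(self.gi_templates, self.true_phase(t))

    def ge_at_time(self, t) -> np.ndarray:
        return sum_waveforms(self.ge_templates, self.true_phase(t))


@numba.njit(cache=True)
def _euler_cc(v0, dt, C, gl, El, gi, ge, Ei, Ee, iinj, inoise,
              spiking, thr, vreset, vpeak):  # pragma: no cover - jit
    n = gi.size
    vm = np.empty(n)
    v = v0
    for k in range(n):
        vm[k] = v
        I = (gl * (El - v) + gi[k] * (Ei - v) + ge[k] * (Ee - v)
             + iinj[k] + inoise[k])
        v = v + dt * I / C * 1e3  # pA/pF -> V/s; *1e3 -> mV/s
        if spiking and v >= thr:
            vm[k] = vpeak
            v = vreset
    return vm


def _reference_signal(phi, r):
    """Phrenic-like burst envelope: sharp onset, augmenting, abrupt end."""
    phi = np.asarray(phi, dtype=float)
    env = np.zeros(phi.shape)
    inside = phi < r
    env[inside] = 0.55 + 0.45 * phi[inside] / r
    return env


def simulate(params: NeuronParams, gi_templates: Sequence,
             ge_templates: Sequence, protocol: Protocol,
             sources: Optional[dict] = None,
             phenotype: Optional[str] = None):
    """Forward-simulate one stimulation epoch.

    Returns ``(Recording, GroundTruth)``.  Current clamp integrates the
    membrane equation with forward Euler at the protocol sample rate
    (stability-checked against tau_m/10); voltage clamp records the
    current required to hold each commanded level.  The synthetic
    reference signal is a burst envelope over the inspiratory window plus
    small noise.  All randomness is drawn from ``params.rng_seed``.
    """
    dt = 1.0 / protocol.sample_rate
    if dt > params.tau_m / 10.0:
        raise ParameterError(
            f"sample interval {dt:g} s too large for stability "
            f"(tau_m/10 = {params.tau_m / 10:g} s)")
    T = protocol.period
    t0 = 0.5 * T                       # first true cycle onset
    n_cycles = protocol.n_cycles
    duration = t0 + (n_cycles + 0.25) * T
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    phi = np.mod((t - t0) / T, 1.0)
    gi = sum_waveforms(gi_templates, phi)
    ge = sum_waveforms(ge_templates, phi)

    cyc = np.floor((t - t0) / T).astype(int)
    lvl_idx = np.clip(cyc // protocol.cycles_per_level, 0,
                      len(protocol.levels) - 1)
    levels = np.asarray(protocol.levels, dtype=float)[lvl_idx]

    rng = np.random.default_rng(params.rng_seed)
    if params.noise_sd > 0:
        g_ref = params.g_leak + gi.mean() + ge.mean()   # nS
        # white current noise whose stationary voltage sd equals noise_sd:
        # sigma_V^2 = sigma_I^2 * dt / (2 G C)  (SI units)
        sigma_i = (params.noise_sd * 1e-3
                   * np.sqrt(2.0 * g_ref * 1e-9 * params.C * 1e-12 / dt))
        inoise = rng.normal(0.0, sigma_i / 1e-12, size=n)  # pA
    else:
        inoise = np.zeros(n)

    if protocol.mode == CURRENT_CLAMP:
        i_inj = levels
        g_tot0 = params.g_leak + gi[0] + ge[0]
        v_init = (params.g_leak * params.E_leak + gi[0] * params.E_i
                  + ge[0] * params.E_e + i_inj[0]) / g_tot0
        spiking = params.spike_threshold is not None
        thr = params.spike_threshold if spiking else 0.0
        vm = _euler_cc(v_init, dt, params.C, params.g_leak, params.E_leak,
                       gi, ge, params.E_i, params.E_e, i_inj, inoise,
                       spiking, thr, params.spike_reset, params.spike_peak)
    else:
        vm = levels
        ionic = (params.g_leak * (params.E_leak - vm)
                 + gi * (params.E_i - vm) + ge * (params.E_e - vm))
        i_inj = -ionic + inoise        # clamp current, pA

    ref = _reference_signal(phi, protocol.inspiratory_fraction)
    ref = ref + rng.normal(0.0, 0.02, size=n)

    recording = Recording(time=t, vm=vm, i_inj=i_inj, ref=ref,
                          sample_rate=protocol.sample_rate,
                          clamp_mode=protocol.mode,
                          metadata={"simulated": True,
                                    "rng_seed": params.rng_seed,
                                    "phenotype": phenotype or ""})
    centers = (np.arange(100) + 0.5) / 100
    truth = GroundTruth(
        gi_templates=tuple(gi_templates), ge_templates=tuple(ge_templates),
        params=params, protocol=protocol, t_first_onset=t0,
        gi_of_phi=sum_waveforms(gi_templates, centers),
        ge_of_phi=sum_waveforms(ge_templates, centers),
        sources=sources or {}, phenotype=phenotype)
    return recording, truth


def phenotype_templates(phenotype: str):
    """(gi_templates, ge_templates, sources) of a phenotype fixture."""
    if phenotype not in FIXTURE_INPUTS:
        raise ParameterError(f"unknown phenotype {phenotype!r}; "
                             f"choose from {PHENOTYPES}")
    spec = FIXTURE_INPUTS[phenotype]

    def scaled(name, w):
        pts = [(p, w * v) for p, v in PHENOTYPE_BREAKPOINTS[name]]
        return ConductanceTemplate(shape="piecewise",
                                   breakpoints=tuple(pts), peak=w,
                                   smooth=0.05)

    gi = tuple(scaled(s, w) for s, w in spec[INHIBITORY].items())
    ge = tuple(scaled(s, w) for s, w in spec[EXCITATORY].items())
    sources = {INHIBITORY: dict(spec[INHIBITORY]),
               EXCITATORY: dict(spec[EXCITATORY])}
    return gi, ge, sources


def make_phenotype_fixture(phenotype: str, seed: int,
                           mode: str = CURRENT_CLAMP,
                           noise_sd: float = 0.5,
                           protocol: Optional[Protocol] = None,
                           params: Optional[NeuronParams] = None):
    """A QC-passing simulated epoch for one firing phenotype.

    The synaptic drive realizes the phenotype's canonical input pattern
    as a weighted sum of source-population activity waveforms; those
    sources are recorded in the ground truth as the expected functional
    connections.  Deterministic given ``seed``.
    """
    gi, ge, sources = phenotype_templates(phenotype)
    if protocol is None:
        if mode == CURRENT_CLAMP:
            protocol = Protocol(mode=mode)
        else:
            protocol = Protocol(mode=mode,
                                levels=(-100.0, -90.0, -80.0, -70.0, -60.0))
    if params is None:
        params = NeuronParams(noise_sd=noise_sd, rng_seed=seed)
    else:
        params = NeuronParams(**{**params.__dict__,
                                 "noise_sd": noise_sd, "rng_seed": seed})
    return simulate(params, gi, ge, protocol, sources=sources,
                    phenotype=phenotype)


def make_standard_fixture(seed: int, mode: str = CURRENT_CLAMP,
                          noise_sd: float = 0.5,
                          protocol: Optional[Protocol] = None,
                          params: Optional[NeuronParams] = None):
    """The standard parameter-recovery fixture.

    Smooth half-sine synaptic waveforms — a broad inhibitory bell over
    the expiratory half of the cycle and an inspiratory excitatory bell —
    under the default 5-level x 10-cycle, 3-s-period protocol.  The bell
    slopes keep tau_m * |dg/dt| well below 1% of each component's peak,
    so the quasi-static premise of the reconstruction holds and recovery
    error measures the estimator, not the membrane's low-pass filtering.
    """
    if params is None:
        params = NeuronParams(noise_sd=noise_sd, rng_seed=seed)
    else:
        params = NeuronParams(**{**params.__dict__,
                                 "noise_sd": noise_sd, "rng_seed": seed})
    if protocol is None:
        if mode == CURRENT_CLAMP:
            protocol = Protocol(mode=mode)
        else:
            protocol = Protocol(mode=mode,
                                levels=(-100.0, -90.0, -80.0, -70.0, -60.0))
    gi = (ConductanceTemplate(shape="bell", window=(0.30, 0.95), peak=8.0),)
    ge = (ConductanceTemplate(shape="bell", window=(0.00, 0.45), peak=3.0),)
    return simulate(params, gi, ge, protocol)


def make_wedge_fixture(seed: int, kind: str = "inhibitory",
                       noise_sd: float = 0.0,
                       protocol: Optional[Protocol] = None,
                       params: Optional[NeuronParams] = None):
    """Fixture with a one-sided synaptic drive for wedge estimation.

    ``kind='inhibitory'``: constant excitatory conductance and a broad
    inhibitory bell, so the whole (G, I0) trajectory traces the
    zero-excitation line (slope -Ei).  ``kind='excitatory'``: the mirror
    case tracing the zero-inhibition line (slope -Ee).
    """
    if params is None:
        params = NeuronParams(noise_sd=noise_sd, rng_seed=seed)
    else:
        params = NeuronParams(**{**params.__dict__,
                                 "noise_sd": noise_sd, "rng_seed": seed})
    if protocol is None:
        protocol = Protocol()
    const = ConductanceTemplate(shape="constant", window=(0.0, 1.0),
                                peak=1.0, baseline=1.0)
    if kind == "inhibitory":
        gi = (ConductanceTemplate(shape="bell", window=(0.35, 0.95),
                                  peak=18.0),)
        ge = (const,)
    elif kind == "excitatory":
        gi = (const,)
        ge = (ConductanceTemplate(shape="bell", window=(0.10, 0.60),
                                  peak=5.0),)
    else:
        raise ParameterError("kind must be 'inhibitory' or 'excitatory'")
    return simulate(params, gi, ge, protocol)
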