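"""Core domain types, unit conventions, configuration and errors.

Canonical units throughout the package:

====================  ======
quantity              unit
====================  ======
time                  s
membrane potential    mV
current               pA
resistance            MOhm
conductance           nS
capacitance           pF
====================  ======

The per-bin I-V regression naturally produces a slope in mV/pA, which is
GOhm; a single conversion constant below turns that into MOhm (and its
reciprocal into nS: 1 pA/mV = 1 nS).  All unit handling funnels through
these helpers so no module carries its own scale factors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: mV/pA (= GOhm) expressed in MOhm.
GOHM_TO_MOHM = 1000.0

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"
CLAMP_MODES = (CURRENT_CLAMP, VOLTAGE_CLAMP)


class SyncondError(Exception):
    """Base class for package errors."""


class ValidationError(SyncondError):
    """A domain-type invariant is violated."""


class FormatError(SyncondError):
    """A trace or result file does not follow the expected layout."""


class ParameterError(SyncondError):
    """An operation was called with out-of-range parameters."""


class DetectionError(SyncondError):
    """Burst/cycle detection could not find a usable rhythm."""


class EstimationError(SyncondError):
    """A fit (e.g. a wedge boundary line) could not be established."""


class QCError(SyncondError):
    """Epoch failed quality control; carries the structured report."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            "epoch failed quality control: " + ", ".join(report.reasons)
        )


def slope_to_resistance_mohm(slope_mv_per_pa: float) -> float:
    """Convert an I-V regression slope (mV/pA) to MOhm."""
    return GOHM_TO_MOHM * slope_mv_per_pa


def resistance_to_conductance(r_mohm):
    """G [nS] = 1000 / R [MOhm]."""
    return GOHM_TO_MOHM / np.asarray(r_mohm, dtype=float)


def conductance_error(r_mohm, dr_mohm):
    """Propagate the resistance standard error: dG = dR / R^2 (nS)."""
    r = np.asarray(r_mohm, dtype=float)
    return GOHM_TO_MOHM * np.asarray(dr_mohm, dtype=float) / (r * r)


def membrane_time_constant_ms(c_pf: float, g_leak_ns: float) -> float:
    """Membrane time constant tau_m = C / g_leak, in ms.

    With C in pF and g_leak in nS the ratio is already in ms
    (1 pF / 1 nS = 1 ms).
    """
    if c_pf <= 0 or g_leak_ns <= 0:
        raise ParameterError("C and g_leak must be positive")
    return c_pf / g_leak_ns


@dataclass
class Recording:
    """A time-aligned intracellular recording epoch.

    ``vm`` is the membrane potential (command potential in voltage clamp),
    ``i_inj`` the injected current (measured clamp current in voltage
    clamp) and ``ref`` the reference nerve signal used to define the cycle.
    """

    time: np.ndarray
    vm: np.ndarray
    i_inj: np.ndarray
    ref: np.ndarray
    sample_rate: float
    clamp_mode: str = CURRENT_CLAMP
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        self.i_inj = np.asarray(self.i_inj, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValidationError("recording must contain at least 2 samples")
        for name in ("vm", "i_inj", "ref"):
            if getattr(self, name).size != n:
                raise ValidationError(
                    f"channel '{name}' length {getattr(self, name).size} "
                    f"differs from time length {n}"
                )
        if not (self.sample_rate > 0):
            raise ValidationError("sample_rate must be positive")
        if self.clamp_mode not in CLAMP_MODES:
            raise ValidationError(f"unknown clamp_mode {self.clamp_mode!r}")
        dt = np.diff(self.time)
        step = 1.0 / self.sample_rate
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.max(np.abs(dt - step)) > 1e-9 * max(step, 1.0):
            raise ValidationError(
                "time grid is not uniform at the declared sample rate"
            )

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def slice_time(self, t0: float, t1: float) -> "Recording":
        """Return the sub-recording with t0 <= time < t1."""
        mask = (self.time >= t0) & (self.time < t1)
        if mask.sum() < 2:
            raise ValidationError("time slice contains fewer than 2 samples")
        return Recording(
            time=self.time[mask],
            vm=self.vm[mask],
            i_inj=self.i_inj[mask],
            ref=self.ref[mask],
            sample_rate=self.sample_rate,
            clamp_mode=self.clamp_mode,
            metadata=dict(self.metadata),
        )

    #: channel the experimenter controls (regressor of the I-V fit)
    @property
    def controlled(self) -> np.ndarray:
        return self.i_inj if self.clamp_mode == CURRENT_CLAMP else self.vm

    #: channel the amplifier measures (response of the I-V fit)
    @property
    def measured(self) -> np.ndarray:
        return self.vm if self.clamp_mode == CURRENT_CLAMP else self.i_inj


@dataclass(frozen=True)
class ReversalPair:
    """Inhibitory and excitatory synaptic reversal potentials, mV."""

    e_i: float
    e_e: float

    def __post_init__(self):
        if not (self.e_i < self.e_e):
            raise ValidationError(
                f"require e_i < e_e, got e_i={self.e_i}, e_e={self.e_e}"
            )


@dataclass
class PipelineConfig:
    """All tunable parameters of the reconstruction pipeline.

    Defaults follow the protocol the method was developed with: 100 phase
    bins per cycle, 0.1 s spike-filter window, analysis rate 100 Hz,
    0.05 s nerve-signal integrator, burst onset at 10% of burst amplitude,
    cycle-period CV < 10%, at least 3 current steps of at least 5 cycles
    each, excitatory reversal defaulting to -10 mV, and a one-tailed
    z-test at alpha = 0.05.
    """

    n_bins: int = 100
    median_window: float = 0.1          # s, spike-removal moving median
    target_rate: float = 100.0          # Hz, analysis sample rate
    integrator_tau: float = 0.05        # s, nerve-signal leaky integrator
    burst_threshold_frac: float = 0.10  # onset at this fraction of amplitude
    cv_max: float = 0.10                # max CV of the cycle period
    min_steps: int = 3                  # min distinct current steps
    min_cycles_per_step: int = 5        # min cycles each step is held
    e_e_default: float = -10.0          # mV, used when no lower boundary
    e_e_range: tuple = (-20.0, 0.0)     # mV, sensitivity-scan range
    e_i_range: tuple = (-110.0, -90.0)  # mV, sensitivity-scan range
    alpha: float = 0.05                 # significance level
    rng_seed: int = 0

    # regression sample selection
    n_min: int = 10                     # min samples per phase bin
    v_window: tuple = (-100.0, -60.0)   # mV, hyperpolarized analysis window
    transient_window: float = 0.05      # s, excluded after each step change
    plateau_tol: float = 5.0            # pA, current-step plateau tolerance
    level_tol_vc: float = 1.0           # mV, voltage-step plateau tolerance
    drift_max: float = 1.0              # mV/min, baseline drift threshold

    # wedge boundary fits
    min_boundary_bins: int = 5
    min_boundary_r2: float = 0.9
    max_boundary_se: float = 3.0        # mV, max slope SE of a boundary
    e_e_accept: tuple = (-30.0, 10.0)   # mV, plausible lower-boundary slope

    # connectome
    sig_fraction: float = 0.25          # fraction of window bins significant
    min_rel_peak: float = 0.10          # window peak vs component max
    inspiratory_fraction: Optional[float] = None  # None: estimate from ref
    tie_margin: float = 0.05            # motif score tie threshold

    # user-supplied reversal potentials win over the wedge estimate
    reversals: Optional[ReversalPair] = None

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if not (0.0 < self.burst_threshold_frac < 1.0):
            raise ValidationError("burst_threshold_frac must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        for name in ("e_e_range", "e_i_range", "v_window", "e_e_accept"):
            lo, hi = getattr(self, name)
            if not (lo < hi):
                raise ValidationError(f"{name} must be ordered low < high")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.reversals is not None:
            d["reversals"] = {"e_i": self.reversals.e_i,
                              "e_e": self.reversals.e_e}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        rev = d.pop("reversals", None)
        for name in ("e_e_range", "e_i_range", "v_window", "e_e_accept"):
            if name in d and d[name] is not None:
                d[name] = tuple(d[name])
        cfg = cls(**d)
        if rev is not None:
            cfg.reversals = ReversalPair(e_i=rev["e_i"], e_e=rev["e_e"])
        return cfg

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
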