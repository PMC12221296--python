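"""Readers and writers for trace and result files.

Exchange formats (the acquisition-system dialects are out of scope):

* delimited traces: columns ``time,vm,i_inj,ref`` with comment header
  lines ``# sample_rate_hz=...`` and ``# clamp_mode=...``;
* HDF5 traces: datasets ``/traces/{vm,i_inj,ref}`` (float64) plus root
  attributes ``sample_rate_hz`` and ``clamp_mode`` (a ``/traces/time``
  dataset is written for self-description and used when present);
* result tables as tab-delimited text, one row per phase bin, invalid
  bins carried as NaN with a ``valid`` flag column, full configuration
  digest in the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .connectome import MotifReport
from .core import (
    CLAMP_MODES,
    FormatError,
    PipelineConfig,
    Recording,
)
from .decomposition import ConductanceProfile
from .regression import PhaseRegressionTable
from .wedge import WedgeFit

TRACE_COLUMNS = ("time", "vm", "i_inj", "ref")

PROFILE_COLUMNS = ("phase_center", "G", "dG", "Gi", "Ge", "dGi_dyn",
                   "dGe_dyn", "err_i", "err_e", "z_i", "z_e", "p_i", "p_e",
                   "valid")


def write_recording_csv(recording: Recording, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={recording.sample_rate!r}\n")
        fh.write(f"# clamp_mode={recording.clamp_mode}\n")
        if recording.metadata:
            fh.write("# metadata=" + json.dumps(recording.metadata) + "\n")
        df = pd.DataFrame({c: getattr(recording, c) for c in TRACE_COLUMNS})
        df.to_csv(fh, index=False, float_format="%.17g")


def _parse_header(path):
    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta, n_header


def read_recording_csv(path) -> Recording:
    meta, n_header = _parse_header(path)
    if "sample_rate_hz" not in meta:
        raise FormatError("missing '# sample_rate_hz=' header line")
    mode = meta.get("clamp_mode", "current_clamp")
    if mode not in CLAMP_MODES:
        raise FormatError(f"unknown clamp_mode {mode!r}")
    df = pd.read_csv(path, skiprows=n_header,
                     float_precision="round_trip")
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing channel column '{col}'")
    metadata = json.loads(meta["metadata"]) if "metadata" in meta else {}
    return Recording(time=df["time"].to_numpy(),
                     vm=df["vm"].to_numpy(),
                     i_inj=df["i_inj"].to_numpy(),
                     ref=df["ref"].to_numpy(),
                     sample_rate=float(meta["sample_rate_hz"]),
                     clamp_mode=mode, metadata=metadata)


def write_recording_hdf5(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("traces")
        for col in TRACE_COLUMNS:
            grp.create_dataset(col, data=getattr(recording, col),
                               dtype="float64")
        f.attrs["sample_rate_hz"] = recording.sample_rate
        f.attrs["clamp_mode"] = recording.clamp_mode
        f.attrs["t0"] = float(recording.time[0])
        if recording.metadata:
            f.attrs["metadata"] = json.dumps(recording.metadata)


def read_recording_hdf5(path) -> Recording:
    with h5py.File(path, "r") as f:
        if "traces" not in f:
            raise FormatError("missing /traces group")
        grp = f["traces"]
        for col in ("vm", "i_inj", "ref"):
            if col not in grp:
                raise FormatError(f"missing dataset /traces/{col}")
        if "sample_rate_hz" not in f.attrs:
            raise FormatError("missing sample_rate_hz attribute")
        fs = float(f.attrs["sample_rate_hz"])
        vm = grp["vm"][...]
        if "time" in grp:
            time = grp["time"][...]
        else:
            t0 = float(f.attrs.get("t0", 0.0))
            time = t0 + np.arange(vm.size) / fs
        mode = f.attrs.get("clamp_mode", "current_clamp")
        if isinstance(mode, bytes):
            mode = mode.decode()
        meta = f.attrs.get("metadata", "")
        metadata = json.loads(meta) if meta else {}
        return Recording(time=time, vm=vm, i_inj=grp["i_inj"][...],
                         ref=grp["ref"][...], sample_rate=fs,
                         clamp_mode=str(mode), metadata=metadata)


def read_recording(path, format: str = None) -> Recording:
    """Dispatch on ``format`` or the file suffix (csv | hdf5)."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "csv":
        return read_recording_csv(path)
    if fmt == "hdf5":
        return read_recording_hdf5(path)
    raise FormatError(f"unknown trace format {fmt!r}")


def write_profile(profile: ConductanceProfile, path) -> None:
    """Tab-delimited conductance profile, one row per phase bin.

    The header records the reversal potentials used, the leak estimate
    and the configuration digest; invalid bins are emitted as NaN with
    ``valid=0``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# e_i_used={profile.e_i_used!r}\n")
        fh.write(f"# e_e_used={profile.e_e_used!r}\n")
        fh.write(f"# g_leak_est={profile.g_leak_est!r}\n")
        fh.write(f"# alpha={profile.alpha!r}\n")
        fh.write(f"# argmin_i={profile.argmin_i}\n")
        fh.write(f"# argmin_e={profile.argmin_e}\n")
        fh.write(f"# config_hash={profile.config_hash}\n")
        data = {c: getattr(profile, c) for c in PROFILE_COLUMNS[:-1]}
        data["valid"] = profile.valid.astype(int)
        pd.DataFrame(data).to_csv(fh, sep="\t", index=False,
                                  float_format="%.17g")


def read_profile(path) -> ConductanceProfile:
    meta, n_header = _parse_header(path)
    for key in ("e_i_used", "e_e_used", "g_leak_est"):
        if key not in meta:
            raise FormatError(f"missing '# {key}=' header line")
    df = pd.read_csv(path, sep="\t", skiprows=n_header,
                     float_precision="round_trip")
    for col in PROFILE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing profile column '{col}'")
    valid = df["valid"].to_numpy().astype(bool)
    kw = {c: df[c].to_numpy() for c in PROFILE_COLUMNS[:-1]}
    return ConductanceProfile(
        valid=valid,
        neg_flag_i=np.isfinite(kw["Gi"]) & (kw["Gi"] < 0),
        neg_flag_e=np.isfinite(kw["Ge"]) & (kw["Ge"] < 0),
        g_leak_est=float(meta["g_leak_est"]),
        e_i_used=float(meta["e_i_used"]),
        e_e_used=float(meta["e_e_used"]),
        argmin_i=int(meta.get("argmin_i", 0)),
        argmin_e=int(meta.get("argmin_e", 0)),
        alpha=float(meta.get("alpha", 0.05)),
        config_hash=meta.get("config_hash", ""),
        **kw)


def write_regression_table(table: PhaseRegressionTable, path) -> None:
    df = pd.DataFrame({
        "phase_center": table.phase_center, "R": table.R, "V0": table.V0,
        "dR": table.dR, "dV0": table.dV0, "n_samples": table.n_samples,
        "n_levels": table.n_levels, "valid": table.valid.astype(int)})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_wedge(fit: WedgeFit, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# e_i_hat={fit.e_i_hat!r}\n")
        fh.write(f"# e_i_se={fit.e_i_se!r}\n")
        fh.write(f"# e_e_hat={fit.e_e_hat!r}\n")
        fh.write(f"# e_e_defaulted={int(fit.e_e_defaulted)}\n")
        for side, line in (("upper", fit.upper_line),
                           ("lower", fit.lower_line)):
            if line is not None:
                fh.write(f"# {side}_line={line.slope!r},{line.intercept!r},"
                         f"r2={line.r2:.6f},n={line.bins.size}\n")
        if fit.notes:
            fh.write("# notes=" + "; ".join(fit.notes) + "\n")
        pd.DataFrame({"G": fit.G, "I0": fit.I0,
                      "valid": fit.valid.astype(int)}).to_csv(
            fh, sep="\t", index=False, float_format="%.17g")


def write_motifs(report: MotifReport, path) -> None:
    """Edge list: source, sign, target, windows, score."""
    rows = [{"source": e.source, "sign": e.sign, "target": report.target,
             "windows": "+".join(e.windows), "score": round(e.score, 6)}
            for e in report.edges]
    df = pd.DataFrame(rows, columns=["source", "sign", "target",
                                     "windows", "score"])
    with open(path, "w") as fh:
        if report.unexplained:
            fh.write("# unexplained=" + ";".join(report.unexplained) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_qc(report, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def write_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(),
                                         sort_keys=True))


def read_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.from_dict(data or {})
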