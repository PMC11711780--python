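"""On-disk formats: waveform CSVs, measurement-bundle folders, parameter JSON.

Waveforms are two-column CSVs with the header ``time_s,flow_ml_s`` and a
leading comment line carrying the site tag and cycle length, so a file
round-trips to an identical :class:`FlowWaveform`.  A measurement bundle is
a folder with ``bundle.json`` (scalars) plus one CSV per flow site and an
optional velocity CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .derivation import FlowWaveform, MeasurementBundle, VelocityTrace

WAVEFORM_HEADER = "time_s,flow_ml_s"
VELOCITY_HEADER = "time_s,velocity_cm_s"


class FormatError(ValueError):
    pass


def write_waveform_csv(w: FlowWaveform, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# site={w.site} T_s={w.T!r}\n")
        fh.write(WAVEFORM_HEADER + "\n")
        for t, q in zip(w.time, w.flow):
            fh.write(f"{float(t)!r},{float(q)!r}\n")


def _read_two_column(path, expected_header: str):
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta = {}
    body_start = 0
    if lines and lines[0].startswith("#"):
        for tok in lines[0].lstrip("#").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        body_start = 1
    if len(lines) <= body_start:
        raise FormatError(f"{path}: empty file")
    header = lines[body_start].strip()
    if header != expected_header:
        raise FormatError(
            f"{path}: expected header {expected_header!r}, found {header!r}")
    xs, ys = [], []
    for lineno, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            if len(parts) != 2:
                raise ValueError
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError:
            raise FormatError(f"{path}: malformed row at line {lineno}: {line!r}")
    x = np.array(xs)
    if len(x) and np.any(np.diff(x) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    return meta, x, np.array(ys)


def read_waveform_csv(path) -> FlowWaveform:
    meta, t, q = _read_two_column(path, WAVEFORM_HEADER)
    if "site" not in meta or "T_s" not in meta:
        raise FormatError(f"{path}: missing '# site=... T_s=...' metadata line")
    try:
        return FlowWaveform(site=meta["site"], time=t, flow=q, T=float(meta["T_s"]))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_velocity_csv(v: VelocityTrace, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(VELOCITY_HEADER + "\n")
        for t, u in zip(v.time, v.velocity):
            fh.write(f"{float(t)!r},{float(u)!r}\n")


def read_velocity_csv(path) -> VelocityTrace:
    _, t, u = _read_two_column(path, VELOCITY_HEADER)
    return VelocityTrace(time=t, velocity=u)


def write_bundle(bundle: MeasurementBundle, directory) -> Path:
    """Serialize one occasion to ``<directory>/`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scalars = {
        "subject_id": bundle.subject_id, "occasion": bundle.occasion,
        "T": bundle.T, "ESV": bundle.ESV, "EOA": bundle.EOA,
        "A_LVOT": bundle.A_LVOT, "SBP": bundle.SBP, "DBP": bundle.DBP,
        "waveforms": {site: f"{site}.csv" for site in bundle.waveforms},
        "velocity": "velocity.csv" if bundle.velocity is not None else None,
    }
    (directory / "bundle.json").write_text(
        json.dumps(scalars, indent=1), encoding="utf-8")
    for site, w in bundle.waveforms.items():
        write_waveform_csv(w, directory / f"{site}.csv")
    if bundle.velocity is not None:
        write_velocity_csv(bundle.velocity, directory / "velocity.csv")
    return directory


def read_bundle(directory) -> MeasurementBundle:
    directory = Path(directory)
    meta = json.loads((directory / "bundle.json").read_text(encoding="utf-8"))
    waveforms = {site: read_waveform_csv(directory / fname)
                 for site, fname in meta["waveforms"].items()}
    velocity = (read_velocity_csv(directory / meta["velocity"])
                if meta.get("velocity") else None)
    return MeasurementBundle(
        subject_id=meta["subject_id"], occasion=meta["occasion"], T=meta["T"],
        ESV=meta["ESV"], EOA=meta["EOA"], A_LVOT=meta["A_LVOT"],
        SBP=meta["SBP"], DBP=meta["DBP"],
        waveforms=waveforms, velocity=velocity,
    )


__all__ = [
    "read_waveform_csv", "write_waveform_csv",
    "read_velocity_csv", "write_velocity_csv",
    "read_bundle", "write_bundle", "FormatError",
    "WAVEFORM_HEADER", "VELOCITY_HEADER",
]
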