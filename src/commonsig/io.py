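"""Recording and report I/O.

Recordings travel as a delimited numeric matrix (UTF-8, comma-separated,
header row of channel labels, rows = samples) plus a JSON sidecar carrying
the metadata the matrix cannot: sampling rate, electrode positions, epoch
structure, and referencing label.  A binary container (JSON header line +
little-endian float64, row-major samples x channels) is provided for
bit-exact round trips; the text form is written with 17 significant digits
which round-trips float64 exactly in practice.

Reports are written as long-format delimited metric tables plus a JSON
summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .common_signal import ChannelLayout
from .pipeline import Recording, SessionReport

__all__ = [
    "read_recording",
    "write_recording",
    "write_report",
    "RecordingIOError",
    "MissingSidecarError",
    "MalformedHeaderError",
    "NonFiniteSamplesError",
    "MetadataMismatchError",
]

_BINARY_MAGIC = b"COMMONSIGBIN1\n"


class RecordingIOError(ValueError):
    """Base class for recording I/O failures; ``code`` identifies the kind."""

    code = "io_error"


class MissingSidecarError(RecordingIOError):
    code = "missing_sidecar"


class MalformedHeaderError(RecordingIOError):
    code = "malformed_header"


class NonFiniteSamplesError(RecordingIOError):
    code = "non_finite_samples"


class MetadataMismatchError(RecordingIOError):
    code = "metadata_mismatch"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def _read_sidecar(sidecar_path: Path) -> dict:
    if not sidecar_path.exists():
        raise MissingSidecarError(f"sidecar file not found: {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise MalformedHeaderError(f"sidecar is not valid JSON: {exc}") from exc
    for key in ("fs_hz", "positions_um"):
        if key not in meta:
            raise MalformedHeaderError(f"sidecar missing required key {key!r}")
    return meta


def _assemble(samples: np.ndarray, meta: dict) -> Recording:
    if not np.all(np.isfinite(samples)):
        raise NonFiniteSamplesError("recording contains NaN or infinite samples")
    positions = np.asarray(meta["positions_um"], dtype=float)
    if positions.size != samples.shape[1]:
        raise MetadataMismatchError(
            f"sidecar lists {positions.size} positions but matrix has "
            f"{samples.shape[1]} channels"
        )
    n_epochs = int(meta.get("n_epochs", 1))
    epoch_s = float(meta.get("epoch_s", samples.shape[0] / float(meta["fs_hz"]) / n_epochs))
    try:
        return Recording(
            samples=samples,
            fs=float(meta["fs_hz"]),
            layout=ChannelLayout(positions),
            label=meta.get("label", "unipolar"),
            n_epochs=n_epochs,
            epoch_s=epoch_s,
        )
    except ValueError as exc:
        raise MetadataMismatchError(str(exc)) from exc


def read_recording(path: str | Path, sidecar_path: str | Path | None = None) -> Recording:
    """Read a recording from a delimited matrix (or binary container) and
    its JSON sidecar (default: ``<path>.json``)."""
    path = Path(path)
    if not path.exists():
        raise RecordingIOError(f"recording file not found: {path}")
    if path.suffix == ".bin":
        return _read_binary(path)
    meta = _read_sidecar(Path(sidecar_path) if sidecar_path else _sidecar_path(path))
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise MalformedHeaderError(f"could not parse delimited matrix: {exc}") from exc
    if table.shape[1] < 1 or not all(isinstance(c, str) for c in table.columns):
        raise MalformedHeaderError("matrix must have a header row of channel labels")
    non_numeric = [c for c in table.columns if not np.issubdtype(table[c].dtype, np.number)]
    if non_numeric:
        raise MalformedHeaderError(f"non-numeric columns: {non_numeric}")
    return _assemble(table.to_numpy(dtype=float), meta)


def write_recording(recording: Recording, path: str | Path, binary: bool = False) -> Path:
    """Write a recording (and its sidecar for the text form); returns the
    data-file path."""
    path = Path(path)
    meta = {
        "fs_hz": recording.fs,
        "positions_um": recording.layout.positions.tolist(),
        "label": recording.label,
        "n_epochs": recording.n_epochs,
        "epoch_s": recording.epoch_s,
        "reference": "thorax" if recording.label == "unipolar" else "local",
    }
    if binary:
        header = json.dumps({**meta, "shape": list(recording.samples.shape)}).encode()
        with open(path, "wb") as fh:
            fh.write(_BINARY_MAGIC)
            fh.write(header + b"\n")
            fh.write(recording.samples.astype("<f8").tobytes(order="C"))
        return path
    labels = [f"ch{i:02d}" for i in range(recording.n_channels)]
    pd.DataFrame(recording.samples, columns=labels).to_csv(
        path, index=False, float_format="%.17g"
    )
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _read_binary(path: Path) -> Recording:
    raw = path.read_bytes()
    if not raw.startswith(_BINARY_MAGIC):
        raise MalformedHeaderError("bad magic in binary recording container")
    rest = raw[len(_BINARY_MAGIC):]
    nl = rest.index(b"\n")
    try:
        meta = json.loads(rest[:nl])
    except json.JSONDecodeError as exc:
        raise MalformedHeaderError(f"binary header is not valid JSON: {exc}") from exc
    shape = tuple(meta.pop("shape"))
    samples = np.frombuffer(rest[nl + 1:], dtype="<f8").reshape(shape)
    return _assemble(samples.copy(), meta)


def write_report(report: SessionReport, out_dir: str | Path) -> Path:
    """Write a session report: per-side metric and power tables (CSV) and a
    JSON summary with the NCR estimate."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for side in (report.unipolar, report.bipolar):
        side.metrics_table().to_csv(out / f"{side.label}_metrics.csv", index=False)
        pd.DataFrame(
            {"frequency": side.freqs, "power_db": side.power_db}
        ).to_csv(out / f"{side.label}_power.csv", index=False)
    (out / "report.json").write_text(json.dumps(report.summary(), indent=1))
    return out
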