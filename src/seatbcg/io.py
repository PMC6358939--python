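"""Readers and writers for the pipeline's delimited-text artifact files.

All artifacts are plain text.  Every file written here starts with comment
lines (``# key: value``) embedding the tool version and, where applicable,
the seed or a hash of the generating configuration; readers skip comments.
Numeric payloads are serialised at 17 significant digits, so a write/read
round trip is exact for double precision.  Writes are atomic: content goes
to a temporary file in the destination directory which is then renamed.
"""

from __future__ import annotations

import hashlib
import os
import tempfile
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .core import GRID_SIZE, N_SENSORS, PressureRecording

__all__ = [
    "read_recording",
    "write_recording",
    "read_frame",
    "write_frame",
    "read_keyvalue",
    "write_keyvalue",
    "read_feature_table",
    "write_feature_table",
    "save_model",
    "load_model",
]

_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed artifact file; the message names the offending line."""


def config_hash(mapping: Mapping) -> str:
    """Short stable hash of a flat config mapping, for provenance headers."""
    blob = ";".join(f"{k}={mapping[k]}" for k in sorted(map(str, mapping)))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _header_lines(extra: Mapping | None = None) -> list[str]:
    lines = [f"# seatbcg: {__version__}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def write_recording(recording: PressureRecording, path: str, meta: Mapping | None = None) -> None:
    """Write a recording as `time_s,s001..s256` delimited text."""
    header = ",".join(["time_s"] + [f"s{i:03d}" for i in range(1, N_SENSORS + 1)])
    meta = dict(meta or {})
    meta.setdefault("sample_rate_hz", repr(recording.sample_rate))
    lines = _header_lines(meta) + [header]
    t = recording.times
    for i in range(recording.n_samples):
        row = [_FMT % t[i]] + [_FMT % v for v in recording.samples[i]]
        lines.append(",".join(row))
    _atomic_write(path, "\n".join(lines) + "\n")


def read_recording(path: str) -> PressureRecording:
    """Parse a recording file, validating the header and time column."""
    expected = ["time_s"] + [f"s{i:03d}" for i in range(1, N_SENSORS + 1)]
    times: list[float] = []
    rows: list[list[float]] = []
    sample_rate = None
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "sample_rate_hz:" in line:
                    try:
                        sample_rate = float(line.split("sample_rate_hz:")[1])
                    except ValueError:
                        raise ParseError(f"{path}:{lineno}: bad sample_rate_hz comment")
                continue
            cells = [c.strip() for c in line.split(",")]
            if not header_seen:
                if cells != expected:
                    raise ParseError(
                        f"{path}:{lineno}: header must be time_s,s001..s{N_SENSORS} "
                        f"({len(cells)} columns found, {len(expected)} expected)"
                    )
                header_seen = True
                continue
            if len(cells) != N_SENSORS + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {N_SENSORS + 1} columns, got {len(cells)}"
                )
            try:
                vals = [float(c) for c in cells]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})")
            times.append(vals[0])
            rows.append(vals[1:])
    if not header_seen:
        raise ParseError(f"{path}: missing header line")
    if not rows:
        raise ParseError(f"{path}: no data rows")
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2  # data row index
        raise ParseError(f"{path}: time column not strictly increasing at data row {bad}")
    if sample_rate is None:
        dt = np.diff(t)
        sample_rate = 1.0 / float(np.median(dt))
    return PressureRecording(np.asarray(rows), sample_rate)


def write_frame(frame: np.ndarray, path: str, meta: Mapping | None = None) -> None:
    """Write a 16 x 16 map as 16 comma-delimited rows."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (GRID_SIZE, GRID_SIZE):
        raise ValueError(f"frame must be {GRID_SIZE}x{GRID_SIZE}")
    lines = _header_lines(meta)
    lines += [",".join(_FMT % v for v in row) for row in frame]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_frame(path: str) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split(",")
            if len(cells) != GRID_SIZE:
                raise ParseError(f"{path}:{lineno}: expected {GRID_SIZE} columns")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})")
    if len(rows) != GRID_SIZE:
        raise ParseError(f"{path}: expected {GRID_SIZE} data rows, got {len(rows)}")
    return np.asarray(rows)


def write_keyvalue(mapping: Mapping, path: str, meta: Mapping | None = None) -> None:
    """Write a flat `key: value` text file (truth files, sidecars)."""
    lines = _header_lines(meta)
    for k, v in mapping.items():
        lines.append(f"{k}: {v}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_keyvalue(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key: value'")
            k, v = line.split(":", 1)
            out[k.strip()] = v.strip()
    return out


def write_feature_table(
    features: np.ndarray,
    labels: np.ndarray | None,
    path: str,
    feature_names: Iterable[str],
    meta: Mapping | None = None,
) -> None:
    df = pd.DataFrame(np.asarray(features, dtype=float), columns=list(feature_names))
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)
    text = "\n".join(_header_lines(meta)) + "\n" + df.to_csv(index=False, float_format=_FMT)
    _atomic_write(path, text)


def read_feature_table(path: str) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), labels, list(df.columns)


def save_model(model, path: str) -> None:
    """Serialise an ELM model (text key-value header plus matrix blocks)."""
    lines = _header_lines({"kind": "elm-model"})
    lines += [
        f"activation: {model.activation}",
        f"n_hidden: {model.n_hidden}",
        f"n_features: {model.n_features}",
        f"n_classes: {model.n_classes}",
        f"seed: {model.seed if model.seed is not None else ''}",
        "feature_order: " + (",".join(model.feature_order) if model.feature_order else ""),
        "scaler: " + (
            " ".join(_FMT % v for v in model.scaler_denominators)
            if model.scaler_denominators is not None
            else ""
        ),
    ]
    for name, arr in (("A", model.A), ("B", model.B.reshape(1, -1)), ("beta", model.beta)):
        lines.append(f"{name}:")
        lines += [" ".join(_FMT % v for v in row) for row in np.atleast_2d(arr)]
    _atomic_write(path, "\n".join(lines) + "\n")


def load_model(path: str):
    from .elm import ELMModel

    scalars: dict[str, str] = {}
    blocks: dict[str, list[list[float]]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if not line or line.startswith("#"):
                continue
            if line in ("A:", "B:", "beta:"):
                current = line[:-1]
                blocks[current] = []
                continue
            if current is not None:
                try:
                    blocks[current].append([float(v) for v in line.split()])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: bad matrix row in block {current}")
            elif ":" in line:
                k, v = line.split(":", 1)
                scalars[k.strip()] = v.strip()
            else:
                raise ParseError(f"{path}:{lineno}: unexpected line")
    for required in ("A", "B", "beta"):
        if required not in blocks or not blocks[required]:
            raise ParseError(f"{path}: missing matrix block {required}")
    feature_order = tuple(s for s in scalars.get("feature_order", "").split(",") if s) or None
    scaler = scalars.get("scaler", "")
    denominators = np.array([float(v) for v in scaler.split()]) if scaler else None
    seed = scalars.get("seed", "")
    return ELMModel(
        A=np.array(blocks["A"]),
        B=np.array(blocks["B"]).ravel(),
        beta=np.array(blocks["beta"]),
        activation=scalars.get("activation", "sigmoid"),
        seed=int(seed) if seed else None,
        feature_order=feature_order,
        scaler_denominators=denominators,
    )


def write_series(t, values, path: str, name: str = "value", meta: Mapping | None = None) -> None:
    """Write a time series as two-column `time_s,<name>` delimited text."""
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.shape != values.shape:
        raise ValueError("time and value arrays differ in length")
    lines = _header_lines(meta) + [f"time_s,{name}"]
    lines += [f"{_FMT % a},{_FMT % b}" for a, b in zip(t, values)]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_series(path: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected two columns (time_s, value)")
    return df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
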