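"""Uniformly sampled multichannel respiratory waveform records and their
delimited-text representation.

Channels: t (s), flow (L/min at the interface; the simulator works in L/s
internally), paw (cmH2O), peso (cmH2O) and optionally ppl (pleural
pressure, emitted as Peso without the cardiac artifact).  Metadata travel
as ``# key=value`` comment lines ahead of the CSV header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["WaveformRecord", "write_waveforms", "read_waveforms", "WaveformParseError"]


class WaveformParseError(ValueError):
    """Malformed waveform table (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass
class WaveformRecord:
    fs: float
    t: np.ndarray
    flow: np.ndarray               # L/min
    paw: np.ndarray                # cmH2O
    peso: np.ndarray | None = None
    ppl: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)
        if self.peso is not None:
            self.peso = np.asarray(self.peso, dtype=float)
        if self.ppl is not None:
            self.ppl = np.asarray(self.ppl, dtype=float)
        lengths = {len(self.t), len(self.flow), len(self.paw)}
        if self.peso is not None:
            lengths.add(len(self.peso))
        if self.ppl is not None:
            lengths.add(len(self.ppl))
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - 1.0 / self.fs)) >= 1e-6:
                raise ValueError("sampling must be uniform at 1/fs")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def flow_ls(self) -> np.ndarray:
        return self.flow / 60.0

    @property
    def has_peso(self) -> bool:
        return self.peso is not None

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t, "flow": self.flow, "paw": self.paw}
        if self.peso is not None:
            cols["peso"] = self.peso
        if self.ppl is not None:
            cols["ppl"] = self.ppl
        return pd.DataFrame(cols)


def _format_meta_value(v) -> str:
    return f"{v}"


def write_waveforms(record: WaveformRecord, path) -> None:
    """Write a record as commented-header CSV (comma, '.', UTF-8)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        for key, val in record.meta.items():
            fh.write(f"# {key}={_format_meta_value(val)}\n")
        record.to_frame().to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def read_waveforms(path) -> WaveformRecord:
    """Read a record written by :func:`write_waveforms`.

    Peso/Ppl are optional; ragged rows raise :class:`WaveformParseError`
    with the offending line number.
    """
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split(",")
            if header is None:
                header = [p.strip() for p in parts]
                if "t" not in header or "flow" not in header:
                    raise WaveformParseError("header must contain 't' and 'flow'", lineno)
                continue
            if len(parts) != len(header):
                raise WaveformParseError(
                    f"expected {len(header)} fields, got {len(parts)}", lineno
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise WaveformParseError(str(exc), lineno) from None
    if header is None or not rows:
        raise WaveformParseError("no data rows found")
    data = {name: np.array([r[i] for r in rows]) for i, name in enumerate(header)}
    fs = float(meta.pop("fs", 0) or 0)
    if fs <= 0:
        t = data["t"]
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 100.0
    for key in list(meta):
        try:
            meta[key] = float(meta[key]) if "." in meta[key] else int(meta[key])
        except ValueError:
            pass
    return WaveformRecord(
        fs=fs,
        t=data["t"],
        flow=data["flow"],
        paw=data.get("paw", np.zeros_like(data["t"])),
        peso=data.get("peso"),
        ppl=data.get("ppl"),
        meta=meta,
    )
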