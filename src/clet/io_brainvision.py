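"""BrainVision Core Data Format 1.0 I/O.

Reads the three-file dialect used by Brain Products amplifiers — a text
header (``.vhdr``), a marker list (``.vmrk``) and binary samples (``.eeg``)
— into :class:`~clet._types.PhotodiodeRecording` and
:class:`~clet._types.MarkerTable`, and writes per-event latency tables as
CSV.

Samples are returned in raw ADC units (binary value times the per-channel
resolution from the header); no unit conversion to volts is applied, because
the detection thresholds are defined on the raw amplitude scale.  Marker
positions in ``.vmrk`` are 1-based sample positions and are converted to
seconds as ``(pos - 1) / fs``.
"""

from __future__ import annotations

import configparser
import io
import os
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from ._types import MarkerEvent, MarkerTable, PhotodiodeRecording

if TYPE_CHECKING:  # pragma: no cover
    from .latency_stats import LatencyResult

__all__ = [
    "BrainVisionError",
    "read_brainvision",
    "write_latency_table",
    "read_latency_table",
]

#: numpy dtypes for the supported binary sample formats (all little-endian).
_BINARY_DTYPES = {
    "INT_16": np.dtype("<i2"),
    "INT_32": np.dtype("<i4"),
    "IEEE_FLOAT_32": np.dtype("<f4"),
}


class BrainVisionError(RuntimeError):
    """Structured error while reading a BrainVision triplet."""


def _parse_ini(path: Path, kind: str) -> configparser.ConfigParser:
    """Parse a .vhdr/.vmrk file, skipping the identification line."""
    text = path.read_text(encoding="utf-8", errors="replace")
    first_bracket = text.find("[")
    if first_bracket < 0:
        raise BrainVisionError(f"{path} does not look like a BrainVision {kind} file")
    parser = configparser.ConfigParser(
        strict=False, allow_no_value=True, interpolation=None, delimiters=("=",)
    )
    parser.optionxform = str  # keys are case-sensitive (Mk1, Ch1, ...)
    parser.read_file(io.StringIO(text[first_bracket:]))
    return parser


def _section(parser: configparser.ConfigParser, name: str, path: Path) -> dict:
    for sec in parser.sections():
        if sec.lower() == name.lower():
            return dict(parser.items(sec))
    raise BrainVisionError(f"section [{name}] missing from {path}")


def _companion(header_path: Path, declared: str, kind: str) -> Path:
    """Resolve a companion file path declared in the header."""
    candidate = Path(declared)
    if not candidate.is_absolute():
        candidate = header_path.parent / declared
    if not candidate.exists():
        # Common dialect: header declares only a base name; fall back to the
        # header's own stem with the conventional extension.
        fallback = header_path.with_suffix(f".{kind}")
        if fallback.exists():
            return fallback
        raise BrainVisionError(
            f"missing companion {kind} file: {candidate} (declared in {header_path})"
        )
    return candidate


def read_brainvision(
    header_path: str | os.PathLike, channel: str, strict_labels: bool = False
) -> tuple[PhotodiodeRecording, MarkerTable]:
    """Read one channel of a BrainVision triplet plus its markers.

    Parameters
    ----------
    header_path : path-like
        Path to the ``.vhdr`` header; the ``.eeg`` and ``.vmrk`` companions
        are resolved from its declarations.
    channel : str
        Name of the channel to extract (e.g. ``"photodiode"``).
    strict_labels : bool
        If True, reject marker descriptions outside the S1/S2/S7/S8
        vocabulary.

    Returns
    -------
    (PhotodiodeRecording, MarkerTable)
        Samples scaled by the channel resolution (ADC units); marker onsets
        in seconds, ``(position - 1) / fs``.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise BrainVisionError(f"header file not found: {header_path}")
    hdr = _parse_ini(header_path, "header")
    common = _section(hdr, "Common Infos", header_path)

    data_format = common.get("DataFormat", "BINARY").upper()
    if data_format != "BINARY":
        raise BrainVisionError(f"unsupported DataFormat {data_format!r} (only BINARY)")
    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation not in ("MULTIPLEXED", "VECTORIZED"):
        raise BrainVisionError(f"unsupported DataOrientation {orientation!r}")
    n_channels = int(common["NumberOfChannels"])
    sampling_interval_us = float(common["SamplingInterval"])
    fs = 1e6 / sampling_interval_us

    binary = _section(hdr, "Binary Infos", header_path)
    binary_format = binary.get("BinaryFormat", "").upper()
    if binary_format not in _BINARY_DTYPES:
        raise BrainVisionError(
            f"unsupported BinaryFormat {binary_format!r}; supported: "
            f"{sorted(_BINARY_DTYPES)}"
        )
    dtype = _BINARY_DTYPES[binary_format]

    channels = _section(hdr, "Channel Infos", header_path)
    names: list[str] = []
    resolutions: list[float] = []
    for i in range(1, n_channels + 1):
        raw = channels.get(f"Ch{i}")
        if raw is None:
            raise BrainVisionError(f"channel Ch{i} missing from {header_path}")
        parts = raw.split(",")
        names.append(parts[0].replace("\\1", ","))
        res = parts[2].strip() if len(parts) > 2 else ""
        resolutions.append(float(res) if res else 1.0)
    if channel not in names:
        raise BrainVisionError(
            f"channel {channel!r} not found; available channels: {names}"
        )
    ch_index = names.index(channel)

    eeg_path = _companion(header_path, common.get("DataFile", ""), "eeg")
    raw_data = np.fromfile(eeg_path, dtype=dtype)
    if raw_data.size % n_channels:
        raise BrainVisionError(
            f"{eeg_path}: {raw_data.size} values not divisible by "
            f"{n_channels} channels"
        )
    if orientation == "MULTIPLEXED":
        trace = raw_data[ch_index::n_channels]
    else:  # VECTORIZED: channel-contiguous blocks
        n_samp = raw_data.size // n_channels
        trace = raw_data[ch_index * n_samp : (ch_index + 1) * n_samp]
    samples = trace.astype(np.float64) * resolutions[ch_index]

    vmrk_path = _companion(header_path, common.get("MarkerFile", ""), "vmrk")
    markers = _read_vmrk(vmrk_path, fs)
    if strict_labels:
        markers.validate_labels()

    recording = PhotodiodeRecording(samples=samples, fs=fs, channel_name=channel)
    return recording, markers


def _read_vmrk(vmrk_path: Path, fs: float) -> MarkerTable:
    mrk = _parse_ini(vmrk_path, "marker")
    infos = _section(mrk, "Marker Infos", vmrk_path)
    events: list[MarkerEvent] = []
    for key in sorted(infos, key=lambda k: int(k[2:]) if k[2:].isdigit() else 0):
        if not key.startswith("Mk"):
            continue
        parts = infos[key].split(",")
        if len(parts) < 3:
            raise BrainVisionError(f"{vmrk_path}: malformed marker line {key}={infos[key]!r}")
        mtype, description, position = parts[0], parts[1], parts[2]
        if not description:  # e.g. the New Segment bookkeeping marker
            continue
        if mtype.strip().lower() not in ("stimulus", "response", "comment"):
            continue
        events.append(MarkerEvent(label=description, onset_s=(int(position) - 1) / fs))
    return MarkerTable(events=events)


# ---------------------------------------------------------------------------
# Latency tables
# ---------------------------------------------------------------------------

def write_latency_table(result: "LatencyResult", path: str | os.PathLike) -> None:
    """Write one latency result as CSV.

    Columns are ``stimulus_type,event_index,tS_s,tD_s,latency_ms`` with fixed
    6-decimal rendering, ``event_index`` 1-based, followed by a trailing
    comment block with per-type n / mean / SD so the file is self-describing
    yet still round-trips through a standard CSV reader.
    """
    if result.n == 0:
        raise ValueError("refusing to write an empty latency result")
    path = Path(path)
    lines = ["stimulus_type,event_index,tS_s,tD_s,latency_ms"]
    for k in range(result.n):
        lines.append(
            f"{result.stimulus_type},{k + 1},{result.tS_s[k]:.6f},"
            f"{result.tD_s[k]:.6f},{result.latencies_ms[k]:.6f}"
        )
    lines.append(
        f"# summary stimulus_type={result.stimulus_type} n={result.n} "
        f"mean_ms={result.mean_ms:.6f} sd_ms={result.sd_ms:.6f}"
    )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_latency_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_latency_table`."""
    return pd.read_csv(path, comment="#")
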