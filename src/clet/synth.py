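"""Synthetic photodiode recordings with known injected display latencies.

The generator emulates the rapid-serial-visual-presentation protocol the
method was designed for: ~100 white and ~100 black full-screen stimuli with
a neutral gray image in between, trigger-to-trigger inter-stimulus interval
uniform in 1.0-1.5 s, stimulus duration 0.3 s, markers "S1" (white), "S2"
(black), "S7" (start) and "S8" (end).  Each event's display onset lags its
trigger by ``latency_ms`` plus optional Gaussian jitter (truncated at 0).

Two waveform morphologies are produced:

* ``led`` — a steady neutral baseline with a transient excursion above the
  white level for the stimulus duration at each white onset, and a drop to
  the black level at each black onset (100 Hz-class TV panel; the square
  pulse is what the photodiode integrates to).
* ``hmd`` — a continuous refresh-rate peak train (90 Hz headset): single-
  sample peaks whose heights take the neutral, white or black level during
  the corresponding regime, with the train re-phased so a peak falls exactly
  on each stimulus onset (the per-event display onset is what detection must
  recover; free-running phase would fold up to one refresh period of
  quantisation into every latency).

Presentation order defaults to strict white/black alternation, the ON/OFF
scheme the protocol describes.  Alternation also keeps consecutive
same-type events at least two inter-stimulus intervals apart, which the
literal edge-grouping comparator of the detection algorithm requires when a
stimulus produces a burst of threshold crossings (every HMD stimulus does);
``order="random"`` is available for stress testing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from ._types import (
    BLACK_LABEL,
    END_LABEL,
    START_LABEL,
    WHITE_LABEL,
    DetectionParams,
    MarkerEvent,
    MarkerTable,
    PhotodiodeRecording,
)

__all__ = ["SyntheticConfig", "GroundTruth", "simulate", "write_fixture"]

#: mode -> (neutral, white, black[, valley]) amplitude levels (ADC units),
#: placed so the reference thresholds (60000/20000 LED, 180000/8000 HMD)
#: separate the regimes with wide margins.
_DEFAULT_LEVELS = {
    "led": {"neutral": 40000.0, "white": 70000.0, "black": 10000.0, "valley": 0.0},
    "hmd": {"neutral": 100000.0, "white": 200000.0, "black": 5000.0, "valley": 0.0},
}
_DEFAULT_REFRESH = {"led": 100.0, "hmd": 90.0}
_REFERENCE_THRESHOLDS = {"led": (60000.0, 20000.0), "hmd": (180000.0, 8000.0)}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic recording."""

    mode: Literal["led", "hmd"] = "led"
    fs: float = 500.0
    n_white: int = 100
    n_black: int = 100
    isi_range_s: tuple[float, float] = (1.0, 1.5)
    stim_dur_s: float = 0.3
    latency_ms: float = 120.0
    latency_jitter_ms: float = 0.0
    #: per-type overrides; None means same as the white-stimulus values
    #: (HMD panels show genuinely different white vs black lags).
    latency_ms_black: float | None = None
    latency_jitter_ms_black: float | None = None
    refresh_hz: float | None = None
    levels: dict[str, float] | None = None
    noise_sd: float = 0.0
    seed: int = 0
    order: Literal["alternating", "random"] = "alternating"
    lead_in_s: float = 2.0
    lead_out_s: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("led", "hmd"):
            raise ValueError(f"mode must be 'led' or 'hmd', got {self.mode!r}")
        if self.refresh_hz is None:
            self.refresh_hz = _DEFAULT_REFRESH[self.mode]
        merged = dict(_DEFAULT_LEVELS[self.mode])
        if self.levels:
            merged.update(self.levels)
        self.levels = merged
        if self.fs <= 0 or self.stim_dur_s <= 0:
            raise ValueError("fs and stim_dur_s must be positive")
        lo, hi = self.isi_range_s
        if not (0 < lo <= hi):
            raise ValueError(f"invalid isi range {self.isi_range_s}")
        if self.latency_ms < 0 or (
            self.latency_ms_black is not None and self.latency_ms_black < 0
        ):
            raise ValueError("injected latency must be >= 0")
        self._validate_detectability()

    def _validate_detectability(self) -> None:
        """Reject level/noise combinations that break single-crossing
        detection with the reference thresholds."""
        lv = self.levels
        gaps = [lv["white"] - lv["neutral"], lv["neutral"] - lv["black"]]
        if min(gaps) <= 0:
            raise ValueError(
                f"levels must be ordered black < neutral < white, got {lv}"
            )
        if self.noise_sd >= 0.1 * min(gaps):
            raise ValueError(
                f"noise_sd={self.noise_sd} is not below 10% of the smallest "
                f"level gap ({min(gaps)}); detection is no longer guaranteed"
            )
        thd1, thd2 = _REFERENCE_THRESHOLDS[self.mode]
        if not (lv["black"] < thd2 < lv["neutral"] < thd1 < lv["white"]):
            raise ValueError(
                f"levels {lv} do not bracket the reference thresholds "
                f"ThD1={thd1}, ThD2={thd2} for mode {self.mode!r}"
            )

    def default_detection_params(self, **overrides) -> DetectionParams:
        """Reference thresholds matching the default amplitude levels."""
        thd1, thd2 = _REFERENCE_THRESHOLDS[self.mode]
        kw = dict(thd1=thd1, thd2=thd2, lisi=self.isi_range_s[0], mode=self.mode)
        kw.update(overrides)
        return DetectionParams(**kw)


@dataclass
class GroundTruth:
    """Per-event truth: what was sent when, and when it really displayed."""

    labels: np.ndarray
    send_s: np.ndarray
    onset_s: np.ndarray
    latency_ms: np.ndarray

    def __len__(self) -> int:
        return int(self.labels.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "send_s": self.send_s,
                "onset_s": self.onset_s,
                "latency_ms": self.latency_ms,
            }
        )

    def select(self, label: str) -> pd.DataFrame:
        frame = self.to_frame()
        return frame[frame["label"] == label].reset_index(drop=True)


def _event_order(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    labels = np.array(
        [WHITE_LABEL] * config.n_white + [BLACK_LABEL] * config.n_black, dtype=object
    )
    if config.order == "random":
        return rng.permutation(labels)
    # strict alternation starting with white; the surplus type trails
    ordered = []
    w, b = config.n_white, config.n_black
    while w or b:
        if w:
            ordered.append(WHITE_LABEL)
            w -= 1
        if b:
            ordered.append(BLACK_LABEL)
            b -= 1
    return np.array(ordered, dtype=object)


def simulate(
    config: SyntheticConfig,
) -> tuple[PhotodiodeRecording, MarkerTable, GroundTruth]:
    """Generate one synthetic recording with markers and ground truth.

    Deterministic for a fixed ``config.seed``.  Trigger-send markers are
    quantised to the sample grid (that is where the amplifier records them);
    the ground truth keeps the continuous send/onset times.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    labels = _event_order(config, rng)
    n_events = labels.size
    if n_events == 0:
        raise ValueError("need at least one stimulus event")

    isis = rng.uniform(*config.isi_range_s, size=max(n_events - 1, 0))
    send = config.lead_in_s + np.concatenate(([0.0], np.cumsum(isis)))

    lat = np.empty(n_events)
    for i, lab in enumerate(labels):
        if lab == BLACK_LABEL and config.latency_ms_black is not None:
            base = config.latency_ms_black
            jit = (
                config.latency_jitter_ms_black
                if config.latency_jitter_ms_black is not None
                else config.latency_jitter_ms
            )
        else:
            base = config.latency_ms
            jit = config.latency_jitter_ms
        lat[i] = max(0.0, base + (rng.normal(0.0, jit) if jit > 0 else 0.0))
    onset = send + lat / 1000.0

    ends = onset + config.stim_dur_s
    if np.any(onset[1:] - ends[:-1] < 2.0 / fs):
        raise ValueError(
            "stimulus intervals overlap: injected latency plus stimulus "
            "duration exceeds the inter-stimulus interval"
        )

    total_s = ends[-1] + config.lead_out_s
    n_samples = int(np.ceil(total_s * fs))
    lv = config.levels

    if config.mode == "led":
        samples = _led_waveform(config, labels, onset, n_samples)
    else:
        samples = _hmd_waveform(config, labels, onset, n_samples)

    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, n_samples).astype(
            np.float32
        )
    samples = samples.astype(np.float32)

    events = [MarkerEvent(START_LABEL, 0.0)]
    for lab, t in zip(labels, send):
        events.append(MarkerEvent(str(lab), round(t * fs) / fs))
    events.append(MarkerEvent(END_LABEL, (n_samples - 1) / fs))
    markers = MarkerTable(events=events)

    truth = GroundTruth(
        labels=np.asarray(labels, dtype=object),
        send_s=send,
        onset_s=onset,
        latency_ms=lat,
    )
    recording = PhotodiodeRecording(samples=samples, fs=fs, channel_name="photodiode")
    return recording, markers, truth


def _led_waveform(
    config: SyntheticConfig,
    labels: np.ndarray,
    onset: np.ndarray,
    n_samples: int,
) -> np.ndarray:
    """Neutral baseline with square stimulus pulses and 2-sample
    half-cosine ramps (the mid-level sample precedes the onset sample, so
    the full level is reached exactly at the quantised onset)."""
    lv = config.levels
    fs = config.fs
    samples = np.full(n_samples, lv["neutral"], dtype=np.float32)
    for lab, t in zip(labels, onset):
        level = lv["white"] if lab == WHITE_LABEL else lv["black"]
        mid = lv["neutral"] + 0.5 * (level - lv["neutral"])
        i0 = int(round(t * fs))
        i1 = int(round((t + config.stim_dur_s) * fs))
        i1 = min(i1, n_samples - 1)
        if i0 < 1 or i0 >= n_samples:
            raise ValueError("stimulus onset outside the recording")
        samples[i0 - 1] = mid
        samples[i0:i1] = level
        samples[i1] = mid
    return samples


def _hmd_waveform(
    config: SyntheticConfig,
    labels: np.ndarray,
    onset: np.ndarray,
    n_samples: int,
) -> np.ndarray:
    """Refresh-rate peak train: single-sample peaks over a valley floor.

    Stimulus segments carry peaks at the stimulus level starting exactly at
    the quantised onset sample; neutral peaks fill the rest of the timeline
    on a fixed grid, skipping positions adjacent to stimulus peaks so every
    peak stays a strict local maximum.
    """
    lv = config.levels
    fs = config.fs
    sp = int(round(fs / config.refresh_hz))  # inter-peak spacing in samples
    if sp < 2:
        raise ValueError(
            f"refresh rate {config.refresh_hz} Hz is not resolvable at "
            f"fs={fs} Hz (needs >= 2 samples per refresh period)"
        )
    samples = np.full(n_samples, lv["valley"], dtype=np.float32)

    stim_idx: list[int] = []
    stim_level: list[float] = []
    blocked = np.zeros(n_samples, dtype=bool)
    n_stim_peaks_min = None
    for lab, t in zip(labels, onset):
        level = lv["white"] if lab == WHITE_LABEL else lv["black"]
        i0 = int(round(t * fs))
        i1 = int(round((t + config.stim_dur_s) * fs))
        if i0 < 1 or i1 >= n_samples:
            raise ValueError("stimulus onset outside the recording")
        idx = np.arange(i0, i1, sp)
        stim_idx.extend(idx.tolist())
        stim_level.extend([level] * idx.size)
        lo = max(0, i0 - 2)
        hi = min(n_samples, i1 + 2)
        blocked[lo:hi] = True
        n_stim_peaks_min = (
            idx.size if n_stim_peaks_min is None else min(n_stim_peaks_min, idx.size)
        )

    run_window_default = 11
    if n_stim_peaks_min is not None and n_stim_peaks_min < run_window_default:
        raise ValueError(
            f"only {n_stim_peaks_min} refresh peaks per stimulus; the "
            f"black-stimulus run rule needs at least {run_window_default}"
        )

    neutral_idx = np.arange(sp, n_samples - 1, sp)
    neutral_idx = neutral_idx[~blocked[neutral_idx]]
    samples[neutral_idx] = lv["neutral"]
    samples[np.asarray(stim_idx, dtype=np.int64)] = np.asarray(
        stim_level, dtype=np.float32
    )
    return samples


# ---------------------------------------------------------------------------
# BrainVision fixture output
# ---------------------------------------------------------------------------

_VHDR_TEMPLATE = """\
Brain Vision Data Exchange Header File Version 1.0
; Synthetic photodiode recording (generated fixture)

[Common Infos]
Codepage=UTF-8
DataFile={data_file}
MarkerFile={marker_file}
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels=1
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
Ch1={channel},,1,
"""

_VMRK_HEADER = """\
Brain Vision Data Exchange Marker File, Version 1.0
; Synthetic markers (generated fixture)

[Common Infos]
Codepage=UTF-8
DataFile={data_file}

[Marker Infos]
Mk1=New Segment,,1,1,0
"""


def write_fixture(
    recording: PhotodiodeRecording,
    markers: MarkerTable,
    dir_path: str | os.PathLike,
    basename: str = "synthetic",
) -> dict[str, Path]:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, IEEE_FLOAT_32,
    multiplexed) readable by :func:`clet.io_brainvision.read_brainvision`
    and by standard third-party readers.  Returns the three paths."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    vhdr = dir_path / f"{basename}.vhdr"
    vmrk = dir_path / f"{basename}.vmrk"
    eeg = dir_path / f"{basename}.eeg"

    sampling_interval = int(round(1e6 / recording.fs))
    vhdr.write_text(
        _VHDR_TEMPLATE.format(
            data_file=eeg.name,
            marker_file=vmrk.name,
            sampling_interval=sampling_interval,
            channel=recording.channel_name,
        ),
        encoding="utf-8",
    )

    lines = [_VMRK_HEADER.format(data_file=eeg.name)]
    for k, ev in enumerate(markers, start=2):
        pos = int(round(ev.onset_s * recording.fs)) + 1
        lines.append(f"Mk{k}=Stimulus,{ev.label},{pos},1,0\n")
    vmrk.write_text("".join(lines), encoding="utf-8")

    recording.samples.astype("<f4").tofile(eeg)
    return {"vhdr": vhdr, "vmrk": vmrk, "eeg": eeg}
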