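"""Core containers for photodiode-based trigger-latency analysis.

A recording session consists of a single analog photodiode trace sampled by
the EEG amplifier plus a table of stimulus markers ("S1" white, "S2" black,
"S7"/"S8" start/end) injected by the presentation software.  Detection
produces arrays of display-onset times which are paired with the marker send
times to yield per-event latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

#: Marker labels understood in strict mode.
KNOWN_LABELS = ("S1", "S2", "S7", "S8")

WHITE_LABEL = "S1"
BLACK_LABEL = "S2"
START_LABEL = "S7"
END_LABEL = "S8"


@dataclass(frozen=True)
class PhotodiodeRecording:
    """A sampled photodiode amplitude trace.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in sensor ADC units (dimensionless).  Must be finite.
    fs : float
        Sampling rate in Hz.
    channel_name : str
        Name of the source channel.
    t0 : float
        Time of sample 0 in recording coordinates (s).  Sample ``i`` sits at
        ``t0 + i / fs`` (0-based convention).
    """

    samples: np.ndarray
    fs: float
    channel_name: str = "photodiode"
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            bad = int(np.count_nonzero(~np.isfinite(samples)))
            raise ValueError(
                f"recording contains {bad} non-finite sample(s); thresholding "
                "raw amplitudes is undefined with NaN/Inf values"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Time axis in seconds, ``t0 + i/fs``."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def crop(self, tmin: float, tmax: float) -> "PhotodiodeRecording":
        """Return the sub-recording covering ``[tmin, tmax]`` (inclusive)."""
        i0 = max(0, int(np.ceil((tmin - self.t0) * self.fs - 1e-9)))
        i1 = min(self.n_samples - 1, int(np.floor((tmax - self.t0) * self.fs + 1e-9)))
        if i1 < i0:
            raise ValueError(f"empty crop window [{tmin}, {tmax}]")
        return PhotodiodeRecording(
            samples=self.samples[i0 : i1 + 1],
            fs=self.fs,
            channel_name=self.channel_name,
            t0=self.t0 + i0 / self.fs,
        )


@dataclass(frozen=True)
class MarkerEvent:
    """One sent-trigger event: a label and its onset in recording time."""

    label: str
    onset_s: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"marker onset must be >= 0, got {self.onset_s}")


@dataclass
class MarkerTable:
    """Ordered collection of sent-trigger events (houses tS1/tS2)."""

    events: list[MarkerEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset_s)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def select(self, label: str) -> np.ndarray:
        """Onset times (s) of all events with the given label, ascending."""
        return np.array(
            [e.onset_s for e in self.events if e.label == label], dtype=np.float64
        )

    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    def validate_labels(self, known: Sequence[str] = KNOWN_LABELS) -> None:
        """Strict-mode check that every label is in the known vocabulary."""
        unknown = sorted({e.label for e in self.events} - set(known))
        if unknown:
            raise ValueError(f"unknown marker labels: {unknown}; expected {list(known)}")


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the onset-detection algorithms.

    ``thd1`` is the amplitude above which the white-stimulus transient is
    detected; ``thd2`` the level below which the black-stimulus signature
    falls (a drop of the trace itself on an LED screen, small refresh-peak
    heights on an HMD).  ``lisi`` is the lower bound of the inter-stimulus
    interval; crossings closer than ``round(fs * lisi)`` samples are grouped
    into one onset.
    """

    thd1: float
    thd2: float
    lisi: float = 1.0
    mode: Literal["led", "hmd"] = "led"
    hmd_run_window: int = 11
    led_black_polarity: Literal["below", "above"] = "below"
    #: "previous_edge" transcribes the grouping rule literally (each edge is
    #: compared against the immediately preceding edge); "last_onset" compares
    #: against the last retained onset instead.
    group_policy: Literal["previous_edge", "last_onset"] = "previous_edge"
    #: "all" requires every peak height in the run window below thd2;
    #: "literal" checks only window positions 0, 1, 2 and window-1 as printed.
    hmd_run_rule: Literal["all", "literal"] = "all"

    def __post_init__(self) -> None:
        if self.lisi <= 0:
            raise ValueError(f"lisi must be positive, got {self.lisi}")
        if self.hmd_run_window < 2:
            raise ValueError(f"hmd_run_window must be >= 2, got {self.hmd_run_window}")
        if self.mode not in ("led", "hmd"):
            raise ValueError(f"mode must be 'led' or 'hmd', got {self.mode!r}")
        if self.mode == "led" and self.led_black_polarity == "below":
            if not self.thd2 < self.thd1:
                raise ValueError(
                    f"LED mode with below-polarity black detection requires "
                    f"thd2 < thd1, got thd2={self.thd2}, thd1={self.thd1}"
                )

    def indx_gap(self, fs: float) -> int:
        """Minimum sample separation between accepted onsets: round(fs*lisi)."""
        return int(round(fs * self.lisi))


@dataclass(frozen=True)
class OnsetArray:
    """Detected display-onset positions (houses tD1/tD2)."""

    onset_samples: np.ndarray
    onset_times_s: np.ndarray
    warning: str | None = None

    def __post_init__(self) -> None:
        onset_samples = np.asarray(self.onset_samples, dtype=np.int64)
        onset_times_s = np.asarray(self.onset_times_s, dtype=np.float64)
        object.__setattr__(self, "onset_samples", onset_samples)
        object.__setattr__(self, "onset_times_s", onset_times_s)
        if onset_samples.shape != onset_times_s.shape:
            raise ValueError("onset_samples and onset_times_s must align")
        if onset_samples.size > 1 and not np.all(np.diff(onset_samples) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.onset_samples.size)

    @classmethod
    def from_samples(
        cls,
        onset_samples: np.ndarray,
        recording: PhotodiodeRecording,
        warning: str | None = None,
    ) -> "OnsetArray":
        onset_samples = np.asarray(onset_samples, dtype=np.int64)
        return cls(
            onset_samples=onset_samples,
            onset_times_s=recording.t0 + onset_samples / recording.fs,
            warning=warning,
        )

    @classmethod
    def empty(cls, warning: str | None = None) -> "OnsetArray":
        return cls(
            onset_samples=np.empty(0, dtype=np.int64),
            onset_times_s=np.empty(0, dtype=np.float64),
            warning=warning,
        )


@dataclass(frozen=True)
class PeakSet:
    """Strict local maxima of a trace: positions and their amplitudes."""

    indices: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        indices = np.asarray(self.indices, dtype=np.int64)
        heights = np.asarray(self.heights, dtype=np.float64)
        object.__setattr__(self, "indices", indices)
        object.__setattr__(self, "heights", heights)
        if indices.shape != heights.shape:
            raise ValueError("indices and heights must align")
        if indices.size > 1 and not np.all(np.diff(indices) > 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)
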