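"""Model/results facade for a full latency-measurement run.

``TriggerLatencyModel`` binds a photodiode recording, its marker table and
the detection parameters; ``fit()`` runs onset detection for both stimulus
types, pairs detections with sent triggers and returns a
``TriggerLatencyResults`` carrying per-event latencies, their summary
statistics and diagnostics, statsmodels-style.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._types import (
    BLACK_LABEL,
    END_LABEL,
    START_LABEL,
    WHITE_LABEL,
    DetectionParams,
    MarkerTable,
    OnsetArray,
    PhotodiodeRecording,
)
from .detect_hmd import detect_onsets_hmd
from .detect_led import detect_onsets_led
from .io_brainvision import read_brainvision, write_latency_table
from .latency_stats import (
    LatencyResult,
    RunReport,
    compute_latencies,
    pair_events,
    summarize_run,
)

__all__ = ["TriggerLatencyModel", "TriggerLatencyResults"]


class TriggerLatencyModel:
    """Trigger-to-display latency measurement on one recording.

    Parameters
    ----------
    recording, markers
        The photodiode trace and the sent-trigger table.
    params : DetectionParams
        Thresholds, minimum ISI and display mode.
    pairing : {"strict", "nearest_following"}
        How sent triggers are matched to detected onsets.  The protocol
        guarantees one onset per trigger, so strict index alignment is the
        default.
    bin_width_ms : float
        Histogram bin width of the latency distributions.

    When both start ("S7") and end ("S8") markers are present, detection is
    restricted to the [tS7, tS8] window.
    """

    def __init__(
        self,
        recording: PhotodiodeRecording,
        markers: MarkerTable,
        params: DetectionParams,
        pairing: Literal["strict", "nearest_following"] = "strict",
        max_lag_s: float | None = None,
        bin_width_ms: float = 1.0,
    ) -> None:
        self.recording = recording
        self.markers = markers
        self.params = params
        self.pairing = pairing
        self.max_lag_s = max_lag_s if max_lag_s is not None else params.lisi
        self.bin_width_ms = bin_width_ms

    @classmethod
    def from_brainvision(
        cls,
        header_path: str | os.PathLike,
        channel: str,
        params: DetectionParams,
        **kwargs,
    ) -> "TriggerLatencyModel":
        recording, markers = read_brainvision(header_path, channel)
        return cls(recording, markers, params, **kwargs)

    # -- fitting -----------------------------------------------------------

    def _analysis_recording(self) -> PhotodiodeRecording:
        starts = self.markers.select(START_LABEL)
        ends = self.markers.select(END_LABEL)
        if starts.size and ends.size:
            return self.recording.crop(float(starts[0]), float(ends[-1]))
        return self.recording

    def _detect(
        self, recording: PhotodiodeRecording, stimulus: Literal["white", "black"]
    ) -> OnsetArray:
        if self.params.mode == "led":
            return detect_onsets_led(recording, self.params, stimulus)
        return detect_onsets_hmd(recording, self.params, stimulus)

    def fit(self) -> "TriggerLatencyResults":
        """Run detection and pairing; returns the results object.

        Raises :class:`~clet.latency_stats.PairingError` under strict
        pairing when sent and detected counts disagree.
        """
        recording = self._analysis_recording()
        per_type: dict[str, LatencyResult] = {}
        onsets: dict[str, OnsetArray] = {}
        unmatched: dict[str, dict[str, list[int]]] = {}
        for label, stimulus in ((WHITE_LABEL, "white"), (BLACK_LABEL, "black")):
            sent = self.markers.select(label)
            detected_arr = self._detect(recording, stimulus)
            onsets[label] = detected_arr
            detected = detected_arr.onset_times_s
            pairs, un_s, un_d = pair_events(
                sent, detected, policy=self.pairing, max_lag_s=self.max_lag_s
            )
            i_s = np.array([p[0] for p in pairs], dtype=np.int64)
            i_d = np.array([p[1] for p in pairs], dtype=np.int64)
            per_type[label] = compute_latencies(
                sent[i_s] if pairs else sent[:0],
                detected[i_d] if pairs else detected[:0],
                stimulus_type=label,
                bin_width_ms=self.bin_width_ms,
            )
            unmatched[label] = {"sent": un_s, "detected": un_d}
        report = summarize_run([per_type[WHITE_LABEL], per_type[BLACK_LABEL]])
        return TriggerLatencyResults(
            model=self, results_by_type=per_type, onsets=onsets,
            unmatched=unmatched, report=report,
        )


@dataclass
class TriggerLatencyResults:
    """Estimated latencies, dispersion and diagnostics for one run."""

    model: TriggerLatencyModel
    results_by_type: dict[str, LatencyResult]
    onsets: dict[str, OnsetArray]
    unmatched: dict[str, dict[str, list[int]]]
    report: RunReport

    @property
    def white(self) -> LatencyResult:
        return self.results_by_type[WHITE_LABEL]

    @property
    def black(self) -> LatencyResult:
        return self.results_by_type[BLACK_LABEL]

    def summary(self) -> str:
        """Human-readable per-type summary table."""
        p = self.model.params
        lines = [
            "Trigger latency results",
            "=======================",
            f"mode: {p.mode}   ThD1: {p.thd1:g}   ThD2: {p.thd2:g}   "
            f"Lisi: {p.lisi:g} s   pairing: {self.model.pairing}",
            "",
            f"{'stimulus':<10}{'n':>5}{'mean_ms':>12}{'sd_ms':>10}"
            f"{'min_ms':>10}{'max_ms':>10}",
        ]
        for label, r in self.results_by_type.items():
            if r.empty:
                lines.append(f"{label:<10}{0:>5}{'--':>12}{'--':>10}{'--':>10}{'--':>10}")
                continue
            lines.append(
                f"{label:<10}{r.n:>5}{r.mean_ms:>12.2f}{r.sd_ms:>10.2f}"
                f"{r.latencies_ms.min():>10.2f}{r.latencies_ms.max():>10.2f}"
            )
        for label, info in self.unmatched.items():
            if info["sent"] or info["detected"]:
                lines.append(
                    f"unmatched {label}: {len(info['sent'])} sent, "
                    f"{len(info['detected'])} detected"
                )
        return "\n".join(lines)

    def plot_distribution(self, path=None, ax=None):
        """Overlaid per-type latency histograms."""
        return self.report.plot(path=path, ax=ax)

    def to_csv(self, outdir: str | os.PathLike) -> list[str]:
        """Write one latency table per non-empty stimulus type."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for label, r in self.results_by_type.items():
            if r.empty:
                continue
            path = outdir / f"latencies_{label}.csv"
            write_latency_table(r, path)
            written.append(str(path))
        return written
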