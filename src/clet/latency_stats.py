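"""Per-event trigger latencies and their summary statistics.

The latency of event ``k`` is ``(tD[k] - tS[k]) * 1000`` in milliseconds,
where ``tS`` is the time the presentation software sent the trigger and
``tD`` the display onset measured on the photodiode.  The protocol
guarantees one display onset per sent trigger, so the default pairing is a
strict index alignment; a ``nearest_following`` policy handles noisy traces
where events may be missed or spurious.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "LatencyResult",
    "PairingError",
    "pair_events",
    "compute_latencies",
    "summarize_run",
    "RunReport",
]


class PairingError(ValueError):
    """Sent triggers and detected onsets cannot be paired."""


def pair_events(
    sent: np.ndarray,
    detected: np.ndarray,
    policy: Literal["strict", "nearest_following"] = "strict",
    max_lag_s: float = 1.0,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Pair sent-trigger times with detected-onset times.

    Returns ``(pairs, unmatched_sent, unmatched_detected)`` where each pair
    is ``(sent_index, detected_index)``.

    ``strict`` requires equal lengths and pairs index-by-index, rejecting any
    negative implied latency.  ``nearest_following`` pairs each sent time
    with the earliest unconsumed detection in ``(sent, sent + max_lag_s]``.
    """
    sent = np.asarray(sent, dtype=np.float64)
    detected = np.asarray(detected, dtype=np.float64)
    for name, arr in (("sent", sent), ("detected", detected)):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise PairingError(f"{name} times must be ascending")
    if max_lag_s <= 0:
        raise PairingError(f"max_lag_s must be positive, got {max_lag_s}")

    if policy == "strict":
        if sent.size != detected.size:
            raise PairingError(
                f"strict pairing needs equal counts: {sent.size} sent triggers "
                f"vs {detected.size} detected onsets"
            )
        neg = np.flatnonzero(detected < sent)
        if neg.size:
            k = int(neg[0])
            raise PairingError(
                f"detection at {detected[k]:.6f} s precedes its trigger at "
                f"{sent[k]:.6f} s (event {k})"
            )
        pairs = [(k, k) for k in range(sent.size)]
        return pairs, [], []

    if policy == "nearest_following":
        pairs = []
        used = np.zeros(detected.size, dtype=bool)
        j = 0
        for i, t in enumerate(sent):
            while j < detected.size and (detected[j] <= t or used[j]):
                j += 1
            if j < detected.size and detected[j] <= t + max_lag_s:
                pairs.append((i, j))
                used[j] = True
                j += 1
        matched_sent = {i for i, _ in pairs}
        matched_det = {j for _, j in pairs}
        unmatched_sent = [i for i in range(sent.size) if i not in matched_sent]
        unmatched_det = [j for j in range(detected.size) if j not in matched_det]
        return pairs, unmatched_sent, unmatched_det

    raise PairingError(f"unknown pairing policy {policy!r}")


@dataclass(frozen=True)
class LatencyResult:
    """Per-event latencies for one stimulus type, with summary statistics.

    ``mean_ms`` and ``sd_ms`` are the arithmetic mean and *sample* standard
    deviation (n-1 denominator); both are NaN when ``n < 1`` resp. ``n < 2``.
    ``histogram`` is ``(bin_edges_ms, counts)`` over 1-ms bins spanning the
    observed range (configurable through :func:`compute_latencies`).
    """

    stimulus_type: str
    tS_s: np.ndarray
    tD_s: np.ndarray
    latencies_ms: np.ndarray
    n: int
    mean_ms: float
    sd_ms: float
    histogram: tuple[np.ndarray, np.ndarray]

    @property
    def empty(self) -> bool:
        return self.n == 0


def compute_latencies(
    sent: np.ndarray,
    detected: np.ndarray,
    stimulus_type: str = "S1",
    bin_width_ms: float = 1.0,
) -> LatencyResult:
    """Element-wise latencies ``(tD - tS) * 1000`` plus mean/SD/histogram.

    Inputs must already be paired (equal lengths, index-aligned).
    """
    tS = np.asarray(sent, dtype=np.float64)
    tD = np.asarray(detected, dtype=np.float64)
    if tS.shape != tD.shape:
        raise PairingError(
            f"paired inputs required: {tS.size} sent vs {tD.size} detected"
        )
    lat = (tD - tS) * 1000.0
    n = int(lat.size)
    if n == 0:
        return LatencyResult(
            stimulus_type=stimulus_type,
            tS_s=tS,
            tD_s=tD,
            latencies_ms=lat,
            n=0,
            mean_ms=float("nan"),
            sd_ms=float("nan"),
            histogram=(np.empty(0), np.empty(0, dtype=np.int64)),
        )
    mean = float(np.mean(lat))
    sd = float(np.std(lat, ddof=1)) if n > 1 else float("nan")
    edges = _bin_edges(lat, bin_width_ms)
    counts, edges = np.histogram(lat, bins=edges)
    return LatencyResult(
        stimulus_type=stimulus_type,
        tS_s=tS,
        tD_s=tD,
        latencies_ms=lat,
        n=n,
        mean_ms=mean,
        sd_ms=sd,
        histogram=(edges, counts),
    )


def _bin_edges(lat: np.ndarray, bin_width_ms: float) -> np.ndarray:
    """Bin edges aligned to multiples of the bin width, covering the data."""
    lo = np.floor(lat.min() / bin_width_ms) * bin_width_ms
    hi = np.ceil(lat.max() / bin_width_ms) * bin_width_ms
    if hi <= lo:
        hi = lo + bin_width_ms
    n_bins = int(round((hi - lo) / bin_width_ms))
    return lo + bin_width_ms * np.arange(n_bins + 1)


@dataclass
class RunReport:
    """Aggregated per-type summary of one analysis run."""

    results: list[LatencyResult]
    table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "stimulus_type": r.stimulus_type,
                    "n": r.n,
                    "mean_ms": r.mean_ms,
                    "sd_ms": r.sd_ms,
                    "empty": r.empty,
                }
            )
        self.table = pd.DataFrame(rows)

    @property
    def empty_types(self) -> list[str]:
        return [r.stimulus_type for r in self.results if r.empty]

    def histogram_series(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-type (bin_edges_ms, counts) for overlaid distribution plots."""
        return {r.stimulus_type: r.histogram for r in self.results if not r.empty}

    def plot(self, path=None, ax=None):
        """Overlaid latency histograms, one series per stimulus type."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for r in self.results:
            if r.empty:
                continue
            edges, counts = r.histogram
            ax.stairs(counts, edges, fill=True, alpha=0.5,
                      label=f"{r.stimulus_type} (n={r.n})")
        ax.set_xlabel("latency (ms)")
        ax.set_ylabel("events")
        ax.set_title("Trigger latency distribution")
        ax.legend()
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt = ax.figure
        return ax

    def __str__(self) -> str:
        lines = ["stimulus  n    mean_ms   sd_ms"]
        for r in self.results:
            if r.empty:
                lines.append(f"{r.stimulus_type:<9} 0    (no events detected)")
            else:
                lines.append(
                    f"{r.stimulus_type:<9} {r.n:<4} {r.mean_ms:<9.2f} {r.sd_ms:.2f}"
                )
        return "\n".join(lines)


def summarize_run(results: list[LatencyResult]) -> RunReport:
    """Per-type n/mean/SD table plus overlaid histogram data."""
    if not results:
        raise ValueError("need at least one latency result to summarize")
    return RunReport(results=list(results))
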