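"""Onset detection for LED-screen photodiode data.

A white stimulus produces a transient rise of the photodiode trace above a
user-chosen threshold ThD1; a black stimulus a transient drop below ThD2.
Detection is a three-stage pipeline:

1. binarise the trace against the threshold (:func:`threshold_mask`),
2. find rising edges of the binary mask with a leading-zero-padded first
   difference (:func:`rising_edges`),
3. group edges closer than the minimum inter-stimulus separation
   ``indxGap = round(fs * Lisi)`` into single onsets (:func:`group_onsets`).

The grouping rule is transcribed literally: an edge is retained when it
exceeds the *immediately preceding edge* by more than ``indxGap`` (not the
last retained onset).  The alternative comparator is available through
``DetectionParams.group_policy`` because the two differ on edge trains whose
bursts are closer together than the inter-stimulus interval.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np

from ._types import DetectionParams, OnsetArray, PhotodiodeRecording

__all__ = [
    "threshold_mask",
    "rising_edges",
    "group_onsets",
    "detect_onsets_led",
    "suggest_thresholds",
]


def threshold_mask(
    recording: PhotodiodeRecording | np.ndarray,
    threshold: float,
    direction: Literal["above", "below"],
) -> np.ndarray:
    """Binary mask of samples beyond a threshold.

    ``above`` marks samples >= threshold, ``below`` marks samples <=
    threshold.  Returns a uint8 array of the recording's length.
    """
    samples = recording.samples if isinstance(recording, PhotodiodeRecording) else np.asarray(recording)
    if direction == "above":
        return (samples >= threshold).astype(np.uint8)
    if direction == "below":
        return (samples <= threshold).astype(np.uint8)
    raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")


def rising_edges(mask: np.ndarray) -> np.ndarray:
    """Indices where the mask steps 0 -> 1.

    The first difference of the mask is padded with a leading zero, so an
    index ``i`` is an edge iff ``i >= 1``, ``mask[i] == 1`` and
    ``mask[i-1] == 0``; a mask starting at 1 contributes no edge at index 0.
    """
    mask = np.asarray(mask)
    if mask.size == 0:
        return np.empty(0, dtype=np.int64)
    diff = np.concatenate(([0], np.diff(mask.astype(np.int8))))
    return np.flatnonzero(diff == 1).astype(np.int64)


def group_onsets(
    edges: np.ndarray,
    indx_gap: int,
    policy: Literal["previous_edge", "last_onset"] = "previous_edge",
) -> np.ndarray:
    """Collapse edge bursts into one onset per stimulus.

    The first edge is always retained.  Under ``previous_edge`` a subsequent
    edge is retained iff it exceeds the immediately preceding *edge* by more
    than ``indx_gap`` samples; under ``last_onset`` the comparison is against
    the last *retained* onset.
    """
    edges = np.asarray(edges, dtype=np.int64)
    if indx_gap < 1:
        raise ValueError(f"indx_gap must be >= 1, got {indx_gap}")
    if edges.size == 0:
        return edges.copy()
    if edges.size > 1 and np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly ascending")
    if policy == "previous_edge":
        keep = np.concatenate(([True], np.diff(edges) > indx_gap))
        return edges[keep]
    if policy == "last_onset":
        onsets = [int(edges[0])]
        for e in edges[1:]:
            if e > onsets[-1] + indx_gap:
                onsets.append(int(e))
        return np.asarray(onsets, dtype=np.int64)
    raise ValueError(f"unknown group policy {policy!r}")


def detect_onsets_led(
    recording: PhotodiodeRecording,
    params: DetectionParams,
    stimulus: Literal["white", "black"],
) -> OnsetArray:
    """Detect display onsets of one stimulus type on an LED-screen trace.

    White: mask above ThD1; black: mask below ThD2 by default (the threshold
    is defined as the level *under* which the black-stimulus drop falls;
    ``params.led_black_polarity="above"`` selects the >= comparator instead).
    """
    if stimulus == "white":
        mask = threshold_mask(recording, params.thd1, "above")
    elif stimulus == "black":
        direction = "below" if params.led_black_polarity == "below" else "above"
        mask = threshold_mask(recording, params.thd2, direction)
    else:
        raise ValueError(f"stimulus must be 'white' or 'black', got {stimulus!r}")
    return _edges_to_onsets(mask, recording, params, stimulus)


def _edges_to_onsets(
    mask: np.ndarray,
    recording: PhotodiodeRecording,
    params: DetectionParams,
    stimulus: str,
) -> OnsetArray:
    """Shared tail of the LED and HMD pipelines: edges -> grouped onsets."""
    edges = rising_edges(mask)
    onsets = group_onsets(edges, params.indx_gap(recording.fs), params.group_policy)
    if onsets.size == 0:
        msg = f"no {stimulus}-stimulus onsets detected"
        warnings.warn(msg, stacklevel=3)
        return OnsetArray.empty(warning=msg)
    return OnsetArray.from_samples(onsets, recording)


def suggest_thresholds(recording: PhotodiodeRecording) -> tuple[float, float]:
    """Convenience suggestion for (ThD1, ThD2); never applied silently.

    Midpoints between the baseline median and the extreme percentiles of the
    trace.  Meant as a starting point for the visual-inspection step the
    method prescribes, not a replacement for it.
    """
    baseline = float(np.median(recording.samples))
    hi = float(np.percentile(recording.samples, 99.9))
    lo = float(np.percentile(recording.samples, 0.1))
    return (baseline + hi) / 2.0, (baseline + lo) / 2.0
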