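"""Onset detection for head-mounted-display photodiode data.

An HMD refreshes continuously (90 Hz on the device used here), so the
photodiode sees a peak train rather than a step: peak heights rise above
ThD1 while a white stimulus is displayed and collapse below ThD2 while a
black stimulus is displayed, sitting in between otherwise.

White onsets therefore use the same pipeline as the LED screen (threshold
mask above ThD1 -> rising edges -> gap grouping).  Black onsets are found by
locating *runs* of consecutive small peaks: a peak belongs to the black
signature when it is part of a run of ``hmd_run_window`` (default 11)
consecutive peaks whose heights all fall strictly below ThD2.  Marked peak
positions form a binary mask that is fed through the same edge/grouping
tail, so the detected onset is the first small peak of each run.

The printed form of the run condition enumerates only window positions
n, n+1, n+2 and n+10; the default rule requires *all* positions of the
window (the strictest consistent reading of an elided enumeration), and
``hmd_run_rule="literal"`` reproduces the 4-position check verbatim.  On
traces whose 11-peak runs are homogeneous the two coincide.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from ._types import DetectionParams, OnsetArray, PeakSet, PhotodiodeRecording
from .detect_led import _edges_to_onsets, detect_onsets_led

__all__ = ["find_all_peaks", "small_peak_mask", "detect_onsets_hmd"]


def find_all_peaks(recording: PhotodiodeRecording | np.ndarray) -> PeakSet:
    """Every strict local maximum of the trace; plateaus count once, at
    their first sample."""
    samples = recording.samples if isinstance(recording, PhotodiodeRecording) else np.asarray(recording, dtype=float)
    if samples.size < 3:
        raise ValueError("need at least 3 samples to define a local maximum")
    _, props = find_peaks(samples, plateau_size=1)
    indices = props["left_edges"].astype(np.int64)
    return PeakSet(indices=indices, heights=samples[indices])


def small_peak_mask(
    peaks: PeakSet,
    recording_length: int,
    thd2: float,
    run_window: int = 11,
    rule: Literal["all", "literal"] = "all",
) -> np.ndarray:
    """Binary mask marking peaks that belong to a run of small peaks.

    A run starts at peak ``k`` when the run condition holds over the window
    of ``run_window`` consecutive peaks beginning at ``k``; every peak of a
    qualifying run is marked.  Non-peak samples are always 0.
    """
    if run_window < 2:
        raise ValueError(f"run_window must be >= 2, got {run_window}")
    mask = np.zeros(recording_length, dtype=np.uint8)
    n = len(peaks)
    if n < run_window:
        warnings.warn(
            f"only {n} peaks found, fewer than the run window of {run_window}; "
            "no black-stimulus signature can be detected",
            stacklevel=2,
        )
        return mask
    small = peaks.heights < thd2  # strict comparison, as specified
    if rule == "all":
        # run-start flag: all of small[k : k + run_window]
        window_sum = np.convolve(small.astype(np.int64), np.ones(run_window, dtype=np.int64), mode="valid")
        starts = window_sum == run_window
    elif rule == "literal":
        # check only window offsets 0, 1, 2 and run_window-1 as printed
        offsets = [0, 1, 2, run_window - 1]
        n_starts = n - run_window + 1
        starts = np.ones(n_starts, dtype=bool)
        for off in offsets:
            starts &= small[off : off + n_starts]
    else:
        raise ValueError(f"unknown run rule {rule!r}")
    marked = np.zeros(n, dtype=bool)
    for k in np.flatnonzero(starts):
        marked[k : k + run_window] = True
    mask[peaks.indices[marked]] = 1
    return mask


def detect_onsets_hmd(
    recording: PhotodiodeRecording,
    params: DetectionParams,
    stimulus: Literal["white", "black"],
) -> OnsetArray:
    """Detect display onsets of one stimulus type on an HMD trace."""
    if stimulus == "white":
        # identical to the LED pipeline with the HMD ThD1
        return detect_onsets_led(recording, params, "white")
    if stimulus != "black":
        raise ValueError(f"stimulus must be 'white' or 'black', got {stimulus!r}")
    peaks = find_all_peaks(recording)
    mask = small_peak_mask(
        peaks,
        recording.n_samples,
        params.thd2,
        run_window=params.hmd_run_window,
        rule=params.hmd_run_rule,
    )
    return _edges_to_onsets(mask, recording, params, stimulus)
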