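"""Independent brute-force interpreters of the detection steps.

These deliberately avoid numpy vectorisation and the package's own code
paths: they walk arrays index by index so that the vectorised
implementations can be checked against a literal transcription.
"""

from __future__ import annotations


def brute_rising_edges(bits) -> list[int]:
    """Leading-zero-padded first difference, == 1 positions, by hand."""
    bits = [int(b) for b in bits]
    diff = [0] + [bits[i] - bits[i - 1] for i in range(1, len(bits))]
    return [i for i, d in enumerate(diff) if d == 1]


def brute_group_onsets(edges, gap: int) -> list[int]:
    """Gap grouping with the previous-edge comparator, by hand.

    onsetsam[0] = edges[0]; for each later n, keep edges[n] iff
    edges[n] > edges[n-1] + gap; zero placeholders removed at the end.
    """
    edges = [int(e) for e in edges]
    if not edges:
        return []
    onsetsam = [0] * len(edges)
    onsetsam[0] = edges[0]
    for n in range(1, len(edges)):
        if edges[n] > edges[n - 1] + gap:
            onsetsam[n] = edges[n]
    return [v for v in onsetsam if v != 0]


def brute_group_onsets_last_onset(edges, gap: int) -> list[int]:
    """Alternative comparator: against the last retained onset."""
    edges = [int(e) for e in edges]
    if not edges:
        return []
    kept = [edges[0]]
    for e in edges[1:]:
        if e > kept[-1] + gap:
            kept.append(e)
    return kept


def brute_small_peak_runs(heights, thd2: float, window: int) -> list[int]:
    """Peak positions (indices into the peak sequence) belonging to a run of
    `window` consecutive peaks all strictly below thd2."""
    n = len(heights)
    marked = set()
    for k in range(n - window + 1):
        if all(heights[k + j] < thd2 for j in range(window)):
            marked.update(range(k, k + window))
    return sorted(marked)
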