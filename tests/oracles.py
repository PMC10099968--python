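"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the ARI oracle
enumerates element pairs directly instead of going through a contingency
table, and the histogram oracle counts spikes bin by bin in pure Python.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ari_pair_counting(labels_a, labels_b) -> float:
    """ARI by explicit enumeration of all element pairs."""
    a = list(labels_a)
    b = list(labels_b)
    n = len(a)
    n11 = n10 = n01 = n00 = 0
    for i, j in combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    total = n * (n - 1) // 2
    sum_a = n11 + n10  # pairs co-grouped in A
    sum_b = n11 + n01  # pairs co-grouped in B
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if n11 == expected else 0.0
    return (n11 - expected) / (max_index - expected)


def set_partitions(items):
    """All set partitions of a sequence, as label vectors."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        k = max(part, default=-1) + 1
        for block in range(k + 1):
            yield [block] + part


def histogram_rate(spike_times_s, align_times_s, window_ms, bin_width_ms):
    """Trial-averaged pre-smoothing rate by per-bin counting in pure Python."""
    start, end = window_ms
    n_bins = int(round((end - start) / bin_width_ms))
    counts = [0] * n_bins
    for t0 in align_times_s:
        for s in spike_times_s:
            rel = (s - t0) * 1000.0
            if start <= rel < end:
                b = int((rel - start) // bin_width_ms)
                if b == n_bins:  # guard float edge
                    b -= 1
                counts[b] += 1
    n_trials = len(align_times_s)
    return np.array(counts) / (n_trials * bin_width_ms / 1000.0)
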