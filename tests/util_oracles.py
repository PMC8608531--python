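"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (enumeration / O(n^2) sums) and never
calls into the clustering implementation it is used to check.
"""

from __future__ import annotations

import numpy as np


def iter_partitions(n: int, k_max: int):
    """All set partitions of range(n) into at most k_max non-empty parts,
    enumerated as restricted-growth strings."""

    def rec(i, labels, n_used):
        if i == n:
            yield list(labels)
            return
        for lab in range(min(n_used + 1, k_max)):
            labels.append(lab)
            yield from rec(i + 1, labels, max(n_used, lab + 1))
            labels.pop()

    yield from rec(0, [], 0)


def partition_sse(x: np.ndarray, labels) -> float:
    """Within-cluster SSE of an explicit partition, from first principles."""
    labels = np.asarray(labels)
    sse = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        sse += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return sse


def best_partition_sse(x: np.ndarray, k: int) -> float:
    """Global optimum of the k-means objective by exhaustive enumeration of
    all partitions into at most k non-empty parts (small n only)."""
    return min(partition_sse(x, lab) for lab in iter_partitions(len(x), k))


def pairwise_within_sse(x: np.ndarray, labels) -> float:
    """Pairwise form of the within-cluster SSE:
    sum_i 1/(2|C_i|) * sum_{x,y in C_i} ||x - y||^2, summed termwise."""
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        m = len(pts)
        acc = 0.0
        for a in range(m):
            for b in range(m):
                acc += float(((pts[a] - pts[b]) ** 2).sum())
        total += acc / (2.0 * m)
    return total


def tally_counts(labels, k: int) -> list[int]:
    """Sort-and-scan label tally, independent of numpy bincount."""
    out = [0] * k
    for lab in sorted(int(v) for v in np.asarray(labels).reshape(-1)):
        out[lab] += 1
    return out
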