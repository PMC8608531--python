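"""Per-cluster pixel counts, percentage ratios, and the denominator cluster.

Ratios are computed from exact integer counts with rational arithmetic, so
the unrounded percentages always sum to exactly 100.  Rounding to two
decimals goes through an intermediate three-decimal half-up step — the
two-stage scheme that reproduces published pixel-ratio tables produced by
re-rounding already-rounded percentages (a single direct rounding differs
in the third decimal's tie cases).  The "denominator cluster" is the
cluster holding the largest pixel share.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClusterStatsTable",
    "count_pixels",
    "pixel_ratios",
    "exact_ratios",
    "denominator_cluster",
    "compute_cluster_stats",
    "write_stats_table",
    "read_stats_table",
]

STATS_COLUMNS = [
    "image_name",
    "cluster_label",
    "pixel_count",
    "ratio_percent",
    "denominator_flag",
]


def count_pixels(labels, k: int) -> np.ndarray:
    """Multiplicity of each label 0..k-1; sums to the number of pixels."""
    labels = np.asarray(labels).reshape(-1)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(
            f"labels must lie in [0, {k}), got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    return np.bincount(labels, minlength=k)


def exact_ratios(counts) -> list[Fraction]:
    """Unrounded percentage shares as exact rationals (sum is exactly 100)."""
    counts = [int(c) for c in np.asarray(counts).reshape(-1)]
    total = sum(counts)
    if total < 1:
        raise ValueError("counts sum to zero; cannot form ratios")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    return [Fraction(100 * c, total) for c in counts]


def _round_half_up(value: Fraction, decimals: int) -> Fraction:
    scaled = value * 10**decimals
    floor = scaled.numerator // scaled.denominator
    if scaled - floor >= Fraction(1, 2):
        floor += 1
    return Fraction(floor, 10**decimals)


def pixel_ratios(counts) -> np.ndarray:
    """Percentage share of each cluster, rounded to 2 decimals.

    Exact rational ratios are rounded half-up to 3 decimals, then half-up
    to 2 (see module docstring for why two stages).
    """
    return np.array(
        [float(_round_half_up(_round_half_up(r, 3), 2)) for r in exact_ratios(counts)]
    )


def denominator_cluster(counts) -> int:
    """1-based label of the largest cluster (ties to the smaller label)."""
    counts = np.asarray(counts).reshape(-1)
    if counts.sum() < 1:
        raise ValueError("counts sum to zero; no denominator cluster")
    return int(np.argmax(counts)) + 1


@dataclass
class ClusterStatsTable:
    """One image's per-cluster pixel distribution (counts + percentage shares).

    ``cluster_labels`` are 1-based reporting labels (luminance-ordered when
    produced by the segmentation pipeline)."""

    image_name: str
    cluster_labels: list[int]
    pixel_counts: np.ndarray
    ratio_percents: np.ndarray
    denominator: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_name": self.image_name,
                "cluster_label": self.cluster_labels,
                "pixel_count": np.asarray(self.pixel_counts, dtype=int),
                "ratio_percent": self.ratio_percents,
                "denominator_flag": [
                    int(lbl == self.denominator) for lbl in self.cluster_labels
                ],
            }
        )


def compute_cluster_stats(labels, k: int, image_name: str = "") -> ClusterStatsTable:
    """Counts, ratios and denominator cluster for one label vector.

    ``labels`` are 0-based cluster indices; reporting labels are 1-based.
    """
    counts = count_pixels(labels, k)
    return ClusterStatsTable(
        image_name=image_name,
        cluster_labels=list(range(1, k + 1)),
        pixel_counts=counts,
        ratio_percents=pixel_ratios(counts),
        denominator=denominator_cluster(counts),
    )


def write_stats_table(tables: list[ClusterStatsTable], path) -> None:
    """Write tables as CSV (UTF-8, header row), grouped by image in input order."""
    if tables:
        frame = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    else:
        frame = pd.DataFrame(columns=STATS_COLUMNS)
    frame.to_csv(Path(path), index=False, lineterminator="\n")


def read_stats_table(path) -> pd.DataFrame:
    """Parse a stats CSV back into a DataFrame (round-trip of write_stats_table)."""
    return pd.read_csv(Path(path))
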