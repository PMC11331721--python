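"""Genome-copy estimation from marker-gene coverage.

Each marker protein's coverage is summarized by a positional trimmed
mean (central 50% of subject positions).  With the default 75% subject
cover cutoff every hit covers the whole central window, so the trimmed
mean equals the number of mapped hits.  The per-marker coverage is the
sum over its constituent subject sequences, and the total genome copies
of a domain is the average coverage over its fixed set of eight markers.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import BACTERIAL_MARKERS, N_MARKERS, ProteinHit


def trim_window(subject_len_aa: int) -> tuple[int, int]:
    """1-based inclusive bounds of the central 50% of subject positions.

    The leftmost and rightmost 25% of positions are sliced off:
    positions floor(0.25 L) + 1 .. ceil(0.75 L) survive.
    """
    if subject_len_aa <= 0:
        raise ValueError("subject length must be positive")
    lo = math.floor(0.25 * subject_len_aa) + 1
    hi = math.ceil(0.75 * subject_len_aa)
    return lo, hi


def trimmed_mean_coverage(
    hits: Sequence[ProteinHit], subject_len_aa: int
) -> float:
    """Positional trimmed-mean coverage of one subject sequence.

    Builds the per-position coverage vector over subject positions
    1..L from the hits' subject ranges, then averages over the central
    window returned by :func:`trim_window`.
    """
    lo, hi = trim_window(subject_len_aa)
    if not hits:
        return 0.0
    depth = np.zeros(subject_len_aa, dtype=np.int64)
    for h in hits:
        a, b = sorted((h.subject_start, h.subject_end))
        b = min(b, subject_len_aa)
        depth[a - 1 : b] += 1
    return float(depth[lo - 1 : hi].mean())


def subject_coverages(
    hits: Iterable[ProteinHit],
) -> dict[str, float]:
    """Trimmed-mean coverage per subject sequence id."""
    by_subject: dict[str, list[ProteinHit]] = defaultdict(list)
    lengths: dict[str, int] = {}
    for h in hits:
        by_subject[h.subject_id].append(h)
        lengths[h.subject_id] = h.subject_len_aa
    return {
        sid: trimmed_mean_coverage(group, lengths[sid])
        for sid, group in by_subject.items()
    }


def marker_coverages(hits: Iterable[ProteinHit]) -> dict[str, float]:
    """Coverage per marker gene: sum of its constituent subjects' trimmed means."""
    hits = list(hits)
    marker_of = {h.subject_id: h.marker for h in hits}
    per_subject = subject_coverages(hits)
    out: dict[str, float] = defaultdict(float)
    for sid, cov in per_subject.items():
        out[marker_of[sid]] += cov
    return dict(out)


def total_genome_copies(
    coverages: Mapping[str, float],
    marker_set: Sequence[str] = BACTERIAL_MARKERS,
) -> float:
    """Average marker coverage over the fixed marker set.

    Markers without hits contribute zero, which pins the detection floor
    at 1/8 genome copies for a species seen through a single
    marker-containing read.
    """
    unknown = set(coverages) - set(marker_set)
    if unknown:
        raise ValueError(f"coverages for markers outside the set: {sorted(unknown)}")
    if len(marker_set) != N_MARKERS:
        raise ValueError(f"marker set must have {N_MARKERS} genes")
    return sum(coverages.get(m, 0.0) for m in marker_set) / len(marker_set)
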