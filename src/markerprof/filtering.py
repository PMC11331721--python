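"""Post-filtering of protein homology hits.

Shared by read profiling and database construction: greedy overlap
culling per query, contig-boundary filtering, and best-hit-per-marker
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ProteinHit


@dataclass(frozen=True)
class CullConfig:
    """Thresholds applied when post-filtering homology hits.

    max_overlap_frac: a candidate hit is discarded if its query-range
        overlap with any already-kept hit reaches this fraction of the
        shorter of the two ranges.
    min_subject_cover: hits aligning to less than this fraction of the
        subject protein are dropped before culling.
    evalue_cutoff: hits above this e-value are dropped before culling.
    """

    max_overlap_frac: float = 0.25
    min_subject_cover: float = 0.75
    evalue_cutoff: float = 1e-15

    def __post_init__(self) -> None:
        if not 0 < self.max_overlap_frac <= 1:
            raise ValueError("max_overlap_frac must be in (0, 1]")
        if not 0 < self.min_subject_cover <= 1:
            raise ValueError("min_subject_cover must be in (0, 1]")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")


def range_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap of closed 1-based intervals, in positions (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap as a fraction of the shorter of the two ranges."""
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return range_overlap(a, b) / shorter


def cull_overlapping_hits(
    hits: list[ProteinHit], cfg: CullConfig | None = None
) -> list[ProteinHit]:
    """Greedy per-query hit culling.

    Hits of one query are sorted by e-value ascending (ties: higher
    bitscore, then input order) and added to the kept set iff their
    query-range overlap with every already-kept hit is below
    ``max_overlap_frac`` of the shorter range.  Multiple copies of the
    same gene can survive, as long as they occupy distinct query ranges.
    """
    cfg = cfg or CullConfig()
    if not hits:
        return []
    query_ids = {h.query_id for h in hits}
    if len(query_ids) > 1:
        raise ValueError(f"hits must share one query id, got {sorted(query_ids)}")

    eligible = [
        h
        for h in hits
        if h.evalue <= cfg.evalue_cutoff and h.subject_cover >= cfg.min_subject_cover
    ]
    order = sorted(
        range(len(eligible)),
        key=lambda i: (eligible[i].evalue, -eligible[i].bitscore, i),
    )
    kept: list[ProteinHit] = []
    for i in order:
        cand = eligible[i]
        if all(
            overlap_fraction(cand.query_range, k.query_range) < cfg.max_overlap_frac
            for k in kept
        ):
            kept.append(cand)
    return kept


def boundary_filter(hits: list[ProteinHit], contig_len: int) -> list[ProteinHit]:
    """Drop hits too close to either contig end.

    A hit is kept only when both its distance to the left contig end
    (query_start - 1) and to the right end (contig_len - query_end) are
    at least the subject length in nucleotides (3 x subject_len_aa).
    Near-boundary hits produce partial alignments and inconsistent
    windows, so they are excluded from window extraction.
    """
    kept = []
    for h in hits:
        if h.query_end > contig_len:
            raise ValueError(
                f"hit end {h.query_end} exceeds contig length {contig_len}"
            )
        subject_nt = 3 * h.subject_len_aa
        left = h.query_start - 1
        right = contig_len - h.query_end
        if left >= subject_nt and right >= subject_nt:
            kept.append(h)
    return kept


def best_hit_per_marker(hits: list[ProteinHit]) -> list[ProteinHit]:
    """Keep at most one hit per marker gene for a query.

    The winner is the hit with the highest alignment identity; ties go
    to the lower e-value, then to input order.  Output preserves the
    input order of the winners.
    """
    best: dict[str, tuple[float, float, int]] = {}
    winner: dict[str, int] = {}
    for i, h in enumerate(hits):
        key = (-h.identity_pct, h.evalue, i)
        if h.marker not in best or key < best[h.marker]:
            best[h.marker] = key
            winner[h.marker] = i
    chosen = sorted(winner.values())
    return [hits[i] for i in chosen]
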