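"""Extraction of marker-gene-containing windows from assemblies.

Each filtered protein hit anchors a nucleotide window of up to 10 kb:
5 kb of flank on either side of the hit's center, clipped (never
shifted) at the contig ends.  Windows are grouped by (species, marker)
and exact duplicates within a group are dropped; the grouped FASTA is
the pre-clustering nucleotide reference used for read classification.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ProteinHit

WINDOW_SIZE = 10_000


@dataclass(frozen=True)
class WindowRecord:
    """A marker-anchored window on a source contig (0-based half-open)."""

    species: str
    marker: str
    contig_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("window coordinates disagree with sequence length")
        if len(self.sequence) > WINDOW_SIZE:
            raise ValueError(f"window longer than {WINDOW_SIZE} bp")

    @property
    def header(self) -> str:
        return f"{self.species}|{self.marker}|{self.contig_id}|{self.start}-{self.end}"


def extract_window(
    contig_seq: str,
    hit: ProteinHit,
    species: str,
    window: int = WINDOW_SIZE,
) -> WindowRecord:
    """Clip a window of up to ``window`` bp around the hit's center.

    The center is the floor midpoint of the hit's nucleotide query
    range; the window is [center - window/2, center + window/2) clipped
    to the contig bounds ("whenever possible" a full-length window).
    """
    L = len(contig_seq)
    # 0-based floor midpoint of the 1-based inclusive query range.
    center = (hit.query_start - 1 + hit.query_end - 1) // 2
    if not 0 <= center < L:
        raise ValueError(f"hit center {center} outside contig of length {L}")
    half = window // 2
    start = max(0, center - half)
    end = min(L, center + half)
    return WindowRecord(
        species=species,
        marker=hit.marker,
        contig_id=hit.query_id,
        start=start,
        end=end,
        sequence=contig_seq[start:end],
    )


def build_windows(
    assemblies: Mapping[str, str],
    hits: Iterable[ProteinHit],
    contig2species: Mapping[str, str],
    window: int = WINDOW_SIZE,
) -> dict[tuple[str, str], list[WindowRecord]]:
    """Extract windows for all hits, grouped by (species, marker).

    Exact duplicate sequences within a group are removed (first
    occurrence in deterministic (contig, start) order wins).
    """
    groups: dict[tuple[str, str], list[WindowRecord]] = defaultdict(list)
    for hit in sorted(hits, key=lambda h: (h.query_id, h.query_start, h.marker)):
        if hit.query_id not in contig2species:
            raise KeyError(f"contig {hit.query_id!r} has no species label")
        species = contig2species[hit.query_id]
        rec = extract_window(assemblies[hit.query_id], hit, species, window)
        groups[(species, rec.marker)].append(rec)
    deduped: dict[tuple[str, str], list[WindowRecord]] = {}
    for key, records in groups.items():
        seen: set[str] = set()
        unique = []
        for rec in records:
            if rec.sequence not in seen:
                seen.add(rec.sequence)
                unique.append(rec)
        deduped[key] = unique
    return dict(sorted(deduped.items()))


def write_window_fasta(
    groups: Mapping[tuple[str, str], list[WindowRecord]],
    path: str | os.PathLike,
) -> None:
    """Write grouped windows as FASTA; headers encode species|marker|contig|coords."""
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.header, description="")
        for key in sorted(groups)
        for rec in groups[key]
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_window_fasta(path: str | os.PathLike) -> list[WindowRecord]:
    """Inverse of :func:`write_window_fasta`."""
    out = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        species, marker, contig, coords = rec.id.split("|")
        start, end = (int(v) for v in coords.split("-"))
        out.append(
            WindowRecord(
                species=species,
                marker=marker,
                contig_id=contig,
                start=start,
                end=end,
                sequence=str(rec.seq),
            )
        )
    return out
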