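"""Readers and writers for the tabular formats the profiler touches.

Three formats matter: blastx-style tabular protein hits (DIAMOND
frame-shift mode dialect), PAF nucleotide alignments with AS/ms/de tags,
and the profiler's own tab-delimited abundance profile.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

from .model import (
    RANKS,
    UNCLASSIFIED,
    AbundanceProfile,
    NucleotideAlignment,
    ProteinHit,
    TaxLineage,
)


class ParseError(ValueError):
    """A malformed record in an input file; message names the line."""


class ConfigError(ValueError):
    """Input file does not match the declared dialect."""


class ReferenceLookupError(KeyError):
    """A reference id has no species mapping."""


#: Standard 12 blastx tabular columns plus qlen and slen, in order.
DIAMOND_COLUMNS: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qlen", "slen",
)


@dataclass(frozen=True)
class HitTableDialect:
    """Column layout of a protein-hit table.

    ``marker_sep`` splits the subject id; the field before the first
    separator is the marker-gene label (subject ids look like
    ``l2|WP_0123...``).
    """

    columns: tuple[str, ...] = DIAMOND_COLUMNS
    marker_sep: str = "|"

    def __post_init__(self) -> None:
        required = set(DIAMOND_COLUMNS)
        missing = required - set(self.columns)
        if missing:
            raise ConfigError(f"dialect missing required columns: {sorted(missing)}")


def read_protein_hits(
    path: str | os.PathLike,
    dialect: HitTableDialect | None = None,
) -> list[ProteinHit]:
    """Read a tab-separated protein-hit table into :class:`ProteinHit` records.

    Reverse-strand hits (qstart > qend) are normalized so that
    query_start <= query_end, with ``strand`` set to ``"-"``.
    """
    dialect = dialect or HitTableDialect()
    idx = {name: i for i, name in enumerate(dialect.columns)}
    hits: list[ProteinHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(dialect.columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(dialect.columns)} columns, "
                    f"got {len(fields)}"
                )
            try:
                qstart = int(fields[idx["qstart"]])
                qend = int(fields[idx["qend"]])
                sstart = int(fields[idx["sstart"]])
                send = int(fields[idx["send"]])
                strand = "+"
                if qstart > qend:
                    qstart, qend = qend, qstart
                    strand = "-"
                subject_id = fields[idx["sseqid"]]
                marker = subject_id.split(dialect.marker_sep, 1)[0]
                hit = ProteinHit(
                    query_id=fields[idx["qseqid"]],
                    subject_id=subject_id,
                    marker=marker,
                    query_start=qstart,
                    query_end=qend,
                    subject_start=sstart,
                    subject_end=send,
                    evalue=float(fields[idx["evalue"]]),
                    identity_pct=float(fields[idx["pident"]]),
                    bitscore=float(fields[idx["bitscore"]]),
                    subject_len_aa=int(fields[idx["slen"]]),
                    query_len_nt=int(fields[idx["qlen"]]),
                    strand=strand,
                )
            except (ValueError, IndexError) as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_protein_hits(
    hits: Iterable[ProteinHit],
    path: str | os.PathLike,
    dialect: HitTableDialect | None = None,
) -> None:
    """Emit hits in the tabular dialect (inverse of :func:`read_protein_hits`)."""
    dialect = dialect or HitTableDialect()
    with open(path, "w") as fh:
        for h in hits:
            qstart, qend = h.query_start, h.query_end
            if h.strand == "-":
                qstart, qend = qend, qstart
            span = h.query_end - h.query_start + 1
            values = {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": f"{h.identity_pct:.1f}",
                "length": str(span // 3),
                "mismatch": "0",
                "gapopen": "0",
                "qstart": str(qstart),
                "qend": str(qend),
                "sstart": str(h.subject_start),
                "send": str(h.subject_end),
                "evalue": f"{h.evalue:.2g}",
                "bitscore": f"{h.bitscore:.1f}",
                "qlen": str(h.query_len_nt),
                "slen": str(h.subject_len_aa),
            }
            fh.write("\t".join(values[c] for c in dialect.columns) + "\n")


def _parse_paf_tags(fields: list[str]) -> dict[str, str]:
    tags: dict[str, str] = {}
    for field in fields:
        parts = field.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return tags


def read_paf_alignments(
    path: str | os.PathLike,
    ref2species: Mapping[str, str],
) -> list[NucleotideAlignment]:
    """Read PAF alignments, labelling each with its reference's species.

    The AS and ms integer tags are required.  Identity comes from the
    gap-compressed divergence tag when present (``ID = 1 - de``); when
    the tag is missing it falls back to matches / alignment-block-length
    (PAF columns 10 and 11).
    """
    alignments: list[NucleotideAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: PAF needs >= 12 columns")
            ref_id = fields[5]
            if ref_id not in ref2species:
                raise ReferenceLookupError(
                    f"{path}:{lineno}: reference id {ref_id!r} absent from "
                    "the species mapping"
                )
            tags = _parse_paf_tags(fields[12:])
            if "AS" not in tags or "ms" not in tags:
                raise ParseError(
                    f"{path}:{lineno}: missing required AS/ms tags"
                )
            if "de" in tags:
                identity = 1.0 - float(tags["de"])
            else:
                nmatch, alen = int(fields[9]), int(fields[10])
                identity = nmatch / alen if alen else 0.0
            alignments.append(
                NucleotideAlignment(
                    read_id=fields[0],
                    ref_id=ref_id,
                    species=ref2species[ref_id],
                    AS=int(tags["AS"]),
                    MS=int(tags["ms"]),
                    ID=identity,
                    is_primary=tags.get("tp", "P") == "P",
                )
            )
    return alignments


def read_ref2species(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV (ref_id, species) -> mapping."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def read_lineages(path: str | os.PathLike) -> dict[str, TaxLineage]:
    """TSV with one column per rank; keyed by species name."""
    lineages: dict[str, TaxLineage] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            rank_idx = [header.index(r) for r in RANKS]
        except ValueError as exc:
            raise ConfigError(f"{path}: header must contain ranks {RANKS}") from exc
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            lin = TaxLineage(tuple(fields[i] for i in rank_idx))
            lineages[lin.species] = lin
    return lineages


PROFILE_HEADER: tuple[str, ...] = RANKS + ("copies", "rel_abundance")


def write_profile(profile: AbundanceProfile, path: str | os.PathLike) -> None:
    """Write a profile as TSV: one column per rank, copies, rel_abundance.

    Rows are ordered by copies descending then lexicographic lineage, so
    output is deterministic regardless of input order.
    """
    ordered = profile.sorted()
    rels = ordered.rel_abundances()
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_HEADER) + "\n")
        for (lineage, copies), rel in zip(ordered.entries, rels):
            fh.write(
                "\t".join(lineage.names)
                + f"\t{copies:.10g}\t{rel:.10g}\n"
            )


def read_profile(path: str | os.PathLike) -> AbundanceProfile:
    """Inverse of :func:`write_profile` (rel_abundance is recomputed)."""
    entries: list[tuple[TaxLineage, float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PROFILE_HEADER:
            raise ConfigError(f"{path}: unexpected profile header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(PROFILE_HEADER):
                raise ParseError(f"{path}:{lineno}: wrong column count")
            lineage = TaxLineage(tuple(fields[: len(RANKS)]))
            entries.append((lineage, float(fields[len(RANKS)])))
    return AbundanceProfile(entries)
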