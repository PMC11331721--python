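"""Shared domain types for the marker-gene profiler.

The profiler works with two alignment layers: protein homology hits of
reads/contigs against a database of single-copy ribosomal protein genes
(RPGs), and nucleotide alignments of marker-containing reads against
10 kb marker-region windows.  Eight markers per prokaryotic domain are
used, so one marker-containing read contributes 1/8 of a genome copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Taxonomic ranks carried by a lineage, most to least inclusive.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Number of marker genes averaged per prokaryotic domain.
N_MARKERS: int = 8

# Ribosomal protein genes retained as universal single-copy markers.
# Membership is configuration: any 8-gene set satisfying the
# universality/deviance/F0.5 screen can be swapped in.
BACTERIAL_MARKERS: tuple[str, ...] = (
    "l2", "l11", "l15", "l20", "s2", "s7", "s9", "s16",
)
ARCHAEAL_MARKERS: tuple[str, ...] = (
    "l2", "l3", "l10e", "l15e", "s3ae", "s8e", "s19e", "s28e",
)

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ProteinHit:
    """One homology-search hit of a query (read or contig) on a marker protein.

    Query coordinates are 1-based inclusive nucleotide positions, already
    normalized so ``query_start <= query_end`` (reverse-strand hits keep
    ``strand == "-"``).  Subject coordinates are amino-acid positions on
    the marker protein sequence.
    """

    query_id: str
    subject_id: str
    marker: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    identity_pct: float
    bitscore: float
    subject_len_aa: int
    query_len_nt: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.query_start <= self.query_end <= self.query_len_nt):
            raise ValueError(
                f"invalid query range {self.query_start}-{self.query_end} "
                f"on query of length {self.query_len_nt} ({self.query_id})"
            )
        if self.evalue < 0 or not math.isfinite(self.evalue):
            raise ValueError(f"e-value must be finite and >= 0, got {self.evalue}")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity must be in [0, 100], got {self.identity_pct}")
        if self.subject_len_aa <= 0:
            raise ValueError("subject length must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def query_range(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start + 1

    @property
    def subject_cover(self) -> float:
        """Aligned fraction of the subject protein, in [0, 1]."""
        lo, hi = sorted((self.subject_start, self.subject_end))
        return (hi - lo + 1) / self.subject_len_aa


@dataclass(frozen=True)
class NucleotideAlignment:
    """A read-vs-marker-window alignment with its ranking scores.

    ``AS`` is the alignment score, ``MS`` the local-best alignment score,
    ``ID`` the gap-compressed per-base identity in [0, 1].  ``species``
    is the taxon label of the reference window the read aligned to.
    """

    read_id: str
    ref_id: str
    species: str
    AS: int
    MS: int
    ID: float
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.ID <= 1.0:
            raise ValueError(f"ID must be in [0, 1], got {self.ID}")
        if not (math.isfinite(self.AS) and math.isfinite(self.MS)):
            raise ValueError("AS and MS must be finite")

    @property
    def score_key(self) -> tuple:
        """Sort key: higher is better, ordered AS, then MS, then ID."""
        return (self.AS, self.MS, self.ID)


@dataclass(frozen=True)
class TaxLineage:
    """A ranked lineage from superkingdom down to species.

    ``is_well_defined`` is False for placeholder species (e.g. a bare
    "<Genus> sp.") and for the reserved unclassified lineage; such taxa
    lose ties against properly named species during hard assignment.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(
                f"lineage needs {len(RANKS)} ranks ({', '.join(RANKS)}), "
                f"got {len(self.names)}"
            )

    @classmethod
    def from_species(cls, species: str, **ranks: str) -> "TaxLineage":
        """Build a lineage given the species name and any known upper ranks."""
        names = tuple(ranks.get(rank, UNCLASSIFIED) for rank in RANKS[:-1]) + (species,)
        return cls(names)

    @classmethod
    def unclassified(cls) -> "TaxLineage":
        return cls(tuple(UNCLASSIFIED for _ in RANKS))

    @property
    def species(self) -> str:
        return self.names[-1]

    @property
    def genus(self) -> str:
        return self.names[-2]

    @property
    def is_classified(self) -> bool:
        return self.species != UNCLASSIFIED

    @property
    def is_well_defined(self) -> bool:
        sp = self.species
        if sp == UNCLASSIFIED:
            return False
        return not sp.endswith(" sp.")


@dataclass
class AbundanceProfile:
    """Per-species genome copies with derived relative (taxonomic) abundances.

    Relative abundance is the fraction of genome copies, i.e. the fraction
    of cells assuming one genome copy per cell.  The reserved unclassified
    row is excluded from the normalization.
    """

    entries: list[tuple[TaxLineage, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for lineage, copies in self.entries:
            if copies < 0:
                raise ValueError(f"negative genome copies for {lineage.species}")

    @property
    def total_copies(self) -> float:
        return sum(c for _, c in self.entries)

    @property
    def classified_copies(self) -> float:
        return sum(c for lin, c in self.entries if lin.is_classified)

    def species_set(self) -> set[str]:
        return {lin.species for lin, _ in self.entries if lin.is_classified}

    def copies_by_species(self) -> dict[str, float]:
        return {lin.species: c for lin, c in self.entries if lin.is_classified}

    def rel_abundances(self) -> list[float]:
        """Relative abundance per entry, normalized over classified rows.

        Unclassified rows report 0.0 and do not take part in the
        normalization, so the classified fractions sum to one.
        """
        denom = self.classified_copies
        out = []
        for lin, copies in self.entries:
            if not lin.is_classified or denom == 0:
                out.append(0.0)
            else:
                out.append(copies / denom)
        return out

    def sorted(self) -> "AbundanceProfile":
        """Deterministic order: copies descending, then lexicographic lineage."""
        order = sorted(self.entries, key=lambda e: (-e[1], e[0].names))
        return AbundanceProfile(order)
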