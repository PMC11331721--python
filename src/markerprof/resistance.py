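"""Species-resolved antibiotic-resistance-gene (ARG) quantification.

ARG-containing reads are mapped to an ARG host database whose reference
windows carry a species label, an ARG family, and a source label
(chromosome, plasmid, or virus).  Filtering keeps a single best
alignment per read, requires the host species to be present in the
taxonomic profile, discards plasmid/virus-sourced hits to sidestep
mobile genetic elements, and drops multidrug-family hits (multidrug
efflux pumps are not antibiotic-specific).  ARG abundance is expressed
as copies per cell, assuming one genome copy per cell.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .model import AbundanceProfile, NucleotideAlignment

SOURCES = ("chromosome", "plasmid", "virus")
MULTIDRUG = "multidrug"


@dataclass(frozen=True)
class HostAlignment:
    """A read-vs-ARG-host-window alignment with its annotations."""

    alignment: NucleotideAlignment
    arg_family: str
    source: str

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")


@dataclass(frozen=True)
class ArgHit:
    """One retained ARG read with its resolved host species."""

    read_id: str
    arg_family: str
    host_species: str
    source: str


def filter_arg_host_alignments(
    alignments: Iterable[HostAlignment],
    profile: AbundanceProfile,
) -> list[ArgHit]:
    """Apply the host-assignment filtering cascade.

    Per read, only the single best alignment (by AS, then MS, then ID)
    survives; reads whose best alignment ties across references with
    different sources are dropped outright.  The best alignment is then
    kept only if its species appears in the profile, its source is
    chromosomal, and its ARG family is not flagged multidrug.
    """
    present = profile.species_set()
    by_read: dict[str, list[HostAlignment]] = defaultdict(list)
    for ha in alignments:
        by_read[ha.alignment.read_id].append(ha)

    hits: list[ArgHit] = []
    for read_id in sorted(by_read):
        group = by_read[read_id]
        best_key = max(ha.alignment.score_key for ha in group)
        top = [ha for ha in group if ha.alignment.score_key == best_key]
        if len({ha.source for ha in top}) > 1:
            continue  # ambiguous chromosome/plasmid tie: conservative drop
        best = min(top, key=lambda ha: (ha.alignment.species, ha.arg_family))
        if best.source != "chromosome":
            continue
        if best.alignment.species not in present:
            continue
        if best.arg_family == MULTIDRUG:
            continue
        hits.append(
            ArgHit(
                read_id=read_id,
                arg_family=best.arg_family,
                host_species=best.alignment.species,
                source=best.source,
            )
        )
    return hits


def arg_copies_per_cell(arg_copies: float, total_genome_copies: float) -> float:
    """ARG copies per cell = ARG copies / genome copies."""
    if total_genome_copies <= 0:
        raise ValueError("total genome copies must be positive")
    if arg_copies < 0:
        raise ValueError("ARG copies must be non-negative")
    return arg_copies / total_genome_copies


def per_species_copies_per_cell(
    arg_copies: Mapping[str, float],
    genome_copies: Mapping[str, float],
) -> dict[str, float]:
    """Copies-per-cell per host species (species absent from the profile
    or with zero genome copies are skipped)."""
    out = {}
    for species, copies in arg_copies.items():
        gc = genome_copies.get(species, 0.0)
        if gc > 0:
            out[species] = copies / gc
    return out
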