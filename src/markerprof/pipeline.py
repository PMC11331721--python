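"""End-to-end orchestration: files in, profile out.

The profiling pipeline chains the stages: read and cull protein hits,
estimate total genome copies from marker coverage, build the
read-species matrix from nucleotide alignments, run EM, hard-assign
reads, and aggregate the abundance profile.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from typing import Mapping, Sequence

from . import io as mio
from .coverage import marker_coverages, total_genome_copies
from .em import (
    aggregate_profile,
    build_read_species_matrix,
    em_iterate,
    hard_assign,
)
from .filtering import CullConfig, cull_overlapping_hits
from .model import BACTERIAL_MARKERS, AbundanceProfile, ProteinHit, TaxLineage
from .resistance import (
    HostAlignment,
    filter_arg_host_alignments,
    per_species_copies_per_cell,
)

logger = logging.getLogger("markerprof")


def cull_per_query(
    hits: Sequence[ProteinHit], cfg: CullConfig | None = None
) -> list[ProteinHit]:
    """Apply greedy overlap culling independently to each query's hits."""
    by_query: dict[str, list[ProteinHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    out: list[ProteinHit] = []
    for qid in sorted(by_query):
        out.extend(cull_overlapping_hits(by_query[qid], cfg))
    return out


def profile_sample(
    hits: Sequence[ProteinHit],
    alignments,
    lineages: Mapping[str, TaxLineage],
    marker_set: Sequence[str] = BACTERIAL_MARKERS,
    cull: CullConfig | None = None,
    em_tol: float = 1e-5,
    em_max_iter: int = 100,
) -> AbundanceProfile:
    """Profile one sample from in-memory hits and alignments.

    Total genome copies come from the trimmed-mean marker coverage of
    the culled protein hits; species shares come from EM-reassigned
    nucleotide alignments of the marker-containing reads.  Marker reads
    with no species-level alignment fall into the unclassified row.
    """
    kept = cull_per_query(hits, cull)
    coverages = marker_coverages(kept)
    total = total_genome_copies(coverages, marker_set)
    marker_reads = {h.query_id for h in kept}
    logger.info(
        "%d marker-containing reads, total genome copies %.4f",
        len(marker_reads), total,
    )

    relevant = [a for a in alignments if a.read_id in marker_reads]
    matrix = build_read_species_matrix(relevant)
    state = em_iterate(matrix, tol=em_tol, max_iter=em_max_iter)
    logger.info(
        "EM finished after %d iterations (converged=%s, k=%d)",
        state.n_iter, state.converged, matrix.k,
    )
    assignments = hard_assign(state, matrix, lineages)
    n_unclassified = len(marker_reads) - len(assignments)
    return aggregate_profile(assignments, total, lineages, n_unclassified)


def run_profile(
    hits_path: str | os.PathLike,
    paf_path: str | os.PathLike,
    ref2species_path: str | os.PathLike,
    lineages_path: str | os.PathLike,
    out_path: str | os.PathLike,
    em_tol: float = 1e-5,
    em_max_iter: int = 100,
) -> AbundanceProfile:
    """File-level entry point behind the `profile` CLI command."""
    hits = mio.read_protein_hits(hits_path)
    ref2species = mio.read_ref2species(ref2species_path)
    lineages = mio.read_lineages(lineages_path)
    alignments = mio.read_paf_alignments(paf_path, ref2species)
    profile = profile_sample(
        hits, alignments, lineages, em_tol=em_tol, em_max_iter=em_max_iter
    )
    mio.write_profile(profile, out_path)
    return profile


def read_host_alignments(path: str | os.PathLike) -> list[HostAlignment]:
    """TSV of ARG host alignments.

    Columns: read_id, ref_id, species, arg_family, source, AS, MS, ID.
    """
    from .model import NucleotideAlignment

    out: list[HostAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["read_id", "ref_id", "species", "arg_family", "source",
                    "AS", "MS", "ID"]
        if header != expected:
            raise mio.ConfigError(f"{path}: expected header {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(expected):
                raise mio.ParseError(f"{path}:{lineno}: wrong column count")
            out.append(
                HostAlignment(
                    alignment=NucleotideAlignment(
                        read_id=f[0], ref_id=f[1], species=f[2],
                        AS=int(f[5]), MS=int(f[6]), ID=float(f[7]),
                    ),
                    arg_family=f[3],
                    source=f[4],
                )
            )
    return out


def run_arg_profile(
    alignments_path: str | os.PathLike,
    profile_path: str | os.PathLike,
    out_path: str | os.PathLike,
) -> dict[str, float]:
    """ARG copies-per-cell per host species, written as TSV."""
    alignments = read_host_alignments(alignments_path)
    profile = mio.read_profile(profile_path)
    hits = filter_arg_host_alignments(alignments, profile)
    arg_copies: dict[str, float] = defaultdict(float)
    for hit in hits:
        arg_copies[hit.host_species] += 1.0
    per_cell = per_species_copies_per_cell(
        arg_copies, profile.copies_by_species()
    )
    with open(out_path, "w") as fh:
        fh.write("species\targ_copies\tgenome_copies\tcopies_per_cell\n")
        genome = profile.copies_by_species()
        for sp in sorted(per_cell):
            fh.write(
                f"{sp}\t{arg_copies[sp]:.10g}\t{genome[sp]:.10g}"
                f"\t{per_cell[sp]:.10g}\n"
            )
    return per_cell
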