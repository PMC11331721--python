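"""Synthetic communities and alignment fixtures with known ground truth.

The generator emulates the structure the profiler consumes downstream
of the aligners: a community of species with log-normally distributed
taxonomic abundances, eight single-copy markers per genome, marker-
containing reads emitted as protein-hit rows (blastx tabular dialect)
and as PAF nucleotide alignments against per-species marker windows.
Cross-species ambiguity is injected by giving a configurable fraction
of reads additional near-tied alignments to a neighbouring species,
with scores straddling the EM validity thresholds.

No base-level sequence or error simulation is performed: the testable
core of the profiler consumes alignment records, and read-level error
models are the aligner's concern.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io as mio
from .model import BACTERIAL_MARKERS, ProteinHit, TaxLineage

#: Score profile of the emitted alignments.  The true species receives
#: AS = MS = BASE_SCORE and identity TRUE_ID; ambiguous neighbours get
#: multiplicative offsets.  The defaults put neighbours inside all
#: validity thresholds (0.996 > 0.99 score ratio, 0.9895/0.99 > 0.999).
BASE_SCORE = 1000
TRUE_ID = 0.99
READ_LEN = 3000
SUBJECT_LEN_AA = 150
WINDOW_LEN = 10_000


@dataclass
class CommunityTruth:
    """Ground truth of a simulated community.

    ``theta`` are taxonomic (cell-fraction) abundances summing to one;
    ``copies`` the planted genome copies (theta x total_copies).  The
    ambiguity graph pairs each species with the neighbours whose marker
    windows are indistinguishable enough to attract near-tied
    alignments.
    """

    species: list[str]
    lineages: dict[str, TaxLineage]
    theta: np.ndarray
    genome_lengths: np.ndarray
    copies: np.ndarray
    ambiguity: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.theta.sum(), 1.0):
            raise ValueError("taxonomic abundances must sum to 1")
        for sp, neighbours in self.ambiguity.items():
            unknown = set(neighbours) - set(self.species) | ({sp} - set(self.species))
            if unknown:
                raise ValueError(f"ambiguity edge to unknown species: {unknown}")

    @property
    def total_copies(self) -> float:
        return float(self.copies.sum())

    def theta_by_species(self) -> dict[str, float]:
        return dict(zip(self.species, self.theta.tolist()))


def sample_community(
    k: int,
    mu: float = 0.0,
    sigma: float = 1.0,
    seed: int | None = None,
    total_copies: float = 100.0,
    length_range: tuple[float, float] = (2e6, 6e6),
) -> CommunityTruth:
    """Draw a k-species community with log-normal taxonomic abundances.

    Abundances are k draws from LogNormal(mu, sigma) normalized to sum
    one; genome copies are theta x ``total_copies``.  Genome lengths are
    uniform over a typical prokaryotic range.  The ambiguity graph pairs
    consecutive species into disjoint symmetric edges: window sharing is
    a symmetric relation, so reads of either partner may align near-tied
    to the other.
    """
    if k < 1:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=mu, sigma=sigma, size=k)
    theta = raw / raw.sum()
    lengths = rng.uniform(*length_range, size=k).round()
    species = [f"Genus{i:03d} species{i:03d}" for i in range(k)]
    lineages = {
        sp: TaxLineage.from_species(
            sp,
            superkingdom="Bacteria",
            phylum=f"Phylum{i % 6:02d}",
            genus=sp.split()[0],
            **{"class": f"Class{i % 6:02d}"},
            order=f"Order{i % 12:02d}",
            family=f"Family{i % 24:02d}",
        )
        for i, sp in enumerate(species)
    }
    ambiguity: dict[str, tuple[str, ...]] = {}
    for i in range(0, k - 1, 2):
        ambiguity[species[i]] = (species[i + 1],)
        ambiguity[species[i + 1]] = (species[i],)
    return CommunityTruth(
        species=species,
        lineages=lineages,
        theta=theta,
        genome_lengths=lengths,
        copies=theta * total_copies,
        ambiguity=ambiguity,
    )


def taxonomic_to_sequence_abundance(
    theta: np.ndarray, genome_lengths: np.ndarray
) -> np.ndarray:
    """Convert cell fractions into read/base fractions by genome length."""
    theta = np.asarray(theta, dtype=float)
    lengths = np.asarray(genome_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("genome lengths must be positive")
    weighted = theta * lengths
    total = weighted.sum()
    if total <= 0:
        raise ValueError("community has zero sequence mass")
    return weighted / total


def _token(species: str) -> str:
    return species.replace(" ", "_")


def ref_window_id(species: str, marker: str) -> str:
    return f"{_token(species)}|{marker}|w0"


@dataclass
class SimulatedSample:
    """In-memory fixture: protein hits, PAF lines, and per-read truth."""

    protein_hits: list[ProteinHit]
    paf_lines: list[str]
    ref2species: dict[str, str]
    read_truth: dict[str, str]
    truth: CommunityTruth


def simulate_marker_alignments(
    truth: CommunityTruth,
    reads_per_copy: float = 8.0,
    ambiguity_frac: float = 0.0,
    seed: int | None = None,
    neighbor_score_frac: float = 0.996,
    neighbor_id: float = 0.9895,
) -> SimulatedSample:
    """Emit marker-read fixtures for a community.

    Each species contributes round(copies x reads_per_copy) marker-
    containing reads, spread over the eight markers by a seeded
    multinomial.  Every read yields one full-cover protein hit (so the
    trimmed-mean/hit-count identity holds) and one true nucleotide
    alignment; a fraction ``ambiguity_frac`` of reads additionally
    aligns near-tied to the species' ambiguity-graph neighbours.
    """
    if not 0.0 <= ambiguity_frac <= 1.0:
        raise ValueError("ambiguity_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    markers = BACTERIAL_MARKERS
    hits: list[ProteinHit] = []
    paf: list[str] = []
    read_truth: dict[str, str] = {}
    ref2species = {
        ref_window_id(sp, m): sp for sp in truth.species for m in markers
    }

    neighbor_as = int(round(BASE_SCORE * neighbor_score_frac))
    for sp, copies in zip(truth.species, truth.copies):
        n_reads = int(round(copies * reads_per_copy))
        if n_reads == 0:
            continue
        per_marker = rng.multinomial(n_reads, np.full(len(markers), 1 / len(markers)))
        idx = 0
        for marker, count in zip(markers, per_marker):
            for _ in range(count):
                read_id = f"{_token(sp)}_r{idx:05d}"
                idx += 1
                read_truth[read_id] = sp
                hits.append(
                    ProteinHit(
                        query_id=read_id,
                        subject_id=f"{marker}|{_token(sp)}",
                        marker=marker,
                        query_start=1001,
                        query_end=1000 + 3 * SUBJECT_LEN_AA,
                        subject_start=1,
                        subject_end=SUBJECT_LEN_AA,
                        evalue=1e-50,
                        identity_pct=95.0,
                        bitscore=300.0,
                        subject_len_aa=SUBJECT_LEN_AA,
                        query_len_nt=READ_LEN,
                    )
                )
                paf.append(
                    _paf_line(read_id, ref_window_id(sp, marker), BASE_SCORE, TRUE_ID,
                              primary=True)
                )
                if truth.ambiguity.get(sp) and rng.random() < ambiguity_frac:
                    for neighbour in truth.ambiguity[sp]:
                        paf.append(
                            _paf_line(
                                read_id,
                                ref_window_id(neighbour, marker),
                                neighbor_as,
                                neighbor_id,
                                primary=False,
                            )
                        )
    return SimulatedSample(hits, paf, ref2species, read_truth, truth)


def _paf_line(
    read_id: str, ref_id: str, score: int, identity: float, primary: bool
) -> str:
    qstart, qend = 0, READ_LEN - 50
    alen = qend - qstart
    nmatch = int(round(alen * identity))
    de = 1.0 - identity
    fields = [
        read_id, str(READ_LEN), str(qstart), str(qend), "+",
        ref_id, str(WINDOW_LEN), "4000", str(4000 + alen), str(nmatch),
        str(alen), "60",
        f"tp:A:{'P' if primary else 'S'}",
        f"AS:i:{score}",
        f"ms:i:{score}",
        f"de:f:{de:.4f}",
    ]
    return "\t".join(fields)


def write_fixture_dir(sample: SimulatedSample, out_dir: str | os.PathLike,
                      config: dict | None = None) -> dict[str, str]:
    """Write a fixture directory: hits TSV, PAF, truth tables, config echo.

    Returns the paths written, keyed by role.  Output is byte-identical
    for identical inputs (no timestamps, deterministic ordering).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    truth = sample.truth
    paths = {
        "hits": os.path.join(out_dir, "protein_hits.tsv"),
        "paf": os.path.join(out_dir, "alignments.paf"),
        "ref2species": os.path.join(out_dir, "ref2species.tsv"),
        "lineages": os.path.join(out_dir, "lineages.tsv"),
        "community": os.path.join(out_dir, "community_truth.tsv"),
        "read_truth": os.path.join(out_dir, "read_truth.tsv"),
        "config": os.path.join(out_dir, "config.yaml"),
    }
    mio.write_protein_hits(sample.protein_hits, paths["hits"])
    with open(paths["paf"], "w") as fh:
        fh.write("\n".join(sample.paf_lines) + ("\n" if sample.paf_lines else ""))
    with open(paths["ref2species"], "w") as fh:
        for ref_id in sorted(sample.ref2species):
            fh.write(f"{ref_id}\t{sample.ref2species[ref_id]}\n")
    with open(paths["lineages"], "w") as fh:
        fh.write("\t".join(mio.RANKS) + "\n")
        for sp in truth.species:
            fh.write("\t".join(truth.lineages[sp].names) + "\n")
    with open(paths["community"], "w") as fh:
        fh.write("species\ttheta\tgenome_length\tcopies\n")
        for sp, th, L, c in zip(
            truth.species, truth.theta, truth.genome_lengths, truth.copies
        ):
            fh.write(f"{sp}\t{th:.10g}\t{L:.0f}\t{c:.10g}\n")
    with open(paths["read_truth"], "w") as fh:
        for read_id in sorted(sample.read_truth):
            fh.write(f"{read_id}\t{sample.read_truth[read_id]}\n")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config or {}, fh, sort_keys=True)
    return paths
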