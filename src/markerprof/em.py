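"""EM-based species assignment of marker-containing reads.

Reads often align comparably well to marker windows of several related
species.  Alignments within tight score ratios of each read's best
(AS > 0.99 max, MS > 0.99 max, or ID > 0.999 max) are considered valid
and recorded in a binary read-species matrix.  An EM loop then estimates
the species mixture theta and the per-read posterior z, after which each
read is hard-assigned to its most probable species.

E-step:  z_{i,j} = x_{i,j} theta_j / sum_j x_{i,j} theta_j
M-step:  theta_j = sum_i z_{i,j} / n

starting from the uniform theta_j = 1/k over the k candidate species,
until the L1 change of theta drops below ``tol`` or ``max_iter`` is hit.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .model import (
    AbundanceProfile,
    NucleotideAlignment,
    TaxLineage,
)

#: Score-ratio thresholds for alignment validity, against the per-read maxima.
AS_RATIO = 0.99
MS_RATIO = 0.99
ID_RATIO = 0.999

#: theta values below this are clamped to zero and theta renormalized.
THETA_FLOOR = 1e-12


@dataclass
class ReadSpeciesMatrix:
    """Binary read-species membership with per-cell best alignment scores.

    ``x[i, j]`` is True iff read i has a valid alignment to species j.
    The AS/MS/ID arrays hold the scores of the single best alignment
    retained per read-species pair (NaN / very negative where absent).
    """

    read_ids: list[str]
    species: list[str]
    x: np.ndarray  # (n, k) bool
    AS: np.ndarray  # (n, k) float
    MS: np.ndarray  # (n, k) float
    ID: np.ndarray  # (n, k) float

    @property
    def n(self) -> int:
        return len(self.read_ids)

    @property
    def k(self) -> int:
        return len(self.species)

    def validate(self) -> None:
        if self.n and not self.x.any(axis=1).all():
            bad = [self.read_ids[i] for i in np.flatnonzero(~self.x.any(axis=1))]
            raise ValueError(f"reads with no valid species: {bad[:5]}")


@dataclass
class EMState:
    """Converged (or max-iteration) EM estimates."""

    theta: np.ndarray  # (k,)
    z: np.ndarray  # (n, k)
    n_iter: int
    converged: bool
    log_likelihood: float


def build_read_species_matrix(
    alignments: Iterable[NucleotideAlignment],
) -> ReadSpeciesMatrix:
    """Retain the best alignment per read-species pair and apply validity.

    Alignments of a read are ranked by (AS, MS, ID) descending; for each
    read-species pair only the top one is kept.  A pair is valid when at
    least one of its scores exceeds the read's best by the tight ratio
    thresholds (strict inequalities).  Reads without alignments simply
    do not appear.
    """
    best: dict[str, dict[str, NucleotideAlignment]] = defaultdict(dict)
    for aln in alignments:
        cur = best[aln.read_id].get(aln.species)
        if cur is None or aln.score_key > cur.score_key:
            best[aln.read_id][aln.species] = aln

    read_ids = sorted(best)
    species = sorted({sp for per_read in best.values() for sp in per_read})
    sp_idx = {sp: j for j, sp in enumerate(species)}
    n, k = len(read_ids), len(species)
    NEG = -np.inf
    AS = np.full((n, k), NEG)
    MS = np.full((n, k), NEG)
    ID = np.full((n, k), NEG)
    for i, rid in enumerate(read_ids):
        for sp, aln in best[rid].items():
            j = sp_idx[sp]
            AS[i, j] = aln.AS
            MS[i, j] = aln.MS
            ID[i, j] = aln.ID

    x = np.zeros((n, k), dtype=bool)
    if n:
        as_max = AS.max(axis=1, keepdims=True)
        ms_max = MS.max(axis=1, keepdims=True)
        id_max = ID.max(axis=1, keepdims=True)
        present = np.isfinite(AS)
        x = present & (
            (AS > AS_RATIO * as_max)
            | (MS > MS_RATIO * ms_max)
            | (ID > ID_RATIO * id_max)
        )
        # A read whose scores are all exactly at the maxima (e.g. a single
        # alignment with AS == 0) must still keep its best species.
        best_j = np.argmax(
            np.where(present, AS, -np.inf)
            + 1e-9 * np.where(present, MS, -np.inf)
            + 1e-12 * np.where(present, ID, -np.inf),
            axis=1,
        )
        x[np.arange(n), best_j] = True

    # Drop species left without any valid read.
    keep = x.any(axis=0) if n else np.zeros(k, dtype=bool)
    if n and not keep.all():
        x, AS, MS, ID = x[:, keep], AS[:, keep], MS[:, keep], ID[:, keep]
        species = [sp for sp, kf in zip(species, keep) if kf]

    m = ReadSpeciesMatrix(read_ids, species, x, AS, MS, ID)
    m.validate()
    return m


def observed_log_likelihood(x: np.ndarray, theta: np.ndarray) -> float:
    """sum_i log sum_j x_{i,j} theta_j (the quantity EM never decreases)."""
    mix = x.astype(float) @ theta
    return float(np.log(mix).sum())


def em_iterate(
    matrix: ReadSpeciesMatrix,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> EMState:
    """Run EM on the binary read-species matrix until theta stabilizes.

    Iterates the posterior E-step and the mixture M-step from the uniform
    initialization until the L1 change in theta falls below ``tol`` or
    ``max_iter`` iterations have run.  theta components underflowing
    below ``THETA_FLOOR`` are clamped to zero and theta renormalized.
    """
    matrix.validate()
    n, k = matrix.n, matrix.k
    if n == 0:
        return EMState(np.zeros(0), np.zeros((0, 0)), 0, True, 0.0)
    x = matrix.x.astype(float)
    theta = np.full(k, 1.0 / k)
    z = x / x.sum(axis=1, keepdims=True)
    converged = False
    t = 0
    for t in range(1, max_iter + 1):
        weighted = x * theta  # E-step numerator
        z = weighted / weighted.sum(axis=1, keepdims=True)
        new_theta = z.sum(axis=0) / n  # M-step
        new_theta[new_theta < THETA_FLOOR] = 0.0
        new_theta /= new_theta.sum()
        delta = np.abs(new_theta - theta).sum()
        theta = new_theta
        if delta < tol:
            converged = True
            break
    return EMState(theta, z, t, converged, observed_log_likelihood(x, theta))


def hard_assign(
    state: EMState,
    matrix: ReadSpeciesMatrix,
    lineages: Mapping[str, TaxLineage] | None = None,
) -> dict[str, str]:
    """Assign each read to a single species by argmax of its posterior.

    Ties are broken by a total order: larger z, properly named species
    over placeholders (a bare "<Genus> sp." is down-weighted), larger
    AS, MS, ID, and finally lexicographic species id.
    """
    lineages = lineages or {}
    assignments: dict[str, str] = {}
    for i, rid in enumerate(matrix.read_ids):
        candidates = np.flatnonzero(matrix.x[i])
        best = max(
            candidates,
            key=lambda j: (
                state.z[i, j],
                _definedness(matrix.species[j], lineages),
                matrix.AS[i, j],
                matrix.MS[i, j],
                matrix.ID[i, j],
                _LexDesc(matrix.species[j]),
            ),
        )
        assignments[rid] = matrix.species[best]
    return assignments


def _definedness(species: str, lineages: Mapping[str, TaxLineage]) -> int:
    lin = lineages.get(species)
    if lin is not None:
        return int(lin.is_well_defined)
    return 0 if species.endswith(" sp.") else 1


class _LexDesc(str):
    """Inverts lexicographic order so max() prefers the earlier name."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def aggregate_profile(
    assignments: Mapping[str, str],
    total_copies: float,
    lineages: Mapping[str, TaxLineage],
    n_unclassified_reads: int = 0,
) -> AbundanceProfile:
    """Aggregate per-read assignments into an abundance profile.

    Genome copies are apportioned to species by their assigned read
    counts: copies_j = total_copies * n_j / n.  Marker-containing reads
    that received no species label contribute to a reserved unclassified
    row instead, so copies still sum to the coverage-based total.
    """
    counts: dict[str, int] = defaultdict(int)
    for sp in assignments.values():
        counts[sp] += 1
    n = sum(counts.values()) + n_unclassified_reads
    if n == 0:
        return AbundanceProfile([])
    entries: list[tuple[TaxLineage, float]] = []
    for sp, cnt in counts.items():
        if sp not in lineages:
            raise KeyError(f"species {sp!r} has no lineage")
        entries.append((lineages[sp], total_copies * cnt / n))
    if n_unclassified_reads:
        entries.append(
            (TaxLineage.unclassified(), total_copies * n_unclassified_reads / n)
        )
    return AbundanceProfile(entries).sorted()
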