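"""Screening statistics for candidate marker genes.

Candidate ribosomal protein genes are scored by universality (fraction
of assemblies carrying the gene), deviance (distance of the mean copy
number from the single-copy ideal), the F0.5-score of the gene's
annotation model, and the genes' mean relative genomic distances on
circular genomes.  Genes passing the thresholds are single-linkage
clustered by distance and one representative per cluster is kept, so
the final marker set is spread around the chromosome rather than
piled near the replication origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

#: Screening thresholds: a gene is a valid marker candidate only if, in
#: both the full assembly panel and the tiny-genome (<1 Mb) subset, its
#: universality exceeds 0.99 and its deviance stays below 0.01, and its
#: annotation model's F0.5-score exceeds 0.99.
UNIVERSALITY_MIN = 0.99
DEVIANCE_MAX = 0.01
F05_MIN = 0.99
LINKAGE_CUTOFF = 0.05


@dataclass
class GeneCopyTable:
    """Copy counts of candidate genes across assemblies.

    ``counts`` is an assemblies x genes DataFrame of non-negative
    integers.  ``subsets`` maps a label (e.g. "tiny") to the subset of
    assembly ids it contains; the full panel is always available as
    ``"full"``.
    """

    counts: pd.DataFrame
    subsets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("copy counts must be non-negative")
        self.subsets.setdefault("full", list(self.counts.index))
        for label, members in self.subsets.items():
            missing = set(members) - set(self.counts.index)
            if missing:
                raise ValueError(f"subset {label!r} has unknown assemblies: {missing}")


def compute_marker_stats(table: GeneCopyTable) -> dict[str, pd.DataFrame]:
    """Universality and deviance per gene, for each assembly subset.

    Universality is the fraction of assemblies with copy count >= 1;
    deviance is |mean copy - 1|, the mean taken over all assemblies of
    the subset (zeros included).
    """
    out: dict[str, pd.DataFrame] = {}
    for label, members in table.subsets.items():
        sub = table.counts.loc[members]
        if sub.empty:
            raise ValueError(f"subset {label!r} is empty")
        out[label] = pd.DataFrame(
            {
                "universality": (sub >= 1).mean(axis=0),
                "deviance": (sub.mean(axis=0) - 1.0).abs(),
            }
        )
    return out


def f05_score(tp: int, fp: int, fn: int) -> float:
    """Precision-weighted F-score with beta = 0.5.

    F0.5 = 1.25 p r / (0.25 p + r); returns 0 when recall is 0.
    """
    if tp + fp == 0 or tp + fn == 0:
        raise ValueError("precision and recall both need a nonzero denominator")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if recall == 0:
        return 0.0
    return 1.25 * precision * recall / (0.25 * precision + recall)


def circular_distance(p: float, q: float, genome_len: float) -> float:
    """Shortest relative distance between two loci on a circular genome."""
    d = abs(p - q)
    return min(d, genome_len - d) / genome_len


def mean_relative_distance_matrix(
    positions: Mapping[str, Mapping[str, Sequence[float]]],
    genome_lengths: Mapping[str, float],
) -> pd.DataFrame:
    """Average pairwise shortest genomic distances across circular assemblies.

    ``positions[assembly][gene]`` lists the gene's loci on that assembly.
    Per assembly each gene pair gets the minimum circular distance over
    copy pairs, normalized by genome length; the matrix averages these
    over assemblies where both genes occur.  Pairs co-occurring nowhere
    are NaN.
    """
    genes = sorted({g for asm in positions.values() for g in asm})
    g_idx = {g: i for i, g in enumerate(genes)}
    m = len(genes)
    total = np.zeros((m, m))
    count = np.zeros((m, m), dtype=int)
    for asm, gene_pos in positions.items():
        L = genome_lengths[asm]
        present = sorted(gene_pos)
        for pos_list in gene_pos.values():
            for p in pos_list:
                if not 0 <= p < L:
                    raise ValueError(f"position {p} outside [0, {L}) on {asm}")
        for a_i, g1 in enumerate(present):
            for g2 in present[a_i:]:
                d = min(
                    circular_distance(p, q, L)
                    for p in gene_pos[g1]
                    for q in gene_pos[g2]
                )
                i, j = g_idx[g1], g_idx[g2]
                total[i, j] += d
                count[i, j] += 1
                if i != j:
                    total[j, i] += d
                    count[j, i] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    np.fill_diagonal(mean, np.where(np.diag(count) > 0, np.diag(mean), np.nan))
    return pd.DataFrame(mean, index=genes, columns=genes)


def single_linkage_clusters(
    distances: pd.DataFrame, cutoff: float = LINKAGE_CUTOFF
) -> list[list[str]]:
    """Single-linkage clusters at the given distance cutoff.

    Cutting a single-linkage dendrogram at ``cutoff`` is the same as
    taking connected components of the graph with an edge wherever the
    pairwise distance is strictly below the cutoff.  NaN entries (gene
    pairs never co-occurring) contribute no edge.
    """
    genes = list(distances.index)
    vals = distances.to_numpy(dtype=float)
    adj = np.nan_to_num(vals, nan=np.inf) < cutoff
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for gene, lab in zip(genes, labels):
        clusters[lab].append(gene)
    clusters = [sorted(c) for c in clusters]
    return sorted(clusters, key=lambda c: c[0])


def valid_genes(
    stats: Mapping[str, pd.DataFrame],
    f05: Mapping[str, float],
    subsets: Sequence[str] = ("full", "tiny"),
) -> list[str]:
    """Genes passing the universality/deviance screen in every subset plus F0.5."""
    genes: set[str] | None = None
    for label in subsets:
        df = stats[label]
        ok = set(
            df.index[
                (df["universality"] > UNIVERSALITY_MIN)
                & (df["deviance"] < DEVIANCE_MAX)
            ]
        )
        genes = ok if genes is None else genes & ok
    assert genes is not None
    return sorted(g for g in genes if f05.get(g, 0.0) > F05_MIN)


def select_representatives(
    clusters: Sequence[Sequence[str]],
    stats: pd.DataFrame,
    f05: Mapping[str, float] | None = None,
) -> list[str]:
    """One representative gene per cluster.

    Ranking within a cluster: higher universality, then lower deviance,
    then higher F0.5, then lexicographic gene id.  ``stats`` is the
    full-panel universality/deviance frame.
    """
    f05 = f05 or {}
    reps = []
    for cluster in clusters:
        if not cluster:
            raise ValueError("empty cluster")
        reps.append(
            min(
                cluster,
                key=lambda g: (
                    -stats.loc[g, "universality"],
                    stats.loc[g, "deviance"],
                    -f05.get(g, 0.0),
                    g,
                ),
            )
        )
    return reps
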