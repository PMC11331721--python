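"""Benchmark metrics for comparing estimated and expected profiles.

Covers genome-copy recovery (x/y ratio, Pearson correlation over sample
totals), species-set detection metrics (precision/recall/F1 where a
true positive is a species present in both profiles), four abundance
dissimilarities (L1, L2, Bray-Curtis, Jensen-Shannon distance), and the
hierarchical genome-size database used to convert sequence abundance
into genome copies for base-pair-reporting profilers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import distance as ssd
from scipy.stats import pearsonr


@dataclass
class EvalReport:
    xy_ratio: float
    pearson_r: float
    precision: float
    recall: float
    f1: float
    l1: float
    l2: float
    bray_curtis: float
    jensen_shannon: float


def copy_metrics(
    estimated: Sequence[float], expected: Sequence[float]
) -> tuple[list[float], float]:
    """Per-sample x/y ratios plus the Pearson correlation across samples.

    x is the estimated and y the expected total genome copies of a
    sample; the ratio is the recovery rate of genome copies.
    """
    est = np.asarray(estimated, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if est.shape != exp.shape:
        raise ValueError("estimated and expected must align")
    if (exp <= 0).any():
        raise ValueError("expected totals must be positive")
    ratios = (est / exp).tolist()
    r = float(pearsonr(est, exp).statistic) if est.size >= 2 else float("nan")
    return ratios, r


def set_metrics(
    estimated: set[str], expected: set[str]
) -> tuple[float, float, float]:
    """Species-detection precision, recall, and F1.

    TP is the number of species observed in both profiles; F1 is the
    harmonic mean 2pr/(p+r).  Unclassified entries must already have
    been removed from both sets.
    """
    if not estimated:
        raise ValueError("estimated species set is empty; precision undefined")
    if not expected:
        raise ValueError("expected species set is empty; recall undefined")
    tp = len(estimated & expected)
    precision = tp / len(estimated)
    recall = tp / len(expected)
    f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def dissimilarities(
    p: Sequence[float], q: Sequence[float]
) -> tuple[float, float, float, float]:
    """(L1, L2, Bray-Curtis, Jensen-Shannon distance) between profiles.

    Inputs are non-negative relative-abundance vectors on the union of
    species (unclassified rows removed and vectors renormalized
    beforehand).  Jensen-Shannon uses base-2 logs, so the distance is
    bounded by 1.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("abundance vectors must be non-negative")
    return (
        float(ssd.cityblock(p, q)),
        float(ssd.euclidean(p, q)),
        float(ssd.braycurtis(p, q)),
        float(ssd.jensenshannon(p, q, base=2)),
    )


def profiles_to_vectors(
    estimated: Mapping[str, float], expected: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Align two species->abundance maps on their union and renormalize."""
    species = sorted(set(estimated) | set(expected))
    p = np.array([estimated.get(s, 0.0) for s in species])
    q = np.array([expected.get(s, 0.0) for s in species])
    if p.sum() > 0:
        p = p / p.sum()
    if q.sum() > 0:
        q = q / q.sum()
    return p, q


class GenomeSizeDB:
    """Hierarchical mean genome sizes over a taxonomy tree.

    Leaves carry measured genome sizes; every internal taxid's size is
    the unweighted mean over its descendant leaf genomes.  Species
    missing from the database borrow the size of their lowest sized
    ancestor.
    """

    def __init__(self, sizes: dict[str, float], parents: dict[str, str]):
        self.sizes = sizes
        self.parents = parents

    def size_of(self, taxid: str) -> float | None:
        """Size of the taxid, walking up the taxonomy if unsized."""
        seen = set()
        node: str | None = taxid
        while node is not None:
            if node in seen:
                raise ValueError(f"cycle in taxonomy at {node!r}")
            seen.add(node)
            if node in self.sizes:
                return self.sizes[node]
            node = self.parents.get(node)
        return None


def build_genome_size_db(
    species_sizes: Mapping[str, float],
    parents: Mapping[str, str],
) -> GenomeSizeDB:
    """Build the hierarchical database from leaf sizes and parent links.

    ``parents`` maps a taxid to its parent taxid (roots absent).  Every
    ancestor of a sized leaf receives the mean of its descendant leaf
    sizes.
    """
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    for leaf, size in species_sizes.items():
        node: str | None = leaf
        seen = set()
        while node is not None:
            if node in seen:
                raise ValueError(f"cycle in taxonomy at {node!r}")
            seen.add(node)
            totals[node] = totals.get(node, 0.0) + size
            counts[node] = counts.get(node, 0) + 1
            node = parents.get(node)
    sizes = {tid: totals[tid] / counts[tid] for tid in totals}
    return GenomeSizeDB(sizes, dict(parents))


def genome_size_correct(
    assigned_bp: Mapping[str, float],
    db: GenomeSizeDB,
    mean_read_length: float | None = None,
    read_counts: bool = False,
) -> tuple[dict[str, float], list[str]]:
    """Convert assigned base pairs per taxid into genome copies.

    copies = bp / genome size, with ancestor fallback for unsized
    species.  When only read counts are available (``read_counts``),
    bp is reads x the sample's mean read length.  Taxids with no sized
    ancestor are returned uncorrected in the warnings list.
    """
    if read_counts and mean_read_length is None:
        raise ValueError("read-count input needs a mean read length")
    copies: dict[str, float] = {}
    uncorrected: list[str] = []
    for taxid, amount in assigned_bp.items():
        bp = amount * mean_read_length if read_counts else amount
        size = db.size_of(taxid)
        if size is None:
            uncorrected.append(taxid)
            continue
        copies[taxid] = bp / size
    return copies, uncorrected


def evaluate_profiles(
    estimated: Mapping[str, float],
    expected: Mapping[str, float],
    estimated_total: float | None = None,
    expected_total: float | None = None,
) -> EvalReport:
    """Full single-sample comparison of an estimated vs expected profile."""
    precision, recall, f1 = set_metrics(set(estimated), set(expected))
    p, q = profiles_to_vectors(estimated, expected)
    l1, l2, bc, js = dissimilarities(p, q)
    if estimated_total is None:
        estimated_total = sum(estimated.values())
    if expected_total is None:
        expected_total = sum(expected.values())
    ratio = estimated_total / expected_total if expected_total else math.nan
    return EvalReport(
        xy_ratio=ratio,
        pearson_r=float("nan"),
        precision=precision,
        recall=recall,
        f1=f1,
        l1=l1,
        l2=l2,
        bray_curtis=bc,
        jensen_shannon=js,
    )
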