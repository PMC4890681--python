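"""Full-length 16S rRNA identity, OTU clustering and novelty calling.

OTUs are built by average-linkage agglomeration on pairwise percent identity
(free-end-gap global alignment), cut at a similarity threshold — 0.987 for
species-level OTUs, 0.97 for general OTUs. The merge order is fully
deterministic: highest mean identity first, ties broken by the
lexicographically smallest cluster pair. Novelty of a query against a
reference set is ranked by its best identity: below the species threshold it
is a candidate novel species, below the genus threshold a novel genus, below
the family threshold a novel family.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .align import pairwise_identity_16s, validate_nucleotide


@dataclass(frozen=True)
class SixteenSRecord:
    sequence_id: str
    sequence: str
    taxonomy: str | None = None

    def __post_init__(self) -> None:
        validate_nucleotide(self.sequence, self.sequence_id)


class NoveltyCall(str, Enum):
    KNOWN_SPECIES = "known_species"
    NOVEL_SPECIES = "novel_species"
    NOVEL_GENUS = "novel_genus"
    NOVEL_FAMILY = "novel_family"


@dataclass
class OtuClustering:
    threshold: float
    clusters: list[set[str]]
    representatives: list[str]  # longest member per cluster, ties lexicographic

    def cluster_of(self, sequence_id: str) -> int:
        for i, members in enumerate(self.clusters):
            if sequence_id in members:
                return i
        raise KeyError(sequence_id)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def identity_matrix(records: Sequence[SixteenSRecord]) -> np.ndarray:
    """Symmetric percent-identity matrix (diagonal 100)."""
    n = len(records)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity_16s(
                records[i].sequence,
                records[j].sequence,
                a_id=records[i].sequence_id,
                b_id=records[j].sequence_id,
            )
            m[i, j] = m[j, i] = ident
    return m


def cluster_otus(
    records: Sequence[SixteenSRecord],
    threshold: float = 0.987,
    linkage: str = "average",
    identities: np.ndarray | None = None,
) -> OtuClustering:
    """Agglomerative OTU clustering cut at a similarity threshold.

    Merging continues while the best linkage identity between two clusters is
    at least ``threshold`` (as a fraction). ``linkage`` is 'average' (default),
    'single' or 'complete'.
    """
    if not records:
        raise ValueError("no sequences to cluster")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    ids = [r.sequence_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    m = identity_matrix(records) if identities is None else identities
    cutoff = 100.0 * threshold

    clusters: list[list[int]] = [[i] for i in range(len(records))]

    def link(a: list[int], b: list[int]) -> float:
        vals = m[np.ix_(a, b)]
        if linkage == "average":
            return float(vals.mean())
        if linkage == "single":
            return float(vals.max())  # similarity space: single = closest pair
        return float(vals.min())

    def label(cluster: list[int]) -> str:
        return min(ids[i] for i in cluster)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                sim = link(clusters[i], clusters[j])
                key = tuple(sorted((label(clusters[i]), label(clusters[j]))))
                cand = (-sim, key, i, j)
                if best is None or cand < best:
                    best = cand
        sim = -best[0]
        if sim < cutoff:
            break
        _, _, i, j = best
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]

    clusters.sort(key=label)
    member_sets = [set(ids[i] for i in c) for c in clusters]
    reps = [
        min((r for r in records if r.sequence_id in members),
            key=lambda r: (-len(r.sequence), r.sequence_id)).sequence_id
        for members in member_sets
    ]
    return OtuClustering(threshold=threshold, clusters=member_sets, representatives=reps)


def call_novelty(
    query: SixteenSRecord,
    references: Iterable[SixteenSRecord],
    species_threshold: float = 98.7,
    genus_threshold: float = 94.5,
    family_threshold: float = 86.5,
) -> NoveltyCall:
    """Rank-level novelty of a query sequence against a reference set.

    The genus and family identity thresholds are conventional rank cut-offs
    and deliberately configurable; only the 98.7% species boundary is fixed
    by the species-level OTU definition.
    """
    refs = list(references)
    if not refs:
        raise ValueError("empty reference set")
    best = max(
        pairwise_identity_16s(
            query.sequence, r.sequence, a_id=query.sequence_id, b_id=r.sequence_id
        )
        for r in refs
    )
    if best >= species_threshold:
        return NoveltyCall.KNOWN_SPECIES
    if best >= genus_threshold:
        return NoveltyCall.NOVEL_SPECIES
    if best >= family_threshold:
        return NoveltyCall.NOVEL_GENUS
    return NoveltyCall.NOVEL_FAMILY
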