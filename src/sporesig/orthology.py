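"""Conserved gene-family identification by heuristic bidirectional best hits.

Every gene of one genome is compared against every gene of another through the
prefiltered local aligner; the best qualifying hit per query gene (score, then
identity, then lexicographically smallest subject id) defines a directed
best-hit map, and mutual best hits (BBH) form an undirected graph whose
connected components are gene families. A family is retained as "conserved"
when it is present in at least ``conservation_fraction`` of the genomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd

from .align import AlignParams, SimilarityHit, pairwise_similarity, validate_protein


class Phenotype(str, Enum):
    RESISTANT = "resistant"  # ethanol-resistant, i.e. spore-former
    SENSITIVE = "sensitive"
    UNKNOWN = "unknown"


@dataclass
class GenomeRecord:
    """A genome: identity, taxonomy, ethanol-resistance phenotype and proteome.

    Gene ids must be unique within the genome (and, for cross-genome analyses,
    globally — the simulator prefixes ids with the genome id to guarantee it).
    """

    genome_id: str
    species: str
    genus: str
    family: str
    phenotype: Phenotype
    genes: list[tuple[str, str]]  # (gene_id, protein sequence)

    def __post_init__(self) -> None:
        self.phenotype = Phenotype(self.phenotype)
        ids = [g for g, _ in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"{self.genome_id}: duplicate gene ids {dupes}")
        for gene_id, seq in self.genes:
            validate_protein(seq, f"{self.genome_id}/{gene_id}")


@dataclass
class OrthologMatrix:
    """Binary family × genome presence matrix plus family membership.

    ``presence`` is indexed by family id with one 0/1 column per genome;
    ``members`` maps family id -> {genome_id: gene_id} (at most one gene per
    genome per family); ``singletons`` lists genes not assigned to any
    retained multi-genome family, so that membership + singletons always
    account for every input gene.
    """

    presence: pd.DataFrame
    members: dict[str, dict[str, str]]
    singletons: list[str] = field(default_factory=list)

    @property
    def family_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.columns)

    def n_members(self) -> int:
        return sum(len(m) for m in self.members.values())


def _pair_hits(
    genome_a: GenomeRecord, genome_b: GenomeRecord, params: AlignParams
) -> dict[tuple[str, str], tuple[float, float, float, float]]:
    """All qualifying alignments between two genomes, computed once per pair.

    Returns {(gene_a, gene_b): (score, identity, coverage_a, coverage_b)}.
    Score and identity are symmetric; coverage is per-direction because query
    lengths differ.
    """
    hits: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for (ga, sa), (gb, sb) in itertools.product(genome_a.genes, genome_b.genes):
        hit = pairwise_similarity(sa, sb, params, query_id=ga, subject_id=gb)
        if hit is None:
            continue
        rev = pairwise_similarity(sb, sa, params, query_id=gb, subject_id=ga)
        cov_b = rev.coverage if rev is not None else 0.0
        hits[(ga, gb)] = (hit.score, hit.identity, hit.coverage, cov_b)
    return hits


def _select_best(
    candidates: list[tuple[str, float, float, float]],
) -> tuple[str, float, float, float] | None:
    """Deterministic best hit: max score, then max identity, then smallest id."""
    if not candidates:
        return None
    return min(candidates, key=lambda c: (-c[1], -c[2], c[0]))


def best_hits(
    query_genome: GenomeRecord,
    subject_genome: GenomeRecord,
    params: AlignParams = AlignParams(),
) -> dict[str, SimilarityHit]:
    """Best qualifying subject gene for each query gene.

    A hit qualifies when identity >= min_identity and query coverage >=
    min_coverage; query genes with no qualifying hit are absent from the map.
    """
    if query_genome.genome_id == subject_genome.genome_id:
        raise ValueError("best_hits requires two distinct genomes")
    pair = _pair_hits(query_genome, subject_genome, params)
    out: dict[str, SimilarityHit] = {}
    for qid, _ in query_genome.genes:
        cands = [
            (sid, sc, ident, cov_q)
            for (g, sid), (sc, ident, cov_q, _cov_s) in pair.items()
            if g == qid and ident >= params.min_identity and cov_q >= params.min_coverage
        ]
        best = _select_best(cands)
        if best is not None:
            sid, sc, ident, cov = best
            out[qid] = SimilarityHit(qid, sid, sc, ident, cov)
    return out


@dataclass
class BbhGraph:
    """Mutual best-hit pairs across all genome pairs, with alignment scores."""

    pairs: set[tuple[str, str]]  # each tuple sorted lexicographically
    scores: dict[tuple[str, str], float]
    gene_genomes: dict[str, str]  # gene id -> genome id


def bbh_graph(
    genomes: list[GenomeRecord], params: AlignParams = AlignParams()
) -> BbhGraph:
    """Bidirectional best hits over every unordered genome pair."""
    if len(genomes) < 2:
        raise ValueError("bidirectional best hits require at least two genomes")
    gene_genomes: dict[str, str] = {}
    for g in genomes:
        for gid, _ in g.genes:
            if gid in gene_genomes:
                raise ValueError(f"gene id {gid!r} appears in more than one genome")
            gene_genomes[gid] = g.genome_id
    pairs: set[tuple[str, str]] = set()
    scores: dict[tuple[str, str], float] = {}
    for ga, gb in itertools.combinations(genomes, 2):
        hits = _pair_hits(ga, gb, params)
        fwd: dict[str, tuple[str, float]] = {}
        for qid, _ in ga.genes:
            cands = [
                (sid, sc, ident, cov_q)
                for (q, sid), (sc, ident, cov_q, _) in hits.items()
                if q == qid
                and ident >= params.min_identity
                and cov_q >= params.min_coverage
            ]
            best = _select_best(cands)
            if best is not None:
                fwd[qid] = (best[0], best[1])
        rev: dict[str, str] = {}
        for sid, _ in gb.genes:
            cands = [
                (q, sc, ident, cov_s)
                for (q, s), (sc, ident, _cov_q, cov_s) in hits.items()
                if s == sid
                and ident >= params.min_identity
                and cov_s >= params.min_coverage
            ]
            best = _select_best(cands)
            if best is not None:
                rev[sid] = best[0]
        for qid, (sid, sc) in fwd.items():
            if rev.get(sid) == qid:
                key = tuple(sorted((qid, sid)))
                pairs.add(key)
                scores[key] = sc
    return BbhGraph(pairs=pairs, scores=scores, gene_genomes=gene_genomes)


def _demoted_components(
    bbh: BbhGraph,
) -> tuple[list[dict[str, str]], list[str]]:
    """BBH connected components with paralogs demoted to singletons.

    Returns (families, singletons) where each family maps genome_id ->
    gene_id (one gene per genome: the member with the highest summed
    within-component score, ties by lexicographically smaller gene id) and
    families are sorted by member gene ids for run-to-run determinism.
    """
    graph = nx.Graph()
    graph.add_nodes_from(bbh.gene_genomes)
    graph.add_edges_from(bbh.pairs)

    families: list[dict[str, str]] = []
    singletons: list[str] = []
    for component in nx.connected_components(graph):
        if len(component) == 1:
            singletons.extend(component)
            continue
        by_genome: dict[str, list[str]] = {}
        for gene in component:
            by_genome.setdefault(bbh.gene_genomes[gene], []).append(gene)
        chosen: dict[str, str] = {}
        for genome_id, genes in by_genome.items():
            if len(genes) == 1:
                chosen[genome_id] = genes[0]
                continue
            # paralog resolution: strongest summed connection wins
            def strength(gene: str) -> float:
                return sum(
                    bbh.scores[tuple(sorted((gene, other)))]
                    for other in component
                    if tuple(sorted((gene, other))) in bbh.scores
                )

            keep = min(genes, key=lambda g: (-strength(g), g))
            chosen[genome_id] = keep
            singletons.extend(g for g in genes if g != keep)
        families.append(chosen)

    families.sort(key=lambda m: sorted(m.values()))
    return families, singletons


def family_partition(bbh: BbhGraph) -> dict[str, str]:
    """Every gene's family label before conservation filtering (demoted
    paralogs and unclustered genes label as their own singleton family)."""
    families, singletons = _demoted_components(bbh)
    labels: dict[str, str] = {}
    for i, members in enumerate(families):
        for gene in members.values():
            labels[gene] = f"FAM{i:05d}"
    for gene in singletons:
        labels[gene] = f"singleton:{gene}"
    return labels


def cluster_families(
    bbh: BbhGraph,
    genomes: list[GenomeRecord],
    conservation_fraction: float = 0.5,
) -> OrthologMatrix:
    """Connected components of the BBH graph -> conserved gene families.

    If a component carries more than one gene from a genome, the member with
    the highest summed within-component alignment score is kept (ties broken
    by lexicographically smaller gene id) and the rest are demoted to
    singletons. A family enters the presence matrix iff it occurs in at least
    ``conservation_fraction`` of the genomes.
    """
    if not (0.0 < conservation_fraction <= 1.0):
        raise ValueError(
            f"conservation_fraction must be in (0, 1], got {conservation_fraction}"
        )
    genome_ids = [g.genome_id for g in genomes]
    families, singletons = _demoted_components(bbh)
    retained: dict[str, dict[str, str]] = {}
    rows = []
    n_genomes = len(genome_ids)
    for i, members in enumerate(families):
        if len(members) / n_genomes >= conservation_fraction:
            fam_id = f"FAM{i:05d}"
            retained[fam_id] = members
            rows.append(
                [fam_id] + [1 if g in members else 0 for g in genome_ids]
            )
        else:
            singletons.extend(members.values())
    presence = pd.DataFrame(
        [r[1:] for r in rows],
        index=[r[0] for r in rows],
        columns=genome_ids,
        dtype=np.int8,
    )
    presence.index.name = "family_id"
    return OrthologMatrix(
        presence=presence, members=retained, singletons=sorted(singletons)
    )


def build_ortholog_matrix(
    genomes: list[GenomeRecord],
    params: AlignParams = AlignParams(),
    conservation_fraction: float = 0.5,
) -> OrthologMatrix:
    """Convenience: BBH graph + family clustering in one call."""
    return cluster_families(bbh_graph(genomes, params), genomes, conservation_fraction)


def conservation_sensitivity(
    bbh: BbhGraph, genomes: list[GenomeRecord], fractions: list[float]
) -> pd.DataFrame:
    """Retained family count as a function of the conservation threshold."""
    counts = [
        len(cluster_families(bbh, genomes, f).family_ids) for f in fractions
    ]
    return pd.DataFrame({"conservation_fraction": fractions, "n_families": counts})
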