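"""Alignment heuristics and BBH family clustering against brute-force oracles."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from sporesig import (
    AlignParams,
    SimConfig,
    bbh_graph,
    best_hits,
    build_ortholog_matrix,
    cluster_families,
    family_partition,
    pairwise_similarity,
    simulate_genomes,
)
from sporesig.orthology import GenomeRecord, Phenotype

from .conftest import mutate, random_protein
from .oracles import exhaustive_bbh, sw_score

NO_PREFILTER = AlignParams(min_shared_kmers=0)


def _genome(genome_id, genes, phenotype=Phenotype.UNKNOWN):
    return GenomeRecord(
        genome_id=genome_id,
        species=f"sp_{genome_id}",
        genus="g",
        family="f",
        phenotype=phenotype,
        genes=genes,
    )


class TestPairwiseSimilarity:
    def test_identical_sequences_full_identity_and_coverage(self, rng):
        seq = random_protein(rng, 60)
        hit = pairwise_similarity(seq, seq)
        assert hit.identity == 100.0
        assert hit.coverage == 1.0

    def test_prefilter_rejects_pairs_sharing_no_kmer(self):
        # disjoint alphabets guarantee zero shared 4-mers
        assert pairwise_similarity("ACDEFGHIK" * 5, "LMNPQRSTV" * 5) is None

    def test_raw_score_equals_dp_oracle_on_random_pairs(self, rng):
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(30, 90)))
            b = mutate(a, 0.3, rng) if rng.random() < 0.5 else random_protein(
                rng, int(rng.integers(30, 90))
            )
            hit = pairwise_similarity(a, b, NO_PREFILTER)
            expected = sw_score(a, b)
            if hit is None:
                assert expected <= 0
            else:
                assert hit.score == expected

    def test_illegal_characters_name_the_gene(self):
        with pytest.raises(ValueError, match="geneZ"):
            pairwise_similarity("ACDEF", "AC1EF", query_id="geneA", subject_id="geneZ")

    def test_prefilter_sound_at_moderate_divergence(self, rng):
        # heuristic equals exhaustive whenever within-family divergence <= 0.15
        for _ in range(20):
            a = random_protein(rng, 80)
            b = mutate(a, 0.15, rng)
            with_pf = pairwise_similarity(a, b)
            without = pairwise_similarity(a, b, NO_PREFILTER)
            assert with_pf == without


class TestBestHits:
    def test_zero_divergence_best_hit_is_family_copy(self):
        cfg = SimConfig(
            seed=5, n_resistant=2, n_sensitive=2, n_core_families=5,
            n_accessory_families=0, n_signature_families=0,
            within_family_divergence=0.0, protein_length_range=(40, 60),
        )
        genomes, truth = simulate_genomes(cfg)
        hits = best_hits(genomes[0], genomes[1])
        assert len(hits) == len(genomes[0].genes)
        for qid, hit in hits.items():
            assert truth.gene_families[qid] == truth.gene_families[hit.subject_id]

    def test_family_absent_from_subject_gives_no_entry(self, rng):
        shared = random_protein(rng, 50)
        only_a = random_protein(rng, 50)
        a = _genome("A", [("A|f1", shared), ("A|f2", only_a)])
        b = _genome("B", [("B|f1", mutate(shared, 0.05, rng))])
        hits = best_hits(a, b)
        assert "A|f1" in hits and "A|f2" not in hits

    def test_same_genome_rejected(self, rng):
        g = _genome("A", [("A|x", random_protein(rng, 40))])
        with pytest.raises(ValueError, match="distinct"):
            best_hits(g, g)


class TestBbhGraph:
    def test_mutual_best_hits_form_pairs_and_match_oracle(self, rng):
        # 3-genome, 5-family random instance vs exhaustive enumeration
        for seed in range(3):
            cfg = SimConfig(
                seed=seed, n_resistant=2, n_sensitive=1, n_core_families=5,
                n_accessory_families=0, n_signature_families=0,
                within_family_divergence=0.08, protein_length_range=(40, 70),
            )
            genomes, _ = simulate_genomes(cfg)
            got = bbh_graph(genomes).pairs
            assert got == exhaustive_bbh(genomes)

    def test_asymmetric_best_hits_are_excluded(self, rng):
        base = random_protein(rng, 60)
        near = mutate(base, 0.02, rng)
        far = mutate(base, 0.1, rng)
        a = _genome("A", [("A|g1", near), ("A|g2", base)])
        b = _genome("B", [("B|g1", base)])
        pairs = bbh_graph([a, b]).pairs
        # B|g1's best in A is its exact copy A|g2; A|g1's best is B|g1 but not mutually
        assert tuple(sorted(("A|g2", "B|g1"))) in pairs
        assert tuple(sorted(("A|g1", "B|g1"))) not in pairs


class TestClusterFamilies:
    def test_zero_divergence_recovers_planted_families_exactly(self):
        cfg = SimConfig(
            seed=2, n_resistant=3, n_sensitive=2, n_core_families=6,
            n_accessory_families=0, n_signature_families=0,
            within_family_divergence=0.0, protein_length_range=(40, 60),
        )
        genomes, truth = simulate_genomes(cfg)
        part = family_partition(bbh_graph(genomes))
        genes = sorted(truth.gene_families)
        ari = adjusted_rand_score(
            [truth.gene_families[g] for g in genes], [part[g] for g in genes]
        )
        assert ari == 1.0

    def test_conservation_fraction_one_keeps_only_universal_families(self, small_panel):
        _, genomes, truth = small_panel
        bbh = bbh_graph(genomes)
        strict = cluster_families(bbh, genomes, conservation_fraction=1.0)
        for fam, members in strict.members.items():
            assert len(members) == len(genomes)

    def test_invalid_conservation_fraction_rejected(self, small_panel):
        _, genomes, _ = small_panel
        bbh = bbh_graph(genomes[:3])
        with pytest.raises(ValueError, match="conservation_fraction"):
            cluster_families(bbh, genomes[:3], conservation_fraction=0.0)

    def test_gene_conservation_accounting(self, small_panel):
        _, genomes, _ = small_panel
        matrix = build_ortholog_matrix(genomes, conservation_fraction=0.5)
        total_genes = sum(len(g.genes) for g in genomes)
        assert matrix.n_members() + len(matrix.singletons) == total_genes

    def test_genome_order_invariance(self, small_panel):
        _, genomes, truth = small_panel
        fwd = build_ortholog_matrix(genomes)
        rev = build_ortholog_matrix(list(reversed(genomes)))
        # same families up to relabelling: compare per-gene partitions
        def labels(matrix):
            out = {}
            for fam, members in matrix.members.items():
                for gene in members.values():
                    out[gene] = fam
            return out

        la, lb = labels(fwd), labels(rev)
        assert set(la) == set(lb)
        genes = sorted(la)
        assert adjusted_rand_score(
            [la[g] for g in genes], [lb[g] for g in genes]
        ) == 1.0
        assert sorted(fwd.presence.sum(axis=1)) == sorted(rev.presence.sum(axis=1))
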