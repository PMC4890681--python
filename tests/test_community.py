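"""Community statistics against hand values and independent numeric oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sporesig import (
    AbundanceTable,
    CoverageRecord,
    GenusCall,
    colonies_required,
    inverse_simpson,
    metagenomic_species_detected,
    paired_ttest,
    sequence_present,
    spearman_correlation,
    spore_fractions,
    standardize,
    turnover_fraction,
    welch_ttest,
)
from sporesig.community import simulate_colony_picks


def _table(rows, mode="relative"):
    return AbundanceTable(data=pd.DataFrame(rows), mode=mode)


def _row(sample, taxon, ab, genus=None, rank="species"):
    return {
        "sample_id": sample,
        "taxon_id": taxon,
        "rank": rank,
        "genus": genus or taxon.split(".")[0],
        "abundance": ab,
    }


class TestStandardize:
    def test_counts_become_relative_and_log2_companion_kept(self):
        t = _table(
            [_row("s1", "a", 100), _row("s1", "b", 300), _row("s1", "c", 600)],
            mode="counts",
        )
        out = standardize(t)
        assert out.data["abundance"].tolist() == [0.1, 0.3, 0.6]
        assert out.data["log2_count"].tolist() == pytest.approx(
            np.log2([101, 301, 601]).tolist()
        )

    def test_single_taxon_goes_to_one(self):
        out = standardize(_table([_row("s1", "a", 42)], mode="counts"))
        assert out.data["abundance"].tolist() == [1.0]

    def test_log2_of_zero_count_is_zero(self):
        out = standardize(
            _table([_row("s1", "a", 0), _row("s1", "b", 10)], mode="counts")
        )
        assert out.data.loc[out.data["taxon_id"] == "a", "log2_count"].item() == 0.0

    def test_zero_total_sample_names_offender(self):
        t = _table([_row("bad", "a", 0)], mode="counts")
        with pytest.raises(ValueError, match="bad"):
            standardize(t)


class TestDetectionFilters:
    @pytest.mark.parametrize(
        "length,aligned,expected",
        [(1000, 2000, True), (1000, 1999, False), (500, 1000, True)],
    )
    def test_twofold_coverage_boundary(self, length, aligned, expected):
        rec = CoverageRecord("t", length, aligned, 0)
        assert sequence_present(rec) is expected

    @pytest.mark.parametrize("reads,expected", [(100, True), (99, False), (0, False)])
    def test_hundred_read_cutoff(self, reads, expected):
        assert metagenomic_species_detected(CoverageRecord("t", 10, 0, reads)) is expected

    def test_fuzzed_filters_match_direct_arithmetic(self, rng):
        for _ in range(200):
            length = int(rng.integers(1, 5000))
            aligned = int(rng.integers(0, 20000))
            reads = int(rng.integers(0, 300))
            rec = CoverageRecord("t", length, aligned, reads)
            assert sequence_present(rec) == (aligned / length >= 2.0)
            assert metagenomic_species_detected(rec) == (reads >= 100)

    def test_zero_length_is_error(self):
        with pytest.raises(ValueError, match="zero target length"):
            sequence_present(CoverageRecord("t", 0, 10, 5))


class TestSporeFractions:
    def test_all_spore_forming_gives_unity(self):
        t = _table([_row("s1", "ga.x", 0.4), _row("s1", "gb.y", 0.6)])
        v = {"ga": GenusCall.SPORE_FORMING, "gb": GenusCall.SPORE_FORMING}
        out = spore_fractions(t, v)
        assert out.iloc[0]["fraction_of_genera"] == 1.0
        assert out.iloc[0]["fraction_of_abundance"] == 1.0

    def test_hand_computed_two_genus_case(self):
        t = _table([_row("s1", "ga.x", 0.3), _row("s1", "gb.y", 0.7)])
        v = {"ga": GenusCall.SPORE_FORMING, "gb": GenusCall.NON_SPORE_FORMING}
        out = spore_fractions(t, v)
        assert out.iloc[0]["fraction_of_genera"] == pytest.approx(0.5)
        assert out.iloc[0]["fraction_of_abundance"] == pytest.approx(0.3)

    def test_unclassified_genera_excluded_from_denominator(self):
        t = _table(
            [_row("s1", "ga.x", 0.3), _row("s1", "gb.y", 0.4), _row("s1", "gc.z", 0.3)]
        )
        v = {"ga": GenusCall.SPORE_FORMING, "gb": GenusCall.NON_SPORE_FORMING}
        out = spore_fractions(t, v)
        assert out.iloc[0]["fraction_of_genera"] == pytest.approx(0.5)
        assert out.iloc[0]["fraction_of_abundance"] == pytest.approx(0.3 / 0.7)

    def test_no_classified_genera_is_error(self):
        t = _table([_row("s1", "ga.x", 1.0)])
        with pytest.raises(ValueError, match="no classified"):
            spore_fractions(t, {})

    def test_abundance_fraction_invariant_to_rescaling(self, rng):
        ab = rng.random(6) + 0.1
        rows = [
            {"sample_id": "s", "taxon_id": f"g{i}.x", "rank": "species",
             "genus": f"g{i}", "abundance": a}
            for i, a in enumerate(ab)
        ]
        v = {f"g{i}": (GenusCall.SPORE_FORMING if i % 2 else GenusCall.NON_SPORE_FORMING)
             for i in range(6)}
        t1 = AbundanceTable(pd.DataFrame(rows), mode="counts")
        scaled = pd.DataFrame(rows).assign(abundance=lambda d: d["abundance"] * 37.0)
        t2 = AbundanceTable(scaled, mode="counts")
        f1 = spore_fractions(t1, v).iloc[0]["fraction_of_abundance"]
        f2 = spore_fractions(t2, v).iloc[0]["fraction_of_abundance"]
        assert f1 == pytest.approx(f2)


class TestSpearman:
    def test_monotone_relations_hit_plus_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_correlation(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_correlation(x, -(x**3)) == pytest.approx(-1.0)

    def test_tied_example_matches_scipy(self):
        x = [1, 2, 2, 3, 4, 4, 4, 5]
        y = [3, 1, 4, 4, 2, 5, 5, 6]
        assert spearman_correlation(x, y) == pytest.approx(
            sps.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_random_instances_match_scipy(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.integers(0, 10, size=n).astype(float)  # ties likely
            y = rng.integers(0, 10, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearman_correlation(x, y) == pytest.approx(
                sps.spearmanr(x, y).statistic, abs=1e-10
            )

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1, 1, 1], [1, 2, 3])


class TestInverseSimpson:
    def test_uniform_equals_taxon_count(self):
        assert inverse_simpson([0.25] * 4) == pytest.approx(4.0)

    def test_single_taxon_is_one(self):
        assert inverse_simpson([1.0]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert inverse_simpson([0.5, 0.3, 0.2]) == pytest.approx(1 / 0.38)

    def test_maximized_at_uniformity(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            assert inverse_simpson(p) <= 6.0 + 1e-12

    def test_subset_renormalization(self):
        # spore-only subset (0.2, 0.2) renormalizes to uniform over 2
        assert inverse_simpson([0.2, 0.2]) == pytest.approx(2.0)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            inverse_simpson([0.0, 0.0])


class TestTurnover:
    def _pair(self, p1, p2):
        rows1 = [_row("s", f"g.t{i}", p) for i, p in enumerate(p1) if p > 0]
        rows2 = [_row("s", f"g.t{i}", p) for i, p in enumerate(p2) if p > 0]
        return (
            AbundanceTable(pd.DataFrame(rows1), mode="counts"),
            AbundanceTable(pd.DataFrame(rows2), mode="counts"),
        )

    def test_exact_twofold_counts_as_changed(self):
        t1, t2 = self._pair([0.1, 0.9], [0.2, 0.8])
        assert turnover_fraction(t1, t2).loc["s"] == pytest.approx(0.5)

    def test_subtwofold_unchanged(self):
        t1, t2 = self._pair([0.1, 0.9], [0.15, 0.85])
        assert turnover_fraction(t1, t2).loc["s"] == 0.0

    def test_single_timepoint_species_counts_as_changed(self):
        t1, t2 = self._pair([0.5, 0.5, 0.0], [0.5, 0.0, 0.5])
        assert turnover_fraction(t1, t2).loc["s"] == pytest.approx(2 / 3)

    def test_symmetric_in_time_direction(self, rng):
        p1 = rng.dirichlet(np.ones(8))
        p2 = rng.dirichlet(np.ones(8))
        t1, t2 = self._pair(p1, p2)
        assert turnover_fraction(t1, t2).loc["s"] == turnover_fraction(t2, t1).loc["s"]

    def test_matches_bruteforce_per_species(self, rng):
        for _ in range(20):
            p1 = np.where(rng.random(10) < 0.2, 0.0, rng.random(10))
            p2 = np.where(rng.random(10) < 0.2, 0.0, rng.random(10))
            if p1.sum() == 0 or p2.sum() == 0:
                continue
            t1, t2 = self._pair(p1, p2)
            changed = n = 0
            for a, b in zip(p1, p2):
                if a == 0 and b == 0:
                    continue
                n += 1
                if a == 0 or b == 0 or max(a / b, b / a) >= 2.0:
                    changed += 1
            assert turnover_fraction(t1, t2).loc["s"] == pytest.approx(changed / n)

    def test_disjoint_samples_is_error(self):
        t1, _ = self._pair([1.0], [1.0])
        rows = [_row("other", "g.t0", 1.0)]
        t2 = AbundanceTable(pd.DataFrame(rows), mode="counts")
        with pytest.raises(ValueError, match="share no sample"):
            turnover_fraction(t1, t2)


class TestTTests:
    def test_identical_paired_vectors(self):
        t, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_welch_equals_pooled_for_mirrored_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t_welch, _ = welch_ttest(a, -a)
        t_pooled = sps.ttest_ind(a, -a, equal_var=True).statistic
        assert t_welch == pytest.approx(t_pooled, abs=1e-12)

    def test_random_instances_match_scipy_to_1e10(self, rng):
        for _ in range(100):
            n, m = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            a = rng.normal(size=n)
            b = rng.normal(loc=rng.normal(), size=m)
            t, p = welch_ttest(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            t2, p2 = paired_ttest(x, y)
            ref2 = sps.ttest_rel(x, y)
            assert t2 == pytest.approx(ref2.statistic, abs=1e-10)
            assert p2 == pytest.approx(ref2.pvalue, abs=1e-10)

    def test_zero_variance_nonzero_difference_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_ttest([1.0, 2.0], [2.0, 3.0])


class TestColoniesRequired:
    def test_single_certain_species_needs_one_pick(self):
        assert colonies_required([1.0]) == pytest.approx(1.0)

    def test_uniform_closed_form(self):
        for s in (2, 5, 10, 25):
            expected = s * sum(1.0 / i for i in range(1, s + 1))
            got = colonies_required(np.full(s, 1.0 / s))
            assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_probability_species_gives_infinite_expectation(self):
        assert colonies_required([1.0, 0.0]) == float("inf")

    def test_per_species_probability_mode_arithmetic(self):
        p = np.array([0.9, 0.1])
        n = colonies_required(p, target="per_species_probability", gamma=0.95)
        assert n == np.ceil(np.log(0.05) / np.log(0.9))

    def test_quadrature_within_discrete_simulation_ci(self, rng):
        p = rng.dirichlet(np.ones(5))
        expected = colonies_required(p)
        draws = simulate_colony_picks(p, 3000, rng, method="discrete")
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3.5 * se

    def test_exponential_embedding_agrees_with_discrete_mean(self, rng):
        p = np.array([0.5, 0.3, 0.2])
        cont = simulate_colony_picks(p, 20000, rng, method="exponential").mean()
        disc = simulate_colony_picks(p, 5000, rng, method="discrete").mean()
        assert cont == pytest.approx(disc, rel=0.1)

    def test_unnormalized_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            colonies_required([0.5, 0.2])
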