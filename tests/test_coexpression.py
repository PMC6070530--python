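"""Risk-gene selection, median cross-correlation, specificity sets, windows."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainvar.config import AnalysisConfig
from brainvar.coexpression import (
    CoexpressionResult,
    RiskGeneSet,
    age_window_scan,
    coexpression_test,
    density_matched_loci_geneset,
    external_geneset,
    median_cross_correlation,
    random_gene_per_locus,
    same_chromosome_geneset,
    select_risk_genes,
)
from brainvar.similarity import bonferroni
from brainvar.types import GeneAnnotation, RiskLocus, ValidationError
from brainvar.variability import VariabilityGeneSet

from conftest import make_dataset, make_samples, make_stratum

CFG = AnalysisConfig(n_point_resamples=10, n_null_resamples=50)
MHC = ("6", 25_000_000, 34_000_000)


def annot(entries):
    return {g: GeneAnnotation(g, g, c, s, e) for g, c, s, e in entries}


class TestSelectRiskGenes:
    def test_single_gene_locus(self):
        a = annot([("gA", "1", 1000, 2000)])
        loci = [RiskLocus("L1", "1", 500, 2500, ((1200, 1e-9),), ("gA",))]
        assert select_risk_genes(loci, a, MHC, CFG).gene_ids == ["gA"]

    def test_containment_beats_proximity(self):
        a = annot([("gA", "1", 1100, 1500), ("gB", "1", 2000, 3000)])
        loci = [RiskLocus("L1", "1", 900, 3200, ((1200, 1e-9),), ("gA", "gB"))]
        assert select_risk_genes(loci, a, MHC, CFG).gene_ids == ["gA"]

    def test_most_significant_variant_decides(self):
        a = annot([("gA", "1", 100, 200), ("gB", "1", 5000, 6000)])
        loci = [RiskLocus("L1", "1", 50, 7000,
                          ((150, 1e-8), (5500, 1e-12)), ("gA", "gB"))]
        # gB hosts the stronger variant
        assert select_risk_genes(loci, a, MHC, CFG).gene_ids == ["gB"]

    def test_duplicate_closest_gene_counted_once(self):
        a = annot([("gT", "1", 1000, 2000)])
        loci = [
            RiskLocus("L1", "1", 500, 2500, ((1500, 1e-9),), ("gT",)),
            RiskLocus("L2", "1", 800, 2600, ((1100, 1e-10),), ("gT",)),
        ]
        res = select_risk_genes(loci, a, MHC, CFG)
        assert res.gene_ids == ["gT"]
        assert "L1" in res.provenance["gT"] or "L2" in res.provenance["gT"]

    def test_mhc_gene_excluded(self):
        a = annot([("gM", "6", 26_000_000, 26_010_000),
                   ("gOK", "6", 40_000_000, 40_010_000)])
        loci = [
            RiskLocus("Lm", "6", 25_900_000, 26_100_000,
                      ((26_005_000, 1e-9),), ("gM",)),
            RiskLocus("Lo", "6", 39_900_000, 40_100_000,
                      ((40_005_000, 1e-9),), ("gOK",)),
        ]
        assert select_risk_genes(loci, a, MHC, CFG).gene_ids == ["gOK"]

    def test_unannotated_candidates_skipped(self):
        a = annot([("gA", "1", 1000, 2000)])
        loci = [RiskLocus("L1", "1", 500, 2500, ((1500, 1e-9),),
                          ("missing", "gA"))]
        assert select_risk_genes(loci, a, MHC, CFG).gene_ids == ["gA"]


class TestMedianCrossCorrelation:
    def _vals(self):
        # 4 subjects; g1 and g2 strongly correlated, g3 anti-correlated
        return np.array([
            [1.0, 2.0, 3.0, 4.0],    # g1
            [2.0, 4.1, 5.9, 8.0],    # g2
            [4.0, 3.0, 2.0, 1.0],    # g3
        ]), ["g1", "g2", "g3"]

    def test_degenerate_self_set_rejected(self):
        vals, ids = self._vals()
        with pytest.raises(ValidationError, match="no valid gene pairs"):
            median_cross_correlation(vals, ids, ["g1"], ["g1"])

    def test_hand_sized_median(self):
        vals, ids = self._vals()
        r12 = stats.pearsonr(vals[0], vals[1]).statistic
        r13 = stats.pearsonr(vals[0], vals[2]).statistic
        expected = np.median([r12, r13])
        got = median_cross_correlation(vals, ids, ["g1"], ["g2", "g3"])
        assert got == pytest.approx(expected)

    def test_exact_copy_gives_one(self):
        vals, ids = self._vals()
        both = np.vstack([vals, vals[:1]])
        ids2 = ids + ["c1"]  # c1 duplicates g1's values under a distinct id
        rho = median_cross_correlation(both, ids2, ["g1"], ["c1"])
        assert rho == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, (6, 5))
        ids = [f"g{i}" for i in range(6)]
        a, b = ["g0", "g1", "g2"], ["g3", "g4"]
        assert median_cross_correlation(vals, ids, a, b) == pytest.approx(
            median_cross_correlation(vals, ids, b, a))


class TestRandomGenePerLocus:
    def test_single_gene_locus_matches_closest_rule(self):
        a = annot([("gA", "1", 1000, 2000)])
        loci = [RiskLocus("L1", "1", 500, 2500, ((1500, 1e-9),), ("gA",))]
        rng = np.random.default_rng(0)
        assert random_gene_per_locus(loci, a, MHC, rng).gene_ids == ["gA"]

    def test_two_gene_locus_uniform(self):
        a = annot([("gA", "1", 100, 200), ("gB", "1", 300, 400)])
        loci = [RiskLocus("L1", "1", 50, 500, ((150, 1e-9),), ("gA", "gB"))]
        rng = np.random.default_rng(1)
        n = 1000
        count_a = sum(
            random_gene_per_locus(loci, a, MHC, rng).gene_ids == ["gA"]
            for _ in range(n))
        # binomial(1000, 1/2) bounds at ~4 sigma
        assert 440 <= count_a <= 560

    def test_all_mhc_locus_skipped(self):
        a = annot([("gM", "6", 26_000_000, 26_010_000)])
        loci = [RiskLocus("Lm", "6", 25_900_000, 26_100_000,
                          ((26_005_000, 1e-9),), ("gM",))]
        rng = np.random.default_rng(2)
        assert random_gene_per_locus(loci, a, MHC, rng).gene_ids == []


class TestDensityMatched:
    def _density(self, chrom="1", span=2_000_000, count=100):
        rows = [{"chromosome": chrom, "start": w, "end": w + 99_999,
                 "count": count}
                for w in range(1, span, 100_000)]
        return pd.DataFrame(rows)

    def test_uniform_density_always_qualifies(self):
        a = annot([(f"g{i}", "1", 50_000 + i * 120_000,
                    70_000 + i * 120_000) for i in range(15)])
        loci = [RiskLocus("L1", "1", 400_000, 500_000, ((450_000, 1e-9),),
                          ("g3",))]
        rng = np.random.default_rng(3)
        res = density_matched_loci_geneset(loci, self._density(), a, CFG, rng)
        assert len(res.gene_ids) == 1
        assert res.gene_ids[0] in a

    def test_no_gene_even_extended_skips_locus(self):
        a = annot([("gFar", "2", 1_000_000, 1_010_000)])  # wrong chromosome
        loci = [RiskLocus("L1", "1", 400_000, 500_000, ((450_000, 1e-9),),
                          ("gFar",))]
        rng = np.random.default_rng(4)
        res = density_matched_loci_geneset(loci, self._density(), a, CFG, rng,
                                           max_attempts=50)
        assert res.gene_ids == []


class TestSameChromosome:
    def test_two_gene_chromosome_picks_the_other(self):
        a = annot([("gA", "1", 100, 200), ("gB", "1", 300, 400)])
        ref = RiskGeneSet(label="closest", gene_ids=["gA"])
        rng = np.random.default_rng(5)
        assert same_chromosome_geneset(ref, a, MHC, rng).gene_ids == ["gB"]

    def test_size_preserved_and_first_slot_uniform(self):
        a = annot([(f"g{i}", "1", 100 + 300 * i, 200 + 300 * i)
                   for i in range(6)])
        ref = RiskGeneSet(label="closest", gene_ids=["g0", "g1"])
        rng = np.random.default_rng(6)
        first_counts = {}
        n = 1000
        for _ in range(n):
            res = same_chromosome_geneset(ref, a, MHC, rng)
            assert len(res.gene_ids) == 2
            assert len(set(res.gene_ids)) == 2
            assert res.gene_ids[0] != "g0" and res.gene_ids[1] != "g1"
            g = res.gene_ids[0]
            first_counts[g] = first_counts.get(g, 0) + 1
        # the first slot draws uniformly among the 5 non-reference genes
        expected = n / 5
        chi2 = sum((first_counts.get(f"g{i}", 0) - expected) ** 2 / expected
                   for i in range(1, 6))
        assert chi2 < stats.chi2.ppf(0.99, df=4)

    def test_singleton_chromosome_rejected(self):
        a = annot([("gA", "2", 100, 200)])
        ref = RiskGeneSet(label="closest", gene_ids=["gA"])
        with pytest.raises(ValidationError):
            same_chromosome_geneset(ref, a, MHC, np.random.default_rng(7))


class TestExternalGeneset:
    def test_reads_annotated_autosomal_list(self, tmp_path):
        a = annot([(f"g{i}", "1", 100 + 200 * i, 200 + 200 * i)
                   for i in range(35)])
        path = tmp_path / "depression_genes.txt"
        path.write_text("\n".join(f"g{i}" for i in range(35)))
        res = external_geneset(path, a)
        assert len(res.gene_ids) == 35
        assert res.label == "depression_genes"

    def test_unknown_and_non_autosomal_dropped(self, tmp_path):
        a = annot([("g1", "1", 100, 200), ("gX", "X", 100, 200)])
        path = tmp_path / "list.txt"
        path.write_text("g1\ngX\nnope\ng1\n")
        assert external_geneset(path, a).gene_ids == ["g1"]

    def test_empty_after_filtering_rejected(self, tmp_path):
        path = tmp_path / "list.txt"
        path.write_text("nope\n")
        with pytest.raises(ValidationError):
            external_geneset(path, annot([("g1", "1", 100, 200)]))


class TestCoexpressionTest:
    def test_copied_risk_set_is_maximal(self):
        """If the risk genes duplicate the variability genes' values, the
        observed rho reaches the upper bound of 1."""
        rng = np.random.default_rng(8)
        spec = [(f"M{i}_{r}", f"M{i}", "M", 700.0, r)
                for i in range(5) for r in ("DFC", "MFC")]
        spec += [(f"F{i}_DFC", f"F{i}", "F", 700.0, "DFC") for i in range(3)]
        samples = make_samples(spec)
        # the three variability genes follow one shared profile, so every
        # cross-set pair with their copies correlates at ~1
        profile = rng.normal(0, 1, len(samples))
        base = profile + rng.normal(0, 1e-6, (6, len(samples)))
        vals = np.vstack([base, base[:3] + rng.normal(0, 1e-9, (3, len(samples)))])
        ids = [f"v{i}" for i in range(6)] + [f"r{i}" for i in range(3)]
        ds = make_dataset(vals, samples, gene_ids=ids)
        st = make_stratum(ds, cluster_id=2, bin_index=8)
        vset = VariabilityGeneSet(2, 8, ["v0", "v1", "v2"], {}, {}, {})
        risk = RiskGeneSet(label="copies", gene_ids=["r0", "r1", "r2"])
        sd_table = {g: float(s) for g, s in
                    zip(ids, vals[:, :10].std(axis=1, ddof=1))}
        res = coexpression_test(st, ds, vset, risk, sd_table, CFG, seed=0)
        assert res.rho == pytest.approx(1.0, abs=1e-6)
        assert res.n_variability_genes == 3 and res.n_risk_genes == 3

    def test_fwer_uses_22_tests_by_default(self):
        r = CoexpressionResult(2, 8, "c2b8", "closest", rho=0.2,
                               empirical_p=0.01, corrected_p=bonferroni(0.01, 22),
                               n_variability_genes=10, n_risk_genes=5)
        assert r.corrected_p == pytest.approx(0.22)


class TestAgeWindowScan:
    def _ds(self, ages, n_genes=20, seed=0):
        rng = np.random.default_rng(seed)
        spec = []
        for i, age in enumerate(ages):
            sex = "M" if i % 2 == 0 else "F"
            d = f"{sex}{i}"
            for r in ("DFC", "MFC"):
                spec.append((f"{d}_{r}", d, sex, age, r))
        samples = make_samples(spec)
        return make_dataset(rng.normal(0, 1, (n_genes, len(samples))), samples)

    def test_six_ages_give_three_windows(self):
        ages = [600.0, 620.0, 640.0, 660.0, 680.0, 700.0] * 2
        ds = self._ds(ages)
        st = make_stratum(ds, cluster_id=2, bin_index=8)
        risk = RiskGeneSet(label="r", gene_ids=["g1", "g2"])
        res = age_window_scan(ds, 2, [st], [8], ["g3", "g4", "g5", "g6"],
                              risk, CFG, seed=0)
        assert [w.window_index for w in res] == [1, 2, 3]
        for w in res:
            assert min(w.donor_ages_days) >= 600 and len(w.donor_ages_days) >= 4

    def test_single_age_rejected(self):
        ds = self._ds([700.0] * 6)
        st = make_stratum(ds, cluster_id=2, bin_index=8)
        risk = RiskGeneSet(label="r", gene_ids=["g1"])
        with pytest.raises(ValidationError, match="distinct donor ages"):
            age_window_scan(ds, 2, [st], [8], ["g2", "g3"], risk, CFG, seed=0)

    def test_window_without_enough_donors_flagged(self):
        # all-male windows: similarity difference unavailable, rho computable
        ages = [600.0, 620.0, 640.0, 660.0]
        rng = np.random.default_rng(1)
        spec = [(f"M{i}_{r}", f"M{i}", "M", age, r)
                for i, age in enumerate(ages * 2) for r in ("DFC",)]
        samples = make_samples(spec)
        ds = make_dataset(rng.normal(0, 1, (10, len(samples))), samples)
        st = make_stratum(ds, cluster_id=2, bin_index=8)
        risk = RiskGeneSet(label="r", gene_ids=["g1", "g2"])
        res = age_window_scan(ds, 2, [st], [8], ["g3", "g4"], risk, CFG, seed=0)
        assert all(w.similarity_difference is None for w in res)
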