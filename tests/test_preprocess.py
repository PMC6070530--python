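"""Filters, normalisation, confounder estimation, residualization, outliers."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from brainvar import preprocess as pp
from brainvar.config import AnalysisConfig
from brainvar.types import GeneAnnotation, StateError, ValidationError

from conftest import make_dataset, make_samples

CFG = AnalysisConfig()


def _donor_ds(donor_rins, region="DFC"):
    """One donor per entry; each entry is a list of per-sample RINs."""
    spec = []
    for i, rins in enumerate(donor_rins):
        for j, rin in enumerate(rins):
            regions = ["DFC", "MFC", "VFC", "OFC"]
            spec.append((f"d{i}_s{j}", f"d{i}", "M", 700, regions[j % 4], rin))
    samples = make_samples(spec)
    values = np.arange(2 * len(samples), dtype=float).reshape(2, -1)
    return make_dataset(values, samples, scale="intensity")


class TestRinFilter:
    def test_donor_at_exact_fraction_kept(self):
        # 1 of 4 samples below 7.5 is a bad fraction of exactly 0.25,
        # not strictly greater -> donor kept
        ds = _donor_ds([[7.0, 8, 8, 8]])
        assert pp.filter_rin(ds, "donor_fraction", CFG).n_samples == 4

    def test_donor_above_fraction_removed(self):
        ds = _donor_ds([[7.0, 8], [8, 8, 8, 8]])
        out = pp.filter_rin(ds, "donor_fraction", CFG)
        assert {s.donor_id for s in out.samples} == {"d1"}

    def test_sample_threshold_removes_boundary(self):
        # the stricter per-sample rule removes RIN <= 7.5
        ds = _donor_ds([[7.5, 7.6, 8.0]])
        out = pp.filter_rin(ds, "sample_threshold", CFG)
        assert [s.rin for s in out.samples] == [7.6, 8.0]

    def test_idempotent(self):
        ds = _donor_ds([[7.0, 8], [8, 8, 8, 8]])
        once = pp.filter_rin(ds, "donor_fraction", CFG)
        twice = pp.filter_rin(once, "donor_fraction", CFG)
        assert twice.sample_ids == once.sample_ids


class TestAgeAndAutosomeFilter:
    def _annot(self, chroms):
        return {f"g{i + 1}": GeneAnnotation(f"g{i + 1}", f"g{i + 1}", c,
                                            100, 200)
                for i, c in enumerate(chroms)}

    def test_sex_chromosome_genes_dropped(self):
        ds = _donor_ds([[8, 8]])
        out = pp.filter_age_and_autosomes(ds, self._annot(["1", "X"]), CFG)
        assert out.gene_ids == ["g1"]

    def test_subject_at_exactly_40_years_kept(self):
        spec = [("s1", "d1", "M", 14890.0, "DFC"),      # exactly 40 y
                ("s2", "d2", "M", 14890.1, "DFC")]      # strictly older
        ds = make_dataset(np.ones((1, 2)), make_samples(spec))
        out = pp.filter_age_and_autosomes(ds, self._annot(["1"]), CFG)
        assert out.sample_ids == ["s1"]

    def test_all_autosomal_unchanged(self):
        ds = _donor_ds([[8, 8]])
        out = pp.filter_age_and_autosomes(ds, self._annot(["1", "22"]), CFG)
        assert out.gene_ids == ds.gene_ids


class TestRpkmFilter:
    def _ds(self, values):
        spec = [(f"s{i}", f"d{i}", "M" if i < 4 else "F", 700, "DFC")
                for i in range(8)]
        return make_dataset(values, make_samples(spec), scale="rpkm")

    def test_gene_low_in_most_males_dropped(self):
        vals = np.full((2, 8), 5.0)
        vals[0, :3] = 0.5  # 3 of 4 male samples below 1 RPKM
        out = pp.filter_rpkm(self._ds(vals), CFG)
        assert out.gene_ids == ["g2"]

    def test_exactly_half_kept(self):
        vals = np.full((1, 8), 5.0)
        vals[0, :2] = 0.5   # 2 of 4 males
        vals[0, 4:6] = 0.5  # 2 of 4 females
        out = pp.filter_rpkm(self._ds(vals), CFG)
        assert out.gene_ids == ["g1"]

    def test_rejects_logged_data(self):
        ds = pp.log2_transform(self._ds(np.full((1, 8), 5.0)), offset=1)
        with pytest.raises(StateError):
            pp.filter_rpkm(ds, CFG)


class TestLog2:
    def test_values(self):
        ds = _donor_ds([[8, 8]])
        ds = dataclasses.replace(ds, values=np.array([[3.0, 0.0]] * 2))
        out = pp.log2_transform(ds, offset=1)
        np.testing.assert_allclose(out.values, [[2.0, 0.0]] * 2)

    def test_double_application_guarded(self):
        ds = _donor_ds([[8, 8]])
        once = pp.log2_transform(ds, offset=1)
        with pytest.raises(StateError):
            pp.log2_transform(once, offset=1)

    def test_negative_with_zero_offset_rejected(self):
        ds = _donor_ds([[8, 8]])
        ds = dataclasses.replace(ds, values=np.array([[-1.0, 1.0]] * 2))
        with pytest.raises(ValidationError):
            pp.log2_transform(ds, offset=0)


class TestQuantileNormalize:
    def _ds(self, cols):
        arr = np.array(cols, dtype=float).T
        spec = [(f"s{i}", f"d{i}", "M", 700, "DFC") for i in range(arr.shape[1])]
        return make_dataset(arr, make_samples(spec))

    def test_two_column_order_statistic_means(self):
        out = pp.quantile_normalize(self._ds([[1, 2, 3], [4, 5, 6]]))
        np.testing.assert_allclose(out.values.T,
                                   [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_identical_columns_are_fixed_point(self):
        ds = self._ds([[3, 1, 2], [3, 1, 2]])
        out = pp.quantile_normalize(ds)
        np.testing.assert_allclose(out.values, ds.values)

    def test_ties_get_mean_of_reference_span(self):
        # column (1,1,4) vs (2,3,10): reference (1.5, 2, 7); the tied pair
        # in column one takes mean(1.5, 2) = 1.75
        out = pp.quantile_normalize(self._ds([[1, 1, 4], [2, 3, 10]]))
        np.testing.assert_allclose(out.values[:, 0], [1.75, 1.75, 7.0])
        np.testing.assert_allclose(out.values[:, 1], [1.5, 2.0, 7.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(arrays(float, (7, 4),
                  elements=st.floats(-50, 50, allow_nan=False),
                  unique=True))
    def test_columns_share_sorted_values(self, arr):
        """Post-condition for tie-free data: every column ends up with the
        identical sorted multiset.  (Tied values instead receive the mean of
        the reference over their span, which deliberately departs from the
        common multiset — covered by the explicit tie test above.)"""
        spec = [(f"s{i}", f"d{i}", "M", 700, "DFC") for i in range(4)]
        out = pp.quantile_normalize(make_dataset(arr, make_samples(spec)))
        ref = np.sort(out.values[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref,
                                       atol=1e-12)


class TestCollapseReplicates:
    def _replicate_ds(self, reps):
        spec = [(f"r{j}", "d1", "M", 700, "DFC") for j in range(len(reps))]
        spec.append(("other", "d2", "F", 700, "DFC"))
        vals = np.array([list(reps) + [99.0]])
        return make_dataset(vals, make_samples(spec))

    @pytest.mark.parametrize("reps,expected", [((1, 2, 10), 2.0), ((1, 3), 2.0)])
    def test_median_collapse(self, reps, expected):
        out = pp.collapse_replicates(self._replicate_ds(reps))
        assert out.n_samples == 2
        d1_col = out.sample_index([s.sample_id for s in out.samples
                                   if s.donor_id == "d1"])[0]
        assert out.values[0, d1_col] == expected

    def test_no_duplicates_is_identity(self, tiny_cohort_ds):
        out = pp.collapse_replicates(tiny_cohort_ds)
        np.testing.assert_array_equal(out.values, tiny_cohort_ds.values)

    def test_one_sample_per_donor_region_after(self):
        out = pp.collapse_replicates(self._replicate_ds((1, 2, 3)))
        keys = [(s.donor_id, s.region) for s in out.samples]
        assert len(keys) == len(set(keys))


class TestImputePh:
    def _ds(self, phs):
        spec = [(f"s{i}", f"d{i}", "M", 700, "DFC", 9.0, 10.0, ph)
                for i, ph in enumerate(phs)]
        return make_dataset(np.ones((1, len(phs))), make_samples(spec))

    def test_missing_filled_with_mean(self):
        out = pp.impute_ph(self._ds([6.0, None, 7.0]))
        assert [s.ph for s in out.samples] == [6.0, 6.5, 7.0]

    def test_complete_data_identity(self):
        ds = self._ds([6.0, 7.0])
        out = pp.impute_ph(ds)
        assert [s.ph for s in out.samples] == [6.0, 7.0]

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError, match="drop ph"):
            pp.impute_ph(self._ds([None, None]))


def _model_samples(n, seed=7):
    rng = np.random.default_rng(seed)
    return make_samples([
        (f"s{i}", f"d{i}", "M" if i % 2 else "F", 100.0 + i * 10, "DFC",
         8 + rng.random(), float(rng.uniform(5, 30)),
         float(rng.normal(6.5, 0.2)))
        for i in range(n)
    ])


def _model(ds=None):
    return pp.CovariateModel(
        full_model_terms=["sex", "age_days", "pmi_hours", "rin", "ph"],
        null_model_terms=["age_days", "pmi_hours", "rin", "ph"],
    )


class TestSurrogateEstimation:
    """Latent-factor counting on matrices with known factor structure."""

    def test_factor_count_recovery_rates(self):
        samples = _model_samples(40)
        model = _model()
        hits = {0: 0, 1: 0, 2: 0}
        n_seeds = 50
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            noise = rng.normal(0, 1, (200, 40))
            hits[0] += pp.estimate_surrogate_count(noise, model, samples, rng) == 0
            f1 = np.outer(rng.normal(0, 3, 200), rng.normal(0, 1, 40))
            hits[1] += pp.estimate_surrogate_count(noise + f1, model, samples,
                                                   rng) == 1
            f2 = np.outer(rng.normal(0, 3, 200), rng.normal(0, 1, 40))
            hits[2] += pp.estimate_surrogate_count(noise + f1 + f2, model,
                                                   samples, rng) == 2
        assert hits[0] / n_seeds >= 0.9   # false factors are rare in pure noise
        assert hits[1] / n_seeds >= 0.9   # one strong factor found
        assert hits[2] / n_seeds >= 0.9   # both orthogonal factors found

    def test_degenerate_design_rejected(self):
        samples = _model_samples(40)
        constant_ph = [dataclasses.replace(s, ph=6.5) for s in samples]
        with pytest.raises(ValidationError, match="collinear"):
            pp.estimate_surrogate_count(np.random.default_rng(0).normal(0, 1, (50, 40)),
                                        _model(), constant_ph,
                                        np.random.default_rng(0))


class TestResidualize:
    def test_gene_linear_in_age_has_null_residuals(self):
        samples = _model_samples(20)
        ages = np.array([s.age_days for s in samples])
        ds = make_dataset(np.vstack([2.0 + 0.5 * ages]), samples)
        model = _model()
        model.surrogate_values = np.zeros((20, 0))
        out = pp.residualize(ds, model)
        np.testing.assert_allclose(out.values, 0, atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        samples = _model_samples(30)
        ds = make_dataset(rng.normal(0, 1, (40, 30)), samples)
        model = _model()
        model.surrogate_values = np.zeros((30, 0))
        out = pp.residualize(ds, model)
        X, _ = pp._design_matrix(samples, model.null_model_terms)
        Xs = X / np.linalg.norm(X, axis=0, keepdims=True)
        R = out.values / np.linalg.norm(out.values, axis=1, keepdims=True)
        assert np.abs(R @ Xs).max() < 1e-6

    def test_sex_shift_survives(self):
        rng = np.random.default_rng(4)
        samples = _model_samples(40)
        male = np.array([s.sex == "M" for s in samples])
        vals = rng.normal(0, 0.3, (30, 40)) + 2.0 * male
        ds = make_dataset(vals, samples)
        model = _model()
        model.surrogate_values = np.zeros((40, 0))
        out = pp.residualize(ds, model)
        diff = out.values[:, male].mean() - out.values[:, ~male].mean()
        assert diff == pytest.approx(2.0, abs=0.15)


class TestOutlierDetection:
    def _ds(self, n_per_sex=16, n_genes=60, seed=0, displace=None, z=10.0):
        rng = np.random.default_rng(seed)
        spec = []
        for sex in ("M", "F"):
            for i in range(n_per_sex):
                spec.append((f"{sex}{i}", f"{sex}{i}", sex, 700, "DFC"))
        samples = make_samples(spec)
        vals = rng.normal(0, 1, (n_genes, len(samples)))
        if displace is not None:
            direction = rng.normal(0, 1, n_genes)
            direction /= np.linalg.norm(direction)
            vals[:, displace] += z * np.sqrt(n_genes / 60) * direction * 3
        return make_dataset(vals, samples)

    def test_displaced_sample_flagged(self):
        ds = self._ds(displace=2, z=10)
        flagged, cleaned = pp.detect_outliers(ds, CFG)
        assert flagged == [ds.samples[2].sample_id]
        assert cleaned.n_samples == ds.n_samples - 1

    def test_homogeneous_noise_rarely_flagged(self):
        total = 0
        for seed in range(20):
            flagged, _ = pp.detect_outliers(self._ds(seed=seed), CFG)
            total += len(flagged)
        # 3-SD two-PC rule on 16 samples/sex: false flags are possible but rare
        assert total <= 4

    def test_mean_profile_duplicate_never_flagged(self):
        ds = self._ds()
        mean_col = ds.values.mean(axis=1)
        vals = ds.values.copy()
        vals[:, 0] = mean_col
        ds = dataclasses.replace(ds, values=vals)
        flagged, _ = pp.detect_outliers(ds, CFG)
        assert ds.samples[0].sample_id not in flagged

    def test_small_sex_skipped(self):
        ds = self._ds(n_per_sex=3)
        flagged, cleaned = pp.detect_outliers(ds, CFG)
        assert flagged == [] and cleaned.n_samples == ds.n_samples


class TestPipeline:
    def test_transform_log_records_order(self, processed_study):
        labels = processed_study["proc"].transform_log
        order = ["filter_rin", "filter_age", "extract_autosomes", "log2",
                 "quantile_normalize", "collapse_replicates", "impute_ph",
                 "residualize", "detect_outliers"]
        positions = []
        for op in order:
            matches = [i for i, lab in enumerate(labels) if lab.startswith(op)]
            assert matches, f"{op} missing from transform_log {labels}"
            positions.append(matches[0])
        assert positions == sorted(positions)

    def test_rnaseq_platform_dialect(self, study):
        cfg = AnalysisConfig(surrogate_count=0, seed=1)
        params = study["params"]
        raw = study["ds"]
        # convert the intensity-scale study matrix to an RPKM-like scale
        ds = dataclasses.replace(raw, values=raw.values / 16.0, scale="rpkm")
        proc, report = pp.run_pipeline(ds, study["annotation"], cfg,
                                       platform="rnaseq",
                                       rng=np.random.default_rng(1))
        assert report["platform"] == "rnaseq"
        assert any(t.startswith("filter_rpkm") for t in proc.transform_log)
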