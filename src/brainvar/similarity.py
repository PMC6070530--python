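"""Between-subject expression similarity and its sex difference.

The core statistic: within one stratum — a (regional cluster, age-bin)
sample subset — expression similarity for one sex is the mean of all
pairwise Pearson correlations between subjects' transcriptome-wide
expression profiles.  Because most donors contribute several regional
samples, a three-stage donor-aware resampling scheme is used:

  1. pick exactly one sample per donor (removes within-donor dependence),
  2. bootstrap donors with replacement per sex and keep the unique set
     (avoids perfect self-correlations),
  3. subsample the larger sex's unique set to the smaller sex's size
     (equalises subject numbers between sexes).

The scheme is repeated ``n_point_resamples`` times; the point estimate is
the mean of the per-draw similarities and the CI the empirical 2.5/97.5
percentiles.  Significance of the female-minus-male difference is assessed
by permuting sex labels at the *donor* level (all samples of one donor keep
one label) and is two-sided via absolute values.

Random-stream contract (required for exact oracle equivalence): within one
draw the generator is consumed in this order —
  (a) ``u = rng.random(n_donors)`` over the participating donors in sorted
      donor_id order; donor i takes its ``int(u[i] * n_samples_i)``-th
      sample, samples of a donor in sorted sample_id order;
  (b) for sex "M" then "F": ``rng.integers(n_donors, size=n_donors)`` over
      that sex's sorted donor list (bootstrap), reduced to the sorted
      unique set;
  (c) if the sexes differ in unique count: ``rng.choice`` without
      replacement on the larger sex's sorted unique set.
Each (stratum, repetition) uses an independently derived substream, so
results do not depend on evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .config import AnalysisConfig
from .types import (
    AgeBin,
    AgePeriodTable,
    ExpressionDataset,
    RegionalCluster,
    ValidationError,
)

log = logging.getLogger(__name__)


class ResampleSkipped(RuntimeError):
    """A resampling draw could not produce >= 2 donors per sex."""


@dataclass
class Stratum:
    """All samples of one (regional cluster, age-bin) combination."""

    cluster_id: int
    bin_index: int
    sample_ids: list[str]
    donor_samples: dict[str, list[str]]  # donor_id -> its sample_ids here
    donor_sex: dict[str, str]
    included: bool = True
    exclusion_reason: str | None = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.cluster_id, self.bin_index)

    def donors_of_sex(self, sex: str) -> list[str]:
        return sorted(d for d, s in self.donor_sex.items() if s == sex)


@dataclass
class SimilarityResult:
    cluster_id: int
    bin_index: int
    sex: str
    estimate: float
    ci_low: float
    ci_high: float
    n_donors: int
    resample_estimates: list[float] = field(default_factory=list)
    available: bool = True


@dataclass
class SexDifferenceResult:
    cluster_id: int
    mean_difference: float  # female - male, averaged over included bins
    empirical_p: float
    corrected_p: float
    n_permutations: int
    included_bins: list[int]
    #: resolution bound: an empirical p of 0 means p < 1/n_permutations
    p_lt: float = 0.0


def build_strata(ds: ExpressionDataset, period_table: AgePeriodTable,
                 clusters: tuple[RegionalCluster, ...], cfg: AnalysisConfig
                 ) -> list[Stratum]:
    """One stratum per (cluster, sliding age-bin).

    Bins overlap, so a donor whose age falls in period p belongs to every
    bin whose window covers p.  Strata with fewer than ``min_donors_per_sex``
    donors in either sex are emitted but flagged excluded.
    """
    bins = period_table.bins(cfg.bin_width_periods)
    sample_period = {s.sample_id: period_table.period_of(s.age_days)
                     for s in ds.samples}
    strata: list[Stratum] = []
    for cluster in clusters:
        for b in bins:
            sel = [s for s in ds.samples
                   if s.region in cluster.member_regions
                   and sample_period[s.sample_id] in b.member_periods]
            donor_samples: dict[str, list[str]] = {}
            donor_sex: dict[str, str] = {}
            for s in sel:
                donor_samples.setdefault(s.donor_id, []).append(s.sample_id)
                donor_sex[s.donor_id] = s.sex
            for d in donor_samples:
                donor_samples[d].sort()
            st = Stratum(
                cluster_id=cluster.cluster_id,
                bin_index=b.bin_index,
                sample_ids=[s.sample_id for s in sel],
                donor_samples=donor_samples,
                donor_sex=donor_sex,
            )
            n_m = len(st.donors_of_sex("M"))
            n_f = len(st.donors_of_sex("F"))
            if min(n_m, n_f) < cfg.min_donors_per_sex:
                st.included = False
                st.exclusion_reason = f"donors per sex M={n_m} F={n_f}"
            strata.append(st)
    return strata


def draw_resample(stratum: Stratum, sex_assignment: dict[str, str],
                  rng: np.random.Generator, cfg: AnalysisConfig,
                  sexes: tuple[str, ...] = ("M", "F")
                  ) -> dict[str, list[tuple[str, str]]]:
    """One three-stage draw; returns sex -> [(donor_id, sample_id), ...].

    ``sex_assignment`` maps each donor to its (possibly permuted) sex label.
    With a single sex in ``sexes`` only stages 1-2 run (male-only
    co-expression analyses).  Raises :class:`ResampleSkipped` after bounded
    retries if a requested sex cannot reach 2 unique donors.
    """
    donors = sorted(d for d in stratum.donor_samples
                    if sex_assignment[d] in sexes)
    for _attempt in range(cfg.max_resample_retries):
        # stage 1: one sample per donor (one uniform variate per donor, in
        # sorted donor order; see the stream contract in the module doc)
        u = rng.random(len(donors))
        chosen_sample = {}
        for i, d in enumerate(donors):
            samples = stratum.donor_samples[d]
            chosen_sample[d] = samples[int(u[i] * len(samples))]
        # stage 2: per-sex donor bootstrap, unique set
        unique: dict[str, list[str]] = {}
        for sex in sexes:
            sex_donors = sorted(d for d in donors if sex_assignment[d] == sex)
            if not sex_donors:
                unique[sex] = []
                continue
            boot = rng.integers(len(sex_donors), size=len(sex_donors))
            unique[sex] = sorted({sex_donors[i] for i in boot})
        if any(len(unique[sex]) < 2 for sex in sexes):
            continue
        # stage 3: equal subject numbers across sexes
        if len(sexes) == 2:
            n_min = min(len(unique[s]) for s in sexes)
            for sex in sexes:
                if len(unique[sex]) > n_min:
                    pick = rng.choice(len(unique[sex]), size=n_min, replace=False)
                    unique[sex] = [unique[sex][i] for i in sorted(pick)]
        return {sex: [(d, chosen_sample[d]) for d in unique[sex]]
                for sex in sexes}
    raise ResampleSkipped(
        f"stratum {stratum.key}: a sex kept < 2 unique donors after "
        f"{cfg.max_resample_retries} retries"
    )


def mean_pairwise_similarity(values: np.ndarray) -> float:
    """Mean of the n(n-1)/2 distinct Pearson correlations between subject
    columns of a genes × subjects matrix."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2 or values.shape[0] < 2:
        raise ValidationError("need a genes x subjects matrix, >=2 of each")
    sd = values.std(axis=0)
    if (sd == 0).any():
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"subject column {j} has zero variance")
    corr = np.corrcoef(values, rowvar=False)
    iu = np.triu_indices(values.shape[1], k=1)
    return float(corr[iu].mean())


def _standardized_columns(ds: ExpressionDataset, sample_ids: list[str],
                          gene_rows: np.ndarray | None
                          ) -> tuple[np.ndarray, dict[str, int]]:
    """Unit-norm centered column per sample over the chosen genes, so the
    Pearson correlation of two samples is a plain dot product."""
    cols = ds.sample_index(sample_ids)
    M = ds.values[np.ix_(gene_rows, cols)] if gene_rows is not None \
        else ds.values[:, cols]
    M = M - M.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(M, axis=0)
    if (norms == 0).any():
        bad = sample_ids[int(np.flatnonzero(norms == 0)[0])]
        raise ValidationError(f"sample {bad} has zero variance across genes")
    Z = M / norms
    return Z, {sid: j for j, sid in enumerate(sample_ids)}


def _mean_pairwise_from_std(Z: np.ndarray) -> float:
    # columns are unit-norm and centered, so diag(Z'Z) = 1 and the mean of
    # the k(k-1)/2 distinct correlations is (sum - k) / (k(k-1))
    k = Z.shape[1]
    C = Z.T @ Z
    return float((C.sum() - k) / (k * (k - 1)))


def estimate_similarity_both(
    stratum: Stratum, ds: ExpressionDataset, cfg: AnalysisConfig, seed: int,
    sex_assignment: dict[str, str] | None = None,
    n_resamples: int | None = None,
    gene_rows: np.ndarray | None = None,
    stream_tag: int = 0,
    compute_ci: bool = True,
) -> dict[str, SimilarityResult]:
    """Point estimate + CI for both sexes from a shared resampling stream.

    The two sexes must share draws because stage 3 couples them.  Each
    repetition r uses substream (seed, cluster, bin, stream_tag, r).
    """
    if not stratum.included:
        raise ValidationError(f"stratum {stratum.key} is excluded")
    if sex_assignment is None:
        sex_assignment = dict(stratum.donor_sex)
    n_rep = n_resamples if n_resamples is not None else cfg.n_point_resamples
    Z, col_of = _standardized_columns(ds, stratum.sample_ids, gene_rows)
    per_sex: dict[str, list[float]] = {"M": [], "F": []}
    for r in range(n_rep):
        rng = substream(seed, stratum.cluster_id, stratum.bin_index,
                        stream_tag, r)
        try:
            picked = draw_resample(stratum, sex_assignment, rng, cfg)
        except ResampleSkipped:
            log.warning("stratum %s: repetition %d skipped", stratum.key, r)
            continue
        assert len(picked["M"]) == len(picked["F"]), "unequal subject counts"
        for sex in ("M", "F"):
            sel = picked[sex]
            assert len({d for d, _ in sel}) == len(sel), "duplicate donor in draw"
            cols = [col_of[sid] for _, sid in sel]
            per_sex[sex].append(_mean_pairwise_from_std(Z[:, cols]))
    out = {}
    for sex in ("M", "F"):
        est = per_sex[sex]
        if not est:
            out[sex] = SimilarityResult(stratum.cluster_id, stratum.bin_index,
                                        sex, np.nan, np.nan, np.nan, 0,
                                        available=False)
            continue
        arr = np.asarray(est)
        out[sex] = SimilarityResult(
            cluster_id=stratum.cluster_id,
            bin_index=stratum.bin_index,
            sex=sex,
            estimate=float(arr.mean()),
            ci_low=float(np.percentile(arr, 2.5)) if compute_ci else float("nan"),
            ci_high=float(np.percentile(arr, 97.5)) if compute_ci else float("nan"),
            n_donors=len(stratum.donors_of_sex(sex)),
            resample_estimates=arr.tolist() if compute_ci else [],
        )
    return out


def estimate_similarity(stratum: Stratum, ds: ExpressionDataset, sex: str,
                        cfg: AnalysisConfig, seed: int) -> SimilarityResult:
    """Similarity point estimate with bootstrap CI for one sex."""
    return estimate_similarity_both(stratum, ds, cfg, seed)[sex]


def _mean_bin_difference(strata: list[Stratum], ds: ExpressionDataset,
                         cfg: AnalysisConfig, seed: int,
                         sex_assignment_by_bin: dict[int, dict[str, str]] | None,
                         n_resamples: int, stream_tag: int,
                         gene_rows: np.ndarray | None = None) -> float:
    diffs = []
    for st in strata:
        assignment = (sex_assignment_by_bin[st.bin_index]
                      if sex_assignment_by_bin else None)
        res = estimate_similarity_both(
            st, ds, cfg, seed, sex_assignment=assignment,
            n_resamples=n_resamples, gene_rows=gene_rows, stream_tag=stream_tag,
            compute_ci=False,
        )
        if res["F"].available and res["M"].available:
            diffs.append(res["F"].estimate - res["M"].estimate)
    if not diffs:
        raise ValidationError("no stratum produced a similarity difference")
    return float(np.mean(diffs))


def _permute_donor_sexes(donor_sex: dict[str, str], rng: np.random.Generator
                         ) -> dict[str, str]:
    """Shuffle sex labels among donors, preserving overall per-sex counts.

    Called once per permutation on the union of a cluster's donors, so a
    donor carries one permuted label in *every* bin it appears in — bins
    overlap, and labels permuted independently per bin would make the null
    too narrow (bin differences would average out across bins in a way the
    observed statistic cannot).
    """
    donors = sorted(donor_sex)
    labels = [donor_sex[d] for d in donors]
    perm = rng.permutation(len(donors))
    return {donors[i]: labels[perm[i]] for i in range(len(donors))}


def sex_difference_test(cluster_id: int, ds: ExpressionDataset,
                        strata: list[Stratum], cfg: AnalysisConfig,
                        seed: int,
                        gene_rows: np.ndarray | None = None
                        ) -> SexDifferenceResult:
    """Donor-level sex-permutation test of the similarity difference.

    Observed statistic: D = mean over the cluster's included bins of
    (female estimate − male estimate).  Null: sex labels are permuted once
    per repetition among the union of the cluster's donors, so every sample
    of one donor — across regions *and* across the overlapping bins —
    carries the same permuted label; two-sided via |D|.
    """
    cluster_strata = [st for st in strata
                      if st.cluster_id == cluster_id and st.included]
    if not cluster_strata:
        raise ValidationError(f"cluster {cluster_id}: no included strata")
    n_inner = cfg.null_inner
    d_obs = _mean_bin_difference(cluster_strata, ds, cfg, seed, None,
                                 n_inner, stream_tag=0, gene_rows=gene_rows)
    cluster_donor_sex: dict[str, str] = {}
    for st in cluster_strata:
        cluster_donor_sex.update(st.donor_sex)
    n_perm = cfg.n_null_resamples
    count = 0
    for p in range(n_perm):
        rng = substream(seed, cluster_id, "perm", p)
        assignment = _permute_donor_sexes(cluster_donor_sex, rng)
        assignment_by_bin = {st.bin_index: assignment for st in cluster_strata}
        d_perm = _mean_bin_difference(
            cluster_strata, ds, cfg, seed, assignment_by_bin, n_inner,
            stream_tag=1_000_000 + p, gene_rows=gene_rows,
        )
        if abs(d_perm) >= abs(d_obs):
            count += 1
    p_emp = count / n_perm
    m = len(cfg.tested_clusters_for_fwer) or 1
    return SexDifferenceResult(
        cluster_id=cluster_id,
        mean_difference=d_obs,
        empirical_p=p_emp,
        corrected_p=bonferroni(p_emp, m),
        n_permutations=n_perm,
        included_bins=[st.bin_index for st in cluster_strata],
        p_lt=(1.0 / n_perm) if count == 0 else 0.0,
    )


def bonferroni(p: float, m: int) -> float:
    """Family-wise error correction: min(1, p * m)."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p outside [0, 1]: {p}")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return min(1.0, p * m)
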