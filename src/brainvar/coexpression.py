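"""Risk-gene selection and co-expression with variability genes.

One gene is selected per GWAS susceptibility locus — the gene closest to
the most significant index variant (distance 0 inside the gene body) —
with MHC-region genes excluded and genes reachable from several loci
counted once.  Co-expression between a variability-gene set and the risk
set is the median of all cross-set pairwise Pearson correlations, computed
in males only as part of the donor-aware resampling (stages 1-2; no
equalisation, since only one sex enters).  Significance comes from
variance-matched random gene sets, one-sided in the high direction, with
Bonferroni control over the 22 tested variability sets (11 bins × 2
cortical clusters) by default.

Specificity comparisons re-run the same test with alternative
"susceptibility" sets: random-in-locus, density-matched random loci,
same-chromosome random genes, and externally supplied disease gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .config import AnalysisConfig
from .similarity import ResampleSkipped, Stratum, bonferroni, draw_resample
from .types import ExpressionDataset, GeneAnnotation, RiskLocus, ValidationError
from .variability import VariabilityGeneSet, matched_random_geneset

log = logging.getLogger(__name__)


@dataclass
class RiskGeneSet:
    label: str
    gene_ids: list[str]
    provenance: dict[str, str] = field(default_factory=dict)  # gene -> note

    def __post_init__(self):
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"risk set {self.label!r} contains duplicates")


@dataclass
class CoexpressionResult:
    cluster_id: int
    bin_index: int
    variability_set: str
    risk_label: str
    rho: float
    empirical_p: float
    corrected_p: float
    n_variability_genes: int
    n_risk_genes: int
    null_mean: float = float("nan")
    null_sd: float = float("nan")
    null_q95: float = float("nan")
    n_null: int = 0


# ---------------------------------------------------------------------------
# risk-gene selection


def _gene_variant_distance(gene: GeneAnnotation, pos: int) -> int:
    """0 if the position lies within the gene body, else bp to the nearer end
    (1-based inclusive coordinates)."""
    if gene.start <= pos <= gene.end:
        return 0
    return min(abs(pos - gene.start), abs(pos - gene.end))


def _in_mhc(gene: GeneAnnotation, mhc: tuple[str, int, int]) -> bool:
    chrom, lo, hi = mhc
    return gene.chromosome == chrom and gene.start <= hi and gene.end >= lo


def select_risk_genes(loci: list[RiskLocus],
                      annotation: dict[str, GeneAnnotation],
                      mhc: tuple[str, int, int],
                      cfg: AnalysisConfig) -> RiskGeneSet:
    """Closest gene to the most significant index variant, one per locus.

    MHC-overlapping genes are dropped; duplicate genes across loci collapse
    to one entry; unannotated candidates are logged and skipped.  Distance
    ties are broken lexicographically by gene id.
    """
    if not loci:
        raise ValidationError("empty locus list")
    genes: list[str] = []
    provenance: dict[str, str] = {}
    for locus in loci:
        pos, pval = locus.top_variant
        candidates = []
        for g in locus.candidate_gene_ids:
            ann = annotation.get(g)
            if ann is None:
                log.info("locus %s: gene %s not annotated, skipped",
                         locus.locus_id, g)
                continue
            if _in_mhc(ann, mhc):
                log.info("locus %s: gene %s inside MHC region, skipped",
                         locus.locus_id, g)
                continue
            candidates.append((_gene_variant_distance(ann, pos), g))
        if not candidates:
            log.warning("locus %s: no eligible annotated genes", locus.locus_id)
            continue
        candidates.sort(key=lambda t: (t[0], t[1]))
        dist, best = candidates[0]
        if best not in provenance:
            genes.append(best)
            provenance[best] = (
                f"{locus.locus_id}: closest to variant {pos} (p={pval:g}, "
                f"distance {dist} bp)"
            )
        else:
            provenance[best] += f"; also {locus.locus_id}"
    return RiskGeneSet(label="closest", gene_ids=genes, provenance=provenance)


def random_gene_per_locus(loci: list[RiskLocus],
                          annotation: dict[str, GeneAnnotation],
                          mhc: tuple[str, int, int],
                          rng: np.random.Generator) -> RiskGeneSet:
    """Specificity procedure: a uniform random eligible gene per locus."""
    genes: list[str] = []
    provenance: dict[str, str] = {}
    for locus in loci:
        eligible = [g for g in locus.candidate_gene_ids
                    if g in annotation and not _in_mhc(annotation[g], mhc)]
        if not eligible:
            log.warning("locus %s: no eligible genes, skipped", locus.locus_id)
            continue
        pick = eligible[int(rng.integers(len(eligible)))]
        if pick not in provenance:
            genes.append(pick)
            provenance[pick] = f"{locus.locus_id}: random in locus"
    return RiskGeneSet(label="random_in_locus", gene_ids=genes,
                       provenance=provenance)


def _locus_density(density: pd.DataFrame, chromosome: str, start: int,
                   end: int) -> float:
    """Common-variant count over [start, end]: window counts weighted by
    overlap fraction."""
    sub = density[density["chromosome"] == chromosome]
    if sub.empty:
        raise ValidationError(f"no density windows for chromosome {chromosome}")
    w_start = sub["start"].to_numpy()
    w_end = sub["end"].to_numpy()
    counts = sub["count"].to_numpy(dtype=float)
    overlap = (np.minimum(w_end, end) - np.maximum(w_start, start) + 1).clip(min=0)
    width = (w_end - w_start + 1).astype(float)
    return float((counts * overlap / width).sum())


def density_matched_loci_geneset(loci: list[RiskLocus],
                                 variant_density: pd.DataFrame,
                                 annotation: dict[str, GeneAnnotation],
                                 cfg: AnalysisConfig,
                                 rng: np.random.Generator,
                                 max_attempts: int = 10_000) -> RiskGeneSet:
    """Specificity procedure: random same-chromosome, same-size windows with
    common-variant density within ``locus_density_tolerance`` of the source
    locus; one random gene from the window extended by
    ``locus_extension_bp`` per side."""
    genes: list[str] = []
    provenance: dict[str, str] = {}
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation.values():
        by_chrom.setdefault(g.chromosome, []).append(g)
    for locus in loci:
        size = locus.end - locus.start + 1
        target = _locus_density(variant_density, locus.chromosome,
                                locus.start, locus.end)
        sub = variant_density[variant_density["chromosome"] == locus.chromosome]
        chrom_lo = int(sub["start"].min())
        chrom_hi = int(sub["end"].max())
        if chrom_hi - chrom_lo + 1 < size:
            log.warning("locus %s larger than chromosome track, skipped",
                        locus.locus_id)
            continue
        chrom_genes = sorted(by_chrom.get(locus.chromosome, []),
                             key=lambda g: g.start)
        pick = None
        for _ in range(max_attempts):
            start = int(rng.integers(chrom_lo, chrom_hi - size + 2))
            end = start + size - 1
            dens = _locus_density(variant_density, locus.chromosome, start, end)
            if target > 0 and abs(dens - target) > cfg.locus_density_tolerance * target:
                continue
            lo = start - cfg.locus_extension_bp
            hi = end + cfg.locus_extension_bp
            overlapping = [g for g in chrom_genes
                           if g.start <= hi and g.end >= lo
                           and not _in_mhc(g, cfg.mhc_region)]
            if not overlapping:
                continue
            pick = overlapping[int(rng.integers(len(overlapping)))]
            assert abs(dens - target) <= cfg.locus_density_tolerance * max(target, dens)
            break
        if pick is None:
            log.warning("locus %s: no density-matched window found, skipped",
                        locus.locus_id)
            continue
        if pick.gene_id not in provenance:
            genes.append(pick.gene_id)
            provenance[pick.gene_id] = (
                f"{locus.locus_id}: density-matched window on "
                f"chr{locus.chromosome}"
            )
    return RiskGeneSet(label="density_matched", gene_ids=genes,
                       provenance=provenance)


def same_chromosome_geneset(reference: RiskGeneSet,
                            annotation: dict[str, GeneAnnotation],
                            mhc: tuple[str, int, int],
                            rng: np.random.Generator) -> RiskGeneSet:
    """Specificity procedure: per reference gene, a uniform random distinct
    gene from the same chromosome (MHC excluded)."""
    by_chrom: dict[str, list[str]] = {}
    for g in annotation.values():
        if not _in_mhc(g, mhc):
            by_chrom.setdefault(g.chromosome, []).append(g.gene_id)
    for c in by_chrom:
        by_chrom[c].sort()
    genes: list[str] = []
    provenance: dict[str, str] = {}
    used: set[str] = set()
    for ref in reference.gene_ids:
        ann = annotation.get(ref)
        if ann is None:
            raise ValidationError(f"reference gene {ref!r} not annotated")
        pool = [g for g in by_chrom.get(ann.chromosome, [])
                if g != ref and g not in used]
        if not pool:
            raise ValidationError(
                f"chromosome {ann.chromosome} has no alternative genes for {ref}"
            )
        pick = pool[int(rng.integers(len(pool)))]
        genes.append(pick)
        used.add(pick)
        provenance[pick] = f"same chromosome as {ref}"
    return RiskGeneSet(label="same_chromosome", gene_ids=genes,
                       provenance=provenance)


def external_geneset(path, annotation: dict[str, GeneAnnotation],
                     label: str | None = None) -> RiskGeneSet:
    """External comparison list (one gene id per line): annotated, autosomal,
    deduplicated; unknown ids are logged and dropped."""
    from .io import read_gene_list

    ids = read_gene_list(path)
    genes: list[str] = []
    provenance: dict[str, str] = {}
    for g in ids:
        ann = annotation.get(g)
        if ann is None:
            log.info("external gene %s not annotated, dropped", g)
            continue
        if not ann.autosomal:
            log.info("external gene %s not autosomal, dropped", g)
            continue
        genes.append(g)
        provenance[g] = "external list"
    if not genes:
        raise ValidationError(f"{path}: no usable genes after filtering")
    return RiskGeneSet(label=label or Path(path).stem, gene_ids=genes,
                       provenance=provenance)


# ---------------------------------------------------------------------------
# the co-expression statistic


def median_cross_correlation(values: np.ndarray, gene_ids: list[str],
                             set_a: list[str], set_b: list[str]) -> float:
    """Median of all Pearson correlations between genes of set A and set B
    across subject columns; self-pairs (same gene on both sides) excluded,
    zero-variance genes dropped with a warning."""
    pos = {g: i for i, g in enumerate(gene_ids)}
    a = [g for g in set_a if g in pos]
    b = [g for g in set_b if g in pos]
    if not a or not b:
        raise ValidationError("a gene set is empty after intersection")
    if values.shape[1] < 3:
        raise ValidationError("need >= 3 subjects for cross-correlation")

    def standardized(genes: list[str]) -> tuple[np.ndarray, list[str]]:
        M = values[[pos[g] for g in genes], :]
        sd = M.std(axis=1, ddof=1)
        ok = sd > 0
        if not ok.all():
            log.warning("dropping %d zero-variance gene(s)", int((~ok).sum()))
        M = M[ok]
        kept = [g for g, k in zip(genes, ok) if k]
        Z = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, ddof=1, keepdims=True)
        return Z, kept

    Za, kept_a = standardized(a)
    Zb, kept_b = standardized(b)
    if not kept_a or not kept_b:
        raise ValidationError("all genes of one set had zero variance")
    C = (Za @ Zb.T) / (values.shape[1] - 1)
    mask = np.ones_like(C, dtype=bool)
    pos_b = {g: j for j, g in enumerate(kept_b)}
    for i, g in enumerate(kept_a):
        if g in pos_b:
            mask[i, pos_b[g]] = False
    vals = C[mask]
    if vals.size == 0:
        raise ValidationError("no valid gene pairs after self-exclusion")
    return float(np.median(vals))


def _resampled_rho(stratum: Stratum, ds: ExpressionDataset,
                   set_a: list[str], set_b: list[str], cfg: AnalysisConfig,
                   seed: int, n_rep: int, stream_tag: int) -> float:
    """Mean over draws (stages 1-2, males only) of the median cross-set
    correlation among the selected male subjects."""
    pos = ds._gene_pos
    rows_a = np.array([pos[g] for g in set_a if g in pos], dtype=int)
    rows_b = np.array([pos[g] for g in set_b if g in pos], dtype=int)
    if rows_a.size == 0 or rows_b.size == 0:
        raise ValidationError("a gene set is empty after intersection")
    # mask excluding pairs where one gene sits on both sides
    b_index = {r: j for j, r in enumerate(rows_b)}
    self_pairs = [(i, b_index[r]) for i, r in enumerate(rows_a) if r in b_index]
    col_of = {sid: j for j, sid in
              enumerate(stratum.sample_ids)}
    stratum_cols = ds.sample_index(stratum.sample_ids)
    Va = ds.values[np.ix_(rows_a, stratum_cols)]
    Vb = ds.values[np.ix_(rows_b, stratum_cols)]

    rhos = []
    for r in range(n_rep):
        rng = substream(seed, stratum.cluster_id, stratum.bin_index,
                        stream_tag, r)
        try:
            picked = draw_resample(stratum, dict(stratum.donor_sex), rng, cfg,
                                   sexes=("M",))
        except ResampleSkipped:
            continue
        sel = picked["M"]
        if len(sel) < 3:
            continue
        cols = [col_of[sid] for _, sid in sel]
        rho = _median_cross_corr_rows(Va[:, cols], Vb[:, cols], self_pairs)
        if rho is not None:
            rhos.append(rho)
    if not rhos:
        raise ResampleSkipped(f"stratum {stratum.key}: no usable male draws")
    return float(np.mean(rhos))


def _median_cross_corr_rows(A: np.ndarray, B: np.ndarray,
                            self_pairs: list[tuple[int, int]]) -> float | None:
    """Median Pearson correlation between rows of A and rows of B (same
    columns), with listed (row_a, row_b) pairs excluded; None if every gene
    on one side has zero variance."""

    def std_rows(M):
        M = M - M.mean(axis=1, keepdims=True)
        sd = np.linalg.norm(M, axis=1)
        ok = sd > 0
        Z = np.zeros_like(M)
        np.divide(M, sd[:, None], out=Z, where=sd[:, None] > 0)
        return Z, ok

    Za, ok_a = std_rows(A)
    Zb, ok_b = std_rows(B)
    if not ok_a.any() or not ok_b.any():
        return None
    C = Za @ Zb.T
    mask = np.outer(ok_a, ok_b)
    for i, j in self_pairs:
        mask[i, j] = False
    vals = C[mask]
    if vals.size == 0:
        return None
    return float(np.median(vals))


def coexpression_test(stratum: Stratum, ds: ExpressionDataset,
                      variability_set: VariabilityGeneSet,
                      risk_set: RiskGeneSet, sd_table: dict[str, float],
                      cfg: AnalysisConfig, seed: int,
                      n_tests: int | None = None) -> CoexpressionResult:
    """Co-expression of a variability set with a risk set, in males.

    Observed rho is the resample-averaged median cross-correlation.  The
    null replaces the variability set by variance-matched random sets; the
    empirical p is the frequency of null rho at least as high as observed
    (one-sided), Bonferroni-corrected over ``n_tests`` variability sets
    (default: 11 bins × number of clusters in the FWER family = 22).
    """
    if len(stratum.donors_of_sex("M")) < 3:
        raise ValidationError(f"stratum {stratum.key}: < 3 male donors")
    var_genes = [g for g in variability_set.gene_ids if g in set(ds.gene_ids)]
    risk_genes = [g for g in risk_set.gene_ids if g in set(ds.gene_ids)]
    if not var_genes or not risk_genes:
        raise ValidationError("gene sets empty after intersection with dataset")
    rho_obs = _resampled_rho(stratum, ds, var_genes, risk_genes, cfg, seed,
                             cfg.n_point_resamples, stream_tag=4)
    nulls = []
    skipped = 0
    for b in range(cfg.n_null_resamples):
        rng = substream(seed, "coexpr_null", stratum.cluster_id,
                        stratum.bin_index, b)
        null_genes = matched_random_geneset(var_genes, sd_table,
                                            cfg.sd_match_tolerance, rng)
        try:
            nulls.append(
                _resampled_rho(stratum, ds, null_genes, risk_genes, cfg, seed,
                               cfg.n_coexpr_null_inner,
                               stream_tag=3_000_000 + b)
            )
        except ResampleSkipped:
            skipped += 1  # tiny stratum: no inner draw reached 3 male subjects
    if skipped:
        log.warning("stratum %s: %d of %d null replicates skipped",
                    stratum.key, skipped, cfg.n_null_resamples)
    if not nulls:
        raise ResampleSkipped(f"stratum {stratum.key}: all null replicates skipped")
    nulls_arr = np.asarray(nulls)
    p = float((nulls_arr >= rho_obs).mean())
    if n_tests is None:
        n_tests = 11 * len(cfg.tested_clusters_for_fwer)
    return CoexpressionResult(
        cluster_id=stratum.cluster_id,
        bin_index=stratum.bin_index,
        variability_set=f"c{variability_set.cluster_id}b{variability_set.bin_index}",
        risk_label=risk_set.label,
        rho=rho_obs,
        empirical_p=p,
        corrected_p=bonferroni(p, n_tests),
        n_variability_genes=len(var_genes),
        n_risk_genes=len(risk_genes),
        null_mean=float(nulls_arr.mean()),
        null_sd=float(nulls_arr.std(ddof=1)) if len(nulls) > 1 else float("nan"),
        null_q95=float(np.quantile(nulls_arr, 0.95)),
        n_null=len(nulls),
    )


# ---------------------------------------------------------------------------
# sliding age-window fine-mapping


@dataclass
class AgeWindowResult:
    window_index: int
    mean_age_days: float
    donor_ages_days: list[float]
    similarity_difference: float | None  # None when a sex lacks donors
    coexpression_rho: float | None


def age_window_scan(ds: ExpressionDataset, cluster_id: int,
                    strata: list[Stratum], bins: list[int],
                    combined_variability_genes: list[str],
                    risk_set: RiskGeneSet, cfg: AnalysisConfig, seed: int
                    ) -> list[AgeWindowResult]:
    """Fine-map effects within a set of age-bins by sliding age windows.

    Samples of the cluster's listed bins are pooled; windows are every run
    of ``fine_window_n_ages`` consecutive distinct donor ages, sliding by
    one.  Per window: (a) the female-minus-male similarity difference
    restricted to the combined variability genes (unavailable when a sex
    has fewer than ``min_donors_per_sex`` donors) and (b) male-only
    co-expression with the risk set.
    """
    pooled: set[str] = set()
    for st in strata:
        if st.cluster_id == cluster_id and st.bin_index in bins:
            pooled.update(st.sample_ids)
    samples = [s for s in ds.samples if s.sample_id in pooled]
    if not samples:
        raise ValidationError("no samples in the requested cluster/bins")
    ages = sorted({s.age_days for s in samples})
    w = cfg.fine_window_n_ages
    if len(ages) < w:
        raise ValidationError(
            f"only {len(ages)} distinct donor ages; need >= {w}"
        )
    var_rows = ds.gene_index(
        [g for g in combined_variability_genes if g in set(ds.gene_ids)]
    )
    results: list[AgeWindowResult] = []
    for k in range(len(ages) - w + 1):
        window_ages = set(ages[k:k + w])
        sel = [s for s in samples if s.age_days in window_ages]
        donor_samples: dict[str, list[str]] = {}
        donor_sex: dict[str, str] = {}
        donor_age: dict[str, float] = {}
        for s in sel:
            donor_samples.setdefault(s.donor_id, []).append(s.sample_id)
            donor_sex[s.donor_id] = s.sex
            donor_age[s.donor_id] = s.age_days
        for d in donor_samples:
            donor_samples[d].sort()
        st = Stratum(cluster_id=cluster_id, bin_index=10_000 + k,
                     sample_ids=[s.sample_id for s in sel],
                     donor_samples=donor_samples, donor_sex=donor_sex)
        n_m = len(st.donors_of_sex("M"))
        n_f = len(st.donors_of_sex("F"))

        diff = None
        if min(n_m, n_f) >= cfg.min_donors_per_sex:
            from .similarity import estimate_similarity_both

            res = estimate_similarity_both(st, ds, cfg, seed,
                                           gene_rows=var_rows, stream_tag=5)
            if res["F"].available and res["M"].available:
                diff = res["F"].estimate - res["M"].estimate

        rho = None
        if n_m >= 3:
            try:
                rho = _resampled_rho(
                    st, ds, [ds.gene_ids[i] for i in var_rows],
                    risk_set.gene_ids, cfg, seed, cfg.n_point_resamples,
                    stream_tag=6,
                )
            except (ResampleSkipped, ValidationError):
                rho = None
        results.append(
            AgeWindowResult(
                window_index=k + 1,
                mean_age_days=float(np.mean(list(donor_age.values()))),
                donor_ages_days=sorted(donor_age.values()),
                similarity_difference=diff,
                coexpression_rho=rho,
            )
        )
    return results
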