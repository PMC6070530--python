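"""Variability genes: ranking by male/female SD ratio and transfer testing.

For one stratum, each gene's expression standard deviation is computed per
draw of the donor-aware resampling scheme and averaged over draws,
separately per sex.  The ratio male-SD / female-SD ranks genes; the top-K
(default 100) are that stratum's "variability genes".  Their transfer to a
second dataset is scored against variance-matched random gene sets: each
real gene is replaced by a random gene whose SD lies within 5% of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .config import AnalysisConfig
from .similarity import (
    ResampleSkipped,
    Stratum,
    draw_resample,
    estimate_similarity_both,
)
from .types import ExpressionDataset, ValidationError

log = logging.getLogger(__name__)

#: genes whose resample-averaged female SD falls below this floor are
#: excluded from ranking (an exactly constant gene would give an infinite
#: ratio)
FEMALE_SD_FLOOR = 1e-8


@dataclass
class VariabilityGeneSet:
    cluster_id: int
    bin_index: int
    gene_ids: list[str]          # ranked, highest ratio first
    sd_ratio: dict[str, float]
    male_sd: dict[str, float]
    female_sd: dict[str, float]

    @property
    def key(self) -> tuple[int, int]:
        return (self.cluster_id, self.bin_index)


def resampled_gene_sd_both(stratum: Stratum, ds: ExpressionDataset,
                           cfg: AnalysisConfig, seed: int,
                           n_resamples: int | None = None,
                           stream_tag: int = 2) -> dict[str, np.ndarray]:
    """Per-gene SD across subjects, averaged over resampling draws, per sex.

    Repetition r consumes substream (seed, cluster, bin, stream_tag, r);
    within a draw the stream order is that documented in
    :func:`brainvar.similarity.draw_resample`.
    """
    if not stratum.included:
        raise ValidationError(f"stratum {stratum.key} is excluded")
    n_rep = n_resamples if n_resamples is not None else cfg.n_point_resamples
    sums = {"M": np.zeros(ds.n_genes), "F": np.zeros(ds.n_genes)}
    counts = {"M": 0, "F": 0}
    for r in range(n_rep):
        rng = substream(seed, stratum.cluster_id, stratum.bin_index,
                        stream_tag, r)
        try:
            picked = draw_resample(stratum, dict(stratum.donor_sex), rng, cfg)
        except ResampleSkipped:
            log.warning("stratum %s: SD repetition %d skipped", stratum.key, r)
            continue
        for sex in ("M", "F"):
            cols = ds.sample_index([sid for _, sid in picked[sex]])
            sums[sex] += ds.values[:, cols].std(axis=1, ddof=1)
            counts[sex] += 1
    if counts["M"] == 0 or counts["F"] == 0:
        raise ResampleSkipped(f"stratum {stratum.key}: all SD draws skipped")
    return {sex: sums[sex] / counts[sex] for sex in ("M", "F")}


def resampled_gene_sd(stratum: Stratum, ds: ExpressionDataset, sex: str,
                      cfg: AnalysisConfig, seed: int) -> np.ndarray:
    """Resample-averaged per-gene SD for one sex."""
    return resampled_gene_sd_both(stratum, ds, cfg, seed)[sex]


def select_variability_genes(male_sd: np.ndarray, female_sd: np.ndarray,
                             gene_ids: list[str], cfg: AnalysisConfig,
                             cluster_id: int = 0, bin_index: int = 0
                             ) -> VariabilityGeneSet:
    """Rank genes by male/female SD ratio and keep the top ``top_k``.

    Genes whose female SD is below the numerical floor are excluded.  Ties
    in the ratio are broken by larger male SD, then lexicographic gene id.
    """
    male_sd = np.asarray(male_sd, dtype=float)
    female_sd = np.asarray(female_sd, dtype=float)
    if not (len(male_sd) == len(female_sd) == len(gene_ids)):
        raise ValidationError("SD vectors must share the gene universe")
    eligible = np.flatnonzero(female_sd >= FEMALE_SD_FLOOR)
    ratio = male_sd[eligible] / female_sd[eligible]
    order = sorted(
        range(len(eligible)),
        key=lambda i: (-ratio[i], -male_sd[eligible[i]], gene_ids[eligible[i]]),
    )
    if len(order) < cfg.top_k:
        log.warning("only %d eligible genes for top_k=%d", len(order), cfg.top_k)
    top = order[: cfg.top_k]
    chosen = [gene_ids[eligible[i]] for i in top]
    return VariabilityGeneSet(
        cluster_id=cluster_id,
        bin_index=bin_index,
        gene_ids=chosen,
        sd_ratio={gene_ids[eligible[i]]: float(ratio[i]) for i in top},
        male_sd={gene_ids[eligible[i]]: float(male_sd[eligible[i]]) for i in top},
        female_sd={gene_ids[eligible[i]]: float(female_sd[eligible[i]]) for i in top},
    )


def variability_genes_for_stratum(stratum: Stratum, ds: ExpressionDataset,
                                  cfg: AnalysisConfig, seed: int
                                  ) -> VariabilityGeneSet:
    """Convenience: resampled SDs then top-k selection for one stratum."""
    sds = resampled_gene_sd_both(stratum, ds, cfg, seed)
    return select_variability_genes(
        sds["M"], sds["F"], ds.gene_ids, cfg,
        cluster_id=stratum.cluster_id, bin_index=stratum.bin_index,
    )


def matched_random_geneset(reference_genes: list[str],
                           sd_table: dict[str, float],
                           tol: float, rng: np.random.Generator) -> list[str]:
    """Variance-matched random replacement of a gene set.

    For each reference gene g a gene h != g with |sd(h) − sd(g)| <= tol·sd(g)
    is drawn uniformly; genes are not reused within one null set.  If no
    candidate exists the tolerance is doubled (at most 4 times, logged).
    """
    universe = sorted(sd_table)
    sds = np.array([sd_table[g] for g in universe])
    chosen: list[str] = []
    used: set[str] = set()
    for g in reference_genes:
        if g not in sd_table:
            raise ValidationError(f"gene {g!r} missing from the SD table")
        target = sd_table[g]
        t = tol
        pick = None
        for _step in range(5):  # original tolerance plus 4 doublings
            window = np.abs(sds - target) <= t * target
            candidates = [universe[i] for i in np.flatnonzero(window)
                          if universe[i] != g and universe[i] not in used]
            if candidates:
                pick = candidates[int(rng.integers(len(candidates)))]
                break
            t *= 2
            log.info("widening SD window for %s to %.3f", g, t)
        if pick is None:
            raise ValidationError(
                f"no SD-matched replacement for {g!r} even at tol {t:g}"
            )
        chosen.append(pick)
        used.add(pick)
    return chosen


def sd_table_from_males(ds: ExpressionDataset, strata: list[Stratum] | None = None
                        ) -> dict[str, float]:
    """Plain per-gene SD across male samples (the matching universe).

    If strata are given, only samples belonging to at least one of them are
    used; otherwise all male samples.
    """
    if strata:
        wanted = set()
        for st in strata:
            wanted.update(st.sample_ids)
        idx = [i for i, s in enumerate(ds.samples)
               if s.sex == "M" and s.sample_id in wanted]
    else:
        idx = [i for i, s in enumerate(ds.samples) if s.sex == "M"]
    if len(idx) < 3:
        raise ValidationError("need >= 3 male samples for the SD table")
    sds = ds.values[:, idx].std(axis=1, ddof=1)
    return {g: float(sd) for g, sd in zip(ds.gene_ids, sds)}


@dataclass
class TransferResult:
    difference: float            # female - male similarity on the gene set
    empirical_p: float
    n_null: int
    n_genes_used: int
    null_differences: list[float] = field(default_factory=list)


def transfer_test(ds2: ExpressionDataset, geneset: VariabilityGeneSet,
                  strata2: list[Stratum], cfg: AnalysisConfig, seed: int
                  ) -> TransferResult:
    """Do variability genes discovered in one dataset transfer to another?

    The observed statistic is the female-minus-male similarity difference on
    ``ds2`` restricted to the gene set (mean over the included strata).  The
    null replaces the set by ``n_null_resamples`` variance-matched random
    sets scored identically; the test is one-sided in the direction of the
    male similarity decrease (null D >= observed D).
    """
    present = [g for g in geneset.gene_ids if g in set(ds2.gene_ids)]
    frac = len(present) / max(1, len(geneset.gene_ids))
    log.info("transfer test: %.0f%% of genes present in second dataset",
             100 * frac)
    if len(present) < 20:
        raise ValidationError(
            f"only {len(present)} gene(s) of the set present in the second "
            "dataset (need >= 20)"
        )
    included = [st for st in strata2 if st.included]
    if not included:
        raise ValidationError("no included strata in the second dataset")
    sd_table = sd_table_from_males(ds2, included)

    def score(genes: list[str], tag: int, n_rep: int) -> float:
        rows = ds2.gene_index(genes)
        diffs = []
        for st in included:
            res = estimate_similarity_both(
                st, ds2, cfg, seed, n_resamples=n_rep, gene_rows=rows,
                stream_tag=tag,
            )
            if res["F"].available and res["M"].available:
                diffs.append(res["F"].estimate - res["M"].estimate)
        if not diffs:
            raise ValidationError("no stratum scored in transfer test")
        return float(np.mean(diffs))

    d_obs = score(present, tag=3, n_rep=cfg.n_point_resamples)
    nulls = []
    for b in range(cfg.n_null_resamples):
        rng = substream(seed, "transfer_null", b)
        null_genes = matched_random_geneset(present, sd_table,
                                            cfg.sd_match_tolerance, rng)
        nulls.append(score(null_genes, tag=2_000_000 + b,
                           n_rep=cfg.null_inner))
    nulls_arr = np.asarray(nulls)
    p = float((nulls_arr >= d_obs).mean())
    return TransferResult(
        difference=d_obs,
        empirical_p=p,
        n_null=len(nulls),
        n_genes_used=len(present),
        null_differences=nulls,
    )
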