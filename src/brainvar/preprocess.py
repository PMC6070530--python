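"""Quality filtering, normalisation, confounder estimation and residualization.

The stages, in their enforced order, turn a raw gene × sample matrix into
the covariate-adjusted dataset all downstream statistics consume:

    RIN filter -> age filter / autosome extraction -> (RPKM filter) ->
    log2 -> quantile normalisation -> replicate collapsing -> pH imputation
    -> surrogate-variable estimation -> residualization -> outlier removal

Sex is deliberately *never* regressed out: its effect on expression
variability is the signal of interest.  Age, post-mortem interval, RIN,
brain pH, batch (when present) and the estimated surrogate variables are.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .types import (
    AUTOSOMES,
    ExpressionDataset,
    GeneAnnotation,
    SampleRecord,
    StateError,
    ValidationError,
    normalize_age,
)

log = logging.getLogger(__name__)

__all__ = [
    "CovariateModel",
    "normalize_age",
    "filter_rin",
    "filter_age_and_autosomes",
    "filter_rpkm",
    "log2_transform",
    "quantile_normalize",
    "collapse_replicates",
    "impute_ph",
    "estimate_surrogate_count",
    "surrogate_values",
    "build_covariate_model",
    "residualize",
    "detect_outliers",
    "run_pipeline",
]


@dataclass
class CovariateModel:
    """Full and null covariate models for confounder adjustment.

    The full model contains sex (whose variance effects must be preserved);
    the null model is the full model minus sex and is what expression is
    residualized against.
    """

    full_model_terms: list[str]
    null_model_terms: list[str]
    surrogate_count: int = 0
    surrogate_values: np.ndarray | None = None  # n_samples x surrogate_count

    def __post_init__(self):
        if not set(self.null_model_terms) < set(self.full_model_terms):
            raise ValidationError("null model terms must be a strict subset of full")
        if "sex" not in self.full_model_terms or "sex" in self.null_model_terms:
            raise ValidationError("sex belongs to the full model only")


# ---------------------------------------------------------------------------
# sample / gene filters


def filter_rin(ds: ExpressionDataset, mode: str, cfg: AnalysisConfig) -> ExpressionDataset:
    """RNA-quality filter.

    ``donor_fraction`` removes every sample of a donor whose fraction of
    samples with RIN < rin_min exceeds donor_rin_bad_fraction (strictly);
    ``sample_threshold`` removes individual samples with RIN <= rin_min.
    """
    if mode == "donor_fraction":
        donors: dict[str, list[float]] = {}
        for s in ds.samples:
            donors.setdefault(s.donor_id, []).append(s.rin)
        bad_donors = {
            d for d, rins in donors.items()
            if np.mean([r < cfg.rin_min for r in rins]) > cfg.donor_rin_bad_fraction
        }
        keep = np.array([s.donor_id not in bad_donors for s in ds.samples])
        note = f"filter_rin:donor_fraction(removed_donors={len(bad_donors)})"
    elif mode == "sample_threshold":
        keep = np.array([s.rin > cfg.rin_min for s in ds.samples])
        note = f"filter_rin:sample_threshold(removed={int((~keep).sum())})"
    else:
        raise ValidationError(f"unknown RIN filter mode {mode!r}")
    return ds.subset_samples(keep, note=note)


def filter_age_and_autosomes(
    ds: ExpressionDataset,
    annotation: dict[str, GeneAnnotation],
    cfg: AnalysisConfig,
) -> ExpressionDataset:
    """Drop subjects strictly older than max_age_years; keep autosomal genes.

    Genes absent from the annotation are dropped with a logged count.
    """
    max_days = cfg.max_age_days
    keep_samples = np.array([s.age_days <= max_days for s in ds.samples])
    ds = ds.subset_samples(
        keep_samples, note=f"filter_age(removed={int((~keep_samples).sum())})"
    )
    unannotated = sum(g not in annotation for g in ds.gene_ids)
    if unannotated:
        log.info("dropping %d genes without annotation", unannotated)
    keep_genes = np.array(
        [g in annotation and annotation[g].chromosome in AUTOSOMES
         for g in ds.gene_ids]
    )
    ds = ds.subset_genes(
        keep_genes, note=f"extract_autosomes(kept={int(keep_genes.sum())})"
    )
    if ds.annotation is None:
        ds = dataclasses.replace(ds, annotation=annotation)
    return ds


def filter_rpkm(ds: ExpressionDataset, cfg: AnalysisConfig) -> ExpressionDataset:
    """Remove genes expressed below rpkm_min in more than rpkm_bad_fraction
    of male *or* of female samples.  Applies to pre-log RPKM data only."""
    if any(t.startswith("log2") for t in ds.transform_log):
        raise StateError("filter_rpkm must run on pre-log RPKM values")
    male = np.array([s.sex == "M" for s in ds.samples])
    keep = np.ones(ds.n_genes, dtype=bool)
    for sex_mask in (male, ~male):
        if sex_mask.sum() == 0:
            continue
        frac_low = (ds.values[:, sex_mask] < cfg.rpkm_min).mean(axis=1)
        keep &= ~(frac_low > cfg.rpkm_bad_fraction)
    return ds.subset_genes(keep, note=f"filter_rpkm(kept={int(keep.sum())})")


def log2_transform(ds: ExpressionDataset, offset: float = 0.0) -> ExpressionDataset:
    """value -> log2(value + offset).  offset 1 for RPKM, 0 for intensities."""
    if any(t.startswith("log2") for t in ds.transform_log):
        raise StateError("log2_transform already applied (see transform_log)")
    shifted = ds.values + offset
    if (shifted <= 0).any():
        raise ValidationError(
            "log2 undefined: non-positive values present; use a positive offset"
        )
    return ds.with_values(np.log2(shifted), scale="log2",
                          note=f"log2(offset={offset:g})")


# ---------------------------------------------------------------------------
# normalisation and collapsing


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample column onto the common distribution of row-rank
    means.

    Rank r in each column is replaced by the mean, across columns, of their
    r-th order statistics.  Ties within a column receive the mean of the
    reference values over the tied rank span.
    """
    if ds.n_samples < 2:
        raise ValidationError("quantile normalisation needs >= 2 samples")
    X = ds.values
    order = np.argsort(X, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(X, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(X)
    n = X.shape[0]
    # cumulative sums let tied spans take the mean reference in O(1)
    ref_cum = np.concatenate([[0.0], np.cumsum(reference)])
    for j in range(X.shape[1]):
        col = X[:, j]
        ord_j = order[:, j]
        col_sorted = col[ord_j]
        # span [lo, hi) of equal values in the sorted column -> mean reference
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [n]])
        span_means = (ref_cum[stops] - ref_cum[starts]) / (stops - starts)
        new_sorted = np.repeat(span_means, stops - starts)
        out[ord_j, j] = new_sorted
    return ds.with_values(out, scale=ds.scale, note="quantile_normalize")


def collapse_replicates(ds: ExpressionDataset) -> ExpressionDataset:
    """Replace samples sharing (donor_id, region) by their per-gene median.

    Metadata is taken from the first replicate; RIN becomes the median RIN.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for i, s in enumerate(ds.samples):
        groups.setdefault((s.donor_id, s.region), []).append(i)
    if all(len(ix) == 1 for ix in groups.values()):
        return dataclasses.replace(
            ds, transform_log=list(ds.transform_log) + ["collapse_replicates(none)"]
        )
    new_samples: list[SampleRecord] = []
    cols = []
    for (donor, region), ix in groups.items():
        first = ds.samples[ix[0]]
        if len(ix) == 1:
            cols.append(ds.values[:, ix[0]])
            new_samples.append(first)
        else:
            cols.append(np.median(ds.values[:, ix], axis=1))
            new_samples.append(
                dataclasses.replace(
                    first,
                    rin=float(np.median([ds.samples[i].rin for i in ix])),
                )
            )
    return dataclasses.replace(
        ds,
        values=np.column_stack(cols),
        samples=new_samples,
        transform_log=list(ds.transform_log)
        + [f"collapse_replicates(n_samples={len(new_samples)})"],
    )


def impute_ph(ds: ExpressionDataset) -> ExpressionDataset:
    """Fill missing brain pH with the mean of the observed values."""
    observed = [s.ph for s in ds.samples if s.ph is not None]
    if not observed:
        raise ValidationError(
            "all pH values missing: drop ph from the covariate model instead"
        )
    if len(observed) == len(ds.samples):
        return dataclasses.replace(
            ds, transform_log=list(ds.transform_log) + ["impute_ph(none)"]
        )
    mean_ph = float(np.mean(observed))
    samples = [
        s if s.ph is not None else dataclasses.replace(s, ph=mean_ph)
        for s in ds.samples
    ]
    n_filled = len(ds.samples) - len(observed)
    return dataclasses.replace(
        ds,
        samples=samples,
        transform_log=list(ds.transform_log) + [f"impute_ph(filled={n_filled})"],
    )


# ---------------------------------------------------------------------------
# covariate model, surrogate variables, residualization


def build_covariate_model(ds: ExpressionDataset) -> CovariateModel:
    """Assemble the standard model: sex + age, pmi, rin, ph, batch (if any)."""
    terms = ["age_days", "pmi_hours", "rin", "ph"]
    null_terms = [t for t in terms if _covariate_column(ds.samples, t) is not None]
    if any(s.batch is not None for s in ds.samples):
        null_terms.append("batch")
    return CovariateModel(full_model_terms=["sex"] + null_terms,
                          null_model_terms=null_terms)


def _covariate_column(samples: list[SampleRecord], term: str) -> np.ndarray | None:
    vals = [getattr(s, term) for s in samples]
    if any(v is None for v in vals):
        return None
    return np.asarray(vals, dtype=float)


def _design_matrix(samples: list[SampleRecord], terms: list[str],
                   surrogate_values: np.ndarray | None = None,
                   include_sex: bool = False) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    if include_sex:
        cols.append(np.array([1.0 if s.sex == "M" else 0.0 for s in samples]))
        names.append("sex")
    for t in terms:
        if t == "sex":
            continue
        if t == "batch":
            levels = sorted({s.batch for s in samples})
            for lev in levels[1:]:  # first level absorbed by the intercept
                cols.append(np.array([1.0 if s.batch == lev else 0.0
                                      for s in samples]))
                names.append(f"batch[{lev}]")
        else:
            col = _covariate_column(samples, t)
            if col is None:
                raise ValidationError(
                    f"covariate {t!r} has missing values; impute first"
                )
            cols.append(col)
            names.append(t)
    X = np.column_stack(cols)
    if surrogate_values is not None and surrogate_values.shape[1] > 0:
        X = np.column_stack([X, surrogate_values])
        names += [f"sv{i + 1}" for i in range(surrogate_values.shape[1])]
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        for j in range(X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(names[j])
        raise ValidationError(f"design matrix rank-deficient; collinear terms: "
                              f"{collinear or names}")


def _residuals_against(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each row of Y (genes) on the columns of X."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


def estimate_surrogate_count(values: np.ndarray, model: CovariateModel,
                             samples: list[SampleRecord],
                             rng: np.random.Generator,
                             n_permutations: int = 20) -> int:
    """Estimate how many latent factors remain after the full model.

    Permutation analogue of the asymptotic spectral approach used in
    surrogate-variable analysis: residualize expression against the full
    model (including sex), take the variance fractions of the residual
    singular spectrum, and compare each rank against the 95th percentile of
    the spectra of row-permuted residual matrices, which destroy any shared
    structure across samples while preserving per-gene variance.  The count
    is the number of leading ranks exceeding their null quantile.
    """
    X, names = _design_matrix(samples, model.full_model_terms, include_sex=True)
    if values.shape[1] <= X.shape[1]:
        raise ValidationError("need more samples than full-model terms")
    _check_full_rank(X, names)

    def residual_spectrum(M: np.ndarray) -> np.ndarray:
        R = _residuals_against(M, X)
        sd = R.std(axis=1, ddof=1)
        R = R[sd > 1e-12] / sd[sd > 1e-12, None]
        s = np.linalg.svd(R, compute_uv=False)
        v = s**2
        return v / v.sum()

    obs = residual_spectrum(values)
    k_model = X.shape[1]  # residual rank deficiency: trailing dims are void
    n_keep = max(1, len(obs) - k_model)
    null = np.empty((n_permutations, len(obs)))
    for b in range(n_permutations):
        # permute each row of the *input* independently, then residualize:
        # under the null any model variance is spread into the permuted rows,
        # so the threshold errs on the conservative side
        idx = np.argsort(rng.random(values.shape), axis=1)
        null[b] = residual_spectrum(np.take_along_axis(values, idx, axis=1))
    # exceeding all B permutation spectra at a rank is an exact rank test of
    # level 1/(B+1) (~5% at the default B=20) under exchangeability
    threshold = null.max(axis=0)
    exceed = obs[:n_keep] > threshold[:n_keep]
    # leading consecutive run: a gap means later excesses are spectral noise
    count = 0
    for e in exceed:
        if not e:
            break
        count += 1
    return count


def surrogate_values(values: np.ndarray, model: CovariateModel,
                     samples: list[SampleRecord], count: int) -> np.ndarray:
    """Right singular vectors of the full-model residual matrix (n x count)."""
    if count == 0:
        return np.zeros((values.shape[1], 0))
    X, _ = _design_matrix(samples, model.full_model_terms, include_sex=True)
    R = _residuals_against(values, X)
    _, _, vt = np.linalg.svd(R, full_matrices=False)
    return vt[:count].T.copy()


def residualize(ds: ExpressionDataset, model: CovariateModel) -> ExpressionDataset:
    """Replace expression by least-squares residuals on the null model.

    The design contains an intercept plus the null-model terms (age, pmi,
    rin, ph, batch dummies, surrogate variables) — never sex.
    """
    X, names = _design_matrix(ds.samples, model.null_model_terms,
                              surrogate_values=model.surrogate_values)
    _check_full_rank(X, names)
    R = _residuals_against(ds.values, X)
    return ds.with_values(
        R, scale="residual", note=f"residualize(terms={','.join(names[1:])})"
    )


# ---------------------------------------------------------------------------
# outlier detection


def detect_outliers(ds: ExpressionDataset, cfg: AnalysisConfig
                    ) -> tuple[list[str], ExpressionDataset]:
    """Flag samples deviating > outlier_z SD on either of the first
    outlier_n_pcs principal components, separately per sex; one-shot.

    A sex with fewer than 4 samples is skipped with a warning.  Returns the
    flagged sample ids and the dataset without them.
    """
    flagged: list[str] = []
    for sex in ("M", "F"):
        idx = [i for i, s in enumerate(ds.samples) if s.sex == sex]
        if len(idx) < 4:
            log.warning("outlier detection skipped for sex %s (<4 samples)", sex)
            continue
        sub = ds.values[:, idx]  # genes x samples of this sex
        centered = sub - sub.mean(axis=1, keepdims=True)
        # PCA over samples: scores are projections onto left singular axes
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        scores = (s[:, None] * vt)[: cfg.outlier_n_pcs]  # pcs x samples
        for pc in range(min(cfg.outlier_n_pcs, scores.shape[0])):
            sc = scores[pc]
            dev = np.abs(sc - sc.mean())
            sd = sc.std(ddof=1)
            if sd == 0:
                continue
            for k in np.flatnonzero(dev > cfg.outlier_z * sd):
                sid = ds.samples[idx[k]].sample_id
                if sid not in flagged:
                    flagged.append(sid)
    keep = np.array([s.sample_id not in flagged for s in ds.samples])
    cleaned = ds.subset_samples(keep, note=f"detect_outliers(removed={len(flagged)})")
    return flagged, cleaned


# ---------------------------------------------------------------------------
# the assembled pipeline


_ORDER = ["filter_rin", "filter_age", "filter_rpkm", "log2", "extract_autosomes",
          "quantile_normalize", "collapse_replicates", "impute_ph",
          "surrogate", "residualize", "detect_outliers"]


def run_pipeline(ds: ExpressionDataset, annotation: dict[str, GeneAnnotation],
                 cfg: AnalysisConfig, *, platform: str = "microarray",
                 rng: np.random.Generator | None = None
                 ) -> tuple[ExpressionDataset, dict]:
    """Run the full preprocessing sequence in its enforced order.

    ``platform`` selects the dialect: ``microarray`` uses the donor-fraction
    RIN rule, log2 with offset 0 and no expression filter; ``rnaseq`` uses
    the stricter per-sample RIN threshold, the RPKM floor filter and log2
    with offset 1.
    """
    if platform not in ("microarray", "rnaseq"):
        raise ValidationError(f"unknown platform {platform!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    report: dict = {"platform": platform}

    rin_mode = "donor_fraction" if platform == "microarray" else "sample_threshold"
    n0 = ds.n_samples
    ds = filter_rin(ds, rin_mode, cfg)
    report["rin_removed_samples"] = n0 - ds.n_samples

    n0, g0 = ds.n_samples, ds.n_genes
    ds = filter_age_and_autosomes(ds, annotation, cfg)
    report["age_removed_samples"] = n0 - ds.n_samples
    report["non_autosomal_genes_removed"] = g0 - ds.n_genes

    if platform == "rnaseq":
        g0 = ds.n_genes
        ds = filter_rpkm(ds, cfg)
        report["rpkm_removed_genes"] = g0 - ds.n_genes

    ds = log2_transform(ds, offset=1.0 if platform == "rnaseq" else 0.0)
    ds = quantile_normalize(ds)
    ds = collapse_replicates(ds)
    if any(s.ph is not None for s in ds.samples):
        ds = impute_ph(ds)

    model = build_covariate_model(ds)
    if cfg.surrogate_count is not None:
        model.surrogate_count = cfg.surrogate_count
    else:
        model.surrogate_count = estimate_surrogate_count(
            ds.values, model, ds.samples, rng
        )
    report["surrogate_count"] = model.surrogate_count
    model.surrogate_values = surrogate_values(
        ds.values, model, ds.samples, model.surrogate_count
    )
    ds = residualize(ds, model)

    flagged, ds = detect_outliers(ds, cfg)
    report["outlier_samples"] = flagged
    report["final_shape"] = (ds.n_genes, ds.n_samples)
    return ds, report
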