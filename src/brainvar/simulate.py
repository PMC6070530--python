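"""Synthetic developmental-brain cohorts with known ground truth.

The generator emulates the structure of a developmental brain expression
atlas: donors spanning 6 post-conceptional weeks to 40 years, several
regional samples per donor (with occasional technical replicates), RIN /
PMI / pH covariates with missing pH, and a gene × sample matrix on a raw
(pre-log) scale so the preprocessing pipeline's own log2 step is exercised.

Planted signal:

* a fraction of genes get their *male* residual noise SD multiplied by
  λ >= 1 (optionally restricted to designated periods/regions) — these are
  the ground-truth "variability genes";
* a standard-normal latent factor per *donor* loads on the variability
  genes and on a designated risk-gene set, scaled so the expected pairwise
  cross-correlation between the two sets in males is ρ*;
* optional batch offsets, age trends, covariate effects and injected
  outlier samples.

Inflated genes are drawn from the lower part of the baseline noise-SD
distribution so their inflated SDs stay inside the cohort-wide SD range;
variance-matched null gene sets therefore have plenty of factor-free
candidates, as the co-expression test requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    DEFAULT_PERIODS,
    GESTATION_DAYS,
    REGION_CODES,
    ExpressionDataset,
    GeneAnnotation,
    RiskLocus,
    SampleRecord,
    ValidationError,
)

_ALL_REGIONS = sorted(REGION_CODES)


@dataclass
class SimulationParams:
    """Cohort and signal parameters; defaults are the study-scale conditions
    used throughout the test suite (desk-scale gene count)."""

    n_donors_per_sex: int = 10
    #: period indices donors are spread over (round-robin per sex) unless
    #: donors_per_period fixes exact counts per sex and period
    periods: list[int] = field(default_factory=lambda: list(range(1, 14)))
    donors_per_period: dict[int, int] | None = None
    regions: list[str] = field(default_factory=lambda: list(_ALL_REGIONS))
    n_genes: int = 2000
    baseline_mean_loc: float = 6.0
    baseline_mean_scale: float = 1.0
    noise_sd_range: tuple[float, float] = (0.4, 1.4)
    #: variability genes are sampled among genes with base SD below this, so
    #: λ-inflated SDs remain inside the overall SD range
    inflated_max_base_sd: float = 0.7
    variability_gene_fraction: float = 0.1
    inflation_lambda: float = 2.0
    inflated_periods: list[int] | None = None   # None -> all periods
    inflated_regions: list[str] | None = None   # None -> all regions
    n_risk_genes: int = 30
    rho_star: float = 0.3
    #: shared expression programs — the structure that makes subjects within
    #: one (cluster, age-bin) stratum resemble each other even after per-gene
    #: covariate residualization, as real regional/developmental programs do
    cluster_effect_sd: float = 1.6   # per-gene offset per regional cluster
    region_effect_sd: float = 0.2    # per-gene offset per region (within cluster)
    age_profile_step_sd: float = 0.25  # per-gene random walk across periods
    age_trend_fraction: float = 0.3
    age_slope_sd: float = 0.5   # expression change over the full age axis
    rin_effect: float = 0.1
    pmi_effect: float = 0.05
    ph_effect: float = 0.1
    n_batches: int = 0
    batch_effect_sd: float = 0.2
    replicate_prob: float = 0.0
    missing_ph_rate: float = 0.1
    n_outliers: int = 0
    outlier_magnitude: float = 8.0
    scale: str = "intensity"  # raw values are 2**log2value
    seed: int = 0

    def __post_init__(self):
        if self.inflation_lambda < 1:
            raise ValidationError("inflation factor must be >= 1")
        if not 0 <= self.rho_star < 1:
            raise ValidationError("rho_star must lie in [0, 1)")
        for name in ("variability_gene_fraction", "replicate_prob",
                     "missing_ph_rate", "age_trend_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        unknown = set(self.regions) - REGION_CODES
        if unknown:
            raise ValidationError(f"unknown region codes: {sorted(unknown)}")


@dataclass
class GroundTruth:
    inflated_genes: list[str]
    inflation_lambda: dict[str, float]
    risk_genes: list[str]
    rho_star: float
    n_batches: int
    outlier_samples: list[str]
    mhc_decoy_gene: str | None = None


def _rng(params: SimulationParams, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, salt]))


def generate_cohort(params: SimulationParams,
                    rng: np.random.Generator | None = None
                    ) -> list[SampleRecord]:
    """Donors with sex, a period-constrained age, and one sample per region
    (plus occasional technical replicates)."""
    if rng is None:
        rng = _rng(params, 1)
    period_bounds = {p.index: (p.lower_days, p.upper_days)
                     for p in DEFAULT_PERIODS}
    assignments: list[tuple[str, int]] = []  # (sex, period)
    if params.donors_per_period is not None:
        for period, count in sorted(params.donors_per_period.items()):
            for sex in ("M", "F"):
                assignments += [(sex, period)] * count
    else:
        for sex in ("M", "F"):
            for i in range(params.n_donors_per_sex):
                assignments.append((sex, params.periods[i % len(params.periods)]))
    samples: list[SampleRecord] = []
    counters = {"M": 0, "F": 0}
    for sex, period in assignments:
        counters[sex] += 1
        donor_id = f"{sex}{counters[sex]:03d}"
        lo, hi = period_bounds[period]
        age = float(rng.uniform(lo, hi))
        rin_donor = float(rng.uniform(7.6, 10.0))
        pmi = float(rng.uniform(5.0, 30.0)) if age > GESTATION_DAYS else None
        ph = float(rng.normal(6.5, 0.25))
        if rng.random() < params.missing_ph_rate:
            ph = None
        batch = (f"b{int(rng.integers(params.n_batches)) + 1}"
                 if params.n_batches > 0 else None)
        for region in params.regions:
            n_rep = 2 if rng.random() < params.replicate_prob else 1
            for r in range(n_rep):
                suffix = f"_r{r + 1}" if n_rep > 1 else ""
                samples.append(
                    SampleRecord(
                        sample_id=f"{donor_id}_{region}{suffix}",
                        donor_id=donor_id,
                        sex=sex,
                        age_days=age,
                        region=region,
                        rin=float(np.clip(rin_donor + rng.normal(0, 0.1), 0, 10)),
                        pmi_hours=pmi,
                        ph=ph,
                        batch=batch,
                    )
                )
    return samples


def _gene_ids(params: SimulationParams) -> list[str]:
    width = len(str(params.n_genes))
    return [f"G{i + 1:0{width}d}" for i in range(params.n_genes)]


def generate_expression(cohort: list[SampleRecord], params: SimulationParams,
                        rng: np.random.Generator | None = None
                        ) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate the matrix on log2 scale, then exponentiate to raw scale."""
    if rng is None:
        rng = _rng(params, 2)
    gene_ids = _gene_ids(params)
    G, S = params.n_genes, len(cohort)
    mu = rng.normal(params.baseline_mean_loc, params.baseline_mean_scale, G)
    sigma = rng.uniform(*params.noise_sd_range, G)

    # planted variability genes: lower part of the SD range (see module doc)
    n_infl = int(round(params.variability_gene_fraction * G))
    low_sd_pool = np.flatnonzero(sigma <= params.inflated_max_base_sd)
    if n_infl > len(low_sd_pool):
        raise ValidationError("not enough low-SD genes to plant inflation")
    inflated_idx = np.sort(rng.choice(low_sd_pool, size=n_infl, replace=False))
    inflated = np.zeros(G, dtype=bool)
    inflated[inflated_idx] = True

    # risk genes: factor-loaded, disjoint from the variability genes
    remaining = np.flatnonzero(~inflated)
    if params.n_risk_genes > len(remaining):
        raise ValidationError(
            f"n_risk_genes={params.n_risk_genes} exceeds the "
            f"{len(remaining)} genes left after planting variability genes"
        )
    risk_idx = np.sort(rng.choice(remaining, size=params.n_risk_genes,
                                  replace=False))
    risk = np.zeros(G, dtype=bool)
    risk[risk_idx] = True

    # latent factor loadings scaled to the *male* noise level so the expected
    # male cross-correlation between loaded gene pairs is rho_star
    lam = params.inflation_lambda
    c = np.sqrt(params.rho_star / (1.0 - params.rho_star))
    sigma_male = np.where(inflated, sigma * lam, sigma)
    loadings = np.where(inflated | risk, c * sigma_male, 0.0)

    trend = np.zeros(G)
    n_trend = int(round(params.age_trend_fraction * G))
    trend_idx = rng.choice(G, size=n_trend, replace=False)
    trend[trend_idx] = rng.normal(0, params.age_slope_sd, n_trend)

    # shared programs: cluster- and region-specific offsets, and a per-gene
    # developmental trajectory (random walk over the 13 periods).  These vary
    # across the dataset but are (near-)constant within one stratum, so they
    # survive residualization and give subjects a positive baseline
    # similarity for the sex-specific noise inflation to dilute.
    from .types import DEFAULT_CLUSTERS as _CL

    region_cluster = {r: c.cluster_id for c in _CL for r in c.member_regions}
    clusters_present = sorted({region_cluster[r] for r in params.regions})
    cluster_offsets = {
        c: rng.normal(0, params.cluster_effect_sd, G) for c in clusters_present
    }
    region_offsets = {
        r: rng.normal(0, params.region_effect_sd, G)
        for r in sorted(set(params.regions))
    }
    n_periods = len(DEFAULT_PERIODS)
    steps = rng.normal(0, params.age_profile_step_sd, (G, n_periods))
    period_profile = np.cumsum(steps, axis=1)  # column p-1: profile in period p

    beta_rin = rng.normal(0, params.rin_effect, G)
    beta_pmi = rng.normal(0, params.pmi_effect, G)
    beta_ph = rng.normal(0, params.ph_effect, G)
    batch_levels = sorted({s.batch for s in cohort if s.batch is not None})
    batch_offsets = {
        b: rng.normal(0, params.batch_effect_sd, G) for b in batch_levels
    }

    donors = sorted({s.donor_id for s in cohort})
    factor = {d: float(rng.normal()) for d in donors}

    age_lo = DEFAULT_PERIODS.periods[0].lower_days
    age_hi = DEFAULT_PERIODS.periods[-1].upper_days
    inflamed_periods = (set(params.inflated_periods)
                        if params.inflated_periods is not None else None)
    inflamed_regions = (set(params.inflated_regions)
                        if params.inflated_regions is not None else None)
    period_of = DEFAULT_PERIODS.period_of

    log_values = np.empty((G, S))
    for j, s in enumerate(cohort):
        age_frac = (s.age_days - age_lo) / (age_hi - age_lo)
        col = mu + trend * age_frac
        col = col + cluster_offsets[region_cluster[s.region]]
        col = col + region_offsets[s.region]
        col = col + period_profile[:, period_of(s.age_days) - 1]
        col = col + beta_rin * (s.rin - 8.5)
        if s.pmi_hours is not None:
            col = col + beta_pmi * (s.pmi_hours - 17.5) / 10.0
        if s.ph is not None:
            col = col + beta_ph * (s.ph - 6.5)
        if s.batch is not None:
            col = col + batch_offsets[s.batch]
        col = col + factor[s.donor_id] * loadings
        in_scope = ((inflamed_periods is None or period_of(s.age_days) in inflamed_periods)
                    and (inflamed_regions is None or s.region in inflamed_regions))
        noise_sd = np.where(inflated & (s.sex == "M") & in_scope,
                            sigma * lam, sigma)
        col = col + rng.normal(0, 1, G) * noise_sd
        log_values[:, j] = col

    outlier_ids: list[str] = []
    if params.n_outliers > 0:
        which = rng.choice(S, size=min(params.n_outliers, S), replace=False)
        direction = rng.normal(0, 1, G)
        direction /= np.linalg.norm(direction) / np.sqrt(G)
        for j in which:
            log_values[:, j] += params.outlier_magnitude * sigma * direction
            outlier_ids.append(cohort[j].sample_id)

    if params.scale == "intensity":
        raw = np.power(2.0, log_values)
    elif params.scale == "rpkm":
        raw = np.maximum(np.power(2.0, log_values) - 1.0, 0.0)
    else:
        raise ValidationError(f"unknown scale {params.scale!r}")

    ds = ExpressionDataset(values=raw, gene_ids=gene_ids,
                           samples=list(cohort), scale=params.scale)
    truth = GroundTruth(
        inflated_genes=[gene_ids[i] for i in inflated_idx],
        inflation_lambda={gene_ids[i]: lam for i in inflated_idx},
        risk_genes=[gene_ids[i] for i in risk_idx],
        rho_star=params.rho_star,
        n_batches=params.n_batches,
        outlier_samples=outlier_ids,
    )
    return ds, truth


_GENE_SPACING = 100_000
_GENE_LENGTH = 20_000
_LOCUS_HALF_WIDTH = 120_000


def generate_annotation(params: SimulationParams, truth: GroundTruth,
                        rng: np.random.Generator | None = None,
                        mhc: tuple[str, int, int] = ("6", 25_000_000, 34_000_000),
                        include_mhc_decoy: bool = True,
                        include_duplicate_locus: bool = True):
    """Toy genome, risk loci and a variant-density track.

    Genes are placed non-overlapping on chromosomes 1 and 2 (100 kb
    spacing); each ground-truth risk gene receives a locus wide enough to
    harbour neighbours, with the index variant inside the gene body so the
    closest-gene rule recovers the planted set exactly.  Optionally a decoy
    locus/gene inside an MHC-like exclusion window on chromosome 6 and a
    duplicated locus mapping to an already-used gene are added.  The density
    track is uniform (constant count per 100 kb window) on every chromosome.

    Returns (annotation dict, loci list, density DataFrame).
    """
    import pandas as pd

    if rng is None:
        rng = _rng(params, 3)
    gene_ids = _gene_ids(params)
    annotation: dict[str, GeneAnnotation] = {}
    for i, g in enumerate(gene_ids):
        chrom = "1" if i % 2 == 0 else "2"
        slot = i // 2
        start = 1_000_000 + slot * _GENE_SPACING
        annotation[g] = GeneAnnotation(
            gene_id=g, symbol=g, chromosome=chrom,
            start=start, end=start + _GENE_LENGTH - 1,
        )

    loci: list[RiskLocus] = []
    for k, g in enumerate(truth.risk_genes):
        ann = annotation[g]
        start = max(1, ann.start - _LOCUS_HALF_WIDTH)
        end = ann.end + _LOCUS_HALF_WIDTH
        pos = (ann.start + ann.end) // 2  # inside the gene body: distance 0
        candidates = tuple(
            x for x, a in annotation.items()
            if a.chromosome == ann.chromosome and a.start <= end and a.end >= start
        )
        loci.append(
            RiskLocus(
                locus_id=f"L{k + 1:03d}",
                chromosome=ann.chromosome,
                start=start, end=end,
                index_variants=((pos, float(10.0 ** rng.uniform(-15, -8))),),
                candidate_gene_ids=candidates,
            )
        )

    if include_duplicate_locus and truth.risk_genes:
        ann = annotation[truth.risk_genes[0]]
        loci.append(
            RiskLocus(
                locus_id="Ldup",
                chromosome=ann.chromosome,
                start=max(1, ann.start - _LOCUS_HALF_WIDTH // 2),
                end=ann.end + _LOCUS_HALF_WIDTH // 2,
                index_variants=((ann.start + 10, 1e-9),),
                candidate_gene_ids=(truth.risk_genes[0],),
            )
        )

    if include_mhc_decoy:
        chrom, lo, hi = mhc
        mid = (lo + hi) // 2
        decoy = GeneAnnotation(gene_id="MHCDECOY", symbol="MHCDECOY",
                               chromosome=chrom, start=mid,
                               end=mid + _GENE_LENGTH - 1)
        annotation[decoy.gene_id] = decoy
        loci.append(
            RiskLocus(
                locus_id="Lmhc", chromosome=chrom,
                start=decoy.start - _LOCUS_HALF_WIDTH,
                end=decoy.end + _LOCUS_HALF_WIDTH,
                index_variants=((decoy.start + 5, 1e-10),),
                candidate_gene_ids=(decoy.gene_id,),
            )
        )
        truth.mhc_decoy_gene = decoy.gene_id

    rows = []
    window = 100_000
    for chrom in sorted({a.chromosome for a in annotation.values()}):
        span_end = max(a.end for a in annotation.values()
                       if a.chromosome == chrom) + 2 * _LOCUS_HALF_WIDTH
        for w0 in range(1, span_end, window):
            rows.append({"chromosome": chrom, "start": w0,
                         "end": w0 + window - 1, "count": 100})
    density = pd.DataFrame(rows)
    return annotation, loci, density


#: cortical regions (clusters 1 and 2) sampled for every donor in the
#: desk-scale study design
STUDY_REGIONS = ["DFC", "MFC", "VFC", "OFC", "M1C", "S1C",
                 "V1C", "STC", "IPC", "ITC", "A1C"]


def study_params(seed: int, **overrides) -> SimulationParams:
    """The desk-scale study design used by the validation harnesses.

    Ten donors per sex concentrated in mid-development (periods 8 and 9,
    i.e. 4 months to 2 years), each sampled in the 11 cortical regions of
    regional clusters 1 and 2, with 1000 genes.  Signal parameters (λ, ρ*,
    inflated fraction) keep the SimulationParams defaults unless overridden.
    """
    kwargs = dict(
        donors_per_period={8: 5, 9: 5},
        regions=list(STUDY_REGIONS),
        n_genes=1000,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationParams(**kwargs)


def simulate_study(params: SimulationParams):
    """Cohort + expression + annotation/loci/density in one call.

    Returns (dataset, truth, annotation, loci, density).  Deterministic for
    a given ``params`` (including its seed).
    """
    cohort = generate_cohort(params)
    ds, truth = generate_expression(cohort, params)
    annotation, loci, density = generate_annotation(params, truth)
    import dataclasses as _dc

    ds = _dc.replace(ds, annotation=annotation)
    return ds, truth, annotation, loci, density
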