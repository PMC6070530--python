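"""Analysis configuration: every fixed constant of the pipeline in one place."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .types import ValidationError


@dataclass
class AnalysisConfig:
    """All tunable constants of the analysis.

    Resampling counts follow the published procedure (100 point resamples,
    1000 permutations / null sets); quality filters mirror the study's
    boundary semantics exactly: donors are dropped when *more than* 25% of
    their samples have RIN < 7.5, sample-level filtering removes RIN <= 7.5,
    subjects strictly older than 40 years are removed, and RNA-seq genes are
    removed when below 1 RPKM in *more than* 50% of male or of female
    samples.
    """

    seed: int = 0
    n_point_resamples: int = 100
    n_null_resamples: int = 1000
    #: inner resample count used when re-scoring the statistic inside each
    #: permutation of the sex-difference null; None means n_point_resamples.
    n_null_inner_resamples: int | None = None
    #: inner draw count for scoring each variance-matched null gene set in
    #: the co-expression test (reduced for tractability; set equal to
    #: n_point_resamples to match the observed statistic exactly).
    n_coexpr_null_inner: int = 10
    top_k: int = 100
    sd_match_tolerance: float = 0.05
    rin_min: float = 7.5
    donor_rin_bad_fraction: float = 0.25
    max_age_years: float = 40.0
    rpkm_min: float = 1.0
    rpkm_bad_fraction: float = 0.5
    outlier_z: float = 3.0
    outlier_n_pcs: int = 2
    bin_width_periods: int = 3
    fine_window_n_ages: int = 4
    locus_density_tolerance: float = 0.10
    locus_extension_bp: int = 20_000
    #: MHC exclusion region (GRCh37 convention), overridable.
    mhc_chromosome: str = "6"
    mhc_start: int = 25_000_000
    mhc_end: int = 34_000_000
    min_donors_per_sex: int = 2
    #: regional clusters entering the co-expression FWER family; with the two
    #: cortical clusters and 11 bins each this gives m = 22 tests.
    tested_clusters_for_fwer: list[int] = field(default_factory=lambda: [1, 2])
    #: surrogate-variable count override; None -> estimate from the data.
    surrogate_count: int | None = None
    max_resample_retries: int = 10

    def __post_init__(self):
        for name in ("n_point_resamples", "n_null_resamples", "top_k",
                     "bin_width_periods", "fine_window_n_ages",
                     "min_donors_per_sex", "n_coexpr_null_inner"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        for name in ("sd_match_tolerance", "rpkm_bad_fraction",
                     "donor_rin_bad_fraction", "locus_density_tolerance"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")

    @property
    def mhc_region(self) -> tuple[str, int, int]:
        return (self.mhc_chromosome, self.mhc_start, self.mhc_end)

    @property
    def null_inner(self) -> int:
        return self.n_null_inner_resamples or self.n_point_resamples

    @property
    def max_age_days(self) -> float:
        from .types import normalize_age

        return normalize_age(self.max_age_years, "years")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
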