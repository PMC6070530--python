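"""Domain types shared by every analysis stage.

The central container is :class:`ExpressionDataset`: a gene × sample matrix
of expression values together with sample metadata, optional gene annotation,
and a log of the transforms applied so far.  Ages are stored on a single
monotone axis of days post-conception; postnatal ages are offset by 280 days
(40 gestational weeks), so the cohort axis runs from the 6th
post-conceptional week (42 days) to 40 years (14 890 days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

ALLOWED_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])
AUTOSOMES = frozenset(str(i) for i in range(1, 23))

#: The 16 brain-region codes of the developmental atlas.
REGION_CODES = frozenset(
    [
        "V1C", "ITC", "IPC", "A1C", "STC",          # occipito-temporal / parietal
        "M1C", "S1C", "VFC", "MFC", "DFC", "OFC",   # prefrontal & motor-somatosensory
        "STR", "HIP", "AMY",                        # subcortical
        "MD", "CBC",                                # thalamus & cerebellum
    ]
)

#: Days from conception to birth (40 gestational weeks).
GESTATION_DAYS = 280.0
DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25


class ValidationError(ValueError):
    """An input table violates a structural constraint."""


class StateError(RuntimeError):
    """An operation was applied to data in the wrong pipeline state."""


def normalize_age(value: float, unit: str) -> float:
    """Convert an age to days post-conception.

    ``pcw`` is weeks post-conception; ``days``/``months``/``years`` are
    postnatal and offset by 280 days of gestation.
    """
    if not value > 0:
        raise ValidationError(f"age value must be positive, got {value}")
    if unit == "pcw":
        return value * 7.0
    if unit == "days":
        return GESTATION_DAYS + value
    if unit == "months":
        return GESTATION_DAYS + value * DAYS_PER_MONTH
    if unit == "years":
        return GESTATION_DAYS + value * DAYS_PER_YEAR
    raise ValidationError(f"unknown age unit {unit!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic location of one gene (1-based, inclusive coordinates)."""

    gene_id: str
    symbol: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.chromosome not in ALLOWED_CHROMOSOMES:
            raise ValidationError(
                f"{self.gene_id}: chromosome {self.chromosome!r} not allowed"
            )
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start > end")

    @property
    def autosomal(self) -> bool:
        return self.chromosome in AUTOSOMES


@dataclass(frozen=True)
class SampleRecord:
    """One tissue sample: donor, sex, age, region and quality covariates.

    ``pmi_hours`` (post-mortem interval), ``ph`` and ``batch`` may be missing
    (``None``); sex, age, region and RIN may not.
    """

    sample_id: str
    donor_id: str
    sex: str
    age_days: float
    region: str
    rin: float
    pmi_hours: float | None = None
    ph: float | None = None
    batch: str | None = None

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValidationError(f"{self.sample_id}: sex must be M or F")
        if self.region not in REGION_CODES:
            raise ValidationError(
                f"{self.sample_id}: unknown region code {self.region!r}"
            )
        if not self.age_days > 0:
            raise ValidationError(f"{self.sample_id}: age_days must be positive")
        if not (0 <= self.rin <= 10):
            raise ValidationError(f"{self.sample_id}: rin outside [0, 10]")


@dataclass
class ExpressionDataset:
    """Gene × sample expression matrix with metadata and a transform log."""

    values: np.ndarray
    gene_ids: list[str]
    samples: list[SampleRecord]
    scale: str = "raw"
    annotation: dict[str, GeneAnnotation] | None = None
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_id in dataset")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in dataset")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def _gene_pos(self) -> dict[str, int]:
        # lazy cache; fresh instances are created by every subset/transform,
        # so the cache cannot go stale
        cache = self.__dict__.get("_gene_pos_cache")
        if cache is None:
            cache = {g: i for i, g in enumerate(self.gene_ids)}
            self.__dict__["_gene_pos_cache"] = cache
        return cache

    @property
    def _sample_pos(self) -> dict[str, int]:
        cache = self.__dict__.get("_sample_pos_cache")
        if cache is None:
            cache = {s.sample_id: i for i, s in enumerate(self.samples)}
            self.__dict__["_sample_pos_cache"] = cache
        return cache

    def gene_index(self, gene_ids) -> np.ndarray:
        pos = self._gene_pos
        return np.array([pos[g] for g in gene_ids], dtype=int)

    def sample_index(self, sample_ids) -> np.ndarray:
        pos = self._sample_pos
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def subset_genes(self, keep: np.ndarray, note: str | None = None) -> "ExpressionDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ds = replace(
            self,
            values=self.values[keep, :].copy(),
            gene_ids=[self.gene_ids[i] for i in keep],
            transform_log=list(self.transform_log) + ([note] if note else []),
        )
        return ds

    def subset_samples(self, keep: np.ndarray, note: str | None = None) -> "ExpressionDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ds = replace(
            self,
            values=self.values[:, keep].copy(),
            samples=[self.samples[i] for i in keep],
            transform_log=list(self.transform_log) + ([note] if note else []),
        )
        return ds

    def with_values(self, values: np.ndarray, scale: str, note: str) -> "ExpressionDataset":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            scale=scale,
            transform_log=list(self.transform_log) + [note],
        )


@dataclass(frozen=True)
class AgePeriod:
    index: int
    lower_days: float  # inclusive
    upper_days: float  # exclusive


class AgePeriodTable:
    """Contiguous, strictly ascending developmental periods.

    Every sample age maps to exactly one period; age-bins are sliding windows
    of ``w`` consecutive periods (13 periods with w = 3 give 11 bins).
    """

    def __init__(self, periods: list[AgePeriod]):
        periods = sorted(periods, key=lambda p: p.index)
        if [p.index for p in periods] != list(range(1, len(periods) + 1)):
            raise ValidationError("period indices must be 1..P without gaps")
        for a, b in zip(periods, periods[1:]):
            if not math.isclose(a.upper_days, b.lower_days):
                raise ValidationError(
                    f"periods {a.index} and {b.index} are not contiguous"
                )
        for p in periods:
            if not p.lower_days < p.upper_days:
                raise ValidationError(f"period {p.index}: empty interval")
        self.periods = periods

    def __len__(self) -> int:
        return len(self.periods)

    def __iter__(self):
        return iter(self.periods)

    def period_of(self, age_days: float) -> int:
        for p in self.periods:
            if p.lower_days <= age_days < p.upper_days:
                return p.index
        raise ValidationError(
            f"age {age_days} days outside the period table "
            f"[{self.periods[0].lower_days}, {self.periods[-1].upper_days})"
        )

    def bins(self, width: int = 3) -> list["AgeBin"]:
        n = len(self.periods)
        if width < 1 or width > n:
            raise ValidationError("bin width outside [1, n_periods]")
        return [
            AgeBin(bin_index=i, member_periods=frozenset(range(i, i + width)))
            for i in range(1, n - width + 2)
        ]


@dataclass(frozen=True)
class AgeBin:
    bin_index: int
    member_periods: frozenset[int]

    def __post_init__(self):
        idx = sorted(self.member_periods)
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValidationError("member periods must be consecutive")


#: Default 13-period table (synthetic stand-in modelled on the BrainSpan
#: scheme; the exact published boundaries live in the study supplements and
#: can be supplied as a TSV instead).  Lower bounds inclusive, upper
#: exclusive, in days post-conception.
DEFAULT_PERIODS = AgePeriodTable(
    [
        AgePeriod(1, 42.0, 63.0),        # 6-9 pcw
        AgePeriod(2, 63.0, 77.0),        # 9-11 pcw
        AgePeriod(3, 77.0, 91.0),        # 11-13 pcw
        AgePeriod(4, 91.0, 112.0),       # 13-16 pcw
        AgePeriod(5, 112.0, 182.0),      # 16-26 pcw
        AgePeriod(6, 182.0, 280.0),      # 26 pcw - birth
        AgePeriod(7, 280.0, 402.0),      # birth - 4 months
        AgePeriod(8, 402.0, 584.0),      # 4 - 10 months
        AgePeriod(9, 584.0, 1011.0),     # 10 months - 2 years
        AgePeriod(10, 1011.0, 1741.0),   # 2 - 4 years
        AgePeriod(11, 1741.0, 4298.0),   # 4 - 11 years
        AgePeriod(12, 4298.0, 7220.0),   # 11 - 19 years
        AgePeriod(13, 7220.0, 14891.0),  # 19 - 40 years (40 y inclusive)
    ]
)


@dataclass(frozen=True)
class RegionalCluster:
    cluster_id: int
    label: str
    member_regions: frozenset[str]


#: The four regional clusters of the 16 codes (fetal-expression clustering).
DEFAULT_CLUSTERS = (
    RegionalCluster(1, "V1C-STC", frozenset({"V1C", "ITC", "IPC", "A1C", "STC"})),
    RegionalCluster(2, "PFC-MSC", frozenset({"M1C", "S1C", "VFC", "MFC", "DFC", "OFC"})),
    RegionalCluster(3, "STR-HIP-AMY", frozenset({"STR", "HIP", "AMY"})),
    RegionalCluster(4, "MD-CBC", frozenset({"MD", "CBC"})),
)


def _check_cluster_partition(clusters=DEFAULT_CLUSTERS):
    seen: set[str] = set()
    for c in clusters:
        if seen & c.member_regions:
            raise ValidationError("regional clusters overlap")
        seen |= c.member_regions
    if seen != REGION_CODES:
        raise ValidationError("regional clusters do not cover all 16 codes")


_check_cluster_partition()


@dataclass(frozen=True)
class RiskLocus:
    """A GWAS susceptibility locus with its index variant(s).

    ``index_variants`` is a list of (position_bp, association_p) sorted by
    p-value ascending; ``candidate_gene_ids`` lists the genes attributed to
    the locus.
    """

    locus_id: str
    chromosome: str
    start: int
    end: int
    index_variants: tuple[tuple[int, float], ...]
    candidate_gene_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.index_variants) < 1:
            raise ValidationError(f"locus {self.locus_id}: no index variants")
        if self.start > self.end:
            raise ValidationError(f"locus {self.locus_id}: start > end")
        object.__setattr__(
            self,
            "index_variants",
            tuple(sorted(self.index_variants, key=lambda v: (v[1], v[0]))),
        )

    @property
    def top_variant(self) -> tuple[int, float]:
        return self.index_variants[0]
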