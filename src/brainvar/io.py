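"""Readers and writers for the plain-text table formats the pipeline uses.

Everything is TSV.  Expression matrices have genes as rows (first column
``gene_id``, remaining columns one per sample); metadata, annotation, loci
and variant-density tables carry one record per row; gene lists are one id
per line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .types import (
    AgePeriod,
    AgePeriodTable,
    ExpressionDataset,
    GeneAnnotation,
    RegionalCluster,
    RiskLocus,
    SampleRecord,
    ValidationError,
    normalize_age,
)

log = logging.getLogger(__name__)


def read_expression_matrix(path, scale_label: str = "raw") -> ExpressionDataset:
    """Parse a genes × samples TSV into an :class:`ExpressionDataset`.

    Gene order is preserved; duplicate gene or sample ids and non-numeric or
    missing cells are rejected.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for sid in header:  # pandas would silently mangle duplicate columns
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample_id {sid!r} in header")
        seen.add(sid)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, index_col=0,
                     float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"{path}: non-numeric cell at gene {df.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
        raise
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ValidationError(
            f"{path}: missing cell at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    samples = [
        # placeholder metadata; attach_metadata replaces these records
        SampleRecord(sample_id=c, donor_id=c, sex="M", age_days=1.0,
                     region="DFC", rin=10.0)
        for c in df.columns
    ]
    return ExpressionDataset(
        values=values,
        gene_ids=list(df.index),
        samples=samples,
        scale=scale_label,
    )


def write_expression_matrix(ds: ExpressionDataset, path) -> None:
    df = pd.DataFrame(ds.values, index=pd.Index(ds.gene_ids, name="gene_id"),
                      columns=ds.sample_ids)
    # %.17g preserves float64 exactly, so write -> read is lossless
    df.to_csv(path, sep="\t", float_format="%.17g")


_AGE_UNITS = ("pcw", "days", "months", "years")


def read_sample_metadata(path) -> list[SampleRecord]:
    """Read the sample table; ages are normalised to days post-conception."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "donor_id", "sex", "age_value", "age_unit",
                "region", "rin"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        unit = row["age_unit"]
        if unit not in _AGE_UNITS:
            raise ValidationError(
                f"{path}: sample {row['sample_id']}: unknown age_unit {unit!r}"
            )
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                donor_id=row["donor_id"],
                sex=row["sex"],
                age_days=normalize_age(float(row["age_value"]), unit),
                region=row["region"],
                rin=float(row["rin"]),
                pmi_hours=_opt_float(row.get("pmi_hours", "")),
                ph=_opt_float(row.get("ph", "")),
                batch=row.get("batch", "") or None,
            )
        )
    return records


def _opt_float(text) -> float | None:
    text = (text or "").strip()
    return float(text) if text else None


def write_sample_metadata(samples: list[SampleRecord], path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "donor_id": s.donor_id,
                "sex": s.sex,
                # pcw spans pre- and postnatal ages alike and round-trips
                # exactly through normalize_age (value * 7)
                "age_value": repr(s.age_days / 7.0),
                "age_unit": "pcw",
                "region": s.region,
                "rin": s.rin,
                "pmi_hours": "" if s.pmi_hours is None else s.pmi_hours,
                "ph": "" if s.ph is None else s.ph,
                "batch": s.batch or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def attach_metadata(ds: ExpressionDataset, samples: list[SampleRecord]) -> ExpressionDataset:
    """Replace the dataset's placeholder sample records, matched by id."""
    by_id = {s.sample_id: s for s in samples}
    missing = [sid for sid in ds.sample_ids if sid not in by_id]
    if missing:
        raise ValidationError(f"metadata missing for samples: {missing[:5]}")
    return dataclasses.replace(ds, samples=[by_id[sid] for sid in ds.sample_ids])


def read_gene_annotation(path) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    table: dict[str, GeneAnnotation] = {}
    for _, row in df.iterrows():
        g = GeneAnnotation(
            gene_id=str(row["gene_id"]),
            symbol=str(row.get("symbol", row["gene_id"])),
            chromosome=str(row["chromosome"]),
            start=int(row["start"]),
            end=int(row["end"]),
        )
        if g.gene_id in table:
            raise ValidationError(f"{path}: duplicate gene_id {g.gene_id!r}")
        table[g.gene_id] = g
    return table


def write_gene_annotation(table: dict[str, GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        [
            {"gene_id": g.gene_id, "symbol": g.symbol, "chromosome": g.chromosome,
             "start": g.start, "end": g.end}
            for g in table.values()
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_risk_loci(path) -> list[RiskLocus]:
    """Read a locus table with one row per index variant.

    Columns: locus_id, chromosome, start, end, variant_pos, variant_p,
    candidate_gene_ids (comma-separated).  Rows sharing a locus_id are merged
    into one locus whose variants are sorted by p ascending.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "locus_id": str})
    if df.empty:
        log.warning("%s: empty risk-locus table", path)
        return []
    loci = []
    for locus_id, grp in df.groupby("locus_id", sort=False):
        first = grp.iloc[0]
        variants = tuple(
            (int(r["variant_pos"]), float(r["variant_p"])) for _, r in grp.iterrows()
        )
        genes: list[str] = []
        for _, r in grp.iterrows():
            for g in str(r.get("candidate_gene_ids", "")).split(","):
                g = g.strip()
                if g and g not in genes:
                    genes.append(g)
        loci.append(
            RiskLocus(
                locus_id=str(locus_id),
                chromosome=str(first["chromosome"]),
                start=int(first["start"]),
                end=int(first["end"]),
                index_variants=variants,
                candidate_gene_ids=tuple(genes),
            )
        )
    return loci


def write_risk_loci(loci: list[RiskLocus], path) -> None:
    rows = []
    for lc in loci:
        for pos, p in lc.index_variants:
            rows.append(
                {"locus_id": lc.locus_id, "chromosome": lc.chromosome,
                 "start": lc.start, "end": lc.end, "variant_pos": pos,
                 "variant_p": p,
                 "candidate_gene_ids": ",".join(lc.candidate_gene_ids)}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_period_table(path) -> AgePeriodTable:
    df = pd.read_csv(path, sep="\t")
    return AgePeriodTable(
        [AgePeriod(int(r["index"]), float(r["lower_days"]), float(r["upper_days"]))
         for _, r in df.iterrows()]
    )


def write_period_table(table: AgePeriodTable, path) -> None:
    pd.DataFrame(
        [{"index": p.index, "lower_days": p.lower_days, "upper_days": p.upper_days}
         for p in table]
    ).to_csv(path, sep="\t", index=False)


def read_clusters(path) -> tuple[RegionalCluster, ...]:
    df = pd.read_csv(path, sep="\t")
    clusters = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        clusters.append(
            RegionalCluster(
                cluster_id=int(cid),
                label=str(grp.iloc[0].get("label", str(cid))),
                member_regions=frozenset(grp["region"]),
            )
        )
    return tuple(clusters)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blanks skipped, duplicates collapsed in order."""
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        g = line.strip()
        if g and g not in seen:
            out.append(g)
            seen.add(g)
    return out


def read_variant_density(path) -> pd.DataFrame:
    """Per-window common-variant counts: chromosome, start, end, count."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    need = {"chromosome", "start", "end", "count"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: density table needs columns {sorted(need)}")
    return df


def write_results(results, path, *, config: AnalysisConfig | None = None,
                  seed: int | None = None,
                  transform_log: list[str] | None = None) -> None:
    """Write a result table as TSV plus a JSON run manifest alongside it.

    ``results`` may be a DataFrame, a list of dataclasses, or a list of
    dicts.  The manifest (same stem, ``.manifest.json``) echoes the config,
    the seed, package and library versions, and the transform log, so a run
    can be reproduced byte-for-byte.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in results
        ]
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    from . import __version__

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "seed": seed,
        "config": dataclasses.asdict(config) if config else None,
        "transform_log": transform_log,
        "table": path.name,
        "n_rows": int(len(df)),
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n"
    )
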