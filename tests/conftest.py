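"""Shared fixtures: hand-built tiny datasets and a seeded synthetic study."""

import logging

import numpy as np
import pytest

from brainvar.config import AnalysisConfig
from brainvar.preprocess import run_pipeline
from brainvar.similarity import Stratum, build_strata
from brainvar.simulate import study_params, simulate_study
from brainvar.types import (
    DEFAULT_CLUSTERS,
    DEFAULT_PERIODS,
    ExpressionDataset,
    SampleRecord,
)

logging.getLogger("brainvar").setLevel(logging.ERROR)


def make_samples(spec):
    """spec: list of (sample_id, donor_id, sex, age_days, region) or full
    tuples with rin/pmi/ph appended."""
    out = []
    for row in spec:
        sid, did, sex, age, region = row[:5]
        rin = row[5] if len(row) > 5 else 9.0
        pmi = row[6] if len(row) > 6 else 10.0
        ph = row[7] if len(row) > 7 else 6.5
        out.append(SampleRecord(sample_id=sid, donor_id=did, sex=sex,
                                age_days=float(age), region=region,
                                rin=float(rin), pmi_hours=pmi, ph=ph))
    return out


def make_dataset(values, samples, gene_ids=None, scale="residual"):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
    return ExpressionDataset(values=values, gene_ids=gene_ids,
                             samples=samples, scale=scale)


def make_stratum(ds, cluster_id=1, bin_index=1):
    donor_samples, donor_sex = {}, {}
    for s in ds.samples:
        donor_samples.setdefault(s.donor_id, []).append(s.sample_id)
        donor_sex[s.donor_id] = s.sex
    for d in donor_samples:
        donor_samples[d].sort()
    return Stratum(cluster_id=cluster_id, bin_index=bin_index,
                   sample_ids=ds.sample_ids, donor_samples=donor_samples,
                   donor_sex=donor_sex)


@pytest.fixture
def tiny_cohort_ds():
    """4 male + 4 female donors, 2 regions each, 12 genes of iid noise."""
    rng = np.random.default_rng(42)
    spec = []
    for sex, n in (("M", 4), ("F", 4)):
        for i in range(n):
            d = f"{sex}{i}"
            for region in ("DFC", "MFC"):
                spec.append((f"{d}_{region}", d, sex, 700.0 + i, region))
    samples = make_samples(spec)
    values = rng.normal(0, 1, (12, len(samples)))
    return make_dataset(values, samples)


@pytest.fixture(scope="session")
def study():
    """One seeded synthetic study (desk scale) shared across unit tests."""
    params = study_params(seed=11, n_genes=500)
    ds, truth, annotation, loci, density = simulate_study(params)
    return {"params": params, "ds": ds, "truth": truth,
            "annotation": annotation, "loci": loci, "density": density}


@pytest.fixture(scope="session")
def processed_study(study):
    cfg = AnalysisConfig(n_point_resamples=20, n_null_resamples=100,
                         surrogate_count=0, seed=11)
    proc, report = run_pipeline(study["ds"], study["annotation"], cfg,
                                rng=np.random.default_rng(11))
    strata = build_strata(proc, DEFAULT_PERIODS, DEFAULT_CLUSTERS, cfg)
    return {"cfg": cfg, "proc": proc, "report": report, "strata": strata}
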