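"""Independent brute-force re-implementation of the resampling statistics.

Plain loops only, no code shared with the package.  Follows the documented
random-stream contract: substreams are SeedSequence([seed, *keys]) with
string keys hashed by CRC32; within a draw the stream is consumed as
(stage 1) one uniform array over donors in sorted order, (stage 2) a
bootstrap integers() call per sex in M, F order, (stage 3) a choice()
without replacement on the larger sex.
"""

import math
import statistics
import zlib

import numpy as np

MASK = (1 << 31) - 1


def oracle_substream(seed, *keys):
    entropy = [int(seed) & MASK]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode("utf-8")) & MASK)
        else:
            entropy.append(int(k) & MASK)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def oracle_draw(donor_samples, donor_sex, rng, max_retries, sexes=("M", "F")):
    """donor_samples: dict donor -> sorted sample list; returns
    {sex: [(donor, sample), ...]} or None if retries exhausted."""
    donors = sorted(d for d in donor_samples if donor_sex[d] in sexes)
    for _ in range(max_retries):
        u = rng.random(len(donors))
        chosen = {}
        for i, d in enumerate(donors):
            samples = sorted(donor_samples[d])
            chosen[d] = samples[int(u[i] * len(samples))]
        unique = {}
        for sex in sexes:
            sd = sorted(d for d in donors if donor_sex[d] == sex)
            if not sd:
                unique[sex] = []
                continue
            boot = rng.integers(len(sd), size=len(sd))
            unique[sex] = sorted({sd[int(i)] for i in boot})
        if any(len(unique[sex]) < 2 for sex in sexes):
            continue
        if len(sexes) == 2:
            n_min = min(len(unique[s]) for s in sexes)
            for sex in sexes:
                if len(unique[sex]) > n_min:
                    pick = rng.choice(len(unique[sex]), size=n_min, replace=False)
                    unique[sex] = [unique[sex][i] for i in sorted(pick)]
        return {sex: [(d, chosen[d]) for d in unique[sex]] for sex in sexes}
    return None


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def mean_pairwise(columns):
    """columns: list of per-subject value lists (same gene order)."""
    vals = []
    for i in range(len(columns)):
        for j in range(i + 1, len(columns)):
            vals.append(pearson(columns[i], columns[j]))
    return sum(vals) / len(vals)


def column_of(values, gene_ids, sample_ids, sid, genes=None):
    j = sample_ids.index(sid)
    rows = range(len(gene_ids)) if genes is None else \
        [gene_ids.index(g) for g in genes]
    return [values[i][j] for i in rows]


def oracle_estimate_similarity(values, gene_ids, sample_ids, donor_samples,
                               donor_sex, cluster_id, bin_index, seed,
                               n_resamples, max_retries, stream_tag=0):
    """Per-sex similarity estimates and 95% CIs, as plain loops."""
    per_sex = {"M": [], "F": []}
    for r in range(n_resamples):
        rng = oracle_substream(seed, cluster_id, bin_index, stream_tag, r)
        picked = oracle_draw(donor_samples, donor_sex, rng, max_retries)
        if picked is None:
            continue
        for sex in ("M", "F"):
            cols = [column_of(values, gene_ids, sample_ids, sid)
                    for _, sid in picked[sex]]
            per_sex[sex].append(mean_pairwise(cols))
    out = {}
    for sex in ("M", "F"):
        est = per_sex[sex]
        out[sex] = {
            "estimate": sum(est) / len(est),
            "ci_low": float(np.percentile(est, 2.5)),
            "ci_high": float(np.percentile(est, 97.5)),
            "draws": est,
        }
    return out


def oracle_resampled_sd(values, gene_ids, sample_ids, donor_samples,
                        donor_sex, cluster_id, bin_index, seed,
                        n_resamples, max_retries, stream_tag=2):
    """Resample-averaged per-gene SD per sex (ddof=1), as plain loops."""
    sums = {"M": [0.0] * len(gene_ids), "F": [0.0] * len(gene_ids)}
    counts = {"M": 0, "F": 0}
    for r in range(n_resamples):
        rng = oracle_substream(seed, cluster_id, bin_index, stream_tag, r)
        picked = oracle_draw(donor_samples, donor_sex, rng, max_retries)
        if picked is None:
            continue
        for sex in ("M", "F"):
            cols = [column_of(values, gene_ids, sample_ids, sid)
                    for _, sid in picked[sex]]
            counts[sex] += 1
            for gi in range(len(gene_ids)):
                sums[sex][gi] += statistics.stdev(c[gi] for c in cols)
    return {sex: [s / counts[sex] for s in sums[sex]] for sex in ("M", "F")}


def oracle_median_cross_corr(values, gene_ids, sample_ids, subject_ids,
                             set_a, set_b):
    """Median of cross-set gene-gene correlations over the given subjects."""
    cols = [sample_ids.index(s) for s in subject_ids]
    corrs = []
    for a in set_a:
        for b in set_b:
            if a == b:
                continue
            xa = [values[gene_ids.index(a)][j] for j in cols]
            xb = [values[gene_ids.index(b)][j] for j in cols]
            corrs.append(pearson(xa, xb))
    return statistics.median(corrs)
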