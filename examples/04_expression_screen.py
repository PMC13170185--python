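"""Temporal-transcriptome screen for meiosis-expressed candidate genes.

Planted data: two gene groups peaking at different anther development
stages (one during early meiosis, one post-meiosis) with replicate noise.
Pipeline: TPM -> replicate R^2 QC -> top-CV gene selection -> fuzzy c-means
on z-scored stage means -> Pearson co-expression network in the
meiosis-peaked cluster -> candidate filter (degree band, copy number <= 4,
known genes excluded).
"""

import numpy as np
import pandas as pd

from xomap import (
    CandidateCriteria,
    candidate_filter,
    correlation_network,
    fuzzy_cmeans,
    replicate_correlation,
    simulate_stage_profiles,
    stage_means,
    standardize_rows,
    top_cv_genes,
    tpm,
)

counts, lengths, samples, truth = simulate_stage_profiles(
    n_per_group=100, peak_stages=(2, 6), noise_cv=0.15, seed=11
)
tpm_values = tpm(counts, lengths)
print(f"TPM columns sum to {tpm_values.sum(axis=0).iloc[0]:,.0f} (per-sample normalisation)")

rep = replicate_correlation(tpm_values, samples)
print(f"replicate consistency: min R^2 = {rep['r2'].min():.3f} (QC threshold 0.90)")

means = stage_means(tpm_values, samples)
top = top_cv_genes(means, n=len(means))
clusters = fuzzy_cmeans(standardize_rows(means.loc[top]), c=2, m=1.25, seed=0)
sizes = clusters.hard.value_counts()
print(f"fuzzy c-means clusters: {dict(sizes)}")

# the meiosis-peaked cluster = the one whose center peaks at stage A3
meiotic = clusters.hard[clusters.hard == sizes.index[0]].index
peak_stage = means.loc[meiotic].mean().idxmax()
print(f"focus cluster peaks at stage {peak_stage}")

network = correlation_network(means.loc[meiotic], r_threshold=0.95)
print(f"co-expression network: {len(network.edges)} edges, "
      f"median degree {network.degrees.median():.0f}")

copy_numbers = pd.Series(
    np.where(np.arange(len(meiotic)) % 10 == 0, 6, 2), index=meiotic
)
known = frozenset(list(meiotic[:5]))  # pretend these have known function
criteria = CandidateCriteria(
    degree_min=int(network.degrees.quantile(0.25)),
    degree_max=int(network.degrees.max()),
    known_gene_exclusion=known,
)
candidates = candidate_filter(network, copy_numbers, criteria)
print(f"candidates after degree/copy-number/known-gene filter: {len(candidates)}")
print(candidates.head(5).to_string(index=False))
print("# top rows = best-connected unknown-function genes with <= 4 copies")
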