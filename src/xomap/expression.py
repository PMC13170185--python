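"""Temporal-transcriptome candidate-gene screen.

From a gene x sample count matrix staged across anther development
(pre-meiosis through post-meiosis): TPM normalisation, replicate
consistency (Pearson R^2 on log2(TPM + 1)), selection of the most
stage-dynamic genes by coefficient of variation, fuzzy c-means clustering
of z-scored stage profiles, a thresholded Pearson co-expression network,
and the candidate filter (connection degree band, gene copy number cap,
exclusion of genes of known function).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "ClusterResult",
    "CoexpressionNetwork",
    "CandidateCriteria",
    "tpm",
    "replicate_correlation",
    "stage_means",
    "top_cv_genes",
    "standardize_rows",
    "fuzzy_cmeans",
    "correlation_network",
    "candidate_filter",
    "simulate_stage_profiles",
]


@dataclass
class ExpressionMatrix:
    """Gene expression with per-gene lengths and a sample -> stage mapping.

    ``values`` is genes x samples (counts or TPM), ``lengths`` the effective
    gene lengths in bp, ``samples`` a DataFrame indexed by sample name with
    columns ``stage`` and ``replicate``.
    """

    values: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values < 0).any().any():
            raise ValidationError("expression values must be non-negative")
        self.lengths = self.lengths.reindex(self.values.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValidationError("every gene needs a positive length")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples without stage mapping: {sorted(missing)}")


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalised counts scaled to 1e6 per sample.

    rate_g = count_g / length_kb_g; TPM_g = 1e6 * rate_g / sum(rates).
    An all-zero sample yields all-zero TPM with a warning rather than NaN.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValidationError("every gene needs a positive length")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero samples: {list(counts.columns[zero])}; TPM set to 0")
        totals = totals.replace(0, np.nan)
    out = rate.div(totals, axis=1) * 1e6
    return out.fillna(0.0)


def replicate_correlation(tpm_values: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Pairwise replicate consistency per stage: Pearson R^2 on log2(TPM + 1)."""
    log = np.log2(tpm_values + 1.0)
    rows = []
    for stage, sub in samples.groupby("stage", sort=False):
        reps = list(sub.index)
        if len(reps) < 2:
            raise ValidationError(f"stage {stage!r} has fewer than 2 replicates")
        for a, b in combinations(reps, 2):
            r = float(np.corrcoef(log[a], log[b])[0, 1])
            rows.append((stage, a, b, r * r))
    return pd.DataFrame(rows, columns=["stage", "sample_a", "sample_b", "r2"])


def stage_means(tpm_values: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM across replicates per stage — the per-gene expression level."""
    stage_of = samples["stage"]
    return tpm_values.T.groupby(stage_of).mean().T


def top_cv_genes(means: pd.DataFrame, n: int = 15_000) -> pd.Index:
    """The n genes with the largest coefficient of variation across stages.

    CV = sample SD / mean over the stage profile; genes with zero mean are
    excluded (their CV is undefined).
    """
    mean = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    cv = cv[mean > 0].dropna()
    return cv.sort_values(ascending=False, kind="stable").index[:n]


def standardize_rows(means: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene's stage profile (mean 0, sample SD 1)."""
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValidationError("constant-profile genes cannot be standardized")
    return means.sub(mu, axis=0).div(sd, axis=0)


@dataclass
class ClusterResult:
    """Soft clustering of stage profiles.

    ``membership`` is genes x clusters in [0, 1] with rows summing to 1;
    ``hard`` the argmax assignment; ``objective`` the (non-increasing)
    objective trace.
    """

    membership: pd.DataFrame
    centers: np.ndarray
    fuzzifier: float
    objective: list[float]

    @property
    def hard(self) -> pd.Series:
        return self.membership.idxmax(axis=1)


def fuzzy_cmeans(
    data: pd.DataFrame,
    c: int = 10,
    m: float = 1.25,
    tol: float = 1e-9,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusterResult:
    """Fuzzy c-means on (standardized) stage profiles.

    Alternating updates: memberships u_gk proportional to (1/d^2_gk)^(1/(m-1))
    normalised per gene; centers are u^m-weighted means. A gene coincident
    with a center gets full membership to it (the m -> limit rule). Centers
    are initialised from c distinct rows drawn with the seeded generator.
    """
    if c < 1:
        raise ConfigError("c must be >= 1")
    if m <= 1:
        raise ConfigError("fuzzifier m must be > 1")
    X = data.to_numpy(dtype=float)
    n = X.shape[0]
    if c > n:
        raise ConfigError("more clusters than genes")
    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=c, replace=False)].copy()
    exponent = 1.0 / (m - 1.0)
    objective: list[float] = []
    u = np.full((n, c), 1.0 / c)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            w = d2 ** (-exponent)
            u = w / w.sum(axis=1, keepdims=True)
        hit = zero.any(axis=1)
        if hit.any():
            u[hit] = 0.0
            u[hit, np.argmax(zero[hit], axis=1)] = 1.0
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        j = float((um * d2).sum())
        objective.append(j)
        if len(objective) > 1 and abs(objective[-2] - objective[-1]) < tol:
            break
    membership = pd.DataFrame(
        u, index=data.index, columns=[f"C{k + 1}" for k in range(c)]
    )
    return ClusterResult(membership, centers, m, objective)


@dataclass
class CoexpressionNetwork:
    """Thresholded Pearson co-expression graph.

    ``edges`` has columns ``gene_a``, ``gene_b``, ``r``, ``p``; ``degrees``
    covers every input gene (isolated genes have degree 0).
    """

    edges: pd.DataFrame
    degrees: pd.Series


def correlation_network(
    profiles: pd.DataFrame, r_threshold: float = 0.95, p_threshold: float = 0.05
) -> CoexpressionNetwork:
    """All-pairs Pearson network on stage profiles.

    An undirected edge joins two genes when |r| > r_threshold and the
    t-transform p-value (n - 2 degrees of freedom over the profile length)
    is below p_threshold. Needs >= 3 observations per gene.
    """
    n_obs = profiles.shape[1]
    if n_obs < 3:
        raise ValidationError("need >= 3 observations per gene for p-values")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn("constant-profile genes have undefined correlations; no edges for them")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
        R = np.clip(R, -1.0, 1.0)
        T = R * np.sqrt((n_obs - 2) / (1.0 - R**2))
    P = 2.0 * sps.t.sf(np.abs(T), df=n_obs - 2)
    P[np.isclose(np.abs(R), 1.0)] = 0.0
    iu, ju = np.triu_indices(len(X), k=1)
    keep = (np.abs(R[iu, ju]) > r_threshold) & (P[iu, ju] < p_threshold)
    keep &= ~np.isnan(R[iu, ju])
    genes = profiles.index
    edges = pd.DataFrame(
        {
            "gene_a": genes[iu[keep]],
            "gene_b": genes[ju[keep]],
            "r": R[iu, ju][keep],
            "p": P[iu, ju][keep],
        }
    )
    degrees = pd.Series(0, index=genes, dtype=int)
    if len(edges):
        counts = pd.concat([edges["gene_a"], edges["gene_b"]]).value_counts()
        degrees.loc[counts.index] = counts.astype(int)
    return CoexpressionNetwork(edges, degrees)


@dataclass(frozen=True)
class CandidateCriteria:
    """Filter for screen hits: degree band, copy-number cap, known-gene list."""

    degree_min: int = 50
    degree_max: int = 206
    max_copy_number: int = 4
    known_gene_exclusion: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.degree_min > self.degree_max:
            raise ConfigError("degree_min must be <= degree_max")


def candidate_filter(
    network: CoexpressionNetwork,
    copy_numbers: pd.Series,
    criteria: CandidateCriteria | None = None,
) -> pd.DataFrame:
    """Rank candidate genes by network degree under the screen criteria.

    Keeps genes whose degree lies in [degree_min, degree_max], whose copy
    number is <= max_copy_number, and which are not in the exclusion set
    (genes of known function); sorted by degree descending.
    """
    criteria = criteria or CandidateCriteria()
    copy_numbers = copy_numbers.reindex(network.degrees.index)
    if copy_numbers.isna().any():
        missing = list(copy_numbers.index[copy_numbers.isna()])[:5]
        raise ValidationError(f"copy number unknown for genes {missing}")
    out = pd.DataFrame(
        {"gene": network.degrees.index, "degree": network.degrees.to_numpy(),
         "copy_number": copy_numbers.to_numpy()}
    )
    keep = (
        out["degree"].between(criteria.degree_min, criteria.degree_max)
        & (out["copy_number"] <= criteria.max_copy_number)
        & ~out["gene"].isin(criteria.known_gene_exclusion)
    )
    return (
        out[keep]
        .sort_values(["degree", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


def simulate_stage_profiles(
    n_per_group: int = 100,
    n_stages: int = 8,
    peak_stages: tuple[int, ...] = (2, 6),
    fold: float = 10.0,
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Planted stage-profile groups for screen validation.

    One gene group per entry of ``peak_stages`` (e.g. a meiosis-peaked and a
    late-peaked group): each gene gets a lognormal baseline, a ``fold``-fold
    induction at its peak stage (half of it carrying into the next stage),
    and multiplicative replicate noise with coefficient of variation
    ``noise_cv``. Returns (counts genes x samples, gene lengths in bp,
    sample map, true group labels).
    """
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    labels: list[int] = []
    profiles: list[np.ndarray] = []
    for g, peak in enumerate(peak_stages):
        shape = np.ones(n_stages)
        shape[peak] += fold
        if peak + 1 < n_stages:
            shape[peak + 1] += fold / 2
        for i in range(n_per_group):
            genes.append(f"G{g + 1}_{i + 1:04d}")
            labels.append(g)
            baseline = rng.lognormal(mean=np.log(50.0), sigma=0.8)
            profiles.append(baseline * shape)
    samples = pd.DataFrame(
        [
            (f"A{s + 1}_r{r + 1}", f"A{s + 1}", r + 1)
            for s in range(n_stages)
            for r in range(n_replicates)
        ],
        columns=["sample", "stage", "replicate"],
    ).set_index("sample")
    mu = np.repeat(np.asarray(profiles), n_replicates, axis=1)
    noise = rng.lognormal(mean=0.0, sigma=noise_cv, size=mu.shape)
    counts = pd.DataFrame(np.round(mu * noise), index=genes, columns=samples.index)
    lengths = pd.Series(
        rng.integers(500, 5000, size=len(genes)).astype(float), index=counts.index
    )
    return counts, lengths, samples, pd.Series(labels, index=counts.index)
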