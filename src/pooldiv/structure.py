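"""Population structure: allele-frequency PCA and hierarchical AMOVA.

PCA factorizes the pools x sites frequency matrix (per-locus mean
centered, no unit-variance scaling) by singular value decomposition;
component k explains s_k^2 / sum(s^2) of the variance.  A chromosome
scope restricts the factorization to sites on one chromosome, which is
how per-chromosome contributions to crop-type differentiation are read.

AMOVA treats each pool's frequency vector as one multivariate
observation and partitions the total Euclidean sum of squares into
among-crop-type, among-accession-within-crop-type and within-accession
strata (Excoffier-style mean squares with the weighted-n coefficients
for unequal group sizes).  With one pool per accession — the pool-seq
design here — the within-accession stratum has zero degrees of freedom
and its component is reported as 0 with a flag.  Negative variance
components are truncated to 0 before percentaging.  Significance of the
among-crop-type component can be assessed by permuting accessions across
crop types.

Both analyses are complete-case by site: any site missing in any pool is
dropped first (count logged), matching an all-pools biallelic filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LineageHierarchy
from .stats import FrequencyMatrix

logger = logging.getLogger(__name__)

__all__ = ["PcaResult", "AmovaResult", "pca", "amova", "amova_permutation"]


@dataclass
class PcaResult:
    scores: pd.DataFrame  # pools x components
    variance_explained: np.ndarray  # fraction per component, in [0, 1]
    loadings: np.ndarray = None  # components x sites (right singular vectors)
    scope: str = "genome"
    n_sites_used: int = 0
    n_sites_dropped: int = 0


def _complete_case(fm: FrequencyMatrix, vt=None, chromosome=None):
    q = fm.q
    if chromosome is not None:
        if vt is None:
            raise ValueError("chromosome scope requires a VariantTable")
        q = q[(vt["chrom"] == chromosome).to_numpy()]
    keep = ~np.isnan(q).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d sites with missing pools", dropped)
    return q[keep], dropped


def pca(
    fm: FrequencyMatrix,
    center: bool = True,
    vt: pd.DataFrame = None,
    chromosome: str = None,
    n_components: int = None,
) -> PcaResult:
    """SVD-based PCA of pool allele frequencies.

    Rows are pools, columns are loci; loci are mean-centered (unless
    ``center=False``) and the pools x loci matrix is factorized as
    U S Vt.  Scores are U S; variance explained is s_k^2 / sum(s^2).
    """
    q, dropped = _complete_case(fm, vt, chromosome)
    x = q.T  # pools x sites
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 pools and 2 sites")
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    u, s, vtmat = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    var_exp = s**2 / total if total > 0 else np.zeros_like(s)
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = pd.DataFrame(
        (u * s)[:, :k],
        index=pd.Index(fm.pool_ids, name="pool_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(
        scores=scores,
        variance_explained=var_exp[:k],
        loadings=vtmat[:k],
        scope=chromosome or "genome",
        n_sites_used=x.shape[1],
        n_sites_dropped=dropped,
    )


@dataclass
class AmovaResult:
    """Variance components of the nested (crop type / accession / pool)
    Euclidean AMOVA, with degrees of freedom, sums of squares, percent of
    total per stratum, and an optional permutation p-value."""

    sigma: dict  # stratum -> variance component (>= 0 after truncation)
    percent: dict  # stratum -> percent of total
    df: dict
    ss: dict
    flags: list = field(default_factory=list)
    p_value: float = None

    STRATA = (
        "among_crop_types",
        "among_accessions_within_crop_types",
        "within_accessions",
    )

    @property
    def total(self) -> float:
        return sum(self.sigma.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": self.df,
                "SS": self.ss,
                "sigma": self.sigma,
                "percent": self.percent,
            }
        ).loc[list(self.STRATA)]


def _amova_components(x: np.ndarray, acc_labels, ct_labels):
    """Nested sums of squares and variance components.

    x: pools x loci matrix of observations; labels give each pool's
    accession and crop type.  Returns (sigma, df, ss, flags) without
    negativity truncation.
    """
    acc_labels = np.asarray(acc_labels)
    ct_labels = np.asarray(ct_labels)
    n = x.shape[0]
    grand = x.mean(axis=0)
    accs = list(dict.fromkeys(acc_labels))
    cts = list(dict.fromkeys(ct_labels))
    g = len(cts)
    a = len(accs)

    ss_total = float(((x - grand) ** 2).sum())
    ss_within = 0.0
    ss_acc = 0.0
    ss_ct = 0.0
    acc_mean = {}
    acc_n = {}
    acc_ct = {}
    for acc in accs:
        m = acc_labels == acc
        acc_n[acc] = int(m.sum())
        acc_mean[acc] = x[m].mean(axis=0)
        acc_ct[acc] = ct_labels[m][0]
        ss_within += float(((x[m] - acc_mean[acc]) ** 2).sum())
    ct_mean = {}
    ct_n = {}
    for ct in cts:
        m = ct_labels == ct
        ct_n[ct] = int(m.sum())
        ct_mean[ct] = x[m].mean(axis=0)
        ss_ct += ct_n[ct] * float(((ct_mean[ct] - grand) ** 2).sum())
    for acc in accs:
        ss_acc += acc_n[acc] * float(((acc_mean[acc] - ct_mean[acc_ct[acc]]) ** 2).sum())

    df = {
        "among_crop_types": g - 1,
        "among_accessions_within_crop_types": a - g,
        "within_accessions": n - a,
    }
    ss = {
        "among_crop_types": ss_ct,
        "among_accessions_within_crop_types": ss_acc,
        "within_accessions": ss_within,
    }
    flags = []
    if abs(ss_total - sum(ss.values())) > 1e-6 * max(1.0, ss_total):
        flags.append("sums of squares do not close")  # defensive; should never happen

    # Weighted-n coefficients for unequal sizes (Excoffier et al. 1992).
    sum_na2_over_ng = sum(
        sum(acc_n[acc] ** 2 for acc in accs if acc_ct[acc] == ct) / ct_n[ct] for ct in cts
    )
    sum_na2_over_n = sum(acc_n[acc] ** 2 for acc in accs) / n
    sum_ng2_over_n = sum(ct_n[ct] ** 2 for ct in cts) / n
    n_prime = (n - sum_na2_over_ng) / (a - g) if a > g else float("nan")
    n_dprime = (sum_na2_over_ng - sum_na2_over_n) / (g - 1) if g > 1 else float("nan")
    n_tprime = (n - sum_ng2_over_n) / (g - 1) if g > 1 else float("nan")

    if df["within_accessions"] > 0:
        sigma_within = ss["within_accessions"] / df["within_accessions"]
    else:
        sigma_within = 0.0
        flags.append("within_accessions df is 0 (one pool per accession); component set to 0")
    if df["among_accessions_within_crop_types"] > 0:
        ms_acc = ss["among_accessions_within_crop_types"] / df["among_accessions_within_crop_types"]
        sigma_acc = (ms_acc - sigma_within) / n_prime
    else:
        sigma_acc = 0.0
        flags.append("among_accessions df is 0; component set to 0")
    if df["among_crop_types"] > 0:
        ms_ct = ss["among_crop_types"] / df["among_crop_types"]
        sigma_ct = (ms_ct - sigma_within - n_dprime * sigma_acc) / n_tprime
    else:
        sigma_ct = 0.0
        flags.append("among_crop_types df is 0; component set to 0")

    sigma = {
        "among_crop_types": sigma_ct,
        "among_accessions_within_crop_types": sigma_acc,
        "within_accessions": sigma_within,
    }
    return sigma, df, ss, flags


def amova(
    fm: FrequencyMatrix,
    h: LineageHierarchy,
    vt: pd.DataFrame = None,
    chromosome: str = None,
    truncate_negative: bool = True,
) -> AmovaResult:
    """Hierarchical AMOVA of pool allele-frequency vectors.

    Requires at least two crop types.  Negative components (sampling
    noise) are truncated to 0 before percents are formed, and the
    truncation is flagged.
    """
    if len(h.crop_types) < 2:
        raise ValueError("AMOVA needs at least two crop types")
    q, _ = _complete_case(fm, vt, chromosome)
    x = q.T  # pools x loci
    pools = fm.pool_ids
    acc_labels = [h.pool_accession[p] for p in pools]
    ct_labels = [h.crop_type_of_pool(p) for p in pools]
    sigma, df, ss, flags = _amova_components(x, acc_labels, ct_labels)
    if truncate_negative:
        for k, v in sigma.items():
            if v < 0:
                sigma[k] = 0.0
                flags.append(f"negative component {k} truncated to 0")
    total = sum(sigma.values())
    percent = {k: (100.0 * v / total if total > 0 else 0.0) for k, v in sigma.items()}
    return AmovaResult(sigma=sigma, percent=percent, df=df, ss=ss, flags=flags)


def amova_permutation(
    fm: FrequencyMatrix,
    h: LineageHierarchy,
    n_perm: int = 999,
    seed: int = 0,
    vt: pd.DataFrame = None,
) -> AmovaResult:
    """Permutation p-value for the among-crop-type component.

    Accession -> crop-type assignments are permuted (group sizes kept),
    and p = (1 + #{permuted component >= observed}) / (n_perm + 1).
    When fewer distinct assignments exist than requested, permutations
    are sampled with replacement (noted in flags).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = amova(fm, h, vt=vt)
    q, _ = _complete_case(fm, vt)
    x = q.T
    pools = fm.pool_ids
    acc_labels = np.array([h.pool_accession[p] for p in pools])
    ct_obs = [h.crop_type_of_pool(p) for p in pools]
    obs_sigma, _, _, _ = _amova_components(x, acc_labels, ct_obs)  # untruncated
    accs = list(dict.fromkeys(acc_labels))
    acc_ct = np.array([h.accession_crop_type[a] for a in accs])
    rng = np.random.default_rng(seed)
    import math

    n_distinct = math.factorial(len(accs))
    if n_distinct <= n_perm:
        observed.flags.append(
            f"only {n_distinct} distinct assignments; permutations sampled with replacement"
        )
    hits = 0
    for _ in range(n_perm):
        perm_ct = {a: c for a, c in zip(accs, rng.permutation(acc_ct))}
        ct_labels = [perm_ct[a] for a in acc_labels]
        sigma, _, _, _ = _amova_components(x, acc_labels, ct_labels)
        if sigma["among_crop_types"] >= obs_sigma["among_crop_types"] - 1e-12:
            hits += 1
    observed.p_value = (1 + hits) / (n_perm + 1)
    return observed
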