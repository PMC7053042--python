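"""Pooled allele-frequency estimation and gene-diversity (2pq) summaries.

For a biallelic site sequenced in a pool, the plug-in estimate of the
alternate-allele frequency is q = alt_reads / depth, with p = 1 - q
anchored to the reference allele.  Gene diversity (expected
heterozygosity) at a site is 2pq, at most 0.5 for a biallelic site;
averaged over sites it summarizes the variation held within one pooled
accession, and lineage-level summaries are the mean +/- sample standard
deviation over member-pool means.

No finite-pool-size bias correction is applied: the plug-in 2pq is the
quantity being reproduced.  Sites missing in a pool (depth below the
threshold) are excluded from that pool's mean rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AlleleCountMatrix, LineageHierarchy

__all__ = [
    "FrequencyMatrix",
    "DiversityTable",
    "allele_frequency",
    "gene_diversity",
    "aggregate_by_lineage",
]


@dataclass
class FrequencyMatrix:
    """Sites x pools alternate-allele frequencies; NaN marks missing."""

    q: np.ndarray
    pool_ids: list

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.pool_ids = list(self.pool_ids)
        if self.q.ndim != 2 or self.q.shape[1] != len(self.pool_ids):
            raise ValueError("q must be sites x pools, aligned with pool_ids")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.q, initial=0.0) < 0 or np.nanmax(self.q, initial=0.0) > 1:
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.q.shape[0]

    @property
    def n_pools(self) -> int:
        return self.q.shape[1]

    def take_sites(self, index) -> "FrequencyMatrix":
        return FrequencyMatrix(self.q[index], self.pool_ids)

    def to_tsv(self, path, vt=None) -> None:
        """Export sites-as-rows, pools-as-columns (the shape of a pooled
        allele-frequency matrix release)."""
        df = pd.DataFrame(self.q, columns=self.pool_ids)
        if vt is not None:
            df.insert(0, "chrom", vt["chrom"].to_numpy())
            df.insert(1, "pos", vt["pos"].to_numpy())
        df.to_csv(path, sep="\t", index=False, na_rep="NA")


def allele_frequency(acm: AlleleCountMatrix, min_depth: int = 1) -> FrequencyMatrix:
    """q = alt_reads / depth per cell; cells with depth < min_depth are
    missing (NaN).  Depth 0 always yields missing, never a division error."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    depth = acm.depth.astype(float)
    ok = acm.depth >= max(min_depth, 1)
    q = np.full(depth.shape, np.nan)
    np.divide(acm.alt_reads, depth, out=q, where=ok)
    return FrequencyMatrix(q, acm.pool_ids)


@dataclass
class DiversityTable:
    """Per-site 2pq values plus per-pool means over non-missing sites."""

    per_site: np.ndarray  # sites x pools, NaN where frequency missing
    per_pool: pd.Series  # mean 2pq per pool (NaN if no usable sites)
    n_sites_used: pd.Series  # non-missing site count per pool


def gene_diversity(fm: FrequencyMatrix) -> DiversityTable:
    """Expected heterozygosity 2pq per site/pool and its per-pool mean.

    A pool with zero non-missing sites gets a NaN mean (flagged by
    ``n_sites_used`` = 0) rather than an error.
    """
    q = fm.q
    per_site = 2.0 * q * (1.0 - q)
    used = (~np.isnan(q)).sum(axis=0)
    sums = np.nansum(per_site, axis=0) if per_site.size else np.zeros(fm.n_pools)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(used > 0, sums / used, np.nan)
    idx = pd.Index(fm.pool_ids, name="pool_id")
    return DiversityTable(
        per_site=per_site,
        per_pool=pd.Series(means, index=idx, name="mean_2pq"),
        n_sites_used=pd.Series(used, index=idx, name="n_sites"),
    )


def aggregate_by_lineage(
    per_pool: pd.Series,
    h: LineageHierarchy,
    level: str = "crop_type",
    exclude=(),
) -> pd.DataFrame:
    """Mean +/- sample sd of member-pool values per lineage.

    ``exclude`` removes pools (e.g. self-fertile inbred accessions)
    before aggregating.  A lineage left with fewer than two members gets
    an undefined (NaN) sd; the species level aggregates all pools.
    """
    exclude = set(exclude)
    rows = []
    for lineage in h.lineages(level):
        members = [p for p in h.pools_of(lineage, level) if p not in exclude]
        vals = per_pool.reindex(members).dropna()
        rows.append(
            {
                "lineage": lineage,
                "level": level,
                "n_pools": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("lineage")
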