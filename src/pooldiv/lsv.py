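"""Lineage-specific variation (LSV) scanning.

An LSV — an apomorphy — is a variant fixed within one lineage (an
accession, a crop type, or the whole species) and not detected in any
other lineage.  The scan discretizes each pool's alternate-allele
frequency into {ABSENT, SEGREGATING, FIXED, MISSING} and then applies
the definition: a site is LSV for lineage L iff every pool inside L is
FIXED and every pool outside L is ABSENT.  At species level there is no
"outside", so the condition reduces to fixation in all pools.

Two discretization routes are provided: frequency thresholding with a
tolerance epsilon (default 0 for noise-free counts; ~0.05 is sensible
for real read counts, where binomial noise makes exact 0/1 frequencies
rare), and a genotype-call mode that maps per-pool diploid-style calls
(hom-alt -> FIXED, het -> SEGREGATING, hom-ref or no call -> ABSENT),
mirroring analyses that work from genotype calls rather than raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .io import LineageHierarchy
from .stats import FrequencyMatrix

__all__ = ["PoolState", "pool_state", "pool_state_from_genotypes", "classify_lsv", "lsv_report", "LsvReport"]


class PoolState(IntEnum):
    ABSENT = 0
    SEGREGATING = 1
    FIXED = 2
    MISSING = 3


def pool_state(fm: FrequencyMatrix, epsilon: float = 0.0) -> np.ndarray:
    """Discretize frequencies: ABSENT iff q <= eps, FIXED iff q >= 1-eps,
    SEGREGATING otherwise; NaN propagates to MISSING.  Requires
    0 <= epsilon < 0.5 so the three bands cannot overlap."""
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    q = fm.q
    out = np.full(q.shape, PoolState.SEGREGATING, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[q <= epsilon] = PoolState.ABSENT
        out[q >= 1.0 - epsilon] = PoolState.FIXED
    out[np.isnan(q)] = PoolState.MISSING
    return out


def pool_state_from_genotypes(genotypes: np.ndarray) -> np.ndarray:
    """Map diploid-style genotype codes (0=hom-ref, 1=het, 2=hom-alt,
    -1=no call) to pool states; no call counts as ABSENT ("not detected")."""
    g = np.asarray(genotypes)
    out = np.full(g.shape, PoolState.ABSENT, dtype=np.int8)
    out[g == 1] = PoolState.SEGREGATING
    out[g == 2] = PoolState.FIXED
    return out


def classify_lsv(
    states: np.ndarray,
    h: LineageHierarchy,
    level: str,
    pool_ids=None,
    missing_policy: str = "strict",
) -> pd.DataFrame:
    """Per-site LSV flags for every lineage at one hierarchy level.

    A site is LSV for lineage L iff all pools inside L are FIXED and all
    pools outside L are ABSENT.  ``missing_policy``:

    - ``strict`` (default): a MISSING pool anywhere disqualifies the site
      for L (absence of evidence is not evidence of absence);
    - ``lenient``: MISSING outside L is treated as ABSENT; MISSING inside
      L still disqualifies (fixation cannot be asserted without data).

    Returns a boolean DataFrame, sites x lineages.
    """
    if missing_policy not in ("strict", "lenient"):
        raise ValueError("missing_policy must be 'strict' or 'lenient'")
    pool_ids = list(pool_ids) if pool_ids is not None else h.pools
    if states.shape[1] != len(pool_ids):
        raise ValueError("states and pool_ids are not aligned")
    col = {p: j for j, p in enumerate(pool_ids)}
    fixed = states == PoolState.FIXED
    absent = states == PoolState.ABSENT
    if missing_policy == "lenient":
        absent_out = absent | (states == PoolState.MISSING)
    else:
        absent_out = absent
    flags = {}
    for lineage in h.lineages(level):
        inside = np.zeros(len(pool_ids), dtype=bool)
        for p in h.pools_of(lineage, level):
            inside[col[p]] = True
        ok_in = fixed[:, inside].all(axis=1)
        ok_out = absent_out[:, ~inside].all(axis=1) if (~inside).any() else True
        flags[lineage] = ok_in & ok_out
    return pd.DataFrame(flags)


@dataclass
class LsvReport:
    """LSV tallies for one hierarchy level.

    ``summary``: per-lineage total / SNP / indel counts.
    ``by_chromosome``: lineages x chromosomes counts, with a ``mean``
    column equal to total / number of chromosomes.
    """

    level: str
    summary: pd.DataFrame
    by_chromosome: pd.DataFrame

    def to_tsv(self, summary_path=None, by_chromosome_path=None) -> None:
        if summary_path is not None:
            self.summary.to_csv(summary_path, sep="\t")
        if by_chromosome_path is not None:
            self.by_chromosome.to_csv(by_chromosome_path, sep="\t")


def lsv_report(
    flags: pd.DataFrame,
    vt: pd.DataFrame,
    level: str = "accession",
    chromosomes=None,
) -> LsvReport:
    """Tally LSV flags by lineage, variant class (SNP vs indel) and
    chromosome; per-chromosome mean = lineage total / number of
    chromosomes."""
    if len(flags) != len(vt):
        raise ValueError("flags and VariantTable are not aligned")
    is_snp = (vt["variant_class"] == "SNP").to_numpy()
    is_indel = (vt["variant_class"] == "indel").to_numpy()
    chrom = vt["chrom"].to_numpy()
    if chromosomes is None:
        chromosomes = list(dict.fromkeys(chrom))
    summary_rows, chrom_rows = [], []
    for lineage in flags.columns:
        f = flags[lineage].to_numpy()
        counts = {c: int((f & (chrom == c)).sum()) for c in chromosomes}
        total = int(f.sum())
        summary_rows.append(
            {
                "lineage": lineage,
                "total": total,
                "snp": int((f & is_snp).sum()),
                "indel": int((f & is_indel).sum()),
            }
        )
        counts["total"] = total
        counts["mean"] = total / len(chromosomes)
        chrom_rows.append({"lineage": lineage, **counts})
    return LsvReport(
        level=level,
        summary=pd.DataFrame(summary_rows).set_index("lineage"),
        by_chromosome=pd.DataFrame(chrom_rows).set_index("lineage"),
    )


def flags_to_bed(flags: pd.DataFrame, vt: pd.DataFrame, level: str) -> pd.DataFrame:
    """Flatten per-site flags to a BED-like table (chrom, pos, lineage,
    level), one row per (site, lineage) hit."""
    rows = []
    chrom = vt["chrom"].to_numpy()
    pos = vt["pos"].to_numpy()
    for lineage in flags.columns:
        idx = np.flatnonzero(flags[lineage].to_numpy())
        for i in idx:
            rows.append({"chrom": chrom[i], "pos": int(pos[i]), "lineage": lineage, "level": level})
    return pd.DataFrame(rows, columns=["chrom", "pos", "lineage", "level"])
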