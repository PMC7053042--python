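"""Shared-variation relationship matrices and bootstrapped NJ clustering.

Relationships between pooled accessions are built from identity-by-state
style sharing of detected variants: a variant is "present" in a pool
when enough alternate reads support it, shared-variant counts N_ij tally
joint presence, and pairwise coefficients normalize those counts (Dice
2N_ij/(N_ii+N_jj) by default, cosine as an alternative).  A KING-robust
kinship estimate on pseudo-genotypes is also provided: pools are not
diploid individuals, so frequencies are first discretized into
diploid-like codes, and the robust estimator

    phi_hat = (N_het,het - 2 * N_opposite_hom) / (N_het(i) + N_het(j))

is evaluated over sites non-missing in both pools.  Neither coefficient
is claimed to be canonical for pools; both are offered.

Trees are unrooted neighbor-joining trees on d_ij = 1 - r_ij (Dice and
cosine keep d >= 0; for kinship d = max(0.5 - phi_hat, 0)), with
bipartition support from resampling sites with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .io import AlleleCountMatrix
from .stats import FrequencyMatrix

__all__ = [
    "presence_matrix",
    "shared_variant_counts",
    "relationship_coefficients",
    "pseudo_genotypes",
    "king_robust",
    "king_matrix",
    "relationship_to_distance",
    "nj_tree",
    "bootstrap_support",
    "SharedVariationMatrix",
    "RelationshipMatrix",
    "SupportTree",
]


def presence_matrix(acm: AlleleCountMatrix, min_alt_reads: int = 2) -> np.ndarray:
    """Boolean sites x pools: variant detected in a pool iff alt reads >=
    ``min_alt_reads`` (default 2, guarding against lone error reads)."""
    return acm.alt_reads >= min_alt_reads


@dataclass
class SharedVariationMatrix:
    """Symmetric pools x pools variant-sharing counts; the diagonal holds
    each pool's own detected-variant count."""

    counts: np.ndarray
    pool_ids: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.pool_ids = list(self.pool_ids)
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("shared-variation matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.pool_ids, columns=self.pool_ids)


@dataclass
class RelationshipMatrix:
    """Symmetric pools x pools relationship coefficients plus method label."""

    values: np.ndarray
    pool_ids: list
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pool_ids, columns=self.pool_ids)


def shared_variant_counts(presence: np.ndarray, pool_ids=None) -> SharedVariationMatrix:
    """N_ij = number of sites where the variant is present in both pools;
    N_ii = sites present in pool i."""
    p = np.asarray(presence, dtype=bool)
    counts = p.astype(np.int64).T @ p.astype(np.int64)
    if pool_ids is None:
        pool_ids = [f"P{j}" for j in range(p.shape[1])]
    return SharedVariationMatrix(counts, pool_ids)


def relationship_coefficients(
    svm: SharedVariationMatrix = None,
    method: str = "dice",
    fm: FrequencyMatrix = None,
    t_low: float = 0.25,
    t_high: float = 0.75,
) -> RelationshipMatrix:
    """Pairwise relationship coefficients.

    ``dice``: 2 N_ij / (N_ii + N_jj);  ``cosine``: N_ij / sqrt(N_ii N_jj)
    — both in [0, 1] with unit diagonal.  ``king_pseudo`` runs the
    KING-robust estimator on pseudo-genotypes from ``fm`` (phi_hat of a
    pool with itself is 0.5).  Pools with no detected variants (or no
    heterozygous-like sites for KING) get NaN coefficients.
    """
    if method in ("dice", "cosine"):
        if svm is None:
            raise ValueError(f"method {method!r} needs a SharedVariationMatrix")
        n = svm.counts.astype(float)
        diag = np.diag(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            if method == "dice":
                denom = diag[:, None] + diag[None, :]
                r = 2.0 * n / denom
            else:
                denom = np.sqrt(diag[:, None] * diag[None, :])
                r = n / denom
        r[~np.isfinite(r)] = np.nan
        empty = diag == 0  # no detected variants: coefficient undefined
        r[empty, :] = np.nan
        r[:, empty] = np.nan
        return RelationshipMatrix(r, svm.pool_ids, method)
    if method == "king_pseudo":
        if fm is None:
            raise ValueError("method 'king_pseudo' needs a FrequencyMatrix")
        return king_matrix(fm, t_low=t_low, t_high=t_high)
    raise ValueError(f"unknown method {method!r}")


def pseudo_genotypes(fm: FrequencyMatrix, t_low: float = 0.25, t_high: float = 0.75) -> np.ndarray:
    """Discretize pool frequencies into diploid-like genotype codes:
    q < t_low -> 0 (hom-ref), q > t_high -> 2 (hom-alt), else 1
    (het-like); missing -> -1."""
    if not 0.0 <= t_low < t_high <= 1.0:
        raise ValueError("thresholds must satisfy 0 <= t_low < t_high <= 1")
    q = fm.q
    g = np.ones(q.shape, dtype=np.int8)
    g[q < t_low] = 0
    g[q > t_high] = 2
    g[np.isnan(q)] = -1
    return g


def king_robust(genotypes_i: np.ndarray, genotypes_j: np.ndarray) -> float:
    """KING-robust kinship between two genotype vectors (codes 0/1/2,
    -1 missing), over sites non-missing in both.  Returns NaN when the
    heterozygote denominator is zero."""
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (gi >= 0) & (gj >= 0)
    gi, gj = gi[ok], gj[ok]
    het_het = int(((gi == 1) & (gj == 1)).sum())
    opp_hom = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    het_i = int((gi == 1).sum())
    het_j = int((gj == 1).sum())
    denom = het_i + het_j
    if denom == 0:
        return float("nan")
    return (het_het - 2.0 * opp_hom) / denom


def king_matrix(fm: FrequencyMatrix, t_low: float = 0.25, t_high: float = 0.75) -> RelationshipMatrix:
    g = pseudo_genotypes(fm, t_low, t_high)
    n = fm.n_pools
    r = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            r[i, j] = r[j, i] = king_robust(g[:, i], g[:, j])
    return RelationshipMatrix(r, fm.pool_ids, "king_pseudo")


def relationship_to_distance(rm: RelationshipMatrix) -> np.ndarray:
    """Tree distance from coefficients: d = 1 - r for Dice/cosine (always
    >= 0); kinship can be negative, so d = max(0.5 - phi_hat, 0).  The
    diagonal is forced to exactly 0."""
    if np.isnan(rm.values).any():
        raise ValueError("relationship matrix has undefined entries")
    if rm.method == "king_pseudo":
        d = np.maximum(0.5 - rm.values, 0.0)
    else:
        d = 1.0 - rm.values
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class SupportTree:
    """Unrooted NJ tree with optional bipartition support fractions.

    ``supports`` maps each internal bipartition (frozenset of pool ids on
    the side not containing the first pool) to the fraction of bootstrap
    replicates whose tree contains that bipartition.
    """

    tree: TreeNode
    pool_ids: list
    supports: dict = None
    n_reps: int = 0

    def newick(self) -> str:
        """Newick string; internal node names carry support values when
        bootstrap supports are present."""
        t = self.tree.copy()
        if self.supports is not None:
            _annotate_supports(t, self.pool_ids, self.supports)
        return str(t)


def nj_tree(rm: RelationshipMatrix = None, distance: np.ndarray = None, pool_ids=None) -> SupportTree:
    """Saitou-Nei neighbor joining on d = 1 - r (or an explicit distance
    matrix).  Negative branch lengths, which plain NJ can produce on
    non-additive input, are clamped to 0 in the returned tree."""
    if distance is None:
        if rm is None:
            raise ValueError("need a RelationshipMatrix or a distance matrix")
        distance = relationship_to_distance(rm)
        pool_ids = rm.pool_ids
    if pool_ids is None:
        pool_ids = [f"P{j}" for j in range(distance.shape[0])]
    if np.isnan(distance).any():
        raise ValueError("distance matrix has undefined entries")
    dm = DistanceMatrix(distance, [str(p) for p in pool_ids])
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return SupportTree(tree=tree, pool_ids=list(pool_ids))


def _bipartitions(tree: TreeNode, pool_ids) -> set:
    """Non-trivial bipartitions of the pool set, each canonicalized as the
    frozenset of leaf names on the side not containing the first pool."""
    all_names = frozenset(str(p) for p in pool_ids)
    anchor = str(pool_ids[0])
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if anchor in side:
            side = all_names - side
        if 1 < len(side) < len(all_names) - 1:
            parts.add(side)
    return parts


def _annotate_supports(tree: TreeNode, pool_ids, supports: dict) -> None:
    all_names = frozenset(str(p) for p in pool_ids)
    anchor = str(pool_ids[0])
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if anchor in side:
            side = all_names - side
        if side in supports:
            node.name = f"{supports[side]:.2f}"


def bootstrap_support(
    presence: np.ndarray = None,
    fm: FrequencyMatrix = None,
    pool_ids=None,
    n_reps: int = 100,
    seed: int = 0,
    method: str = "dice",
    t_low: float = 0.25,
    t_high: float = 0.75,
) -> SupportTree:
    """NJ tree with locus-bootstrap bipartition support.

    Sites (loci) are resampled with replacement ``n_reps`` times; the
    coefficient matrix and NJ tree are rebuilt per replicate, and each
    bipartition of the original tree is scored by the fraction of
    replicate trees containing it.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    def build(pres, freq):
        if method in ("dice", "cosine"):
            svm = shared_variant_counts(pres, pool_ids)
            rm = relationship_coefficients(svm, method=method)
        else:
            rm = king_matrix(freq, t_low, t_high)
        return nj_tree(rm)

    if method in ("dice", "cosine"):
        if presence is None:
            raise ValueError(f"method {method!r} needs a presence matrix")
        n_sites = presence.shape[0]
        if pool_ids is None:
            pool_ids = [f"P{j}" for j in range(presence.shape[1])]
    else:
        if fm is None:
            raise ValueError("method 'king_pseudo' needs a FrequencyMatrix")
        n_sites = fm.n_sites
        pool_ids = fm.pool_ids

    base = build(presence, fm)
    base_parts = _bipartitions(base.tree, pool_ids)
    hits = {part: 0 for part in base_parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, n_sites, size=n_sites)
        pres_b = presence[idx] if presence is not None else None
        fm_b = fm.take_sites(idx) if fm is not None and method == "king_pseudo" else None
        rep = build(pres_b, fm_b)
        rep_parts = _bipartitions(rep.tree, pool_ids)
        for part in hits:
            if part in rep_parts:
                hits[part] += 1
    supports = {part: hits[part] / n_reps for part in hits}
    return SupportTree(tree=base.tree, pool_ids=list(pool_ids), supports=supports, n_reps=n_reps)
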