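"""Synthetic pool-seq generator with hierarchical population structure.

Emulates the study design the rest of the package analyzes: a species
split into crop types, each crop type into pooled accessions, every locus
drifting independently down the hierarchy under the Balding-Nichols model
(descendant allele frequency ~ Beta around the parental frequency,
parameterized by a drift/FST parameter F), followed by binomial sampling
of a finite pool of individuals and Poisson/binomial read sampling with a
symmetric per-read error rate.

Defaults mirror the emulated study: 23 pools (crop-type sizes 10/7/2/4)
of 25 individuals each, ~80X mean depth, 9 chromosomes, a U-shaped
Beta(0.8, 0.8) ancestral site-frequency spectrum, and ~15% of loci
labeled as indels.  Loci are independent; no linkage is simulated —
every downstream statistic here is single-locus.

The generator also returns a :class:`TruthSet` (per-level frequencies,
injected lineage-private variants) so parameter-recovery tests can score
the pipeline against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AlleleCountMatrix, LineageHierarchy, make_variant_table

__all__ = [
    "SimParams",
    "TruthSet",
    "simulate_frequencies",
    "inject_lsv",
    "sample_pool_counts",
    "fst_among",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the hierarchical pool-seq simulation.

    ``accessions_per_type`` may be a single count or one count per crop
    type; the default (10, 7, 2, 4) reproduces the emulated 23-pool
    design.  ``f_ct`` / ``f_acc`` are Balding-Nichols drift parameters
    for the crop-type and accession levels; 0 means the no-drift limit
    (child frequency equals parent frequency).
    """

    n_crop_types: int = 4
    accessions_per_type: object = (10, 7, 2, 4)
    n_individuals_per_pool: int = 25
    n_loci: int = 10_000
    ancestral_freq_dist: tuple = (0.8, 0.8)
    f_ct: float = 0.05
    f_acc: float = 0.01
    mean_depth: float = 80.0
    error_rate: float = 0.001
    n_chromosomes: int = 9
    indel_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        sizes = self.sizes()
        if self.n_crop_types < 1 or self.n_loci < 1 or self.n_chromosomes < 1:
            raise ValueError("counts must be >= 1")
        if self.n_individuals_per_pool < 1 or any(s < 1 for s in sizes):
            raise ValueError("counts must be >= 1")
        for name in ("f_ct", "f_acc", "error_rate", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")

    def sizes(self) -> tuple:
        """Accessions per crop type, expanded to one entry per type."""
        a = self.accessions_per_type
        if np.isscalar(a):
            return (int(a),) * self.n_crop_types
        a = tuple(int(x) for x in a)
        if len(a) != self.n_crop_types:
            raise ValueError("accessions_per_type length must match n_crop_types")
        return a


def _hierarchy(params: SimParams) -> LineageHierarchy:
    pool_acc, acc_ct = {}, {}
    for c, size in enumerate(params.sizes()):
        ct = f"CT{c + 1}"
        for a in range(size):
            acc = f"{ct}-A{a + 1:02d}"
            pool_acc[acc] = acc
            acc_ct[acc] = ct
    return LineageHierarchy("species", pool_acc, acc_ct)


def _balding_nichols(rng, parent: np.ndarray, f: float) -> np.ndarray:
    """Draw descendant frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F).

    F = 0 is the no-drift limit (returns the parent frequencies); parent
    frequencies of exactly 0 or 1 stay fixed, as drift cannot move them.
    """
    if f == 0.0:
        return parent.copy()
    scale = (1.0 - f) / f
    out = np.empty_like(parent)
    interior = (parent > 0) & (parent < 1)
    p = parent[interior]
    out[interior] = rng.beta(p * scale, (1.0 - p) * scale)
    out[~interior] = parent[~interior]
    return out


@dataclass
class TruthSet:
    """Ground truth of a simulation run.

    Frequencies are alternate-allele frequencies at three levels of the
    hierarchy; ``injected_lsv`` records deliberately planted
    lineage-private fixed variants (locus, lineage, level).
    """

    ancestral_freqs: np.ndarray
    croptype_freqs: pd.DataFrame  # crop types x loci
    accession_freqs: pd.DataFrame  # accessions x loci
    chrom: np.ndarray
    pos: np.ndarray
    is_indel: np.ndarray
    injected_lsv: pd.DataFrame
    hierarchy: LineageHierarchy
    params: SimParams

    @property
    def n_loci(self) -> int:
        return self.accession_freqs.shape[1]

    def to_tables(self, outdir) -> None:
        """Write the truth as tab-delimited tables + a JSON param record."""
        import json
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        site = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "is_indel": self.is_indel,
                "ancestral_freq": self.ancestral_freqs,
            }
        )
        site.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        self.croptype_freqs.T.to_csv(out / "truth_croptype_freqs.tsv", sep="\t")
        self.accession_freqs.T.to_csv(out / "truth_accession_freqs.tsv", sep="\t")
        self.injected_lsv.to_csv(out / "truth_injected_lsv.tsv", sep="\t", index=False)
        params = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self.params).items()}
        (out / "sim_params.json").write_text(json.dumps(params, indent=2) + "\n")


def simulate_frequencies(params: SimParams) -> TruthSet:
    """Draw per-level allele frequencies for every locus.

    Ancestral frequency pi ~ Beta(a, b); crop-type frequencies drift from
    pi with F = f_ct; accession frequencies drift from their crop type
    with F = f_acc.  Loci are assigned uniformly at random to chromosomes
    with sorted, distinct positions per chromosome.  Deterministic for a
    given (params, seed).
    """
    rng = np.random.default_rng(params.seed)
    h = _hierarchy(params)
    a, b = params.ancestral_freq_dist
    ancestral = rng.beta(a, b, size=params.n_loci)
    ct_rows = {
        ct: _balding_nichols(rng, ancestral, params.f_ct) for ct in h.crop_types
    }
    acc_rows = {
        acc: _balding_nichols(rng, ct_rows[h.accession_crop_type[acc]], params.f_acc)
        for acc in h.accessions
    }
    chrom_idx = rng.integers(0, params.n_chromosomes, size=params.n_loci)
    chrom, pos = _assign_positions(rng, chrom_idx, params.n_chromosomes)
    is_indel = rng.random(params.n_loci) < params.indel_fraction
    loci = np.arange(params.n_loci)
    return TruthSet(
        ancestral_freqs=ancestral,
        croptype_freqs=pd.DataFrame(ct_rows, index=loci).T,
        accession_freqs=pd.DataFrame(acc_rows, index=loci).T,
        chrom=chrom,
        pos=pos,
        is_indel=is_indel,
        injected_lsv=pd.DataFrame(columns=["locus", "lineage", "level"]),
        hierarchy=h,
        params=params,
    )


def _assign_positions(rng, chrom_idx, n_chromosomes):
    """Distinct, increasing positions per chromosome (1-based)."""
    n = len(chrom_idx)
    chrom = np.array([f"Chr{c + 1}" for c in chrom_idx])
    pos = np.zeros(n, dtype=np.int64)
    for c in range(n_chromosomes):
        mask = chrom_idx == c
        k = int(mask.sum())
        if k:
            gaps = rng.integers(1, 1000, size=k)
            pos[mask] = np.cumsum(gaps)
    return chrom, pos


def inject_lsv(
    truth: TruthSet, lineage_id, level: str, n_variants: int, seed: int
) -> TruthSet:
    """Append ``n_variants`` lineage-private fixed loci to a TruthSet.

    The new loci have alternate-allele frequency 1 in every accession
    inside the named lineage and 0 in every accession outside it —
    the idealized signature of lineage-specific variation.
    """
    h = truth.hierarchy
    if level not in ("accession", "crop_type"):
        raise ValueError("level must be 'accession' or 'crop_type'")
    valid = h.lineages(level)
    if lineage_id not in valid:
        raise KeyError(f"unknown {level} lineage {lineage_id!r}; valid ids: {valid}")
    inside_pools = set(h.pools_of(lineage_id, level))
    rng = np.random.default_rng(seed)
    n0 = truth.n_loci
    new_loci = np.arange(n0, n0 + n_variants)

    acc_new = pd.DataFrame(
        {
            loc: [1.0 if acc in inside_pools else 0.0 for acc in truth.accession_freqs.index]
            for loc in new_loci
        },
        index=truth.accession_freqs.index,
    )
    ct_new = pd.DataFrame(
        {
            loc: [
                float(np.mean([1.0 if a in inside_pools else 0.0
                               for a, c in h.accession_crop_type.items() if c == ct]))
                for ct in truth.croptype_freqs.index
            ]
            for loc in new_loci
        },
        index=truth.croptype_freqs.index,
    )
    chrom_idx = rng.integers(0, truth.params.n_chromosomes, size=n_variants)
    chrom = np.array([f"Chr{c + 1}" for c in chrom_idx])
    # positions beyond any existing coordinate so they stay distinct
    base = int(truth.pos.max()) + 1 if len(truth.pos) else 1
    pos = base + np.arange(n_variants, dtype=np.int64) * 7 + 1
    is_indel = rng.random(n_variants) < truth.params.indel_fraction
    record = pd.DataFrame(
        {"locus": new_loci, "lineage": lineage_id, "level": level}
    )
    return TruthSet(
        ancestral_freqs=np.concatenate([truth.ancestral_freqs, np.zeros(n_variants)]),
        croptype_freqs=pd.concat([truth.croptype_freqs, ct_new], axis=1),
        accession_freqs=pd.concat([truth.accession_freqs, acc_new], axis=1),
        chrom=np.concatenate([truth.chrom, chrom]),
        pos=np.concatenate([truth.pos, pos]),
        is_indel=np.concatenate([truth.is_indel, is_indel]),
        injected_lsv=pd.concat([truth.injected_lsv, record], ignore_index=True),
        hierarchy=h,
        params=truth.params,
    )


def sample_pool_counts(
    truth: TruthSet, params: SimParams = None, seed: int = None
) -> tuple:
    """Sample read counts from truth frequencies.

    Per accession and locus: the pool's realized alternate-allele count
    ~ Binomial(2 * n_individuals, accession frequency) giving pool
    frequency g; depth ~ Poisson(mean_depth); alt reads ~ Binomial(depth,
    g(1-e) + (1-g)e) with symmetric per-read error e; ref = depth - alt.
    Returns (VariantTable, AlleleCountMatrix) aligned to the truth loci.
    """
    params = params or truth.params
    rng = np.random.default_rng(params.seed if seed is None else seed)
    freqs = truth.accession_freqs.to_numpy()  # accessions x loci
    n_acc, n_loci = freqs.shape
    two_n = 2 * params.n_individuals_per_pool
    pool_counts = rng.binomial(two_n, freqs)
    g = pool_counts / two_n
    depth = rng.poisson(params.mean_depth, size=(n_acc, n_loci))
    e = params.error_rate
    p_read = g * (1.0 - e) + (1.0 - g) * e
    alt = rng.binomial(depth, p_read)
    ref = depth - alt
    acm = AlleleCountMatrix(
        depth.T, ref.T, alt.T, list(truth.accession_freqs.index)
    )
    ref_allele = np.where(truth.is_indel, "AT", "A")
    alt_allele = np.where(truth.is_indel, "A", "T")
    vt = make_variant_table(truth.chrom, truth.pos, ref_allele, alt_allele)
    return vt, acm


def fst_among(freqs) -> float:
    """Variance-components FST among populations from a populations x loci
    frequency matrix (Weir-Cockerham-style ratio of averages).

    Per locus: s2 = sample variance (ddof=1) of the K population
    frequencies, pbar = their mean.  FST = sum(s2) / sum(pbar(1-pbar) +
    s2/K); under the Balding-Nichols model this estimates the drift
    parameter F that generated the populations.
    """
    p = np.asarray(freqs, dtype=float)
    k = p.shape[0]
    if k < 2:
        raise ValueError("need at least two populations")
    pbar = p.mean(axis=0)
    s2 = p.var(axis=0, ddof=1)
    denom = np.sum(pbar * (1.0 - pbar) + s2 / k)
    if denom == 0:
        return float("nan")
    return float(np.sum(s2) / denom)
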