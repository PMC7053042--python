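"""End-to-end pipeline: read, filter, estimate, and report.

Chains every stage of the pooled-diversity analysis — VCF + hierarchy
reading, site filters, allele frequencies, gene-diversity summaries,
hierarchical LSV scans, shared-variation relatedness with a bootstrapped
NJ tree, PCA and AMOVA — into a single reproducible run that writes
plain-TSV tables, a newick tree, and a JSON manifest recording
parameters and the seed.  ``consistency_check`` re-derives the
cross-table identities the report tables must satisfy and returns any
violations instead of raising.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    AlleleCountMatrix,
    LineageHierarchy,
    filter_sites,
    read_hierarchy,
    read_vcf,
    validate_hierarchy,
)
from .lsv import classify_lsv, lsv_report, pool_state
from .relatedness import (
    bootstrap_support,
    presence_matrix,
    relationship_coefficients,
    shared_variant_counts,
)
from .stats import aggregate_by_lineage, allele_frequency, gene_diversity
from .structure import amova, amova_permutation, pca

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "consistency_check"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run (all tunables in one place)."""

    vcf: str = None
    hierarchy: str = None
    out_dir: str = None
    min_depth: int = 15
    classes: tuple = ("SNP", "indel")
    biallelic_only: bool = True
    epsilon: float = 0.05
    missing_policy: str = "strict"
    min_alt_reads: int = 2
    coefficient: str = "dice"
    t_low: float = 0.25
    t_high: float = 0.75
    n_bootstrap: int = 100
    n_perm: int = 0
    exclude: tuple = ()
    seed: int = 0


@dataclass
class ReportBundle:
    """Everything one pipeline run produces, publication-table shaped."""

    diversity: pd.DataFrame  # per-pool: variant counts, LSV counts, mean 2pq
    diversity_by_croptype: pd.DataFrame
    lsv_reports: dict  # level -> LsvReport
    shared: "pd.DataFrame"  # pools x pools counts
    relationship: pd.DataFrame  # pools x pools coefficients
    tree_newick: str
    pca_scores: pd.DataFrame
    pca_variance: np.ndarray
    amova_table: pd.DataFrame
    manifest: dict


def run_pipeline(
    cfg: PipelineConfig,
    vt=None,
    acm: AlleleCountMatrix = None,
    h: LineageHierarchy = None,
) -> ReportBundle:
    """Run every stage on a VCF + hierarchy (or in-memory inputs).

    Stage order: read -> validate -> filter -> frequencies ->
    {diversity, LSV, relatedness + tree, PCA, AMOVA} -> bundle.
    Deterministic for a fixed config and inputs (the only randomness —
    bootstrap and permutations — is driven by ``cfg.seed``).
    """
    if vt is None or acm is None:
        if cfg.vcf is None:
            raise ValueError("run_pipeline needs either a VCF path or in-memory inputs")
        vt, acm = read_vcf(cfg.vcf)
    if h is None:
        if cfg.hierarchy is None:
            raise ValueError("run_pipeline needs a hierarchy")
        h = read_hierarchy(cfg.hierarchy)
    report = validate_hierarchy(h, acm)
    if not report["ok"]:
        raise ValueError(f"stage validate_hierarchy: pool mismatch {report}")
    logger.info("input: %d sites x %d pools", acm.n_sites, acm.n_pools)

    vt_f, acm_f = filter_sites(
        vt, acm, min_depth=cfg.min_depth, biallelic_only=cfg.biallelic_only, classes=cfg.classes
    )
    logger.info("filtered: %d sites", acm_f.n_sites)
    if acm_f.n_sites == 0:
        raise ValueError("stage filter_sites: no sites passed the filters")

    fm = allele_frequency(acm_f, min_depth=cfg.min_depth)

    div = gene_diversity(fm)
    presence = presence_matrix(acm_f, min_alt_reads=cfg.min_alt_reads)
    is_snp = (vt_f["variant_class"] == "SNP").to_numpy()
    is_indel = (vt_f["variant_class"] == "indel").to_numpy()

    states = pool_state(fm, epsilon=cfg.epsilon)
    lsv_reports = {}
    acc_flags = None
    for level in ("accession", "crop_type", "species"):
        flags = classify_lsv(states, h, level, pool_ids=fm.pool_ids, missing_policy=cfg.missing_policy)
        lsv_reports[level] = lsv_report(flags, vt_f, level=level)
        if level == "accession":
            acc_flags = flags

    pool_index = pd.Index(fm.pool_ids, name="pool_id")
    diversity = pd.DataFrame(
        {
            "crop_type": [h.crop_type_of_pool(p) for p in fm.pool_ids],
            "total_variants": presence.sum(axis=0),
            "snp_variants": (presence & is_snp[:, None]).sum(axis=0),
            "indel_variants": (presence & is_indel[:, None]).sum(axis=0),
            "lsv_total": [
                int(lsv_reports["accession"].summary.loc[h.pool_accession[p], "total"])
                for p in fm.pool_ids
            ],
            "lsv_snp": [
                int(lsv_reports["accession"].summary.loc[h.pool_accession[p], "snp"])
                for p in fm.pool_ids
            ],
            "lsv_indel": [
                int(lsv_reports["accession"].summary.loc[h.pool_accession[p], "indel"])
                for p in fm.pool_ids
            ],
            "mean_2pq": div.per_pool.to_numpy(),
        },
        index=pool_index,
    )
    diversity_by_ct = aggregate_by_lineage(div.per_pool, h, "crop_type", exclude=cfg.exclude)

    svm = shared_variant_counts(presence, fm.pool_ids)
    rm = relationship_coefficients(
        svm, method=cfg.coefficient, fm=fm, t_low=cfg.t_low, t_high=cfg.t_high
    )
    tree = bootstrap_support(
        presence=presence,
        fm=fm,
        pool_ids=fm.pool_ids,
        n_reps=cfg.n_bootstrap,
        seed=cfg.seed,
        method=cfg.coefficient,
        t_low=cfg.t_low,
        t_high=cfg.t_high,
    )

    pca_res = pca(fm)
    if cfg.n_perm > 0:
        amova_res = amova_permutation(fm, h, n_perm=cfg.n_perm, seed=cfg.seed)
    else:
        amova_res = amova(fm, h)

    manifest = {
        "pooldiv_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "n_sites_input": int(acm.n_sites),
        "n_sites_filtered": int(acm_f.n_sites),
        "n_pools": int(acm_f.n_pools),
        "amova_flags": amova_res.flags,
        "amova_p_value": amova_res.p_value,
    }
    bundle = ReportBundle(
        diversity=diversity,
        diversity_by_croptype=diversity_by_ct,
        lsv_reports=lsv_reports,
        shared=svm.to_frame(),
        relationship=rm.to_frame(),
        tree_newick=tree.newick(),
        pca_scores=pca_res.scores,
        pca_variance=pca_res.variance_explained,
        amova_table=amova_res.to_frame(),
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        write_bundle(bundle, cfg.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.diversity.to_csv(out / "diversity.tsv", sep="\t")
    bundle.diversity_by_croptype.to_csv(out / "diversity_by_croptype.tsv", sep="\t")
    for level, rep in bundle.lsv_reports.items():
        rep.to_tsv(out / f"lsv_{level}.tsv", out / f"lsv_{level}_by_chromosome.tsv")
    # Table-5 layout: coefficients above the diagonal, shared counts below,
    # per-pool variant counts on the diagonal.
    combined = bundle.relationship.copy().astype(float)
    counts = bundle.shared
    for i, pi in enumerate(combined.index):
        combined.iloc[i, i] = counts.iloc[i, i]
        for j in range(i):
            combined.iloc[i, j] = counts.iloc[i, j]
    combined.to_csv(out / "relationship_matrix.tsv", sep="\t")
    (out / "tree.nwk").write_text(bundle.tree_newick)
    bundle.pca_scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(bundle.pca_variance))],
         "variance_explained": bundle.pca_variance}
    ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
    bundle.amova_table.to_csv(out / "amova.tsv", sep="\t")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, default=str) + "\n")


def consistency_check(bundle: ReportBundle) -> list:
    """Cross-table identities every self-produced bundle must satisfy.

    Returns a list of human-readable violations (empty when clean):
    per-lineage total LSV = SNP + indel LSV; per-lineage total = sum of
    chromosome counts; crop-type LSV totals sum to the combined
    crop-type-specific total; shared-variation off-diagonals do not
    exceed diagonals; AMOVA percents sum to 100 (or all strata are 0).
    """
    violations = []
    for level, rep in bundle.lsv_reports.items():
        for lineage, row in rep.summary.iterrows():
            if row["total"] != row["snp"] + row["indel"]:
                violations.append(
                    f"{level} lineage {lineage}: total {row['total']} != "
                    f"SNP {row['snp']} + indel {row['indel']}"
                )
        chrom_cols = [c for c in rep.by_chromosome.columns if c not in ("total", "mean")]
        for lineage, row in rep.by_chromosome.iterrows():
            if row[chrom_cols].sum() != row["total"]:
                violations.append(
                    f"{level} lineage {lineage}: chromosome counts sum to "
                    f"{int(row[chrom_cols].sum())} != total {int(row['total'])}"
                )
    if "crop_type" in bundle.lsv_reports:
        ct = bundle.lsv_reports["crop_type"].summary
        if ct["total"].sum() != ct["snp"].sum() + ct["indel"].sum():
            violations.append("crop-type LSV totals do not equal SNP + indel sums")
    shared = bundle.shared.to_numpy()
    diag = np.diag(shared)
    n = shared.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] > min(diag[i], diag[j]):
                violations.append(
                    f"shared count ({bundle.shared.index[i]},{bundle.shared.index[j]}) "
                    "exceeds a diagonal entry"
                )
    pct = bundle.amova_table["percent"].sum()
    if not (abs(pct - 100.0) < 1e-6 or abs(pct) < 1e-12):
        violations.append(f"AMOVA percents sum to {pct}, not 100")
    return violations
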