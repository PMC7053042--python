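"""Variant and lineage-hierarchy I/O for pooled sequencing data.

A pool-seq experiment sequences DNA pooled from many individuals of one
accession in a single library; per-site read counts then stand in for
population allele frequencies.  This module reads a multi-pool VCF (one
sample column per pooled accession, with per-sample allelic depths) into
two aligned containers — a :class:`VariantTable` of per-site metadata and
an :class:`AlleleCountMatrix` of (depth, ref reads, alt reads) — applies
the study's site filters, and reads/validates the three-level lineage
hierarchy (species -> crop type -> accession) that every downstream
statistic is stratified by.

All coordinates are 1-based inclusive (VCF convention); no 0-based
surface exists anywhere in the package.  Input VCFs are expected to be
pre-filtered for mapping quality upstream of this package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

VARIANT_CLASSES = ("SNP", "indel", "multiallelic_SNP", "other")

#: Columns of a VariantTable (a plain pandas DataFrame).
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alts", "variant_class", "biallelic")


def classify_variant(ref_allele: str, alt_alleles) -> str:
    """Classify a site by its REF/ALT alleles.

    Rules: any REF/ALT length difference makes the site an ``indel``;
    otherwise a single-base REF with one single-base ALT is a ``SNP``,
    with more than one single-base ALT a ``multiallelic_SNP``; equal-length
    multi-base substitutions fall through to ``other``.
    """
    if isinstance(alt_alleles, str):
        alt_alleles = [alt_alleles]
    alt_alleles = list(alt_alleles)
    if not ref_allele:
        raise ValueError("empty ref allele")
    if not alt_alleles or any(not a for a in alt_alleles):
        raise ValueError("empty alt allele")
    if any(len(a) != len(ref_allele) for a in alt_alleles):
        return "indel"
    if len(ref_allele) == 1:
        return "SNP" if len(alt_alleles) == 1 else "multiallelic_SNP"
    return "other"


def make_variant_table(chrom, pos, ref, alts) -> pd.DataFrame:
    """Assemble a VariantTable from aligned per-site vectors.

    ``alts`` is a sequence of tuples of ALT allele strings.  The
    ``biallelic`` flag is true iff exactly one ALT allele was observed
    across all pools (union semantics over the merged record).
    """
    alts = [tuple(a) if not isinstance(a, str) else (a,) for a in alts]
    pos = np.asarray(pos, dtype=np.int64)
    if (pos < 1).any():
        raise ValueError("positions must be >= 1 (1-based coordinates)")
    classes = [classify_variant(r, a) for r, a in zip(ref, alts)]
    return pd.DataFrame(
        {
            "chrom": list(chrom),
            "pos": pos,
            "ref": list(ref),
            "alts": alts,
            "variant_class": classes,
            "biallelic": [len(a) == 1 for a in alts],
        }
    )


@dataclass
class AlleleCountMatrix:
    """Sites x pools grid of sequencing depth and ref/alt read counts.

    Invariant: ``ref_reads + alt_reads == depth`` and all counts >= 0.
    A depth of 0 marks a cell with no usable allelic-depth information;
    it becomes MISSING once frequencies are computed.
    """

    depth: np.ndarray
    ref_reads: np.ndarray
    alt_reads: np.ndarray
    pool_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.ref_reads = np.asarray(self.ref_reads, dtype=np.int64)
        self.alt_reads = np.asarray(self.alt_reads, dtype=np.int64)
        self.pool_ids = list(self.pool_ids)
        if self.depth.shape != self.ref_reads.shape or self.depth.shape != self.alt_reads.shape:
            raise ValueError("depth/ref/alt shapes differ")
        if self.depth.ndim != 2 or self.depth.shape[1] != len(self.pool_ids):
            raise ValueError("count matrices must be sites x pools, aligned with pool_ids")
        if (self.depth < 0).any() or (self.ref_reads < 0).any() or (self.alt_reads < 0).any():
            raise ValueError("negative read counts")
        if (self.ref_reads + self.alt_reads != self.depth).any():
            raise ValueError("ref_reads + alt_reads must equal depth at every cell")

    @property
    def n_sites(self) -> int:
        return self.depth.shape[0]

    @property
    def n_pools(self) -> int:
        return self.depth.shape[1]

    def take_sites(self, index) -> "AlleleCountMatrix":
        return AlleleCountMatrix(
            self.depth[index], self.ref_reads[index], self.alt_reads[index], self.pool_ids
        )


@dataclass(frozen=True)
class LineageHierarchy:
    """Three-level lineage tree: species -> crop types -> accessions.

    Each pool is one accession's pooled library.  The two dicts form a
    partition: every pool belongs to exactly one accession and every
    accession to exactly one crop type.
    """

    species: str
    pool_accession: dict
    accession_crop_type: dict

    def __post_init__(self):
        missing = set(self.pool_accession.values()) - set(self.accession_crop_type)
        if missing:
            raise ValueError(f"accessions without a crop type: {sorted(missing)}")

    @property
    def pools(self) -> list:
        return list(self.pool_accession)

    @property
    def accessions(self) -> list:
        return list(dict.fromkeys(self.pool_accession.values()))

    @property
    def crop_types(self) -> list:
        return list(dict.fromkeys(self.accession_crop_type.values()))

    def crop_type_of_pool(self, pool_id) -> str:
        return self.accession_crop_type[self.pool_accession[pool_id]]

    def lineages(self, level: str) -> list:
        """Lineage ids at a level: accession / crop_type / species."""
        if level == "accession":
            return self.accessions
        if level == "crop_type":
            return self.crop_types
        if level == "species":
            return [self.species]
        raise ValueError(f"unknown level {level!r}")

    def pools_of(self, lineage_id, level: str) -> list:
        if level == "accession":
            out = [p for p, a in self.pool_accession.items() if a == lineage_id]
        elif level == "crop_type":
            out = [
                p
                for p, a in self.pool_accession.items()
                if self.accession_crop_type[a] == lineage_id
            ]
        elif level == "species":
            out = self.pools if lineage_id == self.species else []
        else:
            raise ValueError(f"unknown level {level!r}")
        if not out:
            raise KeyError(
                f"unknown {level} lineage {lineage_id!r}; valid ids: {self.lineages(level)}"
            )
        return out


def read_hierarchy(path) -> LineageHierarchy:
    """Read a lineage hierarchy from TSV (pool_id, accession, crop_type,
    species) or JSON (same keys per record under ``pools``)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            obj = json.load(fh)
        rows = pd.DataFrame(obj["pools"])
        species = obj.get("species") or rows["species"].iloc[0]
    else:
        rows = pd.read_csv(path, sep="\t", dtype=str)
        if rows.empty:
            raise ValueError(f"empty hierarchy file: {path}")
        species = rows["species"].iloc[0] if "species" in rows else "species"
    required = {"pool_id", "accession", "crop_type"}
    if not required.issubset(rows.columns):
        raise ValueError(f"hierarchy file missing columns {sorted(required - set(rows.columns))}")
    dup = rows["pool_id"][rows["pool_id"].duplicated()]
    if len(dup):
        raise ValueError(f"pool(s) assigned more than once: {sorted(set(dup))}")
    acc_ct = {}
    for acc, ct in zip(rows["accession"], rows["crop_type"]):
        if acc in acc_ct and acc_ct[acc] != ct:
            raise ValueError(f"accession {acc!r} assigned to two crop types")
        acc_ct[acc] = ct
    return LineageHierarchy(
        species=str(species),
        pool_accession=dict(zip(rows["pool_id"], rows["accession"])),
        accession_crop_type=acc_ct,
    )


def write_hierarchy(h: LineageHierarchy, path) -> None:
    pd.DataFrame(
        {
            "pool_id": h.pools,
            "accession": [h.pool_accession[p] for p in h.pools],
            "crop_type": [h.crop_type_of_pool(p) for p in h.pools],
            "species": h.species,
        }
    ).to_csv(path, sep="\t", index=False)


def validate_hierarchy(h: LineageHierarchy, acm: AlleleCountMatrix) -> dict:
    """Cross-check hierarchy pools against count-matrix pools.

    Returns a report dict; ``ok`` is true iff the two pool sets agree.
    """
    in_counts = set(acm.pool_ids)
    in_hier = set(h.pools)
    report = {
        "pools_missing_from_hierarchy": sorted(in_counts - in_hier),
        "pools_missing_from_counts": sorted(in_hier - in_counts),
    }
    report["ok"] = not report["pools_missing_from_hierarchy"] and not report[
        "pools_missing_from_counts"
    ]
    return report


def read_vcf(path) -> tuple:
    """Read a multi-pool VCF into (VariantTable, AlleleCountMatrix).

    Per-sample counts are taken from the AD (allelic depth) FORMAT field:
    ref reads = AD[0], alt reads = sum of the remaining entries.  Records
    whose AD is absent fall back to RO/AO observation counts when those
    are present; otherwise the cell gets depth 0 (MISSING downstream).
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    pool_ids = list(vf.header.samples)
    chrom, pos, ref, alts = [], [], [], []
    depth_rows, ref_rows, alt_rows = [], [], []
    used_fallback = False
    for i, rec in enumerate(vf):
        if rec.ref is None or not rec.alts:
            raise ValueError(f"malformed VCF record at data line {i + 1}: missing alleles")
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref)
        alts.append(tuple(rec.alts))
        d_row, r_row, a_row = [], [], []
        for sample in pool_ids:
            fmt = rec.samples[sample]
            ad = fmt.get("AD")
            if ad is not None and ad[0] is not None:
                r = int(ad[0])
                a = int(sum(x for x in ad[1:] if x is not None))
            elif fmt.get("RO") is not None:
                used_fallback = True
                r = int(fmt["RO"])
                ao = fmt.get("AO")
                if ao is None:
                    a = 0
                else:
                    a = int(sum(ao)) if isinstance(ao, tuple) else int(ao)
            else:
                r = a = 0
            d_row.append(r + a)
            r_row.append(r)
            a_row.append(a)
        depth_rows.append(d_row)
        ref_rows.append(r_row)
        alt_rows.append(a_row)
    vf.close()
    if used_fallback:
        logger.info("read_vcf: AD absent for some records, used RO/AO fallback")
    else:
        logger.info("read_vcf: counts taken from AD field")
    vt = make_variant_table(chrom, pos, ref, alts)
    n = len(vt)
    shape = (n, len(pool_ids))
    acm = AlleleCountMatrix(
        np.array(depth_rows, dtype=np.int64).reshape(shape),
        np.array(ref_rows, dtype=np.int64).reshape(shape),
        np.array(alt_rows, dtype=np.int64).reshape(shape),
        pool_ids,
    )
    return vt, acm


def write_vcf(vt: pd.DataFrame, acm: AlleleCountMatrix, path) -> None:
    """Write a VariantTable + AlleleCountMatrix as a plain VCF v4.2 with
    per-sample DP and AD fields (biallelic AD: ref,alt)."""
    if len(vt) != acm.n_sites:
        raise ValueError("VariantTable and AlleleCountMatrix are not aligned")
    contigs = list(dict.fromkeys(vt["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pooldiv\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(p) for p in acm.pool_ids)
            + "\n"
        )
        for i, row in enumerate(vt.itertuples(index=False)):
            cells = [
                f"{acm.depth[i, j]}:{acm.ref_reads[i, j]},{acm.alt_reads[i, j]}"
                for j in range(acm.n_pools)
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{','.join(row.alts)}"
                f"\t.\tPASS\t.\tDP:AD\t" + "\t".join(cells) + "\n"
            )


def filter_sites(
    vt: pd.DataFrame,
    acm: AlleleCountMatrix,
    min_depth: int = 15,
    biallelic_only: bool = True,
    classes=("SNP",),
) -> tuple:
    """Apply the study's site filters, preserving site order.

    Keeps sites where *every* pool has depth >= ``min_depth``, the
    biallelic flag is true (when ``biallelic_only``), and the variant
    class is in ``classes`` (None keeps all classes).
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if len(vt) != acm.n_sites:
        raise ValueError("VariantTable and AlleleCountMatrix are not aligned")
    keep = (acm.depth >= min_depth).all(axis=1)
    if biallelic_only:
        keep &= vt["biallelic"].to_numpy()
    if classes is not None:
        keep &= vt["variant_class"].isin(set(classes)).to_numpy()
    idx = np.flatnonzero(keep)
    logger.info("filter_sites: kept %d / %d sites", len(idx), acm.n_sites)
    return vt.iloc[idx].reset_index(drop=True), acm.take_sites(idx)
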