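import numpy as np
import pandas as pd
import pytest

from pooldiv import (
    LineageHierarchy,
    SimParams,
    inject_lsv,
    sample_pool_counts,
    simulate_frequencies,
)

# Per-accession mean 2pq values as printed in the published diversity table,
# keyed by entry id; used as *inputs* to the aggregation logic under test.
PRINTED_2PQ = {
    "EL10": 0.027, "C869": 0.194, "EL50": 0.159, "EL51": 0.195, "GP10": 0.230,
    "GP9": 0.253, "L19": 0.187, "SP7322": 0.213, "SR102": 0.232, "SR98": 0.202,
    "BBTB": 0.087, "Crosby": 0.198, "DDRT": 0.185, "RQ": 0.154, "TG": 0.103,
    "W357B": 0.043, "WT": 0.159,
    "MAM": 0.221, "WGF": 0.202,
    "FGSC": 0.241, "LUC": 0.240, "RHU": 0.195, "Vulcan": 0.190,
}

CROP_OF = {}
for p in ("EL10", "C869", "EL50", "EL51", "GP10", "GP9", "L19", "SP7322", "SR102", "SR98"):
    CROP_OF[p] = "sugar"
for p in ("BBTB", "Crosby", "DDRT", "RQ", "TG", "W357B", "WT"):
    CROP_OF[p] = "table"
for p in ("MAM", "WGF"):
    CROP_OF[p] = "fodder"
for p in ("FGSC", "LUC", "RHU", "Vulcan"):
    CROP_OF[p] = "chard"


@pytest.fixture
def beet_hierarchy():
    """23-pool hierarchy with the published crop-type sizes 10/7/2/4."""
    return LineageHierarchy(
        species="B. vulgaris",
        pool_accession={p: p for p in CROP_OF},
        accession_crop_type=dict(CROP_OF),
    )


@pytest.fixture
def printed_2pq():
    return pd.Series(PRINTED_2PQ, name="mean_2pq")


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset with injected LSV (shared across tests)."""
    params = SimParams(
        n_crop_types=2,
        accessions_per_type=(3, 3),
        n_loci=600,
        f_ct=0.1,
        f_acc=0.02,
        error_rate=0.0,
        seed=11,
    )
    truth = simulate_frequencies(params)
    truth = inject_lsv(truth, "CT1-A02", "accession", 40, seed=12)
    truth = inject_lsv(truth, "CT2", "crop_type", 25, seed=13)
    vt, acm = sample_pool_counts(truth, params, seed=14)
    return truth, vt, acm


@pytest.fixture
def toy_vcf(tmp_path):
    """Hand-written 3-record VCF with AD fields for two pools."""
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            "##contig=<ID=Chr1>",
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpoolA\tpoolB",
            "Chr1\t100\t.\tA\tT\t.\tPASS\t.\tDP:AD\t30:20,10\t25:25,0",
            "Chr1\t200\t.\tC\tT,G\t.\tPASS\t.\tDP:AD\t40:30,6,4\t33:30,2,1",
            "Chr1\t350\t.\tG\tGA\t.\tPASS\t.\tDP:AD\t18:10,8\t22:0,22",
            "",
        ]
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
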