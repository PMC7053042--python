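"""Simulate a hierarchical pool-seq dataset and look at its ground truth.

Builds the default emulated design — 23 pooled accessions in four crop
types (10/7/2/4), 25 individuals per pool, ~80X depth — injects 50
variants private to one accession, and prints what the truth set holds.
"""

import pooldiv as pv

params = pv.SimParams(n_loci=2000, seed=1)
truth = pv.simulate_frequencies(params)
truth = pv.inject_lsv(truth, "CT2-A01", "accession", 50, seed=2)
vt, acm = pv.sample_pool_counts(truth, params, seed=3)

print(f"pools: {len(truth.hierarchy.pools)}  crop types: {truth.hierarchy.crop_types}")
print(f"loci: {truth.n_loci} (incl. {len(truth.injected_lsv)} injected private variants)")
print(f"count matrix: {acm.n_sites} sites x {acm.n_pools} pools, "
      f"mean depth {acm.depth.mean():.1f}X")
print(f"FST among crop-type frequencies: "
      f"{pv.fst_among(truth.croptype_freqs.to_numpy()):.4f} (drift parameter f_ct = {params.f_ct})")
# The FST estimate tracks the Balding-Nichols drift parameter that
# generated the crop types; depth ~80X matches the sequencing design.
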