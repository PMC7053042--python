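"""Allele-frequency PCA and hierarchical AMOVA.

PCA of the pools x loci frequency matrix shows how crop types separate;
AMOVA partitions the total variance among crop types, among accessions
within crop types, and within accessions.
"""

import pooldiv as pv
from pooldiv.structure import amova_permutation, pca

params = pv.SimParams(n_crop_types=2, accessions_per_type=6, n_loci=3000,
                      f_ct=0.15, f_acc=0.01, seed=21)
truth = pv.simulate_frequencies(params)
vt, acm = pv.sample_pool_counts(truth, params, seed=22)
fm = pv.allele_frequency(acm, min_depth=15)

res = pca(fm)
print("PCA variance explained (first 4 components):",
      [round(float(v), 3) for v in res.variance_explained[:4]])
print("PC1 scores by pool (sign separates the two crop types):")
print(res.scores["PC1"].round(2).to_string())

am = amova_permutation(fm, truth.hierarchy, n_perm=199, seed=23)
print("\nAMOVA table (variance components of pool frequency vectors):")
print(am.to_frame().round(4).to_string())
print(f"permutation p-value for the among-crop-type component: {am.p_value:.4f}")
# With one pool per accession the within-accession stratum has 0 df and
# its component is 0 by construction; the among-crop-type percent grows
# with the crop-type drift parameter f_ct.
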