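# Methods

## Setting and data model

The package analyzes pooled whole-genome sequencing of a hierarchically
structured species: a species contains crop types, a crop type contains
accessions, and each accession is sequenced as one pooled library (one
VCF sample column). Inputs are a multi-pool VCF v4.2 with per-sample
allelic depths (AD; RO/AO accepted as a fallback, the chosen source is
logged) or equivalent count tables, plus a pool → accession → crop type →
species mapping (TSV or JSON). All coordinates are 1-based (VCF
convention). Mapping-quality filtering is assumed to have happened
upstream of the VCF and is a documented precondition, not a package step.

Site filters follow the pooled-WGS convention: keep sites where **every**
pool reaches the depth threshold (default ≥ 15, configurable), restrict
to records with exactly one ALT across the merged data ("biallelic
across all accessions", union semantics), and select variant classes
(SNP / indel; multiallelic SNPs and equal-length substitutions are
labeled but excluded by default). Indels are accepted as represented in
the input VCF; no left-alignment or decomposition is attempted.

## Estimators

**Allele frequency.** Plug-in per cell: `q = alt_reads / depth`, missing
(NaN) below the depth threshold; depth 0 can never raise a division
error. `p = 1 − q` is always derived, anchoring polarity to the
reference allele.

**Gene diversity.** `2pq` per site and pool (≤ 0.5 at a biallelic site);
per-pool mean over non-missing sites (missing sites are excluded, not
imputed — the conservative choice when the original procedure is
unstated). Lineage summaries are mean ± sample sd (ddof = 1) over member
pools; an `exclude` set lets analysts drop atypical members (e.g.
self-fertile inbreds, whose published crop-type summaries are otherwise
not reproducible), and lineages with fewer than two members report an
undefined sd. No finite-pool-size bias correction is applied: the
plug-in `2pq` is itself the quantity of interest.

**LSV scan.** Frequencies are discretized to
{ABSENT ≤ ε, FIXED ≥ 1 − ε, SEGREGATING, MISSING}; a site is LSV for
lineage L iff every pool inside L is FIXED and every pool outside L is
ABSENT (species level has no outside, so the condition is fixation
everywhere). ε defaults to 0 for noise-free counts; ~0.05 is recommended
for real read counts, where binomial noise at ~80X makes exact 0/1
frequencies rare. A genotype-call mode (hom-alt → FIXED, het →
SEGREGATING, hom-ref / no-call → ABSENT) mirrors workflows that
classify from genotype calls rather than raw counts. The missing policy
defaults to `strict` (a MISSING pool anywhere disqualifies the site —
absence of evidence is not evidence of absence); `lenient` treats
MISSING outside L as ABSENT. Reports tally totals, SNP/indel splits and
per-chromosome counts, with the per-chromosome mean defined as
total / n_chromosomes. (Published tables of this kind do not always
satisfy that definition — e.g. a printed per-chromosome mean of 138
against a total of 1,149 over 9 chromosomes, which is 127.7 — so the
package recomputes rather than reproduces such means.)

**Relatedness.** Presence = alt_reads ≥ 2 by default (two reads guard
against lone miscalls). Shared counts `N_ij` feed Dice (default) or
cosine coefficients; both lie in [0, 1] with unit diagonal, and a pool
with no detected variants gets undefined coefficients. Because applying
a diploid kinship estimator to pools is irreducibly ambiguous, the
KING-robust route is explicit about its approximation: frequencies are
discretized at (0.25, 0.75) into pseudo-genotypes and
`φ̂ = (N_het,het − 2N_opp,hom)/(N_het(i) + N_het(j))` is evaluated over
jointly non-missing sites; neither route is claimed canonical. Trees are
neighbor joining (scikit-bio's Saitou–Nei implementation, deterministic
given the input) on `d = 1 − r` (Dice/cosine) or `d = max(0.5 − φ̂, 0)`
(kinship can be negative); bootstrap support resamples **sites** with
replacement — the standard phylogenetic bootstrap unit — rebuilding the
coefficient matrix and tree per replicate and scoring each original
bipartition by its replicate frequency. Negative NJ branch lengths on
non-additive input are clamped to 0.

**PCA.** Pools × loci matrix, per-locus mean centering, no
unit-variance scaling (scaling would distort the frequency geometry the
analysis interprets); SVD gives scores U·S and variance fractions
s²_k/Σs². Chromosome scope restricts to one chromosome's sites.
Complete-case by site: any site missing in any pool is dropped first
(count logged).

**AMOVA.** Each pool's frequency vector is one multivariate observation;
total Euclidean sum of squares is partitioned into among-crop-type,
among-accession-within-crop-type and within-accession strata, with
variance components from the mean squares using the weighted-n
coefficients for unequal group sizes. Stratum names are written out
unambiguously because published tables of this design have been printed
with inverted labels. With one pool per accession — the usual pool-seq
design — the within-accession stratum has 0 df and its component is
reported as 0 with a flag; the same code handles replicate pools per
accession, where all three components are estimable. Negative components
are truncated to 0 before percentaging (standard practice). The whole
multilocus matrix is analyzed at once (multilocus Euclidean SS) rather
than averaging per-locus AMOVAs. Significance: permute accession →
crop-type assignments, `p = (1 + #{σ²_perm ≥ σ²_obs})/(n_perm + 1)`,
comparing untruncated components; when fewer distinct assignments exist
than permutations requested, sampling is with replacement and flagged.

## Synthetic data generator

The generator emulates the study design the estimators assume: 23 pools
in crop-type sizes (10, 7, 2, 4), 25 individuals per pool, mean depth
80X over 9 chromosomes, ~15% of loci labeled indels (labels only; indel
lengths are irrelevant to every statistic here). Ancestral frequencies
are Beta(0.8, 0.8) — U-shaped, mimicking an empirical site-frequency
spectrum — and drift at each level uses the Balding–Nichols
reparameterization Beta(π(1−F)/F, (1−π)(1−F)/F), the standard
FST-parameterized model for structured populations; F = 0 is handled as
the exact no-drift limit. Defaults f_ct = 0.05 and f_acc = 0.01 were
fixed once as plausible weak-divergence values (no generative values are
published for this design; the within-crop-type variance structure is a
free knob). Read sampling per pool and locus: pool allele count ~
Binomial(2n, f) → pool frequency g; depth ~ Poisson(mean depth); alt
reads ~ Binomial(depth, g(1−e) + (1−g)e) with symmetric error e
(multiallelic error products are ignored; the analysis is biallelic
only). Loci are independent — no linkage — because every in-scope
statistic is single-locus; FASTQ/read-level simulation and demographic
trajectories are out of scope. `inject_lsv` appends loci with frequency
exactly 1 inside a chosen lineage and 0 outside, recording them in the
truth set.

What passing recovery tests shows — and does not. The generator produces
independent biallelic loci with exact Balding–Nichols structure and
Poisson-Binomial noise; real pool-seq additionally has linked loci,
alignment artifacts, reference bias, unequal individual contributions to
the pool, and non-Beta ancestral spectra. Recovery results (FST ≈ f_ct,
LSV precision/recall = 1 without noise, bootstrap support 1.0 under
strong divergence) validate the estimators' logic, not their robustness
to those real-data pathologies.

## Numerical and design choices

- Depth filter is ≥ threshold (inclusive) in every pool; the published
  description oscillates between "≥ 15" and "> 15", and the inclusive
  reading was chosen with the threshold configurable.
- ε = 0.5 is rejected (bands would overlap); thresholds are inclusive
  (q ≤ ε ABSENT, q ≥ 1 − ε FIXED).
- Determinism: all sampling uses `numpy.random.default_rng(seed)`;
  identical (params, seed) give bit-identical outputs, and the pipeline
  manifest records the seed and every setting needed to reproduce a run.
- Degenerate inputs: depth-0 cells become missing; empty filter results
  are returned (not errors) by `filter_sites` but abort the full
  pipeline with a stage-named error; a pool with no usable sites gets a
  flagged NaN diversity mean.
- Problem sizes in tests and the acceptance script (≤ 10,000 loci,
  ≤ 23 pools) were chosen as the smallest designs at which the
  Monte-Carlo checks are stable (e.g. the FST estimator's seed-to-seed
  sd at 10,000 loci is ~7×10⁻⁴, against a tolerance of 5×10⁻³ derived
  from 20 replicate seeds).

## Known limitations

- No genotype likelihoods, phasing, or multiallelic decomposition.
- The KING-on-pools route is a labeled approximation, not a validated
  kinship estimate for pooled libraries.
- Plug-in 2pq is biased downward by factor ≈ (1 − 1/(2n))(1 − 1/depth)
  relative to the population value; at 25 individuals and 80X this is
  ~3%, uncorrected by design.
- AMOVA percents are undefined (reported 0) when total variance is 0.
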