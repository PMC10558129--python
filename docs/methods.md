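# Methods

This note documents the models, parameter choices and numerical conventions
behind `stemchrom`, and what the synthetic-data generator does and does not
emulate.

## Gene classification from replicated counts

Counts are normalised to transcripts per million,
TPM<sub>g,s</sub> = 10⁶ · (c<sub>g,s</sub>/L<sub>g</sub>) / Σ<sub>g'</sub>(c<sub>g',s</sub>/L<sub>g'</sub>),
with L the effective gene length in bp. Differential contrasts are computed
for every pair of cell isolations with the first isolation in the numerator.

Two engines are provided behind one interface.

* **welch** (default): two-sided Welch t-test on log2(TPM + 1) across
  replicates, Benjamini–Hochberg correction within each contrast. When both
  groups have zero variance and equal means the p-value is defined as 1.
  With only three replicates per group this test has low power at realistic
  overdispersion (NB dispersion 0.1 gives a per-replicate CV of ~0.32, so a
  fourfold change is a ~5σ effect on ~4 degrees of freedom — the BH-adjusted
  pass rate per contrast is only ~25%). It is kept as the dependency-free
  default and for null-behaviour studies, where it is conservative.
* **deseq2**: Wald contrasts from a single pydeseq2 fit with design
  `~isolation`. Sharing dispersion across genes restores the power the
  3-replicate design needs; this is the engine recommended for
  classification and the one used in the acceptance analyses.

Callers with their own differential tables (e.g. from an external DESeq2
run) can pass them directly to `classify_genes` in the same schema
(gene_id, contrast, log2FC, p_adj).

Classification rules (strict inequalities throughout): neoblast-specific if
log2FC > 1 and p_adj < 0.05 against *every* other isolation; tissue-specific
analogously for one tissue against all other isolations and the neoblasts;
constitutive if mean TPM > 10 in every isolation and no contrast involving
the gene is significant (|log2FC| > 1 and p_adj < 0.05); otherwise
unclassified. A gene absent from any contrast is left unclassified with a
warning. The pharynx participates only as a contrast group, never as a
class. Expression bins: high (> 30 TPM), expressed (> 10 and < 30), weak
(< 10); boundary values 10 and 30 are assigned to the middle bin so the
bins partition all genes.

## Chromatin statistics

Fragments are 0-based half-open intervals. A fragment counts toward a
window if the intervals intersect by ≥ 1 bp (read-coverage semantics, not
midpoint assignment), and RPKM = count · 10⁹ / (window bp · library size)
with library size the sample's total fragment count.

TSS metaprofiles average RPKM-scaled per-bin coverage over TSS ± 1 kb
(default bin 10 bp — the bin width is not a published value and is
configurable); minus-strand genes are mirrored so upstream is negative
everywhere. `per_gene_profile_argmax` applies the same binning per gene,
which is what the architecture-discrimination analyses use.

Consensus peaks pool the replicate peak sets and single-linkage-cluster them
by ≥ 1 bp overlap; a cluster is conserved only if every replicate
contributes a member and every member has −log₁₀ P strictly above 4, and
its coordinates are the union span of its members (union vs intersection is
not specified by the source protocol; union was chosen as the more
inclusive convention and is isolated in one function). Feature assignment
places each summit with priority promoter > exon > intron > TE >
intergenic, the promoter being the strand-aware [TSS − 2000, TSS) window.
The maximum-signal region is the argmax coverage bin in that window,
reported only above 10 RPKM, ties resolved toward the TSS.

The nucleosome-occupancy proxy replaces a cross-correlation-based
occupancy model with a documented, testable contract: midpoints of
nucleosome-sized fragments (length 150–250 bp) are accumulated at 1-bp
resolution around the TSS, Gaussian-smoothed with σ = 20 bp (mirror-padded,
so a uniform midpoint comb stays flat at the window edges) and normalised
to the mean over the |position| ∈ [800, 1000] flanks. It recovers planted
−180/+120 bp phasing to within a few bp; it is *not* a reimplementation of
the original occupancy model and does not estimate absolute occupancy.

## Promoter sequence features

Promoters are read 5′→3′ on the coding strand (minus-strand genes
reverse-complemented), so position −1 abuts the TSS for every gene.
Promoter statistics (composition, T-stretches, k-mers, tandem repeats,
motif frequencies) scan the coding strand only — the documented T-over-A
bias is strand-asymmetric and would cancel on a double-strand scan —
whereas genome-coordinate motif hits used for accessibility profiles scan
both strands.

T-stretches are maximal homopolymer T runs of length ≥ 5 (configurable; a
run of 7 counts once). Tandem arrays are maximal period-u runs (u = 2 or 3)
counted in whole units with ≥ 3 units, AT-only units flagged. k-mer
enrichment counts occurrences with overlaps allowed, takes expected counts
from background k-mer frequency × foreground positions, reports
log2((obs + 0.5)/(exp + 0.5)) and a binomial upper-tail p-value
(positions treated as independent — overlap-aware nulls are out of scope,
so p-values for self-overlapping k-mers are approximate), BH-corrected
across k-mers.

PWM scanning scores log-odds against the background with probabilities
floored at 10⁻³. A p-value threshold is converted to a score cutoff by
exact enumeration of the score distribution under the background model,
quantised to a 10⁻³ grid (threshold accurate to ~w/2 grid steps). The
shipped Initiator- and TATA-like matrices are editable minimal-MEME
fixtures with the field-standard consensus shapes (pyrimidine–purine
Initiator, TATAWAWR-style TATA); they are placeholders, not experimentally
derived planarian motifs. Motif frequencies over TSS ± 40 use a scan
p-value of 10⁻⁴ by default so that chance hits in AT-rich windows stay
below ~1% per gene.

## Hi-C compartments

Compartments are called per contig at 50-kb bins. Low-coverage bins
("white strips") are removed first: a bin is dropped if its row sum is zero
or below `min_coverage_frac` (default 0.05) × the median nonzero row sum.
A relative-coverage cutoff was chosen over a row-sum quantile because a
quantile always removes its own tail — it cannot express "nothing is low
coverage", whereas planted strips sit orders of magnitude below the median
and are separated exactly.

Balancing is Knight–Ruiz-style symmetric diagonal scaling, iterating
d ← d/√(rowsum(D M D)) until the coefficient of variation of row sums is
below 10⁻⁶ (max 3000 iterations; achieved CV is typically < 10⁻⁶ and always
< 10⁻⁴ on convergent matrices). The observed/expected matrix divides each
entry by the mean of its genomic-distance class (computed from bin
coordinates, so the call is equivariant under bin reordering); zero-mean
distance classes are flagged and set to 0. The compartment signal is the
eigenvector of the largest eigenvalue of the Pearson correlation matrix of
O/E rows — stated explicitly to avoid principal-component index ambiguity —
reallocated to original bin coordinates with NaN/NA at dropped bins. The
sign is oriented so the positive (A) side has the higher mean accessibility,
falling back to gene density when accessibility covers less than half of
the retained bins. Feature enrichment of family f in compartment C is
(fraction of f's bases in C) / (fraction of labeled bins in C), so a
uniformly distributed family scores 1.0 in both compartments.

## Colony quantification

Stacks are (z, y, x) arrays with per-axis voxel calibration in µm (defaults
1.38 × 1.38 × 7 µm, the 20× setting; 2.76 × 2.76 × 7 µm at 10×). The
Laplacian convolution of size n is implemented as centre minus the mean of
a (2n+1)² in-plane neighbourhood — which removes any constant offset — with
the z extent rescaled by voxel anisotropy in 3D mode (at 7-µm z steps and
n = 3 this is one slice either side). The detection threshold is
mean + f·std of the filtered image; how the published plugin combines f
with the image statistics is not printed, and this choice is isolated in
one function. Objects are connected components above threshold
(8-connectivity per slice in 2D, 26-connectivity in 3D) of at least
`min_size` voxels; centroids are unweighted voxel means times the voxel
size; colonies are connected components of the centroid graph with edges at
Euclidean distance strictly below 50 µm (chains merge transitively).

The published per-staining presets (DAPI n = 2, f = 1; FISH n = 3, f = 2;
3D colonies n = 3, f = 1.5) are kept in `colonies.PRESETS`. For the
synthetic stacks the pipeline uses n = 3, f = 2.0, min_size = 14 voxels,
fixed by a design sweep: with 8-µm blobs this preset recovers planted
colony-size multisets exactly on 40/40 stacks at signal-to-noise 5 and
20/20 at SNR 10, and yields zero objects on pure-noise stacks — the
parameters f and n are, as in the source protocol, adjusted per staining
type.

## The synthetic-data generator

All generators are seeded from `(plan.seed, stage tag)`; an identical plan
reproduces every artifact byte for byte. Defaults encode the study
conditions: 70% genome AT, 92% AT with a 62% T share in constitutive/stem
promoters, fourfold expression enrichment, NB dispersion 0.1, 3 replicates
× 5 isolations, 50-kb-style bins with 10% white strips, 20× voxel
calibration. The default gene census (150 per tissue class and neoblast,
200 constitutive, 200 unclassified) mirrors the scale of the published
cluster sets.

* **Genome**: i.i.d. background bases with P(A) = P(T) = AT/2 (the source
  analyses report composition, not higher-order structure). Genes are laid
  out sequentially with guaranteed spacing, alternating strands, bodies of
  0.6–3 kb, TE intervals from five named families scattered in spacers.
  Tissue promoters get one TF consensus instance in [−300, −100] and an
  AT/TA trinucleotide tandem array further upstream (plus an Initiator in
  10%); constitutive/stem promoters get a [−250, 0) window redrawn at the
  planted AT fraction with T bias, 2–3 poly(dT) runs of 6–9 nt in
  [−200, −10], and the Initiator consensus at the TSS. Planted instances
  are exempt from the composition dial (they contain C/G by construction).
* **Counts**: negative binomial with per-gene lognormal baseline spread
  (σ = 0.4); class genes fold_change-times higher in their own isolation;
  constitutive high and flat; unclassified weak and flat (sub-10 TPM, so
  they are planted as genuinely unclassifiable).
* **Fragments**: per-promoter counts are Poisson around class templates
  (the simplest noise model consistent with RPKM-level analyses): tissue
  promoters get short fragments (50–100 bp) at −200 ± 35 bp only in the
  matching isolation; constitutive/stem promoters get short fragments at
  0 ± 45 bp plus nucleosome-sized fragments (150–250 bp) with midpoints at
  −180/+120 ± 15 bp; H3K4me3 fragments centre downstream (+300 ± 200 bp)
  with ~3× intensity at constitutive genes. `fragment_depth` is the total
  per-sample fragment count; the non-promoter remainder is uniform genomic
  background. Depth 0 produces an empty fragment set.
* **Hi-C**: expected counts scale·(1+d)^(−1) with a 2× same-compartment
  boost on an alternating 10-bin checkerboard, Poisson-sampled and
  symmetrised; strip bins are damped 1000-fold before sampling. A per-bin
  accessibility proxy (2:1 A:B with lognormal noise) is emitted for
  orientation.
* **Image stacks**: additive Gaussian blobs (σ = radius/2) at given
  physical centroids over Gaussian background noise (SNR =
  amplitude/noise_sd, default 10); truth colony labels come from a direct
  O(N²) transitive closure, independent of the detection module's
  KDTree/graph implementation.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: read-level sequencing error and mapping
artifacts, higher-order sequence structure (dinucleotide periodicity,
isochores), enhancer–promoter architecture, fragment-length biases of real
tagmentation, Hi-C ligation noise and TAD-scale structure, and optical
effects (PSF anisotropy, bleaching, autofluorescence texture). Recovery
rates on synthetic data demonstrate the correctness and statistical
behaviour of the implementations at planted effect sizes, not performance
on real libraries.

## Problem sizes

The test and acceptance analyses use 1,000-gene simulations for
classification (3 × 5 samples), ten 2,000-gene null simulations, 400-gene
genomes at 200k fragments per sample for architecture discrimination,
1,000 random 100-nt sequences for the counter/scanner oracles, ten 100-bin
contact matrices, 100 random point sets of up to 500 cells for the colony
partition oracle, and five image stacks (~0.3 Mvoxel each). The complete
suite runs in a few minutes on one CPU.

## Known limitations

The Welch engine should not be used for real 3-replicate classification
(see above); binomial k-mer p-values are approximate for self-overlapping
k-mers; the consensus-peak "mutual overlap" is single-linkage, which can
chain staggered peaks; composition/at_fraction assumes truncation occurs at
the upstream end of a window (true for the generator, not for genes within
500 bp of a contig's 3′ edge); and the image threshold statistic is a
stated interpretation of an unpublished plugin detail.
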