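# Methods

## Quantification model

Raw protein-group intensities X_ij (protein i, sample j) are arbitrary-unit
label-free quantifications in which exactly 0 encodes "not detected". Each
sample is normalized to its total intensity and log2-transformed with a
pseudocount of one:

    a_ij = log2( X_ij / Σ_i X_ij × 10⁶ + 1 )

This makes abundances *relative* (parts-per-million of the captured protein
mass), preserves Σ_i (2^a − 1) = 10⁶ per sample exactly, and maps
non-detections to 0. No imputation is performed: zeros enter downstream
tests as 0 log-abundance. This is deliberate — in pulldown data a consistent
non-detection in the control group is the strongest evidence of
enzyme-specific capture, and imputation would erase it — but it means the
per-protein variance is a mixture when detection is inconsistent across
replicates, which costs power at n = 4 (see *Limitations*).

Differential abundance between two sample groups is Welch's unequal-variance
t-test per protein with Welch–Satterthwaite degrees of freedom, two-sided
p-values, and Benjamini–Hochberg adjustment across all proteins of that
comparison. Degenerate rows (zero variance in both groups) return p = 1 when
the means agree and p = 0 with a warning when they differ; the t reference
distribution is undefined there, and these conventions make the
all-zero-control case behave as the strong positive evidence it is.
"Enriched" always additionally requires log2FC > 0.

## Filtering cascades

The somatodendritic (VM) and axonal (STR) proteomes are filtered through
explicit boolean cascades that combine the per-region enrichment statistics
with single-cell RNA-seq evidence; every rule is materialized as a boolean
column in a per-protein trail table so the cascade is auditable.

VM: (1) enriched in VM (q < 0.05); (2a) mean target-cell expression of the
encoding gene at or above the lower expression bound OR (2b) enriched in all
three regions; (3) removed if the gene has very low target-cell specificity.
STR: (1) enriched in STR; (2a) enriched in VM or MFB, OR (2b) log2FC > 1 in
both VM and MFB APEX2+ vs control, OR (2c) expression at or above the upper
bound AND positive specificity vs either reference population; (3a)
expression at or above the lower bound OR (3b) enriched in all three
regions; (4) removed on very low specificity vs either reference.

Decisions that the rule text leaves open, resolved here as package defaults
(all configurable through `FilterConfig`):

- **Expression bounds.** Lower/upper = mean ∓ SD (sample SD) of the
  distribution, over genes with nonzero counts in the target cells, of the
  per-gene mean log2 library-size-normalized expression. A linear-scale
  alternative exists; the log scale is the default because UMI expression is
  closer to log-normal across genes. The same distribution supplies both
  bounds.
- **"Very low specificity".** The phrase is qualitative in the underlying
  protocol; here a gene is flagged when the specificity DE (target neurons
  minus reference cells) has q < 0.05 and log2FC ≤ −1, i.e. the gene is
  significantly ≥2-fold *higher* outside the target population. "Positive
  specificity" (rule 2c) is q < 0.05 with log2FC > 0.
- **Genes absent from the single-cell data** fail expression and specificity
  rules (logged, never an error) but can still pass through the
  all-three-regions routes, mirroring the OR structure of the cascade.

The union of both pass sets partitions into vm_only / str_only / both. The
shared ("both") proteins are compared VM-APEX2+ vs STR-APEX2+ (BH within
that set), yielding region-enriched sets; the inputs to over-representation
analysis are region_only ∪ region_enriched, disjoint by construction, so
their sizes decompose additively. For marker localization the same VM vs STR
comparison is evaluated over the whole filtered union, so markers passing
only one region's cascade still receive a compartment call.

## Single-cell procedures

Cells with fewer than 1000 unique transcripts are removed (a cell with
exactly 1000 is kept). The subsampling-equalized DE between two cell groups
proceeds: (i) downsample the larger group, without replacement, to the
smaller group's size; (ii) binomially thin every count of the deeper group
with retention probability target-mean/group-mean, so mean transcripts per
cell match (the thinning mechanism is a package choice; any scheme with the
right expectation would do); (iii) size-factor normalize — default
library-size factors computed jointly over the pooled cells, with a
median-ratio option; the pooling-based normalization used in the original
single-cell protocol is substituted deliberately, so marker counts on real
data may differ slightly; (iv) per-gene two-sided Mann–Whitney U, asymptotic
with tie correction and *without* continuity correction, so identical groups
give exactly p = 1; genes where every value ties (zero variance) are set to
p = 1; (v) BH across genes. log2 fold changes use a pseudocount of 1 on the
normalized group means; because normalized values are on a
counts-per-mean-depth scale, the pseudocount noticeably shrinks fold changes
of weakly expressed genes, and a true 16-fold marker needs a reference-side
mean of roughly one count to clear the log2FC > 3 selection threshold.
Marker genes require log2FC > 3 *and* q < 0.01, both strict. One subsample
is drawn per comparison; all randomness flows from the caller's seed, and
group membership is canonicalized by sorting barcodes first, so cell order
never affects the result. The binomial cluster-specificity test reports
P(X ≥ k) for X ~ Bin(n_cluster, p_out), with the out-of-cluster expressing
fraction floored at 1/(n_out + 1) to avoid a degenerate zero.

## Integration

Slice/synaptosome concordance counts striatum-filtered proteins with
log2FC > 0 and q < 0.15 in the synaptosome APEX2+ vs control comparison
(the deliberately lenient threshold reflects the n = 2 synaptosome design);
the accompanying Pearson r is computed over the same reference set on mean
log2 abundances of APEX2+ replicates. Heatmap ordering z-scores rows
(constant rows excluded with a warning) and clusters with average linkage on
Euclidean distances (scipy's implementation; ties broken by scipy's
deterministic index convention). Sample PCA is centered, over samples as
observations.

## Synthetic data

The proteomics generator emulates the study design: four biological
replicates per region for APEX2+ and control (two APEX2+ synaptosome
replicates), log-normal base intensities (log2 mean 12.5, SD 0.8), a planted
APEX2-specific set — 800 proteins enriched in all regions (150/250 of them
with a 4-fold VM/STR abundance preference) and 150/80/250 region-specific
proteins — 500 abundant background binders (+5 log2), 720 near-threshold
ambient proteins, a +3 log2 (8-fold) enrichment effect in APEX2 samples,
replicate noise SD 0.5, and logistic detection dropout
P(detect) = σ((a − 14)/0.4) applied per protein and sample. The dropout
midpoint/slope were chosen so the detection profile resembles the emulated
experiment (controls detect mostly the background-binder proteome, ~700 of
2500 groups per sample, vs ~1500 in APEX2+ samples) while APEX2-specific
proteins are usually absent from all control replicates. Enrichment in
synaptosome samples mirrors the striatum. The UMI generator draws per-cell
depths log-normally (median 2500), assigns cells to labeled types (a DA
population, other midbrain types, and striatal types in one matrix — a
simplification of the two separate tissues a real experiment would profile),
and samples counts multinomially from type-specific gene probabilities;
planted markers keep their exact base weight in every type and are
multiplied by the planted fold (default 16) only in the target type, so the
planted fold is the true fold.

What the generator does *not* emulate: peptide-level quantification and
roll-up, intensity-dependent variance structure, batch effects, ambient RNA
and doublets, or correlated gene modules. Passing tests therefore
demonstrate the correctness and calibration of the statistics under the
stated model, not robustness to those real-data pathologies.

## Validation experiments and problem sizes

`proxprot.validate` (used by the test suite and `scripts/acceptance.py`)
runs: normalization conservation on 20 random matrices; oracle agreement of
Welch (closed form), BH (brute-force step-up), hypergeometric (exhaustive
enumeration at N = 10) and Mann–Whitney (exhaustive permutation enumeration
at n = 8 + 8, where the asymptotic p-value is expected to match within a few
thousandths); exact equivalence of the cascades with their boolean formulas
over 1152 input combinations; proteomics null calibration (effect 0, 2000
proteins, two regions × 4 vs 4, 20 seeds; mean flagged fraction at q < 0.05
is ~5 × 10⁻⁴, comfortably under the 1% bound, as expected since BH under a
global null bounds the *probability* of any rejection); single-cell null
calibration (one multinomial, 500 vs 500 cells, 2000 genes, 20 seeds, q <
0.01); planted recovery under the default study design (a planted protein
counts as recovered when called enriched in at least one region it was
planted in — the pipeline-level notion of recovery, since the cascades pool
evidence across regions; sensitivity ≈ 0.85, empirical FDR ≈ 0.001); and
16-fold marker selection over 20 seeds (three markers per seed so the
compositional renormalization of the multinomial stays negligible; rate
1.0). These sizes keep the whole suite under a minute on one CPU while
leaving the Monte-Carlo error of each calibration estimate well below its
acceptance margin.

## Known limitations

- With n = 4 and intensity-dependent dropout, proteins whose control
  abundance straddles the detection limit have inflated Welch variance;
  per-region sensitivity for such proteins is ~0.65 even though
  pipeline-level recovery is ~0.85. Moderated-variance tests would help and
  are intentionally out of scope.
- Total-intensity normalization is compositional: planting (or truly
  having) a large enriched fraction shifts all other proteins' relative
  abundances downward, which both shrinks measured enrichment effects and
  gives unenriched proteins a systematic negative fold change. This is a
  property of the normalization, not a bug, and affects real data equally.
- The subsampled single-cell DE uses one random subsample; results on real
  data reproduce only up to subsampling variability unless seeds match.
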