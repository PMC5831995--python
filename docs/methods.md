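# Methods

## Scope and model

`plantlinc` predicts long intergenic non-coding RNAs (lincRNAs) in plant
transcriptomes. A lincRNA is an lncRNA — a transcript longer than 200 nt
with poor protein-coding capacity — whose genomic locus lies between
protein-coding genes, overlapping no gene body. The package implements the
prediction workflow end to end: feature extraction, data-driven selection
of composition features, an SVM discriminator, a filtering cascade that
combines the classifier with external evidence, and a presence/absence
differential-expression procedure across sequencing libraries. External
heavy lifting (read mapping, assembly, BLAST searches) is consumed as
standard files (BED, FASTA, tabular hits), never executed.

## Features

Each transcript is described by 12 features:

* **ORF length** (nt): the longest open reading frame, ATG through the
  first in-frame stop (TAA/TAG/TGA), stop codon included, scanning the
  three frames of the given strand only. Inputs are oriented transcripts,
  so the reverse strand is not searched. ORFs without a terminating stop
  do not count. Ties between equal-length ORFs resolve to the smallest
  start, then smallest frame. The amino-acid length (`nt/3 − 1`) is
  carried alongside because the classical lincRNA landmark is an ORF
  under 100 amino acids.
* **ORF proportion**: ORF length divided by transcript length; 0 when no
  ORF exists. Captures how much of the transcript is devoted to coding
  potential.
* **10 k-mer frequencies**: overlapping window frequencies of selected
  2–4-mers, normalised per k over windows free of ambiguous bases
  (windows containing non-ACGT characters leave both numerator and
  denominator, so N-rich assemblies do not deflate clean patterns).
  Normalising per k keeps a dimer and a trimer feature on the same scale,
  which is what allows a trimer such as CCC to sit alongside dimers in a
  feature list.

The two published per-organism lists ship as presets (`sugarcane`: AA,
AT, CA, CC, CG, GA, GC, GG, TG, TT; `maize`: AA, AC, CA, CC, CCC, CG, GA,
GC, GG, TG), so prediction can bypass selection exactly as the original
per-organism models did. A trained model archive embeds its own pattern
list and scaling statistics, making predict-time feature extraction
inseparable from training.

## Pattern selection

From all 336 candidate patterns (16 dimers, 64 trimers, 256 tetramers),
`KmerPatternSelector` keeps the patterns that best separate the positive
(lncRNA/lincRNA) from the negative (protein-coding) training set:
frequencies are z-scored over the pooled set (a dimer lives near 1/16, a
tetramer near 1/256; unstandardised PCA would never weight a tetramer),
PCA is run on the standardised matrix, and each component's sample scores
are correlated with the class label (point-biserial). Zero-variance and
rank-deficient (negligible-eigenvalue) components and features are
excluded — the latter carry numerical noise that can fake a correlation.

Two scoring rules rank the features. The default (`scoring="weighted"`)
sums loadings over all components weighted by label correlation times
component standard deviation; algebraically this reconstructs the
projection of the between-class mean-difference vector onto each feature,
i.e. features are ranked by how much they actually separate the classes.
The simpler single-component rule (`scoring="component"`, the absolute
loading on the most label-correlated component) is retained for
comparison but conflates discrimination with within-class covariance: any
feature that merely co-varies with a discriminative cluster inherits its
loading, and on planted-signal benchmarks it recovers roughly half as
many planted features. When no component correlates with the label
(indistinguishable classes) the selector warns and falls back to PC1
loadings.

## Classifier

`LincRNAClassifier` is an RBF-kernel SVM with the libSVM-style protocol:

1. classes balanced to equal size by seeded down-sampling of the larger;
2. stratified 80/20 train/test split (`test_fraction` configurable — the
   published case studies themselves used both 80/20 and 88/12);
3. features z-scored with training-split statistics only (constant
   features flagged and left unscaled);
4. grid search over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}
   (the libSVM practical-guide ranges) by mean 10-fold cross-validated
   accuracy on the training split, ties resolved toward the smallest C
   then smallest γ;
5. refit on the whole training split; hold-out accuracy reported.

The kernel is RBF because C and γ are exactly the RBF hyperparameters the
protocol tunes. Model selection uses accuracy, the protocol's only
reported metric. Everything is deterministic given the seed. At predict
time, transcripts shorter than 4 nt (one tetramer window) receive a
`too_short` sentinel and are excluded from positive sets.

## Filtering cascade

`run_pipeline` applies, in order: removal of transcripts with a
protein/coding-database hit at e-value ≤ `coding_evalue_max` (default
1e-10); the ≥ 200 bp rule (boundary inclusive); an intergenic filter; and
finally the intersection of the SVM-positive set with the set annotated
by similarity to a known lncRNA database (e-value ≤ `lnc_evalue_max`,
default 1e-12). The e-value defaults are package choices exposed in the
configuration — the coding threshold is a conventional conservative
value, the annotation threshold matches the similarity threshold the
differential-expression procedure states.

Intergenic means: at least one genome alignment, and no alignment
overlaps any annotated gene body by ≥ 1 bp, half-open and
strand-agnostic, so an alignment that merely touches a gene boundary
survives. Multi-mapping transcripts must be gene-free at every placement
(the safest reading of "between genes"); unmapped transcripts are
dropped. A `min_gene_distance` option (default 0) covers stricter
readings that require clearance around gene bodies. Gene bodies come from
GFF3 `gene` records (restricted to protein-coding biotypes when biotype
tags are present), indexed per chromosome in interval trees.

The `StageReport` records (stage, input, output) rows; counts are
non-increasing by construction and each stage's input equals its
predecessor's output. The two parallel calls feeding the intersection are
reported as side fields (`svm_positive_count`, `lnc_annotated_count`) so
the linear chain invariant holds. Two layouts mirror the published case
studies: `generic`/`sugarcane` apply the coding filter to raw input;
`maize` consumes already-assembled consensus transcripts and enters at
the length filter.

## Differential expression

Predicted lincRNAs from all libraries are pooled with library-qualified
row ids (`library:transcript`; near-identical sequences from two
libraries are deliberately distinct rows). From an all-vs-all similarity
search of the pool, a boolean presence matrix (pooled lincRNAs ×
libraries) is built: a row is present in a library when its home library
is that column, or when it has a hit at e-value ≤ 1e-12 (inclusive) to a
sequence predicted there. Presence uses the query→subject direction;
self-presence is forced regardless of hits. A row is called
differentially expressed when it is present in at least one library of
one condition (treated/control) and absent from every library of the
other — symmetric in the two conditions. With an empty hit table every
row is trivially differential (present only at home), which bounds the
maximal count. `naive_similarity_hits` is test plumbing only: it emits a
synthetic hit for every ordered pair of sequences sharing an exact
substring of a configurable length, standing in for an external
similarity search in fixtures.

## Synthetic data generator

The generator produces every input the workflow consumes and defines the
conditions under which the package is validated.

**Labeled classes.** Negatives (protein-coding-like) carry a
sampled-codon ORF — ATG, interior codons drawn from the 61 non-stop
codons, a stop — of at least 100 amino acids, spanning ≥ 60–90% of the
transcript, flanked by uniform UTR-like sequence. Positives
(lincRNA-like) are background sequence with planted k-mer biases whose
longest ORF is capped below the 100-aa landmark by replacing a
mid-ORF codon with a stop until the cap holds. The two classes are
therefore separable by the ORF features alone at the 100-aa boundary — a
constructed, asserted property. A `relax_orf_ceiling` flag drops the cap
to emulate training on a looser lncRNA positive set. Default sizes are
1000–2000 sequences per class of 400–1200 nt, the scale of the published
training sets (2000 and 4000 per class).

**Planted composition biases.** Enrichment is planted by selection
re-weighting, a finite-pool approximation to exponential tilting: K
candidate sequences (default 12) are drawn uniformly and one is sampled
with probability ∝ exp(score), where the score sums standardised planted-
pattern counts weighted by log multiplier. Enrichment arises purely by
selection, so non-planted patterns shift only through their natural
overlap covariance with planted ones. Constructive alternatives were
measured and rejected: re-weighted transition probabilities are
renormalised into a stationary-composition shift that dilutes the planted
dimers themselves; overwriting or concatenating pattern copies conserves
window counts locally and therefore concentrates compensating depletion
on specific non-formable patterns at planted-signal magnitude,
independent of the effect-size scale. The default planted set (CC, TT,
ACC, AGC, ATT, CCA, CTC, GAA, GTT, TTG) and its multiplier ratios were
chosen against the empirical 336×336 count-correlation matrix of uniform
sequences — counts of a k-mer and a containing (k+1)-mer correlate at
exactly √(E₍ₖ₊₁₎/Eₖ) = 0.5, so an unconstrained set lets neighbours
inherit tilt shifts as large as the planted ones. The chosen set gives
every planted pattern an equal unit shift with the worst non-planted
pattern at 0.70 of it. The tilt strength grows with both the multipliers
and K; K = 1 disables planting, which serves as the zero of the
effect-size dial.

**Toy genome.** One chromosome with non-overlapping genes (300–800 bp,
gaps ≥ 900 bp); each transcript is placed either overlapping a gene body
or strictly inside a gap, per an exact genic fraction; transcript
sequences are cut from the genome; BED alignments and a truth manifest
accompany them.

**Cascade fixtures.** `gen_cascade_fixture` builds an input where every
stage count is forced by construction: designated groups carry a strong
coding hit, are under 200 nt, map inside the gene, or survive to the
parallel calls with designated SVM-positive and annotated subsets of a
chosen overlap. The SVM branch uses a deterministic designated-positive
predictor (test plumbing) so the final count equals the constructed
overlap exactly.

**What the generator does not emulate.** Real transcriptomes have
codon-usage and GC biases, UTR composition structure, repeat content,
sequencing and assembly artifacts, and isoform redundancy; none are
modelled. Passing tests therefore demonstrate that the implementation is
correct under its stated statistical assumptions — not that the published
per-organism accuracies transfer to any particular dataset, which depends
on external training data and databases.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere internally; GFF3 (1-based
  closed) is converted at the parse boundary; BED passes through.
* Similarity-hit tables follow the standard 12-column tabular layout;
  extra columns are ignored; all e-value comparisons are inclusive (≤).
* ORF ties: smallest start, then smallest frame. Sequences with no
  complete ORF yield length 0 and proportion 0.
* k-mer sums over each k equal 1 within 1e-9 whenever at least one valid
  window exists; with none (short or fully ambiguous sequences) all
  frequencies are 0.
* Selection requires ≥ 2 members per class; grid-search ties prefer the
  smallest C then γ; evaluation on a single-class input reports the
  undefined rate as NaN with a warning rather than failing.
* A cascade stage with zero survivors completes the run with an empty
  final set and a warning, never an error.

## Problem sizes used in validation

The test suite and the acceptance script regenerate all inputs at run
time: 1000 random sequences (lengths 1–600, with and without ambiguous
bases) for the ORF oracle; 1000 sequences for frequency normalisation;
1000+1000 for planted-pattern recovery; 2000+2000 with the full default
grids for the separable-accuracy protocol and 100+100 over 10 seeds for
the no-signal null; 50 randomised cascade fixtures plus the forced-count
fixture; 1000 random presence matrices for the differential rule. These
sizes were chosen to match the published training scale where one is
stated and to keep every quantity's sampling error far from its
acceptance margin otherwise.
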