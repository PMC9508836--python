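# Methods

## Problem and approach

A de novo mutation (DNM) is a variant carried by a child but by neither
parent. Selecting child variants absent from the parents' VCFs is easy;
the hard part is telling true DNMs from sequencing errors, mapping
artifacts and missed parental calls. `denovotrio` treats that decision the
way a human analyst does when staring at a read pileup in a genome
browser: the trio's reads around the candidate site are rendered as an
image and classified visually — here by a convolutional network — or,
alternatively, by a deterministic rule on parental read support.

Prediction is two-stage:

1. **Candidate generation.** Child VCF records are split into biallelic
   records, the shared prefix/suffix bases of each allele pair are
   trimmed, and every record whose `(contig, position, ref, alt)` key
   appears in either parent's VCF is discarded (allele-aware set
   subtraction, equivalent to `bcftools isec -C child father mother` on
   normalized inputs; the oracle tests verify this equivalence).
   Parental genotype fields are ignored at this stage — presence of the
   record suffices; evidence-level scrutiny happens in stage two.
2. **Classification.** For each candidate, reads from all three alignment
   files overlapping the 41-position window centred on the site are
   extracted and either encoded as an image and scored by the CNN for the
   candidate's variant type, or passed through the rule-based caller.
   A candidate is called de novo when the DNM probability is >= 0.5
   (inclusive).

## Image encoding

Each site becomes a 160 x 164 x 3 `uint8` tensor:

* **Columns**: 41 genomic positions x 4 pixels, a one-hot block over
  (A, C, T, G). The variant's first base sits in block 20 (0-indexed),
  i.e. columns [80, 84).
* **Rows**: one read per row, capped at 160 reads. Read order is the
  deterministic extraction order (leftmost alignment position, then read
  name), so encoding is reproducible; read-order randomisation is an
  explicit training augmentation, never an inference behaviour.
* **Channels**: child, father, mother.
* **Intensity**: `round(255 * min(1, bq/40) * min(1, mq/60))` with
  half-up rounding — Phred base quality capped at 40 and mapping quality
  at 60, common Illumina maxima. Both caps are `IntensityModel` fields.

Indels are rasterised in read coordinates anchored so that the read base
aligned to the variant position lands in block 20: inserted bases consume
the following blocks (a visible frameshift against non-carrier reads),
and deleted reference positions render as all-zero blocks inside the
read's span. Reads overlapping the window but not the variant anchor by
the reference offset of their leftmost in-window base. Soft-clipped
bases are not reference-aligned and are not rendered; `N` bases and gaps
light no pixel (there is no one-hot slot for them). Duplicate,
secondary, supplementary and QC-fail reads are excluded, as in standard
pileup practice. Coordinates are 0-based half-open internally; VCF
positions convert on read.

## Classifier

Per variant type (substitution / insertion / deletion) one instance of
the same architecture: nine 2D convolutional layers (96 filters, 3x3
kernels, stride 1, size-preserving padding, ReLU), with batch
normalization followed by a squeeze-and-excitation block after every
third convolution; the head concatenates global max and global average
pooling and feeds a single sigmoid unit with an L1 penalty. The SE
reduction ratio defaults to 16 (the canonical value), with the
bottleneck floored at one unit. The output is reported as the DNM
probability p; the inherited-variant probability is 1 - p.

The network stack (convolution, batchnorm, SE gating, pooling head,
Adam/AdamW, manual backprop) is implemented directly on numpy in
`denovotrio.nn`; convolutions are computed as nine shifted channel
matmuls through BLAS. A finite-difference gradient check in the test
suite validates the backward pass end to end.

**Training.** Binary cross-entropy, Adam for the substitution model and
AdamW (decoupled weight decay) for the indel models, which warm-start
from the trained substitution weights. Initial learning rate decays by
0.5 every 10 epochs (`lr(e) = lr0 * 0.5^floor(e/10)`, e 0-based). Up to
100 epochs with early stopping once 40 epochs pass without validation
improvement; the returned weights are those of the best-validation
epoch. Default lr 1e-3, L1 1e-6, batch 32 — package defaults, as the
per-network optima of the original hyperparameter search are not
published in the main text. Hyperparameter search is provided as seeded
random search over the documented space (filters in {32,64,96,128},
batch in {32,64}, L1 in [1e-10, 0.1], lr in [1e-8, 0.01], weight decay
in [1e-8, 0.01]; continuous values log-uniform), selecting the lowest
validation cross-entropy. A bandit-style multi-fidelity scheduler was
deliberately not implemented: at desk-scale budgets plain random search
explores the same space reproducibly.

**Augmentation** (training only): global brightness scaling by a factor
uniform in [0.3, 1]; read-row shuffling; coverage downsampling by random
read discard (at least one read kept per non-empty member); and
multi-nucleotide-variant synthesis, which writes a second, consistent
substitution into the alt-carrying reads at the adjacent window offset —
applied at the window level, before encoding, so quality values remain
realistic, and preserving the inheritance pattern so the label is
unchanged. Brightness is applied globally rather than per-channel:
per-channel scaling would imitate per-individual coverage/quality
differences already produced by the simulator, while global scaling
models overall exposure variation without breaking cross-channel
intensity comparisons.

## Rule-based caller and hard filters

The deterministic caller passes a candidate iff both parents have depth
>= 10 and either zero parental alt reads, or parental VAF <= 15% with
fewer than 3 alt reads in each parent. Population-frequency gates:
exome mode requires gnomAD AF < 1%; genome mode AF < 0.1% plus upstream
caller quality > 15. The high-quality post-filter requires depth >= 10
in all three members, child VAF >= 20% and AF < 0.01%. All inequalities
are implemented exactly as stated (inclusive/exclusive as printed), and
every threshold is an overridable `FilterThresholds` field. Missing
population frequencies count as 0 (novel). Depth counts primary,
non-duplicate reads spanning the position with mapping quality >= 1;
alt support requires the aligned bases to match the alt allele
(CIGAR-consistent for indels). The VAF > 30% preset used for training-
corpus construction is available via `FilterThresholds` overrides but is
not part of the calling path.

## Synthetic data

The generator emulates the evidence the caller consumes — not a
sequencing instrument. Per member, read count ~ Poisson(depth); 101 bp
ungapped single-end reads placed uniformly so every read spans the
variant; carrier reads receive the alt allele (substitution, insertion
or deletion with proper CIGARs) at the member's allele fraction:
child 0.5 for germline DNMs (< 0.5 for mosaic presets), carrier parents
0.5 for inherited modes, and an "artifact" mode that scatters
low-quality (base ~Q12, MAPQ 20) alt reads at ~10% fraction across all
three members. Base qualities ~ N(38, 3) clipped to [2, 41]; mapping
qualities ~ N(58, 3) clipped to [0, 60]; uniform per-base error 1e-3.
Everything derives from one integer seed. Sites can be written as
indexed BAM + per-member VCF + FASTA fixtures that round-trip through
the extraction code bit-for-bit (a property test).

What the simulator does **not** model: alignment ambiguity in repeats
and segmental duplications, strand bias, indel error hotspots, GC
coverage waves, platform-specific error spectra, or joint-calling
artifacts. Passing the synthetic studies therefore demonstrates that
the mechanism is implemented correctly and recovers planted signal
under clean conditions — not that real-cohort accuracy would match; the
published real-data accuracies require the original cohort and trained
weights and are out of scope here.

## Evaluation

Confusion tables are counted over a shared candidate key set with DNM as
the positive class; sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
precision = tp/(tp+fp), accuracy = (tp+tn)/total, reported as
percentages rounded half-up to 2 decimals (the convention that
reproduces every printed cell of the published comparison tables — the
test suite replays all 20 rows). Metrics with zero denominators are
reported as absent, never as 0. Per-variant-type breakdowns recompute
the same metrics inside each type partition.

## Problem sizes and numerical choices

The synthetic studies in `denovotrio.benchmarks` (also run by
`scripts/acceptance.py`) use: a 200-site trio at 30x for the rule-based
recovery study, and 2000 training / 400 held-out images for the CNN
study. The CNN study trains a scaled-down instance of the architecture —
3 convolutional layers of 8 filters with a single batchnorm+SE stage,
lr 3e-3, batch 32, at most 6 epochs — chosen so the study runs in
minutes on one CPU core with the pure-numpy engine; the encoding, loss,
schedule, early stopping and best-epoch selection are identical to the
full 9-layer/96-filter configuration, which the same code builds and
which the unit tests construct and differentiate.

Other numerical choices: half-up rounding for intensities and metric
percentages; ties in global max pooling route the gradient to the first
argmax; batchnorm uses momentum 0.9 running statistics for inference;
the logistic loss uses the log1p(exp(-|z|)) formulation; empty read
lists encode as all-zero images; zero-depth members give VAF 0.

## Known limitations

* VCF normalization trims shared allele prefix/suffix bases but does not
  left-align indels against the reference FASTA; records produced by
  different callers for the same indel in a repeat tract may fail to
  match. Inputs normalized with `bcftools norm` are recommended.
* Soft-clipped bases are never rendered; evidence living entirely in
  clipped sequence is invisible to the classifier.
* The rule-based caller needs parental coverage >= 10 and therefore
  cannot call DNMs in low-coverage regions the CNN might still handle.
* The numpy training engine is single-process and CPU-bound; training
  the full-size network on a large corpus is out of its intended scope.
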