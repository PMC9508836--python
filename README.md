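# denovotrio

De novo mutation (DNM) calling from child–father–mother sequencing
trios. Variants private to the child are taken from the trio's VCFs by
allele-aware subtraction; each candidate's read pileup is then judged
either by a convolutional neural network that reads the trio alignment
as an image, or by a deterministic rule on parental read support. The
package is aimed at rare-disease and trio-sequencing analysts who have
per-sample BAM/CRAM + VCF files from any upstream caller and want DNM
calls without re-calling variants.

## Method

**Stage 1 — candidates.** Child VCF records are split to biallelic,
allele-trimmed keys; any key present in a parent VCF is discarded
(equivalent to `bcftools isec -C child father mother`). Each surviving
candidate is routed by allele length to one of three variant classes:
substitution, insertion, deletion.

**Stage 2 — classification.** Reads overlapping the 41-position window
around the candidate are encoded as a 160 × 164 × 3 image: one read per
row (first 160 kept), 4 one-hot columns per genomic position over
(A, C, T, G), channels = (child, father, mother), and pixel intensity

    I = round(255 · min(1, bq/40) · min(1, mq/60))

so high base and mapping quality saturate at 255. The variant's first
base occupies column block 20 — the window centre. A per-variant-type
CNN (nine 3×3 conv layers, 96 filters, squeeze-and-excitation blocks
after every third layer, global max+avg pooling head, sigmoid output)
maps the image to a DNM probability p; the call is *de novo* when
p ≥ 0.5. Alternatively, `--rule-based` applies the hard filter: both
parents ≥ 10× and either zero parental alt reads, or parental VAF ≤ 15%
with < 3 alt reads each.

Scoring uses the standard confusion-table metrics (sensitivity,
specificity, precision, accuracy, F1) with DNM as the positive class.

The CNN engine (convolutions, batchnorm, SE gating, Adam/AdamW, manual
backpropagation) is implemented directly on numpy — no deep-learning
framework is required. See `docs/methods.md` for the full model
description, training schedule, augmentations and limitations.

## Worked example

Simulate a 10-site trio (5 planted de novo substitutions, 5 inherited),
call DNMs with the rule-based path, and score against the simulation
truth:

```sh
denovotrio simulate --n-sites 10 --denovo-fraction 0.5 --depth 20 \
    --seed 5 -o fixture/
denovotrio predict \
    --child-bam fixture/child.bam --child-vcf fixture/child.vcf \
    --father-bam fixture/father.bam --father-vcf fixture/father.vcf \
    --mother-bam fixture/mother.bam --mother-vcf fixture/mother.vcf \
    --rule-based -o calls.tsv
denovotrio evaluate --calls calls.tsv --truth fixture/manifest.json
```

which prints

```
wrote 10 sites to fixture/
INFO denovotrio.pipeline: 5 candidate sites after parental subtraction
INFO denovotrio.pipeline: candidates per type: {'substitution': 5}
5 candidates -> calls.tsv; 5 DNM calls
 tp  fp  tn  fn  sensitivity  specificity  precision  accuracy
  5   0   5   0        100.0        100.0      100.0     100.0
```

The 5 inherited sites are removed by parental subtraction, the 5 de novo
sites survive and pass the parental-evidence filter, and the confusion
table against the manifest truth is perfect — the expected outcome for
clean, well-covered synthetic data. `calls.tsv` holds one row per
candidate: site key, variant type, DNM probability, label, and the
rule-based / high-quality filter verdicts.

Training CNNs on simulated data works the same way
(`denovotrio train --fixture-dir fixture/ -o models/`, then
`predict --models models/`); the substitution network trains first and
the indel networks warm-start from its weights.

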