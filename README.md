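# dualgenome

Joint two-genome sequence-to-signal modeling at desk scale: train one dilated
residual convolutional network on functional-genomics coverage tracks from two
species simultaneously, with homology-aware leakage-free train/validation/test
splits, then use it for allele-difference variant effect scoring, cross-species
transfer evaluation, and case/control variant statistics. A synthetic
two-species benchmark with a shared regulatory grammar makes the whole pipeline
testable on one CPU without external data.

The network (motif tower of conv/batch-norm/GELU/max-pool blocks, eleven-style
dilated residual stack, per-genome softplus heads; Poisson loss on the cropped
center; reverse-complement and small-shift augmentation; SGD with momentum and
early stopping) is implemented in pure NumPy with hand-written backward passes
(`dualgenome.nn`), verified against finite differences in the test suite — no
deep-learning framework is required.

## Layout

| module | role |
| --- | --- |
| `dualgenome.synthetic` | two-species benchmark generator: genomes with homologous blocks, motif grammar, CAGE-like / accessibility-like truth tracks, planted variants with exact generative effects |
| `dualgenome.split` | genome tiling, bipartite homology graph (> min aligned bp edges), connected components, leakage-free partitioning, leakage audit |
| `dualgenome.prep` | coverage preprocessing (negative clip, blacklist masking to the 25th percentile, replicate averaging, 128-bp binning, soft clip `min(x, t_c + sqrt(max(0, x - t_c)))`), sequence encoding, interval tiling at the half-length-plus-63 stride, HDF5 example containers |
| `dualgenome.model` | the architecture: geometric filter schedule (288 → 768 at full scale), dilated residual stack, per-genome heads; checkpoints; windowed saliency |
| `dualgenome.training` | Poisson loss on center crops, augmentation cycling, proportional genome batching, joint training, per-genome fine-tuning, per-dataset Pearson evaluation |
| `dualgenome.variants` | signed alt-minus-ref variant scores, forward/reverse-complement/shift ensembles, score tables with TSV + signed-annotation export |
| `dualgenome.transfer` | quantile normalization, log transform, top-variable selection, row mean-centering, matched/mismatched cross-species correlation matrices |
| `dualgenome.analyses` | splice-distance filtering, 10-bp cluster thinning, ~1-kb matched negatives, repeated 8-fold random-forest CV, eQTL effect summarization, proband/sibling Mann-Whitney tests with BH FDR, per-individual risk scores with exact binomial tests |
| `dualgenome.benchmark` | end-to-end wiring of all of the above on the synthetic pair (used by the acceptance suite) |

## CLI

```bash
dualgenome synth --out-dir bench --n-chrom 2 --chrom-len 1048576 --seed 1
dualgenome split --sizes-a a.sizes --sizes-b b.sizes \
    --alignment bench/alignment.net.tsv --tiles 1000000 --min-aligned 100000 \
    --valid 0.12 --test 0.12 --seed 1 --out-dir splits
dualgenome prep --genome bench/genome_A.fa --genome-id A --manifest manifest.tsv \
    --split-bed splits/split_A.bed --length 131072 --out data_A.h5
dualgenome train --data-a data_A.h5 --data-b data_B.h5 --joint --out model.h5
dualgenome score --checkpoint model.h5 --genome bench/genome_A.fa --genome-id A \
    --vcf variants.vcf --out scores.tsv
dualgenome transfer-eval --obs obs.tsv --pred pred.tsv --pairs pairs.tsv \
    --top 0.5 --log --out corr.tsv
dualgenome negatives --vcf pathogenic.vcf --genome genome.fa \
    --splice-sites splice.bed --out negatives.vcf
dualgenome classify --features features.tsv --folds 8 --iterations 200 --out aurocs.tsv
dualgenome denovo --proband proband_scores.tsv --sibling sibling_scores.tsv --out tests.tsv
```

Alignments are accepted as the package's simple net-dialect TSV
(`chromA startA endA chromB startB endB strand aligned_len`, 0-based
half-open) or as plain-text UCSC chain files.

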