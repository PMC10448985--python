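# cdscan

Nucleotide-level *ab initio* coding-sequence (CDS) prediction from genomic
DNA, in three stages:

1. **Sensors** — 16 window-based features per nucleotide (centered window of
   W = 69 nt): a period-3 DFT magnitude over Voss-encoded tracks, five k-mer
   log-likelihood sums (k = 2..6) against coding/noncoding frequency tables,
   GC content, eight distance-to-motif features (ATG start, TAG/TAA/TGA stop,
   YAG acceptor, GT donor; left/right of the center), and a window entropy.
2. **Classifier** — a small feed-forward SELU network (16 → 10 → 2,
   unnormalized output scores) trained on class-balanced samples with five
   disjoint 80/20 folds; per-nucleotide argmax gives *initial* predictions.
3. **Consensus** — every motif-bounded *potential CDS* (ATG/YAG on the left,
   GT/stop on the right, interior length strictly between Lmin = 40 and
   Lmax = 400) is scored by its N1/N0 ratio of initial predictions; regions
   above a threshold are flipped entirely to coding (longest first, regions
   contained in an accepted region are skipped), everything else to
   noncoding. The threshold can be fixed or chosen by sweeping until the
   predicted coding fraction falls to a target (+ 0.1 margin by default).

A synthetic-genome simulator (`cdscan.simulate`) plants multi-exon genes with
legal boundary motifs and a tunable codon-usage contrast, so the whole
pipeline is testable without downloads. Evaluation (`cdscan.evaluation`)
reports nucleotide-level Sn, Sp, BA, PPV, MSP and F1.

## Command line

```bash
# make a fixture genome (FASTA + GFF3 + gene table)
cdscan simulate --length 200000 --coding-fraction 0.2 --bias 0.8 --seed 1 \
    --out-prefix demo

# train: estimates k-mer tables, featurizes, balanced-samples, trains 5 folds
cdscan train --fasta demo.fasta --gff demo.gff3 --n-samples 100000 --seed 1 \
    --out model.json

# predict with a fixed CDS/non-CDS threshold ...
cdscan predict --fasta demo.fasta --model model.json --threshold 1 \
    --out-bed pred.bed --out-track pred.tsv

# ... or auto-tune the threshold toward an expected coding fraction
cdscan predict --fasta demo.fasta --model model.json --target-fraction 0.2 \
    --out-bed pred.bed --out-track pred.tsv

cdscan evaluate --pred-track pred.tsv --truth-gff demo.gff3 --out report.json
```

Also available: `estimate-tables` / `featurize` (cache k-mer CSVs and feature
TSVs between stages), `sweep` (threshold-sweep trajectory as CSV),
`run --config cfg.json` (multi-stage runs from one config file), and
`predict --scan-reverse` (additionally scan the reverse complement and union
the predictions).

Coordinates are 0-based half-open internally and in BED output; GFF3 I/O
converts at the boundary. The model archive (`model.json`) bundles the fold
weights, per-fold standardization statistics, the k-mer tables and the sensor
configuration.

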