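# bindsignal

Base-resolution TF–DNA binding-signal regression from DNA sequence with a
symmetric fully-convolutional encoder/decoder (conv blocks + BiGRU + global
average pooling on the way down; bilinear upsampling + additive skips +
blending blocks on the way up). From one trained regression model the
package derives:

- **signal regression** — per-base predicted signal for sequences of
  arbitrary length (inputs are N-padded to the model's length multiple and
  trimmed back);
- **classification** — binding probability as `sigmoid(max(signal))`;
- **localization** — fixed-width regions around the signal argmax, and
  whole-chromosome scanning with a max-signal threshold;
- **motif extraction** — PFMs built from maximal-activation k-mers of the
  best first-layer convolution filter over high-signal 100-bp regions,
  written in minimal MEME format;
- **SNP scoring** — `|alt − ref|` predicted signal at the variant position;
- **openness** — `log10(1 + overlapping-read count)` per region.

The network, backpropagation and Adam training loop are implemented in pure
NumPy (no GPU frameworks required); every backward pass is checked against
finite differences in the test suite.

## Quick start (synthetic end-to-end)

```sh
# generate a motif-planted dataset with per-base signal tracks
bindsignal simulate --n-pos 1000 --n-neg 1000 --seed 1 --out data/

# train (add --search 15 for the random hyperparameter search)
bindsignal train --data data/ --seed 1 --epochs 10 --batch-size 16 \
    --out model.ckpt

# downstream tasks
bindsignal predict  --model model.ckpt --fasta query.fa --out signal.tsv
bindsignal classify --model model.ckpt --fasta query.fa
bindsignal locate   --model model.ckpt --fasta query.fa --out regions.bed
bindsignal scan     --model model.ckpt --fasta chr.fa --threshold 1.5 \
    --width 60 --out hits.bed
bindsignal snp      --model model.ckpt --fasta genome.fa \
    --vcf-like snps.tsv --out scores.tsv
bindsignal openness --peaks peaks.bed --reads reads.bed --out openness.tsv
bindsignal motif    --model model.ckpt --data data/ --out motif.meme
```

Real data enters through `bindsignal prepare` (FASTA genome + BED peaks +
bedGraph signal): peaks are expanded to 1000 bp around their summits,
negatives are placed 3000 bp upstream with their real (low) signals, and
signals are normalized by `log10(1 + v)`.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the end-to-end acceptance suite; it
trains one full synthetic model (several minutes on one CPU) shared across
the recovery/benchmark/motif/SNP criteria.

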