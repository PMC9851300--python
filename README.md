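# ltrnet

Neural detection, curation and lineage classification of
LTR-retrotransposons (LTR-RTs) in plant genome assemblies.

LTR-RTs — Class I transposable elements flanked by two near-identical
long terminal repeats — are the dominant repeat family in plant genomes.
Building a *library* of intact, lineage-classified elements is the first
step of genome annotation, and the slow step of most repeat pipelines.
`ltrnet` is for genome/repeat annotators who want that library built
quickly from an assembled genome, with every prediction carrying
explicit probabilities.

## Method

The pipeline combines four neural components with a structure-based
candidate finder:

1. each sequence is cut into non-overlapping 50 kb windows and one-hot
   encoded (5×n, rows A,C,T,G,N); a CNN keeps only windows predicted to
   contain an element;
2. a seed-and-extend direct-repeat finder locates paired LTRs inside
   retained windows and applies the structural filters: element length
   in [2000, 28000] bp, TG…CA termini, 4–6 bp target-site duplication;
3. k-mer frequencies (1 ≤ k ≤ 6; 4¹+4²+…+4⁶ = 5460 dimensions) of each
   candidate are computed by a fixed-weight convolution — the filter of
   k-mer *m* is the one-hot matrix of *m* with bias 1−k, so rectified
   feature-map sums are exact counts — then PCA-reduced and scaled;
4. an FNN filters non-intact elements (nested insertions, length
   violations, Class II insertions) and a second FNN classifies intact
   elements into 13 lineages;
5. predictions pooled over 1–5 shifted windowing cycles are reduced by
   non-maximal suppression: if two predictions overlap with
   IOU = max(0, min(Y1,X1) − max(Y0,X0)) / (max(Y1,X1) − min(Y0,X0)) > 0.6,
   only the one with the higher score s = (p_detect + p_intact +
   p_lineage)/3 is kept.

Outputs are a FASTA library (`{id}_{start}_{end}#LTR/{lineage}`) and a
TSV table (`ltrnet_predictions.tab`) with the three probabilities and
their mean per element.  No pre-trained weights ship with the package;
models are trained with the built-in commands, on synthetic corpora or
on your own labelled data.  See `docs/methods.md` for the full model
description.

## Worked example

Train a bundle on synthetic data, simulate a genome with ten implanted
elements, and run the pipeline:

```sh
ltrnet train-synthetic -o models/demo --seed 11
ltrnet simulate genome -o sim --length 500000 --implants 10 --seed 11
ltrnet run -f sim/genome.fasta -o out --bundle models/demo -C 1 -c yes
```

The training command prints the held-out accuracy of each network, e.g.

```
bundle saved to models/demo (held-out accuracy: detector 1.000, filter 0.925, classifier 1.000)
```

and the run prints the library size:

```
9 elements written to out
```

`out/ltrnet_predictions.tab` then holds one row per retained element —
coordinates (1-based inclusive), lineage, the three network
probabilities and their mean, e.g.

```
source_id  start   end     lineage    detect_prob  intact_prob  lineage_prob  combined_score
seq1       23613   26465   RLC_Ale    1.000000     0.844759     0.997298      0.947352
```

Comparing `out/ltrnet_library.fasta` with `sim/truth.tsv` shows which
implants were recovered; a tenth implant deliberately straddling a 50 kb
window boundary needs a second cycle (`-C 2`).

The same pipeline is available as a library:

```python
from ltrnet import ModelBundle, run_pipeline
preds = run_pipeline("genome.fasta", ModelBundle.load("models/demo"), cycles=2)
```

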