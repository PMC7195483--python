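# spikechip

Quantitative, spike-in calibrated ChIP-seq analysis for yeast-scale
genomes: barcode demultiplexing, dual-genome exclusive read assignment,
spike-in normalization factors, fragment-extended SPMR coverage tracks,
and TSS-anchored heatmap/metagene matrices — plus a synthetic-data
generator that emulates the full experimental design with known ground
truth, so every stage of the pipeline can be verified quantitatively.

## The problem

Standard ChIP-seq normalization (signal per million reads, SPMR) removes
*global* differences between samples: if a mutant reduces a histone mark
everywhere by 5-fold, per-million scaling largely hides it.  The remedy is
a spike-in: a fixed mass of foreign-species chromatin (here a fission-yeast-like
genome at 10% of the budding-yeast-like experimental chromatin)
added to every sample before immunoprecipitation.  Because the spike-in
chromatin is identical across samples, the fraction of reads it captures
reports each library's global pull-down efficiency.

After demultiplexing (in-line barcodes, one mismatch allowed), reads are
aligned sequentially — spike genome first, then the experimental genome —
keeping only reads *exclusively and uniquely* placed on one genome (the
first base is excluded from matching and multi-aligned reads are
dropped).  With $p_\text{input}$ and $p_\text{IP}$ the spike read
proportions of the input and IP libraries, each IP sample's calibration
factor is

$$ f \;=\; \frac{p_\text{input}}{\sqrt{p_\text{IP}}} $$

where the square root compensates for the per-library SPMR scaling of the
coverage tracks.  Tracks are built by removing duplicate reads (same
chromosome, 5′ position and strand), extending each tag to 150 bp in its
3′ direction, scaling to SPMR, and multiplying IP tracks by $f$.
Calibrated signal is then summarized as genes × bins matrices over
[TSS, TSS+1500 bp), ordered by wild-type signal, averaged into metagene
anchor profiles, and contrasted between conditions as difference
matrices.

## Worked example

The factor arithmetic from exclusive assignment counts:

```sh
$ spikechip normfactor --input-counts 100000 900000 --ip-counts 40000 960000
p_input	0.1
p_ip	0.04
factor	0.5
```

A spike proportion of 0.1 in the input and 0.04 in the IP give
$f = 0.1/\sqrt{0.04} = 0.5$: the IP library captured proportionally more
experimental chromatin than the input predicts, so its track is scaled
down by half.

A complete simulated experiment runs from one YAML file:

```yaml
# run.yaml
outdir: out
seed: 1
simulate: {}            # use the default simulated design
samples:
  - {name: input1, barcode: AACCGG, kind: input, condition: none}
  - {name: WT_IP,  barcode: CCGGTT, kind: IP, condition: WT,
     efficiency: 1.0, input_sample: input1}
  - {name: mut_IP, barcode: TTAACC, kind: IP, condition: mut,
     efficiency: 0.2, input_sample: input1}
params: {order_by: WT}
```

```sh
spikechip run run.yaml
```

This simulates multiplexed FASTQ reads over two generated genomes,
demultiplexes, assigns, normalizes, builds raw/SPMR/calibrated bedGraph
tracks, and writes signal matrices, anchor profiles and condition
difference matrices under `out/`, with a checksummed `manifest.json`.
Reads can also be supplied from real data via an `inputs:` block naming
FASTA genomes, a BED6 gene list and a FASTQ (or per-stage via SAM/BED
with `spikechip assign` and the library API).

On the default simulated design (6 Mb experimental genome, 1.2 Mb spike
genome, 260 genes, 200,000 reads per sample, seed 1) the full validation
experiment prints:

```
calibrated_efficiency_ratio_mut50: 0.5333 (n=200000)
calibrated_efficiency_ratio_mut20: 0.2107 (n=200000)
spmr_efficiency_ratio_mut50: 0.5492 (n=200000)
spmr_efficiency_ratio_mut20: 0.224 (n=200000)
anchor_profile_spearman: -0.9773 (n=60)
row_order_spearman: 0.9387 (n=260)
```

The spike-calibrated tracks recover the programmed global efficiency
ratios (0.5 and 0.2) to within a few percent, while the uncalibrated SPMR
ratios are biased toward 1; the metagene profile decays monotonically
from the TSS and the heatmap row order tracks the true per-gene
enrichment amplitudes.

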