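# trnacharge

Quantify tRNA aminoacylation ("charging") from barcoded paired-end
sequencing of periodate-treated tRNA libraries.

Charged tRNAs carry an amino acid on their 3'-terminal adenosine, which
protects the end from NaIO4 oxidation; uncharged tRNAs are oxidized and
lose the terminal A to β-elimination.  After adapter ligation and
sequencing, a tRNA fragment ending `...CCA` was charged and one ending
`...CC` was uncharged, so the per-isodecoder fraction charged

    f = charged / (charged + uncharged)

can be read directly off the 3' ends of aligned read pairs.  Uncharged
tRNA accumulation is the activating signal of the GCN2 arm of the
integrated stress response, which is the kind of biology these libraries
are made to probe.

The package is aimed at people analysing such libraries (or validating an
analysis) without wanting to re-derive the bookkeeping: it implements
inline-barcode demultiplexing, adapter trimming with an empty-adapter
filter, exhaustive local alignment against a deduplicated CCA-appended
tRNA reference, the CCA/CC charging call, depth normalization
(`coefficient = mean reads across samples / reads in sample`), isodecoder
aggregation, replicate summaries (mean ± SD), and Welch's unpaired t-test
with Benjamini-Hochberg FDR across isodecoders per contrast — plus a
seeded synthetic-library simulator with ground truth, so the whole
pipeline is testable without any download.  See `docs/methods.md` for the
model and its assumptions.

## Worked example

Run a simulated study (3 conditions × 4 replicates, 5,000 read pairs per
sample; His-GTG charging depressed by GCN2 inhibition and restored by
amino-acid supplementation) end-to-end from one config:

```yaml
# demo.yaml
seed: 7
outdir: demo_out
simulate: {reads_per_sample: 5000, n_isodecoders: 6}
contrasts: ['GCN2iB:vehicle', 'GCN2iB_EAA:GCN2iB']
```

```sh
trnacharge run --config demo.yaml
```

prints, among the per-sample diagnostics and condition summaries:

```
trnacharge 0.1.0 run report
==============================================
total pairs: 60000   unassigned: 2968

mean fraction charged ± SD per isodecoder:
  condition GCN2iB:
    ...
    His-GTG      0.5389 ± 0.0317 (n=4)
  condition vehicle:
    ...
    His-GTG      0.9197 ± 0.0117 (n=4)

contrasts (BH-significant rows flagged *):
 * GCN2iB:vehicle         His-GTG      Δ=-0.3809  p=3.45e-05  p_adj=0.000207
 * GCN2iB_EAA:GCN2iB      His-GTG      Δ=+0.3334  p=2.97e-05  p_adj=0.000178
```

Reading it: ~5% of pairs had no identifiable barcode (the simulated rate)
and were discarded; His-GTG charging drops from 0.92 to 0.54 under GCN2iB
and returns to 0.87 with amino-acid rescue, both shifts BH-significant,
while the unperturbed isodecoders stay flat.  The run directory holds the
reference (`reference.fa`, `aliases.tsv`, `isodecoders.tsv`), count and
fraction tables, contrast results, the simulation ground truth, a JSON
manifest with per-stage read accounting, and this report.

The same stages are available as separate verbs (`simulate`, `build-ref`,
`demux`, `quantify`, `stats`, `report`) for real FASTQ input, and
`trnacharge quantify --sam` accepts externally aligned SAM.  Everything is
also importable (`trnacharge.simulate`, `.reference`, `.demux`, `.align`,
`.stats`, `.pipeline`).

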