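# xhyb — cross-species microarray analysis with gDNA probe masking

`xhyb` is a Python library and command-line tool for transcriptomics on a
*heterologous* oligonucleotide array: the situation where a species has no
chip of its own and its RNA is hybridised to a close relative's array
(cross-species hybridisation).  Sequence divergence makes some probes
unreliable, so the analysis starts by hybridising genomic DNA to the same
array and keeping only probes whose gDNA signal clears a threshold —
evidence that the probe matches the target genome.  The pipeline it
implements, end to end:

1. **Probe masking** — per-genotype probe masks from gDNA hybridisations
   (probe pair kept iff intensity > τ; probe set kept iff ≥ *k* pairs
   survive), threshold sweeps, mask comparison, custom chip definitions.
2. **Masked RMA summarization** — log2 → quantile normalization → per-set
   Tukey median polish, restricted to the masked probes.
3. **Expressed-gene calling** — the cutoff is the shallowest-gradient point
   of the descending ranked relative-expression curve (1.0 = array
   average), or a fixed override.
4. **Differential expression** — Welch t-test per probe set, BH FDR per
   contrast, gates q ≤ 0.05 and fold change > 2; cross-genotype DEG overlap
   matched on id *and* direction.
5. **Responsive vs perturbed** — stress DEGs whose recovery-vs-control
   contrast is non-significant have returned to baseline (responsive);
   those still significant carry a stress-induced state change (perturbed).
6. **Co-expression networks** — Spearman |ρ| ≥ 0.9 over a genotype's
   samples, per-genotype networks merged with provenance, transcription
   factors ranked by vertex degree (whole network vs drought subnetwork);
   SIF/GraphML export.
7. **2^-ΔΔCt** — relative qPCR quantification for bench validation of
   array fold changes.

A first-class synthetic-data generator (`xhyb.synthetic_data`) emulates the
two-genotype dehydration study design this pipeline targets — 3/4/3
replicates over water-sufficient / water-limited / recovery, divergence as
Bernoulli probe dropout, planted fold changes mostly below 4-fold, a small
cross-genotype DEG overlap, a 75/25 responsive/perturbed split and
co-fluctuating modules — with full ground truth for recovery testing.
See `docs/methods.md` for models, parameters and design choices.

## Worked example

Run the whole pipeline on a simulated study (2,000 probe sets × 11 probe
pairs, 100 planted DEGs per genotype, 9 common, seed 2):

```bash
xhyb all --simulate --seed 2 --outdir run
```

prints the per-contrast DEG counts of the report bundle:

```
report bundle written to run
genotype           contrast  n_deg  n_up  n_down
    DipC             stress     95    42      53
    DipC     recovery_vs_ws     11     5       6
    DipC stress_vs_recovery     70    33      37
      TN             stress     93    39      54
      TN     recovery_vs_ws     19     9      10
      TN stress_vs_recovery     70    30      40
```

Here 95 of the 100 planted DipC stress DEGs were recovered (the misses are
genes whose planted fold sits just above the >2 gate), stress caused more
down- than up-regulation, and few genes separate recovery from control.
`run/` also contains the threshold-sweep table, mask comparison, expressed
calls, DEG tables with responsive/perturbed classes, the common-DEG table,
PCA variance fractions, degree tables, exported networks, the planted
truth, and a manifest (config + input checksums).  Two runs with the same
seed produce byte-identical report tables.

The same stages are importable:

```python
import xhyb

layout = xhyb.simulate_layout(2000, 11, seed=0)
truth  = xhyb.simulate_truth(layout, n_de_per_genotype=100, n_common_de=9, seed=1)
gdna   = xhyb.simulate_gdna(layout, bind_prob=0.9, seed=2, truth=truth)
sheet  = xhyb.simulate_sample_sheet()
rna    = xhyb.simulate_rna(layout, truth, sheet, noise_sd=0.25, seed=3)

mask = xhyb.select_probe_pairs(gdna.values["gdna_DipC"], layout, 256.0)
cols = sheet.active().query("genotype == 'DipC'")["sample_id"]
expr = xhyb.rma_summarize(xhyb.ProbeIntensityMatrix(rna.values[list(cols)]),
                          mask, layout)
degs = xhyb.call_degs(expr, sheet, "DipC")   # q <= 0.05 and fold > 2
```

Each stage is also its own subcommand (`simulate`, `mask`, `sweep`, `rma`,
`call-expressed`, `de`, `classify`, `network`, `pca`, `ddct`) operating on
plain TSV files; `xhyb <cmd> --help` documents the columns.

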