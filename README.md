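# prodemand

Amino-acid composition profiling of cell-type-associated proteins and
transcriptome-weighted prediction of amino-acid demand change during cell
differentiation.

## The problem

Differentiating cells remodel their proteome. Osteoblasts (bone-forming
cells) are the motivating example: their differentiation program induces
proteins such as RUNX2, OSX, COL1A1 and OCN that are unusually rich in
proline, so the switch to an osteoblast expression program should raise the
cell's biosynthetic demand for proline specifically. `prodemand` implements
the bioinformatic side of that argument as a tested, reusable pipeline:

1. **Composition profiling** — per-protein residue counts `N_aa` and
   fractions from a peptide FASTA (Ensembl dialect understood, one
   representative isoform per gene, longest by default).
2. **Gene-set enrichment** — for a GO-style gene set, the mean residue
   composition, its fold enrichment `f_set(a) / f_background(a)` and percent
   increase `100 (f_set/f_bg − 1)` over the whole-proteome background, and
   percentile-rank analyses (share of members above the background's 75th
   percentile for a residue, mid-rank convention).
3. **Demand prediction** — merging a two-condition expression table
   (FPKM-like abundances `R`) with residue counts on gene stable ID, and
   assuming translation tracks mRNA, the predicted demand change per residue

   ```
   %ΔAA(a) = 100 · Σ_g [(R_diff(g) − R_undiff(g)) · N_a(g)]
                 / Σ_g [R_undiff(g) · N_a(g)]
   ```

   plus the comparison of a residue's fractions between the top-500 induced
   and top-500 suppressed genes (unpaired two-tailed Student's *t*-test).
4. **Panel correlation** — Pearson correlation of protein-level expression
   fold changes (log2-transformed) with proline composition, as used for
   western-blot panels under proline limitation.
5. **Synthetic data** — a generator producing proteomes (Dirichlet
   compositions around the mouse proteome background, designated sets with a
   proline-fraction shift), expression tables (log-normal baselines,
   designated induced/suppressed sets, log-normal noise), and panels with a
   known log-linear slope — so every stage is testable without downloads and
   against known ground truth.

## Worked example

```bash
python analysis/01_simulate.py --seed 0 --results-dir results
python analysis/04_demand_prediction.py --results-dir results
```

prints

```
wrote 2000 proteins, 2000 genes -> results/simdata
planted truth: induced set Pro-shifted +0.03; expected %dPro = 19.35 vs median other 12.24
merged 2000 genes (0 proteome genes without expression, 0 expression genes without protein)
predicted %dAA: Pro +22.64% vs median other residue +14.68%
top-500 Pro fraction: induced mean 0.0859 vs suppressed 0.0620 (t = 9.40, p = 3.72e-20)
```

The simulation plants a +0.03 proline-fraction shift in the 500 induced
genes and doubles their expression in the differentiated condition. The
pipeline recovers that: predicted proline demand rises 22.6%, clearly above
the median of the other 19 residues (the gap to the noise-free expectation
of 19.4% reflects the expression noise), and the induced genes' proline
fractions (mean 0.086) exceed the suppressed genes' (0.062) with
t = 9.4. The other drivers (`02`, `03`, `05`) produce the composition
matrix, set enrichment/percentile summaries (the induced set lands at
+29.8% proline vs background with 43.0% of members above the 75th
percentile) and the panel correlation (r = −0.85 against a planted negative
slope).

The same stages are available as subcommands of the `prodemand` console
script (`compose`, `enrich`, `percentile`, `demand`, `correlate`,
`simulate`).

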