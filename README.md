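# cdkp — combinatorial dual-guide CRISPR perturbation analysis

`cdkp` is a Python toolkit for the computational arms of a combinatorial
CRISPR–Cas9 perturbation study of cell-cycle kinases:

* **Dual-guide screen design and counting** — enumerate all ordered guide
  pairs of a library (n guides → n(n−1) constructs), assemble synthesis
  oligos with Hamming-distance-guaranteed barcodes, build the two-position
  alignment reference, and count guide pairs from paired cassette reads by
  windowed Levenshtein matching (edit distance < 3, ambiguous and
  off-design pairs rejected).
* **Genetic-interaction scoring** — from construct counts, compute log2
  abundances, fold changes versus the baseline timepoint and z-standardized
  construct fitness; impute single-guide fitness from the additive model
  f₁₂ = f₁ + f₂ + π by solving A·x = b with A = (N−2)I + J; score guide- and
  gene-level interactions π, z-normalize per sample, median across
  timepoints and replicates, and call synthetic-lethal / synergistic pairs.
* **Cell-cycle embedding** — score cells against five phase marker sets
  (M, M/G1, G1/S, S, G2/M), embed cosine distances of pan-phase profiles by
  metric MDS into polar coordinates (r, Θ), assign phase arcs by binned
  majority labels, test knockout-induced phase-density shifts with a
  two-sample Kuiper test, regress the cell-cycle signal out of the
  transcriptome, and nominate new phase markers by co-expression.
* **Knockout transcriptome phenotyping** — single-cell QC and
  normalization, median fold-change profiles versus AAVS1 safe-harbor
  controls with (smoothed) bootstrap confidence clouds, joint MDS embedding
  of knockouts, Mann–Whitney/Benjamini–Hochberg differential expression,
  and the perturbation-magnitude-versus-fitness relation.
* **5′ coverage bias** — classify exons (First / AlternativeFirst /
  Internal / Last / AlternativeLast, strand-aware), normalize per-exon
  coverage to log2 RPM, compute fold enrichment against non-targeting
  controls and the 5′ bias = lfc(First) − lfc(Last), cluster genes by bias
  pattern (complete linkage, 12-cluster cut) and test cluster gene lists
  with a local Fisher-exact enrichment helper.

Every analysis has a matching generator in `cdkp.simulate` that plants
ground truth (fitness effects and interactions under multinomial
sequencing noise, circular phase structure with knockout density shifts,
expression signatures, 5′ coverage enrichment), so the whole pipeline is
testable end to end. `cdkp.benchmarks` packages those recovery experiments.

## Worked example

Simulate a 20-gene × 4-guide screen (plus 8 controls) with one planted
synthetic-lethal pair, score it, and look at the top calls:

```python
from cdkp.simulate import synthetic_library, default_screen_truth, simulate_screen
from cdkp.interactions import score_screen

lib = synthetic_library(n_genes=20, seed=1)
truth = default_screen_truth(lib, seed=1, depth=1_000_000,
                             pi_true={("GENE03", "GENE07"): -1.5})
counts = simulate_screen(lib, truth)          # 3 timepoints x 2 replicates
res = score_screen(counts, lib.guide_to_gene())
print(res["gene_final"].sort_values("gene_final").head(3))
```

```
     gene_a  gene_b  gene_final  n_samples  mean_combinations    final_z              call
63   GENE03  GENE07  -12.900377          6               32.0 -13.913896  synthetic_lethal
187  GENE12  GENE14   -0.905955          6               32.0  -0.972830              none
154  GENE09  GENE11   -0.796456          6               32.0  -0.854689              none
```

The planted pair ranks first by a wide margin; its `final_z` (the median
z-score re-standardized across gene pairs) is far beyond the −2 call
threshold while every unplanted pair stays inside it. Aligning the
standardized fitness scale back to planted units recovers π ≈ −1.32 for a
planted −1.5 — the ~10% attenuation is the expected price of dropping the
interaction sums when imputing single-guide fitness — and the imputed
single-guide fitnesses rank-correlate with the planted ones at Spearman
ρ ≈ 0.999.

The same pattern holds for the other components (numbers from
`scripts/acceptance.py --seed 1`): the cell-cycle embedding reproduces
planted phase angles at circular correlation 0.982 on 2,000 cells with
phase-arc boundaries within one 6° bin; the Kuiper test holds its size
(4.5% rejections at p < 0.05 over 1,000 null trials) and detects a planted
G1/S-concentrated knockout at p ≈ 10⁻³⁸; differential expression recovers
3 × 200 planted signature genes with 100% recall at 4.2% empirical FDR;
and a planted 5′ coverage bias of 2.0 is recovered as 2.009.

A command-line interface mirrors the library (`cdkp design | simulate |
count | score | cellcycle | bias`), reading and writing TSV/FASTA/FASTQ/
GTF/JSON.

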