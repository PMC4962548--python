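# gafpause

Quantitative analysis of how an upstream DNA-binding factor's promoter
occupancy relates to promoter-proximal RNA polymerase II pausing and to the
organization of upstream nucleosomes — the kind of question raised by GAGA
factor (GAF) in *Drosophila*, where a sequence-specific factor binds (GA)n
repeats upstream of many paused genes. The package is aimed at
chromatin/transcription groups who have factor ChIP-seq, total-Pol ChIP-seq,
matched input, MNase-seq and expression data for two conditions (e.g. wild
type vs a factor-depleted mutant) and want the whole statistical chain —
from fragment files to rank-stratified tests — reproducible and testable.

Because such datasets are large and rarely redistributable, the package
ships a first-class synthetic-data generator that plants the statistical
structure the analysis assumes (occupancy-graded binding, occupancy-coupled
pausing, phased nucleosomes, planted expression effects) together with a
truth table, so every stage can be verified end to end on a laptop.

## The quantities computed

For each gene with a single TSS, no internal genes and ≥ 2 kb clearance from
neighbours (the analyzable universe):

* **Coverage** — per-base fragment pileup, depth-normalized to
  reads-per-million: `x̃_i = x_i · 10⁶ / N`.
* **Promoter occupancy score** — cumulative enrichment over the promoter
  window *W* = [−500, 0) upstream of the TSS,
  `score = Σ_W chip / Σ_W input` (pseudocount-stabilized, both tracks
  per-million). Scored genes are split into ascending quartile ranks
  I–IV (365 eligible genes split 92/91/91/91).
* **Pausing index** — `PI = d_A / d_B`, the ratio of mean per-bp polymerase
  density in region A = [−100, +150] (promoter-proximal) over region
  B = [+500, gene end] (gene body); a gene is "paused" when PI > 4.
* **Gene-level polymerase detection** — one-sided Fisher exact test on
  ChIP/input fragment counts per gene, Benjamini–Hochberg corrected
  (detected: q < 0.05 and p < 0.01).
* **Occupancy/pausing association** — Spearman's ρ between occupancy score
  and `d_A`, `d_B` or PI; per-rank WT-vs-mutant PI shifts by two-sided
  Mann–Whitney U.
* **Nucleosome organization** — midpoints of 120–180 bp MNase fragments,
  averaged TSS-relative over [−500, +500) (metagene), compared across
  conditions per 250-bp section with two-sample Kolmogorov–Smirnov tests
  on the pooled midpoint positions.
* **Sequence propensity** — cross-gene frequency of SS dinucleotides
  (GG, GC, CC, CG; both bases strong), the classic nucleosome-favoring
  signal, plus a (GA)n / (TC)n repeat scanner.
* **Expression** — Welch t on log2 triplicate intensities with the
  p < 0.05, >1.5-fold, intensity > 100 filters, intersected with promoter
  targets (>2-fold enrichment).

## Worked example

Simulate a 300-gene study and run the full pipeline:

```python
import json
from gafpause import run_pipeline

config = {"seed": 7, "simulate": {"n_genes": 300, "fraction_targets": 0.3}}
run_pipeline(config, "demo_run")
report = json.load(open("demo_run/report.json"))
```

Selected numbers from `demo_run/report.json` as printed by this exact run:

```
selection      n_kept 260 of 310        (planted criterion violations rejected)
targets        rank sizes I..IV = 17/17/16/16, 194 genes below 2-fold
WT   Spearman(score, d_A)  rho = 0.936, p = 8.6e-31   (n = 66 ranked genes)
WT   Spearman(score, PI)   rho = 0.927, p = 5.4e-29
mut  Spearman(score, d_A)  rho = -0.160, p = 0.20     (coupling lost)
rank IV PI WT vs mutant    U = 256, p = 1.5e-06       (pausing collapses)
expression     48 significant genes, 76% of direct targets down-regulated
```

Reading: in the synthetic wild type, promoter-proximal polymerase density
and PI track the planted occupancy gradient; in the decoupled mutant the
correlation vanishes and high-occupancy ranks lose their high PIs — the
contrast the analysis is designed to expose. The same stages are available
as CLI subcommands (`gafpause simulate | select | peaks | targets | rank |
ga-scan | pause | nuc-profile | nuc-test | ss-profile | express | run |
report`) for file-based inputs (FASTA, BED6/BED12/GFF3, BED/BEDPE/SAM
fragments, TSV expression). In BED gene annotations the score column
carries the number of annotated TSSs for the locus (0 is read as 1).

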