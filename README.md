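# degradome

Reusable analysis pipeline for multi-condition bacterial RNA-Seq studies of
lignocellulose degradation ("cellulose degradome" profiling), built around the
model cellulolytic anaerobe *Clostridium cellulolyticum* grown on glucose,
cellobiose, xylose, cellulose, xylan and corn stover. It is aimed at
microbiologists who have per-base coverage tracks (or per-gene counts) for a
small bacterial genome under several carbon sources and want to move from raw
depth to regulatory statements: which genes form the degradome, which are
substrate-specific, and whether their control looks like carbon catabolite
repression (CCR) or two-component-system (TCS) signalling.

## What it computes

* **Quantification.** Per-gene transcript abundance TA_j = (Σ per-base
  unique-hit depth over gene j) / length_j, normalized by the sample's average
  sequencing depth ASD = (total mapped bases)/(genome length):
  **NTA_j = TA_j / ASD**. A gene is *expressed* when NTA > 1.
* **Transcribed regions.** Base-level expressed runs per condition; the *core*
  set (expressed under every substrate) by interval intersection, and
  *condition-specific* regions (expressed under exactly one substrate, not
  overlapping any other condition's transcription, mean depth > 2), each
  annotated as CDS-overlapping, intergenic, or putative 5′-UTR.
* **Differential expression.** Three tests per gene and condition pair on
  (k, N) count pairs — the MA-plot random-sampling z-test (M = log2(k1/N1) −
  log2(k2/N2) conditioned on A under binomial sampling at the pooled
  proportion), Fisher's exact test, and a binomial likelihood-ratio test —
  combined by consensus with the ratio (|log2| ≥ 2), NTA floor (0.01) and
  p-value (≤ 0.05 or ≤ 0.001 presets) filters.
* **Classification.** Degradome membership (NTA > 1 under the target;
  substrate-specific membership additionally needs >2-fold ratios at
  p < 0.001 against every reference), Row Z-scores, hierarchical clustering
  into C-classes or CAZyme Groups I–IV (Group I = the CCR signature: high
  under Glu/Cel/Xyn/CS versus Ceb/Xyl), and flat-term hypergeometric
  enrichment with BH correction.
* **Regulon inference.** Profile R² between gene groups across conditions,
  Spearman anti-correlation between expression and growth rate (exact
  permutation p for n ≤ 8), and a TCS locus scan that classifies
  sensor/regulator operons by their cargo (category I: sugar-binding protein;
  II: CAZyme; III: bare pair) and collects flanking CAZyme/ABC genes.
* **Motif scanning.** Palindromic *cre*-like operator PSSMs with the central
  CG dinucleotide fixed as a model constraint, an *exact* null score
  distribution by dynamic programming over 1/100-bit score bins, scanning of
  upstream regions at p ≤ 1e-4, and site-to-gene assignment with offsets to
  the translation start.
* **Kinetics.** Logistic fits D(t) = K/(1+exp(−r(t−t0))) of cellulose
  degradation curves; peak degradation rate rK/4 (g/L/day) and lag time t0.
* **Synthetic data.** A generator producing genomes with operon structure
  (a 13-gene cellulosomal cluster, a 14-gene hemicellulase cluster, three TCS
  loci), group-structured expression, 36-base-read coverage, planted 16-nt
  palindromic motifs and noisy degradation curves — with full ground truth,
  so every stage is testable end to end.

## Worked example

Generate a synthetic six-condition dataset and quantify it:

```bash
degradome simulate --seed 1 --outdir demo
```

```python
from degradome import read_genome_record, compute_nta_table, growth_anticorrelation
from degradome.expression_quant import read_coverage_tsv
import pandas as pd

record = read_genome_record("demo/genome.fasta", "fasta+gff3",
                            gff3="demo/genome.gff3",
                            annotation_table="demo/annotation.tsv")
conditions = ("Glu", "Ceb", "Xyl", "Cel", "Xyn", "CS")
tracks = {c: read_coverage_tsv(f"demo/coverage_{c}.tsv", condition=c,
                               genome_length=record.length) for c in conditions}
expr = compute_nta_table(tracks, record)
core = [g.gene_id for g in record.genes
        if g.annotations.get("cluster") == "cip-cel-like"]
print({c: round(float(v), 2) for c, v in expr.nta.loc[core].mean().items()})
growth = dict(pd.read_csv("demo/growth.tsv", sep="\t").values)
rho, p, _ = growth_anticorrelation(expr.nta.loc[core].mean(), growth,
                                   rankable_conditions=["Ceb", "Xyl", "Xyn", "Cel"])
print(f"rho = {rho:.2f}, p = {p:.4f}")
```

prints

```
{'Glu': 7.81, 'Ceb': 1.55, 'Xyl': 2.51, 'Cel': 6.46, 'Xyn': 4.21, 'CS': 5.98}
rho = -1.00, p = 0.0417
```

The cellulosomal cluster's mean NTA is highest under glucose, cellulose and
corn stover and lowest under cellobiose — the CCR pattern — and across the
four rankable substrates its expression is perfectly anti-correlated with
growth rate (Spearman ρ = −1; the exact one-sided permutation p at n = 4 is
1/24 ≈ 0.0417). Fitting the simulated degradation curve:

```bash
degradome kinetics --data demo/kinetics.tsv
# K=5.998 g/L  r=1 /day  t0=5.015 day
# peak_rate=1.5 g/L/day  lag_time=5.015 day
```

i.e. about 6 g/L of degradable cellulose, a peak degradation rate of
1.5 g/L/day (= rK/4) reached on day 5.

The whole pipeline (simulate → quantify → regions → deg → classify →
regulons → motifscan → kinetics) runs from a YAML config:

```bash
degradome run-full --config config.yaml --seed 1 --outdir out
```

and writes TSV/BED outputs plus a `manifest.json` recording the config hash,
seed and per-stage row counts; reruns with the same config and seed are
byte-identical.

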