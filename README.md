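# tempro

Temporal transcriptome–proteome coupling analysis for stimulation time
courses.

When cells are activated — the motivating case is primary human CD4 and CD8
T cells stimulated through the T cell receptor — the transcriptome responds
within hours while the proteome follows days later. Measuring *when* the two
layers couple, and which genes drive each phase, requires a pipeline that
treats both omics layers with one consistent statistical machinery. `tempro`
provides that pipeline for paired mRNA count and protein intensity matrices
sampled over a time course (two cell subsets × six timepoints × replicate
donors), plus a kinetic simulator that generates coupled datasets with
ground truth so every analysis step can be validated by recovery.

## What it computes

- **Per-timepoint differential expression** versus the 0 h baseline (and
  CD4 vs CD8 per timepoint): row-wise pooled-variance t-tests on log2
  abundances with the two-stage linear step-up FDR of Benjamini, Krieger &
  Yekutieli. A feature is DE when it passes both a fold-change and a
  significance bound: |log2fc| > 1.5 and q < 0.01 for mRNA (strict),
  |log2fc| ≥ 1.0 and q ≤ 0.05 for protein (inclusive). The reported
  q-value is the smallest nominal level at which the two-stage procedure
  rejects, so thresholding q-values reproduces rejection sets exactly.
- **Normalization**: TMM scaling factors (edgeR-style doubly trimmed,
  precision-weighted mean of log ratios) feeding log2(CPM + 1) for counts;
  peptide/score/missingness QC filters and log2 transform for proteins.
- **Coupling kinetics**: Pearson r between mRNA and protein log2 fold
  changes of matched gene–protein pairs at each timepoint (pairs gated on
  the transcript being DE there), with the conventional strength bands
  (strong ≥ 0.70, moderate ≥ 0.40, weak ≥ 0.10); quadrant concordance of
  fold-change signs; and a translation-lag track counting how many proteins
  of 6 h-DE transcripts become DE at each later timepoint.
- **Kinetic clustering**: fuzzy c-means (Bezdek updates, Schwämmle–Jensen
  fuzzifier, seeded k-means++ initialization with restarts) on z-scored
  fold-change profiles of features DE at ≥ 1 timepoint; core members at
  membership ≥ 0.5; UPGMA profile clustering on 1 − Pearson distance.
  The clusterer is a scikit-learn-compatible estimator (`FuzzyCMeans`).
- **Over-representation analysis**: hypergeometric tail test of query sets
  against GMT gene-set collections with BH FDR, background = all quantified
  features after QC.
- **A simulator** generating negative-binomial counts and log-normal
  protein intensities (with MNAR-weighted missingness) from first-order
  translation/degradation kinetics, with planted responders, kinetic
  archetypes, subset effects and QC failures — all recorded in a truth
  table for recovery tests.

## Worked example

```python
from tempro.simulate import SimConfig, simulate_dataset
from tempro.preprocess import tmm_factors, cpm, filter_proteins, log2_intensities
from tempro.diffexpr import timecourse_de, percent_de_table
from tempro.coupling import (match_features, build_matched_pairs,
                             correlation_kinetics, lag_track)

ds = simulate_dataset(SimConfig(n_genes=2000, protein_fraction=0.3, seed=1))
norm = cpm(ds.mrna, norm_factors=tmm_factors(ds.mrna))
kept, qc_report = filter_proteins(ds.protein)
print(f"proteins kept after QC: {kept.shape[0]}/{ds.protein.shape[0]}")

mrna_de = timecourse_de(norm, ds.metadata, "CD4")
prot_de = timecourse_de(log2_intensities(kept), ds.metadata, "CD4")
print(percent_de_table(mrna_de).to_string(index=False))

pairs = match_features(ds.mrna.feature_ids, kept.feature_ids, ds.id_map)
mp = build_matched_pairs(pairs, mrna_de, prot_de)
print(correlation_kinetics(mp).to_string(index=False))
print(lag_track(mp, 6.0).to_string(index=False))
```

prints

```
proteins kept after QC: 442/600
 timepoint_h  n_de  n_quantified  percent
         6.0    76          2000     3.80
        12.0   108          2000     5.40
        24.0   127          2000     6.35
        72.0   166          2000     8.30
       168.0   193          2000     9.65
 timepoint_h        r  n_pairs strength
         6.0 0.477600       15 moderate
        12.0 0.733835       22   strong
        24.0 0.662943       31 moderate
        72.0 0.915075       42   strong
       168.0 0.939316       49   strong
 timepoint_h  n_up  n_down  n_de  n_cumulative
         6.0     0       0     0             0
        12.0     1       0     1             1
        24.0     3       0     3             3
        72.0     4       0     4             5
       168.0    10       2    12            12
```

Reading the output: 158 of 600 simulated proteins fail the peptide/score/
missingness QC filters. The fraction of DE transcripts grows as later
kinetic archetypes switch on (3.8% at 6 h to 9.65% at 7 d, approaching the
10% of genes planted as responders). The coupling correlation rises from
r = 0.48 at 6 h to r = 0.94 at 7 d — the early-uncoupling/late-coupling
signature — and the lag track shows that of the 15 matched pairs whose
transcript is DE at 6 h, none has a DE protein at 6 h but 12 do by 7 d:
translation lags transcription by days, exactly as the generating kinetics
(protein half-lives of 1–14 days) dictate.

## Command line

```bash
tempro run-all --out results/ --seed 1          # full synthetic-mode pipeline
tempro simulate --out data/ --seed 1            # just the generator
tempro preprocess --mrna counts.tsv --protein prot.tsv --meta meta.tsv --out norm/
tempro de --mrna counts.tsv --protein prot.tsv --meta meta.tsv --subset CD4 --out de/
tempro couple --de-dir de/ --idmap map.tsv --subset CD4 --out coupling/
tempro cluster --de-dir de/ --subset CD4 --c 12 --seed 1 --out clusters/
tempro enrich --query de_up.txt --background bg.txt --gmt sets.gmt --out ora/
```

`run-all` accepts a YAML config (`--config`) selecting synthetic or real
input mode and overriding QC, threshold, clustering and enrichment
parameters; it writes every intermediate table plus a canonical
`run_report.json` that is byte-identical across same-seed runs. Exit codes:
0 ok, 2 validation error, 1 stage failure.

Real-data runs start at the matrices: a gene count TSV, a protein intensity
TSV with `unique_razor_peptides` and `id_score` columns, a sample metadata
TSV (`sample_id`, `subset`, `timepoint_h`, `replicate`) and a
protein-to-gene ID map. Upstream read alignment, quantification and
database search are out of scope.

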