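# haustostage

Stage-marker discovery, reference-gene stability and RT-qPCR stage
classification for staged bulk-expression experiments, built around the
development of the *Cuscuta campestris* haustorium — the lateral infection
organ of a parasitic plant — across four morphologically defined sample
types: non-infective stem (niS), swelling (SWE), attaching (ATT) and
penetrating (PEN).

Given a transcript × sample count matrix with transcript lengths and a
sample sheet (4 stages × 3 biological replicates in the reference design),
the package derives:

1. **housekeeper candidates** — transcripts expressed in every sample with
   mean log₂(RPKM) ≥ 5, lying in the lowest 10% of both the CV and MAD
   distributions, and showing no significant fold change (FDR > 0.05 or
   |log₂FC| < 1.5) in any pairwise stage contrast;
2. **stage-marker candidates** — transcripts significantly up
   (FDR ≤ 0.05, |log₂FC| ≥ 1.5) in one stage against every other stage,
   with mean *z*-score ≥ 1 in that stage and gene significance GS ≥ 0.7
   (p.GS ≤ 0.05), where GS is the Pearson correlation of expression with a
   binary stage-indicator pattern and p.GS comes from the exact transform
   t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom;
3. **a marker-based stage classifier** for new samples measured by RT-qPCR:
   relative quantities RQ = E^(Cq_min − Cq), reference-gene normalization by
   geometric-mean factors, per-gene *z*-scoring, and assignment of each
   sample to the stage whose marker set carries the highest mean *z*-score.

Differential expression uses the classic count workflow: expression
filtering, TMM scaling factors, a common negative-binomial dispersion fitted
by conditional maximum likelihood, a two-sided exact test conditioning on
the pairwise total, and Benjamini–Hochberg FDR control. Reference-gene
stability is ranked by from-scratch implementations of **geNorm** (average
pairwise log-ratio variability M, stepwise exclusion, pairwise variations
V(n/n+1)), **NormFinder** (combined intra-/inter-group variability SV) and
**BestKeeper** (Pearson r against the per-sample index), integrated as the
geometric mean (GM) of the three competition ranks.

A fully tested synthetic-data generator plants housekeepers, stage markers
and background transcripts with configurable effect sizes, NB dispersion and
qPCR noise, so every selection rule is validated by planted-truth recovery.

## Worked example

Run the whole chain on a synthetic staged experiment (600 transcripts,
15 planted housekeepers, 10 planted markers per stage at an 8-fold effect):

```bash
haustostage run --config demo.yaml --out-dir demo_run
```

with `demo.yaml`:

```yaml
seed: 42
sim:
  n_transcripts: 600
  n_housekeepers: 15
  n_markers_per_stage: {niS: 10, SWE: 10, ATT: 10, PEN: 10}
```

The manifest (`demo_run/manifest.json`) reports, among other stages:

```
"diffexp":   {"contrasts": 6, "significant": {"niS_vs_SWE": 20, ...}}
"selection": {"housekeepers": 30, "markers": {"niS": 9, "SWE": 10, "ATT": 10, "PEN": 10}}
"qpcr":      {"references": ["T00013", "T00011"], "correct_stage_calls": 12, "samples": 12}
```

Each contrast flags ~20 transcripts — the planted markers of its two stages.
The housekeeper table (`demo_run/housekeepers.tsv`) starts

```
transcript_id  mean_log2rpkm  se      cv      mad
T00013         12.5591        0.0166  0.0046  0.0420
T00011         11.9446        0.0197  0.0057  0.0392
```

— CV ≈ 0.005 and MAD ≈ 0.04 on the log₂ RPKM scale, the stability range
expected of validated reference genes. The qPCR arm then simulates Cq
tables for a 3-markers-per-stage panel, normalizes against the two top
references and calls all 12 samples (3 per stage) to their true stage
(`demo_run/stage_calls.tsv`).

Individual steps are available as subcommands (`simulate`, `normalize`,
`de`, `cluster`, `enrich`, `gs`, `select`, `stability`, `stage`) or as
library functions (`haustostage.run_contrast`, `haustostage.genorm`, ...).

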