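# cdk11net

From siRNA-knockdown expression chips to a nominated hub gene — plus the
clinical follow-through on a tissue microarray.

## The problem

Knocking down a kinase (here CDK11, in two osteosarcoma cell lines) and
profiling the transcriptome on PM/MM oligonucleotide arrays yields one
knockdown and one control array per line. The analysis question is: which
genes respond in *both* lines, and which node do those responders point to
when projected onto a gene-interaction network? The clinical question is
whether staining for the nominated gene (AR) and for CDK11 on a patient
tissue microarray (TMA) correlates, and whether high staining predicts
worse survival.

`cdk11net` implements that analysis chain as a reusable, tested pipeline:

1. **preprocess** — Wilcoxon signed-rank Present/Marginal/Absent detection
   calls on discrimination scores `R_i = (PM_i − MM_i)/(PM_i + MM_i)`
   (exact p by sign enumeration for ≤12 probe pairs), quantile
   normalization of log2(PM), Tukey median-polish probe-set summarization,
   and filtering of probe sets absent everywhere or never above log2(100).
2. **diffexpr** — per line, the paired difference `d = control − knockdown`
   per probe set ("Diff_Data"), standardized to z-scores by its own mean
   and SD; hits are `|z| ≥ 3`; the two hit lists are intersected at the
   gene level (multi-probe genes averaged, discordant directions kept and
   flagged) and ordered by average-linkage hierarchical clustering for
   heatmap export.
3. **network** — a transparent seed-gene subnetwork construction: linker
   nodes (non-seeds adjacent to ≥2 seeds) join the seeds, connected
   components are scored by a hypergeometric seed-enrichment tail,
   components containing an anchor gene are merged, filtered to
   bone/neoplasm-annotated nodes, trimmed of isolated members, and ranked
   by a degree+betweenness composite to nominate the central node.
4. **tma** — ordinal staining categories 0–5+ from percent positive
   nuclei, dichotomized at ≤2/≥3; stratified cohort tables, χ² association,
   Spearman correlation, Kaplan–Meier curves, log-rank tests, Cox
   proportional hazards (Newton–Raphson, Breslow or Efron ties), and
   forward/backward stepwise covariate selection.
5. **simulate** — generates every input with planted ground truth: a
   log-normal probe model with shared and line-specific responder probe
   sets, a preferential-attachment interaction graph with a planted hub,
   and a cohort with latent-Gaussian-correlated staining scores and a
   staining-dependent event hazard.

## Worked example

```bash
cdk11net all --out out --seed 7
cat out/report.md
```

With the default configuration (500 probe sets × 11 probe pairs, 20 shared
and 10 line-specific responders per line at ±1.5 log2, 50 background
probe sets, an 87-patient cohort) the report reads:

```
## Preprocessing
- probe sets in: 500
- dropped (absent on all arrays): 49
- dropped (max log2 <= threshold): 1
- retained: 450

## Differential expression
- lineA: 27 hit probes (27 genes)
- lineB: 27 hit probes (27 genes)
- common genes in both lines: 19

### Recovery of planted shared responders
- planted: 20, recovered: 19, missed: 1, spurious: 0

## Network
- nominated central node: **HUB**
- planted hub: HUB

## TMA cohort
- Spearman rho (AR vs CDK11 staining): 0.675
- log-rank p (AR high vs low): 5.11e-07
- Cox HR for AR-high: 3.58
```

Reading it: of the 20 genes planted to respond in both cell lines, 19
cross the |z| ≥ 3 threshold in both lines and none of the 430 null genes
do; the seed-network stage correctly nominates the planted hub; and on
the synthetic 87-patient cohort the two markers correlate (ρ ≈ 0.68)
while high staining multiplies the event hazard (the HR of 3.58 is a
small-cohort estimate of the planted 2.5).

Every stage can also run standalone (`cdk11net simulate|preprocess|
diffexpr|network|tma --out DIR`) against files already in the output
directory, so externally produced probe tables, edge lists, or cohort
CSVs in the documented formats slot into any stage boundary — that is the
hook point for real deposited array data.

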