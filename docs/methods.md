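# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic generators do and do not emulate,
and the design decisions made where the procedure was genuinely open.

## Probe-level model and preprocessing

**Generative model.** Perfect-match intensities follow a log-normal
probe model with additive per-probe affinities:

    PM_sj = 2^(b_s + a_sj + δ·I[responder, knockdown] + ε),  ε ~ N(0, σ_noise)
    MM_sj = f_mm · PM_sj · 2^ε′

with probe-set baseline `b_s ~ U(baseline_log2_range)` (default 7–12
log2 units, the bulk of a typical chip's dynamic range), probe affinity
`a_sj ~ N(0, 0.5)`, knockdown effect `δ = ±effect_log2` with a random
planted direction per responder, and mismatch fraction `f_mm` (default
0.5). "Absent" probe sets are drawn at a fixed low background
(`background_log2 = 4`, i.e. 16 intensity units, below the log2(100)
filter) with PM and MM at the same level, so they carry no PM/MM
discrimination and draw Absent calls. This model was chosen because it
makes two oracles exact: at zero noise a responder's knockdown/control
PM ratio is exactly `2^(±effect)`, and median polish recovers the
planted sample effects with zero residual.

The default design is 2 cell lines × {knockdown, control} with one
array each, mirroring a single-comparison knockdown experiment;
`n_replicates` adds technical replicates but defaults to 1.

**Detection calls.** Per probe pair the discrimination score
`R_i = (PM_i − MM_i)/(PM_i + MM_i)` is tested one-sided for
median(R − τ) > 0 with the Wilcoxon signed-rank statistic; the call is
P if p < α1, M if α1 ≤ p < α2, else A. Defaults τ = 0.015, α1 = 0.04,
α2 = 0.06 are the published chip-vendor defaults. Conventions: zero
differences are dropped before ranking, tied magnitudes share mid-ranks,
and the p-value is exact — full enumeration of the 2^n sign
assignments — for n ≤ 12 probe pairs (the common chip sizes), falling
back to a normal approximation with tie correction and a 0.5 continuity
correction above. Vendor saturated-MM special-casing is omitted: the
generator never saturates. The p-value is non-increasing when every
score rises, for score vectors in general position; exact zeros or tied
magnitudes (measure zero for continuous intensities) can break this by
changing the rank structure discontinuously, which the property tests
exclude.

**Normalization and summarization.** The chip-specific GC-content
background model used in the original processing requires probe
sequences and is deliberately not reproduced; the pipeline's
normalization is quantile normalization of log2(PM) (ties share the
mean of the reference values their positions span, making the transform
idempotent and rank-preserving), followed by Tukey median polish per
probe set (convergence when the largest sweep change is < 1e-6, max 20
iterations; the per-sample value is overall + column effect). Gene
lists from real arrays will therefore approximate, not bit-match, lists
produced with the original normalization.

**Filtering.** A probe set is dropped if it is called A on every array
or if its maximum normalized log2 value is ≤ log2(100) ≈ 6.644 (the
"above" is read strictly). The filter is applied after normalization.

## Differential expression

Within a cell line, `d = control − knockdown` per probe set (positive
d ⇒ expression fell upon knockdown), standardized by the mean and
sample SD (n−1) of d over all retained probe sets, so mean(z) = 0 and
sd(z) = 1 exactly. Hits are |z| ≥ 3 inclusive (`strict_gt` flips to
exclusive; the boundary has measure zero). Both probe-level and
gene-level hit counts are reported, since collapsed counts depend on
the annotation's probe-to-gene multiplicity.

The intersection is taken by gene symbol after annotation; probes
without symbols cannot enter it (they are kept on the per-line lists
with a logged warning). Multi-probe genes carry the mean d of their hit
probes per line; genes whose averaged direction differs between lines
are retained with `concordant = False` — discordant common responders
are informative, not artifacts. Heatmap ordering uses average-linkage
agglomerative clustering on Euclidean row distances (linkage and metric
exposed in config); rows are pre-sorted lexicographically so
equal-distance merges resolve identically regardless of input order.

A consequence of self-standardization worth knowing: with responder
fraction q and effect δ ≫ noise, the SD of Diff_Data is ≈ δ√q, so a
responder's z is ≈ 1/√q regardless of δ. Planting more than ~1/9 of
probe sets as responders pushes their own z-scores under the ±3
threshold. The default conditions (30 responders per line among 450
retained probe sets, q ≈ 0.067, z ≈ 3.9) sit comfortably above it;
recovery sweeps average ≈ 94% of shared responders with essentially no
false common genes.

## Network stage

The proprietary network-reconstruction tool used originally is not
reproducible; the package substitutes a transparent construction:
candidate subnetworks are connected components of the subgraph induced
by seeds plus *linkers* — non-seed nodes adjacent to ≥ 2 seeds
(optionally degree-capped to exclude promiscuous nodes). Each component
is scored by the hypergeometric tail P(X ≥ seeds inside) with the whole
graph as population. Components containing the anchor gene are merged
(edges re-induced from the parent graph, enrichment rescored), filtered
to nodes tagged with allowed tissue/disease terms (seeds and the anchor
always survive), and trimmed of nodes left isolated by the filter.

Centrality ranking: degree and betweenness centrality are each ranked
descending with mid-ranks for ties; the composite score is the mean of
the two rank positions and the final 1..n ranking breaks residual ties
lexicographically. Both raw centralities are always reported, since
"central node" is ultimately a judgment call. Betweenness on a
disconnected subnetwork follows the shortest-path definition per
component.

The synthetic graph is a Barabási–Albert preferential-attachment graph
(default 200 nodes, m = 2) with one designated non-seed hub wired to
`⌈0.7·|seeds|⌉` seeds and tagged {bone, neoplasm}; other nodes draw one
tag from {bone 0.3, neoplasm 0.3, other 0.4}. In the orchestrated
pipeline the anchor defaults to the first hub-adjacent seed recorded by
the generator — the anchor's role is "a gene known to sit next to the
driver", which is what the knocked-down gene was in the motivating
design. Under these conditions the planted hub is nominated rank 1 in
≈ 99% of runs.

## TMA cohort and survival

**Staining.** Percent positive nuclei map to ordinal categories: 0 (no
nuclear staining), 1+ (<10%), 2+ (10–25%), 3+ (>25–50%), 4+ (>50–75%),
5+ (>75%); boundaries resolve upper-inclusive because the printed bin
labels leave non-integer boundaries undefined. Dichotomization: ≤ 2 low,
≥ 3 high. Stratified summary percentages are round-half-up to one
decimal, the printed-table convention.

**Generator.** Two latent standard-normal marker scores with
correlation ρ (default 0.8) are thresholded into the six categories;
the default cutpoints are the normal quantiles of the category
frequencies observed on a published osteosarcoma TMA (5, 24, 22, 19,
15, 2 over 87 cores), so the marginal distribution matches that cohort
in expectation. Event times are exponential with hazard
`h0 · HR^I[AR-high]` (defaults h0 = 0.015/month ⇒ median ≈ 46 months
for AR-low, HR = 2.5); censoring is exponential at 0.008/month.
Exponential times keep every downstream check closed-form. Covariate
mixes (gender, grade, metastasis, recurrence, chemo response) follow
the published cohort's marginal frequencies; ages are log-normal with
median 28, clipped to 6–75. The generator plants no covariate–hazard
association except through AR staining, and no dependence between
staining and the clinicopathological covariates.

**Statistics.** χ² is the uncorrected Pearson statistic (Yates by
flag) — the original report does not state a correction, and some of
its printed table cells are not reproducible from its own counts, so
the package always computes from counts. Spearman is tie-corrected
(mid-rank Pearson). Kaplan–Meier and the log-rank test are delegated to
`lifelines`, with events preceding censorings at tied times. Cox
proportional hazards is implemented directly: Newton–Raphson with step
halving on the Breslow partial likelihood (Efron by flag), convergence
at max |Δβ| < 1e-8 within 50 iterations, SEs from the observed
information, 95% Wald intervals; coefficients wandering past |β| > 100
are diagnosed as monotone likelihood (perfect separation). Breslow is
the default because it is the convention assumed elsewhere in the
package's closed-form checks; the Efron path is cross-checked against
`lifelines`. Stepwise selection is forward on Wald p < 0.05 with
backward pruning at p > 0.10 (both configurable), ties broken by
smaller p then lexicographic name, making selection deterministic.
Note that screening k null candidates at p_enter = 0.05 admits at
least one with probability ≈ 1 − 0.95^k, so "empty model under pure
noise" is a ~80% event with five candidates, not a near-certainty.

## What the simulations do not emulate

No GC-content or optical background, no probe saturation, no batch or
lot effects, no cross-hybridization; annotation is one gene per probe
set by default (multi-probe genes are exercised in targeted tests);
graph tags are independent of topology; cohort covariates are
independent of staining and of the hazard. Passing recovery benchmarks
therefore demonstrates the correctness and power of the *procedure*
under its own assumptions — not that real arrays or real cohorts meet
those assumptions.

## Problem sizes

Default benchmark sizes: 20-seed responder sweeps (500 probe sets × 11
probes × 4 arrays each), a 50-seed zero-effect null, 100 graph
generations of 200 nodes, and 20 cohorts of 500 patients. These sizes
put the binomial/sampling error of each reported rate well inside the
margins being asserted while keeping a full run in the minutes range.
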