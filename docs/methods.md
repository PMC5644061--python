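# Methods

## Scales and conventions

Array methylation is a per-probe, per-sample fraction β ∈ [0, 1];
analyses that need a variance-stabilized scale use M = log₂(β/(1−β)).
β = 0 and 1 are clamped to ε = 10⁻⁶ (configurable) before the logit so M
values stay bounded; the transform is monotone on the clamped domain and
round-trips to 10⁻¹² precision. Manifest coordinates are 1-based
inclusive; genomic distance between probes is |pos_a − pos_b|; BED
export converts to 0-based half-open at write time only. Missing β
values propagate as NaN and are dropped pairwise in correlations, with
the number of informative pairs reported per probe.

## Drift survey

Clock drift for sample *s* is the mean over a clock-probe set *C* of
M(p, s) − M̄_NS(p), where M̄_NS is the per-probe mean M across normal
squamous samples (the estimator for the normal reference, chosen here
because it is the natural moment estimator; any per-probe reference
series can be substituted). Each test probe is then correlated with
clock drift across samples: Pearson r, two-sided p from the
t-distribution with n−2 degrees of freedom, and Benjamini–Hochberg
step-up q computed within the scanned set. Defaults: hypomethylated
test set = mean NS β < 0.25 (strict), drift call at r > 0.5 and
q < 0.01, drift island at ≥ 5 drift CpGs (inclusive). Correlations are
computed on the scale of the matrix passed in — M values by convention,
since clock drift is defined on M; β-scale scanning is possible by
passing a β matrix. Zero-variance probes and probes with fewer than 3
complete pairs are excluded rather than assigned r = 0, so they cannot
dilute the BH adjustment. The hypomethylated and hypermethylated NS
sets are adjusted separately; the hypermethylated threshold (mean NS
β > 0.75) is a package default, flagged as such in output metadata, and
the intermediate band belongs to neither set.

## Island correlation structure

Within each island, every island-relation CpG is paired with every
island, shore, or shelf CpG carrying the same island id (shore–shelf
pairs are excluded: one end of every pair anchors in the island).
Pairs enter left-closed 10-bp bins by probe-coordinate distance; mean
Pearson r and pair counts are reported per (island class, partner
relation, bin). The island-size comparison uses Welch's t-test
(unequal variances assumed); two constant groups with equal means
return t = 0, p = 1, while constant groups with different means are
rejected as the degenerate-variance path rather than reported as an
infinite statistic.

## Drift-pattern classification

A sample's β values over its drift CpGs are smoothed with a Gaussian
kernel (absolute bandwidth 0.05 in β units) on a 512-point grid over
[0, 1]; mass outside the unit interval is discarded and the density
renormalized by the trapezoid rule. Modes are local maxima with height
≥ 5% of the global maximum and mutual separation ≥ 0.05 β; boundary
maxima count. Groups: one mode below 0.5 → **L**; two or more modes
with the major (highest) mode below 0.5 → **I**; major mode at or above
0.5 → **H**. A unimodal density with its single mode ≥ 0.5 also maps to
H, since drift level rather than modality drives the downstream stage
contrast. In the literature this grouping is a visual call; the KDE
rule here is a reproducible surrogate, and its three constants are
exposed as parameters and echoed in output metadata. At least 50 values
are required per density — modality estimates from fewer points are
unstable. The stage association contrasts group H against L+I and AJCC
stage I against stage III+; stage II and unknown are excluded
(configurable). p is the two-sided Fisher exact probability; the odds
ratio is the conditional MLE with exact 95% CI.

## Longitudinal transitions

Low/high status uses β < 0.2 vs β ≥ 0.2; the boundary counts as high
(the inclusive convention is recorded in output metadata since either
choice is defensible). Counts n11/n12/n21/n22 partition the evaluable
drift-CpG set; probes missing at either time are excluded and counted.
Annual rates are the conditional fractions divided by the inter-biopsy
interval; an unconditional variant (count over all evaluable probes) is
a one-line change and intentionally not the default, matching the
conditional definition of the advancing/retarding fractions. A patient
with no high probes at either time has an undefined reverse fraction;
such a patient counts as forward-dominant when their forward rate is
positive.

## Stochastic island model

State: a binary matrix of 50 CpGs × 1000 cells (defaults). Initial
states are independent Bernoulli(0.06) — the normal-tissue mean at
drift loci. Per-CpG baseline rates are drawn once per island from a
gamma distribution parameterized by method of moments (mean 10⁻⁴,
variance 4×10⁻⁸ → shape 0.25, scale 4×10⁻⁴) and shared across cells;
redrawing per cell is not supported because inter-island rate
heterogeneity, not inter-cell, is the object of study. Each step, every
unmethylated site methylates independently with its current rate;
methylated sites never revert, so every per-CpG β series is
non-decreasing and the all-methylated state is absorbing.

Nonlinearity: when the ambient mean methylation reaches the threshold
β = 0.2, rates jump. Two open choices were fixed as follows.
*Averaging population* — the ambient mean defaults to the grand mean
over all CpGs × cells (`island_population`), which reproduces the
island-level rapid transitions; a per-cell scope is retained as an
option, with the crossed flag persistent per cell. *Jump form* — the
default multiplies each CpG's own rate by the 100-fold factor
(capped at 1), preserving inter-CpG heterogeneity; setting all rates to
10⁻² exactly is available as `set_to_post`. Threshold evaluation uses
the start-of-step state (synchronous update). The linear control
ignores the threshold entirely.

The random-draw protocol is pinned: one uniform per unmethylated site,
site-major order, with rates/init/stepping on three independent
substreams spawned from the seed. This makes the vectorized engine
bit-identical to a naive per-site loop, which the test suite exploits
as an oracle. Recorded output is the per-CpG β (fraction of methylated
cells) every 100 steps over 3000 steps by default, mimicking what an
array measures on a tissue sample; densities of these 50 values feed
the same classifier as real samples. Post-crossing acceleration is
assessed by finite differences on the recorded island mean over the
two recording intervals immediately after crossing — later windows are
diluted once fast CpGs saturate.

## Expression association

Samples split at island mean β = 0.2 (boundary high). Per mapped
(gene, island) pair: two-sided Mann–Whitney–Wilcoxon U test, exact by
enumeration of label assignments when pooled n ≤ 12 (the permutation
distribution of U is symmetric about n₁n₂/2, midranks being invariant
under rank reversal, so the two-sided p is the symmetric tail mass),
normal approximation with tie correction otherwise. Groups smaller
than 3 are flagged untestable, not silently dropped, and do not enter
the BH adjustment, which is shared with the survey module (single
implementation). Direction comes from the median difference; genes
mapped to several islands are tested once per pair and adjusted
jointly. Island mean β is computed over the island's drift CpGs by
default, or all island CpGs via the probe-subset argument.

## Synthetic-data generator

The generator emulates the features the analyses rely on, not the
genome: islands of ~0.6–1.4 kb with ~10 probes each at ≥ 2 bp spacing,
one shore and one shelf probe per flank carrying the flanked island's
id, isolated open-sea probes, and a dedicated 67-probe clock set laid
on its own islands. Gene regions are drawn per island (drift islands:
63% TSS-associated, 11% body; static: 73%/10%, mirroring array-wide
proportions). Defaults are the study conditions: 52 NS, 64 BE, 24 EAC
samples.

Latent structure: each sample carries a dwell time τ (BE uniform 0–20
years, EAC 5–30, so EAC drift is stochastically more advanced). Drift
islands share a per-island onset t₀ ~ U(4, 20) years; the mean β of a
drift probe follows a logistic in τ rising from its baseline (~0.06)
toward a plateau of ~0.75, exactly equal to baseline at τ = 0. The
onset dispersion matters: it keeps a persistent low mode in every
sample's drift distribution (islands that have not yet crossed), which
is what makes per-sample densities bimodal at intermediate ages and
keeps low probes available to advance in longitudinal pairs. All
onsets lie within the observable dwell window, so every planted island
is in principle detectable by the survey. Clock islands use earlier
onsets (2–6 years) so clock drift indexes tissue age across the whole
dwell range. Measurement noise is Beta(μκ, (1−μ)κ) around the true
mean with concentration κ = 100 (per-sample s.d. ≈ 0.03 at
intermediate β), respecting the [0, 1] support; κ = None disables
noise. Longitudinal patients draw first-biopsy dwell times from
U(2, 14) years — the drift-active window in which repeat biopsies were
informative — and the second biopsy continues the same latent
trajectory.

A flag switches the drift trajectory from the logistic shortcut to
forward runs of the stochastic simulator (100 steps per year, reduced
cell count), which preserves the threshold dynamics at the cost of a
stochastic trajectory shared by all samples of an island. The logistic
is the default: it has identical marginal structure for the downstream
analyses and deterministic runtime.

Expression: genes on repressed islands shift down by 2 log₂ units in
samples whose island mean β ≥ 0.2, a minority shift up, and null genes
(mapped to static islands) are exchangeable. EAC stage is planted with
P(stage I) = 0.6 for above-median dwell vs 0.2 otherwise, giving a
same-direction drift-group × stage association at realistic sample
size.

What passing tests on this generator do **not** show about real data:
no probe-level technical artifacts (cross-reactivity, detection
failures, batch effects), no cell-type or purity mixture, no
chromosome-scale probe-density realism, no sex chromosomes, and drift
that is by construction monotone in a single latent variable. Recovery
rates on the generator are upper bounds on what the same thresholds
achieve on arrays.

## Problem sizes and numerical choices

The recovery analyses use 660 islands × 10 probes plus flanks and
open-sea probes (~10,000 probes, 500 of them planted drift CpGs) with
64 BE samples; simulator checks use the default 50 × 1000 × 3000-step
configuration, with 20-seed batteries for the bimodality contrast.
Stochastic assertions use 3-standard-error bands; oracle comparisons
are exact (bit-equality for the engine, 10⁻¹⁰ for correlation scans).
Tie-breaks: BH uses a stable sort; mode ordering is by height; r is
clipped to [−1, 1] before the t transform; |r| = 1 maps to p = 0.

## Known limitations

The simulator has no demethylation, cell division, clonal expansion, or
spatial (neighbor-dependent) propagation, and the Markov chain is
explored by simulation only. The KDE modality rule is a surrogate for a
visual classification and its constants (bandwidth 0.05, 5% prominence,
0.05 separation) are conventions, not estimates. The hypermethylated-set
threshold and the β = 0.2 boundary conventions are defaults recorded in
output metadata rather than field standards.
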