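# methyldrift

Analysis toolkit for **epigenetic (methylomic) drift**: the gradual,
age-related gain of DNA methylation at normally hypomethylated CpG
sites, as it unfolds in premalignant tissue such as Barrett's esophagus
(BE) and its progression to esophageal adenocarcinoma (EAC). The package
is aimed at methylation-array analysts who want a tested, reusable
implementation of the drift workflow: drift-CpG discovery referenced to
an epigenetic clock, CpG-island-level correlation structure, per-sample
drift-pattern classification, longitudinal threshold-crossing rates,
drift–expression coupling, and a mechanistic stochastic model of island
methylation.

## What it computes

Methylation is measured per probe and sample as a beta value
(methylation fraction) or as the M value, M = log₂(β/(1−β)).

- **Drift survey** (`methyldrift.survey`). A two-step scan: (1) each
  sample's *clock drift* is the mean elevation of M values over a
  reference set of 67 clock CpGs relative to normal-squamous (NS)
  levels; (2) every normally hypomethylated test probe (mean NS β <
  0.25) is correlated with clock drift across samples (Pearson r,
  two-sided t-based p, Benjamini–Hochberg q). Probes with r > 0.5 and
  q < 0.01 are drift CpGs; islands with ≥ 5 drift CpGs are drift
  islands.
- **Island structure** (`methyldrift.islands`). Pairwise correlations
  between island CpGs and island/shore/shelf CpGs of the same island,
  binned by genomic distance at 10 bp, contrasting static vs drift
  islands, plus a Welch t-test on island sizes.
- **Drift patterns** (`methyldrift.patterns`). Kernel-density
  classification of each sample's β distribution over drift CpGs into
  group **L** (unimodal low), **I** (bimodal, all modes β < 0.5) or
  **H** (major mode β ≥ 0.5), and a Fisher-exact drift-group × tumor
  stage association.
- **Longitudinal transitions** (`methyldrift.longitudinal`). For paired
  biopsies, counts of drift CpGs staying below/above β = 0.2 (n11, n22)
  or crossing forward/backward (n12, n21), with annualized conditional
  rates n12/(n12+n11)/Δt and n21/(n21+n22)/Δt.
- **Island simulator** (`methyldrift.simulator`). A multicellular
  stochastic model: an island of 50 CpGs in 1000 cells, binary site
  states, per-CpG de novo methylation rates drawn from a gamma
  distribution (mean 10⁻⁴, variance 4×10⁻⁸ per step), initial states
  Bernoulli(0.06). When the island's mean methylation crosses β = 0.2,
  rates jump 100-fold (to a mean of 10⁻²) — a nonlinear
  ambient-methylation feedback that turns the initially unimodal
  density bimodal over time. A linear no-feedback control is included.
- **Expression association** (`methyldrift.expression`). Genes mapped
  to drift islands are tested for differential expression between
  samples below/above island mean β = 0.2 (two-sided
  Mann–Whitney–Wilcoxon, exact for pooled n ≤ 12, BH-adjusted).
- **Synthetic cohorts** (`methyldrift.synth`). A generator producing
  manifest, NS/BE/EAC β matrices with latent dwell-time-driven drift,
  longitudinal pairs, and repression-coupled expression, with ground
  truth for recovery testing.

## Worked example

```python
from methyldrift import io, survey, synth

cfg = synth.CohortConfig(seed=7)          # 52 NS, 64 BE, 24 EAC samples
man = synth.generate_manifest(cfg)
cohort = synth.generate_cohort(man, cfg)

sheet = cohort.sheet
ns = io.MethylationMatrix(cohort.matrix.values[list(sheet.loc[sheet.tissue == "NS", "sample_id"])])
be = io.MethylationMatrix(cohort.matrix.values[list(sheet.loc[sheet.tissue == "BE", "sample_id"])]).to_m()

clock = io.ClockSet(man.clock_probe_ids)
hypo = survey.select_hypomethylated(ns)                      # mean NS beta < 0.25
drift = survey.compute_clock_drift(be, clock, survey.ns_reference(ns))
calls = survey.scan_probes(be, drift, hypo, clock=clock)     # r > 0.5, q < 0.01
islands = survey.aggregate_islands(calls, man.probes)        # >= 5 drift CpGs

print((calls["call"] == "drift_positive").sum(), "drift CpGs")
print(int(islands["is_drift_island"].sum()), "drift islands")
```

prints

```
150 drift CpGs
15 drift islands
```

— the scan recovers exactly the 150 island CpGs planted on the 15 drift
islands of this seed's cohort (15 islands × 10 probes), with no false
calls among the ~800 static probes.

The same pipeline is available from the shell:

```bash
methyldrift synth --outdir data --seed 7
methyldrift survey --beta data/beta.tsv --samples data/samples.tsv \
    --manifest data/probes.tsv --islands data/islands.tsv \
    --clock data/clock.txt --out survey_out
methyldrift simulate --seed 3 --out sim_out
```

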