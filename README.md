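# peaheat

Field heat-tolerance screening of pea (*Pisum sativum* L.) germplasm and
SNP-marker population genetics, as a tested, reusable pipeline.

Late sowing pushes the reproductive phase of pea into summer heat, so the
grain-weight penalty of delaying the sowing date measures an accession's
heat tolerance. `peaheat` implements the desk side of such a screening
programme end to end:

* **Screening** — for each accession the average grain weight per plant is
  scored under normal sowing (1 March, `W_NS`) and two late sowings
  (16 March `W_LS1`, 31 March `W_LS2`), giving loss rates

  ```
  LR1 (%) = [1 − (W_LS1 / W_NS)] × 100
  LR2 (%) = [1 − (W_LS2 / W_NS)] × 100
  ```

  Accessions with |LR1 − LR2| > 40 points are excluded as inconsistent;
  the rest land on a nine-level scale built from 20-point bands of
  (LR1, LR2) — level = band(LR1) + band(LR2) + 1. Levels 1–3 are
  heat-tolerant (HT), 7–9 heat-sensitive (HS). Iterating the screen over
  successive seasons, carrying forward only HT/HS accessions, yields
  "extremely" tolerant/sensitive sets and a cross-round consistency set.
  Field survival rate (FSR = Σ survivors / (n·10) × 100), grain filling
  rate (GFR = hundred-grain weight / flowering→maturity days), a KS
  normality check on the level histogram, and HT-vs-HS ANOVA on GFR round
  out the stage.
* **Thermal** — growth-window summaries of daily mean temperature: days
  above 16/20/22/30 °C and growing-degree-day accumulation.
* **Diversity** — per-marker NG, NA, MAF, gene diversity GD = 1 − Σp²,
  observed heterozygosity, and Botstein's PIC
  (1 − Σp² − Σ<sub>i&lt;j</sub> 2p<sub>i</sub>²p<sub>j</sub>²), with panel
  summaries and PIC-based informativeness classes.
* **Structure** — allele-sharing and Nei (1972) genetic distances, UPGMA
  trees (Newick), PCoA with axis contribution rates, a STRUCTURE-style
  admixture Gibbs sampler, Evanno ΔK model selection, and subpopulation
  assignment with composition cross-tabs.
* **Primer QC** — SNaPshot peripheral / single-base-extension primer
  validation (length, GC, Tm, self- and cross-complementarity, tailing).
* **Synthetic data** — a generator for temperature series, trial
  phenotypes with latent HT/HS classes, and Balding–Nichols genotype
  panels with planted subpopulations, so every stage is testable with
  known ground truth.

The screening and admixture stages follow the statsmodels idiom: a model
object built from data whose `fit()` returns a results object
(`HeatScreeningModel → HeatScreeningResults`,
`AdmixtureModel → AdmixtureResults`) with estimates and a `summary()`.

## Worked example

```python
from peaheat import simdata
from peaheat.screening import HeatScreeningModel, classify_level, loss_rates

# loss rates and level for one accession: 50 g under normal sowing,
# 45 g and 42 g under the two late sowings
lr1, lr2 = loss_rates(50.0, 45.0, 42.0)
print(round(lr1, 3), round(lr2, 3), classify_level(lr1, lr2))
# 10.0 16.0 1         <- 10% and 16% loss: both in the 0-20 band, level 1 (HT)

# a full synthetic screening round: 200 accessions, HT/HS classes
# separated by 60 points of grain-weight loss, 5-point noise
cfg = simdata.SyntheticPanelConfig(n_accessions=200, seed=17, effect=60.0, noise_sd=5.0)
sim = simdata.simulate_trial(cfg)
res = HeatScreeningModel(sim.records).fit()
print(res.summary())
```

prints

```
Heat-tolerance screening round summary
============================================
accessions scored     : 200
classified (levels)   : 189
excluded              : 11
heat-tolerant (1-3)   : 96
heat-sensitive (7-9)  : 90
level histogram       : 1:10 2:33 3:53 4:3 5:0 6:0 7:42 8:39 9:9
KS normality          : D = 0.2749, p = 0.000
```

189 of 200 accessions get a level (the rest lacked a scoreable stage or
had inconsistent loss rates and are listed in `res.exclusions` with
reasons); the latent classes separate into the HT (1–3) and HS (7–9)
bands with an empty middle, so the KS test rightly rejects normality for
this deliberately bimodal panel. Comparing `res.results` with
`sim.truth` shows ≥ 90% of latent labels recovered.

The same analysis runs from the shell:

```sh
peaheat simulate --config config.yaml --out sim/
peaheat screen --trials sim/trials.tsv --out screened/
peaheat structure --genotypes sim/genotypes.tsv --k-min 1 --k-max 5 --seed 1 --out struct/
peaheat run-all --config config.yaml --out run/
```

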