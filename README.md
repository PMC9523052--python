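# paleoniche

Time-aggregated species distribution modelling for detecting ecological
niche change through time from radiocarbon-dated occurrences.

## The problem

Archaeological and paleontological occurrence records are sparse and
unevenly sampled, so fitting a separate species distribution model (SDM)
to every time slice of the last glacial cycle both underestimates the
niche (unsampled regions look like absences) and overestimates its change
(independent per-slice fits differ by noise alone). `paleoniche`
implements the alternative: pool all dated occurrences in a **single
presence/background binomial GAM** whose smooth terms may interact with
time, and let model selection decide whether the niche actually changed.

Two models are fitted to the same data:

* **constant niche** — `logit P(presence) = α + Σᵥ fᵥ(xᵥ) + g(t)`
* **changing niche** — `logit P(presence) = α + Σᵥ fᵥ(xᵥ, t) + g(t)`

where the `xᵥ` are five environmental covariates (BIO5 maximum
temperature of the warmest month, BIO6 minimum temperature of the coldest
month, BIO12 annual precipitation, net primary productivity, rugosity),
`fᵥ(xᵥ, t)` is an environment × time tensor-product smooth (penalized
B-spline margins, one wiggliness penalty per margin), and `g(t)` absorbs
the per-slice sampling normalization. Presences are contrasted with
random background points matched in time (50 per presence, 25 independent
sets), smoothness is selected by a REML-type criterion with an extra
complexity guard (γ = 1.4), and the two models are compared by AIC per
background repetition. Fits that pass a Continuous Boyce Index gate
(BCI > 0.8, presence-only evaluation) are combined into mean/median
ensembles, projected into per-slice suitability maps, thresholded to
binary range maps at the minimum-predicted-area (MPA) threshold covering
99% of presences, and summarized over the four major climatic periods
(pre-LGM 47–27 kya, LGM 27–18 kya, Late Glacial 18–11.7 kya, Holocene
11.7–7.5 kya).

A synthetic-paleodata module generates climate cubes with a glacial
cycle, shrinking ice sheets, a known (optionally change-point) niche, and
geographically biased sampling, so every stage of the pipeline is
testable against a known truth without downloading anything.

## Worked example

```python
import paleoniche as pn

# 1. simulate a study: climate cube + occurrences from a niche whose
#    cold-temperature optimum shifts from -12 degC to -2 degC at 16 kya
cfg = pn.default_scenario(seed=7)
cube, niche, occ = pn.generate_scenario(cfg)

# 2. window-filter, collapse to one record per cell per slice
coll = pn.collapse_occurrences(pn.filter_occurrences(occ), cube)

# 3. time-matched backgrounds and the model table
reps = pn.sample_background_repetitions(coll, cube, n_repetitions=1,
                                        ratio=50, master_seed=1)
table = pn.build_model_table(coll, reps, cube)

# 4. fit and compare the two models
fc = pn.fit_gam(table, pn.make_formula(pn.CONSTANT_NICHE, list(pn.VARIABLES)))
fg = pn.fit_gam(table, pn.make_formula(pn.CHANGING_NICHE, list(pn.VARIABLES)))
print(f"constant AIC {fc.aic:.1f}  changing AIC {fg.aic:.1f}  "
      f"delta {fc.aic - fg.aic:.1f}")
```

prints (seed 7):

```
constant AIC 5889.4  changing AIC 5828.3  delta 61.1
```

ΔAIC = AIC(constant) − AIC(changing) = 61.1 ≫ 2: the changing-niche
model is decisively better supported, which is correct — the generating
niche really did shift at 16 kya. On the constant-truth scenario
(`pn.constant_scenario`) the same comparison gives small negative deltas
and the constant model wins.

The full pipeline — 25 repetitions, diagnostics, BCI gate, ensembles,
maps — runs from one config:

```bash
paleoniche run --seed 11 --preset default --n-repetitions 5 --out runs/demo
```

writing model selection tables, BCI scores, suitability/binary maps
(netCDF), period summaries, interaction-surface bundles (CSV), and a
manifest with per-file hashes (two runs with the same config and seed are
byte-identical). Individual stages (`simulate`, `collapse`, `background`,
`fit`, `evaluate`, `project`) are also separately invokable.

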