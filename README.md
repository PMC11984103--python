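# adcomm — community metabolic modeling of anaerobic co-digestion

`adcomm` models the microbial community of anaerobic digesters co-fed
sewage sludge (SS) and food waste (FW).  It is aimed at researchers who
have species-level genome-scale metabolic models (from gapseq or similar),
a samples × species relative-abundance table, and reactor measurements, and
who want to simulate each sample's community metabolism, validate the
predictions against biogas measurements, and map who feeds whom and who
competes with whom.

## The model

For each sample, the species models (flux vectors per gram dry weight) are
joined through a shared medium compartment, weighted by relative abundances
*aᵢ*.  The medium availability of each compound — derived from the
feedstock recipe via a nutrient table, in mmol·gVS⁻¹·h⁻¹ — caps the
abundance-weighted community uptake.  Fluxes are predicted by cooperative
trade-off FBA (ctFBA) in three stages:

1. **LP** — maximize community growth μ_c = Σᵢ aᵢ μᵢ subject to per-species
   steady state **S**·**v** = 0, reaction bounds, and the medium limits,
   giving μ_c\*;
2. **QP** — minimize Σᵢ μᵢ² subject to the same constraints plus
   Σᵢ aᵢ μᵢ ≥ ct · μ_c\*.  The L2 objective spreads growth across members
   instead of concentrating it on the single most efficient species — the
   cooperation the trade-off parameter ct ∈ (0, 1] buys;
3. **pFBA** — fix each μᵢ near its stage-2 value and minimize total |flux|,
   resolving degenerate optima parsimoniously.

The trade-off is calibrated by maximizing the mean Pearson correlation of
predicted vs. measured CH₄ and CO₂ production over a 0.4–1.0 grid, with a
penalty when part of the archaeal community cannot grow.  Species
interactions are inferred in three stages: an abundance-correlation screen
(|r| ≥ 0.65, p < 0.001), then competition for negative pairs sharing an
imported compound above 0.01 mmol·gDW⁻¹·h⁻¹, and mutualism for positive
pairs where one member's export is another's import above the same
threshold.  Import-flux vectors can be embedded with t-SNE to visualize
metabolic niches.

Secreted hydrolases (amylase, pectinase, protease, lipase) are inserted
into species models from enzyme annotations via a curated reaction-template
table; their products are public goods reachable by the whole community.

Because the original reactor metagenomes are not shipped, the package
includes a first-class synthetic-data generator: a 20-species guild
community (hydrolyzers, fermenters, a syntrophic propionate oxidizer,
acetoclastic and hydrogenotrophic methanogens, competitors and fillers)
with exactly balanced textbook stoichiometry, a 49-sample FW-gradient feed
series, abundance series with planted correlations, and noisy measurement
series — all with machine-readable ground truth.

## A worked example

```python
from adcomm import calibrate_tradeoff
from adcomm.synth import ARCHAEA, SyntheticSpec, run_pipeline

ds = run_pipeline(SyntheticSpec(rng_seed=1, true_tradeoff=0.7))
result = calibrate_tradeoff(ds.communities, ds.measurements, list(ARCHAEA))
print(result.best_tradeoff)
```

This generates the default 49-sample dataset with measurements simulated at
trade-off 0.7, re-solves every sample across the 0.4–1.0 grid, and prints
`0.75` — one grid step from the generating value; the score table inside
`result.table` shows the prediction–measurement correlations peaking there
(r_CH₄ falls to 0.87 by ct 1.0).  The scripts in `examples/` walk through each
capability the same way — methanogen stoichiometry, feedstock media,
cooperative vs. plain FBA, interaction inference (it prints
`planted mutualisms recovered: 10/10`), calibration, and extracellular
hydrolysis — each printing the numbers it computes and what they mean.

A thin CLI mirrors the main steps:

```bash
adcomm synth --seed 1 --out data/
adcomm build-medium --recipe fw.tsv --nutrients nutrients.tsv --out medium.tsv
adcomm simulate --models data/models --abundance data/abundance.tsv \
    --medium medium.tsv --tradeoff 0.7 --out fluxes.tsv
adcomm infer-interactions --dataset data/ --out network.graphml
adcomm calibrate --dataset data/ --out calibration.tsv
```

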