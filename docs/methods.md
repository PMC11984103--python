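# Methods

## Community model

A community is the abundance-weighted union of species stoichiometric
models sharing one medium compartment.  Each species has three
compartments: cytosol (`c`), its own extracellular space (`e`), and the
shared medium (`m`).  Exchange reactions move compounds between `e` and
`m`; positive flux is secretion.  Keeping a per-species `e` compartment
(rather than wiring transporters straight into the medium) lets secreted
hydrolases be attributed to the species that encodes them while their
products remain community-public through the exchange reactions.

Units: species fluxes are mmol·gDW⁻¹·h⁻¹ (per gram dry weight of that
species); medium bounds and community totals are mmol·gVS⁻¹·h⁻¹ (per gram
volatile solids of feed).  The two scales are linked by the relative
abundances *aᵢ* and one explicit conversion factor `gdw_per_gvs`
(default 1.0), so community uptake of compound c is
Σᵢ aᵢ·`gdw_per_gvs`·(uptake of c by i) ≤ medium(c).  Species below the
inclusion threshold (default 0.1% relative abundance) are dropped per
sample and the rest renormalized to sum to one, so abundances stay a valid
weighting.

## Cooperative trade-off FBA

Stage 1 maximizes μ_c = Σ aᵢμᵢ (LP, HiGHS).  Stage 2 minimizes Σ μᵢ²
subject to Σ aᵢμᵢ ≥ ct·μ_c\* (convex QP, OSQP).  The L2 objective is the
pinned-down formulation of "cooperation": for a fixed weighted community
growth it spreads growth across members (with no other binding constraint
the optimum is μᵢ ∝ aᵢ), instead of the winner-take-all allocation plain
FBA produces when species compete for a shared resource.  Stage 3 fixes
each μᵢ within a relative band of its stage-2 value, re-imposes the
community-growth target as an explicit LP row, and minimizes Σ|v|
(parsimonious FBA via variable splitting v = p − n).

Numerical choices:

* Because stage 3 re-imposes Σ aᵢμᵢ ≥ ct·μ_c\* exactly, the trade-off
  contract holds to LP precision (~10⁻⁹) regardless of QP tolerance; the
  QP therefore runs at a loose ADMM tolerance (10⁻⁷) where it only has to
  localize the growth allocation.  The QP carries a 10⁻⁸ ridge on
  non-growth fluxes so it is strongly convex (this conditions ADMM; the
  parsimonious stage re-resolves flux degeneracy anyway).
* OSQP occasionally stalls on these degenerate polytopes with default
  settings; a retry ladder (smaller step size ρ, over-relaxation off)
  handles the stalls, with an LP fallback (minimize the largest deviation
  of μᵢ from a free common level — a Chebyshev analogue of the L2 spread)
  only if every rung fails or OSQP is absent.
* The stage-3 growth band is 10⁻⁵ relative (10⁻⁹ absolute floor), widened
  ×100 on infeasibility from QP round-off; if the band itself is
  unusable, it is dropped and only the growth target kept.
* Fluxes below 10⁻⁹ are reported as exact zeros; variable order is fixed
  (members in community order, reactions sorted by id), so solves are
  deterministic.  Community exchange totals are summed from raw species
  nets and then projected onto the medium-feasible box: LP primal
  residuals at the solver's default tolerances can leave an apparent
  uptake ~10⁻⁸ over its bound, and the projection (applied only within a
  10⁻⁶ guard) removes that artifact without touching per-reaction fluxes.
  Forcing tighter LP tolerances instead turned out to make vertex
  selection erratic across a trade-off grid, adding noise to predicted
  gas curves.
* Solvers over a trade-off grid reuse the per-sample problem: stage-1 is
  solved once (its optimum does not depend on ct) and the QP warm-starts
  from the previous grid point.

## Feedstock media

flux(c) = Σ_components grams·(mmol of c per gram) / (total g VS) / 24.
Daily loads become hourly fluxes by dividing by 24 (semi-continuous feeding
approximated as continuous).  SS and FW media are mixed convexly by their
VS loads.  Measured VFA concentrations (mmol/L) add
conc·turnover/VS(g/L) to the medium, with turnover defaulting to one
reactor volume per 21-day hydraulic retention time — the conversion from
concentration to flux is not uniquely determined by the reactor data, so
it is an explicit, overridable package choice.  The MFW food-waste group
is closed on both ends ([0.2, 0.6] g FW/L VS) since its neighbors are
defined by strict inequalities.

The packaged nutrient table for the eight food components is synthetic: it
is constructed so the recipe's carbon-mole composition lands at roughly
72% carbohydrate, 9% protein, 18% lipid — the macro-composition envelope
of real food waste — not to reproduce any measured food item.

## Extracellular augmentation

Enzyme annotations (EC/KO + predicted localization) map onto a curated
reaction-template table; only extracellular annotations map, and unmapped
enzymes are reported.  Augmentation adds the template reaction in the
species' `e` compartment, a medium exchange for every participating
compound, and an import transporter for each product, so the species can
eat what it liberates while the rest diffuses to the community.  It only
adds reactions — feasibility can never be lost — and is idempotent.
Extracellular reactions use the same bound convention as other reactions;
flux totals are abundance-weighted |flux| sums, broken down by the
molecule class (carbohydrate/protein/lipid, from a compound-class table)
of the most-consumed non-water substrate.

## Interaction inference

Pairwise Pearson correlations of relative abundance (exact t-transform
p-values, n−2 df); screen |r| ≥ 0.65 and p < 0.001, unadjusted (an
optional Benjamini–Hochberg mode exists, off by default).  Negative pairs
become competition edges when both import the same compound above
0.01 mmol·gDW⁻¹·h⁻¹ in at least `min_samples` samples (default 1; the
per-sample rule is the lenient reading and a stricter one is a flag).
Positive pairs become mutualism edges when an export of one is an import
of the other, both above the threshold, in either direction.  Water is
excluded from flux evidence: it is exchanged by essentially every
organism and carries no niche information.  Imports/exports are net per
species–compound pair, so a species never counts as importing and
exporting the same compound simultaneously.  The niche map embeds
(species, sample) import vectors with t-SNE (fixed seed, PCA init);
optional DBSCAN labels are advisory only.

## Trade-off calibration

For each grid value (0.4–1.0, step 0.05) all sample communities are
solved and scored by mean(r_CH₄, r_CO₂) − penalty·(fraction of
(sample, archaeon) pairs with zero growth).  The composite reflects that
a trade-off producing good gas correlations while predicting a
non-growing archaeal community is not credible; the exact weighting
(default penalty 1.0) is configuration.  Infeasible samples are recorded
per grid value, not fatal.  Ties break toward the larger trade-off (less
deviation from growth optimality).

## Synthetic data generator

The generator emulates the study design: 4 reactors × 12 sampling days
(+1 mid-ramp sample) = 49 samples; sludge at 1.5 g VS·L⁻¹·d⁻¹; FW ramped
to +1/+2/+3 g VS·L⁻¹·d⁻¹ over 30 days in reactors 2–4; a +2 g VS·L⁻¹·d⁻¹
FW pulse on days 125–139 for all reactors, so the LFW/MFW/HFW grouping
exercises all three labels.

Twenty species: the five-guild methanogenic chain (extracellular
amylolytic hydrolyzer, glucose fermenter, syntrophic propionate oxidizer,
acetoclastic and hydrogenotrophic methanogens), a protein pair (secreted
protease feeding a glutamate fermenter), a lipid pair (secreted lipase
feeding a glycerol fermenter), five competitor clones (acetate,
glutamate, glycerol, xylose, galactose), two dedicated sugar pairs
hosting two of those competitions, and four neutral fillers on private
sugars.  All catabolic reactions are elementally balanced whole-number
stoichiometries (glucose → 2 acetate + 2 CO₂ + 4 H₂; propionate →
acetate + CO₂ + 3 H₂; acetate → CH₄ + CO₂; 4 H₂ + CO₂ → CH₄ + 2 H₂O), so
methane yields have closed-form oracles.  Growth couples to catabolism
through an ATP pseudo-metabolite consumed by the biomass reaction
(pseudo-compounds carry no formula and are excluded from balance checks;
the biomass reaction is exempt by design).  Uptake transporters have
finite Vmax so abundances matter to community totals.

Abundances are log-normal with five latent factors, one per interacting
group; members load +0.97, planted competitors −0.97, with total log-sd
0.35.  These two values were chosen so that the generator meets its own
contract — planted pairs reach |r| ≈ 0.7–0.9 on the abundance scale after
the log-normal transform and compositional closure attenuate the latent
correlation — and the methanogenic-chain factor additionally tracks the
FW gradient (weight 0.45).  The ground-truth edge list contains exactly
the pairs that are both planted in the correlation structure and realized
as exchange fluxes above threshold when the communities are solved:
10 mutualisms and 5 competitions.  Pairs that correlate without a flux
route (e.g. hydrolyzer–propionate oxidizer) are deliberate decoys for the
screen, mirroring the fact that correlation alone over-counts
interactions.

Measurements are the ctFBA community CH₄/CO₂ fluxes at the generating
trade-off ct\* plus Gaussian noise (sd 0.02 mmol·gVS⁻¹·h⁻¹ against an
across-sample signal spread of ~0.1–0.3, i.e. roughly 10–20% noise),
truncated at zero; log₂ PTR is an affine transform of archaeal growth
(slope 3, intercept −0.5) plus noise (sd 0.1).  The trade-off is
identifiable because the two fermentation routes differ in ATP yield:
at high ct the efficient route monopolizes scarce sugar, at lower ct the
L2 spread reallocates it, changing the across-sample shape of predicted
CH₄ — so the prediction–measurement correlation peaks near ct\*.

What the generator does **not** emulate: genome-scale model size
(thousands of reactions), thermodynamic/enzyme-capacity constraints, pH
and inhibition dynamics, temporal autocorrelation within reactors, and
compositional artifacts of real amplicon/metagenome pipelines.  Passing
tests therefore demonstrate that the pipeline's logic and numerics
recover planted structure under its stated assumptions — not that the
thresholds would perform identically on real reactor data.

## Problem sizes and determinism

Default solves are ~300 variables per sample community (20 species ×
~15 reactions); a full 49-sample pipeline takes a few seconds, and a
13-point calibration sweep under twenty seconds on one core.  Tests
exercise the full default study size (49 samples, 20 species, 10 seeds
where a criterion is statistical).  All randomness flows from
`numpy.random.default_rng` seeds carried in `SyntheticSpec`/
`AnalysisConfig`; solver paths are deterministic, so fixed-seed pipeline
reruns are byte-identical.

## Known limitations

* The LP fallback for stage 2 (no OSQP) spreads growth by Chebyshev
  rather than Euclidean geometry; allocations differ in degenerate cases.
* Net import/export bookkeeping cannot represent simultaneous
  bidirectional exchange of one compound by one species.
* The calibration score is a heuristic composite; with very low
  measurement noise the correlation curve can plateau for one grid step
  around ct\*, which is why recovery is asserted to within one step.
* t-SNE coordinates are seed-stable but not comparable across datasets;
  only within-map distances are meaningful.
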