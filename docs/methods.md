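# Methods

## The model

`dictypatch` models the long-run consequences of carrying *Paraburkholderia*
symbionts for the social amoeba *Dictyostelium discoideum* in a patchy,
temporally varying food environment.

An environment is `n_patches` discrete soil patches (default 100). In round
*t*, each patch is independently food poor with probability *p_t* and food
rich otherwise. The mean food-poor probability is *p*; temporal variability
enters by drawing *p_t* each round from a beta distribution with mean *p* and
variance *v*<sub>temp</sub>, moment-matched as

    alpha = p k,  beta = (1 - p) k,  k = p(1 - p) / v_temp - 1,

which requires 0 < *v*<sub>temp</sub> < *p*(1 − *p*); *v*<sub>temp</sub> = 0
is the degenerate branch *p_t* ≡ *p* where all variation is spatial.

Three host phenotypes are simulated separately on the same environment:
uninfected, infected with *P. agricolaris*, infected with *P. hayleyella*.
All patches start occupied. Each occupied patch produces spores by resampling
one plate-level value from the empirical pool for its (phenotype, food state)
cell. Uninfected hosts produce nothing in food-poor patches (they cannot
carry food bacteria); infected hosts pay a fractional cost *c* in food-rich
patches, where symbiosis has repeatedly been found costly. Round totals are
divided into sori of 2×10⁵ spores (the dispersal unit; the fractional
remainder is rounded stochastically, which is unbiased and avoids a hard
cliff at low totals). Each sorus lands on a uniformly random patch and
establishes with probability *g*; multiply-colonized patches behave like
singly colonized ones, and previous occupants are assumed dispersed away, so
the colonized set *is* the next round's occupancy. A round with zero total
production is extinction; it is absorbing, and all later totals are 0.

Per-round totals over the horizon are summarized by the arithmetic mean (AM)
and the geometric mean (GM), with GM = 0 whenever any round is 0. GM is the
long-run growth criterion in variable environments; a strategy that beats its
rival in GM while conceding AM is bet-hedging.

### Outcome classification

For each parameter combination, replicate GM/AM comparisons between a focal
infected phenotype and the uninfected baseline are classified:

- **infected_wins / uninfected_wins** — that side has the higher GM in at
  least 75% of replicates (GM ties count for neither side);
- **bet_hedging** — infected wins, and more than half of the winning
  replicates have strictly lower AM than the uninfected baseline;
- **mixed** — neither side reaches 75%;
- **mixed_bet_hedging** — mixed, with at least one infected-winning
  replicate individually showing higher GM with lower AM;
- **extinction** — more than half of replicates lose *both* phenotypes, so
  the comparison has no survivor. A one-sided extinction is not labeled
  extinction: the survivor simply wins that replicate (GM 0 vs GM > 0).
  This choice matters: at *p* ≈ 0.9 uninfected hosts go extinct in most
  replicates while infected hosts persist, and those cells are wins for
  symbiosis, not undecidable. Per-phenotype extinction fractions are always
  reported in the cell so the one-sided cases remain visible.

Extinction-first precedence applies when the extinction rule and a win rule
both fire. Raising the win threshold can only move cells from win labels
toward mixed.

### Common random numbers and seeds

Within a replicate the environment stream is shared by the three phenotypes
(they experience the same world); each phenotype has its own demographic
stream, spawned deterministically from the replicate's demographic seed.
Sweeps derive per-cell seeds as `SeedSequence([master_seed, cell_index])`,
so cells are independent and a whole sweep is reproducible from one integer.

### Dispersal fast path

The per-sorus loop (land on a uniform patch, establish with probability *g*)
is O(number of sori), which can reach 10⁴–10⁵ per round. The production
implementation thins first — `n_hit ~ Binomial(n_sori, g)` — and spreads the
hits multinomially over patches; a patch is colonized iff its count is ≥ 1.
By binomial thinning this is *distributionally identical* to the loop, which
is retained as `method="per_sorus"` and used as the reference route in tests
(two-sample KS on colonized-patch counts).

## Continuous food

The continuous-food variant replaces binary patch states with per-patch food
amounts *f* ∈ [0, 1]: a shared resource follows a stationary latent AR(1)
process mapped into [0, 1] by a logistic transform (lag-1 autocorrelation
φ, innovation SD, and a latent offset controlling how often the world is
food-poor), and each patch adds Gaussian spatial noise, clipped to [0, 1].
Production interpolates linearly between the empirical draws:
(1 − *f*)·X_poor + *f*·X_rich, with the infected rich component scaled by
(1 − *c*). The linear mixture was chosen for its exact endpoint reduction:
with food forced to {0, 1} the continuous simulator reproduces the binary
model distributionally, which the tests verify by KS comparison. A
saturating response curve would be a plausible alternative; nothing in the
pipeline depends on the mixture beyond the endpoint property.

## Synthetic data

The generator stands in for the archived plate-level dataset. Spore counts
per (phenotype × food context) cell are lognormal — strictly positive,
right-skewed, as plate counts are — with multiplicative lognormal clone and
date random effects (random intercepts on the log scale) and per-cell
variance multipliers (food-poor plates are noisier). Defaults: 4 clones per
phenotype, 2 experiment dates, 12 plates per clone × date cell.

Default medians (spores/plate): uninfected rich 1.0×10⁸; infected rich
1.1×10⁸; *P. agricolaris* poor 1.65×10⁷ (15% of its rich output);
*P. hayleyella* poor 2.75×10⁷ (25%); uninfected poor exactly 0 (a structural
zero, enforced, not sampled). Two calibration points deserve comment:

- *Rich medians.* The infected rich median sits 10% above uninfected. At the
  plate-level noise used here (log-SD 0.4 plus clone/date effects) a 10%
  difference is statistically undetectable, consistent with finding no
  infection cost at low infection dosage; but the sign matters, because in
  mostly-rich environments the long-run comparison is decided by the rich-cell
  means, and a symbiosis that wins across *all* food conditions requires
  infected rich output not to fall below the uninfected baseline. Noise
  scales are set so the realized cell means of the default table stay within
  a few percent of these medians — the table is meant to *encode* the
  near-equality, not to re-randomize it away.
- *Absolute scale.* With sori of 2×10⁵ spores, a median rich plate yields
  ~550 sori, so at *g* = 0.05 an occupied rich patch sends out ~27 successful
  colonists while at *g* = 0.005 it sends ~3. This places the uninfected
  phenotype near criticality in harsh (high-*p*) worlds at *g* = 0.05 and
  clearly below it at *g* = 0.005 — the regime split where colonization
  ability starts to decide survival, which is the comparison of interest.

Symbiont density (OD600) per infected plate is lognormal with context-
dependent medians (higher on food-poor plates, where symbionts escape
competition with food bacteria; more strongly so for *P. agricolaris*).
Uninfected plates carry OD 0.

The default table (generator seed 0) is treated as fixed input data
throughout tests and the acceptance script, the way the archived empirical
table would be; simulation seeds, not the table, carry the randomness.

What the generator does *not* emulate: within-clone correlation structure
beyond a single multiplicative intercept, co-infection, partial infection
loss, plate-to-plate spatial effects, and any real dependence between spore
production and measured symbiont density. Passing tests therefore show that
the pipeline reproduces the study's qualitative structure under these
idealized inputs, not that it would reproduce every number from the real
archive.

## Density assay

Total OD600 of a washed plate is food bacteria plus symbionts. The standard
curve (OLS of OD600 on GFP fluorescence, free intercept — forcing the origin
is not assumed) predicts the food-bacterium component from fluorescence;
the symbiont density is `max(0, total_od - predicted)`. Negative raw
differences are clamped to 0 and flagged (OD is a physical density);
fluorescence outside the fitted range yields a flagged, not refused,
estimate. A quadratic term is fitted alongside as a curvature diagnostic
(significance at p < 0.05), since detector nonlinearity at high density
biases the subtraction. Predicted OD is validated against CFU counts by OLS
with r². All fits go through statsmodels.

## Problem sizes and numerical choices

Full-scale defaults match the study design: 100 patches, 100 rounds, 100
replicates per parameter combination, *p* ∈ {0.1, …, 0.9}. The package's own
standard test scale is 100 patches / 50 rounds / 20 replicates with
*v*<sub>temp</sub> ∈ {0.001, 0.01, 0.05} and cost regimes {0, 0.05, 0.15,
0.30}; at this scale every qualitative regime of the full-scale model is
already expressed (all-win at zero cost, the cost transition, transition-band
bet-hedging, low-*g* extinction), and a full two-cost sweep takes seconds.
The *v*<sub>temp</sub> grid and the cost regimes are package choices: the
grid spans "almost purely spatial" to "variance at half the feasibility
bound", and the costs span none to severe.

Degenerate inputs are handled explicitly: *v*<sub>temp</sub> = 0 bypasses
the beta; *v*<sub>temp</sub> ≥ *p*(1 − *p*) is an error (sweeps record such
cells as skipped rather than dropping them); GM of any series containing 0
is exactly 0 (no epsilon flooring); empty pool cells raise with the cell
named; classification ties (equal GM) count as wins for neither side.

## Known limitations

- At temporal variances near the feasibility bound the beta becomes U-shaped
  (α, β < 1) and the environment flips between all-poor and all-rich rounds;
  this produces catastrophe-driven bet-hedging cells at the low-*p* edge of
  the map in addition to the transition band.
- With food-poor production capped at 25% of rich, *P. hayleyella* is
  subcritical at *g* = 0.005 in mostly-poor worlds and goes extinct there
  alongside the other phenotypes; reproducing a survival advantage for it in
  that regime would require poor-context production above ~40% of rich.
- Phenotypes never compete within a patch (each is simulated against the
  environment alone, as in the study design), so the outcome maps compare
  strategies, not invasion dynamics.
- The continuous-food response and the resource mapping are structural
  stand-ins (linear mixture, logistic AR(1)); their endpoint behavior is
  exact but interior curvature is a modeling choice.
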