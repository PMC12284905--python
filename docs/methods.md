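# Methods

## Model structure and assumptions

`wolbsim` simulates a finite haplodiploid population in discrete daily time
with overlapping generations. The model assumes:

- **Arrhenotoky.** Unfertilized eggs develop into haploid males, fertilized
  eggs into diploid females. A fraction λ of eggs is fertilized; λ alone sets
  the natural sex ratio (males per female = (1−λ)/λ).
- **First-male sperm precedence.** A female's first mate fertilizes all her
  eggs for life; his haplotype and infection state are stored immutably.
  Males mate any number of times. Whether never-mated adult females lay
  unfertilized eggs is left open by the biology we model; here virgins do
  not oviposit until mated (they retry mating daily).
- **Maternal transmission.** Each egg of an infected mother inherits the
  infection independently with probability 1−μ. There is no horizontal or
  paternal transmission, so an uninfected population is absorbing.
- **CI with two outcomes.** In an incompatible cross a fertilized egg dies
  with probability σ_fm,eff (female mortality) and otherwise develops into a
  haploid male with probability σ_md,eff (male development), carrying only
  the maternal meiotic product (the oocyte haplotype). σ_fm + σ_md = σ_total,
  and rescaling σ_total preserves the FM:MD proportions.
- **Polygenic suppression.** L = 5 unlinked biallelic loci in the
  fertilizing male act strictly additively: s active alleles multiply both
  CI components by (1 − s/L). No epistasis, no fitness cost to carriers.
- **Sex-allocation distortion.** Infected mothers fertilize each remaining
  unfertilized egg with probability α = Sd/(1−λ); Sd is therefore capped at
  1−λ.
- **Fecundity benefit.** Each egg of an infected mother spawns one extra egg
  with probability F before fertilization is resolved.
- **Logistic density regulation.** Mortality removes a fraction ψ_t of the
  population uniformly at random each day — age-, sex- and infection-blind —
  so density regulation never distorts sex ratios or infection frequencies
  directly. Individuals surviving to their personal death age D are removed
  deterministically.

## CI rescue scope

With imperfect transmission an infected mother lays a fraction μ of
uninfected eggs, and two closures are possible when her stored sperm is
infected: protect those eggs through the mother's infection
(`female_level`) or expose them to CI (`egg_level`). Both are implemented,
in the engine (`ci_rescue_scope`) and in the recursions (`rescue_scope`);
`female_level` is the default in both, which keeps the two model layers
consistent and gives the female recursion the fixed point
f\* = (solved from f(1+F)(1+α(1−λ))(1−μ) = f(1+F)(1+α(1−λ)) + (1−f)(1−σm)),
≈ 0.981 under the reference parameters (σ_total = 1, μ = 0.018). The
egg-level recursion runs slightly hotter (its CI term also removes μ-loss
daughters of infected mothers). The σ_total = 0 limit — and hence the whole
Sd threshold algebra — is identical under both scopes.

## Parameters

| Symbol | Meaning | Default | Units |
|---|---|---|---|
| T | season length | 150 | days |
| K | carrying capacity | 5000 | individuals |
| P0 | founding adult females | 50 | individuals |
| D | death age | 20 (sd 0.5) | days |
| M | maturity age, female / male | 11 / 10 (sd 0.5) | days |
| Mp | oviposition peak age | 16 (sd 0.5) | days |
| Eggs_M, Eggs_Mp | schedule heights | 1, 10 (sd 0.5) | eggs/day |
| λ | fertilized-egg proportion | 0.8 | — |
| μ | transmission failure | 0 (reference 0.018) | — |
| L | suppressor loci per haplotype | 5 | — |
| σ_fm, σ_md, σ_total | CI strengths | 0 | — |
| F | fecundity benefit | 0 | — |
| Sd | sex-allocation distortion | 0 | — |
| ω0 | initial female infection frequency | 0 | — |
| r_half_day | day the logistic target reaches K/2 | 60 | days |

The reference ("Beis") parametrization is σ_fm = 0.98, σ_md = 0.02,
μ = 0.018, ω0 = 0.5. Founders are mated adult females at their individual
maturity age; exactly round(ω0·P0) are infected, and each founder's stored
sperm mirrors her own infection state (within-line matings), with suppressor
alleles i.i.d. Bernoulli(initial frequency) everywhere.

## Numerical choices

- **Oviposition schedule endpoint.** The declining branch is anchored at
  zero eggs at age D, the only value making the schedule continuous at Mp
  and vanishing at death.
- **ψ clamp and calibration.** ψ_t is clamped to [0, 1]; it is zero whenever
  the population sits below the logistic target. r = ln(A)/r_half_day places
  the target exactly at K/2 on day `r_half_day`. When a season starts at or
  above K/2 the midpoint calibration is ill-posed (A ≤ 1): r is retained
  from the run's first season (with full carryover A ≈ 0 and the target is
  ≈ K regardless); a run *founded* above K/2 holds its target at the
  founding size — a degenerate regime outside normal use.
- **Mortality sampling.** Exactly round(ψ_t·P_t) individuals are removed
  without replacement (lower variance than per-individual Bernoulli
  thinning, same mean).
- **Trait draws.** Newborn traits are redrawn until M < Mp < D (an ~8σ
  event at the defaults); ages are integers compared against real-valued
  thresholds, and egg counts are Normal(expected, 0.5) rounded and clamped
  at zero.
- **Daily bookkeeping.** The CI-cross fraction is counted over mated females
  laying ≥ 1 egg that day, with the cross typed at the mother level
  (uninfected mother × infected sperm). Frequencies over empty categories
  report 0. Suppressor-flow statistics count maternal plus paternal allele
  copies: "lost in CI" is alleles in FM-killed eggs relative to alleles in
  newborns of compatible crosses; "newborn from CI" is the CI-cross share of
  all newborn suppressor alleles.
- **Season transitions.** Day resets, ages and states carry over, A is
  recomputed from the new founding size. `full` carryover keeps everyone
  (drift-free bookkeeping at K); `subsample` keeps P0 random individuals
  (periodic bottleneck).
- **Seeds.** One `numpy` Generator per replicate; replicate i of a campaign
  uses base_seed + i (grid campaigns offset by cell), so every campaign is
  bit-reproducible and paired contrasts share seeds across arms.
- **Recursion bookkeeping.** Days map to generations as floor(days/11);
  remainder days are not fractionally iterated. Out-of-range fixed-point
  predictions are reported as explicit loss (0) or capped at 1, never
  silently saturated inside the iteration.
- **Gamma fits and censoring.** Persistence campaigns censor at a stated
  horizon; fits use uncensored times only (`scipy` MLE with the location
  pinned at zero), and an all-equal sample reports the degenerate
  infinite-shape limit rather than an error.
- **Fecundity threshold.** F samples are sorted and a trailing moving
  average (default lag 10) of end-of-horizon frequencies is scanned; the
  first window reaching ω0 defines Fc (ties broken by the first index; an
  immediately satisfied first window returns the smallest sampled F).
- **Relative RMSE.** Simulated daily means are linearly interpolated to the
  observation days; the RMSE is normalized by the mean observed frequency
  by default (range and final-value normalizers are selectable).

## What the simulations emulate — and what they do not

The engine is both the model and the test-data generator: campaigns at the
defaults above *are* the study conditions, and every test statistic is
computed from freshly simulated populations. The simulations emulate mite
demography (strongly juvenile-biased mortality: ~63% of dying individuals
die within their first three days; ~6% of females reach adulthood), the
transient sex-ratio disturbances of CI sweeps, and drift from the seasonal
P0 = 50 founding bottleneck. They do not emulate spatial structure, plant
patch dynamics, diapause, temperature-dependent transmission, multiple
symbiont variants or bidirectional CI, male fitness costs of suppressors, or
measurement error in field sampling — so passing tests establish internal
consistency of the model under its own assumptions, not field realism.

## Scales used in the test suite

Test and verification runs are sized to keep the full suite in a few
minutes: single-season campaigns run at full scale (K = 5000, 30–100
replicates); the recursion-vs-simulation bias uses a 6×6 grid at 10
replicates per cell; persistence and fecundity-threshold checks run at
K = 600–1200 with 6–24 chains over 8–40 year horizons and assert ordering
and order of magnitude only. At reference scale (K = 5000, 100 replicates,
100-year horizons) `wolbsim persistence` and `wolbsim fc-threshold` are
multi-hour jobs.

## Known limitations

- **FM vs MD suppressor spread.** Per fertilized egg of a CI cross whose
  male carries s ~ Binomial(L, p) suppressors, the expected excess of
  suppressor alleles transmitted relative to the pool frequency is
  λp(1−p) under *both* strict FM and strict MD — the first-order selective
  flux on suppressors is identical, FM trading fewer surviving offspring
  for a higher per-capita enrichment. In this implementation the two
  regimes consequently spread suppressors at statistically indistinguishable
  rates at testable scales; they differ sharply in the *routes* (FM destroys
  alleles in CI crosses, strict MD destroys none and recycles maternal
  copies into males), which the daily suppressor-flow statistics expose.
  Claims that one regime fixes suppressors severalfold faster would rest on
  higher-order population feedbacks this model does not reproduce.
- **Persistence scale.** At reference scale a neutral infection (σ_total = 0,
  μ = 0.018, full carryover) persists ≈ 20 years in the mean (gamma
  distributed across replicates). This is sensitive to the emergent
  generation time (~12–14 days), which is itself an output of the trait
  schedule rather than a parameter.
- **Quasi-stationarity.** The Sd fixed-point predictions describe an
  infinite population; finite runs drift around the predicted frequency
  (sd ≈ 0.1 per replicate at K ≈ 10³) and are eventually absorbed at loss,
  so small-K long-horizon means sit below the prediction.
- The deterministic recursions assume non-overlapping generations and an
  infinite population; they overestimate invasion relative to the
  simulation, most strongly at high CI strength and low initial frequency.
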