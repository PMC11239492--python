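# Methods

## The model

A clonal organism is represented as a population of up to `Z` modules, each
module being the stem-cell pool of one ramet (all somatic tissue descends
from these cells and is ignored). The state of a module is the multiset of
its cells' mutation-identifier sets; diploidy enters only through the
read-level convention that a variant fixed in all stem cells sits at allele
frequency 0.5 in bulk sequence.

Dynamics are an exact continuous-time Markov jump process simulated with
the Gillespie algorithm. Four channels exist, with rates recomputed after
every event:

| channel | rate | effect |
|---|---|---|
| growth division | `b · n_growth` | a uniformly chosen cell of a growing module divides (pure birth); at size `N` the module enters homeostasis |
| symmetric (Moran) division | `λ · N · Z_hom` | in a uniform homeostatic module, a uniform cell divides and a different uniform cell is removed |
| asymmetric division | `γ · N · Z_hom` | a uniform cell divides; one progeny stays, the other leaves the stem compartment |
| module formation | `r · Z_hom` | a uniform homeostatic module founds a child from `N0` cells sampled without replacement — *branching* copies them (parent unchanged), *splitting* removes them (parent re-enters growth); at the cap `Z` a uniformly chosen module dies first |

`n_growth` is the total cell count of growing modules and `Z_hom` the
number of homeostatic, non-quiescent modules; quiescent modules contribute
to no channel. Every newly divided cell draws Poisson(`μ`) novel mutations
with globally unique integer identifiers (genome positions are not
modelled; counts suffice for the clock). A variant is *fixed* in a module
when every cell carries it; `count_fixed` is the size of the intersection
of the cells' sets. Waiting times are exponential with the summed rate; a
fixed seed makes entire trajectories bit-reproducible.

### Parameters (units, defaults)

- `b = 122 /yr/cell` — division rate during growth (eelgrass meristem scale).
- `λ = 0`, `γ = 122 /yr/cell` — homeostatic turnover. Purely symmetric
  division is `λ = b` (or `b/2`), `γ = 0`; purely asymmetric is `λ = 0`,
  `γ = b`. The package default is purely asymmetric: in that regime
  fixation happens only through formation bottlenecks, which is the
  drift mechanism the clock is built on and the harder case for lag.
- `r = 5 /yr/module`, `N = 10`, `N0 = 3`, `Z = 100` — formation rate,
  homeostatic size, founder count, module cap; defaults sit mid-range of
  plausible seagrass values (`N` 7–12, `N0` 1–7, `r` 3–8/yr).
- `μ = 0.0069` mutations per cell division (genome-wide, eelgrass scale);
  the equilibrium accumulation rate of fixed variants is `μ·b` per year.
- `ξ` (default 0) — a lifetime-dependent mutation channel: at division the
  dividing cell first acquires Poisson(`ξ·(t − birth_time)`) mutations,
  then the daughters' birth times reset. This charges age-dependent damage
  without adding event types.
- Quiescence: *stochastic* (homeostatic modules enter at `rate_in`, leave
  at `rate_out`, as two extra Gillespie channels) or *seasonal* (a
  deterministic duty cycle; the first `active_fraction` of each `period`
  has normal rates, the rest zero). Seasonal dormancy is implemented as an
  exact time warp between "active time" and wall time, so no approximate
  rate switching is involved.

### Conventions decided where the description is open

- *Mutation draws*: each newly divided daughter draws Poisson(`μ`)
  independently (`mutation_draws="per_daughter"`, switchable to one shared
  count per division). For asymmetric division only the retained progeny
  draws — the removed cell leaves the stem compartment immediately and can
  never contribute to fixation.
- *Kill rule at the cap*: the victim is uniform among existing modules,
  excluding the (not yet created) child; whether the parent is protected is
  a switch (`kill_excludes_parent`, default off).
- *Splitting bound*: `N0 ≤ N − 1`, so a parent is never split to emptiness.
- *Performance*: asymmetric homeostatic divisions that draw zero mutations
  leave the state bit-identical, so by default that channel is thinned to
  rate `γ·N·Z_hom·(1 − e^{−μ})` with zero-truncated Poisson draws. The law
  of the state trajectory is unchanged (only no-ops are skipped); the
  option is disabled automatically when `ξ > 0` and can be turned off.

## Conditional fixation times and their oracle

The closed forms `4N0(1 − N0/N)/r` (splitting), `4N0/((1 − N0²/N²) r)`
(branching) and `N/b` (Moran) are diffusion approximations for the expected
time, conditioned on fixation, for a neutral variant starting in one cell.
They are exposed verbatim as published reference values: they set the
timescale on which the clock becomes applicable for a given life history
(e.g. 6 yr at `N=12, N0=4, r=3/yr` branching; 0.1 yr at `N=12, b=122/yr`
symmetric).

`wf_fixation_oracle` simulates the bottleneck renewal process directly
(hypergeometric sample of founders, stochastic pure-birth regrowth,
bottlenecks at rate `r` along a module lineage; under splitting the lineage
follows the `N0`-cell child or the `N−N0`-cell remainder with equal
probability), and `moran_fixation_oracle` simulates the Moran chain. Two
quantitative caveats, measured by the acceptance suite and deliberately not
papered over:

- The Moran chain's exact conditional fixation time from one copy is
  `(N−1)²/(N·b)` (first-step analysis), so the `N/b` form carries a
  `((N−1)/N)²` finite-size factor (−16 % at `N = 12`). "Scale agreement" is
  what the closed form claims and what holds.
- The bottleneck oracle gives systematically *shorter* times than the
  branching closed form (by roughly 3–4×, e.g. oracle ≈ 2.6 vs 8.0 at
  `N=6, N0=2` in units of `1/r`), and matches the splitting form only near
  `N0 ≈ N/2`. Exact first-step analysis of the discrete chain confirms the
  simulation, and a full agent-based run shows first fixations and lag
  phases shorter than the branching form predicts. The published closed
  forms therefore behave as conservative upper-bound guidance for the lag
  under branching rather than as sharp approximations of this microscopic
  process; the derivation they come from is not reproduced here, and the
  acceptance test that demands 15 % agreement documents the discrepancy by
  failing.

## The calibration-design rate estimator

`simulate_calibration_slopes` mimics the two-timepoint calibration
methodology: per replicate, independent genets are simulated to ages 4 and
17 years (three genets × two sampled modules; two genets × five and six
modules), per-genet mean fixed counts are regressed on age by OLS (with
intercept, unweighted), and the slope estimates the accumulation rate. At
the desk-scale cap `Z = 100` the replicate standard deviation of the slope
is somewhat inflated relative to large module populations: the module
genealogy coalesces on the timescale `Z/r` (20 yr, comparable to the 17-yr
horizon), so sampled modules share ancestry and bottleneck-synchronised
fixation makes per-genet means over-dispersed. The mean slope stays within
a few percent of `μ·b`.

## The clock

- *Pairwise statistic*: `VRF50(X1, X2)` = count of sites with normal depth
  ≥ 12, tumor depth ≥ 23, normal VRF ≤ 0.01 and tumor VRF ≥ 0.50. The four
  thresholds are config defaults (`FilterThresholds`), bit-exact to the
  published pipeline and overridable. Zero-depth records fail the depth
  thresholds; they never raise. Duplicate sites within one pair table are
  an input error.
- *Per ramet*: `VRF50(R_x)_obs` = max over clonemates used as normal — the
  most divergent clonemate best approximates the extinct founder.
- *Genet mean*: `(average VRF50_obs)/(average Size_e) × genome size`, the
  averages running over all ramets of the lineage; `Size_e` is the count of
  sites with coverage ≥ 23.
- *Uncertainty*: the number of fixed variants is modelled as Poisson, so
  the 95 % CI is `m ± 1.96√m`, floored at zero. Ages invert through the
  calibration line `y = slope·x + intercept` (x = age, y = mean VRF50) with
  coefficients treated as fixed; regression uncertainty (adjusted R²,
  n) is reported as a diagnostic, not folded into the CI. Negative
  predicted ages floor at zero and set a `clipped` flag.
- *Totals*: fixed mutations = `2 × mean VRF50`, because the VRF ≥ 0.5 filter
  keeps the right half of the symmetric read-frequency distribution of
  variants at true frequency 0.5.

## The synthetic generator

What it emulates: ramets as leaves of an ultrametric genealogy rooted at
the founder zygote; fixed variants as a Poisson process on branches
(carried at frequency 0.5 by exactly the leaves below); mosaic variants
private to single ramets at Uniform(0.05, 0.35) frequency (the true mosaic
spectrum is uncharacterised — this default is a labelled assumption that
fails the VRF ≥ 0.5 filter at high depth and stresses it at low depth);
per-(ramet, site) depths drawn once and reused in every pair (the same
physical reads), negative-binomial over-dispersed (`var = d + φ·d²`,
`φ = 0` giving fixed depth) with symmetric error `e`: alt reads ~
Binomial(depth, `f(1−e) + (1−f)e`). `Size_e` is a binomial draw of callable
sites over the genome (default 10⁷ bp, scaled down from the ~2×10⁸
reference for speed).

Genealogy patterns: `star` (all splits at founding) is the calibration
default — the sampled genealogy of a rapidly expanding clone, under which
each ramet's fixed-variant count is an independent Poisson(rate × age) draw
and the expected calibration slope is exactly `0.5 × rate`. `yule`
(uniform split times) models slowly expanding clones, where the shared
trunk is invisible to the pairwise statistic and the recovered slope drops
by the expected hidden fraction; `caterpillar` gives a comb. Passing tests
on star genealogies therefore validates the clock's own statistical model,
not the (unknowable) genealogies of field genets.

What it does not emulate: read sequences, mapping and calling artefacts,
indels/CNVs, linked sites, contamination, or heterogeneous per-site error.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, as the package's own
choice: module cap `Z = 100` (versus 1,000 at full scale), 24–40 replicate
simulations per ensemble, 30–50 synthetic calibration fixtures, oracle
grids at ~2,600×N chains per point. Slope recovery for the clock is
assessed on the *mean* fitted slope over replicate fixtures because a
single five-genet calibration has sampling s.d. ≈ 0.08 on a slope of 0.5.
OLS fits use statsmodels (calibration, with adjusted R²) or `numpy.polyfit`
(two-point rate designs). RNG streams derive from `numpy.random.SeedSequence`
spawning, one child per genet/replicate, so results are reproducible and
independent across units. Coordinates in site-bearing files are 1-based
inclusive.

## Known limitations

No selection, no spatial structure, no multi-layer meristem (the one-layer
reduction), no diploid genotypes inside the simulator, no variant calling.
The clock assumes clonemate assignment is correct and that the calibration
rate transfers across environments; the Poisson CI ignores calibration
uncertainty, which matters for extrapolation far beyond the calibrated age
range.
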