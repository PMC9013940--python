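# Methods

`peerspread` simulates a school-based social-network health-behavior
intervention on a synthetic adolescent friendship network with explicit
gender structure, and reproduces the descriptive statistics of the cohort
that motivated the model's parameters.  This note records the model, the
conventions chosen where the published description is ambiguous, and what the
package's own experiments do and do not reproduce.

## The network model

The substrate is a Watts–Strogatz-style small world over `n = 234` agents
(113 girls, 121 boys, matching the study cohort):

1. **Ring lattice.** Each agent links to its `k/2` nearest neighbours on
   either side (`k` even, default 6 after calibration; the ring-with-four-
   links construction corresponds to `k = 4`).
2. **Gender placement.** Genders are placed on the ring by one of four
   layouts: `blocks` (two contiguous arcs), `interleaved`, `random`, or
   `clustered` — `B` alternating same-gender runs per gender
   (`blocks` is `B = 1`).  The clustered layout models gender-homophilous
   friendship circles and is the axis that controls the achievable
   cross-gender link share: with `B` runs per gender on a degree-`k` ring the
   lattice's male–female link share is about
   `2B * (k/2)(k/2+1)/2 / (n k / 2)`.  Two arcs cap it near 1–3%; full
   alternation forces ~50%; `B ≈ 12` on a `k = 6` ring yields the ~21%
   reported for the study network.  Neither pure layout can reach 21% under
   any rewiring probability ≤ 0.2, which is why the clustered layout exists.
3. **Gender-aware rewiring.** Every lattice edge is independently selected
   with probability `p`; for a selected edge `(u, v)` the far endpoint `v`
   is replaced by a uniform draw `w ≠ u` not already adjacent to `u`, taken
   from `u`'s own gender with probability `q` (homophily) and from all
   agents otherwise.  Edge count and simplicity are invariant; degrees are
   not.  `q ≈ 0.5` keeps the cross-gender share approximately invariant
   under rewiring at the calibrated operating point.

**Structural metrics.** Mean local clustering coefficient (nodes of degree
< 2 contribute 0), average path length over all unordered connected pairs
(largest component with a flag if disconnected; shortest paths via
`scipy.sparse.csgraph`), and the (male–male, female–female, male–female)
link-type proportions.

**Calibration.** The published construction is under-determined: the achieved
metrics (CC 0.43, APL 4.81, proportions 0.41/0.38/0.21) are reported but the
generator settings are not, and no `(k ≤ 4, p ≤ 0.1)` setting can produce
APL ≈ 4.8 at `n = 234`.  `calibrate_spec` therefore grid-searches
`k ∈ {4,…,12}`, `p ∈ [0.01, 0.2]`, `q ∈ [0, 1]` and the layouts
(including clustered with `B ∈ {4, 8, 12, 16}`), scoring each candidate by
`1·|ΔCC| + 0.25·|ΔAPL| + 10·Σ|Δproportion|` averaged over seeded replicate
networks (weights configurable; proportions weighted heavily because they are
the only explicitly targeted quantities of the link-structure block).  A
cheap screen (3 replicates) ranks all candidates and the best twelve are
re-scored with the full replicate count (default 20).  The search selects
`k = 6, p = 0.09, q = 0.5, clustered B = 12`, achieving
CC ≈ 0.46, APL ≈ 4.7 and proportions ≈ (0.41, 0.38, 0.21); this spec is
recorded as `DEFAULT_NETWORK_SPEC` and re-derived from scratch by the
acceptance pipeline.

## Seed selection

The intervention trains the top `floor(0.15 · n) = 35` agents ranked by one
of four centralities, against a uniformly random condition:

* **Betweenness** — shortest-path betweenness with fractional credit for
  tied geodesics, normalized by `(n−1)(n−2)/2` (networkx implementation,
  validated against exhaustive geodesic enumeration).
* **Closeness** — Wasserman–Faust form
  `((r−1)/(n−1)) · ((r−1)/Σd)` over the `r` reachable nodes, so scores stay
  comparable on disconnected graphs; isolated nodes score 0.
* **Eigenvector** — power iteration from a uniform positive vector,
  L2-normalized per step, converged when successive iterates differ by less
  than `tol` in max-norm, final scores rescaled so the maximum is exactly 1.
  The iteration runs on `A + I`, which has the same eigenvectors as `A` but a
  strictly positive spectrum: this removes the ±λ oscillation of bipartite
  components and tightens the Perron gap.  On disconnected graphs each
  component is iterated separately and the scores of the component with the
  largest spectral radius (Rayleigh quotient of `A`) are kept, zeros
  elsewhere, with a flag.  Single-gender subnetworks of the calibrated
  generator occasionally have two components with near-tied radii, which is
  why the default iteration budget is large (50 000).
* **PageRank** — undirected PageRank with damping 0.85 (the walker teleports
  15% of the time); defined for any graph, scores sum to 1.

Ties at the 15% cut are broken by lowest node id (deterministic) or by a
seeded random permutation.  All four measures are cross-checked in the test
suite against independent dense oracles (geodesic enumeration, symmetric
eigensolver, linear solve of the PageRank system) on every connected graph
with ≤ 7 nodes and seeded samples of 8-node graphs, at 1e-6.

## The contagion model

Discrete synchronous ticks; both phases of a tick read only the tick-start
state.

* **Infection.** An uninfluenced agent with influenced neighbours is
  influenced with probability `1 − Π (1 − s_link)` over those links, where
  the per-tick, per-link spread chance depends on the link's gender
  composition: male–male 0.20, female–female 0.25, male–female 0.10.
* **Reversion.** Influenced agents fail to persevere with a gender-specific
  resistance chance (male 0.10, female 0.20) and re-enter the uninfluenced
  pool, after which they can be influenced again.  The one-sentence
  persistence rule admits two readings, both implemented:
  * `per_tick` — every influenced non-seed re-draws perseverance each tick
    (a standard susceptible–infected–susceptible process);
  * `on_influence` — a newly influenced agent draws once: with probability
    equal to its resistance chance it reverts at the next tick and re-enters
    diffusion, otherwise it is permanently persisted.
* **Seeds** are committed to the intervention and immune to reversion by
  default (`seeds_immune`, exposed as a flag).

**Stopping.** A run ends at *absorption* (everyone influenced and nobody
able to revert), at *equilibrium* (every consecutive per-tick change of the
influenced fraction across a trailing 10-tick window below 0.5 percentage
points), or at `max_ticks = 500`.  Diffusion speed is
`100 · (final − initial influenced fraction) / ticks_elapsed`, where
`ticks_elapsed` is the absorption tick, or the tick at which the quiet
window *began*: the detection window itself contains no spread by
construction and would otherwise penalize the speed by an arbitrary window
length.

**Mode selection.** A one-time calibration pass (`calibrate_modes`) runs the
random and PageRank conditions under all four
(reversion mode × success metric) pairs and scores them against the
published random/PageRank population speeds and random success rate.  The
`per_tick` reading settles into an endemic plateau near 85% coverage whose
tick-to-tick churn (several agents per tick) never satisfies the equilibrium
rule, so runs hit the tick limit and the published ~99% success rates are
unreachable.  The `on_influence` reading absorbs at ~99–100% coverage in
12–17 ticks and dominates the loss by an order of magnitude; it is the
package default, with success reported as the mean final influenced
percentage (`final_fraction`; the replicate-threshold variant is equivalent
at the calibrated operating point).

## The experiment harness

Each condition runs `n_replicates` (default 500) independent replicates.  A
replicate derives three child RNG streams from
`SeedSequence((macro_seed, condition index, gender-group index, replicate))`
— network generation, seed selection, diffusion — so conditions are
comparable but streams never collide; a fresh network is generated per
replicate (fixed-network mode available).  Summaries report mean ± sd of
success and speeds; comparisons report pooled centrality means, pairwise
Welch (unequal-variance) t-tests on per-replicate speeds, and rank orders.

**Per-gender speeds.** Three quantities are computed because the published
per-gender rows cannot be the subgroup-normalized speeds of the population
runs — those are weighted-average-consistent with the population speed and
therefore can never lie below it, while the published per-gender values are
roughly half the population value:

1. `speed_{g}_subgroup` — subgroup denominator, global elapsed ticks;
   exactly recombines to the population speed weighted by subgroup shares
   (property-tested).
2. `speed_{g}` — the gender's population-share contribution per tick of its
   own curve-stabilization time.
3. **Single-gender subnetwork runs** (`run_condition(..., gender=...)`) —
   the intervention restricted to the girls-only or boys-only induced
   subgraph, seeds being the top 15% of the subgroup.  These are what the
   per-gender rows of the results table report in this package: they
   reproduce, without any tuning, every qualitative per-gender finding of
   the study — female runs faster than male runs under every centrality
   condition, betweenness and PageRank the two leading conditions for girls,
   PageRank the leading condition for boys.

## Synthetic cohort

The study cohort (three annual measurement rounds of 234 students) is not
public.  `generate_synthetic_cohort` reproduces its published margins: exact
per-(gender, round) overweight/obesity counts (integer numerators recovered
from the printed percentages by `reconstruct_counts`, which is an exact left
inverse of two-decimal percentage printing for n ≤ 1000), approximate
per-round mean BMI, and a latent fitness score with a configured negative
correlation (default −0.589) to final-round BMI.  Students carry a
persistent size propensity so status is nested across rounds; BMI values are
truncated-normal draws (bounds 10–45 kg/m²) minimally shifted across the
classification cutoff so counts are exact; PF categories are quantile cuts
(20/30/35/15%) of a noisy per-round fitness value.  The default BMI cutoff
table (girls 22.2/25.2, boys 22.6/25.7 kg/m² for ages 13–15) is a synthetic
stand-in for the national standard's unpublished percentile tables and is
fully configurable.  What the generator does **not** emulate: realistic BMI
distribution shape beyond the first moment, within-student BMI trajectories,
the published per-round p-values (the exact test variants behind them are
not identifiable from the printed aggregates), and the "unhealthy weight in
PF-test failure" row, whose denominator is ambiguous.

Statistical operations (pooled two-proportion z-test, Pearson chi-square
without continuity correction by default, Pearson correlation) delegate to
statsmodels/scipy; degenerate inputs (pooled proportion 0 or 1, zero
expected counts, constant vectors) raise rather than returning arbitrary
values.

## What the experiments reproduce, and what they do not

With the calibrated generator and the calibrated reversion mode, the
acceptance pipeline (problem sizes: 100 networks for structural metrics, 500
replicates per condition for dynamics) reproduces:

* the structural targets — clustering ≈ 0.46 vs 0.43, path length ≈ 4.69 vs
  4.81, link proportions within ±0.01 of 0.41/0.38/0.21;
* the pooled centrality population speed (≈ 6.1 vs 6.17 %/tick) and the
  PageRank condition speed (≈ 6.9 vs 6.37 %/tick), with PageRank the
  fastest condition overall;
* near-total success rates (≈ 100 vs 98.91%);
* all qualitative per-gender orderings listed above.

It does **not** reproduce the random-condition population speed (≈ 6.7 vs
5.22 %/tick — in this implementation random seeding is nearly as fast as
central seeding at the population level, and closeness/eigenvector seeding
is slower than random because those seed sets are spatially clustered on the
calibrated topology), nor the absolute per-gender speeds (≈ 3.5–6.0
simulated vs 2.85–3.85 published).  The published table is internally
inconsistent with any single per-run normalization we could identify (its
per-gender rows neither sum nor average to its population row), and the
original implementation's update order, stopping rule and speed
normalization are unpublished; the residual discrepancies are consistent
with a systematically slower original engine rather than with a different
qualitative regime.  We report our measured values unchanged.

## Numerical and degenerate-input conventions

* Rewiring with no admissible target (pathological small graphs) leaves the
  edge in place with a warning.
* Empty seed sets warn and produce a flat all-uninfluenced trajectory; a
  zero-tick trajectory raises on speed computation.
* Percentage displays round half away from zero to 2 decimals; internal
  computation is unrounded.
* All stochastic components accept explicit seeds or `SeedSequence` children;
  identical seeds give bit-identical networks, trajectories and output files.
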