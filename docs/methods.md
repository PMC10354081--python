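# Methods

`biogeodyn` analyses how a biome (canonically the Arctic tundra flora) was
assembled over time from many independently dated clades. This note records
the models, the numerical choices, what the synthetic-data layer does and
does not emulate, and the limitations we have measured.

## The DEC range-evolution model

Geographic ranges are non-empty subsets of an ordered area set, capped at
`max_range_size` areas (by default the largest range observed among extant
tips). Along a branch the range evolves as a continuous-time Markov chain:

* expansion into area *j* at rate `d · Σ_{i∈G} m[i, j]`, where `m` is the
  per-time-slice dispersal multiplier matrix (values in [0, 1]; branches
  crossing a slice boundary are integrated piecewise against each slice's
  generator);
* extirpation from each occupied area at rate `e`; a singleton range decays
  into the empty (null) range, an absorbing state representing lineage-wide
  extirpation that is excluded from tips, cladogenesis and the root prior.

At a speciation node a singleton range is copied to both daughters. A
widespread range `G` splits by subset sympatry (one daughter keeps `G`, the
other one constituent area) or by vicariance (one singleton, the remainder),
every unordered scenario equally likely. `d` and `e` (units: events/Ma) are
estimated by bounded L-BFGS-B from two fixed starting points, so fits are
deterministic. Marginal ancestral ranges come from a standard two-pass
(inside/outside) algorithm; MAP ties break to the first state in the
deterministic size-then-area order.

**Daughter exchangeability.** The likelihood treats the two daughters of a
node as exchangeable: each unordered splitting scenario has weight
1/(number of unordered scenarios) and contributes through both assignments
of its two ranges to the two children. For a cherry with tips `A` and `B`
and `d = e = 0` the root-conditional likelihood of `AB` is therefore 1/3
(the vicariant scenario's weight 2/6 times the matching data), not the 1/6
an ordered-scenario convention would give. The two conventions order
parameter fits identically in our simulations, but the exchangeable one
slightly inflates support for widespread ancestral states relative to
ordered-scenario implementations; on small clades this shows up as more
`AB` MAP reconstructions. `cladogenesis_distribution` (used by the forward
simulator) still reports ordered scenarios with equal probabilities summing
to one; the two views describe the same unordered distribution.

The brute-force oracles in the test suite (explicit enumeration over all
internal-node state assignments with matrix exponentials) agree with the
pruning implementation to ~1e-15, including time-sliced multipliers.

## Event classification

With MAP ranges on every node (tips from the coding table, internal nodes
from the reconstruction):

* **dispersal into the focal area** — an edge whose child range contains
  the focal area while the parent range does not. The timing window runs
  from the parent node's older 95% HPD bound (or its point age) to the
  child node's younger bound: the gain happened somewhere on that branch.
  Cladogenetic gains are impossible under DEC (daughters are subsets), so
  the edge rule captures every colonisation without double counting; a
  gain-loss-regain path counts once per gaining edge.
* **in-situ diversification** — a node whose range and both children's
  ranges contain the focal area, timed by the node's HPD.

An in-situ node whose stem edge also gained the focal area yields both
events: the two classes are tallied independently. Dispersal events are
annotated with a source region from a finer regional reconstruction when
the parent's non-focal range names exactly one region; widespread parents
stay unassigned and are excluded from per-source percentages (so the
per-source denominator is smaller than the dispersal total).

## MDE curves and features

The MDisE/MDivE statistic counts, per 0.1-Ma slice, the events whose
credibility interval overlaps the slice ("maximal number of observed
events"). Bins run old to young from the oldest interval bound, the last
bin clipped at 0 Ma; each bin is the half-open window (younger, older], so
closed intervals — including degenerate point intervals — always overlap at
least one bin, and overlap counting is unambiguous. The series is smoothed
by a centred 0.5-Ma (5-bin) sliding mean, truncated (not zero-padded) at
the ends so the curve's edges are not dragged down artificially. Curves
report counts per slice; ×10 per-Ma scaling is a flag, off by default.

* **Origination** = the oldest event's point age (the curve's oldest
  nonzero bin is reported separately as the support onset).
* **Peak** = the midpoint of the contiguous run of bins attaining the
  maximum smoothed value (the oldest run on ties; a constant positive curve
  is flagged flat, an all-zero curve undefined).
* **95% CIs** come from 1000 bootstrap pseudoreplicates. The default mode
  redraws one age uniformly inside every event's interval; an
  event-resampling mode (sampling events with replacement, keeping their
  intervals) is available. Both are deterministic under the recorded seed.
  Empirical coverage of the population peak by the event-resample CIs is
  ~94% at 200 events (measured, see `scripts/acceptance.py`).

A caveat worth stating: the expected raw count in a slice is approximately
`intensity × (mean interval width + slice width)`. When interval widths
grow with age — as real node-age HPDs do — the curve estimates the product
of the event intensity and the dating uncertainty, not the intensity alone.
Features of the curve (peak, change points) are then features of that
product.

## Change points

Piecewise-linear trends are fitted by iterative linearisation: given
breakpoints ψ, regress on {1, x, (x−ψ_j)₊, I(x>ψ_j)} and move each ψ_j by
the gap/slope-change coefficient ratio until the largest update falls below
1e-6 Ma (100 iterations maximum, steps halved after 20 to settle
oscillation; non-convergence is reported, not raised). Breakpoints are kept
strictly ordered inside the data range with a minimum separation of 1e-3 of
the x-span. Standard errors use the delta method on the gap/slope-change
ratio; a case-resampling bootstrap is available. The number of breakpoints
is selected over k ∈ {1, 2, 3, 4}, each fitted from the quantile
initialisation plus five seeded random starts, by
BIC = n·ln(RSS/n) + p·ln(n) with p = 2 + 2k; a zero-RSS fit short-circuits
to the smallest perfect k. Fits are run on the smoothed curve at bin
midpoints by the pipeline (the raw series is equally accepted).

**Measured limitation.** On piecewise-linear signals with i.i.d. Gaussian
noise the machinery is reliable: with σ = 0.05 on 100 bins and three
breakpoints of ordinary contrast, BIC selects k = 3 and every breakpoint
lands within 0.3 Ma of the truth in ≳90% of replicates. On binned
point-process data the picture is different: interval widths smear the
kinks, the smoothing window correlates neighbouring residuals, and the
Poisson noise is strongly heteroskedastic (largest where the curve is
highest), so an unweighted OLS/BIC comparison buys a fourth, spurious
breakpoint in roughly a third to a half of replicates *even for ensembles
of thousands of exactly dated events*. Breakpoint locations remain well
estimated (median error 0.1–0.2 Ma, and the k = 4 fits almost always
contain all three true breakpoints plus one extra). The end-to-end property
test therefore asserts what the machinery actually delivers — every true
change point matched by a fitted breakpoint within 0.5 Ma, with k ∈ {3, 4}
— rather than exact-k recovery; single-ensemble change-point counts should
be read with that caveat.

## Habitat reconstruction

Tip habitats are open, closed, or both; "both" is an ambiguous observation
(partial likelihood 1 for either state), not a third state. A two-state
continuous-time Markov model (equal-rates by default, all-rates-different
optional) is fitted by maximum likelihood; because the likelihood saturates
for fast rates, rates are optimised on the log scale after a coarse
log-spaced grid scan. Node marginals use the standard two-pass algorithm
under a flat root prior. This is a deliberate likelihood-based substitute
for Bayesian binary MCMC machinery: the scientific content (ancestral open
vs closed habitat) is carried by the Markov model, and the output metadata
names the model used. The pre-adaptation report calls a dispersal event's
parent-node habitat only when the MAP marginal reaches a threshold (default
0.8, configurable); weaker reconstructions are reported as ambiguous.

## Synthetic data

The generator layers are independent so each downstream stage can be tested
against known truth.

* **Trees**: constant-rate birth–death forward simulation conditioned on
  the number of extant tips; after the target is first reached the clock
  runs one further exponential waiting time (stopping just before the next
  event), which makes the Yule mean root age equal Σ_{i=2..n} 1/(iλ) — the
  closed form the tests check. Extinct lineages are pruned.
* **Range histories**: Gillespie simulation of the DEC generator along
  branches (slice-aware), ordered cladogenetic draws at nodes. Lineages
  absorbed in the null range die and are pruned by default (retry and error
  modes exist). The logged true events are defined at node resolution —
  exactly the resolution the classifier can see — so classification on the
  true ranges must reproduce the log identically; this holds exactly across
  hundreds of tested histories, including ones with pruning.
* **Habitat histories**: two-state Gillespie simulation.
* **Event ensembles**: an inhomogeneous Poisson process (by thinning) with
  a piecewise intensity over age, each event wrapped in a credibility
  interval of configured width placed uniformly around its age, with types
  and source regions drawn from configured mixtures. The intensity is
  piecewise-*linear* by default (interior knots are then exactly the trend
  change points the segmented regression estimates); a piecewise-constant
  mode exists but a step intensity smeared by interval widths yields two
  slope changes per step, which no 3-breakpoint linear model can represent.

The default `SimScenario` encodes the reference conditions the package
targets: 32 clades, 105 expected dispersal and 26 expected in-situ events
(ratio ≈ 4), dispersal intensity originating at 10.24 Ma with change points
at 7.23, 2.56 and 0.63 Ma, in-situ intensity originating at 9.20 Ma with
change points at 6.25, 2.34 and 0.68 Ma, interval widths
(0.5 + 0.05·age) × U(0.5, 1.5) Ma, and ~54% of source-assigned dispersals
from one dominant region ("G", with 79/105 dispersals left unassigned so
the assigned denominator is 26). The intensity shape rises slowly from a
small positive level at the origin and accelerates sharply after the middle
change point, mirroring the assembly dynamics the package targets. What the
ensemble generator does *not* emulate: phylogenetic correlation between
events of one clade, age-heteroskedastic HPD widths beyond the mild default
trend, non-uniform posterior age densities inside intervals, and any
coupling between event type and timing. Passing tests on this generator
show the statistics are computed correctly and recover known truth at
adequate sample sizes; they do not show that 105 real events pin down three
change points — at study scale the selected k fluctuates between 3 and 4
and the oldest change point carries little information (see the limitation
above).

## Numerical choices and degenerate inputs

* Ages are Ma before present, larger = older; intervals are closed
  [older, younger]; event tables validate `older ≥ younger ≥ 0`.
* Tips without dates sit at 0 Ma; node HPDs that exclude the point age are
  flagged, not rejected.
* Likelihood pruning rescales partial-likelihood vectors per node and
  accumulates log factors; a zero conditional likelihood raises a
  `FloatingPointError` naming the node.
* The DEC root prior is flat over observable ranges.
* Empty event sets raise by default (`allow_empty` returns a flagged empty
  curve); an all-zero curve has an undefined peak; a tally without in-situ
  events reports an infinite-ratio flag rather than dividing by zero.
* Every output file carries a provenance header (tool version, hash of the
  analysis-relevant configuration, seed); reruns with the same inputs and
  seed are byte-identical.

## Problem sizes used by the test suite

Oracle enumerations run on ≤5-tip trees over ≤3 areas, where exhaustive
state-assignment sums are exact and fast. Statistical properties use the
smallest sizes at which the property has adequate power: 100 forward
histories for the classification oracle, 20 × 200-tip trees for rate
recovery, 50 replicates for change-point recovery, 250 × 200-event outer
replicates (500 bootstrap draws each) for CI coverage, and 30 ensembles of
5250 exactly dated events for the end-to-end change-point property.
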