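# biogeodyn

Multi-clade biome-assembly dynamics from dated phylogenies.

How does a biome — canonically the Arctic tundra flora — acquire its
species? Two routes exist: lineages **disperse in** from elsewhere, or they
**diversify in situ** once arrived. Given dated, range-coded phylogenies
for many clades, `biogeodyn` reconstructs where ancestors lived,
classifies both kinds of event with their dating uncertainty, and
characterises the assembly dynamic through time: when colonisation began,
when it peaked, and where its tempo changed. It is aimed at historical
biogeographers who have per-clade timetrees (e.g. BEAST MCC trees with
95% HPD node ages) and tip range codings, and want the pooled,
uncertainty-aware picture.

## The models and statistics at the core

**DEC ancestral ranges.** Ranges are subsets of an area set; along each
branch a range expands into area *j* at rate *d* · Σ_{i∈G} m_ij (with
per-time-slice dispersal multipliers m) and loses each occupied area at
rate *e*; at speciation a widespread range splits by subset sympatry or
vicariance, all unordered scenarios equally likely. (d̂, ê) are maximum
likelihood; marginal ancestral ranges come from a two-pass pruning
algorithm.

**Event classification.** With MAP ranges on all nodes, a *dispersal-in*
event is an edge whose child range gains the focal area; its timing window
spans from the parent's older 95% HPD bound to the child's younger bound.
An *in-situ* event is a node that, with both children, occupies the focal
area, timed by its HPD.

**MDisE / MDivE curves.** Pooled over clades, each 0.1-Ma time slice counts
the events whose credibility interval overlaps it ("maximal number of
observed dispersal / in-situ diversification events"); the series is
smoothed with a centred 0.5-Ma window. The curve's **origination** (oldest
event age) and **peak** (midpoint of the maximal run) get 95% CIs from
1000 bootstrap pseudoreplicates drawn from the raw intervals.

**Change points.** Piecewise-linear (segmented) regressions with k = 1…4
breakpoints are fitted by Muggeo-style iterative linearisation; BIC
(p = 2 + 2k) selects k, and breakpoints ψ̂ carry delta-method 95% CIs.

**Habitat pre-adaptation.** A two-state Markov (Mk) reconstruction of
open- vs closed-habitat ancestry asks whether colonising lineages were
already adapted to open vegetation before arriving.

A synthetic-data layer (birth–death trees, forward DEC histories with
logged true events, Mk habitat histories, and event ensembles from known
piecewise intensities) generates every input with known ground truth.

## Worked example

Simulate a study-scale event ensemble (the default scenario emulates 32
clades contributing ~105 dispersal and ~26 in-situ events) and run the
curve analysis:

```python
from biogeodyn import (SimScenario, simulate_event_ensemble, tally,
                       mde_curve, bootstrap_features, select_changepoints)

scenario = SimScenario(master_seed=7)
events = simulate_event_ensemble(scenario, seed=7)
print(tally(events).summary())

disp = events.of_type("dispersal_in")
print("MDisE", bootstrap_features(disp, n_boot=1000, seed=7).summary())

curve = mde_curve(disp)
best, bic_table = select_changepoints(curve.midpoints, curve.smoothed, seed=7)
print(best.summary())
```

prints

```
Biogeographic event tally
========================================
dispersal into focal area: 113
in situ diversification:   17
total events:              130
dispersal : in-situ ratio: 6.65
source regions (assigned dispersals):
  G: 20 (76.9%)
  B: 2 (7.7%)
  F: 2 (7.7%)
  D: 1 (3.8%)
  E: 1 (3.8%)
MDisE origination 9.00 (9.55-8.69); peak 0.63 (1.08-0.27) [1000 bootstrap replicates, mode=interval-age]
Segmented regression, k=4 breakpoint(s)
============================================
n obs:       96
RSS:         92.2438
BIC:         41.8118
converged:   True (7 iterations)
intercept:   18.6881
segment slopes (ascending x): 24.6569, -13.7998, -1.26458, 4, -3.06548
breakpoint:  8.7476 (9.0496-8.4455)
breakpoint:  8.0625 (8.3856-7.7393)
breakpoint:  2.3532 (2.4410-2.2654)
breakpoint:  0.5612 (0.6112-0.5112)
```

Reading this: the 130 simulated events (113 dispersal, 17 in-situ; true
expectation 105/26, so this seed drew a dispersal-heavy ensemble) give a
dispersal curve whose oldest event sits at 9.0 Ma (the generating intensity
originates at 10.24 Ma — the oldest realised event is necessarily younger)
and whose peak at 0.63 Ma matches the generator's intensity maximum at
0.63 Ma. The two young breakpoints, 2.35 and 0.56 Ma, recover the
generator's change points at 2.56 and 0.63 Ma; at ~113 events the BIC
occasionally spends a fourth breakpoint splitting the weak oldest kink
(truth 7.23 Ma) in two, which is exactly the behaviour quantified in
`docs/methods.md`.

The same analysis runs from the shell over a directory of per-clade trees
and codings (DEC fit → ancestral ranges → classification → curves →
change points → habitat report):

```
biogeodyn simulate --out clades/ --n-clades 3 --tips 20 --seed 7
biogeodyn run config.yaml          # summary.txt, events.tsv, curves, fits
biogeodyn classify tree.nwk ranges.tsv --areas AB --focal A
biogeodyn mde events.tsv --type dispersal_in --out mdise_curve.tsv
biogeodyn changepoints mdise_curve.tsv
```

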