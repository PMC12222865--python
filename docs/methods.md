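# Methods

`syncomkit` implements the computational core of a bottom-up synthetic
community (SynCom) design workflow for plant-associated bacteria: quantify
each candidate strain's resource-utilization niche, score every candidate
member combination for cooperative potential and competitive pressure with
constraint-based community models, rank combinations, and characterize
individual strains' biosynthetic robustness. This note records the models,
conventions and defaults, and what the synthetic test beds do and do not
establish.

## Niche indices from utilization profiles

A utilization profile is one strain's respiration signal (OmniLog units) or
binary growth call across an ordered set of carbon sources. A resource counts
as utilized when its signal strictly exceeds the threshold (default 50
OmniLog units; a signal of exactly 50 is *not* utilization). Utilization
proportions are

    P_i = s_i / Σ_j s_j   over utilized resources only, else P_i = 0,

i.e. sub-threshold signals are zeroed before renormalization. On binary 0/1
calls this reduces to P_i = 1/k over the k growth-supporting substrates, so
Levins' width equals the simple substrate count — the "simplified width" used
for large validation panels.

* Levins' niche width `W = 1/Σ P_i²` — the effective number of resources
  used; `1 ≤ W ≤` (number of utilized resources), with equality to the count
  iff the proportions are uniform.
* Pianka's overlap `O_jk = Σ P_ij P_ik / √(Σ P_ij² Σ P_ik²)` — a cosine
  similarity of proportion vectors in [0, 1]; a strain's *average overlap* is
  the mean over all partners in the panel.
* NSR/BSR classes: narrow-spectrum (simplified width ≤ 7) and broad-spectrum
  (≥ 29) resource utilizers, the tail thresholds used for phyllosphere-scale
  panels; both cutoffs are inclusive and configurable.

Strains with no utilized resource are retained with a warning and excluded
from width/overlap statistics; asking for their width or overlap directly is
an error rather than a silent zero.

## Constraint-based layer

Models are standard genome-scale metabolic models (SBML Level 3 with the
fbc extension, read/written through cobrapy) or a small toy-model JSON
dialect (`{"id", "metabolites": [{id, compartment, name?, formula?}],
"reactions": [{id, stoichiometry, lower_bound, upper_bound}], "objective"}`).
Exchange reactions follow the repository convention `1 met_e ↔ ∅` with
negative flux = uptake. Default bounds are ±1000 mmol·gDW⁻¹·h⁻¹ internally
and an uptake bound of 10 for opened medium components.

Flux balance analysis and all mixed-integer programs are formulated directly
on the stoichiometric arrays and solved with HiGHS (through
`scipy.optimize.linprog`/`milp`, zero MIP gap), which is deterministic
run-to-run; infeasibility is reported as a solution status, not an
exception. cobrapy's own glpk-backed optimizer is deliberately unused in the
library so it can serve as an independent cross-check in the test suite.

### Minimal media

A minimal medium is a minimum-cardinality set of environmental metabolites
whose uptake lets the model reach a growth threshold — by default 10% of the
maximum growth on the full medium (absolute override available). One binary
`y_m` per candidate metabolite enforces `v_e ≥ −U·y_m` on every uptake it
controls, and `Σ y_m` is minimized. Among equal-size optima the single-medium
call returns the lexicographically smallest metabolite-id set, found by a
greedy include-and-test pass at fixed cardinality; alternate optima can be
enumerated with integer cuts. A configurable "free" list (water, protons,
metal ions — compounds sourced from the environment in any realistic soil
medium) can be kept always-open and outside the cardinality count; it is off
by default. An exhaustive-subset oracle validates the MILP on every fixture
with ≤ 10 candidate exchanges.

### Community scores

Members are merged with per-member namespaced compartments. Member exchange
reactions become transfers between the member's extracellular species and an
environment pool, preserving each member's own uptake/secretion bounds:

* **interacting** — one shared pool; secretions are available to all members;
* **non-interacting** — private pool copies; only external supply is
  available.

Fresh community-level exchange reactions connect pools to the environment and
carry the medium indicators; in the non-interacting regime one indicator
opens the metabolite for every member simultaneously, so both regimes count
*distinct* environmental metabolites. Total supply capacity per opened
metabolite is `U` per member in both regimes (one shared exchange of
capacity `n·U` versus `n` private exchanges of capacity `U`), so the regimes
differ only in cross-feeding, not in flux capacity — without this matching,
fast-growing members make the shared-pool medium look spuriously larger.
Community growth requires every member to reach its own threshold (10% of
its isolated maximum) simultaneously; there is no abundance weighting.

* **MIP** (metabolic interaction potential) = |minimal medium,
  non-interacting| − |minimal medium, interacting|: the number of nutrients
  the community spares through exchange. Non-negative by construction; a
  tiny solver-noise inversion is clamped to 0 with a warning.
* **MRO** (metabolic resource overlap) = mean over member pairs of
  |M_i ∩ M_j| divided by the mean individual minimal-medium size, with the
  M_i computed in isolation. 0 = disjoint nutritional needs, 1 = identical.
  Optionally the intersection/size terms are averaged over enumerated
  alternate media; the default uses the single lexicographic optimum, which
  keeps scores deterministic and is the convention behind all reported
  numbers.

These two formulas are fixed as this package's definitions of the SMETANA
-style scores. Published absolute MIP/MRO values for specific six-strain
communities depend on the original CarveMe/BIGG model reconstructions and
are not reproducible from toy systems; the package validates the scoring
machinery against enumeration oracles and engineered ground truth instead.

Enumeration covers all member subsets in a size range in lexicographic
order (6 strains, sizes 2–6 → 57 communities). Ranking sorts by MIP
descending, then MRO ascending, then member set. The dropout scan rescores
every leave-one-out subset of a community and reports ΔMIP/ΔMRO per dropped
member.

## Producibility metric

For a target metabolite, every exchangeable metabolite is included in the
environment independently with probability `p_in`; FBA on an unbounded
demand (sink 0–1000) of the target decides producibility; the producible
fraction over sampled environments estimates `P_out(p_in)`. Defaults: 21
evenly spaced grid points on [0, 1], 500 environments per point (the two
degenerate endpoints are computed exactly). The Monte-Carlo curve is made
monotone by isotonic regression, the 0.5 crossing `P_in,0.5` is located by
linear interpolation, and

    PM = 1 − P_in,0.5,

with the conventions: curve everywhere ≥ 0.5 → PM = 1; everywhere < 0.5 →
PM = 0. Ions that appear inside larger biomass components (porphyrins,
cobalamins) are targeted as the species itself, which understates their
effective producibility — an interpretive caveat for panels that include
them. Panel cells get independent seeds derived from a master seed by
hashing `(seed, model, metabolite)`, so any sub-panel reproduces the full
panel's values bit-for-bit. Repeated environments are memoized per curve
(the LP answer is a pure function of the medium), which makes small-model
panels effectively exhaustive.

## Statistical layer

* `linreg` — ordinary least squares with R², the slope's two-sided t-test
  p-value (equivalent to the model F-test in simple regression), and exact
  mean-response confidence bands.
* `gaussian_fit` — nonlinear least-squares Gaussian on the histogram
  (Freedman–Diaconis bins by default), moment-based initial guesses;
  goodness is the R² of the fitted curve against bin counts, so bimodal data
  are flagged by low goodness rather than a misleading (μ, σ). Near-constant
  data raise instead of degenerating to σ → 0.
* `binned_distance_correlation` — community pairs partitioned by
  phylogenetic distance; per-bin OLS of score vs mean member width; bins
  with < 3 pairs are flagged empty, never dropped silently. Distances come
  from a labelled matrix or as patristic distances (summed branch lengths)
  from a newick tree.
* `hier_cluster` — average-linkage/Euclidean clustering of both axes of a
  strains × metabolites matrix; inputs are pre-sorted by label so leaf
  orders are permutation-invariant and ties break on labels.

## Synthetic test beds

The generators define the conditions under which the package is validated:

* **Cross-feeding panels** (`CrossFeedSpec`): every strain imports a shared
  carbon and funnels it into one precursor; biomass consumes the precursor
  plus one unit of each auxotrophic metabolite. Donors synthesize the
  exchanged metabolite *from the precursor* (donating costs carbon) and
  secrete it through an export-only exchange. The expected MIP of any subset
  is the number of distinct exchanged metabolites whose donor and recipient
  are both present — a closed-form ground truth the MILP scores must hit
  exactly.
* **Width-gradient panels**: 8 strains over 9 shared carbon sources with
  nested utilization sets (widths 2–9, drawn per seed with all three
  auxotrophy classes present); strains with width ≤ 4 carry two
  auxotrophies, ≤ 7 one, broader strains none, and every strain can
  synthesize the others' required metabolites. This encodes the designed
  mechanism — narrow-spectrum strains are the cross-feeders — and yields
  pairwise MIP decreasing and MRO increasing with mean width.
* **Prescribed-width panels**: proportion vectors hitting any target Levins
  width exactly via one free proportion over ⌈W⌉ resources (solving
  `1/W = a² + (1−a)²/(m−1)`), randomized in resource assignment and signal
  scale, to which the width is invariant.
* **Width distributions**: truncated-normal (≥ 0) samples for
  distribution-fit recovery at panel scale (n = 3001).

What passing these tests shows: the index algebra, the MILP scoring
machinery, the PM estimator and the statistical layer are correct on systems
with known answers. What they do not show: anything about real
reconstruction quality — toy strains have single-currency metabolism, no
redundancy between pathways, no thermodynamic or regulatory constraints, and
far fewer alternate optima than genome-scale models, where MRO in particular
is sensitive to which minimal medium the solver reports.

## Problem sizes and budgets

Defaults are sized for desk-scale runs: 21-point PM grids at 500
samples/point, 20 width-gradient panels of 8 strains for direction tests,
brute-force oracles limited to 16 candidate exchanges. All are arguments,
not constants.

## Known limitations

* Absolute MIP/MRO for the published six-strain communities require the
  original refined models; only the scoring contracts are reproducible here.
* The lexicographic minimal-medium tie-break is exact for ≤ 50 candidate
  exchanges (binary-weight phase); beyond that a deterministic greedy pass
  still fixes the reported set but true lexicographic minimality is not
  guaranteed.
* Whether published width calculations renormalized over thresholded
  signals (this package's convention) or used raw signals cannot be decided
  without the original per-strain signal table; the convention is recorded
  here and applied uniformly.
* The organic-compound rule behind genome-predicted utilization width
  (carbon and hydrogen present, fixed inorganic blocklist) is an operational
  choice; an all-carbon counter is exposed alongside it.
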