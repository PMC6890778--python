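# Methods

## Scope and model assumptions

`strainflux` treats each strain as a stoichiometric model at steady state:
fluxes `v` satisfy `S·v = 0` within bounds, growth is the flux through a
biomass pseudo-reaction, and all simulation is linear programming. No
kinetic, thermodynamic or regulatory constraints are imposed, and no
experimental flux measurements enter; predictions are therefore
*capabilities* of the network under the stated medium, qualitative rather
than quantitative. Deletions are performed at reaction level (both bounds
set to zero); gene–protein–reaction rules are out of scope.

Exchange conventions follow AGORA/VMH: an exchange reaction carries a
single metabolite with coefficient −1; negative flux is uptake, positive is
secretion. "Unbounded" fluxes are capped at ±1000 mmol/gDW/h so every LP is
bounded.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| carbon uptake rate | 10 | mmol/gDW/h | lower bound −10 on the active carbon exchange |
| universal uptake rate | 1 | mmol/gDW/h | lower bound −1 on each universal media component |
| growth threshold τ | 10⁻⁶ | mmol/gDW/h | FBA optimum above τ counts as growth |
| producer threshold | 0.01 | mmol/gDW/h | FVA maximum strictly above it calls a producer |
| flux-carrying tolerance | 10⁻⁶ | mmol/gDW/h | conserved/non-conserved partitioning |
| lethality cutoff | 0.01 | fraction of wild type | knockout optimum below it is lethal |

The uptake magnitudes and the producer threshold are the conventional
settings for this kind of strain-panel screen; the growth threshold and
flux tolerance are deliberately at solver-tolerance scale, since a binary
growth call should not hinge on values the LP solver cannot distinguish
from zero. The lethality cutoff of 1% of wild-type growth is the usual
convention in the synthetic-lethality literature. All are configurable
through the pipeline configuration.

## Numerical choices

All LPs go through one internal contract backed by HiGHS **dual simplex**
(`scipy.optimize.linprog`, `method="highs-ds"`). Dual simplex returns
vertex (basic) optimal solutions, which matters twice: the L1-minimal flux
distribution then has a parsimonious support, and repeated solves are
deterministic. FVA and the minimal-support problem enforce the biomass
requirement as `v_bio ≥ f·(1 − 10⁻⁶)·v*` rather than strict equality —
"fixed at the optimum" up to solver tolerance — so biomass-constrained
problems never go infeasible through rounding alone. The minimal-support
problem uses the standard split `v = v⁺ − v⁻`, `v± ≥ 0`, minimizing
`Σ(v⁺+v⁻)`; supports are read at |flux| > 10⁻⁶.

Solver statuses are propagated faithfully: an infeasible or unbounded FBA
raises or reports its status, never a silent zero, and a strain that fails
to grow where a computation requires growth (producer calls, lethality) is
a reported error or a logged skip, not a fabricated phenotype.

Producer calls use the FVA **maximum** (capability, not obligate
secretion), with ties at the threshold scored as non-producers (strict
`>`). A metabolite with no exchange reaction in a strain is a non-producer
with a logged notice.

## Fast-SL reduction and its exactness

Any flux vector meeting the growth cutoff is a feasibility witness: a
reaction outside its support cannot be a single lethal, and a pair disjoint
from it cannot be a double lethal. Singles therefore only test the support
of the L1-minimal witness; doubles draw the first member `i` from that
support and the second from the support of the minimal witness of the
`i`-deleted model (any lethal partner of `i` must appear there). Witnesses
are computed at the cutoff fraction itself, which keeps them small. The
reduction is exact regardless of which optimal vertex the solver returns —
degenerate optima change the work done, not the answer — and the test suite
pins this by comparing against exhaustive single and C(n,2) pairwise
deletion scans on randomized strains. Exchange reactions and the biomass
reaction are never deletion candidates.

Two unions are reported for cross-strain essentiality, since "essential
across strains" can reasonably mean either: the union of single lethals,
and that union plus all members of double-lethal pairs. The core essential
set intersects the single-lethal sets with the shared reaction set.

## Conserved/non-conserved partitioning

A listed reaction is *conserved* for a strain when its biomass-pinned FVA
range shows flux capability (max(|min|, |max|) > 10⁻⁶) in **every**
environment where that strain grows; environments where the strain is
infeasible are excluded, since "can carry flux" is undefined there. Two
aggregation modes exist because the pooling is genuinely ambiguous:
per-strain partitions, and a pooled mode in which one non-conserved call in
any strain makes the reaction non-conserved overall. The pipeline exports
both; the pooled mode is the headline number.

## Clustering

Profiles are binary vectors per strain; distance is the Hamming
*proportion* (mismatch fraction), which keeps growth, product and lethality
profiles comparable despite different lengths. Non-growth is encoded as 0
in product profiles (no production observed). Trees are average-linkage
(UPGMA) via `scipy.cluster.hierarchy`; its nearest-neighbor-chain
implementation gives deterministic, platform-independent merges, which is
how the determinism-under-ties requirement is met. Newick branch lengths
are parent height minus child height, making trees ultrametric. Flat
clusters come from `maxclust` cuts. These dendrograms are phenetic
groupings of phenotype vectors, not phylogenies.

## The synthetic generator

The generator emulates the structural features the analysis relies on, at
a scale where every claim can be checked by hand or by enumeration:

* **Core** (20 reactions): glucose → G1P → G6P → F6P (PGMT, PGI); the
  phosphoketolase split FPK/RPE/XPK yielding 2 acetyl-phosphate + 1 G3P per
  F6P; acetate kinase (ATP-yielding, acetate out); lower glycolysis
  GAPD/PGK/PGM/PYK (2 ATP + 1 NADH + 1 pyruvate); and two redox-balanced
  pyruvate fates — LDH (lactate) or PFL + ADHE (formate + ethanol).
  Biomass drains F6P + 2 ATP. This plants: forced acetate secretion,
  free lactate/ethanol/formate split, a sole route to biomass through the
  named enzymes (PGMT, PGM, PGK, RPE among them), and the double-lethal
  pairs {LDH, PFL} and {LDH, ADHE}.
* **Peripheral pathways**: each non-glucose carbon source is usable only
  through a 2-step uptake/degradation chain (yielding 2 G1P, disaccharide
  flavor). Possession is decided per *group*, so same-group strains have
  identical growth profiles; group signatures are re-drawn until pairwise
  distinct so the planted groups are separable by clustering (a mild bias
  of the per-pathway probability, accepted for testability).
* **Duplicated routes**: selected core reactions receive an identical
  parallel copy, converting a single lethal into a planted double-lethal
  pair (the knockout-bypass phenotype).
* **Auxotrophies**: biomass additionally drains 0.1 of each universal
  component; a strain either synthesizes it from F6P or must import it.
  This makes universal-media derivation non-trivial and plants
  transport-essentiality (auxotrophs) and synthesis/transport double
  lethals (prototrophs).

All planted truths (growth matrix, producer flags, lethal sets, group
labels, auxotrophies) are derived **structurally**, without solving any LP,
so pipeline-vs-truth comparisons are a genuine dual route; `verify=True`
additionally brute-forces the lethal sets at generation time. Default
panel: 6 strains, 3 groups, 8 carbon sources, 1 duplicated route per
strain, 2 universal components, 50% pathway and auxotrophy probabilities —
small enough that the exhaustive lethality oracle and the end-to-end
recovery tests run in seconds per panel.

What the generator does **not** emulate: realistic biochemistry
(coefficients are small integers in one compartment), AGORA nomenclature
beyond the named shunt enzymes, blocked/dead-end reactions, near-threshold
growth rates, or thermodynamically infeasible loops that touch biomass.
Passing the planted-truth suite therefore demonstrates the correctness of
the algorithms on networks with the assumed topology, not predictive
accuracy on curated genome-scale reconstructions.

## Universal-media derivation

Leave-one-out, not combinatorial: with the reference carbon (glucose by
default) and all other candidates supplied, a component is retained iff
withholding it alone abolishes growth of at least one strain. The derived
set is verified to support growth of every strain on its own. One-at-a-time
testing keeps the procedure polynomial and matches the "essential to at
least one strain" definition; it will not detect substitutable component
pairs (where either of two components suffices), a known limitation.

## Design choices where the design was open

* Growth threshold, flux tolerance: solver-scale (see above), flagged as
  configurable rather than biological constants.
* Producer ties (= 0.01): non-producer, the strict reading.
* Double-lethal witnesses at the cutoff fraction rather than at the
  optimum: both are exact; the lower requirement yields smaller supports.
* The three-group classification of a real panel is a narrative synthesis
  of several clusterings; the pipeline exposes per-profile trees and k-cut
  assignments and deliberately does not automate that synthesis.
* The pipeline's stages communicate via files with provenance headers so
  partial re-runs are cheap and synthetic and user-supplied panels share
  one code path.

## Known limitations

* Lethality monotonicity under medium enrichment holds empirically on the
  synthetic panels but is not guaranteed in general, because the cutoff is
  relative to the (medium-dependent) wild-type optimum.
* FVA endpoints are reproducible to 10⁻⁶, but flux *vectors* at degenerate
  optima are not asserted pointwise anywhere.
* Very large models would want warm-started or parallel FVA/Fast-SL; the
  implementation solves each LP independently.
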