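# strainflux

Constraint-based phenotyping of bacterial strain panels.

Given a collection of genome-scale metabolic models — one per strain, in
SBML (Level 3 + FBC) or COBRA-style JSON — `strainflux` simulates each
strain across a panel of nutrient environments and derives the comparative
phenotypes that distinguish closely related strains (its design case is
panels of gut anaerobes such as bifidobacteria, whose fermentative core, the
bifid shunt, couples growth to acetate and lactate secretion):

* **Growth phenotyping** — flux balance analysis (FBA) per strain per
  single-carbon-source environment, yielding a binary growth matrix.
* **Fermentation-product capability** — flux variability analysis (FVA)
  of the acetate/lactate/ethanol/formate/succinate exchanges with biomass
  pinned at its optimum; flux above 0.01 mmol/gDW/h calls a producer.
* **Pathway flux conservation** — partition of a reaction list (e.g. the
  bifid-shunt reactions) into *conserved* (able to carry flux in every
  growth-supporting environment) and *non-conserved* (environment-specific),
  plus targeted knockout scans with growth and product readouts.
* **Essentiality and synthetic lethality** — single and double reaction
  lethals per strain on a rich environment via the Fast-SL search-space
  reduction, with an exhaustive-enumeration oracle, union/core-essential
  summaries, and binary lethality profiles.
* **Strain classification** — Hamming distances between binary profiles
  (growth, product, lethality) and average-linkage (UPGMA) dendrograms with
  Newick export and k-cut cluster assignments.
* **Synthetic strain panels** — a generator that emulates the assumed
  structure of such a panel (shared redox-balanced fermentative core,
  group-specific peripheral carbon pathways, duplicated parallel routes,
  universal-component auxotrophies) and exports the planted ground truth
  for every downstream stage, so the whole pipeline is testable end to end.

## The model

Each strain is a stoichiometric matrix `S` (metabolites × reactions) with
flux bounds `l ≤ v ≤ u`. Growth is the linear program

```
max  v_biomass   s.t.  S·v = 0,  l ≤ v ≤ u
```

An environment opens exchange reactions for uptake: the chosen carbon
source at −10 mmol/gDW/h, universal media components at −1 mmol/gDW/h, and
all other uptakes closed (lower bound 0). A strain *grows* when the optimum
exceeds 10⁻⁶ mmol/gDW/h. FVA then minimizes and maximizes each flux of
interest subject to `v_biomass ≥ (1 − 10⁻⁶)·v*`. Lethality uses the
relative cutoff `v*_KO < 0.01·v*_WT`; Fast-SL restricts deletion candidates
to the support of an L1-minimal flux distribution (any flux vector meeting
the growth cutoff is a feasibility witness, so reactions outside its
support cannot be lethal), which is provably equivalent to exhaustive
single and pairwise deletion scans.

## Worked example

The built-in core strain ferments glucose through a phosphoketolase split:
per unit F6P routed through the shunt it gains 4 ATP and must release two
acetate, while the NADH from lower glycolysis is re-oxidized either by
lactate dehydrogenase or by the formate/ethanol branch.

```python
from strainflux import (
    generate_core_shunt, NutrientEnvironment, apply_environment,
    fba, fva, producer_status,
)
from strainflux.lethality import lethal_sets

model = generate_core_shunt()
glucose = NutrientEnvironment(name="glucose", carbon_uptakes={"EX_glc_e": 10.0})

sol = fba(apply_environment(model, glucose))
print(f"growth rate on glucose: {sol.objective_value:.4f} /h")

for ex in ["EX_ac_e", "EX_lac_e", "EX_etoh_e", "EX_for_e"]:
    lo, hi = fva(apply_environment(model, glucose), [ex], biomass_fraction=1.0)[ex]
    flag = producer_status(model, glucose, ex)
    print(f"{ex}: flux range [{lo:.4f}, {hi:.4f}]  producer={flag}")

ls = lethal_sets(model, glucose)
print("single lethals:", sorted(ls.singles))
print("double lethals:", sorted(map(sorted, ls.doubles)))
```

prints

```
growth rate on glucose: 6.6667 /h
EX_ac_e: flux range [6.6667, 6.6667]  producer=1
EX_lac_e: flux range [0.0000, 3.3333]  producer=1
EX_etoh_e: flux range [0.0000, 3.3333]  producer=1
EX_for_e: flux range [0.0000, 3.3333]  producer=1
single lethals: ['ACK', 'FPK', 'GAPD', 'GLCt', 'PGI', 'PGK', 'PGM', 'PGMT', 'PYK', 'RPE', 'XPK']
double lethals: [['ADHE', 'LDH'], ['LDH', 'PFL']]
```

The growth rate 20/3 is the hand value (F6P splits 2:1 between biomass and
the ATP-yielding shunt when 10 glucose enters). Acetate secretion is forced
exactly at 20/3 — a redox/ATP consequence, not a choice — while the 10/3 of
pyruvate may go to lactate or to formate + ethanol, so all four products
are *capable* (producer = 1) but only acetate is obligatory. Every reaction
on the sole route to biomass is a single lethal; the two pyruvate fates are
individually dispensable but jointly lethal.

## Command-line pipeline

```sh
strainflux all -c config.yaml
```

runs `synth → growth → scfa → shunt → lethals → cluster` (plus `patch` and
`media` where configured), with all tabular outputs as TSV, trees as
Newick, and a provenance header (package version, config hash, seed) on
every file. A minimal configuration:

```yaml
output_dir: out
seed: 11
synth: {n_strains: 6, n_groups: 3}
cluster_groups: 3
```

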