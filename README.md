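# aacost

Systems-biology estimation of amino acid biosynthetic cost, and the
downstream analyses it feeds: comparison of cost measures, regression of
yeast gene expression on protein composition, and correlation of cost with
per-site amino acid substitution rates in *Saccharomyces*.

## The problem

Every protein carries a biosynthetic cost set by the synthesis of its
constituent amino acids, and selection for cost minimisation is expected to
leave signatures in gene expression and protein evolution.  Literature cost
measures (Akashi & Gojobori's and Craig & Weber's energetic costs, Wagner's
fermentative/respiratory costs, molecular weight) are manually curated and
condition-independent.  This package instead estimates cost from a
genome-scale metabolic model with flux balance analysis (FBA), so that the
cost of an amino acid can be computed for any simulated nutrient
environment.

## The estimator

A stoichiometric model `S` (metabolites × reactions) is solved at steady
state, `S·v = 0` with flux bounds `lb ≤ v ≤ ub`.  The biomass flux is fixed
to a growth rate `μ` (mimicking a chemostat) and the uptake `U` of one
nutrient — glucose, ammonium or sulphate — is minimised by linear
programming, with all three nutrient exchanges otherwise opened wide.  The
requirement `x` of one amino acid in the biomass reaction is then perturbed
by a symmetric sweep of small changes, either additive (`x → x + δ`) or
fractional (`x → x·(1+δ)`), and the cost is the least-squares slope

* absolute cost `a = dU/dx` (per hour),
* relative cost `r = dU/dδ` for fractional `δ`, with the identity `r = x·a`,

rescaled by `1/μ`, which removes the proportional growth-rate dependence
(absolute costs become unitless, relative costs mmol·gDW⁻¹).  Six costs per
amino acid result (two modes × three nutrient limitations).  Under
ammonium or sulphate limitation the absolute cost reduces to the residue's
nitrogen or sulphur atom count — e.g. exactly 1 for both cysteine and
methionine — while the relative cost additionally weighs the residue's
usage in biomass.

Downstream, the package:

* clusters cost measures by complete-linkage agglomeration on `1 − R`
  (Spearman or Pearson correlation over the 20 residues), bundling an
  8-measure compendium table;
* regresses transcript/protein levels on per-residue cost, CAI, tRNA gene
  number and C/N/S atomic content (log-transformed, centred, RMS-scaled),
  with condition fixed effects, backward AIC pruning of interaction terms,
  and removal-based variable importance (ΔAIC);
* estimates per-alignment-column substitution-rate multipliers by maximum
  likelihood under WAG (or an equal-rates null model) with Felsenstein
  pruning on a fixed 4-taxon *Saccharomyces* tree, reconstructs the
  ancestral residue at the root, normalises rates by gene tree length,
  aggregates by ancestral residue, and correlates mean rates with cost
  (Spearman plus Huber robust trend).

Every stage has a synthetic generator with known truth: toy metabolic
models with analytic costs, expression tables with stated linear structure,
and alignments evolved with known per-site rates.

## Worked example

Build the default toy model (six residues with known glucose/nitrogen/
sulphur demands) and estimate a cost table:

```
$ aacost simulate model --out toy.tsv
$ aacost cost estimate toy.tsv --residue trp --nutrient glucose --mode absolute
trp glucose absolute: rescaled cost 9 (raw slope 0.9, R2 1.000000)
```

The toy tryptophan pathway consumes 9 glucose units per residue, so the
rescaled absolute glucose cost is 9: the raw slope `dU/dx = 0.9` at growth
rate 0.1 h⁻¹, divided by the growth rate.  The full table
(`aacost cost table toy.tsv --out costs.tsv`) reproduces the analytic
costs to ~1e-12, e.g. cysteine and methionine both get sulphate-limitation
absolute cost 1.0000000000002 (one sulphur atom each).

Correlate and cluster the bundled cost compendium:

```
$ aacost compare --out corr.tsv --dendrogram tree.nwk --method pearson
```

yields, among others, `R(abs_glc, wagner_ferm) = 0.522` and
`R(abs_glc, ag_energy) = 0.958`, and a dendrogram in which the FBA absolute
glucose cost groups with the curated energetic measures and molecular
weight long before joining the relative glucose cost — the relative cost
measures something different (usage-weighted marginal cost), essentially
uncorrelated with every literature measure (max rank correlation 0.08).

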