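# Methods

## FBA cost estimation

**Model.**  A stoichiometric model is the matrix `S` (m metabolites × n
reactions) with per-reaction flux bounds in mmol·gDW⁻¹·h⁻¹; negative
coefficients consume, positive produce.  The biomass pseudo-reaction
consumes the 20 amino acids (among other precursors) in fixed ratios; its
flux is the growth rate μ (h⁻¹).  Exchange reactions touch exactly one
metabolite; the model's own sign convention is respected by reading the
exchange coefficient (uptake is the flux direction that supplies the
metabolite), so all cost arithmetic is sign-free.

**Linear program.**  `min c·v` s.t. `S·v = 0`, `lb ≤ v ≤ ub`, solved with
HiGHS (scipy.optimize.linprog) at primal/dual tolerances 1e-9, with a
post-check that the mass-balance residual is ≤ 1e-7.  The biomass flux is
fixed to μ exactly and the three nutrient exchanges (glucose, ammonium,
sulphate) are opened to a "limitless" bound, default magnitude 1000
mmol·gDW⁻¹·h⁻¹ (the conventional unbounded-exchange value; configurable).
Water and oxygen exchanges are never objectives but stay open.  Only the
objective value is contractually unique — alternate optima may differ in
fluxes, and no flux-variability analysis is attempted.  Fixing μ and
minimising uptake (rather than maximising growth at fixed uptake) mimics
chemostat culture and puts every estimate on the same growth-rate scale.

**Perturbation sweep.**  The default sweep is 11 evenly spaced deltas over
±1e-4 mmol·gDW⁻¹ (absolute mode) or ±1% of the coefficient (relative
mode): small enough that the LP optimum is linear in the perturbation,
large enough that solver noise (≲1e-9) is negligible against the signal.
The slope is ordinary least squares over the full sweep — averaging over
sweep points suppresses solver noise relative to a two-point difference —
with R² recorded and a nonlinearity flag below 0.999.  A sweep whose
uptake response is flat to within LP tolerance returns slope 0 (a residue
simply does not consume that nutrient); an infeasible sweep point aborts
the whole sweep rather than being dropped, which would bias the slope.
Perturbations that zero or flip the biomass coefficient are rejected.

**Rescaling and modes.**  Costs are estimated at growth rates 0.05, 0.1
and 0.2 h⁻¹ (feasible chemostat dilution rates; headline values at 0.1)
and divided by the growth rate, which removes the proportionality of the
raw slope to μ — exactly so on toy models, to about 1e-2 on genome-scale
models.  Absolute and relative estimates are linked by `relative =
absolute × x`; the identity is exercised as a test invariant at relative
error ≤ 1e-6 rather than used to derive one mode from the other.

**Toy-model oracle.**  The synthetic generator builds one-reaction
syntheses per residue (k glucose units, n nitrogen, s sulphur atoms per
residue, biomass coefficient x), so minimal uptakes are analytic:
`U = μ·Σ x_r·k_r` etc., absolute costs equal (k, n, s) and relative costs
equal (k·x, n·x, s·x).  An optional shared-intermediate variant routes
glucose through a precursor without changing the analytic costs.  The
master equivalence test requires the estimated 6-column table to match the
analytic table to 1e-8 at all three growth rates.

## Cost compendium

The bundled table carries eight measures for the 20 residues: the
FBA-derived absolute/relative glucose costs for yeast (iND750) and six
literature measures (Akashi & Gojobori energy, Craig & Weber energy and
steps, Wagner fermentative/respiratory, molecular weight), at the
3-significant-figure precision of the published values.

Correlation matrices are computed pairwise-complete with two-sided
p-values; `spearman` (average ranks for ties) is the stated method and
default, `pearson` is also exposed because the published coefficients for
this table (0.522 and 0.65 for the absolute-glucose cost against Wagner's
fermentative cost and Craig & Weber's steps; >0.8 against the four curated
measures) are reproduced exactly by product-moment correlation and not by
rank correlation (which gives 0.66, 0.59 and a group minimum of 0.73 on
the same data).  The acceptance test therefore checks the reported values
under Pearson and the relative-cost maximum (0.077) under Spearman; both
facts are properties of the bundled data that anyone can recompute.

Cost types are clustered by complete-linkage agglomeration on distance
`d = 1 − R` (anti-correlated measures are maximally distant; `1 − |R|` is
available).  Merge heights are non-decreasing (ultrametric), ties break by
scipy's deterministic lowest-index rule, and the tree serialises to Newick
with branch lengths derived from merge heights.  p-values use the
t-distribution approximation at n = 20.

## Expression regression

Per-gene predictors are per-residue averages: chosen cost measure, carbon,
nitrogen and sulphur atom counts, and tRNA gene copies, each summed over
the protein (stop codons excluded) and divided by length; CAI is consumed
as an input column.  All predictors are natural-log transformed, centred,
and divided by the root mean square of the centred values (so RMS = 1;
this reading of "scaled by the root mean square" makes the scale equal the
SD up to the n vs n−1 factor).  Protein responses are log-transformed
before scaling; transcript responses are scaled only, having been
log-scaled upstream.  Zero entries in atomic-content columns (proteins
without cysteine/methionine) receive a pseudocount of half the smallest
positive value before the log.

The model is one pooled OLS fit of response on the six predictors plus
condition fixed effects, with predictor-by-condition interaction terms.
Backward stepwise selection over the interaction terms only (main effects
are never dropped) removes, at each step, the term whose removal most
decreases AIC, ties broken by term name, until no removal decreases it.
Variable importance is removal-based: ΔAIC = AIC(model without the
predictor and its interactions) − AIC(full); positive values mean the
predictor contributes, and a useless predictor costs up to 2 AIC units per
parameter.  ΔAIC is invariant to the AIC constant convention, so only
differences are contractual.  A numerically perfect fit makes AIC diverge;
such importances are capped at 1e6 and flagged.  Rank-deficient designs
raise an error naming the collinear columns.

The synthetic generator draws uniform-random sequences (length 50–500,
CAI ~ U(0.1, 0.9)), computes features through the real pipeline, and
defines the response directly on the *scaled* predictors plus Gaussian
noise, so stated coefficients are the estimands of the fit.  Note that
mean cost and mean carbon content are strongly collinear (r ≈ 0.97 on
random sequences, as in real proteins), which inflates their standard
errors; recovery is therefore asserted within 3 SE, with coverage checked
over 200 seeded replicates.

## Substitution rates

**Model.**  WAG exchangeabilities and frequencies (Whelan & Goldman 2001)
are bundled as text; the null model has identical off-diagonal rates and
uniform frequencies.  Q is scaled to one expected substitution per unit
branch length at equilibrium; transition matrices come from the symmetric
eigendecomposition of `diag(√π)·Q·diag(1/√π)` with rows clipped at zero
and renormalised.

**Estimator.**  Column likelihoods use Felsenstein pruning on the rooted
(trifurcating-root) species tree ((Scer, Spar), Smik, Sbay); gaps and
ambiguous characters are missing data.  Gene branch lengths are first
fitted by ML under a rate-homogeneous model (L-BFGS-B, bounds
[1e-8, 20]); per-column rate multipliers ρ are then fitted by bounded
Brent search on [1e-6, 50] at tolerance 1e-8 with branch lengths held
fixed.  This two-stage fit replaces a joint profile fit, under which tree
length would not be identifiable (only products ρ·t enter the
likelihood); the branch lengths absorb the gene-average rate, so ρ is a
relative, within-gene quantity.  The ancestral residue is the marginal
reconstruction (argmax posterior) at the root at the fitted ρ.  Identical
columns are collapsed to unique patterns before optimisation.  The
estimator deliberately simplifies the discrete-gamma empirical-Bayes site
rates of codeml; a parser for per-site rate tables (tabular, and an
rst-style report dialect with a `tree length =` line and a
`Site Rate Ancestral` table) provides the faithful path for users with
codeml output.

**Normalisation and aggregation.**  Site rates are divided by the gene's
tree length to remove gene-level rate variation (a gene with uniformly
longer branches gets proportionally smaller normalised rates — that is
the point of the correction); genes with tree length 0 are dropped with a
log entry, as are columns containing any gap.  Bookkeeping is exact:
kept + gap + zero-tree-length = total columns.  Mean normalised rate, SEM
(sd/√n) and site count are reported per ancestral residue, and rate–cost
association uses Spearman correlation plus a Huber M-estimator linear
trend with a normal-approximation 95% CI.

**Validation design.**  Alignments are simulated by drawing root states
from π and propagating transition matrices `P(t·ρ)` down the tree, with
per-site rates from a discrete distribution (default classes 0.1, 0.35,
1, 2.5, 5, equal weights — a gamma-like spread) and optional per-leaf,
per-column gap injection.  Four sequences carry limited information about
a single column's rate: on the shallow 4-taxon species tree even the
Bayes-optimal posterior-mean rate under the true prior recovers simulated
rates only to Spearman ≈ 0.8, because low-rate columns are invariant
(tying at the boundary) and high-rate columns saturate.  Rate-recovery
validation therefore uses a balanced 8-taxon tree (branch lengths
0.1–0.25), where ML recovery reaches ≈ 0.86 at 500 sites; exactness
checks (pruning vs brute-force enumeration over all internal states,
1e-10) and pipeline tests remain on the 4-taxon tree.

## Problem sizes and scope

Tests and the acceptance script run on toy models (≤ 10 reactions,
~1200 LP solves for a full cost table), synthetic expression tables of
120–2000 genes, and simulated alignments of 40–500 columns; the complete
suite runs in well under a minute on one core.  Reproducing the published
iND750/iJR904 cost tables requires those SBML models as user-supplied
files (minutes of LP solves); reproducing the published expression and
substitution-rate tables additionally requires the external chemostat
microarray, TAP-tag proteomic, and 4-species ortholog-alignment datasets,
which are out of scope — those pipelines are validated by the synthetic
generators and format-level tests instead, so passing tests demonstrate
estimator correctness, not claims about the biological datasets.

## Known limitations

* The SBML subset covers species, reactions, stoichiometry and fbc flux
  bounds; kinetic laws, gene-protein-reaction rules and groups are
  ignored.
* Amino acid and nutrient resolution relies on a synonym table covering
  common naming styles (BiGG-style ids, full names); unusual ids need an
  explicit mapping.
* The site-rate estimator is not codeml: no discrete-gamma prior, no
  empirical-Bayes shrinkage, branch lengths shared across sites.  Rates
  for nearly invariant columns sit at the search boundary.
* Regression treats conditions as fixed effects in one pooled model with
  interactions; per-condition separate fits and mixed-effects models are
  not implemented.
* The robust-trend CI uses the RLM normal approximation, not a bootstrap.
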