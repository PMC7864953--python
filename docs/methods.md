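# Methods

This note documents the models, parameter choices and numerical decisions
behind `cdtox`, and what the synthetic-data generators do and do not
emulate.

## Concentration-dependent transcriptome engine

### Fold change

Per-gene response is the log2 fold change of each treated sample against
the mean of the vehicle controls,
fc(g, c) = log2((x_gc + q) / (x̄_g,vehicle + q)), with pseudocount
q = 0.5 for zero counts.  Counts are library-size normalized to
counts-per-million first (default on): single-replicate amplicon designs
commonly span an order of magnitude in sequencing depth, and raw-count
ratios would confound fold change with depth.  `normalize=False` restores
the literal raw-count reading.

### The nine-model registry

Three models per named curve type, over x = log10 concentration
(mg carbon/L):

| type | models (parameters) |
|---|---|
| sigmoidal | 4-parameter logistic (bottom, top, mid, slope); 3-parameter logistic (bottom ≡ 0); Gompertz |
| linear | straight line a + b·x; power a·C^b; exponential a·(e^{b·x} − 1) |
| U-shaped | quadratic; Gaussian bell a·exp(−((x−m)/w)²); biphasic — two opposing logistics with a shared slope (5 params) |

Two registry choices differ from the most obvious textbook set, for
identifiability on a seven-point design:

* **Gaussian bell instead of a cubic.**  A cubic in log-concentration is
  monotone over much of its parameter space, so it behaves as a redundant
  sigmoid competitor whose U-shape EC rule then misfires; the bell is the
  canonical genuinely non-monotone (hormesis-like) shape.  Its width is
  floored at 0.5 decades — a bump narrower than the 0.7-decade fivefold
  dilution spacing would fit a single point, which is noise, not a
  concentration response.
* **Shared-slope biphasic.**  With independent slopes the biphasic has six
  parameters, leaving zero residual degrees of freedom at n = 7.

The registry is an argument to `fit_gene_models`, so an alternative set
can be swapped in without touching the pipeline.

### Fitting, selection, significance

Each model is least-squares fitted (Levenberg–Marquardt) from a
deterministic initial guess plus deterministic "step" starts (sigmoid
midpoints at the largest consecutive jumps, both rate signs for
power/exponential, step-position pairs for the biphasic) and seeded random
restarts; non-convergence marks the model failed (infinite AIC) rather
than failing the gene.  Selection uses AIC = n·ln(RSS/n) + 2k (a
small-sample AICc correction is available via an argument but is not the
default; on this design it over-penalizes 3-parameter sigmoids into
linear-family wins).  Because AIC yields no p-value, significance is a
separate F-test of the winning model against the intercept-only null; a
gene is a DEG when the winner's p < α (default 0.05) **and** an EC_DEG is
extractable.

Known property: testing the minimum-AIC model of nine is anticonservative.
At the generator's default noise (negative-binomial dispersion 0.1, fold
change noise ≈ 0.45 log2 units) the realized null-gene call rate is ≈ 8%
at α = 5%, because significant noise fits frequently also cross the
1.5-fold threshold; at lower noise the threshold filter removes most of
the excess.  This is a property of the published selection-then-test
construction itself, not of the optimizer.

### EC extraction

The EC rule follows the shape the winning curve actually realizes on the
search window (tested range ± 1 decade):

* material extremum inside the window → U rule: first upward crossing of
  |fc| = log2(1.5) between the lowest *tested* concentration and the
  extremum ("first monotonic portion"; polynomial forms diverge below the
  tested range and are not evaluated there);
* monotone and saturating (logistic family, or a biphasic whose second
  phase sits outside the window) → concentration at half the asymptotic
  maximum effect;
* monotone and unbounded (line, power, exponential, polynomials) →
  first upward crossing of |fc| = log2(1.5).

"Material" extremum means the curve retraces more than 1% of its range —
flat asymptotes of fitted curves carry numerical wiggles that are not
turning points.  Crossings are bracketed on a 512-point grid and refined
by Brent's method (xtol 1e−12); ECs outside the tested range (allowed up
to one decade beyond either end) are flagged extrapolated.  Direction is
the sign of the fitted fold change at the crossing (for sigmoids, the
sign of the asymptotic effect).

### Pathway potency, distributions, screen

A GO term or KEGG pathway is responsive when ≥ 3 of its member genes are
DEGs; its EC is the geometric mean of the matched EC_DEG values (the ≥ 3
rule is the only enrichment criterion applied; an optional hypergeometric
test exists in the code path but is off by default).  Sample-level potency
fits a log-normal to the ECs: μ, σ are the maximum-likelihood mean and SD
of log10 EC, with Hazen plotting positions (i − 0.5)/n attached for the
empirical curve.  Term clustering is average-linkage on Euclidean
distances of log10 EC profiles; a missing EC (term non-responsive in a
sample) is imputed as that sample's maximum EC × 10 and flagged — "less
potent than anything observed" without dropping the term.  The chemical
screen is strict: coverage must exceed the threshold (default 50%), so
exactly half fails.

### Viability

Relative viability = 100 × (OD_treated − OD_blank)/(OD_control −
OD_blank); values above 100% (growth stimulation) are legal.  ECx fitting
uses a two-parameter log-logistic with top fixed at 100 and bottom at 0,
v = 100/(1 + (C/EC50)^h), and ECx = EC50·(x/(100 − x))^{1/h}; data that
never reach the x% inhibition level return no ECx.

## Formation-kinetics network engine

Products are detected at a timepoint when peak area strictly exceeds 3×
the non-irradiated control; a zero control area falls back to a noise
floor (0.1 × the smallest positive area in the table) and is flagged.
Only products detected at *all* irradiated timepoints enter the kinetics
matrix; rows are Z-scored across timepoints (constant rows dropped).
Day 0 is the detection control, not a kinetics point.

Product–product edges require two-tailed Pearson p < 0.001 (t
distribution, df = timepoints − 2; with four timepoints the critical |r|
is 0.999) and r > 0 by default — the network encodes similarity of
formation kinetics; a flag admits negative correlations.  Louvain
(networkx, resolution 1.0, seeded, nodes canonicalized by sorting) labels
communities by decreasing size; only communities with > 10 nodes are
reported, smaller groups keep labels but are not reported.

Toxicity vectors per cell line are 100 − viability at the highest
concentration common to all irradiation durations (configurable), floored
at 0.1% before log10, then Z-scored.  Product–cell association applies
the same transform to peak areas (log10, Z-score) and requires r > 0 with
p < 0.05.  Community–cell correlations use the mean of member rows on
that same log10-Z scale, so community profiles and toxicity vectors are
commensurable.  Venn summaries satisfy inclusion–exclusion exactly.
Networks export to GEXF and GraphML with community labels and node kinds,
and re-import losslessly.

## Structure annotation

Formula assignment enumerates C/H/N/O/S/Si counts within bounded ranges
(defaults C0–40 H0–80 N0–4 O0–20 S0–2 Si0–2), solving the hydrogen count
from the mass remainder so enumeration is quartic, not six-deep.
Candidates must match the adduct-corrected neutral mass within 10 ppm
(QTOF-class accuracy), have RDBE ≥ 0 and H/C in [0.2, 3.1]; ranking is by
|ppm| then a coarse isotope score comparing the observed M+1/M ratio to
≈ 1.1% per carbon (approximate by design — it ranks, it does not fit
patterns).  Supported ion forms: [M+H]⁺, [M+Na]⁺, [M+NH₄]⁺ and bare
cations (positive mode).  Homologue series chain masses whose residues
modulo the repeat-unit mass (default C₂H₄O, 44.026215 Da) agree within
0.002 Da, requiring ≥ 3 members at distinct repeat indices.
High-frequency fragments pool all MS/MS peaks, single-linkage cluster at
0.005 Da and report clusters present in ≥ 5 distinct spectra (the
count threshold is configurable; no published value exists for it).
Confidence levels follow the standard five-level nontarget scale:
spectral-library hit → 2, diagnostic fragments or series membership plus
a formula → 3, unique formula → 4, exact mass only → 5; level 1
(authentic standard) is never auto-assigned.  Removing evidence can only
lower confidence.

## Chemistry constants

Most-abundant-isotope masses are hard-coded to 6 decimals (IUPAC 2021);
the electron mass 0.000549 Da is applied per unit charge.  PEG masses are
monoisotopic throughout (n·44.026215 + 18.010565).  The Bragg utility
defaults to Cu Kα (0.15406 nm).  Unsupported elements are rejected at
parse time.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed).

**Counts** — 1200 genes, seven fivefold dilutions (default 0.019–300 mg
carbon/L), four vehicle controls, one replicate per treatment; library
sizes uniform in [543084, 5848694]; per-gene baselines log-normal
(σ = 1.2 in ln units); counts negative-binomial (gamma–Poisson,
dispersion 0.1).  A `deg_fraction` (default 10%) of genes follow planted
curves: 3-parameter logistics (|amplitude| 1.5–3 log2 units, slope 1.5–3
per decade, midpoint in the inner 70% of the range), lines anchored at
the lowest concentration (|slope| 0.4–1.2), or downward/upward parabolas
with the vertex mid-range — mirroring the three curve types, with
analytic true ECs recorded in the truth table.

**Peak tables** — products drawn from up to six kinetic archetypes in
log10-area space over {0.5, 1, 4, 8} d (saturating rise, late rise,
steady rise, rise-then-fall, decay, early spike), with multiplicative
lognormal noise (CV default 0.05).  The first three archetypes are exact
affine images of the three cell lines' log10 inhibition profiles, so
their members are collinear with the toxicity vectors by construction;
per-cell truth flags are computed from the noiseless archetype–cell
correlation, which was designed to keep every archetype–cell pair far
from the r ≈ 0.95 significance boundary (nearest pairs ≈ 0.87 and 0.99).
Archetypes span ~3 decades of area so that within-community raw-area
correlations exceed the stringent df = 2 edge threshold.  Decoys (10%)
get control areas set so the 3× rule fails with a 10% margin.  A PEG
ladder (n = 3–11) and 16 aromatic products carry known formulas for the
annotation stage.

**Viability plates** — OD wells (blank 0.08, control 0.90, Gaussian noise
SD 0.005, six replicates) from a log-logistic truth (hill 1.5) whose
EC50 per irradiation duration is back-computed from the shared cell
inhibition profiles, so peak-table toxicity and viability toxicity are
one consistent ground truth.

**Not emulated**: batch effects, retention-time drift, isotope envelopes,
multi-replicate RHT designs, real gene-set topology, compositional
library effects beyond what CPM induces.  Passing tests therefore show
that the *procedures* recover planted structure under the stated noise
models, not that they are robust to every artifact of real instruments.

## Problem sizes and runtime

The default end-to-end synthetic study (1200 genes, 300 products) runs in
roughly a minute on one CPU; recovery and error-control suites use 100–
1000 genes and 300 products.  Gene fitting costs ≈ 20 ms/gene (nine
models, multistart LM).

## Known limitations

* EC recovery for planted sigmoids at heavy noise (SD 0.2 log2) has a
  median |log10 EC ratio| around 0.2 decades: the identifiability floor
  with the *true* model known is already ≈ 0.12, and cross-family winners
  (whose EC definitions differ by construction) add the rest.
* The null-gene DEG rate exceeds the nominal α (≈ 8% at α = 5% under
  default noise) for the reason given above; consumers needing strict
  type-I control should tighten α or pre-filter genes.
* The isotope score is deliberately coarse; formula ranking near-ties
  should be reviewed with real isotope-pattern software.
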