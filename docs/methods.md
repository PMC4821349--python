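# Methods

This note documents the models, algorithms, numerical choices and
limitations of `metnet`, in the order the pipeline runs them.

## Metabolic model representation

A model is a list of metabolites (id, name, compartment, boundary flag)
and reactions (id, stoichiometry as metabolite → signed coefficient,
bounds in mmol·gDW⁻¹·h⁻¹, subsystem, GPR rule, objective coefficient).
The gene set is *derived* — always the union of GPR leaves — so pruning
reactions automatically prunes genes. The stoichiometric matrix S is
built over non-boundary metabolites only; species flagged
`boundaryCondition=true` in SBML or carrying the `_b` id suffix are
treated as external pools exempt from mass balance (the standard
exchange-reaction convention).

SBML reading accepts Level 2 and Level 3 core. GPRs come from the fbc
`geneProductAssociation` when present, otherwise from the legacy
`GENE_ASSOCIATION:` notes field used by COBRA-era models (the iND750
generation predates fbc). Bounds come from fbc flux-bound parameters or
kinetic-law `LOWER_BOUND`/`UPPER_BOUND` parameters; when absent they
default to (−1000, 1000) for reversible and (0, 1000) for irreversible
reactions. If no objective is flagged, the unique reaction whose id
contains "biomass" (case-insensitive) is used; ambiguity is an error
rather than a guess. Writing emits Level 3 + fbc v2 with ids escaped to
valid SBML SIds (`__<codepoint>__`), so BiGG-style ids like `EX_glc(e)`
round-trip exactly. Model equality throughout the package is semantic:
GPRs are compared as truth tables, not strings.

## LP/MILP core

All problems are solved with HiGHS via `scipy.optimize.linprog` /
`milp`. Absolute values are linearised with split or auxiliary
variables. Tolerances: a distribution is accepted as balanced when
‖S·v‖∞ ≤ 1e-6; growth is "zero" below 1e-6 absolute (the LP noise
floor); when a stage fixes a previously optimised flux it allows a
relative slack of 1e-9 so the second stage is never spuriously
infeasible. The optimal objective value is deterministic; the flux
vector may be any optimal vertex.

**Lexicographic product maximisation** runs biomass first, then fixes
biomass at its optimum (the convention used for all reported
product/biomass pairs) — or at `growth_floor × optimum` as a lower bound
when a floor is given — and maximises the product flux.

**Linear MOMA** minimises Σ|vᵢ − v_wt,i| subject to the mutant's
constraints. Because FBA optima are degenerate, the wild-type reference
is made reproducible by a parsimonious tie-break: biomass is fixed at
its optimum and Σ|v| minimised (`wildtype_reference`). Lethality calls
are invariant to this choice — FBA and lMOMA share a feasible region, so
a knockout with zero attainable growth is lethal under both — but
intermediate growth ratios are reference-dependent and should be read
qualitatively.

**Robustness scans** grid the reaction's feasible flux range (two
variability LPs give the range; default 20 points) and re-maximise
biomass at each pinned value; infeasible points report `None`, and a
blocked reaction collapses to a single point.

## Deletion phenotyping

A deletion disables every reaction whose GPR evaluates false with the
gene removed (isoenzyme OR rules survive single deletions; complex AND
rules do not); disabled reactions get both bounds zeroed. Phenotypes:
`unchanged` above a growth ratio of 0.999, `no_growth` at or below the
zero tolerance, `reduced` between. When scoring against an annotated
essential-gene list, "lethal" means `no_growth`; genes absent from the
reference are treated as inessential, and reference genes absent from
the model are dropped with a count rather than scored. Deletions sharing
a disabled-reaction set share one LP solve (a large fraction of genes in
real models disable nothing).

## Consensus evidence and extraction

Presence calls use e-value ≤ 10⁻⁴ (inclusive); the two assembly
strategies are merged by OR, species by intersection. Gene evidence maps
to reactions by AND → min, OR → max. Reactions with no gene association,
and genes missing from the evidence map, are *unevidenced* and treated
as above threshold — they are never penalised or forced off. This
retention rule is why an extracted model can keep slightly more genes
than the evidence set: reactions required for functionality keep their
GPRs, and those GPRs can mention unevidenced genes.

GIMME uses inconsistency weights (T − xᵢ) for below-threshold reactions
with defaults f = 0.9 and T = median evidenced reaction expression (the
pipeline's binary evidence uses T = 0.5); penalised reactions carrying
zero flux (≤ 1e-6) in the minimiser are removed, then orphan metabolites
and genes are pruned. iMAT classifies evidenced reactions by expression
quantile (defaults: low ≤ 0.25 quantile, high ≥ 0.75 quantile,
ε = 1.0 flux unit), gives each high reaction two direction indicators
(at most one active) and each low reaction one off indicator, maximises
the agreement count, and removes low reactions inactive in the optimum.
The MILP has a 300 s default time limit and refuses partial results. On
binary evidence the two algorithms remove the same unexpressed-and-
dispensable reactions; `compare_models` verifies the agreement
structurally.

## Strain design

Candidate designs are scored by the lexicographic LP (biomass, then
product at that biomass) rather than a duality-embedded bilevel MILP:
scoring is exact per candidate, simple, and matches how paired
product/biomass rates are reported for engineered strains; the MILP
embedding is a possible extension. The local search starts from the
empty set, explores all sets within Hamming distance ≤ k (default 2) of
the incumbent subject to the budget K (default 5) and growth floor
(default 0.05 mmol·gDW⁻¹·h⁻¹), and moves to the best product
improvement, breaking ties by fewer knockouts then lexicographic id
order — making the search fully deterministic. One search path is
followed. Exchange reactions may be included in the candidate pool.
Printed reaction ids are normalised for stray whitespace ("GLYt2 m" →
"GLYt2m") when matching knockout lists.

## Expression statistics

RPKM is 10⁹·C/(N·L) with N the per-sample mapped-read total and L the
exon length in bp.

The differential-expression test is a deliberately simple NB test, not a
re-implementation of any published package: size factors by
median-of-ratios to per-gene geometric means; per-gene overdispersion α
(variance μ + αμ²) by method of moments, pooled across the two groups,
with the Poisson shot-noise part subtracted. With few replicates the
per-gene α is noisy and biased low after flooring at 0, which would
inflate the type-I error, so each gene uses the larger of its own
estimate and the across-gene median (conservative "maximum" sharing, no
mean-trend fitting). The test itself conditions on the total count: the
two group sums are approximated as NB with matched means and variances,
and the two-sided p-value sums the probabilities of all splits no more
likely than the observed one. A DEG requires p < 0.05 *and* fold change
strictly > 2 or < 0.5 (a boundary fold change of exactly 2 is not a
DEG). Genes with zero counts everywhere get p = 1 and no call. The
divergence p-threshold defaults to 0.05 and is configurable (stricter
0.01 calls are a reasonable alternative for figure-level claims).

Divergence relative to an outgroup requires the gene to be a DEG in
*every* outgroup-vs-species comparison with a consistent tendency (all
fold changes > 2 or all < 0.5); direction is reported relative to the
outgroup.

Coexpression uses log2(RPKM + 1) — a scale on which correlations are not
dominated by the few highest-expressed genes; the lowest-variance 25 %
of genes is removed (quantile configurable), constant genes are excluded
(undefined r), and all unordered pairs with |Pearson r| ≥ 0.90 across
samples become edges. Note that RPKM shares the per-sample library-size
term across genes, so strong compositional shifts can induce mild
background correlation; the 0.90 threshold sits far above that
background in the simulated designs.

N50 is the largest length L such that contigs ≥ L cover at least half
the total assembled length.

## Synthetic data: what it emulates, and what not

The expression generator reproduces the study design that motivated the
package — four species, two replicates each (20 samples when the two
public datasets are combined; the generator's replicate count is a
parameter) — with NB counts (variance μ + αμ², baseline mean 100,
dispersion 0.1 under the null), per-sample library-size factors in
[0.7, 1.3], planted fold changes as multiplicative mean shifts, and
planted modules as a shared per-sample latent factor on the log2 scale
(amplitude 2, loading and per-gene noise configurable). It does not
emulate read-level artefacts (mapping bias, positional effects), gene-
length-dependent power, mean–dispersion trends, or batch structure; a
passing recovery test shows the estimators work under clean NB
sampling, not that they are robust to those artefacts. The homology
generator plants presence (hit e-value ≤ 10⁻⁶) versus absence (no hit,
or a decoy at e-value ≥ 10⁻²) so threshold behaviour is exercised, but
does not model borderline e-values or paralog confusion. Toy metabolic
models are parallel uptake→branch→biomass pathways with known optima
(uptake × best yield) and ground-truth essentials computed by exhaustive
single-deletion LPs; they exercise GPR logic and LP plumbing, not the
scale or degeneracy of genome-scale networks.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately small
instances — toys of ≤ 10 reactions where exhaustive oracles (vertex
enumeration, truth-table evaluation, knockout-set enumeration, iMAT
activity-pattern enumeration) are exact, 1000–2000-gene simulations for
the statistical calibrations — chosen so the full check runs in a few
minutes on one CPU while every claim is still verified against an
independent oracle. All generators take explicit seeds; pipeline runs
with identical configs and seeds produce byte-identical outputs
(checksummed in the run manifest).

## Known limitations

* Quadratic MOMA, loopless/thermodynamic constraints and flux sampling
  are out of scope; the MOMA variant is the linear one.
* The NB test targets calibration and power at ≥2-fold effects; its DEG
  counts will not numerically match shrinkage-based packages on real
  data.
* Extraction defaults (f, T, quantiles, ε) are heuristics; published
  context-specific models can depend on parameter choices that their
  papers do not state, so re-extraction is validated structurally (on
  planted truths and cross-algorithm agreement), not against published
  gene counts.
* The designed knockout search is locally optimal by construction;
  the exhaustive-enumeration comparison is only feasible on toys.
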