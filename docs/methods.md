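# Methods

## Model

A discrete Bayesian network over nodes V is a DAG plus one conditional
probability table (CPT) per node; the joint distribution factorises as
P(X) = Π_v P(X_v | X_pa(v)). All inference in `bnpool` is exact: marginals
and conditionals are computed by variable elimination, never by sampling,
because elicitation-scale networks (tens of nodes, small state spaces) are
comfortably within exact reach and the pooling comparison must not be
blurred by Monte Carlo noise.

Expert opinions are combined by the linear opinion pool
P(X) = Σᵢ wᵢ Pᵢ(X) with positive weights summing to one, default wᵢ = 1/n.
Two application points are implemented:

* **Prior Linear Pooling (PrLP)**: pool within each CPT row across experts,
  then propagate the single pooled network. Averaged rows are renormalised
  after the weighted sum purely to absorb float error (the average of
  normalised rows is normalised in exact arithmetic).
* **Posterior Linear Pooling (PoLP)**: propagate each expert's network
  under the given evidence, then pool the marginals node by node at the
  requested targets. Pooling is always per node, never jointly over several
  nodes, which sidesteps the failure of linear pools to preserve
  multivariate independence.

Properties the test suite pins down: the two routes coincide exactly when
all experts are identical, and at root nodes with no evidence (both reduce
to averaging one CPT row); PoLP marginals lie in the convex hull of the
per-expert marginals by construction; with no evidence, a PoLP marginal
equals the corresponding marginal of the wᵢ-mixture of the experts' joint
distributions. Under evidence that last identity fails, by design: PoLP
averages the per-expert *posteriors* with the panel weights unchanged,
whereas the mixture posterior would reweight each expert by their evidence
likelihood Pᵢ(evidence). The unweighted reading is implemented because it
is the natural per-node pool of posterior opinions; Bayesian-mixture
reweighting is a documented alternative, not a behaviour. A frozen
regression example (the two-expert chain with evidence B=t) exhibits the
difference, including its sign.

Evidence with probability zero under some expert's network is an explicit
`ImpossibleEvidenceError`, not a NaN, because PoLP must decide what to do
with that expert. Both policies are available: the default raises, naming
the expert; `drop_impossible=True` excludes such experts and renormalises
the remaining weights, logging a warning.

## Inference internals

CPT rows are keyed by parent joint-state tuples in declared parent order,
enumerated with the last parent varying fastest; this makes the row-major
reshape of a CPT table directly usable as a factor and fixes a bit-exact
layout for serialisation. Variable elimination reduces factors by evidence
slicing, then sums out non-target variables in a min-degree order on the
interaction graph with lexicographic tie-breaks, so results and
intermediate orders are deterministic. Optimality of the order is
irrelevant at this scale. The brute-force joint enumeration
(`enumerate_joint`) is a test oracle only, capped at 2^20 joint states.

Numerical tolerances: CPT rows must sum to 1 within 1e-9; rows off by at
most 1e-6 are renormalised with a warning (elicited probabilities are
typically rounded to a few decimals), larger deviations are reported as
validation failures. State labels are case-sensitive exact strings, so
"Good" and "good" never merge silently across experts.

## Panels and subgroups

A panel is n complete CPT assessments over one shared structure (differing
structures are out of scope), plus categorical covariates per expert and
pooling weights. Subgroup analysis filters the panel on covariate
categories and renormalises weights proportionally (wᵢ / Σ_subgroup wⱼ), so
equal weights stay equal. Because the linear pool is linear, the
subgroup-size-weighted average of subgroup PoLP marginals recomposes the
full-panel PoLP marginal exactly, for any partition and any fixed evidence
— a useful audit identity that the tests assert at 1e-12.

`subgroup_report` supports a second subgroup semantics alongside covariate
filtering: when the network itself contains subgroup variables as nodes,
constraints can be applied as evidence inside a single pooled network
(`mode="condition"`). Filtering is the natural route for PoLP, conditioning
for PrLP; the API keeps the distinction explicit.

Across-expert spread statistics use the sample (n−1) standard deviation
(respondents are a sample from a population of travellers/experts; sd = 0
for a single respondent) and linear-interpolation quantiles between order
statistics — the default convention of mainstream numeric stacks, fixed
here in tests so boxplot statistics are reproducible.

## Synthetic panels

The generator emulates an elicitation survey for which no raw responses
are available. Each expert's CPT row is drawn Dirichlet(κ·m), where m is
the consensus row after any subgroup shifts active for that expert and κ is
a shared concentration. The Dirichlet mean is m itself, so pooled CPTs are
unbiased for the (shifted) consensus and converge to it as the panel grows;
the per-entry variance m(1−m)/(κ+1) gives closed-form standard errors that
the recovery tests use. Subgroup shifts add δ to one state's probability in
every row of one node's CPT (clipped to stay inside (0,1), remaining
entries rescaled proportionally) before perturbation, so an injected effect
is an exactly known quantity the analysis pipeline can be asked to recover.

Covariates are assigned with exact largest-remainder counts of the stated
category frequencies and then shuffled by the seed, so subgroup sizes are
deterministic while membership is random. All generators are pure functions
of (inputs, seed) via `numpy.random.default_rng`.

What the generator does *not* emulate: within-expert inconsistency, item
nonresponse, anchoring or other elicitation biases, correlation between an
expert's errors across CPT rows, and disagreement about structure. Passing
tests therefore demonstrate correctness of the pooling and inference
machinery and recoverability of planted effects under a clean response
model — not robustness to the messiness of real survey data.

### Wayfinding fixture

The packaged fixture is a six-node binary network describing airport
wayfinding: Visual Elements of Communication → Communication; Navigation
Pathway → Environmental Factors; and Human Factors, Environmental Factors
and Communication → Wayfinding. Node and state names follow the published
definitions of the six nodes of interest (e.g. Wayfinding:
Effective/Ineffective). The edge set is a schematic reading of those node
descriptions, not a transcription of the full 49-node model, whose graph
and CPTs were never published as data; **every CPT value in the fixture is
synthetic**, chosen once on the scale of the published pooled marginals
(e.g. consensus P(Human Factors = Good) = 0.80).

The fixture panel has 99 respondents with covariate counts matching the
original survey — Gender 46 Female / 53 Male, Travel Purpose 32 Business /
67 Personal, Travel Experience 85 Experienced / 14 Inexperienced — drawn at
κ = 20 with two planted effects mirroring the study's qualitative findings:
Inexperienced travellers' Wayfinding-Effective probabilities shifted by
−0.15 and Female respondents' Human-Factors-Good probabilities by −0.10.
The consensus network ships as BIF text inside the package; the panel is
regenerated deterministically from a fixed seed (a full-precision 99-expert
JSON would be needlessly large to ship) and can be exported with
`bnpool simulate panel --wayfinding --out panel.json`.

## Serialisation

Networks read and write as classic-grammar BIF and as XMLBIF 0.3. The BIF
dialect quotes identifiers containing characters outside
`[A-Za-z0-9_.+-]`, so node names with spaces round-trip. Probability rows
are listed in canonical parent-tuple order. Panels use a versioned JSON
schema (structure block with explicit parent order, per-expert CPT arrays
in canonical row order, covariates, optional weights defaulting to equal).
All writers emit fixed ordering and 17-significant-digit floats, so
repeated writes are byte-identical and write→read is value-identical.

## Problem sizes in tests and the acceptance script

Oracle-equivalence and homogeneity checks run over 100 random networks of
up to 8 binary nodes; generator-recovery runs 20 seeds of 500-expert panels
at κ = 50 (per-entry standard error ≈ 0.003, against a 0.03 recovery band)
and recovers a planted δ = 0.15 shift within two standard errors from 250
experts per subgroup. These sizes give the statistical assertions
comfortable power while the whole suite runs in seconds on one core.

## Known limitations

* Only linear pooling: logarithmic/geometric pools, external Bayesianity
  and measurement-error formulations are out of scope.
* Experts must share the network structure; structural disagreement is not
  pooled.
* Weights are fixed inputs; no performance-based (Cooke-style) weighting.
* Discrete nodes only; no continuous or temporal extensions.
* Missing CPTs for an expert are a validation failure, never imputed — an
  imputation rule would fabricate opinions.
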