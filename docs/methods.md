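# Methods

## Constraint-based model and FBA

A model is a set of metabolites, reactions with signed stoichiometry
(reactants negative), flux bounds in mmol/gAFDW/h, and boolean
gene–protein–reaction (GPR) associations (AND = complex subunits, OR =
isozymes; no association = always catalyzable).  Growth is the flux of a
designated biomass pseudo-reaction.  FBA solves

    max  v_biomass
    s.t. S v = 0
         lb ≤ v ≤ ub

as a single LP per query (scipy HiGHS on the sparse stoichiometric
matrix).  Only objectives are interpreted; flux vectors can be
degenerate and are never asserted.  An LP reported infeasible is a
no-growth outcome; any other solver failure raises.

**Growth threshold.** Growth is qualitative (positive vs. zero optimum).
The call is `objective > 1e-6`, absorbing the LP solver's noise floor;
`1e-9`-scale optima are treated as zero.

**Medium convention** (`set_medium`, all knobs in `MediumSpec`): the
named carbon source and electron acceptor get uptake bound −10; the
nitrogen source (ammonia by default) and the freely available compounds
(default phosphate, sulfate, water, proton — matched by metabolite id
stem or alias map, skipped when a model lacks them) get −1000; every
other exchange is closed for uptake; all exchange upper bounds are 1000
so any compound can be secreted.  ATP maintenance reactions (default id
`ATPM`) have their forced lower bound — the non-growth-associated
demand — set to zero; growth-associated demand enters through the same
flux and is likewise zero.  The rationale is cross-strain
comparability: maintenance parameters fitted for one strain do not
transfer to relatives, and all models must see identical exchange
constraints.  `set_medium` is idempotent: bounds depend only on model
content, condition and spec.

**Knockouts.** Deleting genes closes (bounds 0) every reaction whose
GPR evaluates unsatisfied; unknown gene ids are no-ops.  Essentiality
enumerations (singles, synthetic-lethal pairs) memoize the LP on the
*closed-reaction signature*, since many gene sets close the same
reactions (e.g. all subunits of one complex).  Pair results exclude
supersets of lethal singles, so reported sets are minimal.

## SBML

Reading accepts Level 3 + `fbc` (bound parameters, gene-product
association trees, objectives) and the legacy Level 2 dialect with
`LOWER_BOUND`/`UPPER_BOUND` kinetic-law parameters and
`GENE_ASSOCIATION:`/`SUBSYSTEM:` notes, which is how 2014-era published
reconstructions are encoded.  Writing always emits Level 3 + fbc v2
with a maximize-biomass objective.  The biomass reaction is identified
by the active objective when present, else by a configurable
case-insensitive id/name pattern (default `biomass`); zero candidates
raise an error listing all reaction ids, multiple candidates raise an
ambiguity error.  Gene products carry the raw locus tag in `fbc:label`,
so GPRs round-trip through id sanitization exactly.

## Strain derivation and the core model

Derivation substitutes each template GPR leaf with its functional
orthologs in the target strain (co-orthologs become OR branches, a
convention that directly encodes the multi-ortholog isozyme cases seen
in real families); a reaction is removed when the translated GPR
collapses to constant false.  Non-GPR reactions, exchanges and the
biomass reaction carry over — curated biomass/LPS edits are
user-supplied reaction overrides, not computed.  Pseudogene-flagged
table members are functionally absent throughout.  The derived reaction
set is always a subset of the template's: conflict detection
(`detect_growth_conflicts`) surfaces conditions where FBA disagrees with
observed growth as candidates for *manual* curation; no automated
gap-filling is attempted.

Core construction: (1) GPR reactions keep their association restricted
to genes whose ortholog group is conserved in every strain, surviving
when still satisfiable; (2) removal candidates — reactions whose
restricted GPR died, plus all non-exchange reactions without GPR — are
swept in lexicographic id order, each removed when the current model
still grows on the reference condition without it.  Because removal
only shrinks the network, a candidate found essential once stays
essential against every later (smaller) model, so one sequential sweep
reaches the order-independent fixed point; the fixed candidate order
also makes the construction invariant to strain-list order.  Surviving
dead-GPR reactions are *isozyme exceptions*: kept with their full
template GPR (the non-conserved alternatives encoded as isozymes) and
flagged in the report.  If the finished core cannot grow, construction
fails listing the biomass precursors with zero maximal synthesis flux.
The default reference condition is aerobic pyruvate, the standard
benign condition for this kind of family analysis.

## Phenotyping and clustering

The phenotype matrix evaluates every model over a carbon ×
electron-acceptor grid under identical medium conventions; a compound a
model cannot exchange scores 0 (no growth) rather than missing — the
grids are union sets over the family, and "cannot even transport it" is
itself a phenotype.  Clustering is agglomerative on euclidean distances
between binary model profiles (gene-content or phenotype columns).  The
distance metric is the scientifically meaningful choice; the linkage is
not pinned by the analysis and defaults to average linkage,
configurable.  Model columns are sorted lexicographically before
clustering so tie-breaks are deterministic.  Dendrograms export to
Newick with branch lengths derived from merge heights.  Only topology
(merge order) should be interpreted across datasets — branch heights at
these profile sizes shift with small content changes.

## Gene-aligned network comparison

Candidates are ortholog groups functional in *both* models; deleting a
group removes all member genes from each model simultaneously.  Genes
unique to one model are reported by the alignment instead — deleting
them is a no-op in the other model and would manufacture trivial
differences.  The engine exhaustively enumerates deletion sets of size
1 and 2 (larger k is refused: enumeration is the exactness guarantee at
this scope) with the memoized FBA cache, reporting sets where exactly
one model grows, annotated with the biomass-flux difference; pairs
containing an already-separating single are excluded (minimality).  A
bilevel-optimization engine is unnecessary at these problem sizes —
enumeration is exact and fast — and is deliberately not provided.

Classification of a hit (non-growing model N, growing model G), checks
in order:

1. **genetic** — some reaction disabled by the deletion in N is present
   and still active in G (extra isozymes/subunits in G's GPR);
2. **biomass** — the set of N's biomass precursors whose synthesis the
   deletion blocks (maximal sink flux per precursor drops from positive
   to zero) is non-empty and disjoint from G's biomass composition;
3. **metabolic** — otherwise: the same reactions go down in both
   networks and G reroutes through an alternative pathway.

The per-precursor sink-FBA operationalizes the biomass check; producible
status is compared against the undeleted model so pre-existing blocked
precursors cannot masquerade as the mechanism.  Across a family, the
pairwise results are pooled per victim model and deduplicated by
deletion set; a set explained differently against different partners
(e.g. genetic vs. one strain, biomass vs. the core) carries multiple
labels but counts once in the total.  Subsystem mapping tallies, per
condition, the distinct reactions of the victim model whose GPR contains
a deleted gene.

## Fitness evaluation

Replicate experiments mapping to one simulatable condition are combined
by majority vote at cutoff −3.5 (growth above, no growth below); exact
ties are *undetermined* and excluded from scoring.  A score exactly at
the cutoff counts as growth: the rule is strict on both sides, equality
must land somewhere, and the choice is recorded here.  Scoring uses the
convention: false positive = model predicts growth, data says no
growth; false negative = the opposite; accuracy + FP% + FN% = 100% of
compared calls.  The experiment-to-condition mapping is an input file
with an include flag (stationary-phase, saturated or rich-supplement
experiments are excluded by flag, never inferred from names).  Note the
limit behaviour: a cutoff below all scores eliminates no-growth calls
and hence false *positives*; a cutoff above all scores eliminates false
*negatives*.

Growth curves: rate = least-squares slope of ln(OD) vs. time on an
explicit window or, by default, the maximal-slope sliding window
covering 30% of the readings (≥3 points, OD must be positive); yield =
(stationary OD − starting OD)/substrate mmol, with the stationary level
taken as the mean of the trailing 20% of readings, which must vary by
less than 2% of the curve's range (no plateau → error).

## Synthetic data

The generator emulates the three real inputs at toy scale.  The
template (default ≈44 reactions, ≈30 genes) has deliberate structure:
carbon uptake → linear backbone → four biomass precursors (one
consuming ammonia, one phosphate); a dehydrogenase branch producing
redox cofactor re-oxidized by either an O2 or a nitrate respiration
branch (ATP cycling against biomass and a zero-demand maintenance
reaction); and dead-end secretion branches for non-essential padding,
some without GPR.  GPRs are assigned randomly as singletons, AND pairs
or OR pairs at configurable fractions.  On the designated aerobic
condition the optimum is analytic — 6 carbons per unit biomass, so
uptake 10 gives μ = 10/6 — which every generated template is verified
to attain.

Families apply group-wise gene loss per strain against a one-gene-per-
group ortholog table, with two deliberate constraints:

* **viable isolates** — a sampled loss that would abolish growth on the
  designated condition is rejected, so divergence accumulates in
  dispensable content (alternative respiration, side branches), the way
  real strain families that all grow on the reference condition differ.
  Unconstrained loss kills most random strains and makes every
  downstream comparison vacuous.  Planted (forced) losses bypass the
  check.
* **joint complex loss** — both genes of an AND complex form one loss
  unit.  A half-lost complex would strand a conserved subunit in a dead
  reaction and break the clean "core genes = cross-strain intersection"
  property that the tests rely on.

Lost genes are occasionally recorded as pseudogene fragments (`^`)
rather than absent cells, exercising the pseudogene path.  Family
members are produced by the same derivation routine users run, so
generator and deriver agree by construction; tests close the loop
through the *written* table file.

Planted differences modify an otherwise identical pair: *genetic* adds
a private isozyme in one model on an essential backbone step driven by
a fresh shared gene; *biomass* adds a shared-gene synthesis reaction
for a new compound required only by one model's biomass; *metabolic*
adds a private two-step bypass around the shared-gene step.  In each
case exactly one ortholog-group deletion separates the pair, with the
expected victim and label returned as ground truth.

Simulated fitness draws replicate z-scores from Normal(0, σ) for
mutants whose knockout grows and Normal(−6, σ) otherwise; −6 puts the
−3.5 cutoff between the modes so the cutoff's *semantics* (not the real
compendium's score distribution) are what is emulated.  Defaults σ = 1,
3 replicates.

**What passing synthetic tests does not show.**  The toy networks have
no thermodynamic constraints, no cofactor promiscuity, no regulation,
and essentiality ground truth is by construction FBA-consistent; real
fitness data disagree with FBA for biological reasons (regulation,
media composition, polar effects) that no cutoff recovers.  Synthetic
recovery rates are therefore upper bounds, and genome-scale accuracy
claims require the real compendium and its experiment mapping.

## Verification scales and numerics

The acceptance run (`scripts/acceptance.py`) uses 20 seeded templates
for the independent-LP cross-check (cobrapy + GLPK loading the
package's own SBML output; agreement within 1e-6), six planted
differences (3 kinds × 2 seeds), one ~27-group pair for the k≤2
brute-force comparison (~330 deletion sets), ~50 gene×condition pairs
for fitness recovery, and a four-strain family for the core
properties — sizes chosen so the whole run completes in seconds while
every check still exercises the non-trivial structure (isozymes,
complexes, alternative branches).  LP tolerances: mass-balance residual
and bound violations ≤1e-6 on optimal solutions; biomass-precursor
producibility probes use a 1e-9 flux floor.
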