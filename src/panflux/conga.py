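"""Gene-aligned comparison of metabolic networks (CONGA-style).

Two strain models are aligned at the gene level through an ortholog
table, and the comparison searches for ortholog deletion sets that leave
exactly one model able to grow — i.e., knockouts with the largest
possible biomass-flux difference between the networks.  Each hit is then
explained by one of three mechanisms:

* **genetic** — the same reaction survives the deletion in one model
  because its GPR has extra isozymes or subunits there;
* **biomass** — the deletions block the synthesis of compounds that only
  one model's biomass reaction requires;
* **metabolic** — the same reactions are disabled in both models, but
  one network reroutes through an alternative pathway.

The default engine is exhaustive enumeration over shared ortholog groups
(size 1 and 2 deletion sets) with memoized FBA, which is exact at these
set sizes; results are minimal (no reported set contains another).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from . import gpr as gpr_mod
from .fba import (
    FbaCache,
    GrowthCondition,
    MediumSpec,
    WildtypeNoGrowthError,
    GROWTH_THRESHOLD,
    maximize_growth,
    set_medium,
)
from .model import MetabolicModel, Reaction, apply_gene_deletions
from .orthologs import OrthologTable

__all__ = [
    "GeneAlignment",
    "CongaResult",
    "align_genes",
    "find_deletion_sets",
    "classify_difference",
    "summarize_unique_lethal",
    "map_to_subsystems",
]

BIOMASS = "biomass"
METABOLIC = "metabolic"
GENETIC = "genetic"


@dataclass
class GeneAlignment:
    """Partition of two models' gene sets through the ortholog table."""

    shared_groups: List[str]
    unique_a: FrozenSet[str]
    unique_b: FrozenSet[str]


def align_genes(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    table: OrthologTable,
) -> GeneAlignment:
    """Shared ortholog groups and per-model unique genes.

    Model ids must match strain columns of the table.  Pseudogenes are
    functionally absent and cannot make a group shared.
    """
    for model in (model_a, model_b):
        if model.id not in table.strains:
            raise KeyError(f"strain {model.id!r} not in ortholog table")
    g2g_a = table.gene_to_group(model_a.id)
    g2g_b = table.gene_to_group(model_b.id)
    groups_a = {g2g_a[g] for g in model_a.genes if g in g2g_a}
    groups_b = {g2g_b[g] for g in model_b.genes if g in g2g_b}
    shared = sorted(groups_a & groups_b)
    shared_set = set(shared)
    unique_a = frozenset(
        g for g in model_a.genes if g2g_a.get(g) not in shared_set
    )
    unique_b = frozenset(
        g for g in model_b.genes if g2g_b.get(g) not in shared_set
    )
    return GeneAlignment(shared_groups=shared, unique_a=unique_a, unique_b=unique_b)


@dataclass
class CongaResult:
    """A deletion set that separates the two models' growth outcomes."""

    deletion_set: FrozenSet[str]  # ortholog group ids
    condition: GrowthCondition
    model_a: str
    model_b: str
    grows_a: bool
    grows_b: bool
    objective_a: float
    objective_b: float
    classifications: Set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.grows_a == self.grows_b:
            raise ValueError("a CONGA result must separate the growth outcomes")

    @property
    def flux_difference(self) -> float:
        return abs(self.objective_a - self.objective_b)

    @property
    def lethal_in(self) -> str:
        return self.model_b if self.grows_a else self.model_a


def _group_genes(table: OrthologTable, strain: str, groups) -> FrozenSet[str]:
    out: Set[str] = set()
    for gid in groups:
        out.update(table.functional_members(gid, strain))
    return frozenset(out)


def find_deletion_sets(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    table: OrthologTable,
    condition: GrowthCondition,
    k: int = 1,
    spec: MediumSpec = MediumSpec(),
) -> List[CongaResult]:
    """All minimal shared-ortholog deletion sets (size <= k) separating growth.

    Deleting a group removes all of its member genes from both models
    simultaneously — the gene-aligned knockout.  Only groups present in
    both models are candidates; genes unique to one model trivially
    create differences and are reported by :func:`align_genes` instead.
    Exhaustive enumeration with memoized FBA; ``k`` beyond 2 is refused.
    Raises :class:`WildtypeNoGrowthError` when either wildtype cannot
    grow (the condition is excluded from comparison).
    """
    if k not in (1, 2):
        raise ValueError("enumeration supports deletion sets of size 1 or 2")
    alignment = align_genes(model_a, model_b, table)
    cache_a = FbaCache(model_a, condition, spec)
    cache_b = FbaCache(model_b, condition, spec)
    for model, cache in ((model_a, cache_a), (model_b, cache_b)):
        if cache.objective(frozenset()) <= GROWTH_THRESHOLD:
            raise WildtypeNoGrowthError(
                f"wildtype {model.id!r} does not grow under {condition.label}; "
                "condition excluded from comparison"
            )

    def outcome(groups: FrozenSet[str]) -> Tuple[bool, float, bool, float]:
        genes_a = _group_genes(table, model_a.id, groups)
        genes_b = _group_genes(table, model_b.id, groups)
        obj_a = cache_a.objective(genes_a)
        obj_b = cache_b.objective(genes_b)
        return (obj_a > GROWTH_THRESHOLD, obj_a, obj_b > GROWTH_THRESHOLD, obj_b)

    results: List[CongaResult] = []
    separating_singles: Set[str] = set()
    for gid in alignment.shared_groups:
        grows_a, obj_a, grows_b, obj_b = outcome(frozenset([gid]))
        if grows_a != grows_b:
            separating_singles.add(gid)
            results.append(CongaResult(
                deletion_set=frozenset([gid]), condition=condition,
                model_a=model_a.id, model_b=model_b.id,
                grows_a=grows_a, grows_b=grows_b,
                objective_a=obj_a, objective_b=obj_b,
            ))
    if k == 2:
        candidates = [g for g in alignment.shared_groups
                      if g not in separating_singles]
        for g1, g2 in itertools.combinations(candidates, 2):
            pair = frozenset([g1, g2])
            grows_a, obj_a, grows_b, obj_b = outcome(pair)
            if grows_a != grows_b:
                results.append(CongaResult(
                    deletion_set=pair, condition=condition,
                    model_a=model_a.id, model_b=model_b.id,
                    grows_a=grows_a, grows_b=grows_b,
                    objective_a=obj_a, objective_b=obj_b,
                ))
    return results


def _producible_components(
    model: MetabolicModel,
    condition: GrowthCondition,
    deleted_genes,
    spec: MediumSpec,
) -> FrozenSet[str]:
    """Biomass precursors with positive maximal synthesis flux."""
    constrained = set_medium(apply_gene_deletions(model, deleted_genes),
                             condition, spec)
    producible = set()
    for met in constrained.biomass_components():
        sink = Reaction(id=f"DM_{met}__probe", stoichiometry={met: -1.0},
                        lower_bound=0.0, upper_bound=1000.0)
        probe = constrained.with_reaction(sink)
        sol = maximize_growth(probe, objective_reaction=sink.id)
        if sol.optimal and sol.objective > 1e-9:
            producible.add(met)
    return frozenset(producible)


def classify_difference(
    result: CongaResult,
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    table: OrthologTable,
    spec: MediumSpec = MediumSpec(),
) -> Set[str]:
    """Explain why the deletion set kills one model but not the other.

    With the non-growing model called N and the growing model G, the
    checks run in order:

    1. *genetic* — some reaction disabled by the deletions in N is still
       active in G (its GPR survives there via extra isozymes/subunits);
    2. *biomass* — every biomass precursor of N whose synthesis the
       deletions block is absent from G's biomass composition;
    3. *metabolic* — otherwise: the same reactions go down in both
       networks and G reroutes through an alternative pathway.
    """
    if result.grows_a == result.grows_b:
        raise ValueError("result does not separate the models")
    models = {model_a.id: model_a, model_b.id: model_b}
    grower = models[result.model_a if result.grows_a else result.model_b]
    nongrower = models[result.lethal_in]

    del_grow = _group_genes(table, grower.id, result.deletion_set)
    del_non = _group_genes(table, nongrower.id, result.deletion_set)

    def disabled(model: MetabolicModel, deleted) -> Set[str]:
        return {
            r.id for r in model.reactions.values()
            if r.gpr is not None and not gpr_mod.evaluate(r.gpr, deleted)
        }

    disabled_non = disabled(nongrower, del_non)
    disabled_grow = disabled(grower, del_grow)
    surviving = {
        rid for rid in disabled_non
        if rid in grower.reactions and rid not in disabled_grow
    }
    if surviving:
        label = GENETIC
    else:
        wt_producible = _producible_components(nongrower, result.condition,
                                               frozenset(), spec)
        del_producible = _producible_components(nongrower, result.condition,
                                                del_non, spec)
        blocked = wt_producible - del_producible
        grower_components = grower.biomass_components()
        if blocked and not (blocked & grower_components):
            label = BIOMASS
        else:
            label = METABOLIC
    result.classifications.add(label)
    return {label}


def summarize_unique_lethal(
    models: Sequence[MetabolicModel],
    table: OrthologTable,
    condition: GrowthCondition,
    k: int = 1,
    spec: MediumSpec = MediumSpec(),
) -> Tuple[pd.DataFrame, List[CongaResult]]:
    """Per-model counts of deletion sets lethal there but viable elsewhere.

    Runs the pairwise comparison over every pair of models that grow
    under *condition* (non-growing wildtypes are excluded, as the
    comparison is undefined for them), groups results by the non-growing
    model, deduplicates by deletion set, and splits counts by
    classification.  A set explained differently against different
    partners contributes to each label it received, but only once to the
    total.

    Returns the summary table (rows: model ids; columns: total and the
    three labels) and the full deduplicated result list.
    """
    growing = []
    for model in models:
        cache = FbaCache(model, condition, spec)
        if cache.objective(frozenset()) > GROWTH_THRESHOLD:
            growing.append(model)
    by_model: Dict[str, Dict[FrozenSet[str], Set[str]]] = {
        m.id: {} for m in growing
    }
    kept_results: Dict[Tuple[str, FrozenSet[str]], CongaResult] = {}
    for model_a, model_b in itertools.combinations(growing, 2):
        for result in find_deletion_sets(model_a, model_b, table, condition, k, spec):
            labels = classify_difference(result, model_a, model_b, table, spec)
            entry = by_model[result.lethal_in].setdefault(result.deletion_set, set())
            entry |= labels
            key = (result.lethal_in, result.deletion_set)
            if key not in kept_results:
                kept_results[key] = result
            else:
                kept_results[key].classifications |= labels
    rows = []
    for model in models:
        sets = by_model.get(model.id, {})
        rows.append({
            "model": model.id,
            "total": len(sets),
            BIOMASS: sum(1 for labels in sets.values() if BIOMASS in labels),
            METABOLIC: sum(1 for labels in sets.values() if METABOLIC in labels),
            GENETIC: sum(1 for labels in sets.values() if GENETIC in labels),
        })
    summary = pd.DataFrame(rows).set_index("model")
    return summary, list(kept_results.values())


def map_to_subsystems(
    results: Sequence[CongaResult],
    models: Mapping[str, MetabolicModel],
    table: OrthologTable,
) -> pd.DataFrame:
    """Tally unique reactions touched by deletion sets, per subsystem.

    For each result, the reactions of the non-growing model whose GPR
    contains a deleted gene are collected; each distinct reaction counts
    once per (subsystem, condition).  Returns a subsystem x condition
    table of counts.
    """
    touched: Dict[Tuple[str, str], Set[str]] = {}
    for result in results:
        model = models[result.lethal_in]
        deleted = _group_genes(table, model.id, result.deletion_set)
        for rxn in model.reactions.values():
            if rxn.genes & deleted:
                key = (rxn.subsystem or "(unassigned)", result.condition.label)
                touched.setdefault(key, set()).add(rxn.id)
    if not touched:
        return pd.DataFrame()
    records = [
        {"subsystem": subsystem, "condition": cond, "reactions": len(rids)}
        for (subsystem, cond), rids in touched.items()
    ]
    frame = pd.DataFrame(records)
    return frame.pivot_table(index="subsystem", columns="condition",
                             values="reactions", fill_value=0)
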