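"""In-memory constraint-based metabolic models.

A :class:`MetabolicModel` holds metabolites, reactions with stoichiometry,
flux bounds (mmol/gAFDW/h) and GPR associations, and a designated biomass
pseudo-reaction whose flux is the growth rate.  Content-comparison
operations (pairwise diffs against a reference, multi-way shared-content
Venn regions) work on reaction ids directly and on genes through an
optional ortholog map so that models from different strains can be
compared gene-by-gene.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import gpr as gpr_mod
from .gpr import OptionalGpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelDiff",
    "apply_gene_deletions",
    "model_diff",
    "shared_content",
    "venn_table",
]


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None

    def __post_init__(self):
        if not self.compartment:
            raise ValueError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction.  Reactant coefficients are negative."""

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: OptionalGpr = None
    name: str = ""
    subsystem: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions touch exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> frozenset:
        return gpr_mod.genes(self.gpr)

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


class MetabolicModel:
    """A genome-scale (or toy) metabolic model.

    The gene set is derived, not stored: it is the union of GPR leaves
    over all reactions.
    """

    def __init__(
        self,
        id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction_id: str,
    ) -> None:
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise ValueError(f"duplicate metabolite id {m.id!r}")
            self.metabolites[m.id] = m
        self.reactions: Dict[str, Reaction] = {}
        for r in reactions:
            if r.id in self.reactions:
                raise ValueError(f"duplicate reaction id {r.id!r}")
            for met_id in r.stoichiometry:
                if met_id not in self.metabolites:
                    raise ValueError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
            self.reactions[r.id] = r
        if biomass_reaction_id not in self.reactions:
            raise ValueError(
                f"biomass reaction {biomass_reaction_id!r} not in model {id!r}"
            )
        self.biomass_reaction_id = biomass_reaction_id

    # -- derived views ---------------------------------------------------

    @property
    def genes(self) -> frozenset:
        out = set()
        for r in self.reactions.values():
            out |= r.genes
        return frozenset(out)

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reactions[self.biomass_reaction_id]

    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def biomass_components(self) -> frozenset:
        """Metabolite ids consumed by the biomass reaction."""
        return frozenset(
            m for m, coef in self.biomass_reaction.stoichiometry.items() if coef < 0
        )

    # -- copies and edits ------------------------------------------------

    def copy(self, id: Optional[str] = None) -> "MetabolicModel":
        return MetabolicModel(
            id=id or self.id,
            metabolites=self.metabolites.values(),
            reactions=self.reactions.values(),
            biomass_reaction_id=self.biomass_reaction_id,
        )

    def with_reaction(self, reaction: Reaction) -> "MetabolicModel":
        """Copy with *reaction* added or replaced."""
        reactions = dict(self.reactions)
        reactions[reaction.id] = reaction
        return MetabolicModel(
            self.id, self.metabolites.values(), reactions.values(),
            self.biomass_reaction_id,
        )

    def without_reactions(self, reaction_ids) -> "MetabolicModel":
        drop = set(reaction_ids)
        if self.biomass_reaction_id in drop:
            raise ValueError("cannot remove the biomass reaction")
        kept = [r for r in self.reactions.values() if r.id not in drop]
        return MetabolicModel(
            self.id, self.metabolites.values(), kept, self.biomass_reaction_id
        )

    def content_equal(self, other: "MetabolicModel") -> bool:
        """Structural equality: same metabolites, reactions, bounds, GPRs."""
        return (
            self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.biomass_reaction_id == other.biomass_reaction_id
        )

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes>"
        )


def apply_gene_deletions(model: MetabolicModel, deleted_genes) -> MetabolicModel:
    """Close every reaction whose GPR is not satisfiable without *deleted_genes*.

    Returns a new model with both bounds of affected reactions set to 0;
    the input model is not mutated.  Gene ids absent from the model are
    silently ignored (deleting a gene a strain does not have is a no-op).
    """
    deleted = frozenset(deleted_genes)
    reactions = []
    for r in model.reactions.values():
        if r.gpr is not None and not gpr_mod.evaluate(r.gpr, deleted):
            reactions.append(r.with_bounds(0.0, 0.0))
        else:
            reactions.append(r)
    return MetabolicModel(
        model.id, model.metabolites.values(), reactions, model.biomass_reaction_id
    )


@dataclass
class ModelDiff:
    """Content differences of a model relative to a reference model."""

    reactions_lost: frozenset
    reactions_gained: frozenset
    genes_lost: frozenset
    genes_gained: frozenset

    def __post_init__(self):
        for lost, gained in (
            (self.reactions_lost, self.reactions_gained),
            (self.genes_lost, self.genes_gained),
        ):
            if lost & gained:
                raise ValueError("lost and gained sets overlap")


def model_diff(
    reference: MetabolicModel,
    other: MetabolicModel,
    ortholog_map: Optional[Mapping[str, Sequence[str]]] = None,
) -> ModelDiff:
    """Reactions and genes lost/gained in *other* relative to *reference*.

    Reaction identity is by id.  Gene identity is by id unless
    *ortholog_map* translates reference gene ids into the other strain's
    namespace (a reference gene is "retained" if any of its orthologs is
    in the other model; an other-strain gene is "gained" if it is not an
    ortholog of any reference gene).
    """
    ref_rxns = frozenset(reference.reactions)
    oth_rxns = frozenset(other.reactions)
    ref_genes = reference.genes
    oth_genes = other.genes

    if ortholog_map is None:
        genes_lost = ref_genes - oth_genes
        genes_gained = oth_genes - ref_genes
    else:
        genes_lost = frozenset(
            g for g in ref_genes
            if not (set(ortholog_map.get(g, ())) & oth_genes)
        )
        mapped = set()
        for g in ref_genes:
            mapped |= set(ortholog_map.get(g, ()))
        genes_gained = oth_genes - mapped
    return ModelDiff(
        reactions_lost=ref_rxns - oth_rxns,
        reactions_gained=oth_rxns - ref_rxns,
        genes_lost=genes_lost,
        genes_gained=genes_gained,
    )


def shared_content(
    models: Sequence[MetabolicModel],
    gene_groups: Optional[Mapping[str, Mapping[str, str]]] = None,
    include_exchanges: bool = False,
) -> Dict[str, Dict[frozenset, int]]:
    """Venn-region counts of shared reactions and genes across models.

    For every non-empty subset of model ids, counts the reactions (by id,
    excluding exchange reactions unless *include_exchanges*) and genes
    present in exactly that subset of models.  Gene identity is taken
    through *gene_groups* when given: a mapping ``model id -> {gene id ->
    group id}``; genes then count as ortholog groups, so the same group
    present in two strains under different locus tags is shared.  The
    disjoint regions partition each union, so region counts sum to the
    union size.

    Returns ``{"reactions": {subset: count}, "genes": {subset: count}}``
    with subsets as frozensets of model ids.
    """
    if not models:
        raise ValueError("need at least one model")

    def regions(memberships: Mapping[str, frozenset]) -> Dict[frozenset, int]:
        # memberships: model id -> set of item keys
        out: Dict[frozenset, int] = {}
        all_items = set().union(*memberships.values()) if memberships else set()
        for item in all_items:
            subset = frozenset(m for m, items in memberships.items() if item in items)
            out[subset] = out.get(subset, 0) + 1
        return out

    rxn_members = {}
    gene_members = {}
    for model in models:
        rxns = frozenset(
            r.id for r in model.reactions.values()
            if include_exchanges or not r.is_exchange
        )
        rxn_members[model.id] = rxns
        if gene_groups is not None:
            g2g = gene_groups.get(model.id, {})
            gene_members[model.id] = frozenset(
                g2g.get(g, g) for g in model.genes
            )
        else:
            gene_members[model.id] = model.genes
    return {"reactions": regions(rxn_members), "genes": regions(gene_members)}


def venn_table(regions: Mapping[frozenset, int], model_ids: Sequence[str]):
    """Flatten Venn regions into rows of (per-model membership flags, count).

    Returns a list of tuples ``(tuple of 0/1 flags in *model_ids* order,
    count)`` sorted by descending subset size, for TSV export.
    """
    rows = []
    for subset, count in regions.items():
        flags = tuple(1 if m in subset else 0 for m in model_ids)
        rows.append((flags, count))
    rows.sort(key=lambda row: (-sum(row[0]), row[0]))
    return rows
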