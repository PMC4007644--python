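"""Flux balance analysis with comparative-study medium conventions.

FBA solves the linear program

    max  v_biomass
    s.t. S v = 0          (steady-state mass balance)
         lb <= v <= ub    (flux capacity / medium bounds)

where S is the stoichiometric matrix and v the flux vector in
mmol/gAFDW/h.  The LP is handed to scipy's HiGHS solver.

The medium conventions applied by :func:`set_medium` match simulations
designed for cross-strain comparability: the chosen carbon source and
electron acceptor get an uptake bound of 10 mmol/gAFDW/h, freely
available inorganic compounds (phosphate, sulfate, water, proton, and
ammonia when it is the nitrogen source) are unconstrained at 1000, every
other exchange is closed for uptake, all secretion is open at 1000, and
both growth- and non-growth-associated ATP maintenance are set to zero
(maintenance parameters fitted for one strain do not transfer to its
relatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .model import MetabolicModel, Reaction, apply_gene_deletions

__all__ = [
    "GrowthCondition",
    "MediumSpec",
    "FluxSolution",
    "NotRepresentableError",
    "SolverError",
    "WildtypeNoGrowthError",
    "GROWTH_THRESHOLD",
    "set_medium",
    "maximize_growth",
    "is_growth",
    "deletion_grows",
    "essential_genes",
    "find_exchange",
    "FbaCache",
]

#: Biomass flux above this counts as growth.  Growth is defined
#: qualitatively (positive vs. zero growth rate); the threshold absorbs
#: LP solver noise.
GROWTH_THRESHOLD = 1e-6

UPTAKE_BOUND = 10.0
FREE_BOUND = 1000.0
SECRETION_BOUND = 1000.0


class NotRepresentableError(ValueError):
    """A named condition compound has no exchange reaction in the model."""

    def __init__(self, compound: str, model_id: str):
        self.compound = compound
        super().__init__(
            f"compound {compound!r} has no exchange reaction in model {model_id!r}"
        )


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


class WildtypeNoGrowthError(ValueError):
    """Essentiality is undefined when the wildtype does not grow."""


@dataclass(frozen=True)
class GrowthCondition:
    """A growth medium: carbon source x electron acceptor x nitrogen source.

    Compound names are resolved against the model's exchange reactions
    (``None`` means the nutrient class is withheld entirely).  ``aerobic``
    is a convenience flag derived from the electron acceptor.
    """

    carbon_source: Optional[str]
    electron_acceptor: Optional[str]
    nitrogen_source: str = "nh4"

    @property
    def aerobic(self) -> bool:
        return self.electron_acceptor is not None and (
            self.electron_acceptor.lower() in ("o2", "oxygen")
        )

    @property
    def label(self) -> str:
        return (
            f"{self.carbon_source or 'none'}|{self.electron_acceptor or 'none'}"
            f"|{self.nitrogen_source}"
        )


@dataclass(frozen=True)
class MediumSpec:
    """Configurable knobs of the medium convention.

    ``free_compounds`` are opened at the free bound whenever the model can
    exchange them; compounds a model lacks are skipped (only the carbon,
    acceptor and nitrogen compounds must be representable).
    ``atp_maintenance_ids`` lists reaction ids whose lower bound encodes
    non-growth-associated ATP demand; it is forced to zero.
    ``aliases`` maps condition compound names to metabolite ids for
    dialects whose exchange metabolites use different identifiers.
    """

    free_compounds: Tuple[str, ...] = ("pi", "so4", "h2o", "h")
    atp_maintenance_ids: Tuple[str, ...] = ("ATPM",)
    uptake_bound: float = UPTAKE_BOUND
    free_bound: float = FREE_BOUND
    secretion_bound: float = SECRETION_BOUND
    aliases: Mapping[str, str] = field(default_factory=dict)


def find_exchange(model: MetabolicModel, compound: str,
                  aliases: Optional[Mapping[str, str]] = None) -> Optional[str]:
    """Resolve a compound name to the id of its exchange reaction.

    Matches the exchange reaction's single metabolite by id (with or
    without a trailing compartment suffix such as ``_e``), by name, or
    through the alias map; matching is case-insensitive.
    """
    wanted = {compound.lower()}
    if aliases and compound in aliases:
        wanted.add(aliases[compound].lower())
    for rxn in model.reactions.values():
        if not rxn.is_exchange:
            continue
        (met_id,) = rxn.stoichiometry
        met = model.metabolites[met_id]
        candidates = {met_id.lower(), met.name.lower()}
        stem = met_id.lower()
        if "_" in stem:
            candidates.add(stem.rsplit("_", 1)[0])
        if candidates & wanted:
            return rxn.id
    return None


def set_medium(
    model: MetabolicModel,
    condition: GrowthCondition,
    spec: MediumSpec = MediumSpec(),
) -> MetabolicModel:
    """Return a copy of *model* with exchange bounds set for *condition*.

    Idempotent: the bounds depend only on (model content, condition,
    spec), not on the bounds the model arrived with.
    """
    new_bounds: Dict[str, Tuple[float, float]] = {}
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            new_bounds[rxn.id] = (0.0, spec.secretion_bound)

    def open_exchange(compound: str, bound: float, required: bool) -> None:
        ex_id = find_exchange(model, compound, spec.aliases)
        if ex_id is None:
            if required:
                raise NotRepresentableError(compound, model.id)
            return
        new_bounds[ex_id] = (-bound, spec.secretion_bound)

    if condition.carbon_source is not None:
        open_exchange(condition.carbon_source, spec.uptake_bound, required=True)
    if condition.electron_acceptor is not None:
        open_exchange(condition.electron_acceptor, spec.uptake_bound, required=True)
    open_exchange(condition.nitrogen_source, spec.free_bound, required=True)
    for compound in spec.free_compounds:
        if compound.lower() == condition.nitrogen_source.lower():
            continue
        open_exchange(compound, spec.free_bound, required=False)

    reactions = []
    for rxn in model.reactions.values():
        if rxn.id in new_bounds:
            lb, ub = new_bounds[rxn.id]
            reactions.append(rxn.with_bounds(lb, ub))
        elif rxn.id in spec.atp_maintenance_ids:
            # zero both maintenance demands: NGAM enters as the reaction's
            # forced lower bound, GAM would enter via this same flux
            reactions.append(rxn.with_bounds(0.0, rxn.upper_bound))
        else:
            reactions.append(rxn)
    return MetabolicModel(
        model.id, model.metabolites.values(), reactions, model.biomass_reaction_id
    )


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible"
    objective: float
    fluxes: Dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def maximize_growth(model: MetabolicModel,
                    objective_reaction: Optional[str] = None) -> FluxSolution:
    """Maximize flux through the biomass (or a named) reaction.

    The medium must already be applied.  Infeasible LPs are reported as
    ``status="infeasible"`` with objective 0; other solver failures raise
    :class:`SolverError`.
    """
    rxn_ids = list(model.reactions)
    met_ids = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    n, m = len(rxn_ids), len(met_ids)

    S = lil_matrix((m, n))
    lb = np.empty(n)
    ub = np.empty(n)
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
        for met, coef in rxn.stoichiometry.items():
            S[met_index[met], j] = coef

    target = objective_reaction or model.biomass_reaction_id
    if target not in model.reactions:
        raise KeyError(f"objective reaction {target!r} not in model {model.id!r}")
    c = np.zeros(n)
    c[rxn_ids.index(target)] = -1.0  # linprog minimizes

    res = linprog(
        c,
        A_eq=S.tocsr(),
        b_eq=np.zeros(m),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:  # infeasible
        return FluxSolution(status="infeasible", objective=0.0, fluxes={})
    if not res.success:
        raise SolverError(
            f"LP solve failed for model {model.id!r} (objective {target!r}): "
            f"{res.message}"
        )
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxSolution(status="optimal", objective=-res.fun, fluxes=fluxes)


def is_growth(solution: FluxSolution, threshold: float = GROWTH_THRESHOLD) -> bool:
    """Qualitative growth call: optimal solution with positive biomass flux."""
    return solution.optimal and solution.objective > threshold


def deletion_grows(
    model: MetabolicModel,
    deleted_genes,
    condition: GrowthCondition,
    spec: MediumSpec = MediumSpec(),
    threshold: float = GROWTH_THRESHOLD,
) -> bool:
    """Does the model still grow after deleting *deleted_genes*?"""
    constrained = set_medium(apply_gene_deletions(model, deleted_genes), condition, spec)
    return is_growth(maximize_growth(constrained), threshold)


class FbaCache:
    """Memoizes growth outcomes by the set of reactions a deletion closes.

    Distinct gene deletion sets frequently close the same reactions (all
    subunits of a complex, for example); the LP then only needs solving
    once per closed-reaction signature.
    """

    def __init__(self, model: MetabolicModel, condition: GrowthCondition,
                 spec: MediumSpec = MediumSpec(),
                 threshold: float = GROWTH_THRESHOLD):
        self.base = set_medium(model, condition, spec)
        self.threshold = threshold
        self._cache: Dict[FrozenSet[str], float] = {}
        # precompute, per gene, the reactions it can possibly affect
        self._gene_reactions: Dict[str, Set[str]] = {}
        for rxn in self.base.reactions.values():
            for g in rxn.genes:
                self._gene_reactions.setdefault(g, set()).add(rxn.id)

    def closed_reactions(self, deleted_genes) -> FrozenSet[str]:
        from . import gpr as gpr_mod

        deleted = frozenset(deleted_genes)
        touched = set()
        for g in deleted:
            touched |= self._gene_reactions.get(g, set())
        closed = frozenset(
            rid for rid in touched
            if not gpr_mod.evaluate(self.base.reactions[rid].gpr, deleted)
        )
        return closed

    def objective_for_closed(self, closed: FrozenSet[str]) -> float:
        if closed not in self._cache:
            reactions = [
                r.with_bounds(0.0, 0.0) if r.id in closed else r
                for r in self.base.reactions.values()
            ]
            sub = MetabolicModel(
                self.base.id, self.base.metabolites.values(), reactions,
                self.base.biomass_reaction_id,
            )
            self._cache[closed] = maximize_growth(sub).objective
        return self._cache[closed]

    def grows(self, deleted_genes) -> bool:
        return (
            self.objective_for_closed(self.closed_reactions(deleted_genes))
            > self.threshold
        )

    def objective(self, deleted_genes) -> float:
        return self.objective_for_closed(self.closed_reactions(deleted_genes))


def essential_genes(
    model: MetabolicModel,
    condition: GrowthCondition,
    set_size: int = 1,
    spec: MediumSpec = MediumSpec(),
    threshold: float = GROWTH_THRESHOLD,
) -> Set[FrozenSet[str]]:
    """All minimal gene sets of *set_size* whose deletion abolishes growth.

    ``set_size=1`` returns lethal single genes; ``set_size=2`` returns
    synthetic-lethal pairs, excluding supersets of lethal singles (the
    results are minimal sets).  Raises :class:`WildtypeNoGrowthError`
    if the wildtype itself cannot grow under *condition*.
    """
    if set_size not in (1, 2):
        raise ValueError("set_size must be 1 or 2")
    cache = FbaCache(model, condition, spec, threshold)
    if cache.objective(frozenset()) <= threshold:
        raise WildtypeNoGrowthError(
            f"model {model.id!r} does not grow under {condition.label}; "
            "essentiality is undefined"
        )
    genes = sorted(model.genes)
    lethal_singles = {
        frozenset([g]) for g in genes if not cache.grows(frozenset([g]))
    }
    if set_size == 1:
        return lethal_singles
    lethal_flat = {g for s in lethal_singles for g in s}
    pairs = set()
    viable = [g for g in genes if g not in lethal_flat]
    for i, g1 in enumerate(viable):
        for g2 in viable[i + 1:]:
            pair = frozenset([g1, g2])
            if not cache.grows(pair):
                pairs.add(pair)
    return pairs
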