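"""Template-based strain-model derivation and core-model construction.

A curated template model for a reference strain is projected onto a
related strain through an ortholog table: each template gene in a GPR is
replaced by its ortholog(s) in the target strain (co-orthologs become OR
alternatives), and reactions that lose all genetic support are removed.
Reactions with no gene association, exchanges, and the biomass reaction
carry over unchanged — curated biomass edits are supplied by the user,
not computed.

The core model keeps only content conserved across the whole strain
family, with two deliberate exceptions mirroring how minimal
pan-genus reconstructions are curated in practice:

* reactions without gene associations are kept only if individually
  essential for growth on a reference condition (aerobic pyruvate by
  default);
* a reaction whose every GPR path runs through non-conserved genes is
  kept anyway when it is essential, with the non-conserved alternatives
  encoded as OR-isozymes and flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import gpr as gpr_mod
from .fba import (
    FbaCache,
    GrowthCondition,
    MediumSpec,
    NotRepresentableError,
    deletion_grows,
    is_growth,
    maximize_growth,
    set_medium,
)
from .model import MetabolicModel, Reaction
from .orthologs import OrthologTable

__all__ = [
    "DerivationReport",
    "CoreReport",
    "CoreConstructionError",
    "derive_strain_model",
    "detect_growth_conflicts",
    "build_core_model",
    "DEFAULT_CORE_CONDITION",
]

#: Reference condition for core-model essentiality filtering.
DEFAULT_CORE_CONDITION = GrowthCondition(carbon_source="pyr", electron_acceptor="o2")


@dataclass
class DerivationReport:
    """What happened while projecting a template onto a strain."""

    target_strain: str
    removed_reactions: List[Tuple[str, List[str]]] = field(default_factory=list)
    retained_non_gpr: List[str] = field(default_factory=list)
    conflicts: List[Tuple[GrowthCondition, bool, bool]] = field(default_factory=list)

    def __post_init__(self):
        removed = {rid for rid, _ in self.removed_reactions}
        if removed & set(self.retained_non_gpr):
            raise ValueError("a reaction cannot be both removed and retained")


class CoreConstructionError(RuntimeError):
    """The constructed core model cannot grow on the reference condition."""


def derive_strain_model(
    template: MetabolicModel,
    table: OrthologTable,
    target_strain: str,
    template_strain: Optional[str] = None,
) -> Tuple[MetabolicModel, DerivationReport]:
    """Project *template* onto *target_strain* through the ortholog table.

    Every GPR leaf gene is substituted by its functional ortholog(s) in
    the target strain; reactions whose translated GPR cannot be satisfied
    (all supporting genes missing or pseudogenized) are removed.
    Reactions without GPR, exchange reactions, and the biomass reaction
    are retained.  Self-derivation (target equals template strain) is the
    identity.
    """
    template_strain = template_strain or template.id
    if template_strain not in table.strains:
        raise KeyError(f"template strain {template_strain!r} not in ortholog table")
    if target_strain not in table.strains:
        raise KeyError(f"target strain {target_strain!r} not in ortholog table")

    if target_strain == template_strain:
        mapping = {g: [g] for g in template.genes}
    else:
        mapping = table.mapping(template_strain, target_strain)

    report = DerivationReport(target_strain=target_strain)
    kept: List[Reaction] = []
    for rxn in template.reactions.values():
        if rxn.gpr is None:
            kept.append(rxn)
            if not rxn.is_exchange and rxn.id != template.biomass_reaction_id:
                report.retained_non_gpr.append(rxn.id)
            continue
        translated = gpr_mod.translate(rxn.gpr, mapping)
        if translated is gpr_mod.ALWAYS_OFF:
            if rxn.is_exchange or rxn.id == template.biomass_reaction_id:
                # boundary and biomass stay even without genetic support
                kept.append(Reaction(
                    id=rxn.id, stoichiometry=rxn.stoichiometry,
                    lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
                    gpr=None, name=rxn.name, subsystem=rxn.subsystem,
                ))
            else:
                missing = sorted(
                    g for g in rxn.genes if not mapping.get(g)
                )
                report.removed_reactions.append((rxn.id, missing))
            continue
        if translated is gpr_mod.ALWAYS_ON:
            translated = None
        kept.append(Reaction(
            id=rxn.id, stoichiometry=rxn.stoichiometry,
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            gpr=translated, name=rxn.name, subsystem=rxn.subsystem,
        ))

    derived = MetabolicModel(
        id=target_strain,
        metabolites=template.metabolites.values(),
        reactions=kept,
        biomass_reaction_id=template.biomass_reaction_id,
    )
    return derived, report


def detect_growth_conflicts(
    model: MetabolicModel,
    observations: Sequence[Tuple[GrowthCondition, bool]],
    spec: MediumSpec = MediumSpec(),
) -> List[Tuple[GrowthCondition, bool, bool]]:
    """Conditions where FBA disagrees with observed growth/no-growth.

    Each conflict is reported as ``(condition, observed, predicted)``.
    Conditions the model cannot represent (no exchange for the named
    compound) predict no growth.  The conflicts flag candidates for
    manual curation; no gap-filling is attempted.
    """
    conflicts = []
    for condition, observed in observations:
        try:
            constrained = set_medium(model, condition, spec)
            predicted = is_growth(maximize_growth(constrained))
        except NotRepresentableError:
            predicted = False
        if predicted != observed:
            conflicts.append((condition, observed, predicted))
    return conflicts


@dataclass
class CoreReport:
    """Provenance of core-model construction decisions."""

    conserved_groups: List[str]
    removed_reactions: List[str]
    retained_non_gpr: List[str]
    isozyme_exceptions: List[Tuple[str, List[str]]]  # (reaction, non-conserved genes)


def build_core_model(
    template: MetabolicModel,
    table: OrthologTable,
    strains: Optional[Sequence[str]] = None,
    condition: GrowthCondition = DEFAULT_CORE_CONDITION,
    template_strain: Optional[str] = None,
    spec: MediumSpec = MediumSpec(),
    core_id: str = "core",
) -> Tuple[MetabolicModel, CoreReport]:
    """Build the conserved-content core model of a strain family.

    The gene set is the intersection of functional ortholog memberships
    across *strains* (all table strains by default).  Reactions keep
    their GPR restricted to conserved genes; reactions losing all
    support and reactions without GPR survive only when essential for
    growth on *condition*, the former flagged as isozyme exceptions.
    Construction is order invariant in the strain list and deterministic
    (removal candidates are tested in lexicographic id order).
    """
    template_strain = template_strain or template.id
    strains = sorted(strains if strains is not None else table.strains)
    if template_strain not in table.strains:
        raise KeyError(f"template strain {template_strain!r} not in ortholog table")

    conserved_groups = sorted(table.groups_conserved_in(strains))
    conserved_set = set(conserved_groups)
    gene_group = table.gene_to_group(template_strain)
    conserved_genes = {
        g for g in template.genes if gene_group.get(g) in conserved_set
    }

    keep: Dict[str, Reaction] = {}
    dead_gpr: Dict[str, Reaction] = {}
    empty_gpr: Dict[str, Reaction] = {}
    for rxn in template.reactions.values():
        if rxn.is_exchange or rxn.id == template.biomass_reaction_id:
            keep[rxn.id] = rxn
            continue
        if rxn.gpr is None:
            empty_gpr[rxn.id] = rxn
            continue
        restricted = gpr_mod.restrict(rxn.gpr, conserved_genes)
        if restricted is gpr_mod.ALWAYS_OFF:
            dead_gpr[rxn.id] = rxn  # may be rescued if essential
        else:
            if restricted is gpr_mod.ALWAYS_ON:
                restricted = None
            keep[rxn.id] = Reaction(
                id=rxn.id, stoichiometry=rxn.stoichiometry,
                lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
                gpr=restricted, name=rxn.name, subsystem=rxn.subsystem,
            )

    # Greedy essentiality sweep over removal candidates.  Removal only
    # shrinks the network, so a candidate found essential at any point
    # stays essential against every smaller model: one sweep reaches the
    # fixed point.
    candidates = {**dead_gpr, **empty_gpr}
    current: Dict[str, Reaction] = {**keep, **candidates}

    def grows(reactions: Dict[str, Reaction]) -> bool:
        trial = MetabolicModel(
            core_id, template.metabolites.values(), reactions.values(),
            template.biomass_reaction_id,
        )
        constrained = set_medium(trial, condition, spec)
        return is_growth(maximize_growth(constrained))

    removed: List[str] = []
    for rid in sorted(candidates):
        trial = {k: v for k, v in current.items() if k != rid}
        if grows(trial):
            current = trial
            removed.append(rid)

    retained_non_gpr = sorted(rid for rid in empty_gpr if rid in current)
    isozyme_exceptions = []
    for rid in sorted(dead_gpr):
        if rid in current:
            rxn = dead_gpr[rid]
            non_conserved = sorted(rxn.genes - conserved_genes)
            isozyme_exceptions.append((rid, non_conserved))
            # keep the full template GPR: the non-conserved alternatives
            # are encoded as isozymes of one another
            current[rid] = rxn

    core = MetabolicModel(
        id=core_id,
        metabolites=template.metabolites.values(),
        reactions=current.values(),
        biomass_reaction_id=template.biomass_reaction_id,
    )
    final = set_medium(core, condition, spec)
    solution = maximize_growth(final)
    if not is_growth(solution):
        blocked = _blocked_biomass_components(final)
        raise CoreConstructionError(
            f"core model cannot grow on {condition.label}; blocked biomass "
            f"components: {sorted(blocked)}"
        )
    report = CoreReport(
        conserved_groups=conserved_groups,
        removed_reactions=sorted(set(removed) | {
            rid for rid in dead_gpr if rid not in current
        }),
        retained_non_gpr=retained_non_gpr,
        isozyme_exceptions=isozyme_exceptions,
    )
    return core, report


def _blocked_biomass_components(constrained: MetabolicModel) -> List[str]:
    """Biomass precursors with zero maximal production flux."""
    blocked = []
    for met in sorted(constrained.biomass_components()):
        sink = Reaction(id=f"DM_{met}__probe", stoichiometry={met: -1.0},
                        lower_bound=0.0, upper_bound=1000.0)
        probe = constrained.with_reaction(sink)
        sol = maximize_growth(probe, objective_reaction=sink.id)
        if not sol.optimal or sol.objective <= 1e-9:
            blocked.append(met)
    return blocked
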