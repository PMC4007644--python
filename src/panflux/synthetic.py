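"""Seeded generators of toy strain families for end-to-end testing.

Real comparative reconstructions need curated genome-scale models, an
ortholog table across a genus, and a pooled-mutant fitness compendium.
The generators here emulate all three at toy scale so that every
pipeline stage — derivation, core construction, phenotyping, network
comparison, fitness evaluation — can be exercised deterministically
with known ground truth and no external data.

The template is a small but metabolically structured network: a carbon
source is taken up and processed through a linear backbone into biomass
precursors (one requiring nitrogen, one phosphate), redox cofactor
produced by a dehydrogenase branch is re-oxidized by either an aerobic
or an anaerobic respiration branch (two electron acceptors), ATP cycles
between synthesis and the biomass/maintenance demands, and dead-end
secretion branches pad the network with non-essential content.  GPRs
mix singleton genes, two-subunit AND complexes and two-gene OR
isozymes.  On the designated aerobic condition the optimal growth rate
has a closed form: six carbons are consumed per unit biomass (four for
precursors, two for ATP), so an uptake bound of 10 gives 10/6.

Strain families are made by group-wise gene loss against an ortholog
table; family members are produced by the same template-projection
routine users run, so generator and deriver agree by construction.
Gene pairs forming an AND complex are lost jointly (a half-lost complex
is not a biologically meaningful event at this scale, and joint loss
keeps the core model's gene set exactly the cross-strain intersection).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .fba import FbaCache, GrowthCondition, MediumSpec, is_growth, maximize_growth, set_medium
from .gpr import And, Gene, Or
from .model import MetabolicModel, Metabolite, Reaction
from .orthologs import Member, OrthologTable
from .reconstruction import derive_strain_model

__all__ = [
    "FamilySpec",
    "PlantedDifference",
    "DESIGNATED_CONDITION",
    "ANAEROBIC_CONDITION",
    "generate_template",
    "generate_family",
    "plant_difference",
    "simulate_fitness",
]

#: Aerobic reference condition every generated template grows on.
DESIGNATED_CONDITION = GrowthCondition(carbon_source="carb",
                                       electron_acceptor="o2")
#: Anaerobic alternative supported through the nitrate respiration branch.
ANAEROBIC_CONDITION = GrowthCondition(carbon_source="carb",
                                      electron_acceptor="no3")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic strain family.

    Defaults give a family of four strains over a 30-to-50-reaction
    template — large enough to contain isozymes, complexes and bypasses,
    small enough that exhaustive double-deletion enumeration stays an
    affordable oracle.
    """

    n_strains: int = 4
    n_side_branches: int = 6
    gene_loss_p: float = 0.15
    isozyme_fraction: float = 0.2
    complex_fraction: float = 0.2
    empty_gpr_fraction: float = 0.3
    pseudogene_p: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("gene_loss_p", "isozyme_fraction", "complex_fraction",
                     "empty_gpr_fraction", "pseudogene_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.n_strains < 2:
            raise ValueError("a family needs at least 2 strains")
        if self.n_side_branches < 0:
            raise ValueError("n_side_branches must be non-negative")


@dataclass(frozen=True)
class PlantedDifference:
    """Ground truth of a planted between-model difference."""

    kind: str  # biomass | genetic | metabolic
    deletion_group: str
    lethal_in: str
    condition: GrowthCondition


class _GeneFactory:
    def __init__(self, strain: str):
        self.strain = strain
        self.counter = 0
        self.complexes: List[Tuple[str, str]] = []

    def new(self) -> str:
        self.counter += 1
        return f"{self.strain}_{self.counter:04d}"


def _assign_gpr(rng: np.random.Generator, genes: _GeneFactory,
                spec: FamilySpec):
    draw = rng.random()
    if draw < spec.isozyme_fraction:
        return Or(Gene(genes.new()), Gene(genes.new()))
    if draw < spec.isozyme_fraction + spec.complex_fraction:
        g1, g2 = genes.new(), genes.new()
        genes.complexes.append((g1, g2))
        return And(Gene(g1), Gene(g2))
    return Gene(genes.new())


def generate_template(spec: FamilySpec, strain_id: str = "S1") -> MetabolicModel:
    """Deterministic toy template model for the family's reference strain.

    Same spec (including seed) always yields a content-identical model,
    and therefore byte-identical SBML.  The model is guaranteed to grow
    on :data:`DESIGNATED_CONDITION`; generation fails loudly otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _GeneFactory(strain_id)

    mets: List[Metabolite] = []
    rxns: List[Reaction] = []

    def met(mid: str, compartment: str, name: str = "") -> str:
        mets.append(Metabolite(id=mid, name=name or mid, compartment=compartment))
        return mid

    def rxn(rid: str, stoich: Dict[str, float], lb: float = 0.0,
            ub: float = 1000.0, gpr=None, subsystem: str = "") -> None:
        rxns.append(Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                             upper_bound=ub, gpr=gpr, subsystem=subsystem))

    # extracellular / cytosolic species
    for stem in ("carb", "o2", "no3", "no2", "nh4", "pi", "waste"):
        met(f"{stem}_e", "e")
    for stem in ("carb", "o2", "no3", "no2", "nh4", "pi", "waste",
                 "bb1", "bb2", "bb3", "nadh", "atp", "adp",
                 "prec1", "prec2", "prec3", "prec4"):
        met(f"{stem}_c", "c")

    # exchanges (uptake closed by default; set_medium opens them)
    for stem in ("carb", "o2", "no3", "no2", "nh4", "pi", "waste"):
        rxn(f"EX_{stem}", {f"{stem}_e": -1.0}, lb=0.0, subsystem="Exchange")

    transport = "Transport"
    for stem, sub in (("carb", transport), ("o2", transport),
                      ("no3", transport), ("nh4", transport),
                      ("pi", transport)):
        rxn(f"T_{stem}", {f"{stem}_e": -1.0, f"{stem}_c": 1.0},
            gpr=_assign_gpr(rng, genes, spec), subsystem=sub)
    # secretion transporters (non-essential, no gene requirement)
    rxn("T_no2", {"no2_c": -1.0, "no2_e": 1.0}, subsystem=transport)
    rxn("T_waste", {"waste_c": -1.0, "waste_e": 1.0}, subsystem=transport)

    # backbone carbon processing
    backbone = "Central Metabolism"
    rxn("BB1", {"carb_c": -1.0, "bb1_c": 1.0},
        gpr=_assign_gpr(rng, genes, spec), subsystem=backbone)
    rxn("BB2", {"bb1_c": -1.0, "bb2_c": 1.0},
        gpr=_assign_gpr(rng, genes, spec), subsystem=backbone)
    rxn("BB3", {"bb2_c": -1.0, "bb3_c": 1.0},
        gpr=_assign_gpr(rng, genes, spec), subsystem=backbone)
    rxn("DH", {"carb_c": -1.0, "nadh_c": 1.0, "waste_c": 1.0},
        gpr=_assign_gpr(rng, genes, spec), subsystem=backbone)

    # biomass precursors
    biosynth = "Biosynthesis"
    rxn("PS1", {"bb3_c": -1.0, "prec1_c": 1.0},
        gpr=_assign_gpr(rng, genes, spec), subsystem=biosynth)
    rxn("PS2", {"bb2_c": -1.0, "nh4_c": -1.0, "prec2_c": 1.0},
        gpr=_assign_gpr(rng, genes, spec), subsystem=biosynth)
    rxn("PS3", {"bb3_c": -1.0, "pi_c": -1.0, "prec3_c": 1.0},
        gpr=_assign_gpr(rng, genes, spec), subsystem=biosynth)
    rxn("PS4", {"bb1_c": -1.0, "prec4_c": 1.0},
        gpr=_assign_gpr(rng, genes, spec), subsystem=biosynth)

    # respiration: two electron-acceptor branches regenerate ATP
    energy = "Energy Metabolism"
    rxn("RESP_O2", {"nadh_c": -1.0, "o2_c": -1.0, "adp_c": -1.0, "atp_c": 1.0},
        gpr=_assign_gpr(rng, genes, spec), subsystem=energy)
    rxn("RESP_NO3", {"nadh_c": -1.0, "no3_c": -1.0, "adp_c": -1.0,
                     "atp_c": 1.0, "no2_c": 1.0},
        gpr=_assign_gpr(rng, genes, spec), subsystem=energy)
    rxn("ATPM", {"atp_c": -1.0, "adp_c": 1.0}, lb=0.0, subsystem=energy)

    # biomass: four precursors plus two ATP per unit of growth
    rxn("BIOMASS", {"prec1_c": -1.0, "prec2_c": -1.0, "prec3_c": -1.0,
                    "prec4_c": -1.0, "atp_c": -2.0, "adp_c": 2.0},
        subsystem="Biomass")

    # non-essential dead-end branches: intermediate -> side product -> secreted
    sources = ["bb1_c", "bb2_c", "bb3_c", "prec1_c", "prec4_c", "carb_c"]
    for i in range(spec.n_side_branches):
        src = sources[int(rng.integers(len(sources)))]
        sid = f"side{i + 1}"
        met(f"{sid}_c", "c")
        met(f"{sid}_e", "e")
        gpr = None if rng.random() < spec.empty_gpr_fraction \
            else _assign_gpr(rng, genes, spec)
        rxn(f"SS{i + 1}", {src: -1.0, f"{sid}_c": 1.0}, gpr=gpr,
            subsystem="Secondary Metabolism")
        rxn(f"T_{sid}", {f"{sid}_c": -1.0, f"{sid}_e": 1.0},
            subsystem=transport)
        rxn(f"EX_{sid}", {f"{sid}_e": -1.0}, lb=0.0, subsystem="Exchange")

    model = MetabolicModel(id=strain_id, metabolites=mets, reactions=rxns,
                           biomass_reaction_id="BIOMASS")
    model._complexes = list(genes.complexes)  # loss units for generate_family
    solution = maximize_growth(set_medium(model, DESIGNATED_CONDITION))
    if not is_growth(solution):
        raise RuntimeError(
            f"generated template does not grow on {DESIGNATED_CONDITION.label}"
        )
    return model


def _group_id(index: int) -> str:
    return f"og{index:04d}"


def generate_family(
    template: MetabolicModel,
    spec: FamilySpec,
    planted_losses: Sequence[Tuple[str, str]] = (),
    viability_condition: Optional[GrowthCondition] = DESIGNATED_CONDITION,
) -> Tuple[List[MetabolicModel], OrthologTable]:
    """Derive a strain family from the template by group-wise gene loss.

    One ortholog group per template gene; the template strain keeps every
    gene, the others lose each loss unit (a single gene, or both members
    of an AND complex) independently with ``gene_loss_p``.  A lost gene
    is sometimes recorded as a pseudogene fragment instead of an absent
    cell.  Strains emulate viable isolates: a sampled loss that would
    abolish growth on *viability_condition* is rejected (pass ``None``
    to disable), so divergence accumulates in dispensable content — e.g.
    alternative respiration branches — exactly where real strain families
    differ.  *planted_losses* forces ``(strain, group id)`` losses
    unconditionally.  Strain models are produced by
    :func:`derive_strain_model`, so they match what a user would derive
    from the emitted table exactly.
    """
    rng = np.random.default_rng(spec.seed + 1)
    template_genes = sorted(template.genes)
    gene_index = {g: i + 1 for i, g in enumerate(template_genes)}
    strains = [template.id] + [f"S{i}" for i in range(2, spec.n_strains + 1)
               if f"S{i}" != template.id]
    strains = strains[:spec.n_strains]

    # loss units: AND-complex partners go together
    complexes = getattr(template, "_complexes", [])
    unit_of: Dict[str, int] = {}
    units: List[List[str]] = []
    in_complex = {g for pair in complexes for g in pair}
    for pair in complexes:
        unit_of[pair[0]] = unit_of[pair[1]] = len(units)
        units.append(list(pair))
    for g in template_genes:
        if g not in in_complex:
            unit_of[g] = len(units)
            units.append([g])

    forced = {(strain, gid) for strain, gid in planted_losses}
    groups: Dict[str, Dict[str, List[Member]]] = {}
    for g in template_genes:
        gid = _group_id(gene_index[g])
        groups[gid] = {template.id: [Member(g)]}

    viability_cache = (FbaCache(template, viability_condition)
                       if viability_condition is not None else None)
    for strain in strains[1:]:
        sampled = [
            u for u in range(len(units)) if rng.random() < spec.gene_loss_p
        ]
        lost_units: Set[int] = set()
        lost_genes: Set[str] = set()
        for u in sampled:
            trial = lost_genes | set(units[u])
            if viability_cache is not None \
                    and not viability_cache.grows(frozenset(trial)):
                continue  # a viable isolate cannot have lost this unit
            lost_units.add(u)
            lost_genes = trial
        pseudo_units = {
            u for u in lost_units if rng.random() < spec.pseudogene_p
        }
        for g in template_genes:
            gid = _group_id(gene_index[g])
            unit = unit_of[g]
            target_gene = f"{strain}_{gene_index[g]:04d}"
            if (strain, gid) in forced:
                continue  # absent
            if unit in lost_units:
                if unit in pseudo_units:
                    groups[gid].setdefault(strain, []).append(
                        Member(target_gene, pseudogene=True))
                continue
            groups[gid].setdefault(strain, []).append(Member(target_gene))

    table = OrthologTable(strains, groups)
    models = [template.copy()]
    for strain in strains[1:]:
        derived, _report = derive_strain_model(template, table, strain,
                                               template_strain=template.id)
        models.append(derived)
    return models, table


def _add_group(table: OrthologTable, gid: str,
               members: Dict[str, List[Member]]) -> OrthologTable:
    groups = {g: dict(row) for g, row in table.groups.items()}
    if gid in groups:
        raise ValueError(f"group {gid!r} already in table")
    groups[gid] = members
    return OrthologTable(table.strains, groups)


def plant_difference(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    table: OrthologTable,
    kind: str,
    condition: GrowthCondition = DESIGNATED_CONDITION,
) -> Tuple[MetabolicModel, MetabolicModel, OrthologTable, PlantedDifference]:
    """Plant a single known difference between two family members.

    ``genetic``: both models get a fresh shared gene on the essential
    backbone step BB2, and model A additionally gets a private isozyme —
    deleting the shared group kills only B.  ``biomass``: both models
    gain a synthesis reaction for a new compound driven by a shared gene,
    and only B's biomass reaction requires the compound.  ``metabolic``:
    the shared gene controls BB2 in both models, and A gains a two-step
    genetically independent bypass around it.

    Returns the modified pair, the extended ortholog table, and the
    expected comparison outcome (deletion set, victim model, label).
    """
    if kind not in ("biomass", "genetic", "metabolic"):
        raise ValueError(f"unknown difference kind {kind!r}")
    a, b = model_a.copy(), model_b.copy()
    shared_gene_a = f"{a.id}_plant"
    shared_gene_b = f"{b.id}_plant"
    gid = f"og_plant_{kind}"

    if kind in ("genetic", "metabolic"):
        target = "BB2"
        rxn_a = a.reactions[target]
        rxn_b = b.reactions[target]
        if kind == "genetic":
            iso = f"{a.id}_plant_iso"
            a = a.with_reaction(replace(rxn_a, gpr=Or(Gene(shared_gene_a),
                                                      Gene(iso))))
            b = b.with_reaction(replace(rxn_b, gpr=Gene(shared_gene_b)))
            table = _add_group(table, f"{gid}_iso",
                               {a.id: [Member(iso)]})
        else:
            a = a.with_reaction(replace(rxn_a, gpr=Gene(shared_gene_a)))
            b = b.with_reaction(replace(rxn_b, gpr=Gene(shared_gene_b)))
            # private bypass in A: bb1 -> bypass intermediate -> bb2
            bypass1 = f"{a.id}_plant_by1"
            bypass2 = f"{a.id}_plant_by2"
            a = MetabolicModel(
                a.id,
                list(a.metabolites.values()) + [Metabolite("byp_c", "byp_c", "c")],
                list(a.reactions.values()) + [
                    Reaction("BYP1", {"bb1_c": -1.0, "byp_c": 1.0},
                             gpr=Gene(bypass1), subsystem="Central Metabolism"),
                    Reaction("BYP2", {"byp_c": -1.0, "bb2_c": 1.0},
                             gpr=Gene(bypass2), subsystem="Central Metabolism"),
                ],
                a.biomass_reaction_id,
            )
            table = _add_group(table, f"{gid}_by1", {a.id: [Member(bypass1)]})
            table = _add_group(table, f"{gid}_by2", {a.id: [Member(bypass2)]})
    else:  # biomass
        synth = Reaction("PBSYN", {"bb1_c": -1.0, "pb_c": 1.0},
                         subsystem="Biosynthesis")
        for which in ("a", "b"):
            model = a if which == "a" else b
            gene = shared_gene_a if which == "a" else shared_gene_b
            model = MetabolicModel(
                model.id,
                list(model.metabolites.values()) + [Metabolite("pb_c", "pb_c", "c")],
                list(model.reactions.values()) + [replace(synth, gpr=Gene(gene))],
                model.biomass_reaction_id,
            )
            if which == "a":
                a = model
            else:
                b = model
        bio = b.biomass_reaction
        stoich = dict(bio.stoichiometry)
        stoich["pb_c"] = -0.2
        b = b.with_reaction(replace(bio, stoichiometry=stoich))

    table = _add_group(table, gid, {a.id: [Member(shared_gene_a)],
                                    b.id: [Member(shared_gene_b)]})
    expected = PlantedDifference(kind=kind, deletion_group=gid,
                                 lethal_in=b.id, condition=condition)
    return a, b, table, expected


def simulate_fitness(
    model: MetabolicModel,
    conditions: Sequence[GrowthCondition],
    noise_sd: float = 1.0,
    seed: int = 0,
    n_replicates: int = 3,
    no_growth_mean: float = -6.0,
    spec: MediumSpec = MediumSpec(),
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], bool]]:
    """Simulate pooled-mutant fitness z-scores from a model's essentiality.

    Ground truth for each gene x condition is the FBA single-knockout
    growth call.  Mutants that grow draw replicate z-scores from
    Normal(0, noise_sd); mutants that cannot grow draw from
    Normal(no_growth_mean, noise_sd) — the -6 center puts the
    conventional -3.5 cutoff between the two modes.  Returns the records
    (columns gene, experiment, condition, z) and the ground-truth call
    map keyed by (gene, condition label).
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth: Dict[Tuple[str, str], bool] = {}
    for condition in conditions:
        cache = FbaCache(model, condition, spec)
        for gene in sorted(model.genes):
            grows = cache.grows(frozenset([gene]))
            truth[(gene, condition.label)] = grows
            mean = 0.0 if grows else no_growth_mean
            for rep in range(n_replicates):
                rows.append({
                    "gene": gene,
                    "experiment": f"{condition.label}#r{rep + 1}",
                    "condition": condition.label,
                    "z": mean + noise_sd * rng.standard_normal(),
                })
    return pd.DataFrame(rows), truth
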