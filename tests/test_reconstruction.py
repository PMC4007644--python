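"""Ortholog tables, strain derivation, conflicts, core construction."""

import itertools

import pytest

from panflux.fba import GrowthCondition, is_growth, maximize_growth, set_medium
from panflux.gpr import ALWAYS_OFF, Gene, Or, translate
from panflux.orthologs import (
    Member,
    OrthologTable,
    OrthologTableError,
    read_ortholog_table,
)
from panflux.reconstruction import (
    build_core_model,
    derive_strain_model,
    detect_growth_conflicts,
)
from panflux.synthetic import DESIGNATED_CONDITION, FamilySpec, generate_family, generate_template

TABLE_TSV = """group\tS1\tS2\tS3
og1\tSO2767\tMR4_x\t-
og2\tgeneA^\tgeneB\tgeneC
og3\tg10;g11\tg20\t-
"""


def test_read_ortholog_table_membership(tmp_path):
    path = tmp_path / "orth.tsv"
    path.write_text(TABLE_TSV)
    table = read_ortholog_table(str(path))
    assert table.strains == ["S1", "S2", "S3"]
    assert table.has_functional_member("og1", "S1")
    assert table.has_functional_member("og1", "S2")
    assert not table.has_functional_member("og1", "S3")
    # pseudogene: present in the table but functionally absent
    assert table.groups["og2"]["S1"] == (Member("geneA", pseudogene=True),)
    assert table.functional_members("og2", "S1") == []
    # co-orthologs map to a list
    assert table.mapping("S1", "S2")["g10"] == ["g20"]
    assert table.mapping("S2", "S1")["g20"] == ["g10", "g11"]


def test_duplicate_gene_reports_row(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("group\tS1\nog1\tgA\nog2\tgA\n")
    with pytest.raises(OrthologTableError) as err:
        read_ortholog_table(str(path))
    assert ":3:" in str(err.value)


def test_table_round_trip(family, tmp_path):
    _, table = family
    path = str(tmp_path / "orth.tsv")
    table.to_tsv(path)
    assert read_ortholog_table(path) == table


def test_self_derivation_is_identity(template, family):
    _, table = family
    derived, report = derive_strain_model(template, table, template.id)
    assert derived.content_equal(template)
    assert report.removed_reactions == []


def test_derived_reactions_match_gpr_oracle(template, family):
    """A reaction survives derivation iff its translated GPR is satisfiable."""
    models, table = family
    for strain_model in models[1:]:
        mapping = table.mapping(template.id, strain_model.id)
        for rxn in template.reactions.values():
            if rxn.gpr is None or rxn.is_exchange \
                    or rxn.id == template.biomass_reaction_id:
                assert rxn.id in strain_model.reactions
                continue
            alive = translate(rxn.gpr, mapping) is not ALWAYS_OFF
            assert (rxn.id in strain_model.reactions) == alive, \
                (strain_model.id, rxn.id)


def test_planted_loss_removes_reaction_with_reason(template):
    spec = FamilySpec(seed=11, gene_loss_p=0.0, n_strains=2)
    # pick a reaction with a singleton GPR and force its group lost in S2
    target = next(r for r in sorted(template.reactions.values(),
                                    key=lambda r: r.id)
                  if isinstance(r.gpr, Gene) and not r.is_exchange)
    gene = target.gpr.id
    index = sorted(template.genes).index(gene) + 1
    gid = f"og{index:04d}"
    _, table = generate_family(template, spec, planted_losses=[("S2", gid)])
    derived, report = derive_strain_model(template, table, "S2")
    removed = dict(report.removed_reactions)
    assert target.id not in derived.reactions
    assert removed[target.id] == [gene]


def test_lost_isozyme_leaves_single_gene_gpr(template):
    spec = FamilySpec(seed=11, gene_loss_p=0.0, n_strains=2)
    target = next(r for r in sorted(template.reactions.values(),
                                    key=lambda r: r.id)
                  if isinstance(r.gpr, Or)
                  and all(isinstance(c, Gene) for c in r.gpr.children))
    lost, kept = [c.id for c in target.gpr.children]
    ordered = sorted(template.genes)
    gid = f"og{ordered.index(lost) + 1:04d}"
    _, table = generate_family(template, spec, planted_losses=[("S2", gid)])
    derived, _ = derive_strain_model(template, table, "S2")
    expected = f"S2_{ordered.index(kept) + 1:04d}"
    assert derived.reactions[target.id].gpr == Gene(expected)


def test_detect_growth_conflicts(template):
    obs_ok = (DESIGNATED_CONDITION, True)
    # an exchangeable compound with no catabolic route: predicted no growth
    unusable = GrowthCondition(carbon_source="waste", electron_acceptor="o2")
    assert detect_growth_conflicts(template, [obs_ok]) == []
    conflicts = detect_growth_conflicts(template, [(unusable, True)])
    assert conflicts == [(unusable, True, False)]
    assert detect_growth_conflicts(template, []) == []


class TestCoreModel:
    def test_all_conserved_limit(self, template):
        spec = FamilySpec(seed=11, gene_loss_p=0.0, n_strains=3)
        _, table = generate_family(template, spec)
        core, report = build_core_model(template, table,
                                        condition=DESIGNATED_CONDITION)
        # every GPR reaction survives; only non-essential non-GPR
        # reactions are dropped
        assert report.isozyme_exceptions == []
        for rxn in template.reactions.values():
            if rxn.gpr is not None or rxn.is_exchange \
                    or rxn.id == template.biomass_reaction_id:
                assert rxn.id in core.reactions
        for rid in report.removed_reactions:
            assert template.reactions[rid].gpr is None
        assert core.genes == template.genes

    def test_core_gene_set_is_intersection_plus_exceptions(self, family,
                                                           template):
        models, table = family
        core, report = build_core_model(template, table,
                                        condition=DESIGNATED_CONDITION)
        conserved = set(table.groups_conserved_in(table.strains))
        gene_group = table.gene_to_group(template.id)
        conserved_genes = {g for g in template.genes
                           if gene_group.get(g) in conserved}
        exception_genes = {g for _, gs in report.isozyme_exceptions for g in gs}
        assert core.genes - exception_genes <= conserved_genes
        assert conserved_genes <= core.genes
        # retained non-GPR reactions are individually essential in the core
        for rid in report.retained_non_gpr:
            trimmed = core.without_reactions([rid])
            sol = maximize_growth(set_medium(trimmed, DESIGNATED_CONDITION))
            assert not is_growth(sol), rid

    def test_core_grows_on_construction_condition(self, family, template):
        _, table = family
        core, _ = build_core_model(template, table,
                                   condition=DESIGNATED_CONDITION)
        sol = maximize_growth(set_medium(core, DESIGNATED_CONDITION))
        assert is_growth(sol)

    def test_strain_order_invariance(self, family, template):
        _, table = family
        core_fwd, _ = build_core_model(template, table,
                                       strains=table.strains,
                                       condition=DESIGNATED_CONDITION)
        core_rev, _ = build_core_model(template, table,
                                       strains=list(reversed(table.strains)),
                                       condition=DESIGNATED_CONDITION)
        assert core_fwd.content_equal(core_rev)

    def test_core_reactions_subset_of_template(self, family, template):
        _, table = family
        core, _ = build_core_model(template, table,
                                   condition=DESIGNATED_CONDITION)
        assert set(core.reactions) <= set(template.reactions)
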