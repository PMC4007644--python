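"""Gene-aligned network comparison: deletion sets and classification."""

import itertools

import pytest

from panflux.conga import (
    align_genes,
    classify_difference,
    find_deletion_sets,
    map_to_subsystems,
    summarize_unique_lethal,
)
from panflux.fba import GROWTH_THRESHOLD, FbaCache, WildtypeNoGrowthError, deletion_grows
from panflux.orthologs import Member, OrthologTable
from panflux.synthetic import (
    DESIGNATED_CONDITION,
    FamilySpec,
    generate_family,
    generate_template,
    plant_difference,
)


def test_align_identical_models(identical_pair):
    model_a, model_b, table = identical_pair
    alignment = align_genes(model_a, model_b, table)
    assert not alignment.unique_a and not alignment.unique_b
    assert len(alignment.shared_groups) == len(model_a.genes)


def test_align_partitions_gene_union(family):
    models, table = family
    model_a, model_b = models[1], models[2]
    alignment = align_genes(model_a, model_b, table)
    shared_a = {g for gid in alignment.shared_groups
                for g in table.functional_members(gid, model_a.id)}
    shared_b = {g for gid in alignment.shared_groups
                for g in table.functional_members(gid, model_b.id)}
    assert shared_a | alignment.unique_a == model_a.genes
    assert shared_b | alignment.unique_b == model_b.genes
    assert not shared_a & alignment.unique_a
    assert not shared_b & alignment.unique_b


def test_identical_models_yield_no_results(identical_pair):
    model_a, model_b, table = identical_pair
    assert find_deletion_sets(model_a, model_b, table,
                              DESIGNATED_CONDITION, k=2) == []


@pytest.mark.parametrize("kind", ["genetic", "biomass", "metabolic"])
@pytest.mark.parametrize("seed", [3, 17])
def test_planted_difference_found_and_labeled(kind, seed):
    spec = FamilySpec(seed=seed, gene_loss_p=0.0, n_strains=2)
    t = generate_template(spec)
    (base_a, base_b), base_table = generate_family(t, spec)
    model_a, model_b, table, expected = plant_difference(
        base_a, base_b, base_table, kind)
    results = find_deletion_sets(model_a, model_b, table,
                                 DESIGNATED_CONDITION, k=1)
    assert len(results) == 1
    result = results[0]
    assert result.deletion_set == {expected.deletion_group}
    assert result.lethal_in == expected.lethal_in
    assert result.flux_difference > GROWTH_THRESHOLD
    labels = classify_difference(result, model_a, model_b, table)
    assert labels == {kind}


def test_enumeration_matches_direct_brute_force():
    """The memoized engine agrees with plain per-deletion FBA calls."""
    spec = FamilySpec(seed=5, gene_loss_p=0.2, n_strains=2,
                      n_side_branches=3)
    t = generate_template(spec)
    (model_a, model_b), table = generate_family(t, spec)
    results = find_deletion_sets(model_a, model_b, table,
                                 DESIGNATED_CONDITION, k=2)
    found = {r.deletion_set for r in results}

    alignment = align_genes(model_a, model_b, table)
    brute = set()
    singles = set()
    for gid in alignment.shared_groups:
        ga = set(table.functional_members(gid, model_a.id))
        gb = set(table.functional_members(gid, model_b.id))
        grows_a = deletion_grows(model_a, ga, DESIGNATED_CONDITION)
        grows_b = deletion_grows(model_b, gb, DESIGNATED_CONDITION)
        if grows_a != grows_b:
            brute.add(frozenset([gid]))
            singles.add(gid)
    for g1, g2 in itertools.combinations(alignment.shared_groups, 2):
        if g1 in singles or g2 in singles:
            continue  # not minimal
        ga = set(table.functional_members(g1, model_a.id)) \
            | set(table.functional_members(g2, model_a.id))
        gb = set(table.functional_members(g1, model_b.id)) \
            | set(table.functional_members(g2, model_b.id))
        if deletion_grows(model_a, ga, DESIGNATED_CONDITION) \
                != deletion_grows(model_b, gb, DESIGNATED_CONDITION):
            brute.add(frozenset([g1, g2]))
    assert found == brute


def test_results_are_minimal_and_symmetric():
    spec = FamilySpec(seed=9, gene_loss_p=0.2, n_strains=2)
    t = generate_template(spec)
    (model_a, model_b), table = generate_family(t, spec)
    fwd = find_deletion_sets(model_a, model_b, table,
                             DESIGNATED_CONDITION, k=2)
    rev = find_deletion_sets(model_b, model_a, table,
                             DESIGNATED_CONDITION, k=2)
    # symmetry: same sets, same victims
    assert {(r.deletion_set, r.lethal_in) for r in fwd} \
        == {(r.deletion_set, r.lethal_in) for r in rev}
    # minimality: no reported set contains another
    sets = [r.deletion_set for r in fwd]
    for s1, s2 in itertools.permutations(sets, 2):
        assert not s1 < s2


def test_every_result_is_classified():
    spec = FamilySpec(seed=21, gene_loss_p=0.25, n_strains=2)
    t = generate_template(spec)
    (model_a, model_b), table = generate_family(t, spec)
    results = find_deletion_sets(model_a, model_b, table,
                                 DESIGNATED_CONDITION, k=1)
    for result in results:
        labels = classify_difference(result, model_a, model_b, table)
        assert len(labels) == 1
        assert labels <= {"biomass", "metabolic", "genetic"}


def test_wildtype_no_growth_excludes_condition(template, family):
    from panflux.fba import GrowthCondition

    models, table = family
    dead_condition = GrowthCondition(carbon_source="waste",
                                     electron_acceptor="o2")
    with pytest.raises(WildtypeNoGrowthError):
        find_deletion_sets(models[0], models[1], table, dead_condition)


def test_summarize_matches_hand_enumeration(family):
    models, table = family
    summary, results = summarize_unique_lethal(models, table,
                                               DESIGNATED_CONDITION, k=1)
    # oracle: a group counts for model M iff deleting it kills M but not
    # some other model sharing the group
    caches = {m.id: FbaCache(m, DESIGNATED_CONDITION) for m in models}
    growing = [m for m in models
               if caches[m.id].objective(frozenset()) > GROWTH_THRESHOLD]
    for model in growing:
        expected = set()
        for gid in table.groups:
            genes_m = set(table.functional_members(gid, model.id))
            if not genes_m & model.genes:
                continue
            if caches[model.id].grows(genes_m):
                continue
            for other in growing:
                if other.id == model.id:
                    continue
                genes_o = set(table.functional_members(gid, other.id))
                if not genes_o & other.genes:
                    continue  # group not shared with this partner
                if caches[other.id].grows(genes_o):
                    expected.add(gid)
                    break
        assert summary.loc[model.id, "total"] == len(expected), model.id
        found = {gid for r in results if r.lethal_in == model.id
                 for gid in r.deletion_set}
        assert found == expected


def test_summarize_identical_models_all_zero(identical_pair):
    model_a, model_b, table = identical_pair
    summary, results = summarize_unique_lethal([model_a, model_b], table,
                                               DESIGNATED_CONDITION, k=1)
    assert (summary["total"] == 0).all()
    assert results == []


def test_map_to_subsystems_planted_single_subsystem(identical_pair):
    model_a, model_b, table = identical_pair
    a, b, tab, expected = plant_difference(model_a, model_b, table, "genetic")
    results = find_deletion_sets(a, b, tab, DESIGNATED_CONDITION, k=1)
    frame = map_to_subsystems(results, {a.id: a, b.id: b}, tab)
    assert list(frame.index) == ["Central Metabolism"]
    assert frame.iloc[0, 0] == 1  # the one planted reaction


def test_map_to_subsystems_empty():
    frame = map_to_subsystems([], {}, OrthologTable(["S1"], {}))
    assert frame.empty
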