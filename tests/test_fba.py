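"""FBA engine: medium rules, LP optima, knockouts, essentiality."""

import itertools

import numpy as np
import pytest

from panflux.fba import (
    FbaCache,
    GrowthCondition,
    MediumSpec,
    NotRepresentableError,
    WildtypeNoGrowthError,
    deletion_grows,
    essential_genes,
    find_exchange,
    is_growth,
    maximize_growth,
    set_medium,
)
from panflux.gpr import Gene, Or
from panflux.model import MetabolicModel, Metabolite, Reaction
from panflux.synthetic import DESIGNATED_CONDITION, FamilySpec, generate_template


def _chain_model():
    """EX_A (lb -10) -> transport -> A->B -> biomass, all 1:1."""
    return MetabolicModel(
        "chain",
        [Metabolite("A_e", compartment="e"), Metabolite("A_c", compartment="c"),
         Metabolite("B_c", compartment="c")],
        [
            Reaction("EX_A", {"A_e": -1.0}, -10.0, 1000.0),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, gpr=Gene("gT")),
            Reaction("CONV", {"A_c": -1.0, "B_c": 1.0}, gpr=Gene("gC")),
            Reaction("biomass", {"B_c": -1.0}),
        ],
        "biomass",
    )


def test_uptake_limited_chain_objective():
    sol = maximize_growth(_chain_model())
    assert sol.optimal
    assert sol.objective == pytest.approx(10.0, abs=1e-9)


def test_all_exchanges_closed_no_growth():
    model = _chain_model()
    closed = model.with_reaction(
        model.reactions["EX_A"].with_bounds(0.0, 1000.0))
    sol = maximize_growth(closed)
    assert sol.objective == pytest.approx(0.0, abs=1e-9)
    assert not is_growth(sol)


def test_growth_threshold_calls():
    sol = maximize_growth(_chain_model())
    assert is_growth(sol)
    tiny = maximize_growth(
        _chain_model().with_reaction(
            Reaction("EX_A", {"A_e": -1.0}, -1e-9, 1000.0)))
    assert not is_growth(tiny)  # below the solver-noise threshold


def test_mass_balance_residual(template):
    constrained = set_medium(template, DESIGNATED_CONDITION)
    sol = maximize_growth(constrained)
    assert sol.optimal
    residual = {m: 0.0 for m in constrained.metabolites}
    for rid, flux in sol.fluxes.items():
        for met, coef in constrained.reactions[rid].stoichiometry.items():
            residual[met] += coef * flux
    assert max(abs(v) for v in residual.values()) <= 1e-6
    # bounds respected
    for rid, flux in sol.fluxes.items():
        rxn = constrained.reactions[rid]
        assert rxn.lower_bound - 1e-6 <= flux <= rxn.upper_bound + 1e-6


def test_fba_matches_cobra_oracle(tmp_path):
    """Same optimum from an independent LP stack (cobra + GLPK)."""
    from panflux.sbml_io import write_sbml

    from conftest import build_cobra_model

    for seed in range(5):
        model = generate_template(FamilySpec(seed=100 + seed))
        constrained = set_medium(model, DESIGNATED_CONDITION)
        ours = maximize_growth(constrained).objective
        path = str(tmp_path / f"m{seed}.xml")
        write_sbml(model, path)
        cm = build_cobra_model(path, constrained)
        theirs = cm.slim_optimize()
        assert ours == pytest.approx(theirs, abs=1e-6), seed


def test_set_medium_bounds(template):
    constrained = set_medium(template, DESIGNATED_CONDITION)
    assert constrained.reactions["EX_carb"].lower_bound == -10.0
    assert constrained.reactions["EX_o2"].lower_bound == -10.0
    assert constrained.reactions["EX_nh4"].lower_bound == -1000.0
    assert constrained.reactions["EX_pi"].lower_bound == -1000.0
    # unnamed exchanges closed for uptake, everything open for secretion
    assert constrained.reactions["EX_no3"].lower_bound == 0.0
    for rxn in constrained.exchange_reactions():
        assert rxn.upper_bound == 1000.0
    # maintenance demand zeroed
    assert constrained.reactions["ATPM"].lower_bound == 0.0


def test_set_medium_idempotent(template):
    once = set_medium(template, DESIGNATED_CONDITION)
    twice = set_medium(once, DESIGNATED_CONDITION)
    assert once.content_equal(twice)


def test_set_medium_no_carbon_means_no_growth(template):
    condition = GrowthCondition(carbon_source=None, electron_acceptor="o2")
    sol = maximize_growth(set_medium(template, condition))
    assert sol.objective == pytest.approx(0.0, abs=1e-9)


def test_unmappable_compound_is_named():
    with pytest.raises(NotRepresentableError) as err:
        set_medium(_chain_model(),
                   GrowthCondition("A", "o2", nitrogen_source="A"))
    assert "o2" in str(err.value)


def test_deletion_monotonicity(template):
    cache = FbaCache(template, DESIGNATED_CONDITION)
    genes = sorted(template.genes)
    rng = np.random.default_rng(0)
    for _ in range(15):
        d1 = set(rng.choice(genes, size=3, replace=False))
        d2 = d1 | set(rng.choice(genes, size=2, replace=False))
        assert cache.objective(frozenset(d2)) \
            <= cache.objective(frozenset(d1)) + 1e-6


def test_uptake_scaling_homogeneity(template):
    base = maximize_growth(set_medium(template, DESIGNATED_CONDITION)).objective
    doubled_spec = MediumSpec(uptake_bound=20.0)
    doubled = maximize_growth(
        set_medium(template, DESIGNATED_CONDITION, doubled_spec)).objective
    assert doubled <= 2 * base + 1e-6
    # this template is purely uptake-limited, so equality holds
    assert doubled == pytest.approx(2 * base, rel=1e-9)


def test_deletion_grows_limit_cases(template):
    wt = deletion_grows(template, set(), DESIGNATED_CONDITION)
    assert wt is True
    assert deletion_grows(template, {"not_a_gene"},
                          DESIGNATED_CONDITION) is wt


def test_single_essentials_match_brute_force(template):
    found = essential_genes(template, DESIGNATED_CONDITION, set_size=1)
    brute = {
        frozenset([g]) for g in template.genes
        if not deletion_grows(template, {g}, DESIGNATED_CONDITION)
    }
    assert found == brute
    assert brute  # the backbone guarantees some essential genes


def test_no_gpr_model_has_no_essentials():
    model = _chain_model()
    stripped = MetabolicModel(
        "bare", model.metabolites.values(),
        [Reaction(r.id, r.stoichiometry, r.lower_bound, r.upper_bound)
         for r in model.reactions.values()],
        "biomass",
    )
    assert essential_genes(stripped, GrowthCondition("A", None,
                                                     nitrogen_source="A")) == set()


def test_double_essentials_find_planted_isozyme_pair():
    model = _chain_model()
    redundant = model.with_reaction(
        Reaction("CONV", {"A_c": -1.0, "B_c": 1.0},
                 gpr=Or(Gene("gC"), Gene("gC2"))))
    condition = GrowthCondition("A", None, nitrogen_source="A")
    singles = essential_genes(redundant, condition, set_size=1)
    assert singles == {frozenset(["gT"])}
    doubles = essential_genes(redundant, condition, set_size=2)
    assert doubles == {frozenset(["gC", "gC2"])}
    # minimality: no double contains the lethal single
    assert all("gT" not in pair for pair in doubles)


def test_essentiality_undefined_without_wildtype_growth(template):
    condition = GrowthCondition(carbon_source="waste", electron_acceptor="o2")
    with pytest.raises(WildtypeNoGrowthError):
        essential_genes(template, condition)


def test_find_exchange_matches_stem_and_alias(template):
    assert find_exchange(template, "carb") == "EX_carb"
    assert find_exchange(template, "oxygen", aliases={"oxygen": "o2"}) == "EX_o2"
    assert find_exchange(template, "unobtainium") is None
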