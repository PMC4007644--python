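import os

import pytest
from hypothesis import settings

from panflux.fba import GrowthCondition
from panflux.synthetic import FamilySpec, generate_family, generate_template

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def family_spec():
    return FamilySpec(seed=11)


@pytest.fixture(scope="session")
def template(family_spec):
    return generate_template(family_spec)


@pytest.fixture(scope="session")
def family(template, family_spec):
    """(models, table) for the default four-strain family."""
    return generate_family(template, family_spec)


@pytest.fixture(scope="session")
def identical_pair():
    """Two content-equivalent strains (zero gene loss) plus their table."""
    spec = FamilySpec(seed=3, gene_loss_p=0.0, n_strains=2)
    t = generate_template(spec)
    (model_a, model_b), table = generate_family(t, spec)
    return model_a, model_b, table


@pytest.fixture(scope="session")
def aerobic():
    return GrowthCondition(carbon_source="carb", electron_acceptor="o2")


@pytest.fixture(scope="session")
def anaerobic():
    return GrowthCondition(carbon_source="carb", electron_acceptor="no3")


LEGACY_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="toy_legacy">
  <listOfCompartments><compartment id="c"/><compartment id="e"/></listOfCompartments>
  <listOfSpecies>
   <species id="A_e" compartment="e"/>
   <species id="A_c" compartment="c"/>
   <species id="B_c" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="EX_A" reversible="true">
    <listOfReactants><speciesReference species="A_e"/></listOfReactants>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="-10"/>
      <parameter id="UPPER_BOUND" value="1000"/>
      <parameter id="FLUX_VALUE" value="0"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
   <reaction id="T_A" reversible="false">
    <notes><body xmlns="http://www.w3.org/1999/xhtml">
     <p>GENE_ASSOCIATION: (g1 and g2) or g3</p>
     <p>SUBSYSTEM: Transport</p>
    </body></notes>
    <listOfReactants><speciesReference species="A_e"/></listOfReactants>
    <listOfProducts><speciesReference species="A_c"/></listOfProducts>
   </reaction>
   <reaction id="CONV" reversible="false">
    <notes><body xmlns="http://www.w3.org/1999/xhtml">
     <p>GENE_ASSOCIATION: g4</p>
    </body></notes>
    <listOfReactants><speciesReference species="A_c"/></listOfReactants>
    <listOfProducts><speciesReference species="B_c"/></listOfProducts>
   </reaction>
   <reaction id="Biomass_toy" reversible="false">
    <listOfReactants><speciesReference species="B_c"/></listOfReactants>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


@pytest.fixture()
def legacy_sbml_path(tmp_path):
    path = tmp_path / "legacy.xml"
    path.write_text(LEGACY_SBML)
    return str(path)


def build_cobra_model(sbml_path, reference):
    """Independent LP oracle: load our SBML with cobra, mirror the bounds
    of *reference* (a medium-applied MetabolicModel), solve with GLPK."""
    import cobra
    from cobra.io import read_sbml_model

    cm = read_sbml_model(sbml_path)
    cm.solver = "glpk"
    for rxn in cm.reactions:
        ref = reference.reactions[rxn.id]
        rxn.bounds = (ref.lower_bound, ref.upper_bound)
    return cm
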