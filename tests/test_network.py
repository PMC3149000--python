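"""Structural checks of the default central-carbon-metabolism network."""

from fractions import Fraction

import numpy as np
import pytest

from coliflux.netio import network_to_sbml, read_network, write_network
from coliflux.network import (
    MetabolicNetwork,
    Metabolite,
    NetworkConstructionError,
    Reaction,
    build_default_network,
    carbon_count,
    stoichiometric_matrix,
)


def test_model_dimensions(net):
    """The network has 50 fluxes over 22 balanced metabolites, split into 24
    dependent, 1 measured inflow, 7 outflows and 18 biomass drains."""
    assert len(net.reactions) == 50
    assert len(net.balanced_metabolites) == 22
    assert net.role_counts == {
        "dependent": 24,
        "measured_inflow": 1,
        "outflow": 7,
        "biomass_drain": 18,
    }


def test_expected_pathway_content(net):
    for rid in ("Pts", "Pgi", "Pfk", "Emp", "Pyk", "Pdh", "Zwf", "GltA",
                "Icd", "SucAB", "Ppc", "AceAB", "Pta", "Acs", "Vprod",
                "CarAB", "PyrB", "PyrC", "PyrD", "YjgM", "Oxp", "AtpD",
                "AceOut", "LacOut", "CbaspOut", "DhoOut", "OroOut",
                "NaaOut", "Co2Out"):
        assert net.reaction(rid) is not None


def test_stoichiometric_matrix_shape_and_ordering(net):
    S = stoichiometric_matrix(net)
    assert S.shape == (22, 50)
    # entry (i, j) is the coefficient of balanced metabolite i in reaction j
    row = [m.id for m in net.balanced_metabolites].index("G6P")
    col = [r.id for r in net.reactions].index("Pgi")
    assert S[row, col] == Fraction(-1)


def test_single_reaction_matrix_column():
    mets = [Metabolite("A", "a", 3), Metabolite("B", "b", 3)]
    rxn = Reaction("conv", {"A": Fraction(-1), "B": Fraction(1)}, "dependent")
    small = MetabolicNetwork(metabolites=mets, reactions=[rxn])
    S = stoichiometric_matrix(small)
    assert list(S[:, 0]) == [Fraction(-1), Fraction(1)]


def test_carbon_conservation_is_exact(net):
    """Every non-drain reaction conserves carbon exactly (rational zero)."""
    for r in net.reactions:
        if r.role == "biomass_drain":
            continue
        assert net.carbon_imbalance(r.id) == 0, r.id


def test_carbon_weighted_matrix_columns_vanish(net):
    """Carbon-weighted column sums restate conservation for reactions that
    touch no external species."""
    S = stoichiometric_matrix(net, float_dtype=True)
    carbons = np.array([m.carbon_atoms if not m.is_cofactor else 0
                        for m in net.balanced_metabolites], dtype=float)
    for j, r in enumerate(net.reactions):
        touches_external = any(
            net.metabolite(m).is_external for m in r.stoichiometry
        )
        if touches_external:
            continue
        assert abs(float(carbons @ S[:, j])) < 1e-12, r.id


@pytest.mark.parametrize(
    "name,expected",
    [("glucose", 6), ("orotate", 5), ("NAA", 6), ("CBASP", 5), ("DHO", 5),
     ("acetate", 2), ("lactate", 3), ("CO2", 1)],
)
def test_carbon_count(net, name, expected):
    assert carbon_count(name, net) == expected


def test_carbon_count_unknown_raises(net):
    with pytest.raises(KeyError):
        carbon_count("unobtainium", net)


def test_cofactor_closure(net):
    for cof in ("ATP", "NADH", "NADPH"):
        produced = [r.id for r in net.reactions
                    if r.stoichiometry.get(cof, 0) > 0]
        consumed = [r.id for r in net.reactions
                    if r.stoichiometry.get(cof, 0) < 0]
        assert produced and consumed, cof
    # spilling is the only pure ATP sink (no other products or reactants)
    pure_sinks = [
        r.id for r in net.reactions
        if set(r.stoichiometry) == {"ATP"} and r.stoichiometry["ATP"] < 0
    ]
    assert pure_sinks == ["AtpD"]


def test_dependent_submatrix_full_row_rank(net):
    S = stoichiometric_matrix(net, float_dtype=True)
    dep = [j for j, r in enumerate(net.reactions) if r.role == "dependent"]
    assert np.linalg.matrix_rank(S[:, dep], tol=1e-9) == 22


def test_po_ratio_rescaling(net):
    doubled = net.with_po_ratio(4.0)
    assert doubled.reaction("Oxp").stoichiometry["ATP"] == Fraction(4)
    # all carbon stoichiometry untouched
    for r in net.reactions:
        if r.id == "Oxp":
            continue
        assert doubled.reaction(r.id).stoichiometry == r.stoichiometry


def test_invalid_carbon_balance_names_reaction():
    net = build_default_network()
    bad = Reaction("Leak", {"PYR": Fraction(-1)}, "dependent")
    with pytest.raises(NetworkConstructionError, match="Leak"):
        MetabolicNetwork(
            metabolites=list(net.metabolites),
            reactions=list(net.reactions) + [bad],
        ).validate()


def test_network_file_roundtrip(net, tmp_path):
    path = tmp_path / "network.txt"
    text1 = write_network(net, path)
    net2 = read_network(path)
    assert write_network(net2) == text1
    assert net2.role_counts == net.role_counts
    assert net2.po_ratio == net.po_ratio
    for r in net.reactions:
        assert net2.reaction(r.id).stoichiometry == r.stoichiometry


def test_shipped_network_file_matches_builder(net):
    from importlib.resources import files

    shipped = files("coliflux").joinpath("data/default_network.txt").read_text()
    assert read_network(shipped).role_counts == net.role_counts
    assert write_network(read_network(shipped)) == write_network(net)


def test_sbml_export_is_wellformed(net):
    import xml.etree.ElementTree as ET

    root = ET.fromstring(network_to_sbml(net))
    ns = "{http://www.sbml.org/sbml/level3/version2/core}"
    species = root.findall(f".//{ns}species")
    reactions = root.findall(f".//{ns}reaction")
    assert len(species) == len(net.metabolites)
    assert len(reactions) == 50
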