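"""Read/write the plain-text network format, plus an export-only SBML writer.

The network file is line-oriented and self-contained: a ``[metabolites]``
section (id, name, carbon atoms, kind) followed by a ``[reactions]`` section
(id, equation string, role, reversibility, optional lumped step list).
Coefficients are exact rationals (``4/3 GAP``).  Reading then writing a file
reproduces the same network (lossless round trip).
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from fractions import Fraction
from pathlib import Path

from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = ["write_network", "read_network", "network_to_sbml"]

_KINDS = {"balanced", "cofactor", "external"}


def _format_side(stoich: dict[str, Fraction], sign: int) -> str:
    parts = []
    for mid, coeff in stoich.items():
        if (coeff > 0) != (sign > 0):
            continue
        c = abs(coeff)
        parts.append(f"{c} {mid}")
    return " + ".join(parts) if parts else "(none)"


def format_equation(rxn: Reaction) -> str:
    arrow = "<->" if rxn.reversible else "->"
    return (
        f"{_format_side(rxn.stoichiometry, -1)} {arrow} "
        f"{_format_side(rxn.stoichiometry, +1)}"
    )


def parse_equation(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``1 A + 4/3 B -> 2 C`` into a signed stoichiometry map."""
    if "<->" in text:
        lhs, rhs = text.split("<->")
        reversible = True
    elif "->" in text:
        lhs, rhs = text.split("->")
        reversible = False
    else:
        raise ValueError(f"no arrow in equation {text!r}")
    stoich: dict[str, Fraction] = {}
    for side, sign in ((lhs, -1), (rhs, +1)):
        side = side.strip()
        if side in ("", "(none)"):
            continue
        for term in side.split("+"):
            fields = term.split()
            if len(fields) == 1:
                coeff, mid = Fraction(1), fields[0]
            elif len(fields) == 2:
                coeff, mid = Fraction(fields[0]), fields[1]
            else:
                raise ValueError(f"cannot parse term {term!r}")
            stoich[mid] = stoich.get(mid, Fraction(0)) + sign * coeff
    return stoich, reversible


def write_network(network: MetabolicNetwork, path: str | Path | None = None) -> str:
    """Serialize a network; returns the text and optionally writes it."""
    buf = io.StringIO()
    w = buf.write
    w("# coliflux network file\n")
    w("# metabolite: id | name | carbon_atoms | kind(balanced/cofactor/external)\n")
    w("# reaction:   id | equation | role | reversible|irreversible | lumped:a,b\n")
    w(f"po_ratio = {network.po_ratio}\n")
    w(f"fadh2_discount = {network.fadh2_discount}\n")
    w(f"glyoxylate_coupling = {network.glyoxylate_coupling}\n")
    w("\n[metabolites]\n")
    for m in network.metabolites:
        kind = (
            "cofactor" if m.is_cofactor else "external" if m.is_external else "balanced"
        )
        w(f"{m.id} | {m.name} | {m.carbon_atoms} | {kind}\n")
    w("\n[reactions]\n")
    for r in network.reactions:
        rev = "reversible" if r.reversible else "irreversible"
        line = f"{r.id} | {format_equation(r)} | {r.role} | {rev}"
        if r.lumped_from:
            line += f" | lumped:{','.join(r.lumped_from)}"
        w(line + "\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_network(source: str | Path) -> MetabolicNetwork:
    """Parse a network file (path or literal text) and validate it."""
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    params = {"po_ratio": 2.0, "fadh2_discount": 1.0, "glyoxylate_coupling": 0.8}
    section = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[]").lower()
            continue
        if section is None and "=" in line:
            key, val = (s.strip() for s in line.split("=", 1))
            if key in params:
                params[key] = float(val)
            continue
        fields = [f.strip() for f in line.split("|")]
        if section == "metabolites":
            mid, name, carbons, kind = fields[:4]
            if kind not in _KINDS:
                raise ValueError(f"unknown metabolite kind {kind!r} for {mid}")
            mets.append(
                Metabolite(
                    mid,
                    name,
                    int(carbons),
                    is_cofactor=kind == "cofactor",
                    is_external=kind == "external",
                )
            )
        elif section == "reactions":
            rid, equation, role, rev = fields[:4]
            lumped: tuple[str, ...] = ()
            for extra in fields[4:]:
                if extra.startswith("lumped:"):
                    lumped = tuple(
                        s.strip() for s in extra[len("lumped:"):].split(",") if s.strip()
                    )
            stoich, rev_eq = parse_equation(equation)
            reversible = rev == "reversible" or rev_eq
            rxns.append(Reaction(rid, stoich, role, reversible, lumped))
        else:
            raise ValueError(f"line outside a section: {raw!r}")
    net = MetabolicNetwork(metabolites=mets, reactions=rxns, **params)
    net.validate()
    return net


def network_to_sbml(network: MetabolicNetwork) -> str:
    """Export-only conversion to SBML Level 3 Version 2 core.

    Balanced species live in compartment ``cytosol`` (cofactors flagged via
    SBO term 247), external species in ``environment`` with
    ``boundaryCondition`` semantics expressed through constant=false +
    compartment placement.  Rational coefficients are emitted as decimals.
    """
    ns = "http://www.sbml.org/sbml/level3/version2/core"
    ET.register_namespace("", ns)
    sbml = ET.Element(f"{{{ns}}}sbml", attrib={"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{ns}}}model", attrib={"id": "coliflux_ccm"})
    comps = ET.SubElement(model, f"{{{ns}}}listOfCompartments")
    for cid in ("cytosol", "environment"):
        ET.SubElement(
            comps,
            f"{{{ns}}}compartment",
            attrib={"id": cid, "constant": "true", "spatialDimensions": "3"},
        )
    species_el = ET.SubElement(model, f"{{{ns}}}listOfSpecies")
    for m in network.metabolites:
        attrib = {
            "id": f"M_{m.id}",
            "name": m.name,
            "compartment": "environment" if m.is_external else "cytosol",
            "hasOnlySubstanceUnits": "true",
            "boundaryCondition": "true" if m.is_external else "false",
            "constant": "false",
        }
        if m.is_cofactor:
            attrib["sboTerm"] = "SBO:0000247"
        ET.SubElement(species_el, f"{{{ns}}}species", attrib=attrib)
    rxns_el = ET.SubElement(model, f"{{{ns}}}listOfReactions")
    for r in network.reactions:
        rxn_el = ET.SubElement(
            rxns_el,
            f"{{{ns}}}reaction",
            attrib={
                "id": f"R_{r.id}",
                "reversible": "true" if r.reversible else "false",
                "name": f"{r.id} ({r.role})",
            },
        )
        reactants = ET.SubElement(rxn_el, f"{{{ns}}}listOfReactants")
        products = ET.SubElement(rxn_el, f"{{{ns}}}listOfProducts")
        for mid, coeff in r.stoichiometry.items():
            parent = products if coeff > 0 else reactants
            ET.SubElement(
                parent,
                f"{{{ns}}}speciesReference",
                attrib={
                    "species": f"M_{mid}",
                    "stoichiometry": repr(float(abs(coeff))),
                    "constant": "true",
                },
            )
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)
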