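"""SBML Level 3 export of generated reaction networks (and a minimal reader).

One SBML species per network species (id ``s<i>``, name = canonical label,
compartment from the species' compartment tag, clamped bath species as
boundary conditions), one reaction per network reaction with an expanded
mass-action kinetic law ``factor * k1 * ... * reactant amounts``.  Output is
deterministic: identical input produces byte-identical XML.

The reader supports exactly this dialect (mass-action kinetic laws that are
products of constants, parameters and species) and exists so written
documents can be re-imported into a generic ODE right-hand side for
round-trip checks.  The explicit downstream rate-law block is not part of
the exported network document.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from lxml import etree

from .rulegraph import ReactionNetwork, ValidationError

__all__ = ["write_sbml", "read_sbml_network", "SbmlNetwork", "sbml_rhs"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

COMPARTMENTS = ("PM", "SE1", "SE2", "RE", "CYT", "ER")


def _math_times(factors: list[etree._Element]) -> etree._Element:
    math = etree.Element(f"{{{MATHML_NS}}}math")
    if len(factors) == 1:
        math.append(factors[0])
        return math
    apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
    etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
    for f in factors:
        apply_.append(f)
    return math


def _ci(name: str) -> etree._Element:
    el = etree.Element(f"{{{MATHML_NS}}}ci")
    el.text = f" {name} "
    return el


def _cn(value: float) -> etree._Element:
    el = etree.Element(f"{{{MATHML_NS}}}cn")
    el.text = f" {value!r} "
    return el


def write_sbml(
    network: ReactionNetwork,
    parameters: dict[str, float],
    initial_amounts: dict[str, float] | None = None,
    clamped: list[str] | None = None,
    model_id: str = "angiotriad_network",
) -> str:
    """Serialize a generated network to SBML L3 text."""
    initial_amounts = initial_amounts or {}
    clamped = set(clamped or [])
    nsmap = {None: SBML_NS}
    sbml = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "2")
    model = etree.SubElement(sbml, f"{{{SBML_NS}}}model")
    model.set("id", model_id)

    lc = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for comp in COMPARTMENTS:
        c = etree.SubElement(lc, f"{{{SBML_NS}}}compartment")
        c.set("id", comp)
        c.set("constant", "true")
        c.set("size", "1")

    ls = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for i, (sp, label) in enumerate(zip(network.species, network.labels)):
        s = etree.SubElement(ls, f"{{{SBML_NS}}}species")
        s.set("id", f"s{i}")
        s.set("name", label)
        s.set("compartment", sp.compartment)
        s.set("initialAmount", repr(float(initial_amounts.get(label, 0.0))))
        s.set("hasOnlySubstanceUnits", "true")
        s.set("boundaryCondition", "true" if label in clamped else "false")
        s.set("constant", "false")

    lp = etree.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name in sorted(parameters):
        p = etree.SubElement(lp, f"{{{SBML_NS}}}parameter")
        p.set("id", name)
        p.set("value", repr(float(parameters[name])))
        p.set("constant", "true")

    lr = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for j, rxn in enumerate(network.reactions):
        missing = [nm for nm in rxn.rate_params if nm not in parameters]
        if missing:
            raise ValidationError(
                f"reaction {j} references undefined parameters {missing}"
            )
        r = etree.SubElement(lr, f"{{{SBML_NS}}}reaction")
        r.set("id", f"r{j}")
        r.set("name", rxn.rule)
        r.set("reversible", "false")
        if rxn.reactants:
            lor = etree.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for idx, count in sorted(_multiset(rxn.reactants).items()):
                sr = etree.SubElement(lor, f"{{{SBML_NS}}}speciesReference")
                sr.set("species", f"s{idx}")
                sr.set("stoichiometry", repr(float(count)))
                sr.set("constant", "true")
        if rxn.products:
            lop = etree.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for idx, count in sorted(_multiset(rxn.products).items()):
                sr = etree.SubElement(lop, f"{{{SBML_NS}}}speciesReference")
                sr.set("species", f"s{idx}")
                sr.set("stoichiometry", repr(float(count)))
                sr.set("constant", "true")
        kl = etree.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        factors = [_cn(float(rxn.stat_factor))]
        factors += [_ci(nm) for nm in rxn.rate_params]
        factors += [_ci(f"s{idx}") for idx in rxn.reactants]
        kl.append(_math_times(factors))
    return etree.tostring(
        sbml, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def _multiset(indices) -> dict[int, int]:
    out: dict[int, int] = {}
    for i in indices:
        out[i] = out.get(i, 0) + 1
    return out


# ---------------------------------------------------------------------------
# minimal reader (round-trip checks)


@dataclass
class SbmlNetwork:
    species_ids: list[str]
    species_names: list[str]
    initial_amounts: np.ndarray
    boundary: np.ndarray
    reactions: list[tuple[dict[int, int], dict[int, int], float]]
    # (reactant multiset, product multiset, rate constant incl. factor)


def read_sbml_network(text: str) -> SbmlNetwork:
    """Parse the mass-action dialect written by :func:`write_sbml`."""
    root = etree.fromstring(text.encode())
    ns = {"s": SBML_NS, "m": MATHML_NS}
    species = root.findall(".//s:listOfSpecies/s:species", ns)
    ids = [s.get("id") for s in species]
    names = [s.get("name") for s in species]
    idx = {sid: i for i, sid in enumerate(ids)}
    amounts = np.array([float(s.get("initialAmount", "0")) for s in species])
    boundary = np.array([s.get("boundaryCondition") == "true" for s in species])
    params = {
        p.get("id"): float(p.get("value"))
        for p in root.findall(".//s:listOfParameters/s:parameter", ns)
    }
    reactions = []
    for r in root.findall(".//s:listOfReactions/s:reaction", ns):
        reac = {
            idx[sr.get("species")]: int(float(sr.get("stoichiometry", "1")))
            for sr in r.findall("s:listOfReactants/s:speciesReference", ns)
        }
        prod = {
            idx[sr.get("species")]: int(float(sr.get("stoichiometry", "1")))
            for sr in r.findall("s:listOfProducts/s:speciesReference", ns)
        }
        k = 1.0
        math = r.find("s:kineticLaw/m:math", ns)
        if math is None:
            raise ValidationError(f"reaction {r.get('id')} has no kinetic law")
        tokens = math.findall(".//m:ci", ns) + math.findall(".//m:cn", ns)
        species_factor_count: dict[int, int] = {}
        for tok in tokens:
            name = (tok.text or "").strip()
            if tok.tag.endswith("cn"):
                k *= float(name)
            elif name in params:
                k *= params[name]
            elif name in idx:
                species_factor_count[idx[name]] = species_factor_count.get(idx[name], 0) + 1
            else:
                raise ValidationError(f"unknown kinetic-law symbol {name!r}")
        if species_factor_count != reac:
            raise ValidationError(
                f"reaction {r.get('id')}: kinetic law is not mass action over "
                "its reactants"
            )
        reactions.append((reac, prod, k))
    return SbmlNetwork(
        species_ids=ids, species_names=names, initial_amounts=amounts,
        boundary=boundary, reactions=reactions,
    )


def sbml_rhs(net: SbmlNetwork):
    """Mass-action RHS f(t, y) for an imported network (generic ODE reader)."""

    def rhs(t, y):
        dy = np.zeros_like(y)
        for reac, prod, k in net.reactions:
            rate = k
            for i, n in reac.items():
                rate *= max(y[i], 0.0) ** n
            for i, n in reac.items():
                dy[i] -= n * rate
            for i, n in prod.items():
                dy[i] += n * rate
        dy[net.boundary] = 0.0
        return dy

    return rhs
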