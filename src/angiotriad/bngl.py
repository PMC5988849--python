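"""Read and write the BNGL subset that expresses this model family.

Supported blocks: ``parameters``, ``molecule types``, ``seed species``,
``observables`` and ``reaction rules``.  Bonds are written as numbered
endpoints (``!1``), states as ``~label``, compartments as a species-level
``@COMP:`` prefix (cBNGL-lite), and rates as parameter names or ``*``
products of parameter names.  Rule modifiers map onto the engine's
features::

    exclude_reactants(i, pattern)   species-level filter on reactant i (1-based)
    include_reactants(i, pattern)   required species-level pattern
    compartments(PM, SE1)           rule applies only in these compartments
    TotalRate                       one channel per species (transport semantics)
    DeleteMolecules                 deletion removes matched molecules only

A ``$`` prefix on a seed species marks a clamped bath species (constant
amount).  Unsupported BNGL constructs (functions, energy patterns, explicit
compartment volumes, actions) raise :class:`UnsupportedBnglError` with the
offending line number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .rulegraph import (
    ModelSignature,
    MoleculeType,
    RxnRule,
    SiteDef,
    SpeciesGraph,
    ValidationError,
    canonical_label,
    parse_species,
    to_string,
)

__all__ = [
    "BnglModel",
    "BnglError",
    "UnsupportedBnglError",
    "read_bngl",
    "write_bngl",
    "model_to_bngl",
]

_SUPPORTED_BLOCKS = ("parameters", "molecule types", "seed species",
                     "observables", "reaction rules")
_UNSUPPORTED_BLOCKS = ("functions", "energy patterns", "compartments",
                       "population maps")


class BnglError(ValidationError):
    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UnsupportedBnglError(BnglError):
    pass


@dataclass
class BnglModel:
    """Parsed model file: the ModelSpec-shaped content of the BNGL subset."""

    signature: ModelSignature
    parameters: dict[str, float]
    seeds: list[SpeciesGraph]
    seed_amounts: dict[str, float]  # canonical label -> amount
    clamped: list[str]
    observables: list[tuple[str, str, str]]  # (kind, name, pattern text)
    rules: list[RxnRule]

    def fingerprint(self) -> tuple:
        """Structural identity used for round-trip checks."""
        return (
            tuple(sorted(
                (t.name, tuple((s.name, s.states) for s in t.sites))
                for t in self.signature.types.values()
            )),
            tuple(sorted(self.parameters.items())),
            tuple(sorted(self.seed_amounts.items())),
            tuple(sorted(self.clamped)),
            tuple(sorted(self.observables)),
            tuple(_rule_line(r) for r in self.rules),
        )


# ---------------------------------------------------------------------------
# writing


def _rule_line(rule: RxnRule) -> str:
    lhs = " + ".join(to_string(p, with_compartment=False) for p in rule.reactants) or "0"
    rhs = " + ".join(to_string(p, with_compartment=True if p.compartment else False)
                     for p in rule.products) or "0"
    rate = "*".join(rule.rate)
    mods = []
    for i, pat in rule.include:
        mods.append(f"include_reactants({i + 1},{to_string(pat, with_compartment=False)})")
    for i, pat in rule.exclude:
        mods.append(f"exclude_reactants({i + 1},{to_string(pat, with_compartment=False)})")
    if rule.compartments:
        mods.append(f"compartments({','.join(rule.compartments)})")
    if rule.match_once:
        mods.append("TotalRate")
    if any(a.__class__.__name__ == "_Delete" for a in rule.actions):
        mods.append("DeleteMolecules")
    tail = (" " + " ".join(mods)) if mods else ""
    return f"{rule.name}: {lhs} -> {rhs} {rate}{tail}"


def write_bngl(model: BnglModel) -> str:
    out = ["begin model", "", "begin parameters"]
    for k, v in model.parameters.items():
        out.append(f"  {k} {v!r}")
    out.append("end parameters")
    out.append("")
    out.append("begin molecule types")
    for t in model.signature.types.values():
        sites = []
        for s in t.sites:
            tok = s.name + "".join(f"~{st}" for st in s.states)
            sites.append(tok)
        out.append(f"  {t.name}({','.join(sites)})")
    out.append("end molecule types")
    out.append("")
    out.append("begin seed species")
    for sp in model.seeds:
        label = canonical_label(sp)
        amount = model.seed_amounts.get(label, 0.0)
        prefix = "$" if label in model.clamped else ""
        out.append(f"  {prefix}{to_string(sp)} {amount!r}")
    out.append("end seed species")
    out.append("")
    out.append("begin observables")
    for kind, name, pat in model.observables:
        out.append(f"  {kind} {name} {pat}")
    out.append("end observables")
    out.append("")
    out.append("begin reaction rules")
    for rule in model.rules:
        out.append(f"  {_rule_line(rule)}")
    out.append("end reaction rules")
    out.append("")
    out.append("end model")
    return "\n".join(out) + "\n"


def model_to_bngl(spec) -> str:
    """Serialize a built ModelSpec (see model module) to the BNGL subset."""
    model = BnglModel(
        signature=spec.signature,
        parameters={k: float(v) for k, v in spec.params.items()},
        seeds=spec.seeds,
        seed_amounts=spec.seed_amounts,
        clamped=list(spec.clamped),
        observables=[("Molecules", "pR2", "VEGFR2(Y1175~p)")],
        rules=spec.rules,
    )
    return write_bngl(model)


# ---------------------------------------------------------------------------
# reading

_MOD_RE = re.compile(
    r"(include_reactants|exclude_reactants)"
    r"\(\s*(\d+)\s*,\s*((?:[^()]|\([^()]*\))*)\s*\)"
    r"|compartments\(\s*([\w,\s]+)\)|(TotalRate)|(DeleteMolecules)"
)


def _strip_comment(line: str) -> str:
    return line.split("#", 1)[0].rstrip()


def read_bngl(text: str) -> BnglModel:
    """Parse the supported BNGL subset into a :class:`BnglModel`."""
    lines = text.splitlines()
    blocks: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for ln, raw in enumerate(lines, start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        m = re.match(r"begin\s+(.+)$", line)
        if m:
            name = m.group(1).strip()
            if name == "model":
                continue
            if name in _UNSUPPORTED_BLOCKS:
                raise UnsupportedBnglError(
                    f"unsupported subset feature: block {name!r}", ln
                )
            if name not in _SUPPORTED_BLOCKS:
                raise UnsupportedBnglError(f"unknown block {name!r}", ln)
            if current is not None:
                raise BnglError(f"nested block {name!r}", ln)
            current = name
            blocks.setdefault(name, [])
            continue
        m = re.match(r"end\s+(.+)$", line)
        if m:
            name = m.group(1).strip()
            if name == "model":
                continue
            if current != name:
                raise BnglError(f"unbalanced block delimiter 'end {name}'", ln)
            current = None
            continue
        if re.match(r"\w+\(\s*\{", line) or re.match(r"^(generate_network|simulate|setOption)", line):
            raise UnsupportedBnglError(f"unsupported subset feature: {line!r}", ln)
        if current is None:
            raise BnglError(f"content outside any block: {line!r}", ln)
        blocks[current].append((ln, line))

    if current is not None:
        raise BnglError(f"block {current!r} never closed")

    params: dict[str, float] = {}
    for ln, line in blocks.get("parameters", []):
        parts = line.split()
        if len(parts) != 2:
            raise BnglError(f"cannot parse parameter line {line!r}", ln)
        try:
            params[parts[0]] = float(parts[1])
        except ValueError:
            raise UnsupportedBnglError(
                f"unsupported subset feature: non-numeric parameter {line!r}", ln
            ) from None

    types = []
    for ln, line in blocks.get("molecule types", []):
        m = re.match(r"([A-Za-z_]\w*)\(([^()]*)\)$", line)
        if not m:
            raise BnglError(f"cannot parse molecule type {line!r}", ln)
        name, body = m.group(1), m.group(2)
        sites = []
        if body.strip():
            for tok in body.split(","):
                bits = tok.strip().split("~")
                sites.append(SiteDef(bits[0], tuple(bits[1:])))
        types.append(MoleculeType(name, tuple(sites)))
    signature = ModelSignature(types)

    seeds: list[SpeciesGraph] = []
    amounts: dict[str, float] = {}
    clamped: list[str] = []
    for ln, line in blocks.get("seed species", []):
        m = re.match(r"(\$?)(\S+)\s+(\S+)$", line)
        if not m:
            raise BnglError(f"cannot parse seed species line {line!r}", ln)
        is_clamped, sp_text, amount_text = m.group(1) == "$", m.group(2), m.group(3)
        try:
            amount = float(amount_text)
        except ValueError:
            amount = params.get(amount_text)
            if amount is None:
                raise BnglError(f"unknown seed amount {amount_text!r}", ln) from None
        try:
            sp = parse_species(sp_text, signature)
        except ValidationError as err:
            raise BnglError(str(err), ln) from None
        label = canonical_label(sp)
        seeds.append(sp)
        amounts[label] = amount
        if is_clamped:
            clamped.append(label)

    observables = []
    for ln, line in blocks.get("observables", []):
        parts = line.split()
        if len(parts) != 3:
            raise BnglError(f"cannot parse observable line {line!r}", ln)
        observables.append((parts[0], parts[1], parts[2]))

    rules: list[RxnRule] = []
    for ln, line in blocks.get("reaction rules", []):
        rules.extend(_parse_rule(line, ln, signature))
    return BnglModel(
        signature=signature, parameters=params, seeds=seeds,
        seed_amounts=amounts, clamped=clamped, observables=observables,
        rules=rules,
    )


def _parse_rule(line: str, ln: int, signature: ModelSignature) -> list[RxnRule]:
    m = re.match(r"([\w.\-]+)\s*:\s*(.*)$", line)
    if not m:
        raise BnglError(f"rule needs a 'name:' prefix: {line!r}", ln)
    name, body = m.group(1), m.group(2)

    include, exclude, compartments = [], [], None
    match_once = False
    mods_found = True
    while mods_found:
        mods_found = False
        mm = _MOD_RE.search(body)
        if mm:
            mods_found = True
            if mm.group(1):
                idx = int(mm.group(2)) - 1
                target = include if mm.group(1) == "include_reactants" else exclude
                target.append((idx, mm.group(3)))
            elif mm.group(4):
                compartments = [c.strip() for c in mm.group(4).split(",") if c.strip()]
            elif mm.group(5):
                match_once = True
            body = (body[: mm.start()] + body[mm.end():]).strip()
        # DeleteMolecules is implied by the rule transformation; just strip it
        if "DeleteMolecules" in body:
            body = body.replace("DeleteMolecules", "").strip()
            mods_found = True

    reversible = "<->" in body
    arrow = "<->" if reversible else "->"
    try:
        lhs_text, rest = body.split(arrow, 1)
    except ValueError:
        raise BnglError(f"rule has no '->': {line!r}", ln) from None
    rest = rest.strip()
    parts = rest.rsplit(None, 1)
    if len(parts) != 2:
        raise BnglError(f"rule is missing a rate: {line!r}", ln)
    rhs_text, rate_text = parts
    if reversible:
        rates = [r.strip() for r in rate_text.split(",")]
        if len(rates) != 2:
            raise BnglError("reversible rule needs 'kf,kr' rates", ln)
    else:
        rates = [rate_text.strip()]

    def side(text: str) -> list[str]:
        text = text.strip()
        if text == "0":
            return []
        return [p.strip() for p in re.split(r"\s+\+\s+", text)]

    try:
        fwd = RxnRule(
            name, side(lhs_text), side(rhs_text), tuple(rates[0].split("*")),
            include=include, exclude=exclude, compartments=compartments,
            match_once=match_once, signature=signature,
        )
    except ValidationError as err:
        raise BnglError(f"rule {name!r}: {err}", ln) from None
    out = [fwd]
    if reversible:
        out.append(fwd.reversed(name + "_rev", tuple(rates[1].split("*"))))
    return out
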