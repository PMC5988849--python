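"""Rule-based reaction network generation.

This module is a generic graph-rewriting engine for site-graph models of
protein complexes: molecules carry named sites that can hold internal states
(e.g. a phosphorylation status) and at most one bond to a site of another
molecule.  Sites with the same name may appear more than once on a molecule
(a bivalent ligand has two equivalent receptor-binding sites).  A *species*
is a connected complex of such molecules living in a named compartment; a
*pattern* is a partially specified species used as the left-hand side of a
reaction rule.  Applying every rule to every reachable species until nothing
new appears turns a handful of rules into the full elementary reaction
network, with mass-action statistical factors derived from embedding counts.

The text syntax follows the BioNetGen convention::

    @PM:VEGF(r!1,r,nrp1bd).VEGFR2(L!1,Y1175~u,c)

Molecules in a complex are joined by ``.``; a site listed without ``!`` is
unbound, ``!n`` pairs two endpoints of bond ``n``, ``!+`` means "bound to
anything" and ``!?`` leaves the bond status unconstrained; ``~label`` fixes
an internal state (omitted state = wildcard in patterns).

Embeddings are injective maps at site-slot resolution: a pattern mentioning
one free ``r`` site embeds twice into a ligand whose two ``r`` slots are both
free.  The statistical factor of a generated reaction is the embedding count
of its product class divided by the automorphism count of the rule's
reactant patterns, with an extra 1/2 when a bimolecular rule consumes two
copies of the same species.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "SiteDef",
    "MoleculeType",
    "ModelSignature",
    "Molecule",
    "SpeciesGraph",
    "PatternGraph",
    "RxnRule",
    "Reaction",
    "ReactionNetwork",
    "ValidationError",
    "canonical_label",
    "count_embeddings",
    "find_embeddings",
    "apply_rule",
    "generate_network",
    "parse_pattern",
    "parse_species",
    "to_string",
]

COMPARTMENTS = ("PM", "SE1", "SE2", "RE", "CYT", "ER")

FREE = "free"
BOUND_ANY = "+"
UNSPEC = "?"


class ValidationError(ValueError):
    """A species, pattern or rule violates a structural invariant."""


# ---------------------------------------------------------------------------
# signature


@dataclass(frozen=True)
class SiteDef:
    name: str
    states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValidationError(f"duplicate state labels on site {self.name!r}")


@dataclass(frozen=True)
class MoleculeType:
    name: str
    sites: tuple[SiteDef, ...] = ()

    def slots_named(self, name: str) -> list[int]:
        return [i for i, s in enumerate(self.sites) if s.name == name]


class ModelSignature:
    """The set of molecule types available to a model."""

    def __init__(self, types: Iterable[MoleculeType]):
        self.types: dict[str, MoleculeType] = {}
        for t in types:
            if t.name in self.types:
                raise ValidationError(f"duplicate molecule type {t.name!r}")
            self.types[t.name] = t

    def __contains__(self, name: str) -> bool:
        return name in self.types

    def __getitem__(self, name: str) -> MoleculeType:
        try:
            return self.types[name]
        except KeyError:
            raise ValidationError(f"unknown molecule type {name!r}") from None


# ---------------------------------------------------------------------------
# species


class Molecule:
    """One molecule instance: per-slot states aligned with its type's sites."""

    __slots__ = ("type", "site_names", "states")

    def __init__(self, mtype: MoleculeType, states: Sequence[str | None] | None = None):
        self.type = mtype.name
        self.site_names = tuple(s.name for s in mtype.sites)
        if states is None:
            states = [s.states[0] if s.states else None for s in mtype.sites]
        self.states: list[str | None] = list(states)
        if len(self.states) != len(mtype.sites):
            raise ValidationError(f"molecule {self.type}: wrong number of site states")

    def copy(self) -> "Molecule":
        m = object.__new__(Molecule)
        m.type = self.type
        m.site_names = self.site_names
        m.states = list(self.states)
        return m


class SpeciesGraph:
    """A connected multi-molecule complex with bonds, states and a compartment.

    ``bonds`` maps endpoint ``(mol_index, slot_index)`` to its partner
    endpoint; every bond is stored in both directions.
    """

    def __init__(
        self,
        molecules: Sequence[Molecule],
        bonds: Iterable[tuple[tuple[int, int], tuple[int, int]]] = (),
        compartment: str = "PM",
    ):
        self.molecules = list(molecules)
        self.bonds: dict[tuple[int, int], tuple[int, int]] = {}
        for a, b in bonds:
            self.add_bond(a, b)
        self.compartment = compartment

    def add_bond(self, a: tuple[int, int], b: tuple[int, int]) -> None:
        if a in self.bonds or b in self.bonds:
            ep = a if a in self.bonds else b
            raise ValidationError(f"site {ep} participates in more than one bond")
        if a == b:
            raise ValidationError(f"self-bond at {a}")
        self.bonds[a] = b
        self.bonds[b] = a

    def bond_pairs(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        return [(a, b) for a, b in self.bonds.items() if a < b]

    def validate(self, signature: ModelSignature) -> None:
        for i, mol in enumerate(self.molecules):
            mtype = signature[mol.type]
            if mol.site_names != tuple(s.name for s in mtype.sites):
                raise ValidationError(f"molecule {i} ({mol.type}): site list mismatch")
            for k, sd in enumerate(mtype.sites):
                st = mol.states[k]
                if sd.states:
                    if st not in sd.states:
                        raise ValidationError(
                            f"molecule {i} ({mol.type}.{sd.name}): state {st!r} "
                            f"not in allowed set {sd.states}"
                        )
                elif st is not None:
                    raise ValidationError(
                        f"molecule {i} ({mol.type}.{sd.name}) is a pure binding "
                        f"site but carries state {st!r}"
                    )
        for (i, k) in self.bonds:
            if not (0 <= i < len(self.molecules)):
                raise ValidationError(f"dangling bond endpoint: molecule index {i}")
            if not (0 <= k < len(self.molecules[i].site_names)):
                raise ValidationError(
                    f"dangling bond endpoint: {self.molecules[i].type} slot {k}"
                )
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")
        if len(self.molecules) > 1 and len(self.components()) != 1:
            raise ValidationError("species graph is not connected")

    def components(self) -> list[list[int]]:
        n = len(self.molecules)
        adj: list[set[int]] = [set() for _ in range(n)]
        for (i, _), (j, _) in self.bonds.items():
            adj[i].add(j)
        seen: set[int] = set()
        comps = []
        for start in range(n):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            comps.append(sorted(comp))
        return comps

    def copy(self) -> "SpeciesGraph":
        sp = SpeciesGraph([m.copy() for m in self.molecules], compartment=self.compartment)
        sp.bonds = dict(self.bonds)
        return sp

    def molecule_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.molecules:
            counts[m.type] = counts.get(m.type, 0) + 1
        return counts

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SpeciesGraph({to_string(self)})"


# ---------------------------------------------------------------------------
# patterns


@dataclass
class PatternSite:
    """Constraint on one site token: a site name, an optional state and a
    bond status (FREE | BOUND_ANY | UNSPEC | integer bond id)."""

    name: str
    state: str | None = None
    bond: object = FREE


@dataclass
class PatternMolecule:
    type: str
    sites: list[PatternSite]


class PatternGraph:
    """A partially specified species used for matching.

    Site tokens are positional; bonds between tokens are encoded through
    shared integer bond ids.  Unmentioned sites impose no constraint.
    """

    def __init__(self, molecules: Sequence[PatternMolecule], compartment: str | None = None):
        self.molecules = list(molecules)
        self.compartment = compartment
        self._index_bonds()

    def _index_bonds(self) -> None:
        ends: dict[int, list[tuple[int, int]]] = {}
        for i, mol in enumerate(self.molecules):
            for t, ps in enumerate(mol.sites):
                if isinstance(ps.bond, int):
                    ends.setdefault(ps.bond, []).append((i, t))
        for bid, eps in ends.items():
            if len(eps) != 2:
                raise ValidationError(f"bond id {bid} has {len(eps)} endpoints (need 2)")
        self.bond_partner: dict[tuple[int, int], tuple[int, int]] = {}
        for eps in ends.values():
            a, b = eps
            self.bond_partner[a] = b
            self.bond_partner[b] = a

    def copy(self) -> "PatternGraph":
        return PatternGraph(
            [
                PatternMolecule(m.type, [PatternSite(s.name, s.state, s.bond) for s in m.sites])
                for m in self.molecules
            ],
            self.compartment,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PatternGraph({to_string(self)})"


# ---------------------------------------------------------------------------
# text syntax

_MOL_RE = re.compile(r"([A-Za-z_]\w*)\(([^()]*)\)")
_SITE_RE = re.compile(r"([A-Za-z_]\w*)(~[\w?]+)?(!(?:\d+|\+|\?))?$")


def _parse_molecules(text: str):
    text = text.strip().replace(" ", "")
    comp = None
    if text.startswith("@"):
        comp, _, text = text.partition(":")
        comp = comp[1:]
    mols: list[tuple[str, list[tuple[str, str | None, object]]]] = []
    pos = 0
    while pos < len(text):
        m = _MOL_RE.match(text, pos)
        if not m:
            raise ValidationError(f"cannot parse molecule at {text[pos:]!r}")
        name, body = m.group(1), m.group(2)
        sites: list[tuple[str, str | None, object]] = []
        if body.strip():
            for token in body.split(","):
                sm = _SITE_RE.match(token.strip())
                if not sm:
                    raise ValidationError(f"cannot parse site token {token!r} in {name}")
                sname = sm.group(1)
                state = sm.group(2)[1:] if sm.group(2) else None
                if state == "?":
                    state = None
                bond_tok = sm.group(3)
                if bond_tok is None:
                    bond: object = FREE
                elif bond_tok == "!+":
                    bond = BOUND_ANY
                elif bond_tok == "!?":
                    bond = UNSPEC
                else:
                    bond = int(bond_tok[1:])
                sites.append((sname, state, bond))
        mols.append((name, sites))
        pos = m.end()
        if pos < len(text):
            if text[pos] != ".":
                raise ValidationError(f"expected '.' between molecules in {text!r}")
            pos += 1
    return comp, mols


def parse_pattern(text: str, signature: ModelSignature | None = None) -> PatternGraph:
    comp, mols = _parse_molecules(text)
    pmols = []
    for name, sites in mols:
        if signature is not None:
            mtype = signature[name]
            by_name: dict[str, int] = {}
            for sname, state, _ in sites:
                slots = mtype.slots_named(sname)
                if not slots:
                    raise ValidationError(f"unknown site {name}.{sname}")
                by_name[sname] = by_name.get(sname, 0) + 1
                if by_name[sname] > len(slots):
                    raise ValidationError(f"site {name}.{sname} mentioned too often")
                if state is not None:
                    allowed = signature[name].sites[slots[0]].states
                    if state not in allowed:
                        raise ValidationError(f"unknown state {name}.{sname}~{state}")
        pmols.append(PatternMolecule(name, [PatternSite(n, s, b) for n, s, b in sites]))
    return PatternGraph(pmols, comp)


def parse_species(
    text: str, signature: ModelSignature, compartment: str | None = None
) -> SpeciesGraph:
    """Parse a fully specified species.

    Every stateful site must carry a state; unmentioned pure-binding sites
    are free.  Mentioned sites are assigned to type slots by name in order
    of mention.
    """
    comp, mols = _parse_molecules(text)
    comp = compartment or comp or "PM"
    molecules: list[Molecule] = []
    bond_ends: dict[int, list[tuple[int, int]]] = {}
    for i, (name, sites) in enumerate(mols):
        mtype = signature[name]
        mol = Molecule(mtype)
        taken: set[int] = set()
        for sname, state, bond in sites:
            slots = [k for k in mtype.slots_named(sname) if k not in taken]
            if not slots:
                raise ValidationError(f"site {name}.{sname}: no free slot (or unknown site)")
            k = slots[0]
            taken.add(k)
            sd = mtype.sites[k]
            if sd.states:
                if state is None:
                    raise ValidationError(f"species site {name}.{sname} needs a state")
                mol.states[k] = state
            elif state is not None:
                raise ValidationError(f"site {name}.{sname} does not carry states")
            if bond in (BOUND_ANY, UNSPEC):
                raise ValidationError(f"species site {name}.{sname} has wildcard bond")
            if isinstance(bond, int):
                bond_ends.setdefault(bond, []).append((i, k))
        for k, sd in enumerate(mtype.sites):
            if sd.states and k not in taken:
                raise ValidationError(f"species site {name}.{sd.name} needs a state")
        molecules.append(mol)
    pairs = []
    for bid, eps in bond_ends.items():
        if len(eps) != 2:
            raise ValidationError(f"bond id {bid} has {len(eps)} endpoints (need 2)")
        pairs.append((eps[0], eps[1]))
    sp = SpeciesGraph(molecules, pairs, comp)
    sp.validate(signature)
    return sp


def to_string(graph: SpeciesGraph | PatternGraph, with_compartment: bool = True) -> str:
    """Serialize a species or pattern back to the text syntax (given order)."""
    parts = []
    if isinstance(graph, SpeciesGraph):
        bond_ids: dict[tuple[int, int], int] = {}
        next_id = 1
        for a, b in sorted(graph.bond_pairs()):
            bond_ids[a] = bond_ids[b] = next_id
            next_id += 1
        for i, mol in enumerate(graph.molecules):
            toks = []
            for k, sname in enumerate(mol.site_names):
                st = mol.states[k]
                bonded = (i, k) in bond_ids
                if st is None and not bonded and (i, k) not in graph.bonds:
                    continue
                t = sname
                if st is not None:
                    t += f"~{st}"
                if bonded:
                    t += f"!{bond_ids[(i, k)]}"
                toks.append(t)
            parts.append(f"{mol.type}({','.join(toks)})")
        comp = graph.compartment
    else:
        for mol in graph.molecules:
            toks = []
            for ps in mol.sites:
                t = ps.name
                if ps.state is not None:
                    t += f"~{ps.state}"
                if isinstance(ps.bond, int):
                    t += f"!{ps.bond}"
                elif ps.bond == BOUND_ANY:
                    t += "!+"
                elif ps.bond == UNSPEC:
                    t += "!?"
                toks.append(t)
            parts.append(f"{mol.type}({','.join(toks)})")
        comp = graph.compartment
    body = ".".join(parts)
    if with_compartment and comp:
        return f"@{comp}:{body}"
    return body


# ---------------------------------------------------------------------------
# canonical labeling


def _slot_groups(mol: Molecule) -> list[list[int]]:
    groups: dict[str, list[int]] = {}
    for k, name in enumerate(mol.site_names):
        groups.setdefault(name, []).append(k)
    return [g for g in groups.values() if len(g) > 1]


def _label_for(sp: SpeciesGraph, order: Sequence[int], slot_perms: Mapping[int, Sequence[int]]) -> str:
    """Label for a fixed molecule order and per-molecule slot permutation.

    ``slot_perms[i]`` maps displayed slot position -> actual slot index for
    molecule ``i`` (identity when absent).  Bonds are numbered by first
    appearance in display order.
    """
    bond_ids: dict[frozenset, int] = {}
    counter = itertools.count(1)
    tokens = []
    for old_i in order:
        mol = sp.molecules[old_i]
        perm = slot_perms.get(old_i, range(len(mol.site_names)))
        site_toks = []
        for disp, k in enumerate(perm):
            sname = mol.site_names[k]
            st = mol.states[k]
            ep = (old_i, k)
            bonded = ep in sp.bonds
            if st is None and not bonded:
                continue
            t = sname
            if st is not None:
                t += f"~{st}"
            if bonded:
                key = frozenset((ep, sp.bonds[ep]))
                if key not in bond_ids:
                    bond_ids[key] = next(counter)
                t += f"!{bond_ids[key]}"
            site_toks.append(t)
        tokens.append(f"{mol.type}({','.join(site_toks)})")
    return f"@{sp.compartment}:" + ".".join(tokens)


def _refine_colors(sp: SpeciesGraph) -> list:
    n = len(sp.molecules)
    colors: list = []
    for i, mol in enumerate(sp.molecules):
        per_name: dict[str, list] = {}
        for k, name in enumerate(mol.site_names):
            per_name.setdefault(name, []).append(
                (mol.states[k], (i, k) in sp.bonds)
            )
        colors.append((mol.type, tuple(sorted((n_, tuple(sorted(v))) for n_, v in per_name.items()))))
    for _ in range(n):
        new_colors = []
        for i in range(n):
            nbr = []
            for (j, k), (m, t) in sp.bonds.items():
                if j == i:
                    nbr.append((sp.molecules[i].site_names[k], sp.molecules[m].site_names[t], colors[m]))
            new_colors.append((colors[i], tuple(sorted(nbr))))
        if len(set(new_colors)) == len(set(colors)):
            colors = new_colors
            break
        colors = new_colors
    return colors


def canonical_label(species: SpeciesGraph, signature: ModelSignature | None = None) -> str:
    """Canonical string: identical for isomorphic species, distinct otherwise.

    Molecules are partitioned by iteratively refined colors (type, per-site
    states/bond status, bonded-neighbor colors); the label minimizes over
    permutations of molecules within color classes and over permutations of
    same-named site slots, so symmetric complexes (a bivalent ligand
    bridging two identical receptors) get one well-defined name.
    """
    if signature is not None:
        species.validate(signature)
    n = len(species.molecules)
    # slot permutation alternatives per molecule (identity if no duplicates)
    slot_alternatives: list[list[Sequence[int]]] = []
    for mol in species.molecules:
        groups = _slot_groups(mol)
        if not groups:
            slot_alternatives.append([range(len(mol.site_names))])
            continue
        perms = [list(range(len(mol.site_names)))]
        for g in groups:
            new_perms = []
            for base in perms:
                for gp in itertools.permutations(g):
                    p = list(base)
                    for pos, k in zip(g, gp):
                        p[pos] = k
                    new_perms.append(p)
            perms = new_perms
        slot_alternatives.append(perms)
    if n == 1:
        return min(
            _label_for(species, [0], {0: p}) for p in slot_alternatives[0]
        )
    colors = _refine_colors(species)
    order_key = sorted(range(n), key=lambda i: (repr(colors[i]), i))
    classes: list[list[int]] = []
    for i in order_key:
        if classes and colors[classes[-1][0]] == colors[i]:
            classes[-1].append(i)
        else:
            classes.append([i])
    best: str | None = None
    for perm_parts in itertools.product(*(itertools.permutations(c) for c in classes)):
        order = [i for part in perm_parts for i in part]
        for slot_combo in itertools.product(*(slot_alternatives[i] for i in order)):
            slot_perms = {i: p for i, p in zip(order, slot_combo)}
            label = _label_for(species, order, slot_perms)
            if best is None or label < best:
                best = label
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# embedding / matching

# An embedding of a pattern into a species is a tuple over pattern molecules
# of (species molecule index, tuple mapping pattern site-token index -> slot).


def _token_slot_options(
    pmol: PatternMolecule, sp: SpeciesGraph, mol_i: int
) -> list[tuple[int, ...]]:
    """All injective token->slot assignments satisfying local constraints."""
    smol = sp.molecules[mol_i]
    per_token: list[list[int]] = []
    for ps in pmol.sites:
        opts = []
        for k, name in enumerate(smol.site_names):
            if name != ps.name:
                continue
            if ps.state is not None and smol.states[k] != ps.state:
                continue
            bonded = (mol_i, k) in sp.bonds
            if ps.bond == FREE and bonded:
                continue
            if ps.bond == BOUND_ANY and not bonded:
                continue
            if isinstance(ps.bond, int) and not bonded:
                continue
            opts.append(k)
        if not opts:
            return []
        per_token.append(opts)
    results = []
    for combo in itertools.product(*per_token):
        if len(set(combo)) == len(combo):
            results.append(tuple(combo))
    return results


def find_embeddings(pattern: PatternGraph, species: SpeciesGraph) -> list[tuple]:
    """All injective structure/state-preserving maps pattern -> species."""
    if pattern.compartment is not None and pattern.compartment != species.compartment:
        return []
    np_ = len(pattern.molecules)
    if np_ > len(species.molecules):
        return []
    cands: list[list[tuple[int, tuple[int, ...]]]] = []
    for pmol in pattern.molecules:
        lst = []
        for i, smol in enumerate(species.molecules):
            if smol.type != pmol.type:
                continue
            for slots in _token_slot_options(pmol, species, i):
                lst.append((i, slots))
        if not lst:
            return []
        cands.append(lst)
    results: list[tuple] = []
    assign: list[tuple[int, tuple[int, ...]]] = []
    used: set[int] = set()

    def bond_consistent(p_idx: int) -> bool:
        pmol = pattern.molecules[p_idx]
        s_idx, slots = assign[p_idx]
        for t, ps in enumerate(pmol.sites):
            if not isinstance(ps.bond, int):
                continue
            q, u = pattern.bond_partner[(p_idx, t)]
            if q > p_idx:
                continue  # partner not assigned yet
            qs_idx, q_slots = assign[q] if q != p_idx else (s_idx, slots)
            if species.bonds.get((s_idx, slots[t])) != (qs_idx, q_slots[u]):
                return False
        return True

    def backtrack(p_idx: int) -> None:
        if p_idx == np_:
            results.append(tuple(assign))
            return
        for s_idx, slots in cands[p_idx]:
            if s_idx in used:
                continue
            assign.append((s_idx, slots))
            if bond_consistent(p_idx):
                used.add(s_idx)
                backtrack(p_idx + 1)
                used.discard(s_idx)
            assign.pop()

    backtrack(0)
    return results


def count_embeddings(pattern: PatternGraph, species: SpeciesGraph) -> int:
    """Number of distinct injective embeddings (site-slot resolution)."""
    return len(find_embeddings(pattern, species))


def _pattern_as_pseudospecies(pattern: PatternGraph):
    """View a pattern as a species-like object for self-matching."""

    class _P:
        pass

    ps = _P()
    mols = []
    for pmol in pattern.molecules:
        m = _P()
        m.type = pmol.type
        m.site_names = tuple(s.name for s in pmol.sites)
        m.states = [s.state for s in pmol.sites]
        mols.append(m)
    ps.molecules = mols
    ps.compartment = pattern.compartment
    ps.bonds = dict(pattern.bond_partner)
    return ps


def pattern_automorphisms(pattern: PatternGraph) -> int:
    """Self-embeddings of a pattern, treating its constraints structurally.

    Token bond statuses must agree exactly (a token bound with id maps only
    to a bound-with-id token), which is what a rule symmetry requires.
    """
    pseudo = _pattern_as_pseudospecies(pattern)
    # reuse find_embeddings with a pattern whose FREE/ANY statuses match the
    # pseudo-species bond map: tokens with int ids appear in pseudo.bonds.
    probe = pattern.copy()
    for mol in probe.molecules:
        for ps in mol.sites:
            if ps.bond in (BOUND_ANY, UNSPEC):
                # these tokens are unbonded in the pseudo-species; match them
                # as free so status classes line up
                ps.bond = FREE
    # classify: int bonds stay (checked via pseudo.bonds); FREE stays free
    embs = find_embeddings(probe, pseudo)  # type: ignore[arg-type]
    # filter: wildcard statuses must map to tokens with the same status
    statuses = []
    for mol in pattern.molecules:
        statuses.append([ps.bond if not isinstance(ps.bond, int) else "#" for ps in mol.sites])
    count = 0
    for emb in embs:
        ok = True
        for p_idx, (q_idx, slots) in enumerate(emb):
            for t, u in enumerate(slots):
                if statuses[p_idx][t] != statuses[q_idx][u]:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            count += 1
    return max(count, 1)


# ---------------------------------------------------------------------------
# rules


@dataclass
class _Bind:
    a: tuple[int, int]  # (global reactant molecule idx, token idx)
    b: tuple[int, int]


@dataclass
class _Unbind:
    a: tuple[int, int]
    b: tuple[int, int]


@dataclass
class _SetState:
    mol: int
    token: int
    state: str


@dataclass
class _Delete:
    mol: int


@dataclass
class _Add:
    species_text: str


@dataclass
class _SetCompartment:
    compartment: str


class RxnRule:
    """A reaction rule: reactant patterns, product patterns, a rate reference.

    The transformation is derived by diffing reactant and product patterns
    under an explicit (default: positional) molecule correspondence; site
    tokens correspond positionally, so a molecule's sites must be written in
    the same order on both sides.  Rules may carry species-level
    ``include``/``exclude`` filter patterns per reactant (the analogue of
    BioNetGen's include_reactants/exclude_reactants) and a compartment
    restriction.  ``match_once`` collapses all embeddings into a single
    per-species channel with statistical factor 1 (transport semantics).
    """

    def __init__(
        self,
        name: str,
        reactants: Sequence[str | PatternGraph],
        products: Sequence[str | PatternGraph],
        rate: str | Sequence[str],
        *,
        mol_map: Sequence[int | None] | None = None,
        include: Sequence[tuple[int, str | PatternGraph]] = (),
        exclude: Sequence[tuple[int, str | PatternGraph]] = (),
        compartments: Sequence[str] | None = None,
        match_once: bool = False,
        signature: ModelSignature | None = None,
    ):
        def as_pattern(p):
            return parse_pattern(p, signature) if isinstance(p, str) else p

        self.name = name
        self.reactants = [as_pattern(p) for p in reactants]
        self.products = [as_pattern(p) for p in products]
        self.rate = (rate,) if isinstance(rate, str) else tuple(rate)
        self.include = [(i, as_pattern(p)) for i, p in include]
        self.exclude = [(i, as_pattern(p)) for i, p in exclude]
        self.compartments = tuple(compartments) if compartments else None
        self.match_once = match_once
        self._build_actions(mol_map)
        self._auto = 1
        for p in self.reactants:
            self._auto *= pattern_automorphisms(p)
        self._patterns_equal = (
            len(self.reactants) == 2
            and to_string(self.reactants[0]) == to_string(self.reactants[1])
        )

    # -- transformation derivation ------------------------------------------

    def _build_actions(self, mol_map: Sequence[int | None] | None) -> None:
        rmols: list[PatternMolecule] = []
        for p in self.reactants:
            rmols.extend(p.molecules)
        pmols: list[PatternMolecule] = []
        for p in self.products:
            pmols.extend(p.molecules)
        if mol_map is None:
            if len(pmols) <= len(rmols):
                mol_map = list(range(len(pmols))) + [None] * (len(rmols) - len(pmols))
            else:
                mol_map = list(range(len(rmols)))
        self.mol_map = list(mol_map)
        if len(self.mol_map) != len(rmols):
            raise ValidationError(f"rule {self.name}: mol_map length mismatch")
        mapped = [p for p in self.mol_map if p is not None]
        if len(set(mapped)) != len(mapped):
            raise ValidationError(f"rule {self.name}: atom map is not injective")
        for r_idx, p_idx in enumerate(self.mol_map):
            if p_idx is None:
                continue
            if rmols[r_idx].type != pmols[p_idx].type:
                raise ValidationError(
                    f"rule {self.name}: atom map pairs {rmols[r_idx].type} "
                    f"with {pmols[p_idx].type}"
                )
            rnames = [s.name for s in rmols[r_idx].sites]
            pnames = [s.name for s in pmols[p_idx].sites]
            if rnames != pnames:
                raise ValidationError(
                    f"rule {self.name}: site token order differs between sides "
                    f"for molecule {rmols[r_idx].type}"
                )
        inv = {p: r for r, p in enumerate(self.mol_map) if p is not None}
        actions: list = []

        def side_bonds(patterns: Sequence[PatternGraph]) -> set[frozenset]:
            bonds: set[frozenset] = set()
            offset = 0
            for pat in patterns:
                for (i, t), (j, u) in pat.bond_partner.items():
                    bonds.add(frozenset(((i + offset, t), (j + offset, u))))
                offset += len(pat.molecules)
            return bonds

        rbonds = side_bonds(self.reactants)
        pbonds = side_bonds(self.products)
        rbonds_mapped = set()
        for key in rbonds:
            (i, t), (j, u) = sorted(key)
            mi, mj = self.mol_map[i], self.mol_map[j]
            if mi is None or mj is None:
                continue
            rbonds_mapped.add(frozenset(((mi, t), (mj, u))))
        for key in rbonds_mapped - pbonds:
            (pi, t), (pj, u) = sorted(key)
            actions.append(_Unbind((inv[pi], t), (inv[pj], u)))
        for key in pbonds - rbonds_mapped:
            (pi, t), (pj, u) = sorted(key)
            if pi not in inv or pj not in inv:
                raise ValidationError(
                    f"rule {self.name}: bond formed on a synthesized molecule "
                    "is not supported"
                )
            actions.append(_Bind((inv[pi], t), (inv[pj], u)))
        for r_idx, p_idx in enumerate(self.mol_map):
            if p_idx is None:
                actions.append(_Delete(r_idx))
                continue
            for t, ps in enumerate(pmols[p_idx].sites):
                if ps.state is None:
                    continue
                rs = rmols[r_idx].sites[t]
                if rs.state != ps.state:
                    actions.append(_SetState(r_idx, t, ps.state))
        for p_idx, pmol in enumerate(pmols):
            if p_idx in inv:
                continue
            toks = []
            for ps in pmol.sites:
                t = ps.name
                if ps.state is not None:
                    t += f"~{ps.state}"
                toks.append(t)
            actions.append(_Add(f"{pmol.type}({','.join(toks)})"))
        pcomps = {p.compartment for p in self.products if p.compartment}
        rcomps = {p.compartment for p in self.reactants if p.compartment}
        if pcomps:
            if len(pcomps) > 1:
                raise ValidationError(f"rule {self.name}: conflicting product compartments")
            target = next(iter(pcomps))
            if rcomps != pcomps:
                actions.append(_SetCompartment(target))
        self.actions = actions

    # -- application --------------------------------------------------------

    def species_allowed(self, r_idx: int, species: SpeciesGraph) -> bool:
        if self.compartments is not None and species.compartment not in self.compartments:
            return False
        for i, pat in self.include:
            if i == r_idx and count_embeddings(pat, species) == 0:
                return False
        for i, pat in self.exclude:
            if i == r_idx and count_embeddings(pat, species) > 0:
                return False
        return True

    def arity(self) -> int:
        return len(self.reactants)

    def reversed(self, name: str, rate: str | Sequence[str]) -> "RxnRule":
        """Reverse rule for simple reversible transformations (no synth/deg)."""
        if any(isinstance(a, (_Delete, _Add)) for a in self.actions):
            raise ValidationError(f"rule {self.name}: cannot reverse synth/deg rule")
        n_p = sum(len(p.molecules) for p in self.products)
        inv_map: list[int | None] = [None] * n_p
        for r, p in enumerate(self.mol_map):
            inv_map[p] = r  # type: ignore[index]
        return RxnRule(
            name,
            [p.copy() for p in self.products],
            [p.copy() for p in self.reactants],
            rate,
            mol_map=inv_map,
            compartments=self.compartments,
            match_once=self.match_once,
        )

    def __repr__(self) -> str:  # pragma: no cover
        lhs = " + ".join(to_string(p, with_compartment=False) for p in self.reactants)
        rhs = " + ".join(to_string(p, with_compartment=False) for p in self.products)
        return f"RxnRule({self.name}: {lhs} -> {rhs})"


def _apply_embedding(
    rule: RxnRule,
    reactant_species: Sequence[SpeciesGraph],
    embedding: Sequence[tuple],
    signature: ModelSignature,
) -> list[SpeciesGraph]:
    """Apply rule actions under one embedding; return product species list."""
    comp0 = reactant_species[0].compartment if reactant_species else "PM"
    merged = SpeciesGraph([], compartment=comp0)
    offsets = []
    for sp in reactant_species:
        offsets.append(len(merged.molecules))
        base = len(merged.molecules)
        merged.molecules.extend(m.copy() for m in sp.molecules)
        for (i, k), (j, t) in sp.bonds.items():
            merged.bonds[(i + base, k)] = (j + base, t)
    # rule reactant molecule (global idx) -> (merged mol idx, token->slot)
    gmol: list[int] = []
    gslots: list[tuple[int, ...]] = []
    for r_idx, pat in enumerate(rule.reactants):
        emb = embedding[r_idx]
        for s_idx, slots in emb:
            gmol.append(offsets[r_idx] + s_idx)
            gslots.append(slots)

    def endpoint(ep: tuple[int, int]) -> tuple[int, int]:
        mol, token = ep
        return (gmol[mol], gslots[mol][token])

    deleted: set[int] = set()
    for action in rule.actions:
        if isinstance(action, _Bind):
            a, b = endpoint(action.a), endpoint(action.b)
            if a in merged.bonds or b in merged.bonds:
                raise ValidationError(f"rule {rule.name}: bond-forming site occupied")
            merged.bonds[a] = b
            merged.bonds[b] = a
        elif isinstance(action, _Unbind):
            a = endpoint(action.a)
            b = merged.bonds.pop(a, None)
            if b is not None:
                merged.bonds.pop(b, None)
        elif isinstance(action, _SetState):
            mol_i = gmol[action.mol]
            slot = gslots[action.mol][action.token]
            merged.molecules[mol_i].states[slot] = action.state
        elif isinstance(action, _Delete):
            deleted.add(gmol[action.mol])
        elif isinstance(action, _Add):
            sp_new = parse_species(action.species_text, signature, merged.compartment)
            base = len(merged.molecules)
            merged.molecules.extend(sp_new.molecules)
            for (i, k), (j, t) in sp_new.bonds.items():
                merged.bonds[(i + base, k)] = (j + base, t)
        elif isinstance(action, _SetCompartment):
            merged.compartment = action.compartment
    if deleted:
        for i in deleted:
            for k in [k for (j, k) in list(merged.bonds) if j == i]:
                b = merged.bonds.pop((i, k), None)
                if b is not None:
                    merged.bonds.pop(b, None)
        keep = [i for i in range(len(merged.molecules)) if i not in deleted]
        remap = {old: new for new, old in enumerate(keep)}
        merged.molecules = [merged.molecules[i] for i in keep]
        merged.bonds = {
            (remap[i], k): (remap[j], t) for (i, k), (j, t) in merged.bonds.items()
        }
    comps = merged.components() if merged.molecules else []
    products = []
    for comp in comps:
        remap = {old: new for new, old in enumerate(comp)}
        sub = SpeciesGraph(
            [merged.molecules[i].copy() for i in comp], compartment=merged.compartment
        )
        for (i, k), (j, t) in merged.bonds.items():
            if i in remap:
                sub.bonds[(remap[i], k)] = (remap[j], t)
        products.append(sub)
    return products


def apply_rule(
    rule: RxnRule,
    reactants: Sequence[SpeciesGraph],
    signature: ModelSignature,
) -> list[tuple[list[SpeciesGraph], Fraction]]:
    """Apply a rule to concrete reactant species.

    Returns one entry per distinct product class: (product species list,
    statistical factor).  The factor is the class's embedding count divided
    by the rule's reactant-pattern automorphisms; a bimolecular rule applied
    to two copies of the same species gets an extra 1/2.
    """
    if len(reactants) != rule.arity():
        raise ValidationError(
            f"rule {rule.name} expects {rule.arity()} reactants, got {len(reactants)}"
        )
    for r_idx, sp in enumerate(reactants):
        if not rule.species_allowed(r_idx, sp):
            return []
    if rule.arity() == 2 and reactants[0].compartment != reactants[1].compartment:
        return []
    emb_lists = [find_embeddings(pat, sp) for pat, sp in zip(rule.reactants, reactants)]
    if rule.arity() and any(not e for e in emb_lists):
        return []
    combos = list(itertools.product(*emb_lists)) if emb_lists else [()]
    if rule.match_once:
        combos = combos[:1]
    classes: dict[tuple[str, ...], list] = {}
    for combo in combos:
        products = _apply_embedding(rule, reactants, combo, signature)
        key = tuple(sorted(canonical_label(p) for p in products))
        if key not in classes:
            classes[key] = [products, 0]
        classes[key][1] += 1
    same_species = (
        rule.arity() == 2
        and canonical_label(reactants[0]) == canonical_label(reactants[1])
    )
    out = []
    for products, n_emb in classes.values():
        factor = Fraction(1) if rule.match_once else Fraction(n_emb, rule._auto)
        if same_species:
            factor /= 2
        out.append((products, factor))
    return out


# ---------------------------------------------------------------------------
# network generation


@dataclass
class Reaction:
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate_params: tuple[str, ...]
    stat_factor: Fraction
    rule: str

    def validate(self, n_species: int) -> None:
        if self.stat_factor < 0:
            raise ValidationError("negative statistical factor")
        for idx in self.reactants + self.products:
            if not (0 <= idx < n_species):
                raise ValidationError(f"reaction references invalid species index {idx}")


class ReactionNetwork:
    """Enumerated species + elementary reactions reached from the seeds."""

    def __init__(self, signature: ModelSignature):
        self.signature = signature
        self.species: list[SpeciesGraph] = []
        self.labels: list[str] = []
        self._index: dict[str, int] = {}
        self.reactions: list[Reaction] = []
        self.converged = True
        self.iterations = 0

    def add_species(self, sp: SpeciesGraph) -> tuple[int, bool]:
        label = canonical_label(sp)
        if label in self._index:
            return self._index[label], False
        idx = len(self.species)
        self.species.append(sp)
        self.labels.append(label)
        self._index[label] = idx
        return idx, True

    def index_of(self, sp: SpeciesGraph) -> int | None:
        return self._index.get(canonical_label(sp))

    def merged_reactions(self) -> dict[tuple, list[Reaction]]:
        """Group reactions sharing reactant/product multisets (provenance kept)."""
        groups: dict[tuple, list[Reaction]] = {}
        for rxn in self.reactions:
            key = (tuple(sorted(rxn.reactants)), tuple(sorted(rxn.products)))
            groups.setdefault(key, []).append(rxn)
        return groups

    def summary(self) -> dict:
        return {
            "n_species": len(self.species),
            "n_reactions": len(self.reactions),
            "n_reactions_merged": len(self.merged_reactions()),
            "converged": self.converged,
            "iterations": self.iterations,
        }


def _stoich_ok(sp: SpeciesGraph, max_stoich: Mapping | None) -> bool:
    if not max_stoich:
        return True
    counts = sp.molecule_counts()
    for key, cap in max_stoich.items():
        if isinstance(key, str):
            if counts.get(key, 0) > cap:
                return False
        else:
            if sum(counts.get(t, 0) for t in key) > cap:
                return False
    return True


def generate_network(
    seeds: Sequence[SpeciesGraph],
    rules: Sequence[RxnRule],
    signature: ModelSignature,
    *,
    max_iter: int = 30,
    max_species: int = 5000,
    max_stoich: Mapping | None = None,
    observer: Callable[[int, int], None] | None = None,
) -> ReactionNetwork:
    """Breadth-first fixed-point enumeration of species and reactions.

    Seeds are validated and deduplicated under canonical labeling; each
    iteration applies every rule to every species tuple involving at least
    one species discovered in the previous iteration.  Terminates when no
    new species or reactions appear, or flags non-convergence
    (``network.converged = False``) when a cap is exceeded; the partial
    network is still returned, never silently truncated.
    """
    if max_iter <= 0 or max_species <= 0:
        raise ValidationError("iteration and species caps must be positive")
    net = ReactionNetwork(signature)
    for sp in seeds:
        sp.validate(signature)
        if not _stoich_ok(sp, max_stoich):
            raise ValidationError("seed species violates max_stoich")
        net.add_species(sp)

    emb_cache: dict[tuple[int, int, int], bool] = {}

    def matches(rule_i: int, r_idx: int, sp_idx: int) -> bool:
        key = (rule_i, r_idx, sp_idx)
        if key not in emb_cache:
            rule = rules[rule_i]
            sp = net.species[sp_idx]
            emb_cache[key] = rule.species_allowed(r_idx, sp) and (
                count_embeddings(rule.reactants[r_idx], sp) > 0
            )
        return emb_cache[key]

    applied: set[tuple] = set()
    frontier = list(range(len(net.species)))
    iteration = 0
    first_pass = True
    while frontier or first_pass:
        first_pass = False
        iteration += 1
        if iteration > max_iter:
            net.converged = False
            break
        new_frontier: list[int] = []

        def register(rule: RxnRule, reactant_idx: tuple[int, ...], results) -> None:
            for products, factor in results:
                prod_idx = []
                ok = True
                news = []
                for p in products:
                    if not _stoich_ok(p, max_stoich):
                        ok = False
                        break
                    idx, is_new = net.add_species(p)
                    prod_idx.append(idx)
                    if is_new:
                        news.append(idx)
                if not ok:
                    continue
                new_frontier.extend(news)
                net.reactions.append(
                    Reaction(
                        reactants=reactant_idx,
                        products=tuple(sorted(prod_idx)),
                        rate_params=rule.rate,
                        stat_factor=factor,
                        rule=rule.name,
                    )
                )

        n_before = len(net.species)
        for rule_i, rule in enumerate(rules):
            if rule.arity() == 0:
                key = (rule_i,)
                if key in applied:
                    continue
                applied.add(key)
                register(rule, (), apply_rule(rule, (), signature))
            elif rule.arity() == 1:
                for i in frontier:
                    key = (rule_i, i)
                    if key in applied:
                        continue
                    applied.add(key)
                    if not matches(rule_i, 0, i):
                        continue
                    register(rule, (i,), apply_rule(rule, (net.species[i],), signature))
            else:
                if rule._patterns_equal:
                    cand_new = [i for i in frontier if matches(rule_i, 0, i)]
                    cand_all = [i for i in range(len(net.species)) if matches(rule_i, 0, i)]
                    for i in cand_new:
                        for j in cand_all:
                            a, b = min(i, j), max(i, j)
                            key = (rule_i, a, b)
                            if key in applied:
                                continue
                            applied.add(key)
                            register(
                                rule,
                                (a, b),
                                apply_rule(rule, (net.species[a], net.species[b]), signature),
                            )
                else:
                    cand0_new = [i for i in frontier if matches(rule_i, 0, i)]
                    cand1_new = [i for i in frontier if matches(rule_i, 1, i)]
                    cand0_all = [i for i in range(len(net.species)) if matches(rule_i, 0, i)]
                    cand1_all = [i for i in range(len(net.species)) if matches(rule_i, 1, i)]
                    pairs = {(i, j) for i in cand0_new for j in cand1_all}
                    pairs.update((i, j) for j in cand1_new for i in cand0_all)
                    for i, j in sorted(pairs):
                        key = (rule_i, "o", i, j)
                        if key in applied:
                            continue
                        applied.add(key)
                        register(
                            rule,
                            (i, j),
                            apply_rule(rule, (net.species[i], net.species[j]), signature),
                        )
        if len(net.species) > max_species:
            net.converged = False
            net.iterations = iteration
            break
        if observer:
            observer(iteration, len(net.species))
        frontier = sorted(set(new_frontier))
        net.iterations = iteration
        if not frontier and len(net.species) == n_before:
            break
    for rxn in net.reactions:
        rxn.validate(len(net.species))
    return net
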