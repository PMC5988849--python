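"""Rule engine: canonical labels, embeddings, rule application and network
generation, each validated against independent brute-force oracles."""

import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from angiotriad.rulegraph import (
    ModelSignature,
    MoleculeType,
    RxnRule,
    SiteDef,
    ValidationError,
    apply_rule,
    canonical_label,
    count_embeddings,
    find_embeddings,
    generate_network,
    parse_pattern,
    parse_species,
)

from conftest import random_species


# ---------------------------------------------------------------------------
# oracles


def species_to_nx(sp):
    """Encode a species as a colored graph for the networkx isomorphism oracle:
    one node per molecule (colored by type) and one node per site slot
    (colored by site name + state), sites attached to their molecule and
    bonded sites joined."""
    g = nx.Graph()
    for i, mol in enumerate(sp.molecules):
        g.add_node(("m", i), color=("mol", mol.type))
        for k, name in enumerate(mol.site_names):
            g.add_node(("s", i, k), color=("site", name, mol.states[k]))
            g.add_edge(("m", i), ("s", i, k))
    for (i, k), (j, t) in sp.bonds.items():
        g.add_edge(("s", i, k), ("s", j, t))
    return g


def isomorphic_oracle(a, b) -> bool:
    if a.compartment != b.compartment:
        return False
    return nx.is_isomorphic(
        species_to_nx(a), species_to_nx(b),
        node_match=lambda x, y: x["color"] == y["color"],
    )


def brute_force_embeddings(pattern, species) -> int:
    """Independent enumeration over all molecule/slot assignments."""
    if pattern.compartment is not None and pattern.compartment != species.compartment:
        return 0
    np_ = len(pattern.molecules)
    ns = len(species.molecules)
    count = 0
    for mol_map in itertools.permutations(range(ns), np_):
        slot_choices = []
        ok = True
        for p_idx, pmol in enumerate(pattern.molecules):
            smol = species.molecules[mol_map[p_idx]]
            if smol.type != pmol.type:
                ok = False
                break
            per_token = []
            for ps in pmol.sites:
                per_token.append([k for k, nm in enumerate(smol.site_names) if nm == ps.name])
            slot_choices.append(per_token)
        if not ok:
            continue
        for combo in itertools.product(
            *[itertools.product(*tokens) for tokens in slot_choices]
        ):
            valid = True
            for p_idx, slots in enumerate(combo):
                if len(set(slots)) != len(slots):
                    valid = False
                    break
                s_idx = mol_map[p_idx]
                smol = species.molecules[s_idx]
                for t, ps in enumerate(pattern.molecules[p_idx].sites):
                    k = slots[t]
                    if ps.state is not None and smol.states[k] != ps.state:
                        valid = False
                        break
                    bonded = (s_idx, k) in species.bonds
                    if ps.bond == "free" and bonded:
                        valid = False
                        break
                    if ps.bond == "+" and not bonded:
                        valid = False
                        break
                    if isinstance(ps.bond, int):
                        if not bonded:
                            valid = False
                            break
                        q, u = pattern.bond_partner[(p_idx, t)]
                        partner = species.bonds[(s_idx, k)]
                        if partner != (mol_map[q], combo[q][u]):
                            valid = False
                            break
                if not valid:
                    break
            if valid:
                count += 1
    return count


# ---------------------------------------------------------------------------
# canonical labeling


class TestCanonicalLabel:
    def test_single_molecule_order_invariant(self, full_model):
        sig = full_model.signature
        a = parse_species("VEGFR2(L,Y1175~u,c)", sig)
        b = parse_species("VEGFR2(c,L,Y1175~u)", sig)
        assert canonical_label(a) == canonical_label(b)

    def test_symmetric_dimer_all_orderings(self, full_model):
        """A ligand bridging two identical receptors: every molecule ordering
        yields the same label (exhaustive permutation check)."""
        sig = full_model.signature
        texts = [
            "VEGFR2(L!1,Y1175~u,c).VEGF(r!1,r!2,nrp1bd).VEGFR2(L!2,Y1175~u,c)",
            "VEGF(r!2,r!1,nrp1bd).VEGFR2(L!1,Y1175~u,c).VEGFR2(L!2,Y1175~u,c)",
            "VEGFR2(L!2,Y1175~u,c).VEGFR2(L!1,Y1175~u,c).VEGF(r!1,r!2,nrp1bd)",
        ]
        labels = {canonical_label(parse_species(t, sig)) for t in texts}
        assert len(labels) == 1

    def test_state_is_part_of_identity(self, full_model):
        sig = full_model.signature
        up = parse_species(
            "VEGFR2(L!1,Y1175~u,c).VEGF(r!1,r!2,nrp1bd).VEGFR2(L!2,Y1175~p,c)", sig)
        uu = parse_species(
            "VEGFR2(L!1,Y1175~u,c).VEGF(r!1,r!2,nrp1bd).VEGFR2(L!2,Y1175~u,c)", sig)
        assert canonical_label(up) != canonical_label(uu)

    def test_compartment_is_part_of_identity(self, full_model):
        sig = full_model.signature
        a = parse_species("VEGFR2(L,Y1175~u,c)", sig, "PM")
        b = parse_species("VEGFR2(L,Y1175~u,c)", sig, "SE1")
        assert canonical_label(a) != canonical_label(b)

    def test_matches_isomorphism_oracle_on_random_species(self, bivalent_signature):
        """Label equality coincides with graph isomorphism on random complexes."""
        rng = np.random.default_rng(7)
        species = []
        for _ in range(40):
            sp = random_species(bivalent_signature, rng, n_mols=int(rng.integers(1, 5)))
            if sp is not None:
                species.append(sp)
        assert len(species) > 20
        for a, b in itertools.combinations(species[:20], 2):
            assert (canonical_label(a) == canonical_label(b)) == isomorphic_oracle(a, b)

    def test_full_network_labels_match_oracle_classes(self, full_network):
        """No two distinct network species are isomorphic, per the oracle."""
        rng = np.random.default_rng(0)
        idx = rng.choice(len(full_network.species), size=30, replace=False)
        for a_i, b_i in itertools.combinations(idx, 2):
            a, b = full_network.species[a_i], full_network.species[b_i]
            assert not isomorphic_oracle(a, b)

    def test_malformed_graph_rejected(self, full_model):
        sig = full_model.signature
        with pytest.raises(ValidationError):
            parse_species("VEGFR2(L!1,Y1175~u,c)", sig)  # dangling bond
        with pytest.raises(ValidationError):
            parse_species("VEGFR2(L,Y1175~x,c)", sig)  # unknown state
        with pytest.raises(ValidationError):
            parse_species("VEGFR2(L,c)", sig)  # missing required state


# ---------------------------------------------------------------------------
# embeddings


class TestEmbeddings:
    def test_free_receptor(self, full_model):
        sig = full_model.signature
        pat = parse_pattern("VEGFR2(L)", sig)
        sp = parse_species("VEGFR2(L,Y1175~u,c)", sig)
        assert count_embeddings(pat, sp) == 1

    def test_bivalent_ligand_two_free_sites(self, full_model):
        sig = full_model.signature
        pat = parse_pattern("VEGF(r)", sig)
        sp = parse_species("VEGF(r,r,nrp1bd)", sig)
        assert count_embeddings(pat, sp) == 2

    def test_absent_molecule_gives_zero(self, full_model):
        sig = full_model.signature
        pat = parse_pattern("TSP1(cd47bd!1).CD47(tsp1bd!1)", sig)
        sp = parse_species("CD47(vegfr2bd,tsp1bd)", sig)
        assert count_embeddings(pat, sp) == 0

    def test_matches_brute_force_on_model_patterns(self, full_model, full_network):
        """Every rule pattern against a sample of network species agrees with
        independent exhaustive enumeration."""
        rng = np.random.default_rng(3)
        idx = rng.choice(len(full_network.species), size=25, replace=False)
        patterns = [p for rule in full_model.rules for p in rule.reactants]
        for i in idx:
            sp = full_network.species[i]
            for pat in patterns:
                assert count_embeddings(pat, sp) == brute_force_embeddings(pat, sp), (
                    f"pattern mismatch on species {full_network.labels[i]}"
                )


# ---------------------------------------------------------------------------
# rule application


class TestApplyRule:
    def test_ligand_binding_statistical_factor_two(self, full_model):
        """Free bivalent VEGF + free receptor: one product class, factor 2."""
        sig = full_model.signature
        rule = next(r for r in full_model.rules if r.name == "vegf_r2_bind")
        vegf = parse_species("VEGF(r,r,nrp1bd)", sig)
        r2 = parse_species("VEGFR2(L,Y1175~u,c)", sig)
        results = apply_rule(rule, (vegf, r2), sig)
        assert len(results) == 1
        products, factor = results[0]
        assert factor == Fraction(2)
        assert len(products) == 1
        assert len(products[0].molecules) == 2

    def test_phosphorylation_needs_bridged_dimer(self, full_model):
        sig = full_model.signature
        rule = next(r for r in full_model.rules if r.name == "r2_phos")
        monomer = parse_species(
            "VEGF(r!1,r,nrp1bd).VEGFR2(L!1,Y1175~u,c)", sig)
        assert apply_rule(rule, (monomer,), sig) == []

    def test_tsp1_binds_precoupled_cd47_factor_one(self, full_model):
        sig = full_model.signature
        rule = next(r for r in full_model.rules if r.name == "tsp1_bind")
        tsp1 = parse_species("TSP1(cd47bd)", sig)
        cd47_r2 = parse_species(
            "CD47(vegfr2bd!1,tsp1bd).VEGFR2(c!1,L,Y1175~u)", sig)
        results = apply_rule(rule, (tsp1, cd47_r2), sig)
        assert len(results) == 1
        products, factor = results[0]
        assert factor == Fraction(1)
        assert len(products[0].molecules) == 3
        # free CD47 is not a substrate (requires coupled receptor)
        cd47_free = parse_species("CD47(vegfr2bd,tsp1bd)", sig)
        assert apply_rule(rule, (tsp1, cd47_free), sig) == []

    def test_unbinding_splits_into_two_species(self, full_model):
        sig = full_model.signature
        rule = next(r for r in full_model.rules if r.name == "vegf_r2_unbind")
        complex_ = parse_species("VEGF(r!1,r,nrp1bd).VEGFR2(L!1,Y1175~u,c)", sig)
        results = apply_rule(rule, (complex_,), sig)
        assert len(results) == 1
        products, factor = results[0]
        assert len(products) == 2
        assert factor == Fraction(1)

    def test_degradation_releases_partners(self, full_model):
        """Deleting the receptor from an internalized complex leaves its
        partners as separate species (CD47 is conserved)."""
        sig = full_model.signature
        rule = next(r for r in full_model.rules if r.name == "deg_u")
        sp = parse_species(
            "VEGFR2(c!1,L,Y1175~u).CD47(vegfr2bd!1,tsp1bd)", sig, "SE1")
        results = apply_rule(rule, (sp,), sig)
        assert len(results) == 1
        products, _ = results[0]
        assert len(products) == 1
        assert products[0].molecules[0].type == "CD47"
        assert products[0].compartment == "SE1"


# ---------------------------------------------------------------------------
# network generation: toy systems vs frozen brute-force enumerations


def reaction_set(net):
    """Comparable view: (sorted reactant labels, sorted product labels,
    rate names, factor)."""
    out = set()
    for r in net.reactions:
        out.add((
            tuple(sorted(net.labels[i] for i in r.reactants)),
            tuple(sorted(net.labels[i] for i in r.products)),
            r.rate_params,
            r.stat_factor,
        ))
    return out


class TestToyNetworks:
    def test_monovalent_binding(self, lr_signature):
        """L + R reversible: 3 species, 2 irreversible reactions."""
        sig = lr_signature
        fwd = RxnRule("bind", ["L(s)", "R(s)"], ["L(s!1).R(s!1)"], "kon", signature=sig)
        rev = fwd.reversed("unbind", "koff")
        net = generate_network(
            [parse_species("L(s)", sig), parse_species("R(s)", sig)], [fwd, rev], sig)
        assert net.converged
        assert len(net.species) == 3
        assert len(net.reactions) == 2
        expected = {
            (("@PM:L()", "@PM:R()"), ("@PM:L(s!1).R(s!1)",), ("kon",), Fraction(1)),
            (("@PM:L(s!1).R(s!1)",), ("@PM:L()", "@PM:R()"), ("koff",), Fraction(1)),
        }
        assert reaction_set(net) == expected

    def test_bivalent_symmetric(self, bivalent_signature):
        """V(r,r) + R(l): 4 species (V, R, VR, RVR); embedding-channel count 6."""
        sig = bivalent_signature
        b1 = RxnRule("b1", ["V(r)", "R(l)"], ["V(r!1).R(l!1)"], "kon",
                     exclude=[(0, "V(r!+)")], signature=sig)
        b2 = RxnRule("b2", ["V(r!+,r)", "R(l)"], ["V(r!+,r!1).R(l!1)"], "kon2",
                     signature=sig)
        u1 = RxnRule("u1", ["V(r!1).R(l!1)"], ["V(r)", "R(l)"], "koff", signature=sig)
        net = generate_network(
            [parse_species("V(r,r)", sig), parse_species("R(l)", sig)],
            [b1, b2, u1], sig)
        assert net.converged
        assert len(net.species) == 4
        # solution binding has factor 2 (two equivalent sites); dimer opening
        # likewise; total embedding channels = 2 + 1 + 1 + 2 = 6
        assert sum(r.stat_factor for r in net.reactions) == 6
        by_rule = {r.rule: r.stat_factor for r in net.reactions}
        assert by_rule["b1"] == 2 and by_rule["b2"] == 1

    def test_heterodimer(self):
        """A + B via distinct sites: no homodimers appear."""
        sig = ModelSignature([
            MoleculeType("A", (SiteDef("b"),)),
            MoleculeType("B", (SiteDef("a"),)),
        ])
        fwd = RxnRule("ab", ["A(b)", "B(a)"], ["A(b!1).B(a!1)"], "kon", signature=sig)
        net = generate_network(
            [parse_species("A(b)", sig), parse_species("B(a)", sig)],
            [fwd, fwd.reversed("ba", "koff")], sig)
        assert len(net.species) == 3
        assert {len(sp.molecules) for sp in net.species} == {1, 1, 2}

    def test_state_change(self):
        """Two-state site under a catalytic flip: exactly the 2 state species."""
        sig = ModelSignature([MoleculeType("X", (SiteDef("s", ("off", "on")),))])
        up = RxnRule("up", ["X(s~off)"], ["X(s~on)"], "kact", signature=sig)
        down = RxnRule("down", ["X(s~on)"], ["X(s~off)"], "kdeact", signature=sig)
        net = generate_network([parse_species("X(s~off)", sig)], [up, down], sig)
        assert sorted(net.labels) == ["@PM:X(s~off)", "@PM:X(s~on)"]
        assert len(net.reactions) == 2

    def test_transport(self):
        """Compartment-changing rule: species duplicated across compartments."""
        sig = ModelSignature([MoleculeType("X", (SiteDef("s"),))])
        go = RxnRule("go", ["X()"], ["@SE1:X()"], "kin",
                     compartments=["PM"], match_once=True, signature=sig)
        back = RxnRule("back", ["X()"], ["@PM:X()"], "kout",
                       compartments=["SE1"], match_once=True, signature=sig)
        net = generate_network([parse_species("X(s)", sig)], [go, back], sig)
        assert sorted(net.labels) == ["@PM:X()", "@SE1:X()"]
        assert len(net.reactions) == 2
        assert all(r.stat_factor == 1 for r in net.reactions)

    def test_synthesis_and_degradation(self):
        sig = ModelSignature([MoleculeType("X", (SiteDef("s"),))])
        synth = RxnRule("synth", [], ["@PM:X(s)"], "ks", signature=sig)
        deg = RxnRule("deg", ["X()"], [], "kd", signature=sig)
        net = generate_network([], [synth, deg], sig)
        assert net.labels == ["@PM:X()"]
        kinds = {(r.rule, r.reactants, r.products) for r in net.reactions}
        assert kinds == {("synth", (), (0,)), ("deg", (0,), ())}


class TestGenerationProperties:
    def test_seed_order_invariance(self, full_model):
        seeds = list(full_model.seeds)
        net_a = generate_network(seeds, full_model.rules, full_model.signature,
                                 max_stoich=full_model.max_stoich)
        net_b = generate_network(seeds[::-1], full_model.rules, full_model.signature,
                                 max_stoich=full_model.max_stoich)
        assert set(net_a.labels) == set(net_b.labels)
        assert reaction_set(net_a) == reaction_set(net_b)

    def test_idempotence(self, bivalent_signature):
        sig = bivalent_signature
        b1 = RxnRule("b1", ["V(r)", "R(l)"], ["V(r!1).R(l!1)"], "kon",
                     exclude=[(0, "V(r!+)")], signature=sig)
        b2 = RxnRule("b2", ["V(r!+,r)", "R(l)"], ["V(r!+,r!1).R(l!1)"], "kon2",
                     signature=sig)
        seeds = [parse_species("V(r,r)", sig), parse_species("R(l)", sig)]
        net1 = generate_network(seeds, [b1, b2], sig)
        net2 = generate_network(list(net1.species), [b1, b2], sig)
        assert set(net2.labels) == set(net1.labels)
        assert reaction_set(net2) == reaction_set(net1)

    def test_molecule_conservation_in_reactions(self, full_network):
        """Molecules are conserved reactant->product except for explicit
        synthesis/degradation/decay rules."""
        exempt = ("synthesis", "deg", "decay")
        for r in full_network.reactions:
            if any(tag in r.rule for tag in exempt):
                continue
            before: dict = {}
            after: dict = {}
            for i in r.reactants:
                for t, n in full_network.species[i].molecule_counts().items():
                    before[t] = before.get(t, 0) + n
            for i in r.products:
                for t, n in full_network.species[i].molecule_counts().items():
                    after[t] = after.get(t, 0) + n
            assert before == after, f"rule {r.rule} does not conserve molecules"

    def test_species_cap_flags_nonconvergence(self, full_model):
        net = generate_network(
            full_model.seeds, full_model.rules, full_model.signature,
            max_species=20, max_stoich=full_model.max_stoich)
        assert not net.converged

    def test_iteration_cap_flags_nonconvergence(self, full_model):
        net = generate_network(
            full_model.seeds, full_model.rules, full_model.signature,
            max_iter=2, max_stoich=full_model.max_stoich)
        assert not net.converged

    def test_invalid_caps_rejected(self, full_model):
        with pytest.raises(ValidationError):
            generate_network(full_model.seeds, full_model.rules,
                             full_model.signature, max_iter=0)
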