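"""Shared fixtures: toy signatures and the compiled full model (session-scoped,
since network generation and pre-equilibration dominate test cost)."""

import numpy as np
import pytest

from angiotriad.model import build_model
from angiotriad.ode import compile_network
from angiotriad.rulegraph import (
    ModelSignature,
    MoleculeType,
    RxnRule,
    SiteDef,
    parse_species,
)


@pytest.fixture(scope="session")
def lr_signature():
    """Monovalent ligand-receptor toy."""
    return ModelSignature([
        MoleculeType("L", (SiteDef("s"),)),
        MoleculeType("R", (SiteDef("s"),)),
    ])


@pytest.fixture(scope="session")
def bivalent_signature():
    """Bivalent ligand V(r,r) + monovalent receptor R(l)."""
    return ModelSignature([
        MoleculeType("V", (SiteDef("r"), SiteDef("r"))),
        MoleculeType("R", (SiteDef("l"),)),
    ])


@pytest.fixture(scope="session")
def full_model():
    return build_model()


@pytest.fixture(scope="session")
def full_network(full_model):
    net = full_model.generate()
    assert net.converged
    return net


@pytest.fixture(scope="session")
def full_system(full_model, full_network):
    return compile_network(full_model, full_network)


@pytest.fixture(scope="session")
def rest_state(full_system):
    from angiotriad.ode import preequilibrate

    return preequilibrate(full_system, rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="session")
def control_result(full_model):
    """Control stimulation (50 ng/ml VEGF, no TSP1)."""
    from dataclasses import replace

    from angiotriad.experiments import Protocol, run_protocol

    return run_protocol(full_model, replace(Protocol(), tsp1_nM=0.0))


def random_species(signature, rng, n_mols=3):
    """Random connected species over the bivalent toy signature (test helper)."""
    from angiotriad.rulegraph import Molecule, SpeciesGraph

    mols = []
    for _ in range(n_mols):
        name = rng.choice(list(signature.types))
        mols.append(Molecule(signature[name]))
    sp = SpeciesGraph(mols, compartment="PM")
    # bond random free site pairs until connected
    for i in range(1, n_mols):
        free_a = [(j, k) for j in range(i) for k in range(len(mols[j].site_names))
                  if (j, k) not in sp.bonds]
        free_b = [k for k in range(len(mols[i].site_names)) if (i, k) not in sp.bonds]
        if not free_a or not free_b:
            return None
        a = free_a[rng.integers(len(free_a))]
        sp.add_bond(a, (i, free_b[0]))
    return sp
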