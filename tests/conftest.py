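from __future__ import annotations

import random

import pytest

import pathwayqc as pq
from pathwayqc.model import Connector, ConnectorRole, Entity, PathwayModel, Process


@pytest.fixture(scope="session")
def registry() -> pq.RuleRegistry:
    return pq.default_registry()


@pytest.fixture(scope="session")
def constraints(registry):
    return registry.constraints


def single_process_model(event: str, seed: int = 0) -> tuple[PathwayModel, str]:
    """A one-process clean model for *event*; returns (model, process_id)."""
    m = pq.make_clean_model(
        pq.FixtureSpec(seed=seed, n_processes=1, event_palette=(event,))
    )
    (pid,) = m.processes
    return m, pid


@pytest.fixture
def chain_model() -> PathwayModel:
    """A -> P -> B, both proteins."""
    m = PathwayModel(model_id="chain")
    m.add_entity(Entity(id="A", entity_class=pq.EntityClass.PROTEIN))
    m.add_entity(Entity(id="B", entity_class=pq.EntityClass.PROTEIN))
    m.add_process(Process(id="P", biological_event="ME_UnknownActivation"))
    m.add_connector(Connector(id="c1", role=ConnectorRole.SUBSTRATE,
                              process_id="P", entity_id="A"))
    m.add_connector(Connector(id="c2", role=ConnectorRole.PRODUCT,
                              process_id="P", entity_id="B"))
    m.check()
    return m


def scramble(model: PathwayModel, seed: int, n_mutations: int = 12) -> PathwayModel:
    """Random unverified perturbations (for engine-vs-oracle comparison)."""
    rng = random.Random(seed)
    m = model.copy()
    classes = list(pq.EntityClass)
    ccs = [None, "CC_Cytosol", "CC_Nucleoplasm", "CC_PlasmaMembrane",
           "CC_Cytoplasm", "CC_Extracellular"]
    for _ in range(n_mutations):
        kind = rng.randrange(6)
        if kind == 0 and m.entities:
            e = m.entities[rng.choice(sorted(m.entities))]
            e.entity_class = rng.choice(classes)
            e.component_ids = ()
        elif kind == 1 and m.entities:
            e = m.entities[rng.choice(sorted(m.entities))]
            e.cell_component = rng.choice(ccs)
        elif kind == 2 and m.entities:
            e = m.entities[rng.choice(sorted(m.entities))]
            e.feature_types = frozenset()
            if rng.randrange(2):
                e.unification_xrefs = frozenset()
        elif kind == 3 and m.connectors:
            c = m.connectors[rng.choice(sorted(m.connectors))]
            c.stoichiometry = rng.randrange(1, 25)
        elif kind == 4 and m.connectors:
            del m.connectors[rng.choice(sorted(m.connectors))]
        elif kind == 5 and m.connectors:
            ref = m.connectors[rng.choice(sorted(m.connectors))]
            dup_id = f"dup{rng.randrange(10**6)}"
            if dup_id not in m.connectors:
                m.add_connector(Connector(
                    id=dup_id,
                    role=rng.choice(list(ConnectorRole)),
                    process_id=ref.process_id, entity_id=ref.entity_id,
                    stoichiometry=rng.randrange(1, 4),
                ))
    m.check()
    return m
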