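"""Graph data model: invariants, predicates, serialization."""

import json

import pytest
from hypothesis import given, settings, strategies as st

import pathwayqc as pq
from pathwayqc.model import (
    Connector, ConnectorRole, Entity, PathwayModel, Process, Xref,
    dumps_model, loads_model, to_graphml,
)

from conftest import single_process_model

MINIMAL = json.dumps({
    "model_id": "tiny",
    "entities": [{"id": "e1", "class": "Protein"}],
    "processes": [{"id": "p1", "event": "ME_Binding"}],
    "connectors": [{"id": "c1", "role": "OutputProcessBiological",
                    "process": "p1", "entity": "e1"}],
})


class TestClassHierarchy:
    @pytest.mark.parametrize("cls", list(pq.EntityClass))
    def test_everything_is_an_entity(self, cls):
        assert pq.is_a(cls, pq.EntityClass.ENTITY)

    def test_concrete_classes_are_not_interchangeable(self):
        assert not pq.is_a(pq.EntityClass.PROTEIN, pq.EntityClass.COMPLEX)
        assert pq.is_a(pq.EntityClass.COMPLEX, pq.EntityClass.COMPLEX)
        assert not pq.is_a(pq.EntityClass.ENTITY, pq.EntityClass.COMPLEX)


class TestLoading:
    def test_minimal_document(self):
        m = loads_model(MINIMAL)
        assert (len(m.entities), len(m.processes), len(m.connectors)) == (1, 1, 1)

    def test_malformed_json_has_line_context(self):
        with pytest.raises(pq.ModelError, match="line"):
            loads_model("{\n  broken")

    def test_dangling_reference_names_connector(self):
        doc = json.loads(MINIMAL)
        doc["connectors"][0]["entity"] = "ghost"
        with pytest.raises(pq.ModelError, match="c1.*ghost"):
            loads_model(json.dumps(doc))

    def test_all_offenses_reported_together(self):
        doc = json.loads(MINIMAL)
        doc["connectors"][0]["entity"] = "ghost"
        doc["processes"][0]["event"] = ""
        with pytest.raises(pq.ModelError) as err:
            loads_model(json.dumps(doc))
        assert len(err.value.offenses) == 2

    def test_duplicate_ids_rejected(self):
        doc = json.loads(MINIMAL)
        doc["entities"].append(dict(doc["entities"][0]))
        with pytest.raises(pq.ModelError, match="duplicate"):
            loads_model(json.dumps(doc))

    def test_process_without_event_rejected(self):
        doc = json.loads(MINIMAL)
        del doc["processes"][0]["event"]
        with pytest.raises(pq.ModelError, match="biological event"):
            loads_model(json.dumps(doc))

    def test_strict_mode_rejects_unknown_keys_lax_preserves(self):
        doc = json.loads(MINIMAL)
        doc["entities"][0]["kinetics"] = {"v": 1.0}
        text = json.dumps(doc)
        with pytest.raises(pq.ModelError, match="unknown keys"):
            loads_model(text, strict=True)
        m = loads_model(text)
        assert m.entities["e1"].annotations["kinetics"] == {"v": 1.0}

    def test_unknown_vocabulary_is_a_notice_not_an_error(self):
        doc = json.loads(MINIMAL)
        doc["processes"][0]["event"] = "ME_NotARealEvent"
        m = loads_model(json.dumps(doc))
        assert any("ME_NotARealEvent" in n for n in m.vocabulary_notices())

    def test_connector_joining_two_processes_rejected(self):
        m = PathwayModel()
        m.add_process(Process(id="p1", biological_event="ME_Binding"))
        m.add_process(Process(id="p2", biological_event="ME_Binding"))
        m.connectors["c1"] = Connector(
            id="c1", role=ConnectorRole.SUBSTRATE,
            process_id="p1", entity_id="p2")
        with pytest.raises(pq.ModelError):
            m.check()

    def test_self_component_cycle_rejected(self):
        m = PathwayModel()
        m.add_entity(Entity(id="x", entity_class=pq.EntityClass.COMPLEX,
                            component_ids=("y",)))
        m.add_entity(Entity(id="y", entity_class=pq.EntityClass.COMPLEX,
                            component_ids=("x",)))
        with pytest.raises(pq.ModelError, match="transitive component"):
            m.check()


class TestSerialization:
    def test_empty_model_round_trip(self):
        m = PathwayModel(model_id="empty")
        assert loads_model(dumps_model(m)) == m
        doc = json.loads(dumps_model(m))
        assert doc["entities"] == [] and doc["connectors"] == []

    def test_stoichiometry_default_written_explicitly(self):
        m = loads_model(MINIMAL)
        doc = json.loads(dumps_model(m))
        assert doc["connectors"][0]["stoichiometry"] == 1

    def test_save_is_deterministic(self):
        m, _ = single_process_model("ME_Internalization")
        assert dumps_model(m) == dumps_model(m)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(0, 15))
    def test_load_save_identity_on_generated_fixtures(self, seed, n):
        m = pq.make_clean_model(pq.FixtureSpec(seed=seed, n_processes=n))
        assert loads_model(dumps_model(m)) == m


class TestPredicates:
    def test_role_scans_match_figure_roles(self):
        m = PathwayModel()
        m.add_entity(Entity(id="A"))
        m.add_entity(Entity(id="B"))
        m.add_process(Process(id="P", biological_event="ME_Binding"))
        m.add_connector(Connector(id="c1", role=ConnectorRole.SUBSTRATE,
                                  process_id="P", entity_id="A"))
        m.add_connector(Connector(id="c2", role=ConnectorRole.ACTIVATOR,
                                  process_id="P", entity_id="B"))
        assert {e.id for e, _ in m.has_input("P")} == {"A", "B"}
        assert [e.id for e, _ in m.has_inputprocess("P")] == ["A"]
        assert m.has_output("P") == []

    def test_isolated_process_has_empty_scans(self):
        m = PathwayModel()
        m.add_process(Process(id="P", biological_event="ME_Binding"))
        assert m.has_input("P") == m.has_inputprocess("P") == m.has_output("P") == []

    def test_unknown_id_is_lookup_error(self, chain_model):
        with pytest.raises(pq.LookupIdError):
            chain_model.has_input("nope")
        with pytest.raises(pq.LookupIdError):
            chain_model.connectors_between("P", "nope")

    def test_connectors_between_counts_double_role(self, chain_model):
        chain_model.add_connector(Connector(
            id="c3", role=ConnectorRole.ACTIVATOR,
            process_id="P", entity_id="A"))
        assert len(chain_model.connectors_between("P", "A")) == 2
        assert chain_model.connectors_between("P", "B") == [
            chain_model.connectors["c2"]]

    def test_unconnected_pair_is_empty(self, chain_model):
        chain_model.add_entity(Entity(id="C"))
        assert chain_model.connectors_between("P", "C") == []

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_role_scans_union_equals_edge_scan(self, seed):
        m = pq.make_clean_model(pq.FixtureSpec(seed=seed, n_processes=8))
        for pid in m.processes:
            brute = sorted(c.id for c in m.connectors.values()
                           if c.process_id == pid)
            scanned = sorted(
                c.id for _, c in m.has_input(pid) + m.has_output(pid))
            assert scanned == brute
            # the input family subsumes the substrate scan
            inputs = {c.id for _, c in m.has_input(pid)}
            assert {c.id for _, c in m.has_inputprocess(pid)} <= inputs


class TestXref:
    def test_same_as_is_case_insensitive(self):
        assert Xref("TRANSPATH", "MO123").same_as(Xref("transpath", "mo123"))
        assert not Xref("TRANSPATH", "MO123").same_as(Xref("TRANSPATH", "MO124"))

    def test_parse_rejects_bare_accession(self):
        with pytest.raises(ValueError):
            Xref.parse("no-separator")


def test_graphml_export_contains_roles_and_kinds(chain_model):
    xml = to_graphml(chain_model)
    assert "InputProcessBiological" in xml and "graphml" in xml
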