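"""Event-specific constraint checking: the 36 rules in five groups."""

import json

import pytest

import pathwayqc as pq
from pathwayqc.events import (
    ConstraintConfigError, check_event_process, check_group2,
    check_internalization, check_stoichiometry_event, load_constraint_table,
)
from pathwayqc.fixtures import _candidate_mutations, _process_warnings
from pathwayqc.model import Connector, ConnectorRole, Entity, Xref
from pathwayqc.report import WarningCategory as WC
from pathwayqc.vocab import RULE_COVERED_EVENTS

from conftest import single_process_model


def categories(warnings):
    return [w.category for w in warnings]


# ---------------------------------------------------------------------------
# Constraint table


class TestConstraintTable:
    def test_shipped_default_has_36_constraints_in_expected_groups(self, constraints):
        assert len(constraints) == 36
        sizes = {}
        for con in constraints.values():
            sizes[con.group] = sizes.get(con.group, 0) + 1
        assert sizes == {1: 11, 2: 15, 3: 3, 4: 3, 5: 4}

    def test_feature_map_total_on_group2_but_not_injective(self, registry):
        group2 = [c.event for c in registry.constraints.values() if c.group == 2]
        assert set(group2) <= set(registry.feature_map)
        # two distinct phosphorylation events map onto one modified state
        assert (registry.feature_map["ME_Phosphorylation"]
                == registry.feature_map["ME_Autophosphorylation"]
                == "FT_Phosphorylated")

    def test_truncated_table_rejected_in_strict_mode(self, constraints):
        doc = {"feature_map": {}, "constraints": [
            c.to_json() for e, c in sorted(constraints.items())
        ][:35]}
        with pytest.raises(ConstraintConfigError, match="35"):
            load_constraint_table(json.dumps(doc), strict=True)

    def test_duplicate_event_rejected_with_row_context(self):
        rec = {"event": "ME_Binding", "group": 1}
        doc = {"constraints": [rec, rec]}
        with pytest.raises(ConstraintConfigError, match=r"constraints\[1\]"):
            load_constraint_table(json.dumps(doc), strict=False)

    def test_malformed_spec_rejected_with_row_context(self):
        doc = {"constraints": [{"event": "ME_X", "group": 9}]}
        with pytest.raises(ConstraintConfigError, match="group"):
            load_constraint_table(json.dumps(doc), strict=False)

    def test_user_override_round_trip(self, constraints):
        doc = json.loads(
            __import__("importlib.resources", fromlist=["files"])
            .files("pathwayqc").joinpath("data/constraints.json").read_text()
        )
        for rec in doc["constraints"]:
            if rec["event"] == "ME_Translation":
                del rec["provenance"]  # user tables default to provenance=user
                for p in rec["properties"]:
                    if p["property"] == "cell_component":
                        p["value"] = "CC_EndoplasmicReticulum"
        loaded, _ = load_constraint_table(json.dumps(doc), strict=True)
        con = loaded["ME_Translation"]
        assert con.provenance == "user"
        assert any(p.value == "CC_EndoplasmicReticulum"
                   for p in con.properties)


# ---------------------------------------------------------------------------
# Printed rules, pinned


class TestPrintedRules:
    def test_dna_binding_needs_a_dna_substrate_and_complex_product(self, constraints):
        m, pid = single_process_model("ME_DNABinding")
        assert check_event_process(m, pid, constraints["ME_DNABinding"]) == []
        # losing the Dna substrate type breaks the at-least-one clause
        for e, _ in m.has_inputprocess(pid):
            e.entity_class = pq.EntityClass.PROTEIN
        got = check_event_process(m, pid, constraints["ME_DNABinding"])
        assert categories(got) == [WC.WRONG_TYPE]

    def test_acetylation_product_is_acetylated_form_of_substrate(self, constraints):
        m, pid = single_process_model("ME_Acetylation")
        con = constraints["ME_Acetylation"]
        assert check_event_process(m, pid, con) == []
        (out, _), = m.has_output(pid)
        assert "FT_Acetylated" in out.feature_types
        # a disjoint external reference on the product: not the same molecule
        out.unification_xrefs = frozenset({Xref("TRANSPATH", "OTHER")})
        assert categories(check_event_process(m, pid, con)) == [
            WC.WRONG_UNIFICATIONXREF]

    def test_autophosphorylation_admits_no_enzyme(self, constraints):
        m, pid = single_process_model("ME_Autophosphorylation")
        con = constraints["ME_Autophosphorylation"]
        assert check_group2(m, pid, con) == []
        m.add_entity(Entity(id="enzyme", entity_class=pq.EntityClass.PROTEIN))
        m.add_connector(Connector(id="c_enz", role=ConnectorRole.ACTIVATOR,
                                  process_id=pid, entity_id="enzyme"))
        assert categories(check_group2(m, pid, con)) == [
            WC.WRONG_CARDINALITY_INPUT]

    def test_plain_phosphorylation_permits_an_enzyme(self, constraints):
        m, pid = single_process_model("ME_Phosphorylation")
        m.add_entity(Entity(id="kinase", entity_class=pq.EntityClass.PROTEIN))
        m.add_connector(Connector(id="c_kin", role=ConnectorRole.ACTIVATOR,
                                  process_id=pid, entity_id="kinase"))
        assert check_group2(m, pid, constraints["ME_Phosphorylation"]) == []

    def test_dimerization_shape(self, constraints):
        m, pid = single_process_model("ME_Dimerization")
        con = constraints["ME_Dimerization"]
        assert check_stoichiometry_event(m, pid, con) == []
        (sub, conn), = m.has_inputprocess(pid)
        assert conn.stoichiometry == 2
        (out, _), = m.has_output(pid)
        assert out.entity_class is pq.EntityClass.COMPLEX
        out.entity_class = pq.EntityClass.PROTEIN
        assert categories(check_stoichiometry_event(m, pid, con)) == [
            WC.WRONG_TYPE]

    def test_internalization_locations_and_shared_reference(self, constraints):
        con = constraints["ME_Internalization"]
        m, pid = single_process_model("ME_Internalization")
        assert check_internalization(m, pid, con) == []
        (sub, _), = m.has_inputprocess(pid)
        assert sub.cell_component in ("CC_Extracellular", "CC_PlasmaMembrane")
        (out, _), = m.has_output(pid)
        assert out.cell_component == "CC_Cytosol"
        sub.cell_component = "CC_Cytosol"
        assert categories(check_internalization(m, pid, con)) == [
            WC.WRONG_CELLCOMPONENT]

    def test_internalization_missing_xrefs_suppress_sameas(self, constraints):
        con = constraints["ME_Internalization"]
        m, pid = single_process_model("ME_Internalization")
        for e in m.entities.values():
            e.unification_xrefs = frozenset()
        got = check_internalization(m, pid, con)
        assert categories(got) == [WC.MISSING_UNIFICATIONXREF]

    def test_transcription_output_is_nucleoplasmic_mrna(self, constraints):
        con = constraints["ME_Transcription"]
        m, pid = single_process_model("ME_Transcription")
        assert check_event_process(m, pid, con) == []
        (out, _), = m.has_output(pid)
        assert (out.entity_class, out.cell_component) == (
            pq.EntityClass.MRNA, "CC_Nucleoplasm")
        out.entity_class = pq.EntityClass.PROTEIN
        assert categories(check_event_process(m, pid, con)) == [WC.WRONG_TYPE]

    def test_group_precondition_enforced(self, constraints):
        m, pid = single_process_model("ME_Dimerization")
        with pytest.raises(ValueError):
            check_group2(m, pid, constraints["ME_Dimerization"])
        with pytest.raises(ValueError):
            check_stoichiometry_event(m, pid, constraints["ME_Acetylation"])
        with pytest.raises(ValueError):
            check_event_process(m, pid, constraints["ME_Binding"])


# ---------------------------------------------------------------------------
# Group 3 boundaries


@pytest.mark.parametrize("event,admissible", [
    ("ME_Dimerization", {2}),
    ("ME_Oligomerization", set(range(3, 21))),
    ("ME_Polymerization", set(range(21, 41))),
])
def test_group3_boundary_exactness(event, admissible, constraints):
    """Exhaustive coefficient scan 1..40 against set-membership oracle."""
    con = constraints[event]
    m, pid = single_process_model(event)
    (_, conn), = m.has_inputprocess(pid)
    for k in range(1, 41):
        conn.stoichiometry = k
        got = categories(check_stoichiometry_event(m, pid, con))
        if k in admissible:
            assert got == [], (event, k)
        else:
            assert got == [WC.WRONG_STOICHIOMETRY], (event, k)


# ---------------------------------------------------------------------------
# Group 4 relationship semantics


@pytest.mark.parametrize("src,dst,expect", [
    ("CC_Cytosol", "CC_Nucleoplasm", []),
    ("CC_Cytosol", "CC_Cytosol", [WC.SAME_CELLCOMPONENT_SHOULD_DIFFER]),
    (None, "CC_Cytosol", [WC.MISSING_CELLCOMPONENT]),
    (None, None, [WC.MISSING_CELLCOMPONENT, WC.MISSING_CELLCOMPONENT]),
])
def test_translocation_fires_iff_both_locations_present_and_equal(
        src, dst, expect, constraints):
    con = constraints["ME_Translocation"]
    m, pid = single_process_model("ME_Translocation")
    (sub, _), = m.has_inputprocess(pid)
    (out, _), = m.has_output(pid)
    sub.cell_component, out.cell_component = src, dst
    assert categories(check_event_process(m, pid, con)) == expect


# ---------------------------------------------------------------------------
# Suppression


def test_missing_substrate_suppresses_dependent_clauses(constraints):
    """No substrate: one missing-participant warning, not a cascade of
    property warnings about an entity that is not there."""
    m, pid = single_process_model("ME_Phosphorylation")
    for c in list(m.connectors.values()):
        if c.role is ConnectorRole.SUBSTRATE:
            del m.connectors[c.id]
    got = check_event_process(m, pid, constraints["ME_Phosphorylation"])
    assert categories(got) == [WC.MISSING_INPUTPROCESS]


def test_missing_output_suppresses_feature_and_xref_clauses(constraints):
    m, pid = single_process_model("ME_Amidation")
    for c in list(m.connectors.values()):
        if c.role is ConnectorRole.PRODUCT:
            del m.connectors[c.id]
    got = check_event_process(m, pid, constraints["ME_Amidation"])
    assert categories(got) == [WC.MISSING_OUTPUT]


def test_group2_event_absent_from_feature_map_is_config_error(constraints):
    m, pid = single_process_model("ME_Oxidation")
    with pytest.raises(ConstraintConfigError):
        check_group2(m, pid, constraints["ME_Oxidation"], feature_map={})


# ---------------------------------------------------------------------------
# Constructive soundness and single-defect completeness, all 36 events


@pytest.mark.parametrize("event", RULE_COVERED_EVENTS)
def test_clean_fixture_satisfies_its_constraint(event, constraints):
    m, pid = single_process_model(event)
    assert check_event_process(m, pid, constraints[event]) == []


@pytest.mark.parametrize("event", RULE_COVERED_EVENTS)
def test_every_single_defect_yields_exactly_its_category(event, constraints):
    """Mutation-style completeness: each applicable defect of each category
    produces that category alone."""
    tested = 0
    for category in WC:
        m, pid = single_process_model(event)
        for k, mutation in enumerate(
                _candidate_mutations(m, pid, category, constraints, 900)):
            trial = m.copy()
            mutation(trial)
            trial.check()
            got = categories(_process_warnings(trial, pid, constraints))
            assert got == [category], (event, category, k, got)
            tested += 1
    assert tested > 0, f"no defect applicable to {event}"
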