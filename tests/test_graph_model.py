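"""Graph model: parsing, validation, builders, bounded enumeration."""

import json

import numpy as np
import pytest

from cnavhmm.graph_model import (
    CANONICAL_BUILDERS,
    EnumerationOverflowError,
    GraphSpec,
    GraphSyntaxError,
    GraphValidationError,
    StateSpec,
    TransitionMatrix,
    build_canonical,
    enumerate_paths,
    free_parameter_count,
    parse_graph,
    validate_graph,
    write_graph,
)

ALL_BUILDS = [
    ("hwe_biallelic", {}),
    ("cnav_multiallele", {"alleles": ("A", "B", "C")}),
    ("cnav_multiallele", {"alleles": ("A", "B"), "gain_loop": False}),
    ("cnav_loh", {}),
    ("first_order_dependency", {}),
    ("tandem_allele", {}),
    ("two_locus_phasing", {}),
    ("two_locus_phasing", {"loops": False}),
    ("fully_connected_block", {"genes": ("3A", "2C", "3B")}),
]


@pytest.mark.parametrize("name,opts", ALL_BUILDS)
def test_builders_valid_and_roundtrip(name, opts):
    """Every canonical graph validates cleanly and survives write/parse."""
    g = build_canonical(name, **opts)
    assert validate_graph(g) == []
    text = write_graph(g)
    g2 = parse_graph(text)
    assert g2 == g
    assert write_graph(g2) == text  # byte-identical round trip


def test_hwe_graph_shape(hwe_graph):
    """The single-gene biallelic graph: a bifurcation between two alleles."""
    assert len(hwe_graph.states) == 5
    assert hwe_graph.alphabet == ("H131", "R131")
    assert free_parameter_count(hwe_graph) == 1


def test_parse_reports_syntax_position():
    with pytest.raises(GraphSyntaxError, match="line"):
        parse_graph("{not json")


def test_parse_rejects_unknown_keys():
    doc = {"states": [{"id": "s", "kind": "start", "color": "red"}],
           "edges": [], "extra": 1}
    with pytest.raises(GraphValidationError) as exc:
        parse_graph(json.dumps(doc))
    msgs = " ".join(exc.value.violations)
    assert "unknown" in msgs


def _doc(states, edges):
    return json.dumps({
        "states": states,
        "edges": [{"from": a, "to": b} for a, b in edges],
    })


def test_two_start_states_rejected():
    doc = _doc(
        [{"id": "s1", "kind": "start"}, {"id": "s2", "kind": "start"},
         {"id": "e", "kind": "emit", "emit": "A"},
         {"id": "end", "kind": "end"}],
        [("s1", "e"), ("s2", "e"), ("e", "end")],
    )
    with pytest.raises(GraphValidationError, match="exactly one start"):
        parse_graph(doc)


def test_silent_only_cycle_rejected():
    doc = _doc(
        [{"id": "s", "kind": "start"}, {"id": "a", "kind": "silent"},
         {"id": "b", "kind": "silent"},
         {"id": "e", "kind": "emit", "emit": "A"},
         {"id": "end", "kind": "end"}],
        [("s", "a"), ("a", "b"), ("b", "a"), ("b", "e"), ("e", "end")],
    )
    with pytest.raises(GraphValidationError, match="silent-only cycle"):
        parse_graph(doc)


def test_validate_reports_all_structural_problems():
    """validate_graph is a reporting operation: it lists, never raises."""
    g = GraphSpec(
        states=(
            StateSpec("s", "start"),
            StateSpec("a", "emit", emit_symbol="A"),
            StateSpec("orphan", "silent"),
            StateSpec("end", "end"),
        ),
        edges=(("s", "a"), ("a", "end"), ("end", "a")),
    )
    report = validate_graph(g)
    joined = " ".join(report)
    assert "end" in joined and "absorbing" in joined
    assert "orphan" in joined


def test_free_parameters_chain_and_cnav(cnav_graph):
    chain = GraphSpec(
        states=(StateSpec("s", "start"),
                StateSpec("a", "emit", emit_symbol="A"),
                StateSpec("end", "end")),
        edges=(("s", "a"), ("a", "end")),
    )
    assert free_parameter_count(chain) == 0
    # loss branch + allele bifurcation + gain loop: three degree-2 states
    assert free_parameter_count(cnav_graph) == 3


def test_free_parameter_count_invariant_under_relabeling(cnav_graph):
    mapping = {sid: f"x{i}" for i, sid in enumerate(cnav_graph.state_ids)}
    relabeled = GraphSpec(
        states=tuple(
            StateSpec(mapping[s.id], s.kind, s.emit_symbol, s.alt_emit_symbol)
            for s in cnav_graph.states
        ),
        edges=tuple((mapping[a], mapping[b]) for a, b in cnav_graph.edges),
    )
    assert free_parameter_count(relabeled) == free_parameter_count(cnav_graph)


def test_enumerate_hwe_caps(hwe_graph):
    assert len(enumerate_paths(hwe_graph, copy_cap=1)) == 2
    assert enumerate_paths(hwe_graph, copy_cap=0) == []


def test_enumerate_monotone_and_capped(cnav_graph):
    sizes = [len(enumerate_paths(cnav_graph, copy_cap=c)) for c in range(4)]
    assert sizes == sorted(sizes)
    for cap in (1, 2):
        for p in enumerate_paths(cnav_graph, copy_cap=cap):
            assert p.emissions.max() <= cap


def test_enumerate_lexicographic_and_null_haplotype(cnav_graph):
    paths = enumerate_paths(cnav_graph, copy_cap=1)
    seqs = [p.states for p in paths]
    assert seqs == sorted(seqs)
    # the deletion bypass gives exactly one emission-free path
    assert sum(1 for p in paths if p.emissions.sum() == 0) == 1


def test_enumerate_overflow_guard(cnav_graph):
    with pytest.raises(EnumerationOverflowError):
        enumerate_paths(cnav_graph, copy_cap=5, limit=3)


def test_transition_matrix_validation(hwe_graph):
    tm = TransitionMatrix.uniform(hwe_graph)
    tm.validate()
    bad = TransitionMatrix(hwe_graph, np.array([1.0, 0.6, 0.6, 1.0, 1.0]))
    with pytest.raises(ValueError, match="sum"):
        bad.validate()
    with pytest.raises(ValueError, match="not a graph edge"):
        TransitionMatrix.from_dict(hwe_graph, {("end", "start"): 1.0})


def test_unknown_builder_name():
    with pytest.raises(ValueError, match="unknown canonical graph"):
        build_canonical("no_such_model")
    assert set(CANONICAL_BUILDERS) == {
        "hwe_biallelic", "cnav_multiallele", "cnav_loh",
        "first_order_dependency", "tandem_allele", "two_locus_phasing",
        "fully_connected_block",
    }
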