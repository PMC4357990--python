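"""Directed HMM graphs encoding extended Hardy-Weinberg models of CNAV.

A locus with joint copy-number and allelic variation (CNAV) is modelled as a
stochastic finite-state machine: a directed graph with one *start* state, one
*end* state, *silent* states that emit nothing, and *emit* states that each
increment the count of one symbol (an allele probed by MLPA) per visit.  A
haplotype is one random start-to-end walk; a diploid genotype is the
element-wise sum of the emission tallies of two independent walks.  Gene
deletion appears as a silent bypass branch, gene duplication as a recursion
loop that revisits the emitting block.  Loss and gain loops are wired so that
every directed cycle contains at least one emitting state, which guarantees
that a walk terminates almost surely whenever the end state is reachable with
positive probability.

This module defines the graph data model, a plain-JSON serialization dialect,
validation, canonical graph builders for the standard CNAV scenarios, and a
brute-force bounded path enumerator that serves as the exact oracle for the
simulation-based machinery elsewhere in the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "StateSpec",
    "GraphSpec",
    "TransitionMatrix",
    "PathRecord",
    "GraphSyntaxError",
    "GraphValidationError",
    "EnumerationOverflowError",
    "parse_graph",
    "write_graph",
    "validate_graph",
    "free_parameter_count",
    "build_canonical",
    "enumerate_paths",
    "enumerate_path_arrays",
    "CANONICAL_BUILDERS",
]

STATE_KINDS = ("start", "silent", "emit", "end")

#: default per-symbol, per-haplotype copy cap; MLPA panels resolve roughly
#: 0 to 5 copies per allele, so 5 is the conventional bound.
DEFAULT_COPY_CAP = 5

#: default bound on the number of enumerated paths before aborting.
DEFAULT_ENUMERATION_LIMIT = 200_000


class GraphSyntaxError(ValueError):
    """The graph document is not well-formed (position reported)."""


class GraphValidationError(ValueError):
    """A graph violates structural invariants; ``violations`` lists them all."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid graph: " + "; ".join(self.violations))


class EnumerationOverflowError(RuntimeError):
    """Bounded path enumeration exceeded its configured limit."""


@dataclass(frozen=True)
class StateSpec:
    """One state of the machine.

    ``emit_symbol`` names the counting event incremented on each visit and is
    required exactly for ``kind == "emit"``.  ``alt_emit_symbol`` optionally
    names the alternative (phased) counting event used by the phasing
    translation; it is only meaningful on emit states.
    """

    id: str
    kind: str
    emit_symbol: str | None = None
    alt_emit_symbol: str | None = None


@dataclass(frozen=True)
class GraphSpec:
    """An immutable directed HMM graph.

    ``edges`` is an *ordered* tuple of ``(from_id, to_id)`` pairs; everything
    downstream (Dirichlet prior rows, flattened posterior draws, k-means
    coordinates) follows this edge order, so it is part of the model identity.
    """

    states: tuple[StateSpec, ...]
    edges: tuple[tuple[str, str], ...]

    # --- derived lookups -------------------------------------------------
    @property
    def state_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.states)

    def state(self, state_id: str) -> StateSpec:
        for s in self.states:
            if s.id == state_id:
                return s
        raise KeyError(state_id)

    @property
    def start_id(self) -> str:
        return next(s.id for s in self.states if s.kind == "start")

    @property
    def end_id(self) -> str:
        return next(s.id for s in self.states if s.kind == "end")

    @property
    def alphabet(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.states:
            if s.kind == "emit" and s.emit_symbol is not None:
                seen.setdefault(s.emit_symbol)
        return tuple(seen)

    @property
    def alt_alphabet(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.states:
            if s.kind == "emit" and s.alt_emit_symbol is not None:
                seen.setdefault(s.alt_emit_symbol)
        return tuple(seen)

    @property
    def edge_index(self) -> dict[tuple[str, str], int]:
        return {e: i for i, e in enumerate(self.edges)}

    def out_edges(self, state_id: str) -> list[tuple[int, tuple[str, str]]]:
        """Outgoing edges of a state as ``(edge_index, edge)``, in edge order."""
        return [(i, e) for i, e in enumerate(self.edges) if e[0] == state_id]

    def out_degree(self, state_id: str) -> int:
        return sum(1 for e in self.edges if e[0] == state_id)

    def to_networkx(self) -> nx.DiGraph:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.state_ids)
        dg.add_edges_from(self.edges)
        return dg


@dataclass(frozen=True)
class PathRecord:
    """A start-to-end walk: its state sequence and its emission tally."""

    states: tuple[str, ...]
    emissions: np.ndarray  # int vector over the graph alphabet

    def edge_count_vector(self, g: GraphSpec) -> np.ndarray:
        """Tally of traversals of each graph edge, aligned to ``g.edges``."""
        counts = np.zeros(len(g.edges), dtype=np.int64)
        idx = g.edge_index
        for a, b in zip(self.states[:-1], self.states[1:]):
            counts[idx[(a, b)]] += 1
        return counts

    def __eq__(self, other):  # emissions is an array; compare by value
        return (
            isinstance(other, PathRecord)
            and self.states == other.states
            and np.array_equal(self.emissions, other.emissions)
        )

    def __hash__(self):
        return hash(self.states)


@dataclass
class TransitionMatrix:
    """Row-stochastic probabilities on the graph edges (the parameter A).

    Stored flat, aligned to ``graph.edges``; each non-end state's outgoing
    probabilities must sum to one (tolerance 1e-12 at validation).
    """

    graph: GraphSpec
    probs: np.ndarray  # shape (E,), float

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.graph.edges),):
            raise ValueError(
                f"expected {len(self.graph.edges)} edge probabilities, "
                f"got shape {self.probs.shape}"
            )

    def validate(self, tol: float = 1e-12) -> None:
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        for s in self.graph.states:
            if s.kind == "end":
                continue
            row = [self.probs[i] for i, _ in self.graph.out_edges(s.id)]
            if abs(sum(row) - 1.0) > tol:
                raise ValueError(
                    f"outgoing probabilities of state {s.id!r} sum to "
                    f"{sum(row)!r}, not 1"
                )

    def __getitem__(self, edge: tuple[str, str]) -> float:
        return float(self.probs[self.graph.edge_index[edge]])

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {e: float(p) for e, p in zip(self.graph.edges, self.probs)}

    @classmethod
    def uniform(cls, g: GraphSpec) -> "TransitionMatrix":
        probs = np.zeros(len(g.edges))
        for s in g.states:
            out = g.out_edges(s.id)
            for i, _ in out:
                probs[i] = 1.0 / len(out)
        return cls(g, probs)

    @classmethod
    def from_dict(
        cls, g: GraphSpec, mapping: dict[tuple[str, str], float]
    ) -> "TransitionMatrix":
        """Build from a complete edge -> probability map; validated."""
        probs = np.zeros(len(g.edges))
        index = g.edge_index
        for edge, p in mapping.items():
            if tuple(edge) not in index:
                raise ValueError(f"{edge!r} is not a graph edge")
            probs[index[tuple(edge)]] = p
        tm = cls(g, probs)
        tm.validate(tol=1e-9)
        return tm


# ---------------------------------------------------------------------------
# Serialization: a plain JSON dialect
# ---------------------------------------------------------------------------
# Top-level keys "states" and "edges"; a state is {"id", "kind", "emit",
# "alt_emit"} (emission keys present only when set), an edge is
# {"from", "to"}.  Unknown keys are rejected.  The writer emits keys in this
# order, so write/parse round-trips are byte-identical.

_STATE_KEYS = {"id", "kind", "emit", "alt_emit"}
_EDGE_KEYS = {"from", "to"}


def parse_graph(text: str) -> GraphSpec:
    """Parse a graph document and validate it fully.

    Raises :class:`GraphSyntaxError` for malformed documents (with position)
    and :class:`GraphValidationError` listing every structural violation.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GraphSyntaxError(
            f"graph document is not valid JSON at line {exc.lineno}, "
            f"column {exc.colno}: {exc.msg}"
        ) from exc

    problems: list[str] = []
    if not isinstance(doc, dict):
        raise GraphSyntaxError("graph document must be a JSON object")
    unknown = set(doc) - {"states", "edges"}
    if unknown:
        problems.append(f"unknown top-level keys: {sorted(unknown)}")
    states_raw = doc.get("states")
    edges_raw = doc.get("edges")
    if not isinstance(states_raw, list):
        problems.append("'states' must be a list")
        states_raw = []
    if not isinstance(edges_raw, list):
        problems.append("'edges' must be a list")
        edges_raw = []

    states: list[StateSpec] = []
    for pos, entry in enumerate(states_raw):
        if not isinstance(entry, dict):
            problems.append(f"state #{pos} is not an object")
            continue
        extra = set(entry) - _STATE_KEYS
        if extra:
            problems.append(f"state #{pos}: unknown keys {sorted(extra)}")
        if "id" not in entry or "kind" not in entry:
            problems.append(f"state #{pos}: 'id' and 'kind' are required")
            continue
        states.append(
            StateSpec(
                id=str(entry["id"]),
                kind=str(entry["kind"]),
                emit_symbol=entry.get("emit"),
                alt_emit_symbol=entry.get("alt_emit"),
            )
        )

    edges: list[tuple[str, str]] = []
    for pos, entry in enumerate(edges_raw):
        if not isinstance(entry, dict):
            problems.append(f"edge #{pos} is not an object")
            continue
        extra = set(entry) - _EDGE_KEYS
        if extra:
            problems.append(f"edge #{pos}: unknown keys {sorted(extra)}")
        if "from" not in entry or "to" not in entry:
            problems.append(f"edge #{pos}: 'from' and 'to' are required")
            continue
        edges.append((str(entry["from"]), str(entry["to"])))

    if problems:
        raise GraphValidationError(problems)

    g = GraphSpec(states=tuple(states), edges=tuple(edges))
    violations = validate_graph(g)
    if violations:
        raise GraphValidationError(violations)
    return g


def write_graph(g: GraphSpec) -> str:
    """Serialize a graph to the JSON dialect (stable key order)."""
    states = []
    for s in g.states:
        entry: dict[str, str] = {"id": s.id, "kind": s.kind}
        if s.emit_symbol is not None:
            entry["emit"] = s.emit_symbol
        if s.alt_emit_symbol is not None:
            entry["alt_emit"] = s.alt_emit_symbol
        states.append(entry)
    edges = [{"from": a, "to": b} for a, b in g.edges]
    return json.dumps({"states": states, "edges": edges}, indent=2) + "\n"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_graph(g: GraphSpec) -> list[str]:
    """Return the full list of invariant violations (empty list == valid).

    Checks: unique state ids; legal kinds; emission labels present exactly on
    emit states; a single start (no incoming edges) and a single absorbing end
    state; no duplicate or dangling edges; every state on some start-to-end
    path; and no silent-only directed cycle (every cycle must emit, so walks
    terminate almost surely).
    """
    violations: list[str] = []

    ids = [s.id for s in g.states]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        violations.append(f"duplicate state ids: {sorted(dupes)}")
    for s in g.states:
        if s.kind not in STATE_KINDS:
            violations.append(f"state {s.id!r}: unknown kind {s.kind!r}")
        if s.kind == "emit" and not s.emit_symbol:
            violations.append(f"state {s.id!r}: emit state needs an emit symbol")
        if s.kind != "emit" and s.emit_symbol:
            violations.append(
                f"state {s.id!r}: only emit states may carry an emit symbol"
            )
        if s.kind != "emit" and s.alt_emit_symbol:
            violations.append(
                f"state {s.id!r}: only emit states may carry an alt emit symbol"
            )

    starts = [s.id for s in g.states if s.kind == "start"]
    ends = [s.id for s in g.states if s.kind == "end"]
    if len(starts) != 1:
        violations.append(f"exactly one start state required, found {len(starts)}")
    if len(ends) != 1:
        violations.append(f"exactly one end state required, found {len(ends)}")

    known = set(ids)
    seen_edges: set[tuple[str, str]] = set()
    for a, b in g.edges:
        if a not in known or b not in known:
            violations.append(f"edge ({a!r}, {b!r}) references an unknown state")
        if (a, b) in seen_edges:
            violations.append(f"duplicate edge ({a!r}, {b!r})")
        seen_edges.add((a, b))

    if violations:
        # Structural problems make the path/cycle checks unreliable; stop here.
        return violations

    for sid in starts:
        if any(b == sid for _, b in g.edges):
            violations.append(f"start state {sid!r} must have no incoming edges")
    for sid in ends:
        if any(a == sid for a, _ in g.edges):
            violations.append(f"end state {sid!r} must be absorbing (no outgoing edges)")

    dg = g.to_networkx()
    start, end = starts[0], ends[0]
    reachable = {start} | nx.descendants(dg, start)
    coreachable = {end} | nx.ancestors(dg, end)
    for sid in ids:
        if sid not in reachable or sid not in coreachable:
            violations.append(f"state {sid!r} lies on no start-to-end path")

    silent_ids = {s.id for s in g.states if s.kind != "emit"}
    silent_sub = dg.subgraph(silent_ids)
    if not nx.is_directed_acyclic_graph(silent_sub):
        cyc = nx.find_cycle(silent_sub)
        involved = sorted({a for a, _ in cyc})
        violations.append(
            f"silent-only cycle through {involved}: every directed cycle "
            "must contain at least one emit state"
        )
    return violations


def _require_valid(g: GraphSpec) -> None:
    violations = validate_graph(g)
    if violations:
        raise GraphValidationError(violations)


def free_parameter_count(g: GraphSpec) -> int:
    """Number of free transition probabilities.

    Each non-end state with out-degree d contributes d - 1 free parameters
    (its outgoing row lives on a (d-1)-simplex).  Invariant under state
    relabeling.
    """
    _require_valid(g)
    return sum(
        max(g.out_degree(s.id) - 1, 0) for s in g.states if s.kind != "end"
    )


# ---------------------------------------------------------------------------
# Canonical builders
# ---------------------------------------------------------------------------

def _mk(states: list[StateSpec], edges: list[tuple[str, str]]) -> GraphSpec:
    g = GraphSpec(states=tuple(states), edges=tuple(edges))
    _require_valid(g)
    return g


def build_hwe_biallelic(alleles: tuple[str, str] = ("A", "B")) -> GraphSpec:
    """Classical Hardy-Weinberg model for a single-copy biallelic gene.

    Wiring: ``start -> choose``; ``choose`` bifurcates to one emit state per
    allele (state id equals the allele symbol); each allele state goes to
    ``end``.  The bifurcation probabilities are the haplotype (allele)
    frequencies, so this graph reproduces the p^2 / 2pq / q^2 genotype law.
    """
    if len(alleles) != 2:
        raise ValueError("hwe_biallelic needs exactly 2 alleles")
    states = [
        StateSpec("start", "start"),
        StateSpec("choose", "silent"),
        *[StateSpec(a, "emit", emit_symbol=a) for a in alleles],
        StateSpec("end", "end"),
    ]
    edges = [("start", "choose")]
    edges += [("choose", a) for a in alleles]
    edges += [(a, "end") for a in alleles]
    return _mk(states, edges)


def build_cnav_multiallele(
    alleles: tuple[str, ...] = ("A", "B"),
    loss_branch: bool = True,
    gain_loop: bool = True,
) -> GraphSpec:
    """Extended Hardy-Weinberg model for one gene with k alleles and CNV.

    Wiring (state ids in brackets):
    ``start -> [in]``; ``[in] -> [del] -> [out]`` is the silent deletion
    bypass (probability of a null haplotype); ``[in] -> [choose]`` enters the
    emitting block; ``[choose]`` bifurcates to one emit state per allele;
    every allele state leads to ``[post]``; ``[post] -> [out]`` exits and
    ``[post] -> [gain] -> [choose]`` is the duplication loop (a fresh allele
    is drawn for each extra copy, i.e. copies are independent);
    ``[out] -> end``.  With a shared gain probability g the per-haplotype copy
    number is geometric: P(k | not lost) = (1-g) g^(k-1).

    ``loss_branch=False`` removes [del]; ``gain_loop=False`` removes [post]/
    [gain] and wires allele states straight to [out] (leaving k free
    parameters with loss, k-1 without... concretely: loss + allele choice).
    """
    if len(alleles) < 2:
        raise ValueError("cnav_multiallele needs at least 2 alleles")
    states = [StateSpec("start", "start"), StateSpec("in", "silent")]
    if loss_branch:
        states.append(StateSpec("del", "silent"))
    states.append(StateSpec("choose", "silent"))
    states += [StateSpec(a, "emit", emit_symbol=a) for a in alleles]
    if gain_loop:
        states += [StateSpec("post", "silent"), StateSpec("gain", "silent")]
    states += [StateSpec("out", "silent"), StateSpec("end", "end")]

    edges: list[tuple[str, str]] = [("start", "in")]
    if loss_branch:
        edges += [("in", "del"), ("del", "out")]
    edges.append(("in", "choose"))
    edges += [("choose", a) for a in alleles]
    if gain_loop:
        edges += [(a, "post") for a in alleles]
        edges += [("post", "out"), ("post", "gain"), ("gain", "choose")]
    else:
        edges += [(a, "out") for a in alleles]
    edges.append(("out", "end"))
    return _mk(states, edges)


def build_cnav_loh(alleles: tuple[str, str] = ("A", "B")) -> GraphSpec:
    """Biallelic CNAV model with loss-of-heterozygosity duplication.

    Duplication via microhomology-mediated repair copies the *same* allele, so
    the gain loop is a per-allele self-edge (each allele state may repeat
    itself) rather than a return to the allele bifurcation:
    ``start -> [in]``; ``[in] -> [del] -> [out]`` (deletion);
    ``[in] -> [choose]`` -> one emit state per allele; each allele state has a
    self-edge (LOH repeat) and an edge to ``[out] -> end``.
    """
    if len(alleles) != 2:
        raise ValueError("cnav_loh is the biallelic LOH variant")
    states = [
        StateSpec("start", "start"),
        StateSpec("in", "silent"),
        StateSpec("del", "silent"),
        StateSpec("choose", "silent"),
        *[StateSpec(a, "emit", emit_symbol=a) for a in alleles],
        StateSpec("out", "silent"),
        StateSpec("end", "end"),
    ]
    edges = [("start", "in"), ("in", "del"), ("del", "out"), ("in", "choose")]
    edges += [("choose", a) for a in alleles]
    for a in alleles:
        edges += [(a, a), (a, "out")]
    edges.append(("out", "end"))
    return _mk(states, edges)


def build_first_order_dependency(
    alleles: tuple[str, ...] = ("Na1", "Na2", "SH"),
) -> GraphSpec:
    """First-order dependency between successive gene copies.

    The allele emit states are fully interconnected (including self loops), so
    the allele of copy j+1 depends on the allele of copy j — a first-order
    Markov relaxation of the copy-independence assumption.  Wiring:
    ``start -> [in]``; ``[in] -> [del] -> [out]``; ``[in] -> [choose]`` -> one
    emit state per allele; every allele state connects to every allele state
    (self loops are the per-allele repeat recursions) and to ``[out] -> end``.
    """
    if len(alleles) < 2:
        raise ValueError("first_order_dependency needs at least 2 alleles")
    states = [
        StateSpec("start", "start"),
        StateSpec("in", "silent"),
        StateSpec("del", "silent"),
        StateSpec("choose", "silent"),
        *[StateSpec(a, "emit", emit_symbol=a) for a in alleles],
        StateSpec("out", "silent"),
        StateSpec("end", "end"),
    ]
    edges = [("start", "in"), ("in", "del"), ("del", "out"), ("in", "choose")]
    edges += [("choose", a) for a in alleles]
    for a in alleles:
        edges += [(a, b) for b in alleles]
        edges.append((a, "out"))
    edges.append(("out", "end"))
    return _mk(states, edges)


def build_tandem_allele(
    alleles: tuple[str, ...] = ("Na1", "Na2", "SH"),
    tandem: tuple[str, str] = ("SH", "Na1"),
    repeat_allele: str | None = "SH",
) -> GraphSpec:
    """CNAV model with an additional composite (tandem) allele.

    On top of the :func:`build_cnav_multiallele` wiring, the allele
    bifurcation gains a tandem branch — a two-state chain ``[tandem:X+Y.1]``
    (emits X) ``-> [tandem:X+Y.2]`` (emits Y) ``-> [post]`` — modelling a
    duplication unit that always carries both alleles.  ``repeat_allele``
    optionally adds a self-edge on that allele's emit state (irregular
    repetitions, e.g. an assay artifact).  Emitted symbols of the tandem chain
    are the ordinary allele symbols, so tandem carriers show joint count
    excesses of both member alleles.
    """
    if tandem[0] not in alleles or tandem[1] not in alleles:
        raise ValueError("tandem member alleles must be among the alleles")
    t1 = f"tandem:{tandem[0]}+{tandem[1]}.1"
    t2 = f"tandem:{tandem[0]}+{tandem[1]}.2"
    states = [
        StateSpec("start", "start"),
        StateSpec("in", "silent"),
        StateSpec("del", "silent"),
        StateSpec("choose", "silent"),
        *[StateSpec(a, "emit", emit_symbol=a) for a in alleles],
        StateSpec(t1, "emit", emit_symbol=tandem[0]),
        StateSpec(t2, "emit", emit_symbol=tandem[1]),
        StateSpec("post", "silent"),
        StateSpec("gain", "silent"),
        StateSpec("out", "silent"),
        StateSpec("end", "end"),
    ]
    edges = [("start", "in"), ("in", "del"), ("del", "out"), ("in", "choose")]
    edges += [("choose", a) for a in alleles]
    edges.append(("choose", t1))
    edges.append((t1, t2))
    edges.append((t2, "post"))
    for a in alleles:
        if repeat_allele is not None and a == repeat_allele:
            edges.append((a, a))
        edges.append((a, "post"))
    edges += [("post", "out"), ("post", "gain"), ("gain", "choose"), ("out", "end")]
    return _mk(states, edges)


def build_two_locus_phasing(
    promoter_symbols: tuple[str, str] = ("promC", "promG"),
    locus1_alleles: tuple[str, str] = ("I232", "T232"),
    locus2_alleles: tuple[str, str] = ("ORF", "Stop"),
    prefixes: tuple[str, str] = ("b", "c"),
    loops: bool = True,
) -> GraphSpec:
    """Two loci sharing ambiguous promoter emissions, with phased alternatives.

    Models two tandem genes (e.g. the inhibitory and activating receptor pair)
    whose promoter regions are too homologous for the assay to separate: both
    loci's promoter states emit the *same* primary symbols, but carry
    locus-tagged alternative (phased) symbols.  The coding-region bifurcation
    is reached separately from each promoter state, so coding-allele
    probabilities may depend on the promoter allele — the linkage that makes
    phase recovery possible.

    Wiring (prefix ``b`` = locus 1, fixed single copy; ``c`` = locus 2, with
    optional deletion/duplication loops): ``start -> [b_in]`` -> promoter emit
    states ``b_<prom>`` -> coding emit states ``b_<allele>`` -> ``[c_in]``;
    locus 2 mirrors this via ``[c_choose]`` with a ``[c_del]`` bypass and a
    ``[c_post] -> [c_gain] -> [c_choose]`` duplication loop; ``[c_out] -> end``.
    Coding emit states use their own symbol as the alternative symbol
    (unambiguous); promoter states use ``<prefix>_<symbol>``.
    """
    p1, p2 = prefixes
    states = [StateSpec("start", "start"), StateSpec(f"{p1}_in", "silent")]
    for sym in promoter_symbols:
        states.append(
            StateSpec(f"{p1}_{sym}", "emit", emit_symbol=sym,
                      alt_emit_symbol=f"{p1}_{sym}")
        )
    for a in locus1_alleles:
        states.append(StateSpec(f"{p1}_{a}", "emit", emit_symbol=a,
                                alt_emit_symbol=a))
    states.append(StateSpec(f"{p2}_in", "silent"))
    if loops:
        states.append(StateSpec(f"{p2}_del", "silent"))
    states.append(StateSpec(f"{p2}_choose", "silent"))
    for sym in promoter_symbols:
        states.append(
            StateSpec(f"{p2}_{sym}", "emit", emit_symbol=sym,
                      alt_emit_symbol=f"{p2}_{sym}")
        )
    for a in locus2_alleles:
        states.append(StateSpec(f"{p2}_{a}", "emit", emit_symbol=a,
                                alt_emit_symbol=a))
    if loops:
        states += [StateSpec(f"{p2}_post", "silent"), StateSpec(f"{p2}_gain", "silent")]
    states += [StateSpec(f"{p2}_out", "silent"), StateSpec("end", "end")]

    edges: list[tuple[str, str]] = [("start", f"{p1}_in")]
    edges += [(f"{p1}_in", f"{p1}_{sym}") for sym in promoter_symbols]
    for sym in promoter_symbols:
        edges += [(f"{p1}_{sym}", f"{p1}_{a}") for a in locus1_alleles]
    edges += [(f"{p1}_{a}", f"{p2}_in") for a in locus1_alleles]
    if loops:
        edges += [(f"{p2}_in", f"{p2}_del"), (f"{p2}_del", f"{p2}_out")]
    edges.append((f"{p2}_in", f"{p2}_choose"))
    edges += [(f"{p2}_choose", f"{p2}_{sym}") for sym in promoter_symbols]
    for sym in promoter_symbols:
        edges += [(f"{p2}_{sym}", f"{p2}_{a}") for a in locus2_alleles]
    if loops:
        edges += [(f"{p2}_{a}", f"{p2}_post") for a in locus2_alleles]
        edges += [
            (f"{p2}_post", f"{p2}_out"),
            (f"{p2}_post", f"{p2}_gain"),
            (f"{p2}_gain", f"{p2}_choose"),
        ]
    else:
        edges += [(f"{p2}_{a}", f"{p2}_out") for a in locus2_alleles]
    edges.append((f"{p2}_out", "end"))
    return _mk(states, edges)


def build_fully_connected_block(
    genes: tuple[str, ...] = ("3A", "2C", "3B"),
) -> GraphSpec:
    """All gene blocks connected in both directions (gene-order discovery).

    Each gene is one emitting block (state id and symbol equal the gene name).
    ``start`` connects to every gene and directly to ``end`` (the all-deleted
    haplotype); every gene connects to every other gene in both directions, to
    itself (duplication), and to ``end``.  Because the data contain no
    ordering information, the posterior is multimodal: with m genes the
    highest-probability path can order them in m! ways (forward/reverse pairs
    of m!/2 unique orders).
    """
    if len(genes) < 2:
        raise ValueError("fully_connected_block needs at least 2 genes")
    states = [StateSpec("start", "start")]
    states += [StateSpec(gn, "emit", emit_symbol=gn) for gn in genes]
    states.append(StateSpec("end", "end"))
    edges: list[tuple[str, str]] = [("start", gn) for gn in genes]
    edges.append(("start", "end"))
    for a in genes:
        edges += [(a, b) for b in genes]
        edges.append((a, "end"))
    return _mk(states, edges)


CANONICAL_BUILDERS = {
    "hwe_biallelic": build_hwe_biallelic,
    "cnav_multiallele": build_cnav_multiallele,
    "cnav_loh": build_cnav_loh,
    "first_order_dependency": build_first_order_dependency,
    "tandem_allele": build_tandem_allele,
    "two_locus_phasing": build_two_locus_phasing,
    "fully_connected_block": build_fully_connected_block,
}


def build_canonical(name: str, **options) -> GraphSpec:
    """Build one of the canonical scenario graphs by name.

    Known names: hwe_biallelic, cnav_multiallele, cnav_loh,
    first_order_dependency, tandem_allele, two_locus_phasing,
    fully_connected_block.  Options are forwarded to the named builder; see
    each builder's docstring for the documented state naming.
    """
    if name not in CANONICAL_BUILDERS:
        raise ValueError(
            f"unknown canonical graph {name!r}; known: {sorted(CANONICAL_BUILDERS)}"
        )
    return CANONICAL_BUILDERS[name](**options)


# ---------------------------------------------------------------------------
# Bounded exhaustive path enumeration (the brute-force oracle)
# ---------------------------------------------------------------------------

def enumerate_path_arrays(
    g: GraphSpec,
    copy_cap: int = DEFAULT_COPY_CAP,
    per_symbol_cap: np.ndarray | None = None,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
):
    """Array-form exhaustive path enumeration (the workhorse behind
    :func:`enumerate_paths`).

    Returns ``(states, emissions, edge_counts)`` where ``states`` is a list
    of state-id tuples, ``emissions`` an (P, K) int array over the alphabet
    and ``edge_counts`` an (P, E) int array over the graph edges, all
    ordered lexicographically by state sequence.  Both tallies are built
    incrementally during the depth-first search.
    """
    _require_valid(g)
    if copy_cap < 0:
        raise ValueError("copy_cap must be non-negative")
    alphabet = g.alphabet
    sym_idx = {sym: i for i, sym in enumerate(alphabet)}
    if per_symbol_cap is None:
        caps = np.full(len(alphabet), copy_cap, dtype=np.int64)
    else:
        caps = np.asarray(per_symbol_cap, dtype=np.int64)
        if caps.shape != (len(alphabet),):
            raise ValueError("per_symbol_cap must align with the alphabet")

    edge_idx = g.edge_index
    successors: dict[str, list[tuple[str, int]]] = {
        s.id: sorted(
            ((b, edge_idx[(a, b)]) for a, b in g.edges if a == s.id),
        )
        for s in g.states
    }
    emit_of = {
        s.id: sym_idx[s.emit_symbol] for s in g.states
        if s.kind == "emit" and s.emit_symbol is not None
    }
    start, end = g.start_id, g.end_id
    expansion_limit = max(limit * 50, 10_000)

    states_out: list[tuple[str, ...]] = []
    emis_out: list[list[int]] = []
    ec_out: list[list[int]] = []
    counts = [0] * len(alphabet)
    ecounts = [0] * len(g.edges)
    prefix: list[str] = [start]
    expansions = 0

    def visit(state: str) -> None:
        nonlocal expansions
        if state == end:
            states_out.append(tuple(prefix))
            emis_out.append(counts.copy())
            ec_out.append(ecounts.copy())
            if len(states_out) > limit:
                raise EnumerationOverflowError(
                    f"more than {limit} paths under cap {caps.tolist()}"
                )
            return
        for nxt, e in successors[state]:
            expansions += 1
            if expansions > expansion_limit:
                raise EnumerationOverflowError(
                    f"enumeration exceeded {expansion_limit} node expansions"
                )
            k = emit_of.get(nxt)
            if k is not None:
                if counts[k] + 1 > caps[k]:
                    continue
                counts[k] += 1
            ecounts[e] += 1
            prefix.append(nxt)
            visit(nxt)
            prefix.pop()
            ecounts[e] -= 1
            if k is not None:
                counts[k] -= 1

    visit(start)
    P = len(states_out)
    emissions = np.array(emis_out, dtype=np.int64).reshape(P, len(alphabet))
    edge_counts = np.array(ec_out, dtype=np.int64).reshape(P, len(g.edges))
    return states_out, emissions, edge_counts


def enumerate_paths(
    g: GraphSpec,
    copy_cap: int = DEFAULT_COPY_CAP,
    per_symbol_cap: np.ndarray | None = None,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> list[PathRecord]:
    """Exhaustively enumerate start-to-end paths under per-symbol emission caps.

    ``copy_cap`` bounds the count of each emission symbol per haplotype;
    ``per_symbol_cap`` (vector over the alphabet) overrides it element-wise
    when given.  Output is deterministic, ordered lexicographically by the
    state-id sequence.  Raises :class:`EnumerationOverflowError` when more
    than ``limit`` paths (or 50x ``limit`` node expansions) are reached.

    Since every cycle contains an emitting state, capping emissions bounds
    path length, so the enumeration always terminates.
    """
    states, emissions, _ = enumerate_path_arrays(
        g, copy_cap=copy_cap, per_symbol_cap=per_symbol_cap, limit=limit
    )
    return [
        PathRecord(states=s, emissions=e) for s, e in zip(states, emissions)
    ]
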