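"""Generative side of the CNAV model: random walks, genotypes, distributions.

A haplotype is one random start-to-end walk of the graph under a transition
matrix A; a genotype is the element-wise emission sum of two independent
walks (the diploid assumption: independence between chromosomes).  Haplotype
pairs are *ordered* throughout the package — both (h1, h2) and (h2, h1) are
counted — so simulated frequencies, likelihoods and enumeration oracles all
share one convention and no 2-vs-1 symmetry factors can go missing.

Two routes to the genotype distribution are provided: an exact one built on
bounded exhaustive path enumeration (the brute-force oracle) and an empirical
one built on mass simulation.  The workhorse is :class:`WalkEngine`, which
walks many chains simultaneously with numpy and tallies edge traversals and
(primary and alternative) emissions per walk.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .graph_model import (
    DEFAULT_COPY_CAP,
    DEFAULT_ENUMERATION_LIMIT,
    GraphSpec,
    PathRecord,
    TransitionMatrix,
    enumerate_paths,
)

__all__ = [
    "PathPair",
    "GenotypeDistribution",
    "WalkEngine",
    "RunawayWalkError",
    "sample_path",
    "sample_genotype",
    "simulate_dataset",
    "exact_genotype_distribution",
    "empirical_genotype_distribution",
    "DEFAULT_STEP_LIMIT",
]

DEFAULT_STEP_LIMIT = 10_000


class RunawayWalkError(RuntimeError):
    """A walk exceeded the step guard, indicating a near-absorbing loop."""


@dataclass(frozen=True)
class PathPair:
    """An ordered pair of haplotype walks and their summed genotype."""

    first: PathRecord
    second: PathRecord
    genotype: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        expected = self.first.emissions + self.second.emissions
        if self.genotype is None:
            object.__setattr__(self, "genotype", expected)
        elif not np.array_equal(self.genotype, expected):
            raise ValueError("genotype must equal the summed pair emissions")


@dataclass
class GenotypeDistribution:
    """Probability map over genotype count vectors.

    ``kind`` is ``"exact"`` (from capped enumeration, renormalized over the
    capped path set, with the pre-normalization haplotype mass recorded in
    ``renormalization``) or ``"empirical"`` (relative frequencies of ``draws``
    simulated genotypes under ``seed``).
    """

    alphabet: tuple[str, ...]
    probs: dict[tuple[int, ...], float]
    kind: str  # "exact" | "empirical"
    draws: int | None = None
    seed: int | None = None
    renormalization: float | None = None

    def total(self) -> float:
        return float(sum(self.probs.values()))

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("\t".join(self.alphabet) + "\tprobability\n")
        for geno in sorted(self.probs):
            buf.write(
                "\t".join(str(c) for c in geno)
                + f"\t{self.probs[geno]:.12g}\n"
            )
        return buf.getvalue()


# ---------------------------------------------------------------------------
# Vectorized walking
# ---------------------------------------------------------------------------

class WalkEngine:
    """Simulates many start-to-end walks of (graph, A) simultaneously.

    Precomputes integer state coding, per-state successor/edge tables and
    cumulative transition probabilities; a batch of walks then advances in
    lock-step, each step resolved with a handful of vectorized operations.
    Per walk it tallies edge traversals, primary emissions and (optionally)
    alternative emissions, and can record full state sequences on request.
    """

    def __init__(self, g: GraphSpec, A: TransitionMatrix,
                 step_limit: int = DEFAULT_STEP_LIMIT):
        if A.graph is not g and A.graph != g:
            raise ValueError("transition matrix is bound to a different graph")
        A.validate(tol=1e-9)
        self.graph = g
        self.A = A
        self.step_limit = step_limit

        ids = list(g.state_ids)
        self._id_of = np.array(ids)
        index = {sid: i for i, sid in enumerate(ids)}
        self.start = index[g.start_id]
        self.end = index[g.end_id]

        K = len(g.alphabet)
        Ka = len(g.alt_alphabet)
        self.n_symbols = K
        self.n_alt_symbols = Ka
        sym_idx = {s: i for i, s in enumerate(g.alphabet)}
        alt_idx = {s: i for i, s in enumerate(g.alt_alphabet)}
        self.emit_idx = np.full(len(ids), -1, dtype=np.int64)
        self.alt_emit_idx = np.full(len(ids), -1, dtype=np.int64)
        for s in g.states:
            if s.kind == "emit":
                self.emit_idx[index[s.id]] = sym_idx[s.emit_symbol]
                if s.alt_emit_symbol is not None:
                    self.alt_emit_idx[index[s.id]] = alt_idx[s.alt_emit_symbol]

        max_deg = max((g.out_degree(sid) for sid in ids), default=1)
        S = len(ids)
        # rows padded with prob mass 1 so searchsorted never overruns
        self.cum = np.ones((S, max(max_deg, 1)))
        self.succ = np.zeros((S, max(max_deg, 1)), dtype=np.int64)
        self.edge_of = np.zeros((S, max(max_deg, 1)), dtype=np.int64)
        for sid in ids:
            i = index[sid]
            out = g.out_edges(sid)
            if not out:
                continue
            probs = np.array([A.probs[e] for e, _ in out])
            self.cum[i, : len(out)] = np.minimum(np.cumsum(probs), 1.0)
            self.cum[i, len(out) - 1] = 1.0  # guard against rounding
            self.succ[i, : len(out)] = [index[b] for _, (_, b) in out]
            self.edge_of[i, : len(out)] = [e for e, _ in out]

    def walk_batch(
        self,
        n: int,
        rng: np.random.Generator,
        record_alt: bool = False,
        record_states: bool = False,
    ):
        """Run ``n`` independent walks; returns a dict of per-walk tallies.

        Keys: ``edge_counts`` (n, E) int32; ``emissions`` (n, K) int32;
        ``alt_emissions`` (n, K_alt) when requested; ``states`` — a list of n
        state-id tuples — when requested.
        """
        E = len(self.graph.edges)
        edge_counts = np.zeros((n, E), dtype=np.int32)
        emissions = np.zeros((n, self.n_symbols), dtype=np.int32)
        alt = (
            np.zeros((n, self.n_alt_symbols), dtype=np.int32)
            if record_alt
            else None
        )
        seq: list[list[int]] | None = None
        if record_states:
            seq = [[self.start] for _ in range(n)]

        cur = np.full(n, self.start, dtype=np.int64)
        active = np.arange(n)
        steps = 0
        while active.size:
            steps += 1
            if steps > self.step_limit:
                stuck = sorted(set(self._id_of[cur[active]].tolist()))
                raise RunawayWalkError(
                    f"walk exceeded {self.step_limit} steps; states still "
                    f"active: {stuck} (near-absorbing loop?)"
                )
            states = cur[active]
            u = rng.random(active.size)
            choice = (u[:, None] > self.cum[states]).sum(axis=1)
            nxt = self.succ[states, choice]
            eids = self.edge_of[states, choice]
            np.add.at(edge_counts, (active, eids), 1)
            sym = self.emit_idx[nxt]
            m = sym >= 0
            if m.any():
                np.add.at(emissions, (active[m], sym[m]), 1)
            if alt is not None:
                asym = self.alt_emit_idx[nxt]
                am = asym >= 0
                if am.any():
                    np.add.at(alt, (active[am], asym[am]), 1)
            if seq is not None:
                for w, s in zip(active, nxt):
                    seq[w].append(int(s))
            cur[active] = nxt
            active = active[nxt != self.end]

        out = {"edge_counts": edge_counts, "emissions": emissions}
        if record_alt:
            out["alt_emissions"] = alt
        if record_states:
            out["states"] = [
                tuple(self._id_of[i] for i in s) for s in seq  # type: ignore[union-attr]
            ]
        return out

    def walk_pairs(self, m: int, rng: np.random.Generator,
                   record_alt: bool = False):
        """Simulate ``m`` ordered haplotype pairs (2m walks).

        Returns a dict with ``genotypes`` (m, K), per-haplotype ``emissions``
        (m, 2, K), pair-summed ``edge_counts`` (m, E), and pair-summed
        ``alt_genotypes`` (m, K_alt) when requested.
        """
        res = self.walk_batch(2 * m, rng, record_alt=record_alt)
        em = res["emissions"].reshape(m, 2, -1)
        out = {
            "genotypes": em.sum(axis=1),
            "emissions": em,
            "edge_counts": res["edge_counts"].reshape(m, 2, -1).sum(axis=1),
        }
        if record_alt:
            out["alt_genotypes"] = (
                res["alt_emissions"].reshape(m, 2, -1).sum(axis=1)
            )
        return out


# ---------------------------------------------------------------------------
# Single-walk sampling (scalar, with full path records)
# ---------------------------------------------------------------------------

def sample_path(
    g: GraphSpec,
    A: TransitionMatrix,
    rng: np.random.Generator,
    step_limit: int = DEFAULT_STEP_LIMIT,
) -> PathRecord:
    """Draw one start-to-end walk; the path probability is the edge product."""
    engine = _engine_for(g, A, step_limit)
    res = engine.walk_batch(1, rng, record_states=True)
    return PathRecord(states=res["states"][0],
                      emissions=res["emissions"][0].astype(np.int64))


def sample_genotype(
    g: GraphSpec,
    A: TransitionMatrix,
    rng: np.random.Generator,
    step_limit: int = DEFAULT_STEP_LIMIT,
) -> PathPair:
    """Two independent walks; the genotype is their element-wise emission sum."""
    first = sample_path(g, A, rng, step_limit)
    second = sample_path(g, A, rng, step_limit)
    return PathPair(first=first, second=second)


def _engine_for(g: GraphSpec, A: TransitionMatrix, step_limit: int) -> WalkEngine:
    # tiny per-matrix cache: repeated scalar sampling at a fixed A reuses tables
    cache = getattr(A, "_engine_cache", None)
    if cache is not None and cache.step_limit == step_limit and cache.graph is g:
        return cache
    engine = WalkEngine(g, A, step_limit)
    try:
        A._engine_cache = engine  # type: ignore[attr-defined]
    except Exception:
        pass
    return engine


# ---------------------------------------------------------------------------
# Whole data sets and genotype distributions
# ---------------------------------------------------------------------------

def simulate_dataset(
    g: GraphSpec,
    A: TransitionMatrix,
    N: int,
    seed: int,
    step_limit: int = DEFAULT_STEP_LIMIT,
):
    """Simulate a genotype table of N individuals (reproducible from seed)."""
    from .genotype_io import GenotypeTable  # local import to avoid a cycle

    if N < 1:
        raise ValueError("N must be at least 1")
    rng = np.random.default_rng(seed)
    engine = WalkEngine(g, A, step_limit)
    res = engine.walk_pairs(N, rng)
    width = max(4, len(str(N)))
    individuals = [f"ind{idx + 1:0{width}d}" for idx in range(N)]
    return GenotypeTable(
        individuals=individuals,
        counts=res["genotypes"].astype(np.int64),
        alphabet=g.alphabet,
    )


def haplotype_distribution(
    g: GraphSpec,
    A: TransitionMatrix,
    copy_cap: int = DEFAULT_COPY_CAP,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
    renormalize: bool = True,
    per_symbol_cap: np.ndarray | None = None,
):
    """Exact haplotype emission-vector distribution from capped enumeration.

    Returns ``(probs: dict, mass: float)`` where ``mass`` is the total
    probability of the enumerated (capped) path set; with ``renormalize`` the
    probabilities are divided by ``mass`` so they sum to one.
    """
    paths = enumerate_paths(g, copy_cap=copy_cap, limit=limit,
                            per_symbol_cap=per_symbol_cap)
    idx = g.edge_index
    logp_edge = np.log(np.where(A.probs > 0, A.probs, 1.0))
    dead = A.probs <= 0
    probs: dict[tuple[int, ...], float] = {}
    for path in paths:
        ec = path.edge_count_vector(g)
        if np.any(dead & (ec > 0)):
            continue
        p = float(np.exp(ec @ logp_edge))
        key = tuple(int(c) for c in path.emissions)
        probs[key] = probs.get(key, 0.0) + p
    mass = float(sum(probs.values()))
    if renormalize and mass > 0:
        probs = {k: v / mass for k, v in probs.items()}
    return probs, mass


def exact_genotype_distribution(
    g: GraphSpec,
    A: TransitionMatrix,
    copy_cap: int = DEFAULT_COPY_CAP,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> GenotypeDistribution:
    """Exact genotype distribution: self-convolution of the haplotype law.

    The haplotype distribution is renormalized over the capped path set (the
    truncated mass is recorded in ``renormalization``), then convolved with
    itself over ordered pairs.
    """
    hap, mass = haplotype_distribution(g, A, copy_cap=copy_cap, limit=limit)
    probs: dict[tuple[int, ...], float] = {}
    items = list(hap.items())
    for e1, p1 in items:
        for e2, p2 in items:
            key = tuple(a + b for a, b in zip(e1, e2))
            probs[key] = probs.get(key, 0.0) + p1 * p2
    return GenotypeDistribution(
        alphabet=g.alphabet,
        probs=probs,
        kind="exact",
        renormalization=mass,
    )


def empirical_genotype_distribution(
    g: GraphSpec,
    A: TransitionMatrix,
    M: int,
    seed: int,
    step_limit: int = DEFAULT_STEP_LIMIT,
) -> GenotypeDistribution:
    """Relative genotype frequencies over M simulated ordered pairs."""
    if M < 1:
        raise ValueError("M must be at least 1")
    rng = np.random.default_rng(seed)
    engine = WalkEngine(g, A, step_limit)
    genos = engine.walk_pairs(M, rng)["genotypes"]
    uniq, counts = np.unique(genos, axis=0, return_counts=True)
    probs = {
        tuple(int(c) for c in row): int(n) / M for row, n in zip(uniq, counts)
    }
    return GenotypeDistribution(
        alphabet=g.alphabet, probs=probs, kind="empirical", draws=M, seed=seed
    )
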