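"""Data-augmented Metropolis-within-Gibbs sampling of transition probabilities.

The latent variables are the ordered Markov path *pairs* compatible with each
individual's observed genotype.  One sampling cycle alternates:

1. an *incomplete Gibbs* (pool) update — for each individual, candidate path
   pairs are simulated from the current transition matrix A and the first
   pair whose summed emissions match the observed genotype replaces that
   individual's latent pair.  This is exact conditional sampling by
   rejection, so the acceptance probability is 1; individuals for which the
   pool (of bounded size n) produces no match keep their pair;
2. a *squirrel* backup update for the individuals the pool missed — a
   symmetric Metropolis kernel that proposes uniformly from the set of
   genotype-compatible pairs discovered by a deterministic, bounded,
   genotype-only-dependent tree search, accepted with probability
   min(1, P(proposed | A) / P(current | A));
3. a conjugate draw of A: each state's outgoing row is Dirichlet with
   concentration prior + latent path transition counts (MatrixDirichlet).

Rows with a single outgoing edge have probability exactly 1 throughout.
Because the pool step samples the exact conditional whenever it matches, the
sampler collapses to the closed-form conjugate posterior on graphs where
every observed genotype has a unique compatible pair.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .genotype_io import GenotypeTable
from .graph_model import (
    DEFAULT_COPY_CAP,
    EnumerationOverflowError,
    GraphSpec,
    PathRecord,
    TransitionMatrix,
    enumerate_path_arrays,
    enumerate_paths,
)
from .simulate import DEFAULT_STEP_LIMIT, PathPair, WalkEngine

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "ChainState",
    "PosteriorSamples",
    "DiagnosticsReport",
    "PosteriorSummary",
    "InsufficientSamplesError",
    "ModelIncompatibilityError",
    "LatentSpace",
    "sample_transition_matrix",
    "initialize_latent",
    "pool_path_update",
    "squirrel_update",
    "run_sampler",
    "diagnostics",
    "posterior_summary",
    "interior_project",
]

DEFAULT_SQUIRREL_BUDGET = 20_000


class ModelIncompatibilityError(ValueError):
    """An observed genotype has no compatible path pair under the graph/cap."""


class InsufficientSamplesError(ValueError):
    """Too few post-burn-in draws for the requested summary."""


@dataclass
class PriorSpec:
    """Per-edge Dirichlet concentrations (MatrixDirichlet prior on A)."""

    graph: GraphSpec
    concentrations: np.ndarray  # (E,), all > 0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (len(self.graph.edges),):
            raise ValueError("concentrations must align with the graph edges")
        if np.any(self.concentrations <= 0):
            raise ValueError("Dirichlet concentrations must be positive")

    @classmethod
    def uniform(cls, g: GraphSpec, concentration: float = 1.0) -> "PriorSpec":
        return cls(g, np.full(len(g.edges), concentration))

    @classmethod
    def jeffreys(cls, g: GraphSpec) -> "PriorSpec":
        return cls.uniform(g, 0.5)


@dataclass
class SamplerConfig:
    """Tuning knobs of the Metropolis-within-Gibbs sampler.

    ``pool_size`` is n, the maximum number of candidate path pairs drawn per
    individual per cycle; ``squirrel_budget`` bounds the node expansions of
    the compatible-pair tree search; ``copy_cap`` bounds per-symbol emissions
    per haplotype in that search.
    """

    cycles: int = 1000
    pool_size: int = 1000
    burn_in_fraction: float = 0.5
    squirrel_budget: int = DEFAULT_SQUIRREL_BUDGET
    copy_cap: int = DEFAULT_COPY_CAP
    seed: int = 0
    record_paths: bool = True
    step_limit: int = DEFAULT_STEP_LIMIT

    def __post_init__(self):
        if self.cycles < 1:
            raise ValueError("cycles must be at least 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be at least 1")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must lie in [0, 1)")


@dataclass
class ChainState:
    """Snapshot of the sampler: current A, latent pairs, cycle index."""

    A: TransitionMatrix
    latent: list[PathPair] | None
    cycle: int
    match_fraction: float


@dataclass
class PosteriorSamples:
    """Recorded draws of the transition matrix with chain metadata.

    ``draws`` has one row per cycle, flattened in graph edge order.
    ``transition_counts`` records, per cycle, the latent path-pair edge
    counts that parameterize the full conditional of A — the ingredient of
    the Rao-Blackwellized posterior ordinate in the evidence module.
    """

    graph: GraphSpec
    draws: np.ndarray  # (cycles, E)
    match_fraction: np.ndarray  # (cycles,)
    config: SamplerConfig
    prior: PriorSpec
    transition_counts: np.ndarray | None = None  # (cycles, E) int

    @property
    def n_burn(self) -> int:
        return int(self.config.burn_in_fraction * self.draws.shape[0])

    def post_burn_draws(self) -> np.ndarray:
        return self.draws[self.n_burn:]

    def post_burn_counts(self) -> np.ndarray:
        if self.transition_counts is None:
            raise ValueError("run was recorded without path draws")
        return self.transition_counts[self.n_burn:]

    def free_edge_indices(self) -> np.ndarray:
        """Edges leaving states with out-degree > 1 (the free coordinates)."""
        free = []
        for s in self.graph.states:
            out = self.graph.out_edges(s.id)
            if len(out) > 1:
                free.extend(i for i, _ in out)
        return np.array(sorted(free), dtype=np.int64)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("\t".join(f"{a}->{b}" for a, b in self.graph.edges) + "\n")
        for row in self.draws:
            buf.write("\t".join(f"{p:.10g}" for p in row) + "\n")
        return buf.getvalue()


# ---------------------------------------------------------------------------
# Conjugate transition-matrix draw
# ---------------------------------------------------------------------------

def sample_transition_matrix(
    prior: PriorSpec,
    transition_counts,
    rng: np.random.Generator,
) -> TransitionMatrix:
    """Draw A row-wise from Dirichlet(prior + counts) (MatrixDirichlet).

    ``transition_counts`` is either a vector aligned to the graph edges or a
    mapping edge -> count; a count on a non-edge is an error.  Rows with a
    single outgoing edge get probability exactly 1.
    """
    g = prior.graph
    if isinstance(transition_counts, dict):
        counts = np.zeros(len(g.edges))
        index = g.edge_index
        for edge, c in transition_counts.items():
            if tuple(edge) not in index:
                raise ValueError(f"count on non-edge {edge!r}")
            if c < 0:
                raise ValueError(f"negative count on edge {edge!r}")
            counts[index[tuple(edge)]] = c
    else:
        counts = np.asarray(transition_counts, dtype=float)
        if counts.shape != (len(g.edges),):
            raise ValueError("transition counts must align with graph edges")

    probs = np.zeros(len(g.edges))
    for s in g.states:
        if s.kind == "end":
            continue
        out = g.out_edges(s.id)
        ids = [i for i, _ in out]
        if len(ids) == 1:
            probs[ids[0]] = 1.0
        else:
            alpha = prior.concentrations[ids] + counts[ids]
            probs[ids] = rng.dirichlet(alpha)
    return TransitionMatrix(g, probs)


def interior_project(A: TransitionMatrix, tol: float = 1e-6) -> TransitionMatrix:
    """Push a matrix strictly inside the simplex (floor tol, renormalize rows).

    Rows with a single edge stay at exactly 1; needed before density
    ordinates that are undefined on the simplex boundary.
    """
    g = A.graph
    probs = A.probs.copy()
    for s in g.states:
        if s.kind == "end":
            continue
        ids = [i for i, _ in g.out_edges(s.id)]
        if len(ids) == 1:
            probs[ids[0]] = 1.0
            continue
        row = np.maximum(probs[ids], tol)
        probs[ids] = row / row.sum()
    return TransitionMatrix(g, probs)


# ---------------------------------------------------------------------------
# Genotype-compatible path pairs (deterministic bounded tree search)
# ---------------------------------------------------------------------------

@dataclass
class DecompositionSet:
    """All ordered compatible path pairs of one genotype.

    ``pair_edge_counts[k]`` is the summed edge-traversal vector of pair k;
    ``pairs[k] = (i, j)`` indexes into the enumeration snapshot this set was
    built from (``states``/``emissions``).  The set is a deterministic
    function of (graph, genotype, caps, budget) only — it does not depend
    on any current chain state, which is what makes the squirrel proposal
    symmetric.
    """

    states: list[tuple[str, ...]]  # enumeration snapshot (shared reference)
    emissions: np.ndarray  # (paths, K) of the snapshot
    pairs: list[tuple[int, int]]
    pair_edge_counts: np.ndarray  # (P, E) int
    pair_first_emissions: np.ndarray  # (P, K) int

    def path_states(self, index: int) -> tuple[str, ...]:
        return self.states[index]

    def pair_record(self, k: int) -> PathPair:
        i, j = self.pairs[k]
        return PathPair(
            first=PathRecord(states=self.states[i],
                             emissions=self.emissions[i].copy()),
            second=PathRecord(states=self.states[j],
                              emissions=self.emissions[j].copy()),
        )


#: path-count bound of the shared enumeration (per-genotype pair sets are
#: additionally bounded by the squirrel budget)
SHARED_ENUMERATION_LIMIT = 400_000


class LatentSpace:
    """Cache of per-genotype compatible pair sets for one (graph, cap, budget).

    Paths are enumerated once per cap profile (the running element-wise
    maximum of requested per-genotype caps) and shared across genotypes;
    each genotype's compatible pairs are then assembled by filtering the
    shared enumeration.  A genotype whose pair set would exceed ``budget``
    yields None — the caller falls back to the identity kernel.
    """

    def __init__(
        self,
        g: GraphSpec,
        copy_cap: int = DEFAULT_COPY_CAP,
        budget: int = DEFAULT_SQUIRREL_BUDGET,
    ):
        self.graph = g
        self.copy_cap = copy_cap
        self.budget = budget
        self._cache: dict[tuple[int, ...], DecompositionSet | None] = {}
        K = len(g.alphabet)
        self._caps = np.zeros(K, dtype=np.int64)  # caps of the shared arrays
        self._states: list[tuple[str, ...]] = []
        self._emis = np.zeros((0, K), dtype=np.int64)
        self._ec = np.zeros((0, len(g.edges)), dtype=np.int64)
        self._by_key: dict[tuple[int, ...], list[int]] = {}
        self._overflowed = False

    def _ensure_enumerated(self, caps: np.ndarray) -> bool:
        """Cover ``caps`` with the shared enumeration; False on overflow.

        Normally the shared arrays grow to the running union of requested
        caps.  If the union enumeration overflows, the exact requested caps
        are tried instead (replacing the shared arrays; cached sets keep
        references to their own snapshots, so they stay valid).
        """
        if np.all(caps <= self._caps) and self._states:
            return True
        for target in (
            [np.maximum(self._caps, caps)] if not self._overflowed else []
        ) + [caps]:
            try:
                states, emis, ec = enumerate_path_arrays(
                    self.graph, per_symbol_cap=target,
                    limit=SHARED_ENUMERATION_LIMIT,
                )
            except EnumerationOverflowError:
                if target is not caps:
                    self._overflowed = True  # stop growing the union
                continue
            self._caps = np.asarray(target, dtype=np.int64)
            self._states, self._emis, self._ec = states, emis, ec
            self._by_key = {}
            for j, e in enumerate(emis):
                self._by_key.setdefault(tuple(int(c) for c in e), []).append(j)
            return True
        return False

    def decompositions(self, genotype) -> DecompositionSet | None:
        """Compatible ordered pairs, or None if the bounded search overflowed."""
        key = tuple(int(c) for c in genotype)
        if key in self._cache:
            return self._cache[key]
        if self.budget <= 0:
            self._cache[key] = None
            return None
        caps = np.minimum(np.array(key, dtype=np.int64), self.copy_cap)
        if not self._ensure_enumerated(caps):
            self._cache[key] = None
            return None

        target = np.array(key, dtype=np.int64)
        candidates = np.nonzero((self._emis <= target).all(axis=1))[0]
        pi: list[int] = []
        pj: list[int] = []
        overflow = False
        for i in candidates:
            rest = tuple(int(c) for c in (target - self._emis[i]))
            partners = self._by_key.get(rest)
            if not partners:
                continue
            pi.extend([int(i)] * len(partners))
            pj.extend(partners)
            if len(pi) > self.budget:
                overflow = True
                break
        if overflow:
            self._cache[key] = None
            return None
        if not pi:
            result = DecompositionSet(
                states=self._states, emissions=self._emis, pairs=[],
                pair_edge_counts=np.zeros((0, len(self.graph.edges)),
                                          dtype=np.int64),
                pair_first_emissions=np.zeros(
                    (0, len(self.graph.alphabet)), dtype=np.int64),
            )
            self._cache[key] = result
            return result
        ai = np.array(pi)
        aj = np.array(pj)
        result = DecompositionSet(
            states=self._states,
            emissions=self._emis,
            pairs=list(zip(pi, pj)),
            pair_edge_counts=self._ec[ai] + self._ec[aj],
            pair_first_emissions=self._emis[ai],
        )
        self._cache[key] = result
        return result

    def pair_record(self, genotype, k: int) -> PathPair:
        ds = self.decompositions(genotype)
        assert ds is not None and ds.pairs
        return ds.pair_record(k)


def initialize_latent(
    g: GraphSpec,
    table: GenotypeTable,
    copy_cap: int = DEFAULT_COPY_CAP,
    rng: np.random.Generator | None = None,
    preference: tuple[str, ...] | None = None,
    space: LatentSpace | None = None,
) -> list[PathPair]:
    """One compatible path pair per individual, by exhaustive tree search.

    With ``rng`` given, each individual's pair is drawn uniformly from its
    compatible set; otherwise the deterministic first pair (enumeration
    order) is used.  ``preference`` — an ordered ranking of state ids — biases
    the deterministic choice toward pairs whose walks visit higher-ranked
    states first; the modes module uses this for overdispersed restarts.

    Raises :class:`ModelIncompatibilityError` naming the first individual
    whose genotype admits no decomposition (wrong graph or cap too small).
    """
    space = space or LatentSpace(g, copy_cap=copy_cap, budget=10 ** 6)
    chosen_by_genotype: dict[tuple[int, ...], int] = {}
    latent: list[PathPair] = []
    for ind, row in zip(table.individuals, table.counts):
        key = tuple(int(c) for c in row)
        src = space
        ds = src.decompositions(key)
        if ds is None:
            # genotype beyond the squirrel budget: widen the search just for
            # initialization (cached on the space, so restarts reuse it)
            fallback = getattr(space, "_init_fallback", None)
            if fallback is None:
                fallback = LatentSpace(g, copy_cap=copy_cap, budget=10 ** 7)
                space._init_fallback = fallback  # type: ignore[attr-defined]
            src = fallback
            ds = src.decompositions(key)
        if ds is None or not ds.pairs:
            raise ModelIncompatibilityError(
                f"individual {ind!r}: genotype {key} has no compatible "
                f"path pair under copy cap {copy_cap} — wrong graph or cap?"
            )
        if rng is not None:
            k = int(rng.integers(len(ds.pairs)))
        elif preference is not None:
            if key not in chosen_by_genotype:
                chosen_by_genotype[key] = _preferred_pair(ds, preference)
            k = chosen_by_genotype[key]
        else:
            k = 0
        latent.append(src.pair_record(key, k))
    return latent


def _preferred_pair(ds: DecompositionSet, preference: tuple[str, ...]) -> int:
    rank = {sid: r for r, sid in enumerate(preference)}

    def state_key(sid: str):
        return (0, rank[sid]) if sid in rank else (1, sid)

    def pair_key(k: int):
        i, j = ds.pairs[k]
        return (
            tuple(state_key(s) for s in ds.path_states(i)),
            tuple(state_key(s) for s in ds.path_states(j)),
        )

    return min(range(len(ds.pairs)), key=pair_key)


# ---------------------------------------------------------------------------
# Pool (incomplete Gibbs) update
# ---------------------------------------------------------------------------

def _pool_core(
    engine: WalkEngine,
    targets: np.ndarray,  # (N, K)
    pool_size: int,
    rng: np.random.Generator,
    record_states: bool = False,
):
    """Early-stopping pool update over all individuals at once.

    Pools are independent per individual; candidate pairs are drawn in
    growing chunks and an individual leaves the pool as soon as one of its
    candidates matches (the *first* match in its own draw order is kept, as
    in sequential rejection sampling).  Returns a dict individual-index ->
    {"edge_counts", "emissions"[, "states"]} for the matched individuals.
    """
    N, K = targets.shape
    unmatched = np.arange(N)
    results: dict[int, dict] = {}
    drawn = 0
    chunk = 4
    while unmatched.size and drawn < pool_size:
        b = min(chunk, pool_size - drawn)
        m = unmatched.size
        res = engine.walk_batch(2 * m * b, rng, record_states=record_states)
        em = res["emissions"].reshape(m, b, 2, K)
        geno = em.sum(axis=2)
        match = (geno == targets[unmatched][:, None, :]).all(axis=2)  # (m, b)
        has = match.any(axis=1)
        first = np.argmax(match, axis=1)
        E = res["edge_counts"].shape[1]
        ec = res["edge_counts"].reshape(m, b, 2, E)
        for pos in np.nonzero(has)[0]:
            i = int(unmatched[pos])
            j = int(first[pos])
            entry = {
                "edge_counts": ec[pos, j].sum(axis=0).astype(np.int64),
                "emissions": em[pos, j].astype(np.int64),
            }
            if record_states:
                w = (pos * b + j) * 2
                entry["states"] = (res["states"][w], res["states"][w + 1])
            results[i] = entry
        unmatched = unmatched[~has]
        drawn += b
        chunk *= 2
    return results


def pool_path_update(
    g: GraphSpec,
    A: TransitionMatrix,
    table: GenotypeTable,
    latent: list[PathPair],
    pool_size: int,
    rng: np.random.Generator,
    step_limit: int = DEFAULT_STEP_LIMIT,
) -> tuple[list[PathPair], np.ndarray]:
    """Incomplete Gibbs refresh of the latent pairs (acceptance 1).

    Returns the updated latent list and a boolean match-flag vector; flagged
    False means the individual kept its current pair (identity kernel).
    """
    if pool_size < 1:
        raise ValueError("pool_size must be at least 1")
    engine = WalkEngine(g, A, step_limit)
    results = _pool_core(engine, table.counts, pool_size, rng,
                         record_states=True)
    updated = list(latent)
    flags = np.zeros(table.n, dtype=bool)
    for i, entry in results.items():
        s1, s2 = entry["states"]
        e1, e2 = entry["emissions"]
        updated[i] = PathPair(
            first=PathRecord(states=s1, emissions=np.asarray(e1)),
            second=PathRecord(states=s2, emissions=np.asarray(e2)),
        )
        flags[i] = True
    return updated, flags


# ---------------------------------------------------------------------------
# Squirrel backup kernel
# ---------------------------------------------------------------------------

def _squirrel_core(
    ds: DecompositionSet,
    cur_edge_counts: np.ndarray,
    log_edge_probs: np.ndarray,
    rng: np.random.Generator,
) -> int | None:
    """One symmetric MH step on the compatible-pair set.

    Proposes a pair uniformly from ``ds`` and accepts with probability
    min(1, P(proposed|A)/P(current|A)); returns the accepted pair index or
    None to keep the current pair.
    """
    if not ds.pairs:
        return None
    k = int(rng.integers(len(ds.pairs)))
    delta = ds.pair_edge_counts[k] - cur_edge_counts
    dead = np.isneginf(log_edge_probs)
    if np.any((delta > 0) & dead):
        return None  # proposal traverses a zero-probability edge
    nz = (delta != 0) & ~dead  # dropped dead edges have delta <= 0: ratio +inf
    if np.any((delta != 0) & dead):
        return k  # current pair uses a dead edge, proposal does not
    log_ratio = float((delta[nz] * log_edge_probs[nz]).sum())
    if log_ratio >= 0 or np.log(rng.random()) < log_ratio:
        return k
    return None


def squirrel_update(
    g: GraphSpec,
    A: TransitionMatrix,
    genotype,
    current: PathPair,
    budget: int = DEFAULT_SQUIRREL_BUDGET,
    copy_cap: int = DEFAULT_COPY_CAP,
    rng: np.random.Generator | None = None,
    space: LatentSpace | None = None,
) -> PathPair:
    """Symmetric bounded tree-search Metropolis update of one latent pair.

    The proposal set depends only on (graph, genotype, cap, budget) — never
    on the current pair — so the kernel is symmetric and the Metropolis
    ratio reduces to the path-pair probability ratio under A.  Falls back to
    the identity when the search overflows the budget or nothing is found.
    """
    rng = rng if rng is not None else np.random.default_rng()
    space = space or LatentSpace(g, copy_cap=copy_cap, budget=budget)
    key = tuple(int(c) for c in genotype)
    ds = space.decompositions(key)
    if ds is None or not ds.pairs:
        return current
    with np.errstate(divide="ignore"):
        logp = np.log(A.probs)
    cur_ec = (current.first.edge_count_vector(g)
              + current.second.edge_count_vector(g))
    k = _squirrel_core(ds, cur_ec, logp, rng)
    if k is None:
        return current
    return space.pair_record(key, k)


# ---------------------------------------------------------------------------
# The full sampler
# ---------------------------------------------------------------------------

def run_sampler(
    g: GraphSpec,
    table: GenotypeTable,
    prior: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    init_preference: tuple[str, ...] | None = None,
    space: LatentSpace | None = None,
) -> PosteriorSamples:
    """Run the data-augmented Metropolis-within-Gibbs sampler.

    Per cycle: pool update of all latent pairs, squirrel backup for the
    individuals the pool missed, then a conjugate MatrixDirichlet draw of A
    from the latent transition counts.  Fully reproducible from
    ``config.seed``.  ``init_preference`` selects deterministic concentrated
    initial decompositions (see :func:`initialize_latent`); by default the
    initial pairs are drawn uniformly at random.  ``space`` may pass a
    pre-built compatible-pair cache (it is a deterministic function of the
    graph and caps, so sharing one across runs is safe and fast).
    """
    prior = prior or PriorSpec.uniform(g)
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    if space is None:
        space = LatentSpace(g, copy_cap=config.copy_cap,
                            budget=config.squirrel_budget)
    elif space.graph != g or space.copy_cap != config.copy_cap:
        raise ValueError("shared LatentSpace does not match graph/copy_cap")

    targets = table.counts
    if targets.size:
        # enumerate the compatible-path universe once, at the table's caps
        space._ensure_enumerated(
            np.minimum(targets.max(axis=0), config.copy_cap).astype(np.int64)
        )
    N, K = targets.shape
    E = len(g.edges)

    # initial latent pairs -> edge-count / emission arrays
    init_rng = None if init_preference is not None else rng
    init_pairs = initialize_latent(
        g, table, copy_cap=config.copy_cap, rng=init_rng,
        preference=init_preference, space=space,
    )
    latent_ec = np.zeros((N, E), dtype=np.int64)
    latent_em = np.zeros((N, 2, K), dtype=np.int64)
    for i, pair in enumerate(init_pairs):
        latent_ec[i] = (pair.first.edge_count_vector(g)
                        + pair.second.edge_count_vector(g))
        latent_em[i, 0] = pair.first.emissions
        latent_em[i, 1] = pair.second.emissions

    A = sample_transition_matrix(prior, latent_ec.sum(axis=0), rng)

    draws = np.zeros((config.cycles, E))
    counts_rec = (
        np.zeros((config.cycles, E), dtype=np.int64)
        if config.record_paths
        else None
    )
    match_fraction = np.zeros(config.cycles)

    for cycle in range(config.cycles):
        engine = WalkEngine(g, A, config.step_limit)
        results = _pool_core(engine, targets, config.pool_size, rng)
        for i, entry in results.items():
            latent_ec[i] = entry["edge_counts"]
            latent_em[i] = entry["emissions"]
        matched = np.zeros(N, dtype=bool)
        matched[list(results)] = True
        match_fraction[cycle] = matched.mean()

        if not matched.all():
            with np.errstate(divide="ignore"):
                logp = np.log(A.probs)
            for i in np.nonzero(~matched)[0]:
                key = tuple(int(c) for c in targets[i])
                ds = space.decompositions(key)
                if ds is None or not ds.pairs:
                    continue
                k = _squirrel_core(ds, latent_ec[i], logp, rng)
                if k is not None:
                    latent_ec[i] = ds.pair_edge_counts[k]
                    latent_em[i, 0] = ds.pair_first_emissions[k]
                    latent_em[i, 1] = targets[i] - ds.pair_first_emissions[k]

        # latent invariant: every pair still reproduces its genotype
        if not np.array_equal(latent_em.sum(axis=1), targets):
            raise AssertionError("latent pair lost its genotype (internal bug)")

        totals = latent_ec.sum(axis=0)
        A = sample_transition_matrix(prior, totals, rng)
        draws[cycle] = A.probs
        if counts_rec is not None:
            counts_rec[cycle] = totals

    return PosteriorSamples(
        graph=g,
        draws=draws,
        match_fraction=match_fraction,
        config=config,
        prior=prior,
        transition_counts=counts_rec,
    )


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    """Per-edge mixing diagnostics over one or more chains."""

    edges: tuple[tuple[str, str], ...]
    ess: dict[tuple[str, str], float | None]
    autocorrelation_time: dict[tuple[str, str], float | None]
    psrf: dict[tuple[str, str], float | None] | None
    n_chains: int
    n_draws_per_chain: int


def diagnostics(
    s: PosteriorSamples,
    others: list[PosteriorSamples] | None = None,
) -> DiagnosticsReport:
    """Integrated autocorrelation time, ESS and (multi-chain) PSRF per edge.

    Burn-in is removed per each chain's config.  Constant coordinates (rows
    with a single edge, or degenerate posteriors) are reported as None.
    """
    import arviz as az

    chains = [s] + list(others or [])
    post = [c.post_burn_draws() for c in chains]
    n_draws = min(p.shape[0] for p in post)
    if n_draws < 10:
        raise InsufficientSamplesError(
            f"only {n_draws} post-burn-in draws; at least 10 required"
        )
    stacked = np.stack([p[:n_draws] for p in post])  # (chains, draws, E)

    g = s.graph
    ess: dict = {}
    iat: dict = {}
    psrf: dict | None = {} if len(chains) >= 2 else None
    total = stacked.shape[0] * stacked.shape[1]
    for e_idx, edge in enumerate(g.edges):
        col = stacked[:, :, e_idx]
        if np.ptp(col) == 0.0:
            ess[edge] = None
            iat[edge] = None
            if psrf is not None:
                psrf[edge] = None
            continue
        e = float(az.ess(col))
        ess[edge] = e
        iat[edge] = total / e if e > 0 else None
        if psrf is not None:
            psrf[edge] = float(az.rhat(col))
    return DiagnosticsReport(
        edges=g.edges, ess=ess, autocorrelation_time=iat, psrf=psrf,
        n_chains=len(chains), n_draws_per_chain=n_draws,
    )


@dataclass
class PosteriorSummary:
    """Per-edge location and central credible-interval summaries."""

    edges: tuple[tuple[str, str], ...]
    mean: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    mean_matrix: TransitionMatrix  # row-renormalized posterior mean
    max_row_deviation: float  # |row sum - 1| before renormalization

    def as_rows(self) -> list[dict]:
        return [
            {
                "edge": f"{a}->{b}",
                "mean": float(self.mean[i]),
                "median": float(self.median[i]),
                "lower": float(self.lower[i]),
                "upper": float(self.upper[i]),
            }
            for i, (a, b) in enumerate(self.edges)
        ]


def posterior_summary(
    s: PosteriorSamples, level: float = 0.95
) -> PosteriorSummary:
    """Post-burn-in mean/median/central credible interval per edge.

    The mean matrix is renormalized to be exactly row-stochastic; the largest
    pre-normalization row-sum deviation is reported.
    """
    post = s.post_burn_draws()
    if post.shape[0] < 10:
        raise InsufficientSamplesError(
            f"only {post.shape[0]} post-burn-in draws; at least 10 required"
        )
    mean = post.mean(axis=0)
    median = np.median(post, axis=0)
    tail = (1.0 - level) / 2.0
    lower = np.quantile(post, tail, axis=0)
    upper = np.quantile(post, 1.0 - tail, axis=0)

    g = s.graph
    renorm = mean.copy()
    max_dev = 0.0
    for st in g.states:
        if st.kind == "end":
            continue
        ids = [i for i, _ in g.out_edges(st.id)]
        row_sum = float(mean[ids].sum())
        max_dev = max(max_dev, abs(row_sum - 1.0))
        if row_sum > 0:
            renorm[ids] = mean[ids] / row_sum
    mean_matrix = TransitionMatrix(g, renorm)
    mean_matrix.validate(tol=1e-9)
    return PosteriorSummary(
        edges=g.edges, mean=mean, median=median, lower=lower, upper=upper,
        level=level, mean_matrix=mean_matrix, max_row_deviation=max_dev,
    )
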