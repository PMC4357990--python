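"""Multimodal posterior dissection: restarts, k-means modes, per-mode evidence.

Graphs in which emitting blocks are fully interconnected carry no ordering
information in the data, so the posterior of A is multimodal: with m gene
blocks the highest-probability path can order them in m! ways, and the modes
sit far apart in parameter space (near the corners of a cross-polytope for
m = 3).  A single chain practically never jumps between such modes, so the
procedure is: run the sampler repeatedly from overdispersed starting points,
pool the post-burn-in draws of all runs, cluster them with k-means in the
free-parameter coordinates, and rank the clusters by the Chib-Jeliazkov
marginal likelihood of their member runs evaluated at the cluster-mean
matrix.  If gene copy numbers are fully independent all modes tie; any
copy-number linkage between two genes breaks the symmetry toward orders
that place them adjacently.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .evidence import EvidenceResult, chib_log_marginal
from .genotype_io import GenotypeTable
from .graph_model import (
    DEFAULT_COPY_CAP,
    EnumerationOverflowError,
    GraphSpec,
    PathRecord,
    TransitionMatrix,
)
from .inference import (
    PosteriorSamples,
    PriorSpec,
    SamplerConfig,
    interior_project,
    run_sampler,
)

__all__ = [
    "ModeReport",
    "ModeCluster",
    "ClusterResult",
    "run_restarts",
    "cluster_modes",
    "rank_modes",
    "highest_probability_path",
]


# ---------------------------------------------------------------------------
# Restarts
# ---------------------------------------------------------------------------

def _nth_permutation(items: tuple[str, ...], index: int) -> tuple[str, ...]:
    """The index-th permutation (lexicographic, factorial number system)."""
    pool = list(items)
    n = len(pool)
    index %= math.factorial(n)
    out = []
    for pos in range(n, 0, -1):
        f = math.factorial(pos - 1)
        out.append(pool.pop(index // f))
        index %= f
    return tuple(out)


def run_restarts(
    g: GraphSpec,
    table: GenotypeTable,
    prior: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    R: int = 12,
    seeds: list[int] | None = None,
    init: str = "stratified",
    space=None,
) -> list[PosteriorSamples]:
    """R independent sampler runs with overdispersed initializations.

    ``init="random"`` draws each run's initial latent decompositions
    uniformly at random.  ``init="stratified"`` (default) instead starts run
    r from the deterministic decomposition preferred under the r-th
    lexicographic permutation of the emitting-state ids — cycling through
    permutations so that, on label-symmetric graphs, the restarts cover the
    symmetry-related basins systematically rather than by chance (the usual
    overdispersed-starting-point practice, made deterministic).
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    prior = prior or PriorSpec.uniform(g)
    config = config or SamplerConfig()
    if seeds is None:
        seeds = [
            int(s) for s in
            np.random.SeedSequence(config.seed).generate_state(R) % (2 ** 31)
        ]
    if len(seeds) != R or len(set(seeds)) != R:
        raise ValueError("need R distinct seeds")

    if space is None:
        from .inference import LatentSpace

        space = LatentSpace(g, copy_cap=config.copy_cap,
                            budget=config.squirrel_budget)
    emit_ids = tuple(s.id for s in g.states if s.kind == "emit")
    chains: list[PosteriorSamples] = []
    for r in range(R):
        cfg = SamplerConfig(**{**config.__dict__, "seed": seeds[r]})
        pref = _nth_permutation(emit_ids, r) if init == "stratified" else None
        chains.append(
            run_sampler(g, table, prior, cfg, init_preference=pref, space=space)
        )
    return chains


# ---------------------------------------------------------------------------
# k-means clustering of pooled draws
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """k-means assignment of pooled post-burn-in draws to candidate modes."""

    k: int
    labels: np.ndarray  # (pooled_draws,)
    chain_of_draw: np.ndarray  # (pooled_draws,) chain index per pooled draw
    means: list[TransitionMatrix]  # row-renormalized cluster means
    free_edges: np.ndarray  # coordinate indices used for clustering
    inertia: float


def cluster_modes(
    chains: list[PosteriorSamples],
    k: int,
    burn_in_fraction: float | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Pool post-burn-in draws of all chains and k-means them into k modes.

    Clustering runs on the flattened free-parameter coordinates (edges of
    multi-edge rows, in fixed edge order), with k-means++ initialization, 10
    restarts and a fixed random state, so the result is deterministic given
    ``seed``.  Cluster means are re-embedded as full row-stochastic matrices.
    """
    if not chains:
        raise ValueError("need at least one chain")
    g = chains[0].graph
    free = chains[0].free_edge_indices()
    pooled = []
    chain_of = []
    for ci, c in enumerate(chains):
        if burn_in_fraction is None:
            d = c.post_burn_draws()
        else:
            n_burn = int(burn_in_fraction * c.draws.shape[0])
            d = c.draws[n_burn:]
        pooled.append(d)
        chain_of.append(np.full(d.shape[0], ci))
    X_full = np.vstack(pooled)
    chain_of_draw = np.concatenate(chain_of)
    if X_full.shape[0] < k:
        raise ValueError(
            f"k={k} exceeds the {X_full.shape[0]} pooled post-burn-in draws"
        )
    X = X_full[:, free]

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(X)

    means: list[TransitionMatrix] = []
    for j in range(k):
        member = X_full[labels == j]
        mean = member.mean(axis=0)
        probs = mean.copy()
        for s in g.states:
            if s.kind == "end":
                continue
            ids = [i for i, _ in g.out_edges(s.id)]
            if len(ids) == 1:
                probs[ids[0]] = 1.0
            else:
                row = probs[ids]
                probs[ids] = row / row.sum()
        means.append(TransitionMatrix(g, probs))
    return ClusterResult(
        k=k, labels=labels, chain_of_draw=chain_of_draw, means=means,
        free_edges=free, inertia=float(km.inertia_),
    )


# ---------------------------------------------------------------------------
# Per-mode evidence ranking
# ---------------------------------------------------------------------------

@dataclass
class ModeCluster:
    """One candidate optimum: mean matrix, membership and evidence."""

    index: int  # original cluster label
    mean: TransitionMatrix
    member_runs: list[int]
    member_draws: int
    log_ml_mean: float
    log_ml_sd: float
    log_ml_se: float  # pooled: likelihood-ordinate MC error + run scatter
    log_ml_per_run: list[float]
    best_path: PathRecord
    gene_order: tuple[str, ...]  # emitted symbols along the best path


@dataclass
class ModeReport:
    """Clusters sorted by mean CJ log marginal likelihood (descending)."""

    clusters: list[ModeCluster]
    run_assignment: dict[int, int]  # run index -> cluster index (majority)

    def gene_orders(self) -> list[tuple[str, ...]]:
        return [c.gene_order for c in self.clusters]


def rank_modes(
    g: GraphSpec,
    table: GenotypeTable,
    chains: list[PosteriorSamples],
    clusters: ClusterResult,
    prior: PriorSpec | None = None,
    copy_cap: int = DEFAULT_COPY_CAP,
    likelihood_method: str = "simulated",
    likelihood_draws: int = 100_000,
    seed: int = 0,
    interior_tol: float = 1e-6,
) -> ModeReport:
    """Evaluate each mode's evidence and order the modes by it.

    Each run is assigned to the cluster holding the majority of its draws;
    the CJ log marginal likelihood of every member run is evaluated at its
    cluster's (interior-projected) mean matrix, and the cluster is scored by
    the mean +- sd over member runs.  The likelihood ordinate defaults to
    the simulated approximation (fully connected graphs make exact
    enumeration explode combinatorially) and is computed once per cluster —
    it depends only on A*.  The report also carries each mode's
    highest-probability path and the gene (symbol) order it emits.
    """
    from .evidence import log_likelihood

    prior = prior or PriorSpec.uniform(g)
    # majority run -> cluster assignment
    run_assignment: dict[int, int] = {}
    for ci in range(len(chains)):
        mask = clusters.chain_of_draw == ci
        if not mask.any():
            continue
        counts = np.bincount(clusters.labels[mask], minlength=clusters.k)
        run_assignment[ci] = int(np.argmax(counts))

    report_clusters: list[ModeCluster] = []
    for j in range(clusters.k):
        members = [r for r, c in run_assignment.items() if c == j]
        a_star = interior_project(clusters.means[j], tol=interior_tol)
        lik = log_likelihood(
            g, a_star, table, method=likelihood_method, M=likelihood_draws,
            copy_cap=copy_cap, seed=seed + j,
        )
        log_mls = []
        for r in members:
            res = chib_log_marginal(
                g, table, prior, chains[r], a_star=a_star,
                likelihood_method=likelihood_method, copy_cap=copy_cap,
                likelihood_value=lik,
            )
            log_mls.append(res.log_marginal_likelihood)
        best = highest_probability_path(g, clusters.means[j], copy_cap)
        order = _emitted_sequence(g, best)
        sd = float(np.std(log_mls, ddof=1)) if len(log_mls) > 1 else 0.0
        run_se = sd / math.sqrt(len(log_mls)) if log_mls else float("nan")
        report_clusters.append(
            ModeCluster(
                index=j,
                mean=clusters.means[j],
                member_runs=members,
                member_draws=int((clusters.labels == j).sum()),
                log_ml_mean=float(np.mean(log_mls)) if log_mls else float("nan"),
                log_ml_sd=sd,
                log_ml_se=float(math.sqrt(lik[1] ** 2 + run_se ** 2)),
                log_ml_per_run=log_mls,
                best_path=best,
                gene_order=order,
            )
        )
    report_clusters.sort(
        key=lambda c: (-(c.log_ml_mean if c.log_ml_mean == c.log_ml_mean
                         else -np.inf), c.index)
    )
    return ModeReport(clusters=report_clusters, run_assignment=run_assignment)


def _emitted_sequence(g: GraphSpec, path: PathRecord) -> tuple[str, ...]:
    emit_of = {s.id: s.emit_symbol for s in g.states if s.kind == "emit"}
    return tuple(emit_of[sid] for sid in path.states if sid in emit_of)


# ---------------------------------------------------------------------------
# Highest-probability path (best-first search)
# ---------------------------------------------------------------------------

def highest_probability_path(
    g: GraphSpec,
    A: TransitionMatrix,
    copy_cap: int = DEFAULT_COPY_CAP,
    expansion_limit: int = 500_000,
) -> PathRecord:
    """Maximum-probability start-to-end path under per-symbol emission caps.

    Best-first search over partial paths ordered by probability (admissible:
    extending a path never increases its probability); ties are broken
    lexicographically by the state-id sequence.  Dominated revisits of the
    same (state, emission-count) configuration are pruned.
    """
    from .graph_model import validate_graph

    violations = validate_graph(g)
    if violations:
        from .graph_model import GraphValidationError

        raise GraphValidationError(violations)

    alphabet = g.alphabet
    sym_idx = {s: i for i, s in enumerate(alphabet)}
    emit_of = {
        s.id: sym_idx[s.emit_symbol]
        for s in g.states if s.kind == "emit" and s.emit_symbol is not None
    }
    succ: dict[str, list[tuple[str, float]]] = {s.id: [] for s in g.states}
    for (a, b), p in zip(g.edges, A.probs):
        if p > 0.0:
            succ[a].append((b, float(p)))
    for lst in succ.values():
        lst.sort(key=lambda t: t[0])

    start, end = g.start_id, g.end_id
    zero = tuple(0 for _ in alphabet)
    heap: list[tuple[float, tuple[str, ...], str, tuple[int, ...]]] = [
        (0.0, (start,), start, zero)
    ]
    best_seen: dict[tuple[str, tuple[int, ...]], float] = {(start, zero): 0.0}
    expansions = 0
    while heap:
        neglogp, states, state, counts = heapq.heappop(heap)
        if state == end:
            return PathRecord(
                states=states,
                emissions=np.array(counts, dtype=np.int64),
            )
        if best_seen.get((state, counts), np.inf) < neglogp:
            continue
        for nxt, p in succ[state]:
            expansions += 1
            if expansions > expansion_limit:
                raise EnumerationOverflowError(
                    f"best-first search exceeded {expansion_limit} expansions"
                )
            new_counts = counts
            k = emit_of.get(nxt)
            if k is not None:
                if counts[k] + 1 > copy_cap:
                    continue
                new_counts = counts[:k] + (counts[k] + 1,) + counts[k + 1:]
            nl = neglogp - math.log(p)
            key = (nxt, new_counts)
            if best_seen.get(key, np.inf) < nl:  # keep ties: lex order decides
                continue
            best_seen[key] = nl
            heapq.heappush(heap, (nl, states + (nxt,), nxt, new_counts))
    raise ValueError("no positive-probability start-to-end path exists")
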