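"""Mode dissection: restarts, clustering, ranking, best paths."""

import numpy as np
import pytest

from cnavhmm.fixtures import make_scenario, scenario_matrix
from cnavhmm.graph_model import (
    GraphSpec,
    StateSpec,
    TransitionMatrix,
    build_canonical,
    enumerate_paths,
)
from cnavhmm.inference import PosteriorSamples, PriorSpec, SamplerConfig
from cnavhmm.modes import (
    cluster_modes,
    highest_probability_path,
    rank_modes,
    run_restarts,
)
from conftest import hwe_matrix


# ---------------------------------------------------------------------------
# Highest-probability path
# ---------------------------------------------------------------------------

def test_chain_graph_has_unique_best_path():
    g = GraphSpec(
        states=(StateSpec("s", "start"),
                StateSpec("a", "emit", emit_symbol="A"),
                StateSpec("end", "end")),
        edges=(("s", "a"), ("a", "end")),
    )
    A = TransitionMatrix(g, np.array([1.0, 1.0]))
    best = highest_probability_path(g, A, copy_cap=3)
    assert best.states == ("s", "a", "end")


def test_best_path_emits_majority_allele(hwe_graph):
    A = hwe_matrix(hwe_graph, 0.7)
    best = highest_probability_path(hwe_graph, A, copy_cap=2)
    assert best.emissions.tolist() == [1, 0]


@pytest.mark.parametrize("name,params", [
    ("hwe_biallelic", {"alleles": ("H131", "R131"), "p": 0.35}),
    ("cnav_multiallele",
     {"alleles": ("A", "B"), "loss": 0.3, "gain": 0.2,
      "allele_probs": [0.55, 0.45]}),
    ("cnav_loh", {"alleles": ("A", "B"), "loss": 0.2, "loh": 0.3}),
    ("tandem_allele", {}),
])
def test_best_first_equals_brute_force_argmax(name, params):
    """Best-first search agrees with exhaustive enumeration at cap 3."""
    g = build_canonical(name, **{k: v for k, v in params.items()
                                 if k in ("alleles",)})
    A = scenario_matrix(name, g, params)
    best = highest_probability_path(g, A, copy_cap=3)
    with np.errstate(divide="ignore"):
        logp = np.log(A.probs)

    def path_logp(p):
        ec = p.edge_count_vector(g)
        if np.any((ec > 0) & np.isneginf(logp)):
            return -np.inf
        nz = ec > 0
        return float((ec[nz] * logp[nz]).sum())

    paths = enumerate_paths(g, copy_cap=3)
    brute = max(paths, key=lambda p: (path_logp(p), [-ord(c) for s in p.states for c in s]))
    assert path_logp(best) == pytest.approx(path_logp(brute), abs=1e-12)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _chain_with_draws(g, draws):
    cfg = SamplerConfig(cycles=draws.shape[0], burn_in_fraction=0.0, seed=0)
    return PosteriorSamples(graph=g, draws=draws,
                            match_fraction=np.ones(draws.shape[0]),
                            config=cfg, prior=PriorSpec.uniform(g))


def test_two_separated_blobs_cluster_perfectly(hwe_graph):
    g = hwe_graph
    rng = np.random.default_rng(1)
    e = g.edge_index[("choose", "H131")]
    e2 = g.edge_index[("choose", "R131")]

    def blob(center, n):
        d = np.ones((n, len(g.edges)))
        p = np.clip(center + 0.01 * rng.standard_normal(n), 0.01, 0.99)
        d[:, e] = p
        d[:, e2] = 1 - p
        return d

    c1 = _chain_with_draws(g, blob(0.15, 80))
    c2 = _chain_with_draws(g, blob(0.85, 80))
    res = cluster_modes([c1, c2], k=2, seed=3)
    labels = res.labels
    assert len(set(labels[:80])) == 1
    assert len(set(labels[80:])) == 1
    assert labels[0] != labels[-1]
    for m in res.means:
        m.validate(tol=1e-9)


def test_single_cluster_mean_is_pooled_mean(hwe_graph):
    g = hwe_graph
    rng = np.random.default_rng(2)
    d = np.ones((50, len(g.edges)))
    e = g.edge_index[("choose", "H131")]
    d[:, e] = rng.uniform(0.3, 0.5, 50)
    d[:, g.edge_index[("choose", "R131")]] = 1 - d[:, e]
    res = cluster_modes([_chain_with_draws(g, d)], k=1, seed=4)
    assert res.means[0].probs[e] == pytest.approx(d[:, e].mean(), rel=1e-9)


def test_k_exceeding_draws_is_an_error(hwe_graph):
    d = np.ones((4, len(hwe_graph.edges)))
    with pytest.raises(ValueError, match="exceeds"):
        cluster_modes([_chain_with_draws(hwe_graph, d)], k=10, seed=0)


# ---------------------------------------------------------------------------
# Restarts and ranking
# ---------------------------------------------------------------------------

def test_restarts_are_reproducible_and_distinct_seeds_required(hwe_graph):
    sc = make_scenario("hwe_biallelic",
                       {"alleles": ("H131", "R131"), "p": 0.4}, N=40, seed=5)
    prior = PriorSpec.uniform(sc.graph)
    cfg = SamplerConfig(cycles=40, pool_size=50, seed=6)
    c1 = run_restarts(sc.graph, sc.table, prior, cfg, R=3)
    c2 = run_restarts(sc.graph, sc.table, prior, cfg, R=3)
    for a, b in zip(c1, c2):
        assert np.array_equal(a.draws, b.draws)
    with pytest.raises(ValueError, match="distinct"):
        run_restarts(sc.graph, sc.table, prior, cfg, R=2, seeds=[1, 1])


def test_single_run_single_cluster_ranking(hwe_graph):
    """R=1, k=1: the degenerate single-mode analysis is allowed."""
    sc = make_scenario("hwe_biallelic",
                       {"alleles": ("H131", "R131"), "p": 0.4}, N=60, seed=7)
    prior = PriorSpec.uniform(sc.graph)
    cfg = SamplerConfig(cycles=120, pool_size=100, seed=8)
    chains = run_restarts(sc.graph, sc.table, prior, cfg, R=1)
    res = cluster_modes(chains, k=1, seed=9)
    report = rank_modes(sc.graph, sc.table, chains, res, prior,
                        likelihood_method="exact")
    assert len(report.clusters) == 1
    top = report.clusters[0]
    assert top.member_runs == [0]
    assert top.gene_order in (("H131",), ("R131",))
    assert np.isfinite(top.log_ml_mean)
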