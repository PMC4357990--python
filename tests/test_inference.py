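"""The Metropolis-within-Gibbs sampler and its building blocks."""

import numpy as np
import pytest
from scipy import stats

from cnavhmm.fixtures import make_scenario, scenario_matrix
from cnavhmm.graph_model import TransitionMatrix, build_canonical
from cnavhmm.inference import (
    InsufficientSamplesError,
    LatentSpace,
    ModelIncompatibilityError,
    PosteriorSamples,
    PriorSpec,
    SamplerConfig,
    _squirrel_core,
    diagnostics,
    initialize_latent,
    interior_project,
    pool_path_update,
    posterior_summary,
    run_sampler,
    sample_transition_matrix,
    squirrel_update,
)
from conftest import hwe_matrix


# ---------------------------------------------------------------------------
# Conjugate matrix draws
# ---------------------------------------------------------------------------

def test_single_edge_rows_are_exactly_one(hwe_graph):
    prior = PriorSpec.uniform(hwe_graph)
    rng = np.random.default_rng(0)
    A = sample_transition_matrix(prior, np.zeros(5), rng)
    A.validate()
    assert A[("start", "choose")] == 1.0
    assert A[("H131", "end")] == 1.0


def test_dirichlet_posterior_moments(hwe_graph):
    """Row draws follow Dirichlet(prior + counts): Beta(999, 1) mean check."""
    prior = PriorSpec.uniform(hwe_graph)
    counts = {("choose", "H131"): 998, ("choose", "R131"): 0}
    rng = np.random.default_rng(1)
    draws = np.array([
        sample_transition_matrix(prior, counts, rng)[("choose", "H131")]
        for _ in range(4000)
    ])
    mean, var = 999 / 1000, 999 * 1 / (1000 ** 2 * 1001)
    assert abs(draws.mean() - mean) < 3 * np.sqrt(var / 4000)


def test_prior_predictive_row_is_uniform_in_expectation(hwe_graph):
    prior = PriorSpec.uniform(hwe_graph)
    rng = np.random.default_rng(2)
    draws = np.array([
        sample_transition_matrix(prior, np.zeros(5), rng)[("choose", "H131")]
        for _ in range(4000)
    ])
    se = np.sqrt(1 / 12 / 4000)  # Beta(1,1) variance
    assert abs(draws.mean() - 0.5) < 3 * se


def test_count_on_non_edge_is_an_error(hwe_graph):
    prior = PriorSpec.uniform(hwe_graph)
    with pytest.raises(ValueError, match="non-edge"):
        sample_transition_matrix(prior, {("end", "start"): 1},
                                 np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Latent initialization
# ---------------------------------------------------------------------------

def test_heterozygote_has_unique_decomposition(hwe_graph):
    from cnavhmm.genotype_io import GenotypeTable

    t = GenotypeTable(["i1"], np.array([[1, 1]]), hwe_graph.alphabet)
    pairs = initialize_latent(hwe_graph, t, copy_cap=5)
    (pair,) = pairs
    assert sorted([tuple(pair.first.emissions), tuple(pair.second.emissions)]) \
        == [(0, 1), (1, 0)]


def test_incompatible_genotype_names_individual(hwe_graph):
    from cnavhmm.genotype_io import GenotypeTable

    t = GenotypeTable(["odd_one"], np.array([[3, 0]]), hwe_graph.alphabet)
    with pytest.raises(ModelIncompatibilityError, match="odd_one"):
        initialize_latent(hwe_graph, t, copy_cap=5)


def test_cnav_double_copy_decompositions(cnav_graph):
    """Genotype {A:2} splits as (2,0), (1,1) or (0,2) copies per haplotype."""
    space = LatentSpace(cnav_graph, copy_cap=5, budget=10_000)
    ds = space.decompositions((2, 0))
    assert len(ds.pairs) == 3
    first_counts = sorted(int(e.sum()) for e in ds.pair_first_emissions)
    assert first_counts == [0, 1, 2]
    from cnavhmm.genotype_io import GenotypeTable

    t = GenotypeTable(["i"], np.array([[2, 0]]), cnav_graph.alphabet)
    pair = initialize_latent(cnav_graph, t, copy_cap=5,
                             rng=np.random.default_rng(3))[0]
    assert np.array_equal(pair.genotype, [2, 0])


# ---------------------------------------------------------------------------
# Pool update
# ---------------------------------------------------------------------------

def test_pool_matches_everything_under_concentrated_matrix(hwe_graph):
    from cnavhmm.genotype_io import GenotypeTable

    A = hwe_matrix(hwe_graph, 1.0)
    t = GenotypeTable(["a", "b"], np.array([[2, 0], [2, 0]]),
                      hwe_graph.alphabet)
    latent = initialize_latent(hwe_graph, t)
    updated, flags = pool_path_update(hwe_graph, A, t, latent, pool_size=10,
                                      rng=np.random.default_rng(4))
    assert flags.all()
    for pair, row in zip(updated, t.counts):
        assert np.array_equal(pair.genotype, row)


def test_pool_match_rate_follows_rejection_law(hwe_graph):
    """P(match) = 1 - (1-q)^n with q the genotype probability under A."""
    from cnavhmm.genotype_io import GenotypeTable

    A = hwe_matrix(hwe_graph, 0.5)
    n, reps = 2, 400
    t = GenotypeTable([f"i{k}" for k in range(reps)],
                      np.tile([2, 0], (reps, 1)), hwe_graph.alphabet)
    latent = initialize_latent(hwe_graph, t)
    _, flags = pool_path_update(hwe_graph, A, t, latent, pool_size=n,
                                rng=np.random.default_rng(5))
    expect = 1 - (1 - 0.25) ** n
    se = np.sqrt(expect * (1 - expect) / reps)
    assert abs(flags.mean() - expect) < 3.5 * se


def test_pool_size_must_be_positive():
    with pytest.raises(ValueError):
        SamplerConfig(pool_size=0)


# ---------------------------------------------------------------------------
# Squirrel kernel
# ---------------------------------------------------------------------------

def test_squirrel_proposal_set_depends_only_on_genotype(cnav_graph):
    """Symmetry certificate: the search never sees the current pair."""
    s1 = LatentSpace(cnav_graph, copy_cap=5, budget=10_000)
    s2 = LatentSpace(cnav_graph, copy_cap=5, budget=10_000)
    # warm the second space differently before querying the same genotype
    s2.decompositions((1, 1))
    d1 = s1.decompositions((2, 2))
    d2 = s2.decompositions((2, 2))
    k1 = [(d1.path_states(i), d1.path_states(j)) for i, j in d1.pairs]
    k2 = [(d2.path_states(i), d2.path_states(j)) for i, j in d2.pairs]
    assert k1 == k2


def test_squirrel_identity_cases(hwe_graph, cnav_graph):
    from cnavhmm.genotype_io import GenotypeTable

    A = hwe_matrix(hwe_graph, 0.5)
    t = GenotypeTable(["i"], np.array([[1, 1]]), hwe_graph.alphabet)
    cur = initialize_latent(hwe_graph, t)[0]
    # unique compatible pair -> the chain cannot move
    out = squirrel_update(hwe_graph, A, (1, 1), cur, budget=1000,
                          rng=np.random.default_rng(6))
    assert {tuple(out.first.emissions), tuple(out.second.emissions)} \
        == {(1, 0), (0, 1)}
    # zero budget -> identity fallback
    A2 = scenario_matrix("cnav_multiallele", cnav_graph,
                         {"alleles": ("A", "B")})
    t2 = GenotypeTable(["i"], np.array([[2, 0]]), cnav_graph.alphabet)
    cur2 = initialize_latent(cnav_graph, t2)[0]
    out2 = squirrel_update(cnav_graph, A2, (2, 0), cur2, budget=0,
                           rng=np.random.default_rng(7))
    assert out2 is cur2


def test_squirrel_occupancy_matches_exact_conditional(cnav_graph):
    """Detailed balance: long-run occupancy equals P(pair | A, genotype)."""
    A = scenario_matrix(
        "cnav_multiallele", cnav_graph,
        {"alleles": ("A", "B"), "loss": 0.2, "gain": 0.3,
         "allele_probs": [0.7, 0.3]},
    )
    space = LatentSpace(cnav_graph, copy_cap=5, budget=10_000)
    ds = space.decompositions((2, 0))
    logA = np.where(A.probs > 0, np.log(A.probs), -np.inf)
    lp = ds.pair_edge_counts @ np.where(np.isneginf(logA), 0.0, logA)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    rng = np.random.default_rng(8)
    cur, occ, thin = 0, np.zeros(len(ds.pairs)), 10
    for it in range(30_000):
        k = _squirrel_core(ds, ds.pair_edge_counts[cur], logA, rng)
        if k is not None:
            cur = k
        if it % thin == 0:
            occ[cur] += 1
    expected = w * occ.sum()
    chi2 = ((occ - expected) ** 2 / expected).sum()
    assert 1 - stats.chi2.cdf(chi2, len(ds.pairs) - 1) > 0.01


# ---------------------------------------------------------------------------
# Full sampler
# ---------------------------------------------------------------------------

def test_sampler_collapses_to_conjugate_posterior(hwe_graph):
    """Unambiguous paths: the posterior is Beta(1+n_H, 1+n_R) exactly."""
    sc = make_scenario("hwe_biallelic",
                       {"alleles": ("H131", "R131"), "p": 0.3},
                       N=120, seed=21)
    cfg = SamplerConfig(cycles=600, pool_size=300, seed=22)
    s = run_sampler(sc.graph, sc.table, PriorSpec.uniform(sc.graph), cfg)
    assert s.draws.shape == (600, len(sc.graph.edges))
    assert s.match_fraction.mean() > 0.99
    e = sc.graph.edge_index[("choose", "H131")]
    post = s.post_burn_draws()[:, e]
    a = 1 + sc.table.counts[:, 0].sum()
    b = 1 + sc.table.counts[:, 1].sum()
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    assert abs(post.mean() - mean) < 3 * np.sqrt(var / post.size)
    assert abs(post.var() - var) < 4 * var * np.sqrt(2 / post.size)


def test_sampler_bit_identical_reproducibility(cnav_scenario):
    cfg = SamplerConfig(cycles=40, pool_size=100, seed=23)
    s1 = run_sampler(cnav_scenario.graph, cnav_scenario.table, config=cfg)
    s2 = run_sampler(cnav_scenario.graph, cnav_scenario.table, config=cfg)
    assert np.array_equal(s1.draws, s2.draws)
    assert np.array_equal(s1.transition_counts, s2.transition_counts)


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def _fake_samples(hwe_graph, draws, burn=0.0):
    cfg = SamplerConfig(cycles=draws.shape[0], burn_in_fraction=burn, seed=0)
    return PosteriorSamples(
        graph=hwe_graph, draws=draws,
        match_fraction=np.ones(draws.shape[0]), config=cfg,
        prior=PriorSpec.uniform(hwe_graph),
    )


def _iid_draws(hwe_graph, n, seed):
    rng = np.random.default_rng(seed)
    draws = np.ones((n, len(hwe_graph.edges)))
    e = hwe_graph.edge_index[("choose", "H131")]
    p = rng.beta(30, 70, size=n)
    draws[:, e] = p
    draws[:, hwe_graph.edge_index[("choose", "R131")]] = 1 - p
    return draws


def test_iid_draws_have_unit_autocorrelation_time(hwe_graph):
    s = _fake_samples(hwe_graph, _iid_draws(hwe_graph, 2000, 31))
    rep = diagnostics(s)
    e = ("choose", "H131")
    assert rep.autocorrelation_time[e] == pytest.approx(1.0, abs=0.25)
    assert rep.ess[("start", "choose")] is None  # constant coordinate


def test_psrf_of_identical_chains_is_one(hwe_graph):
    d = _iid_draws(hwe_graph, 500, 32)
    s1 = _fake_samples(hwe_graph, d)
    s2 = _fake_samples(hwe_graph, d.copy())
    rep = diagnostics(s1, [s2])
    assert rep.psrf[("choose", "H131")] == pytest.approx(1.0, abs=0.05)


def test_psrf_converged_independent_chains(hwe_graph):
    """Chains started apart but sampling one Beta target: PSRF < 1.1."""
    chains = [_fake_samples(hwe_graph, _iid_draws(hwe_graph, 800, 33 + k))
              for k in range(3)]
    rep = diagnostics(chains[0], chains[1:])
    assert rep.psrf[("choose", "H131")] < 1.1


def test_diagnostics_requires_enough_draws(hwe_graph):
    s = _fake_samples(hwe_graph, _iid_draws(hwe_graph, 8, 34))
    with pytest.raises(InsufficientSamplesError):
        diagnostics(s)


def test_posterior_summary_properties(hwe_graph):
    d = _iid_draws(hwe_graph, 1500, 35)
    s = _fake_samples(hwe_graph, d)
    summ = posterior_summary(s, level=0.95)
    e = hwe_graph.edge_index[("choose", "H131")]
    lo, hi = stats.beta.ppf([0.025, 0.975], 30, 70)
    assert summ.lower[e] == pytest.approx(lo, abs=0.03)
    assert summ.upper[e] == pytest.approx(hi, abs=0.03)
    summ.mean_matrix.validate(tol=1e-9)
    # degenerate draws -> zero-width intervals
    s0 = _fake_samples(hwe_graph, np.tile(d[0], (20, 1)))
    z = posterior_summary(s0)
    assert np.allclose(z.lower, z.upper)


def test_interior_projection(hwe_graph):
    A = hwe_matrix(hwe_graph, 1.0)
    proj = interior_project(A, tol=1e-6)
    e = hwe_graph.edge_index[("choose", "R131")]
    assert proj.probs[e] > 0
    proj.validate(tol=1e-9)
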