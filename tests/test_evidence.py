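"""Marginal likelihoods: HMM likelihood, Chib-Jeliazkov, NEM, Bayes factors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from cnavhmm.evidence import (
    EvidenceResult,
    bayes_factor,
    chib_log_marginal,
    log_likelihood,
    nem_log_marginal,
)
from cnavhmm.fixtures import make_scenario
from cnavhmm.genotype_io import GenotypeMultiset, GenotypeTable, aggregate
from cnavhmm.inference import (
    PriorSpec,
    SamplerConfig,
    interior_project,
    posterior_summary,
    run_sampler,
)
from conftest import hwe_matrix


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def test_deterministic_matrix_gives_zero_loglik(hwe_graph):
    A = hwe_matrix(hwe_graph, 1.0)
    t = GenotypeTable([f"i{k}" for k in range(10)],
                      np.tile([2, 0], (10, 1)), hwe_graph.alphabet)
    value, se = log_likelihood(hwe_graph, A, t, method="exact")
    assert value == pytest.approx(0.0, abs=1e-12)
    assert se == 0.0


def test_heterozygote_loglik_is_log_2pq(hwe_graph):
    A = hwe_matrix(hwe_graph, 0.5)
    t = GenotypeTable(["i"], np.array([[1, 1]]), hwe_graph.alphabet)
    value, _ = log_likelihood(hwe_graph, A, t, method="exact")
    assert value == pytest.approx(math.log(0.5), abs=1e-12)


def test_simulated_likelihood_agrees_with_exact(cnav_scenario):
    g, A = cnav_scenario.graph, cnav_scenario.truth
    sub = GenotypeTable(
        cnav_scenario.table.individuals[:100],
        cnav_scenario.table.counts[:100],
        g.alphabet,
    )
    exact, _ = log_likelihood(g, A, sub, method="exact")
    sim, se = log_likelihood(g, A, sub, method="simulated", M=200_000, seed=1)
    assert se > 0
    assert abs(sim - exact) < 3.5 * se


def test_unsmoothed_zero_frequency_is_minus_infinity(hwe_graph):
    A = hwe_matrix(hwe_graph, 1.0)  # (0,2) is unreachable
    t = GenotypeTable(["i"], np.array([[0, 2]]), hwe_graph.alphabet)
    sim, _ = log_likelihood(hwe_graph, A, t, method="simulated", M=100,
                            seed=2, smoothing=False)
    assert sim == -np.inf


# ---------------------------------------------------------------------------
# NEM closed form
# ---------------------------------------------------------------------------

def test_single_observation_has_predictive_half():
    ms = GenotypeMultiset(("x",), {(1,): 1}, 1)
    r = nem_log_marginal(ms)
    assert math.exp(r.log_marginal_likelihood) == pytest.approx(0.5, abs=1e-12)
    assert r.se == 0.0 and r.method == "nem_closed_form"


def _nem_sequential_oracle(counts: dict, total: int) -> float:
    """Chain rule of Dirichlet-multinomial predictives, one draw at a time."""
    cats = list(counts) + ["pool"]
    alpha = 0.5
    seen = {c: 0 for c in cats}
    log_m, n_before = 0.0, 0
    for c in counts:
        for _ in range(counts[c]):
            log_m += math.log(
                (alpha + seen[c]) / (alpha * len(cats) + n_before)
            )
            seen[c] += 1
            n_before += 1
    return log_m


def test_nem_matches_hand_computed_two_singletons():
    """Two singleton genotypes: 3 Jeffreys categories, m = (1/3)(1/5) = 1/15."""
    ms = GenotypeMultiset(("x",), {(1,): 1, (2,): 1}, 2)
    r = nem_log_marginal(ms)
    assert math.exp(r.log_marginal_likelihood) == pytest.approx(1 / 15,
                                                                abs=1e-12)
    assert r.log_marginal_likelihood == pytest.approx(
        _nem_sequential_oracle(ms.counts, 2), abs=1e-10)


@settings(derandomize=True, max_examples=40)
@given(st.dictionaries(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                       st.integers(1, 6), min_size=1, max_size=6))
def test_nem_equals_sequential_predictive_oracle(counts):
    total = sum(counts.values())
    ms = GenotypeMultiset(("x", "y"), dict(counts), total)
    r = nem_log_marginal(ms)
    assert r.log_marginal_likelihood == pytest.approx(
        _nem_sequential_oracle(counts, total), abs=1e-10)


def test_nem_is_order_invariant(hwe_graph):
    t1 = GenotypeTable(["a", "b", "c"], np.array([[2, 0], [1, 1], [2, 0]]),
                       hwe_graph.alphabet)
    t2 = GenotypeTable(["c", "a", "b"], np.array([[1, 1], [2, 0], [2, 0]]),
                       hwe_graph.alphabet)
    r1 = nem_log_marginal(aggregate(t1))
    r2 = nem_log_marginal(aggregate(t2))
    assert r1.log_marginal_likelihood == r2.log_marginal_likelihood
    assert r1.data_fingerprint == r2.data_fingerprint


# ---------------------------------------------------------------------------
# Chib-Jeliazkov
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def hwe_fit():
    sc = make_scenario("hwe_biallelic",
                       {"alleles": ("H131", "R131"), "p": 0.3}, N=120, seed=41)
    prior = PriorSpec.uniform(sc.graph)
    cfg = SamplerConfig(cycles=600, pool_size=300, seed=42)
    samples = run_sampler(sc.graph, sc.table, prior, cfg)
    return sc, prior, samples


def _conjugate_log_marginal(table):
    """Closed-form evidence of the unambiguous biallelic model.

    The ordered-pair likelihood is 2^het * p^nH * (1-p)^nR; under a uniform
    prior on p the marginal is 2^het * B(1+nH, 1+nR)."""
    nH = int(table.counts[:, 0].sum())
    nR = int(table.counts[:, 1].sum())
    het = int(((table.counts[:, 0] == 1) & (table.counts[:, 1] == 1)).sum())
    return (het * math.log(2)
            + gammaln(1 + nH) + gammaln(1 + nR) - gammaln(2 + nH + nR)
            - (gammaln(1) + gammaln(1) - gammaln(2)))


def test_cj_identity_holds_exactly(hwe_fit):
    sc, prior, samples = hwe_fit
    r = chib_log_marginal(sc.graph, sc.table, prior, samples)
    c = r.components
    assert r.log_marginal_likelihood == pytest.approx(
        c["log_likelihood_ordinate"] + c["log_prior_ordinate"]
        - c["log_posterior_ordinate"], abs=1e-12)


def test_cj_matches_conjugate_closed_form(hwe_fit):
    sc, prior, samples = hwe_fit
    r = chib_log_marginal(sc.graph, sc.table, prior, samples)
    closed = _conjugate_log_marginal(sc.table)
    assert abs(r.log_marginal_likelihood - closed) < max(3 * r.se, 0.01)


def test_cj_invariant_to_interior_evaluation_point(hwe_fit):
    sc, prior, samples = hwe_fit
    g = sc.graph
    mean = interior_project(posterior_summary(samples).mean_matrix)
    shifted = mean.probs.copy()
    for ids in ([1, 2],):  # nudge the bifurcation row
        shifted[ids] = np.array([0.45, 0.55])
    other = interior_project(
        type(mean)(g, shifted), tol=1e-6)
    r1 = chib_log_marginal(g, sc.table, prior, samples, a_star=mean)
    r2 = chib_log_marginal(g, sc.table, prior, samples, a_star=other)
    tol = max(3 * math.sqrt(r1.se ** 2 + r2.se ** 2), 0.02)
    assert abs(r1.log_marginal_likelihood - r2.log_marginal_likelihood) < tol


def test_cj_rejects_boundary_evaluation_point(hwe_fit):
    sc, prior, samples = hwe_fit
    A = hwe_matrix(sc.graph, 1.0)
    with pytest.raises(ValueError, match="interior"):
        chib_log_marginal(sc.graph, sc.table, prior, samples, a_star=A)


def test_cj_empty_data_gives_zero_log_marginal(hwe_graph):
    empty = GenotypeTable([], np.zeros((0, 2), dtype=int), hwe_graph.alphabet)
    prior = PriorSpec.uniform(hwe_graph)
    cfg = SamplerConfig(cycles=60, pool_size=10, seed=5)
    samples = run_sampler(hwe_graph, empty, prior, cfg)
    r = chib_log_marginal(
        hwe_graph, empty, prior, samples,
        a_star=interior_project(hwe_matrix(hwe_graph, 0.5)),
    )
    assert r.log_marginal_likelihood == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def test_bayes_factor_arithmetic_and_antisymmetry():
    a = EvidenceResult(-100.0, "chib_jeliazkov", se=0.1, data_fingerprint="f")
    b = EvidenceResult(-104.2, "nem_closed_form", se=0.0, data_fingerprint="f")
    bf = bayes_factor(a, b)
    assert bf.bf == pytest.approx(66.7, abs=0.05)  # e^4.2
    assert bf.log10_bf == pytest.approx(4.2 / math.log(10))
    back = bayes_factor(b, a)
    assert bf.bf * back.bf == pytest.approx(1.0, rel=1e-12)
    same = bayes_factor(a, a)
    assert same.bf == 1.0


def test_bayes_factor_requires_matching_data():
    a = EvidenceResult(-1.0, "chib_jeliazkov", data_fingerprint="f1")
    b = EvidenceResult(-2.0, "nem_closed_form", data_fingerprint="f2")
    with pytest.raises(ValueError, match="different data"):
        bayes_factor(a, b)
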