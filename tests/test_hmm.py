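"""Forward-backward, likelihoods and Baum-Welch against independent oracles."""

import numpy as np
import pytest

from missense_states import (
    HmmModel,
    ObservationSequence,
    TrainingConfig,
    baum_welch,
    emission_likelihood,
    forward_backward,
    sequence_loglik,
)
from missense_states.io import read_model, write_model

from conftest import brute_force_posteriors, random_model


@pytest.mark.parametrize(
    "emission, codes, expected",
    [
        ([[0.3]], [1], [0.3]),
        ([[0.4, 0.7], [0.1, 0.2]], [2, 2], [1.0, 1.0]),
        # hand product: state 1: 0.9*0.9*1, state 2: 0.2*0.2*1
        ([[0.9, 0.1, 0.5], [0.2, 0.8, 0.5]], [1, 0, 2], [0.81, 0.04]),
    ],
)
def test_emission_likelihood_examples(emission, codes, expected):
    emission = np.asarray(emission, dtype=float)
    K = emission.shape[0]
    model = HmmModel(np.full(K, 1.0 / K), np.full((K, K), 1.0 / K), emission)
    np.testing.assert_allclose(
        emission_likelihood(model, np.array(codes)), expected, atol=1e-12
    )


def test_emission_likelihood_rejects_bad_code():
    model = HmmModel([1.0], [[1.0]], [[0.5]])
    with pytest.raises(ValueError):
        emission_likelihood(model, np.array([3]))


def test_forward_backward_matches_enumeration():
    """Posteriors and log-likelihood agree with exhaustive path summation."""
    rng = np.random.default_rng(7)
    for _ in range(15):
        K = int(rng.integers(1, 4))
        M = int(rng.integers(1, 4))
        T = int(rng.integers(1, 7))
        model = random_model(rng, K, M)
        codes = rng.integers(0, 3, size=(T, M))
        expected_gamma, expected_ll = brute_force_posteriors(model, codes)
        result = forward_backward(model, ObservationSequence(codes))
        np.testing.assert_allclose(result.gamma, expected_gamma, atol=1e-9)
        assert abs(result.loglik - expected_ll) < 1e-9
        np.testing.assert_allclose(result.gamma.sum(axis=1), 1.0, atol=1e-9)


def test_forward_backward_single_state_and_single_position():
    rng = np.random.default_rng(3)
    # K=1: gamma identically one, loglik = sum of log emissions
    model = HmmModel([1.0], [[1.0]], [[0.7, 0.3]])
    codes = rng.integers(0, 3, size=(5, 2))
    res = forward_backward(model, codes)
    np.testing.assert_allclose(res.gamma, 1.0)
    expected = sum(np.log(emission_likelihood(model, c)[0]) for c in codes)
    assert abs(res.loglik - expected) < 1e-12

    # T=1, uniform initial, emission likelihoods 0.3 and 0.1 -> [0.75, 0.25]
    model2 = HmmModel(
        [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [[0.3], [0.1]]
    )
    res2 = forward_backward(model2, np.array([[1]]))
    np.testing.assert_allclose(res2.gamma[0], [0.75, 0.25], atol=1e-12)


def test_loglik_is_nonpositive_for_probability_observations():
    rng = np.random.default_rng(11)
    model = random_model(rng, 3, 2)
    codes = rng.integers(0, 3, size=(20, 2))
    assert forward_backward(model, codes).loglik <= 0.0


def test_no_underflow_on_long_extreme_sequence():
    """10^5 positions with near-deterministic emissions must not return NaN."""
    model = HmmModel(
        [0.5, 0.5],
        [[0.99, 0.01], [0.01, 0.99]],
        [[0.999, 0.001], [0.001, 0.999]],
    )
    rng = np.random.default_rng(0)
    codes = rng.integers(0, 2, size=(100_000, 2))
    res = forward_backward(model, codes)
    assert np.isfinite(res.loglik)
    assert np.isfinite(res.gamma).all()


def test_sequence_loglik_additivity_and_enumeration(oracle):
    rng = np.random.default_rng(5)
    model = random_model(rng, 3, 2)
    codes = rng.integers(0, 3, size=(5, 2))
    single = forward_backward(model, codes).loglik
    assert abs(sequence_loglik(model, [codes]) - single) < 1e-12
    assert abs(sequence_loglik(model, [codes, codes]) - 2 * single) < 1e-12
    _, expected = oracle(model, codes)
    assert abs(single - expected) < 1e-9
    with pytest.raises(ValueError):
        sequence_loglik(model, [])


def test_missing_row_neutrality_under_uniform_transitions():
    """An all-missing row carries no emission evidence: with uniform
    transitions the posteriors at every other position are unchanged."""
    rng = np.random.default_rng(13)
    K, M = 3, 4
    model = HmmModel(
        rng.dirichlet(np.ones(K)),
        np.full((K, K), 1.0 / K),
        rng.uniform(0.1, 0.9, (K, M)),
    )
    codes = rng.integers(0, 3, size=(6, M))
    augmented = np.insert(codes, 3, np.full(M, 2), axis=0)
    base = forward_backward(model, codes).gamma
    aug = forward_backward(model, augmented).gamma
    np.testing.assert_allclose(aug[:3], base[:3], atol=1e-10)
    np.testing.assert_allclose(aug[4:], base[3:], atol=1e-10)


def test_uniform_transition_posterior_factorizes():
    """With 1/K transition rows, the posterior at t >= 2 is proportional to
    that position's emission likelihood alone."""
    rng = np.random.default_rng(17)
    K, M = 4, 3
    model = HmmModel(
        rng.dirichlet(np.ones(K)),
        np.full((K, K), 1.0 / K),
        rng.uniform(0.1, 0.9, (K, M)),
    )
    codes = rng.integers(0, 3, size=(8, M))
    gamma = forward_backward(model, codes).gamma
    for t in range(1, 8):
        lik = emission_likelihood(model, codes[t])
        np.testing.assert_allclose(gamma[t], lik / lik.sum(), atol=1e-10)


def test_baum_welch_single_state_closed_form():
    """K=1: the emission MLE is the empirical present frequency per feature
    (among non-missing cells)."""
    rng = np.random.default_rng(23)
    p_true = np.array([0.3, 0.7, 0.1])
    codes = (rng.random((10_000, 3)) < p_true).astype(np.int8)
    codes[rng.random((10_000, 3)) < 0.1] = 2
    seqs = [codes[i * 100 : (i + 1) * 100] for i in range(100)]
    res = baum_welch(
        seqs, K=1, config=TrainingConfig(seed=0, pseudocount=0.0, n_restarts=1)
    )
    observed = codes != 2
    empirical = (codes == 1).sum(axis=0) / observed.sum(axis=0)
    np.testing.assert_allclose(res.model.emission[0], empirical, atol=0.01)


def test_baum_welch_monotone_loglik_full_batch():
    """Exact EM (no subsampling, pseudocount 0) never decreases the likelihood."""
    rng = np.random.default_rng(29)
    seqs = [rng.integers(0, 3, size=(30, 3)) for _ in range(8)]
    res = baum_welch(
        seqs,
        K=2,
        config=TrainingConfig(
            seed=1,
            pseudocount=0.0,
            n_restarts=1,
            max_iterations=50,
            convergence_delta=-1.0,  # never triggers: run all iterations
        ),
    )
    trace = np.array(res.loglik_trace)
    assert len(trace) == 50
    assert (np.diff(trace) >= -1e-8).all()


def test_baum_welch_subsampling_runs_fixed_iterations():
    rng = np.random.default_rng(31)
    seqs = [rng.integers(0, 3, size=(10, 2)) for _ in range(20)]
    res = baum_welch(
        seqs,
        K=2,
        config=TrainingConfig(
            seed=2, n_subsample=5, max_iterations=12, n_restarts=1
        ),
    )
    assert res.n_iterations == 12
    assert len(res.loglik_trace) == 12


def test_baum_welch_preserves_stochasticity_and_is_deterministic():
    rng = np.random.default_rng(37)
    seqs = [rng.integers(0, 3, size=(15, 3)) for _ in range(10)]
    config = TrainingConfig(seed=9, n_subsample=4, max_iterations=8, n_restarts=2)
    res1 = baum_welch(seqs, K=3, config=config)
    res2 = baum_welch(seqs, K=3, config=config)
    m = res1.model
    np.testing.assert_allclose(m.initial.sum(), 1.0, atol=1e-12)
    np.testing.assert_allclose(m.transition.sum(axis=1), 1.0, atol=1e-12)
    assert ((m.emission >= 0) & (m.emission <= 1)).all()
    np.testing.assert_array_equal(res1.model.emission, res2.model.emission)
    np.testing.assert_array_equal(res1.model.transition, res2.model.transition)


def test_baum_welch_errors_and_warnings():
    rng = np.random.default_rng(41)
    with pytest.raises(ValueError):
        baum_welch(
            [rng.integers(0, 3, (5, 2)), rng.integers(0, 3, (5, 3))],
            K=2,
            config=TrainingConfig(seed=0),
        )
    with pytest.warns(UserWarning):
        baum_welch(
            [rng.integers(0, 3, (2, 2))],
            K=5,
            config=TrainingConfig(seed=0, max_iterations=2, n_restarts=1),
        )


def test_model_file_round_trip(tmp_path):
    rng = np.random.default_rng(43)
    model = random_model(rng, 3, 4)
    path = tmp_path / "model.txt"
    write_model(model, path)
    back = read_model(path)
    # 6 significant digits in the file
    np.testing.assert_allclose(back.emission, model.emission, rtol=1e-5, atol=1e-6)
    np.testing.assert_allclose(back.transition, model.transition, rtol=1e-4, atol=1e-6)
    np.testing.assert_allclose(back.initial, model.initial, rtol=1e-4, atol=1e-6)
    # and a second write is byte-identical (stable serialization)
    path2 = tmp_path / "model2.txt"
    write_model(back, path2)
    write_model(read_model(path2), tmp_path / "model3.txt")
    assert (tmp_path / "model2.txt").read_text() == (tmp_path / "model3.txt").read_text()


def test_invalid_model_rejected():
    with pytest.raises(ValueError):
        HmmModel([0.5, 0.6], [[0.5, 0.5], [0.5, 0.5]], [[0.5], [0.5]])
    with pytest.raises(ValueError):
        HmmModel([0.5, 0.5], [[0.9, 0.2], [0.5, 0.5]], [[0.5], [0.5]])
    with pytest.raises(ValueError):
        HmmModel([1.0], [[1.0]], [[1.5]])
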