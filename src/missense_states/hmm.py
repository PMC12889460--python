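"""Multivariate Bernoulli-emission hidden Markov model over ternary observations.

Observations are vectors of M codes in {0, 1, 2}: 1 = the score prioritizes
the variant ("present"), 0 = scored but not prioritized ("absent"),
2 = score missing.  Emissions are independent Bernoulli per feature; a
missing feature contributes a factor of 1 to the likelihood (no evidence).

The implementation uses the scaled forward-backward recursions (per-position
normalizers), with an additional per-position rescaling of the emission
likelihood so that long sequences with many extreme emission parameters never
underflow.  Baum-Welch supports gene subsampling per iteration, pseudo-counts
added to every expected count, random restarts and a fixed-iteration schedule
when the likelihood estimate is noisy because of subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence as SequenceType

import numpy as np

__all__ = [
    "HmmModel",
    "ObservationSequence",
    "TrainingConfig",
    "PosteriorResult",
    "TrainingResult",
    "emission_likelihood",
    "forward_backward",
    "sequence_loglik",
    "baum_welch",
]

# Smallest emission probability used inside logs; represents "effectively zero"
# while keeping 0 * log(p) products finite in matrix form.
_LOG_FLOOR = 1e-300


@dataclass
class HmmModel:
    """HMM parameters: K states over M ternary score features.

    Attributes
    ----------
    initial : (K,) initial state distribution.
    transition : (K, K) row-stochastic transition matrix.
    emission : (K, M) Bernoulli "present" probabilities.
    """

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.emission.shape[0]

    @property
    def n_features(self) -> int:
        return self.emission.shape[1]

    # K and M as short aliases, matching the field's usual notation
    K = n_states
    M = n_features

    def validate(self, atol: float = 1e-12) -> None:
        K, M = self.emission.shape
        if K < 1 or M < 1:
            raise ValueError("model needs K >= 1 states and M >= 1 features")
        if self.initial.shape != (K,):
            raise ValueError(f"initial must have shape ({K},)")
        if self.transition.shape != (K, K):
            raise ValueError(f"transition must have shape ({K}, {K})")
        if not np.isclose(self.initial.sum(), 1.0, atol=atol):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=atol):
            raise ValueError("every transition row must sum to 1")
        if (self.emission < 0).any() or (self.emission > 1).any():
            raise ValueError("emission probabilities must lie in [0, 1]")
        if (self.initial < 0).any() or (self.transition < 0).any():
            raise ValueError("probabilities must be nonnegative")

    def copy(self) -> "HmmModel":
        return HmmModel(
            self.initial.copy(), self.transition.copy(), self.emission.copy()
        )


@dataclass
class ObservationSequence:
    """A T x M matrix of ternary codes for one gene's variant positions."""

    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D (T, M) array")
        if codes.shape[0] < 1:
            raise ValueError("sequence must contain at least one position")
        if not np.isin(codes, (0, 1, 2)).all():
            raise ValueError("observation codes must be in {0, 1, 2}")
        self.codes = codes.astype(np.int8)

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def n_features(self) -> int:
        return self.codes.shape[1]


@dataclass
class TrainingConfig:
    """Baum-Welch settings.

    ``n_subsample`` is the number of gene sequences drawn (uniformly, without
    replacement) per EM iteration, or ``"all"`` for full-batch EM.  With
    subsampling the per-iteration likelihood estimate is noisy, so training
    runs for exactly ``max_iterations`` and decreases are tolerated; in
    full-batch mode EM stops once the improvement falls below
    ``convergence_delta``.  ``pseudocount`` is added to every expected
    initial/transition/emission count (both Bernoulli outcomes) before
    normalization in the M-step.
    """

    n_subsample: int | str = "all"
    pseudocount: float = 1.0
    max_iterations: int = 200
    convergence_delta: float = 1e-3
    allow_likelihood_decrease: bool = True
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.n_subsample != "all" and int(self.n_subsample) < 1:
            raise ValueError('n_subsample must be a positive integer or "all"')


@dataclass
class PosteriorResult:
    """Forward-backward output: per-position state posteriors and log-likelihood."""

    gamma: np.ndarray
    loglik: float


@dataclass
class TrainingResult:
    model: HmmModel
    loglik_trace: list[float] = field(default_factory=list)
    full_data_loglik: float = float("nan")
    n_iterations: int = 0


def _as_codes(obs) -> np.ndarray:
    codes = obs.codes if isinstance(obs, ObservationSequence) else np.asarray(obs)
    if not np.isin(codes, (0, 1, 2)).all():
        raise ValueError("observation codes must be in {0, 1, 2}")
    return codes


def _log_emission_matrix(model: HmmModel, codes: np.ndarray) -> np.ndarray:
    """Log emission likelihood for stacked codes.

    codes: (..., M) ternary.  Returns (..., K) log-likelihoods: per state the
    sum over features of log p (code 1), log(1-p) (code 0) and 0 (code 2).
    """
    p = np.clip(model.emission, _LOG_FLOOR, 1.0)
    q = np.clip(1.0 - model.emission, _LOG_FLOOR, 1.0)
    present = (codes == 1).astype(float)
    absent = (codes == 0).astype(float)
    return present @ np.log(p).T + absent @ np.log(q).T


def emission_likelihood(model: HmmModel, obs_row) -> np.ndarray:
    """Per-state likelihood of a single ternary observation vector.

    Component s is the product over features n of ``p[s, n]`` if the code is
    1, ``1 - p[s, n]`` if 0, and 1 if 2 (missing).
    """
    codes = np.asarray(_as_codes(obs_row)).reshape(-1)
    if codes.shape[0] != model.n_features:
        raise ValueError("observation length does not match model features")
    # exact product for a single row; no underflow concern at this scale
    p = model.emission
    factors = np.where(codes == 1, p, np.where(codes == 0, 1.0 - p, 1.0))
    return factors.prod(axis=1)


def _forward_backward_batch(
    model: HmmModel, codes: np.ndarray, want_xi: bool = False
):
    """Scaled forward-backward on a (B, T, M) batch of equal-length sequences.

    Returns ``(gamma, loglik, xi_sum, b_scaled)`` where gamma is (B, T, K),
    loglik (B,), xi_sum (B, K, K) expected transition counts (None unless
    requested), and b_scaled the per-position emission likelihoods after
    per-position rescaling (used only internally).
    """
    B, T, _ = codes.shape
    K = model.n_states
    logb = _log_emission_matrix(model, codes)  # (B, T, K)
    shift = logb.max(axis=2, keepdims=True)  # (B, T, 1)
    # positions where every state has ~zero likelihood are impossible
    if not np.isfinite(shift).all():
        raise FloatingPointError("observation has zero likelihood in every state")
    b = np.exp(logb - shift)  # (B, T, K), max 1 per position

    A = model.transition
    alpha = np.empty((B, T, K))
    c = np.empty((B, T))
    a = model.initial[None, :] * b[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    if (c[:, 0] <= 0).any():
        raise FloatingPointError("zero-probability observation sequence")
    alpha[:, 0, :] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1, :] @ A) * b[:, t, :]
        c[:, t] = a.sum(axis=1)
        if (c[:, t] <= 0).any():
            raise FloatingPointError("zero-probability observation sequence")
        alpha[:, t, :] = a / c[:, t, None]

    beta = np.empty((B, T, K))
    beta[:, T - 1, :] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t, :] = (beta[:, t + 1, :] * b[:, t + 1, :]) @ A.T
        beta[:, t, :] /= c[:, t + 1, None]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    loglik = np.log(c).sum(axis=1) + shift[:, :, 0].sum(axis=1)

    xi_sum = None
    if want_xi:
        xi_sum = np.zeros((B, K, K))
        for t in range(T - 1):
            w = b[:, t + 1, :] * beta[:, t + 1, :] / c[:, t + 1, None]
            xi_sum += alpha[:, t, :, None] * A[None, :, :] * w[:, None, :]
    return gamma, loglik, xi_sum, b


def forward_backward(model: HmmModel, seq) -> PosteriorResult:
    """Posterior state probabilities and log-likelihood of one sequence."""
    codes = _as_codes(seq)
    if codes.ndim != 2 or codes.shape[1] != model.n_features:
        raise ValueError("sequence shape does not match model features")
    gamma, loglik, _, _ = _forward_backward_batch(model, codes[None, :, :])
    return PosteriorResult(gamma=gamma[0], loglik=float(loglik[0]))


def sequence_loglik(model: HmmModel, sequences: SequenceType) -> float:
    """Total log-likelihood over a collection of observation sequences."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("sequences must be nonempty")
    total = 0.0
    for group in _group_by_length(sequences):
        _, ll, _, _ = _forward_backward_batch(model, group)
        total += float(ll.sum())
    return total


def _group_by_length(sequences) -> list[np.ndarray]:
    """Stack equal-length sequences into (B, T, M) batches for vectorized FB."""
    by_len: dict[int, list[np.ndarray]] = {}
    for s in sequences:
        codes = _as_codes(s)
        by_len.setdefault(codes.shape[0], []).append(codes)
    return [np.stack(v) for v in by_len.values()]


def _random_model(K: int, M: int, rng: np.random.Generator) -> HmmModel:
    """Seeded random initialization: emissions ~ U(0.2, 0.8), rows Dirichlet-like."""
    emission = rng.uniform(0.2, 0.8, size=(K, M))
    transition = rng.gamma(5.0, size=(K, K))
    transition /= transition.sum(axis=1, keepdims=True)
    initial = rng.gamma(5.0, size=K)
    initial /= initial.sum()
    return HmmModel(initial, transition, emission)


def _em_step(model: HmmModel, batches: list[np.ndarray], pseudocount: float):
    """One E+M step over the given batches.

    Returns ``(new_model, loglik)`` where loglik is evaluated under the
    *incoming* parameters (the quantity that is monotone for exact EM).
    """
    K, M = model.emission.shape
    init_counts = np.zeros(K)
    trans_counts = np.zeros((K, K))
    emit_num = np.zeros((K, M))
    emit_den = np.zeros((K, M))
    total_ll = 0.0

    for codes in batches:
        want_xi = codes.shape[1] > 1
        gamma, ll, xi_sum, _ = _forward_backward_batch(model, codes, want_xi=want_xi)
        total_ll += float(ll.sum())
        init_counts += gamma[:, 0, :].sum(axis=0)
        if xi_sum is not None:
            trans_counts += xi_sum.sum(axis=0)
        present = (codes == 1).astype(float)
        observed = (codes != 2).astype(float)
        emit_num += np.einsum("btk,btm->km", gamma, present)
        emit_den += np.einsum("btk,btm->km", gamma, observed)

    pc = pseudocount
    new_initial = init_counts + pc
    new_initial /= new_initial.sum()

    trans = trans_counts + pc
    row = trans.sum(axis=1, keepdims=True)
    # a state never left (possible with pc=0): keep its old transition row
    dead = row[:, 0] <= 0
    trans = np.where(dead[:, None], model.transition, trans / np.where(row > 0, row, 1.0))

    num = emit_num + pc
    den = emit_den + 2.0 * pc
    emission = np.where(den > 0, num / np.where(den > 0, den, 1.0), model.emission)
    emission = np.clip(emission, 0.0, 1.0)

    return HmmModel(new_initial, trans, emission), total_ll


def baum_welch(
    sequences: SequenceType, K: int, config: TrainingConfig | None = None
) -> TrainingResult:
    """Fit a K-state model by expectation-maximization.

    With ``n_subsample="all"`` and ``pseudocount=0`` this is exact EM and the
    per-iteration log-likelihood trace is non-decreasing.  With subsampling,
    each iteration draws ``n_subsample`` sequences uniformly without
    replacement from the seeded RNG, the trace records the subsample
    likelihood (noisy), and training runs for exactly ``max_iterations``.
    The best of ``n_restarts`` runs by full-data log-likelihood is returned.

    Draw order per restart: initialization parameters first, then one
    subsample per iteration, all from a single RNG seeded by ``config.seed``.
    """
    if config is None:
        config = TrainingConfig()
    if K < 1:
        raise ValueError("K must be >= 1")
    codes_list = [_as_codes(s) for s in sequences]
    if not codes_list:
        raise ValueError("sequences must be nonempty")
    M = codes_list[0].shape[1]
    if any(c.shape[1] != M for c in codes_list):
        raise ValueError("all sequences must share the same number of features")
    n_obs = sum(c.shape[0] for c in codes_list)
    if K > n_obs:
        warnings.warn(
            f"K={K} exceeds the total number of observations ({n_obs}); "
            "proceeding, but the model is over-parameterized",
            stacklevel=2,
        )

    n_total = len(codes_list)
    subsampling = config.n_subsample != "all" and int(config.n_subsample) < n_total
    n_sub = n_total if not subsampling else int(config.n_subsample)

    rng = np.random.default_rng(config.seed)
    full_batches = _group_by_length(codes_list)

    best: TrainingResult | None = None
    for _ in range(config.n_restarts):
        model = _random_model(K, M, rng)
        trace: list[float] = []
        prev_ll = -np.inf
        n_iter = 0
        for _it in range(config.max_iterations):
            if subsampling:
                idx = rng.choice(n_total, size=n_sub, replace=False)
                batches = _group_by_length([codes_list[i] for i in idx])
            else:
                batches = full_batches
            model, ll = _em_step(model, batches, config.pseudocount)
            trace.append(ll)
            n_iter += 1
            if not subsampling:
                if ll < prev_ll and not config.allow_likelihood_decrease:
                    break
                if np.isfinite(prev_ll) and ll - prev_ll < config.convergence_delta:
                    break
                prev_ll = ll
        full_ll = sequence_loglik(model, codes_list)
        result = TrainingResult(
            model=model,
            loglik_trace=trace,
            full_data_loglik=full_ll,
            n_iterations=n_iter,
        )
        if best is None or full_ll > best.full_data_loglik:
            best = result
    assert best is not None
    return best
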