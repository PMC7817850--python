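"""State inference for a single observation: exact Bayes and variational bound.

The free energy of an arbitrary belief Q(s) under prior p(s) and likelihood
column A[o, :] is

    F(Q) = E_Q[ln Q(s) - ln(p(s) A[o, s])]
         = KL[Q || p(s|o)] - ln p(o),

so F upper-bounds the negative log evidence, with equality exactly when Q is
the true posterior. For a single categorical factor the minimizer is
available in closed form; a mirror-descent iteration is provided as an
alternative scheme and converges to the same fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, ImpossibleObservationError
from .model_core import (EPS, GenerativeModel, assert_categorical,
                         floor_and_normalize, safe_log)

__all__ = [
    "FreeEnergyReport",
    "marginal_likelihood",
    "exact_posterior",
    "variational_free_energy",
    "infer_states",
    "mirror_descent_inference",
]


@dataclass(frozen=True)
class FreeEnergyReport:
    """Free energy in nats with its bound decomposition.

    ``F = kl_term + neg_log_evidence`` where ``kl_term`` is
    KL[Q || exact posterior] (nonnegative) and ``neg_log_evidence`` is
    -ln p(o) under the prior.
    """

    F: float
    kl_term: float
    neg_log_evidence: float


def _check_outcome(model: GenerativeModel, o: int) -> int:
    o = int(o)
    if not 0 <= o < model.n_outcomes:
        raise IndexError(f"outcome index {o} outside [0, {model.n_outcomes})")
    return o


def marginal_likelihood(model: GenerativeModel, prior: np.ndarray, o: int) -> float:
    """P(o) = sum_s prior(s) * A[o, s]."""
    o = _check_outcome(model, o)
    prior = assert_categorical(prior, "prior")
    return float(model.A[o] @ prior)


def exact_posterior(model: GenerativeModel, prior: np.ndarray, o: int) -> np.ndarray:
    """Bayes rule: Q(s) = prior(s) A[o, s] / P(o)."""
    o = _check_outcome(model, o)
    prior = assert_categorical(prior, "prior")
    evidence = float(model.A[o] @ prior)
    if evidence <= 0:
        raise ImpossibleObservationError(
            f"outcome {o} has zero marginal likelihood under the prior")
    return prior * model.A[o] / evidence


def variational_free_energy(model: GenerativeModel, prior: np.ndarray,
                            Q: np.ndarray, o: int) -> FreeEnergyReport:
    """Evaluate F(Q) and its KL + negative-log-evidence decomposition."""
    o = _check_outcome(model, o)
    prior = assert_categorical(prior, "prior")
    Q = assert_categorical(Q, "Q")

    joint = prior * model.A[o]          # unnormalized posterior p(s, o)
    evidence = float(joint.sum())
    if evidence <= 0:
        raise ImpossibleObservationError(
            f"outcome {o} has zero marginal likelihood under the prior")
    F = float(Q @ (safe_log(Q) - safe_log(joint)))
    posterior = joint / evidence
    kl = float(Q @ (safe_log(Q) - safe_log(posterior)))
    return FreeEnergyReport(F=F, kl_term=kl, neg_log_evidence=-np.log(evidence))


def infer_states(model: GenerativeModel, prior: np.ndarray, o: int,
                 tol: float = 1e-8, max_iter: int = 500,
                 ) -> tuple[np.ndarray, FreeEnergyReport]:
    """Minimize F over beliefs; returns the minimizing Q and its report.

    Uses the closed-form fixed point (normalized exponential of
    ``ln prior + ln A[o, :]``), which for a single categorical factor is the
    global minimum and coincides with the exact posterior up to the log
    floor. ``tol`` bounds the total-variation distance accepted between the
    fixed point and the exact posterior.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    o = _check_outcome(model, o)
    prior = assert_categorical(prior, "prior")
    logits = safe_log(prior) + safe_log(model.A[o])
    Q = floor_and_normalize(np.exp(logits - logits.max()), EPS)
    exact = exact_posterior(model, prior, o)
    tv = 0.5 * float(np.abs(Q - exact).sum())
    if tv > tol:
        raise ConvergenceError(
            f"fixed point differs from the exact posterior by TV {tv:.3e} > {tol}",
            last_iterate=Q)
    return Q, variational_free_energy(model, prior, Q, o)


def mirror_descent_inference(model: GenerativeModel, prior: np.ndarray, o: int,
                             step_size: float = 0.5, tol: float = 1e-8,
                             max_iter: int = 500,
                             ) -> tuple[np.ndarray, FreeEnergyReport, np.ndarray]:
    """Exponentiated-gradient descent of F on the simplex.

    Starts from the prior and iterates
    ``Q <- normalize(Q^(1 - step_size) * (prior * A[o, :])^step_size)``.
    Returns the final belief, its free-energy report, and the per-iteration
    free-energy trace (non-increasing). Raises :class:`ConvergenceError`
    carrying the last iterate when ``max_iter`` is exhausted.
    """
    if not 0 < step_size <= 1:
        raise ValueError(f"step_size must be in (0, 1], got {step_size}")
    o = _check_outcome(model, o)
    prior = assert_categorical(prior, "prior")
    target_log = safe_log(prior) + safe_log(model.A[o])

    Q = prior.copy()
    trace = [variational_free_energy(model, prior, Q, o).F]
    for _ in range(max_iter):
        logits = (1.0 - step_size) * safe_log(Q) + step_size * target_log
        Q_next = floor_and_normalize(np.exp(logits - logits.max()), EPS)
        trace.append(variational_free_energy(model, prior, Q_next, o).F)
        delta = 0.5 * float(np.abs(Q_next - Q).sum())
        Q = Q_next
        if delta < tol:
            return Q, variational_free_energy(model, prior, Q, o), np.array(trace)
    raise ConvergenceError(
        f"mirror descent did not reach TV tolerance {tol} in {max_iter} iterations",
        last_iterate=Q, trace=np.array(trace))
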