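"""Policy evaluation: belief rollouts, expected free energy, softmax posterior.

For each policy the belief over states is rolled forward through the
action-indexed transition matrices. Per future step tau the expected free
energy is taken under the joint measure Q(s_tau | pi) * A[o, s_tau]:

    instrumental(pi, tau) = - E[ ln C_tau(o) ]
    epistemic(pi, tau)    =   E[ ln Q(s_tau | pi) - ln P(s_tau | o, pi) ]
    G(pi, tau)            = instrumental + epistemic

where P(s_tau | o, pi) is the Bayes inversion of the predictive state belief
through the likelihood. The epistemic term is minus an expected information
gain and is therefore never positive. Per-policy totals are the plain sum
over tau; the policy posterior is softmax(-gamma * G_total), optionally
supplemented or supplanted by a deontic log-likelihood vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .model_core import (GenerativeModel, assert_categorical, safe_log,
                         softmax)

__all__ = [
    "PolicyEFE",
    "EFEReport",
    "predictive_state_beliefs",
    "predictive_outcome_beliefs",
    "expected_free_energy",
    "evaluate_policies",
    "policy_posterior",
    "select_action",
]

PATHWAY_MODES = ("representational", "supplement", "supplant")


@dataclass(frozen=True)
class PolicyEFE:
    """Per-tau expected free energy of one policy, in nats."""

    policy: np.ndarray          # action sequence
    instrumental: np.ndarray    # [T]
    epistemic: np.ndarray       # [T]
    G: np.ndarray               # [T], = instrumental + epistemic

    @property
    def G_total(self) -> float:
        return float(self.G.sum())


@dataclass(frozen=True)
class EFEReport:
    """Expected-free-energy table over the whole policy set."""

    per_policy: tuple[PolicyEFE, ...]

    @property
    def G_total(self) -> np.ndarray:
        return np.array([p.G_total for p in self.per_policy])


def predictive_state_beliefs(model: GenerativeModel, Q0: np.ndarray,
                             policy: np.ndarray) -> np.ndarray:
    """Roll Q0 forward under the policy; row tau-1 is Q(s_tau | pi)."""
    Q0 = assert_categorical(Q0, "Q0")
    policy = np.asarray(policy, dtype=int)
    if policy.shape != (model.horizon,):
        raise ValueError(f"policy has shape {policy.shape}, expected "
                         f"({model.horizon},)")
    if Q0.size != model.n_states:
        raise ValueError(f"belief has {Q0.size} states, model has {model.n_states}")
    out = np.empty((model.horizon, model.n_states))
    q = Q0
    for tau, action in enumerate(policy):
        q = model.B[action] @ q
        out[tau] = q
    return out


def predictive_outcome_beliefs(model: GenerativeModel,
                               Q_s_tau: np.ndarray) -> np.ndarray:
    """Marginal predictive over outcomes: A @ Q(s_tau | pi)."""
    Q_s_tau = assert_categorical(Q_s_tau, "Q_s_tau")
    return model.A @ Q_s_tau


def expected_free_energy(model: GenerativeModel, Q0: np.ndarray,
                         policy: np.ndarray) -> PolicyEFE:
    """Per-tau G with its instrumental/epistemic decomposition for one policy."""
    policy = np.asarray(policy, dtype=int)
    qs = predictive_state_beliefs(model, Q0, policy)
    if model.lnC.shape[0] < model.horizon:
        raise ConfigurationError(
            f"preferences defined for {model.lnC.shape[0]} steps, "
            f"horizon is {model.horizon}")
    A = model.A
    instrumental = np.empty(model.horizon)
    epistemic = np.empty(model.horizon)
    for tau in range(model.horizon):
        q = qs[tau]
        joint = A * q[None, :]                      # [o, s] = Q(s) A[o|s]
        qo = joint.sum(axis=1)                      # predictive outcomes
        # Bayes inversion of the predictive belief through A, per outcome
        post = joint / np.maximum(qo[:, None], np.finfo(float).tiny)
        instrumental[tau] = -float((joint.sum(axis=1) @ model.lnC[tau]))
        epistemic[tau] = float(
            (joint * (safe_log(q)[None, :] - safe_log(post))).sum())
    return PolicyEFE(policy=policy, instrumental=instrumental,
                     epistemic=epistemic, G=instrumental + epistemic)


def evaluate_policies(model: GenerativeModel, Q0: np.ndarray) -> EFEReport:
    """Expected free energy of every enumerated policy from belief Q0."""
    return EFEReport(per_policy=tuple(
        expected_free_energy(model, Q0, pi) for pi in model.policies))


def policy_posterior(G_total: np.ndarray,
                     deontic_logvec: Optional[np.ndarray] = None,
                     mode: str = "representational",
                     gamma: float = 1.0) -> np.ndarray:
    """Categorical posterior over policies for the requested pathway mode.

    representational: softmax(-gamma * G_total)
    supplement:       softmax(-gamma * G_total + deontic_logvec)
    supplant:         softmax(deontic_logvec), G_total ignored
    """
    from .deontic import combine_pathways  # local import avoids a cycle
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    G_total = np.asarray(G_total, dtype=float)
    logits = combine_pathways(gamma * G_total, deontic_logvec, mode)
    return softmax(logits)


def select_action(posterior: np.ndarray, policies: np.ndarray, t: int,
                  rule: str = "map",
                  rng: Optional[np.random.Generator] = None) -> int:
    """Pick the action at step ``t`` of a policy chosen from the posterior.

    ``rule="map"`` takes the max-posterior policy with ties broken toward the
    lowest policy index; ``rule="sample"`` draws a policy from the posterior
    (requires ``rng``).
    """
    policies = np.asarray(policies, dtype=int)
    if policies.size == 0:
        raise ConfigurationError("empty policy set")
    posterior = assert_categorical(posterior, "policy posterior")
    if not 0 <= t < policies.shape[1]:
        raise IndexError(f"time index {t} outside horizon {policies.shape[1]}")
    if rule == "map":
        k = int(np.argmax(posterior))   # argmax returns the first maximum
    elif rule == "sample":
        if rng is None:
            raise ConfigurationError('rule "sample" requires an rng')
        k = int(rng.choice(len(posterior), p=posterior))
    else:
        raise ConfigurationError(f"unknown action rule {rule!r}")
    return int(policies[k, t])
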