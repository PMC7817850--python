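"""Brute-force reference implementations, independent of the package code.

Everything here is written with explicit Python loops over states and
outcomes so the tested vectorized paths cannot share a bug with the oracle.
"""

import math


def bayes_enumeration(prior, A, o):
    """Exact posterior and evidence by explicit enumeration over states."""
    n_states = len(prior)
    evidence = 0.0
    for s in range(n_states):
        evidence += prior[s] * A[o][s]
    posterior = [prior[s] * A[o][s] / evidence for s in range(n_states)]
    return posterior, evidence


def free_energy_enumeration(Q, prior, A, o, floor=1e-16):
    """F, KL[Q||posterior] and -ln evidence by explicit sums."""

    def ln(x):
        return math.log(max(x, floor))

    posterior, evidence = bayes_enumeration(prior, A, o)
    F = sum(Q[s] * (ln(Q[s]) - ln(prior[s] * A[o][s])) for s in range(len(Q)))
    kl = sum(Q[s] * (ln(Q[s]) - ln(posterior[s])) for s in range(len(Q)))
    return F, kl, -math.log(evidence)


def rollout_enumeration(B, Q0, actions):
    """Belief rollout as explicit per-entry matrix-vector products."""
    beliefs = []
    q = list(Q0)
    for a in actions:
        q = [sum(B[a][i][j] * q[j] for j in range(len(q))) for i in range(len(q))]
        beliefs.append(list(q))
    return beliefs


def efe_joint_enumeration(A, qs, lnC, floor=1e-16):
    """Single-sum joint form of the per-step expected free energy.

    G = sum_{s,o} Q(s) A[o|s] [ln Q(s) - ln(P(s|o) C(o))], with P(s|o) the
    Bayes inversion of Q through A. Returns (G, instrumental, epistemic)
    where the two terms are accumulated by separate explicit sums.
    """

    def ln(x):
        return math.log(max(x, floor))

    n_o = len(A)
    n_s = len(qs)
    qo = [sum(A[o][s] * qs[s] for s in range(n_s)) for o in range(n_o)]
    post = [[A[o][s] * qs[s] / qo[o] if qo[o] > 0 else 0.0
             for s in range(n_s)] for o in range(n_o)]
    G = instrumental = epistemic = 0.0
    for s in range(n_s):
        for o in range(n_o):
            w = qs[s] * A[o][s]
            G += w * (ln(qs[s]) - ln(post[o][s]) - lnC[o])
            instrumental += -w * lnC[o]
            epistemic += w * (ln(qs[s]) - ln(post[o][s]))
    return G, instrumental, epistemic
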