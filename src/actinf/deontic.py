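"""The deontic pathway: cue-conditioned policy value and its acquisition.

Deontic value is the log likelihood of the current observation under each
policy, ``ln E[o, pi]``. It can supplement the negated expected free energy
inside the policy softmax, or supplant it entirely — in which case action
selection reads only the cue and never touches beliefs about hidden states.

Learning is Dirichlet-style: each observed (cue, chosen-policy) pair adds
``eta`` to the corresponding concentration count and the likelihood is the
column-normalized count matrix, so E stays a proper conditional throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .model_core import DeonticModel, safe_log

__all__ = [
    "DeonticUpdateConfig",
    "deontic_log_likelihood",
    "combine_pathways",
    "update_deontic_model",
    "flat_deontic_model",
]


@dataclass(frozen=True)
class DeonticUpdateConfig:
    """Learning increment and flat prior for concentration counts."""

    eta: float = 1.0
    prior_count: float = 1.0

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.prior_count <= 0:
            raise ValueError(f"prior_count must be > 0, got {self.prior_count}")


def flat_deontic_model(n_outcomes: int, n_policies: int,
                       prior_count: float = 1.0) -> DeonticModel:
    """Uniform deontic likelihood with counts initialized to ``prior_count``."""
    counts = np.full((n_outcomes, n_policies), float(prior_count))
    return DeonticModel(E=counts / counts.sum(axis=0, keepdims=True),
                        counts=counts)


def deontic_log_likelihood(deontic: DeonticModel, o: int) -> np.ndarray:
    """ln E[o, pi] for every policy, in the model's policy order."""
    o = int(o)
    if not 0 <= o < deontic.n_outcomes:
        raise IndexError(f"outcome index {o} outside [0, {deontic.n_outcomes})")
    return safe_log(deontic.E[o, :])


def combine_pathways(G_total: np.ndarray,
                     deontic_logvec: Optional[np.ndarray],
                     mode: str) -> np.ndarray:
    """Unnormalized log-prior over policies for the given pathway mode."""
    G_total = np.asarray(G_total, dtype=float)
    if mode == "representational":
        return -G_total
    if mode in ("supplement", "supplant"):
        if deontic_logvec is None:
            raise ConfigurationError(f"mode {mode!r} requires a deontic log vector")
        deontic_logvec = np.asarray(deontic_logvec, dtype=float)
        if deontic_logvec.shape != G_total.shape:
            raise ConfigurationError(
                f"deontic vector shape {deontic_logvec.shape} != "
                f"G shape {G_total.shape}")
        if mode == "supplement":
            return -G_total + deontic_logvec
        return deontic_logvec.copy()
    raise ConfigurationError(f"unknown pathway mode {mode!r}")


def update_deontic_model(deontic: DeonticModel, o: int, pi: int,
                         cfg: DeonticUpdateConfig = DeonticUpdateConfig(),
                         ) -> DeonticModel:
    """Accumulate one (cue, policy) co-occurrence; returns a new model.

    Counts absent on input are initialized flat at ``cfg.prior_count``.
    """
    o = int(o)
    pi = int(pi)
    if not 0 <= o < deontic.n_outcomes:
        raise IndexError(f"outcome index {o} outside [0, {deontic.n_outcomes})")
    if not 0 <= pi < deontic.n_policies:
        raise IndexError(f"policy index {pi} outside [0, {deontic.n_policies})")
    if deontic.counts is None:
        counts = np.full(deontic.E.shape, float(cfg.prior_count))
    else:
        counts = deontic.counts.copy()
    counts[o, pi] += cfg.eta
    return DeonticModel(E=counts / counts.sum(axis=0, keepdims=True),
                        counts=counts)
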