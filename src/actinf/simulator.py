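"""Agent-environment loop, scenario fixtures and habitization experiments.

The environment (generative process) is held strictly separate from the
agent's generative model: its emission and dynamics may differ from A and B,
and the agent interacts with it only through sampled outcomes via
``Environment.observe`` / ``Environment.step``.

Per step the representational agent propagates its prior through the
transition matrix of the previously executed action, infers states from the
new observation, evaluates expected free energy over all policies and picks
the first action of a policy drawn from the softmax posterior (receding
horizon). In supplant mode both state inference and the expected-free-energy
evaluation are skipped: the policy posterior is the softmax of the deontic
log likelihood of the current cue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import deontic as deontic_mod
from . import perception, planning
from .deontic import DeonticUpdateConfig, flat_deontic_model
from .errors import ActinfError, ConfigurationError
from .model_core import (EPS, GenerativeModel, assert_categorical,
                         enumerate_policies, safe_log)

__all__ = [
    "Environment",
    "StepRecord",
    "EpisodeLog",
    "step_environment",
    "run_episode",
    "make_traffic_light_scenario",
    "make_epistemic_probe_scenario",
    "run_habitization_experiment",
]


@dataclass
class Environment:
    """The generative process: true state, true emission, true dynamics."""

    true_state: int
    emission: np.ndarray              # [n_outcomes, n_states], columns stochastic
    dynamics: np.ndarray              # [n_actions, n_states, n_states]
    initial: Optional[np.ndarray] = None   # distribution used by reset()

    def __post_init__(self):
        self.emission = np.asarray(self.emission, dtype=float)
        self.dynamics = np.asarray(self.dynamics, dtype=float)
        for j in range(self.emission.shape[1]):
            assert_categorical(self.emission[:, j], f"emission column {j}")
        for a in range(self.dynamics.shape[0]):
            for j in range(self.dynamics.shape[1]):
                assert_categorical(self.dynamics[a][:, j],
                                   f"dynamics[{a}] column {j}")
        if self.initial is not None:
            self.initial = assert_categorical(np.asarray(self.initial, float),
                                              "initial state distribution")

    def reset(self, rng: np.random.Generator) -> int:
        """Resample the true state from the initial distribution, if any."""
        if self.initial is not None:
            self.true_state = int(rng.choice(len(self.initial), p=self.initial))
        return self.true_state

    def observe(self, rng: np.random.Generator) -> int:
        """Sample an outcome from the emission column of the current state."""
        p = self.emission[:, self.true_state]
        return int(rng.choice(len(p), p=p))

    def step(self, action: int, rng: np.random.Generator) -> tuple[int, int]:
        """Execute an action: sample the next state, then its outcome."""
        action = int(action)
        if not 0 <= action < self.dynamics.shape[0]:
            raise IndexError(f"action index {action} outside "
                             f"[0, {self.dynamics.shape[0]})")
        p = self.dynamics[action][:, self.true_state]
        self.true_state = int(rng.choice(len(p), p=p))
        return self.true_state, self.observe(rng)


def step_environment(env: Environment, action: int,
                     rng: np.random.Generator) -> tuple[int, int]:
    """Functional wrapper around :meth:`Environment.step`."""
    return env.step(action, rng)


@dataclass
class StepRecord:
    t: int
    true_state: int
    outcome: int
    action: int
    mode: str
    belief: Optional[list] = None            # None in supplant mode
    policy_posterior: Optional[list] = None
    F: Optional[float] = None
    G_total: Optional[list] = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


@dataclass
class EpisodeLog:
    """Time-indexed record of one episode plus bookkeeping counters."""

    mode: str
    steps: list[StepRecord] = field(default_factory=list)
    efe_evaluations: int = 0
    inference_calls: int = 0

    @property
    def actions(self) -> list[int]:
        return [s.action for s in self.steps]

    @property
    def outcomes(self) -> list[int]:
        return [s.outcome for s in self.steps]

    def to_jsonl(self) -> str:
        return "\n".join(s.to_json() for s in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def run_episode(model: GenerativeModel, env: Environment, T: int,
                mode: str = "representational", seed=0,
                action_rule: str = "sample",
                update_deontic: bool = False,
                update_cfg: DeonticUpdateConfig = DeonticUpdateConfig(),
                reset_env: bool = False) -> EpisodeLog:
    """Run the closed agent-environment loop for ``T`` steps.

    Component errors are re-raised with the failing step index attached.
    ``update_deontic`` accumulates (cue, chosen-policy) counts into
    ``model.deontic`` in place — in every mode, by default.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if mode not in planning.PATHWAY_MODES:
        raise ConfigurationError(f"unknown pathway mode {mode!r}")
    if mode in ("supplement", "supplant") and model.deontic is None:
        raise ConfigurationError(f"mode {mode!r} requires a deontic model")

    root = np.random.default_rng(seed)
    env_rng, agent_rng = root.spawn(2)
    if reset_env:
        env.reset(env_rng)

    log = EpisodeLog(mode=mode)
    prior = model.D.copy()
    prev_action: Optional[int] = None
    # single bookkeeping read of the process state for the log; thereafter the
    # true state is taken from the values env.step chooses to return
    cur_state = int(env.true_state)
    outcome = env.observe(env_rng)

    for t in range(T):
        try:
            if prev_action is not None and mode != "supplant":
                prior = model.B[prev_action] @ prior

            belief = F = None
            G_total = None
            if mode != "supplant":
                Q, report = perception.infer_states(model, prior, outcome)
                log.inference_calls += 1
                belief, F = Q, report.F
                efe = planning.evaluate_policies(model, Q)
                log.efe_evaluations += 1
                G_total = efe.G_total
            else:
                Q = None

            dlv = None
            if mode in ("supplement", "supplant"):
                dlv = deontic_mod.deontic_log_likelihood(model.deontic, outcome)
            logits_G = G_total if G_total is not None else np.zeros(model.n_policies)
            posterior = planning.policy_posterior(
                logits_G, dlv, mode=mode, gamma=model.gamma)

            action = planning.select_action(posterior, model.policies, 0,
                                            rule=action_rule, rng=agent_rng)
            chosen_policy = _policy_of_action(model, posterior, action)
            if update_deontic and model.deontic is not None:
                model.deontic = deontic_mod.update_deontic_model(
                    model.deontic, outcome, chosen_policy, update_cfg)

            log.steps.append(StepRecord(
                t=t, true_state=cur_state, outcome=int(outcome),
                action=int(action), mode=mode,
                belief=None if Q is None else [float(x) for x in Q],
                policy_posterior=[float(x) for x in posterior],
                F=None if F is None else float(F),
                G_total=None if G_total is None else [float(x) for x in G_total],
            ))

            if Q is not None:
                prior = Q
            prev_action = action
            cur_state, outcome = env.step(action, env_rng)
        except ActinfError as exc:
            raise ActinfError(f"step {t}: {exc}") from exc
    return log


def _policy_of_action(model: GenerativeModel, posterior: np.ndarray,
                      action: int) -> int:
    """Most probable policy whose first action matches the executed one."""
    mask = model.policies[:, 0] == action
    idx = np.flatnonzero(mask)
    return int(idx[np.argmax(posterior[idx])])


# ---------------------------------------------------------------------------
# scenario fixtures
# ---------------------------------------------------------------------------

# traffic-light indices
RED, GREEN = 0, 1
GO, STOP = 0, 1


def make_traffic_light_scenario(prior_count: float = 1.0,
                                ) -> tuple[GenerativeModel, Environment]:
    """Two-state stop/go scenario with a faithful cue and a flat deontic map.

    States and outcomes are {red, green}; actions are {go, stop}. Stopping at
    red eventually yields the green (preferred) outcome, going at red keeps
    the dispreferred red outcome, and at green both actions keep green — so a
    preference for green makes the representational agent stop on red and
    (by the documented tie-break toward policy 0 = go) go on green.
    """
    A = np.eye(2)
    B = np.empty((2, 2, 2))
    B[GO] = np.array([[1.0, 0.0],     # going at red leaves you stuck at red
                      [0.0, 1.0]])
    B[STOP] = np.array([[0.0, 0.0],   # waiting at red brings the green
                        [1.0, 1.0]])
    D = np.array([0.5, 0.5])
    lnC = safe_log(np.array([EPS, 1.0]) / (EPS + 1.0))[None, :]
    policies = np.array([[GO], [STOP]])
    model = GenerativeModel(
        A=A, B=B, D=D, lnC=lnC, policies=policies, horizon=1, gamma=1.0,
        deontic=flat_deontic_model(2, 2, prior_count=prior_count))
    env = Environment(true_state=RED, emission=A.copy(), dynamics=B.copy(),
                      initial=np.array([0.5, 0.5]))
    return model, env


def make_epistemic_probe_scenario() -> tuple[GenerativeModel, Environment]:
    """Three-state fixture where one action resolves state uncertainty.

    The agent starts uncertain between contexts 0 and 1. Action "stay"
    (index 0) leaves both contexts in place, and their likelihood columns are
    identical, so its outcome carries no information. Action "probe"
    (index 1) moves context 1 into a revealed state with a distinct
    likelihood column, so its outcome disambiguates the context either way.
    Preferences are uniform at tau = 1 and peaked on the revealing outcome at
    tau = 2.
    """
    # states: 0 = context-0, 1 = context-1, 2 = context-1 revealed
    # outcomes: 0 = ambiguous, 1 = revealing
    A = np.array([[1.0, 1.0, 0.0],
                  [0.0, 0.0, 1.0]])
    STAY, PROBE = 0, 1
    B = np.empty((2, 3, 3))
    B[STAY] = np.eye(3)
    B[PROBE] = np.array([[1.0, 0.0, 0.0],
                         [0.0, 0.0, 0.0],
                         [0.0, 1.0, 1.0]])
    D = np.array([0.5, 0.5, 0.0])
    uniform = np.log(np.array([0.5, 0.5]))
    peaked = safe_log(np.array([EPS, 1.0]) / (EPS + 1.0))
    lnC = np.vstack([uniform, peaked])
    model = GenerativeModel(A=A, B=B, D=D, lnC=lnC,
                            policies=enumerate_policies(2, 2), horizon=2,
                            gamma=1.0)
    env = Environment(true_state=1, emission=A.copy(), dynamics=B.copy())
    return model, env


# ---------------------------------------------------------------------------
# habitization experiment
# ---------------------------------------------------------------------------

#: cue -> cue-consistent action in the traffic-light scenario
CUE_CONSISTENT = {RED: STOP, GREEN: GO}


def run_habitization_experiment(n_episodes: int, seed=0,
                                switch_at: Optional[int] = None,
                                eta: float = 1.0, prior_count: float = 1.0,
                                phase2_rule: str = "sample") -> pd.DataFrame:
    """Habit acquisition then deontic control in the traffic-light scenario.

    Phase 1 (episodes before ``switch_at``, default the midpoint) runs the
    representational agent with MAP action selection — deterministic
    stop-on-red / go-on-green — while accumulating deontic counts from each
    (cue, chosen-policy) pair. Phase 2 switches to supplant mode and acts
    from the learned cue-policy likelihood alone.

    Returns one row per episode: the cue, the action, whether it was
    cue-consistent, the model probability assigned to the cue-consistent
    policy at decision time, the running E[red, stop], and the mode in force.
    """
    if n_episodes < 1:
        raise ValueError(f"n_episodes must be >= 1, got {n_episodes}")
    if switch_at is None:
        switch_at = n_episodes // 2
    model, env = make_traffic_light_scenario(prior_count=prior_count)
    cfg = DeonticUpdateConfig(eta=eta, prior_count=prior_count)
    root = np.random.default_rng(seed)

    rows = []
    for ep in range(n_episodes):
        phase2 = ep >= switch_at
        mode = "supplant" if phase2 else "representational"
        rule = phase2_rule if phase2 else "map"
        log = run_episode(model, env, T=1, mode=mode,
                          seed=root.integers(2**63), action_rule=rule,
                          update_deontic=True, update_cfg=cfg,
                          reset_env=True)
        step = log.steps[0]
        cue, action = step.outcome, step.action
        consistent_policy = CUE_CONSISTENT[cue]   # policy index == its action
        rows.append({
            "episode": ep,
            "mode": mode,
            "cue": cue,
            "action": action,
            "cue_consistent": int(action == CUE_CONSISTENT[cue]),
            "p_cue_consistent": step.policy_posterior[consistent_policy],
            "E_red_stop": float(model.deontic.E[RED, STOP]),
        })
    return pd.DataFrame(rows)
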