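"""Generative-model data types, validation, (de)serialization and fixtures.

Conventions used throughout the package:

* The likelihood matrix ``A`` is indexed ``[outcome, state]``; every column
  (a fixed state) is a categorical distribution over outcomes, so predictive
  outcome beliefs are the matrix-vector product ``A @ q``.
* Transition matrices ``B[a]`` are indexed ``[next_state, prev_state]``;
  columns are distributions over the next state, so belief propagation is
  ``B[a] @ q``.
* Preferences are stored as the log of a proper distribution over outcomes,
  one row per future time step (shape ``[horizon, n_outcomes]``).
* The deontic matrix ``E`` is indexed ``[outcome, policy]``; every column
  (a fixed policy) is a categorical distribution over outcomes.
* Logarithms are always taken after flooring probabilities at ``EPS`` so
  one-hot columns never produce ``-inf``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, ModelValidationError, ParseError

__all__ = [
    "EPS",
    "CATEGORICAL_ATOL",
    "Violation",
    "DeonticModel",
    "GenerativeModel",
    "assert_categorical",
    "is_categorical",
    "floor_and_normalize",
    "safe_log",
    "softmax",
    "validate_model",
    "load_model",
    "load_model_file",
    "save_model",
    "make_random_model",
    "enumerate_policies",
]

#: Floor applied to probabilities before taking logarithms.
EPS = 1e-16

#: Tolerance for "sums to one" checks on categorical distributions.
CATEGORICAL_ATOL = 1e-9

#: Policy enumeration cap: all action sequences are enumerated when
#: ``n_actions ** horizon`` does not exceed this; larger spaces require an
#: explicit policy list.
POLICY_ENUMERATION_CAP = 256


# ---------------------------------------------------------------------------
# categorical helpers
# ---------------------------------------------------------------------------

def is_categorical(v: np.ndarray, atol: float = CATEGORICAL_ATOL) -> bool:
    """Return True iff ``v`` is a valid probability vector."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 1:
        return False
    return bool(np.all(v >= 0) and abs(v.sum() - 1.0) <= atol)


def assert_categorical(v: np.ndarray, name: str = "vector",
                       atol: float = CATEGORICAL_ATOL) -> np.ndarray:
    """Validate and return ``v`` as a categorical distribution.

    This is the shared guard used by every routine that produces a
    distribution; it raises ``ValueError`` on violation.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-d vector, got shape {v.shape}")
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries: {v}")
    if abs(v.sum() - 1.0) > atol:
        raise ValueError(f"{name} sums to {v.sum()!r}, not 1 within {atol}")
    return v


def floor_and_normalize(v: Sequence[float], epsilon: float = EPS) -> np.ndarray:
    """Return ``(v + epsilon) / sum(v + epsilon)`` as a valid categorical.

    Raises :class:`DegenerateInputError` when ``v`` is all-zero and
    ``epsilon == 0``.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise DegenerateInputError(f"negative entries in {v}")
    w = v + epsilon
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero vector with epsilon = 0 cannot be normalized")
    return w / total


def safe_log(p: np.ndarray, epsilon: float = EPS) -> np.ndarray:
    """Elementwise log with the standard probability floor."""
    return np.log(np.maximum(np.asarray(p, dtype=float), epsilon))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable normalized exponential."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=float)
    z = z - z.max()
    return z - np.log(np.exp(z).sum())


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """A single machine-readable invariant violation."""

    code: str
    path: str
    message: str


@dataclass
class DeonticModel:
    """Outcome-conditioned policy likelihood P(o | pi).

    ``E`` is ``[n_outcomes, n_policies]`` with column distributions; when
    ``counts`` is present ``E`` must equal the column-normalized counts, which
    is how learning keeps the likelihood proper.
    """

    E: np.ndarray
    counts: Optional[np.ndarray] = None

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)

    @property
    def n_outcomes(self) -> int:
        return self.E.shape[0]

    @property
    def n_policies(self) -> int:
        return self.E.shape[1]


@dataclass
class GenerativeModel:
    """Bundle of categorical parameter arrays defining the agent's model.

    Attributes
    ----------
    A : ndarray [n_outcomes, n_states]
        Likelihood of outcomes given states; columns are distributions.
    B : ndarray [n_actions, n_states, n_states]
        Per-action transition matrices, indexed [next, prev].
    D : ndarray [n_states]
        Initial-state prior.
    lnC : ndarray [horizon, n_outcomes]
        Log preferences over outcomes per future step; each row is the log of
        a proper distribution.
    policies : ndarray [n_policies, horizon] of int
        Explicitly enumerated action sequences.
    horizon : int
        Planning horizon T.
    gamma : float
        Softmax temperature (precision) over policies.
    deontic : DeonticModel, optional
        Cue-conditioned policy likelihood for the deontic pathway.
    """

    A: np.ndarray
    B: np.ndarray
    D: np.ndarray
    lnC: np.ndarray
    policies: np.ndarray
    horizon: int
    gamma: float = 1.0
    deontic: Optional[DeonticModel] = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.lnC = np.atleast_2d(np.asarray(self.lnC, dtype=float))
        if self.lnC.shape[0] == 1 and self.horizon > 1:
            self.lnC = np.repeat(self.lnC, self.horizon, axis=0)
        self.policies = np.asarray(self.policies, dtype=int)

    @property
    def n_states(self) -> int:
        return self.A.shape[1]

    @property
    def n_outcomes(self) -> int:
        return self.A.shape[0]

    @property
    def n_actions(self) -> int:
        return self.B.shape[0]

    @property
    def n_policies(self) -> int:
        return self.policies.shape[0]

    def copy(self) -> "GenerativeModel":
        deontic = None
        if self.deontic is not None:
            counts = None if self.deontic.counts is None else self.deontic.counts.copy()
            deontic = DeonticModel(self.deontic.E.copy(), counts)
        return GenerativeModel(
            A=self.A.copy(), B=self.B.copy(), D=self.D.copy(),
            lnC=self.lnC.copy(), policies=self.policies.copy(),
            horizon=self.horizon, gamma=self.gamma, deontic=deontic,
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_columns(M: np.ndarray, path: str, code: str, out: list,
                   what: str) -> None:
    for j in range(M.shape[1]):
        col = M[:, j]
        if np.any(col < 0):
            out.append(Violation(code, f"{path}[:,{j}]",
                                 f"{what} column {j} has negative entries"))
        elif abs(col.sum() - 1.0) > CATEGORICAL_ATOL:
            out.append(Violation(code, f"{path}[:,{j}]",
                                 f"{what} column {j} sums to {col.sum():.12g}, not 1"))


def validate_model(model: GenerativeModel) -> list[Violation]:
    """Enumerate every invariant violation; an empty list means valid.

    Malformed structure is reported, never raised, so callers can present
    complete diagnostics.
    """
    out: list[Violation] = []
    A, B, D = model.A, model.B, model.D

    if A.ndim != 2:
        out.append(Violation("A_SHAPE", "/A", f"A must be 2-d, got ndim {A.ndim}"))
        return out
    n_o, n_s = A.shape
    _check_columns(A, "/A", "A_COLUMN_NOT_STOCHASTIC", out, "likelihood")

    if B.ndim != 3 or B.shape[1] != B.shape[2]:
        out.append(Violation("B_SHAPE", "/B",
                             f"B must be [n_actions, n, n], got shape {B.shape}"))
    else:
        if B.shape[1] != n_s:
            out.append(Violation("DIM_MISMATCH", "/B",
                                 f"B is over {B.shape[1]} states but A has {n_s}"))
        for a in range(B.shape[0]):
            _check_columns(B[a], f"/B[{a}]", "B_COLUMN_NOT_STOCHASTIC", out,
                           f"transition (action {a})")

    if D.ndim != 1 or D.size != n_s:
        out.append(Violation("DIM_MISMATCH", "/D",
                             f"D has shape {D.shape}, expected ({n_s},)"))
    elif not is_categorical(D):
        out.append(Violation("D_NOT_CATEGORICAL", "/D",
                             f"D = {D.tolist()} is not a distribution"))

    if model.lnC.shape != (model.horizon, n_o):
        out.append(Violation("DIM_MISMATCH", "/C",
                             f"preferences have shape {model.lnC.shape}, "
                             f"expected ({model.horizon}, {n_o})"))
    else:
        for t in range(model.horizon):
            total = float(np.exp(model.lnC[t]).sum())
            if abs(total - 1.0) > CATEGORICAL_ATOL:
                out.append(Violation("C_NOT_LOG_DISTRIBUTION", f"/C[{t}]",
                                     f"exp(lnC[{t}]) sums to {total:.12g}, not 1"))

    if model.policies.ndim != 2 or model.policies.shape[1] != model.horizon:
        out.append(Violation("POLICY_SHAPE", "/policies",
                             f"policies have shape {model.policies.shape}, "
                             f"expected (n_policies, {model.horizon})"))
    else:
        n_a = model.B.shape[0] if model.B.ndim == 3 else 0
        bad = np.argwhere((model.policies < 0) | (model.policies >= n_a))
        for i, t in bad:
            out.append(Violation("ACTION_INDEX_RANGE", f"/policies[{i}][{t}]",
                                 f"action index {model.policies[i, t]} outside "
                                 f"[0, {n_a})"))

    if not (isinstance(model.horizon, (int, np.integer)) and model.horizon >= 1):
        out.append(Violation("HORIZON_RANGE", "/horizon",
                             f"horizon must be a positive integer, got {model.horizon}"))
    if not (model.gamma > 0):
        out.append(Violation("GAMMA_RANGE", "/gamma",
                             f"gamma must be > 0, got {model.gamma}"))

    if model.deontic is not None:
        E = model.deontic.E
        if E.ndim != 2 or E.shape[0] != n_o:
            out.append(Violation("DIM_MISMATCH", "/E",
                                 f"E has shape {E.shape}, expected "
                                 f"({n_o}, n_policies)"))
        else:
            if model.policies.ndim == 2 and E.shape[1] != model.n_policies:
                out.append(Violation("DIM_MISMATCH", "/E",
                                     f"E has {E.shape[1]} policy columns but the "
                                     f"model enumerates {model.n_policies}"))
            _check_columns(E, "/E", "E_COLUMN_NOT_STOCHASTIC", out, "deontic")
            counts = model.deontic.counts
            if counts is not None:
                if counts.shape != E.shape:
                    out.append(Violation("DIM_MISMATCH", "/E_counts",
                                         f"counts shape {counts.shape} != E shape {E.shape}"))
                elif np.any(counts < 0):
                    out.append(Violation("E_COUNTS_NEGATIVE", "/E_counts",
                                         "concentration counts must be nonnegative"))
                else:
                    norm = counts / counts.sum(axis=0, keepdims=True)
                    if not np.allclose(norm, E, atol=CATEGORICAL_ATOL):
                        out.append(Violation("E_COUNTS_INCONSISTENT", "/E_counts",
                                             "E differs from column-normalized counts"))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("n_states", "n_outcomes", "n_actions", "horizon",
                  "A", "B", "D", "C", "policies")


def _parse_spec(text: str) -> dict:
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        pass
    try:
        import yaml
        doc = yaml.safe_load(text)
    except Exception as exc:  # pragma: no cover - yaml gives varied errors
        raise ParseError(f"neither valid JSON nor YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError("top-level document must be a mapping")
    return doc


def load_model(text: str) -> GenerativeModel:
    """Parse a JSON (or YAML) model spec into a validated GenerativeModel.

    Schema violations raise :class:`ParseError` naming the offending path;
    probabilistic invariant violations raise :class:`ModelValidationError`.
    """
    doc = _parse_spec(text)
    for key in _REQUIRED_KEYS:
        if key not in doc:
            raise ParseError("required key missing", path=f"/{key}")

    def _num(key):
        v = doc[key]
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 1:
            raise ParseError(f"must be a positive integer, got {v!r}", path=f"/{key}")
        return int(v)

    n_s, n_o, n_a, T = (_num(k) for k in ("n_states", "n_outcomes",
                                          "n_actions", "horizon"))

    def _array(key, value, shape):
        try:
            arr = np.asarray(value, dtype=float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"not a numeric array: {exc}", path=f"/{key}") from exc
        if arr.shape != shape:
            raise ParseError(f"shape {arr.shape} does not match declared "
                             f"dimensions {shape}", path=f"/{key}")
        return arr

    A = _array("A", doc["A"], (n_o, n_s))
    B = _array("B", doc["B"], (n_a, n_s, n_s))
    D = _array("D", doc["D"], (n_s,))

    C = doc["C"]
    if not isinstance(C, dict) or not ({"log_probs", "utilities"} & C.keys()):
        raise ParseError('must be an object with "log_probs" or "utilities"',
                         path="/C")
    if "log_probs" in C:
        raw = np.atleast_2d(np.asarray(C["log_probs"], dtype=float))
        if raw.shape[0] == 1:
            raw = np.repeat(raw, T, axis=0)
        if raw.shape != (T, n_o):
            raise ParseError(f"log_probs shape {raw.shape} incompatible with "
                             f"horizon {T} and {n_o} outcomes", path="/C/log_probs")
        lnC = raw
    else:
        raw = np.atleast_2d(np.asarray(C["utilities"], dtype=float))
        if raw.shape[0] == 1:
            raw = np.repeat(raw, T, axis=0)
        if raw.shape != (T, n_o):
            raise ParseError(f"utilities shape {raw.shape} incompatible with "
                             f"horizon {T} and {n_o} outcomes", path="/C/utilities")
        lnC = np.vstack([log_softmax(row) for row in raw])

    policies = doc["policies"]
    try:
        policies = np.asarray(policies, dtype=int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"not an integer array: {exc}", path="/policies") from exc
    if policies.ndim != 2:
        raise ParseError("must be a list of action-index lists", path="/policies")

    deontic = None
    if doc.get("E") is not None:
        E = np.asarray(doc["E"], dtype=float)
        if E.ndim != 2:
            raise ParseError("must be a 2-d [outcome][policy] matrix", path="/E")
        counts = None
        if doc.get("E_counts") is not None:
            counts = np.asarray(doc["E_counts"], dtype=float)
            if counts.shape != E.shape:
                raise ParseError(f"shape {counts.shape} != E shape {E.shape}",
                                 path="/E_counts")
        deontic = DeonticModel(E, counts)

    gamma = float(doc.get("gamma", 1.0))
    model = GenerativeModel(A=A, B=B, D=D, lnC=lnC, policies=policies,
                            horizon=T, gamma=gamma, deontic=deontic)
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    return model


def load_model_file(path) -> GenerativeModel:
    with open(path, "r", encoding="utf-8") as fh:
        return load_model(fh.read())


def save_model(model: GenerativeModel) -> str:
    """Serialize a model to the canonical JSON spec (round-trips load_model)."""
    doc = {
        "n_states": model.n_states,
        "n_outcomes": model.n_outcomes,
        "n_actions": model.n_actions,
        "horizon": int(model.horizon),
        "A": model.A.tolist(),
        "B": model.B.tolist(),
        "D": model.D.tolist(),
        "C": {"log_probs": model.lnC.tolist()},
        "policies": model.policies.tolist(),
        "gamma": model.gamma,
    }
    if model.deontic is not None:
        doc["E"] = model.deontic.E.tolist()
        if model.deontic.counts is not None:
            doc["E_counts"] = model.deontic.counts.tolist()
    return json.dumps(doc, indent=2)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def enumerate_policies(n_actions: int, horizon: int) -> np.ndarray:
    """All action sequences of the given length, lexicographic order."""
    n_total = n_actions ** horizon
    if n_total > POLICY_ENUMERATION_CAP:
        raise ValueError(
            f"{n_total} policies exceed the enumeration cap "
            f"({POLICY_ENUMERATION_CAP}); supply an explicit policy list")
    return np.array(list(itertools.product(range(n_actions), repeat=horizon)),
                    dtype=int).reshape(n_total, horizon)


def make_random_model(n_states: int, n_outcomes: int, n_actions: int,
                      horizon: int, seed, with_deontic: bool = False,
                      ) -> GenerativeModel:
    """Draw a valid random model with flat-Dirichlet columns.

    Deterministic for a fixed ``seed``; ``seed`` may also be a
    ``numpy.random.Generator``.
    """
    for name, v in (("n_states", n_states), ("n_outcomes", n_outcomes),
                    ("n_actions", n_actions), ("horizon", horizon)):
        if not (isinstance(v, (int, np.integer)) and v >= 1):
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    A = rng.dirichlet(np.ones(n_outcomes), size=n_states).T
    B = np.stack([rng.dirichlet(np.ones(n_states), size=n_states).T
                  for _ in range(n_actions)])
    D = rng.dirichlet(np.ones(n_states))
    lnC = safe_log(rng.dirichlet(np.ones(n_outcomes), size=horizon))
    # renormalize exactly in probability space so exp(lnC) sums to 1
    lnC = np.vstack([np.log(np.exp(row) / np.exp(row).sum()) for row in lnC])
    policies = enumerate_policies(n_actions, horizon)

    deontic = None
    if with_deontic:
        counts = np.ones((n_outcomes, policies.shape[0]))
        deontic = DeonticModel(counts / counts.sum(axis=0, keepdims=True),
                               counts=counts)
    return GenerativeModel(A=A, B=B, D=D, lnC=lnC, policies=policies,
                           horizon=int(horizon), gamma=1.0, deontic=deontic)
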