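"""Norm-based utility, choice and norm-update rules for the six candidate models.

All six models share the same inequity-averse utility and softmax choice
rule and differ only in how the internal fairness norm evolves:

* ``FS_fixed`` / ``FS_free`` — Fehr-Schmidt style non-learning models;
  the norm is constant (10 tokens, or a free parameter).
* ``BO_fixed`` / ``BO_free`` — a Bayesian observer that treats offers as
  draws from a Gaussian with unknown mean and variance under a conjugate
  Normal-Inverse-chi-squared prior; the prevailing norm at trial t is the
  prior mean before seeing that trial's offer.
* ``RW_fixed`` / ``RW_free`` — Rescorla-Wagner delta-rule learning: the
  norm moves toward each offer by a learning rate times the
  norm-prediction error.

``_fixed`` variants pin the initial norm at 10 tokens (an equal split of
the 20-token endowment); ``_free`` variants fit it per participant.

Utility of an offer s given norm x:

    U = s - alpha * max(x - s, 0) - beta * max(s - x, 0)

with envy alpha penalizing disadvantageous inequity (s below the norm)
and guilt beta penalizing advantageous inequity (s above the norm).
Acceptance probability is logistic(gamma * U) with inverse temperature
gamma (gamma = 0 gives chance behavior).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "MODEL_IDS",
    "AgentParams",
    "BayesObserverState",
    "fs_utility",
    "p_accept",
    "rw_update",
    "bo_update",
    "norm_trajectory",
    "negative_log_likelihood",
    "choices_to_accept",
    "DEFAULT_BOUNDS",
]

MODEL_IDS = ("FS_fixed", "FS_free", "BO_fixed", "BO_free", "RW_fixed", "RW_free")

#: probability floor/ceiling inside the log-likelihood (likelihood hygiene)
PROB_EPS = 1e-12

#: default parameter bounds; gamma's upper bound is configurable in fitting
DEFAULT_BOUNDS = {
    "alpha": (0.0, 10.0),
    "beta": (0.0, 10.0),
    "gamma": (0.0, 10.0),
    "epsilon": (0.0, 1.0),
    "initial_norm": (0.0, 20.0),
}

FIXED_INITIAL_NORM = 10.0

# Bayesian observer prior hyperparameters
BO_K0 = 4.0
BO_NU0 = 10.0
BO_SIGMA2_0 = 4.0


def _check_model_id(model_id: str) -> None:
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def free_param_names(model_id: str) -> tuple[str, ...]:
    """Names (and fit order) of the free parameters of a model."""
    _check_model_id(model_id)
    names = ["alpha", "beta", "gamma"]
    if model_id.startswith("RW"):
        names.append("epsilon")
    if model_id.endswith("_free"):
        names.append("initial_norm")
    return tuple(names)


@dataclass(frozen=True)
class AgentParams:
    """Parameters of one responder under one model.

    ``epsilon`` is meaningful only for RW models; ``initial_norm`` is
    pinned at 10 for ``*_fixed`` variants.
    """

    model_id: str
    alpha: float
    beta: float
    gamma: float
    epsilon: float | None = None
    initial_norm: float = FIXED_INITIAL_NORM

    def __post_init__(self) -> None:
        _check_model_id(self.model_id)
        if self.model_id.startswith("RW"):
            if self.epsilon is None:
                raise ValueError(f"{self.model_id} requires epsilon")
            if not 0.0 <= self.epsilon <= 1.0:
                raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        elif self.epsilon is not None:
            raise ValueError(f"{self.model_id} does not take epsilon")
        if self.model_id.endswith("_fixed") and self.initial_norm != FIXED_INITIAL_NORM:
            raise ValueError(
                f"{self.model_id} pins initial_norm at {FIXED_INITIAL_NORM}"
            )
        for name in ("alpha", "beta"):
            lo, hi = DEFAULT_BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        lo, hi = DEFAULT_BOUNDS["initial_norm"]
        if not lo <= self.initial_norm <= hi:
            raise ValueError(f"initial_norm must be in [{lo}, {hi}]")

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "initial_norm": self.initial_norm,
        }
        if self.epsilon is not None:
            d["epsilon"] = self.epsilon
        return d

    @classmethod
    def from_vector(cls, model_id: str, vec: Sequence[float]) -> "AgentParams":
        """Build from the free-parameter vector in :func:`free_param_names` order."""
        names = free_param_names(model_id)
        if len(vec) != len(names):
            raise ValueError(f"{model_id} takes {len(names)} parameters, got {len(vec)}")
        kw = dict(zip(names, (float(v) for v in vec)))
        return cls(model_id=model_id, **kw)

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in free_param_names(self.model_id)])


@dataclass(frozen=True)
class BayesObserverState:
    """Normal-Inverse-chi-squared hyperparameters of the Bayesian observer.

    ``k`` is the pseudo-count on the mean, ``nu`` the degrees of freedom
    on the variance, ``mu_hat`` the current norm estimate (tokens) and
    ``sigma2_hat`` the variance estimate (tokens squared).
    """

    k: float = BO_K0
    nu: float = BO_NU0
    mu_hat: float = FIXED_INITIAL_NORM
    sigma2_hat: float = BO_SIGMA2_0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.nu <= 0 or self.sigma2_hat <= 0:
            raise ValueError("k, nu and sigma2_hat must be strictly positive")


def fs_utility(offer, norm, alpha: float, beta: float):
    """Inequity-averse utility U = s - a*max(x-s,0) - b*max(s-x,0).

    Vectorized over ``offer``/``norm``.  At most one penalty term is
    nonzero for any (offer, norm) pair.
    """
    offer = np.asarray(offer, dtype=float)
    norm = np.asarray(norm, dtype=float)
    out = (
        offer
        - alpha * np.maximum(norm - offer, 0.0)
        - beta * np.maximum(offer - norm, 0.0)
    )
    return out if out.ndim else float(out)


def p_accept(utility, gamma: float):
    """Softmax (logistic) acceptance probability of an offer.

    Returns logistic(gamma * U), clamped into
    ``[PROB_EPS, 1 - PROB_EPS]`` so downstream log-likelihoods stay
    finite at saturating utilities.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    p = expit(gamma * np.asarray(utility, dtype=float))
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return p if p.ndim else float(p)


def rw_update(norm: float, offer: float, epsilon: float) -> float:
    """Rescorla-Wagner norm update x <- x + eps * (s - x)."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    return norm + epsilon * (offer - norm)


def bo_update(state: BayesObserverState, offer: float) -> BayesObserverState:
    """One conjugate Bayesian update of the observer after seeing an offer.

    k and nu increment by one; the norm estimate moves toward the offer
    with weight 1/k_t; the scaled variance accumulates the squared
    prediction error weighted by k_{t-1}/k_t.
    """
    k_new = state.k + 1.0
    nu_new = state.nu + 1.0
    err = offer - state.mu_hat
    mu_new = state.mu_hat + err / k_new
    sigma2_new = (state.nu * state.sigma2_hat + (state.k / k_new) * err * err) / nu_new
    return BayesObserverState(k=k_new, nu=nu_new, mu_hat=mu_new, sigma2_hat=sigma2_new)


# ---------------------------------------------------------------------------
# Norm trajectories
# ---------------------------------------------------------------------------

def _traj_constant(offers: np.ndarray, norm0: float) -> np.ndarray:
    return np.full(len(offers), norm0)


def _traj_rw(offers: np.ndarray, epsilon: float, norm0: float) -> np.ndarray:
    norms = np.empty(len(offers))
    x = float(norm0)
    eps = float(epsilon)
    for t, s in enumerate(offers):
        norms[t] = x
        x += eps * (s - x)
    return norms


def _traj_bo(offers: np.ndarray, norm0: float) -> np.ndarray:
    # Only mu_hat feeds the likelihood; the variance recursion is tracked
    # by bo_update when the full state is needed.
    norms = np.empty(len(offers))
    mu = float(norm0)
    k = BO_K0
    for t, s in enumerate(offers):
        norms[t] = mu
        k += 1.0
        mu += (s - mu) / k
    return norms


def norm_trajectory(params: AgentParams, offers) -> np.ndarray:
    """Per-trial prevailing norm used to evaluate each offer.

    Entry t is the norm *before* the update triggered by offer t; the
    update uses the offer only, never the choice, and is applied on every
    trial.  Entry 0 equals ``params.initial_norm``.
    """
    offers = _offers_array(offers)
    m = params.model_id
    if m.startswith("FS"):
        return _traj_constant(offers, params.initial_norm)
    if m.startswith("RW"):
        return _traj_rw(offers, params.epsilon, params.initial_norm)
    return _traj_bo(offers, params.initial_norm)


def _offers_array(offers) -> np.ndarray:
    if hasattr(offers, "offers"):  # OfferSchedule
        offers = offers.offers
    return np.asarray(offers, dtype=float)


def choices_to_accept(choices) -> np.ndarray:
    """Coerce a choice sequence to a boolean accepted-mask.

    Accepts booleans/0-1 integers (truthy = accept) or the strings /
    keyboard codes ``accept``/``1`` and ``reject``/``2``
    (case-insensitive).
    """
    arr = np.asarray(choices)
    if arr.dtype.kind in "bif":
        return arr.astype(bool)
    out = np.empty(arr.shape, dtype=bool)
    for i, c in enumerate(arr.ravel()):
        s = str(c).strip().lower()
        if s in ("accept", "1", "true"):
            out.ravel()[i] = True
        elif s in ("reject", "2", "false"):
            out.ravel()[i] = False
        else:
            raise ValueError(f"unrecognized choice code {c!r}")
    return out


def negative_log_likelihood(params: AgentParams, offers, choices) -> float:
    """Negative log-likelihood of a choice sequence under one model.

    ``-sum_t log P(choice_t)`` with the acceptance probability from
    :func:`p_accept` applied to :func:`fs_utility` at the trajectory
    norm.  Finite for all in-bound parameters thanks to the probability
    clamp.
    """
    offers = _offers_array(offers)
    accepted = choices_to_accept(choices)
    if len(offers) != len(accepted):
        raise ValueError(
            f"offers ({len(offers)}) and choices ({len(accepted)}) differ in length"
        )
    norms = norm_trajectory(params, offers)
    u = fs_utility(offers, norms, params.alpha, params.beta)
    p = np.clip(expit(params.gamma * u), PROB_EPS, 1.0 - PROB_EPS)
    ll = np.where(accepted, np.log(p), np.log1p(-p))
    return float(-ll.sum())
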