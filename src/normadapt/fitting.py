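"""Per-participant maximum-likelihood estimation and fit scoring.

Each responder's choice sequence is fitted independently per model by
bounded multi-start local optimization (L-BFGS-B) of the negative
log-likelihood; the default start set is one start at the bound
midpoints plus 10 uniform draws within the bounds, seed-controlled.
Fits are scored with BIC = k*ln(n) - 2*LL and AIC = 2k - 2*LL with n the
number of choice trials.

The estimator :class:`NormModelMLE` follows scikit-learn conventions
(``fit``/``predict_proba``/``score``, ``get_params``/``set_params``,
trailing-underscore fitted attributes); :func:`fit_participant` and
:func:`fit_cohort` are thin wrappers over it operating on tidy trial
logs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .models import (
    DEFAULT_BOUNDS,
    FIXED_INITIAL_NORM,
    MODEL_IDS,
    PROB_EPS,
    AgentParams,
    choices_to_accept,
    free_param_names,
    norm_trajectory,
    _offers_array,
    _traj_bo,
    _traj_constant,
    _traj_rw,
)

__all__ = [
    "FitResult",
    "OptimizerConfig",
    "NormModelMLE",
    "count_free_params",
    "fit_participant",
    "fit_cohort",
    "grid_search_nll",
]

_N_FREE = {
    "FS_fixed": 3,
    "FS_free": 4,
    "BO_fixed": 3,
    "BO_free": 4,
    "RW_fixed": 4,
    "RW_free": 5,
}


def count_free_params(model_id: str) -> int:
    """Number of fitted parameters: envy, guilt and temperature for all
    models, plus the learning rate for RW variants and the initial norm
    for ``*_free`` variants."""
    try:
        return _N_FREE[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def bic(log_likelihood: float, n_free: int, n_trials: int) -> float:
    return n_free * np.log(n_trials) - 2.0 * log_likelihood


def aic(log_likelihood: float, n_free: int) -> float:
    return 2.0 * n_free - 2.0 * log_likelihood


@dataclass(frozen=True)
class OptimizerConfig:
    """Multi-start optimizer settings (restart count, seed, NLL tolerance).

    ``n_probe`` cheap objective evaluations at uniform random points seed
    the restart pool: the best probes are promoted to additional local
    starts, which guards against the kinked, multimodal likelihood of
    the free-initial-norm models.
    """

    n_restarts: int = 10
    seed: int = 0
    tol: float = 1e-8
    gamma_bounds: tuple[float, float] = (0.0, 10.0)
    n_probe: int = 512

    def to_dict(self) -> dict:
        return {
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "tol": self.tol,
            "gamma_bounds": list(self.gamma_bounds),
            "n_probe": self.n_probe,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OptimizerConfig":
        gb = d.get("gamma_bounds", (0.0, 10.0))
        return cls(
            n_restarts=int(d.get("n_restarts", 10)),
            seed=int(d.get("seed", 0)),
            tol=float(d.get("tol", 1e-8)),
            gamma_bounds=(float(gb[0]), float(gb[1])),
            n_probe=int(d.get("n_probe", 512)),
        )


@dataclass(frozen=True)
class FitResult:
    """One participant x model maximum-likelihood fit."""

    participant_id: str
    model_id: str
    params: AgentParams
    log_likelihood: float
    n_free: int
    n_trials: int
    bic: float
    aic: float
    n_restarts_used: int
    converged: bool

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "model_id": self.model_id,
            "log_likelihood": self.log_likelihood,
            "n_free": self.n_free,
            "n_trials": self.n_trials,
            "bic": self.bic,
            "aic": self.aic,
            "n_restarts_used": self.n_restarts_used,
            "converged": self.converged,
        }
        row.update({f"param_{k}": v for k, v in self.params.to_dict().items()
                    if k != "model_id"})
        return row


def model_bounds(model_id: str,
                 gamma_bounds: tuple[float, float] = (0.0, 10.0)) -> list[tuple[float, float]]:
    """Box bounds for the free-parameter vector of a model."""
    out = []
    for name in free_param_names(model_id):
        out.append(tuple(gamma_bounds) if name == "gamma" else DEFAULT_BOUNDS[name])
    return out


def _nll_factory(model_id: str, offers: np.ndarray, accepted: np.ndarray):
    """Vectorized NLL objective over the free-parameter vector.

    Norm trajectories for FS/BO models with a pinned start do not depend
    on any free parameter and are hoisted out of the optimization loop.
    """
    offers = np.asarray(offers, dtype=float)
    acc = np.asarray(accepted, dtype=bool)
    sign = np.where(acc, 1.0, -1.0)  # log P(choice) = log expit(sign * g * U)

    def _nll_from_norms(theta, norms):
        a, b, g = theta[0], theta[1], theta[2]
        u = offers - a * np.maximum(norms - offers, 0.0) - b * np.maximum(offers - norms, 0.0)
        p = np.clip(expit(sign * g * u), PROB_EPS, 1.0 - PROB_EPS)
        return -np.log(p).sum()

    if model_id == "FS_fixed":
        norms = _traj_constant(offers, FIXED_INITIAL_NORM)
        return lambda th: _nll_from_norms(th, norms)
    if model_id == "FS_free":
        return lambda th: _nll_from_norms(th, _traj_constant(offers, th[3]))
    if model_id == "BO_fixed":
        norms = _traj_bo(offers, FIXED_INITIAL_NORM)
        return lambda th: _nll_from_norms(th, norms)
    if model_id == "BO_free":
        return lambda th: _nll_from_norms(th, _traj_bo(offers, th[3]))
    if model_id == "RW_fixed":
        return lambda th: _nll_from_norms(th, _traj_rw(offers, th[3], FIXED_INITIAL_NORM))
    if model_id == "RW_free":
        return lambda th: _nll_from_norms(th, _traj_rw(offers, th[3], th[4]))
    raise ValueError(f"unknown model_id {model_id!r}")


class NormModelMLE(BaseEstimator):
    """Maximum-likelihood estimator for one norm model on one responder.

    Parameters
    ----------
    model_id : str
        One of ``FS_fixed``, ``FS_free``, ``BO_fixed``, ``BO_free``,
        ``RW_fixed``, ``RW_free``.
    n_restarts : int
        Uniform random restarts within the bounds, in addition to one
        start at the bound midpoints.
    seed : int
        Seed for the restart draws.
    tol : float
        NLL convergence tolerance passed to the local optimizer.
    gamma_bounds : tuple of float
        Box bounds for the inverse temperature.
    extra_starts : sequence of vectors, optional
        Additional start points (e.g. a nested model's optimum).

    Attributes
    ----------
    params_ : AgentParams
        Fitted parameters.
    nll_, log_likelihood_ : float
        Best negative log-likelihood and its negation.
    bic_, aic_ : float
        Information criteria at the best fit.
    converged_ : bool
        Success flag of the winning local optimization.
    n_restarts_used_ : int
        Total number of starts actually run.
    """

    def __init__(
        self,
        model_id: str = "RW_fixed",
        n_restarts: int = 10,
        seed: int = 0,
        tol: float = 1e-8,
        gamma_bounds: tuple[float, float] = (0.0, 10.0),
        n_probe: int = 512,
        extra_starts=None,
    ):
        self.model_id = model_id
        self.n_restarts = n_restarts
        self.seed = seed
        self.tol = tol
        self.gamma_bounds = gamma_bounds
        self.n_probe = n_probe
        self.extra_starts = extra_starts

    def _starts(self, bounds: list[tuple[float, float]], objective) -> np.ndarray:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        rng = np.random.default_rng(self.seed)
        starts = [0.5 * (lo + hi)]
        if self.n_restarts > 0:
            starts.extend(lo + rng.random((self.n_restarts, len(bounds))) * (hi - lo))
        if self.n_probe > 0:
            probes = lo + rng.random((self.n_probe, len(bounds))) * (hi - lo)
            vals = np.array([objective(p) for p in probes])
            starts.extend(probes[np.argsort(vals)[: min(4, self.n_probe)]])
        if self.extra_starts is not None:
            for s in self.extra_starts:
                starts.append(np.clip(np.asarray(s, dtype=float), lo, hi))
        return np.asarray(starts)

    def fit(self, X, y):
        """Fit to one responder's offers ``X`` and choices ``y``.

        ``X`` is the offer sequence (1-d, or a single-column 2-d array or
        an OfferSchedule); ``y`` the per-trial choices (booleans, 0/1, or
        ``accept``/``reject`` strings).
        """
        offers = _offers_array(X)
        if offers.ndim == 2 and offers.shape[1] == 1:
            offers = offers[:, 0]
        if offers.ndim != 1:
            raise ValueError("X must be a 1-d offer sequence")
        accepted = choices_to_accept(y)
        if len(accepted) != len(offers):
            raise ValueError("offers and choices differ in length")
        if len(offers) == 0:
            raise ValueError("at least one choice trial is required")
        count_free_params(self.model_id)  # validates model_id

        bounds = model_bounds(self.model_id, tuple(self.gamma_bounds))
        objective = _nll_factory(self.model_id, offers, accepted)
        best = None
        n_used = 0
        for x0 in self._starts(bounds, objective):
            res = minimize(
                objective, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": self.tol, "maxiter": 500},
            )
            n_used += 1
            if best is None or res.fun < best.fun - 0.0:
                best = res
        theta = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
        self.params_ = AgentParams.from_vector(self.model_id, theta)
        self.nll_ = float(best.fun)
        self.log_likelihood_ = -self.nll_
        self.n_free_ = count_free_params(self.model_id)
        self.n_trials_ = len(offers)
        self.bic_ = bic(self.log_likelihood_, self.n_free_, self.n_trials_)
        self.aic_ = aic(self.log_likelihood_, self.n_free_)
        self.converged_ = bool(best.success)
        self.n_restarts_used_ = n_used
        self.classes_ = np.array(["accept", "reject"])
        return self

    def predict_proba(self, X):
        """Per-trial [P(accept), P(reject)] under the fitted parameters.

        The norm trajectory is recomputed from trial 1 of ``X``.
        """
        check_is_fitted(self, "params_")
        offers = _offers_array(X)
        if offers.ndim == 2 and offers.shape[1] == 1:
            offers = offers[:, 0]
        norms = norm_trajectory(self.params_, offers)
        u = (
            offers
            - self.params_.alpha * np.maximum(norms - offers, 0.0)
            - self.params_.beta * np.maximum(offers - norms, 0.0)
        )
        p = np.clip(expit(self.params_.gamma * u), PROB_EPS, 1.0 - PROB_EPS)
        return np.column_stack([p, 1.0 - p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 0]
        return np.where(p >= 0.5, "accept", "reject")

    def score(self, X, y):
        """Mean per-trial log-likelihood of choices ``y``."""
        p_acc = self.predict_proba(X)[:, 0]
        accepted = choices_to_accept(y)
        ll = np.where(accepted, np.log(p_acc), np.log1p(-p_acc))
        return float(ll.mean())


def fit_participant(
    records: pd.DataFrame,
    model_id: str,
    config: OptimizerConfig | None = None,
    extra_starts=None,
) -> FitResult:
    """Fit one model to one participant's trial log (tidy rows)."""
    config = config or OptimizerConfig()
    records = records.dropna(subset=["choice"])
    if len(records) == 0:
        raise ValueError("participant has no choice trials")
    pid = str(records["participant_id"].iloc[0]) if "participant_id" in records else "p01"
    est = NormModelMLE(
        model_id=model_id,
        n_restarts=config.n_restarts,
        seed=config.seed,
        tol=config.tol,
        gamma_bounds=config.gamma_bounds,
        n_probe=config.n_probe,
        extra_starts=extra_starts,
    )
    est.fit(records["offer"].to_numpy(dtype=float), records["choice"].to_numpy())
    return FitResult(
        participant_id=pid,
        model_id=model_id,
        params=est.params_,
        log_likelihood=est.log_likelihood_,
        n_free=est.n_free_,
        n_trials=est.n_trials_,
        bic=est.bic_,
        aic=est.aic_,
        n_restarts_used=est.n_restarts_used_,
        converged=est.converged_,
    )


def _nested_start(fixed: FitResult, free_model: str) -> np.ndarray:
    """Start vector for a free-initial-norm model at its fixed sibling's optimum."""
    vec = list(fixed.params.to_vector())
    vec.append(FIXED_INITIAL_NORM)
    return np.asarray(vec)


_FIXED_SIBLING = {"FS_free": "FS_fixed", "BO_free": "BO_fixed", "RW_free": "RW_fixed"}


def fit_cohort(
    dataset: pd.DataFrame,
    model_ids=MODEL_IDS,
    config: OptimizerConfig | None = None,
) -> pd.DataFrame:
    """Fit every requested model to every participant.

    Returns one row per (participant, model) with scores and fitted
    parameters.  When a ``*_free`` model is requested together with its
    ``*_fixed`` sibling, the sibling's optimum (with initial norm 10) is
    added as an extra start so the nested model never fits worse.
    """
    config = config or OptimizerConfig()
    model_ids = list(model_ids)
    for m in model_ids:
        count_free_params(m)
    # fixed variants first so their optima can warm-start the free ones
    ordered = sorted(model_ids, key=lambda m: m.endswith("_free"))
    rows = []
    for pid, grp in dataset.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial")
        fixed_fits: dict[str, FitResult] = {}
        for m in ordered:
            extra = None
            sib = _FIXED_SIBLING.get(m)
            if sib in fixed_fits:
                extra = [_nested_start(fixed_fits[sib], m)]
            try:
                fr = fit_participant(grp, m, config, extra_starts=extra)
            except Exception as exc:  # pragma: no cover - context for caller
                raise RuntimeError(f"fitting {m} for participant {pid!r} failed") from exc
            if m.endswith("_fixed"):
                fixed_fits[m] = fr
            rows.append(fr.to_row())
    df = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(model_ids)}
    return (
        df.sort_values(["participant_id", "model_id"],
                       key=lambda s: s.map(order) if s.name == "model_id" else s)
        .reset_index(drop=True)
    )


def grid_search_nll(
    records: pd.DataFrame,
    model_id: str,
    n_points: int = 11,
    gamma_bounds: tuple[float, float] = (0.0, 10.0),
) -> float:
    """Best NLL on a coarse full-factorial parameter grid.

    A brute-force reference for optimizer quality: ``n_points`` evenly
    spaced values per free parameter, every combination evaluated.
    Vectorized over the (alpha, beta, gamma) axes.
    """
    records = records.dropna(subset=["choice"]).sort_values("trial")
    offers = records["offer"].to_numpy(dtype=float)
    accepted = choices_to_accept(records["choice"].to_numpy())
    sign = np.where(accepted, 1.0, -1.0)

    bounds = dict(zip(free_param_names(model_id), model_bounds(model_id, gamma_bounds)))
    axes = {k: np.linspace(lo, hi, n_points) for k, (lo, hi) in bounds.items()}

    # trajectory-shaping parameters (epsilon and/or initial_norm)
    traj_names = [n for n in ("epsilon", "initial_norm") if n in axes]
    traj_combos = list(itertools.product(*(axes[n] for n in traj_names))) or [()]

    a = axes["alpha"][:, None, None, None]  # (A,1,1,1)
    b = axes["beta"][None, :, None, None]   # (1,B,1,1)
    g = axes["gamma"][None, None, :, None]  # (1,1,G,1)
    best = np.inf
    for combo in traj_combos:
        kw = dict(zip(traj_names, combo))
        if model_id.startswith("FS"):
            norms = _traj_constant(offers, kw.get("initial_norm", FIXED_INITIAL_NORM))
        elif model_id.startswith("BO"):
            norms = _traj_bo(offers, kw.get("initial_norm", FIXED_INITIAL_NORM))
        else:
            norms = _traj_rw(offers, kw["epsilon"], kw.get("initial_norm", FIXED_INITIAL_NORM))
        under = np.maximum(norms - offers, 0.0)
        over = np.maximum(offers - norms, 0.0)
        u = offers - a * under - b * over          # (A,B,1,T)
        p = np.clip(expit(sign * (g * u)), PROB_EPS, 1.0 - PROB_EPS)  # (A,B,G,T)
        nll = -np.log(p).sum(axis=-1)
        m = float(nll.min())
        if m < best:
            best = m
    return best
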