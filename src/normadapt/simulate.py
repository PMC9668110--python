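"""Synthetic responders, ratings and study-like cohorts.

Everything downstream (fitting, model comparison, behavioral statistics)
is exercised on cohorts generated here, emulating the study conditions:
30 responders, 60 trials in 20/20/20 baseline / conditioning / post
blocks, offers from N(8, 1.5) / N(4, 1.5) rounded to integer tokens of a
20-token endowment, ratings prompted on ~67% of trials, and choices
generated by one of the candidate norm models with parameters sampled
around the fitted-moment defaults (envy 2.58, guilt 0.17, temperature
1.78, learning rate 0.16).

The rating generator is synthetic plumbing: a linear-in-offer 1-9 scale
response with Gaussian noise, present only so the rating analysis has
something to run on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import AgentParams, MODEL_IDS, fs_utility, norm_trajectory, p_accept
from .task import OfferSchedule, TaskConfig, make_schedule

__all__ = [
    "ParamDist",
    "CohortSpec",
    "simulate_agent",
    "simulate_ratings",
    "simulate_cohort",
    "default_param_sampler",
]

TRIAL_COLUMNS = [
    "participant_id",
    "trial",
    "block",
    "offer",
    "choice",
    "rating",
    "norm_at_trial",
]


@dataclass(frozen=True)
class ParamDist:
    """Truncated-Gaussian sampling spec for one model parameter."""

    mean: float
    sd: float
    low: float
    high: float

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.low, self.high))
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return float(
            stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng)
        )


def default_param_sampler(model_id: str) -> dict[str, ParamDist]:
    """Per-parameter truncated Gaussians at the fitted-moment defaults.

    Means/SDs: envy 2.58/2.53, guilt 0.17/0.32, temperature 1.78/1.58,
    learning rate 0.16/0.28, each truncated to the parameter's bounds.
    Free-initial-norm variants sample the initial norm around the equal
    split (10 tokens, SD 2.5) — no population moment is reported for it.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    sampler = {
        "alpha": ParamDist(2.58, 2.53, 0.0, 10.0),
        "beta": ParamDist(0.17, 0.32, 0.0, 10.0),
        "gamma": ParamDist(1.78, 1.58, 0.0, 10.0),
    }
    if model_id.startswith("RW"):
        sampler["epsilon"] = ParamDist(0.16, 0.28, 0.0, 1.0)
    if model_id.endswith("_free"):
        sampler["initial_norm"] = ParamDist(10.0, 2.5, 0.0, 20.0)
    return sampler


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one simulated cohort."""

    n_participants: int = 30
    model_id: str = "RW_fixed"
    param_sampler: dict[str, ParamDist] | None = None
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")

    def sampler(self) -> dict[str, ParamDist]:
        return self.param_sampler or default_param_sampler(self.model_id)


def sample_params(spec_sampler: dict[str, ParamDist], model_id: str,
                  rng: np.random.Generator) -> AgentParams:
    """Draw one in-bounds AgentParams from a per-parameter sampler."""
    kw = {name: dist.sample(rng) for name, dist in spec_sampler.items()}
    if model_id.endswith("_fixed"):
        kw.pop("initial_norm", None)
    if not model_id.startswith("RW"):
        kw.pop("epsilon", None)
    return AgentParams(model_id=model_id, **kw)


def simulate_agent(
    params: AgentParams,
    schedule: OfferSchedule,
    seed: int | np.random.Generator,
    participant_id: str = "p01",
) -> pd.DataFrame:
    """Simulate one responder's choices on a schedule.

    Each choice is Bernoulli with the model's acceptance probability at
    the prevailing norm; the norm then updates from the offer (never the
    choice).  The pre-update norm is logged as ``norm_at_trial``.
    Ratings are left missing; see :func:`simulate_ratings`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offers = schedule.offers.astype(float)
    norms = norm_trajectory(params, offers)
    u = fs_utility(offers, norms, params.alpha, params.beta)
    p = np.asarray(p_accept(u, params.gamma))
    accepted = rng.random(len(offers)) < p
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial": np.arange(1, schedule.n_trials + 1),
            "block": schedule.block_labels,
            "offer": schedule.offers,
            "choice": np.where(accepted, "accept", "reject"),
            "rating": pd.array([pd.NA] * schedule.n_trials, dtype="Int64"),
            "norm_at_trial": norms,
        }
    )


def simulate_ratings(
    records: pd.DataFrame,
    rating_flags: np.ndarray,
    seed: int | np.random.Generator,
    slope: float = 0.6,
    intercept: float = 1.0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Fill 1-9 emotion ratings on flagged trials of one participant's log.

    rating = clip(round(intercept + slope*offer + N(0, noise_sd)), 1, 9).
    Synthetic by construction — the generating study collects ratings but
    implies no generative model for them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = records.copy()
    flags = np.asarray(rating_flags, dtype=bool)
    if len(flags) != len(records):
        raise ValueError("rating_flags length must match records")
    noise = rng.normal(0.0, noise_sd, size=len(records)) if noise_sd > 0 else 0.0
    raw = intercept + slope * records["offer"].to_numpy(dtype=float) + noise
    vals = np.clip(np.floor(raw + 0.5), 1, 9).astype(int)
    ratings = pd.array([pd.NA] * len(records), dtype="Int64")
    ratings[flags] = vals[flags]
    records["rating"] = ratings
    return records


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort of independent responders.

    Each participant gets independently sampled parameters and a freshly
    sampled offer schedule.  Returns ``(trials, truth)``: the tidy
    trial-level log and the true-parameter table keyed by
    ``participant_id`` (for recovery studies).
    """
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(spec.n_participants)
    sampler = spec.sampler()
    width = max(2, len(str(spec.n_participants)))
    all_trials: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"p{i + 1:0{width}d}"
        params = sample_params(sampler, spec.model_id, rng)
        schedule = make_schedule(spec.task, rng)
        rec = simulate_agent(params, schedule, rng, participant_id=pid)
        rec = simulate_ratings(rec, schedule.rating_flags, rng)
        all_trials.append(rec)
        row = {"participant_id": pid, **params.to_dict()}
        truth_rows.append(row)
    trials = pd.concat(all_trials, ignore_index=True)[TRIAL_COLUMNS]
    truth = pd.DataFrame(truth_rows)
    return trials, truth
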