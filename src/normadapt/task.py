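"""Offer-schedule generation for the conditioning Ultimatum Game.

The task is a three-block responder-side Ultimatum Game: a 20-trial
baseline block of "medium" offers, a 20-trial conditioning block of
"low" offers, and a 20-trial post-conditioning block of medium offers
again.  Offers are integer token splits of a 20-token endowment, drawn
per block from a Gaussian distribution (medium: mean 8, SD 1.5; low:
mean 4, SD 1.5), rounded to the nearest integer and clipped into the
valid range.  After a random subset of offers (default 67%) the
responder is prompted for a 1-9 emotion rating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OfferDistribution",
    "BlockSpec",
    "TaskConfig",
    "OfferSchedule",
    "make_schedule",
    "default_task",
]

#: canonical block labels, in session order
BLOCK_LABELS = ("baseline", "conditioning", "post")


class ConfigError(ValueError):
    """Raised for invalid task configurations."""


@dataclass(frozen=True)
class OfferDistribution:
    """Gaussian offer distribution in token units (before discretization)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError(f"offer distribution sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class BlockSpec:
    """One contiguous block of the session."""

    label: str
    n_trials: int
    distribution: OfferDistribution

    def __post_init__(self) -> None:
        if self.label not in BLOCK_LABELS:
            raise ConfigError(
                f"block label must be one of {BLOCK_LABELS}, got {self.label!r}"
            )
        if self.n_trials < 1:
            raise ConfigError(f"block n_trials must be >= 1, got {self.n_trials}")


def _default_blocks() -> tuple[BlockSpec, ...]:
    medium = OfferDistribution(mean=8.0, sd=1.5)
    low = OfferDistribution(mean=4.0, sd=1.5)
    return (
        BlockSpec("baseline", 20, medium),
        BlockSpec("conditioning", 20, low),
        BlockSpec("post", 20, medium),
    )


@dataclass(frozen=True)
class TaskConfig:
    """Design of one session of the conditioning Ultimatum Game.

    Parameters
    ----------
    endowment : int
        Tokens the proposer splits each trial (default 20).
    blocks : tuple of BlockSpec
        Ordered blocks; the default is the 20/20/20 baseline /
        conditioning / post design.
    rating_probability : float
        Per-trial probability of an emotion-rating prompt (default 0.67).
    offer_min, offer_max : int
        Clip range for discretized offers; defaults 0 and ``endowment``.
    """

    endowment: int = 20
    blocks: tuple[BlockSpec, ...] = field(default_factory=_default_blocks)
    rating_probability: float = 0.67
    offer_min: int = 0
    offer_max: int | None = None

    def __post_init__(self) -> None:
        if self.endowment < 1:
            raise ConfigError(f"endowment must be >= 1, got {self.endowment}")
        if not self.blocks:
            raise ConfigError("at least one block is required")
        if not 0.0 <= self.rating_probability <= 1.0:
            raise ConfigError(
                f"rating_probability must be in [0, 1], got {self.rating_probability}"
            )
        omax = self.endowment if self.offer_max is None else self.offer_max
        if not 0 <= self.offer_min <= omax <= self.endowment:
            raise ConfigError(
                f"need 0 <= offer_min <= offer_max <= endowment, got "
                f"[{self.offer_min}, {omax}] with endowment {self.endowment}"
            )
        for b in self.blocks:
            if not 0 <= b.distribution.mean <= self.endowment:
                raise ConfigError(
                    f"block {b.label!r} mean {b.distribution.mean} outside "
                    f"[0, {self.endowment}]"
                )

    @property
    def clip_max(self) -> int:
        return self.endowment if self.offer_max is None else self.offer_max

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    # ---- JSON round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "endowment": self.endowment,
            "blocks": [
                {
                    "label": b.label,
                    "n_trials": b.n_trials,
                    "mean": b.distribution.mean,
                    "sd": b.distribution.sd,
                }
                for b in self.blocks
            ],
            "rating_probability": self.rating_probability,
            "offer_min": self.offer_min,
            "offer_max": self.clip_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        blocks = tuple(
            BlockSpec(b["label"], int(b["n_trials"]), OfferDistribution(b["mean"], b["sd"]))
            for b in d.get("blocks", [])
        ) or _default_blocks()
        return cls(
            endowment=int(d.get("endowment", 20)),
            blocks=blocks,
            rating_probability=float(d.get("rating_probability", 0.67)),
            offer_min=int(d.get("offer_min", 0)),
            offer_max=d.get("offer_max"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TaskConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_task() -> TaskConfig:
    """The study design: 20/20/20 blocks, N(8,1.5)/N(4,1.5)/N(8,1.5)."""
    return TaskConfig()


@dataclass(frozen=True)
class OfferSchedule:
    """A realized sequence of offers with block labels and rating prompts."""

    offers: np.ndarray  # int tokens, shape (n_trials,)
    block_labels: np.ndarray  # str labels, shape (n_trials,)
    rating_flags: np.ndarray  # bool, shape (n_trials,)

    def __post_init__(self) -> None:
        n = len(self.offers)
        if len(self.block_labels) != n or len(self.rating_flags) != n:
            raise ConfigError("schedule arrays must have equal length")

    @property
    def n_trials(self) -> int:
        return len(self.offers)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: trial (1-based), block, offer, rating_flag."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "block": self.block_labels,
                "offer": self.offers,
                "rating_flag": self.rating_flags.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OfferSchedule":
        df = pd.read_csv(path, comment="#")
        expected = np.arange(1, len(df) + 1)
        if not np.array_equal(df["trial"].to_numpy(), expected):
            raise ConfigError("schedule trial indices must be 1..n in order")
        return cls(
            offers=df["offer"].to_numpy(dtype=int),
            block_labels=df["block"].to_numpy(dtype=object),
            rating_flags=df["rating_flag"].to_numpy(dtype=bool),
        )


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer, halves away from zero (symmetric around means)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def sample_offers(
    dist: OfferDistribution,
    n: int,
    rng: np.random.Generator,
    offer_min: int = 0,
    offer_max: int = 20,
) -> np.ndarray:
    """Draw ``n`` integer offers: Gaussian draws, rounded then clipped."""
    raw = rng.normal(dist.mean, dist.sd, size=n)
    return np.clip(round_half_away(raw), offer_min, offer_max).astype(int)


def make_schedule(config: TaskConfig, seed: int | np.random.Generator) -> OfferSchedule:
    """Generate one seeded session schedule from a task design.

    Offers are drawn block by block from the block's Gaussian, rounded
    half-away-from-zero to integer tokens and clipped into
    ``[offer_min, offer_max]``.  Rating prompts are independent
    Bernoulli(``rating_probability``) per trial.  Equal ``(config, seed)``
    pairs yield identical schedules.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offers: list[np.ndarray] = []
    labels: list[str] = []
    for b in config.blocks:
        offers.append(
            sample_offers(b.distribution, b.n_trials, rng, config.offer_min, config.clip_max)
        )
        labels.extend([b.label] * b.n_trials)
    flags = rng.random(config.n_trials) < config.rating_probability
    return OfferSchedule(
        offers=np.concatenate(offers),
        block_labels=np.asarray(labels, dtype=object),
        rating_flags=flags,
    )
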