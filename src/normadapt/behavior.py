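"""Model-free behavioral analyses of conditioning Ultimatum Game logs.

Covers the standard analysis battery for the paradigm: per-block (and
per offer-size) rejection rates, sliding-window rejection curves, paired
pre/post contrasts with Cohen's d, Benjamini-Hochberg FDR correction,
a mixed-effects logistic regression of choice on offer size, and the
pre/post emotion-rating contrast.

Direction convention: contrasts are reported as post minus baseline, so
a decrease in rejection rate yields a negative t; Cohen's d is reported
as a magnitude (|t|/sqrt(n)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "BlockStats",
    "PairedTestResult",
    "BHResult",
    "OfferRegressionResult",
    "block_stats",
    "rejection_rates",
    "sliding_rejection",
    "paired_contrast",
    "bh_correct",
    "offer_size_regression",
    "rating_contrast",
    "per_offer_contrasts",
]


def _reject_mask(records: pd.DataFrame) -> pd.Series:
    from .models import choices_to_accept

    return pd.Series(~choices_to_accept(records["choice"].to_numpy()),
                     index=records.index, name="rejected")


def rejection_rates(records: pd.DataFrame, grouping: str = "block") -> pd.DataFrame:
    """Per-participant percent rejections within each group.

    ``grouping`` is ``"block"`` or ``"block_offer"``.  Empty cells are
    simply absent (never 0/0).
    """
    keys = {"block": ["participant_id", "block"],
            "block_offer": ["participant_id", "block", "offer"]}
    if grouping not in keys:
        raise ValueError(f"grouping must be one of {sorted(keys)}, got {grouping!r}")
    df = records.copy()
    df["rejected"] = _reject_mask(df)
    out = (
        df.groupby(keys[grouping], sort=True, observed=True)["rejected"]
        .agg(rejection_rate=lambda s: 100.0 * s.mean(), n_trials="size")
        .reset_index()
    )
    return out


@dataclass(frozen=True)
class BlockStats:
    """Per-participant block summaries: rejection rates and rating means."""

    by_block: pd.DataFrame
    by_block_offer: pd.DataFrame
    rating_means: pd.DataFrame


def block_stats(records: pd.DataFrame) -> BlockStats:
    rated = records.dropna(subset=["rating"])
    rating_means = (
        rated.groupby(["participant_id", "block"], sort=True)["rating"]
        .mean()
        .rename("rating_mean")
        .reset_index()
    )
    return BlockStats(
        by_block=rejection_rates(records, "block"),
        by_block_offer=rejection_rates(records, "block_offer"),
        rating_means=rating_means,
    )


def sliding_rejection(records: pd.DataFrame, window: int = 5) -> pd.Series:
    """Mean rejection (%) in a trailing window, averaged across participants.

    The window ends at trial t and is defined for t >= window, so a
    session of n trials yields a curve of length n - window + 1.
    """
    n_trials = int(records["trial"].max())
    if window < 1 or window > n_trials:
        raise ValueError(f"window must be in [1, {n_trials}], got {window}")
    df = records.copy()
    df["rejected"] = _reject_mask(df).astype(float)
    wide = df.pivot(index="trial", columns="participant_id", values="rejected").sort_index()
    rolled = wide.rolling(window).mean().dropna(how="all")
    curve = 100.0 * rolled.mean(axis=1)
    curve.name = f"rejection_rate_w{window}"
    return curve


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired t-test with Cohen's d = |t|/sqrt(n)."""

    t: float
    df: int
    p: float
    mean_diff: float
    sem_diff: float
    cohens_d: float
    ci_d: tuple[float, float] | None
    n: int

    def to_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p,
            "mean_diff": self.mean_diff, "sem_diff": self.sem_diff,
            "cohens_d": self.cohens_d,
            "ci_d": list(self.ci_d) if self.ci_d is not None else None,
            "n": self.n,
        }


def _d_confidence_interval(t_obs: float, n: int, level: float = 0.95):
    """CI for d via inversion of the noncentral t distribution."""
    df = n - 1
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2

    def solve(target):
        f = lambda nc: stats.nct.cdf(t_obs, df, nc) - target
        lo, hi = t_obs - 40, t_obs + 40
        if f(lo) * f(hi) > 0:
            raise RuntimeError("noncentrality bracket failed")
        return brentq(f, lo, hi, xtol=1e-8)

    try:
        nc_lo, nc_hi = solve(lo_q), solve(hi_q)
    except Exception:
        return None
    return (nc_lo / np.sqrt(n), nc_hi / np.sqrt(n))


def paired_contrast(pre, post) -> PairedTestResult:
    """Paired t-test of post vs. pre (diff = post - pre), two-tailed.

    Zero-variance differences: t is 0 when the vectors are identical and
    undefined (NaN, flagged by a warning) for a constant nonzero shift.
    The CI of d uses the noncentral-t inversion on |t|.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-d vectors")
    n = len(pre)
    if n < 2:
        raise ValueError("paired contrast requires n >= 2")
    diff = post - pre
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    sem = sd_diff / np.sqrt(n)
    df = n - 1
    if sd_diff == 0.0:
        if mean_diff == 0.0:
            return PairedTestResult(0.0, df, 1.0, 0.0, 0.0, 0.0, (0.0, 0.0), n)
        warnings.warn("zero variance of paired differences: t undefined")
        return PairedTestResult(np.nan, df, np.nan, mean_diff, 0.0, np.nan, None, n)
    t = mean_diff / sem
    p = 2.0 * stats.t.sf(abs(t), df)
    d = abs(t) / np.sqrt(n)
    ci = _d_confidence_interval(abs(t), n)
    return PairedTestResult(float(t), df, float(p), mean_diff, float(sem), float(d), ci, n)


@dataclass(frozen=True)
class BHResult:
    """Benjamini-Hochberg step-up FDR correction at level q."""

    p_sorted: np.ndarray
    ranks: np.ndarray
    critical_values: np.ndarray
    cutoff_p: float | None
    significant: np.ndarray  # in the original input order
    q: float

    def to_dict(self) -> dict:
        return {
            "p_sorted": self.p_sorted.tolist(),
            "ranks": self.ranks.tolist(),
            "critical_values": self.critical_values.tolist(),
            "cutoff_p": self.cutoff_p,
            "significant": self.significant.tolist(),
            "q": self.q,
        }


def bh_correct(p_values, q: float = 0.05) -> BHResult:
    """The five-step Benjamini-Hochberg procedure.

    1) order the p-values ascending; 2) assign ranks 1..m; 3) compute the
    critical value (rank/m)*q for each; 4) the cutoff is the largest
    p-value smaller than its critical value; 5) every p-value at or below
    the cutoff is significant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    m = p.size
    ranks = np.arange(1, m + 1)
    crit = ranks / m * q
    below = p_sorted < crit
    if below.any():
        cutoff = float(p_sorted[np.nonzero(below)[0].max()])
        significant = p <= cutoff
    else:
        cutoff = None
        significant = np.zeros(m, dtype=bool)
    return BHResult(p_sorted, ranks, crit, cutoff, significant, q)


@dataclass(frozen=True)
class OfferRegressionResult:
    """Logistic regression of rejection on offer size.

    The predictor is coded per token *decrease* (negated offer), so the
    coefficient is the increase in log-odds of rejection for each token
    less offered and the odds ratio is >= 1 for offer-monotone
    responders.
    """

    coefficient: float
    se: float
    z: float
    p: float
    ci: tuple[float, float]
    odds_ratio: float
    or_ci: tuple[float, float]
    method: str  # "mixed_vb" or "pooled_cluster"
    coding: str = "log-odds of rejection per token decrease in offer"

    def to_dict(self) -> dict:
        return {
            "coefficient": self.coefficient, "se": self.se, "z": self.z,
            "p": self.p, "ci": list(self.ci), "odds_ratio": self.odds_ratio,
            "or_ci": list(self.or_ci), "method": self.method, "coding": self.coding,
        }


def offer_size_regression(records: pd.DataFrame) -> OfferRegressionResult:
    """Mixed-effects logistic regression of reject/accept on offer size.

    Random intercept and random offer slope per participant, fitted by
    the variational Bayes mixed GLM; falls back to a pooled logistic
    with participant-clustered standard errors (with a logged warning)
    if the mixed fit fails.
    """
    import statsmodels.api as sm
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    df = records.copy()
    if df["participant_id"].nunique() < 2:
        raise ValueError("offer-size regression requires >= 2 participants")
    df["rejected"] = _reject_mask(df).astype(int)
    if df["rejected"].nunique() < 2:
        raise ValueError("single-outcome data: choices are completely separated")
    df["neg_offer"] = -df["offer"].astype(float)

    coef = se = None
    method = "mixed_vb"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM.from_formula(
                "rejected ~ neg_offer",
                {"icpt": "0 + C(participant_id)",
                 "slope": "0 + C(participant_id):neg_offer"},
                df,
            )
            # deterministic VB start (the default start is drawn from the
            # global RNG, which would make repeated runs differ)
            n_par = model.k_fep + model.k_vcp + model.k_vc
            fit = model.fit_vb(mean=np.zeros(n_par), sd=np.full(n_par, -0.5))
        idx = list(fit.model.exog_names).index("neg_offer")
        coef = float(fit.fe_mean[idx])
        se = float(fit.fe_sd[idx])
        if not np.isfinite(coef) or not np.isfinite(se) or se <= 0:
            raise RuntimeError("non-finite mixed-model estimate")
    except Exception as exc:
        logger.warning("mixed logistic fit failed (%s); falling back to "
                       "participant-clustered pooled logistic", exc)
        method = "pooled_cluster"
        X = sm.add_constant(df[["neg_offer"]])
        glm = sm.GLM(df["rejected"], X, family=sm.families.Binomial())
        fit = glm.fit(cov_type="cluster",
                      cov_kwds={"groups": df["participant_id"].to_numpy()})
        coef = float(fit.params["neg_offer"])
        se = float(fit.bse["neg_offer"])

    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    ci = (coef - 1.959963984540054 * se, coef + 1.959963984540054 * se)
    return OfferRegressionResult(
        coefficient=coef, se=se, z=float(z), p=float(p), ci=ci,
        odds_ratio=float(np.exp(coef)),
        or_ci=(float(np.exp(ci[0])), float(np.exp(ci[1]))),
        method=method,
    )


def _paired_block_values(per_block: pd.DataFrame, value: str,
                         pre_block: str = "baseline", post_block: str = "post"):
    wide = per_block.pivot(index="participant_id", columns="block", values=value)
    missing = [b for b in (pre_block, post_block) if b not in wide.columns]
    if missing:
        raise ValueError(f"blocks absent from data: {missing}")
    wide = wide[[pre_block, post_block]].dropna()
    return wide[pre_block].to_numpy(), wide[post_block].to_numpy(), wide.index


def rejection_contrast(records: pd.DataFrame) -> PairedTestResult:
    """Baseline vs post-conditioning contrast of per-participant rejection rates."""
    rates = rejection_rates(records, "block")
    pre, post, _ = _paired_block_values(rates, "rejection_rate")
    return paired_contrast(pre, post)


def per_offer_contrasts(records: pd.DataFrame, q: float = 0.05):
    """Baseline vs post contrast per offer size, BH-corrected.

    A participant enters an offer size's contrast only if that size
    occurs for them in both blocks.  Returns ``(table, BHResult)`` with
    the table ordered by offer size.
    """
    rates = rejection_rates(records, "block_offer")
    rows = []
    for offer, grp in rates.groupby("offer"):
        try:
            pre, post, idx = _paired_block_values(grp, "rejection_rate")
        except ValueError:
            continue
        if len(pre) < 2:
            continue
        res = paired_contrast(pre, post)
        if np.isnan(res.p):
            continue
        rows.append({"offer": int(offer), "n": res.n, "t": res.t, "p": res.p,
                     "cohens_d": res.cohens_d, "mean_diff": res.mean_diff})
    if not rows:
        raise ValueError("no offer size occurs in both blocks for >= 2 participants")
    table = pd.DataFrame(rows).sort_values("offer").reset_index(drop=True)
    bh = bh_correct(table["p"].to_numpy(), q=q)
    table["significant"] = bh.significant
    return table, bh


def rating_contrast(records: pd.DataFrame) -> PairedTestResult:
    """Baseline vs post contrast of per-participant mean emotion ratings.

    Participants without ratings in either block are excluded; the
    exclusion count is logged.
    """
    rated = records.dropna(subset=["rating"])
    if rated.empty:
        raise ValueError("no ratings present")
    means = (
        rated.groupby(["participant_id", "block"], sort=True)["rating"]
        .mean()
        .rename("rating_mean")
        .reset_index()
    )
    n_all = records["participant_id"].nunique()
    pre, post, idx = _paired_block_values(means, "rating_mean")
    n_excluded = n_all - len(idx)
    if n_excluded:
        logger.info("rating contrast: excluded %d participant(s) lacking "
                    "ratings in a block", n_excluded)
    return paired_contrast(pre, post)


def behavior_report(records: pd.DataFrame, q: float = 0.05, window: int = 5) -> dict:
    """Run the full model-free battery and return a JSON-serializable report."""
    report: dict = {}
    report["rejection_contrast"] = rejection_contrast(records).to_dict()
    table, bh = per_offer_contrasts(records, q=q)
    report["per_offer_contrasts"] = table.to_dict(orient="records")
    report["bh"] = bh.to_dict()
    report["offer_size_regression"] = offer_size_regression(records).to_dict()
    curve = sliding_rejection(records, window=window)
    report["sliding_rejection"] = {
        "trial": [int(t) for t in curve.index],
        "rejection_rate": [float(v) for v in curve.to_numpy()],
        "window": window,
    }
    try:
        report["rating_contrast"] = rating_contrast(records).to_dict()
    except ValueError:
        report["rating_contrast"] = None
    return report


def plot_summary(records: pd.DataFrame, window: int = 5, path=None):
    """Three-panel figure: rejection by offer size, sliding curve, block bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    df = records.copy()
    df["rejected"] = _reject_mask(df).astype(float)

    by_offer = df.groupby("offer")["rejected"].mean() * 100
    axes[0].plot(by_offer.index, by_offer.to_numpy(), "o-")
    axes[0].set(xlabel="offer (tokens)", ylabel="rejection rate (%)",
                title="rejection by offer size")

    curve = sliding_rejection(records, window=window)
    axes[1].plot(curve.index, curve.to_numpy())
    axes[1].set(xlabel="trial", ylabel="rejection rate (%)",
                title=f"sliding window ({window} trials)")

    rates = rejection_rates(records, "block")
    means = rates.groupby("block", sort=False)["rejection_rate"].agg(["mean", "sem"])
    order = [b for b in ("baseline", "conditioning", "post") if b in means.index]
    means = means.loc[order]
    axes[2].bar(means.index, means["mean"], yerr=means["sem"], capsize=4)
    axes[2].set(ylabel="rejection rate (%)", title="block means +/- SEM")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
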