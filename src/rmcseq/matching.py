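"""Propensity-score selection of covariate-matched controls.

A logistic model of case membership on the chosen covariates (age, by
default) yields a propensity score per sample; controls are paired to cases
1:1 by greedy nearest-neighbour matching on the logit score, without
replacement, cases processed in descending propensity. An optional caliper
(a maximum logit distance, expressed in sd of the logit score) drops pairs
that would be too far apart. Balance before/after is reported as
standardized mean differences and Welch t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._firth import firth_logit
from .io import SampleTable

__all__ = ["PropensityMatch", "PropensityFit", "MatchResult", "BalanceReport",
           "fit_propensity", "match_one_to_one", "balance_report"]

_EPS = 1e-9


@dataclass
class PropensityFit:
    covariates: list[str]
    coef: np.ndarray          # intercept first
    propensity: pd.Series     # strictly in (0, 1)
    logit: pd.Series
    is_case: pd.Series
    firth_fallback: bool = False


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]          # (case_id, control_id)
    excluded_controls: list[str]
    excluded_cases: list[str]
    caliper: float | None

    @property
    def matched_cases(self) -> list[str]:
        return [c for c, _ in self.pairs]

    @property
    def matched_controls(self) -> list[str]:
        return [k for _, k in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "control_id"])


@dataclass
class BalanceReport:
    table: pd.DataFrame  # per covariate: smd_pre/post, p_pre/post, group means/sds

    def flagged(self) -> list[str]:
        t = self.table
        bad = (t["p_post"].fillna(1.0) <= 0.05) | (t["smd_post"] > 0.1)
        return list(t.index[bad])


def fit_propensity(samples: SampleTable, covariates: list[str]) -> PropensityFit:
    """Maximum-likelihood logistic fit of condition on covariates.

    Constant covariates are dropped with a warning; on (quasi-)separation or
    non-convergence the fit falls back to the Firth-penalized estimator and
    is flagged.
    """
    df = samples.data
    usable = []
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"covariate {c!r} not in sample table")
        if df[c].isna().any():
            raise ValueError(f"covariate {c!r} has missing values")
        if np.ptp(df[c].to_numpy(float)) == 0:
            warnings.warn(f"constant covariate {c!r} dropped")
            continue
        usable.append(c)
    if not usable:
        raise ValueError("all covariates constant; cannot fit propensity model")
    y = samples.is_case().astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    X = np.column_stack([np.ones(len(y))] + [df[c].to_numpy(float) for c in usable])

    beta, fallback = _ml_logit(y, X)
    eta = X @ beta
    prop = 1.0 / (1.0 + np.exp(-eta))
    prop = np.clip(prop, _EPS, 1 - _EPS)
    logit = np.log(prop / (1 - prop))
    idx = df.index
    return PropensityFit(usable, beta, pd.Series(prop, index=idx),
                         pd.Series(logit, index=idx),
                         pd.Series(y.astype(bool), index=idx), fallback)


def _ml_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, bool]:
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta = np.asarray(res.params)
            converged = bool(res.mle_retvals.get("converged", True))
            # a diverging fit drives fitted probabilities to 0/1: separation
            eta = X @ beta
            separated = np.max(np.abs(eta)) > 30
            if converged and not separated and np.all(np.isfinite(beta)):
                return beta, False
        except Exception:
            pass
    beta, _, _ = firth_logit(y, X)
    return beta, True


def match_one_to_one(fit: PropensityFit, caliper_sd: float | None = 0.2
                     ) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the logit propensity score.

    Cases are processed in descending propensity; ties in logit distance are
    broken by control sample_id order, so identical inputs always produce
    identical pairings. ``caliper_sd`` scales sd(logit) into an absolute
    caliper; ``None`` disables the caliper (every case gets a match while
    controls remain).
    """
    case_ids = list(fit.logit.index[fit.is_case])
    ctrl_ids = list(fit.logit.index[~fit.is_case])
    if not ctrl_ids:
        raise ValueError("no controls to match")
    caliper = None
    if caliper_sd is not None:
        caliper = float(caliper_sd) * float(np.std(fit.logit.to_numpy(), ddof=1))

    # descending propensity; ties by sample_id for determinism
    case_ids.sort(key=lambda s: (-fit.propensity[s], s))
    available = sorted(ctrl_ids)
    pairs: list[tuple[str, str]] = []
    excluded_cases: list[str] = []
    for cid in case_ids:
        if not available:
            excluded_cases.append(cid)
            continue
        d = np.array([abs(fit.logit[cid] - fit.logit[k]) for k in available])
        j = int(np.argmin(d))  # argmin takes the first minimum: id-order tie-break
        if caliper is not None and d[j] > caliper:
            excluded_cases.append(cid)
            continue
        pairs.append((cid, available.pop(j)))
    return MatchResult(pairs, available, sorted(excluded_cases), caliper)


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return abs(a.mean() - b.mean()) / pooled


def balance_report(samples: SampleTable, result: MatchResult,
                   covariates: list[str], *, welch: bool = True) -> BalanceReport:
    """Pre/post-match covariate balance: SMD and two-sample t-test p-values.

    Welch's unequal-variance test by default; ``welch=False`` restores the
    pooled-variance Student's test. With a single pair the post-match p is
    undefined and reported missing.
    """
    if not result.pairs:
        raise ValueError("empty match result")
    df = samples.data
    rows = {}
    for c in covariates:
        a_pre = df.loc[df["condition"] == "case", c].to_numpy(float)
        b_pre = df.loc[df["condition"] == "control", c].to_numpy(float)
        a_post = df.loc[result.matched_cases, c].to_numpy(float)
        b_post = df.loc[result.matched_controls, c].to_numpy(float)
        p_pre = _ttest_p(a_pre, b_pre, welch)
        p_post = _ttest_p(a_post, b_post, welch) if len(a_post) > 1 else np.nan
        rows[c] = {
            "smd_pre": _smd(a_pre, b_pre), "smd_post": _smd(a_post, b_post),
            "p_pre": p_pre, "p_post": p_post,
            "case_mean": a_post.mean(), "case_sd": np.std(a_post, ddof=1),
            "control_mean": b_post.mean(), "control_sd": np.std(b_post, ddof=1),
        }
    return BalanceReport(pd.DataFrame(rows).T)


def _ttest_p(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


class PropensityMatch:
    """Model-style interface: construct from a sample table, ``fit()`` matches.

    >>> res = PropensityMatch(samples, covariates=["age"]).fit(caliper_sd=None)
    >>> res.match.pairs; res.balance.table
    """

    def __init__(self, samples: SampleTable, covariates: list[str] | None = None):
        self.samples = samples
        self.covariates = covariates or ["age"]

    def fit(self, caliper_sd: float | None = 0.2) -> "PropensityMatchResults":
        pfit = fit_propensity(self.samples, self.covariates)
        match = match_one_to_one(pfit, caliper_sd)
        balance = balance_report(self.samples, match, self.covariates)
        return PropensityMatchResults(self, pfit, match, balance)


class PropensityMatchResults:
    def __init__(self, model: PropensityMatch, propensity: PropensityFit,
                 match: MatchResult, balance: BalanceReport):
        self.model = model
        self.propensity = propensity
        self.match = match
        self.balance = balance

    def matched_table(self) -> SampleTable:
        ids = self.match.matched_cases + self.match.matched_controls
        return self.model.samples.subset(ids)

    def summary(self) -> str:
        m = self.match
        lines = [
            "Propensity-score 1:1 matching",
            f"  covariates: {', '.join(self.model.covariates)}"
            + ("  [Firth fallback]" if self.propensity.firth_fallback else ""),
            f"  pairs: {len(m.pairs)}   excluded controls: {len(m.excluded_controls)}"
            f"   excluded cases: {len(m.excluded_cases)}",
            f"  caliper (logit): {m.caliper if m.caliper is not None else 'none'}",
            "",
            self.balance.table.round(4).to_string(),
        ]
        return "\n".join(lines)
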