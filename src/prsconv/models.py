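"""Conversion-prediction statistics.

Logistic regression is a compact iteratively-reweighted-least-squares
fitter written for the very large number of small refits the permutation
threshold sweep performs; it is cross-checked against statsmodels in the
test suite.  The Cox model stands on lifelines.  The chi-square test is
Pearson's without continuity correction and the two-sample t-test uses the
pooled variance — the conventions that reproduce the published
group-comparison statistics this pipeline mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, NumericalError

__all__ = [
    "logistic_irls",
    "logistic_fit",
    "LogisticFit",
    "nagelkerke_r2",
    "roc_auc",
    "cox_fit",
    "CoxFit",
    "chisq_independence",
    "two_sample_t",
    "two_sample_t_raw",
    "stratify_groups",
]


def _check_design(X: np.ndarray, names: list[str] | None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        labels = [names[i] if names else f"col{i}" for i in bad]
        raise DataError(f"singular design matrix; collinear columns: {labels}")


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    check_rank: bool = True,
    names: list[str] | None = None,
):
    """Maximum-likelihood logistic regression by IRLS.

    Converges when the largest score component |X'(y - mu)| drops below
    ``tol``.  Returns ``(beta, cov, llf, converged, separated, n_iter)``;
    ``separated`` flags diverging linear predictors (quasi-complete
    separation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise DataError(f"need more observations ({n}) than parameters ({p})")
    if y.min() == y.max():
        raise DataError("outcome has no variation")
    if check_rank:
        _check_design(X, names)
    beta = np.zeros(p)
    separated = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        xw = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ xw, xw.T @ (eta + (y - mu) / w))
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"IRLS weighted solve failed: {exc}") from exc
        if np.max(np.abs(X @ beta)) > 30:
            separated = True
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    try:
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, llf, converged, separated, it


def _ll_intercept_only(y: np.ndarray) -> float:
    n = len(y)
    k = float(np.sum(y))
    if k == 0 or k == n:
        return 0.0
    pbar = k / n
    return float(k * np.log(pbar) + (n - k) * np.log1p(-pbar))


def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke's rescaled likelihood-ratio pseudo-R^2.

    ``[1 - exp((2/n)(ll_null - ll_full))] / [1 - exp((2/n) ll_null)]``.
    """
    if n <= 0:
        raise DataError(f"n must be positive, got {n}")
    denom = 1.0 - np.exp((2.0 / n) * ll_null)
    if denom == 0.0:
        return 0.0
    return float((1.0 - np.exp((2.0 / n) * (ll_null - ll_full))) / denom)


@dataclass
class LogisticFit:
    """Fitted logistic model with the summaries the pipeline reports."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    llf: float
    llnull: float
    n: int
    converged: bool
    separated: bool
    nagelkerke: float
    auc: float
    or_per_sd: float | None = None
    or_ci: tuple[float, float] | None = None
    prs_p: float | None = None

    def pvalues(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def table(self) -> pd.DataFrame:
        p = self.pvalues()
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.coef,
                "se": self.se,
                "z": self.coef / self.se,
                "p": p,
                "odds_ratio": np.exp(self.coef),
            }
        )


def logistic_fit(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    prs_col: str | int | None = None,
    add_intercept: bool = True,
) -> LogisticFit:
    """Fit a covariate-adjusted logistic model of a binary outcome.

    ``prs_col`` names the score column; its exponentiated coefficient is
    reported as the odds ratio per unit (per SD for a z-scored score) with
    a 95% Wald interval.  The AUC is that of the fitted linear predictor.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
    if add_intercept:
        Xv = np.column_stack([np.ones(len(Xv)), Xv])
        names = ["intercept"] + names
    y = np.asarray(y, dtype=float)
    beta, cov, llf, converged, separated, _ = logistic_irls(Xv, y, names=names)
    se = np.sqrt(np.diag(cov))
    llnull = _ll_intercept_only(y)
    fit = LogisticFit(
        names=names,
        coef=beta,
        se=se,
        llf=llf,
        llnull=llnull,
        n=len(y),
        converged=converged,
        separated=separated,
        nagelkerke=nagelkerke_r2(llnull, llf, len(y)),
        auc=roc_auc(Xv @ beta, y),
    )
    if prs_col is not None:
        idx = names.index(prs_col) if isinstance(prs_col, str) else int(prs_col)
        b, s = beta[idx], se[idx]
        fit.or_per_sd = float(np.exp(b))
        fit.or_ci = (float(np.exp(b - 1.959964 * s)), float(np.exp(b + 1.959964 * s)))
        fit.prs_p = float(2.0 * stats.norm.sf(abs(b / s)))
    return fit


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC = P(score_case > score_control) + P(tie)/2, by rank statistic."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise DataError("ROC AUC requires both outcome classes")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (lifelines backend)."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    log_likelihood: float
    n: int
    n_events: int
    baseline_cumhaz: pd.Series = field(repr=False)

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def cumulative_risk(self, profile: np.ndarray, times: np.ndarray) -> np.ndarray:
        """``1 - exp(-Lambda0(t) * exp(x'beta))`` for one covariate profile."""
        lam0 = np.interp(
            np.asarray(times, dtype=float),
            self.baseline_cumhaz.index.to_numpy(dtype=float),
            self.baseline_cumhaz.to_numpy(dtype=float),
            left=0.0,
        )
        return 1.0 - np.exp(-lam0 * np.exp(float(np.asarray(profile) @ self.coef)))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.coef,
                "se": self.se,
                "p": self.p,
                "hazard_ratio": np.exp(self.coef),
            }
        )


def cox_fit(time: np.ndarray, event: np.ndarray, X: pd.DataFrame | np.ndarray) -> CoxFit:
    """Proportional-hazards regression of time-to-conversion.

    Raises on degenerate inputs (no events, constant covariates,
    non-positive times) rather than letting the optimizer wander.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if (time <= 0).any():
        raise DataError("event/censoring times must be positive")
    if event.sum() == 0:
        raise DataError("no events observed")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        df = X.reset_index(drop=True).astype(float).copy()
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(time):
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
        df = pd.DataFrame(X, columns=names)
    for c in names:
        if df[c].std() == 0:
            raise DataError(f"covariate {c!r} is constant (no information)")
    df["time"] = time
    df["event"] = event
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise NumericalError(f"Cox fit failed to converge: {exc}") from exc
    summary = fitter.summary
    return CoxFit(
        names=names,
        coef=summary["coef"].to_numpy(),
        se=summary["se(coef)"].to_numpy(),
        p=summary["p"].to_numpy(),
        log_likelihood=float(fitter.log_likelihood_),
        n=len(df),
        n_events=int(event.sum()),
        baseline_cumhaz=fitter.baseline_cumulative_hazard_.iloc[:, 0],
    )


def chisq_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise DataError("contingency table must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataError("contingency table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance Student t from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise DataError("each group needs at least two observations")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def two_sample_t_raw(x1: np.ndarray, x2: np.ndarray) -> tuple[float, int, float]:
    """Pooled-variance Student t from raw vectors."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    res = stats.ttest_ind(x1, x2, equal_var=True)
    return float(res.statistic), len(x1) + len(x2) - 2, float(res.pvalue)


def stratify_groups(z_scores: np.ndarray, k: int) -> np.ndarray:
    """Rank-based split into k score-ordered groups (0 = lowest scores).

    Remainder samples go to the upper groups, so n=278 splits as 139/139
    (k=2) and 92/93/93 (k=3).  Ties are broken by stable input order.
    """
    z = np.asarray(z_scores, dtype=float)
    if np.isnan(z).any():
        raise DataError("scores contain missing values")
    n = len(z)
    if k not in (2, 3):
        raise ConfigurationError(f"k must be 2 or 3, got {k}")
    if n < k:
        raise DataError(f"cannot split {n} samples into {k} groups")
    base, rem = divmod(n, k)
    sizes = [base] * (k - rem) + [base + 1] * rem
    order = np.argsort(z, kind="stable")
    labels = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes):
        labels[order[start : start + size]] = g
        start += size
    return labels
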