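"""One-sample Mendelian randomization by two-stage least squares.

The polygenic score is the instrument, a regional brain measure the
exposure, and conversion the outcome (treated as a linear-probability
outcome, the plain-TSLS convention).  Stage 1 regresses the exposure on
[1 | instrument | covariates]; stage 2 regresses the outcome on
[1 | fitted exposure | covariates].  Standard errors are the classical
homoskedastic TSLS ones: stage-2 residuals are recomputed with the
*observed* exposure plugged into the stage-2 coefficients
(heteroskedasticity-robust errors are available as an option).
The exposure is standardized to unit SD by default so the estimate reads
as outcome change per SD of exposure attributable to the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

WEAK_INSTRUMENT_F = 10.0


@dataclass
class MrResult:
    """TSLS estimate with first-stage diagnostics."""

    beta: float
    se: float
    p: float
    stage1_beta: float
    stage1_se: float
    stage1_f: float
    n: int
    weak_instrument: bool


def _design(n: int, *cols: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(n), *cols])


def tsls_fit(
    Z: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    C: np.ndarray | pd.DataFrame | None = None,
    standardize_exposure: bool = True,
    robust: bool = False,
) -> MrResult:
    """Two-stage least squares with a single instrument.

    With no covariates this reduces exactly to the Wald ratio
    ``cov(Z, Y) / cov(Z, X)``.  Raises if the instrument has no partial
    variance for the exposure given the covariates.
    """
    Z = np.asarray(Z, dtype=float).ravel()
    X = np.asarray(X, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    n = len(Z)
    if C is None:
        Cv = np.empty((n, 0))
    else:
        Cv = C.to_numpy(dtype=float) if isinstance(C, pd.DataFrame) else np.asarray(C, dtype=float)
        if Cv.ndim == 1:
            Cv = Cv[:, None]
    if n <= Cv.shape[1] + 3:
        raise DataError(f"need n > k + 3 observations (n={n}, k={Cv.shape[1]})")
    if standardize_exposure:
        sd = X.std()
        if sd == 0:
            raise DataError("exposure has zero variance")
        X = (X - X.mean()) / sd

    # stage 1: exposure on [1 | Z | C]
    D1 = _design(n, Z, Cv)
    g1, _, _, _ = np.linalg.lstsq(D1, X, rcond=None)
    xhat = D1 @ g1
    resid1 = X - xhat
    dof1 = n - D1.shape[1]
    sigma1 = float(resid1 @ resid1) / dof1
    try:
        cov1 = sigma1 * np.linalg.inv(D1.T @ D1)
    except np.linalg.LinAlgError as exc:
        raise DataError(f"stage-1 design is singular: {exc}") from exc
    stage1_beta = float(g1[1])
    stage1_se = float(np.sqrt(cov1[1, 1]))
    if stage1_se == 0 or not np.isfinite(stage1_se):
        raise DataError("instrument irrelevant: zero partial variance in stage 1")
    stage1_f = (stage1_beta / stage1_se) ** 2
    if stage1_f == 0:
        raise DataError("instrument irrelevant: stage-1 partial R^2 is zero")

    # stage 2: outcome on [1 | fitted exposure | C]
    D2 = _design(n, xhat, Cv)
    g2, _, _, _ = np.linalg.lstsq(D2, Y, rcond=None)
    beta = float(g2[1])
    # classical TSLS covariance: residuals with the observed exposure
    D2_obs = _design(n, X, Cv)
    resid = Y - D2_obs @ g2
    dof = n - D2.shape[1]
    bread = np.linalg.inv(D2.T @ D2)
    if robust:
        meat = D2.T @ (D2 * resid[:, None] ** 2)
        cov2 = bread @ meat @ bread
    else:
        sigma2 = float(resid @ resid) / dof
        cov2 = sigma2 * bread
    se = float(np.sqrt(cov2[1, 1]))
    p = float(2.0 * stats.t.sf(abs(beta / se), dof)) if se > 0 else np.nan
    return MrResult(
        beta=beta,
        se=se,
        p=p,
        stage1_beta=stage1_beta,
        stage1_se=stage1_se,
        stage1_f=float(stage1_f),
        n=n,
        weak_instrument=stage1_f < WEAK_INSTRUMENT_F,
    )


def mr_chain_report(
    z_scores: np.ndarray,
    cohort: pd.DataFrame,
    regions: list[tuple[str, str]],
    outcome: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    sample_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """TSLS per listed (region, measure) pair with the standard covariates.

    ``sign_pattern`` flags the mediation direction of interest: a negative
    stage-1 coefficient (higher score, smaller measure) together with a
    negative exposure->outcome estimate.
    """
    mask = np.ones(len(cohort), dtype=bool) if sample_mask is None else np.asarray(sample_mask, bool)
    z = np.asarray(z_scores, dtype=float)[mask]
    y = np.asarray(outcome, dtype=float)[mask]
    C = None
    if covariates is not None:
        C = (covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame)
             else np.asarray(covariates, dtype=float))[mask]
    rows = []
    for region, measure in regions:
        x = cohort[f"{region}_{measure}"].to_numpy(dtype=float)[mask]
        res = tsls_fit(z, x, y, C)
        rows.append(
            {
                "region": region,
                "measure": measure,
                "stage1_beta": res.stage1_beta,
                "stage1_se": res.stage1_se,
                "stage1_f": res.stage1_f,
                "beta_tsls": res.beta,
                "se": res.se,
                "p": res.p,
                "n": res.n,
                "weak_instrument": res.weak_instrument,
                "sign_pattern": res.stage1_beta < 0 and res.beta < 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "measure", "stage1_beta", "stage1_se", "stage1_f",
            "beta_tsls", "se", "p", "n", "weak_instrument", "sign_pattern",
        ],
    )
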