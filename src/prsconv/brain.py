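"""Covariate-adjusted score-vs-brain-structure association scan.

Each regional measure is tested against the z-scored PRS by partial
Pearson correlation (both sides residualized on the covariates), with
Benjamini-Hochberg FDR control across the whole region-by-measure family
by default (a per-measure family is available as an option).
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .simulate import MEASURES

_REGION_RE = re.compile(r"^(?P<region>.+)_(?P<measure>" + "|".join(MEASURES) + r")$")


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | pd.DataFrame | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on covariates.

    The p-value uses ``t = r sqrt((n-2-k)/(1-r^2))`` with ``n-2-k`` degrees
    of freedom, where k is the number of covariate columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    if n <= k + 2:
        raise DataError(f"need n > k + 2 observations (n={n}, k={k})")
    D = np.column_stack([np.ones(n), C])
    rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
    ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    # treat residuals at numerical-noise scale as exactly collinear
    if sx <= 1e-10 * max(x.std(), 1e-300) or sy <= 1e-10 * max(y.std(), 1e-300):
        raise DataError("zero residual variance; correlation undefined")
    r = float(np.clip((rx @ ry) / (n * sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals.copy()
    if np.any((pvals <= 0) | (pvals > 1) | np.isnan(pvals)):
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def region_scan(
    cohort: pd.DataFrame,
    z_scores: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    q_threshold: float = 0.05,
    family: str = "joint",
    sample_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Partial-correlation scan of the score against every regional measure.

    ``family`` controls the BH correction family: ``"joint"`` corrects all
    region-by-measure tests together (the conservative default),
    ``"per_measure"`` corrects each measure type separately.  Columns with
    missing values or degenerate residuals are reported with NaN statistics
    and skipped by the correction.  Returns one row per test sorted by p.
    """
    if family not in ("joint", "per_measure"):
        raise ConfigurationError(f"family must be 'joint' or 'per_measure', got {family!r}")
    mask = np.ones(len(cohort), dtype=bool) if sample_mask is None else np.asarray(sample_mask, bool)
    z = np.asarray(z_scores, dtype=float)[mask]
    C = None
    if covariates is not None:
        C = (covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame)
             else np.asarray(covariates, dtype=float))[mask]
    rows = []
    for col in cohort.columns:
        m = _REGION_RE.match(col)
        if not m:
            continue
        values = cohort[col].to_numpy(dtype=float)[mask]
        if np.isnan(values).any():
            rows.append((m["region"], m["measure"], np.nan, np.nan))
            continue
        try:
            r, p = partial_pearson(z, values, C)
        except DataError:
            rows.append((m["region"], m["measure"], np.nan, np.nan))
            continue
        rows.append((m["region"], m["measure"], r, p))
    if not rows:
        raise DataError("cohort table contains no regional measure columns")
    out = pd.DataFrame(rows, columns=["region", "measure", "r", "p"])
    out["q"] = np.nan
    ok = out["p"].notna()
    if family == "joint":
        if ok.any():
            out.loc[ok, "q"] = fdr_bh(out.loc[ok, "p"].to_numpy())
    else:
        for measure in out["measure"].unique():
            sel = ok & (out["measure"] == measure)
            if sel.any():
                out.loc[sel, "q"] = fdr_bh(out.loc[sel, "p"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def replication_scan(
    cohort: pd.DataFrame,
    z_scores_replication: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    discovery_hits: pd.DataFrame,
    p_threshold: float = 0.05,
    sample_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Re-test the discovery-significant set with a second score.

    Replication uses the unadjusted ``p < p_threshold`` rule restricted to
    the previously significant region-measure pairs.
    """
    mask = np.ones(len(cohort), dtype=bool) if sample_mask is None else np.asarray(sample_mask, bool)
    z = np.asarray(z_scores_replication, dtype=float)[mask]
    C = None
    if covariates is not None:
        C = (covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame)
             else np.asarray(covariates, dtype=float))[mask]
    rows = []
    for rec in discovery_hits.itertuples(index=False):
        col = f"{rec.region}_{rec.measure}"
        values = cohort[col].to_numpy(dtype=float)[mask]
        r, p = partial_pearson(z, values, C)
        rows.append((rec.region, rec.measure, r, p, p < p_threshold))
    return pd.DataFrame(rows, columns=["region", "measure", "r", "p", "replicated"])
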