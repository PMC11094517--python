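"""Clumping-and-thresholding polygenic score construction.

The score for sample *i* at threshold ``p_T`` is the raw weighted allele
count ``sum_{j: p_j <= p_T} G_ij * beta_j`` over LD-clumped index variants,
z-transformed before modelling.  The threshold grid defaults to
0.001..1.000 in steps of 0.001 (1000 scores); the best threshold maximizes
the covariate-adjusted incremental Nagelkerke R^2 for conversion, and the
selection is corrected by a label-permutation test that re-runs the whole
sweep under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .models import _ll_intercept_only, logistic_irls, nagelkerke_r2
from .panel import GenotypePanel, is_ambiguous

log = logging.getLogger(__name__)

#: Column-name synonyms tolerated by the summary-statistic reader.
_SYNONYMS = {
    "SNP": ["SNP", "ID", "RSID", "MARKERNAME", "VARIANT_ID"],
    "CHR": ["CHR", "CHROM", "CHROMOSOME"],
    "BP": ["BP", "POS", "POSITION", "BASE_PAIR_LOCATION"],
    "A1": ["A1", "EA", "EFFECT_ALLELE", "ALLELE1"],
    "A2": ["A2", "OA", "NEA", "OTHER_ALLELE", "ALLELE2", "ALLELE0"],
    "BETA": ["BETA", "B", "EFFECT"],
    "SE": ["SE", "STDERR", "STANDARD_ERROR"],
    "P": ["P", "PVAL", "P_VALUE", "PVALUE"],
}


def read_gwas_summary(path) -> pd.DataFrame:
    """Read a delimited summary-statistic table, normalizing column names.

    ``OR`` columns (odds ratios) are log-transformed into BETA.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    upper = {c.upper(): c for c in df.columns}
    out = {}
    for canon, alts in _SYNONYMS.items():
        for alt in alts:
            if alt in upper:
                out[canon] = df[upper[alt]]
                break
    if "BETA" not in out and "OR" in upper:
        out["BETA"] = np.log(df[upper["OR"]].astype(float))
    required = {"SNP", "A1", "A2", "BETA", "P"}
    missing = required - out.keys()
    if missing:
        raise DataError(f"summary statistics missing required columns: {sorted(missing)}")
    res = pd.DataFrame(out)
    res["A1"] = res["A1"].str.upper()
    res["A2"] = res["A2"].str.upper()
    return res


@dataclass
class AlignedWeights:
    """Discovery effects mapped onto target-panel columns.

    ``table`` columns: variant_id, col_index (target panel column), beta
    (sign-harmonized to the panel's counted allele) and the discovery
    p-value.  ``dropped`` records mismatched or strand-ambiguous variants.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.table)

    def restrict(self, p_max: float) -> "AlignedWeights":
        return AlignedWeights(self.table[self.table["p"] <= p_max].reset_index(drop=True))


def align_alleles(summary: pd.DataFrame, panel: GenotypePanel) -> AlignedWeights:
    """Match summary variants to panel columns, harmonizing effect signs.

    Keep beta when the discovery effect allele equals the panel's counted
    allele; negate it when the allele pair is swapped; drop (and log) when
    allele sets disagree or the pair is strand-ambiguous.
    """
    pv = panel.variants
    pos = {vid: j for j, vid in enumerate(pv["variant_id"])}
    rows, dropped = [], []
    for rec in summary.itertuples(index=False):
        j = pos.get(rec.SNP)
        if j is None:
            continue
        pa1, pa2 = pv["a1"].iloc[j], pv["a2"].iloc[j]
        if is_ambiguous(rec.A1, rec.A2) or is_ambiguous(pa1, pa2):
            dropped.append((rec.SNP, "ambiguous"))
            continue
        if rec.A1 == pa1 and rec.A2 == pa2:
            beta = float(rec.BETA)
        elif rec.A1 == pa2 and rec.A2 == pa1:
            beta = -float(rec.BETA)
        else:
            dropped.append((rec.SNP, "allele_mismatch"))
            continue
        rows.append((rec.SNP, j, beta, float(rec.P)))
    if not rows:
        raise DataError("no summary variants could be aligned to the panel")
    table = pd.DataFrame(rows, columns=["variant_id", "col_index", "beta", "p"])
    dropped_df = pd.DataFrame(dropped, columns=["variant_id", "reason"])
    if len(dropped_df):
        log.info("align_alleles dropped %d variants (%s)", len(dropped_df),
                 dropped_df["reason"].value_counts().to_dict())
    return AlignedWeights(table, dropped_df)


def _pairwise_r2(x: np.ndarray, y: np.ndarray, min_samples: int = 50) -> float:
    valid = ~np.isnan(x) & ~np.isnan(y)
    if valid.sum() < min_samples:
        raise DataError(
            f"only {int(valid.sum())} samples with both variants non-missing "
            f"(need >= {min_samples})"
        )
    xv, yv = x[valid], y[valid]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r * r


def ld_r2(panel: GenotypePanel, j: int, k: int, min_samples: int = 50) -> float:
    """Squared Pearson correlation of two variants' dosage vectors
    (composite LD on unphased dosages); 0 if either is monomorphic."""
    return _pairwise_r2(panel.dosage[:, j], panel.dosage[:, k], min_samples)


def clump(
    weights: AlignedWeights,
    panel: GenotypePanel,
    r2_threshold: float = 0.5,
    window_kb: float = 250.0,
    min_samples: int = 50,
) -> AlignedWeights:
    """Greedy LD clumping at the target panel.

    Variants are processed in ascending discovery p (ties: ascending
    position); each surviving variant becomes an index and removes all
    unprocessed variants within ``window_kb`` whose r^2 with it exceeds
    ``r2_threshold``.  Only index variants are returned.
    """
    t = weights.table
    positions = panel.variants["pos"].to_numpy()[t["col_index"].to_numpy()]
    order = np.lexsort((positions, t["p"].to_numpy()))
    removed = np.zeros(len(t), dtype=bool)
    is_index = np.zeros(len(t), dtype=bool)
    window_bp = window_kb * 1000.0
    cols = t["col_index"].to_numpy()
    rank = np.empty(len(t), dtype=int)
    rank[order] = np.arange(len(t))
    for oi, idx in enumerate(order):
        if removed[idx]:
            continue
        is_index[idx] = True
        near = (
            (~removed)
            & (~is_index)
            & (rank > oi)
            & (np.abs(positions - positions[idx]) <= window_bp)
        )
        for other in np.where(near)[0]:
            if ld_r2(panel, int(cols[idx]), int(cols[other]), min_samples) > r2_threshold:
                removed[other] = True
    return AlignedWeights(t[is_index].reset_index(drop=True), weights.dropped)


def score(panel: GenotypePanel, weights: AlignedWeights, p_T: float = 1.0) -> np.ndarray:
    """Raw PRS at threshold ``p_T``; missing dosages imputed with twice the
    counted-allele frequency among non-missing calls."""
    t = weights.table
    include = t["p"].to_numpy() <= p_T
    if not include.any():
        log.warning("no variant passes p_T=%g; scores are all zero", p_T)
        return np.zeros(panel.n_samples)
    cols = t["col_index"].to_numpy()[include]
    betas = t["beta"].to_numpy()[include]
    g = panel.dosage[:, cols].copy()
    freq = panel.allele_freq()[cols]
    nan_r, nan_c = np.where(np.isnan(g))
    g[nan_r, nan_c] = 2.0 * freq[nan_c]
    return g @ betas


def default_grid() -> np.ndarray:
    """The 1000-point threshold grid 0.001, 0.002, ..., 1.000."""
    return np.round(np.arange(1, 1001) / 1000.0, 3)


@dataclass
class PrsProfile:
    """Threshold-sweep result.

    ``per_threshold`` has one row per grid point: p_T, n_variants,
    r2 (incremental Nagelkerke attributable to the score), coefficient and
    p of the score term.  ``best_z`` is the z-transformed score at the best
    threshold; ``outlier_mask`` marks samples outside mean +/- 2 SD of it.
    """

    per_threshold: pd.DataFrame
    best_p_t: float
    best_r2: float
    best_raw: np.ndarray
    best_z: np.ndarray
    outlier_mask: np.ndarray
    n_variants_best: int
    permutation_p: float | None = None


class _SweepEngine:
    """Precomputes per-threshold z-scored PRS columns so that the sweep can
    be re-run cheaply under outcome permutations."""

    def __init__(self, panel, weights, covariates, grid, trim_sd=2.0):
        self.grid = np.asarray(grid, dtype=float)
        if self.grid.ndim != 1 or len(self.grid) == 0:
            raise ConfigurationError("threshold grid must be a non-empty 1-D array")
        t = weights.table.sort_values(["p", "col_index"], kind="stable")
        self.p_sorted = t["p"].to_numpy()
        cols = t["col_index"].to_numpy()
        betas = t["beta"].to_numpy()
        g = panel.dosage[:, cols].copy()
        freq = panel.allele_freq()[cols]
        nan_r, nan_c = np.where(np.isnan(g))
        g[nan_r, nan_c] = 2.0 * freq[nan_c]
        self.cum = np.cumsum(g * betas[None, :], axis=1)
        self.counts = np.searchsorted(self.p_sorted, self.grid, side="right")
        self.trim_sd = trim_sd
        n = panel.n_samples
        if covariates is None:
            self.C = np.ones((n, 1))
            self.cov_names = ["intercept"]
        else:
            C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
            self.C = np.column_stack([np.ones(n), C])
            self.cov_names = ["intercept"] + (
                list(covariates.columns) if isinstance(covariates, pd.DataFrame) else
                [f"c{i}" for i in range(C.shape[1])]
            )
        # z-scored score per distinct variant count (count 0 -> degenerate)
        self.z_by_count: dict[int, np.ndarray | None] = {0: None}
        for c in np.unique(self.counts):
            if c == 0:
                continue
            s = self.cum[:, c - 1]
            sd = s.std()
            self.z_by_count[int(c)] = None if sd == 0 else (s - s.mean()) / sd

    def raw_at_count(self, count: int) -> np.ndarray:
        return self.cum[:, count - 1] if count > 0 else np.zeros(self.cum.shape[0])

    def sweep(self, y: np.ndarray):
        """Per-distinct-count incremental R^2 for outcome ``y``.

        Returns (results dict count -> (r2, coef, p), best_count, best_r2).
        """
        ll_null = _ll_intercept_only(y)
        n = len(y)
        try:
            _, _, ll_cov, *_ = logistic_irls(self.C, y, check_rank=False)
        except DataError:
            raise
        r2_cov = nagelkerke_r2(ll_null, ll_cov, n)
        results: dict[int, tuple[float, float, float]] = {}
        from scipy import stats as _st

        for count, z in self.z_by_count.items():
            if z is None:
                continue
            X = np.column_stack([self.C, z])
            try:
                beta, cov, llf, converged, separated, _ = logistic_irls(
                    X, y, check_rank=False
                )
            except Exception as exc:  # noqa: BLE001 - a failed threshold is skipped, not fatal
                log.info("sweep: fit failed at count=%d (%s); skipped", count, exc)
                continue
            if not converged and not separated:
                log.info("sweep: non-convergent fit at count=%d skipped", count)
                continue
            r2 = nagelkerke_r2(ll_null, llf, n) - r2_cov
            se = float(np.sqrt(cov[-1, -1]))
            pval = float(2.0 * _st.norm.sf(abs(beta[-1] / se))) if se > 0 else np.nan
            results[count] = (r2, float(beta[-1]), pval)
        if not results:
            raise DataError("no threshold produced a usable fit")
        best_count = max(results, key=lambda c: (results[c][0], -c))
        return results, best_count, results[best_count][0]


def sweep_and_select(
    panel: GenotypePanel,
    weights: AlignedWeights,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    grid: np.ndarray | None = None,
    trim_sd: float = 2.0,
) -> PrsProfile:
    """Threshold sweep with covariate-adjusted model selection.

    For every grid threshold, the z-scored PRS enters a logistic model of
    conversion alongside the covariates; the recorded R^2 is the Nagelkerke
    R^2 of that model minus the covariate-only model's.  The best threshold
    maximizes R^2 (ties toward smaller p_T, i.e. the sparser score).  The
    best score is z-transformed and samples outside mean +/- ``trim_sd`` SD
    are flagged in ``outlier_mask`` (flagged, not deleted, so downstream
    sensitivity analyses can toggle the trim).
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    engine = _SweepEngine(panel, weights, covariates, grid, trim_sd)
    y = np.asarray(y, dtype=float)
    results, best_count, best_r2 = engine.sweep(y)

    rows = []
    for p_t, count in zip(engine.grid, engine.counts):
        r2, coef, pval = results.get(int(count), (np.nan, np.nan, np.nan))
        rows.append((p_t, int(count), r2, coef, pval))
    per_threshold = pd.DataFrame(rows, columns=["p_t", "n_variants", "r2", "coef", "p"])

    eligible = per_threshold[per_threshold["n_variants"] == best_count]
    best_p_t = float(eligible["p_t"].iloc[0])
    raw = engine.raw_at_count(best_count)
    z = (raw - raw.mean()) / raw.std()
    mask = np.abs(z - z.mean()) > trim_sd * z.std()
    return PrsProfile(
        per_threshold=per_threshold,
        best_p_t=best_p_t,
        best_r2=float(best_r2),
        best_raw=raw,
        best_z=z,
        outlier_mask=mask,
        n_variants_best=int(best_count),
    )


def permutation_correct(
    panel: GenotypePanel,
    weights: AlignedWeights,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    observed_best_r2: float,
    grid: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation-corrected p-value for the selected threshold's R^2.

    Permutes the outcome vector only, re-runs the full threshold sweep per
    permutation, and returns ``(1 + #{permuted best R^2 >= observed}) /
    (1 + n_perm)`` — a family-wise correction over the whole grid.
    """
    if n_perm < 100:
        raise ConfigurationError(f"n_perm must be >= 100, got {n_perm}")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    engine = _SweepEngine(panel, weights, covariates, grid)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        try:
            _, _, best_r2 = engine.sweep(yp)
        except DataError:
            continue
        if best_r2 >= observed_best_r2:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
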