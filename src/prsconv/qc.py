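"""SNP- and sample-level genotype quality control.

Variant filters: call rate, minor-allele frequency, an exact
Hardy-Weinberg equilibrium test, and strand-ambiguous allele pairs.
Sample filters: reported-vs-genetic sex mismatch, relatedness by a
method-of-moments PI_HAT (IBD-sharing) estimate, heterozygosity outliers
and per-sample call rate.  Principal components of the standardized
dosage matrix provide population-stratification covariates.

Two threshold presets are provided: the clinical-cohort default
(call rate >= 0.95, MAF >= 0.01, HWE p >= 5e-7, sample call rate >= 0.97,
PI_HAT <= 0.1875, heterozygosity within mean +/- 5 SD) and a biobank
preset that relaxes the MAF bound to 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError, DataError
from .panel import GenotypePanel, is_ambiguous


@dataclass(frozen=True)
class QcThresholds:
    variant_call_rate: float = 0.95
    maf: float = 0.01
    hwe_p: float = 5e-7
    drop_ambiguous: bool = True
    sample_call_rate: float = 0.97
    pi_hat: float = 0.1875
    het_sd: float = 5.0
    pca_outlier_sd: float = 6.0


#: Clinical-cohort defaults.
ADNI_PRESET = QcThresholds()
#: Biobank preset: much larger sample supports rarer variants.
UKBB_PRESET = QcThresholds(maf=0.001)

PRESETS = {"adni": ADNI_PRESET, "ukbb": UKBB_PRESET}


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity) that are no more probable than
    the observed one.  Monomorphic sites return 1.0.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise DataError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise DataError("HWE test undefined for zero genotypes")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    # log P(het | allele counts) up to a shared constant
    logp = hets * np.log(2.0) - (
        gammaln(homr + 1) + gammaln(hets + 1) + gammaln(homc + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.where(hets == n_Aa)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


def variant_qc_table(panel: GenotypePanel) -> pd.DataFrame:
    """Per-variant call rate, MAF, HWE p and strand-ambiguity flags."""
    freq = panel.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    call_rate = panel.variant_call_rate()
    hwe = np.empty(panel.n_variants)
    d = panel.dosage
    for j in range(panel.n_variants):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            hwe[j] = np.nan
            continue
        n_aa = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        hwe[j] = hwe_exact_test(n_AA, n_het, n_aa)
    ambiguous = np.array(
        [is_ambiguous(a1, a2) for a1, a2 in zip(panel.variants["a1"], panel.variants["a2"])]
    )
    out = panel.variants[["variant_id", "chrom", "pos", "a1", "a2"]].copy()
    out["call_rate"] = call_rate
    out["maf"] = maf
    out["hwe_p"] = hwe
    out["ambiguous"] = ambiguous
    return out


def filter_variants(
    panel: GenotypePanel, thresholds: QcThresholds = ADNI_PRESET
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Drop variants failing call rate, MAF, HWE or strand-ambiguity filters.

    Returns the filtered panel and a report with per-variant metrics, a
    ``pass`` flag and semicolon-joined failure ``reasons``.
    """
    report = variant_qc_table(panel)
    reasons = []
    for _, row in report.iterrows():
        r = []
        if row["call_rate"] < thresholds.variant_call_rate:
            r.append("call_rate")
        if not np.isnan(row["maf"]) and row["maf"] < thresholds.maf:
            r.append("maf")
        if not np.isnan(row["hwe_p"]) and row["hwe_p"] < thresholds.hwe_p:
            r.append("hwe")
        if thresholds.drop_ambiguous and row["ambiguous"]:
            r.append("ambiguous")
        reasons.append(";".join(r))
    report["reasons"] = reasons
    report["pass"] = report["reasons"] == ""
    keep = report["pass"].to_numpy()
    if not keep.any():
        raise DataError("no variants remain after variant QC")
    return panel.subset(variant_mask=keep), report


def _ibd_expectations(freq: np.ndarray) -> dict[str, np.ndarray]:
    p = freq
    q = 1.0 - freq
    return {
        "e0_ibd0": 2.0 * p**2 * q**2,
        "e1_ibd0": 4.0 * p**3 * q + 4.0 * p * q**3,
        "e1_ibd1": 2.0 * p**2 * q + 2.0 * p * q**2,
        "e2_ibd0": p**4 + q**4 + 4.0 * p**2 * q**2,
        "e2_ibd1": p**3 + q**3 + p**2 * q + p * q**2,
    }


def _pi_hat_from_counts(ibs0, ibs1, ibs2, E0, E1_0, E1_1, E2_0, E2_1, n_valid):
    """Method-of-moments P(IBD=0,1,2) from IBS counts; clamped, renormalized."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = ibs0 / E0
        p1 = (ibs1 - p0 * E1_0) / E1_1
        p2 = (ibs2 - p0 * E2_0 - p1 * E2_1) / n_valid
    p0 = np.clip(p0, 0.0, 1.0)
    p1 = np.clip(p1, 0.0, 1.0)
    p2 = np.clip(p2, 0.0, 1.0)
    total = p0 + p1 + p2
    total = np.where(total == 0, 1.0, total)
    p1 = p1 / total
    p2 = p2 / total
    return np.clip(p2 + 0.5 * p1, 0.0, 1.0)


def estimate_pi_hat(panel: GenotypePanel, i: int, j: int, min_overlap: int = 200) -> float:
    """PI_HAT between two samples from IBS counts and panel allele frequencies."""
    gi, gj = panel.dosage[i], panel.dosage[j]
    valid = ~np.isnan(gi) & ~np.isnan(gj)
    if valid.sum() < min_overlap:
        raise DataError(
            f"only {int(valid.sum())} overlapping non-missing variants "
            f"(need >= {min_overlap})"
        )
    freq = panel.allele_freq()[valid]
    diff = np.abs(gi[valid] - gj[valid])
    ibs0 = float((diff == 2).sum())
    ibs1 = float((diff == 1).sum())
    ibs2 = float((diff == 0).sum())
    e = _ibd_expectations(freq)
    return float(
        _pi_hat_from_counts(
            ibs0, ibs1, ibs2,
            e["e0_ibd0"].sum(), e["e1_ibd0"].sum(), e["e1_ibd1"].sum(),
            e["e2_ibd0"].sum(), e["e2_ibd1"].sum(), float(valid.sum()),
        )
    )


def pairwise_pi_hat(panel: GenotypePanel) -> np.ndarray:
    """Full PI_HAT matrix, vectorized via genotype-indicator matmuls."""
    d = panel.dosage
    valid = ~np.isnan(d)
    ind = [np.where(valid & (d == v), 1.0, 0.0) for v in (0.0, 1.0, 2.0)]
    counts = {(a, b): ind[a] @ ind[b].T for a in range(3) for b in range(3)}
    ibs2 = counts[(0, 0)] + counts[(1, 1)] + counts[(2, 2)]
    ibs0 = counts[(0, 2)] + counts[(2, 0)]
    vmat = valid.astype(float)
    n_valid = vmat @ vmat.T
    ibs1 = n_valid - ibs2 - ibs0
    freq = panel.allele_freq()
    e = _ibd_expectations(np.nan_to_num(freq, nan=0.0))
    # exact per-pair expectation sums over the pair's non-missing variants
    E = {k: (vmat * v[None, :]) @ vmat.T for k, v in e.items()}
    pi = _pi_hat_from_counts(
        ibs0, ibs1, ibs2,
        E["e0_ibd0"], E["e1_ibd0"], E["e1_ibd1"], E["e2_ibd0"], E["e2_ibd1"],
        np.maximum(n_valid, 1.0),
    )
    np.fill_diagonal(pi, 0.0)
    return pi


def filter_samples(
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    thresholds: QcThresholds = ADNI_PRESET,
) -> tuple[GenotypePanel, pd.DataFrame, pd.DataFrame]:
    """Sequential sample-level filters with per-sample reason accounting.

    Order: sex mismatch, relatedness (PI_HAT above threshold; of each pair
    the lower-call-rate member is removed, ties broken toward the
    lexicographically larger id), heterozygosity beyond mean +/- ``het_sd``
    SD, then call rate.  Each removed sample carries exactly one reason, so
    ``n_in = n_out + sum(per-reason removals)``.
    """
    n = panel.n_samples
    ids = list(panel.samples)
    call_rate = panel.sample_call_rate()
    het = panel.het_rate()
    removed_reason: dict[str, str] = {}
    active = np.ones(n, dtype=bool)

    if "sex_reported" in cohort.columns and "sex_genetic" in cohort.columns:
        rep = cohort.set_index("sample_id").loc[ids, "sex_reported"].to_numpy()
        gen = cohort.set_index("sample_id").loc[ids, "sex_genetic"].to_numpy()
        mismatch = (gen != "unknown") & (rep != gen)
        for i in np.where(mismatch)[0]:
            removed_reason[ids[i]] = "sex_mismatch"
            active[i] = False

    pi = pairwise_pi_hat(panel)
    max_pi = pi.max(axis=1, initial=0.0)
    pairs = np.argwhere(np.triu(pi > thresholds.pi_hat, k=1))
    # deterministic resolution order: strongest sharing first
    pairs = sorted(map(tuple, pairs), key=lambda ij: (-pi[ij], ids[ij[0]], ids[ij[1]]))
    for i, j in pairs:
        if not (active[i] and active[j]):
            continue
        if call_rate[i] < call_rate[j]:
            drop = i
        elif call_rate[j] < call_rate[i]:
            drop = j
        else:
            drop = i if ids[i] > ids[j] else j
        removed_reason[ids[drop]] = "relatedness"
        active[drop] = False

    het_active = het[active]
    mu, sd = float(np.nanmean(het_active)), float(np.nanstd(het_active))
    for i in np.where(active)[0]:
        if sd > 0 and abs(het[i] - mu) > thresholds.het_sd * sd:
            removed_reason[ids[i]] = "heterozygosity"
            active[i] = False

    for i in np.where(active)[0]:
        if call_rate[i] < thresholds.sample_call_rate:
            removed_reason[ids[i]] = "call_rate"
            active[i] = False

    report = pd.DataFrame(
        {
            "sample_id": ids,
            "call_rate": call_rate,
            "het_rate": het,
            "max_pi_hat": max_pi,
            "removed": ~active,
            "reason": [removed_reason.get(s, "") for s in ids],
        }
    )
    panel_out = panel.subset(sample_mask=active)
    kept_ids = set(panel_out.samples)
    cohort_out = cohort[cohort["sample_id"].isin(kept_ids)].reset_index(drop=True)
    return panel_out, cohort_out, report


def compute_pcs(panel: GenotypePanel, k: int = 4) -> np.ndarray:
    """Top-k principal-component scores of the standardized dosage matrix.

    Missing dosages are mean-imputed; each variant is scaled to unit
    variance (zero-variance variants are dropped from the decomposition).
    Sign convention: the largest-magnitude variant loading of each
    component is positive.
    """
    if k < 0:
        raise ConfigurationError(f"k must be non-negative, got {k}")
    if k > min(panel.n_samples, panel.n_variants):
        raise ConfigurationError(
            f"k={k} exceeds min(n_samples, n_variants)="
            f"{min(panel.n_samples, panel.n_variants)}"
        )
    if k == 0:
        return np.zeros((panel.n_samples, 0))
    g = panel.imputed_dosage()
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    keep = sd > 0
    z = (g[:, keep] - mu[keep]) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for c in range(k):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            scores[:, c] *= -1.0
    return scores


def flag_pca_outliers(scores: np.ndarray, sd: float = 6.0, n_components: int = 4) -> np.ndarray:
    """Samples beyond ``sd`` standard deviations on any leading component."""
    use = scores[:, : min(n_components, scores.shape[1])]
    if use.shape[1] == 0:
        return np.zeros(scores.shape[0], dtype=bool)
    z = (use - use.mean(axis=0)) / np.where(use.std(axis=0) > 0, use.std(axis=0), 1.0)
    return (np.abs(z) > sd).any(axis=1)


def preset(name: str) -> QcThresholds:
    try:
        return PRESETS[name.lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown QC preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
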