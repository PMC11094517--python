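"""Synthetic discovery GWAS and target-cohort generator.

The downstream pipeline (QC -> clumping+thresholding PRS -> conversion
prediction -> regional brain scan -> one-sample MR) was designed for
restricted clinical genotype data.  This module generates a statistically
analogous stand-in: LD-blocked biallelic genotypes, marginal discovery
summary statistics estimated on an explicitly simulated discovery cohort
(so LD tagging of marginal effects is real, not closed-form noise), and a
target cohort in which a polygenic liability drives conversion partly
through a designated "mediator" brain region whose surface area loads
negatively on the true score.

LD model
--------
Haplotypes are generated blockwise by a first-order allele-copying Markov
chain: within a block every variant shares one allele frequency ``f`` drawn
from ``maf_range``; the first variant of each haplotype is Bernoulli(f) and
each subsequent allele copies its left neighbour with probability
``ld_copy_prob`` (else a fresh Bernoulli(f) draw).  Because all variants in
a block share ``f``, the chain preserves marginal frequencies exactly and
the haplotype-allele correlation between variants ``d`` apart is
``ld_copy_prob ** d``, so dosage r^2 decays geometrically within a block and
is zero across blocks.  Variants sit on one synthetic chromosome at a fixed
10 kb spacing, so a 250 kb clumping window spans 25 variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .panel import GenotypePanel

VARIANT_SPACING_BP = 10_000

_NONAMBIGUOUS_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

MEASURES = ("surface_area", "thickness", "volume")


@dataclass
class QcViolationRates:
    """Per-filter injection probabilities for :func:`inject_qc_violations`."""

    sex_flip: float = 0.0
    duplicate: float = 0.0
    first_degree: float = 0.0
    excess_het: float = 0.0
    missingness: float = 0.0

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if not 0.0 <= value <= 0.5:
                raise ConfigurationError(
                    f"qc_violation_rates.{name} must be in [0, 0.5], got {value}"
                )


@dataclass
class SimConfig:
    """Generator configuration.

    The defaults describe the emulated study: a target cohort of 304
    patients aged ~75 +/- 7 years followed for conversion over 10 years, a
    discovery GWAS of 5,000 samples, and a mediation chain in which one
    region's surface area carries part of the score's effect on conversion.

    Parameters
    ----------
    gamma_med:
        Effect (per SD of the true score) on the mediator region's surface
        area; applied with a negative sign, so positive values mean a higher
        score shrinks the region.
    beta_med_out, beta_direct:
        Log-odds effects of the mediator and of the score itself on 1-year
        conversion.
    base_rate:
        Baseline 1-year conversion probability at covariate means.
    """

    n_target: int = 304
    n_discovery: int = 5000
    n_variants: int = 10000
    n_blocks: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_copy_prob: float = 0.8
    n_causal: int = 50
    h2: float = 0.3
    gamma_med: float = 0.7
    beta_med_out: float = -1.0
    beta_direct: float = 0.5
    base_rate: float = 0.12
    n_regions: int = 130
    n_sites: int = 6
    missing_rate: float = 0.002
    qc_violation_rates: QcViolationRates = field(default_factory=QcViolationRates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_target < 1:
            raise ConfigurationError(f"n_target must be >= 1, got {self.n_target}")
        if self.n_variants < 1:
            raise ConfigurationError(f"n_variants must be >= 1, got {self.n_variants}")
        if not 1 <= self.n_blocks <= self.n_variants:
            raise ConfigurationError(
                f"n_blocks must be in [1, n_variants], got {self.n_blocks}"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range bounds must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not 0.0 <= self.ld_copy_prob < 1.0:
            raise ConfigurationError(f"ld_copy_prob must be in [0, 1), got {self.ld_copy_prob}")
        if not 0 <= self.n_causal <= self.n_variants:
            raise ConfigurationError(f"n_causal must be in [0, n_variants], got {self.n_causal}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigurationError(f"h2 must be in [0, 1], got {self.h2}")
        if not 0.0 < self.base_rate < 1.0:
            raise ConfigurationError(f"base_rate must be in (0, 1), got {self.base_rate}")
        if self.n_regions < 1:
            raise ConfigurationError(f"n_regions must be >= 1, got {self.n_regions}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        self.qc_violation_rates.validate()


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # Independent streams keyed on (stream id, seed) so that e.g. variant
    # metadata is identical between the target and discovery panels.
    return np.random.default_rng([stream, cfg.seed & 0x7FFFFFFF])


def _block_structure(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Block sizes (summing to n_variants) and per-block allele frequencies."""
    rng = _rng(cfg, 0)
    base = cfg.n_variants // cfg.n_blocks
    sizes = np.full(cfg.n_blocks, base, dtype=int)
    sizes[: cfg.n_variants - base * cfg.n_blocks] += 1
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_blocks)
    return sizes, freqs


def variant_metadata(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic variant table shared by target and discovery panels."""
    sizes, freqs = _block_structure(cfg)
    rng = _rng(cfg, 7)
    pair_idx = rng.integers(0, len(_NONAMBIGUOUS_PAIRS), size=cfg.n_variants)
    a1 = np.array([_NONAMBIGUOUS_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_NONAMBIGUOUS_PAIRS[i][1] for i in pair_idx])
    block = np.repeat(np.arange(cfg.n_blocks), sizes)
    return pd.DataFrame(
        {
            "variant_id": [f"snp{j + 1:05d}" for j in range(cfg.n_variants)],
            "chrom": "1",
            "pos": VARIANT_SPACING_BP * (np.arange(cfg.n_variants) + 1),
            "a1": a1,
            "a2": a2,
            "block": block,
            "freq": np.repeat(freqs, sizes),
        }
    )


def _sim_haplotypes(
    rng: np.random.Generator, n: int, sizes: np.ndarray, freqs: np.ndarray, copy_prob: float
) -> np.ndarray:
    m = int(sizes.sum())
    hap = np.empty((n, 2, m), dtype=np.int8)
    col = 0
    for size, f in zip(sizes, freqs):
        hap[:, :, col] = rng.random((n, 2)) < f
        for j in range(1, size):
            fresh = (rng.random((n, 2)) < f).astype(np.int8)
            copy = rng.random((n, 2)) < copy_prob
            hap[:, :, col + j] = np.where(copy, hap[:, :, col + j - 1], fresh)
        col += size
    return hap


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Simulate the target cohort's LD-blocked biallelic genotype panel.

    Dosages count the ``a1`` allele; a small fraction ``missing_rate`` of
    calls is set missing.  Haplotypes are retained on the panel so that
    :func:`inject_qc_violations` can construct relatives.
    """
    cfg.validate()
    sizes, freqs = _block_structure(cfg)
    meta = variant_metadata(cfg)
    hap = _sim_haplotypes(_rng(cfg, 1), cfg.n_target, sizes, freqs, cfg.ld_copy_prob)
    dosage = hap.sum(axis=1).astype(float)
    if cfg.missing_rate > 0:
        mask = _rng(cfg, 2).random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan
    samples = [f"tgt{i + 1:04d}" for i in range(cfg.n_target)]
    return GenotypePanel(dosage, meta, samples, haplotypes=hap)


def draw_true_betas(cfg: SimConfig) -> np.ndarray:
    """Per-variant true effects: N(0,1) draws at ``n_causal`` random variants,
    rescaled so the *analytic* variance of the genetic score equals ``h2``.

    The variance accounts for within-block LD:
    ``Var = sum_jk b_j b_k rho^|j-k| * 2 f (1-f)`` with
    ``rho = ld_copy_prob`` inside a block and 0 across blocks.
    """
    cfg.validate()
    rng = _rng(cfg, 4)
    betas = np.zeros(cfg.n_variants)
    if cfg.n_causal == 0 or cfg.h2 == 0:
        return betas
    causal = rng.choice(cfg.n_variants, size=cfg.n_causal, replace=False)
    betas[causal] = rng.normal(0.0, 1.0, size=cfg.n_causal)
    meta = variant_metadata(cfg)
    var = 0.0
    for b in range(cfg.n_blocks):
        idx = np.where(meta["block"].to_numpy() == b)[0]
        bb = betas[idx]
        if not np.any(bb):
            continue
        f = float(meta["freq"].iloc[idx[0]])
        d = np.abs(np.subtract.outer(np.arange(len(idx)), np.arange(len(idx))))
        rho = cfg.ld_copy_prob ** d
        var += 2.0 * f * (1.0 - f) * float(bb @ rho @ bb)
    if var <= 0:
        return betas
    betas *= np.sqrt(cfg.h2 / var)
    return betas


def _simulate_discovery(cfg: SimConfig, true_betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Discovery dosage matrix and continuous phenotype with heritability h2."""
    sizes, freqs = _block_structure(cfg)
    rng = _rng(cfg, 3)
    hap = _sim_haplotypes(rng, cfg.n_discovery, sizes, freqs, cfg.ld_copy_prob)
    dosage = hap.sum(axis=1, dtype=np.float32)
    genetic = dosage @ true_betas
    noise_sd = np.sqrt(max(1.0 - cfg.h2, 0.0))
    y = genetic + rng.normal(0.0, noise_sd, size=cfg.n_discovery)
    return dosage, y


def simulate_discovery_summary(cfg: SimConfig, true_betas: np.ndarray) -> pd.DataFrame:
    """Marginal per-variant GWAS summary statistics from an explicit
    discovery cohort.

    Each variant's BETA/SE/P come from a simple least-squares regression of
    the simulated continuous phenotype on that variant's dosage alone, so
    marginal effects at non-causal variants reflect LD tagging.  BETA is
    oriented to the ``A1`` (counted) allele.
    """
    cfg.validate()
    if cfg.n_discovery < 50:
        raise ConfigurationError(
            f"n_discovery must be >= 50 for stable standard errors, got {cfg.n_discovery}"
        )
    true_betas = np.asarray(true_betas, dtype=float)
    if true_betas.shape != (cfg.n_variants,):
        raise ConfigurationError("true_betas must have length n_variants")
    dosage, y = _simulate_discovery(cfg, true_betas)
    n = cfg.n_discovery
    gc = dosage - dosage.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-300), 0.0)
        rss = syy - slope * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / np.maximum(sxx, 1e-300))
        se = np.where(sxx > 0, se, np.inf)
        t = np.where(se > 0, slope / se, 0.0)
    from scipy import stats

    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    meta = variant_metadata(cfg)
    return pd.DataFrame(
        {
            "SNP": meta["variant_id"],
            "CHR": meta["chrom"],
            "BP": meta["pos"],
            "A1": meta["a1"],
            "A2": meta["a2"],
            "BETA": slope,
            "SE": se,
            "P": p,
        }
    )


def true_score(panel: GenotypePanel, true_betas: np.ndarray) -> np.ndarray:
    """Standardized true polygenic score of the panel samples."""
    s = panel.imputed_dosage() @ np.asarray(true_betas, dtype=float)
    sd = s.std()
    if sd == 0:
        return np.zeros_like(s)
    return (s - s.mean()) / sd


def simulate_target_cohort(
    cfg: SimConfig, panel: GenotypePanel, true_betas: np.ndarray
) -> pd.DataFrame:
    """Covariates, regional brain measures and conversion outcomes.

    The designated mediator region's surface area is
    ``-gamma_med * S + covariate loadings + N(0,1)`` where ``S`` is the
    standardized true score; all other region-by-measure columns are unit
    noise.  Conversion follows
    ``logit(P_1yr) = logit(base_rate) + beta_med_out*M + beta_direct*S +
    covariate terms``; time-to-event is exponential with the per-sample rate
    chosen so that ``P(T <= 1) = P_1yr``, censored at 10 years.

    Returns a cohort table whose ``attrs`` record the mediator region name
    and the true score.
    """
    cfg.validate()
    rng = _rng(cfg, 5)
    n = panel.n_samples
    s = true_score(panel, true_betas)

    age = rng.normal(75.02, 7.20, size=n)
    male = rng.random(n) < 201 / 304
    sex = np.where(male, "male", "female")
    site = np.array([f"S{i + 1}" for i in rng.integers(0, cfg.n_sites, size=n)])
    edu = np.clip(np.round(rng.normal(15.7, 3.0, size=n)), 6, 20).astype(int)
    apoe4 = rng.choice([0, 1, 2], size=n, p=[0.43, 0.44, 0.13])

    cohort = pd.DataFrame(
        {
            "sample_id": panel.samples,
            "sex_reported": sex,
            "sex_genetic": sex,
            "age": age,
            "site": site,
            "education_years": edu,
            "apoe4_count": apoe4,
        }
    )

    mediator_idx = int(rng.integers(cfg.n_regions))
    mediator_region = f"region_{mediator_idx + 1:03d}"
    region_cols = {}
    for r in range(cfg.n_regions):
        name = f"region_{r + 1:03d}"
        for measure in MEASURES:
            noise = rng.normal(0.0, 1.0, size=n)
            if r == mediator_idx and measure == "surface_area":
                values = (
                    -cfg.gamma_med * s
                    + 0.10 * male.astype(float)
                    - 0.02 * (age - 75.02)
                    + noise
                )
            else:
                values = noise
            region_cols[f"{name}_{measure}"] = values
    cohort = pd.concat([cohort, pd.DataFrame(region_cols, index=cohort.index)], axis=1)

    m = cohort[f"{mediator_region}_surface_area"].to_numpy()
    # covariate terms are centered so base_rate is the conversion
    # probability at covariate means
    lp = (
        np.log(cfg.base_rate / (1.0 - cfg.base_rate))
        + cfg.beta_med_out * m
        + cfg.beta_direct * s
        + 0.02 * (age - 75.02)
        + 0.35 * (apoe4 - 0.70)
        + 0.10 * (male.astype(float) - 201 / 304)
        - 0.02 * (edu - 15.7)
    )
    p1 = 1.0 / (1.0 + np.exp(-lp))
    # Exponential waiting time whose 1-year CDF equals the logistic probability.
    rate = -np.log1p(-np.clip(p1, 1e-12, 1 - 1e-12))
    t_event = rng.exponential(1.0 / rate)
    cohort["conversion_1yr"] = (t_event <= 1.0).astype(int)
    cohort["conversion_10yr"] = (t_event <= 10.0).astype(int)
    cohort["event_observed"] = (t_event <= 10.0).astype(int)
    cohort["time_to_event"] = np.minimum(t_event, 10.0)

    cohort.attrs["mediator_region"] = mediator_region
    cohort.attrs["true_score"] = s
    return cohort


def inject_qc_violations(
    panel: GenotypePanel, cohort: pd.DataFrame, cfg: SimConfig
) -> tuple[GenotypePanel, pd.DataFrame, pd.DataFrame]:
    """Plant QC failures with ground-truth labels.

    Applies, at the configured rates: reported-sex flips; genotype-row
    duplication with a 0.5% mutation rate (expected PI_HAT near 1);
    first-degree relatives built by giving the target one haplotype from the
    source plus one fresh haplotype (expected PI_HAT near 0.5);
    heterozygosity inflation; and per-sample masking pushing missingness
    above 3%.  Returns modified copies and a truth table
    ``(sample_id, violation, partner)``.
    """
    cfg.validate()
    rates = cfg.qc_violation_rates
    panel = panel.copy()
    cohort = cohort.copy()
    rng = _rng(cfg, 6)
    n = panel.n_samples
    records: list[dict] = []
    used: set[int] = set()

    def _pick(k: int) -> np.ndarray:
        free = np.array([i for i in range(n) if i not in used])
        if len(free) < k:
            raise DataError("not enough unused samples for requested violation rates")
        chosen = rng.choice(free, size=k, replace=False)
        used.update(int(i) for i in chosen)
        return chosen

    k_flip = int(round(rates.sex_flip * n))
    for i in _pick(k_flip) if k_flip else []:
        current = cohort.iloc[i, cohort.columns.get_loc("sex_reported")]
        cohort.iloc[i, cohort.columns.get_loc("sex_reported")] = (
            "female" if current == "male" else "male"
        )
        records.append({"sample_id": panel.samples[i], "violation": "sex_flip", "partner": ""})

    sizes, freqs = _block_structure(cfg)
    freq_per_variant = np.repeat(freqs, sizes)

    def _overwrite(target: int, dosage_row: np.ndarray, hap_row: np.ndarray | None) -> None:
        panel.dosage[target] = dosage_row
        if panel.haplotypes is not None and hap_row is not None:
            panel.haplotypes[target] = hap_row

    k_dup = int(round(rates.duplicate * n / 2))
    for _ in range(k_dup):
        src, tgt = _pick(2)
        row = panel.dosage[src].copy()
        mut = rng.random(panel.n_variants) < 0.005
        row[mut] = rng.binomial(2, freq_per_variant[mut]).astype(float)
        hap = None if panel.haplotypes is None else panel.haplotypes[src].copy()
        _overwrite(tgt, row, hap)
        records.append({"sample_id": panel.samples[tgt], "violation": "duplicate",
                        "partner": panel.samples[src]})

    k_rel = int(round(rates.first_degree * n / 2))
    for _ in range(k_rel):
        src, tgt = _pick(2)
        if panel.haplotypes is not None:
            shared = panel.haplotypes[src, rng.integers(2)].copy()
        else:
            shared = (rng.random(panel.n_variants) < freq_per_variant).astype(np.int8)
        fresh = (rng.random(panel.n_variants) < freq_per_variant).astype(np.int8)
        row = (shared + fresh).astype(float)
        hap = np.stack([shared, fresh]) if panel.haplotypes is not None else None
        _overwrite(tgt, row, hap)
        records.append({"sample_id": panel.samples[tgt], "violation": "first_degree",
                        "partner": panel.samples[src]})

    k_het = int(round(rates.excess_het * n))
    for i in _pick(k_het) if k_het else []:
        hom = np.where(np.isin(panel.dosage[i], [0.0, 2.0]))[0]
        flip = rng.choice(hom, size=int(0.4 * len(hom)), replace=False)
        panel.dosage[i, flip] = 1.0
        records.append({"sample_id": panel.samples[i], "violation": "excess_het", "partner": ""})

    k_miss = int(round(rates.missingness * n))
    for i in _pick(k_miss) if k_miss else []:
        mask = rng.random(panel.n_variants) < 0.05
        panel.dosage[i, mask] = np.nan
        records.append({"sample_id": panel.samples[i], "violation": "missingness", "partner": ""})

    truth = pd.DataFrame(records, columns=["sample_id", "violation", "partner"])
    return panel, cohort, truth
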