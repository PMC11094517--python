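"""In-memory genotype container used throughout the pipeline.

A :class:`GenotypePanel` holds a sample-by-variant dosage matrix (counted
allele copies, ``NaN`` for missing calls) together with per-variant metadata.
Dosages count the ``a1`` allele (the VCF ALT allele when round-tripped
through VCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

#: Columns every variant-metadata table carries.
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "a1", "a2"]

AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


def is_ambiguous(a1: str, a2: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T or C/G)."""
    return {a1, a2} in AMBIGUOUS_PAIRS


@dataclass
class GenotypePanel:
    """Sample x variant dosage matrix plus variant metadata.

    Parameters
    ----------
    dosage:
        ``(n_samples, n_variants)`` float array with entries in ``{0, 1, 2}``
        and ``NaN`` for missing genotypes.
    variants:
        DataFrame with at least :data:`VARIANT_COLUMNS`; simulated panels also
        carry ``block`` and ``freq`` (the generating allele frequency).
    samples:
        Sample identifiers, aligned with dosage rows.
    haplotypes:
        Optional ``(n_samples, 2, n_variants)`` int8 haplotype array kept by
        the simulator so that relatives can be constructed.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise DataError("dosage must be 2-dimensional (samples x variants)")
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise DataError(f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.variants) != m:
            raise DataError(f"{len(self.variants)} variant rows for {m} dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise DataError(f"variant table missing columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Counted-allele (a1) frequency per variant among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=1)

    def het_rate(self) -> np.ndarray:
        """Observed heterozygosity fraction per sample (among non-missing)."""
        het = (self.dosage == 1).sum(axis=1)
        valid = (~np.isnan(self.dosage)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(valid > 0, het / valid, np.nan)

    def imputed_dosage(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by 2 x allele frequency."""
        filled = self.dosage.copy()
        freq = self.allele_freq()
        nan_r, nan_c = np.where(np.isnan(filled))
        filled[nan_r, nan_c] = 2.0 * freq[nan_c]
        return filled

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Boolean-mask subsetting along either axis; returns a new panel."""
        dosage = self.dosage
        variants = self.variants
        samples = self.samples
        haps = self.haplotypes
        if variant_mask is not None:
            variant_mask = np.asarray(variant_mask, dtype=bool)
            dosage = dosage[:, variant_mask]
            variants = variants.loc[variant_mask].reset_index(drop=True)
            if haps is not None:
                haps = haps[:, :, variant_mask]
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask, dtype=bool)
            dosage = dosage[sample_mask]
            samples = [s for s, keep in zip(samples, sample_mask) if keep]
            if haps is not None:
                haps = haps[sample_mask]
        return GenotypePanel(dosage.copy(), variants.copy(), list(samples),
                             None if haps is None else haps.copy())

    def copy(self) -> "GenotypePanel":
        return replace(
            self,
            dosage=self.dosage.copy(),
            variants=self.variants.copy(),
            samples=list(self.samples),
            haplotypes=None if self.haplotypes is None else self.haplotypes.copy(),
        )
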