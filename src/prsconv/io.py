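"""Plain-text readers and writers for panels, summary statistics and cohorts.

Genotypes round-trip through VCF (biallelic SNVs, GT plus a DS dosage
field, REF = other allele, ALT = counted allele) or a tab-separated dosage
matrix (samples x variants, ``NA`` for missing).  Summary statistics use
the conventional ``SNP CHR BP A1 A2 BETA SE P`` header.  A JSON sidecar
records the generating configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .panel import GenotypePanel

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(panel: GenotypePanel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Counted-allele dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        v = panel.variants
        for j in range(panel.n_variants):
            fields = [
                str(v["chrom"].iloc[j]), str(int(v["pos"].iloc[j])),
                str(v["variant_id"].iloc[j]),
                str(v["a2"].iloc[j]), str(v["a1"].iloc[j]), ".", "PASS", ".", "GT:DS",
            ]
            col = panel.dosage[:, j]
            calls = [
                "./.:." if np.isnan(d) else f"{_GT[int(d)]}:{d:g}" for d in col
            ]
            fh.write("\t".join(fields + calls) + "\n")


def read_vcf(path) -> GenotypePanel:
    """Read a biallelic SNV VCF into a panel (GT field, counted = ALT)."""
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise DataError(f"genotype file not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta_rows = []
    dosage_rows = []
    # cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN/missing, 3 HOM_ALT
    gt_to_dosage = np.array([0.0, 1.0, np.nan, 2.0])
    for record in vcf:
        if len(record.ALT) != 1:
            continue
        meta_rows.append(
            (record.ID, record.CHROM, record.POS, record.ALT[0], record.REF)
        )
        dosage_rows.append(gt_to_dosage[record.gt_types])
    if not samples or not meta_rows:
        raise DataError(f"no usable records in VCF: {path}")
    variants = pd.DataFrame(meta_rows, columns=["variant_id", "chrom", "pos", "a1", "a2"])
    return GenotypePanel(np.array(dosage_rows).T, variants, samples)


def write_dosage_tsv(panel: GenotypePanel, path) -> None:
    """Dosage matrix with a variant-metadata header block.

    First five columns describe the variant; remaining columns are samples.
    """
    v = panel.variants[["variant_id", "chrom", "pos", "a1", "a2"]].copy()
    mat = pd.DataFrame(
        panel.dosage.T, columns=panel.samples, index=v.index
    )
    pd.concat([v, mat], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> GenotypePanel:
    path = Path(path)
    if not path.exists():
        raise DataError(f"genotype file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["variant_id", "chrom", "pos", "a1", "a2"]
    if df.columns[:5].tolist() != meta_cols:
        raise DataError(f"dosage table must start with columns {meta_cols}")
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    samples = df.columns[5:].tolist()
    dosage = df[samples].to_numpy(dtype=float).T
    return GenotypePanel(dosage, variants, samples)


def write_summary_tsv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False)


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"cohort file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise DataError("cohort table must carry a sample_id column")
    return df


def write_sidecar(config, path, **extra) -> None:
    """JSON sidecar recording the generating config (dataclasses accepted)."""
    payload = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
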