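"""End-to-end orchestration: simulate -> qc -> prs -> predict -> brain -> mr.

Each stage reads its inputs from (and writes its reports into) one run
directory, so stages are resumable from prior outputs.  Every stage writes
a ``manifest_<stage>.json`` with the config hash, seed, package version and
input checksums; manifests carry no timestamps, so identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import brain as brain_mod
from . import io, mr, prs, qc
from .errors import ConfigurationError, DataError
from .models import chisq_independence, cox_fit, logistic_fit, stratify_groups
from .simulate import (
    SimConfig,
    draw_true_betas,
    inject_qc_violations,
    simulate_discovery_summary,
    simulate_genotypes,
    simulate_target_cohort,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "prs", "predict", "brain", "mr")


@dataclass
class RunConfig:
    """Flat pipeline configuration; unknown keys in a config file are an error."""

    outdir: str = "prsconv_run"
    stages: tuple[str, ...] = STAGES
    qc_preset: str = "adni"
    grid_step: float = 0.001
    n_perm: int = 200
    horizon: int = 1
    fdr_family: str = "joint"
    apply_outlier_trim: bool = True
    n_pcs: int = 4
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ConfigurationError(f"unknown stage {s!r}; valid: {STAGES}")
        if self.horizon not in (1, 10):
            raise ConfigurationError(f"horizon must be 1 or 10 (years), got {self.horizon}")
        if not 0 < self.grid_step <= 1:
            raise ConfigurationError(f"grid_step must be in (0, 1], got {self.grid_step}")
        self.sim.seed = self.seed

    def grid(self) -> np.ndarray:
        n = int(round(1.0 / self.grid_step))
        return np.round(np.arange(1, n + 1) * self.grid_step, 9)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        run_fields = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        sim_kwargs, run_kwargs = {}, {}
        for key, value in mapping.items():
            if key in run_fields:
                run_kwargs[key] = value
            elif key in sim_fields:
                sim_kwargs[key] = value
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        if "stages" in run_kwargs and isinstance(run_kwargs["stages"], str):
            run_kwargs["stages"] = tuple(run_kwargs["stages"].split(","))
        if "maf_range" in sim_kwargs:
            sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
        return cls(sim=SimConfig(**sim_kwargs), **run_kwargs)


def _config_hash(cfg: RunConfig) -> str:
    payload = dataclasses.asdict(cfg)
    payload.pop("outdir")  # where a run lives is not part of its identity
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, stage: str, inputs: list[Path], outputs: list[Path]) -> None:
    outdir = Path(cfg.outdir)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "inputs": {p.name: io.sha256_of(p) for p in inputs if p.exists()},
        "outputs": {p.name: io.sha256_of(p) for p in outputs if p.exists()},
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _require(path: Path) -> Path:
    if not path.exists():
        raise DataError(f"required input missing: {path}")
    return path


def covariate_design(cohort: pd.DataFrame, pcs: np.ndarray | None = None) -> pd.DataFrame:
    """Standard covariate matrix: sex, age, site dummies, education,
    APOE e4 count and the leading principal components."""
    design = pd.DataFrame(index=cohort.index)
    design["sex_male"] = (cohort["sex_reported"] == "male").astype(float)
    design["age"] = cohort["age"].astype(float)
    site = pd.get_dummies(cohort["site"], prefix="site", drop_first=True, dtype=float)
    design = pd.concat([design, site], axis=1)
    design["education_years"] = cohort["education_years"].astype(float)
    design["apoe4_count"] = cohort["apoe4_count"].astype(float)
    if pcs is not None:
        for c in range(pcs.shape[1]):
            design[f"pc{c + 1}"] = pcs[:, c]
    return design


def stage_simulate(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim
    panel = simulate_genotypes(sim)
    betas = draw_true_betas(sim)
    summary = simulate_discovery_summary(sim, betas)
    cohort = simulate_target_cohort(sim, panel, betas)
    panel, cohort, truth = inject_qc_violations(panel, cohort, sim)

    io.write_dosage_tsv(panel, outdir / "genotypes.tsv")
    io.write_vcf(panel, outdir / "genotypes.vcf")
    io.write_summary_tsv(summary, outdir / "gwas_summary.tsv")
    io.write_cohort_tsv(cohort, outdir / "cohort.tsv")
    truth.to_csv(outdir / "qc_truth.tsv", sep="\t", index=False)
    io.write_sidecar(
        sim,
        outdir / "simulate_config.json",
        mediator_region=cohort.attrs["mediator_region"],
    )
    _write_manifest(cfg, "simulate", [], [
        outdir / "genotypes.tsv", outdir / "genotypes.vcf",
        outdir / "gwas_summary.tsv", outdir / "cohort.tsv",
        outdir / "qc_truth.tsv", outdir / "simulate_config.json",
    ])


def stage_qc(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    geno = _require(outdir / "genotypes.tsv")
    coh = _require(outdir / "cohort.tsv")
    panel = io.read_dosage_tsv(geno)
    cohort = io.read_cohort_tsv(coh)
    thresholds = qc.preset(cfg.qc_preset)
    panel_v, variant_report = qc.filter_variants(panel, thresholds)
    panel_s, cohort_s, sample_report = qc.filter_samples(panel_v, cohort, thresholds)
    pcs = qc.compute_pcs(panel_s, cfg.n_pcs)
    pcs_df = pd.DataFrame(pcs, columns=[f"pc{c + 1}" for c in range(pcs.shape[1])])
    pcs_df.insert(0, "sample_id", panel_s.samples)

    variant_report.to_csv(outdir / "variant_qc.tsv", sep="\t", index=False)
    sample_report.to_csv(outdir / "sample_qc.tsv", sep="\t", index=False)
    io.write_dosage_tsv(panel_s, outdir / "genotypes_qc.tsv")
    io.write_cohort_tsv(cohort_s, outdir / "cohort_qc.tsv")
    pcs_df.to_csv(outdir / "pcs.tsv", sep="\t", index=False)
    _write_manifest(cfg, "qc", [geno, coh], [
        outdir / "variant_qc.tsv", outdir / "sample_qc.tsv",
        outdir / "genotypes_qc.tsv", outdir / "cohort_qc.tsv", outdir / "pcs.tsv",
    ])


def _load_qc_outputs(cfg: RunConfig):
    outdir = Path(cfg.outdir)
    panel = io.read_dosage_tsv(_require(outdir / "genotypes_qc.tsv"))
    cohort = io.read_cohort_tsv(_require(outdir / "cohort_qc.tsv"))
    pcs_df = pd.read_csv(_require(outdir / "pcs.tsv"), sep="\t")
    pcs = pcs_df.drop(columns="sample_id").to_numpy(dtype=float)
    return panel, cohort, pcs


def stage_prs(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    summary = prs.read_gwas_summary(_require(outdir / "gwas_summary.tsv"))
    panel, cohort, pcs = _load_qc_outputs(cfg)
    outcome = cohort[f"conversion_{cfg.horizon}yr"].to_numpy(dtype=float)
    covariates = covariate_design(cohort, pcs)

    weights = prs.align_alleles(summary, panel)
    clumped = prs.clump(weights, panel)
    profile = prs.sweep_and_select(panel, clumped, outcome, covariates, cfg.grid())
    profile.permutation_p = prs.permutation_correct(
        panel, clumped, outcome, covariates, profile.best_r2,
        cfg.grid(), n_perm=cfg.n_perm, seed=cfg.seed,
    )

    profile.per_threshold.to_csv(outdir / "prs_thresholds.tsv", sep="\t", index=False)
    scores = pd.DataFrame(
        {
            "sample_id": panel.samples,
            "raw_score": profile.best_raw,
            "z_score": profile.best_z,
            "n_variants": profile.n_variants_best,
            "outlier": profile.outlier_mask.astype(int),
        }
    )
    scores.to_csv(outdir / "prs_scores.tsv", sep="\t", index=False)
    best = {
        "best_p_t": profile.best_p_t,
        "best_r2": profile.best_r2,
        "n_variants_best": profile.n_variants_best,
        "n_clumped": len(clumped),
        "n_aligned": len(weights),
        "permutation_p": profile.permutation_p,
        "n_outliers": int(profile.outlier_mask.sum()),
    }
    (outdir / "prs_best.json").write_text(json.dumps(best, indent=2, sort_keys=True) + "\n")
    _write_manifest(cfg, "prs", [
        outdir / "gwas_summary.tsv", outdir / "genotypes_qc.tsv",
        outdir / "cohort_qc.tsv", outdir / "pcs.tsv",
    ], [outdir / "prs_thresholds.tsv", outdir / "prs_scores.tsv", outdir / "prs_best.json"])


def _load_scores(cfg: RunConfig):
    outdir = Path(cfg.outdir)
    scores = pd.read_csv(_require(outdir / "prs_scores.tsv"), sep="\t")
    mask = scores["outlier"].to_numpy() == 0 if cfg.apply_outlier_trim else np.ones(len(scores), bool)
    return scores, mask


def stage_predict(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    _, cohort, pcs = _load_qc_outputs(cfg)
    scores, keep = _load_scores(cfg)
    outcome = cohort[f"conversion_{cfg.horizon}yr"].to_numpy(dtype=float)
    covariates = covariate_design(cohort, pcs)

    z = scores["z_score"].to_numpy()
    X = covariates.copy()
    X["prs_z"] = z
    fit = logistic_fit(outcome[keep], X.loc[keep], prs_col="prs_z")
    fit.table().to_csv(outdir / "predict_logistic.tsv", sep="\t", index=False)

    cox_X = covariates.copy()
    cox_X["prs_z"] = z
    cox = cox_fit(
        cohort["time_to_event"].to_numpy()[keep],
        cohort["event_observed"].to_numpy()[keep],
        cox_X.loc[keep],
    )
    cox.table().to_csv(outdir / "predict_cox.tsv", sep="\t", index=False)

    summary = {
        "horizon_years": cfg.horizon,
        "n": int(keep.sum()),
        "n_converters": int(outcome[keep].sum()),
        "or_per_sd": fit.or_per_sd,
        "or_ci_low": fit.or_ci[0],
        "or_ci_high": fit.or_ci[1],
        "prs_p": fit.prs_p,
        "nagelkerke_r2": fit.nagelkerke,
        "auc": fit.auc,
        "cox_prs_hr": float(np.exp(cox.coef[cox.names.index("prs_z")])),
        "cox_prs_p": float(cox.p[cox.names.index("prs_z")]),
    }
    for k in (2, 3):
        labels = stratify_groups(z[keep], k)
        table = np.array(
            [
                [
                    int(((labels == g) & (outcome[keep] == 0)).sum()),
                    int(((labels == g) & (outcome[keep] == 1)).sum()),
                ]
                for g in range(k)
            ]
        )
        chi2, df, p = chisq_independence(table)
        name = "dichotomized" if k == 2 else "trichotomized"
        summary[f"{name}_chi2"] = chi2
        summary[f"{name}_df"] = df
        summary[f"{name}_p"] = p
        summary[f"{name}_rates"] = [
            float(outcome[keep][labels == g].mean()) for g in range(k)
        ]
    (outdir / "predict_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    _write_manifest(cfg, "predict", [
        outdir / "cohort_qc.tsv", outdir / "prs_scores.tsv", outdir / "pcs.tsv",
    ], [outdir / "predict_logistic.tsv", outdir / "predict_cox.tsv",
        outdir / "predict_summary.json"])


def stage_brain(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    _, cohort, pcs = _load_qc_outputs(cfg)
    scores, keep = _load_scores(cfg)
    covariates = covariate_design(cohort, pcs)
    assoc = brain_mod.region_scan(
        cohort,
        scores["z_score"].to_numpy(),
        covariates,
        family=cfg.fdr_family,
        sample_mask=keep,
    )
    assoc.to_csv(outdir / "brain_assoc.tsv", sep="\t", index=False)
    _write_manifest(cfg, "brain", [
        outdir / "cohort_qc.tsv", outdir / "prs_scores.tsv", outdir / "pcs.tsv",
    ], [outdir / "brain_assoc.tsv"])


def stage_mr(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    _, cohort, pcs = _load_qc_outputs(cfg)
    scores, keep = _load_scores(cfg)
    assoc = pd.read_csv(_require(outdir / "brain_assoc.tsv"), sep="\t")
    hits = assoc[assoc["significant"] == True]  # noqa: E712 - TSV round-trip
    if len(hits) == 0:
        # fall back to the top association so the report is never empty
        hits = assoc.head(1)
    covariates = covariate_design(cohort, pcs)
    report = mr.mr_chain_report(
        scores["z_score"].to_numpy(),
        cohort,
        list(zip(hits["region"], hits["measure"])),
        cohort[f"conversion_{cfg.horizon}yr"].to_numpy(dtype=float),
        covariates,
        sample_mask=keep,
    )
    report.to_csv(outdir / "mr_report.tsv", sep="\t", index=False)
    _write_manifest(cfg, "mr", [
        outdir / "cohort_qc.tsv", outdir / "prs_scores.tsv", outdir / "brain_assoc.tsv",
    ], [outdir / "mr_report.tsv"])


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "prs": stage_prs,
    "predict": stage_predict,
    "brain": stage_brain,
    "mr": stage_mr,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the selected stages in canonical order; returns the run dir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        log.info("=== stage %s ===", stage)
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    return outdir
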