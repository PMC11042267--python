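"""Pipeline orchestration: configuration, stage execution, report assembly.

Stages run in dependency order -- classify -> ILS/SFS -> balancing stats ->
cophenetic test -> segregation/F_IS -- over either user-supplied VCF input
or the built-in synthetic demo.  Every stochastic stage receives an explicit
seed derived from the run seed; outputs are plain TSV/JSON carrying the
config hash so a run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import balancing, core, segregation, sfs, simulate, trees

logger = logging.getLogger("transpoly")

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


_DEFAULTS = dict(
    vcf=None,
    sample_table=None,
    phased_vcf=None,
    newick_dir=None,
    species_A="NAm_pulex",
    species_B="Euro_pulex",
    maf_min=0.01,
    cpd_maf_min=0.25,
    flank_bp=500,
    beta_window_bp=500,
    depth_lo=8.0,
    depth_hi=35.0,
    max_missing=0.10,
    sfs_projection=10,
    shared_min_count=1,
    samples_per_species=30,
    seed=1,
    out_dir="transpoly_out",
    stages=["classify", "ils", "sfs", "balance", "cpd", "segregate"],
    synthetic=None,
)

_RANGES = {
    "maf_min": (0.0, 0.5),
    "cpd_maf_min": (0.0, 0.5),
    "max_missing": (0.0, 1.0),
}

_STAGES = ("classify", "ils", "sfs", "balance", "cpd", "segregate")


@dataclass
class RunConfig:
    vcf: str | None = None
    sample_table: str | None = None
    phased_vcf: str | None = None
    newick_dir: str | None = None
    species_A: str = "NAm_pulex"
    species_B: str = "Euro_pulex"
    maf_min: float = 0.01
    cpd_maf_min: float = 0.25
    flank_bp: int = 500
    beta_window_bp: int = 500
    depth_lo: float | None = 8.0
    depth_hi: float | None = 35.0
    max_missing: float = 0.10
    sfs_projection: int = 10
    shared_min_count: int = 1
    samples_per_species: int | None = 30
    seed: int = 1
    out_dir: str = "transpoly_out"
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    synthetic: dict | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validate_config(source) -> RunConfig:
    """Validate a config mapping or YAML path; defaults injected and echoed.

    Raises :class:`ConfigError` listing every problem at once.  Unknown keys
    produce a warning listing the accepted keys rather than an error.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    elif isinstance(source, RunConfig):
        data = asdict(source)
    else:
        data = dict(source or {})

    errors: list[str] = []
    unknown = sorted(set(data) - set(_DEFAULTS))
    if unknown:
        logger.warning(
            "unknown config keys %s ignored; accepted keys: %s",
            unknown,
            ", ".join(sorted(_DEFAULTS)),
        )
    merged = {**_DEFAULTS, **{k: v for k, v in data.items() if k in _DEFAULTS}}

    for key, (lo, hi) in _RANGES.items():
        v = merged[key]
        if not isinstance(v, (int, float)) or not lo <= float(v) <= hi:
            errors.append(f"{key}={v!r} out of range [{lo}, {hi}]")
    for key in ("flank_bp", "beta_window_bp", "sfs_projection"):
        if not isinstance(merged[key], int) or merged[key] < 1:
            errors.append(f"{key}={merged[key]!r} must be a positive integer")
    if not isinstance(merged["seed"], int):
        errors.append(f"seed={merged['seed']!r} must be an integer")
    for key in ("vcf", "sample_table", "phased_vcf", "newick_dir"):
        v = merged[key]
        if v is not None and not Path(v).exists():
            errors.append(f"{key}={v!r} does not exist")
    bad_stages = [s for s in merged["stages"] if s not in _STAGES]
    if bad_stages:
        errors.append(f"unknown stages {bad_stages}; valid: {list(_STAGES)}")
    if merged["synthetic"] is None:
        if merged["vcf"] is None or merged["sample_table"] is None:
            errors.append("either synthetic demo settings or vcf+sample_table required")
        if "cpd" in merged["stages"] and merged["phased_vcf"] is None and merged["vcf"] is None:
            errors.append("cpd stage enabled but phased_vcf missing")
    if errors:
        raise ConfigError(errors)
    return RunConfig(**merged)


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages; write TSVs and a JSON summary; return it.

    Stage failure aborts with the stage name while partial outputs are
    preserved on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "species": [cfg.species_A, cfg.species_B],
    }
    stage = "load"
    try:
        gm, truth = _load_input(cfg)
        classes = None
        if "classify" in cfg.stages:
            stage = "classify"
            gm_f, report = core.filter_sites(
                gm, max_missing=cfg.max_missing,
                depth_lo=cfg.depth_lo if _has_depth(gm) else None,
                depth_hi=cfg.depth_hi if _has_depth(gm) else None,
            )
            report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
            classes = core.classify_sites(gm_f, cfg.species_A, cfg.species_B, cfg.maf_min)
            classes.to_tsv(out / "site_classes.tsv")
            summary["classification_counts"] = classes.counts()
            gm = gm_f
        if classes is None:
            classes = core.classify_sites(gm, cfg.species_A, cfg.species_B, cfg.maf_min)

        if "ils" in cfg.stages:
            stage = "ils"
            div = sfs.diversity_stats(gm, cfg.species_A, cfg.species_B)
            ils = sfs.expected_shared_ils(div)
            observed_shared = classes.counts()["shared_poly"]
            summary["ils"] = {
                "pi_A": div.pi_A,
                "pi_B": div.pi_B,
                "dxy": div.dxy,
                "n_sites": div.n_sites,
                "expected_shared": ils.expected_count,
                "retention_exponent": ils.exponent,
                "observed_shared": observed_shared,
            }
        if "sfs" in cfg.stages:
            stage = "sfs"
            proj = cfg.sfs_projection
            spectrum = sfs.joint_sfs(
                gm, cfg.species_A, cfg.species_B, proj=(proj, proj)
            )
            spectrum.to_file(out / "joint_sfs.txt")
            n_cells, mass = sfs.count_shared_sfs(spectrum, cfg.shared_min_count)
            summary["sfs"] = {
                "projection": proj,
                "segregating_mass": spectrum.segregating_mass,
                "shared_cells": n_cells,
                "shared_mass": mass,
                "sites_dropped": spectrum.n_sites_dropped,
            }
        if "balance" in cfg.stages:
            stage = "balance"
            table = balancing.AlphaBTable.from_site_classes(classes)
            block: dict = {"counts": {
                "poly_syn": table.poly_syn, "poly_ns": table.poly_ns,
                "sp_syn": table.sp_syn, "sp_ns": table.sp_ns,
            }}
            try:
                res = balancing.alpha_b(table)
                block["alpha_b"] = res.value
                if table.per_gene is not None and len(table.per_gene) >= 2:
                    boot = balancing.alpha_b_bootstrap(
                        table, seed=_stage_seed(cfg.seed, "alpha_b")
                    )
                    block["ci"] = [boot.ci_low, boot.ci_high]
                    block["p_one_sided"] = boot.p_one_sided
                    block["ci_unreliable"] = boot.unreliable
            except ValueError as exc:
                block["alpha_b_error"] = str(exc)
            per_site, summary_beta = balancing.beta1_scan(
                gm, cfg.species_A, classes, window_bp=cfg.beta_window_bp
            )
            per_site.to_csv(out / "beta1_sites.tsv", sep="\t", index=False)
            summary_beta.to_csv(out / "beta1_summary.tsv", sep="\t", index=False)
            block["beta1_class_means"] = {
                f"{row.annotation}|{'shared' if row.shared else 'nonshared'}": row.mean_beta1
                for row in summary_beta.itertuples()
            }
            summary["balancing"] = block
        if "cpd" in cfg.stages:
            stage = "cpd"
            gm_phased = _load_phased(cfg, gm)
            cls_p = core.classify_sites(
                gm_phased, cfg.species_A, cfg.species_B, cfg.maf_min
            )
            table = trees.cpd_batch(
                gm_phased,
                cls_p,
                maf_min=cfg.cpd_maf_min,
                flank_bp=cfg.flank_bp,
                samples_per_species=cfg.samples_per_species,
                seed=_stage_seed(cfg.seed, "cpd"),
            )
            table.to_csv(out / "cpd_results.tsv", sep="\t", index=False)
            pos = table[table["cpd_diff"] > 0]
            summary["cpd"] = {
                "n_trees": int(len(table)),
                "n_shared": int(table["shared"].sum()),
                "n_positive_diff": int(len(pos)),
                "n_positive_diff_shared": int((pos["shared"]).sum()),
            }
        if "segregate" in cfg.stages:
            stage = "segregate"
            summary["segregation"] = _segregation_stage(cfg, out)
    except Exception as exc:
        (out / "summary.json").write_text(
            json.dumps({**summary, "failed_stage": stage, "error": str(exc)},
                       indent=2, sort_keys=True)
        )
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary


def _has_depth(gm: core.GenotypeMatrix) -> bool:
    return any(np.isfinite(s.mean_depth) for s in gm.sites)


def _load_input(cfg: RunConfig):
    if cfg.synthetic is not None:
        syn = dict(cfg.synthetic)
        syn.setdefault("seed", cfg.seed)
        syn.setdefault("species_A", cfg.species_A)
        syn.setdefault("species_B", cfg.species_B)
        dem = simulate.DemographyConfig(**syn)
        gm, prov = simulate.simulate_split(dem)
        return gm, prov
    gm = core.read_vcf(cfg.vcf, cfg.sample_table)
    return gm, None


def _load_phased(cfg: RunConfig, gm: core.GenotypeMatrix) -> core.GenotypeMatrix:
    if cfg.phased_vcf is not None:
        return core.read_vcf(cfg.phased_vcf, cfg.sample_table)
    if gm.phased_haplotypes is None:
        raise ValueError("cpd stage needs phased input (phased_vcf or phased demo data)")
    return gm


def _segregation_stage(cfg: RunConfig, out: Path) -> dict:
    """Synthetic AB x AB cross analysis mirroring the F1 heterozygote test."""
    seed = _stage_seed(cfg.seed, "segregate")
    obs, _ = simulate.simulate_cross(
        5, n_offspring=400, het_advantage=0.5, depth_mean=12.0, seed=seed
    )
    neutral_obs, _ = simulate.simulate_cross(
        5, n_offspring=400, het_advantage=0.0, depth_mean=12.0, seed=seed + 1
    )
    _, gene_freqs = segregation.observed_segregation(obs)
    expected = segregation.expected_segregation(obs.depths[0], seed=seed + 2)
    res = segregation.fis_null(obs, n_sim=400, seed=seed + 3)
    res_neutral = segregation.fis_null(neutral_obs, n_sim=400, seed=seed + 4)
    rows = []
    for name, r in (("selected", res), ("neutral", res_neutral)):
        rows.append({
            "gene": name,
            "observed_fis": r.observed_fis,
            "null_mean": r.null_mean,
            "null_p2.5": r.null_percentile(2.5),
            "null_p97.5": r.null_percentile(97.5),
            "quantile": r.quantile,
        })
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "fis_results.tsv", sep="\t", index=False)
    return {
        "observed_freqs_selected": [round(v, 6) for v in gene_freqs],
        "expected_freqs_null": [round(v, 6) for v in expected],
        "fis_selected": res.observed_fis,
        "fis_selected_null_quantile": res.quantile,
        "fis_neutral": res_neutral.observed_fis,
        "fis_neutral_null_quantile": res_neutral.quantile,
    }
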