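"""Pipeline orchestration and the consolidated JSON report.

``run_pipeline`` executes filter -> per-pair agreement -> PCA screen ->
per-pair differential testing and writes a single JSON report embedding all
stage outputs plus provenance (config hash, package version, seed). The
report layout is published as a JSON schema (generated from the pydantic
models below) so downstream consumers can validate it. Timestamps are
isolated in the header so that repeated runs with the same configuration and
seed are byte-identical apart from that one field.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from datetime import datetime, timezone
from itertools import combinations
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .agreement import (
    difference_distribution,
    fit_variance_model,
    normality_screen,
    pairwise_points,
)
from .differential import find_bumps, global_paired_t, per_site_paired_t
from .io_model import BetaDataset, FilterSpec, filter_sites, read_beta_dataset
from .multivariate import pc_association_screen, run_pca

__all__ = ["PipelineConfig", "ReportModel", "run_pipeline", "report_json_schema"]


class PipelineConfig(BaseModel):
    """Everything a pipeline run depends on; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    beta_path: str
    annotation_path: str
    samplesheet_path: str
    out_dir: str
    pairs: list[tuple[str, str]] | None = None  # default: all pairwise combos
    seed: int = 0

    # stage toggles
    run_filter: bool = True
    run_agreement: bool = True
    run_pca: bool = True
    run_global: bool = True
    run_dmp: bool = True
    run_dmr: bool = True

    # filter parameters
    detection_threshold: float = 0.01
    blacklist_ids: list[str] = Field(default_factory=list)
    drop_non_cpg: bool = True
    drop_missing: bool = True
    drop_chroms: list[str] = Field(default_factory=lambda: ["chrX", "chrY"])

    # agreement parameters
    z: float = 1.96
    fit_subsample: int | None = None
    normality_subsample_n: int = 5000
    normality_repeats: int = 10

    # pca parameters
    n_components: int | None = None
    covariates: list[str] = Field(
        default_factory=lambda: [
            "method",
            "chip_position",
            "yield_ug",
            "a260_280",
            "a260_230",
        ]
    )

    # differential parameters
    max_gap: int = 1000
    cutoff: float = 0.01
    loess_span: float = 0.75
    n_boot: int = 250

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# -- report schema ---------------------------------------------------------

class HeaderModel(BaseModel):
    timestamp: str
    package: str
    version: str


class ProvenanceModel(BaseModel):
    config_hash: str
    seed: int
    config: dict


class FilterBlock(BaseModel):
    counts: dict[str, int]
    n_input: int
    n_retained: int


class FitBlock(BaseModel):
    a: float
    b: float
    z: float
    converged: bool
    n_used: int
    mean_d: float
    final_objective: float


class AgreementBlock(BaseModel):
    n_points: int
    fit: FitBlock
    distribution_bin_lo: list[float]
    distribution_percent: list[float]
    normality_p: list[float | None]


class AssociationBlock(BaseModel):
    component_index: int
    covariate: str
    test: str
    statistic: float | None
    p_raw: float | None
    p_adjusted: float | None


class PCABlock(BaseModel):
    n_components: int
    variance_explained: list[float]
    associations: list[AssociationBlock]


class GlobalTestBlock(BaseModel):
    mean_diff: float
    t: float | None
    df: int
    p: float | None


class RegionBlock(BaseModel):
    cluster_id: int
    chrom: str
    start: int
    end: int
    n_sites: int
    area: float
    direction: str
    fwer: float


class DifferentialBlock(BaseModel):
    global_test: GlobalTestBlock | None = None
    n_sites_tested: int | None = None
    n_significant_sites: int | None = None
    min_p_bh: float | None = None
    regions: list[RegionBlock] | None = None
    n_significant_regions: int | None = None


class ReportModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    header: HeaderModel
    provenance: ProvenanceModel
    filter: FilterBlock | None = None
    agreement: dict[str, AgreementBlock] | None = None
    pca: PCABlock | None = None
    differential: dict[str, DifferentialBlock] | None = None


def report_json_schema() -> dict:
    return ReportModel.model_json_schema()


def _nan_to_none(x: float) -> float | None:
    return None if x is None or not np.isfinite(x) else float(x)


def run_pipeline(config: PipelineConfig, ds: BetaDataset | None = None) -> dict:
    """Execute all enabled stages and write ``report.json`` + ``MANIFEST.json``.

    The dataset may be passed directly (e.g. simulated in memory); otherwise
    it is read from the configured paths. Returns the report as a dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    manifest_path = out_dir / "MANIFEST.json"

    def _save_manifest() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    report: dict = {
        "header": {
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "package": "methylagree",
            "version": __version__,
        },
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "config": config.model_dump(),
        },
        "filter": None,
        "agreement": None,
        "pca": None,
        "differential": None,
    }

    try:
        if ds is None:
            ds = read_beta_dataset(
                config.beta_path, config.annotation_path, config.samplesheet_path
            )
        manifest["load"] = "ok"

        if config.run_filter:
            spec = FilterSpec(
                detection_threshold=config.detection_threshold,
                blacklist_ids=frozenset(config.blacklist_ids),
                drop_non_cpg=config.drop_non_cpg,
                drop_missing=config.drop_missing,
                drop_chroms=frozenset(config.drop_chroms),
            )
            ds, filt = filter_sites(ds, spec)
            report["filter"] = {
                "counts": filt.counts,
                "n_input": filt.n_input,
                "n_retained": filt.n_retained,
            }
            manifest["filter"] = "ok"

        pairs = config.pairs or list(combinations(ds.methods, 2))

        if config.run_agreement:
            block = {}
            for m1, m2 in pairs:
                pts = pairwise_points(ds, m1, m2)
                fit = fit_variance_model(
                    pts, z=config.z, subsample=config.fit_subsample, seed=config.seed
                )
                dist = difference_distribution(ds, m1, m2)
                sub_n = min(config.normality_subsample_n, pts.n_points)
                screen = normality_screen(
                    pts,
                    subsample_n=sub_n,
                    n_repeats=config.normality_repeats,
                    seed=config.seed,
                )
                block[f"{m1}_vs_{m2}"] = {
                    "n_points": pts.n_points,
                    "fit": {
                        "a": fit.a,
                        "b": fit.b,
                        "z": fit.z,
                        "converged": fit.converged,
                        "n_used": fit.n_used,
                        "mean_d": fit.mean_d,
                        "final_objective": fit.final_objective,
                    },
                    "distribution_bin_lo": [float(v) for v in dist.bin_edges[:-1]],
                    "distribution_percent": [float(v) for v in dist.percentages],
                    "normality_p": [_nan_to_none(p) for p in screen.p_values],
                }
            report["agreement"] = block
            manifest["agreement"] = "ok"

        if config.run_pca:
            pca = run_pca(ds, n_components=config.n_components)
            assoc = pc_association_screen(pca, ds.samples, config.covariates)
            report["pca"] = {
                "n_components": pca.n_components,
                "variance_explained": [float(v) for v in pca.variance_explained],
                "associations": [
                    {
                        "component_index": r.component_index,
                        "covariate": r.covariate,
                        "test": r.test,
                        "statistic": _nan_to_none(r.statistic),
                        "p_raw": _nan_to_none(r.p_raw),
                        "p_adjusted": _nan_to_none(r.p_adjusted),
                    }
                    for r in assoc
                ],
            }
            manifest["pca"] = "ok"

        if config.run_global or config.run_dmp or config.run_dmr:
            block = {}
            for m1, m2 in pairs:
                entry: dict = {}
                if config.run_global:
                    g = global_paired_t(ds, m1, m2)
                    entry["global_test"] = {
                        "mean_diff": g.mean_diff,
                        "t": _nan_to_none(g.t),
                        "df": g.df,
                        "p": _nan_to_none(g.p_raw),
                    }
                if config.run_dmp:
                    per_site = per_site_paired_t(ds, m1, m2)
                    sig = per_site["p_bh"] < 0.05
                    entry["n_sites_tested"] = int(per_site["p_raw"].notna().sum())
                    entry["n_significant_sites"] = int(sig.sum())
                    entry["min_p_bh"] = _nan_to_none(float(per_site["p_bh"].min()))
                if config.run_dmr:
                    regions = find_bumps(
                        ds,
                        m1,
                        m2,
                        cutoff=config.cutoff,
                        loess_span=config.loess_span,
                        n_boot=config.n_boot,
                        seed=config.seed,
                        max_gap=config.max_gap,
                    )
                    entry["regions"] = [
                        {
                            "cluster_id": r.cluster_id,
                            "chrom": r.chrom,
                            "start": r.start,
                            "end": r.end,
                            "n_sites": r.n_sites,
                            "area": r.area,
                            "direction": r.direction,
                            "fwer": r.fwer,
                        }
                        for r in regions
                    ]
                    entry["n_significant_regions"] = int(
                        sum(r.fwer < 0.05 for r in regions)
                    )
                block[f"{m1}_vs_{m2}"] = entry
            report["differential"] = block
            manifest["differential"] = "ok"
    except Exception as err:
        manifest["FAILED"] = f"{type(err).__name__}: {err}"
        _save_manifest()
        raise

    ReportModel.model_validate(report)  # schema check before writing
    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    manifest["report"] = "ok"
    _save_manifest()
    return report
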