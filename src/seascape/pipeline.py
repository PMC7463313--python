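"""End-to-end orchestration: synthetic data -> particle tracking ->
connectivity -> population genetics -> spatial eigenfunctions -> RDA.

A single global seed deterministically derives per-stage seeds (by hashing
the stage name), so any stage can be re-run in isolation and the whole run is
bit-reproducible.  Every artifact is written with a provenance header (stage,
config hash, seed) and listed, with its checksum, in a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import derive_seed
from .connectivity import connectivity_matrix, seasonal_average, self_recruitment
from .flowfield import FlowField, FlowGridSpec, FrontResidual, GyreResidual, UniformResidual, gen_flow
from .genotypes import EnvTable, GenotypeMatrix, gen_env_table, gen_genotypes
from .popgen import (
    FilterParams,
    FstOutlierScan,
    PcaOutlierScan,
    filter_pipeline,
    multilocus_fst,
    outlier_intersection,
    pop_maf_matrix,
)
from .ptm import PTMConfig, ReleaseSchedule, run_ptm
from .rda import forward_select, hellinger, rda, rda_anova
from .sites import SiteTable
from .spatial import aem, dbmem, graph_from_connectivity, project_xy

log = logging.getLogger("seascape")

RESIDUAL_KINDS = {"uniform": UniformResidual, "gyre": GyreResidual, "front": FrontResidual}


@dataclass
class PipelineConfig:
    """Configuration of a full run.  Paths may be omitted when the synthetic
    generators are used instead (``synthetic: true``)."""

    out_dir: str = "seascape_out"
    seed: int = 0
    synthetic: bool = True
    # input paths (used when synthetic is false)
    flow_path: str | None = None
    sites_path: str | None = None
    genotypes_path: str | None = None
    popmap_path: str | None = None
    env_path: str | None = None
    # synthetic-stage parameters
    grid: dict = field(default_factory=dict)
    tidal_amplitude_ms: float = 0.5
    tidal_period_h: float = 12.42
    residual: dict = field(default_factory=lambda: {"kind": "uniform", "u0": 0.02, "v0": 0.0})
    n_months: int = 6
    genotype_params: dict = field(default_factory=dict)
    # stage parameters
    ptm: dict = field(default_factory=dict)
    release: dict = field(default_factory=dict)
    filter_params: dict = field(default_factory=dict)
    outlier_params: dict = field(default_factory=lambda: {"K": 2, "alpha": 0.05, "n_sim": 20_000})
    eigen_params: dict = field(default_factory=lambda: {"threshold": 0.0})
    rda_params: dict = field(default_factory=lambda: {"alpha": 0.05, "n_perm": 999})
    run_genetics: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded, so
        identical runs into different directories share a hash)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("flow_path", "sites_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} missing or does not exist: {p}")
            if self.run_genetics:
                for name in ("genotypes_path", "popmap_path", "env_path"):
                    p = getattr(self, name)
                    if p is None or not Path(p).exists():
                        raise FileNotFoundError(f"{name} missing or does not exist: {p}")


# three demo sites ~57 km apart along the default eastward residual drift,
# so the 30-40 day settlement window produces a downstream connectivity chain
DEFAULT_DEMO_SITES = pd.DataFrame(
    {
        "site_id": ["A", "B", "C"],
        "name": ["Site A", "Site B", "Site C"],
        "lon": [-5.6, -4.75, -3.9],
        "lat": [53.0, 53.03, 52.98],
    }
)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.entries: list[dict] = []
        self.provenance = {"config_hash": config.config_hash(), "seed": config.seed}

    def add(self, stage: str, path: Path) -> None:
        self.entries.append(
            {"stage": stage, "path": str(path.relative_to(self.out_dir)), "sha256": _checksum(path)}
        )

    def write(self, status: str = "complete", failed_stage: str | None = None) -> Path:
        payload = {"provenance": self.provenance, "status": status, "artifacts": self.entries}
        if failed_stage:
            payload["failed_stage"] = failed_stage
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=2))
        return path


def _write_with_header(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str, seed: int, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={cfg_hash} seed={seed}\n")
        df.to_csv(fh, **kw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest as a dict.

    Stage order: flow/site (synthetic or loaded) -> particle tracking per
    month -> connectivity -> genotype filtering, diversity, outlier scans ->
    dbMEM/AEM bases -> forward selection and RDA on the outlier and neutral
    panels.  Any stage failure writes a partial manifest naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    cfg_hash = config.config_hash()
    seed = config.seed
    stage = "setup"
    try:
        t0 = time.time()
        # ------------------------------------------------------------- flow
        stage = "flow"
        if config.synthetic:
            sites = SiteTable(DEFAULT_DEMO_SITES.copy()) if config.sites_path is None else SiteTable.read_csv(config.sites_path)
            grid_kw = dict(config.grid)
            grid_spec = FlowGridSpec(**grid_kw)
            res_kw = dict(config.residual)
            kind = res_kw.pop("kind", "uniform")
            residual = RESIDUAL_KINDS[kind](**res_kw)
            field_ = gen_flow(
                grid_spec,
                tidal_amplitude_ms=config.tidal_amplitude_ms,
                tidal_period_h=config.tidal_period_h,
                residual=residual,
                seed=derive_seed(seed, "flow"),
            )
        else:
            sites = SiteTable.read_csv(config.sites_path)
            field_ = FlowField.from_netcdf(config.flow_path)
        sites_path = out / "sites.csv"
        sites.to_csv(sites_path)
        manifest.add(stage, sites_path)
        log.info("flow stage done in %.1fs", time.time() - t0)

        # -------------------------------------------------- ptm + connectivity
        stage = "ptm"
        t0 = time.time()
        ptm_cfg = PTMConfig(**config.ptm)
        release = ReleaseSchedule(**config.release)
        window_days = ptm_cfg.pld_days
        month_span = 30.0 * 86_400.0
        t_max = field_.grid.time_axis[-1]
        matrices = []
        for month in range(config.n_months):
            start = month * month_span
            need = start + (release.n_release_days - 1) * 86_400.0 + window_days * 86_400.0 + 86_400.0
            if need > t_max:
                if month == 0:
                    raise ValueError("flow field too short for even one monthly release")
                log.info("flow field covers %d of %d requested months", month, config.n_months)
                break
            final, _ = run_ptm(field_, sites, month_start_s=start, schedule=release, config=ptm_cfg,
                               seed=derive_seed(seed, f"ptm-month{month}"))
            matrices.append(connectivity_matrix(final, sites, label=f"month{month + 1}"))
        stage = "connectivity"
        seasonal = seasonal_average(matrices)
        conn_path = out / "connectivity_seasonal.csv"
        _write_with_header(seasonal.to_dataframe(), conn_path, stage, cfg_hash, seed, index_label="site_id")
        manifest.add(stage, conn_path)
        sr = self_recruitment(matrices)
        sr_path = out / "self_recruitment.csv"
        _write_with_header(sr, sr_path, stage, cfg_hash, seed, index=False)
        manifest.add(stage, sr_path)
        log.info("ptm/connectivity done in %.1fs (%d monthly matrices)", time.time() - t0, len(matrices))

        # ------------------------------------------------------ spatial bases
        stage = "spatial_eigen"
        t0 = time.time()
        xy = project_xy(sites)
        mem_basis = dbmem(xy)
        mem_path = out / "dbmem.csv"
        mem_basis.to_csv(mem_path)
        manifest.add(stage, mem_path)
        graph = graph_from_connectivity(seasonal, threshold=config.eigen_params.get("threshold", 0.0))
        aem_basis = aem(graph)
        aem_path = out / "aem.csv"
        aem_basis.to_csv(aem_path)
        manifest.add(stage, aem_path)
        log.info("spatial bases done in %.1fs", time.time() - t0)

        results: dict = {}
        if config.run_genetics:
            # ------------------------------------------------------- genetics
            stage = "popgen"
            t0 = time.time()
            if config.synthetic:
                env = gen_env_table(sites, seed=derive_seed(seed, "env"))
                gp = dict(
                    n_pops=len(sites), n_per_pop=20, n_loci=1000, target_fst=0.02,
                    n_outlier_loci=12, outlier_effect=2.0, env_var="sst_min_apr",
                    missing_rate=0.05,
                )
                gp.update(config.genotype_params)
                G = gen_genotypes(env=env, pop_ids=sites.site_ids, seed=derive_seed(seed, "genotypes"), **gp)
            else:
                env = EnvTable.read_csv(config.env_path)
                if str(config.genotypes_path).endswith(".vcf"):
                    G = GenotypeMatrix.from_vcf(config.genotypes_path, config.popmap_path)
                else:
                    G = GenotypeMatrix.from_tsv(config.genotypes_path, config.popmap_path)
            env_path = out / "env.csv"
            env.to_csv(env_path)
            manifest.add(stage, env_path)

            Gf, report = filter_pipeline(G, FilterParams(**config.filter_params))
            report_path = out / "filter_report.json"
            report.to_json(report_path)
            manifest.add(stage, report_path)

            op = config.outlier_params
            pca_scan = PcaOutlierScan(n_components=op.get("K", 2), alpha=op.get("alpha", 0.05)).fit(Gf)
            fst_scan = FstOutlierScan(
                n_sim=op.get("n_sim", 20_000), alpha=op.get("alpha", 0.05),
                seed=derive_seed(seed, "fst-scan"),
            ).fit(Gf)
            outliers, neutral = outlier_intersection(pca_scan.result_, fst_scan.result_)
            scan_path = out / "outlier_scans.tsv"
            merged = pca_scan.result_.table.merge(
                fst_scan.result_.table, on="locus", suffixes=("_pca", "_fst")
            )
            merged["outlier"] = merged["locus"].isin(outliers)
            _write_with_header(merged, scan_path, stage, cfg_hash, seed, index=False, sep="\t")
            manifest.add(stage, scan_path)
            results["n_outliers"] = len(outliers)
            results["multilocus_fst"] = multilocus_fst(Gf)
            log.info("popgen done in %.1fs (%d outliers)", time.time() - t0, len(outliers))

            # ----------------------------------------------------------- RDA
            stage = "ea_rda"
            t0 = time.time()
            maf = pop_maf_matrix(Gf)
            maf = maf.loc[sites.site_ids]
            loci = list(maf.columns)
            outlier_cols = [c for c in loci if c in outliers]
            neutral_cols = [c for c in loci if c in neutral]

            candidates = pd.DataFrame(index=maf.index)
            mem_df = mem_basis.to_dataframe().loc[maf.index]
            for col in mem_df.columns[: min(3, mem_df.shape[1])]:
                candidates[col] = mem_df[col]
            aem_df = aem_basis.to_dataframe().loc[maf.index]
            for col in aem_df.columns[: min(3, aem_df.shape[1])]:
                candidates[col] = aem_df[col]
            env_df = env.table.loc[maf.index]
            for col in env_df.columns:
                candidates[col] = env_df[col]

            rp = config.rda_params
            rda_out = {}
            for panel, cols in (("outlier", outlier_cols), ("neutral", neutral_cols)):
                if not cols:
                    continue
                Yh = hellinger(maf[cols])
                trace = forward_select(
                    Yh, candidates, alpha=rp.get("alpha", 0.05),
                    n_perm=rp.get("n_perm", 999), seed=derive_seed(seed, f"select-{panel}"),
                )
                entry = {"selected": trace.selected, "stopped_by": trace.stopped_by}
                if trace.selected:
                    fit = rda(Yh, candidates[trace.selected])
                    f, p = rda_anova(Yh, candidates[trace.selected],
                                     n_perm=rp.get("n_perm", 999), seed=derive_seed(seed, f"anova-{panel}"))
                    entry.update({"r2": fit.r2, "adj_r2": fit.adj_r2, "pseudo_f": f, "p": p})
                rda_out[panel] = entry
            rda_path = out / "rda_results.json"
            rda_path.write_text(json.dumps(
                {"provenance": manifest.provenance, "panels": rda_out}, indent=2))
            manifest.add(stage, rda_path)
            results["rda"] = rda_out
            log.info("ea_rda done in %.1fs", time.time() - t0)

        manifest_path = manifest.write()
        with open(manifest_path) as fh:
            return json.load(fh)
    except Exception:
        manifest.write(status="failed", failed_stage=stage)
        log.error("pipeline failed at stage %s", stage)
        raise
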