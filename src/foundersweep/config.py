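"""Run configuration and end-to-end pipeline orchestration.

A run is fully described by a :class:`RunConfig` (YAML on disk); every
run writes the resolved configuration, the seed and a config hash next
to its outputs so any artefact directory can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import joint_sfs, sliding_windows, window_stats
from .simulate import DemographicModel, simulate_genome
from .filters import filter_sites
from .demography import fit_grid, n1_from_pi
from .scan import calibrate_null, call_outliers, map_to_genes
from . import clr as clr_mod
from .enrich import enrich
from .io import (
    read_genes,
    read_go_annotation,
    read_vcf,
    write_joint_sfs,
    write_vcf,
    write_window_stats,
)

log = logging.getLogger("foundersweep")

ALL_STAGES = ("simulate", "filter", "stats", "fit", "calibrate", "scan", "clr", "enrich")


@dataclass
class RunConfig:
    # demographic model
    N1: float = 35_000.0
    N2b: float = 14.4
    N2f: float = 1290.0
    T: float = 50.0
    mu: float = 1e-8
    # samples
    n_native: int = 8  # diploids
    n_introduced: int = 8
    # simulated genome
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 500_000})
    sweeps: list = field(default_factory=list)
    missing_rate: float = 0.0
    # filters
    qual_min: float = 10.0
    depth_max: float = 100.0
    hwe_alpha: float = 0.01
    # windows / scans
    window_size: int = 10_000
    step: int = 5_000
    alpha: float = 0.05
    null_reps: int = 5_000
    clr_top_frac: float = 0.001
    # demography fit
    fit_coarse: int = 25
    fit_n_mc: int = 300
    fit_total_sites: int = 1_212_784
    # bookkeeping
    seed: int = 1
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    # optional inputs for real-data runs
    vcf: str | None = None
    popmap: dict = field(default_factory=dict)
    genes: str | None = None
    go_annotation: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def model(self) -> DemographicModel:
        return DemographicModel(N1=self.N1, N2b=self.N2b, N2f=self.N2f, T=self.T, mu=self.mu)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def header(self) -> str:
        return f"foundersweep {__version__} seed={self.seed} config={self.config_hash()}"


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the selected stages; return the artefact directory.

    Stage order: simulate -> filter -> stats -> fit -> calibrate -> scan
    -> clr -> enrich.  Deterministic under a fixed seed.  Each stage
    logs its record counts; every output carries a version/seed/hash
    header.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    stages = list(config.stages)
    model = config.model()
    rng_seed = config.seed
    hdr = config.header()

    table = None
    if "simulate" in stages:
        table = simulate_genome(
            model,
            chrom_lengths=dict(config.chrom_lengths),
            n1=2 * config.n_native,
            n2=2 * config.n_introduced,
            sweeps=list(config.sweeps),
            missing_rate=config.missing_rate,
            seed=rng_seed,
        )
        write_vcf(table, outdir / "simulated.vcf", header_lines=[hdr])
        log.info("simulate: %d sites, %d samples", len(table.sites), len(table.samples))
    elif config.vcf:
        table = read_vcf(config.vcf, popmap=config.popmap or None)
        log.info("loaded %s: %d sites", config.vcf, len(table.sites))
    if table is None and set(stages) & {"filter", "stats", "scan", "clr"}:
        raise FileNotFoundError("no input data: enable the simulate stage or set 'vcf'")

    if "filter" in stages:
        table, report = filter_sites(
            table, qual_min=config.qual_min, depth_max=config.depth_max,
            hwe_alpha=config.hwe_alpha,
        )
        with open(outdir / "filter_report.tsv", "w") as fh:
            fh.write(f"# {hdr}\nrule\tcount\n")
            for rule, count in report.as_rows():
                fh.write(f"{rule}\t{count}\n")
                log.info("filter %s: %d", rule, count)

    pops = list(table.populations) if table is not None else []
    scan_pop = "introduced" if "introduced" in pops else (pops[0] if pops else None)
    other_pop = "native" if "native" in pops else (pops[1] if len(pops) > 1 else None)

    stats = None
    if "stats" in stages:
        windows = sliding_windows(
            {c: config.chrom_lengths.get(c, max(s.pos for s in table.chrom_sites(c)))
             for c in table.chroms},
            config.window_size, config.step,
        )
        stats = window_stats(table, windows, scan_pop, other_pop)
        write_window_stats(stats, outdir / "window_stats.tsv", header_comment=hdr)
        log.info("stats: %d windows", len(stats))

    if "fit" in stages:
        obs = joint_sfs(table, other_pop, scan_pop, fold=True)
        write_joint_sfs(obs, outdir / "observed_joint_sfs.tsv")
        # for simulated genomes the analysed-site total is the genome size;
        # for user VCFs it must be supplied (fit_total_sites)
        total_sites = (
            sum(config.chrom_lengths.values())
            if "simulate" in stages
            else config.fit_total_sites
        )
        surface = fit_grid(
            obs, N1=config.N1, T=config.T, mu=config.mu,
            coarse=config.fit_coarse, n_mc=config.fit_n_mc,
            total_sites=total_sites, seed=config.seed,
        )
        surface.to_dataframe().to_csv(outdir / "likelihood_surface.tsv", sep="\t", index=False)
        b, f, ll = surface.argmax
        with open(outdir / "fitted_model.yaml", "w") as fh:
            yaml.safe_dump(
                {"N1": config.N1, "N2b": float(b), "N2f": float(f), "T": config.T,
                 "mu": config.mu, "log_likelihood": float(ll)}, fh,
            )
        log.info("fit: N2b=%.3g N2f=%.3g ll=%.2f", b, f, ll)

    null = None
    if "calibrate" in stages:
        null = calibrate_null(
            model, n_reps=config.null_reps, window=config.window_size,
            seed=config.seed + 1,
            n1=2 * config.n_native, n2=2 * config.n_introduced,
        )
        thr = null.thresholds(config.alpha)
        with open(outdir / "null_thresholds.tsv", "w") as fh:
            fh.write(f"# {hdr}\nstatistic\tthreshold\n")
            for k, v in thr.items():
                fh.write(f"{k}\t{v:.6g}\n")
        log.info("calibrate: R=%d thresholds=%s", null.R, thr)

    genes_df = read_genes(config.genes) if config.genes else None
    candidates: set[str] = set()
    if "scan" in stages:
        if stats is None or null is None:
            raise ValueError("scan stage requires the stats and calibrate stages")
        regions = call_outliers(stats, null, alpha=config.alpha)
        with open(outdir / "candidate_windows.tsv", "w") as fh:
            fh.write(f"# {hdr}\nchrom\tstart\tend\ttajima_d\tpi_10kb\tfst\tp_d\tp_pi\tp_fst\n")
            for r in regions:
                fh.write(
                    f"{r.window.chrom}\t{r.window.start + 1}\t{r.window.end}\t"
                    f"{r.tajima_d:.4g}\t{r.pi_10kb:.4g}\t{r.fst:.4g}\t"
                    f"{r.p_d:.4g}\t{r.p_pi:.4g}\t{r.p_fst:.4g}\n"
                )
        log.info("scan: %d candidate windows", len(regions))
        if genes_df is not None:
            gene_table = map_to_genes(regions, genes_df)
            gene_table.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
            candidates |= set(gene_table["gene_id"])
            log.info("scan: %d candidate genes", len(gene_table))

    if "clr" in stages:
        clr_df = clr_mod.scan(
            table, scan_pop, chrom_lengths=dict(config.chrom_lengths) or None,
            spacing=config.window_size, top_frac=config.clr_top_frac,
        )
        clr_df.to_csv(outdir / "clr_scan.tsv", sep="\t", index=False)
        log.info("clr: %d grid points, %d outliers", len(clr_df), int(clr_df["outlier"].sum()))

    if "enrich" in stages and config.go_annotation:
        ann = read_go_annotation(config.go_annotation)
        cand = candidates & set(ann["gene_id"])
        results = enrich(cand, ann) if cand else []
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write(f"# {hdr}\nterm\tk\tK\tn\tN\tp_raw\tp_adj\n")
            for r in results:
                fh.write(f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_raw:.4g}\t{r.p_adj:.4g}\n")
        log.info("enrich: %d terms tested", len(results))

    return outdir
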