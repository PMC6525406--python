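"""End-to-end orchestration: simulate (optional) -> read QC -> SNP matrix ->
diversity -> phylogeny/dating -> D-statistics -> migration edges.

Stages run in a fixed order; each enabled stage writes its outputs under the
output directory with stable names, and the run report echoes the full
configuration so a run can be reproduced exactly from its report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .diversity import diversity_table, write_diversity_tsv
from .introgression import quartet_scan, write_dstat_tsv
from .migration import add_migration_edges, frequency_covariance, tree_from_covariance, write_edges_tsv
from .phylogeny import (
    CalibrationPoint,
    bootstrap_support,
    calibrate_ages,
    nei_distance,
    neighbor_joining,
)
from .qc import filter_fastq_file
from .snp_matrix import SiteFilterSpec, allele_frequencies, filter_sites, read_vcf, write_vcf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    vcf: Optional[str] = None
    popmap: Optional[str] = None
    fastq: Optional[str] = None
    adapter: Optional[str] = None
    # stage toggles
    run_qc: bool = False
    run_matrix: bool = True
    run_diversity: bool = True
    run_phylogeny: bool = True
    run_dstat: bool = True
    run_migration: bool = True
    # parameters
    filter_spec: SiteFilterSpec = field(default_factory=SiteFilterSpec)
    outgroup: Optional[str] = None
    calibration: Optional[CalibrationPoint] = None
    bootstrap_reps: int = 100
    block_size: int = 500
    max_edges: int = 5
    migration_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.run_qc and not self.fastq:
            raise ValueError("QC stage enabled but no FASTQ input given")
        needs_vcf = any(
            [self.run_matrix, self.run_diversity, self.run_phylogeny,
             self.run_dstat, self.run_migration]
        )
        if needs_vcf and not (self.vcf and self.popmap):
            raise ValueError("variant stages enabled but VCF/popmap missing")
        for path in (self.vcf, self.popmap, self.fastq):
            if path and not Path(path).exists():
                raise FileNotFoundError(path)
        if (self.run_dstat or self.run_migration) and not self.outgroup:
            raise ValueError("D-statistic/migration stages require an outgroup")


@dataclass
class RunReport:
    version: str
    config: PipelineConfig
    sections: dict[str, dict] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"radpop\t{self.version}\n")
            for key, val in sorted(_flatten_config(self.config).items()):
                fh.write(f"config.{key}\t{val}\n")
            for stage, info in self.sections.items():
                for k, v in info.items():
                    fh.write(f"{stage}.{k}\t{v}\n")


def _flatten_config(config: PipelineConfig) -> dict[str, str]:
    out: dict[str, str] = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            for sub in dataclasses.fields(v):
                out[f"{f.name}.{sub.name}"] = str(getattr(v, sub.name))
        else:
            out[f.name] = str(v)
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=config)

    if config.run_qc:
        qc_report = filter_fastq_file(
            config.fastq, out / "reads.filtered.fastq", config.adapter
        )
        report.sections["qc"] = {
            "total_in": qc_report.total_in,
            "removed_n_rule": qc_report.removed_n_rule,
            "removed_quality_rule": qc_report.removed_quality_rule,
            "removed_adapter_rule": qc_report.removed_adapter_rule,
            "kept": qc_report.kept,
        }
        qc_report.to_tsv(out / "qc_report.tsv")
        logger.info("qc: kept %d/%d reads", qc_report.kept, qc_report.total_in)

    gm = None
    freqs = None
    if config.run_matrix:
        gm = read_vcf(config.vcf, config.popmap)
        n_in = gm.n_sites
        gm, counts = filter_sites(gm, config.filter_spec)
        write_vcf(gm, out / "snp_matrix.filtered.vcf")
        report.sections["matrix"] = {"sites_in": n_in, **counts}
        logger.info("matrix: %d -> %d sites", n_in, gm.n_sites)
        freqs = allele_frequencies(gm)
        freqs.to_frame().to_csv(out / "allele_frequencies.tsv", sep="\t", index=False)

    if config.run_diversity:
        rows = diversity_table(gm)
        write_diversity_tsv(rows, out / "diversity.tsv")
        report.sections["diversity"] = {
            f"{r.population}.pi": f"{r.pi:.6f}" for r in rows
        }

    if config.run_phylogeny:
        dist = nei_distance(freqs)
        dist.to_csv(out / "nei_distances.tsv", sep="\t")
        tree = bootstrap_support(
            gm,
            n_reps=config.bootstrap_reps,
            seed=config.seed,
            fast=True,
            outgroup=config.outgroup,
        )
        with open(out / "population_tree.nwk", "w") as fh:
            fh.write(tree.to_newick(support=True) + "\n")
        section = {"tree": "population_tree.nwk", "bootstrap_reps": config.bootstrap_reps}
        if config.calibration is not None:
            dated = calibrate_ages(dist, config.calibration)
            with open(out / "dated_tree.nwk", "w") as fh:
                fh.write(dated.to_newick() + "\n")
            section["root_age_myr"] = f"{dated.root.age:.4f}"
        report.sections["phylogeny"] = section

    if config.run_dstat:
        results = quartet_scan(freqs, config.outgroup, config.block_size)
        write_dstat_tsv(results, out / "dstat.tsv")
        n_sig = sum(1 for r in results if r.fitted_model != "none")
        report.sections["dstat"] = {
            "n_quartets": len(results),
            "n_significant": n_sig,
        }

    if config.run_migration:
        cov, _ = frequency_covariance(freqs, config.block_size)
        cov.to_csv(out / "frequency_covariance.tsv", sep="\t")
        base = tree_from_covariance(cov, outgroup=config.outgroup)
        graph = add_migration_edges(
            cov,
            base,
            max_edges=config.max_edges,
            accept_threshold=config.migration_threshold,
        )
        with open(out / "migration_base_tree.nwk", "w") as fh:
            fh.write(base.to_newick() + "\n")
        write_edges_tsv(graph, out / "migration_edges.tsv")
        graph.residuals.to_csv(out / "migration_residuals.tsv", sep="\t")
        report.sections["migration"] = {
            "n_edges": len(graph.migration_edges),
            "fit_sse": f"{graph.fit_sse:.6g}",
        }

    report.write(out / "run_report.tsv")
    return report
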