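"""SNP genotype matrices: VCF input/output, site filtering, allele frequencies.

The central object is :class:`GenotypeMatrix`, a sites x samples table of
diploid alt-allele dosages (0/1/2, -1 for missing) with per-genotype depth and
a sample-to-population map. Site filters follow common reduced-representation
practice: per-genotype depth masking (dp), minimum per-site call rate
(interpreted from a "mis" missingness parameter), pooled minor-allele
frequency (maf), and a duplicated-region proxy combining excess
heterozygosity with excess depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    sites: pd.DataFrame  # columns chrom, pos, ref, alt
    samples: list[str]
    dosage: np.ndarray   # (n_sites, n_samples) int8, -1 = missing
    depth: np.ndarray    # (n_sites, n_samples) int32, -1 = missing
    popmap: dict[str, str]

    def __post_init__(self) -> None:
        n_sites, n_samples = self.dosage.shape
        if len(self.sites) != n_sites or len(self.samples) != n_samples:
            raise ValueError("inconsistent matrix dimensions")
        if self.depth.shape != self.dosage.shape:
            raise ValueError("depth and dosage shapes differ")
        missing_pops = [s for s in self.samples if s not in self.popmap]
        if missing_pops:
            raise ValueError(
                f"samples absent from population map: {missing_pops}"
            )

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.popmap[s], None)
        return list(seen)

    def restrict_population(self, population: str) -> "GenotypeMatrix":
        cols = [i for i, s in enumerate(self.samples) if self.popmap[s] == population]
        if not cols:
            raise KeyError(f"no samples for population {population!r}")
        samples = [self.samples[i] for i in cols]
        return GenotypeMatrix(
            sites=self.sites.reset_index(drop=True),
            samples=samples,
            dosage=self.dosage[:, cols],
            depth=self.depth[:, cols],
            popmap={s: self.popmap[s] for s in samples},
        )

    def take_sites(self, index) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[index],
            depth=self.depth[index],
            popmap=dict(self.popmap),
        )


@dataclass
class SiteFilterSpec:
    """Thresholds for site filtering.

    call_rate_min is the minimum fraction of samples with a called genotype
    (after depth masking); dp_min masks individual genotypes below that depth;
    maf_min applies to the pooled minor-allele frequency across all called
    allele copies; the duplicated-region proxy removes sites with
    heterozygote fraction above dup_het_max or mean depth above
    dup_depth_factor times the genome-wide mean.
    """

    maf_min: float = 0.01
    call_rate_min: float = 0.7
    dp_min: int = 2
    dup_het_max: float = 0.75
    dup_depth_factor: float = 2.5

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "dup_het_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dp_min < 0:
            raise ValueError("dp_min must be non-negative")


@dataclass
class PopulationAlleleFrequencies:
    sites: pd.DataFrame
    populations: list[str]
    freq: np.ndarray       # (n_sites, n_pops) float, nan = no calls
    n_alleles: np.ndarray  # (n_sites, n_pops) int, called allele copies

    def __post_init__(self) -> None:
        if self.freq.shape != self.n_alleles.shape:
            raise ValueError("freq and n_alleles shapes differ")
        if self.freq.shape[1] != len(self.populations):
            raise ValueError("population count mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = self.sites.copy()
        for j, pop in enumerate(self.populations):
            df[pop] = self.freq[:, j]
        return df


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_popmap(path) -> dict[str, str]:
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            popmap[sample] = pop
    return popmap


def read_vcf(path, popmap: dict[str, str] | str) -> GenotypeMatrix:
    """Load a multi-sample VCF of biallelic SNPs.

    Multiallelic and non-SNP records are skipped with a logged count. Dosages
    come from GT regardless of phasing; absent DP is recorded as missing depth
    (treated as passing any depth filter).
    """
    from cyvcf2 import VCF

    if isinstance(popmap, (str,)) or hasattr(popmap, "__fspath__"):
        popmap = read_popmap(popmap)

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    offenders = [s for s in samples if s not in popmap]
    if offenders:
        raise ValueError(f"samples absent from population map: {offenders}")

    chroms, poss, refs, alts = [], [], [], []
    dosage_rows, depth_rows = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = var.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        dosage_rows.append(gt)
        dp = var.format("DP")
        if dp is None:
            depth_rows.append(np.full(len(samples), MISSING, dtype=np.int32))
        else:
            dp = dp.astype(np.int32).reshape(-1)
            dp[dp < 0] = MISSING
            depth_rows.append(dp)
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records", n_skipped)

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = (
        np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(samples)), np.int8)
    )
    depth = (
        np.vstack(depth_rows) if depth_rows else np.empty((0, len(samples)), np.int32)
    )
    return GenotypeMatrix(sites, samples, dosage, depth, dict(popmap))


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as VCFv4.2 with GT and DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        for chrom in pd.unique(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i in range(gm.n_sites):
            row = gm.sites.iloc[i]
            fields = [
                str(row["chrom"]),
                str(row["pos"]),
                ".",
                str(row["ref"]),
                str(row["alt"]),
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for j in range(gm.n_samples):
                dp = gm.depth[i, j]
                dp_str = "." if dp == MISSING else str(int(dp))
                fields.append(f"{gt_str[int(gm.dosage[i, j])]}:{dp_str}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# filtering and frequencies
# ---------------------------------------------------------------------------

def filter_sites(
    gm: GenotypeMatrix, spec: SiteFilterSpec = SiteFilterSpec()
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply depth masking then the per-site filters.

    Order of attribution: genotypes below dp_min are first masked; then sites
    are removed for (a) call rate, (b) pooled MAF, (c) the duplicated-region
    proxy, each site credited to the first rule it fails.
    """
    counts = {
        "genotypes_depth_masked": 0,
        "removed_call_rate": 0,
        "removed_maf": 0,
        "removed_duplicate_proxy": 0,
        "kept": 0,
    }
    if gm.n_sites == 0:
        return gm, counts

    dosage = gm.dosage.copy()
    depth = gm.depth
    mask = (depth != MISSING) & (depth < spec.dp_min) & (dosage != MISSING)
    counts["genotypes_depth_masked"] = int(mask.sum())
    dosage[mask] = MISSING

    called = dosage != MISSING
    n_called = called.sum(axis=1)
    call_rate = n_called / gm.n_samples

    alt_copies = np.where(called, dosage, 0).sum(axis=1)
    total_copies = 2 * n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total_copies > 0, alt_copies / np.maximum(total_copies, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)

    het_frac = np.where(
        n_called > 0, (dosage == 1).sum(axis=1) / np.maximum(n_called, 1), 0.0
    )
    depth_ok = depth != MISSING
    site_depth = np.where(
        depth_ok.any(axis=1),
        np.where(depth_ok, depth, 0).sum(axis=1) / np.maximum(depth_ok.sum(axis=1), 1),
        0.0,
    )
    overall_mean_depth = (
        np.where(depth_ok, depth, 0).sum() / max(depth_ok.sum(), 1)
    )

    fail_call = call_rate < spec.call_rate_min
    fail_maf = ~fail_call & ((total_copies == 0) | np.isnan(maf) | (maf < spec.maf_min))
    fail_dup = (
        ~fail_call
        & ~fail_maf
        & (
            (het_frac > spec.dup_het_max)
            | (site_depth > spec.dup_depth_factor * overall_mean_depth)
        )
    )
    keep = ~(fail_call | fail_maf | fail_dup)

    counts["removed_call_rate"] = int(fail_call.sum())
    counts["removed_maf"] = int(fail_maf.sum())
    counts["removed_duplicate_proxy"] = int(fail_dup.sum())
    counts["kept"] = int(keep.sum())

    out = GenotypeMatrix(
        sites=gm.sites.loc[keep].reset_index(drop=True),
        samples=list(gm.samples),
        dosage=dosage[keep],
        depth=gm.depth[keep],
        popmap=dict(gm.popmap),
    )
    return out, counts


def allele_frequencies(gm: GenotypeMatrix) -> PopulationAlleleFrequencies:
    """Per-site, per-population alt-allele frequencies over called genotypes."""
    pops = gm.populations
    n_sites = gm.n_sites
    freq = np.full((n_sites, len(pops)), np.nan)
    n_alleles = np.zeros((n_sites, len(pops)), dtype=np.int64)
    for j, pop in enumerate(pops):
        cols = [i for i, s in enumerate(gm.samples) if gm.popmap[s] == pop]
        sub = gm.dosage[:, cols]
        called = sub != MISSING
        n = 2 * called.sum(axis=1)
        alt = np.where(called, sub, 0).sum(axis=1)
        n_alleles[:, j] = n
        with np.errstate(divide="ignore", invalid="ignore"):
            freq[:, j] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return PopulationAlleleFrequencies(
        sites=gm.sites.reset_index(drop=True),
        populations=pops,
        freq=freq,
        n_alleles=n_alleles,
    )
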