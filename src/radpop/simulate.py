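"""Synthetic SNP datasets with known ground truth.

Allele frequencies evolve down a rooted population tree under Balding–Nichols
beta drift: along a branch with drift parameter ``c`` the child frequency is
drawn from a beta distribution with mean ``p`` (the parent frequency) and
variance ``c * p * (1 - p)``. Admixture is a single pulse applied at the tips,
``p_target <- (1 - alpha) * p_target + alpha * p_source``. Genotypes are drawn
under inbreeding-adjusted Hardy–Weinberg proportions, with Poisson depth and
Bernoulli missingness, then written as VCFv4.2 plus a two-column population
map. A toy FASTQ generator plants reads of known QC classes (clean, high-N,
low-quality, adapter-bearing) for testing read filters.

All randomness flows from a single integer seed. Each stage uses its own
stream, ``numpy.random.default_rng(SeedSequence([seed, stage]))`` with stage
0 = frequencies, 1 = genotypes, 2 = reads, so stages are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .trees import Tree

C_MIN = 1e-6
C_MAX = 0.999

_QC_CLASSES = ("clean", "high_n", "low_quality", "adapter")


@dataclass
class SimulationConfig:
    """Ground-truth scenario for one synthetic dataset.

    ``tree`` carries per-branch drift parameters c in (0,1) as branch lengths;
    node ages (Myr), when the scenario is clock-like, live on ``Node.age``.
    ``admixture_events`` are (source_pop, target_pop, alpha) pulses applied at
    tip time in list order.
    """

    tree: Tree
    n_sites: int = 10_000
    n_per_pop: dict[str, int] = field(default_factory=dict)
    admixture_events: list[tuple[str, str, float]] = field(default_factory=list)
    inbreeding_f: dict[str, float] = field(default_factory=dict)
    miss_rate: float = 0.0
    depth_mean: float = 16.0
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        tips = set(self.tree.tip_labels())
        if len(tips) < 2:
            raise ValueError("tree must have at least 2 tips")
        for node in self.tree.postorder():
            if node.parent is None:
                continue
            if not (0.0 < node.length < 1.0):
                raise ValueError(
                    f"drift parameter c={node.length} on branch above "
                    f"{node.label or 'internal node'} must lie in (0, 1)"
                )
        for src, dst, alpha in self.admixture_events:
            if src == dst:
                raise ValueError("admixture source and target must differ")
            if not (0.0 <= alpha <= 1.0):
                raise ValueError(f"admixture proportion {alpha} outside [0, 1]")
            if src not in tips or dst not in tips:
                raise ValueError(f"admixture populations {src!r}/{dst!r} must be tree tips")
        if not (0.0 <= self.miss_rate < 1.0):
            raise ValueError("miss_rate must lie in [0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be an interval within (0, 1)")
        for pop, f in self.inbreeding_f.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"inbreeding F for {pop} outside [0, 1]")


@dataclass
class SimulationTruth:
    """Planted quantities: ancestral and per-population frequencies, seeds,
    and (after genotype sampling) the monomorphic-site discard count."""

    config: SimulationConfig
    ancestral_freq: np.ndarray  # (n_sites,)
    pop_freq: dict[str, np.ndarray]  # tip label -> (n_sites,)
    n_monomorphic_discarded: int = 0
    kept_site_index: Optional[np.ndarray] = None


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


def _beta_drift(rng: np.random.Generator, p: np.ndarray, c: float) -> np.ndarray:
    """Child frequencies: beta with mean p and variance c p(1-p)."""
    c = float(np.clip(c, C_MIN, C_MAX))
    scale = 1.0 / c - 1.0
    a = np.maximum(p * scale, 1e-12)
    b = np.maximum((1.0 - p) * scale, 1e-12)
    out = rng.beta(a, b)
    # frequencies exactly fixed stay fixed
    out = np.where(p <= 0.0, 0.0, out)
    out = np.where(p >= 1.0, 1.0, out)
    return out


def simulate_frequencies(config: SimulationConfig) -> SimulationTruth:
    """Evolve per-site allele frequencies down the configured tree.

    Deterministic given ``config.seed``. Admixture pulses are applied to tip
    frequencies after drift, in the order listed.
    """
    rng = _stage_rng(config.seed, 0)
    lo, hi = config.ancestral_freq_range
    anc = rng.uniform(lo, hi, size=config.n_sites)

    freq_at: dict[int, np.ndarray] = {id(config.tree.root): anc}
    for node in config.tree.preorder():
        if node.parent is None:
            continue
        parent_freq = freq_at[id(node.parent)]
        freq_at[id(node)] = _beta_drift(rng, parent_freq, node.length)

    pop_freq = {
        leaf.label: freq_at[id(leaf)].copy() for leaf in config.tree.leaves()
    }
    for src, dst, alpha in config.admixture_events:
        pop_freq[dst] = (1.0 - alpha) * pop_freq[dst] + alpha * pop_freq[src]

    return SimulationTruth(config=config, ancestral_freq=anc, pop_freq=pop_freq)


def sample_genotypes(truth: SimulationTruth, config: Optional[SimulationConfig] = None):
    """Draw diploid genotypes from the planted frequencies.

    Genotype probabilities follow inbreeding-adjusted Hardy-Weinberg:
    P(het) = 2p(1-p)(1-F), P(hom alt) = p^2 + F p(1-p). Per-genotype depth is
    Poisson(depth_mean); each genotype is independently set missing with
    probability miss_rate. Sites monomorphic across all sampled (called)
    genotypes are discarded and counted on the returned truth.

    Returns a :class:`radpop.snp_matrix.GenotypeMatrix`.
    """
    from .snp_matrix import GenotypeMatrix  # local import to avoid a cycle

    config = config or truth.config
    pops = list(config.tree.tip_labels())
    for pop in pops:
        if pop not in config.n_per_pop:
            raise ValueError(f"n_per_pop missing tree tip {pop!r}")

    rng = _stage_rng(config.seed, 1)
    n_sites = config.n_sites

    sample_names: list[str] = []
    popmap: dict[str, str] = {}
    dosage_cols = []
    for pop in pops:
        n_ind = config.n_per_pop[pop]
        f_coef = config.inbreeding_f.get(pop, 0.0)
        p = truth.pop_freq[pop][:, None]  # (sites, 1)
        p_hom_ref = (1.0 - p) ** 2 + f_coef * p * (1.0 - p)
        p_het = 2.0 * p * (1.0 - p) * (1.0 - f_coef)
        u = rng.uniform(size=(n_sites, n_ind))
        dos = np.where(u < p_hom_ref, 0, np.where(u < p_hom_ref + p_het, 1, 2))
        dosage_cols.append(dos.astype(np.int8))
        for i in range(n_ind):
            name = f"{pop}_{i}"
            sample_names.append(name)
            popmap[name] = pop

    dosage = np.concatenate(dosage_cols, axis=1)
    depth = rng.poisson(config.depth_mean, size=dosage.shape).astype(np.int32)
    if config.miss_rate > 0:
        miss = rng.uniform(size=dosage.shape) < config.miss_rate
        dosage = np.where(miss, -1, dosage).astype(np.int8)

    called = dosage >= 0
    any_called = called.any(axis=1)
    site_min = np.where(any_called, np.min(np.where(called, dosage, 2), axis=1), 0)
    site_max = np.where(any_called, np.max(np.where(called, dosage, 0), axis=1), 0)
    polymorphic = any_called & (site_min != site_max)

    truth.n_monomorphic_discarded = int((~polymorphic).sum())
    truth.kept_site_index = np.flatnonzero(polymorphic)

    dosage = dosage[polymorphic]
    depth = depth[polymorphic]
    n_kept = dosage.shape[0]
    import pandas as pd

    sites = pd.DataFrame(
        {
            "chrom": np.repeat("chr1", n_kept),
            "pos": 1 + 1000 * np.arange(n_kept, dtype=np.int64),
            "ref": np.repeat("A", n_kept),
            "alt": np.repeat("C", n_kept),
        }
    )
    return GenotypeMatrix(
        sites=sites,
        samples=sample_names,
        dosage=dosage,
        depth=depth,
        popmap=popmap,
    )


def write_popmap(popmap: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# toy FASTQ generator for the read-QC stage
# ---------------------------------------------------------------------------

def simulate_reads(
    n_reads: int,
    read_len: int,
    n_frac_planted: float,
    lowq_frac_planted: float,
    adapter: str,
    adapter_insert_len: int,
    seed: int,
    adapter_frac_planted: float = 0.0,
    fastq_path=None,
    truth_path=None,
):
    """Generate reads of known QC classes and return (records, truth_rows).

    Each read belongs to exactly one planted class. ``high_n`` reads carry at
    least 10% N bases; ``low_quality`` reads have more than half their bases
    below phred 5; ``adapter`` reads contain an exact adapter substring of
    ``adapter_insert_len`` bases. Reads are audited against all three filter
    rules at construction so a read fails only the rule of its own class.

    records: list of (identifier, bases, quals_string phred+33);
    truth_rows: list of (identifier, class).
    """
    from . import qc

    if adapter_insert_len > read_len:
        raise ValueError("adapter insert longer than read")
    if adapter_insert_len > len(adapter):
        raise ValueError("adapter insert longer than adapter itself")
    for frac in (n_frac_planted, lowq_frac_planted, adapter_frac_planted):
        if not (0.0 <= frac <= 1.0):
            raise ValueError("planted fractions must lie in [0, 1]")
    if n_frac_planted + lowq_frac_planted + adapter_frac_planted > 1.0:
        raise ValueError("planted fractions sum above 1")

    rng = _stage_rng(seed, 2)
    if adapter_frac_planted > 0 and adapter_insert_len <= 10:
        raise ValueError(
            "adapter_insert_len must exceed 10 nt for planted adapter reads "
            "to fail the adapter rule"
        )
    n_highn = int(round(n_frac_planted * n_reads))
    n_lowq = int(round(lowq_frac_planted * n_reads))
    n_adapt = int(round(adapter_frac_planted * n_reads))
    classes = (
        ["high_n"] * n_highn
        + ["low_quality"] * n_lowq
        + ["adapter"] * n_adapt
        + ["clean"] * (n_reads - n_highn - n_lowq - n_adapt)
    )
    rng.shuffle(classes)

    bases_alphabet = np.array(list("ACGT"))

    def random_bases(k: int) -> np.ndarray:
        return bases_alphabet[rng.integers(0, 4, size=k)]

    def high_quals(k: int) -> np.ndarray:
        return rng.integers(30, 41, size=k)

    def passes_no_rule(bases: str, quals: np.ndarray) -> tuple[bool, bool, bool]:
        n_fail = bases.count("N") / len(bases) >= qc.N_FRAC_MAX
        q_fail = (quals < qc.PHRED_MIN).sum() / len(quals) > qc.LOWQ_FRAC_MAX
        a_fail = qc.adapter_match_len(bases, adapter, qc.ADAPTER_MISMATCH_FRAC) > qc.ADAPTER_MATCH_MAX
        return n_fail, q_fail, a_fail

    records = []
    truth_rows = []
    for i, cls in enumerate(classes):
        while True:
            bases = random_bases(read_len)
            quals = high_quals(read_len)
            if cls == "high_n":
                k = int(np.ceil(0.10 * read_len))
                pos = rng.choice(read_len, size=k, replace=False)
                bases[pos] = "N"
            elif cls == "low_quality":
                k = read_len // 2 + 1
                pos = rng.choice(read_len, size=k, replace=False)
                quals[pos] = rng.integers(0, 5, size=k)
            elif cls == "adapter":
                start = int(rng.integers(0, read_len - adapter_insert_len + 1))
                bases[start : start + adapter_insert_len] = list(
                    adapter[:adapter_insert_len]
                )
            seq = "".join(bases)
            n_fail, q_fail, a_fail = passes_no_rule(seq, quals)
            expect = (cls == "high_n", cls == "low_quality", cls == "adapter")
            if (n_fail, q_fail, a_fail) == expect:
                break
        ident = f"read_{i:06d}"
        qual_str = "".join(chr(int(q) + 33) for q in quals)
        records.append((ident, seq, qual_str))
        truth_rows.append((ident, cls))

    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for ident, seq, qual in records:
                fh.write(f"@{ident}\n{seq}\n+\n{qual}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read\tclass\n")
            for ident, cls in truth_rows:
                fh.write(f"{ident}\t{cls}\n")
    return records, truth_rows
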