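"""ABBA-BABA D-statistics from population allele frequencies, with
block-jackknife standard errors.

For an ordered quartet (W, X, Y, Z) — Z the outgroup, Y the reference
lineage — and per-site alt-allele frequencies w', x', y', z', each site
contributes

    num_i = (w' - x') (y' - z')
    den_i = (w' + x' - 2 w' x') (y' + z' - 2 y' z')

and D = sum(num) / sum(den). Positive D is an excess of BABA patterns
(W shares the derived allele with Y), negative D an excess of ABBA
(X shares with Y). The standard error comes from a weighted delete-one
block jackknife over contiguous SNP blocks (weights: each block's share of
the denominator), and |Z| > 2 is called significant: BABA for Z > 2, ABBA
for Z < -2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .snp_matrix import PopulationAlleleFrequencies

logger = logging.getLogger(__name__)


@dataclass
class DStatSpec:
    w: str
    x: str
    y: str
    z: str
    block_size: int = 500

    def __post_init__(self) -> None:
        if len({self.w, self.x, self.y, self.z}) != 4:
            raise ValueError("the four population labels must be distinct")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")


@dataclass
class DStatResult:
    spec: DStatSpec
    sum_num: float
    sum_den: float
    d: float
    se: float
    z: float
    n_sites_used: int
    n_blocks: int
    fitted_model: str  # "BABA", "ABBA" or "none"


def _weighted_jackknife(est: float, loo: np.ndarray, weights: np.ndarray) -> float:
    """Weighted delete-one block jackknife SE (Busing-style).

    ``loo[j]`` is the estimate with block j removed; ``weights[j]`` the
    block's weight (here its denominator mass); h_j = n / m_j.
    """
    n = weights.sum()
    h = n / weights
    g = len(loo)
    theta_dot = g * est - ((1.0 - weights / n) * loo).sum()
    pseudo = h * est - (h - 1.0) * loo
    var = np.sum((pseudo - theta_dot) ** 2 / (h - 1.0)) / g
    return float(np.sqrt(var))


def d_statistic(
    freqs: PopulationAlleleFrequencies, spec: DStatSpec
) -> DStatResult:
    """Compute D, its jackknife SE and Z for one quartet.

    Sites where any of the four frequencies is missing are dropped
    (complete-case); sites with zero denominator contribute nothing.
    """
    idx = {p: i for i, p in enumerate(freqs.populations)}
    for lab in (spec.w, spec.x, spec.y, spec.z):
        if lab not in idx:
            raise KeyError(f"population {lab!r} absent from frequency table")
    w = freqs.freq[:, idx[spec.w]]
    x = freqs.freq[:, idx[spec.x]]
    y = freqs.freq[:, idx[spec.y]]
    z = freqs.freq[:, idx[spec.z]]
    complete = ~(np.isnan(w) | np.isnan(x) | np.isnan(y) | np.isnan(z))
    w, x, y, z = w[complete], x[complete], y[complete], z[complete]

    num = (w - x) * (y - z)
    den = (w + x - 2.0 * w * x) * (y + z - 2.0 * y * z)

    total_den = float(den.sum())
    if total_den == 0.0:
        raise ValueError("no informative sites")
    total_num = float(num.sum())
    d = total_num / total_den

    n_sites = len(num)
    n_blocks = n_sites // spec.block_size + (1 if n_sites % spec.block_size else 0)
    if n_blocks < 2:
        raise ValueError(
            f"need >= 2 jackknife blocks, got {n_blocks} "
            f"({n_sites} usable sites at block size {spec.block_size})"
        )
    edges = np.arange(0, n_sites + spec.block_size, spec.block_size)[: n_blocks + 1]
    edges[-1] = n_sites
    block_num = np.array([num[a:b].sum() for a, b in zip(edges[:-1], edges[1:])])
    block_den = np.array([den[a:b].sum() for a, b in zip(edges[:-1], edges[1:])])

    usable = block_den > 0
    block_num, block_den = block_num[usable], block_den[usable]
    if len(block_num) < 2:
        raise ValueError("need >= 2 jackknife blocks with nonzero denominator")
    loo = (total_num - block_num) / (total_den - block_den)
    se = _weighted_jackknife(d, loo, block_den)
    if se > 0:
        zscore = d / se
    else:  # degenerate: identical blocks; sign still meaningful
        zscore = 0.0 if d == 0 else np.copysign(np.inf, d)

    if zscore > 2.0:
        model = "BABA"
    elif zscore < -2.0:
        model = "ABBA"
    else:
        model = "none"
    return DStatResult(
        spec=spec,
        sum_num=total_num,
        sum_den=total_den,
        d=d,
        se=se,
        z=float(zscore),
        n_sites_used=n_sites,
        n_blocks=int(len(block_num)),
        fitted_model=model,
    )


def quartet_scan(
    freqs: PopulationAlleleFrequencies,
    outgroup: str,
    block_size: int = 500,
) -> list[DStatResult]:
    """All quartets with the given outgroup as Z.

    Ordered (W, X, Y) triples over the non-outgroup populations, keeping only
    W < X lexicographically (swapping W and X merely negates D); results are
    sorted by |Z| descending.
    """
    pops = [p for p in freqs.populations if p != outgroup]
    if len(pops) < 3:
        raise ValueError("need at least 3 non-outgroup populations")
    results = []
    for w, x in itertools.combinations(sorted(pops), 2):
        for y in pops:
            if y in (w, x):
                continue
            spec = DStatSpec(w=w, x=x, y=y, z=outgroup, block_size=block_size)
            try:
                results.append(d_statistic(freqs, spec))
            except (ValueError, KeyError) as exc:
                logger.info("skipping quartet %s: %s", spec, exc)
    results.sort(key=lambda r: (-abs(r.z), r.spec.w, r.spec.x, r.spec.y))
    return results


def write_dstat_tsv(results: list[DStatResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("W\tX\tY\tZ\td\tse\tz\tn_sites\tn_blocks\tfitted_model\n")
        for r in results:
            fh.write(
                f"{r.spec.w}\t{r.spec.x}\t{r.spec.y}\t{r.spec.z}\t"
                f"{r.d:.6f}\t{r.se:.6f}\t{r.z:.4f}\t{r.n_sites_used}\t"
                f"{r.n_blocks}\t{r.fitted_model}\n"
            )
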