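"""Per-population diversity statistics: nucleotide diversity (pi), expected
heterozygosity (He, Nei's unbiased estimator) and observed heterozygosity (Ho).

pi at a site with n called allele copies of which k are the alt allele is the
probability that two copies drawn without replacement differ,
2k(n-k)/(n(n-1)); the reported pi is the mean over usable sites, optionally
rescaled by a callable-length L to a per-bp figure. He uses the small-sample
correction 2n/(2n-1) on the heterozygosity expected from allele frequencies;
the plain 1 - p^2 - q^2 form is available via ``unbiased=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .snp_matrix import MISSING, GenotypeMatrix


@dataclass
class DiversitySummary:
    population: str
    pi: float
    he: float
    ho: float
    n_sites_used: int
    n_samples: int


def _site_counts(gm_pop: GenotypeMatrix):
    called = gm_pop.dosage != MISSING
    n_ind = called.sum(axis=1)               # called diploid individuals
    alt = np.where(called, gm_pop.dosage, 0).sum(axis=1)
    het = (gm_pop.dosage == 1).sum(axis=1)
    return n_ind, alt, het


def nucleotide_diversity(
    gm_pop: GenotypeMatrix, callable_length: Optional[float] = None
) -> float:
    """Mean per-site pi over sites with >= 2 called allele copies.

    With ``callable_length`` L the sum of per-site pi is divided by L instead
    of the usable site count, giving a per-bp estimate.
    """
    n_ind, alt, _ = _site_counts(gm_pop)
    n = 2 * n_ind
    usable = n >= 2
    if not usable.any():
        raise ValueError("no informative sites")
    n_u = n[usable].astype(float)
    k = alt[usable].astype(float)
    pi_site = 2.0 * k * (n_u - k) / (n_u * (n_u - 1.0))
    if callable_length is not None:
        return float(pi_site.sum() / callable_length)
    return float(pi_site.mean())


def heterozygosity(
    gm_pop: GenotypeMatrix, unbiased: bool = True
) -> tuple[float, float]:
    """(He, Ho): means over sites with >= 2 called individuals."""
    n_ind, alt, het = _site_counts(gm_pop)
    usable = n_ind >= 2
    if not usable.any():
        raise ValueError("no informative sites")
    n = n_ind[usable].astype(float)
    p = alt[usable] / (2.0 * n)
    he_site = 1.0 - p**2 - (1.0 - p) ** 2
    if unbiased:
        he_site = he_site * (2.0 * n) / (2.0 * n - 1.0)
    ho_site = het[usable] / n
    return float(he_site.mean()), float(ho_site.mean())


def diversity_table(
    gm: GenotypeMatrix,
    callable_length: Optional[float] = None,
    unbiased: bool = True,
) -> list[DiversitySummary]:
    """One summary row per population, in population-map order."""
    rows = []
    for pop in gm.populations:
        sub = gm.restrict_population(pop)
        pi = nucleotide_diversity(sub, callable_length)
        he, ho = heterozygosity(sub, unbiased)
        n_ind, _, _ = _site_counts(sub)
        rows.append(
            DiversitySummary(
                population=pop,
                pi=pi,
                he=he,
                ho=ho,
                n_sites_used=int((n_ind >= 2).sum()),
                n_samples=sub.n_samples,
            )
        )
    return rows


def write_diversity_tsv(rows: list[DiversitySummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("population\tpi\the\tho\tn_sites_used\tn_samples\n")
        for r in rows:
            fh.write(
                f"{r.population}\t{r.pi:.6f}\t{r.he:.6f}\t{r.ho:.6f}\t"
                f"{r.n_sites_used}\t{r.n_samples}\n"
            )
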