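"""Migration-edge inference from allele-frequency covariance.

Under Gaussian drift down a tree, the covariance (across sites) of
population allele frequencies is, before centering, V_ab = drift path length
shared by a and b from the root to their MRCA. Observed frequencies are
centered by the across-population mean per site, so the model fitted to data
is the doubly centered matrix H V H. Branch lengths are fitted by
non-negative least squares; migration is modeled as a pulse that makes a
target tip's lineage a mixture of its own path and the source tip's path,
and edges are added greedily while each best edge still explains at least a
set fraction of the residual sum of squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .snp_matrix import PopulationAlleleFrequencies
from .trees import Node, Tree

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2))


@dataclass
class MigrationEdge:
    source: str
    target: str
    alpha: float
    sse_reduction: float  # relative reduction when the edge was accepted


@dataclass
class PopGraph:
    base_tree: Tree
    migration_edges: list[MigrationEdge]
    branch_lengths: dict[str, float]
    fit_sse: float
    residuals: pd.DataFrame
    sse_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# empirical covariance
# ---------------------------------------------------------------------------

def frequency_covariance(
    freqs: PopulationAlleleFrequencies,
    block_size: int = 500,
    sample_size_correction: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centered allele-frequency covariance with block-jackknife SEs.

    Per complete-case site the frequencies are centered by the
    across-population mean; the covariance is the average outer product.
    With ``sample_size_correction`` the binomial sampling variance of each
    estimated frequency, p(1-p)/(n_alleles - 1) averaged over sites, is
    removed in its centered form H diag(S) H — centering spreads the noise
    of each population into every entry, so the subtraction must be centered
    identically or a bias of order S/k remains everywhere.
    """
    pops = freqs.populations
    if len(pops) < 3:
        raise ValueError("need at least 3 populations")
    complete = ~np.isnan(freqs.freq).any(axis=1)
    if complete.sum() < 100:
        raise ValueError(f"only {int(complete.sum())} complete-case sites (< 100)")
    p = freqs.freq[complete]
    n_al = freqs.n_alleles[complete]
    for j, pop in enumerate(pops):
        if (n_al[:, j] == 0).all():
            raise ValueError(f"population {pop} has no complete-case sites")

    centered = p - p.mean(axis=1, keepdims=True)
    n_sites = centered.shape[0]
    cov = centered.T @ centered / n_sites

    # unbiased estimate of the binomial sampling variance of each p-hat:
    # E[p(1-p)/(n-1)] = p(1-p)/n. Centering mixes this noise into every
    # entry, so the correction must be centered the same way: subtract
    # H diag(S) H, not just the diagonal.
    if sample_size_correction:
        with np.errstate(divide="ignore", invalid="ignore"):
            samp_var = np.where(n_al > 1, p * (1.0 - p) / np.maximum(n_al - 1, 1), 0.0)
        correction = samp_var.mean(axis=0)
        k = len(pops)
        h = np.eye(k) - np.ones((k, k)) / k
        cov = cov - h @ np.diag(correction) @ h

    # block jackknife SEs
    n_blocks = max(n_sites // block_size, 1)
    if n_blocks > 1:
        edges = np.linspace(0, n_sites, n_blocks + 1).astype(int)
        reps = []
        for a, b in zip(edges[:-1], edges[1:]):
            keep = np.ones(n_sites, dtype=bool)
            keep[a:b] = False
            sub = centered[keep]
            reps.append(sub.T @ sub / keep.sum())
        reps = np.array(reps)
        g = len(reps)
        se = np.sqrt((g - 1) / g * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0))
    else:
        se = np.zeros_like(cov)
    return (
        pd.DataFrame(cov, index=pops, columns=pops),
        pd.DataFrame(se, index=pops, columns=pops),
    )


# ---------------------------------------------------------------------------
# tree fitting
# ---------------------------------------------------------------------------

def _branch_list(tree: Tree) -> list[Node]:
    return [n for n in tree.postorder() if n.parent is not None]


def _branch_name(node: Node, counter: dict) -> str:
    if node.is_leaf:
        return node.label
    key = id(node)
    if key not in counter:
        counter[key] = f"internal_{len(counter)}"
    return counter[key]


def _root_paths(tree: Tree) -> tuple[list[str], dict[str, np.ndarray], list[Node]]:
    """Indicator vectors over branches for each tip's root-to-tip path."""
    branches = _branch_list(tree)
    index = {id(b): i for i, b in enumerate(branches)}
    tips = tree.tip_labels()
    paths: dict[str, np.ndarray] = {}
    for leaf in tree.leaves():
        vec = np.zeros(len(branches))
        node = leaf
        while node.parent is not None:
            vec[index[id(node)]] = 1.0
            node = node.parent
        paths[leaf.label] = vec
    return tips, paths, branches


def _design_matrix(
    paths: dict[str, np.ndarray], pops: list[str]
) -> np.ndarray:
    """Rows: (a, b) pairs incl. diagonal; columns: branches. The centered
    model prediction is H V H flattened over the same pairs."""
    k = len(pops)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    n_branches = len(next(iter(paths.values())))
    # uncentered V = sum_e b_e r_a[e] r_b[e]; centered via H on both sides.
    # Build, per branch e, the centered basis matrix and flatten its pairs.
    r = np.stack([paths[p] for p in pops])  # (k, n_branches)
    design = np.zeros((len(pairs), n_branches))
    h = np.eye(k) - np.ones((k, k)) / k
    for e in range(n_branches):
        basis = np.outer(r[:, e], r[:, e])
        cb = h @ basis @ h
        design[:, e] = [cb[i, j] for i, j in pairs]
    return design


def _pair_vector(mat: np.ndarray, k: int) -> np.ndarray:
    return np.array([mat[i, j] for i in range(k) for j in range(i, k)])


def fit_tree_ls(
    cov: pd.DataFrame,
    topology: Tree,
    paths: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, float], pd.DataFrame, pd.DataFrame, float]:
    """Fit non-negative branch lengths to a centered covariance.

    Returns (branch lengths keyed by tip label or an internal id, predicted
    centered covariance, residuals, sse).
    """
    pops = list(cov.index)
    if set(topology.tip_labels()) != set(pops):
        raise ValueError("topology tips do not match covariance labels")
    tips, auto_paths, branches = _root_paths(topology)
    paths = paths or auto_paths
    design = _design_matrix(paths, pops)
    target = _pair_vector(cov.to_numpy(dtype=float), len(pops))
    lengths, _ = nnls(design, target)
    pred_vec = design @ lengths
    k = len(pops)
    pred = np.zeros((k, k))
    for (i, j), v in zip(
        [(i, j) for i in range(k) for j in range(i, k)], pred_vec
    ):
        pred[i, j] = pred[j, i] = v
    resid = cov.to_numpy(dtype=float) - pred
    sse = float((_pair_vector(resid, k) ** 2).sum())
    counter: dict = {}
    names = [_branch_name(b, counter) for b in branches]
    bl = dict(zip(names, lengths))
    return (
        bl,
        pd.DataFrame(pred, index=pops, columns=pops),
        pd.DataFrame(resid, index=pops, columns=pops),
        sse,
    )


def tree_from_covariance(cov: pd.DataFrame, outgroup: str | None = None) -> Tree:
    """NJ topology from the covariance-implied distances
    d_ab = cov_aa + cov_bb - 2 cov_ab."""
    from .phylogeny import neighbor_joining

    arr = cov.to_numpy(dtype=float)
    diag = np.diag(arr)
    d = diag[:, None] + diag[None, :] - 2.0 * arr
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    dist = pd.DataFrame(d, index=cov.index, columns=cov.columns)
    return neighbor_joining(dist, outgroup=outgroup)


def add_migration_edges(
    cov: pd.DataFrame,
    base: Tree,
    max_edges: int = 5,
    alpha_grid=DEFAULT_ALPHA_GRID,
    accept_threshold: float = 0.05,
) -> PopGraph:
    """Greedy migration-edge search on top of a fixed tree topology.

    A candidate edge (source s, target t, weight alpha) replaces t's
    root-to-tip indicator path with (1-alpha)*path(t) + alpha*path(s) and
    refits all branch lengths; the best candidate is accepted while its
    relative sse reduction is at least ``accept_threshold``.
    """
    for alpha in alpha_grid:
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha grid values must lie in (0, 1)")
    pops = list(cov.index)
    tips, base_paths, _ = _root_paths(base)

    current_paths = {p: base_paths[p].copy() for p in pops}
    bl, pred, resid, sse = fit_tree_ls(cov, base, current_paths)
    trace = [sse]
    edges: list[MigrationEdge] = []

    for _ in range(max_edges):
        if sse <= 1e-12:
            break
        best = None
        for s, t in itertools.permutations(pops, 2):
            if any(e.target == t for e in edges):
                continue  # one inbound pulse per target
            for alpha in alpha_grid:
                trial = dict(current_paths)
                trial[t] = (1.0 - alpha) * current_paths[t] + alpha * base_paths[s]
                _, _, _, trial_sse = fit_tree_ls(cov, base, trial)
                if best is None or trial_sse < best[0]:
                    best = (trial_sse, s, t, float(alpha), trial)
        if best is None:
            break
        trial_sse, s, t, alpha, trial = best
        rel = (sse - trial_sse) / sse
        if rel < accept_threshold:
            break
        current_paths = trial
        edges.append(MigrationEdge(s, t, alpha, rel))
        bl, pred, resid, sse = fit_tree_ls(cov, base, current_paths)
        trace.append(sse)

    return PopGraph(
        base_tree=base,
        migration_edges=edges,
        branch_lengths=bl,
        fit_sse=sse,
        residuals=resid,
        sse_trace=trace,
    )


def write_edges_tsv(graph: PopGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\talpha\tsse_reduction\n")
        for e in graph.migration_edges:
            fh.write(f"{e.source}\t{e.target}\t{e.alpha:g}\t{e.sse_reduction:.6f}\n")
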