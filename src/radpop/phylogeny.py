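"""Population trees: Nei distances, neighbor joining, UPGMA, two-state
pruning likelihood with NNI search, bootstrap supports, and
calibration-anchored divergence dating.

SNP matrices carry biallelic sites only, so the substitution model is the
two-state symmetric chain: along a branch of length t the probability of
observing a different state is (1 - exp(-2t))/2 and the stationary
distribution is (1/2, 1/2). Because matrices of variable sites carry no
constant columns, the pruning likelihood offers an ascertainment correction
that conditions each site on being variable. Divergence dating replaces a
relaxed-clock analysis with UPGMA (ultrametric by construction) scaled so
that one anchored node matches a known age.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar

from .snp_matrix import MISSING, GenotypeMatrix, PopulationAlleleFrequencies, allele_frequencies
from .trees import Node, Tree

BL_MIN = 1e-9
BL_MAX = 10.0
NNI_TOL = 1e-6


@dataclass
class CalibrationPoint:
    taxon_a: str
    taxon_b: str
    age_min: float  # Myr
    age_max: float

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ValueError("age_min must not exceed age_max")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_min + self.age_max)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def nei_distance(
    freqs: PopulationAlleleFrequencies,
    cap_factor: float = 2.0,
    unbiased: bool = True,
) -> pd.DataFrame:
    """Nei standard genetic distance, biallelic form, over jointly called sites.

    D_ab = -ln( sum_i (p_a p_b + q_a q_b)
                / sqrt(sum_i (p_a^2 + q_a^2) * sum_i (p_b^2 + q_b^2)) ).
    With ``unbiased`` (default) the within-population identities use the
    small-sample-corrected estimator (n J - 1)/(n - 1) with n the called
    allele copies — the raw p^2 sums are inflated by sampling variance,
    which would add a spurious constant to every between-population distance.
    Infinite distances (disjoint alleles at every site) are capped at
    ``cap_factor`` times the largest finite entry; negative estimates (a
    small-sample artifact) are clamped to zero.
    """
    pops = freqs.populations
    k = len(pops)
    if k < 2:
        raise ValueError("need at least 2 populations")
    p = freqs.freq
    n_al = freqs.n_alleles
    d = np.zeros((k, k))
    infinite: list[tuple[int, int]] = []
    for a, b in itertools.combinations(range(k), 2):
        joint = ~np.isnan(p[:, a]) & ~np.isnan(p[:, b])
        if not joint.any():
            raise ValueError(
                f"no jointly called sites for pair ({pops[a]}, {pops[b]})"
            )
        pa, pb = p[joint, a], p[joint, b]
        qa, qb = 1.0 - pa, 1.0 - pb
        jab = float((pa * pb + qa * qb).sum())
        jaa_site = pa**2 + qa**2
        jbb_site = pb**2 + qb**2
        if unbiased:
            na = n_al[joint, a]
            nb = n_al[joint, b]
            with np.errstate(divide="ignore", invalid="ignore"):
                jaa_site = np.where(na > 1, (na * jaa_site - 1.0) / (na - 1.0), jaa_site)
                jbb_site = np.where(nb > 1, (nb * jbb_site - 1.0) / (nb - 1.0), jbb_site)
        jaa = float(jaa_site.sum())
        jbb = float(jbb_site.sum())
        identity = jab / np.sqrt(max(jaa, 1e-300) * max(jbb, 1e-300))
        if identity <= 0.0:
            infinite.append((a, b))
        else:
            d[a, b] = d[b, a] = max(-np.log(identity), 0.0)
    if infinite:
        finite_max = d.max() if d.max() > 0 else 1.0
        for a, b in infinite:
            d[a, b] = d[b, a] = cap_factor * finite_max
    return pd.DataFrame(d, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# distance-based tree building
# ---------------------------------------------------------------------------

def _check_distance(dist: pd.DataFrame) -> None:
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("distance table must be square")
    if np.abs(arr - arr.T).max() > 1e-9:
        raise ValueError("distance table not symmetric")


def neighbor_joining(dist: pd.DataFrame, outgroup: str | None = None) -> Tree:
    """Standard NJ agglomeration; exact on additive distances.

    Negative branch lengths are clamped to zero. The unrooted result is
    rooted at the midpoint of the outgroup's pendant branch when an outgroup
    is given, else on the first taxon's branch (likelihoods under reversible
    models do not depend on the root position).
    """
    _check_distance(dist)
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    d = dist.to_numpy(dtype=float).copy()
    nodes: list[Node] = [Node(lab) for lab in labels]
    active = list(range(len(labels)))

    while len(active) > 2:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (n - 2))
        lj = dij - li
        parent = Node()
        ni, nj = nodes[i], nodes[j]
        ni.length = max(li, 0.0)
        nj.length = max(lj, 0.0)
        parent.add_child(ni)
        parent.add_child(nj)
        # distances from the new node
        new_d = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_d
        d[active, k] = new_d
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j = active
    ni, nj = nodes[i], nodes[j]
    root = Node()
    half = 0.5 * max(d[i, j], 0.0)
    ni.length = half
    nj.length = half
    root.add_child(ni)
    root.add_child(nj)
    tree = Tree(root)
    return root_at_tip(tree, outgroup or labels[0])


def root_at_tip(tree: Tree, tip_label: str) -> Tree:
    """Reroot so the root sits at the midpoint of the named tip's branch."""
    tree = tree.copy()
    tip = tree.find(tip_label)
    if tip.parent is None:
        raise ValueError("cannot root at a root tip")
    # walk from tip's parent to the old root, reversing parent links
    path = []
    node = tip.parent
    while node is not None:
        path.append(node)
        node = node.parent
    new_root = Node()
    half = 0.5 * tip.length
    tip_copy = tip
    tip_copy.parent.children.remove(tip_copy)
    tip_copy.length = half
    new_root.add_child(tip_copy)

    # re-hang the remainder: path[0] becomes the other child of new_root
    prev_len = half
    prev = new_root
    for idx, node in enumerate(path):
        # detach node from its parent (next in path)
        if idx + 1 < len(path):
            path[idx + 1].children.remove(node)
        saved_len = node.length
        node.length = prev_len
        node.parent = None
        prev.add_child(node)
        prev_len = saved_len
        prev = node
    return Tree(_suppress_unifurcations(new_root))


def _suppress_unifurcations(root: Node) -> Node:
    def fix(node: Node) -> Node:
        node.children = [fix(c) for c in node.children]
        for c in node.children:
            c.parent = node
        if len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            child.length += node.length
            child.parent = node.parent
            return child
        return node

    root = fix(root)
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = 0.0
    return root


def upgma(dist: pd.DataFrame) -> Tree:
    """Average-linkage clustering; ultrametric by construction.

    Node depths (root-to-node path lengths) equal half the cophenetic
    distance at each merge; tips sit at depth equal to the tree height.
    """
    _check_distance(dist)
    labels = list(dist.index)
    arr = dist.to_numpy(dtype=float)
    condensed = arr[np.triu_indices(len(labels), k=1)]
    z = linkage(condensed, method="average")
    nodes: dict[int, tuple[Node, float]] = {
        i: (Node(lab), 0.0) for i, lab in enumerate(labels)
    }
    n = len(labels)
    for step, (a, b, height, _) in enumerate(z):
        ha = height / 2.0
        left, left_h = nodes[int(a)]
        right, right_h = nodes[int(b)]
        parent = Node()
        left.length = ha - left_h
        right.length = ha - right_h
        parent.add_child(left)
        parent.add_child(right)
        nodes[n + step] = (parent, ha)
    root, _ = nodes[n + len(z) - 1]
    return Tree(root)


# ---------------------------------------------------------------------------
# two-state pruning likelihood
# ---------------------------------------------------------------------------

def _tip_partials(gm: GenotypeMatrix, labels: list[str]):
    """Tip partial likelihoods over unique site patterns, plus pattern weights.

    Dosage columns restricted to the tree tips are collapsed to their unique
    rows; the likelihood of each pattern is computed once and weighted by its
    multiplicity — with few tips this shrinks the site dimension by orders of
    magnitude.
    """
    col = {s: i for i, s in enumerate(gm.samples)}
    for lab in labels:
        if lab not in col:
            raise KeyError(f"tree tip {lab!r} absent from matrix samples")
    sub = gm.dosage[:, [col[lab] for lab in labels]]
    patterns, weights = np.unique(sub, axis=0, return_counts=True)
    partials = {}
    for j, lab in enumerate(labels):
        dos = patterns[:, j]
        part = np.ones((len(patterns), 2))
        part[dos == 0, 1] = 0.0
        part[dos == 2, 0] = 0.0
        partials[lab] = part
    return partials, weights.astype(float)


def _site_logliks(tree: Tree, partials: dict[str, np.ndarray], n_sites: int) -> np.ndarray:
    """Felsenstein pruning, vectorized across sites, with per-site rescaling."""
    log_scale = np.zeros(n_sites)
    part_at: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            part_at[id(node)] = partials[node.label]
            continue
        acc = np.ones((n_sites, 2))
        for child in node.children:
            t = max(child.length, 0.0)
            e = np.exp(-2.0 * t)
            p_same = 0.5 * (1.0 + e)
            p_diff = 0.5 * (1.0 - e)
            cp = part_at[id(child)]
            msg = np.empty_like(cp)
            msg[:, 0] = p_same * cp[:, 0] + p_diff * cp[:, 1]
            msg[:, 1] = p_diff * cp[:, 0] + p_same * cp[:, 1]
            acc *= msg
        m = acc.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        acc /= m[:, None]
        log_scale += np.log(m)
        part_at[id(node)] = acc
    root_part = part_at[id(tree.root)]
    lik = 0.5 * (root_part[:, 0] + root_part[:, 1])
    return np.log(lik) + log_scale


def _constant_pattern_lik(tree: Tree, state: int, n_tips: int) -> float:
    """Likelihood of the all-ref (state 0) or all-alt (state 1) pattern."""
    partials = {}
    for lab in [n.label for n in tree.leaves()]:
        part = np.zeros((1, 2))
        part[0, state] = 1.0
        partials[lab] = part
    return float(np.exp(_site_logliks(tree, partials, 1))[0])


def pruning_loglik(
    tree: Tree, gm: GenotypeMatrix, asc_correction: bool = False
) -> float:
    """Total log-likelihood of the matrix on the tree under the two-state
    symmetric model. Dosage 0 -> state {ref}, 2 -> {alt}, 1 or missing ->
    {ref, alt}. With ``asc_correction`` each site likelihood is conditioned
    on the site being variable."""
    labels = tree.tip_labels()
    partials, weights = _tip_partials(gm, labels)
    site_ll = _site_logliks(tree, partials, len(weights))
    if asc_correction:
        l_const = _constant_pattern_lik(tree, 0, len(labels)) + _constant_pattern_lik(
            tree, 1, len(labels)
        )
        site_ll = site_ll - np.log(max(1.0 - l_const, 1e-300))
    if not np.isfinite(site_ll).all():
        bad = int(np.flatnonzero(~np.isfinite(site_ll))[0])
        raise FloatingPointError(f"non-finite likelihood at site pattern {bad}")
    return float((site_ll * weights).sum())


# ---------------------------------------------------------------------------
# ML search
# ---------------------------------------------------------------------------

def _optimize_branch_lengths(
    tree: Tree, gm: GenotypeMatrix, asc: bool, max_passes: int = 10
) -> float:
    labels = tree.tip_labels()
    partials, weights = _tip_partials(gm, labels)
    n_pat = len(weights)

    def loglik() -> float:
        site_ll = _site_logliks(tree, partials, n_pat)
        if asc:
            l_const = _constant_pattern_lik(tree, 0, len(labels)) + _constant_pattern_lik(tree, 1, len(labels))
            site_ll = site_ll - np.log(max(1.0 - l_const, 1e-300))
        return float((site_ll * weights).sum())

    branches = [n for n in tree.postorder() if n.parent is not None]
    current = loglik()
    for _ in range(max_passes):
        for node in branches:
            def neg(t: float) -> float:
                node.length = t
                return -loglik()

            res = minimize_scalar(
                neg, bounds=(BL_MIN, BL_MAX), method="bounded",
                options={"xatol": 1e-6},
            )
            node.length = float(res.x)
        new = loglik()
        if new - current < 1e-6:
            current = max(new, current)
            break
        current = new
    return current


def _nni_neighbors(tree: Tree):
    """Yield trees one NNI move away (both rearrangements per internal edge)."""
    edges = [
        (i, j)
        for i, node in enumerate(tree.postorder())
        if not node.is_leaf and node.parent is not None
        for j in range(2)
    ]
    nodes = list(tree.postorder())
    for i, which in edges:
        new = tree.copy()
        new_nodes = list(new.postorder())
        c = new_nodes[i]
        p = c.parent
        siblings = [x for x in p.children if x is not c]
        if not siblings or len(c.children) < 2:
            continue
        s = siblings[0]
        a = c.children[which % len(c.children)]
        # swap subtree a with sibling s
        p.children[p.children.index(s)] = a
        c.children[c.children.index(a)] = s
        a.parent, s.parent = p, c
        yield new


def ml_search(
    gm: GenotypeMatrix,
    start: Tree,
    asc_correction: bool = False,
    max_rounds: int = 20,
) -> tuple[Tree, float, list[float]]:
    """Alternate branch-length optimization and NNI sweeps.

    Each round optimizes every branch length (bounded scalar search), then
    tries both NNI rearrangements across every internal edge, accepting a
    move if it improves the log-likelihood by more than 1e-6 (after
    re-optimizing branch lengths). Stops after a sweep with no accepted move
    or ``max_rounds`` rounds. Returns (tree, log-likelihood, trace); the
    trace is non-decreasing.
    """
    tree = start.copy()
    best_ll = _optimize_branch_lengths(tree, gm, asc_correction)
    trace = [best_ll]
    for _ in range(max_rounds):
        improved = False
        for cand in _nni_neighbors(tree):
            cand_ll = _optimize_branch_lengths(cand, gm, asc_correction)
            if cand_ll > best_ll + NNI_TOL:
                tree, best_ll = cand, cand_ll
                improved = True
                trace.append(best_ll)
                break  # restart the sweep from the improved tree
        if not improved:
            break
    return tree, best_ll, trace


# ---------------------------------------------------------------------------
# bootstrap and dating
# ---------------------------------------------------------------------------

def population_consensus(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse a matrix to one pseudo-sample per population.

    The consensus dosage is the alt-allele frequency rounded to the nearest
    of {0, 1, 2} copies (thresholds 0.25 and 0.75); missing when a
    population has no calls at the site.
    """
    freqs = allele_frequencies(gm)
    p = freqs.freq
    dosage = np.full(p.shape, MISSING, dtype=np.int8)
    called = ~np.isnan(p)
    dosage[called & (p < 0.25)] = 0
    dosage[called & (p >= 0.25) & (p < 0.75)] = 1
    dosage[called & (p >= 0.75)] = 2
    depth = np.where(called, freqs.n_alleles, MISSING).astype(np.int32)
    return GenotypeMatrix(
        sites=freqs.sites,
        samples=list(freqs.populations),
        dosage=dosage,
        depth=depth,
        popmap={p_: p_ for p_ in freqs.populations},
    )


def bootstrap_support(
    gm: GenotypeMatrix,
    n_reps: int = 100,
    seed: int = 0,
    fast: bool = True,
    outgroup: str | None = None,
    tree: Tree | None = None,
    asc_correction: bool = False,
) -> Tree:
    """Attach bootstrap supports (percent of replicates containing each
    internal bipartition) to the best tree.

    Site columns are resampled with replacement; each replicate is rebuilt by
    NJ on Nei distances (fast) or by a full NNI likelihood search.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    def build(matrix: GenotypeMatrix) -> Tree:
        freqs = allele_frequencies(matrix)
        dist = nei_distance(freqs)
        nj = neighbor_joining(dist, outgroup=outgroup)
        if fast:
            return nj
        t, _, _ = ml_search(population_consensus(matrix), nj, asc_correction)
        return t

    if tree is None:
        tree = build(gm)
    else:
        tree = tree.copy()

    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, gm.n_sites, size=gm.n_sites)
        rep_tree = build(gm.take_sites(idx))
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1

    all_tips = set(tree.tip_labels())
    anchor = min(all_tips)
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        from .trees import _subtree_leaves

        below = {n.label for n in _subtree_leaves(node)}
        if len(below) < 2 or len(all_tips - below) < 2:
            continue
        side = below if anchor not in below else all_tips - below
        node.support = 100.0 * counts.get(frozenset(side), 0) / n_reps
    return tree


def calibrate_ages(dist: pd.DataFrame, cal: CalibrationPoint) -> Tree:
    """UPGMA tree with node ages anchored to one calibrated divergence.

    The scale factor is the calibration midpoint divided by the depth
    (distance from tip level) of the MRCA of the two calibration taxa; every
    node age is its depth times that factor, so the anchored node's age is
    exactly the midpoint and tips sit at age 0.
    """
    for taxon in (cal.taxon_a, cal.taxon_b):
        if taxon not in dist.index:
            raise KeyError(f"calibration taxon {taxon!r} absent from distances")
    tree = upgma(dist)
    depths = tree.depths()
    height = max(depths[leaf] for leaf in tree.leaves())
    mrca = tree.mrca([cal.taxon_a, cal.taxon_b])
    mrca_height = height - depths[mrca]
    if mrca_height <= 0:
        raise ValueError("calibration taxa not separated")
    scale = cal.midpoint / mrca_height
    for node in tree.postorder():
        node.age = (height - depths[node]) * scale
        if node.is_leaf:
            node.age = 0.0
    return tree
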