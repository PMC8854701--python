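"""Clonal structure from multi-gland MAF profiles.

Covers the spatially-resolved analyses: selection of informative mutation
sites, hierarchical clustering of gland MAF profiles into clone clusters,
projection of clusters onto the sampling grid, classification of each
mutation as public / partially shared / private within a cluster, and
phylogeny reconstruction from binary mutation profiles (Hamming distances,
neighbor joining, Fitch parsimony scoring).

Clusters are defined by shared clonal mutations (MAF >= 0.25 in every
member) rather than by a dendrogram height cut: a clone cluster is a
maximal dendrogram clade whose members all carry at least ``min_shared``
such defining mutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from skbio import TreeNode


@dataclass
class MafMatrix:
    """Mutation sites x glands MAF matrix with optional metadata."""

    values: pd.DataFrame  # rows = sites, columns = glands, entries in [0, 1]
    site_meta: pd.DataFrame | None = None
    gland_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("MAF values outside [0, 1]")

    @property
    def sites(self) -> list:
        return list(self.values.index)

    @property
    def glands(self) -> list:
        return list(self.values.columns)


@dataclass
class CloneCluster:
    """A set of glands sharing clonal mutations."""

    cluster_id: str
    members: tuple[str, ...]
    defining_mutations: tuple = ()
    grid_footprint: frozenset = frozenset()

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SharingProfile:
    """Public / partially shared / private partition of a cluster's mutations."""

    cluster_id: str
    labels: dict  # site -> "public" | "partial" | "private"
    mb_pub: int
    mb_ps: int
    mb_priv: int

    @property
    def total(self) -> int:
        return self.mb_pub + self.mb_ps + self.mb_priv


def select_informative_mutations(
    matrix: MafMatrix,
    share_maf: float = 0.10,
    clonal_maf: float = 0.25,
    min_glands: int = 2,
    blood_maf: pd.Series | None = None,
    max_blood_maf: float = 0.05,
) -> MafMatrix:
    """Reduce a MAF matrix to informative sites.

    A site is retained when its MAF reaches ``clonal_maf`` in at least
    ``min_glands`` glands; sites whose matched-blood MAF exceeds
    ``max_blood_maf`` are excluded first as likely germline. The number of
    glands co-sharing each retained site at >= ``share_maf`` is recorded in
    the site metadata (column ``n_supporting``).
    """
    vals = matrix.values
    if vals.empty:
        raise ValueError("empty MAF matrix")
    if blood_maf is not None:
        germline = blood_maf.reindex(vals.index).fillna(0.0) > max_blood_maf
        vals = vals.loc[~germline]
    keep = (vals >= clonal_maf).sum(axis=1) >= min_glands
    reduced = vals.loc[keep]
    if reduced.empty:
        warnings.warn("no informative mutation sites passed selection")
    meta = pd.DataFrame(
        {"n_supporting": (reduced >= share_maf).sum(axis=1)}, index=reduced.index
    )
    if matrix.site_meta is not None:
        meta = matrix.site_meta.reindex(reduced.index).join(meta)
    return MafMatrix(values=reduced, site_meta=meta, gland_meta=matrix.gland_meta)


def cluster_glands(
    matrix: MafMatrix,
    linkage: str = "average",
    metric: str = "euclidean",
    min_shared: int = 2,
    clonal_maf: float = 0.25,
) -> tuple[list[CloneCluster], np.ndarray]:
    """Group glands into clone clusters by hierarchical clustering.

    Gland MAF columns are clustered agglomeratively; a clone cluster is a
    maximal clade of the dendrogram whose members all carry at least
    ``min_shared`` mutations at MAF >= ``clonal_maf`` (the cluster's
    defining mutations). Glands in no such clade are singletons. Returns
    the clusters (multi-gland first, then singletons) and the scipy
    linkage matrix of the dendrogram.
    """
    vals = matrix.values
    glands = list(vals.columns)
    if len(glands) < 2:
        raise ValueError("need at least 2 glands to cluster")
    X = vals.to_numpy(dtype=float).T  # glands x sites
    Z = scipy_linkage(X, method=linkage, metric=metric)
    clonal = vals >= clonal_maf  # sites x glands

    def shared_sites(members: list[str]) -> tuple:
        mask = clonal[members].all(axis=1)
        return tuple(vals.index[mask])

    root = to_tree(Z)
    clusters: list[CloneCluster] = []
    clustered: set[str] = set()

    def visit(node) -> None:
        leaves = [glands[i] for i in node.pre_order(lambda n: n.id) if i < len(glands)]
        if len(leaves) >= 2:
            defining = shared_sites(leaves)
            if len(defining) >= min_shared:
                clusters.append(
                    CloneCluster(
                        cluster_id=f"cluster{len(clusters) + 1}",
                        members=tuple(leaves),
                        defining_mutations=defining,
                    )
                )
                clustered.update(leaves)
                return
        if not node.is_leaf():
            visit(node.left)
            visit(node.right)

    visit(root)
    for g in glands:
        if g not in clustered:
            clusters.append(
                CloneCluster(
                    cluster_id=f"singleton_{g}", members=(g,),
                    defining_mutations=(),
                )
            )
    return clusters, Z


@dataclass
class GridFootprint:
    """A cluster's spatial extent on the sampling lattice."""

    cluster_id: str
    grids: frozenset
    contiguous: bool | None


def map_clusters_to_grid(
    clusters: Sequence[CloneCluster],
    gland_grid: Mapping[str, str],
    layout: Mapping[str, tuple[int, int]] | None = None,
) -> list[GridFootprint]:
    """Project clusters onto the sampling grid.

    ``gland_grid`` maps gland id to grid label; ``layout`` maps grid label
    to (row, col) lattice coordinates used for the 4-neighborhood
    contiguity check (contiguity is None when no layout is given). Glands
    without a grid assignment are excluded with a warning.
    """
    out = []
    for cluster in clusters:
        grids = set()
        for g in cluster.members:
            grid = gland_grid.get(g, "")
            if not grid:
                warnings.warn(f"gland {g} has no grid assignment; excluded")
                continue
            grids.add(grid)
        contiguous: bool | None = None
        if layout is not None and grids:
            coords = []
            for grid in grids:
                if grid not in layout:
                    raise KeyError(f"grid {grid!r} missing from layout")
                coords.append(tuple(layout[grid]))
            contiguous = _connected_4(coords)
        cluster.grid_footprint = frozenset(grids)
        out.append(
            GridFootprint(
                cluster_id=cluster.cluster_id,
                grids=frozenset(grids),
                contiguous=contiguous,
            )
        )
    return out


def _connected_4(coords: list[tuple[int, int]]) -> bool:
    """Is the cell set connected under 4-neighborhood adjacency?"""
    cells = set(coords)
    stack = [next(iter(cells))]
    seen = set()
    while stack:
        r, c = stack.pop()
        if (r, c) in seen:
            continue
        seen.add((r, c))
        for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
            if nb in cells and nb not in seen:
                stack.append(nb)
    return seen == cells


def classify_sharing(
    cluster: CloneCluster,
    matrix: MafMatrix,
    presence_maf: float = 0.25,
) -> SharingProfile:
    """Partition a cluster's mutations into public / partial / private.

    Presence of a mutation in a gland means MAF >= ``presence_maf``. A
    mutation present in all member glands is public (predating the most
    recent clonal expansion), in a strict subset of >= 2 glands partially
    shared, and in exactly one gland private. Sites absent from every
    member do not belong to the cluster and are ignored.
    """
    if cluster.size < 2:
        raise ValueError("sharing classification needs >= 2 member glands")
    present = matrix.values[list(cluster.members)] >= presence_maf
    n_present = present.sum(axis=1)
    labels = {}
    for site, n in n_present.items():
        if n == 0:
            continue
        if n == cluster.size:
            labels[site] = "public"
        elif n == 1:
            labels[site] = "private"
        else:
            labels[site] = "partial"
    counts = pd.Series(labels).value_counts() if labels else pd.Series(dtype=int)
    return SharingProfile(
        cluster_id=cluster.cluster_id,
        labels=labels,
        mb_pub=int(counts.get("public", 0)),
        mb_ps=int(counts.get("partial", 0)),
        mb_priv=int(counts.get("private", 0)),
    )


def hamming_matrix(profiles: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Hamming distances (counts of differing sites).

    ``profiles`` is taxa x sites, binary (presence/absence of each SNV).
    """
    P = (
        profiles.to_numpy() if isinstance(profiles, pd.DataFrame) else np.asarray(profiles)
    ).astype(int)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D taxa x sites array")
    D = np.zeros((P.shape[0], P.shape[0]), dtype=float)
    for i in range(P.shape[0]):
        diff = (P != P[i]).sum(axis=1)
        D[i, :] = diff
    return D


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Classic neighbor-joining tree from a distance matrix.

    Uses the Saitou-Nei Q-criterion for pair selection and the standard
    branch-length formulas; for an additive distance matrix the tree
    reproduces all pairwise path distances exactly. Negative branch
    lengths (possible for non-additive inputs) are clamped to zero with a
    warning. The result is an unrooted tree represented with a trifurcating
    root, as a scikit-bio ``TreeNode`` (Newick-serializable).
    """
    D = np.asarray(dist, dtype=float).copy()
    labels = list(labels)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    clamped = False

    def _len(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    nodes: list[TreeNode] = [TreeNode(name=str(lab)) for lab in labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        row = sub.sum(axis=1)
        Q = (m - 2) * sub - row[:, None] - row[None, :]
        np.fill_diagonal(Q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(Q), Q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        d_ij = sub[i_s, j_s]
        li = 0.5 * d_ij + (row[i_s] - row[j_s]) / (2.0 * (m - 2))
        lj = d_ij - li
        gi, gj = active[i_s], active[j_s]
        nodes[gi].length = _len(li)
        nodes[gj].length = _len(lj)
        parent = TreeNode(children=[nodes[gi], nodes[gj]])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0])
        for k_s in range(m):
            if k_s in (i_s, j_s):
                continue
            gk = active[k_s]
            new_row[gk] = 0.5 * (D[gi, gk] + D[gj, gk] - d_ij)
        D = np.vstack([D, new_row[None, :]])
        new_col = np.append(new_row, 0.0)
        D = np.hstack([D, new_col[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = _len(length)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    if clamped:
        warnings.warn("negative branch length(s) clamped to 0")
    return root


def parsimony_score(
    tree: TreeNode, characters: Mapping[str, Sequence[int]]
) -> int:
    """Fitch small-parsimony score of binary characters on a tree.

    ``characters`` maps each leaf name to its 0/1 profile; all profiles
    must be equal-length and the leaf set must match the tree's leaves.
    Returns the minimum total number of state changes over all characters.
    Polytomies are resolved arbitrarily with zero-length edges first
    (which leaves the minimum unchanged only for bifurcating input; the
    trifurcating NJ root is handled exactly).
    """
    leaves = {node.name for node in tree.tips()}
    if leaves != set(characters):
        raise ValueError("tree leaves do not match character profiles")
    lengths = {len(v) for v in characters.values()}
    if len(lengths) != 1:
        raise ValueError("character profiles must be equal-length")
    n_char = lengths.pop()

    score = 0
    for pos in range(n_char):
        def fitch(node) -> frozenset:
            nonlocal score
            if node.is_tip():
                return frozenset({int(characters[node.name][pos])})
            sets = [fitch(ch) for ch in node.children]
            state = sets[0]
            for s in sets[1:]:
                inter = state & s
                if inter:
                    state = inter
                else:
                    state = state | s
                    score += 1
            return state

        fitch(tree)
    return score
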