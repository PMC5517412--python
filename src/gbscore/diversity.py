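"""Genetic-diversity analyses on binary marker matrices.

Implements Gower's distance for presence/absence data with missing
values (simple-matching mismatch fraction over jointly observed
variables), redundancy-group detection and core-collection selection,
complete-linkage hierarchical clustering with plain-bootstrap branch
supports, and principal-coordinates analysis (classical MDS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .markers import MarkerMatrix

__all__ = [
    "DistanceMatrix", "RedundancyPartition", "Dendrogram", "PCoAResult",
    "gower_distance", "find_redundant", "calibrate_epsilon",
    "core_collection", "hclust_complete", "bootstrap_support", "pcoa",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance in [0, 1] with sample ids.

    ``shared`` counts the jointly observed variables behind each entry.
    """

    values: np.ndarray
    ids: list[str]
    shared: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("self-distances must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP-style lower-triangle writer."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{name} {row}".rstrip() + "\n")


@dataclass
class RedundancyPartition:
    """Redundancy groups (size >= 2), the remaining unique accessions and
    one representative per group."""

    groups: list[set[str]]
    unique_accessions: list[str]
    representatives: dict[int, str]
    epsilon: float

    def __post_init__(self) -> None:
        members = [m for g in self.groups for m in g]
        if len(members) != len(set(members)):
            raise ValueError("redundancy groups must be disjoint")
        for gid, rep in self.representatives.items():
            if rep not in self.groups[gid]:
                raise ValueError("representative must belong to its group")

    @property
    def n_redundant(self) -> int:
        """Non-representative group members (the accessions a core drops)."""
        return sum(len(g) - 1 for g in self.groups)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for gid, group in enumerate(self.groups):
            for member in sorted(group):
                rows.append({"group_id": gid, "member": member,
                             "is_representative": int(member == self.representatives[gid])})
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage form plus bootstrap supports.

    ``linkage`` is the (n-1, 4) agglomeration table (ids, height, size);
    ``supports`` maps internal-node index (n + merge step) to a
    percentage in [0, 100].
    """

    linkage: np.ndarray
    leaf_ids: list[str]
    supports: dict[int, float] = field(default_factory=dict)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def node_leafsets(self) -> dict[int, frozenset[int]]:
        """Leaf-index set under every internal node."""
        n = len(self.leaf_ids)
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for step, (a, b, _h, _s) in enumerate(self.linkage):
            sets[n + step] = sets[int(a)] | sets[int(b)]
        return {k: v for k, v in sets.items() if k >= n}

    def bipartitions(self) -> set[frozenset[int]]:
        """Canonical leaf bipartitions (the side not holding leaf 0);
        the root's trivial all-leaves split is excluded."""
        n = len(self.leaf_ids)
        full = frozenset(range(n))
        out = set()
        for side in self.node_leafsets().values():
            canon = full - side if 0 in side else side
            if 0 < len(canon) < n:
                out.add(canon)
        return out

    def cut(self, k: int) -> np.ndarray:
        """Labels for a k-group flat cut (scipy maxclust criterion)."""
        from scipy.cluster.hierarchy import fcluster
        return fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self, path: str | Path | None = None) -> str:
        """Newick string with bootstrap support as internal-node labels."""
        n = len(self.leaf_ids)

        def fmt(node: int, parent_h: float) -> str:
            if node < n:
                h = 0.0
                label = self.leaf_ids[node]
            else:
                step = node - n
                a, b, h = (int(self.linkage[step, 0]), int(self.linkage[step, 1]),
                           self.linkage[step, 2])
                sup = self.supports.get(node)
                label = f"({fmt(a, h)},{fmt(b, h)})" + (
                    f"{sup:.0f}" if sup is not None else "")
            return f"{label}:{max(parent_h - h, 0.0):.6f}"

        root = 2 * n - 2
        a, b, h = (int(self.linkage[-1, 0]), int(self.linkage[-1, 1]),
                   self.linkage[-1, 2])
        sup = self.supports.get(root)
        s = f"({fmt(a, h)},{fmt(b, h)})" + (f"{sup:.0f}" if sup is not None else "") + ";"
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


@dataclass
class PCoAResult:
    """Classical-MDS ordination: positive eigenvalues, coordinates and the
    proportion of analysed variance explained (PAVE) per axis."""

    eigenvalues: np.ndarray
    coordinates: np.ndarray  # (n, m) scaled eigenvectors
    pave: np.ndarray
    ids: list[str]

    @property
    def cumulative_pave(self) -> np.ndarray:
        return np.cumsum(self.pave)

    def to_csv(self, coords_path: str | Path, eig_path: str | Path) -> None:
        m = self.coordinates.shape[1]
        cols = [f"PC{i + 1}" for i in range(m)]
        pd.DataFrame(self.coordinates, index=self.ids, columns=cols).to_csv(
            coords_path, index_label="sample_id")
        pd.DataFrame({"eigenvalue": self.eigenvalues, "pave": self.pave,
                      "cumulative_pave": self.cumulative_pave},
                     index=cols).to_csv(eig_path, index_label="axis")


# ---------------------------------------------------------------------------
# distances and redundancy
# ---------------------------------------------------------------------------

def gower_distance(matrix: MarkerMatrix | pd.DataFrame,
                   treatment: str = "symmetric") -> DistanceMatrix:
    """Gower's distance between samples of a binary marker matrix.

    For the default symmetric-binary treatment this is the
    simple-matching mismatch fraction over the variables jointly
    observed in both samples; ``treatment="asymmetric"`` gives the
    Jaccard form, where joint absences are uninformative.  Raises if a
    sample pair shares no observed variable.
    """
    df = matrix.scores if isinstance(matrix, MarkerMatrix) else matrix
    ids = list(df.columns)
    X = df.to_numpy(dtype=float).T  # samples x variables
    M = (~np.isnan(X)).astype(float)
    A = np.nan_to_num(X) * M        # observed presences
    B = (1.0 - np.nan_to_num(X)) * M  # observed absences
    mismatches = A @ B.T + B @ A.T
    if treatment == "symmetric":
        shared = M @ M.T
    elif treatment == "asymmetric":
        shared = A @ A.T + mismatches  # pairs with at least one presence
    else:
        raise ValueError(f"unknown treatment {treatment!r}")
    off = ~np.eye(len(ids), dtype=bool)
    if np.any(shared[off] == 0):
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValueError(
            f"samples {ids[i]!r} and {ids[j]!r} share no observed variable")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(shared > 0, mismatches / np.maximum(shared, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(values=d, ids=ids, shared=M @ M.T)


def find_redundant(D: DistanceMatrix, epsilon: float) -> RedundancyPartition:
    """Redundancy groups = connected components of the graph joining
    sample pairs at distance <= ``epsilon`` (components of size >= 2).

    The representative of each group is the member with the fewest
    missing entries behind its distances (largest mean jointly observed
    count), ties broken by lexicographically smallest id.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    n = D.n
    close = (D.values <= epsilon) & ~np.eye(n, dtype=bool)
    r, c = np.nonzero(close)
    adj = coo_matrix((np.ones(len(r), dtype=np.int8), (r, c)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    comp: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comp.setdefault(lab, []).append(i)
    obs = (D.shared.sum(axis=1) if D.shared is not None
           else np.zeros(n))
    groups: list[set[str]] = []
    representatives: dict[int, str] = {}
    unique: list[str] = []
    for members in sorted(comp.values(), key=lambda m: m[0]):
        if len(members) == 1:
            unique.append(D.ids[members[0]])
            continue
        gid = len(groups)
        groups.append({D.ids[i] for i in members})
        rep = min(members, key=lambda i: (-obs[i], D.ids[i]))
        representatives[gid] = D.ids[rep]
    return RedundancyPartition(groups=groups, unique_accessions=unique,
                               representatives=representatives, epsilon=epsilon)


def calibrate_epsilon(D: DistanceMatrix,
                      replicate_pairs: list[tuple[str, str]],
                      inflation: float = 2.0,
                      floor: float = 0.0) -> float:
    """Redundancy threshold from technical-replicate distances.

    Technical replicates are genetically identical, so their observed
    distances measure pure technical noise; epsilon is set to the
    largest replicate distance times a safety ``inflation`` (the max of
    a few pairs underestimates the noise tail over all pairs), but never
    below ``floor``.

    A floor matters for clonal germplasm: replicate distances say
    nothing about *somatic* divergence, and after quality filtering
    (which by construction keeps replicate-concordant markers) they can
    be exactly zero while genuine clone mates still differ at a small
    fraction of marker loci.
    """
    idx = {s: i for i, s in enumerate(D.ids)}
    dists = [D.values[idx[a], idx[b]] for a, b in replicate_pairs
             if a in idx and b in idx]
    if not dists:
        raise ValueError("no replicate pairs present in the distance matrix")
    return max(float(max(dists)) * inflation, floor)


def core_collection(partition: RedundancyPartition) -> list[str]:
    """Unique accessions plus one representative per redundancy group,
    sorted; size = n_total - sum(group_size - 1)."""
    core = list(partition.unique_accessions)
    core.extend(partition.representatives[g] for g in range(len(partition.groups)))
    return sorted(core)


# ---------------------------------------------------------------------------
# hierarchical clustering with bootstrap supports
# ---------------------------------------------------------------------------

def hclust_complete(D: DistanceMatrix) -> Dendrogram:
    """Agglomerative complete-linkage clustering.

    Repeatedly merges the closest pair of clusters, where inter-cluster
    distance is the maximum over member pairs.  Ties are broken
    deterministically in favour of the pair whose smallest original leaf
    index is lowest (then the other member's smallest leaf index).
    """
    n = D.n
    if n < 2:
        raise ValueError("need at least two samples to cluster")
    d = D.values.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    node_id = np.arange(n)             # dendrogram node id per live column
    min_leaf = np.arange(n)            # smallest original leaf per cluster
    sizes = np.ones(n, dtype=int)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        m = d.min()
        rs, cs = np.nonzero(d == m)
        # tie-break: lowest smallest-member leaf index first, then the
        # partner cluster's smallest leaf
        best = min(
            ((min(min_leaf[r], min_leaf[c]), max(min_leaf[r], min_leaf[c]), r, c)
             for r, c in zip(rs, cs) if r < c))
        _, _, ca, cb = best
        h = d[ca, cb]
        ia, ib = int(node_id[ca]), int(node_id[cb])
        Z[step] = [min(ia, ib), max(ia, ib), h, sizes[ca] + sizes[cb]]
        merged = np.maximum(d[ca], d[cb])  # complete-linkage update
        d[ca, :] = merged
        d[:, ca] = merged
        d[ca, ca] = np.inf
        d[cb, :] = np.inf
        d[:, cb] = np.inf
        node_id[ca] = n + step
        sizes[ca] += sizes[cb]
        min_leaf[ca] = min(min_leaf[ca], min_leaf[cb])
    return Dendrogram(linkage=Z, leaf_ids=list(D.ids))


def bootstrap_support(matrix: MarkerMatrix | pd.DataFrame, n_boot: int = 1000,
                      seed: int = 0, treatment: str = "symmetric") -> Dendrogram:
    """Complete-linkage dendrogram with plain-bootstrap branch supports.

    Markers (the variables) are resampled with replacement ``n_boot``
    times; the support of an internal edge is the percentage of
    replicate trees containing the same leaf bipartition.  With
    ``n_boot=0`` the tree is returned without supports.
    """
    df = matrix.scores if isinstance(matrix, MarkerMatrix) else matrix
    if df.shape[0] < 2:
        raise ValueError("need at least two markers to bootstrap")
    tree = hclust_complete(gower_distance(df, treatment=treatment))
    if n_boot == 0:
        return tree
    rng = np.random.default_rng(seed)
    n_markers = df.shape[0]
    full = frozenset(range(len(tree.leaf_ids)))

    def canon(side: frozenset[int]) -> frozenset[int]:
        return full - side if 0 in side else side

    target = {node: canon(side) for node, side in tree.node_leafsets().items()}
    hits = dict.fromkeys(target, 0)
    values = df.to_numpy()
    for _ in range(n_boot):
        idx = rng.integers(0, n_markers, size=n_markers)
        boot = pd.DataFrame(values[idx], columns=df.columns)
        btree = hclust_complete(gower_distance(boot, treatment=treatment))
        boot_splits = {canon(s) for s in btree.node_leafsets().values()}
        for node, split in target.items():
            if split in boot_splits:
                hits[node] += 1
    tree.supports = {node: 100.0 * h / n_boot for node, h in hits.items()}
    return tree


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

def pcoa(D: DistanceMatrix, eig_tol: float = 1e-9) -> PCoAResult:
    """Classical multidimensional scaling (Torgerson–Gower scaling).

    Double-centres the squared distances, B = -1/2 J D^2 J, keeps the
    positive eigenvalues and returns coordinates scaled by sqrt(lambda).
    PAVE is each eigenvalue's share of the positive-eigenvalue total.
    """
    n = D.n
    d2 = D.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = eig_tol * max(abs(eigval[0]), 1.0)
    pos = eigval > tol
    if not pos.any():
        raise ValueError("degenerate input: no positive eigenvalues")
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)[None, :]
    pave = lam / lam.sum()
    return PCoAResult(eigenvalues=lam, coordinates=coords, pave=pave,
                      ids=list(D.ids))
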