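"""Population-structure summaries: genotype PCA and a neighbor-joining
cladogram from the weighted F_ST distance matrix.

The PCA mean-imputes missing dosages per SNP, centers columns (optional
unit-variance scaling) and takes the singular-value decomposition; the sign
of each component is fixed so its largest-magnitude SNP loading is positive.
NJ is the classic Saitou-Nei agglomeration on the Q-criterion with a
deterministic tie-break (lexicographically smallest cluster-label pair);
negative branch-length estimates are floored at zero and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    coords: pd.DataFrame           # sample_id, breed, PC1..PCK
    explained_variance: np.ndarray  # fractions, non-increasing, sum <= 1
    dropped_snps: int = 0


def pca_genotypes(g: GenotypeMatrix, K: int = 2, scale: bool = False) -> PcaResult:
    """PCA of the samples x SNPs dosage matrix.

    Missing dosages are replaced by the SNP's mean dosage; SNPs with no
    called genotypes (or zero variance when ``scale``) are dropped with a
    warning.  Explained-variance fractions are relative to the total
    variance of the processed matrix.
    """
    if g.n_samples < 2:
        raise ValueError("PCA needs >=2 samples")
    x = g.values.astype(float)
    x[g.values == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_mean = np.nanmean(x, axis=0, keepdims=True)
    all_missing = np.isnan(col_mean[0])
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} all-missing SNPs before PCA",
            stacklevel=2,
        )
    keep = ~all_missing
    x = x[:, keep]
    col_mean = col_mean[:, keep]
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean[0], inds[1])
    x -= col_mean
    if scale:
        sd = x.std(axis=0, ddof=1)
        nz = sd > 0
        if not nz.all():
            warnings.warn(
                f"dropping {int((~nz).sum())} zero-variance SNPs before "
                "scaled PCA", stacklevel=2,
            )
        x = x[:, nz] / sd[nz]
    K = min(K, min(x.shape))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic orientation: largest-|loading| entry of each PC positive
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u[:, :K] * s[:K]
    total_var = (s ** 2).sum()
    explained = (s[:K] ** 2) / total_var if total_var > 0 else np.zeros(K)
    coords = pd.DataFrame(scores, columns=[f"PC{k + 1}" for k in range(K)])
    coords.insert(0, "breed", g.samples.breed)
    coords.insert(0, "sample_id", g.samples.sample_id)
    return PcaResult(
        coords=coords,
        explained_variance=explained,
        dropped_snps=int(all_missing.sum()),
    )


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    """Node of an (unrooted, stored rooted-at-trifurcation) NJ tree."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class NjTree:
    root: TreeNode
    labels: list[str]
    negative_branches_floored: int = 0
    join_order: list[tuple[str, str]] = field(default_factory=list)

    def leaf_distances(self) -> pd.DataFrame:
        """Patristic (path-length) distances between all leaf pairs."""
        dist: dict[str, list[tuple[TreeNode, float]]] = {}

        def collect(node: TreeNode, depth: float, trail):
            trail = trail + [(node, depth)]
            if node.is_leaf():
                dist[node.name] = trail
                return
            for child, bl in node.children:
                collect(child, depth + bl, trail)

        collect(self.root, 0.0, [])
        labels = sorted(dist)
        out = pd.DataFrame(0.0, index=labels, columns=labels)
        for a in labels:
            for b in labels:
                if a >= b:
                    continue
                nodes_a = {id(n): d for n, d in dist[a]}
                lca_depth = max(d for n, d in dist[b] if id(n) in nodes_a)
                da = dist[a][-1][1]
                db = dist[b][-1][1]
                out.loc[a, b] = out.loc[b, a] = da + db - 2 * lca_depth
        return out


def nj_tree(d, labels: list[str] | None = None, use: str = "weighted") -> NjTree:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    ``d`` may be an FstMatrix (its ``use`` matrix is taken), a DataFrame, or
    an ndarray with ``labels``.  Requires >=3 labels.  Ties in the
    Q-criterion break on the lexicographically smallest cluster-name pair
    (a cluster is named by its smallest leaf label).
    """
    from .fst import FstMatrix

    if isinstance(d, FstMatrix):
        labels = list(d.labels)
        mat = d.weighted if use == "weighted" else d.mean
    elif isinstance(d, pd.DataFrame):
        labels = list(d.index)
        mat = d.to_numpy(dtype=float)
    else:
        mat = np.asarray(d, dtype=float)
        if labels is None:
            raise ValueError("labels required with a bare array")
        labels = list(labels)
    n = len(labels)
    if mat.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    if n < 3:
        raise ValueError("NJ needs >=3 taxa")

    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    names = list(labels)                     # active cluster names
    dm = {a: {b: float(mat[i, j]) for j, b in enumerate(labels)}
          for i, a in enumerate(labels)}
    cluster_key = {lab: lab for lab in labels}  # smallest leaf label per cluster
    floored = 0
    join_order: list[tuple[str, str]] = []

    while len(names) > 3:
        r = len(names)
        sums = {a: sum(dm[a][b] for b in names if b != a) for a in names}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = names[i], names[j]
                q = (r - 2) * dm[a][b] - sums[a] - sums[b]
                key = tuple(sorted((cluster_key[a], cluster_key[b])))
                cand = (q, key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        join_order.append(tuple(sorted((cluster_key[a], cluster_key[b]))))
        la = 0.5 * dm[a][b] + (sums[a] - sums[b]) / (2.0 * (r - 2))
        lb = dm[a][b] - la
        if la < 0:
            floored += 1
            la = 0.0
        if lb < 0:
            floored += 1
            lb = 0.0
        new_name = f"({a},{b})"
        new_node = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        new_d = {}
        for c in names:
            if c in (a, b):
                continue
            new_d[c] = 0.5 * (dm[a][c] + dm[b][c] - dm[a][b])
        for c, v in new_d.items():
            dm[c][new_name] = v
        dm[new_name] = new_d
        nodes[new_name] = new_node
        cluster_key[new_name] = min(cluster_key[a], cluster_key[b])
        names = [c for c in names if c not in (a, b)] + [new_name]

    a, b, c = names
    # three-point formulas for the final star
    la = 0.5 * (dm[a][b] + dm[a][c] - dm[b][c])
    lb = 0.5 * (dm[a][b] + dm[b][c] - dm[a][c])
    lc = 0.5 * (dm[a][c] + dm[b][c] - dm[a][b])
    lens = []
    for v in (la, lb, lc):
        if v < 0:
            floored += 1
            v = 0.0
        lens.append(v)
    root = TreeNode(children=[(nodes[a], lens[0]), (nodes[b], lens[1]),
                              (nodes[c], lens[2])])
    return NjTree(root=root, labels=list(labels),
                  negative_branches_floored=floored, join_order=join_order)


def to_newick(t: NjTree, precision: int = 6) -> str:
    def render(node: TreeNode) -> str:
        if node.is_leaf():
            return node.name
        inner = ",".join(
            f"{render(child)}:{bl:.{precision}f}" for child, bl in node.children
        )
        return f"({inner})"

    return render(t.root) + ";"


def write_newick(t: NjTree, path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(t, precision=precision) + "\n")
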