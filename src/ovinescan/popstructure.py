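"""Individual-level population structure: allele-sharing distances,
neighbor-joining trees and classical multidimensional scaling.

The allele-sharing distance between individuals i and j is the average,
over markers where both are called, of ``1 - shared/2`` where shared is
the number of alleles identical by state (0, 1 or 2).  For fully called
data this equals the identity-by-state distance matrix; both feed NJ
and MDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plinkio import MISSING, GenotypeDataset

logger = logging.getLogger("ovinescan")


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------

def asd_matrix(dataset: GenotypeDataset, markers: np.ndarray | None = None) -> pd.DataFrame:
    """Allele-sharing distance matrix over (a subset of) markers.

    Missing data use pairwise deletion: each pair of individuals is
    compared over the markers where both have calls.  Raises if a pair
    shares no called marker.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least two samples")
    g = dataset.genotypes if markers is None else dataset.genotypes[:, markers]
    ids = dataset.samples["sample_id"].tolist()
    n = g.shape[0]
    gf = g.astype(np.float64)
    called = g != MISSING
    d = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1:]
        n_co = both.sum(axis=1)
        if (n_co == 0).any():
            bad = ids[i + 1 + int(np.argmax(n_co == 0))]
            raise ValueError(f"samples {ids[i]!r} and {bad!r} share no called marker")
        diff = np.abs(gf[i] - gf[i + 1:])
        diff[~both] = 0.0
        row = diff.sum(axis=1) / (2.0 * n_co)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return pd.DataFrame(d, index=ids, columns=ids)


def ibs_distance_matrix(dataset: GenotypeDataset, markers: np.ndarray | None = None) -> pd.DataFrame:
    """Identity-by-state distance (1 - mean shared/2); equals ASD."""
    return asd_matrix(dataset, markers)


# ----------------------------------------------------------------------
# neighbor-joining
# ----------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an unrooted NJ tree (stored rooted at the final join)."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(
            f"{child._newick()}:{length:.10g}" for child, length in self.children
        )
        return f"({inner})"

    def leaf_distances(self) -> pd.DataFrame:
        """Patristic (path-length) distances between all leaf pairs."""
        rows: list[tuple[str, str, float]] = []

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            merged: dict[str, float] = {}
            for child, length in node.children:
                below = {k: v + length for k, v in walk(child).items()}
                for k1, v1 in merged.items():
                    for k2, v2 in below.items():
                        rows.append((k1, k2, v1 + v2))
                merged.update(below)
            return merged

        walk(self)
        names = self.leaf_names()
        out = pd.DataFrame(0.0, index=names, columns=names)
        for a, b, v in rows:
            out.loc[a, b] = out.loc[b, a] = v
        return out


def neighbor_joining(distance: pd.DataFrame, clamp_negative: bool = True) -> TreeNode:
    """Saitou-Nei neighbor joining with the Studier-Keppler criterion.

    On an additive distance matrix the generating tree is recovered
    exactly.  Ties in the Q criterion join the lexicographically lowest
    index pair.  Negative branch lengths are clamped to zero with the
    deficit moved to the sibling edge (flagged in the log).
    """
    d = np.asarray(distance, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least three taxa")
    nodes: list[TreeNode] = [TreeNode(name=str(nm)) for nm in distance.index]
    d = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin of flattened array scans row-major
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if clamp_negative and (li < 0 or lj < 0):
            logger.info("neighbor_joining: clamping negative branch length")
            if li < 0:
                lj, li = lj + li, 0.0
            elif lj < 0:
                li, lj = li + lj, 0.0
        new = TreeNode(children=[(nodes[active[i]], float(li)),
                                 (nodes[active[j]], float(lj))])
        # distances from the new node to the remaining taxa
        ai, aj = active[i], active[j]
        new_idx = len(nodes)
        nodes.append(new)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (ai, aj):
                continue
            dk = 0.5 * (d[ai, k] + d[aj, k] - dij)
            d[new_idx, k] = d[k, new_idx] = dk
        active = [k for k in active if k not in (ai, aj)] + [new_idx]

    # resolve the last three nodes around a central vertex
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lengths = [la, lb, lc]
    if clamp_negative:
        for t in range(3):
            if lengths[t] < 0:
                logger.info("neighbor_joining: clamping negative terminal length")
                deficit = lengths[t]
                lengths[t] = 0.0
                # move deficit to the other two edges equally
                for u in range(3):
                    if u != t:
                        lengths[u] += deficit / 2
    return TreeNode(children=[(nodes[a], float(lengths[0])),
                              (nodes[b], float(lengths[1])),
                              (nodes[c], float(lengths[2]))])


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ----------------------------------------------------------------------
# classical MDS
# ----------------------------------------------------------------------

def mds_classical(distance: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers -D^2/2 and eigendecomposes; returns the top-``k``
    coordinates ordered by eigenvalue (negative eigenvalues clipped).
    The sign of each axis is fixed so its largest-magnitude loading is
    positive, making the output deterministic.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals_k)[None, :]
    for axis in range(k):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return pd.DataFrame(
        coords,
        index=distance.index,
        columns=[f"dim{t + 1}" for t in range(k)],
    )
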