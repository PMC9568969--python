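"""Hierarchical clustering of methylomes with bootstrap branch support.

Samples are clustered on correlation distance ``d(a, b) = 1 - Pearson
r(beta_a, beta_b)`` with average linkage (UPGMA) — the defaults of the
standard methylome-clustering stack. The agglomeration is implemented here
with an explicit deterministic tie-break (the lexicographically smallest
eligible cluster pair merges first), so the merge sequence is reproducible
bit-for-bit.

Branch support is the plain bootstrap probability: probes are resampled with
replacement B times, the tree recomputed per replicate, and each internal
node's support is the fraction of replicates containing the same leaf
bipartition. (Multiscale-bootstrap AU p-values are a separate algorithm and
are deliberately not implemented.)

"Outlier branches" operationalizes a sample visually sticking out of a
dendrogram: the samples whose singleton join heights (the height at which a
still-unmerged leaf finally joins any cluster) are the k largest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import BetaMatrix, DataValidationError

logger = logging.getLogger("methylomp")

LINKAGES = ("average", "complete", "single")


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------


def methylome_distance(m: BetaMatrix, metric: str = "correlation") -> pd.DataFrame:
    """Sample-by-sample distance matrix, 1 - Pearson r over shared probes.

    Pairwise complete-case: probes missing in either sample of a pair are
    dropped for that pair. ``metric='euclidean'`` is available as an
    alternative. A constant sample vector makes correlation undefined and is
    an error.
    """
    if m.n_samples < 2 or m.n_probes < 2:
        raise DataValidationError("need >= 2 samples and >= 2 probes for distances")
    vals = m.values
    ids = list(m.sample_ids)
    has_nan = np.isnan(vals).any()
    if metric == "correlation":
        if not has_nan:
            sd = vals.std(axis=0)
            if (sd == 0).any():
                bad = ids[int(np.argmax(sd == 0))]
                raise DataValidationError(f"constant methylome for sample {bad!r}")
            d = 1.0 - np.corrcoef(vals.T)
        else:
            n = len(ids)
            d = np.zeros((n, n))
            for a in range(n):
                for b in range(a + 1, n):
                    ok = ~(np.isnan(vals[:, a]) | np.isnan(vals[:, b]))
                    xa, xb = vals[ok, a], vals[ok, b]
                    if len(xa) < 2 or xa.std() == 0 or xb.std() == 0:
                        raise DataValidationError(
                            f"constant or empty overlap between samples "
                            f"{ids[a]!r} and {ids[b]!r}"
                        )
                    d[a, b] = d[b, a] = 1.0 - np.corrcoef(xa, xb)[0, 1]
    elif metric == "euclidean":
        if has_nan:
            raise DataValidationError("euclidean distance requires a complete matrix")
        diff = vals.T[:, None, :] - vals.T[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    else:
        raise DataValidationError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Dendrogram + UPGMA
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over labelled leaves.

    Leaves are node ids ``0..n-1`` (in ``labels`` order); the k-th merge
    creates internal node ``n + k``. ``support`` maps internal node ids to
    bootstrap probabilities in [0, 1].
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]
    support: dict[int, float] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        """Node id -> set of leaf labels under it (leaves included)."""
        n = self.n_leaves
        sets: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        for k, (a, b, _h) in enumerate(self.merges):
            sets[n + k] = sets[a] | sets[b]
        return sets

    def heights(self) -> dict[int, float]:
        h = {i: 0.0 for i in range(self.n_leaves)}
        for k, (_a, _b, hk) in enumerate(self.merges):
            h[self.n_leaves + k] = hk
        return h

    def bipartitions(self) -> dict[int, frozenset[str]]:
        """Internal node id -> canonical leaf bipartition.

        Canonical form: the smaller side of the split (ties broken by sorted
        label order), so a cluster and its complement compare equal.
        """
        all_leaves = frozenset(self.labels)
        out = {}
        for node, leaves in self.leaf_sets().items():
            if node < self.n_leaves:
                continue
            comp = all_leaves - leaves
            if len(leaves) < len(comp) or (
                len(leaves) == len(comp) and sorted(leaves) <= sorted(comp)
            ):
                out[node] = leaves
            else:
                out[node] = comp
        return out

    def singleton_join_heights(self) -> dict[str, float]:
        """Label -> height of the merge in which that leaf stops being a singleton."""
        out: dict[str, float] = {}
        n = self.n_leaves
        for a, b, h in self.merges:
            for node in (a, b):
                if node < n:
                    out[self.labels[node]] = h
        return out

    def is_clade(self, labels: set[str]) -> bool:
        """True if some node's leaf set equals ``labels`` exactly."""
        want = frozenset(labels)
        return any(s == want for s in self.leaf_sets().values())

    def to_newick(self, with_support: bool = True, digits: int = 6) -> str:
        """Newick string; branch lengths are height differences, internal
        node labels carry bootstrap support when available."""
        heights = self.heights()
        n = self.n_leaves

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < n:
                return f"{self.labels[node]}:{bl:.{digits}f}"
            a, b, h = self.merges[node - n]
            inner = f"({render(a, h)},{render(b, h)})"
            lab = ""
            if with_support and node in self.support:
                lab = f"{self.support[node]:.3f}"
            return f"{inner}{lab}:{bl:.{digits}f}"

        if not self.merges:
            return f"({','.join(self.labels)});"
        root = n + len(self.merges) - 1
        a, b, h = self.merges[-1]
        lab = f"{self.support[root]:.3f}" if with_support and root in self.support else ""
        return f"({render(a, h)},{render(b, h)}){lab};"


def hclust_average(d: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Average linkage (UPGMA) by default; ``complete`` and ``single`` are
    available. Ties are broken by merging the pair of clusters with the
    lexicographically smallest (older, younger) node ids, making the merge
    sequence fully deterministic.
    """
    if linkage not in LINKAGES:
        raise DataValidationError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    labels = list(d.index)
    n = len(labels)
    dist = {
        (i, j): float(d.iloc[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                key = (i, j) if i < j else (j, i)
                dij = dist[key]
                cand = (dij, key)
                if best is None or cand < best:
                    best = cand
        h, (i, j) = best
        merges.append((i, j, h))
        for k in active:
            if k in (i, j):
                continue
            ki = (min(i, k), max(i, k))
            kj = (min(j, k), max(j, k))
            if linkage == "average":
                dk = (size[i] * dist[ki] + size[j] * dist[kj]) / (size[i] + size[j])
            elif linkage == "complete":
                dk = max(dist[ki], dist[kj])
            else:
                dk = min(dist[ki], dist[kj])
            dist[(k, next_id) if k < next_id else (next_id, k)] = dk
        size[next_id] = size[i] + size[j]
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return Dendrogram(labels=labels, merges=merges)


def bootstrap_support(
    m: BetaMatrix,
    B: int = 100,
    seed: int = 0,
    metric: str = "correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Tree on the full data plus bootstrap bipartition probabilities.

    Probes are resampled with replacement B times; each original internal
    node's support is the fraction of replicate trees containing the same
    leaf bipartition. Seeded and reproducible.
    """
    if B < 1:
        raise DataValidationError("B must be >= 1")
    base = hclust_average(methylome_distance(m, metric), linkage)
    targets = base.bipartitions()
    hits = {node: 0 for node in targets}
    rng = np.random.default_rng(seed)
    vals = m.values
    P = m.n_probes
    for _ in range(B):
        idx = rng.integers(0, P, size=P)
        rep = BetaMatrix.from_arrays(
            [f"p{i}" for i in range(P)], list(m.sample_ids), vals[idx]
        )
        rep_tree = hclust_average(methylome_distance(rep, metric), linkage)
        rep_biparts = set(rep_tree.bipartitions().values())
        for node, bp in targets.items():
            if bp in rep_biparts:
                hits[node] += 1
    base.support = {node: hits[node] / B for node in targets}
    return base


# ---------------------------------------------------------------------------
# Interpretation
# ---------------------------------------------------------------------------


def outlier_branches(dend: Dendrogram, k: int) -> set[str]:
    """Samples with the k largest singleton-join heights."""
    if k >= dend.n_leaves:
        raise DataValidationError("k must be smaller than the number of leaves")
    if k <= 0:
        return set()
    joins = dend.singleton_join_heights()
    ranked = sorted(joins.items(), key=lambda kv: (-kv[1], kv[0]))
    return {label for label, _h in ranked[:k]}


def family_clade_report(
    dend: Dendrogram, families: Mapping[str, Sequence[str]]
) -> dict[str, bool]:
    """Per family with >= 2 leaves present: do its members form a clade?"""
    leaves = set(dend.labels)
    out = {}
    for fam, members in families.items():
        present = [s for s in members if s in leaves]
        if len(present) >= 2:
            out[fam] = dend.is_clade(set(present))
    return out
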