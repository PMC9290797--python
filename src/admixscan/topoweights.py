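"""Topology weighting over (outgroup, west, east, focal) haplotype groups.

Each window gets a neighbour-joining tree built from pairwise Hamming
distances between phased haplotypes.  Weights for the three possible rooted
quartet topologies are estimated by sampling one haplotype per group
(exhaustive enumeration when the group-size product is small enough), and a
window's ancestry score is the weight supporting the focal-west sister
grouping minus the weight supporting focal-east.

Topology ids: 1 = {O,E} | {W,I} (west ancestry of the focal group),
2 = {O,W} | {E,I} (east ancestry), 3 = {O,I} | {W,E} (diverged).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, HaplotypeMatrix, PopulationMap, WindowSpec

ROLES = ("outgroup", "west", "east", "focal")

_TOL = 1e-12


class PhasingError(ValueError):
    """Raised when unphased heterozygotes reach a haplotype-based analysis."""


@dataclass
class GroupAssignment:
    """Role -> haplotype-id list for the four quartet roles."""

    outgroup: list[str]
    west: list[str]
    east: list[str]
    focal: list[str]

    def __post_init__(self) -> None:
        groups = [self.outgroup, self.west, self.east, self.focal]
        for role, g in zip(ROLES, groups):
            if not g:
                raise ValueError(f"group {role!r} is empty")
        flat = [h for g in groups for h in g]
        if len(set(flat)) != len(flat):
            raise ValueError("groups must be disjoint")

    @classmethod
    def from_popmap(
        cls,
        popmap: PopulationMap,
        hm: HaplotypeMatrix,
        outgroup: str | Sequence[str],
        west: str | Sequence[str],
        east: str | Sequence[str],
        focal: str | Sequence[str],
    ) -> "GroupAssignment":
        """Build groups from population labels, expanding to haplotype ids."""

        def haps(pops) -> list[str]:
            if isinstance(pops, str):
                pops = [pops]
            out = []
            for pop in pops:
                for s in popmap.samples(pop):
                    if s in hm.samples:
                        out.extend([f"{s}__1", f"{s}__2"])
            return out

        return cls(haps(outgroup), haps(west), haps(east), haps(focal))

    @property
    def all_haplotypes(self) -> list[str]:
        return self.outgroup + self.west + self.east + self.focal


@dataclass
class TopologyWeights:
    """Per-window topology support and derived quantities."""

    w1: float
    w2: float
    w3: float
    unresolved_frac: float
    n_subtrees: int
    exhaustive: bool

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------


def window_distance_matrix(
    hm: HaplotypeMatrix,
    window: WindowSpec,
    haplotype_rows: Sequence[int],
) -> np.ndarray:
    """Pairwise Hamming distance (proportion of differing sites) in a window.

    Entry (i, j) is computed over sites non-missing in both haplotypes; a
    pair with zero comparable sites raises, naming the pair.
    """
    if len(haplotype_rows) < 4:
        raise ValueError("need at least 4 haplotypes")
    sl = hm.site_slice(window.start, window.end)
    block = hm.alleles[list(haplotype_rows), sl]
    if block.shape[1] == 0:
        raise ValueError("window contains no SNPs")
    called = block != MISSING
    comparable = (called.astype(np.int64) @ called.T.astype(np.int64))
    eq = np.zeros_like(comparable)
    for a in (0, 1):
        isa = ((block == a) & called).astype(np.int64)
        eq += isa @ isa.T
    if np.any(comparable == 0):
        i, j = np.argwhere(comparable == 0)[0]
        ids = hm.haplotype_ids
        raise ValueError(
            "no comparable sites for haplotype pair "
            f"({ids[haplotype_rows[i]]}, {ids[haplotype_rows[j]]})"
        )
    dist = (comparable - eq) / comparable
    np.fill_diagonal(dist, 0.0)
    return dist


@dataclass
class Tree:
    """Unrooted tree with branch lengths.

    Nodes ``0 .. n_leaves-1`` are leaves, in the order of ``leaf_names``;
    internal nodes follow.  ``edges`` is a list of ``(u, v, length)``.
    """

    n_leaves: int
    leaf_names: list[str]
    edges: list[tuple[int, int, float]]
    _leaf_dist: np.ndarray | None = field(default=None, repr=False, compare=False)

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for u, v, l in self.edges:
            adj.setdefault(u, []).append((v, l))
            adj.setdefault(v, []).append((u, l))
        return adj

    def leaf_distance_matrix(self) -> np.ndarray:
        """Path-length distances between all leaf pairs (cached)."""
        if self._leaf_dist is not None:
            return self._leaf_dist
        adj = self.adjacency()
        n_nodes = max(max(u, v) for u, v, _ in self.edges) + 1
        D = np.zeros((self.n_leaves, self.n_leaves))
        for src in range(self.n_leaves):
            dist = np.full(n_nodes, np.nan)
            dist[src] = 0.0
            stack = [src]
            while stack:
                u = stack.pop()
                for v, l in adj[u]:
                    if np.isnan(dist[v]):
                        dist[v] = dist[u] + l
                        stack.append(v)
            D[src] = dist[: self.n_leaves]
        self._leaf_dist = D
        return D

    def to_newick(self) -> str:
        adj = self.adjacency()
        root = max(adj)  # last internal node

        def sub(u: int, parent: int | None) -> str:
            children = [(v, l) for v, l in adj[u] if v != parent]
            if not children and u < self.n_leaves:
                return self.leaf_names[u]
            parts = [f"{sub(v, u)}:{l:.10g}" for v, l in children]
            return "(" + ",".join(parts) + ")"

        return sub(root, None) + ";"


def nj_tree(dist: np.ndarray, names: Sequence[str] | None = None) -> Tree:
    """Neighbour-joining tree from a symmetric distance matrix.

    Ties in the Q criterion are broken by the lowest (row, column) index;
    negative branch lengths are floored at 0, so the output is deterministic
    for a given input.  Requires at least 4 taxa.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 4:
        raise ValueError("neighbour joining here requires >= 4 taxa")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    if names is None:
        names = [f"t{i}" for i in range(n)]
    names = list(names)
    if len(names) != n:
        raise ValueError("names length mismatch")

    cur = D.copy()
    active = list(range(n))
    next_id = n
    edges: list[tuple[int, int, float]] = []
    while len(active) > 3:
        m = len(active)
        r = cur.sum(axis=1)
        Q = (m - 2) * cur - r[:, None] - r[None, :]
        Q[np.tril_indices(m)] = np.inf  # keep i < j; argmin is row-major
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        d_ij = cur[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        edges.append((active[i], next_id, max(li, 0.0)))
        edges.append((active[j], next_id, max(lj, 0.0)))
        dnew = 0.5 * (cur[i, :] + cur[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        new = np.empty((m - 1, m - 1))
        new[:-1, :-1] = cur[np.ix_(keep, keep)]
        new[-1, :-1] = dnew[keep]
        new[:-1, -1] = dnew[keep]
        new[-1, -1] = 0.0
        cur = new
        active = [active[k] for k in keep] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (cur[0, 1] + cur[0, 2] - cur[1, 2])
    lb = 0.5 * (cur[0, 1] + cur[1, 2] - cur[0, 2])
    lc = 0.5 * (cur[0, 2] + cur[1, 2] - cur[0, 1])
    center = next_id
    edges.append((a, center, max(la, 0.0)))
    edges.append((b, center, max(lb, 0.0)))
    edges.append((c, center, max(lc, 0.0)))
    return Tree(n_leaves=n, leaf_names=names, edges=edges)


# ---------------------------------------------------------------------------
# Quartets
# ---------------------------------------------------------------------------


def _quartet_from_sums(s1, s2, s3, tol=_TOL):
    s = np.stack([np.asarray(s1), np.asarray(s2), np.asarray(s3)])
    order = np.sort(s, axis=0)
    unresolved = (order[1] - order[0]) <= tol
    topo = np.argmin(s, axis=0) + 1
    return np.where(unresolved, 0, topo)


def quartet_topology(tree: Tree, o: str, w: str, e: str, i: str) -> int:
    """Topology id of the quartet induced by four leaves (0 = unresolved).

    Equivalent to pruning the tree to the four leaves and reading the
    internal-edge bipartition: the pair-sum of path distances matching the
    split is smaller than the other two by twice the internal edge length
    (four-point condition); all three sums equal means a zero-length internal
    edge, i.e. unresolved.
    """
    idx = {name: k for k, name in enumerate(tree.leaf_names)}
    try:
        io, iw, ie, ii = idx[o], idx[w], idx[e], idx[i]
    except KeyError as exc:
        raise KeyError(f"leaf {exc.args[0]!r} not in tree") from None
    D = tree.leaf_distance_matrix()
    s1 = D[io, ie] + D[iw, ii]
    s2 = D[io, iw] + D[ie, ii]
    s3 = D[io, ii] + D[iw, ie]
    return int(_quartet_from_sums(s1, s2, s3))


def topology_weights(
    tree: Tree,
    groups: GroupAssignment,
    n_subtrees: int = 600,
    seed: int | np.random.Generator | None = None,
) -> TopologyWeights:
    """Topology weights by sampling one leaf per group.

    If the number of one-per-group combinations is at most *n_subtrees* all
    combinations are enumerated (the result is then independent of the
    seed); otherwise *n_subtrees* quartets are drawn uniformly with
    replacement.  Weights are proportions among resolved quartets; the
    unresolved fraction is reported separately.
    """
    if n_subtrees < 1:
        raise ValueError("n_subtrees must be >= 1")
    idx = {name: k for k, name in enumerate(tree.leaf_names)}
    try:
        go = np.array([idx[h] for h in groups.outgroup])
        gw = np.array([idx[h] for h in groups.west])
        ge = np.array([idx[h] for h in groups.east])
        gi = np.array([idx[h] for h in groups.focal])
    except KeyError as exc:
        raise KeyError(f"haplotype {exc.args[0]!r} not in tree") from None
    D = tree.leaf_distance_matrix()
    total = go.size * gw.size * ge.size * gi.size
    if total <= n_subtrees:
        O, W, E, I = (
            g.ravel() for g in np.meshgrid(go, gw, ge, gi, indexing="ij")
        )
        exhaustive = True
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        O = rng.choice(go, size=n_subtrees, replace=True)
        W = rng.choice(gw, size=n_subtrees, replace=True)
        E = rng.choice(ge, size=n_subtrees, replace=True)
        I = rng.choice(gi, size=n_subtrees, replace=True)
        exhaustive = False
    s1 = D[O, E] + D[W, I]
    s2 = D[O, W] + D[E, I]
    s3 = D[O, I] + D[W, E]
    topo = _quartet_from_sums(s1, s2, s3)
    n_eval = topo.size
    counts = np.bincount(topo[topo > 0] - 1, minlength=3)
    resolved = int(counts.sum())
    if resolved == 0:
        w1 = w2 = w3 = float("nan")
    else:
        w1, w2, w3 = (counts / resolved).tolist()
    return TopologyWeights(
        w1=w1,
        w2=w2,
        w3=w3,
        unresolved_frac=float((n_eval - resolved) / n_eval),
        n_subtrees=int(n_eval),
        exhaustive=exhaustive,
    )


def classify_window(weights: TopologyWeights, threshold: float = 0.5) -> str:
    """Classify a window: ``topo{k}`` iff w_k > threshold (strict), else ambiguous."""
    for k, w in enumerate(weights.weights, start=1):
        if not np.isnan(w) and w > threshold:
            return f"topo{k}"
    return "ambiguous"


def ancestry_score(weights: TopologyWeights) -> float:
    """w1 - w2: positive = west-leaning ancestry of the focal group."""
    return weights.w1 - weights.w2


def ancestry_correlation(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    method: str = "spearman",
) -> tuple[float, float]:
    """Rank correlation of two per-window ancestry-score vectors.

    Windows where either score is undefined (NaN) are dropped; fewer than
    three remaining pairs is an error.  Returns (rho, p).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired windows with defined scores")
    if method == "spearman":
        rho, p = stats.spearmanr(a[ok], b[ok])
    elif method == "pearson":
        rho, p = stats.pearsonr(a[ok], b[ok])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Per-window driver
# ---------------------------------------------------------------------------


def windows_topology_weights(
    hm: HaplotypeMatrix,
    windows: Sequence[WindowSpec],
    groups: GroupAssignment,
    n_subtrees: int = 600,
    seed: int | None = None,
    newick_out: list[str] | None = None,
) -> pd.DataFrame:
    """Topology weights, classification and ancestry score for many windows.

    Requires fully phased input (read the VCF with random phasing to force
    this).  Windows without SNPs yield NaN weights and class ``ambiguous``.
    """
    if hm.has_unphased_hets:
        raise PhasingError(
            "matrix contains unphased heterozygotes; topology weighting "
            "requires phased haplotypes (use random_phase_seed on read)"
        )
    hap_ids = hm.haplotype_ids
    row_of = {h: k for k, h in enumerate(hap_ids)}
    rows = [row_of[h] for h in groups.all_haplotypes]
    names = list(groups.all_haplotypes)
    rng = np.random.default_rng(seed)
    records = []
    for win in windows:
        rec = {
            "scaffold": win.scaffold,
            "start": win.start,
            "end": win.end,
            "n_subtrees": 0,
            "topo1": np.nan,
            "topo2": np.nan,
            "topo3": np.nan,
            "unresolved": np.nan,
            "class": "ambiguous",
            "score": np.nan,
        }
        sl = hm.site_slice(win.start, win.end)
        if sl.stop > sl.start:
            dist = window_distance_matrix(hm, win, rows)
            tree = nj_tree(dist, names)
            tw = topology_weights(tree, groups, n_subtrees=n_subtrees, seed=rng)
            rec.update(
                n_subtrees=tw.n_subtrees,
                topo1=tw.w1,
                topo2=tw.w2,
                topo3=tw.w3,
                unresolved=tw.unresolved_frac,
            )
            rec["class"] = classify_window(tw)
            if not np.isnan(tw.w1):
                rec["score"] = ancestry_score(tw)
            if newick_out is not None:
                newick_out.append(tree.to_newick())
        records.append(rec)
    return pd.DataFrame.from_records(records)
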