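"""Function-repertoire analysis.

Proteins from all strains are clustered into orthogroups with a Markov
clustering (MCL) of the all-vs-all protein similarity graph (edge weight
-log10 e-value capped at 300, normalized per strain pair by the mean
weight of that pair's edges, OrthoMCL-style).  Each orthogroup becomes a
binary "function" column: present (1) in a strain iff the strain has at
least one member.  Proteins that end up ungrouped are assigned a
best-hit function against an optional annotated database, else a
singleton function; the two namespaces are kept apart via provenance
tags and are never merged.

Repertoires are compared by Manhattan distance (equal to Hamming count on
binary profiles) and average-linkage (UPGMA) clustering, with bootstrap
probabilities from column resampling.  Phylogenomic and functional trees
are compared through cophenetic correlation, Baker's gamma, tanglegram
entanglement, and a nearest-neighbour discordance detector that flags
ecotype-like strains whose placement differs between the two trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

from .coregenome import search_all
from .mlsa import PhyloTree

__all__ = [
    "Orthogroups",
    "Dendrogram",
    "DendroComparison",
    "assign_orthogroups",
    "build_function_matrix",
    "function_set_counts",
    "cluster_repertoire",
    "compare_dendrograms",
]


# ---------------------------------------------------------------------------
# orthogroup assignment (MCL)


@dataclass
class Orthogroups:
    groups: list[list[tuple[str, str]]]  # each: [(strain, gene_id), ...]
    ungrouped: list[tuple[str, str]]
    representatives: dict[int, dict[str, str]] = field(default_factory=dict)


def _mcl(matrix: np.ndarray, inflation: float, tol: float, max_iter: int) -> np.ndarray:
    M = matrix.astype(float)
    np.fill_diagonal(M, M.diagonal() + 1.0)  # self-loops stabilise convergence
    colsum = M.sum(axis=0)
    colsum[colsum == 0] = 1.0
    M = M / colsum
    for _ in range(max_iter):
        expanded = M @ M
        inflated = np.power(expanded, inflation)
        colsum = inflated.sum(axis=0)
        colsum[colsum == 0] = 1.0
        inflated = inflated / colsum
        change = np.abs(inflated - M).max()
        M = inflated
        if change < tol:
            break
    return M


def assign_orthogroups(
    proteomes: dict[str, list[tuple[str, str]]],
    e_cutoff: float = 1e-5,
    inflation: float = 1.5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> Orthogroups:
    """MCL orthogroups over the all-vs-all protein similarity graph."""
    if len(proteomes) < 2:
        raise ValueError("need >= 2 proteomes")
    strains = sorted(proteomes)
    nodes: list[tuple[str, str]] = []
    seqs: list[str] = []
    for sid in strains:
        for gid, prot in proteomes[sid]:
            nodes.append((sid, gid))
            seqs.append(prot)
    index = {n: i for i, n in enumerate(nodes)}
    N = len(nodes)

    # all-vs-all similarity (query strain x subject strain, both directions)
    W = np.zeros((N, N))
    evalues: dict[tuple[int, int], float] = {}
    for qa in strains:
        queries = [(f"{qa}\t{gid}", prot) for gid, prot in proteomes[qa]]
        for sb in strains:
            db = [(f"{sb}\t{gid}", prot) for gid, prot in proteomes[sb]]
            for h in search_all(queries, db, e_cutoff):
                qs, qg = h.query_id.split("\t")
                ss_, sg = h.subject_id.split("\t")
                i, j = index[(qs, qg)], index[(ss_, sg)]
                if i == j:
                    continue
                w = min(300.0, -np.log10(max(h.e_value, 1e-300)))
                if w > W[i, j]:
                    W[i, j] = w
                    evalues[(i, j)] = h.e_value
    W = np.maximum(W, W.T)  # symmetric graph

    # OrthoMCL-style per-strain-pair normalization by the pair's mean weight
    strain_of = np.array([strains.index(s) for s, _ in nodes])
    for a in range(len(strains)):
        for b in range(a, len(strains)):
            mask = np.zeros((N, N), dtype=bool)
            sel_a, sel_b = strain_of == a, strain_of == b
            mask[np.ix_(sel_a, sel_b)] = True
            mask[np.ix_(sel_b, sel_a)] = True
            vals = W[mask]
            nz = vals[vals > 0]
            if nz.size:
                W[mask] = W[mask] / nz.mean()

    if not W.any():
        groups = []
        ungrouped = list(nodes)
        return Orthogroups(groups=groups, ungrouped=ungrouped)

    M = _mcl(W, inflation, tol, max_iter)
    # clusters = connected components of the converged flow (thresholded)
    adj = (M + M.T) > 1e-8
    np.fill_diagonal(adj, False)
    seen = np.zeros(N, dtype=bool)
    clusters: list[list[int]] = []
    for start in range(N):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        clusters.append(sorted(comp))

    groups: list[list[tuple[str, str]]] = []
    ungrouped: list[tuple[str, str]] = []
    reps: dict[int, dict[str, str]] = {}
    for comp in sorted(clusters, key=lambda c: c[0]):
        members = [nodes[i] for i in comp]
        if len(comp) == 1:
            ungrouped.append(members[0])
            continue
        gidx = len(groups)
        groups.append(members)
        # paralog rule: keep the member with the lowest e-value to the group
        rep: dict[str, str] = {}
        for sid in {s for s, _ in members}:
            cand = [i for i in comp if nodes[i][0] == sid]
            if len(cand) == 1:
                rep[sid] = nodes[cand[0]][1]
            else:
                def best_e(i: int) -> float:
                    es = [
                        evalues.get((i, j), evalues.get((j, i), 1.0))
                        for j in comp
                        if j != i
                    ]
                    return min(es) if es else 1.0

                chosen = min(cand, key=lambda i: (best_e(i), nodes[i][1]))
                rep[sid] = nodes[chosen][1]
        reps[gidx] = rep
    return Orthogroups(groups=groups, ungrouped=ungrouped, representatives=reps)


def build_function_matrix(
    groups: Orthogroups,
    strains: list[str],
    fallback_db: list[tuple[str, str]] | None = None,
    proteins: dict[tuple[str, str], str] | None = None,
    fallback_e_cutoff: float = 1e-5,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Binary strains x functions matrix + provenance per function column.

    One column per orthogroup; ungrouped proteins get a best-hit function
    against ``fallback_db`` (keyed by the db protein id) when provided and
    a hit exists, else a private singleton column.  Output never contains
    an all-zero column.
    """
    data: dict[str, dict[str, int]] = {}
    provenance: dict[str, str] = {}
    for gi, members in enumerate(groups.groups):
        col = f"OG{gi:04d}"
        provenance[col] = "orthogroup"
        data[col] = {s: 0 for s in strains}
        for sid, _ in members:
            data[col][sid] = 1

    fallback_hits: dict[tuple[str, str], str] = {}
    if fallback_db and groups.ungrouped:
        if proteins is None:
            raise ValueError("fallback_db given but no protein sequences supplied")
        queries = [
            (f"{s}\t{g}", proteins[(s, g)]) for s, g in groups.ungrouped
        ]
        best: dict[str, str] = {}
        for h in search_all(queries, fallback_db, fallback_e_cutoff):
            best.setdefault(h.query_id, h.subject_id)
        for q, subj in best.items():
            s, g = q.split("\t")
            fallback_hits[(s, g)] = subj

    for s, g in groups.ungrouped:
        hit = fallback_hits.get((s, g))
        if hit is not None:
            col = f"FB:{hit}"
            provenance[col] = "best_hit_fallback"
            data.setdefault(col, {x: 0 for x in strains})[s] = 1
        else:
            col = f"SG:{s}:{g}"
            provenance[col] = "singleton"
            data.setdefault(col, {x: 0 for x in strains})[s] = 1

    m = pd.DataFrame(
        {c: [v[s] for s in strains] for c, v in data.items()},
        index=strains,
        dtype=np.int8,
    )
    nz = m.columns[(m.sum(axis=0) > 0).values]
    m = m[nz]
    provenance = {c: provenance[c] for c in m.columns}
    return m, provenance


def function_set_counts(
    m: pd.DataFrame, subsets: dict[str, list[str]]
) -> dict[str, dict[str, int]]:
    """Core/private function counts per named strain subset, plus pan size."""
    out: dict[str, dict[str, int]] = {}
    all_strains = list(m.index)
    for name, members in subsets.items():
        if not members:
            raise ValueError(f"subset {name!r} is empty")
        missing = [s for s in members if s not in m.index]
        if missing:
            raise ValueError(f"subset {name!r} has unknown strains {missing}")
        sub = m.loc[members]
        outside = [s for s in all_strains if s not in members]
        core = int((sub.sum(axis=0) == len(members)).sum())
        if outside:
            private = int(
                ((sub.sum(axis=0) > 0) & (m.loc[outside].sum(axis=0) == 0)).sum()
            )
        else:
            private = int((sub.sum(axis=0) > 0).sum())
        out[name] = {"core": core, "private": private, "pan": int((sub.sum(axis=0) > 0).sum())}
    out["__all__"] = {
        "core": int((m.sum(axis=0) == len(all_strains)).sum()),
        "private": 0,
        "pan": int((m.sum(axis=0) > 0).sum()),
    }
    return out


# ---------------------------------------------------------------------------
# repertoire clustering


@dataclass
class Dendrogram:
    ids: list[str]
    linkage_matrix: np.ndarray
    bootstrap: dict[frozenset, float] = field(default_factory=dict)

    def cophenetic(self):
        from .mlsa import DistanceMatrix

        d = squareform(hierarchy.cophenet(self.linkage_matrix))
        return DistanceMatrix(ids=self.ids, data=d, model="cophenetic")

    def clusters(self) -> set[frozenset]:
        return _linkage_clusters(self.ids, self.linkage_matrix)

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.ids[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            bp = self.bootstrap.get(
                frozenset(self.ids[i] for i in node.pre_order())
            )
            label = f"{bp:.0f}" if bp is not None else ""
            return f"({left},{right}){label}"

        return rec(tree) + ";"


def _linkage_clusters(ids: list[str], Z: np.ndarray) -> set[frozenset]:
    n = len(ids)
    members: dict[int, frozenset] = {i: frozenset([ids[i]]) for i in range(n)}
    out: set[frozenset] = set()
    for step, (a, b, _, _) in enumerate(Z[:, :4]):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        if len(merged) < n:
            out.add(merged)
    return out


def cluster_repertoire(
    m: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of Manhattan repertoire distances
    with column-resampling bootstrap probabilities per internal cluster."""
    if len(m.index) < 3:
        raise ValueError("need >= 3 strains")
    ids = list(m.index)
    X = m.values.astype(float)
    Z = hierarchy.linkage(pdist(X, metric="cityblock"), method="average")
    counts = {c: 0 for c in _linkage_clusters(ids, Z)}
    rng = np.random.default_rng(seed)
    L = X.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        Zb = hierarchy.linkage(pdist(X[:, cols], metric="cityblock"), method="average")
        rep = _linkage_clusters(ids, Zb)
        for c in counts:
            if c in rep:
                counts[c] += 1
    bp = {c: 100.0 * v / n_boot for c, v in counts.items()} if n_boot else {}
    return Dendrogram(ids=ids, linkage_matrix=Z, bootstrap=bp)


# ---------------------------------------------------------------------------
# dendrogram comparison


@dataclass
class DendroComparison:
    cophenetic_correlation: float
    bakers_gamma: float
    entanglement: float
    discordant: list[tuple[str, int]]  # (strain, symmetric-difference score)


class _Node:
    __slots__ = ("name", "children", "height")

    def __init__(self, name=None, children=None, height=0.0):
        self.name = name
        self.children = children or []
        self.height = height

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _node_from_linkage(d: Dendrogram) -> _Node:
    root = hierarchy.to_tree(d.linkage_matrix)

    def rec(node) -> _Node:
        if node.is_leaf():
            return _Node(name=d.ids[node.id])
        return _Node(
            children=[rec(node.get_left()), rec(node.get_right())],
            height=node.dist,
        )

    return rec(root)


def _node_from_phylo(t: PhyloTree) -> _Node:
    # midpoint-root a copy: an unrooted NJ tree's arbitrary root can split
    # a clade across the traversal, inflating entanglement artificially
    tree = t.tree.copy()
    try:
        tree = tree.root_at_midpoint()
    except Exception:  # degenerate branch lengths: keep original rooting
        pass

    def rec(n) -> _Node:
        if n.is_tip():
            return _Node(name=n.name)
        return _Node(children=[rec(c) for c in n.children], height=0.0)

    return rec(tree)


def _as_node(obj) -> _Node:
    if isinstance(obj, Dendrogram):
        return _node_from_linkage(obj)
    if isinstance(obj, PhyloTree):
        return _node_from_phylo(obj)
    raise TypeError(f"cannot compare object of type {type(obj).__name__}")


def _cophenetic_vector(obj, pair_order: list[tuple[str, str]]) -> np.ndarray:
    if isinstance(obj, Dendrogram):
        dm = obj.cophenetic()
    elif isinstance(obj, PhyloTree):
        dm = obj.tip_distances()
    else:
        raise TypeError(type(obj).__name__)
    return np.array([dm.value(a, b) for a, b in pair_order])


def _entanglement(order1: list[str], order2: list[str]) -> float:
    pos2 = {s: i for i, s in enumerate(order2)}
    n = len(order1)
    if n < 2:
        return 0.0
    diffs = sum(abs(i - pos2[s]) for i, s in enumerate(order1))
    worst = sum(abs(i - (n - 1 - i)) for i in range(n))
    return diffs / worst if worst else 0.0


def _untangle(a: _Node, b: _Node, passes: int = 2) -> tuple[list[str], list[str]]:
    """Alternating 'step' rotation heuristic: greedily reorder children
    where it reduces entanglement, two passes each side.  Nodes with up to
    three children (e.g. the unrooted-tree root trichotomy) try every
    child permutation; larger polytomies only try the reversal."""

    def internal_nodes(node: _Node) -> list[_Node]:
        out = []
        stack = [node]
        while stack:
            x = stack.pop()
            if x.children:
                out.append(x)
                stack.extend(x.children)
        return out

    for _ in range(passes):
        for mobile, fixed in ((a, b), (b, a)):
            fixed_order = fixed.leaves()
            for node in internal_nodes(mobile):
                if len(node.children) <= 3:
                    options = list(itertools.permutations(node.children))
                else:
                    options = [tuple(node.children), tuple(reversed(node.children))]
                best = None
                for opt in options:
                    node.children = list(opt)
                    e = _entanglement(mobile.leaves(), fixed_order)
                    if best is None or e < best[0]:
                        best = (e, opt)
                node.children = list(best[1])
    return a.leaves(), b.leaves()


def compare_dendrograms(
    d_phylo, d_func, k_neighbors: int = 3
) -> DendroComparison:
    """Cophenetic r, Baker's gamma, entanglement, and discordant strains.

    A strain is discordant when its ``k_neighbors`` cophenetically nearest
    strains differ between the two trees; the score is the size of the
    symmetric difference of the two neighbour sets (ecotype detector).
    """
    node_a, node_b = _as_node(d_phylo), _as_node(d_func)
    leaves_a, leaves_b = sorted(node_a.leaves()), sorted(node_b.leaves())
    if leaves_a != leaves_b:
        raise ValueError(
            f"leaf sets differ: {sorted(set(leaves_a) ^ set(leaves_b))}"
        )
    leaves = leaves_a
    pair_order = list(itertools.combinations(leaves, 2))
    va = _cophenetic_vector(d_phylo, pair_order)
    vb = _cophenetic_vector(d_func, pair_order)
    r = float(pearsonr(va, vb).statistic) if va.std() and vb.std() else float("nan")
    gamma = float(spearmanr(va, vb).statistic) if va.std() and vb.std() else float("nan")

    o1, o2 = _untangle(node_a, node_b)
    ent = _entanglement(o1, o2)

    def knn(obj) -> dict[str, frozenset]:
        if isinstance(obj, Dendrogram):
            dm = obj.cophenetic()
        else:
            dm = obj.tip_distances()
        out = {}
        for s in leaves:
            others = sorted(
                ((dm.value(s, t), t) for t in leaves if t != s),
                key=lambda x: (x[0], x[1]),
            )
            out[s] = frozenset(t for _, t in others[:k_neighbors])
        return out

    ka, kb = knn(d_phylo), knn(d_func)
    discordant = sorted(
        ((s, len(ka[s] ^ kb[s])) for s in leaves if ka[s] != kb[s]),
        key=lambda x: (-x[1], x[0]),
    )
    return DendroComparison(
        cophenetic_correlation=r,
        bakers_gamma=gamma,
        entanglement=ent,
        discordant=discordant,
    )
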