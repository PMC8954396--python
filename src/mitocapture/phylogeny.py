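"""Tree inference: Jukes-Cantor distances, neighbor joining, Fitch
parsimony with random-addition + NNI search, and column bootstrap.

Parsimony treats gaps and '?' as missing (the universal state set), with
length variation carried separately by the binary indel characters, so
indel signal is counted once.  All searches are deterministic under a
fixed seed; ties break lexicographically.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import dendropy
import numpy as np

from .alignment import CaptureAlignment, IndelMatrix
from .core_io import BASES, parse_newick

JC_SATURATION_CAP = 5.0

# Fitch state-set bitmasks: A=1 C=2 G=4 T=8; gap/missing = universal (15)
_FITCH_LUT = np.full(256, 15, dtype=np.uint8)
for _b, _m in zip(BASES, (1, 2, 4, 8)):
    _FITCH_LUT[_b] = _m


# ---------------------------------------------------------------------------
# Distances


@dataclasses.dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    n_comparable: np.ndarray
    saturated: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")

    @classmethod
    def from_square(cls, taxa: Sequence[str], matrix: np.ndarray) -> "DistanceMatrix":
        matrix = np.asarray(matrix, dtype=float)
        n = len(taxa)
        return cls(list(taxa), matrix, np.full((n, n), -1), np.zeros((n, n), dtype=bool))


def jc_p_distance(row_a: np.ndarray, row_b: np.ndarray) -> tuple[float, int]:
    """Mismatch fraction over pairwise-comparable nucleotide columns."""
    comp = np.isin(row_a, BASES) & np.isin(row_b, BASES)
    n = int(np.count_nonzero(comp))
    if n == 0:
        raise ValueError("no pairwise-comparable nucleotide columns")
    return float(np.count_nonzero(comp & (row_a != row_b)) / n), n


def jc_correct(p: float) -> float:
    """Jukes-Cantor correction; saturation (p >= 0.75) is capped."""
    if p >= 0.75:
        return JC_SATURATION_CAP
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def jc_distance(aln: CaptureAlignment, taxon_a: str, taxon_b: str) -> float:
    p, _ = jc_p_distance(aln.row(taxon_a), aln.row(taxon_b))
    return jc_correct(p)


def jc_matrix(aln: CaptureAlignment, taxa: Sequence[str] | None = None) -> DistanceMatrix:
    taxa = list(taxa) if taxa is not None else list(aln.taxa)
    rows = aln.subset_rows(taxa)
    n = len(taxa)
    d = np.zeros((n, n))
    nc = np.zeros((n, n), dtype=np.int64)
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            p, cnt = jc_p_distance(rows[i], rows[j])
            d[i, j] = d[j, i] = jc_correct(p)
            nc[i, j] = nc[j, i] = cnt
            sat[i, j] = sat[j, i] = p >= 0.75
    return DistanceMatrix(taxa, d, nc, sat)


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou-Nei), deterministic with lexicographic tie-break


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(D.matrix)):
        raise ValueError("non-finite distance entries")
    # active clusters: (sort key = smallest member label, newick string)
    labels = [(t, t) for t in D.taxa]
    d = D.matrix.astype(float).copy()
    active = list(range(n))
    newicks = {i: D.taxa[i] for i in range(n)}
    keys = {i: D.taxa[i] for i in range(n)}
    next_id = n
    dd = {(i, j): d[i, j] for i in range(n) for j in range(n)}

    def dist(i, j):
        return dd[(i, j)] if i <= j else dd[(j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for a, b in itertools.combinations(sorted(active, key=lambda i: keys[i]), 2):
            q = (m - 2) * dist(a, b) - r[a] - r[b]
            cand = (q, keys[a], keys[b], a, b)
            if best is None or cand < best:
                best = cand
        _, _, _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        u = next_id
        next_id += 1
        for k in active:
            if k in (a, b):
                continue
            duk = 0.5 * (dist(a, k) + dist(b, k) - dab)
            dd[(min(u, k), max(u, k))] = max(duk, 0.0)
        newicks[u] = f"({newicks[a]}:{la:.10g},{newicks[b]}:{lb:.10g})"
        keys[u] = min(keys[a], keys[b])
        active = [k for k in active if k not in (a, b)] + [u]
    # final three clusters join at a star node with exact branch lengths
    a, b, c = sorted(active, key=lambda i: keys[i])
    la = max(0.5 * (dist(a, b) + dist(a, c) - dist(b, c)), 0.0)
    lb = max(0.5 * (dist(a, b) + dist(b, c) - dist(a, c)), 0.0)
    lc = max(0.5 * (dist(a, c) + dist(b, c) - dist(a, b)), 0.0)
    text = f"({newicks[a]}:{la:.10g},{newicks[b]}:{lb:.10g},{newicks[c]}:{lc:.10g});"
    tree = parse_newick(text)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Pooled parsimony characters


def pooled_fitch_masks(
    aln: CaptureAlignment, m: IndelMatrix | None = None, taxa: Sequence[str] | None = None
) -> np.ndarray:
    """Per-taxon Fitch bitmask rows over pooled nucleotide + indel characters."""
    taxa = list(taxa) if taxa is not None else list(aln.taxa)
    nuc = _FITCH_LUT[aln.subset_rows(taxa)]
    if m is not None and len(m.events):
        ev = m.states[[m.taxa.index(t) for t in taxa]]
        ev_masks = np.where(ev < 0, 3, np.where(ev == 0, 1, 2)).astype(np.uint8)
        return np.concatenate([nuc, ev_masks], axis=1)
    return nuc


def compress_patterns(masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical character patterns; returns (patterns, weights)."""
    uniq, counts = np.unique(masks.T, axis=0, return_counts=True)
    return uniq.T.copy(), counts


# ---------------------------------------------------------------------------
# Unrooted trees as adjacency maps (leaves are 0..n-1 in taxa order)


def _postorder(adj: dict[int, list[int]], root: int) -> list[tuple[int, int]]:
    """(node, parent) pairs in postorder."""
    out = []
    stack = [(root, -1)]
    while stack:
        node, parent = stack.pop()
        out.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    out.reverse()
    return out


def fitch_steps(adj: dict[int, list[int]], leaf_masks: np.ndarray, weights: np.ndarray) -> int:
    """Weighted Fitch parsimony length of an unrooted tree."""
    n_leaves = leaf_masks.shape[0]
    root = next(v for v in adj if v >= n_leaves) if len(adj) > 2 else next(iter(adj))
    steps = np.zeros(leaf_masks.shape[1], dtype=np.int64)
    masks: dict[int, np.ndarray] = {}
    for node, parent in _postorder(adj, root):
        if node < n_leaves:
            masks[node] = leaf_masks[node]
            continue
        acc = None
        for nb in adj[node]:
            if nb == parent:
                continue
            cm = masks.pop(nb)
            if acc is None:
                acc = cm.copy()
            else:
                inter = acc & cm
                conflict = inter == 0
                steps += conflict
                acc = np.where(conflict, acc | cm, inter)
        masks[node] = acc
    return int((steps * weights).sum())


def fitch_score(
    tree: dendropy.Tree, aln: CaptureAlignment, m: IndelMatrix | None = None
) -> int:
    """Fitch minimum-mutation count of a tree over pooled characters.

    Gaps and '?' are missing (universal state); the score is the unrooted
    parsimony length, invariant under re-rooting.
    """
    taxa = list(aln.taxa)
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = leaf_labels - set(taxa)
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {sorted(missing)}")
    order = [t for t in taxa if t in leaf_labels]
    masks = pooled_fitch_masks(aln, m, order)
    patterns, weights = compress_patterns(masks)
    adj, _ = _tree_to_adjacency(tree, order)
    return fitch_steps(adj, patterns, weights)


def _tree_to_adjacency(tree: dendropy.Tree, taxa_order: Sequence[str]):
    index = {t: i for i, t in enumerate(taxa_order)}
    n = len(taxa_order)
    adj: dict[int, list[int]] = {}
    ids: dict[int, int] = {}
    next_id = n

    def node_id(node):
        nonlocal next_id
        key = id(node)
        if key not in ids:
            if node.is_leaf():
                ids[key] = index[node.taxon.label]
            else:
                ids[key] = next_id
                next_id += 1
        return ids[key]

    for node in tree.preorder_node_iter():
        u = node_id(node)
        adj.setdefault(u, [])
        for child in node.child_nodes():
            v = node_id(child)
            adj.setdefault(v, [])
            adj[u].append(v)
            adj[v].append(u)
    # suppress a degree-2 root (unrooted semantics)
    root = node_id(tree.seed_node)
    if len(adj[root]) == 2:
        a, b = adj.pop(root)
        adj[a] = [x for x in adj[a] if x != root] + [b]
        adj[b] = [x for x in adj[b] if x != root] + [a]
    return adj, next_id


def _adjacency_to_newick(adj: dict[int, list[int]], taxa: Sequence[str]) -> str:
    n = len(taxa)
    root = next((v for v in adj if v >= n), None)
    if root is None:  # two-leaf tree
        a, b = sorted(adj)
        return f"({taxa[a]},{taxa[b]});"

    def render(node, parent):
        if node < n:
            return taxa[node]
        parts = [render(nb, node) for nb in adj[node] if nb != parent]
        return "(" + ",".join(parts) + ")"

    return render(root, -1) + ";"


def _bipartitions(adj: dict[int, list[int]], n_leaves: int) -> frozenset[int]:
    """Canonical nontrivial split bitmasks (side not containing leaf 0)."""
    full = (1 << n_leaves) - 1
    root = next((v for v in adj if v >= n_leaves), None)
    if root is None:
        return frozenset()
    below: dict[int, int] = {}
    splits = set()
    for node, parent in _postorder(adj, root):
        if node < n_leaves:
            below[node] = 1 << node
        else:
            mask = 0
            for nb in adj[node]:
                if nb != parent:
                    mask |= below[nb]
            below[node] = mask
        if parent != -1:
            mask = below[node]
            if mask & 1:
                mask = full & ~mask
            pop = bin(mask).count("1")
            if 2 <= pop <= n_leaves - 2:
                splits.add(mask)
    return frozenset(splits)


def tree_bipartitions(tree: dendropy.Tree, taxa_order: Sequence[str]) -> frozenset[int]:
    adj, _ = _tree_to_adjacency(tree, taxa_order)
    return _bipartitions(adj, len(taxa_order))


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric split difference)."""
    taxa = sorted(l.taxon.label for l in t1.leaf_node_iter())
    taxa2 = sorted(l.taxon.label for l in t2.leaf_node_iter())
    if taxa != taxa2:
        raise ValueError("trees are over different leaf sets")
    s1 = tree_bipartitions(t1, taxa)
    s2 = tree_bipartitions(t2, taxa)
    return len(s1 ^ s2)


# ---------------------------------------------------------------------------
# MP heuristic search: random stepwise addition + NNI


@dataclasses.dataclass
class MPResult:
    tree: dendropy.Tree  # best tree, or strict consensus of tied optima
    score: int
    n_optima: int
    best_newicks: list[str]


def _edges(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    return sorted((u, v) for u in adj for v in adj[u] if u < v)


def _attach(adj, u, v, internal, leaf):
    adj[u] = [x if x != v else internal for x in adj[u]]
    adj[v] = [x if x != u else internal for x in adj[v]]
    adj[internal] = [u, v, leaf]
    adj[leaf] = [internal]


def _detach(adj, u, v, internal, leaf):
    adj[u] = [x if x != internal else v for x in adj[u]]
    adj[v] = [x if x != internal else u for x in adj[v]]
    del adj[internal]
    del adj[leaf]


def _stepwise_addition(order, patterns, weights, next_internal):
    adj = {}
    a, b, c = order[:3]
    w = next_internal
    adj[a], adj[b], adj[c] = [w], [w], [w]
    adj[w] = [a, b, c]
    next_internal += 1
    for leaf in order[3:]:
        best = None
        for (u, v) in _edges(adj):
            _attach(adj, u, v, next_internal, leaf)
            s = fitch_steps(adj, patterns, weights)
            _detach(adj, u, v, next_internal, leaf)
            if best is None or s < best[0]:
                best = (s, u, v)
        _, u, v = best
        _attach(adj, u, v, next_internal, leaf)
        next_internal += 1
    return adj, next_internal


def _nni_neighbors(adj, u, v):
    """The two NNI rearrangements around internal edge (u, v)."""
    a, b = [x for x in adj[u] if x != v]
    c, d = [x for x in adj[v] if x != u]
    return [((u, b, v, c)), ((u, b, v, d))]  # swap b with c / with d


def _apply_nni(adj, u, b, v, c):
    adj[u] = [x if x != b else c for x in adj[u]]
    adj[v] = [x if x != c else b for x in adj[v]]
    adj[b] = [x if x != u else v for x in adj[b]]
    adj[c] = [x if x != v else u for x in adj[c]]


def _nni_search(adj, patterns, weights, n_leaves):
    score = fitch_steps(adj, patterns, weights)
    improved = True
    while improved:
        improved = False
        for (u, v) in _edges(adj):
            if u < n_leaves or v < n_leaves:
                continue
            for (uu, b, vv, c) in _nni_neighbors(adj, u, v):
                _apply_nni(adj, uu, b, vv, c)
                s = fitch_steps(adj, patterns, weights)
                if s < score:
                    score = s
                    improved = True
                    break  # neighbor lists are stale after an accepted swap
                _apply_nni(adj, uu, c, vv, b)  # undo
            if improved:
                break
    return adj, score


def mp_search(
    aln: CaptureAlignment,
    m: IndelMatrix | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> MPResult:
    """Random-addition-sequence parsimony search with NNI refinement.

    Returns the best tree found; when several distinct topologies tie at
    the best score their strict consensus is returned instead.
    """
    taxa = list(aln.taxa)
    if len(taxa) < 4:
        raise ValueError("parsimony search needs at least 4 taxa")
    masks = pooled_fitch_masks(aln, m, taxa)
    patterns, weights = compress_patterns(masks)
    rng = np.random.default_rng(seed)
    n = len(taxa)
    best_score = None
    best_set: dict[frozenset[int], str] = {}
    for _ in range(max(1, n_starts)):
        order = list(rng.permutation(n))
        adj, _ = _stepwise_addition(order, patterns, weights, n)
        adj, score = _nni_search(adj, patterns, weights, n)
        if best_score is None or score < best_score:
            best_score = score
            best_set = {}
        if score == best_score:
            key = _bipartitions(adj, n)
            best_set.setdefault(key, _adjacency_to_newick(adj, taxa))
    newicks = sorted(best_set.values())
    trees = [parse_newick(t) for t in newicks]
    if len(trees) == 1:
        tree = trees[0]
    else:
        tree = strict_consensus(trees)
    return MPResult(tree=tree, score=int(best_score), n_optima=len(trees), best_newicks=newicks)


def strict_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Strict consensus: keep only splits present in every input tree."""
    taxa = sorted(l.taxon.label for l in trees[0].leaf_node_iter())
    common = None
    for t in trees:
        s = tree_bipartitions(t, taxa)
        common = s if common is None else (common & s)
    return _tree_from_splits(common or frozenset(), taxa)


def _tree_from_splits(splits: frozenset[int], taxa: Sequence[str]) -> dendropy.Tree:
    """Build a (possibly multifurcating) unrooted tree from compatible splits."""
    n = len(taxa)
    # treat splits as nested clades on the side away from leaf 0
    clades = sorted(splits, key=lambda s: bin(s).count("1"))
    children: dict[int, list[object]] = {s: [] for s in clades}
    assigned = {}
    for i in range(n):
        holder = None
        for s in clades:  # smallest enclosing clade
            if s >> i & 1:
                holder = s
                break
        assigned[i] = holder
    parent = {}
    for si, s in enumerate(clades):
        p = None
        for t in clades[si + 1 :]:
            if s & t == s:
                p = t
                break
        parent[s] = p

    def render_clade(s):
        parts = [taxa[i] for i in range(n) if assigned[i] == s]
        parts += [render_clade(c) for c in clades if parent.get(c) == s]
        return "(" + ",".join(parts) + ")"

    top_leaves = [taxa[i] for i in range(n) if assigned[i] is None]
    top_clades = [render_clade(s) for s in clades if parent[s] is None]
    text = "(" + ",".join(top_leaves + top_clades) + ");"
    tree = parse_newick(text)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap(
    aln: CaptureAlignment,
    m: IndelMatrix | None = None,
    B: int = 100,
    method: str = "nj",
    seed: int = 0,
    n_starts: int = 2,
) -> tuple[dendropy.Tree, dict[int, float]]:
    """Column bootstrap over pooled characters; supports on the best tree.

    Resamples nucleotide columns and indel characters as one pooled set,
    infers a tree per replicate (``nj`` distances are computed from the
    resampled nucleotide columns; ``mp`` uses every resampled character),
    and annotates each internal bipartition of the full-data best tree
    with its replicate frequency x 100.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if method not in ("nj", "mp"):
        raise ValueError("method must be 'nj' or 'mp'")
    taxa = list(aln.taxa)
    n = len(taxa)
    rng = np.random.default_rng(seed)

    nuc = aln.subset_rows(taxa)
    n_nuc = nuc.shape[1]
    if m is not None and len(m.events):
        ev = m.states[[m.taxa.index(t) for t in taxa]]
    else:
        ev = np.zeros((n, 0), dtype=np.int8)
    n_chars = n_nuc + ev.shape[1]

    def infer(nuc_cols: np.ndarray, ev_cols: np.ndarray) -> dendropy.Tree:
        if method == "nj":
            D = _jc_matrix_from_rows(taxa, nuc_cols)
            t = neighbor_joining(D)
            # zero-length internal branches carry no signal: collapse them so
            # arbitrary tie-break resolutions do not masquerade as support
            for edge in list(t.preorder_edge_iter()):
                if (
                    edge.head_node.parent_node is not None
                    and not edge.head_node.is_leaf()
                    and (edge.length or 0.0) <= 0.0
                ):
                    edge.collapse()
            return t
        masks = _FITCH_LUT[nuc_cols]
        ev_masks = np.where(ev_cols < 0, 3, np.where(ev_cols == 0, 1, 2)).astype(np.uint8)
        pooled = np.concatenate([masks, ev_masks], axis=1)
        patterns, weights = compress_patterns(pooled)
        rng_local = np.random.default_rng(int(rng.integers(2**31)))
        best = None
        for _ in range(max(1, n_starts)):
            order = list(rng_local.permutation(n))
            adj, _ = _stepwise_addition(order, patterns, weights, n)
            adj, score = _nni_search(adj, patterns, weights, n)
            if best is None or score < best[0]:
                best = (score, _adjacency_to_newick(adj, taxa))
        return parse_newick(best[1])

    best_tree = infer(nuc, ev)
    target_splits = tree_bipartitions(best_tree, taxa)
    counts = {s: 0 for s in target_splits}
    for _ in range(B):
        idx = rng.integers(0, n_chars, size=n_chars)
        nuc_idx = idx[idx < n_nuc]
        ev_idx = idx[idx >= n_nuc] - n_nuc
        rep = infer(nuc[:, nuc_idx], ev[:, ev_idx])
        rep_splits = tree_bipartitions(rep, taxa)
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / B for s, c in counts.items()}
    _annotate_support(best_tree, taxa, support)
    return best_tree, support


def _jc_matrix_from_rows(taxa: Sequence[str], rows: np.ndarray) -> DistanceMatrix:
    n = len(taxa)
    d = np.zeros((n, n))
    nc = np.zeros((n, n), dtype=np.int64)
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            comp = np.isin(rows[i], BASES) & np.isin(rows[j], BASES)
            cnt = int(np.count_nonzero(comp))
            p = float(np.count_nonzero(comp & (rows[i] != rows[j])) / cnt) if cnt else 0.0
            d[i, j] = d[j, i] = jc_correct(p)
            nc[i, j] = nc[j, i] = cnt
            sat[i, j] = sat[j, i] = p >= 0.75
    return DistanceMatrix(list(taxa), d, nc, sat)


def _annotate_support(tree: dendropy.Tree, taxa_order: Sequence[str], support: dict[int, float]):
    index = {t: i for i, t in enumerate(taxa_order)}
    full = (1 << len(taxa_order)) - 1
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        mask = 0
        for l in node.leaf_iter():
            mask |= 1 << index[l.taxon.label]
        if mask & 1:
            mask = full & ~mask
        if mask in support:
            node.label = f"{support[mask]:.0f}"
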