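"""Penalized-likelihood divergence-time estimation on a fixed topology.

Node ages and per-branch rates are fit by minimizing a penalized Poisson
deviance: each branch contributes -[x ln(rt) - rt - ln x!] with x the
(rounded) expected substitution count from the branch length, t the time
span, r the branch rate; a smoothing term lambda * [sum over non-root
branches of (r - r_parent)^2 + Var(rates of the root's children)]
discourages rate changes between adjacent branches.  Fossil calibrations
are box constraints on clade MRCA ages.  Optimization is deterministic:
alternating coordinate passes over ages and rates with box projection.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import dendropy
import numpy as np
import yaml
from scipy.optimize import nnls
from scipy.special import gammaln

from .alignment import CaptureAlignment, IndelMatrix
from .core_io import BASES
from .phylogeny import jc_correct

_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class Calibration:
    """Min/max age constraint (Mya) on the MRCA of a leaf set."""

    leaves: tuple[str, ...]
    min_age: float
    max_age: float

    def __post_init__(self):
        if not 0 < self.min_age <= self.max_age:
            raise ValueError("calibration requires 0 < min <= max")


def load_calibrations(path) -> list[Calibration]:
    """YAML: list of {leaves: [a, b, ...], min: x, max: y}."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [Calibration(tuple(c["leaves"]), float(c["min"]), float(c["max"])) for c in data]


@dataclasses.dataclass
class Chronogram:
    tree: dendropy.Tree  # node.age set on every node
    ages: dict[frozenset[str], float]  # clade leafset -> age
    rates: dict[frozenset[str], float]  # clade leafset of edge's child -> rate
    smoothing: float
    score: float


# ---------------------------------------------------------------------------
# Flattened tree scaffold


class _Scaffold:
    """Arrays over nodes of a rooted tree; node 0 is the root (preorder)."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.nodes = list(tree.preorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[id(n.parent_node)] if n.parent_node else -1 for n in self.nodes]
        )
        self.is_leaf = np.array([n.is_leaf() for n in self.nodes])
        self.bl = np.array([(n.edge.length or 0.0) for n in self.nodes])
        self.children: list[list[int]] = [[] for _ in self.nodes]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.leafsets = [frozenset(l.taxon.label for l in n.leaf_iter()) for n in self.nodes]
        self.postorder = list(range(len(self.nodes)))[::-1]  # reverse preorder

    def heights(self) -> np.ndarray:
        """Max branch-length distance to any descendant leaf."""
        h = np.zeros(len(self.nodes))
        for i in self.postorder:
            for c in self.children[i]:
                h[i] = max(h[i], h[c] + self.bl[c])
        return h


def _resolve_calibrations(sc: _Scaffold, calibrations: Sequence[Calibration]):
    lo = np.zeros(len(sc.nodes))
    hi = np.full(len(sc.nodes), np.inf)
    for cal in calibrations:
        want = set(cal.leaves)
        missing = want - sc.leafsets[0]
        if missing:
            raise ValueError(f"calibration leaves not in tree: {sorted(missing)}")
        # MRCA = shallowest node whose clade contains all named leaves
        node = None
        for i, ls in enumerate(sc.leafsets):
            if want <= ls and (node is None or ls < sc.leafsets[node]):
                node = i
        if len(want) > 2 and sc.leafsets[node] != frozenset(want):
            raise ValueError(
                f"calibration clade {sorted(want)} is not monophyletic in the tree"
            )
        lo[node] = max(lo[node], cal.min_age)
        hi[node] = min(hi[node], cal.max_age)
    # propagate: a node can be no older than any ancestor's max,
    # no younger than any descendant's min
    for i in range(len(sc.nodes)):  # preorder: parents first
        p = sc.parent[i]
        if p >= 0:
            hi[i] = min(hi[i], hi[p])
    for i in sc.postorder:
        for c in sc.children[i]:
            lo[i] = max(lo[i], lo[c])
    bad = lo > hi + 1e-12
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"infeasible calibrations at clade {sorted(sc.leafsets[i])[:4]}...: "
            f"min {lo[i]} > max {hi[i]}"
        )
    return lo, hi


# ---------------------------------------------------------------------------
# Objective


def _poisson_terms(x: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    rt = r * t
    with np.errstate(divide="ignore", invalid="ignore"):
        ln = np.where(x > 0, x * np.log(rt), 0.0)
    return ln - rt - gammaln(x + 1)


def pl_objective(
    tree: dendropy.Tree,
    ages: Mapping[frozenset[str], float],
    rates: Mapping[frozenset[str], float],
    smoothing: float,
    n_sites: int,
) -> float:
    """Penalized-likelihood score of explicit ages/rates (lower is better).

    ``ages`` and ``rates`` are keyed by clade leafset (as produced by
    :func:`date_tree`); rates are in substitutions/site/My.
    """
    sc = _Scaffold(tree)
    age = np.array([ages.get(ls, 0.0) for ls in sc.leafsets])
    rate = np.array([rates.get(ls, np.nan) for ls in sc.leafsets]) * n_sites
    x = np.maximum(np.rint(sc.bl * n_sites), 0.0)
    return _score(sc, age, rate, x, smoothing)


def _score(sc: _Scaffold, age, rate, x, lam) -> float:
    nonroot = sc.parent >= 0
    t = age[sc.parent[nonroot]] - age[nonroot]
    if np.any(t <= 0):
        raise ValueError("every branch must have positive duration (parent age > child age)")
    r = rate[nonroot]
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("rates must be positive on every branch")
    loglik = _poisson_terms(x[nonroot], r, t).sum()
    pen = 0.0
    for i in range(len(sc.nodes)):
        p = sc.parent[i]
        if p > 0:  # parent is itself a nonroot edge
            pen += (rate[i] - rate[p]) ** 2
    root_children = sc.children[0]
    if len(root_children) > 1:
        rc = rate[root_children]
        pen += float(np.var(rc))
    return float(-loglik + lam * pen)


# ---------------------------------------------------------------------------
# Fitting


_U_LO, _U_HI = 1e-6, 1.0 - 1e-6


def date_tree(
    tree: dendropy.Tree,
    calibrations: Sequence[Calibration],
    smoothing: float = 10.0,
    n_sites: int = 1000,
    tol: float = 1e-10,
) -> Chronogram:
    """Fit node ages and branch rates under calibration box constraints.

    Ages are parameterized as nested fractions of their feasible interval
    (each internal node sits a fraction u of the way between the larger
    of its calibration minimum and 0, and the smaller of its parent's
    age and its calibration maximum), which turns the ordering + box
    constraints into plain bounds; rates are optimized on a log scale.
    The joint problem is solved with L-BFGS-B from a deterministic
    height-proportional initialization.
    """
    work = tree.clone(depth=1)
    sc = _Scaffold(work)
    lo, hi = _resolve_calibrations(sc, calibrations)
    n = len(sc.nodes)
    x = np.maximum(np.rint(sc.bl * n_sites), 0.0)
    nonroot = np.nonzero(sc.parent >= 0)[0]
    internal = [i for i in range(n) if not sc.is_leaf[i]]  # preorder, root first
    n_int = len(internal)

    h = sc.heights()
    if not np.isfinite(hi[0]):
        hi[0] = max(4.0 * lo[0], 4.0 * h[0], 1.0)

    def decode(params: np.ndarray):
        u = params[:n_int]
        rate = np.full(n, np.nan)
        rate[nonroot] = np.exp(params[n_int:])
        age = np.zeros(n)
        for idx, i in enumerate(internal):
            upper = hi[i] if sc.parent[i] < 0 else min(age[sc.parent[i]], hi[i])
            lower = lo[i]
            age[i] = lower + u[idx] * (upper - lower)
        return age, rate

    def objective(params: np.ndarray) -> float:
        age, rate = decode(params)
        t = age[sc.parent[nonroot]] - age[nonroot]
        t = np.maximum(t, 1e-12 * max(hi[0], 1.0))
        r = rate[nonroot]
        loglik = _poisson_terms(x[nonroot], r, t).sum()
        pen = 0.0
        for i in nonroot:
            p = sc.parent[i]
            if p > 0:
                pen += (rate[i] - rate[p]) ** 2
        rc = sc.children[0]
        if len(rc) > 1:
            pen += float(np.var(rate[rc]))
        return float(-loglik + smoothing * pen)

    # deterministic init: height-proportional ages inverted into fractions
    root_age0 = 0.5 * (max(lo[0], _EPS) + hi[0])
    age0 = h / h[0] * root_age0 if h[0] > 0 else np.full(n, root_age0 / 2)
    age0[sc.is_leaf] = 0.0
    u0 = np.empty(n_int)
    age_tmp = np.zeros(n)
    for idx, i in enumerate(internal):
        upper = hi[i] if sc.parent[i] < 0 else min(age_tmp[sc.parent[i]], hi[i])
        lower = lo[i]
        width = max(upper - lower, _EPS)
        u0[idx] = np.clip((age0[i] - lower) / width, 0.05, 0.95)
        age_tmp[i] = lower + u0[idx] * width
    t_init = np.maximum(age_tmp[sc.parent[nonroot]] - age_tmp[nonroot], _EPS)
    r0 = max(sc.bl[nonroot].sum() * n_sites / max(t_init.sum(), _EPS), 1e-8)
    params0 = np.concatenate([u0, np.full(nonroot.size, np.log(r0))])

    from scipy.optimize import minimize

    bounds = [(_U_LO, _U_HI)] * n_int + [(np.log(1e-12), np.log(1e12))] * nonroot.size
    res = minimize(
        objective,
        params0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 2000, "maxfun": 200_000, "ftol": tol, "gtol": 1e-10},
    )
    age, rate = decode(res.x)
    score = float(res.fun)

    # post-hoc invariant checks
    for i in nonroot:
        assert age[sc.parent[i]] > age[i] or sc.is_leaf[i] and age[i] == 0.0, (
            "chronogram violates parent > child ordering"
        )
    assert np.all(age >= lo - 1e-6) and np.all(age <= hi + 1e-6), "calibration box violated"

    ages = {}
    rates = {}
    for i, node in enumerate(sc.nodes):
        node.age = float(age[i])
        ages[sc.leafsets[i]] = float(age[i])
        if sc.parent[i] >= 0:
            rates[sc.leafsets[i]] = float(rate[i]) / n_sites  # per site per My
    return Chronogram(tree=work, ages=ages, rates=rates, smoothing=smoothing, score=score)


# ---------------------------------------------------------------------------
# Smoothing selection by branch-pruning cross-validation


def select_lambda(
    tree: dendropy.Tree,
    calibrations: Sequence[Calibration],
    grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0, 1000.0),
    n_sites: int = 1000,
) -> tuple[float, dict[float, float]]:
    """Pick the smoothing value minimizing terminal-branch prediction error.

    For each grid value and each terminal branch: the leaf is pruned, the
    pruned tree re-dated, and the leaf's substitution count predicted as
    (rate of the sibling-subtree edge) x (age of its parent in the
    pruned fit); the squared error is summed over leaves.
    """
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    errors: dict[float, float] = {}
    for lam in grid:
        err = 0.0
        for leaf in leaves:
            err += _prune_prediction_error(tree, calibrations, leaf, lam, n_sites)
        errors[lam] = err
    best = min(grid, key=lambda l: (errors[l], l))
    return best, errors


def _prune_prediction_error(tree, calibrations, leaf, lam, n_sites) -> float:
    node = next(l for l in tree.leaf_node_iter() if l.taxon.label == leaf)
    x_leaf = max(round((node.edge.length or 0.0) * n_sites), 0)
    parent = node.parent_node
    siblings = [c for c in parent.child_nodes() if c is not node]
    sib_set = frozenset(l.taxon.label for s in siblings for l in s.leaf_iter())
    pruned = tree.clone(depth=1)
    pruned.prune_taxa_with_labels([leaf], suppress_unifurcations=True)
    if len(pruned.leaf_nodes()) < 3:
        return 0.0
    kept = {l.taxon.label for l in pruned.leaf_node_iter()}
    cals = []
    for cal in calibrations:
        keep = tuple(t for t in cal.leaves if t != leaf)
        if len(keep) >= 2 and set(keep) <= kept:
            cals.append(Calibration(keep, cal.min_age, cal.max_age))
    if not cals:
        return 0.0
    chrono = date_tree(pruned, cals, smoothing=lam, n_sites=n_sites)
    # locate the sibling subtree's root edge in the pruned fit
    target = None
    for ls, r in chrono.rates.items():
        if ls == sib_set or (target is None and sib_set <= ls):
            if ls == sib_set:
                target = (ls, r)
                break
            target = (ls, r)
    if target is None:
        return 0.0
    ls, r = target
    parent_age = None
    for node2 in chrono.tree.preorder_node_iter():
        ls2 = frozenset(l.taxon.label for l in node2.leaf_iter())
        if ls2 == ls and node2.parent_node is not None:
            parent_age = node2.parent_node.age
            break
    if parent_age is None:
        parent_age = chrono.ages[frozenset(kept)]
    predicted = r * parent_age * n_sites
    return float((x_leaf - predicted) ** 2)


# ---------------------------------------------------------------------------
# Bootstrap ages


@dataclasses.dataclass
class AgeSummary:
    clade: frozenset[str]
    mean: float
    lower: float  # central 95% interval
    upper: float


def _ls_branch_lengths(tree: dendropy.Tree, dist: np.ndarray, taxa: Sequence[str]) -> None:
    """Least-squares branch lengths (non-negative) for a fixed topology, in place."""
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    masks = []
    for nd in edges:
        mask = 0
        for l in nd.leaf_iter():
            mask |= 1 << index[l.taxon.label]
        masks.append(mask)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        d[row] = dist[i, j]
        for col, mask in enumerate(masks):
            below_i = bool(mask >> i & 1)
            below_j = bool(mask >> j & 1)
            if below_i != below_j:
                A[row, col] = 1.0
    b, _ = nnls(A, d)
    for nd, length in zip(edges, b):
        nd.edge.length = float(length)


def bootstrap_ages(
    aln: CaptureAlignment,
    m: IndelMatrix | None,
    topology: dendropy.Tree,
    calibrations: Sequence[Calibration],
    B: int = 100,
    seed: int = 0,
    smoothing: float = 10.0,
    outgroup: str | None = None,
) -> dict[frozenset[str], AgeSummary]:
    """Column-bootstrap node ages on a fixed topology.

    Per replicate: pooled characters are resampled, branch lengths are
    re-fit by non-negative least squares against Jukes-Cantor distances
    from the resampled nucleotide columns, and the tree is re-dated.
    Ages are summarized per clade as mean and central 95% interval.

    An ``outgroup`` leaf at the root makes the two root-child branch
    lengths identifiable during the least-squares fit; it is pruned
    before dating so its (typically near-zero) branch does not distort
    the rate smoothing.
    """
    taxa = [l.taxon.label for l in topology.leaf_node_iter()]
    nuc = aln.subset_rows(taxa)
    n_nuc = nuc.shape[1]
    n_ev = len(m.events) if m is not None else 0
    n_chars = n_nuc + n_ev
    rng = np.random.default_rng(seed)
    samples: dict[frozenset[str], list[float]] = {}
    for _ in range(B):
        idx = rng.integers(0, n_chars, size=n_chars)
        nuc_idx = idx[idx < n_nuc]
        rows = nuc[:, nuc_idx]
        n = len(taxa)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                comp = np.isin(rows[i], BASES) & np.isin(rows[j], BASES)
                cnt = int(np.count_nonzero(comp))
                p = float(np.count_nonzero(comp & (rows[i] != rows[j])) / cnt) if cnt else 0.0
                dist[i, j] = dist[j, i] = jc_correct(p)
        work = topology.clone(depth=1)
        _ls_branch_lengths(work, dist, taxa)
        if outgroup is not None:
            work.prune_taxa_with_labels([outgroup], suppress_unifurcations=True)
        chrono = date_tree(work, calibrations, smoothing=smoothing, n_sites=nuc_idx.size)
        for ls, a in chrono.ages.items():
            if len(ls) > 1:
                samples.setdefault(ls, []).append(a)
    out = {}
    for ls, vals in samples.items():
        arr = np.array(vals)
        out[ls] = AgeSummary(
            clade=ls,
            mean=float(arr.mean()),
            lower=float(np.percentile(arr, 2.5)),
            upper=float(np.percentile(arr, 97.5)),
        )
    return out
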