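"""Synthetic capture-experiment generator.

Emulates the statistical structure of a mitochondrial target-capture
dataset: a multi-contig reference, sequences evolved along a known tree
by substitutions and non-overlapping indels, regional capture dropout
whose extent grows with phylogenetic distance from the reference taxon,
and optional introgression (column transfer between clades).  Everything
is deterministic under a fixed seed, and the generator keeps exact truth
bookkeeping so downstream stages can be checked for identity.

The root sequence equals the reference; the reference taxon is a leaf
with zero branch length, mirroring reference-mapping geometry.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import dendropy
import numpy as np

from .alignment import (
    CaptureAlignment,
    IndelEvent,
    IndelMatrix,
    ReferenceIndex,
    SampleConsensus,
)
from .core_io import A, BASES, GAP, MISSING, decode_seq, parse_newick


@dataclasses.dataclass
class SimParams:
    """Knobs of the generator; defaults loosely mirror the target study."""

    n_contigs: int = 19
    total_ref_len: int = 1_000_000
    tree: str | None = None  # newick; generated randomly when None
    n_taxa: int = 12  # used only when tree is None
    mean_branch_len: float = 0.005  # for the random tree
    ref_taxon: str = "REF"
    subst_model: str = "JC"  # "JC" | "HKY"
    hky_kappa: float = 2.0
    indel_rate: float = 0.3  # indel events per expected substitution
    indel_len_mean: float = 4.0  # geometric mean length, bp
    dropout_base: float = 0.08
    dropout_slope: float = 0.0  # per unit root-to-tip divergence
    dropout_window_mean: float = 2000.0  # bp, geometric segment length
    captured_mean_depth: float = 100.0
    captured_min_depth: int = 20  # captured depth is shifted NB: never below this
    dropout_mean_depth: float = 2.0
    nb_size: float = 10.0  # negative-binomial dispersion of captured depth
    introgression_events: list[tuple[tuple[str, ...], tuple[str, ...], float]] = dataclasses.field(
        default_factory=list
    )
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_base <= 1.0:
            raise ValueError("dropout_base must be in [0, 1]")
        if self.subst_model not in ("JC", "HKY"):
            raise ValueError("subst_model must be JC or HKY")
        for donor, recipient, f in self.introgression_events:
            if not 0.0 <= f <= 1.0:
                raise ValueError("introgression fraction must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class TrueIndel:
    """A generated indel event in concatenated reference coordinates."""

    kind: str  # "del" | "ins"
    start: int  # for ins: the insertion point (between start-1 and start)
    end: int  # half-open; == start for ins
    seq: str  # inserted sequence ("" for del)
    clade: frozenset[str]  # leaves carrying the event


@dataclasses.dataclass
class SimTruth:
    """Exact bookkeeping of everything the generator did."""

    tree: str
    taxa: list[str]
    indel_events: list[TrueIndel]
    branch_subs: dict[str, int]  # leafset-key of child clade -> applied substitutions
    divergence: dict[str, float]  # leaf -> root-to-tip path length
    masked_fraction: dict[str, float] = dataclasses.field(default_factory=dict)
    dropout_fraction: dict[str, float] = dataclasses.field(default_factory=dict)
    introgressed_columns: set[int] = dataclasses.field(default_factory=set)

    def expected_indel_matrix(self, ref: ReferenceIndex, taxa: Sequence[str]) -> IndelMatrix:
        """The IndelMatrix a perfect (dropout-free) builder must recover.

        Independent of the builder: constructed purely from the event
        bookkeeping, with deletions sorted by coordinate followed by
        insertions sorted by (position, sequence).
        """
        dels = sorted(
            [e for e in self.indel_events if e.kind == "del"], key=lambda e: (e.start, e.end)
        )
        inss = sorted(
            [e for e in self.indel_events if e.kind == "ins"], key=lambda e: (e.start, e.seq)
        )
        events: list[IndelEvent] = []
        for e in dels:
            contig, local = ref.contig_of(e.start)
            events.append(IndelEvent(contig, local, local + (e.end - e.start), "del"))
        for e in inss:
            contig, local = ref.contig_of(e.start)
            events.append(IndelEvent(contig, local, local, "ins", e.seq))
        states = np.zeros((len(taxa), len(events)), dtype=np.int8)
        for j, e in enumerate(dels + inss):
            for i, t in enumerate(taxa):
                states[i, j] = 1 if t in e.clade else 0
        return IndelMatrix(taxa=list(taxa), events=events, states=states)


@dataclasses.dataclass
class SimDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    params: SimParams
    ref_index: ReferenceIndex
    ref_records: list[tuple[str, str]]
    tree: dendropy.Tree
    alignment: CaptureAlignment  # the true alignment (post-introgression)
    truth: SimTruth
    samples: list[SampleConsensus]


# ---------------------------------------------------------------------------
# Reference and tree


def simulate_reference(params: SimParams, rng: np.random.Generator) -> tuple[ReferenceIndex, list[tuple[str, str]]]:
    """Random contigs of i.i.d. uniform bases summing to ``total_ref_len``."""
    k, total = params.n_contigs, params.total_ref_len
    if total < k * 200:
        raise ValueError("total_ref_len must allow >= 200 bp per contig")
    extra = rng.multinomial(total - 200 * k, np.full(k, 1.0 / k))
    lengths = (200 + extra).tolist()
    records = []
    for i, L in enumerate(lengths):
        seq = decode_seq(BASES[rng.integers(0, 4, size=L)])
        records.append((f"contig{i + 1:02d}", seq))
    return ReferenceIndex.from_records(records), records


def random_tree(
    n_taxa: int, rng: np.random.Generator, mean_branch_len: float = 0.005, ref_taxon: str = "REF"
) -> str:
    """Random binary tree newick over T01..Tnn plus a zero-length reference leaf.

    Branch lengths are mean_branch_len x (0.2 + Exp(0.8)): exponential-ish
    but floored at 20% of the mean so no branch is effectively invisible.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa besides the reference")

    def draw():
        return mean_branch_len * (0.2 + rng.exponential(0.8))

    nodes = [f"T{i + 1:02d}" for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b1 = draw()
        b2 = draw()
        merged = f"({nodes[i]}:{b1:.8f},{nodes[j]}:{b2:.8f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({ref_taxon}:0.0,{nodes[0]}:{draw():.8f});"


def _clade_key(leaves: Sequence[str]) -> str:
    return "|".join(sorted(leaves))


# ---------------------------------------------------------------------------
# Sequence evolution


def evolve_alignment(
    ref_index: ReferenceIndex,
    ref_records: Sequence[tuple[str, str]],
    tree: dendropy.Tree,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[CaptureAlignment, SimTruth]:
    """Evolve leaf sequences from the reference along the tree.

    Substitutions are Poisson per branch (mean = branch length x sites);
    indels are Poisson with rate ``indel_rate`` per expected substitution
    and geometric lengths.  Event footprints are globally disjoint with a
    1 bp buffer, so truth bookkeeping and simple indel coding are exact.
    """
    R = ref_index.total_length
    root_seq = np.concatenate([np.frombuffer(s.encode(), dtype=np.uint8) for _, s in ref_records])
    assert root_seq.size == R
    bounds = ref_index.contig_bounds()
    contig_of_pos = np.empty(R, dtype=np.int64)
    for ci, (lo, hi) in enumerate(bounds):
        contig_of_pos[lo:hi] = ci

    blocked = np.zeros(R + 1, dtype=bool)  # footprints + 1bp buffers
    ins_positions: set[int] = set()
    events: list[TrueIndel] = []
    branch_subs: dict[str, int] = {}

    # deterministic traversal order
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        edges.append((node, leaves, node.edge.length or 0.0))

    # phase 1: place indel events
    edge_events: dict[int, list[TrueIndel]] = {}
    for ei, (node, leaves, bl) in enumerate(edges):
        lam = params.indel_rate * bl * R
        n_ev = rng.poisson(lam) if lam > 0 else 0
        placed = []
        for _ in range(n_ev):
            kind = "del" if rng.random() < 0.5 else "ins"
            length = int(rng.geometric(min(1.0, 1.0 / params.indel_len_mean)))
            for _attempt in range(200):
                if kind == "del":
                    a = int(rng.integers(0, R - length + 1))
                    b = a + length
                    if contig_of_pos[a] != contig_of_pos[b - 1]:
                        continue
                    if blocked[max(a - 1, 0) : min(b + 1, R)].any():
                        continue
                    blocked[max(a - 1, 0) : min(b + 1, R)] = True
                    ev = TrueIndel("del", a, b, "", leaves)
                else:
                    p = int(rng.integers(1, R))  # strictly inside the concatenation
                    if contig_of_pos[p - 1] != contig_of_pos[p]:
                        continue
                    if p in ins_positions or blocked[p - 1 : p + 1].any():
                        continue
                    blocked[p - 1 : p + 1] = True
                    ins_positions.add(p)
                    seq = decode_seq(BASES[rng.integers(0, 4, size=length)])
                    ev = TrueIndel("ins", p, p, seq, leaves)
                placed.append(ev)
                events.append(ev)
                break
        edge_events[ei] = placed

    # phase 2: substitutions + application of events down the tree
    node_seq: dict[int, np.ndarray] = {id(tree.seed_node): root_seq.copy()}
    node_ins: dict[int, frozenset[int]] = {id(tree.seed_node): frozenset()}
    ev_index = {ev: i for i, ev in enumerate(events)}
    for ei, (node, leaves, bl) in enumerate(edges):
        parent = node.parent_node
        seq = node_seq[id(parent)].copy()
        carried = set(node_ins[id(parent)])
        for ev in edge_events[ei]:
            if ev.kind == "del":
                seq[ev.start : ev.end] = GAP
            else:
                carried.add(ev_index[ev])
        n_sub = rng.poisson(bl * R) if bl > 0 else 0
        applied = 0
        for _ in range(n_sub):
            for _attempt in range(100):
                pos = int(rng.integers(0, R))
                old = seq[pos]
                if old == GAP:
                    continue
                seq[pos] = _draw_new_base(old, params, rng)
                applied += 1
                break
        branch_subs[_clade_key(leaves)] = branch_subs.get(_clade_key(leaves), 0) + applied
        node_seq[id(node)] = seq
        node_ins[id(node)] = frozenset(carried)

    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    leaf_nodes = {l.taxon.label: l for l in tree.leaf_node_iter()}
    # root-to-tip path length per leaf
    divergence = {}
    for lab in leaves:
        d, node = 0.0, leaf_nodes[lab]
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        divergence[lab] = d

    aln = _assemble_true_alignment(ref_index, leaves, node_seq, node_ins, leaf_nodes, events)
    truth = SimTruth(
        tree=tree.as_string(schema="newick").strip(),
        taxa=leaves,
        indel_events=events,
        branch_subs=branch_subs,
        divergence=divergence,
    )
    return aln, truth


_TRANSITION = {A: ord("G"), ord("G"): A, ord("C"): ord("T"), ord("T"): ord("C")}


def _draw_new_base(old: int, params: SimParams, rng: np.random.Generator) -> int:
    others = BASES[BASES != old]
    if params.subst_model == "JC":
        return int(others[rng.integers(0, 3)])
    # HKY: the transition partner (A<->G, C<->T) is kappa-fold more likely
    w = np.array([params.hky_kappa if int(b) == _TRANSITION[int(old)] else 1.0 for b in others])
    return int(rng.choice(others, p=w / w.sum()))


def _assemble_true_alignment(ref_index, leaves, node_seq, node_ins, leaf_nodes, events):
    R = ref_index.total_length
    ins_events = sorted(
        [(e.start, e.seq, i) for i, e in enumerate(events) if e.kind == "ins"],
        key=lambda t: (t[0], t[1]),
    )
    ins_lens = [len(seq) for _, seq, _ in ins_events]
    n_cols = R + sum(ins_lens)
    col_ref = np.full(n_cols, -1, dtype=np.int64)
    col_ins = np.full(n_cols, -1, dtype=np.int64)
    col_map = np.empty(R, dtype=np.int64)
    cursor, it = 0, 0
    ins_col_start = []
    for pos in range(R + 1):
        while it < len(ins_events) and ins_events[it][0] == pos:
            ins_col_start.append(cursor)
            L = ins_lens[it]
            col_ins[cursor : cursor + L] = it
            cursor += L
            it += 1
        if pos < R:
            col_map[pos] = cursor
            col_ref[cursor] = pos
            cursor += 1
    matrix = np.full((len(leaves), n_cols), GAP, dtype=np.uint8)
    from .core_io import encode_seq

    for i, lab in enumerate(leaves):
        node = leaf_nodes[lab]
        matrix[i, col_map] = node_seq[id(node)]
        carried = node_ins[id(node)]
        for j, (pos, seq, ev_i) in enumerate(ins_events):
            if ev_i in carried:
                c0 = ins_col_start[j]
                matrix[i, c0 : c0 + len(seq)] = encode_seq(seq)
    return CaptureAlignment(
        taxa=list(leaves),
        matrix=matrix,
        ref=ref_index,
        col_ref=col_ref,
        col_insertion=col_ins,
        insertion_keys=[(p, s) for p, s, _ in ins_events],
    )


# ---------------------------------------------------------------------------
# Capture mask


def apply_capture_mask(
    aln: CaptureAlignment,
    truth: SimTruth,
    params: SimParams,
    rng: np.random.Generator,
) -> list[SampleConsensus]:
    """Derive per-sample consensus calls + simulated coverage from the truth.

    Coverage follows a two-state regional process: captured windows with
    shifted negative-binomial depth (never below ``captured_min_depth``)
    and dropout windows with mean depth ~2, both with geometric lengths.
    The dropout state fraction is ``dropout_base + dropout_slope x
    root-to-tip divergence``.
    """
    R = aln.ref.total_length
    anchored = aln.col_ref >= 0
    ref_cols = np.empty(R, dtype=np.int64)
    ref_cols[aln.col_ref[anchored]] = np.nonzero(anchored)[0]
    ins_by_leaf: dict[str, list[tuple[int, str]]] = {t: [] for t in aln.taxa}
    for e in truth.indel_events:
        if e.kind == "ins":
            for t in e.clade:
                if t in ins_by_leaf:
                    ins_by_leaf[t].append((e.start, e.seq))

    out = []
    for i, taxon in enumerate(aln.taxa):
        div = truth.divergence.get(taxon, 0.0)
        p_drop = float(np.clip(params.dropout_base + params.dropout_slope * div, 0.0, 1.0))
        coverage = _simulate_coverage(R, p_drop, params, rng)
        calls = aln.matrix[i, ref_cols].copy()
        insertions = [
            (p, seq, int(coverage[min(p, R - 1)])) for p, seq in sorted(ins_by_leaf[taxon])
        ]
        out.append(SampleConsensus(taxon, calls, coverage, insertions))
        truth.dropout_fraction[taxon] = p_drop
        truth.masked_fraction[taxon] = float(
            np.count_nonzero(coverage < params.captured_min_depth) / R
        )
    return out


def _simulate_coverage(R: int, p_drop: float, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    cov = np.empty(R, dtype=np.int64)
    nb_n = params.nb_size
    cap_mean = max(params.captured_mean_depth - params.captured_min_depth, 1.0)
    nb_p = nb_n / (nb_n + cap_mean)
    drop_p = 1.0 / (1.0 + params.dropout_mean_depth)
    if p_drop <= 0.0:
        return params.captured_min_depth + rng.negative_binomial(nb_n, nb_p, size=R)
    if p_drop >= 1.0:
        return rng.negative_binomial(1, drop_p, size=R)
    mean_drop_len = params.dropout_window_mean
    mean_cap_len = mean_drop_len * (1.0 - p_drop) / p_drop
    pos = 0
    state_drop = rng.random() < p_drop
    while pos < R:
        mean_len = mean_drop_len if state_drop else mean_cap_len
        seg = int(rng.geometric(min(1.0, 1.0 / mean_len)))
        seg = min(seg, R - pos)
        if state_drop:
            cov[pos : pos + seg] = rng.negative_binomial(1, drop_p, size=seg)
        else:
            cov[pos : pos + seg] = params.captured_min_depth + rng.negative_binomial(
                nb_n, nb_p, size=seg
            )
        pos += seg
        state_drop = not state_drop
    return cov


# ---------------------------------------------------------------------------
# Introgression


def inject_introgression(
    aln: CaptureAlignment,
    truth: SimTruth,
    events: Sequence[tuple[Sequence[str], Sequence[str], float]],
    rng: np.random.Generator,
) -> CaptureAlignment:
    """Overwrite a random fraction of variable columns in the recipient
    clade with the donor-clade plurality state; modifies a copy.

    Eligible columns are those variable (>= 2 distinct determinate
    states) among donor + recipient members; each is transferred
    independently with probability ``f``.  Transferred column indices are
    recorded in ``truth.introgressed_columns``.
    """
    matrix = aln.matrix.copy()
    for donor, recipient, f in events:
        donor, recipient = list(donor), list(recipient)
        if set(donor) & set(recipient):
            raise ValueError("donor and recipient clades must be disjoint")
        d_idx = [aln.taxa.index(t) for t in donor]
        r_idx = [aln.taxa.index(t) for t in recipient]
        sub = matrix[d_idx + r_idx]
        det = sub != MISSING
        n_states = np.zeros(sub.shape[1], dtype=np.int64)
        seen = np.zeros(sub.shape[1], dtype=bool)
        for code in np.unique(sub):
            if code == MISSING:
                continue
            present = ((sub == code) & det).any(axis=0)
            n_states += present
        eligible = n_states >= 2
        cons, cons_ok = _plurality(matrix[d_idx])
        chosen = eligible & cons_ok & (rng.random(sub.shape[1]) < f)
        idx = np.nonzero(chosen)[0]
        for r in r_idx:
            matrix[r, idx] = cons[idx]
        truth.introgressed_columns.update(int(j) for j in idx)
    return dataclasses.replace(aln, matrix=matrix)


def _plurality(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise plurality state over determinate rows; flag ties/all-missing."""
    codes = np.array([c for c in np.unique(rows) if c != MISSING], dtype=np.uint8)
    if codes.size == 0:
        n = rows.shape[1]
        return np.full(n, MISSING, dtype=np.uint8), np.zeros(n, dtype=bool)
    counts = np.stack([(rows == c).sum(axis=0) for c in codes])
    best = counts.max(axis=0)
    n_best = (counts == best).sum(axis=0)
    winner = codes[counts.argmax(axis=0)]
    ok = (best > 0) & (n_best == 1)
    winner = np.where(ok, winner, MISSING).astype(np.uint8)
    return winner, ok


# ---------------------------------------------------------------------------
# Orchestration


def simulate_dataset(params: SimParams) -> SimDataset:
    """Run the full generator pipeline under one seeded RNG stream."""
    rng = np.random.default_rng(params.rng_seed)
    ref_index, ref_records = simulate_reference(params, rng)
    newick = params.tree or random_tree(params.n_taxa, rng, params.mean_branch_len, params.ref_taxon)
    tree = parse_newick(newick)
    aln, truth = evolve_alignment(ref_index, ref_records, tree, params, rng)
    if params.introgression_events:
        aln = inject_introgression(aln, truth, params.introgression_events, rng)
    samples = apply_capture_mask(aln, truth, params, rng)
    return SimDataset(params, ref_index, ref_records, tree, aln, truth, samples)


def truth_to_json(truth: SimTruth) -> str:
    return json.dumps(
        {
            "tree": truth.tree,
            "taxa": truth.taxa,
            "indel_events": [
                {"kind": e.kind, "start": e.start, "end": e.end, "seq": e.seq, "clade": sorted(e.clade)}
                for e in truth.indel_events
            ],
            "branch_subs": truth.branch_subs,
            "divergence": truth.divergence,
            "masked_fraction": truth.masked_fraction,
            "dropout_fraction": truth.dropout_fraction,
            "introgressed_columns": sorted(truth.introgressed_columns),
        },
        indent=2,
    )
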