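import itertools
import math

import numpy as np
import pytest

from mitocapture import phylogeny as P
from mitocapture import simdata
from mitocapture.alignment import CaptureAlignment, IndelEvent, IndelMatrix
from mitocapture.core_io import parse_newick


def aln_from(rows):
    return CaptureAlignment.from_records(list(rows.items()))


# ---------------------------------------------------------------------------
# Independent oracles


def all_unrooted_topologies(labels):
    """Enumerate all unrooted binary topologies as nested-tuple structures."""
    if len(labels) == 3:
        return [tuple(labels)]
    trees = []
    for sub in all_unrooted_topologies(labels[:-1]):
        trees.extend(_insert_everywhere(sub, labels[-1], top=True))
    return trees


def _insert_everywhere(tree, leaf, top=False):
    out = []
    if isinstance(tree, tuple):
        kids = list(tree)
        for i, kid in enumerate(kids):
            for alt in _insert_everywhere(kid, leaf):
                out.append(tuple(kids[:i] + [alt] + kids[i + 1 :]))
        if not top:
            out.append((tree, leaf))
    else:
        if not top:
            out.append((tree, leaf))
    return out


def naive_fitch(tree, column):
    """Set-based Fitch oracle on a nested-tuple tree; returns (steps, states)."""
    if not isinstance(tree, tuple):
        ch = column[tree]
        return 0, (set("ACGT") if ch in "-?" else {ch})
    steps = 0
    acc = None
    for kid in tree:
        s, states = naive_fitch(kid, column)
        steps += s
        if acc is None:
            acc = states
        else:
            inter = acc & states
            if inter:
                acc = inter
            else:
                acc = acc | states
                steps += 1
    return steps, acc


def tuple_to_newick(tree):
    if not isinstance(tree, tuple):
        return tree
    return "(" + ",".join(tuple_to_newick(k) for k in tree) + ")"


class TestJCDistance:
    def test_identical(self):
        aln = aln_from({"a": "ACGT" * 10, "b": "ACGT" * 10})
        assert P.jc_distance(aln, "a", "b") == 0.0

    def test_closed_form(self):
        # 45.7 mismatches per 1000 sites
        seq_a = "A" * 1000
        seq_b = "C" * 46 + "A" * 954
        aln = aln_from({"a": seq_a, "b": seq_b})
        p = 46 / 1000
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert P.jc_distance(aln, "a", "b") == pytest.approx(expected, rel=1e-12)

    def test_saturation_capped(self):
        seq_a = "A" * 100
        seq_b = "C" * 75 + "A" * 25
        aln = aln_from({"a": seq_a, "b": seq_b})
        assert P.jc_distance(aln, "a", "b") == P.JC_SATURATION_CAP
        D = P.jc_matrix(aln)
        assert D.saturated[0, 1]

    def test_no_comparable_columns_rejected(self):
        aln = aln_from({"a": "AC??", "b": "??GT"})
        with pytest.raises(ValueError):
            P.jc_distance(aln, "a", "b")

    def test_pairwise_deletion(self):
        aln = aln_from({"a": "ACGT????", "b": "ACTT????"})
        p, n = P.jc_p_distance(aln.row("a"), aln.row("b"))
        assert (p, n) == (0.25, 4)


class TestNeighborJoining:
    def test_four_taxon_additive_split(self):
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        tree = P.neighbor_joining(P.DistanceMatrix.from_square(taxa, d))
        splits = P.tree_bipartitions(tree, taxa)
        assert splits == frozenset({0b1100})  # C,D vs A,B

    def test_three_taxa_closed_form(self):
        taxa = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = P.neighbor_joining(P.DistanceMatrix.from_square(taxa, d))
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        # a = (dAB + dAC - dBC)/2 etc.
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = int(rng.integers(5, 9))
            newick = simdata.random_tree(n, rng, mean_branch_len=1.0, ref_taxon="Z")
            true = parse_newick(newick)
            taxa = sorted(l.taxon.label for l in true.leaf_node_iter())
            pdm = true.phylogenetic_distance_matrix()
            d = np.zeros((len(taxa), len(taxa)))
            for i, a in enumerate(taxa):
                for j, b in enumerate(taxa):
                    if i < j:
                        t1 = true.taxon_namespace.get_taxon(a)
                        t2 = true.taxon_namespace.get_taxon(b)
                        d[i, j] = d[j, i] = pdm.distance(t1, t2)
            nj = P.neighbor_joining(P.DistanceMatrix.from_square(taxa, d))
            assert P.rf_distance(nj, true) == 0

    def test_nonfinite_rejected(self):
        d = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            P.neighbor_joining(P.DistanceMatrix.from_square(["a", "b", "c"], d))


class TestFitchScore:
    def test_one_step(self):
        aln = aln_from({"A1": "A", "A2": "A", "C1": "C", "C2": "C"})
        tree = parse_newick("((A1,A2),(C1,C2));")
        assert P.fitch_score(tree, aln) == 1

    def test_two_steps(self):
        aln = aln_from({"A1": "A", "A2": "A", "C1": "C", "C2": "C"})
        tree = parse_newick("((A1,C1),(A2,C2));")
        assert P.fitch_score(tree, aln) == 2

    def test_missing_is_free(self):
        aln = aln_from({"A1": "A", "A2": "?", "C1": "-", "C2": "C"})
        tree = parse_newick("((A1,A2),(C1,C2));")
        assert P.fitch_score(tree, aln) == 1

    def test_indel_events_add_steps(self):
        aln = aln_from({"a": "A", "b": "A", "c": "A", "d": "A"})
        m = IndelMatrix(
            taxa=["a", "b", "c", "d"],
            events=[IndelEvent("c", 0, 2, "del")],
            states=np.array([[1], [1], [0], [0]], dtype=np.int8),
        )
        tree = parse_newick("((a,b),(c,d));")
        assert P.fitch_score(tree, aln, m) == 1

    def test_rerooting_invariance(self):
        rng = np.random.default_rng(1)
        rows = {
            t: "".join(rng.choice(list("ACGT"), size=30)) for t in "abcdef"
        }
        aln = aln_from(rows)
        t1 = parse_newick("((a,b),((c,d),(e,f)));")
        t2 = parse_newick("((((a,b),(c,d)),e),f);")  # same unrooted topology? no
        t2 = parse_newick("(((a,b),(c,d)),(e,f));")
        assert P.fitch_score(t1, aln) == P.fitch_score(t2, aln)

    def test_leaf_absent_rejected(self):
        aln = aln_from({"a": "A", "b": "C", "c": "G", "d": "T"})
        tree = parse_newick("((a,b),(c,zzz));")
        with pytest.raises(ValueError):
            P.fitch_score(tree, aln)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("abcdef")
        rows = {t: "".join(rng.choice(list("ACGT?"), size=40, p=[0.23] * 4 + [0.08])) for t in labels}
        aln = aln_from(rows)
        topologies = all_unrooted_topologies(labels)
        assert len(topologies) == 105
        best_naive, best_tuple = None, None
        for topo in topologies:
            score = sum(
                naive_fitch(topo, {t: rows[t][i] for t in labels})[0]
                for i in range(40)
            )
            if best_naive is None or score < best_naive:
                best_naive, best_tuple = score, topo
        tree = parse_newick(tuple_to_newick(best_tuple) + ";")
        assert P.fitch_score(tree, aln) == best_naive
        # and the package's own search attains the same optimum
        res = P.mp_search(aln, None, n_starts=5, seed=seed)
        assert res.score == best_naive


class TestMPSearch:
    def test_four_taxa_exhaustive(self):
        rng = np.random.default_rng(2)
        labels = list("abcd")
        rows = {t: "".join(rng.choice(list("ACGT"), size=30)) for t in labels}
        aln = aln_from(rows)
        scores = []
        for topo in all_unrooted_topologies(labels):
            s = sum(
                naive_fitch(topo, {t: rows[t][i] for t in labels})[0] for i in range(30)
            )
            scores.append(s)
        res = P.mp_search(aln, None, n_starts=3, seed=0)
        assert res.score == min(scores)

    def test_more_starts_never_worse(self):
        ds = simdata.simulate_dataset(
            simdata.SimParams(n_contigs=1, total_ref_len=2000, n_taxa=7,
                              rng_seed=3, dropout_base=0.0, indel_rate=0.0)
        )
        s1 = P.mp_search(ds.alignment, None, n_starts=1, seed=5).score
        s10 = P.mp_search(ds.alignment, None, n_starts=10, seed=5).score
        assert s10 <= s1

    def test_strong_signal_recovers_truth(self):
        ds = simdata.simulate_dataset(
            simdata.SimParams(n_contigs=1, total_ref_len=20_000, n_taxa=8,
                              rng_seed=4, dropout_base=0.0, indel_rate=0.0,
                              mean_branch_len=0.02)
        )
        res = P.mp_search(ds.alignment, None, n_starts=5, seed=0)
        assert P.rf_distance(res.tree, parse_newick(ds.truth.tree)) == 0

    def test_too_few_taxa_rejected(self):
        aln = aln_from({"a": "A", "b": "C", "c": "G"})
        with pytest.raises(ValueError):
            P.mp_search(aln)


class TestBootstrap:
    def _dataset(self):
        return simdata.simulate_dataset(
            simdata.SimParams(n_contigs=1, total_ref_len=5000, n_taxa=6,
                              rng_seed=6, dropout_base=0.0, indel_rate=0.2,
                              mean_branch_len=0.02)
        )

    def test_b1_supports_binary(self):
        ds = self._dataset()
        _, sup = P.bootstrap(ds.alignment, None, B=1, method="nj", seed=0)
        assert set(sup.values()) <= {0.0, 100.0}

    def test_identical_sequences_unsupported(self):
        aln = aln_from({t: "ACGT" * 25 for t in "abcde"})
        _, sup = P.bootstrap(aln, None, B=20, method="nj", seed=0)
        assert all(v <= 50 for v in sup.values()) or not sup

    def test_strong_clade_support_high(self):
        ds = self._dataset()
        tree, sup = P.bootstrap(ds.alignment, None, B=30, method="nj", seed=1)
        assert np.mean(list(sup.values())) > 90

    def test_fixed_seed_reproducible(self):
        ds = self._dataset()
        t1, s1 = P.bootstrap(ds.alignment, None, B=10, method="mp", seed=7)
        t2, s2 = P.bootstrap(ds.alignment, None, B=10, method="mp", seed=7)
        assert s1 == s2
        assert P.rf_distance(t1, t2) == 0


class TestConsensusAndSplits:
    def test_strict_consensus_collapses_conflict(self):
        t1 = parse_newick("((a,b),(c,d),(e,f));")
        t2 = parse_newick("((a,c),(b,d),(e,f));")
        cons = P.strict_consensus([t1, t2])
        splits = P.tree_bipartitions(cons, sorted("abcdef"))
        assert splits == frozenset({sum(1 << sorted("abcdef").index(x) for x in "ef")})

    def test_rf_distance_requires_same_leaves(self):
        with pytest.raises(ValueError):
            P.rf_distance(parse_newick("((a,b),(c,d));"), parse_newick("((a,b),(c,e));"))

    def test_rf_zero_same_topology(self):
        t1 = parse_newick("((a,b),(c,(d,e)));")
        t2 = parse_newick("(((d,e),c),(a,b));")
        assert P.rf_distance(t1, t2) == 0
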