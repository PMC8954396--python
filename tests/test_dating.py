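import math

import numpy as np
import pytest
from scipy.special import gammaln

from mitocapture import dating as D
from mitocapture.core_io import parse_newick


def clades(tree):
    return {
        frozenset(l.taxon.label for l in n.leaf_iter())
        for n in tree.preorder_node_iter()
    }


class TestCalibration:
    def test_order_validated(self):
        with pytest.raises(ValueError):
            D.Calibration(("a", "b"), 10.0, 5.0)
        with pytest.raises(ValueError):
            D.Calibration(("a", "b"), 0.0, 5.0)

    def test_yaml_loader(self, tmp_path):
        p = tmp_path / "cal.yaml"
        p.write_text("- {leaves: [a, b], min: 1.5, max: 4}\n")
        cals = D.load_calibrations(p)
        assert cals == [D.Calibration(("a", "b"), 1.5, 4.0)]

    def test_non_monophyletic_clade_rejected(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="monophyletic"):
            D.date_tree(tree, [D.Calibration(("a", "b", "c"), 1.0, 2.0)])

    def test_infeasible_box_rejected(self):
        tree = parse_newick("((a:1,b:1):1,c:2);")
        cals = [
            D.Calibration(("a", "b"), 5.0, 10.0),  # child clade older than root max
            D.Calibration(("a", "b", "c"), 1.0, 2.0),
        ]
        with pytest.raises(ValueError, match="infeasible"):
            D.date_tree(tree, cals)


class TestPLObjective:
    def _fit(self, lam=1.0):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        cal = [D.Calibration(("A", "B", "C"), 2.0, 2.0)]
        return tree, D.date_tree(tree, cal, smoothing=lam, n_sites=10_000)

    def test_clock_fit_zero_penalty(self):
        tree, ch = self._fit()
        rates = np.array(list(ch.rates.values()))
        assert np.allclose(rates, rates[0], rtol=1e-3)
        # score == pure Poisson term when rates are equal
        poisson = 0.0
        for bl, t in ((1.0, 1.0), (1.0, 1.0), (1.0, 1.0), (2.0, 2.0)):
            x = round(bl * 10_000)
            rt = rates[0] * 10_000 * t
            poisson -= x * math.log(rt) - rt - gammaln(x + 1)
        assert ch.score == pytest.approx(poisson, rel=1e-4)

    def test_lambda_zero_matches_closed_form(self):
        tree, ch = self._fit()
        score = D.pl_objective(tree, ch.ages, ch.rates, 0.0, 10_000)
        # independent evaluation of the Poisson sum
        expected = 0.0
        for leafset, rate in ch.rates.items():
            t_parent = ch.ages[
                min(
                    (ls for ls in ch.ages if leafset < ls),
                    key=len,
                )
            ]
            t = t_parent - ch.ages.get(leafset, 0.0)
            x = round((1.0 if len(leafset) < 3 and leafset != frozenset("C") else 2.0) * 10_000)
            if leafset == frozenset(["C"]):
                x = 20_000
            else:
                x = 10_000
            rt = rate * 10_000 * t
            expected -= x * math.log(rt) - rt - gammaln(x + 1)
        assert score == pytest.approx(expected, rel=1e-9)

    def test_penalty_monotone_in_lambda(self):
        tree = parse_newick("((A:0.5,B:1):1,C:2);")  # non-clock data
        ages, rates = None, None
        cal = [D.Calibration(("A", "B", "C"), 2.0, 2.0)]
        ch = D.date_tree(tree, cal, smoothing=1.0, n_sites=1000)
        s1 = D.pl_objective(tree, ch.ages, ch.rates, 1.0, 1000)
        s2 = D.pl_objective(tree, ch.ages, ch.rates, 2.0, 1000)
        s0 = D.pl_objective(tree, ch.ages, ch.rates, 0.0, 1000)
        assert s2 >= s1 >= s0  # doubling lambda never decreases the penalty

    def test_negative_duration_rejected(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        ages = {
            frozenset("ABC"): 1.0,
            frozenset(["A", "B"]): 2.0,  # child older than parent
            frozenset(["A"]): 0.0,
            frozenset(["B"]): 0.0,
            frozenset(["C"]): 0.0,
        }
        rates = {frozenset(s): 1.0 for s in (["A"], ["B"], ["C"], ["A", "B"])}
        with pytest.raises(ValueError):
            D.pl_objective(tree, ages, rates, 1.0, 1000)


class TestDateTree:
    def test_exact_clock_limit(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        cal = [D.Calibration(("A", "B", "C"), 2.0, 2.0)]
        ch = D.date_tree(tree, cal, smoothing=1.0, n_sites=10_000)
        assert ch.ages[frozenset("ABC")] == pytest.approx(2.0)
        assert ch.ages[frozenset(["A", "B"])] == pytest.approx(1.0, rel=1e-3)
        rates = list(ch.rates.values())
        assert np.allclose(rates, 1.0, rtol=1e-3)

    def test_active_min_constraint_pushes_age_to_bound(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        cal = [
            D.Calibration(("A", "B", "C"), 2.0, 2.0),
            D.Calibration(("A", "B"), 1.6, 2.0),  # above the unconstrained optimum 1.0
        ]
        ch = D.date_tree(tree, cal, smoothing=1.0, n_sites=10_000)
        assert ch.ages[frozenset(["A", "B"])] == pytest.approx(1.6, rel=1e-2)

    def test_rescaling_invariance(self):
        tree1 = parse_newick("((A:1,B:1):1,C:2);")
        tree2 = parse_newick("((A:2,B:2):2,C:4);")
        cal = [D.Calibration(("A", "B", "C"), 2.0, 2.0)]
        ch1 = D.date_tree(tree1, cal, smoothing=1.0, n_sites=10_000)
        ch2 = D.date_tree(tree2, cal, smoothing=1.0, n_sites=5_000)
        for k in ch1.ages:
            assert ch1.ages[k] == pytest.approx(ch2.ages[k], rel=1e-4, abs=1e-6)

    def test_parameter_recovery_under_clock(self):
        # clock simulation: known ages, rate r=0.01/My; root calibrated to truth
        rng = np.random.default_rng(0)
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            true_ages = {"ab": 2.0 + 2 * rng.random(), "abc": 6.0, "abcd": 10.0}
            r, L = 0.01, 100_000
            def bl(t):  # noisy Poisson branch length for duration t
                return rng.poisson(r * t * L) / L
            a = bl(true_ages["ab"]); b = bl(true_ages["ab"])
            ab = bl(true_ages["abc"] - true_ages["ab"]); c = bl(true_ages["abc"])
            abc = bl(true_ages["abcd"] - true_ages["abc"]); d = bl(true_ages["abcd"])
            nwk = f"(((A:{a},B:{b}):{ab},C:{c}):{abc},D:{d});"
            tree = parse_newick(nwk)
            cal = [D.Calibration(("A", "B", "C", "D"), 10.0, 10.0)]
            ch = D.date_tree(tree, cal, smoothing=10.0, n_sites=L)
            errs.append(abs(ch.ages[frozenset(["A", "B"])] - true_ages["ab"]) / true_ages["ab"])
            errs.append(abs(ch.ages[frozenset(["A", "B", "C"])] - true_ages["abc"]) / true_ages["abc"])
        assert np.median(errs) < 0.1

    def test_lambda_infinity_matches_strict_clock(self):
        tree = parse_newick("((A:0.8,B:1.2):1,C:2.2);")
        cal = [D.Calibration(("A", "B", "C"), 2.0, 2.0)]
        ch = D.date_tree(tree, cal, smoothing=1e7, n_sites=1000)
        rates = np.array(list(ch.rates.values()))
        assert rates.std() / rates.mean() < 0.01


class TestSelectLambda:
    def _clock_tree(self, seed=0, L=20_000, r=0.01):
        rng = np.random.default_rng(seed)
        def bl(t):
            return rng.poisson(r * t * L) / L
        nwk = (
            f"((((A:{bl(1)},B:{bl(1)}):{bl(1)},C:{bl(2)}):{bl(2)},"
            f"D:{bl(4)}):{bl(2)},E:{bl(6)});"
        )
        return parse_newick(nwk)

    def test_single_grid_value_returned(self):
        tree = self._clock_tree()
        cal = [D.Calibration(("A", "B", "C", "D", "E"), 6.0, 6.0)]
        lam, _ = D.select_lambda(tree, cal, grid=[7.5], n_sites=20_000)
        assert lam == 7.5

    def test_clock_data_prefers_large_lambda(self):
        cal = [D.Calibration(("A", "B", "C", "D", "E"), 6.0, 6.0)]
        grid = [0.1, 1000.0]
        wins = 0
        for seed in range(3):
            lam, errors = D.select_lambda(self._clock_tree(seed), cal, grid=grid, n_sites=20_000)
            if lam == 1000.0:
                wins += 1
        assert wins >= 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            D.select_lambda(self._clock_tree(), [], grid=[])


class TestBootstrapAges:
    def _setup(self):
        from mitocapture import simdata

        # clock tree: every branch 0.01 subs/site per unit time
        nwk = "((A:0.02,B:0.02):0.02,(C:0.02,D:0.02):0.02);"
        ds = simdata.simulate_dataset(
            simdata.SimParams(
                n_contigs=1, total_ref_len=30_000, tree=None, n_taxa=4,
                rng_seed=0, dropout_base=0.0, indel_rate=0.0,
            )
        )
        return ds

    def test_b1_interval_collapses(self):
        from mitocapture import simdata
        from mitocapture import alignment as A

        ds = self._setup()
        topo = parse_newick(ds.truth.tree)
        taxa = tuple(ds.alignment.taxa)
        cal = [D.Calibration(taxa, 10.0, 10.0)]
        out = D.bootstrap_ages(ds.alignment, None, topo, cal, B=1, seed=0)
        for s in out.values():
            assert s.lower == pytest.approx(s.mean)
            assert s.upper == pytest.approx(s.mean)

    def test_fixed_seed_reproducible(self):
        ds = self._setup()
        topo = parse_newick(ds.truth.tree)
        cal = [D.Calibration(tuple(ds.alignment.taxa), 10.0, 10.0)]
        o1 = D.bootstrap_ages(ds.alignment, None, topo, cal, B=5, seed=3)
        o2 = D.bootstrap_ages(ds.alignment, None, topo, cal, B=5, seed=3)
        assert {k: (v.mean, v.lower, v.upper) for k, v in o1.items()} == {
            k: (v.mean, v.lower, v.upper) for k, v in o2.items()
        }

    def test_clock_coverage(self):
        # true tree heights in time units: calibrate root to truth and check
        # the 95% intervals cover the true internal ages
        from mitocapture import simdata

        newick = "(REF:0.0,((T01:0.01,T02:0.01):0.01,(T03:0.01,T04:0.01):0.01):0.0);"
        covered, total = 0, 0
        for seed in range(3):
            ds = simdata.simulate_dataset(
                simdata.SimParams(
                    n_contigs=1, total_ref_len=50_000, tree=newick,
                    rng_seed=seed, dropout_base=0.0, indel_rate=0.0,
                )
            )
            topo = parse_newick(ds.truth.tree)
            taxa = tuple(ds.alignment.taxa)
            # time scale: r = 0.01 subs/site/My -> T01..T02 MRCA at 1 My, root at 2
            cal = [D.Calibration(taxa, 2.0, 2.0)]
            out = D.bootstrap_ages(ds.alignment, None, topo, cal, B=20, seed=seed)
            true_ages = {
                frozenset(["T01", "T02"]): 1.0,
                frozenset(["T03", "T04"]): 1.0,
                frozenset(["T01", "T02", "T03", "T04"]): 2.0,
            }
            for k, t in true_ages.items():
                if k in out:
                    total += 1
                    if out[k].lower - 0.15 <= t <= out[k].upper + 0.15:
                        covered += 1
        assert total > 0
        assert covered / total >= 0.8
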