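import numpy as np
import pandas as pd
import pytest

import plastedit as pe
from plastedit.core import ValidationError
from plastedit.gainloss import TreeIndex, _expected_transition_integrals

from _oracles import enumeration_fitch, enumeration_likelihood


def random_binary_matrix(labels, nsites, rng, missing_frac=0.0):
    m = pd.DataFrame(rng.integers(0, 2, (len(labels), nsites)).astype(float),
                     index=labels)
    if missing_frac:
        mask = rng.random(m.shape) < missing_frac
        m[mask] = np.nan
    return m


class TestLikelihood:
    def test_two_taxon_closed_form(self):
        """Pattern (1,0) on a symmetric 2-taxon tree, g=l=1, t=0.1:
        L = 0.5 * 2 * [((1+e^-0.2)/2) * ((1-e^-0.2)/2)]."""
        tree = pe.read_tree("(A:0.1,B:0.1);")
        m = pd.DataFrame({"s": [1, 0]}, index=["A", "B"])
        ll = pe.likelihood(m, tree, pe.GainLossModel(1.0, 1.0))
        expect = 0.5 * 2 * ((1 + np.exp(-0.2)) / 2) * ((1 - np.exp(-0.2)) / 2)
        assert np.exp(ll) == pytest.approx(expect, rel=1e-12)

    def test_zero_branch_limit_gives_root_prior(self):
        tree = pe.read_tree("(A:0.0,B:0.0);")
        model = pe.GainLossModel(0.7, 1.3)
        for state in (0, 1):
            m = pd.DataFrame({"s": [state, state]}, index=["A", "B"])
            ll = pe.likelihood(m, tree, model)
            assert np.exp(ll) == pytest.approx(model.prior()[state], rel=1e-12)

    @pytest.mark.parametrize("newick", [
        "(A:0.2,B:0.35);",
        "((A:0.13,B:0.21):0.1,C:0.3);",
        "((A:0.13,B:0.21):0.1,(C:0.3,D:0.08):0.2);",
        "(((A:0.1,B:0.2):0.05,C:0.3):0.1,(D:0.25,E:0.15):0.2);",
    ])
    def test_pruning_equals_enumeration(self, newick):
        """Pruning equals brute-force summation over all internal-state
        assignments, including with missing tips."""
        tree = pe.read_tree(newick)
        labels = [l.taxon.label for l in tree.leaf_nodes()]
        rng = np.random.default_rng(len(labels))
        m = random_binary_matrix(labels, 6, rng, missing_frac=0.15)
        for g, l in [(1.0, 1.0), (0.3, 2.0), (5.0, 0.4)]:
            model = pe.GainLossModel(g, l)
            assert pe.likelihood(m, tree, model) == pytest.approx(
                enumeration_likelihood(m, TreeIndex(tree), model), rel=1e-9
            )

    def test_rate_time_rescaling_invariance(self):
        tree1 = pe.read_tree("((A:0.1,B:0.2):0.05,C:0.3);")
        tree2 = pe.read_tree("((A:0.2,B:0.4):0.1,C:0.6);")
        m = pd.DataFrame({"s": [1, 0, 1], "t": [0, 0, 1]}, index=["A", "B", "C"])
        assert pe.likelihood(m, tree1, pe.GainLossModel(1.0, 0.8)) == pytest.approx(
            pe.likelihood(m, tree2, pe.GainLossModel(0.5, 0.4)), rel=1e-12
        )

    def test_missing_tip_never_decreases_site_likelihood(self):
        tree = pe.read_tree("((A:0.13,B:0.21):0.1,(C:0.3,D:0.08):0.2);")
        model = pe.GainLossModel(0.6, 1.1)
        rng = np.random.default_rng(3)
        m = random_binary_matrix(list("ABCD"), 5, rng)
        base = np.array([
            np.exp(pe.likelihood(m[[c]], tree, model)) for c in m.columns
        ])
        for tip in "ABCD":
            m2 = m.copy()
            m2.loc[tip] = np.nan
            relaxed = np.array([
                np.exp(pe.likelihood(m2[[c]], tree, model)) for c in m.columns
            ])
            assert (relaxed >= base - 1e-12).all()

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValidationError):
            pe.GainLossModel(0.0, 1.0)


class TestFit:
    def test_all_present_drives_loss_to_bound(self):
        tree = pe.default_tree()
        m = pd.DataFrame(1.0, index=[l.taxon.label for l in tree.leaf_nodes()],
                         columns=range(20))
        fit = pe.fit_rates(m, tree, bounds=(1e-3, 1e2))
        assert fit.loss == pytest.approx(1e-3, rel=1e-4)

    def test_recovers_simulated_rates(self):
        tree = pe.default_tree()
        m = pe.simulate_site_matrix(tree, 0.5, 1.0, 2000, seed=5)
        fit = pe.fit_rates(m, tree)
        assert abs(fit.gain - 0.5) / 0.5 < 0.2
        assert abs(fit.loss - 1.0) / 1.0 < 0.2


class TestExpectedEvents:
    def test_transition_integrals_match_quadrature(self):
        from scipy.integrate import quad

        g, l, t = 0.7, 1.3, 0.8
        lam = g + l
        pi = np.array([l / lam, g / lam])

        def P(a, b, s):
            return pi[b] + ((1.0 if a == b else 0.0) - pi[b]) * np.exp(-lam * s)

        E01, E10 = _expected_transition_integrals(g, l, t)
        for a in (0, 1):
            for b in (0, 1):
                num = quad(lambda s: P(a, 0, s) * g * P(1, b, t - s), 0, t)[0]
                assert E01[a, b] == pytest.approx(num / P(a, b, t), rel=1e-8)
                num = quad(lambda s: P(a, 1, s) * l * P(0, b, t - s), 0, t)[0]
                assert E10[a, b] == pytest.approx(num / P(a, b, t), rel=1e-8)

    def test_tiny_gain_rate_all_absent_no_gains(self):
        tree = pe.read_tree("((A:0.13,B:0.21):0.1,(C:0.3,D:0.08):0.2);")
        m = pd.DataFrame({"s": [0, 0, 0, 0]}, index=list("ABCD"))
        res = pe.expected_events(m, tree, pe.GainLossModel(1e-6, 1.0))
        assert res.total_gains < 1e-4

    def test_agrees_with_stochastic_mapping(self):
        """Analytic per-branch expectations match the exact conditional
        sampler within Monte-Carlo error (4-tip toy, m=10^4)."""
        tree = pe.read_tree("((A:0.13,B:0.21):0.1,(C:0.3,D:0.08):0.2);")
        pattern = {"A": 1, "B": 1, "C": 0, "D": 0}
        m = pd.DataFrame({"s": [pattern[x] for x in "ABCD"]}, index=list("ABCD"))
        model = pe.GainLossModel(0.5, 0.5)
        res = pe.expected_events(m, tree, model)
        sm = pe.stochastic_mapping(pattern, tree, model, m=10_000, seed=7)
        merged = res.branches.merge(sm, on="branch")
        for _, row in merged.iterrows():
            tol = 3 * np.sqrt(max(row["mean_gains"], 0.01) / 10_000) + 0.01
            assert abs(row["expected_gains"] - row["mean_gains"]) < tol
            tol = 3 * np.sqrt(max(row["mean_losses"], 0.01) / 10_000) + 0.01
            assert abs(row["expected_losses"] - row["mean_losses"]) < tol

    def test_expectation_dominates_parsimony(self):
        """Expected gains+losses per site >= Fitch minimal changes."""
        tree = pe.default_tree()
        m = pe.simulate_site_matrix(tree, 0.8, 0.8, 40, seed=6)
        model = pe.fit_rates(m, tree)
        changes, _ = pe.fitch_parsimony(m, tree)
        for j, col in enumerate(m.columns):
            res = pe.expected_events(m[[col]], tree, model)
            assert res.total_gains + res.total_losses >= changes[j] - 1e-6

    def test_dominant_event_on_split_branch(self):
        """Pattern (1,1,0,0) on ((A,B),(C,D)) concentrates the expected
        event where Fitch places the single change."""
        tree = pe.read_tree("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        m = pd.DataFrame({"s": [1, 1, 0, 0]}, index=list("ABCD"))
        res = pe.expected_events(m, tree, pe.GainLossModel(0.5, 0.5))
        b = res.branches.set_index("branch")
        ab_events = b.loc["A|B", "expected_gains"] + b.loc["A|B", "expected_losses"]
        cd_events = b.loc["C|D", "expected_gains"] + b.loc["C|D", "expected_losses"]
        others = res.total_gains + res.total_losses - ab_events - cd_events
        assert ab_events + cd_events > others


class TestFitch:
    def _tree4(self):
        return pe.read_tree("((A:1,B:1):1,(C:1,D:1):1);")

    def test_uniform_pattern_no_change(self):
        m = pd.DataFrame({"s": [1, 1, 1, 1]}, index=list("ABCD"))
        changes, totals = pe.fitch_parsimony(m, self._tree4())
        assert changes.tolist() == [0] and totals["changes"].sum() == 0

    @pytest.mark.parametrize("pattern,expect", [
        ((1, 1, 0, 0), 1),
        ((1, 0, 1, 0), 2),
        ((1, 0, 0, 0), 1),
        ((1, np.nan, 0, 0), 1),
    ])
    def test_matches_enumeration(self, pattern, expect):
        tree = self._tree4()
        m = pd.DataFrame({"s": list(pattern)}, index=list("ABCD"))
        changes, _ = pe.fitch_parsimony(m, tree)
        assert changes[0] == expect
        assert changes[0] == enumeration_fitch(dict(zip("ABCD", pattern)),
                                               TreeIndex(tree))

    def test_random_patterns_match_enumeration(self):
        tree = pe.read_tree("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        rng = np.random.default_rng(12)
        m = random_binary_matrix(list("ABCDE"), 16, rng, missing_frac=0.2)
        changes, _ = pe.fitch_parsimony(m, tree)
        ti = TreeIndex(tree)
        for j, col in enumerate(m.columns):
            assert changes[j] == enumeration_fitch(m[col].to_dict(), ti)
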