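import numpy as np
import pytest

from clonecn.deconvolution import DeconvolutionParams, Solution
from clonecn.model_selection import (
    ModelGrid,
    _hypothesis_n_star,
    classify_clusters,
    select_solution,
    summarize,
)


def fake_solution(D, n=2, k=1, wgd=False, A=None, B=None, U=None, lengths=None):
    class Hyp:
        pass

    hyp = Hyp()
    hyp.wgd = wgd
    m = 3 if A is None else A.shape[0]
    if A is None:
        A = np.ones((m, n), dtype=int)
        B = np.ones((m, n), dtype=int)
    if U is None:
        U = np.zeros((n, k))
        U[0] = 1.0
    if lengths is None:
        lengths = np.full(m, 1.0)
    return Solution(A, B, U, D, lengths, DeconvolutionParams(), hyp,
                    cluster_ids=list(range(m)),
                    samples=[f"S{p+1}" for p in range(k)])


class TestSelection:
    def test_elbow_rule_arithmetic(self):
        # D = {2: 100, 3: 99, 4: 98.5}: improvement 2->3 is 1% < 5% -> n*=2
        grid = ModelGrid()
        for n, d in {2: 100.0, 3: 99.0, 4: 98.5}.items():
            grid.solutions[("noWGD", n)] = fake_solution(d, n=n)
        assert _hypothesis_n_star(grid, "noWGD", 0.05, 1e-9) == 2
        sol = select_solution(grid, tau=0.05)
        assert sol.D == 100.0

    def test_deepest_n_when_elbow_never_triggers(self):
        grid = ModelGrid()
        for n, d in {2: 300.0, 3: 90.0, 4: 35.0}.items():
            grid.solutions[("noWGD", n)] = fake_solution(d, n=n)
        assert _hypothesis_n_star(grid, "noWGD", 0.05, 1e-9) == 4

    def test_wgd_infeasible_defaults_to_no_wgd(self):
        grid = ModelGrid()
        for n, d in {2: 100.0, 3: 10.0, 4: 9.9}.items():
            grid.solutions[("noWGD", n)] = fake_solution(d, n=n)
        sol = select_solution(grid)
        assert sol.hypothesis.wgd is False

    def test_wgd_wins_when_it_makes_the_genome_clonal(self):
        # diploid explanation leaves half the genome subclonal; the WGD
        # explanation is fully clonal with odd-copy states
        grid = ModelGrid()
        A_sub = np.array([[1, 2, 3], [1, 1, 1]])
        B_sub = np.array([[1, 1, 1], [1, 1, 1]])
        U3 = np.array([[0.4], [0.3], [0.3]])
        grid.solutions[("noWGD", 3)] = fake_solution(
            10.0, n=3, A=A_sub, B=B_sub, U=U3, lengths=np.array([1.0, 1.0]),
        )
        A_cl = np.array([[2, 5], [2, 2]])
        B_cl = np.array([[2, 2], [2, 2]])
        U2 = np.array([[0.4], [0.6]])
        sol_w = fake_solution(10.0, n=2, A=A_cl, B=B_cl, U=U2,
                              lengths=np.array([1.0, 1.0]), wgd=True)
        grid.solutions[("WGD", 2)] = sol_w
        assert select_solution(grid).hypothesis.wgd is True

    def test_all_even_wgd_solution_rejected_on_tie(self):
        # both explanations fully clonal; the WGD states are all even,
        # i.e. a doubled re-interpretation of the diploid solution
        grid = ModelGrid()
        A_no = np.array([[1, 2], [1, 1]])
        B_no = np.array([[1, 1], [1, 0]])
        U2 = np.array([[0.4], [0.6]])
        grid.solutions[("noWGD", 2)] = fake_solution(
            10.0, n=2, A=A_no, B=B_no, U=U2, lengths=np.array([1.0, 1.0]),
        )
        grid.solutions[("WGD", 2)] = fake_solution(
            10.0, n=2, A=2 * A_no, B=2 * B_no, U=U2,
            lengths=np.array([1.0, 1.0]), wgd=True,
        )
        assert select_solution(grid).hypothesis.wgd is False
        # odd states over enough genome flip the call
        A_odd = np.array([[2, 5], [2, 3]])
        B_odd = np.array([[2, 2], [2, 2]])
        grid.solutions[("WGD", 2)] = fake_solution(
            10.0, n=2, A=A_odd, B=B_odd, U=U2,
            lengths=np.array([1.0, 1.0]), wgd=True,
        )
        assert select_solution(grid).hypothesis.wgd is True

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_solution(ModelGrid())


class TestChooseHypothesis:
    def _pair(self, wgd, states, u1, lengths):
        from clonecn.fractional_scaling import (FractionalMatrixPair,
                                                ScalingHypothesis)

        u1 = np.asarray(u1, float)
        k = len(u1)
        FA = np.zeros((len(states), k))
        FB = np.zeros((len(states), k))
        for s, (a, b) in enumerate(states):
            f = 2 * u1 + (a + b) * (1 - u1)
            fb = u1 + b * (1 - u1)
            FA[s] = f - np.minimum(fb, f - fb)
            FB[s] = np.minimum(fb, f - fb)
        hyp = ScalingHypothesis(
            wgd=wgd, anchor1=0, omega1=4 if wgd else 2,
            gamma=np.ones(k), anchor2=1 if wgd else None,
            omega2=3 if wgd else None, u_normal=u1 if wgd else None,
        )
        return FractionalMatrixPair(FA, FB, hyp), np.array(lengths, float)

    def test_odd_scars_trigger_wgd(self):
        from clonecn.model_selection import choose_hypothesis

        # genuinely doubled genome: (2,2) baseline with odd-copy scars
        states = [(2, 2), (2, 1), (3, 2), (4, 2)]
        w_pair, lengths = self._pair(True, states, [0.4, 0.3], [50, 20, 15, 15])
        no_pair, _ = self._pair(False, [(1, 1)] * 4, [0.4, 0.3],
                                [50, 20, 15, 15])
        chosen = choose_hypothesis([no_pair, w_pair], lengths)
        assert chosen.hypothesis.wgd is True

    def test_all_even_doubling_rejected(self):
        from clonecn.model_selection import choose_hypothesis

        # a diploid tumor doubled: every state even
        states = [(2, 2), (2, 0), (4, 2), (2, 2)]
        w_pair, lengths = self._pair(True, states, [0.4, 0.3], [50, 20, 15, 15])
        no_pair, _ = self._pair(False, [(1, 1), (1, 0), (2, 1), (1, 1)],
                                [0.4, 0.3], [50, 20, 15, 15])
        chosen = choose_hypothesis([no_pair, w_pair], lengths)
        assert chosen.hypothesis.wgd is False

    def test_missing_wgd_candidate_defaults_to_diploid(self):
        from clonecn.model_selection import choose_hypothesis

        no_pair, lengths = self._pair(False, [(1, 1), (2, 1)], [0.5],
                                      [50, 50])
        chosen = choose_hypothesis([no_pair], lengths)
        assert chosen.hypothesis.wgd is False

    def test_clonal_explanation_recovers_purity(self):
        from clonecn.model_selection import clonal_explanation

        no_pair, lengths = self._pair(
            False, [(1, 1), (2, 1), (3, 1), (1, 0)], [0.35, 0.6],
            [50, 20, 20, 10],
        )
        explained, odd, u1 = clonal_explanation(no_pair, lengths)
        assert explained == pytest.approx(1.0)
        np.testing.assert_allclose(u1, [0.35, 0.6], atol=0.011)


class TestClassification:
    def test_two_clone_solution_all_clonal(self):
        rng = np.random.default_rng(0)
        from conftest import tree_truth

        A, B, U = tree_truth(6, 2, 2, rng)
        sol = fake_solution(0.0, n=2, k=2, A=A, B=B, U=U)
        cls = classify_clusters(sol)
        assert cls.sample_clonal.to_numpy().all()
        assert cls.tumor_clonal.all()

    def test_mixed_states_sample_subclonal(self):
        A = np.array([[1, 2, 3]])
        B = np.array([[1, 1, 1]])
        U = np.array([[0.2], [0.4], [0.4]])
        sol = fake_solution(0.0, A=A, B=B, U=U, lengths=np.array([1.0]))
        cls = classify_clusters(sol)
        assert not cls.sample_clonal.iloc[0, 0]
        assert not cls.tumor_clonal.iloc[0]

    def test_absent_clone_does_not_affect_sample_clonality(self):
        A = np.array([[1, 2, 3]])
        B = np.array([[1, 1, 1]])
        both = np.array([[0.2], [0.4], [0.4]])
        sol = fake_solution(0.0, A=A, B=B, U=both, lengths=np.array([1.0]))
        # both tumor states (2,1) and (3,1) present -> subclonal
        assert not classify_clusters(sol).sample_clonal.iloc[0, 0]
        # the deviant tumor clone absent from the sample -> clonal
        absent = np.array([[0.6], [0.4], [0.0]])
        sol2 = fake_solution(0.0, A=A, B=B, U=absent, lengths=np.array([1.0]))
        assert classify_clusters(sol2).sample_clonal.iloc[0, 0]

    def test_sample_subclonal_implies_tumor_subclonal(self):
        rng = np.random.default_rng(1)
        from conftest import tree_truth

        A, B, U = tree_truth(10, 3, 2, rng)
        sol = fake_solution(0.0, n=3, k=2, A=A, B=B, U=U)
        cls = classify_clusters(sol)
        subclonal_any = ~cls.sample_clonal.all(axis=1)
        assert (~cls.tumor_clonal[subclonal_any]).all()


class TestSummarize:
    def test_pure_normal_sample(self):
        A = np.ones((3, 2), dtype=int)
        B = np.ones((3, 2), dtype=int)
        U = np.array([[1.0], [0.0]])
        sol = fake_solution(0.0, n=2, k=1, A=A, B=B, U=U)
        rep = summarize(sol)
        assert rep["PURITY"].iloc[0] == 0.0
        assert rep["SUBCLONAL_FRACTION"].iloc[0] == 0.0

    def test_single_tumor_clone_purity(self):
        A = np.array([[1, 2], [1, 3]])
        B = np.array([[1, 1], [1, 0]])
        U = np.array([[0.3], [0.7]])
        sol = fake_solution(0.0, A=A, B=B, U=U, lengths=np.array([1.0, 1.0]))
        rep = summarize(sol)
        assert rep["PURITY"].iloc[0] == pytest.approx(0.7)
        assert rep["SUBCLONAL_FRACTION"].iloc[0] == 0.0

    def test_subclonal_fraction_length_accounting(self):
        # two clones differ on clusters covering 30% of the genome
        A = np.array([[1, 2, 2], [1, 2, 3], [1, 1, 1]])
        B = np.array([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
        U = np.array([[0.2, 0.2], [0.4, 0.4], [0.4, 0.4]])
        lengths = np.array([50.0, 30.0, 20.0])
        sol = fake_solution(0.0, n=3, k=2, A=A, B=B, U=U, lengths=lengths)
        rep = summarize(sol)
        assert rep["SUBCLONAL_FRACTION"].iloc[0] == pytest.approx(0.30)

    def test_ploidy_identity(self):
        rng = np.random.default_rng(2)
        from conftest import tree_truth

        A, B, U = tree_truth(8, 3, 2, rng)
        lengths = rng.uniform(1, 5, size=8)
        sol = fake_solution(0.0, n=3, k=2, A=A, B=B, U=U, lengths=lengths)
        rep = summarize(sol)
        L = lengths.sum()
        Li = sol.clone_genome_lengths
        for p in range(2):
            mu = sol.purity[p]
            if mu > 0:
                assert rep["PLOIDY"].iloc[p] * mu * L == pytest.approx(
                    float(U[1:, p] @ Li[1:])
                )
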