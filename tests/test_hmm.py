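import itertools

import numpy as np
import pytest

from dtmn import (
    DomainError,
    HMMParams,
    baum_welch,
    forward_backward,
    init_random,
    posterior_decode,
)
from dtmn.hmm import baum_welch_restarts, segmental_refine


def brute_force_posteriors(params, y):
    """Independent oracle: sum over all N^T hidden paths."""
    y0 = np.asarray(y) - 1
    N, T = params.N, len(y0)
    gamma = np.zeros((T, N))
    total = 0.0
    for path in itertools.product(range(N), repeat=T):
        p = params.pi[path[0]] * params.E[path[0], y0[0]]
        for t in range(1, T):
            p *= params.A[path[t - 1], path[t]] * params.E[path[t], y0[t]]
        total += p
        for t, j in enumerate(path):
            gamma[t, j] += p
    return gamma / total, np.log(total)


def random_params(rng, N, L):
    def rows(*shape):
        M = rng.uniform(0.05, 1.0, size=shape)
        return M / M.sum(axis=-1, keepdims=True)

    return HMMParams(pi=rows(N), A=rows(N, N), E=rows(N, L))


class TestInitRandom:
    def test_seed_determinism(self):
        a, b = init_random(80, 5, seed=0), init_random(80, 5, seed=0)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.E, b.E)
        np.testing.assert_array_equal(a.pi, b.pi)

    def test_single_state_is_degenerate(self):
        p = init_random(1, 5, seed=3)
        assert p.A.tolist() == [[1.0]]
        assert p.pi.tolist() == [1.0]
        assert abs(p.E.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("N,L", [(3, 5), (10, 2), (80, 5)])
    def test_rows_normalised(self, N, L):
        p = init_random(N, L, seed=7)
        for M in (p.pi[None, :], p.A, p.E):
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("N,L", [(0, 5), (2, 1)])
    def test_out_of_range_rejected(self, N, L):
        with pytest.raises(DomainError):
            init_random(N, L)


class TestForwardBackward:
    def test_single_state_closed_form(self):
        E = np.array([[0.1, 0.2, 0.3, 0.25, 0.15]])
        p = HMMParams(pi=[1.0], A=[[1.0]], E=E)
        y = [1, 3, 5, 2]
        r = forward_backward(p, y)
        np.testing.assert_allclose(r.gamma, 1.0)
        expected = sum(np.log(E[0, l - 1]) for l in y)
        assert abs(r.loglik - expected) < 1e-12

    def test_uniform_model_loglik(self):
        p = HMMParams(
            pi=[0.5, 0.5],
            A=np.full((2, 2), 0.5),
            E=np.full((2, 5), 0.2),
        )
        r = forward_backward(p, [1, 2, 3])
        assert abs(r.loglik - 3 * np.log(0.2)) < 1e-12

    def test_two_state_worked_example_matches_enumeration(self):
        p = HMMParams(
            pi=[0.6, 0.4],
            A=[[0.7, 0.3], [0.4, 0.6]],
            E=[[0.9, 0.1], [0.2, 0.8]],
        )
        y = [1, 2, 2, 1]
        g_ref, ll_ref = brute_force_posteriors(p, y)
        r = forward_backward(p, y)
        np.testing.assert_allclose(r.gamma, g_ref, atol=1e-10)
        assert abs(r.loglik - ll_ref) < 1e-10

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            N = int(rng.integers(1, 4))
            T = int(rng.integers(1, 7))
            p = random_params(rng, N, 5)
            y = rng.integers(1, 6, size=T)
            g_ref, ll_ref = brute_force_posteriors(p, y)
            r = forward_backward(p, y)
            np.testing.assert_allclose(r.gamma, g_ref, atol=1e-10)
            assert abs(r.loglik - ll_ref) < 1e-10

    def test_long_sequence_does_not_underflow(self):
        p = init_random(4, 5, seed=0)
        y = np.random.default_rng(0).integers(1, 6, size=1000)
        r = forward_backward(p, y)
        assert np.isfinite(r.loglik) and r.loglik < 0
        np.testing.assert_allclose(r.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(DomainError):
            forward_backward(init_random(2, 5, seed=0), [])

    def test_agrees_with_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(5)
        p = random_params(rng, 3, 5)
        y = rng.integers(1, 6, size=40)
        m = hmmlearn.CategoricalHMM(n_components=3)
        m.startprob_, m.transmat_, m.emissionprob_ = p.pi, p.A, p.E
        obs = (y - 1).reshape(-1, 1)
        r = forward_backward(p, y)
        assert abs(r.loglik - m.score(obs)) < 1e-8
        np.testing.assert_allclose(r.gamma, m.predict_proba(obs), atol=1e-8)


class TestBaumWelch:
    def test_single_state_emission_is_empirical_frequency(self):
        # 30% label 1, 70% label 2 -> E = (0.3, 0.7) after one M-step
        y = [1] * 3 + [2] * 7
        p0 = HMMParams(pi=[1.0], A=[[1.0]], E=[[0.5, 0.5]])
        fit, _ = baum_welch(p0, [y], max_iter=2)
        np.testing.assert_allclose(fit.E[0], [0.3, 0.7], atol=1e-12)

    def test_loglik_trace_nondecreasing_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            N = int(rng.integers(1, 5))
            p0 = random_params(rng, N, 4)
            data = [rng.integers(1, 5, size=int(rng.integers(2, 30)))
                    for _ in range(int(rng.integers(1, 4)))]
            _, trace = baum_welch(p0, data, max_iter=15)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_rows_stochastic_after_fit(self):
        rng = np.random.default_rng(2)
        p0 = random_params(rng, 4, 5)
        fit, _ = baum_welch(p0, [rng.integers(1, 6, size=100)], max_iter=10)
        for M in (fit.pi[None, :], fit.A, fit.E):
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_well_separated_transition_matrix(self):
        # simulate from a known 3-state HMM and recover A within TV 0.1/row
        rng = np.random.default_rng(0)
        A = np.array([[0.8, 0.1, 0.1], [0.15, 0.7, 0.15], [0.05, 0.15, 0.8]])
        E = np.array(
            [[0.9, 0.05, 0.05, 0.0, 0.0],
             [0.0, 0.05, 0.9, 0.05, 0.0],
             [0.0, 0.0, 0.05, 0.05, 0.9]]
        )
        pi = np.array([1 / 3, 1 / 3, 1 / 3])
        data = []
        for _ in range(20):
            q = rng.choice(3, p=pi)
            ys = []
            for _ in range(200):
                ys.append(rng.choice(5, p=E[q]) + 1)
                q = rng.choice(3, p=A[q])
            data.append(np.array(ys))
        fit, _ = baum_welch_restarts(data, 3, 5, n_restarts=5, seed=0,
                                     max_iter=200, tol=1e-6)
        # greedy state matching on emission rows
        perm = [int(np.argmin(np.abs(fit.E - E[i]).sum(axis=1))) for i in range(3)]
        assert len(set(perm)) == 3
        tv = 0.5 * np.abs(fit.A[perm][:, perm] - A).sum(axis=1)
        assert np.all(tv < 0.1)

    def test_invalid_label_rejected(self):
        with pytest.raises(DomainError):
            baum_welch(init_random(2, 3, seed=0), [[1, 4]], max_iter=1)


class TestPosteriorDecode:
    def test_single_state_path(self):
        p = HMMParams(pi=[1.0], A=[[1.0]], E=[[0.4, 0.6]])
        assert posterior_decode(p, [1, 2, 1]).tolist() == [1, 1, 1]

    def test_matches_brute_force_argmax(self):
        p = HMMParams(
            pi=[0.6, 0.4],
            A=[[0.7, 0.3], [0.4, 0.6]],
            E=[[0.9, 0.1], [0.2, 0.8]],
        )
        y = [1, 2, 2, 1]
        g_ref, _ = brute_force_posteriors(p, y)
        assert posterior_decode(p, y).tolist() == (np.argmax(g_ref, 1) + 1).tolist()

    def test_exact_tie_prefers_smaller_state(self):
        # two exchangeable states -> gamma rows exactly 0.5/0.5
        p = HMMParams(
            pi=[0.5, 0.5],
            A=np.full((2, 2), 0.5),
            E=[[0.3, 0.7], [0.3, 0.7]],
        )
        assert posterior_decode(p, [2, 1, 2]).tolist() == [1, 1, 1]


class TestSegmentalRefine:
    def test_rows_remain_stochastic_and_purity_not_reduced(self):
        rng = np.random.default_rng(4)
        # persistent labels so decode structure exists
        ys = []
        for _ in range(10):
            y = [int(rng.integers(1, 6))]
            for _ in range(99):
                y.append(y[-1] if rng.random() < 0.8 else int(rng.integers(1, 6)))
            ys.append(np.array(y))
        fit, _ = baum_welch(init_random(8, 5, seed=1), ys, max_iter=50)
        ref = segmental_refine(fit, ys)
        for M in (ref.pi[None, :], ref.A, ref.E):
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-9)

        def purity(params):
            cnt = np.zeros((8, 5))
            for y in ys:
                q = posterior_decode(params, y)
                np.add.at(cnt, (q - 1, y - 1), 1)
            return cnt.max(axis=1).sum() / cnt.sum()

        # refinement keeps the decoded states strongly label-informative
        assert purity(ref) >= 0.9
        assert purity(ref) >= purity(fit) - 0.05
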