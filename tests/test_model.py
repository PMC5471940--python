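import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actopics.corpus import Corpus, Document
from actopics.model import (
    Hyperparams,
    conditional_distribution,
    estimate_posterior,
    fit,
    gibbs_sweep,
    init_assignments,
    joint_log_prob,
)
from helpers import enumeration_conditional, tally_counts

HP2 = Hyperparams(K=2, alpha=0.7, beta=0.3, gamma=0.5, iterations=5, seed=7)


def tiny_instance():
    """D=2, K=2, A=2, J=2, V=3, 5 tokens: small enough to enumerate."""
    docs = [
        Document(id="d1", authors=["a0", "a1"], journal="j0", year=1996,
                 tokens=["w0", "w1", "w0"]),
        Document(id="d2", authors=["a1"], journal="j1", year=2001,
                 tokens=["w2", "w1"]),
    ]
    return Corpus(docs)


class TestInit:
    def test_counts_consistent_with_assignments(self, tiny_corpus):
        state = init_assignments(tiny_corpus, HP2)
        nAT, nTW, nTJ = tally_counts(tiny_corpus, state.z, state.x, HP2.K)
        assert (state.counts_AT == nAT).all()
        assert (state.counts_TW == nTW).all()
        assert (state.counts_TJ == nTJ).all()
        assert state.counts_AT.sum() == state.counts_TW.sum() == 5

    def test_same_seed_identical(self, tiny_corpus):
        s1 = init_assignments(tiny_corpus, HP2)
        s2 = init_assignments(tiny_corpus, HP2)
        assert (s1.z == s2.z).all() and (s1.x == s2.x).all()

    def test_k1_all_tokens_in_topic_zero(self, tiny_corpus):
        hp = Hyperparams(K=1, alpha=1.0, iterations=1, seed=0)
        state = init_assignments(tiny_corpus, hp)
        assert (state.z == 0).all()
        assert state.counts_TW[0].sum() == tiny_corpus.n_tokens

    def test_x_always_a_document_author(self, tiny_corpus):
        state = init_assignments(tiny_corpus, HP2)
        for d in range(tiny_corpus.n_documents):
            for i in state.token_range(d):
                assert state.x[i] in tiny_corpus.author_ids[d]


class TestConditional:
    def test_k1_single_author_certain(self):
        corpus = Corpus(
            [Document(id="d", authors=["a"], journal="j", year=2000, tokens=["w"])]
        )
        hp = Hyperparams(K=1, alpha=1.0, iterations=1, seed=0)
        state = init_assignments(corpus, hp)
        state._apply(0, int(state.z[0]), int(state.x[0]), -1)
        table = conditional_distribution(state, 0, 0, hp)
        assert table.shape == (1, 1)
        assert table[0, 0] == pytest.approx(1.0)

    def test_all_zero_counts_symmetric_uniform(self, tiny_corpus):
        state = init_assignments(tiny_corpus, HP2)
        for d in range(tiny_corpus.n_documents):
            for i in state.token_range(d):
                state._apply(i, int(state.z[i]), int(state.x[i]), -1)
        # empty tables + symmetric priors: every (k, a) cell equally likely
        table = conditional_distribution(state, 0, 0, HP2)
        assert table.shape == (2, 2)
        assert np.allclose(table, 0.25)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration_oracle_every_token(self, seed):
        """Sampler conditional equals the brute-force enumeration posterior."""
        corpus = tiny_instance()
        hp = Hyperparams(K=2, alpha=1.3, beta=0.2, gamma=0.4, iterations=1, seed=seed)
        state = init_assignments(corpus, hp)
        flat_i = 0
        for d in range(corpus.n_documents):
            for pos, i in enumerate(state.token_range(d)):
                work = state.copy()
                work._apply(i, int(work.z[i]), int(work.x[i]), -1)
                got = conditional_distribution(work, d, pos, hp)
                expected = enumeration_conditional(corpus, state.z, state.x, flat_i, hp)
                assert np.abs(got - expected).max() < 1e-10
                flat_i += 1

    def test_decrement_contract_enforced(self, tiny_corpus):
        state = init_assignments(tiny_corpus, HP2)
        k, a = int(state.z[0]), int(state.x[0])
        state._apply(0, k, a, -1)
        with pytest.raises(RuntimeError, match="negative count"):
            state._apply(0, k, a, -1)
            state._apply(0, k, a, -1)


class TestSweep:
    def test_count_conservation(self, tiny_corpus, rng):
        state = init_assignments(tiny_corpus, HP2)
        for _ in range(10):
            gibbs_sweep(state, HP2, rng)
            assert state.counts_AT.sum() == tiny_corpus.n_tokens
            assert state.counts_TW.sum() == tiny_corpus.n_tokens
            assert state.counts_TJ.sum() == tiny_corpus.n_tokens
            assert (state.counts_AT >= 0).all()

    def test_counts_stay_consistent_with_assignments(self, tiny_corpus, rng):
        state = init_assignments(tiny_corpus, HP2)
        for _ in range(5):
            gibbs_sweep(state, HP2, rng)
        nAT, nTW, nTJ = tally_counts(tiny_corpus, state.z, state.x, HP2.K)
        assert (state.counts_AT == nAT).all()
        assert (state.counts_TW == nTW).all()
        assert (state.counts_TJ == nTJ).all()

    def test_k1_topics_fixed_authors_resampled(self, tiny_corpus):
        hp = Hyperparams(K=1, alpha=1.0, iterations=1, seed=3)
        state = init_assignments(tiny_corpus, hp)
        rng = np.random.default_rng(0)
        for _ in range(3):
            gibbs_sweep(state, hp, rng)
        assert (state.z == 0).all()
        for d in range(tiny_corpus.n_documents):
            for i in state.token_range(d):
                assert state.x[i] in tiny_corpus.author_ids[d]

    def test_fixed_seed_identical_trajectory(self, tiny_corpus):
        trajs = []
        for _ in range(2):
            state = init_assignments(tiny_corpus, HP2)
            rng = np.random.default_rng(99)
            tr = []
            for _ in range(4):
                gibbs_sweep(state, HP2, rng)
                tr.append((state.z.copy(), state.x.copy()))
            trajs.append(tr)
        for (z1, x1), (z2, x2) in zip(*trajs):
            assert (z1 == z2).all() and (x1 == x2).all()


class TestPosterior:
    def test_all_zero_counts_symmetric(self, tiny_corpus):
        state = init_assignments(tiny_corpus, HP2)
        for name in ("counts_AT", "counts_TW", "counts_TJ", "author_totals", "topic_totals"):
            getattr(state, name)[:] = 0
        post = estimate_posterior(state, HP2)
        assert np.allclose(post.theta, 0.5)

    def test_direct_formula(self, tiny_corpus):
        hp = Hyperparams(K=2, alpha=0.5, iterations=1, seed=0)
        state = init_assignments(tiny_corpus, hp)
        state.counts_AT[:] = 0
        state.counts_AT[0] = [2, 0]
        post = estimate_posterior(state, hp)
        assert post.theta[0] == pytest.approx([2.5 / 3, 0.5 / 3])

    def test_rows_normalized(self, tiny_corpus, rng):
        state = init_assignments(tiny_corpus, HP2)
        gibbs_sweep(state, HP2, rng)
        post = estimate_posterior(state, HP2)
        for m in (post.theta, post.phi, post.psi):
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)

    def test_topic_label_permutation_equivariance(self, tiny_corpus, rng):
        """Permuting topic labels of a state permutes posterior rows/columns."""
        hp = Hyperparams(K=3, alpha=0.9, iterations=1, seed=5)
        state = init_assignments(tiny_corpus, hp)
        gibbs_sweep(state, hp, rng)
        post = estimate_posterior(state, hp)
        perm = np.array([2, 0, 1])
        permuted = state.copy()
        permuted.z = perm[state.z]
        permuted.counts_AT = state.counts_AT[:, np.argsort(perm)]
        # rebuild emission tables from permuted assignments
        _, permuted.counts_TW, permuted.counts_TJ = tally_counts(
            tiny_corpus, permuted.z, permuted.x, hp.K
        )
        permuted.topic_totals = permuted.counts_TW.sum(axis=1)
        post_p = estimate_posterior(permuted, hp)
        assert np.allclose(post_p.theta, post.theta[:, np.argsort(perm)])
        assert np.allclose(post_p.psi[perm[0]], post.psi[0])
        assert np.allclose(post_p.phi[perm[1]], post.phi[1])


class TestFit:
    def test_invalid_iterations_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            Hyperparams(K=2, iterations=0)

    def test_empty_modelable_corpus_rejected(self):
        corpus = Corpus(
            [Document(id="d", authors=["a"], journal="j", year=2000, tokens=[])]
        )
        with pytest.raises(ValueError, match="zero tokens"):
            fit(corpus, HP2)

    def test_log_joint_trend_non_decreasing(self):
        from actopics.synthetic import GeneratorSettings, sample_corpus, sample_ground_truth

        settings = GeneratorSettings(
            D=60, K=3, A=10, J=4, V=40, tokens_per_doc=(10, 20), seed=2
        )
        corpus, _, _ = sample_corpus(sample_ground_truth(settings))
        hp = Hyperparams(K=3, iterations=60, seed=2)
        _, _, log_joint = fit(corpus, hp)
        assert np.median(log_joint[-20:]) >= np.median(log_joint[:20])

    def test_joint_log_prob_matches_oracle(self, tiny_corpus):
        state = init_assignments(tiny_corpus, HP2)
        from helpers import collapsed_joint_log

        got = joint_log_prob(state, HP2)
        want = collapsed_joint_log(tiny_corpus, state.z, state.x, HP2)
        assert got == pytest.approx(want, abs=1e-9)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(deadline=None, derandomize=True, max_examples=20)
def test_conservation_property_random_seeds(seed):
    """Count totals equal the corpus token count after any sweeps, any seed."""
    corpus = tiny_instance()
    hp = Hyperparams(K=3, alpha=0.4, beta=0.1, gamma=0.2, iterations=1, seed=seed)
    state = init_assignments(corpus, hp)
    rng = np.random.default_rng(seed)
    for _ in range(3):
        gibbs_sweep(state, hp, rng)
    assert state.counts_AT.sum() == state.counts_TW.sum() == state.counts_TJ.sum() == 5
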