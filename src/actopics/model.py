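"""Three-facet topic model over keyphrases, authors, and journals.

The generative story (an author–conference–topic style model with journals in
the venue role and keyphrases as tokens): for each token of a paper, one of
the paper's ``A_d`` authors is chosen uniformly at random; that author draws a
topic ``z`` from their topic distribution θ_a; the topic emits the keyphrase
``w`` from ψ_z and the paper's journal ``j`` from φ_z. Symmetric Dirichlet
priors (α on θ rows, β on ψ rows, γ on φ rows) are integrated out, and the
discrete assignments ``(z, x)`` are resampled jointly per token by collapsed
Gibbs sampling from

    P(z=k, x=a | rest) ∝ (n_AT[a,k]+α)/(n_A[a]+Kα)
                       × (n_TW[k,w]+β)/(n_T[k]+Vβ)
                       × (n_TJ[k,j]+γ)/(n_T[k]+Jγ)

where the count tables exclude the token being resampled. Because every
token emits its document's journal, each row of the topic×journal table sums
to the topic's total token count ``n_T[k]``, which is why the same total
appears in both emission denominators.

Following common practice for this model family, α defaults to ``50/K``
and β = γ = 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .corpus import Corpus

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparams",
    "SamplerState",
    "Posterior",
    "init_assignments",
    "conditional_distribution",
    "gibbs_sweep",
    "estimate_posterior",
    "joint_log_prob",
    "fit",
]


@dataclass
class Hyperparams:
    """Model and sampler settings.

    ``alpha`` defaults to the 50/K heuristic when left ``None``.
    """

    K: int = 20
    alpha: float | None = None
    beta: float = 0.01
    gamma: float = 0.01
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha is None:
            self.alpha = 50.0 / self.K
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("alpha, beta, gamma must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def replace(self, **kw) -> "Hyperparams":
        d = dict(
            K=self.K, alpha=self.alpha, beta=self.beta, gamma=self.gamma,
            iterations=self.iterations, seed=self.seed,
        )
        d.update(kw)
        return Hyperparams(**d)


class SamplerState:
    """Per-token topic/author assignments plus the three count tables.

    Internally tokens are flattened across documents; ``doc_offsets`` gives
    each document's span in the flat arrays. ``z`` holds topic assignments,
    ``x`` holds the responsible author's *global* index (always one of its
    document's authors).
    """

    def __init__(self, corpus: Corpus, K: int) -> None:
        self.corpus = corpus
        self.K = K
        lengths = [len(t) for t in corpus.token_ids]
        self.doc_offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
        self.token_word = (
            np.concatenate(corpus.token_ids)
            if corpus.n_tokens
            else np.empty(0, dtype=np.int64)
        )
        self.token_doc = np.repeat(np.arange(corpus.n_documents), lengths)
        self.z = np.zeros(len(self.token_word), dtype=np.int64)
        self.x = np.zeros(len(self.token_word), dtype=np.int64)
        self.counts_AT = np.zeros((corpus.A, K), dtype=np.int64)
        self.counts_TW = np.zeros((K, corpus.V), dtype=np.int64)
        self.counts_TJ = np.zeros((K, corpus.J), dtype=np.int64)
        self.author_totals = np.zeros(corpus.A, dtype=np.int64)
        self.topic_totals = np.zeros(K, dtype=np.int64)

    # -- assignment bookkeeping -------------------------------------------
    def _apply(self, i: int, k: int, a: int, delta: int) -> None:
        w = self.token_word[i]
        j = self.corpus.journal_id[self.token_doc[i]]
        self.counts_AT[a, k] += delta
        self.counts_TW[k, w] += delta
        self.counts_TJ[k, j] += delta
        self.author_totals[a] += delta
        self.topic_totals[k] += delta
        if delta < 0 and (
            self.counts_AT[a, k] < 0 or self.counts_TW[k, w] < 0 or self.counts_TJ[k, j] < 0
        ):
            raise RuntimeError("negative count: decrement without matching increment")

    def token_range(self, d: int) -> range:
        return range(self.doc_offsets[d], self.doc_offsets[d + 1])

    def total_count(self) -> int:
        return int(self.counts_TW.sum())

    def copy(self) -> "SamplerState":
        new = SamplerState.__new__(SamplerState)
        new.corpus = self.corpus
        new.K = self.K
        new.doc_offsets = self.doc_offsets
        new.token_word = self.token_word
        new.token_doc = self.token_doc
        for name in ("z", "x", "counts_AT", "counts_TW", "counts_TJ",
                     "author_totals", "topic_totals"):
            setattr(new, name, getattr(self, name).copy())
        return new


@dataclass
class Posterior:
    """Smoothed point estimates of the three stochastic matrices.

    theta: author×topic, phi: topic×journal, psi: topic×word; every row sums
    to one. Label lists mirror the training corpus registries.
    """

    theta: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    author_labels: list[str] = field(default_factory=list)
    journal_labels: list[str] = field(default_factory=list)
    vocab_labels: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.psi.shape[0]


def init_assignments(corpus: Corpus, hp: Hyperparams, rng=None) -> SamplerState:
    """Uniform random initialization of (z, x) with consistent count tables."""
    rng = np.random.default_rng(hp.seed) if rng is None else rng
    state = SamplerState(corpus, hp.K)
    for d in range(corpus.n_documents):
        authors = corpus.author_ids[d]
        if len(authors) == 0:
            raise ValueError(f"document {corpus.documents[d].id!r} has no authors")
        for i in state.token_range(d):
            k = int(rng.integers(hp.K))
            a = int(authors[rng.integers(len(authors))])
            state.z[i] = k
            state.x[i] = a
            state._apply(i, k, a, +1)
    return state


def conditional_distribution(
    state: SamplerState, doc_index: int, token_position: int, hp: Hyperparams
) -> np.ndarray:
    """Full conditional over (topic, author) for one held-out token.

    The token's current assignment must already be decremented from the count
    tables. Returns an ``A_d × K`` matrix of probabilities summing to one;
    row order follows the document's author list.
    """
    corpus = state.corpus
    i = state.doc_offsets[doc_index] + token_position
    w = state.token_word[i]
    j = corpus.journal_id[doc_index]
    authors = corpus.author_ids[doc_index]
    if (state.counts_AT < 0).any():
        raise RuntimeError("negative count in counts_AT")
    fa = (state.counts_AT[authors, :] + hp.alpha) / (
        state.author_totals[authors, None] + hp.K * hp.alpha
    )
    fk = (state.counts_TW[:, w] + hp.beta) / (state.topic_totals + corpus.V * hp.beta)
    fk = fk * (state.counts_TJ[:, j] + hp.gamma) / (
        state.topic_totals + corpus.J * hp.gamma
    )
    table = fa * fk[None, :]
    return table / table.sum()


def gibbs_sweep(state: SamplerState, hp: Hyperparams, rng) -> None:
    """One in-place sweep: every token visited in document then token order.

    For each token the current assignment is decremented, a new ``(z, x)``
    pair is drawn from the collapsed conditional by inverse CDF over the
    flattened (author-major) table, and the counts are re-incremented.
    """
    corpus = state.corpus
    K = state.K
    alpha, beta, gamma = hp.alpha, hp.beta, hp.gamma
    Kalpha = K * alpha
    Vbeta = corpus.V * beta
    Jgamma = corpus.J * gamma
    counts_AT = state.counts_AT
    counts_TW = state.counts_TW
    counts_TJ = state.counts_TJ
    author_totals = state.author_totals
    topic_totals = state.topic_totals
    token_word = state.token_word
    journal_of_doc = state.corpus.journal_id
    z = state.z
    x = state.x
    n_tok = len(token_word)
    unif = rng.random(n_tok) if n_tok else np.empty(0)
    for d in range(corpus.n_documents):
        authors = corpus.author_ids[d]
        j = journal_of_doc[d]
        for i in range(state.doc_offsets[d], state.doc_offsets[d + 1]):
            w = token_word[i]
            k0, a0 = z[i], x[i]
            counts_AT[a0, k0] -= 1
            counts_TW[k0, w] -= 1
            counts_TJ[k0, j] -= 1
            author_totals[a0] -= 1
            topic_totals[k0] -= 1
            fk = (counts_TW[:, w] + beta) * (counts_TJ[:, j] + gamma) / (
                (topic_totals + Vbeta) * (topic_totals + Jgamma)
            )
            table = (
                (counts_AT[authors, :] + alpha)
                / (author_totals[authors, None] + Kalpha)
            ) * fk
            # inverse CDF over (k, a) pairs, k-major, for a deterministic draw
            flat = np.cumsum(table.T.ravel())
            idx = int(np.searchsorted(flat, unif[i] * flat[-1], side="right"))
            idx = min(idx, flat.size - 1)
            n_auth = len(authors)
            k_new = idx // n_auth
            a_new = int(authors[idx % n_auth])
            z[i] = k_new
            x[i] = a_new
            counts_AT[a_new, k_new] += 1
            counts_TW[k_new, w] += 1
            counts_TJ[k_new, j] += 1
            author_totals[a_new] += 1
            topic_totals[k_new] += 1


def estimate_posterior(state: SamplerState, hp: Hyperparams) -> Posterior:
    """Smoothed row-normalized point estimates from the current counts."""
    corpus = state.corpus
    theta = (state.counts_AT + hp.alpha) / (
        state.counts_AT.sum(axis=1, keepdims=True) + hp.K * hp.alpha
    )
    psi = (state.counts_TW + hp.beta) / (
        state.counts_TW.sum(axis=1, keepdims=True) + corpus.V * hp.beta
    )
    phi = (state.counts_TJ + hp.gamma) / (
        state.counts_TJ.sum(axis=1, keepdims=True) + corpus.J * hp.gamma
    )
    return Posterior(
        theta=theta,
        phi=phi,
        psi=psi,
        author_labels=corpus.authors.labels,
        journal_labels=corpus.journals.labels,
        vocab_labels=corpus.vocabulary.labels,
    )


def _dirichlet_multinomial_term(counts: np.ndarray, conc: float) -> float:
    """log ∏_rows [Γ(Nc)/Γ(n_row+Nc) × ∏_cols Γ(n+c)/Γ(c)] for one table."""
    n_cols = counts.shape[1]
    row_tot = counts.sum(axis=1)
    out = gammaln(n_cols * conc) * counts.shape[0] - gammaln(row_tot + n_cols * conc).sum()
    out += gammaln(counts + conc).sum() - gammaln(conc) * counts.size
    return float(out)


def joint_log_prob(state: SamplerState, hp: Hyperparams) -> float:
    """Collapsed joint log P(w, j, z, x) up to the constant uniform-author term."""
    return (
        _dirichlet_multinomial_term(state.counts_AT, hp.alpha)
        + _dirichlet_multinomial_term(state.counts_TW, hp.beta)
        + _dirichlet_multinomial_term(state.counts_TJ, hp.gamma)
    )


def fit(
    corpus: Corpus,
    hp: Hyperparams,
    log_every: int = 0,
    average_last: int = 0,
) -> tuple[SamplerState, Posterior, np.ndarray]:
    """Run the collapsed Gibbs sampler and return the point-estimate posterior.

    Documents with zero tokens are excluded from fitting (registries are
    shared, so indices stay aligned with the input corpus). The point
    estimate comes from the final state; ``average_last > 0`` instead
    averages the posterior over the last that many sweeps.

    Returns ``(state, posterior, log_joint_per_sweep)``.
    """
    modeled = corpus.modeled() if any(len(t) == 0 for t in corpus.token_ids) else corpus
    if modeled.n_tokens == 0:
        raise ValueError("no modelable documents: every document has zero tokens")
    rng = np.random.default_rng(hp.seed)
    state = init_assignments(modeled, hp, rng)
    log_joint = np.empty(hp.iterations)
    avg_acc = None
    for sweep in range(hp.iterations):
        gibbs_sweep(state, hp, rng)
        log_joint[sweep] = joint_log_prob(state, hp)
        if log_every and (sweep + 1) % log_every == 0:
            logger.info("sweep %d/%d log-joint %.2f", sweep + 1, hp.iterations, log_joint[sweep])
        if average_last and sweep >= hp.iterations - average_last:
            post = estimate_posterior(state, hp)
            if avg_acc is None:
                avg_acc = [post.theta, post.phi, post.psi]
            else:
                avg_acc = [acc + m for acc, m in zip(avg_acc, (post.theta, post.phi, post.psi))]
    if average_last and avg_acc is not None:
        n = min(average_last, hp.iterations)
        posterior = Posterior(
            theta=avg_acc[0] / n,
            phi=avg_acc[1] / n,
            psi=avg_acc[2] / n,
            author_labels=modeled.authors.labels,
            journal_labels=modeled.journals.labels,
            vocab_labels=modeled.vocabulary.labels,
        )
    else:
        posterior = estimate_posterior(state, hp)
    return state, posterior, log_joint
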