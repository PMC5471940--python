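"""Model evaluation: held-out perplexity via fold-in, topic similarity, and
run-to-run stability.

Perplexity is ``exp(−Σ log p(token) / N)`` over held-out tokens; the uniform
model scores exactly the vocabulary size V, and lower is better. Held-out
documents are scored by fold-in: the trained topic-keyphrase (ψ) and
topic-journal (φ) matrices are frozen and short Gibbs runs estimate each
held-out document's local author-topic mixture, giving

    p(w | d) = Σ_k [ (1/A_d) Σ_a θ̂_local[a,k] ] ψ[k,w].

Out-of-vocabulary held-out tokens are dropped from the score (and counted);
a held-out journal unseen in training contributes a constant factor to the
local conditional and therefore simply drops out.

Topic similarity within a run is the mean Pearson correlation between all
C(K,2) pairs of ψ rows; stability across runs repeats the full fit under
different seeds and compares these per-run values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Corpus, PeriodPartition
from .model import Hyperparams, Posterior, fit

logger = logging.getLogger(__name__)

__all__ = [
    "PerplexityReport",
    "StabilityReport",
    "fold_in",
    "perplexity",
    "topic_similarity",
    "run_stability",
    "perplexity_grid",
]


@dataclass
class PerplexityReport:
    per_document_loglik: np.ndarray
    n_tokens: int
    n_oov_dropped: int
    perplexity: float


@dataclass
class StabilityReport:
    per_run: np.ndarray
    mean: float
    range: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"run": np.arange(1, len(self.per_run) + 1), "mean_topic_correlation": self.per_run}
        )


def fold_in(
    posterior: Posterior,
    heldout: Corpus,
    hp: Hyperparams,
    sweeps: int = 50,
    burn_in: int = 20,
    rng=None,
) -> tuple[list[np.ndarray], int]:
    """Predictive per-token probabilities for held-out documents.

    ψ and φ stay frozen; per document, token-level (z, x) assignments over
    the document's own authors are resampled for ``sweeps`` local Gibbs
    sweeps, and the local author-topic estimate θ̂ is averaged after
    ``burn_in``. Held-out corpora must be indexed against the training
    vocabulary/journal registries (tokens or journals absent from the
    training registries are handled per the module docstring).

    Returns ``(per_document_probability_arrays, n_oov_dropped)``.
    """
    if heldout.n_documents == 0:
        raise ValueError("empty held-out corpus")
    if sweeps <= burn_in:
        raise ValueError("sweeps must exceed burn_in")
    rng = np.random.default_rng(hp.seed) if rng is None else rng
    K = posterior.K
    V = posterior.psi.shape[1]
    J = posterior.phi.shape[1]
    psi, phi = posterior.psi, posterior.phi
    alpha = hp.alpha
    probs_per_doc: list[np.ndarray] = []
    n_oov = 0
    for d in range(heldout.n_documents):
        words_all = heldout.token_ids[d]
        in_vocab = words_all < V
        n_oov += int((~in_vocab).sum())
        words = words_all[in_vocab]
        A_d = len(heldout.author_ids[d])
        j = int(heldout.journal_id[d])
        phi_j = phi[:, j] if j < J else np.ones(K)  # unseen journal: constant factor
        n_tok = len(words)
        if n_tok == 0:
            probs_per_doc.append(np.empty(0))
            continue
        m_at = np.zeros((A_d, K))
        m_a = np.zeros(A_d)
        zloc = np.empty(n_tok, dtype=np.int64)
        xloc = np.empty(n_tok, dtype=np.int64)
        for i in range(n_tok):
            zloc[i] = rng.integers(K)
            xloc[i] = rng.integers(A_d)
            m_at[xloc[i], zloc[i]] += 1
            m_a[xloc[i]] += 1
        theta_acc = np.zeros((A_d, K))
        n_acc = 0
        for sweep in range(sweeps):
            unif = rng.random(n_tok)
            for i in range(n_tok):
                a0, k0 = xloc[i], zloc[i]
                m_at[a0, k0] -= 1
                m_a[a0] -= 1
                table = ((m_at + alpha) / (m_a[:, None] + K * alpha)) * (
                    psi[:, words[i]] * phi_j
                )[None, :]
                flat = np.cumsum(table.T.ravel())
                idx = int(np.searchsorted(flat, unif[i] * flat[-1], side="right"))
                idx = min(idx, flat.size - 1)
                k_new, a_new = idx // A_d, idx % A_d
                zloc[i] = k_new
                xloc[i] = a_new
                m_at[a_new, k_new] += 1
                m_a[a_new] += 1
            if sweep >= burn_in:
                theta_acc += (m_at + alpha) / (m_a[:, None] + K * alpha)
                n_acc += 1
        theta_hat = theta_acc / n_acc
        topic_mix = theta_hat.mean(axis=0)  # uniform over the document's authors
        probs_per_doc.append(psi[:, words].T @ topic_mix)
    return probs_per_doc, n_oov


def perplexity(probs) -> float:
    """exp of the negative mean log token probability.

    ``probs`` is a flat array or a list of per-document arrays. A zero
    probability is an error naming the offending token position.
    """
    if isinstance(probs, (list, tuple)):
        flat = np.concatenate([np.asarray(p, dtype=float) for p in probs]) if probs else np.empty(0)
    else:
        flat = np.asarray(probs, dtype=float)
    if flat.size == 0:
        raise ValueError("no token probabilities to score")
    bad = np.nonzero(flat <= 0)[0]
    if bad.size:
        raise ValueError(f"zero probability for token at flat position {int(bad[0])}")
    return float(np.exp(-np.log(flat).mean()))


def heldout_perplexity(
    posterior: Posterior, heldout: Corpus, hp: Hyperparams, sweeps: int = 50,
    burn_in: int = 20, rng=None,
) -> PerplexityReport:
    """Fold-in + perplexity convenience wrapper with a per-document report."""
    probs, n_oov = fold_in(posterior, heldout, hp, sweeps=sweeps, burn_in=burn_in, rng=rng)
    per_doc = np.array([np.log(p).sum() if p.size else 0.0 for p in probs])
    n_tok = int(sum(p.size for p in probs))
    return PerplexityReport(
        per_document_loglik=per_doc,
        n_tokens=n_tok,
        n_oov_dropped=n_oov,
        perplexity=perplexity([p for p in probs if p.size]),
    )


def topic_similarity(posterior: Posterior) -> float:
    """Mean Pearson correlation over all unordered pairs of ψ rows.

    Pairs involving a zero-variance row are skipped (with a log report); if
    every pair is degenerate the result is NaN.
    """
    psi = posterior.psi
    K = psi.shape[0]
    if K < 2:
        raise ValueError("topic similarity requires K >= 2")
    centered = psi - psi.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    vals = []
    skipped = 0
    for i in range(K):
        for j in range(i + 1, K):
            if norms[i] == 0 or norms[j] == 0:
                skipped += 1
                continue
            vals.append(float(centered[i] @ centered[j] / (norms[i] * norms[j])))
    if skipped:
        logger.warning("topic_similarity: skipped %d zero-variance pairs", skipped)
    return float(np.mean(vals)) if vals else float("nan")


def run_stability(corpus: Corpus, hp: Hyperparams, runs: int = 10) -> StabilityReport:
    """Refit the model ``runs`` times with distinct seeds and compare topics.

    Each run reports its within-run mean pairwise topic correlation; the
    report carries all per-run values plus their mean and min–max range.
    """
    if runs < 2:
        raise ValueError("need at least 2 runs")
    per_run = np.empty(runs)
    for r in range(runs):
        _, post, _ = fit(corpus, hp.replace(seed=hp.seed + r))
        per_run[r] = topic_similarity(post)
    return StabilityReport(
        per_run=per_run,
        mean=float(per_run.mean()),
        range=(float(per_run.min()), float(per_run.max())),
    )


def perplexity_grid(
    partition: PeriodPartition,
    heldout: Corpus,
    K_values,
    hp_base: Hyperparams,
    sweeps: int = 50,
    burn_in: int = 20,
) -> pd.DataFrame:
    """Held-out perplexity for every (training period, K) cell.

    Each cell fits the model on that period's corpus at that K (α follows
    the 50/K rule unless ``hp_base`` pins it) and scores the common held-out
    corpus by fold-in. "Average" row and column are appended.
    """
    rows = {}
    for i, label in enumerate(partition.labels()):
        period_corpus = partition.slices[i]
        cells = {}
        for K in K_values:
            hp = hp_base.replace(K=K, alpha=None)
            _, post, _ = fit(period_corpus, hp)
            # held-out docs re-indexed against this period's registries
            ho = Corpus(
                heldout.documents,
                vocabulary=period_corpus.vocabulary.labels,
                authors=period_corpus.authors.labels,
                journals=period_corpus.journals.labels,
            )
            rep = heldout_perplexity(post, ho, hp, sweeps=sweeps, burn_in=burn_in)
            cells[K] = rep.perplexity
        rows[label] = cells
    grid = pd.DataFrame(rows).T  # periods × K
    grid.index.name = "period"
    grid.columns = [str(k) for k in K_values]
    grid["Average"] = grid.mean(axis=1)
    grid.loc["Average"] = grid.mean(axis=0)
    return grid
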