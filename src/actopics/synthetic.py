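"""Synthetic corpora drawn from the model's own generative process.

Used to test fitting, evaluation, and trend analysis with known ground truth:
author-topic (θ), topic-journal (φ), and topic-keyphrase (ψ) matrices are
drawn from symmetric Dirichlet distributions, then documents are generated by
the same story the sampler inverts — per token an author is picked uniformly
from the document's author set, a topic from that author's θ row, a keyphrase
from the topic's ψ row; the document's single journal is drawn from φ at the
first token's topic. Publication years cycle round-robin over the configured
period labels. No attempt is made to imitate real MEDLINE text, author-name
statistics, or citation structure.

The default Dirichlet concentration of 0.1 gives peaked (recoverable) truths;
concentrations near or above 1 give diffuse rows useful for null tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .corpus import Corpus, Document
from .model import Posterior

__all__ = [
    "GeneratorSettings",
    "GroundTruth",
    "sample_ground_truth",
    "sample_corpus",
    "match_topics",
    "recovery_error",
]


@dataclass
class GeneratorSettings:
    """Dimensions and shape parameters of a synthetic study corpus."""

    D: int = 400
    K: int = 5
    A: int = 30
    J: int = 8
    V: int = 200
    authors_per_doc: tuple[int, int] = (1, 4)
    tokens_per_doc: tuple[int, int] = (30, 80)
    concentration: float = 0.1
    years: tuple[int, ...] = (1996, 2001, 2006, 2011)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.D, self.K, self.A, self.J, self.V) < 1:
            raise ValueError("all dimensions must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if not (1 <= self.authors_per_doc[0] <= self.authors_per_doc[1] <= self.A):
            raise ValueError("invalid authors_per_doc range")
        if not (0 <= self.tokens_per_doc[0] <= self.tokens_per_doc[1]):
            raise ValueError("invalid tokens_per_doc range")


@dataclass
class GroundTruth:
    """The generating distributions of a synthetic corpus."""

    theta_true: np.ndarray  # A × K
    phi_true: np.ndarray    # K × J
    psi_true: np.ndarray    # K × V
    settings: GeneratorSettings = field(default_factory=GeneratorSettings)

    def validate(self) -> None:
        for name, m in (("theta", self.theta_true), ("phi", self.phi_true),
                        ("psi", self.psi_true)):
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name}_true rows must sum to 1")


def sample_ground_truth(settings: GeneratorSettings) -> GroundTruth:
    """Draw θ, φ, ψ rows from symmetric Dirichlets; seeded and reproducible."""
    rng = np.random.default_rng(settings.seed)
    c = settings.concentration
    truth = GroundTruth(
        theta_true=rng.dirichlet(np.full(settings.K, c), size=settings.A),
        phi_true=rng.dirichlet(np.full(settings.J, c), size=settings.K),
        psi_true=rng.dirichlet(np.full(settings.V, c), size=settings.K),
        settings=settings,
    )
    truth.validate()
    return truth


def _labels(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}_{i:0{width}d}" for i in range(n)]


def sample_corpus(
    truth: GroundTruth, rng=None
) -> tuple[Corpus, list[np.ndarray], list[np.ndarray]]:
    """Generate a corpus from the ground truth.

    Returns ``(corpus, true_z, true_x)`` where ``true_z[d][i]`` /
    ``true_x[d][i]`` are the generating topic and author index of token ``i``
    of document ``d``. Zero-token documents are allowed (they are flagged by
    the corpus' ``modeled()`` view). Registries are laid out in ground-truth
    index order so recovered matrices align column-for-column with the truth.
    """
    truth.validate()
    s = truth.settings
    rng = np.random.default_rng(s.seed + 1) if rng is None else rng
    vocab = _labels("kp", s.V)
    author_names = _labels("author", s.A)
    journal_names = _labels("journal", s.J)
    docs: list[Document] = []
    true_z: list[np.ndarray] = []
    true_x: list[np.ndarray] = []
    for d in range(s.D):
        a_d = int(rng.integers(s.authors_per_doc[0], s.authors_per_doc[1] + 1))
        authors = rng.choice(s.A, size=a_d, replace=False)
        n_d = int(rng.integers(s.tokens_per_doc[0], s.tokens_per_doc[1] + 1))
        xs = authors[rng.integers(a_d, size=n_d)]
        zs = np.empty(n_d, dtype=np.int64)
        ws = np.empty(n_d, dtype=np.int64)
        for i in range(n_d):
            zs[i] = rng.choice(s.K, p=truth.theta_true[xs[i]])
            ws[i] = rng.choice(s.V, p=truth.psi_true[zs[i]])
        if n_d > 0:
            j = int(rng.choice(s.J, p=truth.phi_true[zs[0]]))
        else:
            j = int(rng.integers(s.J))
        docs.append(
            Document(
                id=f"syn{d:05d}",
                authors=[author_names[a] for a in authors],
                journal=journal_names[j],
                year=int(s.years[d % len(s.years)]),
                title=f"synthetic document {d}",
                abstract=f"synthetic abstract {d}",
                tokens=[vocab[w] for w in ws],
            )
        )
        true_z.append(zs)
        true_x.append(xs)
    corpus = Corpus(docs, vocabulary=vocab, authors=author_names, journals=journal_names)
    return corpus, true_z, true_x


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1))[:, None] * np.sqrt((b**2).sum(axis=1))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (a @ b.T) / denom
    return np.nan_to_num(corr)


def match_topics(
    estimated: Posterior, truth: GroundTruth
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve label switching by greedy best-first matching on ψ rows.

    Returns ``(perm, corrs)`` where ``perm[t]`` is the estimated topic matched
    to true topic ``t`` (each used once) and ``corrs[t]`` the corresponding
    Pearson correlation.
    """
    K = truth.psi_true.shape[0]
    if estimated.psi.shape[0] != K:
        raise ValueError(
            f"topic count mismatch: estimated K={estimated.psi.shape[0]}, true K={K}"
        )
    corr = _pearson_rows(truth.psi_true, estimated.psi)
    perm = np.full(K, -1, dtype=np.int64)
    corrs = np.zeros(K)
    work = corr.copy()
    for _ in range(K):
        t, e = np.unravel_index(np.argmax(work), work.shape)
        perm[t] = e
        corrs[t] = corr[t, e]
        work[t, :] = -np.inf
        work[:, e] = -np.inf
    return perm, corrs


def match_topics_exhaustive(
    estimated: Posterior, truth: GroundTruth
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal assignment by exhaustive permutation search (small K only)."""
    K = truth.psi_true.shape[0]
    corr = _pearson_rows(truth.psi_true, estimated.psi)
    best, best_perm = -np.inf, None
    for p in permutations(range(K)):
        s = corr[np.arange(K), p].sum()
        if s > best:
            best, best_perm = s, p
    perm = np.array(best_perm, dtype=np.int64)
    return perm, corr[np.arange(K), perm]


@dataclass
class RecoveryReport:
    """Agreement between a fitted posterior and the generating truth."""

    psi_corr_mean: float
    psi_corrs: np.ndarray
    phi_corr_mean: float
    phi_corrs: np.ndarray
    theta_mae: float
    n_theta_authors: int


def recovery_error(
    estimated: Posterior,
    truth: GroundTruth,
    matching: np.ndarray,
    author_token_counts: np.ndarray | None = None,
    min_author_tokens: int = 1,
) -> RecoveryReport:
    """Matched-topic correlations for ψ and φ plus θ mean absolute error.

    θ error is averaged over authors with at least ``min_author_tokens``
    attributed tokens (all authors when counts are not given), after applying
    the topic matching to the estimated columns.
    """
    K = truth.psi_true.shape[0]
    psi_corrs = np.array(
        [_pearson_rows(truth.psi_true[t:t + 1], estimated.psi[matching[t]:matching[t] + 1])[0, 0]
         for t in range(K)]
    )
    phi_corrs = np.array(
        [_pearson_rows(truth.phi_true[t:t + 1], estimated.phi[matching[t]:matching[t] + 1])[0, 0]
         for t in range(K)]
    )
    theta_est = estimated.theta[:, matching]  # columns reordered to true topics
    if author_token_counts is not None:
        mask = np.asarray(author_token_counts) >= min_author_tokens
    else:
        mask = np.ones(truth.theta_true.shape[0], dtype=bool)
    theta_mae = float(np.abs(theta_est[mask] - truth.theta_true[mask]).mean()) if mask.any() else float("nan")
    return RecoveryReport(
        psi_corr_mean=float(psi_corrs.mean()),
        psi_corrs=psi_corrs,
        phi_corr_mean=float(phi_corrs.mean()),
        phi_corrs=phi_corrs,
        theta_mae=theta_mae,
        n_theta_authors=int(mask.sum()),
    )
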