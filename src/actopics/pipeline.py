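"""End-to-end study orchestration.

``run_study`` drives the full analysis: read records → drop abstract-less
papers → slice into periods → fit the topic model per period (independent
seeds) → evaluate (stability, optional perplexity grid) → summarize trends
(top entities, journal trajectories with shape patterns, presence counts).
Every stage writes CSV artifacts plus a manifest recording the configuration
and seeds, so a run is reproducible byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus import (
    DEFAULT_PERIODS,
    Corpus,
    corpus_statistics,
    filter_abstracts,
    read_records,
    slice_periods,
)
from .evaluation import perplexity_grid, run_stability
from .model import Hyperparams, Posterior, fit
from .trends import (
    journal_topic_mass,
    presence_counts,
    summaries_to_frame,
    top_entities,
    trajectories_to_frame,
    trajectory_table,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study", "save_posterior", "load_posterior"]


@dataclass
class StudyConfig:
    """Inputs, periods, model settings and outputs of one study run."""

    input_path: str
    input_format: str = "tabular"
    output_dir: str = "study_output"
    periods: list[tuple[int, int]] = field(
        default_factory=lambda: [list(p) for p in DEFAULT_PERIODS]
    )
    K: int = 20
    beta: float = 0.01
    gamma: float = 0.01
    iterations: int = 1000
    seed: int = 0
    top_n: int = 30
    stability_runs: int = 0
    heldout_path: str | None = None
    K_grid: list[int] = field(default_factory=list)
    require_abstract: bool = True

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def hyperparams(self, seed: int | None = None) -> Hyperparams:
        return Hyperparams(
            K=self.K, beta=self.beta, gamma=self.gamma,
            iterations=self.iterations, seed=self.seed if seed is None else seed,
        )


def save_posterior(posterior: Posterior, outdir: Path, prefix: str = "") -> None:
    """Write θ, φ, ψ as labeled CSV matrices."""
    topics = [f"topic_{k}" for k in range(posterior.K)]
    pd.DataFrame(posterior.theta, index=posterior.author_labels, columns=topics).to_csv(
        outdir / f"{prefix}theta.csv"
    )
    pd.DataFrame(posterior.phi, index=topics, columns=posterior.journal_labels).to_csv(
        outdir / f"{prefix}phi.csv"
    )
    pd.DataFrame(posterior.psi, index=topics, columns=posterior.vocab_labels).to_csv(
        outdir / f"{prefix}psi.csv"
    )


def load_posterior(outdir: Path, prefix: str = "") -> Posterior:
    theta = pd.read_csv(outdir / f"{prefix}theta.csv", index_col=0)
    phi = pd.read_csv(outdir / f"{prefix}phi.csv", index_col=0)
    psi = pd.read_csv(outdir / f"{prefix}psi.csv", index_col=0)
    return Posterior(
        theta=theta.to_numpy(),
        phi=phi.to_numpy(),
        psi=psi.to_numpy(),
        author_labels=list(theta.index),
        journal_labels=list(phi.columns),
        vocab_labels=list(psi.columns),
    )


def run_study(config: StudyConfig) -> Path:
    """Execute the study and return the output directory.

    Stage failures are re-raised with the stage name prefixed.
    """
    boundaries = [tuple(p) for p in config.periods]
    # validate before any compute
    probe = sorted(boundaries)
    for (lo, hi), (lo2, _) in zip(probe, probe[1:]):
        if lo2 <= hi:
            raise ValueError(f"run_study[config]: period ranges overlap ({lo},{hi})/({lo2},..)")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"run_study[{name}]: {exc}") from exc

    docs, dropped = stage(
        "read", read_records, config.input_path, config.input_format, None, True
    )
    if config.require_abstract:
        docs = stage("filter", filter_abstracts, docs)
    partition = stage("slice", slice_periods, docs, boundaries)

    stage("stats", corpus_statistics, docs, "journal").to_csv(
        out / "stats_journal.csv", index=False
    )
    stage("stats", corpus_statistics, docs, "year").to_csv(
        out / "stats_year.csv", index=False
    )
    stage("stats", corpus_statistics, docs, "period", boundaries).to_csv(
        out / "stats_period.csv", index=False
    )

    per_period_masses = []
    all_summaries = []
    period_seeds = {}
    for i, label in enumerate(partition.labels()):
        corpus = partition.slices[i]
        if corpus.modeled().n_tokens == 0:
            logger.warning("period %s has no modelable documents; skipped", label)
            continue
        seed = config.seed + 1000 * (i + 1)
        period_seeds[label] = seed
        hp = config.hyperparams(seed=seed)
        _, posterior, log_joint = stage("fit", fit, corpus, hp)
        pdir = out / f"period_{label}"
        pdir.mkdir(exist_ok=True)
        save_posterior(posterior, pdir)
        np.savetxt(pdir / "log_joint.csv", log_joint, header="log_joint", comments="")
        summaries = stage("trends", top_entities, posterior, corpus, config.top_n, label)
        summaries_to_frame(summaries).to_csv(pdir / "topic_summaries.csv", index=False)
        all_summaries.extend(summaries)
        per_period_masses.append(journal_topic_mass(posterior))

    if len(per_period_masses) >= 2:
        rows, excluded = stage("trends", trajectory_table, per_period_masses)
        trajectories_to_frame(rows).to_csv(out / "journal_trajectories.csv", index=False)
        (out / "journals_not_in_all_periods.txt").write_text(
            "\n".join(excluded) + ("\n" if excluded else "")
        )
        for kind in ("author", "journal", "keyphrase"):
            pc = stage("trends", presence_counts, all_summaries, kind)
            pc["topic_counts"].rename("topic_count").rename_axis("entity").to_csv(
                out / f"presence_{kind}_topics.csv"
            )
            pc["period_counts"].rename("period_count").rename_axis("entity").to_csv(
                out / f"presence_{kind}_periods.csv"
            )

    full = Corpus(docs)
    if config.stability_runs >= 2 and full.modeled().n_tokens > 0:
        rep = stage("evaluate", run_stability, full, config.hyperparams(), config.stability_runs)
        rep.to_frame().to_csv(out / "stability.csv", index=False)

    if config.heldout_path and config.K_grid:
        heldout = stage("read", read_records, config.heldout_path, config.input_format)
        grid = stage(
            "evaluate", perplexity_grid, partition, Corpus(heldout),
            config.K_grid, config.hyperparams(),
        )
        grid.to_csv(out / "perplexity_grid.csv")

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "period_seeds": period_seeds,
        "records_dropped_on_read": dropped,
        "documents_after_filtering": len(docs),
        "documents_outside_periods": partition.n_excluded,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out
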