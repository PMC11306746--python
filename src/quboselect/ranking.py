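"""Cardinality-sweep feature ranking.

The core selection loop: the QUBO is minimized once per target subset size
k (k = 1..p by default, mirroring the 1..161 sweep on the full survey),
each time under a quadratic penalty enforcing exactly k selected items.
A feature's importance is the number of per-k solutions it appears in;
ranks resolve ties first by diagonal relevance, then by feature index.

Per-k solutions need not be nested (the k-solution is not necessarily the
(k-1)-solution plus one item), and no nesting is assumed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annealer import EXACT_GUARD, AnnealSchedule, solve_exact, solve_sa
from .info_theory import BinningRule
from .qubo import QuboMatrix, add_cardinality_penalty, build_qubo, lambda_auto
from .synthetic import SurveyTable

__all__ = ["FeatureRanking", "sweep", "rank_from_counts"]

log = logging.getLogger(__name__)


@dataclass
class FeatureRanking:
    """Per-feature importance from a cardinality sweep (or a baseline).

    ``ranks`` is a permutation of 1..p with 1 the most important feature.
    ``counts`` holds appearance counts for sweep-based rankings and is
    None for baselines ranked by a score; ``scores`` holds the per-feature
    criterion (diagonal relevance -Q_ii for sweeps, |standardized
    coefficient| for the regression baseline).
    """

    feature_names: list[str]
    ranks: np.ndarray
    counts: np.ndarray | None = None
    scores: np.ndarray | None = None
    selected_sets: dict[int, tuple[int, ...]] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        p = len(self.feature_names)
        if sorted(self.ranks) != list(range(1, p + 1)):
            raise ValueError("ranks must be a permutation of 1..p")

    @property
    def p(self) -> int:
        return len(self.feature_names)

    def top(self, k: int) -> list[str]:
        """Feature names of the k most important features, best first."""
        order = np.argsort(self.ranks, kind="stable")
        return [self.feature_names[i] for i in order[:k]]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "feature": self.feature_names,
                "rank": self.ranks,
                "count": self.counts if self.counts is not None else np.nan,
                "score": self.scores if self.scores is not None else np.nan,
            }
        ).sort_values("rank")
        df.to_csv(Path(path), sep="\t", index=False)


def rank_from_counts(counts, relevance=None) -> np.ndarray:
    """Resolve appearance counts into ranks 1..p.

    Sort by count descending, then by ``relevance`` (the negated QUBO
    diagonal, -Q_ii) descending, then by feature index ascending.
    """
    counts = np.asarray(counts)
    p = counts.size
    if relevance is None:
        relevance = np.zeros(p)
    relevance = np.asarray(relevance, dtype=float)
    order = np.lexsort((np.arange(p), -relevance, -counts))
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return ranks


def _solve_for_k(
    qubo: QuboMatrix, k: int, lam: float, schedule: AnnealSchedule, exact_guard: int
) -> np.ndarray:
    penalized = add_cardinality_penalty(qubo, k, lam)
    if qubo.p <= exact_guard:
        best = solve_exact(penalized)
    else:
        best = solve_sa(penalized, schedule)[0]
    return best.x


def sweep(
    table: SurveyTable,
    k_range=None,
    mode: str = "literal",
    schedule: AnnealSchedule | None = None,
    binning: BinningRule | None = None,
    exact_guard: int = EXACT_GUARD,
) -> FeatureRanking:
    """Run the full cardinality sweep on a preprocessed table.

    One QUBO is built per dataset (the information estimates do not depend
    on k); the cardinality penalty with automatic weight is re-applied for
    each k and the penalized problem minimized — exactly for p up to
    ``exact_guard``, by simulated annealing (best read) beyond.  A solution
    violating its cardinality constraint triggers one retry at 10x the
    penalty; if that also violates, the sweep aborts naming the offending k.
    """
    schedule = schedule or AnnealSchedule()
    qubo = build_qubo(table, mode=mode, binning=binning)
    p = qubo.p
    k_values = list(k_range) if k_range is not None else list(range(1, p + 1))
    if any(k < 1 or k > p for k in k_values):
        raise ValueError(f"k_range must lie within [1, {p}]")

    lam = lambda_auto(qubo)
    counts = np.zeros(p, dtype=int)
    selected_sets: dict[int, tuple[int, ...]] = {}
    retries = []
    for k in k_values:
        # per-k seed so the SA streams differ across k but stay reproducible
        k_seed = int(np.random.SeedSequence([schedule.seed, k]).generate_state(1)[0] % (2**31))
        k_schedule = AnnealSchedule(
            n_sweeps=schedule.n_sweeps,
            beta_start=schedule.beta_start,
            beta_end=schedule.beta_end,
            n_reads=schedule.n_reads,
            seed=k_seed,
        )
        x = _solve_for_k(qubo, k, lam, k_schedule, exact_guard)
        if int(x.sum()) != k:
            log.warning("sweep: k=%d solution has %d ones; retrying at 10x penalty", k, int(x.sum()))
            retries.append(k)
            x = _solve_for_k(qubo, k, 10.0 * lam, k_schedule, exact_guard)
            if int(x.sum()) != k:
                raise RuntimeError(f"cardinality constraint violated at k={k} even after retry")
        sel = tuple(int(i) for i in np.flatnonzero(x))
        selected_sets[k] = sel
        counts[list(sel)] += 1

    assert counts.sum() == sum(k_values), "appearance-count conservation violated"
    relevance = -qubo.diagonal
    ranks = rank_from_counts(counts, relevance)
    return FeatureRanking(
        feature_names=table.feature_names,
        ranks=ranks,
        counts=counts,
        scores=relevance,
        selected_sets=selected_sets,
        metadata={
            "mode": mode,
            "k_values": k_values,
            "lambda": lam,
            "penalty_retries": retries,
            "seed": schedule.seed,
            "solver": "exact" if p <= exact_guard else "sa",
        },
    )
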