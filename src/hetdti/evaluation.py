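"""Ranking metrics (AUROC, AUPRC as average precision) and the case-study
top-m candidate aggregation / hit-count procedure.

AUROC is the Mann-Whitney statistic: the probability that a uniformly random
positive outscores a uniformly random negative, ties counted 1/2.  AUPRC is
average precision — the step-wise integral of precision over recall at each
retrieved positive — with deterministic tie handling (descending score, then
ascending index), the standard estimator for imbalanced link prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
from scipy.stats import rankdata


@dataclass
class MetricResult:
    fold_id: int
    round_id: int
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int


def _check_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return scores, labels


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC; requires both classes present."""
    scores, labels = _check_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties at 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision with ties broken by descending score then index."""
    scores, labels = _check_labels(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("auprc needs at least one positive")
    order = np.lexsort((np.arange(len(scores)), -scores))
    hits = np.cumsum(labels[order])
    ranks = np.arange(1, len(scores) + 1)
    precision_at_pos = (hits / ranks)[labels[order] == 1]
    return float(precision_at_pos.sum() / n_pos)


@dataclass
class CandidateTable:
    """Per-drug ranked candidate targets from one (round, fold) score table."""

    candidates: list[np.ndarray]  # per drug, ordered target indices (best first)


def build_candidate_tables(score_tables: list[np.ndarray], known_dti: np.ndarray,
                           m_prime: int = 40) -> list[CandidateTable]:
    """Per score table and per drug, the m' highest-scoring targets that are
    not known positives (ties: higher score, then lower target index)."""
    if m_prime < 1:
        raise ValueError("m_prime must be >= 1")
    n_drug, n_prot = known_dti.shape
    unknown = known_dti == 0
    n_unknown_min = int(unknown.sum(axis=1).min())
    if n_unknown_min < m_prime:
        import warnings
        warnings.warn(
            f"some drug has only {n_unknown_min} unknown targets; lists truncated")
    tables = []
    for S in score_tables:
        if S.shape != known_dti.shape:
            raise ValueError("score table shape mismatch")
        per_drug = []
        for d in range(n_drug):
            targets = np.flatnonzero(unknown[d])
            order = np.lexsort((targets, -S[d, targets]))
            per_drug.append(targets[order][:m_prime])
        tables.append(CandidateTable(candidates=per_drug))
    return tables


def aggregate_candidates(tables: list[CandidateTable]) -> list[list[tuple[int, int, float]]]:
    """Per drug: (target, occurrence count, mean within-table rank) triples,
    ordered by count desc, mean rank asc, target index asc."""
    if not tables:
        return []
    n_drug = len(tables[0].candidates)
    out = []
    for d in range(n_drug):
        counts: dict[int, int] = defaultdict(int)
        rank_sum: dict[int, float] = defaultdict(float)
        for tab in tables:
            for rank, t in enumerate(tab.candidates[d]):
                counts[int(t)] += 1
                rank_sum[int(t)] += rank
        triples = [(t, c, rank_sum[t] / c) for t, c in counts.items()]
        triples.sort(key=lambda x: (-x[1], x[2], x[0]))
        out.append(triples)
    return out


def hit_count(tables: list[CandidateTable], new_dti_set: set[tuple[int, int]],
              m: int) -> int:
    """Size of the intersection of the top-m-per-drug prediction set (ranked
    by occurrence count across tables) with a set of newly confirmed DTIs."""
    if m < 1:
        raise ValueError("m must be >= 1")
    hits = 0
    for d, triples in enumerate(aggregate_candidates(tables)):
        for t, _, _ in triples[:m]:
            if (d, t) in new_dti_set:
                hits += 1
    return hits
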