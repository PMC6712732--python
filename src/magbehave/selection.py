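"""Univariate filter-method feature ranking and descriptor selection.

One feature is chosen per biomechanical descriptor: posture is served by
the only posture candidate (meanRoll); the movement-intensity candidate
must separate both static-vs-dynamic and foraging-vs-running; the
periodicity candidate must separate foraging-vs-running.  Each candidate
is scored univariately with five two-sample separability criteria and
winners are decided by majority vote across criteria.

Criteria (all "larger = more separable"):

* ``ttest``          — |Welch two-sample t statistic|
* ``entropy``        — symmetric Kullback–Leibler divergence between
                       Gaussian fits to the two classes
* ``bhattacharyya``  — Bhattacharyya distance between Gaussian fits
* ``roc``            — |AUC − 0.5| of the feature as a score
* ``wilcoxon``       — |z| of the normal-approximated rank-sum statistic
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DYNAMIC_BEHAVIOURS, STATIC_BEHAVIOURS, ValidationError

__all__ = [
    "CRITERIA",
    "INTENSITY_CANDIDATES",
    "PERIODICITY_CANDIDATES",
    "Ranking",
    "rank_features",
    "select_descriptor_features",
]

#: Criterion order is also the documented tie-break order.
CRITERIA: tuple[str, ...] = ("ttest", "entropy", "bhattacharyya", "roc", "wilcoxon")

INTENSITY_CANDIDATES: tuple[str, ...] = (
    "stdRoll", "meanAbsDiffRoll", "axMaxMeanAbsDiff", "avgMeanAbsDiff")
PERIODICITY_CANDIDATES: tuple[str, ...] = (
    "rollFftPeakPower", "avgFftPeakPower", "rollDiffFftPeakPower",
    "avgDiffFftPeakPower")

_EPS = 1e-12


def _moments(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), max(float(np.std(x, ddof=1)), _EPS)


def _score_ttest(x0, x1) -> float:
    return abs(float(stats.ttest_ind(x0, x1, equal_var=False).statistic))


def _score_entropy(x0, x1) -> float:
    # symmetric KL between N(m0, s0²) and N(m1, s1²)
    m0, s0 = _moments(x0)
    m1, s1 = _moments(x1)
    v0, v1 = s0 * s0, s1 * s1
    dm2 = (m0 - m1) ** 2
    kl01 = 0.5 * (v0 / v1 + dm2 / v1 - 1.0 + np.log(v1 / v0))
    kl10 = 0.5 * (v1 / v0 + dm2 / v0 - 1.0 + np.log(v0 / v1))
    return float(0.5 * (kl01 + kl10))


def _score_bhattacharyya(x0, x1) -> float:
    m0, s0 = _moments(x0)
    m1, s1 = _moments(x1)
    v0, v1 = s0 * s0, s1 * s1
    vbar = 0.5 * (v0 + v1)
    return float((m0 - m1) ** 2 / (8.0 * vbar) + 0.5 * np.log(vbar / np.sqrt(v0 * v1)))


def _auc(x0, x1) -> float:
    u = stats.mannwhitneyu(x1, x0, alternative="two-sided").statistic
    return float(u) / (len(x0) * len(x1))


def _score_roc(x0, x1) -> float:
    return abs(_auc(x0, x1) - 0.5)


def _score_wilcoxon(x0, x1) -> float:
    n0, n1 = len(x0), len(x1)
    u = stats.mannwhitneyu(x1, x0, alternative="two-sided").statistic
    mu = n0 * n1 / 2.0
    sd = np.sqrt(n0 * n1 * (n0 + n1 + 1) / 12.0)
    return abs((float(u) - mu) / sd)


_SCORERS = {
    "ttest": _score_ttest,
    "entropy": _score_entropy,
    "bhattacharyya": _score_bhattacharyya,
    "roc": _score_roc,
    "wilcoxon": _score_wilcoxon,
}

#: Named binary tasks: (positive-group labels, negative-group labels).
TASKS: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "static_dynamic": (frozenset(STATIC_BEHAVIOURS), frozenset(DYNAMIC_BEHAVIOURS)),
    "foraging_running": (frozenset({"foraging"}), frozenset({"running"})),
}


@dataclass(frozen=True)
class Ranking:
    """Separability ranking of candidate features under one criterion."""

    criterion: str
    features: tuple[str, ...]  # best first
    scores: dict[str, float]

    @property
    def best(self) -> str:
        return self.features[0]


def _task_groups(task) -> tuple[frozenset[str], frozenset[str]]:
    if isinstance(task, str):
        if task not in TASKS:
            raise ValidationError(f"unknown task {task!r}; options: {sorted(TASKS)}")
        return TASKS[task]
    a, b = task
    wrap = lambda g: frozenset({g}) if isinstance(g, str) else frozenset(g)
    return wrap(a), wrap(b)


def rank_features(fm: pd.DataFrame, task, criterion: str,
                  candidates: tuple[str, ...] | None = None) -> Ranking:
    """Rank candidate features by two-class separability.

    ``task`` is a named task (``"static_dynamic"``, ``"foraging_running"``)
    or a pair of label groups.  Ties are broken lexicographically, so the
    ordering is deterministic.
    """
    if criterion not in _SCORERS:
        raise ValidationError(f"unknown criterion {criterion!r}; options: {CRITERIA}")
    group0, group1 = _task_groups(task)
    labels = fm["label"].to_numpy()
    mask0 = np.isin(labels, list(group0))
    mask1 = np.isin(labels, list(group1))
    if mask0.sum() < 2 or mask1.sum() < 2:
        raise ValidationError(
            f"both classes need >= 2 windows (got {mask0.sum()} vs {mask1.sum()})")
    if candidates is None:
        meta = {"label", "session_id", "individual_id", "start_time"}
        candidates = tuple(c for c in fm.columns if c not in meta)
    scorer = _SCORERS[criterion]
    scores = {}
    for name in candidates:
        x = fm[name].to_numpy(dtype=float)
        scores[name] = float(scorer(x[mask0], x[mask1]))
        if not np.isfinite(scores[name]):
            raise ValidationError(f"non-finite score for feature {name!r}")
    ordered = tuple(sorted(scores, key=lambda n: (-scores[n], n)))
    return Ranking(criterion=criterion, features=ordered, scores=scores)


def _majority_winner(fm: pd.DataFrame, task, candidates: tuple[str, ...]) -> str:
    """Feature winning the most of the five criteria on one task."""
    if len(candidates) == 1:
        return candidates[0]
    votes: dict[str, int] = {c: 0 for c in candidates}
    first_win: dict[str, int] = {}
    for i, criterion in enumerate(CRITERIA):
        best = rank_features(fm, task, criterion, candidates).best
        votes[best] += 1
        first_win.setdefault(best, i)
    # tie-break: earliest criterion win in the documented order, then name
    return min(votes, key=lambda c: (-votes[c], first_win.get(c, len(CRITERIA)), c))


def select_descriptor_features(fm: pd.DataFrame,
                               intensity_candidates: tuple[str, ...] = INTENSITY_CANDIDATES,
                               periodicity_candidates: tuple[str, ...] = PERIODICITY_CANDIDATES,
                               ) -> dict[str, str]:
    """Choose one feature per biomechanical descriptor.

    Posture is meanRoll by default (the only posture candidate).  The
    intensity winner is the majority winner on the static-vs-dynamic
    task; if the foraging-vs-running task disagrees, the static/dynamic
    choice takes precedence (it feeds the upstream node).  The
    periodicity winner is the majority winner on foraging-vs-running.
    """
    intensity_sd = _majority_winner(fm, "static_dynamic", intensity_candidates)
    return {
        "posture": "meanRoll",
        "intensity": intensity_sd,
        "periodicity": _majority_winner(fm, "foraging_running", periodicity_candidates),
    }
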