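"""Cost-sensitive best-subset selection of screening elements.

Missing malnutrition is costlier than over-flagging, and missing severe
malnutrition is costlier still.  Each candidate rule — the OR of a
subset of daily screen elements — is charged a weighted misclassification
penalty: 1, 3 and 5 per missed mild, moderate and severe case, and 0.2
per patient flagged who has no malnutrition.  The subset with the lowest
penalty wins.  In ``moderate_severe`` mode mild cases join the negative
class: a flagged mild (or none) patient costs the false-positive weight
and a missed mild case costs nothing.

With the merged anthropometric element there are 7 daily elements, i.e.
127 nonempty subsets; the search is exhaustive up to 20 elements.
Status-change elements are excluded from the vocabulary by default
because they fire too rarely to inform selection; pass
``include_status_change=True`` to re-admit them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

from .cohort import PatientRecord
from .diagnostics import (
    DiagnosticMetrics,
    PositiveClass,
    SeverityConfusion,
    confusion,
    metrics,
)
from .engine import ALL_ELEMENTS, DAILY_ELEMENTS, aggregate

EXHAUSTIVE_CAP = 20

Mode = PositiveClass  # "any_malnutrition" | "moderate_severe"


@dataclass(frozen=True)
class PenaltyWeights:
    """Misclassification penalties (defaults 1 / 3 / 5 / 0.2)."""

    miss_mild: float = 1.0
    miss_moderate: float = 3.0
    miss_severe: float = 5.0
    false_positive: float = 0.2

    def __post_init__(self) -> None:
        if min(self.miss_mild, self.miss_moderate, self.miss_severe,
               self.false_positive) < 0:
            raise ValueError("penalty weights must be nonnegative")


def penalty_score(
    conf: SeverityConfusion,
    weights: PenaltyWeights = PenaltyWeights(),
    mode: Mode = "any_malnutrition",
) -> float:
    """Weighted prediction-quality penalty for one confusion layout.

    any_malnutrition:  w_mild*FN_mild + w_mod*FN_mod + w_sev*FN_sev
                       + w_fp*FP_none
    moderate_severe:   w_mod*FN_mod + w_sev*FN_sev
                       + w_fp*(FP_none + FP_mild)
    """
    fn = conf.neg_by_severity
    fp = conf.pos_by_severity
    if mode == "any_malnutrition":
        return (
            weights.miss_mild * fn["mild"]
            + weights.miss_moderate * fn["moderate"]
            + weights.miss_severe * fn["severe"]
            + weights.false_positive * fp["none"]
        )
    if mode == "moderate_severe":
        return (
            weights.miss_moderate * fn["moderate"]
            + weights.miss_severe * fn["severe"]
            + weights.false_positive * (fp["none"] + fp["mild"])
        )
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class CandidateModel:
    """One scored subset: elements, penalty, confusion and metrics."""

    elements: tuple[str, ...]
    score: float
    confusion: SeverityConfusion
    metrics: DiagnosticMetrics

    @property
    def size(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class SelectionResult:
    """Best model(s) per subset size and overall; ties are all kept."""

    per_size_best: Mapping[int, tuple[CandidateModel, ...]]
    global_best: tuple[CandidateModel, ...]
    mode: Mode
    vocabulary: tuple[str, ...]
    all_models: tuple[CandidateModel, ...] = field(repr=False, default=())


def enumerate_models(
    cohort: Sequence[PatientRecord],
    vocabulary: Sequence[str] | None = None,
    weights: PenaltyWeights = PenaltyWeights(),
    mode: Mode = "any_malnutrition",
    include_status_change: bool = False,
    tie_tol: float = 1e-9,
) -> SelectionResult:
    """Exhaustively score every nonempty element subset on the cohort.

    Only assessed patients enter the confusion counts.  Subsets are
    visited in (size, lexicographic) order, which also fixes the order
    of reported ties.
    """
    if vocabulary is None:
        vocabulary = ALL_ELEMENTS if include_status_change else DAILY_ELEMENTS
    vocab = tuple(sorted(set(vocabulary)))
    if not vocab:
        raise ValueError("element vocabulary must be nonempty")
    if len(vocab) > EXHAUSTIVE_CAP:
        raise ValueError(
            f"{len(vocab)} elements exceed the exhaustive cap of "
            f"{EXHAUSTIVE_CAP}; prune the vocabulary or use a greedy search"
        )
    assessed = [r for r in cohort if r.assessed]
    if not assessed:
        raise ValueError("cohort contains no assessed patients")

    # element -> per-patient boolean column, computed once
    columns = {
        e: [r.elements[e] for r in assessed] for e in vocab
    }

    all_models: list[CandidateModel] = []
    for size in range(1, len(vocab) + 1):
        for subset in combinations(vocab, size):
            preds = [any(columns[e][i] for e in subset)
                     for i in range(len(assessed))]
            conf = confusion(assessed, preds)
            all_models.append(
                CandidateModel(
                    elements=subset,
                    score=penalty_score(conf, weights, mode),
                    confusion=conf,
                    metrics=metrics(conf, mode),
                )
            )

    per_size: dict[int, tuple[CandidateModel, ...]] = {}
    for size in range(1, len(vocab) + 1):
        models = [m for m in all_models if m.size == size]
        best = min(m.score for m in models)
        per_size[size] = tuple(m for m in models if m.score <= best + tie_tol)
    best_overall = min(m.score for m in all_models)
    global_best = tuple(
        m for m in all_models if m.score <= best_overall + tie_tol
    )
    return SelectionResult(
        per_size_best=per_size,
        global_best=global_best,
        mode=mode,
        vocabulary=vocab,
        all_models=tuple(all_models),
    )


def _fmt_metric(x: float | None) -> str:
    return "NA" if x is None else f"{x:.3f}"


def selection_report(result: SelectionResult) -> list[dict[str, str]]:
    """Best-model-per-size rows: N, Score, variables, and the four metrics."""
    rows = []
    for size in sorted(result.per_size_best):
        for model in result.per_size_best[size]:
            m = model.metrics
            rows.append(
                {
                    "N": str(size),
                    "Score": f"{model.score:.1f}",
                    "Screening Variables": ", ".join(model.elements),
                    "Sensitivity": _fmt_metric(m.sensitivity),
                    "Specificity": _fmt_metric(m.specificity),
                    "PPV": _fmt_metric(m.ppv),
                    "NPV": _fmt_metric(m.npv),
                }
            )
    return rows
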