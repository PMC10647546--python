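"""Severity-stratified diagnostic accuracy and exact 2x2 association tests.

Screen predictions are cross-classified against the four-level ordinal
malnutrition scale (none/mild/moderate/severe).  Two dichotomies matter
downstream: *any malnutrition* (none vs the rest) and *moderate/severe
only* (none and mild grouped as negative).  The stored counts are always
by the full scale; the dichotomy only governs how metrics collapse them.

Sensitivity, specificity, PPV and NPV with zero denominators are
``None`` (undefined), never silently 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import scipy.stats

from .cohort import PatientRecord
from .engine import ALL_ELEMENTS, ELEMENT_LABELS
from .fixtures import SEVERITY_LEVELS

PositiveClass = Literal["any_malnutrition", "moderate_severe"]

#: severities counted as disease-positive under each dichotomy
_POSITIVE_SEVERITIES: Mapping[str, tuple[str, ...]] = {
    "any_malnutrition": ("mild", "moderate", "severe"),
    "moderate_severe": ("moderate", "severe"),
}


@dataclass(frozen=True)
class SeverityConfusion:
    """Screen-positive/negative counts per malnutrition severity."""

    pos_by_severity: Mapping[str, int]
    neg_by_severity: Mapping[str, int]

    def __post_init__(self) -> None:
        for d in (self.pos_by_severity, self.neg_by_severity):
            if set(d) != set(SEVERITY_LEVELS):
                raise ValueError("confusion must cover all four severities")
            if any(v < 0 for v in d.values()):
                raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return sum(self.pos_by_severity.values()) + sum(
            self.neg_by_severity.values()
        )

    def stratum_total(self, severity: str) -> int:
        return self.pos_by_severity[severity] + self.neg_by_severity[severity]

    def dichotomize(self, positive_class: PositiveClass) -> tuple[int, int, int, int]:
        """Return (TP, FN, FP, TN) under the chosen dichotomy."""
        pos_sev = _POSITIVE_SEVERITIES[positive_class]
        tp = sum(self.pos_by_severity[s] for s in pos_sev)
        fn = sum(self.neg_by_severity[s] for s in pos_sev)
        neg_sev = tuple(s for s in SEVERITY_LEVELS if s not in pos_sev)
        fp = sum(self.pos_by_severity[s] for s in neg_sev)
        tn = sum(self.neg_by_severity[s] for s in neg_sev)
        return tp, fn, fp, tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV; None marks an undefined ratio."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; rows = stratum (exposed first), cols = (positive, negative)."""

    a: int  # exposed, positive
    b: int  # exposed, negative
    c: int  # unexposed, positive
    d: int  # unexposed, negative

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table must have a positive total")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def confusion(
    cohort: Sequence[PatientRecord],
    predictions: Sequence[bool],
) -> SeverityConfusion:
    """Cross-classify per-patient screen predictions by severity.

    Only assessed patients (known severity) are admissible; an unknown
    severity in the input is a data error, not a silent drop.
    """
    if len(predictions) != len(cohort):
        raise ValueError("predictions must align 1:1 with the cohort")
    pos = {s: 0 for s in SEVERITY_LEVELS}
    neg = {s: 0 for s in SEVERITY_LEVELS}
    for record, pred in zip(cohort, predictions):
        if record.severity not in pos:
            raise ValueError(
                f"patient {record.patient_id} has unknown severity; "
                "confusion requires assessed patients"
            )
        (pos if pred else neg)[record.severity] += 1
    return SeverityConfusion(pos, neg)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(
    conf: SeverityConfusion, positive_class: PositiveClass = "any_malnutrition"
) -> DiagnosticMetrics:
    tp, fn, fp, tn = conf.dichotomize(positive_class)
    return DiagnosticMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: mass of tables (at fixed margins) no more
    probable than the observed one, the convention of mainstream
    statistical software."""
    p = scipy.stats.fisher_exact(table.as_array(), alternative="two-sided")[1]
    return float(min(p, 1.0))


def element_table(
    cohort: Sequence[PatientRecord],
    element_name: str,
    stratification: Literal["no_vs_any", "assessed_vs_not"] = "no_vs_any",
) -> ContingencyTable2x2:
    """2x2 table for one element under the requested stratification.

    ``no_vs_any`` restricts to assessed patients and strata by the
    malnutrition dichotomy (malnourished = exposed row); the per-element
    pseudo-cohorts from the bundled fixture reproduce the published
    stratified counts through this function.  ``assessed_vs_not`` uses
    the whole cohort with assessed as the exposed row.
    """
    if element_name not in ALL_ELEMENTS:
        raise KeyError(f"unknown screen element: {element_name!r}")
    if stratification == "no_vs_any":
        sub = [r for r in cohort if r.assessed]
        exposed = [r for r in sub if r.malnourished]
        unexposed = [r for r in sub if not r.malnourished]
    elif stratification == "assessed_vs_not":
        exposed = [r for r in cohort if r.assessed]
        unexposed = [r for r in cohort if not r.assessed]
    else:
        raise ValueError(f"unknown stratification {stratification!r}")
    a = sum(r.elements[element_name] for r in exposed)
    c = sum(r.elements[element_name] for r in unexposed)
    return ContingencyTable2x2(a, len(exposed) - a, c, len(unexposed) - c)


# ---------------------------------------------------------------------------
# Report rendering


def format_count_percent(count: int, total: int) -> str:
    """``"56 (22.4%)"``-style cell; zero counts render as ``"0 (0%)"``."""
    if total == 0:
        return f"{count} (--)"
    if count == 0:
        return "0 (0%)"
    return f"{count} ({100.0 * count / total:.1f}%)"


def format_p(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    if p > 0.999:
        return ">0.999"
    return f"{p:.3f}"


def assessed_report(
    cohorts_by_element: Mapping[str, Sequence[PatientRecord]],
    any_positive_counts: tuple[int, int] | None = None,
) -> list[dict[str, str]]:
    """Stratified positivity report for the assessed cohort.

    ``cohorts_by_element`` maps element name to the (pseudo-)cohort used
    for that element's row — the per-element fixture expansion, or the
    same full cohort repeated for every element.  Optionally prepends an
    any-positive-screen row from ``(count_no_malnutrition, count_any)``.
    """
    rows: list[dict[str, str]] = []

    def make_row(label: str, tab: ContingencyTable2x2) -> dict[str, str]:
        n1, n0 = tab.a + tab.b, tab.c + tab.d
        return {
            "variable": label,
            "total": format_count_percent(tab.a + tab.c, n0 + n1),
            "no_malnutrition": format_count_percent(tab.c, n0),
            "any_malnutrition": format_count_percent(tab.a, n1),
            "p_value": format_p(fisher_exact(tab)),
        }

    if any_positive_counts is not None:
        some_cohort = next(iter(cohorts_by_element.values()))
        assessed = [r for r in some_cohort if r.assessed]
        n1 = sum(r.malnourished for r in assessed)
        n0 = len(assessed) - n1
        k0, k1 = any_positive_counts
        rows.append(
            make_row(
                "Any positive screen",
                ContingencyTable2x2(k1, n1 - k1, k0, n0 - k0),
            )
        )
    for name, cohort in cohorts_by_element.items():
        rows.append(make_row(ELEMENT_LABELS[name], element_table(cohort, name)))
    return rows


def unassessed_report(
    cohort: Sequence[PatientRecord],
    elements: Iterable[str] = ALL_ELEMENTS,
) -> list[dict[str, str]]:
    """Marginal positivity report for patients without an assessment."""
    sub = [r for r in cohort if not r.assessed]
    n = len(sub)
    rows = []
    any_pos = sum(
        any(r.elements[e] for e in ALL_ELEMENTS) for r in sub
    )
    rows.append(
        {"variable": "Any positive screen", "total": format_count_percent(any_pos, n)}
    )
    for name in elements:
        k = sum(r.elements[name] for r in sub)
        rows.append(
            {"variable": ELEMENT_LABELS[name], "total": format_count_percent(k, n)}
        )
    return rows


def rows_to_tsv(rows: Sequence[Mapping[str, str]]) -> str:
    if not rows:
        return ""
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    lines += ["\t".join(str(r[c]) for c in cols) for r in rows]
    return "\n".join(lines) + "\n"


def rows_to_text(rows: Sequence[Mapping[str, str]]) -> str:
    """Aligned fixed-width rendering of a report table."""
    if not rows:
        return ""
    cols = list(rows[0])
    widths = {c: max(len(c), *(len(str(r[c])) for r in rows)) for c in cols}
    def fmt(vals: Iterable[str]) -> str:
        return "  ".join(str(v).ljust(widths[c]) for c, v in zip(cols, vals))
    lines = [fmt(cols), fmt("-" * widths[c] for c in cols)]
    lines += [fmt(r[c] for c in cols) for r in rows]
    return "\n".join(lines) + "\n"
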