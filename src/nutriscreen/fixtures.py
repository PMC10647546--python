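"""Bundled contingency-count fixtures for the assessed and unassessed strata.

The study's patient-level data were never deposited; what survives are
per-element positivity counts stratified by malnutrition status for the
250 dietitian-assessed patients, and unstratified counts for the 918
patients never assessed.  These cell counts ship with the package so the
reporting and diagnostics layers can be exercised (and the synthetic
generator calibrated) without any download.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Any

from .engine import ALL_ELEMENTS

SEVERITY_LEVELS: tuple[str, ...] = ("none", "mild", "moderate", "severe")
UNKNOWN_SEVERITY = "unknown"


def _load(name: str) -> dict[str, Any]:
    with resources.files("nutriscreen.data").joinpath(name).open() as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def assessed_counts() -> dict[str, Any]:
    """Element counts for assessed patients, by malnutrition dichotomy."""
    fx = _load("assessed_counts.json")
    _validate_assessed(fx)
    return fx


@lru_cache(maxsize=None)
def unassessed_counts() -> dict[str, Any]:
    """Element counts for the never-assessed stratum."""
    fx = _load("unassessed_counts.json")
    n = fx["n_total"]
    for name, k in fx["elements"].items():
        if name not in ALL_ELEMENTS:
            raise ValueError(f"fixture element {name!r} not in vocabulary")
        if not (0 <= k <= n):
            raise ValueError(f"fixture count {k} outside [0, {n}] for {name}")
    return fx


def _validate_assessed(fx: dict[str, Any]) -> None:
    n0, n1 = fx["n_no_malnutrition"], fx["n_any_malnutrition"]
    sev = fx["severity_counts"]
    if set(sev) != set(SEVERITY_LEVELS):
        raise ValueError("severity fixture must cover none/mild/moderate/severe")
    if sev["none"] != n0 or sum(sev.values()) != n0 + n1:
        raise ValueError("severity counts inconsistent with stratum totals")
    rows = dict(fx["elements"])
    rows["any_positive_screen"] = fx["any_positive_screen"]
    for name, row in rows.items():
        if name != "any_positive_screen" and name not in ALL_ELEMENTS:
            raise ValueError(f"fixture element {name!r} not in vocabulary")
        if not (0 <= row["no_malnutrition"] <= n0):
            raise ValueError(f"count outside stratum for {name}")
        if not (0 <= row["any_malnutrition"] <= n1):
            raise ValueError(f"count outside stratum for {name}")


def severity_probs() -> dict[str, float]:
    """Severity distribution among assessed patients, from the fixture."""
    fx = assessed_counts()
    total = sum(fx["severity_counts"].values())
    return {k: v / total for k, v in fx["severity_counts"].items()}


def assessed_element_rates() -> dict[str, tuple[float, float]]:
    """Per-element (rate | no malnutrition, rate | any malnutrition)."""
    fx = assessed_counts()
    n0, n1 = fx["n_no_malnutrition"], fx["n_any_malnutrition"]
    return {
        name: (row["no_malnutrition"] / n0, row["any_malnutrition"] / n1)
        for name, row in fx["elements"].items()
    }


def unassessed_element_rates() -> dict[str, float]:
    fx = unassessed_counts()
    n = fx["n_total"]
    return {name: k / n for name, k in fx["elements"].items()}
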