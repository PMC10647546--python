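"""Synthetic PICU cohort generator calibrated to the published strata.

The evaluation cohort this package targets is not publicly available, so
analyses run on synthetic cohorts with the same statistical skeleton: an
assessed stratum whose malnutrition severity follows the published
181/27/24/18 (none/mild/moderate/severe) split out of 250 and whose
screen-element positivity rates are conditioned on the malnutrition
dichotomy, plus an unassessed stratum (918 patients) with its own
marginal element rates and severity recorded as ``unknown``.

Element rates condition on the dichotomy none-vs-any only — that is the
granularity the published stratified counts provide; per-grade rates can
be supplied via ``severity_element_rates`` when a scenario needs them.

Within-patient dependence between elements is optional: a per-patient
latent standard-logistic factor is added to each element's log-odds with
loading ``sqrt(rho/(1-rho))`` (so ``rho`` is the latent share of the
logit variance).  Each element's intercept is then solved numerically so
the configured marginal rate is preserved exactly; with ``rho = 0`` (the
default, matching the purely marginal published evidence) draws are
independent Bernoullis at the configured rates.

Randomness uses one master seed with per-stream children spawned by a
fixed counter scheme (``numpy.random.SeedSequence(seed, spawn_key=(k,))``),
so adding a stratum or stream never perturbs earlier draws:

====  =======================================
k     stream
====  =======================================
0     assessed severity draws
1     assessed latent factors
2     assessed element uniforms
3     assessed ages
4     unassessed latent factors
5     unassessed element uniforms
6     unassessed ages
====  =======================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import fixtures
from .engine import ALL_ELEMENTS, ScreenElementVector
from .fixtures import SEVERITY_LEVELS, UNKNOWN_SEVERITY


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


class FixtureError(ValueError):
    """Inconsistent contingency-count fixture."""


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults reproduce the published strata."""

    n_assessed: int = 250
    n_unassessed: int = 918
    severity_probs: Mapping[str, float] = field(
        default_factory=fixtures.severity_probs
    )
    element_rates: Mapping[str, tuple[float, float]] = field(
        default_factory=fixtures.assessed_element_rates
    )
    unassessed_element_rates: Mapping[str, float] = field(
        default_factory=fixtures.unassessed_element_rates
    )
    #: optional per-grade override: severity -> element -> rate
    severity_element_rates: Mapping[str, Mapping[str, float]] | None = None
    dependence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assessed <= 0:
            raise ConfigurationError("n_assessed must be positive")
        if self.n_unassessed < 0:
            raise ConfigurationError("n_unassessed must be nonnegative")
        if set(self.severity_probs) != set(SEVERITY_LEVELS):
            raise ConfigurationError(
                "severity_probs must cover exactly none/mild/moderate/severe"
            )
        probs = list(self.severity_probs.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("severity probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ConfigurationError("severity_probs must sum to 1 within 1e-12")
        for name, pair in self.element_rates.items():
            if name not in ALL_ELEMENTS:
                raise ConfigurationError(f"unknown element {name!r}")
            for p in pair:
                if not (0.0 <= p <= 1.0):
                    raise ConfigurationError(f"rate for {name} outside [0, 1]")
        for name, p in self.unassessed_element_rates.items():
            if name not in ALL_ELEMENTS:
                raise ConfigurationError(f"unknown element {name!r}")
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"rate for {name} outside [0, 1]")
        if not (0.0 <= self.dependence < 1.0):
            raise ConfigurationError("dependence must lie in [0, 1)")

    @property
    def element_names(self) -> tuple[str, ...]:
        """Elements in canonical vocabulary order."""
        return tuple(e for e in ALL_ELEMENTS if e in self.element_rates)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: demographics, assessed status, severity, element states."""

    patient_id: str
    age_years: float
    corrected_age_years: float
    severity: str
    assessed: bool
    elements: ScreenElementVector

    def __post_init__(self) -> None:
        valid = set(SEVERITY_LEVELS) | {UNKNOWN_SEVERITY}
        if self.severity not in valid:
            raise ValueError(f"invalid severity {self.severity!r}")
        if self.assessed and self.severity == UNKNOWN_SEVERITY:
            raise ValueError("assessed patients must carry a known severity")
        if not self.assessed and self.severity != UNKNOWN_SEVERITY:
            raise ValueError("unassessed patients carry severity 'unknown'")
        if self.corrected_age_years > self.age_years:
            raise ValueError("corrected age cannot exceed chronological age")

    @property
    def malnourished(self) -> bool:
        return self.severity in ("mild", "moderate", "severe")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def latent_loading(dependence: float) -> float:
    """Loading on the standard-logistic latent factor for a given rho."""
    return math.sqrt(dependence / (1.0 - dependence))


@lru_cache(maxsize=4096)
def _calibrated_intercept(p: float, lam: float) -> float:
    """Intercept c with E_u[expit(c + lam*u)] = p, u ~ standard logistic."""
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    if lam == 0.0:
        return float(logit(p))

    def marginal(c: float) -> float:
        # expectation over the standard-logistic latent factor
        def integrand(u: float) -> float:
            pdf = expit(u) * expit(-u)
            return expit(c + lam * u) * pdf

        val, _ = quad(integrand, -60.0, 60.0, limit=200)
        return val

    lo, hi = logit(p) - 10 * (1 + lam), logit(p) + 10 * (1 + lam)
    return float(brentq(lambda c: marginal(c) - p, lo, hi, xtol=1e-12))


def _draw_elements(
    probs: np.ndarray,  # (n_patients, n_elements) marginal rates
    lam: float,
    latent: np.ndarray,  # (n_patients,)
    uniforms: np.ndarray,  # (n_patients, n_elements)
) -> np.ndarray:
    if lam == 0.0:
        return uniforms < probs
    cond = np.empty_like(probs)
    for j in range(probs.shape[1]):
        for p in np.unique(probs[:, j]):
            c = _calibrated_intercept(float(p), lam)
            mask = probs[:, j] == p
            if math.isinf(c):
                cond[mask, j] = 0.0 if c < 0 else 1.0
            else:
                cond[mask, j] = expit(c + lam * latent[mask])
    return uniforms < cond


def _draw_ages(
    rng: np.random.Generator, n: int, median: float, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Lognormal ages clipped to [0.01, 17], plus corrected ages.

    A prematurity correction (up to ~4 months) is applied to 10% of
    children under two; corrected age never exceeds chronological age.
    """
    age = np.clip(rng.lognormal(math.log(median), sigma, size=n), 0.01, 17.0)
    correction = np.where(
        (age < 2.0) & (rng.random(n) < 0.10),
        rng.uniform(0.0, 16.0 / 52.0, size=n),
        0.0,
    )
    corrected = np.clip(age - correction, 0.0, None)
    return age, corrected


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate the assessed + unassessed strata; deterministic in seed."""
    lam = latent_loading(config.dependence)
    names = config.element_names
    records: list[PatientRecord] = []

    # --- assessed stratum ---
    n = config.n_assessed
    sev_rng = _rng(config.seed, 0)
    probs = np.array([config.severity_probs[s] for s in SEVERITY_LEVELS])
    sev_idx = sev_rng.choice(len(SEVERITY_LEVELS), size=n, p=probs)
    severities = [SEVERITY_LEVELS[i] for i in sev_idx]

    latent = _rng(config.seed, 1).logistic(size=n)
    uniforms = _rng(config.seed, 2).random((n, len(names)))
    rate_mat = np.empty((n, len(names)))
    for j, name in enumerate(names):
        p0, p1 = config.element_rates[name]
        for i, sev in enumerate(severities):
            if config.severity_element_rates is not None and sev in (
                config.severity_element_rates
            ) and name in config.severity_element_rates[sev]:
                rate_mat[i, j] = config.severity_element_rates[sev][name]
            else:
                rate_mat[i, j] = p0 if sev == "none" else p1
    flags = _draw_elements(rate_mat, lam, latent, uniforms)
    age, corrected = _draw_ages(_rng(config.seed, 3), n, median=2.0, sigma=1.31)

    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"A{i + 1:05d}",
                age_years=float(age[i]),
                corrected_age_years=float(corrected[i]),
                severity=severities[i],
                assessed=True,
                elements=ScreenElementVector(
                    **{name: bool(flags[i, j]) for j, name in enumerate(names)}
                ),
            )
        )

    # --- unassessed stratum ---
    m = config.n_unassessed
    if m:
        u_names = tuple(
            e for e in ALL_ELEMENTS if e in config.unassessed_element_rates
        )
        latent_u = _rng(config.seed, 4).logistic(size=m)
        uniforms_u = _rng(config.seed, 5).random((m, len(u_names)))
        rate_u = np.tile(
            np.array([config.unassessed_element_rates[e] for e in u_names]), (m, 1)
        )
        flags_u = _draw_elements(rate_u, lam, latent_u, uniforms_u)
        age_u, corrected_u = _draw_ages(
            _rng(config.seed, 6), m, median=4.0, sigma=0.97
        )
        for i in range(m):
            records.append(
                PatientRecord(
                    patient_id=f"U{i + 1:05d}",
                    age_years=float(age_u[i]),
                    corrected_age_years=float(corrected_u[i]),
                    severity=UNKNOWN_SEVERITY,
                    assessed=False,
                    elements=ScreenElementVector(
                        **{e: bool(flags_u[i, j]) for j, e in enumerate(u_names)}
                    ),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Contingency-fixture expansion


def expand_contingency_fixture(
    fixture: Mapping | None = None,
) -> dict[str, list[PatientRecord]]:
    """Expand stratified cell counts into per-element pseudo-cohorts.

    For each element the returned pseudo-cohort's 2x2 table (malnutrition
    dichotomy x element state) equals the fixture counts exactly.  Joint
    structure across elements is *not* claimed: each element gets its own
    pseudo-cohort, with positives assigned from the start of each stratum
    and severities among malnourished patients assigned in fixed blocks.
    """
    fx = dict(fixture) if fixture is not None else dict(fixtures.assessed_counts())
    n0 = int(fx["n_no_malnutrition"])
    n1 = int(fx["n_any_malnutrition"])
    sev_counts = fx.get("severity_counts")
    if sev_counts is not None:
        graded = {k: int(v) for k, v in sev_counts.items() if k != "none"}
        if sum(graded.values()) != n1:
            raise FixtureError("graded severity counts must sum to the stratum")
    else:
        graded = {"mild": n1}
    sev_labels = [s for s in ("mild", "moderate", "severe") for _ in
                  range(graded.get(s, 0))]

    out: dict[str, list[PatientRecord]] = {}
    for name, row in fx["elements"].items():
        k0, k1 = int(row["no_malnutrition"]), int(row["any_malnutrition"])
        if not (0 <= k0 <= n0 and 0 <= k1 <= n1):
            raise FixtureError(f"cell count exceeds stratum total for {name!r}")
        recs: list[PatientRecord] = []
        for i in range(n1):
            recs.append(
                PatientRecord(
                    patient_id=f"{name}-M{i + 1:04d}",
                    age_years=1.0,
                    corrected_age_years=1.0,
                    severity=sev_labels[i],
                    assessed=True,
                    elements=ScreenElementVector(**{name: i < k1}),
                )
            )
        for i in range(n0):
            recs.append(
                PatientRecord(
                    patient_id=f"{name}-N{i + 1:04d}",
                    age_years=1.0,
                    corrected_age_years=1.0,
                    severity="none",
                    assessed=True,
                    elements=ScreenElementVector(**{name: i < k0}),
                )
            )
        out[name] = recs
    return out


# ---------------------------------------------------------------------------
# Delimited-text I/O

_META_COLUMNS = ("patient_id", "age_years", "corrected_age_years",
                 "assessed", "severity")


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age_years": r.age_years,
            "corrected_age_years": r.corrected_age_years,
            "assessed": int(r.assessed),
            "severity": r.severity,
        }
        row.update({k: int(v) for k, v in r.elements.to_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(ALL_ELEMENTS))


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    missing = set(_META_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    element_cols = [c for c in frame.columns if c in ALL_ELEMENTS]
    records = []
    for _, row in frame.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age_years=float(row["age_years"]),
                corrected_age_years=float(row["corrected_age_years"]),
                severity=str(row["severity"]),
                assessed=bool(int(row["assessed"])),
                elements=ScreenElementVector(
                    **{c: bool(int(row[c])) for c in element_cols}
                ),
            )
        )
    return records


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    cohort_to_frame(records).to_csv(path, sep=sep, index=False)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return frame_to_cohort(
        pd.read_csv(path, sep=sep, float_precision="round_trip")
    )


def config_from_dict(d: Mapping) -> CohortConfig:
    """Build a config from a parsed YAML/JSON mapping; missing keys default."""
    kwargs = dict(d)
    if "element_rates" in kwargs:
        kwargs["element_rates"] = {
            k: tuple(v) for k, v in kwargs["element_rates"].items()
        }
    try:
        return CohortConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
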