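"""End-to-end pipeline: cohort -> reports -> selection -> summary bundle.

A run resolves its cohort from exactly one source (synthetic generator,
delimited-text file, or the bundled contingency fixture), emits the
stratified positivity reports, the best-subset selection tables for each
requested dichotomy, and a screen-vs-PNST comparison, plus a
machine-readable JSON summary from which every number in the
human-readable tables is recomputable.  A manifest records the config,
seed and content hash of every artifact; identical config + seed yields
a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

from . import cohort as cohort_mod
from . import diagnostics as diag
from . import selection as sel
from .cohort import CohortConfig, PatientRecord
from .engine import ALL_ELEMENTS
from .fixtures import SEVERITY_LEVELS, assessed_counts

log = logging.getLogger(__name__)

CohortSource = Literal["synthetic", "file", "fixture"]


@dataclass(frozen=True)
class PipelineConfig:
    cohort_source: CohortSource = "synthetic"
    cohort_config: CohortConfig | None = None
    cohort_path: str | None = None
    weights: sel.PenaltyWeights = field(default_factory=sel.PenaltyWeights)
    modes: tuple[sel.Mode, ...] = ("any_malnutrition", "moderate_severe")
    output_dir: str = "nutriscreen_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cohort_source == "file" and not self.cohort_path:
            raise ValueError("cohort_source 'file' requires cohort_path")
        if self.cohort_source != "file" and self.cohort_path:
            raise ValueError("cohort_path only applies to cohort_source 'file'")


def _metrics_block(conf: diag.SeverityConfusion) -> dict:
    out: dict = {"counts": {
        "pos_by_severity": dict(conf.pos_by_severity),
        "neg_by_severity": dict(conf.neg_by_severity),
    }}
    for mode in ("any_malnutrition", "moderate_severe"):
        out[mode] = diag.metrics(conf, mode).as_dict()
    return out


def screen_comparison(cohort: Sequence[PatientRecord]) -> dict:
    """Full-screen (all elements, OR rule) versus PNST alone."""
    assessed = [r for r in cohort if r.assessed]
    full = [any(r.elements[e] for e in ALL_ELEMENTS) for r in assessed]
    pnst = [r.elements["pnst_positive"] for r in assessed]
    return {
        "full_screen": _metrics_block(diag.confusion(assessed, full)),
        "pnst_alone": _metrics_block(diag.confusion(assessed, pnst)),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the summary and writes the bundle."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "cohort_source": config.cohort_source}
    written: list[Path] = []

    log.info("resolving cohort from source %r", config.cohort_source)
    if config.cohort_source == "fixture":
        pseudo = cohort_mod.expand_contingency_fixture()
        fx = assessed_counts()
        any_pos = (
            fx["any_positive_screen"]["no_malnutrition"],
            fx["any_positive_screen"]["any_malnutrition"],
        )
        rows = diag.assessed_report(pseudo, any_positive_counts=any_pos)
        cohort: list[PatientRecord] = []
        summary["severity_counts"] = dict(fx["severity_counts"])
    else:
        if config.cohort_source == "synthetic":
            cc = config.cohort_config or CohortConfig(seed=config.seed)
            if config.cohort_config is None:
                cc = dataclasses.replace(cc, seed=config.seed)
            cohort = cohort_mod.generate_cohort(cc)
            path = out_dir / "cohort.csv"
            cohort_mod.write_cohort(cohort, path)
            written.append(path)
        else:
            cohort = cohort_mod.read_cohort(config.cohort_path)
        assessed = [r for r in cohort if r.assessed]
        pseudo = {e: assessed for e in ALL_ELEMENTS}
        rows = diag.assessed_report(
            pseudo,
            any_positive_counts=(
                sum(any(r.elements[e] for e in ALL_ELEMENTS)
                    for r in assessed if not r.malnourished),
                sum(any(r.elements[e] for e in ALL_ELEMENTS)
                    for r in assessed if r.malnourished),
            ),
        )
        summary["severity_counts"] = {
            s: sum(r.severity == s for r in assessed) for s in SEVERITY_LEVELS
        }

    log.info("writing stratified positivity report")
    for suffix, render in (("tsv", diag.rows_to_tsv), ("txt", diag.rows_to_text)):
        path = out_dir / f"assessed_report.{suffix}"
        path.write_text(render(rows))
        written.append(path)
    summary["assessed_report"] = rows

    if cohort and any(not r.assessed for r in cohort):
        urows = diag.unassessed_report(cohort)
        path = out_dir / "unassessed_report.tsv"
        path.write_text(diag.rows_to_tsv(urows))
        written.append(path)
        summary["unassessed_report"] = urows

    if cohort:
        summary["selection"] = {}
        for mode in config.modes:
            log.info("running exhaustive subset selection, mode=%s", mode)
            result = sel.enumerate_models(
                cohort, weights=config.weights, mode=mode
            )
            srows = sel.selection_report(result)
            path = out_dir / f"selection_{mode}.tsv"
            path.write_text(diag.rows_to_tsv(srows))
            written.append(path)
            summary["selection"][mode] = {
                "report": srows,
                "global_best": [
                    {"elements": list(m.elements), "score": m.score}
                    for m in result.global_best
                ],
                "all_models": [
                    {"elements": list(m.elements), "score": m.score,
                     **{k: v for k, v in m.metrics.as_dict().items()}}
                    for m in result.all_models
                ],
            }
        log.info("comparing full screen against PNST alone")
        summary["screen_comparison"] = screen_comparison(cohort)

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(summary_path)

    manifest = {
        "seed": config.seed,
        "cohort_source": config.cohort_source,
        "modes": list(config.modes),
        "weights": dataclasses.asdict(config.weights),
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(written)
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return summary
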