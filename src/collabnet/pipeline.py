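"""Top-level pipeline: simulate/ingest → metrics → compare → report → figures.

Driven by a JSON config with either a ``simulate`` block (synthetic
districts; fully self-contained) or a ``surveys`` block (paths to actor
attribute tables and tie lists).  Every design-decision branch that fires
along the way — dropped self-nominations, off-roster nominations, dropped
incomplete pairs, zero-variance tests — is logged.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd

from .core_model import MetricsReport, PrePostStudy, validate_network
from .prepost_stats import build_report
from .survey_ingest import load_study
from .synthetic_cohort import CohortConfig, generate_district
from .viz import SociogramStyle, render_sociogram

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Pipeline failure carrying the stage it happened in."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    if not path.exists():
        raise PipelineError("config", f"missing input path: {path}")
    return json.loads(path.read_text())


def _studies_from_config(config: dict, seed: Optional[int]) -> list[PrePostStudy]:
    if "simulate" in config:
        stage = "simulate"
        blocks = config["simulate"].get("districts", [config["simulate"]])
        studies = []
        for k, block in enumerate(blocks):
            params = {k: v for k, v in block.items()}
            params.setdefault("district", f"district-{k + 1}")
            if seed is not None:
                params["seed"] = int(seed) + k
            try:
                study, _ = generate_district(CohortConfig(**params))
            except (TypeError, ValueError) as exc:
                raise PipelineError(stage, str(exc)) from exc
            studies.append(study)
        return studies
    if "surveys" in config:
        stage = "ingest"
        studies = []
        for block in config["surveys"].get("districts", []):
            for key in ("actors", "ties"):
                if key not in block:
                    raise PipelineError(stage, f"survey block lacks {key!r} path")
                if not Path(block[key]).exists():
                    raise PipelineError(
                        stage, f"missing input path: {block[key]}"
                    )
            try:
                studies.append(
                    load_study(
                        block["actors"], block["ties"], block.get("district", "")
                    )
                )
            except ValueError as exc:
                raise PipelineError(stage, str(exc)) from exc
        if not studies:
            raise PipelineError(stage, "surveys block lists no districts")
        return studies
    raise PipelineError("config", "config needs a 'simulate' or 'surveys' block")


def run_pipeline(
    config: str | Path | dict,
    outdir: str | Path,
    seed: Optional[int] = None,
    figures: bool = True,
) -> MetricsReport:
    """Execute the full analysis; writes report tables, JSON and figures to
    ``outdir`` and returns the in-memory report."""
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = cfg.get("seed")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        studies = _studies_from_config(cfg, seed)
    for w in caught:
        logger.warning("ingest: %s", w.message)

    for study in studies:
        for network in (study.t0, study.t1):
            violations = validate_network(network)
            if violations:
                raise PipelineError(
                    "validate",
                    f"{network.district} {network.timepoint.value}: "
                    + "; ".join(violations[:5]),
                )

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            report = build_report(studies)
        for w in caught:
            logger.warning("compare: %s", w.message)
    except ValueError as exc:
        raise PipelineError("report", str(exc)) from exc

    try:
        report.table.to_csv(outdir / "report.tsv", sep="\t", index=False)
        report.tests.to_csv(outdir / "report_tests.tsv", sep="\t", index=False)
        report.to_wide().to_csv(outdir / "report_table3.tsv", sep="\t")
        (outdir / "report.json").write_text(
            json.dumps(
                {
                    "rows": json.loads(report.table.to_json(orient="records")),
                    "paired_tests": json.loads(
                        report.tests.to_json(orient="records")
                    ),
                    "not_applicable": sorted(map(list, report.not_applicable)),
                },
                indent=2,
            )
        )
    except OSError as exc:
        raise PipelineError("report", str(exc)) from exc

    if figures:
        layout_seed = int(seed or 0)
        for study in studies:
            for network in (study.t0, study.t1):
                stem = f"{network.district}_{network.timepoint.value}"
                try:
                    render_sociogram(
                        network, outdir / f"{stem}_contacts.png",
                        SociogramStyle(edge_mode="plain"), layout_seed,
                    )
                    render_sociogram(
                        network, outdir / f"{stem}_reciprocity.png",
                        SociogramStyle(edge_mode="reciprocity"), layout_seed,
                    )
                except ValueError as exc:
                    raise PipelineError("figures", str(exc)) from exc
    logger.info(
        "pipeline complete: %d district(s), report in %s", len(studies), outdir
    )
    return report
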