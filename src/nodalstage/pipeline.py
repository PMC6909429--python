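"""End-to-end analysis pipeline: cohort in, staging tables and thresholds out.

``run_full_analysis`` chains load -> select -> stage -> summarise ->
per-stage prior estimation -> accuracy and N2 tables -> threshold report,
writing every artifact plus a run manifest under an output directory.
Re-running with the same config (and seed, where simulation is involved)
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .cohort import (
    apply_selection,
    load_cohort,
    stage_cohort,
    summarize_cohort,
)
from .model import ModelConfig, NodalStageError
from .priors import NodalPrior, estimate_prior
from .tables import (
    DEFAULT_M_RANGE,
    DEFAULT_N_RANGE,
    accuracy_table,
    n2_table,
    threshold_report,
)

logger = logging.getLogger("nodalstage")


@dataclass
class RunConfig:
    cohort_path: str
    output_dir: str
    model: ModelConfig = field(default_factory=ModelConfig)
    stages: Sequence[str] = ("T1", "T2", "T3")
    n_range: Sequence[int] = tuple(DEFAULT_N_RANGE)
    m_range: Sequence[int] = tuple(DEFAULT_M_RANGE)
    accuracy_levels: Sequence[float] = (0.80, 0.90)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if Path(self.cohort_path).resolve() == Path(self.output_dir).resolve():
            raise NodalStageError("cohort_path and output_dir must differ")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        model = payload.pop("model", None)
        if model is not None:
            payload["model"] = ModelConfig(**model)
        return cls(**payload)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.start = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.start
        if exc is None:
            logger.info("stage %s: done in %.3fs", self.name, elapsed)
        else:
            logger.error("stage %s: failed after %.3fs: %s", self.name, elapsed, exc)
        return False


@dataclass
class AnalysisBundle:
    priors: dict[str, NodalPrior]
    output_dir: Path
    artifacts: list[Path]


def run_full_analysis(config: RunConfig) -> AnalysisBundle:
    """Run the whole analysis; any stage error aborts naming the stage."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(path: Path, writer) -> None:
        writer(path)
        artifacts.append(path)

    try:
        with _StageTimer("load_cohort"):
            loaded = load_cohort(config.cohort_path)
        with _StageTimer("apply_selection"):
            selected = apply_selection(loaded.records, config.model)
            logger.info("selection: kept %d, excluded %s",
                        len(selected), selected.exclusion_counts)
        with _StageTimer("assign_t_stage"):
            staged = stage_cohort(selected.records)
        with _StageTimer("summarize_cohort"):
            summary = summarize_cohort(staged, config.model)
            emit(out / "cohort_summary.csv", lambda p: summary.per_stage.to_csv(p, index=False))
            emit(out / "cohort_summary.txt", lambda p: p.write_text(summary.to_text()))

        priors: dict[str, NodalPrior] = {}
        with _StageTimer("estimate_prior"):
            for stage in config.stages:
                priors[stage] = estimate_prior(staged, stage, config.model)
                emit(out / f"prior_{stage}.csv", priors[stage].to_csv)
                emit(out / f"prior_{stage}.json", priors[stage].to_json)

        with _StageTimer("staging_tables"):
            for stage, prior in priors.items():
                acc = accuracy_table(prior, config.n_range, config.m_range, config.model)
                n2 = n2_table(prior, config.n_range, config.m_range, config.model)
                emit(out / f"accuracy_{stage}.csv", acc.to_csv)
                emit(out / f"n2_probability_{stage}.csv", n2.to_csv)
                emit(out / f"tables_{stage}.txt",
                     lambda p, a=acc, b=n2: p.write_text(a.to_text() + "\n" + b.to_text()))

        with _StageTimer("threshold_report"):
            frames = []
            for stage, prior in priors.items():
                frame = threshold_report(prior, config.model, config.accuracy_levels)
                frame.insert(0, "stage", stage)
                frames.append(frame)
            import pandas as pd

            report = pd.concat(frames, ignore_index=True)
            emit(out / "thresholds.csv", lambda p: report.to_csv(p, index=False))
    except NodalStageError:
        raise

    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "config": asdict(config),
        "artifacts": [p.name for p in artifacts],
    }
    import numpy, pandas, scipy  # noqa: PLC0415

    manifest["versions"] = {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    artifacts.append(manifest_path)
    return AnalysisBundle(priors=priors, output_dir=out, artifacts=artifacts)
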