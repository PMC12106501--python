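"""End-to-end pipeline: read -> sum -> normalize -> features -> call -> evaluate.

The pipeline is a pure function of (input files, config): every output is
written with fixed number formats and no timestamps, and carries the
SHA-256 hash of the canonical config serialization, so a rerun on
identical inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import caller as caller_mod
from . import evaluate as evaluate_mod
from . import features as features_mod
from . import intensity_io, normalize
from .locus_model import read_locus_map

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "config_hash"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    manifest: str
    intensities: str
    locus_map: str
    regions: str
    out_dir: str
    truth: str | None = None
    quantile_offset: str = "hazen"
    pool_by_version: bool = False
    mad_rule: str = "piecewise"
    diff_max: float = caller_mod.DEFAULT_DIFF_MAX
    mad_max: float = caller_mod.DEFAULT_MAD_MAX
    suggest_thresholds: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def config_hash(config) -> str:
    """SHA-256 of a canonical JSON rendering of any config dataclass."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in fixed order; returns a dict of output paths.

    Stages: io -> sum -> normalize -> features -> call -> evaluate (the
    last only when a truth file is configured).  Any stage error aborts
    with a stage-tagged :class:`PipelineError`.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)

    @_stage("io")
    def stage_io():
        for key in ("manifest", "intensities", "locus_map", "regions"):
            p = getattr(config, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        manifest = intensity_io.read_manifest(config.manifest)
        locus_map = read_locus_map(config.locus_map, config.regions)
        table = intensity_io.read_intensities(config.intensities, manifest,
                                              locus_map)
        return manifest, locus_map, table

    manifest, locus_map, table = stage_io()

    @_stage("sum")
    def stage_sum():
        return normalize.sum_to_locus(table, locus_map)

    summed = stage_sum()

    @_stage("normalize")
    def stage_norm():
        group = manifest.version_of() if config.pool_by_version else None
        return normalize.inverse_normal_transform(
            summed, offset=config.quantile_offset, group_by=group
        )

    normalized = stage_norm()

    @_stage("features")
    def stage_features():
        return features_mod.compute_features(normalized, locus_map,
                                             mad_rule=config.mad_rule)

    feats = stage_features()

    @_stage("call")
    def stage_call():
        if config.suggest_thresholds:
            thr = caller_mod.suggest_thresholds(feats)
        else:
            thr = caller_mod.CallThresholds(config.diff_max, config.mad_max,
                                            provenance="user")
        return caller_mod.call_cohort(feats, thr, config_hash=chash)

    calls = stage_call()

    outputs: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        outputs[name] = str(path)

    emit("locus_matrix_normalized.tsv",
         lambda p: normalize.write_locus_matrix(normalized, p))
    emit("features.tsv", lambda p: features_mod.write_features(feats, p))
    emit("calls.tsv", lambda p: caller_mod.write_calls(calls, p))

    report = evaluate_mod.summarize_run(calls, manifest)
    report["config_hash"] = chash
    conf = None
    if config.truth:
        @_stage("evaluate")
        def stage_eval():
            truth_df = pd.read_csv(config.truth, sep="\t",
                                   dtype={"sample_id": str})
            truth = truth_df.set_index("sample_id")["truth_label"]
            return evaluate_mod.confusion(calls, truth)

        conf = stage_eval()
        report["confusion"] = conf.as_dict()

    emit("report.json", lambda p: Path(p).write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"))
    emit("report.txt", lambda p: Path(p).write_text(
        evaluate_mod.render_report(report, conf)))
    log.info("pipeline complete (config hash %s): %s", chash,
             ", ".join(outputs))
    return outputs
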