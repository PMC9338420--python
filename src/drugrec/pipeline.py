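"""End-to-end orchestration: simulate -> preprocess -> cluster -> evaluate.

A single :class:`RunConfig` (YAML or JSON on disk) nests the per-stage
configurations and one global seed from which every stage's randomness
derives.  ``run_pipeline`` executes the stages in order, writing each
artifact to the output directory; re-running with the same inputs and seed
reproduces byte-identical artifacts.  Stage failures are wrapped in
:class:`~drugrec.errors.PipelineStageError` carrying the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterConfig, fit_cluster_pipeline
from .errors import ConfigError, PipelineStageError
from .evaluation import EvalConfig, evaluate_split
from .preprocess import PreprocessConfig, build_feature_table
from .recommender import build_rating_matrix
from .schema import read_encounters, write_feature_table
from .synthetic import SyntheticConfig, generate_encounters

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "drugrec_out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        import zlib

        h = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(h.generate_state(1)[0] % (2**31))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return {
            "schema_version": CONFIG_SCHEMA_VERSION,
            "seed": self.seed,
            "outdir": self.outdir,
            "preprocess": _plain(dataclasses.asdict(self.preprocess)),
            "clustering": _plain(dataclasses.asdict(self.clustering)),
            "evaluation": _plain(dataclasses.asdict(self.evaluation)),
            "synthetic": {
                k: _plain(v)
                for k, v in dataclasses.asdict(self.synthetic).items()
                if k != "profiles"  # profiles are code-level objects
            },
        }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ConfigError("run config must be a mapping")
        doc.pop("schema_version", None)
        kwargs = {}
        for key in ("seed", "outdir"):
            if key in doc:
                kwargs[key] = doc.pop(key)
        sections = {
            "preprocess": PreprocessConfig,
            "clustering": ClusterConfig,
            "evaluation": EvalConfig,
            "synthetic": SyntheticConfig,
        }
        for name, klass in sections.items():
            if name in doc:
                section = doc.pop(name) or {}
                section = _revive(klass, section)
                kwargs[name] = klass(**section)
        if doc:
            raise ConfigError(f"unknown config keys: {sorted(doc)}")
        return cls(**kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _revive(klass, section: dict) -> dict:
    fields = {f.name for f in dataclasses.fields(klass)}
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(f"unknown keys for {klass.__name__}: {sorted(unknown)}")
    out = dict(section)
    for key in ("explicit_drop", "kmeans_k_range", "cluster_weights"):
        if key in out and out[key] is not None:
            out[key] = tuple(out[key])
    if "dbscan_grid" in out and out["dbscan_grid"] is not None:
        out["dbscan_grid"] = tuple((float(e), int(m)) for e, m in out["dbscan_grid"])
    return out


def run_pipeline(config: RunConfig, raw_path=None) -> dict:
    """Execute the full pipeline; returns a dict of artifact paths.

    Without *raw_path* the synthetic generator produces the input cohort
    (writing ``data.csv`` and the ground-truth sidecar ``truth.csv``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        return result

    if raw_path is None:
        def simulate():
            scfg = dataclasses.replace(config.synthetic, seed=config.child_seed("simulate"))
            raw, truth = generate_encounters(scfg)
            raw.to_csv(outdir / "data.csv", index=False)
            truth.to_csv(outdir / "truth.csv")
            return raw

        raw = stage("simulate", simulate)
        artifacts["data"] = str(outdir / "data.csv")
        artifacts["truth"] = str(outdir / "truth.csv")
    else:
        raw = stage("read", lambda: read_encounters(raw_path))

    def preprocess():
        result = build_feature_table(raw, config.preprocess)
        write_feature_table(result.features, outdir / "features.csv")
        with open(outdir / "drops.json", "w") as fh:
            json.dump(result.report, fh, sort_keys=True, indent=1)
        return result

    result = stage("preprocess", preprocess)
    artifacts["features"] = str(outdir / "features.csv")
    artifacts["drops"] = str(outdir / "drops.json")

    def cluster():
        ccfg = dataclasses.replace(config.clustering, seed=config.child_seed("cluster"))
        pipeline, leaderboard = fit_cluster_pipeline(result.full, ccfg)
        pipeline.to_json(outdir / "model.json")
        labels = pd.Series(
            pipeline.model.labels, index=result.full.index, name="cluster"
        )
        matrix = build_rating_matrix(result.drug_ratings, labels)
        matrix.to_csv(outdir / "ratings.csv")
        return pipeline

    stage("cluster", cluster)
    artifacts["model"] = str(outdir / "model.json")
    artifacts["ratings"] = str(outdir / "ratings.csv")

    def evaluate():
        ecfg = dataclasses.replace(config.evaluation, seed=config.child_seed("evaluate"))
        ccfg = dataclasses.replace(config.clustering, seed=config.child_seed("cluster"))
        report, _ = evaluate_split(
            result.features, result.drug_ratings, ecfg, ccfg
        )
        report.to_json(outdir / "report.json")
        return report

    stage("evaluate", evaluate)
    artifacts["report"] = str(outdir / "report.json")
    return artifacts
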