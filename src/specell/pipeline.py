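"""End-to-end orchestration: simulate -> preprocess -> features -> model -> validate.

One `PipelineConfig` (deserializable from a single YAML file with per-stage
sections) drives a full reproducible run.  Every output file is recorded in
a manifest with its SHA-256 checksum; rerunning with the same config and
seed reproduces the manifest byte-for-byte, and `verify_run` detects any
tampered file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as dbio
from .blocks import ValidationError
from .channels import default_channel_set
from .features import FeatureSetPolicy
from .model import CanonicalDiscriminantModel
from .preprocess import CorrectionSettings, preprocess_block
from .synthetic import CohortConfig, make_endmembers
from .validation import CVConfig, make_report

logger = logging.getLogger(__name__)

VERSION = "0.1.0"


def _default_cohort() -> CohortConfig:
    # reference scale: two unbalanced groups of 41 and 84 cells
    return CohortConfig(n_patients_per_group=8, cells_per_group=(41, 84))


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=_default_cohort)
    correction: CorrectionSettings = field(default_factory=CorrectionSettings)
    feature_policy: FeatureSetPolicy = field(default_factory=FeatureSetPolicy)
    cv: CVConfig = field(default_factory=CVConfig)
    n_features: int = 6
    redundancy_rho: float = 0.95
    seed: int = 0
    version: str = VERSION

    def __post_init__(self) -> None:
        # cross-stage consistency: the selection size must be attainable
        if self.cohort.cells_per_group is not None:
            counts = self.cohort.cells_per_group
        else:
            per_group = (
                self.cohort.n_patients_per_group
                * self.cohort.fields_per_patient
                * self.cohort.cells_per_field
            )
            counts = (per_group, per_group)
        if self.n_features >= min(counts):
            raise ValidationError(
                f"n_features = {self.n_features} must stay below the smaller "
                f"group's cell count {min(counts)}"
            )

    def resolved(self) -> "PipelineConfig":
        """Propagate the master seed into the stage configs."""
        return replace(
            self,
            cohort=replace(self.cohort, seed=self.seed),
            cv=replace(self.cv, seed=self.seed + 1),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            for key in ("image_shape", "cells_per_group", "cell_radius_range"):
                if key in c and c[key] is not None:
                    c[key] = tuple(c[key])
            kwargs["cohort"] = CohortConfig(**c)
        if "correction" in raw:
            kwargs["correction"] = CorrectionSettings(**raw["correction"])
        if "feature_policy" in raw:
            p = dict(raw["feature_policy"])
            for key in ("ratio_channels", "extra_ratio_pairs"):
                if key in p:
                    p[key] = tuple(tuple(x) if isinstance(x, list) else x for x in p[key]) if key == "extra_ratio_pairs" else tuple(p[key])
            kwargs["feature_policy"] = FeatureSetPolicy(**p)
        if "cv" in raw:
            cv = dict(raw["cv"])
            if "n_grid" in cv:
                cv["n_grid"] = tuple(cv["n_grid"])
            kwargs["cv"] = CVConfig(**cv)
        for key in ("n_features", "redundancy_rho", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute all stages, writing per-stage outputs and a checksum manifest."""
    cfg = cfg.resolved()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stages 1-3: simulate, preprocess, extract (streaming per field)")
    channel_set = default_channel_set()
    spectra = make_endmembers(channel_set, seed=cfg.cohort.seed)
    cohort_dir = out / "cohort"
    from .features import build_feature_table
    from .synthetic import iter_cohort

    import pandas as pd

    truth_frames, table_frames = [], []
    n_bad = n_blocks = 0
    for block, mask, truth in iter_cohort(cfg.cohort, spectra, out_dir=cohort_dir):
        processed, bad = preprocess_block(block, cfg.correction)
        n_bad += int(bad.sum())
        n_blocks += 1
        table_frames.append(build_feature_table([processed], [mask], cfg.feature_policy))
        truth_frames.append(truth.cells)
    logger.info("processed %d blocks, repaired %d bad pixels", n_blocks, n_bad)
    dbio.write_feature_table(
        pd.concat(truth_frames, ignore_index=True),
        out / "truth.csv",
        provenance={"version": cfg.version},
    )
    from .blocks import validate_feature_table

    table = validate_feature_table(pd.concat(table_frames, ignore_index=True))
    provenance = {"version": cfg.version, "config_hash": _config_hash(cfg)}
    dbio.write_feature_table(table, out / "features.csv", provenance=provenance)

    logger.info("stage 4/5: fit discriminant model (n = %d)", cfg.n_features)
    model = CanonicalDiscriminantModel(table)
    results = model.fit(n_features=cfg.n_features, redundancy_rho=cfg.redundancy_rho)
    results.projection.to_json(out / "model.json")
    (out / "summary.txt").write_text(results.summary() + "\n")

    logger.info("stage 5/5: nested cross-validation")
    report = model.cross_validate(cfg.cv, redundancy_rho=cfg.redundancy_rho)
    summary = make_report(report, results.projection, table, out / "report")

    manifest = {
        "version": cfg.version,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "files": {},
    }
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json" and path.suffix != ".png" and path.suffix != ".svg":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    summary["manifest"] = str(out / "manifest.json")
    return summary


def verify_run(run_dir) -> list:
    """Re-hash every manifest entry; returns the list of mismatched files."""
    run = Path(run_dir)
    with open(run / "manifest.json") as fh:
        manifest = json.load(fh)
    bad = []
    for rel, digest in manifest["files"].items():
        path = run / rel
        if not path.exists() or _sha256(path) != digest:
            bad.append(rel)
    return bad
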