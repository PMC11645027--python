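"""End-to-end orchestration: synth -> preprocess -> segment -> features -> fit.

One :class:`RunConfig` nests the stage configurations and a single global
seed; every stochastic stage receives a child seed derived from it, so a
rerun with the same config is bit-identical (modulo timestamps in the
manifest). Each stage writes its artifact under the output directory and
the manifest records the config hash, seeds and stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import LocomoError, SegmentationError
from .features import build_feature_vector, feature_table
from .modeling import CohortTable, MlpSpec, PipelineConfig, run_classification
from .preprocess import PreprocessConfig, preprocess_recording
from .recording import ImuRecording, read_recording_csv, write_recording_csv
from .segmentation import SegmentationConfig, segment_recording
from .synth import CohortConfig, KinematicParams, cohort_manifest, generate_cohort

STAGES = ("synth", "preprocess", "segment", "features", "fit")


@dataclass
class RunConfig:
    out_dir: str = "locomo_run"
    seed: int = 42
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    mlp: MlpSpec = field(default_factory=MlpSpec)
    models: list[str] = field(default_factory=lambda: ["SVM-rbf", "KNN", "RF", "LR", "MLP"])
    skip_synth: bool = False
    rec_dir: str | None = None  # external recordings when skip_synth is set
    write_recordings: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            cohort = dict(kwargs["cohort"])
            if "group_kinematics" in cohort:
                cohort["group_kinematics"] = {
                    g: KinematicParams(**v) for g, v in cohort["group_kinematics"].items()
                }
            if "glfs_ranges" in cohort:
                cohort["glfs_ranges"] = {
                    g: tuple(v) if v is not None else None
                    for g, v in cohort["glfs_ranges"].items()
                }
            kwargs["cohort"] = CohortConfig(**cohort)
        for key, cls_ in (
            ("preprocess", PreprocessConfig),
            ("segmentation", SegmentationConfig),
            ("pipeline", PipelineConfig),
        ):
            if key in kwargs:
                kwargs[key] = cls_(**kwargs[key])
        if "mlp" in kwargs:
            mlp = dict(kwargs["mlp"])
            if "hidden_layers" in mlp:
                mlp["hidden_layers"] = tuple(mlp["hidden_layers"])
            kwargs["mlp"] = MlpSpec(**mlp)
        return cls(**kwargs)

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj

        blob = json.dumps(encode(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest.

    Any stage failure aborts with the failing stage named. Identical
    configs produce identical artifacts (the manifest timestamp aside).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__ as pkg_version

    manifest: dict = {
        "package_version": pkg_version,
        "config_hash": config.config_hash(),
        "global_seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
        "stages": {},
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    stage = "synth"
    try:
        if config.skip_synth:
            if not config.rec_dir:
                raise LocomoError("skip_synth requires rec_dir pointing at recording CSVs")
            rec_paths = sorted(Path(config.rec_dir).glob("*.csv"))
            rec_paths = [p for p in rec_paths if p.name != "cohort.csv"]
            recordings = [read_recording_csv(p) for p in rec_paths]
            manifest_path = Path(config.rec_dir) / "cohort.csv"
            if not manifest_path.exists():
                manifest_path = Path(config.rec_dir).parent / "cohort.csv"
            meta = pd.read_csv(manifest_path) if manifest_path.exists() else None
            manifest["stages"][stage] = {"source": str(config.rec_dir), "n": len(recordings)}
        else:
            profiles, recordings = generate_cohort(config.cohort, _stage_seed(config.seed, stage))
            meta = cohort_manifest(profiles)
            meta.to_csv(out / "cohort.csv", index=False)
            if config.write_recordings:
                rec_out = out / "recordings"
                rec_out.mkdir(exist_ok=True)
                for rec in recordings:
                    write_recording_csv(rec, rec_out / f"{rec.participant_id}.csv")
            manifest["stages"][stage] = {"output": "cohort.csv", "n": len(recordings)}

        stage = "preprocess"
        processed = [preprocess_recording(r, config.preprocess) for r in recordings]
        manifest["stages"][stage] = {
            "target_rate_hz": config.preprocess.target_rate_hz,
            "n": len(processed),
        }

        stage = "segment"
        seg_rows = []
        segmented: list[tuple[ImuRecording, list]] = []
        skipped = []
        for rec in processed:
            try:
                segs = segment_recording(rec, config.segmentation)
            except SegmentationError as exc:
                skipped.append(str(exc))
                continue
            segmented.append((rec, segs))
            for s in segs:
                seg_rows.append(
                    {
                        "participant_id": rec.participant_id,
                        "kind": s.kind,
                        "repetition": s.repetition,
                        "start_index": s.start_index,
                        "end_index": s.end_index,
                        "start_s": s.start_index / rec.sample_rate_hz,
                        "end_s": s.end_index / rec.sample_rate_hz,
                    }
                )
        if not segmented:
            raise SegmentationError("segmentation failed on every recording")
        if skipped:
            warnings.warn(f"segmentation skipped {len(skipped)} recording(s)", stacklevel=2)
        pd.DataFrame(seg_rows).to_csv(out / "segments.csv", index=False)
        manifest["stages"][stage] = {"output": "segments.csv", "n": len(segmented)}

        stage = "features"
        rows = [
            (rec.participant_id, build_feature_vector(rec, segs)) for rec, segs in segmented
        ]
        features = feature_table(rows, metadata=meta, include_cv=True)
        features.to_csv(out / "features.csv", index=False)
        manifest["stages"][stage] = {
            "output": "features.csv",
            "n_rows": len(features),
            "n_primary_features": len(rows[0][1].values),
        }

        stage = "fit"
        if "group" not in features.columns:
            raise LocomoError(
                "fit requires group labels; provide a cohort.csv manifest alongside "
                "the recordings"
            )
        table = CohortTable.from_frame(features)
        reports = run_classification(
            table,
            config.pipeline,
            models=config.models,
            mlp_spec=config.mlp,
            seed=_stage_seed(config.seed, stage),
        )
        report_payload = {name: r.as_dict() for name, r in reports.items()}
        with open(out / "report.json", "w") as fh:
            json.dump(report_payload, fh, indent=2)
        for name, r in reports.items():
            pd.DataFrame(r.confusion, index=r.classes, columns=r.classes).to_csv(
                out / f"confusion_{name.replace('+', '_')}.csv"
            )
        manifest["stages"][stage] = {
            "output": "report.json",
            "models": {name: round(r.accuracy, 4) for name, r in reports.items()},
        }
    except LocomoError as exc:
        raise LocomoError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
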