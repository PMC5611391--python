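"""One-command orchestration: generate (or load) a study, run every
measure, and write the descriptive tables plus a JSON run report.

Stages communicate only through the in-memory :class:`StudyDataset`
and files on disk, so each stage can be run and tested alone. All
randomness flows from the single configured seed; a fixed seed
reproduces every CSV byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import AgreementConfig, MaskCache, summary_tables
from .datamodel import StudyDataset
from .io import read_dataset, write_dataset
from .raster import observer_slice_mask
from .saliency import SaliencyConfig, compute_saliency, contour_saliency_score
from .scanmatch import AlignmentConfig, group_similarity
from .synthetic import (
    EXPERT_DEFAULTS,
    NOVICE_DEFAULTS,
    GroupParams,
    default_phantoms,
    generate_study,
)

__all__ = ["RunConfig", "StudyParams", "RunReport", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("generate", "agreement", "similarity", "saliency")


@dataclass
class StudyParams:
    """Size and behavioral parameters of a synthetic study."""

    n_experts: int = 8
    n_novices: int = 12
    width: int = 512
    n_slices: int = 31
    include_independent_set: bool = True
    expert: GroupParams = field(default_factory=lambda: replace(EXPERT_DEFAULTS))
    novice: GroupParams = field(default_factory=lambda: replace(NOVICE_DEFAULTS))


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    mode: str = "synthetic"
    seed: int | None = None
    input_dir: str | None = None
    out_dir: str = "delinmetrics_out"
    stages: tuple[str, ...] = ALL_STAGES
    study: StudyParams = field(default_factory=StudyParams)
    agreement: AgreementConfig = field(default_factory=AgreementConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    saliency: SaliencyConfig = field(default_factory=SaliencyConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "load"):
            raise ValueError(f"mode must be 'synthetic' or 'load', got {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires a seed")
        if self.mode == "load" and not self.input_dir:
            raise ValueError("load mode requires input_dir")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}; valid: {ALL_STAGES}")


@dataclass
class RunReport:
    """Everything needed to audit a run."""

    config: dict
    tables: dict[str, str]
    warnings: list[str]
    version: str
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _build_nested(cls, data: dict, context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        if isinstance(value, dict):
            sub = {
                "study": StudyParams,
                "agreement": AgreementConfig,
                "alignment": AlignmentConfig,
                "saliency": SaliencyConfig,
                "expert": GroupParams,
                "novice": GroupParams,
            }.get(key)
            if sub is None:
                raise ValueError(f"{context}: key {key!r} does not take a mapping")
            value = _build_nested(sub, value, f"{context}.{key}")
        elif key in ("stages", "channels") and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ValueError(f"{context}: {e}") from e


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys take their defaults; unknown keys are rejected by
    name; constraint violations name the field. ``overrides`` (e.g.
    from CLI flags) are applied on top of the file.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data = raw
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    return _build_nested(RunConfig, data, "config")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


@_stage("generate")
def _obtain_dataset(config: RunConfig, out: Path) -> StudyDataset:
    if config.mode == "load":
        logger.info("loading dataset from %s", config.input_dir)
        return read_dataset(config.input_dir)
    sp = config.study
    logger.info("generating synthetic study (seed=%s)", config.seed)
    study = generate_study(
        phantoms=default_phantoms(sp.width, sp.width, sp.n_slices),
        expert_gp=sp.expert,
        novice_gp=sp.novice,
        n_experts=sp.n_experts,
        n_novices=sp.n_novices,
        seed=int(config.seed),
        include_independent_set=sp.include_independent_set,
    )
    if "generate" in config.stages:
        write_dataset(study.dataset, out / "dataset")
    return study.dataset


@_stage("agreement")
def _run_agreement(dataset: StudyDataset, config: RunConfig, out: Path, cache: MaskCache) -> dict[str, str]:
    tables = summary_tables(dataset, config.agreement, cache)
    written = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        written[name] = str(p)
    return written


@_stage("similarity")
def _run_similarity(dataset: StudyDataset, config: RunConfig, out: Path) -> dict[str, str]:
    pair_frames, obs_frames = [], []
    for stack in dataset.stacks:
        if stack.independent_slices:
            continue  # inspection order is meaningless across patients
        res = group_similarity(dataset, stack.set_id, config.alignment)
        pair_frames.append(res["pairwise"].assign(set_id=stack.set_id))
        obs_frames.append(res["observers"])
    if not pair_frames:
        return {}
    pairwise = pd.concat(pair_frames, ignore_index=True)
    observers = pd.concat(obs_frames, ignore_index=True)
    summary = (
        observers.groupby(["set_id", "group"])["similarity"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    written = {}
    for name, df in [
        ("similarity", pairwise),
        ("similarity_observers", observers),
        ("similarity_summary", summary),
    ]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        written[name] = str(p)
    return written


@_stage("saliency")
def _run_saliency(dataset: StudyDataset, config: RunConfig, out: Path) -> dict[str, str]:
    rows = []
    smap_dir = out / "saliency_maps"
    smap_dir.mkdir(parents=True, exist_ok=True)
    for stack in dataset.stacks:
        if not stack.independent_slices:
            continue  # whole-brain slices are contextually biased; skipped
        cfg = replace(config.saliency, output_resolution=stack.width)
        modality = stack.modalities[0]
        for k in range(stack.n_slices):
            smap = compute_saliency(stack.images[modality][k], stack.brain_masks[k], cfg)
            iio.imwrite(
                smap_dir / f"set{stack.set_id}_slice{k:03d}_saliency.png",
                np.rint(smap * 65535).astype(np.uint16),
            )
            for obs in dataset.observers:
                boundary = observer_slice_mask(
                    obs, stack.set_id, k, stack.width, stack.height, "boundary"
                )
                if not boundary.any():
                    continue
                rows.append(
                    {
                        "observer_id": obs.observer_id,
                        "group": obs.group,
                        "set_id": stack.set_id,
                        "slice_index": k,
                        "location": (stack.slice_location_labels or [None] * stack.n_slices)[k],
                        "score": contour_saliency_score(smap, boundary),
                    }
                )
    if not rows:
        return {}
    df = pd.DataFrame(rows)
    p = out / "contour_saliency.csv"
    df.to_csv(p, index=False, float_format="%.6f")
    return {"contour_saliency": str(p), "saliency_maps": str(smap_dir)}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and write all artifacts.

    Any stage failure aborts the run with the stage name in the error
    message. The JSON report echoes the configuration and collects
    every warning emitted during the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, str] = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        dataset = _obtain_dataset(config, out)
        cache = MaskCache(dataset)
        if "agreement" in config.stages:
            tables.update(_run_agreement(dataset, config, out, cache))
        if "similarity" in config.stages:
            tables.update(_run_similarity(dataset, config, out))
        if "saliency" in config.stages:
            tables.update(_run_saliency(dataset, config, out))
    seen: list[str] = []
    for w in caught:
        msg = str(w.message)
        if msg not in seen:
            seen.append(msg)
    report = RunReport(
        config=dataclasses.asdict(config),
        tables=tables,
        warnings=seen,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out / "report.json").write_text(report.to_json())
    return report
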