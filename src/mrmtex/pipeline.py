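"""End-to-end orchestration: phantom -> preprocess -> texture -> stromal
proportion -> binned association -> SVM classification.

Each specimen is processed independently (phantom seed = run seed + index);
pixel tables are then pooled across specimens for the association report
and the classifier, mirroring a multi-specimen study.  A manifest records
every artifact with a SHA-256 checksum of its numeric content, so two runs
with one seed can be compared bit-for-bit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, viz
from .association import association_report
from .classify import (
    build_feature_table,
    evaluate,
    predict_map,
    sample_and_split,
    train_svm,
)
from .histomaps import resample_labels, stromal_proportion
from .phantom import PhantomConfig, generate_phantom
from .preprocess import PreprocessConfig, preprocess
from .texture import quantize, texture_map
from .types import IntensityVolume, LabelMap

logger = logging.getLogger(__name__)


@dataclass
class TextureConfig:
    levels: int = 64
    radius: int = 3
    mode: str = "2d-4dir"
    distance: int = 1


@dataclass
class ClassifyConfig:
    threshold: float = 50.0
    sample_frac: float = 0.30
    train_frac: float = 0.50
    folds: int = 20
    kernel: str = "rbf"
    C: float = 1.0
    with_si: bool = False


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    stroma_radius: int = 3
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    n_specimens: int = 4
    seed: int = 0
    write_png: bool = True

    def to_dict(self) -> dict:
        # round-trip through JSON so tuples become plain lists (YAML-safe)
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        kwargs = {}
        for fld, sub in (
            ("phantom", PhantomConfig),
            ("preprocess", PreprocessConfig),
            ("texture", TextureConfig),
            ("classify", ClassifyConfig),
        ):
            if fld in raw:
                block = raw.pop(fld)
                if not isinstance(block, dict):
                    raise ValueError(f"config block {fld!r} must be a mapping")
                known = {f.name for f in dataclasses.fields(sub)}
                unknown = set(block) - known
                if unknown:
                    raise ValueError(f"unknown keys in block {fld!r}: {sorted(unknown)}")
                for key in ("image_shape", "voxel_spacing", "lobule_radius_range",
                            "void_radius_range"):
                    if key in block:
                        block[key] = tuple(block[key])
                kwargs[fld] = sub(**block)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(raw or {})


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _frame_checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def process_specimen(
    vol: IntensityVolume,
    labels: LabelMap,
    pre_cfg: PreprocessConfig,
    tex_cfg: TextureConfig,
    stroma_radius: int,
):
    """Preprocess one specimen and derive its texture stack and proportion map."""
    clean, log = preprocess(vol, pre_cfg)
    q = quantize(clean, tex_cfg.levels)
    stack = texture_map(
        q, radius=tex_cfg.radius, mode=tex_cfg.mode, distance=tex_cfg.distance,
        si=clean.data,
    )
    labels_on_grid = resample_labels(labels, clean.shape, clean.spacing)
    prop = stromal_proportion(labels_on_grid, stroma_radius)
    return clean, stack, labels_on_grid, prop, log


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage on synthetic specimens and write all artifacts.

    Returns the manifest (also written to ``manifest.json``): per-stage
    outputs, checksums, masked-pixel counts, and final metrics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(config.to_dict(), out / "config.json")
    manifest: dict = {"seed": config.seed, "stages": {}, "checksums": {}, "files": []}

    def record(name: str, path: Path | None, checksum: str | None = None):
        if path is not None:
            manifest["files"].append(str(path.relative_to(out)))
        if checksum is not None:
            manifest["checksums"][name] = checksum

    tables = []
    specimens = []
    for i in range(config.n_specimens):
        sid = f"specimen_{i}"
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        ph_cfg = dataclasses.replace(config.phantom, seed=config.seed + i)
        try:
            vol, labels = generate_phantom(ph_cfg)
            record(f"{sid}/image", io.write_image(vol, sdir / "image.nii"),
                   _checksum(vol.data))
            record(f"{sid}/labels", io.write_labels(labels, sdir / "labels.nii"),
                   _checksum(labels.labels))
            clean, stack, labels_on_grid, prop, pre_log = process_specimen(
                vol, labels, config.preprocess, config.texture, config.stroma_radius
            )
        except Exception as exc:  # keep partial outputs, name the stage
            raise RuntimeError(f"stage failed for {sid}: {exc}") from exc
        record(f"{sid}/preprocessed", io.write_image(clean, sdir / "preprocessed.nii"),
               _checksum(clean.data))
        for name, arr in stack.maps.items():
            record(f"{sid}/map_{name}", None, _checksum(np.nan_to_num(arr)))
        np.save(sdir / "texture_maps.npy", np.stack(list(stack.maps.values())))
        record(
            f"{sid}/proportion",
            io.write_image(
                IntensityVolume(prop.proportion, prop.spacing, prop.mask),
                sdir / "stromal_proportion.nii",
            ),
            _checksum(prop.proportion),
        )
        io.write_json({"preprocess_log": pre_log}, sdir / "preprocess_log.json")
        if config.write_png:
            viz.save_map_png(prop.proportion, prop.mask, sdir / "stromal_proportion.png")
        table = build_feature_table(
            stack, prop, config.classify.threshold, tumor_id=i,
            with_si=config.classify.with_si,
        )
        tables.append(table)
        specimens.append((sid, sdir, stack, prop))
        manifest["stages"].setdefault("specimens", []).append(
            {
                "id": sid,
                "n_masked_input": int(vol.mask.sum()),
                "n_masked_preprocessed": int(clean.mask.sum()),
                "n_valid_texture": int(stack.mask.sum()),
                "n_table_rows": int(len(table)),
            }
        )

    pooled = pd.concat(tables, ignore_index=True)
    pooled.attrs.update(tables[0].attrs)

    # Association stage uses the pooled per-specimen maps.
    reports = []
    for i, (sid, sdir, stack, prop) in enumerate(specimens):
        rep = association_report(stack, prop)
        rep.insert(0, "tumor_id", i)
        reports.append(rep)
    pooled_assoc = _pooled_association(specimens)
    io.write_table(pooled_assoc, out / "association.csv")
    io.write_table(pd.concat(reports, ignore_index=True), out / "association_per_tumor.csv")
    record("association", out / "association.csv", _frame_checksum(pooled_assoc))
    manifest["stages"]["association"] = {
        "n_features": int(len(pooled_assoc)),
        "n_significant": int(pooled_assoc["significant"].sum()),
    }

    # Classification stage on the pooled table.
    train, test = sample_and_split(
        pooled, config.classify.sample_frac, config.classify.train_frac, config.seed
    )
    result = train_svm(
        train, folds=config.classify.folds, seed=config.seed,
        kernel=config.classify.kernel, C=config.classify.C,
    )
    result = evaluate(result, test)
    metrics_rows = [
        {"subset": "test_set", "cv_accuracy": result.cv_accuracy, **result.rates,
         **result.confusion}
    ]
    for i, (sid, sdir, stack, prop) in enumerate(specimens):
        predicted, evaluation, rates = predict_map(
            result, stack, prop, config.classify.threshold
        )
        np.save(sdir / "predicted_classes.npy", predicted)
        np.save(sdir / "evaluation.npy", evaluation)
        record(f"{sid}/predicted", None, _checksum(predicted))
        if config.write_png:
            viz.save_prediction_png(predicted, sdir / "predicted.png")
            viz.save_evaluation_png(evaluation, sdir / "evaluation.png")
        metrics_rows.append({"subset": sid, **rates})
    metrics = pd.DataFrame(metrics_rows)
    io.write_table(metrics, out / "classification_metrics.csv")
    record("classification", out / "classification_metrics.csv",
           _frame_checksum(metrics))
    manifest["stages"]["classification"] = {
        "train_rows": int(len(train)),
        "test_rows": int(len(test)),
        "cv_accuracy": result.cv_accuracy,
        "test_rates": result.rates,
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _pooled_association(specimens) -> pd.DataFrame:
    """Association over all specimens' pixels pooled together."""
    from .association import associate

    names = specimens[0][2].names
    rows = []
    props = []
    values = {n: [] for n in names}
    for _, _, stack, prop in specimens:
        valid = stack.mask & prop.mask
        props.append(prop.proportion[valid])
        for n in names:
            values[n].append(stack[n][valid])
    prop_all = np.concatenate(props)
    for n in names:
        assoc = associate(prop_all, np.concatenate(values[n]), n)
        rows.append(
            {
                "feature": n,
                "r": assoc.r,
                "p": assoc.p,
                "n_bins": assoc.n_bins_used,
                "significant": assoc.significant,
                "note": assoc.note,
            }
        )
    return pd.DataFrame(rows)
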