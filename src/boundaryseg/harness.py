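"""End-to-end evaluation harness.

Ties the pipeline together: dataset manifests, checkpoints, per-case
metric reports (mean and standard deviation aggregates) and the
key-point-selection comparison against uniform-random contour sampling.
All reports are written with 4 decimal places and are byte-reproducible
given the same inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import io as bsio
from .coarse import extract_coarse_contour
from .errors import ConfigError, DataError
from .keypoints import filter_two_per_column, random_contour_sample, refine_keypoints
from .metrics import evaluate_masks, iou, region_from_keypoints
from .nn.config import NetworkConfig, TrainingConfig
from .nn.training import predict
from .nn.unet import BoundaryUNet, build_model
from .phantom import PhantomSpec

__all__ = [
    "RunConfig",
    "load_run_config",
    "save_checkpoint",
    "load_checkpoint",
    "load_manifest",
    "run_evaluate",
    "run_compare_sampling",
]

_FMT = "{:.4f}"


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Flat merged configuration for CLI runs."""

    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)
    training: TrainingConfig = dataclasses.field(default_factory=TrainingConfig)
    phantom: PhantomSpec = dataclasses.field(default_factory=PhantomSpec)
    target_n: int = 16
    stamp_radius: int = 2
    verbosity: int = 1


def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a flat key/value YAML document.

    Keys are the dataclass field names, optionally prefixed by
    ``network.``, ``training.`` or ``phantom.`` to disambiguate.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    groups: dict[str, dict] = {"network": {}, "training": {}, "phantom": {}, "": {}}
    fields = {
        "network": {f.name for f in dataclasses.fields(NetworkConfig)},
        "training": {f.name for f in dataclasses.fields(TrainingConfig)},
        "phantom": {f.name for f in dataclasses.fields(PhantomSpec)},
    }
    top = {"target_n", "stamp_radius", "verbosity"}
    for key, value in raw.items():
        if "." in key:
            group, name = key.split(".", 1)
            if group not in fields or name not in fields[group]:
                raise ConfigError(f"unknown config key {key!r}")
            groups[group][name] = value
        elif key in top:
            groups[""][key] = value
        else:
            hits = [g for g, names in fields.items() if key in names]
            if len(hits) != 1:
                raise ConfigError(f"ambiguous or unknown config key {key!r}")
            groups[hits[0]][key] = value
    for group in ("network", "phantom"):
        for name in ("input_size", "raster_size", "semi_axes_range"):
            if name in groups[group]:
                groups[group][name] = tuple(groups[group][name])
    return RunConfig(
        network=NetworkConfig(**groups["network"]),
        training=TrainingConfig(**groups["training"]),
        phantom=PhantomSpec(**groups["phantom"]),
        **groups[""],
    )


def save_checkpoint(path, model: BoundaryUNet) -> None:
    """Write model weights + architecture to an .npz checkpoint."""
    cfg = dataclasses.asdict(model.cfg)
    cfg["input_size"] = list(cfg["input_size"])
    arrays = {f"param_{i:04d}": p for i, (p, _) in enumerate(model.params())}
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> BoundaryUNet:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config"]))
        cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
        model = build_model(NetworkConfig(**cfg_dict))
        state = [data[k] for k in sorted(k for k in data.files if k.startswith("param_"))]
    model.load_state_dict(state)
    return model


def load_manifest(manifest_path):
    """Load a dataset manifest; returns (manifest dict, base directory)."""
    path = Path(manifest_path)
    if path.is_dir():
        path = path / "manifest.json"
    if not path.exists():
        raise IOError(f"manifest not found: {path}")
    with open(path) as fh:
        manifest = json.load(fh)
    base = path.parent
    missing = [
        str(base / p)
        for case in manifest["cases"]
        for p in case.values()
        if not (base / p).exists()
    ]
    if missing:
        raise IOError("missing dataset files: " + ", ".join(missing))
    return manifest, base


def load_dataset_arrays(manifest_path, supervision: str = "sampled_points") -> dict:
    """Materialise a written dataset into in-memory training arrays.

    The sampled-points supervision uses the boundary-map PNGs from disk;
    the boundary-mask variant recomputes the inner-boundary map from each
    mask.
    """
    from .maps import mask_to_map

    manifest, base = load_manifest(manifest_path)
    imgs, masks, maps = [], [], []
    for case in manifest["cases"]:
        imgs.append(bsio.read_gray(base / case["image"]))
        mask = bsio.read_mask(base / case["mask"])
        masks.append(mask.astype(np.float64))
        if supervision == "boundary_mask":
            maps.append(np.asarray(mask_to_map(mask), dtype=np.float64))
        else:
            maps.append((bsio.read_gray(base / case["boundary_map"]) > 0.5).astype(np.float64))
    return {
        "images": np.stack(imgs),
        "masks": np.stack(masks),
        "maps": np.stack(maps),
    }


def _aggregate(rows: list[dict]) -> dict:
    keys = [k for k in rows[0] if k != "case"]
    agg = {}
    for k in keys:
        vals = np.asarray([r[k] for r in rows], dtype=np.float64)
        agg[k] = {"mean": float(vals.mean()), "std": float(vals.std(ddof=0))}
    return agg


def run_evaluate(
    manifest_path,
    checkpoint_path=None,
    out_dir=None,
    predict_fn=None,
    target_n: int = 16,
) -> dict:
    """Per-case PA / MIOU / DSC / JC plus key-point-polygon IOU, with aggregates.

    Predictions come from ``predict_fn(image) -> mask`` when given,
    otherwise from the checkpointed model.  Writes ``report.csv`` and
    ``report.json`` into ``out_dir`` when provided.
    """
    manifest, base = load_manifest(manifest_path)
    if predict_fn is None:
        if checkpoint_path is None:
            raise DataError("either a checkpoint or a predict_fn is required")
        model = load_checkpoint(checkpoint_path)
        predict_fn = lambda img: predict(model, img)  # noqa: E731
    rows = []
    for i, case in enumerate(manifest["cases"]):
        img = bsio.read_gray(base / case["image"])
        gt = bsio.read_mask(base / case["mask"])
        pred = predict_fn(img)
        rep = evaluate_masks(pred, gt)
        kps = bsio.read_keypoints_csv(base / case["keypoints"])
        kp_region = region_from_keypoints(kps, gt.shape)
        rows.append(
            {
                "case": i,
                "pixel_accuracy": rep.pixel_accuracy,
                "mean_iou": rep.mean_iou,
                "dice": rep.dice,
                "jaccard": rep.jaccard,
                "keypoint_iou": iou(kp_region, gt),
            }
        )
    report = {"per_case": rows, "aggregate": _aggregate(rows)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        _write_rows_csv(out / "report.csv", rows, report["aggregate"])
    return report


def _write_rows_csv(path, rows, aggregate):
    keys = [k for k in rows[0] if k != "case"]
    lines = ["case," + ",".join(keys)]
    for r in rows:
        lines.append(str(r["case"]) + "," + ",".join(_FMT.format(r[k]) for k in keys))
    lines.append("mean," + ",".join(_FMT.format(aggregate[k]["mean"]) for k in keys))
    lines.append("std," + ",".join(_FMT.format(aggregate[k]["std"]) for k in keys))
    Path(path).write_text("\n".join(lines) + "\n")


def run_compare_sampling(manifest_path, n_points: int = 16, seed: int = 0, out_csv=None) -> dict:
    """Key-point polygon IOU vs ground truth: bisector refinement vs random sampling.

    For each case the ground-truth mask is traced, the bisector key points
    and ``n_points`` uniformly-random contour points (seeded) each
    polygon-filled, and both compared to the mask by region IOU.  Outputs
    per-case rows plus mean/std per method.
    """
    manifest, base = load_manifest(manifest_path)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A3]))
    rows = []
    for i, case in enumerate(manifest["cases"]):
        gt = bsio.read_mask(base / case["mask"])
        coarse = extract_coarse_contour(gt)
        filtered = filter_two_per_column(coarse)
        kps = refine_keypoints(filtered, n_points)
        rand = random_contour_sample(coarse, n_points, rng)
        rows.append(
            {
                "case": i,
                "keypoint_iou": iou(region_from_keypoints(kps, gt.shape), gt),
                "random_iou": iou(region_from_keypoints(rand, gt.shape), gt),
            }
        )
    result = {"per_case": rows, "aggregate": _aggregate(rows)}
    if out_csv is not None:
        _write_rows_csv(out_csv, rows, result["aggregate"])
    return result
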