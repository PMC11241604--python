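"""End-to-end screening pipeline: preprocess -> segment -> features ->
select -> classify -> risk screen.

All stages are pure functions of (inputs, config, seed). The single global
seed deterministically derives every stage's randomness through
``numpy.random.SeedSequence(global_seed, spawn_key)`` children, where the
spawn key encodes the stage and the image index — re-running any stage from
its persisted inputs reproduces its outputs byte for byte.

``demo`` mode is the self-contained study: it renders a seeded phantom
corpus (default 60 images, half abnormal at the generator's default
conditions), runs the full chain, trains the classifier on a stratified
train split, evaluates on the held-out images, and writes the predictions
CSV and a metrics report containing every confusion-matrix rate plus lung
and quadrant Dice summaries.

Feature columns are z-scored with statistics fitted on the training split
before entering the network (stored with the checkpoint so prediction mode
applies the same affine map).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import features as _features
from . import metrics as _metrics
from . import phantom as _phantom
from . import preprocess as _preprocess
from . import segment as _segment
from . import select as _select

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_image",
    "save_image",
    "stage_rng",
    "process_image",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Nested per-stage configuration with one global seed."""

    seed: int = 0
    n_phantoms: int = 60
    abnormal_fraction: float = 0.5
    train_fraction: float = 0.7
    phantom_size: int = 160
    stretch_low_pct: float = 1.0
    stretch_high_pct: float = 99.9
    unsharp_eta: float = 0.5
    unsharp_sigma: float = 1.5
    tau_risk: float = 8.0
    save_intermediates: bool = True
    diffusion: _preprocess.DiffusionConfig = field(default_factory=_preprocess.DiffusionConfig)
    segment: _segment.SegmentConfig = field(default_factory=_segment.SegmentConfig)
    features: _features.FeatureConfig = field(default_factory=_features.FeatureConfig)
    select: _select.AlphaConfig = field(default_factory=_select.AlphaConfig)
    # classifier capacity matched to the demo's ~40-sample training split;
    # the PresnetConfig class defaults describe the full-size network
    presnet: _classify.PresnetConfig = field(
        default_factory=lambda: _classify.PresnetConfig(
            width=8, n_blocks=1, weight_decay=1e-3
        )
    )

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {
            "diffusion": _preprocess.DiffusionConfig,
            "segment": _segment.SegmentConfig,
            "features": _features.FeatureConfig,
            "select": _select.AlphaConfig,
            "presnet": _classify.PresnetConfig,
        }
        valid = {f.name for f in dataclasses.fields(PipelineConfig)}
        for key, value in raw.items():
            if key not in valid:
                raise ValueError(f"unknown config key: {key}")
            if key in nested:
                kwargs[key] = nested[key](**(value or {}))
            else:
                kwargs[key] = value
        return PipelineConfig(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


# ------------------------------------------------------------------ raster IO


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF as float in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr /= 65535.0 if arr.max() > 255 else 255.0
    return arr


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] raster (or boolean mask) as 16-bit PNG."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(float)
    arr = np.clip(arr, 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 65535.0 + 0.5).astype(np.uint16))


def stage_rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    """Deterministic per-stage, per-image generator derived from the seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage, index)))


# --------------------------------------------------------------- per image


@dataclass(frozen=True)
class ImageResult:
    """Everything the pipeline computed for one image."""

    pre: _preprocess.PreprocessResult
    seg: _segment.SegmentationResult
    fv: _features.FeatureVector


def process_image(image: np.ndarray, config: PipelineConfig,
                  rng: np.random.Generator) -> ImageResult:
    """Run preprocess, segmentation and feature extraction for one frame."""
    pre = _preprocess.preprocess_image(
        image,
        diffusion=config.diffusion,
        low_pct=config.stretch_low_pct,
        high_pct=config.stretch_high_pct,
        eta=config.unsharp_eta,
        kernel_sigma=config.unsharp_sigma,
    )
    seg = _segment.segment_lungs(pre.enhanced, pre.lung_mask, config.segment, rng)
    fv = _features.extract_features(seg, pre.enhanced, config.features,
                                    region=pre.lung_region)
    return ImageResult(pre, seg, fv)


def _persist_image(out_dir: Path, name: str, result: ImageResult) -> None:
    save_image(out_dir / f"{name}_enhanced.png", result.pre.enhanced)
    save_image(out_dir / f"{name}_lungmask.png", result.pre.lung_mask)
    for i, mask in enumerate(result.seg.masks):
        save_image(out_dir / f"{name}_part{i}.png", mask)


# ------------------------------------------------------------------- stages


def _fit_scaler(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    return mean, std


def _save_head(out_dir: Path, selection: _select.SelectionResult,
               mean: np.ndarray, std: np.ndarray, tau_risk: float) -> None:
    payload = {
        "selected": list(selection.selected),
        "critical_value": selection.critical_value,
        "significance_rank": selection.significance_rank,
        "scores": selection.scores.tolist(),
        "scaler_mean": mean.tolist(),
        "scaler_std": std.tolist(),
        "tau_risk": tau_risk,
        "feature_names": _features.feature_names(),
    }
    (out_dir / "selection.json").write_text(json.dumps(payload, indent=1))


def _load_head(out_dir: Path) -> dict:
    path = out_dir / "selection.json"
    if not path.exists():
        raise FileNotFoundError(f"missing selection artifact: {path}")
    return json.loads(path.read_text())


def _predictions_frame(names, preds, scores) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "filename": names,
            "class_label": [p.class_label for p in preds],
            "abnormal_score": [f"{s:.8f}" for s in scores],
            "risk_label": [p.risk_label for p in preds],
        }
    )


def _quadrant_truth_dice(seg: _segment.SegmentationResult,
                         lung_mask: np.ndarray, truth_lung: np.ndarray) -> float:
    quads = _segment._quadrant_slices(lung_mask)
    scores = []
    for mask, (rs, cs) in zip(seg.masks, quads):
        qt = np.zeros_like(truth_lung)
        qt[rs, cs] = truth_lung[rs, cs]
        scores.append(_metrics.dice(mask, qt))
    return float(np.mean(scores))


def run_pipeline(
    config: PipelineConfig,
    mode: str = "demo",
    out_dir: str | Path = "lungscreen_out",
    images: list[np.ndarray] | None = None,
    names: list[str] | None = None,
    labels: list[str] | None = None,
) -> dict:
    """Execute the screening pipeline.

    * ``demo``  — self-contained: phantom corpus, train, evaluate, report.
    * ``train`` — preprocess + features on the given images/labels, feature
      selection, classifier training; persists the model head.
    * ``predict`` — load a previously trained head from ``out_dir`` and
      classify the given images.

    Returns the report dict (also written to ``out_dir/report.json``).
    """
    if mode not in ("demo", "train", "predict"):
        raise ValueError(f"unknown mode {mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    if mode == "demo":
        report = _run_demo(config, out)
    elif mode == "train":
        if images is None or labels is None:
            raise ValueError("train mode requires images and labels")
        report = _run_train(config, out, images, names, labels)
    else:
        if images is None:
            raise ValueError("predict mode requires images")
        report = _run_predict(config, out, images, names)
    report["runtime_s"] = round(time.time() - t_start, 2)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _extract_corpus(config: PipelineConfig, out: Path, images, names):
    rows = []
    results = []
    for i, (img, name) in enumerate(zip(images, names)):
        logger.info("processing %s (%d/%d)", name, i + 1, len(images))
        res = process_image(img, config, stage_rng(config.seed, 2, i))
        results.append(res)
        rows.append(res.fv.values)
        if config.save_intermediates:
            _persist_image(out, name, res)
    matrix = np.vstack(rows)
    frame = pd.DataFrame(matrix, columns=_features.feature_names())
    frame.insert(0, "filename", names)
    frame.to_csv(out / "features.csv", index=False, float_format="%.10g")
    return matrix, results


def _run_demo(config: PipelineConfig, out: Path) -> dict:
    n = config.n_phantoms
    n_abn = int(round(n * config.abnormal_fraction))
    flags = np.array([i < n_abn for i in range(n)])
    rng = stage_rng(config.seed, 0)
    rng.shuffle(flags)

    images, names, truths, specs = [], [], [], []
    for i, abnormal in enumerate(flags):
        spec_seed = int(stage_rng(config.seed, 1, i).integers(0, 2**31 - 1))
        spec = _phantom.random_spec(
            spec_seed, bool(abnormal), height=config.phantom_size,
            width=config.phantom_size,
        )
        img, truth = _phantom.generate_phantom(spec)
        images.append(img)
        truths.append(truth)
        specs.append(spec)
        names.append(f"phantom_{i:03d}")
    pd.DataFrame(
        {
            "filename": names,
            "class_label": [t.class_label for t in truths],
            "risk_label": [t.risk_label for t in truths],
            "seed": [s.seed for s in specs],
        }
    ).to_csv(out / "labels.csv", index=False)

    matrix, results = _extract_corpus(config, out, images, names)
    y = np.array([t.class_label == "Abnormal" for t in truths], dtype=int)

    # stratified train/test split, seeded
    split_rng = stage_rng(config.seed, 3)
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        idx = idx[split_rng.permutation(len(idx))]
        k = int(round(len(idx) * config.train_fraction))
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    train_idx, test_idx = sorted(train_idx), sorted(test_idx)

    selection = _select.select_features(matrix[train_idx], y[train_idx], config.select)
    sel = list(selection.selected)
    x_sel = matrix[:, sel]
    mean, std = _fit_scaler(x_sel[train_idx])
    x_std = (x_sel - mean) / std
    _save_head(out, selection, mean, std, config.tau_risk)

    net_cfg = dataclasses.replace(
        config.presnet, seed=int(stage_rng(config.seed, 4).integers(0, 2**31 - 1))
    )
    model = _classify.build_presnet(net_cfg, input_dim=len(sel))
    model, history = _classify.train(model, x_std[train_idx], y[train_idx], net_cfg)
    _classify.save_model(model, out / "model.npz")

    preds = _classify.predict_batch(model, x_std)
    preds = [
        _classify.risk_screen(p, matrix[i], tau_risk=config.tau_risk)
        if p.class_label == "Abnormal"
        else p
        for i, p in enumerate(preds)
    ]
    scores = [p.abnormal_score for p in preds]
    _predictions_frame(names, preds, scores).to_csv(out / "predictions.csv", index=False)

    def confusion(idx) -> _metrics.ConfusionCounts:
        tp = sum(1 for i in idx if y[i] == 1 and preds[i].class_label == "Abnormal")
        fp = sum(1 for i in idx if y[i] == 0 and preds[i].class_label == "Abnormal")
        tn = sum(1 for i in idx if y[i] == 0 and preds[i].class_label == "Normal")
        fn = sum(1 for i in idx if y[i] == 1 and preds[i].class_label == "Normal")
        return _metrics.ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)

    test_metrics = _metrics.confusion_metrics(confusion(test_idx))
    train_metrics = _metrics.confusion_metrics(confusion(train_idx))

    lung_dice = [
        _metrics.dice(res.pre.lung_mask, t.lung_mask)
        for res, t in zip(results, truths)
    ]
    quad_dice = [
        _quadrant_truth_dice(res.seg, res.pre.lung_mask, t.lung_mask)
        for res, t in zip(results, truths)
    ]
    abn_test = [i for i in test_idx if y[i] == 1]
    risk_hits = sum(
        1 for i in abn_test if preds[i].risk_label == truths[i].risk_label
    )
    report = {
        "mode": "demo",
        "n_images": n,
        "n_train": len(train_idx),
        "n_test": len(test_idx),
        "n_selected_features": len(sel),
        "significance_rank": selection.significance_rank,
        "critical_value": selection.critical_value,
        "test": test_metrics,
        "train": train_metrics,
        "risk_accuracy_abnormal_test": (risk_hits / len(abn_test)) if abn_test else 0.0,
        "mean_lung_dice": float(np.mean(lung_dice)),
        "mean_quadrant_dice": float(np.mean(quad_dice)),
        "final_train_loss": history["loss"][-1],
    }
    return report


def _run_train(config: PipelineConfig, out: Path, images, names, labels) -> dict:
    names = names or [f"image_{i:03d}" for i in range(len(images))]
    y = np.array([str(lbl) == "Abnormal" for lbl in labels], dtype=int)
    matrix, _ = _extract_corpus(config, out, images, names)
    selection = _select.select_features(matrix, y, config.select)
    sel = list(selection.selected)
    mean, std = _fit_scaler(matrix[:, sel])
    x_std = (matrix[:, sel] - mean) / std
    _save_head(out, selection, mean, std, config.tau_risk)
    net_cfg = dataclasses.replace(
        config.presnet, seed=int(stage_rng(config.seed, 4).integers(0, 2**31 - 1))
    )
    model = _classify.build_presnet(net_cfg, input_dim=len(sel))
    model, history = _classify.train(model, x_std, y, net_cfg)
    _classify.save_model(model, out / "model.npz")
    return {
        "mode": "train",
        "n_images": len(images),
        "n_selected_features": len(sel),
        "final_train_loss": history["loss"][-1],
        "final_train_accuracy": history["accuracy"][-1],
    }


def _run_predict(config: PipelineConfig, out: Path, images, names) -> dict:
    model_path = out / "model.npz"
    if not model_path.exists():
        raise FileNotFoundError(f"missing model checkpoint: {model_path}")
    head = _load_head(out)
    model = _classify.load_model(model_path)
    names = names or [f"image_{i:03d}" for i in range(len(images))]
    matrix, _ = _extract_corpus(config, out, images, names)
    sel = head["selected"]
    x_std = (matrix[:, sel] - np.array(head["scaler_mean"])) / np.array(head["scaler_std"])
    preds = _classify.predict_batch(model, x_std)
    preds = [
        _classify.risk_screen(p, matrix[i], tau_risk=head["tau_risk"])
        if p.class_label == "Abnormal"
        else p
        for i, p in enumerate(preds)
    ]
    scores = [p.abnormal_score for p in preds]
    _predictions_frame(names, preds, scores).to_csv(out / "predictions.csv", index=False)
    n_abn = sum(p.class_label == "Abnormal" for p in preds)
    return {"mode": "predict", "n_images": len(images), "n_abnormal": n_abn}
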