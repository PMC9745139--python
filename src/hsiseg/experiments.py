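"""Desk-scale comparison experiments on synthetic scenes.

Three ladders mirror the method's ablation structure:

* ``e1`` — architecture: plain-convolution U-Net vs the improved block
  with the residual shortcut off vs the full block, all single-branch on
  the PCA input. Surfaces the parameter-count invariants (residual adds
  none; the separable block is far smaller than plain convolution).
* ``e2`` — single-channel stacking: the hand-crafted features appended
  to the PCA bands as one ever-wider input (PCA, +NDVI, +Sobel, +GLCM).
* ``e3`` — dual-branch fusion: PCA alone, then PCA paired with NDVI,
  NDVI+GLCM, NDVI+GLCM+Sobel in the second branch.

Every variant in a run consumes the same tiles and split (variants slice
channels out of one shared 12-channel tile set), trains from the same
seed, and is written out as a checkpoint plus a row of the comparison
table; the table regenerates from checkpoints without retraining.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import MetricsReport, confusion_matrix
from .features import build_artificial_stack
from .network import (
    NetConfig,
    build_dual_branch,
    build_plain_unet,
    build_single_branch,
    count_parameters,
)
from .preprocess import (
    Tile,
    TileSet,
    apply_pca,
    fit_pca,
    split_tiles,
    tile_scene,
)
from .synthetic import SceneSpec, generate_scene
from .training import TrainConfig, load_checkpoint, save_checkpoint, train_model
from .types import FeatureStack, LabelMap

__all__ = [
    "Variant",
    "ExperimentSpec",
    "EXPERIMENTS",
    "prepare_tiles",
    "run_experiment",
    "regenerate_report",
]

# channel layout of the shared 12-channel tile stack
PCA_CH = list(range(6))
NDVI_CH = [6]
GLCM_CH = [7, 8, 9, 10]
SOBEL_CH = [11]


@dataclass
class Variant:
    """One model in a comparison ladder."""

    name: str
    branch_mode: str = "single"  # single | dual
    block: str = "separable"  # separable | plain
    residual: bool = True
    pca_channels: list[int] = field(default_factory=lambda: list(PCA_CH))
    art_channels: list[int] = field(default_factory=list)


EXPERIMENTS: dict[str, list[Variant]] = {
    "e1": [
        Variant("plain_unet", block="plain"),
        Variant("separable_no_residual", residual=False),
        Variant("separable_residual"),
    ],
    "e2": [
        Variant("pca"),
        Variant("pca_ndvi", pca_channels=PCA_CH + NDVI_CH),
        Variant("pca_ndvi_sobel", pca_channels=PCA_CH + NDVI_CH + SOBEL_CH),
        Variant("pca_ndvi_sobel_glcm",
                pca_channels=PCA_CH + NDVI_CH + SOBEL_CH + GLCM_CH),
    ],
    "e3": [
        Variant("pca"),
        Variant("pca|ndvi", branch_mode="dual", art_channels=NDVI_CH),
        Variant("pca|ndvi+glcm", branch_mode="dual",
                art_channels=NDVI_CH + GLCM_CH),
        Variant("pca|ndvi+glcm+sobel", branch_mode="dual",
                art_channels=NDVI_CH + GLCM_CH + SOBEL_CH),
    ],
}


@dataclass
class ExperimentSpec:
    """Scene, variants and protocol of one comparison run.

    Defaults are the desk-scale study conditions: a 256x256x32 scene
    with 5 classes, 64-pixel tiles split 8:2, 30 epochs at lr 1e-3 (the
    constant-rate protocol rescaled for the short desk-scale schedule).
    """

    name: str
    scene: SceneSpec = field(default_factory=SceneSpec)
    variants: list[Variant] | None = None
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        max_epochs=30, lr=1e-3))
    tile: int = 64
    ratio: float = 0.8
    channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variants is None:
            if self.name not in EXPERIMENTS:
                raise ValueError(f"unknown experiment {self.name!r}")
            self.variants = EXPERIMENTS[self.name]


def prepare_tiles(spec: ExperimentSpec
                  ) -> tuple[TileSet, TileSet, LabelMap]:
    """Scene -> PCA + features -> shared 12-channel tiles -> 8:2 split."""
    cube, labels, _ = generate_scene(spec.scene)
    model = fit_pca(cube, k=6)
    pca_cube = apply_pca(cube, model)
    stack = build_artificial_stack(cube, model)
    combined = FeatureStack(
        np.concatenate([pca_cube.data, stack.data], axis=-1),
        channel_names=tuple(f"pc{i + 1}" for i in range(6))
        + stack.channel_names,
    )
    from .types import SpectralCube

    combined_cube = SpectralCube(combined.data)
    tiles = tile_scene(combined_cube, None, labels, tile=spec.tile)
    train, test = split_tiles(tiles, ratio=spec.ratio, seed=spec.seed)
    return train, test, labels


def _slice_tiles(tiles: TileSet, variant: Variant) -> TileSet:
    out = []
    for t in tiles:
        pca = t.pca[:, :, variant.pca_channels]
        art = (t.pca[:, :, variant.art_channels]
               if variant.art_channels else None)
        out.append(Tile(pca, art, t.labels, t.origin, t.valid))
    return TileSet(out, role=tiles.role, scene_shape=tiles.scene_shape)


def _build_model(variant: Variant, spec: ExperimentSpec, n_classes: int):
    cfg = NetConfig(
        n_classes=n_classes,
        channels=spec.channels,
        in_channels=len(variant.pca_channels),
        in_channels_art=len(variant.art_channels) or None,
        residual=variant.residual,
        branch_mode=variant.branch_mode,
        seed=spec.seed,
    )
    if variant.branch_mode == "dual":
        return build_dual_branch(cfg)
    if variant.block == "plain":
        return build_plain_unet(cfg)
    return build_single_branch(cfg)


def _test_metrics(model, test: TileSet, labels: LabelMap) -> MetricsReport:
    """Confusion accumulated over held-out tiles, padding masked out."""
    from .training import _forward_tiles

    n = labels.scheme.n_classes
    model.eval()
    cm = np.zeros((n, n), dtype=np.int64)
    for start in range(0, len(test), 4):
        batch = test.tiles[start:start + 4]
        logits = _forward_tiles(model, batch)
        pred = logits.data.argmax(axis=1).astype(np.int32) + 1
        for t, p in zip(batch, pred):
            m = t.valid_mask()
            cm += confusion_matrix(
                np.where(m, t.labels, 0), np.where(m, p, 1), n_classes=n)
    model.train()
    return MetricsReport(cm, labels.scheme)


def _safe(name: str) -> str:
    return name.replace("|", "_vs_").replace("+", "-")


def run_experiment(spec: ExperimentSpec, out_dir) -> list[dict]:
    """Train every variant on the shared tiles and tabulate the results.

    Writes ``table.csv`` / ``table.json``, a Markdown summary, per-variant
    histories and checkpoints, a loss/accuracy plot when matplotlib is
    available, and the experiment spec needed to regenerate the report.
    Returns the table rows. A diverging variant is recorded as failed and
    the remaining variants still run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train, test, labels = prepare_tiles(spec)
    rows: list[dict] = []
    histories: dict[str, list[dict]] = {}
    for variant in spec.variants:
        model = _build_model(variant, spec, labels.scheme.n_classes)
        v_train = _slice_tiles(train, variant)
        v_test = _slice_tiles(test, variant)
        row: dict = {
            "variant": variant.name,
            "parameters": count_parameters(model),
        }
        try:
            model, history = train_model(model, v_train, spec.train,
                                         val=v_test)
        except RuntimeError as exc:
            row["status"] = f"failed: {exc}"
            rows.append(row)
            continue
        histories[variant.name] = history
        report = _test_metrics(model, v_test, labels)
        row["status"] = "ok"
        row["overall_accuracy"] = round(100 * report.overall_accuracy, 2)
        row["macro_f1"] = round(100 * report.macro_f1, 2)
        for group, f1 in report.grouped_f1.items():
            row[f"f1_{group}"] = round(100 * f1, 2)
        rows.append(row)
        save_checkpoint(model, out / f"{_safe(variant.name)}.ckpt.npz")
        with open(out / f"{_safe(variant.name)}.history.csv", "w",
                  newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=history[0].keys())
            writer.writeheader()
            writer.writerows(history)
    _write_report(spec, rows, out)
    _plot_histories(histories, out)
    (out / "experiment.json").write_text(json.dumps({
        "name": spec.name,
        "seed": spec.seed,
        "tile": spec.tile,
        "ratio": spec.ratio,
        "channels": list(spec.channels),
        "scene": vars(spec.scene) | {
            "class_kinds": list(spec.scene.class_kinds),
            "wavelength_range": list(spec.scene.wavelength_range),
        },
        "variants": [vars(v) for v in spec.variants],
    }, indent=2))
    return rows


def _write_report(spec: ExperimentSpec, rows: list[dict], out: Path) -> None:
    keys: list[str] = []
    for row in rows:
        for k in row:
            if k not in keys:
                keys.append(k)
    with open(out / "table.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(rows)
    (out / "table.json").write_text(json.dumps(rows, indent=2))
    lines = [f"# Experiment {spec.name}", "",
             "| " + " | ".join(keys) + " |",
             "|" + "---|" * len(keys)]
    for row in rows:
        lines.append("| " + " | ".join(str(row.get(k, "")) for k in keys)
                     + " |")
    (out / "summary.md").write_text("\n".join(lines) + "\n")


def _plot_histories(histories: dict[str, list[dict]], out: Path) -> None:
    if not histories:
        return
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    fig, (ax_loss, ax_acc) = plt.subplots(1, 2, figsize=(10, 4))
    for name, history in histories.items():
        epochs = [h["epoch"] for h in history]
        ax_loss.plot(epochs, [h["loss"] for h in history], label=name)
        ax_acc.plot(epochs, [h["accuracy"] for h in history], label=name)
    ax_loss.set_xlabel("epoch")
    ax_loss.set_ylabel("training loss")
    ax_acc.set_xlabel("epoch")
    ax_acc.set_ylabel("training accuracy")
    ax_acc.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "history.png", dpi=120)
    plt.close(fig)


def regenerate_report(out_dir) -> list[dict]:
    """Rebuild the comparison table from saved checkpoints, retraining
    nothing: the tiles are regenerated deterministically from the saved
    experiment spec and each checkpoint is only re-evaluated."""
    out = Path(out_dir)
    meta = json.loads((out / "experiment.json").read_text())
    scene_kwargs = dict(meta["scene"])
    scene_kwargs["class_kinds"] = tuple(scene_kwargs["class_kinds"])
    scene_kwargs["wavelength_range"] = tuple(
        scene_kwargs["wavelength_range"])
    spec = ExperimentSpec(
        name=meta["name"],
        scene=SceneSpec(**scene_kwargs),
        variants=[Variant(**v) for v in meta["variants"]],
        tile=meta["tile"],
        ratio=meta["ratio"],
        channels=tuple(meta["channels"]),
        seed=meta["seed"],
    )
    train, test, labels = prepare_tiles(spec)
    del train
    rows = []
    for variant in spec.variants:
        ckpt = out / f"{_safe(variant.name)}.ckpt.npz"
        if not ckpt.exists():
            continue
        model = load_checkpoint(ckpt)
        report = _test_metrics(model, _slice_tiles(test, variant), labels)
        row = {
            "variant": variant.name,
            "parameters": count_parameters(model),
            "status": "ok",
            "overall_accuracy": round(100 * report.overall_accuracy, 2),
            "macro_f1": round(100 * report.macro_f1, 2),
        }
        for group, f1 in report.grouped_f1.items():
            row[f"f1_{group}"] = round(100 * f1, 2)
        rows.append(row)
    return rows
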