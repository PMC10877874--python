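"""Training loop and the two experiment shapes: a per-system metric
comparison table and the loss × ROI-size grid.

Training is Adam on the fused-head loss (optionally also on the three
side outputs when deep supervision is enabled). Data preparation inside
the harness mirrors the preprocessing pipeline: normalize each slice,
crop a tumor-centered ROI at the configured size, augment the training
split five-fold. The held-out split is evaluated with the four-metric
suite. Every source of randomness is derived from ``config.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import metrics
from .losses import LOSS_FUNCTIONS, loss_and_logit_grad
from .network import EdgeOutputNet, NetworkConfig, binarize, build_network
from .preprocess import ROISpec, augment_five_fold, crop_roi, normalize_pair
from .synthetic import PhantomDataset
from ._nn import Adam, sigmoid

logger = logging.getLogger("ovadx")

__all__ = [
    "TrainConfig",
    "train_model",
    "evaluate_model",
    "run_loss_roi_grid",
    "compare_models",
    "compare_scores",
    "easy_phantom_spec",
    "easy_train_config",
    "grid_phantom_spec",
    "grid_train_config",
    "GRID_LOSSES",
    "GRID_SIZES",
]

# ---------------------------------------------------------------------------
# Canonical desk-scale experiment conditions. Two setups are exercised
# throughout: an "easy" demonstration (64 px phantoms, clear contrast,
# five-fold augmentation) on which a trained reduced-backbone network is
# expected to reach high Dice scores, and the loss × ROI-size grid
# (320 px source phantoms with small absolute-size tumors so that the
# tumor/background imbalance grows sharply with ROI size).
# ---------------------------------------------------------------------------

GRID_LOSSES = ("cbce", "ce", "dice")
GRID_SIZES = (96, 192, 320)


def easy_phantom_spec(seed: int = 11):
    from .synthetic import PhantomSpec

    return PhantomSpec(image_size=64, tumor_intensity_contrast=0.6,
                       noise_sd=0.05, seed=seed)


def easy_train_config(seed: int = 0) -> "TrainConfig":
    return TrainConfig(loss_name="cbce", roi_size=64, epochs=8, batch_size=8,
                       learning_rate=3e-3, seed=seed, split_fraction=0.8)


def grid_phantom_spec(seed: int = 21):
    from .synthetic import PhantomSpec

    return PhantomSpec(image_size=320, tumor_intensity_contrast=0.6,
                       noise_sd=0.05, tumor_radius=(12, 20), seed=seed)


def grid_train_config(seed: int = 0) -> "TrainConfig":
    return TrainConfig(loss_name="cbce", roi_size=96, epochs=8, batch_size=4,
                       learning_rate=5e-3, seed=seed, split_fraction=2 / 3,
                       augment=False)


@dataclass(frozen=True)
class TrainConfig:
    loss_name: str = "cbce"
    roi_size: int = 64
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 3e-3
    seed: int = 0
    split_fraction: float = 0.8
    augment: bool = True
    network: NetworkConfig | None = None

    def __post_init__(self) -> None:
        if self.loss_name not in LOSS_FUNCTIONS:
            raise ValueError(
                f"loss_name must be one of {sorted(LOSS_FUNCTIONS)}, "
                f"got {self.loss_name!r}"
            )
        if self.roi_size < 32:
            raise ValueError("roi_size must be >= 32")

    def network_config(self) -> NetworkConfig:
        if self.network is not None:
            return replace(self.network, input_size=self.roi_size)
        return NetworkConfig.reduced_default(
            input_size=self.roi_size, seed=self.seed
        )


def _prepare(dataset: PhantomDataset, roi_size: int) -> PhantomDataset:
    pairs = tuple(
        crop_roi(normalize_pair(p), ROISpec(size=roi_size)) for p in dataset
    )
    return PhantomDataset(pairs=pairs)


def split_dataset(dataset: PhantomDataset, fraction: float, seed: int):
    """Case-level held-out split (seeded shuffle)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_train = int(round(fraction * len(dataset)))
    train = PhantomDataset(pairs=tuple(dataset[i] for i in order[:n_train]))
    test = PhantomDataset(pairs=tuple(dataset[i] for i in order[n_train:]))
    return train, test


def train_model(config: TrainConfig, data: PhantomDataset) -> EdgeOutputNet:
    """Train a network on (the training split of) ``data``.

    Returns the trained network; per-epoch mean losses are attached as
    ``net.history`` and logged. Aborts on a non-finite loss.
    """
    if len(data) == 0:
        raise ValueError("training data is empty")
    train = _prepare(data, config.roi_size)
    if config.augment:
        train = augment_five_fold(train)
    net = build_network(config.network_config())
    return _fit(net, train, config)


def _fit(net: EdgeOutputNet, train: PhantomDataset, config: TrainConfig):
    images = np.stack([p.image for p in train])[:, None]
    masks = np.stack([p.mask for p in train])
    opt = Adam(net.param_slots(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    n = len(train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x, y = images[idx], masks[idx]
            logits, sides = net.forward_logits(x)
            probs = sigmoid(logits[:, 0])
            value, grad = loss_and_logit_grad(config.loss_name, probs, y)
            d_sides = None
            if sides:
                d_sides = []
                for s in sides:
                    sv, sg = loss_and_logit_grad(
                        config.loss_name, sigmoid(s[:, 0]), y
                    )
                    value += sv
                    d_sides.append(sg[:, None])
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite {config.loss_name} loss at epoch {epoch + 1}"
                )
            net.backward_logits(grad[:, None], d_sides)
            opt.step()
            epoch_loss += value * len(idx)
        history.append(epoch_loss / n)
        logger.info("epoch %d/%d  %s loss %.6f", epoch + 1, config.epochs,
                    config.loss_name, history[-1])
    net.history = history
    return net


def evaluate_model(net: EdgeOutputNet, data: PhantomDataset,
                   threshold: float = 0.5):
    """Predict, binarize at ``threshold`` and score against gold masks.

    Returns (mean±sd table, list of per-case SegScore)."""
    test = _prepare(data, net.config.input_size)
    preds, golds, scores = [], [], []
    for pair in test:
        mask = binarize(net.predict(pair.image), threshold)
        preds.append(mask)
        golds.append(pair.mask)
        scores.append(metrics.score_pair(mask, pair.mask))
    return metrics.summarize_scores(scores), scores


def run_loss_roi_grid(losses, sizes, data: PhantomDataset,
                      base_config: TrainConfig | None = None):
    """Train one network per (loss, ROI size) cell and score the held-out
    split; the default 3 losses × 3 sizes yields the 9-network grid.

    Returns a DataFrame with one row per cell (mean metrics, percent
    scale). A failing cell is recorded with an ``error`` entry rather
    than dropped.
    """
    import pandas as pd

    base = base_config or TrainConfig()
    rows = []
    for loss_name in losses:
        for size in sizes:
            cfg = replace(base, loss_name=loss_name, roi_size=size)
            try:
                train, test = split_dataset(data, cfg.split_fraction, cfg.seed)
                net = train_model(replace(cfg, split_fraction=1.0), train)
                table, _ = evaluate_model(net, test)
                rows.append({
                    "loss": loss_name, "roi_size": size,
                    "dsc": table.loc["DSC/%", "mean"],
                    "se": table.loc["Se/%", "mean"],
                    "sp": table.loc["Sp/%", "mean"],
                    "hd": table.loc["HD", "mean"],
                    "error": "",
                })
            except Exception as exc:  # record, never silently drop a cell
                logger.exception("grid cell (%s, %d) failed", loss_name, size)
                rows.append({
                    "loss": loss_name, "roi_size": size,
                    "dsc": np.nan, "se": np.nan, "sp": np.nan, "hd": np.nan,
                    "error": str(exc),
                })
    return pd.DataFrame(rows)


def compare_scores(scores_by_system: dict):
    """Per-system mean ± sd of the four metrics plus pairwise differences
    of means, from per-case :class:`~ovadx.metrics.SegScore` lists."""
    import pandas as pd

    names = list(scores_by_system)
    summaries = {name: metrics.summarize_scores(s)
                 for name, s in scores_by_system.items()}
    table = pd.concat(summaries, axis=1)
    diffs = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diffs[f"{b} - {a}"] = (
                summaries[b]["mean"] - summaries[a]["mean"]
            )
    return table, pd.DataFrame(diffs)


def compare_models(model_outputs: dict, golds):
    """Score ≥2 systems' predicted masks on the same cases and tabulate
    mean ± sd per system with pairwise mean differences."""
    golds = list(golds)
    scores_by_system = {}
    for name, preds in model_outputs.items():
        preds = list(preds)
        if len(preds) != len(golds):
            raise ValueError(
                f"system {name!r} predicts {len(preds)} cases, expected "
                f"{len(golds)}"
            )
        scores_by_system[name] = [
            metrics.score_pair(p, g) for p, g in zip(preds, golds)
        ]
    return compare_scores(scores_by_system)
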