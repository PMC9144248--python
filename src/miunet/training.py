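"""Training protocols: single-contrast, joint, transfer, and grid search.

Thin functional wrappers over the estimators in :mod:`miunet.estimators`;
each returns the fitted estimator (whose ``history_`` frame is the
training record) so the pieces compose with the evaluation module and
with sklearn tooling alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.model_selection import ParameterGrid

from ._exceptions import ConfigurationError
from .estimators import MIUNetSegmenter, UNetSegmenter
from .losses import LossWeights
from .models import ModelConfig

__all__ = [
    "TrainConfig",
    "train_single",
    "train_joint",
    "train_transfer",
    "grid_search",
]

# hyperparameter search bounds used for validation of grid-produced configs
BATCH_RANGE = (2, 24)
LR_RANGE = (1e-6, 1e-1)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 6
    learning_rate: float = 3e-3
    epochs: int = 20
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    augment_copies: int = 0
    select_best: bool = True

    def validate_search_bounds(self):
        if not BATCH_RANGE[0] <= self.batch_size <= BATCH_RANGE[1]:
            raise ConfigurationError(
                f"batch_size {self.batch_size} outside {BATCH_RANGE}"
            )
        if not LR_RANGE[0] <= self.learning_rate <= LR_RANGE[1]:
            raise ConfigurationError(
                f"learning_rate {self.learning_rate} outside {LR_RANGE}"
            )


def _estimator_kwargs(model_cfg: ModelConfig, train_cfg: TrainConfig) -> dict:
    return dict(
        depth=model_cfg.depth,
        base_channels=model_cfg.base_channels,
        batch_norm=model_cfg.batch_norm,
        n_classes=model_cfg.n_classes,
        init_sigma=model_cfg.init_sigma,
        lambda1=train_cfg.weights.lambda1,
        learning_rate=train_cfg.learning_rate,
        batch_size=train_cfg.batch_size,
        epochs=train_cfg.epochs,
        seed=train_cfg.seed,
        augment_copies=train_cfg.augment_copies,
        select_best=train_cfg.select_best,
    )


def train_single(
    model_cfg: ModelConfig,
    X,
    y,
    train_cfg: TrainConfig,
    X_val=None,
    y_val=None,
) -> UNetSegmenter:
    """Train a single-image UNet on one contrast."""
    est = UNetSegmenter(**_estimator_kwargs(model_cfg, train_cfg))
    return est.fit(X, y, X_val=X_val, y_val=y_val)


def train_joint(
    model_cfg: ModelConfig,
    X_pairs,
    y_pairs,
    train_cfg: TrainConfig,
    X_val=None,
    y_val=None,
    stop_gradient: str = "none",
) -> MIUNetSegmenter:
    """Train the dual-stream joint model on contrast pairs."""
    est = MIUNetSegmenter(
        lambda_tv=train_cfg.weights.lambda_tv,
        lambda_sp=train_cfg.weights.lambda_sp,
        join_level=model_cfg.join_level,
        stop_gradient=stop_gradient,
        **_estimator_kwargs(model_cfg, train_cfg),
    )
    return est.fit(X_pairs, y_pairs, X_val=X_val, y_val=y_val)


def train_transfer(
    model_cfg: ModelConfig,
    X_pre,
    y_pre,
    X_fine,
    y_fine,
    train_cfg: TrainConfig,
    pretrain_epochs: int | None = None,
    X_val=None,
    y_val=None,
) -> UNetSegmenter:
    """Pretrain a UNet on one contrast, fine-tune the whole network on the
    other (no layer freezing)."""
    pre_epochs = train_cfg.epochs if pretrain_epochs is None else pretrain_epochs
    est = UNetSegmenter(
        **{**_estimator_kwargs(model_cfg, train_cfg), "epochs": pre_epochs}
    )
    est.fit(X_pre, y_pre)
    est.set_params(epochs=train_cfg.epochs, warm_start=True)
    return est.fit(X_fine, y_fine, X_val=X_val, y_val=y_val)


def grid_search(
    grid: dict[str, list],
    X,
    y,
    X_val,
    y_val,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    joint: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search maximizing validation mean Dice.

    `grid` maps estimator parameter names (e.g. ``learning_rate``,
    ``batch_size``, ``batch_norm``, ``lambda_tv``, ``lambda_sp``,
    ``join_level``) to candidate lists. Returns the winning parameter
    combination and the full results table; ties break toward lower
    learning rate, then smaller batch.
    """
    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    combos = list(ParameterGrid(grid))
    if not combos:
        raise ConfigurationError("empty hyperparameter grid")
    model_cfg = model_cfg if model_cfg is not None else ModelConfig(
        depth=3, base_channels=4
    )
    train_cfg = train_cfg if train_cfg is not None else TrainConfig(epochs=3)
    rows = []
    for params in combos:
        if joint:
            est = MIUNetSegmenter(
                lambda_tv=train_cfg.weights.lambda_tv,
                lambda_sp=train_cfg.weights.lambda_sp,
                **_estimator_kwargs(model_cfg, train_cfg),
            )
        else:
            est = UNetSegmenter(**_estimator_kwargs(model_cfg, train_cfg))
        est.set_params(**params)
        est.fit(X, y, X_val=X_val, y_val=y_val)
        val_dice = est.score(X_val, y_val)
        rows.append({**params, "val_dice": float(val_dice)})
    table = pd.DataFrame(rows)
    # argmax with documented tie-break: lower lr first, then smaller batch
    ranked = table.copy()
    ranked["_lr"] = ranked.get("learning_rate", train_cfg.learning_rate)
    ranked["_bs"] = ranked.get("batch_size", train_cfg.batch_size)
    ranked = ranked.sort_values(
        ["val_dice", "_lr", "_bs"], ascending=[False, True, True], kind="stable"
    )
    best = {k: ranked.iloc[0][k] for k in combos[0]}
    return best, table
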