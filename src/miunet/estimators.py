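"""Scikit-learn-style segmentation estimators.

`UNetSegmenter` fits the single-image network on (n, H, W) image stacks
with integer masks; `MIUNetSegmenter` fits the dual-stream joint network
on (n, 2, H, W) contrast pairs (axis 1: cine, LGE). Both follow the
sklearn estimator contract — keyword-only constructor params mirrored by
get_params/set_params, fit/predict/score, fitted attributes with a
trailing underscore — and compose with sklearn model selection.

Training is fully deterministic in `seed`: weight initialization, epoch
shuffles and augmentation angles all derive from it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._exceptions import ConfigurationError, DataError
from .losses import LossWeights, joint_loss, seg_loss
from .models import MIUNet, ModelConfig, UNet, count_parameters
from .nn import Adam, Tensor
from .phantom import LabeledSlice
from .preprocess import augment_rotation

__all__ = ["UNetSegmenter", "MIUNetSegmenter"]


def one_hot(masks: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, H, W) integer masks -> (N, C, H, W) float32 one-hot."""
    masks = np.asarray(masks)
    out = np.zeros((masks.shape[0], n_classes, *masks.shape[1:]), dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = masks == c
    return out


def hard_dice(pred_mask: np.ndarray, ref_mask: np.ndarray, label: int) -> float:
    a, b = pred_mask == label, ref_mask == label
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def mean_foreground_dice(pred: np.ndarray, ref: np.ndarray, n_classes: int = 4):
    """Per-slice structure-mean Dice over foreground labels, then averaged."""
    per_slice = [
        np.mean([hard_dice(p, r, c) for c in range(1, n_classes)])
        for p, r in zip(pred, ref)
    ]
    return float(np.mean(per_slice))


class _BaseSegmenter(BaseEstimator):
    def __init__(
        self,
        depth=4,
        base_channels=8,
        batch_norm=True,
        n_classes=4,
        lambda1=0.5,
        learning_rate=3e-3,
        batch_size=6,
        epochs=20,
        seed=0,
        init_sigma="he",
        augment_copies=0,
        rotation_range=(-60.0, 60.0),
        select_best=True,
        warm_start=False,
    ):
        self.depth = depth
        self.base_channels = base_channels
        self.batch_norm = batch_norm
        self.n_classes = n_classes
        self.lambda1 = lambda1
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.init_sigma = init_sigma
        self.augment_copies = augment_copies
        self.rotation_range = rotation_range
        self.select_best = select_best
        self.warm_start = warm_start

    def _model_config(self, **extra) -> ModelConfig:
        return ModelConfig(
            depth=self.depth,
            base_channels=self.base_channels,
            n_classes=self.n_classes,
            batch_norm=self.batch_norm,
            init_sigma=self.init_sigma,
            **extra,
        )

    def _validate_train_args(self, n: int):
        if n < 1:
            raise DataError("training set is empty")
        if not 0 <= self.lambda1 <= 1:
            raise ConfigurationError("lambda1 must be in [0, 1]")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")

    def _seeds(self):
        ss = np.random.SeedSequence(self.seed)
        init_seed, shuffle_seed, aug_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
        )
        return init_seed, shuffle_seed, aug_seed

    def _finalize(self, model, history_rows, best_state):
        if self.select_best and best_state is not None:
            model.load_state_dict(best_state)
        model.eval()
        self.model_ = model
        self.history_ = pd.DataFrame(history_rows)
        self.n_params_ = count_parameters(model)
        return self

    def _check_finite(self, value: float, epoch: int):
        if not np.isfinite(value):
            raise DataError(
                f"non-finite training loss ({value}) at epoch {epoch}; "
                "reduce the learning rate"
            )


class UNetSegmenter(_BaseSegmenter):
    """Single-image UNet trained with the Dice/BCE segmentation loss."""

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape != y.shape:
            raise DataError(f"expected matching (n, H, W) arrays, got {X.shape}")
        self._validate_train_args(len(X))
        init_seed, shuffle_seed, aug_seed = self._seeds()

        if self.warm_start and hasattr(self, "model_"):
            model = self.model_
        else:
            model = UNet(self._model_config(), seed=init_seed)
        opt = Adam(model.parameters(), lr=self.learning_rate)
        shuffle_rng = np.random.default_rng(shuffle_seed)
        aug_rng = np.random.default_rng(aug_seed)

        rows, best_state, best_val = [], None, -np.inf
        for epoch in range(self.epochs):
            imgs, msks = self._epoch_data(X, y, aug_rng)
            order = shuffle_rng.permutation(len(imgs))
            model.train()
            losses = []
            for lo in range(0, len(order), self.batch_size):
                idx = order[lo : lo + self.batch_size]
                opt.zero_grad()
                prob = model(Tensor(imgs[idx][:, None]))
                loss = seg_loss(
                    prob, Tensor(one_hot(msks[idx], self.n_classes)), self.lambda1
                )
                loss.backward()
                opt.step()
                losses.append(loss.item())
            train_loss = float(np.mean(losses))
            self._check_finite(train_loss, epoch)
            row = {"epoch": epoch, "loss": train_loss}
            if X_val is not None:
                val = self.score(np.asarray(X_val, dtype=np.float32), y_val, _model=model)
                row["val_dice"] = val
                if val > best_val:
                    best_val, best_state = val, model.state_dict()
            rows.append(row)
        return self._finalize(model, rows, best_state)

    def _epoch_data(self, X, y, aug_rng):
        if self.augment_copies <= 0:
            return X, y
        imgs, msks = [X], [y]
        for img, msk in zip(X, y):
            for _ in range(self.augment_copies):
                angle = aug_rng.uniform(*self.rotation_range)
                aug = augment_rotation(
                    LabeledSlice(img, msk), angle, self.rotation_range
                )
                imgs.append(aug.image[None].astype(np.float32))
                msks.append(aug.mask[None])
        return np.concatenate(imgs), np.concatenate(msks)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        return np.concatenate(
            [
                self.model_.predict_proba(X[lo : lo + self.batch_size])
                for lo in range(0, len(X), self.batch_size)
            ]
        )

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y, _model=None) -> float:
        """Mean per-slice foreground Dice against reference masks."""
        if _model is None:
            pred = self.predict(X)
        else:
            X = np.asarray(X, dtype=np.float32)
            pred = np.concatenate(
                [
                    _model.predict_proba(X[lo : lo + self.batch_size]).argmax(axis=1)
                    for lo in range(0, len(X), self.batch_size)
                ]
            )
        return mean_foreground_dice(pred, np.asarray(y), self.n_classes)


class MIUNetSegmenter(_BaseSegmenter):
    """Dual-stream joint segmenter with the composite objective.

    X is (n, 2, H, W) with axis 1 ordered (cine, LGE); y matches. The two
    slices of each pair share every augmentation draw (same anatomy).
    """

    def __init__(
        self,
        depth=4,
        base_channels=8,
        batch_norm=True,
        n_classes=4,
        lambda1=0.5,
        lambda_tv=0.0,
        lambda_sp=0.0,
        join_level=None,
        stop_gradient="none",
        learning_rate=3e-3,
        batch_size=6,
        epochs=20,
        seed=0,
        init_sigma="he",
        augment_copies=0,
        rotation_range=(-60.0, 60.0),
        select_best=True,
        warm_start=False,
    ):
        super().__init__(
            depth=depth,
            base_channels=base_channels,
            batch_norm=batch_norm,
            n_classes=n_classes,
            lambda1=lambda1,
            learning_rate=learning_rate,
            batch_size=batch_size,
            epochs=epochs,
            seed=seed,
            init_sigma=init_sigma,
            augment_copies=augment_copies,
            rotation_range=rotation_range,
            select_best=select_best,
            warm_start=warm_start,
        )
        self.lambda_tv = lambda_tv
        self.lambda_sp = lambda_sp
        self.join_level = join_level
        self.stop_gradient = stop_gradient

    @property
    def loss_weights(self) -> LossWeights:
        return LossWeights(self.lambda1, self.lambda_tv, self.lambda_sp)

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[1] != 2 or X.shape != y.shape:
            raise DataError(f"expected matching (n, 2, H, W) arrays, got {X.shape}")
        self._validate_train_args(len(X))
        weights = self.loss_weights
        init_seed, shuffle_seed, aug_seed = self._seeds()

        if self.warm_start and hasattr(self, "model_"):
            model = self.model_
        else:
            model = MIUNet(
                self._model_config(join_level=self.join_level), seed=init_seed
            )
        opt = Adam(model.parameters(), lr=self.learning_rate)
        shuffle_rng = np.random.default_rng(shuffle_seed)
        aug_rng = np.random.default_rng(aug_seed)
        self.augment_log_ = []

        term_keys = ("seg_cine", "seg_lge", "tv_cine", "tv_lge", "spatial")
        rows, best_state, best_val = [], None, -np.inf
        for epoch in range(self.epochs):
            pairs, masks = self._epoch_data(X, y, aug_rng, epoch)
            order = shuffle_rng.permutation(len(pairs))
            model.train()
            totals, term_sums = [], {k: [] for k in term_keys}
            for lo in range(0, len(order), self.batch_size):
                idx = order[lo : lo + self.batch_size]
                opt.zero_grad()
                pc, pl = model(
                    Tensor(pairs[idx][:, 0:1]), Tensor(pairs[idx][:, 1:2])
                )
                total, terms = joint_loss(
                    pc,
                    pl,
                    Tensor(one_hot(masks[idx][:, 0], self.n_classes)),
                    Tensor(one_hot(masks[idx][:, 1], self.n_classes)),
                    weights,
                    stop_gradient=self.stop_gradient,
                )
                total.backward()
                opt.step()
                totals.append(total.item())
                for k in term_keys:
                    term_sums[k].append(terms[k].item())
            train_loss = float(np.mean(totals))
            self._check_finite(train_loss, epoch)
            row = {"epoch": epoch, "loss": train_loss}
            row.update({k: float(np.mean(v)) for k, v in term_sums.items()})
            if X_val is not None:
                vc, vl = self._score_streams(
                    np.asarray(X_val, dtype=np.float32), np.asarray(y_val), model
                )
                row.update(
                    {"val_dice_cine": vc, "val_dice_lge": vl, "val_dice": (vc + vl) / 2}
                )
                if row["val_dice"] > best_val:
                    best_val, best_state = row["val_dice"], model.state_dict()
            rows.append(row)
        return self._finalize(model, rows, best_state)

    def _epoch_data(self, X, y, aug_rng, epoch):
        if self.augment_copies <= 0:
            return X, y
        pairs, masks = [X], [y]
        for i, (pair, msk) in enumerate(zip(X, y)):
            for _ in range(self.augment_copies):
                angle = aug_rng.uniform(*self.rotation_range)
                self.augment_log_.append((epoch, i, angle, angle))
                aug_imgs, aug_msks = [], []
                for s in range(2):  # both contrasts rotate by the same angle
                    aug = augment_rotation(
                        LabeledSlice(pair[s], msk[s]), angle, self.rotation_range
                    )
                    aug_imgs.append(aug.image.astype(np.float32))
                    aug_msks.append(aug.mask)
                pairs.append(np.stack(aug_imgs)[None])
                masks.append(np.stack(aug_msks)[None])
        return np.concatenate(pairs), np.concatenate(masks)

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float32)
        pc, pl = [], []
        for lo in range(0, len(X), self.batch_size):
            c, l = self.model_.predict_proba(
                X[lo : lo + self.batch_size, 0], X[lo : lo + self.batch_size, 1]
            )
            pc.append(c)
            pl.append(l)
        return np.concatenate(pc), np.concatenate(pl)

    def predict(self, X) -> np.ndarray:
        pc, pl = self.predict_proba(X)
        return np.stack([pc.argmax(axis=1), pl.argmax(axis=1)], axis=1)

    def _score_streams(self, X, y, model):
        pc, pl = [], []
        for lo in range(0, len(X), self.batch_size):
            c, l = model.predict_proba(
                X[lo : lo + self.batch_size, 0], X[lo : lo + self.batch_size, 1]
            )
            pc.append(c.argmax(axis=1))
            pl.append(l.argmax(axis=1))
        pc, pl = np.concatenate(pc), np.concatenate(pl)
        return (
            mean_foreground_dice(pc, y[:, 0], self.n_classes),
            mean_foreground_dice(pl, y[:, 1], self.n_classes),
        )

    def score(self, X, y) -> float:
        X = np.asarray(X, dtype=np.float32)
        vc, vl = self._score_streams(X, np.asarray(y), self.model_)
        return (vc + vl) / 2.0
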