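"""The multi-view image-set classifier.

One convolutional encoder, with a single weight set shared by all six
views, maps each photograph to a d-dimensional feature token. A Transformer
encoder (multi-head self-attention, post-norm blocks) then fuses the six
tokens — optionally with learned per-view identity embeddings added — and a
pooled set representation feeds a linear head producing class
probabilities. The pooled representation immediately before the head is the
set embedding exported for visualization.

Exposed as a scikit-learn estimator (:class:`MultiViewSetClassifier`) so it
composes with pipelines and model selection; the training recipe (Adam,
decoupled weight decay on weight matrices only, linear warmup + polynomial
decay, label-smoothed cross-entropy) lives in :mod:`toothset.training`.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from ._autograd import Tensor, concat, softmax
from .preprocessing import AugmentationPolicy, augment, resize_pad, to_unit
from .records import MultiViewRecord, VIEW_TAGS

__all__ = ["TinyEncoder", "ConvNeXtSLikeEncoder", "SetFusion", "SetClassifierNet",
           "MultiViewSetClassifier", "records_to_array"]


class TinyEncoder(nn.Module):
    """Four stride-2 conv stages, global average pool to the embedding dim.

    Small enough to train on one CPU; the default encoder for tests and
    desk-scale experiments.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        widths = [max(8, dim // 8), max(16, dim // 4), max(32, dim // 2), dim]
        # full-resolution first stage: fine cues (cusp bumps, thin roots)
        # survive into the strided stages
        strides = [1, 2, 2, 2]
        self.convs = [
            nn.Conv2d(c_in, c_out, kernel=3, stride=s, rng=rng)
            for c_in, c_out, s in zip([3] + widths[:-1], widths, strides)
        ]
        self.dim = dim

    def __call__(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        """Return (embeddings (N, d), final feature map (N, d, h, w))."""
        for conv in self.convs:
            x = conv(x).relu()
        return x.mean(axis=(2, 3)), x


class ConvNeXtSLikeEncoder(nn.Module):
    """An encoder following the ConvNeXt-S stage layout (depths 3/3/27/3).

    Residual 3x3 conv blocks stand in for the original depthwise blocks; no
    pretrained weights. Intended for larger machines — it is far too heavy
    for the CPU test path.
    """

    DEPTHS = (3, 3, 27, 3)
    WIDTHS = (96, 192, 384, 768)

    def __init__(self, dim: int, rng: np.random.Generator):
        self.stem = nn.Conv2d(3, self.WIDTHS[0], kernel=4, stride=4, rng=rng, pad=0)
        self.downsamples = []
        self.blocks = []
        for si, (depth, width) in enumerate(zip(self.DEPTHS, self.WIDTHS)):
            if si > 0:
                self.downsamples.append(
                    nn.Conv2d(self.WIDTHS[si - 1], width, kernel=2, stride=2, rng=rng, pad=0)
                )
            stage = []
            for _ in range(depth):
                stage.append(nn.Conv2d(width, width, kernel=3, stride=1, rng=rng))
                stage.append(nn.Conv2d(width, width, kernel=3, stride=1, rng=rng))
            self.blocks.append(stage)
        self.proj = nn.Linear(self.WIDTHS[-1], dim, rng)
        self.dim = dim

    def __call__(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        x = self.stem(x)
        for si, stage in enumerate(self.blocks):
            if si > 0:
                x = self.downsamples[si - 1](x)
            for i in range(0, len(stage), 2):
                x = x + stage[i + 1](stage[i](x).relu())
        return self.proj(x.mean(axis=(2, 3))), x


class SetFusion(nn.Module):
    """Attention fusion of view tokens into one set representation."""

    def __init__(
        self,
        dim: int,
        n_views: int,
        layers: int,
        heads: int,
        mlp_ratio: int,
        pooling: str,
        view_embedding: bool,
        rng: np.random.Generator,
    ):
        if pooling not in ("learned_token", "mean"):
            raise ValueError(f"unknown pooling {pooling!r}")
        self.pooling = pooling
        self.n_views = n_views
        self.view_embed = (
            nn.Parameter(rng.normal(0.0, 0.02, (n_views, dim)), decay=False)
            if view_embedding
            else None
        )
        self.agg_token = (
            nn.Parameter(rng.normal(0.0, 0.02, (1, 1, dim)), decay=False)
            if pooling == "learned_token"
            else None
        )
        # normalizing the incoming view tokens keeps the attention input at
        # unit scale regardless of the encoder's activation statistics
        self.input_norm = nn.LayerNorm(dim)
        self.blocks = [
            nn.TransformerBlock(dim, heads, mlp_ratio, rng) for _ in range(layers)
        ]
        self.output_norm = nn.LayerNorm(dim)

    def __call__(self, tokens: Tensor) -> Tensor:
        """(B, V, d) view tokens -> (B, d) set embedding."""
        B, V, D = tokens.shape
        if V != self.n_views:
            raise ValueError(f"expected {self.n_views} view tokens, got {V}")
        tokens = self.input_norm(tokens)
        if self.view_embed is not None:
            tokens = tokens + self.view_embed.reshape(1, V, D)
        if self.agg_token is not None:
            agg = self.agg_token * np.ones((B, 1, D), dtype=np.float32)
            tokens = concat([agg, tokens], axis=1)
        for block in self.blocks:
            tokens = block(tokens)
        tokens = self.output_norm(tokens)
        if self.pooling == "learned_token":
            return tokens[:, 0, :]
        return tokens.mean(axis=1)


class SetClassifierNet(nn.Module):
    """Encoder shared across views + attention fusion + linear head."""

    def __init__(
        self,
        encoder: str,
        dim: int,
        n_views: int,
        n_classes: int,
        fusion_layers: int,
        fusion_heads: int,
        mlp_ratio: int,
        pooling: str,
        view_embedding: bool,
        seed: int,
    ):
        rng = np.random.default_rng(seed)
        if encoder == "tiny":
            self.encoder = TinyEncoder(dim, rng)
        elif encoder == "convnext_s_like":
            self.encoder = ConvNeXtSLikeEncoder(dim, rng)
        else:
            raise ValueError(f"unknown encoder {encoder!r}")
        self.fusion = SetFusion(
            dim, n_views, fusion_layers, fusion_heads, mlp_ratio, pooling,
            view_embedding, rng,
        )
        self.head = nn.Linear(dim, n_classes, rng)
        self.dim = dim
        self.n_views = n_views
        self.n_classes = n_classes

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        """(B, V, 3, S, S) -> (logits (B, C), set embeddings (B, d)).

        Every view passes through the same encoder parameters; one forward
        pass over a batch of B specimens processes B*V images.
        """
        B, V, C, H, W = x.shape
        if V != self.n_views:
            raise ValueError(f"expected {self.n_views} views per specimen, got {V}")
        flat = x.reshape(B * V, C, H, W)
        feats, _ = self.encoder(flat)
        tokens = feats.reshape(B, V, self.dim)
        embedding = self.fusion(tokens)
        return self.head(embedding), embedding

    def feature_map(self, images: Tensor) -> Tensor:
        """Final encoder feature map for a batch of single images."""
        _, fmap = self.encoder(images)
        return fmap


def records_to_array(
    records: Sequence[MultiViewRecord],
    side: int,
    views: Sequence[str] = VIEW_TAGS,
) -> np.ndarray:
    """Load, letterbox and stack records to (N, V, side, side, 3) uint8."""
    out = np.empty((len(records), len(views), side, side, 3), dtype=np.uint8)
    for i, rec in enumerate(records):
        for j, view in enumerate(views):
            if view not in rec.views:
                raise ValueError(
                    f"specimen {rec.specimen_id!r} is missing view {view!r}"
                )
            out[i, j] = resize_pad(rec.image(view), side)
    return out


class MultiViewSetClassifier(ClassifierMixin, BaseEstimator):
    """Image-set classifier: shared-weight per-view encoder + attention fusion.

    Parameters mirror the model and training recipe: a ``tiny`` (default)
    or ``convnext_s_like`` encoder producing ``embedding_dim``-dimensional
    view tokens (default 512), ``fusion_layers`` post-norm Transformer
    blocks with ``fusion_heads`` heads, learned-token or mean pooling, and
    optional learned view-identity embeddings. Training uses Adam
    (betas 0.9/0.99), decoupled weight decay 0.5 on weight matrices,
    linear warmup followed by polynomial decay (power 1.5), and
    label-smoothed cross-entropy (0.1); gradients are clipped to a global
    norm (default 1.0) for stability in short schedules. The base learning
    rate default of 1e-4 is a package choice — it is the one knob the
    recipe leaves open.

    ``fit`` accepts either an array ``(N, V, H, W, 3)`` of uint8 images in
    canonical view order or a list of :class:`MultiViewRecord`; images of
    any size are letterboxed to ``image_size``. ``views`` restricts the
    model to a subset of views (e.g. a single-view baseline).
    """

    def __init__(
        self,
        encoder: str = "tiny",
        embedding_dim: int = 512,
        fusion_layers: int = 2,
        fusion_heads: int = 8,
        mlp_ratio: int = 4,
        pooling: str = "learned_token",
        view_embedding: bool = True,
        image_size: int = 224,
        views: Tuple[str, ...] = VIEW_TAGS,
        epochs: int = 300,
        warmup_epochs: int = 60,
        poly_power: float = 1.5,
        base_lr: float = 1e-4,
        weight_decay: float = 0.5,
        adam_betas: Tuple[float, float] = (0.9, 0.99),
        decoupled_decay: bool = True,
        label_smoothing: float = 0.1,
        batch_specimens: int = 16,
        clip_grad_norm: float = 1.0,
        augment_policy: Optional[AugmentationPolicy] = None,
        standardize: bool = False,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.encoder = encoder
        self.embedding_dim = embedding_dim
        self.fusion_layers = fusion_layers
        self.fusion_heads = fusion_heads
        self.mlp_ratio = mlp_ratio
        self.pooling = pooling
        self.view_embedding = view_embedding
        self.image_size = image_size
        self.views = views
        self.epochs = epochs
        self.warmup_epochs = warmup_epochs
        self.poly_power = poly_power
        self.base_lr = base_lr
        self.weight_decay = weight_decay
        self.adam_betas = adam_betas
        self.decoupled_decay = decoupled_decay
        self.label_smoothing = label_smoothing
        self.batch_specimens = batch_specimens
        self.clip_grad_norm = clip_grad_norm
        self.augment_policy = augment_policy
        self.standardize = standardize
        self.seed = seed
        self.verbose = verbose

    # -- data plumbing -------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], MultiViewRecord):
            return records_to_array(X, self.image_size, self.views)
        arr = np.asarray(X)
        if arr.ndim != 5 or arr.shape[-1] != 3:
            raise ValueError(
                f"X must be (N, V, H, W, 3) images or MultiViewRecords, got {arr.shape}"
            )
        if arr.shape[1] != len(self.views):
            raise ValueError(
                f"X has {arr.shape[1]} views per specimen, expected {len(self.views)}"
            )
        if arr.shape[2] != self.image_size or arr.shape[3] != self.image_size:
            arr = np.stack(
                [
                    np.stack([resize_pad(v, self.image_size) for v in spec])
                    for spec in arr
                ]
            )
        return arr.astype(np.uint8)

    def _to_model_input(self, batch: np.ndarray, train: bool, rng=None) -> Tensor:
        # (B, V, S, S, 3) uint8 -> (B, V, 3, S, S) float tensor in [0, 1].
        # Augmentation draws are independent per image, train-time only.
        if train and getattr(self, "_policy", None) is not None:
            aug = np.empty_like(batch)
            for i in range(batch.shape[0]):
                for j in range(batch.shape[1]):
                    aug[i, j] = augment(
                        batch[i, j], self._policy, int(rng.integers(2**31))
                    )
            batch = aug
        unit = np.stack(
            [
                np.stack([to_unit(v, self.standardize) for v in spec])
                for spec in batch
            ]
        )
        return Tensor(unit.transpose(0, 1, 4, 2, 3))

    def _build_net(self, n_classes: int) -> SetClassifierNet:
        return SetClassifierNet(
            encoder=self.encoder,
            dim=self.embedding_dim,
            n_views=len(self.views),
            n_classes=n_classes,
            fusion_layers=self.fusion_layers,
            fusion_heads=self.fusion_heads,
            mlp_ratio=self.mlp_ratio,
            pooling=self.pooling,
            view_embedding=self.view_embedding,
            seed=self.seed,
        )

    # -- estimator API ---------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on specimens X with labels y; optionally track a val set."""
        from .training import lr_at, smoothed_cross_entropy  # cycle guard

        X = self._validate_X(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError(f"X has {len(X)} specimens but y has {len(y)} labels")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_idx, minlength=len(self.classes_))
        if self.verbose and (counts == 0).any():
            print("warning: empty classes in training data")

        self._policy = (
            self.augment_policy
            if isinstance(self.augment_policy, AugmentationPolicy)
            else None
        )
        self.net_ = self._build_net(len(self.classes_))
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x7EA]))
        n = len(X)
        batches_per_epoch = math.ceil(n / self.batch_specimens)
        total_steps = self.epochs * batches_per_epoch
        warmup_steps = self.warmup_epochs * batches_per_epoch
        optimizer = nn.Adam(
            self.net_.parameters(),
            lr=self.base_lr,
            betas=self.adam_betas,
            weight_decay=self.weight_decay,
            decoupled=self.decoupled_decay,
        )

        if X_val is not None:
            X_val = self._validate_X(X_val)
            y_val = np.asarray(y_val)

        self.history_ = []
        self.lr_log_ = []
        best_val = -np.inf
        step = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for b in range(batches_per_epoch):
                idx = order[b * self.batch_specimens : (b + 1) * self.batch_specimens]
                xb = self._to_model_input(X[idx], train=True, rng=rng)
                lr = lr_at(
                    step, total_steps, warmup_steps, self.base_lr, self.poly_power
                )
                optimizer.lr = lr
                self.lr_log_.append(lr)
                logits, _ = self.net_.forward(xb)
                loss = smoothed_cross_entropy(
                    logits, y_idx[idx], self.label_smoothing, len(self.classes_)
                )
                self.net_.zero_grad()
                loss.backward()
                if self.clip_grad_norm:
                    params = self.net_.parameters()
                    total = math.sqrt(
                        sum(float((p.grad**2).sum()) for p in params)
                    )
                    if total > self.clip_grad_norm:
                        scale = self.clip_grad_norm / total
                        for p in params:
                            p.grad *= scale
                optimizer.step()
                epoch_loss += float(loss.data) * len(idx)
                step += 1
            entry = {
                "epoch": epoch,
                "loss": epoch_loss / n,
                "lr": self.lr_log_[-1],
            }
            if X_val is not None:
                val_top1 = float(
                    np.mean(self._predict_indices(X_val) == self._encode(y_val))
                )
                entry["val_top1"] = val_top1
                if val_top1 >= best_val:
                    best_val = val_top1
                    self.best_state_ = self.net_.state_dict()
                    self.best_epoch_ = epoch
            self.history_.append(entry)
            if self.verbose:
                print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.4g}" for k, v in entry.items() if k != "epoch"))
        if X_val is not None and hasattr(self, "best_state_"):
            self.net_.load_state_dict(self.best_state_)
        return self

    def _encode(self, y) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes_)}
        try:
            return np.asarray([index[v] for v in np.asarray(y)])
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not seen during fit") from None

    def _forward_eval(self, X: np.ndarray, want_embedding: bool = False):
        probs, embeds = [], []
        for start in range(0, len(X), self.batch_specimens):
            xb = self._to_model_input(X[start : start + self.batch_specimens], train=False)
            logits, emb = self.net_.forward(xb)
            probs.append(softmax(logits, axis=-1).data)
            embeds.append(emb.data)
        return np.concatenate(probs), np.concatenate(embeds)

    def _predict_indices(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self._forward_eval(X)
        return probs.argmax(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        """Row-stochastic (N, C) probability matrix, classes in classes_ order."""
        check_is_fitted(self, "net_")
        probs, _ = self._forward_eval(self._validate_X(X))
        return probs

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def embed(self, X) -> np.ndarray:
        """Set embeddings (N, embedding_dim): the pre-head pooled representation."""
        check_is_fitted(self, "net_")
        _, emb = self._forward_eval(self._validate_X(X))
        return emb

    def view_feature_map(self, image: np.ndarray) -> np.ndarray:
        """Final encoder feature map (channels, h, w) for one view image."""
        check_is_fitted(self, "net_")
        arr = to_unit(resize_pad(image, self.image_size), self.standardize)
        fmap = self.net_.feature_map(Tensor(arr.transpose(2, 0, 1)[None]))
        return fmap.data[0]
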