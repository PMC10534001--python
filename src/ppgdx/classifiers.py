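"""The two classification branches.

Image branch: a transfer-learning-style image classifier with a
configurable backbone. ``tiny_test_cnn`` (the default) is a small
NumPy network that trains from scratch in minutes on CPU; the named
pretrained backbones (``googlenet``, ``efficientnet_b0``) are optional
plug-ins requiring the ``torch`` extra, with the final classification
layer replaced by an n-class head.

Feature branch: linear discriminant analysis and K-nearest-neighbour
(K = 9) classifiers on the 144 DWT band features. Both are scikit-learn
pipelines with a StandardScaler fitted on training data only — energy
and skewness live on wildly different scales and KNN is scale-sensitive.
The LDA pooled covariance gets light diagonal loading (shrinkage toward
the average variance) because 144 features exceed the participant count.

Training hyperparameters follow the published regime: learning rate
0.005, stochastic gradient descent, cross-entropy loss, 10 minibatches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cnn import TinyScalogramCNN

BACKBONES = ("tiny_test_cnn", "googlenet", "efficientnet_b0")


@dataclass(frozen=True)
class TrainConfig:
    backbone: str = "tiny_test_cnn"
    learning_rate: float = 0.005
    momentum: float = 0.9
    n_minibatches: int = 10
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; available: {BACKBONES}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


@dataclass(frozen=True)
class ImagePrediction:
    participant_id: str
    channel: str
    window_index: int
    true_label: str
    predicted_label: str
    scores: tuple[float, ...]  # (p_ssc, p_control), sums to 1


def build_model(config: TrainConfig, n_classes: int = 2):
    """Instantiate the configured backbone with an ``n_classes`` head."""
    if config.backbone == "tiny_test_cnn":
        return TinyScalogramCNN(n_classes=n_classes, seed=config.seed)
    try:  # pragma: no cover - exercised only with the torch extra installed
        import torch  # noqa: F401
        import torchvision
    except ImportError as exc:
        raise ImportError(
            f"backbone {config.backbone!r} requires the optional 'torch' extra "
            "(pip install ppgdx[torch]); use backbone='tiny_test_cnn' otherwise"
        ) from exc
    import torch.nn as nn  # pragma: no cover

    if config.backbone == "googlenet":  # pragma: no cover
        model = torchvision.models.googlenet(weights="DEFAULT")
        model.fc = nn.Linear(model.fc.in_features, n_classes)
    else:  # pragma: no cover
        model = torchvision.models.efficientnet_b0(weights="DEFAULT")
        model.classifier[-1] = nn.Linear(model.classifier[-1].in_features, n_classes)
    return model  # pragma: no cover


def train(model, images: np.ndarray, labels: np.ndarray, config: TrainConfig):
    """Fit the image classifier; returns (model, per-epoch loss trace)."""
    if not isinstance(model, TinyScalogramCNN):
        raise NotImplementedError(
            "in-package training is implemented for tiny_test_cnn; torch backbones "
            "come with their own training loops"
        )
    trace = model.fit(
        images,
        labels,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        n_minibatches=config.n_minibatches,
        seed=config.seed + 1,
    )
    return model, trace


def fit_lda(X: np.ndarray, y: np.ndarray, shrinkage: float = 1e-4) -> Pipeline:
    """Pooled-covariance LDA with diagonal loading, on z-scored features."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("LDA requires at least 2 training participants per class")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("lda", LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)),
    ])
    return pipe.fit(np.asarray(X, dtype=np.float64), y)


def fit_knn(X: np.ndarray, y: np.ndarray, k: int = 9) -> Pipeline:
    """Euclidean K-nearest-neighbour majority vote on z-scored features."""
    X = np.asarray(X, dtype=np.float64)
    if k > len(X):
        raise ValueError(f"k = {k} exceeds the training-set size {len(X)}")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("knn", KNeighborsClassifier(n_neighbors=k)),
    ])
    return pipe.fit(X, np.asarray(y))
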