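"""Scikit-learn style estimator facade over the segmentation pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .augment import AugmentConfig, RSSConfig
from .io import Sample
from .losses import LossConfig
from .metrics import segmentation_metrics
from .network import NetworkConfig
from .training import TrainConfig, evaluate, train

__all__ = ["ESUNetSegmenter"]


class ESUNetSegmenter(BaseEstimator):
    """3D semantic segmentation with the ES-UNet architecture.

    A fit/predict wrapper: ``fit`` trains the network on a list of
    :class:`~esunet.io.Sample` cases (or ``(image, label)`` pairs) with the
    full augmentation + deep-supervision pipeline; ``predict`` returns
    thresholded binary masks; ``predict_proba`` the fused probability maps;
    ``score`` the mean Dice similarity coefficient.

    Parameters mirror the architecture, loss, augmentation and optimisation
    knobs; fitted state lives in trailing-underscore attributes
    (``model_``, ``history_``, ``n_parameters_``).

    Examples
    --------
    >>> from esunet.phantoms import PhantomSpec, make_phantom
    >>> cases = [make_phantom(PhantomSpec(shape=(32, 32, 32), seed=s,
    ...                                   lesion_radius_range=(4, 6)))
    ...          for s in range(5)]
    >>> seg = ESUNetSegmenter(base_channels=8, path_channels=8, epochs=10,
    ...                       restart_period=10, seed=0)
    >>> seg = seg.fit(cases)                                   # doctest: +SKIP
    >>> masks = seg.predict(cases[:1])                         # doctest: +SKIP
    """

    def __init__(
        self,
        n_levels: int = 4,
        base_channels: int = 32,
        path_channels: int = 32,
        attention_ratio: float = 0.25,
        variant: str = "both",
        deep_supervision: bool = True,
        threshold: float = 0.5,
        gamma: float = 2.0,
        alpha: float = 1.0,
        pairing: str = "narrative",
        epochs: int = 100,
        restart_period: int = 25,
        lr_max: float = 1e-3,
        lr_min: float = 1e-5,
        batch_size: int = 1,
        val_fraction: float = 0.2,
        augment: bool = True,
        mirror_prob: float = 0.5,
        rotation_max_deg: float = 15.0,
        rss_p_overall: float = 0.5,
        seed: int = 0,
    ) -> None:
        self.n_levels = n_levels
        self.base_channels = base_channels
        self.path_channels = path_channels
        self.attention_ratio = attention_ratio
        self.variant = variant
        self.deep_supervision = deep_supervision
        self.threshold = threshold
        self.gamma = gamma
        self.alpha = alpha
        self.pairing = pairing
        self.epochs = epochs
        self.restart_period = restart_period
        self.lr_max = lr_max
        self.lr_min = lr_min
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.augment = augment
        self.mirror_prob = mirror_prob
        self.rotation_max_deg = rotation_max_deg
        self.rss_p_overall = rss_p_overall
        self.seed = seed

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _as_samples(X) -> list[Sample]:
        out = []
        for item in X:
            if isinstance(item, Sample):
                out.append(item)
            else:
                image, label = item
                image = np.asarray(image)
                if image.ndim == 3:
                    image = image[None]
                out.append(Sample(image, np.asarray(label)))
        return out

    def _train_config(self, in_channels: int) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            restart_period=self.restart_period,
            lr_max=self.lr_max,
            lr_min=self.lr_min,
            batch_size=self.batch_size,
            val_fraction=self.val_fraction,
            seed=self.seed,
            augment_enabled=self.augment,
            loss=LossConfig(gamma=self.gamma, alpha=self.alpha, pairing=self.pairing),
            augment=AugmentConfig(
                mirror_prob=self.mirror_prob,
                rotation_max_deg=self.rotation_max_deg,
                rss=RSSConfig(p_overall=self.rss_p_overall),
            ),
            model=NetworkConfig(
                n_levels=self.n_levels,
                in_channels=in_channels,
                base_channels=self.base_channels,
                path_channels=self.path_channels,
                attention_ratio=self.attention_ratio,
                variant=self.variant,
                deep_supervision=self.deep_supervision,
                threshold=self.threshold,
                seed=self.seed,
            ),
        )

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y=None, train_ids=None, val_ids=None):
        """Train on a list of cases; labels travel inside the samples."""
        cases = self._as_samples(X)
        if not cases:
            raise ValueError("need at least one training case")
        cfg = self._train_config(in_channels=cases[0].image.shape[0])
        self.model_, self.history_ = train(cfg, cases, train_ids=train_ids, val_ids=val_ids)
        self.n_parameters_ = self.model_.n_parameters()
        self.train_config_ = cfg
        return self

    def predict_proba(self, X) -> list[np.ndarray]:
        check_is_fitted(self, "model_")
        return [self.model_.predict_proba(s.image) for s in self._as_samples(X)]

    def predict(self, X) -> list[np.ndarray]:
        check_is_fitted(self, "model_")
        return [self.model_.predict_mask(s.image) for s in self._as_samples(X)]

    def score(self, X, y=None) -> float:
        """Mean Dice similarity coefficient over the given cases."""
        check_is_fitted(self, "model_")
        cases = self._as_samples(X)
        masks = self.predict(cases)
        return float(
            np.mean([segmentation_metrics(m, s.label).dsc for m, s in zip(masks, cases)])
        )

    def evaluate(self, X):
        """Per-case DSC/IoU/VOE table with a final mean row."""
        check_is_fitted(self, "model_")
        return evaluate(self.model_, self._as_samples(X))
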