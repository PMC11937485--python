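"""Model/Results front end over the pipeline, in the fit-then-summarize
style of statistical modelling packages.

``MVMDM`` bundles a labelled cohort (phantom or on-disk manifests) with the
route bindings and training protocol; ``fit()`` trains the three routes and
the max-voting ensemble and returns an :class:`MVMDMResults` carrying the
per-route and ensemble metrics, confusion matrices and training histories,
with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import pipeline
from .models import TrainConfig

__all__ = ["MVMDM", "MVMDMResults"]


class MVMDM:
    """Max-voting multidimensional CNN ensemble bound to a cohort.

    Construct with in-memory features (via :meth:`from_phantom`) or from
    train/test manifest CSVs (via :meth:`from_manifests`), then call
    :meth:`fit`.
    """

    def __init__(
        self,
        train_features: dict[str, np.ndarray],
        y_train: np.ndarray,
        test_features: dict[str, np.ndarray],
        y_test: np.ndarray,
        profile: str = "test",
    ) -> None:
        self.train_features = train_features
        self.y_train = np.asarray(y_train, dtype=int)
        self.test_features = test_features
        self.y_test = np.asarray(y_test, dtype=int)
        self.profile = profile

    @classmethod
    def from_phantom(
        cls,
        n_train_per_class: int = 20,
        n_test_per_class: int = 10,
        effect: float = 0.6,
        profile: str = "test",
        seed: int = 0,
    ) -> "MVMDM":
        """Simulate disjoint phantom train/test cohorts and extract features."""
        cfg = pipeline.RunConfig(
            out_dir=".",
            profile=profile,
            seed=seed,
            n_train_per_class=n_train_per_class,
            n_test_per_class=n_test_per_class,
            effect=effect,
        )
        f_tr, y_tr, f_te, y_te = pipeline.simulate_features(cfg)
        return cls(f_tr, y_tr, f_te, y_te, profile=profile)

    @classmethod
    def from_manifests(
        cls,
        train_manifest: str | Path,
        test_manifest: str | Path,
        n_keep: int | None = None,
        profile: str = "paper",
    ) -> "MVMDM":
        f_tr, y_tr, _ = pipeline.features_from_manifest(train_manifest, n_keep=n_keep)
        f_te, y_te, _ = pipeline.features_from_manifest(test_manifest, n_keep=n_keep)
        return cls(f_tr, y_tr, f_te, y_te, profile=profile)

    def fit(self, cfg: TrainConfig | None = None, seed: int | None = None) -> "MVMDMResults":
        """Train all three routes and evaluate them plus the ensemble on the
        held-out cohort."""
        if cfg is None:
            cfg = pipeline.train_config(self.profile, seed=0 if seed is None else seed)
        routes = pipeline.train_routes(self.train_features, self.y_train, cfg)
        predictions = pipeline.predict_routes(routes, self.test_features, threshold=cfg.threshold)
        report = pipeline.evaluate_predictions(self.y_test, predictions)
        return MVMDMResults(
            model=self, report=report, routes=routes, predictions=predictions, config=cfg
        )


@dataclass
class MVMDMResults:
    """Fitted ensemble: metrics, confusion matrices, histories, predictions."""

    model: MVMDM
    report: dict
    routes: dict
    predictions: dict
    config: TrainConfig

    _ORDER = ("1d", "2d", "3d", "mvmdm")

    @property
    def metrics(self) -> pd.DataFrame:
        rows = []
        for name in self._ORDER:
            if name in self.report:
                rows.append({"model": name, **self.report[name]["metrics"]})
        return pd.DataFrame(rows).set_index("model")

    @property
    def confusion(self) -> pd.DataFrame:
        rows = []
        for name in self._ORDER:
            if name in self.report:
                rows.append({"model": name, **self.report[name]["confusion"]})
        return pd.DataFrame(rows).set_index("model")

    def accuracy(self, name: str = "mvmdm") -> float:
        return self.report[name]["accuracy_fraction"]

    def summary(self) -> str:
        """A compact fit report: data sizes, protocol, metrics table."""
        m = self.model
        lines = [
            "Max-voting multidimensional CNN ensemble",
            "=" * 56,
            f"profile: {m.profile}    seed: {self.config.seed}",
            f"train subjects: {len(m.y_train)}  (class 1: {int(m.y_train.sum())})",
            f"test subjects:  {len(m.y_test)}  (class 1: {int(m.y_test.sum())})",
            f"optimizer: {self.config.optimizer}  lr: {self.config.learning_rate}  "
            f"epochs: {self.config.epochs}  batch: {self.config.batch_size}",
            "-" * 56,
            "metrics (%) on held-out subjects:",
            self.metrics.to_string(),
            "-" * 56,
            "confusion counts (positive class = disease):",
            self.confusion.to_string(),
        ]
        return "\n".join(lines)
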