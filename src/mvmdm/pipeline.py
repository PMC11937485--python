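"""End-to-end orchestration: volumes → subbands → route features → three
trained routes → max-voting ensemble → metric reports.

Two size profiles are built in.  The ``paper`` profile uses the reference
geometry (88 slices of 256x256, subbands 88x128x128) and the reference
training protocol (20 epochs).  The ``test`` profile shrinks the phantom
geometry to 16 slices of 64x64 and trains for 12 epochs so a full run of
all three routes fits comfortably on one CPU; the architecture pattern is
unchanged (the 3D route keeps the block prefix that its smaller input
admits).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import ensemble as ens
from . import features as feat
from . import models, phantom, volume_io, wavelet

__all__ = [
    "PROFILES",
    "RouteScaler",
    "RouteModel",
    "DEFAULT_BINDINGS",
    "RunConfig",
    "phantom_config",
    "train_config",
    "extract_route_features",
    "features_from_manifest",
    "train_routes",
    "predict_routes",
    "evaluate_predictions",
    "generalization_run",
    "run_pipeline",
    "check_architecture",
    "REFERENCE_ARCHITECTURE",
]

PROFILES = {
    "paper": {"n_slices": 88, "slice_size": 256, "epochs": 20},
    "test": {"n_slices": 16, "slice_size": 64, "epochs": 12},
}

#: Which subband feeds which route in the headline configuration.
DEFAULT_BINDINGS = {"1d": "CD", "2d": "CH", "3d": "CV"}

ROUTE_TO_KIND = {"1d": "conv1d_energy", "2d": "conv2d_fused", "3d": "conv3d_volume"}


def phantom_config(profile: str = "test", **overrides) -> phantom.PhantomConfig:
    """Phantom generator configuration at a profile's geometry."""
    p = PROFILES[profile]
    kwargs = {"n_slices": p["n_slices"], "slice_size": p["slice_size"]}
    kwargs.update(overrides)
    return phantom.PhantomConfig(**kwargs)


def train_config(profile: str = "test", **overrides) -> models.TrainConfig:
    """Training configuration at a profile's epoch budget."""
    kwargs = {"epochs": PROFILES[profile]["epochs"]}
    kwargs.update(overrides)
    return models.TrainConfig(**kwargs)


@dataclass
class RouteScaler:
    """Scalar z-scoring fitted on the training features of one route."""

    mean: float = 0.0
    sd: float = 1.0

    @classmethod
    def fit(cls, x: np.ndarray) -> "RouteScaler":
        sd = float(x.std())
        return cls(mean=float(x.mean()), sd=sd if sd > 0 else 1.0)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.mean) / self.sd).astype(np.float32)


@dataclass
class RouteModel:
    spec: models.ModelSpec
    network: "models.nn.Network"
    scaler: RouteScaler
    history: dict


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str | Path
    profile: str = "test"
    seed: int = 0
    n_train_per_class: int = 20
    n_test_per_class: int = 10
    effect: float = 0.6
    noise_sd: float = 0.02
    train_manifest: str | Path | None = None
    test_manifest: str | Path | None = None
    bindings: dict = field(default_factory=lambda: dict(DEFAULT_BINDINGS))
    wavelet: str = "db1"
    epochs: int | None = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {sorted(PROFILES)}")


def extract_route_features(
    volumes: np.ndarray,
    bindings: dict | None = None,
    wavelet_name: str = "db1",
    normalize: bool = True,
) -> dict[str, np.ndarray]:
    """Route feature arrays from a stack of subject volumes.

    ``volumes`` has shape (n_subjects, n_slices, H, W).  Returns channels-
    last arrays: ``1d`` (n, n_slices, 1) energy vectors, ``2d``
    (n, H/2, W/2, 1) mean-fused images, ``3d`` (n, n_slices, H/2, W/2, 1)
    subband volumes, per the route→subband bindings.
    """
    bindings = dict(DEFAULT_BINDINGS if bindings is None else bindings)
    x1, x2, x3 = [], [], []
    for vol in volumes:
        v = volume_io.normalize(vol) if normalize else np.asarray(vol, dtype=np.float64)
        sub = wavelet.decompose_volume(v, wavelet=wavelet_name)
        x1.append(feat.energy_vector(sub.get(bindings["1d"])).values)
        x2.append(feat.mean_fusion(sub.get(bindings["2d"])).data)
        x3.append(sub.get(bindings["3d"]))
    return {
        "1d": np.asarray(x1, dtype=np.float32)[..., None],
        "2d": np.asarray(x2, dtype=np.float32)[..., None],
        "3d": np.asarray(x3, dtype=np.float32)[..., None],
    }


def features_from_manifest(
    manifest: phantom.CohortManifest | str | Path,
    n_keep: int | None = None,
    window_start: int | None = None,
    bindings: dict | None = None,
    wavelet_name: str = "db1",
) -> tuple[dict[str, np.ndarray], np.ndarray, list[str]]:
    """Load every subject of a manifest and extract the route features."""
    if not isinstance(manifest, phantom.CohortManifest):
        manifest = phantom.load_manifest(manifest)
    vols, labels, ids = [], [], []
    for rec in manifest.records:
        raw, _ = volume_io.read_volume(rec.path)
        keep = raw.shape[0] if n_keep is None else n_keep
        vols.append(volume_io.select_slices(raw, n_keep=keep, start=window_start))
        labels.append(rec.label)
        ids.append(rec.subject_id)
    feats = extract_route_features(np.stack(vols), bindings=bindings, wavelet_name=wavelet_name)
    return feats, np.asarray(labels, dtype=int), ids


def train_routes(
    feats: dict[str, np.ndarray],
    y: np.ndarray,
    cfg: models.TrainConfig,
) -> dict[str, RouteModel]:
    """Fit the three routes on standardized training features."""
    routes = {}
    for route, kind in ROUTE_TO_KIND.items():
        scaler = RouteScaler.fit(feats[route])
        x = scaler.transform(feats[route])
        spec = models.model_spec(kind, input_shape=tuple(x.shape[1:]))
        net, history = models.train(spec, x, y, cfg)
        routes[route] = RouteModel(spec=spec, network=net, scaler=scaler, history=history)
    return routes


def predict_routes(
    routes: dict[str, RouteModel],
    feats: dict[str, np.ndarray],
    threshold: float = 0.5,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-route predictions plus the max-voting ensemble prediction."""
    out = {}
    for route, model in routes.items():
        x = model.scaler.transform(feats[route])
        pred, prob = models.classify(model.network, x, threshold=threshold)
        out[route] = {"pred": pred, "prob": prob}
    votes = np.stack([out[r]["pred"] for r in ("1d", "2d", "3d")])
    out["mvmdm"] = {"pred": ens.majority_vote(votes)}
    return out


def evaluate_predictions(
    y_true: np.ndarray, predictions: dict[str, dict[str, np.ndarray]]
) -> dict[str, dict]:
    """Confusion matrix and the five metrics for each route and the ensemble."""
    report = {}
    for name, p in predictions.items():
        cm = ens.confusion_matrix(y_true, p["pred"])
        metrics = ens.compute_metrics(cm)
        report[name] = {
            "confusion": {"TP": cm.TP, "TN": cm.TN, "FP": cm.FP, "FN": cm.FN},
            "metrics": metrics.rounded(2),
            "accuracy_fraction": None
            if metrics.accuracy is None
            else metrics.accuracy / 100.0,
        }
    return report


def _run_core(
    train_feats, y_train, test_feats, y_test, cfg: RunConfig
) -> tuple[dict, dict[str, RouteModel]]:
    tcfg = train_config(cfg.profile, seed=cfg.seed, threshold=cfg.threshold)
    if cfg.epochs is not None:
        tcfg = replace(tcfg, epochs=cfg.epochs)
    routes = train_routes(train_feats, y_train, tcfg)
    predictions = predict_routes(routes, test_feats, threshold=cfg.threshold)
    report = evaluate_predictions(y_test, predictions)
    return report, routes


def simulate_features(
    cfg: RunConfig,
) -> tuple[dict, np.ndarray, dict, np.ndarray]:
    """Generate disjoint train/test phantom cohorts in memory and extract
    route features for both."""
    pc = phantom_config(cfg.profile, effect=cfg.effect, noise_sd=cfg.noise_sd)
    train_seed = cfg.seed
    test_seed = cfg.seed + 1000003  # distinct cohort stream
    vol_tr, y_tr, _ = phantom.generate_cohort_arrays(cfg.n_train_per_class, pc, seed=train_seed)
    vol_te, y_te, _ = phantom.generate_cohort_arrays(cfg.n_test_per_class, pc, seed=test_seed)
    f_tr = extract_route_features(vol_tr, cfg.bindings, cfg.wavelet)
    f_te = extract_route_features(vol_te, cfg.bindings, cfg.wavelet)
    return f_tr, y_tr, f_te, y_te


def generalization_run(
    train_manifest: phantom.CohortManifest | str | Path,
    test_manifest: phantom.CohortManifest | str | Path,
    cfg: RunConfig,
) -> dict[str, dict]:
    """Train on one cohort, test on a disjoint cohort (cross-dataset
    protocol).  Any subject id shared between the manifests is a hard error."""
    if not isinstance(train_manifest, phantom.CohortManifest):
        train_manifest = phantom.load_manifest(train_manifest)
    if not isinstance(test_manifest, phantom.CohortManifest):
        test_manifest = phantom.load_manifest(test_manifest)
    shared = set(train_manifest.subject_ids) & set(test_manifest.subject_ids)
    if shared:
        raise ValueError(f"subject leakage between manifests: {sorted(shared)[:5]} ...")
    f_tr, y_tr, _ = features_from_manifest(
        train_manifest, bindings=cfg.bindings, wavelet_name=cfg.wavelet
    )
    f_te, y_te, _ = features_from_manifest(
        test_manifest, bindings=cfg.bindings, wavelet_name=cfg.wavelet
    )
    report, _ = _run_core(f_tr, y_tr, f_te, y_te, cfg)
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Full run: simulate (or load manifests) → train → evaluate → report.

    Writes metrics JSON/CSV, per-route confusion matrices, training
    histories, the architecture dump and a hashed artifact manifest into
    ``cfg.out_dir``; returns the metrics report as a dict.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg.train_manifest is not None and cfg.test_manifest is not None:
        report = generalization_run(cfg.train_manifest, cfg.test_manifest, cfg)
        routes = None
    else:
        f_tr, y_tr, f_te, y_te = simulate_features(cfg)
        report, routes = _run_core(f_tr, y_tr, f_te, y_te, cfg)

    header = {
        "profile": cfg.profile,
        "seed": cfg.seed,
        "effect": cfg.effect,
        "bindings": cfg.bindings,
        "wavelet": cfg.wavelet,
    }
    (out_dir / "metrics.json").write_text(
        json.dumps({"config": header, "results": report}, indent=2, sort_keys=True)
    )
    import csv as _csv

    with open(out_dir / "metrics.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["model", "accuracy", "precision", "sensitivity", "specificity", "f1"])
        for name, entry in report.items():
            m = entry["metrics"]
            w.writerow(
                [name, m["accuracy"], m["precision"], m["sensitivity"], m["specificity"], m["f1"]]
            )
    for name, entry in report.items():
        with open(out_dir / f"confusion_{name}.csv", "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["", "pred_healthy", "pred_disease"])
            c = entry["confusion"]
            w.writerow(["true_healthy", c["TN"], c["FP"]])
            w.writerow(["true_disease", c["FN"], c["TP"]])
    input_shapes = None
    if routes is not None:
        input_shapes = {ROUTE_TO_KIND[r]: m.spec.input_shape for r, m in routes.items()}
        import pandas as pd

        for r, m in routes.items():
            pd.DataFrame(m.history).to_csv(out_dir / f"history_{r}.csv", index=False)
    (out_dir / "architecture.json").write_text(
        json.dumps(models.architecture_report(input_shapes), indent=2, sort_keys=True)
    )
    artifacts = {
        p.name: _sha256(p) for p in sorted(out_dir.iterdir()) if p.is_file() and p.name != "artifacts.json"
    }
    (out_dir / "artifacts.json").write_text(json.dumps(artifacts, indent=2, sort_keys=True))
    return report


#: The published reference tables the symbolic tracer must reproduce.
REFERENCE_ARCHITECTURE = {
    "conv1d_energy": {
        "shape_trace": [
            [86, 32], [43, 32], [41, 64], [20, 64], [1280], [64], [1],
        ],
        "total_params": 88_385,
        "trainable_params": 88_385,
        "non_trainable_params": 0,
    },
    "conv2d_fused": {
        "shape_trace": [
            [126, 126, 32], [126, 126, 32], [63, 63, 32],
            [61, 61, 64], [61, 61, 64], [30, 30, 64],
            [28, 28, 128], [28, 28, 128], [14, 14, 128],
            [25088], [128], [128], [1],
        ],
        "total_params": 3_305_089,
        "trainable_params": 3_304_641,
        "non_trainable_params": 448,
    },
    "conv3d_volume": {
        "shape_trace": [
            [87, 126, 126, 32], [87, 63, 63, 32],
            [86, 61, 61, 64], [86, 30, 30, 64],
            [85, 28, 28, 64], [85, 14, 14, 64],
            [84, 12, 12, 64], [84, 6, 6, 64],
            [193536], [128], [1],
        ],
        "total_params": 24_957_985,
        "trainable_params": 24_957_985,
        "non_trainable_params": 0,
    },
}


def check_architecture() -> tuple[bool, dict]:
    """Compare the symbolically traced reference architectures with the
    published tables.  Needs no data; returns (all_match, detailed report)."""
    report = models.architecture_report()
    detail = {}
    ok = True
    for kind, expected in REFERENCE_ARCHITECTURE.items():
        got = report[kind]
        matches = {
            key: got[key] == expected[key]
            for key in ("shape_trace", "total_params", "trainable_params", "non_trainable_params")
        }
        detail[kind] = {"expected": expected, "got": {k: got[k] for k in matches}, "match": matches}
        ok = ok and all(matches.values())
    return ok, detail
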