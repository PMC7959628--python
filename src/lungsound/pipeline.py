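"""End-to-end orchestration: simulate/load -> preprocess -> features ->
augment -> train -> evaluate, with a serializable run configuration.

A run is reproducible from its :class:`RunConfig` alone: the single global
seed fans out to per-stage seeds by fixed offsets (dataset +0, fold assignment
+1, augmentation +2, model init +3, training +4), so any stage can be rerun in
isolation.

Feature matrices are standardized per bin row (mean/variance estimated on the
training portion only) before entering the CNN; the raw extractors put, e.g.,
MFCC coefficient 0 two orders of magnitude above the rest, and row-wise
standardization is what lets a small CNN train on all five kinds with one
optimizer setting.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import audio_io, features, evaluation
from .audio_io import AudioClip, Label
from .augmentation import AugmentationSpec, balance_classes
from .features import FeatureKind
from .model import CNNClassifier, ModelConfig, TrainConfig, build
from .evaluation import EvalMetrics, round_half_up

_SEED_OFFSETS = {"dataset": 0, "folds": 1, "augment": 2, "model": 3, "train": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + _SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    audio_dir: str = ""
    labels_csv: str = ""
    out_dir: str = "run_out"
    feature_kinds: tuple[str, ...] = ("mfcc",)
    augment: bool = True
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    k_folds: int = 10
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_flat_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` text file; dotted keys reach subconfigs.

        Example::

            audio_dir = data/
            labels_csv = data/labels.csv
            feature_kinds = mfcc,melspectrogram
            augment = true
            train.epochs = 30
            k_folds = 10
            seed = 7
        """
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            cfg._set(key, value)
        return cfg

    def _set(self, key: str, value: str) -> None:
        target, attr = self, key
        if "." in key:
            prefix, attr = key.split(".", 1)
            target = getattr(self, {"train": "train", "model": "model", "aug": "augmentation"}[prefix])
        if not hasattr(target, attr):
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(target, attr)
        if attr == "feature_kinds":
            setattr(target, attr, tuple(v.strip() for v in value.split(",")))
        elif isinstance(current, bool):
            setattr(target, attr, value.lower() in ("1", "true", "yes", "on"))
        elif isinstance(current, int):
            setattr(target, attr, int(value))
        elif isinstance(current, float):
            setattr(target, attr, float(value))
        elif isinstance(current, tuple):
            setattr(target, attr, tuple(float(v) for v in value.split(",")))
        else:
            setattr(target, attr, value)


def clip_to_input(clip: AudioClip, kind: FeatureKind) -> np.ndarray:
    """fix_duration -> extract -> pad_to_frames: one clip to a 40x862 array."""
    fixed = audio_io.fix_duration(clip)
    fm = features.extract(fixed, kind)
    return features.pad_to_frames(fm).values


def _prepare(clips: list[AudioClip], kind: FeatureKind) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([clip_to_input(c, kind) for c in clips]).astype(np.float32)
    y = np.array([1 if c.label == Label.COPD else 0 for c in clips])
    return x[..., None], y


class _RowStandardizer:
    """Per-bin-row standardization fitted on training features only."""

    def fit(self, x: np.ndarray) -> "_RowStandardizer":
        self.mean = x.mean(axis=(0, 2, 3), keepdims=True)
        self.std = x.std(axis=(0, 2, 3), keepdims=True)
        self.std = np.where(self.std < 1e-8, 1.0, self.std)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


def fit_and_score(
    train_clips: list[AudioClip],
    test_clips: list[AudioClip],
    cfg: RunConfig,
    kind: FeatureKind,
    fold_seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train the CNN on one training split and score a held-out split.

    Augmentation (when enabled) is applied to the training clips only.
    Returns (y_true, y_pred, y_score) with 1 = COPD and score = P(COPD).
    """
    if cfg.augment:
        aug_spec = AugmentationSpec(
            **{**asdict(cfg.augmentation), "rng_seed": stage_seed(fold_seed, "augment")}
        )
        train_clips = balance_classes(train_clips, aug_spec)
    x_train, y_train = _prepare(train_clips, kind)
    x_test, y_true = _prepare(test_clips, kind)
    scaler = _RowStandardizer().fit(x_train)
    x_train, x_test = scaler.transform(x_train), scaler.transform(x_test)

    clf = build(cfg.model, seed=stage_seed(fold_seed, "model"))
    tcfg = TrainConfig(**{**asdict(cfg.train), "rng_seed": stage_seed(fold_seed, "train")})
    clf.fit(x_train, y_train, tcfg)
    probs = clf.predict_proba(x_test)
    return y_true, np.argmax(probs, axis=1), probs[:, 1]


def run_single_split(
    clips: list[AudioClip],
    cfg: RunConfig,
    kind: FeatureKind,
    test_fraction: float = 0.25,
) -> EvalMetrics:
    """Stratified single train/test split, then fit_and_score and metrics."""
    from sklearn.model_selection import train_test_split

    y = [1 if c.label == Label.COPD else 0 for c in clips]
    train_clips, test_clips = train_test_split(
        clips, test_size=test_fraction, stratify=y, random_state=stage_seed(cfg.seed, "folds")
    )
    y_true, y_pred, y_score = fit_and_score(train_clips, test_clips, cfg, kind, cfg.seed)
    c = evaluation.confusion(list(y_true), list(y_pred), positive_class=1)
    return evaluation.metrics_from_counts(c, evaluation.auc_from_scores(y_score, y_true))


def run_cv(
    clips: list[AudioClip], cfg: RunConfig, kind: FeatureKind
) -> tuple[list[EvalMetrics], EvalMetrics]:
    """k-fold cross-validation with the CNN pipeline as the fold runner."""

    def runner(train_clips, test_clips, fold_seed):
        return fit_and_score(train_clips, test_clips, cfg, kind, fold_seed)

    return evaluation.kfold_cv(clips, runner, k=cfg.k_folds, seed=stage_seed(cfg.seed, "folds"))


def run(cfg: RunConfig, clips: list[AudioClip] | None = None, log=print) -> dict:
    """Execute the full pipeline for every requested feature kind.

    Returns a report dict (also written to ``out_dir`` as JSON and CSV) with
    one row per feature kind: Se, Sp, ICBHI, accuracy, AUC (pooled over CV
    folds), plus per-fold metrics.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if clips is None:
        table = audio_io.LabelTable.from_csv(cfg.labels_csv)
        clips = audio_io.load_dataset(cfg.audio_dir, table)
    log(f"[load] {len(clips)} clips "
        f"({sum(c.label == Label.COPD for c in clips)} COPD)")

    report: dict = {"config": json.loads(cfg.to_json()), "rows": []}
    for kind_name in cfg.feature_kinds:
        kind = FeatureKind(kind_name)
        t0 = time.perf_counter()
        per_fold, pooled = run_cv(clips, cfg, kind)
        elapsed = time.perf_counter() - t0
        row = {
            "feature": kind.value,
            "augmented": cfg.augment,
            "sensitivity": round_half_up(pooled.sensitivity),
            "specificity": round_half_up(pooled.specificity),
            "icbhi_score": round_half_up(pooled.icbhi_score),
            "accuracy": round_half_up(pooled.accuracy),
            "auc": round_half_up(pooled.auc),
            "per_fold": [asdict(m) for m in per_fold],
            "seconds": round(elapsed, 2),
        }
        report["rows"].append(row)
        log(
            f"[eval] {kind.value}: Se={row['sensitivity']:.2f} "
            f"Sp={row['specificity']:.2f} ICBHI={row['icbhi_score']:.2f} "
            f"AUC={row['auc']:.2f} ({elapsed:.1f}s)"
        )

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    write_report_csv(report, out_dir / "report.csv")
    return report


def write_report_csv(report: dict, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {k: r[k] for k in ("feature", "augmented", "sensitivity", "specificity",
                           "icbhi_score", "accuracy", "auc")}
        for r in report["rows"]
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
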