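"""The stacked risk-score ensemble.

Six gradient-boosted base learners — presence and odds-ratio blocks for the
DX, RX and PROC channels — are each cross-fitted over the training split so
their out-of-fold scores carry no in-fold leakage.  Those six score columns,
together with sex and age, feed a final (meta) classifier that emits the
risk score in [0, 1].

Class imbalance is handled by positive-class weighting rather than
resampling.  All randomness flows from one explicit seed recorded in the
model's training fingerprint; models are persisted as plain-text LightGBM
dumps plus a manifest whose checksums are verified on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import lightgbm as lgb
import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import BLOCKS

__all__ = [
    "BaseModelSpec",
    "EnsembleModel",
    "DEFAULT_BASE_PARAMS",
    "DEFAULT_META_PARAMS",
    "train_base",
    "train_meta",
    "train_ensemble",
    "predict_risk",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

#: Shallow trees, a few hundred rounds with early stopping on the held fold.
DEFAULT_BASE_PARAMS: dict = {
    "objective": "binary",
    "num_leaves": 31,
    "max_depth": 6,
    "learning_rate": 0.1,
    "n_estimators": 300,
    "min_child_samples": 20,
    "is_unbalance": True,
    "verbosity": -1,
    "num_threads": 1,
    "deterministic": True,
    "force_row_wise": True,
}

#: The meta learner is a small model of the same family over only 8 inputs.
DEFAULT_META_PARAMS: dict = {
    "objective": "binary",
    "num_leaves": 7,
    "max_depth": 3,
    "learning_rate": 0.1,
    "n_estimators": 150,
    "min_child_samples": 20,
    "is_unbalance": True,
    "verbosity": -1,
    "num_threads": 1,
    "deterministic": True,
    "force_row_wise": True,
}


@dataclass(frozen=True)
class BaseModelSpec:
    block: str
    seed: int = 0
    hyperparameters: Optional[dict] = None
    n_splits: int = 5
    early_stopping_rounds: int = 25

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}; expected one of {BLOCKS}")

    @property
    def params(self) -> dict:
        p = dict(DEFAULT_BASE_PARAMS)
        if self.hyperparameters:
            p.update(self.hyperparameters)
        return p


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must be binary with both classes present")
    return y


def _fit_booster(params: dict, X: np.ndarray, y: np.ndarray, seed: int,
                 valid: Optional[tuple[np.ndarray, np.ndarray]] = None,
                 early_stopping_rounds: int = 25) -> lgb.Booster:
    params = dict(params)
    n_rounds = params.pop("n_estimators")
    params["seed"] = seed
    train_set = lgb.Dataset(np.asarray(X, dtype=np.float64), label=y, params={"verbosity": -1})
    kwargs: dict = {}
    if valid is not None:
        vset = lgb.Dataset(
            np.asarray(valid[0], dtype=np.float64), label=valid[1], reference=train_set
        )
        kwargs["valid_sets"] = [vset]
        kwargs["callbacks"] = [lgb.early_stopping(early_stopping_rounds, verbose=False)]
    return lgb.train(params, train_set, num_boost_round=n_rounds, **kwargs)


def train_base(
    X: np.ndarray, y: np.ndarray, spec: BaseModelSpec
) -> tuple[lgb.Booster, np.ndarray]:
    """Fit one base learner and produce its out-of-fold scores.

    K-fold cross-fitting (stratified, shuffled with the spec's seed):
    each fold's scores come from a model that never saw those patients, with
    early stopping on the held fold.  The returned booster is refit on all
    rows using the median of the per-fold best iteration counts.
    """
    y = _check_labels(y)
    X = np.asarray(X, dtype=np.float64)
    oof = np.zeros(len(y), dtype=float)
    best_iters = []
    skf = StratifiedKFold(n_splits=spec.n_splits, shuffle=True, random_state=spec.seed)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        booster = _fit_booster(
            spec.params, X[tr], y[tr], seed=spec.seed + fold,
            valid=(X[te], y[te]), early_stopping_rounds=spec.early_stopping_rounds,
        )
        oof[te] = booster.predict(X[te], num_iteration=booster.best_iteration)
        best_iters.append(booster.best_iteration or spec.params["n_estimators"])
    final_params = dict(spec.params)
    final_params["n_estimators"] = int(np.median(best_iters))
    final = _fit_booster(final_params, X, y, seed=spec.seed)
    return final, oof


def train_meta(
    oof_scores: np.ndarray,
    sex: np.ndarray,
    age: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    params: Optional[dict] = None,
) -> lgb.Booster:
    """Fit the final classifier over the 8 meta inputs (6 base scores + sex + age)."""
    y = _check_labels(y)
    oof_scores = np.asarray(oof_scores, dtype=float)
    if oof_scores.ndim != 2 or oof_scores.shape[1] != len(BLOCKS):
        raise ValueError(f"expected {len(BLOCKS)} out-of-fold score columns")
    n = len(y)
    if not (len(sex) == len(age) == oof_scores.shape[0] == n):
        raise ValueError("misaligned rows between score columns, sex, age and labels")
    X = np.column_stack([oof_scores, np.asarray(sex, float), np.asarray(age, float)])
    return _fit_booster(dict(params or DEFAULT_META_PARAMS), X, y, seed=seed)


@dataclass
class EnsembleModel:
    """Six fitted base boosters plus the meta classifier and a training fingerprint."""

    base_models: dict[str, lgb.Booster]
    meta_model: lgb.Booster
    manifest: dict

    def __post_init__(self) -> None:
        if set(self.base_models) != set(BLOCKS):
            raise ValueError("ensemble requires exactly the six canonical blocks")


def train_ensemble(
    blocks: Mapping[str, np.ndarray],
    sex: np.ndarray,
    age: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    feature_manifest: Optional[dict] = None,
    base_params: Optional[dict] = None,
    meta_params: Optional[dict] = None,
) -> EnsembleModel:
    """Train the full two-stage ensemble from per-block feature matrices."""
    missing = set(BLOCKS) - set(blocks)
    if missing:
        raise ValueError(f"missing feature blocks: {sorted(missing)}")
    base_models: dict[str, lgb.Booster] = {}
    oof = np.zeros((len(y), len(BLOCKS)), dtype=float)
    for k, block in enumerate(BLOCKS):
        spec = BaseModelSpec(block=block, seed=seed + k, hyperparameters=base_params)
        base_models[block], oof[:, k] = train_base(blocks[block], y, spec)
    meta = train_meta(oof, sex, age, y, seed=seed + len(BLOCKS), params=meta_params)
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "blocks": {b: int(np.asarray(blocks[b]).shape[1]) for b in BLOCKS},
        "seed": int(seed),
        "lightgbm_version": lgb.__version__,
    }
    if feature_manifest:
        manifest["features"] = feature_manifest
    return EnsembleModel(base_models=base_models, meta_model=meta, manifest=manifest)


def predict_risk(
    model: EnsembleModel,
    blocks: Mapping[str, np.ndarray],
    sex: np.ndarray,
    age: np.ndarray,
) -> np.ndarray:
    """Risk scores in [0, 1] for a batch of patients.

    Pure function of (model, features); refuses blocks whose width does not
    match the training manifest, naming the offending block.
    """
    for b in BLOCKS:
        if b not in blocks:
            raise ValueError(f"missing feature block {b!r}")
        width = np.asarray(blocks[b]).shape[1]
        if width != model.manifest["blocks"][b]:
            raise ValueError(
                f"feature manifest mismatch for block {b!r}: "
                f"got {width} columns, model expects {model.manifest['blocks'][b]}"
            )
    base_scores = np.column_stack(
        [
            model.base_models[b].predict(np.asarray(blocks[b], dtype=np.float64))
            for b in BLOCKS
        ]
    )
    X = np.column_stack([base_scores, np.asarray(sex, float), np.asarray(age, float)])
    scores = model.meta_model.predict(X)
    return np.clip(scores, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Persistence: one text file per booster + manifest with checksums


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_model(model: EnsembleModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for block, booster in model.base_models.items():
        fname = f"base-{block}.txt"
        booster.save_model(str(directory / fname))
        checksums[fname] = _sha256(directory / fname)
    model.meta_model.save_model(str(directory / "meta.txt"))
    checksums["meta.txt"] = _sha256(directory / "meta.txt")
    manifest = dict(model.manifest)
    manifest["checksums"] = checksums
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def load_model(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    version = manifest.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model directory has format version {version}, "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    for fname, expected in manifest["checksums"].items():
        actual = _sha256(directory / fname)
        if actual != expected:
            raise ValueError(f"checksum mismatch for {fname}: model files were modified")
    base_models = {
        block: lgb.Booster(model_file=str(directory / f"base-{block}.txt"))
        for block in BLOCKS
    }
    meta = lgb.Booster(model_file=str(directory / "meta.txt"))
    manifest = {k: v for k, v in manifest.items() if k != "checksums"}
    return EnsembleModel(base_models=base_models, meta_model=meta, manifest=manifest)
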