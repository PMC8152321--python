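"""End-to-end training, prediction, ablations, and nested cross-validation.

The full model runs three independent stages on each training split:

1. variance masks are fit per omics layer (training samples only),
2. one triplet-loss encoder per active layer is trained to convergence,
3. the encoders are frozen and a linear sigmoid head is trained on the
   concatenated embeddings.

Ablation modes mirror the method-comparison cases: ``expression_only``
(single-layer model on gene expression), ``mut_cna`` (mutation + CNA, no
expression), and ``no_encoder`` (selected features feed the classifier
directly — the plain neural-net-after-feature-selection baseline).

The evaluation protocol is 5x5 nested cross-validation: per repeat, a
stratified 5-fold split yields 20% test cells; each remaining 80% is
further split 80/20 into training and validation, i.e. 64% / 16% / 20% of
the data. Validation AUC selects the hyperparameter set whose test AUC is
reported. A master seed deterministically derives every per-(repeat,
fold, hp-set, stage) seed, so any cell is re-runnable in isolation.
"""

from __future__ import annotations

import io
import json
import zipfile
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import classifier_head as ch
from . import triplet_encoder as te
from .errors import ConfigurationError, MaskMismatchError, TrainingError
from .feature_selection import FeatureMask, apply_mask, fit_mask
from .metrics import roc_auc  # noqa: F401  (re-exported; AUC lives with the protocol)
from .omics_data import MultiOmicsDataset, OmicsMatrix

LAYER_ORDER = ("expression", "mutation", "cna")  # fixed concatenation order

MODES = {
    "all": ("expression", "mutation", "cna"),
    "expression_only": ("expression",),
    "mut_cna": ("mutation", "cna"),
    "no_encoder": ("expression", "mutation", "cna"),
}


def derive_seed(master: int, *parts: int | str) -> int:
    """Stable sub-seed for a named stage of a named CV cell (< 2^31)."""
    ints = [int(master)]
    for p in parts:
        ints.append(zlib.crc32(p.encode()) if isinstance(p, str) else int(p))
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31))


@dataclass
class HyperParams:
    """One hyperparameter set for the full three-stage model.

    Encoder widths must respect expression > cna > mutation when all three
    layers are active, reflecting the layers' predictive importance.
    ``top_k`` optionally fixes the selected-feature count per layer instead
    of the elbow rule.
    """

    output_dims: dict = field(
        default_factory=lambda: {"expression": 256, "cna": 64, "mutation": 32}
    )
    margin: float = 1.0
    encoder_lr: float = 0.01
    encoder_weight_decay: float = 1e-4
    encoder_dropout: float = 0.1
    encoder_epochs: int = 100
    encoder_patience: int = 10
    classifier_lr: float = 0.01
    classifier_weight_decay: float = 1e-4
    classifier_dropout: float = 0.1
    classifier_epochs: int = 150
    classifier_patience: int = 15
    batch_size: int = 32
    include_bias: bool = True
    top_k: dict | None = None

    def validate(self, mode: str = "all") -> None:
        if mode == "all":
            d = self.output_dims
            if not d["expression"] > d["cna"] > d["mutation"]:
                raise ConfigurationError(
                    "encoder widths must satisfy expression > cna > mutation, got "
                    f"{d}"
                )

    def encoder_config(self, kind: str, seed: int) -> te.EncoderConfig:
        return te.EncoderConfig(
            output_dim=self.output_dims[kind],
            margin=self.margin,
            learning_rate=self.encoder_lr,
            weight_decay=self.encoder_weight_decay,
            dropout_rate=self.encoder_dropout,
            batch_size=self.batch_size,
            max_epochs=self.encoder_epochs,
            patience=self.encoder_patience,
            seed=seed,
        )

    def classifier_config(self, seed: int) -> ch.ClassifierConfig:
        return ch.ClassifierConfig(
            learning_rate=self.classifier_lr,
            weight_decay=self.classifier_weight_decay,
            dropout_rate=self.classifier_dropout,
            batch_size=self.batch_size,
            max_epochs=self.classifier_epochs,
            patience=self.classifier_patience,
            include_bias=self.include_bias,
            seed=seed,
        )


@dataclass
class SuperFeltModel:
    """The persistable artifact of one training run."""

    mode: str
    masks: dict  # kind -> FeatureMask
    encoders: dict  # kind -> EncoderModel ({} in no_encoder mode)
    classifier: ch.LinearSigmoidClassifier
    hyperparams: HyperParams
    seed: int = 0

    def save(self, path: str | Path) -> None:
        """Write a single compressed archive (zip of JSON + .npy).

        Archive members carry a fixed timestamp so identical models
        produce byte-identical files (reproducibility contract).
        """

        def writestr(zf: zipfile.ZipFile, name: str, data) -> None:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, data)

        hp = asdict(self.hyperparams)
        manifest = {
            "format_version": 1,
            "mode": self.mode,
            "seed": self.seed,
            "hyperparams": hp,
            "encoder_kinds": sorted(self.encoders),
            "include_bias": self.classifier.bias is not None,
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            writestr(zf, "manifest.json", json.dumps(manifest, indent=1))
            writestr(
                zf, "masks.json",
                json.dumps({k: m.to_dict() for k, m in self.masks.items()}, indent=1),
            )
            enc_meta = {}
            for kind in sorted(self.encoders):
                enc = self.encoders[kind]
                buf = io.BytesIO()
                np.save(buf, enc.weights)
                writestr(zf, f"encoder_{kind}.npy", buf.getvalue())
                enc_meta[kind] = {
                    "feature_ids": enc.feature_ids,
                    "config": asdict(enc.config),
                }
            writestr(zf, "encoders.json", json.dumps(enc_meta, indent=1))
            buf = io.BytesIO()
            np.save(buf, self.classifier.weights)
            writestr(zf, "classifier_w.npy", buf.getvalue())
            if self.classifier.bias is not None:
                writestr(zf, "classifier_b.json", json.dumps(self.classifier.bias))

    @classmethod
    def load(cls, path: str | Path) -> "SuperFeltModel":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            masks = {
                k: FeatureMask.from_dict(d)
                for k, d in json.loads(zf.read("masks.json")).items()
            }
            enc_meta = json.loads(zf.read("encoders.json"))
            encoders = {}
            for kind, meta in enc_meta.items():
                w = np.load(io.BytesIO(zf.read(f"encoder_{kind}.npy")))
                encoders[kind] = te.EncoderModel(
                    kind, w, meta["feature_ids"], te.EncoderConfig(**meta["config"])
                )
            w = np.load(io.BytesIO(zf.read("classifier_w.npy")))
            bias = (
                json.loads(zf.read("classifier_b.json"))
                if "classifier_b.json" in zf.namelist()
                else None
            )
        return cls(
            manifest["mode"],
            masks,
            encoders,
            ch.LinearSigmoidClassifier(w, bias),
            HyperParams(**manifest["hyperparams"]),
            manifest["seed"],
        )


def _features(model: SuperFeltModel, layers: dict) -> np.ndarray:
    """Masked (and, unless no_encoder, encoded) concatenated design matrix."""
    blocks = []
    for kind in LAYER_ORDER:
        if kind not in model.masks:
            continue
        m = layers.get(kind)
        if m is None:
            raise MaskMismatchError(f"model requires the {kind} layer")
        reduced = apply_mask(m, model.masks[kind])
        if model.mode == "no_encoder":
            blocks.append(reduced.values)
        else:
            blocks.append(te.encode(model.encoders[kind], reduced.values))
    return ch.concatenate(*blocks)


def train_superfelt(
    train: MultiOmicsDataset,
    val: MultiOmicsDataset,
    hp: HyperParams,
    mode: str = "all",
    seed: int = 0,
) -> SuperFeltModel:
    """Run the three stages on one train/validation split.

    Masks are fit on training samples only; each active encoder trains
    independently with early stopping on validation triplet loss; the
    classifier then trains on frozen embeddings with early stopping on
    validation AUC. ``no_encoder`` skips stage 2.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; one of {sorted(MODES)}")
    hp.validate(mode)
    kinds = MODES[mode]

    masks = {k: fit_mask(train.layer(k), (hp.top_k or {}).get(k)) for k in kinds}
    reduced_tr = {k: apply_mask(train.layer(k), masks[k]).values for k in kinds}
    reduced_va = {k: apply_mask(val.layer(k), masks[k]).values for k in kinds}
    y_tr, y_va = train.labels.labels, val.labels.labels

    encoders: dict = {}
    if mode != "no_encoder":
        for k in kinds:
            cfg = hp.encoder_config(k, derive_seed(seed, "encoder", k))
            encoders[k] = te.train_encoder(
                reduced_tr[k], y_tr, reduced_va[k], y_va, cfg,
                kind=k, feature_ids=masks[k].feature_ids,
            )
        xhat_tr = ch.concatenate(*[te.encode(encoders[k], reduced_tr[k]) for k in LAYER_ORDER if k in encoders])
        xhat_va = ch.concatenate(*[te.encode(encoders[k], reduced_va[k]) for k in LAYER_ORDER if k in encoders])
    else:
        xhat_tr = ch.concatenate(*[reduced_tr[k] for k in LAYER_ORDER if k in reduced_tr])
        xhat_va = ch.concatenate(*[reduced_va[k] for k in LAYER_ORDER if k in reduced_va])

    clf = ch.train_classifier(
        xhat_tr, y_tr, xhat_va, y_va, hp.classifier_config(derive_seed(seed, "classifier"))
    )
    return SuperFeltModel(mode, masks, encoders, clf, hp, seed)


def predict(
    model: SuperFeltModel,
    expression: OmicsMatrix | None = None,
    mutation: OmicsMatrix | None = None,
    cna: OmicsMatrix | None = None,
) -> np.ndarray:
    """Deterministic sensitivity probabilities (no dropout at inference)."""
    layers = {"expression": expression, "mutation": mutation, "cna": cna}
    return ch.predict_proba(model.classifier, _features(model, layers))


def predict_dataset(model: SuperFeltModel, data: MultiOmicsDataset) -> np.ndarray:
    return predict(model, data.expression, data.mutation, data.cna)


# ---------------------------------------------------------------------------
# Cross-validation protocol


@dataclass
class SplitCell:
    repeat: int
    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def nested_split(
    labels: np.ndarray,
    repeats: int = 5,
    folds: int = 5,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> list[SplitCell]:
    """Stratified (repeats x folds) plan with an inner validation split.

    Each fold's 1/folds share is the test set; ``val_fraction`` of the
    remainder becomes validation — with the defaults, 64% train / 16%
    validation / 20% test. Stratification keeps the class ratio in every
    part, which with heavily imbalanced panels is what keeps the AUC
    defined in every cell.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise TrainingError(
            f"smallest class has {counts.min()} samples; cannot stratify {folds} folds"
        )
    cells = []
    for rep in range(repeats):
        skf = StratifiedKFold(folds, shuffle=True, random_state=derive_seed(seed, "outer", rep))
        for fold, (rest, test) in enumerate(skf.split(labels, labels)):
            tr, va = train_test_split(
                rest,
                test_size=val_fraction,
                stratify=labels[rest],
                random_state=derive_seed(seed, "inner", rep, fold),
            )
            cells.append(SplitCell(rep, fold, np.sort(tr), np.sort(va), np.sort(test)))
    return cells


@dataclass
class CVResult:
    """Per-cell, per-hyperparameter-set AUC records and their summary."""

    records: pd.DataFrame  # columns: repeat, fold, hp_set, val_auc, test_auc, selected
    mean_test_auc: float

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, float_format="%.10g")


def _select(records: pd.DataFrame, selection: str) -> pd.DataFrame:
    records = records.copy()
    records["selected"] = False
    if selection == "per_cell":
        for (_, _), grp in records.groupby(["repeat", "fold"], sort=False):
            records.loc[grp["val_auc"].idxmax(), "selected"] = True
    elif selection == "global":
        best_hp = records.groupby("hp_set", sort=False)["val_auc"].mean().idxmax()
        records.loc[records["hp_set"] == best_hp, "selected"] = True
    else:
        raise ConfigurationError("selection must be 'per_cell' or 'global'")
    return records


def cross_validate(
    data: MultiOmicsDataset,
    hp_sets: list[HyperParams],
    mode: str = "all",
    repeats: int = 5,
    folds: int = 5,
    val_fraction: float = 0.2,
    seed: int = 0,
    selection: str = "per_cell",
) -> CVResult:
    """Nested CV with validation-AUC hyperparameter selection.

    Per cell and hp set, a model is trained on the 64% split and scored on
    validation (16%) and test (20%). With ``selection='per_cell'`` the hp
    set with the best validation AUC in each cell contributes that cell's
    test AUC (ties go to the first set); ``'global'`` picks one set by mean
    validation AUC. The summary is the mean selected test AUC.
    """
    if not hp_sets:
        raise ConfigurationError("need at least one hyperparameter set")
    cells = nested_split(data.labels.labels, repeats, folds, val_fraction, seed)
    rows = []
    for cell in cells:
        d_tr = data.take(cell.train_idx)
        d_va = data.take(cell.val_idx)
        d_te = data.take(cell.test_idx)
        for h, hp in enumerate(hp_sets):
            model = train_superfelt(
                d_tr, d_va, hp, mode, derive_seed(seed, "cell", cell.repeat, cell.fold, h)
            )
            rows.append({
                "repeat": cell.repeat,
                "fold": cell.fold,
                "hp_set": h,
                "val_auc": roc_auc(predict_dataset(model, d_va), d_va.labels.labels),
                "test_auc": roc_auc(predict_dataset(model, d_te), d_te.labels.labels),
            })
    records = _select(pd.DataFrame(rows), selection)
    return CVResult(records, float(records.loc[records["selected"], "test_auc"].mean()))


def external_validate(
    train: MultiOmicsDataset,
    external: MultiOmicsDataset,
    hp_sets: list[HyperParams],
    mode: str = "all",
    repeats: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Train/validate on internal folds, test every model externally.

    Per repeat the training panel is split into ``folds`` stratified folds;
    each fold serves once as validation while the rest trains. Every
    trained model is scored on the full external panel. The hp set with
    the best mean validation AUC is reported with its mean external AUC.
    """
    if not hp_sets:
        raise ConfigurationError("need at least one hyperparameter set")
    y = train.labels.labels
    rows = []
    for rep in range(repeats):
        skf = StratifiedKFold(folds, shuffle=True, random_state=derive_seed(seed, "ext", rep))
        for fold, (tr, va) in enumerate(skf.split(y, y)):
            d_tr, d_va = train.take(tr), train.take(va)
            for h, hp in enumerate(hp_sets):
                model = train_superfelt(
                    d_tr, d_va, hp, mode, derive_seed(seed, "extcell", rep, fold, h)
                )
                rows.append({
                    "repeat": rep,
                    "fold": fold,
                    "hp_set": h,
                    "val_auc": roc_auc(predict_dataset(model, d_va), d_va.labels.labels),
                    "external_auc": roc_auc(
                        predict_dataset(model, external), external.labels.labels
                    ),
                })
    records = pd.DataFrame(rows)
    means = records.groupby("hp_set", sort=False)[["val_auc", "external_auc"]].mean()
    best = int(means["val_auc"].idxmax())
    return {
        "records": records,
        "selected_hp_set": best,
        "mean_val_auc": float(means.loc[best, "val_auc"]),
        "mean_external_auc": float(means.loc[best, "external_auc"]),
    }
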