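"""Experimental regimes: repeated within-subject CV, cross-subject
transfer learning, and cropped training.

Bookkeeping follows the study design: each subject/network/preprocess
combination is evaluated by a stratified 5-fold cross-validation
repeated 3 times (15 accuracies); transfer learning pre-trains on a 90%
subject pool (20% of it held out for validation with early-stopping
patience 15) and fine-tunes each held-out subject's clone for 15 epochs
without validation, every subject being held out exactly once across the
10 iterations; cropped training computes folds on parent epochs and only
then expands them to crops, so crops of one epoch never straddle a
train/test split.

Filtering and FASTER are applied to the whole subject recording before
any splitting — a deliberate global-preprocessing choice, as in the
study — so the only fold-dependent computations are model fitting and
normalisation inside the networks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from . import models
from .containers import EpochSet
from .faster import FasterConfig, run_faster
from .filters import STUDY_BANDS, BandSpec, butter_bandpass
from .representation import build_dense_grid, crop_epochs, to_dense_3d

REGIMES = ("simple", "transfer", "cropped-simple", "cropped-transfer")


@dataclass(frozen=True)
class TrainSchedule:
    regime: str = "simple"
    k_folds: int = 5
    repeats: int = 3
    tl_iterations: int = 10
    val_fraction: float = 0.2
    patience: int = 15
    finetune_epochs: int = 15
    max_epochs: int = 100
    batch_size: int = 32
    lr: float | None = None
    crop_window: float = 1.0
    crop_step: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")

    def replace(self, **kw) -> "TrainSchedule":
        return replace(self, **kw)


RESULT_COLUMNS = ("subject", "network", "preprocess", "regime", "variant",
                  "repeat", "fold", "accuracy")


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


def _tensorize(data: np.ndarray, ch_names, montage, input_kind: str) -> np.ndarray:
    """Arrange (n, channels, T) arrays into the input a model expects."""
    if input_kind in ("channels_x_time", "any"):
        return data
    if input_kind == "dense3d":
        grid = build_dense_grid(montage)
        tmp = EpochSet(data=data, fs=1.0, ch_names=ch_names,
                       labels=np.zeros(data.shape[0], dtype=object))
        return to_dense_3d(tmp, grid)
    raise ValueError(f"unknown input kind {input_kind!r}")


def _model_spec(name: str, fs: float, n_channels: int, T: int, n_classes: int,
                hp: dict | None = None) -> models.ModelSpec:
    return models.build_model(name, T=T, fs=fs, n_channels=n_channels,
                              n_classes=n_classes, **(hp or {}))


def _fit_eval(spec, x_tr, y_tr, x_te, y_te, schedule: TrainSchedule, seed: int,
              classes, init_weights=None, use_val: bool = True,
              epochs: int | None = None) -> tuple[float, models.TrainedModel]:
    n_classes = len(np.unique(y_tr))
    n_val = int(round(len(y_tr) * schedule.val_fraction))
    if use_val and len(y_tr) >= 10 and n_val >= n_classes:
        xt, xv, yt, yv = train_test_split(
            x_tr, y_tr, test_size=schedule.val_fraction, random_state=seed % (2 ** 31),
            stratify=y_tr)
        val = (xv, yv)
    else:
        xt, yt, val = x_tr, y_tr, None
    model = models.fit(
        spec, xt, yt, val=val,
        epochs=epochs or schedule.max_epochs, batch_size=schedule.batch_size,
        lr=schedule.lr, patience=schedule.patience if val is not None else None,
        seed=seed, classes=classes, init_weights=init_weights)
    return model.accuracy(x_te, y_te), model


def _preprocess_tag(epochs: EpochSet) -> str:
    band = epochs.info.get("band", "none")
    ar = "faster" if epochs.info.get("faster") else "raw"
    return f"{band}|{ar}"


def simple_cv(subject_data: EpochSet, model_name: str, schedule: TrainSchedule,
              model_hp: dict | None = None) -> pd.DataFrame:
    """Repeated stratified k-fold CV on one subject: k_folds x repeats rows."""
    labels = subject_data.labels.astype(str)
    classes = tuple(sorted(set(labels)))
    counts = pd.Series(labels).value_counts()
    if counts.min() < schedule.k_folds:
        raise ValueError("need at least k_folds epochs of every class")
    subject = subject_data.info.get("subject", -1)
    spec = _model_spec(model_name, subject_data.fs, subject_data.n_channels,
                       subject_data.n_samples, len(classes), model_hp)
    x = _tensorize(subject_data.data, subject_data.ch_names, subject_data.montage,
                   spec.input_kind)
    cv_seed = _derived_seed(schedule.seed, subject, 0xCF)
    rkf = RepeatedStratifiedKFold(n_splits=schedule.k_folds,
                                  n_repeats=schedule.repeats, random_state=cv_seed)
    rows = []
    for split_i, (tr, te) in enumerate(rkf.split(x, labels)):
        rep, fold = divmod(split_i, schedule.k_folds)
        seed = _derived_seed(schedule.seed, subject, rep, fold)
        acc, _ = _fit_eval(spec, x[tr], labels[tr], x[te], labels[te],
                           schedule, seed, classes)
        rows.append((subject, model_name, _preprocess_tag(subject_data), "simple",
                     "simple", rep, fold, acc))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def transfer_protocol(cohort: list[EpochSet], model_name: str,
                      schedule: TrainSchedule,
                      model_hp: dict | None = None) -> pd.DataFrame:
    """Cross-subject transfer learning.

    Subjects are partitioned into ``tl_iterations`` held-out groups (each
    subject exactly once); per iteration a network is pre-trained on the
    remaining pool, then each held-out subject's copy is fine-tuned for
    ``finetune_epochs`` epochs without validation and evaluated on the
    subject's CV test folds.  Rows carry variant "frozen" (pre-trained
    weights as-is) and "finetuned".
    """
    if len(cohort) < 2:
        raise ValueError("transfer learning needs at least 2 subjects")
    n_iter = min(schedule.tl_iterations, len(cohort))
    labels_all = [ep.labels.astype(str) for ep in cohort]
    classes = tuple(sorted(set(np.concatenate(labels_all))))
    first = cohort[0]
    spec = _model_spec(model_name, first.fs, first.n_channels, first.n_samples,
                      len(classes), model_hp)
    xs = [_tensorize(ep.data, ep.ch_names, ep.montage, spec.input_kind)
          for ep in cohort]

    rng = np.random.default_rng(_derived_seed(schedule.seed, 0x7F))
    order = rng.permutation(len(cohort))
    groups = np.array_split(order, n_iter)

    rows = []
    for it, held in enumerate(groups):
        held = set(int(h) for h in held)
        pool = [i for i in range(len(cohort)) if i not in held]
        if not pool:
            raise ValueError("empty pre-training pool")
        assert not held.intersection(pool)
        x_pool = np.concatenate([xs[i] for i in pool])
        y_pool = np.concatenate([labels_all[i] for i in pool])
        seed = _derived_seed(schedule.seed, 0x7F, it)
        _, pre_model = _fit_eval(spec, x_pool, y_pool, x_pool[:1], y_pool[:1],
                                 schedule, seed, classes, use_val=True)
        pre_weights = pre_model.network.get_weights()

        for si in sorted(held):
            ep, x, y = cohort[si], xs[si], labels_all[si]
            subject = ep.info.get("subject", si)
            cv_seed = _derived_seed(schedule.seed, subject, 0xCF)
            rkf = RepeatedStratifiedKFold(n_splits=schedule.k_folds,
                                          n_repeats=schedule.repeats,
                                          random_state=cv_seed)
            for split_i, (tr, te) in enumerate(rkf.split(x, y)):
                rep, fold = divmod(split_i, schedule.k_folds)
                frozen_acc = pre_model.accuracy(x[te], y[te])
                ft_seed = _derived_seed(schedule.seed, subject, rep, fold, 1)
                ft_acc, _ = _fit_eval(
                    spec, x[tr], y[tr], x[te], y[te], schedule, ft_seed, classes,
                    init_weights=pre_weights, use_val=False,
                    epochs=schedule.finetune_epochs)
                tag = _preprocess_tag(ep)
                rows.append((subject, model_name, tag, "transfer", "frozen",
                             rep, fold, frozen_acc))
                rows.append((subject, model_name, tag, "transfer", "finetuned",
                             rep, fold, ft_acc))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def cropped_regime(subject_data: EpochSet, model_name: str,
                   schedule: TrainSchedule,
                   model_hp: dict | None = None) -> pd.DataFrame:
    """Within-subject CV on sliding-window crops.

    Folds are computed on parent epochs and expanded to crops; accuracy
    is per crop (each crop counts as one sample).
    """
    crops = crop_epochs(subject_data, window=schedule.crop_window,
                        step=schedule.crop_step)
    labels_parent = subject_data.labels.astype(str)
    classes = tuple(sorted(set(labels_parent)))
    subject = subject_data.info.get("subject", -1)
    T = crops.windows.shape[2]
    spec = _model_spec(model_name, subject_data.fs, subject_data.n_channels, T,
                       len(classes), model_hp)
    x = _tensorize(crops.windows, crops.ch_names, subject_data.montage,
                   spec.input_kind)
    y = crops.labels.astype(str)
    gid = crops.group_id

    cv_seed = _derived_seed(schedule.seed, subject, 0xCF)
    rkf = RepeatedStratifiedKFold(n_splits=schedule.k_folds,
                                  n_repeats=schedule.repeats, random_state=cv_seed)
    rows = []
    parents = np.arange(subject_data.n_epochs)
    for split_i, (ptr, pte) in enumerate(rkf.split(parents, labels_parent)):
        rep, fold = divmod(split_i, schedule.k_folds)
        tr = np.isin(gid, parents[ptr])
        te = np.isin(gid, parents[pte])
        assert not (set(gid[tr]) & set(gid[te])), "crop groups straddle the split"
        seed = _derived_seed(schedule.seed, subject, rep, fold, 2)
        acc, _ = _fit_eval(spec, x[tr], y[tr], x[te], y[te], schedule, seed, classes)
        rows.append((subject, model_name, _preprocess_tag(subject_data), "cropped-simple",
                     "cropped", rep, fold, acc))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def preprocess_subject(epochs: EpochSet, band: BandSpec | str | None,
                       artifact_rejection: bool,
                       faster_cfg: FasterConfig | None = None) -> EpochSet:
    """Band-filter and optionally FASTER-clean one subject's recording."""
    if isinstance(band, str):
        band = STUDY_BANDS[band]
    out = butter_bandpass(epochs, band)
    if artifact_rejection:
        out, _ = run_faster(out, faster_cfg or FasterConfig())
    return out


def run_experiment_grid(cohort: list[EpochSet], networks, bands, ar_options,
                        regimes, schedule: TrainSchedule,
                        out_dir: str | Path | None = None,
                        faster_cfg: FasterConfig | None = None,
                        model_hp: dict | None = None) -> pd.DataFrame:
    """Cartesian product driver over bands x AR x regime x network.

    Each (band, ar, regime, network) group is checkpointed to CSV under
    ``out_dir`` and skipped when its file already exists, so interrupted
    grids resume.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    tables = []
    for band_key, ar, regime, network in product(bands, ar_options, regimes, networks):
        tag = f"{band_key}_{'ar' if ar else 'raw'}_{regime}_{network}".replace("|", "-")
        ckpt = out_dir / f"{tag}.csv" if out_dir is not None else None
        if ckpt is not None and ckpt.exists():
            tables.append(pd.read_csv(ckpt))
            continue
        pre = [preprocess_subject(ep, band_key, ar, faster_cfg) for ep in cohort]
        sched = schedule.replace(regime=regime if regime in REGIMES else "simple")
        if regime == "simple":
            grp = pd.concat([simple_cv(ep, network, sched, model_hp) for ep in pre])
        elif regime == "cropped-simple":
            grp = pd.concat([cropped_regime(ep, network, sched, model_hp) for ep in pre])
        elif regime == "transfer":
            grp = transfer_protocol(pre, network, sched, model_hp)
        else:
            raise ValueError(f"grid does not support regime {regime!r}")
        if ckpt is not None:
            grp.to_csv(ckpt, index=False)
        tables.append(grp)
    return pd.concat(tables, ignore_index=True)
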