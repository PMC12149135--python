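"""Training loop, metrics, cross-validation, ablation grid, cross-type
matrix and permutation feature importance.

All randomness (initialization, batch order, validation split, fold
shuffling, permutations) derives deterministically from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import (auc as sk_auc, average_precision_score,
                             precision_recall_curve, roc_auc_score, roc_curve)
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import model as M
from . import _autodiff as ad
from .encoders import Dataset

logger = logging.getLogger("nmfuse")

ABLATION_ROWS = {
    "Seq": dict(use_seq=True, use_chem=False, use_str=False),
    "Che": dict(use_seq=False, use_chem=True, use_str=False),
    "Str": dict(use_seq=False, use_chem=False, use_str=True),
    "Seq+Che": dict(use_seq=True, use_chem=True, use_str=False),
    "Seq+Str": dict(use_seq=True, use_chem=False, use_str=True),
    "Che+Str": dict(use_seq=False, use_chem=True, use_str=True),
    "All": dict(use_seq=True, use_chem=True, use_str=True),
}

SCALAR_METRICS = ("acc", "precision", "recall", "f1", "mcc", "auc", "aupr")


@dataclass
class TrainConfig:
    """Optimizer settings: Adam, early stopping on a validation split."""

    lr: float = 5e-4
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc: float
    aupr: float
    roc_points: list = field(repr=False, default_factory=list)
    pr_points: list = field(repr=False, default_factory=list)

    def scalars(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SCALAR_METRICS}


@dataclass
class ImportanceProfile:
    """Per-position AUC drop when one view's feature row is permuted."""

    view: str
    values: np.ndarray  # length L; positive = important (standard - permuted)


@dataclass
class CVResult:
    reports: list          # (round, fold, MetricsReport)
    mean: dict
    sd: dict

    def metric_matrix(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for _, _, r in self.reports])


def _strata(dataset: Dataset) -> np.ndarray:
    """Joint label x subtype strata for fold/split stratification."""
    if dataset.subtypes is None:
        return dataset.labels.astype("U8")
    return np.char.add(dataset.labels.astype("U2"),
                       dataset.subtypes.astype("U8"))


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2 ** 31 - 1))


def _batch_probs(x_seq, x_chem, x_str, x_node, params, config,
                 batch_size: int = 512) -> np.ndarray:
    n = len(x_seq)
    out = np.empty(n, dtype=float)
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        probs = M._forward_batch(x_seq[lo:hi], x_chem[lo:hi], x_str[lo:hi],
                                 x_node[lo:hi], params, config, train=False)
        out[lo:hi] = probs.data
    return out


# ------------------------------------------------------------------ training

def train(dataset: Dataset, config: M.ModelConfig, seed: int,
          train_config: TrainConfig | None = None):
    """Fit the network with Adam + early stopping; returns (params, history).

    A stratified ``val_fraction`` split monitors validation loss; training
    stops after ``patience`` epochs without improvement and the
    best-validation parameters are restored. Fully deterministic for a
    fixed seed under single-threaded execution.
    """
    tc = train_config or TrainConfig()
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes to be present")
    master = np.random.default_rng(seed)
    split_seed = _derive_seed(master)
    init_seed = _derive_seed(master)
    shuffle_rng = np.random.default_rng(_derive_seed(master))
    dropout_rng = np.random.default_rng(_derive_seed(master))

    strata = _strata(dataset)
    n_val = max(2, int(round(tc.val_fraction * len(dataset))))
    names, counts = np.unique(strata, return_counts=True)
    if counts.min() < 2 or n_val < len(names):
        strata = labels  # joint strata too sparse for this dataset size
    idx_train, idx_val = train_test_split(
        np.arange(len(dataset)), test_size=n_val,
        stratify=strata, random_state=split_seed)
    tr, va = dataset.subset(idx_train), dataset.subset(idx_val)

    params = M.init_params(config, dataset.window_len, seed=init_seed)
    opt = ad.Adam(params.values(), lr=tc.lr)

    def val_loss():
        probs = _batch_probs(va.x_seq, va.x_chem, va.x_str, va.x_node,
                             params, config)
        return M.bce_loss(probs, va.labels)

    best = {"loss": np.inf, "params": None, "epoch": -1}
    history = {"train_loss": [], "val_loss": []}
    stale = 0
    for epoch in range(tc.max_epochs):
        order = shuffle_rng.permutation(len(tr))
        epoch_losses = []
        for lo in range(0, len(tr), tc.batch_size):
            sel = order[lo:lo + tc.batch_size]
            probs = M._forward_batch(
                tr.x_seq[sel], tr.x_chem[sel], tr.x_str[sel], tr.x_node[sel],
                params, config, train=True, rng=dropout_rng)
            loss = M.bce_loss(probs, tr.labels[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        vloss = val_loss()
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(vloss)
        if vloss < best["loss"] - 1e-6:
            best.update(loss=vloss,
                        params={k: t.data.copy() for k, t in params.items()},
                        epoch=epoch)
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break
    if best["params"] is not None:
        for name, t in params.items():
            t.data = best["params"][name]
    history["best_epoch"] = best["epoch"]
    history["best_val_loss"] = best["loss"]
    logger.debug("train: stopped after %d epochs, best val loss %.4f "
                 "(epoch %d)", len(history["val_loss"]), best["loss"],
                 best["epoch"])
    return params, history


# ------------------------------------------------------------------- metrics

def compute_metrics(probs, labels, threshold: float = 0.5) -> MetricsReport:
    """Confusion counts, threshold metrics, and ROC/PR curves.

    AUC is the trapezoidal area under the ROC (tie-aware, equal to the
    normalized Mann-Whitney U statistic); AUPR is the step-wise
    precision-recall integral.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size == 0:
        raise ValueError("compute_metrics: empty input")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels differ in shape")
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc = (tp + tn) / (tn + fp + tp + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    denom = np.sqrt(float(tp + fp) * (tn + fn) * (tp + fn) * (tn + fp))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0

    if len(np.unique(labels)) < 2:
        auc_val, aupr, roc_pts, pr_pts = float("nan"), float("nan"), [], []
    else:
        fpr, tpr, _ = roc_curve(labels, probs)
        auc_val = float(sk_auc(fpr, tpr))
        prec_c, rec_c, _ = precision_recall_curve(labels, probs)
        aupr = float(average_precision_score(labels, probs))
        roc_pts = list(zip(fpr.tolist(), tpr.tolist()))
        pr_pts = list(zip(rec_c.tolist(), prec_c.tolist()))
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, acc=acc,
                         precision=precision, recall=recall, f1=f1,
                         mcc=float(mcc), auc=auc_val, aupr=aupr,
                         roc_points=roc_pts, pr_points=pr_pts)


# ---------------------------------------------------------- cross-validation

def cross_validate(dataset: Dataset, config: M.ModelConfig, k: int = 5,
                   n_rounds: int = 1, seed: int = 0,
                   train_config: TrainConfig | None = None) -> CVResult:
    """Stratified k-fold cross-validation, optionally repeated.

    Folds preserve the joint label x subtype balance; each round reshuffles
    with a round-specific derived seed. Reports per-fold metrics and their
    mean +/- sd across all folds and rounds.
    """
    if k > len(dataset):
        raise ValueError(f"k={k} exceeds dataset size {len(dataset)}")
    master = np.random.default_rng(seed)
    strata = _strata(dataset)
    reports = []
    for rnd in range(n_rounds):
        fold_seed = _derive_seed(master)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        for fold, (idx_tr, idx_te) in enumerate(skf.split(np.zeros(len(dataset)), strata)):
            params, _ = train(dataset.subset(idx_tr), config,
                              seed=_derive_seed(master),
                              train_config=train_config)
            test = dataset.subset(idx_te)
            probs = _batch_probs(test.x_seq, test.x_chem, test.x_str,
                                 test.x_node, params, config)
            reports.append((rnd, fold,
                            compute_metrics(probs, test.labels,
                                            config.threshold)))
    mean = {name: float(np.mean([getattr(r, name) for _, _, r in reports]))
            for name in SCALAR_METRICS}
    sd = {name: float(np.std([getattr(r, name) for _, _, r in reports]))
          for name in SCALAR_METRICS}
    return CVResult(reports=reports, mean=mean, sd=sd)


# ---------------------------------------------------------------- cross-type

def cross_type_matrix(dataset: Dataset, config: M.ModelConfig, seed: int = 0,
                      train_config: TrainConfig | None = None,
                      test_fraction: float = 0.25):
    """Train on each subtype (and on all) and test on each subtype.

    The dataset is first split into disjoint train/test partitions
    (stratified by label x subtype); each grid cell then trains on the
    train-partition samples of the training key and scores the
    test-partition samples of the test subtype. Returns
    {"auc": {...}, "aupr": {...}} nested dicts keyed [train_key][test_subtype].
    """
    if dataset.subtypes is None:
        raise ValueError("cross_type_matrix needs subtype annotations")
    master = np.random.default_rng(seed)
    idx_tr, idx_te = train_test_split(
        np.arange(len(dataset)), test_size=test_fraction,
        stratify=_strata(dataset), random_state=_derive_seed(master))
    if set(idx_tr) & set(idx_te):
        raise RuntimeError("train/test partitions overlap")
    train_part, test_part = dataset.subset(idx_tr), dataset.subset(idx_te)

    subtypes = sorted(set(map(str, dataset.subtypes)))
    grids = {"auc": {}, "aupr": {}}
    for key in subtypes + ["all"]:
        if key == "all":
            cell_train = train_part
        else:
            cell_train = train_part.subset(
                np.flatnonzero(train_part.subtypes == key))
        params, _ = train(cell_train, config, seed=_derive_seed(master),
                          train_config=train_config)
        grids["auc"][key] = {}
        grids["aupr"][key] = {}
        for sub in subtypes:
            cell_test = test_part.subset(
                np.flatnonzero(test_part.subtypes == sub))
            probs = _batch_probs(cell_test.x_seq, cell_test.x_chem,
                                 cell_test.x_str, cell_test.x_node,
                                 params, config)
            rep = compute_metrics(probs, cell_test.labels, config.threshold)
            grids["auc"][key][sub] = rep.auc
            grids["aupr"][key][sub] = rep.aupr
    return grids


# --------------------------------------------------- permutation importance

_VIEW_ARRAYS = {"seq": "x_seq", "chem": "x_chem", "str": "x_str"}


def _permute_position(arr: np.ndarray, view: str, p: int, perm: np.ndarray,
                      rng: np.random.Generator, mode: str) -> np.ndarray:
    out = arr.copy()
    if mode == "across":
        if view == "str":
            row = arr[perm][:, p, :]
            out[:, p, :] = row
            out[:, :, p] = row
        else:
            out[:, p, :] = arr[perm, p, :]
    elif mode == "within":
        partners = rng.integers(0, arr.shape[1], size=len(arr))
        rows = np.arange(len(arr))
        if view == "str":
            out[rows, p, :], out[rows, partners, :] = (
                arr[rows, partners, :], arr[rows, p, :])
            out[rows, :, p], out[rows, :, partners] = (
                arr[rows, :, partners], arr[rows, :, p])
        else:
            out[rows, p, :], out[rows, partners, :] = (
                arr[rows, partners, :], arr[rows, p, :])
    else:
        raise ValueError(f"unknown permutation mode '{mode}'")
    return out


def permutation_importance(dataset: Dataset, config: M.ModelConfig,
                           view: str, n_folds: int = 5, seed: int = 0,
                           train_config: TrainConfig | None = None,
                           mode: str = "across") -> ImportanceProfile:
    """Per-position permutation importance of one feature view.

    For each fold of a stratified k-fold, a model is trained on the
    training part; for every window position p the view's features at p are
    permuted across the validation samples and importance[p] is the mean
    over folds of (standard AUC - permuted AUC), so positive values mark
    important positions. ``mode="within"`` instead swaps position p with a
    random other position inside each sample.
    """
    if view not in _VIEW_ARRAYS:
        raise ValueError(f"view must be one of {sorted(_VIEW_ARRAYS)}")
    enabled = {"seq": config.use_seq, "chem": config.use_chem,
               "str": config.use_str}
    if not enabled[view]:
        raise ValueError(f"view '{view}' is disabled in the model config")
    master = np.random.default_rng(seed)
    strata = _strata(dataset)
    L = dataset.window_len
    deltas = np.zeros((n_folds, L))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=_derive_seed(master))
    for fold, (idx_tr, idx_va) in enumerate(
            skf.split(np.zeros(len(dataset)), strata)):
        params, _ = train(dataset.subset(idx_tr), config,
                          seed=_derive_seed(master), train_config=train_config)
        va = dataset.subset(idx_va)
        arrays = {name: getattr(va, attr)
                  for name, attr in _VIEW_ARRAYS.items()}
        arrays["node"] = va.x_node
        base_auc = roc_auc_score(va.labels, _batch_probs(
            arrays["seq"], arrays["chem"], arrays["str"], arrays["node"],
            params, config))
        perm_rng = np.random.default_rng(_derive_seed(master))
        for p in range(L):
            perm = perm_rng.permutation(len(va))
            shuffled = dict(arrays)
            shuffled[view] = _permute_position(arrays[view], view, p, perm,
                                               perm_rng, mode)
            probs = _batch_probs(shuffled["seq"], shuffled["chem"],
                                 shuffled["str"], shuffled["node"],
                                 params, config)
            deltas[fold, p] = base_auc - roc_auc_score(va.labels, probs)
    return ImportanceProfile(view=view, values=deltas.mean(axis=0))


# ------------------------------------------------------------------ ablation

def run_ablation(dataset: Dataset, config: M.ModelConfig, seed: int = 0,
                 k: int = 5, n_rounds: int = 1,
                 train_config: TrainConfig | None = None) -> dict[str, CVResult]:
    """Cross-validate the seven feature-view combinations."""
    results = {}
    for row, switches in ABLATION_ROWS.items():
        row_config = replace(config, **switches)
        results[row] = cross_validate(dataset, row_config, k=k,
                                      n_rounds=n_rounds, seed=seed,
                                      train_config=train_config)
    return results
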