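"""Training loop, split plan, Dice scoring, and the ablation experiment harness.

The protocol mirrors the emulated study: a fixed holdout of subjects is
reserved for final validation, the remainder is split into k
cross-validation folds; per fold, one model is trained (Adam, batch size 1,
mean per-vertex cross-entropy, fresh Gaussian feature-noise augmentation
each epoch, plateau-triggered learning-rate decay monitoring the fold's
validation loss) and evaluated on the holdout; cell scores are the mean ±
std of the fold models' holdout macro-Dice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Adam, cross_entropy
from .feature_assembly import FeatureSpec, assemble_features, cohort_minmax
from .gnn_models import ModelConfig, build_model
from .surface_mesh import VertexGraph
from .synthetic_cohort import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "HyperParams",
    "SplitPlan",
    "TrainingDivergedError",
    "make_splits",
    "train_model",
    "predict_labels",
    "dice_score",
    "macro_dice",
    "paired_ttest",
    "run_ablation",
]


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during training."""


@dataclass
class HyperParams:
    lr: float = 0.01
    epochs: int = 100
    batch_size: int = 1       # subjects per gradient step (the study used 1)
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    min_lr: float = 1e-5
    augment_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class SplitPlan:
    """Holdout subject ids plus k disjoint folds covering the rest."""

    holdout: list[str]
    folds: list[list[str]]

    def __post_init__(self) -> None:
        flat = [i for f in self.folds for i in f]
        if set(flat) & set(self.holdout):
            raise ValueError("holdout and folds must be disjoint")
        if len(set(flat)) != len(flat):
            raise ValueError("folds must be pairwise disjoint")

    @property
    def k(self) -> int:
        return len(self.folds)

    def fold_split(self, fold: int) -> tuple[list[str], list[str]]:
        """(train ids, validation ids) for one fold."""
        val = self.folds[fold]
        train = [i for j, f in enumerate(self.folds) if j != fold for i in f]
        return train, val


def make_splits(subject_ids: list[str], n_holdout: int = 8, k: int = 5,
                seed: int = 0) -> SplitPlan:
    """Uniform random holdout, then k near-equal folds of the remainder."""
    ids = list(subject_ids)
    if not (0 <= n_holdout < len(ids)):
        raise ValueError("need 0 <= n_holdout < number of subjects")
    if k < 2 or k > len(ids) - n_holdout:
        raise ValueError(f"k={k} incompatible with {len(ids) - n_holdout} remaining subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    holdout = shuffled[:n_holdout]
    rest = shuffled[n_holdout:]
    folds = [list(f) for f in np.array_split(np.asarray(rest, dtype=object), k)]
    return SplitPlan(holdout=holdout, folds=[[str(x) for x in f] for f in folds])


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def dice_score(pred: np.ndarray, truth: np.ndarray, n_classes: int,
               ignore_label: int | None = None) -> dict[int, float]:
    """Per-region Dice: 2|P∩T| / (|P|+|T|).

    Regions absent from both prediction and truth are skipped (not scored);
    a region present in exactly one side scores 0.  ``ignore_label`` (e.g.
    an UNKNOWN class) is never scored.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"label arrays differ in shape: {pred.shape} vs {truth.shape}")
    scores: dict[int, float] = {}
    for r in range(n_classes):
        if r == ignore_label:
            continue
        p = pred == r
        t = truth == r
        denom = p.sum() + t.sum()
        if denom == 0:
            continue
        scores[r] = 2.0 * np.logical_and(p, t).sum() / denom
    return scores


def macro_dice(pred: np.ndarray, truth: np.ndarray, n_classes: int,
               ignore_label: int | None = None) -> float:
    """Unweighted mean of per-region Dice over the scored regions."""
    scores = dice_score(pred, truth, n_classes, ignore_label)
    return float(np.mean(list(scores.values()))) if scores else float("nan")


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject scores.

    Degenerate cases: all differences zero → (0, p=1) by convention;
    constant nonzero differences (zero sd) → p floored at the smallest
    positive float rather than an undefined statistic.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D score arrays with n >= 2")
    d = a - b
    if np.all(d == 0):
        logger.info("paired_ttest: all differences zero; returning p = 1.0")
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        return float(np.sign(d[0]) * np.inf), float(np.finfo(np.float64).tiny)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def predict_labels(model, features: np.ndarray, graph: VertexGraph) -> np.ndarray:
    """Argmax class per vertex (ties resolve to the lowest class index)."""
    logits = model.forward(features, graph)
    return np.argmax(logits.data, axis=1)


def _mean_macro_dice(model, graph, feats, labels, n_classes) -> float:
    return float(np.mean([
        macro_dice(predict_labels(model, x, graph), y, n_classes)
        for x, y in zip(feats, labels)
    ]))


def train_model(
    config: ModelConfig,
    hyper: HyperParams,
    graph: VertexGraph,
    train_features: list[np.ndarray],
    train_labels: list[np.ndarray],
    val_features: list[np.ndarray] | None = None,
    val_labels: list[np.ndarray] | None = None,
):
    """Train one node classifier; returns (model, per-epoch history DataFrame).

    Subjects are visited singly in a reshuffled order each epoch with fresh
    Gaussian noise on the (normalized) input features; the optimizer is Adam
    on the mean per-vertex cross-entropy, with a reduce-on-plateau schedule
    monitoring validation loss (training loss if no validation set is given).
    """
    in_dim = train_features[0].shape[1]
    model = build_model(config, in_dim)
    params = model.parameters()
    opt = Adam(params, lr=hyper.lr)
    rng = np.random.default_rng(hyper.seed)

    best_monitor = np.inf
    stale = 0
    history: list[dict] = []

    for epoch in range(hyper.epochs):
        order = rng.permutation(len(train_features))
        epoch_loss = 0.0
        for i in order:
            x = train_features[i] + rng.normal(
                0.0, hyper.augment_sigma, size=train_features[i].shape
            ) if hyper.augment_sigma > 0 else train_features[i]
            opt.zero_grad()
            loss = cross_entropy(model.forward(x, graph), train_labels[i])
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        epoch_loss /= len(train_features)

        if val_features:
            val_loss = float(np.mean([
                cross_entropy(model.forward(x, graph), y).data
                for x, y in zip(val_features, val_labels)
            ]))
            val_dice = _mean_macro_dice(model, graph, val_features, val_labels,
                                        config.n_classes)
        else:
            val_loss, val_dice = float("nan"), float("nan")
        train_dice = _mean_macro_dice(model, graph, train_features, train_labels,
                                      config.n_classes)

        monitor = val_loss if val_features else epoch_loss
        if monitor < best_monitor - 1e-12:
            best_monitor = monitor
            stale = 0
        else:
            stale += 1
            if stale > hyper.plateau_patience and opt.lr > hyper.min_lr:
                opt.lr = max(opt.lr * hyper.plateau_factor, hyper.min_lr)
                stale = 0
                logger.info("epoch %d: reducing lr to %.2e", epoch, opt.lr)

        history.append({
            "epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss,
            "train_dice": train_dice, "val_dice": val_dice, "lr": opt.lr,
        })

    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Ablation harness (the Table-1-style experiment)
# ---------------------------------------------------------------------------

@dataclass
class AblationResult:
    """Summary table plus per-subject holdout scores for significance tests."""

    table: pd.DataFrame
    # (feature_set, architecture) -> array of shape (k folds, n holdout subjects)
    holdout_scores: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    plan: SplitPlan | None = None

    def subject_means(self, feature_set: str, architecture: str) -> np.ndarray:
        """Per-holdout-subject Dice averaged over the fold models."""
        return self.holdout_scores[(feature_set, architecture)].mean(axis=0)


def run_ablation(
    cohort: Cohort,
    feature_specs: list[FeatureSpec],
    configs: list[ModelConfig],
    hyper: HyperParams,
    hemisphere: str = "L",
    n_holdout: int = 8,
    k: int = 5,
    split_seed: int = 0,
    fit_scaler_on_train: bool = False,
) -> AblationResult:
    """Train once per (feature set, architecture, fold); evaluate each fold
    model on the fixed holdout subjects; report mean ± std across folds.

    By default the min-max scaler is fitted across the entire cohort (the
    original protocol); set ``fit_scaler_on_train`` to fit it per fold on
    the training subjects only.
    """
    if not feature_specs or not configs:
        raise ValueError("feature_specs and configs must be nonempty")
    subjects = {s.id: s for s in cohort.filter(hemisphere)}
    if not subjects:
        raise ValueError(f"cohort has no {hemisphere!r}-hemisphere subjects")
    ids = sorted(subjects)
    plan = make_splits(ids, n_holdout=n_holdout, k=k, seed=split_seed)
    graph = _cohort_graph(cohort)
    n_classes = cohort.params.k_regions
    labels = {sid: subjects[sid].labels for sid in ids}

    rows = []
    holdout_scores: dict[tuple[str, str], np.ndarray] = {}
    for spec in feature_specs:
        raw = {sid: assemble_features(subjects[sid], spec) for sid in ids}
        if not fit_scaler_on_train:
            normed, _ = cohort_minmax([raw[sid] for sid in ids])
            feats_all = {sid: m.values for sid, m in zip(ids, normed)}
        for config in configs:
            fold_subject_scores = np.empty((plan.k, len(plan.holdout)))
            for fold in range(plan.k):
                train_ids, val_ids = plan.fold_split(fold)
                if fit_scaler_on_train:
                    _, scaler = cohort_minmax([raw[sid] for sid in train_ids])
                    feats_all = {sid: scaler.transform(raw[sid]).values for sid in ids}
                model, _ = train_model(
                    config, hyper, graph,
                    [feats_all[s] for s in train_ids], [labels[s] for s in train_ids],
                    [feats_all[s] for s in val_ids], [labels[s] for s in val_ids],
                )
                for j, sid in enumerate(plan.holdout):
                    pred = predict_labels(model, feats_all[sid], graph)
                    fold_subject_scores[fold, j] = macro_dice(pred, labels[sid], n_classes)
            fold_means = fold_subject_scores.mean(axis=1)
            holdout_scores[(spec.name, config.architecture)] = fold_subject_scores
            rows.append({
                "feature_set": spec.name,
                "architecture": config.architecture,
                "mean_dice": float(fold_means.mean()),
                "std_dice": float(fold_means.std(ddof=1)) if plan.k > 1 else 0.0,
                "std_dice_subjects": float(fold_subject_scores.mean(axis=0).std(ddof=1))
                if len(plan.holdout) > 1 else 0.0,
            })
            logger.info("ablation cell %s/%s: %.4f ± %.4f", spec.name,
                        config.architecture, rows[-1]["mean_dice"], rows[-1]["std_dice"])
    return AblationResult(table=pd.DataFrame(rows), holdout_scores=holdout_scores,
                          plan=plan)


def _cohort_graph(cohort: Cohort) -> VertexGraph:
    from .surface_mesh import mesh_to_graph

    return mesh_to_graph(cohort.base_mesh)
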