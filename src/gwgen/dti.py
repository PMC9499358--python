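"""Drug-target interaction (DTI) classification.

Drugs and targets arrive as precomputed numeric descriptor tables (in the
reference setting 363 molecular-descriptor features per drug and 996
protein-descriptor features per target).  A drug-target pair is the
concatenation [D, T] of its descriptor vectors.  Preprocessing, fitted on
training pairs only: z-score standardization per feature, class balancing by
seeded undersampling of the majority class, and per-block PCA retaining the
minimal leading components whose cumulative explained variance reaches the
threshold (0.85).  The classifier is a feed-forward network
(input -> 512 -> 256 -> 128 -> 64 -> 1) with ReLU hidden layers, inverted
dropout (rate 0.4) after each hidden layer, a sigmoid output, binary
cross-entropy loss, and mini-batch gradient descent (learning rate 0.003,
batch 100, 100 epochs) with early stopping on validation loss; Adam is
available as a config option.  Evaluation reports the confusion counts at
cutoff 0.5, TPR/specificity/FPR, the ROC curve over all score cutoffs, and
the trapezoid AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gwgen")

DEFAULT_VARIANCE_THRESHOLD = 0.85


# -- feature sets ---------------------------------------------------------------


@dataclass
class DTIFeatureSet:
    """Descriptor matrices plus labelled drug-target pairs.

    ``pairs`` columns: drug, target, label (0/1).
    """

    drug_features: pd.DataFrame
    target_features: pd.DataFrame
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("drug", "target", "label"):
            if col not in self.pairs.columns:
                raise ValueError(f"pairs table missing column {col!r}")
        labels = set(self.pairs["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary, got {sorted(labels)}")
        bad_drugs = set(self.pairs["drug"]) - set(self.drug_features.index)
        bad_targets = set(self.pairs["target"]) - set(self.target_features.index)
        if bad_drugs or bad_targets:
            raise KeyError(
                f"pairs reference unknown drugs {sorted(bad_drugs)[:3]} /"
                f" targets {sorted(bad_targets)[:3]}"
            )

    @property
    def n_drug_features(self) -> int:
        return self.drug_features.shape[1]

    @property
    def n_target_features(self) -> int:
        return self.target_features.shape[1]


def build_pair_features(feature_set: DTIFeatureSet, drug: str, target: str) -> np.ndarray:
    """Concatenated feature vector [D, T] of one pair (drug block first)."""
    if drug not in feature_set.drug_features.index:
        raise KeyError(f"unknown drug {drug!r}")
    if target not in feature_set.target_features.index:
        raise KeyError(f"unknown target {target!r}")
    return np.concatenate(
        [
            feature_set.drug_features.loc[drug].to_numpy(dtype=float),
            feature_set.target_features.loc[target].to_numpy(dtype=float),
        ]
    )


def pair_blocks(
    feature_set: DTIFeatureSet, pairs: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drug-block matrix, target-block matrix and label vector for a pair table."""
    D = feature_set.drug_features.loc[pairs["drug"]].to_numpy(dtype=float)
    T = feature_set.target_features.loc[pairs["target"]].to_numpy(dtype=float)
    y = pairs["label"].to_numpy(dtype=float)
    return D, T, y


# -- preprocessing --------------------------------------------------------------


@dataclass
class Standardization:
    mean: np.ndarray
    std: np.ndarray  # zeros replaced by 1 (constant features map to 0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def standardize(
    X: np.ndarray, state: Standardization | None = None
) -> tuple[np.ndarray, Standardization]:
    """Z-score features; fit mean/sd when no state is given.

    Constant features (sd = 0) are mapped to 0 with a warning.
    """
    if state is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        n_const = int(np.sum(std == 0))
        if n_const:
            warnings.warn(f"{n_const} constant feature(s) standardized to zero", stacklevel=2)
        state = Standardization(mean=mean, std=np.where(std == 0, 1.0, std))
    elif X.shape[1] != state.mean.shape[0]:
        raise ValueError("feature dimension does not match the fitted state")
    return state.transform(X), state


@dataclass
class PCABlock:
    components: np.ndarray  # retained x features
    explained_variance_ratio: np.ndarray  # full spectrum
    retained: int
    mean: np.ndarray | None = None  # training-block mean (~0 after z-scoring)

    def transform(self, X_std: np.ndarray) -> np.ndarray:
        if self.mean is not None:
            X_std = X_std - self.mean
        return X_std @ self.components.T


def _fit_pca_block(X_std: np.ndarray, threshold: float) -> PCABlock:
    if X_std.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    # standardized input: principal axes of the correlation structure
    mean = X_std.mean(axis=0)
    Xc = X_std - mean
    _, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    var = sv**2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    cumulative = np.cumsum(ratio)
    retained = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    retained = min(retained, len(sv))
    if threshold >= 1.0:
        retained = int(np.sum(ratio > 1e-12))
    return PCABlock(
        components=vt[:retained], explained_variance_ratio=ratio, retained=retained, mean=mean
    )


@dataclass
class PreprocessingState:
    """Standardization and per-block PCA fitted on training pairs only."""

    drug_standardization: Standardization
    target_standardization: Standardization
    drug_pca: PCABlock
    target_pca: PCABlock
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD

    @property
    def output_dim(self) -> int:
        return self.drug_pca.retained + self.target_pca.retained

    def transform(self, D: np.ndarray, T: np.ndarray) -> np.ndarray:
        Dz = self.drug_standardization.transform(D)
        Tz = self.target_standardization.transform(T)
        return np.hstack([self.drug_pca.transform(Dz), self.target_pca.transform(Tz)])


def reduce_dimensions(
    D_std: np.ndarray,
    T_std: np.ndarray,
    drug_state: Standardization,
    target_state: Standardization,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> tuple[PreprocessingState, np.ndarray]:
    """Fit per-block PCA on standardized training blocks and transform them.

    Each block keeps the minimal count of leading principal components whose
    cumulative explained variance reaches the threshold.
    """
    drug_pca = _fit_pca_block(D_std, variance_threshold)
    target_pca = _fit_pca_block(T_std, variance_threshold)
    state = PreprocessingState(
        drug_standardization=drug_state,
        target_standardization=target_state,
        drug_pca=drug_pca,
        target_pca=target_pca,
        variance_threshold=variance_threshold,
    )
    X = np.hstack([drug_pca.transform(D_std), target_pca.transform(T_std)])
    return state, X


def fit_preprocessing(
    feature_set: DTIFeatureSet,
    train_pairs: pd.DataFrame,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> tuple[PreprocessingState, np.ndarray, np.ndarray]:
    """Standardize + PCA-reduce, fitted on the training pairs only.

    Returns ``(state, X_train, y_train)``; held-out pairs are transformed
    with :meth:`PreprocessingState.transform` (no leakage).
    """
    D, T, y = pair_blocks(feature_set, train_pairs)
    D_std, d_state = standardize(D)
    T_std, t_state = standardize(T)
    state, X = reduce_dimensions(D_std, T_std, d_state, t_state, variance_threshold)
    return state, X, y


def balance_classes(pairs: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Seeded undersampling of the majority class to a 1:1 ratio.

    The minority class (normally the verified positive interactions) is kept
    untouched; majority rows are sampled without replacement.
    """
    pos = pairs[pairs["label"] == 1]
    neg = pairs[pairs["label"] == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to balance")
    if len(pos) == len(neg):
        return pairs.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    if len(neg) > len(pos):
        major, minor = neg, pos
    else:
        major, minor = pos, neg
    keep = rng.choice(len(major), size=len(minor), replace=False)
    out = pd.concat([minor, major.iloc[np.sort(keep)]], ignore_index=True)
    return out.sort_values(["drug", "target"]).reset_index(drop=True)


# -- feed-forward classifier ----------------------------------------------------


@dataclass
class DTIConfig:
    hidden_layers: tuple[int, ...] = (512, 256, 128, 64)
    dropout: float = 0.4
    learning_rate: float = 0.003
    epochs: int = 100
    batch_size: int = 100
    patience: int = 10
    optimizer: str = "sgd"  # or "adam"
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD


_EPS = 1e-12


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binary_cross_entropy(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Mean binary cross-entropy L = -(1/N) sum [y log p + (1-y) log(1-p)]."""
    p = np.clip(y_prob, _EPS, 1 - _EPS)
    return float(-np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))


@dataclass
class TrainedDTIModel:
    """Feed-forward binary classifier: parameters theta = (weights, biases)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: DTIConfig
    seed: int
    loss_trace: list[float] = field(default_factory=list)
    val_loss_trace: list[float] = field(default_factory=list)
    accuracy_trace: list[float] = field(default_factory=list)
    val_accuracy_trace: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None

    @property
    def layer_widths(self) -> tuple[int, ...]:
        return (self.weights[0].shape[1],) + tuple(w.shape[0] for w in self.weights)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Binding probabilities in (0,1); inference is deterministic (dropout off)."""
        X = np.atleast_2d(X)
        if X.shape[1] != self.weights[0].shape[1]:
            raise ValueError(
                f"input dim {X.shape[1]} != model input dim {self.weights[0].shape[1]}"
            )
        a = X
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w.T + b, 0.0)
        z = a @ self.weights[-1].T + self.biases[-1]
        return _sigmoid(z).ravel()


def _init_params(widths: tuple[int, ...], rng: np.random.Generator):
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        weights.append(rng.normal(0.0, scale, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward_train(X, weights, biases, dropout, rng):
    acts = [X]
    masks = []
    a = X
    for w, b in zip(weights[:-1], biases[:-1]):
        a = np.maximum(a @ w.T + b, 0.0)
        if dropout > 0:
            mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
            a = a * mask
        else:
            mask = None
        masks.append(mask)
        acts.append(a)
    z = a @ weights[-1].T + biases[-1]
    p = _sigmoid(z).ravel()
    return acts, masks, p


def train_dti(
    X: np.ndarray,
    y: np.ndarray,
    config: DTIConfig | None = None,
    seed: int = 0,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedDTIModel:
    """Train the feed-forward DTI classifier by seeded mini-batch descent.

    Early stopping monitors validation loss with the configured patience and
    restores the best parameters; without a validation set the model trains
    for the full epoch budget.  A NaN loss aborts with diagnostics.
    """
    config = config or DTIConfig()
    rng = np.random.default_rng(seed)
    n, d = X.shape
    widths = (d,) + tuple(config.hidden_layers) + (1,)
    weights, biases = _init_params(widths, rng)

    if config.optimizer == "adam":
        mw = [np.zeros_like(w) for w in weights]
        vw = [np.zeros_like(w) for w in weights]
        mb = [np.zeros_like(b) for b in biases]
        vb = [np.zeros_like(b) for b in biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t_step = 0
    elif config.optimizer != "sgd":
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    model = TrainedDTIModel(weights=weights, biases=biases, config=config, seed=seed)
    best_val = np.inf
    best_params = None
    stall = 0

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, yb = X[idx], y[idx]
            acts, masks, p = _forward_train(Xb, weights, biases, config.dropout, rng)
            m = len(idx)
            # BCE + sigmoid: output-layer delta is (p - y) / m
            delta = ((p - yb) / m)[:, None]
            grads_w, grads_b = [None] * len(weights), [None] * len(weights)
            for layer in range(len(weights) - 1, -1, -1):
                a_prev = acts[layer]
                grads_w[layer] = delta.T @ a_prev
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = delta @ weights[layer]
                    if masks[layer - 1] is not None:
                        delta = delta * masks[layer - 1]
                    delta = delta * (acts[layer] > 0)
            if config.optimizer == "sgd":
                for layer in range(len(weights)):
                    weights[layer] -= config.learning_rate * grads_w[layer]
                    biases[layer] -= config.learning_rate * grads_b[layer]
            else:
                t_step += 1
                lr_t = config.learning_rate * np.sqrt(1 - beta2**t_step) / (1 - beta1**t_step)
                for layer in range(len(weights)):
                    mw[layer] = beta1 * mw[layer] + (1 - beta1) * grads_w[layer]
                    vw[layer] = beta2 * vw[layer] + (1 - beta2) * grads_w[layer] ** 2
                    weights[layer] -= lr_t * mw[layer] / (np.sqrt(vw[layer]) + eps)
                    mb[layer] = beta1 * mb[layer] + (1 - beta1) * grads_b[layer]
                    vb[layer] = beta2 * vb[layer] + (1 - beta2) * grads_b[layer] ** 2
                    biases[layer] -= lr_t * mb[layer] / (np.sqrt(vb[layer]) + eps)

        p_train = model.predict_proba(X)
        loss = binary_cross_entropy(y, p_train)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={loss},"
                f" max|w|={max(np.abs(w).max() for w in weights):.3g}"
            )
        model.loss_trace.append(loss)
        model.accuracy_trace.append(float(np.mean((p_train >= 0.5) == (y == 1))))
        if validation is not None:
            Xv, yv = validation
            pv = model.predict_proba(Xv)
            vloss = binary_cross_entropy(yv, pv)
            model.val_loss_trace.append(vloss)
            model.val_accuracy_trace.append(float(np.mean((pv >= 0.5) == (yv == 1))))
            if vloss < best_val - 1e-9:
                best_val = vloss
                best_params = ([w.copy() for w in weights], [b.copy() for b in biases])
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    model.stopped_epoch = epoch
                    logger.info("early stopping at epoch %d (val loss %.5f)", epoch, best_val)
                    break

    if best_params is not None:
        model.weights, model.biases = best_params
    return model


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded disjoint folds that exactly partition range(n)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, k)]


@dataclass
class EvaluationMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    tpr: float
    specificity: float
    fpr: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float | None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def evaluate_scores(y_true: np.ndarray, scores: np.ndarray, cutoff: float = 0.5) -> EvaluationMetrics:
    """Confusion counts at the cutoff, plus the ROC curve and trapezoid AUC.

    The ROC sweeps the cutoff over all distinct scores; with a single-class
    truth vector the AUC is undefined and reported as None.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    tpr = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    fpr = 1.0 - spec if n_neg else float("nan")
    if n_pos == 0 or n_neg == 0:
        return EvaluationMetrics(tp, tn, fp, fn, tpr, spec, fpr,
                                 np.array([]), np.array([]), None)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted == 1)[distinct]
    fps = np.cumsum(y_sorted == 0)[distinct]
    roc_tpr = np.r_[0.0, tps / n_pos]
    roc_fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(roc_tpr, roc_fpr))
    return EvaluationMetrics(tp, tn, fp, fn, tpr, spec, fpr, roc_fpr, roc_tpr, auc)


def evaluate(model: TrainedDTIModel, X: np.ndarray, y: np.ndarray) -> EvaluationMetrics:
    return evaluate_scores(y, model.predict_proba(X))


def predict_binding(
    model: TrainedDTIModel,
    state: PreprocessingState,
    drug_descriptors: np.ndarray,
    target_descriptors: np.ndarray,
) -> float:
    """Binding probability for one raw drug/target descriptor pair."""
    D = np.atleast_2d(np.asarray(drug_descriptors, dtype=float))
    T = np.atleast_2d(np.asarray(target_descriptors, dtype=float))
    X = state.transform(D, T)
    return float(model.predict_proba(X)[0])


@dataclass
class CrossValidationResult:
    fold_models: list[TrainedDTIModel]
    fold_metrics: list[EvaluationMetrics]
    fold_indices: list[np.ndarray]

    @property
    def mean_auc(self) -> float:
        aucs = [m.auc for m in self.fold_metrics if m.auc is not None]
        return float(np.mean(aucs)) if aucs else float("nan")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    config: DTIConfig | None = None,
    seed: int = 0,
) -> CrossValidationResult:
    """k-fold cross-validation with disjoint seeded folds partitioning the data."""
    folds = kfold_indices(len(y), k, seed)
    models, metrics = [], []
    for i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        model = train_dti(
            X[train_idx], y[train_idx], config, seed=seed + i,
            validation=(X[val_idx], y[val_idx]),
        )
        models.append(model)
        metrics.append(evaluate(model, X[val_idx], y[val_idx]))
    return CrossValidationResult(fold_models=models, fold_metrics=metrics, fold_indices=folds)
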