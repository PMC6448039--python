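"""Feature-learnability: decoding the stimulated nerve from signal features.

*Feature-learnability* quantifies the information content of a chosen set of
signal-feature/electrode inputs as the classification accuracy of a small
feed-forward network trained to name the stimulated nerve (4 classes: RSN,
LSN, RPN, LPN).  The network has one hidden layer of 20 tanh units and a
4-way softmax output trained by full-batch gradient descent with momentum
and an adaptive learning rate, with early stopping on a held-out validation
set.  Training is repeated (default 10 times) under different random
initial conditions and data splits; the repeat-averaged, row-normalized
confusion matrix gives feature-learnability as mean +/- SEM of its diagonal
(SEM across the four class accuracies, a spread over outcomes rather than
over animals).

Three data-partitioning schemes probe different generalization questions:

- WIA (within individual animal): 70/15/15 train/val/test within each
  animal; per-animal confusions are averaged into a cohort matrix.  This is
  the benchmark scheme.
- PP (pooled population): 70/15/15 on all animals pooled.
- LOO (leave one animal out): train/val 70/30 on the remaining animals,
  test on 100% of the held-out animal; one fold per animal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .features import SF_NAMES, feature_columns
from .synthetic import NERVES

__all__ = [
    "ClassifierSpec",
    "PartitionScheme",
    "LearnabilityResult",
    "normalize_features",
    "partition",
    "loo_folds",
    "train_eval_once",
    "run_learnability",
    "rank_results",
    "near_benchmark",
    "resolve_inputs",
    "fl_from_confusion",
    "CHANCE_LEVEL",
]

#: 4-class chance accuracy, %.
CHANCE_LEVEL = 25.0


@dataclass(frozen=True)
class ClassifierSpec:
    """Network architecture and optimizer settings.

    The optimizer follows the gradient-descent-with-momentum-and-adaptive-
    learning-rate family: steps that worsen the loss by more than
    ``max_perf_inc`` are rejected and shrink the learning rate by
    ``lr_dec``; improving steps grow it by ``lr_inc``.  Early stopping
    monitors validation loss with ``patience`` consecutive failures.
    """

    hidden_units: int = 20
    n_classes: int = 4
    learning_rate: float = 0.05
    lr_inc: float = 1.15
    lr_dec: float = 0.7
    momentum: float = 0.9
    max_perf_inc: float = 1.04
    max_epochs: int = 250
    patience: int = 6
    loss_goal: float = 5e-3  # stop when training cross-entropy reaches this


@dataclass(frozen=True)
class PartitionScheme:
    """How trials are split into train/validation/test pools."""

    kind: str = "WIA"  # WIA | PP | LOO
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    loo_val_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.kind not in ("WIA", "PP", "LOO"):
            raise ValueError(f"unknown partition scheme {self.kind!r}")
        if self.kind in ("WIA", "PP") and abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("train/val/test fractions must sum to 1")


@dataclass
class LearnabilityResult:
    """Averaged confusion matrix and learnability scores for one input set."""

    descriptor: str
    inputs: list[str]
    scheme: str
    classes: tuple[str, ...]
    confusion: np.ndarray            # 4x4, rows = true nerve, row sums 100
    fl_mean: float
    fl_sem: float
    per_animal_fl: dict[str, float] | None
    n_repeats: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LearnabilityResult":
        d = dict(d)
        d["confusion"] = np.asarray(d["confusion"], dtype=float)
        d["classes"] = tuple(d["classes"])
        d["inputs"] = list(d["inputs"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LearnabilityResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fl_from_confusion(confusion: np.ndarray) -> tuple[float, float]:
    """Feature-learnability mean and SEM from a row-normalized confusion.

    The SEM is across the k class accuracies on the diagonal (SD/sqrt(k)),
    measuring the spread of accuracy over the possible outcomes.
    """
    diag = np.diag(np.asarray(confusion, dtype=float))
    return float(diag.mean()), float(diag.std(ddof=1) / np.sqrt(len(diag)))


def resolve_inputs(inputs) -> list[str]:
    """Turn an input descriptor into feature-table column names.

    Accepts a ``(electrodes, sfs)`` pair (cross product), an iterable of
    ``(electrode, sf)`` candidate pairs, or an explicit list of column names.
    """
    if isinstance(inputs, tuple) and len(inputs) == 2:
        electrodes, sfs = inputs
        if all(isinstance(e, (int, np.integer)) for e in electrodes) and all(
            isinstance(s, str) and s in SF_NAMES for s in sfs
        ):
            return feature_columns(tuple(electrodes), tuple(sfs))
    cols = []
    for item in inputs:
        if isinstance(item, str):
            cols.append(item)
        else:
            e, sf = item
            cols.append(f"e{int(e)}_{sf}")
    return cols


def normalize_features(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Affine-map each feature column onto [-1, 1] (observed min -> -1,
    max -> +1); constant columns map to 0 with a warning.

    Returns the scaled table and the per-column (min, max) transform, which
    inverts via ``x = lo + (z + 1) * (hi - lo) / 2``.
    """
    if columns is None:
        columns = [
            c for c in table.columns if c not in ("animal", "nerve", "trial")
        ]
    scaled = table.copy()
    transform: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        transform[col] = (float(lo), float(hi))
        if hi > lo:
            scaled[col] = 2.0 * (x - lo) / (hi - lo) - 1.0
        else:
            warnings.warn(
                f"feature {col!r} is constant; mapped to 0", stacklevel=2
            )
            scaled[col] = 0.0
    return scaled, transform


def inverse_transform(
    scaled: pd.DataFrame, transform: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    out = scaled.copy()
    for col, (lo, hi) in transform.items():
        out[col] = lo + (scaled[col].to_numpy(dtype=float) + 1.0) * (hi - lo) / 2.0
    return out


def _stratified_split(
    labels: np.ndarray, fractions: tuple[float, ...], rng: np.random.Generator
) -> list[np.ndarray]:
    """Split indices stratified by class: floor(fraction * n) per non-train
    pool, remainder to the first (training) pool."""
    pools: list[list[int]] = [[] for _ in fractions]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        sizes = [int(np.floor(f * len(idx))) for f in fractions[1:]]
        n_train = len(idx) - sum(sizes)
        cut = np.cumsum([n_train] + sizes)
        parts = np.split(idx, cut[:-1])
        for pool, part in zip(pools, parts):
            pool.extend(part.tolist())
    return [np.array(sorted(p)) for p in pools]


def partition(
    table: pd.DataFrame, scheme: PartitionScheme, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(train, val, test) positional index sets for WIA or PP.

    Splits are stratified by nerve so every class appears in every pool;
    within each class the non-train pools get floor(fraction * n) trials and
    the remainder goes to training.  Reproducible from ``seed``.  For the
    WIA scheme the table must already be restricted to a single animal.
    """
    if scheme.kind == "LOO":
        raise ValueError("use loo_folds() for the LOO scheme")
    if scheme.kind == "WIA" and table["animal"].nunique() != 1:
        raise ValueError("WIA partitions operate on a single animal's table")
    labels = table["nerve"].to_numpy()
    for attempt in range(2):
        rng = np.random.default_rng(
            np.random.SeedSequence((int(seed), attempt, 0xF17))
        )
        train, val, test = _stratified_split(labels, scheme.fractions, rng)
        ok = all(
            len(np.intersect1d(pool, np.flatnonzero(labels == c))) > 0
            for pool in (train, val, test)
            for c in np.unique(labels)
        )
        if ok:
            return train, val, test
    raise ValueError("could not populate every class in every split")


def loo_folds(
    table: pd.DataFrame, scheme: PartitionScheme, seed: int
) -> list[tuple[str, np.ndarray, np.ndarray, np.ndarray]]:
    """Leave-one-animal-out folds: per fold, train/val stratified 70/30 over
    the remaining animals and test on all trials of the held-out animal."""
    animals = list(pd.unique(table["animal"]))
    if len(animals) < 2:
        raise ValueError("LOO requires at least 2 animals")
    folds = []
    labels = table["nerve"].to_numpy()
    animal_col = table["animal"].to_numpy()
    for i, held in enumerate(animals):
        test = np.flatnonzero(animal_col == held)
        pool = np.flatnonzero(animal_col != held)
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), i, 0x100)))
        tr, val = _stratified_split(
            labels[pool],
            (1.0 - scheme.loo_val_fraction, scheme.loo_val_fraction),
            rng,
        )
        folds.append((held, pool[tr], pool[val], test))
    return folds


# --------------------------------------------------------------------------
# The classifier
# --------------------------------------------------------------------------

def _init_params(n_in: int, spec: ClassifierSpec, rng: np.random.Generator):
    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    return [
        glorot(n_in, spec.hidden_units),
        np.zeros(spec.hidden_units),
        glorot(spec.hidden_units, spec.n_classes),
        np.zeros(spec.n_classes),
    ]


def _forward(params, X):
    W1, b1, W2, b2 = params
    H = np.tanh(X @ W1 + b1)
    logits = H @ W2 + b2
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    P = expl / expl.sum(axis=1, keepdims=True)
    return H, P


def _loss(P, y_onehot):
    return float(-np.mean(np.log(np.sum(P * y_onehot, axis=1) + 1e-300)))


def _gradients(params, X, y_onehot):
    W1, b1, W2, b2 = params
    H, P = _forward(params, X)
    n = len(X)
    dlogits = (P - y_onehot) / n
    dW2 = H.T @ dlogits
    db2 = dlogits.sum(axis=0)
    dH = (dlogits @ W2.T) * (1.0 - H**2)
    dW1 = X.T @ dH
    db1 = dH.sum(axis=0)
    return [dW1, db1, dW2, db2], _loss(P, y_onehot)


def _train_network(X_tr, Y_tr, X_val, Y_val, spec: ClassifierSpec, rng):
    """Full-batch gradient descent with momentum + adaptive learning rate,
    early-stopped on validation loss.  Returns (params, converged)."""
    params = _init_params(X_tr.shape[1], spec, rng)
    velocity = [np.zeros_like(p) for p in params]
    lr = spec.learning_rate
    grads, loss = _gradients(params, X_tr, Y_tr)
    best_val = _loss(_forward(params, X_val)[1], Y_val)
    best_params = [p.copy() for p in params]
    fails = 0
    converged = False
    for _ in range(spec.max_epochs):
        velocity = [spec.momentum * v - lr * g for v, g in zip(velocity, grads)]
        proposal = [p + v for p, v in zip(params, velocity)]
        new_grads, new_loss = _gradients(proposal, X_tr, Y_tr)
        if new_loss > loss * spec.max_perf_inc:
            # reject the step, damp the learning rate, kill momentum
            velocity = [np.zeros_like(p) for p in params]
            lr *= spec.lr_dec
            if lr < 1e-10:
                break
            continue
        if new_loss < loss:
            lr *= spec.lr_inc
        params, grads, loss = proposal, new_grads, new_loss
        val_loss = _loss(_forward(params, X_val)[1], Y_val)
        if val_loss < best_val:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            fails = 0
            if loss <= spec.loss_goal:
                converged = True
                break
        else:
            fails += 1
            if fails >= spec.patience:
                converged = True
                break
    return best_params, converged


def _class_order(labels: np.ndarray) -> tuple[str, ...]:
    uniq = set(str(v) for v in np.unique(labels))
    if uniq <= set(NERVES):
        return tuple(n for n in NERVES if n in uniq)
    return tuple(sorted(uniq))


def train_eval_once(
    train_Xy, val_Xy, test_Xy, spec: ClassifierSpec, seed: int,
    classes: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Train one network and return its test confusion matrix in %.

    Each argument is an ``(X, y)`` pair of feature matrix (already scaled to
    [-1, 1]) and nerve labels.  Rows of the returned matrix are true
    classes, row-normalized to sum to 100.  A network that never converges
    still returns the evaluation of its best weights.
    """
    X_tr, y_tr = train_Xy
    X_val, y_val = val_Xy
    X_te, y_te = test_Xy
    if classes is None:
        classes = _class_order(y_tr)
    if set(np.unique(y_tr)) != set(classes):
        raise ValueError("all classes must be present in the training set")
    cls_index = {c: i for i, c in enumerate(classes)}
    k = len(classes)

    def onehot(y):
        out = np.zeros((len(y), k))
        out[np.arange(len(y)), [cls_index[v] for v in y]] = 1.0
        return out

    rng = np.random.default_rng(seed)
    params, _ = _train_network(
        np.asarray(X_tr, float), onehot(y_tr),
        np.asarray(X_val, float), onehot(y_val), spec, rng,
    )
    _, P = _forward(params, np.asarray(X_te, float))
    pred = np.argmax(P, axis=1)
    conf = np.zeros((k, k))
    for true, p in zip((cls_index[v] for v in y_te), pred):
        conf[true, p] += 1
    row_sums = conf.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError("a class is missing from the test set")
    return 100.0 * conf / row_sums


def _repeat_confusion(df, cols, scheme, spec, n_repeats, seed, classes):
    """Average the confusion over n_repeats random splits/initializations."""
    mats = []
    for rep in range(n_repeats):
        rep_seed = int(
            np.random.SeedSequence((int(seed), rep, 0xAB)).generate_state(1)[0]
        )
        tr, val, te = partition(df, scheme, rep_seed)
        X = df[cols].to_numpy(dtype=float)
        y = df["nerve"].to_numpy()
        mats.append(
            train_eval_once(
                (X[tr], y[tr]), (X[val], y[val]), (X[te], y[te]),
                spec, rep_seed, classes,
            )
        )
    return np.mean(mats, axis=0)


def run_learnability(
    table: pd.DataFrame,
    inputs,
    scheme: PartitionScheme | str = "WIA",
    spec: ClassifierSpec | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    descriptor: str | None = None,
) -> LearnabilityResult:
    """Feature-learnability of one input configuration under one scheme.

    Features are min-max normalized to [-1, 1] over the whole table before
    splitting.  Aggregation: WIA averages the 10 repeat confusions within
    each animal, then averages the per-animal matrices (each animal also
    yields a per-animal FL = mean of its own diagonal); PP averages repeats
    on the pooled table; LOO averages repeats within each fold and then the
    fold matrices, with per-fold FLs kept per held-out animal.
    """
    if isinstance(scheme, str):
        scheme = PartitionScheme(kind=scheme)
    spec = spec or ClassifierSpec()
    cols = resolve_inputs(inputs)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"inputs not in table: {missing}")
    scaled, _ = normalize_features(table, cols)
    scaled = scaled.dropna(subset=cols).reset_index(drop=True)
    classes = _class_order(scaled["nerve"].to_numpy())
    per_animal: dict[str, float] | None = None

    if scheme.kind == "WIA":
        per_animal = {}
        animal_mats = []
        for a_idx, (animal, df_a) in enumerate(scaled.groupby("animal", sort=True)):
            df_a = df_a.reset_index(drop=True)
            conf = _repeat_confusion(
                df_a, cols, scheme, spec, n_repeats,
                int(np.random.SeedSequence((int(seed), a_idx)).generate_state(1)[0]),
                classes,
            )
            animal_mats.append(conf)
            per_animal[animal] = float(np.diag(conf).mean())
        confusion = np.mean(animal_mats, axis=0)
    elif scheme.kind == "PP":
        confusion = _repeat_confusion(
            scaled, cols, scheme, spec, n_repeats, seed, classes
        )
    else:  # LOO
        per_animal = {}
        fold_mats = []
        X = scaled[cols].to_numpy(dtype=float)
        y = scaled["nerve"].to_numpy()
        animal_col = scaled["animal"].to_numpy()
        animals = list(pd.unique(scaled["animal"]))
        if len(animals) < 2:
            raise ValueError("LOO requires at least 2 animals")
        for f_idx, held in enumerate(animals):
            te = np.flatnonzero(animal_col == held)
            pool = np.flatnonzero(animal_col != held)
            mats = []
            for rep in range(n_repeats):
                rep_seed = int(
                    np.random.SeedSequence(
                        (int(seed), f_idx, rep, 0xCD)
                    ).generate_state(1)[0]
                )
                # fresh train/val allocation and initial weights each repeat
                rng = np.random.default_rng(rep_seed)
                tr, val = _stratified_split(
                    y[pool],
                    (1.0 - scheme.loo_val_fraction, scheme.loo_val_fraction),
                    rng,
                )
                tr, val = pool[tr], pool[val]
                mats.append(
                    train_eval_once(
                        (X[tr], y[tr]), (X[val], y[val]), (X[te], y[te]),
                        spec, rep_seed, classes,
                    )
                )
            conf = np.mean(mats, axis=0)
            fold_mats.append(conf)
            per_animal[held] = float(np.diag(conf).mean())
        confusion = np.mean(fold_mats, axis=0)

    fl_mean, fl_sem = fl_from_confusion(confusion)
    return LearnabilityResult(
        descriptor=descriptor or "+".join(cols),
        inputs=cols,
        scheme=scheme.kind,
        classes=classes,
        confusion=confusion,
        fl_mean=fl_mean,
        fl_sem=fl_sem,
        per_animal_fl=per_animal,
        n_repeats=n_repeats,
    )


def rank_results(results: list[LearnabilityResult]) -> list[LearnabilityResult]:
    """Descending by FL mean; ties broken by ascending SEM, then by input
    descriptor (stable lexicographic order)."""
    return sorted(results, key=lambda r: (-r.fl_mean, r.fl_sem, r.descriptor))


def _logit_pct(values: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(values, float), 0.5, 99.5) / 100.0
    return np.log(p / (1.0 - p))


def near_benchmark(
    candidate: LearnabilityResult,
    benchmark: LearnabilityResult,
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Is the candidate's learnability statistically indistinguishable from
    the benchmark's?  Paired t-test on per-animal FL values (df = n - 1); a
    logit transform is applied first when any value exceeds 95% (ceiling
    guard).  Returns ``(is_near, p)`` with ``is_near`` iff p >= alpha.
    """
    if candidate.per_animal_fl is None or benchmark.per_animal_fl is None:
        raise ValueError("both results need per-animal FL values")
    animals = sorted(benchmark.per_animal_fl)
    if sorted(candidate.per_animal_fl) != animals:
        raise ValueError("mismatched animal sets")
    if len(animals) < 2:
        raise ValueError("paired t-test needs at least 2 animals")
    a = np.array([candidate.per_animal_fl[k] for k in animals])
    b = np.array([benchmark.per_animal_fl[k] for k in animals])
    if np.any(a > 95.0) or np.any(b > 95.0):
        a, b = _logit_pct(a), _logit_pct(b)
    if np.allclose(a, b):
        return True, 1.0
    t = stats.ttest_rel(a, b)
    p = float(t.pvalue)
    if np.isnan(p):
        p = 1.0
    return p >= alpha, p
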