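"""Feature scaling, mRMR + stability selection, and the RBF-SVM scorer.

The classifier follows the published protocol: features scaled to
[0, 1], a radial-basis-function SVM with C=128 and gamma=0.01, Platt-style
probability estimates, and disease scores = 100 x P(disease) with a
decision cutoff of 50.

Feature selection is stability selection over minimum-redundancy
maximum-relevance (mRMR): mRMR is run on 100 random half-samples of the
variants and only features chosen in every subset are kept. Relevance
and redundancy are plug-in mutual information on features discretised
into 10 equal-frequency bins (labels are binary already); the greedy
objective for a candidate f given the selected set S is

    I(f; label) - alpha * mean_{s in S} I(f; s)

with alpha = 0.5 by default and ties broken by feature name.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import FeatureMatrix, RunConfig, SelectionConfig, SvmConfig, child_seed, logger
from .errors import DegenerateInputError, SchemaError, ValidationError

N_BINS = 10  # equal-frequency bins for MI estimation

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Scaling


@dataclass
class Scaler:
    """Per-feature min/max from training data; maps features onto [0, 1]."""

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maxs < self.mins):
            raise ValidationError("scaler max < min")


def fit_scaler(train: FeatureMatrix | np.ndarray, feature_names=None) -> Scaler:
    if isinstance(train, FeatureMatrix):
        values, names = train.values, train.feature_names
        values = np.where(train.missing_mask, np.nan, values)
    else:
        values = np.asarray(train, float)
        names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(values.shape[1])
        ]
    if values.shape[0] == 0:
        raise DegenerateInputError("cannot fit a scaler on zero rows")
    with np.errstate(all="ignore"):
        mins = np.nanmin(values, axis=0)
        maxs = np.nanmax(values, axis=0)
    # all-missing columns scale to 0
    mins = np.where(np.isnan(mins), 0.0, mins)
    maxs = np.where(np.isnan(maxs), 0.0, maxs)
    return Scaler(list(names), mins, maxs)


def apply_scaler(scaler: Scaler, m: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; constant features map to 0; out-of-range values clip."""
    if isinstance(m, FeatureMatrix):
        if m.feature_names != scaler.feature_names:
            extra = set(m.feature_names) - set(scaler.feature_names)
            miss = set(scaler.feature_names) - set(m.feature_names)
            raise SchemaError(f"feature mismatch: unknown {extra or '{}'}, absent {miss or '{}'}")
        values = m.values
    else:
        values = np.asarray(m, float)
    span = scaler.maxs - scaler.mins
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (values - scaler.mins) / span
    scaled = np.where(span == 0, 0.0, scaled)
    return np.clip(scaled, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Mutual information / mRMR


def discretize_column(x: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Equal-frequency integer codes; NaN goes to its own top bin."""
    x = np.asarray(x, float)
    codes = np.zeros(len(x), dtype=np.int64)
    finite = np.isfinite(x)
    if finite.any():
        qs = np.nanquantile(x[finite], np.linspace(0, 1, n_bins + 1)[1:-1])
        codes[finite] = np.searchsorted(qs, x[finite], side="right")
    codes[~finite] = n_bins
    return codes


def mutual_information(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """Plug-in MI (bits) between two integer-coded variables."""
    kx = int(x_codes.max()) + 1
    ky = int(y_codes.max()) + 1
    joint = np.bincount(x_codes * ky + y_codes, minlength=kx * ky).astype(float)
    joint = joint.reshape(kx, ky) / len(x_codes)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float((joint[nz] * np.log2(joint[nz] / outer[nz])).sum())


def mrmr_select(
    m: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    k: int,
    alpha: float = 0.5,
    feature_names: Sequence[str] | None = None,
) -> list[str]:
    """Greedy mRMR: returns min(k, n_features) feature names in pick order."""
    if isinstance(m, FeatureMatrix):
        values = np.where(m.missing_mask, np.nan, m.values)
        names = m.feature_names
    else:
        values = np.asarray(m, float)
        names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(values.shape[1])
        ]
    if k < 1:
        raise ValidationError("k must be >= 1")
    labels = np.asarray(labels)
    if len(labels) != values.shape[0]:
        raise ValidationError("labels length != rows")
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("mRMR needs both classes present")
    p = values.shape[1]
    codes = np.column_stack([discretize_column(values[:, j]) for j in range(p)])
    y = np.unique(labels, return_inverse=True)[1]
    relevance = np.array([mutual_information(codes[:, j], y) for j in range(p)])

    selected: list[int] = []
    pair_mi: dict[tuple[int, int], float] = {}
    remaining = set(range(p))
    while remaining and len(selected) < min(k, p):
        best_j, best_key = None, None
        for j in sorted(remaining, key=lambda j: names[j]):
            if selected:
                red = 0.0
                for s in selected:
                    key = (min(j, s), max(j, s))
                    if key not in pair_mi:
                        pair_mi[key] = mutual_information(codes[:, j], codes[:, s])
                    red += pair_mi[key]
                score = relevance[j] - alpha * red / len(selected)
            else:
                score = relevance[j]
            if best_key is None or score > best_key:
                best_key, best_j = score, j
        selected.append(best_j)
        remaining.discard(best_j)
    return [names[j] for j in selected]


@dataclass
class SelectionReport:
    """Outcome of stability selection."""

    feature_names: list[str]
    frequencies: dict[str, float]
    chosen: list[str]
    per_subset: list[list[str]]
    n_subsets: int
    keep_threshold: float
    seed: int

    def summary_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "feature": list(self.frequencies),
                "frequency": list(self.frequencies.values()),
            }
        ).sort_values("frequency", ascending=False, kind="stable")
        df["chosen"] = df["feature"].isin(self.chosen)
        return df.reset_index(drop=True)


def stability_select(
    m: FeatureMatrix,
    labels: np.ndarray | None = None,
    cfg: SelectionConfig | None = None,
    seed: int = 0,
) -> SelectionReport:
    """Run mRMR on repeated subsamples and keep consistently chosen features.

    Each of ``cfg.n_subsets`` seeded draws takes
    floor(subsample_fraction * n) rows without replacement and runs
    mRMR with ``k_per_iteration`` picks. A feature's frequency is the
    fraction of subsets that picked it; the chosen set keeps features at
    or above ``keep_threshold`` (default 1.0, i.e. picked every time).
    """
    cfg = cfg or SelectionConfig()
    if labels is None:
        labels = m.labels
    labels = np.asarray(labels)
    n = m.n_savs
    size = int(np.floor(cfg.subsample_fraction * n))
    counts = {name: 0 for name in m.feature_names}
    per_subset: list[list[str]] = []
    values = np.where(m.missing_mask, np.nan, m.values)
    usable = 0
    for i in range(cfg.n_subsets):
        rng = np.random.default_rng(child_seed(seed, 1, i))
        idx = rng.choice(n, size=size, replace=False)
        sub_labels = labels[idx]
        if size < 2 or len(np.unique(sub_labels)) < 2:
            logger.warning("subset %d skipped (too small or single-class)", i)
            per_subset.append([])
            continue
        picks = mrmr_select(
            values[idx],
            sub_labels,
            k=cfg.k_per_iteration,
            alpha=cfg.alpha,
            feature_names=m.feature_names,
        )
        per_subset.append(picks)
        usable += 1
        for name in picks:
            counts[name] += 1
    if usable == 0:
        raise DegenerateInputError("all stability-selection subsets were degenerate")
    freqs = {name: counts[name] / cfg.n_subsets for name in m.feature_names}
    chosen = [
        name for name in m.feature_names if freqs[name] >= cfg.keep_threshold
    ]
    return SelectionReport(
        list(m.feature_names),
        freqs,
        chosen,
        per_subset,
        cfg.n_subsets,
        cfg.keep_threshold,
        seed,
    )


# ---------------------------------------------------------------------------
# SVM


@dataclass
class TrainedModel:
    """A fitted scorer: imputation means + scaler + calibrated RBF-SVM."""

    feature_names: list[str]
    feature_means: np.ndarray
    scaler: Scaler
    svm: SVC
    config: SvmConfig
    seed: int

    def save(self, path: str | Path) -> None:
        header = {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_names": self.feature_names,
            "C": self.config.C,
            "gamma": self.config.gamma,
            "seed": self.seed,
        }
        with open(path, "wb") as fh:
            fh.write(json.dumps(header).encode() + b"\n")
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            if header.get("format_version") != MODEL_FORMAT_VERSION:
                raise ValidationError(
                    f"unsupported model format {header.get('format_version')}"
                )
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise ValidationError("model payload has unexpected type")
        return model


def _impute(values: np.ndarray, mask: np.ndarray, means: np.ndarray) -> np.ndarray:
    out = values.copy()
    missing = mask | ~np.isfinite(out)
    if missing.any():
        out[missing] = np.broadcast_to(means, out.shape)[missing]
    return out


def train_svm(
    m: FeatureMatrix,
    labels: np.ndarray | None = None,
    cfg: SvmConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the RBF-SVM with probability calibration.

    Missing entries are imputed with the training-set feature mean, then
    all features are scaled to [0, 1]. The model stores the means, the
    scaler and the feature list, so prediction is self-contained.
    """
    cfg = cfg or SvmConfig()
    if labels is None:
        labels = m.labels
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("training needs both classes present")
    values = np.where(m.missing_mask, np.nan, m.values)
    if np.isinf(m.values[~m.missing_mask]).any():
        raise ValidationError("non-finite feature values outside the missing mask")
    with np.errstate(all="ignore"):
        means = np.nanmean(values, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    imputed = _impute(m.values, m.missing_mask, means)
    scaler = fit_scaler(imputed, m.feature_names)
    X = apply_scaler(scaler, imputed)
    import warnings

    with warnings.catch_warnings():
        # SVC(probability=True) is the Platt-calibration route we want;
        # newer sklearn suggests CalibratedClassifierCV instead.
        warnings.simplefilter("ignore", FutureWarning)
        svm = SVC(
            kernel="rbf",
            C=cfg.C,
            gamma=cfg.gamma,
            probability=True,
            random_state=child_seed(seed, 2),
        )
        svm.fit(X, labels)
    return TrainedModel(list(m.feature_names), means, scaler, svm, cfg, seed)


def predict_score(
    model: TrainedModel, m: FeatureMatrix, cutoff: float = 50.0
):
    """Disease probability, 0-100 score and binary call per SAV.

    score = 100 x P(disease); call is "disease" strictly above the
    cutoff, "neutral" at or below it.
    """
    import pandas as pd

    sub = m.select_features(model.feature_names)
    imputed = _impute(sub.values, sub.missing_mask, model.feature_means)
    X = apply_scaler(model.scaler, imputed)
    class_index = list(model.svm.classes_).index(1)
    prob = model.svm.predict_proba(X)[:, class_index]
    score = 100.0 * prob
    call = np.where(score > cutoff, "disease", "neutral")
    return pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in sub.savs],
            "position": [s.position for s in sub.savs],
            "wt": [s.wt for s in sub.savs],
            "mut": [s.mut for s in sub.savs],
            "probability": prob,
            "score": score,
            "call": call,
        }
    )


def sigest_gamma(
    X: np.ndarray, seed: int = 0, n_pairs: int = 5000
) -> float:
    """Gamma from the quantile-of-pairwise-distances heuristic.

    Samples squared Euclidean distances between random row pairs and
    returns 1 over the midpoint of their 0.1 and 0.9 quantiles.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 2:
        raise DegenerateInputError("need at least two rows")
    rng = np.random.default_rng(child_seed(seed, 3))
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n, size=n_pairs)
    keep = i != j
    d2 = ((X[i[keep]] - X[j[keep]]) ** 2).sum(axis=1)
    q10, q90 = np.quantile(d2, [0.1, 0.9])
    mid = (q10 + q90) / 2.0
    if mid <= 0:
        raise DegenerateInputError(
            "pairwise distances are all zero; gamma heuristic undefined"
        )
    return float(1.0 / mid)


def grid_search_cv(
    m: FeatureMatrix,
    labels: np.ndarray | None = None,
    C_grid: Sequence[float] = (1, 2, 8, 32, 128, 512),
    folds: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Choose gamma by the sigest heuristic and C by stratified k-fold CV
    maximising mean balanced accuracy (ties -> smallest C)."""
    from .evalstats import ConfusionCounts, confusion_metrics

    if labels is None:
        labels = m.labels
    labels = np.asarray(labels, int)
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if not len(C_grid):
        raise ValidationError("empty C grid")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise DegenerateInputError("grid search needs both classes")
    if counts.min() < folds:
        raise DegenerateInputError(
            f"cannot form {folds} stratified folds with class counts {counts.tolist()}"
        )
    values = _impute(m.values, m.missing_mask, np.zeros(len(m.feature_names)))
    scaler = fit_scaler(values, m.feature_names)
    X = apply_scaler(scaler, values)
    gamma = sigest_gamma(X, seed=seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=child_seed(seed, 4))
    best = None
    for C in sorted(set(float(c) for c in C_grid)):
        accs = []
        for train_idx, test_idx in skf.split(X, labels):
            svm = SVC(kernel="rbf", C=C, gamma=gamma)
            svm.fit(X[train_idx], labels[train_idx])
            pred = svm.predict(X[test_idx])
            y = labels[test_idx]
            c = ConfusionCounts(
                tp=int(((pred == 1) & (y == 1)).sum()),
                tn=int(((pred == 0) & (y == 0)).sum()),
                fp=int(((pred == 1) & (y == 0)).sum()),
                fn=int(((pred == 0) & (y == 1)).sum()),
            )
            accs.append(confusion_metrics(c)["balanced_accuracy"])
        mean_acc = float(np.mean(accs))
        if best is None or mean_acc > best[1]:  # ties keep the smaller C
            best = (C, mean_acc)
    return {"C": best[0], "gamma": gamma, "cv_balanced_accuracy": best[1]}
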