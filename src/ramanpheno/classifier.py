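"""L1-regularized logistic classification of spectra.

The fitted object is the minimizer of

    mean negative log-likelihood + lambda * sum(|coefficient|)

with an unpenalized intercept, computed on internally standardized channels.
The coefficient vector on the standardized scale is the separation vector;
positive score means Treg.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ConvergenceError
from .spectra_io import BandAssignmentTable

POSITIVE_CLASS = "Treg"
NEGATIVE_CLASS = "Tconv"


def encode_labels(labels: Sequence) -> np.ndarray:
    """Map Tconv/Treg (or 0/1) labels to a {0, 1} int array; Treg is 1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iufb":
        y = arr.astype(int)
        if not np.isin(y, [0, 1]).all():
            raise ValueError("numeric labels must be 0/1")
        return y
    y = np.empty(arr.size, dtype=int)
    for i, v in enumerate(arr.ravel()):
        if v == POSITIVE_CLASS:
            y[i] = 1
        elif v == NEGATIVE_CLASS:
            y[i] = 0
        else:
            raise ValueError(f"unexpected label {v!r}")
    return y


@dataclass
class FittedModel:
    """Sparse logistic model aligned to a wavenumber axis."""

    intercept: float
    coefficients: np.ndarray          # standardized scale (separation vector)
    lambda_: float
    center: np.ndarray                # per-channel standardization center
    scale: np.ndarray                 # per-channel standardization scale
    axis: np.ndarray | None = None
    class_orientation: str = "positive score => Treg"
    training_manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=float)
            if self.axis.size != self.coefficients.size:
                raise ValueError("coefficient length must equal axis length")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coefficients.size:
            raise ValueError(
                f"X has {X.shape[1]} channels, model expects "
                f"{self.coefficients.size}"
            )
        Z = (X - self.center) / self.scale
        return self.intercept + Z @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "schema": "ramanpheno.model/1",
            "intercept": float(self.intercept),
            "coefficients": self.coefficients.tolist(),
            "lambda": float(self.lambda_),
            "center": np.asarray(self.center).tolist(),
            "scale": np.asarray(self.scale).tolist(),
            "axis": None if self.axis is None else self.axis.tolist(),
            "class_orientation": self.class_orientation,
            "training_manifest": self.training_manifest,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            intercept=d["intercept"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            lambda_=d["lambda"],
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            axis=None if d.get("axis") is None else np.asarray(d["axis"]),
            class_orientation=d.get(
                "class_orientation", "positive score => Treg"
            ),
            training_manifest=d.get("training_manifest", {}),
        )


def _manifest(cell_ids, seed, extra: dict | None = None) -> dict:
    m = {
        "cell_ids": list(cell_ids) if cell_ids is not None else None,
        "seed": seed,
    }
    if extra:
        m.update(extra)
    m["config_hash"] = hashlib.sha256(
        json.dumps(
            {k: v for k, v in m.items() if k != "cell_ids"}, sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()[:16]
    return m


def fit_lasso_logistic(
    X: np.ndarray,
    y: Sequence,
    lambda_: float,
    *,
    axis: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    cell_ids: Sequence[str] | None = None,
    seed: int | None = None,
) -> FittedModel:
    """Fit the L1-penalized logistic model at penalty weight ``lambda_``.

    Channels are standardized internally (constant channels get unit scale).
    ``lambda_`` multiplies the L1 norm of the coefficients against the *mean*
    negative log-likelihood; the intercept is unpenalized.
    """
    X = np.asarray(X, dtype=float)
    yv = encode_labels(y)
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    n = X.shape[0]
    if n != yv.size:
        raise ValueError("X rows must match y length")
    for cls in (0, 1):
        if (yv == cls).sum() < 2:
            raise ValueError("need >= 2 samples in each class")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    degenerate = scale <= 0
    scale = np.where(degenerate, 1.0, scale)
    if degenerate.all() and lambda_ == 0:
        raise ConvergenceError(
            "all channels are constant and lambda is 0: the objective has no "
            "unique minimizer in the coefficients"
        )
    Z = (X - center) / scale

    prev = float(yv.mean())
    # lambda at/above which the all-zero solution is optimal
    lambda_max = np.max(np.abs(Z.T @ (yv - prev))) / n
    if lambda_ >= lambda_max:
        coefs = np.zeros(X.shape[1])
        icpt = float(np.log(prev / (1.0 - prev)))
    else:
        if lambda_ == 0:
            est = LogisticRegression(
                C=np.inf, solver="lbfgs", tol=tol, max_iter=max_iter,
            )
        else:
            # liblinear: intercept_scaling large so the intercept penalty
            # (|b| / intercept_scaling) is negligible
            est = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (n * lambda_),
                solver="liblinear",
                intercept_scaling=1000.0,
                tol=tol,
                max_iter=max_iter,
                random_state=0,  # liblinear shuffles; pin for reproducibility
            )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                est.fit(Z, yv)
            except ConvergenceWarning as exc:
                raise ConvergenceError(
                    f"optimizer hit iteration cap {max_iter}: {exc}"
                ) from None
        coefs = est.coef_.ravel().copy()
        icpt = float(est.intercept_[0])
    return FittedModel(
        intercept=icpt,
        coefficients=coefs,
        lambda_=float(lambda_),
        center=center,
        scale=scale,
        axis=axis,
        training_manifest=_manifest(
            cell_ids, seed, {"n": int(n), "lambda": float(lambda_)}
        ),
    )


def predict_proba(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Probability of Treg for each row of X (aligned to the model's axis)."""
    s = model.decision_scores(X)
    return 1.0 / (1.0 + np.exp(-s))


# ---------------------------------------------------------------------------
# splitting / model selection

def stratified_split(
    labels: Sequence, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified disjoint (train_idx, test_idx) positions.

    Per class, round(test_fraction * n_class) cells go to test, so the class
    proportions are preserved within one cell per class.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    arr = np.asarray(labels)
    classes = pd.unique(pd.Series(arr))
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    test_parts = []
    for cls in sorted(classes, key=str):
        idx = np.flatnonzero(arr == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 cells")
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        perm = rng.permutation(idx)
        test_parts.append(perm[:n_test])
    test_idx = np.sort(np.concatenate(test_parts))
    mask = np.ones(arr.size, dtype=bool)
    mask[test_idx] = False
    return np.flatnonzero(mask), test_idx


DEFAULT_LAMBDA_GRID = (0.001, 0.003, 0.01, 0.03, 0.1)


def select_lambda_cv(
    X: np.ndarray,
    y: Sequence,
    folds: int = 5,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    *,
    tol: float = 1e-6,
) -> float:
    """Pick the penalty by out-of-fold AUC with a one-standard-error rule.

    The selected lambda is the largest grid member whose mean out-of-fold
    AUC is within one standard error of the best mean — the conventional
    sparse tie-break; with zero spread this reduces to "max mean AUC, ties
    to the larger lambda".
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    grid = sorted(float(v) for v in lambda_grid)
    if not grid:
        raise ValueError("lambda grid is empty")
    if any(v < 0 for v in grid):
        raise ValueError("lambda grid values must be >= 0")
    X = np.asarray(X, dtype=float)
    yv = encode_labels(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, yv))
    fold_aucs = []
    for lam in grid:
        aucs = []
        for tr, te in splits:
            m = fit_lasso_logistic(X[tr], yv[tr], lam, tol=tol)
            p = predict_proba(m, X[te])
            if len(np.unique(yv[te])) < 2:
                continue
            aucs.append(roc_and_auc(p, yv[te])["auc"])
        fold_aucs.append(np.asarray(aucs))
    mean_auc = [a.mean() for a in fold_aucs]
    best = int(np.argmax(mean_auc))
    se = (
        fold_aucs[best].std(ddof=1) / np.sqrt(len(fold_aucs[best]))
        if len(fold_aucs[best]) > 1
        else 0.0
    )
    for i in range(len(grid) - 1, -1, -1):  # sparsest within one SE
        if mean_auc[i] >= mean_auc[best] - se - 1e-12:
            return grid[i]
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# evaluation

def roc_and_auc(scores: Sequence[float], labels: Sequence) -> dict:
    """ROC by threshold sweep and trapezoid AUC.

    The AUC equals the pairwise concordance probability with ties counted
    one half; it is computed from integer cumulative counts so the identity
    is exact.
    """
    s = np.asarray(scores, dtype=float)
    yv = encode_labels(labels)
    n_pos = int(yv.sum())
    n_neg = int(yv.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = yv[order]
    # cumulative counts at each distinct threshold
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tp = np.r_[0, tp]
    fp = np.r_[0, fp]
    area2 = np.sum((fp[1:] - fp[:-1]) * (tp[1:] + tp[:-1]))  # 2*area in counts
    auc = float(area2) / (2.0 * n_pos * n_neg)
    return {
        "fpr": (fp / n_neg).tolist(),
        "tpr": (tp / n_pos).tolist(),
        "auc": auc,
        "n_pos": n_pos,
        "n_neg": n_neg,
    }


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence, threshold: float = 0.5
) -> dict:
    """Confusion counts and accuracy at a probability threshold.

    Ties (score == threshold) are assigned to Treg.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty input")
    yv = encode_labels(labels)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (yv == 1)).sum())
    tn = int(((pred == 0) & (yv == 0)).sum())
    fp = int(((pred == 1) & (yv == 0)).sum())
    fn = int(((pred == 0) & (yv == 1)).sum())
    return {
        "threshold": float(threshold),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / s.size,
    }


def evaluate(
    scores: Sequence[float], labels: Sequence, threshold: float = 0.5
) -> dict:
    """Full evaluation fragment: ROC points, AUC, confusion, accuracy."""
    out = roc_and_auc(scores, labels)
    out.update(confusion_at_threshold(scores, labels, threshold))
    out["n"] = int(np.asarray(scores).size)
    return out


# ---------------------------------------------------------------------------
# band annotation

def annotate_bands(
    model: FittedModel,
    table: BandAssignmentTable,
    min_coefficient: float = 0.0,
) -> dict:
    """Match separation-vector features to a band-assignment table.

    For each table entry, the extremal (largest |value|) coefficient within
    the tolerance window is reported, with whether its sign agrees with the
    expected one.  Coefficients below ``min_coefficient`` in absolute value
    do not count as matches.
    """
    if model.axis is None:
        raise ValueError("model carries no axis; cannot annotate bands")
    records = []
    for _, row in table.entries.iterrows():
        lo = row["center_cm1"] - row["tol_cm1"]
        hi = row["center_cm1"] + row["tol_cm1"]
        window = np.flatnonzero((model.axis >= lo) & (model.axis <= hi))
        rec = {
            "center_cm1": float(row["center_cm1"]),
            "assignment": row["assignment"],
            "expected_sign": row["sign"],
            "matched": False,
            "channel_cm1": None,
            "coefficient": None,
            "sign_agrees": None,
        }
        if window.size:
            coefs = model.coefficients[window]
            j = int(np.argmax(np.abs(coefs)))
            if abs(coefs[j]) >= max(min_coefficient, np.finfo(float).tiny):
                expected = 1.0 if row["sign"] == "positive" else -1.0
                rec.update(
                    matched=True,
                    channel_cm1=float(model.axis[window[j]]),
                    coefficient=float(coefs[j]),
                    sign_agrees=bool(np.sign(coefs[j]) == expected),
                )
        records.append(rec)
    return {
        "bands": records,
        "n_nonzero": model.n_nonzero,
        "n_channels": int(model.coefficients.size),
    }
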