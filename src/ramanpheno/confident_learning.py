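"""Detection and pruning of mislabeled (sort-impurity) cells.

Pipeline: out-of-fold class probabilities from the sparse logistic
classifier, per-class self-confidence thresholds, a confident joint of
(given label, inferred true label) counts, and ranked removal of the cells
most confidently carrying the wrong label.  Cells are removed, never
relabeled; FrIII-sorted cells are never pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .classifier import encode_labels, fit_lasso_logistic, predict_proba
from .spectra_io import SpectrumSet

CLASSES = ("Tconv", "Treg")  # column order of probability matrices


@dataclass
class OOFResult:
    """Out-of-fold probabilities plus per-fold training manifests."""

    probs: np.ndarray            # n x 2, columns (Tconv, Treg)
    fold_of_cell: np.ndarray     # which fold each cell was held out in
    manifests: list = field(default_factory=list)


@dataclass
class PruningReport:
    oof_probs: np.ndarray
    class_thresholds: dict
    confident_joint: np.ndarray          # 2x2 counts, rows = sorted label
    estimated_noise_rates: np.ndarray    # rows sum to 1
    removed_ids: list
    removed_fraction: float
    removed_fraction_by_class: dict
    method: str = "by_noise_rate"
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "class_thresholds": {
                k: float(v) for k, v in self.class_thresholds.items()
            },
            "confident_joint": self.confident_joint.tolist(),
            "estimated_noise_rates": self.estimated_noise_rates.tolist(),
            "n_removed": len(self.removed_ids),
            "removed_fraction": float(self.removed_fraction),
            "removed_fraction_by_class": {
                k: float(v)
                for k, v in self.removed_fraction_by_class.items()
            },
            "method": self.method,
            "seed": self.seed,
            "removed_ids": list(self.removed_ids),
        }


def out_of_fold_probs(
    X: np.ndarray,
    labels: Sequence,
    folds: int = 5,
    lambda_: float = 0.001,
    seed: int = 0,
    *,
    tol: float = 1e-6,
) -> OOFResult:
    """Class probabilities for every cell from a model it never trained.

    Stratified K folds; each fold's held-out cells are scored by a model fit
    on the remaining folds at penalty ``lambda_``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    yv = encode_labels(labels)
    n = yv.size
    folds = min(folds, n)
    probs = np.full((n, 2), np.nan)
    fold_of = np.full(n, -1, dtype=int)
    manifests = []
    min_class = min(int((yv == 0).sum()), int((yv == 1).sum()))
    if folds <= min_class:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:  # leave-one-out style folding cannot be stratified
        skf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(skf.split(X, yv)):
        m = fit_lasso_logistic(
            X[tr], yv[tr], lambda_, tol=tol, cell_ids=tr.tolist(), seed=seed
        )
        p_treg = predict_proba(m, X[te])
        probs[te, 1] = p_treg
        probs[te, 0] = 1.0 - p_treg
        fold_of[te] = k
        manifests.append(m.training_manifest)
    assert not np.isnan(probs).any()
    return OOFResult(probs=probs, fold_of_cell=fold_of, manifests=manifests)


def class_thresholds(oof_probs: np.ndarray, labels: Sequence) -> dict:
    """Per-class mean self-confidence of the cells carrying that label."""
    yv = encode_labels(labels)
    out = {}
    for c, name in enumerate(CLASSES):
        members = yv == c
        if not members.any():
            raise ValueError(f"class {name} is empty")
        out[name] = float(oof_probs[members, c].mean())
    return out


def confident_joint(
    oof_probs: np.ndarray, labels: Sequence, thresholds: dict
) -> np.ndarray:
    """2x2 counts of (sorted label, confidently inferred true label).

    A cell counts for inferred class t when its probability of t reaches
    threshold_t; if it clears both thresholds it goes to the higher
    probability; if neither, it is uncounted.
    """
    yv = encode_labels(labels)
    thr = np.array([thresholds[c] for c in CLASSES])
    above = oof_probs >= thr[None, :]
    joint = np.zeros((2, 2), dtype=int)
    both = above.all(axis=1)
    none = ~above.any(axis=1)
    inferred = np.where(both, np.argmax(oof_probs, axis=1),
                        np.argmax(above, axis=1))
    for i in range(yv.size):
        if none[i]:
            continue
        joint[yv[i], inferred[i]] += 1
    return joint


def estimate_noise_rates(joint: np.ndarray) -> np.ndarray:
    """Row-normalized confident joint: P(inferred true = t | sorted = s)."""
    joint = np.asarray(joint, dtype=float)
    sums = joint.sum(axis=1, keepdims=True)
    sums = np.where(sums == 0, 1.0, sums)
    return joint / sums


def prune(
    oof_probs: np.ndarray,
    labels: Sequence,
    joint: np.ndarray,
    method: str = "by_noise_rate",
    cell_ids: Sequence | None = None,
    *,
    thresholds: dict | None = None,
    seed: int | None = None,
) -> PruningReport:
    """Rank and remove the cells most confidently mislabeled.

    by_noise_rate (default): for each off-diagonal joint entry (s, t) with
    count k, remove the k cells labeled s with the largest margin
    p(t) - p(s).  by_class: per class s, remove the total off-diagonal row
    mass, lowest self-confidence first.
    """
    yv = encode_labels(labels)
    n = yv.size
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids = np.asarray(cell_ids, dtype=object)
    joint = np.asarray(joint)
    remove = np.zeros(n, dtype=bool)
    if method == "by_noise_rate":
        for s in range(2):
            t = 1 - s
            k = int(joint[s, t])
            if k == 0:
                continue
            members = np.flatnonzero(yv == s)
            margin = oof_probs[members, t] - oof_probs[members, s]
            top = members[np.argsort(-margin, kind="stable")[:k]]
            remove[top] = True
    elif method == "by_class":
        for s in range(2):
            k = int(joint[s, 1 - s])
            if k == 0:
                continue
            members = np.flatnonzero(yv == s)
            conf = oof_probs[members, s]
            low = members[np.argsort(conf, kind="stable")[:k]]
            remove[low] = True
    else:
        raise ValueError(f"unknown pruning method {method!r}")
    by_class = {}
    for c, name in enumerate(CLASSES):
        members = yv == c
        by_class[name] = (
            float(remove[members].mean()) if members.any() else 0.0
        )
    if thresholds is None:
        thresholds = class_thresholds(oof_probs, labels)
    return PruningReport(
        oof_probs=oof_probs,
        class_thresholds=thresholds,
        confident_joint=np.asarray(joint, dtype=int),
        estimated_noise_rates=estimate_noise_rates(joint),
        removed_ids=list(cell_ids[remove]),
        removed_fraction=float(remove.mean()),
        removed_fraction_by_class=by_class,
        method=method,
        seed=seed,
    )


def prune_mislabeled(
    sset: SpectrumSet,
    folds: int = 5,
    lambda_: float = 0.001,
    method: str = "by_noise_rate",
    seed: int = 0,
    label_source: str = "sorted",
    *,
    tol: float = 1e-6,
) -> tuple[SpectrumSet, PruningReport]:
    """End-to-end pruning of a SpectrumSet.

    Only Tconv/Treg-sorted cells are eligible; FrIII cells (and any cell
    with another label) pass through untouched.  Removed cells get
    qc_flag='pruned' in the report's id list and are dropped from the
    returned set.
    """
    lab = sset.labels(label_source)
    eligible = np.isin(lab, CLASSES)
    sub = sset.select(eligible)
    oof = out_of_fold_probs(
        sub.intensities, sub.labels(label_source), folds, lambda_, seed,
        tol=tol,
    )
    thr = class_thresholds(oof.probs, sub.labels(label_source))
    joint = confident_joint(oof.probs, sub.labels(label_source), thr)
    report = prune(
        oof.probs,
        sub.labels(label_source),
        joint,
        method=method,
        cell_ids=sub.cell_ids,
        thresholds=thr,
        seed=seed,
    )
    removed = set(report.removed_ids)
    keep_mask = np.array(
        [cid not in removed for cid in sset.cell_ids], dtype=bool
    )
    pruned_set = sset.select(keep_mask)
    return pruned_set, report
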