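"""End-to-end study orchestration.

Five studies, each consuming a SpectrumSet (synthetic or real-shaped) and
emitting a JSON-serializable report: random-split classification, pruned
(label-noise-cleaned) classification, mixture scoring of the FrIII pool,
donor holdout, and the naive-vs-full subpopulation comparison.

Every study audits that no cell id appears on both sides of a
train/evaluation boundary, and every number in a report is re-derivable
from the echoed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import classifier as clf
from .classifier import FittedModel
from .confident_learning import CLASSES, prune_mislabeled
from .errors import LeakageError
from .spectra_io import SpectrumSet

STUDY_KINDS = (
    "random_split", "pruned", "mixture_scoring", "donor_holdout",
    "subpopulation",
)


@dataclass
class StudyConfig:
    study_kind: str = "random_split"
    test_fraction: float = 0.2
    threshold: float = 0.5
    mixture_low: float = 0.10
    mixture_high: float = 0.90
    holdout_donor: str | None = None
    seed: int = 0
    #: "auto" selects lambda by out-of-fold AUC on the training pool.
    lambda_: float | str = "auto"
    lambda_grid: Sequence[float] = clf.DEFAULT_LAMBDA_GRID
    cv_folds: int = 5
    cl_folds: int = 5
    cl_lambda: float = 0.001
    cl_method: str = "by_noise_rate"
    label_source: str = "sorted"
    optimizer_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.study_kind not in STUDY_KINDS:
            raise ValueError(f"unknown study kind {self.study_kind!r}")
        if not (0.0 < self.mixture_low < self.mixture_high < 1.0):
            raise ValueError("need 0 < mixture_low < mixture_high < 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda_grid"] = [float(v) for v in d["lambda_grid"]]
        return d


@dataclass
class StudyReport:
    kind: str
    config: dict
    results: dict
    manifest: dict
    models: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "config": self.config,
            "results": self.results,
            "manifest": self.manifest,
        }


def stage_seed(seed: int, stage: int) -> int:
    """Deterministically fork a per-stage seed from the study master seed."""
    return int(
        np.random.SeedSequence([int(seed), int(stage)]).generate_state(1)[0]
        % (2**31 - 1)
    )


def _labeled_subset(sset: SpectrumSet, label_source: str) -> SpectrumSet:
    lab = sset.labels(label_source)
    return sset.select(np.isin(lab, CLASSES))


def _audit_disjoint(train_ids: Sequence, eval_ids: Sequence) -> None:
    overlap = set(train_ids) & set(eval_ids)
    if overlap:
        raise LeakageError(
            f"{len(overlap)} cell(s) appear in both train and evaluation "
            f"sets, e.g. {sorted(overlap)[:3]}"
        )


def _choose_lambda(
    X: np.ndarray, y: np.ndarray, config: StudyConfig, seed: int
) -> float:
    if config.lambda_ == "auto":
        return clf.select_lambda_cv(
            X, y, folds=config.cv_folds, lambda_grid=config.lambda_grid,
            seed=seed, tol=config.optimizer_tol,
        )
    return float(config.lambda_)


def _fit_and_evaluate(
    sub: SpectrumSet,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: StudyConfig,
    seed: int,
) -> tuple[FittedModel, dict, dict]:
    y = clf.encode_labels(sub.labels(config.label_source))
    Xtr, Xte = sub.intensities[train_idx], sub.intensities[test_idx]
    lam = _choose_lambda(Xtr, y[train_idx], config, seed)
    ids = np.asarray(sub.cell_ids, dtype=object)
    model = clf.fit_lasso_logistic(
        Xtr, y[train_idx], lam, axis=sub.axis, tol=config.optimizer_tol,
        cell_ids=ids[train_idx].tolist(), seed=seed,
    )
    ev_train = clf.evaluate(
        clf.predict_proba(model, Xtr), y[train_idx], config.threshold
    )
    ev_test = clf.evaluate(
        clf.predict_proba(model, Xte), y[test_idx], config.threshold
    )
    return model, ev_train, ev_test


# ---------------------------------------------------------------------------
# studies

def run_random_split_study(
    sset: SpectrumSet, config: StudyConfig
) -> StudyReport:
    """Stratified 80/20 (by default) split, fit on train, report both splits."""
    sub = _labeled_subset(sset, config.label_source)
    labels = sub.labels(config.label_source)
    split_seed = stage_seed(config.seed, 0)
    train_idx, test_idx = clf.stratified_split(
        labels, config.test_fraction, split_seed
    )
    model, ev_train, ev_test = _fit_and_evaluate(
        sub, train_idx, test_idx, config, stage_seed(config.seed, 1)
    )
    ids = np.asarray(sub.cell_ids, dtype=object)
    train_ids, test_ids = ids[train_idx].tolist(), ids[test_idx].tolist()
    _audit_disjoint(train_ids, test_ids)
    return StudyReport(
        kind="random_split",
        config=config.to_dict(),
        results={
            "lambda": model.lambda_,
            "n_nonzero_coefficients": model.n_nonzero,
            "train": ev_train,
            "test": ev_test,
        },
        manifest={
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "train_ids": train_ids,
            "test_ids": test_ids,
        },
        models={"model": model},
    )


def run_pruned_study(sset: SpectrumSet, config: StudyConfig) -> StudyReport:
    """Confident-learning pruning, then a random-split study on pruned cells.

    The unpruned random-split study on the same pool is run alongside for
    comparison.  FrIII-sorted cells are never pruned nor trained on.
    """
    sub = _labeled_subset(sset, "sorted")
    n_frIII = int((sset.labels("sorted") == "FrIII").sum())
    pruned_set, prune_report = prune_mislabeled(
        sub,
        folds=config.cl_folds,
        lambda_=config.cl_lambda,
        method=config.cl_method,
        seed=stage_seed(config.seed, 10),
        label_source="sorted",
        tol=config.optimizer_tol,
    )
    unpruned = run_random_split_study(sub, config)
    pruned = run_random_split_study(pruned_set, config)
    return StudyReport(
        kind="pruned",
        config=config.to_dict(),
        results={
            "pruning": prune_report.to_dict(),
            "unpruned": unpruned.results,
            "pruned": pruned.results,
        },
        manifest={
            "n_labeled_pool": sub.n_cells,
            "n_after_pruning": pruned_set.n_cells,
            "n_frIII_excluded": n_frIII,
            "unpruned": unpruned.manifest,
            "pruned": pruned.manifest,
        },
        models={
            "unpruned": unpruned.models["model"],
            "pruned": pruned.models["model"],
        },
    )


def score_mixture_fraction(
    model: FittedModel, sset: SpectrumSet, config: StudyConfig
) -> dict:
    """Per-donor tail fractions of the Treg probability on an FrIII pool.

    Reports, per donor, the fraction of cells below ``mixture_low`` and
    above ``mixture_high``, plus the derived point estimate
    high / (high + low) of the pool's Treg fraction, and the planted
    fraction when ground-truth labels are present.
    """
    frIII = sset.select(sset.labels("sorted") == "FrIII")
    if frIII.n_cells == 0:
        raise ValueError("no FrIII-sorted cells in the input set")
    trained_on = set(model.training_manifest.get("cell_ids") or [])
    overlap = trained_on & set(frIII.cell_ids)
    if overlap:
        raise LeakageError(
            f"model was trained on {len(overlap)} FrIII cell(s)"
        )
    probs = clf.predict_proba(model, frIII.intensities)
    per_donor = {}
    for donor in sorted(frIII.meta["donor_id"].unique()):
        mask = (frIII.meta["donor_id"] == donor).to_numpy()
        p = probs[mask]
        lo = float((p < config.mixture_low).mean())
        hi = float((p > config.mixture_high).mean())
        est = hi / (hi + lo) if (hi + lo) > 0 else None
        rec = {
            "n_cells": int(mask.sum()),
            "fraction_below_low": lo,
            "fraction_above_high": hi,
            "treg_fraction_estimate": est,
        }
        true = frIII.meta.loc[mask, "true_label"].to_numpy()
        if (true != "unknown").all():
            rec["planted_treg_fraction"] = float((true == "Treg").mean())
        per_donor[donor] = rec
    return {
        "cutoffs": {"low": config.mixture_low, "high": config.mixture_high},
        "n_frIII": frIII.n_cells,
        "per_donor": per_donor,
    }


def run_mixture_study(sset: SpectrumSet, config: StudyConfig) -> StudyReport:
    """Pruned-model training on sorted cells, then FrIII mixture scoring."""
    pruned = run_pruned_study(sset, config)
    model = pruned.models["pruned"]
    mixture = score_mixture_fraction(model, sset, config)
    return StudyReport(
        kind="mixture_scoring",
        config=config.to_dict(),
        results={"pruned_study": pruned.results, "mixture": mixture},
        manifest=pruned.manifest,
        models=pruned.models,
    )


def run_donor_holdout(sset: SpectrumSet, config: StudyConfig) -> StudyReport:
    """Train (with pruning) on all donors but one; test on every holdout cell.

    Holdout-donor cells are never pruned: a deployed model cannot prune
    unseen data.
    """
    if config.holdout_donor is None:
        raise ValueError("holdout_donor must be set for a donor-holdout study")
    donors = set(sset.meta["donor_id"].unique())
    if config.holdout_donor not in donors:
        raise ValueError(f"unknown donor {config.holdout_donor!r}")
    train_donors = sorted(donors - {config.holdout_donor})
    if len(train_donors) < 2:
        raise ValueError(
            f"need >= 2 training donors, got {len(train_donors)}"
        )
    sub = _labeled_subset(sset, config.label_source)
    is_holdout = (sub.meta["donor_id"] == config.holdout_donor).to_numpy()
    train_pool = sub.select(~is_holdout)
    test_pool = sub.select(is_holdout)
    if test_pool.n_cells == 0:
        raise ValueError("holdout donor has no labeled cells")
    pruned_pool, prune_report = prune_mislabeled(
        train_pool,
        folds=config.cl_folds,
        lambda_=config.cl_lambda,
        method=config.cl_method,
        seed=stage_seed(config.seed, 10),
        label_source=config.label_source,
        tol=config.optimizer_tol,
    )
    y_tr = clf.encode_labels(pruned_pool.labels(config.label_source))
    fit_seed = stage_seed(config.seed, 1)
    lam = _choose_lambda(pruned_pool.intensities, y_tr, config, fit_seed)
    model = clf.fit_lasso_logistic(
        pruned_pool.intensities, y_tr, lam, axis=pruned_pool.axis,
        tol=config.optimizer_tol, cell_ids=pruned_pool.cell_ids,
        seed=fit_seed,
    )
    _audit_disjoint(
        model.training_manifest["cell_ids"], test_pool.cell_ids
    )
    y_te = clf.encode_labels(test_pool.labels(config.label_source))
    ev_train = clf.evaluate(
        clf.predict_proba(model, pruned_pool.intensities), y_tr,
        config.threshold,
    )
    ev_test = clf.evaluate(
        clf.predict_proba(model, test_pool.intensities), y_te,
        config.threshold,
    )
    return StudyReport(
        kind="donor_holdout",
        config=config.to_dict(),
        results={
            "lambda": model.lambda_,
            "pruning": prune_report.to_dict(),
            "train": ev_train,
            "test": ev_test,
        },
        manifest={
            "holdout_donor": config.holdout_donor,
            "train_donors": train_donors,
            "n_train": pruned_pool.n_cells,
            "n_test": test_pool.n_cells,
            "train_ids": pruned_pool.cell_ids,
            "test_ids": test_pool.cell_ids,
        },
        models={"model": model},
    )


def run_subpopulation_comparison(
    sset: SpectrumSet, config: StudyConfig
) -> StudyReport:
    """Naive-only vs full-population training, scored on one common test pool."""
    sub = _labeled_subset(sset, config.label_source)
    subpops = sub.meta["subpop"].to_numpy()
    if not np.isin(subpops, ["naive", "effector"]).any():
        raise ValueError("set carries no naive/effector subpopulation tags")
    labels = sub.labels(config.label_source)
    split_seed = stage_seed(config.seed, 0)
    train_idx, test_idx = clf.stratified_split(
        labels, config.test_fraction, split_seed
    )
    naive_train = train_idx[subpops[train_idx] == "naive"]
    if naive_train.size < 4:
        raise ValueError("too few naive cells to train the naive-only model")
    fit_seed = stage_seed(config.seed, 1)
    y = clf.encode_labels(labels)
    ids = np.asarray(sub.cell_ids, dtype=object)
    reports = {}
    models = {}
    for name, tr_idx in (("naive", naive_train), ("full", train_idx)):
        lam = _choose_lambda(
            sub.intensities[tr_idx], y[tr_idx], config, fit_seed
        )
        model = clf.fit_lasso_logistic(
            sub.intensities[tr_idx], y[tr_idx], lam, axis=sub.axis,
            tol=config.optimizer_tol, cell_ids=ids[tr_idx].tolist(),
            seed=fit_seed,
        )
        _audit_disjoint(ids[tr_idx].tolist(), ids[test_idx].tolist())
        reports[name] = {
            "lambda": model.lambda_,
            "n_train": int(tr_idx.size),
            "train": clf.evaluate(
                clf.predict_proba(model, sub.intensities[tr_idx]),
                y[tr_idx], config.threshold,
            ),
            "test": clf.evaluate(
                clf.predict_proba(model, sub.intensities[test_idx]),
                y[test_idx], config.threshold,
            ),
        }
        models[name] = model
    return StudyReport(
        kind="subpopulation",
        config=config.to_dict(),
        results=reports,
        manifest={
            "n_test": int(test_idx.size),
            "test_ids": ids[test_idx].tolist(),
            "n_naive_train": int(naive_train.size),
            "train_ids": ids[train_idx].tolist(),
        },
        models=models,
    )


def run_study(sset: SpectrumSet, config: StudyConfig) -> StudyReport:
    """Dispatch on ``config.study_kind``."""
    runner = {
        "random_split": run_random_split_study,
        "pruned": run_pruned_study,
        "mixture_scoring": run_mixture_study,
        "donor_holdout": run_donor_holdout,
        "subpopulation": run_subpopulation_comparison,
    }[config.study_kind]
    return runner(sset, config)
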