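"""Pyramided marker-effect prediction model with cross-validated accuracy.

A fitted model stores the pooled training mean plus per-marker genotype-
class effect tables.  A hybrid's genomics-predicted value (GPV) is the
training mean plus the sum of its genotype-class effects over all model
markers; only hybrids with a complete (non-missing) genotype across the
model markers receive a GPV.  Accuracy is the Pearson correlation between
GPV and observed phenotype value (OPV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import GenotypeTable
from .marker_effects import (
    DEFAULT_MIN_CLASS_N,
    MarkerEffect,
    estimate_genotype_effects,
    _opv_by_hybrid,
)

logger = logging.getLogger(__name__)


class AccuracyUndefinedError(ValueError):
    """Pearson accuracy is undefined (constant vector or too few pairs)."""


@dataclass
class GapModel:
    trait: Optional[str]
    overall_mean: float
    effects: dict[str, MarkerEffect]
    training_ids: list[str] = field(default_factory=list)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.effects)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "overall_mean": self.overall_mean,
            "effects": {m: e.to_dict() for m, e in self.effects.items()},
            "training_ids": self.training_ids,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GapModel":
        return cls(
            trait=payload["trait"],
            overall_mean=float(payload["overall_mean"]),
            effects={
                m: MarkerEffect.from_dict(e) for m, e in payload["effects"].items()
            },
            training_ids=list(payload["training_ids"]),
        )


def fit(genotypes: GenotypeTable, phenotypes: pd.DataFrame,
        trait: Optional[str] = None,
        min_class_n: int = DEFAULT_MIN_CLASS_N) -> GapModel:
    """Fit the prediction model: pooled overall mean + per-marker effects."""
    opv = _opv_by_hybrid(phenotypes, trait)
    opv = opv.loc[opv.index.intersection(genotypes.calls.index)]
    if opv.empty:
        raise ValueError("no phenotyped hybrids found in the genotype table")
    if not genotypes.marker_ids:
        return GapModel(trait, float(opv.mean()), {}, sorted(opv.index))
    effect_list = estimate_genotype_effects(
        genotypes, phenotypes, trait=trait, min_class_n=min_class_n
    )
    return GapModel(
        trait=trait,
        overall_mean=float(opv.mean()),
        effects={e.marker_id: e for e in effect_list},
        training_ids=sorted(opv.index),
    )


def predict(model: GapModel, genotypes: GenotypeTable,
            phenotypes: Optional[pd.DataFrame] = None,
            include_incomplete: bool = False) -> pd.DataFrame:
    """Compute GPVs: overall mean plus summed genotype-class effects.

    Returns a frame with columns ``hybrid_id``, ``gpv``, ``opv`` (NaN when
    no phenotype is supplied) and ``complete``.  Hybrids with any missing
    call across the model markers get no GPV and are dropped unless
    ``include_incomplete`` is set.  Genotype classes unseen in training
    contribute 0 with a logged warning.
    """
    missing_markers = [m for m in model.marker_ids if m not in genotypes.calls.columns]
    if missing_markers:
        raise KeyError(
            f"marker(s) absent from genotype table: {missing_markers}"
        )
    calls = genotypes.calls[model.marker_ids] if model.marker_ids else genotypes.calls
    complete = calls.notna().all(axis=1) if model.marker_ids else pd.Series(
        True, index=genotypes.calls.index
    )
    gpv = pd.Series(model.overall_mean, index=genotypes.calls.index, dtype=float)
    for marker in model.marker_ids:
        effect = model.effects[marker]
        lookup = dict(zip(effect.classes, effect.effects))
        column = calls[marker]
        observed = column[column.notna()].astype(str)
        unseen = set(observed.unique()) - set(effect.classes)
        if unseen:
            logger.warning(
                "marker %s: genotype class(es) %s unseen in training; effect 0",
                marker, sorted(unseen),
            )
        gpv.loc[observed.index] += observed.map(lookup).fillna(0.0)
    gpv[~complete] = np.nan

    result = pd.DataFrame(
        {
            "hybrid_id": genotypes.calls.index,
            "gpv": gpv.to_numpy(),
            "opv": np.nan,
            "complete": complete.to_numpy(),
        }
    )
    if phenotypes is not None:
        opv = _opv_by_hybrid(phenotypes, model.trait)
        result["opv"] = result["hybrid_id"].map(opv).to_numpy()
    if not include_incomplete:
        result = result[result["complete"]].reset_index(drop=True)
    return result


def accuracy(predictions: pd.DataFrame) -> float:
    """Pearson r between GPV and OPV over complete, phenotyped hybrids."""
    frame = predictions
    if "complete" in frame.columns:
        frame = frame[frame["complete"]]
    keep = frame["gpv"].notna() & frame["opv"].notna()
    gpv = frame.loc[keep, "gpv"].to_numpy(float)
    opv = frame.loc[keep, "opv"].to_numpy(float)
    if gpv.size < 3:
        raise AccuracyUndefinedError("need >=3 complete (gpv, opv) pairs")
    if np.ptp(gpv) == 0 or np.ptp(opv) == 0:
        raise AccuracyUndefinedError("constant gpv or opv vector")
    return float(stats.pearsonr(gpv, opv).statistic)


def _encode_classes(genotypes: GenotypeTable,
                    hybrid_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray, int]:
    """Integer-code the (complete) calls matrix for the fast CV path.

    Returns codes offset so every (marker, class) pair gets a distinct
    global index, plus the per-marker offsets and the total class count.
    """
    calls = genotypes.calls.loc[list(hybrid_ids)]
    columns = []
    offsets = np.zeros(calls.shape[1], dtype=int)
    running = 0
    for j, marker in enumerate(calls.columns):
        codes_j, uniques = pd.factorize(calls[marker].astype(str), sort=True)
        offsets[j] = running
        columns.append(codes_j + running)
        running += len(uniques)
    codes = np.column_stack(columns) if columns else np.zeros((len(calls), 0), dtype=int)
    return codes, offsets, running


def _fold_gpv(codes: np.ndarray, y: np.ndarray, train_mask: np.ndarray,
              test_mask: np.ndarray, total_classes: int,
              min_class_n: int) -> np.ndarray:
    """GPVs of test hybrids from class-mean deviations fitted on the train set.

    Identical semantics to ``fit`` + ``predict`` on complete-genotype
    hybrids: classes with fewer than ``min_class_n`` training members, and
    classes unseen in training, contribute effect 0.
    """
    n_markers = codes.shape[1]
    train_codes = codes[train_mask]
    y_train = y[train_mask]
    counts = np.bincount(train_codes.ravel(), minlength=total_classes)
    sums = np.bincount(
        train_codes.ravel(),
        weights=np.repeat(y_train, n_markers),
        minlength=total_classes,
    )
    train_mean = float(y_train.mean())
    effects = np.zeros(total_classes)
    ok = counts >= max(1, min_class_n)
    effects[ok] = sums[ok] / counts[ok] - train_mean
    return train_mean + effects[codes[test_mask]].sum(axis=1)


@dataclass
class CvResult:
    k: int
    n_runs: int
    fold_accuracies: list[list[float]]  # one inner list per run
    mean_accuracy: float
    seed: int
    n_hybrids: int
    n_skipped_folds: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (run + 1, fold + 1, acc)
            for run, accs in enumerate(self.fold_accuracies)
            for fold, acc in enumerate(accs)
        ]
        return pd.DataFrame(rows, columns=["run", "fold", "accuracy"])


def cross_validate(genotypes: GenotypeTable, phenotypes: pd.DataFrame,
                   trait: Optional[str] = None, k: int = 5, runs: int = 5,
                   seed: int = 0,
                   min_class_n: int = DEFAULT_MIN_CLASS_N) -> CvResult:
    """Repeated k-fold cross-validation of prediction accuracy.

    Uses only hybrids with a complete genotype across all markers and an
    observed phenotype.  Per run, hybrids are partitioned at random into k
    near-equal folds; each fold is predicted from a model fitted on the
    remaining folds (overall mean re-estimated on training only).  The
    reported mean is the unweighted mean over all fold x run accuracies.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    opv = _opv_by_hybrid(phenotypes, trait)
    complete_ids = [
        h for h in genotypes.complete_hybrids() if h in opv.index
    ]
    n = len(complete_ids)
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} complete hybrids, got {n}")
    rng = np.random.default_rng(seed)
    y = opv.loc[complete_ids].to_numpy(float)
    codes, offsets, total_classes = _encode_classes(genotypes, complete_ids)
    fold_accuracies: list[list[float]] = []
    skipped = 0
    for _run in range(runs):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        run_accs: list[float] = []
        for fold_idx in folds:
            test_mask = np.zeros(n, dtype=bool)
            test_mask[fold_idx] = True
            gpv = _fold_gpv(codes, y, ~test_mask, test_mask, total_classes,
                            min_class_n)
            opv_test = y[test_mask]
            if gpv.size < 3 or np.ptp(gpv) == 0 or np.ptp(opv_test) == 0:
                logger.warning("fold skipped: undefined accuracy")
                skipped += 1
                continue
            run_accs.append(float(stats.pearsonr(gpv, opv_test).statistic))
        fold_accuracies.append(run_accs)
    all_accs = [a for accs in fold_accuracies for a in accs]
    if not all_accs:
        raise AccuracyUndefinedError("every fold had undefined accuracy")
    return CvResult(
        k=k,
        n_runs=runs,
        fold_accuracies=fold_accuracies,
        mean_accuracy=float(np.mean(all_accs)),
        seed=seed,
        n_hybrids=n,
        n_skipped_folds=skipped,
    )
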