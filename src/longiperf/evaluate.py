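"""Repeated cross-validation, diagnostic metrics and rater comparison.

The headline evaluation protocol is repeated stratified two-fold
cross-validation: each iteration draws a fresh stratified split, runs the
full nested pipeline (standardise -> LASSO -> SVM, all inside the training
fold) per fold, and pools held-out predictions into that iteration's error
rate.  Median and mean error across iterations are both reported, along
with pooled confusion counts and each subject's modal held-out prediction
(the per-subject label used for sensitivity/specificity against raters).

Sensitivity and specificity treat progressive disease (PD) as the positive
class versus PsP + SD combined — the clinically relevant dichotomy, where a
false negative is a missed progression.  Model-vs-rater agreement is tested
with McNemar's paired test on discordant correctness counts (exact binomial
below 25 discordant pairs, chi-square with continuity correction above).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import comb
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .classify import BinaryStageClassifier, StepwiseGliomaClassifier
from .io_core import CLASS_LABELS, PERFUSION_SEQUENCES, STRUCTURAL_SEQUENCES, logger

PERFUSION_MAPS = ("ZrBV", "ZrBF")
STRUCTURAL_MAPS = ("T1", "T1Gad", "T2", "FLAIR")

#: Discordant-pair threshold below which the exact McNemar test is used.
MCNEMAR_EXACT_MAX = 25


class MetricError(ValueError):
    """Raised when a diagnostic metric has a zero denominator."""


@dataclass
class CVConfig:
    """Settings for one repeated-CV run."""

    n_iterations: int = 250
    n_folds: int = 2
    feature_set: str = "combined"  # structural | perfusion | combined
    timepoint_set: Sequence[str] | None = None  # e.g. ("TP1", "TP2", "Diff21")
    task: str = "3class"  # 3class | "PD vs rest" | "SD vs rest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.feature_set not in ("structural", "perfusion", "combined"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.task not in ("3class", "PD vs rest", "SD vs rest"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class CVResult:
    """Outcome of one repeated-CV run."""

    iteration_errors: list[float]
    confusion: pd.DataFrame  # pooled counts, rows = truth, cols = predicted
    modal_prediction: pd.Series
    config: CVConfig

    @property
    def median_error(self) -> float:
        return float(np.median(self.iteration_errors))

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.iteration_errors))

    def to_dict(self) -> dict:
        return {
            "feature_set": self.config.feature_set,
            "timepoint_set": list(self.config.timepoint_set)
            if self.config.timepoint_set
            else None,
            "task": self.config.task,
            "n_iterations": self.config.n_iterations,
            "median_error": self.median_error,
            "mean_error": self.mean_error,
            "iteration_errors": [float(e) for e in self.iteration_errors],
            "confusion": {
                t: {p: int(self.confusion.loc[t, p]) for p in self.confusion.columns}
                for t in self.confusion.index
            },
            "modal_prediction": self.modal_prediction.to_dict(),
        }


@dataclass
class McNemarResult:
    b: int  # model correct, rater wrong
    c: int  # model wrong, rater correct
    statistic: float
    p_value: float
    method: str  # "exact" | "chi2_cc"


def select_feature_columns(
    df: pd.DataFrame,
    feature_set: str = "combined",
    timepoint_set: Sequence[str] | None = None,
) -> list[str]:
    """Filter feature columns by modality and region prefix.

    Column names follow ``<region>_<map>_<feature>`` with region ``TP{k}``
    or ``Diff{j}{i}``; perfusion maps are ZrBV/ZrBF, structural maps
    T1/T1Gad/T2/FLAIR.
    """
    if feature_set == "perfusion":
        maps = PERFUSION_MAPS
    elif feature_set == "structural":
        maps = STRUCTURAL_MAPS
    else:
        maps = PERFUSION_MAPS + STRUCTURAL_MAPS
    cols = []
    for c in df.columns:
        parts = c.split("_")
        if len(parts) != 3:
            continue
        region, m, _ = parts
        if m not in maps:
            continue
        if timepoint_set is not None and region not in timepoint_set:
            continue
        cols.append(c)
    return cols


def _collapse_labels(y: pd.Series, task: str) -> pd.Series:
    if task == "3class":
        return y
    positive = task.split(" ")[0]
    return y.where(y == positive, other="rest")


def _default_factory(cfg: CVConfig) -> Callable[[int], object]:
    if cfg.task == "3class":
        return lambda seed: StepwiseGliomaClassifier(random_state=seed)
    return lambda seed: BinaryStageClassifier(random_state=seed)


def repeated_cv(
    X: pd.DataFrame,
    y: pd.Series,
    cfg: CVConfig,
    model_factory: Callable[[int], object] | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV with a fully nested pipeline per fold.

    Each iteration reshuffles the stratified split; the model (including
    standardisation, LASSO penalty and SVM hyperparameters) is refit from
    scratch on each training fold, and held-out predictions from all folds
    pool into that iteration's misclassification fraction.
    """
    cols = select_feature_columns(X, cfg.feature_set, cfg.timepoint_set)
    if not cols:
        raise ValueError(
            f"no feature columns match feature_set={cfg.feature_set!r}, "
            f"timepoint_set={cfg.timepoint_set!r}"
        )
    Xf = X[cols]
    if Xf.isna().any().any():
        raise ValueError("feature table contains missing values for this selection")
    y = _collapse_labels(pd.Series(y, index=X.index), cfg.task)
    label_order = (
        list(CLASS_LABELS) if cfg.task == "3class" else sorted(y.unique())
    )
    counts = y.value_counts()
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} member(s), "
            f"fewer than n_folds={cfg.n_folds}"
        )
    factory = model_factory or _default_factory(cfg)

    yv = y.to_numpy()
    errors: list[float] = []
    pooled = np.zeros((len(label_order), len(label_order)), dtype=int)
    vote = pd.DataFrame(0, index=X.index, columns=label_order)
    lbl_idx = {l: i for i, l in enumerate(label_order)}
    for it in range(cfg.n_iterations):
        it_seed = (cfg.seed * 100003 + it * 7919 + 1) % (2**31)
        skf = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=it_seed
        )
        preds = np.empty(len(y), dtype=object)
        for tr, te in skf.split(Xf, yv):
            model = factory(it_seed)
            model.fit(Xf.iloc[tr], yv[tr])
            preds[te] = model.predict(Xf.iloc[te])
        errors.append(float(np.mean(preds != yv)))
        for t, p in zip(yv, preds):
            pooled[lbl_idx[t], lbl_idx[p]] += 1
        for sid, p in zip(X.index, preds):
            vote.loc[sid, p] += 1
    confusion = pd.DataFrame(pooled, index=label_order, columns=label_order)
    modal = vote.idxmax(axis=1)
    result = CVResult(
        iteration_errors=errors, confusion=confusion, modal_prediction=modal,
        config=cfg,
    )
    logger.info(
        "repeated CV [%s | %s | %s]: median error %.3f, mean error %.3f "
        "(%d iterations, %d features)",
        cfg.feature_set,
        cfg.timepoint_set or "all regions",
        cfg.task,
        result.median_error,
        result.mean_error,
        cfg.n_iterations,
        len(cols),
    )
    return result


def collapse_confusion(cm: pd.DataFrame, positive: str = "PD") -> pd.DataFrame:
    """Collapse a 3x3 confusion table to positive-vs-rest 2x2 counts."""
    if positive not in cm.index:
        raise MetricError(f"positive class {positive!r} not in confusion table")
    others = [c for c in cm.index if c != positive]
    tp = int(cm.loc[positive, positive])
    fn = int(cm.loc[positive, others].sum())
    fp = int(cm.loc[others, positive].sum())
    tn = int(cm.loc[others, others].to_numpy().sum())
    return pd.DataFrame(
        [[tp, fn], [fp, tn]],
        index=[positive, "rest"],
        columns=[positive, "rest"],
    )


def binary_metrics(cm: pd.DataFrame, positive: str = "PD") -> dict[str, float]:
    """Sensitivity, specificity and accuracy (percent, 2 decimals).

    A 3x3 input is collapsed to positive-vs-rest first.  A zero denominator
    raises :class:`MetricError` naming the metric.
    """
    if cm.shape == (3, 3):
        cm = collapse_confusion(cm, positive)
    tp, fn = int(cm.iloc[0, 0]), int(cm.iloc[0, 1])
    fp, tn = int(cm.iloc[1, 0]), int(cm.iloc[1, 1])
    total = tp + fn + fp + tn
    if total == 0:
        raise MetricError("empty confusion table")
    if tp + fn == 0:
        raise MetricError("sensitivity undefined: no positive cases")
    if tn + fp == 0:
        raise MetricError("specificity undefined: no negative cases")
    return {
        "sensitivity": round(100.0 * tp / (tp + fn), 2),
        "specificity": round(100.0 * tn / (tn + fp), 2),
        "accuracy": round(100.0 * (tp + tn) / total, 2),
    }


def confusion_from_labels(
    truth: Sequence[str], predicted: Sequence[str], labels=CLASS_LABELS
) -> pd.DataFrame:
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("label lists differ in length")
    cm = pd.DataFrame(0, index=list(labels), columns=list(labels))
    for t, p in zip(truth, predicted):
        cm.loc[t, p] += 1
    return cm


def mcnemar(
    model_labels: Sequence[str],
    rater_labels: Sequence[str],
    truth_labels: Sequence[str],
) -> McNemarResult:
    """McNemar's paired test on per-case correctness of model vs rater.

    b counts cases the model got right and the rater wrong; c the reverse.
    For b + c below 25 the exact two-sided binomial tail is used,
    p = min(1, 2 * sum_{k >= max(b, c)} C(b+c, k) / 2^(b+c)); otherwise the
    chi-square statistic with continuity correction, (|b-c|-1)^2 / (b+c).
    """
    model_labels, rater_labels, truth_labels = (
        list(model_labels),
        list(rater_labels),
        list(truth_labels),
    )
    if not (len(model_labels) == len(rater_labels) == len(truth_labels)):
        raise ValueError("model, rater and truth label lists differ in length")
    model_ok = np.array([m == t for m, t in zip(model_labels, truth_labels)])
    rater_ok = np.array([r == t for r, t in zip(rater_labels, truth_labels)])
    b = int((model_ok & ~rater_ok).sum())
    c = int((~model_ok & rater_ok).sum())
    n = b + c
    if n == 0:
        return McNemarResult(b=0, c=0, statistic=0.0, p_value=1.0, method="exact")
    if n < MCNEMAR_EXACT_MAX:
        k0 = max(b, c)
        tail = sum(comb(n, k) for k in range(k0, n + 1)) / 2**n
        p = min(1.0, 2.0 * tail)
        return McNemarResult(b=b, c=c, statistic=float(k0), p_value=p, method="exact")
    stat = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(b=b, c=c, statistic=float(stat), p_value=p, method="chi2_cc")


DEFAULT_FEATURE_SETS = ("structural", "perfusion", "combined")


def default_timepoint_sets(n_time_points: int = 2) -> dict[str, tuple[str, ...] | None]:
    sets: dict[str, tuple[str, ...] | None] = {"TP1": ("TP1",)}
    if n_time_points >= 2:
        sets["TP1+TP2+Diff21"] = ("TP1", "TP2", "Diff21")
    if n_time_points >= 3:
        sets["all"] = None
    return sets


def run_comparison_suite(
    feature_table: pd.DataFrame,
    cfg: CVConfig | None = None,
    feature_sets: Sequence[str] = DEFAULT_FEATURE_SETS,
    timepoint_sets: Mapping[str, Sequence[str] | None] | None = None,
    model_factory: Callable[[int], object] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run repeated CV over feature-set x time-point combinations.

    ``feature_table`` is the cohort table from
    :func:`longiperf.radiomics.extract_cohort_features` (``class_label`` and
    ``rater_label`` columns plus features).  The report includes, for the
    combined-features run on the richest time-point set, per-subject modal
    predictions, diagnostic metrics against truth for both model and rater,
    and the McNemar comparison.  Optionally writes ``report.json``, a
    per-iteration error-rate CSV and a box plot.
    """
    cfg = cfg or CVConfig(n_iterations=50)
    y = feature_table["class_label"]
    rater = feature_table.get("rater_label")
    X = feature_table.drop(
        columns=[c for c in ("class_label", "rater_label") if c in feature_table]
    )
    if timepoint_sets is None:
        has_tp2 = any(c.startswith("TP2_") for c in X.columns)
        timepoint_sets = default_timepoint_sets(2 if has_tp2 else 1)

    results: dict[str, CVResult] = {}
    for fs in feature_sets:
        for tps_name, tps in timepoint_sets.items():
            run_cfg = replace(cfg, feature_set=fs, timepoint_set=tps)
            results[f"{fs}|{tps_name}"] = repeated_cv(
                X, y, run_cfg, model_factory=model_factory
            )

    richest = list(timepoint_sets)[-1]
    key = f"combined|{richest}"
    report: dict = {
        "runs": {k: r.to_dict() for k, r in results.items()},
        "primary_run": key,
    }
    primary = results[key]
    model_labels = [primary.modal_prediction[s] for s in feature_table.index]
    truth_labels = list(y)
    model_cm = confusion_from_labels(truth_labels, model_labels)
    report["model_metrics"] = binary_metrics(model_cm, positive="PD")
    report["model_metrics"]["accuracy_3class"] = round(
        100.0 * float(np.mean(np.array(model_labels) == np.array(truth_labels))), 2
    )
    if rater is not None and rater.notna().all():
        rater_labels = list(rater)
        rater_cm = confusion_from_labels(truth_labels, rater_labels)
        report["rater_metrics"] = binary_metrics(rater_cm, positive="PD")
        report["rater_metrics"]["accuracy_3class"] = round(
            100.0 * float(np.mean(np.array(rater_labels) == np.array(truth_labels))), 2
        )
        mc = mcnemar(model_labels, rater_labels, truth_labels)
        report["mcnemar_model_vs_rater"] = {
            "b": mc.b, "c": mc.c, "statistic": mc.statistic,
            "p_value": mc.p_value, "method": mc.method,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
        err_df = pd.DataFrame(
            {k: r.iteration_errors for k, r in results.items()}
        )
        err_df.to_csv(out_dir / "iteration_errors.csv", index=False)
        _error_boxplot(results, out_dir / "error_rates.svg")
    return report


def _error_boxplot(results: Mapping[str, CVResult], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.4 * len(results) + 2, 4))
    keys = list(results)
    ax.boxplot(
        [np.asarray(results[k].iteration_errors) * 100 for k in keys],
        tick_labels=keys,
    )
    ax.set_ylabel("held-out error rate (%)")
    ax.set_title("Repeated 2-fold CV error by feature set / time points")
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
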