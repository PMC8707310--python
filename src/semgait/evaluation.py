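"""Experiment drivers: per-condition accuracy, cross-load-style matrices,
and mixed-load-style training combinations.

The common protocol is a random 60/20/20 train/validation/test split,
stratified by gait phase.  Each evaluation reports the five per-phase
accuracies (recall per phase on the test windows) and their mean — the
"average recognition accuracy" of a trial — plus the 5×5 confusion matrix
and the full prediction log, so every summary can be recomputed from raw
predictions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .core import AnalysisWindow, ConfigurationError, N_PHASES

DEFAULT_RATIOS: tuple[float, float, float] = (0.6, 0.2, 0.2)


@dataclass(frozen=True)
class ExperimentSplit:
    """Disjoint train / validation / test window indices."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ConfigurationError("split sets must be disjoint")


def split_dataset(
    labels: np.ndarray,
    ratios: tuple[float, float, float] = DEFAULT_RATIOS,
    seed: int = 0,
    stratify: bool = True,
) -> ExperimentSplit:
    """Random (stratified) 60/20/20 split over window indices.

    Falls back to an unstratified split, with a warning, when some phase has
    fewer than 3 windows.  Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < 5:
        raise ConfigurationError("need at least 5 windows to split 60/20/20")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError("split ratios must sum to 1")
    strat: np.ndarray | None = labels if stratify else None
    if strat is not None:
        counts = np.bincount(labels)
        if counts[counts > 0].min() < 3:
            warnings.warn("a phase has fewer than 3 windows; falling back to unstratified split")
            strat = None

    idx = np.arange(n)
    rest, test = train_test_split(
        idx, test_size=ratios[2], random_state=seed,
        stratify=strat if strat is not None else None,
    )
    val_frac = ratios[1] / (ratios[0] + ratios[1])
    strat_rest = labels[rest] if strat is not None else None
    train, val = train_test_split(
        rest, test_size=val_frac, random_state=seed, stratify=strat_rest
    )
    return ExperimentSplit(np.sort(train), np.sort(val), np.sort(test), seed=seed)


@dataclass
class EvaluationReport:
    """Per-phase and average accuracy of one train/test evaluation."""

    per_phase_pct: np.ndarray          # 5 values, NaN for empty test phases
    average_pct: float
    confusion: np.ndarray              # 5×5 counts, rows = true phase
    n_train: int
    n_test: int
    predictions: np.ndarray            # (n_test, 3): window index, true, predicted
    condition: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_phase_pct": [None if np.isnan(v) else round(float(v), 4)
                              for v in self.per_phase_pct],
            "average_pct": round(float(self.average_pct), 4),
            "confusion": self.confusion.tolist(),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "condition": self.condition,
        }


def score_report(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    test_idx: np.ndarray | None = None,
    n_train: int = 0,
    condition: dict | None = None,
) -> EvaluationReport:
    """Build a report from raw predictions (the single scoring path)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = confusion_matrix(y_true, y_pred, labels=list(range(N_PHASES)))
    row = cm.sum(axis=1)
    per_phase = np.full(N_PHASES, np.nan)
    present = row > 0
    per_phase[present] = 100.0 * np.diag(cm)[present] / row[present]
    if not present.all():
        warnings.warn("some phases absent from the test set; excluded from the average")
    average = float(np.nanmean(per_phase))
    if test_idx is None:
        test_idx = np.arange(y_true.shape[0])
    preds = np.column_stack([test_idx, y_true, y_pred])
    return EvaluationReport(per_phase, average, cm, n_train, y_true.shape[0],
                            preds, condition or {})


def evaluate_condition(
    classifier,
    windows: list[AnalysisWindow],
    labels: np.ndarray | None = None,
    seed: int = 0,
    split: ExperimentSplit | None = None,
    condition: dict | None = None,
) -> EvaluationReport:
    """60/20/20 split, train, and score on held-out test windows."""
    labels = np.asarray(labels if labels is not None
                        else [w.label for w in windows], dtype=int)
    if split is None:
        split = split_dataset(labels, seed=seed)
    tr, va, te = split.train_idx, split.val_idx, split.test_idx
    classifier.fit([windows[i] for i in tr], labels[tr],
                   [windows[i] for i in va], labels[va])
    y_pred = np.asarray(classifier.predict([windows[i] for i in te]), dtype=int)
    return score_report(labels[te], y_pred, te, len(tr), condition)


@dataclass
class CrossStyleMatrix:
    """3×3 accuracies (training style × testing style) at one speed."""

    styles: tuple[str, ...]
    matrix_pct: np.ndarray   # (3, 3)
    speed_kmh: int | None = None
    reports: dict = field(default_factory=dict)

    @property
    def intra_pct(self) -> float:
        return float(np.mean(np.diag(self.matrix_pct)))

    @property
    def inter_pct(self) -> float:
        off = self.matrix_pct[~np.eye(len(self.styles), dtype=bool)]
        return float(np.mean(off))

    @property
    def overall_pct(self) -> float:
        return float(np.mean(self.matrix_pct))

    def to_dict(self) -> dict:
        return {
            "styles": list(self.styles),
            "matrix_pct": np.round(self.matrix_pct, 4).tolist(),
            "intra_pct": round(self.intra_pct, 4),
            "inter_pct": round(self.inter_pct, 4),
            "overall_pct": round(self.overall_pct, 4),
            "speed_kmh": self.speed_kmh,
        }


def cross_style_experiment(
    classifier_factory,
    windows_by_style: dict[str, list[AnalysisWindow]],
    seed: int = 0,
    speed_kmh: int | None = None,
) -> CrossStyleMatrix:
    """Train per load style, test on every style at the same speed.

    Diagonal entries score the training style's held-out test split; an
    off-diagonal entry scores the *full* window set of the foreign style
    (none of which was trained on).
    """
    styles = tuple(windows_by_style)
    if len(styles) < 2:
        raise ConfigurationError("cross-style experiment needs all load styles")
    labels = {s: np.array([w.label for w in ws], dtype=int)
              for s, ws in windows_by_style.items()}
    splits = {s: split_dataset(labels[s], seed=seed + i)
              for i, s in enumerate(styles)}

    matrix = np.zeros((len(styles), len(styles)))
    reports = {}
    for i, s_train in enumerate(styles):
        sp = splits[s_train]
        clf = classifier_factory()
        ws = windows_by_style[s_train]
        clf.fit([ws[k] for k in sp.train_idx], labels[s_train][sp.train_idx],
                [ws[k] for k in sp.val_idx], labels[s_train][sp.val_idx])
        for j, s_test in enumerate(styles):
            if s_test == s_train:
                test_w = [windows_by_style[s_test][k] for k in sp.test_idx]
                test_y = labels[s_test][sp.test_idx]
                idx = sp.test_idx
            else:
                test_w = windows_by_style[s_test]
                test_y = labels[s_test]
                idx = np.arange(len(test_w))
            y_pred = np.asarray(clf.predict(test_w), dtype=int)
            rep = score_report(test_y, y_pred, idx, len(sp.train_idx),
                               {"train": s_train, "test": s_test})
            matrix[i, j] = rep.average_pct
            reports[(s_train, s_test)] = rep
    return CrossStyleMatrix(styles, matrix, speed_kmh, reports)


@dataclass
class MixedStyleTable:
    """Accuracy on the pooled test set for each training-style combination."""

    rows: list[dict]                  # {"styles": tuple, "accuracy_pct": float}
    speed_kmh: int | None = None

    def mean_by_size(self) -> dict[int, float]:
        out: dict[int, list[float]] = {}
        for row in self.rows:
            out.setdefault(len(row["styles"]), []).append(row["accuracy_pct"])
        return {k: float(np.mean(v)) for k, v in sorted(out.items())}

    def to_dict(self) -> dict:
        return {
            "rows": [{"styles": list(r["styles"]),
                      "accuracy_pct": round(r["accuracy_pct"], 4)} for r in self.rows],
            "mean_by_size_pct": {str(k): round(v, 4)
                                 for k, v in self.mean_by_size().items()},
            "speed_kmh": self.speed_kmh,
        }


def mixed_style_experiment(
    classifier_factory,
    windows_by_style: dict[str, list[AnalysisWindow]],
    seed: int = 0,
    speed_kmh: int | None = None,
) -> MixedStyleTable:
    """Train on each non-empty style subset; test on the pooled held-out set.

    All three styles contribute their 20% test split to a single pooled test
    group; the seven training sets are the non-empty subsets of the styles'
    training splits, so no evaluation ever touches its own training windows.
    """
    styles = tuple(windows_by_style)
    if len(styles) != 3:
        raise ConfigurationError("mixed-style experiment needs all three load styles")
    labels = {s: np.array([w.label for w in ws], dtype=int)
              for s, ws in windows_by_style.items()}
    splits = {s: split_dataset(labels[s], seed=seed + i)
              for i, s in enumerate(styles)}

    pooled_w = [windows_by_style[s][k] for s in styles for k in splits[s].test_idx]
    pooled_y = np.concatenate([labels[s][splits[s].test_idx] for s in styles])

    subsets = [c for size in (1, 2, 3) for c in combinations(styles, size)]
    rows = []
    for subset in subsets:
        train_w = [windows_by_style[s][k] for s in subset for k in splits[s].train_idx]
        train_y = np.concatenate([labels[s][splits[s].train_idx] for s in subset])
        val_w = [windows_by_style[s][k] for s in subset for k in splits[s].val_idx]
        val_y = np.concatenate([labels[s][splits[s].val_idx] for s in subset])
        clf = classifier_factory()
        clf.fit(train_w, train_y, val_w, val_y)
        y_pred = np.asarray(clf.predict(pooled_w), dtype=int)
        rep = score_report(pooled_y, y_pred, None, len(train_w),
                           {"train_styles": list(subset)})
        rows.append({"styles": subset, "accuracy_pct": rep.average_pct, "report": rep})
    return MixedStyleTable(rows, speed_kmh)


def save_report(report: EvaluationReport | CrossStyleMatrix | MixedStyleTable,
                path: str | Path) -> Path:
    """Serialize any report as sorted-key JSON (byte-stable for fixed inputs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    return path


def save_predictions_csv(report: EvaluationReport, path: str | Path) -> Path:
    """Prediction log: window_index, true, predicted."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, report.predictions, fmt="%d", delimiter=",",
               header="window_index,true,predicted", comments="")
    return path
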