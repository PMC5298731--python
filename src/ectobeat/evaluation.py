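"""Leave-one-subject-out evaluation with summed confusion matrices.

One classifier instance is trained per fold on the beats of all but one
subject and tested on the held-out subject; the per-fold 3x3 confusion
matrices (rows = true class N/S/V, columns = predicted) are summed and the
performance measures are derived from the total matrix.  Because no
subject ever contributes to both training and testing of a fold, the
resulting sensitivity/specificity generalize to unseen patients.

Sensitivity here is the fraction of truly ectopic beats (S or V) predicted
as any ectopic class; specificity is the fraction of truly normal beats
predicted normal.  Per-class sensitivities count a beat as detected when it
is predicted as either ectopic class (the headline task is binary), with
strict same-class variants reported alongside.  The alternative reading of
"correct among those labeled ectopic" (positive predictivity) is also
reported under its own name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from .mlp import CLASSES, EctopicBeatClassifier

logger = logging.getLogger(__name__)

_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


def confusion_matrix3(y_true, y_pred) -> np.ndarray:
    """3x3 integer counts, rows = true class (N,S,V), columns = predicted."""
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[_CLASS_INDEX[str(t)], _CLASS_INDEX[str(p)]] += 1
    return cm


@dataclass
class ClassificationMetrics:
    """Sensitivity/specificity block derived from a summed confusion matrix.

    ``None`` marks a metric whose defining class is absent (undefined, not
    zero).  ``*_strict`` requires the exact ectopic class to be predicted;
    the plain per-class sensitivities accept either ectopic class.
    """

    sensitivity: float | None
    sensitivity_sveb: float | None
    sensitivity_veb: float | None
    specificity: float | None
    sensitivity_sveb_strict: float | None = None
    sensitivity_veb_strict: float | None = None
    positive_predictivity: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(cm: np.ndarray) -> ClassificationMetrics:
    """Performance measures from a 3x3 confusion matrix (rows true N,S,V)."""
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    n_row, s_row, v_row = cm[0], cm[1], cm[2]
    ectopic_true = s_row.sum() + v_row.sum()
    ectopic_detected = s_row[1:].sum() + v_row[1:].sum()
    pred_ectopic_total = cm[:, 1:].sum()
    return ClassificationMetrics(
        sensitivity=_ratio(ectopic_detected, ectopic_true),
        sensitivity_sveb=_ratio(s_row[1:].sum(), s_row.sum()),
        sensitivity_veb=_ratio(v_row[1:].sum(), v_row.sum()),
        specificity=_ratio(n_row[0], n_row.sum()),
        sensitivity_sveb_strict=_ratio(s_row[1], s_row.sum()),
        sensitivity_veb_strict=_ratio(v_row[2], v_row.sum()),
        positive_predictivity=_ratio(ectopic_detected, pred_ectopic_total),
    )


@dataclass
class LosoResult:
    confusion: np.ndarray
    per_subject: dict[str, np.ndarray] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    @property
    def metrics(self) -> ClassificationMetrics:
        return compute_metrics(self.confusion)


def loso_cross_validation(
    dataset: dict[str, tuple[np.ndarray, np.ndarray]],
    classifier: EctopicBeatClassifier | None = None,
    strict: bool = False,
) -> LosoResult:
    """Leave-one-subject-out cross-validation.

    Parameters
    ----------
    dataset:
        Mapping subject id -> (X, y) with y in {"N","S","V"}.
    classifier:
        Template estimator, cloned per fold (default
        :class:`EctopicBeatClassifier` with its defaults).
    strict:
        If True, a training pool missing one of the three classes raises;
        otherwise the fold is skipped with a warning.
    """
    if len(dataset) < 2:
        raise ValueError("need >= 2 subjects for LOSO")
    template = classifier if classifier is not None else EctopicBeatClassifier()
    total = np.zeros((3, 3), dtype=int)
    result = LosoResult(confusion=total)
    for held_out in dataset:
        X_test, y_test = dataset[held_out]
        train_parts = [dataset[s] for s in dataset if s != held_out]
        X_train = np.vstack([p[0] for p in train_parts])
        y_train = np.concatenate([np.asarray(p[1], dtype=object) for p in train_parts])
        missing = [c for c in CLASSES if not np.any(y_train == c)]
        if missing:
            msg = f"fold {held_out!r}: class(es) {missing} absent from training pool"
            if strict:
                raise ValueError(msg)
            logger.warning("%s — fold skipped", msg)
            result.skipped.append(held_out)
            continue
        est = clone(template)
        est.fit(X_train, y_train)
        cm = confusion_matrix3(y_test, est.predict(X_test))
        result.per_subject[held_out] = cm
        total += cm
    result.confusion = total
    return result
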