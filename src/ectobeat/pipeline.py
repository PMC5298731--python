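"""Record-level pipeline glue: delineate, extract, align labels.

Thin composition of the delineation and feature modules used by the
evaluation harness, the experiment driver and the CLI.
"""

from __future__ import annotations

import numpy as np

from .delineation import DelineatedBeat, delineate_record
from .features import extract_features
from .signal_io import AnnotationSet, Record


def match_labels(
    beats: list[DelineatedBeat],
    annotations: AnnotationSet,
    fs: float,
    tolerance_s: float = 0.075,
) -> list[str | None]:
    """Annotation class of each delineated beat (None when unannotated).

    A beat inherits the label of the nearest annotation within
    ``tolerance_s`` of its R peak.
    """
    ann_samples = annotations.samples
    ann_labels = annotations.labels
    tol = tolerance_s * fs
    out: list[str | None] = []
    for b in beats:
        if len(ann_samples) == 0:
            out.append(None)
            continue
        j = int(np.argmin(np.abs(ann_samples - b.r)))
        out.append(ann_labels[j] if abs(int(ann_samples[j]) - b.r) <= tol else None)
    return out


def subject_dataset(
    record: Record, annotations: AnnotationSet
) -> tuple[np.ndarray, np.ndarray, list[DelineatedBeat], np.ndarray]:
    """Feature matrix + aligned true labels for one annotated record.

    Returns ``(X, y, beats, beat_idx)``; beats without an extractable
    feature vector or without a matching annotation are dropped.
    """
    beats = delineate_record(record)
    X, idx = extract_features(record, beats)
    labels = match_labels(beats, annotations, record.fs)
    keep = [k for k, i in enumerate(idx) if labels[i] is not None]
    X = X[keep]
    y = np.array([labels[idx[k]] for k in keep], dtype=object)
    return X, y, beats, idx[keep]


def feature_subset(X: np.ndarray, subset: str) -> np.ndarray:
    """Column view for the all/ecg/ppg feature subsets (f1-f20 / f1-f14 / f15-f20)."""
    if subset == "all":
        return X
    if subset == "ecg":
        return X[:, :14]
    if subset == "ppg":
        return X[:, 14:]
    raise ValueError(f"unknown feature subset {subset!r}")


def beat_reference_sbp(record: Record, beats: list[DelineatedBeat]) -> np.ndarray:
    """Per-beat systolic reference from the ABP channel (max over [r, r_next))."""
    abp = record.channel("abp")
    ref = np.full(len(beats), np.nan)
    for i, b in enumerate(beats):
        if b.r_next > b.r >= 0:
            ref[i] = float(np.max(abp[b.r : b.r_next]))
    return ref
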