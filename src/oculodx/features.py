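"""Original eye-movement features: per-trace min-max normalization.

Each raw per-frame pupil parameter series f = [f1..fM] from one stimulus
scheme becomes an original feature vector g with

    g_i = (f_i - min f) / (max f - min f),

so every feature lives in [0, 1] with its minimum at exactly 0 and maximum
at exactly 1 (a constant series, where the formula is 0/0, maps to all
zeros — a constant carries no information).  A subject tested under s
schemes with k parameters per scheme yields s x k feature vectors in a
fixed canonical order: scheme-major, parameter-minor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthesis import EyeTrace

DEFAULT_PARAMETERS = ("x", "y", "area")


@dataclass(frozen=True)
class OriginalFeature:
    """A normalized length-M feature vector for one (scheme, parameter)."""

    values: np.ndarray
    scheme_id: str
    parameter: str
    subject_id: str

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FeatureSet:
    """All s x k original features of one subject, canonically ordered."""

    subject_id: str
    features: tuple[OriginalFeature, ...]
    class_label: str

    def __len__(self) -> int:
        return len(self.features)


def normalize_feature(
    raw: np.ndarray,
    scheme_id: str = "",
    parameter: str = "",
    subject_id: str = "",
) -> OriginalFeature:
    """Min-max normalize a raw parameter series into [0, 1]."""
    f = np.asarray(raw, dtype=float)
    if f.ndim != 1 or len(f) < 2:
        raise ValueError("raw feature must be a 1-D vector of length >= 2")
    if not np.all(np.isfinite(f)):
        raise ValueError("raw feature contains non-finite values")
    lo, hi = f.min(), f.max()
    if hi == lo:
        g = np.zeros_like(f)
    else:
        g = (f - lo) / (hi - lo)
    return OriginalFeature(values=g, scheme_id=scheme_id,
                           parameter=parameter, subject_id=subject_id)


def build_feature_set(
    traces: dict[str, EyeTrace] | list[EyeTrace],
    parameters: tuple[str, ...] = DEFAULT_PARAMETERS,
) -> FeatureSet:
    """Assemble a subject's s x k normalized features.

    Traces are keyed (or re-keyed) by scheme id and iterated in sorted
    scheme order, so input ordering never changes the canonical feature
    layout: scheme1-param1, scheme1-param2, ..., scheme2-param1, ...
    """
    if isinstance(traces, list):
        traces = {t.scheme_id: t for t in traces}
    if not traces:
        raise ValueError("need at least one trace")
    lengths = {len(t) for t in traces.values()}
    if len(lengths) != 1:
        raise ValueError("all traces of a subject must have equal length")
    subject_ids = {t.subject_id for t in traces.values()}
    labels = {t.class_label for t in traces.values()}
    if len(subject_ids) != 1 or len(labels) != 1:
        raise ValueError("traces must belong to a single subject")
    subject_id, label = subject_ids.pop(), labels.pop()

    feats = []
    for scheme_id in sorted(traces):
        trace = traces[scheme_id]
        for p in parameters:
            if p not in trace.data.columns:
                raise KeyError(f"parameter {p!r} not in trace schema")
            feats.append(normalize_feature(trace.parameter(p), scheme_id, p,
                                           subject_id))
    return FeatureSet(subject_id=subject_id, features=tuple(feats),
                      class_label=label)


def feature_sets_to_frame(feature_sets: list[FeatureSet]) -> pd.DataFrame:
    """Long-format export: subject_id, feature_index, frame, value."""
    rows = []
    for fs in feature_sets:
        for j, feat in enumerate(fs.features, start=1):
            for i, v in enumerate(feat.values):
                rows.append((fs.subject_id, j, i, v))
    return pd.DataFrame(rows, columns=["subject_id", "feature_index",
                                       "frame", "value"])


def feature_matrix(feature_sets: list[FeatureSet],
                   feature_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack one feature (1-based index) across subjects.

    Returns ``(X, y)`` with X of shape (n_subjects, M_frames) and y the
    integer class labels (1..3 for C1..C3).
    """
    from .synthesis import CLASS_LABELS

    X = np.stack([fs.features[feature_index - 1].values
                  for fs in feature_sets])
    y = np.array([CLASS_LABELS.index(fs.class_label) + 1
                  for fs in feature_sets])
    return X, y
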