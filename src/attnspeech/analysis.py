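"""Descriptive analysis of frame-level features by diagnostic group.

Before any model is fitted, it is worth asking whether single descriptors
separate depressed from control speech at all.  The tools here compute
per-segment feature means, compare the two classes as sorted curves with
an overlap statistic, and run k-means clustering on selected feature
triples to see whether the groups form distinct centres.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix

__all__ = [
    "segment_feature_means",
    "compare_classes",
    "cluster_feature_combo",
    "FEATURE_COMBOS",
]

# Feature triples observed to separate the groups in corpus-level cluster
# analyses; arbitrary triples are accepted as well.
FEATURE_COMBOS: dict[str, tuple[str, str, str]] = {
    "harmonic": ("harmonicERMS", "mfcc_0", "dloudness"),
    "voicing": ("voiceProb", "noiseERMS", "dmfcc_0"),
}


def segment_feature_means(
    matrices: Sequence[FeatureMatrix], labels: Sequence[int]
) -> pd.DataFrame:
    """Mean of each feature over the time axis, one row per segment.

    The resulting table (columns = schema names, plus ``label`` and
    ``source_id``) is the input of the class comparison and clustering
    below.
    """
    if len(matrices) != len(labels):
        raise ValueError("need one label per feature matrix")
    if not matrices:
        raise ValueError("need at least one segment")
    schema = matrices[0].schema
    rows = []
    for fm, label in zip(matrices, labels):
        if fm.schema.names != schema.names:
            raise ValueError(f"{fm.source_id}: schema differs from the first segment")
        rows.append(fm.values.mean(axis=0))
    table = pd.DataFrame(rows, columns=list(schema.names))
    table["label"] = np.asarray(labels, dtype=int)
    table["source_id"] = [fm.source_id for fm in matrices]
    return table


def compare_classes(
    mean_table: pd.DataFrame, feature: str
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sorted per-class curves of one feature plus an overlap statistic.

    Returns (control_sorted, depression_sorted, overlap).  The overlap is
    an estimate of the overlapping coefficient of the two class
    distributions: the total misclassified probability mass when
    thresholding at the midpoint of the class means (1 for identical
    distributions, 0 for perfectly separated ones).
    """
    if feature not in mean_table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    a = np.sort(mean_table.loc[mean_table["label"] == 0, feature].to_numpy())
    b = np.sort(mean_table.loc[mean_table["label"] == 1, feature].to_numpy())
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be present in the table")
    lo, hi = (a, b) if a.mean() <= b.mean() else (b, a)
    threshold = 0.5 * (lo.mean() + hi.mean())
    overlap = float(np.mean(lo > threshold) + np.mean(hi <= threshold))
    return a, b, min(overlap, 1.0)


def cluster_feature_combo(
    mean_table: pd.DataFrame,
    feature_triple: Sequence[str] | str,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[np.ndarray, float]:
    """k-means on a standardized 3-feature subspace; label agreement.

    ``feature_triple`` may be one of the named presets in
    :data:`FEATURE_COMBOS`.  Agreement is the best accuracy over cluster
    index permutations, so it is invariant to cluster relabeling.
    """
    if isinstance(feature_triple, str):
        feature_triple = FEATURE_COMBOS[feature_triple]
    missing = [f for f in feature_triple if f not in mean_table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    x = mean_table[list(feature_triple)].to_numpy(dtype=float)
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct points for {k}-means")
    x = StandardScaler().fit_transform(x)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assignments = km.fit_predict(x)
    labels = mean_table["label"].to_numpy()
    agree = np.mean(assignments == labels)
    agreement = float(max(agree, 1.0 - agree)) if k == 2 else float(agree)
    return assignments, agreement
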