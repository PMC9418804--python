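"""PLP-style feature constructions and tree-learner comparators.

Two constructions over the tokenized observation window: plain binary
presence (one 0/1 slot per dictionary concept) and time-bucketed presence,
where the presence block is replicated for cumulative lookback windows of
30, 180, 365 and unlimited days before the index date (time 0).  Buckets
are cumulative, not disjoint: an event within 30 days is also within 180,
so the blocks are slotwise monotone and the unlimited block equals the
plain presence vector.  The vectors feed off-the-shelf tree learners
(random forest, gradient-boosted trees) used as comparators.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .events import N_RESERVED, ConceptDictionary, LabeledSample

DEFAULT_LOOKBACKS: tuple[float, ...] = (30, 180, 365, math.inf)

__all__ = [
    "DEFAULT_LOOKBACKS",
    "binary_presence_features",
    "time_bucket_features",
    "feature_matrix",
    "fit_tree_baseline",
    "export_features",
]


def binary_presence_features(
    sample: LabeledSample, dictionary: ConceptDictionary
) -> np.ndarray:
    """0/1 vector: slot c is 1 iff concept c occurs in the observation window.

    Slots follow dictionary token order (token 2 → slot 0); length equals
    the dictionary size.  Invariant to event order and duplicates.
    """
    vec = np.zeros(dictionary.size, dtype=np.uint8)
    real = sample.tokens[sample.real_mask]
    vec[real - N_RESERVED] = 1
    return vec


def time_bucket_features(
    sample: LabeledSample,
    dictionary: ConceptDictionary,
    lookbacks: Sequence[float] = DEFAULT_LOOKBACKS,
) -> np.ndarray:
    """Presence features replicated per cumulative lookback window.

    For each lookback L (days) and concept c, the slot is 1 iff c occurs
    within L days before time 0.  Output length is
    ``len(lookbacks) * dictionary.size``.
    """
    for lb in lookbacks:
        if not lb > 0:
            raise ValueError(f"lookback windows must be positive, got {lb}")
    real = sample.real_mask
    toks = sample.tokens[real] - N_RESERVED
    days = sample.days_before_index[real]
    blocks = []
    for lb in lookbacks:
        vec = np.zeros(dictionary.size, dtype=np.uint8)
        vec[toks[days <= lb]] = 1
        blocks.append(vec)
    return np.concatenate(blocks)


def feature_matrix(
    samples: Sequence[LabeledSample],
    dictionary: ConceptDictionary,
    kind: str = "presence",
    lookbacks: Sequence[float] = DEFAULT_LOOKBACKS,
) -> np.ndarray:
    """Stack per-sample feature vectors into an (n_samples, n_features) array."""
    if kind == "presence":
        rows = [binary_presence_features(s, dictionary) for s in samples]
    elif kind == "time_buckets":
        rows = [time_bucket_features(s, dictionary, lookbacks) for s in samples]
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return np.stack(rows).astype(np.float32)


class TreeScorer:
    """Fitted tree model exposing positive-class probability scores."""

    def __init__(self, model):
        self._model = model

    def scores(self, features: np.ndarray) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            # LightGBM's sklearn wrapper warns about absent feature names
            # even for plain arrays; the prediction is unaffected
            warnings.simplefilter("ignore", UserWarning)
            return self._model.predict_proba(features)[:, 1]


def fit_tree_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    learner: str = "random_forest",
    seed: int = 0,
) -> TreeScorer:
    """Fit a tree-ensemble comparator with library-default hyperparameters.

    ``learner`` selects a random forest or gradient-boosted trees
    (LightGBM).  The seed is fixed for reproducibility; degenerate
    single-class label vectors are rejected.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; cannot fit a scorer")
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels are misaligned")
    if learner == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        model = RandomForestClassifier(random_state=seed, n_jobs=1)
    elif learner == "gradient_boosted_trees":
        from lightgbm import LGBMClassifier

        model = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
    else:
        raise ValueError(
            f"unknown learner {learner!r} "
            "(use 'random_forest' or 'gradient_boosted_trees')"
        )
    model.fit(features, labels)
    return TreeScorer(model)


def export_features(
    features: np.ndarray, column_names: Sequence[str], out_prefix
) -> None:
    """Write features as sparse (row, col, value) triplet text plus a
    column-name sidecar, for audit."""
    out_prefix = Path(out_prefix)
    rows, cols = np.nonzero(features)
    with open(f"{out_prefix}.triplets.txt", "w") as fh:
        fh.write("row\tcol\tvalue\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\t{features[r, c]:g}\n")
    with open(f"{out_prefix}.columns.txt", "w") as fh:
        fh.write("\n".join(column_names) + "\n")
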