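"""Random-forest discovery of state-discriminating features.

Procedure: bootstrap samples from the (reweighted) ensemble, label each
sample by eRMSD threshold to the reference structure, compute features
(torsion angles, ring-centre distances, or back-calculated experimental
data), train a shallow random forest (max depth 2), and rank features by
impurity importance.  The classifier itself is incidental; its feature
ranking identifies the degrees of freedom (or the measurements) that
discriminate the two conformational states.

Circular torsion features are encoded as (sin, cos) pairs by default to
avoid wrap-around artifacts in axis-aligned tree splits; the importance of
a pair is summed under its torsion's name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .ensemble_io import Ensemble, WeightSet
from .errors import ValidationError
from .structure_metrics import StateLabels, ring_center, torsion_matrix

logger = logging.getLogger(__name__)

N_TREES = 100          # paper-style shallow forest; depth is the pinned knob
MAX_DEPTH = 2
TRAIN_FRACTION = 0.8
IMPORTANCE_CUTOFF = 0.2
N_BOOTSTRAP = 50_000


@dataclass
class FeatureTable:
    """Sample-by-feature value grid with per-column grouping.

    ``groups`` maps each column to the reporting name under which its
    importance is accumulated (e.g. the sin/cos columns of one torsion share
    a group).  ``kind`` is one of torsion_deg | ring_distance_A |
    backcalc_observable.
    """

    names: list
    values: np.ndarray
    kind: str
    groups: list | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise ValidationError("feature count mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite feature values")
        if self.groups is None:
            self.groups = list(self.names)
        if len(self.groups) != len(self.names):
            raise ValidationError("groups must align with feature columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class ImportanceRanking:
    """Feature names with normalized importance scores, descending."""

    names: list
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != len(self.scores):
            raise ValidationError("name/score length mismatch")
        if np.any(self.scores < 0):
            raise ValidationError("importance scores must be non-negative")
        total = self.scores.sum()
        if self.scores.size and abs(total - 1.0) > 1e-9:
            raise ValidationError("importance scores must sum to 1")
        order = np.argsort(-self.scores, kind="stable")
        self.names = [self.names[i] for i in order]
        self.scores = self.scores[order]


def bootstrap_samples(n_frames: int, weights: WeightSet,
                      n_samples: int = N_BOOTSTRAP, seed: int = 0) -> np.ndarray:
    """Frame indices drawn with replacement with probability = weight."""
    if len(weights) != n_frames:
        raise ValidationError("weight length must equal frame count")
    if not np.any(weights.weights > 0):
        raise ValidationError("all-zero weights")
    rng = np.random.default_rng(seed)
    return rng.choice(n_frames, size=n_samples, replace=True,
                      p=weights.weights)


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def torsion_feature_table(ensemble: Ensemble, samples: np.ndarray,
                          torsions=None, encoding: str = "sincos") -> FeatureTable:
    """Per-sample torsion features, sin/cos-encoded by default.

    Torsions undefined in the topology are dropped with a log record.
    """
    if encoding not in ("sincos", "degrees"):
        raise ValidationError(f"unknown encoding {encoding!r}")
    names, values = torsion_matrix(ensemble, torsions)
    defined = [k for k in range(len(names))
               if np.all(np.isfinite(values[:, k]))]
    dropped = sorted(set(range(len(names))) - set(defined))
    if dropped:
        logger.info("dropping undefined torsions: %s",
                    [names[k] for k in dropped])
    names = [names[k] for k in defined]
    values = values[:, defined][samples]
    if encoding == "degrees":
        return FeatureTable(names, values, kind="torsion_deg")
    rad = np.radians(values)
    cols, col_names, groups = [], [], []
    for k, name in enumerate(names):
        cols += [np.sin(rad[:, k]), np.cos(rad[:, k])]
        col_names += [f"{name}_sin", f"{name}_cos"]
        groups += [name, name]
    return FeatureTable(col_names, np.column_stack(cols) if cols else
                        np.empty((len(samples), 0)), kind="torsion_deg",
                        groups=groups)


def ring_distance_feature_table(ensemble: Ensemble, samples: np.ndarray,
                                pairs=None) -> FeatureTable:
    """Per-sample distances between nucleobase ring centres (Å).

    ``pairs`` is a list of (resid_i, resid_j); default: all residue pairs.
    """
    frame0 = ensemble.frame(0)
    res_ids = [int(r) for r in frame0.residue_ids()]
    if pairs is None:
        pairs = list(combinations(res_ids, 2))
    centers = np.empty((ensemble.n_frames, len(res_ids), 3))
    pos = {rid: k for k, rid in enumerate(res_ids)}
    for j in range(ensemble.n_frames):
        frame = ensemble.frame(j)
        for rid in res_ids:
            centers[j, pos[rid]] = ring_center(frame, rid)
    names, cols = [], []
    labels = {rid: f"{frame0.residue_name(rid)}{rid}" for rid in res_ids}
    for i, j in pairs:
        d = np.linalg.norm(centers[:, pos[i]] - centers[:, pos[j]], axis=1)
        names.append(f"ringdist_{labels[i]}_{labels[j]}")
        cols.append(d[samples])
    return FeatureTable(names, np.column_stack(cols), kind="ring_distance_A")


def observable_feature_table(matrix, measurements,
                             samples: np.ndarray) -> FeatureTable:
    """Per-sample single-frame back-calculated observables.

    NOE rows (stored as r^-6) are back-transformed to distances for
    interpretability; couplings and RDCs are used as-is.
    """
    values = matrix.values[:, samples].T.copy()
    if matrix.transform == "r_minus_6":
        values = values ** (-1.0 / 6.0)
    names = [f"obs_{mid}" for mid in matrix.ids]
    del measurements  # ids already carried by the matrix
    return FeatureTable(names, values, kind="backcalc_observable")


def concat_features(tables: list) -> FeatureTable:
    names, groups, cols, kinds = [], [], [], []
    for t in tables:
        names += t.names
        groups += t.groups
        cols.append(t.values)
        kinds.append(t.kind)
    kind = kinds[0] if len(set(kinds)) == 1 else "mixed"
    return FeatureTable(names, np.hstack(cols), kind=kind, groups=groups)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

def train_state_classifier(features: FeatureTable, labels: StateLabels,
                           max_depth: int = MAX_DEPTH,
                           train_fraction: float = TRAIN_FRACTION,
                           n_estimators: int = N_TREES, seed: int = 0):
    """Train a shallow random forest; returns (classifier, held-out accuracy).

    The train/test split is a seeded shuffle; class imbalance is left as-is.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split

    y = labels.labels
    if features.n_samples != len(y):
        raise ValidationError("feature/label sample count mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValidationError("need at least 2 samples in each of 2 classes")
    x_train, x_test, y_train, y_test = train_test_split(
        features.values, y, train_size=train_fraction, random_state=seed,
        shuffle=True,
    )
    clf = RandomForestClassifier(n_estimators=n_estimators,
                                 max_depth=max_depth, random_state=seed)
    clf.fit(x_train, y_train)
    accuracy = float(clf.score(x_test, y_test))
    logger.info("held-out accuracy: %.4f", accuracy)
    return clf, accuracy


def rank_importance(classifier, features: FeatureTable) -> ImportanceRanking:
    """Impurity-based importances, grouped (sin/cos pairs summed), normalized.

    Importance is the total (sample-weighted) impurity decrease a feature
    achieves across the whole forest, normalized once at the end.  This
    differs from sklearn's ``feature_importances_``, which normalizes per
    tree and therefore credits a tree's best *sampled* feature with full
    importance even when its split is barely informative; summing raw
    impurity decreases keeps weakly and strongly discriminating features
    on a common scale.
    """
    try:
        estimators = getattr(classifier, "estimators_", None)
        if estimators:
            raw = np.sum(
                [est.tree_.compute_feature_importances(normalize=False)
                 for est in estimators], axis=0)
        else:
            raw = np.asarray(classifier.feature_importances_, dtype=float)
    except Exception as exc:
        raise ValidationError(f"untrained or invalid classifier: {exc}") from exc
    if len(raw) != len(features.names):
        raise ValidationError("classifier/feature column count mismatch")
    grouped: dict[str, float] = {}
    for g, v in zip(features.groups, raw):
        grouped[g] = grouped.get(g, 0.0) + float(v)
    names = list(grouped.keys())
    scores = np.array([grouped[n] for n in names])
    total = scores.sum()
    if total <= 0:
        # degenerate forest with no splits: flat ranking
        scores = np.full(len(names), 1.0 / len(names))
    else:
        scores = scores / total
    return ImportanceRanking(names, scores)


def select_sensitive_measurements(ranking: ImportanceRanking,
                                  cutoff: float = IMPORTANCE_CUTOFF) -> list:
    """Feature names with importance strictly greater than the cutoff."""
    return [n for n, s in zip(ranking.names, ranking.scores) if s > cutoff]


def compare_zscores(predictions_a, predictions_b, measurements):
    """Paired |Z| table for two ensembles' predictions on shared measurements.

    Returns ``(table, counts)``: a pandas DataFrame with columns id, z_a,
    z_b, and counts of points above the diagonal (z_b > z_a: ensemble *a*
    agrees better) and below it; exact ties count for neither.
    """
    import pandas as pd

    predictions_a = np.atleast_1d(np.asarray(predictions_a, dtype=float))
    predictions_b = np.atleast_1d(np.asarray(predictions_b, dtype=float))
    if not (len(predictions_a) == len(predictions_b) == len(measurements)):
        raise ValidationError("prediction/measurement count mismatch")
    f_exp = np.array([m.value for m in measurements])
    sigma = np.array([m.sigma for m in measurements])
    z_a = np.abs(predictions_a - f_exp) / sigma
    z_b = np.abs(predictions_b - f_exp) / sigma
    table = pd.DataFrame({"id": [m.id for m in measurements],
                          "z_a": z_a, "z_b": z_b})
    counts = {"above_diagonal": int(np.sum(z_b > z_a)),
              "below_diagonal": int(np.sum(z_b < z_a))}
    return table, counts
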