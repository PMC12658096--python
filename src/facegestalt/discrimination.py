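"""Control distributions and ROC/Youden threshold selection.

The discrimination question: does a cohort's mean pairwise embedding
distance separate groups of patients sharing a syndrome from random groups?
For every syndrome S in a control gallery and every cohort size
n in 2..|S|, two samples of cohorts are drawn (without duplicates): cohorts
of n patients from S, and cohorts of n random gallery patients.  Each cohort
is scored by its mean pairwise distance.  Pooling all cells gives one
two-class sample on which a single classification threshold is selected by
maximizing the Youden index (J = sensitivity + specificity - 1), with
k-fold cross-validation supplying honest held-out error rates.

Orientation is fixed throughout: *smaller* distance means *more* similar, so
a cohort is classified as same-syndrome when its value is strictly below the
threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .gallery import Cohort, Gallery, GalleryError
from .distances import DistanceMatrix, mean_pairwise_from_indices, pairwise_distance_matrix

__all__ = [
    "RANDOM",
    "CohortDistanceSamples",
    "RocResult",
    "sample_cohorts",
    "build_control_distributions",
    "roc_curve",
    "youden_threshold",
    "crossval_roc",
]

RANDOM = "__random__"
"""Sentinel syndrome value: draw cohorts from the whole gallery."""

SAME_SYNDROME = "same_syndrome"
RANDOM_LABEL = "random"

# Rejection-sampling safety factor before giving up on finding further
# distinct cohorts (only reachable when reps is close to the number of
# distinct combinations; below the enumeration cutoff we enumerate instead).
_RESAMPLE_CAP = 100


@dataclass(frozen=True)
class CohortDistanceSamples:
    """Labelled mean-pairwise-distance draws, one row per sampled cohort.

    ``table`` columns: ``label`` ('same_syndrome' | 'random'), ``syndrome_id``
    (empty for random cohorts), ``n`` (cohort size), ``value`` (mean pairwise
    distance), ``members`` (sorted ';'-joined id tuple).  Within one
    (label, syndrome, n) cell all member tuples are distinct.
    """

    table: pd.DataFrame

    def values_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, is_positive) arrays; positives are same-syndrome cohorts."""
        values = self.table["value"].to_numpy(dtype=np.float64)
        labels = (self.table["label"] == SAME_SYNDROME).to_numpy()
        return values, labels

    def random_values(self, max_n: int | None = None, min_n: int = 2) -> np.ndarray:
        """Random-cohort values, optionally restricted to sizes in [min_n, max_n]."""
        t = self.table[self.table["label"] == RANDOM_LABEL]
        if max_n is not None:
            t = t[(t["n"] >= min_n) & (t["n"] <= max_n)]
        return t["value"].to_numpy(dtype=np.float64)

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("label,syndrome_id,n,value,members\n")
            for row in self.table.itertuples(index=False):
                fh.write(f"{row.label},{row.syndrome_id},{row.n},"
                         f"{repr(float(row.value))},{row.members}\n")


@dataclass(frozen=True)
class FoldResult:
    """Youden threshold fit on one training fold, evaluated on its held-out fold."""

    threshold: float
    sensitivity: float
    specificity: float
    auc: float


@dataclass(frozen=True)
class RocResult:
    """ROC points, AUC and Youden threshold for the pooled two-class sample.

    ``points`` is the (threshold, sensitivity, specificity) sweep in
    increasing threshold order.  ``youden_*`` fields hold the full-sample
    Youden solution; when produced by :func:`crossval_roc`,
    ``cv_sensitivity``/``cv_specificity`` are pooled held-out rates and
    ``folds`` retains each fold's fit.
    """

    points: list[tuple[float, float, float]]
    auc: float
    youden_threshold: float | None = None
    youden_sensitivity: float | None = None
    youden_specificity: float | None = None
    cv_sensitivity: float | None = None
    cv_specificity: float | None = None
    folds: tuple[FoldResult, ...] = ()
    n_pos: int | None = None
    n_neg: int | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "youden_threshold": self.youden_threshold,
            "youden_sensitivity": self.youden_sensitivity,
            "youden_specificity": self.youden_specificity,
            "cv_sensitivity": self.cv_sensitivity,
            "cv_specificity": self.cv_specificity,
            "folds": [f.__dict__ for f in self.folds],
            "points": [list(p) for p in self.points],
        }


# ---------------------------------------------------------------------------
# Cohort sampling


def sample_cohorts(gallery: Gallery, syndrome: str, n: int, reps: int,
                   rng: np.random.Generator) -> list[Cohort]:
    """Up to ``reps`` cohorts of size ``n`` with distinct sorted member tuples.

    ``syndrome`` selects the pool (its image ids), or :data:`RANDOM` for the
    whole gallery.  If the pool admits at most ``reps`` distinct combinations
    the full enumeration is returned (in lexicographic pool order) instead of
    sampling.
    """
    if syndrome == RANDOM:
        pool = gallery.image_ids
    else:
        if syndrome not in gallery.syndrome_index:
            raise GalleryError(f"unknown syndrome {syndrome!r}")
        pool = gallery.syndrome_index[syndrome]
    if n < 2:
        raise GalleryError("cohort size must be >= 2")
    if n > len(pool):
        raise GalleryError(f"cohort size {n} exceeds pool of {len(pool)}")

    total = math.comb(len(pool), n)
    if total <= reps:
        return [Cohort(c) for c in itertools.combinations(pool, n)]

    pool_arr = np.asarray(pool, dtype=object)
    seen: set[tuple[str, ...]] = set()
    cohorts: list[Cohort] = []
    attempts = 0
    max_attempts = _RESAMPLE_CAP * reps
    while len(cohorts) < reps and attempts < max_attempts:
        attempts += 1
        draw = tuple(sorted(rng.choice(pool_arr, size=n, replace=False)))
        if draw in seen:
            continue
        seen.add(draw)
        cohorts.append(Cohort(draw))
    return cohorts


def build_control_distributions(gallery: Gallery, reps: int = 100,
                                rng: np.random.Generator | None = None,
                                dmatrix: DistanceMatrix | None = None,
                                ) -> CohortDistanceSamples:
    """Same-syndrome and random control samples over all syndromes and sizes.

    For every syndrome S with at least two images and every cohort size n in
    2..|S|, draws ``reps`` same-syndrome cohorts and ``reps`` size-matched
    random cohorts (unrestricted draws from the whole gallery), scoring each
    by mean pairwise distance.
    """
    rng = np.random.default_rng(rng)
    eligible = gallery.syndromes(min_size=2)
    if not eligible:
        raise GalleryError("no syndrome with >= 2 images")
    if dmatrix is None:
        dmatrix = pairwise_distance_matrix(gallery)
    index = {image_id: i for i, image_id in enumerate(dmatrix.ids)}
    values = dmatrix.values

    rows: list[tuple] = []

    def score(cohort: Cohort) -> float:
        idx = np.fromiter((index[x] for x in cohort.members), dtype=np.intp,
                          count=cohort.n)
        return mean_pairwise_from_indices(values, idx)

    for syndrome in sorted(eligible):
        size = len(eligible[syndrome])
        for n in range(2, size + 1):
            for cohort in sample_cohorts(gallery, syndrome, n, reps, rng):
                rows.append((SAME_SYNDROME, syndrome, n, score(cohort),
                             ";".join(sorted(cohort.members))))
            # random cells keep the syndrome they are size-matched to, so the
            # (label, syndrome, n) cell identity is preserved
            for cohort in sample_cohorts(gallery, RANDOM, n, reps, rng):
                rows.append((RANDOM_LABEL, syndrome, n, score(cohort),
                             ";".join(sorted(cohort.members))))
    table = pd.DataFrame(rows, columns=["label", "syndrome_id", "n", "value", "members"])
    return CohortDistanceSamples(table)


# ---------------------------------------------------------------------------
# ROC / Youden


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct values plus below-min/above-max sentinels.

    With the strict value < threshold rule, the minimum itself classifies
    nothing positive (the below-min sentinel) and the next float above the
    maximum classifies everything positive.
    """
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0]], mids, [np.nextafter(distinct[-1], np.inf)]))


def _sens_spec(thresholds: np.ndarray, pos: np.ndarray, neg: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    sens = np.searchsorted(pos_sorted, thresholds, side="left") / len(pos)
    spec = 1.0 - np.searchsorted(neg_sorted, thresholds, side="left") / len(neg)
    return sens, spec


def _auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(positive value < negative value), ties counting 1/2 (Mann-Whitney)."""
    ranks = rankdata(np.concatenate([pos, neg]), method="average")
    s_neg = ranks[len(pos):].sum()
    u = s_neg - len(neg) * (len(neg) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _split_classes(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise GalleryError("values and labels must be 1-D arrays of equal length")
    pos, neg = values[labels], values[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise GalleryError("both classes must be present")
    return pos, neg


def roc_curve(values, labels) -> RocResult:
    """ROC sweep and AUC for a two-class sample.

    ``labels`` True marks positives (same-syndrome cohorts); a sample is
    classified positive when its value is strictly below the threshold.
    """
    pos, neg = _split_classes(values, labels)
    thresholds = _candidate_thresholds(np.concatenate([pos, neg]))
    sens, spec = _sens_spec(thresholds, pos, neg)
    points = [(float(t), float(se), float(sp))
              for t, se, sp in zip(thresholds, sens, spec)]
    return RocResult(points=points, auc=_auc(pos, neg),
                     n_pos=len(pos), n_neg=len(neg))


def youden_threshold(roc: RocResult) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing J = sens + spec - 1.

    Candidates are the ROC's threshold sweep (midpoints of adjacent distinct
    values plus sentinels); ties in J resolve to the smallest threshold, the
    stricter classifier.  When the ROC carries class sizes, J is compared via
    exact integer counts (tp * n_neg + tn * n_pos) so that mathematically
    tied thresholds are tied regardless of floating-point rounding.
    """
    if not roc.points:
        raise GalleryError("ROC has no points")
    if roc.n_pos and roc.n_neg:
        n_pos, n_neg = roc.n_pos, roc.n_neg

        def key(p):
            tp = round(p[1] * n_pos)
            tn = round(p[2] * n_neg)
            return (tp * n_neg + tn * n_pos, -p[0])
    else:
        def key(p):
            return (p[1] + p[2] - 1.0, -p[0])
    best = max(roc.points, key=key)
    return best[0], best[1], best[2]


def _classify_counts(values: np.ndarray, labels: np.ndarray, threshold: float
                     ) -> tuple[int, int, int, int]:
    """(tp, fn, tn, fp) under the value < threshold positive rule."""
    pred = values < threshold
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    return tp, fn, tn, fp


def crossval_roc(samples: CohortDistanceSamples | tuple, folds: int = 5,
                 rng: np.random.Generator | None = None) -> RocResult:
    """Stratified k-fold cross-validated ROC over the pooled control sample.

    Per fold, a Youden threshold is fit on the training portion and applied
    to the held-out portion; the headline ``cv_sensitivity``/``cv_specificity``
    pool the held-out classifications across folds.  The headline threshold
    itself (``youden_threshold``, with its full-sample sensitivity and
    specificity) and the AUC are computed on the full pooled sample.
    """
    rng = np.random.default_rng(rng)
    if isinstance(samples, CohortDistanceSamples):
        values, labels = samples.values_labels()
    else:
        values, labels = samples
        values = np.asarray(values, dtype=np.float64)
        labels = np.asarray(labels, dtype=bool)
    pos, neg = _split_classes(values, labels)
    if min(len(pos), len(neg)) < folds:
        raise GalleryError(f"need >= {folds} samples per class for {folds}-fold CV")

    splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                               random_state=int(rng.integers(0, 2**31 - 1)))
    fold_results = []
    tp = fn = tn = fp = 0
    for train_idx, test_idx in splitter.split(values.reshape(-1, 1), labels):
        train_roc = roc_curve(values[train_idx], labels[train_idx])
        c_fold, _, _ = youden_threshold(train_roc)
        t_values, t_labels = values[test_idx], labels[test_idx]
        ftp, ffn, ftn, ffp = _classify_counts(t_values, t_labels, c_fold)
        tp, fn, tn, fp = tp + ftp, fn + ffn, tn + ftn, fp + ffp
        fold_auc = _auc(t_values[t_labels], t_values[~t_labels]) \
            if 0 < t_labels.sum() < len(t_labels) else float("nan")
        fold_results.append(FoldResult(
            threshold=c_fold,
            sensitivity=ftp / (ftp + ffn) if ftp + ffn else float("nan"),
            specificity=ftn / (ftn + ffp) if ftn + ffp else float("nan"),
            auc=fold_auc,
        ))

    full = roc_curve(values, labels)
    c, se, sp = youden_threshold(full)
    return RocResult(
        points=full.points,
        auc=full.auc,
        youden_threshold=c,
        youden_sensitivity=se,
        youden_specificity=sp,
        cv_sensitivity=tp / (tp + fn),
        cv_specificity=tn / (tn + fp),
        folds=tuple(fold_results),
    )
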