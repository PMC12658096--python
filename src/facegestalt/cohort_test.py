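"""Resampling test of target-cohort facial similarity.

Given a target cohort C (e.g. 15 subjects sharing a candidate gene), the
test resamples sub-cohorts of C of every size n in 2..|C| (size drawn
uniformly, then a uniform subset of that size; duplicates removed), scoring
each by mean pairwise distance.  Two summaries are reported:

* the fraction of sub-cohort values strictly below the discrimination
  threshold c (plus an auxiliary pairs-only fraction over the C(|C|, 2)
  pairwise distances, since "subject combinations" can be read either way);
* an empirical p-value comparing the cohort against random-cohort controls,
  with an add-one pseudo-count so it is never exactly zero.  Small distances
  are the extreme direction.

For the p-value the cohort's statistic is the *median* of its sub-cohort
values.  Calibration requires the null statistics to be exchangeable with
that median under the null, so :func:`matched_median_null` computes the very
same statistic on random cohorts of the same size (see docs/methods.md);
:func:`empirical_p_value` itself accepts any null sample, including pooled
raw random-cohort values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .gallery import Cohort, Gallery, GalleryError
from .distances import DistanceMatrix, mean_pairwise_from_indices

__all__ = [
    "CohortTestResult",
    "subsample_cohort_distribution",
    "fraction_below_threshold",
    "empirical_p_value",
    "matched_median_null",
    "run_cohort_test",
]

_RESAMPLE_CAP = 100  # attempts per requested rep before giving up


@dataclass(frozen=True)
class CohortTestResult:
    """Outcome of the resampling cohort-similarity test."""

    subcohort_values: list[tuple[int, tuple[str, ...], float]]
    fraction_below: float
    pairs_fraction_below: float
    threshold_used: float
    empirical_p: float | None
    reps_requested: int
    reps_obtained: int

    def to_dict(self) -> dict:
        return {
            "fraction_below": self.fraction_below,
            "pairs_fraction_below": self.pairs_fraction_below,
            "threshold_used": self.threshold_used,
            "empirical_p": self.empirical_p,
            "reps_requested": self.reps_requested,
            "reps_obtained": self.reps_obtained,
        }


def total_subcohorts(size: int) -> int:
    """Number of distinct sub-cohorts of size >= 2: 2^|C| - |C| - 1."""
    return 2 ** size - size - 1


def subsample_cohort_distribution(cohort: Cohort, dmatrix: DistanceMatrix,
                                  reps: int = 10_000,
                                  rng: np.random.Generator | None = None,
                                  ) -> list[tuple[int, tuple[str, ...], float]]:
    """Distinct sub-cohorts of C with their mean pairwise distances.

    Each draw picks a size n uniformly from {2..|C|} and then a uniform
    sub-cohort of that size; duplicates (by sorted member tuple) are removed.
    Stops at ``reps`` distinct sub-cohorts, or returns the full enumeration
    when at most ``reps`` distinct sub-cohorts exist.
    """
    if cohort.n < 2:
        raise GalleryError("cohort test needs |C| >= 2")
    rng = np.random.default_rng(rng)
    members = np.asarray(sorted(cohort.members), dtype=object)
    idx_all = dmatrix.indices_of(members)
    values = dmatrix.values
    size = cohort.n

    def score(sel: np.ndarray) -> float:
        return mean_pairwise_from_indices(values, idx_all[sel])

    total = total_subcohorts(size)
    out: list[tuple[int, tuple[str, ...], float]] = []
    if total <= reps:
        for n in range(2, size + 1):
            for combo in itertools.combinations(range(size), n):
                sel = np.asarray(combo, dtype=np.intp)
                out.append((n, tuple(members[sel]), score(sel)))
        return out

    seen: set[tuple[int, ...]] = set()
    attempts = 0
    max_attempts = _RESAMPLE_CAP * reps
    while len(out) < reps and len(out) < total and attempts < max_attempts:
        attempts += 1
        n = int(rng.integers(2, size + 1))
        sel = np.sort(rng.choice(size, size=n, replace=False))
        key = tuple(int(i) for i in sel)
        if key in seen:
            continue
        seen.add(key)
        out.append((n, tuple(members[sel]), score(sel)))
    return out


def fraction_below_threshold(values, c: float) -> float:
    """Strict proportion #(value < c) / count."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise GalleryError("no values")
    return float(np.mean(values < c))


def empirical_p_value(cohort_values, null_values) -> float:
    """Add-one empirical p for the cohort median against a null sample.

    T = median of ``cohort_values``; p = (1 + #{null <= T}) / (1 + #null).
    Small distances are the extreme (similar) direction, so the p-value is
    the lower tail.  Never returns 0; returns 1 when T exceeds every null.
    """
    cohort_values = np.asarray(cohort_values, dtype=np.float64)
    null_values = np.asarray(null_values, dtype=np.float64)
    if cohort_values.size == 0 or null_values.size == 0:
        raise GalleryError("empty input to empirical_p_value")
    t = float(np.median(cohort_values))
    return float((1 + np.sum(null_values <= t)) / (1 + null_values.size))


def matched_median_null(dmatrix: DistanceMatrix, pool: list[str], cohort_size: int,
                        n_null: int = 999, reps: int = 200,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Null sample of the cohort-test statistic itself.

    Draws ``n_null`` random cohorts of ``cohort_size`` from ``pool``, runs
    the same sub-cohort resampling on each (``reps`` draws) and returns the
    medians.  Because null cohorts undergo the identical procedure as the
    target cohort, the empirical p-value is uniformly distributed under the
    null by exchangeability.
    """
    rng = np.random.default_rng(rng)
    if cohort_size > len(pool):
        raise GalleryError(f"cohort_size {cohort_size} exceeds pool of {len(pool)}")
    pool_arr = np.asarray(pool, dtype=object)
    medians = np.empty(n_null)
    for i in range(n_null):
        draw = rng.choice(pool_arr, size=cohort_size, replace=False)
        sub = subsample_cohort_distribution(Cohort(tuple(draw)), dmatrix,
                                            reps=reps, rng=rng)
        medians[i] = np.median([v for _, _, v in sub])
    return medians


def run_cohort_test(cohort: Cohort, dmatrix: DistanceMatrix, threshold: float,
                    reps: int = 10_000, rng: np.random.Generator | None = None,
                    null_values=None) -> CohortTestResult:
    """Full cohort test: sub-cohort distribution, threshold fraction, p-value.

    ``null_values`` (e.g. from :func:`matched_median_null`) may be omitted,
    in which case no p-value is reported.
    """
    rng = np.random.default_rng(rng)
    sub = subsample_cohort_distribution(cohort, dmatrix, reps=reps, rng=rng)
    values = np.asarray([v for _, _, v in sub])

    idx = dmatrix.indices_of(cohort.members)
    pair_d = dmatrix.values[np.ix_(idx, idx)][np.triu_indices(cohort.n, k=1)]

    p = None
    if null_values is not None:
        p = empirical_p_value(values, null_values)
    return CohortTestResult(
        subcohort_values=sub,
        fraction_below=fraction_below_threshold(values, threshold),
        pairs_fraction_below=fraction_below_threshold(pair_d, threshold),
        threshold_used=float(threshold),
        empirical_p=p,
        reps_requested=reps,
        reps_obtained=len(sub),
    )
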