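"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's code paths: AUC by explicit
positive-negative pair enumeration, Youden by exhaustive threshold scan,
ranks by sorting the whole competitor list, linkage by naive agglomeration.
"""

import numpy as np


def auc_pair_counting(pos, neg):
    """P(pos < neg) with ties counting 1/2, by full pair enumeration."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p < n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def youden_exhaustive(pos, neg):
    """Best (threshold, sens, spec) over midpoints + sentinels; smallest on ties.

    J is compared as an exact rational (tp/n_pos + tn/n_neg) so thresholds
    that are mathematically tied stay tied under floating point.
    """
    from fractions import Fraction

    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    values = np.unique(np.concatenate([pos, neg]))
    candidates = [values[0]]
    candidates += [(a + b) / 2.0 for a, b in zip(values[:-1], values[1:])]
    candidates += [np.nextafter(values[-1], np.inf)]
    best = None
    for c in candidates:
        tp = int(np.sum(pos < c))
        tn = int(np.sum(neg >= c))
        j = Fraction(tp, len(pos)) + Fraction(tn, len(neg))
        if best is None or j > best[0]:
            best = (j, float(c), tp / len(pos), tn / len(neg))
    return best[1], best[2], best[3]


def rank_by_full_sort(probe_distances, target_pos):
    """Rank of competitor ``target_pos`` by sorting all probe distances.

    Worst rank under ties: position of the last occurrence of the target's
    distance in the ascending sort.
    """
    d = np.asarray(probe_distances, dtype=float)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    target_d = d[target_pos]
    # last index with distance == target_d, 1-based
    return int(np.searchsorted(d_sorted, target_d, side="right"))


def average_linkage_naive(dist):
    """Naive average-linkage agglomeration on a symmetric matrix.

    Returns the merge sequence as (frozenset_a, frozenset_b, height).
    """
    clusters = [frozenset([i]) for i in range(len(dist))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or h < best[0] - 1e-12:
                    best = (h, i, j)
        h, i, j = best
        merges.append((clusters[i], clusters[j], h))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges
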