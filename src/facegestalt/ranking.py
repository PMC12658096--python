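"""Leave-one-out pairwise rank matrix against a background gallery.

For each cohort subject (probe) the remaining cohort members are ranked
within the full image space: the competitor set is the background gallery
plus the probe's cohort-mates (each image exactly once, the probe itself
excluded).  rank(i -> j) = 1 + the number of competitors at least as close
to the probe as the target, ties taking the worst rank — so rank 1 means the
cohort-mate is the single closest image.  The matrix is directed:
rank(i -> j) need not equal rank(j -> i).

Match summaries apply strict cutoffs ("rank below 50" means < 50): a subject
is *matched* when the better of the two directed ranks against any
cohort-mate is below the cutoff, and a pair is *strong* when either directed
rank is below the strong cutoff (default 10).

For display ordering, the directed matrix is symmetrized by the elementwise
minimum and clustered agglomeratively (average linkage by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .gallery import Cohort, Gallery, GalleryError
from .distances import DistanceMatrix

__all__ = [
    "RankMatrix",
    "MatchSummary",
    "ClusterResult",
    "rank_of_match",
    "pairwise_rank_matrix",
    "match_summary",
    "cluster_rank_matrix",
]

DIAG_SENTINEL = 0  # ranks are >= 1, so 0 marks the undefined diagonal


@dataclass(frozen=True)
class RankMatrix:
    """Directed leave-one-out ranks among cohort subjects.

    ``ranks[i, j]`` is the rank of subject j when probing with subject i
    against the background-plus-cohort competitor set; the diagonal holds
    :data:`DIAG_SENTINEL`.  Off-diagonal ranks lie in
    [1, gallery_size + k - 1] where k is the cohort size.
    """

    subject_ids: tuple[str, ...]
    ranks: np.ndarray
    gallery_size: int
    cutoff: int = 50
    strong_cutoff: int = 10

    def __post_init__(self):
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        r = np.asarray(self.ranks, dtype=np.int64)
        k = len(self.subject_ids)
        if r.shape != (k, k):
            raise GalleryError(f"rank matrix shape {r.shape} does not match {k} ids")
        off = r[~np.eye(k, dtype=bool)]
        if k > 1 and (off.min() < 1 or off.max() > self.gallery_size + k - 1):
            raise GalleryError("off-diagonal ranks outside [1, gallery_size + k - 1]")
        object.__setattr__(self, "ranks", r)

    def min_symmetric(self) -> np.ndarray:
        """min(rank(i->j), rank(j->i)) with zero diagonal."""
        s = np.minimum(self.ranks, self.ranks.T)
        np.fill_diagonal(s, 0)
        return s

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("," + ",".join(self.subject_ids) + "\n")
            for sid, row in zip(self.subject_ids, self.ranks):
                fh.write(sid + "," + ",".join(str(int(x)) for x in row) + "\n")


def rank_of_match(probe: str, target: str, competitors: Sequence[str],
                  dmatrix: DistanceMatrix) -> int:
    """Rank of ``target`` among ``competitors`` by distance to ``probe``.

    rank = 1 + #{x != target : d(probe, x) < d(probe, target)}
             + #{x != target : d(probe, x) = d(probe, target)}  (worst rank on ties).
    """
    competitors = list(competitors)
    if probe in competitors:
        raise GalleryError("probe must not be among the competitors")
    if target not in competitors:
        raise GalleryError(f"target {target!r} missing from competitors")
    p = dmatrix.indices_of([probe])[0]
    comp_idx = dmatrix.indices_of(competitors)
    d = dmatrix.values[p, comp_idx]
    d_target = dmatrix.values[p, dmatrix.indices_of([target])[0]]
    # counts the target itself once (d == d_target), which supplies the +1
    return int(np.sum(d <= d_target))


def pairwise_rank_matrix(cohort: Cohort, background: Gallery,
                         dmatrix: DistanceMatrix, cutoff: int = 50,
                         strong_cutoff: int = 10) -> RankMatrix:
    """Directed rank matrix of every cohort subject against every other.

    The competitor set for probe i is the background gallery's images united
    with the probe's cohort-mates, each exactly once and never the probe
    itself.  ``dmatrix`` must cover background and cohort ids (build it on
    ``background.merged_with(cohort_gallery)``).
    """
    k = cohort.n
    if k < 2:
        raise GalleryError("rank matrix needs a cohort of >= 2")
    cohort_set = set(cohort.members)
    base = [x for x in background.image_ids if x not in cohort_set]
    gallery_size = len(base)
    base_idx = dmatrix.indices_of(base) if base else np.empty(0, dtype=np.intp)
    coh_idx = dmatrix.indices_of(cohort.members)
    values = dmatrix.values

    ranks = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        mates = np.delete(coh_idx, i)
        comp = np.concatenate([base_idx, mates])
        d = np.sort(values[coh_idx[i], comp])
        d_mates = values[coh_idx[i], mates]
        r = np.searchsorted(d, d_mates, side="right")  # worst rank under ties
        ranks[i, np.arange(k) != i] = r
    return RankMatrix(tuple(cohort.members), ranks, gallery_size,
                      cutoff=cutoff, strong_cutoff=strong_cutoff)


@dataclass(frozen=True)
class MatchSummary:
    """Cutoff-based match flags derived from a rank matrix."""

    matched_ids: tuple[str, ...]
    matched_count: int
    best_rank: dict[str, int]
    strong_pairs: tuple[tuple[str, str], ...]
    cutoff: int
    strong_cutoff: int

    def to_dict(self) -> dict:
        return {
            "matched_ids": list(self.matched_ids),
            "matched_count": self.matched_count,
            "best_rank": dict(self.best_rank),
            "strong_pairs": [list(p) for p in self.strong_pairs],
            "cutoff": self.cutoff,
            "strong_cutoff": self.strong_cutoff,
        }


def match_summary(rm: RankMatrix, cutoff: int | None = None,
                  strong_cutoff: int | None = None) -> MatchSummary:
    """Per-subject matched flags and strong pairs under strict rank cutoffs.

    Subject i is matched iff min_j min(rank(i->j), rank(j->i)) < cutoff;
    an unordered pair is strong iff either directed rank < strong_cutoff.
    """
    cutoff = rm.cutoff if cutoff is None else cutoff
    strong_cutoff = rm.strong_cutoff if strong_cutoff is None else strong_cutoff
    s = rm.min_symmetric()
    k = len(rm.subject_ids)
    if k < 2:
        raise GalleryError("match summary needs >= 2 subjects")
    off = np.where(np.eye(k, dtype=bool), np.iinfo(np.int64).max, s)
    best = off.min(axis=1)
    matched = tuple(sid for sid, b in zip(rm.subject_ids, best) if b < cutoff)
    strong = tuple(
        (rm.subject_ids[i], rm.subject_ids[j])
        for i in range(k) for j in range(i + 1, k)
        if s[i, j] < strong_cutoff
    )
    return MatchSummary(
        matched_ids=matched,
        matched_count=len(matched),
        best_rank={sid: int(b) for sid, b in zip(rm.subject_ids, best)},
        strong_pairs=strong,
        cutoff=cutoff,
        strong_cutoff=strong_cutoff,
    )


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of the min-symmetrized rank matrix."""

    leaf_order: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]  # scipy linkage rows
    newick: str
    linkage_method: str


def _canonical(node, labels):
    """(min leaf label, leaf order, newick) with children ordered by min label."""
    if node.is_leaf():
        label = labels[node.id]
        return label, [label], label
    left = _canonical(node.get_left(), labels)
    right = _canonical(node.get_right(), labels)
    bl = node.dist - node.get_left().dist
    br = node.dist - node.get_right().dist
    if right[0] < left[0]:  # deterministic rotation: smaller min label first
        left, right = right, left
        bl, br = br, bl
    newick = f"({left[2]}:{bl:g},{right[2]}:{br:g})"
    return left[0], left[1] + right[1], newick


def cluster_rank_matrix(rm: RankMatrix, method: str = "average") -> ClusterResult:
    """Hierarchical clustering of subjects by min-symmetrized ranks.

    Subjects are pre-sorted by id and each internal node puts the subtree
    with the smaller minimal id first, so leaf order is deterministic and
    ties resolve by subject id.  ``method`` is any scipy linkage method;
    average linkage is the default.  The dendrogram is also rendered as a
    Newick string with branch lengths from merge heights.
    """
    k = len(rm.subject_ids)
    if k < 2:
        raise GalleryError("clustering needs >= 2 subjects")
    order = np.argsort(np.asarray(rm.subject_ids, dtype=object))
    ids = [rm.subject_ids[i] for i in order]
    s = rm.min_symmetric()[np.ix_(order, order)].astype(np.float64)
    condensed = squareform(s, checks=False)
    z = hierarchy.linkage(condensed, method=method)
    tree = hierarchy.to_tree(z)
    _, leaf_order, newick = _canonical(tree, ids)
    return ClusterResult(
        leaf_order=tuple(leaf_order),
        merges=tuple((int(a), int(b), float(h), int(c)) for a, b, h, c in z),
        newick=newick + ";",
        linkage_method=method,
    )
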