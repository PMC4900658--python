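"""QC panel construction: marker filtering, grouping, allocation strategies,
uniform genomic spread, panel evaluation, and resampling optimization.

A QC panel is a small ordered subset of SNP markers whose job is to
distinguish every pair of lines in a reference collection.  The selection
pipeline mirrors routine fingerprinting practice:

1.  screen markers on missingness / MAF / heterogeneity / coverage,
2.  group the survivors by PCA + K-means on their call profiles and allocate
    picks across groups (randomly, proportionally, equally, or weighted by
    inter-group distance — the PGD strategy),
3.  optionally enforce uniform genomic spread across chromosomes,
4.  evaluate candidate panels by the proportion of entry pairs they fail to
    distinguish, and
5.  optimize by replicated random resampling, keeping trait-diagnostic
    markers mandatory, then nest a rapid panel inside the broad one.

The fit/transform-shaped stages are exposed as sklearn-style estimators
(:class:`MarkerFilter`, :class:`MarkerGrouper`, :class:`PanelOptimizer`);
the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import chi2 as _chi2
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .marker_stats import MarkerStatsRecord, compute_marker_stats
from .matrix import HET, MISSING, GenotypeMatrix, MarkerRecord, subset as _subset

__all__ = [
    "FilterThresholds",
    "INITIAL_SCREEN",
    "STRINGENT_QC",
    "MarkerFilter",
    "filter_markers",
    "MarkerGroupAssignment",
    "MarkerGrouper",
    "group_markers",
    "allocate_by_strategy",
    "select_uniform_genomic",
    "PanelSpec",
    "PanelEvaluation",
    "evaluate_panel",
    "PanelOptimizer",
    "optimize_panel",
    "select_rapid_panel",
    "TraitAssociationResult",
    "trait_marker_scan",
]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterThresholds:
    """Survival thresholds for marker screening.

    A marker survives iff ``missing_rate <= max_missing``,
    ``maf >= min_maf``, ``het_rate <= max_het``, coverage lies inside
    ``coverage_range`` (when given), and the marker is placed on a chromosome
    (when ``require_placed``).
    """

    max_missing: float = 1.0
    min_maf: float = 0.0
    max_het: float = 1.0
    coverage_range: Optional[Tuple[float, float]] = None
    require_placed: bool = False

    def __post_init__(self) -> None:
        for name in ("max_missing", "min_maf", "max_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage_range is not None:
            lo, hi = self.coverage_range
            if lo > hi:
                raise ValueError("coverage_range low must be <= high")


#: first-pass screen: drop missing > 40%, MAF < 5%, heterogeneity > 10%
INITIAL_SCREEN = FilterThresholds(max_missing=0.40, min_maf=0.05, max_het=0.10)

#: stringent QC-candidate rules: coverage 2-15, missing < 20%,
#: heterogeneity < 6%, chromosome position required
STRINGENT_QC = FilterThresholds(
    max_missing=0.20, max_het=0.06, coverage_range=(2.0, 15.0), require_placed=True
)


class MarkerFilter(TransformerMixin, BaseEstimator):
    """Threshold-based marker screen as a transformer.

    Parameters mirror :class:`FilterThresholds`.  ``fit`` takes a
    :class:`GenotypeMatrix` (statistics computed internally) or a
    precomputed list of :class:`MarkerStatsRecord`; ``transform`` subsets a
    matrix to the surviving markers.

    Attributes
    ----------
    survivors_ : list of str
        Marker ids passing every rule, in input order.
    removed_ : dict
        marker_id -> list of failed rule names.
    """

    def __init__(
        self,
        max_missing: float = 1.0,
        min_maf: float = 0.0,
        max_het: float = 1.0,
        coverage_range: Optional[Tuple[float, float]] = None,
        require_placed: bool = False,
    ) -> None:
        self.max_missing = max_missing
        self.min_maf = min_maf
        self.max_het = max_het
        self.coverage_range = coverage_range
        self.require_placed = require_placed

    @classmethod
    def from_thresholds(cls, thresholds: FilterThresholds) -> "MarkerFilter":
        return cls(
            max_missing=thresholds.max_missing,
            min_maf=thresholds.min_maf,
            max_het=thresholds.max_het,
            coverage_range=thresholds.coverage_range,
            require_placed=thresholds.require_placed,
        )

    def fit(self, X, y=None, placed: Optional[Mapping[str, bool]] = None):
        if isinstance(X, GenotypeMatrix):
            stats = compute_marker_stats(X)
            placed = {m.marker_id: m.placed for m in X.markers}
        else:
            stats = list(X)
        if self.require_placed and placed is None:
            raise ValueError(
                "require_placed needs marker placement info; pass a "
                "GenotypeMatrix or the `placed` mapping"
            )
        survivors: List[str] = []
        removed: Dict[str, List[str]] = {}
        for s in stats:
            fails: List[str] = []
            if s.all_missing:
                fails.append("all_missing")
            else:
                if s.missing_rate > self.max_missing:
                    fails.append("missing_rate")
                if s.maf < self.min_maf:
                    fails.append("maf")
                if s.het_rate > self.max_het:
                    fails.append("het_rate")
                if self.coverage_range is not None:
                    if s.coverage is None:
                        raise ValueError(
                            f"marker {s.marker_id}: coverage filter requested "
                            "but no depth information available"
                        )
                    lo, hi = self.coverage_range
                    if not lo <= s.coverage <= hi:
                        fails.append("coverage")
                if self.require_placed and not placed[s.marker_id]:
                    fails.append("unplaced")
            if fails:
                removed[s.marker_id] = fails
            else:
                survivors.append(s.marker_id)
        self.survivors_ = survivors
        self.removed_ = removed
        return self

    def transform(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        return _subset(gm, marker_ids=self.survivors_)


def filter_markers(
    stats: Sequence[MarkerStatsRecord],
    thresholds: FilterThresholds,
    placed: Optional[Mapping[str, bool]] = None,
) -> Tuple[List[str], Dict[str, List[str]]]:
    """Apply screening rules; returns (survivor ids, removal report)."""
    f = MarkerFilter.from_thresholds(thresholds).fit(stats, placed=placed)
    return f.survivors_, f.removed_


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

@dataclass
class MarkerGroupAssignment:
    """K-means partition of markers with centroid geometry.

    ``assignment`` maps marker_id to a group id in 1..k; ``distance_scores``
    holds, per group, the mean Euclidean distance from its centroid to every
    other group centroid (the PGD weight).
    """

    assignment: Dict[str, int]
    centroids: np.ndarray
    distance_scores: np.ndarray

    @property
    def k(self) -> int:
        return len(self.distance_scores)

    def members(self, group: int) -> List[str]:
        return [mid for mid, g in self.assignment.items() if g == group]


class MarkerGrouper(BaseEstimator):
    """PCA + K-means grouping of markers by their call profiles.

    Markers are the observations and entries the variables: calls are coded
    as minor-allele dosage 0/1/2, missing values mean-imputed per marker,
    centered (not scaled), projected onto ``n_components`` principal
    components and partitioned by K-means with ``n_init`` restarts.
    """

    def __init__(
        self,
        k: int = 5,
        n_components: int = 3,
        random_state: Optional[int] = None,
        n_init: int = 10,
    ) -> None:
        self.k = k
        self.n_components = n_components
        self.random_state = random_state
        self.n_init = n_init

    def fit(self, gm: GenotypeMatrix, candidate_ids: Optional[Sequence[str]] = None):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        sub = gm if candidate_ids is None else _subset(gm, marker_ids=list(candidate_ids))
        if sub.n_markers < self.k:
            raise ValueError(f"{sub.n_markers} candidates < k={self.k}")
        X = sub.calls.astype(float)
        X[sub.calls == MISSING] = np.nan
        row_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=1)
        row_means = np.where(np.isnan(row_means), 0.0, row_means)
        idx = np.where(np.isnan(X))
        X[idx] = row_means[idx[0]]
        n_distinct = np.unique(X, axis=0).shape[0]
        if n_distinct < self.k:
            raise ValueError(
                f"only {n_distinct} distinct marker profiles for k={self.k} groups"
            )
        ncomp = min(self.n_components, X.shape[0], X.shape[1])
        pcs = PCA(n_components=ncomp, random_state=self.random_state).fit_transform(X)
        km = KMeans(
            n_clusters=self.k,
            n_init=max(self.n_init, 10),
            random_state=self.random_state,
        ).fit(pcs)
        centroids = km.cluster_centers_
        k = self.k
        scores = np.empty(k)
        for g in range(k):
            others = np.delete(np.arange(k), g)
            scores[g] = np.linalg.norm(centroids[others] - centroids[g], axis=1).mean()
        self.assignment_ = MarkerGroupAssignment(
            assignment={
                m.marker_id: int(lab) + 1 for m, lab in zip(sub.markers, km.labels_)
            },
            centroids=centroids,
            distance_scores=scores,
        )
        self.embedding_ = pcs
        return self


def group_markers(
    gm: GenotypeMatrix,
    candidate_ids: Optional[Sequence[str]],
    k: int,
    n_components: int,
    seed: Optional[int] = None,
) -> MarkerGroupAssignment:
    """Partition candidate markers into k groups; see :class:`MarkerGrouper`."""
    return (
        MarkerGrouper(k=k, n_components=n_components, random_state=seed)
        .fit(gm, candidate_ids)
        .assignment_
    )


# ---------------------------------------------------------------------------
# allocation strategies
# ---------------------------------------------------------------------------

def _apportion(
    weights: Sequence[float],
    total: int,
    caps: Sequence[int],
    ensure_min_one: bool,
) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` seats with capacities."""
    k = len(weights)
    caps = np.asarray(caps, dtype=int)
    if total > caps.sum():
        raise ValueError(f"cannot allocate {total} from capacity {caps.sum()}")
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones(k)
    shares = total * w / w.sum()
    counts = np.minimum(np.floor(shares).astype(int), caps)
    remainders = shares - np.floor(shares)
    while counts.sum() < total:
        order = sorted(range(k), key=lambda i: (-remainders[i], i))
        for i in order:
            if counts[i] < caps[i]:
                counts[i] += 1
                remainders[i] -= 1.0  # demote after each award so seats rotate
                break
    if ensure_min_one and total >= k:
        for i in range(k):
            if counts[i] == 0 and caps[i] > 0:
                donor = int(np.argmax(counts))
                if counts[donor] > 1:
                    counts[donor] -= 1
                    counts[i] += 1
    return counts


STRATEGIES = ("RANDOM", "PG", "NG", "PGD")


def allocate_by_strategy(
    groups: MarkerGroupAssignment,
    total: int,
    strategy: str,
    seed: Optional[int] = None,
) -> Tuple[Dict[int, int], List[str]]:
    """Allocate a marker budget across groups and sample within them.

    Strategies: ``RANDOM`` ignores grouping entirely; ``PG`` allocates
    proportionally to group sizes; ``NG`` splits equally; ``PGD``
    proportionally to each group's mean distance to the other group
    centroids.  Counts sum to ``total`` (largest-remainder rounding, every
    group getting at least one pick when the budget allows); within-group
    sampling is uniform without replacement.

    Returns (counts per group id, sampled marker ids).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    rng = np.random.default_rng(seed)
    all_ids = list(groups.assignment.keys())
    if total > len(all_ids):
        raise ValueError(f"total {total} exceeds candidate count {len(all_ids)}")
    if strategy == "RANDOM":
        picked = list(rng.choice(all_ids, size=total, replace=False))
        counts: Dict[int, int] = {g: 0 for g in range(1, groups.k + 1)}
        for mid in picked:
            counts[groups.assignment[mid]] += 1
        return counts, picked
    member_lists = {g: groups.members(g) for g in range(1, groups.k + 1)}
    caps = [len(member_lists[g]) for g in range(1, groups.k + 1)]
    if strategy == "PG":
        weights = [float(c) for c in caps]
    elif strategy == "NG":
        weights = [1.0] * groups.k
    else:  # PGD
        weights = list(groups.distance_scores)
    counts_arr = _apportion(weights, total, caps, ensure_min_one=True)
    picked = []
    for g in range(1, groups.k + 1):
        c = int(counts_arr[g - 1])
        if c:
            picked.extend(rng.choice(member_lists[g], size=c, replace=False))
    return {g: int(counts_arr[g - 1]) for g in range(1, groups.k + 1)}, picked


# ---------------------------------------------------------------------------
# uniform genomic spread
# ---------------------------------------------------------------------------

def select_uniform_genomic(
    markers: Sequence[MarkerRecord],
    total: int,
    chrom_lengths: Optional[Mapping[str, float]] = None,
) -> List[str]:
    """Pick ``total`` markers spread evenly along the genome.

    Chromosome quotas are proportional to chromosome length (largest
    remainder; length defaults to the maximum marker position).  Each
    chromosome is split into quota equal-width bins; per bin the marker
    nearest the bin midpoint wins (ties to the lower position).  Empty bins
    forfeit their pick to the nearest bin that still has unselected markers.
    """
    unplaced = [m.marker_id for m in markers if not m.placed]
    if unplaced:
        raise ValueError(f"unplaced markers cannot be spread: {unplaced[:5]}")
    if total > len(markers):
        raise ValueError(f"requested {total} markers from {len(markers)} placed")
    by_chrom: Dict[str, List[MarkerRecord]] = {}
    for m in markers:
        by_chrom.setdefault(m.chrom, []).append(m)
    chroms = list(by_chrom)
    spans = {
        c: float(chrom_lengths[c]) if chrom_lengths else max(m.pos for m in by_chrom[c])
        for c in chroms
    }
    caps = [len(by_chrom[c]) for c in chroms]
    quotas = _apportion([spans[c] for c in chroms], total, caps, ensure_min_one=False)
    selected: List[str] = []
    for c, quota in zip(chroms, quotas):
        q = int(quota)
        if q == 0:
            continue
        span = spans[c]
        width = span / q
        bins: List[List[MarkerRecord]] = [[] for _ in range(q)]
        for m in sorted(by_chrom[c], key=lambda r: r.pos):
            b = min(int(np.ceil(m.pos / width)) - 1, q - 1)
            bins[max(b, 0)].append(m)
        taken = set()

        def nearest(pool: List[MarkerRecord], midpoint: float) -> Optional[MarkerRecord]:
            best = None
            for m in pool:
                if m.marker_id in taken:
                    continue
                key = (abs(m.pos - midpoint), m.pos)
                if best is None or key < best[0]:
                    best = (key, m)
            return best[1] if best else None

        deferred = []
        for b in range(q):
            midpoint = (b + 0.5) * width
            pick = nearest(bins[b], midpoint)
            if pick is None:
                deferred.append((b, midpoint))
            else:
                taken.add(pick.marker_id)
                selected.append(pick.marker_id)
        for b, midpoint in deferred:
            # forfeit to nearest bin with spare markers
            order = sorted(range(q), key=lambda j: (abs(j - b), j))
            for j in order:
                pick = nearest(bins[j], midpoint)
                if pick is not None:
                    taken.add(pick.marker_id)
                    selected.append(pick.marker_id)
                    break
    return selected


# ---------------------------------------------------------------------------
# panel evaluation
# ---------------------------------------------------------------------------

@dataclass
class PanelSpec:
    """An ordered marker subset, with trait-diagnostic markers mandatory."""

    markers: List[str]
    mandatory: List[str] = field(default_factory=list)
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate markers in panel")
        missing = set(self.mandatory) - set(self.markers)
        if missing:
            raise ValueError(f"mandatory markers not in panel: {sorted(missing)}")

    @property
    def size(self) -> int:
        return len(self.markers)


@dataclass
class PanelEvaluation:
    """Discrimination profile of a panel over all unordered entry pairs."""

    undistinguished_pair_proportion: float
    undistinguished_pairs: List[Tuple[str, str]]
    pair_mismatch_counts: Dict[Tuple[str, str], int]
    min_mismatch: int
    mean_mismatch: float


def _pair_mismatch_counts(calls: np.ndarray) -> np.ndarray:
    """n x n matrix of jointly non-missing, differing call counts."""
    n = calls.shape[1]
    if calls.shape[0] == 0:
        return np.zeros((n, n), dtype=int)
    present = (calls != MISSING).astype(np.float64)
    joint = present.T @ present
    matches = np.zeros_like(joint)
    for state in (0, 1, 2):
        ind = (calls == state).astype(np.float64)
        matches += ind.T @ ind
    return np.rint(joint - matches).astype(int)


def evaluate_panel(gm: GenotypeMatrix, panel: PanelSpec) -> PanelEvaluation:
    """Count, per entry pair, the panel markers that tell the pair apart.

    A pair is *undistinguished* when no jointly non-missing panel marker
    differs between the two entries — including pairs with no marker overlap
    at all, which is the conservative reading for QC.
    """
    sub = _subset(gm, marker_ids=panel.markers) if panel.markers else None
    calls = sub.calls if sub is not None else np.zeros((0, gm.n_entries), dtype=np.int8)
    mm = _pair_mismatch_counts(calls)
    labels = gm.entries
    n = len(labels)
    counts: Dict[Tuple[str, str], int] = {}
    undist: List[Tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            c = int(mm[i, j])
            counts[(labels[i], labels[j])] = c
            if c == 0:
                undist.append((labels[i], labels[j]))
    total_pairs = n * (n - 1) // 2
    vals = np.fromiter(counts.values(), dtype=int, count=total_pairs)
    return PanelEvaluation(
        undistinguished_pair_proportion=len(undist) / total_pairs,
        undistinguished_pairs=undist,
        pair_mismatch_counts=counts,
        min_mismatch=int(vals.min()) if total_pairs else 0,
        mean_mismatch=float(vals.mean()) if total_pairs else 0.0,
    )


# ---------------------------------------------------------------------------
# resampling optimization
# ---------------------------------------------------------------------------

class PanelOptimizer(TransformerMixin, BaseEstimator):
    """Replicated random resampling of marker subsets, ranked by power.

    Each of ``reps`` replicates draws a ``size``-marker subset from the
    candidates (always containing the mandatory trait markers), evaluates it
    over all entry pairs, and the replicates are ranked: subsets that
    distinguish every pair come first, ordered by descending minimum pairwise
    mismatch count, then descending mean, then draw order; otherwise by
    ascending undistinguished-pair proportion with the same tie-breaks.

    Attributes
    ----------
    panels_ : list of PanelSpec, best first
    evaluations_ : list of PanelEvaluation, aligned with panels_
    best_panel_ : PanelSpec
    """

    def __init__(
        self,
        size: int,
        reps: int = 2000,
        mandatory: Optional[Sequence[str]] = None,
        random_state: Optional[int] = None,
    ) -> None:
        self.size = size
        self.reps = reps
        self.mandatory = mandatory
        self.random_state = random_state

    def fit(self, gm: GenotypeMatrix, candidates: Optional[Sequence[str]] = None):
        candidates = list(candidates) if candidates is not None else gm.marker_ids
        mandatory = list(self.mandatory) if self.mandatory else []
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.size > len(candidates):
            raise ValueError(f"size {self.size} > {len(candidates)} candidates")
        if self.size < len(mandatory):
            raise ValueError("size smaller than the mandatory marker set")
        unknown = set(mandatory) - set(candidates)
        if unknown:
            raise ValueError(f"mandatory markers not among candidates: {sorted(unknown)}")
        sub = _subset(gm, marker_ids=candidates)
        free = [c for c in candidates if c not in set(mandatory)]
        n_draw = self.size - len(mandatory)
        rng = np.random.default_rng(self.random_state)
        pos = {mid: i for i, mid in enumerate(candidates)}
        results = []
        seen = set()
        for rep in range(self.reps):
            drawn = (
                list(rng.choice(free, size=n_draw, replace=False)) if n_draw else []
            )
            ids = mandatory + sorted(drawn, key=pos.__getitem__)
            key = frozenset(ids)
            if key in seen:
                continue
            seen.add(key)
            rows = [pos[m] for m in ids]
            mm = _pair_mismatch_counts(sub.calls[rows])
            iu = np.triu_indices(sub.n_entries, k=1)
            vals = mm[iu]
            prop = float(np.count_nonzero(vals == 0)) / len(vals)
            results.append((prop, int(vals.min()), float(vals.mean()), rep, ids))
        results.sort(key=lambda r: (r[0], -r[1], -r[2], r[3]))
        self.panels_ = []
        self.evaluations_ = []
        for prop, _mn, _mean, rep, ids in results:
            spec = PanelSpec(markers=ids, mandatory=mandatory, name=f"rep{rep}")
            self.panels_.append(spec)
            self.evaluations_.append(evaluate_panel(sub, spec))
        self.best_panel_ = self.panels_[0]
        return self

    def transform(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        return _subset(gm, marker_ids=self.best_panel_.markers)


def optimize_panel(
    gm: GenotypeMatrix,
    candidates: Sequence[str],
    size: int,
    reps: int,
    mandatory: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
) -> Tuple[List[PanelSpec], List[PanelEvaluation]]:
    """Ranked resampled panels; see :class:`PanelOptimizer`."""
    opt = PanelOptimizer(
        size=size, reps=reps, mandatory=mandatory, random_state=seed
    ).fit(gm, candidates)
    return opt.panels_, opt.evaluations_


def select_rapid_panel(
    gm: GenotypeMatrix,
    broad: PanelSpec,
    size: int,
    reps: int,
    seed: Optional[int] = None,
    mandatory: Optional[Sequence[str]] = None,
) -> Tuple[List[PanelSpec], List[PanelEvaluation]]:
    """Resample a small rapid-QC panel nested inside the broad panel."""
    if size > broad.size:
        raise ValueError("rapid panel cannot exceed the broad panel size")
    return optimize_panel(
        gm, broad.markers, size=size, reps=reps, mandatory=mandatory, seed=seed
    )


# ---------------------------------------------------------------------------
# trait-marker association scan
# ---------------------------------------------------------------------------

@dataclass
class TraitAssociationResult:
    marker_id: str
    statistic: float
    p_value: float
    trait: str


def trait_marker_scan(
    gm: GenotypeMatrix,
    trait_values: Mapping[str, int],
    trait_name: str = "trait",
) -> Tuple[List[TraitAssociationResult], TraitAssociationResult]:
    """Case-control allele association scan over all markers.

    Per marker a 2x2 allele-count table (trait class x allele; homozygotes
    contribute two copies, heterogeneous calls one of each) is tested with
    the Pearson chi-square statistic (1 df, no continuity correction).
    Markers monomorphic in the pooled classes score 0 with p = 1.  Returns
    all results plus the best marker (smallest p, ties to the larger
    statistic, then marker order).
    """
    case_entries = [e for e in gm.entries if trait_values.get(e) == 1]
    ctrl_entries = [e for e in gm.entries if trait_values.get(e) == 0]
    if not case_entries or not ctrl_entries:
        raise ValueError("both trait classes must be non-empty")
    case_idx = [gm.entry_index(e) for e in case_entries]
    ctrl_idx = [gm.entry_index(e) for e in ctrl_entries]
    results = []
    for i, m in enumerate(gm.markers):
        row = gm.calls[i]
        cells = []
        for idx in (case_idx, ctrl_idx):
            sel = row[idx]
            ok = sel != MISSING
            minor = int(sel[ok].sum())
            major = 2 * int(np.count_nonzero(ok)) - minor
            cells.append((major, minor))
        (a, b), (c, d) = cells
        n = a + b + c + d
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        if 0 in (r1, r2, c1, c2) or n == 0:
            stat, p = 0.0, 1.0
        else:
            stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
            p = float(_chi2.sf(stat, df=1))
        results.append(TraitAssociationResult(m.marker_id, float(stat), p, trait_name))
    best = min(enumerate(results), key=lambda t: (t[1].p_value, -t[1].statistic, t[0]))[1]
    return results, best
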