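"""Blind-test identity verification and entry purity assessment.

Given a reference collection genotyped on a QC panel, a query profile is
assigned to its most similar reference entry (allele-sharing similarity).  A
query whose declared label disagrees with its best match is flagged as
mislabeled.  Entry purity is assessed by genotyping many individuals per
entry and counting *off-types* — individuals whose panel calls deviate from
the entry's reference profile beyond a per-individual mismatch tolerance; an
entry passes QC when the off-type count stays at or below a threshold
(default two per entry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .matrix import HET, MISSING, GenotypeMatrix, subset as _subset

__all__ = [
    "IdentityAssignment",
    "IdentityClassifier",
    "assign_identity",
    "heterogeneity_check",
    "EntryPurityReport",
    "count_off_types",
    "align_to_reference",
]

#: absolute similarity tie window below which a top match is ambiguous
TIE_TOLERANCE = 1e-9


def align_to_reference(query: GenotypeMatrix, reference: GenotypeMatrix,
                       marker_ids: Sequence[str]) -> np.ndarray:
    """Query calls re-oriented onto the reference's major/minor axes.

    Returns a (n_markers, n_query_entries) call array.  Markers whose allele
    pair differs between query and reference raise; markers whose major/minor
    orientation is swapped are recoded.
    """
    rows = np.empty((len(marker_ids), query.n_entries), dtype=np.int8)
    for i, mid in enumerate(marker_ids):
        rm = reference.markers[reference.marker_index(mid)]
        qm = query.markers[query.marker_index(mid)]
        row = query.calls[query.marker_index(mid)].copy()
        if qm.allele_pair != rm.allele_pair:
            raise ValueError(
                f"marker {mid}: allele pair mismatch between query and reference"
            )
        if qm.allele_major != rm.allele_major:
            hom = (row == 0) | (row == 2)
            row[hom] = 2 - row[hom]
        rows[i] = row
    return rows


@dataclass
class IdentityAssignment:
    """Outcome of one blind-test identity query."""

    query: str
    ranking: List[Tuple[str, float]]  # (reference label, similarity), best first
    best_match: str
    best_similarity: float
    markers_used: Dict[str, int]  # per reference entry
    verdict: str  # MATCH / MISLABELED / AMBIGUOUS
    expected: Optional[str] = None
    dropped_references: List[str] = field(default_factory=list)


class IdentityClassifier(BaseEstimator):
    """Nearest-reference classifier over allele-sharing similarity.

    ``fit`` stores the reference collection restricted to the QC panel;
    ``predict`` returns the best-matching reference label for each query
    entry, and :meth:`assign` the full ranked report with a
    MATCH / MISLABELED / AMBIGUOUS verdict against an expected label.
    """

    def __init__(self, panel: Optional[Sequence[str]] = None,
                 tie_tolerance: float = TIE_TOLERANCE) -> None:
        self.panel = panel
        self.tie_tolerance = tie_tolerance

    def fit(self, reference: GenotypeMatrix, y=None):
        panel = list(self.panel) if self.panel is not None else reference.marker_ids
        self.panel_ = panel
        self.reference_ = _subset(reference, marker_ids=panel)
        return self

    def _assign_one(self, calls: np.ndarray, label: str,
                    expected: Optional[str]) -> IdentityAssignment:
        if np.all(calls == MISSING):
            raise ValueError(f"query {label!r} has no usable call on the panel")
        ref = self.reference_
        sims: List[Tuple[str, float]] = []
        used: Dict[str, int] = {}
        dropped: List[str] = []
        q = calls.astype(float)
        q[calls == MISSING] = np.nan
        for j, ref_label in enumerate(ref.entries):
            r = ref.calls[:, j].astype(float)
            r[ref.calls[:, j] == MISSING] = np.nan
            diff = np.abs(q - r)
            ok = ~np.isnan(diff)
            m = int(np.count_nonzero(ok))
            if m == 0:
                dropped.append(ref_label)
                warnings.warn(
                    f"reference {ref_label!r} shares no usable panel marker "
                    f"with query {label!r}; dropped from ranking"
                )
                continue
            used[ref_label] = m
            shared = 2 * m - float(diff[ok].sum())
            sims.append((ref_label, shared / (2 * m)))
        if not sims:
            raise ValueError(f"query {label!r}: no reference entry comparable")
        sims.sort(key=lambda t: (-t[1], t[0]))
        best_label, best_sim = sims[0]
        if len(sims) > 1 and abs(sims[1][1] - best_sim) <= self.tie_tolerance:
            verdict = "AMBIGUOUS"
        elif expected is not None and expected != best_label:
            verdict = "MISLABELED"
        else:
            verdict = "MATCH"
        return IdentityAssignment(
            query=label,
            ranking=sims,
            best_match=best_label,
            best_similarity=best_sim,
            markers_used=used,
            verdict=verdict,
            expected=expected,
            dropped_references=dropped,
        )

    def assign(self, query: GenotypeMatrix,
               expected: Optional[Dict[str, str]] = None) -> List[IdentityAssignment]:
        """Full blind-test report for every query entry.

        ``expected`` maps query labels to their declared reference identity;
        by default the query's own label is used when it exists in the
        reference collection.
        """
        calls = align_to_reference(query, self.reference_, self.panel_)
        out = []
        ref_labels = set(self.reference_.entries)
        for j, label in enumerate(query.entries):
            if expected is not None:
                exp = expected.get(label)
            else:
                exp = label if label in ref_labels else None
            out.append(self._assign_one(calls[:, j], label, exp))
        return out

    def predict(self, query: GenotypeMatrix) -> List[str]:
        """Best-matching reference label per query entry."""
        return [a.best_match for a in self.assign(query, expected={})]


def assign_identity(
    query: GenotypeMatrix,
    query_label: str,
    reference: GenotypeMatrix,
    panel: Sequence[str],
    expected: Optional[str] = None,
) -> IdentityAssignment:
    """Blind-test one query profile against a reference collection."""
    clf = IdentityClassifier(panel=panel).fit(reference)
    sub = _subset(query, entry_labels=[query_label])
    return clf.assign(sub, expected={query_label: expected})[0]


def heterogeneity_check(
    profile: np.ndarray, threshold: float
) -> Tuple[float, bool]:
    """Residual heterogeneity of one profile: #HET / #non-missing calls.

    Returns (rate, flagged); flagged when the rate exceeds the threshold.
    """
    profile = np.asarray(profile)
    ok = profile != MISSING
    n = int(np.count_nonzero(ok))
    if n == 0:
        raise ValueError("profile has no non-missing call")
    rate = int(np.count_nonzero(profile[ok] == HET)) / n
    return rate, rate > threshold


@dataclass
class EntryPurityReport:
    """Off-type census for one entry's individuals on a QC panel."""

    entry: str
    n_individuals: int
    off_type_count: int
    off_type_individuals: List[str]
    excluded_individuals: List[str]
    heterogeneity_rate: float
    threshold: int
    passed: bool


def count_off_types(
    individuals: GenotypeMatrix,
    reference: GenotypeMatrix,
    reference_entry: str,
    panel: Sequence[str],
    mismatch_tolerance: int = 1,
    threshold: int = 2,
    entry_label: Optional[str] = None,
) -> EntryPurityReport:
    """Count off-type individuals within one entry and apply the QC gate.

    An individual is an off-type when its count of jointly non-missing panel
    calls differing from the entry's reference profile exceeds
    ``mismatch_tolerance`` (default 1, absorbing a single genotyping error).
    The entry passes when at most ``threshold`` off-types are found (default
    2).  Individuals with zero usable panel calls are excluded and reported.
    """
    if individuals.n_entries == 0:
        raise ValueError("no individuals supplied")
    ref_sub = _subset(reference, marker_ids=list(panel))
    ref_profile = ref_sub.entry_calls(reference_entry).astype(float)
    ref_profile[ref_profile == MISSING] = np.nan
    calls = align_to_reference(individuals, ref_sub, list(panel)).astype(float)
    calls[calls == MISSING] = np.nan
    off: List[str] = []
    excluded: List[str] = []
    n_het = 0
    n_calls = 0
    for j, label in enumerate(individuals.entries):
        col = calls[:, j]
        usable = ~np.isnan(col)
        n_calls += int(np.count_nonzero(usable))
        n_het += int(np.count_nonzero(col[usable] == HET))
        diff = np.abs(col - ref_profile)
        ok = ~np.isnan(diff)
        if not ok.any():
            excluded.append(label)
            continue
        mismatches = int(np.count_nonzero(diff[ok] > 0))
        if mismatches > mismatch_tolerance:
            off.append(label)
    n_counted = individuals.n_entries - len(excluded)
    if n_counted == 0:
        raise ValueError("every individual lacked usable panel calls")
    return EntryPurityReport(
        entry=entry_label or reference_entry,
        n_individuals=n_counted,
        off_type_count=len(off),
        off_type_individuals=off,
        excluded_individuals=excluded,
        heterogeneity_rate=n_het / n_calls if n_calls else float("nan"),
        threshold=threshold,
        passed=len(off) <= threshold,
    )
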