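"""Pairwise identity metrics between entries: allele-sharing distance,
blind-test similarity, complete-linkage clustering, and principal coordinate
embedding.

The allele-sharing distance at one locus is ``2 - (number of shared
alleles)`` between the two unordered diploid genotypes, averaged over loci
that are non-missing in both entries; it ranges from 0 (identical) to 2
(opposite homozygotes everywhere).  Similarity is its complement on the same
marker set: shared alleles divided by total compared alleles, so
``similarity = 1 - distance / 2`` exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .matrix import MISSING, GenotypeMatrix, subset as _subset

__all__ = [
    "shared_alleles",
    "allele_sharing_distance",
    "similarity",
    "SimilarityScore",
    "DistanceMatrix",
    "cluster_tree",
    "pcoa",
    "PCoAResult",
]


def shared_alleles(call_a: int, call_b: int) -> int:
    """Alleles shared between two unordered diploid calls at one marker.

    With calls coded as minor-allele dosage this is ``2 - |a - b|``:
    AA/AA -> 2, AA/AB -> 1, AA/BB -> 0, AB/AB -> 2.
    """
    if call_a == MISSING or call_b == MISSING:
        raise ValueError("shared_alleles requires non-missing calls")
    return 2 - abs(int(call_a) - int(call_b))


@dataclass
class DistanceMatrix:
    """Symmetric allele-sharing distances with per-pair marker counts.

    ``values[i, j]`` is NaN for pairs with no jointly non-missing marker —
    their identity is unknown, not zero.
    """

    labels: List[str]
    values: np.ndarray
    counts: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    def undefined_pairs(self) -> List[tuple]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.counts[i, j] == 0:
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def allele_sharing_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Mean per-locus allele-sharing distance over jointly non-missing loci."""
    if gm.n_entries < 2:
        raise ValueError("need at least two entries")
    calls = gm.calls.astype(float)
    calls[gm.calls == MISSING] = np.nan
    n = gm.n_entries
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = int(np.count_nonzero(~np.isnan(calls[:, i])))
        for j in range(i + 1, n):
            diff = np.abs(calls[:, i] - calls[:, j])
            ok = ~np.isnan(diff)
            m = int(np.count_nonzero(ok))
            counts[i, j] = counts[j, i] = m
            d = float(diff[ok].mean()) if m else np.nan
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(gm.entries), values, counts)


@dataclass
class SimilarityScore:
    entry_a: str
    entry_b: str
    similarity: float
    markers_used: int


def similarity(
    gm: GenotypeMatrix,
    entry_a: str,
    entry_b: str,
    panel: Optional[Sequence[str]] = None,
) -> SimilarityScore:
    """Blind-test similarity: identical alleles / compared alleles on a panel.

    Equals ``1 - allele_sharing_distance / 2`` over the same markers.  Raises
    ``ValueError`` when the two entries share no usable marker.
    """
    sub = gm if panel is None else _subset(gm, marker_ids=list(panel))
    a = sub.entry_calls(entry_a).astype(float)
    b = sub.entry_calls(entry_b).astype(float)
    a[a == MISSING] = np.nan
    b[b == MISSING] = np.nan
    diff = np.abs(a - b)
    ok = ~np.isnan(diff)
    m = int(np.count_nonzero(ok))
    if m == 0:
        raise ValueError(
            f"similarity undefined: {entry_a!r} and {entry_b!r} share no "
            "jointly non-missing marker on this panel"
        )
    shared = 2 * m - float(diff[ok].sum())
    return SimilarityScore(entry_a, entry_b, shared / (2 * m), m)


# ---------------------------------------------------------------------------
# complete-linkage tree
# ---------------------------------------------------------------------------

def cluster_tree(dm: DistanceMatrix) -> str:
    """Complete-linkage agglomerative tree as a Newick string.

    Branch lengths are parent merge height minus child height (leaves at 0).
    Children of each internal node are ordered by their lexicographically
    smallest leaf label, so output is reproducible across input orderings.
    """
    undef = dm.undefined_pairs()
    if undef:
        raise ValueError(
            f"{len(undef)} entry pairs have no shared markers (e.g. {undef[0]}); "
            "expand the marker set before clustering"
        )
    z = linkage(squareform(dm.values, checks=False), method="complete")
    n = dm.n
    # node -> (newick string without trailing length, height, min leaf label)
    nodes = {i: (dm.labels[i], 0.0, dm.labels[i]) for i in range(n)}
    for k, (a, b, height, _) in enumerate(z):
        na, nb = nodes.pop(int(a)), nodes.pop(int(b))
        children = sorted((na, nb), key=lambda t: t[2])
        parts = [f"{s}:{height - h:g}" for s, h, _ in children]
        nodes[n + k] = ("(" + ",".join(parts) + ")", float(height), children[0][2])
    (s, _, _), = nodes.values()
    return s + ";"


# ---------------------------------------------------------------------------
# principal coordinate analysis
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # entries x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_warning: bool

    def to_tsv(self, path: str, labels: Optional[Sequence[str]] = None) -> str:
        df = self.coordinates.copy()
        if labels is not None:
            df["label"] = list(labels)
        df.to_csv(path, sep="\t", index_label="entry")
        return path


def pcoa(dm: DistanceMatrix, n_axes: int) -> PCoAResult:
    """Classical metric scaling of the allele-sharing distance matrix.

    Axes are ordered by descending eigenvalue.  A warning flag is set when
    negative-eigenvalue mass reaches into the requested axes (the distances
    are then not fully Euclidean-embeddable at this rank).
    """
    if dm.undefined_pairs():
        raise ValueError("PCoA requires all pairwise distances defined")
    if not 0 < n_axes < dm.n:
        raise ValueError("n_axes must be in [1, n_entries)")
    from skbio import DistanceMatrix as _SkbioDM
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(_SkbioDM(dm.values, ids=dm.labels), method="eigh")
    eig = res.eigvals.values
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.columns = [f"PCo{i + 1}" for i in range(n_axes)]
    neg_warn = bool((eig[:n_axes] < -1e-8 * max(abs(eig[0]), 1.0)).any())
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eig,
        proportion_explained=res.proportion_explained.values,
        negative_eigenvalue_warning=neg_warn,
    )
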