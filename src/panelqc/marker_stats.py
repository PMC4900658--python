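"""Per-marker informativeness statistics and pairwise linkage disequilibrium.

The statistics mirror standard marker-screening practice for inbred
germplasm: minor allele frequency (MAF), residual heterogeneity (fraction of
non-homozygous calls), missing rate, polymorphic information content (PIC,
biallelic Botstein form), mean read coverage, and the transition/transversion
class of the SNP.  Allele counting treats each homozygote as two copies of its
allele and each heterogeneous call as one copy of each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import HET, HOM_MAJOR, HOM_MINOR, MISSING, GenotypeMatrix

__all__ = [
    "MarkerStatsRecord",
    "compute_marker_stats",
    "stats_frame",
    "mutation_class_summary",
    "mutation_class",
    "pic_biallelic",
    "ld_r2",
    "MONOMORPHIC",
]

MUTATION_CLASSES = ("AG_TC", "AC_TG", "AT_CG")

_CLASS_BY_PAIR = {
    frozenset("AG"): "AG_TC",
    frozenset("CT"): "AG_TC",
    frozenset("AC"): "AC_TG",
    frozenset("GT"): "AC_TG",
    frozenset("AT"): "AT_CG",
    frozenset("CG"): "AT_CG",
}

#: sentinel flag for markers whose every call is missing
MONOMORPHIC = "all_missing"


def mutation_class(allele_a: str, allele_b: str) -> str:
    """Classify a SNP by its allele pair: transition (A/G, T/C) vs the two
    transversion classes (A/C, T/G) and (A/T, C/G)."""
    return _CLASS_BY_PAIR[frozenset((allele_a, allele_b))]


def pic_biallelic(p: float) -> float:
    """Polymorphic information content for a biallelic marker.

    ``1 - (p^2 + q^2) - 2 p^2 q^2`` with q = 1 - p; maximal (0.375) at
    p = 0.5.
    """
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


@dataclass
class MarkerStatsRecord:
    marker_id: str
    maf: float  # NaN when all calls missing
    het_rate: float
    missing_rate: float
    pic: float
    coverage: Optional[float]
    mutation_class: str
    all_missing: bool = False


def compute_marker_stats(gm: GenotypeMatrix) -> List[MarkerStatsRecord]:
    """Compute MAF / heterogeneity / missing rate / PIC / coverage per marker.

    ``het_rate`` divides by non-missing calls; ``missing_rate`` divides by all
    entries (the two need not sum below 1).  Markers with every call missing
    get NaN frequencies and are flagged ``all_missing``.
    """
    if gm.n_markers == 0 or gm.n_entries == 0:
        raise ValueError("empty genotype matrix")
    calls = gm.calls
    n_entries = gm.n_entries
    out: List[MarkerStatsRecord] = []
    for i, m in enumerate(gm.markers):
        row = calls[i]
        ok = row != MISSING
        n_ok = int(np.count_nonzero(ok))
        n_missing = n_entries - n_ok
        cov = float(gm.depth[i]) if gm.depth is not None else None
        if n_ok == 0:
            out.append(
                MarkerStatsRecord(
                    m.marker_id, math.nan, math.nan, 1.0, math.nan, cov,
                    mutation_class(m.allele_major, m.allele_minor),
                    all_missing=True,
                )
            )
            continue
        n_minor = int(row[ok].sum())  # codes double as minor-allele dosage
        total_alleles = 2 * n_ok
        n_major = total_alleles - n_minor
        maf = min(n_major, n_minor) / total_alleles
        het_rate = int(np.count_nonzero(row == HET)) / n_ok
        p = n_major / total_alleles
        out.append(
            MarkerStatsRecord(
                m.marker_id,
                maf,
                het_rate,
                n_missing / n_entries,
                pic_biallelic(p),
                cov,
                mutation_class(m.allele_major, m.allele_minor),
            )
        )
    return out


def stats_frame(stats: Sequence[MarkerStatsRecord]) -> pd.DataFrame:
    """Tabular view of the statistics, one row per marker."""
    return pd.DataFrame(
        {
            "marker_id": [s.marker_id for s in stats],
            "maf": [s.maf for s in stats],
            "het_rate": [s.het_rate for s in stats],
            "missing_rate": [s.missing_rate for s in stats],
            "pic": [s.pic for s in stats],
            "coverage": [s.coverage for s in stats],
            "mutation_class": [s.mutation_class for s in stats],
            "all_missing": [s.all_missing for s in stats],
        }
    )


def mutation_class_summary(stats: Sequence[MarkerStatsRecord]) -> Dict[str, float]:
    """Fraction of markers in each mutation class (sums to 1)."""
    if not stats:
        raise ValueError("no marker statistics supplied")
    counts = {c: 0 for c in MUTATION_CLASSES}
    for s in stats:
        counts[s.mutation_class] += 1
    n = len(stats)
    return {c: counts[c] / n for c in MUTATION_CLASSES}


def ld_r2(gm: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared LD correlation between two markers on homozygous entries.

    Heterogeneous calls are dropped; each entry homozygous at both loci is
    treated as a single haplotype, giving ``r^2 = D^2 / (pA qA pB qB)`` with
    ``D = p(AB) - pA * pB`` where A/B denote major alleles.

    Raises ``ValueError`` when fewer than two usable entries remain or either
    locus is monomorphic among them.
    """
    ia, ib = gm.marker_index(marker_a), gm.marker_index(marker_b)
    ra, rb = gm.calls[ia], gm.calls[ib]
    usable = (
        ((ra == HOM_MAJOR) | (ra == HOM_MINOR))
        & ((rb == HOM_MAJOR) | (rb == HOM_MINOR))
    )
    n = int(np.count_nonzero(usable))
    if n < 2:
        raise ValueError(
            f"LD undefined for {marker_a}/{marker_b}: {n} jointly homozygous entries"
        )
    # haplotype indicator: 1 when the entry carries the major allele
    ha = (ra[usable] == HOM_MAJOR).astype(float)
    hb = (rb[usable] == HOM_MAJOR).astype(float)
    pa, pb = ha.mean(), hb.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError(
            f"LD undefined for {marker_a}/{marker_b}: monomorphic in usable set"
        )
    p_ab = float(np.mean(ha * hb))
    d = p_ab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))
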