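"""Core genotype containers for inbred-line QC genotyping.

A :class:`GenotypeMatrix` holds diploid biallelic SNP calls for a panel of
inbred entries (lines, regenerations, or individual plants).  Calls are stored
against each marker's own two alleles in a compact integer coding:

====================  =====  ==========================================
symbol                code   meaning
====================  =====  ==========================================
``HOM_MAJOR``           0    homozygous for the more frequent allele
``HET``                 1    heterozygous / heterogeneous (unphased)
``HOM_MINOR``           2    homozygous for the rarer allele
``MISSING``            -1    no call
====================  =====  ==========================================

The code doubles as a minor-allele dosage for the non-missing states, which is
what the distance, LD and grouping computations consume.  Heterozygous calls
are unordered (AB == BA): pooled-tissue genotyping-by-sequencing carries no
phase, and in a largely homozygous inbred panel a HET call mostly signals
residual heterogeneity rather than true single-plant heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "HOM_MAJOR",
    "HET",
    "HOM_MINOR",
    "MISSING",
    "VALID_BASES",
    "MarkerRecord",
    "GenotypeMatrix",
    "TraitTable",
    "subset",
]

HOM_MAJOR: int = 0
HET: int = 1
HOM_MINOR: int = 2
MISSING: int = -1

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MarkerRecord:
    """A single SNP marker: identifier, map position, and its two alleles.

    ``chrom`` is a free-form label; ``"0"`` denotes an unplaced marker with no
    reliable map position.  ``pos`` is 1-based.  ``allele_major`` and
    ``allele_minor`` are single IUPAC bases and must differ.
    """

    marker_id: str
    chrom: str
    pos: int
    allele_major: str
    allele_minor: str

    def __post_init__(self) -> None:
        if self.allele_major not in VALID_BASES or self.allele_minor not in VALID_BASES:
            raise ValueError(
                f"marker {self.marker_id!r}: alleles must be in A/C/G/T, "
                f"got {self.allele_major!r}/{self.allele_minor!r}"
            )
        if self.allele_major == self.allele_minor:
            raise ValueError(f"marker {self.marker_id!r}: alleles must differ")
        if self.chrom != "0" and self.pos < 1:
            raise ValueError(
                f"marker {self.marker_id!r}: position must be >= 1 on placed chromosomes"
            )

    @property
    def placed(self) -> bool:
        return self.chrom != "0"

    @property
    def allele_pair(self) -> frozenset:
        return frozenset((self.allele_major, self.allele_minor))


class GenotypeMatrix:
    """Markers x entries diploid call matrix with marker metadata.

    Parameters
    ----------
    markers : sequence of MarkerRecord
        One record per row, unique ``marker_id``.
    entries : sequence of str
        One unique label per column.
    calls : array-like of shape (n_markers, n_entries)
        Integer codes in {0, 1, 2, -1} (see module docstring).
    depth : array-like of shape (n_markers,), optional
        Mean sequencing reads per allele for each marker (coverage).
    """

    def __init__(
        self,
        markers: Sequence[MarkerRecord],
        entries: Sequence[str],
        calls,
        depth=None,
    ) -> None:
        self.markers = list(markers)
        self.entries = list(entries)
        self.calls = np.asarray(calls, dtype=np.int8)

        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated marker_id in matrix")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicated entry label in matrix")
        if self.calls.shape != (len(self.markers), len(self.entries)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.markers)}, {len(self.entries)})"
            )
        valid = np.isin(self.calls, (HOM_MAJOR, HET, HOM_MINOR, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid call codes present: {bad.tolist()}")

        if depth is not None:
            depth = np.asarray(depth, dtype=float)
            if depth.shape != (len(self.markers),):
                raise ValueError("depth must have one value per marker")
            if not np.all(np.isfinite(depth)) or np.any(depth < 0):
                raise ValueError("depth values must be finite and non-negative")
        self.depth = depth

        self._marker_index = {mid: i for i, mid in enumerate(ids)}
        self._entry_index = {lab: j for j, lab in enumerate(self.entries)}

    # -- basic introspection ------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def marker_ids(self) -> list:
        return [m.marker_id for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def entry_index(self, label: str) -> int:
        try:
            return self._entry_index[label]
        except KeyError:
            raise KeyError(f"unknown entry label {label!r}") from None

    def entry_calls(self, label: str) -> np.ndarray:
        """Call vector (length n_markers) for one entry."""
        return self.calls[:, self.entry_index(label)]

    # -- equality (used heavily by round-trip tests) ------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.markers != other.markers or self.entries != other.entries:
            return False
        if not np.array_equal(self.calls, other.calls):
            return False
        if (self.depth is None) != (other.depth is None):
            return False
        if self.depth is not None and not np.allclose(self.depth, other.depth):
            return False
        return True

    def __repr__(self) -> str:
        d = ", depth" if self.depth is not None else ""
        return f"GenotypeMatrix({self.n_markers} markers x {self.n_entries} entries{d})"

    # -- transforms ---------------------------------------------------------

    def canonicalized(self) -> "GenotypeMatrix":
        """Return a copy with major/minor oriented by observed frequency.

        For each marker the more frequent allele becomes ``allele_major``
        (ties broken alphabetically); calls are recoded accordingly.  Matrices
        read from disk are already canonical.
        """
        markers = []
        calls = self.calls.copy()
        for i, m in enumerate(self.markers):
            row = calls[i]
            ok = row != MISSING
            # each HOM contributes 2 of its allele, HET one of each
            n_minor = int(np.sum(row[ok]))
            n_major = int(2 * np.count_nonzero(ok) - n_minor)
            swap = n_minor > n_major or (
                n_minor == n_major and m.allele_minor < m.allele_major
            )
            if swap:
                markers.append(
                    replace(m, allele_major=m.allele_minor, allele_minor=m.allele_major)
                )
                hom = (row == HOM_MAJOR) | (row == HOM_MINOR)
                calls[i, hom] = 2 - row[hom]
            else:
                markers.append(m)
        return GenotypeMatrix(markers, list(self.entries), calls, self.depth)


@dataclass
class TraitTable:
    """Binary trait annotations per entry (1 = trait present, 0 = absent)."""

    values: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for entry, traits in self.values.items():
            for trait, v in traits.items():
                if v not in (0, 1):
                    raise ValueError(
                        f"trait {trait!r} for entry {entry!r}: value must be 0 or 1"
                    )

    def trait_vector(self, trait: str, entries: Sequence[str]) -> np.ndarray:
        """Trait values aligned to ``entries``; every entry must be annotated."""
        out = np.empty(len(entries), dtype=np.int8)
        for j, e in enumerate(entries):
            try:
                out[j] = self.values[e][trait]
            except KeyError:
                raise KeyError(
                    f"entry {e!r} has no annotation for trait {trait!r}"
                ) from None
        return out


def subset(
    gm: GenotypeMatrix,
    marker_ids: Optional[Sequence[str]] = None,
    entry_labels: Optional[Sequence[str]] = None,
) -> GenotypeMatrix:
    """Slice a matrix to the requested markers and/or entries, in request order.

    Metadata and depth are sliced consistently.  Unknown identifiers raise
    ``KeyError`` naming the offender.
    """
    if marker_ids is None:
        ridx = np.arange(gm.n_markers)
        markers = gm.markers
    else:
        ridx = np.array([gm.marker_index(mid) for mid in marker_ids], dtype=int)
        markers = [gm.markers[i] for i in ridx]
    if entry_labels is None:
        cidx = np.arange(gm.n_entries)
        entries = gm.entries
    else:
        cidx = np.array([gm.entry_index(lab) for lab in entry_labels], dtype=int)
        entries = [gm.entries[j] for j in cidx]
    calls = gm.calls[np.ix_(ridx, cidx)]
    depth = gm.depth[ridx] if gm.depth is not None else None
    return GenotypeMatrix(markers, entries, calls, depth)
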