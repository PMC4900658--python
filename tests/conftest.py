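"""Shared fixtures: compact matrix builders and brute-force oracles."""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pytest

from panelqc.matrix import GenotypeMatrix, MarkerRecord, MISSING


_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]


def build_matrix(
    codes: Sequence[Sequence[int]],
    entries: Optional[Sequence[str]] = None,
    chroms: Optional[Sequence[str]] = None,
    positions: Optional[Sequence[int]] = None,
    depth: Optional[Sequence[float]] = None,
    alleles: Optional[Sequence[tuple]] = None,
) -> GenotypeMatrix:
    """Build a matrix from integer call codes with auto-generated metadata."""
    codes = np.asarray(codes, dtype=np.int8)
    n_m, n_e = codes.shape
    entries = list(entries) if entries else [f"E{j + 1}" for j in range(n_e)]
    markers = []
    for i in range(n_m):
        a, b = alleles[i] if alleles else _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
        markers.append(
            MarkerRecord(
                f"m{i + 1}",
                chroms[i] if chroms else "1",
                positions[i] if positions else (i + 1) * 100,
                a,
                b,
            )
        )
    return GenotypeMatrix(markers, entries, codes, depth)


def oracle_allele_counts(gm: GenotypeMatrix, marker_idx: int):
    """Count alleles call-by-call: HOM gives 2 of its allele, HET one each."""
    m = gm.markers[marker_idx]
    counts = {m.allele_major: 0, m.allele_minor: 0}
    n_het = n_ok = 0
    for c in gm.calls[marker_idx]:
        if c == MISSING:
            continue
        n_ok += 1
        if c == 0:
            counts[m.allele_major] += 2
        elif c == 2:
            counts[m.allele_minor] += 2
        else:
            counts[m.allele_major] += 1
            counts[m.allele_minor] += 1
            n_het += 1
    return counts, n_het, n_ok


def oracle_pair_mismatches(gm: GenotypeMatrix, panel_ids: List[str]):
    """Per-pair count of jointly non-missing, differing panel calls."""
    idx = [gm.marker_index(m) for m in panel_ids]
    out = {}
    for i in range(gm.n_entries):
        for j in range(i + 1, gm.n_entries):
            c = 0
            for r in idx:
                a, b = gm.calls[r, i], gm.calls[r, j]
                if a != MISSING and b != MISSING and a != b:
                    c += 1
            out[(gm.entries[i], gm.entries[j])] = c
    return out


def random_matrix(
    rng: np.random.Generator,
    n_markers: int,
    n_entries: int,
    missing_rate: float = 0.15,
    het_rate: float = 0.1,
) -> GenotypeMatrix:
    codes = rng.choice([0, 2], size=(n_markers, n_entries)).astype(np.int8)
    codes[rng.random(codes.shape) < het_rate] = 1
    codes[rng.random(codes.shape) < missing_rate] = MISSING
    return build_matrix(codes)


@pytest.fixture(scope="session")
def structured_panel():
    """A small structured reference panel with ground truth (seeded)."""
    from panelqc.simulate import SimulationConfig, simulate_reference_panel

    cfg = SimulationConfig(
        n_lines=30, n_markers=600, n_groups=3, divergence=0.3, seed=11
    )
    return simulate_reference_panel(cfg)
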