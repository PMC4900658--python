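"""Read and write genotype matrices in VCF, HapMap, and plain-TSV formats.

All readers normalize onto the same in-memory model: diploid biallelic SNPs
with calls coded against the marker's own major/minor alleles, where *major*
is the allele observed more often in the file (ties broken alphabetically).
Multi-allelic or non-SNP records are skipped, not fatal; the list of skipped
rows is attached to the returned matrix as ``read_report``.

Per-marker coverage (mean reads per allele) travels as a two-column TSV
sidecar ``<path>.depth.tsv``, written automatically when present and picked up
automatically on read.
"""

from __future__ import annotations

import os
from typing import List, Optional, Tuple

import numpy as np

from .matrix import (
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    VALID_BASES,
    GenotypeMatrix,
    MarkerRecord,
)

__all__ = [
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_depth_table",
    "write_depth_table",
    "infer_format",
]

_MISSING_TOKENS = {"--", "NN", "..", "N"}

_HAPMAP_HEADER = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def infer_format(path: str) -> str:
    """Guess a format from the file name (vcf / hapmap / tsv)."""
    lower = path.lower()
    if lower.endswith((".vcf", ".vcf.gz")):
        return "vcf"
    if lower.endswith((".hmp.txt", ".hapmap", ".hmp")):
        return "hapmap"
    return "tsv"


def _orient_calls(
    marker_id: str, chrom: str, pos: int, a1: str, a2: str, dosage: np.ndarray
) -> Tuple[MarkerRecord, np.ndarray]:
    """Assign major/minor by observed allele frequency and recode dosages.

    ``dosage`` counts copies of ``a2`` per entry (-1 missing).  Returns the
    oriented record plus calls coded on the major/minor axis.
    """
    ok = dosage != MISSING
    n_a2 = int(dosage[ok].sum())
    n_a1 = int(2 * np.count_nonzero(ok) - n_a2)
    major, minor = a1, a2
    calls = dosage.copy()
    if n_a2 > n_a1 or (n_a2 == n_a1 and a2 < a1):
        major, minor = a2, a1
        hom = ok & (dosage != HET)
        calls[hom] = 2 - dosage[hom]
    rec = MarkerRecord(marker_id, chrom, pos, major, minor)
    return rec, calls


# ---------------------------------------------------------------------------
# TSV dialect: marker_id  chrom  pos  alleles  <entry1> <entry2> ...
# calls as two-letter strings ("AA", "AG", ...), "--"/"NN" missing.
# ---------------------------------------------------------------------------

def _read_tsv(path: str):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("##")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].lstrip("#").split("\t")
    if len(header) < 5:
        raise ValueError(f"{path}: TSV needs marker_id/chrom/pos/alleles + entries")
    entries = header[4:]
    markers: List[MarkerRecord] = []
    rows: List[np.ndarray] = []
    skipped = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        mid, chrom, pos_s, alleles = parts[0], parts[1], parts[2], parts[3]
        toks = parts[4:]
        allele_list = alleles.replace(",", "/").split("/")
        if len(allele_list) != 2 or any(
            len(a) != 1 or a not in VALID_BASES for a in allele_list
        ):
            skipped.append((mid, f"not a biallelic SNP: alleles {alleles!r}"))
            continue
        a_lo, a_hi = sorted(allele_list)
        pair = {a_lo, a_hi}
        dosage = np.empty(len(entries), dtype=np.int8)
        bad = None
        for j, tok in enumerate(toks):
            if tok in _MISSING_TOKENS:
                dosage[j] = MISSING
            elif len(tok) == 2 and tok[0] in pair and tok[1] in pair:
                dosage[j] = tok.count(a_hi)
            else:
                bad = tok
                break
        if bad is not None:
            skipped.append((mid, f"call {bad!r} outside declared alleles"))
            continue
        rec, calls = _orient_calls(mid, chrom, int(pos_s), a_lo, a_hi, dosage)
        markers.append(rec)
        rows.append(calls)
    return markers, entries, rows, skipped


def _write_tsv(gm: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tchrom\tpos\talleles\t" + "\t".join(gm.entries) + "\n")
        for i, m in enumerate(gm.markers):
            toks = []
            for c in gm.calls[i]:
                if c == MISSING:
                    toks.append("--")
                elif c == HOM_MAJOR:
                    toks.append(m.allele_major * 2)
                elif c == HOM_MINOR:
                    toks.append(m.allele_minor * 2)
                else:
                    toks.append(m.allele_major + m.allele_minor)
            fh.write(
                f"{m.marker_id}\t{m.chrom}\t{m.pos}\t"
                f"{m.allele_major}/{m.allele_minor}\t" + "\t".join(toks) + "\n"
            )


# ---------------------------------------------------------------------------
# HapMap diploid text
# ---------------------------------------------------------------------------

def _read_hapmap(path: str):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    entries = header[11:]
    markers, rows, skipped = [], [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        mid, alleles, chrom, pos_s = parts[0], parts[1], parts[2], parts[3]
        toks = parts[11:]
        allele_list = alleles.split("/")
        if len(allele_list) != 2 or any(
            len(a) != 1 or a not in VALID_BASES for a in allele_list
        ):
            skipped.append((mid, f"not a biallelic SNP: alleles {alleles!r}"))
            continue
        a_lo, a_hi = sorted(allele_list)
        pair = {a_lo, a_hi}
        dosage = np.empty(len(entries), dtype=np.int8)
        bad = None
        for j, tok in enumerate(toks):
            if tok in _MISSING_TOKENS:
                dosage[j] = MISSING
            elif len(tok) == 2 and tok[0] in pair and tok[1] in pair:
                dosage[j] = tok.count(a_hi)
            else:
                bad = tok
                break
        if bad is not None:
            skipped.append((mid, f"call {bad!r} outside declared alleles"))
            continue
        rec, calls = _orient_calls(mid, chrom, int(pos_s), a_lo, a_hi, dosage)
        markers.append(rec)
        rows.append(calls)
    return markers, entries, rows, skipped


def _write_hapmap(gm: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_HEADER + list(gm.entries)) + "\n")
        for i, m in enumerate(gm.markers):
            toks = []
            for c in gm.calls[i]:
                if c == MISSING:
                    toks.append("NN")
                elif c == HOM_MAJOR:
                    toks.append(m.allele_major * 2)
                elif c == HOM_MINOR:
                    toks.append(m.allele_minor * 2)
                else:
                    toks.append(m.allele_major + m.allele_minor)
            fixed = [
                m.marker_id, f"{m.allele_major}/{m.allele_minor}", m.chrom,
                str(m.pos), "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            fh.write("\t".join(fixed + toks) + "\n")


# ---------------------------------------------------------------------------
# VCF 4.x (GT field only)
# ---------------------------------------------------------------------------

def _read_vcf(path: str):
    from cyvcf2 import VCF

    vcf = VCF(path)
    entries = list(vcf.samples)
    markers, rows, skipped = [], [], []
    for idx, v in enumerate(vcf):
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        if len(v.ALT) != 1:
            skipped.append((mid, f"multi-allelic ({len(v.ALT)} ALT alleles)"))
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
            skipped.append((mid, f"not a SNP: REF={ref} ALT={alt}"))
            continue
        dosage = np.empty(len(entries), dtype=np.int8)
        for j, g in enumerate(v.genotypes):
            a0, a1 = g[0], g[1]
            dosage[j] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        rec, calls = _orient_calls(mid, v.CHROM, v.POS, ref, alt, dosage)
        markers.append(rec)
        rows.append(calls)
    vcf.close()
    return markers, entries, rows, skipped


_GT_STRINGS = {HOM_MAJOR: "0/0", HET: "0/1", HOM_MINOR: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path: str) -> None:
    chroms = []
    for m in gm.markers:
        if m.pos < 1:
            raise ValueError(
                f"marker {m.marker_id}: VCF cannot represent position {m.pos}"
            )
        if m.chrom not in chroms:
            chroms.append(m.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelqc\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.entries) + "\n"
        )
        for i, m in enumerate(gm.markers):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in gm.calls[i])
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.marker_id}\t{m.allele_major}\t"
                f"{m.allele_minor}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# depth sidecar
# ---------------------------------------------------------------------------

def write_depth_table(gm: GenotypeMatrix, path: str) -> str:
    """Write per-marker mean reads per allele as a two-column TSV."""
    if gm.depth is None:
        raise ValueError("matrix carries no depth information")
    with open(path, "w") as fh:
        fh.write("marker_id\tmean_reads_per_allele\n")
        for m, d in zip(gm.markers, gm.depth):
            fh.write(f"{m.marker_id}\t{d:g}\n")
    return path


def read_depth_table(path: str) -> dict:
    """marker_id -> mean reads per allele."""
    out = {}
    with open(path) as fh:
        next(fh)
        for ln in fh:
            mid, val = ln.rstrip("\n").split("\t")
            out[mid] = float(val)
    return out


def _depth_sidecar(path: str) -> str:
    return path + ".depth.tsv"


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

_READERS = {"tsv": _read_tsv, "hapmap": _read_hapmap, "vcf": _read_vcf}
_WRITERS = {"tsv": _write_tsv, "hapmap": _write_hapmap, "vcf": _write_vcf}


def read_genotype_matrix(path: str, format: Optional[str] = None) -> GenotypeMatrix:
    """Load a genotype matrix, validating and normalizing calls.

    The returned matrix carries ``read_report``: a list of
    ``(marker_id, reason)`` tuples for rows skipped as multi-allelic or
    otherwise not representable as a biallelic SNP.  A depth sidecar
    ``<path>.depth.tsv`` is merged in when present.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or infer_format(path)
    if fmt not in _READERS:
        raise ValueError(f"unsupported format {fmt!r}")
    markers, entries, rows, skipped = _READERS[fmt](path)
    if not markers:
        raise ValueError(f"{path}: no valid biallelic SNP records")
    calls = np.vstack(rows)
    depth = None
    sidecar = _depth_sidecar(path)
    if os.path.exists(sidecar):
        table = read_depth_table(sidecar)
        depth = np.array([table.get(m.marker_id, np.nan) for m in markers])
        if np.isnan(depth).any():
            missing = [m.marker_id for m, d in zip(markers, depth) if np.isnan(d)]
            raise ValueError(f"depth sidecar lacks markers: {missing[:5]} ...")
    gm = GenotypeMatrix(markers, entries, calls, depth)
    gm.read_report = skipped
    return gm


def write_genotype_matrix(
    gm: GenotypeMatrix, path: str, format: Optional[str] = None
) -> str:
    """Write a matrix so that :func:`read_genotype_matrix` round-trips it.

    Depth, which none of the genotype formats carry inline, goes to the
    ``<path>.depth.tsv`` sidecar.
    """
    if gm.n_entries == 0:
        raise ValueError("refusing to write a matrix with no entries")
    if gm.n_markers == 0:
        raise ValueError("refusing to write a matrix with no markers")
    fmt = format or infer_format(path)
    if fmt not in _WRITERS:
        raise ValueError(f"unsupported format {fmt!r}")
    _WRITERS[fmt](gm, path)
    if gm.depth is not None:
        write_depth_table(gm, _depth_sidecar(path))
    return path
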