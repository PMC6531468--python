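"""Motif-array grammar scanner for transcript regions (e.g. 3'-UTRs).

A motif array is an arrangement of selection-derived tetramer elements
satisfying three sequential criteria (all gaps are end-to-start nucleotide
counts, coordinates 0-based half-open):

    (i)   two flanking GGC-core anchors (CGGC or GGCA) spaced 30-200 nt:
          (GGC) - N30-200 - (GGC)
    (ii)  two CA elements strictly between the anchors, each at least 10 nt
          from its anchor and at least 6 nt apart:
          (GGC) - N>=10 - (CA) - N>=6 - (CA) - N>=10 - (GGC)
    (iii) one further CA element outside the anchor pair, 6-200 nt from the
          nearer anchor: (GGC) - N6-200 - (CA) or (CA) - N6-200 - (GGC)

Qualifying anchor pairs are reduced to a non-overlapping set by greedy
left-to-right selection on the anchor interval [G1.start, G2.end). The CA
element list is a parameter (default: the 30 CA-rich tetramers) because
published scans used a curated subset; absolute array counts depend on it.
Scanning is single-strand (sense) only.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._encode import encode, kmer_to_index
from .spacing import CA_RICH_TETRAMERS, GGC_CORE

logger = logging.getLogger(__name__)

GROUP_LABELS = ("0", "1", "2/3", ">=4")


@dataclass
class ScanParams:
    """Grammar parameters; defaults follow the relaxed transcriptome screen."""

    ggc_core_set: tuple[str, ...] = GGC_CORE
    ca_element_set: tuple[str, ...] = CA_RICH_TETRAMERS
    flank_gap_bounds: tuple[int, int] = (30, 200)
    internal_margin: int = 10
    internal_ca_gap_min: int = 6
    external_ca_gap_bounds: tuple[int, int] = (6, 200)

    def __post_init__(self) -> None:
        for lo, hi in (self.flank_gap_bounds, self.external_ca_gap_bounds):
            if lo < 0 or lo > hi:
                raise ValueError("bounds must be non-negative with min <= max")
        if self.internal_margin < 0 or self.internal_ca_gap_min < 0:
            raise ValueError("margins must be non-negative")


@dataclass(frozen=True)
class MotifHit:
    kind: str  # "ggc_core" | "ca_element"
    motif: str
    start: int

    @property
    def end(self) -> int:
        return self.start + 4


@dataclass
class MotifArray:
    anchor_5p: MotifHit
    anchor_3p: MotifHit
    internal_ca: tuple[MotifHit, MotifHit]
    external_ca: MotifHit

    @property
    def span(self) -> tuple[int, int]:
        comps = [self.anchor_5p, self.anchor_3p, *self.internal_ca, self.external_ca]
        return min(h.start for h in comps), max(h.end for h in comps)

    @property
    def anchor_interval(self) -> tuple[int, int]:
        return self.anchor_5p.start, self.anchor_3p.end


def find_motif_hits(sequence: str, params: ScanParams | None = None) -> list[MotifHit]:
    """All occurrences (including overlaps) of GGC-core and CA elements."""
    params = params or ScanParams()
    codes = encode(sequence.upper().replace("T", "U"))
    n = len(codes)
    if n < 4:
        return []
    ids = np.zeros(n - 3, dtype=np.int32)
    bad = np.zeros(n - 3, dtype=bool)
    for j in range(4):
        col = codes[j : n - 3 + j]
        bad |= col == 255
        ids = ids * 4 + np.where(col == 255, 0, col).astype(np.int32)
    if bad.any():
        logger.info("%d windows skipped for ambiguous bases", int(bad.sum()))
    kinds = {}
    for m in params.ggc_core_set:
        kinds[kmer_to_index(m)] = ("ggc_core", m.upper().replace("T", "U"))
    for m in params.ca_element_set:
        kinds[kmer_to_index(m)] = ("ca_element", m.upper().replace("T", "U"))
    lut = np.zeros(256, dtype=bool)
    lut[list(kinds)] = True
    positions = np.where(lut[ids] & ~bad)[0]
    return [MotifHit(kinds[int(ids[p])][0], kinds[int(ids[p])][1], int(p)) for p in positions]


def _gap(left_end: int, right_start: int) -> int:
    return right_start - left_end


def _find_internal(
    ca_hits: list[MotifHit], g1: MotifHit, g2: MotifHit, params: ScanParams
) -> tuple[MotifHit, MotifHit] | None:
    inside = [h for h in ca_hits if h.start >= g1.end and h.end <= g2.start]
    for i, c1 in enumerate(inside):
        if _gap(g1.end, c1.start) < params.internal_margin:
            continue
        for c2 in inside[i + 1 :]:
            if _gap(c1.end, c2.start) < params.internal_ca_gap_min:
                continue
            if _gap(c2.end, g2.start) < params.internal_margin:
                continue
            return (c1, c2)
    return None


def _find_external(
    ca_hits: list[MotifHit], g1: MotifHit, g2: MotifHit, params: ScanParams
) -> MotifHit | None:
    lo, hi = params.external_ca_gap_bounds
    best: tuple[int, int, MotifHit] | None = None
    for h in ca_hits:
        if h.start >= g2.end:
            gap = _gap(g2.end, h.start)
            side = 0  # downstream preferred on gap ties
        elif h.end <= g1.start:
            gap = _gap(h.end, g1.start)
            side = 1
        else:
            continue
        if lo <= gap <= hi and (best is None or (gap, side) < best[:2]):
            best = (gap, side, h)
    return best[2] if best else None


def scan_motif_arrays(sequence: str, params: ScanParams | None = None) -> list[MotifArray]:
    """Report the non-overlapping motif arrays of a sequence.

    Candidate anchor pairs satisfying all three criteria are sorted by
    (G1.start, G2.end) and selected greedily left to right, skipping
    candidates whose anchor interval overlaps an already selected one.
    """
    params = params or ScanParams()
    hits = find_motif_hits(sequence, params)
    ggc = [h for h in hits if h.kind == "ggc_core"]
    ca = [h for h in hits if h.kind == "ca_element"]
    lo, hi = params.flank_gap_bounds
    candidates: list[MotifArray] = []
    for i, g1 in enumerate(ggc):
        for g2 in ggc[i:]:
            if g2.start < g1.end:
                continue
            gap = _gap(g1.end, g2.start)
            if gap < lo or gap > hi:
                continue
            internal = _find_internal(ca, g1, g2, params)
            if internal is None:
                continue
            external = _find_external(ca, g1, g2, params)
            if external is None:
                continue
            arr = MotifArray(g1, g2, internal, external)
            _verify(arr, params)
            candidates.append(arr)
    candidates.sort(key=lambda a: a.anchor_interval)
    selected: list[MotifArray] = []
    right = -1
    for arr in candidates:
        s, e = arr.anchor_interval
        if s >= right:
            selected.append(arr)
            right = e
    return selected


def _verify(arr: MotifArray, params: ScanParams) -> None:
    """Re-check all three criteria on the stored coordinates (emit-time guard)."""
    g1, g2 = arr.anchor_5p, arr.anchor_3p
    c1, c2 = arr.internal_ca
    lo, hi = params.flank_gap_bounds
    ok = lo <= _gap(g1.end, g2.start) <= hi
    ok &= _gap(g1.end, c1.start) >= params.internal_margin
    ok &= _gap(c1.end, c2.start) >= params.internal_ca_gap_min
    ok &= _gap(c2.end, g2.start) >= params.internal_margin
    x = arr.external_ca
    elo, ehi = params.external_ca_gap_bounds
    if x.start >= g2.end:
        ok &= elo <= _gap(g2.end, x.start) <= ehi
    elif x.end <= g1.start:
        ok &= elo <= _gap(x.end, g1.start) <= ehi
    else:
        ok = False
    if not ok:
        raise AssertionError("emitted motif array fails criteria re-verification")


def array_count_group(count: int) -> str:
    """Group label for a per-region array count: 0, 1, 2/3 or >=4."""
    if count < 0:
        raise ValueError("array count must be non-negative")
    if count == 0:
        return "0"
    if count == 1:
        return "1"
    if count <= 3:
        return "2/3"
    return ">=4"


def annotate_sequences(
    records: Iterable[tuple[str, str]], params: ScanParams | None = None
) -> tuple[pd.DataFrame, dict[str, list[MotifArray]]]:
    """Scan (id, sequence) records; per-record array counts and group labels.

    Returns a table (region_id, length, n_arrays, group) and the arrays per
    record. Records failing to scan are skipped with a logged identifier.
    """
    params = params or ScanParams()
    rows = []
    arrays: dict[str, list[MotifArray]] = {}
    for rec_id, seq in records:
        try:
            arrs = scan_motif_arrays(seq, params)
        except ValueError as exc:
            logger.warning("skipping malformed record %s: %s", rec_id, exc)
            continue
        arrays[rec_id] = arrs
        rows.append(
            {
                "region_id": rec_id,
                "length": len(seq),
                "n_arrays": len(arrs),
                "group": array_count_group(len(arrs)),
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "length", "n_arrays", "group"]), arrays


def annotate_fasta(path: str | Path, params: ScanParams | None = None):
    from Bio import SeqIO

    records = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))
    return annotate_sequences(records, params)


def write_arrays_bed(arrays: dict[str, list[MotifArray]], path: str | Path) -> None:
    """BED6 of array spans; the name encodes the anchor coordinates."""
    with open(path, "w") as fh:
        for rec_id, arrs in arrays.items():
            for arr in arrs:
                s, e = arr.span
                name = f"array_g{arr.anchor_5p.start}_g{arr.anchor_3p.start}"
                fh.write(f"{rec_id}\t{s}\t{e}\t{name}\t0\t+\n")
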