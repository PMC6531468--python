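"""Preprocessing of selection-round sequencing reads into clean sequence tags.

A raw read is laid out as::

    [sample barcode][5' adapter][UMI][insert][3' adapter]...

Demultiplexing matches the sample barcode exactly at the 5' terminus (zero
mismatches). Trimming locates the 5' adapter by its leftmost occurrence and
the 3' adapter by its rightmost occurrence, extracts the UMI (a random
barcode of configurable length sitting immediately 5' of the insert), and
keeps inserts whose length falls within the manifest bounds (38-40 nt by
default). PCR duplicates are collapsed on the (UMI, insert) pair, keeping
the first occurrence.

All sequences are canonicalized to the RNA alphabet (T -> U) on input.
"""

from __future__ import annotations

import gzip
import logging
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._encode import canonicalize

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

REJECT_ADAPTER = "adapter_not_found"
REJECT_SHORT = "too_short"
REJECT_LONG = "too_long"
REJECT_AMBIGUOUS = "ambiguous_base"


@dataclass
class RawRead:
    """One sequencing read (canonical RNA alphabet, quality passed through)."""

    identifier: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        self.sequence = canonicalize(self.sequence)


@dataclass
class PoolManifest:
    """Pool configuration: sample barcodes, adapters, UMI length, length bounds."""

    samples: dict[str, str]
    adapters: tuple[str, str]
    umi_length: int = 5
    rounds: tuple[str, ...] = ("R1", "R2", "R3", "R4")
    length_bounds: tuple[int, int] = (38, 40)

    def __post_init__(self) -> None:
        self.samples = {name: canonicalize(bc) for name, bc in self.samples.items()}
        barcodes = list(self.samples.values())
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in manifest")
        self.adapters = (canonicalize(self.adapters[0]), canonicalize(self.adapters[1]))
        if self.umi_length < 0:
            raise ValueError("umi_length must be non-negative")
        lo, hi = self.length_bounds
        if lo > hi:
            raise ValueError("length_bounds min must not exceed max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PoolManifest":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            samples=dict(cfg["samples"]),
            adapters=(cfg["adapters"]["five_prime"], cfg["adapters"]["three_prime"]),
            umi_length=int(cfg.get("umi_length", 5)),
            rounds=tuple(cfg.get("rounds", ("R1", "R2", "R3", "R4"))),
            length_bounds=tuple(cfg.get("length_bounds", (38, 40))),
        )


@dataclass
class SequenceTag:
    """A trimmed, deduplicated selection-round insert."""

    insert: str
    sample: str
    round: str

    def __post_init__(self) -> None:
        self.insert = canonicalize(self.insert)


@dataclass
class Rejection:
    reason: str
    identifier: str = ""


@dataclass
class TrimmedRead:
    tag: SequenceTag
    umi: str


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream reads from a FASTQ file (gzip transparently supported)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield RawRead(rec.id, str(rec.seq), qual)


def demultiplex(
    reads: Iterable[RawRead], manifest: PoolManifest
) -> dict[str, list[RawRead]]:
    """Assign each read to a sample by exact 5'-terminal barcode match.

    The barcode is stripped from assigned reads. Reads matching no barcode
    land in the ``"unassigned"`` bin unchanged; the total read count is
    conserved across bins.
    """
    bins: dict[str, list[RawRead]] = {name: [] for name in manifest.samples}
    bins[UNASSIGNED] = []
    by_barcode = sorted(
        ((bc, name) for name, bc in manifest.samples.items()),
        key=lambda x: -len(x[0]),
    )
    for read in reads:
        for bc, name in by_barcode:
            if read.sequence.startswith(bc):
                q = read.quality[len(bc) :] if read.quality else None
                bins[name].append(RawRead(read.identifier, read.sequence[len(bc) :], q))
                break
        else:
            bins[UNASSIGNED].append(read)
    for name, content in bins.items():
        logger.info("demultiplex: bin %s holds %d reads", name, len(content))
    return bins


def trim_and_filter(
    read: RawRead, manifest: PoolManifest, sample: str = "", round_label: str = ""
) -> TrimmedRead | Rejection:
    """Trim adapters and the UMI from a barcode-stripped read.

    Returns a :class:`TrimmedRead` (tag + UMI) or a typed :class:`Rejection`
    with reason in {adapter_not_found, too_short, too_long, ambiguous_base}.
    """
    a5, a3 = manifest.adapters
    if not a5 or not a3:
        raise ValueError("adapters must be configured for trimming")
    seq = read.sequence
    p5 = seq.find(a5)
    if p5 < 0:
        return Rejection(REJECT_ADAPTER, read.identifier)
    insert_start = p5 + len(a5) + manifest.umi_length
    p3 = seq.rfind(a3)
    if p3 < insert_start:
        return Rejection(REJECT_ADAPTER, read.identifier)
    umi = seq[p5 + len(a5) : insert_start]
    insert = seq[insert_start:p3]
    lo, hi = manifest.length_bounds
    if len(insert) < lo:
        return Rejection(REJECT_SHORT, read.identifier)
    if len(insert) > hi:
        return Rejection(REJECT_LONG, read.identifier)
    if "N" in insert or "N" in umi:
        return Rejection(REJECT_AMBIGUOUS, read.identifier)
    return TrimmedRead(SequenceTag(insert, sample, round_label), umi)


def dedupe_umi(pairs: Iterable[tuple[str, SequenceTag]]) -> list[SequenceTag]:
    """Collapse PCR duplicates: keep one tag per distinct (UMI, insert) pair.

    Output preserves the input order of first occurrences; tags seen with an
    empty UMI are passed through unchanged (UMI filtering disabled).
    """
    pairs = list(pairs)
    if pairs and all(umi == "" for umi, _ in pairs):
        logger.info("dedupe_umi: empty UMIs, operation is identity")
        return [tag for _, tag in pairs]
    seen: set[tuple[str, str]] = set()
    out: list[SequenceTag] = []
    for umi, tag in pairs:
        key = (umi, tag.insert)
        if key not in seen:
            seen.add(key)
            out.append(tag)
    return out


@dataclass
class PreprocessResult:
    tags: dict[str, list[SequenceTag]]
    stats: pd.DataFrame = field(repr=False)


def preprocess(
    reads: Iterable[RawRead], manifest: PoolManifest, round_label: str
) -> PreprocessResult:
    """Full preprocessing of one round: demultiplex, trim, filter, deduplicate.

    Returns per-sample tag lists plus a per-sample rejection-statistics table.
    """
    bins = demultiplex(reads, manifest)
    tags: dict[str, list[SequenceTag]] = {}
    rows = []
    for sample, sample_reads in bins.items():
        if sample == UNASSIGNED:
            continue
        kept: list[tuple[str, SequenceTag]] = []
        counts = {REJECT_ADAPTER: 0, REJECT_SHORT: 0, REJECT_LONG: 0, REJECT_AMBIGUOUS: 0}
        for read in sample_reads:
            res = trim_and_filter(read, manifest, sample, round_label)
            if isinstance(res, Rejection):
                counts[res.reason] += 1
            else:
                kept.append((res.umi, res.tag))
        deduped = dedupe_umi(kept)
        tags[sample] = deduped
        rows.append(
            {
                "sample": sample,
                "round": round_label,
                "input_reads": len(sample_reads),
                "passed_trim": len(kept),
                "tags_after_dedupe": len(deduped),
                **counts,
            }
        )
    rows.append(
        {
            "sample": UNASSIGNED,
            "round": round_label,
            "input_reads": len(bins[UNASSIGNED]),
            "passed_trim": 0,
            "tags_after_dedupe": 0,
            REJECT_ADAPTER: 0,
            REJECT_SHORT: 0,
            REJECT_LONG: 0,
            REJECT_AMBIGUOUS: 0,
        }
    )
    return PreprocessResult(tags=tags, stats=pd.DataFrame(rows))


def write_tags_fasta(tags: Iterable[SequenceTag], path: str | Path) -> None:
    """Write tags as RNA FASTA (U alphabet); record ids carry sample/round."""
    records = [
        SeqRecord(Seq(t.insert), id=f"{t.sample}|{t.round}|{i}", description="")
        for i, t in enumerate(tags)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tags_fasta(path: str | Path) -> list[SequenceTag]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        sample = parts[0] if len(parts) >= 2 else ""
        rnd = parts[1] if len(parts) >= 2 else ""
        out.append(SequenceTag(str(rec.seq), sample, rnd))
    return out
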