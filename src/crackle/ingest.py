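"""Alignment ingestion: SAM/BAM parsing, barcode duplicate collapse, pileups.

Coordinates are 0-based half-open everywhere inside the package; the only
1-based surface is SAM itself (handled by pysam).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: CIGAR operations the pipeline understands.
ALLOWED_CIGAR_OPS = frozenset("MIDSN")

_PYSAM_OP_CHARS = "MIDNSHP=XB"
_REF_CONSUMING = frozenset("MDN")


class SampleInfo(NamedTuple):
    """Replicate index (1-based) and control flag for one sample label."""

    replicate: int
    is_control: bool


@dataclass(frozen=True)
class AlignmentRecord:
    """A single primary alignment reduced to what the pipeline needs.

    ``start`` is the 0-based leftmost aligned reference base; ``cigar`` is an
    ordered tuple of ``(length, op)`` pairs with ops in :data:`ALLOWED_CIGAR_OPS`.
    """

    read_id: str
    contig: str
    start: int
    strand: str
    cigar: tuple[tuple[int, str], ...]
    sample: str
    replicate: int = 1
    is_control: bool = False
    barcode: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative alignment start for read {self.read_id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for read {self.read_id!r}")
        if not self.cigar:
            raise ValueError(f"empty CIGAR for read {self.read_id!r}")
        for length, op in self.cigar:
            if op not in ALLOWED_CIGAR_OPS:
                raise ValueError(
                    f"unsupported CIGAR op {op!r} in read {self.read_id!r}"
                )
            if length <= 0:
                raise ValueError(f"non-positive CIGAR length in read {self.read_id!r}")

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed (M + D + N)."""
        return sum(n for n, op in self.cigar if op in _REF_CONSUMING)

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.start + self.reference_span

    @property
    def five_prime_start(self) -> int:
        """0-based reference position of the 5'-most aligned base on the read strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PileupTrack:
    """Per-contig, per-sample position counts.

    ``coverage`` counts aligned (M) bases; deleted reference bases are kept in
    the separate ``deletions`` track and NOT in ``coverage``.  Reads spanning a
    position through a D op are recovered via :attr:`spanning`.
    """

    contig: str
    sample: str
    coverage: np.ndarray
    deletions: np.ndarray
    read_starts: np.ndarray
    strand: str = "+"

    def __post_init__(self) -> None:
        lengths = {len(self.coverage), len(self.deletions), len(self.read_starts)}
        if len(lengths) != 1:
            raise ValueError(f"track arrays for {self.contig!r} differ in length")

    def __len__(self) -> int:
        return len(self.coverage)

    @property
    def spanning(self) -> np.ndarray:
        """Reads overlapping each position, counting overlap via a D op."""
        return self.coverage + self.deletions


def read_sample_sheet(path: str | Path) -> dict[str, SampleInfo]:
    """Read a TSV with columns ``sample``, ``replicate``, ``is_control``."""
    sheet: dict[str, SampleInfo] = {}
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            flag = str(row["is_control"]).strip().lower() in ("1", "true", "yes")
            sheet[row["sample"]] = SampleInfo(int(row["replicate"]), flag)
    return sheet


def write_sample_sheet(sheet: Mapping[str, SampleInfo], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "replicate", "is_control"])
        for sample in sorted(sheet):
            info = sheet[sample]
            writer.writerow([sample, info.replicate, int(info.is_control)])


def _cigar_from_pysam(read: pysam.AlignedSegment) -> tuple[tuple[int, str], ...]:
    out = []
    for code, length in read.cigartuples:
        op = _PYSAM_OP_CHARS[code]
        if op not in ALLOWED_CIGAR_OPS:
            raise ValueError(
                f"unsupported CIGAR op {op!r} in read {read.query_name!r}"
            )
        out.append((int(length), op))
    return tuple(out)


def load_alignments(
    path: str | Path,
    sample_sheet: Mapping[str, SampleInfo] | None = None,
    default_sample: str | None = None,
) -> list[AlignmentRecord]:
    """Load primary alignments from SAM/BAM.

    The sample label comes from the read's ``RG`` tag when present, otherwise
    ``default_sample``.  When ``sample_sheet`` is given, every encountered
    sample must appear in it; replicate/control metadata are taken from there.
    Secondary, supplementary and unmapped records are skipped with a logged
    count.  An empty file yields an empty list.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    records: list[AlignmentRecord] = []
    skipped = {"secondary": 0, "supplementary": 0, "unmapped": 0}
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for read in handle:
            if read.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if read.is_secondary:
                skipped["secondary"] += 1
                continue
            if read.is_supplementary:
                skipped["supplementary"] += 1
                continue
            sample = read.get_tag("RG") if read.has_tag("RG") else default_sample
            if sample is None:
                raise ValueError(
                    f"read {read.query_name!r} has no RG tag and no default sample "
                    "was provided"
                )
            if sample_sheet is not None:
                if sample not in sample_sheet:
                    raise KeyError(f"sample {sample!r} absent from sample sheet")
                info = sample_sheet[sample]
            else:
                info = SampleInfo(1, False)
            barcode = str(read.get_tag("BC")) if read.has_tag("BC") else ""
            records.append(
                AlignmentRecord(
                    read_id=read.query_name,
                    contig=read.reference_name,
                    start=int(read.reference_start),
                    strand="-" if read.is_reverse else "+",
                    cigar=_cigar_from_pysam(read),
                    sample=str(sample),
                    replicate=info.replicate,
                    is_control=info.is_control,
                    barcode=barcode,
                )
            )
    if any(skipped.values()):
        logger.info("skipped alignments in %s: %s", path, skipped)
    return records


def collapse_duplicates(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep one record per (contig, start, strand, barcode, sample).

    The survivor is the record with the lexicographically smallest ``read_id``,
    which makes the operation deterministic and idempotent.
    """
    kept: dict[tuple, AlignmentRecord] = {}
    for rec in records:
        key = (rec.contig, rec.start, rec.strand, rec.barcode, rec.sample)
        prev = kept.get(key)
        if prev is None or rec.read_id < prev.read_id:
            kept[key] = rec
    return sorted(kept.values(), key=lambda r: (r.sample, r.contig, r.start, r.read_id))


def build_pileup(
    records: Iterable[AlignmentRecord],
    contig_lengths: Mapping[str, int],
    strand: str = "+",
) -> dict[str, dict[str, PileupTrack]]:
    """Build per-sample, per-contig coverage / deletion / read-start tracks.

    M advances coverage, D advances deletions (not coverage), N advances the
    reference cursor only, and I/S consume no reference.  Records on the
    opposite strand are ignored with a logged count (CRAC libraries are
    stranded; all site logic runs on the annotated strand).
    """
    data: dict[str, dict[str, PileupTrack]] = {}
    n_antisense = 0
    for rec in records:
        if rec.strand != strand:
            n_antisense += 1
            continue
        if rec.contig not in contig_lengths:
            raise ValueError(
                f"read {rec.read_id!r} maps to unknown contig {rec.contig!r}"
            )
        length = contig_lengths[rec.contig]
        if rec.end > length:
            raise ValueError(
                f"read {rec.read_id!r} extends past end of contig {rec.contig!r} "
                f"({rec.end} > {length})"
            )
        contigs = data.setdefault(rec.sample, {})
        if rec.contig not in contigs:
            contigs[rec.contig] = PileupTrack(
                contig=rec.contig,
                sample=rec.sample,
                coverage=np.zeros(length, dtype=np.int64),
                deletions=np.zeros(length, dtype=np.int64),
                read_starts=np.zeros(length, dtype=np.int64),
                strand=strand,
            )
        track = contigs[rec.contig]
        ref = rec.start
        for n, op in rec.cigar:
            if op == "M":
                track.coverage[ref : ref + n] += 1
                ref += n
            elif op == "D":
                track.deletions[ref : ref + n] += 1
                ref += n
            elif op == "N":
                ref += n
            # I and S consume no reference
        track.read_starts[rec.five_prime_start] += 1
    if n_antisense:
        logger.info("ignored %d antisense alignments", n_antisense)
    # every sample gets a (possibly all-zero) track for every contig, so
    # replicate merging never sees ragged contig sets
    for sample, contigs in data.items():
        for contig, length in contig_lengths.items():
            if contig not in contigs:
                contigs[contig] = PileupTrack(
                    contig=contig,
                    sample=sample,
                    coverage=np.zeros(length, dtype=np.int64),
                    deletions=np.zeros(length, dtype=np.int64),
                    read_starts=np.zeros(length, dtype=np.int64),
                    strand=strand,
                )
    return data


def write_pileup_tsv(
    tracks: Mapping[str, Mapping[str, PileupTrack]], path: str | Path
) -> None:
    """Write sparse pileup rows: contig, pos0, sample, coverage, deletions, read_starts."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["contig", "pos0", "sample", "coverage", "deletions", "read_starts"]
        )
        for sample in sorted(tracks):
            for contig in sorted(tracks[sample]):
                track = tracks[sample][contig]
                nonzero = np.nonzero(
                    track.coverage + track.deletions + track.read_starts
                )[0]
                for pos in nonzero:
                    writer.writerow(
                        [
                            contig,
                            int(pos),
                            sample,
                            int(track.coverage[pos]),
                            int(track.deletions[pos]),
                            int(track.read_starts[pos]),
                        ]
                    )


def load_pileup_tsv(
    path: str | Path, contig_lengths: Mapping[str, int], strand: str = "+"
) -> dict[str, dict[str, PileupTrack]]:
    """Read the pileup TSV dialect written by :func:`write_pileup_tsv`."""
    data: dict[str, dict[str, PileupTrack]] = {}
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            contig = row["contig"]
            if contig not in contig_lengths:
                raise ValueError(f"unknown contig {contig!r} in pileup TSV")
            sample = row["sample"]
            contigs = data.setdefault(sample, {})
            if contig not in contigs:
                length = contig_lengths[contig]
                contigs[contig] = PileupTrack(
                    contig=contig,
                    sample=sample,
                    coverage=np.zeros(length, dtype=np.int64),
                    deletions=np.zeros(length, dtype=np.int64),
                    read_starts=np.zeros(length, dtype=np.int64),
                    strand=strand,
                )
            track = contigs[contig]
            pos = int(row["pos0"])
            track.coverage[pos] = int(row["coverage"])
            track.deletions[pos] = int(row["deletions"])
            track.read_starts[pos] = int(row["read_starts"])
    for sample, contigs in data.items():
        for contig, length in contig_lengths.items():
            if contig not in contigs:
                contigs[contig] = PileupTrack(
                    contig=contig,
                    sample=sample,
                    coverage=np.zeros(length, dtype=np.int64),
                    deletions=np.zeros(length, dtype=np.int64),
                    read_starts=np.zeros(length, dtype=np.int64),
                    strand=strand,
                )
    return data
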