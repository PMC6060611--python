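"""Transcript annotation of binding sites: region assignment, interaction
weights, transcript metaprofiles, and polyadenylation-site usage."""

from __future__ import annotations

import logging
import re
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import PileupTrack
from .motif import BindingSite

logger = logging.getLogger(__name__)

CODING_REGIONS = ("5UTR", "CDS", "3UTR")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_UTR5_FEATURES = {"five_prime_utr", "5UTR", "five_prime_UTR"}
_UTR3_FEATURES = {"three_prime_utr", "3UTR", "three_prime_UTR"}


@dataclass
class TranscriptModel:
    """A transcript with genomic region segments, ordered 5'->3' in transcript space.

    ``segments`` maps region names (5UTR/CDS/3UTR for protein-coding,
    ncRNA_exon otherwise) to lists of 0-based half-open genomic intervals.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    biotype: str
    segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    exons: list[tuple[int, int]] = field(default_factory=list)
    pA_sites: list[int] = field(default_factory=list)

    def region_at(self, pos: int) -> str | None:
        for region, intervals in self.segments.items():
            for start, end in intervals:
                if start <= pos < end:
                    return region
        return None

    def _ordered(self, region: str) -> list[tuple[int, int]]:
        intervals = sorted(self.segments.get(region, []))
        return intervals if self.strand == "+" else intervals[::-1]

    def region_length(self, region: str) -> int:
        return sum(end - start for start, end in self.segments.get(region, []))

    def region_offset(self, region: str, pos: int) -> int:
        """Transcript-space offset of ``pos`` from the region's 5' end."""
        offset = 0
        for start, end in self._ordered(region):
            if start <= pos < end:
                return offset + (pos - start if self.strand == "+" else end - 1 - pos)
            offset += end - start
        raise ValueError(f"position {pos} not inside region {region!r}")


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def _subtract_intervals(
    intervals: list[tuple[int, int]], remove: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    pieces = list(intervals)
    for r_start, r_end in remove:
        next_pieces = []
        for start, end in pieces:
            if r_end <= start or r_start >= end:
                next_pieces.append((start, end))
                continue
            if start < r_start:
                next_pieces.append((start, r_start))
            if r_end < end:
                next_pieces.append((r_end, end))
        pieces = next_pieces
    return sorted(pieces)


def read_gtf(path: str | Path) -> dict[str, TranscriptModel]:
    """Parse a GTF restricted to exon/CDS/UTR (and optional polyA_site) features.

    Missing UTR features on protein-coding transcripts are derived by
    subtracting the CDS from the exons and classifying the remainder by
    position relative to the CDS span on the transcript strand.
    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    raw: dict[str, dict] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            contig, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in (
                {"exon", "CDS", "UTR", "polyA_site"} | _UTR5_FEATURES | _UTR3_FEATURES
            ):
                continue
            parsed = _parse_attributes(attrs)
            tid = parsed.get("transcript_id")
            if tid is None:
                continue
            entry = raw.setdefault(
                tid,
                {
                    "gene_id": parsed.get("gene_id", tid),
                    "contig": contig,
                    "strand": strand,
                    "biotype": parsed.get("transcript_biotype")
                    or parsed.get("transcript_type")
                    or parsed.get("gene_biotype")
                    or parsed.get("gene_type")
                    or "protein_coding",
                    "exon": [],
                    "CDS": [],
                    "5UTR": [],
                    "3UTR": [],
                    "UTR": [],
                    "pA": [],
                },
            )
            iv = (int(start) - 1, int(end))
            if feature == "exon":
                entry["exon"].append(iv)
            elif feature == "CDS":
                entry["CDS"].append(iv)
            elif feature in _UTR5_FEATURES:
                entry["5UTR"].append(iv)
            elif feature in _UTR3_FEATURES:
                entry["3UTR"].append(iv)
            elif feature == "UTR":
                entry["UTR"].append(iv)
            elif feature == "polyA_site":
                entry["pA"].append(int(start) - 1)
    models: dict[str, TranscriptModel] = {}
    for tid, entry in raw.items():
        strand = entry["strand"]
        exons = sorted(entry["exon"]) or sorted(entry["CDS"])
        segments: dict[str, list[tuple[int, int]]] = {}
        if entry["biotype"] == "protein_coding" and entry["CDS"]:
            cds = sorted(entry["CDS"])
            segments["CDS"] = cds
            utr5 = sorted(entry["5UTR"])
            utr3 = sorted(entry["3UTR"])
            pending = sorted(entry["UTR"])
            if not (utr5 or utr3 or pending):
                pending = _subtract_intervals(exons, cds)
            if pending:
                cds_start = cds[0][0]
                cds_end = cds[-1][1]
                for start, end in pending:
                    upstream = end <= cds_start
                    downstream = start >= cds_end
                    if (strand == "+" and upstream) or (strand == "-" and downstream):
                        utr5.append((start, end))
                    elif (strand == "+" and downstream) or (strand == "-" and upstream):
                        utr3.append((start, end))
                    else:
                        logger.warning(
                            "UTR interval %s inside CDS span of %s; ignored",
                            (start, end),
                            tid,
                        )
            if utr5:
                segments["5UTR"] = sorted(utr5)
            if utr3:
                segments["3UTR"] = sorted(utr3)
        else:
            segments["ncRNA_exon"] = exons
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=entry["gene_id"],
            contig=entry["contig"],
            strand=strand,
            biotype=entry["biotype"],
            segments=segments,
            exons=exons,
            pA_sites=sorted(entry["pA"]),
        )
    return models


def annotate_sites(
    sites: Iterable[BindingSite],
    models: Mapping[str, TranscriptModel],
    expression: Mapping[str, float] | None = None,
) -> list[BindingSite]:
    """Assign each site to a transcript, region and biotype.

    A site overlapping several transcripts goes to the one with highest FPKM
    (lexicographically smallest id on ties).  Sites outside every model stay
    ``unassigned``.
    """
    expression = expression or {}
    by_contig: dict[tuple[str, str], list[TranscriptModel]] = {}
    for model in models.values():
        by_contig.setdefault((model.contig, model.strand), []).append(model)
    out = []
    for site in sites:
        hits: list[tuple[float, str, str, TranscriptModel]] = []
        for model in by_contig.get((site.contig, site.strand), []):
            region = model.region_at(site.pos)
            if region is not None:
                fpkm = float(expression.get(model.transcript_id, 0.0))
                hits.append((-fpkm, model.transcript_id, region, model))
        if hits:
            hits.sort(key=lambda h: (h[0], h[1]))
            _, tid, region, model = hits[0]
            site.transcript_id = tid
            site.gene_id = model.gene_id
            site.biotype = model.biotype
            site.region = region
        else:
            site.region = "unassigned"
        out.append(site)
    return out


def interaction_weights(
    sites: Sequence[BindingSite], group_by: str = "rna"
) -> dict[str, float]:
    """Percentage of summed site intensity per RNA or per RNA species class."""
    if group_by not in ("rna", "species"):
        raise ValueError("group_by must be 'rna' or 'species'")
    totals: dict[str, float] = {}
    grand = 0.0
    for site in sites:
        if group_by == "rna":
            key = site.transcript_id or "unassigned"
        else:
            key = site.biotype or "unassigned"
        totals[key] = totals.get(key, 0.0) + site.intensity
        grand += site.intensity
    if grand <= 0:
        raise ValueError("total site intensity is zero")
    return {key: 100.0 * value / grand for key, value in totals.items()}


def metaprofile(
    sites: Sequence[BindingSite],
    models: Mapping[str, TranscriptModel],
    bins: tuple[int, int, int] = (10, 30, 10),
) -> pd.DataFrame:
    """Binned site density over scaled 5'UTR/CDS/3'UTR of coding transcripts.

    Each site contributes to bin floor(relative_position * n_bins) of its
    region; densities are normalized to sum to 1 over all bins.
    """
    n_bins = dict(zip(CODING_REGIONS, bins))
    counts = {region: np.zeros(n_bins[region], dtype=float) for region in CODING_REGIONS}
    n_used = 0
    for site in sites:
        if site.region not in n_bins or site.transcript_id not in models:
            continue
        model = models[site.transcript_id]
        length = model.region_length(site.region)
        if length == 0:
            continue
        rel = model.region_offset(site.region, site.pos) / length
        b = min(int(rel * n_bins[site.region]), n_bins[site.region] - 1)
        counts[site.region][b] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no sites fall inside coding-transcript regions")
    rows = []
    for region in CODING_REGIONS:
        density = counts[region] / n_used
        for b, d in enumerate(density):
            rows.append({"region": region, "bin": b, "density": d})
    return pd.DataFrame(rows)


def apa_pau(
    read_starts: PileupTrack | np.ndarray,
    pA_sites: Sequence[int],
    window: int = 10,
) -> dict[int, int]:
    """Read starts within ``window`` nt of each polyadenylation site.

    A start within range of several pA sites counts toward the nearest one
    (ties to the 5'-most, i.e. smallest coordinate).
    """
    starts = (
        read_starts.read_starts if isinstance(read_starts, PileupTrack) else np.asarray(read_starts)
    )
    pa_sorted = sorted(pA_sites)
    usage = {pa: 0 for pa in pa_sorted}
    if not pa_sorted:
        return usage
    for pos in np.nonzero(starts)[0]:
        pos = int(pos)
        i = bisect_left(pa_sorted, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(pa_sorted):
                dist = abs(pos - pa_sorted[j])
                if dist <= window and (
                    best is None
                    or dist < best[0]
                    or (dist == best[0] and pa_sorted[j] < best[1])
                ):
                    best = (dist, pa_sorted[j])
        if best is not None:
            usage[best[1]] += int(starts[pos])
    return usage
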