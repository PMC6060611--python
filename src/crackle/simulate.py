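"""Synthetic-data generators for every input the pipeline consumes.

A toy transcriptome is simulated with one contig per transcript (splicing is
out of scope), 7-nt motif instances drawn from a planted PWM embedded mostly
in 3'UTRs, and one designated short non-coding RNA acting as a high-intensity
sponge.  Cross-linked reads carry a deletion at planted centres with a
configured probability; control reads carry only background deletions.  All
generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left, bisect_right
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .annotate import TranscriptModel
from .ingest import SampleInfo, write_sample_sheet
from .translation import AbsorbanceTrace

_BASES = "ACGT"


def default_planted_pwm(consensus: str = "CUUUCUU", consensus_p: float = 0.92) -> np.ndarray:
    """A sharply peaked 4x7 PWM around a CU-rich consensus heptamer."""
    from .motif import ALPHABET

    pwm = np.full((4, len(consensus)), (1.0 - consensus_p) / 3.0)
    for j, base in enumerate(consensus):
        pwm[ALPHABET.index(base), j] = consensus_p
    return pwm


@dataclass
class SimulationConfig:
    """Knobs for the synthetic transcriptome, read sets, TE counts and trace."""

    seed: int = 0
    # transcriptome
    n_transcripts: int = 60
    utr5_range: tuple[int, int] = (60, 120)
    cds_range: tuple[int, int] = (240, 450)
    utr3_range: tuple[int, int] = (150, 300)
    ncrna_length: int = 100
    # planted motif sites
    planted_pwm: np.ndarray | None = None
    n_planted_sites: int = 500
    utr3_site_fraction: float = 0.9
    n_sponge_sites: int = 5
    sponge_fraction: float = 0.7
    min_site_spacing: int = 8
    # reads
    reads_per_replicate: int = 50_000
    n_replicates: int = 2
    control_reads: int = 50_000
    read_length: int = 32
    crosslink_deletion_rate: float = 0.3
    background_deletion_rate: float = 0.001
    deletion_length: int = 1
    pcr_duplicate_rate: float = 0.05
    barcode_length: int = 5
    # expression
    fpkm_log_mean: float = 2.0
    fpkm_log_sigma: float = 0.4
    # TE experiment
    te_n_genes: int = 500
    te_n_targets: int = 50
    te_effect: float = 1.0
    te_depth: int = 1_000_000
    te_dispersion: float = 0.002
    # absorbance trace
    trace_ratio: float = 2.0
    trace_n_points: int = 4001

    def __post_init__(self) -> None:
        if self.planted_pwm is None:
            self.planted_pwm = default_planted_pwm()
        self.planted_pwm = np.asarray(self.planted_pwm, dtype=float)
        for name in ("utr3_site_fraction", "crosslink_deletion_rate",
                     "background_deletion_rate", "pcr_duplicate_rate",
                     "sponge_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ncrna_length < self.read_length + self.deletion_length + 1:
            raise ValueError("ncRNA too short for the configured read length")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            payload = json.load(handle)
        if "planted_pwm" in payload and payload["planted_pwm"] is not None:
            payload["planted_pwm"] = np.asarray(payload["planted_pwm"], dtype=float)
        for key in ("utr5_range", "cds_range", "utr3_range"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_pwm"] = self.planted_pwm.tolist()
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")


@dataclass(frozen=True)
class TruthSite:
    contig: str
    pos: int
    strand: str
    transcript_id: str
    region: str


@dataclass
class Transcriptome:
    """Synthetic reference: sequences, transcript models, expression, truth sites."""

    sequences: dict[str, str]
    models: dict[str, TranscriptModel]
    fpkm: dict[str, float]
    truth: list[TruthSite]
    sponge_id: str | None

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


def _draw_heptamer(pwm: np.ndarray, rng: np.random.Generator) -> str:
    from .motif import ALPHABET

    letters = []
    for j in range(pwm.shape[1]):
        letters.append(ALPHABET[rng.choice(4, p=pwm[:, j] / pwm[:, j].sum())])
    return "".join(letters).replace("U", "T")


def make_transcriptome(config: SimulationConfig) -> Transcriptome:
    """Build the toy transcriptome with planted motif sites.

    Placements that cannot be satisfied (region too short, spacing exhausted)
    are retried on a fresh transcript; after repeated failure the site is
    skipped with a warning, so the realized truth set can be slightly smaller
    than requested on extreme configs.
    """
    rng = np.random.default_rng(config.seed)
    n_coding = max(config.n_transcripts - 1, 1)
    sequences: dict[str, str] = {}
    models: dict[str, TranscriptModel] = {}
    fpkm: dict[str, float] = {}
    layouts: dict[str, tuple[int, int, int]] = {}
    coding_ids = []
    for i in range(n_coding):
        tid = f"tx{i + 1:04d}"
        u5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        cds = int(rng.integers(config.cds_range[0], config.cds_range[1] + 1))
        u3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        length = u5 + cds + u3
        seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
        sequences[tid] = seq
        layouts[tid] = (u5, cds, u3)
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=f"g{i + 1:04d}",
            contig=tid,
            strand="+",
            biotype="protein_coding",
            segments={
                "5UTR": [(0, u5)],
                "CDS": [(u5, u5 + cds)],
                "3UTR": [(u5 + cds, length)],
            },
            exons=[(0, length)],
            pA_sites=[length - 1],
        )
        fpkm[tid] = float(rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sigma))
        coding_ids.append(tid)
    nc_id = "ncRNA001"
    nc_len = config.ncrna_length
    sequences[nc_id] = "".join(_BASES[b] for b in rng.integers(0, 4, size=nc_len))
    models[nc_id] = TranscriptModel(
        transcript_id=nc_id,
        gene_id="gnc0001",
        contig=nc_id,
        strand="+",
        biotype="ncRNA",
        segments={"ncRNA_exon": [(0, nc_len)]},
        exons=[(0, nc_len)],
        pA_sites=[],
    )

    taken: dict[str, list[int]] = {tid: [] for tid in sequences}
    truth: list[TruthSite] = []
    flank = config.planted_pwm.shape[1] // 2
    margin = config.read_length  # keep sites coverable by interior read bases

    def place(tid: str, lo: int, hi: int) -> int | None:
        # centre must keep the whole window inside [lo, hi) and clear of ends
        length = len(sequences[tid])
        c_lo = max(lo + flank, 2)
        c_hi = min(hi - flank - 1, length - 3 - config.deletion_length)
        if c_hi < c_lo:
            return None
        for _ in range(60):
            center = int(rng.integers(c_lo, c_hi + 1))
            if all(abs(center - other) >= config.min_site_spacing for other in taken[tid]):
                return center
        return None

    n_sponge = min(config.n_sponge_sites, config.n_planted_sites)
    n_mrna_sites = config.n_planted_sites - n_sponge
    region_cut = config.utr3_site_fraction
    placed_mrna = 0
    attempts = 0
    while placed_mrna < n_mrna_sites and attempts < 50 * n_mrna_sites:
        attempts += 1
        tid = coding_ids[int(rng.integers(len(coding_ids)))]
        u5, cds, u3 = layouts[tid]
        u = rng.random()
        if u < region_cut:
            region, lo, hi = "3UTR", u5 + cds, u5 + cds + u3
        elif u < region_cut + 0.75 * (1 - region_cut):
            region, lo, hi = "CDS", u5, u5 + cds
        else:
            region, lo, hi = "5UTR", 0, u5
        lo = max(lo, margin // 2)
        hi = min(hi, len(sequences[tid]) - margin // 2)
        center = place(tid, lo, hi)
        if center is None:
            continue
        heptamer = _draw_heptamer(config.planted_pwm, rng)
        seq = sequences[tid]
        sequences[tid] = seq[: center - flank] + heptamer + seq[center + flank + 1 :]
        taken[tid].append(center)
        truth.append(TruthSite(tid, center, "+", tid, region))
        placed_mrna += 1

    for _ in range(n_sponge):
        center = place(nc_id, 0, nc_len)
        if center is None:
            break
        heptamer = _draw_heptamer(config.planted_pwm, rng)
        seq = sequences[nc_id]
        sequences[nc_id] = seq[: center - flank] + heptamer + seq[center + flank + 1 :]
        taken[nc_id].append(center)
        truth.append(TruthSite(nc_id, center, "+", nc_id, "ncRNA_exon"))

    # choose ncRNA expression so that its planted sites carry roughly
    # `sponge_fraction` of the total planted intensity (site intensity scales
    # with its transcript's FPKM under uniform per-base sampling)
    n_nc_sites = len(taken[nc_id])
    mrna_site_fpkm = sum(fpkm[t.transcript_id] for t in truth if t.contig != nc_id)
    if n_nc_sites > 0 and config.sponge_fraction < 1.0 and mrna_site_fpkm > 0:
        target = (
            config.sponge_fraction
            / (1.0 - config.sponge_fraction)
            * mrna_site_fpkm
            / n_nc_sites
        )
        # duplicate collapse keys on (contig, start, strand, barcode); on the
        # very deep sponge contig those keys saturate, so inflate its FPKM by
        # the expected dedup retention (fixed point, a few iterations)
        mrna_mass = sum(
            fpkm[tid] * len(sequences[tid]) for tid in coding_ids
        )
        n_keys = (nc_len - config.read_length - config.deletion_length) * (
            4 ** config.barcode_length
        )
        fresh = config.reads_per_replicate * (1.0 - config.pcr_duplicate_rate)
        value = target
        for _ in range(50):
            demand = fresh * value * nc_len / (value * nc_len + mrna_mass)
            lam = demand / n_keys
            retention = 1.0 if lam < 1e-9 else -np.expm1(-lam) / lam
            value = target / retention
        fpkm[nc_id] = float(value)
    else:
        fpkm[nc_id] = float(np.exp(config.fpkm_log_mean))

    return Transcriptome(
        sequences=sequences, models=models, fpkm=fpkm, truth=truth, sponge_id=nc_id
    )


def write_transcriptome(tx: Transcriptome, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, GTF, truth BED and expression TSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "genome.fa",
        "gtf": out_dir / "annotation.gtf",
        "truth": out_dir / "truth_sites.bed",
        "expression": out_dir / "expression.tsv",
    }
    with open(paths["fasta"], "w") as handle:
        for name in sorted(tx.sequences):
            handle.write(f">{name}\n")
            seq = tx.sequences[name]
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")
    with open(paths["gtf"], "w") as handle:
        for tid in sorted(tx.models):
            model = tx.models[tid]
            length = len(tx.sequences[tid])
            attrs = (
                f'gene_id "{model.gene_id}"; transcript_id "{tid}"; '
                f'transcript_biotype "{model.biotype}";'
            )

            def line(feature: str, start0: int, end0: int) -> str:
                return (
                    f"{model.contig}\tcrackle\t{feature}\t{start0 + 1}\t{end0}\t.\t"
                    f"{model.strand}\t.\t{attrs}\n"
                )

            handle.write(line("exon", 0, length))
            for region, feature in (
                ("5UTR", "five_prime_utr"),
                ("CDS", "CDS"),
                ("3UTR", "three_prime_utr"),
            ):
                for start, end in model.segments.get(region, []):
                    handle.write(line(feature, start, end))
            for pa in model.pA_sites:
                handle.write(line("polyA_site", pa, pa + 1))
    with open(paths["truth"], "w") as handle:
        for site in tx.truth:
            handle.write(
                f"{site.contig}\t{site.pos}\t{site.pos + 1}\t"
                f"{site.transcript_id}\t0\t{site.strand}\n"
            )
    with open(paths["expression"], "w") as handle:
        handle.write("transcript_id\tfpkm\n")
        for tid in sorted(tx.fpkm):
            handle.write(f"{tid}\t{tx.fpkm[tid]:.6g}\n")
    return paths


def _sample_reads(
    config: SimulationConfig,
    tx: Transcriptome,
    rng: np.random.Generator,
    n_reads: int,
    sample: str,
    with_crosslink: bool,
) -> list[tuple[str, str, int, str, str, str]]:
    """Generate ``n_reads`` alignment tuples (qname, contig, start, cigar, seq, barcode)."""
    contigs = sorted(tx.sequences)
    lens = np.array([len(tx.sequences[c]) for c in contigs], dtype=float)
    fpkms = np.array([tx.fpkm[c] for c in contigs], dtype=float)
    weights = fpkms * lens
    weights = weights / weights.sum()
    truth_by_contig: dict[str, list[int]] = {}
    for site in tx.truth:
        truth_by_contig.setdefault(site.contig, []).append(site.pos)
    for centers in truth_by_contig.values():
        centers.sort()

    L = config.read_length
    dlen = config.deletion_length
    p_bg = 1.0 - (1.0 - config.background_deletion_rate) ** (L - 1)

    t_idx = rng.choice(len(contigs), size=n_reads, p=weights)
    start_u = rng.random(n_reads)
    dup_u = rng.random(n_reads)
    xl_u = rng.random(n_reads)
    bg_u = rng.random(n_reads)
    pick_u = rng.random(n_reads)
    bc_codes = rng.integers(0, 4, size=(n_reads, config.barcode_length))

    reads: list[tuple[str, str, int, str, str, str]] = []
    for i in range(n_reads):
        qname = f"{sample}.{i:07d}"
        if reads and dup_u[i] < config.pcr_duplicate_rate:
            src = reads[int(pick_u[i] * len(reads))]
            reads.append((qname,) + src[1:])
            continue
        contig = contigs[t_idx[i]]
        seq_ref = tx.sequences[contig]
        n_starts = len(seq_ref) - L - dlen
        start = int(start_u[i] * n_starts)
        del_pos: int | None = None
        if with_crosslink:
            centers = truth_by_contig.get(contig, ())
            lo = bisect_left(centers, start + 1)
            hi = bisect_right(centers, start + L - 1)
            if hi > lo and xl_u[i] < config.crosslink_deletion_rate:
                del_pos = centers[lo + int(pick_u[i] * (hi - lo))]
        if del_pos is None and bg_u[i] < p_bg:
            del_pos = start + 1 + int(rng.integers(0, L - 1))
        if del_pos is not None:
            a = del_pos - start
            cigar = f"{a}M{dlen}D{L - a}M"
            seq = seq_ref[start:del_pos] + seq_ref[del_pos + dlen : start + L + dlen]
        else:
            cigar = f"{L}M"
            seq = seq_ref[start : start + L]
        barcode = "".join(_BASES[b] for b in bc_codes[i])
        reads.append((qname, contig, start, cigar, seq, barcode))
    return reads


def simulate_crac_reads(
    config: SimulationConfig, tx: Transcriptome, out_dir: str | Path
) -> dict[str, Path]:
    """Write one SAM per cross-linked replicate plus one control, and a sample sheet.

    Every file holds exactly the configured number of primary records.  Reads
    are sampled proportionally to FPKM x length; case reads covering a truth
    centre (away from the alignment ends) carry a deletion there with
    probability ``crosslink_deletion_rate``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = sorted(tx.sequences)
    sheet: dict[str, SampleInfo] = {}
    paths: dict[str, Path] = {}
    jobs = [(f"rep{r + 1}", r + 1, False, config.reads_per_replicate)
            for r in range(config.n_replicates)]
    jobs.append(("control", 1, True, config.control_reads))
    for k, (sample, replicate, is_control, n_reads) in enumerate(jobs):
        rng = np.random.default_rng([config.seed, 1000 + k])
        reads = _sample_reads(config, tx, rng, n_reads, sample, not is_control)
        path = out_dir / f"{sample}.sam"
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(tx.sequences[c])} for c in contigs],
            "RG": [{"ID": sample, "SM": sample}],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            tid_of = {c: i for i, c in enumerate(contigs)}
            for qname, contig, start, cigar, seq, barcode in reads:
                aln = pysam.AlignedSegment(out.header)
                aln.query_name = qname
                aln.flag = 0
                aln.reference_id = tid_of[contig]
                aln.reference_start = start
                aln.mapping_quality = 60
                aln.cigarstring = cigar
                aln.query_sequence = seq
                aln.set_tags([("RG", sample), ("BC", barcode)])
                out.write(aln)
        sheet[sample] = SampleInfo(replicate, is_control)
        paths[sample] = path
    write_sample_sheet(sheet, out_dir / "sample_sheet.tsv")
    paths["sample_sheet"] = out_dir / "sample_sheet.tsv"
    return paths


@dataclass
class TECounts:
    """Polysomal and total count matrices with nominal library sizes."""

    pol: pd.DataFrame
    tot: pd.DataFrame
    pol_lib_sizes: dict[str, float]
    tot_lib_sizes: dict[str, float]
    genes: list[str]
    targets: list[str]


def simulate_te_counts(
    config: SimulationConfig,
    gene_list: Sequence[str] | None = None,
    target_set: Sequence[str] | None = None,
) -> TECounts:
    """Gamma-Poisson count matrices with a planted TE shift for target genes.

    Polysomal case means are multiplied by 2**te_effect for targets only;
    total counts are unchanged in expectation.  The nominal sequencing depth
    is reported as the library size of every library, so CPM built from it
    recovers the planted effect without compositional bias.
    """
    rng = np.random.default_rng([config.seed, 777])
    if gene_list is None:
        gene_list = [f"g{i + 1:04d}" for i in range(config.te_n_genes)]
    genes = list(gene_list)
    if target_set is None:
        idx = rng.choice(len(genes), size=min(config.te_n_targets, len(genes)),
                         replace=False)
        targets = sorted(genes[i] for i in idx)
    else:
        targets = sorted(target_set)
        if not set(targets) <= set(genes):
            raise ValueError("target set must be a subset of the gene list")
    target_mask = np.isin(np.array(genes), np.array(targets))
    rel = rng.lognormal(0.0, 1.0, size=len(genes))
    base = rel / rel.sum()
    depth = float(config.te_depth)

    def draw(mean: np.ndarray) -> np.ndarray:
        if config.te_dispersion > 0:
            lam = rng.gamma(
                shape=1.0 / config.te_dispersion,
                scale=mean * config.te_dispersion,
            )
        else:
            lam = mean
        return rng.poisson(lam)

    pol_ctrl = draw(depth * base)
    pol_case_mean = depth * base * np.where(target_mask, 2.0 ** config.te_effect, 1.0)
    pol_case = draw(pol_case_mean)
    tot_ctrl = draw(depth * base)
    tot_case = draw(depth * base)
    pol = pd.DataFrame({"ctrl": pol_ctrl, "case": pol_case}, index=genes)
    tot = pd.DataFrame({"ctrl": tot_ctrl, "case": tot_case}, index=genes)
    return TECounts(
        pol=pol,
        tot=tot,
        pol_lib_sizes={"ctrl": depth, "case": depth},
        tot_lib_sizes={"ctrl": depth, "case": depth},
        genes=genes,
        targets=targets,
    )


_TRACE_PEAKS = (
    ("RNP", 8.0, 1.5, 0.6),
    ("40S", 18.0, 1.5, 0.7),
    ("60S", 26.0, 1.2, 0.9),
    ("80S", 38.0, 2.0, 1.0),
)
_POLYSOME_PEAKS = ((52.0, 2.0, 0.8), (58.0, 2.0, 0.65), (64.0, 2.0, 0.5),
                   (70.0, 2.0, 0.4), (77.0, 2.0, 0.3))
_TRACE_BOUNDARIES = {
    "RNP": (4.0, 12.0),
    "40S": (13.0, 23.0),
    "60S": (23.0, 31.0),
    "80S": (31.0, 45.0),
    "polysomes": (45.0, 85.0),
}


def simulate_trace(config: SimulationConfig) -> AbsorbanceTrace:
    """Gaussian-peak absorbance profile with a configured polysome/80S area ratio.

    Peaks are well separated from the boundary edges, so trapezoidal
    integration recovers the configured ratio to well within 1% at the
    default sampling density.
    """
    if config.trace_ratio < 0:
        raise ValueError("trace ratio must be non-negative")
    x = np.linspace(0.0, 100.0, config.trace_n_points)
    y = np.zeros_like(x)
    for _label, center, sd, amp in _TRACE_PEAKS:
        y += amp * np.exp(-0.5 * ((x - center) / sd) ** 2)
    area_80s = 1.0 * 2.0 * math.sqrt(2.0 * math.pi)
    raw_poly_area = sum(amp * sd * math.sqrt(2.0 * math.pi)
                        for _c, sd, amp in _POLYSOME_PEAKS)
    scale = config.trace_ratio * area_80s / raw_poly_area
    for center, sd, amp in _POLYSOME_PEAKS:
        y += scale * amp * np.exp(-0.5 * ((x - center) / sd) ** 2)
    return AbsorbanceTrace(position=x, a254=y, boundaries=dict(_TRACE_BOUNDARIES))
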