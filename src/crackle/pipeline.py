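"""End-to-end driver: SAM replicates + control -> high-confidence binding sites.

Stages: ingest & duplicate collapse, replicate merge, control penalization,
empirical p-values with Fisher combination, seed-PWM construction from the
significant windows, exhaustive-null threshold, scoring and high-confidence
filtering, then annotation, affinity weighting, interaction weights and the
transcript metaprofile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from . import annotate as annotate_mod
from . import detect, motif
from .ingest import (
    AlignmentRecord,
    PileupTrack,
    SampleInfo,
    build_pileup,
    collapse_duplicates,
    load_alignments,
)
from .io import read_expression_tsv, read_genome_fasta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    pseudocount: float = 1.0
    percentile: float = 95.0
    expression_floor: float = 0.1
    min_del_total: float = 3
    min_rep_del: int = 1
    min_cov_total: int = 6
    min_rep_cov: int = 2
    min_candidate_del: int = 1
    control_scale_mode: str = "library_size"  # or "fixed"
    control_scale: float = 1.0
    remove_control_dominated: bool = True
    dedup: bool = True
    metaprofile_bins: tuple[int, int, int] = (10, 30, 10)


@dataclass
class PipelineResult:
    candidates: list[detect.DeletionSite]
    seeds: list[detect.DeletionSite]
    pwm: motif.SeedPWM
    tau: float
    sites: list[motif.BindingSite]
    control_scale: float
    logo: np.ndarray | None = None
    weights_by_rna: dict[str, float] | None = None
    weights_by_species: dict[str, float] | None = None
    metaprofile: pd.DataFrame | None = None

    @property
    def high_confidence(self) -> list[motif.BindingSite]:
        return [s for s in self.sites if s.passes_filters]


def _sample_name(path: str | Path, fallback: str) -> str:
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        groups = handle.header.to_dict().get("RG", [])
    if len(groups) == 1:
        return groups[0]["ID"]
    return fallback


def _load_sample(
    path: str | Path, replicate: int, is_control: bool, dedup: bool
) -> tuple[str, list[AlignmentRecord]]:
    name = _sample_name(path, Path(path).stem)
    sheet = {name: SampleInfo(replicate, is_control)}
    records = load_alignments(path, sample_sheet=sheet, default_sample=name)
    if dedup:
        records = collapse_duplicates(records)
    return name, records


def run_pipeline(
    case_sams: Sequence[str | Path],
    control_sam: str | Path | None,
    genome_fasta: str | Path,
    gtf_path: str | Path | None = None,
    expression_tsv: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full site-calling pipeline.

    ``case_sams`` are the cross-linked replicates in replicate order.  The
    control sample, annotation and expression table are optional; downstream
    products that need them are skipped when absent.
    """
    config = config or PipelineConfig()
    genome = read_genome_fasta(genome_fasta)
    contig_lengths = {name: len(seq) for name, seq in genome.items()}

    rep_tracks: list[Mapping[str, PileupTrack]] = []
    n_case = 0
    for i, path in enumerate(case_sams):
        name, records = _load_sample(path, i + 1, False, config.dedup)
        n_case += len(records)
        pileups = build_pileup(records, contig_lengths)
        rep_tracks.append(pileups[name])
    merged = detect.merge_replicates(rep_tracks)
    candidates = detect.find_candidates(merged, min_del=config.min_candidate_del)
    logger.info("%d candidate deletion positions", len(candidates))

    scale = config.control_scale
    control_tracks = None
    if control_sam is not None:
        name, records = _load_sample(control_sam, 1, True, config.dedup)
        control_tracks = build_pileup(records, contig_lengths)[name]
        if config.control_scale_mode == "library_size":
            if not records:
                raise ValueError("control sample has no alignments")
            scale = n_case / len(records)
    candidates = detect.subtract_control(
        candidates,
        control_tracks,
        scale=scale,
        remove_dominated=config.remove_control_dominated,
    )
    logger.info("%d candidates after control penalization", len(candidates))

    candidates = detect.assign_pvalues(candidates, merged)
    seeds = detect.select_seed_sites(candidates, alpha=config.alpha)
    logger.info("%d seed sites at alpha=%g", len(seeds), config.alpha)

    _, seed_windows = motif.extract_windows(seeds, genome)
    pwm = motif.build_seed_pwm(seed_windows, pseudocount=config.pseudocount)
    tau = motif.null_threshold(pwm, percentile=config.percentile)
    pwm.threshold = tau

    sites = motif.score_sites(candidates, pwm, genome)
    sites = motif.high_confidence_filter(
        sites,
        tau,
        min_del_total=config.min_del_total,
        min_rep_del=config.min_rep_del,
        min_cov_total=config.min_cov_total,
        min_rep_cov=config.min_rep_cov,
    )
    result = PipelineResult(
        candidates=candidates,
        seeds=seeds,
        pwm=pwm,
        tau=tau,
        sites=sites,
        control_scale=scale if control_tracks is not None else 0.0,
    )
    hc = result.high_confidence
    logger.info("%d high-confidence sites", len(hc))

    if gtf_path is not None:
        models = annotate_mod.read_gtf(gtf_path)
        expression = read_expression_tsv(expression_tsv) if expression_tsv else {}
        annotate_mod.annotate_sites(sites, models, expression)
        if expression:
            motif.affinity_weights(sites, expression, floor=config.expression_floor)
        if hc:
            result.weights_by_rna = annotate_mod.interaction_weights(hc, "rna")
            result.weights_by_species = annotate_mod.interaction_weights(hc, "species")
            with_affinity = [s for s in hc if s.affinity is not None]
            if with_affinity:
                result.logo = motif.weighted_logo(with_affinity)
            try:
                result.metaprofile = annotate_mod.metaprofile(
                    hc, models, bins=config.metaprofile_bins
                )
            except ValueError:
                result.metaprofile = None
    return result


def match_truth(
    sites: Sequence[motif.BindingSite],
    truth: Sequence[tuple[str, int, str]],
    tolerance: int = 3,
) -> tuple[float, float]:
    """(recall, false-discovery proportion) of calls against truth positions.

    A call matches a truth site when it lies within ``tolerance`` nt on the
    same contig and strand.
    """
    truth_by_contig: dict[tuple[str, str], list[int]] = {}
    for contig, pos, strand in truth:
        truth_by_contig.setdefault((contig, strand), []).append(pos)
    for positions in truth_by_contig.values():
        positions.sort()
    hit = set()
    n_false = 0
    for site in sites:
        positions = truth_by_contig.get((site.contig, site.strand), [])
        matched = None
        for pos in positions:
            if abs(pos - site.pos) <= tolerance:
                matched = pos
                break
        if matched is None:
            n_false += 1
        else:
            hit.add((site.contig, matched, site.strand))
    recall = len(hit) / len(truth) if truth else 0.0
    fdp = n_false / len(sites) if sites else 0.0
    return recall, fdp
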