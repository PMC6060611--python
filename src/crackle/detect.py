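"""Stage 1 of site calling: deletion-site candidates, control penalization,
empirical p-values, and Fisher combination.

Candidate cross-link positions are localized by cross-link-induced deletions:
any position with at least one deletion after replicate merging.  Each
candidate receives empirical right-tail p-values for its total coverage and
total deletion count, drawn from the genome-wide distributions over
coverage-positive positions, and the two are combined with Fisher's method
(chi-square with 4 degrees of freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ingest import PileupTrack

logger = logging.getLogger(__name__)


@dataclass
class DeletionSite:
    """A candidate cross-link position with its per-replicate evidence.

    ``del_total`` may become fractional after library-size-scaled control
    subtraction; the per-replicate vectors always keep the raw counts needed
    by the per-replicate high-confidence clauses.
    """

    contig: str
    pos: int
    strand: str
    del_by_rep: tuple[int, ...]
    cov_by_rep: tuple[int, ...]
    del_total: float
    cov_total: int
    ctrl_del: float = 0.0
    ctrl_cov: float = 0.0
    p_cov: float | None = None
    p_del: float | None = None
    p_comb: float | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.strand)


@dataclass
class MergedPileup:
    """Replicate-merged case pileup: per-contig (R, L) count arrays.

    ``cov_by_rep`` counts reads overlapping each position including overlap
    via a D op (deleted base), the permissive reading of "aligned reads" used
    by the coverage filters.
    """

    del_by_rep: dict[str, np.ndarray]
    cov_by_rep: dict[str, np.ndarray]
    strand: str = "+"

    @property
    def n_replicates(self) -> int:
        first = next(iter(self.del_by_rep.values()))
        return first.shape[0]

    def del_total(self, contig: str) -> np.ndarray:
        return self.del_by_rep[contig].sum(axis=0)

    def cov_total(self, contig: str) -> np.ndarray:
        return self.cov_by_rep[contig].sum(axis=0)


def merge_replicates(
    replicate_tracks: Sequence[Mapping[str, PileupTrack]],
) -> MergedPileup:
    """Stack >=2 replicate pileups into per-contig (R, L) arrays."""
    if len(replicate_tracks) < 2:
        raise ValueError("at least two cross-linked replicates are required")
    contig_sets = [set(tracks) for tracks in replicate_tracks]
    if any(s != contig_sets[0] for s in contig_sets[1:]):
        raise ValueError("replicate pileups cover different contigs")
    strand = next(iter(replicate_tracks[0].values())).strand
    del_by_rep: dict[str, np.ndarray] = {}
    cov_by_rep: dict[str, np.ndarray] = {}
    for contig in sorted(contig_sets[0]):
        lengths = {len(tracks[contig]) for tracks in replicate_tracks}
        if len(lengths) != 1:
            raise ValueError(f"contig {contig!r} has mismatched lengths across replicates")
        del_by_rep[contig] = np.stack(
            [tracks[contig].deletions for tracks in replicate_tracks]
        )
        cov_by_rep[contig] = np.stack(
            [tracks[contig].spanning for tracks in replicate_tracks]
        )
    return MergedPileup(del_by_rep=del_by_rep, cov_by_rep=cov_by_rep, strand=strand)


def find_candidates(merged: MergedPileup, min_del: int = 1) -> list[DeletionSite]:
    """Positions with at least ``min_del`` total deletions after merging."""
    sites: list[DeletionSite] = []
    for contig in sorted(merged.del_by_rep):
        del_total = merged.del_total(contig)
        cov_total = merged.cov_total(contig)
        for pos in np.nonzero(del_total >= min_del)[0]:
            sites.append(
                DeletionSite(
                    contig=contig,
                    pos=int(pos),
                    strand=merged.strand,
                    del_by_rep=tuple(int(v) for v in merged.del_by_rep[contig][:, pos]),
                    cov_by_rep=tuple(int(v) for v in merged.cov_by_rep[contig][:, pos]),
                    del_total=float(del_total[pos]),
                    cov_total=int(cov_total[pos]),
                )
            )
    return sites


def subtract_control(
    candidates: Sequence[DeletionSite],
    control_tracks: Mapping[str, PileupTrack] | None,
    scale: float = 1.0,
    remove_dominated: bool = True,
) -> list[DeletionSite]:
    """Penalize candidates showing control signal.

    ``del_total`` is reduced by ``scale`` x control deletions (floored at 0);
    candidates whose adjusted total falls below 1, or whose raw control
    deletions reach the raw case total, are removed.  With no control tracks
    this is the identity.
    """
    if control_tracks is None:
        return list(candidates)
    if scale <= 0:
        raise ValueError("control scale must be positive")
    kept: list[DeletionSite] = []
    for site in candidates:
        track = control_tracks.get(site.contig)
        raw_del = float(track.deletions[site.pos]) if track is not None else 0.0
        raw_cov = float(track.spanning[site.pos]) if track is not None else 0.0
        if remove_dominated and raw_del >= site.del_total:
            continue
        adjusted = max(0.0, site.del_total - scale * raw_del)
        if adjusted < 1.0:
            continue
        kept.append(
            replace(
                site,
                del_total=adjusted,
                ctrl_del=scale * raw_del,
                ctrl_cov=scale * raw_cov,
            )
        )
    return kept


def empirical_pvalue(values, observed):
    """Right-tail empirical p-value(s): #{v >= observed} / N.

    ``values`` is the genome-wide multiset the observation was drawn from, so
    the minimum attainable p is 1/N and p is never 0.  ``observed`` may be a
    scalar or an array.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empirical distribution is empty")
    ordered = np.sort(values)
    n = ordered.size
    idx = np.searchsorted(ordered, observed, side="left")
    p = (n - idx) / n
    if np.isscalar(observed) or np.ndim(observed) == 0:
        return float(p)
    return p


def fisher_combine(p1, p2):
    """Fisher's method for two p-values: chi-square(4) survival of
    X = -2(ln p1 + ln p2), i.e. the closed form exp(-X/2) (1 + X/2)."""
    a1 = np.asarray(p1, dtype=float)
    a2 = np.asarray(p2, dtype=float)
    if np.any(a1 <= 0) or np.any(a2 <= 0) or np.any(a1 > 1) or np.any(a2 > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * (np.log(a1) + np.log(a2))
    combined = stats.chi2.sf(x, df=4)
    if np.ndim(p1) == 0 and np.ndim(p2) == 0:
        return float(combined)
    return combined


def assign_pvalues(
    candidates: Sequence[DeletionSite], merged: MergedPileup
) -> list[DeletionSite]:
    """Attach p_cov, p_del and p_comb to each candidate.

    Both empirical null distributions are taken over coverage-positive
    positions of the merged case pileup (positions overlapped by at least one
    read, counting overlap via D), not over the whole genome.
    """
    cov_chunks = []
    del_chunks = []
    for contig in sorted(merged.cov_by_rep):
        cov_total = merged.cov_total(contig)
        del_total = merged.del_total(contig)
        mask = cov_total >= 1
        cov_chunks.append(cov_total[mask])
        del_chunks.append(del_total[mask])
    cov_values = np.sort(np.concatenate(cov_chunks)) if cov_chunks else np.array([])
    del_values = np.sort(np.concatenate(del_chunks)) if del_chunks else np.array([])
    if cov_values.size == 0:
        raise ValueError("no coverage-positive positions: cannot build null distributions")
    n = cov_values.size
    obs_cov = np.array([s.cov_total for s in candidates], dtype=float)
    obs_del = np.array([s.del_total for s in candidates], dtype=float)
    if len(candidates) == 0:
        return []
    p_cov = (n - np.searchsorted(cov_values, obs_cov, side="left")) / n
    p_del = (n - np.searchsorted(del_values, obs_del, side="left")) / n
    # floor at 1/N: a control-adjusted fractional total can exceed every raw
    # value in the universe, but a p-value of 0 would break the log transform
    p_cov = np.maximum(p_cov, 1.0 / n)
    p_del = np.maximum(p_del, 1.0 / n)
    p_comb = fisher_combine(p_cov, p_del)
    out = []
    for site, pc, pd_, pf in zip(candidates, p_cov, p_del, p_comb):
        out.append(replace(site, p_cov=float(pc), p_del=float(pd_), p_comb=float(pf)))
    return out


def select_seed_sites(
    candidates: Sequence[DeletionSite], alpha: float = 0.05
) -> list[DeletionSite]:
    """Unique genomic locations with combined p strictly below ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    seen: dict[tuple, DeletionSite] = {}
    for site in candidates:
        if site.p_comb is None:
            raise ValueError("candidates must carry combined p-values")
        if site.p_comb < alpha and site.key not in seen:
            seen[site.key] = site
    if not seen:
        raise ValueError(
            "no seed sites at alpha=%g: the seed PWM cannot be built; "
            "review deletion/coverage thresholds or alpha" % alpha
        )
    return list(seen.values())
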