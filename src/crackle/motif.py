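"""Stage 2 of site calling: seed PWM, exhaustive-null score threshold,
high-confidence filtering, and the affinity-weighted logo.

The seed PWM is built from 7-nt windows centred on significant deletion
sites.  Scores are log2-odds sums against an explicit background, so a
uniform PWM scores 0 for every heptamer.  The score threshold is the 95th
percentile of the scores of all 4^7 = 16,384 heptamers, weighted by their
background probability; with the default uniform background this is an
unweighted order statistic and therefore fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detect import DeletionSite

logger = logging.getLogger(__name__)

ALPHABET = "ACGU"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

WINDOW = 7
FLANK = WINDOW // 2


@dataclass
class SeedPWM:
    """4x7 frequency matrix over A,C,G,U plus its log2-odds form."""

    freq: np.ndarray
    background: np.ndarray
    pseudocount: float
    n_seed: int
    threshold: float | None = None
    logodds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freq.shape != (4, WINDOW):
            raise ValueError(f"frequency matrix must be 4x{WINDOW}")
        if not np.allclose(self.freq.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("frequency columns must sum to 1")
        with np.errstate(divide="ignore"):
            self.logodds = np.log2(self.freq / self.background[:, None])


def reverse_complement(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def extract_windows(
    sites: Sequence[DeletionSite],
    genome: Mapping[str, str],
    flank: int = FLANK,
) -> tuple[list[DeletionSite], list[str]]:
    """7-nt windows centred on each deletion site, as RNA on the site strand.

    Minus-strand windows are reverse-complemented; T is transliterated to U.
    Sites whose window runs off the contig are dropped with a logged count.
    Returns the kept sites and their windows, index-aligned.
    """
    kept: list[DeletionSite] = []
    windows: list[str] = []
    dropped = 0
    for site in sites:
        if site.contig not in genome:
            raise KeyError(f"contig {site.contig!r} missing from genome")
        seq = genome[site.contig]
        lo, hi = site.pos - flank, site.pos + flank + 1
        if lo < 0 or hi > len(seq):
            dropped += 1
            continue
        window = seq[lo:hi].upper()
        if site.strand == "-":
            window = reverse_complement(window)
        windows.append(window.replace("T", "U"))
        kept.append(site)
    if dropped:
        logger.info("dropped %d sites with out-of-bounds windows", dropped)
    return kept, windows


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[b] for b in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"bad letter {exc.args[0]!r} in window {seq!r}") from None


def build_seed_pwm(
    windows: Sequence[str],
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> SeedPWM:
    """Per-column letter frequencies with a pseudocount per letter per column.

    freq[b, j] = (count_j(b) + pseudocount) / (n + 4 * pseudocount).
    Windows containing N are excluded (with a logged count) before counting.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    usable = [w for w in windows if "N" not in w.upper()]
    if len(usable) < len(windows):
        logger.info("excluded %d windows containing N", len(windows) - len(usable))
    if not usable:
        raise ValueError("no usable windows to build the seed PWM")
    counts = np.zeros((4, WINDOW), dtype=float)
    for window in usable:
        if len(window) != WINDOW:
            raise ValueError(f"window {window!r} is not {WINDOW} nt")
        counts[_encode(window.upper().replace("T", "U")), np.arange(WINDOW)] += 1
    n = len(usable)
    freq = (counts + pseudocount) / (n + 4 * pseudocount)
    return SeedPWM(freq=freq, background=background, pseudocount=pseudocount, n_seed=n)


def score_window(pwm: SeedPWM, seq: str) -> float:
    """Sum over columns of log2(freq[letter, j] / background[letter])."""
    if len(seq) != WINDOW:
        raise ValueError(f"sequence {seq!r} is not {WINDOW} nt")
    codes = _encode(seq.upper().replace("T", "U"))
    return float(pwm.logodds[codes, np.arange(WINDOW)].sum())


def score_windows(pwm: SeedPWM, seqs: Sequence[str]) -> np.ndarray:
    if len(seqs) == 0:
        return np.array([])
    codes = np.stack([_encode(s.upper().replace("T", "U")) for s in seqs])
    return pwm.logodds[codes, np.arange(WINDOW)].sum(axis=1)


def _all_heptamer_codes() -> np.ndarray:
    grids = np.meshgrid(*([np.arange(4)] * WINDOW), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def enumerate_null_scores(pwm: SeedPWM) -> tuple[np.ndarray, np.ndarray]:
    """Scores and background weights of all 4^7 heptamers."""
    codes = _all_heptamer_codes()
    scores = pwm.logodds[codes, np.arange(WINDOW)].sum(axis=1)
    weights = pwm.background[codes].prod(axis=1)
    return scores, weights


def null_threshold(pwm: SeedPWM, percentile: float = 95.0) -> float:
    """Deterministic score threshold from exhaustive heptamer enumeration.

    Lower nearest-rank percentile of the background-weighted score multiset:
    the smallest score whose cumulative weight reaches ``percentile``%.  No
    sampling is involved, so the value is bit-identical across runs.
    """
    scores, weights = enumerate_null_scores(pwm)
    order = np.argsort(scores, kind="stable")
    cum = np.cumsum(weights[order])
    cum /= cum[-1]
    idx = int(np.searchsorted(cum, percentile / 100.0, side="left"))
    return float(scores[order][min(idx, len(scores) - 1)])


def null_threshold_sampled(
    pwm: SeedPWM, percentile: float = 95.0, n: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo variant of :func:`null_threshold` for fidelity experiments."""
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=(n, WINDOW), p=pwm.background / pwm.background.sum())
    scores = np.sort(pwm.logodds[codes, np.arange(WINDOW)].sum(axis=1))
    idx = min(int(np.ceil(percentile / 100.0 * n)) - 1, n - 1)
    return float(scores[idx])


@dataclass
class BindingSite:
    """A scored 7-nt candidate site with filter flags and annotation slots."""

    contig: str
    pos: int
    strand: str
    window_seq: str
    score: float
    intensity: float
    del_by_rep: tuple[int, ...]
    cov_by_rep: tuple[int, ...]
    del_total: float
    cov_total: int
    p_comb: float | None = None
    passes_filters: bool = False
    transcript_id: str | None = None
    gene_id: str | None = None
    biotype: str | None = None
    region: str = "unassigned"
    fpkm: float | None = None
    affinity: float | None = None


def score_sites(
    sites: Sequence[DeletionSite],
    pwm: SeedPWM,
    genome: Mapping[str, str],
) -> list[BindingSite]:
    """Extract windows for candidate sites and score them against the PWM.

    Sites with out-of-bounds or N-containing windows are skipped (logged).
    Site intensity is the control-adjusted deletion total.
    """
    kept, windows = extract_windows(sites, genome)
    out: list[BindingSite] = []
    n_with_n = 0
    for site, window in zip(kept, windows):
        if "N" in window:
            n_with_n += 1
            continue
        out.append(
            BindingSite(
                contig=site.contig,
                pos=site.pos,
                strand=site.strand,
                window_seq=window,
                score=score_window(pwm, window),
                intensity=site.del_total,
                del_by_rep=site.del_by_rep,
                cov_by_rep=site.cov_by_rep,
                del_total=site.del_total,
                cov_total=site.cov_total,
                p_comb=site.p_comb,
            )
        )
    if n_with_n:
        logger.info("excluded %d sites with N in window", n_with_n)
    return out


def high_confidence_filter(
    sites: Iterable[BindingSite],
    threshold: float,
    min_del_total: float = 3,
    min_rep_del: int = 1,
    min_cov_total: int = 6,
    min_rep_cov: int = 2,
) -> list[BindingSite]:
    """Set ``passes_filters`` on each site.

    A site passes iff score > threshold (strict), total deletions >= 3 with
    at least 1 in every replicate, and total overlapping reads >= 6 with at
    least 2 in every replicate.
    """
    out = []
    for site in sites:
        site.passes_filters = (
            site.score > threshold
            and site.del_total >= min_del_total
            and all(d >= min_rep_del for d in site.del_by_rep)
            and site.cov_total >= min_cov_total
            and all(c >= min_rep_cov for c in site.cov_by_rep)
        )
        out.append(site)
    return out


def affinity_weights(
    sites: Iterable[BindingSite],
    expression: Mapping[str, float],
    floor: float = 0.1,
) -> list[BindingSite]:
    """Expression-normalized affinity: intensity / max(FPKM, floor).

    Sites on transcripts absent from the expression table keep affinity None
    and are excluded downstream from the weighted logo (logged count).
    """
    if floor <= 0:
        raise ValueError("expression floor must be positive")
    missing = 0
    out = []
    for site in sites:
        if site.transcript_id is not None and site.transcript_id in expression:
            site.fpkm = float(expression[site.transcript_id])
            site.affinity = site.intensity / max(site.fpkm, floor)
        else:
            site.affinity = None
            missing += 1
        out.append(site)
    if missing:
        logger.info("%d sites lack expression values; affinity undefined", missing)
    return out


def weighted_logo(sites: Sequence[BindingSite]) -> np.ndarray:
    """4x7 affinity-weighted letter matrix rescaled so the maximum entry is 1."""
    usable = [s for s in sites if s.affinity is not None]
    if not usable:
        raise ValueError("no sites with defined affinity")
    weights = np.zeros((4, WINDOW), dtype=float)
    total = 0.0
    for site in usable:
        codes = _encode(site.window_seq)
        weights[codes, np.arange(WINDOW)] += site.affinity
        total += site.affinity
    weights /= total
    return weights / weights.max()
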