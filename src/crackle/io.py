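"""Readers and writers for the package's tabular interchange formats."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motif import ALPHABET, BindingSite, SeedPWM, WINDOW

LIBRARY_SIZE_ROW = "library_size"


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into a dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    """TSV with columns transcript_id, fpkm."""
    out: dict[str, float] = {}
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            out[row["transcript_id"]] = float(row["fpkm"])
    return out


def sites_to_dataframe(sites: Sequence[BindingSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append(
            {
                "contig": s.contig,
                "pos0": s.pos,
                "strand": s.strand,
                "window_seq": s.window_seq,
                "score": s.score,
                "intensity": s.intensity,
                "del_total": s.del_total,
                "cov_total": s.cov_total,
                "del_by_rep": ",".join(str(v) for v in s.del_by_rep),
                "cov_by_rep": ",".join(str(v) for v in s.cov_by_rep),
                "p_comb": s.p_comb,
                "passes_filters": s.passes_filters,
                "transcript_id": s.transcript_id,
                "gene_id": s.gene_id,
                "biotype": s.biotype,
                "region": s.region,
                "fpkm": s.fpkm,
                "affinity": s.affinity,
            }
        )
    return pd.DataFrame(rows)


def write_sites_tsv(sites: Sequence[BindingSite], path: str | Path) -> None:
    sites_to_dataframe(sites).to_csv(path, sep="\t", index=False)


def write_sites_bed(sites: Sequence[BindingSite], path: str | Path) -> None:
    """BED6+ rows: name=transcript id, score=PWM score x100 rounded, then
    del_total, cov_total, p_comb, affinity, passes_filters."""
    with open(path, "w") as handle:
        for s in sites:
            name = s.transcript_id or "."
            affinity = "" if s.affinity is None else f"{s.affinity:.6g}"
            p_comb = "" if s.p_comb is None else f"{s.p_comb:.6g}"
            handle.write(
                f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{name}\t"
                f"{round(s.score * 100)}\t{s.strand}\t{s.del_total:.6g}\t"
                f"{s.cov_total}\t{p_comb}\t{affinity}\t{int(s.passes_filters)}\n"
            )


def write_pwm_tsv(pwm: SeedPWM, path: str | Path) -> None:
    """4x7 frequency matrix; rows are A,C,G,U, columns pos1..pos7."""
    frame = pd.DataFrame(
        pwm.freq, index=list(ALPHABET), columns=[f"pos{j + 1}" for j in range(WINDOW)]
    )
    frame.index.name = "base"
    frame.to_csv(path, sep="\t", float_format="%.8g")


def read_pwm_tsv(path: str | Path, pseudocount: float = 0.0) -> SeedPWM:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    freq = frame.loc[list(ALPHABET)].to_numpy(dtype=float)
    return SeedPWM(
        freq=freq, background=np.full(4, 0.25), pseudocount=pseudocount,
        n_seed=0,
    )


def write_logo_tsv(logo: np.ndarray, path: str | Path) -> None:
    frame = pd.DataFrame(
        logo, index=list(ALPHABET), columns=[f"pos{j + 1}" for j in range(WINDOW)]
    )
    frame.index.name = "base"
    frame.to_csv(path, sep="\t", float_format="%.8g")


def write_weights_tsv(weights: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("key\tweight_pct\n")
        for key in sorted(weights, key=lambda k: (-weights[k], k)):
            handle.write(f"{key}\t{weights[key]:.6g}\n")


def write_metaprofile_tsv(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_counts_tsv(
    counts: pd.DataFrame,
    path: str | Path,
    lib_sizes: Mapping[str, float] | None = None,
) -> None:
    """Genes x samples TSV; an optional `library_size` row carries nominal depths."""
    frame = counts.copy()
    if lib_sizes is not None:
        frame = pd.concat(
            [pd.DataFrame([lib_sizes], index=[LIBRARY_SIZE_ROW]), frame]
        )
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, float] | None]:
    """Read a count matrix, splitting off the `library_size` row when present."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    lib_sizes = None
    if LIBRARY_SIZE_ROW in frame.index:
        lib_sizes = {c: float(v) for c, v in frame.loc[LIBRARY_SIZE_ROW].items()}
        frame = frame.drop(index=LIBRARY_SIZE_ROW)
    return frame, lib_sizes


def read_truth_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """Truth sites as (contig, pos0, strand) triples."""
    out = []
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            strand = fields[5] if len(fields) > 5 else "+"
            out.append((fields[0], int(fields[1]), strand))
    return out


def write_json(payload, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
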