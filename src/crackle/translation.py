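"""Translation-efficiency statistics and molecule-stoichiometry arithmetic.

Global TE is the ratio of the polysome absorbance area to the 80S (monosome)
area on a sucrose-gradient trace.  Gene-level TE is the polysomal-to-total
abundance ratio; delta-TE is its log2 change between conditions.  Target-set
enrichment uses the one-sided hypergeometric tail.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

AVOGADRO = 6.02214076e23


@dataclass
class AbsorbanceTrace:
    """A254 absorbance along a gradient, with labeled boundary intervals."""

    position: np.ndarray
    a254: np.ndarray
    boundaries: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.a254 = np.asarray(self.a254, dtype=float)
        if self.position.shape != self.a254.shape:
            raise ValueError("position and absorbance arrays differ in shape")
        if np.any(np.diff(self.position) <= 0):
            raise ValueError("positions must be strictly increasing")

    def area(self, label: str) -> float:
        if label not in self.boundaries:
            raise KeyError(f"no boundary labeled {label!r}")
        lo, hi = self.boundaries[label]
        mask = (self.position >= lo) & (self.position <= hi)
        return float(np.trapezoid(self.a254[mask], self.position[mask]))


def global_te(
    trace: AbsorbanceTrace,
    polysome_label: str = "polysomes",
    monosome_label: str = "80S",
) -> float:
    """Polysome area divided by the non-translating 80S area (trapezoidal)."""
    mono = trace.area(monosome_label)
    if mono <= 0:
        raise ValueError("80S area is zero; cannot form the TE ratio")
    return trace.area(polysome_label) / mono


def gene_te_qpcr(pol_fc: float, tot_fc: float) -> float:
    """Gene-specific TE: polysomal fold change over total fold change."""
    if pol_fc <= 0 or tot_fc <= 0:
        raise ValueError("fold changes must be positive")
    return pol_fc / tot_fc


def _cpm(counts: pd.DataFrame, lib_sizes: Mapping[str, float] | None) -> pd.DataFrame:
    if lib_sizes is None:
        sizes = counts.sum(axis=0)
    else:
        sizes = pd.Series({c: float(lib_sizes[c]) for c in counts.columns})
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(sizes, axis=1) * 1e6


def delta_te_table(
    pol_counts: pd.DataFrame,
    tot_counts: pd.DataFrame,
    ctrl: str = "ctrl",
    case: str = "case",
    pol_lib_sizes: Mapping[str, float] | None = None,
    tot_lib_sizes: Mapping[str, float] | None = None,
    min_cpm: float = 1.0,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene delta-TE with an up/down/unchanged classification.

    Counts are CPM-normalized per library (explicit library sizes when given,
    column sums otherwise).  Genes below ``min_cpm`` in any library are
    excluded; |delta_te| >= ``threshold`` defines the changed classes.
    """
    if set(pol_counts.index) != set(tot_counts.index):
        raise ValueError("polysomal and total matrices carry different gene sets")
    tot_counts = tot_counts.loc[pol_counts.index]
    pol = _cpm(pol_counts[[ctrl, case]].astype(float), pol_lib_sizes)
    tot = _cpm(tot_counts[[ctrl, case]].astype(float), tot_lib_sizes)
    table = pd.DataFrame(
        {
            "pol_ctrl_cpm": pol[ctrl],
            "pol_case_cpm": pol[case],
            "tot_ctrl_cpm": tot[ctrl],
            "tot_case_cpm": tot[case],
        }
    )
    keep = (table >= min_cpm).all(axis=1)
    table = table[keep].copy()
    table["te_ctrl"] = table["pol_ctrl_cpm"] / table["tot_ctrl_cpm"]
    table["te_case"] = table["pol_case_cpm"] / table["tot_case_cpm"]
    table["delta_te"] = np.log2(table["te_case"] / table["te_ctrl"])
    table["te_class"] = "unchanged"
    table.loc[table["delta_te"] >= threshold, "te_class"] = "up"
    table.loc[table["delta_te"] <= -threshold, "te_class"] = "down"
    return table


def target_enrichment(
    target_set: set, class_set: set, universe: set
) -> tuple[float, float]:
    """Fold enrichment of a target set within a class, with hypergeometric p.

    fold = (|overlap| / |class|) / (|targets| / |universe|).  The p-value is
    the one-sided over-representation tail P(X >= overlap) when fold >= 1 and
    the complementary under-representation tail P(X <= overlap) otherwise.
    """
    if not universe:
        raise ValueError("universe is empty")
    class_set = set(class_set) & set(universe)
    target_set = set(target_set) & set(universe)
    if not class_set:
        raise ValueError("class set is empty")
    if not target_set:
        raise ValueError("target set is empty")
    n_universe = len(universe)
    n_targets = len(target_set)
    n_class = len(class_set)
    overlap = len(target_set & class_set)
    fold = (overlap / n_class) / (n_targets / n_universe)
    dist = stats.hypergeom(n_universe, n_targets, n_class)
    if fold >= 1.0:
        p = float(dist.sf(overlap - 1))
    else:
        p = float(dist.cdf(overlap))
    return fold, p


@dataclass
class StoichiometryEstimate:
    """Calibration-curve estimate of molecules per cell for >=1 species."""

    standards: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    molecules_per_cell: dict[str, float] = field(default_factory=dict)

    def ratio(self, numerator: str, denominator: str) -> float:
        return molecule_ratio(
            self.molecules_per_cell[numerator], self.molecules_per_cell[denominator]
        )


def fit_standard_curve(
    standards: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Least-squares line OD = slope * ng + intercept through the standards."""
    if len(standards) < 2:
        raise ValueError("at least two calibration standards are required")
    ng = np.array([s[0] for s in standards], dtype=float)
    od = np.array([s[1] for s in standards], dtype=float)
    slope, intercept = np.polyfit(ng, od, 1)
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    return float(slope), float(intercept)


def infer_amount_ng(slope: float, intercept: float, sample_od: float) -> float:
    """Invert the calibration line: ng = (OD - intercept) / slope."""
    return (sample_od - intercept) / slope


def stoichiometry(
    standards: Sequence[tuple[float, float]],
    sample_od: Mapping[str, float],
    molar_mass_g: Mapping[str, float],
    cells: float,
) -> StoichiometryEstimate:
    """Molecules per cell for each species from a shared calibration curve.

    ``molar_mass_g`` holds molar masses in g/mol; nanogram amounts convert to
    molecule counts via Avogadro's number, then divide by cell count.
    """
    if cells <= 0:
        raise ValueError("cell count must be positive")
    slope, intercept = fit_standard_curve(standards)
    molecules: dict[str, float] = {}
    for species, od in sample_od.items():
        ng = infer_amount_ng(slope, intercept, od)
        moles = ng * 1e-9 / molar_mass_g[species]
        molecules[species] = moles * AVOGADRO / cells
    return StoichiometryEstimate(
        standards=tuple((float(a), float(b)) for a, b in standards),
        slope=slope,
        intercept=intercept,
        molecules_per_cell=molecules,
    )


def molecule_ratio(molecules_a: float, molecules_b: float) -> float:
    """Per-cell molecule ratio of two species, reported to two decimals."""
    if molecules_b <= 0:
        raise ValueError("denominator molecule count must be positive")
    return round(molecules_a / molecules_b, 2)


def write_trace_tsv(trace: AbsorbanceTrace, path: str | Path) -> None:
    """TSV with `#boundary label lo hi` header comments, then position/a254."""
    with open(path, "w", newline="") as handle:
        for label, (lo, hi) in trace.boundaries.items():
            handle.write(f"#boundary\t{label}\t{lo:.6g}\t{hi:.6g}\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["position", "a254"])
        for pos, val in zip(trace.position, trace.a254):
            writer.writerow([f"{pos:.6g}", f"{val:.8g}"])


def read_trace_tsv(path: str | Path) -> AbsorbanceTrace:
    boundaries: dict[str, tuple[float, float]] = {}
    positions: list[float] = []
    values: list[float] = []
    with open(path) as handle:
        header_seen = False
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("#boundary"):
                _, label, lo, hi = line.split("\t")
                boundaries[label] = (float(lo), float(hi))
                continue
            if not line:
                continue
            if not header_seen:
                header_seen = True  # position\ta254 header row
                continue
            pos, val = line.split("\t")
            positions.append(float(pos))
            values.append(float(val))
    return AbsorbanceTrace(
        position=np.array(positions), a254=np.array(values), boundaries=boundaries
    )
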