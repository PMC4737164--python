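"""NMR chemical-shift-perturbation combination and significance mapping.

Backbone amide 1H/15N peaks move on titration of a ligand; in fast exchange
the observed position is the population-weighted average of free and bound
states.  Per-residue 1H and 15N differences are combined as

    d_combined = sqrt(ddH**2 + (alpha * ddN)**2)

with alpha = 0.20 for glycine and 0.14 for every other residue type,
reflecting the larger 15N shift range of Gly.  Residues whose combined shift
exceeds the mean plus one standard deviation over all assigned residues are
flagged as the putative binding surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CSPRecord",
    "AMINO_ACIDS",
    "alpha_for",
    "combined_shift",
    "significant_residues",
    "titration_endpoint",
    "SignificanceResult",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

ALPHA_GLY = 0.20
ALPHA_OTHER = 0.14


def alpha_for(residue_type: str) -> float:
    """Nitrogen scaling factor: 0.20 for glycine, 0.14 otherwise."""
    aa = residue_type.strip().upper()
    if len(aa) != 1 or aa not in AMINO_ACIDS:
        raise ValueError(f"unknown one-letter residue type {residue_type!r}")
    return ALPHA_GLY if aa == "G" else ALPHA_OTHER


def combined_shift(delta_H: float, delta_N: float, residue_type: str) -> float:
    """Combined 1H/15N chemical shift difference (ppm).

    ``sqrt(delta_H**2 + (alpha * delta_N)**2)``; non-negative and even in
    both arguments.
    """
    if not (math.isfinite(delta_H) and math.isfinite(delta_N)):
        raise ValueError("shift differences must be finite")
    a = alpha_for(residue_type)
    return math.hypot(delta_H, a * delta_N)


@dataclass
class CSPRecord:
    """Per-residue shift differences between free and bound states."""

    residue_id: int
    residue_type: str
    delta_H: float = float("nan")  # ppm
    delta_N: float = float("nan")  # ppm
    assigned: bool = True
    combined: float = field(init=False)

    def __post_init__(self) -> None:
        if self.assigned:
            self.combined = combined_shift(self.delta_H, self.delta_N, self.residue_type)
        else:
            self.combined = float("nan")

    @property
    def alpha(self) -> float:
        return alpha_for(self.residue_type)


class SignificanceResult(NamedTuple):
    flagged: frozenset  # residue ids strictly above threshold
    threshold: float  # ppm, mean + 1 sample SD
    mean: float
    sd: float


def significant_residues(records: Sequence[CSPRecord]) -> SignificanceResult:
    """Residues with combined shift above mean + 1 SD of assigned residues.

    Prolines (no backbone amide) and unassigned residues are excluded from
    the statistic.  The sample (n-1) standard deviation is used.  The
    comparison is strict, so a residue exactly at the threshold — including
    the all-equal degenerate case where SD = 0 — is never flagged.
    """
    usable = [r for r in records if r.assigned and r.residue_type.upper() != "P"]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 assigned non-proline residues, got {len(usable)}")
    shifts = np.array([r.combined for r in usable])
    mean = float(shifts.mean())
    sd = float(shifts.std(ddof=1))
    threshold = mean + sd
    flagged = frozenset(r.residue_id for r in usable if r.combined > threshold)
    return SignificanceResult(flagged=flagged, threshold=threshold, mean=mean, sd=sd)


def titration_endpoint(series: pd.DataFrame) -> list[CSPRecord]:
    """Per-residue shift differences between the final titration point and free.

    ``series`` is a long-format table with columns ``ratio`` (ligand/protein
    molar ratio; 0 = free state), ``residue_id``, ``residue_type``,
    ``H_ppm`` and ``N_ppm``.  Differences are taken between the highest
    ratio present and the free state.  Residues missing (or with NaN peaks)
    at either end are returned as unassigned records.
    """
    required = {"ratio", "residue_id", "residue_type", "H_ppm", "N_ppm"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"titration table missing columns: {sorted(missing)}")
    ratios = series["ratio"].unique()
    if 0 not in ratios:
        raise ValueError("titration series must contain the free state (ratio 0)")
    if len(ratios) < 2:
        raise ValueError("titration series needs the free state and >= 1 titration point")
    endpoint = ratios.max()

    free = series[series["ratio"] == 0].set_index("residue_id")
    bound = series[series["ratio"] == endpoint].set_index("residue_id")
    records: list[CSPRecord] = []
    for rid in sorted(set(free.index) | set(bound.index)):
        rtype = str((free if rid in free.index else bound).loc[rid, "residue_type"])
        if rid not in free.index or rid not in bound.index:
            records.append(CSPRecord(residue_id=int(rid), residue_type=rtype, assigned=False))
            continue
        dh = float(bound.loc[rid, "H_ppm"]) - float(free.loc[rid, "H_ppm"])
        dn = float(bound.loc[rid, "N_ppm"]) - float(free.loc[rid, "N_ppm"])
        if math.isnan(dh) or math.isnan(dn):
            records.append(CSPRecord(residue_id=int(rid), residue_type=rtype, assigned=False))
        else:
            records.append(CSPRecord(residue_id=int(rid), residue_type=rtype, delta_H=dh, delta_N=dn))
    return records
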