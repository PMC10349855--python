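"""Chemical shift perturbation mapping and ambiguous restraint generation.

CSPs compare backbone amide positions in 1H-15N correlation spectra of the
free and ligand-bound protein.  The combined shift per residue is

    ddelta = sqrt(ddelta_H^2 + (alpha * ddelta_N)^2)

with alpha = 0.2 scaling the nitrogen dimension to the proton one.  Residues
whose combined shift exceeds a threshold (default 0.08 ppm, strict
inequality) are taken as binding-site reporters; when no high-resolution
complex structure exists for a domain they are converted into ambiguous
heavy-atom distance restraints (default 4 +/- 1 Angstrom) to a window of
partner nucleotides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, EmptyOverlapError

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["residue_number", "residue_name", "dH_ppm", "dN_ppm", "intensity"]


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited peak table (residue_number, residue_name, dH_ppm,
    dN_ppm, intensity[, flag])."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["residue_number"].duplicated().any():
        raise ValueError(f"{path}: duplicate residue numbers")
    return df


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def compute_csp(
    free: pd.DataFrame, bound: pd.DataFrame, alpha: float = 0.2
) -> pd.DataFrame:
    """Combined amide CSP per residue shared between the two tables.

    Residues missing from either table (unassigned, or broadened beyond
    detection in the bound state) are omitted from the profile and logged;
    rows flagged ``unassigned``/``overlapped`` in a ``flag`` column are
    likewise excluded.

    Returns a DataFrame (residue_number, delta_delta) with ``alpha`` in
    ``.attrs``.
    """

    def usable(df: pd.DataFrame) -> pd.DataFrame:
        if "flag" in df.columns:
            bad = df["flag"].astype(str).isin(["unassigned", "overlapped"])
            return df[~bad]
        return df

    f = usable(free).set_index("residue_number")
    b = usable(bound).set_index("residue_number")
    shared = f.index.intersection(b.index)
    if len(shared) == 0:
        raise EmptyOverlapError("free and bound tables share no residues")
    dropped = sorted(set(f.index).symmetric_difference(b.index))
    if dropped:
        logger.info("CSP: %d residues present in only one table: %s", len(dropped), dropped)
    dH = b.loc[shared, "dH_ppm"].to_numpy() - f.loc[shared, "dH_ppm"].to_numpy()
    dN = b.loc[shared, "dN_ppm"].to_numpy() - f.loc[shared, "dN_ppm"].to_numpy()
    dd = np.sqrt(dH**2 + (alpha * dN) ** 2)
    out = pd.DataFrame(
        {"residue_number": shared.to_numpy(dtype=int), "delta_delta": dd}
    ).sort_values("residue_number", ignore_index=True)
    out.attrs["alpha"] = alpha
    return out


def select_above_threshold(profile: pd.DataFrame, threshold: float = 0.08) -> list[int]:
    """Residues with delta_delta strictly above the threshold, ascending."""
    if len(profile) == 0:
        raise EmptyInputError("empty CSP profile")
    hits = profile.loc[profile["delta_delta"] > threshold, "residue_number"]
    return sorted(int(r) for r in hits)


@dataclass(frozen=True)
class AmbiguousRestraint:
    """Flat-bottom ambiguous distance restraint: any heavy atom of one protein
    residue to any heavy atom of any nucleotide in the partner set."""

    protein_residue: int
    rna_positions: tuple[int, ...]
    target: float = 4.0  # Angstrom
    halfwidth: float = 1.0  # Angstrom
    weight: float = 1.0
    protein_chain: str = "A"
    rna_chain: str = "R"

    def __post_init__(self) -> None:
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be positive")
        if not self.rna_positions:
            raise ValueError("empty nucleotide set")

    @property
    def lower(self) -> float:
        return self.target - self.halfwidth

    @property
    def upper(self) -> float:
        return self.target + self.halfwidth


def build_ambiguous_restraints(
    residues: Iterable[int],
    rna_positions: Sequence[int],
    target: float = 4.0,
    halfwidth: float = 1.0,
    protein_chain: str = "A",
    rna_chain: str = "R",
) -> list[AmbiguousRestraint]:
    """One ambiguous restraint per selected protein residue against the whole
    nucleotide window (heavy atoms only)."""
    residues = sorted(set(int(r) for r in residues))
    if not residues:
        raise EmptyInputError("no residues selected")
    if not rna_positions:
        raise EmptyInputError("no RNA positions")
    rp = tuple(int(p) for p in rna_positions)
    return [
        AmbiguousRestraint(
            protein_residue=r,
            rna_positions=rp,
            target=target,
            halfwidth=halfwidth,
            protein_chain=protein_chain,
            rna_chain=rna_chain,
        )
        for r in residues
    ]


def write_csp_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index=False)


def read_csp_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ambiguous_restraints(
    restraints: Sequence[AmbiguousRestraint], path: str | Path
) -> None:
    rows = [
        {
            "protein_chain": r.protein_chain,
            "protein_residue": r.protein_residue,
            "rna_chain": r.rna_chain,
            "rna_positions": ",".join(str(p) for p in r.rna_positions),
            "target": r.target,
            "halfwidth": r.halfwidth,
            "weight": r.weight,
        }
        for r in restraints
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ambiguous_restraints(path: str | Path) -> list[AmbiguousRestraint]:
    df = pd.read_csv(path, sep="\t")
    return [
        AmbiguousRestraint(
            protein_residue=int(row.protein_residue),
            rna_positions=tuple(int(p) for p in str(row.rna_positions).split(",")),
            target=float(row.target),
            halfwidth=float(row.halfwidth),
            weight=float(row.weight),
            protein_chain=str(row.protein_chain),
            rna_chain=str(row.rna_chain),
        )
        for row in df.itertuples()
    ]
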